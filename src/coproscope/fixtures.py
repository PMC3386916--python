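"""Packaged study fixtures: taxon occurrence counts and radiocarbon dates.

Two small TSVs ship inside the package: a per-taxon occurrence table (how
many of the 35 coprolites each taxon was found in, per proxy, with
min/mean/max percent of pollen sum for pollen taxa) and the 12 dated
coprolites (CRA, error and published 95.4% calibrated ranges).  They back
the acceptance tests and the occurrence-arithmetic checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tables import TaxonRegistry


def _data_path(name: str):
    return resources.files("coproscope.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """Per-taxon occurrence fixture.

    Columns: group, family, taxon, dna_k/dna_n (clone-library detections out
    of 8 sampled coprolites), pollen_k/pollen_n (presence out of 35),
    pollen_min/mean/max (percent of pollen sum), macro (kind:count pairs).
    """
    with resources.as_file(_data_path("table1_occurrence.tsv")) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    for col in ("dna_k", "dna_n", "pollen_k", "pollen_n"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    for col in ("pollen_min", "pollen_mean", "pollen_max"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def load_table2() -> pd.DataFrame:
    """Dated-coprolite fixture: 12 rows of CRA, error and published ranges."""
    with resources.as_file(_data_path("table2_dates.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def fixture_registry() -> TaxonRegistry:
    """Occurrence fixture reshaped as a TaxonRegistry (detection sets only)."""
    df = load_table1()
    rows = []
    for _, r in df.iterrows():
        detected = []
        if pd.notna(r["dna_k"]) and r["dna_k"] > 0:
            detected.append("DNA")
        if pd.notna(r["pollen_k"]) and r["pollen_k"] > 0:
            detected.append("pollen")
        if str(r["macro"]).strip():
            detected.append("macrofossil")
        rows.append(
            {
                "taxon": r["taxon"],
                "family": r["family"],
                "growth_form": r["group"],
                "detected_by": ",".join(detected),
                "macrofossil_kind": str(r["macro"]),
                "habitats": "",
            }
        )
    return TaxonRegistry(pd.DataFrame(rows))


def emit_fixture_table1() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The packaged occurrence table and the dated-coprolite table."""
    return load_table1(), load_table2()


def occurrence_count(taxon: str, proxy: str = "pollen") -> tuple[int, int]:
    """(k, n) occurrence for one taxon under one proxy from the fixture."""
    df = load_table1()
    row = df[df["taxon"] == taxon]
    if row.empty:
        raise KeyError(f"taxon {taxon!r} not in fixture")
    r = row.iloc[0]
    if proxy == "pollen":
        k, n = r["pollen_k"], r["pollen_n"]
    elif proxy == "DNA":
        k, n = r["dna_k"], r["dna_n"]
    else:
        raise ValueError("proxy must be 'pollen' or 'DNA'")
    if pd.isna(k):
        raise KeyError(f"taxon {taxon!r} has no {proxy} occurrence data")
    return int(k), int(n)
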