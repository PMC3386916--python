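"""Pollen count matrices, taxon registries and derived summary tables.

The central objects are :class:`PollenMatrix` (raw pollen/spore counts per
coprolite, plus the exotic-spike counts used for concentration estimates) and
:class:`TaxonRegistry` (per-taxon metadata: which proxies detected it, growth
form, habitat memberships and prevalence-index factor scores).  All I/O is
plain UTF-8 TSV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROXIES = ("DNA", "pollen", "macrofossil")

GROWTH_FORMS = (
    "tree/shrub",
    "liane",
    "dicot herb",
    "monocot",
    "fern",
    "bryophyte",
    "other",
)

#: Pollen-sum convention: terrestrial pollen and fern/lycophyte spores are
#: in-sum; the exotic spike and coprophilous fungal spores are out-of-sum.
OUT_OF_SUM_DEFAULT = ("Lycopodium spike", "Sporormiella")


class ZeroPollenSumError(ValueError):
    """Raised when a coprolite has no in-sum pollen counts at all."""


@dataclass
class PollenMatrix:
    """Coprolite x taxon raw counts with spike and mass metadata.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, index = coprolite IDs,
        columns = taxon IDs.
    spike_observed
        Exotic-spike grains counted per coprolite (index-aligned to counts).
    spike_total
        Number of exotic spores added to every sample.
    sample_mass_g
        Subsample dry mass per coprolite in grams.
    in_pollen_sum
        Boolean per taxon; out-of-sum columns (spike, coprophilous fungi)
        are excluded from percentage denominators.
    """

    counts: pd.DataFrame
    spike_observed: pd.Series
    spike_total: int
    sample_mass_g: pd.Series
    in_pollen_sum: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("pollen counts must be non-negative")
        if self.spike_total <= 0:
            raise ValueError("spike_total must be positive")
        self.spike_observed = self.spike_observed.reindex(self.counts.index)
        self.sample_mass_g = self.sample_mass_g.reindex(self.counts.index)
        self.in_pollen_sum = self.in_pollen_sum.reindex(self.counts.columns).fillna(True)

    @property
    def coprolites(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def pollen_sum_totals(self) -> pd.Series:
        """Per-coprolite totals over in-sum taxa only."""
        insum = self.counts.loc[:, self.in_pollen_sum.values.astype(bool)]
        return insum.sum(axis=1)

    def low_count_flags(self, minimum: int = 250) -> pd.Series:
        """Coprolites whose in-sum total falls below the counting standard."""
        return self.pollen_sum_totals() < minimum


@dataclass
class TaxonRegistry:
    """Per-taxon metadata table.

    ``table`` columns: taxon, family, growth_form, detected_by
    (comma-joined subset of DNA/pollen/macrofossil), macrofossil_kind,
    habitats (comma-joined), epi_mode, epi_production, epi_dispersal,
    epi_include, in_pollen_sum.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"taxon", "detected_by"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"registry missing columns: {sorted(missing)}")
        self.table = self.table.set_index("taxon", drop=False) if self.table.index.name != "taxon" else self.table

    @property
    def taxa(self) -> list[str]:
        return list(self.table["taxon"])

    def detected_by(self, taxon: str) -> frozenset[str]:
        raw = self.table.loc[taxon, "detected_by"]
        if not isinstance(raw, str) or not raw.strip():
            return frozenset()
        parts = frozenset(p.strip() for p in raw.split(",") if p.strip())
        unknown = parts - set(PROXIES)
        if unknown:
            raise ValueError(f"unknown proxies {sorted(unknown)} for taxon {taxon!r}")
        return parts

    def habitats(self, taxon: str) -> frozenset[str]:
        raw = self.table.loc[taxon, "habitats"] if "habitats" in self.table.columns else ""
        if not isinstance(raw, str) or not raw.strip():
            return frozenset()
        return frozenset(p.strip() for p in raw.split(",") if p.strip())

    def epi_factors(self, taxon: str):
        from .epi import EPIFactors  # local import avoids a cycle

        row = self.table.loc[taxon]
        return EPIFactors(
            mode=int(row["epi_mode"]),
            production=int(row["epi_production"]),
            dispersal=int(row["epi_dispersal"]),
        )


@dataclass
class OccurrenceSummary:
    """Per-taxon presence counts with min/mean/max percent of pollen sum."""

    table: pd.DataFrame  # columns: taxon, n_present, n_total, min_pct, mean_pct, max_pct

    def __post_init__(self) -> None:
        t = self.table
        if ((t["n_present"] < 0) | (t["n_present"] > t["n_total"])).any():
            raise ValueError("n_present must lie in [0, n_total]")


# ---------------------------------------------------------------------------
# summary arithmetic


def occurrence_percent(k: int, n: int) -> float:
    """Occurrence percentage 100*k/n, rounded half-up to one decimal place."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    pct = Decimal(100) * Decimal(k) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percentages(matrix: PollenMatrix) -> pd.DataFrame:
    """Percent-of-pollen-sum matrix over in-sum taxa.

    The denominator for each coprolite is the sum of counts over taxa with
    ``in_pollen_sum=True``; spike and coprophilous-fungus columns never enter
    the sum and are dropped from the output.
    """
    mask = matrix.in_pollen_sum.values.astype(bool)
    insum = matrix.counts.loc[:, mask]
    totals = insum.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ZeroPollenSumError(
            f"zero pollen-sum total for coprolite(s): {', '.join(map(str, zero.index))}"
        )
    return insum.div(totals, axis=0) * 100.0


def concentration(count: int, spike_observed: int, spike_total: int, mass_g: float) -> float:
    """Palynomorph concentration in grains per gram dry weight."""
    if spike_observed < 1:
        raise ValueError("undefined concentration: spike_observed must be >= 1")
    if mass_g <= 0:
        raise ValueError("mass_g must be positive")
    return (count / spike_observed) * spike_total / mass_g


def loi_organic(dry_mass_g: float, ash_mass_g: float) -> float:
    """Organic content by loss on ignition, percent of dry mass."""
    if dry_mass_g <= 0:
        raise ValueError("dry mass must be positive")
    if ash_mass_g < 0 or ash_mass_g > dry_mass_g:
        raise ValueError("ash mass must lie in [0, dry mass]")
    return 100.0 * (dry_mass_g - ash_mass_g) / dry_mass_g


def occurrence_summary(matrix: PollenMatrix) -> OccurrenceSummary:
    """Presence counts and min/mean/max percentages per in-sum taxon."""
    pct = percentages(matrix)
    n_total = len(matrix.coprolites)
    rows = []
    for taxon in pct.columns:
        col = pct[taxon]
        rows.append(
            {
                "taxon": taxon,
                "n_present": int((matrix.counts[taxon] > 0).sum()),
                "n_total": n_total,
                "min_pct": float(col.min()),
                "mean_pct": float(col.mean()),
                "max_pct": float(col.max()),
            }
        )
    return OccurrenceSummary(pd.DataFrame(rows))


def multiproxy_venn(registry: TaxonRegistry) -> dict[frozenset[str], int]:
    """Counts of taxa per non-empty proxy subset (the 7 Venn cells).

    Every taxon lands in exactly one cell — the one matching its full
    detection set — so cell counts sum to the registry size (taxa with an
    empty detection set are rejected by the registry contract).
    """
    cells: dict[frozenset[str], int] = {}
    for r in range(1, 4):
        from itertools import combinations

        for combo in combinations(PROXIES, r):
            cells[frozenset(combo)] = 0
    for taxon in registry.taxa:
        det = registry.detected_by(taxon)
        if not det:
            raise ValueError(f"taxon {taxon!r} has an empty detection set")
        cells[det] += 1
    return cells


def habitat_tally(
    registry: TaxonRegistry, valid_habitats: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-habitat taxon counts and fractions of all registry taxa.

    Taxa may belong to several habitats, so counts can sum to more than the
    registry size.  Fractions use the total number of registry taxa as the
    denominator.
    """
    n = len(registry.taxa)
    tallies: dict[str, int] = {h: 0 for h in (valid_habitats or [])}
    for taxon in registry.taxa:
        for h in sorted(registry.habitats(taxon)):
            if valid_habitats is not None and h not in valid_habitats:
                raise ValueError(
                    f"unknown habitat {h!r}; valid names: {', '.join(valid_habitats)}"
                )
            tallies[h] = tallies.get(h, 0) + 1
    rows = [
        {"habitat": h, "n_taxa": c, "fraction_pct": float(occurrence_percent(c, n)) if n else 0.0}
        for h, c in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=["habitat", "n_taxa", "fraction_pct"])


# ---------------------------------------------------------------------------
# TSV I/O

_SPIKE_KEY = "# spike_total="


def write_pollen_matrix(matrix: PollenMatrix, path: str | Path) -> None:
    path = Path(path)
    df = matrix.counts.copy()
    df.insert(0, "coprolite", matrix.counts.index)
    df["spike_observed"] = matrix.spike_observed.values
    df["sample_mass_g"] = matrix.sample_mass_g.values
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_SPIKE_KEY}{matrix.spike_total}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_pollen_matrix(
    path: str | Path, out_of_sum: Iterable[str] = OUT_OF_SUM_DEFAULT
) -> PollenMatrix:
    path = Path(path)
    spike_total = 1
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith(_SPIKE_KEY):
            spike_total = int(first[len(_SPIKE_KEY):].strip())
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(io.StringIO(body), sep="\t")
    df = df.set_index("coprolite")
    df.index.name = None
    spike_observed = df.pop("spike_observed").astype(int)
    mass = df.pop("sample_mass_g").astype(float)
    counts = df.astype(int)
    in_sum = pd.Series(
        [t not in set(out_of_sum) for t in counts.columns], index=counts.columns
    )
    return PollenMatrix(counts, spike_observed, spike_total, mass, in_sum)


def write_registry(registry: TaxonRegistry, path: str | Path) -> None:
    registry.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_registry(path: str | Path) -> TaxonRegistry:
    df = pd.read_csv(path, sep="\t", dtype={"taxon": str}, keep_default_na=False)
    for col in ("epi_mode", "epi_production", "epi_dispersal"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return TaxonRegistry(df)


def write_occurrence_summary(summary: OccurrenceSummary, path: str | Path) -> None:
    df = summary.table.copy()
    for col in ("min_pct", "mean_pct", "max_pct"):
        df[col] = df[col].map(lambda v: float(Decimal(repr(v)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
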