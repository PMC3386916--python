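"""End-to-end orchestration: counts -> percentages -> EPI -> clustering ->
aDNA assignment -> calibration -> deposition events -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd
import yaml

from . import adna, clustering, epi, events as events_mod, radiocarbon, tables

log = logging.getLogger("coproscope")


@dataclass
class PipelineConfig:
    pollen_counts: str = "pollen_counts.tsv"
    registry: str = "taxon_registry.tsv"
    moa_refs: str = "moa_refs.fasta"
    moa_amplicons: str = "moa_amplicons.fasta"
    rbcl_refs: str = "rbcl_refs.fasta"
    rbcl_sidecar: str = "rbcl_refs.tsv"
    rbcl_clones: str = "rbcl_clones.fasta"
    ages: str = "ages.tsv"
    curve: str | None = None
    metric: str = "uncentered_pearson"
    linkage: str = "average"
    cluster_threshold: float = 0.1
    epi_margin: float = 0.0
    identity_threshold: float = 96.0
    hpd_level: float = 0.954
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.hpd_level < 1.0:
            raise ValueError("hpd_level must lie in (0, 1)")
        if not 0.0 <= self.identity_threshold <= 100.0:
            raise ValueError("identity_threshold must lie in [0, 100]")
        if self.cluster_threshold < 0 or self.epi_margin < 0:
            raise ValueError("thresholds must be non-negative")
        if self.metric not in clustering.METRICS:
            raise ValueError(f"metric must be one of {clustering.METRICS}")
        if self.linkage not in clustering.LINKAGES:
            raise ValueError(f"linkage must be one of {clustering.LINKAGES}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _read_fasta_map(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: PipelineConfig, in_dir: str | Path, out_dir: str | Path) -> dict:
    """Run every stage on a directory of inputs; returns the report dict.

    Stages that lack their inputs (e.g. no ages file, no curve) are skipped
    with a log message rather than failing, but a *referenced* missing file
    (a curve path that does not exist while ages are present) is an error.
    """
    config.validate()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name: str):
        log.info("stage: %s", name)
        report["stages"][name] = "ok"

    # --- pollen percentages and summaries
    stage("percentages")
    matrix = tables.read_pollen_matrix(in_dir / config.pollen_counts)
    registry = tables.read_registry(in_dir / config.registry)
    pct = tables.percentages(matrix)
    pct.to_csv(out_dir / "percentages.tsv", sep="\t", lineterminator="\n")
    summary = tables.occurrence_summary(matrix)
    tables.write_occurrence_summary(summary, out_dir / "occurrence_summary.tsv")
    report["n_coprolites"] = len(matrix.coprolites)
    report["n_taxa"] = len(matrix.taxa)

    # --- EPI representation calls
    stage("epi")
    reg = registry.table
    epi_cols = ["epi_mode", "epi_production", "epi_dispersal"]
    if not set(epi_cols) <= set(reg.columns):
        raise ValueError("registry lacks EPI factor columns (epi stage)")
    has_epi = reg.dropna(subset=epi_cols)
    epi_values = {
        t: epi.compute_epi(registry.epi_factors(t)) for t in has_epi["taxon"]
    }
    include = None
    if "epi_include" in reg.columns:
        include = [t for t in has_epi["taxon"] if bool(reg.loc[t, "epi_include"])]
    rep = epi.representation_table(pct, epi_values, margin=config.epi_margin, include=include)
    rep.to_csv(out_dir / "epi_representation.tsv", sep="\t", index=False, lineterminator="\n")
    report["n_over_represented"] = int((rep["call"] == "over").sum())

    # --- clustering
    stage("clustering")
    dist = clustering.assemblage_distance(pct, metric=config.metric)
    tree = clustering.hierarchical_cluster(dist, linkage=config.linkage)
    (out_dir / "assemblage_tree.nwk").write_text(tree.to_newick() + "\n")
    groups = clustering.group_assignments(tree, config.cluster_threshold)
    clustering.write_groups(groups, out_dir / "assemblage_groups.tsv")
    report["n_similar_groups"] = len(clustering.similar_groups(tree, config.cluster_threshold))

    # --- bird haplotypes
    haplotype_calls: dict[str, str] = {}
    moa_ref_path = in_dir / config.moa_refs
    amp_path = in_dir / config.moa_amplicons
    if moa_ref_path.exists() and amp_path.exists():
        stage("haplotypes")
        refs = adna.ReferenceSet.from_fasta(moa_ref_path, marker="control_region")
        refs.taxa = {rid: rid.split("_")[0] for rid in refs.records}
        amps = _read_fasta_map(amp_path)
        rows = []
        for cop, seq in sorted(amps.items()):
            call = adna.call_haplotype(cop, seq, refs)
            haplotype_calls[cop] = call.diagnostic_base
            rows.append(
                {
                    "coprolite": cop,
                    "species": call.species or "ambiguous",
                    "identity": round(call.identity, 2),
                    "haplotype": call.diagnostic_base,
                    "damage_consistent": call.damage_consistent,
                }
            )
        pd.DataFrame(rows).to_csv(
            out_dir / "haplotype_calls.tsv", sep="\t", index=False, lineterminator="\n"
        )
        report["n_haplotypes"] = len(set(haplotype_calls.values()))
    else:
        log.info("skipping haplotypes: no amplicon/reference FASTA")

    # --- plant clone assignment
    clone_path = in_dir / config.rbcl_clones
    if clone_path.exists() and (in_dir / config.rbcl_refs).exists():
        stage("clone_assignment")
        sidecar = in_dir / config.rbcl_sidecar
        refs = adna.ReferenceSet.from_fasta(
            in_dir / config.rbcl_refs, marker="rbcl",
            sidecar=sidecar if sidecar.exists() else None,
        )
        clones = _read_fasta_map(clone_path)
        assignments = adna.assign_clone_library(clones, refs, config.identity_threshold)
        adna.write_assignments(assignments, out_dir / "clone_assignments.tsv")
        report["n_clones_assigned"] = sum(a.assigned for a in assignments)
        report["n_unique_clones"] = len(adna.collapse_unique_clones(clones))
    else:
        log.info("skipping clone assignment: no clone/reference FASTA")

    # --- calibration
    calibrated: dict[str, radiocarbon.CalibratedDate] = {}
    ages_path = in_dir / config.ages
    if ages_path.exists():
        if config.curve is None:
            raise FileNotFoundError(
                "ages present but no calibration curve configured (set 'curve')"
            )
        curve_path = Path(config.curve)
        if not curve_path.is_absolute() and not curve_path.exists():
            curve_path = in_dir / config.curve
        if not curve_path.exists():
            raise FileNotFoundError(f"calibration curve file not found: {config.curve}")
        stage("calibration")
        curve = radiocarbon.load_curve(curve_path)
        ages = pd.read_csv(ages_path, sep="\t")
        for _, row in ages.iterrows():
            calibrated[str(row["coprolite"])] = radiocarbon.calibrate(
                float(row["cra"]), float(row["error"]), curve, level=config.hpd_level
            )
        radiocarbon.write_calibrations(calibrated, out_dir / "calibrated_ages.tsv")
        report["n_dated"] = len(calibrated)
    else:
        log.info("skipping calibration: no ages file")

    # --- deposition events and MNI
    stage("events")
    evts = events_mod.group_events(
        matrix.coprolites, groups, haplotype_calls, calibrated
    )
    individuals = events_mod.link_individuals(evts)
    events_mod.events_table(evts, individuals).to_csv(
        out_dir / "deposition_events.tsv", sep="\t", index=False, lineterminator="\n"
    )
    (out_dir / "report.txt").write_text(
        events_mod.narrative_report(evts, individuals)
    )
    report["n_events"] = len(evts)
    report["mni"] = events_mod.mni(individuals)

    with open(out_dir / "report.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    return report
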