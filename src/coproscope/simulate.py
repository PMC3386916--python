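"""Synthetic coprolite datasets with known ground truth.

The generator plants a small number of individual birds, each with a
Dirichlet diet profile over a subset of plant taxa and a fixed mtDNA
haplotype.  Each individual deposits one or more defecation events; each
event has one true calendar age and one or more coprolites.  Per coprolite,
pollen counts are multinomial draws whose expected proportions mix the
individual's diet with an ambient pollen rain proportional to each taxon's
environmental prevalence index:

    p_t = (1 - w) * diet_t + w * rain_t,    rain_t ∝ EPI_t

Clone libraries are multinomial draws over the diet (with per-sample
dropout) whose sequences are amplicon-length reference fragments carrying
independent per-site C->T damage.  Radiocarbon measurements are the
calibration curve evaluated at the true age plus Gaussian noise.  All draws
flow from one seeded generator, so a config reproduces its dataset exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables
from .adna import ReferenceSet
from .radiocarbon import CalibrationCurve
from .tables import PollenMatrix, TaxonRegistry

BASES = "ACGT"
_STOPLESS_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
]

HABITATS = tuple(f"H{i}" for i in range(1, 10))  # nine local communities
GROWTH_FORMS = ("tree/shrub", "liane", "dicot herb", "monocot", "fern", "bryophyte")

#: 1-based diagnostic site on the 31 bp bird amplicon; haplotypes differ
#: by a C/T state here.
DIAGNOSTIC_POSITION = 25


@dataclass
class SimConfig:
    n_individuals: int = 5
    events_per_individual: int = 1
    coprolites_per_event: int = 2
    n_taxa: int = 20
    diet_concentration: float = 1.0
    env_mixing_weight: float = 0.3
    count_depth: int = 300
    spike_total: int = 10000
    clone_library_size_range: tuple[int, int] = (16, 52)
    clone_dropout_prob: float = 1.0 / 3.0
    damage_rate: float = 0.01
    age_range_bp: tuple[float, float] = (700.0, 6400.0)
    age_error: float = 30.0
    seed: int = 0
    # knobs beyond the core generative story
    diet_subset_size: int = 6
    n_haplotypes: int = 2
    dated_fraction: float = 1.0
    macro_detect_prob: float = 0.4
    diet_epi_bias: str | None = None  # None = random subsets, "low" = low-EPI taxa
    rbcl_ref_length: int = 300
    amplicon_length: int = 95

    def validate(self) -> None:
        if self.n_individuals < 1 or self.events_per_individual < 1:
            raise ValueError("individual/event counts must be positive")
        if self.coprolites_per_event < 1:
            raise ValueError("coprolites_per_event must be >= 1")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if not 0.0 <= self.env_mixing_weight <= 1.0:
            raise ValueError("env_mixing_weight must lie in [0, 1]")
        for name in ("clone_dropout_prob", "damage_rate", "dated_fraction", "macro_detect_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.count_depth < 250:
            raise ValueError("count_depth must be >= 250 (counting standard)")
        if self.diet_concentration <= 0 or self.age_error <= 0 or self.spike_total <= 0:
            raise ValueError("diet_concentration, age_error, spike_total must be positive")
        lo, hi = self.clone_library_size_range
        if not 0 < lo <= hi:
            raise ValueError("invalid clone_library_size_range")
        if self.n_haplotypes < 1:
            raise ValueError("n_haplotypes must be >= 1")
        if self.diet_epi_bias not in (None, "low"):
            raise ValueError("diet_epi_bias must be None or 'low'")
        if self.rbcl_ref_length < self.amplicon_length + 6:
            raise ValueError("rbcl_ref_length too short for the amplicon")


@dataclass
class SimTruth:
    coprolite_individual: dict[str, str]
    coprolite_event: dict[str, str]
    individual_haplotype: dict[str, str]
    event_age: dict[str, float]
    diet: pd.DataFrame  # individuals x taxa dietary proportions
    epi: pd.Series  # taxon -> EPI value
    clone_taxa: dict[str, str]  # clone id -> true source taxon

    def __post_init__(self) -> None:
        for c, e in self.coprolite_event.items():
            if c not in self.coprolite_individual:
                raise ValueError(f"coprolite {c} has an event but no individual")
        events_per_cop = pd.Series(self.coprolite_event)
        if events_per_cop.index.has_duplicates:
            raise ValueError("a coprolite maps to more than one event")


@dataclass
class SimDataset:
    config: SimConfig
    pollen: PollenMatrix
    registry: TaxonRegistry
    moa_refs: ReferenceSet
    moa_amplicons: dict[str, str]  # coprolite -> 31 bp sequence
    rbcl_refs: ReferenceSet
    clone_libraries: dict[str, dict[str, str]]  # coprolite -> {clone id: seq}
    ages: pd.DataFrame  # coprolite, cra, error
    truth: SimTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables.write_pollen_matrix(self.pollen, out / "pollen_counts.tsv")
        tables.write_registry(self.registry, out / "taxon_registry.tsv")
        self.moa_refs.to_fasta(out / "moa_refs.fasta")
        self.rbcl_refs.to_fasta(out / "rbcl_refs.fasta")
        _write_sidecar(self.rbcl_refs, out / "rbcl_refs.tsv")
        _write_fasta_map(self.moa_amplicons, out / "moa_amplicons.fasta")
        merged = {
            f"{cop}|{cid}": seq
            for cop, lib in sorted(self.clone_libraries.items())
            for cid, seq in sorted(lib.items())
        }
        _write_fasta_map(merged, out / "rbcl_clones.fasta")
        self.ages.to_csv(out / "ages.tsv", sep="\t", index=False, lineterminator="\n")
        truth = {
            "coprolite_individual": self.truth.coprolite_individual,
            "coprolite_event": self.truth.coprolite_event,
            "individual_haplotype": self.truth.individual_haplotype,
            "event_age": self.truth.event_age,
            "clone_taxa": self.truth.clone_taxa,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        self.truth.diet.to_csv(out / "truth_diet.tsv", sep="\t", lineterminator="\n")


def _write_fasta_map(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sorted(seqs.items()):
            fh.write(f">{name}\n{seq}\n")


def _write_sidecar(refs: ReferenceSet, path: Path) -> None:
    rows = [
        {"id": rid, "taxon": refs.taxon_of(rid), "frame_offset": refs.frame_of(rid)}
        for rid in sorted(refs.records)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _random_stopless_seq(rng: np.random.Generator, length: int) -> str:
    n_codons = length // 3 + 1
    idx = rng.integers(0, len(_STOPLESS_CODONS), size=n_codons)
    return "".join(_STOPLESS_CODONS[i] for i in idx)[:length]


def _damage(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i, b in enumerate(out):
        if b == "C" and rng.random() < rate:
            out[i] = "T"
    return "".join(out)


def simulate_dataset(config: SimConfig, curve: CalibrationCurve | None = None) -> SimDataset:
    """Generate one complete dataset plus its ground truth.

    ``curve`` maps true calendar ages to expected 14C measurements; the
    default identity curve makes measured age = true age + noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if curve is None:
        lo, hi = config.age_range_bp
        curve = CalibrationCurve.identity(min(0.0, lo - 500), hi + 500)

    taxa = [f"T{i + 1:02d}" for i in range(config.n_taxa)]

    # prevalence factors and ambient pollen rain
    modes = rng.choice([1, 3], size=config.n_taxa)
    prods = rng.integers(1, 4, size=config.n_taxa)
    disps = rng.integers(1, 4, size=config.n_taxa)
    epi = pd.Series(modes * prods * disps, index=taxa, dtype=int)
    rain = epi.to_numpy(dtype=float)
    rain = rain / rain.sum()

    # individuals: diet subsets + Dirichlet profiles + haplotypes
    individuals = [f"I{i + 1}" for i in range(config.n_individuals)]
    subset_size = min(config.diet_subset_size, config.n_taxa)
    diet = pd.DataFrame(0.0, index=individuals, columns=taxa)
    low_order = np.argsort(epi.to_numpy(), kind="stable")
    for ind in individuals:
        if config.diet_epi_bias == "low":
            chosen = low_order[:subset_size]
        else:
            chosen = rng.choice(config.n_taxa, size=subset_size, replace=False)
        profile = rng.dirichlet(np.full(subset_size, config.diet_concentration))
        diet.loc[ind, [taxa[j] for j in chosen]] = profile

    base31 = "".join(rng.choice(list(BASES), size=31))
    hap_bases = ["C", "T", "A", "G"]
    hap_seqs: dict[str, str] = {}
    for h in range(config.n_haplotypes):
        s = list(base31)
        s[DIAGNOSTIC_POSITION - 1] = hap_bases[h % 4]
        if h >= 4:  # extra haplotypes vary a second site
            s[(h * 3) % 24] = hap_bases[(h // 4) % 4]
        hap_seqs[f"hap{h + 1}"] = "".join(s)
    individual_haplotype = {
        ind: f"hap{(i % config.n_haplotypes) + 1}" for i, ind in enumerate(individuals)
    }

    # bird reference set: one focal species carrying every haplotype, plus a
    # distinct decoy species several substitutions away
    moa_records: dict[str, str] = {}
    moa_taxa: dict[str, str] = {}
    for name, seq in hap_seqs.items():
        rid = f"species1_{name}"
        moa_records[rid] = seq
        moa_taxa[rid] = "species1"
    decoy = list(base31)
    for pos in (2, 9, 16, 29):
        decoy[pos] = BASES[(BASES.index(decoy[pos]) + 2) % 4]
    moa_records["species2_ref"] = "".join(decoy)
    moa_taxa["species2_ref"] = "species2"
    moa_refs = ReferenceSet(marker="control_region", records=moa_records, taxa=moa_taxa)

    # plant references: stop-free in frame 0, one amplicon window per taxon
    rbcl_records: dict[str, str] = {}
    rbcl_taxa: dict[str, str] = {}
    frames: dict[str, int] = {}
    amplicon_start: dict[str, int] = {}
    for t in taxa:
        rid = f"ref_{t}"
        rbcl_records[rid] = _random_stopless_seq(rng, config.rbcl_ref_length)
        rbcl_taxa[rid] = t
        frames[rid] = 0
        amplicon_start[t] = int(
            rng.integers(0, config.rbcl_ref_length - config.amplicon_length)
        )
    rbcl_refs = ReferenceSet(
        marker="rbcl", records=rbcl_records, taxa=rbcl_taxa, frame_offsets=frames
    )

    # deposition structure
    coprolite_individual: dict[str, str] = {}
    coprolite_event: dict[str, str] = {}
    event_age: dict[str, float] = {}
    n_events = config.n_individuals * config.events_per_individual
    lo, hi = config.age_range_bp
    spaced = np.linspace(lo, hi, n_events) if n_events > 1 else np.array([(lo + hi) / 2.0])
    order = rng.permutation(n_events)
    cop_ids: list[str] = []
    e = 0
    for i, ind in enumerate(individuals):
        for j in range(config.events_per_individual):
            event = f"E{e + 1}"
            event_age[event] = float(round(spaced[order[e]], 1))
            for k in range(config.coprolites_per_event):
                cop = f"C{len(cop_ids) + 1:03d}"
                cop_ids.append(cop)
                coprolite_individual[cop] = ind
                coprolite_event[cop] = event
            e += 1

    # pollen counts
    counts = pd.DataFrame(0, index=cop_ids, columns=taxa, dtype=int)
    for cop in cop_ids:
        ind = coprolite_individual[cop]
        p = (1.0 - config.env_mixing_weight) * diet.loc[ind].to_numpy() \
            + config.env_mixing_weight * rain
        p = p / p.sum()
        counts.loc[cop] = rng.multinomial(config.count_depth, p)
    spike_observed = pd.Series(
        rng.integers(30, 81, size=len(cop_ids)), index=cop_ids, dtype=int
    )
    mass = pd.Series(
        np.round(rng.uniform(0.08, 0.54, size=len(cop_ids)), 3), index=cop_ids
    )
    pollen = PollenMatrix(
        counts=counts,
        spike_observed=spike_observed,
        spike_total=config.spike_total,
        sample_mass_g=mass,
        in_pollen_sum=pd.Series(True, index=taxa),
    )

    # bird amplicons: the individual's haplotype sequence, undamaged
    moa_amplicons = {
        cop: hap_seqs[individual_haplotype[coprolite_individual[cop]]]
        for cop in cop_ids
    }

    # clone libraries: multinomial over diet, per-sample dropout, C->T damage
    clone_libraries: dict[str, dict[str, str]] = {}
    clone_taxa: dict[str, str] = {}
    lo_sz, hi_sz = config.clone_library_size_range
    for cop in cop_ids:
        if rng.random() < config.clone_dropout_prob:
            continue
        ind = coprolite_individual[cop]
        probs = diet.loc[ind].to_numpy()
        size = int(rng.integers(lo_sz, hi_sz + 1))
        draws = rng.multinomial(size, probs)
        lib: dict[str, str] = {}
        n = 0
        for t, cnt in zip(taxa, draws):
            start = amplicon_start[t]
            frag = rbcl_records[f"ref_{t}"][start:start + config.amplicon_length]
            for _ in range(cnt):
                n += 1
                cid = f"cl{n:03d}"
                lib[cid] = _damage(rng, frag, config.damage_rate)
                clone_taxa[f"{cop}|{cid}"] = t
        clone_libraries[cop] = lib

    # radiocarbon measurements
    dated = [cop for cop in cop_ids if rng.random() < config.dated_fraction]
    rows = []
    for cop in dated:
        true_age = event_age[coprolite_event[cop]]
        mu = float(curve.mu(np.array([true_age]))[0])
        cra = round(mu + rng.normal(0.0, config.age_error), 1)
        rows.append({"coprolite": cop, "cra": cra, "error": config.age_error})
    ages = pd.DataFrame(rows, columns=["coprolite", "cra", "error"])

    # registry assembled from truth: pollen presence, DNA detections, and
    # macrofossil survival of dietary taxa
    dna_detected = set(clone_taxa.values())
    dietary = set(diet.columns[(diet > 0).any(axis=0)])
    reg_rows = []
    for idx, t in enumerate(taxa):
        detected = []
        if t in dna_detected:
            detected.append("DNA")
        if (counts[t] > 0).any():
            detected.append("pollen")
        macro = t in dietary and rng.random() < config.macro_detect_prob
        if macro:
            detected.append("macrofossil")
        n_hab = int(rng.integers(1, 4))
        habs = sorted(rng.choice(HABITATS, size=n_hab, replace=False))
        reg_rows.append(
            {
                "taxon": t,
                "family": f"Fam{(idx % 7) + 1}",
                "growth_form": GROWTH_FORMS[idx % len(GROWTH_FORMS)],
                "detected_by": ",".join(detected),
                "macrofossil_kind": "seed" if macro else "",
                "habitats": ",".join(habs),
                "epi_mode": int(modes[idx]),
                "epi_production": int(prods[idx]),
                "epi_dispersal": int(disps[idx]),
                "epi_include": True,
                "in_pollen_sum": True,
            }
        )
    registry = TaxonRegistry(pd.DataFrame(reg_rows))

    truth = SimTruth(
        coprolite_individual=coprolite_individual,
        coprolite_event=coprolite_event,
        individual_haplotype=individual_haplotype,
        event_age=event_age,
        diet=diet,
        epi=epi,
        clone_taxa=clone_taxa,
    )
    return SimDataset(
        config=config,
        pollen=pollen,
        registry=registry,
        moa_refs=moa_refs,
        moa_amplicons=moa_amplicons,
        rbcl_refs=rbcl_refs,
        clone_libraries=clone_libraries,
        ages=ages,
        truth=truth,
    )
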