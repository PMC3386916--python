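"""Assignment of short ancient-DNA amplicons to reference taxa.

Two markers are handled: a 31 bp mitochondrial control-region fragment that
identifies the depositing bird species and its haplotype (a C/T state at
amplicon position 25), and 95 bp chloroplast rbcL fragments from clone
libraries that identify dietary plants against full-length references.
Assignment is nearest-reference percent identity with an explicit ambiguity
state — a deliberate, deterministic stand-in for Bayesian phylogenetic
placement.  Post-mortem damage shows up as C<->T differences and as internal
stop codons in the conserved protein-coding marker; both are flagged, never
silently corrected.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC = set("ACGTRYSWKMBDHVN")
STOP_CODONS = {"TAA", "TAG", "TGA"}

#: 1-based position of the species-internal diagnostic site on the 31 bp
#: control-region amplicon.
DIAGNOSTIC_POSITION = 25

HAPLOTYPE_AMPLICON_LENGTH = 31


@dataclass
class ReferenceSet:
    """Named reference sequences for one marker.

    For protein-coding markers each record may carry a reading-frame offset
    (0/1/2 = offset of the first complete codon from sequence start).
    """

    marker: str
    records: dict[str, str]
    taxa: dict[str, str] = field(default_factory=dict)  # record id -> taxon label
    frame_offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.records) != len(set(self.records)):
            raise ValueError("reference IDs must be unique")
        self.records = {k: v.upper() for k, v in self.records.items()}

    def taxon_of(self, ref_id: str) -> str:
        return self.taxa.get(ref_id, ref_id)

    def frame_of(self, ref_id: str) -> int:
        return self.frame_offsets.get(ref_id, 0)

    @classmethod
    def from_fasta(cls, path: str | Path, marker: str = "",
                   sidecar: str | Path | None = None) -> "ReferenceSet":
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        taxa: dict[str, str] = {}
        frames: dict[str, int] = {}
        if sidecar is not None:
            import pandas as pd

            side = pd.read_csv(sidecar, sep="\t")
            for _, row in side.iterrows():
                taxa[str(row["id"])] = str(row.get("taxon", row["id"]))
                if "frame_offset" in side.columns:
                    frames[str(row["id"])] = int(row["frame_offset"])
        return cls(marker=marker or Path(path).stem, records=records,
                   taxa=taxa, frame_offsets=frames)

    def to_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(s), id=i, description="") for i, s in sorted(self.records.items())]
        SeqIO.write(recs, str(path), "fasta")


@dataclass(frozen=True)
class HaplotypeCall:
    query_id: str
    species: str | None  # None = ambiguous (tied references)
    identity: float
    diagnostic_base: str
    damage_consistent: bool
    tied_species: tuple[str, ...] = ()


@dataclass(frozen=True)
class CloneAssignment:
    clone_id: str
    best_taxon: str
    identity: float
    ref_span: tuple[int, int]  # aligned [start, end) on the reference
    internal_stop: bool
    assigned: bool


def _validate_seq(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - IUPAC
    if bad:
        raise ValueError(f"{name} contains non-IUPAC characters: {sorted(bad)}")
    return seq


def hamming_identity(a: str, b: str) -> float:
    """Percent identity of equal-length sequences; N positions excluded."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    pairs = [(x, y) for x, y in zip(a.upper(), b.upper()) if x != "N" and y != "N"]
    if not pairs:
        return 0.0
    matches = sum(x == y for x, y in pairs)
    return 100.0 * matches / len(pairs)


def call_haplotype(query_id: str, query: str, refs: ReferenceSet) -> HaplotypeCall:
    """Species/haplotype call for one 31 bp control-region amplicon.

    Best species by maximum Hamming identity; ties across species produce an
    ambiguous call (species=None) — some species pairs are genuinely
    indistinguishable at this fragment.  The diagnostic base is read at
    amplicon position 25 (1-based).
    """
    query = _validate_seq(query, f"query {query_id}")
    if len(query) != HAPLOTYPE_AMPLICON_LENGTH:
        raise ValueError(
            f"query {query_id}: length {len(query)} != {HAPLOTYPE_AMPLICON_LENGTH}"
        )
    if not refs.records:
        raise ValueError("empty reference set")
    scores: dict[str, float] = {}
    for rid, rseq in refs.records.items():
        if len(rseq) < HAPLOTYPE_AMPLICON_LENGTH:
            raise ValueError(f"reference {rid} shorter than amplicon")
        scores[rid] = hamming_identity(query, rseq[:HAPLOTYPE_AMPLICON_LENGTH])
    best = max(scores.values())
    best_ids = sorted(r for r, s in scores.items() if s == best)
    best_species = sorted({refs.taxon_of(r) for r in best_ids})
    species = best_species[0] if len(best_species) == 1 else None
    ref_seq = refs.records[best_ids[0]][:HAPLOTYPE_AMPLICON_LENGTH]
    mismatches = [
        (q, r) for q, r in zip(query, ref_seq) if q != r and q != "N" and r != "N"
    ]
    damage_consistent = bool(mismatches) and all(
        {q, r} == {"C", "T"} for q, r in mismatches
    )
    return HaplotypeCall(
        query_id=query_id,
        species=species,
        identity=best,
        diagnostic_base=query[DIAGNOSTIC_POSITION - 1],
        damage_consistent=damage_consistent,
        tied_species=tuple(best_species) if species is None else (),
    )


def _make_aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    # semi-global: reference overhangs (end gaps in the clone) are free
    aligner.left_deletion_score = 0.0
    aligner.right_deletion_score = 0.0
    return aligner


def _alignment_identity(alignment) -> tuple[float, tuple[int, int]]:
    """Percent identity over aligned columns within the clone's span.

    Reference overhangs beyond the clone are excluded; internal gap columns
    count against identity; columns with N on either side are excluded from
    both numerator and denominator.
    """
    t, q = str(alignment[0]), str(alignment[1])
    # trim columns where the clone (query) has leading/trailing end gaps
    first = 0
    while first < len(q) and q[first] == "-":
        first += 1
    last = len(q)
    while last > first and q[last - 1] == "-":
        last -= 1
    matches = 0
    columns = 0
    for x, y in zip(t[first:last], q[first:last]):
        if x == "N" or y == "N":
            continue
        columns += 1
        if x == y and x != "-":
            matches += 1
    identity = 100.0 * matches / columns if columns else 0.0
    ref_start = sum(1 for c in t[:first] if c != "-")
    ref_end = ref_start + sum(1 for c in t[first:last] if c != "-")
    return identity, (ref_start, ref_end)


def detect_stop_codon(fragment: str, frame_offset: int) -> bool:
    """True iff a stop codon occupies a complete in-frame codon.

    ``frame_offset`` is the offset of the first complete codon within the
    fragment.  A stop split across the trailing partial codon is not
    internal and returns False.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame offset must be 0, 1 or 2")
    fragment = fragment.upper()
    if len(fragment) - frame_offset < 3:
        raise ValueError("fragment too short to contain one full codon")
    for i in range(frame_offset, len(fragment) - 2, 3):
        if fragment[i:i + 3] in STOP_CODONS:
            return True
    return False


def assign_clone(
    clone_id: str,
    clone: str,
    refs: ReferenceSet,
    threshold: float = 96.0,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    ignore_stop: bool = False,
) -> CloneAssignment:
    """Nearest-reference assignment of one rbcL clone.

    The clone is semi-globally aligned against every reference; the best
    scoring reference wins (ties broken by reference ID for determinism).
    The clone is assigned iff identity strictly exceeds ``threshold`` and no
    internal stop codon interrupts the reading frame (damage signal).
    """
    clone = _validate_seq(clone, f"clone {clone_id}")
    if not 60 <= len(clone) <= 150:
        raise ValueError(f"clone {clone_id}: length {len(clone)} outside [60, 150]")
    if not refs.records:
        raise ValueError("empty reference set")
    aligner = _make_aligner(match, mismatch, gap)
    best: tuple[float, str, float, tuple[int, int]] | None = None
    for rid in sorted(refs.records):
        alignment = aligner.align(refs.records[rid], clone)[0]
        identity, span = _alignment_identity(alignment)
        key = (alignment.score, identity)
        if best is None or key > (best[0], best[2]):
            best = (alignment.score, rid, identity, span)
    _score, rid, identity, span = best
    frame = (3 - (span[0] - refs.frame_of(rid)) % 3) % 3
    try:
        internal_stop = detect_stop_codon(clone, frame)
    except ValueError:
        internal_stop = False
    assigned = identity > threshold and (ignore_stop or not internal_stop)
    return CloneAssignment(
        clone_id=clone_id,
        best_taxon=refs.taxon_of(rid),
        identity=identity,
        ref_span=span,
        internal_stop=internal_stop,
        assigned=assigned,
    )


def assign_clone_library(
    clones: Mapping[str, str], refs: ReferenceSet, threshold: float = 96.0, **kw
) -> list[CloneAssignment]:
    return [assign_clone(cid, seq, refs, threshold, **kw) for cid, seq in sorted(clones.items())]


def collapse_unique_clones(
    clones: Mapping[str, str]
) -> list[tuple[str, int, tuple[str, ...]]]:
    """Exact-sequence deduplication preserving provenance.

    Returns (sequence, multiplicity, sorted clone IDs) per unique sequence,
    ordered by descending multiplicity then sequence.
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for cid, seq in clones.items():
        groups[seq.upper()].append(cid)
    out = [(seq, len(ids), tuple(sorted(ids))) for seq, ids in groups.items()]
    return sorted(out, key=lambda r: (-r[1], r[0]))


def write_assignments(assignments: Sequence[CloneAssignment], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "clone": a.clone_id,
            "best_taxon": a.best_taxon,
            "identity": round(a.identity, 2),
            "ref_start": a.ref_span[0],
            "ref_end": a.ref_span[1],
            "internal_stop": a.internal_stop,
            "assigned": a.assigned,
        }
        for a in assignments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
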