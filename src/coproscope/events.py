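"""Grouping coprolites into deposition events and individual birds.

Three lines of evidence are combined: shared (highly similar) pollen
assemblage group, identical mtDNA haplotype, and overlapping calibrated-age
ranges.  Two coprolites join one deposition event iff they share an
assemblage group, their haplotypes do not conflict, and their age ranges do
not conflict; the transitive closure of that relation defines events.
Missing evidence is permissive at the event level (it cannot veto a merge)
but linking events into one individual requires a haplotype match AND an
age-range overlap — distinct-assemblage events of one bird on different
days can only be tied together by those two signals.  The minimum number of
individuals (MNI) is the number of individual groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .radiocarbon import CalibratedDate, intersect_hpd, ranges_overlap


@dataclass
class DepositionEvent:
    event_id: str
    coprolites: tuple[str, ...]
    haplotype: str | None
    assemblage_group: str | None
    age_consensus: list[tuple[int, int]] = field(default_factory=list)
    evidence: dict[str, bool] = field(default_factory=dict)


@dataclass
class IndividualGroup:
    individual_id: str
    event_ids: tuple[str, ...]
    haplotype: str | None
    rationale: str
    probable: bool = False


class _UnionFind:
    def __init__(self, items: Sequence[str]):
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller label becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo

    def groups(self) -> list[list[str]]:
        out: dict[str, list[str]] = {}
        for item in self.parent:
            out.setdefault(self.find(item), []).append(item)
        return [sorted(v) for _, v in sorted(out.items())]


def _ages_compatible(
    a: str, b: str, dates: Mapping[str, CalibratedDate], strict: bool
) -> bool:
    da, db = dates.get(a), dates.get(b)
    if da is None or db is None:
        return not strict
    return ranges_overlap(da, db)


def group_events(
    coprolites: Sequence[str],
    assemblage_groups: Mapping[str, str],
    haplotype_calls: Mapping[str, str],
    calibrated_dates: Mapping[str, CalibratedDate],
    strict: bool = False,
) -> list[DepositionEvent]:
    """Partition coprolites into deposition events.

    ``assemblage_groups`` maps coprolite -> group label (singletons carry
    their own label).  ``haplotype_calls`` and ``calibrated_dates`` may be
    partial.  With ``strict=True`` an undated coprolite cannot chain two
    dated ones together (both members of a joining pair must be dated).
    Conflicting haplotypes inside one assemblage group always split the
    group, never merge.
    """
    coprolites = sorted(coprolites)
    uf = _UnionFind(coprolites)
    for i, a in enumerate(coprolites):
        for b in coprolites[i + 1:]:
            ga, gb = assemblage_groups.get(a), assemblage_groups.get(b)
            if ga is None or gb is None or ga != gb:
                continue
            ha, hb = haplotype_calls.get(a), haplotype_calls.get(b)
            if ha is not None and hb is not None and ha != hb:
                continue  # haplotype veto
            if not _ages_compatible(a, b, calibrated_dates, strict):
                continue
            uf.union(a, b)

    events: list[DepositionEvent] = []
    raw_groups = uf.groups()
    # enforce the haplotype invariant: split any event with conflicting calls
    split_groups: list[list[str]] = []
    for grp in raw_groups:
        haps = {haplotype_calls.get(c) for c in grp} - {None}
        if len(haps) <= 1:
            split_groups.append(grp)
        else:
            for h in sorted(haps):
                split_groups.append([c for c in grp if haplotype_calls.get(c) == h])
            untyped = [c for c in grp if haplotype_calls.get(c) is None]
            if untyped:
                split_groups.append(untyped)
    for k, grp in enumerate(sorted(split_groups, key=lambda g: g[0]), start=1):
        haps = {haplotype_calls.get(c) for c in grp} - {None}
        dated = [calibrated_dates[c] for c in grp if c in calibrated_dates]
        groups_present = {assemblage_groups.get(c) for c in grp} - {None}
        events.append(
            DepositionEvent(
                event_id=f"E{k}",
                coprolites=tuple(grp),
                haplotype=next(iter(haps)) if haps else None,
                assemblage_group=next(iter(groups_present)) if len(groups_present) == 1 else None,
                age_consensus=intersect_hpd(dated) if dated else [],
                evidence={
                    "assemblage": len(grp) > 1,
                    "haplotype": len(haps) == 1 and len(grp) > 1,
                    "age": len(dated) > 1,
                },
            )
        )
    return events


def link_individuals(events: Sequence[DepositionEvent]) -> list[IndividualGroup]:
    """Merge events into (probable) individuals.

    Two events belong to one individual iff both carry the same non-missing
    haplotype AND their age-consensus ranges overlap.  Events that never
    merge each stand for (at least) one individual.
    """
    ids = [e.event_id for e in events]
    by_id = {e.event_id: e for e in events}
    uf = _UnionFind(ids)
    linked: set[str] = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ea, eb = by_id[a], by_id[b]
            if ea.haplotype is None or ea.haplotype != eb.haplotype:
                continue
            if not ea.age_consensus or not eb.age_consensus:
                continue
            if _interval_sets_overlap(ea.age_consensus, eb.age_consensus):
                uf.union(a, b)
                linked.update((a, b))
    out: list[IndividualGroup] = []
    for k, grp in enumerate(uf.groups(), start=1):
        members = [by_id[g] for g in grp]
        hap = members[0].haplotype
        if len(grp) > 1:
            rationale = "same haplotype and overlapping calibrated ages across distinct assemblage events"
        else:
            rationale = "single event"
        out.append(
            IndividualGroup(
                individual_id=f"I{k}",
                event_ids=tuple(grp),
                haplotype=hap,
                rationale=rationale,
                probable=len(grp) > 1,
            )
        )
    return out


def _interval_sets_overlap(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> bool:
    for ao, ay in a:
        for bo, by in b:
            if max(ay, by) <= min(ao, bo):
                return True
    return False


def mni(individuals: Sequence[IndividualGroup]) -> int:
    """Minimum number of individuals = number of individual groups."""
    return len(individuals)


def events_table(
    events: Sequence[DepositionEvent], individuals: Sequence[IndividualGroup]
) -> pd.DataFrame:
    event_of = {c: e.event_id for e in events for c in e.coprolites}
    individual_of = {
        eid: ind.individual_id for ind in individuals for eid in ind.event_ids
    }
    rows = []
    for e in events:
        for c in e.coprolites:
            rows.append(
                {
                    "coprolite": c,
                    "event": e.event_id,
                    "individual": individual_of.get(e.event_id, ""),
                    "haplotype": e.haplotype or "",
                    "assemblage_group": e.assemblage_group or "",
                    "evidence_assemblage": e.evidence.get("assemblage", False),
                    "evidence_haplotype": e.evidence.get("haplotype", False),
                    "evidence_age": e.evidence.get("age", False),
                }
            )
    return pd.DataFrame(rows).sort_values("coprolite").reset_index(drop=True)


def narrative_report(
    events: Sequence[DepositionEvent], individuals: Sequence[IndividualGroup]
) -> str:
    """Human-readable accumulation summary."""
    lines = [f"Deposition events: {len(events)}"]
    for e in events:
        cons = "; ".join(f"{o}-{y}" for o, y in e.age_consensus) or "undated"
        lines.append(
            f"  {e.event_id}: {', '.join(e.coprolites)} "
            f"(haplotype {e.haplotype or '?'}; age consensus {cons})"
        )
    lines.append(f"Individual groups: {len(individuals)} (MNI = {len(individuals)})")
    for ind in individuals:
        tag = " [probable]" if ind.probable else ""
        lines.append(
            f"  {ind.individual_id}: events {', '.join(ind.event_ids)}{tag} — {ind.rationale}"
        )
    return "\n".join(lines) + "\n"
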