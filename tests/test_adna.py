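import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coproscope.adna import (
    DIAGNOSTIC_POSITION,
    ReferenceSet,
    assign_clone,
    call_haplotype,
    collapse_unique_clones,
    detect_stop_codon,
    hamming_identity,
)

RNG = np.random.default_rng(42)


def random_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def moa_refs():
    rng = np.random.default_rng(8)
    base = random_seq(31, rng)
    s1 = list(base)
    s1[DIAGNOSTIC_POSITION - 1] = "C"
    s2 = list(base)
    for pos in (1, 8, 15, 28):
        s2[pos] = "ACGT"[("ACGT".index(s2[pos]) + 1) % 4]
    return ReferenceSet(
        marker="cr",
        records={"sp1_a": "".join(s1), "sp2_a": "".join(s2)},
        taxa={"sp1_a": "sp1", "sp2_a": "sp2"},
    )


class TestCallHaplotype:
    def test_exact_match(self, moa_refs):
        q = moa_refs.records["sp1_a"]
        call = call_haplotype("q1", q, moa_refs)
        assert call.species == "sp1"
        assert call.identity == 100.0
        assert not call.damage_consistent

    def test_ct_pair_same_species_different_haplotype(self, moa_refs):
        q_c = moa_refs.records["sp1_a"]
        q_t = q_c[:DIAGNOSTIC_POSITION - 1] + "T" + q_c[DIAGNOSTIC_POSITION:]
        call_c = call_haplotype("qc", q_c, moa_refs)
        call_t = call_haplotype("qt", q_t, moa_refs)
        assert call_c.species == call_t.species == "sp1"
        assert call_c.diagnostic_base == "C" and call_t.diagnostic_base == "T"
        assert call_t.damage_consistent  # single C<->T difference from best ref

    def test_equidistant_tie_is_ambiguous(self):
        refs = ReferenceSet(
            marker="cr",
            records={"r1": "A" * 31, "r2": "A" * 30 + "G"},
            taxa={"r1": "spA", "r2": "spB"},
        )
        q = "A" * 30 + "T"  # final base mismatches both references
        call = call_haplotype("q", q, refs)
        assert call.species is None
        assert call.tied_species == ("spA", "spB")

    def test_tie_within_one_species_is_not_ambiguous(self, moa_refs):
        refs = ReferenceSet(
            marker="cr",
            records={"r1": "A" * 31, "r2": "A" * 30 + "G"},
            taxa={"r1": "spA", "r2": "spA"},
        )
        call = call_haplotype("q", "A" * 30 + "T", refs)
        assert call.species == "spA"

    def test_length_validation(self, moa_refs):
        with pytest.raises(ValueError, match="length"):
            call_haplotype("q", "ACGT", moa_refs)

    def test_non_iupac_rejected(self, moa_refs):
        with pytest.raises(ValueError, match="non-IUPAC"):
            call_haplotype("q", "Z" * 31, moa_refs)

    def test_n_positions_excluded(self):
        refs = ReferenceSet(marker="cr", records={"r": "A" * 31})
        q = "N" + "A" * 30
        assert call_haplotype("q", q, refs).identity == 100.0


@pytest.fixture(scope="module")
def rbcl_refs():
    rng = np.random.default_rng(5)
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
              if a + b + c not in ("TAA", "TAG", "TGA")]
    records = {}
    for i in range(4):
        seq = "".join(codons[j] for j in rng.integers(0, len(codons), size=100))
        records[f"ref{i}"] = seq
    return ReferenceSet(marker="rbcl", records=records,
                        taxa={f"ref{i}": f"taxon{i}" for i in range(4)},
                        frame_offsets={f"ref{i}": 0 for i in range(4)})


class TestAssignClone:
    def test_exact_substring_assigned(self, rbcl_refs):
        clone = rbcl_refs.records["ref1"][30:125]
        a = assign_clone("c", clone, rbcl_refs)
        assert a.identity == 100.0
        assert a.best_taxon == "taxon1"
        assert a.assigned
        assert a.ref_span == (30, 125)

    def test_five_mismatches_below_threshold(self, rbcl_refs):
        clone = list(rbcl_refs.records["ref1"][0:95])
        # five transversion mismatches that cannot create stop codons or
        # shift the best hit to another reference
        for pos in (10, 25, 40, 55, 70):
            clone[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[clone[pos]]
        a = assign_clone("c", "".join(clone), rbcl_refs)
        assert a.identity == pytest.approx(100 * 90 / 95, abs=0.01)  # 94.7
        assert not a.assigned
        assert a.best_taxon == "taxon1"  # best reference still reported

    def test_internal_stop_flagged(self, rbcl_refs):
        seq = rbcl_refs.records["ref2"][0:95]
        damaged = seq[:30] + "TAA" + seq[33:]  # in-frame internal stop
        a = assign_clone("c", damaged, rbcl_refs)
        assert a.internal_stop
        assert not a.assigned

    def test_threshold_monotonicity(self, rbcl_refs):
        rng = np.random.default_rng(77)
        clones = {}
        for i in range(12):
            src = rbcl_refs.records[f"ref{i % 4}"]
            start = int(rng.integers(0, 200))
            clone = list(src[start:start + 95])
            for _ in range(int(rng.integers(0, 8))):
                p = int(rng.integers(0, 95))
                clone[p] = "ACGT"[int(rng.integers(0, 4))]
            clones[f"c{i}"] = "".join(clone)
        counts = []
        for thr in (80.0, 90.0, 96.0, 99.0):
            counts.append(
                sum(assign_clone(cid, s, rbcl_refs, thr, ignore_stop=True).assigned
                    for cid, s in clones.items())
            )
        assert counts == sorted(counts, reverse=True)

    def test_self_assignment(self):
        # references short enough to be queried against their own set
        rng = np.random.default_rng(3)
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                  if a + b + c not in ("TAA", "TAG", "TGA")]
        records = {
            f"r{i}": "".join(codons[j] for j in rng.integers(0, len(codons), size=32))[:95]
            for i in range(5)
        }
        refs = ReferenceSet(marker="rbcl", records=records)
        for rid, seq in records.items():
            a = assign_clone(rid, seq, refs)
            assert a.best_taxon == rid and a.identity == 100.0 and a.assigned

    def test_empty_reference_set(self):
        with pytest.raises(ValueError, match="empty"):
            assign_clone("c", "A" * 95, ReferenceSet(marker="rbcl", records={}))

    def test_length_contract(self, rbcl_refs):
        with pytest.raises(ValueError, match="length"):
            assign_clone("c", "A" * 59, rbcl_refs)


class TestDetectStopCodon:
    def test_no_stop(self):
        assert detect_stop_codon("ATGGCT", 0) is False

    def test_internal_taa(self):
        assert detect_stop_codon("ATGTAAGCT", 0) is True

    def test_stop_in_trailing_partial_codon_not_internal(self):
        # TA at the end cannot complete a codon -> not internal
        assert detect_stop_codon("ATGGCTTA", 0) is False

    def test_frame_offset(self):
        assert detect_stop_codon("ATAAGC", 1) is True  # TAA at offset 1
        assert detect_stop_codon("ATAAGC", 0) is False

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            detect_stop_codon("AT", 0)


class TestCollapseUniqueClones:
    def test_multiplicities(self):
        clones = {"a": "ACGT", "b": "ACGT", "c": "ACGT", "d": "GGGG"}
        out = collapse_unique_clones(clones)
        assert [(seq, mult) for seq, mult, _ in out] == [("ACGT", 3), ("GGGG", 1)]
        assert out[0][2] == ("a", "b", "c")

    def test_empty(self):
        assert collapse_unique_clones({}) == []

    @given(st.dictionaries(st.text("ab", min_size=1, max_size=6),
                           st.text("ACGT", min_size=4, max_size=8), max_size=20))
    @settings(max_examples=25, deadline=None)
    def test_unique_count_matches_set_oracle(self, clones):
        out = collapse_unique_clones(clones)
        assert len(out) == len({s.upper() for s in clones.values()})
        assert sum(m for _, m, _ in out) == len(clones)


class TestHammingIdentity:
    def test_symmetry_and_self(self):
        rng = np.random.default_rng(1)
        a, b = random_seq(40, rng), random_seq(40, rng)
        assert hamming_identity(a, b) == hamming_identity(b, a)
        assert hamming_identity(a, a) == 100.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming_identity("AC", "ACG")
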