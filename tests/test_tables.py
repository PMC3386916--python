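import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from coproscope import tables
from coproscope.tables import (
    PollenMatrix,
    TaxonRegistry,
    ZeroPollenSumError,
    concentration,
    habitat_tally,
    loi_organic,
    multiproxy_venn,
    occurrence_percent,
    occurrence_summary,
    percentages,
)


def make_matrix(counts: dict, in_sum=None, spike_obs=None, spike_total=10000, mass=None):
    df = pd.DataFrame(counts).T
    n = len(df)
    return PollenMatrix(
        counts=df,
        spike_observed=pd.Series(spike_obs or [50] * n, index=df.index),
        spike_total=spike_total,
        sample_mass_g=pd.Series(mass or [0.39] * n, index=df.index),
        in_pollen_sum=pd.Series(
            in_sum if in_sum is not None else [True] * df.shape[1], index=df.columns
        ),
    )


class TestPercentages:
    def test_symmetric_split(self):
        m = make_matrix({"c1": {"A": 125, "B": 125}})
        pct = percentages(m)
        assert pct.loc["c1", "A"] == pytest.approx(50.0)
        assert pct.loc["c1", "B"] == pytest.approx(50.0)

    def test_spike_excluded_from_sum(self):
        m = make_matrix({"c1": {"A": 250, "spike": 50}}, in_sum=[True, False])
        pct = percentages(m)
        assert pct.loc["c1", "A"] == pytest.approx(100.0)
        assert "spike" not in pct.columns

    def test_zero_sum_names_coprolite(self):
        m = make_matrix({"c1": {"A": 1}, "bad": {"A": 0}})
        with pytest.raises(ZeroPollenSumError, match="bad"):
            percentages(m)

    def test_rows_total_100(self):
        rng = np.random.default_rng(4)
        counts = {f"c{i}": {f"T{j}": int(x) for j, x in
                            enumerate(rng.integers(0, 60, size=8))}
                  for i in range(6)}
        for c in counts.values():
            c["T0"] += 1  # keep sums positive
        pct = percentages(make_matrix(counts))
        assert np.allclose(pct.sum(axis=1), 100.0, atol=0.01)

    def test_poaceae_style_minimum_reproduced(self):
        # a coprolite where one taxon sits at 0.7% of the pollen sum
        m = make_matrix({"c1": {"Poaceae": 7, "Other": 993},
                         "c2": {"Poaceae": 860, "Other": 140}})
        summary = occurrence_summary(m).table.set_index("taxon")
        assert round(summary.loc["Poaceae", "min_pct"], 1) == 0.7
        assert round(summary.loc["Poaceae", "max_pct"], 1) == 86.0


class TestOccurrencePercent:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(33, 35, 94.3), (35, 35, 100.0), (0, 35, 0.0), (8, 12, 66.7),
         (13, 35, 37.1), (34, 35, 97.1), (30, 35, 85.7)],
    )
    def test_values(self, k, n, expected):
        assert occurrence_percent(k, n) == expected

    def test_half_up_rounding(self):
        # 100*1/8 = 12.5 -> 12.5; 100*5/8 = 62.5 stays 62.5 at 1 dp,
        # but 100*1/16 = 6.25 must round UP to 6.3 (half-up, not banker's)
        assert occurrence_percent(1, 16) == 6.3

    def test_errors(self):
        with pytest.raises(ValueError):
            occurrence_percent(1, 0)
        with pytest.raises(ValueError):
            occurrence_percent(5, 4)

    @given(n=st.integers(1, 200), data=st.data())
    def test_monotone_in_k(self, n, data):
        k = data.draw(st.integers(0, n - 1))
        assert occurrence_percent(k, n) <= occurrence_percent(k + 1, n)


class TestConcentration:
    def test_direct_arithmetic(self):
        assert concentration(250, 50, 10000, 0.39) == pytest.approx(128205.1, abs=0.05)

    def test_zero_count(self):
        assert concentration(0, 50, 10000, 0.39) == 0.0

    def test_mass_proportionality(self):
        assert concentration(100, 50, 10000, 0.8) == pytest.approx(
            concentration(100, 50, 10000, 0.4) / 2
        )

    def test_zero_spike_error(self):
        with pytest.raises(ValueError, match="undefined concentration"):
            concentration(100, 0, 10000, 0.39)


class TestLoi:
    @pytest.mark.parametrize(
        "dry,ash,expected", [(1.000, 0.486, 51.4), (1.0, 1.0, 0.0), (1.0, 0.0, 100.0)]
    )
    def test_values(self, dry, ash, expected):
        assert loi_organic(dry, ash) == pytest.approx(expected)

    def test_ash_exceeds_dry(self):
        with pytest.raises(ValueError):
            loi_organic(1.0, 1.2)


def registry_from(rows):
    return TaxonRegistry(pd.DataFrame(rows))


class TestMultiproxyVenn:
    def test_three_singletons(self):
        reg = registry_from(
            [
                {"taxon": "a", "detected_by": "DNA"},
                {"taxon": "b", "detected_by": "pollen"},
                {"taxon": "c", "detected_by": "macrofossil"},
            ]
        )
        venn = multiproxy_venn(reg)
        assert venn[frozenset({"DNA"})] == 1
        assert venn[frozenset({"pollen"})] == 1
        assert venn[frozenset({"macrofossil"})] == 1
        assert sum(venn.values()) == 3

    def test_triple_counted_once(self):
        reg = registry_from([{"taxon": "a", "detected_by": "DNA,pollen,macrofossil"}])
        venn = multiproxy_venn(reg)
        assert venn[frozenset({"DNA", "pollen", "macrofossil"})] == 1
        assert sum(venn.values()) == 1

    def test_partition_sums_to_registry_size(self):
        rng = np.random.default_rng(1)
        from itertools import combinations

        subsets = [",".join(c) for r in (1, 2, 3)
                   for c in combinations(("DNA", "pollen", "macrofossil"), r)]
        rows = [{"taxon": f"t{i}", "detected_by": subsets[rng.integers(len(subsets))]}
                for i in range(25)]
        venn = multiproxy_venn(registry_from(rows))
        assert sum(venn.values()) == 25


class TestHabitatTally:
    def test_multimembership(self):
        reg = registry_from(
            [
                {"taxon": "a", "detected_by": "pollen", "habitats": "F"},
                {"taxon": "b", "detected_by": "pollen", "habitats": "F,G"},
            ]
        )
        tally = habitat_tally(reg).set_index("habitat")
        assert tally.loc["F", "n_taxa"] == 2
        assert tally.loc["G", "n_taxa"] == 1

    def test_empty_memberships(self):
        reg = registry_from([{"taxon": "a", "detected_by": "pollen", "habitats": ""}])
        tally = habitat_tally(reg, valid_habitats=["F"])
        assert (tally["n_taxa"] == 0).all()

    def test_unknown_habitat_lists_valid_names(self):
        reg = registry_from([{"taxon": "a", "detected_by": "pollen", "habitats": "X"}])
        with pytest.raises(ValueError, match="F, G"):
            habitat_tally(reg, valid_habitats=["F", "G"])

    def test_sinkhole_fraction(self):
        # 12 of 35 taxa restricted to sinkhole walls -> 34.3%
        rows = [
            {"taxon": f"t{i}", "detected_by": "pollen",
             "habitats": "sinkhole" if i < 12 else "forest"}
            for i in range(35)
        ]
        tally = habitat_tally(registry_from(rows)).set_index("habitat")
        assert tally.loc["sinkhole", "fraction_pct"] == 34.3


class TestIO:
    def test_pollen_matrix_roundtrip(self, tmp_path, small_dataset):
        path = tmp_path / "counts.tsv"
        tables.write_pollen_matrix(small_dataset.pollen, path)
        back = tables.read_pollen_matrix(path)
        pd.testing.assert_frame_equal(back.counts, small_dataset.pollen.counts)
        assert back.spike_total == small_dataset.pollen.spike_total

    def test_registry_roundtrip(self, tmp_path, small_dataset):
        path = tmp_path / "reg.tsv"
        tables.write_registry(small_dataset.registry, path)
        back = tables.read_registry(path)
        assert back.taxa == small_dataset.registry.taxa
        t = back.taxa[0]
        assert back.detected_by(t) == small_dataset.registry.detected_by(t)

    def test_low_count_flags(self):
        m = make_matrix({"c1": {"A": 260}, "c2": {"A": 200}})
        flags = m.low_count_flags()
        assert not flags["c1"] and flags["c2"]
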