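import os
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from coproscope.radiocarbon import CalibrationCurve, write_curve
from coproscope.simulate import SimConfig, simulate_dataset

REPO_ROOT = Path(__file__).resolve().parent.parent

#: Candidate locations for a user-supplied SHCal04 file.  The curve is not
#: redistributed with the package; tests needing it skip when absent.
_CURVE_CANDIDATES = [
    os.environ.get("COPROSCOPE_CURVE", ""),
    str(REPO_ROOT / "data" / "shcal04.14c"),
    str(REPO_ROOT / "shcal04.14c"),
    str(REPO_ROOT / "scratch" / "shcal04.14c"),
]


def find_shcal04() -> Path | None:
    for cand in _CURVE_CANDIDATES:
        if cand and Path(cand).is_file():
            return Path(cand)
    return None


@pytest.fixture(scope="session")
def shcal04_path():
    p = find_shcal04()
    if p is None:
        pytest.skip("user-supplied SHCal04 curve file not available")
    return p


@pytest.fixture(scope="session")
def identity_curve():
    return CalibrationCurve.identity(0.0, 10000.0)


@pytest.fixture()
def identity_curve_file(tmp_path, identity_curve):
    path = tmp_path / "identity.14c"
    write_curve(identity_curve, path)
    return path


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimConfig(seed=11, n_individuals=3, coprolites_per_event=2,
                    n_taxa=12, count_depth=300, clone_library_size_range=(8, 16),
                    rbcl_ref_length=200)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def mni_recovery_rate():
    """(hits, runs) for recovering 5 planted individuals over 100 seeds."""
    from coproscope.adna import call_haplotype
    from coproscope.clustering import (
        assemblage_distance,
        group_assignments,
        hierarchical_cluster,
    )
    from coproscope.events import group_events, link_individuals, mni
    from coproscope.radiocarbon import calibrate
    from coproscope.tables import percentages

    curve = CalibrationCurve.identity(0.0, 10000.0)
    hits, runs = 0, 100
    for seed in range(runs):
        cfg = SimConfig(seed=seed, n_individuals=5, events_per_individual=1,
                        coprolites_per_event=2, n_taxa=12, count_depth=500,
                        diet_concentration=0.7, env_mixing_weight=0.2,
                        diet_subset_size=5, clone_dropout_prob=1.0,
                        age_range_bp=(700.0, 6400.0), age_error=30.0)
        ds = simulate_dataset(cfg)
        tree = hierarchical_cluster(assemblage_distance(percentages(ds.pollen)))
        groups = group_assignments(tree, 0.1)
        haps = {
            cop: call_haplotype(cop, seq, ds.moa_refs).diagnostic_base
            for cop, seq in ds.moa_amplicons.items()
        }
        dates = {
            str(r["coprolite"]): calibrate(float(r["cra"]), float(r["error"]), curve)
            for _, r in ds.ages.iterrows()
        }
        events = group_events(ds.pollen.coprolites, groups, haps, dates)
        hits += mni(link_individuals(events)) == 5
    return hits, runs


@pytest.fixture()
def tiny_percent_matrix():
    return pd.DataFrame(
        {"A": [50.0, 30.0], "B": [30.0, 50.0], "C": [20.0, 20.0]},
        index=["c1", "c2"],
    )
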