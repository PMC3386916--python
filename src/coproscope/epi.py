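"""Environmental prevalence index (EPI) and rank-abundance null comparison.

Each pollen taxon gets a prevalence score — the product of a pollination-mode
factor (wind = 3, animal = 1), a pollen-production factor (1-3) and a
dispersability factor (1-3) — predicting how common its pollen should be in
the ambient pollen rain regardless of diet.  Taxa whose observed abundance
rank in the coprolites beats the rank expected from prevalence alone are
called over-represented (candidate dietary items); taxa ranking worse are
under-represented (incidental or environmental).

The null is operationalised as the tie-averaged rank of each taxon when taxa
are ordered by descending EPI (the cumulative-frequency ordering).  This is
an interpretation of a line that the source method draws graphically without
a formula; it reproduces the documented reading (plotting above the line =
over-represented) and is exact under strict orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

MODE_VALUES = (1, 3)
PRODUCTION_VALUES = (1, 2, 3)
DISPERSAL_VALUES = (1, 2, 3)


@dataclass(frozen=True)
class EPIFactors:
    """Factor scores for one pollen taxon."""

    mode: int
    production: int
    dispersal: int

    def __post_init__(self) -> None:
        if self.mode not in MODE_VALUES:
            raise ValueError(f"mode must be in {MODE_VALUES}, got {self.mode}")
        if self.production not in PRODUCTION_VALUES:
            raise ValueError(f"production must be in {PRODUCTION_VALUES}, got {self.production}")
        if self.dispersal not in DISPERSAL_VALUES:
            raise ValueError(f"dispersal must be in {DISPERSAL_VALUES}, got {self.dispersal}")


@dataclass(frozen=True)
class RepresentationCall:
    taxon: str
    observed_rank: float
    expected_rank: float
    call: str  # over | neutral | under


def compute_epi(factors: EPIFactors) -> int:
    """Product of the three factor scores; always in [1, 27]."""
    return factors.mode * factors.production * factors.dispersal


def all_epi_values() -> list[int]:
    """Every attainable EPI value over the legal factor combinations."""
    return sorted(
        {
            m * p * d
            for m in MODE_VALUES
            for p in PRODUCTION_VALUES
            for d in DISPERSAL_VALUES
        }
    )


def ranked_abundance(percent_matrix: pd.DataFrame) -> pd.Series:
    """Tie-averaged abundance ranks from summed per-coprolite percentages.

    Rank 1 is the most abundant taxon (largest summed percentage).
    """
    if percent_matrix.empty:
        raise ValueError("percent matrix is empty")
    sums = percent_matrix.sum(axis=0)
    ranks = rankdata(-sums.to_numpy(), method="average")
    return pd.Series(ranks, index=sums.index, name="observed_rank")


def null_expected_rank(epi_values: Mapping[str, int] | pd.Series) -> pd.Series:
    """Expected rank of each taxon if abundance tracked prevalence exactly.

    Taxa are ordered by descending EPI; ties within one EPI class receive
    the average of the tied rank positions.
    """
    s = pd.Series(dict(epi_values)) if not isinstance(epi_values, pd.Series) else epi_values
    if ((s < 1) | (s > 27)).any():
        raise ValueError("EPI values must lie in [1, 27]")
    ranks = rankdata(-s.to_numpy(), method="average")
    return pd.Series(ranks, index=s.index, name="expected_rank")


def classify_representation(
    observed_rank: float, expected_rank: float, margin: float = 0.0
) -> str:
    """over / neutral / under from the signed rank difference."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if observed_rank < expected_rank - margin:
        return "over"
    if observed_rank > expected_rank + margin:
        return "under"
    return "neutral"


def representation_table(
    percent_matrix: pd.DataFrame,
    epi_values: Mapping[str, int] | pd.Series,
    margin: float = 0.0,
    include: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full scatter table: taxon, EPI, observed rank, expected rank, call.

    ``include`` restricts the analysis to taxa with prevalence factor data
    (taxa without published factor scores are excluded upstream).
    """
    epi = pd.Series(dict(epi_values)) if not isinstance(epi_values, pd.Series) else epi_values
    taxa = [t for t in percent_matrix.columns if t in epi.index]
    if include is not None:
        taxa = [t for t in taxa if t in set(include)]
    if not taxa:
        raise ValueError("no taxa with EPI values present in the percent matrix")
    observed = ranked_abundance(percent_matrix[taxa])
    expected = null_expected_rank(epi.loc[taxa])
    rows = []
    for t in taxa:
        rows.append(
            {
                "taxon": t,
                "epi": int(epi.loc[t]),
                "observed_rank": float(observed.loc[t]),
                "expected_rank": float(expected.loc[t]),
                "call": classify_representation(observed.loc[t], expected.loc[t], margin),
            }
        )
    return pd.DataFrame(rows)


def permutation_margin(
    percent_matrix: pd.DataFrame,
    epi_values: Mapping[str, int] | pd.Series,
    n_permutations: int = 999,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Optional permutation-derived neutrality margin (off by default).

    Shuffles summed abundances over taxa and returns the chosen quantile of
    |observed_rank - expected_rank| under the shuffle null.
    """
    epi = pd.Series(dict(epi_values)) if not isinstance(epi_values, pd.Series) else epi_values
    taxa = [t for t in percent_matrix.columns if t in epi.index]
    expected = null_expected_rank(epi.loc[taxa]).to_numpy()
    sums = percent_matrix[taxa].sum(axis=0).to_numpy()
    rng = np.random.default_rng(seed)
    devs = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(sums)
        obs = rankdata(-perm, method="average")
        devs[i] = np.abs(obs - expected).max()
    return float(np.quantile(devs, quantile))


def plot_representation(table: pd.DataFrame, path: str) -> None:
    """Optional prevalence-vs-rank scatter (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    order = table.sort_values("expected_rank")
    ax.plot(order["expected_rank"], order["expected_rank"], "k--", lw=1, label="null")
    colors = {"over": "tab:green", "neutral": "tab:gray", "under": "tab:red"}
    for call, sub in table.groupby("call"):
        ax.scatter(sub["expected_rank"], sub["observed_rank"], s=18,
                   c=colors.get(call, "k"), label=call)
    ax.invert_yaxis()
    ax.set_xlabel("expected rank (prevalence null)")
    ax.set_ylabel("observed abundance rank")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
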