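"""Significance and conservation tests for the protein shift ordering.

Three complementary views of the same question — is the serial order of
summit positions along the motif (CTCF before SMC before RAD21/STAG)
real, or an artifact of per-site noise?

* paired Wilcoxon signed-rank on per-site offset differences between two
  proteins (exact null distribution for small n, normal approximation
  with tie correction otherwise);
* Friedman rank test across k >= 3 proteins on complete sites;
* a permutation ("simulation") test of the hypothesized ordering whose
  null shuffles protein labels independently within each site, thereby
  conditioning on the observed per-site offset multiset and testing only
  protein exchangeability.

The permutation p-value uses the standard +1 correction,
``p = (1 + #{T_perm >= T_obs}) / (1 + n_permutations)``, so it can never
be exactly zero; its resolution floor is ``1/(n_permutations + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OrderingTestResult",
    "paired_wilcoxon",
    "friedman_ordering",
    "simulation_order_test",
    "complete_case_matrix",
    "ordering_report",
]


@dataclass
class OrderingTestResult:
    observed_order: tuple[str, ...]
    p_wilcoxon: dict[tuple[str, str], float]
    p_friedman: float | None
    p_simulation: float
    statistic: float
    n_sites: int
    n_permutations: int
    seed: int
    medians: dict[str, float] = field(default_factory=dict)


def _exact_signed_rank_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p via the null distribution of W+.

    Midranks handle tied |d|; ranks are doubled to keep the dynamic
    program over rank sums integral.  Two-sided p is twice the smaller
    tail (capped at 1), each tail inclusive of the observed statistic.
    """
    ranks = sps.rankdata(np.abs(d))
    r2 = np.round(ranks * 2).astype(int)  # doubled midranks are integers
    w_obs = int(r2[d > 0].sum())
    total = int(r2.sum())
    # distribution of the doubled positive-rank sum over all 2^n signings
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    lower = counts[: w_obs + 1].sum()
    upper = counts[w_obs:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def paired_wilcoxon(
    offsets_a: Sequence[float], offsets_b: Sequence[float], exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test of b vs a.

    Inputs are per-site offsets already joined on site id.  Zero
    differences are dropped (Wilcoxon convention) before ranking; the
    returned median difference is over all pairs.  Returns
    ``(p_value, median_difference)``; if every difference is zero,
    ``(1.0, 0.0)``.
    """
    a = np.asarray(offsets_a, dtype=float)
    b = np.asarray(offsets_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired offsets must have equal length")
    d_all = b - a
    d = d_all[d_all != 0]
    if d.size == 0:
        return 1.0, 0.0
    if d.size <= exact_max_n:
        p = _exact_signed_rank_p(d)
    else:
        p = float(
            sps.wilcoxon(d, alternative="two-sided", method="approx").pvalue
        )
    return p, float(np.median(d_all))


def friedman_ordering(
    offsets_by_protein: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> tuple[float, float]:
    """Friedman chi-square test across k >= 3 proteins on complete sites.

    Within-site midranks with the standard tie correction; a fully tied
    dataset has statistic 0 and p = 1.  Returns ``(statistic, p_value)``.
    """
    X = _as_matrix(offsets_by_protein)
    n, k = X.shape
    if k < 3:
        raise ValueError("Friedman test needs k >= 3 proteins; use paired_wilcoxon")
    if n < 1:
        raise ValueError("no complete sites")
    ranks = np.apply_along_axis(sps.rankdata, 1, X)
    col_sums = ranks.sum(axis=0)
    S = float(((col_sums - n * (k + 1) / 2) ** 2).sum())
    stat = 12.0 * S / (n * k * (k + 1))
    # tie correction: subtract sum(t^3 - t) over tie groups within sites
    tie_term = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = 1.0 - tie_term / (n * (k**3 - k))
    if denom <= 0:
        return 0.0, 1.0
    stat /= denom
    return stat, float(sps.chi2.sf(stat, k - 1))


def _as_matrix(
    offsets_by_protein: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> np.ndarray:
    if isinstance(offsets_by_protein, pd.DataFrame):
        return offsets_by_protein.to_numpy(dtype=float)
    lengths = {len(v) for v in offsets_by_protein.values()}
    if len(lengths) > 1:
        raise ValueError("per-protein offset vectors must align on sites")
    return np.column_stack([np.asarray(v, float) for v in offsets_by_protein.values()])


def _order_statistic(medians: np.ndarray, order_idx: np.ndarray) -> float:
    ordered = medians[order_idx]
    return float(np.sum(np.diff(ordered)))


def simulation_order_test(
    offsets_by_protein: Mapping[str, Sequence[float]] | pd.DataFrame,
    n_permutations: int = 100_000,
    seed: int = 0,
    order: Sequence[str] | None = None,
    batch: int = 500,
) -> OrderingTestResult:
    """Permutation test of a hypothesized protein ordering.

    The statistic is the sum over adjacent protein pairs, in the
    hypothesized order, of (median of next - median of previous); under
    the null, protein labels are permuted independently within each site.
    ``order`` defaults to the observed order by median offset, making the
    test a check that the observed serial arrangement is stronger than
    label exchangeability allows.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if isinstance(offsets_by_protein, pd.DataFrame):
        proteins = list(offsets_by_protein.columns)
    else:
        proteins = list(offsets_by_protein.keys())
    if len(proteins) < 2:
        raise ValueError("ordering test needs at least two proteins")
    X = _as_matrix(offsets_by_protein)
    n, k = X.shape
    medians = np.median(X, axis=0)
    observed_order = tuple(proteins[i] for i in np.argsort(medians, kind="stable"))
    target = list(order) if order is not None else list(observed_order)
    if set(target) != set(proteins):
        raise ValueError("order must be a permutation of the protein labels")
    order_idx = np.array([proteins.index(p) for p in target])
    t_obs = _order_statistic(medians, order_idx)

    rng = np.random.default_rng(seed)
    n_ge = 0
    done = 0
    while done < n_permutations:
        m = min(batch, n_permutations - done)
        # independent within-site label permutations via random-key argsort
        keys = rng.random((m, n, k))
        perm = np.argsort(keys, axis=2)
        shuffled = np.take_along_axis(np.broadcast_to(X, (m, n, k)), perm, axis=2)
        med = np.median(shuffled, axis=1)  # (m, k)
        t_perm = (med[:, order_idx[1:]] - med[:, order_idx[:-1]]).sum(axis=1)
        n_ge += int(np.sum(t_perm >= t_obs))
        done += m
    p_sim = (1 + n_ge) / (1 + n_permutations)

    p_wilcoxon = {
        (pa, pb): paired_wilcoxon(X[:, proteins.index(pa)], X[:, proteins.index(pb)])[0]
        for pa, pb in combinations(target, 2)
    }
    p_friedman = friedman_ordering(offsets_by_protein)[1] if k >= 3 else None
    return OrderingTestResult(
        observed_order=observed_order,
        p_wilcoxon=p_wilcoxon,
        p_friedman=p_friedman,
        p_simulation=float(p_sim),
        statistic=t_obs,
        n_sites=n,
        n_permutations=n_permutations,
        seed=seed,
        medians=dict(zip(proteins, medians.tolist())),
    )


def complete_case_matrix(
    records: pd.DataFrame, proteins: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pivot a shift-record table to a sites x proteins offset matrix,
    keeping only sites with a record for every protein (complete blocks,
    as rank tests require).  Multiple samples of one protein at a site
    are averaged.
    """
    wide = records.pivot_table(
        index="cts_id", columns="protein", values="offset", aggfunc="mean"
    )
    if proteins is not None:
        wide = wide[[p for p in proteins if p in wide.columns]]
    return wide.dropna()


def ordering_report(result: OrderingTestResult) -> pd.DataFrame:
    """Flatten an OrderingTestResult into a tidy test/statistic/p table."""
    rows = [
        {
            "test": "simulation",
            "comparison": "->".join(result.observed_order),
            "statistic": result.statistic,
            "p_value": result.p_simulation,
        }
    ]
    if result.p_friedman is not None:
        rows.append(
            {
                "test": "friedman",
                "comparison": "all",
                "statistic": float("nan"),
                "p_value": result.p_friedman,
            }
        )
    for (pa, pb), p in sorted(result.p_wilcoxon.items()):
        rows.append(
            {
                "test": "wilcoxon",
                "comparison": f"{pa}-vs-{pb}",
                "statistic": float("nan"),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
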