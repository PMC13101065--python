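"""Paired and trend statistics for cohort feature tables.

Inference follows the study design for paired single-cell time series:

* Wilcoxon signed-rank for within-cell comparisons between two timepoints.
  Zero differences are dropped (Wilcoxon's convention; Pratt's available),
  the null distribution of W+ is enumerated exactly (with average ranks for
  ties) when the effective sample is small, and approximated by a normal
  with tie and continuity corrections otherwise.
* Mann-Kendall tau-b for monotone trends in per-timepoint cohort means,
  with tie-corrected denominator and variance.
* Rayleigh cavitation-bubble energy, E = (4/3) pi R_max^3 * delta_p, the
  work done against the driving pressure by a bubble expanding to R_max.

No multiple-testing correction is applied by default (features are
reported one per row, each at alpha); Benjamini-Hochberg is available
behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import FEATURE_NAMES

__all__ = [
    "PairedComparison",
    "TrendResult",
    "CavitationParams",
    "wilcoxon_signed_rank",
    "mann_kendall_tau_b",
    "summarize_pairwise",
    "trend_over_time",
    "rayleigh_bubble_energy",
]

#: 1 atm minus the saturation vapor pressure of water at 20 C (Pa)
DEFAULT_DELTA_P_PA = 101_325.0 - 2_339.0

#: differences count for exact signed-rank enumeration at or below this n
EXACT_ENUMERATION_MAX_N = 25


@dataclass
class PairedComparison:
    """One feature's paired two-timepoint comparison (table row)."""

    feature_name: str
    n_pairs: int
    mean_diff: float
    sem_diff: float
    statistic: float  # signed-rank W+ (sum of positive-difference ranks)
    p_value: float
    significant: bool
    n_zero_dropped: int = 0
    degenerate: bool = False


@dataclass
class TrendResult:
    """Mann-Kendall trend test result for an ordered series."""

    series_length: int
    tau_b: float
    p_value: float
    S_statistic: int
    degenerate: bool = False


@dataclass
class CavitationParams:
    """Rayleigh-model bubble parameters."""

    r_max_um: float = 21.0
    delta_p_pa: float = DEFAULT_DELTA_P_PA

    def __post_init__(self) -> None:
        if self.r_max_um < 0 or self.delta_p_pa <= 0:
            raise ValueError("r_max_um must be >= 0 and delta_p_pa > 0")


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ by dynamic-programming enumeration.

    ``ranks`` are the (possibly tied, average) ranks of the nonzero
    |differences|.  Half-integer ranks are doubled so the distribution lives
    on an integer lattice; the count table enumerates all 2^n equally likely
    sign assignments without listing them.
    """
    scaled = np.rint(ranks * 2).astype(np.int64)
    total = int(scaled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for s in scaled:
        shifted = np.zeros_like(counts)
        shifted[s:] = counts[: counts.size - s]
        counts = counts + shifted
    denom = 2.0 ** len(scaled)
    w2 = int(np.rint(w_plus * 2))
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def _signed_rank_normal_p(ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with tie and continuity corrections."""
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups of |d|
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    d = w_plus - mean
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var) if d != 0 else 0.0
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    feature_name: str = "",
    alpha: float = 0.05,
    zero_method: str = "wilcox",
    exact_threshold: int = EXACT_ENUMERATION_MAX_N,
) -> PairedComparison:
    """Paired Wilcoxon signed-rank test on differences d = x - y.

    ``zero_method="wilcox"`` (default) drops zero differences before
    ranking; ``"pratt"`` ranks them but excludes them from W+.  The exact
    null distribution is enumerated when the effective sample size is at
    most ``exact_threshold``; otherwise the normal approximation with tie
    and continuity corrections is used.  Two-sided p-values throughout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1D samples with n >= 1")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    d = x - y
    n_pairs = d.size
    mean_diff = float(d.mean())
    sem_diff = float(d.std(ddof=1) / np.sqrt(n_pairs)) if n_pairs > 1 else 0.0

    nz = d != 0
    n_zero = int(n_pairs - nz.sum())
    if not nz.any():
        warnings.warn(f"wilcoxon_signed_rank({feature_name or 'unnamed'}): all differences zero")
        return PairedComparison(
            feature_name=feature_name, n_pairs=n_pairs, mean_diff=0.0, sem_diff=sem_diff,
            statistic=0.0, p_value=1.0, significant=False,
            n_zero_dropped=n_zero, degenerate=True,
        )

    if zero_method == "wilcox":
        dd = d[nz]
        ranks_all = sps.rankdata(np.abs(dd))
        w_plus = float(ranks_all[dd > 0].sum())
        ranks = ranks_all
    else:  # pratt: rank zeros too, then drop their ranks from the statistic
        ranks_full = sps.rankdata(np.abs(d))
        ranks = ranks_full[nz]
        w_plus = float(ranks_full[d > 0].sum())

    n_eff = int(nz.sum())
    if n_eff <= exact_threshold and zero_method == "wilcox":
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        p = _signed_rank_normal_p(ranks, w_plus)

    return PairedComparison(
        feature_name=feature_name, n_pairs=n_pairs, mean_diff=mean_diff,
        sem_diff=sem_diff, statistic=w_plus, p_value=p,
        significant=bool(p < alpha), n_zero_dropped=n_zero,
    )


def mann_kendall_tau_b(series: Sequence[float]) -> TrendResult:
    """Mann-Kendall trend test with tie-corrected tau-b.

    S = sum_{i<j} sign(x_j - x_i); tau_b = S / sqrt((D - T_x)(D - T_t))
    with D = n(n-1)/2 and T the tie corrections (T_t = 0 for an ordered
    sequence without repeated observation times).  The p-value uses the
    normal approximation with tie-corrected variance and a continuity
    correction of 1 toward zero.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1D with length >= 3")
    n = x.size
    sgn = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(sgn, k=1).sum())

    _, tie_counts = np.unique(x, return_counts=True)
    t = tie_counts.astype(float)
    D = n * (n - 1) / 2.0
    T_x = float(np.sum(t * (t - 1) / 2.0))
    T_t = 0.0
    denom = np.sqrt((D - T_x) * (D - T_t))
    if denom == 0:
        warnings.warn("mann_kendall_tau_b: all values tied, tau-b undefined")
        return TrendResult(series_length=n, tau_b=float("nan"), p_value=1.0,
                           S_statistic=S, degenerate=True)
    tau_b = S / denom

    var_s = (n * (n - 1) * (2 * n + 5) - float(np.sum(t * (t - 1) * (2 * t + 5)))) / 18.0
    if var_s <= 0:
        p = 1.0
    elif S == 0:
        p = 1.0
    else:
        z = (S - np.sign(S)) / np.sqrt(var_s)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TrendResult(series_length=n, tau_b=float(tau_b), p_value=p, S_statistic=S)


def summarize_pairwise(
    cohort: pd.DataFrame,
    t_ref: float,
    t_cmp: float,
    features: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-feature paired comparison between two timepoints of a cohort table.

    ``cohort`` is tidy: one row per (cell_id, timepoint_min) with feature
    columns.  Differences are t_cmp - t_ref per cell; cells missing either
    timepoint are excluded and counted in the result's ``attrs``
    (``n_excluded``).  Returns one row per feature with columns
    (parameter, n, mean_diff, sem, statistic, p_value, significant).
    """
    features = list(features) if features is not None else [
        f for f in FEATURE_NAMES if f in cohort.columns
    ]
    missing = [f for f in features if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks feature columns: {missing}")

    ref = cohort[cohort["timepoint_min"] == t_ref].set_index("cell_id")
    cmp_ = cohort[cohort["timepoint_min"] == t_cmp].set_index("cell_id")
    common = ref.index.intersection(cmp_.index)
    n_excluded = len(ref.index.union(cmp_.index)) - len(common)
    if len(common) < 2:
        raise ValueError("fewer than 2 cells with both timepoints present")

    rows = []
    for feat in features:
        comp = wilcoxon_signed_rank(
            cmp_.loc[common, feat].to_numpy(),
            ref.loc[common, feat].to_numpy(),
            feature_name=feat,
            alpha=alpha,
        )
        rows.append({
            "parameter": feat,
            "n": comp.n_pairs,
            "mean_diff": comp.mean_diff,
            "sem": comp.sem_diff,
            "statistic": comp.statistic,
            "p_value": comp.p_value,
            "significant": comp.significant,
        })
    table = pd.DataFrame(rows)
    if bh_correction:
        warnings.warn("Benjamini-Hochberg correction applied; per-feature "
                      "reporting without correction is the default convention")
        order = np.argsort(table["p_value"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, table["p_value"].iloc[i] * m / (rank_idx + 1))
            adj[i] = prev
        table["p_value_bh"] = adj
        table["significant"] = table["p_value_bh"] < alpha
    table.attrs["n_excluded"] = int(n_excluded)
    table.attrs["t_ref"] = t_ref
    table.attrs["t_cmp"] = t_cmp
    table.attrs["alpha"] = alpha
    return table


def trend_over_time(
    cohort: pd.DataFrame,
    feature: str,
    timepoints: Optional[Sequence[float]] = None,
    mode: str = "means",
):
    """Mann-Kendall tau-b over the per-timepoint cohort means of a feature.

    ``mode="means"`` (default) averages the feature across cells at each
    timepoint and tests that mean series; ``mode="cells"`` returns a dict of
    per-cell TrendResults instead.
    """
    if feature not in cohort.columns:
        raise ValueError(f"unknown feature {feature!r}")
    sub = cohort if timepoints is None else cohort[cohort["timepoint_min"].isin(timepoints)]
    if mode == "means":
        means = sub.groupby("timepoint_min")[feature].mean().sort_index()
        return mann_kendall_tau_b(means.to_numpy())
    if mode == "cells":
        out = {}
        for cell_id, grp in sub.sort_values("timepoint_min").groupby("cell_id"):
            out[cell_id] = mann_kendall_tau_b(grp[feature].to_numpy())
        return out
    raise ValueError("mode must be 'means' or 'cells'")


def rayleigh_bubble_energy(cp: CavitationParams | float, delta_p_pa: Optional[float] = None) -> float:
    """Cavitation-bubble energy from the Rayleigh model, in nJ.

    E = (4/3) pi R_max^3 * delta_p.  Accepts either a CavitationParams or a
    radius in um (with optional ``delta_p_pa``, defaulting to 1 atm minus
    water vapor pressure at 20 C).
    """
    if isinstance(cp, CavitationParams):
        r_um, dp = cp.r_max_um, cp.delta_p_pa
    else:
        r_um = float(cp)
        dp = DEFAULT_DELTA_P_PA if delta_p_pa is None else float(delta_p_pa)
        CavitationParams(r_max_um=r_um if r_um > 0 else 0.0, delta_p_pa=dp)  # validation
    if r_um < 0 or dp <= 0:
        raise ValueError("radius must be >= 0 and delta_p positive")
    e_joule = (4.0 / 3.0) * np.pi * (r_um * 1e-6) ** 3 * dp
    return float(e_joule * 1e9)
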