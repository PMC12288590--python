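"""Differential-methylation testing with two FDR regimes.

Per-site case/control differences in methylation beta values are tested
with the two-sided Mann-Whitney U test. Significance is controlled either
by Benjamini-Hochberg adjustment or by a permutation-estimated p-value
threshold: group labels are re-sampled ``n_perm`` times, per-permutation
p-values are recomputed, and the plug-in estimator

    FDR(t) = mean_perm #{p_perm <= t} / max(1, #{p_obs <= t})

selects t* as the largest observed p-value with FDR(t*) below the target.
A differentially methylated CpG (DMC) must additionally show an absolute
between-group beta difference above ``delta_min``.

The scalar test delegates to scipy (exact enumeration for small tie-free
samples, tie-corrected continuity-corrected normal approximation
otherwise); matrix-wide testing uses an in-module vectorized normal
approximation whose per-site ranks and tie corrections are computed once,
so a 1,000-permutation run costs one matrix product per permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MethylationCall
from .params import Parameters

logger = logging.getLogger("methref")


@dataclass
class BetaMatrix:
    """Sites x samples methylation beta values with group labels.

    ``betas`` is a DataFrame indexed by site identifier with one column per
    sample; values in [0,1], NaN for missing. ``groups`` maps each sample
    to "case" or "control"; ``replicate_sets`` optionally maps samples to a
    technical-replicate set label.
    """

    betas: pd.DataFrame
    groups: dict[str, str]
    replicate_sets: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        missing = [s for s in self.betas.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = {g for g in self.groups.values()} - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        vals = self.betas.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    def case_columns(self) -> list[str]:
        return [s for s in self.betas.columns if self.groups[s] == "case"]

    def control_columns(self) -> list[str]:
        return [s for s in self.betas.columns if self.groups[s] == "control"]


def mann_whitney_u(values_x, values_y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Exact enumeration when min(n_x, n_y) <= 8 and there are no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction. All values tied across both groups yields p = 1.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty after dropping missing values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning("mann_whitney_u: all values tied; p = 1 by convention")
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class _MatrixTestPrep:
    """Per-site quantities of a beta matrix that survive label permutation."""

    ranks_filled: np.ndarray  # sites x samples, NaN -> 0
    notnan: np.ndarray        # sites x samples, float 0/1
    tie_term: np.ndarray      # per-site sum(t^3 - t) over tied groups


def _prepare_matrix(values: np.ndarray) -> _MatrixTestPrep:
    ranks = stats.rankdata(values, axis=1, nan_policy="omit")
    notnan = np.isfinite(values).astype(float)
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        row = values[i][np.isfinite(values[i])]
        if row.size:
            _, counts = np.unique(row, return_counts=True)
            tie_term[i] = np.sum(counts.astype(float) ** 3 - counts)
    return _MatrixTestPrep(np.nan_to_num(ranks, nan=0.0), notnan, tie_term)


def _matrix_pvalues(prep: _MatrixTestPrep, case_mask: np.ndarray) -> np.ndarray:
    """Two-sided tie-corrected continuity-corrected MW p per site.

    Sites with fewer than 2 non-missing values in either group get NaN.
    """
    ind = case_mask.astype(float)
    n1 = prep.notnan @ ind
    n2 = prep.notnan @ (1 - ind)
    n = n1 + n2
    r1 = prep.ranks_filled @ ind
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        var = n1 * n2 / 12 * ((n + 1) - prep.tie_term / (n * (n - 1)))
        sigma = np.sqrt(var)
        u_big = np.maximum(u1, n1 * n2 - u1)
        z = (u_big - mu - 0.5) / sigma
        p = np.minimum(1.0, 2 * stats.norm.sf(z))
    p = np.where(sigma > 0, p, 1.0)
    p = np.where((n1 >= 2) & (n2 >= 2), p, np.nan)
    return p


def matrix_mann_whitney(betas: pd.DataFrame, case_columns: list[str]) -> np.ndarray:
    """Vectorized per-site two-sided MW p-values (normal approximation)."""
    values = betas.to_numpy(dtype=float)
    prep = _prepare_matrix(values)
    mask = np.array([c in set(case_columns) for c in betas.columns])
    return _matrix_pvalues(prep, mask)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def permutation_fdr_threshold(
    matrix: BetaMatrix,
    n_perm: int = 1000,
    target_fdr: float = 0.05,
    seed: int = 0,
) -> tuple[float | None, np.ndarray]:
    """Permutation-estimated p-value threshold controlling the FDR.

    Returns (t*, observed p-values). t* is the largest observed p-value t
    with FDR(t) = [mean over permutations of #{p_perm <= t}] /
    max(1, #{p_obs <= t}) at or below ``target_fdr``; None when no
    observed p-value qualifies. Deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = matrix.betas.to_numpy(dtype=float)
    prep = _prepare_matrix(values)
    case_mask = np.array([matrix.groups[c] == "case" for c in matrix.betas.columns])
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    p_obs = _matrix_pvalues(prep, case_mask)
    p_obs_ok = np.sort(p_obs[np.isfinite(p_obs)])
    if p_obs_ok.size == 0:
        return None, p_obs
    rng = np.random.default_rng(seed)
    perm_ps: list[np.ndarray] = []
    for _ in range(n_perm):
        perm_mask = rng.permutation(case_mask)
        pp = _matrix_pvalues(prep, perm_mask)
        perm_ps.append(pp[np.isfinite(pp)])
    all_perm = np.sort(np.concatenate(perm_ps))
    n_perm_le = np.searchsorted(all_perm, p_obs_ok, side="right") / n_perm
    n_obs_le = np.arange(1, p_obs_ok.size + 1)
    fdr = n_perm_le / np.maximum(1, n_obs_le)
    qualifying = np.flatnonzero(fdr <= target_fdr)
    if qualifying.size == 0:
        return None, p_obs
    t_star = float(p_obs_ok[qualifying.max()])
    return t_star, p_obs


def call_dmcs(
    matrix: BetaMatrix,
    params: Parameters | None = None,
    fdr_mode: str = "bh",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site differential methylation calls.

    Output columns: site, p_value, delta_beta (mean case - mean control),
    fdr (BH mode) or p_threshold (permutation mode), significant.
    Significance requires |delta_beta| > delta_min and passing the chosen
    FDR rule at ``fdr_max``. Sites with fewer than 2 non-missing values in
    either group are excluded (counted in the log).
    """
    params = params or Parameters()
    if fdr_mode not in ("bh", "permutation"):
        raise ValueError("fdr_mode must be 'bh' or 'permutation'")
    case_cols = matrix.case_columns()
    ctrl_cols = matrix.control_columns()
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    values = matrix.betas.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        delta = np.nanmean(
            matrix.betas[case_cols].to_numpy(dtype=float), axis=1
        ) - np.nanmean(matrix.betas[ctrl_cols].to_numpy(dtype=float), axis=1)
    if fdr_mode == "permutation":
        t_star, p = permutation_fdr_threshold(matrix, params.n_perm, params.fdr_max, seed)
        passes = np.zeros_like(p, dtype=bool) if t_star is None else (p <= t_star)
        extra = {"p_threshold": t_star if t_star is not None else np.nan}
        fdr_col = None
    else:
        p = matrix_mann_whitney(matrix.betas, case_cols)
        fdr_col = bh_fdr(p)
        passes = np.where(np.isfinite(fdr_col), fdr_col < params.fdr_max, False)
        extra = {}
    ok = np.isfinite(p)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("call_dmcs: %d sites excluded (<2 non-missing values per group)", n_excluded)
    significant = ok & passes & (np.abs(delta) > params.delta_min)
    out = pd.DataFrame(
        {
            "site": matrix.betas.index,
            "p_value": p,
            "delta_beta": delta,
            "significant": significant,
        }
    )
    if fdr_col is not None:
        out.insert(3, "fdr", fdr_col)
    for k, v in extra.items():
        out[k] = v
    out = out[ok].reset_index(drop=True)
    logger.info(
        "call_dmcs (%s): %d tested, %d significant", fdr_mode, len(out), int(out["significant"].sum())
    )
    return out


def replicate_sd(matrix: BetaMatrix, replicate_set: str | None = None) -> pd.Series:
    """Per-site sample standard deviation (n-1 denominator) over replicates."""
    if replicate_set is not None:
        cols = [s for s, r in matrix.replicate_sets.items() if r == replicate_set]
    else:
        cols = list(matrix.betas.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 replicates")
    return matrix.betas[cols].std(axis=1, ddof=1)


def platform_abs_diff(
    array_betas: pd.Series,
    wgbs_calls: list[MethylationCall],
    coverage_min: int = 10,
) -> pd.Series:
    """Per-site |array beta - WGBS beta| over the cross-platform intersection.

    WGBS sites below ``coverage_min`` are excluded before intersecting;
    array sites are keyed (contig, position) like the WGBS calls.
    """
    wgbs = {
        (c.contig, c.position): c.beta
        for c in wgbs_calls
        if c.coverage >= coverage_min and c.beta is not None
    }
    shared = [s for s in array_betas.index if s in wgbs and np.isfinite(array_betas[s])]
    if not shared:
        logger.warning("platform_abs_diff: empty cross-platform intersection")
        return pd.Series(dtype=float)
    return pd.Series(
        {s: abs(float(array_betas[s]) - wgbs[s]) for s in shared}, dtype=float
    )


def compare_probe_groups(
    values: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]],
) -> pd.DataFrame:
    """Pairwise two-sided MW tests between probe groups, BH across the family.

    ``values`` maps a group label (e.g. "both", "T2T_unique") to the metric
    values of its probes (replicate SD, platform |difference|, ...).
    """
    rows = []
    for a, b in comparisons:
        if a not in values or b not in values:
            raise ValueError(f"unknown group label in comparison ({a}, {b})")
        if len(values[a]) < 2 or len(values[b]) < 2:
            raise ValueError("each compared group needs >= 2 members")
        u, p = mann_whitney_u(values[a], values[b])
        rows.append({"group_a": a, "group_b": b, "U": u, "p_value": p})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df
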