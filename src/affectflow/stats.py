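"""Statistical layer: permutation correlations with bootstrap intervals,
rank tests, partial correlation, inter-rater agreement, and the
scale-by-feature correlation screen.

Small-cohort practice drives the choices here. Pearson correlations are
tested by permutation (two-sided, add-one estimator, so p is never 0 and
never below 1/(n_perm+1)); confidence intervals are percentile bootstrap
over paired resamples; and findings are tiered rather than formally
corrected: p < 0.01 counts as *significant* (a deliberately strict
cut-off given the number of screens), p < 0.05 as a *trend*. An optional
Benjamini–Hochberg column is available but off by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

TIER_SIGNIFICANT = "significant"
TIER_TREND = "trend"
TIER_NS = "ns"


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN")
    return arr


def _check_pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    xv, yv = _as_vector(x, "x"), _as_vector(y, "y")
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {len(xv)} vs {len(yv)}")
    if len(xv) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(xv)}")
    return xv, yv


def pearson_r(x, y) -> float:
    """Plain sample Pearson coefficient (closed form)."""
    xv, yv = _check_pair(x, y, 2)
    xs = xv - xv.mean()
    ys = yv - yv.mean()
    denom = np.sqrt((xs @ xs) * (ys @ ys))
    if denom == 0:
        raise ValueError("constant input: correlation undefined")
    return float(np.clip((xs @ ys) / denom, -1.0, 1.0))


def perm_corr_test(x, y, n_perm: int = 10_000,
                   seed: int | np.random.Generator | None = 0
                   ) -> tuple[float, float]:
    """Two-sided permutation test of the Pearson correlation.

    ``y`` is permuted ``n_perm`` times with a seeded generator;
    p = (1 + #{|r_perm| >= |r|}) / (n_perm + 1). The add-one estimator
    keeps p in [1/(n_perm+1), 1].
    """
    xv, yv = _check_pair(x, y, 3)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("constant vector: permutation correlation undefined")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    n = len(xv)
    xs = (xv - xv.mean())
    xs /= np.sqrt(xs @ xs)
    ys = (yv - yv.mean())
    ys /= np.sqrt(ys @ ys)
    r = float(np.clip(xs @ ys, -1.0, 1.0))
    # all permutations at once: each row of `order` is one shuffle of y
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    r_perm = ys[order] @ xs
    exceed = int(np.sum(np.abs(r_perm) >= abs(r) - 1e-12))
    p = (1 + exceed) / (n_perm + 1)
    return r, float(p)


def bootstrap_ci(x, y, n_boot: int = 2_000, level: float = 0.95,
                 seed: int | np.random.Generator | None = 0,
                 max_retries: int = 100) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the Pearson r.

    Users are resampled in pairs with replacement; resamples on which the
    correlation is undefined (a constant vector) are redrawn, up to
    ``max_retries`` sweeps.
    """
    xv, yv = _check_pair(x, y, 5)
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    n = len(xv)

    def batch_r(idx: np.ndarray) -> np.ndarray:
        bx, by = xv[idx], yv[idx]
        bx = bx - bx.mean(axis=1, keepdims=True)
        by = by - by.mean(axis=1, keepdims=True)
        denom = np.sqrt((bx * bx).sum(axis=1) * (by * by).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (bx * by).sum(axis=1) / denom, np.nan)

    rs = batch_r(rng.integers(0, n, size=(n_boot, n)))
    for _ in range(max_retries):
        bad = np.isnan(rs)
        if not bad.any():
            break
        rs[bad] = batch_r(rng.integers(0, n, size=(int(bad.sum()), n)))
    else:
        raise RuntimeError("could not draw non-degenerate bootstrap resamples")
    alpha = (1 - level) / 2
    lo, hi = np.quantile(rs, [alpha, 1 - alpha])
    return float(lo), float(hi)


def partial_r_from_pairwise(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation from the three pairwise r's."""
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("degenerate: control variable collinear with input")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    return float(np.clip(r, -1.0, 1.0))


def partial_corr(x, y, z) -> tuple[float, float]:
    """First-order partial correlation r_xy.z with a t-approximation p.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2));
    the test statistic is t = r sqrt((n-3)/(1-r^2)) on n-3 degrees of
    freedom (two-sided).
    """
    xv, yv = _check_pair(x, y, 4)
    zv = _as_vector(z, "z")
    if len(zv) != len(xv):
        raise ValueError("z must align with x and y")
    r = partial_r_from_pairwise(pearson_r(xv, yv), pearson_r(xv, zv),
                                pearson_r(yv, zv))
    n = len(xv)
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r ** 2))
    p = 2 * sps.t.sf(abs(t), df)
    return r, float(p)


def perm_partial_corr(x, y, z, n_perm: int = 10_000,
                      seed: int | np.random.Generator | None = 0
                      ) -> tuple[float, float]:
    """Permutation variant of the partial-correlation test: the residuals
    of x|z are permuted against the residuals of y|z."""
    xv, yv = _check_pair(x, y, 4)
    zv = _as_vector(z, "z")
    design = np.column_stack([np.ones_like(zv), zv])
    rx = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
    ry = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    r, _ = partial_corr(xv, yv, zv)
    _, p = perm_corr_test(rx, ry, n_perm=n_perm, seed=seed)
    return r, p


def mann_whitney(x, y) -> tuple[float, float, float]:
    """Wilcoxon–Mann–Whitney test with tie-corrected normal approximation.

    Returns (U, Z, two-sided p), with U counted for the first sample.
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if len(xv) == 0 or len(yv) == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = len(xv), len(yv)
    pooled = np.concatenate([xv, yv])
    ranks = sps.rankdata(pooled)
    u_x = ranks[:nx].sum() - nx * (nx + 1) / 2
    mu = nx * ny / 2
    # tie correction on the variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = nx + ny
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
                if n > 1 else 0.0)
    var = nx * ny / 12 * ((n + 1) - tie_term)
    if var == 0:
        return float(u_x), 0.0, 1.0
    z = (u_x - mu) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return float(u_x), float(z), float(min(p, 1.0))


def exact_mann_whitney_p(x, y) -> float:
    """Exhaustive-enumeration two-sided p for tiny samples (oracle use)."""
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    nx = len(xv)
    pooled = np.concatenate([xv, yv])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), nx):
        s = ranks[list(combo)].sum()
        if abs(s - mu) >= abs(obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's chance-corrected agreement between two annotators.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement from the
    product of marginal label distributions. Two identical constant
    ratings agree perfectly (kappa 1); two different constant ratings
    are degenerate.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    if not a:
        raise ValueError("empty label vectors")
    n = len(a)
    cats = sorted(set(a) | set(b), key=str)
    p_o = sum(1 for u, v in zip(a, b) if u == v) / n
    pa = {c: sum(1 for u in a if u == c) / n for c in cats}
    pb = {c: sum(1 for v in b if v == c) / n for c in cats}
    p_e = sum(pa[c] * pb[c] for c in cats)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("degenerate: chance agreement is 1 but raters differ")
    return (p_o - p_e) / (1 - p_e)


def average_pairwise_kappa(raters: Sequence[Sequence]) -> float:
    """Mean Cohen's kappa over all unordered pairs of raters."""
    if len(raters) < 2:
        raise ValueError("need at least two raters")
    ks = [cohens_kappa(a, b) for a, b in itertools.combinations(raters, 2)]
    return float(np.mean(ks))


def normality_check(x) -> tuple[float, float]:
    """Shapiro–Wilk W and p (delegated to scipy)."""
    xv = _as_vector(x, "x")
    if not (3 <= len(xv) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(xv) == 0:
        raise ValueError("constant vector: normality test undefined")
    res = sps.shapiro(xv)
    return float(res.statistic), float(res.pvalue)


def assign_tier(p: float, alpha_sig: float = 0.01,
                alpha_trend: float = 0.05) -> str:
    if p < alpha_sig:
        return TIER_SIGNIFICANT
    if p < alpha_trend:
        return TIER_TREND
    return TIER_NS


@dataclass
class CorrelationResult:
    """One scale x feature correlation with its permutation p, bootstrap
    CI and significance tier."""

    scale_name: str
    feature_name: str
    representation: str
    n: int
    r: float
    p_perm: float
    ci: tuple[float, float]
    tier: str
    n_perm: int
    n_boot: int
    seed: int

    @property
    def r2(self) -> float:
        return self.r ** 2

    def to_dict(self) -> dict:
        return {
            "scale": self.scale_name,
            "feature": self.feature_name,
            "representation": self.representation,
            "n": self.n,
            "r": self.r,
            "ci_lo": self.ci[0],
            "ci_hi": self.ci[1],
            "r2": self.r2,
            "p": self.p_perm,
            "tier": self.tier,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


@dataclass
class ScreenConfig:
    n_perm: int = 10_000
    n_boot: int = 2_000
    seed: int = 0
    alpha_sig: float = 0.01
    alpha_trend: float = 0.05
    ci_level: float = 0.95
    bh_column: bool = False        # optional Benjamini-Hochberg adjunct

    def __post_init__(self) -> None:
        if not (0 < self.alpha_sig < self.alpha_trend < 1):
            raise ValueError("need 0 < alpha_sig < alpha_trend < 1")


def correlation_screen(features: pd.DataFrame, scales: pd.DataFrame,
                       config: ScreenConfig | None = None,
                       representation: str = "",
                       skip_constant: bool = True
                       ) -> list[CorrelationResult]:
    """Correlate every scale column against every feature column.

    ``features`` and ``scales`` are user-indexed tables; their indices
    must match as sets (rows are aligned by user id). Each pair gets its
    own child generator spawned deterministically from ``config.seed``,
    so results do not depend on screen traversal order. Constant columns
    (a transition type nobody exhibits) are skipped with a warning
    unless ``skip_constant`` is False, in which case they raise.
    """
    cfg = config or ScreenConfig()
    f_idx, s_idx = set(features.index), set(scales.index)
    if f_idx != s_idx:
        offenders = sorted(map(str, f_idx ^ s_idx))[:10]
        raise ValueError(f"user mismatch between feature and scale tables: "
                         f"{offenders}")
    scales = scales.loc[features.index]
    constant = {c for c in features.columns
                if np.ptp(features[c].to_numpy(dtype=float)) == 0}
    constant |= {c for c in scales.columns
                 if np.ptp(scales[c].to_numpy(dtype=float)) == 0}
    if constant:
        msg = (f"constant column(s) carry no correlation signal: "
               f"{sorted(constant)}")
        if not skip_constant:
            raise ValueError(msg)
        warnings.warn(msg + "; skipped")
    results: list[CorrelationResult] = []
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(scales.columns) * len(features.columns))
    i = 0
    for scale in scales.columns:
        sv = scales[scale].to_numpy(dtype=float)
        for feat in features.columns:
            child = children[i]
            i += 1
            if scale in constant or feat in constant:
                continue
            fv = features[feat].to_numpy(dtype=float)
            rng = np.random.default_rng(child)
            r, p = perm_corr_test(sv, fv, n_perm=cfg.n_perm, seed=rng)
            ci = bootstrap_ci(sv, fv, n_boot=cfg.n_boot, level=cfg.ci_level,
                              seed=rng)
            results.append(CorrelationResult(
                scale_name=scale, feature_name=feat,
                representation=representation, n=len(fv), r=r, p_perm=p,
                ci=ci, tier=assign_tier(p, cfg.alpha_sig, cfg.alpha_trend),
                n_perm=cfg.n_perm, n_boot=cfg.n_boot, seed=cfg.seed))
    return results


def screen_to_frame(results: Sequence[CorrelationResult],
                    bh_column: bool = False) -> pd.DataFrame:
    """Long-format table of screen results; optionally appends
    Benjamini-Hochberg adjusted p-values across all rows."""
    frame = pd.DataFrame([r.to_dict() for r in results])
    if bh_column and len(frame):
        frame["p_bh"] = _benjamini_hochberg(frame["p"].to_numpy())
    return frame


def screen_to_matrix(results: Sequence[CorrelationResult],
                     pooled_counts: Optional[pd.Series] = None
                     ) -> pd.DataFrame:
    """Wide matrix (scales x features) of r values, optionally headed by
    a pooled occurrence-count row."""
    frame = pd.DataFrame([r.to_dict() for r in results])
    mat = frame.pivot(index="scale", columns="feature", values="r")
    if pooled_counts is not None:
        mat = pd.concat(
            [pooled_counts.to_frame().T.reindex(columns=mat.columns), mat])
    return mat


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
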