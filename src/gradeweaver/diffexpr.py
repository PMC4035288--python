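"""SAM-style two-class differential expression with permutation FDR.

The moderated statistic for feature i is::

    d_i = (mean_B - mean_A) / (s_i + s0)
    s_i = sqrt((1/n_A + 1/n_B) * (SS_A + SS_B) / (n_A + n_B - 2))

where SS is the within-class sum of squared deviations and ``s0`` is
the fudge factor that stabilises d for low-variance features.  The
false-discovery rate is estimated from label permutations with the
null proportion pi0 fixed at 1 (conservative), and q-values are made
monotone in |d| by a running maximum.  Used identically for mRNA and
miRNA matrices.

Batch harmonisation offers two modes: a deterministic per-gene
mean/variance rescaling, and a parametric empirical-Bayes scheme
(normal prior on batch location, inverse-gamma on batch scale,
method-of-moments hyperparameters, iterated posterior updates) in the
spirit of the standard microarray batch-correction method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "ContrastSpec",
    "DifferentialResult",
    "SamModel",
    "batch_adjust",
    "sam_statistic",
    "choose_s0",
    "permutation_qvalues",
    "call_differential",
    "compare_contrast_overlap",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Two-class contrast; "up" means higher mean in ``class_b``."""

    class_a: str
    class_b: str

    def __post_init__(self) -> None:
        if self.class_a == self.class_b:
            raise ValueError("contrast classes must differ")

    def __str__(self) -> str:
        return f"{self.class_a}:{self.class_b}"


@dataclass
class DifferentialResult:
    """Per-feature SAM output for one two-class contrast."""

    feature_ids: list[str]
    d: np.ndarray
    s: np.ndarray
    q: np.ndarray
    call: np.ndarray            # "up" | "down" | "ns"
    s0: float = float("nan")
    threshold: float = 0.01
    contrast: Optional[ContrastSpec] = None
    B: int = 0
    seed: Optional[int] = None
    zero_variance: np.ndarray = field(default=None)  # per-feature flag

    def __post_init__(self) -> None:
        n = len(self.feature_ids)
        for name in ("d", "s", "q", "call"):
            v = getattr(self, name)
            if len(v) != n:
                raise ValueError(f"{name} has length {len(v)}, expected {n}")
        if self.zero_variance is None:
            self.zero_variance = np.zeros(n, dtype=bool)

    def genes_called(self, direction: str) -> set:
        return {f for f, c in zip(self.feature_ids, self.call) if c == direction}

    @property
    def up(self) -> set:
        return self.genes_called("up")

    @property
    def down(self) -> set:
        return self.genes_called("down")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_ids, "d": self.d, "s": self.s, "q": self.q, "call": self.call}
        )


def _split_classes(labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list]:
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    a_mask = labels == classes[0]
    b_mask = labels == classes[1]
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    return a_mask, b_mask, classes


def sam_statistic(
    values: np.ndarray, labels: Sequence[str], s0: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (d, s, zero_variance_flag) for a features x samples matrix.

    Class A/B are the lexicographically first/second label; d is positive
    when the mean in class B is higher.  Features with s_i + s0 == 0 get
    d = 0 and are flagged rather than raising.
    """
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    values = np.asarray(values, dtype=float)
    a_mask, b_mask, _ = _split_classes(labels)
    n_a, n_b = int(a_mask.sum()), int(b_mask.sum())
    xa, xb = values[:, a_mask], values[:, b_mask]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    ss_a = ((xa - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n_a + 1.0 / n_b) * (ss_a + ss_b) / (n_a + n_b - 2))
    denom = s + s0
    zero = denom == 0.0
    d = np.zeros_like(s)
    np.divide(mean_b - mean_a, denom, out=d, where=~zero)
    return d, s, zero


def choose_s0(values: np.ndarray, labels: Sequence[str]) -> float:
    """Select the fudge factor over percentile candidates of {s_i}.

    Candidates are the alpha-percentiles of the s_i for alpha in
    0,5,...,100.  For each candidate the features are binned into
    deciles of s_i; the coefficient of variation of the per-bin median
    absolute deviations of d is minimised, ties going to the smallest
    alpha.
    """
    _, s, _ = sam_statistic(values, labels, s0=0.0)
    if np.all(s == 0.0):
        raise ValueError("all features have zero pooled sd; cannot choose s0")
    num = _sam_numerator(values, labels)
    alphas = np.arange(0, 101, 5)
    candidates = np.percentile(s, alphas)
    # decile bins of s_i (shared across candidates)
    edges = np.percentile(s, np.arange(0, 101, 10))
    bin_idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 9)
    best_alpha, best_cv, best_s0 = None, math.inf, None
    for alpha, cand in zip(alphas, candidates):
        denom = s + cand
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(denom > 0, num / denom, 0.0)
        mads = []
        for b in range(10):
            sel = bin_idx == b
            if sel.sum() == 0:
                continue
            db = d[sel]
            mads.append(np.median(np.abs(db - np.median(db))))
        mads = np.asarray(mads, dtype=float)
        mean_mad = mads.mean()
        cv = mads.std() / mean_mad if mean_mad > 0 else math.inf
        if cv < best_cv - 1e-15:
            best_alpha, best_cv, best_s0 = alpha, cv, float(cand)
    if best_s0 is None:
        # all candidates degenerate (e.g. every s_i equal): any candidate works
        best_s0 = float(candidates[0])
    return best_s0


def _sam_numerator(values: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    a_mask, b_mask, _ = _split_classes(labels)
    return values[:, b_mask].mean(axis=1) - values[:, a_mask].mean(axis=1)


def permutation_qvalues(
    values: np.ndarray,
    labels: Sequence[str],
    s0: float,
    B: int = 300,
    seed: Optional[int] = None,
    exhaustive: bool = False,
) -> np.ndarray:
    """Permutation q-values with pi0 = 1 and monotone enforcement.

    For feature i::

        q_i = min(1, [(1/B) sum_b #{j: |d*_jb| >= |d_i|}] / #{j: |d_j| >= |d_i|})

    Permuted statistics d* use the same s0 on shuffled label vectors
    (class sizes preserved).  With ``exhaustive=True`` all distinct
    label assignments are enumerated instead of sampling B of them.
    Monotone enforcement takes a running maximum down the |d|-sorted
    feature list so q never decreases as |d| decreases.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    d_obs, _, _ = sam_statistic(values, labels, s0)
    n_feat = len(d_obs)
    a_mask, b_mask, classes = _split_classes(labels)
    n = len(labels)
    n_a = int(a_mask.sum())

    if exhaustive:
        perms = []
        for combo in combinations(range(n), n_a):
            lab = np.full(n, classes[1], dtype=object)
            lab[list(combo)] = classes[0]
            perms.append(lab)
    else:
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        perms = []
        for _ in range(B):
            order = rng.permutation(n)
            perms.append(labels[order])

    abs_obs = np.abs(d_obs)
    # for each feature: observed count of |d_j| >= |d_i| and mean permuted count
    order = np.argsort(-abs_obs, kind="stable")
    sorted_abs = abs_obs[order]
    obs_counts = np.searchsorted(-sorted_abs, -abs_obs, side="right")

    perm_counts = np.zeros(n_feat)
    for lab in perms:
        d_perm, _, _ = sam_statistic(values, lab, s0)
        abs_perm = np.sort(np.abs(d_perm))
        # #{j: |d*_j| >= |d_i|} = n_feat - first index with abs_perm >= abs_obs_i
        perm_counts += n_feat - np.searchsorted(abs_perm, abs_obs, side="left")
    perm_counts /= len(perms)

    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.minimum(1.0, perm_counts / obs_counts)
    # running max from largest |d| downwards
    q_sorted = np.maximum.accumulate(q[order])
    q_out = np.empty_like(q)
    q_out[order] = q_sorted
    return q_out


def call_differential(
    feature_ids: Sequence[str],
    d: np.ndarray,
    q: np.ndarray,
    threshold: float = 0.01,
    **kwargs,
) -> DifferentialResult:
    """Directional significance calls: up if q < threshold and d > 0, etc."""
    d = np.asarray(d, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (len(feature_ids) == len(d) == len(q)):
        raise ValueError("feature_ids, d and q must have equal length")
    call = np.full(len(d), "ns", dtype=object)
    call[(q < threshold) & (d > 0)] = "up"
    call[(q < threshold) & (d < 0)] = "down"
    s = kwargs.pop("s", np.full(len(d), np.nan))
    return DifferentialResult(
        feature_ids=list(feature_ids), d=d, s=np.asarray(s), q=q, call=call,
        threshold=threshold, **kwargs,
    )


class SamModel:
    """Two-class SAM analysis of an expression matrix (model object).

    Parameters
    ----------
    matrix : ExpressionMatrix
    sample_labels : per-sample class labels aligned with the matrix columns
    contrast : ContrastSpec, optional
        Orientation record; class_b is the "up" direction.  When given,
        only samples belonging to the two contrast classes are used.
    """

    def __init__(self, matrix: ExpressionMatrix, sample_labels: Sequence[str],
                 contrast: Optional[ContrastSpec] = None):
        labels = np.asarray([str(x) for x in sample_labels])
        if len(labels) != len(matrix.sample_ids):
            raise ValueError("labels must align with matrix samples")
        if contrast is not None:
            keep = np.isin(labels, [contrast.class_a, contrast.class_b])
            matrix = matrix.subset_samples([s for s, k in zip(matrix.sample_ids, keep) if k])
            labels = labels[keep]
            if sorted({contrast.class_a, contrast.class_b}) != sorted(set(labels.tolist())):
                raise ValueError("contrast classes not both present")
            # orient so that class_b ("up") is the lexicographically second
            # class seen by sam_statistic; if not, flip sign afterwards
        self.matrix = matrix
        self.labels = labels
        self.contrast = contrast

    def fit(
        self,
        q_threshold: float = 0.01,
        B: int = 300,
        seed: Optional[int] = None,
        s0: Optional[float] = None,
        exhaustive: bool = False,
    ) -> DifferentialResult:
        values = self.matrix.values
        if s0 is None:
            s0 = choose_s0(values, self.labels)
        d, s, zero = sam_statistic(values, self.labels, s0)
        if self.contrast is not None and sorted(
            [self.contrast.class_a, self.contrast.class_b]
        )[1] != self.contrast.class_b:
            d = -d  # class_b is lexicographically first; flip so "up" = higher in class_b
        q = permutation_qvalues(values, self.labels, s0, B=B, seed=seed, exhaustive=exhaustive)
        q = np.where(zero, 1.0, q)
        res = call_differential(
            self.matrix.feature_ids, d, q, threshold=q_threshold,
            s=s, s0=s0, contrast=self.contrast, B=B, seed=seed,
        )
        res.zero_variance = zero
        return res


# ---------------------------------------------------------------------------
# Batch harmonisation
# ---------------------------------------------------------------------------

def batch_adjust(
    matrix: ExpressionMatrix, batches: Sequence[str], mode: str = "eb"
) -> ExpressionMatrix:
    """Remove additive/multiplicative batch structure per gene.

    mode="meanvar"
        Each batch slice of each gene is standardised and rescaled to
        the gene's grand mean and pooled within-batch sd.  Exactly
        idempotent; a single batch passes through unchanged.
    mode="eb"
        Parametric empirical-Bayes shrinkage of per-batch location and
        scale (normal / inverse-gamma priors, method-of-moments
        hyperparameters, iterated posterior updates) before adjustment.
    """
    batches = np.asarray([str(b) for b in batches])
    if len(batches) != len(matrix.sample_ids):
        raise ValueError("batch labels must align with matrix samples")
    levels = sorted(set(batches.tolist()))
    for lev in levels:
        if (batches == lev).sum() < 2:
            raise ValueError(f"batch {lev!r} has fewer than 2 samples (variance undefined)")
    X = matrix.values.copy()
    if mode == "meanvar":
        out = _meanvar_adjust(X, batches, levels)
    elif mode == "eb":
        out = _eb_adjust(X, batches, levels)
    else:
        raise ValueError(f"unknown batch-adjust mode {mode!r}")
    return ExpressionMatrix(
        list(matrix.feature_ids), list(matrix.sample_ids), out, matrix.feature_kind
    )


def _meanvar_adjust(X: np.ndarray, batches: np.ndarray, levels: list) -> np.ndarray:
    n = X.shape[1]
    grand_mean = X.mean(axis=1)
    # pooled within-batch sd (ddof=1 per batch); idempotent by construction
    ss, dof = np.zeros(X.shape[0]), 0
    stats = {}
    for lev in levels:
        sel = batches == lev
        nb = int(sel.sum())
        mu = X[:, sel].mean(axis=1)
        ssb = ((X[:, sel] - mu[:, None]) ** 2).sum(axis=1)
        stats[lev] = (sel, mu, np.sqrt(ssb / (nb - 1)))
        ss += ssb
        dof += nb - 1
    pooled_sd = np.sqrt(ss / dof)
    out = np.empty_like(X)
    for lev in levels:
        sel, mu, sd = stats[lev]
        z = np.zeros((X.shape[0], int(sel.sum())))
        nz = sd > 0
        z[nz] = (X[np.ix_(nz, sel)] - mu[nz, None]) / sd[nz, None]
        out[:, sel] = grand_mean[:, None] + pooled_sd[:, None] * z
    return out


def _eb_adjust(
    X: np.ndarray, batches: np.ndarray, levels: list, tol: float = 1e-8, max_iter: int = 200
) -> np.ndarray:
    """Parametric EB batch adjustment (no covariates).

    Standardise each gene with its sample-size-weighted grand mean and
    grand sd; per batch, shrink the observed location gamma_hat towards
    the across-gene batch mean (normal prior) and the observed scale
    delta2_hat towards an inverse-gamma prior with method-of-moments
    hyperparameters, iterating the coupled posterior updates to
    convergence; then remove the shrunken location/scale and restore
    the gene's grand mean and sd.
    """
    G, n = X.shape
    batch_sel = {lev: batches == lev for lev in levels}
    n_b = {lev: int(batch_sel[lev].sum()) for lev in levels}

    grand_mean = sum(n_b[lev] / n * X[:, batch_sel[lev]].mean(axis=1) for lev in levels)
    var_pooled = ((X - grand_mean[:, None]) ** 2).sum(axis=1) / n
    sd_pooled = np.sqrt(var_pooled)
    if np.any(sd_pooled == 0):
        sd_pooled = np.where(sd_pooled == 0, 1.0, sd_pooled)
    Z = (X - grand_mean[:, None]) / sd_pooled[:, None]

    out = np.empty_like(Z)
    for lev in levels:
        sel = batch_sel[lev]
        Zb = Z[:, sel]
        nb = n_b[lev]
        gamma_hat = Zb.mean(axis=1)
        delta2_hat = Zb.var(axis=1, ddof=1)

        gamma_bar = gamma_hat.mean()
        tau2_bar = gamma_hat.var(ddof=1)
        lam_bar = _aprior(delta2_hat)
        theta_bar = _bprior(delta2_hat)

        gamma_star = gamma_hat.copy()
        delta2_star = delta2_hat.copy()
        for _ in range(max_iter):
            g_new = (nb * tau2_bar * gamma_hat + delta2_star * gamma_bar) / (
                nb * tau2_bar + delta2_star
            )
            ssq = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta_bar + 0.5 * ssq) / (nb / 2.0 + lam_bar - 1.0)
            change = max(
                np.abs(g_new - gamma_star).max(initial=0.0),
                np.abs(d_new - delta2_star).max(initial=0.0),
            )
            gamma_star, delta2_star = g_new, d_new
            if change < tol:
                break
        out[:, sel] = (Zb - gamma_star[:, None]) / np.sqrt(delta2_star)[:, None]
    return out * sd_pooled[:, None] + grand_mean[:, None]


def _aprior(delta2_hat: np.ndarray) -> float:
    m, s2 = delta2_hat.mean(), delta2_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2 if s2 > 0 else 2.0


def _bprior(delta2_hat: np.ndarray) -> float:
    m, s2 = delta2_hat.mean(), delta2_hat.var(ddof=1)
    return (m * s2 + m**3) / s2 if s2 > 0 else m


# ---------------------------------------------------------------------------
# Contrast comparison
# ---------------------------------------------------------------------------

def compare_contrast_overlap(result_x: DifferentialResult, result_y: DifferentialResult) -> dict:
    """Containment of x's directional calls within y's, both orientations.

    Returns a mapping ``(dir_x, dir_y) -> {count, total, fraction}``
    where ``fraction`` is |x_dir ∩ y_dir| / |x_dir| (None when x made
    no calls in that direction).
    """
    if set(result_x.feature_ids) != set(result_y.feature_ids):
        raise ValueError("contrast results cover different feature universes")
    out = {}
    for dx in ("up", "down"):
        x_set = result_x.genes_called(dx)
        for dy in ("up", "down"):
            y_set = result_y.genes_called(dy)
            count = len(x_set & y_set)
            out[(dx, dy)] = {
                "count": count,
                "total": len(x_set),
                "fraction": count / len(x_set) if x_set else None,
            }
    return out
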