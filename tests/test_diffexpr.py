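"""SAM statistics, fudge factor, permutation q-values, batch adjustment."""

import itertools
import math

import numpy as np
import pytest

from gradeweaver.cohort import CohortConfig, generate_cohort
from gradeweaver.diffexpr import (
    ContrastSpec,
    SamModel,
    batch_adjust,
    call_differential,
    choose_s0,
    compare_contrast_overlap,
    permutation_qvalues,
    sam_statistic,
)
from gradeweaver.io import ExpressionMatrix, FeatureKind


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_sam(values, labels, s0):
    """Direct per-feature evaluation of the moderated t formula (loops)."""
    labels = list(labels)
    classes = sorted(set(labels))
    a_idx = [i for i, l in enumerate(labels) if l == classes[0]]
    b_idx = [i for i, l in enumerate(labels) if l == classes[1]]
    d_out, s_out = [], []
    for row in values:
        ma = sum(row[i] for i in a_idx) / len(a_idx)
        mb = sum(row[i] for i in b_idx) / len(b_idx)
        ssa = sum((row[i] - ma) ** 2 for i in a_idx)
        ssb = sum((row[i] - mb) ** 2 for i in b_idx)
        s = math.sqrt(
            (1 / len(a_idx) + 1 / len(b_idx)) * (ssa + ssb) / (len(a_idx) + len(b_idx) - 2)
        )
        d_out.append((mb - ma) / (s + s0) if s + s0 > 0 else 0.0)
        s_out.append(s)
    return np.array(d_out), np.array(s_out)


def oracle_exhaustive_q(values, labels, s0):
    """q-values by enumerating every distinct label assignment (loops)."""
    labels = list(labels)
    n = len(labels)
    classes = sorted(set(labels))
    n_a = labels.count(classes[0])
    d_obs, _ = oracle_sam(values, labels, s0)
    perm_stats = []
    for combo in itertools.combinations(range(n), n_a):
        lab = [classes[0] if i in combo else classes[1] for i in range(n)]
        d_perm, _ = oracle_sam(values, lab, s0)
        perm_stats.append(np.abs(d_perm))
    B = len(perm_stats)
    q = []
    for i, di in enumerate(np.abs(d_obs)):
        perm_count = sum((p >= di).sum() for p in perm_stats) / B
        obs_count = (np.abs(d_obs) >= di).sum()
        q.append(min(1.0, perm_count / obs_count))
    q = np.array(q)
    order = np.argsort(-np.abs(d_obs), kind="stable")
    running = -np.inf
    out = np.empty(len(q))
    for idx in order:
        running = max(running, q[idx])
        out[idx] = running
    return out


# ---------------------------------------------------------------------------
# sam_statistic
# ---------------------------------------------------------------------------

def test_sam_statistic_derived_example():
    d, s, _ = sam_statistic(np.array([[1.0, 2, 3, 4, 5, 6]]), list("AAABBB"), 0.0)
    assert s[0] == pytest.approx(math.sqrt(2 / 3), abs=1e-10)
    assert d[0] == pytest.approx(3.0 / math.sqrt(2 / 3), abs=1e-10)


def test_sam_statistic_zero_difference_and_antisymmetry(rng):
    values = rng.normal(size=(30, 10))
    values[0] = np.concatenate([rng.normal(0, 1, 5), rng.normal(0, 2, 5)])
    values[0, :5] -= values[0, :5].mean()
    values[0, 5:] -= values[0, 5:].mean()   # identical class means
    labels = ["A"] * 5 + ["B"] * 5
    d, s, _ = sam_statistic(values, labels, 0.1)
    assert d[0] == pytest.approx(0.0, abs=1e-12)
    # swapping labels negates d, leaves s unchanged
    swapped = ["B"] * 5 + ["A"] * 5
    d2, s2, _ = sam_statistic(values, swapped, 0.1)
    assert np.allclose(d2, -d, atol=1e-12)
    assert np.allclose(s2, s, atol=1e-12)


def test_sam_statistic_matches_loop_oracle(rng):
    values = rng.normal(size=(50, 9))
    labels = ["A"] * 4 + ["B"] * 5
    d, s, _ = sam_statistic(values, labels, 0.2)
    d_o, s_o = oracle_sam(values, labels, 0.2)
    assert np.allclose(d, d_o, atol=1e-10)
    assert np.allclose(s, s_o, atol=1e-10)


def test_sam_statistic_constant_feature_flagged():
    values = np.vstack([np.ones(8), np.arange(8.0)])
    d, s, zero = sam_statistic(values, ["A"] * 4 + ["B"] * 4, 0.0)
    assert zero[0] and not zero[1]
    assert d[0] == 0.0


def test_sam_requires_two_per_class():
    with pytest.raises(ValueError):
        sam_statistic(np.ones((3, 3)), ["A", "B", "B"], 0.0)


# ---------------------------------------------------------------------------
# choose_s0
# ---------------------------------------------------------------------------

def oracle_choose_s0(values, labels):
    """Brute-force scan over the same alpha grid, independently coded."""
    d0, s = oracle_sam(values, labels, 0.0)
    num = d0 * s  # numerator = d * s when s0 = 0
    edges = np.percentile(s, np.arange(0, 101, 10))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 9)
    best = (np.inf, None)
    for alpha in range(0, 101, 5):
        cand = np.percentile(s, alpha)
        d = np.where(s + cand > 0, num / (s + cand), 0.0)
        mads = []
        for b in range(10):
            db = d[bins == b]
            if len(db):
                mads.append(np.median(np.abs(db - np.median(db))))
        mads = np.array(mads)
        cv = mads.std() / mads.mean() if mads.mean() > 0 else np.inf
        if cv < best[0] - 1e-15:
            best = (cv, float(cand))
    return best[1]


def test_choose_s0_matches_bruteforce_scan():
    rng = np.random.default_rng(11)
    values = rng.normal(size=(500, 12)) * rng.gamma(2, 1, size=(500, 1))
    labels = ["A"] * 6 + ["B"] * 6
    assert choose_s0(values, labels) == pytest.approx(
        oracle_choose_s0(values, labels), abs=1e-12
    )


def test_choose_s0_bounds_and_degenerate(rng):
    values = rng.normal(size=(200, 8))
    labels = ["A"] * 4 + ["B"] * 4
    _, s, _ = sam_statistic(values, labels, 0.0)
    s0 = choose_s0(values, labels)
    assert s.min() - 1e-12 <= s0 <= s.max() + 1e-12
    with pytest.raises(ValueError):
        choose_s0(np.ones((50, 8)), labels)


def test_choose_s0_all_s_identical_returns_that_value(rng):
    # equal within-class variance pattern for every feature -> all s_i equal
    base = rng.normal(size=(1, 8))
    values = np.tile(base, (60, 1)) + rng.normal(size=(60, 1))  # per-feature offset
    labels = ["A"] * 4 + ["B"] * 4
    _, s, _ = sam_statistic(values, labels, 0.0)
    assert np.allclose(s, s[0])
    assert choose_s0(values, labels) == pytest.approx(s[0])


# ---------------------------------------------------------------------------
# permutation q-values
# ---------------------------------------------------------------------------

def test_qvalues_match_exhaustive_oracle(rng):
    values = rng.normal(size=(40, 4))
    values[:5, 2:] += 3.0
    labels = ["A", "A", "B", "B"]
    q = permutation_qvalues(values, labels, s0=0.1, exhaustive=True)
    q_o = oracle_exhaustive_q(values, labels, 0.1)
    assert np.array_equal(q, q_o)


def test_top_feature_without_permuted_exceedance_gets_zero(rng):
    values = rng.normal(size=(20, 20)) * 0.01
    values[0, 10:] += 100.0   # dominated only by the original labeling itself
    labels = ["A"] * 10 + ["B"] * 10
    q = permutation_qvalues(values, labels, s0=0.05, B=100, seed=9)
    assert q[0] == 0.0


def test_qvalues_null_calibration():
    rng = np.random.default_rng(3)
    values = rng.normal(size=(1000, 80))
    labels = ["A"] * 40 + ["B"] * 40
    s0 = choose_s0(values, labels)
    q = permutation_qvalues(values, labels, s0, B=200, seed=3)
    assert np.mean(q < 0.01) <= 0.03


def test_qvalues_monotone_in_abs_d(rng):
    values = rng.normal(size=(100, 8))
    labels = ["A"] * 4 + ["B"] * 4
    d, _, _ = sam_statistic(values, labels, 0.1)
    q = permutation_qvalues(values, labels, 0.1, B=50, seed=5)
    order = np.argsort(-np.abs(d))
    assert np.all(np.diff(q[order]) >= 0)


def test_qvalues_require_positive_B(rng):
    with pytest.raises(ValueError):
        permutation_qvalues(rng.normal(size=(5, 6)), ["A"] * 3 + ["B"] * 3, 0.1, B=0)


# ---------------------------------------------------------------------------
# calls and contrasts
# ---------------------------------------------------------------------------

def test_call_directions_and_length_mismatch():
    res = call_differential(["a", "b", "c"], np.array([2.0, -2.0, 5.0]),
                            np.array([0.001, 0.001, 0.2]))
    assert list(res.call) == ["up", "down", "ns"]
    with pytest.raises(ValueError):
        call_differential(["a"], np.array([1.0, 2.0]), np.array([0.5, 0.5]))


def test_contrast_antisymmetry(small_cohort):
    _, c = small_cohort
    grade_of = dict(zip(c.samples.df["sample_id"], c.samples.df["grade"]))
    labels = [grade_of[s] for s in c.mrna.sample_ids]
    fwd = SamModel(c.mrna, labels, ContrastSpec("G1", "G3")).fit(B=60, seed=1)
    rev = SamModel(c.mrna, labels, ContrastSpec("G3", "G1")).fit(B=60, seed=1)
    assert np.allclose(fwd.d, -rev.d, atol=1e-10)
    assert fwd.up == rev.down and fwd.down == rev.up


def test_planted_gene_recovery():
    """Planted effects are called in the planted direction; null genes are not."""
    cfg = CohortConfig(n_g1=60, n_g2=0, n_g3=60, n_genes=2000, n_mirnas=25,
                       n_informative_up=50, n_informative_down=50,
                       delta=1.5, noise_sd=1.0, batches=(("b1", 0.0, 1.0),), seed=5)
    c = generate_cohort(cfg)
    grade_of = dict(zip(c.samples.df["sample_id"], c.samples.df["grade"]))
    labels = [grade_of[s] for s in c.mrna.sample_ids]
    res = SamModel(c.mrna, labels, ContrastSpec("G1", "G3")).fit(B=300, seed=5)
    calls = dict(zip(res.feature_ids, res.call))
    planted_ok = sum(calls[g] == d for g, d in c.truth.gene_direction.items())
    assert planted_ok / len(c.truth.gene_direction) >= 0.90
    null_genes = [g for g in res.feature_ids if g not in c.truth.gene_direction]
    null_called = sum(calls[g] != "ns" for g in null_genes)
    assert null_called / len(null_genes) <= 0.02


def test_contrast_overlap_containment():
    d = np.array([2.0, 2.0, 2.0, -2.0])
    mk = lambda q: call_differential(list("ABCD"), d, np.array(q))
    x = mk([0.001, 0.001, 0.001, 0.5])     # up = {A,B,C}
    y_q = [0.001, 0.001, 0.5, 0.001]
    y = call_differential(list("ABCD"), np.array([2.0, 2.0, -2.0, -2.0]), np.array(y_q))
    table = compare_contrast_overlap(x, y)
    assert table[("up", "up")]["fraction"] == pytest.approx(2 / 3)
    same = compare_contrast_overlap(x, x)
    assert same[("up", "up")]["fraction"] == 1.0
    empty = mk([0.5, 0.5, 0.5, 0.5])
    assert compare_contrast_overlap(empty, y)[("up", "up")]["count"] == 0
    assert compare_contrast_overlap(empty, y)[("up", "up")]["fraction"] is None
    with pytest.raises(ValueError):
        compare_contrast_overlap(x, call_differential(["Z"], np.array([1.0]), np.array([0.5])))


# ---------------------------------------------------------------------------
# batch adjustment
# ---------------------------------------------------------------------------

def _matrix(values):
    f = [f"g{i}" for i in range(values.shape[0])]
    s = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(f, s, values, FeatureKind.mRNA)


def test_meanvar_single_batch_identity(rng):
    m = _matrix(rng.normal(size=(30, 10)))
    out = batch_adjust(m, ["b"] * 10, mode="meanvar")
    assert np.allclose(out.values, m.values, atol=1e-10)


def test_meanvar_removes_additive_shift(rng):
    base = rng.normal(size=(40, 6))
    shifted = np.hstack([base, base + 5.0])
    m = _matrix(shifted)
    batches = ["b1"] * 6 + ["b2"] * 6
    out = batch_adjust(m, batches, mode="meanvar")
    b1 = out.values[:, :6].mean(axis=1)
    b2 = out.values[:, 6:].mean(axis=1)
    assert np.allclose(b1, b2, atol=1e-8)


def test_meanvar_idempotent(rng):
    m = _matrix(rng.normal(size=(25, 12)) + np.repeat([0.0, 3.0], 6)[None, :])
    batches = ["b1"] * 6 + ["b2"] * 6
    once = batch_adjust(m, batches, mode="meanvar")
    twice = batch_adjust(once, batches, mode="meanvar")
    assert np.allclose(once.values, twice.values, atol=1e-10)


def oracle_eb_adjust(X, batches):
    """Independently coded EB adjustment (explicit loops over genes)."""
    X = np.asarray(X, float)
    G, n = X.shape
    levels = sorted(set(batches))
    sel = {lev: np.array([b == lev for b in batches]) for lev in levels}
    nb = {lev: sel[lev].sum() for lev in levels}
    grand = np.zeros(G)
    for lev in levels:
        grand += nb[lev] / n * X[:, sel[lev]].mean(axis=1)
    var_pooled = np.array([np.mean((X[g] - grand[g]) ** 2) for g in range(G)])
    sd = np.sqrt(var_pooled)
    Z = (X - grand[:, None]) / sd[:, None]
    out = np.empty_like(Z)
    for lev in levels:
        Zb = Z[:, sel[lev]]
        gamma_hat = Zb.mean(axis=1)
        delta2_hat = Zb.var(axis=1, ddof=1)
        gbar, t2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        m, s2 = delta2_hat.mean(), delta2_hat.var(ddof=1)
        lam = (2 * s2 + m**2) / s2
        theta = (m * s2 + m**3) / s2
        g_star, d_star = gamma_hat.copy(), delta2_hat.copy()
        for _ in range(200):
            g_new = (nb[lev] * t2 * gamma_hat + d_star * gbar) / (nb[lev] * t2 + d_star)
            d_new = (theta + 0.5 * ((Zb - g_new[:, None]) ** 2).sum(axis=1)) / (
                nb[lev] / 2 + lam - 1
            )
            if max(np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max()) < 1e-8:
                g_star, d_star = g_new, d_new
                break
            g_star, d_star = g_new, d_new
        out[:, sel[lev]] = (Zb - g_star[:, None]) / np.sqrt(d_star)[:, None]
    return out * sd[:, None] + grand[:, None], {
        lev: None for lev in levels
    }


def test_eb_matches_independent_method_of_moments(rng):
    X = rng.normal(size=(50, 14))
    X[:, 7:] += rng.normal(1.0, 0.3, size=(50, 1))
    batches = ["b1"] * 7 + ["b2"] * 7
    m = _matrix(X)
    out = batch_adjust(m, batches, mode="eb")
    expected, _ = oracle_eb_adjust(X, batches)
    assert np.allclose(out.values, expected, atol=1e-6)


def test_batch_too_small_rejected(rng):
    m = _matrix(rng.normal(size=(5, 3)))
    with pytest.raises(ValueError, match="fewer than 2"):
        batch_adjust(m, ["b1", "b1", "b2"], mode="meanvar")
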