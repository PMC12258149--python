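"""TPM, ratio categories, dip test (with LP oracle), GMM decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from zwscan.dosage import (build_ratios, dip_null, dip_statistic, dip_test,
                           dosage_report, gmm_bic, tpm_normalize)


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def _counts(gene_counts, sample="s1"):
    return pd.DataFrame([(g, sample, c) for g, c in gene_counts.items()],
                        columns=["gene", "sample", "count"])


def test_two_equal_genes_split_the_million():
    df = tpm_normalize(_counts({"a": 10, "b": 10}), {"a": 1000, "b": 1000})
    assert df["tpm"].tolist() == [5e5, 5e5]


def test_tpm_scale_invariance():
    lengths = {"a": 500, "b": 1500, "c": 900}
    t1 = tpm_normalize(_counts({"a": 5, "b": 30, "c": 11}), lengths)
    t2 = tpm_normalize(_counts({"a": 10, "b": 60, "c": 22}), lengths)
    assert np.allclose(t1["tpm"], t2["tpm"])


def test_three_gene_hand_oracle():
    # rates: 10/0.5=20, 20/2=10, 30/1.5=20 -> sum 50
    df = tpm_normalize(_counts({"a": 10, "b": 20, "c": 30}),
                       {"a": 500, "b": 2000, "c": 1500})
    expect = {"a": 20 / 50 * 1e6, "b": 10 / 50 * 1e6, "c": 20 / 50 * 1e6}
    for _, row in df.iterrows():
        assert row["tpm"] == pytest.approx(expect[row["gene"]])
    assert df["tpm"].sum() == pytest.approx(1e6)


def test_zero_library_errors():
    with pytest.raises(ValueError, match="zero library"):
        tpm_normalize(_counts({"a": 0, "b": 0}), {"a": 100, "b": 100})


def test_per_sample_tpm_sums_to_one_million(clean_dataset):
    expr = clean_dataset.expression.rename(columns={"total_count": "count"})
    lengths = {g.gene_id: g.cds_length for g in clean_dataset.genes}
    tpm = tpm_normalize(expr[["gene", "sample", "count"]], lengths)
    sums = tpm.groupby("sample")["tpm"].sum()
    assert np.allclose(sums, 1e6)


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

def _expr_table(rows):
    return pd.DataFrame(rows, columns=["gene", "sample", "sex", "z_count",
                                       "w_count", "total_count"])


def _with_reference(rows):
    """Add a large equal-expression autosomal-style gene so that TPM
    normalisation is anchored (TPM on one gene alone is degenerate)."""
    samples = {(s, sex) for _g, s, sex, *_ in rows}
    ref = [("ref", s, sex, 0, 0, 100_000) for s, sex in sorted(samples)]
    return _expr_table(rows + ref)


def test_silenced_w_gene_is_category_one_at_half_dose():
    rows = [("g1", "f1", "F", 10, 0, 10), ("g1", "f2", "F", 10, 0, 10),
            ("g1", "m1", "M", 0, 0, 20), ("g1", "m2", "M", 0, 0, 20)]
    out = build_ratios(_with_reference(rows),
                       {"g1": 900, "ref": 900}).set_index("gene")
    assert out.loc["g1", "wz_female"] == 0.0
    assert out.loc["g1", "category"] == 1
    assert out.loc["g1", "zf_zzm"] == pytest.approx(0.5, abs=0.001)


def test_compensated_gene_ratio_near_one():
    rows = [("g1", "f1", "F", 20, 0, 20), ("g1", "m1", "M", 0, 0, 20),
            ("g2", "f1", "F", 10, 10, 20), ("g2", "m1", "M", 0, 0, 20)]
    out = build_ratios(_with_reference(rows),
                       {"g1": 900, "g2": 900, "ref": 900}).set_index("gene")
    assert out.loc["g1", "zf_zzm"] == pytest.approx(1.0, abs=0.001)
    assert out.loc["g2", "category"] == 4  # w/z = 1 >= 0.667


def test_category_boundaries():
    rows = []
    for g, (z, w) in {"g1": (100, 0), "g2": (100, 10), "g3": (100, 30),
                      "g4": (100, 80)}.items():
        rows += [(g, "f1", "F", z, w, z + w), (g, "m1", "M", 0, 0, 200)]
    out = build_ratios(_expr_table(rows),
                       {g: 900 for g in ("g1", "g2", "g3", "g4")}).set_index("gene")
    assert out["category"].to_dict() == {"g1": 1, "g2": 2, "g3": 3, "g4": 4}


def test_uncompensated_cohort_is_unimodal_near_half(clean_dataset):
    """With no planted compensation the Zf/ZZm distribution is unimodal with
    its bulk near 0.5."""
    from zwscan.config import SimConfig
    from zwscan.simulate import simulate_dataset

    cfg = SimConfig(seed=17, compensated_fraction=0.0, expr_baseline=500.0)
    ds = simulate_dataset(cfg)
    lengths = {g.gene_id: g.cds_length for g in ds.genes}
    ratios = build_ratios(ds.expression, lengths)
    vals = ratios["zf_zzm"].to_numpy()
    med = np.median(vals)
    assert 0.4 < med < 0.62
    res = dip_test(vals, n_boot=500, rng=np.random.default_rng(0))
    assert res.pvalue > 0.05


def test_male_floor_excludes_silent_genes():
    rows = [("g1", "f1", "F", 10, 0, 10), ("g1", "m1", "M", 0, 0, 0),
            ("g2", "f1", "F", 10, 0, 10), ("g2", "m1", "M", 0, 0, 50)]
    out = build_ratios(_expr_table(rows), {"g1": 900, "g2": 900})
    assert out["gene"].tolist() == ["g2"]


# ---------------------------------------------------------------------------
# dip statistic / test
# ---------------------------------------------------------------------------

def _dip_lp_oracle(values, tol=1e-5):
    """Independent LP feasibility oracle for the dip.

    dip = min over unimodal CDFs G of sup|F_n - G|. For a candidate d and
    mode placement, existence of G is a linear feasibility problem in G's
    values at the sample points (band, monotonicity and convex/concave shape
    constraints); d is found by bisection.
    """

    def piece(xs, los, his, off, n_vars, A, b, concave):
        k = len(xs)
        for j in range(k):
            row = [0.0] * n_vars
            row[off + j] = -1.0
            A.append(row[:]); b.append(-los[j])
            row2 = [0.0] * n_vars
            row2[off + j] = 1.0
            A.append(row2); b.append(his[j])
        for j in range(k - 1):
            row = [0.0] * n_vars
            row[off + j] = 1.0
            row[off + j + 1] = -1.0
            A.append(row); b.append(0.0)
        for j in range(1, k - 1):
            dx1, dx2 = xs[j] - xs[j - 1], xs[j + 1] - xs[j]
            s = 1.0 if not concave else -1.0
            row = [0.0] * n_vars
            row[off + j - 1] = -s * dx2
            row[off + j] = s * (dx1 + dx2)
            row[off + j + 1] = -s * dx1
            A.append(row); b.append(0.0)

    def feasible(xu, cum, d):
        K = len(xu)
        lo = [cum[j] - d for j in range(K)]
        hi = [(cum[j - 1] if j > 0 else 0.0) + d for j in range(K)]
        for m in range(K):  # mode at node m, jump allowed there
            n_left, n_right = m + 1, K - m
            n_vars = n_left + n_right
            A, b = [], []
            piece(list(xu[: m + 1]),
                  lo[:m] + [(cum[m - 1] if m > 0 else 0.0) - d],
                  hi[:m] + [(cum[m - 1] if m > 0 else 0.0) + d],
                  0, n_vars, A, b, concave=False)
            piece(list(xu[m:]), [cum[m] - d] + lo[m + 1:],
                  [cum[m] + d] + hi[m + 1:], n_left, n_vars, A, b, concave=True)
            row = [0.0] * n_vars
            row[n_left - 1] = 1.0
            row[n_left] = -1.0
            A.append(row); b.append(0.0)
            if linprog([0.0] * n_vars, A_ub=np.array(A), b_ub=np.array(b),
                       bounds=[(None, None)] * n_vars,
                       method="highs").status == 0:
                return True
        for s in range(1, K):  # mode strictly between nodes s-1 and s
            A, b = [], []
            piece(list(xu[:s]), lo[:s], hi[:s], 0, K, A, b, concave=False)
            piece(list(xu[s:]), lo[s:], hi[s:], s, K, A, b, concave=True)
            if linprog([0.0] * K, A_ub=np.array(A), b_ub=np.array(b),
                       bounds=[(None, None)] * K, method="highs").status == 0:
                return True
        return False

    x = np.sort(np.asarray(values, float))
    xu, counts = np.unique(x, return_counts=True)
    if len(xu) == 1:
        return 0.0
    cum = np.cumsum(counts) / x.size
    lo_d, hi_d = 0.0, 0.25
    if feasible(xu, cum, 0.0):
        return 0.0
    while hi_d - lo_d > tol:
        mid = 0.5 * (lo_d + hi_d)
        if feasible(xu, cum, mid):
            hi_d = mid
        else:
            lo_d = mid
    return hi_d


def test_dip_known_exact_values():
    assert dip_statistic([0.0] * 50 + [1.0] * 50) == pytest.approx(0.25, abs=1e-9)
    n = 20
    assert dip_statistic(np.arange(n)) == pytest.approx(1 / (2 * n), abs=1e-9)
    assert dip_statistic([3.0, 3.0, 3.0]) == 0.0


def test_dip_matches_lp_oracle_on_small_samples():
    rng = np.random.default_rng(99)
    for trial in range(12):
        n = int(rng.integers(4, 11))
        if trial % 3 == 0:
            x = rng.random(n)
        elif trial % 3 == 1:
            x = rng.integers(0, 3, n).astype(float)  # ties
        else:
            x = np.concatenate([rng.normal(0, 0.2, n // 2),
                                rng.normal(2, 0.2, n - n // 2)])
        if np.ptp(x) == 0:
            continue
        assert dip_statistic(x) == pytest.approx(_dip_lp_oracle(x), abs=2e-4)


def test_dip_bounds():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(4, 60))
        x = rng.normal(size=n)
        d = dip_statistic(x)
        assert 1 / (2 * n) - 1e-9 <= d <= 0.25 + 1e-9


def test_dip_test_rejects_perfect_bimodality():
    res = dip_test([0.0] * 50 + [1.0] * 50, n_boot=1000,
                   rng=np.random.default_rng(0))
    assert res.pvalue < 0.01


def test_dip_test_requires_four_values():
    with pytest.raises(ValueError):
        dip_test([1.0, 2.0, 3.0])


def test_dip_type_one_error_calibrated():
    """Rejection rate on uniform data is ~alpha (shared null table)."""
    rng = np.random.default_rng(8)
    null = dip_null(100, 1500, rng)
    rej = 0
    reps = 500
    for _ in range(reps):
        d = dip_statistic(rng.random(100))
        p = (1 + np.sum(null >= d - 1e-12)) / (len(null) + 1)
        rej += p < 0.05
    rate = rej / reps
    assert abs(rate - 0.05) < 0.03


def test_dip_power_on_thirty_percent_second_mode():
    """>= 80% power at alpha=0.05 for a 30% compensated subpopulation
    (modes 0.5 and 1.0, n=300)."""
    rng = np.random.default_rng(9)
    null = dip_null(300, 1500, rng)
    rej = 0
    reps = 40
    for _ in range(reps):
        x = np.concatenate([rng.normal(0.5, 0.1, 210), rng.normal(1.0, 0.1, 90)])
        d = dip_statistic(x)
        p = (1 + np.sum(null >= d - 1e-12)) / (len(null) + 1)
        rej += p < 0.05
    assert rej / reps >= 0.8


# ---------------------------------------------------------------------------
# GMM
# ---------------------------------------------------------------------------

def test_gmm_single_gaussian_prefers_k1():
    chosen = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.5, 0.1, 500)
        chosen.append(gmm_bic(x, rng=rng).k)
    assert sum(k == 1 for k in chosen) >= 9  # >= 95% in expectation


def test_gmm_recovers_separated_modes():
    rng = np.random.default_rng(4)
    x = np.concatenate([rng.normal(0.5, 0.05, 350), rng.normal(1.0, 0.05, 150)])
    res = gmm_bic(x, rng=rng)
    assert res.k == 2
    assert res.means[0] == pytest.approx(0.5, abs=0.03)
    assert res.means[1] == pytest.approx(1.0, abs=0.03)
    assert res.weights[1] == pytest.approx(0.3, abs=0.06)


def test_gmm_loglik_nondecreasing():
    rng = np.random.default_rng(5)
    x = np.concatenate([rng.normal(0, 1, 60), rng.normal(1, 2, 60)])
    res = gmm_bic(x, k_set=(2,), rng=rng)
    tr = res.loglik_trace
    assert len(tr) >= 2
    assert all(b >= a - 1e-7 for a, b in zip(tr, tr[1:]))


def test_gmm_degenerate_input_flagged():
    res = gmm_bic([1.0] * 20)
    assert res.k == 1 and res.zero_variance


def test_gmm_matches_sklearn_crosscheck():
    """Independent route: sklearn's GaussianMixture on the same data finds
    the same k-2 solution (means within 0.02, log-likelihood within 1%)."""
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(6)
    x = np.concatenate([rng.normal(0.5, 0.07, 300), rng.normal(1.0, 0.07, 200)])
    ours = gmm_bic(x, k_set=(2,), rng=rng)
    sk = GaussianMixture(2, n_init=5, tol=1e-8, reg_covar=1e-6,
                         random_state=0).fit(x[:, None])
    sk_means = np.sort(sk.means_.ravel())
    assert np.allclose(ours.means, sk_means, atol=0.02)
    sk_ll = sk.score(x[:, None]) * len(x)
    assert ours.loglik == pytest.approx(sk_ll, rel=0.01)


def test_gmm_needs_eight_points():
    with pytest.raises(ValueError):
        gmm_bic([0.1, 0.2, 0.3])


# ---------------------------------------------------------------------------
# report plumbing
# ---------------------------------------------------------------------------

def test_dosage_report_runs_gmm_only_on_low_wz(clean_dataset):
    lengths = {g.gene_id: g.cds_length for g in clean_dataset.genes}
    ratios = build_ratios(clean_dataset.expression, lengths)
    rep = dosage_report(ratios, n_boot=200, rng=np.random.default_rng(0))
    assert set(rep["categories"]) <= {1, 2, 3, 4}
    n_low = int(ratios["category"].isin((1, 2)).sum())
    if n_low >= 8:
        assert "gmm_low_wz" in rep
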