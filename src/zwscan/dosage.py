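"""Dosage-compensation testing from allele-tagged expression counts.

TPM normalisation, female W:Z and Zfemale:ZZmale ratio construction, the
four-way W:Z category partition, Hartigan's dip test of unimodality (with a
Monte-Carlo uniform null), and 1-D Gaussian-mixture decomposition with BIC
model choice. Under no compensation the Zfemale/ZZmale ratio concentrates
near 0.5 (one Z dose vs two); female-specific upregulation of hemizygous
genes shows up as a second mode near 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .config import ConfigError

log = logging.getLogger("zwscan")

#: W:Z ratio category boundaries (category 1: wz == 0; 2: (0, 0.256);
#: 3: [0.256, 0.667); 4: >= 0.667)
WZ_BOUNDS = (0.256, 0.667)


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def tpm_normalize(counts: pd.DataFrame, lengths: dict) -> pd.DataFrame:
    """Transcripts per million from a long (gene, sample, count) table.

    rate = count / length_kb; tpm = rate * 1e6 / sum(rate) per sample.
    Every per-sample TPM column sums to 1e6 (within float tolerance).
    """
    df = counts.copy()
    missing = set(df["gene"]) - set(lengths)
    if missing:
        raise KeyError(f"genes without length: {sorted(missing)[:5]}...")
    lens = df["gene"].map(lengths).astype(float)
    if (lens <= 0).any():
        raise ValueError("gene lengths must be > 0")
    df["rate"] = df["count"] / (lens / 1000.0)
    out = []
    for sample, sub in df.groupby("sample", sort=True):
        total = sub["rate"].sum()
        if total == 0:
            raise ValueError(f"{sample}: zero library (no mapped counts)")
        s = sub.copy()
        s["tpm"] = s["rate"] * 1e6 / total
        out.append(s)
    res = pd.concat(out, ignore_index=True).drop(columns=["rate"])
    return res


# ---------------------------------------------------------------------------
# ratio construction
# ---------------------------------------------------------------------------

def build_ratios(expression: pd.DataFrame, lengths: dict,
                 min_male_tpm: float = 1.0) -> pd.DataFrame:
    """Per-gene W:Z (females) and Zfemale:ZZmale expression ratios.

    ``expression`` is the allele-tagged counts table (gene, sample, sex,
    z_count, w_count, total_count). Female allele-level expression is the
    allele fraction times the gene's TPM; replicates are aggregated by
    arithmetic mean. Genes whose mean male TPM is below ``min_male_tpm``
    are excluded (ratio undefined at the expression floor). Category:
    1 wz=0; 2 0<wz<0.256; 3 0.256<=wz<0.667; 4 wz>=0.667.
    """
    df = expression.copy()
    if not len(df):
        return pd.DataFrame(columns=["gene", "wz_female", "zf_zzm", "category"])
    if (df["sex"] == "F").sum() == 0 or (df["sex"] == "M").sum() == 0:
        raise ConfigError("need expression samples of both sexes")
    tot = df.rename(columns={"total_count": "count"})[["gene", "sample", "count"]]
    tpm = tpm_normalize(tot, lengths).set_index(["gene", "sample"])["tpm"]
    df = df.set_index(["gene", "sample"])
    df["tpm"] = tpm
    df = df.reset_index()

    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        fem = sub[sub["sex"] == "F"]
        mal = sub[sub["sex"] == "M"]
        male_mean = mal["tpm"].mean()
        if not np.isfinite(male_mean) or male_mean < min_male_tpm:
            continue
        # W:Z ratio per female sample; samples with z=0 excluded from the mean
        wz_vals = []
        zf_vals = []
        for _, r in fem.iterrows():
            tc = r["z_count"] + r["w_count"]
            if r["z_count"] > 0:
                wz_vals.append(r["w_count"] / r["z_count"])
            zfrac = r["z_count"] / tc if tc > 0 else 0.0
            zf_vals.append(zfrac * r["tpm"])
        if not wz_vals:
            continue
        wz = float(np.mean(wz_vals))
        zf_zzm = float(np.mean(zf_vals)) / float(male_mean)
        if wz == 0:
            cat = 1
        elif wz < WZ_BOUNDS[0]:
            cat = 2
        elif wz < WZ_BOUNDS[1]:
            cat = 3
        else:
            cat = 4
        rows.append((gene, wz, zf_zzm, cat))
    return pd.DataFrame(rows, columns=["gene", "wz_female", "zf_zzm", "category"])


# ---------------------------------------------------------------------------
# Hartigan's dip statistic
# ---------------------------------------------------------------------------
#
# dip(F_n) is the smallest d such that some unimodal CDF G stays within the
# sup-norm band F_n +/- d. Collapsing ties to unique points x_j with
# cumulative fractions c_j, the band constraints at the nodes are
# lo_j = c_j - d (from the right limit) and hi_j = c_{j-1} + d (left limit);
# a convex nondecreasing piece fits nodes 0..m-1 iff the greatest convex
# minorant of hi stays above lo at every node but the last (the mode, where a
# jump is allowed), and symmetrically a concave piece fits a suffix iff the
# least concave majorant of lo stays below hi. G exists iff some prefix and
# suffix overlap. d is found by bisection; checks are numba-compiled.


@njit(cache=False)
def _prefix_len(x, lo, hi):
    """Max nodes in a prefix admitting a convex nondecreasing in-band piece."""
    K = len(x)
    hull = np.empty(K, dtype=np.int64)
    hull[0] = 0
    h = 1  # hull size
    for j in range(1, K):
        # pop while the turn (hull[h-2] -> hull[h-1] -> j) is not convex
        while h >= 2:
            a, b = hull[h - 2], hull[h - 1]
            if (hi[b] - hi[a]) * (x[j] - x[b]) <= (hi[j] - hi[b]) * (x[b] - x[a]):
                break
            h -= 1
        v = hull[h - 1]
        # nodes v..j-1 sit under the segment v -> j; hull must clear lo there
        for i in range(v, j):
            if i == v:
                val = hi[v]
            else:
                val = hi[v] + (hi[j] - hi[v]) * (x[i] - x[v]) / (x[j] - x[v])
            if val < lo[i] - 1e-12:
                return j  # prefix 0..j-1 was the last feasible one
        hull[h] = j
        h += 1
    return K


@njit(cache=False)
def _suffix_len(x, lo, hi):
    """Max nodes in a suffix admitting a concave nondecreasing in-band piece."""
    K = len(x)
    hull = np.empty(K, dtype=np.int64)
    hull[0] = K - 1
    h = 1
    count = 1
    for j in range(K - 2, -1, -1):
        while h >= 2:
            a, b = hull[h - 2], hull[h - 1]
            # concave from the right: slopes must decrease leftwards
            if (lo[a] - lo[b]) * (x[b] - x[j]) <= (lo[b] - lo[j]) * (x[a] - x[b]):
                break
            h -= 1
        v = hull[h - 1]
        for i in range(j + 1, v + 1):
            if i == v:
                val = lo[v]
            else:
                val = lo[j] + (lo[v] - lo[j]) * (x[i] - x[j]) / (x[v] - x[j])
            if val > hi[i] + 1e-12:
                return count
        hull[h] = j
        h += 1
        count += 1
    return K


@njit(cache=False)
def _dip_feasible(x, cum, d):
    K = len(x)
    lo = np.empty(K)
    hi = np.empty(K)
    for j in range(K):
        lo[j] = cum[j] - d
        hi[j] = (cum[j - 1] if j > 0 else 0.0) + d
    left = _prefix_len(x, lo, hi)
    right = _suffix_len(x, lo, hi)
    # mode at a shared node (the ECDF jump there may be absorbed by G's jump)
    if left + right >= K + 1:
        return True
    # mode strictly between nodes s-1 and s: both junction nodes then need a
    # nonempty band (their own jumps must be halved by d)
    if left + right >= K:
        for s in range(max(1, K - right), min(left, K - 1) + 1):
            jump_l = cum[s - 1] - (cum[s - 2] if s >= 2 else 0.0)
            jump_r = cum[s] - cum[s - 1]
            if d >= jump_l / 2.0 - 1e-12 and d >= jump_r / 2.0 - 1e-12:
                return True
    return False


@njit(cache=False)
def _dip_stat(x, cum):
    lo_d, hi_d = 0.0, 0.25
    if _dip_feasible(x, cum, lo_d):
        return 0.0
    for _ in range(50):
        mid = 0.5 * (lo_d + hi_d)
        if _dip_feasible(x, cum, mid):
            hi_d = mid
        else:
            lo_d = mid
    return hi_d


def dip_statistic(values) -> float:
    """Hartigan & Hartigan's dip: sup-norm distance from the ECDF to the
    closest unimodal distribution function."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("dip requires finite values")
    uniq, counts = np.unique(x, return_counts=True)
    if len(uniq) == 1:
        return 0.0
    cum = np.cumsum(counts) / x.size
    return float(_dip_stat(uniq, cum))


def dip_null(n: int, n_boot: int, rng) -> np.ndarray:
    """Monte-Carlo null distribution of the dip for uniform samples of size n."""
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])


@dataclass
class DipResult:
    dip: float
    pvalue: float
    n: int
    n_boot: int


def dip_test(values, n_boot: int = 2000, rng=None,
             null_dips: np.ndarray | None = None) -> DipResult:
    """Dip test of unimodality; p is the Monte-Carlo fraction of uniform(0,1)
    samples of the same size whose dip is at least the observed one."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError(f"dip test needs n >= 4 finite values, got {x.size}")
    if rng is None:
        rng = np.random.default_rng(0)
    obs = dip_statistic(x)
    if null_dips is None:
        null_dips = dip_null(x.size, n_boot, rng)
    p = (1.0 + np.sum(null_dips >= obs - 1e-12)) / (len(null_dips) + 1.0)
    return DipResult(obs, float(p), int(x.size), len(null_dips))


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture with BIC selection
# ---------------------------------------------------------------------------

@dataclass
class GmmResult:
    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    bic: dict
    loglik_trace: list = field(default_factory=list)
    zero_variance: bool = False


def _em_1d(x, k, rng, tol, max_iter, var_floor):
    n = x.size
    means = np.sort(rng.choice(x, size=k, replace=False)) if k <= n else None
    var = max(x.var(), var_floor)
    variances = np.full(k, var)
    weights = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    trace = []
    for _ in range(max_iter):
        # E step
        logp = (-0.5 * np.log(2 * np.pi * variances)[None, :]
                - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
                + np.log(weights)[None, :])
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logp - lse[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return ll, weights, means, variances, trace


def gmm_bic(values, k_set=(1, 2), n_init: int = 10, rng=None, tol: float = 1e-8,
            max_iter: int = 500, var_floor: float = 1e-6) -> GmmResult:
    """Fit 1-D Gaussian mixtures by EM for each k and choose by BIC.

    BIC = -2 logL + (3k - 1) log n. The best of ``n_init`` random
    initialisations is kept per k. An all-equal sample returns k=1 with the
    zero-variance flag set.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise ValueError(f"gmm_bic needs n >= 8, got {x.size}")
    if rng is None:
        rng = np.random.default_rng(0)
    if np.ptp(x) == 0:
        return GmmResult(1, np.array([1.0]), np.array([x[0]]),
                         np.array([0.0]), float("inf"), {1: float("-inf")},
                         [], zero_variance=True)
    n = x.size
    fits = {}
    for k in sorted(k_set):
        best = None
        for init in range(n_init if k > 1 else 1):
            ll, w, mu, var, trace = _em_1d(x, k, rng, tol, max_iter, var_floor)
            if best is None or ll > best[0]:
                best = (ll, w, mu, var, trace)
        bic = -2.0 * best[0] + (3 * k - 1) * np.log(n)
        fits[k] = (bic, best)
    bics = {k: fits[k][0] for k in fits}
    k_best = min(bics, key=lambda k: bics[k])
    ll, w, mu, var, trace = fits[k_best][1]
    order = np.argsort(mu)
    return GmmResult(k_best, w[order], mu[order], var[order], ll,
                     bics, trace)


# ---------------------------------------------------------------------------
# per-category report
# ---------------------------------------------------------------------------

def dosage_report(ratios: pd.DataFrame, n_boot: int = 2000, rng=None,
                  gmm_categories=(1, 2)) -> dict:
    """Dip test per W:Z category; GMM on the low-W categories only.

    The mixture decomposition is run only for categories with W:Z below the
    first boundary (hemizygous-like genes), where a compensated subgroup
    would appear as a second mode near 1.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = {"categories": {}}
    for cat, sub in ratios.groupby("category", sort=True):
        vals = sub["zf_zzm"].to_numpy()
        entry = {"n": int(len(vals)), "median": float(np.median(vals))
                 if len(vals) else float("nan")}
        if len(vals) >= 4:
            res = dip_test(vals, n_boot=n_boot, rng=rng)
            entry["dip"] = res.dip
            entry["dip_p"] = res.pvalue
        out["categories"][int(cat)] = entry
    low = ratios[ratios["category"].isin(gmm_categories)]["zf_zzm"].to_numpy()
    if low.size >= 8:
        g = gmm_bic(low, rng=rng)
        out["gmm_low_wz"] = {"k": g.k, "weights": g.weights.tolist(),
                             "means": g.means.tolist(),
                             "variances": g.variances.tolist(),
                             "bic": {int(k): float(v) for k, v in g.bic.items()}}
    return out
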