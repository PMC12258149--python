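"""Sex-linked region discovery from sexed cohorts.

Sex-linked variant ascertainment (heterozygous in one sex, homozygous in the
other), windowed Weir-Cockerham FST between the sexes, log2 female:male
window ratios (SNP density or coverage), linkage-disequilibrium profiling
(second-highest r-squared per window pair), reference-free k-mer sex
markers, and Z/W phase assignment of assembly contigs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codon import revcomp
from .config import ConfigError
from .io import MISSING, GenotypeMatrix

log = logging.getLogger("zwscan")


# ---------------------------------------------------------------------------
# sex-linked variants
# ---------------------------------------------------------------------------

@dataclass
class HeterogametyCall:
    system: str          # 'ZW', 'XY' or 'ambiguous'
    n_zw_like: int
    n_xy_like: int


def find_sex_linked_variants(gm: GenotypeMatrix, min_het: int,
                             hom_policy: str = "min_count",
                             majority: float = 0.8):
    """Variants heterozygous in one sex and homozygous in the other.

    A variant is ZW-like when >= ``min_het`` females are heterozygous and the
    males are homozygous: under ``hom_policy='all'`` every male must be
    observed homozygous (missing disqualifies), under ``'min_count'`` at
    least ``min_het`` males must be. XY-like is the mirror image. Returns
    (DataFrame of qualifying variants, HeterogametyCall); the system is
    called when one class holds >= ``majority`` of qualifying variants.
    """
    if min_het < 1:
        raise ConfigError(f"min_het must be >= 1, got {min_het}")
    if hom_policy not in ("all", "min_count"):
        raise ConfigError(f"hom_policy must be 'all' or 'min_count', got {hom_policy!r}")
    f_idx, m_idx = gm.females(), gm.males()
    if len(f_idx) == 0 or len(m_idx) == 0:
        raise ConfigError("both sexes must be present in the cohort")
    if min_het > min(len(f_idx), len(m_idx)):
        raise ConfigError(f"min_het={min_het} exceeds the smaller sex sample size")

    d = gm.dosage
    het_f = (d[:, f_idx] == 1).sum(axis=1)
    hom_f = ((d[:, f_idx] == 0) | (d[:, f_idx] == 2)).sum(axis=1)
    miss_f = (d[:, f_idx] == MISSING).sum(axis=1)
    het_m = (d[:, m_idx] == 1).sum(axis=1)
    hom_m = ((d[:, m_idx] == 0) | (d[:, m_idx] == 2)).sum(axis=1)
    miss_m = (d[:, m_idx] == MISSING).sum(axis=1)

    if hom_policy == "all":
        hom_ok_m = hom_m == len(m_idx)
        hom_ok_f = hom_f == len(f_idx)
    else:
        hom_ok_m = hom_m >= min_het
        hom_ok_f = hom_f >= min_het
    zw_like = (het_f >= min_het) & hom_ok_m
    xy_like = (het_m >= min_het) & hom_ok_f

    mask = zw_like | xy_like
    out = gm.variants.loc[mask].copy()
    out["het_count_F"] = het_f[mask]
    out["hom_count_F"] = hom_f[mask]
    out["missing_F"] = miss_f[mask]
    out["het_count_M"] = het_m[mask]
    out["hom_count_M"] = hom_m[mask]
    out["missing_M"] = miss_m[mask]
    out["class"] = np.where(zw_like[mask] & ~xy_like[mask], "ZW-like",
                            np.where(xy_like[mask] & ~zw_like[mask], "XY-like", "both"))
    out = out.reset_index(drop=True)

    n_zw = int((out["class"] == "ZW-like").sum())
    n_xy = int((out["class"] == "XY-like").sum())
    total = n_zw + n_xy
    if total == 0:
        system = "ambiguous"
    elif n_zw / total >= majority:
        system = "ZW"
    elif n_xy / total >= majority:
        system = "XY"
    else:
        system = "ambiguous"
    log.info("find_sex_linked_variants: input=%d qualifying=%d ZW-like=%d XY-like=%d",
             gm.n_variants, len(out), n_zw, n_xy)
    return out, HeterogametyCall(system, n_zw, n_xy)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def wc_fst_components(dosage_row: np.ndarray, f_idx, m_idx):
    """Per-variant Weir & Cockerham (1984) variance components (a, b, c).

    Two populations (females, males), diploid; missing genotypes excluded.
    Returns None for variants unusable (a population fully missing, or
    monomorphic across both sexes).
    """
    comps = []
    for idx in (f_idx, m_idx):
        d = dosage_row[idx]
        d = d[d != MISSING]
        if d.size == 0:
            return None
        n_i = d.size
        p_i = d.sum() / (2.0 * n_i)
        h_i = np.mean(d == 1)
        comps.append((n_i, p_i, h_i))
    r = 2.0
    n1, p1, h1 = comps[0]
    n2, p2, h2 = comps[1]
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return None
    p_all = (n1 * p1 + n2 * p2) / (r * nbar)
    if p_all <= 0.0 or p_all >= 1.0:
        return None
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    s2 = (n1 * (p1 - p_all) ** 2 + n2 * (p2 - p_all) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (p_all * (1 - p_all) - (r - 1.0) / r * s2 - hbar / 4.0)
                       / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (p_all * (1 - p_all) - (r - 1.0) / r * s2
                                 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


def variant_fst(dosage_row: np.ndarray, f_idx, m_idx):
    """Single-variant Weir-Cockerham estimate a/(a+b+c), or NaN."""
    comp = wc_fst_components(dosage_row, f_idx, m_idx)
    if comp is None:
        return np.nan
    a, b, c = comp
    denom = a + b + c
    return np.nan if denom == 0 else a / denom


def windowed_fst(gm: GenotypeMatrix, window: int = 50_000) -> pd.DataFrame:
    """Weighted window FST: sum(a) / sum(a+b+c) over variants per window.

    Windows tile each chromosome as half-open [start, start+window);
    variant-free windows are reported with NaN.
    """
    if window <= 0:
        raise ConfigError(f"window must be > 0, got {window}")
    f_idx, m_idx = gm.females(), gm.males()
    if len(f_idx) < 2 or len(m_idx) < 2:
        raise ConfigError("need >= 2 individuals per sex for FST")
    rows = []
    for chrom, sub in gm.variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        idx = sub.index.to_numpy()
        last = int(pos.max())
        for start in range(0, last + 1, window):
            in_win = (pos >= start + 1) & (pos < start + window + 1)
            num = den = 0.0
            n_var = 0
            for vi in idx[in_win]:
                comp = wc_fst_components(gm.dosage[vi], f_idx, m_idx)
                if comp is None:
                    continue
                a, b, c = comp
                num += a
                den += a + b + c
                n_var += 1
            fst = num / den if den != 0 and n_var else np.nan
            rows.append((chrom, start, start + window, n_var, fst))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_variants", "fst"])


# ---------------------------------------------------------------------------
# female:male log2 window ratios
# ---------------------------------------------------------------------------

def fm_log2_windows(values: pd.DataFrame, sex_map: dict,
                    value_col: str = "value") -> pd.DataFrame:
    """log2(mean female value) - log2(mean male value) per window.

    ``values`` is long-form with columns chrom, start, end, sample and the
    value column (per-sample SNP density or coverage, >= 0). Windows where
    either sex mean is zero are reported as NaN rather than +/-inf.
    """
    if (values[value_col] < 0).any():
        raise ValueError(f"{value_col}: negative values not allowed")
    df = values.copy()
    missing = set(df["sample"]) - set(sex_map)
    if missing:
        raise ValueError(f"samples without sex label: {sorted(missing)}")
    df["sex"] = df["sample"].map(sex_map)
    rows = []
    for (chrom, start, end), sub in df.groupby(["chrom", "start", "end"], sort=True):
        mf = sub.loc[sub["sex"] == "F", value_col].mean()
        mm = sub.loc[sub["sex"] == "M", value_col].mean()
        if not np.isfinite(mf) or not np.isfinite(mm) or mf == 0 or mm == 0:
            ratio = np.nan
        else:
            ratio = float(np.log2(mf) - np.log2(mm))
        rows.append((chrom, start, end, ratio))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "log2_fm"])


def per_sample_het_density(gm: GenotypeMatrix, window: int = 50_000) -> pd.DataFrame:
    """Heterozygous-site density per individual per window (sites/kb)."""
    rows = []
    for chrom, sub in gm.variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        idx = sub.index.to_numpy()
        last = int(pos.max())
        for start in range(0, last + 1, window):
            in_win = (pos >= start + 1) & (pos < start + window + 1)
            d = gm.dosage[idx[in_win]]
            het = (d == 1).sum(axis=0)
            for s, h in zip(gm.samples, het):
                rows.append((chrom, start, start + window, s,
                             1000.0 * float(h) / window))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "value"])


def female_snp_density_track(gm: GenotypeMatrix, chrom: str,
                             window: int = 50_000) -> np.ndarray:
    """Mean female heterozygous-site count per window along one chromosome.

    This is the series the stratum-boundary changepoint operates on.
    """
    f_idx = gm.females()
    sub = gm.variants[gm.variants["chrom"] == chrom]
    pos = sub["pos"].to_numpy()
    idx = sub.index.to_numpy()
    last = int(pos.max()) if len(pos) else 0
    out = []
    for start in range(0, last + 1, window):
        in_win = (pos >= start + 1) & (pos < start + window + 1)
        d = gm.dosage[idx[in_win]][:, f_idx]
        out.append(float((d == 1).sum()) / max(1, len(f_idx)))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_profile(gm: GenotypeMatrix, chrom: str, region=None, maf_min: float = 0.15,
               max_missing: float = 0.0, thin: int = 10_000,
               window: int = 100_000, decay_bin: int = 10_000):
    """Second-highest r-squared per 100-kb window pair, plus an LD decay curve.

    r-squared is the squared Pearson correlation of diploid dosage vectors
    over pairwise-complete individuals; variants are thinned to at most one
    per ``thin`` bp (first by position). Window pairs with fewer than two
    usable comparisons get NaN.
    """
    sub = gm.variants[gm.variants["chrom"] == chrom]
    if region is not None:
        sub = sub[(sub["pos"] >= region[0]) & (sub["pos"] <= region[1])]
    keep = []
    last_kept = -np.inf
    for vi, pos in zip(sub.index.to_numpy(), sub["pos"].to_numpy()):
        d = gm.dosage[vi]
        n_miss = int((d == MISSING).sum())
        if n_miss / len(d) > max_missing:
            continue
        called = d[d != MISSING]
        if called.size == 0:
            continue
        p = called.sum() / (2 * called.size)
        if min(p, 1 - p) < maf_min:
            continue
        if pos - last_kept < thin:
            continue
        keep.append((vi, pos))
        last_kept = pos
    if not keep:
        raise ValueError("no variants left after LD filters")
    idx = np.array([k[0] for k in keep])
    pos = np.array([k[1] for k in keep])
    dos = gm.dosage[idx].astype(float)
    dos[dos == MISSING] = np.nan

    n = len(idx)
    r2 = np.full((n, n), np.nan)
    for i in range(n):
        for j_ in range(i + 1, n):
            ok = ~np.isnan(dos[i]) & ~np.isnan(dos[j_])
            if ok.sum() < 2:
                continue
            x, y = dos[i][ok], dos[j_][ok]
            if x.std() == 0 or y.std() == 0:
                continue  # monomorphic after pairing: skip
            r = np.corrcoef(x, y)[0, 1]
            r2[i, j_] = r2[j_, i] = r * r

    win_of = (pos - 1) // window
    windows = np.unique(win_of)
    rows = []
    for wi in windows:
        for wj in windows:
            if wj < wi:
                continue
            ii = np.flatnonzero(win_of == wi)
            jj = np.flatnonzero(win_of == wj)
            vals = r2[np.ix_(ii, jj)].ravel()
            if wi == wj:
                vals = r2[np.ix_(ii, jj)][np.triu_indices(len(ii), k=1)] \
                    if len(ii) > 1 else np.array([])
            vals = vals[~np.isnan(vals)]
            second = float(np.sort(vals)[-2]) if vals.size >= 2 else np.nan
            rows.append((int(wi) * window, int(wj) * window, vals.size, second))
    pairs = pd.DataFrame(rows, columns=["window_i", "window_j", "n_pairs",
                                        "second_max_r2"])

    # decay curve
    dec_rows = []
    iu = np.triu_indices(n, k=1)
    dists = np.abs(pos[iu[0]] - pos[iu[1]])
    vals = r2[iu]
    ok = ~np.isnan(vals)
    dists, vals = dists[ok], vals[ok]
    if dists.size:
        bins = (dists // decay_bin).astype(int)
        for b in np.unique(bins):
            sel = bins == b
            dec_rows.append((int(b) * decay_bin, int(sel.sum()),
                             float(vals[sel].mean())))
    decay = pd.DataFrame(dec_rows, columns=["distance", "n_pairs", "mean_r2"])
    return pairs, decay


# ---------------------------------------------------------------------------
# k-mer sex markers
# ---------------------------------------------------------------------------

def _canonical_kmers(read: str, k: int):
    for i in range(len(read) - k + 1):
        kmer = read[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        yield kmer if kmer <= rc else rc


def kmer_sex_markers(reads: dict, sex_map: dict, k: int = 31,
                     min_presence: int = 11, max_other_presence: int = 0,
                     target_sex: str = "M"):
    """Sex-specific k-mers from raw reads (reference-free).

    A marker is a canonical k-mer present (>= 1 occurrence) in at least
    ``min_presence`` individuals of ``target_sex`` and in at most
    ``max_other_presence`` of the other sex. Returns (marker set,
    carrier reads dict: sample -> reads containing >= 1 marker).
    """
    if k % 2 == 0:
        raise ConfigError(f"k must be odd, got {k}")
    for sample, rd in reads.items():
        if not rd:
            raise ValueError(f"{sample}: empty read set")
        if any(len(r) < k for r in rd):
            raise ConfigError(f"{sample}: k={k} exceeds a read length")
    per_sample = {s: set() for s in reads}
    for sample, rd in reads.items():
        ks = per_sample[sample]
        for r in rd:
            ks.update(_canonical_kmers(r.upper(), k))
    target = [s for s in sorted(reads) if sex_map[s] == target_sex]
    other = [s for s in sorted(reads) if sex_map[s] != target_sex]

    counts = {}
    for s in target:
        for km in per_sample[s]:
            counts[km] = counts.get(km, 0) + 1
    candidates = {km for km, c in counts.items() if c >= min_presence}
    other_counts = {km: 0 for km in candidates}
    for s in other:
        for km in candidates & per_sample[s]:
            other_counts[km] += 1
    candidates = {km for km in candidates
                  if other_counts[km] <= max_other_presence}

    carriers = {}
    for sample, rd in reads.items():
        hit_reads = []
        for r in rd:
            if any(km in candidates for km in _canonical_kmers(r.upper(), k)):
                hit_reads.append(r)
        if hit_reads:
            carriers[sample] = hit_reads
    log.info("kmer_sex_markers: markers=%d carrier_samples=%d",
             len(candidates), len(carriers))
    return candidates, carriers


# ---------------------------------------------------------------------------
# haplotig phase assignment
# ---------------------------------------------------------------------------

def assign_haplotigs(observations: pd.DataFrame,
                     min_confidence: float = 0.9977) -> pd.DataFrame:
    """Assign contigs to the W or Z haplotype from informative-site alleles.

    ``observations`` columns: contig, site, allele_haplotype ('W'/'Z').
    Confidence is the fraction of sites matching the contig's majority
    haplotype; contigs below ``min_confidence`` (or tied) stay unassigned.
    """
    rows = []
    for contig, sub in observations.groupby("contig", sort=True):
        n = len(sub)
        if n == 0:
            rows.append((contig, "unassigned", np.nan, 0))
            continue
        n_w = int((sub["allele_haplotype"] == "W").sum())
        n_z = n - n_w
        if n_w == n_z:
            rows.append((contig, "unassigned", 0.5, n))
            continue
        label = "W" if n_w > n_z else "Z"
        conf = max(n_w, n_z) / n
        if conf < min_confidence:
            label = "unassigned"
        rows.append((contig, label, conf, n))
    return pd.DataFrame(rows, columns=["contig", "label", "confidence", "n_sites"])
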