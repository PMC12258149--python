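"""Evolutionary strata detection, gametolog divergence and dating.

A stratum boundary is a changepoint in female SNP density along the Z; W-Z
gametolog pairs are matched by reciprocal best hit (RBH) protein alignment;
per-pair Ka/Ks uses Nei-Gojobori (1986) pathway counting with the
Jukes-Cantor multiple-hit correction; strata are compared with Mann-Whitney
U tests; synonymous divergence is converted to ages and degeneration rates
with the pairwise-divergence-per-year convention (rate = interspecies Ks /
split time, with no factor of two, i.e. Z and W assumed to diverge at the
same rate as the two species).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from ._codon import CODON_TABLE, STOP_CODONS
from .config import ConfigError

log = logging.getLogger("zwscan")


# ---------------------------------------------------------------------------
# changepoint detection (mean + variance, Gaussian cost)
# ---------------------------------------------------------------------------

@dataclass
class ChangepointResult:
    index: int                  # first index of the right segment
    accepted: bool
    improvement: float          # cost(no split) - cost(best split)
    left_mean: float
    left_var: float
    right_mean: float
    right_var: float
    flagged_constant: bool = False


_VAR_FLOOR = 1e-12


def _gauss_cost(n, sumx, sumx2) -> float:
    """n * log(MLE variance) for a segment, from its sufficient statistics."""
    var = sumx2 / n - (sumx / n) ** 2
    return n * math.log(max(var, _VAR_FLOOR))


def detect_stratum_boundary(values, mode: str = "force_one",
                            penalty: float | None = None) -> ChangepointResult:
    """Single changepoint in mean and variance of a window series.

    The cost of a segment is n*log(sigma^2_MLE); ``force_one`` returns the
    split minimising total cost (ties broken toward the smaller position),
    ``penalized`` additionally requires the cost drop to exceed ``penalty``
    (default 3*log(n), three extra parameters). Each segment keeps >= 2
    windows. A constant series is returned flagged, with zero improvement.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ConfigError(f"need >= 4 windows for a changepoint, got {n}")
    if mode not in ("force_one", "penalized"):
        raise ConfigError(f"mode must be 'force_one' or 'penalized', got {mode!r}")
    if penalty is None:
        penalty = 3.0 * math.log(n)

    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    full_cost = _gauss_cost(n, csum[n], csum2[n])

    best_k, best_cost = None, np.inf
    for k in range(2, n - 1):  # left = x[:k], right = x[k:]
        cost = (_gauss_cost(k, csum[k], csum2[k])
                + _gauss_cost(n - k, csum[n] - csum[k], csum2[n] - csum2[k]))
        if cost < best_cost - 1e-12:  # strict improvement: ties go left
            best_cost, best_k = cost, k

    improvement = full_cost - best_cost
    k = best_k
    left, right = x[:k], x[k:]
    constant = bool(np.ptp(x) == 0)
    accepted = True
    if mode == "penalized" and improvement <= penalty:
        accepted = False
    if constant:
        accepted = False
    return ChangepointResult(
        index=k, accepted=accepted, improvement=float(improvement),
        left_mean=float(left.mean()), left_var=float(left.var()),
        right_mean=float(right.mean()), right_var=float(right.var()),
        flagged_constant=constant)


@dataclass
class StratumPartition:
    """PAR / Stratum 2 / Stratum 1 intervals on the Z (1-based inclusive)."""

    chrom: str
    par: tuple
    stratum2: tuple
    stratum1: tuple
    boundary_support: float = float("nan")

    def __post_init__(self):
        seq = [self.par, self.stratum2, self.stratum1]
        for (s1, e1), (s2, e2) in zip(seq, seq[1:]):
            if not (s1 <= e1 and s2 == e1 + 1 and s2 <= e2):
                raise ConfigError(
                    "strata intervals must be contiguous, ordered PAR < S2 < S1")

    def region_of(self, pos: int) -> str:
        if self.par[0] <= pos <= self.par[1]:
            return "PAR"
        if self.stratum2[0] <= pos <= self.stratum2[1]:
            return "S2"
        if self.stratum1[0] <= pos <= self.stratum1[1]:
            return "S1"
        raise KeyError(f"position {pos} outside the partition")

    def to_json(self) -> dict:
        return {"chrom": self.chrom, "par": list(self.par),
                "stratum2": list(self.stratum2), "stratum1": list(self.stratum1),
                "boundary_support": self.boundary_support}

    @classmethod
    def from_json(cls, d) -> "StratumPartition":
        return cls(d["chrom"], tuple(d["par"]), tuple(d["stratum2"]),
                   tuple(d["stratum1"]), d.get("boundary_support", float("nan")))


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

def _make_protein_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def rbh_pairs(proteins_a: dict, proteins_b: dict,
              min_query_coverage: float = 0.6,
              min_score_ratio: float = 0.2):
    """Reciprocal best hits between two protein sets.

    Similarity is the global alignment score (BLOSUM62, gap open -11 /
    extend -1). A pair is kept iff each sequence is the other's unique best
    hit (score ties are dropped as ambiguous), the aligned fraction of each
    sequence is >= ``min_query_coverage``, and the score is at least
    ``min_score_ratio`` of the smaller self-alignment score (unrelated
    proteins score near zero on this normalised scale, genuine homologs near
    one); the reciprocal-unique rule also removes any many-to-one
    relationships. Returns a DataFrame with columns id_a, id_b, score,
    coverage_a, coverage_b.
    """
    if not proteins_a or not proteins_b:
        raise ConfigError("rbh_pairs: both protein sets must be nonempty")
    aligner = _make_protein_aligner()
    ids_a, ids_b = sorted(proteins_a), sorted(proteins_b)
    self_a = {i: aligner.align(proteins_a[i].rstrip("*"),
                               proteins_a[i].rstrip("*")).score for i in ids_a}
    self_b = {i: aligner.align(proteins_b[i].rstrip("*"),
                               proteins_b[i].rstrip("*")).score for i in ids_b}
    score = np.full((len(ids_a), len(ids_b)), -np.inf)
    cov_a = np.zeros_like(score)
    cov_b = np.zeros_like(score)
    for i, ia in enumerate(ids_a):
        sa = proteins_a[ia].rstrip("*")
        for j, ib in enumerate(ids_b):
            sb = proteins_b[ib].rstrip("*")
            aln = aligner.align(sa, sb)[0]
            score[i, j] = aln.score
            aligned_cols = sum(int(qe - qs) for (qs, qe) in aln.aligned[0])
            cov_a[i, j] = aligned_cols / len(sa)
            cov_b[i, j] = aligned_cols / len(sb)

    def unique_best(row):
        order = np.argsort(row)[::-1]
        if len(row) > 1 and row[order[0]] == row[order[1]]:
            return None
        return int(order[0])

    best_a = [unique_best(score[i]) for i in range(len(ids_a))]
    best_b = [unique_best(score[:, j]) for j in range(len(ids_b))]
    rows = []
    for i, j in enumerate(best_a):
        if j is None or best_b[j] != i:
            continue
        if cov_a[i, j] < min_query_coverage or cov_b[i, j] < min_query_coverage:
            continue
        floor = min_score_ratio * min(self_a[ids_a[i]], self_b[ids_b[j]])
        if score[i, j] < floor:
            continue
        rows.append((ids_a[i], ids_b[j], float(score[i, j]),
                     float(cov_a[i, j]), float(cov_b[i, j])))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "score",
                                       "coverage_a", "coverage_b"])


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    ka: float
    ks: float
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    n_codons: int
    saturated: bool = False


from functools import lru_cache


@lru_cache(maxsize=None)
def _codon_syn_fraction(codon: str) -> float:
    """Fractional synonymous sites of one codon (stop neighbours excluded
    from neither count: NG86 counts all 3 mutational opportunities/site)."""
    s = 0.0
    aa = CODON_TABLE[codon]
    for pos in range(3):
        syn = 0
        for nuc in "ACGT":
            if nuc == codon[pos]:
                continue
            new = codon[:pos] + nuc + codon[pos + 1 :]
            if CODON_TABLE[new] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str):
    """Mean (syn, nonsyn) differences over all shortest substitution pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all pathways are used (equal weights either way).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    blocked_results = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked_results if blocked else results).append((sd, nd))
    use = results if results else blocked_results
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def _jc_correct(p: float):
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3); None when saturated."""
    if p < 0:
        return 0.0
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(seq1: str, seq2: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for an aligned codon pair.

    Sites are counted fractionally per codon and averaged over the two
    sequences; multiple-substitution codons average synonymous/nonsynonymous
    differences over shortest pathways with equal weights; the proportions
    are corrected for multiple hits with the Jukes-Cantor formula. Codons
    with a gap in either sequence are excluded pairwise; codons that are
    stops in both sequences are skipped; a proportion >= 3/4 is flagged
    saturated (Ka/Ks reported as NaN).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal lengths")
    if len(seq1) % 3:
        raise ValueError("aligned length must be divisible by 3")
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if "-" in c1 or "-" in c2 or len(set(c1 + c2) - set("ACGT")) > 0:
            continue
        if c1 in STOP_CODONS and c2 in STOP_CODONS:
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            # one-sided stop (defective sequence): skip, as site counting is
            # undefined for stops in the NG86 scheme
            continue
        n_codons += 1
        s1, s2 = _codon_syn_fraction(c1), _codon_syn_fraction(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += 3.0 - (s1 + s2) / 2.0
        dsd, dnd = _pathway_counts(c1, c2)
        sd += dsd
        nd += dnd
    if n_codons == 0:
        return KaKsResult(float("nan"), float("nan"), 0.0, 0.0, 0.0, 0.0, 0, True)
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    saturated = ks is None or ka is None
    return KaKsResult(
        ka=float("nan") if ka is None else ka,
        ks=float("nan") if ks is None else ks,
        s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd,
        n_codons=n_codons, saturated=saturated)


# ---------------------------------------------------------------------------
# strata comparison
# ---------------------------------------------------------------------------

def compare_strata(records: pd.DataFrame, value_col: str = "ks",
                   exclude_saturated: bool = True) -> dict:
    """Per-region means and pairwise two-sided Mann-Whitney U tests.

    ``records`` needs columns region and the value column (plus optionally
    ``saturated``). Exact U for small tie-free samples, normal approximation
    with midrank tie correction otherwise (scipy's automatic policy). The
    PAR mean is labelled diversity-dominated: where recombination persists a
    haplotype comparison measures diversity, not divergence.
    """
    df = records.copy()
    if exclude_saturated and "saturated" in df.columns:
        df = df[~df["saturated"].astype(bool)]
    df = df[np.isfinite(df[value_col])]
    regions = [r for r in ("PAR", "S2", "S1") if r in set(df["region"])]
    regions += [r for r in df["region"].unique() if r not in regions]
    means, counts = {}, {}
    for r in regions:
        vals = df.loc[df["region"] == r, value_col]
        if len(vals) < 2:
            log.warning("compare_strata: region %s has <2 records, excluded", r)
            continue
        means[r] = float(vals.mean())
        counts[r] = int(len(vals))
    tests = {}
    usable = [r for r in regions if r in means]
    for i, r1 in enumerate(usable):
        for r2 in usable[i + 1 :]:
            v1 = df.loc[df["region"] == r1, value_col].to_numpy()
            v2 = df.loc[df["region"] == r2, value_col].to_numpy()
            res = stats.mannwhitneyu(v1, v2, alternative="two-sided",
                                     method="auto")
            tests[f"{r1}_vs_{r2}"] = {"U": float(res.statistic),
                                      "p": float(res.pvalue)}
    notes = {}
    if "PAR" in means:
        notes["PAR"] = "diversity-dominated (recombining region)"
    return {"value": value_col, "means": means, "n": counts,
            "tests": tests, "notes": notes}


# ---------------------------------------------------------------------------
# dating and degeneration-rate arithmetic
# ---------------------------------------------------------------------------

def divergence_rate_and_ages(ks_interspecies: float, t_split_years: float,
                             ks_by_stratum: dict):
    """Substitution rate per site per year and stratum ages.

    rate = interspecies Ks / split time (pairwise divergence per year, no
    factor of two: Z-W pairs are assumed to accumulate divergence at the same
    pairwise rate as the species pair); age = stratum Ks / rate.
    """
    if ks_interspecies <= 0:
        raise ValueError(f"ks_interspecies must be > 0, got {ks_interspecies}")
    if t_split_years <= 0:
        raise ValueError(f"t_split_years must be > 0, got {t_split_years}")
    rate = ks_interspecies / t_split_years
    ages = {}
    for name, ks in ks_by_stratum.items():
        if ks < 0:
            raise ValueError(f"ks_by_stratum[{name}] must be >= 0, got {ks}")
        ages[name] = ks / rate
    return rate, ages


def degeneration_rates(pct_lof: float, age_my: float,
                       generation_time_years: float):
    """(% of genes degenerated per MY, % per million generations).

    per_mgen = per_my * generation_time_years (a million generations spans
    generation_time x 1e6 years).
    """
    if age_my <= 0:
        raise ValueError(f"age_my must be > 0, got {age_my}")
    per_my = pct_lof / age_my
    per_mgen = per_my * generation_time_years
    return per_my, per_mgen


@dataclass
class StrataReport:
    partition: StratumPartition
    comparison: dict
    rate_per_site_year: float
    ages_years: dict
    degeneration: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def build_strata_report(partition, divergence_records, ks_interspecies,
                        t_split_years, pct_lof_by_stratum=None,
                        generation_time_years: float = 1.5) -> StrataReport:
    """Full strata report: means, tests, ages, degeneration rates."""
    comp_ks = compare_strata(divergence_records, "ks")
    rate, ages = divergence_rate_and_ages(
        ks_interspecies, t_split_years,
        {r: m for r, m in comp_ks["means"].items() if r != "PAR"})
    degen = {}
    flags = []
    if pct_lof_by_stratum:
        for r, pct in pct_lof_by_stratum.items():
            if r in ages and ages[r] > 0:
                per_my, per_mgen = degeneration_rates(
                    pct, ages[r] / 1e6, generation_time_years)
                degen[r] = {"pct_lof": pct, "per_my": per_my,
                            "per_mgen": per_mgen}
        flags.append(
            "per-Mgen rates follow the stated arithmetic (%/MY x years per "
            "generation); published per-stratum per-Mgen figures with the "
            "reverse assignment do not match that arithmetic")
    return StrataReport(partition, comp_ks, rate, ages, degen, flags)
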