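"""Sex-linked scan: variant criterion, WC84 FST, F:M ratios, LD, k-mers,
haplotig phasing."""

import numpy as np
import pandas as pd
import pytest

from zwscan._codon import revcomp
from zwscan.config import ConfigError
from zwscan.io import MISSING, GenotypeMatrix
from zwscan.sexscan import (assign_haplotigs, find_sex_linked_variants,
                            fm_log2_windows, kmer_sex_markers, ld_profile,
                            per_sample_het_density, variant_fst, wc_fst_components,
                            windowed_fst)
from zwscan.simulate import (simulate_haplotig_observations,
                             simulate_marker_reads)


def _gm(dosage_rows, n_f=12, n_m=12, chrom="chr1"):
    d = np.array(dosage_rows, dtype=np.int8)
    variants = pd.DataFrame({"chrom": [chrom] * len(d),
                             "pos": np.arange(1, len(d) + 1) * 100,
                             "ref": ["A"] * len(d), "alt": ["G"] * len(d)})
    samples = [f"F{i}" for i in range(n_f)] + [f"M{i}" for i in range(n_m)]
    sex = np.array(["F"] * n_f + ["M"] * n_m)
    return GenotypeMatrix(variants, samples, sex, d)


# ---------------------------------------------------------------------------
# sex-linked variants
# ---------------------------------------------------------------------------

def test_truth_recovery_on_error_free_cohort(clean_dataset):
    """Every planted W-specific variant is found; no autosomal site qualifies."""
    gm = clean_dataset.genotypes
    n_f = int((gm.sex == "F").sum())
    out, call = find_sex_linked_variants(gm, min_het=n_f, hom_policy="all")
    found = set(zip(out["chrom"], out["pos"]))
    truth = {(v["chrom"], v["pos"]) for v in clean_dataset.truth["variants"]
             if v["sex_linked"]}
    assert truth <= found
    assert not any(c == "chrA" for c, _p in found)
    assert call.system == "ZW"


def test_all_homozygous_matrix_yields_nothing():
    gm = _gm([[0] * 24, [2] * 24])
    out, call = find_sex_linked_variants(gm, min_het=9)
    assert len(out) == 0 and call.system == "ambiguous"


def test_one_sex_cohort_is_an_error():
    d = np.zeros((1, 4), dtype=np.int8)
    variants = pd.DataFrame({"chrom": ["c"], "pos": [1], "ref": ["A"], "alt": ["G"]})
    gm = GenotypeMatrix(variants, ["a", "b", "c", "d"],
                        np.array(["F", "F", "F", "F"]), d)
    with pytest.raises(ConfigError, match="both sexes"):
        find_sex_linked_variants(gm, min_het=2)
    with pytest.raises(ConfigError, match="min_het"):
        find_sex_linked_variants(_gm([[0] * 24]), min_het=0)


def test_xy_like_detection_is_symmetric():
    rows = [[0] * 12 + [1] * 12] * 5  # males het, females hom
    out, call = find_sex_linked_variants(_gm(rows), min_het=12, hom_policy="all")
    assert (out["class"] == "XY-like").all()
    assert call.system == "XY"


def test_sex_permutation_kills_signal(clean_dataset, rng):
    """After random sex relabelling the qualifying count collapses to near
    the binomial expectation (tested at 3 sigma around a small bound)."""
    gm = clean_dataset.genotypes
    n_f = int((gm.sex == "F").sum())
    perm = rng.permutation(len(gm.sex))
    gm_perm = GenotypeMatrix(gm.variants, gm.samples, gm.sex[perm],
                             gm.dosage)
    out, _call = find_sex_linked_variants(gm_perm, min_het=n_f, hom_policy="all")
    # requiring all 12 of a random half to be het while the other random half
    # is homozygous is essentially impossible: expectation ~ sum over variants
    # of hypergeometric mass, < 1 for this cohort
    assert len(out) <= 5


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def test_fixed_difference_gives_fst_one():
    row = np.array([0] * 12 + [2] * 12, dtype=np.int8)
    assert variant_fst(row, np.arange(12), np.arange(12, 24)) == pytest.approx(1.0)


def test_identical_genotype_vectors_give_nonpositive_fst():
    row = np.array(([0, 1, 2] * 4) * 2, dtype=np.int8)
    est = variant_fst(row, np.arange(12), np.arange(12, 24))
    assert est <= 0


def test_wc84_three_variant_window_matches_hand_computation():
    """Hand-derived WC84 components for a 3-variant toy window.

    For each variant with per-sex counts n=4: p and het fractions below give
    (a, b, c) via the published formulas; the window estimate is
    sum(a)/sum(a+b+c). The expected value was computed by hand with r=2,
    nbar=nc=4.
    """
    f_idx, m_idx = np.arange(4), np.arange(4, 8)
    rows = np.array([
        [1, 1, 1, 1, 0, 0, 0, 0],   # all F het, all M hom-ref
        [2, 2, 2, 2, 0, 0, 0, 0],   # fixed difference
        [0, 1, 1, 2, 1, 0, 1, 1],   # mixed
    ], dtype=np.int8)

    def hand(nf, pf, hf, nm, pm, hm):
        r = 2.0
        nbar = (nf + nm) / r
        nc = (r * nbar - (nf**2 + nm**2) / (r * nbar)) / (r - 1)
        pbar = (nf * pf + nm * pm) / (r * nbar)
        s2 = (nf * (pf - pbar) ** 2 + nm * (pm - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (nf * hf + nm * hm) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        return a, b, c

    params = [
        (4, 0.5, 1.0, 4, 0.0, 0.0),
        (4, 1.0, 0.0, 4, 0.0, 0.0),
        (4, 0.5, 0.5, 4, 0.375, 0.75),
    ]
    num = den = 0.0
    for row, pr in zip(rows, params):
        a, b, c = wc_fst_components(row, f_idx, m_idx)
        ha, hb, hc = hand(*pr)
        assert a == pytest.approx(ha)
        assert b == pytest.approx(hb)
        assert c == pytest.approx(hc)
        num += ha
        den += ha + hb + hc
    gm = _gm(rows, n_f=4, n_m=4)
    win = windowed_fst(gm, window=1000)
    assert win.loc[0, "fst"] == pytest.approx(num / den)
    assert win.loc[0, "n_variants"] == 3


def test_windowed_fst_validates_inputs(clean_dataset):
    with pytest.raises(ConfigError, match="window"):
        windowed_fst(clean_dataset.genotypes, window=0)


def test_slr_fst_far_exceeds_autosomal(clean_dataset):
    fst = windowed_fst(clean_dataset.genotypes, 100_000)
    z = fst[fst["chrom"] == "chrZ"]
    slr = z[z["start"] >= 700_000]["fst"].dropna()
    auto = fst[fst["chrom"] == "chrA"]["fst"].dropna()
    assert slr.mean() > 0.3
    assert abs(auto.mean()) < 0.05


# ---------------------------------------------------------------------------
# F:M log2 windows
# ---------------------------------------------------------------------------

def _fm_table(f_vals, m_vals):
    rows = []
    for i, v in enumerate(f_vals):
        rows.append(("c", 0, 100, f"F{i}", v))
    for i, v in enumerate(m_vals):
        rows.append(("c", 0, 100, f"M{i}", v))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "value"])
    sex = {f"F{i}": "F" for i in range(len(f_vals))}
    sex.update({f"M{i}": "M" for i in range(len(m_vals))})
    return df, sex


def test_fm_log2_basic_values():
    df, sex = _fm_table([4.0, 4.0], [4.0, 4.0])
    assert fm_log2_windows(df, sex)["log2_fm"].iloc[0] == pytest.approx(0.0)
    df, sex = _fm_table([2.0, 2.0], [4.0, 4.0])
    assert fm_log2_windows(df, sex)["log2_fm"].iloc[0] == pytest.approx(-1.0)
    df, sex = _fm_table([0.0, 0.0], [4.0, 4.0])
    assert np.isnan(fm_log2_windows(df, sex)["log2_fm"].iloc[0])
    with pytest.raises(ValueError, match="negative"):
        fm_log2_windows(*_fm_table([-1.0], [1.0]))


def test_w_deletion_window_halves_female_coverage(clean_dataset):
    cov = clean_dataset.coverage.rename(columns={
        "window_start": "start", "window_end": "end", "mean_depth": "value"})
    fm = fm_log2_windows(cov, clean_dataset.sex_map)
    (ds_start, ds_end), = clean_dataset.truth["large_deletions"]
    hit = fm[(fm["chrom"] == "chrZ") & (fm["start"] >= ds_start)
             & (fm["end"] <= ds_end)]
    assert len(hit) >= 1
    assert np.allclose(hit["log2_fm"], -1.0, atol=0.25)
    auto = fm[fm["chrom"] == "chrA"]["log2_fm"]
    assert abs(auto.mean()) < 0.1


def test_slr_snp_density_is_female_biased(clean_dataset):
    dens = per_sample_het_density(clean_dataset.genotypes, 100_000)
    fm = fm_log2_windows(dens, clean_dataset.sex_map)
    slr = fm[(fm["chrom"] == "chrZ") & (fm["start"] >= 700_000)]["log2_fm"].dropna()
    auto = fm[fm["chrom"] == "chrA"]["log2_fm"].dropna()
    assert (slr > 0.5).mean() > 0.9
    assert abs(auto.mean()) < 0.2


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def test_duplicated_variant_column_gives_r2_one(rng):
    base = rng.binomial(2, 0.5, 24).astype(np.int8)
    while base.std() == 0:
        base = rng.binomial(2, 0.5, 24).astype(np.int8)
    gm = _gm([base, base], n_f=12, n_m=12)
    gm.variants.loc[1, "pos"] = 50_000  # defeat thinning
    pairs, _decay = ld_profile(gm, "chr1", maf_min=0.0, thin=10_000,
                               window=100_000)
    same = pairs[(pairs.window_i == 0) & (pairs.window_j == 0)]
    # only one comparison in the window: second-max undefined, so check decay
    _pairs2, decay = ld_profile(gm, "chr1", maf_min=0.0, thin=10_000)
    assert decay["mean_r2"].iloc[0] == pytest.approx(1.0)


def test_window_with_too_few_variants_is_missing(rng):
    base = rng.binomial(2, 0.5, 24).astype(np.int8)
    gm = _gm([base], n_f=12, n_m=12)
    pairs, _ = ld_profile(gm, "chr1", maf_min=0.0)
    assert np.isnan(pairs["second_max_r2"]).all()


def test_independent_variants_mean_r2_near_1_over_n(rng):
    n_ind = 100
    rows = rng.binomial(2, 0.5, size=(60, n_ind)).astype(np.int8)
    variants = pd.DataFrame({"chrom": "c", "pos": np.arange(60) * 20_000 + 1,
                             "ref": "A", "alt": "G"})
    gm = GenotypeMatrix(variants, [f"F{i}" for i in range(50)] +
                        [f"M{i}" for i in range(50)],
                        np.array(["F"] * 50 + ["M"] * 50), rows)
    _pairs, decay = ld_profile(gm, "c", maf_min=0.1, thin=10_000)
    mean_r2 = np.average(decay["mean_r2"], weights=decay["n_pairs"])
    assert abs(mean_r2 - 1.0 / n_ind) < 3.0 / n_ind


# ---------------------------------------------------------------------------
# k-mer markers
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def marker_scenario():
    return simulate_marker_reads(n_per_sex=12, genome_len=20_000,
                                 insert_len=2_000, n_carriers=11, depth=4,
                                 seed=5)


def test_kmer_markers_fall_only_inside_insert(marker_scenario):
    reads, sexes, truth = marker_scenario
    markers, carriers = kmer_sex_markers(reads, sexes, k=31)
    assert len(markers) > 0
    region = truth["insert_with_junctions"]  # insert + junction-spanning kmers
    for m in markers:
        assert m in region or revcomp(m) in region
    # every carrier read contains a marker (by construction of the output)
    for s, rds in carriers.items():
        assert sexes[s] == "M"


def test_kmer_scan_swapped_sexes_is_empty(marker_scenario):
    reads, sexes, _truth = marker_scenario
    flipped = {s: ("F" if x == "M" else "M") for s, x in sexes.items()}
    markers, _ = kmer_sex_markers(reads, flipped, k=31)
    assert markers == set()


def test_kmer_scan_identical_reads_is_empty():
    reads = {f"S{i}": ["ACGTACGTACGTACGTACGTACGTACGTACGTACG"] for i in range(8)}
    sexes = {f"S{i}": ("M" if i < 4 else "F") for i in range(8)}
    markers, _ = kmer_sex_markers(reads, sexes, k=31, min_presence=4)
    assert markers == set()


def test_kmer_scan_invariant_to_read_order_and_strand(marker_scenario):
    reads, sexes, _truth = marker_scenario
    markers1, _ = kmer_sex_markers(reads, sexes, k=31)
    flipped = {s: [revcomp(r) for r in reversed(rd)] for s, rd in reads.items()}
    markers2, _ = kmer_sex_markers(flipped, sexes, k=31)
    assert markers1 == markers2


def test_kmer_k_larger_than_read_errors():
    reads = {"a": ["ACGT"], "b": ["ACGT"]}
    with pytest.raises(ConfigError):
        kmer_sex_markers(reads, {"a": "M", "b": "F"}, k=31, min_presence=1)


# ---------------------------------------------------------------------------
# haplotig assignment
# ---------------------------------------------------------------------------

def test_pure_w_contig_full_confidence():
    obs = pd.DataFrame({"contig": ["c1"] * 100, "site": range(100),
                        "allele_haplotype": ["W"] * 100})
    out = assign_haplotigs(obs)
    assert out.loc[0, "label"] == "W"
    assert out.loc[0, "confidence"] == 1.0


def test_balanced_contig_unassigned():
    obs = pd.DataFrame({"contig": ["c1"] * 10, "site": range(10),
                        "allele_haplotype": ["W"] * 5 + ["Z"] * 5})
    out = assign_haplotigs(obs)
    assert out.loc[0, "label"] == "unassigned"


def test_one_percent_switch_errors_fail_threshold():
    obs, truth = simulate_haplotig_observations(
        n_contigs=30, sites_per_contig=100, switch_rate=0.01, seed=2)
    out = assign_haplotigs(obs, min_confidence=0.9977)
    merged = out.assign(truth=out["contig"].map(truth))
    chimeric = merged[merged["confidence"] < 0.9977]
    assert (chimeric["label"] == "unassigned").all()
    clean = merged[merged["confidence"] >= 0.9977]
    assert (clean["label"] == clean["truth"]).all()


def test_error_free_contigs_recover_truth():
    obs, truth = simulate_haplotig_observations(
        n_contigs=25, sites_per_contig=60, switch_rate=0.0, seed=3)
    out = assign_haplotigs(obs)
    assert all(out["label"] == out["contig"].map(truth))
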