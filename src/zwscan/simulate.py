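"""Synthetic ZW-system generator with complete truth tables.

Emulates a young female-heterogametic sex chromosome: a Z chromosome
partitioned into PAR / Stratum 2 / Stratum 1, a W haplotype derived from the
Z by region-specific divergence, planted loss-of-function events on W gene
copies, a sexed diploid cohort (ZW females, ZZ males), per-window coverage,
allele-tagged expression counts, and gametolog gene trees. Every emitted
variant, gene, window and tree has exactly one truth record, so each
downstream stage can be validated against a known answer.

All randomness flows from a single ``numpy.random.Generator`` seeded from
``SimConfig.seed``; identical seed and config give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as zio
from ._codon import CODON_TABLE, STOP_CODONS, codon_changes, random_cds, translate
from .config import LOF_CLASSES, SimConfig, ConfigError

_NUCS = "ACGT"
_NUC_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class LofPlantingError(ValueError):
    """Requested LoF class incompatible with the gene structure."""


from functools import lru_cache


@lru_cache(maxsize=None)
def _codon_candidates(codon: str, want_syn: bool) -> tuple:
    """Single-base changes of one kind available from a codon (stop-avoiding)."""
    out = []
    for pos, nuc, new, syn in codon_changes(codon):
        if new in STOP_CODONS:
            continue
        if syn == want_syn:
            out.append((pos, nuc, new))
    return tuple(out)


# ---------------------------------------------------------------------------
# CDS evolution
# ---------------------------------------------------------------------------

def _ng86_site_fractions(codons) -> tuple:
    """Fractional synonymous / nonsynonymous site counts (NG86 convention)."""
    s = 0.0
    for codon in codons:
        for _pos, _nuc, _new, syn in codon_changes(codon):
            if syn:
                s += 1.0 / 3.0
    n = 3.0 * len(codons) - s
    return s, n


def evolve_cds(ancestral_cds: str, ds_target: float, omega: float, rng,
               _return_changes: bool = False):
    """Derive a diverged coding sequence from an ancestor.

    Substitution events are drawn as Poisson(S * dS) synonymous and
    Poisson(N * dS * omega) nonsynonymous single-base changes, applied
    sequentially and uniformly over the currently available changes of the
    matching kind (Jukes-Cantor-like: every admissible target nucleotide
    equally likely, stop codons never created). Multiple hits at a site are
    possible and are exactly what the downstream NG86+JC estimator corrects
    for. A terminal stop codon, if present, is frozen.

    Returns ``(derived_cds, n_syn_events, n_nonsyn_events)``.
    """
    if ds_target < 0:
        raise ValueError(f"ds_target must be >= 0, got {ds_target}")
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    if len(ancestral_cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    codons = [ancestral_cds[i : i + 3] for i in range(0, len(ancestral_cds), 3)]
    has_stop_tail = codons and codons[-1] in STOP_CODONS
    body = codons[:-1] if has_stop_tail else list(codons)
    if any(c in STOP_CODONS for c in body):
        raise ValueError("ancestor contains an internal stop codon")

    s_sites, n_sites = _ng86_site_fractions(body)
    n_syn = int(rng.poisson(s_sites * ds_target))
    n_nonsyn = int(rng.poisson(n_sites * ds_target * omega))

    # per-codon candidate lists; the start codon is frozen (like the stop):
    # start-codon loss is a planted LoF event, never background divergence
    start_frozen = bool(body) and body[0] == "ATG"

    def candidates(ci, codon, want_syn):
        if start_frozen and ci == 0:
            return ()
        return _codon_candidates(codon, want_syn)

    changed = []  # CDS positions touched (0-based)
    order = ["s"] * n_syn + ["n"] * n_nonsyn
    rng.shuffle(order)
    for kind in order:
        want_syn = kind == "s"
        per_codon = [candidates(i, c, want_syn) for i, c in enumerate(body)]
        counts = np.array([len(c) for c in per_codon], dtype=float)
        total = counts.sum()
        if total == 0:
            break
        ci = int(rng.choice(len(body), p=counts / total))
        pos, nuc, new = per_codon[ci][int(rng.integers(0, len(per_codon[ci])))]
        body[ci] = new
        changed.append(3 * ci + pos)

    derived = "".join(body) + (codons[-1] if has_stop_tail else "")
    if _return_changes:
        return derived, n_syn, n_nonsyn, sorted(set(changed))
    return derived, n_syn, n_nonsyn


# ---------------------------------------------------------------------------
# local gene representation & LoF planting
# ---------------------------------------------------------------------------

@dataclass
class LocalGene:
    """A gene as a self-contained genomic segment.

    ``seq`` is the genomic sequence of the gene span; ``exons`` are 0-based
    half-open intervals into ``seq``, sorted 5'->3'.
    """

    gene_id: str
    seq: str
    exons: list

    @property
    def cds(self) -> str:
        return "".join(self.seq[s:e] for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list:
        return [(e1, s2) for (_s1, e1), (s2, _e2) in zip(self.exons, self.exons[1:])]


def plant_lof(gene: LocalGene, lof_class: str, rng):
    """Apply one loss-of-function event of the requested class to a W gene copy.

    Returns ``(mutated LocalGene, truth record dict)``. The truth record
    carries the evidence (deleted span, lost exon index, stop position, indel
    offset/length, or mutated splice terminus).
    """
    if lof_class not in LOF_CLASSES:
        raise LofPlantingError(f"unknown LoF class {lof_class!r}")
    if lof_class in ("exon_loss", "splice") and len(gene.exons) < 2:
        raise LofPlantingError(f"{gene.gene_id}: class {lof_class} needs >= 2 exons")
    seq, exons = gene.seq, [list(e) for e in gene.exons]
    truth = {"class": lof_class}

    if lof_class == "sequence_loss":
        # delete a genomic chunk spanning >= 55% of CDS bases, starting inside
        # the first exon so most of the coding sequence disappears
        target = math.ceil(0.55 * gene.cds_length)
        s0, e0 = gene.exons[0]
        start = s0 + int(rng.integers(3, max(4, (e0 - s0) // 3)))
        removed, end = 0, start
        for es, ee in gene.exons:
            lo, hi = max(es, start), ee
            if hi > lo:
                take = min(hi - lo, target - removed)
                removed += take
                end = lo + take
                if removed >= target:
                    break
        new_seq = seq[:start] + seq[end:]
        new_exons = _shift_exons(gene.exons, start, end)
        truth.update(deleted_span=[start, end], cds_bases_removed=removed)
        return LocalGene(gene.gene_id, new_seq, new_exons), truth

    if lof_class == "exon_loss":
        # remove one complete internal (or smaller terminal) exon
        k = len(gene.exons)
        idx = int(rng.integers(1, k - 1)) if k > 2 else int(
            np.argmin([e - s for s, e in gene.exons]))
        es, ee = gene.exons[idx]
        new_seq = seq[:es] + seq[ee:]
        new_exons = _shift_exons([e for i, e in enumerate(gene.exons) if i != idx], es, ee)
        truth.update(lost_exon_index=idx, deleted_span=[es, ee])
        return LocalGene(gene.gene_id, new_seq, new_exons), truth

    if lof_class == "orf_disrupt":
        subtype = ("start_loss", "premature_stop", "frameshift")[int(rng.integers(0, 3))]
        if subtype == "start_loss":
            s0 = gene.exons[0][0]
            alt = _other_nuc(seq[s0], rng)
            new_seq = seq[:s0] + alt + seq[s0 + 1 :]
            truth.update(subtype=subtype, position=s0)
            return LocalGene(gene.gene_id, new_seq, list(gene.exons)), truth
        if subtype == "premature_stop":
            n_codons = gene.cds_length // 3
            ci = int(rng.integers(max(1, n_codons // 5), max(2, (4 * n_codons) // 5)))
            stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
            cds_pos = [p for s, e in gene.exons for p in range(s, e)]
            new = list(seq)
            for off in range(3):
                new[cds_pos[3 * ci + off]] = stop[off]
            truth.update(subtype=subtype, stop_codon_index=ci)
            return LocalGene(gene.gene_id, "".join(new), list(gene.exons)), truth
        # frameshift: small indel of length not divisible by 3, mid-exon
        length = (1, 2, 4)[int(rng.integers(0, 3))]
        s0, e0 = max(gene.exons, key=lambda x: x[1] - x[0])
        pos = int(rng.integers(s0 + 10, e0 - 10))
        if rng.random() < 0.5:  # deletion
            new_seq = seq[:pos] + seq[pos + length :]
            new_exons = _shift_exons(gene.exons, pos, pos + length)
            truth.update(subtype="frameshift", indel_offset=pos, indel_length=-length)
        else:  # insertion
            ins = "".join(_NUCS[int(i)] for i in rng.integers(0, 4, size=length))
            new_seq = seq[:pos] + ins + seq[pos:]
            new_exons = [
                [s + (length if s >= pos else 0), e + (length if e > pos else 0)]
                for s, e in gene.exons
            ]
            new_exons = [tuple(x) for x in new_exons]
            truth.update(subtype="frameshift", indel_offset=pos, indel_length=length)
        return LocalGene(gene.gene_id, new_seq, new_exons), truth

    # splice: break exactly one GT donor or AG acceptor dinucleotide
    introns = gene.introns()
    ii = int(rng.integers(0, len(introns)))
    donor = bool(rng.integers(0, 2))
    istart, iend = introns[ii]
    pos = istart + int(rng.integers(0, 2)) if donor else iend - 2 + int(rng.integers(0, 2))
    alt = _other_nuc(seq[pos], rng)
    new_seq = seq[:pos] + alt + seq[pos + 1 :]
    # ensure the terminus really is broken (e.g. GT -> GG, not GT -> G T)
    if donor:
        while new_seq[istart : istart + 2] == "GT":
            alt = _other_nuc(seq[pos], rng)
            new_seq = seq[:pos] + alt + seq[pos + 1 :]
    else:
        while new_seq[iend - 2 : iend] == "AG":
            alt = _other_nuc(seq[pos], rng)
            new_seq = seq[:pos] + alt + seq[pos + 1 :]
    truth.update(intron_index=ii, terminus="donor" if donor else "acceptor", position=pos)
    return LocalGene(gene.gene_id, new_seq, list(gene.exons)), truth


def _shift_exons(exons, del_start, del_end):
    """Exon intervals after deleting [del_start, del_end) from the sequence."""
    length = del_end - del_start
    out = []
    for s, e in exons:
        ns = s - length if s >= del_end else min(s, del_start)
        ne = e - length if e >= del_end else min(e, del_start)
        if ne > ns:
            out.append((ns, ne))
    return out


def _other_nuc(nuc, rng):
    options = [n for n in _NUCS if n != nuc]
    return options[int(rng.integers(0, 3))]


# ---------------------------------------------------------------------------
# neutral background divergence
# ---------------------------------------------------------------------------

def _jc_prob(ds: float) -> float:
    """Expected proportion of differing sites at JC divergence ``ds``."""
    return 0.75 * (1.0 - math.exp(-4.0 * ds / 3.0))


def _mutate_background(seq: str, p: float, rng, protect=()):
    """Substitute each position independently with probability ``p``.

    ``protect`` lists 0-based positions that must stay untouched (e.g. splice
    dinucleotides). Returns (new_seq, changed_positions).
    """
    n = len(seq)
    if n == 0 or p <= 0:
        return seq, []
    hits = np.flatnonzero(rng.random(n) < p)
    if protect:
        prot = set(protect)
        hits = np.array([h for h in hits if h not in prot], dtype=int)
    if hits.size == 0:
        return seq, []
    out = list(seq)
    for h in hits:
        out[h] = _other_nuc(out[h], rng)
    return "".join(out), hits.tolist()


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimConfig
    z_seq: str
    w_seq: str
    genes: list                      # io.GeneModel on Z coordinates
    z_cds: dict                      # gene_id -> spliced Z CDS
    genotypes: zio.GenotypeMatrix
    coverage: pd.DataFrame
    expression: pd.DataFrame
    trees: list                      # newick strings
    tree_classes: list
    marker_reads: dict               # sample -> list of reads (XY-like insert scenario)
    marker_sex: dict
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        """Write every component as plain-text files under ``outdir``."""
        import os

        os.makedirs(outdir, exist_ok=True)
        j = lambda name: os.path.join(outdir, name)
        self.config.to_yaml(j("config.yaml"))
        zio.write_vcf(self.genotypes, j("cohort.vcf"))
        zio.write_fasta({"chrZ": self.z_seq, "chrW": self.w_seq}, j("genome.fasta"))
        zio.write_fasta(self.z_cds, j("z_cds.fasta"))
        zio.write_gff(self.genes, j("genes.gff3"))
        zio.write_coverage(self.coverage, j("coverage.tsv"))
        zio.write_counts(self.expression, j("expression.tsv"))
        zio.write_newick_list(self.trees, j("gene_trees.nwk"))
        with open(j("reads.fasta"), "w") as fh:
            for sample in sorted(self.marker_reads):
                for i, read in enumerate(self.marker_reads[sample]):
                    fh.write(f">{sample}_r{i}\n{read}\n")
        zio.write_truth(self.truth, j("truth.json"))

    @property
    def sex_map(self) -> dict:
        return dict(zip(self.genotypes.samples, self.genotypes.sex))


# ---------------------------------------------------------------------------
# top-level simulation
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic ZW dataset from a validated config."""
    cfg = (config or SimConfig()).validate()
    rng = np.random.default_rng(cfg.seed)

    z_arr = _NUC_BYTES[rng.integers(0, 4, size=cfg.chrom_length)]
    z_seq = z_arr.tobytes().decode()

    genes, z_seq = _place_genes(cfg, z_seq, rng)
    (w_seq, gene_truth, w_variants, w_spans, deleted_intervals) = _build_w(
        cfg, z_seq, genes, rng)
    deleted_intervals += _plant_large_deletions(cfg, genes, rng)
    # drop W-specific variants inside large deletions
    large = [iv for iv in deleted_intervals if iv[2] == "large"]
    if large:
        w_variants = [v for v in w_variants
                      if not any(s <= v[0] - 1 < e for s, e, _k in large)]
        w_seq = _apply_large_deletions(w_seq, genes, w_spans, large)

    gm, variant_truth = _build_cohort(cfg, z_seq, w_variants, rng)
    coverage, cov_truth = _simulate_coverage(cfg, deleted_intervals, gm, rng)
    expression, expr_truth = simulate_expression(genes, gene_truth, cfg, rng)
    trees, tree_classes = simulate_gene_trees(cfg.gene_tree_counts, rng=rng)
    marker_reads, marker_sex, marker_truth = simulate_marker_reads(rng=rng,
        read_length=cfg.read_length)

    z_cds = {}
    for g in genes:
        z_cds[g.gene_id] = g.cds(z_seq)
        gene_truth[g.gene_id]["w_span"] = list(w_spans.get(g.gene_id, (0, 0)))
        gene_truth[g.gene_id].update(expr_truth[g.gene_id])

    truth = {
        "note": ("all distributional choices are generator stand-ins; "
                 "no empirical generative model is implied"),
        "variants": variant_truth,
        "genes": gene_truth,
        "coverage_factor": cov_truth,
        "large_deletions": [[s, e] for s, e, k in deleted_intervals if k == "large"],
        "tree_classes": tree_classes,
        "marker_insert": marker_truth,
    }
    return SyntheticDataset(cfg, z_seq, w_seq, genes, z_cds, gm, coverage,
                            expression, trees, tree_classes, marker_reads,
                            marker_sex, truth)


# -- gene placement ---------------------------------------------------------

def _place_genes(cfg: SimConfig, z_seq: str, rng):
    genes = []
    seq = list(z_seq)
    counter = 0
    for region in ("PAR", "S2", "S1"):
        start, end = cfg.region_interval(region)
        if region == "S1" and cfg.n_large_w_deletions > 0:
            # keep the stratum-1 tail gene-free so large W deletions fit there
            end = end - (cfg.large_w_deletion_bp + 20_000)
        n = cfg.n_genes[region]
        if n == 0:
            continue
        slot = (end - start + 1) // n
        for i in range(n):
            counter += 1
            gid = f"g{counter:03d}"
            local = _random_local_gene(cfg, gid, rng)
            slot_start = start + i * slot
            # leave the tail of each slot empty (room for large deletions)
            offset = int(rng.integers(0, max(1, slot // 4)))
            gstart = slot_start + offset  # 1-based
            if gstart + len(local.seq) - 1 > end:
                gstart = max(start, end - len(local.seq))
            seq[gstart - 1 : gstart - 1 + len(local.seq)] = local.seq
            exons = [(gstart + s, gstart + e - 1) for s, e in local.exons]
            genes.append(zio.GeneModel(gid, "chrZ", "+", exons, region))
    return genes, "".join(seq)


def _random_local_gene(cfg: SimConfig, gid: str, rng) -> LocalGene:
    lo, hi = cfg.gene_length_range
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    cds = random_cds(n_codons, rng)
    k = int(rng.integers(cfg.exons_per_gene_range[0], cfg.exons_per_gene_range[1] + 1))
    k = min(k, max(2, len(cds) // 90))  # keep exons >= ~60 bp
    # evenly spaced cut points with jitter, codon-aligned, so no micro-exons
    seg = len(cds) / k
    cuts = []
    for i in range(1, k):
        jitter = rng.integers(-int(seg // 6), int(seg // 6) + 1)
        c = int(round((i * seg + jitter) / 3.0) * 3)
        cuts.append(min(max(c, 60 * i), len(cds) - 60 * (k - i)))
    bounds = [0] + cuts + [len(cds)]
    pieces, exons, cursor = [], [], 0
    for i in range(k):
        chunk = cds[bounds[i] : bounds[i + 1]]
        exons.append((cursor, cursor + len(chunk)))
        pieces.append(chunk)
        cursor += len(chunk)
        if i < k - 1:
            ilen = int(rng.integers(200, 801))
            intron = ("GT"
                      + _NUC_BYTES[rng.integers(0, 4, size=ilen - 4)].tobytes().decode()
                      + "AG")
            pieces.append(intron)
            cursor += ilen
    return LocalGene(gid, "".join(pieces), exons)


# -- W haplotype ------------------------------------------------------------

def _build_w(cfg: SimConfig, z_seq: str, genes, rng):
    """Derive the W haplotype from the Z, gene by gene.

    Returns (w_seq, gene_truth, w_variants, w_spans, deleted_intervals).
    ``w_variants`` are (z_pos_1based, ref, alt) substitutions in the SLR;
    ``deleted_intervals`` are (z_start0, z_end0, kind) spans missing from W.
    """
    pieces = []
    w_variants = []
    gene_truth = {}
    w_spans = {}
    deleted_intervals = []
    cursor = 0  # Z coordinate, 0-based
    w_cursor = 0

    def emit_background(z0, z1):
        nonlocal w_cursor
        if z1 <= z0:
            return
        # a background stretch may span region boundaries; mutate per region
        s = z0
        while s < z1:
            region = cfg.region_of(s + 1)
            _rs, re_ = cfg.region_interval(region)
            e = min(z1, re_)
            p = _jc_prob(cfg.ds_true[region])
            mutated, hits = _mutate_background(z_seq[s:e], p, rng)
            if region != "PAR":
                for h in hits:
                    w_variants.append((s + h + 1, z_seq[s + h], mutated[h]))
            pieces.append(mutated)
            w_cursor += e - s
            s = e

    for g in genes:
        emit_background(cursor, g.start - 1)
        region = g.region
        gstart0 = g.start - 1
        local_exons = [(s - g.start, e - g.start + 1) for s, e in g.exons]
        local = LocalGene(g.gene_id, z_seq[gstart0 : g.end], local_exons)

        derived_cds, n_syn, n_nonsyn, changes = evolve_cds(
            local.cds, cfg.ds_true[region], cfg.omega[region], rng,
            _return_changes=True)
        w_local_seq, cds_changed_local = _write_cds_back(local, derived_cds)
        introns = local.introns()
        protect = set()
        for istart, iend in introns:
            protect.update((istart, istart + 1, iend - 2, iend - 1))
        w_local_seq, intron_hits = _mutate_background_gene(
            w_local_seq, local_exons, _jc_prob(cfg.ds_true[region]), rng, protect)
        w_gene = LocalGene(g.gene_id, w_local_seq, local_exons)
        pre_lof_seq = w_local_seq  # alleles read before indels shift coordinates

        truth = {"region": region, "lof_class": "intact",
                 "syn_events": n_syn, "nonsyn_events": n_nonsyn}
        if rng.random() < cfg.lof_prob[region]:
            cls = LOF_CLASSES[int(rng.choice(4, p=np.asarray(cfg.lof_class_weights)))]
            w_gene, ev = plant_lof(w_gene, cls, rng)
            truth["lof_class"] = cls
            truth["lof_evidence"] = ev
            if "deleted_span" in ev:
                ds, de = ev["deleted_span"]
                deleted_intervals.append((gstart0 + ds, gstart0 + de, "gene"))

        if region != "PAR":
            deleted = truth.get("lof_evidence", {}).get("deleted_span")
            for h in sorted(set(cds_changed_local) | set(intron_hits)):
                if deleted and deleted[0] <= h < deleted[1]:
                    continue
                w_variants.append((gstart0 + h + 1, z_seq[gstart0 + h],
                                   pre_lof_seq[h]))
        pieces.append(w_gene.seq)
        w_spans[g.gene_id] = (w_cursor + 1, w_cursor + len(w_gene.seq))
        w_cursor += len(w_gene.seq)
        gene_truth[g.gene_id] = truth
        cursor = g.end

    emit_background(cursor, len(z_seq))
    w_seq = "".join(pieces)
    w_variants = sorted(v for v in w_variants if v[1] != v[2])
    return w_seq, gene_truth, w_variants, w_spans, deleted_intervals


def _write_cds_back(local: LocalGene, derived_cds: str):
    """Replace exon bases with the derived CDS; report changed local positions."""
    seq = list(local.seq)
    changed = []
    i = 0
    for s, e in local.exons:
        for p in range(s, e):
            if seq[p] != derived_cds[i]:
                changed.append(p)
            seq[p] = derived_cds[i]
            i += 1
    return "".join(seq), changed


def _mutate_background_gene(seq, exons, p, rng, protect):
    """Mutate intron/flank positions only (exonic bases already evolved)."""
    exonic = set()
    for s, e in exons:
        exonic.update(range(s, e))
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < p)
    out = list(seq)
    kept = []
    for h in hits:
        if h in exonic or h in protect:
            continue
        out[h] = _other_nuc(out[h], rng)
        kept.append(int(h))
    return "".join(out), kept


def _plant_large_deletions(cfg: SimConfig, genes, rng):
    """Reserve gene-free stretches of Stratum 1 as large W deletions."""
    if cfg.n_large_w_deletions == 0:
        return []
    s1_start, s1_end = cfg.region_interval("S1")
    spans = sorted((g.start, g.end) for g in genes if g.region == "S1")
    gaps = []
    prev = s1_start
    for s, e in spans:
        if s - prev >= cfg.large_w_deletion_bp + 2:
            gaps.append((prev, s - 1))
        prev = e + 1
    if s1_end - prev >= cfg.large_w_deletion_bp:
        gaps.append((prev, s1_end))
    out = []
    for i in range(min(cfg.n_large_w_deletions, len(gaps))):
        gs, ge = gaps[i]
        start = gs + int(rng.integers(0, max(1, ge - gs - cfg.large_w_deletion_bp)))
        out.append((start - 1, start - 1 + cfg.large_w_deletion_bp, "large"))
    return out


def _apply_large_deletions(w_seq, genes, w_spans, large):
    """Remove large-deletion spans from the W sequence.

    Large deletions are placed in gene-free stretches, so Z and W coordinates
    are offset only by upstream in-gene indels; we locate each span via the
    nearest upstream gene anchor.
    """
    cuts = []
    for zs, ze, _k in sorted(large):
        offset = sum((w_spans[g.gene_id][1] - w_spans[g.gene_id][0] + 1)
                     - (g.end - g.start + 1)
                     for g in genes if g.end - 1 < zs)
        cuts.append((zs + offset, ze + offset))
    out = w_seq
    for ws, we in sorted(cuts, reverse=True):
        out = out[:ws] + out[we:]
    return out


# -- cohort genotypes -------------------------------------------------------

def _hwe_sites(chrom, start, end, density, n_f, n_m, rng):
    """Hardy-Weinberg biallelic sites; returns rows + dosage rows + truth."""
    n_sites = int((end - start + 1) * density / 0.39)  # 0.39 = E[2p(1-p)], p~U(.1,.9)
    if n_sites == 0:
        return [], [], []
    pos = np.sort(rng.choice(np.arange(start, end + 1), size=n_sites, replace=False))
    rows, dos, truth = [], [], []
    for p_ in pos:
        freq = rng.uniform(0.1, 0.9)
        ref, alt = "A", "G"
        d = rng.binomial(2, freq, size=n_f + n_m).astype(np.int8)
        if len(set(d.tolist())) == 1:
            continue  # monomorphic draw, skip
        rows.append((chrom, int(p_), ref, alt))
        dos.append(d)
        truth.append({"chrom": chrom, "pos": int(p_), "origin": "HWE",
                      "sex_linked": False})
    return rows, dos, truth


def _build_cohort(cfg: SimConfig, z_seq: str, w_variants, rng):
    n_f, n_m = cfg.n_females, cfg.n_males
    samples = [f"F{i+1:02d}" for i in range(n_f)] + [f"M{i+1:02d}" for i in range(n_m)]
    sex = np.array(["F"] * n_f + ["M"] * n_m)

    rows, dos, truth = [], [], []

    # PAR + SLR-Z diversity on chrZ
    par_rows, par_dos, par_truth = _hwe_sites(
        "chrZ", 1, cfg.par_end, cfg.par_diversity, n_f, n_m, rng)
    rows += par_rows; dos += par_dos; truth += par_truth

    # Z-linked polymorphism inside the SLR: males HWE on two Z's, females one Z
    slr_density = 0.2 * cfg.par_diversity
    n_sites = int((cfg.chrom_length - cfg.par_end) * slr_density / 0.39)
    if n_sites:
        zpos = np.sort(rng.choice(np.arange(cfg.par_end + 1, cfg.chrom_length + 1),
                                  size=n_sites, replace=False))
        taken = {p for p, _r, _a in w_variants}
        for p_ in zpos:
            if int(p_) in taken:
                continue
            freq = rng.uniform(0.1, 0.9)
            d = np.concatenate([
                rng.binomial(1, freq, size=n_f),   # single Z in females (W = ref)
                rng.binomial(2, freq, size=n_m),
            ]).astype(np.int8)
            if len(set(d.tolist())) == 1:
                continue
            rows.append(("chrZ", int(p_), "C", "T"))
            dos.append(d)
            truth.append({"chrom": "chrZ", "pos": int(p_), "origin": "Z-diversity",
                          "sex_linked": False})

    # W-specific variants: females het, males hom-ref
    for pos, ref, alt in w_variants:
        rows.append(("chrZ", pos, ref, alt))
        dos.append(np.array([1] * n_f + [0] * n_m, dtype=np.int8))
        truth.append({"chrom": "chrZ", "pos": pos, "origin": "W",
                      "sex_linked": True})

    # autosome
    auto_rows, auto_dos, auto_truth = _hwe_sites(
        "chrA", 1, cfg.autosome_length, cfg.par_diversity, n_f, n_m, rng)
    rows += auto_rows; dos += auto_dos; truth += auto_truth

    order = sorted(range(len(rows)), key=lambda i: (rows[i][0], rows[i][1]))
    # deduplicate positions (HWE site may collide with a W-specific one)
    seen, uniq = set(), []
    for i in order:
        key = (rows[i][0], rows[i][1])
        if key in seen:
            continue
        seen.add(key)
        uniq.append(i)
    variants = pd.DataFrame([rows[i] for i in uniq],
                            columns=["chrom", "pos", "ref", "alt"])
    dosage = np.array([dos[i] for i in uniq], dtype=np.int8)
    truth = [truth[i] for i in uniq]

    # genotyping error then missingness
    if cfg.genotype_error_rate > 0 and dosage.size:
        err = rng.random(dosage.shape) < cfg.genotype_error_rate
        shift = rng.integers(1, 3, size=dosage.shape).astype(np.int8)
        dosage = np.where(err, (dosage + shift) % 3, dosage).astype(np.int8)
    if cfg.missing_rate > 0 and dosage.size:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage = np.where(miss, np.int8(zio.MISSING), dosage)

    gm = zio.GenotypeMatrix(variants, samples, sex, dosage)
    return gm, truth


# -- coverage ---------------------------------------------------------------

def _simulate_coverage(cfg: SimConfig, deleted_intervals, gm, rng):
    """Per-sample mean depth in windows tiling chrZ (and the autosome).

    Female depth halves over spans deleted from the W (females carry Z+W, so
    a W deletion removes half the female dose). Window truth factor is
    1 - 0.5 * (deleted fraction of window).
    """
    win = cfg.cov_window_bp
    rows, cov_truth = [], {}
    dels = [(s, e) for s, e, _k in deleted_intervals]
    for chrom, length in (("chrZ", cfg.chrom_length), ("chrA", cfg.autosome_length)):
        starts = np.arange(0, length, win)
        for s0 in starts:
            e0 = min(int(s0) + win, length)
            overlap = sum(max(0, min(e0, de) - max(int(s0), ds)) for ds, de in dels) \
                if chrom == "chrZ" else 0
            factor = 1.0 - 0.5 * overlap / (e0 - int(s0))
            cov_truth[f"{chrom}:{int(s0)}"] = factor
            for sample, sx in zip(gm.samples, gm.sex):
                f = factor if sx == "F" else 1.0
                lam = cfg.depth_mean * f * (e0 - int(s0)) / cfg.read_length
                depth = rng.poisson(lam) * cfg.read_length / (e0 - int(s0))
                rows.append((chrom, int(s0), e0, sample, round(float(depth), 4)))
    df = pd.DataFrame(rows, columns=zio.COVERAGE_COLS)
    return df, cov_truth


# -- expression -------------------------------------------------------------

def simulate_expression(genes, gene_truth, cfg: SimConfig, rng):
    """Allele-tagged expression counts for a 2F+2M (by default) cohort.

    Males: total ~ NB(mean 2u). Females: Z-allele ~ NB(u), or NB(2u) when the
    gene is dosage compensated; W-allele ~ NB(w_factor * u), w_factor = 0 for
    silenced copies. NB dispersion ``size`` fixed by config (default 10).
    """
    def nb(mean, size=cfg.nb_size, n=1):
        if mean <= 0:
            return np.zeros(n, dtype=int)
        return rng.negative_binomial(size, size / (size + mean), size=n)

    f_samples = [f"XF{i+1}" for i in range(cfg.n_expr_females)]
    m_samples = [f"XM{i+1}" for i in range(cfg.n_expr_males)]
    rows = []
    expr_truth = {}
    for g in genes:
        u = float(cfg.expr_baseline * rng.lognormal(0.0, 0.6))
        lof = gene_truth[g.gene_id]["lof_class"] != "intact"
        if lof:
            w_factor = 0.0 if rng.random() < 0.7 else float(rng.uniform(0.03, 0.2))
        else:
            w_factor = float(np.clip(rng.normal(1.0, 0.15), 0.3, None))
        hemizygous = w_factor < 0.256
        compensated = bool(hemizygous and rng.random() < cfg.compensated_fraction)
        z_mean = 2 * u if compensated else u
        for s in f_samples:
            z = int(nb(z_mean)[0])
            w = int(nb(w_factor * u)[0])
            rows.append((g.gene_id, s, "F", z, w, z + w))
        for s in m_samples:
            t = int(nb(2 * u)[0])
            rows.append((g.gene_id, s, "M", 0, 0, t))
        expr_truth[g.gene_id] = {"u": u, "w_factor": w_factor,
                                 "compensated": compensated}
    df = pd.DataFrame(rows, columns=zio.COUNTS_COLS)
    return df, expr_truth


# -- gene trees -------------------------------------------------------------

DEFAULT_TREE_LABELS = {"z": "focal_Z", "w": "focal_W",
                       "sister_species": "sister", "outgroup": "outgroup"}


def simulate_gene_trees(counts, labels: dict | None = None, rng=None,
                        extra_taxa=()):
    """Rooted gametolog gene trees realising planted topology classes.

    ``counts`` = (n ZW-sister, n W-loss, n Z-loss). Returns (newick strings,
    class labels). Branch lengths are uniform(0.01, 0.1); child order is
    randomised so classifiers cannot rely on string layout.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if any(c < 0 for c in counts):
        raise ConfigError(f"gene_tree_counts: counts must be >= 0, got {counts}")
    lab = dict(DEFAULT_TREE_LABELS)
    if labels:
        lab.update(labels)
    for key in ("z", "w", "sister_species", "outgroup"):
        if key not in lab:
            raise ConfigError(f"tree labels: missing {key}")
    if lab["outgroup"] in (lab["z"], lab["w"], lab["sister_species"]):
        raise ConfigError("tree labels: outgroup must differ from focal labels")

    def bl():
        return f"{rng.uniform(0.01, 0.1):.4f}"

    def pair(a, b):
        kids = [a, b]
        rng.shuffle(kids)
        return f"({kids[0]}:{bl()},{kids[1]}:{bl()})"

    trees, classes = [], []
    plan = (["ZW_sister"] * counts[0] + ["W_loss"] * counts[1]
            + ["Z_loss"] * counts[2])
    for cls in plan:
        if cls == "ZW_sister":
            core = pair(pair(lab["z"], lab["w"]), lab["sister_species"])
        elif cls == "W_loss":
            core = pair(pair(lab["z"], lab["sister_species"]), lab["w"])
        else:
            core = pair(pair(lab["w"], lab["sister_species"]), lab["z"])
        tree = pair(core, lab["outgroup"])
        for extra in extra_taxa:
            tree = pair(tree, extra)
        trees.append(tree + ";")
        classes.append(cls)
    return trees, classes


# -- k-mer marker scenario --------------------------------------------------

def simulate_marker_reads(n_per_sex: int = 12, genome_len: int = 30_000,
                          insert_len: int = 5_000, carrier_sex: str = "M",
                          n_carriers: int = 11, depth: float = 4.0,
                          read_length: int = 150, rng=None, seed: int = 0):
    """Short reads for a sex-specific presence/absence k-mer scan.

    One sex carries a hemizygous insert (an XY-like male-specific region by
    default); reads are error-free substrings of the individual's haplotypes,
    half of them reverse-complemented. Returns (reads dict, sex map, truth)
    where truth holds the insert sequence and its interval in the carrier
    haplotype.
    """
    from ._codon import revcomp

    if rng is None:
        rng = np.random.default_rng(seed)
    backbone = _NUC_BYTES[rng.integers(0, 4, size=genome_len)].tobytes().decode()
    insert = _NUC_BYTES[rng.integers(0, 4, size=insert_len)].tobytes().decode()
    ipos = genome_len // 2
    carrier_hap = backbone[:ipos] + insert + backbone[ipos:]

    reads, sexes = {}, {}
    carriers = set(range(n_carriers))
    for sx in ("M", "F"):
        for i in range(n_per_sex):
            sample = f"{sx}{i+1:02d}"
            sexes[sample] = sx
            is_carrier = sx == carrier_sex and i in carriers
            hap1 = carrier_hap if is_carrier else backbone
            hap2 = backbone
            n_reads = int(depth * len(hap1) / read_length)
            out = []
            for _ in range(n_reads):
                hap = hap1 if rng.random() < 0.5 else hap2
                start = int(rng.integers(0, len(hap) - read_length))
                r = hap[start : start + read_length]
                if rng.random() < 0.5:
                    r = revcomp(r)
                out.append(r)
            reads[sample] = out
    # k-mers spanning the insert/backbone junctions are carrier-specific too;
    # include 60 bp of flanking backbone so truth checks can allow them
    truth = {"insert": insert, "interval": [ipos, ipos + insert_len],
             "insert_with_junctions": carrier_hap[max(0, ipos - 60):
                                                  ipos + insert_len + 60],
             "carrier_sex": carrier_sex, "n_carriers": n_carriers}
    return reads, sexes, truth


# -- haplotig phasing scenario ----------------------------------------------

def simulate_haplotig_observations(n_contigs: int = 20, sites_per_contig: int = 100,
                                   switch_rate: float = 0.0, rng=None, seed: int = 0):
    """Allele observations at informative sites for contig phase assignment.

    Each contig is truly W or Z; each informative site reports which haplotype
    the observed allele matches, with ``switch_rate`` of sites flipped (phase
    switch errors / chimeric joins). Returns (DataFrame, truth dict).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows, truth = [], {}
    for i in range(n_contigs):
        contig = f"ctg{i+1:03d}"
        hap = "W" if rng.random() < 0.5 else "Z"
        truth[contig] = hap
        for s in range(sites_per_contig):
            obs = hap
            if rng.random() < switch_rate:
                obs = "Z" if hap == "W" else "W"
            rows.append((contig, s, obs))
    return pd.DataFrame(rows, columns=["contig", "site", "allele_haplotype"]), truth
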