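"""Readers and writers for the formats the pipeline touches.

VCFv4.2 (GT-only FORMAT, "." missing), FASTA, a GFF3 subset
(gene/mRNA/exon/CDS), tab-separated coverage and expression-count tables,
Newick tree lists and a JSON truth table. Parsers validate strictly and are
total on this package's own writers (round-trip safe).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("zwscan")

MISSING = -1  # dosage code for missing genotypes


class FormatError(ValueError):
    """Malformed input file."""


class LabelError(ValueError):
    """Sample present in the data but absent from the sex map (or vice versa)."""


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic variants x sexed diploid individuals.

    ``variants`` has columns chrom, pos (1-based), ref, alt; ``dosage`` is an
    int8 array of ALT-allele counts in {0, 1, 2} with -1 for missing.
    """

    variants: pd.DataFrame
    samples: list
    sex: np.ndarray  # 'F'/'M' per sample
    dosage: np.ndarray

    def __post_init__(self):
        if self.dosage.shape != (len(self.variants), len(self.samples)):
            raise ValueError("dosage shape does not match variants x samples")
        if len(self.sex) != len(self.samples):
            raise LabelError("every sample needs a sex label")
        bad = set(self.sex) - {"F", "M"}
        if bad:
            raise LabelError(f"unknown sex labels: {sorted(bad)}")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise FormatError(f"{chrom}: positions must be strictly increasing")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == "F")

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == "M")

    def subset_variants(self, mask) -> "GenotypeMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return GenotypeMatrix(
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.samples),
            self.sex.copy(),
            self.dosage[idx],
        )


@dataclass
class FilterReport:
    n_input: int = 0
    n_retained: int = 0
    rejected: dict = field(default_factory=dict)  # reason -> count

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """VCFv4.2 with a GT-only FORMAT column; unphased '/' separators."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=zwscan\n")
        for chrom, sub in gm.variants.groupby("chrom", sort=False):
            length = int(sub["pos"].max()) + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in gm.samples) + "\n")
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        var = gm.variants.itertuples(index=True)
        for row in var:
            gts = "\t".join(gt_code[int(d)] for d in gm.dosage[row.Index])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, sex_map: dict, maf_min: float = 0.0, max_missing: float = 1.0,
             biallelic_only: bool = True):
    """Read a VCF into a GenotypeMatrix, applying cohort filters.

    ``sex_map`` maps sample id -> 'F'/'M' and must cover every sample.
    ``max_missing`` is the maximum tolerated fraction of missing genotypes per
    record. Returns (GenotypeMatrix, FilterReport).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in sex_map]
    if unknown:
        raise LabelError(f"samples without sex label: {unknown}")
    sex = np.array([sex_map[s] for s in samples])
    report = FilterReport()
    rows, dosages = [], []
    for v in vcf:
        report.n_input += 1
        if v.FILTER not in (None, "PASS"):
            report.rejected["filter"] = report.rejected.get("filter", 0) + 1
            continue
        if biallelic_only and len(v.ALT) != 1:
            report.rejected["not_biallelic"] = report.rejected.get("not_biallelic", 0) + 1
            continue
        try:
            geno = v.genotypes
        except Exception as exc:  # pragma: no cover - cyvcf2 raises on no GT
            raise FormatError(f"record without GT at {v.CHROM}:{v.POS}") from exc
        if geno is None:
            raise FormatError(f"record without GT at {v.CHROM}:{v.POS}")
        dos = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(geno):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                dos[i] = MISSING
            else:
                dos[i] = sum(1 for a in alleles if a == 1)
        n_missing = int(np.sum(dos == MISSING))
        if len(samples) and n_missing / len(samples) > max_missing:
            report.rejected["missing"] = report.rejected.get("missing", 0) + 1
            continue
        called = dos[dos != MISSING]
        if maf_min > 0:
            if called.size == 0:
                report.rejected["maf"] = report.rejected.get("maf", 0) + 1
                continue
            p = called.sum() / (2 * called.size)
            if min(p, 1 - p) < maf_min:
                report.rejected["maf"] = report.rejected.get("maf", 0) + 1
                continue
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0] if v.ALT else "."))
        dosages.append(dos)
    report.n_retained = len(rows)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = np.array(dosages, dtype=np.int8) if dosages else np.empty((0, len(samples)), np.int8)
    gm = GenotypeMatrix(variants, samples, sex, dosage)
    log.info("read_vcf: input=%d retained=%d rejected=%s",
             report.n_input, report.n_retained, report.rejected)
    return gm, report


# ---------------------------------------------------------------------------
# gene models / GFF subset
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A protein-coding gene: ordered, non-overlapping exons on one strand.

    Exon intervals are 1-based inclusive genomic coordinates sorted 5'->3'
    (equals genomic order on the + strand, which is the only strand the
    synthetic generator emits).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list  # [(start, end), ...]
    region: str = "autosome"

    def __post_init__(self):
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise FormatError(f"{self.gene_id}: overlapping exons")
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = ex

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def cds(self, chrom_seq: str) -> str:
        """Spliced CDS extracted from a chromosome sequence (+ strand)."""
        return "".join(chrom_seq[s - 1 : e] for s, e in self.exons)

    def exon_seqs(self, chrom_seq: str) -> list:
        return [chrom_seq[s - 1 : e] for s, e in self.exons]


def write_gff(genes: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};region={g.region}"
            fh.write(f"{g.chrom}\tzwscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            fh.write(f"{g.chrom}\tzwscan\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}.t1;Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tzwscan\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.exon{i};Parent={g.gene_id}.t1\n")
                fh.write(f"{g.chrom}\tzwscan\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                         f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n")


def read_gff(path) -> list:
    """Parse the GFF3 subset back into GeneModel objects (via gffutils)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = []
        for mrna in db.children(g, featuretype="mRNA"):
            for ex in db.children(mrna, featuretype="exon", order_by="start"):
                if ex.start < g.start or ex.end > g.end:
                    raise FormatError(
                        f"{g.id}: exon {ex.start}-{ex.end} outside gene span "
                        f"{g.start}-{g.end}"
                    )
                exons.append((ex.start, ex.end))
        region = g.attributes.get("region", ["autosome"])[0]
        genes.append(GeneModel(g.id, g.seqid, g.strand, exons, region))
    return genes


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

COVERAGE_COLS = ["chrom", "window_start", "window_end", "sample", "mean_depth"]
COUNTS_COLS = ["gene", "sample", "sex", "z_count", "w_count", "total_count"]


def write_coverage(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COVERAGE_COLS)


def read_coverage(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COVERAGE_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"coverage table missing columns: {sorted(missing)}")
    bad = df.index[df["mean_depth"] < 0]
    if len(bad):
        raise FormatError(f"negative depth at line {bad[0] + 2}")  # +2: header + 1-based
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COUNTS_COLS)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNTS_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"counts table missing columns: {sorted(missing)}")
    for col in ("z_count", "w_count", "total_count"):
        vals = df[col]
        if len(vals) and (vals < 0).any():
            raise FormatError(f"negative count in column {col} at line "
                              f"{int(vals.index[vals < 0][0]) + 2}")
        if len(vals) and not np.issubdtype(vals.dtype, np.integer):
            raise FormatError(f"non-integer counts in column {col}")
    return df


# ---------------------------------------------------------------------------
# Newick lists
# ---------------------------------------------------------------------------

def check_newick(s: str) -> None:
    """Cheap structural check; raises FormatError at the offending offset."""
    depth = 0
    for i, ch in enumerate(s):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' at offset {i}")
    if depth != 0:
        raise FormatError(f"unbalanced '(' ({depth} unclosed) at offset {len(s)}")


def write_newick_list(trees: list, path) -> None:
    """One Newick string per line."""
    with open(path, "w") as fh:
        for t in trees:
            t = t.strip()
            fh.write(t + ("\n" if t.endswith(";") else ";\n"))


def read_newick_list(path) -> list:
    import dendropy

    trees = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            check_newick(line)
            try:
                tree = dendropy.Tree.get(data=line, schema="newick",
                                         preserve_underscores=True)
            except Exception as exc:
                raise FormatError(f"malformed Newick at line {lineno}: {exc}") from exc
            trees.append(tree)
    return trees


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=_jsonable)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
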