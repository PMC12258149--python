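"""Classify the functional state of W-linked gene copies.

Each Z-linked gene's CDS is aligned exon by exon against its W region; the W
copy is then assigned exactly one class with a fixed precedence, matching
exclusive counting of loss-of-function (LoF) categories:

1. ``sequence_loss``  — query coverage < 0.5 or identity < 0.6
2. ``exon_loss``      — at least one complete exon missing
3. ``orf_disrupt``    — start codon lost, premature stop, or a net indel
                        whose length is not a multiple of 3
4. ``splice_disrupt`` — an intron terminus no longer GT...AG
5. ``intact``         — none of the above

Alignment is a simplified exon-aware nucleotide aligner: per-exon local
alignments (match 2 / mismatch -3 / gap open -5 / extend -2), searched
left-to-right so exon order is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codon import STOP_CODONS, translate
from .strata import degeneration_rates

log = logging.getLogger("zwscan")

CLASSES = ("intact", "sequence_loss", "exon_loss", "orf_disrupt", "splice_disrupt")


def _make_dna_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


@dataclass
class ExonAlignment:
    index: int
    lost: bool
    aligned_fraction: float     # fraction of exon bases in aligned columns
    identity: float             # matches / aligned columns (NaN if lost)
    query_span: tuple           # [qs, qe) within the exon, aligned part
    target_span: tuple          # [ts, te) within the W region
    w_segment: str              # W sequence homologous to the exon (with indels)
    net_indel: int              # target-minus-query length difference


@dataclass
class CdsAlignment:
    gene_id: str
    exons: list                 # ExonAlignment per exon
    query_coverage: float       # aligned Z-CDS fraction over all exons
    identity: float             # matches / aligned columns over all exons

    @property
    def lost_exons(self):
        return [e.index for e in self.exons if e.lost]


@dataclass
class WAlleleStatus:
    gene_id: str
    w_class: str
    query_coverage: float
    identity: float
    evidence: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# exon-aware alignment
# ---------------------------------------------------------------------------

def align_cds_to_region(exon_seqs: list, w_region: str, gene_id: str = "gene",
                        lost_max_aligned: float = 0.2) -> CdsAlignment:
    """Align each exon of a Z CDS against a W genomic region.

    Exons are searched in order: each local alignment is constrained to start
    at or after the previous exon's end in the region. An exon with less
    than ``lost_max_aligned`` of its bases aligned is flagged lost. An empty
    region yields coverage 0 for every exon.
    """
    aligner = _make_dna_aligner()
    results = []
    cursor = 0
    total_q = sum(len(e) for e in exon_seqs)
    aligned_bases = 0
    match_cols = 0.0
    total_cols = 0.0
    for i, exon in enumerate(exon_seqs):
        target = w_region[cursor:]
        if not target or not exon:
            results.append(ExonAlignment(i, True, 0.0, float("nan"),
                                         (0, 0), (cursor, cursor), "", 0))
            continue
        aln = aligner.align(exon, target)
        # a genuine homolog scores near 2*len(exon); spurious local hits in a
        # few kb of unrelated sequence stay far below len(exon)
        if aln.score < len(exon):
            results.append(ExonAlignment(i, True, 0.0, float("nan"),
                                         (0, 0), (cursor, cursor), "", 0))
            continue
        best = aln[0]
        q_blocks, t_blocks = best.aligned
        qs, qe = int(q_blocks[0][0]), int(q_blocks[-1][1])
        ts, te = int(t_blocks[0][0]), int(t_blocks[-1][1])
        # local alignment trims mismatching terminal bases; extend the target
        # span by those few trimmed query bases so splice termini line up
        # (capped: long unaligned query tails are genuine absence, not trimming)
        ext_left = min(qs, ts, 4)
        ext_right = min(len(exon) - qe, len(target) - te, 4)
        n_aligned = qe - qs + ext_left + ext_right
        frac = n_aligned / len(exon)
        if frac < lost_max_aligned:
            results.append(ExonAlignment(i, True, frac, float("nan"),
                                         (qs, qe), (cursor, cursor), "", 0))
            continue
        matches = 0
        cols = 0
        for (qb0, qb1), (tb0, tb1) in zip(q_blocks, t_blocks):
            cols += qb1 - qb0
            for qq, tt in zip(range(qb0, qb1), range(tb0, tb1)):
                if exon[qq] == target[tt]:
                    matches += 1
        for off in range(1, ext_left + 1):
            cols += 1
            matches += exon[qs - off] == target[ts - off]
        for off in range(ext_right):
            cols += 1
            matches += exon[qe + off] == target[te + off]
        ident = matches / cols if cols else float("nan")
        seg = target[ts - ext_left : te + ext_right]
        results.append(ExonAlignment(
            i, False, frac, ident,
            (qs - ext_left, qe + ext_right),
            (cursor + ts - ext_left, cursor + te + ext_right),
            seg, len(seg) - n_aligned - (0)))
        # net indel: target segment length vs aligned query length
        results[-1].net_indel = len(seg) - (qe - qs + ext_left + ext_right)
        aligned_bases += n_aligned
        match_cols += matches
        total_cols += cols
        cursor = cursor + te
    coverage = aligned_bases / total_q if total_q else 0.0
    identity = match_cols / total_cols if total_cols else 0.0
    return CdsAlignment(gene_id, results, coverage, identity)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_w_allele(alignment: CdsAlignment, exon_seqs: list, w_region: str,
                      min_coverage: float = 0.5, min_identity: float = 0.6,
                      min_lost_exons: int = 1) -> WAlleleStatus:
    """Assign the W copy one functional class by fixed precedence."""
    ev = {}
    if (alignment.query_coverage < min_coverage
            or alignment.identity < min_identity):
        ev["query_coverage"] = alignment.query_coverage
        ev["identity"] = alignment.identity
        return WAlleleStatus(alignment.gene_id, "sequence_loss",
                             alignment.query_coverage, alignment.identity, ev)
    lost = alignment.lost_exons
    if len(lost) >= min_lost_exons:
        ev["lost_exons"] = lost
        return WAlleleStatus(alignment.gene_id, "exon_loss",
                             alignment.query_coverage, alignment.identity, ev)

    w_cds = "".join(e.w_segment for e in alignment.exons)
    z_cds = "".join(exon_seqs)
    orf_ev = _orf_disruption(z_cds, w_cds, alignment)
    if orf_ev:
        ev.update(orf_ev)
        return WAlleleStatus(alignment.gene_id, "orf_disrupt",
                             alignment.query_coverage, alignment.identity, ev)

    splice_ev = _splice_disruption(alignment, w_region)
    if splice_ev:
        ev.update(splice_ev)
        return WAlleleStatus(alignment.gene_id, "splice_disrupt",
                             alignment.query_coverage, alignment.identity, ev)
    return WAlleleStatus(alignment.gene_id, "intact",
                         alignment.query_coverage, alignment.identity, {})


def _orf_disruption(z_cds: str, w_cds: str, alignment: CdsAlignment):
    """Start-codon loss, premature stop, or frame-disrupting net indel."""
    ev = {}
    net = sum(e.net_indel for e in alignment.exons)
    if net % 3 != 0:
        ev["net_indel"] = net
        return ev
    if not w_cds.startswith("ATG") and z_cds.startswith("ATG"):
        ev["start_codon"] = w_cds[:3]
        return ev
    # premature stop: an in-frame stop >= 1 codon before the annotated stop
    prot = translate(w_cds)
    expected_stop = len(z_cds) // 3 - 1
    stop_at = prot.find("*")
    if stop_at != -1 and stop_at < expected_stop:
        ev["premature_stop_codon_index"] = stop_at
        return ev
    return None


def _splice_disruption(alignment: CdsAlignment, w_region: str):
    """Check GT...AG at the introns implied by consecutive aligned exons."""
    bad = []
    aligned = [e for e in alignment.exons if not e.lost]
    for e1, e2 in zip(aligned, aligned[1:]):
        donor_pos = e1.target_span[1]
        acceptor_pos = e2.target_span[0]
        if acceptor_pos - donor_pos < 4:
            continue  # no room for an intron; treat as contiguous
        donor = w_region[donor_pos : donor_pos + 2]
        acceptor = w_region[acceptor_pos - 2 : acceptor_pos]
        if donor != "GT":
            bad.append((e1.index, "donor", donor))
        if acceptor != "AG":
            bad.append((e2.index - 1, "acceptor", acceptor))
    if bad:
        return {"splice": bad}
    return None


# ---------------------------------------------------------------------------
# convenience: classify a whole gene set
# ---------------------------------------------------------------------------

def classify_genes(genes, z_seq: str, w_seq: str, w_spans: dict,
                   flank: int = 500) -> list:
    """Run alignment + classification for every gene.

    ``w_spans`` maps gene_id -> (start, end) 1-based inclusive interval of
    the gene's homologous span on the W sequence (synthetic truth span or a
    user-supplied interval); ``flank`` bases are added on both sides.
    """
    statuses = []
    for g in genes:
        ws, we = w_spans[g.gene_id]
        region = w_seq[max(0, ws - 1 - flank) : min(len(w_seq), we + flank)]
        exon_seqs = g.exon_seqs(z_seq)
        aln = align_cds_to_region(exon_seqs, region, g.gene_id)
        statuses.append(classify_w_allele(aln, exon_seqs, region))
    return statuses


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def summarize_degeneration(statuses: list, regions: dict,
                           ages_my: dict | None = None,
                           generation_time_years: float = 1.5) -> pd.DataFrame:
    """Per-region LoF counts, percentages, and (optionally) rates.

    ``regions`` maps gene_id -> region label; every classified gene must be
    present. Nonfunctional = any class != intact. When ``ages_my`` gives a
    stratum age in MY, %/MY and %/Mgen are added via ``degeneration_rates``.
    """
    missing = [s.gene_id for s in statuses if s.gene_id not in regions]
    if missing:
        raise KeyError(f"genes without region assignment: {missing}")
    rows = {}
    for s in statuses:
        r = regions[s.gene_id]
        d = rows.setdefault(r, {"total": 0, "nonfunctional": 0,
                                **{c: 0 for c in CLASSES}})
        d["total"] += 1
        d[s.w_class] += 1
        if s.w_class != "intact":
            d["nonfunctional"] += 1
    out = []
    order = [r for r in ("PAR", "S2", "S1") if r in rows]
    order += [r for r in rows if r not in order]
    for r in order:
        d = rows[r]
        pct = 100.0 * d["nonfunctional"] / d["total"]
        rec = {"region": r, **d, "pct_nonfunctional": pct}
        if ages_my and r in ages_my:
            per_my, per_mgen = degeneration_rates(pct, ages_my[r],
                                                  generation_time_years)
            rec["pct_per_my"] = per_my
            rec["pct_per_mgen"] = per_mgen
        out.append(rec)
    total = sum(d["total"] for d in rows.values())
    nonf = sum(d["nonfunctional"] for d in rows.values())
    overall = {"region": "all", "total": total, "nonfunctional": nonf,
               **{c: sum(d[c] for d in rows.values()) for c in CLASSES},
               "pct_nonfunctional": 100.0 * nonf / total if total else 0.0}
    out.append(overall)
    return pd.DataFrame(out)
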