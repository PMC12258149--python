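"""Codon table helpers shared by the sequence generator and the Ka/Ks estimator.

Standard (NCBI table 1) genetic code; DNA alphabet, uppercase.
"""

from __future__ import annotations

NUCS = "ACGT"

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a DNA sequence codon by codon; incomplete tail codon dropped."""
    return "".join(
        CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - len(cds) % 3, 3)
    )


def codon_changes(codon: str):
    """All single-nucleotide neighbours of ``codon``.

    Yields (position, alt_nucleotide, new_codon, is_synonymous); neighbours that
    are stop codons are included (callers decide how to treat them).
    """
    aa = CODON_TABLE[codon]
    for pos in range(3):
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            new = codon[:pos] + nuc + codon[pos + 1 :]
            yield pos, nuc, new, CODON_TABLE[new] == aa


def random_cds(n_codons: int, rng) -> str:
    """A random open reading frame: ATG start, stop-free body, one stop at the end."""
    if n_codons < 3:
        raise ValueError("need at least start + 1 codon + stop")
    sense = [c for c in CODON_TABLE if CODON_TABLE[c] != "*"]
    body = ["ATG"]
    idx = rng.integers(0, len(sense), size=n_codons - 2)
    body.extend(sense[i] for i in idx)
    stops = sorted(STOP_CODONS)
    body.append(stops[rng.integers(0, len(stops))])
    return "".join(body)
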