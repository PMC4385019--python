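"""Nucleotide sequence utilities: IUPAC degenerate codes, reverse complement,
FASTA / GFF3 helpers and promoter extraction.

IUPAC degenerate symbols describe the set of bases allowed at a motif
position (R = A/G, Y = C/T, ..., N = any).  All sequence handling in the
package is uppercase DNA over {A, C, G, T, N}.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Allowed bases per IUPAC symbol.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA or IUPAC-degenerate string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_iupac(consensus: str) -> str:
    """Return the uppercased consensus, raising ``ValueError`` on bad symbols."""
    consensus = consensus.upper()
    if not consensus:
        raise ValueError("empty IUPAC consensus")
    bad = set(consensus) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC symbol(s) {sorted(bad)} in {consensus!r}")
    return consensus


def validate_dna(seq: str, allow_n: bool = False) -> str:
    """Uppercase and validate a plain DNA string (optionally allowing N)."""
    seq = seq.upper()
    allowed = set("ACGTN") if allow_n else set("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-DNA symbol(s) {sorted(bad)} in sequence")
    return seq


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature estimate: 2(A+T) + 4(G+C) degrees C."""
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def extract_upstream(chrom_seq: str, start: int, end: int, strand: str, length: int) -> str:
    """Extract the ``length`` bases immediately 5' of a feature, on its strand.

    ``start``/``end`` are 1-based inclusive genomic coordinates.  For a
    plus-strand feature the upstream region is ``[start-length, start-1]``;
    for a minus-strand feature it is ``[end+1, end+length]`` reverse
    complemented.  Truncated silently at contig edges (the caller may warn).
    """
    if strand == "+":
        lo = max(0, start - 1 - length)
        return chrom_seq[lo : start - 1]
    if strand == "-":
        return revcomp(chrom_seq[end : end + length])
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA with deterministic ordering."""
    items = records.items() if isinstance(records, Mapping) else records
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
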