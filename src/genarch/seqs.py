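"""Shared nucleotide/protein sequence helpers and FASTA I/O.

All coordinates inside the package are 0-based, half-open. Conversion to
1-based inclusive happens only at GFF3/report boundaries.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVNacgtrykmswbdhvn",
                            "TGCAYRMKSWVHDBNtgcayrmkswvhdbn")

# IUPAC codes for ambiguous consensus columns (frozenset of bases -> code).
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS with the standard eukaryotic code ('*' for stops)."""
    return str(Seq(cds).translate())


def gc_fraction(seq: str) -> float:
    """G+C over unambiguous A/C/G/T bases only (case-insensitive)."""
    s = seq.upper()
    counts = {b: s.count(b) for b in DNA}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return (counts["G"] + counts["C"]) / total


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def iter_kmers(seq: str, k: int) -> Iterator[tuple[int, str]]:
    for i in range(len(seq) - k + 1):
        yield i, seq[i:i + k]
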