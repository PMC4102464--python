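"""Shared helpers: IUPAC tables, report rounding, FASTA/FASTQ text IO."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator

# IUPAC nucleotide ambiguity codes.  Keys are the exact observed base sets;
# lowercase 'n' is reserved for missing data (no coverage), never a variant.
IUPAC_CODE: dict[frozenset[str], str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

IUPAC_BASES: dict[str, frozenset[str]] = {v: k for k, v in IUPAC_CODE.items()}

# 4-bit base masks; a reference code is compatible with a read base when the
# masks intersect.  'n' (missing) gets mask 0 and thus never matches.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASK: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_BASES.items()
}
IUPAC_MASK["n"] = 0

AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as report tables do (2.5 -> 3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def seq_mask(seq: str) -> list[int]:
    """Per-position compatibility masks for a reference sequence."""
    return [IUPAC_MASK.get(c, 0) for c in seq]


# ---------------------------------------------------------------------------
# Plain-text sequence IO (line-wrapped FASTA, Phred+33 FASTQ)
# ---------------------------------------------------------------------------

FASTA_WIDTH = 80


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def read_fasta(path) -> Iterator[tuple[str, str]]:
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:], seq, qual
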