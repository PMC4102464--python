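"""Hash-seeded read mapping against an IUPAC-aware consensus transcriptome.

Reads are seeded with fixed-length hash words (default 14), candidate
placements are verified by full-read comparison under a mismatch cap
(default 2), and only reads with exactly one minimal-mismatch placement are
counted.  IUPAC ambiguity codes in the reference match any compatible read
base; lowercase 'n' never matches.

For reads shorter than 3x the hash length a clean 14-mer seed is not
guaranteed to exist for every 2-mismatch placement, so candidate generation
falls back to the pigeonhole word length floor(L / (max_mismatch + 1)),
which makes seeded search exactly equivalent to a brute-force scan.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import IUPAC_BASES, IUPAC_MASK, round_half_up

DEFAULT_HASH_LENGTH = 14
DEFAULT_MAX_MISMATCH = 2
_MAX_WORD_VARIANTS = 256  # expansion cap for ambiguity codes within one word

_MASK_TABLE = str.maketrans(
    {c: chr(m) for c, m in IUPAC_MASK.items()}
    | {c.lower(): chr(m) for c, m in IUPAC_MASK.items() if c in "ACGT"}
    | {c.lower(): chr(0) for c in "RYSWKMBDHV"}
)


def _mask_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.translate(_MASK_TABLE).encode("latin1"), dtype=np.uint8)


@dataclass(frozen=True)
class Placement:
    read_id: str
    gene_id: str
    offset: int
    mismatches: int


@dataclass
class MappingSummary:
    """Read-fate accounting for one sample."""

    sample: str = ""
    generated: int = 0
    aligned: int = 0
    filtered_for_mismatches: int = 0
    multi_mapped: int = 0
    unique_mapped: int = 0
    unseeded: int = 0
    per_gene_unique: dict[str, int] = field(default_factory=dict)
    depth: dict[str, np.ndarray] = field(default_factory=dict)

    def check(self) -> None:
        if self.generated != (
            self.unique_mapped + self.multi_mapped
            + self.filtered_for_mismatches + self.unseeded
        ):
            raise ValueError("read fates do not sum to generated")
        if self.aligned != self.unique_mapped + self.multi_mapped:
            raise ValueError("aligned != unique + multi")


class HashIndex:
    """Word index over an IUPAC-aware reference set.

    Every reference window of the word length that is free of 'n' and whose
    ambiguity-code expansion stays under a cap is indexed under all compatible
    ACGT words.
    """

    def __init__(self, references: Mapping[str, str], h: int = DEFAULT_HASH_LENGTH):
        if h < 8:
            raise ValueError("hash length must be >= 8")
        self.h = h
        self.references = dict(references)
        self.masks = {g: _mask_array(s) for g, s in self.references.items()}
        self._indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}
        self._build(h)

    def _build(self, w: int) -> None:
        index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for gene, seq in self.references.items():
            for i in range(len(seq) - w + 1):
                window = seq[i : i + w]
                for word in _expand_word(window):
                    index[word].append((gene, i))
        self._indexes[w] = dict(index)

    def lookup(self, word: str, w: int | None = None) -> list[tuple[str, int]]:
        w = self.h if w is None else w
        if w not in self._indexes:
            self._build(w)
        return self._indexes[w].get(word, [])

    def ensure_word_length(self, w: int) -> None:
        if w not in self._indexes:
            self._build(w)


def _expand_word(window: str) -> list[str]:
    """All ACGT words compatible with a reference window; [] if unindexable."""
    sets = []
    n_variants = 1
    for c in window:
        bases = IUPAC_BASES.get(c)
        if bases is None:  # 'n' or unknown
            return []
        sets.append(sorted(bases))
        n_variants *= len(bases)
        if n_variants > _MAX_WORD_VARIANTS:
            return []
    if n_variants == 1:
        return [window]
    return ["".join(t) for t in product(*sets)]


def build_hash_index(references: Mapping[str, str], h: int = DEFAULT_HASH_LENGTH) -> HashIndex:
    return HashIndex(references, h)


def _candidate_offsets(
    read: str, index: HashIndex, max_mismatch: int, full_sensitivity: bool
) -> set[tuple[str, int]]:
    length = len(read)
    w = index.h
    if full_sensitivity:
        pigeon = length // (max_mismatch + 1)
        if pigeon < index.h:
            # fully sensitive word length; its candidate set is a superset of
            # the h-mer candidate set, so querying it alone suffices
            w = pigeon
            index.ensure_word_length(w)
    cands: set[tuple[str, int]] = set()
    for s in range(length - w + 1):
        for gene, pos in index.lookup(read[s : s + w], w):
            off = pos - s
            if 0 <= off <= len(index.references[gene]) - length:
                cands.add((gene, off))
    return cands


def map_read(
    read: str,
    index: HashIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    read_id: str = "",
    full_sensitivity: bool = True,
) -> list[Placement]:
    """All minimal-mismatch placements of a read within the mismatch cap."""
    if len(read) < index.h:
        return []
    rmask = _mask_array(read)
    length = len(read)
    results: list[tuple[str, int, int]] = []
    for gene, off in _candidate_offsets(read, index, max_mismatch, full_sensitivity):
        seg = index.masks[gene][off : off + length]
        mism = int(np.count_nonzero((seg & rmask) == 0))
        if mism <= max_mismatch:
            results.append((gene, off, mism))
    if not results:
        return []
    best = min(m for _, _, m in results)
    return [
        Placement(read_id, g, o, m)
        for g, o, m in sorted(results)
        if m == best
    ]


def map_reads(
    reads: Iterable[tuple[str, str]],
    index: HashIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    sample: str = "",
    full_sensitivity: bool = True,
) -> MappingSummary:
    """Map (read_id, sequence) pairs and account for every read's fate.

    A read with exactly one minimal-mismatch placement is unique and
    contributes to its gene's count and per-position depth; two or more
    placements anywhere (even on one gene) make it multi-mapped; reads whose
    candidates all exceed the mismatch cap are filtered; reads with no seeded
    candidate are unseeded.
    """
    summary = MappingSummary(sample=sample)
    depth = {g: np.zeros(len(s), dtype=np.int32) for g, s in index.references.items()}
    per_gene: dict[str, int] = defaultdict(int)
    for read_id, seq in reads:
        summary.generated += 1
        if len(seq) < index.h:
            summary.unseeded += 1
            continue
        rmask = _mask_array(seq)
        length = len(seq)
        cands = _candidate_offsets(seq, index, max_mismatch, full_sensitivity)
        if not cands:
            summary.unseeded += 1
            continue
        results = []
        for gene, off in cands:
            seg = index.masks[gene][off : off + length]
            mism = int(np.count_nonzero((seg & rmask) == 0))
            if mism <= max_mismatch:
                results.append((gene, off, mism))
        if not results:
            summary.filtered_for_mismatches += 1
            continue
        best = min(m for _, _, m in results)
        placements = [(g, o) for g, o, m in results if m == best]
        if len(placements) == 1:
            gene, off = placements[0]
            summary.unique_mapped += 1
            per_gene[gene] += 1
            depth[gene][off : off + length] += 1
        else:
            summary.multi_mapped += 1
    summary.aligned = summary.unique_mapped + summary.multi_mapped
    summary.per_gene_unique = dict(per_gene)
    summary.depth = depth
    summary.check()
    return summary


def read_fate_percentages(summary: MappingSummary) -> dict[str, float]:
    """Percentages of generated reads per fate, rounded to one decimal."""
    if summary.generated <= 0:
        raise ValueError("no reads generated")
    g = summary.generated
    return {
        "pct_aligned": round_half_up(100.0 * summary.aligned / g, 1),
        "pct_filtered": round_half_up(100.0 * summary.filtered_for_mismatches / g, 1),
        "pct_multi": round_half_up(100.0 * summary.multi_mapped / g, 1),
        "pct_unique": round_half_up(100.0 * summary.unique_mapped / g, 1),
    }


# ---------------------------------------------------------------------------
# Brute-force oracle (independent of the seeded path; used by the test suite
# and exposed for verification runs)
# ---------------------------------------------------------------------------


def brute_force_placements(
    read: str,
    references: Mapping[str, str],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    read_id: str = "",
) -> list[Placement]:
    """Exhaustive all-positions scan under the same IUPAC mismatch rules."""
    rmask = _mask_array(read)
    length = len(read)
    results = []
    for gene, seq in references.items():
        gmask = _mask_array(seq)
        for off in range(len(seq) - length + 1):
            mism = int(np.count_nonzero((gmask[off : off + length] & rmask) == 0))
            if mism <= max_mismatch:
                results.append((gene, off, mism))
    if not results:
        return []
    best = min(m for _, _, m in results)
    return [Placement(read_id, g, o, m) for g, o, m in sorted(results) if m == best]


def summary_table(summaries: Sequence[MappingSummary]):
    import pandas as pd

    rows = []
    for s in summaries:
        pct = read_fate_percentages(s)
        rows.append(
            (s.sample, s.generated, s.aligned, s.filtered_for_mismatches,
             s.multi_mapped, s.unique_mapped, s.unseeded,
             pct["pct_aligned"], pct["pct_filtered"], pct["pct_multi"],
             pct["pct_unique"])
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "generated", "aligned", "filtered", "multi", "unique",
                 "unseeded", "pct_aligned", "pct_filtered", "pct_multi",
                 "pct_unique"],
    )
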