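"""Reference-anchored consensus construction with IUPAC ambiguity codes.

Contigs assigned to a gene are placed on the reference coordinate frame by
their best ungapped hit (the frame extends over any UTR overhang), collapsed
into a consensus where variable columns become IUPAC codes and uncovered
columns become lowercase 'n', and screened by an ambiguity-fraction QC with
per-gene kmer selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from ._util import IUPAC_CODE, AMBIGUITY_CODES, round_half_up
from .homology import PairwiseHit, ScoringScheme, seed_and_extend
from .synthdata import ReferenceGene

DEFAULT_AMBIGUITY_THRESHOLD = 0.019


@dataclass(frozen=True)
class AlignedRow:
    contig_id: str
    sample: str
    start: int  # reference coordinate of contig position 0 (may be negative)
    sequence: str

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass(frozen=True)
class AnchoredAlignment:
    """Contigs of one gene placed on an extended reference coordinate frame."""

    gene_id: str
    kmer: int
    ref_length: int
    cds_start: int
    cds_end: int
    rows: tuple[AlignedRow, ...]

    @property
    def frame_start(self) -> int:
        return min(0, min((r.start for r in self.rows), default=0))

    @property
    def frame_end(self) -> int:
        return max(self.ref_length, max((r.end for r in self.rows), default=0))


@dataclass(frozen=True)
class ConsensusRecord:
    gene_id: str
    kmer: int
    sequence: str  # over {A,C,G,T} + IUPAC codes + lowercase n
    frame_start: int  # reference coordinate of sequence[0]
    cds_start: int  # reference coordinates
    cds_end: int
    ambiguity_fraction: float
    assembled_length: int
    cds_coverage_fraction: float
    utr5_extra_bp: int
    utr3_extra_bp: int


@dataclass(frozen=True)
class QCOutcome:
    gene_id: str
    category: str  # misalignment | utr_divergent_paralog | divergent_contig_removed | clean
    contigs_removed: tuple[str, ...] = ()


def anchor_contigs(
    gene: ReferenceGene,
    contigs: Sequence[tuple[str, str, str]],
    kmer: int,
    hits: Mapping[str, PairwiseHit] | None = None,
    scheme: ScoringScheme | None = None,
) -> AnchoredAlignment:
    """Place contigs (id, sample, sequence) on the gene's coordinate frame.

    Each contig's offset comes from its best hit to the gene; unaligned
    termini extend the frame.  The reference row itself is excluded from the
    consensus (it only provides the frame).
    """
    if scheme is None:
        scheme = ScoringScheme.create(db_len=len(gene.sequence))
    rows = []
    for contig_id, sample, seq in contigs:
        hit = hits.get(contig_id) if hits else None
        if hit is None:
            hit = seed_and_extend(contig_id, seq, gene.gene_id, gene.sequence, scheme)
        if hit is None:
            raise ValueError(
                f"contig {contig_id} has no hit to {gene.gene_id}; "
                "homology assignment must precede anchoring"
            )
        offset = hit.s_start - hit.q_start
        rows.append(AlignedRow(contig_id, sample, offset, seq))
    return AnchoredAlignment(
        gene_id=gene.gene_id,
        kmer=kmer,
        ref_length=len(gene.sequence),
        cds_start=gene.cds_start,
        cds_end=gene.cds_end,
        rows=tuple(rows),
    )


def build_consensus(aln: AnchoredAlignment) -> ConsensusRecord:
    """Collapse an anchored alignment into an IUPAC consensus.

    Columns with one distinct base take that base; columns with >= 2 distinct
    bases take the IUPAC code for exactly the observed set; uncovered columns
    become 'n'.  The ambiguity fraction excludes n positions from its
    denominator.
    """
    if not aln.rows:
        raise ValueError("cannot build consensus from zero contigs")
    fs, fe = aln.frame_start, aln.frame_end
    width = fe - fs
    columns: list[set[str]] = [set() for _ in range(width)]
    for row in aln.rows:
        for i, base in enumerate(row.sequence):
            if base in "ACGT":
                columns[row.start - fs + i].add(base)
    chars = []
    n_ambig = 0
    n_covered = 0
    for col in columns:
        if not col:
            chars.append("n")
            continue
        n_covered += 1
        code = IUPAC_CODE[frozenset(col)]
        if code in AMBIGUITY_CODES:
            n_ambig += 1
        chars.append(code)
    seq = "".join(chars)
    cds_lo, cds_hi = aln.cds_start - fs, aln.cds_end - fs
    cds_non_n = sum(1 for c in seq[cds_lo:cds_hi] if c != "n")
    utr5 = sum(1 for c in seq[:cds_lo] if c != "n")
    utr3 = sum(1 for c in seq[cds_hi:] if c != "n")
    return ConsensusRecord(
        gene_id=aln.gene_id,
        kmer=aln.kmer,
        sequence=seq,
        frame_start=fs,
        cds_start=aln.cds_start,
        cds_end=aln.cds_end,
        ambiguity_fraction=(n_ambig / n_covered) if n_covered else 0.0,
        assembled_length=n_covered,
        cds_coverage_fraction=cds_non_n / (aln.cds_end - aln.cds_start),
        utr5_extra_bp=utr5,
        utr3_extra_bp=utr3,
    )


def select_kmer(
    records: Sequence[ConsensusRecord],
    ambiguity_threshold: float = DEFAULT_AMBIGUITY_THRESHOLD,
) -> ConsensusRecord | None:
    """Pick the longest assembly among kmers passing the ambiguity QC.

    Ties in assembled length go to the smaller kmer.  Returns None when no
    kmer passes (the gene goes to QC triage).
    """
    if not records:
        raise ValueError("no consensus records to select from")
    passing = [r for r in records if r.ambiguity_fraction < ambiguity_threshold]
    if not passing:
        return None
    return max(passing, key=lambda r: (r.assembled_length, -r.kmer))


# ---------------------------------------------------------------------------
# QC triage for high-ambiguity alignments
# ---------------------------------------------------------------------------


def _pair_identity(a: AlignedRow, b: AlignedRow, lo: int, hi: int) -> float | None:
    """Identity of two rows over their shared columns within [lo, hi)."""
    start = max(a.start, b.start, lo)
    end = min(a.end, b.end, hi)
    if end <= start:
        return None
    same = sum(
        1
        for p in range(start, end)
        if a.sequence[p - a.start] == b.sequence[p - b.start]
    )
    return same / (end - start)


def _row_ref_identity(row: AlignedRow, ref: str, lo: int, hi: int) -> float | None:
    start = max(row.start, lo, 0)
    end = min(row.end, hi, len(ref))
    if end <= start:
        return None
    same = sum(
        1 for p in range(start, end) if row.sequence[p - row.start] == ref[p]
    )
    return same / (end - start)


def triage_high_ambiguity(
    aln: AnchoredAlignment,
    record: ConsensusRecord,
    gene: ReferenceGene,
    ambiguity_threshold: float = DEFAULT_AMBIGUITY_THRESHOLD,
    scheme: ScoringScheme | None = None,
) -> tuple[QCOutcome, ConsensusRecord | None]:
    """Repair or classify a consensus that failed the ambiguity QC.

    In order: (a) re-anchor misplaced contigs and rebuild; (b) detect the
    conserved-CDS / divergent-UTR paralog pattern (contigs kept, gene
    labelled); (c) remove contigs whose CDS identity to the reference trails
    the best contig's by more than 5 points and rebuild.  A gene whose
    ambiguity cannot be brought under the threshold is dropped.
    """
    if record.ambiguity_fraction < ambiguity_threshold:
        return QCOutcome(aln.gene_id, "clean"), record
    if scheme is None:
        scheme = ScoringScheme.create(db_len=len(gene.sequence))

    # (a) re-anchor every contig from scratch
    contigs = [(r.contig_id, r.sample, r.sequence) for r in aln.rows]
    realigned = anchor_contigs(gene, contigs, aln.kmer, hits=None, scheme=scheme)
    if any(r.start != s.start for r, s in zip(realigned.rows, aln.rows)):
        rebuilt = build_consensus(realigned)
        if rebuilt.ambiguity_fraction < ambiguity_threshold:
            return QCOutcome(aln.gene_id, "misalignment"), rebuilt
        aln = realigned  # continue triage from the corrected placement

    # (b) conserved-CDS, divergent-UTR paralog pattern
    cds_lo, cds_hi = aln.cds_start, aln.cds_end
    rows = aln.rows
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            cds_id = _pair_identity(rows[i], rows[j], cds_lo, cds_hi)
            utr_id_5 = _pair_identity(rows[i], rows[j], aln.frame_start, cds_lo)
            utr_id_3 = _pair_identity(rows[i], rows[j], cds_hi, aln.frame_end)
            utr_ids = [u for u in (utr_id_5, utr_id_3) if u is not None]
            if cds_id is not None and cds_id >= 0.98 and utr_ids and min(utr_ids) < 0.90:
                return QCOutcome(aln.gene_id, "utr_divergent_paralog"), build_consensus(aln)

    # (c) drop contigs clearly more divergent from the reference than the best
    idents = {
        r.contig_id: _row_ref_identity(r, gene.sequence, cds_lo, cds_hi)
        for r in aln.rows
    }
    known = [v for v in idents.values() if v is not None]
    if known:
        best_ident = max(known)
        removed = tuple(
            cid for cid, v in idents.items() if v is not None and best_ident - v > 0.05
        )
        keep = tuple(r for r in aln.rows if r.contig_id not in removed)
        if removed and keep:
            slim = AnchoredAlignment(
                aln.gene_id, aln.kmer, aln.ref_length, aln.cds_start, aln.cds_end, keep
            )
            rebuilt = build_consensus(slim)
            if rebuilt.ambiguity_fraction < ambiguity_threshold:
                return QCOutcome(aln.gene_id, "divergent_contig_removed", removed), rebuilt

    # unresolvable: gene dropped
    all_ids = tuple(r.contig_id for r in aln.rows)
    return QCOutcome(aln.gene_id, "misalignment", all_ids), None


def coverage_stats(record: ConsensusRecord) -> tuple[float, int, int]:
    """(percent CDS coverage to one decimal, extra 5' bp, extra 3' bp)."""
    pct = round_half_up(100.0 * record.cds_coverage_fraction, 1)
    return pct, record.utr5_extra_bp, record.utr3_extra_bp


def append_external_sequence(
    transcriptome: dict[str, str], gene_id: str, sequence: str
) -> dict[str, str]:
    """Append an externally characterized sequence to the mapping reference."""
    if gene_id in transcriptome:
        raise ValueError(f"duplicate gene id {gene_id}")
    transcriptome[gene_id] = sequence
    return transcriptome


def consensus_table(records: Sequence[ConsensusRecord]):
    """Per-gene stats table mirroring the assembly-report layout."""
    import pandas as pd

    rows = []
    for r in records:
        pct, u5, u3 = coverage_stats(r)
        rows.append(
            (r.gene_id, r.kmer, r.cds_end - r.cds_start, r.assembled_length,
             pct, u5, u3, round(r.ambiguity_fraction, 5))
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "kmer", "cds_length", "assembled_length",
                 "pct_cds_coverage", "utr5_extra_bp", "utr3_extra_bp",
                 "ambiguity_fraction"],
    )
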