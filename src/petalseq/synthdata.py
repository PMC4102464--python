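"""Synthetic data generation for pipeline testing.

Produces reference gene sets, a diverged two-haplotype focal transcriptome
with ground-truth expression and fold changes, simulated 3'-biased single-end
reads, multi-kmer contig sets emulating a de Bruijn assembler's output, and
flat GO annotation tables.  Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import write_fasta, write_fastq

BASES = np.array(list("ACGT"))
SAMPLES = ("pop1_p", "pop1_w", "pop2_p", "pop2_w")
POPULATIONS = ("pop1", "pop2")
MORPHS = ("purple", "white")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceGene:
    """A reference-species transcript with CDS/UTR structure.

    Coordinates are 0-based half-open offsets into ``sequence``; the strand is
    always '+' (transcript orientation).
    """

    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(f"invalid CDS bounds for {self.gene_id}")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"non-ACGT characters in {self.gene_id}")

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]


@dataclass(frozen=True)
class FocalGene:
    """A focal-species transcript: two haplotypes sharing the reference frame."""

    gene_id: str
    source_ref: str
    haplotypes: tuple[str, str]
    cds_start: int
    cds_end: int

    @property
    def length(self) -> int:
        return len(self.haplotypes[0])


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    sample: str
    kmer: int
    source_genes: tuple[str, ...]


@dataclass
class GroundTruth:
    """True expression levels, fold changes, and structural annotations."""

    expression: dict[str, dict[str, float]]
    fold_change: dict[str, dict[str, float]]
    labels: dict[str, str]
    divergence: dict[str, float]
    paralog_map: dict[str, list[str]]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for gene, fcs in self.fold_change.items():
            if any(fc <= 0 for fc in fcs.values()):
                raise ValueError(f"non-positive fold change for {gene}")
            label = self.labels[gene]
            if label == "P>W" and not all(fc > 1 for fc in fcs.values()):
                raise ValueError(f"label P>W inconsistent with folds for {gene}")
            if label == "W>P" and not all(fc < 1 for fc in fcs.values()):
                raise ValueError(f"label W>P inconsistent with folds for {gene}")
        for gene, d in self.divergence.items():
            if not 0 <= d < 1:
                raise ValueError(f"divergence out of range for {gene}")

    def true_rpkm(self, gene: str, sample: str) -> float:
        """Expected RPKM implied by the true levels and transcript lengths."""
        total = sum(
            self.expression[g][sample] * self.lengths[g] for g in self.expression
        )
        return 1e9 * self.expression[gene][sample] / total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.expression:
            row = {"gene_id": gene, "label": self.labels[gene]}
            row.update({s: self.expression[gene][s] for s in SAMPLES})
            row.update(
                {f"fold_{p}": self.fold_change[gene][p] for p in POPULATIONS}
            )
            rows.append(row)
        return pd.DataFrame(rows).set_index("gene_id")


@dataclass(frozen=True)
class SimParams:
    """Knobs for the whole synthetic scenario; one seed drives everything."""

    n_genes: int = 100
    read_length: int = 40
    reads_per_sample: int = 100_000
    error_rate: float = 0.005
    bias3p_strength: float = 0.0
    intraspecific_variation: float = 0.019
    coding_divergence: float = 0.11
    utr_divergence_paralog: float = 0.30
    kmer_list: tuple[int, ...] = (19, 21, 23, 25, 27, 29)
    paralog_fraction: float = 0.0
    n_de_purple: int = 0
    n_de_white: int = 0
    de_fold: float = 3.0
    de_folds_purple: tuple[float, ...] | None = None
    mean_contigs_per_gene: float = 1.475
    chimera_rate: float = 0.0
    expression_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.read_length < 14 + 2:
            raise ValueError("read_length must cover hash length plus mismatches")
        for p in ("error_rate", "intraspecific_variation", "coding_divergence",
                  "utr_divergence_paralog"):
            v = getattr(self, p)
            if not 0 <= v < 1:
                raise ValueError(f"{p} must be in [0, 1)")
        for k in self.kmer_list:
            if k % 2 == 0:
                raise ValueError(f"kmer {k} must be odd")
            if k > self.read_length - 10:
                raise ValueError(
                    f"kmer {k} exceeds read_length - 10 = {self.read_length - 10}"
                )


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------


def _draw_lengths(rng: np.random.Generator, n: int, length_distribution) -> np.ndarray:
    if isinstance(length_distribution, int):
        lengths = np.full(n, length_distribution)
    elif callable(length_distribution):
        lengths = np.asarray(length_distribution(rng, n), dtype=int)
    else:
        kind, *args = length_distribution
        if kind != "lognormal":
            raise ValueError(f"unknown length distribution {kind!r}")
        median, sigma = args
        lengths = rng.lognormal(math.log(median), sigma, size=n).astype(int)
    return np.maximum(lengths, 150)


def generate_reference(
    n_genes: int, length_distribution=("lognormal", 676, 0.45), seed: int = 0
) -> list[ReferenceGene]:
    """Generate a reference gene set with UTR-flanked CDS regions.

    ``length_distribution`` may be a fixed int, a ``("lognormal", median,
    sigma)`` tuple, or a callable ``(rng, n) -> lengths``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = _draw_lengths(rng, n_genes, length_distribution)
    width = len(str(n_genes))
    genes = []
    for i, length in enumerate(lengths):
        seq = "".join(rng.choice(BASES, size=length))
        # UTRs take 8-15% of the transcript on each side
        utr5 = int(length * rng.uniform(0.08, 0.15))
        utr3 = int(length * rng.uniform(0.08, 0.15))
        genes.append(
            ReferenceGene(
                gene_id=f"RG{i + 1:0{width}d}",
                sequence=seq,
                cds_start=utr5,
                cds_end=length - utr3,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Focal transcriptome with ground truth
# ---------------------------------------------------------------------------


def _substitute(seq: str, rate: float, rng: np.random.Generator,
                region: tuple[int, int] | None = None) -> str:
    """Substitute each position in ``region`` (default: whole) w.p. ``rate``."""
    if rate <= 0:
        return seq
    lo, hi = region if region is not None else (0, len(seq))
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(hi - lo) < rate) + lo
    for pos in hits:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(3)]
    return "".join(arr)


def mutate_transcriptome(
    reference: Sequence[ReferenceGene], params: SimParams, seed: int | None = None
) -> tuple[list[FocalGene], GroundTruth]:
    """Derive a diverged focal transcriptome and its ground truth.

    Each reference gene yields one focal gene with two haplotypes; a
    ``paralog_fraction`` of genes additionally yield a paralog whose CDS stays
    >= 98% identical to the focal copy while the UTRs diverge at
    ``utr_divergence_paralog``.  Expression levels are lognormal with planted
    purple>white and white>purple fold changes applied in both populations.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    genes: list[FocalGene] = []
    divergence: dict[str, float] = {}
    paralog_map: dict[str, list[str]] = {}

    n_paralogs = int(round(params.paralog_fraction * len(reference)))
    paralog_idx = set(
        rng.choice(len(reference), size=n_paralogs, replace=False).tolist()
    )

    for i, ref in enumerate(reference):
        focal = _substitute(ref.sequence, params.coding_divergence, rng)
        diffs = sum(a != b for a, b in zip(focal, ref.sequence))
        divergence_i = diffs / len(ref.sequence)
        hap_rate = rng.uniform(0, params.intraspecific_variation)
        hap2 = _substitute(focal, hap_rate, rng)
        gene = FocalGene(ref.gene_id, ref.gene_id, (focal, hap2),
                         ref.cds_start, ref.cds_end)
        genes.append(gene)
        divergence[gene.gene_id] = divergence_i
        if i in paralog_idx:
            par = _substitute(focal, 0.01, rng, (ref.cds_start, ref.cds_end))
            par = _substitute(par, params.utr_divergence_paralog, rng,
                              (0, ref.cds_start))
            par = _substitute(par, params.utr_divergence_paralog, rng,
                              (ref.cds_end, len(ref.sequence)))
            par_id = f"{ref.gene_id}.p"
            par2 = _substitute(par, hap_rate, rng)
            genes.append(FocalGene(par_id, ref.gene_id, (par, par2),
                                   ref.cds_start, ref.cds_end))
            divergence[par_id] = divergence_i
            paralog_map[ref.gene_id] = [par_id]

    # expression levels and planted DE
    gene_ids = [g.gene_id for g in genes]
    base = rng.lognormal(math.log(30.0), params.expression_sigma, size=len(genes))
    non_paralogs = [gid for gid in gene_ids if not gid.endswith(".p")]
    n_pw, n_wp = params.n_de_purple, params.n_de_white
    de_pick = rng.choice(len(non_paralogs), size=n_pw + n_wp, replace=False)
    pw_genes = [non_paralogs[j] for j in de_pick[:n_pw]]
    wp_genes = [non_paralogs[j] for j in de_pick[n_pw:]]

    folds_pw = (list(params.de_folds_purple) if params.de_folds_purple
                else [params.de_fold] * n_pw)
    if len(folds_pw) < n_pw:
        folds_pw = (folds_pw * n_pw)[:n_pw]

    expression: dict[str, dict[str, float]] = {}
    fold_change: dict[str, dict[str, float]] = {}
    labels: dict[str, str] = {}
    for gid, lvl in zip(gene_ids, base):
        fold = {p: 1.0 for p in POPULATIONS}
        label = "null"
        if gid in pw_genes:
            f = folds_pw[pw_genes.index(gid)]
            fold = {p: f for p in POPULATIONS}
            label = "P>W"
        elif gid in wp_genes:
            fold = {p: 1.0 / params.de_fold for p in POPULATIONS}
            label = "W>P"
        expr = {}
        for pop in POPULATIONS:
            f = fold[pop]
            expr[f"{pop}_p"] = lvl * math.sqrt(f)
            expr[f"{pop}_w"] = lvl / math.sqrt(f)
        expression[gid] = expr
        fold_change[gid] = fold
        labels[gid] = label

    truth = GroundTruth(
        expression=expression,
        fold_change=fold_change,
        labels=labels,
        divergence=divergence,
        paralog_map=paralog_map,
        lengths={g.gene_id: g.length for g in genes},
    )
    return genes, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _position_probs(n_starts: int, bias: float) -> np.ndarray:
    if bias <= 0:
        return np.full(n_starts, 1.0 / n_starts)
    x = np.arange(n_starts) / max(n_starts - 1, 1)
    w = np.exp(bias * x)  # exponential weighting toward the 3' end
    return w / w.sum()


def simulate_reads(
    transcriptome: Sequence[FocalGene],
    truth: GroundTruth,
    sample_id: str,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str, str]]:
    """Simulate single-end reads for one sample as (id, seq, qual) tuples.

    Expected per-gene read share is proportional to true level x transcript
    length; start positions are exponentially weighted toward the 3' end when
    ``bias3p_strength`` > 0; per-base substitution errors at ``error_rate``.
    Quality strings are constant (unfiltered input emulation).
    """
    if not transcriptome:
        raise ValueError("empty transcriptome")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rl = params.read_length
    eligible = [g for g in transcriptome if g.length >= rl]
    weights = np.array(
        [truth.expression[g.gene_id][sample_id] * g.length for g in eligible]
    )
    if weights.sum() <= 0:
        raise ValueError(f"no expressed genes in sample {sample_id}")
    counts = rng.multinomial(params.reads_per_sample, weights / weights.sum())
    qual = "I" * rl
    reads: list[tuple[str, str, str]] = []
    serial = 0
    for gene, n in zip(eligible, counts):
        if n == 0:
            continue
        n_starts = gene.length - rl + 1
        starts = rng.choice(n_starts, size=n,
                            p=_position_probs(n_starts, params.bias3p_strength))
        haps = rng.integers(2, size=n)
        n_err = rng.binomial(rl, params.error_rate, size=n)
        for s, h, ne in zip(starts, haps, n_err):
            seq = gene.haplotypes[h][s : s + rl]
            if ne:
                arr = list(seq)
                for pos in rng.choice(rl, size=ne, replace=False):
                    choices = [b for b in "ACGT" if b != arr[pos]]
                    arr[pos] = choices[rng.integers(3)]
                seq = "".join(arr)
            reads.append(
                (f"{sample_id}:{gene.gene_id}:{h}:{s}:{serial}", seq, qual)
            )
            serial += 1
    return reads


# ---------------------------------------------------------------------------
# Contig simulation (emulates multi-kmer de Bruijn assembly output)
# ---------------------------------------------------------------------------


def simulate_contigs(
    transcriptome: Sequence[FocalGene],
    kmer_list: Sequence[int],
    params: SimParams,
    truth: GroundTruth | None = None,
    samples: Sequence[str] = MORPHS,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, int], list[Contig]]:
    """Simulate per-sample per-kmer contig sets.

    Each expressed gene yields 1-11 contigs per kmer (Poisson around
    ``mean_contigs_per_gene``); smaller kmers give longer expected contigs.
    With ``chimera_rate`` > 0 a fraction of contigs concatenate fragments of
    two genes.
    """
    if not kmer_list:
        raise ValueError("kmer_list must be non-empty")
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    kmin = min(kmer_list)
    out: dict[tuple[str, int], list[Contig]] = {}
    for sample in samples:
        # a morph's assembly uses pop1 reads; genes with zero pop1 expression
        # in that morph produce no contigs
        sample_key = "pop1_p" if sample == "purple" else "pop1_w"
        for k in kmer_list:
            contigs: list[Contig] = []
            frac_mu = max(0.3, 0.9 - 0.04 * (k - kmin))
            for gene in transcriptome:
                if truth is not None and truth.expression[gene.gene_id][sample_key] <= 0:
                    continue
                n = min(11, 1 + rng.poisson(max(params.mean_contigs_per_gene - 1, 0)))
                for j in range(n):
                    frac = float(np.clip(rng.normal(frac_mu, 0.12), 0.2, 1.0))
                    clen = max(min(int(frac * gene.length), gene.length),
                               min(2 * k + 20, gene.length))
                    start = rng.integers(gene.length - clen + 1)
                    hap = rng.integers(2)
                    seq = gene.haplotypes[hap][start : start + clen]
                    sources = (gene.gene_id,)
                    if params.chimera_rate > 0 and rng.random() < params.chimera_rate:
                        other = transcriptome[rng.integers(len(transcriptome))]
                        half = clen // 2
                        tail_len = min(half, other.length)
                        tail_start = rng.integers(other.length - tail_len + 1)
                        seq = seq[: clen - half] + other.haplotypes[0][
                            tail_start : tail_start + tail_len
                        ]
                        sources = (gene.gene_id, other.gene_id)
                    cid = f"{sample}_k{k}_{gene.gene_id}_{j}"
                    contigs.append(Contig(cid, seq, sample, k, sources))
            out[(sample, k)] = contigs
    return out


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichedTermSpec:
    term_id: str
    background_freq: float
    de_freq: float


def generate_go_annotations(
    gene_ids: Sequence[str],
    n_terms: int,
    enriched_term_spec: Sequence[EnrichedTermSpec] = (),
    seed: int = 0,
    de_genes: Iterable[str] = (),
) -> pd.DataFrame:
    """Generate a flat gene->term annotation table (columns gene_id, term_id).

    Background term frequencies are drawn uniformly in [0.02, 0.10]; terms in
    ``enriched_term_spec`` use their configured background frequency, elevated
    to ``de_freq`` for genes in ``de_genes``.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    de = set(de_genes)
    spec_by_term = {s.term_id: s for s in enriched_term_spec}
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    for s in enriched_term_spec:
        if s.term_id not in term_ids:
            term_ids.append(s.term_id)
    bg_freq = {t: rng.uniform(0.02, 0.10) for t in term_ids}
    rows = []
    for gene in gene_ids:
        for term in term_ids:
            spec = spec_by_term.get(term)
            if spec is None:
                p = bg_freq[term]
            else:
                p = spec.de_freq if gene in de else spec.background_freq
            if rng.random() < p:
                rows.append((gene, term))
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


# ---------------------------------------------------------------------------
# File export
# ---------------------------------------------------------------------------


def write_reference_fasta(genes: Sequence[ReferenceGene], path) -> None:
    write_fasta(((g.gene_id, g.sequence) for g in genes), path)


def write_reference_table(genes: Sequence[ReferenceGene], path) -> None:
    pd.DataFrame(
        [(g.gene_id, len(g.sequence), g.cds_start, g.cds_end, g.strand)
         for g in genes],
        columns=["gene_id", "length", "cds_start", "cds_end", "strand"],
    ).to_csv(path, sep="\t", index=False)


def write_transcriptome_fasta(genes: Sequence[FocalGene], path) -> None:
    records = []
    for g in genes:
        for h, seq in enumerate(g.haplotypes):
            records.append((f"{g.gene_id}|hap{h}", seq))
    write_fasta(records, path)


def write_contigs_fasta(contigs: Sequence[Contig], path) -> None:
    write_fasta(((c.contig_id, c.sequence) for c in contigs), path)


def write_reads_fastq(reads: Sequence[tuple[str, str, str]], path) -> None:
    write_fastq(reads, path)


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t")
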