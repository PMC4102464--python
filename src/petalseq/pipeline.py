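"""End-to-end orchestration: simulate -> assign -> consensus -> map ->
express -> classify -> enrich -> validate.

All randomness flows from the single config seed; rerunning with the same
config and seed produces byte-identical outputs.  Stage functions are pure
given (config, upstream results) so the CLI can rerun any prefix
deterministically.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import consensus as cns
from . import enrichment as enr
from . import expression as expr
from . import homology as hom
from . import mapper as mp
from . import synthdata as sd
from . import validation as val

STAGES = (
    "simulate", "assign", "consensus", "map", "express", "classify",
    "enrich", "validate",
)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, mirrored one-to-one by the config file."""

    seed: int = 0
    outdir: str | None = None
    # synthetic scenario
    n_genes: int = 60
    read_length: int = 40
    reads_per_sample: int = 40_000
    error_rate: float = 0.005
    bias3p_strength: float = 0.0
    intraspecific_variation: float = 0.019
    coding_divergence: float = 0.11
    utr_divergence_paralog: float = 0.30
    paralog_fraction: float = 0.0
    n_de_purple: int = 3
    n_de_white: int = 6
    de_fold: float = 3.5
    de_folds_purple: list[float] | None = None
    mean_contigs_per_gene: float = 1.475
    chimera_rate: float = 0.0
    expression_sigma: float = 1.0
    kmer_list: list[int] = field(default_factory=lambda: [19, 21])
    # thresholds
    evalue_threshold: float = 1e-10
    ambiguity_threshold: float = 0.019
    hash_length: int = 14
    max_mismatch: int = 2
    min_reads: int = 10
    rd_cutoff: float = 0.5
    consistency_cutoff: float = 0.25
    top_fraction: float = 0.02
    fdr_significant: float = 0.01
    fdr_marginal: float = 0.05
    word_size: int = 11
    n_go_terms: int = 30
    n_qpcr_genes: int = 8
    outlier_genes: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data.pop("outdir", None)  # path-independent so reruns are comparable
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def digest(self) -> str:
        data = asdict(self)
        data.pop("outdir", None)
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sim_params(self) -> sd.SimParams:
        return sd.SimParams(
            n_genes=self.n_genes,
            read_length=self.read_length,
            reads_per_sample=self.reads_per_sample,
            error_rate=self.error_rate,
            bias3p_strength=self.bias3p_strength,
            intraspecific_variation=self.intraspecific_variation,
            coding_divergence=self.coding_divergence,
            utr_divergence_paralog=self.utr_divergence_paralog,
            kmer_list=tuple(self.kmer_list),
            paralog_fraction=self.paralog_fraction,
            n_de_purple=self.n_de_purple,
            n_de_white=self.n_de_white,
            de_fold=self.de_fold,
            de_folds_purple=tuple(self.de_folds_purple) if self.de_folds_purple else None,
            mean_contigs_per_gene=self.mean_contigs_per_gene,
            chimera_rate=self.chimera_rate,
            expression_sigma=self.expression_sigma,
            seed=self.seed,
        )


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of violated invariants (empty means the config is OK)."""
    errors = []
    max_kmer = config.read_length - 10
    for k in config.kmer_list:
        if k > max_kmer:
            errors.append(f"kmer {k} exceeds read_length - 10 = {max_kmer}")
        if k % 2 == 0:
            errors.append(f"kmer {k} must be odd")
    if not config.kmer_list:
        errors.append("kmer_list must be non-empty")
    for name in ("evalue_threshold", "ambiguity_threshold", "rd_cutoff",
                 "consistency_cutoff", "top_fraction", "fdr_significant",
                 "fdr_marginal"):
        if getattr(config, name) <= 0:
            errors.append(f"{name} must be positive")
    if not 0 < config.top_fraction < 1:
        errors.append("top_fraction must be in (0, 1)")
    if config.min_reads < 1:
        errors.append("min_reads must be >= 1")
    if config.hash_length < 8:
        errors.append("hash_length must be >= 8")
    if config.hash_length + config.max_mismatch > config.read_length:
        errors.append("read_length must cover hash_length + max_mismatch")
    if config.word_size < 8:
        errors.append("word_size must be >= 8")
    if config.n_genes < 1 or config.reads_per_sample < 1:
        errors.append("n_genes and reads_per_sample must be positive")
    return errors


@dataclass
class PipelineResult:
    config: PipelineConfig
    reference: list[sd.ReferenceGene] = field(default_factory=list)
    transcriptome: list[sd.FocalGene] = field(default_factory=list)
    truth: sd.GroundTruth | None = None
    contigs: dict[tuple[str, int], list[sd.Contig]] = field(default_factory=dict)
    reads: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    annotations: pd.DataFrame | None = None
    qpcr_records: list[val.QPCRRecord] = field(default_factory=list)
    assignments: dict[tuple[str, int], dict[str, list[str]]] = field(default_factory=dict)
    forward_hits: dict[tuple[str, int], dict[str, hom.PairwiseHit]] = field(default_factory=dict)
    consensus_records: dict[str, cns.ConsensusRecord] = field(default_factory=dict)
    qc_outcomes: list[cns.QCOutcome] = field(default_factory=list)
    summaries: dict[str, mp.MappingSummary] = field(default_factory=dict)
    counts: pd.DataFrame | None = None
    rpkm: pd.DataFrame | None = None
    retained: pd.Index | None = None
    differential: pd.DataFrame | None = None
    study_sets: dict[str, enr.StudySet] = field(default_factory=dict)
    enrichment: pd.DataFrame | None = None
    qpcr_regression: val.RegressionResult | None = None
    manifest: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(res: PipelineResult) -> None:
    cfg = res.config
    params = cfg.sim_params()
    res.reference = sd.generate_reference(cfg.n_genes, seed=cfg.seed)
    res.transcriptome, res.truth = sd.mutate_transcriptome(res.reference, params)
    rng = np.random.default_rng(cfg.seed + 10)
    res.contigs = sd.simulate_contigs(
        res.transcriptome, cfg.kmer_list, params, truth=res.truth, rng=rng
    )
    for i, sample in enumerate(sd.SAMPLES):
        res.reads[sample] = sd.simulate_reads(
            res.transcriptome, res.truth, sample, params,
            rng=np.random.default_rng(cfg.seed + 100 + i),
        )
    de_genes = [g for g, lab in res.truth.labels.items() if lab != "null"]
    res.annotations = sd.generate_go_annotations(
        sorted(res.truth.labels),
        cfg.n_go_terms,
        enriched_term_spec=(
            sd.EnrichedTermSpec("GO:9000001", 0.05, 0.40),
        ),
        seed=cfg.seed + 200,
        de_genes=de_genes,
    )
    res.qpcr_records = _simulate_qpcr(res, seed=cfg.seed + 300)


def _simulate_qpcr(res: PipelineResult, seed: int) -> list[val.QPCRRecord]:
    """Synthesize CT tables whose linearized values track true expression."""
    cfg = res.config
    rng = np.random.default_rng(seed)
    truth = res.truth
    genes = sorted(
        truth.expression,
        key=lambda g: -np.mean([truth.expression[g][s] for s in sd.SAMPLES]),
    )[: cfg.n_qpcr_genes]
    records = []
    for gene in genes:
        eff = float(rng.uniform(0.926, 1.0))
        for sample in sd.SAMPLES:
            level = truth.expression[gene][sample]
            ct_control = 20.0
            dct = math.log(level) / math.log(1.0 + eff)
            ct_target = ct_control - dct + float(rng.normal(0, 0.1))
            records.append(
                val.QPCRRecord(sample, gene, max(ct_target, 1.0), ct_control, eff)
            )
    return records


def stage_assign(res: PipelineResult) -> None:
    cfg = res.config
    refs = {g.gene_id: g.sequence for g in res.reference}
    scheme = hom.ScoringScheme.create(db_len=sum(len(s) for s in refs.values()))
    for key, contigs in res.contigs.items():
        queries = {c.contig_id: c.sequence for c in contigs}
        fwd = hom.best_hits(queries, refs, scheme, cfg.word_size)
        rev_scheme = hom.ScoringScheme(
            scheme.match, scheme.mismatch, scheme.lam, scheme.K,
            sum(len(s) for s in queries.values()),
        )
        rev = hom.best_hits(refs, queries, rev_scheme, cfg.word_size)
        res.forward_hits[key] = fwd
        res.assignments[key] = hom.reciprocal_best_hit_filter(
            fwd, rev, cfg.evalue_threshold
        )


def stage_consensus(res: PipelineResult) -> None:
    cfg = res.config
    ref_by_id = {g.gene_id: g for g in res.reference}
    contig_by_id = {
        c.contig_id: c for contigs in res.contigs.values() for c in contigs
    }
    per_gene_kmer: dict[str, dict[int, list[tuple[str, str, str]]]] = {}
    hits_by_contig: dict[str, hom.PairwiseHit] = {}
    for (sample, k), assignment in res.assignments.items():
        for gene, contig_ids in assignment.items():
            for cid in contig_ids:
                per_gene_kmer.setdefault(gene, {}).setdefault(k, []).append(
                    (cid, sample, contig_by_id[cid].sequence)
                )
                hits_by_contig[cid] = res.forward_hits[(sample, k)][cid]
    for gene_id in sorted(per_gene_kmer):
        gene = ref_by_id[gene_id]
        records, alns = [], {}
        for k in sorted(per_gene_kmer[gene_id]):
            aln = cns.anchor_contigs(
                gene, per_gene_kmer[gene_id][k], k, hits=hits_by_contig
            )
            rec = cns.build_consensus(aln)
            records.append(rec)
            alns[k] = aln
        chosen = cns.select_kmer(records, cfg.ambiguity_threshold)
        if chosen is None:
            # all kmers failed QC: triage the longest assembly
            worst = max(records, key=lambda r: r.assembled_length)
            outcome, repaired = cns.triage_high_ambiguity(
                alns[worst.kmer], worst, gene, cfg.ambiguity_threshold
            )
            res.qc_outcomes.append(outcome)
            if repaired is None:
                continue
            chosen = repaired
        else:
            res.qc_outcomes.append(cns.QCOutcome(gene_id, "clean"))
        res.consensus_records[gene_id] = chosen


def stage_map(res: PipelineResult) -> None:
    cfg = res.config
    references = {g: r.sequence for g, r in res.consensus_records.items()}
    index = mp.HashIndex(references, cfg.hash_length)
    for sample in sd.SAMPLES:
        reads = ((rid, seq) for rid, seq, _ in res.reads[sample])
        res.summaries[sample] = mp.map_reads(
            reads, index, cfg.max_mismatch, sample=sample
        )


def stage_express(res: PipelineResult) -> None:
    cfg = res.config
    genes = sorted(res.consensus_records)
    counts = pd.DataFrame(
        {
            sample: [res.summaries[sample].per_gene_unique.get(g, 0) for g in genes]
            for sample in sd.SAMPLES
        },
        index=pd.Index(genes, name="gene_id"),
    )
    lengths = {g: res.consensus_records[g].assembled_length for g in genes}
    res.counts = counts
    res.rpkm = expr.rpkm_matrix(counts, lengths)
    res.retained = expr.low_count_filter(counts, cfg.min_reads)


def stage_classify(res: PipelineResult) -> None:
    cfg = res.config
    thr = expr.Thresholds(cfg.rd_cutoff, cfg.consistency_cutoff, cfg.min_reads)
    res.differential = expr.classify_differential(
        res.rpkm.loc[res.retained], thr
    )


def stage_enrich(res: PipelineResult) -> None:
    cfg = res.config
    frames = []
    study_sets = []
    for direction in ("P>W", "W>P"):
        try:
            s = enr.select_top_fraction(
                res.differential, direction, cfg.top_fraction, cfg.consistency_cutoff
            )
        except ValueError:
            continue
        res.study_sets[direction] = s
        study_sets.append(s)
    null_set = enr.build_null_set(res.retained, study_sets)
    for s in study_sets:
        frames.append(enr.run_enrichment(s, null_set, res.annotations))
    res.enrichment = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    )


def stage_validate(res: PipelineResult) -> None:
    cfg = res.config
    if not res.qpcr_records:
        return
    rel = val.ddct_standardize(res.qpcr_records, calibrator="pop1_p")
    eff = {r.gene: r.efficiency for r in res.qpcr_records}
    xs, ys, labels = [], [], []
    for r in res.qpcr_records:
        if r.gene not in res.rpkm.index:
            continue
        linear = val.linearize_qpcr(r.ct_control - r.ct_target, eff[r.gene])
        rpkm_v = res.rpkm.at[r.gene, r.sample_id]
        if rpkm_v > 0 and linear > 0:
            xs.append(linear)
            ys.append(rpkm_v)
            labels.append(r.gene)
    if len(xs) >= 3:
        res.qpcr_regression = val.regress_loglog(
            xs, ys, labels, exclusions=cfg.outlier_genes
        )
    res.manifest["qpcr_relative_expression_n"] = len(rel)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "assign": stage_assign,
    "consensus": stage_consensus,
    "map": stage_map,
    "express": stage_express,
    "classify": stage_classify,
    "enrich": stage_enrich,
    "validate": stage_validate,
}


def run_pipeline(
    config: PipelineConfig, through: str = "validate", log=None
) -> PipelineResult:
    """Run stages in order up to ``through``; write outputs if outdir is set."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    res = PipelineResult(config=config)
    res.manifest = {
        "version": __version__,
        "config_digest": config.digest(),
        "stages": {},
    }
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](res)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - t0
        res.manifest["stages"][stage] = {
            "seconds": round(elapsed, 3),
            **_stage_counts(stage, res),
        }
        if log is not None:
            log(f"[{stage}] done in {elapsed:.2f}s")
        if stage == through:
            break
    if config.outdir:
        write_outputs(res, Path(config.outdir))
    return res


def _stage_counts(stage: str, res: PipelineResult) -> dict[str, int]:
    if stage == "simulate":
        return {
            "n_reference_genes": len(res.reference),
            "n_focal_genes": len(res.transcriptome),
            "n_contigs": sum(len(v) for v in res.contigs.values()),
            "n_reads": sum(len(v) for v in res.reads.values()),
        }
    if stage == "assign":
        return {
            "n_assigned_contigs": sum(
                len(cs) for a in res.assignments.values() for cs in a.values()
            )
        }
    if stage == "consensus":
        return {"n_consensus_genes": len(res.consensus_records)}
    if stage == "map":
        return {
            "unique_mapped": sum(s.unique_mapped for s in res.summaries.values())
        }
    if stage == "express":
        return {"n_retained_genes": int(len(res.retained))}
    if stage == "classify":
        counts = res.differential["class"].value_counts().to_dict()
        return {f"class_{k}": int(v) for k, v in counts.items()}
    if stage == "enrich":
        n = 0 if res.enrichment is None else len(res.enrichment)
        return {"n_terms_tested": int(n)}
    return {}


def write_outputs(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = res.config
    sd.write_reference_fasta(res.reference, outdir / "reference.fasta")
    sd.write_reference_table(res.reference, outdir / "reference.tsv")
    sd.write_ground_truth(res.truth, outdir / "ground_truth.tsv")
    for (sample, k), contigs in res.contigs.items():
        sd.write_contigs_fasta(contigs, outdir / f"contigs_{sample}_k{k}.fasta")
    for sample, reads in res.reads.items():
        sd.write_reads_fastq(reads, outdir / f"reads_{sample}.fastq")
    res.annotations.to_csv(outdir / "go_annotations.tsv", sep="\t", index=False)
    if res.consensus_records:
        from ._util import write_fasta

        write_fasta(
            ((g, r.sequence) for g, r in sorted(res.consensus_records.items())),
            outdir / "consensus.fasta",
        )
        cns.consensus_table(
            [res.consensus_records[g] for g in sorted(res.consensus_records)]
        ).to_csv(outdir / "consensus_stats.tsv", sep="\t", index=False)
    if res.qc_outcomes:
        pd.DataFrame(
            [(q.gene_id, q.category, ",".join(q.contigs_removed))
             for q in res.qc_outcomes],
            columns=["gene_id", "category", "contigs_removed"],
        ).to_csv(outdir / "qc_log.tsv", sep="\t", index=False)
    if res.summaries:
        mp.summary_table(list(res.summaries.values())).to_csv(
            outdir / "mapping_summary.tsv", sep="\t", index=False
        )
    if res.counts is not None:
        expr.expression_table(res.counts, res.rpkm).to_csv(
            outdir / "expression.tsv", sep="\t", index=False
        )
    if res.differential is not None:
        res.differential.to_csv(outdir / "differential.tsv", sep="\t")
    if res.enrichment is not None and len(res.enrichment):
        res.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    if res.qpcr_regression is not None:
        reg = res.qpcr_regression
        pd.DataFrame(
            [(reg.slope, reg.intercept, reg.r2, reg.f_stat, reg.p, reg.n,
              ",".join(reg.excluded))],
            columns=["slope", "intercept", "r2", "f_stat", "p", "n", "excluded"],
        ).to_csv(outdir / "qpcr_regression.tsv", sep="\t", index=False)
    cfg.to_yaml(outdir / "config.yaml")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, sort_keys=True)
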