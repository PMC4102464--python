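import numpy as np
import pytest
from scipy import stats

from petalseq import synthdata as sd


class TestGenerateReference:
    def test_minimal_case(self):
        genes = sd.generate_reference(1, 300, seed=7)
        assert len(genes) == 1
        g = genes[0]
        assert len(g.sequence) == 300
        assert 0 <= g.cds_start < g.cds_end <= 300

    def test_median_length_near_676(self):
        genes = sd.generate_reference(500, ("lognormal", 676, 0.45), seed=1)
        median = np.median([len(g.sequence) for g in genes])
        assert abs(median - 676) < 80

    def test_deterministic(self):
        a = sd.generate_reference(10, 300, seed=5)
        b = sd.generate_reference(10, 300, seed=5)
        assert a == b

    def test_unique_ids_and_utr_flanks(self):
        genes = sd.generate_reference(50, 400, seed=2)
        ids = [g.gene_id for g in genes]
        assert len(set(ids)) == 50
        for g in genes:
            assert g.cds_start > 0 and g.cds_end < len(g.sequence)

    def test_nonpositive_n_genes(self):
        with pytest.raises(ValueError):
            sd.generate_reference(0, 300, seed=1)


class TestMutateTranscriptome:
    def test_zero_divergence_identity(self):
        ref = sd.generate_reference(5, 300, seed=1)
        params = sd.SimParams(
            n_genes=5, coding_divergence=0.0, intraspecific_variation=0.0, seed=1
        )
        genes, truth = sd.mutate_transcriptome(ref, params)
        for r, g in zip(ref, genes):
            assert g.haplotypes[0] == r.sequence
            assert g.haplotypes[1] == r.sequence

    def test_realized_divergence_near_target(self):
        ref = sd.generate_reference(60, 1000, seed=2)
        params = sd.SimParams(n_genes=60, coding_divergence=0.11, seed=2)
        genes, truth = sd.mutate_transcriptome(ref, params)
        ident = []
        for r, g in zip(ref, genes):
            same = sum(a == b for a, b in zip(r.sequence, g.haplotypes[0]))
            ident.append(same / len(r.sequence))
        assert abs(np.mean(ident) - 0.89) < 0.02

    def test_paralog_structure(self):
        ref = sd.generate_reference(30, 600, seed=3)
        params = sd.SimParams(
            n_genes=30, paralog_fraction=0.5, utr_divergence_paralog=0.30, seed=3
        )
        genes, truth = sd.mutate_transcriptome(ref, params)
        by_id = {g.gene_id: g for g in genes}
        assert truth.paralog_map
        for parent, pars in truth.paralog_map.items():
            p, q = by_id[parent], by_id[pars[0]]
            cds_same = sum(
                a == b
                for a, b in zip(
                    p.haplotypes[0][p.cds_start : p.cds_end],
                    q.haplotypes[0][q.cds_start : q.cds_end],
                )
            )
            assert cds_same / (p.cds_end - p.cds_start) >= 0.98
            utr = (
                p.haplotypes[0][: p.cds_start] + p.haplotypes[0][p.cds_end :],
                q.haplotypes[0][: q.cds_start] + q.haplotypes[0][q.cds_end :],
            )
            utr_same = sum(a == b for a, b in zip(*utr)) / len(utr[0])
            assert abs(utr_same - 0.70) < 0.10

    def test_haplotype_variation_bounded(self):
        ref = sd.generate_reference(40, 800, seed=4)
        params = sd.SimParams(n_genes=40, intraspecific_variation=0.019, seed=4)
        genes, _ = sd.mutate_transcriptome(ref, params)
        for g in genes:
            d = sum(a != b for a, b in zip(*g.haplotypes)) / g.length
            assert d <= 0.019 + 3 * np.sqrt(0.019 / g.length)

    def test_ground_truth_label_consistency_enforced(self):
        with pytest.raises(ValueError):
            sd.GroundTruth(
                expression={"g": {s: 1.0 for s in sd.SAMPLES}},
                fold_change={"g": {"pop1": 0.5, "pop2": 0.5}},
                labels={"g": "P>W"},
                divergence={"g": 0.1},
                paralog_map={},
                lengths={"g": 100},
            )


class TestSimulateReads:
    @pytest.fixture()
    def one_gene(self):
        ref = sd.generate_reference(1, 600, seed=9)
        params = sd.SimParams(
            n_genes=1, reads_per_sample=2000, coding_divergence=0.0,
            intraspecific_variation=0.0, error_rate=0.0, seed=9,
        )
        genes, truth = sd.mutate_transcriptome(ref, params)
        return genes, truth, params

    def test_exact_read_count(self, one_gene):
        genes, truth, params = one_gene
        reads = sd.simulate_reads(genes, truth, "pop1_p", params)
        assert len(reads) == params.reads_per_sample

    def test_uniform_starts_without_bias(self, one_gene):
        genes, truth, params = one_gene
        reads = sd.simulate_reads(genes, truth, "pop1_p", params)
        starts = np.array([int(r[0].split(":")[3]) for r in reads])
        n_starts = genes[0].length - params.read_length + 1
        counts, _ = np.histogram(starts, bins=10, range=(0, n_starts))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_read_share_proportional_to_level(self):
        ref = sd.generate_reference(2, 500, seed=10)
        params = sd.SimParams(
            n_genes=2, reads_per_sample=30_000, coding_divergence=0.0,
            intraspecific_variation=0.0, error_rate=0.0, seed=10,
        )
        genes, truth = sd.mutate_transcriptome(ref, params)
        g0, g1 = genes[0].gene_id, genes[1].gene_id
        for s in sd.SAMPLES:
            truth.expression[g0][s] = 2.0
            truth.expression[g1][s] = 1.0
        reads = sd.simulate_reads(genes, truth, "pop1_p", params)
        n0 = sum(1 for r in reads if r[0].split(":")[1] == g0)
        p_hat = n0 / len(reads)
        se = np.sqrt(2 / 3 * 1 / 3 / len(reads))
        assert abs(p_hat - 2 / 3) < 4 * se

    def test_3prime_bias_shifts_starts(self, one_gene):
        genes, truth, params = one_gene
        params_many = sd.SimParams(
            n_genes=1, reads_per_sample=20_000, coding_divergence=0.0,
            intraspecific_variation=0.0, error_rate=0.0, seed=9,
        )
        def mean_start(bias):
            p = sd.SimParams(
                n_genes=1, reads_per_sample=20_000, coding_divergence=0.0,
                intraspecific_variation=0.0, error_rate=0.0,
                bias3p_strength=bias, seed=9,
            )
            reads = sd.simulate_reads(genes, truth, "pop1_p", p)
            return np.mean([int(r[0].split(":")[3]) for r in reads])

        assert mean_start(2.0) > mean_start(0.0)

    def test_empty_transcriptome_error(self, one_gene):
        _, truth, params = one_gene
        with pytest.raises(ValueError):
            sd.simulate_reads([], truth, "pop1_p", params)

    def test_error_rate_applied(self):
        ref = sd.generate_reference(1, 500, seed=12)
        params = sd.SimParams(
            n_genes=1, reads_per_sample=5000, coding_divergence=0.0,
            intraspecific_variation=0.0, error_rate=0.02, seed=12,
        )
        genes, truth = sd.mutate_transcriptome(ref, params)
        reads = sd.simulate_reads(genes, truth, "pop1_p", params)
        hap = genes[0].haplotypes[0]
        mism = 0
        for rid, seq, _ in reads:
            pos = int(rid.split(":")[3])
            mism += sum(a != b for a, b in zip(seq, hap[pos : pos + 40]))
        rate = mism / (len(reads) * 40)
        assert abs(rate - 0.02) < 0.005


class TestSimulateContigs:
    @pytest.fixture()
    def transcriptome(self):
        ref = sd.generate_reference(200, 600, seed=20)
        params = sd.SimParams(n_genes=200, seed=20)
        genes, truth = sd.mutate_transcriptome(ref, params)
        return genes, truth, params

    def test_contigs_are_substrings(self):
        ref = sd.generate_reference(1, 600, seed=21)
        params = sd.SimParams(n_genes=1, seed=21)
        genes, _ = sd.mutate_transcriptome(ref, params)
        contigs = sd.simulate_contigs(genes, [19], params)
        for c in contigs[("purple", 19)]:
            assert any(c.sequence in h for h in genes[0].haplotypes)

    def test_mean_contigs_per_gene(self, transcriptome):
        genes, truth, params = transcriptome
        contigs = sd.simulate_contigs(genes, [19], params)
        n = len(contigs[("purple", 19)])
        assert abs(n / len(genes) - 1.475) / 1.475 < 0.10

    def test_contig_count_bounds(self, transcriptome):
        genes, truth, params = transcriptome
        contigs = sd.simulate_contigs(genes, [19, 29], params)
        for key, cs in contigs.items():
            per_gene = {}
            for c in cs:
                per_gene[c.source_genes[0]] = per_gene.get(c.source_genes[0], 0) + 1
            assert all(1 <= v <= 11 for v in per_gene.values())

    def test_smaller_kmer_longer_contigs(self, transcriptome):
        genes, truth, params = transcriptome
        contigs = sd.simulate_contigs(genes, [19, 29], params)
        mean19 = np.mean([len(c.sequence) for c in contigs[("purple", 19)]])
        mean29 = np.mean([len(c.sequence) for c in contigs[("purple", 29)]])
        assert mean19 > mean29

    def test_chimera_fraction(self, transcriptome):
        genes, truth, params = transcriptome
        import dataclasses

        params = dataclasses.replace(params, chimera_rate=0.05)
        contigs = sd.simulate_contigs(genes, [19], params)
        all_c = [c for cs in contigs.values() for c in cs]
        frac = sum(1 for c in all_c if len(c.source_genes) == 2) / len(all_c)
        assert abs(frac - 0.05) < 0.02

    def test_empty_kmer_list_error(self, transcriptome):
        genes, truth, params = transcriptome
        with pytest.raises(ValueError):
            sd.simulate_contigs(genes, [], params)


class TestGoAnnotations:
    def test_independence_without_enrichment(self):
        genes = [f"g{i}" for i in range(1500)]
        de = set(genes[:100])
        ann = sd.generate_go_annotations(genes, 5, seed=1, de_genes=de)
        term = "GO:0000001"
        has = set(ann.loc[ann["term_id"] == term, "gene_id"])
        table = np.array(
            [
                [len(has & de), len(de - has)],
                [len(has - de), len(set(genes) - de - has)],
            ]
        )
        assert stats.chi2_contingency(table).pvalue > 0.01

    def test_planted_enrichment_frequency(self):
        genes = [f"g{i}" for i in range(2000)]
        de = set(genes[:25])
        spec = (sd.EnrichedTermSpec("GO:9000001", 0.05, 0.40),)
        ann = sd.generate_go_annotations(genes, 5, spec, seed=2, de_genes=de)
        has = set(ann.loc[ann["term_id"] == "GO:9000001", "gene_id"])
        k = len(has & de)
        # binomial expectation 10 +- 3 SD
        assert abs(k - 10) < 3 * np.sqrt(25 * 0.4 * 0.6) + 1

    def test_deterministic(self):
        genes = [f"g{i}" for i in range(100)]
        a = sd.generate_go_annotations(genes, 10, seed=3)
        b = sd.generate_go_annotations(genes, 10, seed=3)
        assert a.equals(b)

    def test_invalid_n_terms(self):
        with pytest.raises(ValueError):
            sd.generate_go_annotations(["g"], 0)
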