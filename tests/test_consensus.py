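import random

import numpy as np
import pytest

from petalseq import consensus as cns
from petalseq.synthdata import ReferenceGene


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture()
def gene(rng):
    seq = _rand_seq(rng, 400)
    return ReferenceGene("G1", seq, 50, 350)


class TestAnchorContigs:
    def test_identical_cds_contig(self, gene):
        contig = gene.sequence[gene.cds_start : gene.cds_end]
        aln = cns.anchor_contigs(gene, [("c1", "purple", contig)], kmer=19)
        assert len(aln.rows) == 1
        assert aln.rows[0].start == gene.cds_start
        assert aln.frame_start == 0
        assert aln.frame_end == 400

    def test_5prime_overhang_extends_frame(self, rng, gene):
        # contig extends 54 bp beyond the reference start
        overhang = _rand_seq(rng, 54)
        contig = overhang + gene.sequence[:200]
        aln = cns.anchor_contigs(gene, [("c1", "purple", contig)], kmer=19)
        assert aln.rows[0].start == -54
        assert aln.frame_start == -54
        rec = cns.build_consensus(aln)
        assert len(rec.sequence) == 400 + 54

    def test_overlapping_contigs_share_columns(self, gene):
        # offset oracle: contig2 starts 100 before contig1's end
        c1 = gene.sequence[0:200]
        c2 = gene.sequence[100:300]
        aln = cns.anchor_contigs(
            gene, [("c1", "purple", c1), ("c2", "white", c2)], kmer=19
        )
        starts = sorted(r.start for r in aln.rows)
        assert starts == [0, 100]
        rec = cns.build_consensus(aln)
        assert rec.sequence[:300] == gene.sequence[:300]
        assert rec.ambiguity_fraction == 0.0

    def test_unassigned_contig_errors(self, gene):
        with pytest.raises(ValueError):
            cns.anchor_contigs(gene, [("c1", "purple", "ACGT" * 10)], kmer=19)


class TestBuildConsensus:
    def test_identical_contigs(self, gene):
        contig = gene.sequence[50:250]
        aln = cns.anchor_contigs(
            gene, [("c1", "purple", contig), ("c2", "white", contig)], kmer=19
        )
        rec = cns.build_consensus(aln)
        covered = rec.sequence.replace("n", "")
        assert covered == contig
        assert rec.ambiguity_fraction == 0.0
        assert rec.assembled_length == 200

    def test_single_variant_column(self, gene):
        contig = gene.sequence[50:250]
        pos = next(i for i, b in enumerate(contig) if b in "AG")
        other = list(contig)
        other[pos] = "G" if contig[pos] == "A" else "A"
        aln = cns.anchor_contigs(
            gene, [("c1", "purple", contig), ("c2", "white", "".join(other))], kmer=19
        )
        rec = cns.build_consensus(aln)
        assert rec.sequence[50 + pos] == "R"
        assert rec.ambiguity_fraction == pytest.approx(1 / 200)

    def test_internal_gap_padded_and_excluded(self, gene):
        c1 = gene.sequence[0:100]
        c2 = gene.sequence[137:300]  # leaves a 37-column hole
        aln = cns.anchor_contigs(
            gene, [("c1", "purple", c1), ("c2", "white", c2)], kmer=19
        )
        rec = cns.build_consensus(aln)
        assert rec.sequence[100:137] == "n" * 37
        assert rec.assembled_length == 100 + 163
        assert rec.ambiguity_fraction == 0.0

    def test_reorder_invariance(self, gene, rng):
        contigs = [
            ("c1", "purple", gene.sequence[0:180]),
            ("c2", "white", gene.sequence[90:320]),
            ("c3", "purple", gene.sequence[200:400]),
        ]
        recs = []
        for perm in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            aln = cns.anchor_contigs(gene, [contigs[i] for i in perm], kmer=19)
            recs.append(cns.build_consensus(aln))
        assert len({r.sequence for r in recs}) == 1
        assert len({r.ambiguity_fraction for r in recs}) == 1

    def test_two_haplotype_ambiguity_matches_divergence(self, rng):
        """Full-coverage haplotype pair at divergence d -> ambiguity ~ d."""
        for d in (0.005, 0.015):
            seq = _rand_seq(rng, 2000)
            arr = list(seq)
            k = int(d * len(seq))
            for pos in rng.choice(len(seq), size=k, replace=False):
                arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
            g = ReferenceGene("G", seq, 100, 1900)
            aln = cns.anchor_contigs(
                g, [("h1", "purple", seq), ("h2", "white", "".join(arr))], kmer=19
            )
            rec = cns.build_consensus(aln)
            assert rec.ambiguity_fraction == pytest.approx(d, abs=3 * np.sqrt(d / 2000))

    def test_consensus_length_invariants(self, gene):
        aln = cns.anchor_contigs(gene, [("c1", "purple", gene.sequence[10:200])], kmer=19)
        rec = cns.build_consensus(aln)
        assert len(rec.sequence) >= rec.assembled_length
        assert rec.assembled_length == sum(1 for c in rec.sequence if c != "n")


class TestSelectKmer:
    def _rec(self, kmer, length, amb):
        return cns.ConsensusRecord(
            "G", kmer, "A" * length, 0, 0, length, amb, length, 1.0, 0, 0
        )

    def test_threshold_excludes_long_ambiguous(self):
        recs = [self._rec(19, 800, 0.005), self._rec(25, 900, 0.025)]
        assert cns.select_kmer(recs).kmer == 19

    def test_longest_passing_wins(self):
        recs = [self._rec(19, 700, 0.001), self._rec(21, 800, 0.002),
                self._rec(23, 750, 0.001)]
        assert cns.select_kmer(recs).assembled_length == 800

    def test_tie_goes_to_smaller_kmer(self):
        recs = [self._rec(23, 800, 0.001), self._rec(19, 800, 0.002)]
        assert cns.select_kmer(recs).kmer == 19

    def test_all_failing_returns_none(self):
        recs = [self._rec(19, 800, 0.02), self._rec(21, 900, 0.05)]
        assert cns.select_kmer(recs) is None

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cns.select_kmer([])

    def test_selected_never_exceeds_threshold(self, rng):
        for _ in range(50):
            recs = [
                self._rec(k, int(rng.integers(300, 1000)), float(rng.uniform(0, 0.04)))
                for k in (19, 21, 23, 25)
            ]
            chosen = cns.select_kmer(recs)
            if chosen is not None:
                assert chosen.ambiguity_fraction < 0.019


class TestTriage:
    def test_utr_divergent_paralog_kept(self, rng):
        seq = _rand_seq(rng, 600)
        g = ReferenceGene("G", seq, 100, 500)
        # second contig: same CDS, 30%-diverged UTRs
        arr = list(seq)
        for pos in list(range(0, 100)) + list(range(500, 600)):
            if rng.random() < 0.30:
                arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
        par = "".join(arr)
        aln = cns.anchor_contigs(
            g, [("c1", "purple", seq), ("c2", "white", par)], kmer=19
        )
        rec = cns.build_consensus(aln)
        assert rec.ambiguity_fraction >= 0.019
        outcome, repaired = cns.triage_high_ambiguity(aln, rec, g)
        assert outcome.category == "utr_divergent_paralog"
        assert outcome.contigs_removed == ()
        assert repaired is not None

    def test_misplaced_contig_reanchored(self, rng):
        seq = _rand_seq(rng, 500)
        g = ReferenceGene("G", seq, 50, 450)
        c1 = seq[0:300]
        c2 = seq[150:500]
        good = cns.anchor_contigs(
            g, [("c1", "purple", c1), ("c2", "white", c2)], kmer=19
        )
        # inject a 5-column anchoring error on c2
        bad_rows = (good.rows[0],
                    cns.AlignedRow("c2", "white", good.rows[1].start + 5, c2))
        bad = cns.AnchoredAlignment(
            g.gene_id, 19, 500, 50, 450, bad_rows
        )
        rec = cns.build_consensus(bad)
        assert rec.ambiguity_fraction >= 0.019
        outcome, repaired = cns.triage_high_ambiguity(bad, rec, g)
        assert outcome.category == "misalignment"
        assert repaired.ambiguity_fraction < 0.019

    def test_divergent_contig_removed(self, rng):
        seq = _rand_seq(rng, 600)
        g = ReferenceGene("G", seq, 50, 550)

        def diverge(rate):
            arr = list(seq)
            for pos in rng.choice(len(seq), size=int(rate * len(seq)), replace=False):
                arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
            return "".join(arr)

        near = diverge(0.01)
        far = diverge(0.22)
        aln = cns.anchor_contigs(
            g, [("good1", "purple", seq), ("good2", "white", near),
                ("bad", "white", far)], kmer=19
        )
        rec = cns.build_consensus(aln)
        assert rec.ambiguity_fraction >= 0.019
        outcome, repaired = cns.triage_high_ambiguity(aln, rec, g)
        assert outcome.category == "divergent_contig_removed"
        assert "bad" in outcome.contigs_removed
        assert repaired.ambiguity_fraction < 0.019


class TestCoverageStats:
    def _rec_with_cov(self, cds_len, covered, u5=0, u3=0):
        return cns.ConsensusRecord(
            "G", 19, "A" * cds_len, 0, 0, cds_len, 0.0, covered,
            covered / cds_len, u5, u3,
        )

    def test_full_coverage(self):
        pct, u5, u3 = cns.coverage_stats(self._rec_with_cov(1185, 1185, 54, 175))
        assert (pct, u5, u3) == (100.0, 54, 175)

    def test_partial_coverage_one_decimal(self):
        pct, _, _ = cns.coverage_stats(self._rec_with_cov(2178, 2035, 0, 25))
        assert pct == 93.4

    def test_zero_coverage(self):
        pct, u5, u3 = cns.coverage_stats(self._rec_with_cov(500, 0))
        assert (pct, u5, u3) == (0.0, 0, 0)


class TestAppendExternal:
    def test_append(self):
        t = {"g1": "ACGT"}
        out = cns.append_external_sequence(t, "ext", "TTTT")
        assert out["ext"] == "TTTT" and len(out) == 2

    def test_duplicate_errors(self):
        with pytest.raises(ValueError):
            cns.append_external_sequence({"g1": "ACGT"}, "g1", "TTTT")
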