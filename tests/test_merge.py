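"""Peptide matching, contig classification, clustering, N50, and the
anchored extension/bridging procedure."""
import numpy as np
import pytest

from rorqual import merge as mg
from rorqual import synth
from rorqual.align import align_peptides

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng, n):
    return "".join(rng.choice(list(AA), size=n))


class TestAlignPeptides:
    def test_identical_peptides(self, rng):
        p = random_peptide(rng, 120)
        m = align_peptides(p, p)
        assert (m.identity, m.q_cov, m.s_cov) == (100.0, 100.0, 100.0)

    def test_prefix_half_coverage(self, rng):
        p = random_peptide(rng, 200)
        m = align_peptides(p[:100], p)
        assert m.q_cov == pytest.approx(100.0, abs=2.0)
        assert m.s_cov == pytest.approx(50.0, abs=2.0)

    def test_unrelated_peptides_low_identity(self, rng):
        for _ in range(100):
            a = random_peptide(rng, 100)
            b = random_peptide(rng, 100)
            assert align_peptides(a, b).identity < 40.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_peptides("", "MKL")


class TestFilterMatches:
    def _m(self, ident, q, s):
        return mg.GeneMatch("a", "b", ident, q, s)

    def test_threshold_semantics(self):
        kept = mg.filter_matches([
            self._m(96, 80, 110),   # kept
            self._m(95.0, 80, 80),  # identity not strictly > 95
            self._m(99, 69, 100),   # q_cov too low
            self._m(99, 100, 130),  # s_cov not strictly < 130
            self._m(99, 70, 80),    # q_cov not strictly > 70
        ])
        assert [(m.identity, m.q_cov, m.s_cov) for m in kept] == [(96, 80, 110)]


class TestClassification:
    def _contig(self, cid, sample, genes):
        seq = "A" * 3000
        anns = [mg.GeneAnnotation(g, cid, 0, 300, "+", "M" * 100)
                for g in genes]
        return mg.Contig(cid, sample, seq, anns)

    def test_four_way_partition(self):
        contigs = [
            self._contig("c0", "S1", []),
            self._contig("c1", "S1", ["g1"]),
            self._contig("c2", "S1", ["g2"]),
            self._contig("c3", "S2", ["g3", "g4"]),
        ]
        kept = [
            mg.GeneMatch("g2", "g3", 99, 90, 90),
            mg.GeneMatch("g3", "g2", 99, 90, 90),
            mg.GeneMatch("g4", "g2", 99, 90, 90),
        ]
        classes = mg.classify_contigs(contigs, kept)
        assert classes["c0"] is mg.ContigClass.NO_GENES
        assert classes["c1"] is mg.ContigClass.SAMPLE_SPECIFIC_GENES
        assert classes["c2"] is mg.ContigClass.SINGLE_GENE
        assert classes["c3"] is mg.ContigClass.MULTI_GENE
        assert len(classes) == len(contigs)  # partition: all classified


class TestClustering:
    def test_transitive_closure(self):
        kept = [mg.GeneMatch("a", "b", 99, 90, 90),
                mg.GeneMatch("b", "c", 99, 90, 90)]
        assert mg.cluster_genes(kept) == [{"a", "b", "c"}]

    def test_no_matches_singletons(self):
        assert mg.cluster_genes([], all_genes=["x", "y"]) == [{"x"}, {"y"}]

    def test_disjoint_pairs(self):
        kept = [mg.GeneMatch("a", "b", 99, 90, 90),
                mg.GeneMatch("c", "d", 99, 90, 90)]
        assert mg.cluster_genes(kept) == [{"a", "b"}, {"c", "d"}]


class TestAssemblyStats:
    def test_equal_lengths(self):
        s = mg.assembly_stats(["A" * 10] * 3)
        assert s.n50 == 10 and s.max_length == 10

    def test_dominant_contig(self):
        # brute-force check of the cumulative-sum definition
        lengths = [1, 1, 1, 97]
        total = sum(lengths)
        best = max(
            L for L in lengths
            if sum(x for x in lengths if x >= L) >= total / 2
        )
        s = mg.assembly_stats(["A" * n for n in lengths])
        assert s.n50 == best == 97

    def test_random_sets_match_bruteforce(self, rng):
        for _ in range(50):
            lengths = rng.integers(1, 500, size=rng.integers(1, 30)).tolist()
            total = sum(lengths)
            best = max(
                L for L in lengths
                if sum(x for x in lengths if x >= L) >= total / 2
            )
            assert mg.assembly_stats(["A" * n for n in lengths]).n50 == best

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mg.assembly_stats([])


def _universe_contig(cid, sample, seq, genes=()):
    return mg.Contig(cid, sample, seq, list(genes))


class TestExtendAndBridge:
    def _genome(self, rng, n=12000):
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_contained_contig_leaves_anchor_unchanged(self, rng):
        genome = self._genome(rng)
        anchor = _universe_contig(
            "a1", "S30", genome[:6000],
            [mg.GeneAnnotation("gA", "a1", 1000, 1300, "+", "M" * 100)])
        inner = _universe_contig(
            "o1", "S34", genome[500:5500],
            [mg.GeneAnnotation("gB", "o1", 500, 800, "+", "M" * 100)])
        combined = mg.extend_and_bridge(
            "S30", [anchor, inner], [{"gA", "gB"}])
        assert [c.sequence for c in combined] == [anchor.sequence]

    def test_protruding_contig_extends_anchor(self, rng):
        genome = self._genome(rng)
        anchor = _universe_contig(
            "a1", "S30", genome[:5000],
            [mg.GeneAnnotation("gA", "a1", 4000, 4300, "+", "M" * 100)])
        right = _universe_contig(
            "o1", "S34", genome[4200:9000],
            [mg.GeneAnnotation("gB", "o1", 100, 400, "+", "M" * 100)])
        combined = mg.extend_and_bridge(
            "S30", [anchor, right], [{"gA", "gB"}])
        assert len(combined) == 1
        assert combined[0].sequence == genome[:9000]

    def test_spanning_contig_bridges_two_anchors(self, rng):
        genome = self._genome(rng)
        a1 = _universe_contig(
            "a1", "S30", genome[:4000],
            [mg.GeneAnnotation("g1", "a1", 3500, 3800, "+", "M" * 100)])
        a2 = _universe_contig(
            "a2", "S30", genome[5000:9000],
            [mg.GeneAnnotation("g2", "a2", 100, 400, "+", "M" * 100)])
        span = _universe_contig(
            "o1", "S34", genome[3000:6000],
            [mg.GeneAnnotation("g1x", "o1", 500, 800, "+", "M" * 100),
             mg.GeneAnnotation("g2x", "o1", 2100, 2400, "+", "M" * 100)])
        combined = mg.extend_and_bridge(
            "S30", [a1, a2, span], [{"g1", "g1x", "g2", "g2x"}])
        assert len(combined) == 1
        assert combined[0].sequence == genome[:9000]

    def test_reverse_complement_contig_still_extends(self, rng):
        genome = self._genome(rng)
        anchor = _universe_contig(
            "a1", "S30", genome[:5000],
            [mg.GeneAnnotation("gA", "a1", 4000, 4300, "+", "M" * 100)])
        right = _universe_contig(
            "o1", "S34", mg.revcomp(genome[4200:9000]),
            [mg.GeneAnnotation("gB", "o1", 100, 400, "-", "M" * 100)])
        combined = mg.extend_and_bridge(
            "S30", [anchor, right], [{"gA", "gB"}])
        assert combined[0].sequence == genome[:9000]

    def test_anchorless_cluster_contributes_consensus(self, rng):
        genome = self._genome(rng)
        c1 = _universe_contig(
            "o1", "S34", genome[2000:7000],
            [mg.GeneAnnotation("gX", "o1", 1000, 1300, "+", "M" * 100)])
        c2 = _universe_contig(
            "o2", "S35", genome[2500:7500],
            [mg.GeneAnnotation("gY", "o2", 500, 800, "+", "M" * 100)])
        combined = mg.extend_and_bridge("S30", [c1, c2], [{"gX", "gY"}])
        assert len(combined) == 1
        assert combined[0].sequence == genome[2000:7500]


@pytest.fixture(scope="module")
def universe():
    return synth.simulate_contig_universe(
        synth.ContigUniverseConfig(seed=17))


@pytest.fixture(scope="module")
def result(universe):
    return mg.merge_assemblies(universe.samples, anchor="S30")


class TestMergePipeline:

    def test_every_observed_gene_is_in_combined(self, universe, result):
        combined = "|".join(c.sequence for c in result["combined"])
        present = universe.genes_present()
        for gid, gs, ge in universe.genes:
            if present[gid]:
                assert universe.genome[gs:ge] in combined, gid

    def test_anchor_contigs_never_truncated(self, universe, result):
        combined = "|".join(c.sequence for c in result["combined"])
        for c in universe.samples["S30"]:
            if len(c) >= 2000:
                assert c.sequence in combined

    def test_max_length_monotone(self, result):
        assert result["stats"].max_length >= result["anchor_stats"].max_length

    def test_classification_is_total(self, universe, result):
        n_contigs = sum(
            1 for s in universe.samples.values() for c in s if len(c) >= 2000
        )
        assert len(result["classes"]) == n_contigs

    def test_no_duplicates_without_dropout(self):
        # with zero dropout and no error, every gene appears exactly once
        uni = synth.simulate_contig_universe(synth.ContigUniverseConfig(
            dropout_rate=0.0, per_base_error=0.0, seed=23))
        res = mg.merge_assemblies(uni.samples, anchor="S30")
        combined = "|".join(c.sequence for c in res["combined"])
        for gid, gs, ge in uni.genes:
            if uni.genes_present()[gid]:
                assert combined.count(uni.genome[gs:ge]) == 1, gid
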