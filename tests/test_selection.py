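"""NG86 counting, F3X4 frequencies, the GY94 likelihood and the branch
test machinery, each checked against an independent oracle."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm
from scipy.stats import chi2

from rorqual import codons as cd
from rorqual import selection as sel
from rorqual.seqio import read_newick


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_pair_counts(c1: str, c2: str):
    """Pathway averaging by explicit enumeration of substitution orders."""
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    acc = []
    for allow_stops in (False, True):
        for order in itertools.permutations(diffs):
            cur, s, n, ok = c1, 0.0, 0.0, True
            for k in order:
                nxt = cur[:k] + c2[k] + cur[k + 1:]
                if nxt in cd.STOP_CODONS and not allow_stops:
                    ok = False
                    break
                if (nxt not in cd.STOP_CODONS
                        and cd.AMINO_ACID[cur] == cd.AMINO_ACID[nxt]):
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                acc.append((s, n))
        if acc:
            break
    return (sum(a[0] for a in acc) / len(acc),
            sum(a[1] for a in acc) / len(acc))


def oracle_lnl(newick, seqs, kappa, omega, pi):
    """Brute-force GY94 likelihood: matrix exponentials via scipy and an
    explicit sum over internal states for star/two-leaf trees."""
    q = sel.build_rate_matrix(pi, kappa, omega)
    tree = read_newick(newick)
    leaves = list(tree.seed_node.child_nodes())
    assert all(lf.is_leaf() for lf in leaves)
    pmats = [expm(q * lf.edge.length) for lf in leaves]
    rows = [cd.codon_indices(seqs[lf.taxon.label]) for lf in leaves]
    n_sites = rows[0].size
    lnl = 0.0
    for site in range(n_sites):
        like = 0.0
        for r in range(cd.N_SENSE):
            term = pi[r]
            for p, row in zip(pmats, rows):
                term *= p[r, row[site]]
            like += term
        lnl += np.log(like)
    return lnl


def random_f3x4(rng, concentration: float = 5.0):
    freqs = rng.dirichlet(np.full(4, concentration), size=3)
    pi = np.array([
        freqs[0][cd.BASE_INDEX[c[0]]]
        * freqs[1][cd.BASE_INDEX[c[1]]]
        * freqs[2][cd.BASE_INDEX[c[2]]]
        for c in cd.SENSE_CODONS
    ])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

class TestNG86:
    def test_site_counts_sum_to_three(self):
        for c in cd.SENSE_CODONS:
            s, n = sel.ng86_site_counts(c)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_pair_counts_match_enumeration_oracle_sample(self, rng):
        pairs = rng.choice(cd.N_SENSE, size=(300, 2))
        for i, j in pairs:
            c1, c2 = cd.SENSE_CODONS[i], cd.SENSE_CODONS[j]
            assert sel.ng86_pair_counts(c1, c2) == pytest.approx(
                oracle_pair_counts(c1, c2), abs=1e-12
            )

    def test_identical_sequences_have_na_omega(self):
        r = sel.ng86_dnds("ATGGCTAAA", "ATGGCTAAA")
        assert r.dn == 0.0 and r.ds == 0.0
        assert np.isnan(r.omega)

    def test_single_synonymous_difference_gives_omega_zero(self):
        # GGT->GGC is synonymous; pad with codons that carry syn sites
        pad = "GCTCTTCGAACCGTA" * 20
        r = sel.ng86_dnds("GGT" + pad, "GGC" + pad)
        assert r.dn == 0.0
        assert r.ds > 0.0
        assert r.omega == 0.0

    def test_sites_partition_total(self, rng):
        idx = rng.integers(0, cd.N_SENSE, size=120)
        seq = "".join(cd.SENSE_CODONS[i] for i in idx)
        r = sel.ng86_dnds(seq, seq)
        assert r.syn_sites + r.nonsyn_sites == pytest.approx(
            3 * 120, abs=1e-9
        )

    def test_gapped_codons_excluded_pairwise(self):
        r = sel.ng86_dnds("ATG---AAA", "ATGGCTAAA")
        assert r.n_codons_used == 2


# ---------------------------------------------------------------------------
# F3X4 and the rate matrix
# ---------------------------------------------------------------------------

class TestF3X4:
    def test_uniform_usage_gives_uniform_pi(self):
        # all four bases equally often at every position
        seqs = ["".join(b1 + b2 + b3
                        for b1 in "TCAG" for b2 in "TCAG" for b3 in "TCAG")]
        pi = sel.f3x4_frequencies(seqs)
        assert pi == pytest.approx(np.full(61, 1 / 61), abs=1e-12)

    def test_single_repeated_codon(self):
        pi = sel.f3x4_frequencies(["AAAAAAAAA"])
        assert pi[cd.CODON_INDEX["AAA"]] == pytest.approx(1.0)

    def test_matches_hand_product(self):
        # 2 sequences of 2 codons: position freqs computable by hand
        seqs = ["ATGGCT", "ATGGCA"]
        # pos1: A,G,A,G ; pos2: T,C,T,C ; pos3: G,T,G,A
        f1 = {"A": 0.5, "G": 0.5}
        f2 = {"T": 0.5, "C": 0.5}
        f3 = {"G": 0.5, "T": 0.25, "A": 0.25}
        raw = {}
        for c in cd.SENSE_CODONS:
            raw[c] = f1.get(c[0], 0) * f2.get(c[1], 0) * f3.get(c[2], 0)
        z = sum(raw.values())
        pi = sel.f3x4_frequencies(seqs)
        for c in ("ATG", "GCT", "ACA", "GTG"):
            assert pi[cd.CODON_INDEX[c]] == pytest.approx(raw[c] / z, rel=1e-9)

    def test_rate_matrix_rows_sum_to_zero_and_stationary(self, rng):
        pi = random_f3x4(rng)
        q = sel.build_rate_matrix(pi, kappa=3.0, omega=0.4)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(pi @ q, 0.0, atol=1e-12)     # stationarity
        assert -float(pi @ np.diag(q)) == pytest.approx(1.0)  # mean rate 1


# ---------------------------------------------------------------------------
# GY94 likelihood
# ---------------------------------------------------------------------------

class TestGY94Likelihood:
    def test_zero_branch_single_codon_equals_log_pi(self):
        aln = sel.CodonAlignment.from_sequences([("a", "ATG"), ("b", "ATG")])
        tree = read_newick("(a:0.0,b:0.0);")
        pi = np.full(61, 1 / 61)
        lnl = sel.gy94_loglikelihood(aln, tree, 2.0, 0.5, pi)
        assert lnl == pytest.approx(np.log(pi[cd.CODON_INDEX["ATG"]]))

    def test_matches_bruteforce_on_toy_cases(self, rng):
        # data simulated under the model so site likelihoods are plausible
        from rorqual import synth
        for trial in range(15):
            pi = random_f3x4(rng)
            kappa = float(rng.uniform(1, 5))
            omega = float(rng.uniform(0.1, 2))
            ts = rng.uniform(0.05, 1.0, size=3)
            newick = f"(a:{ts[0]},b:{ts[1]},c:{ts[2]});"
            aln, _ = synth.simulate_codon_alignment(synth.CodonSimConfig(
                tree=read_newick(newick), kappa=kappa,
                omega_by_branch={"*": omega}, codon_freqs=pi,
                n_codons=2, seed=trial))
            seqs = {t: aln.sequence(t) for t in aln.taxa}
            lnl = sel.gy94_loglikelihood(
                aln, read_newick(newick), kappa, omega, pi,
            )
            assert lnl == pytest.approx(
                oracle_lnl(newick, seqs, kappa, omega, pi), abs=1e-8
            )

    def test_invariant_under_taxon_relabeling(self, rng):
        pi = np.full(61, 1 / 61)
        idx = rng.integers(0, cd.N_SENSE, size=(2, 5))
        s1 = "".join(cd.SENSE_CODONS[i] for i in idx[0])
        s2 = "".join(cd.SENSE_CODONS[i] for i in idx[1])
        tree = read_newick("(a:0.2,b:0.2);")
        l1 = sel.gy94_loglikelihood(
            sel.CodonAlignment.from_sequences([("a", s1), ("b", s2)]),
            tree, 2.0, 0.5, pi)
        l2 = sel.gy94_loglikelihood(
            sel.CodonAlignment.from_sequences([("a", s2), ("b", s1)]),
            tree, 2.0, 0.5, pi)
        assert l1 == pytest.approx(l2, abs=1e-10)

    def test_gap_codons_marginalized(self):
        pi = np.full(61, 1 / 61)
        tree = read_newick("(a:0.1,b:0.1);")
        full = sel.CodonAlignment.from_sequences([("a", "ATG"), ("b", "---")])
        lnl = sel.gy94_loglikelihood(full, tree, 2.0, 0.5, pi)
        assert lnl == pytest.approx(np.log(pi[cd.CODON_INDEX["ATG"]]))


class TestBranchModelFit:
    def test_alt_never_below_null_and_summary(self):
        rng = np.random.default_rng(1)
        idx = rng.integers(0, cd.N_SENSE, size=(3, 40))
        aln = sel.CodonAlignment(
            ["a", "b", "c"], idx
        )
        tree = read_newick("(a:0.3,b:0.3,c:0.3);")
        model = sel.BranchCodonModel(aln, tree, foreground="c")
        null = model.fit(two_ratio=False)
        alt = model.fit(two_ratio=True, start={
            "kappa": null.kappa, "omega": null.omega,
            "omega_foreground": null.omega,
            "branch_lengths": null.branch_lengths})
        assert alt.llf >= null.llf - 1e-4
        assert "log-likelihood" in null.summary()
        table = alt.branch_table()
        assert table["foreground"].sum() == 1
        fg = table.query("foreground").iloc[0]
        if fg.dS > 0:
            assert fg.dN / fg.dS == pytest.approx(fg.omega, rel=1e-6)


class TestLRTandFDR:
    def test_lrt_boundaries(self):
        assert sel.lrt_pvalue(-100.0, -100.0) == 1.0
        assert sel.lrt_pvalue(-100.0, -100.0 + 3.841 / 2) == pytest.approx(
            chi2.sf(3.841, 1), abs=1e-12)
        assert sel.lrt_pvalue(-100.0, -100.0 + 3.841 / 2) == pytest.approx(
            0.050, abs=5e-4)

    def test_lrt_nesting_violation_raises(self):
        with pytest.raises(ValueError, match="optimizer"):
            sel.lrt_pvalue(-99.0, -100.0)

    def test_bh_stepup_worked_example(self):
        q = sel.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert sel.bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert sel.bh_fdr([0.2]) == pytest.approx([0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_bh_matches_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests
        expected = multipletests(ps, method="fdr_bh")[1]
        assert sel.bh_fdr(ps) == pytest.approx(expected, abs=1e-12)

    def test_bh_monotone_and_bounded(self, rng):
        p = rng.uniform(0, 1, size=200)
        q = sel.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= p - 1e-12) & (q <= 1.0))


class TestPostFilter:
    def _result(self, ds, omega):
        return sel.BranchTestResult(
            gene_id="g", lnl_null=0, lnl_alt=0, lrt_stat=0, p_value=1,
            kappa=2, omega_background=0.2, omega_foreground=omega,
            t_foreground=0.1, dn_foreground=0.1, ds_foreground=ds,
        )

    def test_thresholds_are_strict(self):
        out = sel.postfilter_results([
            self._result(3.5, 0.5),
            self._result(0.5, 6.0),
            self._result(3.0, 5.0),
        ])
        assert [r.filtered for r in out] == [True, True, False]
        assert out[0].filter_reason == "dS>3"
        assert out[1].filter_reason == "dN/dS>5"
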