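"""r^2 / D statistics, LD profiles, gene-level LD and pn/ps."""
import itertools

import numpy as np
import pandas as pd
import pytest

from hyperld import ld
from hyperld.genomes import UndefinedStatisticError
from hyperld.ld import LdUndefinedError

from conftest import make_alignment, make_snp_table


def brute_force_r2(x, y):
    """Independent oracle from 2x2 haplotype counts."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.mean() > 0.5:
        x = 1 - x
    if y.mean() > 0.5:
        y = 1 - y
    n = len(x)
    n11 = np.sum((x == 1) & (y == 1))
    pa, pb, pab = x.sum() / n, y.sum() / n, n11 / n
    d = pab - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


class TestRSquared:
    def test_perfect_coupling(self):
        v = np.array([1, 1, 0, 0])
        assert ld.r_squared(v, v) == pytest.approx(1.0)

    def test_exact_independence(self):
        x = np.array([1, 1, 0, 0])
        y = np.array([1, 0, 1, 0])
        assert ld.r_squared(x, y) == pytest.approx(0.0)

    def test_hand_evaluated_formula(self):
        # haplotype counts AB=4, Ab=1, aB=1, ab=4 (n=10)
        x = np.array([1] * 5 + [0] * 5)
        y = np.array([1] * 4 + [0] + [1] + [0] * 4)
        assert ld.r_squared(x, y) == pytest.approx(0.36)

    def test_monomorphic_raises(self):
        with pytest.raises(LdUndefinedError):
            ld.r_squared(np.zeros(4, dtype=int), np.array([1, 0, 1, 0]))

    def test_exhaustive_small_n_oracle(self):
        """Matches brute-force haplotype counting on all n<=6 configs."""
        for n in (2, 3, 4, 5, 6):
            for bits_x in itertools.product([0, 1], repeat=n):
                x = np.array(bits_x)
                if x.sum() in (0, n):
                    continue
                for bits_y in itertools.product([0, 1], repeat=n):
                    y = np.array(bits_y)
                    if y.sum() in (0, n):
                        continue
                    assert ld.r_squared(x, y) == pytest.approx(
                        brute_force_r2(x, y), abs=1e-12)

    def test_symmetry_and_relabeling_invariance(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            if x.sum() in (0, n) or y.sum() in (0, n):
                continue
            r = ld.r_squared(x, y)
            assert ld.r_squared(y, x) == pytest.approx(r)
            assert ld.r_squared(1 - x, y) == pytest.approx(r)


class TestDMinor:
    def test_attraction(self):
        v = np.array([1, 1, 0, 0])
        assert ld.d_minor(v, v) == pytest.approx(0.25)

    def test_repulsion(self):
        x = np.array([1, 1, 0, 0])
        assert ld.d_minor(x, 1 - x) == pytest.approx(-0.25)

    def test_independence(self):
        x = np.array([1, 1, 0, 0])
        y = np.array([1, 0, 1, 0])
        assert ld.d_minor(x, y) == pytest.approx(0.0)

    def test_d_squared_normalized_equals_r2(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 20))
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            if x.sum() in (0, n) or y.sum() in (0, n):
                continue
            xm = x if 2 * x.sum() <= n else 1 - x
            ym = y if 2 * y.sum() <= n else 1 - y
            pa, pb = xm.mean(), ym.mean()
            d = ld.d_minor(x, y)
            assert d * d / (pa * (1 - pa) * pb * (1 - pb)) == pytest.approx(
                ld.r_squared(x, y), abs=1e-12)

    def test_polarization_is_canonical_under_relabeling(self):
        # a 0/1 relabel of one site is undone by minor-allele polarization,
        # so D is invariant; the sign only distinguishes minor-allele
        # coupling from repulsion
        x = np.array([1, 1, 0, 0, 0])
        y = np.array([1, 1, 0, 0, 0])
        assert ld.d_minor(x, y) > 0
        assert ld.d_minor(x, 1 - y) == pytest.approx(ld.d_minor(x, y))
        assert ld.d_minor(1 - x, 1 - y) == pytest.approx(ld.d_minor(x, y))


class TestLdProfile:
    def test_single_pair_aggregation(self):
        states = np.array([[1, 1, 0, 0, 0, 0], [1, 0, 1, 0, 0, 0]])
        snps = make_snp_table(states, positions=[0, 100],
                              genes=["gA", "gA"], exons=[0, 0],
                              classes=["synonymous", "synonymous"])
        prof = ld.ld_profile(snps, maf_min=0.05, max_distance=2000,
                             bin_edges=np.arange(0, 2001, 250))
        assert prof.n_pairs_total == 1
        row = prof.table.iloc[0]
        assert row["bin_left"] == 0 and row["relation"] == "same_gene"
        r2 = ld.r_squared(states[0], states[1])
        assert row["mean_r2"] == pytest.approx(r2)
        assert row["n_pairs"] == 1

    def test_maf_filter_excludes_rare_snp(self):
        n = 25
        s1 = np.zeros(n, dtype=int)
        s1[0] = 1  # maf 0.04
        s2 = np.zeros(n, dtype=int)
        s2[:5] = 1
        snps = make_snp_table(np.array([s1, s2]), positions=[0, 10])
        prof = ld.ld_profile(snps, maf_min=0.05)
        assert prof.n_pairs_total == 0

    def test_planted_class_gap(self):
        """nonsyn pairs r2=1 and syn pairs r2=0 -> gap 1 in populated bins."""
        n = 8
        coupled = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        b = np.array([1, 1, 0, 0, 1, 1, 0, 0])  # p_AB = p_A p_B exactly
        assert ld.r_squared(a, b) == pytest.approx(0.0)
        states = np.array([coupled, coupled, a, b])
        snps = make_snp_table(states, positions=[0, 50, 10, 60],
                              genes=["g"] * 4, exons=[0] * 4,
                              classes=["nonsynonymous", "nonsynonymous",
                                       "synonymous", "synonymous"])
        prof = ld.ld_profile(snps, maf_min=0.05, max_distance=100,
                             bin_edges=np.array([0, 100]))
        t = prof.table.set_index("class_pair")
        assert t.loc["nonsyn-nonsyn", "mean_r2"] == pytest.approx(1.0)
        assert t.loc["syn-syn", "mean_r2"] == pytest.approx(0.0)

    def test_pair_count_conservation(self, rng):
        m, n = 30, 12
        states = rng.integers(0, 2, size=(m, n))
        keep = [i for i in range(m) if 0 < states[i].sum() < n]
        states = states[keep]
        states = np.array([s if 2 * s.sum() <= n else 1 - s for s in states])
        pos = np.sort(rng.choice(3000, size=len(states), replace=False))
        snps = make_snp_table(states, positions=pos)
        prof = ld.ld_profile(snps, maf_min=0.0, max_distance=2000)
        pairs = ld.pair_table(snps, maf_min=0.0, max_distance=2000)
        in_range = (pairs["distance"] <= 2000).sum()
        assert prof.table["n_pairs"].sum() == in_range == prof.n_pairs_total

    def test_pair_at_exact_max_distance_is_counted(self):
        n = 10
        s = np.zeros(n, dtype=int)
        s[:4] = 1
        snps = make_snp_table(np.array([s, s, s]),
                              positions=[0, 1000, 2000])
        prof = ld.ld_profile(snps, maf_min=0.0, max_distance=2000)
        assert prof.table["n_pairs"].sum() == 3 == prof.n_pairs_total


class TestMafMatchedContrast:
    def _snps(self, rng, n=20, m=60):
        states = []
        classes = []
        for i in range(m):
            k = int(rng.integers(2, n // 2 + 1))
            s = np.zeros(n, dtype=int)
            s[rng.choice(n, k, replace=False)] = 1
            states.append(s)
            classes.append("nonsynonymous" if i % 2 else "synonymous")
        pos = np.sort(rng.choice(2000, size=m, replace=False))
        return make_snp_table(np.array(states), positions=pos,
                              genes=["g"] * m, exons=[0] * m,
                              classes=classes)

    def test_matching_noop_when_distributions_identical(self, rng):
        snps = self._snps(rng)
        out = ld.maf_matched_contrast(snps, relation="same_gene",
                                      n_resamples=400, rng_seed=5,
                                      bin_edges=np.array([0, 2000]))
        assert len(out) == 1
        row = out.iloc[0]
        # identical MAF laws for both classes: matched mean ~ unmatched mean
        assert row["syn_matched_mean"] == pytest.approx(
            row["syn_unmatched_mean"], abs=0.08)

    def test_stratified_resampling_targets_matched_cell(self):
        n = 20
        # nonsyn pairs all at MAF (0.25, 0.25); syn pairs half in that cell
        # with low LD, half at MAF 0.5 with high LD
        def site(k, coupled_with=None, rngseed=0):
            s = np.zeros(n, dtype=int)
            s[:k] = 1
            return s

        a = np.zeros(n, dtype=int); a[:5] = 1
        b = np.zeros(n, dtype=int); b[3:8] = 1          # maf .25, low ld
        c = np.zeros(n, dtype=int); c[:10] = 1
        d = np.zeros(n, dtype=int); d[:10] = 1          # maf .5, r2=1
        states = np.array([a, b, a, b, c, d])
        snps = make_snp_table(states, positions=[0, 10, 20, 30, 40, 50],
                              genes=["g"] * 6, exons=[0] * 6,
                              classes=["nonsynonymous", "nonsynonymous",
                                       "synonymous", "synonymous",
                                       "synonymous", "synonymous"])
        pairs = ld.pair_table(snps)
        out = ld.maf_matched_contrast(snps, relation="same_gene",
                                      n_resamples=300, rng_seed=3,
                                      bin_edges=np.array([0, 2000]))
        row = out.iloc[0]
        low_ld = ld.r_squared(a, b)
        # matched syn mean collapses onto the (0.25, 0.25) cell
        assert row["syn_matched_mean"] == pytest.approx(low_ld, abs=1e-9)
        assert row["syn_unmatched_mean"] > row["syn_matched_mean"]

    def test_seeded_determinism(self, rng):
        snps = self._snps(np.random.default_rng(7))
        a = ld.maf_matched_contrast(snps, n_resamples=100, rng_seed=11)
        b = ld.maf_matched_contrast(snps, n_resamples=100, rng_seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestGeneLdStats:
    def _gene_snps(self, n_pairs_target, r2_nonsyn, r2_syn, n=12):
        # coupled duos: all nonsyn identical states (r2=1 within class)
        m = 16
        half = np.zeros(n, dtype=int)
        half[:4] = 1
        other = np.zeros(n, dtype=int)
        other[4:8] = 1
        states, classes = [], []
        for i in range(m):
            if i % 2 == 0:
                states.append(half)
                classes.append("nonsynonymous")
            else:
                states.append(other)
                classes.append("synonymous")
        pos = np.arange(0, m * 10, 10)
        return make_snp_table(np.array(states), positions=pos,
                              genes=["g"] * m, exons=[0] * m,
                              classes=classes)

    def test_min_pairs_exclusion(self):
        snps = self._gene_snps(None, 1, 1)
        pairs = ld.pair_table(snps, max_distance=300)
        n_pairs = (pairs["relation"] == "same_gene").sum()
        out_keep = ld.gene_ld_stats(snps, min_pairs=n_pairs)
        out_drop = ld.gene_ld_stats(snps, min_pairs=n_pairs + 1)
        assert len(out_keep) == 1
        assert len(out_drop) == 0

    def test_uniform_r2_gives_zero_excess(self):
        n = 10
        s = np.zeros(n, dtype=int)
        s[:5] = 1
        states = np.array([s] * 6)
        snps = make_snp_table(states, positions=np.arange(0, 60, 10),
                              genes=["g"] * 6, exons=[0] * 6,
                              classes=["nonsynonymous"] * 3 +
                                      ["synonymous"] * 3)
        out = ld.gene_ld_stats(snps, min_pairs=1)
        row = out.iloc[0]
        assert row["ld_all"] == pytest.approx(1.0)
        assert row["excess"] == pytest.approx(0.0)

    def test_planted_excess(self):
        n = 12
        coupled = np.zeros(n, dtype=int)
        coupled[:4] = 1
        s1 = np.zeros(n, dtype=int); s1[:4] = 1
        s2 = np.zeros(n, dtype=int); s2[2:6] = 1
        r2_syn = ld.r_squared(s1, s2)
        states = np.array([coupled, coupled, coupled, s1, s2])
        snps = make_snp_table(states, positions=[0, 10, 20, 30, 40],
                              genes=["g"] * 5, exons=[0] * 5,
                              classes=["nonsynonymous"] * 3 +
                                      ["synonymous"] * 2)
        out = ld.gene_ld_stats(snps, min_pairs=1)
        row = out.iloc[0]
        assert row["ld_nonsyn"] == pytest.approx(1.0)
        assert row["ld_syn"] == pytest.approx(r2_syn)
        assert row["excess"] == pytest.approx(1.0 - r2_syn)


class TestGenePnPs:
    def test_codon_site_counts_ttt(self):
        syn, nonsyn = ld._codon_site_counts("TTT")
        assert syn == pytest.approx(1 / 3)
        assert nonsyn == pytest.approx(8 / 3)

    def test_codon_site_counts_exhaustive_sum(self):
        """Each codon's syn + nonsyn fractional sites total 3."""
        import itertools as it
        for codon in map("".join, it.product("ACGT", repeat=3)):
            s, ns = ld._codon_site_counts(codon)
            assert s + ns == pytest.approx(3.0)
            assert 0 <= s <= 3

    def test_zero_nonsyn_snps(self):
        from hyperld.genomes import GeneAnnotation, extract_snps, \
            classify_coding_sites
        # GGx codons: third position always synonymous
        seq = "GGAGGTGGC"
        mut = "GGTGGTGGC"  # pos2 A->T, still Gly
        aln = make_alignment([seq, seq, mut, mut])
        ann = GeneAnnotation("g", "c1", "+", ((0, 9),))
        snps = classify_coding_sites(extract_snps(aln, [ann]), aln, [ann])
        assert ld.gene_pn_ps(aln, ann, snps) == 0.0

    def test_neutral_gene_ratio_near_one(self, rng):
        """Class-blind mutation at every site -> pn/ps ~ 1 in expectation."""
        from hyperld import synth, genomes
        ratios = []
        for seed in range(6):
            spec = synth.SynthSpec(n_genotypes=40, contig_length=3000,
                                   n_genes=1, gene_length=2400,
                                   poly_prob=0.25, rng_seed=seed)
            aln, anns, _ = synth.generate_population(spec)
            snps = genomes.classify_coding_sites(
                genomes.extract_snps(aln, anns), aln, anns)
            ratios.append(ld.gene_pn_ps(aln, anns[0], snps))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.25)


class TestCorrelateGeneStats:
    def test_monotone(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": 2 * np.arange(10.0)})
        rep = ld.correlate_gene_stats(df, "x", "y")
        assert rep["rho"] == pytest.approx(1.0)
        assert rep["pvalue"] < 0.01

    def test_null_permutation(self, rng):
        x = rng.normal(size=1000)
        y = rng.permutation(rng.normal(size=1000))
        rep = ld.correlate_gene_stats(pd.DataFrame({"x": x, "y": y}),
                                      "x", "y")
        assert abs(rep["rho"]) < 0.1

    def test_confound_removed_by_control(self):
        # x and y share only the control variable; a uniform control makes
        # within-stratum control variation negligible
        r = np.random.default_rng(5)
        n = 1000
        c = r.uniform(size=n)
        x = c + 0.15 * r.normal(size=n)
        y = c + 0.15 * r.normal(size=n)
        rep = ld.correlate_gene_stats(
            pd.DataFrame({"x": x, "y": y, "c": c}), "x", "y", control="c",
            n_strata=10)
        assert rep["rho"] > 0.6                      # raw: confounded
        assert abs(rep["combined_rho"]) < 0.3        # controlled: mostly gone

    def test_constant_variable_undefined(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1, 2, 3, 4]})
        with pytest.raises(UndefinedStatisticError):
            ld.correlate_gene_stats(df, "x", "y")
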