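"""GLM association, empirical p-values, FDR arithmetic, pathway tests and
metabolic path search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tilingsweep import association as assoc
from tilingsweep.types import MetabolicNetwork


class TestMafFilter:
    def test_five_percent_boundary_at_54_accessions(self):
        geno = pd.DataFrame(
            [[1] * 2 + [0] * 52,    # 2 carriers: MAF 0.037, removed
             [1] * 3 + [0] * 51,    # 3 carriers: MAF 0.056, retained
             [0] * 54],             # monomorphic, removed
            index=["a", "b", "c"])
        out = assoc.maf_filter(geno, 0.05)
        assert list(out.index) == ["b"]

    def test_zero_threshold_keeps_all_polymorphic(self):
        geno = pd.DataFrame([[1, 0, 0, 0], [0, 0, 0, 0]], index=["a", "b"])
        assert list(assoc.maf_filter(geno, 0.0).index) == ["a"]


def _ols_normal_equations(x, y):
    """Independent textbook oracle: solve the normal equations directly."""
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    resid = y - x @ beta
    return beta, float(resid @ resid)


class TestFitGlm:
    def test_one_way_anova_arithmetic(self):
        trait = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        marker = pd.Series([0, 0, 0, 1, 1, 1])
        fit = assoc.fit_glm(trait, marker)
        assert fit.fscore == pytest.approx(13.5)
        assert fit.lsmeans[0] == pytest.approx(2.0)
        assert fit.lsmeans[1] == pytest.approx(5.0)

    def test_orthogonal_marker_gives_null_f(self, rng):
        q = pd.DataFrame({"Q1": [0.2, 0.8, 0.2, 0.8, 0.2, 0.8],
                          "Q2": [0.8, 0.2, 0.8, 0.2, 0.8, 0.2]})
        trait = pd.Series(q["Q1"] * 2.0)  # trait depends on Q only
        marker = pd.Series([0, 0, 1, 1, 0, 1])
        fit = assoc.fit_glm(trait, marker, q=q)
        assert fit.fscore == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_oracle_on_random_designs(self):
        for seed in range(25):
            r = np.random.default_rng(seed)
            n = int(r.integers(12, 30))
            marker = pd.Series(r.integers(0, 2, n))
            if marker.sum() < 2 or marker.sum() > n - 2:
                continue
            env = pd.Series(r.integers(0, 2, n).astype(str))
            q = pd.DataFrame(r.dirichlet(np.ones(3), n),
                             columns=["Q1", "Q2", "Q3"])
            trait = pd.Series(r.normal(0, 1, n) + marker * 0.8)
            fit = assoc.fit_glm(trait, marker, q, env)
            x_full, _ = assoc._design(marker.to_numpy(float),
                                      env.to_numpy(), q.to_numpy())
            _, ssr_full = _ols_normal_equations(x_full, trait.to_numpy())
            _, ssr_red = _ols_normal_equations(x_full[:, :-1], trait.to_numpy())
            df = n - x_full.shape[1]
            expect = (ssr_red - ssr_full) / (ssr_full / df)
            assert fit.fscore == pytest.approx(expect, rel=1e-8)

    def test_singular_design_names_collinear_columns(self):
        trait = pd.Series([1.0, 2.0, 3.0, 4.0])
        marker = pd.Series([0, 0, 1, 1])
        env = pd.Series(["a", "a", "b", "b"])  # aliased with the marker
        with pytest.raises(assoc.SingularDesignError, match="marker"):
            assoc.fit_glm(trait, marker, env=env)

    def test_monomorphic_marker_rejected(self):
        with pytest.raises(assoc.SingularDesignError):
            assoc.fit_glm(pd.Series([1.0, 2.0, 3.0]), pd.Series([1, 1, 1]))


class TestEmpiricalP:
    def test_rank_definition(self):
        scores = np.arange(1000, dtype=float)
        p = assoc.empirical_pvalues(scores)
        assert p[np.argmax(scores)] == pytest.approx(1 / 1000)
        assert p[np.argmin(scores)] == pytest.approx(1.0)

    def test_all_ties_give_one(self):
        p = assoc.empirical_pvalues(np.full(7, 3.3))
        np.testing.assert_allclose(p, 1.0)

    def test_matches_sort_then_rank_oracle(self, rng):
        scores = rng.normal(0, 1, 500)
        scores[rng.integers(0, 500, 30)] = scores[0]  # inject ties
        p = assoc.empirical_pvalues(scores)
        for i in rng.integers(0, 500, 40):
            assert p[i] == pytest.approx((scores >= scores[i]).mean())


class TestFdrEstimate:
    def test_published_scan_arithmetic(self):
        fdr = assoc.estimate_fdr(612_249, 9, 1e-3, 12_189)
        assert round(fdr) == 45

    def test_pure_null_yields_100_percent(self):
        assert assoc.estimate_fdr(1000, 1, 0.05, 50) == 100.0

    def test_excess_expectation_caps_with_warning(self):
        with pytest.warns(UserWarning):
            assert assoc.estimate_fdr(1000, 1, 0.05, 10) == 100.0

    def test_alpha_zero_limit(self):
        assert assoc.estimate_fdr(1000, 9, 0.0, 10) == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(1, 10))
    def test_scale_invariance(self, k):
        a = assoc.estimate_fdr(5000, 3, 1e-3, 200)
        b = assoc.estimate_fdr(5000 * k, 3, 1e-3, 200 * k)
        assert a == pytest.approx(b)


def _toy_network() -> MetabolicNetwork:
    # chain: A -> B -> D, with a currency-only shortcut A -> (ATP) -> E
    reactions = pd.DataFrame([
        {"reaction_id": "R1", "substrates": ("A",), "products": ("B", "ATP")},
        {"reaction_id": "R2", "substrates": ("B",), "products": ("D",)},
        {"reaction_id": "R3", "substrates": ("ATP",), "products": ("E",)},
    ])
    return MetabolicNetwork(
        reactions=reactions,
        gene_reactions={"g1": ("R1",), "g2": ("R2",)},
        gene_pathway={"g1": "P1", "g2": "P2"},
        currency=frozenset({"ATP", "H2O"}))


class TestMetabolicPath:
    def test_direct_product_is_one_hop(self):
        assert assoc.min_metabolic_path("g1", "B", _toy_network()) == 1

    def test_two_reaction_chain(self):
        assert assoc.min_metabolic_path("g1", "D", _toy_network()) == 2

    def test_currency_only_route_is_unreachable(self):
        assert assoc.min_metabolic_path("g1", "E", _toy_network()) is None

    def test_unknown_gene_and_metabolite_raise(self):
        with pytest.raises(KeyError):
            assoc.min_metabolic_path("nope", "B", _toy_network())
        with pytest.raises(KeyError):
            assoc.min_metabolic_path("g1", "nope", _toy_network())

    def test_matches_exhaustive_enumeration_on_small_networks(self, rng):
        """BFS distance equals brute-force enumeration over all reaction
        chains on random networks of <= 8 reactions."""
        from itertools import permutations

        for seed in range(12):
            r = np.random.default_rng(seed)
            comps = [f"C{i}" for i in range(6)]
            rx = []
            for k in range(int(r.integers(3, 9))):
                subs = tuple(r.choice(comps, r.integers(1, 3), replace=False))
                prods = tuple(r.choice(comps, r.integers(1, 3), replace=False))
                rx.append({"reaction_id": f"R{k}", "substrates": subs,
                           "products": prods})
            net = MetabolicNetwork(
                reactions=pd.DataFrame(rx),
                gene_reactions={"g": ("R0",)},
                gene_pathway={"g": "P"}, currency=frozenset({"C5"}))

            def compounds_of(rxrow):
                return {c for c in (*rxrow["substrates"], *rxrow["products"])
                        if c != "C5"}

            # brute force: shortest chain R0, Ri1, ..., Rik sharing
            # non-currency compounds consecutively, ending at the target
            def brute(target):
                best = None
                others = [row for row in rx if row["reaction_id"] != "R0"]
                for k in range(0, len(others) + 1):
                    for perm in permutations(others, k):
                        chain = [rx[0], *perm]
                        ok = all(compounds_of(a) & compounds_of(b)
                                 for a, b in zip(chain, chain[1:]))
                        if ok and target in compounds_of(chain[-1]):
                            ln = len(chain)
                            best = ln if best is None else min(best, ln)
                    if best is not None and best <= k:
                        break
                return best

            for target in ("C1", "C3"):
                known = any(target in compounds_of(row) for row in rx)
                if not known:
                    continue
                assert assoc.min_metabolic_path("g", target, net) == brute(target)


class TestPathwayTests:
    def test_bh_textbook_arithmetic(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, 0.04)

    def test_extreme_separation_reaches_minimal_p(self):
        fits = pd.DataFrame({
            "site": [f"s{i}" for i in range(12)],
            "trait": "t",
            "fscore": [9.0] * 4 + [1.0] * 8,
        })
        site_genes = pd.Series(["gA"] * 4 + ["gB"] * 8,
                               index=[f"s{i}" for i in range(12)])
        net = MetabolicNetwork(
            reactions=pd.DataFrame([{"reaction_id": "R1",
                                     "substrates": ("A",), "products": ("B",)}]),
            gene_reactions={"gA": ("R1",), "gB": ("R1",)},
            gene_pathway={"gA": "P1", "gB": "P2"}, currency=frozenset())
        out = assoc.pathway_overrepresentation(fits, site_genes, net,
                                               ["P1", "P2"]).set_index("pathway")
        # complete separation: P1 at the smallest p attainable for (4, 8),
        # the complementary pathway at the opposite tail
        assert out.loc["P1", "p"] < 0.005
        assert out.loc["P2", "p"] > 0.99

    def test_null_pathway_u_centred(self, rng):
        """Pathway scores drawn from the background distribution give a
        U statistic near its null mean over seeds."""
        us = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            scores = r.normal(0, 1, 60)
            fits = pd.DataFrame({"site": [f"s{i}" for i in range(60)],
                                 "trait": "t", "fscore": scores})
            genes = pd.Series(np.where(np.arange(60) < 20, "gA", "gB"),
                              index=fits["site"])
            net = MetabolicNetwork(
                reactions=pd.DataFrame([{"reaction_id": "R1",
                                         "substrates": ("A",),
                                         "products": ("B",)}]),
                gene_reactions={"gA": ("R1",), "gB": ("R1",)},
                gene_pathway={"gA": "P1", "gB": "P2"}, currency=frozenset())
            out = assoc.pathway_overrepresentation(fits, genes, net, ["P1"])
            us.append(out.iloc[0]["u"] / (20 * 40))
        assert abs(np.mean(us) - 0.5) < 0.06

    def test_geneset_shift_degenerate_and_power(self, rng):
        fits = pd.DataFrame({"fscore": [2.0, 2.0]})
        assert assoc.geneset_score_shift(fits, np.array([True, False])) == 1.0
        scores = np.concatenate([rng.normal(5, 1, 60), rng.normal(0, 1, 60)])
        fits = pd.DataFrame({"fscore": scores})
        in_set = np.arange(120) < 60
        assert assoc.geneset_score_shift(fits, in_set) < 1e-4


class TestDensityCorrelation:
    def _inputs(self, fvals, positions, window=1000, chrom_bp=10_000):
        fits = pd.DataFrame({"site": [f"s{i}" for i in range(len(fvals))],
                             "fscore": fvals})
        sites = pd.DataFrame({"site": fits["site"], "chrom": "chr1",
                              "pos": positions})
        genes = pd.DataFrame({"chrom": "chr1",
                              "start": np.arange(0, chrom_bp, window),
                              "end": np.arange(0, chrom_bp, window)
                              + np.linspace(100, 900, chrom_bp // window)})
        return fits, sites, genes, {"chr1": chrom_bp}, window

    def test_monotone_and_antitone_identities(self):
        # one site per window, F proportional to that window's gene bp
        dens = np.linspace(100, 900, 10)
        pos = np.arange(10) * 1000 + 50
        fits, sites, genes, bp, w = self._inputs(dens, pos)
        out = assoc.density_fscore_correlation(fits, sites, genes, bp, w)
        assert out.iloc[0]["rho"] == pytest.approx(1.0)
        fits2, *_ = self._inputs(dens[::-1], pos)
        out2 = assoc.density_fscore_correlation(fits2, sites, genes, bp, w)
        assert out2.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_null_correlation_small_over_seeds(self):
        rhos = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            pos = np.arange(10) * 1000 + 50
            fits, sites, genes, bp, w = self._inputs(r.normal(5, 1, 10), pos)
            out = assoc.density_fscore_correlation(fits, sites, genes, bp, w)
            rhos.append(out.iloc[0]["rho"])
        assert abs(np.mean(rhos)) < 0.2


class TestScanTypeIError:
    def test_empirical_p_fraction_matches_alpha(self, rng):
        """Pooled empirical p-values: the fraction below alpha equals alpha
        up to rank granularity (the scan's calibration property)."""
        scores = rng.chisquare(1, 2000)
        p = assoc.empirical_pvalues(scores)
        for alpha in (0.01, 0.05, 0.1):
            assert (p <= alpha).mean() == pytest.approx(alpha, abs=2 / 2000)
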