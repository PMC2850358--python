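"""PHS scan components: genetic map, sharing lengths, standardisation,
pruning, windows, geography and region descriptors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tilingsweep import sweep as swp
from tilingsweep.types import ConfigError, DataError


def _gmap_linear(rate=4e-6, chroms=("chr1",), span=1_000_000):
    bp = np.linspace(0, span, 20).astype(int)
    markers = pd.concat([
        pd.DataFrame({"chrom": c, "bp": bp, "cm": bp * rate})
        for c in chroms])
    return swp.fit_genetic_map(markers, degree=1)


def _data(genotypes: np.ndarray, positions=None, chrom="chr1",
          cm_rate=1.0):
    """SharingData from a raw genotype array with unit-slope genetic map."""
    n_sites = genotypes.shape[0]
    if positions is None:
        positions = np.arange(n_sites)
    geno = pd.DataFrame(genotypes,
                        index=[f"s{i}" for i in range(n_sites)],
                        columns=[f"A{j}" for j in range(genotypes.shape[1])])
    sites = pd.DataFrame({"site": geno.index, "chrom": chrom,
                          "pos": positions})
    markers = pd.DataFrame({"chrom": chrom,
                            "bp": np.linspace(0, max(positions) + 1, 10),
                            "cm": np.linspace(0, max(positions) + 1, 10)
                            * cm_rate})
    gmap = swp.fit_genetic_map(markers, degree=1)
    return swp.compute_sharing(geno, gmap, sites)


class TestGeneticMap:
    def test_exact_linear_recovery(self):
        gmap = _gmap_linear(rate=4e-6)
        assert gmap.rmse["chr1"] == pytest.approx(0.0, abs=1e-6)
        got = gmap.evaluate("chr1", np.array([0, 500_000]))
        assert got[1] - got[0] == pytest.approx(2.0, rel=1e-6)

    def test_constant_map_rejected(self):
        markers = pd.DataFrame({"chrom": "chr1", "bp": [0, 100, 200],
                                "cm": [1.0, 1.0, 1.0]})
        with pytest.raises(DataError):
            swp.fit_genetic_map(markers, degree=0)

    def test_insufficient_markers_rejected(self):
        markers = pd.DataFrame({"chrom": "chr1", "bp": [0, 100],
                                "cm": [0.0, 1.0]})
        with pytest.raises(DataError):
            swp.fit_genetic_map(markers, degree=3)

    def test_noisy_cubic_truth_recovered(self):
        """Polynomial fit recovers a cubic map within tolerance over seeds."""
        errs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            bp = np.linspace(0, 1e6, 60)
            cm_true = 4e-6 * bp + 1e-18 * bp ** 3
            markers = pd.DataFrame({"chrom": "chr1", "bp": bp.astype(int),
                                    "cm": cm_true + r.normal(0, 0.05, 60)})
            gmap = swp.fit_genetic_map(markers, degree=3)
            pred = gmap.evaluate("chr1", bp)
            errs.append(np.sqrt(np.mean((pred - (cm_true - cm_true.min())) ** 2)))
        assert np.mean(errs) < 0.1

    def test_evaluation_is_monotone(self):
        r = np.random.default_rng(5)
        markers = pd.DataFrame({"chrom": "chr1",
                                "bp": np.linspace(0, 1e5, 10).astype(int),
                                "cm": np.sort(r.random(10))})
        gmap = swp.fit_genetic_map(markers, degree=3)
        out = gmap.evaluate("chr1", np.linspace(0, 1e5, 200))
        assert (np.diff(out) >= 0).all()


class TestSharingLength:
    def test_toy_run_convention(self):
        # 4 markers at cM (0,1,2,3); pattern same,same,diff,same at x = 2nd
        g = np.array([[0, 0], [1, 1], [0, 1], [1, 1]], dtype=np.int8)
        data = _data(g)
        assert swp.sharing_length(data, 0, 1, 1) == pytest.approx(1.0)

    def test_discordant_at_focus_is_zero(self):
        g = np.array([[0, 0], [1, 0], [0, 0]], dtype=np.int8)
        data = _data(g)
        assert swp.sharing_length(data, 0, 1, 1) == 0.0

    def test_identical_pair_spans_chromosome(self):
        r = np.random.default_rng(3)
        col = r.integers(0, 2, 30).astype(np.int8)
        other = r.integers(0, 2, 30).astype(np.int8)
        g = np.column_stack([col, col, other])
        data = _data(g)
        assert swp.sharing_length(data, 0, 1, 10) == pytest.approx(29.0)

    def test_same_accession_rejected(self):
        g = np.zeros((4, 3), np.int8)
        g[0, 0] = 1
        data = _data(g)
        with pytest.raises(ValueError):
            swp.sharing_length(data, 1, 1, 0)


def _brute_phs(geno: np.ndarray, cm: np.ndarray, x: int, allele: int,
               form="difference") -> float:
    """Independent O(n^2 m) enumeration oracle for raw PHS."""
    n_sites, n_acc = geno.shape
    zmat = {}
    for i in range(n_acc):
        for j in range(i + 1, n_acc):
            z = np.zeros(n_sites)
            for s in range(n_sites):
                if geno[s, i] != geno[s, j]:
                    continue
                lo = s
                while lo > 0 and geno[lo - 1, i] == geno[lo - 1, j]:
                    lo -= 1
                hi = s
                while hi < n_sites - 1 and geno[hi + 1, i] == geno[hi + 1, j]:
                    hi += 1
                z[s] = cm[hi] - cm[lo]
            if z.std(ddof=1) == 0:
                continue  # zero-variance pairs are excluded by convention
            zmat[(i, j)] = (z - z.mean()) / z.std(ddof=1)
    carriers = [k for k in range(n_acc) if geno[x, k] == allele]
    cz = [zmat[(i, j)][x] for a, i in enumerate(carriers)
          for j in carriers[a + 1:] if (i, j) in zmat]
    allz = [zmat[p][x] for p in zmat]
    if form == "single":
        return float(np.mean(cz))
    return float(np.mean(cz) - np.mean(allz))


FIXTURE_HAPLOTYPES = np.array([
    # 4 haplotypes over 12 markers; haplotypes 0/1 share a long block
    [0, 1, 1, 0, 1, 1, 1, 0, 0, 1, 0, 1],
    [0, 1, 1, 0, 1, 1, 1, 0, 0, 0, 1, 1],
    [1, 0, 1, 1, 0, 1, 0, 1, 0, 0, 1, 0],
    [0, 0, 0, 1, 1, 0, 1, 1, 1, 0, 0, 1],
], dtype=np.int8).T


class TestPhs:
    def test_monomorphic_site_difference_form_is_zero(self):
        r = np.random.default_rng(2)
        g = r.integers(0, 2, (15, 6)).astype(np.int8)
        g[7] = 0  # all accessions carry allele 0: carrier pairs = all pairs
        data = _data(g)
        assert swp.phs(data, 7, 0) == pytest.approx(0.0, abs=1e-12)

    def test_fixture_matches_enumeration_oracle(self):
        data = _data(FIXTURE_HAPLOTYPES)
        cm = np.arange(12, dtype=float)
        for x in (2, 5, 8):
            for allele in (0, 1):
                if (FIXTURE_HAPLOTYPES[x] == allele).sum() < 2:
                    continue
                expect = _brute_phs(FIXTURE_HAPLOTYPES, cm, x, allele)
                assert swp.phs(data, x, allele) == pytest.approx(expect, rel=1e-9)

    def test_random_panels_match_oracle_both_forms(self):
        for seed in range(4):
            r = np.random.default_rng(seed)
            g = r.integers(0, 2, (20, 8)).astype(np.int8)
            data = _data(g)
            cm = np.arange(20, dtype=float)
            for x in (5, 13):
                for form in ("difference", "single"):
                    allele = int(g[x].sum() >= 4)
                    if (g[x] == allele).sum() < 2:
                        continue
                    expect = _brute_phs(g, cm, x, allele, form)
                    assert swp.phs(data, x, allele, form=form) == pytest.approx(
                        expect, rel=1e-9)

    def test_scan_agrees_with_single_site_api(self):
        data = _data(FIXTURE_HAPLOTYPES)
        scan = swp.phs_scan(data, min_maf=0.05)
        for _, row in scan.iterrows():
            assert row["raw_phs"] == pytest.approx(
                swp.phs(data, int(row["site_idx"]), int(row["allele"])),
                rel=1e-9)

    def test_too_few_carriers_rejected(self):
        g = np.zeros((6, 4), np.int8)
        g[:, 0] = [1, 0, 0, 0, 0, 0]
        data = _data(g)
        with pytest.raises(DataError):
            swp.phs(data, 0, 1)


class TestStandardisation:
    def _scores(self, raw, carriers, n_acc=20):
        return pd.DataFrame({
            "site": [f"s{i}" for i in range(len(raw))],
            "site_idx": np.arange(len(raw)),
            "chrom": "chr1", "pos": np.arange(len(raw)),
            "allele": 1, "carriers": carriers,
            "freq": np.asarray(carriers) / n_acc,
            "raw_phs": raw, "mean_sharing_cm": 1.0,
        })

    def test_class_median_centred(self):
        raw = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = swp.standardize_scores(self._scores(raw, [5] * 5), min_class=2)
        centre = out[out["raw_phs"] == 3.0]["standardized"].iloc[0]
        assert centre == pytest.approx(0.0)
        top = out[out["raw_phs"] == 5.0]["standardized"].iloc[0]
        assert top == pytest.approx(2.0 / np.std(raw, ddof=1))
        assert top == pytest.approx(1.265, abs=1e-3)

    def test_location_invariance(self):
        raw = np.array([0.3, 1.1, 2.7, 0.9, 1.8])
        a = swp.standardize_scores(self._scores(raw, [6] * 5), min_class=2)
        b = swp.standardize_scores(self._scores(raw + 10.0, [6] * 5),
                                   min_class=2)
        np.testing.assert_allclose(a["standardized"], b["standardized"],
                                   atol=1e-12)

    def test_sparse_counts_fall_back_to_frequency_bins(self):
        raw = np.arange(10, dtype=float)
        carriers = [4, 5] * 5  # each exact count too sparse for min_class=20
        out = swp.standardize_scores(self._scores(raw, carriers, n_acc=100))
        # counts 4 and 5 share the 0.04-0.05 frequency neighbourhood bins
        assert np.isfinite(out["standardized"]).all()

    def test_null_classes_have_median_zero_sd_one(self, rng):
        raw = rng.normal(0, 2, 300)
        carriers = rng.integers(5, 8, 300)
        out = swp.standardize_scores(self._scores(raw, carriers, n_acc=40),
                                     min_class=20)
        for _, sub in out.groupby("carriers"):
            s = sub["standardized"]
            assert abs(np.median(s)) < 0.15
            assert np.std(s, ddof=1) == pytest.approx(1.0, abs=0.15)


class TestPruning:
    def _scores_for(self, geno: pd.DataFrame, standardized):
        return pd.DataFrame({
            "site": geno.index, "site_idx": np.arange(len(geno)),
            "chrom": "chr1", "pos": np.arange(len(geno)) * 100,
            "allele": 1,
            "carriers": geno.sum(axis=1).to_numpy(),
            "freq": geno.mean(axis=1).to_numpy(),
            "raw_phs": standardized, "standardized": standardized,
        })

    def test_identical_neighbours_drop_lower_scorer(self):
        g = pd.DataFrame([[1, 1, 0, 0], [1, 1, 0, 0], [0, 1, 1, 0]],
                         index=["a", "b", "c"])
        scores = self._scores_for(g, [1.0, 2.0, 0.5])
        out = swp.ld_prune(scores, g)
        assert list(out["site"]) == ["b", "c"]

    def test_negative_r_pairs_kept(self):
        g = pd.DataFrame([[1, 1, 1, 0, 0, 0, 0, 0, 0, 1],
                          [0, 0, 0, 1, 1, 1, 1, 1, 1, 0]],
                         index=["a", "b"])
        r = np.corrcoef(g.loc["a"], g.loc["b"])[0, 1]
        assert r < 0 and r * r > 0.5
        out = swp.ld_prune(self._scores_for(g, [1.0, 2.0]), g)
        assert len(out) == 2

    def test_weak_ld_kept(self, rng):
        g = pd.DataFrame(rng.integers(0, 2, (2, 40)), index=["a", "b"])
        r = np.corrcoef(g.loc["a"], g.loc["b"])[0, 1]
        if r * r <= 0.5:  # overwhelmingly likely for independent rows
            out = swp.ld_prune(self._scores_for(g, [1.0, 2.0]), g)
            assert len(out) == 2

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_pruning_idempotent(self, seed):
        r = np.random.default_rng(seed)
        g = pd.DataFrame(r.integers(0, 2, (12, 10)),
                         index=[f"s{i}" for i in range(12)])
        scores = self._scores_for(g, r.normal(0, 1, 12))
        once = swp.ld_prune(scores, g)
        twice = swp.ld_prune(once, g)
        assert list(once["site"]) == list(twice["site"])


class TestWindowScan:
    def _scores(self, standardized, positions=None, chrom="chr1"):
        n = len(standardized)
        return pd.DataFrame({
            "site": [f"s{i}" for i in range(n)], "site_idx": np.arange(n),
            "chrom": chrom,
            "pos": positions if positions is not None else np.arange(n) * 100,
            "allele": 1, "carriers": 10, "freq": 0.3,
            "raw_phs": standardized, "standardized": standardized,
        })

    def test_no_outlier_concentration_no_candidates(self, rng):
        scores = self._scores(rng.normal(0, 1, 400))
        assert swp.window_scan(scores, window=100, offset=5,
                               outlier_quantile=0.05,
                               min_proportion=0.45) == []

    def test_45_percent_rule_is_strict(self):
        # tie-free background; exactly 45 outliers in the first window is
        # not a candidate, 46 is
        base = np.linspace(-3.0, -1.0, 1000)
        scores = self._scores(base.copy())
        scores.loc[:44, "standardized"] = 100.0
        assert swp.window_scan(scores, window=100, offset=100,
                               outlier_quantile=45 / 1000,
                               min_proportion=0.45) == []
        scores.loc[:45, "standardized"] = 100.0
        out = swp.window_scan(scores, window=100, offset=100,
                              outlier_quantile=46 / 1000,
                              min_proportion=0.45)
        assert len(out) == 1

    def test_window_count_arithmetic(self):
        # 3000 SFPs, window 1000, offset 50 -> floor((3000-1000)/50)+1 = 41
        n, window, offset = 3000, 1000, 50
        assert len(range(0, n - window + 1, offset)) == 41

    def test_window_larger_than_scan_rejected(self, rng):
        scores = self._scores(rng.normal(0, 1, 50))
        with pytest.raises(ConfigError):
            swp.window_scan(scores, window=100, offset=5)

    def test_overlapping_windows_merge_and_focal_is_max(self):
        vals = np.zeros(600)
        vals[200:320] = 50.0
        scores = self._scores(vals)
        vals2 = scores["standardized"].to_numpy()
        vals2[250] = 99.0
        scores["standardized"] = vals2
        out = swp.window_scan(scores, window=100, offset=10,
                              outlier_quantile=0.2, min_proportion=0.45)
        assert len(out) == 1
        region = out[0]
        assert region.focal_pos == 250 * 100
        assert region.start <= 200 * 100 <= region.end


class TestRegionDescriptors:
    def test_reference_table_interval_arithmetic(self, reference_sweep_table):
        t = reference_sweep_table
        lengths = t["to"] - t["from"]
        np.testing.assert_array_equal(
            lengths.to_numpy(), t["length_avg_haplotype_sharing"].to_numpy())

    def test_identical_carriers_span_chromosome(self):
        r = np.random.default_rng(8)
        col = r.integers(0, 2, 40).astype(np.int8)
        g = np.column_stack([col, col, col,
                             r.integers(0, 2, 40),
                             r.integers(0, 2, 40)]).astype(np.int8)
        x = 20
        g[x, :3] = 1
        g[x, 3:] = 0
        data = _data(g)
        region = swp.SweepRegion(
            name="SR1", chrom="chr1", start=0, end=39,
            focal_site=f"s{x}", focal_pos=x, selected_allele=1,
            n_sites=40, max_score=5.0)
        out = swp.avg_sharing_interval(region, data)
        assert out.sharing_from == 0
        assert out.sharing_to == 39
        assert out.sharing_length == 39


class TestGeography:
    def test_haversine_identity_and_known_distance(self):
        assert swp.haversine_km(48.8, 8.2, 48.8, 8.2) == 0.0
        # one degree of latitude is ~111 km
        assert swp.haversine_km(48.0, 8.0, 49.0, 8.0) == pytest.approx(111.2, abs=1)

    def test_extreme_clustering_detected(self):
        geo = pd.DataFrame({
            "accession": [f"A{i}" for i in range(30)],
            "lat": [45.0] * 10 + list(np.linspace(20, 70, 20)),
            "lon": [8.0] * 10 + list(np.linspace(-20, 80, 20)),
        })
        p = swp.geographic_clustering([f"A{i}" for i in range(10)], geo,
                                      n_shuffles=200, seed=1)
        assert p < 1e-6

    def test_deterministic_given_seed(self):
        r = np.random.default_rng(0)
        geo = pd.DataFrame({"accession": [f"A{i}" for i in range(20)],
                            "lat": r.uniform(35, 60, 20),
                            "lon": r.uniform(-10, 40, 20)})
        carriers = [f"A{i}" for i in range(0, 20, 3)]
        p1 = swp.geographic_clustering(carriers, geo, n_shuffles=100, seed=42)
        p2 = swp.geographic_clustering(carriers, geo, n_shuffles=100, seed=42)
        assert p1 == p2

    def test_single_carrier_skipped(self):
        geo = pd.DataFrame({"accession": ["A0", "A1"], "lat": [1.0, 2.0],
                            "lon": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            assert np.isnan(swp.geographic_clustering(["A0"], geo, seed=0))


class TestSweepTraitAssociation:
    def test_single_region_single_trait_shape(self):
        r = np.random.default_rng(4)
        geno = pd.DataFrame(r.integers(0, 2, (10, 20)),
                            index=[f"s{i}" for i in range(10)],
                            columns=[f"A{j}" for j in range(20)])
        phen = pd.DataFrame({"accession": [f"A{j}" for j in range(20)],
                             "experiment": "E1",
                             "trait": r.normal(0, 1, 20)})
        region = swp.SweepRegion(name="SR1", chrom="chr1", start=0, end=900,
                                 focal_site="s5", focal_pos=500,
                                 selected_allele=1, n_sites=10, max_score=3.0)
        out = swp.sweep_trait_association([region], geno, phen)
        assert len(out["table"]) == 1
        assert out["table"].iloc[0]["region"] == "SR1"
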