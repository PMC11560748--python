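"""Diversity, ordination and distance statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from soilsqi.diversity import (DistanceSqiRegression, alpha_diversity,
                               bray_curtis, composition_by_rank,
                               distance_vs_sqi_regression, mantel, pcoa, rda,
                               spearman_panel)
from soilsqi.simulate import CommunityMatrix


def make_cm(counts: np.ndarray, phyla=None, domain="bacteria") -> CommunityMatrix:
    counts = np.asarray(counts)
    otus = [f"OTU{i}" for i in range(counts.shape[1])]
    samples = [f"S{i}" for i in range(counts.shape[0])]
    tax = pd.DataFrame(
        {"domain": domain,
         "phylum": phyla or ["P1"] * len(otus),
         "genus": [f"g{i}" for i in range(len(otus))]},
        index=pd.Index(otus, name="otu_id"))
    return CommunityMatrix(
        counts=pd.DataFrame(counts, index=samples, columns=otus),
        taxonomy=tax, domain=domain)


def chao1_brute(v: np.ndarray) -> float:
    """Frequency-of-frequencies recomputation of bias-corrected Chao1."""
    v = v[v > 0]
    f1 = int((v == 1).sum())
    f2 = int((v == 2).sum())
    return len(v) + f1 * (f1 - 1) / (2.0 * (f2 + 1))


class TestAlpha:
    def test_chao1_hand_case(self):
        out = alpha_diversity(make_cm([[1, 1, 2, 2, 5]]))
        assert out.loc[0, "chao1"] == pytest.approx(5 + 2 * 1 / (2 * 3))
        assert out.loc[0, "observed_otus"] == 5

    def test_even_two_species_community(self):
        out = alpha_diversity(make_cm([[10, 10]]))
        assert out.loc[0, "shannon"] == pytest.approx(np.log(2))
        assert out.loc[0, "pielou"] == pytest.approx(1.0)

    def test_no_singletons_chao1_equals_observed(self):
        out = alpha_diversity(make_cm([[3, 4, 5, 2]]))
        assert out.loc[0, "chao1"] == pytest.approx(4.0)

    def test_chao1_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(42)
        counts = rng.poisson(1.2, size=(1000, 40))
        counts[:, 0] += 1   # no empty samples
        out = alpha_diversity(make_cm(counts))
        expected = np.array([chao1_brute(row) for row in counts])
        assert np.allclose(out["chao1"].to_numpy(), expected)
        assert (out["chao1"] >= out["observed_otus"] - 1e-12).all()
        assert out["pielou"].between(0, 1).all()

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="S1"):
            alpha_diversity(make_cm([[1, 2], [0, 0]]))


class TestComposition:
    def test_single_phylum_is_total(self):
        rel = composition_by_rank(make_cm([[5, 5]], phyla=["P1", "P1"]))
        assert rel["P1"].tolist() == [1.0]

    def test_hand_normalization(self):
        rel = composition_by_rank(
            make_cm([[30, 70, 100]], phyla=["A", "A", "B"]))
        assert rel.loc["S0", "A"] == pytest.approx(0.5)
        assert rel.loc["S0", "B"] == pytest.approx(0.5)

    def test_treatment_means_sum_to_one(self, communities, chem):
        tr = chem.set_index("sample_id")["treatment"]
        comp = composition_by_rank(communities["bacteria"], "phylum", tr)
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_control_pseudomonadota_near_target(self):
        # scenario targets control Pseudomonadota at 20%: realized replicate
        # mean within +/-5 percentage points averaged over seeds
        from soilsqi import ScenarioSpec, simulate_scenario

        vals = []
        for seed in range(10):
            chem, comms = simulate_scenario(ScenarioSpec(seed=seed))
            tr = chem.set_index("sample_id")["treatment"]
            comp = composition_by_rank(comms["bacteria"], "phylum", tr)
            vals.append(comp.loc["CK", "Pseudomonadota"])
        assert abs(np.mean(vals) - 0.20) < 0.05


class TestBrayCurtis:
    def test_hand_cases(self):
        cm = make_cm([[5, 5, 0], [0, 5, 5], [5, 5, 0], [4, 0, 0]])
        d = bray_curtis(cm)
        assert d["S0", "S2"] == pytest.approx(0.0)      # identical profiles
        assert d["S1", "S3"] == pytest.approx(1.0)      # disjoint support
        assert d["S0", "S1"] == pytest.approx(0.5)      # half-overlap

    def test_metric_properties_random(self):
        rng = np.random.default_rng(0)
        cm = make_cm(rng.integers(0, 50, size=(10, 20)) + (rng.random((10, 20)) < 0.1))
        d = bray_curtis(cm).data
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 1 + 1e-12)).all()


class TestPcoa:
    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=[f"S{i}" for i in range(7)]))
        emb = res.coordinates.to_numpy()
        d2 = squareform(pdist(emb))
        assert np.allclose(d, d2, atol=1e-9)

    def test_collinear_points_single_axis(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert res.proportion_explained[0] == pytest.approx(100.0)

    def test_permutation_invariant_eigenvalues(self, communities):
        d = bray_curtis(communities["fungi"])
        ids = list(d.ids)
        perm = ids[::-1]
        e1 = pcoa(d).eigenvalues
        e2 = pcoa(d.filter(perm)).eigenvalues
        assert np.allclose(sorted(e1), sorted(e2), atol=1e-9)

    def test_explained_nonincreasing_and_matches_skbio(self, communities):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        d = bray_curtis(communities["bacteria"])
        res = pcoa(d)
        assert (np.diff(res.proportion_explained) <= 1e-9).all()
        ref = skbio_pcoa(d, number_of_dimensions=2)
        assert abs(res.coordinates.iloc[:, 0].abs().to_numpy()
                   - ref.samples.iloc[:, 0].abs().to_numpy()).max() < 1e-6

    def test_degenerate_all_zero(self):
        res = pcoa(DistanceMatrix(np.zeros((3, 3)), ids=list("abc")))
        assert res.warnings


class TestRda:
    def _chem(self, x: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(x, columns=[f"v{i}" for i in range(x.shape[1])])
        df.insert(0, "sample_id", [f"S{i}" for i in range(len(df))])
        return df

    def test_perfect_linear_response_explains_all(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 1))
        comm_raw = np.exp(0.3 * x @ rng.normal(size=(1, 6)))
        comm = comm_raw / comm_raw.sum(axis=1, keepdims=True)
        # response linear in x after Hellinger: construct directly instead
        y = np.sqrt(comm)
        # use squared table so the Hellinger transform returns y itself
        table = pd.DataFrame(y ** 2, index=[f"S{i}" for i in range(12)])
        res = rda(table, self._chem(x), indicators=["v0"])
        # single exponential gradient: most variance captured
        assert res.total_explained > 80.0

    def test_orthogonal_noise_explains_little(self):
        rng = np.random.default_rng(1)
        n = 40
        comm = pd.DataFrame(rng.dirichlet(np.ones(15), size=n),
                            index=[f"S{i}" for i in range(n)])
        chem = self._chem(rng.normal(size=(n, 5)))
        res = rda(comm, chem, indicators=[f"v{i}" for i in range(5)])
        assert res.total_explained < 20.0

    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(2)
        comm = pd.DataFrame(rng.dirichlet(np.ones(8), size=10),
                            index=[f"S{i}" for i in range(10)])
        x = rng.normal(size=(10, 2))
        base = rda(comm, self._chem(x), indicators=["v0", "v1"])
        dup = self._chem(np.column_stack([x, x[:, 0]]))
        res = rda(comm, dup, indicators=["v0", "v1", "v2"])
        assert any("collinear" in w for w in res.warnings)
        assert res.total_explained == pytest.approx(base.total_explained,
                                                    abs=1e-9)


class TestMantel:
    def _dm(self, arr, ids=None):
        return DistanceMatrix(arr, ids=ids or [f"S{i}" for i in range(len(arr))])

    def test_self_correlation_is_one(self, communities):
        d = bray_curtis(communities["fungi"])
        r, p = mantel(d, d, permutations=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_scale_invariance(self, communities):
        d = bray_curtis(communities["fungi"])
        d2 = self._dm(2.0 * d.data, ids=list(d.ids))
        r, _ = mantel(d, d2, permutations=9, seed=0)
        assert r == pytest.approx(1.0)

    def test_constant_matrix_flagged(self):
        d1 = self._dm(1 - np.eye(4))
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(4, 2))
        d2 = self._dm(squareform(pdist(pts)))
        with pytest.raises(ValueError, match="constant"):
            mantel(d1, d2, permutations=9, seed=0)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        n, reps = 10, 400
        rejected = 0
        for i in range(reps):
            d1 = squareform(pdist(rng.normal(size=(n, 3))))
            d2 = squareform(pdist(rng.normal(size=(n, 3))))
            _, p = mantel(self._dm(d1), self._dm(d2), permutations=199,
                          seed=int(rng.integers(2**31)))
            rejected += p < 0.05
        assert 0.03 <= rejected / reps <= 0.07


class TestSpearmanPanel:
    def _setup(self, abundances, env):
        n = len(env)
        counts = np.column_stack([abundances, 100 - abundances]).astype(int)
        cm = make_cm(counts)
        chem = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)],
                             "treatment": "T", "replicate": range(n),
                             "AN": env})
        return cm, chem

    @staticmethod
    def _rho(panel: pd.DataFrame, taxon: str) -> float:
        return panel.set_index("taxon").loc[taxon, "spearman_rho"]

    def test_monotone_gives_unit_rho(self):
        cm, chem = self._setup(np.array([10, 20, 30, 40, 50]),
                               np.array([1.0, 2, 3, 4, 5]))
        panel = spearman_panel(cm, chem, rank="genus", top_n=2,
                               indicators=["AN"])
        assert self._rho(panel, "g0") == pytest.approx(1.0)

    def test_antimonotone_gives_minus_one(self):
        cm, chem = self._setup(np.array([50, 40, 30, 20, 10]),
                               np.array([1.0, 2, 3, 4, 5]))
        panel = spearman_panel(cm, chem, rank="genus", top_n=2,
                               indicators=["AN"])
        assert self._rho(panel, "g0") == pytest.approx(-1.0)

    def test_tied_ranks_match_hand_computation(self):
        # abundances (10,20,20,30,40) vs env (1,2,3,4,5): average ranks
        # (1, 2.5, 2.5, 4, 5) vs (1..5); Pearson of the rank vectors by hand:
        # cov 9.5/4, variances 9.5/4 and 10/4 -> rho = sqrt(9.5/10)
        cm, chem = self._setup(np.array([10, 20, 20, 30, 40]),
                               np.array([1.0, 2, 3, 4, 5]))
        panel = spearman_panel(cm, chem, rank="genus", top_n=2,
                               indicators=["AN"])
        expected = np.sqrt(9.5 / 10)
        assert self._rho(panel, "g0") == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        ab = rng.integers(1, 80, size=8)
        env = rng.normal(size=8)
        cm, chem = self._setup(ab, env)
        base = spearman_panel(cm, chem, rank="genus", top_n=1,
                              indicators=["AN"])
        chem2 = chem.copy()
        chem2["AN"] = np.exp(chem2["AN"])          # strictly monotone
        after = spearman_panel(cm, chem2, rank="genus", top_n=1,
                               indicators=["AN"])
        assert base.loc[0, "spearman_rho"] == pytest.approx(
            after.loc[0, "spearman_rho"])


class TestDistanceSqiRegression:
    def test_proportional_distances_r2_one(self):
        s = pd.Series([1.0, 2.0, 4.0], index=list("abc"))
        diff = np.abs(s.values[:, None] - s.values[None, :])
        dm = DistanceMatrix(diff / diff.max(), ids=list("abc"))
        res = distance_vs_sqi_regression(dm, s, permutations=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_sqi_degenerate(self):
        dm = DistanceMatrix(1 - np.eye(4), ids=list("abcd"))
        res = distance_vs_sqi_regression(
            dm, pd.Series(1.0, index=list("abcd")), permutations=9, seed=0)
        assert isinstance(res, DistanceSqiRegression) and res.degenerate

    def test_coupled_scenario_detects_association(self):
        # community composition and SQI both driven by treatment: the
        # permutation test should find the association in most realizations
        from soilsqi import ScenarioSpec, simulate_scenario

        hits = 0
        seeds = range(12)
        for seed in seeds:
            chem, comms = simulate_scenario(ScenarioSpec(seed=seed))
            alpha = {d: alpha_diversity(c) for d, c in comms.items()}
            from soilsqi.sqi import run_sqi_pipeline

            res = run_sqi_pipeline(chem, alpha)
            tr = chem.set_index("sample_id")["treatment"]
            sqi_per_sample = tr.map(res.sqi)
            reg = distance_vs_sqi_regression(
                bray_curtis(comms["bacteria"]), sqi_per_sample,
                permutations=199, seed=seed)
            hits += reg.p_permutation < 0.05
        assert hits / len(list(seeds)) >= 0.8
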