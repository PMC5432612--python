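import math

import numpy as np
import pytest
from scipy.stats import norm

from paleoks.age_distribution import (
    DECREASING,
    FLAT,
    INCREASING,
    SPARSE,
    KsSample,
    MixtureComponent,
    MixtureFit,
    build_ks_sample,
    classify_wgd_components,
    filter_pairs,
    fit_mixture,
    node_average,
    sizer,
)
from paleoks.codonalign_ks import PairDivergence


def pd_(a, b, ks, ka=0.1):
    return PairDivergence(a, b, ks, ka, 100)


class TestFilterPairs:
    def test_constructed_fixture_counts(self):
        pairs = (
            [pd_("A|t1", "A|x1", 0.5), pd_("A|t2", "A|x2", 0.5)]  # TE
            + [pd_(f"A|z{i}", f"A|w{i}", 0.0) for i in range(3)]  # zero
            + [pd_("A|s1", "A|s2", 2.5)]  # beyond ks_max
            + [pd_(f"A|k{i}", f"A|m{i}", 0.4) for i in range(4)]
        )
        te = {"A|t1", "A|t2"}
        retained, prov = filter_pairs(pairs, te)
        assert len(retained) == 4
        assert (prov["te_removed"], prov["zero_removed"], prov["saturated_removed"]) == (2, 3, 1)

    def test_boundary_ks_2_retained(self):
        retained, _ = filter_pairs([pd_("A|a", "A|b", 2.0)], set())
        assert len(retained) == 1

    def test_saturation_flag_removed(self):
        retained, prov = filter_pairs([pd_("A|a", "A|b", None)], set())
        assert retained == [] and prov["saturated_removed"] == 1

    def test_empty_input(self):
        retained, prov = filter_pairs([], set())
        assert retained == [] and prov["retained"] == 0

    def test_counts_partition_the_input(self, rng):
        pairs = [
            pd_(f"A|a{i}", f"A|b{i}", float(k))
            for i, k in enumerate(rng.uniform(0, 3, size=50))
        ]
        te = {p.gene_a for p in pairs[::7]}
        retained, prov = filter_pairs(pairs, te)
        assert sum(prov.values()) == len(pairs)  # removals + retained partition
        assert set(retained) <= set(pairs)


class TestNodeAverage:
    def test_two_members(self):
        assert node_average([[0, 0.4], [0.4, 0]]) == [0.4]

    def test_three_members_hand_computed(self):
        # a,b merge at 0.1; {a,b} joins c at mean(0.5, 0.5) = 0.5
        mat = [[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]]
        assert sorted(node_average(mat)) == pytest.approx([0.1, 0.5])

    def test_two_recent_pairs_duplicated_anciently(self):
        # two pairs at 0.05 each, all cross distances 0.8
        mat = np.full((4, 4), 0.8)
        np.fill_diagonal(mat, 0.0)
        mat[0, 1] = mat[1, 0] = 0.05
        mat[2, 3] = mat[3, 2] = 0.05
        assert sorted(node_average(mat)) == pytest.approx([0.05, 0.05, 0.8])

    def test_returns_m_minus_1_values(self, rng):
        for m in (2, 3, 5, 8):
            x = rng.uniform(0.05, 1.5, size=(m, m))
            mat = (x + x.T) / 2
            np.fill_diagonal(mat, 0)
            assert len(node_average(mat)) == m - 1

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            node_average([[0, 0.1], [0.3, 0]])


class TestBuildKsSample:
    def test_zero_pairs_collapse_identical_genes(self):
        # a and b are identical transcripts; both at 0.4 from c
        pairs = {
            ("A|a", "A|b"): pd_("A|a", "A|b", 0.0),
            ("A|a", "A|c"): pd_("A|a", "A|c", 0.4),
            ("A|b", "A|c"): pd_("A|b", "A|c", 0.4),
        }
        sample = build_ks_sample("A", {"f1": pairs}, set())
        assert list(sample.values) == pytest.approx([0.4])
        assert sample.provenance["zero_removed"] == 1

    def test_te_family_removed_entirely(self):
        pairs = {("A|a", "A|b"): pd_("A|a", "A|b", 0.4)}
        sample = build_ks_sample("A", {"f1": pairs}, {"A|a"})
        assert len(sample.values) == 0
        assert sample.provenance["te_removed"] == 1

    def test_saturated_node_values_cut(self):
        pairs = {("A|a", "A|b"): pd_("A|a", "A|b", None)}
        sample = build_ks_sample("A", {"f1": pairs}, set())
        assert len(sample.values) == 0
        assert sample.provenance["saturated_removed"] == 1

    def test_multicopy_family_yields_m_minus_1_values(self):
        genes = [f"A|g{i}" for i in range(4)]
        pairs = {}
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                pairs[(a, b)] = pd_(a, b, 0.4)
        sample = build_ks_sample("A", {"f1": pairs}, set())
        assert len(sample.values) == 3
        assert sample.provenance["clustered_collapsed"] == 6 - 3


class TestFitMixture:
    def test_single_lognormal_recovered(self, rng):
        values = np.exp(rng.normal(-1.0, 0.3, size=1000))
        fit = fit_mixture(values, seed=1)
        assert fit.k == 1
        assert abs(fit.components[0].mu_log - (-1.0)) < 0.05

    def test_planted_wgd_component_recovered(self, rng):
        ssd = rng.exponential(0.25, size=1400)
        wgd = np.exp(rng.normal(math.log(0.40), 0.12, size=600))
        values = np.concatenate([ssd[(ssd > 0.01) & (ssd <= 2.0)], wgd])
        fit = fit_mixture(values, seed=2)
        hits = [
            c for c in fit.components if 0.35 <= c.peak_ks <= 0.45 and 0.2 <= c.weight <= 0.4
        ]
        assert hits, [(c.peak_ks, c.weight) for c in fit.components]

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="floor|degenerate"):
            fit_mixture(np.full(100, 0.4))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="30"):
            fit_mixture(np.linspace(0.1, 1, 10))

    def test_weights_sum_to_one_and_bic_identity(self, rng):
        values = np.exp(rng.normal(-0.8, 0.5, size=400))
        fit = fit_mixture(values, seed=3)
        assert sum(c.weight for c in fit.components) == pytest.approx(1.0, abs=1e-9)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + (3 * fit.k - 1) * math.log(fit.n)
        )

    def test_matches_sklearn_likelihood(self, rng):
        """Cross-check: our restarted EM is no worse than sklearn's GMM."""
        sklearn = pytest.importorskip("sklearn.mixture")
        values = np.concatenate(
            [np.exp(rng.normal(-1.5, 0.4, 700)), np.exp(rng.normal(-0.9, 0.15, 300))]
        )
        x = np.log(values).reshape(-1, 1)
        fit = fit_mixture(values, k_max=2, seed=4)
        gm = sklearn.GaussianMixture(2, n_init=5, random_state=0).fit(x)
        ours = fit.loglik if fit.k == 2 else None
        if ours is not None:
            assert ours >= gm.score(x) * len(x) - 1e-3


class TestClassifyWgd:
    def make_fit(self, specs):
        comps = tuple(
            MixtureComponent(w, math.log(peak), 0.2, w * 1000) for w, peak in specs
        )
        return MixtureFit(len(comps), comps, -1.0, 2.0, 1000, 0)

    def test_initial_peak_excluded(self):
        fit = self.make_fit([(0.5, 0.05), (0.3, 0.37), (0.2, 1.7)])
        peaks = [round(c.peak_ks, 2) for c in classify_wgd_components(fit)]
        assert peaks == [0.37, 1.7]

    def test_all_below_cutoff_gives_empty(self):
        fit = self.make_fit([(0.6, 0.03), (0.4, 0.08)])
        assert classify_wgd_components(fit) == []

    def test_tiny_weight_excluded(self):
        fit = self.make_fit([(0.96, 0.05), (0.04, 0.4)])
        assert classify_wgd_components(fit) == []


def brute_force_cell(values, x, h, alpha=0.05, ess_min=5.0):
    """Independent recomputation of one SiZer cell from the definitions."""
    terms = []
    kern = []
    for v in values:
        u = (x - v) / h
        phi = math.exp(-0.5 * u * u) / math.sqrt(2 * math.pi)
        kern.append(phi)
        terms.append(-(x - v) / h**3 * phi)
    if sum(kern) / (1 / math.sqrt(2 * math.pi)) < ess_min:
        return SPARSE
    n = len(values)
    mean = sum(terms) / n
    sd = math.sqrt(sum((t - mean) ** 2 for t in terms) / (n - 1))
    z = norm.ppf(1 - alpha / 2)
    if mean - z * sd / math.sqrt(n) > 0:
        return INCREASING
    if mean + z * sd / math.sqrt(n) < 0:
        return DECREASING
    return FLAT


class TestSizer:
    def test_unimodal_flanks_are_signed(self, rng):
        values = np.clip(rng.normal(0.4, 0.12, size=500), 0.01, 2.0)
        smap = sizer(values)
        h_idx = int(np.argmin(abs(smap.bandwidths - 0.1)))
        left = (smap.x_grid >= 0.2) & (smap.x_grid <= 0.3)
        right = (smap.x_grid >= 0.55) & (smap.x_grid <= 0.8)
        assert (smap.states[h_idx, left] == INCREASING).any()
        assert (smap.states[h_idx, right] == DECREASING).any()

    def test_sparse_far_from_the_data(self, rng):
        values = np.clip(rng.normal(0.1, 0.01, size=30), 0.02, 2.0)
        smap = sizer(values)
        j = int(np.argmin(abs(smap.x_grid - 1.9)))
        assert smap.states[0, j] == SPARSE

    def test_cells_match_brute_force_recomputation(self, rng):
        values = np.clip(rng.normal(0.5, 0.2, size=200), 0.01, 2.0)
        smap = sizer(values)
        for _ in range(10):
            i = int(rng.integers(0, len(smap.bandwidths)))
            j = int(rng.integers(0, len(smap.x_grid)))
            expected = brute_force_cell(values, smap.x_grid[j], smap.bandwidths[i])
            assert smap.states[i, j] == expected

    def test_mirror_symmetry_of_the_estimator(self):
        base = np.array([0.3, 0.5, 0.55, 0.7, 0.9, 1.1] * 10)
        values = np.concatenate([base, 2.0 - base])  # exactly symmetric about 1
        smap = sizer(values)
        flipped = smap.states[:, ::-1]
        swap = np.where(
            flipped == INCREASING, DECREASING, np.where(flipped == DECREASING, INCREASING, flipped)
        )
        # exact up to floating-point ties at cell-state boundaries
        assert (smap.states == swap).mean() > 0.99

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            sizer(np.linspace(0.1, 1, 10))


class TestKsSampleInvariants:
    def test_values_outside_range_rejected(self):
        with pytest.raises(ValueError):
            KsSample("A", np.array([0.5, 2.5]))
        with pytest.raises(ValueError):
            KsSample("A", np.array([0.0, 0.5]))
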