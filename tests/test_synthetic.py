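import numpy as np
import pytest
from scipy import stats

from metabridge.synthetic import (
    CopulaSpec,
    StudyDesign,
    SyntheticStandardSpec,
    default_group_effects,
    make_standard_library,
    pearson_to_spearman,
    simulate_concentration_table,
    spearman_to_pearson,
    synthesize_mixture_spectrum,
)

ONE_GROUP = [("male", "WT", "early")]


def _design(n, reps, seed=0):
    return StudyDesign(
        n_metabolites_blood=n, n_metabolites_csf=n, n_shared=n,
        groups=ONE_GROUP, replicates_per_group=reps, seed=seed,
    )


class TestStandardLibrary:
    def test_each_standard_sums_to_one(self, two_standard_library):
        np.testing.assert_allclose(two_standard_library.matrix.sum(axis=1), 1.0, rtol=1e-12)

    def test_disjoint_standards_nearly_orthogonal(self, two_standard_library):
        s1, s2 = two_standard_library.matrix
        # peaks are >1.5 ppm apart with 0.004 ppm half-widths; only the slow
        # Lorentzian tails overlap, so the cosine similarity is tiny
        cosine = float(s1 @ s2) / np.sqrt(float(s1 @ s1) * float(s2 @ s2))
        assert cosine < 1e-3

    def test_two_equal_peaks_symmetric_about_midpoint(self):
        axis = np.arange(0.5, 9.5, 0.001)
        spec = SyntheticStandardSpec("sym", [(3.0, 1.0, 0.01), (5.0, 1.0, 0.01)])
        lib = make_standard_library([spec], axis)
        mid = 4.0
        left = np.interp(mid - np.linspace(0, 1.2, 300), axis, lib.matrix[0])
        right = np.interp(mid + np.linspace(0, 1.2, 300), axis, lib.matrix[0])
        np.testing.assert_allclose(left, right, rtol=1e-6, atol=1e-12)

    def test_peak_outside_axis_names_standard(self):
        axis = np.arange(0.5, 5.0, 0.001)
        spec = SyntheticStandardSpec("lactate", [(7.0, 1.0, 0.01)])
        with pytest.raises(ValueError, match="lactate"):
            make_standard_library([spec], axis)

    def test_peak_center_outside_signal_region_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SyntheticStandardSpec("bad", [(10.2, 1.0, 0.01)])


class TestMixtureSpectrum:
    def test_linearity_without_noise(self, two_standard_library):
        s, truth = synthesize_mixture_spectrum(
            two_standard_library, np.array([0.3, 0.7]), reference_height=0.0
        )
        expected = 0.3 * two_standard_library.matrix[0] + 0.7 * two_standard_library.matrix[1]
        np.testing.assert_allclose(s.intensity, expected, rtol=1e-12)
        np.testing.assert_array_equal(truth["concentrations"], [0.3, 0.7])

    def test_zero_concentrations_give_baseline_plus_reference(self, two_standard_library):
        s, truth = synthesize_mixture_spectrum(
            two_standard_library, np.zeros(2), baseline_offset=5.0
        )
        far = np.abs(s.ppm) > 2.0  # beyond the reference peak's slow tail
        np.testing.assert_allclose(s.intensity[far], 5.0, atol=1e-3)
        assert truth["reference_area"] > 0

    def test_fixed_seed_reproducible(self, two_standard_library):
        args = dict(noise_sd=0.1, shift=0.004, seed=77)
        s1, _ = synthesize_mixture_spectrum(two_standard_library, np.array([0.5, 0.5]), **args)
        s2, _ = synthesize_mixture_spectrum(two_standard_library, np.array([0.5, 0.5]), **args)
        np.testing.assert_array_equal(s1.intensity, s2.intensity)

    def test_different_seeds_differ(self, two_standard_library):
        s1, _ = synthesize_mixture_spectrum(two_standard_library, np.zeros(2), noise_sd=0.1, seed=1)
        s2, _ = synthesize_mixture_spectrum(two_standard_library, np.zeros(2), noise_sd=0.1, seed=2)
        assert not np.array_equal(s1.intensity, s2.intensity)

    def test_negative_concentration_rejected(self, two_standard_library):
        with pytest.raises(ValueError, match="negative"):
            synthesize_mixture_spectrum(two_standard_library, np.array([0.5, -0.1]))

    def test_shift_is_circular_by_grid_points(self, two_standard_library):
        s0, _ = synthesize_mixture_spectrum(
            two_standard_library, np.array([1.0, 0.0]), reference_height=0.0
        )
        s1, truth = synthesize_mixture_spectrum(
            two_standard_library, np.array([1.0, 0.0]), shift=0.01, reference_height=0.0
        )
        assert truth["shift_applied"] == pytest.approx(0.01, abs=1e-12)
        np.testing.assert_array_equal(s1.intensity, np.roll(s0.intensity, 5))  # 0.01/0.002


class TestCopulaConversion:
    def test_conversion_roundtrip(self):
        rho = np.linspace(-0.95, 0.95, 21)
        np.testing.assert_allclose(pearson_to_spearman(spearman_to_pearson(rho)), rho, rtol=1e-12)


class TestConcentrationTables:
    def test_independence_target_gives_small_empirical_rho(self):
        design = _design(3, 10_000, seed=5)
        cop = CopulaSpec(target_spearman=np.zeros((3, 3)))
        blood, csf, _ = simulate_concentration_table(design, cop, group_effects={})
        for bi in design.shared_names:
            for cj in design.shared_names:
                rho = stats.spearmanr(blood[bi], csf[cj]).statistic
                assert abs(rho) < 0.05

    def test_strong_target_recovered(self):
        design = _design(2, 10_000, seed=6)
        target = np.array([[0.9, 0.0], [0.0, 0.0]])
        blood, csf, _ = simulate_concentration_table(
            design, CopulaSpec(target_spearman=target), group_effects={}
        )
        rho = stats.spearmanr(blood["met01"], csf["met01"]).statistic
        assert 0.85 <= rho <= 0.95

    def test_lognormal_marginals_pass_ks(self):
        design = _design(2, 10_000, seed=8)
        cop = CopulaSpec(target_spearman=np.eye(2) * 0.5, marginal_mu=1.0, marginal_sigma=0.3)
        blood, _, _ = simulate_concentration_table(design, cop, group_effects={})
        p = stats.kstest(np.log(blood["met01"]), "norm", args=(1.0, 0.3)).pvalue
        assert p > 0.01

    def test_same_seed_identical_different_seed_not(self):
        d1, d2 = _design(3, 5, seed=9), _design(3, 5, seed=9)
        cop = CopulaSpec(target_spearman=np.eye(3) * 0.4)
        b1, c1, _ = simulate_concentration_table(d1, cop)
        b2, c2, _ = simulate_concentration_table(d2, cop)
        assert b1.equals(b2) and c1.equals(c2)
        b3, _, _ = simulate_concentration_table(_design(3, 5, seed=10), cop)
        assert not b1.drop(columns="sample_id").equals(b3.drop(columns="sample_id"))

    def test_non_psd_target_reports_eigenvalue(self):
        design = _design(2, 5)
        # rank-correlating one blood metabolite at ~1 with two independent CSF
        # metabolites simultaneously is impossible
        target = np.array([[0.999, 0.999], [0.999, -0.999]])
        with pytest.raises(ValueError, match="eigenvalue"):
            simulate_concentration_table(design, CopulaSpec(target_spearman=target))

    def test_group_effects_shift_log_means(self):
        design = StudyDesign(
            n_metabolites_blood=2, n_metabolites_csf=2, n_shared=2,
            groups=[("male", "WT", "early"), ("male", "APP", "early")],
            replicates_per_group=4000, seed=11,
        )
        effects = {("APP", "early"): np.array([1.0, 0.0, 0.0, 0.0])}
        cop = CopulaSpec(target_spearman=np.zeros((2, 2)))
        blood, _, _ = simulate_concentration_table(design, cop, group_effects=effects)
        wt = np.log(blood.loc[blood.genotype == "WT", "met01"]).mean()
        app = np.log(blood.loc[blood.genotype == "APP", "met01"]).mean()
        assert app - wt == pytest.approx(1.0, abs=0.05)

    def test_default_group_effects_cover_all_cells(self):
        design = StudyDesign()
        effects = default_group_effects(design)
        assert set(effects) == {(g, a) for g in ("WT", "APP") for a in ("early", "late")}


def test_design_invariants():
    with pytest.raises(ValueError, match="n_shared"):
        StudyDesign(n_metabolites_blood=5, n_metabolites_csf=5, n_shared=6)
    with pytest.raises(ValueError, match="duplicate"):
        StudyDesign(groups=[("male", "WT", "early")] * 2)
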