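"""Spectral unmixing: design construction, per-voxel recovery, ratio
images, automatic ROIs, and the two wavelength cost functions."""

import numpy as np
import pytest

from paquant.exceptions import ValidationError
from paquant.simulate import (NOISELESS, PHANTOM_WAVELENGTHS_NM, NoiseSpec,
                              make_phantom_scene, render_stack)
from paquant.stacks import PAImageStack
from paquant.unmixing import (SpectralUnmixingModel, WavelengthScore,
                              auto_tube_roi, build_design, derive_ratio_images,
                              invivo_cost, phantom_cost, roi_scalar,
                              select_wavelengths, unmix_stack)
from paquant.workflows import simulate_phantom_experiment


class TestBuildDesign:
    def test_phantom_design_full_rank(self, phantom_design):
        assert phantom_design.rank == 3
        assert phantom_design.matrix.shape == (6, 3)

    def test_duplicate_chromophore_rejected(self, library):
        with pytest.raises(ValidationError, match="duplicat"):
            build_design(library, PHANTOM_WAVELENGTHS_NM, ["hbo2", "hhb", "hbo2"])

    def test_too_few_wavelengths_rejected(self, library):
        with pytest.raises(ValidationError):
            build_design(library, [760.0, 800.0], ["hbo2", "hhb", "patrace"])


def _stack_from_matrix(data, wavelengths):
    return PAImageStack(data, wavelengths, spacing_mm=(0.5, 0.1, 0.1))


class TestUnmixStack:
    def test_single_chromophore_exact(self, library):
        wl = [760.0, 800.0, 890.0, 910.0]
        design = build_design(library, wl, ["hbo2", "hhb", "patrace"])
        conc = 3.7e-4
        data = np.tile(conc * library["hbo2"](wl), (1, 4, 4, 1))
        res = unmix_stack(_stack_from_matrix(data, wl), design)
        assert np.allclose(res["hbo2"], conc, rtol=1e-9)
        assert np.allclose(res["hhb"], 0.0, atol=conc * 1e-9)
        assert np.allclose(res.residual_norm, 0.0, atol=conc * 1e-9)

    def test_overdetermined_matches_square_solve(self, library, phantom_design):
        """A noiseless 3-chromophore mixture on 6 wavelengths must agree
        with the direct linear solve on any square 3-wavelength subset."""
        rng = np.random.default_rng(0)
        conc = rng.uniform(0.1, 1.0, 3) * [2e-4, 1e-4, 2e-6]
        wl = list(PHANTOM_WAVELENGTHS_NM)
        spectrum = phantom_design.matrix @ conc
        data = spectrum.reshape(1, 1, 1, -1)
        res = unmix_stack(_stack_from_matrix(data, wl), phantom_design)
        recovered = np.array([res[n][0, 0, 0] for n in phantom_design.chromophores])
        for rows in ([0, 2, 5], [1, 3, 4]):
            sq = np.linalg.solve(phantom_design.matrix[rows], spectrum[rows])
            assert np.allclose(recovered, sq, rtol=1e-8)
        assert np.allclose(recovered, conc, rtol=1e-8)

    def test_zero_stack_zero_coefficients(self, phantom_design):
        data = np.zeros((2, 3, 3, 6))
        res = unmix_stack(_stack_from_matrix(data, list(PHANTOM_WAVELENGTHS_NM)),
                          phantom_design)
        for name in phantom_design.chromophores:
            assert np.all(res[name] == 0)

    def test_nonneg_matches_ols_when_interior(self, library):
        wl = [760.0, 800.0, 890.0, 910.0]
        design = build_design(library, wl, ["hbo2", "hhb", "patrace"])
        conc = np.array([2e-4, 1e-4, 2e-6])
        data = (design.matrix @ conc).reshape(1, 1, 1, -1)
        stack = _stack_from_matrix(data, wl)
        a = unmix_stack(stack, design, nonneg=False)
        b = unmix_stack(stack, design, nonneg=True)
        for name in design.chromophores:
            assert a[name][0, 0, 0] == pytest.approx(b[name][0, 0, 0], rel=1e-6)

    def test_wavelength_mismatch_rejected(self, library, phantom_design):
        data = np.zeros((1, 2, 2, 3))
        stack = _stack_from_matrix(data, [700.0, 800.0, 900.0])
        with pytest.raises(ValidationError):
            unmix_stack(stack, phantom_design)


class TestRatioImages:
    def _result(self, hbo2, hhb, probe, library):
        wl = [760.0, 800.0, 890.0, 910.0]
        design = build_design(library, wl, ["hbo2", "hhb", "patrace"])
        coeffs = {"hbo2": np.array([[[hbo2]]]), "hhb": np.array([[[hhb]]]),
                  "patrace": np.array([[[probe]]])}
        from paquant.unmixing import UnmixResult

        return UnmixResult(coefficients=coeffs, residual_norm=np.zeros((1, 1, 1)),
                           design=design)

    def test_pure_hbo2(self, library):
        so2, frac = derive_ratio_images(self._result(1.0, 0.0, 0.0, library), "patrace")
        assert so2[0, 0, 0] == 1.0
        assert frac[0, 0, 0] == 0.0

    def test_defined_mixture(self, library):
        so2, frac = derive_ratio_images(self._result(0.7, 0.3, 0.0, library), "patrace")
        assert so2[0, 0, 0] == pytest.approx(0.70)
        assert frac[0, 0, 0] == 0.0

    def test_probe_only_voxel_so2_invalid(self, library):
        so2, frac = derive_ratio_images(self._result(0.0, 0.0, 2.0, library), "patrace")
        assert np.isnan(so2[0, 0, 0])
        assert frac[0, 0, 0] == 1.0

    def test_missing_probe_errors(self, library):
        with pytest.raises(ValidationError):
            derive_ratio_images(self._result(1.0, 0.0, 0.0, library), "icg_monomer_serum")


class TestAutoTubeRoi:
    def test_roi_on_tube_center(self, small_phantom):
        scene, stack = small_phantom
        roi = auto_tube_roi(stack)
        assert roi.sum() == 9  # one 3x3 window on the single slice
        assert roi[0, 100, 100]  # contains the tube center voxel
        assert np.all(scene.rois["tube"][roi])  # fully inside the tube

    def test_flat_image_first_voxel_wins(self):
        stack = _stack_from_matrix(np.ones((1, 8, 8, 1)), [800.0])
        with pytest.warns(UserWarning, match="clipped"):
            roi = auto_tube_roi(stack)
        assert roi[0, 0, 0]
        assert roi.sum() == 4  # 2x2 corner window after clipping

    def test_roi_scalar_arithmetic(self):
        img = np.zeros((1, 4, 4))
        img[0, :2] = 0.4
        img[0, 2:] = 0.6
        assert roi_scalar(img, np.ones_like(img, dtype=bool)) == pytest.approx(0.5)
        const = np.full((1, 3, 3), 1.23)
        assert roi_scalar(const, np.ones_like(const, dtype=bool)) == pytest.approx(1.23)

    def test_volume_mean_equals_mean_of_slice_means(self, library):
        """For equal per-slice ROI sizes the volume mean equals the mean of
        per-slice means."""
        scene = make_phantom_scene(0.7, 0.9, shape=(4, 120, 120), library=library)
        stack = render_stack(scene, PHANTOM_WAVELENGTHS_NM, noise=NoiseSpec(0.05, 0.0),
                             seed=3)
        roi = auto_tube_roi(stack)
        img = stack.plane(800.0)
        per_slice = [roi_scalar(img[s][None], roi[s][None]) for s in range(4)]
        assert roi_scalar(img, roi) == pytest.approx(np.mean(per_slice), rel=1e-12)


@pytest.fixture(scope="module")
def tiny_experiment(library):
    return simulate_phantom_experiment("patrace", noise=NOISELESS, seed=0,
                                       shape=(1, 200, 200), library=library)


class TestPhantomCost:
    def test_noiseless_cost_is_pure_penalty(self, library, tiny_experiment):
        """Perfect data: both error terms vanish except for the sub-1e-3
        fraction-saturation effect, leaving essentially the sqrt penalty."""
        score = phantom_cost(PHANTOM_WAVELENGTHS_NM, tiny_experiment, library,
                             alpha=0.01)
        assert score.terms["so2_error"] < 1e-9
        assert score.terms["ratio_error"] < 0.01
        assert score.penalty == pytest.approx(0.01 * np.sqrt(6))
        assert score.total == pytest.approx(sum(score.terms.values()) + score.penalty)

    def test_sqrt_penalty_ratio(self, library, tiny_experiment):
        s4 = phantom_cost([710.0, 760.0, 800.0, 870.0], tiny_experiment, library)
        s9 = phantom_cost(list(tiny_experiment.wavelengths_nm), tiny_experiment, library)
        assert s4.penalty / s9.penalty == pytest.approx(2.0 / 3.0)

    def test_costs_favor_aggregate_probe_under_noise(self, library):
        """Over repeated noise, a subset bracketing the 890 nm band scores
        lower (better) for the J-aggregate probe than the same subset does
        for monomeric ICG."""
        subset = [760.0, 800.0, 830.0, 870.0, 890.0, 910.0]
        totals = {}
        for probe in ("patrace", "icg_monomer_serum"):
            costs = []
            for seed in range(50):
                exp = simulate_phantom_experiment(
                    probe, wavelengths_nm=subset, noise=NoiseSpec(0.05, 0.0),
                    seed=seed, shape=(1, 120, 120), spectral_coloring=True,
                    library=library)
                costs.append(phantom_cost(subset, exp, library).total)
            totals[probe] = np.median(costs)
        assert totals["patrace"] < totals["icg_monomer_serum"]


class TestInvivoCost:
    def test_identical_stacks_no_probe_zero_terms(self, library):
        scene = make_phantom_scene(0.7, 0.0, shape=(1, 120, 120), library=library)
        stack = render_stack(scene, (730.0, 760.0, 780.0, 800.0, 830.0, 890.0, 910.0),
                             noise=NOISELESS)
        roi = auto_tube_roi(stack)
        score = invivo_cost((730.0, 760.0, 780.0, 800.0, 830.0, 890.0, 910.0),
                            stack, stack, roi, library)
        assert score.terms["delta_so2"] == pytest.approx(0.0, abs=1e-12)
        assert score.terms["pre_probe"] == pytest.approx(0.0, abs=1e-9)

    def test_full_invivo_set_exact_on_noiseless_study(self, library):
        """The full seven-wavelength in vivo set achieves zero error terms
        on a noiseless synthetic pre/post pair."""
        wl = (730.0, 760.0, 780.0, 800.0, 830.0, 890.0, 910.0)
        pre_scene = make_phantom_scene(0.7, 0.0, shape=(1, 120, 120), library=library)
        post_scene = make_phantom_scene(0.7, 0.45, shape=(1, 120, 120), library=library)
        pre = render_stack(pre_scene, wl, noise=NOISELESS)
        post = render_stack(post_scene, wl, noise=NOISELESS)
        roi = auto_tube_roi(pre)
        score = invivo_cost(wl, pre, post, roi, library)
        assert score.terms["delta_so2"] < 1e-9
        assert score.terms["pre_probe"] < 1e-9
        assert score.total == pytest.approx(score.penalty, abs=1e-9)


class TestSelectWavelengths:
    def test_enumeration_count(self):
        calls = []

        def cost(subset):
            calls.append(subset)
            from paquant.unmixing import _score

            return _score(subset, {"err": 0.0}, alpha=0.01)

        select_wavelengths([700.0, 750.0, 800.0, 850.0], cost, min_size=3)
        assert len(calls) == 5  # C(4,3) + C(4,4)

    def test_noiseless_smallest_subset_wins(self, library, tiny_experiment):
        wl6 = list(PHANTOM_WAVELENGTHS_NM)
        scores = select_wavelengths(
            wl6, lambda s: phantom_cost(s, tiny_experiment, library), min_size=3)
        assert len(scores[0].subset) == 3  # penalty dominates on perfect data

    def test_ranking_deterministic(self, library, tiny_experiment):
        wl = [710.0, 800.0, 870.0, 890.0]
        run = lambda: [s.subset for s in select_wavelengths(
            wl, lambda sub: phantom_cost(sub, tiny_experiment, library), min_size=3)]
        assert run() == run()

    def test_no_feasible_subset(self):
        with pytest.raises(ValidationError):
            select_wavelengths([700.0, 800.0], lambda s: None, min_size=3)
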