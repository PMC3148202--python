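"""Modified Gaussian evaluation, image sectioning and constrained fitting."""

import numpy as np
import pytest

from ad3ri.gpl import segment
from ad3ri.io import RetinalImage, roi_mask
from ad3ri.modelling import (
    DrusenModel,
    ModifiedGaussian,
    Section,
    build_model,
    evaluate_mg,
    fit_section,
    section_image,
)


def _norm_image(pixels, resolution_um=12.5):
    rows, cols = pixels.shape
    return RetinalImage(
        pixels=pixels, resolution_um=resolution_um,
        roi_center=((rows - 1) / 2, (cols - 1) / 2),
        roi_diameter_um=0.95 * min(rows, cols) * resolution_um,
    )


def render(gaussians, shape, background=85.0):
    rr, cc = np.meshgrid(np.arange(shape[0], dtype=float),
                         np.arange(shape[1], dtype=float), indexing="ij")
    out = np.full(shape, background)
    for g in gaussians:
        out += g.bump(rr, cc)
    return out


class TestEvaluateMg:
    @pytest.mark.parametrize("theta,sigma,s_f,d",
                             [(0.0, 3.0, 1.0, 1.0), (0.7, 5.0, 2.0, 0.5),
                              (2.1, 2.0, 0.4, 2.5)])
    def test_peak_value_is_z0_plus_A(self, theta, sigma, s_f, d):
        g = ModifiedGaussian(x0=10.0, y0=7.0, z0=85.0, A=30.0, theta=theta,
                             sigma_x=sigma, s_F=s_f, d=d)
        assert evaluate_mg(g, 7.0, 10.0) == pytest.approx(115.0)

    def test_isotropic_bell_half_maximum_radius(self):
        # d=1, s_F=1: half maximum at radius sigma*sqrt(2 ln 2)
        g = ModifiedGaussian(x0=0, y0=0, z0=0, A=100, theta=0,
                             sigma_x=4.0, s_F=1.0, d=1.0)
        r_half = 4.0 * np.sqrt(2 * np.log(2))
        assert evaluate_mg(g, 0.0, r_half) == pytest.approx(50.0, rel=1e-9)
        assert evaluate_mg(g, r_half, 0.0) == pytest.approx(50.0, rel=1e-9)

    def test_shape_factor_scales_rotated_y_axis(self):
        g = ModifiedGaussian(x0=0, y0=0, z0=0, A=80, theta=0,
                             sigma_x=3.0, s_F=2.0, d=1.0)
        r_half_x = 3.0 * np.sqrt(2 * np.log(2))
        assert evaluate_mg(g, 0.0, r_half_x) == pytest.approx(40.0, rel=1e-9)
        assert evaluate_mg(g, 2 * r_half_x, 0.0) == pytest.approx(40.0, rel=1e-9)

    def test_exponent_morphs_profile(self):
        # at the 1-sigma locus q = 1/2: value = A*exp(-(1/2)^d), increasing in d
        vals = []
        for d in (0.5, 1.0, 2.0):
            g = ModifiedGaussian(x0=0, y0=0, z0=0, A=1.0, theta=0,
                                 sigma_x=5.0, s_F=1.0, d=d)
            vals.append(evaluate_mg(g, 0.0, 5.0))
        assert vals[0] < vals[1] < vals[2]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModifiedGaussian(0, 0, 0, A=-1, theta=0, sigma_x=1, s_F=1, d=1)
        with pytest.raises(ValueError):
            ModifiedGaussian(0, 0, 0, A=1, theta=0, sigma_x=0, s_F=1, d=1)


class TestSectionImage:
    def test_flat_background_yields_no_sections(self, flat_image):
        img = flat_image.with_pixels(np.full(flat_image.shape, 85.0))
        labels = segment(img.pixels, roi_mask(img))
        assert section_image(img, labels) == []

    def test_disjoint_bumps_one_seed_each(self):
        gs = [ModifiedGaussian(40, 40, 0, 35, 0, 5, 1, 1),
              ModifiedGaussian(100, 100, 0, 35, 0, 5, 1, 1)]
        img = _norm_image(render(gs, (144, 144)))
        labels = segment(img.pixels, roi_mask(img))
        secs = section_image(img, labels)
        assert len(secs) == 2
        assert all(len(s.seeds) == 1 for s in secs)

    def test_confluent_bumps_share_section_with_two_seeds(self):
        gs = [ModifiedGaussian(60, 60, 0, 35, 0, 5, 1, 1),
              ModifiedGaussian(60, 74, 0, 30, 0, 5, 1, 1)]
        img = _norm_image(render(gs, (128, 128)))
        labels = segment(img.pixels, roi_mask(img))
        secs = section_image(img, labels)
        assert len(secs) == 1
        assert len(secs[0].seeds) == 2

    def test_threshold_level(self):
        # sectioning threshold sits 10% above the normalized background
        px = np.full((128, 128), 85.0)
        px[60:66, 60:66] = 93.0  # below 93.5: no section
        img = _norm_image(px)
        labels = segment(img.pixels, roi_mask(img))
        assert section_image(img, labels) == []
        px[60:66, 60:66] = 94.0  # above: one section
        img = _norm_image(px)
        labels = segment(img.pixels, roi_mask(img))
        assert len(section_image(img, labels)) == 1


class TestFitSection:
    def _section_for(self, gaussians, shape=(48, 48), background=85.0, noise=0.0,
                     seed=0):
        px = render(gaussians, shape, background)
        if noise:
            px = px + np.random.default_rng(seed).normal(0, noise, shape)
        seeds = [(int(round(g.y0)), int(round(g.x0)),
                  float(px[int(round(g.y0)), int(round(g.x0))]))
                 for g in gaussians]
        return Section(bbox=(0, 0, shape[0], shape[1]), pixels=px, seeds=seeds)

    def test_noiseless_parameter_recovery(self):
        truth = ModifiedGaussian(x0=23.4, y0=25.1, z0=85.0, A=32.0, theta=0.6,
                                 sigma_x=5.0, s_F=1.4, d=1.2)
        sec = self._section_for([truth])
        fitted, rmse, flagged = fit_section(sec)
        assert not flagged
        g = fitted[0]
        assert abs(g.A - truth.A) / truth.A < 0.01
        assert np.hypot(g.x0 - truth.x0, g.y0 - truth.y0) < 0.1
        assert rmse < 1e-3 * truth.A

    def test_amplitude_recovery_under_noise(self):
        truth = ModifiedGaussian(x0=24.0, y0=24.0, z0=85.0, A=30.0, theta=0.0,
                                 sigma_x=5.0, s_F=1.0, d=1.0)
        errs = []
        for seed in range(20):
            sec = self._section_for([truth], noise=2.0, seed=seed)
            fitted, _, _ = fit_section(sec)
            errs.append(abs(fitted[0].A - truth.A) / truth.A)
        assert np.mean(errs) < 0.05
        assert np.max(errs) < 0.10

    def test_two_component_fit_beats_single_on_superimposed_pair(self):
        pair = [ModifiedGaussian(20, 24, 0, 30, 0, 4, 1, 1),
                ModifiedGaussian(30, 24, 0, 25, 0, 4, 1, 1)]
        px = render(pair, (48, 48))
        sec2 = Section((0, 0, 48, 48), px,
                       seeds=[(20, 24, float(px[20, 24])), (30, 24, float(px[30, 24]))])
        sec1 = Section((0, 0, 48, 48), px, seeds=[(20, 24, float(px[20, 24]))])
        _, rmse2, _ = fit_section(sec2)
        _, rmse1, _ = fit_section(sec1)
        assert rmse2 < rmse1

    def test_fit_never_increases_residual(self):
        rng = np.random.default_rng(5)
        truth = ModifiedGaussian(22, 22, 85.0, 28, 0.3, 6.0, 0.9, 1.1)
        px = render([truth], (44, 44)) + rng.normal(0, 2.0, (44, 44))
        seed_amp = float(px[22, 22])
        sec = Section((0, 0, 44, 44), px, seeds=[(22, 22, seed_amp)])
        fitted, rmse, _ = fit_section(sec)
        init = ModifiedGaussian(22, 22, 85.0, max(seed_amp - 85.0, 1e-3), 0.0,
                                fitted[0].sigma_x, 1.0, 1.0)
        # conservative bound: final residual no worse than the bell-shaped
        # initialisation evaluated on the same pixels
        rr, cc = np.meshgrid(np.arange(44.0), np.arange(44.0), indexing="ij")
        init_rmse = np.sqrt(np.mean((85.0 + init.bump(rr, cc) - px) ** 2))
        assert rmse <= init_rmse + 1e-12

    def test_constraints_respected(self):
        truth = ModifiedGaussian(20, 20, 85.0, 60.0, 0.0, 3.0, 1.0, 1.0)
        sec = self._section_for([truth], shape=(40, 40))
        fitted, _, _ = fit_section(sec)
        g = fitted[0]
        assert 0.0 <= g.A <= 170.0
        assert 0.5 <= g.sigma_x <= 40.0
        assert 0.2 <= g.s_F <= 5.0
        assert 0.3 <= g.d <= 3.0

    def test_empty_section_rejected(self):
        with pytest.raises(ValueError):
            fit_section(Section((0, 0, 8, 8), np.zeros((8, 8)), seeds=[]))


class TestBuildModel:
    def test_empty_image_gives_flat_background_model(self, flat_image):
        img = flat_image.with_pixels(np.full(flat_image.shape, 85.0))
        labels = segment(img.pixels, roi_mask(img))
        model = build_model(img, labels)
        assert model.gaussians == []
        assert np.allclose(model.render(img.shape), 85.0)

    def test_ten_disjoint_components_recovered(self):
        rng = np.random.default_rng(11)
        shape = (192, 192)
        truths = []
        while len(truths) < 10:
            r, c = rng.uniform(20, 172, 2)
            if all(np.hypot(r - t.y0, c - t.x0) > 30 for t in truths):
                truths.append(ModifiedGaussian(
                    x0=c, y0=r, z0=0.0, A=rng.uniform(22, 38),
                    theta=rng.uniform(0, np.pi), sigma_x=rng.uniform(3.5, 5.5),
                    s_F=rng.uniform(0.8, 1.2), d=1.0))
        img = _norm_image(render(truths, shape))
        labels = segment(img.pixels, roi_mask(img))
        model = build_model(img, labels)
        assert len(model.gaussians) == 10
        for t in truths:
            g = min(model.gaussians,
                    key=lambda g: np.hypot(g.x0 - t.x0, g.y0 - t.y0))
            assert np.hypot(g.x0 - t.x0, g.y0 - t.y0) < 0.1
            assert abs(g.A - t.A) / t.A < 0.01
        resid = model.render(shape) - img.pixels
        assert np.sqrt(np.mean(resid**2)) < 0.1

    def test_translation_equivariance(self):
        truth = ModifiedGaussian(60, 58, 0, 30, 0.4, 5, 1.2, 1.0)
        shifted = ModifiedGaussian(66, 63, 0, 30, 0.4, 5, 1.2, 1.0)
        img_a = _norm_image(render([truth], (128, 128)))
        img_b = _norm_image(render([shifted], (128, 128)))
        ga = build_model(img_a, segment(img_a.pixels, roi_mask(img_a))).gaussians[0]
        gb = build_model(img_b, segment(img_b.pixels, roi_mask(img_b))).gaussians[0]
        assert gb.x0 - ga.x0 == pytest.approx(6.0, abs=0.1)
        assert gb.y0 - ga.y0 == pytest.approx(5.0, abs=0.1)

    def test_model_json_round_trip(self):
        model = DrusenModel(
            gaussians=[ModifiedGaussian(1, 2, 85, 30, 0.5, 3, 1.1, 0.9)],
            background=85.0, fit_rmse=[0.01], flagged_sections=[])
        back = DrusenModel.from_json(model.to_json())
        assert back.background == model.background
        assert back.gaussians[0].A == pytest.approx(30.0)
        assert back.gaussians[0].theta == pytest.approx(0.5)
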