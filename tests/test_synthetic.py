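"""Synthetic scene generator: signatures, determinism, ground-truth links."""

import numpy as np
import pytest

from rootsip.debye import TauGrid, debye_forward, fit_debye
from rootsip.quality import ErrorModel
from rootsip.spectra import ComplexSpectrum
from rootsip.synthetic import (
    PlantAnomaly,
    RbdCoupling,
    SceneConfig,
    beet_terms,
    build_scene,
    maize_scene_config,
    maize_terms,
    mixed_scene_config,
    soil_terms,
)
from rootsip.traits import select_zone


def zone_mean_phase_mrad(scene, stem_x, width=0.20):
    g = scene.stack.grid
    from rootsip.traits import PlantRecord

    zone = select_zone(g, PlantRecord("p", "maize", stem_x, 0.0), width=width)
    ph = np.mean([scene.stack.spectrum(c).phase for c in zone.cell_ids], axis=0)
    return ph * 1e3


class TestSceneComposition:
    def test_no_plants_noise_free_equals_soil_forward(self):
        cfg = SceneConfig(nx=6, nz=4, error_model=None)
        scene = build_scene(cfg)
        ms = [m for m, _ in cfg.soil]
        ts = [t for _, t in cfg.soil]
        expected = debye_forward(cfg.soil_rho0, ms, ts,
                                 scene.stack.frequency_grid.frequencies)
        for s in scene.stack.spectra:
            np.testing.assert_allclose(s.rho, expected, rtol=1e-12)

    def test_same_seed_identical_output(self):
        a = build_scene(maize_scene_config(seed=7, n_plants=2))
        b = build_scene(maize_scene_config(seed=7, n_plants=2))
        for sa, sb in zip(a.stack.spectra, b.stack.spectra):
            np.testing.assert_array_equal(sa.magnitude, sb.magnitude)
            np.testing.assert_array_equal(sa.phase, sb.phase)
        assert a.true_rbd == b.true_rbd

    def test_different_seed_differs(self):
        a = build_scene(maize_scene_config(seed=1, n_plants=2))
        b = build_scene(maize_scene_config(seed=2, n_plants=2))
        assert not np.array_equal(a.stack.spectra[0].phase, b.stack.spectra[0].phase)

    def test_chargeability_overflow_rejected(self):
        bad = PlantAnomaly("p", "maize", 0.2, ((0.999, 0.01),))
        cfg = SceneConfig(nx=8, nz=4, plants=(bad,), error_model=None)
        with pytest.raises(ValueError, match="below 1"):
            build_scene(cfg)


class TestSpectralSignatures:
    def test_soil_phase_levels(self):
        """Soil: phase decreasing with frequency to about -10 mrad at 1 kHz."""
        f = np.logspace(-1, 4, 23)
        terms = soil_terms()
        rho = debye_forward(60.0, [m for m, _ in terms], [t for _, t in terms], f)
        ph = np.angle(rho) * 1e3
        i1k = np.argmin(abs(f - 1000))
        assert -13 < ph[i1k] < -8
        assert ph[i1k] < ph[np.argmin(abs(f - 1.0))] < 0

    def test_maize_monotone_high_frequency_dispersion(self):
        """Maize phase decreases monotonically from 100 Hz to 1 kHz and is
        steeper than the levelling soil response."""
        f = np.logspace(-1, 4, 23)
        sel = (f >= 100) & (f <= 1000)

        def phases(terms):
            rho = debye_forward(60.0, [m for m, _ in terms],
                                [t for _, t in terms], f)
            return np.angle(rho) * 1e3

        soil = phases(soil_terms())
        maize = phases(soil_terms() + maize_terms(1.0))
        assert np.all(np.diff(maize[sel]) < 0)
        assert (maize[sel][-1] - maize[sel][0]) < (soil[sel][-1] - soil[sel][0])
        assert -17 < maize[np.argmin(abs(f - 1000))] < -13  # ~ -15 mrad

    @pytest.mark.parametrize("timestep,f_lo,f_hi", [("t2", 1.0, 5.0), ("t3", 1.0, 5.0)])
    def test_beet_low_frequency_peak_position(self, timestep, f_lo, f_hi):
        f = np.logspace(-1, 4, 23)
        terms = soil_terms() + beet_terms(timestep)
        rho = debye_forward(60.0, [m for m, _ in terms], [t for _, t in terms], f)
        ph = np.angle(rho) * 1e3
        peaks = [
            f[j] for j in range(1, len(f) - 1)
            if ph[j] < ph[j - 1] and ph[j] < ph[j + 1] and f[j] < 30
        ]
        assert len(peaks) == 1 and f_lo <= peaks[0] <= f_hi

    def test_beet_peak_shifts_down_and_high_frequency_strengthens(self):
        f = np.logspace(-1, 4, 23)

        def peak_freq(timestep):
            terms = soil_terms() + beet_terms(timestep)
            rho = debye_forward(60.0, [m for m, _ in terms], [t for _, t in terms], f)
            ph = np.angle(rho) * 1e3
            cands = [
                (f[j], ph[j]) for j in range(1, len(f) - 1)
                if ph[j] < ph[j - 1] and ph[j] < ph[j + 1] and f[j] < 30
            ]
            return cands[0] if cands else (None, None)

        f2, p2 = peak_freq("t2")
        f3, p3 = peak_freq("t3")
        assert f3 < f2  # peak moves to lower frequency over the season
        assert p3 < p2  # and deepens
        # high-frequency polarization reaches about -25 mrad
        terms = soil_terms() + beet_terms("t3")
        rho = debye_forward(60.0, [m for m, _ in terms], [t for _, t in terms], f)
        assert np.angle(rho)[np.argmin(abs(f - 1000))] * 1e3 == pytest.approx(
            -25.0, abs=3.0
        )

    def test_t1_has_no_low_frequency_peak(self):
        f = np.logspace(-1, 4, 23)
        terms = soil_terms() + beet_terms("t1")
        rho = debye_forward(60.0, [m for m, _ in terms], [t for _, t in terms], f)
        ph = np.angle(rho) * 1e3
        peaks = [
            f[j] for j in range(1, len(f) - 1)
            if ph[j] < ph[j - 1] and ph[j] < ph[j + 1] and f[j] < 30
        ]
        assert peaks == []


class TestNoiseFreeRecovery:
    def test_fit_debye_recovers_scene_exactly(self):
        """Noise-free scene spectra are reproduced by the decomposition to
        rms < 1e-6 when the true relaxation times are on the grid."""
        cfg = SceneConfig(nx=4, nz=3, error_model=None)
        scene = build_scene(cfg)
        true_taus = sorted({t for _, t in cfg.soil})
        taus = np.sort(np.unique(np.concatenate(
            [np.logspace(-6, 2, 81), true_taus])))
        s = scene.stack.spectra[0]
        fit = fit_debye(s, tau_grid=TauGrid(taus), lam=0.0)
        assert fit.rms < 1e-6
        assert fit.m_tot == pytest.approx(scene.true_m_tot(0), abs=1e-3)


class TestRestrictedSeasonalTrend:
    def test_restricted_fit_isolates_slow_process_and_tracks_season(self):
        """The <= 55 Hz decomposition of beet-zone mean spectra yields mean
        relaxation times an order of magnitude above the full-band fit and
        increasing monotonically from t1 to t3 (storage-cell growth)."""
        from rootsip.debye import fit_debye_restricted

        taus = {}
        for timestep in ("t1", "t2", "t3"):
            scene = build_scene(mixed_scene_config(timestep, seed=5))
            g = scene.stack.grid
            vals = []
            fulls = []
            for rec in scene.plants:
                if rec.species != "sugar_beet":
                    continue
                zone = select_zone(g, rec)
                rho = np.mean(
                    [scene.stack.spectrum(c).rho for c in zone.cell_ids], axis=0
                )
                s = ComplexSpectrum.from_complex(scene.stack.frequency_grid, rho)
                vals.append(fit_debye_restricted(s, 55.0).tau_mean)
                fulls.append(fit_debye(s, f_max=1000.0).tau_mean)
            taus[timestep] = np.mean(vals)
            assert np.mean(vals) > 4 * np.mean(fulls)
        assert taus["t1"] < taus["t2"] < taus["t3"]


class TestValidationCoupling:
    def test_rank_order_preserved_without_noise(self):
        cfg = maize_scene_config(seed=3, noise=False, sigma_rbd=0.0)
        scene = build_scene(cfg)
        g = scene.stack.grid
        true_m = []
        for rec in scene.plants:
            zone = select_zone(g, rec)
            true_m.append(np.mean(
                [scene.true_root_hf_chargeability(c) for c in zone.cell_ids]
            ))
        masses = [r.fresh_root_mass for r in scene.plants]
        assert np.argsort(masses).tolist() == np.argsort(true_m).tolist()

    def test_zero_gain_gives_intercept(self):
        plants = (PlantAnomaly("p1", "maize", 0.5, tuple(maize_terms())),)
        cfg = SceneConfig(nx=20, nz=8, plants=plants,
                          coupling=RbdCoupling(gain=0.0, intercept=0.042),
                          error_model=None)
        scene = build_scene(cfg)
        assert scene.plants[0].fresh_root_mass == pytest.approx(0.042)

    def test_masses_are_plausible_field_values(self):
        scene = build_scene(maize_scene_config(seed=0))
        masses = [r.fresh_root_mass for r in scene.plants]
        assert all(0.001 < m < 2.0 for m in masses)  # kg, field shovelomics range


class TestNoiseModel:
    def test_noise_magnitude_matches_error_model(self):
        cfg = SceneConfig(nx=40, nz=20, error_model=ErrorModel())
        noisy = build_scene(cfg)
        clean = build_scene(SceneConfig(nx=40, nz=20, error_model=None))
        dmag = np.concatenate([
            n.magnitude - c.magnitude
            for n, c in zip(noisy.stack.spectra, clean.stack.spectra)
        ])
        dph = np.concatenate([
            n.phase - c.phase
            for n, c in zip(noisy.stack.spectra, clean.stack.spectra)
        ])
        mag0 = np.concatenate([c.magnitude for c in clean.stack.spectra])
        # relative magnitude scatter ~ a = 2 %
        assert np.std(dmag / mag0) == pytest.approx(0.02, rel=0.1)
        # phase scatter floor ~ d = 1 mrad
        assert 0.8e-3 < np.std(dph) < 1.5e-3
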