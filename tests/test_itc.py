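"""One-set-of-sites isotherm simulation, fitting and thermodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bafdyn as b
from bafdyn.itc import ScheduleError, UnidentifiableParametersError


@pytest.fixture()
def lamin_schedule():
    """29 x 10 µL, 15 µM monomer in the cell, 100 µM IgFold syringe, 288 K."""
    return b.standard_schedule(15e-6, 100e-6)


@pytest.fixture()
def dna_schedule():
    """29 x 10 µL, 10 µM in the cell, 33 µM dsDNA syringe, 288 K."""
    return b.standard_schedule(10e-6, 33e-6)


class TestSimulateIsotherm:
    def test_zero_enthalpy_gives_pure_offset(self, lamin_schedule):
        iso = b.simulate_isotherm(lamin_schedule, kd=1e-6, dh=0.0, n=0.5,
                                  dilution_offset=-0.37)
        np.testing.assert_allclose(iso.heats, -0.37, atol=1e-12)

    def test_tight_binding_stoichiometric_limit(self):
        """Mole-bookkeeping oracle at kd -> 0: each pre-saturation injection
        releases dH x (moles injected); post-saturation injections release
        nothing; the crossover sits at molar ratio = n."""
        dh, n = -18.0, 1.0
        schedule = b.standard_schedule(10e-6, 100e-6)  # saturates near ratio 2
        iso = b.simulate_isotherm(schedule, kd=1e-15, dh=dh, n=n)
        moles_per_inj = 100e-6 * 10e-6  # mol of titrant per 10 µL shot
        expected_first = dh * moles_per_inj * 1e9  # µcal
        np.testing.assert_allclose(iso.heats[:5], expected_first, rtol=0.02)
        assert abs(iso.heats[-1]) < 0.02 * abs(expected_first)
        # the steepest heat drop brackets molar ratio ~ n
        drop = np.argmax(np.abs(np.diff(iso.heats)))
        assert iso.molar_ratio[drop] <= n * 1.15
        assert iso.molar_ratio[drop + 1] >= n * 0.85

    def test_noise_is_seeded(self, lamin_schedule):
        a = b.simulate_isotherm(lamin_schedule, 1e-6, -10.0, 0.5, noise_sd=0.3, seed=7)
        c = b.simulate_isotherm(lamin_schedule, 1e-6, -10.0, 0.5, noise_sd=0.3, seed=7)
        np.testing.assert_array_equal(a.heats, c.heats)

    def test_injection_volume_cannot_reach_cell_volume(self):
        with pytest.raises(ScheduleError):
            b.TitrationSchedule(1e-5, 1e-4, (1500.0,), cell_volume=1.4e-3)


class TestFitIsotherm:
    def test_lamin_round_trip_with_fixed_n(self, lamin_schedule):
        iso = b.simulate_isotherm(lamin_schedule, kd=2.7e-6, dh=-10.0, n=0.5)
        fit = b.fit_isotherm(iso, fix_n=0.5)
        assert fit.kd == pytest.approx(2.7e-6, rel=0.01)
        assert fit.dh == pytest.approx(-10.0, rel=0.01)
        assert fit.n == 0.5 and fit.n_fixed

    def test_dna_round_trip(self, dna_schedule):
        iso = b.simulate_isotherm(dna_schedule, kd=16.3e-9, dh=-18.1, n=1.0)
        fit = b.fit_isotherm(iso)
        assert fit.kd == pytest.approx(16.3e-9, rel=0.01)
        assert fit.dh == pytest.approx(-18.1, rel=0.01)
        assert fit.n == pytest.approx(1.0, rel=0.01)

    @settings(max_examples=12, deadline=None)
    @given(
        log_kd=st.floats(-9.0, -5.0),
        dh=st.floats(-50.0, -5.0),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_identity_across_kd_range(self, log_kd, dh, seed):
        """fit(simulate(theta, noise=0)) recovers theta within 1% whenever the
        c-value is in the informative 5-500 window."""
        kd = 10.0**log_kd
        cell = 15e-6
        c = cell / kd
        if not 5.0 <= c <= 500.0:
            cell = np.clip(50.0 * kd, 2e-6, 2e-4)
        schedule = b.standard_schedule(cell, 10.0 * cell)
        iso = b.simulate_isotherm(schedule, kd=kd, dh=dh, n=1.0)
        fit = b.fit_isotherm(iso)
        assert fit.kd == pytest.approx(kd, rel=0.01)
        assert fit.dh == pytest.approx(dh, rel=0.01)

    def test_offset_recovered(self, lamin_schedule):
        iso = b.simulate_isotherm(
            lamin_schedule, kd=2.7e-6, dh=-10.0, n=0.5, dilution_offset=-0.8
        )
        fit = b.fit_isotherm(iso, fix_n=0.5)
        assert fit.dilution_offset == pytest.approx(-0.8, abs=0.01)
        assert fit.kd == pytest.approx(2.7e-6, rel=0.01)

    def test_flat_isotherm_unidentifiable(self, lamin_schedule):
        iso = b.simulate_isotherm(lamin_schedule, kd=1e-6, dh=0.0, n=0.5,
                                  dilution_offset=0.5)
        with pytest.raises(UnidentifiableParametersError):
            b.fit_isotherm(iso, fix_n=0.5)

    def test_total_heat_equals_moles_times_dh_when_tight(self):
        """Integrated heat (offset-free) = n * dH * moles of limiting species.

        The syringe is concentrated enough to saturate within the first
        injections, so essentially no free sites are expelled unbound."""
        dh = -20.0
        schedule = b.standard_schedule(10e-6, 2e-3)  # ratio ~1.4 after 1 shot
        iso = b.simulate_isotherm(schedule, kd=1e-14, dh=dh, n=1.0)
        total = iso.heats.sum()  # µcal
        moles_cell = 10e-6 * 1.4e-3  # limiting species: macromolecule sites
        assert total == pytest.approx(dh * moles_cell * 1e9, rel=0.01)

    def test_noisy_recovery_unbiased(self, dna_schedule):
        """Seeded noisy replicates: kd bias < 5% and dispersion of the same
        order as the tens-of-percent uncertainty of a single titration.

        Stoichiometry 0.3 sites per cell molecule (several protein copies per
        22-bp duplex) puts the equivalence point at molar ratio 0.3, inside
        the 29-injection program, so Kd is actually identifiable under noise.
        """
        kds = []
        for seed in range(40):
            iso = b.simulate_isotherm(
                dna_schedule, kd=16.3e-9, dh=-18.1, n=0.3, noise_sd=0.2, seed=seed
            )
            kds.append(b.fit_isotherm(iso).kd)
        kds = np.array(kds)
        assert abs(np.median(kds) - 16.3e-9) / 16.3e-9 < 0.05
        assert np.std(kds) / 16.3e-9 < 0.5

    def test_consistency_invariant_on_every_fit(self, lamin_schedule):
        iso = b.simulate_isotherm(lamin_schedule, kd=2.7e-6, dh=-10.0, n=0.5)
        fit = b.fit_isotherm(iso, fix_n=0.5)
        assert abs(fit.dg - fit.dh - fit.entropic_penalty) < 1e-6

    def test_drop_first_masks_heat_but_keeps_bookkeeping(self, lamin_schedule):
        iso = b.simulate_isotherm(lamin_schedule, kd=2.7e-6, dh=-10.0, n=0.5)
        masked = iso.drop_first()
        assert np.isnan(masked.heats[0]) and len(masked.heats) == 29
        fit = b.fit_isotherm(masked, fix_n=0.5)
        assert fit.kd == pytest.approx(2.7e-6, rel=0.01)


class TestThermodynamics:
    @pytest.mark.parametrize(
        "kd, expected",
        [(117e-9, -9.1), (16.3e-9, -10.3), (1.0, 0.0)],
    )
    def test_gibbs_from_kd_at_288K(self, kd, expected):
        assert b.gibbs_from_kd(kd, 288.0) == pytest.approx(expected, abs=0.05)

    def test_gibbs_rejects_nonpositive_kd(self):
        with pytest.raises(ValueError):
            b.gibbs_from_kd(0.0, 288.0)

    @pytest.mark.parametrize(
        "kd, dh, expected",
        [(117e-9, -49.5, 40.4), (16.3e-9, -18.1, 7.8)],
    )
    def test_entropic_penalty_decomposition(self, kd, dh, expected):
        dg = b.gibbs_from_kd(kd, 288.0)
        assert b.decompose(dg, dh) == pytest.approx(expected, abs=0.1)

    def test_decompose_zero_when_dg_equals_dh(self):
        assert b.decompose(-5.0, -5.0) == 0.0

    @pytest.mark.parametrize(
        "kd_ref, kd_alt, ratio, fold",
        [
            (117e-9, 16.3e-9, 7.18, 7),
            (2.7e-6, 9.0e-6, 0.30, 3),
            (1e-6, 1e-6, 1.0, 1),
        ],
    )
    def test_affinity_fold_change(self, kd_ref, kd_alt, ratio, fold):
        r, f = b.affinity_fold_change(kd_ref, kd_alt)
        assert r == pytest.approx(ratio, abs=0.01)
        assert f == fold

    def test_fold_change_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            b.affinity_fold_change(-1.0, 1e-6)
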