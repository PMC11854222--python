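"""Unit tests of the swelling law, fluxes, ODE right-hand side and simulator."""

import numpy as np
import pytest

from lfrelease.kinetics import (
    BatchConfig,
    ConcentrationTriple,
    DomainError,
    ReleaseState,
    SwellingParams,
    concentrations,
    equilibrium_state,
    flux_ll,
    flux_sl,
    release_rhs,
    simulate_release,
    swelling_closed_form,
    swelling_rate,
)

PARAMS = SwellingParams(k_v=0.00335, V_max=1.27e-3, V_ads0=0.0)


class TestSwellingLaw:
    def test_rate_zero_at_plateau(self):
        assert swelling_rate(PARAMS.V_max, PARAMS) == 0.0

    def test_rate_from_dry(self):
        # k_v * V_max for a fully dry particle
        assert swelling_rate(0.0, PARAMS) == pytest.approx(4.2545e-6, rel=1e-12)

    def test_rate_linearity(self):
        full = swelling_rate(0.0, PARAMS)
        assert swelling_rate(PARAMS.V_max / 2, PARAMS) == pytest.approx(full / 2)

    def test_rate_rejects_overswollen(self):
        with pytest.raises(DomainError):
            swelling_rate(PARAMS.V_max * 1.01, PARAMS)

    def test_closed_form_initial_condition(self):
        p = SwellingParams(k_v=0.1, V_max=2.0, V_ads0=0.5)
        assert swelling_closed_form(0.0, p) == pytest.approx(0.5, rel=1e-15)

    def test_closed_form_asymptote(self):
        t = 30.0 / PARAMS.k_v
        assert swelling_closed_form(t, PARAMS) == pytest.approx(
            PARAMS.V_max, rel=1e-12)

    def test_closed_form_two_days(self):
        # 1.27e-3 * (1 - exp(-0.00335 * 1440))
        assert swelling_closed_form(1440.0, PARAMS) == pytest.approx(
            1.2598e-3, rel=1e-4)

    def test_closed_form_rejects_negative_time(self):
        with pytest.raises(DomainError):
            swelling_closed_form(-1.0, PARAMS)

    def test_params_validation(self):
        with pytest.raises(DomainError):
            SwellingParams(k_v=-1.0, V_max=1.0)
        with pytest.raises(DomainError):
            SwellingParams(k_v=1.0, V_max=1e-9, V_ads0=1e-8)


class TestConcentrationsAndFluxes:
    def test_quotients(self, batch1):
        state = ReleaseState(t=0, V_ads=1e-8, V_b=40.0,
                             n_s=1.6e-7, n_ads=0.0, n_b=0.0)
        c = concentrations(state, batch1)
        assert c.C_s == pytest.approx(6.6667e-4, rel=1e-4)
        assert c.C_ads == 0.0 and c.C_b == 0.0

    def test_homogeneity(self, batch1):
        s1 = ReleaseState(t=0, V_ads=1e-3, V_b=40.0,
                          n_s=1e-8, n_ads=2e-8, n_b=3e-8)
        s2 = ReleaseState(t=0, V_ads=1e-3, V_b=40.0,
                          n_s=2e-8, n_ads=4e-8, n_b=6e-8)
        c1, c2 = concentrations(s1, batch1), concentrations(s2, batch1)
        assert c2.C_s == pytest.approx(2 * c1.C_s)
        assert c2.C_ads == pytest.approx(2 * c1.C_ads)
        assert c2.C_b == pytest.approx(2 * c1.C_b)

    def test_degenerate_state_rejected(self, batch1):
        state = ReleaseState(t=0, V_ads=0.0, V_b=40.0, n_s=0, n_ads=0, n_b=0)
        with pytest.raises(DomainError):
            concentrations(state, batch1)

    def test_flux_sl_zero_at_partition_equilibrium(self, batch1):
        c = ConcentrationTriple(C_s=batch1.H_Lf * 5e-4, C_ads=5e-4, C_b=0.0)
        assert flux_sl(c, batch1) == pytest.approx(0.0, abs=1e-18)

    def test_flux_sl_magnitude(self, batch1):
        c = ConcentrationTriple(C_s=6.667e-4, C_ads=0.0, C_b=0.0)
        # beta_sl * C_s / H_Lf
        assert flux_sl(c, batch1) == pytest.approx(1.4819e4, rel=1e-3)

    def test_flux_sl_back_transfer_sign(self, batch1):
        c = ConcentrationTriple(C_s=0.0, C_ads=1e-6, C_b=0.0)
        assert flux_sl(c, batch1) < 0

    def test_flux_ll(self, batch1):
        same = ConcentrationTriple(C_s=0, C_ads=3e-9, C_b=3e-9)
        assert flux_ll(same, batch1) == 0.0
        c = ConcentrationTriple(C_s=0, C_ads=2e-9, C_b=0.0)
        assert flux_ll(c, batch1) == pytest.approx(2.0255e-9, rel=1e-3)
        doubled = batch1.replace(beta_ll=2 * batch1.beta_ll)
        assert flux_ll(c, doubled) == pytest.approx(2 * flux_ll(c, batch1))


class TestReleaseRHS:
    @pytest.fixture
    def midstate(self, batch1):
        return ReleaseState(t=5.0, V_ads=1e-3, V_b=39.999,
                            n_s=5e-8, n_ads=6e-8, n_b=5e-8)

    def test_conservative_moles_sum_to_zero(self, batch1, midstate):
        d = release_rhs(5.0, midstate, batch1, mode="conservative")
        # cancellation is exact up to float rounding of the flux terms
        assert abs(d[2] + d[3] + d[4]) <= 1e-14 * np.max(np.abs(d))
        assert abs(d[0] + d[1]) <= 1e-14 * np.max(np.abs(d))

    def test_equilibrium_is_fixed_point(self, batch1):
        eq = equilibrium_state(batch1)
        d = release_rhs(0.0, eq, batch1, mode="conservative")
        np.testing.assert_allclose(d, 0.0, atol=1e-18)

    def test_as_printed_mole_defect(self, batch1, midstate):
        """The sign-swapped adsorbed-phase balance leaks 2(J_ll - J_sl) V_ads."""
        d = release_rhs(5.0, midstate, batch1, mode="as_printed")
        c = concentrations(midstate, batch1)
        leak = 2 * (flux_ll(c, batch1) - flux_sl(c, batch1)) * midstate.V_ads
        assert abs(leak) > 0
        assert d[2] + d[3] + d[4] == pytest.approx(leak, rel=1e-12)

    def test_unknown_mode_rejected(self, batch1, midstate):
        with pytest.raises(ValueError, match="mode"):
            release_rhs(0.0, midstate, batch1, mode="exact")


class TestSimulateRelease:
    def test_no_transfer_path_keeps_bulk_empty(self, batch1):
        cfg = batch1.replace(beta_ll=0.0)
        traj = simulate_release(cfg, np.linspace(0, 600, 20))
        np.testing.assert_allclose(traj.n_b, 0.0, atol=1e-25)

    def test_volume_and_mole_conservation(self, batch1):
        t = np.concatenate([[0], np.geomspace(0.1, 2880, 40)])
        traj = simulate_release(batch1, t)
        total_v = traj.V_ads + traj.V_b
        assert np.max(np.abs(total_v - (batch1.V_ads0 + batch1.V_b0))) \
            <= 1e-9 * batch1.V_b0
        total_n = traj.n_s + traj.n_ads + traj.n_b
        assert np.max(np.abs(total_n - batch1.n_total)) <= 1e-6 * batch1.n_total

    def test_swollen_volume_nondecreasing(self, batch1):
        t = np.concatenate([[0], np.geomspace(0.1, 2880, 40)])
        traj = simulate_release(batch1, t)
        assert np.all(np.diff(traj.V_ads) >= -1e-12 * batch1.V_max)

    def test_bulk_moles_monotone_when_swelling_limited(self, batch1):
        # with swelling much faster than transfer, the overshoot-and-relax
        # pathway is closed and n_b rises monotonically
        cfg = batch1.replace(k_v=10.0, beta_ll=1e-3)
        traj = simulate_release(cfg, np.linspace(0, 2000, 50))
        assert np.all(np.diff(traj.n_b) >= -1e-9 * cfg.n_total)

    def test_dissolution_sends_everything_to_bulk(self, batch1):
        cfg = batch1.replace(t_dissolve=10.0, beta_ll=1e-4)
        traj = simulate_release(cfg, np.array([0.0, 5.0, 10.0, 20.0, 100.0]))
        assert traj.release_fraction[1] < 1.0
        np.testing.assert_allclose(traj.release_fraction[2:], 1.0, rtol=1e-12)
        assert list(traj.dissolved) == [False, False, True, True, True]

    def test_dissolution_freezes_state(self, batch1):
        cfg = batch1.replace(t_dissolve=15.0)
        traj = simulate_release(cfg, np.array([0.0, 20.0, 100.0, 500.0]))
        assert traj.V_ads[1] == traj.V_ads[3]
        assert traj.n_b[1] == traj.n_b[3] == pytest.approx(cfg.n_total)

    def test_grid_validation(self, batch1):
        with pytest.raises(ValueError):
            simulate_release(batch1, [1.0, 2.0])      # does not start at 0
        with pytest.raises(ValueError):
            simulate_release(batch1, [0.0, 2.0, 2.0])  # not strictly increasing

    def test_frame_columns(self, batch1):
        traj = simulate_release(batch1, np.array([0.0, 1.0, 10.0]))
        assert list(traj.to_frame().columns) == [
            "t_min", "V_ads_cm3", "V_b_cm3", "n_s_mol", "n_ads_mol",
            "n_b_mol", "C_b_mol_per_cm3", "release_fraction", "dissolved",
        ]


class TestEquilibrium:
    def test_batch1_bulk_fraction(self, batch1):
        eq = equilibrium_state(batch1)
        c = eq.n_ads / eq.V_ads
        assert c == pytest.approx(4.0e-9, rel=2e-3)
        assert eq.n_b / batch1.n_total == pytest.approx(0.9976, abs=5e-4)

    def test_strong_partition_retains_protein(self, batch1):
        held = batch1.replace(H_Lf=1e9)
        eq = equilibrium_state(held)
        assert eq.n_b / held.n_total < 1e-3

    def test_long_horizon_simulation_matches(self, batch1):
        eq = equilibrium_state(batch1)
        t_end = 35.0 / batch1.k_v
        traj = simulate_release(batch1, np.array([0.0, t_end / 2, t_end]))
        assert traj.n_b[-1] == pytest.approx(eq.n_b, rel=1e-6)
        assert traj.V_ads[-1] == pytest.approx(eq.V_ads, rel=1e-6)

    def test_requires_no_dissolution(self, batch1):
        with pytest.raises(ValueError):
            equilibrium_state(batch1.replace(t_dissolve=5.0))


class TestBatchConfig:
    def test_v_max_is_hydration_times_dry_mass(self, batch1):
        assert batch1.V_max == pytest.approx(0.0955, rel=1e-12)

    def test_validation(self):
        with pytest.raises(DomainError):
            BatchConfig(W_s=0.025, V_s=2.4e-4, V_b0=40, k_v=0.00335,
                        n_s0=1.6e-7, H_Lf=-1.0, beta_sl=1.0, beta_ll=1.0)
        with pytest.raises(DomainError):
            # hydration capacity must exceed the initial adsorbed volume
            BatchConfig(W_s=0.025, V_s=2.4e-4, V_b0=40, k_v=0.00335,
                        n_s0=1.6e-7, H_Lf=1e-4, beta_sl=1.0, beta_ll=1.0,
                        V_h=1e-8, V_ads0=1.0)
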