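import numpy as np
import pytest

from acylsim import (
    FeedingProtocol,
    apply_feeding_step,
    find_steady_state,
    simulate_timecourse,
)
from acylsim.engine import default_time_grid
from acylsim.observables import fold_change_at


class TestSteadyState:
    def test_residual_criterion_met(self, model, baseline):
        dc = model.rhs(baseline.values)
        free = [i for i, s in enumerate(model.species) if s not in model.clamped]
        residual = np.max(np.abs(dc[free]) / (np.abs(baseline.values[free]) + 1e-6))
        assert residual < 1e-8

    def test_perturbed_initialisation_converges_to_same_state(self, model, baseline):
        """A 10% perturbation of the default initial condition lands on
        the same steady state to 1e-4 relative (same conserved totals)."""
        perturbed = model.initial_state({
            "holo-ACP": model.params.acp_total * 0.9,
            "C16:0-ACP": model.params.acp_total * 0.1,
        })
        ss2 = find_steady_state(model, perturbed)
        ref = baseline.values
        mask = ref > 1e-6
        assert np.max(np.abs(ss2.values[mask] - ref[mask]) / ref[mask]) < 1e-4

    def test_baseline_viability_without_acyl_coa(self, model, baseline):
        """With all acyl-CoA clamped to zero the pathway still runs:
        malonyl-ACP is present and PA is being produced."""
        assert baseline["C16:0-CoA"] == pytest.approx(0.0, abs=1e-12)
        assert baseline["malonyl-ACP"] > 0
        pa_flux = sum(
            rate for rxn, rate in zip(
                model.reactions, model.reaction_rates(baseline.values))
            if rxn.name.startswith("PlsC-cat"))
        assert pa_flux > 0

    def test_nonconvergence_raises_with_residual(self, model):
        from acylsim.engine import SteadyStateError
        with pytest.raises(SteadyStateError) as err:
            find_steady_state(model, t_max=10.0, tol=1e-14)
        assert err.value.residual > 0

    def test_conserved_totals_at_steady_state(self, model, baseline):
        totals = model.conserved_totals(baseline)
        for key, expected in model.totals.items():
            assert totals[key] == pytest.approx(expected, rel=1e-6)


class TestFeedingStep:
    def test_step_sets_clamp_and_keeps_other_species(self, model, baseline):
        protocol = FeedingProtocol("C16:0-CoA", clamp_value=30.0)
        stepped = apply_feeding_step(model, baseline, protocol)
        assert stepped["C16:0-CoA"] == 30.0
        for sp in model.species:
            if sp != "C16:0-CoA":
                assert stepped[sp] == baseline[sp]

    def test_unknown_fatty_acid_rejected(self):
        with pytest.raises(ValueError, match="palmitate"):
            FeedingProtocol.for_fatty_acid("oleate")

    def test_non_clampable_species_rejected(self):
        with pytest.raises(ValueError):
            FeedingProtocol("C16:0-ACP", 1.0)


class TestTimecourse:
    def test_first_state_equals_initial(self, model, baseline):
        grid = np.array([0.0, 50.0, 100.0])
        traj = simulate_timecourse(model, baseline, grid)
        assert np.allclose(traj.values[0], baseline.values)

    def test_null_feeding_leaves_all_species_flat(self, model, baseline, palmitate):
        """Clamping the fed species at its pre-step value (zero) is a null
        perturbation: every fold change is 1 within 1e-4."""
        protocol = FeedingProtocol("C16:0-CoA", clamp_value=baseline["C16:0-CoA"],
                                   t_step=1000.0)
        grid = np.concatenate([[0.0, 500.0], 1000.0 + np.arange(0.0, 301.0, 30.0)])
        traj = simulate_timecourse(model, baseline, grid, protocol)
        for sp in ("malonyl-ACP", "C16:0-ACP", "C18:1-ACP", "holo-ACP",
                   "PlsB", "PlsC"):
            assert fold_change_at(traj, sp) == pytest.approx(1.0, abs=1e-4)

    def test_pre_step_window_is_flat(self, palmitate):
        """Over the last 10% of the pre-step window every non-clamped
        species varies by less than 0.1% (genuine steady state)."""
        traj = palmitate.trajectory
        t_step = palmitate.t_step
        mask = (traj.times >= 0.9 * t_step) & (traj.times <= t_step)
        window = traj.values[mask]
        model = traj.model
        for i, sp in enumerate(model.species):
            if sp in model.clamped or window[:, i].max() < 1e-9:
                continue
            spread = np.ptp(window[:, i]) / window[:, i].max()
            assert spread < 1e-3, sp

    def test_conservation_drift_below_tolerance(self, palmitate):
        traj = palmitate.trajectory
        model = traj.model
        start = model.conserved_totals(traj.values[0])
        end = model.conserved_totals(traj.values[-1])
        for key in start:
            assert end[key] == pytest.approx(start[key], rel=1e-6)

    def test_nonnegativity_at_solver_output(self, palmitate):
        assert palmitate.trajectory.values.min() >= -1e-9

    def test_tolerance_halving_stability(self, model, baseline):
        """Halving rtol/atol changes the reported trajectory by < 1e-6
        relative, so the solver tolerances are converged."""
        protocol = FeedingProtocol("C16:0-CoA", 30.0, t_step=200.0)
        grid = np.concatenate([[0.0, 100.0], 200.0 + np.arange(0.0, 301.0, 50.0)])
        a = simulate_timecourse(model, baseline, grid, protocol,
                                rtol=1e-8, atol=1e-12)
        b = simulate_timecourse(model, baseline, grid, protocol,
                                rtol=5e-9, atol=5e-13)
        scale = np.abs(a.values) + 1e-9
        assert np.max(np.abs(a.values - b.values) / scale) < 1e-6

    def test_determinism(self, model, baseline):
        grid = np.array([0.0, 100.0, 200.0])
        a = simulate_timecourse(model, baseline, grid)
        b = simulate_timecourse(model, baseline, grid)
        assert np.array_equal(a.values, b.values)

    def test_time_grid_resolves_immediate_response(self):
        grid = default_time_grid(8000.0, 3600.0)
        fine = grid[(grid > 8000.0) & (grid <= 8600.0)]
        assert np.all(np.diff(fine) <= 10.0 + 1e-9)


class TestFeedingExperiments:
    @pytest.mark.parametrize("fatty_acid,up,down", [
        ("palmitate", ["C16:0-ACP", "C18:0-ACP"], ["malonyl-ACP"]),
        ("palmitoleate", ["C18:1-ACP"], ["malonyl-ACP"]),
        ("cis-vaccenate", ["C16:0-ACP", "C18:1-ACP"], ["malonyl-ACP"]),
    ])
    def test_immediate_response_signs(self, experiments, fatty_acid, up, down):
        """The immediate (60-300 s) responses of the acyl-ACP pools have
        the observed directions for each fed fatty acid."""
        traj = experiments[fatty_acid].trajectory
        for sp in up:
            assert fold_change_at(traj, sp) > 1.0
        for sp in down:
            assert fold_change_at(traj, sp) < 1.0

    def test_times_reported_relative_to_step(self, palmitate):
        traj = palmitate.trajectory
        assert traj.times[0] == 0.0
        assert traj.times[-1] >= palmitate.t_step + 3600.0

    def test_monotone_accumulation_in_fed_clamp(self, model, baseline):
        """Post-step C16:0-ACP accumulation is nondecreasing in the fed
        C16:0-CoA clamp over a 10x range around the default."""
        folds = []
        grid = np.concatenate([[0.0, 500.0], 1000.0 + np.arange(0.0, 301.0, 30.0)])
        for clamp in (9.5, 30.0, 95.0):
            protocol = FeedingProtocol("C16:0-CoA", clamp, t_step=1000.0)
            traj = simulate_timecourse(model, baseline, grid, protocol)
            folds.append(fold_change_at(traj, "C16:0-ACP"))
        assert folds == sorted(folds)
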