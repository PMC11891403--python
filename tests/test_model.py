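import numpy as np
import pytest

from acylsim.model import (
    PLSB_SUBSTRATES,
    PLSC_SUBSTRATES,
    ModelParams,
    ModelSpec,
    Reaction,
    StateVector,
    acyltransferase_cycle,
    build_model,
)


class TestNetworkStructure:
    def test_conservation_vectors_in_left_null_space(self, model):
        """ACP, PlsB and PlsC moiety vectors annihilate the stoichiometry
        matrix: conservation holds by construction."""
        N = model.stoichiometry_matrix
        for w in (model.acp_weights, model.plsb_weights, model.plsc_weights):
            assert np.abs(w @ N).max() == 0.0

    def test_acyltransferase_substrate_sets(self, model):
        expected = {f"{c}-ACP" for c in ("C16:0", "C16:1", "C18:1")} | \
                   {f"{c}-CoA" for c in ("C16:0", "C16:1", "C18:1")}
        assert set(PLSB_SUBSTRATES) == expected
        assert set(PLSC_SUBSTRATES) == expected
        p = model.params
        # PlsB disfavours C16:1, PlsC disfavours C16:0 (reduced kon)
        for carrier in ("ACP", "CoA"):
            assert p.kon("PlsB", f"C16:1-{carrier}") < p.kon("PlsB", f"C16:0-{carrier}")
            assert p.kon("PlsB", f"C16:1-{carrier}") < p.kon("PlsB", f"C18:1-{carrier}")
            assert p.kon("PlsC", f"C16:0-{carrier}") < p.kon("PlsC", f"C16:1-{carrier}")
            assert p.kon("PlsC", f"C16:0-{carrier}") < p.kon("PlsC", f"C18:1-{carrier}")

    def test_clamped_set_contains_boundary_species(self, model):
        assert {"acetyl-CoA", "G3P", "C16:0-CoA", "C16:1-CoA",
                "C18:1-CoA"} <= set(model.clamped)

    def test_zero_elongation_weight_cuts_reachability(self):
        """Setting one elongation weight to zero makes that chain and all
        longer chains on its branch unreachable from the initiation
        substrates (graph-reachability oracle over the reaction network)."""
        m = build_model({"elong_weights": {"C14:0": 0.0, "C18:1": 0.06,
                                           "C18:0": 0.002}})
        # AND-semantics closure: a species is producible once every
        # substrate of some producing reaction is available
        reachable = set(m.clamped) | {"holo-ACP", "PlsB", "PlsC"}
        changed = True
        while changed:
            changed = False
            for rxn in m.reactions:
                subs = {s for s, c in rxn.stoich.items() if c < 0}
                prods = {s for s, c in rxn.stoich.items() if c > 0}
                if subs <= reachable and not prods <= reachable:
                    reachable |= prods
                    changed = True
        for unreachable in ("C14:0-ACP", "C16:0-ACP", "C18:0-ACP"):
            assert unreachable not in reachable
        # the unsaturated branch is unaffected
        for ok in ("C12:0-ACP", "C16:1-ACP", "C18:1-ACP"):
            assert ok in reachable

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="not_a_param"):
            build_model({"not_a_param": 1.0})

    @pytest.mark.parametrize("bad", [
        {"vmax_acc": -1.0},
        {"disfavor_factor": 0.5},
        {"elong_weights": {"C12:0": 1.5}},
        # disfavoured C16:1 kon would not be below the C18:1 kon
        {"kon_weights": {"PlsB": {"C18:1": 0.05}, "PlsC": {}}},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            build_model(bad)


class TestRhs:
    def test_clamped_species_have_zero_derivative(self, model):
        rng = np.random.default_rng(0)
        c = rng.uniform(0.1, 5.0, len(model.species))
        dc = model.rhs(c)
        for s in model.clamped:
            assert dc[model.index[s]] == 0.0

    def test_moiety_weighted_derivatives_vanish(self, model):
        rng = np.random.default_rng(1)
        c = rng.uniform(0.0, 10.0, len(model.species))
        dc = model.rhs(c)
        assert abs(model.acp_weights @ dc) < 1e-10
        assert abs(model.plsb_weights @ dc) < 1e-10
        assert abs(model.plsc_weights @ dc) < 1e-10

    def test_rhs_rejects_wrong_length(self, model):
        with pytest.raises(ValueError):
            model.rhs(np.ones(3))

    def test_toy_single_reaction_matches_hand_computed_rate(self):
        """A hand-assembled two-species network with one MM reaction has
        the derivative vmax*s/(km+s) computed by hand."""
        params = ModelParams()
        rxn = Reaction("toy", {"A": -1, "B": +1},
                       lambda c: 2.0 * c[0] / (3.0 + c[0]))
        toy = ModelSpec(params, ["A", "B"], [rxn], clamped=[])
        dc = toy.rhs(np.array([6.0, 0.0]))
        expected = 2.0 * 6.0 / (3.0 + 6.0)  # = 4/3
        assert dc[0] == pytest.approx(-expected)
        assert dc[1] == pytest.approx(expected)


class TestConservedTotals:
    def test_holo_only_state(self, model):
        s = StateVector(model, {"holo-ACP": 10.0})
        assert model.conserved_totals(s)["acp_total"] == pytest.approx(10.0)

    def test_complex_counts_toward_both_totals(self, model):
        s = StateVector(model, {"PlsB:C16:0-ACP": 1.0, "holo-ACP": 2.0})
        totals = model.conserved_totals(s)
        assert totals["acp_total"] == pytest.approx(3.0)
        assert totals["plsb_total"] == pytest.approx(1.0)
        assert totals["plsc_total"] == pytest.approx(0.0)

    def test_coa_complex_carries_no_acp(self, model):
        s = StateVector(model, {"PlsB:C16:0-CoA": 1.0})
        totals = model.conserved_totals(s)
        assert totals["acp_total"] == 0.0
        assert totals["plsb_total"] == pytest.approx(1.0)

    def test_initial_state_matches_declared_totals(self, model):
        totals = model.conserved_totals(model.initial_state())
        for key, val in model.totals.items():
            assert totals[key] == pytest.approx(val, rel=1e-12)


class TestStateVector:
    def test_unknown_species_rejected(self, model):
        with pytest.raises(KeyError):
            StateVector(model, {"unobtainium": 1.0})

    def test_negative_concentration_rejected(self, model):
        with pytest.raises(ValueError):
            StateVector(model, {"holo-ACP": -0.5})


class TestAcyltransferaseCycle:
    def test_no_free_enzyme_means_no_binding(self, model):
        s = StateVector(model, {"C16:0-ACP": 5.0})  # PlsB absent
        fluxes = acyltransferase_cycle(model, "PlsB", "C16:0-ACP", s)
        assert fluxes["bind"] == 0.0

    def test_bind_flux_is_mass_action(self, model):
        s = StateVector(model, {"PlsB": 0.5, "C18:1-ACP": 2.0})
        fluxes = acyltransferase_cycle(model, "PlsB", "C18:1-ACP", s)
        kon = model.params.kon("PlsB", "C18:1-ACP")
        assert fluxes["bind"] == pytest.approx(kon * 0.5 * 2.0)

    def test_plsb_feedback_halves_catalysis_at_half_point(self):
        """With total PL equal to k_pl_feedback and Hill 1, PlsB catalysis
        is exactly half its unregulated value."""
        m1 = build_model({"pl_hill": 1.0})
        half = {"PlsB:C16:0-ACP": 1.0, "G3P": m1.params.g3p,
                "PL(C16:0,C16:1)": m1.params.k_pl_feedback}
        none = {"PlsB:C16:0-ACP": 1.0, "G3P": m1.params.g3p}
        f_half = acyltransferase_cycle(m1, "PlsB", "C16:0-ACP",
                                       StateVector(m1, half))
        f_none = acyltransferase_cycle(m1, "PlsB", "C16:0-ACP",
                                       StateVector(m1, none))
        assert f_half["catalyze"] == pytest.approx(0.5 * f_none["catalyze"])

    def test_substrate_outside_set_rejected(self, model):
        with pytest.raises(ValueError):
            acyltransferase_cycle(model, "PlsB", "C14:0-ACP",
                                  model.initial_state())
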