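import dataclasses
import math

import numpy as np
import pytest

from avpvk.errors import CalibrationError, InvalidSpecError
from avpvk.gating import DrivingForce, DrivingLaw, GatingSpec, TauForm, TauSpec
from avpvk.neuron import (
    ConductanceSpec,
    NeuronModel,
    calibrate,
    isolate,
    markov_rates,
    markov_steady_state,
    measure_input_resistance,
    preset,
    resting_potential,
    steady_state_model,
    swap,
)

DI_GBAR = {"slow": 37.4, "fast": 36.9, "resid": 29.7, "NaP": 0.14, "CaT": 1.60, "h": 0.11}
PRO_GBAR = {"slow": 42.0, "fast": 45.7, "resid": 32.9, "NaP": 0.20, "CaT": 2.0, "h": 0.64}


class TestPresets:
    def test_diestrus_gbar(self, di_model):
        for name, g in DI_GBAR.items():
            assert di_model.channel(name).gbar == pytest.approx(g)
        assert di_model.g_leak == pytest.approx(1.06)

    def test_proestrus_gbar(self, pro_model):
        for name, g in PRO_GBAR.items():
            assert pro_model.channel(name).gbar == pytest.approx(g)
        assert pro_model.channel("h").gbar == pytest.approx(0.64)
        assert pro_model.g_leak == pytest.approx(0.88)

    def test_nat_shared(self, di_model, pro_model):
        assert di_model.nat.gbar == pytest.approx(68.12)
        assert di_model.nat == pro_model.nat

    @pytest.mark.parametrize("stage", ["diestrus", "proestrus"])
    def test_reversals_and_laws(self, stage):
        m = preset(stage)
        for name in ("slow", "fast", "resid"):
            c = m.channel(name)
            assert c.df.law is DrivingLaw.GHK
            assert c.df.E == pytest.approx(-92.0)
        for name, E in (("NaP", 50.0), ("CaT", 155.0), ("h", -19.9)):
            c = m.channel(name)
            assert c.df.law is DrivingLaw.OHMIC
            assert c.df.E == pytest.approx(E)
        assert m.Cm == pytest.approx(17.62)
        assert m.E_leak == pytest.approx(-70.0)

    def test_gate_exponents(self, di_model):
        assert di_model.channel("CaT").r == 2
        for name in ("slow", "fast", "resid", "NaP", "h"):
            assert di_model.channel(name).r == 1

    def test_hcn_has_no_inactivation(self, di_model):
        assert di_model.channel("h").inactivation == ()

    def test_unknown_stage(self):
        with pytest.raises(ValueError):
            preset("estrus")


class TestMarkov:
    def test_alpha_midpoint(self, di_model):
        a, _, _, _ = markov_rates(di_model.nat, -65.24)
        assert a == pytest.approx(38.40 / 2, rel=1e-9)

    def test_beta_depolarized_limit(self, di_model):
        _, b, _, _ = markov_rates(di_model.nat, 1e4)
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_r3_hand_evaluation(self, di_model):
        _, _, _, r3 = markov_rates(di_model.nat, -100.0)
        expected = 0.014 / (1 + math.exp((-100 + 12.68) / 3.08))
        assert r3 == pytest.approx(expected, rel=1e-12)

    def test_rates_nonnegative(self, di_model):
        for V in np.linspace(-120, 60, 37):
            assert all(r >= 0 for r in markov_rates(di_model.nat, V))

    def test_occupancies_sum_to_one(self, di_model):
        for V in (-100.0, -70.0, -40.0, 0.0):
            C, O, I = markov_steady_state(di_model.nat, V)
            assert C + O + I == pytest.approx(1.0, abs=1e-12)
            assert 0 <= C <= 1 and 0 <= O <= 1 and 0 <= I <= 1

    def test_steady_state_matches_dense_relaxation(self, di_model):
        # oracle: explicit time stepping of the occupancy ODEs for 10 s
        V = -70.0
        a, b, r1, r3 = markov_rates(di_model.nat, V)
        C, O = 1.0, 0.0
        dt = 0.001
        for _ in range(int(10_000 / dt)):
            I = 1.0 - C - O
            dC = b * O + r3 * I - a * C
            dO = a * C - (b + r1) * O
            C += dt * dC
            O += dt * dO
        Cs, Os, _ = markov_steady_state(di_model.nat, V)
        assert C == pytest.approx(Cs, abs=1e-6)
        assert O == pytest.approx(Os, abs=1e-6)


class TestSteadyStateModel:
    def test_gates_are_fixed_points(self, di_model):
        from avpvk.gating import steady_state, time_constant

        V = -55.0
        state = steady_state_model(di_model, V)
        for c in di_model.conductances:
            m, hs = state.gates[c.name]
            assert (steady_state(c.m, V) - m) / time_constant(c.m.tau, V) == pytest.approx(0.0)
            for (g, _), h in zip(c.inactivation, hs):
                assert steady_state(g, V) == pytest.approx(h)

    def test_markov_normalized(self, di_model):
        C, O, I = steady_state_model(di_model, -70.0).markov
        assert C + O + I == pytest.approx(1.0, abs=1e-12)


def _leak_only_cell(g=1.0, E=-70.0):
    tau = TauSpec(form=TauForm.CONSTANT, fixed_value=1.0)
    silent = ConductanceSpec(
        name="probe", gbar=0.0,
        df=DrivingForce(law=DrivingLaw.OHMIC, E=0.0),
        m=GatingSpec(V50=-40.0, K=-5.0, tau=tau),
    )
    nat = dataclasses.replace(preset("diestrus").nat, gbar=0.0)
    return NeuronModel(Cm=17.62, conductances=(silent,), nat=nat,
                       g_leak=g, E_leak=E, label="passive")


class TestCalibrate:
    def test_leak_only_cell_is_exact(self):
        m = calibrate(_leak_only_cell(g=1.0, E=-70.0))
        assert m.Ihold == pytest.approx(0.0, abs=1e-9)
        assert m.g_leak == pytest.approx(1.0, rel=5e-3)

    def test_rest_within_50_microvolts(self, di_cal):
        assert abs(resting_potential(di_cal) + 70.0) < 0.05  # 50 uV

    def test_rinput_within_half_percent(self, di_cal):
        R = measure_input_resistance(di_cal)
        assert R == pytest.approx(1.0, rel=5e-3)

    def test_idempotent(self, di_cal):
        again = calibrate(di_cal)
        assert again.g_leak == pytest.approx(di_cal.g_leak, rel=1e-3)
        assert abs(again.Ihold - di_cal.Ihold) < max(0.001, abs(di_cal.Ihold) * 1e-3) + 0.01

    def test_passive_rin_is_inverse_leak(self):
        m = _leak_only_cell(g=2.0, E=-70.0)
        R = measure_input_resistance(m)
        assert R == pytest.approx(1.0 / 2.0, rel=1e-3)

    def test_infeasible_raises(self, di_model):
        # the voltage-gated channels set a slope-conductance floor at rest,
        # so a huge target input resistance needs a negative leak
        with pytest.raises(CalibrationError):
            calibrate(di_model, Rin_target=50.0)


class TestSwap:
    def test_empty_swap_identity(self, di_cal, pro_cal):
        assert swap(di_cal, pro_cal, set()) is di_cal

    def test_k_swap_fields(self, di_cal, pro_cal):
        hybrid = swap(di_cal, pro_cal, {"slow", "fast", "resid"}, recalibrate=False)
        for name in ("slow", "fast", "resid"):
            assert hybrid.channel(name).gbar == pro_cal.channel(name).gbar
        for name in ("NaP", "CaT", "h"):
            assert hybrid.channel(name).gbar == di_cal.channel(name).gbar
        assert hybrid.label == "hybrid"

    def test_involution(self, di_cal, pro_cal):
        names = set(di_cal.channel_names)
        there = swap(di_cal, pro_cal, names, recalibrate=False)
        back = swap(there, di_cal, names, recalibrate=False)
        assert back.conductances == di_cal.conductances

    def test_unknown_name(self, di_cal, pro_cal):
        with pytest.raises(KeyError):
            swap(di_cal, pro_cal, {"nope"})

    def test_recalibrated_hybrid_rests_at_target(self, di_cal, pro_cal):
        hybrid = swap(di_cal, pro_cal, {"CaT"})
        assert abs(resting_potential(hybrid) + 70.0) < 0.05


class TestInvariantValidation:
    def test_duplicate_names_rejected(self, di_model):
        with pytest.raises(InvalidSpecError):
            di_model.replace(conductances=di_model.conductances + (di_model.conductances[0],))

    def test_bad_inactivation_weights(self, di_model):
        c = di_model.channel("slow")
        bad = tuple((g, 0.4) for g, _ in c.inactivation)
        with pytest.raises(InvalidSpecError):
            dataclasses.replace(c, inactivation=bad)

    def test_isolate_zeroes_everything_else(self, di_model):
        iso = isolate(di_model, "slow")
        assert iso.channel("slow").gbar == pytest.approx(37.4)
        assert iso.nat.gbar == 0.0
        assert all(c.gbar == 0.0 for c in iso.conductances if c.name != "slow")
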