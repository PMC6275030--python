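import copy

import numpy as np
import pytest

from abscopal.calibration import (
    CalibrationArm,
    CalibrationDataset,
    FREE_PARAMETER_NAMES,
    _vector_from,
    fit,
    goodness_report,
    infiltration_ratio,
    objective,
    params_from_vector,
)
from abscopal.parameters import (
    ImmunotherapyProtocol,
    RadiationProtocol,
    default_parameters,
)
from abscopal.synthetic import design_from_paper, generate


@pytest.fixture(scope="module")
def x_true(params, table):
    return _vector_from(params, table)


class TestObjective:
    def test_zero_at_generating_parameters(self, noiseless_dataset, x_true):
        assert objective(x_true, noiseless_dataset) < 1e-4

    def test_zero_at_generating_parameters_adaptive(self, params, table):
        # small design to keep the adaptive re-solve cheap
        design = design_from_paper(noise_cv=0.0, seed=2,
                                   restrict_combinations=True)
        data = generate(design, params, table)
        assert objective(x_true_from(params, table), data, accurate=True) < 1e-4

    def test_relative_error_formula(self, params, table, noiseless_dataset):
        """Scaling every measured volume by 1/1.2 makes each residual exactly
        0.2, so the objective equals 0.04 per volume point (the hand value
        2*(0.2)^2 = 0.08 for one time point at both sites)."""
        data = copy.deepcopy(noiseless_dataset)
        arm = data.arms[0]
        one_day = CalibrationArm(arm_id=arm.arm_id, rt=arm.rt, it=arm.it,
                                 days=arm.days[:1], v1=arm.v1[:1] / 1.2,
                                 v2=arm.v2[:1] / 1.2)
        small = CalibrationDataset(arms=[one_day], ic=data.ic)
        x = _vector_from(params, table)
        assert objective(x, small) == pytest.approx(2 * 0.2 ** 2, abs=1e-6)

    def test_infiltration_term_adds_squared_error(self, params, table,
                                                  noiseless_dataset):
        data = copy.deepcopy(noiseless_dataset)
        combo = next(a for a in data.arms if a.infiltration_ratio is not None)
        base = objective(_vector_from(params, table), data)
        combo.infiltration_ratio += 0.5  # simulated ratio now off by 0.5
        shifted = objective(_vector_from(params, table), data)
        assert shifted - base == pytest.approx(0.25, abs=1e-6)

    def test_invariant_to_arm_order(self, noiseless_dataset, x_true):
        data = copy.deepcopy(noiseless_dataset)
        data.arms = data.arms[::-1]
        assert objective(x_true, data) == pytest.approx(
            objective(x_true, noiseless_dataset), abs=1e-12)

    def test_nonpositive_measured_volume_rejected(self, noiseless_dataset):
        arm = noiseless_dataset.arms[0]
        with pytest.raises(ValueError, match="> 0"):
            CalibrationArm(arm_id="bad", rt=arm.rt, it=arm.it, days=arm.days,
                           v1=np.zeros_like(arm.v1), v2=arm.v2)


def x_true_from(params, table):
    return _vector_from(params, table)


class TestInfiltrationRatio:
    def test_control_arm_ratio_is_one(self, params, table):
        ctrl = CalibrationArm(arm_id="c", rt=RadiationProtocol(),
                              it=ImmunotherapyProtocol(),
                              days=np.array([12.0]), v1=np.array([32.0]),
                              v2=np.array([21.0]))
        assert infiltration_ratio(params, table, ctrl, ctrl) == \
            pytest.approx(1.0, rel=1e-9)

    def test_treatment_boosts_secondary_infiltration(self, params, table):
        ctrl = CalibrationArm(arm_id="c", rt=RadiationProtocol(),
                              it=ImmunotherapyProtocol(),
                              days=np.array([12.0]), v1=np.array([32.0]),
                              v2=np.array([21.0]))
        combo = CalibrationArm(arm_id="x", rt=RadiationProtocol.daily(12, 3, 8.0),
                               it=ImmunotherapyProtocol(injection_times=[12, 14, 16]),
                               days=np.array([12.0]), v1=np.array([32.0]),
                               v2=np.array([21.0]))
        assert infiltration_ratio(params, table, combo, ctrl) >= 1.0


class TestGoodnessReport:
    def test_perfect_fit_is_zero(self, noiseless_dataset, x_true):
        rep = goodness_report(x_true, noiseless_dataset)
        assert rep["abs_mean_mm3"] == pytest.approx(0.0, abs=1e-6)
        assert rep["rel_mean"] == pytest.approx(0.0, abs=1e-8)
        assert rep["n_points"] == noiseless_dataset.n_points

    def test_two_point_toy_hand_check(self, params, table, noiseless_dataset):
        data = copy.deepcopy(noiseless_dataset)
        arm = data.arms[0]
        # shift both sites by +10% at one day and -10% at another
        toy = CalibrationArm(arm_id="t", rt=arm.rt, it=arm.it,
                             days=arm.days[:2],
                             v1=arm.v1[:2] * np.array([1.1, 1 / 1.1]),
                             v2=arm.v2[:2] * np.array([1.1, 1 / 1.1]))
        rep = goodness_report(_vector_from(params, table),
                              CalibrationDataset(arms=[toy], ic=data.ic))
        assert rep["n_points"] == 4
        # relative deviations: |sim-obs|/obs = 1/11 (obs high) and 0.1 (obs low)
        assert rep["rel_mean"] == pytest.approx((2 * (1 / 11) + 2 * 0.1) / 4,
                                                rel=1e-6)


class TestFit:
    def test_start_at_truth_converges_immediately(self, noiseless_dataset,
                                                  x_true):
        rep = fit(noiseless_dataset, n_starts=1, seed=0, x0=x_true,
                  n_polish=1)
        assert rep.objective < 1e-8
        assert rep.convergence_fraction == 1.0

    def test_recovers_identifiable_quantities(self, noiseless_dataset, params,
                                              table):
        """Noiseless recovery of the identifiable parameters and parameter
        combinations: the effector-density scale is a gauge freedom (only
        a*w and w2*AI_D are observable), so those enter as products."""
        rep = fit(noiseless_dataset, n_starts=6, seed=5)
        assert rep.objective < 1e-4
        for name in ("K", "d", "e", "clr"):
            assert rep.parameters[name] == pytest.approx(
                getattr(params, name), rel=0.05), name
        for name, dose in (("SF6", 6.0), ("SF8", 8.0), ("SF20", 20.0)):
            assert rep.parameters[name] == pytest.approx(
                table.lookup(dose)[0], rel=0.05), name
        assert rep.parameters["a"] * rep.parameters["w"] == pytest.approx(
            params.a * params.w, rel=0.05)
        for name, dose in (("AI6", 6.0), ("AI8", 8.0), ("AI20", 20.0)):
            assert rep.parameters["w2"] * rep.parameters[name] == pytest.approx(
                params.w2 * table.lookup(dose)[1], rel=0.05), name

    def test_degenerate_directions_flagged(self, noiseless_dataset, x_true):
        rep = fit(noiseless_dataset, n_starts=1, seed=0, x0=x_true, n_polish=1)
        flagged = {frozenset(p[:2]) for p in rep.sensitivity["correlated_pairs"]}
        assert frozenset(("a", "w")) in flagged

    def test_deterministic_given_seed(self, noiseless_dataset):
        rep1 = fit(noiseless_dataset, n_starts=3, seed=9)
        rep2 = fit(noiseless_dataset, n_starts=3, seed=9)
        assert rep1.parameters == rep2.parameters
        assert rep1.convergence_fraction == rep2.convergence_fraction
        assert [c["cost"] for c in rep1.clusters] == \
            [c["cost"] for c in rep2.clusters]

    def test_noisy_fit_error_matches_noise_level(self, params, table):
        """At the generating parameters, a 20%-CV dataset shows ~20% mean
        relative deviation."""
        design = design_from_paper(noise_cv=0.20, seed=21)
        data = generate(design, params, table)
        rep = goodness_report(_vector_from(params, table), data)
        assert 0.12 < rep["rel_mean"] < 0.30

    def test_invalid_start_count(self, noiseless_dataset):
        with pytest.raises(ValueError):
            fit(noiseless_dataset, n_starts=0)


class TestVectorMapping:
    def test_roundtrip(self, params, table):
        x = _vector_from(params, table)
        p2, t2 = params_from_vector(x)
        assert p2 == params
        assert t2.entries == table.entries
        assert len(FREE_PARAMETER_NAMES) == 13
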