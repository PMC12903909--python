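"""Chemistry/geometry/complexity score arithmetic and the linear correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flpga import (
    DescriptorSet,
    FitnessConfig,
    LinearCorrection,
    fit_linear_correction,
    gaussian_score,
    geometry_score,
    r_chem,
    scores,
    scs_score,
)
from flpga.fitness import ConfigurationError

finite = st.floats(min_value=-500, max_value=500, allow_nan=False)


class TestRChem:
    def test_reported_lead_candidate_arithmetic(self):
        # FEPA -228.6, FEHA -87.3: cumulative -315.9, 1.3 kcal/mol off the line
        assert r_chem(-228.6, -87.3) == pytest.approx(1.3 / math.sqrt(2), abs=1e-12)

    def test_on_line_point_is_zero(self):
        assert r_chem(-200.0, -117.2) == 0.0

    def test_unit_step_off_the_line(self):
        base = r_chem(-200.0, -117.2)
        assert r_chem(-200.0 + math.sqrt(2), -117.2) - base == \
            pytest.approx(1.0, abs=1e-12)

    @given(fepa=finite, feha=finite)
    @settings(max_examples=50, deadline=None)
    def test_symmetric_in_descriptor_exchange(self, fepa, feha):
        assert r_chem(fepa, feha) == r_chem(feha, fepa)


class TestGaussianScore:
    def test_peak_at_target(self):
        assert gaussian_score(2.7, 2.7, 0.6) == 1.0

    def test_one_sigma_value(self):
        assert gaussian_score(3.3, 2.7, 0.6) == pytest.approx(math.exp(-0.5), rel=1e-12)

    @given(delta=st.floats(min_value=0, max_value=50, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_about_target(self, delta):
        # float subtraction of the two offsets may differ in the last ulp
        assert gaussian_score(100 + delta, 100, 0.75) == pytest.approx(
            gaussian_score(100 - delta, 100, 0.75), rel=1e-9, abs=1e-300)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            gaussian_score(1.0, 1.0, 0.0)


class TestGeometryScore:
    @pytest.mark.parametrize("fd,fphi,c1,c2,expected", [
        (1.0, 1.0, 0.5, 0.5, 1.0),
        (1.0, 0.0, 0.5, 0.5, 0.5),
        (0.5, 1.0, 0.7, 0.3, 0.65),
    ])
    def test_weighted_sum(self, fd, fphi, c1, c2, expected):
        assert geometry_score(fd, fphi, c1, c2) == pytest.approx(expected)


class TestScores:
    def _ds(self, **kw):
        base = dict(fepa=-228.6, feha=-87.3, d=2.7, phi=100.0, scs=3.0, q=1)
        base.update(kw)
        return DescriptorSet(**base)

    def test_quench_gate_zeroes_cs_and_gs(self):
        fv = scores(self._ds(q=0))
        assert fv.cs == 0.0 and fv.gs == 0.0
        assert fv.scs == 3.0  # complexity passes through the gate

    def test_on_line_chemistry_saturates_at_inverse_epsilon(self):
        fv = scores(self._ds(fepa=-230.0, feha=-87.2))
        assert fv.cs == pytest.approx(1.0 / 1e-3)

    def test_lead_candidate_chemistry_score(self):
        fv = scores(self._ds())
        assert fv.cs == pytest.approx(1.0 / r_chem(-228.6, -87.3), rel=1e-12)
        assert fv.cs == pytest.approx(1.0879, abs=1e-4)

    def test_on_target_geometry_is_unity(self):
        assert scores(self._ds()).gs == pytest.approx(1.0)

    def test_phi_width_in_radians_keeps_angle_term_alive(self):
        # 30 degrees off target must still cost a visible share of GS
        fv = scores(self._ds(phi=70.0))
        assert 0.5 < fv.gs < 0.95

    def test_degrees_convention_is_available(self):
        cfg = FitnessConfig(phi_units="degrees")
        fv = scores(self._ds(phi=70.0), cfg)
        assert fv.gs == pytest.approx(0.5)  # angle term numerically dead


class TestLinearCorrection:
    def test_exact_line_recovered(self):
        pairs = [(x, 2 * x + 1) for x in (-10.0, 0.0, 5.0, 20.0)]
        c = fit_linear_correction(pairs)
        assert (c.slope, c.intercept, c.r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_identity_pairs(self):
        c = fit_linear_correction([(x, x) for x in (-1.0, 0.0, 1.0)])
        assert c.apply(42.0) == pytest.approx(42.0)

    def test_noisy_slope_recovery(self, rng):
        x = rng.uniform(-300, -100, size=50)
        y = 1.1 * x + 5 + rng.normal(0, 2.0, size=50)
        c = fit_linear_correction(list(zip(x, y)))
        se = 2.0 / (np.std(x) * np.sqrt(50))  # approximate slope standard error
        assert abs(c.slope - 1.1) < 3 * se
        assert c.r2 > 0.95

    def test_degenerate_input_rejected(self):
        with pytest.raises(ConfigurationError, match="degenerate"):
            fit_linear_correction([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])

    def test_identity_correction_is_identity_limit(self):
        c = LinearCorrection(slope=1.0, intercept=0.0, r2=1.0)
        assert c.apply(-228.6) == -228.6


class TestScs:
    def test_minimal_molecule_scores_low(self):
        assert scs_score("C") < 2.0

    def test_deterministic(self):
        smi = "CC(C)c1ccccc1B(c1ccccc1)c1ccccc1"
        assert scs_score(smi) == scs_score(smi)

    def test_ring_fusion_does_not_decrease_complexity(self):
        chain = scs_score("c1ccccc1")
        fused1 = scs_score("c1ccc2ccccc2c1")
        fused2 = scs_score("c1ccc2cc3ccccc3cc2c1")
        assert chain <= fused1 <= fused2

    def test_bounded_in_1_5(self):
        huge = "C1CC2CC3CC4CC5CC6CCC6C5C4C3C2C1" * 1
        assert 1.0 <= scs_score(huge) <= 5.0
        assert 1.0 <= scs_score("C") <= 5.0

    def test_invalid_smiles_errors(self):
        with pytest.raises(ValueError):
            scs_score("not-a-smiles")

    def test_external_backend_is_clipped(self):
        assert scs_score("C", backend="external-model",
                         external_model=lambda s: 7.3) == 5.0
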