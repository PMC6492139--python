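"""Signal model: b-values, GPD sphere series, compartments, ADC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dwires.change_scenarios import apply_cell_loss, apply_shrinkage
from dwires.protocols import CLINICAL_ADC_PROTOCOL, PROTOCOLS
from dwires.signal_model import (
    BimodalTissue,
    Measurement,
    PhysicsConstants,
    Tissue,
    adc_fit,
    b_value,
    bessel_derivative_roots,
    extracellular_signal,
    mixture_signal,
    sphere_signal,
    tortuous_diffusivity,
    total_signal,
)


class TestBValue:
    @pytest.mark.parametrize(
        "G, expected",
        [(13.2, 150.0), (18.6, 300.0), (24.0, 500.0), (30.4, 800.0)],
    )
    def test_clinical_protocol_b_values(self, G, expected):
        """The printed clinical ADC measurements hit their nominal b-values."""
        m = Measurement(G=G, Delta=32.0, delta=22.2)
        assert b_value(m) == pytest.approx(expected, rel=0.02)

    def test_zero_gradient(self):
        assert b_value(Measurement(G=0.0, Delta=30.0, delta=10.0)) == 0.0

    @given(
        G=st.floats(1.0, 300.0),
        Delta=st.floats(15.0, 80.0),
        frac=st.floats(0.05, 1.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_positive_and_increasing_in_G(self, G, Delta, frac):
        delta = frac * min(Delta, 40.0)
        m = Measurement(G=G, Delta=Delta, delta=delta)
        m2 = Measurement(G=G * 1.1, Delta=Delta, delta=delta)
        assert b_value(m) > 0
        assert b_value(m2) > b_value(m)


class TestSphereSignal:
    def test_first_eigen_root(self):
        """First root of the sphere eigenvalue equation (j1'(x) = 0)."""
        roots = bessel_derivative_roots(5)
        assert roots[0] == pytest.approx(2.0816, abs=1e-4)
        assert np.all(np.diff(roots) > 0)

    def test_zero_gradient_gives_unity(self):
        m = Measurement(G=0.0, Delta=30.0, delta=10.0)
        assert sphere_signal(10.0, 1.0, m) == 1.0

    def test_free_diffusion_limit(self):
        """For R >> diffusion length the sphere signal approaches exp(-b D)."""
        m = Measurement(G=40.0, Delta=30.0, delta=10.0)
        constants = PhysicsConstants(n_terms=150)
        got = sphere_signal(200.0, 1.0, m, constants)
        want = math.exp(-b_value(m) * 1e-3 * 1.0)
        assert got == pytest.approx(want, rel=0.01)

    def test_unconverged_series_is_refused(self):
        """Too few terms for a large sphere raises instead of returning junk."""
        m = Measurement(G=40.0, Delta=30.0, delta=10.0)
        with pytest.raises(ValueError, match="n_terms"):
            sphere_signal(200.0, 1.0, m, PhysicsConstants(n_terms=10))

    def test_series_converged_at_default_truncation(self):
        """Doubling the truncation changes ln S_i negligibly (< 1e-5, i.e.
        orders of magnitude below the noise floor) over the whole fitting
        range at clinical gradient strengths."""
        from dwires.signal_model import sphere_log_attenuation

        c20 = PhysicsConstants(n_terms=20)
        c40 = PhysicsConstants(n_terms=40)
        for protocol in (PROTOCOLS["D-opt_80"], PROTOCOLS["Non-opt_80"]):
            for m in protocol:
                for R in (0.5, 2.0, 10.0, 25.0):
                    for D in (0.1, 1.0, 3.0):
                        a = sphere_log_attenuation(R, D, m.G, m.Delta, m.delta, c20)
                        b = sphere_log_attenuation(R, D, m.G, m.Delta, m.delta, c40)
                        assert abs(a - b) < 1e-5

    def test_monotonically_decreasing_in_G(self):
        for G1, G2 in zip(range(0, 100, 10), range(10, 110, 10)):
            m1 = Measurement(G=float(G1), Delta=30.0, delta=10.0)
            m2 = Measurement(G=float(G2), Delta=30.0, delta=10.0)
            assert sphere_signal(8.0, 1.5, m2) < sphere_signal(8.0, 1.5, m1) or G1 == 0


class TestExtracellular:
    def test_no_weighting(self):
        assert extracellular_signal(0.5, 2.0, 0.0) == 1.0

    def test_no_tortuosity_when_empty(self):
        b = 1000.0
        assert extracellular_signal(0.0, 2.0, b) == pytest.approx(
            math.exp(-b * 1e-3 * 2.0)
        )

    def test_hindrance_rule_value(self):
        # D_tort = D_e / (1 + f_i/2) -> 2/1.25 = 1.6 at f_i = 0.5
        got = extracellular_signal(0.5, 2.0, 1000.0)
        assert got == pytest.approx(math.exp(-1.6), rel=1e-12)

    @pytest.mark.parametrize("model", ["hindrance", "linear", "sqrt"])
    def test_tortuosity_reduces_diffusivity(self, model):
        assert tortuous_diffusivity(2.0, 0.5, model) < 2.0
        assert tortuous_diffusivity(2.0, 0.0, model) == pytest.approx(2.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="tortuosity"):
            tortuous_diffusivity(2.0, 0.5, "bogus")


class TestTotalSignal:
    def test_t2_decay_at_zero_gradient(self, baseline):
        m = Measurement(G=0.0, Delta=40.0, delta=20.0, TE=100.0)
        assert total_signal(baseline, m) == pytest.approx(math.exp(-0.8), rel=1e-12)

    def test_single_compartment_limits(self):
        m = Measurement(G=40.0, Delta=30.0, delta=10.0)
        b = b_value(m)
        t_intra = Tissue(R=8.0, f_i=1.0, D_i=1.0, D_e=2.0)
        want = math.exp(-m.TE / 125.0) * sphere_signal(8.0, 1.0, m)
        assert total_signal(t_intra, m) == pytest.approx(want, rel=1e-12)
        t_extra = Tissue(R=8.0, f_i=1e-12, D_i=1.0, D_e=2.0)
        want = math.exp(-m.TE / 125.0) * math.exp(-b * 1e-3 * 2.0)
        assert total_signal(t_extra, m) == pytest.approx(want, rel=1e-6)

    def test_strictly_decreasing_in_G(self, baseline):
        sigs = [
            total_signal(baseline, Measurement(G=g, Delta=30.0, delta=10.0))
            for g in np.linspace(0, 200, 21)
        ]
        assert np.all(np.diff(sigs) < 0)

    @given(t2=st.floats(40.0, 300.0))
    @settings(max_examples=20, derandomize=True)
    def test_normalization_independent_of_t2(self, t2):
        """S(G)/S(G=0) at equal TE cancels the relaxation factor."""
        t = Tissue(R=10.0, f_i=0.5, D_i=1.0, D_e=2.0, T2=t2)
        m = Measurement(G=60.0, Delta=30.0, delta=10.0)
        m0 = Measurement(G=0.0, Delta=30.0, delta=10.0, TE=m.TE)
        ref = Tissue(R=10.0, f_i=0.5, D_i=1.0, D_e=2.0, T2=125.0)
        ratio = total_signal(t, m) / total_signal(t, m0)
        ratio_ref = total_signal(ref, m) / total_signal(ref, m0)
        assert ratio == pytest.approx(ratio_ref, rel=1e-10)


class TestMixtureSignal:
    def test_unimodal_degenerate_case(self, baseline):
        bt = BimodalTissue(
            R_same=10.0, R_shrunk=5.0, f_same=0.6, f_shrunk=0.0, D_i=1.0, D_e=2.0
        )
        for m in PROTOCOLS["D-opt_80"]:
            assert mixture_signal(bt, m) == pytest.approx(
                total_signal(baseline, m), rel=1e-12
            )

    def test_equal_radii_collapse(self):
        bt = BimodalTissue(
            R_same=9.0, R_shrunk=9.0, f_same=0.25, f_shrunk=0.35, D_i=1.0, D_e=2.0
        )
        t = Tissue(R=9.0, f_i=0.60, D_i=1.0, D_e=2.0)
        for m in PROTOCOLS["D-opt_80"]:
            assert mixture_signal(bt, m) == pytest.approx(total_signal(t, m), rel=1e-12)


class TestAdcFit:
    def test_exact_monoexponential(self):
        b = np.array([150.0, 300.0, 500.0, 800.0])
        s = np.exp(-b * 1e-3 * 1.0)
        assert adc_fit(s, b) == pytest.approx(1.0, rel=1e-12)

    def test_constant_signals_zero_adc(self):
        assert adc_fit([0.5] * 4, [150.0, 300.0, 500.0, 800.0]) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_rejects_nonpositive_signal(self):
        with pytest.raises(ValueError, match="positive"):
            adc_fit([0.5, 0.0], [100.0, 200.0])

    def test_both_changes_increase_adc(self, baseline):
        """Shrinkage and cell loss both raise the ADC of the clinical
        multi-b acquisition, so ADC alone cannot tell them apart."""
        bvals = [b_value(m) for m in CLINICAL_ADC_PROTOCOL]

        def adc_of(t):
            sig = [total_signal(t, m) for m in CLINICAL_ADC_PROTOCOL]
            return adc_fit(sig, bvals)

        adc0 = adc_of(baseline)
        assert adc_of(apply_shrinkage(baseline, 0.60)) > adc0
        assert adc_of(apply_cell_loss(baseline, 0.60)) > adc0


class TestTypes:
    def test_tissue_invariants(self):
        with pytest.raises(ValueError):
            Tissue(R=-1.0, f_i=0.5, D_i=1.0, D_e=2.0)
        with pytest.raises(ValueError):
            Tissue(R=10.0, f_i=1.5, D_i=1.0, D_e=2.0)

    def test_measurement_timing(self):
        with pytest.raises(ValueError):
            Measurement(G=10.0, Delta=10.0, delta=20.0)
        m = Measurement(G=10.0, Delta=30.0, delta=10.0)
        assert m.TE == pytest.approx(53.0)  # minimum feasible TE
        # long timing pins TE at the 100 ms ceiling
        m2 = Measurement(G=10.0, Delta=80.0, delta=10.2)
        assert m2.TE == 100.0

    def test_bimodal_fraction_cap(self):
        with pytest.raises(ValueError):
            BimodalTissue(
                R_same=10.0, R_shrunk=7.0, f_same=0.6, f_shrunk=0.5, D_i=1.0, D_e=2.0
            )
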