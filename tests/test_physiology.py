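"""Cell-model closures and the assembled derivative, including the
machine-precision agreement between the reference equations and the
compiled kernel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytopond import _core
from phytopond.chemostat import OperatingPoint
from phytopond.physiology import (
    CultureState,
    MediumSpec,
    StrainParams,
    cex_fraction,
    derivatives,
    nutrient_limited_growth,
    photoacclimation_rate,
    quota_growth_factor,
    respiration,
    uptake_rate,
)

P = StrainParams(Um=0.693, name="test")


class TestQuotaGrowthFactor:
    def test_endpoints(self):
        assert quota_growth_factor(0.055, 0.055, 0.15, 10.0) == 0.0
        assert quota_growth_factor(0.15, 0.055, 0.15, 10.0) == pytest.approx(1.0)

    def test_hand_value(self):
        # (1 + 0.1) * 0.5 / (0.5 + 0.1) with normalized quota 0.5
        assert quota_growth_factor(0.10, 0.05, 0.15, 0.1) == pytest.approx(
            0.9167, abs=1e-4
        )

    def test_clipped_outside_bounds(self):
        assert quota_growth_factor(0.01, 0.05, 0.15, 0.1) == 0.0
        assert quota_growth_factor(0.99, 0.05, 0.15, 0.1) == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(
        q1=st.floats(0.051, 0.149),
        q2=st.floats(0.051, 0.149),
        KQ=st.floats(0.01, 50.0),
    )
    def test_strictly_increasing(self, q1, q2, KQ):
        if abs(q1 - q2) < 1e-9:
            return
        lo, hi = min(q1, q2), max(q1, q2)
        assert quota_growth_factor(lo, 0.05, 0.15, KQ) < quota_growth_factor(
            hi, 0.05, 0.15, KQ
        )

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            quota_growth_factor(0.1, 0.15, 0.05, 0.1)
        with pytest.raises(ValueError):
            quota_growth_factor(0.1, 0.05, 0.15, 0.0)


class TestNutrientLimitedGrowth:
    def test_replete_grows_at_maximum(self):
        assert nutrient_limited_growth(P.NCmax, P.PCmax, P) == pytest.approx(P.Um)

    def test_zero_at_subsistence_quota(self):
        assert nutrient_limited_growth(P.NCmin, P.PCmax, P) == 0.0

    def test_minimum_law(self):
        # pick NC so that uN = 0.5 exactly: q = uN*KQ/(1 + KQ - uN)
        q = 0.5 * P.KQN / (1 + P.KQN - 0.5)
        NC = P.NCmin + q * (P.NCmax - P.NCmin)
        assert nutrient_limited_growth(NC, P.PCmax, P) == pytest.approx(
            0.5 * P.Um, rel=1e-9
        )


class TestUptake:
    def test_no_substrate_no_transport(self):
        assert uptake_rate(0.0, P.KsN, 0.1, P.NCmin, P.NCmax, P) == 0.0

    def test_satiation_shuts_transport(self):
        assert uptake_rate(10.0, P.KsN, P.NCmax, P.NCmin, P.NCmax, P) == 0.0

    def test_saturated_derepressed_maximum(self):
        v = uptake_rate(1e6, P.KsN, P.NCmin, P.NCmin, P.NCmax, P)
        assert v == pytest.approx(P.Vscale * P.Um * P.NCmax, rel=1e-5)


class TestCexFraction:
    def test_replete_no_excess(self):
        assert cex_fraction(P.NCmax, P) == 0.0

    def test_ceiling_matches_quota_bounds(self):
        # 1 - 0.055/0.15
        assert cex_fraction(P.NCmin, P) == pytest.approx(0.6333, abs=1e-4)
        assert P.cex_max == pytest.approx(1 - P.NCmin / P.NCmax)

    def test_hand_value(self):
        assert cex_fraction(0.10, P) == pytest.approx(1 - 0.10 / 0.15, rel=1e-9)

    def test_decreasing_in_quota(self):
        nc = np.linspace(P.NCmin, P.NCmax, 20)
        assert np.all(np.diff(cex_fraction(nc, P)) < 0)


class TestRespiration:
    def test_dark_basal(self):
        assert respiration(0.0, P) == pytest.approx(P.r_basal * P.Um)

    def test_disabled(self):
        p0 = P.with_(r_basal=0.0, r_growth=0.0)
        assert respiration(0.5, p0) == 0.0

    def test_hand_value(self):
        p = P.with_(r_basal=0.05, r_growth=0.2)
        assert respiration(0.693, p) == pytest.approx(0.05 * 0.693 + 0.2 * 0.693)


class TestPhotoacclimation:
    def test_low_light_replete_pigments_up(self):
        rate = photoacclimation_rate(0.03, uN=1.0, PS_lightsat=0.0, p=P)
        assert rate > 0

    def test_nitrogen_starvation_degrades_pigment(self):
        rate = photoacclimation_rate(0.05, uN=0.0, PS_lightsat=0.0, p=P)
        assert rate < 0

    def test_fixed_point(self):
        target = min(P.ChlCmax * 1.0 * (1 - 0.5) + P.ChlC_floor, P.ChlCmax)
        assert photoacclimation_rate(target, 1.0, 0.5, P) == pytest.approx(0.0)


def _state(Cb=10.0, NC=0.12, PC=0.015, ChlC=0.03, Sn=5.0, Sp=0.5):
    return CultureState(Cb, NC * Cb, PC * Cb, ChlC * Cb, Sn, Sp)


class TestDerivatives:
    def test_closed_system_conserves_totals(self):
        op = OperatingPoint(45.0, 0.0, 0.1)
        d = derivatives(_state(), 500.0, op, P, MediumSpec())
        assert d[1] + d[4] == pytest.approx(0.0, abs=1e-14)  # N
        assert d[2] + d[5] == pytest.approx(0.0, abs=1e-14)  # P

    def test_dark_closed_pure_basal_respiration(self):
        op = OperatingPoint(45.0, 0.0, 0.1)
        s = _state()
        d = derivatives(s, 0.0, op, P, MediumSpec())
        assert d[0] == pytest.approx(-P.r_basal * P.Um * s.Cb, rel=1e-12)

    def test_no_respiration_dark_carbon_constant(self):
        p0 = P.with_(r_basal=0.0, r_growth=0.0)
        d = derivatives(_state(), 0.0, OperatingPoint(45.0, 0.0, 0.1), p0, MediumSpec())
        assert d[0] == 0.0

    def test_chemostat_total_balance(self):
        # d(Nb + Sn)/dt = D (N_in - Sn - Nb), same for P
        m = MediumSpec()
        op = OperatingPoint(45.0, 0.3, 0.1, m)
        s = _state()
        d = derivatives(s, 800.0, op, P, m)
        assert d[1] + d[4] == pytest.approx(op.D * (m.N_in - s.Sn - s.Nb), rel=1e-12)
        assert d[2] + d[5] == pytest.approx(op.D * (m.P_in - s.Sp - s.Pb), rel=1e-12)

    def test_rejects_negative_pool(self):
        bad = CultureState(1.0, -0.1, 0.01, 0.03, 5.0, 0.5)
        with pytest.raises(ValueError):
            derivatives(bad, 100.0, OperatingPoint(45.0, 0.1, 0.1), P, MediumSpec())

    @settings(max_examples=100, deadline=None)
    @given(
        Cb=st.floats(0.5, 300.0),
        NC=st.floats(0.056, 0.149),
        PC=st.floats(0.003, 0.019),
        ChlC=st.floats(0.001, 0.059),
        Sn=st.floats(0.0, 25.0),
        Sp=st.floats(0.0, 2.5),
        pfd=st.floats(0.0, 2500.0),
        D=st.floats(0.0, 1.0),
    )
    def test_kernel_matches_reference(self, Cb, NC, PC, ChlC, Sn, Sp, pfd, D):
        """The compiled kernel integrates the same equations as the readable
        reference implementation."""
        m = MediumSpec()
        op = OperatingPoint(45.0, D, 0.1, m)
        s = CultureState(Cb, NC * Cb, PC * Cb, ChlC * Cb, Sn, Sp)
        ref = derivatives(s, pfd, op, P, m)
        pp_vec = _core.pack_params(P, 0.1, 18.0)
        ker = np.array(_core._deriv(Cb, s.Nb, s.Pb, s.Chl, Sn, Sp, pfd, pp_vec,
                                    D, op.tau, m.N_in, m.P_in))
        np.testing.assert_allclose(ker, ref, rtol=1e-12, atol=1e-12)


class TestStrainParams:
    def test_invariant_enforcement(self):
        with pytest.raises(ValueError):
            StrainParams(Um=-1.0)
        with pytest.raises(ValueError):
            StrainParams(Um=0.5, NCmin=0.2, NCmax=0.1)
        with pytest.raises(ValueError):
            StrainParams(Um=0.5, PCmin=0.02, PCmax=0.002)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "strain.yaml"
        P.to_yaml(path)
        assert StrainParams.from_yaml(path) == P

    def test_shipped_preset_files_match_code(self):
        from importlib.resources import files

        import phytopond
        from phytopond.scenario import STRAIN_PRESETS

        data = files(phytopond) / "data"
        for name, preset in STRAIN_PRESETS.items():
            loaded = StrainParams.from_yaml(str(data / f"strain_{name}.yaml"))
            assert loaded == preset


class TestMediumSpec:
    def test_f2_reference_concentrations(self):
        m = MediumSpec.f2()
        assert m.N_in == pytest.approx(12.35)
        assert m.P_in == pytest.approx(1.11)

    def test_np_ratio_constant_across_multipliers(self):
        base = MediumSpec.f2(1.0)
        for mult in (0.5, 1.5, 2.0):
            m = MediumSpec.f2(mult)
            assert m.N_in / m.P_in == pytest.approx(base.N_in / base.P_in)
        assert MediumSpec.f4().N_in == pytest.approx(12.35 / 2)
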