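"""Year-long integration: conservation, determinism, washout, steady state."""

import numpy as np
import pytest

import phytopond as pp
from phytopond.chemostat import (
    OperatingPoint,
    default_inoculum,
    simulate_year,
    steady_growth_check,
)
from phytopond.forcing import ForcingSeries
from phytopond.physiology import CultureState, MediumSpec

S = pp.STRAIN_PRESETS["S"]


def dark_forcing(dt: float = 0.0025) -> ForcingSeries:
    n = int(round(365.0 / dt))
    return ForcingSeries(latitude_rad=0.0, times=np.arange(n) * dt,
                         pfd=np.zeros(n))


class TestSimulateYear:
    def test_closed_dark_no_respiration_all_pools_constant(self):
        p = S.with_(r_basal=0.0, r_growth=0.0, kChl=0.0)
        op = OperatingPoint(0.0, 0.0, 0.1)
        traj = simulate_year(p, op, forcing=dark_forcing(), dt=0.005)
        for col in ("Cb", "Nb", "Pb", "Chl", "Sn", "Sp"):
            x = traj.column(col)
            assert np.allclose(x, x[0], rtol=1e-9, atol=1e-12), col

    def test_closed_system_mass_conservation(self, run):
        # D = 0 under full diel light: total N and total P drift <= 1e-6 rel.
        traj = run("S", 45.0, 0.0, 0.1)
        totN = traj.column("Nb") + traj.column("Sn")
        totP = traj.column("Pb") + traj.column("Sp")
        assert np.max(np.abs(totN / totN[0] - 1)) < 1e-6
        assert np.max(np.abs(totP / totP[0] - 1)) < 1e-6

    def test_deterministic_bit_identical(self):
        op = OperatingPoint(45.0, 0.2, 0.1)
        t1 = simulate_year(S, op, dt=0.01)
        t2 = simulate_year(S, op, dt=0.01)
        assert np.array_equal(t1.states, t2.states)
        assert np.array_equal(t1.times, t2.times)

    def test_quota_confinement(self, run):
        # N:C and P:C stay within their bounds at every recorded state
        for args in (("S", 45.0, 0.2, 0.1, 1.0), ("S", 45.0, 0.1, 0.1, 0.5)):
            traj = run(*args)
            NC = traj.column("Nb") / traj.column("Cb")
            PC = traj.column("Pb") / traj.column("Cb")
            assert NC.max() <= S.NCmax * (1 + 1e-9)
            assert NC.min() >= S.NCmin * (1 - 1e-3)
            assert PC.max() <= S.PCmax * (1 + 1e-9)
            assert PC.min() >= S.PCmin * (1 - 1e-3)

    def test_washout_flagged_not_raised(self, run):
        traj = run("S", 0.0, 0.4, 0.1)
        assert traj.washout
        assert pp.annual_mean(traj).AP == 0.0

    def test_inoculum_insensitivity(self):
        # non-washout periodic state forgets the inoculum after spin-up
        op = OperatingPoint(45.0, 0.2, 0.1)
        m = MediumSpec()
        a = simulate_year(S, op, dt=0.01, seed_state=default_inoculum(S, m, Cb0=1.0))
        b = simulate_year(S, op, dt=0.01,
                          seed_state=CultureState(20.0, 0.1 * 20, 0.01 * 20,
                                                  0.02 * 20, 1.0, 0.1))
        assert pp.annual_mean(a).AP == pytest.approx(pp.annual_mean(b).AP, rel=1e-3)

    def test_self_convergence_halving_dt(self):
        op = OperatingPoint(45.0, 0.2, 0.1)
        ap = {}
        for dt in (0.01, 0.005):
            ap[dt] = pp.annual_mean(simulate_year(S, op, dt=dt)).AP
        assert abs(ap[0.005] - ap[0.01]) / ap[0.005] < 0.005

    def test_dt_validation(self):
        op = OperatingPoint(45.0, 0.2, 0.1)
        with pytest.raises(ValueError):
            simulate_year(S, op, dt=0.02)
        with pytest.raises(ValueError):
            simulate_year(S, op, dt=-0.001)
        with pytest.raises(ValueError):
            simulate_year(S, op, dt=0.005, spinup_years=0)

    def test_trajectory_spans_one_year(self, run):
        traj = run("S", 45.0, 0.2, 0.1)
        assert traj.times[0] == 0.0
        assert traj.times[-1] == pytest.approx(365.0)
        assert np.all(np.diff(traj.times) > 0)

    def test_csv_writer(self, run, tmp_path):
        import pandas as pd

        traj = run("S", 45.0, 0.2, 0.1)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "Cb", "Nb", "Pb", "Chl", "Sn", "Sp", "pfd"]
        assert len(df) == len(traj.times)


class TestOperatingPoint:
    def test_validation_and_warnings(self):
        with pytest.raises(ValueError):
            OperatingPoint(45.0, -0.1, 0.1)
        with pytest.raises(ValueError):
            OperatingPoint(45.0, 0.1, 0.0)
        with pytest.warns(UserWarning):
            OperatingPoint(45.0, 1.5, 0.1)
        with pytest.warns(UserWarning):
            OperatingPoint(45.0, 0.1, 1.0)


class TestSteadyGrowthCheck:
    def test_equilibrated_chemostat_growth_equals_dilution(self, run):
        # equatorial forcing: no seasonal trend on top of the diel balance
        rep = steady_growth_check(run("S", 0.0, 0.2, 0.1))
        assert rep.equilibrated
        assert rep.relative_error < 0.02

    def test_full_year_growth_equals_dilution_any_latitude(self, run):
        # over the whole periodic year the balance holds at any latitude
        rep = steady_growth_check(run("S", 45.0, 0.2, 0.1), window_days=365.0)
        assert rep.relative_error < 0.005

    def test_washout_marked_non_equilibrium(self, run):
        rep = steady_growth_check(run("S", 0.0, 0.4, 0.1))
        assert not rep.equilibrated
        assert rep.limitation == "washout"

    def test_low_nutrient_run_is_nitrogen_limited(self, run):
        # f/4, shallow, slow dilution: dissolved N exhausted, uN low
        rep = steady_growth_check(run("S", 45.0, 0.1, 0.05, 0.5))
        assert rep.limitation == "N-limited"
        assert rep.mean_uN < 0.5
        assert rep.mean_Sn < S.KsN
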