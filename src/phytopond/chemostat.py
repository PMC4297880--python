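"""Year-long continuous-culture (chemostat) simulation.

Assembles solar forcing, the acclimative cell model and depth-integrated
photosynthesis into a fixed-step RK4 integration of one virtual facility:
a flat, homogeneous pond of optical depth ``tau`` diluted continuously at
``D`` system volumes per day with fresh medium. The forcing year is
repeated for a spin-up period (discarded) so the reported year is the
periodic annual state, insensitive to the inoculum for non-washout runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _core, optics
from .forcing import ForcingSeries, SolarConfig, ClearnessTable, make_forcing
from .physiology import CultureState, MediumSpec, StrainParams, quota_growth_factor

__all__ = [
    "OperatingPoint",
    "Trajectory",
    "SteadyStateReport",
    "simulate_year",
    "steady_growth_check",
]

#: Operating ranges the production surfaces were mapped over.
D_RANGE = (0.0, 1.0)
TAU_RANGE = (0.03, 0.5)

#: Washout definition: algal C below this fraction of the inoculum ...
WASHOUT_FRACTION = 1e-6
#: ... persisting for more than this many consecutive days.
WASHOUT_DAYS = 30.0


@dataclass(frozen=True)
class OperatingPoint:
    """One virtual facility: latitude, dilution rate, optical depth, medium."""

    latitude_deg: float
    D: float  # dilution rate, system volumes per day
    tau: float  # optical depth, m
    media: MediumSpec = field(default_factory=MediumSpec)

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("dilution rate must be non-negative")
        if self.tau <= 0:
            raise ValueError("optical depth must be positive")
        if not D_RANGE[0] <= self.D <= D_RANGE[1]:
            warnings.warn(f"D={self.D} outside the mapped range {D_RANGE}", stacklevel=2)
        if not TAU_RANGE[0] <= self.tau <= TAU_RANGE[1]:
            warnings.warn(f"tau={self.tau} outside the mapped range {TAU_RANGE}", stacklevel=2)

    def key(self) -> tuple:
        m = self.media
        return (round(self.latitude_deg, 9), round(self.D, 9), round(self.tau, 9),
                round(m.N_in, 9), round(m.P_in, 9))


@dataclass
class Trajectory:
    """Recorded final-year trajectory of one run.

    ``times`` are days from the start of the reported year; ``states`` has
    one row per time, columns (Cb, Nb, Pb, Chl, Sn, Sp); ``pfd`` is the
    forcing sampled at the recorded times. ``metadata`` carries the strain,
    operating point and integrator settings, plus the washout flag.
    """

    times: np.ndarray
    states: np.ndarray
    pfd: np.ndarray
    metadata: dict[str, Any]

    @property
    def strain(self) -> StrainParams:
        return self.metadata["strain"]

    @property
    def op(self) -> OperatingPoint:
        return self.metadata["op"]

    @property
    def washout(self) -> bool:
        return bool(self.metadata.get("washout", False))

    def state_at(self, i: int) -> CultureState:
        return CultureState.from_array(self.states[i])

    def column(self, name: str) -> np.ndarray:
        idx = {"Cb": 0, "Nb": 1, "Pb": 2, "Chl": 3, "Sn": 4, "Sp": 5}[name]
        return self.states[:, idx]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.states, columns=["Cb", "Nb", "Pb", "Chl", "Sn", "Sp"]
        )
        df.insert(0, "time", self.times)
        df["pfd"] = self.pfd
        df.to_csv(path, index=False)

    def summary_json(self, path) -> None:
        import json

        from .metrics import annual_mean

        s = annual_mean(self)
        with open(path, "w") as fh:
            json.dump(s.to_dict() | {"metadata": _meta_jsonable(self.metadata)}, fh, indent=2)


def _meta_jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, StrainParams):
            out[k] = v.to_dict()
        elif isinstance(v, OperatingPoint):
            out[k] = {"latitude_deg": v.latitude_deg, "D": v.D, "tau": v.tau,
                      "N_in": v.media.N_in, "P_in": v.media.P_in}
        elif isinstance(v, (bool, int, float, str)) or v is None:
            out[k] = v
        else:
            out[k] = repr(v)
    return out


def default_inoculum(p: StrainParams, m: MediumSpec, Cb0: float = 1.0) -> CultureState:
    """Balanced-quota inoculum in fresh medium (Cb = 1 gC m⁻³ by default)."""
    return CultureState(
        Cb=Cb0,
        Nb=p.NCmax * Cb0,
        Pb=p.PCmax * Cb0,
        Chl=0.03 * Cb0,
        Sn=m.N_in,
        Sp=m.P_in,
    )


class IntegrationError(RuntimeError):
    """Non-finite or negative state during integration; carries the time."""

    def __init__(self, message: str, t: float):
        super().__init__(f"{message} at t = {t:.4f} d")
        self.t = t


def _pfd_half_steps(forcing: ForcingSeries, dt: float, n_year: int) -> np.ndarray:
    """Forcing sampled at half-step resolution over one year (periodic)."""
    t_half = np.arange(2 * n_year + 1) * (dt / 2.0)
    return np.asarray(forcing.at(t_half), dtype=float)


def simulate_year(
    p: StrainParams,
    op: OperatingPoint,
    forcing: ForcingSeries | None = None,
    dt: float = 0.002,
    spinup_years: int = 1,
    seed_state: CultureState | None = None,
    record_stride_days: float = 0.02,
    solar: SolarConfig | None = None,
    clearness: ClearnessTable | None = None,
    k_bg: float = optics.K_BACKGROUND,
    eps_chl: float = optics.EPS_CHL,
) -> Trajectory:
    """Integrate one virtual facility through spin-up plus one reported year.

    The forcing year is tiled periodically; ``spinup_years`` full years are
    integrated and discarded before the reported year. ``dt`` (days) must be
    at most 0.01 and divide one day evenly; the run is deterministic for
    fixed inputs. Washout (algal C below 10⁻⁶ of the inoculum for more than
    30 consecutive days) is flagged in metadata, not raised.
    """
    if dt <= 0 or dt > 0.01:
        raise ValueError("dt must lie in (0, 0.01] days")
    if abs(1.0 / dt - round(1.0 / dt)) > 1e-9:
        raise ValueError("dt must divide 1 day evenly")
    if spinup_years < 1:
        raise ValueError("spinup_years must be >= 1")
    if forcing is None:
        # half-step nodes coincide with forcing nodes, so sampling is exact
        forcing = make_forcing(
            op.latitude_deg,
            solar if solar is not None else SolarConfig(),
            clearness,
            dt=dt / 2.0,
        )
    year = forcing.year_length
    n_year = int(round(year / dt))
    if abs(n_year * dt - year) > 1e-9:
        raise ValueError("dt must divide the year evenly")
    stride = int(round(record_stride_days / dt))
    stride = max(stride, 1)
    while n_year % stride != 0:
        stride -= 1

    m = op.media
    y0 = (seed_state or default_inoculum(p, m)).as_array()
    pfd_half = _pfd_half_steps(forcing, dt, n_year)
    pp = _core.pack_params(p, k_bg, eps_chl)

    rec, status, t_fail = _core.integrate(
        y0, pfd_half, dt, n_year, spinup_years, stride, pp,
        op.D, op.tau, m.N_in, m.P_in,
    )
    if status == _core.STATUS_NONFINITE:
        raise IntegrationError("non-finite state", t_fail - spinup_years * year)
    if status == _core.STATUS_NEGATIVE_C:
        raise IntegrationError("negative pool", t_fail - spinup_years * year)

    times = rec[:, 0]
    states = rec[:, 1:7]
    pfd = np.asarray(forcing.at(times), dtype=float)

    washout = _washout_flag(times, states[:, 0], y0[0])
    meta = {
        "strain": p,
        "op": op,
        "dt": dt,
        "spinup_years": spinup_years,
        "record_stride_days": stride * dt,
        "integrator": "rk4-fixed",
        "k_bg": k_bg,
        "eps_chl": eps_chl,
        "washout": washout,
        "parameter_provenance": "phytopond defaults unless overridden",
    }
    return Trajectory(times=times, states=states, pfd=pfd, metadata=meta)


def _washout_flag(times: np.ndarray, Cb: np.ndarray, Cb0: float) -> bool:
    below = Cb < WASHOUT_FRACTION * Cb0
    if not below.any():
        return False
    # longest consecutive below-threshold stretch, in days
    run_start = None
    longest = 0.0
    for t, b in zip(times, below):
        if b and run_start is None:
            run_start = t
        elif not b and run_start is not None:
            longest = max(longest, t - run_start)
            run_start = None
    if run_start is not None:
        longest = max(longest, times[-1] - run_start)
    return longest > WASHOUT_DAYS


@dataclass
class SteadyStateReport:
    """Chemostat-balance check over the final 30 days of a trajectory."""

    equilibrated: bool
    mean_net_growth: float  # d^-1
    D: float
    relative_error: float  # |growth - D| / D
    limitation: str  # "N-limited" | "light-limited" | "replete" | "washout"
    mean_uN: float
    mean_Sn: float  # g m^-3


def steady_growth_check(traj: Trajectory, window_days: float = 30.0,
                        tol: float = 0.02) -> SteadyStateReport:
    """Verify the chemostat balance: over the final ``window_days`` the mean
    net specific growth rate should equal the dilution rate (a periodic
    annual state neither accumulates nor loses biomass on average), and
    classify the limiting resource from the N-sufficiency quotient uN and
    the residual dissolved N."""
    p, op = traj.strain, traj.op
    t, Cb = traj.times, traj.column("Cb")
    mask = t >= t[-1] - window_days
    tw, cw = t[mask], Cb[mask]
    if traj.washout or cw.min() <= 0:
        return SteadyStateReport(False, float("nan"), op.D, float("inf"),
                                 "washout", 0.0, float(traj.column("Sn")[mask].mean()))
    # mean net growth = D + mean d(ln Cb)/dt over the window
    growth = op.D + (np.log(cw[-1]) - np.log(cw[0])) / (tw[-1] - tw[0])
    rel = abs(growth - op.D) / op.D if op.D > 0 else abs(growth)
    NC = traj.column("Nb")[mask] / cw
    uN = quota_growth_factor(NC, p.NCmin, p.NCmax, p.KQN)
    mean_uN = float(np.mean(uN))
    mean_sn = float(traj.column("Sn")[mask].mean())
    if mean_uN < 0.5 and mean_sn < p.KsN:
        limitation = "N-limited"
    elif mean_uN >= 0.9:
        limitation = "replete" if mean_sn > p.KsN else "light-limited"
    else:
        limitation = "light-limited"
    return SteadyStateReport(rel <= tol, float(growth), op.D, float(rel),
                             limitation, mean_uN, mean_sn)
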