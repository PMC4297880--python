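"""Solar forcing: diel/seasonal surface photon-flux-density series by latitude.

Surface photosynthetically active radiation (PAR) is modelled from standard
solar geometry: the instantaneous flux is proportional to the cosine of the
solar zenith angle,

    cos Z = sin(phi) sin(delta) + cos(phi) cos(delta) cos(theta),

clamped at zero below the horizon, where ``phi`` is latitude, ``delta`` the
solar declination and ``theta`` the hour angle (zero at local solar noon).
The top-of-atmosphere PAR flux is scaled by a dimensionless *clearness
index* (the average fraction of extraterrestrial radiation reaching the
surface, accounting for cloud and dust) which varies with latitude, and by
a fixed usable fraction absorbing the difference between incident PAR and
what the cells can actually exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SolarConfig",
    "ClearnessTable",
    "ForcingSeries",
    "solar_declination",
    "surface_pfd",
    "make_forcing",
]

#: Maximum solar declination, radians (23.45 degrees).
DECL_MAX = 0.4093

#: Latitude range the default clearness table was constructed for, degrees.
LAT_RANGE = (0.0, 65.0)


@dataclass(frozen=True)
class SolarConfig:
    """Solar-geometry configuration.

    Parameters
    ----------
    solar_constant_par
        Top-of-atmosphere PAR photon flux, µmol photons m⁻² s⁻¹. The default
        (2800) together with ``par_usable_fraction`` = 0.9 was calibrated
        once, jointly with the photosynthetic efficiency and attenuation
        defaults, against typical field production rates; the clear-sky
        noon equatorial surface PAR it implies is ≈ 2500 µmol m⁻² s⁻¹
        before the clearness index is applied.
    par_usable_fraction
        Dimensionless (0, 1]: the fraction of incident PAR the cells can use.
    year_length
        Days per year (365).
    """

    solar_constant_par: float = 2800.0
    par_usable_fraction: float = 0.9
    year_length: float = 365.0

    def __post_init__(self) -> None:
        if self.solar_constant_par <= 0:
            raise ValueError("solar_constant_par must be positive")
        if not 0.0 < self.par_usable_fraction <= 1.0:
            raise ValueError("par_usable_fraction must lie in (0, 1]")
        if self.year_length <= 0:
            raise ValueError("year_length must be positive")


# Default clearness-index profile: a synthetic stand-in for per-latitude
# atmospheric climatology, staying within the observed 0.45-0.7 band.
_DEFAULT_CLEARNESS = ((0.0, 0.52), (20.0, 0.48), (35.0, 0.55), (55.0, 0.45), (65.0, 0.50))


@dataclass(frozen=True)
class ClearnessTable:
    """Piecewise-linear clearness index versus latitude (degrees).

    Latitudes are interpreted by absolute value (the atmosphere profile is
    assumed hemisphere-symmetric); values outside the tabulated range are
    clamped to the nearest endpoint.
    """

    latitudes_deg: tuple[float, ...] = field(
        default=tuple(p[0] for p in _DEFAULT_CLEARNESS)
    )
    clearness: tuple[float, ...] = field(
        default=tuple(p[1] for p in _DEFAULT_CLEARNESS)
    )

    def __post_init__(self) -> None:
        if len(self.latitudes_deg) != len(self.clearness) or not self.latitudes_deg:
            raise ValueError("latitudes and clearness must be equal-length, non-empty")
        if list(self.latitudes_deg) != sorted(self.latitudes_deg):
            raise ValueError("latitudes must be sorted ascending")
        for c in self.clearness:
            if not 0.0 < c <= 1.0:
                raise ValueError("clearness values must lie in (0, 1]")

    def __call__(self, latitude_deg: float) -> float:
        return float(
            np.interp(abs(latitude_deg), self.latitudes_deg, self.clearness)
        )

    @classmethod
    def constant(cls, value: float) -> "ClearnessTable":
        return cls((0.0,), (value,))

    @classmethod
    def from_csv(cls, path) -> "ClearnessTable":
        """Read a 2-column CSV ``latitude_deg, clearness`` (header required)."""
        import pandas as pd

        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("clearness CSV needs two columns (latitude_deg, clearness)")
        df = df.sort_values(df.columns[0])
        return cls(tuple(df.iloc[:, 0].astype(float)), tuple(df.iloc[:, 1].astype(float)))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"latitude_deg": self.latitudes_deg, "clearness": self.clearness}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ForcingSeries:
    """One year of surface PAR at fixed time step for one latitude.

    Attributes
    ----------
    latitude_rad
        Latitude in radians (sign gives hemisphere).
    times
        Days since Jan 1, fractional, fixed step, covering exactly one year
        (endpoint excluded; the series is periodic).
    pfd
        Surface photon flux density, µmol photons m⁻² s⁻¹, same length.
    """

    latitude_rad: float
    times: np.ndarray
    pfd: np.ndarray
    year_length: float = 365.0

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def at(self, t) -> np.ndarray:
        """Periodic linear interpolation of the flux at arbitrary times (days)."""
        tmod = np.asarray(t, dtype=float) % self.year_length
        # wrap-around node so interpolation is periodic
        tgrid = np.concatenate([self.times, [self.year_length]])
        pgrid = np.concatenate([self.pfd, [self.pfd[0]]])
        return np.interp(tmod, tgrid, pgrid)

    def daily_dose(self) -> np.ndarray:
        """Photon dose per calendar day, mol photons m⁻² d⁻¹."""
        per_day = int(round(1.0 / self.dt))
        n_days = int(round(self.year_length))
        p = self.pfd[: per_day * n_days].reshape(n_days, per_day)
        return p.mean(axis=1) * 86400.0 * 1e-6

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_days": self.times, "pfd_umol_m2_s": self.pfd}).to_csv(
            path, index=False
        )


def solar_declination(day_of_year, year_length: float = 365.0):
    """Solar declination angle, radians, for a (fractional) day of year.

    Uses the standard cosine approximation with the +10-day offset placing
    the December solstice near day 355; the day wraps modulo the year.
    """
    day = np.asarray(day_of_year, dtype=float) % year_length
    return -DECL_MAX * np.cos(2.0 * np.pi * (day + 10.0) / 365.0)


def surface_pfd(
    latitude: float,
    day,
    hour_angle,
    cfg: SolarConfig = SolarConfig(),
    clearness: float = 1.0,
):
    """Instantaneous surface PAR, µmol photons m⁻² s⁻¹.

    ``latitude`` in radians; ``hour_angle`` in radians with zero at local
    solar noon. Zero whenever the sun is below the horizon.
    """
    if not 0.0 < clearness <= 1.0:
        raise ValueError("clearness must lie in (0, 1]")
    delta = solar_declination(day, cfg.year_length)
    cos_z = np.sin(latitude) * np.sin(delta) + np.cos(latitude) * np.cos(delta) * np.cos(
        np.asarray(hour_angle, dtype=float)
    )
    return (
        cfg.solar_constant_par
        * cfg.par_usable_fraction
        * clearness
        * np.maximum(0.0, cos_z)
    )


def make_forcing(
    latitude_deg: float,
    cfg: SolarConfig = SolarConfig(),
    table: ClearnessTable | None = None,
    dt: float = 0.001,
) -> ForcingSeries:
    """Build the one-year surface PAR series for a latitude.

    ``dt`` (days) must divide one day evenly. Latitudes outside the
    tabulated clearness range are allowed with a warning.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    per_day = 1.0 / dt
    if abs(per_day - round(per_day)) > 1e-9:
        raise ValueError("dt must divide 1 day evenly")
    if not LAT_RANGE[0] <= abs(latitude_deg) <= LAT_RANGE[1]:
        warnings.warn(
            f"latitude {latitude_deg} deg outside the calibrated range "
            f"{LAT_RANGE}; extrapolating clearness",
            stacklevel=2,
        )
    table = table if table is not None else ClearnessTable()
    clearness = table(latitude_deg)

    n = int(round(cfg.year_length / dt))
    times = np.arange(n) * dt
    phi = np.deg2rad(latitude_deg)
    # hour angle: theta = 0 at local solar noon = 0.5 day fraction
    theta = 2.0 * np.pi * ((times % 1.0) - 0.5)
    pfd = surface_pfd(phi, times, theta, cfg, clearness)
    return ForcingSeries(
        latitude_rad=phi, times=times, pfd=pfd, year_length=cfg.year_length
    )
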