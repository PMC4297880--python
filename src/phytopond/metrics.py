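"""Production accounting: harvest fluxes, annual means, quarterly breakdowns.

Production is the *harvest flux* of the chemostat — dilution rate times
standing stock — not net photosynthesis: a washed-out culture produces
nothing regardless of its photophysiology. Volumetric rates (VP, VXP;
g m⁻³ d⁻¹) convert to areal rates (AP, AXP; g m⁻² d⁻¹) through the optical
depth, AP = VP·tau, exactly. Annual means are trapezium-rule integrals of
the instantaneous rate over the reported year divided by the year length;
quarterly means use calendar quarters with the hemisphere convention that
Q1 is January-March in the north and July-September in the south.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .chemostat import OperatingPoint, Trajectory
from .physiology import CultureState, StrainParams, cex_fraction

__all__ = [
    "AnnualSummary",
    "instantaneous_production",
    "annual_mean",
    "C_TO_DRY_WEIGHT",
    "FUEL_CARBON_DENSITY",
    "dry_weight_tonnes_per_ha_year",
    "fuel_litres_per_ha_year",
]

#: Carbon fraction of algal dry weight (gC per g dw).
C_TO_DRY_WEIGHT = 0.31

#: Carbon content of diesel-type fuel, gC per litre.
FUEL_CARBON_DENSITY = 720.0

# calendar-quarter day boundaries (Jan-Mar, Apr-Jun, Jul-Sep, Oct-Dec)
_QUARTER_DAYS = (0.0, 90.0, 181.0, 273.0, 365.0)


def dry_weight_tonnes_per_ha_year(ap_gc_m2_d: float) -> float:
    """Convert an areal C production rate to t dry weight ha⁻¹ yr⁻¹."""
    return ap_gc_m2_d * 365.0 / C_TO_DRY_WEIGHT * 1e4 / 1e6


def fuel_litres_per_ha_year(axp_tc_ha_yr: float) -> float:
    """Convert an areal excess-C yield (tC ha⁻¹ yr⁻¹) to litres of fuel
    ha⁻¹ yr⁻¹, assuming all excess C is recoverable as lipid."""
    return axp_tc_ha_yr * 1e6 / FUEL_CARBON_DENSITY


def instantaneous_production(
    state: CultureState, op: OperatingPoint, p: StrainParams
) -> tuple[float, float, float, float]:
    """Instantaneous (VP, AP, VXP, AXP) harvest fluxes for one state."""
    state.validate()
    VP = op.D * state.Cb
    AP = VP * op.tau
    VXP = VP * float(cex_fraction(state.NC, p))
    AXP = VXP * op.tau
    return VP, AP, VXP, AXP


@dataclass
class AnnualSummary:
    """Trapezium-integrated annual means for one run.

    AP/VP in gC m⁻²/m⁻³ d⁻¹, AXP/VXP in g Cex m⁻²/m⁻³ d⁻¹; quarterly
    entries are day-weighted quarter means whose weighted average equals
    the annual mean. ``mean_cex_percent`` is 100·AXP/AP.
    """

    AP: float
    VP: float
    AXP: float
    VXP: float
    quarterly_AP: tuple[float, float, float, float]
    quarterly_AXP: tuple[float, float, float, float]
    mean_cex_percent: float
    washout: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _quarter_slices(times: np.ndarray, year: float):
    bounds = [b * year / 365.0 for b in _QUARTER_DAYS]
    step = times[1] - times[0]
    idx = [min(int(round(b / step)), len(times) - 1) for b in bounds]
    return [(idx[i], idx[i + 1]) for i in range(4)], bounds


def annual_mean(traj: Trajectory, op: OperatingPoint | None = None) -> AnnualSummary:
    """Annual and quarterly mean production for a full-year trajectory.

    Requires the recorded times to span exactly one year; a washout run is
    reported as zero production with the flag set.
    """
    op = op if op is not None else traj.op
    p = traj.strain
    t = traj.times
    year = t[-1] - t[0]
    if abs(year - 365.0) > 1.0:
        raise ValueError("annual_mean needs a full-year trajectory")

    Cb = traj.column("Cb")
    NC = np.divide(traj.column("Nb"), Cb, out=np.full_like(Cb, p.NCmax),
                   where=Cb > 0)
    vp = op.D * Cb
    vxp = vp * cex_fraction(NC, p)

    if traj.washout:
        zero4 = (0.0, 0.0, 0.0, 0.0)
        return AnnualSummary(0.0, 0.0, 0.0, 0.0, zero4, zero4, 0.0, True)

    VP = float(np.trapezoid(vp, t) / year)
    VXP = float(np.trapezoid(vxp, t) / year)
    AP, AXP = VP * op.tau, VXP * op.tau

    slices, _ = _quarter_slices(t - t[0], year)
    q_vp, q_vxp = [], []
    for i0, i1 in slices:
        seg = slice(i0, i1 + 1)
        length = t[i1] - t[i0]
        q_vp.append(float(np.trapezoid(vp[seg], t[seg]) / length))
        q_vxp.append(float(np.trapezoid(vxp[seg], t[seg]) / length))

    # hemisphere convention: southern-hemisphere quarters shift by half a year
    if traj.op.latitude_deg < 0:
        q_vp = q_vp[2:] + q_vp[:2]
        q_vxp = q_vxp[2:] + q_vxp[:2]

    q_ap = tuple(v * op.tau for v in q_vp)
    q_axp = tuple(v * op.tau for v in q_vxp)
    cex_pct = 100.0 * AXP / AP if AP > 0 else 0.0
    return AnnualSummary(AP, VP, AXP, VXP, q_ap, q_axp, cex_pct, False)


def summary_row(traj: Trajectory, extra: dict | None = None) -> dict:
    """One flat CSV-ready row: operating point, strain id, summary fields."""
    s = annual_mean(traj)
    op, p = traj.op, traj.strain
    row = {
        "strain": p.name or f"Um={p.Um:g}",
        "Um": p.Um,
        "latitude_deg": op.latitude_deg,
        "D": op.D,
        "tau": op.tau,
        "N_in": op.media.N_in,
        "P_in": op.media.P_in,
        "media_multiplier": op.media.multiplier,
        "dt": traj.metadata.get("dt"),
        "spinup_years": traj.metadata.get("spinup_years"),
        "provenance": traj.metadata.get("parameter_provenance"),
        "AP": s.AP,
        "VP": s.VP,
        "AXP": s.AXP,
        "VXP": s.VXP,
        "mean_cex_percent": s.mean_cex_percent,
        "washout": s.washout,
    }
    for i in range(4):
        row[f"AP_Q{i+1}"] = s.quarterly_AP[i]
        row[f"AXP_Q{i+1}"] = s.quarterly_AXP[i]
    if extra:
        row.update(extra)
    return row
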