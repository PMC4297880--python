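"""Acclimative variable-stoichiometry (C:N:P:Chl) microalgal cell model.

Growth follows normalized cell-quota (Droop-type) kinetics: the C-specific
growth capacity rises from zero at the minimum quota (N:C = NCmin, all
carbon structural or stored, none spare for growth) to the maximum rate
``Um`` at the replete quota (NCmax), with nitrogen and phosphorus combined
by a minimum law. Nutrient transport is Michaelis-Menten in the external
substrate, down-regulated by satiation as the internal quota approaches its
maximum. Chlorophyll acclimates dynamically: the Chl:C ratio relaxes toward
a target that rises under low light and falls under nutrient stress or
light-saturated photosynthesis.

Excess carbon (Cex) — the biofuel-feedstock proxy — is diagnosed from the
nitrogen quota: a replete cell (N:C = NCmax) carries no excess C, and the
excess fraction grows linearly as N:C falls, to a ceiling of
``1 - NCmin/NCmax`` at the zero-growth quota. Surplus C fixation beyond the
balanced-growth demand (the ``Pq_surge`` headroom) lets this store fill
under N stress; fixation shuts off smoothly as the store saturates, which
is what keeps the quota above its floor dynamically.

All closures here are named, swappable strategies; parameter defaults are
typical literature values for non-GM strains, with the quota bounds set so
the excess-C ceiling is 63 % of cell carbon.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .chemostat import OperatingPoint

__all__ = [
    "StrainParams",
    "CultureState",
    "MediumSpec",
    "quota_growth_factor",
    "nutrient_limited_growth",
    "uptake_rate",
    "cex_fraction",
    "photoacclimation_rate",
    "respiration",
    "derivatives",
]

#: f/2 medium nutrient content, g m^-3 (== mg L^-1).
F2_N = 12.35
F2_P = 1.11

#: Cap on the e-folding rate at which the culture can strip a dissolved
#: nutrient from the medium, d^-1. Bounds the stiffness of the
#: Michaelis-Menten drawdown near exhaustion so a fixed-step integrator
#: stays stable; the cap only binds in the last few percent of drawdown.
CLEARANCE_CAP = 100.0


@dataclass(frozen=True)
class StrainParams:
    """Physiological parameter set defining one 'strain'.

    Parameters
    ----------
    Um
        Maximum C-specific growth rate at continuous saturating light and
        nutrients, d⁻¹ (0.693 d⁻¹ = one doubling per day).
    NCmin, NCmax
        N:C quota bounds, gN gC⁻¹: zero growth (maximum excess-C content)
        and maximum growth respectively.
    PCmin, PCmax
        P:C quota bounds, gP gC⁻¹.
    KQN, KQP
        Dimensionless curvature of the normalized quota-growth curves. The
        large N value gives the near-linear N:C response and the small P
        value the steep, luxury-storage P:C response typical of microalgae.
    ChlCmax
        Maximum Chl:C ratio, gChl gC⁻¹ (typical pigmentation: 0.06).
    ChlC_floor
        Residual Chl:C retained under extreme N stress, gChl gC⁻¹.
    alpha_chl
        Chl-specific initial slope of the photosynthesis-irradiance curve,
        gC (gChl)⁻¹ (µmol photons m⁻² s⁻¹)⁻¹ d⁻¹.
    KsN, KsP
        Half-saturation constants for dissolved N and P uptake, g m⁻³.
    Vscale
        Uptake headroom: Vmax = Vscale·Um·Qmax, so a growing cell can refill
        its quota faster than growth dilutes it.
    r_basal, r_growth
        Respiration: basal fraction of Um plus a fraction of gross fixation.
    Pq_surge
        Surplus-fixation headroom on the maximum photosynthesis rate,
        allowing C storage beyond balanced-growth demand under N stress.
    h_uptake
        Exponent of the satiation feedback on transport; values below one
        keep uptake de-repressed until the quota is nearly full, letting a
        replete, fast-growing cell hold its quota near the maximum.
    hCex
        Exponent of the smooth shut-off of surplus fixation as the excess-C
        store approaches its ceiling.
    kChl
        Photoacclimation relaxation rate, d⁻¹; None means "equal to Um"
        (acclimation on the growth timescale).
    name
        Optional label carried through outputs.
    """

    Um: float
    NCmin: float = 0.055
    NCmax: float = 0.15
    PCmin: float = 0.002
    PCmax: float = 0.02
    KQN: float = 10.0
    KQP: float = 0.1
    ChlCmax: float = 0.06
    ChlC_floor: float = 0.015
    alpha_chl: float = 0.45
    KsN: float = 0.03
    KsP: float = 0.005
    Vscale: float = 3.0
    r_basal: float = 0.05
    r_growth: float = 0.2
    Pq_surge: float = 1.25
    hCex: float = 0.3
    h_uptake: float = 0.5
    kChl: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.Um <= 0:
            raise ValueError("Um must be positive")
        if not 0 < self.NCmin < self.NCmax:
            raise ValueError("need 0 < NCmin < NCmax")
        if not 0 < self.PCmin < self.PCmax:
            raise ValueError("need 0 < PCmin < PCmax")
        if self.ChlCmax <= 0:
            raise ValueError("ChlCmax must be positive")
        for attr in ("KQN", "KQP", "alpha_chl", "KsN", "KsP", "Vscale",
                     "r_basal", "r_growth", "Pq_surge", "hCex", "h_uptake", "ChlC_floor"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")

    @property
    def kchl_effective(self) -> float:
        return self.Um if self.kChl is None else self.kChl

    @property
    def cex_max(self) -> float:
        """Ceiling of the excess-C fraction: 1 - NCmin/NCmax."""
        return 1.0 - self.NCmin / self.NCmax

    @property
    def Pqm_replete(self) -> float:
        """Maximum photosynthesis rate of an N-replete cell, gC gC⁻¹ d⁻¹."""
        return self.Um * (1.0 + self.r_basal) * self.Pq_surge

    # -- flat YAML/JSON round trip -------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StrainParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StrainParams":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_(self, **kw) -> "StrainParams":
        return replace(self, **kw)


@dataclass
class CultureState:
    """Instantaneous chemostat state (all pools per m³ of culture).

    ``Cb, Nb, Pb, Chl`` are the particulate (algal) carbon, nitrogen,
    phosphorus and chlorophyll pools; ``Sn, Sp`` the dissolved inorganic
    N and P (g m⁻³ ≡ mg L⁻¹).
    """

    Cb: float
    Nb: float
    Pb: float
    Chl: float
    Sn: float
    Sp: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Cb, self.Nb, self.Pb, self.Chl, self.Sn, self.Sp])

    @classmethod
    def from_array(cls, a) -> "CultureState":
        return cls(*map(float, a))

    @property
    def NC(self) -> float:
        return self.Nb / self.Cb

    @property
    def PC(self) -> float:
        return self.Pb / self.Cb

    @property
    def ChlC(self) -> float:
        return self.Chl / self.Cb

    def validate(self) -> None:
        for f in ("Cb", "Nb", "Pb", "Chl", "Sn", "Sp"):
            if getattr(self, f) < 0:
                raise ValueError(f"negative pool {f}")


@dataclass(frozen=True)
class MediumSpec:
    """Inflow medium; at multiplier 1.0 this is f/2 (12.35 gN m⁻³, 1.11 gP m⁻³),
    with the N:P mass ratio held constant across multipliers."""

    N_in: float = F2_N
    P_in: float = F2_P
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.N_in < 0 or self.P_in < 0:
            raise ValueError("inflow concentrations must be non-negative")

    @classmethod
    def f2(cls, multiplier: float = 1.0) -> "MediumSpec":
        return cls(N_in=F2_N * multiplier, P_in=F2_P * multiplier, multiplier=multiplier)

    @classmethod
    def f4(cls) -> "MediumSpec":
        return cls.f2(0.5)


# ---------------------------------------------------------------------------
# rate closures
# ---------------------------------------------------------------------------

def quota_growth_factor(Q, Qmin: float, Qmax: float, KQ: float):
    """Normalized quota-growth curve, dimensionless in [0, 1].

    u = (1 + KQ)(Q - Qmin) / ((Q - Qmin) + KQ (Qmax - Qmin)), clipped: zero
    at the subsistence quota, one at the replete quota, strictly increasing
    between; KQ sets the curvature (large = near-linear, small = hyperbolic
    luxury storage).
    """
    if Qmax <= Qmin:
        raise ValueError("need Qmin < Qmax")
    if KQ <= 0:
        raise ValueError("KQ must be positive")
    Qn = (np.asarray(Q, dtype=float) - Qmin) / (Qmax - Qmin)
    Qn = np.clip(Qn, 0.0, 1.0)
    u = (1.0 + KQ) * Qn / (Qn + KQ)
    return u[()] if u.ndim == 0 else u


def nutrient_limited_growth(NC: float, PC: float, p: StrainParams) -> float:
    """Quota-limited growth capacity, d⁻¹: Um times the minimum of the N and
    P quota factors (Liebig-style threshold control)."""
    uN = quota_growth_factor(NC, p.NCmin, p.NCmax, p.KQN)
    uP = quota_growth_factor(PC, p.PCmin, p.PCmax, p.KQP)
    return p.Um * min(uN, uP)


def uptake_rate(S, Ks: float, Q: float, Qmin: float, Qmax: float,
                p: StrainParams, h: float = 1.0):
    """C-specific nutrient transport, gX gC⁻¹ d⁻¹.

    Michaelis-Menten in the dissolved substrate, times a satiation feedback
    ``((Qmax - Q)/(Qmax - Qmin))**h`` that shuts transport off as the quota
    fills; Vmax = Vscale·Um·Qmax.
    """
    if np.any(np.asarray(S) < 0):
        raise ValueError("substrate must be non-negative")
    vmax = p.Vscale * p.Um * Qmax
    fq = np.clip((Qmax - Q) / (Qmax - Qmin), 0.0, 1.0) ** h
    v = vmax * np.asarray(S, dtype=float) / (np.asarray(S, dtype=float) + Ks) * fq
    return v[()] if np.ndim(v) == 0 else v


def cex_fraction(NC, p: StrainParams):
    """Excess-C fraction of cell carbon, diagnosed from the N quota:
    f = max(0, 1 - NC/NCmax); zero for a replete cell, ceiling
    1 - NCmin/NCmax at the subsistence quota."""
    f = 1.0 - np.asarray(NC, dtype=float) / p.NCmax
    f = np.maximum(0.0, f)
    return f[()] if f.ndim == 0 else f


def surge_downregulation(NC: float, p: StrainParams) -> float:
    """Smooth shut-off of surplus C fixation as the excess-C store fills:
    (1 - cex/cex_max)**hCex in [0, 1]."""
    frac = min(cex_fraction(NC, p) / p.cex_max, 1.0)
    return (1.0 - frac) ** p.hCex


def pqm_current(NC: float, p: StrainParams) -> float:
    """Current maximum photosynthesis rate, gC gC⁻¹ d⁻¹: the replete-cell
    ceiling scaled by the excess-C down-regulation."""
    return p.Pqm_replete * surge_downregulation(NC, p)


def photoacclimation_rate(ChlC: float, uN: float, PS_lightsat: float,
                          p: StrainParams) -> float:
    """Chl:C relaxation rate, gChl gC⁻¹ d⁻¹ (dilution by growth is applied
    separately in pool form).

    The target pigmentation rises to ChlCmax under low light
    (``PS_lightsat`` → 0) with a replete N quota (uN → 1), and collapses to
    the floor under N stress or light-saturated photosynthesis.
    """
    PS_lightsat = min(max(PS_lightsat, 0.0), 1.0)
    target = min(p.ChlCmax * uN * (1.0 - PS_lightsat) + p.ChlC_floor, p.ChlCmax)
    return p.kchl_effective * (target - ChlC)


def respiration(U_gross: float, p: StrainParams) -> float:
    """C-specific respiration, d⁻¹: basal (fraction of Um) plus
    growth-linked (fraction of gross fixation)."""
    if U_gross < 0:
        raise ValueError("U_gross must be non-negative")
    return p.r_basal * p.Um + p.r_growth * U_gross


# ---------------------------------------------------------------------------
# full derivative
# ---------------------------------------------------------------------------

def derivatives(
    state: CultureState,
    pfd: float,
    op: "OperatingPoint",
    p: StrainParams,
    m: MediumSpec,
    k_bg: float | None = None,
    eps_chl: float | None = None,
) -> np.ndarray:
    """Time derivatives of (Cb, Nb, Pb, Chl, Sn, Sp), per day.

    Chemostat balance: each particulate pool is produced by the cells and
    washed out at dilution rate D; dissolved pools are resupplied from the
    inflow medium and drawn down by uptake. Gross C fixation is the
    depth-integrated Smith rate at the current Chl:C and self-shading;
    realized growth is further capped by the quota-limited capacity, with
    any surplus fixation accumulating as excess C (diagnosed from N:C).

    This is the readable reference implementation; the compiled kernel in
    ``_core`` integrates the identical equations.
    """
    from . import optics

    state.validate()
    if pfd < 0:
        raise ValueError("pfd must be non-negative")
    Cb, Nb, Pb, Chl, Sn, Sp = state.as_array()
    NC, PC, ChlC = Nb / Cb, Pb / Cb, Chl / Cb
    D = op.D

    uN = quota_growth_factor(NC, p.NCmin, p.NCmax, p.KQN)

    Pqm = pqm_current(NC, p)
    k = optics.attenuation(
        Chl,
        optics.K_BACKGROUND if k_bg is None else k_bg,
        optics.EPS_CHL if eps_chl is None else eps_chl,
    )
    if Pqm > 1e-12:
        PS = float(optics.smith_depth_integrated_ps(
            pfd, ChlC, p.alpha_chl, Pqm, k, op.tau))
        lightsat = PS / Pqm
    else:
        PS, lightsat = 0.0, 1.0

    R = respiration(PS, p)
    VN = min(uptake_rate(Sn, p.KsN, NC, p.NCmin, p.NCmax, p, p.h_uptake),
             CLEARANCE_CAP * Sn / Cb)
    VP = min(uptake_rate(Sp, p.KsP, PC, p.PCmin, p.PCmax, p, p.h_uptake),
             CLEARANCE_CAP * Sp / Cb)
    rho_chl = photoacclimation_rate(ChlC, uN, lightsat, p)

    dCb = (PS - R - D) * Cb
    dNb = VN * Cb - D * Nb
    dPb = VP * Cb - D * Pb
    dChl = rho_chl * Cb - D * Chl
    dSn = D * (m.N_in - Sn) - VN * Cb
    dSp = D * (m.P_in - Sp) - VP * Cb
    return np.array([dCb, dNb, dPb, dChl, dSn, dSp])
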