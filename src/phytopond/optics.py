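"""Depth-integrated photosynthesis in a homogeneous, self-shading suspension.

The local photosynthesis-irradiance response is the Smith function

    P(I) = Pqm * x / sqrt(1 + x**2),      x = I * alpha * ChlC / Pqm,

a saturating curve with initial slope ``alpha * ChlC`` (per unit chlorophyll,
scaled by the cell's current Chl:C ratio) and plateau ``Pqm``, the absolute
maximum C-specific photosynthesis rate. Light decays exponentially with
depth, I(z) = I0 * exp(-k z), and the Smith form integrates over the
illuminated depth ``tau`` in closed form:

    PS = Pqm / (k tau) * [asinh(x0) - asinh(x0 * exp(-k tau))].

No photoinhibition term is included: the Smith curve is retained for its
analytic depth integral even though it can overestimate photosynthesis near
a bright surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LightField", "attenuation", "smith_depth_integrated_ps", "smith_local_ps"]

#: Background attenuation of the clear medium, m^-1.
K_BACKGROUND = 0.1

#: Chlorophyll-specific attenuation cross-section, m^2 (g Chl)^-1.
EPS_CHL = 18.0


@dataclass(frozen=True)
class LightField:
    """Light environment of the culture: surface PAR, optical depth, attenuation."""

    I0: float  # surface PAR, µmol photons m^-2 s^-1
    tau: float  # optical (culture) depth, m
    k: float  # attenuation coefficient, m^-1

    def __post_init__(self) -> None:
        if self.I0 < 0:
            raise ValueError("I0 must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")


def attenuation(chl_conc, k_bg: float = K_BACKGROUND, eps_chl: float = EPS_CHL):
    """Attenuation coefficient (m⁻¹) of a suspension with chlorophyll
    concentration ``chl_conc`` (g Chl m⁻³): background plus a linear
    chlorophyll term."""
    chl_conc = np.asarray(chl_conc, dtype=float)
    if np.any(chl_conc < 0):
        raise ValueError("chl_conc must be non-negative")
    return k_bg + eps_chl * chl_conc


def smith_local_ps(I, ChlC, alpha, Pqm):
    """Local (un-integrated) Smith rate, gC gC⁻¹ d⁻¹, at irradiance ``I``."""
    x = np.asarray(I, dtype=float) * alpha * ChlC / Pqm
    return Pqm * x / np.sqrt(1.0 + x * x)


def smith_depth_integrated_ps(I0, ChlC, alpha, Pqm, k, tau):
    """Depth-averaged C-specific photosynthesis rate, gC gC⁻¹ d⁻¹.

    Closed-form depth integral of the Smith curve over an exponentially
    attenuated light field; ``ln(x + sqrt(1+x²))`` is evaluated as
    ``asinh(x)`` for stability at small ``x``. The ``k·tau → 0`` limit
    reduces smoothly to the local surface rate.
    """
    if Pqm <= 0:
        raise ValueError("Pqm must be positive")
    x0 = np.asarray(I0, dtype=float) * alpha * ChlC / Pqm
    ktau = np.asarray(k, dtype=float) * tau
    if np.any(ktau < 0):
        raise ValueError("k*tau must be non-negative")
    ktau_safe = np.where(ktau > 1e-12, ktau, 1.0)
    integrated = Pqm / ktau_safe * (np.arcsinh(x0) - np.arcsinh(x0 * np.exp(-ktau)))
    local = Pqm * x0 / np.sqrt(1.0 + x0 * x0)
    out = np.where(ktau > 1e-12, integrated, local)
    return out[()] if out.ndim == 0 else out
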