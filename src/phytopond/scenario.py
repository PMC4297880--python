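"""Scenario generation: presets and randomized parameter draws.

Bundles every external input the simulator needs — a per-latitude clearness
profile (a documented synthetic stand-in for atmospheric climatology; real
data can be supplied as CSV), the four preset strains spanning 0.5 to 2
doublings per day, and the f/2 media family — plus seeded random strain
draws for property-based testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcing import ClearnessTable, SolarConfig
from .physiology import MediumSpec, StrainParams

__all__ = ["ScenarioBundle", "default_bundle", "random_strain",
           "STRAIN_PRESETS", "MEDIA_PRESETS"]

#: One doubling per day, d^-1.
LN2 = 0.693

#: The four preset strains: 0.5x, 1.0x, 1.5x, 2.0x one doubling per day.
#: "S" and "F" are the slow and fast reference strains.
STRAIN_PRESETS: dict[str, StrainParams] = {
    "XS": StrainParams(Um=0.347, name="XS"),
    "S": StrainParams(Um=0.693, name="S"),
    "M": StrainParams(Um=1.040, name="M"),
    "F": StrainParams(Um=1.386, name="F"),
}

MEDIA_PRESETS: dict[str, MediumSpec] = {
    "f/4": MediumSpec.f2(0.5),
    "f/2": MediumSpec.f2(1.0),
    "f/2 x1.5": MediumSpec.f2(1.5),
    "f/2 x2": MediumSpec.f2(2.0),
}


@dataclass
class ScenarioBundle:
    """All external inputs for one study: clearness, strains, media, forcing."""

    clearness: ClearnessTable = field(default_factory=ClearnessTable)
    solar: SolarConfig = field(default_factory=SolarConfig)
    strains: dict[str, StrainParams] = field(default_factory=lambda: dict(STRAIN_PRESETS))
    media: dict[str, MediumSpec] = field(default_factory=lambda: dict(MEDIA_PRESETS))
    forcing_dt: float = 0.001
    seed: int = 0


def default_bundle() -> ScenarioBundle:
    """The deterministic default scenario (no randomness involved)."""
    return ScenarioBundle()


# bounds for random strain draws: (low, high) per parameter
_DEFAULT_DRAW_BOUNDS: dict[str, tuple[float, float]] = {
    "Um": (0.3, 1.5),
    "NCmin": (0.03, 0.08),
    "NCmax": (0.1, 0.2),
    "PCmin": (0.001, 0.005),
    "PCmax": (0.01, 0.03),
    "KQN": (1.0, 20.0),
    "KQP": (0.05, 1.0),
    "ChlCmax": (0.02, 0.08),
    "alpha_chl": (0.03, 0.3),
    "KsN": (0.005, 0.1),
    "KsP": (0.001, 0.02),
    "Vscale": (1.1, 3.0),
    "r_basal": (0.0, 0.1),
    "r_growth": (0.0, 0.3),
    "Pq_surge": (1.0, 1.5),
    "hCex": (1.0, 3.0),
}


def random_strain(
    seed: int,
    bounds: dict[str, tuple[float, float]] | None = None,
    nc_ratio: float | None = None,
) -> StrainParams:
    """Draw a random but always-valid strain parameter set.

    Quota bounds are drawn from disjoint (min, max) ranges so ordering holds
    by construction; ``nc_ratio`` optionally pins NCmin/NCmax (e.g. 0.37 for
    a 63 % excess-C ceiling). Deterministic per seed.
    """
    b = dict(_DEFAULT_DRAW_BOUNDS)
    if bounds:
        b.update(bounds)
    for key in ("NCmin", "NCmax", "PCmin", "PCmax"):
        lo, hi = b[key]
        if not lo < hi:
            raise ValueError(f"impossible bounds for {key}")
    if b["NCmin"][1] >= b["NCmax"][0] and nc_ratio is None:
        raise ValueError("NCmin and NCmax ranges must be disjoint")
    if b["PCmin"][1] >= b["PCmax"][0]:
        raise ValueError("PCmin and PCmax ranges must be disjoint")

    rng = np.random.default_rng(seed)
    draw = {k: float(rng.uniform(*b[k])) for k in b}
    if nc_ratio is not None:
        if not 0 < nc_ratio < 1:
            raise ValueError("nc_ratio must lie in (0, 1)")
        draw["NCmin"] = draw["NCmax"] * nc_ratio
    return StrainParams(name=f"random-{seed}", **draw)
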