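"""Ordinal density classes and the class-to-continuous sampling transform.

Roadside locust surveys record an ordinal density class (absent, isolated,
scattered, ... swarm) rather than a continuous density.  For regression the
classes are converted to continuous individuals-per-square-metre values by
drawing from a normal distribution centred on the class midpoint with a
standard deviation of 30% of that midpoint (negative draws rejected).  The
response is then compressed with a sixth-root power transform, which, unlike
a log, keeps true absences at exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DensityClass",
    "DensityClassScheme",
    "TransformConfig",
    "DEFAULT_SCHEME",
    "sample_density",
    "sample_densities",
    "power_transform",
    "inverse_power_transform",
]


@dataclass(frozen=True)
class DensityClass:
    """One ordinal abundance class.

    ``lower``/``upper`` bound the half-open interval ``(lower, upper]`` of
    true densities assigned to the class; ``midpoint`` is the centre of the
    sampling distribution used to convert the class back to a continuous
    density.  Class 0 (absence) has all three equal to zero.
    """

    code: int
    label: str
    lower: float
    upper: float  # math.inf for the open-ended top class
    midpoint: float


@dataclass(frozen=True)
class DensityClassScheme:
    """An ordered set of density classes plus the sampling CV.

    ``cv`` is the coefficient of variation (sd / mean) of the normal draw
    used by :func:`sample_density`; 0.30 reflects the precision ceiling of
    categorical field surveys.
    """

    classes: tuple[DensityClass, ...]
    cv: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 < self.cv < 1.0:
            raise ValueError(f"cv must lie in (0, 1), got {self.cv}")
        codes = [c.code for c in self.classes]
        if codes != sorted(codes) or len(set(codes)) != len(codes) or codes[0] != 0:
            raise ValueError("class codes must be strictly increasing from 0")
        zero = self.classes[0]
        if not (zero.lower == zero.upper == zero.midpoint == 0.0):
            raise ValueError("class 0 must have lower = upper = midpoint = 0")
        mids = [c.midpoint for c in self.classes]
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise ValueError("midpoints must be strictly increasing")
        for c in self.classes[1:]:
            if not (c.lower <= c.midpoint <= c.upper):
                raise ValueError(f"class {c.code}: midpoint outside [lower, upper]")

    def by_code(self, code: int) -> DensityClass:
        for c in self.classes:
            if c.code == code:
                return c
        raise KeyError(f"unknown density class code {code!r}")

    @property
    def codes(self) -> list[int]:
        return [c.code for c in self.classes]

    def classify(self, density: float) -> int:
        """Bin a true density into its class: 0 for exactly 0, else the class
        whose half-open interval ``(lower, upper]`` contains it."""
        if density < 0:
            raise ValueError(f"density must be >= 0, got {density}")
        if density == 0.0:
            return 0
        for c in self.classes[1:]:
            if c.lower < density <= c.upper:
                return c.code
        raise ValueError(f"density {density} not covered by scheme")

    def classify_array(self, density: np.ndarray) -> np.ndarray:
        density = np.asarray(density, dtype=float)
        if np.any(density < 0):
            raise ValueError("densities must be >= 0")
        edges = np.array([c.upper for c in self.classes[1:-1]])
        codes = np.searchsorted(edges, density, side="left") + 1
        codes[density == 0.0] = 0
        return codes


#: Default scheme.  The original survey protocol's class bounds are not public;
#: these log-spaced classes span the densities discussed in the field
#: (isolated individuals up to swarms) and are fully replaceable via config.
DEFAULT_SCHEME = DensityClassScheme(
    classes=(
        DensityClass(0, "absent", 0.0, 0.0, 0.0),
        DensityClass(1, "isolated", 0.0, 0.2, 0.05),
        DensityClass(2, "scattered", 0.2, 2.0, 0.5),
        DensityClass(3, "numerous", 2.0, 10.0, 5.0),
        DensityClass(4, "concentrated", 10.0, 50.0, 25.0),
        DensityClass(5, "swarm", 50.0, math.inf, 75.0),
    )
)


@dataclass(frozen=True)
class TransformConfig:
    """Power-transform settings: response = density ** lambda_."""

    lambda_: float = 1.0 / 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_ < 1.0:
            raise ValueError(f"lambda_ must lie in (0, 1), got {self.lambda_}")


def sample_density(
    class_code: int, scheme: DensityClassScheme, rng: np.random.Generator
) -> float:
    """Draw one continuous density for an ordinal class.

    Class 0 returns exactly 0.0.  Positive classes draw from
    Normal(midpoint, cv * midpoint) with negative draws rejected and redrawn,
    so the class-conditional mean stays at the midpoint and zero remains
    reserved for true absence.
    """
    c = scheme.by_code(class_code)
    if c.code == 0:
        return 0.0
    sd = scheme.cv * c.midpoint
    while True:
        d = rng.normal(c.midpoint, sd)
        if d >= 0.0:
            return float(d)


def sample_densities(
    class_codes: np.ndarray, scheme: DensityClassScheme, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised :func:`sample_density` (rejection applied per element)."""
    codes = np.asarray(class_codes)
    valid = set(scheme.codes)
    bad = set(np.unique(codes)) - valid
    if bad:
        raise KeyError(f"unknown density class codes {sorted(bad)!r}")
    mids = np.array([scheme.by_code(int(k)).midpoint for k in codes])
    out = rng.normal(mids, scheme.cv * mids)
    neg = out < 0
    while np.any(neg):
        out[neg] = rng.normal(mids[neg], scheme.cv * mids[neg])
        neg = out < 0
    out[codes == 0] = 0.0
    return out


def _as_lambda(cfg) -> float:
    return cfg.lambda_ if isinstance(cfg, TransformConfig) else float(cfg)


def power_transform(density, cfg: TransformConfig | float = 1.0 / 6.0):
    """density ** lambda.  Zero maps to zero; strictly increasing."""
    lam = _as_lambda(cfg)
    d = np.asarray(density, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be >= 0")
    out = np.power(d, lam)
    return float(out) if np.isscalar(density) else out


def inverse_power_transform(y, cfg: TransformConfig | float = 1.0 / 6.0):
    """y ** (1/lambda): maps the transformed response back to density."""
    lam = _as_lambda(cfg)
    v = np.asarray(y, dtype=float)
    if np.any(v < 0):
        raise ValueError("transformed response must be >= 0")
    out = np.power(v, 1.0 / lam)
    return float(out) if np.isscalar(y) else out
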