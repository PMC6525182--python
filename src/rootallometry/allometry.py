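"""Geometric two-tissue model of an absorptive root.

An absorptive root is modelled as a cylinder of two concentric tissues: a
central stele of radius ``SR`` (lignified vascular tissue) wrapped in the
tissues outside the stele (epidermis + exodermis + cortex) of thickness
``tToS``, so that ``SR + tToS = diameter / 2``.  Across species the outer
tissue thickens allometrically with diameter,

    tToS = k * x + c,

with slope ``k`` and intercept ``c`` (mm).  The proportion of the root
cross-section occupied by the stele then follows

    PRS(x) = (2 * SR / x)**2 = (1 - 2k - 2c / x)**2,

a nonlinear function of diameter whose direction of change is controlled by
the sign of ``c``.  Because stele tissue is denser and poorer in nitrogen
than the outer tissue, an area-weighted two-tissue mixture turns the PRS
curve into nonlinear diameter dependencies of root tissue density (RTD) and
root nitrogen concentration (RN).

Units: diameters, ``tToS`` and ``SR`` are millimetres; tissue densities are
g cm^-3; nitrogen concentrations mg g^-1.  Unit conversions to centimetres
are localized inside :func:`srl` and :func:`dry_mass_per_length`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "DomainError",
    "GeometryError",
    "AllometryParams",
    "TissueMixture",
    "FlaggedValues",
    "MonotonicityReport",
    "prs_from_diameter",
    "prs_from_anatomy",
    "stele_radius_from_allometry",
    "mixture_trait",
    "srl",
    "dry_mass_per_length",
    "dry_mass_monotonicity",
]


class DomainError(ValueError):
    """An input lies outside the mathematical domain of the model."""


class GeometryError(ValueError):
    """Anatomical measurements violate the cylinder geometry."""


@dataclass(frozen=True)
class AllometryParams:
    """Slope/intercept of the tToS-diameter line, ``tToS = k*x + c``.

    ``k`` must lie in (0, 0.5): the stele-radius line implied by the
    geometry has slope ``0.5 - k``, which must stay positive.  ``c`` may be
    either sign; its sign decides whether PRS falls (c < 0, the woody
    pattern) or rises (c > 0, the non-woody pattern) with diameter.
    """

    k: float
    c: float

    def __post_init__(self) -> None:
        if not 0.0 < self.k < 0.5:
            raise DomainError(
                f"tToS slope k={self.k!r} outside (0, 0.5); implied stele "
                f"slope 0.5 - k would be non-positive"
            )

    @property
    def stele_slope(self) -> float:
        """Slope of SR vs. diameter under exact complement geometry."""
        return 0.5 - self.k

    @property
    def stele_intercept(self) -> float:
        """Intercept of SR vs. diameter under exact complement geometry."""
        return -self.c


@dataclass(frozen=True)
class TissueMixture:
    """Densities and N concentrations of the two root tissues.

    Stele tissue must be denser and nitrogen-poorer than the outer tissue
    (``rho_stele > rho_outer``, ``nu_outer > nu_stele``): this ordering is
    what makes RTD increase and RN decrease with PRS.  Defaults are
    generator conveniences placing mixture outputs in realistic trait
    ranges (RTD roughly 0.1-0.5 g cm^-3, RN roughly 5-15 mg g^-1); they are
    not estimates of real tissue properties.
    """

    rho_stele: float = 0.45
    rho_outer: float = 0.12
    nu_stele: float = 6.0
    nu_outer: float = 14.0

    def __post_init__(self) -> None:
        if not self.rho_stele > self.rho_outer > 0:
            raise DomainError(
                f"need rho_stele > rho_outer > 0, got "
                f"{self.rho_stele!r}, {self.rho_outer!r}"
            )
        if not self.nu_outer > self.nu_stele > 0:
            raise DomainError(
                f"need nu_outer > nu_stele > 0, got "
                f"{self.nu_outer!r}, {self.nu_stele!r}"
            )

    def rtd(self, prs: ArrayLike) -> NDArray[np.float64]:
        """Root tissue density of the mixture at a given PRS."""
        return mixture_trait(prs, self.rho_stele, self.rho_outer)

    def rn(self, prs: ArrayLike) -> NDArray[np.float64]:
        """Root N concentration of the mixture at a given PRS."""
        return mixture_trait(prs, self.nu_stele, self.nu_outer)


@dataclass(frozen=True)
class FlaggedValues:
    """Values with a per-element validity flag.

    Out-of-domain elements carry NaN in ``values`` and False in
    ``in_domain``.  They are never clipped into the domain: clipping a PRS
    at 0 or 1 would fabricate curvature in downstream fits.
    """

    values: NDArray[np.float64]
    in_domain: NDArray[np.bool_]

    @property
    def n_out_of_domain(self) -> int:
        return int((~self.in_domain).sum())

    def valid(self) -> NDArray[np.float64]:
        """The in-domain values only."""
        return self.values[self.in_domain]


def _as_positive(x: ArrayLike, name: str) -> NDArray[np.float64]:
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError(f"{name} must be finite and > 0")
    return arr


def prs_from_diameter(x: ArrayLike, params: AllometryParams) -> FlaggedValues:
    """PRS predicted from diameter by the allometric model.

    Evaluates ``(1 - 2k - 2c/x)**2``.  Elements whose inner term
    ``1 - 2k - 2c/x`` falls outside [0, 1] (geometrically impossible stele)
    are flagged out-of-domain, not clipped.

    Parameters
    ----------
    x : array-like
        Root diameter in mm, strictly positive.
    params : AllometryParams
        Slope/intercept of the tToS-diameter line.
    """
    arr = _as_positive(x, "diameter")
    inner = 1.0 - 2.0 * params.k - 2.0 * params.c / arr
    ok = (inner >= 0.0) & (inner <= 1.0)
    values = np.where(ok, inner**2, np.nan)
    return FlaggedValues(values=values, in_domain=ok)


def prs_from_anatomy(sr: ArrayLike, x: ArrayLike) -> NDArray[np.float64]:
    """PRS from measured stele radius and diameter: ``(2*SR/x)**2``.

    Raises :class:`GeometryError` if the stele radius is negative or larger
    than the root radius.
    """
    x_arr = _as_positive(x, "diameter")
    sr_arr = np.asarray(sr, dtype=float)
    if np.any(~np.isfinite(sr_arr)) or np.any(sr_arr < 0):
        raise GeometryError("stele radius must be finite and >= 0")
    if np.any(2.0 * sr_arr > x_arr):
        raise GeometryError("stele diameter 2*SR exceeds root diameter")
    return (2.0 * sr_arr / x_arr) ** 2


def stele_radius_from_allometry(
    x: ArrayLike, params: AllometryParams
) -> NDArray[np.float64]:
    """Stele radius implied by exact complement geometry, ``x/2 - (kx+c)``."""
    arr = _as_positive(x, "diameter")
    return arr / 2.0 - (params.k * arr + params.c)


def mixture_trait(
    prs: ArrayLike, v_stele: ArrayLike, v_outer: ArrayLike
) -> NDArray[np.float64]:
    """Area-weighted two-tissue mixture: ``PRS*v_stele + (1-PRS)*v_outer``.

    Monotone increasing in PRS when ``v_stele > v_outer`` (the RTD case),
    decreasing when ``v_stele < v_outer`` (the RN case).
    """
    p = np.asarray(prs, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("PRS must lie in [0, 1]")
    return p * np.asarray(v_stele, float) + (1.0 - p) * np.asarray(v_outer, float)


_MM_PER_CM = 10.0
_CM_PER_M = 100.0


def srl(
    x: ArrayLike,
    rtd: ArrayLike,
    diameter_unit: str = "mm",
    output_unit: str = "m_per_g",
) -> NDArray[np.float64]:
    """Specific root length of a cylindrical root, ``4 / (pi * RTD * x^2)``.

    Parameters
    ----------
    x : array-like
        Diameter, in the unit named by ``diameter_unit`` ("mm" or "cm").
    rtd : array-like
        Root tissue density in g cm^-3, strictly positive.
    output_unit : str
        "m_per_g" (default) or "cm_per_g".
    """
    x_arr = _as_positive(x, "diameter")
    rtd_arr = _as_positive(rtd, "RTD")
    if diameter_unit == "mm":
        x_cm = x_arr / _MM_PER_CM
    elif diameter_unit == "cm":
        x_cm = x_arr
    else:
        raise ValueError(f"unknown diameter_unit {diameter_unit!r}")
    srl_cm_per_g = 4.0 / (np.pi * rtd_arr * x_cm**2)
    if output_unit == "cm_per_g":
        return srl_cm_per_g
    if output_unit == "m_per_g":
        return srl_cm_per_g / _CM_PER_M
    raise ValueError(f"unknown output_unit {output_unit!r}")


def dry_mass_per_length(x: ArrayLike, rtd: ArrayLike) -> NDArray[np.float64]:
    """Dry mass per unit length of a cylindrical root, g cm^-1.

    ``m = pi * (x/2)^2 * RTD`` with the diameter ``x`` given in mm and
    converted to cm internally.  RTD = 0 is allowed (massless limit).
    """
    x_cm = _as_positive(x, "diameter") / _MM_PER_CM
    rtd_arr = np.asarray(rtd, dtype=float)
    if np.any(~np.isfinite(rtd_arr)) or np.any(rtd_arr < 0):
        raise DomainError("RTD must be finite and >= 0")
    return np.pi * (x_cm / 2.0) ** 2 * rtd_arr


@dataclass(frozen=True)
class MonotonicityReport:
    """Outcome of the dry-mass-vs-diameter simulation on a grid."""

    strictly_increasing: bool
    min_slope: float
    x_grid: NDArray[np.float64]
    mass: NDArray[np.float64]
    n_out_of_domain: int = 0
    out_of_domain_x: NDArray[np.float64] = field(
        default_factory=lambda: np.empty(0)
    )


def dry_mass_monotonicity(
    params: AllometryParams,
    mixture: TissueMixture,
    x_grid: ArrayLike,
) -> MonotonicityReport:
    """Does dry mass per length rise monotonically with diameter?

    Under the allometric model RTD falls with diameter (woody direction),
    so whether ``m(x) = pi*(x/2)^2 * RTD(x)`` still rises everywhere is a
    genuine question: the quadratic volume term must outpace the falling
    density.  Evaluates ``m`` on the grid, flags grid points whose PRS is
    out of domain, and reports the minimum finite-difference slope over the
    valid points.  The report states what happened; it never asserts.
    """
    grid = _as_positive(x_grid, "x_grid")
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("x_grid must be a 1-D array with >= 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("x_grid must be strictly increasing")
    prs = prs_from_diameter(grid, params)
    valid_x = grid[prs.in_domain]
    rtd = mixture.rtd(prs.values[prs.in_domain])
    mass = dry_mass_per_length(valid_x, rtd)
    slopes = np.diff(mass) / np.diff(valid_x / _MM_PER_CM)
    min_slope = float(slopes.min()) if slopes.size else float("nan")
    return MonotonicityReport(
        strictly_increasing=bool(slopes.size and np.all(slopes > 0)),
        min_slope=min_slope,
        x_grid=valid_x,
        mass=mass,
        n_out_of_domain=prs.n_out_of_domain,
        out_of_domain_x=grid[~prs.in_domain],
    )
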