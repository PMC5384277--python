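"""Parametric pharyngeal phantoms and paired pre/post synthetic cohorts.

A phantom is a body of revolution: a smooth axial area profile A(z) over the
three pharyngeal regions (nasopharynx, oropharynx, hypopharynx), carrying a
single cosine-bump constriction whose depth is solved so the global minimum
cross-sectional area hits a prescribed target. Region volumes, the minimum
area, and the inlet (hypopharynx-bottom) area are all matched to within a
fraction of a percent, so slice/volume extraction round-trips the inputs.

Axial coordinate ``z`` is 0 at the choana plane and increases inferiorly,
in millimetres. Areas are cm^2 and volumes cm^3 at the interface; the
internal profile is stored in mm/mm^2.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import root
from scipy.stats import truncnorm

REGION_NAMES = ("nasopharynx", "oropharynx", "hypopharynx")

_VOL_TOL = 5e-3  # relative tolerance on region volumes and a_min


class InfeasibleSpecError(ValueError):
    """Raised when no positive-radius profile can satisfy a PhantomSpec."""


@dataclass(frozen=True)
class RegionSpec:
    """One pharyngeal region: axial extent (mm) and target volume (cm^3)."""

    name: str
    length: float
    volume: float

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ValueError(f"region name must be one of {REGION_NAMES}, got {self.name!r}")
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be > 0, got {self.length}")
        if self.volume <= 0:
            raise ValueError(f"{self.name}: volume must be > 0, got {self.volume}")

    @property
    def mean_area(self) -> float:
        """Region-mean cross-sectional area, cm^2."""
        return self.volume * 1e3 / self.length * 1e-2  # cm^3/mm -> mm^2 -> cm^2


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom prescription: three ordered regions plus constriction.

    ``a_min_frac`` locates the constriction as a fraction of its region's
    axial extent; ``inlet_area`` is the cross-section at the hypopharynx
    bottom where the extraction velocity is applied.
    """

    regions: tuple[RegionSpec, RegionSpec, RegionSpec]
    a_min: float  # cm^2
    a_min_region: str = "hypopharynx"
    a_min_frac: float = 0.5
    inlet_area: float = 2.5  # cm^2
    constriction_width: float | None = None  # mm; default 0.5 * region length

    def __post_init__(self) -> None:
        names = tuple(r.name for r in self.regions)
        if names != REGION_NAMES:
            raise ValueError(f"regions must be ordered {REGION_NAMES}, got {names}")
        if self.a_min <= 0:
            raise ValueError("a_min must be > 0")
        if self.a_min_region not in REGION_NAMES:
            raise ValueError(f"unknown a_min_region {self.a_min_region!r}")
        if not 0.0 <= self.a_min_frac <= 1.0:
            raise ValueError("a_min_frac must lie in [0, 1]")
        if self.inlet_area <= 0:
            raise ValueError("inlet_area must be > 0")

    @property
    def total_length(self) -> float:
        return sum(r.length for r in self.regions)

    @property
    def total_volume(self) -> float:
        return sum(r.volume for r in self.regions)

    @property
    def mean_area(self) -> float:
        """A_mean = V/L in cm^2."""
        return self.total_volume * 1e3 / self.total_length * 1e-2

    def region(self, name: str) -> RegionSpec:
        return self.regions[REGION_NAMES.index(name)]

    def boundaries(self) -> tuple[float, float]:
        """z of the naso/oro and oro/hypo interface planes, mm."""
        l0, l1, _ = (r.length for r in self.regions)
        return (l0, l0 + l1)

    def to_dict(self) -> dict:
        return {
            "regions": [
                {"name": r.name, "length": r.length, "volume": r.volume} for r in self.regions
            ],
            "a_min": self.a_min,
            "a_min_region": self.a_min_region,
            "a_min_frac": self.a_min_frac,
            "inlet_area": self.inlet_area,
            "constriction_width": self.constriction_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        regions = tuple(RegionSpec(**r) for r in d["regions"])
        return cls(
            regions=regions,  # type: ignore[arg-type]
            a_min=d["a_min"],
            a_min_region=d.get("a_min_region", "hypopharynx"),
            a_min_frac=d.get("a_min_frac", 0.5),
            inlet_area=d.get("inlet_area", 2.5),
            constriction_width=d.get("constriction_width"),
        )


def uniform_tube_spec(area_cm2: float, length_mm: float) -> PhantomSpec:
    """Degenerate spec whose solution is a constant-area tube.

    All three regions share the same mean area, the constriction target
    equals that area (zero bump depth), and the inlet matches it too.
    """
    area_mm2 = area_cm2 * 1e2
    lengths = (length_mm * 0.25, length_mm * 0.5, length_mm * 0.25)
    regions = tuple(
        RegionSpec(name, l, area_mm2 * l * 1e-3) for name, l in zip(REGION_NAMES, lengths)
    )
    return PhantomSpec(
        regions=regions,  # type: ignore[arg-type]
        a_min=area_cm2,
        a_min_region="oropharynx",
        a_min_frac=0.5,
        inlet_area=area_cm2,
    )


@dataclass(frozen=True)
class AirwayPhantom:
    """Realized axisymmetric phantom: sampled profile plus region planes."""

    z: np.ndarray  # mm, ascending, z[0] = 0 at choana
    radius: np.ndarray  # mm
    boundaries: tuple[float, float]  # naso/oro and oro/hypo planes, mm
    spec: PhantomSpec | None = None

    @property
    def area(self) -> np.ndarray:
        """A(z) = pi R^2, mm^2."""
        return np.pi * self.radius**2

    @property
    def length(self) -> float:
        return float(self.z[-1] - self.z[0])

    def area_at(self, z: float | np.ndarray) -> np.ndarray:
        """Interpolated cross-sectional area at z (mm), in mm^2."""
        return np.interp(z, self.z, self.area)

    def radius_at(self, z: float | np.ndarray) -> np.ndarray:
        return np.interp(z, self.z, self.radius)

    def region_of(self, z: float) -> str:
        b1, b2 = self.boundaries
        if z < b1:
            return "nasopharynx"
        if z < b2:
            return "oropharynx"
        return "hypopharynx"

    def region_slices(self) -> dict[str, tuple[float, float]]:
        b1, b2 = self.boundaries
        return {
            "nasopharynx": (0.0, b1),
            "oropharynx": (b1, b2),
            "hypopharynx": (b2, float(self.z[-1])),
        }

    def region_volume(self, name: str) -> float:
        """Volume of one region by trapezoidal quadrature, cm^3."""
        z0, z1 = self.region_slices()[name]
        zs = np.linspace(z0, z1, max(int((z1 - z0) * 8), 16) + 1)
        return float(np.trapezoid(self.area_at(zs), zs)) * 1e-3

    def total_volume(self) -> float:
        """Whole-phantom volume, cm^3."""
        return float(np.trapezoid(self.area, self.z)) * 1e-3

    def a_min(self) -> tuple[float, float]:
        """(minimum area in cm^2, its z location in mm); ties -> smallest z."""
        i = int(np.argmin(self.area))
        return float(self.area[i]) * 1e-2, float(self.z[i])


def _pchip_slopes(h: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Fritsch-Carlson monotone derivative estimates (same rule as PCHIP)."""
    n = h.size + 1
    d = np.zeros(n)
    # interior: weighted harmonic mean where secants agree in sign
    w1 = 2.0 * h[1:] + h[:-1]
    w2 = h[1:] + 2.0 * h[:-1]
    agree = (np.sign(s[:-1]) * np.sign(s[1:])) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        hm = (w1 + w2) / (w1 / s[:-1] + w2 / s[1:])
    d[1:-1] = np.where(agree, hm, 0.0)

    def edge(h0, h1, s0, s1):
        de = ((2.0 * h0 + h1) * s0 - h0 * s1) / (h0 + h1)
        if np.sign(de) != np.sign(s0):
            return 0.0
        if np.sign(s0) != np.sign(s1) and abs(de) > 3.0 * abs(s0):
            return 3.0 * s0
        return de

    d[0] = edge(h[0], h[1], s[0], s[1])
    d[-1] = edge(h[-1], h[-2], s[-1], s[-2])
    return d


def _hermite_profile(knots_z: np.ndarray, z: np.ndarray):
    """Fast re-evaluatable monotone cubic through fixed knot positions.

    Returns ``evaluate(values)``; segment lookup and local coordinates are
    precomputed, so each call is pure arithmetic (the profile solve
    re-evaluates the same interpolant many times with shifting values).
    """
    h = np.diff(knots_z)
    idx = np.clip(np.searchsorted(knots_z, z, side="right") - 1, 0, h.size - 1)
    t = (z - knots_z[idx]) / h[idx]
    t2 = t * t
    t3 = t2 * t
    h00 = 2.0 * t3 - 3.0 * t2 + 1.0
    h10 = t3 - 2.0 * t2 + t
    h01 = -2.0 * t3 + 3.0 * t2
    h11 = t3 - t2
    hseg = h[idx]

    def evaluate(values: np.ndarray) -> np.ndarray:
        s = np.diff(values) / h
        d = _pchip_slopes(h, s)
        return (
            h00 * values[idx]
            + h10 * hseg * d[idx]
            + h01 * values[idx + 1]
            + h11 * hseg * d[idx + 1]
        )

    return evaluate


def _cosine_bump(z: np.ndarray, center: float, width: float) -> np.ndarray:
    """C1 bump in [0, 1], support (center - w/2, center + w/2)."""
    x = (z - center) / width
    out = np.zeros_like(z)
    inside = np.abs(x) < 0.5
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[inside]))
    return out


def build_phantom(spec: PhantomSpec, axial_resolution: float = 8.0) -> AirwayPhantom:
    """Construct a phantom satisfying a PhantomSpec.

    The base area profile is a shape-preserving cubic (PCHIP) through the
    region-mean areas anchored at the region midpoints, pinned to the inlet
    area at the bottom. A multiplicative cosine bump carves the constriction;
    its depth is solved by bisection so the global minimum equals ``a_min``,
    and region volumes are re-normalized after each depth solve until both
    the volumes and the minimum agree with the spec to < 0.5 %.

    Parameters
    ----------
    spec
        Geometric prescription; must be feasible.
    axial_resolution
        Profile samples per millimetre (>= 1).

    Raises
    ------
    InfeasibleSpecError
        If ``a_min`` exceeds what the volume-consistent base profile allows.
    """
    if axial_resolution < 1:
        raise ValueError("axial_resolution must be >= 1 sample/mm")

    total_l = spec.total_length
    n = int(round(total_l * axial_resolution)) + 1
    z = np.linspace(0.0, total_l, n)

    lengths = np.array([r.length for r in spec.regions])
    starts = np.concatenate([[0.0], np.cumsum(lengths)[:-1]])
    mids = starts + lengths / 2.0
    vols_mm3 = np.array([r.volume for r in spec.regions]) * 1e3
    inlet_area_mm2 = spec.inlet_area * 1e2
    a_min_mm2 = spec.a_min * 1e2

    ridx = REGION_NAMES.index(spec.a_min_region)
    center = starts[ridx] + spec.a_min_frac * lengths[ridx]
    width = spec.constriction_width if spec.constriction_width else 0.5 * lengths[ridx]
    # the dip support must stay interior: a constriction clipped by the
    # domain end would undercut the inlet pin and break the minimum solve
    width = min(width, 2.0 * (total_l - center - 1.0), 2.0 * (center - 1.0))
    if width < 4.0:
        raise InfeasibleSpecError(
            "constriction too close to the domain end for any usable width"
        )
    # volume-neutral constriction: the dip is paired with compensating
    # shoulders scaled so the carved volume is restored locally (exactly on
    # this grid, even when the shoulder support is clipped by the domain
    # end); region renormalization then barely moves the base profile,
    # which would otherwise inflate it, steepen walls and starve
    # neighbouring regions
    dip = _cosine_bump(z, center, width)
    # compensating shoulders flanking the dip, with supports kept strictly
    # inside the domain so the end areas (choana, inlet pin) are untouched
    edge_lo, edge_hi = center - 0.5 * width, center + 0.5 * width
    w_l = min(width, edge_lo - 1.0)
    w_r = min(width, (total_l - 1.0) - edge_hi)
    ring = np.zeros_like(z)
    if w_l > 1.0:
        ring += _cosine_bump(z, edge_lo - 0.5 * w_l, w_l)
    if w_r > 1.0:
        ring += _cosine_bump(z, edge_hi + 0.5 * w_r, w_r)
    ring_int = np.trapezoid(ring, z)
    lam = np.trapezoid(dip, z) / ring_int if ring_int > 1e-9 else 0.0
    bump = dip - min(lam, 2.0) * ring

    # initial control values: region-mean areas in mm^2
    c = vols_mm3 / lengths

    # extra knot at the naso/oro plane pinned to the nasopharyngeal control:
    # the nasopharynx is flat and decoupled from downstream volume changes
    # (the na->oro transition lives inside the oropharynx)
    knots_z = np.array([0.0, mids[0], lengths[0], mids[1], mids[2], total_l])
    _eval = _hermite_profile(knots_z, z)

    def base_profile(cvals: np.ndarray) -> np.ndarray:
        return _eval(
            np.array([cvals[0], cvals[0], cvals[0], cvals[1], cvals[2], inlet_area_mm2])
        )

    bounds = np.concatenate([[0.0], np.cumsum(lengths)])
    dz_prof = np.diff(z)

    def region_integrals(area: np.ndarray) -> np.ndarray:
        # cumulative trapezoid evaluated exactly at the region planes
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (area[1:] + area[:-1]) * dz_prof)])
        at_bounds = np.interp(bounds, z, cum)
        return np.diff(at_bounds)

    bump_support = bump > 1e-12

    def solve_depth(cvals: np.ndarray, base: np.ndarray) -> tuple[float, np.ndarray]:
        """Closed-form bump depth so the global minimum area equals a_min.

        The base interpolant is shape-preserving, so its exact minimum is
        the smallest knot value — a resolution-independent feasibility
        check. For depth d the area is base*(1 - d*bump); the largest d
        keeping every sample >= a_min is min over the bump support of
        (1 - a_min/base)/bump, and at that d the bound is attained.
        """
        knot_min = min(cvals.min(), inlet_area_mm2)
        if knot_min <= 0:
            raise InfeasibleSpecError("base area profile is non-positive; volumes/lengths inconsistent")
        f0 = knot_min - a_min_mm2
        if f0 < -_VOL_TOL * a_min_mm2 - 1e-9:
            raise InfeasibleSpecError(
                "a_min target exceeds the minimum of the volume-consistent base "
                f"profile ({knot_min * 1e-2:.3f} cm^2 < {spec.a_min:.3f} cm^2); "
                "reduce a_min or adjust region volumes/lengths"
            )
        if f0 <= 0 or base[bump_support].min() <= a_min_mm2:
            return 0.0, base
        d = float(((1.0 - a_min_mm2 / base[bump_support]) / bump[bump_support]).min())
        d = max(d, 0.0)  # area >= a_min on the dip support by construction
        return d, base * (1.0 - d * bump)

    def carve(base: np.ndarray) -> np.ndarray:
        """Apply the deepest admissible bump (clamped, non-raising form)."""
        if base.min() <= 0:
            return base
        d = float(((1.0 - a_min_mm2 / base[bump_support]) / bump[bump_support]).min())
        d = max(d, 0.0)  # area >= a_min on the dip support by construction
        return base * (1.0 - d * bump)

    def residual(x: np.ndarray) -> np.ndarray:
        base = base_profile(np.exp(np.clip(x, -30.0, 30.0)))
        return region_integrals(carve(base)) / vols_mm3 - 1.0

    sol = root(residual, np.log(c), method="hybr", tol=1e-12)
    c = np.exp(sol.x)
    _, area = solve_depth(c, base_profile(c))  # strict: raises if infeasible

    integrals = region_integrals(area)
    vol_err = np.max(np.abs(integrals / vols_mm3 - 1.0))
    amin_err = abs(area.min() / a_min_mm2 - 1.0)
    if vol_err > _VOL_TOL or amin_err > _VOL_TOL:
        raise InfeasibleSpecError(
            f"profile solve did not converge (volume err {vol_err:.2%}, a_min err {amin_err:.2%})"
        )
    if area.min() <= 0:
        raise InfeasibleSpecError("solved profile has non-positive area")

    radius = np.sqrt(area / np.pi)
    b1, b2 = float(np.cumsum(lengths)[0]), float(np.cumsum(lengths)[1])
    return AirwayPhantom(z=z, radius=radius, boundaries=(b1, b2), spec=spec)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedCase:
    """One synthetic patient: pre/post phantom specs and the retraction."""

    pre: PhantomSpec
    post: PhantomSpec
    ice: float  # mm

    def __post_init__(self) -> None:
        if self.ice < 0:
            raise ValueError("ice must be >= 0")


@dataclass(frozen=True)
class CohortParams:
    """Generator parameters for a paired pre/post cohort.

    Defaults reproduce the study cohort's pre-treatment summary statistics
    and the 6.84 +/- 1.68 mm retraction distribution; the ice->anatomy
    sensitivities are calibrated so the mean post anatomy at the mean
    retraction matches the post-treatment summary means.
    """

    v_na_mean: float = 5.68
    v_na_sd: float = 0.59
    v_or_mean: float = 20.83
    v_or_sd: float = 4.86
    v_hy_mean: float = 8.50
    v_hy_sd: float = 3.44
    a_min_mean: float = 2.21
    a_min_sd: float = 0.64
    # physiological lower truncation: pre-treatment patients breathe
    # adequately, and throats below ~1.2 cm^2 leave the steady laminar
    # regime the solver (and the study's assumption) covers
    a_min_floor: float = 1.2
    # anatomy scales together: loading of the latent airway-size factor
    # shared by volumes, areas (0.3x for lengths); marginals are preserved
    size_correlation: float = 0.6
    inlet_area_mean: float = 3.0
    inlet_area_sd: float = 0.35
    # lengths proportional to region volumes so every region's mean area
    # equals the whole-pharynx A_mean = A_min/0.69 at the T1 means; this
    # keeps the feasible range for a_min wide (any draw below ~0.97 A_mean
    # is achievable without repair)
    len_na_mean: float = 17.7
    len_na_sd: float = 1.8
    len_or_mean: float = 65.0
    len_or_sd: float = 5.0
    len_hy_mean: float = 26.5
    len_hy_sd: float = 2.7
    ice_mean: float = 6.84
    ice_sd: float = 1.68
    # fractional reduction per mm of retraction, calibrated to the post means
    sens_v_or: float = (20.83 - 15.64) / 20.83 / 6.84
    sens_v_hy: float = (8.50 - 6.04) / 8.50 / 6.84
    sens_a_min: float = (2.21 - 1.51) / 2.21 / 6.84
    noise_v_or_sd: float = 0.03
    noise_v_hy_sd: float = 0.03
    noise_a_min_sd: float = 0.03
    noise_v_na_sd: float = 0.06
    pre_a_min_region: str = "hypopharynx"
    pre_a_min_frac: float = 0.5
    post_a_min_region: str = "oropharynx"
    # tongue-root narrowing: the post constriction sits in the inferior
    # oropharynx, so its suction tail reaches the hypopharynx below
    post_a_min_frac: float = 0.9
    max_wall_slope: float = 0.85  # |dR/dz| cap; keeps phantoms in the regime
    # where the axisymmetric solver's thin-layer approximations hold
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "v_na_sd", "v_or_sd", "v_hy_sd", "a_min_sd", "inlet_area_sd",
            "len_na_sd", "len_or_sd", "len_hy_sd", "ice_sd",
            "noise_v_or_sd", "noise_v_hy_sd", "noise_a_min_sd", "noise_v_na_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sens_v_or", "sens_v_hy", "sens_a_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "CohortParams":
        return cls(**d)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, size: int) -> np.ndarray:
    """Normal draws truncated below at ``lo`` (one-sided)."""
    if sd == 0:
        return np.full(size, mean)
    a = (lo - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _floor_compensated_loc(mean: float, sd: float, lo: float) -> float:
    """Location for a lower-truncated normal whose mean equals ``mean``.

    A non-trivial floor raises the truncated mean; shifting the location
    down restores the configured mean so cohort-level recovery holds.
    """
    if sd == 0 or lo <= mean - 6 * sd:
        return mean

    def excess(loc):
        return truncnorm.mean((lo - loc) / sd, np.inf, loc=loc, scale=sd) - mean

    from scipy.optimize import brentq

    hi = mean
    low = mean - 4 * sd
    if excess(low) > 0:  # floor too close to the mean to compensate fully
        return low
    return float(brentq(excess, low, hi, xtol=1e-10))


def _bumpless_knot_min(lengths: np.ndarray, vols_mm3: np.ndarray, inlet_mm2: float) -> float:
    """Exact minimum of the volume-matched base profile, mm^2.

    Solves the same control-value root problem as the phantom builder but
    without a constriction; since the interpolant is shape-preserving its
    global minimum is the smallest knot value. Used to bound feasible
    a_min targets without surrogate error.
    """
    total_l = float(lengths.sum())
    n = int(round(total_l)) + 1
    z = np.linspace(0.0, total_l, n)
    starts = np.concatenate([[0.0], np.cumsum(lengths)[:-1]])
    mids = starts + lengths / 2.0
    knots_z = np.array([0.0, mids[0], lengths[0], mids[1], mids[2], total_l])
    _eval = _hermite_profile(knots_z, z)
    bounds = np.concatenate([[0.0], np.cumsum(lengths)])
    dz_prof = np.diff(z)

    def integrals(area):
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (area[1:] + area[:-1]) * dz_prof)])
        return np.diff(np.interp(bounds, z, cum))

    def residual(x):
        c = np.exp(np.clip(x, -30.0, 30.0))
        area = _eval(np.array([c[0], c[0], c[0], c[1], c[2], inlet_mm2]))
        return integrals(area) / vols_mm3 - 1.0

    sol = root(residual, np.log(vols_mm3 / lengths), method="hybr", tol=1e-10)
    c = np.exp(sol.x)
    if np.abs(sol.fun).max() > 1e-6 or c.min() <= 0:
        raise InfeasibleSpecError("region volumes/lengths admit no positive base profile")
    return float(min(c.min(), inlet_mm2))


def _cap_a_min(a_min: float, regions: tuple[RegionSpec, ...], inlet_area: float) -> float:
    """Keep the constriction target below the base profile's global minimum."""
    lengths = np.array([r.length for r in regions])
    vols = np.array([r.volume for r in regions]) * 1e3
    floor = 0.97 * _bumpless_knot_min(lengths, vols, inlet_area * 1e2) * 1e-2
    return min(a_min, floor)


def apply_retraction(
    pre: PhantomSpec,
    ice: float,
    params: CohortParams,
    rng: np.random.Generator | None = None,
) -> PhantomSpec:
    """Map a pre-treatment spec to a post-treatment spec for a retraction.

    Fractional reductions of oropharyngeal/hypopharyngeal volume and of the
    minimum area are linear in ``ice`` (plus Gaussian noise when ``rng`` is
    given); the nasopharynx is unchanged in expectation; the constriction
    relocates to ``params.post_a_min_region``.
    """
    if ice < 0:
        raise ValueError("ice must be >= 0")

    def noise(sd: float) -> float:
        return float(rng.normal(0.0, sd)) if rng is not None else 0.0

    f_or = np.clip(params.sens_v_or * ice + noise(params.noise_v_or_sd), 0.0, 0.9)
    f_hy = np.clip(params.sens_v_hy * ice + noise(params.noise_v_hy_sd), 0.0, 0.9)
    f_am = np.clip(params.sens_a_min * ice + noise(params.noise_a_min_sd), 0.0, 0.9)
    f_na = noise(params.noise_v_na_sd)

    na, oro, hy = pre.regions
    post_na = replace(na, volume=max(na.volume * (1.0 + f_na), 0.1 * na.volume))
    post_or = replace(oro, volume=oro.volume * (1.0 - f_or))
    post_hy = replace(hy, volume=hy.volume * (1.0 - f_hy))
    post_regions = (post_na, post_or, post_hy)

    inlet_post = min(pre.inlet_area * (1.0 - f_hy), 0.95 * post_hy.volume * 10.0 / post_hy.length)
    a_min_target = pre.a_min * (1.0 - f_am)
    for _ in range(4):
        try:
            a_min_post = _cap_a_min(a_min_target, post_regions, inlet_post)
            break
        except InfeasibleSpecError:
            inlet_post *= 0.8  # shrink the inlet pin until the base profile closes
    else:
        raise InfeasibleSpecError("could not derive a feasible post-treatment spec")

    post_region_len = post_regions[REGION_NAMES.index(params.post_a_min_region)].length
    return PhantomSpec(
        regions=post_regions,
        a_min=a_min_post,
        a_min_region=params.post_a_min_region,
        a_min_frac=params.post_a_min_frac,
        inlet_area=inlet_post,
        constriction_width=0.9 * post_region_len,
    )


def mean_spec(params: CohortParams, post: bool = False) -> PhantomSpec:
    """The noise-free spec at the parameter means (post at the mean ice)."""
    regions = (
        RegionSpec("nasopharynx", params.len_na_mean, params.v_na_mean),
        RegionSpec("oropharynx", params.len_or_mean, params.v_or_mean),
        RegionSpec("hypopharynx", params.len_hy_mean, params.v_hy_mean),
    )
    pre = PhantomSpec(
        regions=regions,
        a_min=_cap_a_min(params.a_min_mean, regions, params.inlet_area_mean),
        a_min_region=params.pre_a_min_region,
        a_min_frac=params.pre_a_min_frac,
        inlet_area=params.inlet_area_mean,
    )
    if not post:
        return pre
    return apply_retraction(pre, params.ice_mean, params, rng=None)


def _copula_trunc_normal(
    rng: np.random.Generator,
    latent: np.ndarray,
    load: float,
    mean: float,
    sd: float,
    lo: float,
) -> np.ndarray:
    """Lower-truncated normal draws correlated through a latent size factor.

    Gaussian copula: z = load*latent + sqrt(1-load^2)*noise is standard
    normal, so mapping through the truncated-normal inverse CDF preserves
    the marginal exactly while inducing the airway-size correlation.
    """
    from scipy.special import ndtr, ndtri

    n = latent.size
    if sd == 0:
        return np.full(n, mean)
    z = load * latent + np.sqrt(max(1.0 - load**2, 0.0)) * rng.standard_normal(n)
    u = ndtr(z)
    pa = ndtr((lo - mean) / sd)
    u = np.clip(pa + u * (1.0 - pa), 1e-12, 1.0 - 1e-12)
    return mean + sd * ndtri(u)


def sample_cohort(params: CohortParams, n: int) -> list[PairedCase]:
    """Draw ``n`` paired pre/post cases; fully reproducible from the seed.

    Pre-treatment variables are truncated-normal (truncated at 10 % of the
    mean, or the a_min floor, to stay physical) and share a latent airway
    "size" factor — large airways come with large minimum areas, as in real
    anatomy; marginals are preserved exactly via a Gaussian copula. ice is
    normal truncated at 0; post specs follow from :func:`apply_retraction`
    with noise.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(params.seed)

    latent = rng.standard_normal(n)
    load = params.size_correlation

    def draws(mean: float, sd: float, lo: float | None = None, ld: float | None = None):
        lo = 0.1 * mean if lo is None else lo
        # truncation raises the mean; shift the location so the recovered
        # sample mean matches the configured one
        loc = _floor_compensated_loc(mean, sd, lo)
        return _copula_trunc_normal(
            rng, latent, load if ld is None else ld, loc, sd, lo
        )

    v_na = draws(params.v_na_mean, params.v_na_sd)
    v_or = draws(params.v_or_mean, params.v_or_sd)
    v_hy = draws(params.v_hy_mean, params.v_hy_sd)
    a_min_lo = max(params.a_min_floor, 0.1 * params.a_min_mean)
    a_min_loc = _floor_compensated_loc(params.a_min_mean, params.a_min_sd, a_min_lo)
    a_min = _copula_trunc_normal(rng, latent, load, a_min_loc, params.a_min_sd, a_min_lo)
    inlet = draws(params.inlet_area_mean, params.inlet_area_sd)
    l_na = draws(params.len_na_mean, params.len_na_sd, ld=0.3 * load)
    l_or = draws(params.len_or_mean, params.len_or_sd, ld=0.3 * load)
    l_hy = draws(params.len_hy_mean, params.len_hy_sd, ld=0.3 * load)
    ice = _trunc_normal(rng, params.ice_mean, params.ice_sd, 0.0, n)

    def trial_tighten(spec: PhantomSpec, is_pre: bool) -> PhantomSpec:
        """Validate with a cheap 1 sample/mm build and adjust if needed.

        Repair ladder (each step the ground truth the surrogate cap can
        miss): infeasible profiles first shorten this case's lengths
        (raising areas; volumes and a_min untouched); a hypopharyngeal
        constriction that still does not fit is relocated to the (much
        longer) oropharynx — the cohort's minimum is only *mainly*
        hypopharyngeal pre-treatment; walls steeper than the slope cap get
        a widened, then superiorly shifted, then relocated constriction.
        Shrinking a_min is the last resort, and eroding it below the
        physiological floor triggers a redraw.
        """
        original_total = spec.total_length
        relocated = spec.a_min_region != "hypopharynx"
        best_buildable: PhantomSpec | None = None
        for _ in range(24):
            try:
                ph = build_phantom(spec, axial_resolution=1.0)
            except InfeasibleSpecError:
                if spec.total_length > 0.75 * original_total:
                    spec = replace(
                        spec,
                        regions=tuple(
                            replace(r, length=r.length * 0.93) for r in spec.regions
                        ),
                    )
                    continue
                if not relocated:
                    spec = replace(
                        spec,
                        a_min_region="oropharynx",
                        a_min_frac=0.55,
                        constriction_width=None,
                    )
                    relocated = True
                    continue
                spec = replace(spec, a_min=spec.a_min * 0.92)
                if is_pre and spec.a_min < 0.9 * params.a_min_floor:
                    if best_buildable is not None:
                        return best_buildable
                    raise InfeasibleSpecError("pre a_min eroded below floor")
                continue
            slope = float(np.abs(np.gradient(ph.radius, ph.z)).max())
            if slope <= params.max_wall_slope:
                return spec
            best_buildable = spec  # steep but valid; better than a redraw
            ridx = REGION_NAMES.index(spec.a_min_region)
            lengths = [r.length for r in spec.regions]
            start = sum(lengths[:ridx])
            center = start + spec.a_min_frac * lengths[ridx]
            total = spec.total_length
            width_bound = 2.0 * min(total - center - 1.0, center - 1.0)
            width = spec.constriction_width or 0.5 * lengths[ridx]
            if width * 1.3 <= min(width_bound, 1.4 * lengths[ridx]):
                spec = replace(spec, constriction_width=width * 1.3)
            elif spec.a_min_frac > 0.25:
                spec = replace(spec, a_min_frac=spec.a_min_frac - 0.1)
            elif not relocated:
                spec = replace(
                    spec,
                    a_min_region="oropharynx",
                    a_min_frac=0.55,
                    constriction_width=None,
                )
                relocated = True
            else:
                # out of geometric levers; accept the residual steepness
                # rather than distorting the a_min draw
                return spec
        if best_buildable is not None:
            # repairs ping-ponged; a steep-but-buildable spec beats a
            # selective redraw (the solver ladder or case exclusion copes)
            return best_buildable
        raise InfeasibleSpecError("spec not buildable within slope/feasibility limits")

    def make_case(vals: dict, ice_i: float) -> PairedCase:
        # Airway size and minimum area scale together in real anatomy; an
        # independently drawn a_min that exceeds what the drawn volumes and
        # lengths allow is repaired by shrinking this case's lengths
        # (raising areas everywhere) rather than by clipping a_min, so the
        # configured A_min distribution is preserved.
        a_min_d = vals["a_min"]
        lengths0 = np.array([vals["l_na"], vals["l_or"], vals["l_hy"]])
        vols = np.array([vals["v_na"], vals["v_or"], vals["v_hy"]])

        def feasibility_floor(lengths):
            hy_mean_area = vols[2] * 10.0 / lengths[2]
            inlet = min(max(vals["inlet"], a_min_d / 0.95), hy_mean_area)
            # deep minima need a tapering hypopharynx: capping the inlet
            # keeps the dip shallow relative to its local base, so the
            # carved volume stays small enough to compensate in-region
            # (a persistently narrow outlet below a tight throat)
            inlet = min(inlet, max(3.6 * a_min_d - hy_mean_area, 1.05 * a_min_d))
            try:
                knot_min = _bumpless_knot_min(lengths, vols * 1e3, inlet * 1e2)
            except InfeasibleSpecError:
                return inlet, -np.inf
            return inlet, 0.97 * knot_min * 1e-2

        # Volumes and a_min are the variables with recovery guarantees;
        # lengths are free. Independently drawn volumes can be mutually
        # inconsistent with the drawn lengths (no smooth positive profile)
        # or leave no room for the drawn a_min — repair by blending this
        # case's lengths toward volume-proportional (a flat, always
        # feasible profile), then one mild overall shrink, then clip.
        total0 = lengths0.sum()
        vol_prop = total0 * vols / vols.sum()
        lengths = lengths0
        inlet_i, floor = feasibility_floor(lengths)
        for t in (0.5, 1.0):
            if a_min_d <= floor:
                break
            lengths = (1.0 - t) * lengths0 + t * vol_prop
            inlet_i, floor = feasibility_floor(lengths)
        if a_min_d > floor > 0:
            lengths = lengths * max(floor / a_min_d, 0.85)
            inlet_i, floor = feasibility_floor(lengths)
        if not np.isfinite(floor) or floor <= 0:
            raise InfeasibleSpecError("no feasible geometry for drawn case")
        if min(a_min_d, floor) < 0.9 * params.a_min_floor:
            # a small airway whose repair pushed the pre-treatment minimum
            # under the physiological floor: redraw rather than keep an
            # anatomy the steady laminar regime does not cover
            raise InfeasibleSpecError("pre-treatment a_min below physiological floor")
        regions = (
            RegionSpec("nasopharynx", float(lengths[0]), vals["v_na"]),
            RegionSpec("oropharynx", float(lengths[1]), vals["v_or"]),
            RegionSpec("hypopharynx", float(lengths[2]), vals["v_hy"]),
        )
        pre = PhantomSpec(
            regions=regions,
            a_min=min(a_min_d, floor),
            a_min_region=params.pre_a_min_region,
            a_min_frac=params.pre_a_min_frac,
            inlet_area=inlet_i,
        )
        pre = trial_tighten(pre, is_pre=True)
        post = trial_tighten(apply_retraction(pre, ice_i, params, rng=rng), is_pre=False)
        return PairedCase(pre=pre, post=post, ice=ice_i)

    def comp(mean, sd, lo):
        return (_floor_compensated_loc(mean, sd, lo), sd, lo)

    means_sds = {
        "v_na": comp(params.v_na_mean, params.v_na_sd, 0.1 * params.v_na_mean),
        "v_or": comp(params.v_or_mean, params.v_or_sd, 0.1 * params.v_or_mean),
        "v_hy": comp(params.v_hy_mean, params.v_hy_sd, 0.1 * params.v_hy_mean),
        "a_min": (a_min_loc, params.a_min_sd, a_min_lo),
        "inlet": comp(params.inlet_area_mean, params.inlet_area_sd, 0.1 * params.inlet_area_mean),
        "l_na": comp(params.len_na_mean, params.len_na_sd, 0.1 * params.len_na_mean),
        "l_or": comp(params.len_or_mean, params.len_or_sd, 0.1 * params.len_or_mean),
        "l_hy": comp(params.len_hy_mean, params.len_hy_sd, 0.1 * params.len_hy_mean),
    }
    cases: list[PairedCase] = []
    for i in range(n):
        vals = {
            "v_na": float(v_na[i]), "v_or": float(v_or[i]), "v_hy": float(v_hy[i]),
            "a_min": float(a_min[i]), "inlet": float(inlet[i]),
            "l_na": float(l_na[i]), "l_or": float(l_or[i]), "l_hy": float(l_hy[i]),
        }
        ice_i = float(ice[i])
        for attempt in range(20):
            try:
                cases.append(make_case(vals, ice_i))
                break
            except InfeasibleSpecError:
                # pathological tail draw (e.g. regions too disparate for a
                # positive base profile): redraw this case
                vals = {
                    k: float(_trunc_normal(rng, m, s, lo, 1)[0])
                    for k, (m, s, lo) in means_sds.items()
                }
                ice_i = float(_trunc_normal(rng, params.ice_mean, params.ice_sd, 0.0, 1)[0])
        else:
            raise InfeasibleSpecError(
                "could not draw a feasible case in 20 attempts; check CohortParams"
            )
    return cases


# ---------------------------------------------------------------------------
# voxel / HU segmentation stand-in
# ---------------------------------------------------------------------------

HU_AIR = -1000.0
HU_TISSUE = 40.0


@dataclass(frozen=True)
class VoxelVolume:
    """Synthetic CT block: HU scalar grid with isotropic voxels."""

    hu: np.ndarray  # (nx, ny, nz) HU values
    voxel_mm: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ValueError("voxel edge must be > 0")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU values must be finite")


def voxelize(phantom: AirwayPhantom, voxel_mm: float, margin_mm: float = 2.0) -> VoxelVolume:
    """Rasterize the phantom into an HU block (air inside, tissue outside)."""
    if voxel_mm <= 0:
        raise ValueError("voxel_mm must be > 0")
    r_max = float(phantom.radius.max()) + margin_mm
    nx = int(np.ceil(2.0 * r_max / voxel_mm))
    nz = int(np.ceil(phantom.length / voxel_mm))
    x = (np.arange(nx) + 0.5) * voxel_mm - r_max
    zc = (np.arange(nz) + 0.5) * voxel_mm + float(phantom.z[0])
    rr2 = x[:, None] ** 2 + x[None, :] ** 2  # (nx, nx)
    r_of_z = phantom.radius_at(zc)  # (nz,)
    inside = rr2[:, :, None] < (r_of_z[None, None, :] ** 2)
    hu = np.where(inside, HU_AIR, HU_TISSUE).astype(np.float32)
    return VoxelVolume(hu=hu, voxel_mm=voxel_mm, origin=(-r_max, -r_max, float(phantom.z[0])))


def segment(volume: VoxelVolume, lo_hu: float = -1024.0, hi_hu: float = -480.0) -> tuple[np.ndarray, float]:
    """Threshold segmentation; returns (mask, segmented volume in cm^3)."""
    if lo_hu >= hi_hu:
        raise ValueError("lo_hu must be < hi_hu")
    mask = (volume.hu >= lo_hu) & (volume.hu <= hi_hu)
    count = int(mask.sum())
    if count == 0:
        warnings.warn("segmentation selected zero voxels", stacklevel=2)
    return mask, count * volume.voxel_mm**3 * 1e-3


def voxelize_and_segment(
    phantom: AirwayPhantom,
    voxel_mm: float,
    lo_hu: float = -1024.0,
    hi_hu: float = -480.0,
) -> tuple[np.ndarray, float]:
    """Rasterize then threshold; the CBCT reconstruction stand-in."""
    return segment(voxelize(phantom, voxel_mm), lo_hu, hi_hu)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def phantom_profile_csv(phantom: AirwayPhantom, path) -> None:
    """Write (z_mm, radius_mm, area_mm2) rows."""
    data = np.column_stack([phantom.z, phantom.radius, phantom.area])
    np.savetxt(path, data, delimiter=",", header="z_mm,radius_mm,area_mm2", comments="")


def phantom_to_stl(phantom: AirwayPhantom, path, n_theta: int = 64, ascii_format: bool = False) -> None:
    """Triangulate the surface of revolution and write STL.

    Binary by default (the conventional interchange form); ``ascii_format``
    gives a text file.
    """
    z = phantom.z
    r = phantom.radius
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    # ring i vertex k: (r_i ct_k, r_i st_k, z_i)
    tris: list[np.ndarray] = []
    for i in range(len(z) - 1):
        for k in range(n_theta):
            k2 = (k + 1) % n_theta
            a = np.array([r[i] * ct[k], r[i] * st[k], z[i]])
            b = np.array([r[i] * ct[k2], r[i] * st[k2], z[i]])
            c = np.array([r[i + 1] * ct[k], r[i + 1] * st[k], z[i + 1]])
            d = np.array([r[i + 1] * ct[k2], r[i + 1] * st[k2], z[i + 1]])
            tris.append(np.stack([a, b, c]))
            tris.append(np.stack([b, d, c]))
    tri = np.asarray(tris)
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    if ascii_format:
        with open(path, "w") as fh:
            fh.write("solid phantom\n")
            for nv, t in zip(n, tri):
                fh.write(f"  facet normal {nv[0]:.6e} {nv[1]:.6e} {nv[2]:.6e}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid phantom\n")
        return
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 80)
        fh.write(struct.pack("<I", len(tri)))
        for nv, t in zip(n, tri):
            fh.write(struct.pack("<12fH", *nv, *t[0], *t[1], *t[2], 0))
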