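"""Pairwise nanoparticle interaction free energies.

A potential of mean force (PMF) between two identical spherical
nanoparticles — in practice the output of umbrella-sampling MD — is
represented as a sampled curve, fitted with a piecewise analytic model
(two 5th-order polynomials joined at the well minimum plus a logarithmic
tail beyond the sampled cutoff), and tabulated on a uniform grid for the
Brownian-dynamics engine.  The classical sphere-sphere van der Waals
(Hamaker) attraction is provided as the DLVO reference.

Units: distances in nm, energies in kJ/mol, forces in kJ/mol/nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from scipy.linalg import null_space

from .constants import AVOGADRO

__all__ = [
    "PMFCurve",
    "PMFFit",
    "TabulatedPotential",
    "PMFFitError",
    "dlvo_attraction",
    "fit_pmf",
    "evaluate_fit",
    "tabulate",
]

_DEGREE = 5  # polynomial order of both branches


class PMFFitError(RuntimeError):
    """Raised when a PMF curve cannot be fitted (e.g. no interior minimum)."""


@dataclass
class PMFCurve:
    """Sampled free-energy profile G(d) for one nanoparticle size.

    Parameters
    ----------
    distances : array
        Strictly increasing center-to-center separations d (nm), all > 0.
    energies : array
        Free energy G(d) (kJ/mol).
    radius : float
        Nanoparticle radius R (nm).
    """

    distances: np.ndarray
    energies: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.distances.ndim != 1 or self.distances.shape != self.energies.shape:
            raise ValueError("distances and energies must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.distances)) and np.all(np.isfinite(self.energies))):
            raise ValueError("PMF curve contains non-finite values")
        if self.distances.size and self.distances[0] <= 0:
            raise ValueError("distances must be positive")
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def __len__(self) -> int:
        return self.distances.size

    def shifted_to_zero_baseline(self) -> "PMFCurve":
        """Down-shift so the mean of the last 10% of points is zero.

        Mirrors the convention of plotting PMFs with null interaction at
        d -> infinity.
        """
        n_tail = max(3, len(self) // 10)
        baseline = float(np.mean(self.energies[-n_tail:]))
        return PMFCurve(self.distances, self.energies - baseline, self.radius)


@dataclass
class PMFFit:
    """Piecewise analytic fit of a PMF curve.

    The model is a 5th-order polynomial on the repulsive branch
    (d <= d_afe), a 5th-order polynomial on the attractive branch
    (d_afe < d <= r_c), and a logarithmic tail c1*ln(d) + c0 beyond the
    fitted cutoff r_c, clamped to exactly zero past its first zero
    crossing d_zero.

    Coefficients are raw power-series coefficients in d (kJ/mol per nm^i).
    """

    a: np.ndarray  # repulsive-branch coefficients a0..a5
    b: np.ndarray  # attractive-branch coefficients b0..b5
    c0: float
    c1: float
    d_afe: float  # well position (nm)
    r_c: float  # cutoff = largest fitted distance (nm)
    afe: float  # well depth (kJ/mol, positive for attractive systems)
    radius: float  # NP radius R (nm)
    d_lo: float  # smallest fitted distance (nm)
    d_zero: float = field(default=np.nan)  # tail zero crossing (nm)
    rms_residual: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if np.isnan(self.d_zero):
            self.d_zero = _tail_zero(self.c0, self.c1, self.r_c)

    def __call__(self, d):
        return evaluate_fit(self, d)


def _tail_zero(c0: float, c1: float, r_c: float) -> float:
    """First zero crossing of c1*ln(d)+c0 beyond r_c, or r_c if none."""
    if c1 == 0.0:
        return r_c
    x = float(np.exp(-c0 / c1))
    tail_rc = c1 * np.log(r_c) + c0
    # the tail is used only if it actually moves toward zero past r_c
    if x > r_c and (tail_rc < 0) == (c1 > 0):
        return x
    return r_c


@dataclass
class TabulatedPotential:
    """Uniform-grid energy/force table for the BD engine.

    force[i] = -dU/dd at distances[i]; zero interaction beyond d_max.
    """

    step: float
    d_min: float
    d_max: float
    energy: np.ndarray
    force: np.ndarray
    radius: float = np.nan
    afe: float = np.nan
    r_c: float = np.nan

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.energy.size
        if self.force.size != n:
            raise ValueError("energy and force columns differ in length")
        if n < 2:
            raise ValueError("table needs at least two points")
        if not np.isclose((self.d_max - self.d_min) / (n - 1), self.step, rtol=1e-9):
            raise ValueError("grid is not uniform with the declared step")

    @property
    def distances(self) -> np.ndarray:
        return self.d_min + self.step * np.arange(self.energy.size)


def dlvo_attraction(d, R: float, A_H: float):
    """Sphere-sphere van der Waals attraction W(d) in kJ/mol.

    W(d) = -A_H/6 * [ 2R^2/(d^2-4R^2) + 2R^2/d^2 + ln((d^2-4R^2)/d^2) ]

    Parameters
    ----------
    d : float or array
        Center-to-center distance (nm), strictly > 2R (diverges at contact).
    R : float
        Particle radius (nm).
    A_H : float
        Hamaker constant (J).
    """
    if A_H <= 0:
        raise ValueError("Hamaker constant must be positive")
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 2.0 * R):
        raise ValueError("dlvo_attraction requires d > 2R (diverges at contact)")
    ratio = (d_arr * d_arr - 4.0 * R * R) / (d_arr * d_arr)
    w_joule = -(A_H / 6.0) * (
        2.0 * R * R / (d_arr * d_arr - 4.0 * R * R)
        + 2.0 * R * R / (d_arr * d_arr)
        + np.log(ratio)
    )
    w = w_joule * AVOGADRO / 1000.0  # J -> kJ/mol
    return float(w) if np.isscalar(d) else w


def _constrained_branch_fit(d, g, split):
    """Least-squares fit of the two polynomial branches.

    Both branches are fitted simultaneously in scaled variables with
    value and first-derivative continuity enforced at the split via a
    null-space reduction of the linear system.

    Returns (a_raw, b_raw) power-series coefficients in d.
    """
    left = d <= split
    right = ~left
    n_l, n_r = int(left.sum()), int(right.sum())
    if n_l < _DEGREE + 2 or n_r < _DEGREE + 2:
        raise PMFFitError(
            f"too few points per branch ({n_l} repulsive, {n_r} attractive); "
            f"need at least {_DEGREE + 2} each"
        )

    d0, rc = d[0], d[-1]
    # scaled variables z in [-1, 1] per branch for conditioning
    def scale_l(x):
        return (2.0 * x - (d0 + split)) / (split - d0)

    def scale_r(x):
        return (2.0 * x - (split + rc)) / (rc - split)

    s_l = 2.0 / (split - d0)
    s_r = 2.0 / (rc - split)

    powers = np.arange(_DEGREE + 1)
    V_l = scale_l(d[left])[:, None] ** powers
    V_r = scale_r(d[right])[:, None] ** powers
    A = np.zeros((d.size, 2 * (_DEGREE + 1)))
    A[left, : _DEGREE + 1] = V_l
    A[right, _DEGREE + 1 :] = V_r

    # continuity at the split: z_l = +1, z_r = -1
    z_l, z_r = 1.0, -1.0
    C = np.zeros((2, 2 * (_DEGREE + 1)))
    C[0, : _DEGREE + 1] = z_l ** powers
    C[0, _DEGREE + 1 :] = -(z_r ** powers)
    dpow = np.concatenate(([0.0], powers[1:] * z_l ** (powers[1:] - 1)))
    dpow_r = np.concatenate(([0.0], powers[1:] * z_r ** (powers[1:] - 1)))
    C[1, : _DEGREE + 1] = s_l * dpow
    C[1, _DEGREE + 1 :] = -s_r * dpow_r

    Z = null_space(C)
    xi, *_ = np.linalg.lstsq(A @ Z, g, rcond=None)
    theta = Z @ xi
    p_l, p_r = theta[: _DEGREE + 1], theta[_DEGREE + 1 :]

    # convert scaled-basis coefficients to raw power series in d
    lin_l = Polynomial([-(d0 + split) / (split - d0), s_l])
    lin_r = Polynomial([-(split + rc) / (rc - split), s_r])
    a_raw = Polynomial(p_l)(lin_l).coef
    b_raw = Polynomial(p_r)(lin_r).coef
    a_raw = np.pad(a_raw, (0, _DEGREE + 1 - a_raw.size))
    b_raw = np.pad(b_raw, (0, _DEGREE + 1 - b_raw.size))
    return a_raw, b_raw


def _refine_minimum(a, b, split, d_lo, r_c, h):
    """Refine the well position on the fitted branches near the grid split."""
    lo = max(d_lo, split - 2.0 * h)
    hi = min(r_c, split + 2.0 * h)
    grid = np.linspace(lo, hi, 801)
    vals = np.where(grid <= split, np.polynomial.polynomial.polyval(grid, a),
                    np.polynomial.polynomial.polyval(grid, b))
    k = int(np.argmin(vals))
    if 0 < k < grid.size - 1:
        # parabolic interpolation around the discrete minimum
        y0, y1, y2 = vals[k - 1], vals[k], vals[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom > 0:
            return float(grid[k] + 0.5 * (y0 - y2) / denom * (grid[1] - grid[0]))
    return float(grid[k])


def fit_pmf(
    curve: PMFCurve,
    r_c: float | None = None,
    tail_frac: float = 0.15,
    d_afe: float | None = None,
) -> PMFFit:
    """Fit a PMF curve with the piecewise polynomial + log-tail model.

    The curve is first down-shifted to a zero far-field baseline.  The
    polynomial branches are split at the well minimum d_AFE (grid
    minimum, then the junction is iterated onto the refined minimum of
    the fitted branches); value and slope continuity are enforced at
    d_AFE.  The polynomial cutoff r_c defaults to the first distance
    past the well where the profile has decayed to ``tail_frac`` of the
    well depth — a 5th-order polynomial cannot track the decay over
    many length scales, and the small remainder is the log tail's job.
    The log tail is fitted by least squares to the data beyond r_c with
    value continuity at r_c (slope continuity if there is no data
    there), and clamped to zero past its first zero crossing.

    Raises
    ------
    PMFFitError
        If the profile has no unique interior minimum ("monotonic
        profile") or a branch has fewer points than coefficients.
    """
    if len(curve) < 30:
        raise PMFFitError("need at least 30 points spanning the well and a flat tail")
    shifted = curve.shifted_to_zero_baseline()
    d_all, g_all = shifted.distances, shifted.energies

    k_min = int(np.argmin(g_all))
    if k_min == 0 or k_min == d_all.size - 1 or g_all[k_min] >= 0.0:
        raise PMFFitError("monotonic profile: no interior minimum to fit")

    if r_c is None:
        depth_est = -g_all[k_min]
        past_well = np.nonzero(
            (np.arange(d_all.size) > k_min) & (np.abs(g_all) <= tail_frac * depth_est)
        )[0]
        k_rc = int(past_well[0]) if past_well.size else d_all.size - 1
        # keep enough points on the attractive branch
        k_rc = max(k_rc, k_min + _DEGREE + 2)
        r_c = float(d_all[k_rc])
    else:
        k_rc = int(np.searchsorted(d_all, r_c, side="right")) - 1
        r_c = float(d_all[k_rc])
    d, g = d_all[: k_rc + 1], g_all[: k_rc + 1]

    split = float(d[k_min])
    h = float(np.median(np.diff(d)))
    if d_afe is not None:
        # caller pins the branch junction (e.g. refitting data generated
        # by a known piecewise model)
        split = float(d_afe)
        a, b = _constrained_branch_fit(d, g, split)
    else:
        # iterate split <- refined minimum so the branch junction
        # converges onto the well position; d_afe is always the junction
        # of the last fit, so the stored piecewise model is continuous at
        # d_afe exactly (the continuity constraint is imposed there)
        a = b = None
        for it in range(6):
            a, b = _constrained_branch_fit(d, g, split)
            refined = _refine_minimum(a, b, split, d[0], d[-1], h)
            if abs(refined - split) < 1e-6 or it == 5:
                break
            split = refined
    d_afe = split

    d_lo = float(d[0])
    b_poly = Polynomial(b)
    val_rc = float(b_poly(r_c))
    tail_d, tail_g = d_all[k_rc + 1 :], g_all[k_rc + 1 :]
    if tail_d.size >= 2:
        # least-squares log tail with value continuity at r_c:
        # model = val_rc + c1 * ln(d / r_c)
        x = np.log(tail_d / r_c)
        c1 = float(np.sum(x * (tail_g - val_rc)) / np.sum(x * x))
    else:
        # no data beyond r_c: attach the tail by slope continuity
        c1 = r_c * float(b_poly.deriv()(r_c))
    c0 = val_rc - c1 * np.log(r_c)

    afe = -float(np.polynomial.polynomial.polyval(d_afe, a))
    fit = PMFFit(
        a=a, b=b, c0=c0, c1=c1, d_afe=d_afe, r_c=r_c, afe=afe,
        radius=curve.radius, d_lo=d_lo,
    )
    resid = evaluate_fit(fit, d_all) - g_all
    fit.rms_residual = float(np.sqrt(np.mean(resid**2)))
    return fit


def evaluate_fit(fit: PMFFit, d):
    """Evaluate the piecewise model at distance(s) d (nm) -> kJ/mol."""
    d_arr = np.atleast_1d(np.asarray(d, dtype=float))
    if not np.all(np.isfinite(d_arr)) or np.any(d_arr <= 0):
        raise ValueError("distances must be finite and positive")
    out = np.empty_like(d_arr)
    rep = d_arr <= fit.d_afe
    att = (d_arr > fit.d_afe) & (d_arr <= fit.r_c)
    tail = (d_arr > fit.r_c) & (d_arr <= fit.d_zero)
    far = d_arr > fit.d_zero
    out[rep] = np.polynomial.polynomial.polyval(d_arr[rep], fit.a)
    out[att] = np.polynomial.polynomial.polyval(d_arr[att], fit.b)
    out[tail] = fit.c1 * np.log(d_arr[tail]) + fit.c0
    out[far] = 0.0
    return float(out[0]) if np.isscalar(d) else out


def tabulate(
    fit: PMFFit,
    step: float = 2e-3,
    d_max: float | None = None,
    wall_cap: float = 100.0,
) -> TabulatedPotential:
    """Build a uniform energy/force table from a fitted PMF.

    Force is the analytic branch derivative except at the two points
    flanking each branch junction, where a central finite difference of
    the tabulated energy is used.  Below the lowest fitted distance the
    repulsive polynomial is extrapolated; the table is truncated (d_min)
    where that extrapolated wall stops rising or exceeds ``wall_cap``
    times the well depth — pair distances below d_min are treated as
    overlap errors by the simulator.

    Parameters
    ----------
    step : float
        Grid spacing (nm), default 2e-3.
    d_max : float, optional
        Table end (nm); must exceed r_c.  Default: just past the tail
        zero crossing, so U(d_max) = F(d_max) = 0.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    well_width = fit.r_c - fit.d_afe
    if step > well_width:
        raise ValueError(
            f"step {step} nm larger than the well width {well_width:.3g} nm: "
            "table would undersample the well"
        )
    if d_max is None:
        d_max = fit.d_zero + 10 * step
    if d_max <= fit.r_c:
        raise ValueError("d_max must exceed the fitted cutoff r_c")

    a_poly = Polynomial(fit.a)
    da_poly = a_poly.deriv()
    # walk the repulsive extrapolation downward from the lowest fitted point
    u_cap = wall_cap * max(fit.afe, 1.0)
    d_min = step
    n_lo = int(np.floor(fit.d_lo / step))
    for k in range(n_lo, 0, -1):
        x = k * step
        if da_poly(x) >= 0.0 or a_poly(x) > u_cap:
            d_min = (k + 1) * step
            break
    else:
        d_min = step

    n = int(np.floor((d_max - d_min) / step + 0.5)) + 1
    grid = d_min + step * np.arange(n)
    d_max = float(grid[-1])
    energy = evaluate_fit(fit, grid)

    b_poly = Polynomial(fit.b)
    db_poly = b_poly.deriv()
    force = np.empty(n)
    rep = grid <= fit.d_afe
    att = (grid > fit.d_afe) & (grid <= fit.r_c)
    tail = (grid > fit.r_c) & (grid <= fit.d_zero)
    far = grid > fit.d_zero
    force[rep] = -da_poly(grid[rep])
    force[att] = -db_poly(grid[att])
    force[tail] = -fit.c1 / grid[tail]
    force[far] = 0.0
    # central finite differences at points flanking branch junctions
    for junction in (fit.d_afe, fit.r_c, fit.d_zero):
        j = int(np.floor((junction - d_min) / step))
        for k in (j, j + 1):
            if 0 < k < n - 1:
                force[k] = -(energy[k + 1] - energy[k - 1]) / (2.0 * step)
    return TabulatedPotential(
        step=step, d_min=float(grid[0]), d_max=d_max,
        energy=energy, force=force,
        radius=fit.radius, afe=fit.afe, r_c=fit.r_c,
    )
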