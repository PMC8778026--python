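"""Synthetic inputs for the aggregation pipeline.

Real inputs to this package are PMF curves from umbrella-sampling MD and
particle configurations from experiment-matched volume fractions.  This
module generates physically shaped stand-ins for both, plus synthetic
kinetics traces for fit-recovery studies, so the whole pipeline runs
without any external data.

A synthetic PMF is a scaled sphere-sphere Hamaker attraction plus an
exponential steric wall, rescaled so the well minimum sits exactly at the
requested depth and position.  Only the depth and position of the well
matter downstream; the atomistic fine structure of real PMFs (solvent
layering oscillations, sampling noise) is deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import HAMAKER_TIO2_WATER
from .potentials import PMFCurve, dlvo_attraction

__all__ = [
    "SyntheticPMFSpec",
    "make_synthetic_pmf",
    "particles_for_phi",
    "random_configuration",
    "synthetic_kinetics_trace",
]


@dataclass
class SyntheticPMFSpec:
    """Parameters of a synthetic PMF well.

    Attributes
    ----------
    radius : float
        NP radius R (nm).
    depth : float
        Well depth (kJ/mol, positive).  depth = 0 gives a flat curve.
    surface_gap : float
        Well position above contact, d_AFE - 2R (nm).
    r_c : float, optional
        Largest sampled distance (nm).  Default: chosen so the curve has
        decayed to under 0.5% of the depth (capped at 2R + 15 nm).
    spacing : float
        Grid spacing of the sampled curve (nm).
    hamaker : float
        Hamaker constant (J) shaping the attractive branch.
    wall_cap : float
        The grid starts where the steric wall reaches wall_cap * depth,
        emulating the limited wall height sampled by umbrella windows.
    """

    radius: float
    depth: float
    surface_gap: float
    r_c: float | None = None
    spacing: float = 0.01
    hamaker: float = HAMAKER_TIO2_WATER
    wall_cap: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.spacing <= 0:
            raise ValueError("radius and spacing must be positive")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.depth > 0 and self.surface_gap <= 0:
            raise ValueError("surface_gap must be positive")
        if self.r_c is not None and self.surface_gap >= self.r_c - 2 * self.radius:
            raise ValueError("well must sit below the cutoff: surface_gap < r_c - 2R")


def _soft_attraction(spec: SyntheticPMFSpec):
    """Scaled sphere-sphere attraction with a softened contact divergence.

    Real PMF wells are an order of magnitude deeper than the bare Hamaker
    prediction at the well position, so the attraction must be scaled up;
    the 1/h contact divergence of the unscaled form would then punch
    through any finite steric wall.  The divergence is regularized by
    evaluating the attraction at the smoothed separation
    g(h) = (h^3 + h_s^3)^(1/3) with h_s = surface_gap/2, which is
    inconsequential at and beyond the well but finite at contact.
    Returns the unit-scale attraction as a function of h = d - 2R.
    """
    R, gap = spec.radius, spec.surface_gap
    h_s = gap / 2.0

    def attraction(h):
        g = (np.asarray(h, dtype=float) ** 3 + h_s**3) ** (1.0 / 3.0)
        return dlvo_attraction(2.0 * R + g, R, spec.hamaker)

    return attraction


def _well_scales(spec: SyntheticPMFSpec):
    """Solve the 2x2 linear system pinning the well depth and position.

    G(2R + h) = s * attraction(h) + A * exp(-h/lam),  lam = surface_gap/3.
    Conditions: G = -depth and G' = 0 at h = surface_gap.
    """
    gap = spec.surface_gap
    lam = gap / 3.0
    attraction = _soft_attraction(spec)
    w = float(attraction(gap))
    eps = 1e-6
    w_prime = float(attraction(gap + eps) - attraction(gap - eps)) / (2.0 * eps)
    denom = w + lam * w_prime
    if denom >= 0:
        raise ValueError(
            "infeasible synthetic PMF spec: steric wall and attraction "
            "cannot form a well at the requested position"
        )
    s = -spec.depth / denom
    amp = s * lam * w_prime * np.exp(gap / lam)
    if s < 0 or amp < 0:
        raise ValueError("infeasible synthetic PMF spec: negative branch scale")
    return s, amp, lam


def make_synthetic_pmf(spec: SyntheticPMFSpec) -> PMFCurve:
    """Generate a smooth synthetic PMF curve from a well specification.

    The unique minimum is exactly -depth at d = 2R + surface_gap; the
    curve decays toward zero at large d (within 2% of zero at r_c under
    the default adaptive cutoff).
    """
    R = spec.radius
    if spec.depth == 0.0:
        r_c = spec.r_c if spec.r_c is not None else 2.0 * R + 3.0
        d = np.arange(2.0 * R + spec.spacing, r_c + spec.spacing / 2, spec.spacing)
        return PMFCurve(d, np.zeros_like(d), R)

    s, amp, lam = _well_scales(spec)
    attraction = _soft_attraction(spec)

    def profile(d):
        h = np.asarray(d, dtype=float) - 2.0 * R
        return s * attraction(h) + amp * np.exp(-h / lam)

    # grid start: walk left from the well minimum up the steric wall until
    # it reaches wall_cap * depth (umbrella windows sample a wall of
    # limited height); unscreened Hamaker divergence further in is never
    # sampled
    fine = np.arange(2.0 * R + 1e-4, 2.0 * R + spec.surface_gap, 1e-4)
    vals = profile(fine)
    k_peak = int(np.argmax(vals))
    if vals[k_peak] <= 0:
        raise ValueError("infeasible synthetic PMF spec: no steric wall forms")
    rising = vals[k_peak:]
    above = np.nonzero(rising >= spec.wall_cap * spec.depth)[0]
    k_start = k_peak + (int(above[-1]) if above.size else 0)
    d_start = float(fine[k_start])

    if spec.r_c is not None:
        r_c = spec.r_c
    else:
        # extend until the attraction has decayed to 0.5% of the depth
        r_c = 2.0 * R + spec.surface_gap + 1.0
        while abs(profile(r_c)) > 0.005 * spec.depth and r_c < 2.0 * R + 15.0:
            r_c += 0.25
    d = np.arange(d_start, r_c + spec.spacing / 2, spec.spacing)
    return PMFCurve(d, profile(d), R)


def particles_for_phi(phi: float, h_box: float, radius: float) -> int:
    """Number of spheres of given radius filling volume fraction phi.

    round(phi * h_box^3 / (4/3 pi R^3)); raises if fewer than 2.
    """
    if not 0.0 < phi < 0.4:
        raise ValueError("phi must be in (0, 0.4)")
    n = int(round(phi * h_box**3 / ((4.0 / 3.0) * np.pi * radius**3)))
    if n < 2:
        raise ValueError(f"phi={phi} in a {h_box} nm box yields {n} particle(s); need >= 2")
    return n


def random_configuration(
    n: int,
    h_box: float,
    radius: float,
    min_gap: float | None = None,
    seed: int = 0,
    max_tries: int = 200,
):
    """Uniform random non-overlapping positions in a periodic cubic box.

    All minimum-image pair distances are >= 2R + min_gap (default
    min_gap = 0.1 R).  Returns an (n, 3) array of positions in [0, h_box).
    """
    if min_gap is None:
        min_gap = 0.1 * radius
    d_min = 2.0 * radius + min_gap
    if n * (4.0 / 3.0) * np.pi * (radius + min_gap / 2.0) ** 3 >= 0.3 * h_box**3:
        raise ValueError("packing infeasible: lower the volume fraction")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        pos = rng.uniform(0.0, h_box, size=(n, 3))
        if n == 1:
            return pos
        tree = cKDTree(pos, boxsize=h_box)
        if not tree.query_pairs(d_min, output_type="ndarray").size:
            return pos
        # resample only the offenders
        for _ in range(50 * n):
            pairs = cKDTree(pos, boxsize=h_box).query_pairs(d_min, output_type="ndarray")
            if pairs.size == 0:
                return pos
            bad = np.unique(pairs.ravel())
            pos[bad] = rng.uniform(0.0, h_box, size=(bad.size, 3))
    raise RuntimeError(
        "rejection sampling exceeded retry budget; lower phi or min_gap"
    )


def synthetic_kinetics_trace(
    n2: float,
    n3: float,
    params,
    W: float,
    dt: float,
    t_end: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_total: int | None = None,
    n_frames: int = 200,
):
    """Ground-truth kinetics trace from the size-aware discretized model.

    Runs the modified aggregation recursion and optionally applies
    multiplicative Gaussian noise to the mean cluster size.  The implied
    cluster count n_total / N(t) is emitted so downstream fits can apply
    the >5-aggregates frame filter.

    Parameters mirror :func:`nanoagg.kinetics.modified_trace`; ``params``
    is a :class:`nanoagg.kinetics.SuspensionParams`.
    """
    from .clusters import KineticsTrace
    from .kinetics import modified_trace

    base = modified_trace(n2, n3, params, W, dt, t_end, n_frames=n_frames)
    mean_size = base.mean_size.copy()
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        mean_size = mean_size * (1.0 + noise_sigma * rng.standard_normal(mean_size.size))
        mean_size = np.maximum(mean_size, 1.0)
    if n_total is None:
        n_total = particles_for_phi(params.phi, 100.0, params.radius)
    return KineticsTrace(
        times=base.times,
        n_clusters=n_total / mean_size,
        mean_size=mean_size,
        n_total=float(n_total),
    )
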