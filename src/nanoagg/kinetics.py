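"""Aggregation kinetics: Smoluchowski theory and the size-aware model.

For a diffusion-limited colloidal suspension the mean number of particles
per aggregate grows linearly, N(t) = 1 + t/tp, with characteristic time
tp = pi*mu*R^3*W / (kB*T*phi).  The stability ratio W folds the pair
interaction and the near-contact hydrodynamic correction B(h) into a
single dimensionless retardation factor:

    W = 2R * Int_0^inf  B(h) / (h+2R)^2 * exp[(W_R + W_A)/kBT] dh

with h the surface-to-surface separation.  For charge-neutral particles
W_R = 0 and W_A is the sphere-sphere Hamaker attraction.

Because the linear law ignores the slowdown of large aggregates, a
discretized model adds a size-dependent time constant,

    N_i = N_{i-1} + dt / tp*,   tp* = exp(n2 * N_{i-1} * phi^(1/3)) *
                                      pi*mu*R^3*(n3*W) / (kB*T*phi),

iterated from N_0 = 1; n2 = 0, n3 = 1 recovers the linear model.  Both
coefficients are bounded to [0, 1] and fitted to simulation traces by
deterministic multi-start bounded least squares, using only frames with
more than 5 aggregates in the box.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import quad
from scipy.optimize import least_squares

from .clusters import KineticsTrace
from .constants import (
    HAMAKER_TIO2_WATER,
    KB_J,
    KB_KJ_MOL_K,
    WATER_VISCOSITY_310K,
)
from .potentials import dlvo_attraction

__all__ = [
    "SuspensionParams",
    "StabilityResult",
    "ModifiedModelFit",
    "hydrodynamic_B",
    "stability_ratio",
    "aggregation_time",
    "smoluchowski_N",
    "modified_trace",
    "fit_n1",
    "fit_n2_n3",
    "rmse",
]


@dataclass
class SuspensionParams:
    """Physical parameters of a monodisperse colloidal suspension."""

    radius: float  # nm
    phi: float  # volume fraction
    mu: float = WATER_VISCOSITY_310K  # Pa s
    T: float = 310.0  # K
    hamaker: float = HAMAKER_TIO2_WATER  # J

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must be in (0, 1)")
        if min(self.radius, self.mu, self.T, self.hamaker) <= 0:
            raise ValueError("radius, mu, T and hamaker must all be positive")


@dataclass
class StabilityResult:
    """Stability ratio with quadrature diagnostics."""

    W: float
    abs_error: float
    n_evaluations: int


@dataclass
class ModifiedModelFit:
    """Result of fitting the size-aware discretized aggregation model."""

    n2: float
    n3: float
    dt: float  # us
    rmse: float
    n_frames_used: int
    W: float
    tp: float  # us


def hydrodynamic_B(h, R: float):
    """Near-contact hydrodynamic correction to relative pair diffusion.

    B(h) = (6(h/R)^2 + 13(h/R) + 2) / (6(h/R)^2 + 4(h/R)); > 1 for all
    finite h, diverging at contact and tending to 1 far away.
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr <= 0):
        raise ValueError("hydrodynamic correction diverges at h = 0; require h > 0")
    x = h_arr / R
    out = (6.0 * x * x + 13.0 * x + 2.0) / (6.0 * x * x + 4.0 * x)
    return float(out) if np.isscalar(h) else out


def stability_ratio(
    params: SuspensionParams,
    with_hydro: bool = True,
    potential="hamaker",
) -> StabilityResult:
    """Stability ratio W by adaptive quadrature.

    ``potential`` is the interaction energy as a function of the surface
    separation h (nm), in kJ/mol; the default ``"hamaker"`` uses the
    sphere-sphere van der Waals attraction for the suspension's
    parameters (the repulsive term is zero for charge-neutral
    particles).  ``potential=None`` means zero interaction, which with
    ``with_hydro=False`` is the ideal-diffusion case, W = 1.

    The improper integral over h in (0, inf) is mapped onto y in (0, 1]
    through y = 2R/(h + 2R), which has unit Jacobian against the
    (h+2R)^-2 kernel: W = Int_0^1 B(h(y)) exp(V(h(y))/kBT) dy.  The
    substitution makes the zero-potential case exact and resolves both
    the contact region (where exp(V/kBT) -> 0 beats the B(h) divergence)
    and the far tail.
    """
    R = params.radius
    kbt = KB_KJ_MOL_K * params.T
    if potential == "hamaker":
        pot = lambda h: dlvo_attraction(h + 2.0 * R, R, params.hamaker)
    elif potential is None:
        pot = lambda h: 0.0
    else:
        pot = potential

    def integrand(y):
        if y <= 0.0 or y >= 1.0:
            return 1.0 if y <= 0.0 else 0.0
        h = 2.0 * R * (1.0 - y) / y
        if h <= 0.0:
            return 0.0
        log_val = pot(h) / kbt
        if with_hydro:
            x = h / R
            log_val += math.log(6.0 * x * x + 13.0 * x + 2.0) - math.log(
                6.0 * x * x + 4.0 * x
            )
        if log_val < -700.0:
            return 0.0
        return math.exp(log_val)

    val, err, info = quad(
        integrand, 0.0, 1.0, epsabs=1e-12, epsrel=1e-11, limit=500, full_output=True
    )[:3]
    if not np.isfinite(val) or (err > 1e-6 * max(abs(val), 1.0)):
        raise RuntimeError(
            f"stability-ratio quadrature did not converge: W={val}, err={err}"
        )
    return StabilityResult(W=float(val), abs_error=float(err), n_evaluations=int(info["neval"]))


def aggregation_time(params: SuspensionParams, W: float) -> float:
    """Characteristic aggregation time tp = pi*mu*R^3*W/(kB*T*phi), in us."""
    if W <= 0:
        raise ValueError("W must be positive")
    R_m = params.radius * 1e-9
    tp_s = math.pi * params.mu * R_m**3 * W / (KB_J * params.T * params.phi)
    return tp_s * 1e6


def smoluchowski_N(t, tp: float):
    """Mean particles per aggregate under the linear growth law, 1 + t/tp."""
    if tp <= 0:
        raise ValueError("tp must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = 1.0 + t_arr / tp
    return float(out) if np.isscalar(t) else out


@njit(cache=True)
def _iterate_model(n2, n3, phi13, tp, dt, sample_times):  # pragma: no cover
    """Iterate N_i = N_{i-1} + dt/tp* and sample at given times (us)."""
    out = np.empty(sample_times.size)
    n_prev = 1.0
    t = 0.0
    j = 0
    while j < sample_times.size and sample_times[j] <= 0.0:
        out[j] = 1.0
        j += 1
    t_end = sample_times[-1]
    while t < t_end and j < sample_times.size:
        tp_star = math.exp(n2 * n_prev * phi13) * n3 * tp
        n_new = n_prev + dt / tp_star
        t_new = t + dt
        while j < sample_times.size and sample_times[j] <= t_new:
            # linear interpolation inside the step
            frac = (sample_times[j] - t) / dt
            out[j] = n_prev + frac * (n_new - n_prev)
            j += 1
        n_prev = n_new
        t = t_new
    while j < sample_times.size:
        out[j] = n_prev
        j += 1
    return out


def modified_trace(
    n2: float,
    n3: float,
    params: SuspensionParams,
    W: float,
    dt: float,
    t_end: float,
    n_frames: int = 200,
    n_total: float | None = None,
) -> KineticsTrace:
    """Mean-cluster-size trace predicted by the size-aware model.

    Iterates the discretized recursion from N_0 = 1 with step ``dt`` (us)
    up to ``t_end`` (us), sampling ``n_frames`` evenly spaced frames.
    Monotone non-decreasing; n2 = 0, n3 = 1 recovers the linear law up
    to O(dt) discretization error.
    """
    if not (0.0 <= n2 <= 1.0 and 0.0 < n3 <= 1.0):
        raise ValueError("require 0 <= n2 <= 1 and 0 < n3 <= 1")
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    tp = aggregation_time(params, W)
    if dt / (n3 * tp) > 1.0:
        warnings.warn(
            "dt too large: first-step growth exceeds one particle per aggregate",
            stacklevel=2,
        )
    times = np.linspace(0.0, t_end, n_frames + 1)
    mean_size = _iterate_model(n2, n3, params.phi ** (1.0 / 3.0), tp, dt, times)
    if n_total is None:
        from .synth import particles_for_phi

        n_total = float(particles_for_phi(params.phi, 100.0, params.radius))
    return KineticsTrace(
        times=times,
        n_clusters=n_total / mean_size,
        mean_size=mean_size,
        n_total=float(n_total),
    )


def fit_n1(trace: KineticsTrace, params: SuspensionParams, W: float) -> float:
    """Single-coefficient rescaling of tp: least squares for n1 in
    N(t) = 1 + t/(n1*tp).

    Linear in 1/n1, so the estimate is closed-form:
    1/n1 = tp * sum(t*(N-1)) / sum(t^2).
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 frames to fit n1")
    t = trace.times
    y = trace.mean_size - 1.0
    tp = aggregation_time(params, W)
    num = float(np.sum(t * y))
    den = float(np.sum(t * t))
    if num <= 0 or den <= 0:
        raise ValueError("degenerate flat trace: no growth to fit")
    return den / (num * tp)


def fit_n2_n3(
    trace: KineticsTrace,
    params: SuspensionParams,
    W: float,
    dt: float | None = None,
    min_aggregates: int = 5,
) -> ModifiedModelFit:
    """Fit (n2, n3) of the size-aware model to a kinetics trace.

    Frames with no more than ``min_aggregates`` clusters in the box are
    discarded before fitting (late, statistically thin frames).  The
    bounded least-squares problem on [0,1]^2 is solved from a
    deterministic 5x5 grid of starts with local refinement; the best
    local solution by cost is returned.
    """
    tp = aggregation_time(params, W)
    if dt is None:
        dt = tp / 1000.0
    mask = trace.n_clusters > min_aggregates
    t = trace.times[mask]
    y = trace.mean_size[mask]
    if t.size < 3:
        raise ValueError(
            f"only {t.size} frames have more than {min_aggregates} aggregates; "
            "need at least 3 to fit"
        )
    order = np.argsort(t)
    t, y = t[order], y[order]
    phi13 = params.phi ** (1.0 / 3.0)

    def residuals(theta):
        n2, n3 = theta
        model = _iterate_model(n2, max(n3, 1e-9), phi13, tp, dt, t)
        return model - y

    n2_starts = [0.0, 0.1, 0.3, 0.6, 1.0]
    n3_starts = [0.02, 0.1, 0.3, 0.6, 1.0]
    best = None
    for s2 in n2_starts:
        for s3 in n3_starts:
            sol = least_squares(
                residuals,
                x0=[s2, s3],
                bounds=([0.0, 1e-6], [1.0, 1.0]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
    n2_fit, n3_fit = best.x
    fit_rmse = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    return ModifiedModelFit(
        n2=float(n2_fit),
        n3=float(n3_fit),
        dt=dt,
        rmse=fit_rmse,
        n_frames_used=int(t.size),
        W=W,
        tp=tp,
    )


def rmse(model_trace: KineticsTrace, data_trace: KineticsTrace) -> float:
    """RMSE between two mean-size traces on the data trace's time grid.

    The model trace is linearly interpolated to the data times; only the
    overlapping time range contributes.
    """
    t_lo = max(model_trace.times.min(), data_trace.times.min())
    t_hi = min(model_trace.times.max(), data_trace.times.max())
    mask = (data_trace.times >= t_lo) & (data_trace.times <= t_hi)
    if not mask.any():
        raise ValueError("traces have no overlapping time range")
    model_on_data = np.interp(
        data_trace.times[mask], model_trace.times, model_trace.mean_size
    )
    return float(np.sqrt(np.mean((model_on_data - data_trace.mean_size[mask]) ** 2)))
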