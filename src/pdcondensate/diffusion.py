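"""Multi-mode diffusion decomposition from radial displacement distributions.

The mean-square displacement averages over coexisting protein populations,
so a condensate with several dynamical environments is analyzed instead
through the distribution of radial single-particle displacements at lag t,
modeled as a population-weighted sum of 3-D Gaussian propagators:

    P(r, t) = sum_i  p_i * 4 pi r^2 / (4 pi D_i t)^(3/2) * exp(-r^2 / 4 D_i t)

with sum_i p_i = 1.  Each mode i is one protein population with fraction
p_i and diffusivity D_i; for simple Brownian motion the fitted D_i are
independent of the lag time, so constancy across lags validates the
decomposition.  Units: r in Å, t in ns, D in Å^2/ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

from .forcefield import PROTEIN
from .units import FS_PER_NS

__all__ = [
    "DisplacementDistribution",
    "DiffusionModeFit",
    "displacement_distribution",
    "mixture_pdf",
    "mixture_cdf",
    "fit_diffusion_modes",
    "select_mode_count",
    "sample_displacements",
    "distribution_from_samples",
]


@dataclass
class DisplacementDistribution:
    """Binned radial displacement probability at one lag time."""

    lag: float                    # ns
    bin_edges: np.ndarray         # Å
    probability: np.ndarray       # per-bin probability mass, sums to 1
    n_samples: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def density(self) -> np.ndarray:
        """Probability density (1/Å) at the bin centers."""
        return self.probability / np.diff(self.bin_edges)


@dataclass
class DiffusionModeFit:
    """Fitted mixture: fractions p (simplex), diffusivities D (descending)."""

    n_modes: int
    p: np.ndarray
    D: np.ndarray
    rms_residual: float
    per_lag_D: dict = field(default_factory=dict)   # lag -> D array
    per_lag_p: dict = field(default_factory=dict)
    converged: bool = True


def mixture_pdf(r, t: float, p, D):
    """Evaluate the propagator mixture density (1/Å) at radii ``r``."""
    p = np.asarray(p, dtype=float)
    D = np.asarray(D, dtype=float)
    if t <= 0:
        raise ValueError("lag time must be positive")
    if np.any(D <= 0):
        raise ValueError("diffusivities must be positive")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must lie on the simplex")
    r = np.asarray(r, dtype=float)
    four_dt = 4.0 * D * t
    comp = (4.0 * np.pi * r[..., None] ** 2 /
            (np.pi * four_dt) ** 1.5 *
            np.exp(-r[..., None] ** 2 / four_dt))
    out = comp @ p
    return out if out.ndim else float(out)


def mixture_cdf(r, t: float, p, D):
    """Cumulative radial propagator mixture P(|dr| <= r) at lag t.

    Closed form per component: erf(x) - (2/sqrt(pi)) x exp(-x^2) with
    x = r / sqrt(4 D t).  Used to fit per-bin probability *mass* exactly,
    which makes the fit independent of bin width even when a slow mode is
    narrower than one bin.
    """
    p = np.asarray(p, dtype=float)
    D = np.asarray(D, dtype=float)
    r = np.asarray(r, dtype=float)
    x = r[..., None] / np.sqrt(4.0 * D * t)
    comp = erf(x) - (2.0 / np.sqrt(np.pi)) * x * np.exp(-x * x)
    out = comp @ p
    return out if out.ndim else float(out)


def displacement_distribution(traj, lag: float, species: str = PROTEIN,
                              n_bins: int = 300,
                              r_max: float | None = None) -> DisplacementDistribution:
    """Histogram of unwrapped radial displacements at one lag time.

    All beads of the requested species and all frame pairs separated by
    ``lag`` (overlapping time origins) contribute.  ``lag`` is in ns and
    must be an integer multiple of the frame interval.
    """
    times = traj.times_fs
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    dt_frame = times[1] - times[0]
    lag_fs = lag * FS_PER_NS
    n_shift = lag_fs / dt_frame
    if abs(n_shift - round(n_shift)) > 1e-6 or round(n_shift) < 1:
        raise ValueError(
            f"lag {lag} ns is not a positive multiple of the frame "
            f"interval {dt_frame / FS_PER_NS} ns"
        )
    n_shift = int(round(n_shift))
    if n_shift >= traj.n_frames:
        raise ValueError("lag exceeds the trajectory span")
    unwrapped = traj.unwrapped()[:, np.asarray(traj.species) == species]
    disp = unwrapped[n_shift:] - unwrapped[:-n_shift]
    r = np.sqrt(np.einsum("fij,fij->fi", disp, disp)).ravel()
    return distribution_from_samples(r, lag, n_bins, r_max)


def distribution_from_samples(r: np.ndarray, lag: float, n_bins: int = 300,
                              r_max: float | None = None) -> DisplacementDistribution:
    """Bin radial displacement samples into a unit-mass distribution."""
    r = np.asarray(r, dtype=float)
    if r_max is None:
        r_max = float(r.max()) * 1.02 + 1e-12
    counts, edges = np.histogram(r, bins=n_bins, range=(0.0, r_max))
    prob = counts / counts.sum()
    return DisplacementDistribution(lag=float(lag), bin_edges=edges,
                                    probability=prob, n_samples=len(r))


def _softmax(a: np.ndarray) -> np.ndarray:
    e = np.exp(a - a.max())
    return e / e.sum()


def _fit_single_lag(dist: DisplacementDistribution, n: int,
                    weight_floor: float = 1e-2) -> tuple:
    """Weighted LSQ of the mixture against one binned distribution.

    The model predicts the probability *mass* in each bin through the
    closed-form radial CDF, so the fit carries no bin-center
    discretization bias.  Optimizes over (log10 D_i, softmax logits of
    p); ten deterministic starts with log-spaced diffusivity ladders
    spanning the r^2/4t range of the data.  Returns (p, D, rms residual
    of the probability mass).
    """
    r = dist.centers
    target = dist.probability
    t = dist.lag
    edges = dist.bin_edges
    nz = target > 0
    # characteristic D range from the data support
    r_lo = max(np.min(r[nz]) if np.any(nz) else r[1], dist.bin_width)
    r_hi = np.max(r[nz]) if np.any(nz) else r[-1]
    log_d_lo = np.log10(max(r_lo ** 2 / (6.0 * t), 1e-12))
    log_d_hi = np.log10(max(r_hi ** 2 / (6.0 * t), 1e-10))
    w = 1.0 / np.maximum(target, weight_floor * target.max())

    def residual(x):
        # exponent clip keeps the optimizer's exploratory steps finite
        D = 10.0 ** np.clip(x[:n], log_d_lo - 6.0, log_d_hi + 6.0)
        p = _softmax(x[n:]) if n > 1 else np.array([1.0])
        mass = np.diff(mixture_cdf(edges, t, p, D))
        return (mass - target) * w

    span = log_d_hi - log_d_lo
    starts = []
    for k in range(10):
        frac = k / 9.0
        lo = log_d_lo + 0.4 * frac * span
        hi = log_d_hi - 0.2 * (1.0 - frac) * span
        ladder = np.linspace(lo, hi, n) if n > 1 \
            else np.array([lo + 0.5 * (hi - lo)])
        logits = np.zeros(n) if n > 1 else np.zeros(0)
        starts.append(np.concatenate([ladder, logits]))
    best = None
    for x0 in starts:
        sol = least_squares(residual, x0, max_nfev=4000)
        if best is None or sol.cost < best.cost:
            best = sol
    D = 10.0 ** np.clip(best.x[:n], log_d_lo - 6.0, log_d_hi + 6.0)
    p = _softmax(best.x[n:]) if n > 1 else np.array([1.0])
    order = np.argsort(D)[::-1]
    D, p = D[order], p[order]
    model_mass = np.diff(mixture_cdf(dist.bin_edges, t, p, D))
    rms = float(np.sqrt(np.mean((model_mass - dist.probability) ** 2)))
    return p, D, rms


def fit_diffusion_modes(dists, n: int) -> DiffusionModeFit:
    """Fit the n-mode mixture to one or several per-lag distributions.

    Each lag is fitted independently; the reported (p, D) are the
    across-lag means and ``per_lag_D`` retains the per-lag values so that
    the Brownian plateau (constancy of D_i with lag) can be checked.
    """
    if n < 1:
        raise ValueError("need at least one mode")
    if isinstance(dists, DisplacementDistribution):
        dists = [dists]
    per_lag_D, per_lag_p, rms_all = {}, {}, []
    for dist in dists:
        if dist.n_samples == 0 or np.sum(dist.probability) == 0:
            raise ValueError("degenerate displacement distribution")
        p, D, rms = _fit_single_lag(dist, n)
        per_lag_D[dist.lag] = D
        per_lag_p[dist.lag] = p
        rms_all.append(rms)
    D_mean = np.mean(np.array(list(per_lag_D.values())), axis=0)
    p_mean = np.mean(np.array(list(per_lag_p.values())), axis=0)
    p_mean = p_mean / p_mean.sum()
    return DiffusionModeFit(n_modes=n, p=p_mean, D=D_mean,
                            rms_residual=float(np.mean(rms_all)),
                            per_lag_D=per_lag_D, per_lag_p=per_lag_p)


def select_mode_count(dists, n_max: int = 6,
                      improvement_threshold: float = 0.2,
                      p_min: float = 0.01) -> int:
    """Mode count at which adding further modes stops paying off.

    Fits are computed for n = 1 .. n_max in turn.  The selected count is
    the largest n whose refinement step (n-1 -> n) reduced the rms
    residual by at least ``improvement_threshold`` (relative); scanning
    stops outright at the first fit containing a component with
    population below ``p_min``, the signature of a superfluous mode.
    Judging each refinement step on its own (rather than stopping at the
    first insignificant one) keeps the selection robust when the residual
    gain sequence dips before the true mode count is reached.  The same n
    applies jointly across all lags.
    """
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    fits = [fit_diffusion_modes(dists, n) for n in range(1, n_max + 1)]
    selected = 1
    for n in range(2, n_max + 1):
        cur, prev = fits[n - 1], fits[n - 2]
        rel_gain = ((prev.rms_residual - cur.rms_residual) /
                    prev.rms_residual) if prev.rms_residual > 0 else 0.0
        if np.min(cur.p) < p_min:
            break
        if rel_gain >= improvement_threshold:
            selected = n
    return selected


def sample_displacements(p, D, t: float, n_samples: int,
                         seed: int = 0) -> np.ndarray:
    """Draw radial displacements from the known-truth mixture.

    Component i is chosen with probability p_i, then the displacement is
    the norm of a 3-D Gaussian step with per-axis variance 2 D_i t.
    Deterministic for a fixed seed.
    """
    p = np.asarray(p, dtype=float)
    D = np.asarray(D, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ValueError("fractions must lie on the simplex")
    if np.any(D <= 0) or t <= 0:
        raise ValueError("diffusivities and lag must be positive")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(p), size=n_samples, p=p)
    sigma = np.sqrt(2.0 * D[comp] * t)
    steps = rng.standard_normal((n_samples, 3)) * sigma[:, None]
    return np.linalg.norm(steps, axis=1)
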