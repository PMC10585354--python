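"""Hazards, drift/diffusion, the linear generator, and moment propagation.

Under mass action every hazard is linear in the state, so the drift
``mu(x) = V h(x; theta)`` can be rewritten as ``V_theta x`` with a constant
generator matrix ``V_theta``.  Between observation times the predictive mean
follows the linear ODE ``m' = V_theta m`` (solved exactly by the matrix
exponential) and the predictive covariance follows

    P' = V_theta P + P V_theta' + s * beta(m(t); theta),

with ``beta = V diag(h) V'`` the chemical-Langevin diffusion evaluated along
the mean path.  The scale ``s`` is either the current inter-observation
interval length (``diffusion_dt_scaling="paper"``, the default, stemming
from the local-linear discretisation of the master equation) or 1
(``"unit"``, the standard moment ODE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .network import RateParameters, ReactionSystem

logger = logging.getLogger(__name__)

DT_SCALINGS = ("paper", "unit")


class DivergenceError(FloatingPointError):
    """Raised when moment integration produces non-finite values."""


@dataclass
class MomentPair:
    """Gaussian belief: mean m (cells) and covariance P (cells^2)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        n = self.mean.shape[0]
        if self.cov.shape != (n, n):
            raise ValueError(f"cov shape {self.cov.shape} != ({n}, {n})")

    def copy(self) -> "MomentPair":
        return MomentPair(self.mean.copy(), self.cov.copy())


def hazard(x: np.ndarray, theta: RateParameters | np.ndarray,
           rs: ReactionSystem) -> np.ndarray:
    """Mass-action hazard vector h_k = x_{i(k)} * rate_k, in reaction order."""
    x = np.asarray(x, dtype=float)
    rates = theta.values if isinstance(theta, RateParameters) else np.asarray(theta)
    return x[rs.source_index] * rates[rs.rate_index]


def drift_diffusion(x: np.ndarray, theta: RateParameters | np.ndarray,
                    rs: ReactionSystem) -> tuple[np.ndarray, np.ndarray]:
    """Drift mu = V h and diffusion beta = V diag(h) V' at state x."""
    h = hazard(x, theta, rs)
    V = rs.net_effect_float
    mu = V @ h
    beta = (V * h) @ V.T
    return mu, beta


def linearize(theta: RateParameters | np.ndarray, rs: ReactionSystem) -> np.ndarray:
    """Constant generator V_theta with V_theta x = V h(x; theta) for all x."""
    rates = theta.values if isinstance(theta, RateParameters) else np.asarray(theta)
    n = rs.n
    A = np.zeros((n, n))
    V = rs.net_effect_matrix
    for k in range(rs.K):
        A[:, rs.source_index[k]] += V[:, k] * rates[rs.rate_index[k]]
    return A


def _diffusion_at_mean(m: np.ndarray, rates: np.ndarray,
                       rs: ReactionSystem) -> np.ndarray:
    # hazards at a Gaussian mean can go negative; floor them so beta stays PSD
    x = np.maximum(m, 0.0)
    if np.any(m < 0):
        logger.debug("negative mean coordinates floored for diffusion: %s", m)
    h = x[rs.source_index] * rates[rs.rate_index]
    V = rs.net_effect_float
    return (V * h) @ V.T


def propagate_moments_batch(means: np.ndarray, covs: np.ndarray,
                            theta: RateParameters | np.ndarray,
                            rs: ReactionSystem, dt: float, substeps: int = 32,
                            diffusion_dt_scaling: str = "paper",
                            expm_cache: dict | None = None,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Propagate many Gaussian beliefs over one interval in a single sweep.

    ``means`` is (C, n), ``covs`` is (C, n, n); all beliefs share the same
    rates and interval, as happens for the clones of one dataset.  The
    result is identical (same operations, broadcast) to propagating each
    belief separately — per-clone filter evaluations are independent, the
    batching is purely an execution layout.
    """
    if diffusion_dt_scaling not in DT_SCALINGS:
        raise ValueError(f"diffusion_dt_scaling must be one of {DT_SCALINGS}")
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    means = np.asarray(means, dtype=float)
    covs = np.asarray(covs, dtype=float)
    if dt == 0:
        return means.copy(), covs.copy()

    rates = theta.values if isinstance(theta, RateParameters) \
        else np.asarray(theta, dtype=float)
    A = linearize(rates, rs)
    scale = dt if diffusion_dt_scaling == "paper" else 1.0
    h_sub = dt / substeps
    # cache half-substep transition matrices for repeated interval lengths
    # (valid only within one fixed-theta sweep; callers own the dict)
    key = (dt, substeps)
    if expm_cache is not None and key in expm_cache:
        E_half = expm_cache[key]
    else:
        E_half = expm(A * (h_sub / 2.0))
        if expm_cache is not None:
            expm_cache[key] = E_half

    # mean path on the half-step grid: (2*substeps + 1, C, n)
    n_half = 2 * substeps
    mpath = np.empty((n_half + 1,) + means.shape)
    mpath[0] = means
    for j in range(n_half):
        mpath[j + 1] = mpath[j] @ E_half.T

    # diffusion along the mean path, hazards floored at nonnegative means
    V = rs.net_effect_float
    H = np.maximum(mpath, 0.0)[..., rs.source_index] * rates[rs.rate_index]
    Q = scale * np.einsum("jk,tck,lk->tcjl", V, H, V)

    # every RK4 stage preserves symmetry, so A P + P A' = M + M' with
    # M = A P — one matmul per stage
    def rhs(Pm, Qm):
        M = A @ Pm
        return M + M.transpose(0, 2, 1) + Qm

    P = covs.copy()
    for j in range(substeps):
        Q0, Qh, Q1 = Q[2 * j], Q[2 * j + 1], Q[2 * j + 2]
        k1 = rhs(P, Q0)
        k2 = rhs(P + (0.5 * h_sub) * k1, Qh)
        k3 = rhs(P + (0.5 * h_sub) * k2, Qh)
        k4 = rhs(P + h_sub * k3, Q1)
        P = P + (h_sub / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        P = 0.5 * (P + P.transpose(0, 2, 1))

    mean_out = mpath[-1]
    if not (np.all(np.isfinite(mean_out)) and np.all(np.isfinite(P))):
        raise DivergenceError(
            f"moment integration diverged (dt={dt}, theta={rates})")
    return mean_out, P


def propagate_moments(start: MomentPair, theta: RateParameters | np.ndarray,
                      rs: ReactionSystem, dt: float, substeps: int = 32,
                      diffusion_dt_scaling: str = "paper") -> MomentPair:
    """Advance a Gaussian belief over an inter-observation interval.

    The mean uses the exact linear solution ``expm(V_theta dt) m``; the
    covariance is integrated with fixed-step RK4 (``substeps`` steps), the
    mean path entering the diffusion term taken from the closed form.  The
    returned covariance is symmetrised.  ``dt = 0`` returns the input.
    """
    m, P = propagate_moments_batch(
        start.mean[None, :], start.cov[None, :, :], theta, rs, dt,
        substeps=substeps, diffusion_dt_scaling=diffusion_dt_scaling)
    return MomentPair(m[0], P[0])
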