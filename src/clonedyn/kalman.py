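"""Continuous-discrete extended Kalman filter and RTS smoother.

Per clone, the latent cell counts evolve continuously between the clone's
observation times (moment ODEs of :mod:`clonedyn.dynamics`) and are measured
at those times through a selection matrix ``G_k`` (one row per lineage
actually recaptured at that time) with noise covariance
``R_k = rho0 I + rho1 diag(G_k m*_k)`` evaluated at the predictive mean.
The filter produces the marginal log-likelihood of the measurements; the
fixed-interval smoother conditions every state on the whole record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .dynamics import (MomentPair, linearize, propagate_moments,
                       propagate_moments_batch)
from .network import RateParameters, ReactionSystem

logger = logging.getLogger(__name__)

_JITTERS = (0.0, 1e-9, 1e-6)
_LOG2PI = float(np.log(2.0 * np.pi))


class ConditioningError(np.linalg.LinAlgError):
    """Raised when a covariance cannot be factorised after jitter escalation."""


@dataclass(frozen=True)
class Prior:
    """Gaussian prior on the initial state of one clone."""

    m0: np.ndarray
    P0: np.ndarray


@dataclass
class GaussianBeliefSequence:
    """Predictive / filtered / smoothed moments of one clone's states."""

    times: np.ndarray
    pred_mean: list = field(default_factory=list)
    pred_cov: list = field(default_factory=list)
    filt_mean: list = field(default_factory=list)
    filt_cov: list = field(default_factory=list)
    innovation_mean: list = field(default_factory=list)   # mu_k (d_k,)
    innovation_cov: list = field(default_factory=list)    # S_k (d_k, d_k)
    gain: list = field(default_factory=list)              # K_k (n, d_k)
    smooth_mean: list = field(default_factory=list)
    smooth_cov: list = field(default_factory=list)
    loglik: float = 0.0

    @property
    def n_times(self) -> int:
        return len(self.times)


def _chol_with_jitter(S: np.ndarray, what: str, k: int | None = None):
    """Lower Cholesky factor with escalating jitter; returns (L, S_jittered).

    Jitter is scaled to the matrix's diagonal magnitude so that escalation
    remains meaningful for covariances far from unit scale.
    """
    d = np.abs(np.diagonal(S))
    scale = max(1.0, float(d.sum() / max(len(d), 1)))
    for jit in _JITTERS:
        Sj = S if jit == 0.0 else S + (jit * scale) * np.eye(S.shape[0])
        try:
            return np.linalg.cholesky(Sj), Sj
        except np.linalg.LinAlgError:
            continue
    where = f" at time index {k}" if k is not None else ""
    raise ConditioningError(f"{what} not positive definite after jitter "
                            f"escalation{where}")


def measurement_covariance(G: np.ndarray, pred_mean: np.ndarray,
                           rho: np.ndarray) -> np.ndarray:
    """R_k = rho0 I + rho1 diag(G m*), the mean floored at 0."""
    gm = np.maximum(G @ pred_mean, 0.0)
    return rho[0] * np.eye(G.shape[0]) + rho[1] * np.diag(gm)


def predict(prev: MomentPair, theta: RateParameters | np.ndarray,
            rs: ReactionSystem, dt: float, substeps: int = 32,
            diffusion_dt_scaling: str = "paper") -> MomentPair:
    """Prediction step: propagate the belief over the interval (m*_k, P*_k)."""
    return propagate_moments(prev, theta, rs, dt, substeps=substeps,
                             diffusion_dt_scaling=diffusion_dt_scaling)


def update(pred: MomentPair, y: np.ndarray, G: np.ndarray, rho: np.ndarray,
           time_index: int | None = None) -> tuple[MomentPair, float, dict]:
    """Gaussian correction step.

    Returns the filtered belief, the per-time log-likelihood increment
    ``log N(y_k; mu_k, S_k)``, and a dict with the innovation moments and
    gain.  An empty ``G`` (nothing recaptured at this time) is a vacuous
    update: filtered = predicted, increment 0.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    d = G.shape[0]
    if d == 0:
        n = pred.mean.shape[0]
        return pred.copy(), 0.0, {
            "innovation_mean": np.zeros(0), "innovation_cov": np.zeros((0, 0)),
            "gain": np.zeros((n, 0))}

    mu = G @ pred.mean
    R = measurement_covariance(G, pred.mean, np.asarray(rho, dtype=float))
    S = G @ pred.cov @ G.T + R
    S = 0.5 * (S + S.T)
    L, Sj = _chol_with_jitter(S, "innovation covariance", time_index)

    PGt = pred.cov @ G.T
    resid = y - mu
    # one LAPACK solve for both the gain and the quadratic form
    sol = np.linalg.solve(Sj, np.concatenate([PGt.T, resid[:, None]], axis=1))
    K = sol[:, :-1].T                            # P* G' S^-1
    alpha = sol[:, -1]
    m = pred.mean + K @ resid
    P = pred.cov - K @ Sj @ K.T
    P = 0.5 * (P + P.T)

    logdet = 2.0 * float(np.sum(np.log(np.diagonal(L))))
    ll = -0.5 * (d * _LOG2PI + logdet + resid @ alpha)
    return MomentPair(m, P), float(ll), {
        "innovation_mean": mu, "innovation_cov": Sj, "gain": K}


@dataclass(frozen=True)
class CloneObservations:
    """One clone's measurement record: times, and per time (G_k, y_k)."""

    clone_id: str
    times: np.ndarray                 # strictly increasing
    G: tuple[np.ndarray, ...]         # (d_k, n) selection matrices
    y: tuple[np.ndarray, ...]         # (d_k,) measured counts

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError(f"observation times of clone {self.clone_id} "
                             f"must be strictly increasing")


def filter_clone(obs: CloneObservations, prior: Prior,
                 theta: RateParameters | np.ndarray, rho: np.ndarray,
                 rs: ReactionSystem, *, t0: float | None = None,
                 substeps: int = 32, diffusion_dt_scaling: str = "paper",
                 ) -> GaussianBeliefSequence:
    """Forward pass: alternate predict/update along one clone's record.

    The prior is anchored at ``t0`` (default: the clone's first observation
    time, making the first prediction interval vanish).  Returns the belief
    sequence with the clone's marginal log-likelihood.
    """
    times = np.asarray(obs.times, dtype=float)
    beliefs = GaussianBeliefSequence(times=times)
    if len(times) == 0:
        return beliefs
    if t0 is None:
        t0 = float(times[0])

    current = MomentPair(prior.m0, prior.P0)
    t_prev = t0
    ll = 0.0
    cache: dict = {}
    for k, t in enumerate(times):
        dt = float(t - t_prev)
        pm, pc = propagate_moments_batch(
            current.mean[None], current.cov[None], theta, rs, dt,
            substeps=substeps, diffusion_dt_scaling=diffusion_dt_scaling,
            expm_cache=cache)
        pred = MomentPair(pm[0], pc[0])
        filt, inc, aux = update(pred, obs.y[k], obs.G[k], rho, time_index=k)
        beliefs.pred_mean.append(pred.mean)
        beliefs.pred_cov.append(pred.cov)
        beliefs.filt_mean.append(filt.mean)
        beliefs.filt_cov.append(filt.cov)
        beliefs.innovation_mean.append(aux["innovation_mean"])
        beliefs.innovation_cov.append(aux["innovation_cov"])
        beliefs.gain.append(aux["gain"])
        ll += inc
        current = filt
        t_prev = t
    beliefs.loglik = float(ll)
    return beliefs


def filter_clones_shared_grid(obs_list: Sequence[CloneObservations],
                              priors: Sequence[Prior],
                              theta: RateParameters | np.ndarray,
                              rho: np.ndarray, rs: ReactionSystem, *,
                              t0: float | None = None, substeps: int = 32,
                              diffusion_dt_scaling: str = "paper",
                              ) -> list[GaussianBeliefSequence]:
    """Filter several clones that share one observation-time grid.

    Per-clone filters are independent; this runs their prediction steps in
    one batched sweep per interval (identical arithmetic to
    :func:`filter_clone`, broadcast over clones) and the per-time
    corrections clone by clone.
    """
    times = np.asarray(obs_list[0].times, dtype=float)
    for o in obs_list[1:]:
        if not np.array_equal(o.times, times):
            raise ValueError("clones do not share an observation grid")
    C = len(obs_list)
    beliefs = [GaussianBeliefSequence(times=times) for _ in range(C)]
    if len(times) == 0:
        return beliefs
    lls = np.zeros(C)
    means = np.stack([np.asarray(p.m0, dtype=float) for p in priors])
    covs = np.stack([np.asarray(p.P0, dtype=float) for p in priors])
    t_prev = float(times[0]) if t0 is None else float(t0)
    cache: dict = {}
    rho = np.asarray(rho, dtype=float)
    # selection row indices per clone per time (G rows are unit vectors)
    sel = [[tuple(np.argmax(o.G[k], axis=1)) if o.G[k].shape[0] else ()
            for k in range(len(times))] for o in obs_list]
    for k, t in enumerate(times):
        dt = float(t - t_prev)
        pm, pc = propagate_moments_batch(
            means, covs, theta, rs, dt, substeps=substeps,
            diffusion_dt_scaling=diffusion_dt_scaling, expm_cache=cache)
        # group clones by selection-pattern size at this time and run one
        # vectorised correction per group (per-clone index gathers)
        groups: dict[int, list[int]] = {}
        for c in range(C):
            groups.setdefault(len(sel[c][k]), []).append(c)
        for d_k, members in groups.items():
            batch = None
            if d_k and len(members) > 1:
                batch = _update_batch(
                    pm[members], pc[members],
                    np.array([sel[c][k] for c in members]),
                    np.stack([obs_list[c].y[k] for c in members]), rho)
            if batch is not None:
                fm, fc, inc, mus, Ss, Ks = batch
                for i, c in enumerate(members):
                    b = beliefs[c]
                    b.pred_mean.append(pm[c])
                    b.pred_cov.append(pc[c])
                    b.filt_mean.append(fm[i])
                    b.filt_cov.append(fc[i])
                    b.innovation_mean.append(mus[i])
                    b.innovation_cov.append(Ss[i])
                    b.gain.append(Ks[i])
                    lls[c] += inc[i]
                    means[c] = fm[i]
                    covs[c] = fc[i]
            else:
                for c in members:
                    obs, b = obs_list[c], beliefs[c]
                    pred = MomentPair(pm[c], pc[c])
                    filt, inc1, aux = update(pred, obs.y[k], obs.G[k], rho,
                                             time_index=k)
                    b.pred_mean.append(pred.mean)
                    b.pred_cov.append(pred.cov)
                    b.filt_mean.append(filt.mean)
                    b.filt_cov.append(filt.cov)
                    b.innovation_mean.append(aux["innovation_mean"])
                    b.innovation_cov.append(aux["innovation_cov"])
                    b.gain.append(aux["gain"])
                    lls[c] += inc1
                    means[c] = filt.mean
                    covs[c] = filt.cov
        t_prev = t
    for c in range(C):
        beliefs[c].loglik = float(lls[c])
    return beliefs


def _update_batch(pm: np.ndarray, pc: np.ndarray, idx: np.ndarray,
                  ys: np.ndarray, rho: np.ndarray):
    """Vectorised correction for clones with equally sized selections.

    ``idx`` is (C, d): each clone's selected state coordinates (they may
    differ across clones).  Same arithmetic as :func:`update` broadcast
    over clones; returns None when any clone's innovation covariance needs
    jitter escalation (the caller then falls back to the sequential path,
    which escalates).
    """
    C, n = pm.shape
    idx = np.atleast_2d(idx)
    if idx.shape[0] == 1:
        idx = np.broadcast_to(idx, (C, idx.shape[1]))
    d = idx.shape[1]
    rows = np.arange(C)[:, None]
    mu = pm[rows, idx]                                     # (C, d)
    S = pc[np.arange(C)[:, None, None], idx[:, :, None], idx[:, None, :]].copy()
    di = np.arange(d)
    S[:, di, di] += rho[0] + rho[1] * np.maximum(mu, 0.0)
    S = 0.5 * (S + np.swapaxes(S, -1, -2))
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return None
    PGt = pc[np.arange(C)[:, None, None], np.arange(n)[None, :, None],
             idx[:, None, :]]                              # (C, n, d)
    resid = ys - mu
    rhs = np.concatenate([np.swapaxes(PGt, -1, -2), resid[:, :, None]],
                         axis=2)
    sol = np.linalg.solve(S, rhs)
    K = np.swapaxes(sol[:, :, :-1], -1, -2)                # (C, n, d)
    alpha = sol[:, :, -1]
    fm = pm + np.einsum("cnd,cd->cn", K, resid)
    fc = pc - K @ S @ np.swapaxes(K, -1, -2)
    fc = 0.5 * (fc + np.swapaxes(fc, -1, -2))
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=-2, axis2=-1)), axis=1)
    inc = -0.5 * (d * _LOG2PI + logdet + np.einsum("cd,cd->c", resid, alpha))
    return fm, fc, inc, mu, S, K


def smooth_clone(beliefs: GaussianBeliefSequence,
                 theta: RateParameters | np.ndarray, rs: ReactionSystem, *,
                 smoother_expm_dt: str = "interval") -> GaussianBeliefSequence:
    """Backward RTS pass; fills ``smooth_mean`` / ``smooth_cov`` in place.

    Gain ``B_{k+1} = P_k expm(V_theta' dt_{k+1}) (P*_{k+1})^{-1}`` with
    ``dt_{k+1}`` the interval length (``smoother_expm_dt="interval"``,
    dimensionally consistent with the prediction's transition matrix) or a
    unit exponent (``"unit"``, the literal backward-gain reading).
    """
    if smoother_expm_dt not in ("interval", "unit"):
        raise ValueError("smoother_expm_dt must be 'interval' or 'unit'")
    tau = beliefs.n_times
    if tau == 0:
        return beliefs
    A = linearize(theta, rs)
    sm = [None] * tau
    sc = [None] * tau
    sm[-1] = beliefs.filt_mean[-1].copy()
    sc[-1] = beliefs.filt_cov[-1].copy()
    times = beliefs.times
    for k in range(tau - 2, -1, -1):
        dt = float(times[k + 1] - times[k]) if smoother_expm_dt == "interval" else 1.0
        F = expm(A * dt)
        Pstar = beliefs.pred_cov[k + 1]
        _, Pj = _chol_with_jitter(Pstar, "predictive covariance", k + 1)
        # B = P_k F' (P*)^-1; with P_k symmetric, B' = (P*)^-1 F P_k
        B = np.linalg.solve(Pj, F @ beliefs.filt_cov[k]).T
        sm[k] = beliefs.filt_mean[k] + B @ (sm[k + 1] - beliefs.pred_mean[k + 1])
        Pk = beliefs.filt_cov[k] + B @ (sc[k + 1] - Pstar) @ B.T
        sc[k] = 0.5 * (Pk + Pk.T)
    beliefs.smooth_mean = sm
    beliefs.smooth_cov = sc
    return beliefs
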