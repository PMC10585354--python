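"""Shared fixtures: small networks, simulated datasets, oracle helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import clonedyn as cd
from clonedyn.simulate import MeasurementDesign, euler_maruyama, observe


@pytest.fixture
def two_node():
    """A -> B with duplication and death on both nodes (5 reactions)."""
    net = cd.DifferentiationNetwork(
        nodes=("A", "B"), observed=(True, True), branch=("none", "none"),
        ancestor=(None, "A"), edges=(("A", "B"),),
        dup=(True, True), death=(True, True))
    rs = cd.build_reaction_system(net)
    theta = cd.RateParameters.from_mapping(rs, {
        "alpha:A": 0.2, "delta:A": 0.1, "lambda:A->B": 0.3,
        "alpha:B": 0.4, "delta:B": 0.05})
    return net, rs, theta


@pytest.fixture
def single_death_node():
    """One lineage with pure death at rate 0.1 (exponential decay)."""
    net = cd.DifferentiationNetwork(
        nodes=("A",), observed=(True,), branch=("none",), ancestor=(None,),
        edges=(), dup=(False,), death=(True,))
    rs = cd.build_reaction_system(net)
    return net, rs, np.array([0.1])


def chain4_network() -> cd.DifferentiationNetwork:
    """Fully observed 4-node single-branch net HSC -> P1 -> {T, B}."""
    return cd.DifferentiationNetwork(
        nodes=("HSC", "P1", "T", "B"), observed=(True,) * 4,
        branch=("none", "none", "lymphoid", "lymphoid"),
        ancestor=(None, "HSC", "P1", "P1"),
        edges=(("HSC", "P1"), ("P1", "T"), ("P1", "B")),
        dup=(True,) * 4, death=(True,) * 4)


CHAIN4_TRUTH = {
    "alpha:HSC": 0.2, "alpha:P1": 0.25, "alpha:T": 0.3, "alpha:B": 0.2,
    "delta:HSC": 0.1, "delta:P1": 0.1, "delta:T": 0.15, "delta:B": 0.1,
    "lambda:HSC->P1": 0.4, "lambda:P1->T": 0.3, "lambda:P1->B": 0.25,
}


def simulate_dataset(net: cd.DifferentiationNetwork, truth: dict,
                     n_clones: int = 20, seed: int = 7, zeta: float = 0.0,
                     rho: tuple[float, float] = (0.1, 0.01), tau: int = 10,
                     t_max: float = 10.0, x0_mass: float = 100.0,
                     ) -> cd.ClonalTrackingDataset:
    """Euler–Maruyama + measurement-model dataset from a given truth."""
    rs = cd.build_reaction_system(net)
    theta = cd.RateParameters.from_mapping(rs, truth)
    x0 = np.zeros(net.n)
    x0[0] = x0_mass
    t_grid = np.linspace(0.0, t_max, 1001)
    obs_t = np.linspace(t_max / tau, t_max, tau)
    design = MeasurementDesign(obs_t, net.observed_nodes(), zeta, rho)
    frames = []
    for c, child in enumerate(np.random.SeedSequence(seed).spawn(n_clones)):
        traj_seq, obs_seq = child.spawn(2)
        traj = euler_maruyama(rs, theta, x0, t_grid,
                              np.random.default_rng(traj_seq),
                              clone_id=f"c{c:03d}")
        frames.append(observe(traj, design, obs_seq, net))
    return cd.ClonalTrackingDataset(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# independent textbook oracles (discrete Kalman filter / RTS smoother)

def discrete_kf(ms0, P0, F_list, Q_list, obs, R_fn):
    """Textbook discrete-time Kalman filter.

    ``F_list[k]``/``Q_list[k]`` move the state from step k-1 to k; ``obs``
    is a list of (G, y) with possibly empty G; ``R_fn(G, m_pred)`` builds
    the measurement covariance.  Returns per-step dicts and the total
    log-likelihood.  Implemented directly from the standard recursions,
    independent of the package's filter.
    """
    m, P = np.asarray(ms0, float), np.asarray(P0, float)
    out, ll = [], 0.0
    for k, (G, y) in enumerate(obs):
        F, Q = F_list[k], Q_list[k]
        m_pred = F @ m
        P_pred = F @ P @ F.T + Q
        if G.shape[0] == 0:
            m, P = m_pred, P_pred
            out.append({"m_pred": m_pred, "P_pred": P_pred,
                        "m_filt": m, "P_filt": P})
            continue
        R = R_fn(G, m_pred)
        S = G @ P_pred @ G.T + R
        K = P_pred @ G.T @ np.linalg.inv(S)
        resid = y - G @ m_pred
        m = m_pred + K @ resid
        P = P_pred - K @ S @ K.T
        d = len(y)
        ll += -0.5 * (d * np.log(2 * np.pi) + np.linalg.slogdet(S)[1]
                      + resid @ np.linalg.solve(S, resid))
        out.append({"m_pred": m_pred, "P_pred": P_pred,
                    "m_filt": m, "P_filt": P})
    return out, ll


def discrete_rts(steps, F_list):
    """Textbook fixed-interval RTS smoother over discrete_kf output."""
    tau = len(steps)
    sm = [None] * tau
    sP = [None] * tau
    sm[-1] = steps[-1]["m_filt"]
    sP[-1] = steps[-1]["P_filt"]
    for k in range(tau - 2, -1, -1):
        F = F_list[k + 1]
        Pp = steps[k + 1]["P_pred"]
        C = steps[k]["P_filt"] @ F.T @ np.linalg.inv(Pp)
        sm[k] = steps[k]["m_filt"] + C @ (sm[k + 1] - steps[k + 1]["m_pred"])
        sP[k] = steps[k]["P_filt"] + C @ (sP[k + 1] - Pp) @ C.T
    return sm, sP


def lyapunov_quadrature(A, Q_of_t, dt, n_points=4001):
    """Brute-force quadrature of the linear covariance update over [0, dt].

    Computes ``int_0^dt e^{A(dt-s)} Q(s) e^{A'(dt-s)} ds`` on a fine Simpson
    grid — the independent oracle for the moment-ODE integrator.
    """
    from scipy.integrate import simpson
    from scipy.linalg import expm

    s = np.linspace(0.0, dt, n_points)
    vals = np.array([expm(A * (dt - si)) @ Q_of_t(si) @ expm(A.T * (dt - si))
                     for si in s])
    return simpson(vals, x=s, axis=0)
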