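"""Forward simulation of clonal dynamics and the measurement process.

Trajectories follow the chemical-Langevin Itô SDE

    dx = V h(x; theta) dt + (V diag(h) V')^{1/2} dW,

integrated with fixed-step Euler–Maruyama.  The measurement layer selects
the assay's measurable lineages at the sampling times, masks each entry
independently with the false-negative probability ``zeta`` (masked entries
become missing rows, never zeros), and adds Gaussian noise with variance
``rho0 + rho1 * x``.  Together these produce synthetic clonal tracking
datasets with the same statistical structure as barcoding / integration-site
studies: sparse recapture, count-scaled noise, hidden progenitors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .datasets import ClonalTrackingDataset
from .dynamics import drift_diffusion
from .network import (DifferentiationNetwork, RateParameters, ReactionSystem,
                      build_reaction_system)

logger = logging.getLogger(__name__)

SCENARIOS = ("fig2a", "fig2b", "fig2c", "fig2d",
             "fig3a", "fig3b", "fig3c", "fig3d")


class SimulationBlowUpError(FloatingPointError):
    """Raised when an SDE trajectory leaves the finite range."""


@dataclass(frozen=True)
class CloneTrajectory:
    """Fine-grid latent trajectory of one clone (states may be fractional)."""

    clone_id: str
    times: np.ndarray          # (T,), strictly increasing
    states: np.ndarray         # (T, n)

    def at(self, t: float) -> np.ndarray:
        """State at the fine-grid point nearest to t."""
        i = int(np.argmin(np.abs(self.times - t)))
        return self.states[i]

    def to_frame(self, net: DifferentiationNetwork) -> pd.DataFrame:
        """Wide table (one column per lineage, indexed by time)."""
        df = pd.DataFrame(self.states, columns=list(net.nodes))
        df.insert(0, "time", self.times)
        df.insert(0, "clone_id", self.clone_id)
        return df


@dataclass(frozen=True)
class MeasurementDesign:
    """Sampling times, measurable lineages, dropout and noise of an assay."""

    observation_times: np.ndarray
    observed_lineages: tuple[str, ...]
    dropout_fraction: float = 0.0            # zeta, false-negative probability
    rho: tuple[float, float] = (0.0, 0.0)    # (rho0, rho1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.rho[0] < 0 or self.rho[1] < 0:
            raise ValueError("noise parameters must be nonnegative")


def euler_maruyama(rs: ReactionSystem, theta: RateParameters | np.ndarray,
                   x0: np.ndarray, t_grid: np.ndarray, rng,
                   *, allow_negative_states: bool = False,
                   deterministic: bool = False,
                   clone_id: str = "clone") -> CloneTrajectory:
    """One Euler–Maruyama path of the chemical-Langevin SDE.

    Matrix square roots of the diffusion use a symmetric eigendecomposition
    with negative eigenvalues clipped at zero.  States are floored at zero
    after each step unless ``allow_negative_states`` (counts cannot go
    negative; the flag exists for pure filter-validation runs).
    """
    rng = np.random.default_rng(rng)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    x = np.asarray(x0, dtype=float).copy()
    if np.any(x < 0):
        raise ValueError("x0 must be nonnegative")
    states = np.empty((len(t_grid), rs.n))
    states[0] = x
    for s in range(len(t_grid) - 1):
        dt = t_grid[s + 1] - t_grid[s]
        mu, beta = drift_diffusion(np.maximum(x, 0.0), theta, rs)
        if deterministic:          # drift-only Euler limit
            x = x + mu * dt
        else:
            w, U = np.linalg.eigh(beta)
            root = U @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ U.T
            x = x + mu * dt + np.sqrt(dt) * (root @ rng.standard_normal(rs.n))
        if not allow_negative_states:
            x = np.maximum(x, 0.0)
        if not np.all(np.isfinite(x)):
            raise SimulationBlowUpError(f"trajectory blew up at step {s + 1}")
        states[s + 1] = x
    return CloneTrajectory(clone_id=clone_id, times=t_grid, states=states)


def euler_maruyama_ensemble(rs: ReactionSystem, theta: RateParameters | np.ndarray,
                            x0: np.ndarray, t_grid: np.ndarray, n_rep: int,
                            rng, *, allow_negative_states: bool = False,
                            ) -> np.ndarray:
    """Vectorised replicate paths; returns states of shape (n_rep, T, n).

    Same scheme as :func:`euler_maruyama` (batched eigendecomposition for
    the per-replicate diffusion square root), intended for Monte-Carlo
    moment checks.
    """
    rng = np.random.default_rng(rng)
    t_grid = np.asarray(t_grid, dtype=float)
    rates = theta.values if isinstance(theta, RateParameters) else np.asarray(theta)
    V = rs.net_effect_matrix.astype(float)
    x = np.broadcast_to(np.asarray(x0, dtype=float), (n_rep, rs.n)).copy()
    out = np.empty((n_rep, len(t_grid), rs.n))
    out[:, 0] = x
    for s in range(len(t_grid) - 1):
        dt = t_grid[s + 1] - t_grid[s]
        xpos = np.maximum(x, 0.0)
        h = xpos[:, rs.source_index] * rates[rs.rate_index]      # (R, K)
        mu = h @ V.T
        beta = np.einsum("jk,rk,lk->rjl", V, h, V)               # (R, n, n)
        w, U = np.linalg.eigh(beta)
        root = np.einsum("rij,rj,rkj->rik", U, np.sqrt(np.clip(w, 0.0, None)), U)
        z = rng.standard_normal((n_rep, rs.n))
        x = x + mu * dt + np.sqrt(dt) * np.einsum("rij,rj->ri", root, z)
        if not allow_negative_states:
            x = np.maximum(x, 0.0)
        out[:, s + 1] = x
    if not np.all(np.isfinite(out)):
        raise SimulationBlowUpError("ensemble simulation blew up")
    return out


def observe(traj: CloneTrajectory, design: MeasurementDesign, rng,
            net: DifferentiationNetwork, *, clip_negative: bool = True,
            ) -> pd.DataFrame:
    """Apply the measurement model to one trajectory.

    Returns long rows ``(clone_id, time, lineage, count)``; masked entries
    (probability ``zeta`` each, independently) are simply absent.  Noise is
    drawn for every measurable entry from a dedicated stream and applied
    only to surviving ones, so runs with the same seed but different
    ``zeta`` share the surviving entries' noise (common random numbers).
    """
    if isinstance(rng, np.random.Generator):
        mask_rng, noise_rng = rng.spawn(2)
    else:
        seq = rng if isinstance(rng, np.random.SeedSequence) \
            else np.random.SeedSequence(rng)
        mask_seq, noise_seq = seq.spawn(2)
        mask_rng = np.random.default_rng(mask_seq)
        noise_rng = np.random.default_rng(noise_seq)

    lineages = [x for x in net.nodes if x in design.observed_lineages]
    rho0, rho1 = design.rho
    records = []
    n_masked = 0
    for t in np.asarray(design.observation_times, dtype=float):
        x = traj.at(t)
        z = noise_rng.standard_normal(len(lineages))
        u = mask_rng.random(len(lineages))
        for j, lin in enumerate(lineages):
            if u[j] < design.dropout_fraction:
                n_masked += 1
                continue
            true = float(x[net.index(lin)])
            var = rho0 + rho1 * max(true, 0.0)
            if var > 0.0:
                var = max(var, rho0 + 1e-9)
                val = true + np.sqrt(var) * z[j]
            else:
                val = true
            if clip_negative:
                val = max(val, 0.0)
            records.append((traj.clone_id, float(t), lin, val))
    if not records:
        logger.warning("clone %s: all entries masked at all times "
                       "(empty measurement record)", traj.clone_id)
    return pd.DataFrame(records, columns=["clone_id", "time", "lineage", "count"])


# -- shipped topology fixtures and benchmark scenarios ----------------------

def load_network(name: str) -> DifferentiationNetwork:
    """Load a shipped topology fixture (``fig2a`` ... ``fig3d``) by name."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown network fixture {name!r}; "
                       f"choose from {SCENARIOS}")
    ref = resources.files("clonedyn") / "networks" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return DifferentiationNetwork.from_yaml(path)


def default_rates(net: DifferentiationNetwork, *, alpha: float = 0.2,
                  delta: float = 0.1, lam: float = 0.3) -> dict[str, float]:
    """Opinionated ground-truth rates for benchmark scenarios.

    Uniform duplication/death/differentiation rates in the realistic band
    (per unit time of the study clock); recorded in each scenario's
    ground-truth file rather than claimed to match any published table.
    """
    rates: dict[str, float] = {}
    for i, node in enumerate(net.nodes):
        if net.dup[i]:
            rates[f"alpha:{node}"] = alpha
        if net.death[i]:
            rates[f"delta:{node}"] = delta
    for src, dst in net.edges:
        rates[f"lambda:{src}->{dst}"] = lam
    return rates


def _root_of(net: DifferentiationNetwork) -> str:
    roots = [x for x, a in zip(net.nodes, net.ancestor) if a is None]
    return roots[0] if roots else net.nodes[0]


def make_benchmark(scenario: str, n_clones: int = 3, *, seed: int = 0,
                   overrides: dict | None = None,
                   ) -> tuple[ClonalTrackingDataset, dict]:
    """Simulate a benchmark clonal tracking dataset from a shipped topology.

    Returns the dataset and a ground-truth record (generating rates, noise,
    initial state, hidden lineages, seed); fully reproducible from the seed.

    ``overrides`` may set: ``theta`` (name->rate), ``rho0``, ``rho1``,
    ``zeta``, ``tau`` (number of sampling times), ``t_max``, ``x0_mass``
    (initial root mass), ``n_grid`` (fine-grid steps), ``observed``
    (per-node observability override).
    """
    ov = dict(overrides or {})
    net = load_network(scenario)
    if "observed" in ov:
        net = net.with_observed(ov["observed"])
    rs = build_reaction_system(net)

    rates = default_rates(net)
    rates.update(ov.get("theta", {}))
    theta = RateParameters.from_mapping(rs, rates)
    rho = (float(ov.get("rho0", 0.1)), float(ov.get("rho1", 0.01)))
    zeta = float(ov.get("zeta", 0.0))
    tau = int(ov.get("tau", 10))
    t_max = float(ov.get("t_max", 10.0))
    x0_mass = float(ov.get("x0_mass", 100.0))
    n_grid = int(ov.get("n_grid", 1000))

    x0 = np.zeros(net.n)
    x0[net.index(_root_of(net))] = x0_mass
    t_grid = np.linspace(0.0, t_max, n_grid + 1)
    obs_times = np.linspace(t_max / tau, t_max, tau)
    design = MeasurementDesign(observation_times=obs_times,
                               observed_lineages=net.observed_nodes(),
                               dropout_fraction=zeta, rho=rho)

    root_seq = np.random.SeedSequence(seed)
    frames = []
    for c, child in enumerate(root_seq.spawn(n_clones)):
        traj_seq, obs_seq = child.spawn(2)
        traj = euler_maruyama(rs, theta, x0, t_grid,
                              np.random.default_rng(traj_seq),
                              clone_id=f"clone{c + 1:03d}")
        frames.append(observe(traj, design, obs_seq, net))
    frames = [f for f in frames if not f.empty]
    frame = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["clone_id", "time", "lineage", "count"])

    dataset = ClonalTrackingDataset(frame, metadata={
        "source": f"simulated:{scenario}", "seed": int(seed),
        "scenario": scenario})
    truth = {
        "scenario": scenario,
        "seed": int(seed),
        "theta": theta.as_dict(),
        "rho": list(rho),
        "zeta": zeta,
        "x0": {x: float(v) for x, v in zip(net.nodes, x0)},
        "observation_times": [float(t) for t in obs_times],
        "unobserved": [x for x in net.nodes if not net.is_observed(x)],
    }
    return dataset, truth


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
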