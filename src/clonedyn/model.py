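"""Maximum-marginal-likelihood fitting of differentiation networks.

The public surface follows the Model/Results convention: build a
:class:`CellDifferentiationModel` from a clonal tracking dataset and a
candidate topology, call :meth:`~CellDifferentiationModel.fit`, and read the
estimates, log-likelihood, AIC, smoothed states and summary table off the
returned :class:`CellDifferentiationResults`.

The parameter vector is ``psi = (theta_free, rho0, rho1)``: the free dynamic
rates (after the identifiability-constraint map) plus the two measurement
noise parameters.  The objective is the measurements' marginal
log-likelihood produced by the per-clone extended Kalman filters; it is
maximised by an iterated loop of filtering, bound-constrained quasi-Newton
steps on numerically differentiated gradients, and RTS smoothing for state
reconstruction and convergence monitoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import kalman
from .datasets import ClonalTrackingDataset, read_dataset
from .dynamics import DivergenceError, MomentPair
from .kalman import CloneObservations, ConditioningError, Prior
from .network import (ConstraintMap, DifferentiationNetwork, RateParameters,
                      ReactionSystem, build_constraint_map,
                      build_reaction_system, transition_probabilities)

logger = logging.getLogger(__name__)

_OBJECTIVE_SURROGATE = 1e12     # optimizer-safe stand-in for +inf
_LOWER_BOUND = 1e-8             # keeps hazards and R_k well defined


def numeric_gradient(objective: Callable[[np.ndarray], float],
                     psi: np.ndarray, *, f0: float | None = None,
                     ) -> np.ndarray:
    """Forward finite-difference gradient, one objective call per coordinate.

    Step ``h_i = max(1e-6, 1e-6 |psi_i|)``.  A non-finite (or surrogate)
    perturbed value triggers a one-sided retreat to ``h/10``.
    """
    psi = np.asarray(psi, dtype=float)
    if f0 is None:
        f0 = objective(psi)
    if not np.isfinite(f0) or f0 >= _OBJECTIVE_SURROGATE:
        raise ValueError("objective not finite at the expansion point")
    grad = np.empty_like(psi)
    for i in range(len(psi)):
        h = max(1e-6, 1e-6 * abs(psi[i]))
        pert = psi.copy()
        pert[i] += h
        fi = objective(pert)
        if not np.isfinite(fi) or fi >= _OBJECTIVE_SURROGATE:
            logger.warning("gradient coordinate %d: retreating step to h/10", i)
            h /= 10.0
            pert = psi.copy()
            pert[i] += h
            fi = objective(pert)
        grad[i] = (fi - f0) / h
    return grad


class CellDifferentiationModel:
    """State-space model of clonal cell differentiation.

    Parameters
    ----------
    dataset
        Long-format clonal tracking table (missing rows = unmeasured).
    network
        Candidate differentiation topology; its observability flags define
        which lineages the assay can measure at all.
    use_conservation, use_averaging
        Enable the identifiability constraints for rates that involve only
        unmeasured lineages (tree conservation sums / measured-sibling
        averages).
    substeps
        Fixed RK4 steps per inter-observation interval for the covariance
        moment ODE.
    diffusion_dt_scaling
        ``"paper"`` scales the diffusion term of the covariance ODE by the
        interval length; ``"unit"`` is the standard moment ODE.
    smoother_expm_dt
        ``"interval"`` (default) or ``"unit"`` exponent in the backward
        smoother gain.
    prior_root_mass
        Prior mean placed on an unmeasured root compartment; default: the
        clone's total count at its first observation, floored at 1.
    prior_var_scale
        Per-coordinate prior variance is ``max(m0, 1) * prior_var_scale``.
    priors
        Optional per-clone :class:`~clonedyn.kalman.Prior` overrides; clones
        not listed keep the default data-derived prior.
    """

    def __init__(self, dataset: ClonalTrackingDataset,
                 network: DifferentiationNetwork, *,
                 use_conservation: bool = True, use_averaging: bool = True,
                 substeps: int = 32, diffusion_dt_scaling: str = "paper",
                 smoother_expm_dt: str = "interval",
                 prior_root_mass: float | None = None,
                 prior_var_scale: float = 1.0,
                 priors: Mapping[str, Prior] | None = None):
        if dataset.n_records == 0:
            raise ValueError("dataset is empty")
        self.data = dataset
        self.network = network
        self.rs: ReactionSystem = build_reaction_system(network)
        self.cmap: ConstraintMap = build_constraint_map(
            network, use_conservation=use_conservation,
            use_averaging=use_averaging)
        self.substeps = int(substeps)
        self.diffusion_dt_scaling = diffusion_dt_scaling
        self.smoother_expm_dt = smoother_expm_dt
        self.prior_var_scale = float(prior_var_scale)
        self.prior_root_mass = prior_root_mass

        self.observations: dict[str, CloneObservations] = \
            dataset.observation_sequences(network)
        # all clones are filtered on the union of sampling times: a time at
        # which a clone has no record is a vacuous update (log-likelihood
        # contribution zero), so the likelihood is unchanged while the
        # prediction sweeps stay batched across clones
        union = np.array(sorted({float(t) for obs in self.observations.values()
                                 for t in obs.times}))
        self._union_times = union
        self._aligned: dict[str, CloneObservations] = {}
        empty_G = np.zeros((0, network.n))
        empty_y = np.zeros(0)
        for clone, obs in self.observations.items():
            lookup = {float(t): k for k, t in enumerate(obs.times)}
            Gs, ys = [], []
            for t in union:
                k = lookup.get(float(t))
                Gs.append(obs.G[k] if k is not None else empty_G)
                ys.append(obs.y[k] if k is not None else empty_y)
            self._aligned[clone] = CloneObservations(
                clone_id=clone, times=union, G=tuple(Gs), y=tuple(ys))
        self.priors: dict[str, Prior] = {
            clone: self._build_prior(obs)
            for clone, obs in self.observations.items()}
        if priors:
            for clone, p in priors.items():
                if clone not in self.priors:
                    raise ValueError(f"prior for unknown clone {clone!r}")
                self.priors[clone] = p
        self.param_names: tuple[str, ...] = \
            tuple(self.cmap.free_names) + ("rho0", "rho1")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_csv(cls, data_path, network: DifferentiationNetwork | str, *,
                 zeros_are_observations: bool = False, **kwargs
                 ) -> "CellDifferentiationModel":
        if isinstance(network, str):
            network = DifferentiationNetwork.from_yaml(network)
        ds = read_dataset(data_path,
                          zeros_are_observations=zeros_are_observations)
        return cls(ds, network, **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       network: DifferentiationNetwork, **kwargs
                       ) -> "CellDifferentiationModel":
        return cls(ClonalTrackingDataset(frame), network, **kwargs)

    # -- parameterisation -------------------------------------------------

    @property
    def k_free(self) -> int:
        """Free dynamic-rate dimension (after constraints)."""
        return self.cmap.p_free

    @property
    def k_params(self) -> int:
        """Total free parameter count p_M = p_free + 2 noise parameters."""
        return self.k_free + 2

    def split_psi(self, psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        psi = np.asarray(psi, dtype=float)
        if psi.shape != (self.k_params,):
            raise ValueError(f"psi has shape {psi.shape}, "
                             f"expected ({self.k_params},)")
        theta_full = self.cmap.expand(psi[:self.k_free])
        return theta_full, psi[self.k_free:]

    def _build_prior(self, obs: CloneObservations) -> Prior:
        """Data-derived per-clone prior.

        Mean: the clone's first-time observations for recaptured lineages;
        an assumed root mass for an unmeasured root; zero elsewhere.
        Variance: diagonal ``max(m0_i, 1) * c``, except that a lineage the
        assay measures but that is *missing* at the first sampling (a
        false negative) gets a diffuse prior with variance
        ``(total first counts)^2 * c``: its true count is unknown — not
        zero — so the prior must be weak enough for the first actual
        sighting to set the state rather than register as a shock.
        """
        net = self.network
        m0 = np.zeros(net.n)
        total_first = 0.0
        seen_first: set[int] = set()
        if obs.times.size:
            G, y = obs.G[0], obs.y[0]
            idx = np.argmax(G, axis=1)
            m0[idx] = y
            seen_first = set(int(i) for i in idx)
            total_first = float(np.sum(y))
        roots = [x for x, a in zip(net.nodes, net.ancestor) if a is None]
        for r in roots:
            i = net.index(r)
            if not net.observed[i]:
                m0[i] = (self.prior_root_mass if self.prior_root_mass is not None
                         else max(total_first, 1.0))
        var = np.maximum(m0, 1.0)
        clone_scale = max(total_first, 1.0)
        for i in range(net.n):
            if net.observed[i] and i not in seen_first:
                var[i] = clone_scale ** 2
        P0 = np.diag(var * self.prior_var_scale)
        return Prior(m0=m0, P0=P0)

    # -- likelihood -------------------------------------------------------

    def filter(self, psi: np.ndarray) -> dict[str, kalman.GaussianBeliefSequence]:
        """Run the EKF on every clone at psi; beliefs carry per-clone ll.

        All clones are filtered in one batched sweep over the union time
        grid; per clone the result equals a sequential filter on that grid.
        """
        theta_full, rho = self.split_psi(psi)
        clones = sorted(self._aligned)
        beliefs = kalman.filter_clones_shared_grid(
            [self._aligned[c] for c in clones],
            [self.priors[c] for c in clones], theta_full, rho, self.rs,
            substeps=self.substeps,
            diffusion_dt_scaling=self.diffusion_dt_scaling)
        return dict(zip(clones, beliefs))

    def smooth(self, psi: np.ndarray) -> dict[str, kalman.GaussianBeliefSequence]:
        theta_full, _ = self.split_psi(psi)
        beliefs = self.filter(psi)
        for b in beliefs.values():
            kalman.smooth_clone(b, theta_full, self.rs,
                                smoother_expm_dt=self.smoother_expm_dt)
        return beliefs

    def loglike(self, psi: np.ndarray) -> float:
        """Marginal log-likelihood of all measurements (clone-additive)."""
        return float(sum(b.loglik for b in self.filter(psi).values()))

    def nloglik(self, psi: np.ndarray) -> float:
        """Negative marginal log-likelihood with an optimizer-safe surrogate."""
        try:
            val = -self.loglike(psi)
        except (ConditioningError, DivergenceError) as exc:
            logger.warning("objective infeasible at psi (surrogate used): %s", exc)
            return _OBJECTIVE_SURROGATE
        if not np.isfinite(val):
            return _OBJECTIVE_SURROGATE
        return val

    def score(self, psi: np.ndarray) -> np.ndarray:
        """Numeric gradient of the log-likelihood (p + q filter passes)."""
        return -numeric_gradient(self.nloglik, np.asarray(psi, dtype=float))

    # -- fitting ----------------------------------------------------------

    def _series_roughness(self) -> float:
        """Sample variance of first differences of the observed series."""
        diffs = []
        for obs in self.observations.values():
            wide: dict[int, dict[float, float]] = {}
            for t, G, y in zip(obs.times, obs.G, obs.y):
                for row, val in zip(np.argmax(G, axis=1), y):
                    wide.setdefault(int(row), {})[float(t)] = float(val)
            for series in wide.values():
                vals = [series[t] for t in sorted(series)]
                diffs.extend(np.diff(vals))
        return float(np.var(diffs)) if len(diffs) > 1 else 0.0

    def _initial_psi(self, rng: np.random.Generator) -> np.ndarray:
        """Seeded random start: rates uniform in [0.1, 1]; rho0 log-uniform
        between the floor 0.1 and the series' first-difference variance.

        The series roughness bounds how much variability the noise model
        could at most absorb; drawing rho0 across that whole range (rather
        than starting every restart at the upper end) lets restarts explore
        both dynamics-dominated and noise-dominated basins.
        """
        theta0 = rng.uniform(0.1, 1.0, size=self.k_free)
        hi = max(self._series_roughness(), 0.1)
        rho0 = float(np.exp(rng.uniform(np.log(0.1), np.log(max(hi, 0.2)))))
        return np.concatenate([theta0, [rho0, 0.1]])

    def _optimize_once(self, psi0: np.ndarray, *, inner_maxiter: int,
                       max_outer: int, tol: float
                       ) -> tuple[np.ndarray, float, list[float], bool, int]:
        bounds = [(_LOWER_BOUND, None)] * self.k_params
        psi = np.maximum(np.asarray(psi0, dtype=float), _LOWER_BOUND)
        best_psi, best_ll = psi, -self.nloglik(psi)
        trace: list[float] = [best_ll]
        converged = False
        n_outer = 0
        for outer in range(max_outer):
            n_outer = outer + 1
            res = minimize(self.nloglik, psi, jac=lambda p: numeric_gradient(
                self.nloglik, p), method="L-BFGS-B", bounds=bounds,
                options={"maxiter": inner_maxiter})
            ll_new = -float(res.fun)
            if ll_new > best_ll:
                best_psi, best_ll = res.x.copy(), ll_new
            trace.append(best_ll)
            if abs(trace[-1] - trace[-2]) < tol * max(abs(trace[-1]), 1.0):
                converged = True
                break
            psi = best_psi
        return best_psi, best_ll, trace, converged, n_outer

    def fit(self, *, start: np.ndarray | None = None, restarts: int = 3,
            seed: int = 0, inner_maxiter: int = 150, max_outer: int = 50,
            tol: float = 1e-4) -> "CellDifferentiationResults":
        """Fit psi by iterated filtering / constrained quasi-Newton ascent.

        ``restarts`` independent seeded starting points are tried (the
        provided ``start``, if any, replaces the first); the best final
        log-likelihood wins.  The fit is deterministic given ``seed``.
        """
        rng = np.random.default_rng(seed)
        best = None
        for r in range(restarts):
            # an infeasible random start (diverging moments at the drawn
            # rates) is redrawn rather than forfeiting the restart
            for attempt in range(5):
                psi0 = self._initial_psi(rng)
                if start is not None and r == 0 and attempt == 0:
                    psi0 = np.asarray(start, dtype=float)
                if self.nloglik(psi0) < _OBJECTIVE_SURROGATE:
                    break
                logger.warning("restart %d: infeasible start, redrawing", r)
            try:
                psi, ll, trace, conv, n_outer = self._optimize_once(
                    psi0, inner_maxiter=inner_maxiter, max_outer=max_outer,
                    tol=tol)
            except ValueError as exc:
                logger.warning("restart %d failed: %s", r, exc)
                continue
            if best is None or ll > best[1]:
                best = (psi, ll, trace, conv, n_outer)
        if best is None:
            raise RuntimeError("no restart produced a finite objective")
        psi, ll, trace, conv, n_outer = best
        if not conv:
            logger.warning("fit did not converge in %d outer iterations; "
                           "best iterate returned", n_outer)
        smoothed = self.smooth(psi)
        return CellDifferentiationResults(
            model=self, params=psi, loglik=ll, trace=trace, converged=conv,
            n_iterations=n_outer, smoothed=smoothed, seed=int(seed))


@dataclass
class CellDifferentiationResults:
    """Fit outcome: estimates, likelihood, AIC, smoothed states."""

    model: CellDifferentiationModel
    params: np.ndarray                 # psi = (theta_free, rho0, rho1)
    loglik: float
    trace: list[float]
    converged: bool
    n_iterations: int
    smoothed: dict[str, kalman.GaussianBeliefSequence]
    seed: int

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.model.param_names

    @property
    def n_params(self) -> int:
        return self.model.k_params

    @property
    def aic(self) -> float:
        """Akaike information criterion 2 p_M - 2 l, p_M counting free
        coordinates plus the two noise parameters."""
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def theta_full(self) -> RateParameters:
        theta, _ = self.model.split_psi(self.params)
        return RateParameters(self.model.rs, theta)

    @property
    def rho(self) -> np.ndarray:
        _, rho = self.model.split_psi(self.params)
        return rho

    def transition_probabilities(self) -> pd.DataFrame:
        """Edge table (source, target, lambda, p_ij) at the estimate."""
        theta = self.theta_full
        probs = transition_probabilities(self.model.network, theta)
        rows = [(i, j, theta.lam(i, j), p) for (i, j), p in probs.items()]
        return pd.DataFrame(rows, columns=["source", "target", "lambda", "p_ij"])

    def smoothed_frame(self) -> pd.DataFrame:
        """Long table of smoothed state means and sds for every lineage."""
        rows = []
        nodes = self.model.network.nodes
        for clone in sorted(self.smoothed):
            b = self.smoothed[clone]
            for k, t in enumerate(b.times):
                sd = np.sqrt(np.maximum(np.diag(b.smooth_cov[k]), 0.0))
                for i, lin in enumerate(nodes):
                    rows.append((clone, float(t), lin,
                                 float(b.smooth_mean[k][i]), float(sd[i])))
        return pd.DataFrame(rows, columns=[
            "clone_id", "time", "lineage", "smoothed_mean", "smoothed_sd"])

    def summary(self) -> str:
        lines = [
            f"Cell differentiation network: {self.model.network.name}",
            f"  clones: {len(self.model.observations)}   "
            f"records: {self.model.data.n_records}",
            f"  log-likelihood: {self.loglik:.4f}   AIC: {self.aic:.4f}",
            f"  free parameters: {self.n_params} "
            f"(rates {self.model.k_free} + noise 2)",
            f"  converged: {self.converged} "
            f"in {self.n_iterations} outer iterations",
            "",
            f"  {'parameter':<24}{'estimate':>12}",
        ]
        for nm, v in zip(self.param_names, self.params):
            lines.append(f"  {nm:<24}{v:>12.5f}")
        theta = self.theta_full
        constrained = [nm for nm in theta.rs.rate_names
                       if nm not in self.param_names]
        if constrained:
            lines.append("")
            lines.append(f"  {'constrained rate':<24}{'implied':>12}")
            for nm in constrained:
                lines.append(f"  {nm:<24}{theta.rate(nm):>12.5f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        theta = self.theta_full
        return {
            "network": self.model.network.name,
            "psi_free": dict(zip(self.param_names, map(float, self.params))),
            "psi_full": {**theta.as_dict(),
                         "rho0": float(self.rho[0]), "rho1": float(self.rho[1])},
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
            "iterations": int(self.n_iterations),
            "seed": int(self.seed),
            "config": {
                "substeps": self.model.substeps,
                "diffusion_dt_scaling": self.model.diffusion_dt_scaling,
                "smoother_expm_dt": self.model.smoother_expm_dt,
            },
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def compare_models(dataset: ClonalTrackingDataset,
                   networks: Sequence[DifferentiationNetwork], *,
                   seed: int = 0, model_kwargs: Mapping | None = None,
                   **fit_kwargs
                   ) -> tuple[pd.DataFrame, dict[str, CellDifferentiationResults]]:
    """Fit each candidate topology and rank by AIC (ascending).

    Ties are broken by smaller parameter count, then declaration order.
    Noise parameters are refit per candidate.  A candidate that fails to
    fit is reported with infinite AIC and a diagnostic, never dropped.
    Returns the ranked table and the per-model results.
    """
    if len(networks) < 1:
        raise ValueError("at least one candidate network required")
    children = np.random.SeedSequence(seed).spawn(len(networks))
    rows = []
    results: dict[str, CellDifferentiationResults] = {}
    for order, (net, child) in enumerate(zip(networks, children)):
        model_seed = int(child.generate_state(1)[0] % (2 ** 31))
        label = net.name if net.name not in results else f"{net.name}#{order}"
        try:
            model = CellDifferentiationModel(dataset, net,
                                             **dict(model_kwargs or {}))
            res = model.fit(seed=model_seed, **fit_kwargs)
            results[label] = res
            rows.append((label, float(res.loglik), int(res.n_params),
                         float(res.aic), bool(res.converged), order, ""))
        except Exception as exc:     # report, never drop silently
            logger.error("model %s failed to fit: %s", net.name, exc)
            rows.append((label, float("nan"), -1, float("inf"), False,
                         order, f"{type(exc).__name__}: {exc}"))
    table = pd.DataFrame(rows, columns=[
        "model", "loglik", "n_params", "aic", "converged", "order",
        "diagnostic"])
    table = table.sort_values(["aic", "n_params", "order"],
                              kind="stable").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table, results


def neg_marginal_loglik(psi: np.ndarray, model: CellDifferentiationModel) -> float:
    """Functional alias for the model's negative marginal log-likelihood."""
    return model.nloglik(psi)
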