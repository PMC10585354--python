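# Methods

## The model

`clonedyn` treats the cells of one gene-marked clone as a population spread
over `n` compartments (lineages) of a differentiation network. Three
reaction kinds act on the state vector `x(t)` under mass action:

* duplication `x_i -> 2 x_i`, hazard `alpha_i x_i`, net effect `+1` on `i`;
* death `x_i -> 0`, hazard `delta_i x_i`, net effect `-1` on `i`;
* differentiation `x_i -> 2 x_j` along an edge `i -> j`, hazard
  `lambda_ij x_i`, net effect `-1` on `i` and `+2` on `j` (one parent cell
  commits into two daughters of the downstream compartment).

Collecting the net-effect vectors into the `n x K` matrix `V` and the
hazards into `h(x; theta)`, the chemical-Langevin (diffusion) approximation
of the underlying Markov jump process gives the Itô SDE

    dx = V h(x; theta) dt + (V diag(h) V')^{1/2} dW.

Because every hazard is linear in `x`, the drift is `V_theta x` for a
constant generator matrix `V_theta`, which makes the predictive mean ODE
exactly linear.

Measurements at times `t_1 < ... < t_tau` are

    y_k = G_k x_{t_k} + r_k,    r_k ~ N(0, rho0 I + rho1 diag(G_k x_{t_k})),

where `G_k` selects the lineages actually recaptured for that clone at that
time. A missing (clone, time, lineage) entry is a *false negative* — an
unmeasured state — never an observation of zero; zero rows read from input
files are dropped to missing under the default dialect.

## Filtering, smoothing, likelihood

Between observations the Gaussian belief `(m, P)` propagates through the
moment ODEs: the mean by the exact matrix-exponential solution, the
covariance by

    P' = V_theta P + P V_theta' + s * beta(m(t); theta),

integrated with fixed-step RK4 (default 32 substeps per interval, the mean
path entering `beta` taken from the closed form). At each observation time
the standard Gaussian correction applies, with `R_k` evaluated at the
predictive mean (the true state being unknown at update time; negative
means are floored at zero inside `R_k` and inside `beta`). The per-time
innovations `N(y_k; mu_k, S_k)` multiply into the marginal likelihood of
the clone; clones are independent, so the dataset log-likelihood is the sum
over clones. A fixed-interval RTS backward pass with gain
`B_{k+1} = P_k expm(V_theta' dt_{k+1}) (P*_{k+1})^{-1}` conditions every
state on the whole record.

Per-clone priors are data-derived: the mean takes the clone's
first-sampling observations for recaptured lineages, an assumed root mass
(default: the clone's total first-sampling count) for an unmeasured root,
and zero elsewhere; the variance is diagonal, `max(m0_i, 1) * c` with
`c = prior_var_scale` (default 1). One case needs care: a lineage the
assay *can* measure but that is missing at the clone's first sampling is a
false negative whose true count is unknown, not zero. Such coordinates get
a diffuse variance `(clone total)^2 * c`, weak enough that the first
actual sighting sets the state instead of registering as a shock —
without this, standardized innovations at entry run an order of magnitude
hot under heavy dropout and the maximum-likelihood fit escapes into an
inflated-turnover regime. All clones of a dataset are filtered on the
union of the dataset's sampling times (a time with no record for a clone
is a vacuous update contributing zero log-likelihood), with priors
anchored at the union's first time; this keeps the prediction sweeps
batched across clones regardless of how dropout fragments individual
records.

Two deliberately switchable conventions (both defaults documented, neither
claimed to be uniquely correct):

* `diffusion_dt_scaling`: the covariance ODE's diffusion term is scaled by
  the current inter-observation interval length (`"paper"`, the default,
  arising from the local-linear discretisation of the master equation) or
  by 1 (`"unit"`, the standard moment ODE). With unit sampling spacing the
  two coincide. The `"unit"` variant is the one that agrees exactly with a
  discrete-time Kalman filter whose process noise is the integrated
  diffusion, and is what the oracle-equivalence tests pin down.
* `smoother_expm_dt`: the backward gain's exponent uses the interval length
  (`"interval"`, default — dimensionally consistent with the forward
  transition matrix) or a unit exponent (`"unit"`).

## Identifiability constraints

Rates whose reactions touch only unmeasured lineages are not identifiable.
They are eliminated by a nonnegative linear map `theta_full = C theta_free`
built from two rules, applied leaf-to-root so that chains of hidden
compartments compose:

* **conservation**: a differentiation rate `a -> b` between hidden lineages
  where `b` itself differentiates equals the sum of `b`'s outgoing rates
  (cells flowing into a transit compartment are the cells flowing out);
* **averaging**: a hidden-to-hidden rate whose target is terminal equals the
  mean of the source's rates into its *measured* offspring; duplication and
  death rates of a hidden lineage equal the mean of the corresponding rates
  of measured lineages in a compatible branch that share its resolved
  ancestor.

"Resolved ancestor" is this package's reading of the ambiguous
same-ancestor condition: walk each lineage's ancestor chain upward and
compare the first measured-or-root compartment encountered. The literal
same-parent condition is unsatisfiable on the shipped haematopoietic
models once all progenitors are hidden (no measured lineage is a direct
sibling of a hidden progenitor), whereas the resolved-ancestor form makes
every shipped topology identifiable. The branch label `none` (the root and
shared multipotent compartments) is treated as compatible with both
branches when averaging sets are formed. An empty resolving set raises an
explicit unidentifiable-parameter error naming the coordinate.

AIC counts the *free* dimension, `p_M = p_free + 2` (the two noise
parameters): constrained coordinates are deterministic functions of free
ones and would be double-counted otherwise.

## Estimation

`psi = (theta_free, rho0, rho1)` is estimated by maximising the marginal
log-likelihood directly (the optimisation step targets the measurement
likelihood itself, not an expected complete-data surrogate; smoothing
serves state reconstruction and convergence monitoring). The loop
alternates: filter at the current `psi`; a bound-constrained L-BFGS-B run
(lower bound `1e-8`, forward-finite-difference gradients, one extra filter
pass per coordinate, step `max(1e-6, 1e-6 |psi_i|)` with a tenfold retreat
on a non-finite perturbation); an RTS pass. Outer iterations stop when the
log-likelihood changes by less than `1e-4 |l|` (default; at most 50 outer
rounds). Each inner run is allowed up to 150 quasi-Newton iterations:
short inner rounds would discard the accumulated curvature estimate at
every outer restart, which makes the optimiser crawl along the nearly
flat duplication/death ridge that heavy dropout induces and stall at
boundary-collapsed death rates well below the true optimum. Infeasible parameter points (a covariance that cannot be
factorised even after jitter) return a large finite surrogate so the line
search can retreat.

Starting points: free rates uniform in `[0.1, 1]`; `rho1 = 0.1`; `rho0`
drawn log-uniformly between `0.1` and the sample variance of first
differences of the observed series. That variance bounds how much
variability the noise model could at most absorb; always starting at the
upper end parks the optimiser in a noise-dominated local optimum
(`rho0` huge, dynamics ignored), so restarts explore the whole range.
Three independent restarts by default; the best final likelihood wins; the
whole fit is deterministic given its seed.

Numerical safeguards: every covariance factorisation uses Cholesky with
escalating jitter `1e-9 -> 1e-6` *relative to the matrix's diagonal
magnitude* (absolute jitter is inert when covariances sit at the scale of
squared cell counts); failure after escalation is an error, not a silent
pseudo-inverse. Covariances are symmetrised after every substep and update.

## Synthetic data

The simulator is the package's stand-in for barcoding / integration-site
studies: Euler–Maruyama paths of the SDE above (default fine grid of 1000
steps per horizon; states floored at zero, counts being nonnegative — a
flag disables the floor for pure filter-validation runs), observed at
`tau` sampling times through the measurement model, with each measurable
entry masked independently with probability `zeta` (false negatives) and
Gaussian noise of variance `rho0 + rho1 x` added to the survivors. Noise
is pre-drawn for every measurable entry from a stream separate from the
masking stream, so runs differing only in `zeta` share the surviving
entries' noise (common random numbers). Noisy counts are clipped at zero.

Shipped topologies: four candidate haematopoietic models (`fig2a`–`fig2d`:
single-branch via a common myeloid–lymphoid progenitor; the classical
dichotomic tree; the myeloid-based variant in which the common myeloid
progenitor also feeds NK cells; a three-branch variant with a dedicated NK
progenitor) and four in-silico validation networks (`fig3a`–`fig3d`).
`fig3a` is the single-branch chain HSC→P1→P2→{T,B,G}; `fig3d` is the
classical tree with every progenitor hidden and all mature lineages
measured. `fig3b`/`fig3c` are two- and cross-branch variants of
intermediate depth; they are structural stand-ins chosen by this package
(documented as such), since only the two endpoints of the in-silico suite
are pinned down by published text. Benchmark ground truth uses uniform
rates (duplication 0.2, death 0.1, differentiation 0.3 per unit time, the
realistic band for reconstitution dynamics on a months-scale clock),
initial mass 100 in the root, horizon 10 time units, `rho = (0.1, 0.01)`;
every scenario records its generating parameters in a ground-truth file.

What the generator does *not* emulate: read-level sequencing artefacts
(PCR amplification, barcode collisions), inter-sample depth differences
(the `rescale_by_sample` hook is the extension point), and non-Gaussian
heavy-tailed noise. Passing tests therefore demonstrate correct inference
under the model's own measurement assumptions, not robustness to every
artefact of real assays.

## Validation experiments and problem sizes

The experiment harness (also run by `scripts/acceptance.py`) uses these
sizes, chosen once as the package's desk-scale defaults:

* **Moment agreement**: 10 000 Euler–Maruyama replicates of the 2-node
  system on a 1000-step grid; empirical mean against `expm(V_theta t) x0`
  (3 Monte-Carlo SEs), empirical covariance against the unit-scaled moment
  ODE (10% relative).
* **Parameter recovery**: 20 clones from a fully observed 4-node
  single-branch tree, 10 sampling times, low noise; 3 restarts. Reported
  as estimate/truth ratios; repeated at 50% dropout with the wider
  tolerance expected under heavy masking.
* **Model selection**: 20 seeded replicates of 3 clones / 5 sampling times
  from the 4-node tree, compared by AIC against a structurally
  misspecified rewiring of the same lineages (a strictly sequential
  chain), mirroring the cross-topology misspecification design; fits use
  8 RK4 substeps and 3 restarts per candidate to keep each replicate at a
  few tens of seconds. A merely over-branched (nested) alternative differs
  by only ~2 AIC per extra parameter, below desk-scale optimizer noise;
  distinguishing nested near-equivalent topologies needs a larger
  optimization budget than this harness spends.
* **Constraint correctness**: a fit with hidden HSC/MPP whose full rate
  vector must satisfy the conservation/averaging identities to 1e-12
  (they hold by construction of `C`; the check guards the expansion path).

## Known limitations

* The Gaussian (first-two-moment) approximation degrades for very small
  counts and near-extinct clones; no higher-order closure is provided.
* Duplication and death rates are separately informed only through the
  diffusion term; with few clones and times their individual estimates are
  the least stable (their difference — net growth — is well determined).
* No standard errors or confidence intervals for the estimates; point
  estimates plus AIC only.
* Rates are constant in time; time-varying extensions are out of scope.
* The optimizer is a local quasi-Newton method with random restarts; on
  multimodal surfaces more restarts may be needed than the default three.
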