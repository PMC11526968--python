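# Methods

## Model

Each brain region is a Stuart–Landau oscillator — the normal form of a
supercritical Hopf bifurcation — with additive Gaussian noise. In Cartesian
coordinates `z_n = x_n + i y_n`:

    dx_n/dt = (a_n − x_n² − y_n²) x_n − ω_n y_n + Σ_p G_np (x_p − x_n) + β η_n
    dy_n/dt = (a_n − x_n² − y_n²) y_n + ω_n x_n + Σ_p G_np (y_p − y_n) + β η'_n

For `a_n < 0` the origin is a stable focus and the node produces noisy
damped oscillations; for `a_n > 0` a limit cycle of radius `√a_n`. Defaults:
`a_n = −0.02` (just below criticality), `β = 0.01`, `ω_n = 2π·0.05` rad/s
(configurable per node; `estimate_intrinsic_frequencies` recovers regional
peak frequencies from data). Coupling is diffusive through a possibly signed
matrix `G`; a negative `G_np` makes region p's excursions *suppress* region
n — a competitive interaction — using the identical functional form as
positive coupling. The x component sampled at the repetition time (TR) is
the BOLD proxy; no haemodynamic convolution is applied, following the usual
practice for this model class.

Note one typesetting subtlety in the source literature for the y-equation:
a literal reading would place `−ω x` in `dy/dt`, which is not a rotation; we
implement the standard Hopf rotation (`+ω x`).

### Integration

Euler–Maruyama with target step `dt = 0.1 s`; the actual step divides the TR
exactly (`dt_eff = TR / round(TR/dt)`, e.g. 0.103 s at TR 0.72 s) so samples
land on the TR grid. The Euler discretization of a rotation inflates the
effective growth rate by ≈ `ω²·dt`; at the defaults this bias is shared by
the empirical and simulated sides of the fitting loop and cancels, but
experiments that compare the stochastic integrator against the *exact*
linear theory use a slower frequency (0.01 Hz) or a finer step so the bias
is well below the comparison tolerance. The integration-accuracy regression
test couples runs at `dt` and `dt/2` through a common Brownian path (the
`noise` argument of `simulate`), isolating discretization error from
sampling noise.

### Linearized fast path

For subcritical, weakly coupled networks the stationary statistics follow
from the linearization at the origin: with `C = G − diag(G·1)` and the 2N×2N
Jacobian `J`, the zero-lag covariance solves the continuous Lyapunov
equation `JΣ + ΣJᵀ = −β²I`, and the lag-τ cross-covariance is
`Σ·exp(Jτ)ᵀ`. For a stationary linear Gaussian process the time-reversed
lagged correlation matrix is the transpose of the forward one, which gives
the reversal statistics in closed form. `linearized_covariance` raises when
the spectral abscissa of `J` is nonnegative — the signal that the coupling
has left the near-critical noisy regime the linearization describes.

## GEC estimation

`GECModel.fit` iterates: forward model → FC statistics → heuristic update

    G_np ← G_np + ε (FC^emp − FC^sim)_np − ε′ ([FCf−FCr]^emp − [FCf−FCr]^sim)_np

with `ε = 2·10⁻⁴`, `ε′ = 4·10⁻⁵`, lag 1 TR, updates restricted to the
nonzero support of the initial structural connectome. The cooperative-only
variant clamps entries at zero (clamped edges may later re-grow); the
competitive variant lets them cross. Two forward engines are provided: the
stochastic simulator (500 TR per iteration by default, freshly seeded
noise), and the deterministic linearized engine used throughout the
validation experiments — with `ε` this small, sign reversal of an edge takes
on the order of a thousand iterations, and the Lyapunov solve makes those
iterations cheap (~2 ms at N = 30) and exactly reproducible.

Convergence: stop when the running-best FC correlation has not improved by
more than `tol` for `patience` consecutive iterations (defaults 10⁻³ / 10,
with `max_iter` raised to a few thousand in the validation experiments to
accommodate the slow update). If the fit deteriorates persistently, or a
candidate GEC leaves the stable linear regime, the loop stops and returns
the best iterate with `converged=False` — the best-iterate rule means a
late excursion never degrades the reported model. Fitting is per subject;
group analyses average the FC statistics before fitting.

Stopping depth matters and is chosen per purpose. Iterating far past the
fit plateau fits FC estimation noise: in the recovery experiments the
weight correlation with the ground truth peaks near the plateau and then
decays while the fit correlation still creeps upward, so recovery uses the
default tolerance. The two-variant comparison instead fits to deep
convergence (`tol` 10⁻⁶, `patience` 100): it concerns the dynamics of fully
converged models, and its negative control runs at the same depth.

## Dynamical and computational metrics

* **Metastability** — SD over time of the Kuramoto order parameter
  `KOP_t = |Σ_k e^{iφ_k(t)}|/N`, phases from the analytic signal of the
  band-passed series. The first and last 5% of samples are trimmed against
  Hilbert edge effects. Population (divide-by-n) SD throughout.
* **Intrinsic-driven ignition** — events are upward crossings of `z > 1`
  per region; each driver event's breadth is the number of regions with an
  event inside a 4-TR window (all active regions co-occur pairwise, so the
  largest connected component of the co-occurrence matrix is the active set
  itself). Hierarchy = SD across regions of mean breadth; regions with no
  events are excluded from the SD; crossings inside an ongoing window start
  their own window (no refractoriness).
* **Temporal irreversibility** — forward vs time-reversed lagged
  correlations at 1 TR; each is mapped to Gaussian mutual information
  `FS = −½ log(1 − c²)` and the hierarchy is the SD of the off-diagonal
  squared differences `(FS_f − FS_r)²`. The squared-correlation convention
  keeps the log argument in (0, 1]; a printed form without the square can
  exceed 1. The per-region mean (send–receive view) and its SD are also
  returned; the element-wise SD is the headline.
* **ΦID persistent synergy** — Gaussian minimum-mutual-information
  integrated information decomposition per region pair at lag 1 TR: the
  double-redundancy of a pair of antichains is the minimum MI over all
  crossed past/future subsets, atoms follow by Möbius inversion over the
  product lattice, in nats. Two analytic properties worth knowing: atoms can
  be negative, and for two *independent self-coupled* AR(1) processes the
  persistent-synergy atom equals `2·min(self-MI)` rather than 0 — the known
  artifact of min-MI redundancy with a multivariate target. In the
  two-parameter coupled AR family (cross-coupling `a`, innovation
  correlation `c`, no self-coupling) synergy is exactly 0 at independence
  and grows monotonically with `a`. On oversampled band-limited BOLD the
  pair synergy therefore carries a large self-predictability baseline;
  comparisons between model variants are differences on top of it.
* **Cognitive matching** — per volume, the best positive spatial
  correlation between the activity pattern and a bank of canonical maps,
  floored at 0 when no map correlates positively; scan score = mean over
  volumes.
* **Differential identifiability** — `I_diff = ⟨A_ii⟩ − ⟨A_ij⟩` where
  `A_ij` is the upper-triangle correlation between simulated subject i and
  empirical subject j.
* **Memory capacity** — echo-state reservoir `x(t+1) = tanh(W_in u +
  W x(t))` wired by the fitted GEC, `W = α·W₀/ρ(W₀)` over
  `α ∈ {0.1,…,1.6}`; input gain 10⁻⁴ into half of the "visual" pool
  (drawn per repeat, 10 repeats), one ridge readout (α=0.5) per lag 1–20 on
  "somatomotor" states, 4050 input samples, 70:30 train/test split, 50-step
  washout; MC = Σ_τ |ρ(y, ŷ)| on test data, best α reported (ties to the
  smaller α). The zero matrix cannot be spectral-normalized and is used
  as-is (memoryless limit, MC = 0).
* **Graph statistics** — Newman spectral modularity (leading-eigenvector
  bipartition + Kernighan–Lin refinement, recursive via the generalized
  modularity matrix) and the binary clustering coefficient
  `C_i = 2t_i/(k_i(k_i−1))` (`C_i = 0` for degree < 2). Sign classes are
  profiled on |weights| (modularity assumes nonnegative weights); an
  asymmetric GEC is symmetrized by averaging first; edge lengths are
  Euclidean distances between region centroids.
* **Statistics** — paired comparisons use the sign-flip resampling t-test
  (two-sided via |t| exceedance, add-one rule, default 10⁴ draws) and
  Hedges' g with the small-sample correction `1 − 3/(4(2S−2)−1)`.

## Synthetic data: what it emulates and what it does not

`make_ground_truth` builds a signed connectome with the structural premises
the analyses rely on: dense strong positive couplings inside modules
(weights U(0.5, 1)), a sparse weak positive between-module remainder
(U(0.1, 0.3), 15% of positive edges), and negative couplings placed on the
longest cross-module pairs (top 40% of the distance distribution) at half
the positive scale, 30% of edges by default — inside the 25–40% envelope
reported for fitted competitive connectivity. Region coordinates are
module-clustered in a 100-mm box (or on a ring), so negative edges are
long-range by construction and the generator's own edge statistics
(negatives weaker, longer, less clustered) are testable downstream.

Because negative diffusive edges are self-exciting (they flip the sign of
the stabilizing row-sum term), the signed matrix is rescaled so the
linearized system's spectral abscissa sits at `a/2 = −0.01`: the network
stays in the near-critical noisy regime whatever its competitive content.
An all-positive ground truth (Laplacian coupling, unconditionally stable)
falls back to a max-weight of 0.2. Per-subject individuality is one knob:
multiplicative lognormal jitter (SD 0.1) on coupling magnitudes,
sign-preserving. Species-style presets set TR and band: human 0.72 s /
0.008–0.09 Hz (default), macaque 2.6 s / 0.008–0.09 Hz, mouse 1.0 s /
0.01–0.1 Hz; the default scan length is 1200 volumes.

What passing tests on these cohorts show: that the estimator recovers the
kind of signed, modular, long-range-competitive architecture it presumes,
at realistic noise and scan lengths. What they do not show: anything about
real BOLD — the generator has no haemodynamics, no physiological noise or
motion, no spatial autocorrelation beyond the module geometry, and its FC
distributions are not matched to any empirical dataset.

## Validation experiments (problem sizes)

`gecnet.experiments` fixes the desk-scale conditions shared by the test
suite and `scripts/acceptance.py`:

* limit-cycle radius: one node, `a = 0.04`, `dt = 5 ms`, 100 s of samples;
* stochastic-vs-linear FC: 10 nodes, 50 000 samples at TR 5 s, f = 0.01 Hz
  (sparse sampling keeps the finite-sample error of each correlation small:
  the amplitude correlation time is `1/|a|` = 50 s);
* sign recovery: 30 regions, 3 subjects, 2400 volumes each (~29-minute
  scans, comparable to the half-hour animal acquisitions that motivate the
  cohort design; at 1200 volumes the group FC estimate is noise-limited and
  recovery straddles its thresholds), group-averaged FC statistics,
  competitive fit with the linearized engine;
* direction suite: 10 subjects at 1200 volumes, both variants fitted per
  subject to deep convergence, dynamical metrics on 1200-volume forward
  simulations, sign-flip tests;
* negative control: five independent all-positive cohorts (5 subjects, 400
  volumes) fitted at the same depth — the sign constraint should cost
  nothing there;
* calibration checks for ΦID identities (1000 random correlation
  matrices), irreversibility against a 50-replicate i.i.d. null, the
  delay-line reservoir, the sign-flip test's type-I rate (500 replicates),
  and the Kuramoto closed forms.

## Known limitations

* The heuristic GEC update has no convergence guarantee; with the paper's
  `ε` it is slow, and the competitive variant can walk to the stability
  boundary of the linear regime (handled by best-iterate return).
* FC estimation at fMRI-like scan lengths is noise-limited for this model
  class (correlation time `1/|a|`); recovery statements are tied to the
  stated scan lengths.
* Under the synthetic conditions the competitive variant reproduces the
  expected fit, identifiability, metastability, irreversibility and
  memory-capacity effects, but not the ignition-hierarchy or mean-synergy
  directions: diffusely placed weak negative edges frustrate global
  synchrony without differentiating regional ignition capacity, and pair
  synergy at 1 TR is dominated by the self-predictability baseline. The
  corresponding checks are reported as measured.
* MMI-ΦID atoms can be negative and carry the artifact described above;
  they are reported in nats without correction.
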