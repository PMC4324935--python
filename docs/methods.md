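# Methods

This note documents the models, estimators and numerical choices behind
`nmmnet`, in enough detail to reproduce or audit any number the package
prints.

## Column model

A cortical macrocolumn is a three-population Jansen-Rit neural mass.  Two
transformations define the dynamics: (i) presynaptic pulse density →
postsynaptic potential (PSP), the linear filter with kernel
`h(t) = G k t e^{−kt}` for `t ≥ 0` (zero before), implemented in
state-space form as `y'' = G k p(t) − 2k y' − k² y`; (ii) net PSP → firing
rate, the sigmoid `S(m) = 2e₀/(1 + e^{r(ν₀−m)})`, bounded in `(0, 2e₀)`.
The six-dimensional column state is `(y0, y1, y2, v0, v1, v2)`: PSP input
to the interneurons, excitatory and inhibitory PSP input to the pyramidal
population, and their time derivatives.  The observable is `y1 − y2`.

Default constants (all adjustable through `ColumnParams`): `A = 3.25` mV,
`B = 22` mV, `a = 100` /s, `b = 50` /s, `C = 133.5` with
`C1..C4 = (1, 0.8, 0.25, 0.25)·C`, `e₀ = 2.5` /s, `r = 0.56` /mV,
`ν₀ = 6` mV.  The pyramidal population additionally receives a constant
pulse density `p̄ = 155` /s plus a periodic drive `δ sin(2πft + φ)`
(defaults `δ = 65` /s, `f = 8.5` Hz, `φ = 0`, identical for every node).
With `δ = 0` the column sits on a limit cycle near 10.8 Hz; with the
default drive it is chaotic.

The sigmoid exponent is clamped to ±500 so that arbitrarily extreme
transient PSPs (possible with random initial conditions) saturate instead
of overflowing.

## Network coupling

Columns sit on an undirected simple graph.  Node *i* receives
`p_α,i = α Σ_{j∈nbr(i)} S(y1ⱼ − y2ⱼ)/(NᵢNⱼ)` into its pyramidal
(excitatory) pathway and `p_β,i = β Σ_{j∈nbr(i)} S(C₃ y0ⱼ)/(NᵢNⱼ)` into
its inhibitory pathway, `Nᵢ` being the undirected degree.  Because each of
the `Nᵢ` terms is at most `2e₀/Nᵢ`, every node's coupling input is bounded
by `2e₀α` (resp. `2e₀β`) regardless of degree.  Isolated nodes receive
exactly zero (empty sum).  User-facing coupling values are the scaled
`α/C`, `β/C`.

Topologies: Barabási-Albert preferential attachment (`m0 = 1` grows a
hub-dominated tree), Watts-Strogatz rings with rewiring probability 0
(regular), 0.5 (small-world) or 1 (random), and custom two-column
edge-list files.  Generation is delegated to networkx and recorded with
algorithm, parameters and seed for provenance.

## Integration

Fixed step, `dt = 1 ms` throughout.  Two schemes, both second order:

* **Heun** (explicit trapezoidal predictor-corrector) for all
  attractor-statistics runs: 50 s total, first 25 s discarded.
* **Two-step Adams-Bashforth**, bootstrapped by one Heun step, for
  Lyapunov runs: 500 s total, first 100 s discarded.

Coupling sums are recomputed from the concurrent states of all nodes at
every stage evaluation (fully synchronous), so the decoupled limit
`α = β = 0` reproduces isolated-column trajectories *exactly* — a unit
test asserts bit-identity.  The hot loops are numba-compiled; the
pure-Python `heun_step`/`adams_bashforth_step` implement the identical
schemes and serve as reference paths in tests.  Stability: the fast rates
(`a = 100` /s) put the explicit schemes' limit near `dt ≈ 20 ms`; at 1 ms
halving the step moves attractor statistics by less than the across-seed
spread (tested).  A state is declared blown up when any component is
non-finite or exceeds 10¹⁰ mV — the saturating sigmoid otherwise keeps a
numerically unstable solution finite for a long time.

Initial conditions are uniform on `[0, 0.1]` for all six components of
every node.  The study source does not state its distribution; small
perturbations off rest converge to the attractor within the discarded
transient, and tests confirm the retained statistics are insensitive to
much wider ranges.

## Lyapunov spectra

The variational (tangent) system `Q' = J(y)Q` is co-integrated with the
state from an orthonormal `Q(0) = I`; the drive is additive, so the
Jacobian depends on the state only.  The analytic Jacobian has, per node,
`−2k` diagonal and `−k²` position entries in the velocity rows plus
sigmoid-derivative cross terms, and neighbor blocks scaled by `α/(NᵢNⱼ)`
and `βC₃/(NᵢNⱼ)`.  Every `reortho_every` steps (default 1) `Q` is
QR-factorized, `log|diag R|` accumulated, and the R-diagonal signs folded
into `Q`; exponents are the accumulated logs divided by the post-transient
time, reported in 1/s, largest first.  The state advances by
Adams-Bashforth; the tangent by a history-free trapezoidal update
`Q ← Q + dt/2 [J(yₙ)Q + J(yₙ₊₁)(Q + dt J(yₙ)Q)]`, chosen so that
re-orthonormalization never invalidates multistep history.  Results are
invariant to `reortho_every ∈ {1, 5, 10}` within tolerance (tested).

Cross-checks: (i) the exponent sum must equal the time-averaged Jacobian
trace, which for this model is the constant `−n(4a + 2b)` (−500 /s per
column) — satisfied within a fraction of a percent; (ii) an independent
Benettin two-trajectory estimator (Heun scheme, separation `d₀ = 10⁻⁹`
renormalized every 10 steps, no Jacobian) agrees with the QR MLE within
5% on seed averages at the chaotic operating point; (iii) the generic
pure-Python QR path reproduces the canonical Lorenz MLE ≈ 0.906.

Convergence: at 500 s the driven-column MLE is reproducible to ±0.04
across initial conditions.  Spectra of whole 50-node networks (a
6·N-dimensional tangent basis) are supported but not part of the standard
analyses, which use the regularity index instead at network scale.

## Regularity (Reg)

`Reg` is the height of the **second absolute peak of the autocorrelation
function**.  Operationally: the normalized autocorrelation ρ(τ) is
estimated with mean removal and the biased (divide-by-n) estimator, so
|ρ| ≤ 1 and ρ(0) = 1; peaks of |ρ| are ordered by lag, the unit peak at
lag 0 being the first; `Reg` is the height of the next local maximum of
|ρ| (the first one beyond the first local minimum of |ρ|).  A perfectly
periodic signal scores ≈ 1 (for a sinusoid the τ = T/2 lobe has |ρ| = 1),
white noise ≈ 0, and a constant signal is defined as 1.  Lags are
searched up to half the record by default.

Choosing the peak of |ρ| rather than of ρ matters: the two readings agree
for broadband noise and for strongly periodic signals, but differ for
chaotic oscillations whose anticorrelated half-period lobe exceeds the
first positive recurrence peak.  Only the |ρ| reading reproduces both
published reference values simultaneously (driven-column chaos point
0.37; 50-node network at α/C = 0.56, β/C = 0.26 ≈ 0.6); the
max-of-positive-ρ alternative gives 0.28 and 0.77 respectively.  Network
`Reg` averages the per-signal values over all nodes and all
initial-condition realizations.

## Cross-correlation, spectra, classification, EIS

* `C_max(τ)`: both series are standardized and the biased
  Pearson-normalized cross-correlogram maximized over |τ| ≤ 1 s (default);
  ties break toward the smallest |τ|.  The biased estimator tapers peak
  heights by `(n − |τ|)/n` and can shift a peak by one sample —
  irrelevant at the 25 s records used, but visible in short synthetic
  tests.  A positive lag means the second series is delayed.
* Welch PSD: 4 s Hann segments, 50% overlap (0.25 Hz resolution —
  separates the 8.5 Hz drive line from the ≈10.8 Hz intrinsic peak in a
  25 s record); the dominant frequency is the largest nonzero-frequency
  bin.
* E/I class: a node is *inhibitory* iff its time-averaged output
  `⟨y1 − y2⟩` is negative (zero counts as excitatory).
* `EIS = |CM_e A_e CM_i A_i|` over a node-activity sample: `CM_e`/`CM_i`
  are the means of the nonnegative/negative activities and `A_e`/`A_i`
  the node fractions on each side (`A_e + A_i = 1`); zero whenever either
  side is empty.  The index is computed from raw node values, not from a
  binned histogram, making it deterministic and bin-free.  It scales
  quadratically under uniform scaling of the activities and uses the same
  ≥ 0 convention as the node classifier.

## Wilson-Cowan pair

Two oscillators `x' = −x + S(ax − by + p) + K_exc(x_j − x_i)`,
`y' = −y + S(cx − dy + q) + K_inh(y_j − y_i)` with logistic `S` and gains
`a = 16, b = 12, c = 16, d = −2`.  `d = −2` is used exactly as printed in
the source parameterization even though it makes the `−dy` term
self-exciting; a `flip_d_sign` switch provides the conventional reading
for sensitivity checks (both segregate at the reference coupling).  The
four stimuli are `p₁ = −3.5, p₂ = −1.0, q₁ = −6.5, q₂ = −4.0`; the source
prints the `q₁` value with a duplicated `q₂` label, resolved here as `q₁`
since two `q₂` values are contradictory.  Integration: Heun at
`dt = 10⁻³` (dimensionless time), 200 time units with 100 discarded;
initial conditions uniform on [0, 1]⁴.  The pair is *segregated* when the
time averages `⟨x₁ − y₁⟩` and `⟨x₂ − y₂⟩` have opposite signs; the
segregation map stores the signed product (negative ⇒ segregated), which
also grades the separation magnitude.  Segregation requires asymmetric
stimuli: with `p₁ = p₂, q₁ = q₂` the synchronized manifold is
flow-invariant (tested) and both averages coincide.

## Experiments, seeding and problem sizes

Every pipeline is a pure function of its parameters and a master seed.
Per-task integer seeds derive from `numpy.random.SeedSequence(master)`
children indexed by a flat `(cell, realization)` counter, so any single
cell can be regenerated in isolation.  Full-design ensemble sizes (50
networks for the segregation/degree reports, 10 networks per EIS-map
cell, 20 initial conditions for the coupling sweep) are defaults; a
`scale_down` factor divides them uniformly.

The bundled acceptance runs use: 5 initial-condition seeds for
single-column statistics (500 s runs for exponents, 50 s for regularity),
one fixed 50-node scale-free architecture (generator seed 1) with 5
initial-condition seeds for the network regularity and pair-correlation
analyses, and 10-network ensembles for the segregation points.  The fixed
reference architecture mirrors the study design, which analyzes one
network and resamples only initial conditions; node-averaged regularity
varies by roughly ±0.07 across architecture realizations, which is the
dominant variance term and is *not* part of the single-network claim.

## Synthetic fixtures and what tests do (and do not) show

The test suite drives every estimator with closed-form or seeded
generators (sinusoids, white noise, AR(1), shifted copies, constants) and
hand-enumerable toy graphs (pair, star, ring, tree), so estimator
contracts are verified independently of the simulator.  These fixtures
emulate idealized stationary signals; they do not contain the
nonstationarity, 1/f background or measurement noise of real EEG/MEG
recordings, so passing tests validate the estimators and the model
implementation, not the model's fit to empirical data.  The package
deliberately contains no spiking-level detail, conduction delays, noise
terms, adaptive stepping, or parameter fitting.

## Known limitations

* Whole-network Lyapunov spectra scale as O((6N)³) per step and are
  impractical beyond a few tens of nodes; regularity is the intended
  network-scale irregularity measure.
* The regularity peak-picker assumes at least two full periods of the
  slowest rhythm in the record; signals shorter than that raise rather
  than return a value.
* The biased cross-correlogram slightly penalizes large lags; with the
  default ±1 s window on 25 s records the effect is < 4%.
* `m0 > 1` preferential-attachment graphs use the standard growth rule
  (every new node attaches exactly `m0` links), one of several readings
  of "up to m0 links"; the bundled analyses use `m0 = 1`, where the rules
  coincide.
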