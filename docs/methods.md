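# Methods

## Model

The estimator treats redundancy as a *constrained decoding* problem. Given
row-aligned observations of sources `X1, …, Xn` and a discrete target
`Y ∈ {0, …, K−1}`, one probabilistic decoder `fᵢ : Xᵢ → P(Y)` is fitted per
source, and the decoders' predicted distributions are required to agree:

```
L∩V  =  min_{f1..fn ∈ V}  (1/n) Σᵢ H_fᵢ(Y|Xᵢ)     s.t.  D(fᵢ, fⱼ) = 0  ∀ i<j
I∩V  =  H(Y) − L∩V
```

* `H_fᵢ(Y|Xᵢ)` — empirical cross-entropy of decoder `i` in bits,
  `mean(−log₂ fᵢ(y|x))` over held-out rows.
* `D(fᵢ,fⱼ) = E‖fᵢ(y|xᵢ) − fⱼ(y|xⱼ)‖₁` — expected L1 distance between the
  two predicted distributions, estimated over jointly observed rows (the
  same observation supplies `xᵢ` and `xⱼ`); ranges over `[0, 2]`.
* With one source the constraint set is vacuous and the quantity degenerates
  to the *usable information* `H(Y) − H_V(Y|X)` — the decoder-limited
  analogue of mutual information, which equals Shannon MI when `V` is
  unrestricted.

The constraint confines the decoders to information they can express
*identically*; a decoder that cannot see some distinguishing feature forces
its partners to discard that feature too. In the deterministic-decoder limit
the optimum coincides with the Gács–Körner common-variable redundancy
`I(Y;Q)`, where `Q` is the finest random variable that is a deterministic
function of every source — computed exactly in `redinfo.pmf` as connected
components of the support graph (vertices: supported source symbols; edges:
co-occurrence in a support point). Redundancy defined through stochastic
channels is larger on distributions like IMPERFECTRDN (0.99 bits vs 0), and
the trained estimator empirically tracks that stochastic value there; both
reference values ship with the benchmark suite.

## Optimisation

The constrained problem is relaxed to a Lagrangian
`(1/n) Σᵢ H_fᵢ + β Σ_{i<j} D(fᵢ,fⱼ)` minimised jointly over all decoder
weights by mini-batch gradient descent. Key choices:

* **Decoder family.** Fully-connected networks, ReLU or tanh hidden layers
  (default 2 × 64), softmax head over `K` classes. Gradients are analytic
  (numpy); Adam (default, lr 1e−3) or SGD, optional decoupled L2 weight
  decay. Convolutional decoders are declared in the family spec but not
  implemented.
* **Reverse β annealing.** β ramps linearly from `beta_start` (default 0) to
  `beta_final` over the first `ramp_fraction` (default 0.8) of training.
  Starting at the final β routinely collapses both decoders onto a constant
  prediction — the trivial solution that satisfies the constraint with zero
  information. The estimator warns (`ConstantPredictionWarning`) when a
  fitted decoder's per-class prediction variance over the evaluation set
  falls below 1e−6; note that for genuinely redundancy-free tasks the
  constant predictor *is* the correct optimum.
* **Penalty-gradient smoothing.** The L1 distance has a kink at agreement;
  a raw sign subgradient injects ±β gradient chatter exactly where training
  should settle, which measurably biases converged decoders. The training
  gradient therefore uses the pseudo-Huber form `d/√(d²+ε²)` with ε = 1e−3;
  every *reported* distance remains the exact L1.
* **Learning-rate decay.** Linear decay to 10 % of the base rate across
  training lets the coupled pair settle instead of orbiting the penalised
  optimum.
* **Units.** The Lagrangian is optimised on the bits scale (cross-entropy in
  log₂), so β weights the agreement penalty against bits of cross-entropy.
* **Numerical floors.** Predicted probabilities are clamped at 1e−12 before
  logs; a non-finite loss or gradient aborts the run with a `TrainingError`
  carrying the epoch/batch/β diagnostics.
* **Multi-source form.** For n > 2 sources the penalty is the sum of all
  pairwise L1 distances — symmetric, reduces to the two-source form, and
  drives all predictions together as β → ∞.

## Reporting

`H(Y)` is taken exactly from the generating distribution when it is known
(canonical tasks, overlap task) and otherwise plugged in from the pooled
train + evaluation label frequencies. Cross-entropies and the residual
distance are evaluated on held-out data of the same size as training (a
fresh draw for synthetic tasks): training-set evaluation rewards decoders
that overfit, which inflates the estimate. Training is repeated over
independent initialisations (default 5); the mean and sample standard
deviation are reported, negative per-run values included as-is (near-zero
redundancy plus evaluation noise legitimately produces small negative
numbers). A failed run is recorded and skipped; the aggregate errors only if
every run fails.

### Default study conditions

Canonical benchmarks (UNQ, AND, RDNXOR, IMPERFECTRDN): 10 000 train /
10 000 test samples, ReLU MLP 2 × 64, Adam lr 1e−3, 150 epochs, batch 256,
5 seeds, β_final 15 for the reference-table comparison (50 is the
general-purpose default elsewhere). At these sizes sampling error is well
below the 0.05-bit scale at which the reference values are compared. The
property suite and worked examples run at 4 000 samples / 100 epochs / 3
seeds, where each training run takes ~2 s on one CPU and the same
conclusions hold.

## Synthetic class-overlap task

The overlap generator emulates paired population recordings during an
8-class discrimination. Source 1 encodes the first `n` classes, source 2 the
last `n`, so `2n − 8` classes are encoded by both. Each source observes 10
class-selective informative units: unit `u` fires with mean 4 (unit-variance
Gaussian noise) when the source's *effective class* equals the unit's
assigned class, mean 0 otherwise, with 100 samples per class.

Two design points matter:

* **Aliasing of non-encoded classes.** A source's non-encoded classes are
  mapped onto encoded ones (`g_s(c)`) through a cyclic shift chosen so the
  co-occurrence graph of `(g₁(Y), g₂(Y))` links all non-overlap classes into
  a single block. Without aliasing, "is the class in my encoded set?" is
  itself decodable by each source, and at minimum overlap the two membership
  indicators are the *same* bit — a full bit of unintended redundancy. With
  it, the exact ground truth (available as `overlap_ground_truth_pmf`, via
  the common-variable oracle) runs 0, 1.06, 2.0, 2.75, 3.0 bits for
  n = 4…8.
* **Selectivity.** The mean-4 separation keeps per-source decoding near
  ceiling, as in motor-cortex population decoding where tens of units
  suffice to identify the reach target; redundancy is then governed by the
  class overlap rather than by decoder error. At weaker selectivity the
  estimate is capped by per-source decodability and the overlap trend
  degrades.

Per-source noise units (independent standard normal) and shared non-task
units (identical label-independent draws appended to both sources) are drawn
from dedicated substreams, so adding them leaves labels and informative
activations bitwise unchanged. The sweep contrasts the redundancy estimate
(insensitive to both manipulations by construction of the decoders) with the
mean row-wise cosine similarity between the paired observation vectors,
which decreases with noise units and increases with shared units. Sweep
training defaults to tanh decoders, β_final 50, 100 epochs, batch 64: tanh
avoids a co-memorisation failure mode where ReLU pairs satisfy the
constraint on the training set by jointly memorising it.

## What the synthetic generators do and do not show

The samplers draw i.i.d. observations from known distributions with exact
`H(Y)`; passing tests demonstrate that the estimator recovers known
redundancy values under matched train/test distributions. Real recordings
add non-stationarity, correlated noise across units, unknown `H(Y)`, and
train/test drift, none of which the generators emulate. Estimates on real
data inherit the usual caveats of decoder-based measures: they are lower
bounds relative to the decoder family, and they can overfit small samples.

## Known limitations

* Finite β biases the estimate slightly: the reported value sits where the
  cross-entropy gradient balances β times the agreement gradient, typically
  ~0.01 bits below the unconstrained value on a source paired with itself.
  Raising β tightens the constraint but amplifies the collapse risk.
* Small samples with high-capacity decoders can co-memorise: the pair
  satisfies the constraint on training rows while test cross-entropy
  exceeds `H(Y)`, driving the estimate negative. Held-out evaluation makes
  this visible rather than hiding it; tanh decoders and weight decay
  mitigate it.
* Discrete targets only; continuous-target (regression) decoder heads are
  out of scope.
* Exact oracles require explicit probability tables and are exponential in
  alphabet size only in the brute-force validation path; the
  connected-components oracle itself is linear in the support.
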