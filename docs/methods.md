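# Methods

## Model

A mutation catalogue is a matrix of non-negative integer counts X[k, j]
over samples k = 1..N_S and the 96 SBS channels j (six pyrimidine-centred
base substitution classes × 16 flanking contexts).  Given a fixed set of
signature profiles μ (each a probability distribution over the channels),
the additive reconstruction is X̃[k, j] = Σ_i a[k, i] μ[i, j] with
activities a ≥ 0.  The extended model multiplies this by one global
modulatory process — a profile r ∈ [−1, 1]^96 with per-sample activities
c[k] ≥ 0 — and observes Poisson counts:

    X[k, j] ~ Poisson( p[k, j] · X̃[k, j] ),   p[k, j] = 1 + c[k] r[j] ≥ 0.

Dropping the data-only log(X!) term, the log-likelihood is

    L = Σ_kj [ −p X̃ + X log(p X̃) ],

with analytic gradients

    ∂L/∂a[k, i] = Σ_j μ[i, j] ( X[k, j]/X̃[k, j] − p[k, j] ),
    ∂L/∂r[j]    = Σ_k c[k] ( X[k, j]/p[k, j] − X̃[k, j] ),
    ∂L/∂c[k]    = Σ_j r[j] ( X[k, j]/p[k, j] − X̃[k, j] ).

Because only the product c·r enters p, the likelihood is invariant under
r → r/α, c → αc (α > 0).  This gauge freedom is fixed by dividing r, and
multiplying c, by max|r|, so max|r| = 1 (an identically zero r forces
c = 0, where c is unidentified).  Dropped log(X!) makes absolute
likelihood values comparable only within one catalogue; every reported
*gain* (extended − additive) is unaffected.  The additive model is nested
(c = 0), so the maximized gain is never negative beyond optimizer
tolerance.

## Inference

Signatures are always treated as known.  `alternating_fit` runs:

1. an additive-only activity refit (per sample, a ≥ 0), which also
   provides the baseline likelihood for the gain;
2. up to `n_alternations` (default 3) rounds of: joint (r, c) fit with
   the additive part fixed, then an activity refit with the modulation
   fixed — each block warm-started from its current value, so the
   likelihood trace is non-decreasing (coordinate ascent); the loop
   stops early when a round improves the likelihood by less than
   `outer_tolerance` (1e-4).

Each per-sample activity problem is concave (the rate is linear in a),
so a single bound-constrained quasi-Newton run suffices; samples are
independent, and an all-zero sample gets a = 0 exactly.  Activities are
initialised by non-negative least squares on the pseudo-counted
catalogue.  The joint (r, c) block is not concave; the first attempt
starts from the centred, gauged mean multiplicative residual of the
current additive fit (with c = 0.5), and failed convergences are retried
from uniform random initial values up to `max_restarts` (100) times,
keeping the best likelihood.  The optimizer is any bound-constrained
quasi-Newton method with analytic gradients; L-BFGS-B is the default and
truncated Newton (TNC) is available via `FitConfig.optimizer`.  r and c
are re-gauged after every optimizer run.

Numerical choices:

- **Convergence** is declared when the optimizer reports success or the
  infinity norm of the projected gradient falls below
  `gradient_tolerance · max(1, √ΣX)` (default 1e-6 relative); gradient
  components of a Poisson likelihood scale like the square root of the
  counts, so the criterion is burden-invariant.
- **Feasibility boundary.**  Modulation factors are floored at
  `P_FLOOR = 1e-9` inside rates so logs stay finite where p → 0 with
  X = 0.  Since the floored likelihood is *flat* for p < 0 at zero-count
  cells, a quadratic penalty `X̃ · min(p, 0)²` (zero everywhere feasible)
  makes the infeasible region strictly unprofitable; a final exact
  projection caps each c at 1/|min r| so 1 + c·r ≥ 0 holds to machine
  precision.  Without the penalty, c drifts arbitrarily in flat
  directions at samples with empty depleted channels.
- **Unidentified channels.**  A channel carrying essentially no additive
  mass (ΣX̃ ≈ 0) and no observed counts genuinely prefers r = −1 at the
  MLE (predict nothing); r there is data-free and should not be
  over-interpreted.  Signature pools that cover all channels (any flat
  member suffices) avoid the issue; see the generator notes below.
- **Pseudo-counts** (default 1) are applied only where counts are
  divided or logged — multiplicative residuals and the NNLS warm start —
  never in the Poisson likelihood, where zeros are informative.
- `model_comparison` counts 96 + N_S extra parameters for the extension
  and uses the number of catalogue cells (N_S · 96) as the observation
  count in the BIC penalty.

## Residual diagnostics

Residuals of a fitted catalogue are X − X̃ (additive) and
(X + 1)/(X̃ + 1) (multiplicative).  Samples are compared by Pearson
correlation of their 96-channel residual profiles (Spearman available),
clustered by complete linkage on the distance 1 − correlation, and cut at
the distance corresponding to a correlation threshold of 0.75.  Flat
clusters with ≥ 10 samples are ranked by the entropy S = −Σ p_i log p_i
(natural log) of their cancer-type composition: S = 0 means one type.
Heat-map rendering conventionally clips correlations to [0, 1]; the
clustering itself always uses unclipped values.  The null control
resamples every count from a Poisson distribution with the observed count
as its rate: residuals of a model that matched every rate exactly show no
correlation structure beyond chance (< 1% of off-diagonal |ρ| > 0.5 in a
200-sample catalogue), which calibrates what "structure" means in the
real diagnostics.

## Synthetic-data generator and benchmark

`SimulationConfig` defines the study conditions; `run_benchmark`
simulates `n_datasets` independent datasets and fits each one.  Per
dataset: a pool of 10 signature profiles; per sample, 4 of the 10 active
with log-normal activities; one structured modulatory process r shared by
the dataset; c ~ U(0, 1) per sample; Poisson counts around
(1 + c·r)·(a@μ).  The structured r assigns all 16 channels of one base
class positive U(0, 1) values and all 16 of another negative ones, adds
N(0, sd 0.05) noise on all 96 channels, and is gauged to max|r| = 1
(feasibility 1 + c·r ≥ 0 then holds for c ∈ [0, 1] by construction; a
redraw guard covers other configurations).

Defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `n_datasets` × `n_samples` | 50 × 100 | benchmark scale |
| `n_signatures_pool` / `n_active_per_sample` | 10 / 4 | plausible per-cancer-type signature menu and per-sample sparsity |
| `activity_lognormal_mean`, `_scale` | 0, 1.5 | underlying-normal parameters of the activity distribution |
| `activity_burden_scale` | 100 | mutations per unit activity draw; mean sample burden ≈ 1.2 × 10³, median ≈ 1.3 × 10³ — the information regime in which recovery of c is accurate to MSE ≈ 0.02 while profile recovery stays imperfect; ~1000 emulates whole-genome burdens (~10⁴), where recovery saturates |
| `modulation_noise_sd` | 0.05 | off-class leakage of the injected process |
| `signature_concentration` | (0.05, 5.0) | per-signature symmetric-Dirichlet concentration, log-uniform: pools mix sharply peaked (α ≈ 0.05, a few dominant channels) and nearly flat (α ≈ 5, clock-like) profiles, so aggregate pool coverage leaves no channel empty — as with real SBS catalogues.  A single small α makes *every* profile sparse; such pools can leave whole channels unpopulated, where r is unidentifiable and recovered modulatory activities degrade sharply |

The generator emulates: peaked-and-flat signature shape diversity,
sparse per-sample signature usage, heavy-tailed burdens, a single
structured base-class-level modulatory process, and Poisson counting
noise.  It does **not** emulate: real COSMIC profile correlations and
flat-context structure (CpG effects, strand asymmetries), per-cancer-type
signature composition, hypermutator subpopulations, multiple concurrent
modulatory processes, or uncertainty in the signature set itself (μ is
known exactly to the fitter).  Passing benchmarks therefore demonstrate
correct and well-conditioned inference under the model's own assumptions;
they do not certify recovery when the signature set is misspecified, which
on real catalogues is the dominant extra error source.

Benchmark metrics, per dataset: cosine(r̂, r_true) of gauged profiles;
squared error of gauged ĉ against c (pooled over all samples for the
reported MSE); mean per-sample cosine between additive-only and
extended-model activity vectors.  The whole benchmark is a pure function
of its seed (per-dataset child seed streams), runs in well under a minute
on one CPU at the default scale, and is exercised at full scale by
`scripts/acceptance.py` and the acceptance test suite.

## Known limitations

- One modulatory process per fitted group; interacting or multiple
  concurrent processes are out of scope.
- Signatures are fixed inputs; no de-novo or joint (μ, r, c) inference.
- r in channels without additive mass is unidentified (see above); the
  gauge max|r| = 1 can then be carried by a data-free channel, which
  inflates inferred c.  Well-covered signature pools avoid this.
- The MSE of predicted counts is not guaranteed to decrease under the
  extended model (the fit maximizes likelihood, not MSE); on strongly
  structured modulation it does, and the report tables expose both.
- Reported log-likelihoods omit the log(X!) constant and are only
  comparable within one catalogue.
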