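# Methods

## Problem and data model

The package predicts the last measured blood glucose of a hospital stay
from (a) patient features — six age-decade flags over [18,30), [30,40),
[40,50), [50,60), [60,70), [70,∞), two gender flags, and the stay's peak
glucose — and (b) the identity of the stay's dominant care provider, i.e.
the provider with the most order rows for that admission (ties broken to
the lexicographically smallest identifier so the rule is deterministic).
Stays qualify for the cohort when their peak glucose is abnormal
(≥ 125 mg/dL). Glucose values are winsorized at 500 mg/dL and mapped
linearly onto [0, 1] via `(min(v, 500) − 125)/375`; last-measurement values
below 125 mg/dL clip to 0. All errors are RMSE on this unit scale
(1 unit = 375 mg/dL).

## Synthetic cohort generator

Real cohorts of this shape require credentialed access, so the generator
(`cdld.synthetic_data`) emulates the four consumed tables — patients,
admissions, labevents, provider orders — on top of a latent-factor process
whose ground truth is retained:

- Patient latents `u_i ~ N(0, I_d)` (default `d = 4`); the first coordinate
  is a severity trait. The stay's peak glucose is a deterministic monotone
  map of severity, `peak_norm = 0.25 + 0.75·Φ(u_i0)`, so the numeric
  feature genuinely carries the severity information.
- The patient contribution to the outcome blends an observable and a
  hidden coordinate, `s_p·(√f·u_i0 + √(1−f)·u_i1)`, where
  `f = feature_informativeness` (default 1.0: the observed features fully
  determine the patient side, which gives the zero-noise condition an exact
  learnable target) and `s_p = patient_effect_sd` (default 0.15 unit).
  Demographics add a small effect that is an exact step function of the age
  bucket and gender flag (±0.05, ±0.02), so one-hot inputs can represent it.
- Provider latents `v_j ~ N(0, I_d)` contribute `provider_effect_sd · v_j0`
  (default 0.10 unit).
- Noise-free outcome: `y* = clip(min(0.3 + patient + provider, peak_norm), 0, 1)`.
  The observed last reading adds Gaussian noise (`noise_sd`, default 0.05)
  before the same caps. Capping at the stay's own peak encodes that a last
  reading cannot exceed the stay maximum; without it, noisy outcomes above
  the intended peak would *become* the observed peak, leaking the target
  into a feature and making the mapping non-identifiable even without noise.
- Each stay gets 3–10 measurements at strictly increasing integer-minute
  timestamps; one non-final slot holds the peak, the final slot the last
  reading, fillers sit below the peak. The dominant provider receives
  strictly more order rows than up to two decoys, so most-frequent counting
  recovers the true assignment exactly.

Defaults emulate the study cohort: 5,001 stays from 2,551 patients
(~53.8 % male, ages ≈ N(63, 15.5) clipped to [18, 95]), 300 providers, every
stay abnormal (`frac_abnormal = 1.0`). The generator does **not** emulate
irregular measurement schedules, missing demographics, within-stay
treatment dynamics, provider teams (one dominant provider per stay), or any
correlation between provider quality and patient case mix. Passing tests
therefore show that the pipeline and training scheme behave correctly under
a faithful latent-factor world — not that the clinical effect sizes of any
real cohort are reproduced.

## Model and training

Patient discoverer: fully connected 9 → 64 → 32 → 32 (ReLU, linear output).
Provider discoverer: a 32-dimensional embedding row per provider plus one
fallback row for unseen codes, set to the mean trained row at each phase
end. Synthesis head: 64 → 64 → 1 on the concatenated latents with a sigmoid
output (targets live in [0, 1]); predictions are clipped to [0, 1] at
inference only, never inside the loss, where clipping would zero gradients
at the rails. Loss is batch-mean MSE under Adam, batch size 1,024; curve
metrics are recomputed over the full split at each epoch so logs are
comparable across batch sizes.

The cyclic schedule runs 10 iterations of (10 patient+head sub-epochs with
the provider table frozen, then 10 provider+head sub-epochs with the
patient network frozen), followed by 10 head-only synthesis epochs with
both discoverers frozen (a config flag switches to a freshly initialized
synthesis head instead of fine-tuning). Parameters are snapshotted at the
end of each phase so every phase can be evaluated on every split.

Two training choices deviate from the obvious defaults, for cause:

- **Learning rate 1e-4** (not Adam's canonical 1e-3). At 1e-3 over the
  210-pass budget the network memorises the nearly-unique continuous peak
  feature and the train/validation gap grows to roughly 2.5×, far beyond
  the mild gap this architecture exhibits otherwise; worse, the provider
  embeddings absorb per-provider observation noise, so the model *loses* to
  a patient-only baseline when provider effects are absent — the opposite
  of how a well-posed interaction model must degrade.
- **Embedding regularization.** Provider rows are zero-initialized (a
  random init hands the head a distinctive per-provider signature it can
  regress noise onto before the embedding ever trains) and carry a ridge
  penalty (0.1, weighted per active row to match the MSE normalization),
  the classical latent-factor remedy for entities with few observations —
  here ~13 training stays against 32 free coordinates per provider.

The patient-only baseline shares the architecture minus the provider path
and receives the identical total budget of gradient passes
(`epochs·sub_epochs·2 + epochs`), making the comparison an equal-compute
ablation of the provider side.

## Evaluation

RMSE is reported per phase and split on un-augmented rows only (augmented
copies exist solely in the training stream; a provenance index makes the
audit trivial). Latent recovery is the mean canonical correlation between
learned provider embeddings and true provider latents, computed by SVD
orthonormalization — appropriate because latent factors are identifiable
only up to invertible linear maps — and judged against a 200-draw
row-permutation null. Since the outcome carries only a one-dimensional
projection of each provider latent, perfect recovery of the full latent
space is impossible by construction; the meaningful claim is separation
from the permutation null. Multi-seed model comparisons use win counts
rather than significance tests, keeping the claim at the level the single
error metric supports.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng`; stage seeds are
  derived by hashing (global seed, stage name), so stages rerun standalone
  reproduce the full run bit for bit, and manifests contain no wall-clock
  data.
- Duplicate (admission, timestamp) lab rows keep file order (stable sort)
  with a logged warning; admissions lacking labs or provider orders are
  dropped with logged counts; split sizes use floor for train/valid with the
  remainder to test (5,001 rows → 4000/500/501); the split unit is the
  interaction row, so a patient with several stays may span splits.
- `sub_epochs = 0` is an explicit no-op (unchanged model, empty curve log);
  non-finite losses abort with phase/epoch/batch context; predicting with
  an unknown provider code routes to the fallback embedding instead of
  failing.
- Simulation sizes in the test-suite scenarios (5,000-stay cohorts, 10
  replicates for the win-count comparison, 3 for the parity check, 200
  permutations for the null) are the package's chosen problem sizes: large
  enough that effect-size arithmetic (e.g. a 0.3-unit provider sd against a
  0.05 noise floor) dominates seed-to-seed variation, small enough that the
  whole suite runs on a laptop CPU in minutes.

## Limitations

The generator's linear-Gaussian latent world is far simpler than clinical
reality; results here validate mechanism, not clinical performance. The
provider side is a pure ID-embedding — nothing constrains what the latent
*means*, and with a single dominant provider per stay, team care is
invisible. Headline error levels depend directly on the configured noise
floor and effect sizes; they are not comparable to errors reported on any
real cohort.
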