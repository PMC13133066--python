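# Methods

This note documents the models, procedures and design choices behind
`fairseg`: what is simulated, what the training strategies do, which knobs
matter, and what the packaged experiments do and do not demonstrate.

## Problem setting

Segmentation models for musculoskeletal radiographs can perform unevenly
across demographic subgroups. The package studies that phenomenon — and
mitigation strategies for it — on synthetic data, with patients labelled by
two binary protected attributes, race (White/Black) and gender
(Male/Female), giving four intersectional subgroups (MW, FW, MB, FB).

## Synthetic data generator

Each sample is a grayscale image with an integer label mask of C = 6
foreground classes drawn as three left/right pairs of elliptical structures
(a large "head", an elongated "shaft", a small "joint space"), echoing the
paired anatomy of hip radiograph annotations without claiming realism.
Geometry is jittered per sample; the image is
`rendering × contrast_g + N(0, (noise_sd_g · jitter_i)²)` clipped to [0, 1],
where `g` indexes the subgroup and `jitter_i ~ U(0.6, 1.4)` is a per-sample
difficulty factor.

Disparity induction has two deliberate axes:

1. **Appearance** (units: intensity SD on a [0, 1] scale): White subgroups
   get `noise_sd = 0.08, contrast = 1.0`; Black subgroups
   `noise_sd = 0.16, contrast = 0.85`. The gap is moderate on purpose: a
   large gap creates an *irreducible* accuracy ceiling for the noisy groups
   that no training strategy can remove, which would make mitigation
   studies vacuous.
2. **Representation**: the packaged benchmark scales the bundled hip-cohort
   group proportions down to the requested size (≈30/28/12/29% for
   MW/FW/MB/FB), so the smallest subgroup (MB) is also under-represented,
   the mechanism balanced curricula actually address.

With these defaults the shuffled baseline shows a race-and-gender mean SER
of ≈1.26–1.55 once trained to near-convergence, i.e. a measurable but
mitigable skew.

The bundled demographic tables (`fixtures/hip_sites.csv`,
`knee_sites.csv`) reproduce a real multi-site cohort exactly: 761 hip and
707 knee patients across five acquisition sites, with strongly non-IID site
mixes (e.g. hip site A holds 157 Black patients, 112 of them FB, while
sites B/C are predominantly White). Federated experiments partition samples
to match those cells exactly.

What the generator does **not** emulate: anatomical texture, scanner
artefacts, annotation noise, or correlations between anatomy and
demographics. Masks are exact by construction, so label noise plays no
role. Passing trend tests here shows the algorithms behave as designed
under controlled disparity — not that they would close real clinical gaps.

All randomness flows from one master seed through named substreams
(rendering, splitting, site assignment, epoch orders, DP noise), so
components can be re-seeded independently and every run is reproducible.

## Metrics

* Multi-class IoU macro-averages the per-class pixel IoU over the
  foreground classes present in the truth plus any the prediction asserts;
  classes with an empty union are skipped; an image with no foreground in
  either mask scores 1.0 by convention.
* "IoU SD" is the **population** SD of the four subgroup mean IoUs — a
  group-level spread, not a per-sample one.
* SER is computed per attribute (race-wise and gender-wise); the reported
  "R&G mean SER" is their arithmetic mean. The denominator is clamped at
  1e-6 so a perfect group cannot divide by zero; a single present group
  scores 1.0.
* MMD is computed over the four intersectional subgroup means, the finest
  partition reported.
* The paired *t*-test uses the sample SD (n−1) with n−1 degrees of freedom;
  zero-variance differences give p = 1 when the mean difference is zero and
  p = 0 otherwise.

## Backbone and training loop

The backbone is a miniature U-Net (3 resolution levels, 8 base channels,
~30k parameters, ≈3×3 convs + 2×2 average pooling + nearest-neighbour
upsampling) implemented directly in numpy with hand-written backward passes
(strided im2col convolutions; adjoints verified against float64 finite
differences in the test suite). The network input is the grayscale image
plus a normalized horizontal-coordinate channel: the left/right paired
classes are visually identical and only position separates them, which a
small receptive field cannot otherwise resolve.

Training uses Adam (default lr 1e-3; the packaged benchmark uses 3e-3,
selected on the baseline arm's validation accuracy from the explored range
1e-4..1e-2), pixelwise cross-entropy as the standard loss, batch size 8,
and global gradient-norm clipping at 5.0. Clipping exists because a rare
exploding step late in training can destroy an otherwise converged model
(observed as a one-epoch train-IoU collapse); cosine lr decay was evaluated
as an alternative stabilizer and rejected as a default because it
structurally disadvantages growing-subset curricula, whose full-data epochs
arrive exactly when an annealed rate approaches zero. Learning rate and
weight decay are validated against the explored ranges ([1e-4, 1e-2] and
[1e-8, 1e-3]); zero is allowed to disable either.

Per-sample hard IoU is recorded by a gradient-free sweep after each epoch
and cached; curricula consume it as the "ease" signal for the next epoch.

## Curricula

All orderings are permutations of the active set and are consumed verbatim
by the epoch loop. Demographic interleaving cycles the four subgroups in a
fixed order, skipping exhausted groups; within a group, samples come either
uniformly at random or by descending ease, ties broken by sample id.

BCL starts from a demographically balanced random 20% subset (equal
per-group quotas, largest-remainder rounding) and grows linearly —
`size(e) = ceil(N·(0.2 + 0.8·(e−1)/(E−1)))` — admitting the highest-IoU
pool samples (scored by a forward pass of the current model) until the
target is met, reaching the full set at the final epoch. Veterans and new
admissions are re-ranked jointly by their latest available IoU, then
interleaved by group. The linear schedule and the joint re-ranking are
package choices where the procedure was underdetermined.

TCL uses a teacher trained as a shuffled baseline for the same budget and
frozen; the signed gap (teacher − student) defines difficulty, so a student
overtaking its teacher makes a sample maximally easy.

## Progressive losses

`ΔP_i = softIoU_i − IoU_ref`, where soft IoU is the differentiable
surrogate `Σ(p·y)/Σ(p + y − p·y)` macro-averaged with the same
class-selection rule as the hard metric (so it equals hard IoU on one-hot
inputs), and `IoU_ref` is the previous epoch's mean per-sample IoU,
detached; epoch 1 uses ΔP = 0 so training starts on the plain loss.

The weight `w` interpolates linearly per optimizer step from +α (start) to
−α (end of the planned step budget); α defaults to 1.0. Under BCL the
budget is the planned growing-subset step count, so `w` still reaches −α
by the end of training. Two gradient semantics are provided:

* **reweight** (default): per-sample multipliers `1 + w·max(ΔP_i, 0)`
  (SPL) or `1 + max(w·ΔP_i, 0)` (TPL), clipped below at zero, scaling each
  sample's cross-entropy gradient; ΔP is fully detached.
* **additive**: the literal formulas `L + w·Σ max(ΔP_i, 0)` (SPL) and
  `L + Σ max(w·ΔP_i, 0)` (TPL), estimated per batch and normalized by batch
  size, with gradients flowing through the soft IoU.

At w = 0 both variants and both modes reduce exactly to the standard loss,
and for w ≥ 0 the two variants' penalties coincide; they diverge only for
negative w, where TPL re-weights under-performers and SPL flips the sign of
the easy-sample term.

## Federated simulation

Each round: broadcast → every client trains locally (`local_epochs` of the
configured curriculum and loss; FedProx adds `μ·(θ − θ_global)` to each
step's gradient) → optional per-parameter Gaussian noise (FedDP/FedDPfair)
→ strategy weights → convex aggregation → global evaluation on the pooled
test split. Client scores (`IoU_k`, `SER_k`) come from a 10% stratified
local validation split; a client with a single subgroup reports
`SER_k = 1`. Quartiles for the outlier filter use linear interpolation
between closest ranks, threshold `Q1 − 1.5·IQR`, boundary retained; the
retained set can never be empty. Excluded clients still receive the next
global model — exclusion is per-round, never permanent. Defaults: 20
rounds, 1 local epoch, μ = 0.01, σ = 0.001 (inside the explored
1e-5..0.1 noise range). No gradient clipping of DP noise, privacy
accounting, partial participation or transport simulation is attempted.

Degeneracies hold exactly under shared seeds: σ = 0 makes FedDP reproduce
FedAvg round-by-round; μ = 0 makes FedProx reproduce plain local training;
a single-client federation equals sequentially chained local training.

## Packaged studies and their problem sizes

* **Fairness benchmark**: n = 200 samples (hip-cohort proportions), 96×96
  images, 25 epochs, lr 3e-3 — Base vs BCL vs BCL+TPL on identical splits,
  ~7 minutes on one CPU. 25 epochs is the low end of the explored 25–200
  range; shorter schedules leave the models so under-trained that the
  subgroup pattern itself is unstable.
* **Adversarial robustness**: five clients (32 samples each, 32×32,
  uniform mild appearance — this scenario needs no demographic gap), one
  client submitting `N(0,1)` random parameters with a reported local IoU of
  0.1; 2 rounds × 30 local epochs at lr 5e-3, run under FedAvg and
  FedIoUoutlier on identical seeds. The long first local phase matters:
  exclusion in round 1 requires honest clients to be past their learning
  take-off, where their local IoUs cluster tightly above the adversary's.

## Known limitations

* At this scale BCL's growing subset performs ≈60% of the baseline's
  optimizer steps. Because the baseline has not saturated, those missing
  steps cost ≈0.04 mean IoU at every epoch budget tried, even though BCL is
  more *step-efficient* (a step-matched baseline scores below BCL) and
  consistently narrows SER and MMD. Accuracy parity with the baseline —
  reported for BCL on large cohorts trained to saturation — is therefore
  not reproduced at desk scale, and the corresponding acceptance test is
  expected to fail; the fairness-direction tests pass.
* The float32 forward pass makes gradient checks on the full network
  noisy; exactness is asserted at the primitive level in float64.
* Single CPU, small images, no augmentation; absolute IoU values are not
  comparable to results on real radiographs.
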