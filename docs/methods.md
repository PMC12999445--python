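# Methods

## The diagnostic model

Per-image classification is reformulated as an episodic sequential decision
process solved by a cooperative two-agent team.

**Agent 1 (spatial).** At step *t* it observes `s¹_t = (o_t, p_t)`: a 64×64
RGB patch `o_t` cropped from the 224×224 image on a stride-32 lattice (50%
overlap, 6×6 = 36 windows) and a positional embedding `p_t` of the patch
center. A CNN backbone maps the ImageNet-normalized patch to a pooled
feature vector `f_t`, which — concatenated with `p_t` — feeds a two-layer
MLP (hidden 512, ReLU) producing action values `Q¹` over
`A1 = {move_up, move_down, move_left, move_right, class_1 … class_K}`.

**Agent 2 (temporal/text).** Each frame of the lesion's (pseudo-)sequence
is summarized by a rule-based text descriptor (see below); the token
sequence is embedded (`d_emb = 32`) and encoded by a bidirectional GRU
(default) or LSTM with per-direction hidden size 32, so the episode state
`s²_t = h_t` has dimension 64. An MLP head maps `h_t` to `Q²` over the K
classification actions only — this agent expresses a text-informed class
preference and never navigates. `h_t` is computed once per episode and held
fixed while the team navigates, since the text input does not change
within an episode.

**Team decision (VDN).** The team value of a classification action is the
sum `Q_tot(class c) = Q¹(s¹, class c) + Q²(s², class c)`; navigation team
values are `Q¹` alone, the only consistent completion given the asymmetric
action spaces. The joint action is the team argmax (ε-greedy during
training, ties to the lowest action index). Class probabilities for metric
computation come from a temperature softmax over the per-class team values
with τ = 1. Alternative fusion rules are available behind the same
interface for ablations: a fixed 0.5:0.5 average, attention weighting
(softmax over learned linear scores of the two agents' state summaries;
gradients reach the scorer and the Q-vectors, the summaries are treated as
constants inside the fusion rule), and a learned linear head over the
concatenated class-value vectors (initialized at the identity sum).

**Reward and objective.** Navigation costs −0.01; terminating with the
correct class pays +1, with a wrong class −1; the discounted return uses
γ = 0.99. Training minimizes the squared TD error
`(y_t − Q_tot(s_t, a_t))²` with the one-step target
`y_t = r_t + γ · max_a' Q_tot(s_{t+1}, a'; Θ⁻)` computed from hard-synced
target copies Θ⁻ (plain max; no double-Q correction). Transitions are drawn
uniformly without replacement from a bounded FIFO replay buffer.

## Training procedure

Centralized training, decentralized execution: one optimizer (Adam,
lr 1e-4) spans both agents (and any learned fusion parameters), while each
agent acts from its own observation. Defaults, chosen to match the stated
baseline settings where given and standard practice elsewhere: replay
capacity 10 000; batch 32; one gradient step every 4 environment steps
after a 200-transition warm-up; target sync every 200 gradient steps;
ε annealed linearly 1.0 → 0.05 over the first 60% of episodes.

Episodes start at the grid index nearest the image center (ties toward the
lower index → (2, 2) on the 6×6 grid), reflecting that dermoscopy crops
center the lesion. Off-grid moves clip to the boundary and still cost the
navigation penalty, keeping the action space state-independent. Episodes
are capped at T_max = 16 navigation steps, after which the environment
forces a classification decision (team argmax restricted to class actions);
every episode therefore ends within T_max + 1 steps. An optional supervised
warm start (regressing both agents' class values toward ±1 targets) is
provided to accelerate the RL phase but is never required.

All networks are implemented in numpy with hand-written reverse-mode
gradients (dense, conv via im2col, masked-BPTT GRU/LSTM, embeddings, Adam),
finite-difference checked in the test suite. The default spatial backbone
is a desk-scale 3-block CNN (stride-2 convs, channels 16/32/64, global
average pooling, `d_f = 64`); a ResNet-50-style residual backbone with
`d_f = 2048` after global average pooling exists behind the same interface
(randomly initialized — no pretrained weights are downloaded). The
literature this design follows describes the sequence encoder as a GRU in
one place and an LSTM in another; both are provided, with GRU the default.

## Synthetic data generator

The generator emulates two-class dermoscopy crops: a skin-toned background
with smoothed noise and one elliptical lesion whose polar boundary radius
is modulated by a Fourier series. The first harmonic produces asymmetry,
harmonics 2–6 produce border irregularity, interior Voronoi color sites
produce color heterogeneity, and optional dark dots stand in for
dermoscopic structures. Malignant parameter ranges strictly dominate benign
ranges on every axis (asymmetry 0.15–0.35 vs 0.00–0.06; border amplitude
0.10–0.22 vs 0.00–0.05; 3–5 vs 1–2 colors; darker base colors), so the
classes are separable by construction and the learning task is well-posed.
Every generated image carries its ground-truth feature record.

**Pseudo-sequences.** A single-timepoint lesion is expanded into three
frames (t−2, t−1, t) with one area growth rate drawn uniformly from 5–15%
per step and one interior darkening rate from 3–10% per step — drawn once
per sequence, since a gradual trend should be consistent. Growth applies to
mask area (pixel count): because the boundary radius is linear in its
scale, the rasterized area at any scale is an order statistic of
ρ/f(θ) over the pixel grid, and the scale is set exactly between the two
order statistics bracketing the target pixel count, so the measured
area ratio equals the drawn rate to within one pixel. Darkening is imposed
exactly by rescaling the interior so the measured mean-intensity ratio
equals (1 − rate).

**Descriptors.** A deterministic rule-based descriptor replaces the
prompt-based visual-language model that would produce lesion text in a
production system: each cue whose ground-truth score exceeds its threshold
(asymmetry ≥ 0.10, border ≥ 0.08, ≥ 3 colors, structures present)
contributes a fixed phrase over an 11-token vocabulary; a lesion with no
flagged cue yields the "regular lesion" template. For images without
ground truth (real data read from a manifest) the same cues are measured
from the pixels and an Otsu-estimated mask. This preserves the information
pathway the temporal agent consumes while removing any network dependency.

**Augmentation** follows the standard stack: random horizontal/vertical
flips, rotation within ±20°, and brightness/contrast/hue jitter within
±10%, with the mask transformed consistently and the label untouched.

**What the generator does not emulate:** hair, rulers, gel bubbles, or any
photorealistic texture; multi-lesion images; real longitudinal acquisition
noise. Passing tests therefore demonstrate that the decision process,
fusion algebra, optimization and evaluation machinery are correct and that
the team can learn a separable task end to end — not that the system
reaches clinical performance on real dermoscopy data.

## Evaluation protocol

Malignant is the positive class. Confusion-matrix metrics return NaN for
undefined ratios rather than raising. ROC uses a threshold sweep with
rank-average tie handling, so the trapezoidal AUC equals the concordance
probability. Stratified k-fold keeps per-fold class counts within one
sample of exact proportionality. Model comparison uses one-way ANOVA
followed by Tukey's HSD (studentized-range distribution). Decision-curve
analysis evaluates

    NB(thr) = sens·prev − (1 − spec)·(1 − prev)·thr/(1 − thr)

over thresholds 0.01–0.30 (step 0.01) at an assumed screening prevalence of
20%, against treat-none (identically zero) and treat-all references.

## Problem sizes and numerical choices

The package's reference experiment trains on 400 synthetic images (200 per
class) for 3000 episodes and evaluates on 200 held-out images — a
desk-scale problem chosen so the full suite runs on a single CPU in
minutes. Probability normalization holds to 1e-12 across temperatures; the
tabular two-state team-learning check converges to the value-iteration
solution within 1e-2. Degenerate inputs are handled explicitly: empty
masks, empty token lists, out-of-vocabulary indices, single-class datasets
and non-divisible patch geometries raise typed errors; zero-variance ANOVA
inputs return NaN markers. Greedy rollouts are fully deterministic, and all
stochastic components (generator, exploration, replay, initialization) are
driven by explicit seeds.

## Known limitations

- Real-image support is limited to what a manifest provides: masks are
  Otsu estimates and descriptor cues are simple measured statistics.
- The attention fusion scorer does not backpropagate into the backbone
  summaries; with strong Q-signals this has little effect, but it is a
  simplification relative to end-to-end attention.
- No prioritized replay, distributional RL, Transformer encoders, or
  pretrained backbones; the ResNet-50-style option shares only the feature
  interface (d_f = 2048) with its namesake.
- Reported learning results are on synthetic, separable data; they bound
  nothing about HAM10000/PH2-scale performance.
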