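# Methods

This note records the modelling choices behind `formucomet`: what is
computed, which knobs matter, what the synthetic generator does and
does not emulate, and where the design was genuinely open.

## Formulations and labels

A formulation is a list of (molecule, molar %) pairs summing to 100,
plus an N/P ratio (or an ionizable-lipid/RNA weight ratio convertible
to N/P), an aqueous/organic phase category and optional per-task
labels.  Inputs whose molar sum deviates by ≤ 0.01 are renormalized
with a logged warning; larger deviations are rejected (tolerance
1e-6).  Weight-ratio conversion uses

    N/P = Σ_il mass_il / MW_il · amines_il / (mass_RNA / m_nt)

with m_nt = 330 g/mol per RNA nucleotide by default (configurable);
for dual-ionizable recipes the ionizable mass is split by molar
proportion.  RNA is represented only by mass and per-nucleotide molar
mass — sequence effects are out of scope.

Labels model a plate-based bioluminescence assay: raw values are
divided by each plate's standard formulation, log-transformed and
min–max scaled to [0, 1] globally per task.  The log base is 10 by
default; any base gives identical labels after min–max, so the choice
is cosmetic and configurable.  Per-task global (not per-plate) min–max
is used.  Lyophilization stability uses the degradation label
pre − post (sign preserved; higher = worse), and the stability task is
trained on that value directly.

## Architecture

Token dimension 256 throughout.  Components: frozen 512-d molecular
embedding ‖ 128-d Gaussian RBF embedding of molar % (shared, learnable
centres/widths, initialized evenly on [0, 100] with width = grid
spacing) ‖ 128-d class embedding, projected by a two-layer MLP.  The
N/P token is a 256-d Gaussian embedding initialized on [0, 2·30]; the
phase token embeds a closed categorical vocabulary (unseen categories
are errors, not silently embedded).  One learned CLS token per task is
appended; all CLS tokens co-attend in a single pass.  Blocks are
Pre-LayerNorm (LN → multi-head attention → LN → MLP, residuals), with
no positional encoding so the score is permutation invariant over
components — the property tests assert this at 1e-5.

Defaults: 2 blocks, 8 heads, MLP hidden 512, head hidden 128.  Width
and depth are not externally prescribed; two blocks were chosen
because, on the numpy engine, a training step at batch 64 costs
~0.12 s single-threaded versus ~0.22 s at four blocks while synthetic
recovery quality is indistinguishable, and all of these are config
fields.  The default molecular encoder is a count-based radius-2
Morgan fingerprint folded to 512 buckets (square-root-damped counts)
— deterministic, parameter-free and frozen by construction.  Counts
rather than presence bits matter for lipids: homologous structures
such as C14- and C18-tailed PEG lipids contain exactly the same local
substructures and differ only in how many, so a binary fingerprint
cannot tell them apart at all.  3-D-aware encoders can be registered
under the same interface, and no encoder is ever trained or
fine-tuned here.

## Numerical engine

The network, its training and integrated gradients run on a minimal
reverse-mode automatic differentiation engine over numpy float32
arrays (`autodiff.py`): broadcasting arithmetic, batched matmul,
softmax, layer norm, relu, stable log-sigmoid, reductions, concat and
gather.  Every operator is verified against central finite differences
in the test suite.  Float32 keeps CPU matmuls fast; Gaussian-tail
underflow to exact zero is accepted (the encoders' contract is (0, 1]
up to underflow).

## Training

Pairwise margin ranking loss, λ_margin = 0.01; all C(64,2) = 2,016
pairs per 64-batch, exact label ties dropped.  Molar-percentage noise
augmentation: m ← max(0, m + N(0, (0.1 m)²)), composition deliberately
not renormalized (pipetting errors do not conserve totals), labels
untouched, training mode only.  Optimizer is Adam at lr 1e-3 — the
optimizer family and rate are our choice; 1e-3 converges in ~10 epochs
on the synthetic campaign where 1e-4 needs several times more — with
early stopping on validation Spearman (patience 10) and best-weight
restore.  The regression objective (squared error) exists solely for
the ablation arm.  Multitask gradients are combined with CAGrad: the
direction maximizing the worst task's improvement within a ball of
radius c‖g₀‖ around the mean gradient g₀, solved via its simplex dual
with SLSQP (verified against a brute-force solve of the primal maximin
on toy problems); c = 0.2, c = 0 recovers plain averaging.

## Ensembling and the screening funnel

Deployment ensembles: five models on disjoint fivefold validation
splits, distinct derived seeds.  Per-model scores are normalized by
the mean/sd of that model's scores on the reference campaign —
population (÷N) standard deviations everywhere, for determinism — and
averaged.  Relative uncertainty divides the across-model sd by the
ensemble score shifted by the reference minimum; non-positive shifted
scores are dropped outright.  The funnel applies, in order: near-hit
exclusion (inclusive ≤ at the L1 radius, compared only against hits
with the same lipid identity set), top-fraction selection (floor
semantics, ties by enumeration order), the uncertainty half-drop
(floor(N/2) lowest u_rel), and K-means diversity selection on per-slot
molar-% vectors (one slot per catalogue molecule; 14-d for the bundled
catalogue), best of n restarts by inertia (default 1,000; scaled runs
use fewer), top scorer per cluster.  Streamed screening keeps a
bounded candidate pool (4× the expected selection) so libraries far
larger than memory can be processed; enumeration order is a fixed
odometer over declared axes, making every stage reproducible from the
grid hash and seed.

Lead optimization splits the neighbourhood of a lead into disjoint
zones — same lipids within 20% L1; ≥ 1 substituted lipid within 20%
L1; and a changed N/P (lipid mode) or an added second ionizable lipid
(polymer mode) — and returns the top-scoring candidate per zone,
reporting empty zones rather than failing.

## Synthetic campaign generator

The generator is the package's study bench: a catalogue of 7 ionizable
/ 3 sterol / 2 helper / 2 PEG representative structures (PEG chains
truncated for compactness; molar masses from the drawn structures), 13
named base molar ratios around BASE = 35/16/46.5/2.5 varied one class
at a time, 60:40 dual-ionizable splits over all ordered pairs, and
24-point molar sweeps from 10–80% per class.  The latent oracle is a
sum of class-scaled per-molecule potencies, quadratic penalties around
per-class molar optima, a dual-ionizable synergy matrix over ordered
pairs, a Gaussian N/P bump and a phase×helper interaction.  Labels are
produced through the same pipeline as real campaigns: latent efficacy
mapped to 2.5 decades of luminescence, per-plate gain, multiplicative
lognormal handling noise (additive in log domain; sd 0.1 decades by
default), plate-standard division, log transform, min–max.  Hidden
oracle values are returned in a separate structure so tests cannot
leak them into features.

What this does not emulate: real structure–activity relationships (the
oracle's potencies are random draws, so passing recovery tests shows
the architecture can learn composition–activity surfaces of this
shape, not that it predicts real transfection), cell-line-specific
biology beyond independent oracle draws per task, and assay artefacts
other than lognormal plate noise.

## Evaluation protocol

Random 70/10/20 splits; a hits-test split withholding the top decile
by label plus a random tenth of the non-hits (remainder split 7:1
train/valid); leave-chemistry-out splits excluding all formulations
containing named molecules.  Metrics are Spearman/Pearson (ties
mid-ranked, NaN on zero variance) and top-half hit classification
(ceiling for odd N; hit threshold = 90th percentile, ties included).
Baselines are scikit-learn k-NN (k = 5) and random forest (100 trees)
on flattened features (per-slot molar %, presence indicators, N/P,
phase one-hot).  The identity-corruption probe shuffles lipid
identities in a fraction of training samples (within-class,
cross-class, or additionally synthesis parameters) with labels fixed;
the robustness tests check that test metrics degrade monotonically
with the corrupted fraction, using the random-forest baseline as the
probe model for speed.

## Integrated gradients

Attribution is computed in embedding space: the path runs from a
reference baseline to the input over the leaves the network actually
consumes — molecular embeddings, Gaussian-encoded molar % and N/P
vectors, phase one-hot — with per-class baseline means over a
reference set of conventional (non-polymer) formulations.  Integrating
over the raw scalars instead is numerically hostile: the learned
Gaussian bases are narrow, so the path integrand oscillates on the
scale of one basis width and midpoint integration fails at any
reasonable step count.  In embedding space a midpoint rule with the
default 512 steps keeps the completeness residual |Σa − (f(x)−f(b))|
below 1% of |f(x)−f(b)| on every tested formulation (128 steps can
leave several percent when f(x)≈f(b)).  Attributions are summed into
groups (molecule choice per class, molar % per class, N/P, phase),
normalized per model to max |a| = 1 and averaged across the ensemble.
Representation export picks the ensemble member best Spearman-
correlated with the ensemble scores on a probe set and emits its CLS
vectors with ionizable-class labels (dual-ionizable as its own class);
t-SNE itself is left to any standard implementation.

## Problem sizes and determinism

Test-suite runs use desk-scale sizes chosen as reasonable defaults for
a CPU workstation: recovery trains a fivefold ensemble on n = 2,000
labelled formulations (held-out probe of 400), the acceptance script
uses a three-model ensemble on n = 800 (probe 300) plus a 100,000
candidate scaled funnel, and smoke runs use n ≈ 200–600.  All
randomness flows from explicit seeds through named substreams (data,
fold, init, batching, clustering); parameter initialization is keyed
per parameter name so extending the class vocabulary (e.g. adding
polymer component types) leaves all shared weights bit-identical.

## Known limitations

* The measured campaign itself is not shipped; headline correlations
  on real data are not reproducible here and are not claimed.
* The default fingerprint encoder carries no 3-D information; plugged
  encoders must be deterministic and frozen.
* CAGrad's dual is solved with SLSQP from multiple starts — adequate
  at the small task counts used here, not a global-optimality proof.
* The funnel's streamed top-k pool assumes scores are exchangeable
  across chunks; pathological orderings could in principle evict a
  late winner, which the 4× pool cap makes unlikely but not
  impossible.
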