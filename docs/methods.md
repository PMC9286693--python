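# Methods

## The model

`noisylex` implements a deep bimodal autoencoder account of spoken-word
recognition in noise for bilingual listeners.  The network maps two input
codes onto themselves and onto each other:

- **Phonology** (292 bits): a 13-slot disyllabic template CCCVVCCCVVCCC.
  Each slot carries 22 binary articulatory features (consonant place 6,
  manner 7, voicing 1; vowel height 4, backness 3, rounding/length 1 —
  the last bit doubles as a secondary-articulation marker for consonants,
  e.g. aspirated `kh` vs plain `k`).  Words are aligned to the left within
  each syllable: onset consonants into the syllable's C slots, vowels into
  its V slots, coda consonants after.  The three C slots in the middle of
  the template are shared: they hold the first syllable's coda and then
  whatever of the second syllable's onset still fits (a word whose coda and
  following onset together exceed three consonants is rejected).  Left
  alignment encodes "time into space": word onsets always occupy the same
  leftmost slots, so onset-overlapping words share bits — the substrate of
  cohort-style competition.  Prosody is appended as 2 thermometer-coded
  length bits (monosyllabic `01`, disyllabic `11`) and 2 one-hot stress
  bits, plus 2 one-hot language-membership bits, for 13 × 22 + 6 = 292.
- **Semantics** (300 bits): sparse binary vectors, identical within a
  translation pair.  Real-valued 300-d embeddings can be imported and
  binarized with the strict threshold rule bit = 1 iff value < −0.175.

Architecture (defaults): phonology encoder 292 → P0 (200) → P1 (120),
semantics encoder 300 → S1 (200), both feeding the shared bottleneck PS2
(80); decoders PS2 → P3 (200) → 292 and PS2 → S3 (120) → S4 (200) → 300.
All units are logistic sigmoids; outputs are scored with binary
cross-entropy against clean binary targets.

## Training

Training has two stages.

**Greedy layerwise pretraining** (50 epochs/layer, SGD with momentum,
lr 0.1 — hotter rates occasionally leave some initializations in a
slow-start regime that fine-tuning cannot escape) trains each encoder layer — P0, P1, S1, then PS2 on the concatenated
penultimate activations — as a shallow autoencoder on the activations from
the layers below, discarding the temporary decoders.

**Denoising fine-tuning** interleaves three mapping types, one per
presentation in strict rotation (exactly 1/3 each): phonology →
phonology, semantics → semantics, and both presented simultaneously →
both.  A presentation draws its word with probability proportional to its
language's exposure weight; the *native* version of a model uses a 3:1
ratio in favour of the target language, the *non-native* version 1:3, and
both see the same total number of presentations, so any performance
difference is attributable to exposure alone.

Presented inputs are corrupted and the network is trained to reproduce the
*uncorrupted* targets.  Corruption is additive Gaussian noise (sd 0.1) on
every presented input plus masking noise on the semantic input: each
presented semantic entry is zeroed with probability 0.9.  The masking
component (the canonical denoising-autoencoder corruption) is the
mechanism by which word comprehension emerges without explicit cross-modal
training: the network repeatedly has to reconstruct full semantics from
presentations in which semantic evidence is almost entirely absent, so it
learns to fill semantics in from the phonological pathway through the
shared bottleneck.  At test time the semantic input is exactly zero and
the same mechanism produces the word's semantics from phonology alone.
With Gaussian-only corruption this transfer plateaus around 50% correct;
with the masking component the majority language reaches ceiling.

Optimization is SGD (lr 0.03, momentum 0.9, minibatch 64).  The default
budget is a fixed total of 363,000 word presentations (1500 epochs on the
default 242-word vocabulary), so small vocabularies are trained as
thoroughly as large ones.  Long runs on small vocabularies can
destabilize late in training; an adaptive step decay (lr × 0.3 after
three epochs whose loss exceeds 1.3 × the best epoch loss) catches this
without shortening healthy runs.  An Adam optimizer is available as an
option but SGD is the default.

## Test regimes

**Offline identification.**  Full phonological forms, prosody bits zeroed
(no assumption about how noise affects prosody), language unit set to the
task language.  Gaussian noise (sd 0, 0.30, 0.60, 0.90) is added only to
the feature bits of slots the word actually occupies, either on the
word-initial phones (first ⌈k/2⌉) or the word-final phones (last ⌊k/2⌋).
The half-split is a deterministic stand-in for the per-word phone masks of
the original listening experiments, which are not published; a per-word
mask file can override it.  The response is the task-language word whose
semantics is nearest (Euclidean) to the generated output semantics; ties
resolve in lexicon order.  Noisified inputs are real-valued and not
clipped to [0, 1].

**Online (visual-world) simulation.**  Words are presented incrementally:
timestep 0 is an all-zero input, timestep t carries the first t phonemes'
slots (noisified where applicable); prosody and language bits stay zero.
Each target has a display of four items: the critical item (the target
itself, or its onset competitor — the same-language word sharing the
longest phoneme prefix, ties by phonological distance then lexicon order)
and three distractors chosen to maximize the sum of their phonological and
semantic distance ranks from the target/competitor pair.  At each timestep
the model "looks" at the display item whose semantics is nearest to the
output semantics.  Looking preference is
log((looks_critical + 0.5) / (mean distractor looks + 0.5)), with the
timestep-0 value subtracted afterwards, so L(0) = 0 exactly.  The 0.5
smoothing guards the ratio against empty cells; the log is applied before
baseline subtraction because subtracting raw ratios first can produce
non-positive log arguments.

**Input-based baseline.**  No network at all: the response is the word
with the nearest full phonological vector to the (noisified) input.  It is
exactly identical under native/non-native labels — there is no learning
process to differentiate the groups — which is why it cannot capture
group effects, while it does inherit noise and position effects from the
representations themselves.

## Mechanistic measures

Rank-order closeness: where the target's reference pattern falls when all
reference patterns are sorted by Euclidean distance to the current
activation (rank 1 = recognized; rank r > 1 means r − 1 spurious
competitors outperform the target).  References per layer: the semantic
vectors (output), the full phonological vectors (input), and hidden-layer
activations elicited by the full phonological form presented together
with the word's semantics, computed once per trained model in the clean
condition.  The interlingual variant ranks the target's translation
equivalent within the other-language vocabulary: the translation shares
the target's semantics but not its phonology, so cross-language
competition is weak at the input layer and strengthens toward the
semantic layers, where the two vocabularies converge on shared
representations.  The cumulative
unique-misperception count per word freezes at the first timestep the word
is recognized.  The mechanistic noise level defaults to sd 0.75.

RSA: per layer, timestep and noise condition, a word-by-word RDM of cosine
distances between evoked activations (under noise, averaged over fresh
noise repetitions; a zero-norm activation is defined as maximally
dissimilar, distance 1).  Layer RDMs are Pearson-correlated with reference
RDMs built from the phonological and semantic representations themselves.
Correlations use the strict upper triangle only — correlating full
symmetric matrices would double-count every pair — and a constant triangle
yields a missing value.

## Statistics

Accuracy effects are estimated with a binomial fixed-effects GLM (logit
link) of correctness on noise intensity (scaled to [0, 1]), word-initial
position and non-native group, with cluster-robust standard errors by
trained replication; this replaces the random-effects structure of the
original mixed models, which is not specified.  All three empirical
effects correspond to negative coefficients under this coding.  Looking
preferences are tested per timestep bin with item-based paired one-tailed
t-tests against the timestep-0 baseline.  Fit-to-data measures are
Pearson correlations between model and human condition-cell means, either
over all cells or over within-factor difference vectors (one level as
baseline); a constant difference vector (e.g. the Input-based baseline
across groups) is reported as a missing correlation — a non-capture.

## The synthetic lexicon

The generator emulates the structure of the study vocabulary without any
external data: 121 translation pairs; 39 disyllabic words in language A
and 45 in language B (the rest monosyllabic, all words at least two
phonemes); phoneme sequences sampled from a 39-symbol SAMPA-like
inventory under the template constraints, pairwise distinct within each
language; stress on the first syllable 75% of the time.  Semantics are
sampled around 8 cluster prototypes, each bit Bernoulli(52.7/300), and
each pair's vector perturbs its prototype with expectation-preserving
asymmetric flips (1→0 with probability 0.3; 0→1 with probability
0.3 · p/(1−p)), giving loose semantic neighbourhoods comparable to
binarized corpus embeddings; translation pairs share one vector.  A flip
rate an order of magnitude smaller makes within-cluster vectors nearly
identical and word-level semantic decoding information-theoretically
impossible — clean joint-presentation accuracy collapses below 10% — so
the loose setting is the realistic one.

What the generator does **not** emulate: real phonotactics (sequences are
random within template constraints, so onset-cohort structure is thinner
than in a natural lexicon), frequency effects, cross-language cognates,
and graded within-pair semantic differences.  Passing direction tests on
this fixture therefore shows that the mechanisms produce the qualitative
effects, not that the model reproduces the published quantitative fits,
which depend on the original word list, corpus embeddings and human data.

## Problem sizes and numerical choices

The shipped analyses train 5 replications per model version on the default
121-pair lexicon and use 5 fresh noise draws per word and condition at
test (the corruption module's default is 10; the analysis scripts pass 5),
timesteps 0–5.  Ties in every nearest-neighbour and rank computation
resolve in lexicon order, making all tables bit-reproducible from the
master seed, from which every stage derives its own stream.  Degenerate
cases are defined, not special-cased away: zero-norm activations get RDM
distance 1, constant RDM triangles and zero-variance t-tests report
missing values, and single-level factors are dropped from the GLM with a
warning.

## Known limitations

- The slot code discretizes time; there is no genuine temporal dynamics or
  recurrence, and rhyme similarity across syllable positions is invisible.
- Additive Gaussian noise on binary features is a crude stand-in for
  acoustic masking; no SNR calibration is attempted.
- Bilingual proficiency is a single exposure-ratio parameter.
- The online "looks" rule is a hard argmin; humans distribute gaze.
- Reported human-fit correlations require the original human datasets,
  which are not bundled; the stats module accepts them as CSV if
  available.
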