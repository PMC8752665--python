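# Methods

This note records the modeling assumptions, parameter choices and known
limitations behind `temporient`. It is written for a reader who wants to
know *why* the package behaves as it does, not just what it computes.

## Generative label model

**Model.** For M tweets and L labeling functions (LFs) the observed label
matrix Λ ∈ {0..K}^{M×L} (0 = abstain, K = 3 temporal classes) and the latent
true class y_p of each tweet are scored by indicator factors of three
dependency types: per-LF accuracy 1{Λ_pq = y_p}, per-LF labeling propensity
1{Λ_pq ≠ 0}, and pairwise agreement 1{Λ_pq = Λ_pr} for pairs (q,r) in the
estimated dependency set S. One weight per factor (L + L + |S| in total); a
single accuracy weight per LF, not class-conditional. The joint
ρ(Λ_p, y) ∝ exp(w·φ) is normalized **exactly** over all (K+1)^L possible
rows × K classes. This keeps the model a proper distribution and makes all
quantities testable against brute-force enumeration; the cost is the
(K+1)^L enumeration, so L is capped at 10 (the intended regime is L = 5).
The prior over classes is uniform — no class-prior factor is included.

**Fitting.** The true classes are latent; the weights minimize the exact
negative log marginal likelihood, which factorizes over tweets as
M·log U − Σ_p logsumexp_y(w·φ_p). Optimization is full-batch gradient
descent with analytic gradients (model expectation minus posterior-weighted
observed expectation), zero initialization (deterministic — no seed
sensitivity), learning rate 0.05 scaled by 1/M so the step size is
corpus-size invariant, 500 iterations, L2 penalty 1e-4. A patience guard
(20 non-improving iterations) aborts with advice to lower the step size.
With zero weights the NLL equals M·L·log(K+1) exactly, a closed form used
as a smoke invariant.

**Posterior and ties.** Row posteriors are softmax over the K per-class
scores; all-abstain rows are exactly uniform. Hard labels take the argmax
with ties broken by the fixed class order past < present < future.

**Structure estimation.** A dependency-free model (accuracy + propensity
only) is fitted first. Conditioned on the latent class that model makes LFs
independent, so it implies a pairwise agreement rate computable from the
fitted weights alone (per-LF emission distributions over {abstain, correct,
each wrong class}). A pair enters S when its observed agreement rate, over
rows where both LFs commit, exceeds the implied rate by more than 0.15
(configurable). Comparing against the *fitted independent* model rather
than raw marginal products is essential: two accurate LFs agree far more
often than their marginals suggest simply because both track the truth, and
that shared-truth agreement must not be mistaken for a dependency. Matrices
(or pairs) with fewer than 20 usable rows return the empty set with a
warning.

**Balanced selection.** The training set for the discriminator takes the
top n/3 tweets per class by posterior probability (remainder going to
earlier classes in fixed order), excluding exactly-uniform rows. Confidence
ranking interacts with LF coverage: if some class markers are covered by
fewer LFs, a too-small n concentrates the selection on the best-covered
patterns and the discriminator generalizes worse. The end-to-end studies
therefore size n at 40% of the corpus.

## Multi-task discriminator

**Architecture.** Token embeddings (learned; optionally initialized from a
GloVe-style vector file, out-of-vocabulary rows from seeded small-variance
noise, pad row zero) feed a bidirectional GRU (final states of both
directions concatenated) and, in parallel, a width-7 temporal convolution
with ReLU and global max pooling. The two summaries concatenate into one
shared dense ReLU layer — the hard-parameter-sharing point. A temporal
dense+softmax head (3 classes) and an emotion dense layer with a softmax
head (4 classes) and a sigmoid scalar intensity head branch from it. The
intensity head is a regressor rather than a softmax because intensity is
continuous in [0,1] and evaluated by Pearson r; ordinal annotations are
mapped into the same scale by EI-oc × 0.25 + 0.125, which places the four
ordinal levels at the midpoints of the four user-level intensity bins.

**Training.** One mini-batch per task in alternation, cycling the shorter
dataset; temporal batches optimize categorical cross-entropy, emotion
batches cross-entropy + squared error with equal weights. RMSprop
(lr 5e-3, decay 0.9), batch 64 (shrunk with a warning when a dataset is
smaller), dropout 0.2 on the shared layer, up to 100 epochs, sequences
right-truncated/padded to 50 tokens with masked recurrent updates so
padding never leaks into the summaries. 10% of each task's data is held
out; the epoch with the best held-out loss supplies the returned weights.
All randomness flows from one integer seed; two runs with the same seed are
bit-identical.

The network runs on `temporient.nn`, a ~300-line numpy reverse-mode
autodiff with exactly the ops this architecture needs (dense, embedding
gather, GRU/LSTM cells, temporal convolution, max pooling, dropout,
softmax cross-entropy, squared error, RMSprop). Float64 throughout; at
desk scale (thousands of tweets, tens of units) training takes seconds to
a couple of minutes on one core.

## Weak labelers

Lexicon and keyword LFs label a tweet when words of exactly one temporal
class match, and abstain on cross-class conflicts (precision over coverage;
a majority-vote variant is available). The part-of-speech rule maps
past-tense verb tags to past, present-tense tags to present, and the
modals will/shall/gonna to future, with future > past > present precedence
when several co-occur — an explicit modal is the strongest signal. The
bundled rule-based tagger is a deterministic miniature (suffix and
word-list rules over a Penn-style alphabet); any real tweet tagger can be
injected as a `tokens -> [(token, tag)]` callable. The trainable weak
models — tf-idf linear SVM and a bidirectional LSTM — are full classifiers
that never abstain, matching their role as model-based label sources.

## Synthetic data and the correlation oracle

The generator emulates the *structure* of the target data, not its
linguistics: each user draws an orientation mixture from a Dirichlet
(default (1.5, 1.5, 1.5)); each tweet draws a temporal class from it, an
emotion from a 3×4 orientation-conditional table, an intensity from that
emotion's Beta (default Beta(2,2)), and a token stream of 4–7 filler words
plus class-marker tokens injected with probability 0.9 (1–2 temporal
markers; 1–3 emotion markers, the count growing with intensity so the
intensity head has signal). Five marker tokens per class. The planted
population couples future with joy and past with sadness
(rows (0.10, 0.60, 0.15, 0.15) / uniform / (0.60, 0.10, 0.15, 0.15));
the independent population uses uniform rows, and an alternative
zero-correlation design draws per-user emotion mixtures from their own
Dirichlet, independent of orientation. `planted_correlation` computes the
user-level Pearson r implied by the generative parameters by Monte-Carlo on
the latent class fractions alone (10^5 users by default; sampling error
~0.003 per cell), serving as the oracle for end-to-end recovery.

What passing on this generator does **not** show: robustness to real
linguistic variation (sarcasm, negation, code-switching), to tokenizer
noise, or to markers that are themselves ambiguous between classes — real
temporal/emotion cues are far weaker and more entangled than planted marker
tokens.

## End-to-end validation studies

`experiments.run_correlation_study` chains weak labeling → structure →
generative fit → balanced selection (40% of the corpus) → multi-task
training (48 recurrent units / 48 filters / 96 shared units, embedding 32,
25 epochs, 1600 emotion training tweets) → prediction → aggregation →
correlation. Study sizes: planted population 300 users × 20 tweets;
independent population 1000 users × 10 tweets. These sizes keep a full
study under two minutes on one core while leaving the statistical
comparisons meaningful.

The study uses the three heuristic LFs only. The SVM/B-LSTM weak models
bootstrap from a few hundred seed tweets and therefore carry small spurious
associations between emotion-marker tokens and temporal classes; because
those associations are baked into the models, the bias they inject into the
selected training labels does not average out as the corpus grows, and it
contaminates precisely the orientation–emotion correlations the study
measures. The weak models remain first-class components, exercised by their
own tests and available in the CLI pipeline.

**Known limitation — spurious correlation floor.** On a planted population
the pipeline recovers the oracle r to within a few hundredths. On an
independent population, however, the recovered correlations do not vanish
entirely: with hard per-tweet labels aggregated into per-user fractions,
any residual tendency of the temporal head to read emotion markers (or vice
versa) — a few percent per tweet, from finite training data co-adapting the
shared encoder — shows up as user-level |r| of roughly 0.05–0.15 on the
orientation×emotion grid. The effect is strongest for the emotion ×
intensity-bin cells: the sigmoid/MSE intensity head compresses predictions
toward the middle bins, leaving the extreme bins nearly empty, so their
per-user fractions have tiny variance and even a small systematic coupling
produces |r| of 0.2–0.3. For reference, with *true* labels the pure
sampling distribution of the max over the 12 grid cells at 1000 users is
already ≈0.08. Interpreting small user-level correlations from this
pipeline therefore requires a null calibration (e.g., the independent
population study), which the acceptance script reports alongside the
planted-recovery numbers.

## Numerical and interface conventions

- Class codes: 0 abstain, 1 past, 2 present, 3 future; emotions indexed
  joy, sadness, anger, fear.
- Intensity bins are half-open as printed ([0,.25), [.25,.5), [.5,.75),
  [.75,1)) with 1.0 assigned to HI so the bins cover [0,1] without a gap.
- Pearson significance uses the standard t-test with n−2 df at α 0.05.
  McNemar's exact test is provided separately as a paired-classifier
  comparison utility — that is the setting it is valid for; it is not a
  correlation test.
- All file formats are plain text (TSV/CSV/JSON/JSONL); UTF-8 everywhere;
  emoji survive tokenization as single tokens.
- Every stochastic routine takes an explicit seed; CLI stages log a config
  hash and append to a provenance file.
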