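# Methods

## Profile HMM architecture

`ksclass.phmm` implements a simplified Plan7-like profile: `M` match
states with position-specific emissions over the 20 amino acids, one
insert-emission vector shared by all insert states, delete states, and
per-node transition tuples `(MM, MI, MD, IM, II, DM, DD)` with node 0
acting as the begin state and node `M`'s match/delete transitions
routing to the end state. Deliberately absent: multihit alignment,
bias-composition filtering, per-node insert emissions, and any
null-length correction. The package needs *relative* scores — the
geometry of FAS vs PKS vs FASII scores — so HMMER-exact numerics are a
non-goal, and absolute bit values from `hmmsearch` (e.g. the published
full-length anchors near 600 bits) are not reproduction targets for
models built here.

### Scoring

The bit score is `log2(P(x|profile, mode) / P(x|null))` with an i.i.d.
background null of the same length. Two modes:

- **glocal** (default, used by all classification paths): the full
  model is traversed and the full sequence emitted.
- **local** (unihit): alignments may start and end at any match state
  with unit entry/exit weights; residues outside the fragment are
  emitted by the null. This is a scoring regime, not a normalized
  probability model.

`X` residues emit their background probability in both numerator and
denominator, contributing exactly 0 bits everywhere — this keeps scores
defined for sequences containing non-standard residue codes, which the
readers map to `X`.

### Numerics

The forward recursion runs in emission-odds space (each emission
probability divided by its background probability), which makes the
null cancel algebraically and the all-`X` identity exact. Per emitted
position the three state vectors are renormalized by their maximum and
the log2 of the scale accumulated; this is numerically equivalent to a
log-sum-exp recursion but vectorizes across model nodes. The
within-position delete chain `d[k] = b[k] + c[k]·d[k-1]` is solved in
closed form over chunks of 24 nodes (cumulative products and sums per
chunk), bounding intermediate magnitudes; contributions routed through
near-zero delete transitions are absorbed into a 1e-12 floor, far below
score resolution. Local-mode Viterbi (used by `locate_domain`) runs in
plain log2 space with a `maximum.accumulate` closed form for the delete
chain and an explicit traceback for the hit window.

Correctness is pinned by an independent oracle: exhaustive enumeration
of every state path for all toy models with `M ∈ {1,2,3}` and sequences
up to length 5, which the DP must match within 1e-9 log2 units (the
observed worst deviation is ~1e-15).

### Profile construction

`build_profile` follows standard practice where the underlying tools
leave choices open:

- match columns: gap fraction ≤ 0.5 (ties inclusive);
- match emissions: `(count + w·bg) / (n + w)` with pseudocount weight
  `w = 5.0` by default; `X` contributes no count;
- transitions: observed state-path counts blended with fixed priors
  (MM 0.90, MI 0.05, MD 0.05; IM 0.60, II 0.40; DM 0.60, DD 0.40) at
  the same weight. `I→D` and `D→I` transitions are outside the
  topology and contribute no counts;
- insert emissions = background; default background uniform (0.05),
  which makes the hand-checkable examples exact.

HMMER3 ASCII profiles (`HMMER3/f`, amino alphabet) are read for
interop: values decode as `exp(-v)`, `*` as probability 0 floored to
1e-9 with per-group renormalization, `COMPO` (when present) supplies
the background, and per-node insert emissions are averaged into the
shared vector.

## The rule cascade

`classify_ks` orders its rules deliberately: the hit gate first
(below-gate triples carry no class signal), then the FASII check
(type II is a separate enzyme system whose score signature — FASII
above both type I scores — is unambiguous when present), then the
y = x rule (strictly greater; ties fall to the FAS side), then the
FAS-score band. FAS-side sequences below the band default to PKS: in
the full-scale score landscape that region grades into the PKS cloud,
and sequences there need the embedding path or phylogeny for a
confident call.

### Threshold calibration

The published thresholds (gate 180, bands 400–600 / 200–500) presume
full-length (~420-state) profiles. Bit scores scale roughly linearly
with model length, so `KSRuleClassifier.fit` calibrates all three
thresholds from labeled training triples:

- gate = half the 1st percentile of the best-of-triple among training
  KS sequences (floored at 1 bit);
- `band_high` = midpoint of the mean FAS scores of the AFPK and
  TYPE_I_FAS training classes;
- `band_low` = midpoint between the 5th percentile of AFPK FAS scores
  and the 95th percentile of PKS FAS scores.

These are deliberately simple order-statistics; they assume the
training classes are unimodal in FAS score, which holds for the
synthetic families and for the published class geometry. Without
labels, `fit` adopts the configured full-scale defaults unchanged.

## AFPK-Finder

The embedding path is: score matrix → per-column z-score (population
SD; constant columns to zero) → 2D embedding → DBSCAN → ARI against
clade labels. Choices:

- **Normalization** is per-profile z-scoring, making profiles of
  different lengths (hence different score scales) comparable.
- **t-SNE** (scikit-learn, PCA initialization) is the default
  embedding, deterministic for a fixed seed on a given platform;
  perplexity defaults to 30 and is auto-shrunk below `(n-1)/3` with a
  warning. A **PCA** mode (top two components, each component's sign
  fixed so its largest-magnitude loading is positive) exists for
  bit-reproducible, permutation-equivariant tests.
- **Clustering** uses DBSCAN with `min_pts = 5`; when `eps` is not
  given it defaults to 3× the median 4th-nearest-neighbor distance,
  a scale-free rule that merges within-cluster gaps without bridging
  separated clusters. A core point counts itself among its `min_pts`
  neighbors (scikit-learn convention).
- **Congruence** is the adjusted Rand index over ids shared between
  clustering and reference; noise points become singletons so that
  declaring everything noise is not rewarded.
- **Panel selection** evaluates seeded random candidate subsets
  end-to-end and keeps the subset with the best training ARI (ties to
  the first drawn), logging the per-trial table.
- **Query classification** embeds references and queries jointly
  (t-SNE has no out-of-sample transform) and votes among the k = 5
  nearest references; confidence is the vote fraction, ties broken by
  the single nearest neighbor.

## Synthetic families

`make_family_hmm` draws one preferred residue per match column
(uniformly, seeded) and gives it `conservation` emission mass, the
remainder spread over the other residues proportional to background;
transitions are uniform across nodes with `MI = MD = indel_rate/2`.
Intermediate families are convex combinations `(1-λ)·A + λ·B` of every
emission and transition row — a single tunable axis with provable
endpoint behavior, in preference to sequence-level chimeras.

Defaults, chosen once as the desk-scale study conditions: `M = 120`
match states (a `--realistic` CLI flag uses 420, a typical KS domain
length), `conservation = 0.7`, `indel_rate = 0.02`, substitution noise
0.05 per site, 100 sequences per class for the rule-classifier
benchmark and 3 × 60 with a 30-profile panel for the embedding
benchmark. At these settings within-family scores sit ~450 bits above
cross-family scores, and the λ-grid mean scores move monotonically
against each parent — the synthetic reproduction of the observed
FAS-to-PKS score continuum.

The three-class benchmark's intermediate class defaults to
**λ = 0.35**, not 0.5. The bridging (AFPK) enzymes sit on the FAS side
of the y = x line — the published anchor scores roughly 2:1
FAS:PKS — with an intermediate FAS score. A λ = 0.5 model average is
exactly symmetric between its parents, so its samples straddle the
y = x line and no band calibration can recover them (the cascade's
PKS rule fires first on half of them, by symmetry); a FAS-weighted
mixture reproduces the class geometry the band rule was designed for.
λ remains a free parameter of `MixtureSpec` and
`three_class_benchmark` for experiments along the whole continuum.

What the generator does **not** emulate: phylogenetic correlation
among sequences, site-rate heterogeneity, realistic indel length
distributions, domain architecture beyond the KS region, and the
shared homologous core that makes real FAS and PKS domains weakly
similar everywhere. Passing the synthetic benchmarks therefore shows
the pipeline's rules and numerics behave as specified under controlled
geometry; it does not by itself validate threshold choices on real
sequence collections.

## Dereplication

`dereplicate` removes exact duplicates and substring-contained
sequences, keeping the longest representative (ties to the
lexicographically smallest id) and preserving input order of the
survivors. No similarity threshold is applied: exact containment is
conservative, deterministic and permutation-invariant, which the tests
rely on.

## Known limitations

- Bit scores are not HMMER-comparable; thresholds must be calibrated
  whenever profiles differ in length or construction from those that
  anchored the published values.
- The local-mode forward score is a fragment-sum regime, not a
  probability; it is exposed for exploration while `locate_domain`
  (Viterbi) is the supported hit-finding path.
- t-SNE determinism holds for a fixed seed on one platform/library
  version; cross-platform bit-identity is not guaranteed (use PCA mode
  where that matters).
- Continuum-intermediate classes near λ = 0.5 are genuinely ambiguous
  in score space — both for the rule cascade and the embedding — which
  mirrors the motivation for confirming borderline calls with
  phylogeny.
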