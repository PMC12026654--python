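# Methods

## Problem and model

`plantlnc` is a binary classifier separating plant long non-coding RNAs
(positive class) from protein-coding mRNAs (negative class) using only
the transcript sequence. The discriminative signal is classical:
mRNAs carry one long open reading frame (ORF), lncRNAs are stop-codon
dense; the two classes also differ in nucleotide composition and,
weakly, in predicted secondary structure. The model is a gradient-
boosted tree ensemble over a fixed 100-dimensional encoding; the trees
and their objective are XGBoost's standard machinery and are
deliberately not re-implemented here — the package's contribution is
the encoding, the balancing/evaluation protocol and the harness around
the engine.

## The 100-feature encoding

Feature order is fixed by `plantlnc.features.SCHEMA` and never changes
within a major version:

1. **Biological (3).** `orf_count`, `orf_coverage`, `orf_length`.
   ORFs are scanned per forward frame (transcripts are sense-strand,
   so reverse frames are out of scope), left to right: first AUG, first
   in-frame stop, emit AUG..stop inclusive, resume after the stop. An
   AUG with no downstream in-frame stop emits nothing. Minimum ORF is
   6 nt (start + stop adjacent); coordinates are 0-based half-open.
   Within a frame ORFs never overlap; across frames they may, so ORF
   coverage is computed from the union of covered positions and is
   bounded by 100%. `orf_length` is the longest ORF, the convention of
   comparable coding-potential tools.
2. **Sequence (90).** Length; GC%; the three Z-curve axes as raw count
   differences (not normalized); the AU/GC ratio with its denominator
   clamped to 1 when a sequence has no G or C (keeps the feature finite
   without sentinel values — a warning is logged); mononucleotide
   frequencies (sum to 1); 16 dinucleotide and 64 trinucleotide
   frequencies in lexicographic A<C<G<U order. The di-/tri-nucleotide
   denominators are L−2 and L−3 rather than the window counts L−1 and
   L−2; the encoding keeps those printed denominators for comparability
   with published feature tables, so the DNC block sums to (L−1)/(L−2)
   and the TNC block to (L−2)/(L−3) — both asserted to 1e−9 in tests.
3. **Structure (7).** Six counts parsed from a dot-bracket structure —
   base pairs, AU pairs, GC pairs (GU wobble pairs count in the total
   only), internal loops, external loops, unpaired bases — plus the
   free energy divided by length. Loop conventions are explicit
   choices, since count definitions vary between tools: a pair whose
   enclosed region holds exactly one nested pair and at least one
   unpaired base is an internal loop (bulges included); hairpins and
   multiloops are counted in neither reported feature; "external
   loops" is the number of maximal unpaired runs in the exterior
   region, and a structure with no pairs has zero loops. One fixed
   convention, not configurable — models stay comparable.

## Folding backends

* `external`: ViennaRNA's MFE folder through its Python bindings
  (thermodynamic energies, kcal/mol). Default when importable.
* `builtin`: a deterministic Nussinov-style maximum-weight pairing with
  weights GC=3, AU=2, GU=1, minimum hairpin loop of 3 unpaired bases,
  and traceback ties resolved toward pairing the leftmost base with its
  smallest optimal partner. Its energy proxy is minus the total pair
  weight — **not** calibrated to kcal/mol. The dynamic program is
  numba-compiled (O(L³), ~tens of ms at 500 nt).

Because the two backends produce different feature scales, the schema
fingerprint embedded in every model bundle includes the backend tag;
`predict` refuses a matrix built under a different backend or feature
order. The structural feature *parser* is backend-agnostic and is
validated against hand-decomposed structures and an exhaustive pairing
search (lengths ≤ 12).

## Preprocessing

FASTA input is uppercased and DNA T is converted to U (public mRNA
dumps are DNA-alphabet); records with ambiguity codes (N, X, ...) are
skipped with a logged (id, reason) report rather than aborting the
batch. Length filtering keeps 200–6000 nt inclusive. Redundancy
removal is a greedy longest-first filter: a record is dropped when its
ungapped sliding identity (best offset, matches / shorter length) to a
retained record reaches the threshold (default 0.9). This is a
desk-scale equivalent of external greedy clustering tools; large
corpora that were already clustered pass through unchanged. Whether
positives and negatives are clustered jointly or separately is left to
the caller (`--cluster-jointly` semantics are simply "concatenate
before filtering"); the library applies it per set.

## Synthetic transcript generator

`simulate_sequences` emulates the two classes:

* mRNA-like: one embedded ORF occupying a uniformly sampled 60–100% of
  the sequence, built from an AUG, sense codons (61-codon alphabet) and
  a sampled stop, flanked by i.i.d. UTR-like sequence.
* lncRNA-like: i.i.d. nucleotide draws at the target GC (default 0.45,
  a typical plant transcript value), with rejection of draws whose
  longest ORF exceeds 40% of the length. Natural stop-codon density
  (3/64) makes long ORFs rare, so rejection is infrequent.

Defaults: lengths uniform in 200–6000 nt inclusive, GC 0.45, fully
deterministic per seed. The 60%/40% thresholds are engineering choices
that make the classes separable but overlapping — suitable for
end-to-end recovery tests. The generator does **not** emulate codon
usage bias, splice isoforms, UTR composition or real length
distributions, so passing tests demonstrate pipeline correctness and
recoverability, not field accuracy on real transcriptomes. Tests and
the worked examples use 200–800 nt (and smaller n) to keep the cubic
folding step and tree training at desk scale; this is the package's
own choice of problem size and changes no default.

## SMOTE

Implemented in-house (no oversampling dependency): minority rows are
standardized (minority-class mean/SD, zero SDs clamped to 1) for the
k-nearest-neighbour search only; interpolation x_i + u·(x_nn − x_i)
happens in the original feature space with u ~ U(0,1) from a seeded
generator. k defaults to 5 (the technique's original default) and is
clamped to minority_size − 1 with a warning. Originals are retained
bit-identically; synthetic ids are tagged; optional provenance records
(base row, neighbour, u) make the convex-combination contract
checkable. Balancing is only ever applied to the set the caller passes
— the pipeline never silently resamples a test pool; replaying the
published balanced-test-set design is an explicit caller decision.

## Training, tuning, persistence

Training uses `XGBClassifier.fit` (hist tree method, logistic
objective, seeded). The tuned default is 300 trees, depth 8, learning
rate 0.1, subsample 0.7, colsample_bytree 0.8, α=0, λ=1; the random
search protocol samples uniformly without replacement from a
36 288-combination grid and scores by stratified k-fold (default 5)
mean accuracy — accuracy because it is the primary reported metric;
ties go to the first sampled combination. Fold assignment depends only
on (labels, folds, seed). The classification threshold is fixed at
0.5. Bundles persist as a directory: engine-native `model.ubj` plus a
JSON sidecar (hyperparameters, feature names, backend tag, seed,
engine version — a version mismatch at load is a warning, not an
error). Prediction, importances (split-frequency "weight") and
persistence go through the raw Booster API; the sklearn wrapper is
used for fitting only.

## Evaluation

Standard confusion-matrix definitions (precision = TP/(TP+FP),
SN = TP/(TP+FN), SP = TN/(TN+FP), F1 = 2TP/(2TP+FP+FN), MCC with the
square-root denominator). Conventions: MCC = 0 when any marginal is
zero; F1 = 0 with no true positives and no positive predictions; ROC
thresholds at every distinct score, trapezoidal AUC. Redundancy
filtering visits feature pairs in schema order and drops a seeded
random member of each |ρ| > threshold pair, guaranteeing (and
asserting) that no retained pair exceeds the threshold; zero-variance
columns correlate 0 with everything. The reintroduction experiment
retrains from scratch at every step with identical hyperparameters and
seed. Category ablation evaluates all/sequence/structure/biological
feature subsets on a stratified 70/30 split. The cross-species harness
trains one model per group and evaluates on every group, using a
held-out 30% split on the diagonal and refusing any train/test id
overlap.

## Known limitations

* The builtin folder maximizes pair weight, not thermodynamic
  stability; its structures are denser than ViennaRNA's and its
  energies are unitless. Cross-backend model reuse is blocked by
  design rather than supported.
* The greedy identity filter is O(n²·L²) and meant for desk-scale
  sets, not hundred-thousand-sequence corpora.
* Synthetic data cannot certify accuracy on real plant transcripts;
  external validation data is required for that claim.
* Binary classification only; no multi-class ncRNA typing, no
  pseudoknots, no probability calibration.
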