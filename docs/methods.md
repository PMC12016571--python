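# Methods

This note documents the scientific model behind `nphosite`, the defaults
that matter, the synthetic study conditions, and the numerical choices made
where the design was genuinely open.

## Windows and coordinates

All analyses use a phosphosite-centered window of 31 residues. The
half-width of 15 reflects the span over which kinase-recognition sequence
signal around phosphosites is conserved. Coordinates are 1-based and fully
closed (UniProt convention); windows that overrun a terminus are padded
with the literal character `-`, which is carried through the encoders as a
dedicated 21st symbol rather than dropped, so a near-terminal site still
yields a fixed-length feature vector. Ambiguity letters (B, Z, X, U, O) are
accepted on input, flagged on windows, and treated exactly like pads by the
encoders — they contribute no composition mass, a zero HQI8 block, and the
BLOSUM62 "any" row.

## Feature encodings

* **AAC** (20 values): frequencies of the canonical amino acids among the
  window's canonical residues. Pads are excluded from the denominator, so
  components always sum to 1.
* **HQI8** (248 values): the eight "high-quality" AAindex indices obtained
  by fuzzy clustering of the full AAindex collection — BLAM930101,
  BIOV880101, MAXF760101, TSAJ990101, NAKH920108, CEDJ970104, LIFS790101,
  MIYS990104 — one 8-block per window position (position-major). The table
  ships with the package and can be replaced via
  `features.hqi8_from_table`. Values are used as published, without
  per-feature standardization; tree ensembles are invariant to monotone
  per-feature scaling, so z-scaling would not change the default models.
* **BLOSUM62** (620 values): each position contributes its 20-long
  substitution row. The pad/any character uses the standard matrix's X row
  (the closest published "any one of 20 amino acids" semantics);
  alternative matrices load from NCBI-format files. Rows come from
  Biopython's packaged BLOSUM62.

Combinations concatenate in the fixed order AAC, HQI8, BLOSUM62 giving
dimensions 20/248/620/268/640/868/888. Per-type defaults are AAC+HQI8 for
pHis and pArg and AAC+HQI8+BLOSUM62 for pLys, the combinations that
performed best per type in benchmark comparisons.

## Benchmark construction

Positives: one example per distinct (site type, peptide string); duplicate
windows arising from conserved paralogs collapse to one.

Negatives (four steps): candidates are non-annotated H/K/R residues in
proteins carrying at least one annotated site; residues with RSA above the
per-letter ceiling (His 0.12, Lys 0.30, Arg 0.20 — ceilings chosen for
per-letter dataset balance, configurable) are excluded; survivors are
windowed; finally any candidate with ungapped identity ≥ 30% to some
positive of the same type is removed. Identity is matching non-pad
positions divided by window length (31), so the 30% threshold means "10 or
more shared positions". The filter is an exact vectorised all-pairs scan
rather than a wrapped clustering tool: it is dependency-free, reproducible,
and well-defined at 30%, where word-based clustering tools operate at or
below their documented identity floor. Negatives are deduplicated but not
filtered against each other. Candidates lacking an RSA annotation are
dropped (counted in the log), never imputed — the RSA constraint is the
defining feature of the rule.

A consequence worth noting: because identical windows have identity ≥ the
threshold, no peptide string can ever appear with both labels.

## Models and evaluation

The classifier is scikit-learn's `GradientBoostingClassifier`. Published
hyperparameters for comparable site predictors are not available, so the
package ships a documented default — 200 trees, depth 3, learning rate 0.1,
subsample 0.8, `max_features="sqrt"` — plus a small grid (trees ∈ {100,
200}, depth ∈ {3, 5}, learning rate ∈ {0.05, 0.1}) selected by mean 10-fold
CV AUC when grid search is requested. `max_features="sqrt"` is the standard
variance-reduction/speed lever for boosted trees on wide encodings; with
200 trees it costs little accuracy and makes repeated-split and CV
protocols cheap. The learner registry (`model.register_learner`) accepts
any scikit-learn-style classifier, so alternative algorithms (random
forest, logistic regression, …) can be plugged in without core changes.

Evaluation: five independent stratified 80/20 splits; per split the model
is refit on the 80% and scored on the 20% at probability cutoff 0.5
(sensitivity, specificity, precision, F1, accuracy, MCC) plus
threshold-free AUC; reports carry mean ± std (population std, hence 0 for
a single repeat). Stratification preserves the ~1:3 class ratio in every
part (plain shuffling is also unbiased but noisier at these sizes).
Internal robustness uses stratified 10-fold CV repeated ten times, pooling
out-of-fold predictions within each repeat. All randomness flows from one
top-level seed through `numpy.random.SeedSequence`-derived child seeds.

Two printed-formula corrections are deliberate: specificity is implemented
as TN/(TN+FP) (the universal definition; the variant FN/(FP+TN) sometimes
seen in print is inconsistent with reported specificities near 97% at
sensitivities near 62%), and MCC uses the standard denominator
√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Undefined ratios (zero denominators) are
reported as NaN, never as 0.

## Enrichment and motifs

The E-ratio (m·N)/(M·n) compares a category's share among phosphosites (m
of M) versus non-phosphosites (n of N); significance is the chi-squared
test on [[m, M−m], [n, N−n]] without Yates correction (the mainstream
default at these sample sizes; configurable). Missing category annotations
are excluded from totals and reported; categories absent from the
background are skipped with a warning.

Motif discovery is greedy motif-x: at each step the (offset, residue) pair
with the smallest exact binomial upper-tail p-value P(X ≥ k) of its
foreground count given the current background frequency is fixed, both
sets are reduced to matching windows, and the process repeats until no
pair passes the per-step cutoff (default 1e-4, the motif-x family
convention) or would leave fewer than the occurrence floor. A motif is
accepted at score Σ −log₁₀(p) ≥ 5 with ≥ 10 supporting windows; its
windows are removed and the search restarts. Numerical choices: exact
binomial tails (robust at small counts, unlike the normal approximation);
a zero background count is replaced by 1/(n_bg+1) to keep the step
p-value defined; p-values are floored at 1e-300 so scores stay finite;
ties break by smaller offset magnitude, then alphabetical residue, then
upstream before downstream — making results fully deterministic.

## Prediction and grading

Every H/K/R residue of a query is windowed (near-terminal residues are
padded, consistent with the `-` symbol in the encoders, rather than
skipped), scored with the per-type model, and reported above probability
0.50 with reliability grades high (0.85, 1.00], middle (0.70, 0.85], low
(0.50, 0.70]; boundaries belong to the lower bin and are applied to the
full-precision probability (output files round to four decimals). Queries
must have more than 16 residues — 17 is the hard minimum (half-width 15 +
center + 1). Proteome-wide scans use the 0.85 threshold and count distinct
sites and proteins per type, excluding known annotated positions when a
table is supplied.

## Synthetic study conditions

The generator emulates exactly the structure the pipeline assumes:

| parameter | default | rationale |
|---|---|---|
| proteins | 1000 | ~2000 planted sites per type |
| length | Normal(500, 100), min 40 | typical protein-length scale |
| background composition | uniform 1/20 | makes planted enrichment analytically checkable; a UniProt-like preset is included |
| sites per protein per type | Poisson(2) | sparse, multi-site proteins occur |
| signal residues/offsets | pHis: K/E at ±1..7; pLys: S/P at −6..−1; pArg: S/P at ±1..3 | the observed flank preferences per type |
| effect multiplier | 6.0 | signal residues' probability ×6, renormalized; chosen from a signal-detection calculation giving optimal AUC ≈ 0.91–0.96 across types, i.e. a clearly learnable but imperfect signal |
| RSA | sites Beta(5,5); background U(0,1) | sites mostly exposed (mean 0.5); the U(0,1) candidate pool gives the RSA filter bite |
| negative cap | 3× positives (seeded subsample) | keeps the ~1:3 class balance typical of curated benchmarks |

`make_benchmark` routes the generated annotations through the *real*
dataset rules, so the benchmark inherits every invariant of the four-step
procedure. An effect multiplier of 1.0 yields flanks statistically
indistinguishable from background (null calibration).

What the generator does **not** emulate: real amino-acid usage and window
autocorrelation, homology families (beyond exact duplicates), detection
noise and biased site ascertainment from mass spectrometry, species
differences, and any structure beyond per-residue RSA. Passing tests
therefore demonstrate that the pipeline recovers signal of the planted
form faithfully and calibrates correctly under the null — not that any
particular real-data performance level is guaranteed.

## Problem sizes used in tests and the acceptance script

Unit tests run on a 60-protein study; the end-to-end acceptance checks use
the full default conditions (~2k positives / ≤6k negatives per type) with
a single 80/20 split per type, one 10-fold CV pass on the pHis training
portion, a 500-window motif-recovery experiment at 4× effect against 5000
background windows, and 50–100 null motif runs at 200 foreground windows.
These sizes give stable statistics while keeping the whole suite fast on a
single CPU.

## Known limitations

* RSA, secondary structure and disorder are consumed as annotations; the
  package never predicts them from sequence.
* The homology filter is all-pairs over equal-length windows (O(n·m·w));
  exact but quadratic, fine up to ~10⁵×10⁴ pairs.
* Default models are trained on whatever benchmark they are given; no
  pretrained weights ship with the package.
* The motif search fixes one residue per offset (motif-x semantics); it
  will not represent degenerate positions such as [ST] within one motif.
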