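# Methods

## Scope and model

`cinslnet` operationalises a target-discovery chain for synthetic lethality
(SL) in chromosome-instability (CIN) backgrounds. Its stages make the
following assumptions:

* **Chemical-genetic scoring.** A strain's sensitivity to a chemical is a
  property of its relative colony growth, chemical vs. matched no-chemical
  control, after plate-level normalisation. The published screens this
  emulates used an external image-analysis scoring method; here the decision
  structure is made explicit and configurable: a gene is *sensitive* when its
  relative growth is ≤ `growth_threshold` (default 0.5) **and** its robust
  z-score across the array for that chemical is ≤ −`z_threshold` (default 2).
  Medians and the MAD are used throughout because pinned-colony data contain
  outliers from pinning failures; when the array MAD is zero (noise-free
  input) any value below the median counts as an extreme negative z.
* **Enrichment and coverage.** The enrichment quotient of a sensitivity list
  is the percentage of CIN genes in the list divided by the percentage of CIN
  genes in the genome; it is exactly 1 for the genome itself and has
  expectation 1 for uniformly random lists. Coverage statistics (fraction of
  a gene set sensitive to ≥ 1 chemical) keep full precision internally and
  round to whole percent only for display.
* **Network calling.** Interaction records are retained when *p* <
  `p_threshold` (default 0.05, boundary exclusive as written "P < 0.05") and
  score ≤ `score_threshold` (default −0.20, boundary inclusive: the stated
  cut-off carries no strictness marker, so the conventional ≤ is used).
  The CIN network is bipartite-style and deliberately asymmetric — CIN genes
  are the screen queries — and a gene's *CIN degree* counts **distinct** CIN
  queries, not edge multiplicity; duplicate measurements collapse to the most
  negative score. Hubs are array-side genes with CIN degree ≥ `min_degree`
  (default 40; 5 is the analogous choice against a small cancer-ortholog
  query panel).
* **Surrogate-SL prediction.** Members of a protein complex share genetic
  interactions, so a hub's SL profile (cancer-ortholog queries adjacent to
  it) is propagated exactly one hop to its complex partners. Multi-hop
  closure is rejected: each additional hop compounds the false-positive rate
  with no way to control it from the data at hand. Support counts
  deduplicate *hubs*, not complexes, since one hub may anchor several
  complexes. The evaluator reports recall against planted truth restricted
  to the (partner, cancer-gene) universe the predictor can reach — partners
  that fail to validate experimentally are expected (hypomorphic alleles of
  essential genes need not reproduce every null-allele interaction).
* **Multiplicative-model validation.** Relative proliferation is the mean
  count of a condition over the mean control count (median available via
  `agg="median"`). The null prediction for a double knockdown is the product
  of the singles; the proliferative defect is `1 − observed/predicted`,
  oriented so aggravating interactions are positive, and a defect ≥ 0.15
  (inclusive) is called SL. The reversed orientation
  (`1 − predicted/observed`) is available for comparison but makes
  aggravating interactions negative, contradicting a "defect of 15 % or
  greater" reading, and is not the default. Nuclei counts and
  colony-formation counts share this code path unchanged.

## Synthetic data: what it emulates and what it does not

The generator plants known truth behind every stage:

* a gene universe (default 2000 genes, matching the scale of an
  essential-gene mutant array) with a CIN subset (default 20 %), a
  cancer-ortholog subset of the CIN genes (default 25 % of them), and an
  essential flag (default 40 %, hubs forced essential);
* an interaction screen in which each of `n_hubs` (default 10) non-CIN array
  genes carries planted negative interactions with `hub_cin_degree` (default
  45) distinct CIN queries at score mean −0.35, while non-planted pairs are
  measured with probability `background_edge_prob` (default 0.05) and score
  mean 0. A pair's score is the mean of three replicate draws scaled so the
  score itself is Normal(mean, `score_noise_sd`); the p-value is a two-sided
  one-sample t-test of those replicates against zero, so the downstream
  p-filter is exercised honestly. The magnitude distribution of real scores
  is not published, so −0.35/0.05 are explicit placeholders in the config;
* colony sizes in nine replicates per strain × chemical (triplicate pinning
  passaged in triplicate) with matched controls, sensitive strains growing
  at `sensitive_growth_ratio` (default 0.4) of the control mean;
* complexes assigning `complex_size` distinct essential partners to each of
  `n_complexes` distinct hubs, and SL pairs propagated exactly as the
  predictor assumes: (partner, cancer-ortholog query adjacent to the hub)
  with planted defect 0.3;
* proliferation counts under the multiplicative model with per-gene single
  knockdown effects uniform in (0.6, 0.9), six replicates, and
  `n_null_pairs` extra non-SL pairs so the null calibration is represented.

Noise is multiplicative log-normal everywhere (sizes and counts are positive
and right-skewed), parameterised by a coefficient of variation and mean-
corrected so a zero CV reproduces planted values exactly. All randomness
derives from one seed; each table uses a deterministically derived
sub-stream, so outputs are bit-identical across reruns.

Deliberately **not** emulated: real genome composition, plate geometry and
spatial effects, replicate correlation beyond the shared control, knockdown
efficiency, and measurement censoring. Passing tests therefore demonstrate
that the decision rules recover truth planted under their own assumptions —
they do not certify performance on real screens, where the score
distribution, noise structure, and annotation quality differ.

At the default score noise (sd 0.05) roughly 7 % of planted edges fail the
three-replicate t-test at p < 0.05, so a degree-45 hub occasionally dips
below the 40-interaction filter; exact hub recovery is a low-noise (sd ≤
0.02) property, and the tests assert it there.

## Numerical and design choices

* Zero-noise limits return planted parameters *exactly* (no rounded means):
  degenerate t-tests report p = 0 for nonzero scores and p = 1 otherwise.
* Deterministic ordering everywhere: stable sorts with documented tie-breaks
  (hubs by descending CIN degree then gene ID; predictions by descending
  support then lexicographic), so outputs are diffable.
* Undefined quantities (empty sensitivity list, empty CIN set, zero control
  mean, predicted proliferation ≤ 0) raise typed errors rather than
  returning sentinels; in `score_experiment` a missing condition produces a
  per-pair error row so one bad pair does not abort an experiment.
* Overlap tables report all 2^k chemical-membership combinations including
  the empty one (genes in no list); counts over non-empty combinations sum
  to |target ∩ union|.
* The pipeline configuration is a flat key=value text file with a
  `--set key=value` override, hashed into every output file's provenance
  header together with the tool version and seed; log lines carry no
  timestamps so reruns are byte-identical.

## Problem sizes

The test suite and the acceptance script run on simulations of 200–4000
genes, up to 10,000 interaction records or planted edges, 1000-pair null
calibrations and ~500–650-pair detection sets — sizes chosen so planted
effects are estimated with Monte-Carlo error well inside the asserted
tolerances while the whole suite completes in seconds.

## Known limitations

* The sensitivity cut-off is a stand-in with the same decision structure as
  the published screens, not a reimplementation of their image-based scorer.
* Whether the public-network extraction applied a score filter beyond
  "negative" is not recoverable; `build_cin_network` exposes an optional
  `score_cutoff` for that reason.
* Single-hop propagation treats essential and nonessential partners alike;
  ranking partners by allele strength is out of scope.
* The evaluator's precision/recall are meaningful only against planted or
  curated truth; on real data, absence of a validated interaction is not a
  false positive.
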