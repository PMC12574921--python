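# Methods

## Interface scoring (LIS / LIA)

AlphaFold-Multimer emits, per model, a square predicted-aligned-error
(PAE) matrix over the concatenated residues of the two chains. The
entry `E[i, j]` estimates the positional error (Å) of residue *j* when
the model is aligned on residue *i*'s frame; it is not symmetric, so
both off-diagonal blocks carry information. For a pair with chain
lengths `len_a`, `len_b` there are exactly `2·len_a·len_b` inter-chain
cells.

With cutoff `c` (default 12 Å, strict `<`), the selected set
`S = {cells with E < c}` gives

- `LIA = |S|` — interface size in residue pairs,
- `LIS = mean_S (c − E)/c` — mean rescaled confidence in [0, 1],
  defined as 0 when `S` is empty (so `LIA = 0 ⇒ LIS = 0`).

Per-model scores are combined across the models of a pair; the default
aggregation is the arithmetic mean of each field. `max` (field-wise
maxima) and `best_model` (fields of the highest-LIS model, ties broken
by lowest model id) are available because the field has no single
convention for multi-model summaries, and whether published LIA
thresholds refer to per-model or model-averaged values is usually not
stated. A pair is a positive PPI when the aggregated `LIS ≥ 0.203` and
`LIA ≥ 3432`, both inclusive — these defaults reproduce a published
decision boundary and are plain `ScoreConfig` fields, as is the 12 Å
cutoff. Counting both PAE blocks is the default (`block_mode="both"`);
`block_mode="max"` keeps the better block only.

Numerical notes: scoring is exact (a mask and a mean); the unit tests
pin the strict/inclusive boundary behaviour at `E = c` and at the
thresholds, and a brute-force double-loop oracle over raw indices
checks the vectorised path exactly for LIA and to 1e-12 for LIS.

## Enrichment filtering

The fold change of a prey is
`(mean(bait counts) + ψ) / (mean(control counts) + ψ)` with pseudocount
`ψ = 1` on both arms; replicates are summarised by the arithmetic mean
(whether published ">2-fold" rules sum or average replicates is rarely
stated; the mean is this package's documented choice, and with equal
replicate numbers the two agree). The retention rule is strict:
`FC > min_fold` with `min_fold = 2`. `ψ = 0` recovers the raw ratio and
raises an error when the control mean is zero. The filter is monotone
(raising a bait count can only add preys; raising a control count can
only remove them) and, at `ψ = 0`, scale-invariant per prey; both
properties are fuzz-tested. No probabilistic enrichment model (SAINT,
MIST) is computed here; such scores can ride along as annotations.

## Three-round screen

Inputs: a bait id, a candidate list (usually the enrichment output),
and a *prediction provider* — any callable mapping an unordered pair to
a list of PAE predictions or `None`. Rounds:

1. bait × every candidate; passers → Group 1, rest → failed set;
2. Group 1 × failed set and Group 1 × Group 1; a failed candidate
   passing against ≥ 1 Group-1 member → Group 2 (with an edge to every
   passing partner); passing intra-Group-1 pairs add edges only.
   Rescued candidates are not reused as screening partners within the
   round — the design is three single passes, not a fixed-point loop;
3. remaining candidates × consolidated core (bait ∪ G1 ∪ G2 by
   default; `include_bait_in_core=False` drops the bait); passers →
   Group 3.

The same thresholds govern every round, including intra-Group-1
scoring (configurable only through `ScoreConfig`). Pairs with no
predictions count as non-passing and are logged and listed in the run
manifest; `strict=True` raises instead. Pair scores are cached by
unordered key, candidates are processed in lexicographic order, and
the manifest (config snapshot, per-round nodes and edge counts,
evaluation count, skipped pairs) is serialised with sorted keys, so
identical inputs give byte-identical manifests. Structural invariants
— exactly one bait, disjoint groups, every edge above threshold, every
node connected to the bait — are asserted after every run.

Export formats: GraphML and a single-file TSV round-trip losslessly
(the TSV interleaves node and edge records under a `record` column so
node groups and bait-only networks survive one file); SIF is a plain
relation list for viewers. The edge `weight` attribute equals LIS.

## Eye-pigmentation quantification

Corrected intensity of one eye = mean red-channel value under the
background mask − mean red under the eye mask (arithmetic means over
mask pixels; green/blue never enter). This orientation follows the
assay's literal description — darker (more pigmented) eyes give larger
corrected values — and `convention="eye-minus-background"` covers the
opposite reading, since the prose of such methods sections is
ambiguous. Masks are user-supplied PNGs; no segmentation is attempted.
Per genotype, the primary summary is the fold change of group means
relative to a control genotype (the control maps to exactly 1.0);
per-fly folds against the control group mean are reported alongside.
Zero or missing control signal raises rather than returning infinities.

## Synthetic data

The generator exists to give every stage a testable ground truth:

- **Counts**: control counts i.i.d. Poisson(`background_rate`, default
  5 per replicate, 4 replicates per arm, 50 preys); enriched preys draw
  bait counts at `background_rate × fold` (default fold 4, 10 preys).
  Poisson is the simplest model consistent with spectral counts; a
  negative-binomial option (`dispersion`) adds overdispersion. Real
  IP-MS counts also carry protein-size and detectability biases and
  shared-peptide ambiguity that are not modelled, so recovery rates
  here speak to the filter's arithmetic, not to real-data sensitivity.
- **PAE maps**: intra-chain blocks uniform on [1, 5] Å; inter-chain
  cells uniform on [20, 31.75] Å except a planted patch drawn from
  [2, 8] Å. The default patch is 60×60 and mirrored on 100-residue
  chains, forcing per-model `LIA = 2·60·60 = 7200 ≥ 3432` and
  `LIS ≥ (12−8)/12 = 1/3 ≥ 0.203`, so planted pairs clear the printed
  cutoffs with margin and decoys score exactly (0, 0). The PAE ceiling
  31.75 is the conventional maximum in AFM output files. Real PAE maps
  have graded, spatially correlated error; the rectangular-patch
  surrogate tests the scoring and screening logic, not AFM itself.
- **Eye images**: an elliptical-disk eye mask and a right-edge
  background strip on a 64×64 8-bit frame; eye red pixels
  Normal(planted mean, `noise_sd`) clipped to range, background
  Normal(200, `noise_sd`), other channels constant. The planted
  corrected intensity is `200 − planted mean`; the default 0.5-ratio
  scenario uses eye means 40 (control, corrected 160) and 120 (mutant,
  corrected 80). Clipping bias is negligible at the default
  `noise_sd = 2` because all means sit far from 0 and 255.

All generators are pure functions of (config, seed) via
`numpy.random.default_rng`; per-pair seeds in the screen scenarios are
derived with a CRC32 mix so providers are symmetric and repeatable.

## Problem sizes and verification

The test suite and `scripts/acceptance.py` use: 200 random PAE maps
(chains 5–50) against the brute-force oracle; 100 planted interactomes
of 20 candidates (5 direct / 3 bridge / 12 decoy) for screen recovery,
each also checked against an independent exhaustive all-pairs oracle
that applies the round semantics by breadth order from the bait; 1,000
fuzzed tables for filter monotonicity; and 100 seeds × 10 flies per
genotype for pigmentation recovery. These sizes make the whole suite
run in well under a minute on one CPU while keeping Monte-Carlo
standard errors an order of magnitude below the asserted tolerances.

## Known limitations

- The LIS/LIA formula and the 12 Å cutoff reproduce a published
  decision boundary but are configurable because the upstream
  convention varies; swapping the aggregation between `mean`,
  `max` and `best_model` can move pairs across the thresholds when
  models disagree.
- The screen trusts its provider: it never re-runs structure
  prediction, and a missing prediction silently (but loggedly) counts
  as a non-interaction under the default policy.
- The pigmentation module measures what the masks delimit; mask
  quality, illumination drift between photographs and white-balance
  differences are the user's responsibility.
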