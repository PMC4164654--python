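# Methods

## Problem and model

The pipeline treats discrimination of sumoylated from acetylated lysines as
a supervised analysis problem whose *product is the selected feature set*,
not the classifier. A 21-residue window (sites 1..21, lysine fixed at site
11) is the unit of analysis; the window length reflects the span of known
sumoylation/acetylation motifs and of acetyltransferase substrate grooves.
Windows overhanging a terminus keep their length via BLANK slots; BLANK is a
distinguished slot state, not a 21st residue letter, and every encoder maps
it to all-zero features, so padding never fabricates signal.

Five per-residue information sources are concatenated into 646 features per
window, in a fixed canonical column order (PSSM 420, Atchley factors 100,
secondary structure 63, solvent accessibility 42, disorder 21; within a
block, sites ascend and subtypes follow a documented fixed order —
alphabetical one-letter amino acids for PSSM columns). Provider values are
consumed as given with no rescaling: a PSSM row is whatever the profile
search produced (integer log-odds or synthetic reals), disorder scores live
in [0, 1]. Every feature column is identified by a descriptor
(block, site, subtype); descriptor identity — never the column index — is
used when feature sets from different datasets are compared or merged. The
Atchley five-factor solution is embedded as a data asset in
`feature_encoding.ATCHLEY_FACTORS` (column order: polarity,
secondary-structure propensity, molecular volume, codon diversity,
electrostatic charge); the central lysine contributes no factor features
since it is constant by construction.

## Class imbalance and the split

Acetylation sites outnumber sumoylation sites roughly 13:1 (2780 vs 218 at
the emulated study scale). Rather than resampling, the negatives are split
by a seeded uniform permutation into disjoint parts of near-equal size
(floor/ceil of N/n_parts, remainders to the later parts — 2780 into 3 gives
926/927/927), each bundled with all positives. The split is at window
level, as is standard for this workflow; windows from one protein may land
in different parts, which mildly flatters cross-validation when homologous
windows exist (the generator produces one protein per window, where the
issue vanishes).

## mRMR ranking

Features are ordered by greedy forward selection under the difference (MID)
criterion: relevance is I(feature; class), redundancy the mean mutual
information against the already-selected features, and each step maximizes
relevance − redundancy; ties go to the smaller column index, making the
ranking deterministic. MI is the plug-in estimator in bits (log base 2 —
any consistent base gives the same order). Because plug-in MI needs
discrete variables, continuous columns are cut into three states at
mean ± 1 σ computed per column over the whole dataset; binary and one-hot
columns keep their native two states; constant columns collapse to one
state. The ranking is computed once per dataset before cross-validation,
mirroring the classical mRMR+IFS workflow; this leaks label information
into feature selection, so reported jackknife metrics are optimistic as
estimates of generalization. `ifs.foldsafe_ifs_curve` re-ranks inside every
leave-one-out training fold for leakage-free estimates; it costs n full
rankings and is intended for small diagnostic runs.

## IFS, classifier, and metrics

For k on a grid, the top-k prefix of the mRMR table feeds a random forest
with the classical Weka defaults: 10 unpruned trees, ⌊log₂ m⌋+1 candidate
features per split, majority vote (scikit-learn's
`RandomForestClassifier`). Evaluation is strict jackknife: each sample is
predicted by a forest trained on the other n−1, with the per-fold random
state derived deterministically from (run seed, fold index) via
`numpy.random.SeedSequence`, so results are exactly reproducible. A
stratified k-fold fallback exists for large problems. Metrics are SN, SP,
ACC and MCC from the aggregated confusion counts; MCC is defined as 0 when
its denominator vanishes, while SN/SP raise if their own denominator is
zero (an evaluation set without one class is a usage error). The optimal k
is the argmax of MCC, smallest k on ties; prefixes whose classifier cannot
be built are recorded as missing rather than failing the run.

### Instability of the optimal k

A property worth stating plainly: past the informative prefix, the
jackknife MCC curve of a random forest is essentially flat, because extra
uninformative features barely degrade a forest. The argmax over a flat,
noisy curve is close to uniformly distributed over the plateau, so the
*location* of the optimal k — and therefore the exact membership of the
optimal feature set — is unstable between seeds and between replicate
datasets, even when the *performance* at the optimum is stable. The
parameter-recovery experiment on synthetic data shows this directly: the
optimal MCC reliably clears 0.6, and the top of the mRMR table reliably
contains the planted signal, but the Jaccard overlap between the
(argmax-selected) optimal set and the planted ledger is small and
seed-dependent because the argmax typically lands tens of features deep
into the plateau. Published optimal-k values from this workflow should be
read with the same caution; prefix-containment statements ("the signal is
in the top 20") are robust where set-identity statements are not.

## Analysis stage

Optimal sets are merged by descriptor identity with per-dataset provenance.
Summaries are plain count tables: per block (with each block's total, so
fractions like 8-of-21 disorder features are readable), per site
cross-tabulated by block, and per subtype within a block — the marginals
agree pairwise by construction and are property-tested. Positional
amino-acid frequency matrices are computed per class over the raw windows;
BLANK slots are excluded from numerator and denominator (a row is the
residue distribution among windows actually covering that site), which is
the interpretable choice for terminus-padded data and is asserted in tests.
Matrices are written as TSV consumable by standard logo tools; no plotting
dependency is part of the core.

## Synthetic data: what it emulates, and what it does not

The generator draws one protein per window: flanks from a fixed proteome
background composition, the annotated lysine at the center, with a 10%
chance of placing the site near a terminus so padding is exercised.
Planted class structure, all configurable:

* **Motif** — with probability `motif_prob` (default 0.8) a positive window
  carries an aliphatic Ψ at site 10 (V/I/L drawn 0.4/0.4/0.2, matching the
  V/I dominance reported for sumoylation) and E at site 13.
* **K enrichment** — each flanking site of a negative window becomes K with
  excess probability 0.10, mimicking the lysine-rich acetylation context.
* **Secondary structure** — per-residue states drawn H/E/O at 0.30/0.20/0.50,
  with a +0.2 excess of 'other' at site 13 of positives (taken
  proportionally from helix and strand).
* **Solvent accessibility** — buried/exposed at 0.45/0.55, with optional
  per-site exposed shifts (none by default, matching the observation that
  accessibility discriminates the two modifications poorly).
* **Disorder** — Beta-distributed with concentration 20 (sd ≈ 0.1, the
  within-class spread of a well-behaved disorder predictor), mean 0.5
  everywhere except sites 12/14/15/16, where positives have mean 0.65 and
  negatives 0.55 — a downstream-weighted disorder difference.
* **PSSM** — a residue's row is a noisy own-residue profile: +4 in its own
  column, −1 elsewhere, Gaussian noise sd 1.0. Sequence-level class
  differences thereby propagate into the PSSM block the way conservation
  differences would.

`planted_descriptors` returns the signal ledger used as ground truth by
recovery tests: one *primary carrier* per effect channel — the PSSM columns
of the planted residues, the shifted one-hot state, the shifted disorder
sites, and at each motif site the single Atchley factor with the largest
analytic standardized class difference (computed from the configured
residue distributions, not from data). Secondary encodings of the same
effect (the other four factor projections, the complementary one-hot bits)
are deliberately not ledgered: a redundancy-minimizing selector keeps one
representative per channel. The diffuse K enrichment touches the K column
and factor projections of every flank site weakly (≈0.25 σ each) and is
likewise not ledgered; it acts as a realism/nuisance term.

What the generator does **not** emulate: homology between proteins (every
window is independent, so jackknife results are not flattered by relatives
across folds — unlike real UniProt-derived data), realistic evolutionary
PSSM structure (columns are conditionally independent given the residue),
position-dependent background composition, or correlated
structure/disorder along the chain (providers are drawn per residue).
Passing recovery tests therefore demonstrates correctness of the machinery
on clean, independent signal, not performance expected on curated
proteome data.

## Numerical and scale choices

* Discretization thresholds use the biased (ddof = 0) standard deviation;
  for a constant column σ = 0 and the column collapses to one code.
* MI sums skip zero cells (0·log 0 = 0); no pseudocounts.
* Jackknife per-fold seeds come from `SeedSequence([seed, fold])`, keeping
  every derived seed below 2³¹.
* Desk-scale problem sizes: the recovery experiment uses 150+150 windows
  with the IFS grid k = 1..101 in steps of 5 (21 jackknife scans, ≈90 s on
  one CPU); null calibrations use n = 60 with 10 replicates, summarized by
  the *mean* MCC across replicates — the mean is the calibration-of-bias
  statistic (per-replicate null MCC at n = 60 has sd ≈ 0.13, so individual
  replicates legitimately stray past ±0.25). Full 646-prefix scans at study
  scale (3000 windows) are cluster-sized and out of desk scope.

## Known limitations

* One-shot whole-dataset mRMR ranking leaks labels (see above); fold-safe
  re-ranking is provided but quadratically expensive.
* Plug-in MI is biased upward at small n; rankings among near-zero-relevance
  features are noise.
* The optimal-k argmax instability above is inherent to IFS-with-forests,
  not an implementation artifact.
* Provider alphabets are strict (H/E/O, B/X); 8-state secondary structure
  or continuous accessibility must be reduced upstream.
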