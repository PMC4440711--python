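# Methods

## Model and assumptions

`pwmcleave` models primary substrate specificity of a protease as a
position weight matrix (PWM) over the five Schechter–Berger positions
P3–P2′ around the scissile bond. The matrix is a log2 ratio of aligned
foreground frequencies (substrates selected by the enzyme) to the residue
composition of an unselected background library; a bond's score is the sum
of its five window cells, and a bond is called cleaved when the score
reaches an enzyme-specific threshold. The model is purely sequence-local:
it knows nothing about structure, solvent accessibility or localisation,
and the five-position window is fixed (cross-validation with wider windows
is known not to improve the statistics materially for MMPs).

Two modelling choices deserve spelling out:

* **Background frequencies are pooled, not positional.** Background
  peptides carry no cleavage annotation, so they cannot be aligned on a
  bond. The default background is therefore the position-independent
  residue composition of the whole background set, broadcast to all five
  columns. For scaffolded libraries where every peptide shares a layout, an
  opt-in positional mode (`compute_frequencies(...,
  positional_window_start=...)`) uses per-position composition over a fixed
  window instead.
* **Zero foreground frequencies become the offset, with no pseudocounts.**
  A residue never observed at a position contributes exactly `offset`
  (a negative log2 penalty) rather than −∞ or a smoothed estimate. This
  keeps the threshold and the matrix on the same, directly interpretable
  scale, and makes the offset a genuine tuning parameter of the method.

The decision rule is inclusive (`score ≥ threshold`): the threshold is the
minimal score still called cleaved. Ties are measure-zero on real data.

## Parameter selection

`offset` and `threshold` are selected by exhaustive grid search under
k-fold (default 10) cross-validation at the substrate level: for each grid
cell, the matrix is re-derived on each fold's training substrates with the
cell's offset and evaluated on the held-out fold's labelled bonds with the
cell's threshold; the cell maximising mean F1 across folds wins. Labelled
bonds are the annotated bond (positive) and every other full-window bond
of the same peptide, constant flanks included (negatives) — the flanks are
physically present in the phage construct, so a scanner will meet them.

Defaults: thresholds −2.0…3.0 in steps of 0.1 and offsets −8.0…−1.0 in
steps of 0.5 (log2 units), which bracket the optima published for all
eleven MMP matrices. Ties at the maximal mean F1 break toward the higher
threshold, then the larger (less negative) offset — the more conservative
model. Folds with no positive bond are flagged and excluded from
averaging. Fold summaries report the mean and *sample* standard deviation
of each metric. A substrate-level 2:1 split (`split_train_test`) supports
an internal test: grid search on the larger share, one evaluation of the
frozen parameters on the smaller.

Implementation note: a window score is linear in the offset — the sum of
the nonzero-cell log2 ratios plus (number of zero cells) × offset — so
frequencies are derived once per fold and the entire grid is evaluated by
vectorised arithmetic. This is an exact restatement, not an approximation;
the full default grid (15 × 51 cells, 10 folds, 300 substrates) runs in
well under a second.

## Evaluation machinery

* Confusion metrics: TPR/sensitivity, specificity, accuracy, precision,
  FPR, MCC and F1. Zero-denominator rates are reported as 0 and flagged,
  and flagged values are excluded from fold averaging.
* ROC/AUC by threshold sweep (scikit-learn); the area equals the
  Mann–Whitney pair statistic with ties counted ½, which the test suite
  checks against brute-force pair counting.
* Two-sample Kolmogorov–Smirnov D (scipy) between the score distributions
  of cleaved and non-cleaved bonds, checked against a brute-force ECDF
  maximum.
* Protein-level evaluation emulates external validation: positives are
  annotated full-window bonds, negatives are sampled without replacement
  from the same proteins' other bonds at a 1:100 ratio (all of them, with
  a warning, if the pool is smaller).
* Cleavage-position refinement: an experimentally reported bond that
  scores below threshold is reassigned to the highest-scoring
  above-threshold bond within ±4 bonds (ties to the smaller shift, then
  the N-terminal side), if one exists. Refinement never moves a site
  further than the window and never lowers its score.

## Virtual mass spectra

Cut boundaries are the protein termini plus every predicted site. The
default *partial* digest enumerates every contiguous fragment between any
two boundaries — (n+1)(n+2)/2 fragments for n sites — because partially
cleaved species are observable in practice and the per-fragment intensity
model is well defined for any boundary pair; a *complete* mode keeps only
adjacent pairs (n+1 fragments). Intensity is `100 · ws1 · ws2` with each
`ws` the boundary site's score normalised linearly to [0, 1] between the
matrix's minimal and maximal achievable scores (sums of per-column
extrema); protein termini weigh 1.0, so the full-length species always has
intensity 100. Masses are neutral monoisotopic sums of the standard
20-residue table plus one water (18.010565 Da), via pyteomics; no charges,
adducts, modifications or isotope envelopes are modelled. Fragments
containing nonstandard residues have no defined mass and are reported as
such.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the phage-display construct: constant flanks
(`ggsg…tasgaet`) around a variable hexamer, with the designated bond
between hexamer positions 3 and 4 so the P3–P2′ window spans hexamer
positions 1–5. Substrate window residues are drawn from per-position
probability vectors (`deterministic_motif`, `peaked_motif(weight=0.7)` for
a noisy-but-dominant motif, as phage-display logos typically show);
remaining variable residues and background hexamers are uniform. Default
set sizes are 300 substrates and 766 background peptides, the study's
conditions. Synthetic proteins for protein-level evaluation are uniform
400-mers with three non-overlapping planted windows each.

Passing tests on these data show that the estimator recovers a planted
signal at realistic sample sizes and that the evaluation machinery is
correct; they do not show that real MMP specificity is as concentrated as
the planted motif, nor do they reproduce selection biases, residue
composition or correlated positions of a real phage library.

One structural caveat the tests make explicit: a uniform ("null") motif
inside the constant-flank scaffold is *not* information-free, because the
flanks' composition differs from the variable region's and the matrix
learns flank-vs-hexamer position (grid-max F1 ≈ 0.45). The no-information
null — background equal to foreground — is therefore constructed
scaffold-free (fully uniform 17-mers), where the grid-max F1 settles at
the all-positive bound 2p/(1+p) ≈ 0.14 for prevalence p = 1/13.

## Numerical choices and degenerate inputs

Scores accumulate in double precision; PWM files round-trip at 1e−6
(values written at 6 decimal places). A matrix with `score_min ==
score_max` is rejected as degenerate (it cannot rank bonds, and the
spectrum normalisation would divide by zero). Background sets must cover
all 20 residues, otherwise the log ratio is undefined and derivation
fails. Windows containing nonstandard residues (X, B, Z, U, …) are
skipped with a warning — an *unscorable* signal distinct from a low score.
Sequences shorter than five residues have no scorable bond. Normalised
weights are clipped to [0, 1]. One integer seed drives splitting, fold
assignment and negative sampling through independent derived streams;
outputs embed the seed and input checksums in their headers.

## Problem sizes

The self-contained test suite and the acceptance script run at the study's
nominal scale — 300 substrates, 766 background peptides, the full default
grid under 10-fold CV, 10 synthetic proteins of length 400 with 1:100
sampled negatives — which completes in a few seconds thanks to the
vectorised grid evaluation.

## Known limitations

* No structural or contextual filters (secondary structure, disorder,
  accessibility, localisation): sequence-only scores over-predict on
  globular proteins, as any PWM method does.
* The published per-enzyme substrate tables are not redistributable here,
  so the reproduction tests against them are inactive until a user
  transcribes the supplements (see `tests/test_acceptance.py`).
* The exact grid resolution and fold seeds behind the published
  per-enzyme optima are unknown, so recovering those exact
  threshold/offset pairs from transcribed data is expected only
  approximately.
* Background positional mode assumes a shared peptide layout; it is not
  meaningful for heterogeneous background sets.
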