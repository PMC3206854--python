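# Methods

## Model

A motif of length `m` is modelled by a feed-forward network with one
sigmoid hidden layer and a sigmoid output mapping an encoded core (plus
optional context features) to a score in (0, 1). For a peptide longer than
`m`, the network itself chooses the register: all `L − m + 1` cores are
scored and the argmax is the peptide's *binding core* (ties go to the
smallest offset). Training is stochastic and online — per epoch the
training peptides are visited in a seeded random order, each peptide's best
core is re-selected under the *current* weights, and a single gradient step
on `E = ½(o − t)²` is taken at that core. Re-selecting per example (rather
than once per epoch) uses the freshest weights and converges faster; it is
the package's fixed convention. No gaps are ever introduced: the alignment
is purely a choice of an ungapped window.

Assumptions: one dominant ungapped motif per dataset; a monotone
relationship between motif match and the quantitative readout; residues act
approximately independently per position (the hidden layer can capture
limited pairwise structure).

## Encodings

* *sparse*: one-hot over the 20 residues.
* *blosum*: the residue's BLOSUM62 row divided by 5 (similar residues get
  similar inputs). `X` encodes as the mean of the 20 residue vectors in
  either scheme.
* Optional features, frozen in this order after the `m·20` core block: PFR
  composition (mean residue vector of up to `flank_len` residues on the N
  side, then the C side; zero vector when no flank exists), PFR lengths
  (`min(actual, flank_len)/flank_len` per side), and peptide length
  (`1/(1 + exp((L − 15)/2))`, a logistic squashing centred at 15 residues,
  the middle of typical array/MHC-II peptide lengths). The PFR and length
  feature forms are this package's own bounded parameterisations of
  "flank composition / flank length / peptide length" information; other
  implementations of this model family may use different functional forms
  with the same information content.

## Preprocessing

Raw measurements are rescaled to [0, 1] per cross-validation training set:
optional natural-log transform (shifted by `−min + 1e−6·range` if any value
is ≤ 0), symmetric clamping of outliers at mean ± 3 population standard
deviations, then linear mapping of the clamped min/max onto [0, 1]. The
clamp-then-minmax order removes empty sparse tails from the target
spectrum. Test folds are rescaled with their training fold's parameters and
clipped to [0, 1]; 0/1 class labels pass through unchanged.

## Cross-validation and ensembles

Partitions: random near-equal split; Hobohm-1 greedy clustering on ungapped
identity (processing order: descending length, ties alphabetical; a
sequence joins the first representative with identity *strictly* greater
than the threshold; identity = best ungapped overlap matches / length of
the shorter sequence, with overlaps shorter than the motif length ignored
when a motif length is supplied); or single-linkage clustering on shared
identical substrings of at least the smallest candidate motif length.
Clusters are dealt whole, largest first, onto the currently smallest fold;
optionally only one representative per cluster is retained. Constant flanks
shared by ≥ 95% of the peptides (array linkers) can be trimmed before
identity computation.

Per fold, a grid of (hidden sizes × random seeds) networks is trained on
the other folds. *Fast* evaluation uses the held-out fold both for early
stopping and for the performance estimate; *exhaustive* evaluation nests a
second level — each remaining fold takes a turn as the stopping set, the
best-stopping network of each inner step is kept, and the held-out fold is
predicted by their average. With 2 folds the inner level degenerates; the
remainder then serves as both training and stopping set, which makes the
two modes coincide when stopping is off (a tested invariant). Every record
thus receives exactly one cross-validated prediction from networks that
never trained on it. The final ensemble keeps the top-N networks per fold
by stopping-set RMSE. Ensemble predictions are the mean of member best-core
scores; the reported core is the plurality of member choices after shifting
each member's register by its logo offset (ties to the smallest offset,
clipped into the valid range).

When a motif-length interval is given, the whole cross-validation is
repeated per length and the length with the lowest cross-validated RMSE is
selected (ties to the shorter length). The RMSE table carries a bootstrap
mean and standard error (100 seeded resamples of the prediction pairs) so a
flat length dependence is recognisable.

## Logos and offset correction

Each member network is characterised by scoring `n_background` random
peptides (default 100,000, length `m + 2·flank_len`) drawn i.i.d. from a
bundled Swiss-Prot-like residue composition, and stacking the best cores of
the top 1% into a PSSM (flat pseudocount 1/20 per residue per column).
Networks may learn the same motif in shifted registers, so the per-network
PSSMs are aligned by simulated annealing over integer column offsets
(default ±4): a move shifts one PSSM by ±1 and is accepted with probability
`min(1, exp(ΔI/T))`, where `ΔI` is the change in summed column information
of the frequency-averaged matrix restricted to the columns covered by every
PSSM (an empty overlap scores −∞). T cools geometrically from 1.0 to 0.01
(×0.95 every 20·n proposals, then 200·n proposals at the final
temperature); the best state seen is returned, re-centred to zero (lower)
median — hence never worse than the unshifted overlay. On small instances
the annealed optimum matches exhaustive enumeration (tested). The
re-aligned cores of all networks are pooled into the combined logo
(`R_i = log2 20 + Σ f log2 f`, `h = f·R`, no small-sample correction) and a
half-bit log-odds matrix `2·log2(f/q)`. When `flank_len = 0` the background
windows equal the motif length and shifted cores cannot be re-extracted; in
that case (or when the user skips the correction) the unshifted core pool
is used. Letter colours follow chemical classes (polar green, amide pink,
basic blue, acidic red, hydrophobic black).

## Defaults and numerical choices

| parameter | default | rationale |
|---|---|---|
| folds | 5 | standard for this data scale |
| seeds per architecture | 5 | ensemble variance reduction |
| hidden neurons | [3] | sufficient for single-motif regression |
| learning rate | 0.05, constant | stable for sigmoid nets of this size |
| epochs | 500 | conservative; early stopping optional |
| weight init | uniform ±0.05 | small symmetric start |
| motif length | **required** | problem-specific |
| rescaling | linear | log is data-dependent, left to the user |
| AUC threshold | 0.5 | on the rescaled observation scale |
| pseudocount | 1/20 per column | keeps log-odds finite at 1,000 cores |
| background size / top fraction | 100,000 / 1% | stable 1,000-core PSSMs |

Determinism: every run is a pure function of one integer seed. Per-network
seeds are derived from (run seed, fold, inner step, architecture index,
seed index); epoch shuffles come from a generator seeded by the network
seed. Model files are JSON with full-precision floats, so save → load is
the identity on every weight and bit-identical re-runs produce
byte-identical model files (tested). Duplicate peptides are kept by default
(arrays measure replicates); an option collapses them to their mean first.

## Synthetic benchmarks — what they show and what they do not

`synthetic.make_planted_motif_dataset` emulates receptor-binding data:
background-composition peptides of lengths 10–16, a hidden 9-mer position
weight matrix with three anchor positions (anchor residue mass 0.9 over 2–3
residues, background elsewhere), clean score = best-window log-likelihood
mapped affinely to [0, 1], plus Gaussian noise (sd 0.05 — small enough to
keep recovery sharp while exercising regression rather than
classification). `synthetic.make_cleavage_dataset` emulates a protease
microarray: `GAGA + 5 random residues + GAGA` (lysine excluded, as on
arrays where free amines are the detection chemistry), with targets in a
high band (0.85–0.97) for peptides containing cleavable arginine, a very
high band (0.97–1.0) for R–R pairs, and a low band (< 0.1) otherwise —
reproducing the two-population structure of real digestion data.

These generators produce position-independent backgrounds, a single exact
planted rule, and homoscedastic noise. Real peptide data has compositional
bias, correlated synthesis/measurement errors, batch effects and possibly
multiple motifs; passing the synthetic benchmarks demonstrates that the
estimator and its machinery are correct and recover a true signal under the
stated noise, not that any particular biological dataset will reach the
same accuracy.

Problem sizes used by the test suite and `scripts/acceptance.py` —
1,500-peptide motif recovery (150 epochs, 2 seeds), 5,000-peptide cleavage
run (100 epochs, early stopping), a 3-length scan at 1 seed and 100 epochs,
and a 20,000-peptide background for the flank-less cleavage logo — were
chosen as the smallest sizes at which the recovery properties are stable
across seeds; the length scan uses peptides of lengths 11–16 so that every
candidate length in {7, 9, 11} fits every peptide.

## Known limitations

* One motif per model; mixtures of specificities blur into one logo.
* No gapped alignment, by design.
* The exhaustive CV mode trains `n·(n−1)·seeds·architectures` networks and
  is correspondingly slower.
* Correlations are undefined (reported as absent, with a warning) on
  zero-variance inputs, and AUC on single-class observations.
* Hobohm-1 with threshold 1.0 merges nothing, since the similarity test is
  strict (`> threshold`).
* The annealer is stochastic; its oracle-equivalence is verified on small
  instances, and larger instances inherit only the best-seen ≥ start
  guarantee.
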