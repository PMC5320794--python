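# Methods

## Model architecture

The profile HMM is the textbook match/insert/delete architecture restricted
to single-hit local alignment in the model:

* nodes `k = 1..M` with states `M_k` (emitting), `I_k` (emitting, between
  nodes `k` and `k+1`) and `D_k` (silent);
* entry `B -> M_k` uniform at `1/M`; there is no entry into deletes or
  inserts — partial-domain matches enter at the first matched node;
* early exit `M_k -> E` with constant probability `epsilon` (default 0.05)
  for `k < M`; `M_M -> E = 1` and `D_M -> E = 1`;
* flank states `N` (before `B`) and `C` (after `E`) emit background
  residues with self-loop probability `p_flank`.

All nine core transitions (`M/I/D -> M/I/D`) are allowed. Internally every
probability is handled as a natural logarithm; bit scores appear only at
the reporting boundary. The Forward recursion is vectorized over nodes,
with the within-row delete chain resolved by an explicit scan; Viterbi uses
plain loops with stored back-pointers and a fixed tie order (B < M < I < D,
then the lower node index) so outputs are bit-for-bit reproducible.

### Null model and flank cancellation

The null is i.i.d. Robinson & Robinson (1991) amino-acid frequencies with a
geometric length distribution, `P(x) = (1-p1) p1^L prod q(x_i)`, `p1 =
350/351` by default (mean length 350). `p_flank` is tied to `p1`: a flank
residue contributes `ln(p_flank q(a))` to the model and `ln(p1 q(a))` to
the null, so unrelated flanking sequence cancels exactly in the log-odds
bit score. Ambiguity codes (X/B/Z/U/O) emit `1/20` in every emitting state
*and* in the null, making their log-odds contribution exactly zero; this is
also why masking residues to `X` neutralizes rather than penalizes them.

### Parameter estimation

* **Match columns.** An alignment column becomes a match node iff its gap
  fraction is strictly below 0.5 (ties go to insert). Configurable.
* **Sequence weights.** Henikoff & Henikoff (1994) position-based weights
  over match columns, normalized to sum to the number of sequences.
* **Emissions.** Weighted counts with background-proportional pseudocounts
  `e_k(a) = (c_k(a) + alpha q(a)) / (C_k + alpha)`, `alpha = 1` by default.
  Insert states emit the background.
* **Transitions.** Weighted observed M/I/D transitions plus a pseudocount
  vector per source state, renormalized (match rows are then scaled by
  `1 - epsilon` to make room for the early exit). The default pseudocount
  is the flat +1 per allowed transition. Family sub-models are built with
  match-favoring vectors — (0.9, 0.05, 0.05) from M, (0.7, 0.25, 0.05)
  from I, (0.7, 0.05, 0.25) from D — because with only one to eight
  training sequences a flat +1 puts near-half mass on non-match moves
  (t(M->M) = 0.5 for a single sequence, about -0.74 nats per node, which
  swamps the emission signal entirely). Single-sequence families
  additionally use `alpha = 2`: large enough to avoid overconfident
  emissions, small enough that the sub-model's own generative samples
  remain recognizably members of it.

## E-values and thresholds

Calibration scores `n_sim = 500` background sequences of fixed length 350
(a documented simplification: length is not matched per target) and fits a
Gumbel by maximum likelihood — `lambda` via Brent root-finding on the
standard MLE equation, `mu` in closed form. E-values follow
`E(S) = Z(1 - exp(-exp(-lambda (S - mu))))` with `Z` defaulting to the
number of searched sequences. Note the fitted `lambda` on Forward scores is
considerably steeper than the ~`ln 2` typical of max-based local alignment
statistics; E-values far into the tail are therefore extrapolations and
should be read comparatively, not literally.

The **trusted cutoff** is the maximum E-value over a curated positive set;
sensitivity on that set is 100% by definition. The relaxed default
threshold is `E <= 1e-3`. Both are stored in the model file and the mining
report records which was applied.

## Bias-composition filter

An opt-in masking stage: every length-40 window with Shannon entropy below
2.2 bits is replaced by `X`, flagged windows are merged, and sequences
shorter than the window are treated as one window. Masking is deliberately
*score-neutral* for residues the model does not match (see above), so the
filter removes hits only when the biased region itself carries the
homology signal — which is precisely the failure mode that makes
composition filtering dangerous for LPMOs, whose domains legitimately
contain S/T-rich tracts. Mining therefore defaults to no filtering.

## Hallmark annotation

* **Signal peptide.** An explicit heuristic (neural predictors are known to
  miss the weak cleavage sites of some LPMO families): candidate cleavage
  positions c in [10, 45] require (a) a run of >= 6 residues with mean
  Kyte–Doolittle hydropathy >= 1.5 inside [c-12, c-1]; (b) residues at c
  and c-2 drawn from the small/neutral (-1) and (-3) sets of the classic
  A-X-A rule; (c) non-negative net charge before the h-region. Among valid
  candidates, one followed by histidine is preferred (mature LPMOs start
  with the brace histidine); if only that preference selected it, the call
  is flagged `weak` rather than silently accepted.
* **Histidine brace.** Mature residue 1 must be H and the residue the
  Viterbi path aligns to the annotated second brace column must be H; a
  deletion there is reported as its own failure reason.
* **Motif.** Residues aligned to the annotated triple are matched against
  `[NQE]-X-[FY]`; a first-position mismatch with an intact third position
  is a `variant` (a warning, never a rejection — characterized LPMOs with
  alanine there exist), anything else non-canonical is `absent`.
* **Linkers.** Spans covered by any 20-residue window with S/T/A fraction
  >= 0.6, merged, minimum length 15.
* **CBM1.** A secondary profile HMM (same machinery, packaged synthetic
  alignment); envelopes with E <= 1e-3 are reported, found copies are
  masked and the search repeated so multiple modules are recovered.
* **Architecture string.** Elements (SP, LPMO core envelope, linkers
  extending beyond the core, CBM1 spans) ordered by start position, e.g.
  `SP-LPMO-linker-CBM1`. Annotation is a deterministic function of
  (sequence, model, path) and depends only on aligned columns, never on
  absolute alignment coordinates.

Model annotation itself (locating the hallmark columns in a training
alignment) picks the two most H-rich match columns (each >= 0.7 non-gap H
frequency) as the brace and the consecutive triple C-terminal of the
second brace column maximizing `freq([NQE]) + freq([FY])` as the motif;
explicit overrides always win, and failure to find H-rich columns is an
error instructing manual annotation rather than a silent guess.

## Family assignment and novel candidates

Each hit is scored against per-family sub-models built from the family
subsets of the training alignment; the best family by E-value wins if it
reaches `family_cutoff_E` (default 1e-5; the choice is free and exposed),
otherwise the hit is a `novel-candidate`. Ties break toward the family
with more training sequences, then alphabetically.

The synthetic novel-candidate generator reflects what a novel family looks
like: it shares the hallmarks and *scattered* residues with every known
family while resembling none, so candidates are per-column mosaics (each
family-discriminative column drawn from a uniformly random family, with
background substitutions at rate 0.6, hallmark columns kept canonical).
Because the weak single-sequence sub-models have broad self-sample score
distributions, mosaics are additionally rejection-verified against the
defining oracle (combined E <= 1e-3 and every family E > cutoff); the
returned set carries the novel-candidate property by construction rather
than by a tuned mutation rate.

## Synthetic training data

The shipped 14-row alignment emulates the *shape* of a curated cross-family
LPMO training set: 4 AA9-like, 8 AA10-like, 1 AA11-like and 1 AA13-like
rows; hallmark columns (H at nodes 1 and 60, N-X-F at 80–82, G at 20/40/70,
P at 50) shared by all rows with one AA10 row carrying the alanine motif
variant; an S/T-rich conserved block at nodes 90–113; family-specific
consensus at all remaining columns with 8% within-family substitution; a
6-column insertion private to the AA9-like rows and short deletions in the
single-sequence rows. What it does **not** emulate: real evolutionary
covariation, realistic family divergence times, domain-length variation,
or any actual LPMO sequence content — so green tests certify the
*machinery* (construction, scoring, calibration, thresholding, annotation
logic), not performance on real proteomes. The mining fixture (5 forced
positives + 50 background decoys, plus one S/T-biased partial positive for
the filter experiment) defines the study conditions used by the tests and
the acceptance script; positives are resampled until indel-free within 4
nodes of each hallmark so that alignment-based annotation is exact (an
indel adjacent to a conserved column lets the aligner slide the gap).

## Numerical choices and degenerate inputs

* Stochastic rows are validated to sum to 1 within 1e-12; the LPHMM1 text
  format stores natural logs at 12 significant digits (round trips agree
  to < 1e-9; `-inf` encodes zero probability).
* Empty sequences score `-inf` (the core must emit at least one residue);
  empty proteomes yield empty reports; an uncalibrated model is a hard
  error at mining time, not a warning.
* E-values saturate at `Z` in double precision for scores far below `mu`;
  monotonicity guarantees apply to the unsaturated range.
* k-means is scikit-learn's (k-means++ init, best of 10 seeded restarts);
  UPGMA is scipy average-linkage with ultrametric node heights equal to
  half the merge distance; no implicit expression normalization is applied
  (an explicit log2 option exists, since the provenance of any real
  matrix's normalization is the user's knowledge, not ours).
* Problem sizes in tests and the acceptance script (200–500 enumeration
  cases on models with M <= 4 and L <= 6 over a 4-letter alphabet, 500
  calibration sequences, 56-protein fixture proteomes, 200-gene expression
  matrices) were chosen so that the full pipeline re-runs comfortably on a
  single CPU while every statistical check retains clear margins.

## Known limitations

* Single-hit architecture: one domain envelope per protein (CBM1 search
  works around this by mask-and-rescan). No multi-domain decomposition.
* The bias filter is an entropy mask, not a composition-adjusted null
  correction; it reproduces the qualitative filter-loss phenomenon, not
  any particular tool's internals.
* The signal-peptide heuristic is rule-based and tuned for the fungal
  secretory signals relevant here; it is not a general predictor.
* Gumbel tail extrapolation (above) — compare E-values within a run.
* HMMER3 `.hmm` files are neither read nor written; LPHMM1 is the only
  persistence format.
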