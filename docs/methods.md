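# Methods

## The identification model

A panel of n authentic standards is distributed over k pooled mixtures so
that each compound occurs in exactly two of them; the unordered pair of
mixture labels is the compound's *pair-code*.  Injecting the k mixtures in
a batch turns identification into a binary readout: a compound is confirmed
iff it is detected in both of its code mixtures and in no other.  With
C(k,2) available codes, up to 6 (k = 4), 10 (k = 5) or 15 (k = 6) compounds
that neither retention nor spectra separate can still be distinguished,
because at most one candidate's code can match a peak's across-mixture
occurrence.  Confirmed entries donate their freshly measured retention
(intensity-weighted mean of the two supporting peaks) back to the library,
which then identifies the biological samples of the same batch.

Assumptions built into this model:

* standards appear only in the mixtures they were pipetted into — the
  pattern is ground truth, not an estimate;
* spiked amounts are tuned to give clearly detectable peaks, so the
  not-found threshold can be set high and absence is informative;
* within one batch, replicate peaks of one compound agree in retention far
  more tightly than the library-to-batch matching window.

## Retention indices

Retention times are converted to retention indices by van den Dool–Kratz
linear interpolation between co-injected n-alkane anchors (RI = 100·carbon
at each anchor).  Linear interpolation is the appropriate convention for
temperature-programmed GC; the logarithmic (isothermal) variant is not
implemented.  Beyond the first/last anchor the terminal segment is
continued linearly and the value is flagged as extrapolated.  The default
anchor set C10, C12, C15, C17, C19, C22, C28, C32, C36 has uneven carbon
gaps (C17 instead of C18, which coelutes with analytes near RI 1800); the
formula needs no special-casing for that.  `rt_for_ri` is the exact inverse
(round-trip to 1e-9 relative), used to place windows and by the simulator.

Cross-setup diagnostics (`shift_report`) compare per-compound retention
between two setups: deltas with mean/median/SD, a histogram (default bin
width 5 — RI units for GC, seconds for LC), and the explicit list of
elution-order inversions (pairs ordered oppositely in the two setups; ties
in either setup are not counted).  `ambiguity_risk` chains library entries
along the RI axis by single linkage (gap ≤ tolerance) to show which entries
become interchangeable once retention shifts by a given amount.

## Spectral similarity

Match factors are the Stein–Scott weighted cosine: peaks are binned to unit
m/z (intensities summed per bin), weighted w = intensity^a · mz^b with
defaults a = 0.6, b = 3, and the squared cosine of the weighted vectors is
scaled to 0–1000 and rounded.  Forward mode runs over the union of occupied
bins; reverse mode restricts to the reference's bins, making it tolerant to
impurity peaks in the query — which is why the identification pipeline uses
the reverse score against library spectra.  The composite variant with a
ratio-of-adjacent-peaks term is deliberately not implemented: the pure
weighted cosine is hand-checkable and the weighting is configurable; the
binning/weighting hook is the extension point.  Scores from commercial
search tools are therefore comparable in behaviour but not bit-identical.

## Identification pipeline and its tolerances

Per entry and mixture run, a peak *qualifies* when

* its RI (GC mode) or RT (LC mode) lies within the matching window of the
  entry's expectation — defaults **±10 RI units** / **±30 s** (the LC value
  reflects the observed need to re-align LC retention by some tens of
  seconds between experiments);
* its intensity clears max(absolute floor, **5%** of the run's base peak);
* when both sides carry spectra, reverse match factor ≥ **650**;
* it is not a gap-filled (imputed) peak, unless explicitly included —
  imputed values defeat the purpose of a presence/absence readout.

The matching window absorbs library-to-batch drift, and is therefore wide
enough that neighbouring isomers qualify for each other's peaks.  Two
exclusion rules clean this up before the pattern is scored:

1. **coding**: a peak in run L is released by claimants whose codes do not
   contain L, provided some claimant's code does (this lets coeluters with
   fully separated codes, e.g. {B,C} vs {A,D}, both confirm);
2. **occurrence**: among claimants coded for L, the peak belongs to the one
   whose code equals the peak's across-mixture occurrence — the set of runs
   showing a peak at that retention within the *clustering tolerance*
   (default **1 RI unit** / **5 s**), which should be set to roughly 3× the
   within-batch retention scatter.  Swaps are logged; if two claimants with
   the same code match, both become `ambiguous`; if no claimant matches,
   everyone keeps the peak and the resulting `conflict` is reported rather
   than guessed away.

A confirmation additionally requires a *consistent pair*: supporting peaks
in the two code mixtures within the clustering tolerance of each other
(they are replicate injections of one analyte).  Among consistent pairs the
most intense wins.  Without this, an absent compound could assemble a
"confirmed" pattern from two different neighbours' peaks, one per mixture —
the one failure mode the plain binary readout does not catch.  Statuses are
`confirmed`, `conflict`, `not_found`, `ambiguous`, plus `unvalidated` for
entries carrying no pair-code (matched by retention/spectrum only).

Updated retention = intensity-weighted mean over the two supporting peaks,
using both replicates the design provides.

## Mixture design

Codes are assigned by seeded backtracking (depth-first with an explicit
stack): most-constrained compound first, candidate codes ordered by current
mixture load, random tie-breaks from the seed.  Constraint types: DISTINCT
(codes differ), DISJOINT (codes share no mixture — the pair is never
co-injected), OVERLAP_ONE (codes share exactly one mixture — one run
deliberately tests whether the pair still separates); the latter two imply
the former.  A DISTINCT clique larger than C(k,2) is rejected up front with
the offending clique named.  Load balance (max − min ≤ 2) is an objective,
not a constraint — constraint satisfaction wins.  Where no explicit
constraints are given, the default conflict rule treats any two compounds
within the matching window (10 RI units) as similar.

## The synthetic-data generator

`identmix.synth` emulates one batch of Ident-Mix injections.  Ground truth:
a panel (default 105 compounds, the size of a routine validation panel)
over k = 4 mixtures spanning RI 1000–3600, with 8 isomer clusters of 2–4
members inside a 25-RI-unit spread (the four hexoses span 24); cluster
members and any pair within the 10-unit conflict window get DISTINCT codes.
Cluster centres are drawn with enough separation that different clusters
never overlap, and singletons are rejected where they would crowd a
retention neighbourhood beyond the code capacity — as a panel designer
would spread standards the codes cannot disentangle.

Peak lists: each compound yields a peak in exactly its code's mixtures at
RI ~ Normal(expected, `noise_sd`), converted to RT through a fixed monotone
alkane-ladder map (mildly convex in carbon number, ~2–29 min).  Default
`noise_sd` = 0.25 RI units, a typical within-batch repeatability for
back-to-back GC injections — consistent with the 1-unit clustering
tolerance being ~3× the replicate-difference scatter.  Dropout removes a
compound's peak per mixture with probability `dropout_rate`; decoys are
scattered uniformly over the RI range at `decoy_rate` per compound per run.
Standard intensities are log-normal (μ = 11, σ = 0.4 — amount-tuned
standards spread only ~2–3-fold), decoys weaker and more variable
(μ − 2, σ + 0.6).  In `clean_decoys` mode decoys keep ≥ 2·noise_sd away
from every true RI so dropout effects can be studied without accidental
decoy rescues.  Everything derives from the single seed.

What the generator does **not** emulate: peak shapes and deconvolution
artefacts, co-elution-dependent ionisation suppression, systematic
(non-random) retention drift within a batch, derivatisation by-products
(each compound yields one peak), and realistic fragmentation (optional
spectra are random sparse peak sets).  Passing tests therefore demonstrate
the combinatorial and retention logic, not robustness to raw-data
processing errors; on real data the upstream peak picking still matters.

The `table2` preset pins the 13-compound sugar panel (pentoses, hexoses,
sugar derivatives) with its published expected RIs and mixture occurrences;
fructose is represented by its main derivatisation product at RI 1862, the
near-equal-intensity second product (RI 1872) is kept as metadata.

## Isobar statistics

Database exports are flat TSVs (a schema mapping adapts column names; no
live database clients).  Filters are declarative and audited (counts per
rule sum with survivors to the input): formula/reaction present, organic
(formula contains carbon — "C" not followed by a lowercase letter), mass
cutoff, the textual lipid rule (name contains two numbers separated by a
colon — deliberately simple, with documented false positives such as
"1:1 complex"), and status/pathway whitelists (unknown whitelist entries
warn, not fail).  Isobar group sizes count records sharing a mass: *exact*
groups by equality after rounding to 4 decimals (databases store
fixed-precision values), *unit* rounds to integers first (half away from
zero).  The cumulative curve reports the percentage of compounds with at
least t isobaric partners; window densities report the maximal exact-mass
group per half-open 5-Da window.  Published database-level percentages
depend on the specific database snapshot and are not reproduced here; the
pipeline is validated on fixtures with known answers.

## Numerical and interface choices

* Encoded names: underscore-delimited, `Compound_Derivstate_[MP|BP]_RI:<int>_RT:<int>_IDENT:<labels>`;
  compound names must not contain underscores, labels must not contain
  `_`/`+`; RI/RT render as nearest integers but stay float internally;
  unknown trailing segments survive the round trip.  `BP` (by-product) is
  this package's extension for ranking non-main derivatisation products.
* msp dialect: NIST text flavour; unrecognised headers are preserved
  verbatim; intensities are written base-peak-normalised to 999 with 6
  significant digits.
* Mass-window and RI-window conventions are half-open / inclusive
  respectively and stated at the function level; occurrence clustering is
  strict (<) so that exact-tie neighbours one unit apart do not merge.
* All tabular IO is UTF-8 TSV with a header row; designs serialise to JSON.
* Problem sizes in the test and acceptance runs (50-compound panels, 100
  seeded batches, 200-point oracle comparisons) are chosen to exercise
  every code path at desk scale; the algorithms are linear to quadratic in
  panel size and handle the full 105-compound routine panel unchanged.

## Known limitations

* Compounds whose expected RIs differ by less than the clustering tolerance
  *and* whose codes overlap cannot be resolved; they surface as `conflict`
  or `ambiguous` (by design — the remedy is a better code assignment, k > 4,
  or spectral thresholds).
* The exclusion logic trusts the design: a pipetting error that puts a
  compound into a wrong mixture produces `conflict`, not a correction.
* LC mode matches on raw RT; no retention alignment across runs is
  performed (inputs are assumed to come from one aligned batch).
* `unvalidated` entries (no pair-code) get no exclusion protection; their
  matches are as good as the retention window and spectra allow.
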