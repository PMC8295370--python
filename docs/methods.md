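# Methods

`recallnets` implements a forward-encoding-model analysis of categorized
free recall: ridge models trained to predict intracranial spectral power
from the semantic category or the serial position of studied words are
inverted to decode those attributes from held-out encoding epochs and from
the moments just before recall, quantifying *content* and *context*
reinstatement in the anterior temporal (AT) and posterior medial (PM)
cortical networks. Everything runs against a synthetic-data generator with
known ground truth, so every stage has recoverable answers.

## Task model

The simulated experiment mirrors the categorized free-recall design: each
session presents 25 lists of 12 words; a list draws 3 categories from a
25-category pool and presents 4 exemplars per category as two
same-category *pairs* in consecutive serial positions. By default the two
pairs of one category are never adjacent in the pair order (a
`allow_adjacent_pairs` flag removes the constraint for sensitivity checks).
The exactly sized default pool (25 categories x 12 words = 300 words for
25 lists x 12 items) is scheduled by always drawing the categories with the
most remaining availability, with random tie-breaking; this never deadlocks
and keeps lists non-repeating within a session.

Word embeddings are synthetic 300-dimensional vectors: one standard-normal
centroid per category plus isotropic within-category jitter
(`embedding_within_sd`, default 0.3, chosen so within-category distances are
clearly below between-category distances, as for real distributional
embeddings).

## Behavioral model and factor scores

Recall sequences are sampled with transition weight
`exp(-theta_T * |lag|) * exp(-theta_S * d_cat)` over not-yet-recalled
items (`d_cat` = 0 for same category, 1 otherwise), a stop probability per
output position, and a uniform first recall. `theta_T = theta_S = 0`
yields uniformly random no-repeat sequences.

The temporal clustering factor scores each transition by the percentile
rank of its absolute serial-position lag among the lags to every item not
yet recalled, with smaller lags ranking higher; the category factor uses a
0/1 same/different-category distance. Ties receive average rank, i.e.
credit `(n_farther + 0.5 * n_tied_others) / (n_candidates - 1)`. This
convention makes the expectation under uniformly random transitions exactly
0.5 (verified by exhaustive enumeration on short lists). Transitions with
fewer than two candidates are excluded rather than scored zero, because a
percentile rank is undefined there. Only correct recalls are scored;
intrusions and repetitions are assumed removed upstream.

The paired list structure biases these scores for particular strategies:
purely serial recall of four consecutive items elevates the category factor
to about 0.64, which the acceptance suite reproduces. Random-order recall
of a single category's four items deflates the temporal factor below 0.5;
under the convention above and the non-adjacent pair arrangement this
package computes about 0.52, a value that depends strongly on how far apart
the two pairs of a category sit (from ~0.62 when two slots apart to ~0.34
at maximal separation) and therefore on the stimulus lists' arrangement
statistics. `structure_matched_z` removes such structure bias by
standardizing observed scores against uniform random no-repeat nulls
matched per list to the observed recall count (default 1000 null draws).

## Signal model

Normalized log-power "features" are electrode x frequency cells. The
generator plants:

- a **category signal** on AT electrodes only: per-feature gain
  (`category_loadings`, standard normal on AT rows) times a scalar drive
  obtained by projecting the word's embedding through a fixed unit-norm
  random vector per frequency — linear in the same 300 features the
  content model regresses on;
- a **serial-position signal** on PM electrodes only: a planted pattern per
  position (`position_loadings`, shape positions x electrodes x
  frequencies). Per-position patterns (rather than a single gain map) are
  required for the correlation-based decoder to have anything to decode:
  Pearson correlation is scale-invariant, so twelve collinear patterns
  would be indistinguishable;
- **network-shared fluctuations**: one Gaussian draw per event per network
  (scale `network_shared_sd`) added to every feature of that network —
  the target of the connectivity analysis;
- independent Gaussian noise (`noise_sd`).

Default gains (1.0 effect sizes, shared sd 0.5, noise sd 1.0) put
single-subject decoding well above chance without saturating it.
Pre-recall epochs carry `reinstatement_gain` times the recalled item's
*noise-free* encoding pattern at each of the 40 samples, plus fresh shared
and independent noise; a per-sample gain profile supports time-varying
reinstatement. Electrode coordinates scatter each network over three
anatomical subcenters (PM: retrosplenial, parahippocampal, posterior
parietal; AT: temporal pole, perirhinal, inferior angular gyrus) with 8 mm
jitter; the cross-network adjacencies (perirhinal/parahippocampal,
inferior angular/posterior parietal) make within- and between-network pair
distances overlap, which is what renders distance matching feasible, as in
real electrode coverage.

## Spectral features

Raw multichannel signal (the optional oscillation-plus-noise mode, or user
data) passes through: bipolar referencing (adjacent contacts within each
strip/grid/depth group), a fourth-order 2 Hz-wide zero-phase Butterworth
band-stop at 60 Hz (forward-backward filtering preserves event timing),
and Morlet wavelet power (wave number 5) at 8 log-spaced frequencies from
3 to 180 Hz. 1000 ms buffers absorb convolution edges — supplied in the
data for encoding epochs, reflection-padded for retrieval epochs. Power is
log-transformed, decimated to 50 Hz (the wavelet envelope is the
anti-alias stage at analysis frequencies), epoched (word onset to offset,
0–1600 ms, for encoding; −900 to −100 ms pre-vocalization, 40 samples at
20 ms, for retrieval), and z-scored per session within each electrode x
frequency feature. Retrieval epochs are dropped when another vocalization
onset falls within the preceding 1500 ms. Encoding-model features are the
time-average over the word window — this reconciles one pattern per word
with the time-resolved recall analysis; a per-sample mode remains
available through the unaveraged tensor.

## Encoding models and decoding

The content design assigns each event the mean embedding of its category's
presented words (300 columns); the context design concatenates one-hot
serial position (12), one-hot list, and one-hot session blocks, omitting
the session block for single-session subjects. Design columns are
standardized and the neural responses centered on the training split only.

Ridge weights are fit per neural feature with nested cross-validation:
5 outer folds split over *words* (repeated presentations stay together),
and within each outer training set a 10-fold inner CV selects, per neural
feature, the penalty minimizing held-out squared error over 50 candidates
log-spaced from 1e-2 to 1e10. The full penalty path is evaluated from a
single SVD per training split (predictions are formed directly from the
factors, never materializing per-penalty weight matrices), which keeps the
electrode bootstrap affordable; tests pin the result to the
normal-equations solution at 1e-8 relative tolerance and to scikit-learn's
`Ridge`. With the smallest grid penalty the attainable noiseless-recovery
error is bounded by the shrinkage bias lambda/n (~1e-4 relative), which the
recovery tests respect.

Decoding inverts the fit: predicted patterns for all 25 categories (or 12
positions, with list/session blocks at zero) are Pearson-correlated with
an observed pattern, a unit-temperature softmax over the correlations
yields class probabilities, and performance is the macro one-vs-rest AUC
over classes present (rank-based, ties at half credit). Macro averaging is
the documented choice where pooling was ambiguous; chance is 0.5 either
way. Network comparisons decode from 5 electrodes sampled without
replacement per bootstrap replicate (1000 replicates at full scale; tests
and the demo pipeline use fewer), which controls for unequal electrode
counts across networks.

## Reinstatement

Encoding-trained models decode each of the 40 pre-vocalization samples;
each recall is decoded with the class patterns of the outer fold that held
that word out during encoding (fold-averaged patterns when the word is
unknown). The AUC series is smoothed with an edge-renormalized Gaussian
kernel. The stated 7 ms FWHM is honored literally even though it is
sub-sample on the 20 ms grid (near-identity); `fwhm_samples` reinterprets
the width in samples for sensitivity analyses. Across subjects, mean AUC
over the FWER-significant timepoints (falling back to the full window when
none survive) is Pearson-correlated with the behavioral factor scores,
with a two-sided t test at n−2 degrees of freedom.

## Connectivity

Connectivity is the Pearson correlation across encoding events of two
electrodes' time-averaged power at one frequency. The within-minus-between
contrast is estimated by a distance-matched bootstrap: each replicate
samples between-network pairs with replacement (sample size: half the
smallest pair pool, leaving the matcher freedom), then greedily assigns to
each — longest first — the unused within-network pair of closest distance.
Replicates whose mean |distance mismatch| exceeds 20 mm are skipped; a
subject with more than half of replicates skipped is flagged excluded, the
analogue of real subjects whose coverage cannot support matched samples.
Greedy nearest-distance matching is deterministic given the sample and
keeps matched mean distances unbiased when the distance distributions
coincide (tested). Group inference is a one-sample t per frequency with
sign-flip max-|t| FWER correction (2000 permutations at full scale).

## Permutation statistics

TFCE enhances a 1-D statistic series as `sum_k h_k^H * e_k(t)^E * dh` over
thresholds `h_k = dh, 2dh, ..., max`, with H=2, E=0.5, dh=0.01; `e_k(t)`
is the length of the contiguous supra-threshold run containing `t`.
Negative excursions are enhanced on the negated series and recombined with
sign for two-tailed inference. A constant series of value c over T samples
enhances to `sqrt(T) * c^3 / 3` up to dh discretization (tested against
the analytic integral and a literal triple-loop oracle). The group test
enhances the one-sample t series (against 0.5 for AUC series), builds the
null by sign-flipping subject deviation series and recording the maximum
|enhanced| value (10000 permutations at full scale), and reports per-
position corrected p-values, floored at 1/(n_perm+1). Both permutation
procedures are calibration-tested: simulated nulls yield family-wise false
positive rates of 0.05 ± 0.02.

## What the generator does and does not emulate

It emulates the task structure, clustered recall dynamics, network-
segregated linear stimulus coding, shared network fluctuations, pre-recall
reinstatement, and distance structure of electrode coverage. It does not
emulate: nonstationary drift within sessions, oscillatory dynamics or 1/f
spectra in the power-level mode, epileptiform artifacts, intrusions or
repetitions in recall, retrieved-context dynamics (no TCM-style model), or
correlated noise between specific electrode pairs beyond the network-level
shared term. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the model's assumptions — not that real
iEEG would yield the same effect sizes.

## Problem sizes

Defaults in tests and the demo pipeline are scaled for a laptop-class
single CPU: 5–25 lists per subject, 10 electrodes, 8 frequencies, tens to
hundreds of bootstrap/permutation replicates, with the full-scale counts
(1000 bootstrap, 2000/10000 permutations) available as parameters. The
acceptance script uses 10,000 simulated lists for factor-score targets and
50 label-permutation repetitions of the full content-model pipeline for the
chance-decoding target.

## Known limitations

- The structure-bias temporal factor depends on pair-arrangement
  statistics that the task description does not fully determine (see the
  factor-score section); the package reports the value its documented
  convention and arrangement produce.
- Distance matching with only 5 electrodes per network excludes an
  appreciable fraction of simulated subjects (as it does real ones);
  estimates are conditional on matchable coverage.
- The per-feature penalty search assumes independent neural features;
  correlated features share no strength across the fits.
- `brain_behavior_correlation` treats subjects as exchangeable; no
  hierarchical shrinkage is applied.
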