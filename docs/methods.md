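# Methods

## The classifier

`cytobayes.bayes` implements a naive Bayesian classifier with a Laplacian
correction, designed for sparse, high-dimensional, noisy screening data.
Each binary feature D observed in the training set gets the corrected
conditional probability

    P_corr(active | D) = (A_D + P(active)·K) / (T_D + K),   K = 1/P(active)

where A_D is the number of active training molecules containing D, T_D the
number of training molecules containing D, and P(active) = A/(A+I) the
baseline hit rate. The correction adds K virtual samples at the baseline
rate, so a feature's evidence is shrunk toward "no information" in
proportion to how rarely it was seen; at T_D = 0 the probability equals
P(active) exactly. A molecule's score is the sum over its present features
of ln(P_corr / P(active)) — the log of the product of per-feature relative
likelihoods. The log-relative form (rather than the raw probability
product) makes 0 the neutral threshold and keeps the arithmetic stable for
molecules with hundreds of features.

Assumptions worth keeping in mind: features contribute independently
(naive Bayes), presence/absence only (no counts), and the score is a
ranking statistic, not a calibrated probability. The model tolerates
unbalanced classes — changing the active/inactive ratio shifts all scores
but barely perturbs the ranking (a tested property) — and cannot overfit
through uninformative features, whose weights shrink to zero.

Continuous descriptors participate as categorical tokens: each descriptor
is discretized into quantile bins learned from the training data (10 bins
by default, configurable and recorded in the model), and "descriptor d in
bin b" behaves exactly like a fingerprint feature. Values outside the
training range map to the nearest extreme bin; a molecule missing a
descriptor simply contributes no token for it. Quantile (rather than
equal-width) bins keep per-bin support roughly constant, which suits the
count-based correction.

## Featurization

`cytobayes.featurize` uses a functional-class circular fingerprint of
diameter 6: Morgan environments of radius 3 over pharmacophoric atom
invariants (donor/acceptor/aromatic/halogen/basic/acidic), hashed to
unfolded integer identifiers. Functional-class abstraction groups
bioisosteric atoms, which is the appropriate granularity for toxicity
mechanisms shared across a series; plain connectivity invariants are
available by flag. Hashed ids are left unfolded by default because the
Bayes learner handles sparse unbounded vocabularies natively; folding (to
a power of two ≥ 1024) is offered for memory-constrained runs. Descriptors
are the atomic-contribution logP estimate, molecular weight, H-bond
donor/acceptor counts, rotatable bonds, and fractional polar surface area
(polar N/O Labute surface contributions over the whole-molecule surface,
guaranteed in [0,1]). Featurization is deterministic for a fixed toolkit
version and invariant to SMILES atom ordering.

## Labelling rules

Three rules convert continuous readouts to binary labels, all with strict
`>` at the cutoff and "higher = more toxic":

- **fixed cutoff** — e.g. pIC50 > 5.5 for dose-response data;
- **top fraction** (default 0.20) — equalizes hit rates across
  heterogeneous assays; the count is ceil(fraction·n) so tiny assays keep
  at least one active, and boundary ties break by ascending compound id
  for determinism;
- **mean + k·SD** (default k = 3) — the conservative HTS hit rule; sample
  SD (n−1) by default with a population-SD flag, since either convention
  is defensible for a screening deck.

Assays with fewer than 10 toxic compounds are excluded from network
panels: below that the per-assay model is too information-poor to
cross-predict.

## Evaluation

The ROC score is the midrank Mann-Whitney statistic, chosen because it
equals the "probability a random active outranks a random inactive"
definition exactly, ties counted half; tests verify agreement with
brute-force pair counting and with an independent library implementation.
k-fold cross-validation (default k = 5) uses unstratified random
equal-sized folds; fold AUCs are reported as mean ± sample SD, and a fold
whose test part is single-class is excluded from the mean with a warning
rather than silently imputed.

The cutoff scan trains one model per candidate percent-inhibition cutoff
(default grid −20 to 100 in 1% steps; points leaving fewer than two
compounds in either class are skipped with a reason) and scores each model
by its ROC at retrieving confirmation-assay actives against all other
screened compounds. The default evaluation mode trains on the full screen
and scores every compound; a cross-validated mode is available. Ties in
the optimum resolve to the lowest cutoff, the cheaper, more inclusive
choice.

Similarity diagnostics (per-compound maximum Tanimoto within class, and
versus each class of a reference set) characterize whether a toxic class
is clustered enough in chemical space to be learnable. Two empty feature
sets get similarity 0 by convention. The score-agreement table bins two
models' scores on shared compounds into a 16×16 equal-width grid with
per-cell counts and toxic fractions, the numeric content of a binned
pie-chart comparison.

## Prediction networks

For every ordered pair of assays in a readout-homogeneous panel, a model
trained on one assay's labelled compounds scores the other's, giving a
generally asymmetric directed ROC matrix. An undirected edge requires both
directions to reach the threshold, 0.60 by default and inclusive (≥);
a strict-inequality flag exists because either convention is defensible.
Compounds shared between train and test assay remain in the test set by
default (an `exclude_overlap` option enables the stricter protocol).
Connected components of the thresholded graph are merged into training
sets; label conflicts for compounds measured in several assays default to
**any_toxic** — cytotoxic in any assay raises the alert, the right
semantics for a triage tool — with majority-vote and keep-duplicates
policies available. The merged-model pipeline builds both networks, merges
the largest component of each, cross-validates the two sub-models and the
combined (union) model, and checks on a held-out 10% + 10% sample that the
two sub-models' scores agree (toxic compounds concentrated in the
high-high corner of the agreement table) before trusting the union.
Networks export as a three-column directed-pairs TSV
(`training_set`, `test_set`, `roc`), SIF and GraphML (with node sizes and
both directed AUCs as attributes) for external viewers, plus a JSON
summary; no layout or rendering is done here.

## The simulator

`cytobayes.simulate` generates the statistical structure the method
assumes, not chemistry:

- **SAR series**: each of 40 series (40 molecules each by default) has 30
  scaffold features drawn without replacement from a 2^20 id space, so
  scaffolds never collide; each molecule adds 40 decoration features drawn
  from a shared pool of 2,000 "common fragment" ids. The shared pool
  mirrors the heavy-tailed frequency structure of real fingerprint
  vocabularies, in which frequent substituent features recur across
  unrelated series — drawing decorations i.i.d. from the full space would
  make each molecule's decoration set a unique identifier and let models
  memorize individual training compounds.
- **Toxicity**: each series is toxic with probability 0.25 (or an explicit
  list); toxic series carry one of 3 latent mechanisms and per-molecule
  latent potency uniform on (0.1, 0.9), so the weak end of a series sits
  inside assay noise, as real series do. Toxic series optionally get a
  higher mean logP (a lipophilicity-toxicity correlation, on by default).
- **Percent-inhibition assays** observe a footprint of series:
  value = 1.2 + 100·potency·[mechanism ∈ assay sensitivity] + N(0, 9.8),
  clipped to [−20, 100]. Baseline and noise match the empirical profile of
  a large single-concentration cytotoxicity HTS (mean 1.2%, SD 9.8%).
- **pIC50**: follow-up assays re-measure the top primary hits plus filler
  compounds; standalone IC50 screens measure their own footprint. Both map
  potency to pIC50 = 4.2 + 3.0·potency + N(0, 0.2), placing inert
  compounds near 4.2 and potent ones above 6, so the conventional
  pIC50 > 5.5 call separates them; the intercept/slope were fixed once to
  bracket that cutoff at mid-range potency.

Determinism: one seeded generator builds the universe; each assay draws
from its own stream keyed by (universe seed, assay id), so adding an assay
never perturbs another's values.

Packaged scenarios: `scenario_chain` (footprints A = series 0–9,
B = 5–14, C = 10–19, toxic series at every third index so both overlap
regions contain shared SAR; the lipophilicity correlate is disabled there
because a global property correlate would carry predictivity across the
A–C gap the scenario exists to open), `default_followup_scenario` (one
full-universe HTS plus its IC50 confirmation, the cutoff-scan input), and
`default_panels` (three overlapping percent-inhibition screens and three
independent IC50 screens over a partially complementary region, the
merged-model input).

What the simulator does **not** emulate: real substructure chemistry
(features are abstract integers; an end-to-end structure path exists via
the featurize module and SMILES fixtures), dose-response curve shapes,
plate/edge effects, assay-technology covariates, or correlated activity
cliffs within a series. Passing tests therefore demonstrate that the
machinery recovers planted series/mechanism structure under realistic
noise — not that any particular real dataset is predictable.

## Problem sizes and numerical choices

Simulated studies run at 1,600 molecules per universe, panels of 3–4
assays of 400–1,200 compounds, and 71–121 cutoff-scan grid points; at
these sizes the full test suite and pipeline complete in well under a
minute each, and behaviour at 10× is the same machinery linearly scaled.
Ties: midranks in the AUC, lowest cutoff at scan ties, ascending-id at
label ties, lower threshold at Youden ties. Degenerate inputs raise
explicit errors (single-class training, empty components, unparsable
structures are collected per-batch) rather than propagating NaN.

## Known limitations

- The score is uncalibrated; threshold 0 is a convention (a Youden-optimal
  threshold chooser is provided but not default).
- Feature independence is assumed; heavily correlated features (scaffold
  atoms of one series) multiply their evidence.
- The merged-model interval behaviour — the combined model
  cross-validating between its two sub-models — holds when the panels
  differ in label quality; when the two sub-models happen to tie, the
  combined model can edge slightly above both because it simply trains on
  more data.
- Percent-inhibition values outside [−20, 100] are flagged, not rejected;
  the cutoff grid spans the same range so they remain classifiable.
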