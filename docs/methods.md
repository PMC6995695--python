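# Methods

## Statistical model

### Empirical null from internal controls

Isobaric-tag reporter ratios have run-specific technical variation that is
poorly captured by parametric models, so significance is defined
distribution-free. Within one run, peptide log2 ratios between the two CD34+
control channels contain no biological AML signal; their empirical
(1−c)/2 and 1−(1−c)/2 quantiles (numpy's linear-interpolation quantile
definition) bracket a fraction c of technical variation and serve as
intra-run confidence limits, c = 0.90 by default. A protein comparison is
significant when its ratio is **strictly** outside the limits; a ratio
exactly on a limit is not significant, making tie behaviour deterministic.

Limits are built per run ("intra-experiment"). A run with fewer than
`min_null_peptides` (default 50) control:control ratios falls back to a null
pooled over all runs. The null is built at **peptide level** by default; a
`null_level="protein"` option first rolls the control:control peptides up to
protein ratios with the same estimator, matching the aggregation level of
the tested comparisons. The peptide-level default means multi-peptide
proteins are called *conservatively* (a median over k peptides has smaller
spread than one peptide), which trades sensitivity on well-covered proteins
for simplicity and robustness on one-peptide proteins. Calibration checks
therefore measure coverage with one peptide per protein, where the 10%
nominal call rate at c = 0.90 holds exactly.

### Normalization and rollup

Each (run, sample channel, control channel) pair is median-centred on the
log2 scale (`normalize="median"`), absorbing labelling/loading bias; with a
small changed fraction the median tracks the technical offset. Peptides roll
up to proteins by the **median** of their log2 ratios (robust to a single
outlier peptide); the mean is available for sensitivity analysis.
`min_peptides` defaults to 1 — no peptide floor is imposed.

### Coincidence, recurrence and ranking

In a dual-control run a patient's verdict for a protein is *changed* only
when both control comparisons are significant in the same direction
(consensus log2 ratio = mean of the two); single-control runs use the
comparison's own call. A patient measured in several runs counts **once**:
changed if changed in any run, dropped for that protein if changed runs
disagree in direction, consensus ratio averaged over the changed runs.

A protein survives the recurrence filter when one shared direction has
≥ `min_patients` (5) changed patients at |fold| strictly > `min_fold` (2),
whose evidence spans ≥ `min_runs` (2) distinct runs. If both directions
qualify the dominant one is kept and exact ties are dropped (cannot occur
under the generator; pinned for determinism). The average fold is the
arithmetic mean of signed linear folds over the qualifying patients only —
"significant-only averaging" — because published frequency × fold products
reconcile exactly on that scale; a geometric alternative
(`fold_average="geometric"`) is provided. The ranking score is
`frequency × |avg_fold|`, direction-free.

Signed folds use the symmetric convention `+2^r` (r ≥ 0) / `−2^(−r)`
(r < 0), so |fold| ≥ 1 always and up/down magnitudes are comparable.

### Transcriptome stage

Per-gene one-way fixed-effects ANOVA, computed directly from sums of squares
(with two groups F equals the squared equal-variance t statistic — asserted
against an independent implementation in the tests). No batch covariates; a
Welch variant is available behind `variant="welch"`. No multiple-testing
correction is applied at this stage — DE selection uses raw P < 0.05 with
|fold| > 1.5 (strict), matching the upstream discovery convention; users
needing FDR control should apply it downstream. Constant genes get p = 1 by
convention and are logged. The fold sign convention is shared (same code
path) with the proteomic stage.

### Concordance

A recurrent protein joined to its gene (identity join on shared identifiers
by default; an explicit protein→gene mapping file overrides; unmapped
proteins are excluded from the rates) is classified:

- **concordant** — mRNA-change flag set (ANOVA P < 0.05 and |fold| ≥ 1.3,
  *inclusive*) and mRNA fold co-directional with the protein fold;
- **discordant** — flag set, signs differ;
- **no_mrna_change** — flag not set.

Note the deliberate asymmetry: the mRNA threshold is inclusive (≥ 1.3) while
the protein recurrence threshold is strict (> 2); both conventions are
pinned by the boundary tests. The concordance rate is 100 × concordant /
records, reported both as a float and as an exact fraction. The Pearson
protein–mRNA correlation helper returns a Fisher-z 95% CI
(`tanh(atanh r ± 1.96/√(n−3))`), n ≥ 3, error on zero variance.

## Synthetic-data generator

The generator emulates the discovery design: 15 AML patients and five
distinct CD34+ controls across three 8-plex runs, two control channels per
run (one control reused to fill the third run's pair). Peptide log2 ratio
for a sample:control comparison = per-patient true protein effect + run bias
+ N(0, σ_pep); control:control ratios draw from N(0, σ_pep) alone, because a
shared run bias cancels between channels of one run.

Generative assumptions and defaults (all log2 units unless stated):

| parameter | default | why |
|---|---|---|
| `n_proteins` | 600 | desk-scale stand-in for a few thousand quantifiable proteins |
| `peptides_per_protein` | geometric, mean 3, min 1 | right-skewed evidence; exercises one-peptide proteins |
| `peptide_noise_sd` | 0.3 | gives null limits ≈ ±0.49, a realistic ~1.4-fold technical band |
| `run_bias` | 0.05 (SD of per-run shift) | small systematic offset removed by normalization |
| `changed_fraction` | 0.025 | order of magnitude of the published hit rate (~113 of 4666) |
| `penetrance` | 0.7 | reproduces observed frequencies of 5–14 of 15 patients |
| `effect_mean`, `effect_sd` | 2.0, 0.5 | ~4-fold average effects, like the published top proteins (3.9–6.3 fold) |
| `mrna_concordant_fraction` | 0.6 | matches the reported ~60% protein–mRNA agreement |
| `mrna_noise_sd` | 0.3 | array-scale residual noise |

Changed proteins get a random direction and per-patient effects
`direction × |N(effect_mean, effect_sd)|`, realised per patient with a
Bernoulli(penetrance); unchanged proteins have all effects 0. The matched
expression matrix is one gene per protein: AML samples of *mRNA-mirrored*
genes inherit the patient's true protein effect on top of a N(8, 1) baseline,
so concordance is planted at a known rate. Nuclear designation is a
pass-through annotation (75% nuclear), never predicted.

The generator does **not** emulate: spectrum-level noise, retention time,
isotope impurity, peptide-level missingness mechanisms beyond optional
uniform dropout, probe-level microarray structure, shared peptides between
proteins, or correlated patient effects. Passing tests therefore demonstrate
the *inference rules* are correct and calibrated under a Gaussian additive
model — not that real acquisitions meet these assumptions.

## Numerical and degenerate-input choices

- Quantiles: numpy linear interpolation everywhere; the tests pin equality
  against an explicit sort-and-index oracle.
- Strict inequalities at the significance limits and the protein fold
  threshold; inclusive at the mRNA 1.3 threshold (see above).
- Non-finite peptide ratios are dropped with a logged count; an all-empty
  run is an error.
- Zero peptides for a protein in a comparison: the protein is simply absent
  from that comparison, not an error.
- Constant genes: p = 1; zero within-group variance with a real mean
  difference: p = 0.
- Empty recurrence output is valid (no planted signal ⇒ empty report).

## Problem sizes

The default test and analysis runs use 600-protein studies (≈ 20,000 peptide
rows per run) and complete in seconds; the calibration checks use
5000-protein null studies (150,000 null comparisons, ≥ 10,000 null ratios
for the limits) chosen so the Monte-Carlo error of the coverage estimate is
comfortably below one percentage point.

## Known limitations

- The peptide-level null is conservative for multi-peptide proteins
  (protein-level nulls are available but not default).
- "Frequency" counts patients, not comparisons; the dual-run patient rule
  (changed in either, directions must agree) is a design choice the
  published procedure leaves unstated.
- The transcriptome stage is a plain two-group model with no covariates and
  no multiplicity correction by design; it is a discovery filter, not a
  confirmatory test.
- The identity protein→gene join assumes shared symbols; many-to-one
  mappings require an explicit mapping file.
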