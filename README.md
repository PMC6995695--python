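# amlproteo

Discovery pipeline for differential **nuclear proteome** analysis of acute
myeloid leukemia (AML) blasts against normal human CD34+ hemopoietic
stem/progenitor cells, with an integrated transcriptome stage. It is aimed at
proteomics analysts working with multiplexed isobaric-tag (iTRAQ/TMT-style)
cohort designs who need distribution-free significance calling, cross-patient
recurrence filtering and protein–mRNA concordance, all reproducible at desk
scale from a seeded synthetic study.

## The method

Each 8-plex MS run mixes AML patient channels with one or two CD34+ control
channels and yields per-peptide log2 ratios (sample vs. control). The
pipeline's stages:

1. **Empirical null / significance calling.** Within a run, peptide ratios
   between the two control channels measure pure technical variation. Their
   empirical quantiles at (1−c)/2 and 1−(1−c)/2 form intra-run confidence
   limits at level c (default 0.90). A protein's rolled-up ratio (median over
   its peptides) is *significant* when it falls strictly outside its own
   run's limits. Operationally, 90% limits flag ~10% of null comparisons.
2. **Coincidence rule.** In dual-control runs a protein counts as *changed*
   in a patient only if both sample:control comparisons are significant in
   the same direction; the consensus log2 ratio is their mean.
3. **Recurrence filter and ranking.** A protein is retained when it changed
   co-directionally at |fold| > 2 in ≥ 5 of 15 patients observed across ≥ 2
   independent runs. Its average fold is the arithmetic mean of signed linear
   folds over significantly changed patients only, and proteins are ranked by
   `score = frequency × |avg_fold|`. Signed folds follow the symmetric
   convention `+2^r` for log2 ratio `r ≥ 0`, `−2^(−r)` otherwise.
4. **Transcriptome stage.** Per-gene one-way ANOVA (two groups, so F = t²)
   on a normalized log2 expression matrix with signed fold changes; DE genes
   pass P < 0.05 and |fold| > 1.5.
5. **Concordance.** A recurrent protein is *concordant* when its gene carries
   the mRNA-change flag (P < 0.05, |fold| ≥ 1.3) and the mRNA fold shares the
   protein fold's direction; *discordant* when flagged with opposite sign;
   otherwise *no mRNA change*. The concordance rate quantifies how far
   protein changes are transcriptionally driven.

A seeded generator (`amlproteo.simulate`) produces ground-truth-labelled
peptide tables and a matched expression matrix under the cohort design
(15 patients, 5 controls, 3 runs), so every stage is testable without any
data download. See `docs/methods.md` for the generative model and all
parameter choices.

## Worked example

```sh
python analysis/01_simulate.py --seed 0   # cohort-shaped synthetic study
python analysis/02_quantify.py            # nulls + significance calls
python analysis/03_rank.py                # recurrence filter and ranking
python analysis/04_transcriptome.py       # ANOVA DE stage
python analysis/05_integrate.py           # protein-mRNA concordance
```

prints (abridged):

```
  proteins: 600, truly changed: 14 (9 mirrored at mRNA level)
  run1: 1852 null ratios, limits [-0.505, 0.487] log2
  significant comparisons: 5.6%
14 recurrent proteins (>= 5 patients, >= 2 runs, |fold| > 2.0)
protein_id  frequency  n_runs_supporting  avg_fold     score  nuclear
    P00404         14                  3  4.182380 58.553317     True
    P00334         12                  3  4.602822 55.233860     True
...
14 recurrent proteins integrated with mRNA data:
  concordance rate 57.1% (prints as 57%)
```

The null limits sit near ±1.645 × the peptide noise SD (0.3 log2 units), the
recurrence filter recovers the 14 planted proteins, and the measured
concordance tracks the planted 60% mirrored fraction. The same stages are
available as CLI subcommands (`amlproteo generate|quant|rank|detest|
integrate|run-all`), and `amlproteo run-all --out results/pipeline` runs
everything from one YAML config with a provenance record.

`analysis/06_reference_checks.py` additionally evaluates the ranking and
concordance rules on curated published reference rows (top-ranked proteins
and the 11 frequently changed transcription factors): the frequency × fold
products reconcile and the TF concordance classifies to 6/11 = 54.5%,
printing as 55%.

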