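"""Configuration objects for the generator and the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is outside its documented range."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study generator.

    All effect and noise scales are in log2 units.  Defaults emulate the
    discovery-cohort conditions: a small fraction of proteins truly changed in
    AML, around 4-fold effects with patient-to-patient heterogeneity
    (penetrance ~0.7 reproduces observed frequencies of 5-14 out of 15
    patients), and roughly 60% of protein changes mirrored at mRNA level.

    Attributes
    ----------
    n_proteins
        Proteins simulated per study.
    peptides_per_protein_mean, peptides_per_protein_min
        Peptide evidence per protein is drawn from a geometric distribution
        truncated below at the minimum; real peptide counts are right-skewed.
    peptide_noise_sd
        SD of additive Gaussian noise on each peptide log2 ratio.
    run_bias
        Systematic per-run shift applied to sample:control ratios (removed by
        median normalization); control:control ratios are unaffected because
        the bias cancels between two channels of the same run.
    changed_fraction
        Proportion of proteins truly changed in AML.
    penetrance
        Probability that a changed protein is affected in a given patient.
    effect_mean, effect_sd
        Magnitude distribution of the true per-patient log2 effect.
    mrna_concordant_fraction
        Proportion of changed proteins whose change is mirrored at mRNA level.
    mrna_noise_sd
        SD of Gaussian noise on log2 expression values.
    dropout
        Probability that a peptide observation is missing at random.
    seed
        Generator seed; a fixed seed gives byte-identical output tables.
    """

    n_proteins: int = 600
    peptides_per_protein_mean: float = 3.0
    peptides_per_protein_min: int = 1
    peptide_noise_sd: float = 0.3
    run_bias: float = 0.05
    changed_fraction: float = 0.025
    penetrance: float = 0.7
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    mrna_concordant_fraction: float = 0.6
    mrna_noise_sd: float = 0.3
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("changed_fraction", "penetrance", "mrna_concordant_fraction",
                     "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        for name in ("peptide_noise_sd", "mrna_noise_sd", "effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_proteins < 0:
            raise ConfigError("n_proteins must be >= 0")
        if self.peptides_per_protein_min < 1:
            raise ConfigError("peptides_per_protein_min must be >= 1")
        if self.peptides_per_protein_mean < self.peptides_per_protein_min:
            raise ConfigError("peptides_per_protein_mean below its minimum")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds for every stage of the discovery pipeline, with the study's
    published operating point as defaults."""

    confidence: float = 0.90        # empirical-null confidence level
    min_null_peptides: int = 50     # null ratios required for a per-run null
    estimator: str = "median"       # peptide->protein rollup
    normalize: str = "median"       # per-channel-pair normalization
    min_patients: int = 5           # recurrence: patients with a change
    min_runs: int = 2               # recurrence: independent MS runs
    min_fold: float = 2.0           # recurrence: |fold| must exceed this
    p_max: float = 0.05             # transcriptome ANOVA threshold
    de_fold: float = 1.5            # transcriptome DE fold (strict >)
    concord_fold: float = 1.3       # mRNA-change fold for concordance (>=)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ConfigError("confidence must lie in (0, 1)")
        if self.estimator not in ("median", "mean"):
            raise ConfigError("estimator must be 'median' or 'mean'")
        if self.normalize not in ("median", "none"):
            raise ConfigError("normalize must be 'median' or 'none'")
        for name in ("min_fold", "de_fold", "concord_fold"):
            if getattr(self, name) < 1.0:
                raise ConfigError(f"{name} is a linear fold, must be >= 1")
        if not 0.0 < self.p_max <= 1.0:
            raise ConfigError("p_max must lie in (0, 1]")
        if min(self.min_patients, self.min_runs) < 1:
            raise ConfigError("min_patients and min_runs must be >= 1")

    # -- (de)serialization ---------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        gen = d.pop("generator", {}) or {}
        return cls(generator=GeneratorConfig(**gen), **d)
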