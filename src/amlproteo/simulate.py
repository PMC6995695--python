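"""Seeded synthetic studies: ground-truth-labelled peptide ratio tables and a
matched expression matrix.

The generator emulates the discovery design — AML patients and CD34+ controls
multiplexed across 8-plex isobaric-tag runs — at desk scale.  Every peptide
log2 ratio for a sample:control comparison is

    true per-patient protein effect + run bias + Gaussian noise,

while control:control comparisons (the empirical-null source) draw from the
noise alone, since a shared run bias cancels between two channels of the same
run.  A configurable fraction of proteins is truly changed in AML; each
changed protein carries a direction and a per-patient effect realised with a
Bernoulli penetrance, which creates the cross-patient frequency structure the
recurrence filter is designed to exploit.  The matched expression matrix
shifts group means only for the subset of changed proteins flagged as
mRNA-mirrored, so protein-mRNA concordance has a known planted rate.

Peptide counts, noise SDs and run bias are generator assumptions — the source
study reports protein-level results only; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .design import StudyDesign

PEPTIDE_COLUMNS = ["run_id", "peptide_id", "protein_id", "sample_id",
                   "control_id", "log2_ratio"]
TRUTH_COLUMNS = ["protein_id", "is_changed", "direction", "mrna_mirrored",
                 "compartment"]

BASELINE_LOG2_EXPRESSION = 8.0  # typical normalized array intensity


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of one synthetic study.

    ``proteins`` has one row per protein (is_changed, direction,
    mrna_mirrored, compartment); ``effects`` is a proteins x patients frame of
    true per-patient log2 effects (0 everywhere for unchanged proteins).
    """

    proteins: pd.DataFrame
    effects: pd.DataFrame

    def __post_init__(self) -> None:
        unchanged = ~self.proteins["is_changed"].to_numpy(bool)
        if unchanged.any():
            rows = self.effects.loc[self.proteins.index[unchanged]]
            assert (rows.to_numpy() == 0).all(), "unchanged protein with effect"
        mirrored = self.proteins["mrna_mirrored"].to_numpy(bool)
        assert not (mirrored & unchanged).any(), "mrna_mirrored implies is_changed"

    @property
    def changed_ids(self) -> list[str]:
        return list(self.proteins.index[self.proteins["is_changed"]])


@dataclass(frozen=True)
class SyntheticStudy:
    """Bundle returned by :func:`generate_study`."""

    peptides: dict[str, pd.DataFrame]   # run_id -> peptide table
    expression: pd.DataFrame            # genes x samples, log2 intensity
    groups: pd.Series                   # sample_id -> {AML, control}
    truth: TruthTable
    design: StudyDesign
    config: GeneratorConfig


def _peptide_counts(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    """Right-skewed peptide evidence: geometric, truncated below at the min."""
    lo = cfg.peptides_per_protein_min
    excess = cfg.peptides_per_protein_mean - lo
    if excess <= 0:
        return np.full(cfg.n_proteins, lo)
    # geometric on {1,2,...} has mean 1/p; shift so the mean matches
    p = 1.0 / (excess + 1.0)
    return lo - 1 + rng.geometric(p, size=cfg.n_proteins)


def _draw_truth(rng: np.random.Generator, cfg: GeneratorConfig,
                design: StudyDesign) -> TruthTable:
    ids = [f"P{i + 1:05d}" for i in range(cfg.n_proteins)]
    changed = rng.random(cfg.n_proteins) < cfg.changed_fraction
    direction = np.where(rng.random(cfg.n_proteins) < 0.5, 1, -1)
    direction[~changed] = 0
    mirrored = changed & (rng.random(cfg.n_proteins) < cfg.mrna_concordant_fraction)
    # 3 of 4 changed proteins nuclear, mirroring the dominant nuclear designation
    compartment = np.where(rng.random(cfg.n_proteins) < 0.75, "nuclear", "cytoplasmic")

    patients = design.patient_ids
    affected = rng.random((cfg.n_proteins, len(patients))) < cfg.penetrance
    magnitude = np.abs(rng.normal(cfg.effect_mean, cfg.effect_sd,
                                  size=(cfg.n_proteins, len(patients))))
    effects = affected * magnitude * direction[:, None]
    effects[~changed] = 0.0

    proteins = pd.DataFrame(
        {
            "is_changed": changed,
            "direction": direction,
            "mrna_mirrored": mirrored,
            "compartment": compartment,
        },
        index=pd.Index(ids, name="protein_id"),
    )
    eff = pd.DataFrame(effects, index=proteins.index, columns=patients)
    return TruthTable(proteins=proteins, effects=eff)


def generate_study(config: GeneratorConfig, design: StudyDesign) -> SyntheticStudy:
    """Generate one complete synthetic study.

    Returns peptide tables per run (including control:control null-source
    rows), a genes x samples expression matrix with group labels, and the
    ground truth.  Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(rng, config, design)
    n_peptides = _peptide_counts(rng, config)
    protein_ids = truth.proteins.index.to_numpy()

    run_bias = {run_id: rng.normal(0.0, config.run_bias) if config.run_bias > 0
                else 0.0 for run_id in design.run_ids}

    peptides: dict[str, pd.DataFrame] = {}
    for run_id, (run_patients, run_controls) in design.assignment.items():
        # sample:control comparisons for every patient channel vs every control
        comparisons = [(s, c) for s in run_patients for c in run_controls]
        # control:control null source (one orientation per control pair)
        if len(run_controls) == 2:
            comparisons.append((run_controls[0], run_controls[1]))

        frames = []
        for sample_id, control_id in comparisons:
            is_null = sample_id not in run_patients
            rows_protein = np.repeat(protein_ids, n_peptides)
            total = int(n_peptides.sum())
            if is_null:
                effect = np.zeros(total)
                bias = 0.0
            else:
                eff = truth.effects.loc[:, sample_id].to_numpy()
                effect = np.repeat(eff, n_peptides)
                bias = run_bias[run_id]
            noise = rng.normal(0.0, config.peptide_noise_sd, size=total)
            pep_index = (np.concatenate([np.arange(k) for k in n_peptides])
                         if len(n_peptides) else np.empty(0, dtype=int))
            frame = pd.DataFrame(
                {
                    "run_id": run_id,
                    "peptide_id": [f"{p}_pep{j + 1}" for p, j in
                                   zip(rows_protein, pep_index)],
                    "protein_id": rows_protein,
                    "sample_id": sample_id,
                    "control_id": control_id,
                    "log2_ratio": effect + bias + noise,
                }
            )
            if config.dropout > 0:
                frame = frame[rng.random(len(frame)) >= config.dropout]
            frames.append(frame)
        if frames:
            peptides[run_id] = pd.concat(frames, ignore_index=True)
        else:
            peptides[run_id] = pd.DataFrame(columns=PEPTIDE_COLUMNS)

    expression, groups = _expression_matrix(rng, config, design, truth)
    return SyntheticStudy(peptides=peptides, expression=expression,
                          groups=groups, truth=truth, design=design,
                          config=config)


def _expression_matrix(rng, cfg: GeneratorConfig, design: StudyDesign,
                       truth: TruthTable):
    """One gene per protein; AML samples of mRNA-mirrored genes inherit the
    patient's true protein effect, so concordance is planted at gene level."""
    samples = design.patient_ids + design.control_ids
    groups = pd.Series(
        ["AML"] * len(design.patient_ids) + ["control"] * len(design.control_ids),
        index=pd.Index(samples, name="sample_id"), name="group",
    )
    base = BASELINE_LOG2_EXPRESSION + rng.normal(0.0, 1.0, size=len(truth.proteins))
    values = np.tile(base[:, None], (1, len(samples)))
    mirrored = truth.proteins["mrna_mirrored"].to_numpy(bool)
    shift = truth.effects.to_numpy() * mirrored[:, None]
    values[:, : len(design.patient_ids)] += shift
    values += rng.normal(0.0, cfg.mrna_noise_sd, size=values.shape)
    expr = pd.DataFrame(values, index=truth.proteins.index.rename("gene_id"),
                        columns=samples)
    return expr, groups


# ---------------------------------------------------------------------------
# on-disk round trip

def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a study to TSV (UTF-8, tab-delimited, header row).

    Files: ``peptides_<run>.tsv`` with the documented peptide columns, an
    ``expression.tsv`` matrix (gene_id + one column per sample), a
    ``samples.tsv`` with group labels and run assignment, and a
    ``truth.tsv`` + ``truth_effects.tsv`` ground-truth pair.  Reading the
    files back reproduces the in-memory tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for run_id, frame in study.peptides.items():
        p = out / f"peptides_{run_id}.tsv"
        frame.to_csv(p, sep="\t", index=False, columns=PEPTIDE_COLUMNS,
                     float_format="%.10g")
        paths[f"peptides_{run_id}"] = p

    p = out / "expression.tsv"
    study.expression.to_csv(p, sep="\t", float_format="%.10g")
    paths["expression"] = p

    rows = []
    for sample_id, group in study.groups.items():
        runs = (study.design.runs_of_patient(sample_id) if group == "AML" else
                [r for r, (_, cs) in study.design.assignment.items()
                 if sample_id in cs])
        rows.append({"sample_id": sample_id, "group": group,
                     "runs": ",".join(runs)})
    p = out / "samples.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    paths["samples"] = p

    p = out / "truth.tsv"
    study.truth.proteins.to_csv(p, sep="\t")
    paths["truth"] = p
    p = out / "truth_effects.tsv"
    study.truth.effects.to_csv(p, sep="\t", float_format="%.10g")
    paths["truth_effects"] = p
    return paths


def read_peptides(path: str | Path) -> pd.DataFrame:
    """Read one run's peptide table written by :func:`write_study`."""
    frame = pd.read_csv(path, sep="\t", dtype={"run_id": str, "peptide_id": str,
                                               "protein_id": str,
                                               "sample_id": str,
                                               "control_id": str})
    missing = set(PEPTIDE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"peptide table {path} missing columns {sorted(missing)}")
    return frame[PEPTIDE_COLUMNS]


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna({"runs": ""})
    return frame
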