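"""Study design: how AML patients and CD34+ controls are laid out across
multiplexed isobaric-tag runs.

An 8-plex run carries up to eight reporter channels.  Each run mixes a handful
of AML patient samples with one or two normal CD34+ control channels; ratios
are always reported sample-channel vs. control-channel within a run.  Runs
with two control channels additionally yield control:control peptide ratios
(the empirical-null source) and enable the dual-control coincidence rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class DesignError(ValueError):
    """Raised when a study layout violates channel or assignment constraints."""


@dataclass(frozen=True)
class StudyDesign:
    """Assignment of patients and controls to multiplexed runs.

    Parameters
    ----------
    n_patients, n_controls, n_runs
        Cohort sizes and number of MS runs.
    channels_per_run
        Reporter channels available per run (8 for an 8-plex).
    assignment
        Mapping ``run_id -> (patient_ids, control_ids)``.  Every patient must
        appear in at least one run and each run must fit in its channels.
    """

    n_patients: int
    n_controls: int
    n_runs: int
    channels_per_run: int = 8
    assignment: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_controls, self.n_runs) < 1:
            raise DesignError("n_patients, n_controls and n_runs must be >= 1")
        if not self.assignment:
            object.__setattr__(self, "assignment", self._default_assignment())
        self._validate()

    # -- construction ---------------------------------------------------

    def _default_assignment(self):
        """Round-robin layout: patients split evenly across runs, two control
        channels per run drawn cyclically from the control pool."""
        patients = [f"AML{i + 1:02d}" for i in range(self.n_patients)]
        controls = [f"CD34_{i + 1}" for i in range(self.n_controls)]
        per_run = -(-self.n_patients // self.n_runs)  # ceil
        assignment = {}
        c = 0
        for r in range(self.n_runs):
            run_patients = tuple(patients[r * per_run : (r + 1) * per_run])
            n_ctrl = 2 if self.n_controls >= 2 else 1
            run_controls = tuple(
                controls[(c + j) % self.n_controls] for j in range(n_ctrl)
            )
            c += n_ctrl
            assignment[f"run{r + 1}"] = (run_patients, run_controls)
        return assignment

    def _validate(self) -> None:
        seen_patients: set[str] = set()
        for run_id, (patients, controls) in self.assignment.items():
            if not 1 <= len(controls) <= 2:
                raise DesignError(f"{run_id}: need 1 or 2 control channels")
            if len(patients) + len(controls) > self.channels_per_run:
                raise DesignError(
                    f"{run_id}: {len(patients)} patients + {len(controls)} "
                    f"controls exceed {self.channels_per_run} channels"
                )
            if set(patients) & set(controls):
                raise DesignError(f"{run_id}: sample assigned as both patient and control")
            seen_patients.update(patients)
        if len(seen_patients) < self.n_patients:
            raise DesignError("every patient must be assigned to at least one run")

    # -- convenience ----------------------------------------------------

    @property
    def patient_ids(self) -> list[str]:
        out: list[str] = []
        for patients, _ in self.assignment.values():
            out.extend(p for p in patients if p not in out)
        return out

    @property
    def control_ids(self) -> list[str]:
        out: list[str] = []
        for _, controls in self.assignment.values():
            out.extend(c for c in controls if c not in out)
        return out

    @property
    def run_ids(self) -> list[str]:
        return list(self.assignment)

    def runs_of_patient(self, patient_id: str) -> list[str]:
        return [
            run_id
            for run_id, (patients, _) in self.assignment.items()
            if patient_id in patients
        ]


def cohort_design() -> StudyDesign:
    """The discovery-cohort layout: 15 FAB-M1 AML patients and five CD34+
    controls analysed across three 8-plex runs, two control channels per run."""
    return StudyDesign(n_patients=15, n_controls=5, n_runs=3)
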