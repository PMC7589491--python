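"""Shared data model for Franz-cell permeation experiments and results.

Conventions used throughout the package:

* time is stored in **hours** at every API boundary and converted to seconds
  only inside flux/permeability arithmetic (permeabilities are reported in
  cm/s, the field's customary unit);
* concentrations are in µg/mL, volumes in mL, membrane area in cm²
  (1 mL = 1 cm³, so µg/mL ≡ µg/cm³ and no unit factors appear in the
  permeability formulas);
* missing tabulated values are represented as ``None`` / ``NaN``, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellGeometry",
    "SamplingSchedule",
    "PermeationExperiment",
    "FluxEstimate",
    "PappResult",
    "DrugRecord",
    "CorrelationResult",
    "ValidationFinding",
    "validate_experiment",
    "load_drug_table",
    "drug_table_frame",
    "DEFAULT_GEOMETRY",
    "DEFAULT_SCHEDULE_H",
    "EXCLUDED_ACTIVE_TRANSPORT",
    "PAPP_COLUMNS",
]

#: Sampling times (hours) of the standard 12 h Franz-cell run.
DEFAULT_SCHEDULE_H: tuple[float, ...] = (
    0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 10.0, 12.0,
)

#: Drugs excluded from the fraction-absorbed regression as actively
#: transported.  Note the reference table additionally flags ketoprofen as
#: actively transported; only this trio is excluded in the correlation
#: analysis.
EXCLUDED_ACTIVE_TRANSPORT: tuple[str, ...] = (
    "ranitidine", "trimethoprim", "verapamil",
)

#: Permeability columns of the reference drug table (all in 1e-6 cm/s).
PAPP_COLUMNS: tuple[str, ...] = (
    "papp_franz", "papp_nonsink", "papp_caco2",
    "papp_corti", "papp_pampa74", "papp_permeapad",
)


@dataclass(frozen=True)
class CellGeometry:
    """Physical constants of one Franz diffusion cell.

    Parameters
    ----------
    area:
        Membrane diffusion area in cm².
    donor_volume, receiver_volume:
        Chamber volumes in mL.
    sample_volume:
        Volume in mL withdrawn at each sampling time and immediately
        replaced with fresh buffer.
    """

    area: float
    donor_volume: float
    receiver_volume: float
    sample_volume: float

    def __post_init__(self) -> None:
        for name in ("area", "donor_volume", "receiver_volume"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sample_volume < 0:
            raise ValueError("sample_volume must be non-negative")
        if self.sample_volume >= self.receiver_volume:
            raise ValueError("sample_volume must be smaller than receiver_volume")

    @property
    def dilution_factor(self) -> float:
        """Replacement dilution factor f = (V_receiver − V_sample)/V_receiver."""
        return (self.receiver_volume - self.sample_volume) / self.receiver_volume


#: Standard cell: 1.77 cm² membrane, 1 mL donor, 7 mL receiver, 1 mL sample.
#: The 1 mL sample volume is an assumption (the withdrawn volume is not
#: reported for the reference assay); it is configurable everywhere.
DEFAULT_GEOMETRY = CellGeometry(
    area=1.77, donor_volume=1.0, receiver_volume=7.0, sample_volume=1.0
)


@dataclass(frozen=True)
class SamplingSchedule:
    """Strictly increasing sampling times in hours."""

    times: tuple[float, ...]

    def __init__(self, times: Sequence[float]) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in times))
        arr = np.asarray(self.times)
        if arr.size == 0:
            raise ValueError("schedule must contain at least one time")
        if arr[0] <= 0 or np.any(np.diff(arr) <= 0):
            raise ValueError("times must be strictly increasing and > 0")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def intervals_h(self) -> np.ndarray:
        """Interval lengths Δt in hours, the first measured from t = 0."""
        return np.diff(np.concatenate([[0.0], self.times]))


@dataclass
class PermeationExperiment:
    """Receiver-compartment concentration–time observations for one drug.

    ``replicates`` holds one concentration series (µg/mL) per cell, each
    aligned to ``schedule``; concentrations are the values measured in the
    withdrawn sample, i.e. before replacement dilution.
    """

    drug_name: str
    geometry: CellGeometry
    schedule: SamplingSchedule
    donor_concentration_0: float
    replicates: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def mean_series(self) -> np.ndarray:
        """Replicate-mean receiver concentration at each schedule time."""
        if not self.replicates:
            raise ValueError("experiment has no replicates")
        return np.mean(np.vstack(self.replicates), axis=0)


@dataclass
class FluxEstimate:
    """Steady-state flux from the linear portion of cumulative transport."""

    slope: float                    # mean cumulative-mass slope, µg/h
    window_start_index: int
    window_end_index: int           # inclusive
    r_squared: float | None         # OLS R² of the mean-series window
    flux_J: float                   # µg/cm²/s
    cv_percent: float               # CV of per-replicate flux, %


@dataclass
class PappResult:
    """Apparent permeability estimates with fit diagnostics."""

    papp_sink: float | None = None      # cm/s, steady-state flux / C0
    papp_nonsink: float | None = None   # cm/s, two-compartment model fit
    ssr: float | None = None            # final sum of squared residuals, (µg/mL)²
    qtotal_mode: str | None = None      # "paper-literal" | "mass-conserving"
    classification: str = "unclassified"
    degenerate_fit: bool = False


@dataclass
class DrugRecord:
    """One row of the reference drug table (permeabilities in 1e-6 cm/s)."""

    name: str
    bcs_class: str
    fa_percent: float
    papp_franz: float | None = None
    papp_nonsink: float | None = None
    papp_caco2: float | None = None
    papp_corti: float | None = None
    papp_pampa74: float | None = None
    papp_permeapad: float | None = None
    log_p: float | None = None
    log_d: float | None = None
    pka: tuple[float, ...] = ()
    intrinsic_solubility: float | None = None
    actively_transported: bool = False
    hp_literature: bool = False

    def __post_init__(self) -> None:
        if self.bcs_class not in {"I", "II", "III", "IV"}:
            raise ValueError(f"bcs_class must be I–IV, got {self.bcs_class!r}")
        if not 0 <= self.fa_percent <= 100:
            raise ValueError("fa_percent must lie in [0, 100]")
        for col in PAPP_COLUMNS:
            v = getattr(self, col)
            if v is not None and v < 0:
                raise ValueError(f"{col} must be non-negative when present")


@dataclass
class CorrelationResult:
    """A fitted permeability–absorption (or cross-membrane) regression."""

    model_form: str                 # "log-linear" | "linear"
    x_column: str
    included_drugs: tuple[str, ...]
    n: int
    slope: float
    intercept: float
    r: float
    r_squared: float


@dataclass(frozen=True)
class ValidationFinding:
    """One violated invariant: which field, and what rule it broke."""

    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.message}"


def validate_experiment(exp: PermeationExperiment) -> list[ValidationFinding]:
    """Check every invariant of a :class:`PermeationExperiment`.

    Returns an empty list for a well-formed experiment, otherwise one
    finding per violation.  Never raises: findings, not exceptions.
    """
    findings: list[ValidationFinding] = []
    if not exp.drug_name:
        findings.append(ValidationFinding("drug_name", "must be non-empty"))
    if not exp.donor_concentration_0 > 0:
        findings.append(
            ValidationFinding("donor_concentration_0", "must be strictly positive")
        )
    n_times = len(exp.schedule)
    if not exp.replicates:
        findings.append(ValidationFinding("replicates", "at least one replicate required"))
    for i, rep in enumerate(exp.replicates):
        if len(rep) != n_times:
            findings.append(ValidationFinding(
                f"replicates[{i}]",
                f"length mismatch: {len(rep)} values for {n_times} schedule times",
            ))
            continue
        if np.any(~np.isfinite(rep)):
            findings.append(ValidationFinding(
                f"replicates[{i}]", "non-finite concentration"))
        bad = np.where(rep < 0)[0]
        for j in bad:
            findings.append(ValidationFinding(
                f"replicates[{i}][{j}]",
                f"negative concentration {rep[j]:g} µg/mL",
            ))
    return findings


# ---------------------------------------------------------------------------
# Reference drug table
# ---------------------------------------------------------------------------

def drug_table_frame() -> pd.DataFrame:
    """Load the packaged reference drug table as a DataFrame.

    Permeability columns are in 1e-6 cm/s; empty cells are NaN.
    """
    with resources.files("franzperm.data").joinpath("drug_table.csv").open() as fh:
        df = pd.read_csv(fh)
    for col in ("actively_transported", "hp_literature"):
        df[col] = df[col].astype(bool)
    return df


def load_drug_table() -> list[DrugRecord]:
    """Load the packaged reference drug table as :class:`DrugRecord` objects."""
    records = []
    for _, row in drug_table_frame().iterrows():
        def _opt(v):
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        pka_raw = row["pka"]
        pka = ()
        if isinstance(pka_raw, str) and pka_raw.strip():
            pka = tuple(float(x) for x in pka_raw.split(";"))
        records.append(DrugRecord(
            name=row["name"],
            bcs_class=row["bcs_class"],
            fa_percent=float(row["fa_percent"]),
            papp_franz=_opt(row["papp_franz"]),
            papp_nonsink=_opt(row["papp_nonsink"]),
            papp_caco2=_opt(row["papp_caco2"]),
            papp_corti=_opt(row["papp_corti"]),
            papp_pampa74=_opt(row["papp_pampa74"]),
            papp_permeapad=_opt(row["papp_permeapad"]),
            log_p=_opt(row["log_p"]),
            log_d=_opt(row["log_d"]),
            pka=pka,
            intrinsic_solubility=_opt(row["intrinsic_solubility"]),
            actively_transported=bool(row["actively_transported"]),
            hp_literature=bool(row["hp_literature"]),
        ))
    return records
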