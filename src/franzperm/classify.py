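"""BCS permeability classification against an internal reference drug.

A drug is called highly permeable when its apparent permeability exceeds
0.8× that of metoprolol measured under the same conditions — metoprolol
sitting near the low/high permeability class boundary.  The comparison
must use permeabilities computed by the same method (sink with sink,
non-sink with non-sink).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "classify_permeability",
    "classify_table",
    "dose_number",
    "ClassificationReport",
    "REFERENCE_FRACTION",
]

#: High-permeability threshold as a fraction of the reference drug's Papp.
REFERENCE_FRACTION = 0.8

#: Standard reference gastric volume for the dose number, mL.
REFERENCE_VOLUME_ML = 250.0


@dataclass
class ClassificationReport:
    """Per-drug permeability labels plus summary counts."""

    reference_drug: str
    reference_papp: float
    threshold: float
    labels: dict[str, str]      # drug -> "high" | "low" | "missing"
    n_high: int
    n_low: int
    n_missing: int


def classify_permeability(papp: float, papp_reference: float) -> str:
    """Label a permeability ``high`` or ``low`` against the reference.

    ``high`` iff papp > 0.8 × papp_reference, strictly: a drug exactly at
    the threshold is low.  Both values must be positive and computed by
    the same method.
    """
    if papp <= 0 or papp_reference <= 0:
        raise ValueError("permeabilities must be strictly positive")
    return "high" if papp > REFERENCE_FRACTION * papp_reference else "low"


def classify_table(
    records: list[tuple[str, float | None]],
    reference_drug: str,
) -> ClassificationReport:
    """Classify every non-reference drug of a (name, papp) table.

    Drugs with a missing permeability are counted as ``missing``.  The
    reference drug itself is not labelled.
    """
    ref = {name.lower(): papp for name, papp in records}.get(reference_drug.lower())
    if ref is None:
        raise ValueError(f"reference drug {reference_drug!r} not found or has no Papp")
    if ref <= 0:
        raise ValueError("reference permeability must be strictly positive")

    labels: dict[str, str] = {}
    for name, papp in records:
        if name.lower() == reference_drug.lower():
            continue
        if papp is None:
            labels[name] = "missing"
        else:
            labels[name] = classify_permeability(papp, ref)
    counts = {"high": 0, "low": 0, "missing": 0}
    for lab in labels.values():
        counts[lab] += 1
    return ClassificationReport(
        reference_drug=reference_drug,
        reference_papp=ref,
        threshold=REFERENCE_FRACTION * ref,
        labels=labels,
        n_high=counts["high"],
        n_low=counts["low"],
        n_missing=counts["missing"],
    )


def dose_number(
    dose_mass: float,
    solubility: float,
    reference_volume: float = REFERENCE_VOLUME_ML,
) -> float:
    """Dose number D0 = (dose / reference volume) / solubility.

    ``dose_mass`` in mg, ``solubility`` in mg/mL, ``reference_volume`` in
    mL (250 mL standard gastric volume).  D0 ≪ 1 means solubility does not
    limit absorption of the dose.
    """
    if dose_mass <= 0 or solubility <= 0 or reference_volume <= 0:
        raise ValueError("dose, solubility and reference volume must be positive")
    return (dose_mass / reference_volume) / solubility
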