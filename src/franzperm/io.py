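"""File formats and configuration.

Concentration–time observations travel as long-format CSV with columns
``drug,replicate,time_h,conc_ug_ml`` (header required, UTF-8, "." decimal
separator); long format keeps ragged replicates representable even though
the data model requires schedule-aligned series.  Experiment geometry and
the donor concentration are not part of the CSV: they come from a YAML
configuration (keys ``geometry``, ``schedule``, ``simulation``,
``fitting``, ``correlation``) or are supplied directly.

Result tables are written as CSV or JSON with a stable column order and
floats rendered to 6 significant digits, so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from franzperm.core import (
    CellGeometry,
    PermeationExperiment,
    SamplingSchedule,
    validate_experiment,
)

__all__ = [
    "ParseError",
    "read_concentration_csv",
    "write_concentration_csv",
    "write_results",
    "load_config",
    "geometry_from_config",
    "schedule_from_config",
]

CONCENTRATION_COLUMNS = ("drug", "replicate", "time_h", "conc_ug_ml")


class ParseError(ValueError):
    """Malformed input file; message names the offending line or column."""


def read_concentration_csv(
    path: str | Path,
    geometry: CellGeometry,
    donor_concentration_0: float,
    drug: str | None = None,
    validate: bool = True,
) -> PermeationExperiment:
    """Read one experiment from the long-format concentration CSV.

    All rows must share one drug name (or match ``drug`` when given) and
    every replicate must cover the same strictly increasing schedule.
    Raises :class:`ParseError` for malformed files and ``ValueError``
    listing the findings when the assembled experiment violates its
    invariants.
    """
    path = Path(path)
    by_replicate: dict[str, list[tuple[float, float]]] = {}
    drug_seen: str | None = None
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file")
        missing = [c for c in CONCENTRATION_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ParseError(f"{path}: missing required column(s) {', '.join(missing)}")
        for row in reader:
            line = reader.line_num
            name = (row["drug"] or "").strip()
            if drug is not None and name != drug:
                continue
            if drug_seen is None:
                drug_seen = name
            elif name != drug_seen:
                raise ParseError(
                    f"{path}:{line}: multiple drugs in file "
                    f"({drug_seen!r} and {name!r}); pass drug= to select one"
                )
            try:
                t = float(row["time_h"])
                c = float(row["conc_ug_ml"])
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}:{line}: non-numeric time_h/conc_ug_ml value"
                ) from None
            by_replicate.setdefault(row["replicate"].strip(), []).append((t, c))
    if not by_replicate:
        raise ParseError(f"{path}: no data rows" + (f" for drug {drug!r}" if drug else ""))

    schedules = []
    series = []
    for rep_id in sorted(by_replicate):
        pairs = sorted(by_replicate[rep_id])
        schedules.append(tuple(t for t, _ in pairs))
        series.append(np.array([c for _, c in pairs]))
    if len(set(schedules)) != 1:
        raise ParseError(f"{path}: replicates do not share one sampling schedule")

    exp = PermeationExperiment(
        drug_name=drug_seen or "",
        geometry=geometry,
        schedule=SamplingSchedule(schedules[0]),
        donor_concentration_0=donor_concentration_0,
        replicates=series,
    )
    if validate:
        findings = validate_experiment(exp)
        if findings:
            raise ValueError(
                "invalid experiment: " + "; ".join(str(f) for f in findings)
            )
    return exp


def write_concentration_csv(exp: PermeationExperiment, path: str | Path) -> None:
    """Write an experiment in the long-format concentration CSV dialect."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CONCENTRATION_COLUMNS)
        for i, rep in enumerate(exp.replicates, start=1):
            for t, c in zip(exp.schedule.times, rep):
                writer.writerow([exp.drug_name, i, _fmt(t), _fmt(c)])


def _fmt(x: Any) -> Any:
    """Render floats to 6 significant digits; pass everything else through."""
    if isinstance(x, (bool, str)) or x is None:
        return x
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return ""
        return format(float(x), ".6g")
    return x


def write_results(
    results: list[dict[str, Any]],
    path: str | Path,
    format: str = "csv",
) -> None:
    """Write result rows as CSV or JSON with deterministic byte output.

    Column order is that of the first row (subsequent rows may not
    introduce new keys); an empty result list yields a header-only CSV or
    an empty JSON array.
    """
    path = Path(path)
    if format not in ("csv", "json"):
        raise ValueError("format must be 'csv' or 'json'")
    columns: list[str] = list(results[0].keys()) if results else []
    for row in results[1:]:
        extra = set(row) - set(columns)
        if extra:
            raise ValueError(f"inconsistent result keys: {sorted(extra)}")

    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(columns)
            for row in results:
                writer.writerow([_fmt(row.get(c)) for c in columns])
    else:
        def _json_value(v: Any) -> Any:
            rendered = _fmt(v)
            if rendered == "":
                return None
            if isinstance(v, (float, np.floating)):
                return float(rendered)   # numeric, rounded to 6 significant digits
            return rendered

        payload = [{c: _json_value(row.get(c)) for c in columns} for row in results]
        with path.open("w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=False)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load the top-level YAML configuration."""
    with Path(path).open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a mapping")
    return cfg


def geometry_from_config(cfg: dict) -> CellGeometry:
    """Build a :class:`CellGeometry` from the ``geometry`` config section."""
    g = cfg.get("geometry", {})
    try:
        return CellGeometry(
            area=float(g["area_cm2"]),
            donor_volume=float(g["donor_volume_ml"]),
            receiver_volume=float(g["receiver_volume_ml"]),
            sample_volume=float(g["sample_volume_ml"]),
        )
    except KeyError as err:
        raise ParseError(f"geometry section missing key {err}") from None


def schedule_from_config(cfg: dict) -> SamplingSchedule:
    """Build a :class:`SamplingSchedule` from the ``schedule`` config section."""
    s = cfg.get("schedule", {})
    try:
        return SamplingSchedule([float(t) for t in s["times_h"]])
    except KeyError:
        raise ParseError("schedule section missing key 'times_h'") from None
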