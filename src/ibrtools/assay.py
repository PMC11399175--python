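"""Microplate assay processing: raw plate reads to per-animal biomarker endpoints.

Kinetic assays (e.g. acetylcholinesterase read at 412 nm every minute for
six minutes, superoxide dismutase at 420 nm every 30 s for four minutes,
glutathione S-transferase at 340 nm every 30 s for three minutes,
electron-transport-system activity at 490 nm) are reduced to an
ordinary-least-squares slope in optical density per minute.  Endpoint
assays (metallothionein, catalase, malondialdehyde, protein carbonyls,
reduced glutathione, glucose, lipid, protein) keep the single absorbance.

All endpoints are blank-corrected against procedural blanks, triplicate
wells are averaged with a coefficient-of-variation quality flag, and
values are standardised to the protein content of each sample.  Because
no extinction coefficients are applied, endpoints are expressed in
blank-corrected signal units per mg protein (OD/min/mg or OD/mg); every
downstream statistic in this package (rank tests, standardisation, IBRv2)
is invariant to per-biomarker linear rescaling, so absolute enzymatic
units are never required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticTrace",
    "EndpointRead",
    "PlateLayout",
    "InvalidTraceError",
    "BlankConfigurationError",
    "NormalizationError",
    "PlateInputError",
    "kinetic_rate",
    "blank_correct",
    "aggregate_replicates",
    "normalize_to_protein",
    "build_biomarker_table",
    "read_plate_csv",
    "process_plate",
]

#: default replicate coefficient-of-variation warning threshold (fraction)
DEFAULT_CV_THRESHOLD = 0.20


class InvalidTraceError(ValueError):
    """A kinetic trace cannot yield a slope (too few points, zero time span)."""


class BlankConfigurationError(ValueError):
    """An assay run has no blank wells to correct against."""


class NormalizationError(ValueError):
    """Protein standardisation is impossible (non-positive protein)."""


class PlateInputError(ValueError):
    """Malformed plate or grouping input (duplicate animals, unknown groups)."""


@dataclass(frozen=True)
class KineticTrace:
    """Absorbance-versus-time reads for one well of a kinetic assay."""

    well_id: str
    sample_id: str
    role: str  # "sample" | "blank"
    times: tuple[float, ...]  # seconds, strictly increasing
    absorbances: tuple[float, ...]  # optical density
    wavelength: float  # nm

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if t.size != a.size:
            raise InvalidTraceError(
                f"well {self.well_id}: {t.size} times vs {a.size} absorbances"
            )
        if t.size < 2:
            raise InvalidTraceError(f"well {self.well_id}: fewer than 2 reads")
        if not np.all(np.diff(t) > 0):
            raise InvalidTraceError(f"well {self.well_id}: times not strictly increasing")
        if self.wavelength <= 0:
            raise InvalidTraceError(f"well {self.well_id}: wavelength must be > 0")


@dataclass(frozen=True)
class EndpointRead:
    """A single absorbance read for one well of an endpoint assay."""

    well_id: str
    sample_id: str
    role: str  # "sample" | "blank"
    absorbance: float
    wavelength: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.absorbance):
            raise PlateInputError(f"well {self.well_id}: non-finite absorbance")
        if self.wavelength <= 0:
            raise PlateInputError(f"well {self.well_id}: wavelength must be > 0")


@dataclass
class PlateLayout:
    """Maps well ids to (sample_id, role, replicate_index)."""

    wells: dict[str, tuple[str, str, int]] = field(default_factory=dict)

    def add(self, well_id: str, sample_id: str, role: str, replicate: int = 1) -> None:
        self.wells[well_id] = (sample_id, role, replicate)

    def sample_of(self, well_id: str) -> str:
        return self.wells[well_id][0]

    def role_of(self, well_id: str) -> str:
        return self.wells[well_id][1]

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid, role, _ in self.wells.values():
            if role == "sample":
                seen.setdefault(sid, None)
        return list(seen)


def kinetic_rate(trace: KineticTrace) -> float:
    """Ordinary-least-squares slope of absorbance against time, in OD/min.

    The sign is preserved: a decreasing trace (substrate-depletion read)
    gives a negative rate.  All reads are used; callers wanting lag-phase
    trimming should slice the trace first.
    """
    t_min = np.asarray(trace.times, dtype=float) / 60.0
    a = np.asarray(trace.absorbances, dtype=float)
    if t_min[-1] == t_min[0]:
        raise InvalidTraceError(f"well {trace.well_id}: zero time span")
    # OLS slope; centering keeps the normal equations well conditioned
    tc = t_min - t_min.mean()
    return float(np.dot(tc, a - a.mean()) / np.dot(tc, tc))


def blank_correct(
    values: Mapping[str, float], layout: PlateLayout
) -> tuple[dict[str, float], float]:
    """Subtract the mean blank signal from every sample well.

    ``values`` maps well ids to per-well measurements — endpoint
    absorbances or kinetic rates; the correction is the same subtraction
    either way.  Returns (corrected sample-well values, blank mean used).
    """
    blanks = [v for w, v in values.items() if layout.role_of(w) == "blank"]
    if not blanks:
        raise BlankConfigurationError("no blank wells present in this assay run")
    blank_mean = float(np.mean(blanks))
    corrected = {
        w: float(v) - blank_mean
        for w, v in values.items()
        if layout.role_of(w) == "sample"
    }
    return corrected, blank_mean


def aggregate_replicates(
    values: Mapping[str, float],
    layout: PlateLayout,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> pd.DataFrame:
    """Average replicate wells per sample and report the replicate CV.

    Returns a frame indexed by sample_id with columns ``value`` (replicate
    mean), ``cv`` (sd/|mean|, NaN for a single replicate or zero mean) and
    ``cv_flag`` (True when the CV exceeds ``cv_threshold``).
    """
    per_sample: dict[str, list[float]] = {}
    for well, v in values.items():
        sid, role, _ = layout.wells[well]
        if role != "sample":
            continue
        per_sample.setdefault(sid, []).append(float(v))
    rows = []
    for sid, reps in per_sample.items():
        mean = float(np.mean(reps))
        if len(reps) < 2 or mean == 0.0:
            cv = float("nan")
        else:
            cv = float(np.std(reps, ddof=1) / abs(mean))
        rows.append(
            {
                "sample_id": sid,
                "value": mean,
                "cv": cv,
                "cv_flag": bool(cv > cv_threshold) if math.isfinite(cv) else False,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def normalize_to_protein(raw: float, protein: float, sample_id: str = "?") -> float:
    """Standardise an endpoint by sample protein content (per mg protein)."""
    if not protein > 0:
        raise NormalizationError(
            f"sample {sample_id}: protein content must be > 0, got {protein}"
        )
    return raw / protein


def build_biomarker_table(
    assay_values: Mapping[str, Mapping[str, float]],
    groups: Mapping[str, str],
    units: Mapping[str, str] | None = None,
    valid_groups: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Assemble per-assay per-animal values into a tidy wide table.

    ``assay_values`` maps biomarker name -> {animal_id: value}; ``groups``
    maps animal_id -> group label.  Animals missing an assay get NaN, never
    a dropped row.  Unit strings are attached as ``DataFrame.attrs['units']``.
    """
    animal_ids = list(groups)
    if len(set(animal_ids)) != len(animal_ids):
        raise PlateInputError("duplicate animal_id in group assignment")
    if valid_groups is not None:
        bad = sorted(set(groups.values()) - set(valid_groups))
        if bad:
            raise PlateInputError(f"unknown group label(s): {bad}")
    table = pd.DataFrame({"animal_id": animal_ids, "group": [groups[a] for a in animal_ids]})
    for biomarker, per_animal in assay_values.items():
        extra = set(per_animal) - set(animal_ids)
        if extra:
            raise PlateInputError(
                f"assay {biomarker}: sample ids {sorted(extra)} have no group label"
            )
        table[biomarker] = [per_animal.get(a, np.nan) for a in animal_ids]
    table.attrs["units"] = dict(units or {})
    return table


# ---------------------------------------------------------------------------
# plate CSV front end

PLATE_COLUMNS = ["well", "sample", "role", "replicate", "time_s", "absorbance", "wavelength_nm", "assay"]


def read_plate_csv(path) -> pd.DataFrame:
    """Read a long-format plate CSV (one row per read) and validate columns."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateInputError(f"plate CSV missing columns: {missing}")
    return df


def process_plate(
    plate: pd.DataFrame,
    assay: str,
    kinetic: bool,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> pd.DataFrame:
    """Reduce one assay's plate rows to per-sample blank-corrected values.

    Kinetic assays are sloped per well first; endpoint assays use the read
    as-is.  The order blank-correct-then-average equals average-then-blank-
    correct (both are linear), so the choice here is one of bookkeeping.
    """
    rows = plate[plate["assay"] == assay]
    if rows.empty:
        raise PlateInputError(f"no rows for assay {assay!r}")
    layout = PlateLayout()
    per_well: dict[str, float] = {}
    for well, grp in rows.groupby("well", sort=False):
        first = grp.iloc[0]
        layout.add(str(well), str(first["sample"]), str(first["role"]), int(first["replicate"]))
        if kinetic:
            grp = grp.sort_values("time_s")
            trace = KineticTrace(
                well_id=str(well),
                sample_id=str(first["sample"]),
                role=str(first["role"]),
                times=tuple(grp["time_s"].astype(float)),
                absorbances=tuple(grp["absorbance"].astype(float)),
                wavelength=float(first["wavelength_nm"]),
            )
            per_well[str(well)] = kinetic_rate(trace)
        else:
            if len(grp) != 1:
                raise PlateInputError(f"endpoint assay {assay!r}: well {well} has {len(grp)} reads")
            per_well[str(well)] = float(first["absorbance"])
    corrected, blank_mean = blank_correct(per_well, layout)
    out = aggregate_replicates(corrected, layout, cv_threshold=cv_threshold)
    out.attrs["blank_mean"] = blank_mean
    out.attrs["assay"] = assay
    return out
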