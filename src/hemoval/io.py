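"""Data model, validation and CSV readers/writers.

Two interchange files are used throughout the package:

``series.csv``
    columns ``patient_id,t_seconds,map_mmHg,hpi`` — one row per 20-s
    sample of a patient's mean arterial pressure (MAP, mmHg) and the
    prediction index (HPI, 0-100; empty cell = device dropout).

``pairs.csv``
    columns ``patient_id,t_seconds,variable,reference,device`` — one
    row per same-timepoint paired measurement of cardiac output
    (``CO``, L·min⁻¹) or systemic vascular resistance
    (``SVR``, dynes·s·cm⁻⁵) from the reference pulmonary artery
    catheter and the device under evaluation.

Time is stored as seconds from each series' own start (0-based); no
clock times or time zones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SERIES_COLUMNS = ["patient_id", "t_seconds", "map_mmHg", "hpi"]
PAIRS_COLUMNS = ["patient_id", "t_seconds", "variable", "reference", "device"]

VARIABLES = ("CO", "SVR")

#: Clinically acceptable difference per variable: ±1 L·min⁻¹ for cardiac
#: output, ±200 dynes·s·cm⁻⁵ for systemic vascular resistance.
DEFAULT_CAD = {"CO": 1.0, "SVR": 200.0}


class ValidationError(ValueError):
    """Raised when input data violates a model invariant."""


@dataclass(frozen=True)
class HemoSeries:
    """One patient's timestamped MAP and HPI samples.

    Parameters
    ----------
    patient_id : str
        Cohort-unique identifier.
    t : ndarray of float
        Sample times in seconds from series start, strictly increasing.
    map_mmHg : ndarray of float
        Mean arterial pressure; NaN marks a missing MAP sample.
    hpi : ndarray of float
        Prediction index in [0, 100]; NaN marks device dropout, which
        downstream alert detection treats as below the alert threshold.
    nominal_dt : float
        Nominal sampling interval in seconds (device default 20).
    """

    patient_id: str
    t: np.ndarray
    map_mmHg: np.ndarray
    hpi: np.ndarray
    nominal_dt: float = 20.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        m = np.asarray(self.map_mmHg, dtype=float)
        h = np.asarray(self.hpi, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "map_mmHg", m)
        object.__setattr__(self, "hpi", h)
        if not (len(t) == len(m) == len(h)):
            raise ValidationError(
                f"patient {self.patient_id!r}: t/map/hpi lengths differ "
                f"({len(t)}/{len(m)}/{len(h)})"
            )
        if self.nominal_dt <= 0:
            raise ValidationError("nominal_dt must be positive")
        if len(t) > 1:
            bad = np.where(np.diff(t) <= 0)[0]
            if bad.size:
                i = int(bad[0])
                raise ValidationError(
                    f"patient {self.patient_id!r}: non-increasing time at row "
                    f"{i + 1} (t={t[i]} followed by t={t[i + 1]})"
                )
        with np.errstate(invalid="ignore"):
            if np.any(m[~np.isnan(m)] <= 0):
                raise ValidationError(
                    f"patient {self.patient_id!r}: MAP must be positive where present"
                )
            hv = h[~np.isnan(h)]
            if np.any((hv < 0) | (hv > 100)):
                raise ValidationError(
                    f"patient {self.patient_id!r}: HPI must lie in [0, 100]"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Monitored span in seconds under sample-and-hold (last sample holds dt)."""
        if len(self.t) == 0:
            return 0.0
        return float(self.t[-1] - self.t[0] + self.nominal_dt)

    def gaps(self, factor: float = 2.0) -> list[tuple[float, float]]:
        """Return (start, end) of inter-sample intervals longer than factor×nominal_dt."""
        if len(self.t) < 2:
            return []
        dt = np.diff(self.t)
        idx = np.where(dt > factor * self.nominal_dt)[0]
        return [(float(self.t[i]), float(self.t[i + 1])) for i in idx]


@dataclass(frozen=True)
class PairedMeasurement:
    """A same-timepoint (reference, device) value pair for one variable.

    ``reference`` is the pulmonary-artery-catheter value and ``device``
    the prediction-platform value, in L·min⁻¹ for CO and
    dynes·s·cm⁻⁵ for SVR. Both must be positive; the relative
    difference is undefined otherwise.
    """

    patient_id: str
    t: float
    variable: str
    reference: float
    device: float

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValidationError(
                f"unknown variable {self.variable!r}; expected one of {VARIABLES}"
            )
        if not (self.reference > 0) or math.isnan(self.reference):
            raise ValidationError(
                f"patient {self.patient_id!r}: reference must be > 0 "
                f"(got {self.reference})"
            )
        if not (self.device > 0) or math.isnan(self.device):
            raise ValidationError(
                f"patient {self.patient_id!r}: device must be > 0 (got {self.device})"
            )

    @property
    def difference(self) -> float:
        """reference − device, in the variable's units."""
        return self.reference - self.device


@dataclass
class Cohort:
    """A study cohort: per-patient series plus paired CO/SVR measurements.

    A patient may contribute pairs without a series (missing
    intraoperative recording); such ids are listed in
    ``series_absent``.
    """

    series: list[HemoSeries] = field(default_factory=list)
    pairs: list[PairedMeasurement] = field(default_factory=list)

    @property
    def series_ids(self) -> list[str]:
        return [s.patient_id for s in self.series]

    @property
    def pair_ids(self) -> list[str]:
        return sorted({p.patient_id for p in self.pairs})

    @property
    def series_absent(self) -> list[str]:
        """Patient ids contributing pairs but no time series."""
        have = set(self.series_ids)
        return [pid for pid in self.pair_ids if pid not in have]

    def pairs_for(self, variable: str) -> list[PairedMeasurement]:
        if variable not in VARIABLES:
            raise ValidationError(f"unknown variable {variable!r}")
        return [p for p in self.pairs if p.variable == variable]


# ---------------------------------------------------------------------------
# CSV readers / writers


def _require_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def read_series(path, nominal_dt: float = 20.0) -> list[HemoSeries]:
    """Read a ``series.csv`` file into one :class:`HemoSeries` per patient.

    Rows are sorted by time within each patient; empty HPI cells parse
    as missing (NaN). Duplicate or non-monotone timestamps within a
    patient raise :class:`ValidationError` naming the patient.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, SERIES_COLUMNS, path)
    out: list[HemoSeries] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("t_seconds", kind="stable")
        t = grp["t_seconds"].to_numpy(dtype=float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            i = int(np.where(np.diff(t) <= 0)[0][0])
            raise ValidationError(
                f"{path}: patient {pid!r} has duplicate/non-increasing "
                f"t_seconds at value {t[i + 1]}"
            )
        out.append(
            HemoSeries(
                patient_id=str(pid),
                t=t,
                map_mmHg=grp["map_mmHg"].to_numpy(dtype=float),
                hpi=grp["hpi"].to_numpy(dtype=float),
                nominal_dt=nominal_dt,
            )
        )
    logger.info("read %d series (%d samples) from %s", len(out), len(df), path)
    return out


def write_series(series: Iterable[HemoSeries], path) -> None:
    """Write series to CSV; exact float round-trip via repr formatting."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "t_seconds": s.t,
                    "map_mmHg": s.map_mmHg,
                    "hpi": s.hpi,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=SERIES_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_pairs(path) -> list[PairedMeasurement]:
    """Read a ``pairs.csv`` file into validated :class:`PairedMeasurement` rows."""
    df = pd.read_csv(path, dtype={"patient_id": str, "variable": str})
    _require_columns(df, PAIRS_COLUMNS, path)
    out: list[PairedMeasurement] = []
    for row in df.itertuples(index=False):
        out.append(
            PairedMeasurement(
                patient_id=str(row.patient_id),
                t=float(row.t_seconds),
                variable=str(row.variable),
                reference=float(row.reference),
                device=float(row.device),
            )
        )
    counts = {v: sum(1 for p in out if p.variable == v) for v in VARIABLES}
    logger.info("read %d pairs from %s (per variable: %s)", len(out), path, counts)
    return out


def write_pairs(pairs: Iterable[PairedMeasurement], path) -> None:
    rows = [
        (p.patient_id, p.t, p.variable, p.reference, p.device) for p in pairs
    ]
    df = pd.DataFrame(rows, columns=PAIRS_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort validation report


def validate_cohort(cohort: Cohort, gap_factor: float = 2.0) -> dict:
    """Build a report-only summary of a cohort; never mutates its input.

    The report lists patients, samples per patient, pairs per patient
    and variable, the replicate range across patients, and data-gap
    locations (inter-sample interval > gap_factor × nominal_dt).
    """
    patients: dict[str, dict] = {}
    for s in cohort.series:
        patients.setdefault(s.patient_id, {})["n_samples"] = len(s)
        patients[s.patient_id]["gaps"] = s.gaps(gap_factor)
    pair_counts: dict[str, dict[str, int]] = {}
    for p in cohort.pairs:
        per = pair_counts.setdefault(p.patient_id, {v: 0 for v in VARIABLES})
        per[p.variable] += 1
        patients.setdefault(p.patient_id, {}).setdefault("n_samples", 0)
    for pid, per in pair_counts.items():
        patients[pid]["pairs"] = per
    replicates = [sum(per.values()) for per in pair_counts.values()]
    report = {
        "n_patients": len(patients),
        "n_series": len(cohort.series),
        "n_pairs": len(cohort.pairs),
        "pairs_per_variable": {
            v: sum(1 for p in cohort.pairs if p.variable == v) for v in VARIABLES
        },
        "replicate_range": (
            [int(min(replicates)), int(max(replicates))] if replicates else None
        ),
        "series_absent": cohort.series_absent,
        "patients": patients,
    }
    return report
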