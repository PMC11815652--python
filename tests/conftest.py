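"""Shared fixtures: hand-built series and randomized stress generators."""

from __future__ import annotations

import numpy as np
import pytest

from hemoval.io import HemoSeries, PairedMeasurement


def make_series(
    map_vals,
    hpi_vals=None,
    dt: float = 20.0,
    patient_id: str = "P01",
    t=None,
) -> HemoSeries:
    """Build a series from plain lists; None entries become NaN."""
    map_arr = np.array(
        [np.nan if v is None else float(v) for v in map_vals], dtype=float
    )
    n = len(map_arr)
    if hpi_vals is None:
        hpi_arr = np.full(n, 10.0)
    else:
        hpi_arr = np.array(
            [np.nan if v is None else float(v) for v in hpi_vals], dtype=float
        )
    tt = np.arange(n) * dt if t is None else np.asarray(t, dtype=float)
    return HemoSeries(
        patient_id=patient_id, t=tt, map_mmHg=map_arr, hpi=hpi_arr, nominal_dt=dt
    )


def random_stress_series(seed: int, n: int = 200, dt: float = 20.0) -> HemoSeries:
    """Random series hovering near both thresholds, with dropouts and gaps.

    Designed to exercise every branch of detection/matching: MAP walks
    around 65 mmHg, HPI around 85, ~3% of either channel missing, and
    occasional over-sized time steps that must break runs.
    """
    rng = np.random.default_rng(seed)
    steps = np.where(rng.random(n) < 0.03, rng.uniform(2.5, 8.0, n) * dt, dt)
    steps[0] = 0.0
    t = np.cumsum(steps)
    map_vals = 65.0 + np.cumsum(rng.normal(0.0, 2.0, n))
    map_vals = 65.0 + (map_vals - 65.0) % 24.0 - 12.0  # keep near the threshold
    map_vals = np.clip(map_vals, 30.0, 110.0)
    hpi_vals = np.clip(85.0 + rng.normal(0.0, 12.0, n), 0.0, 100.0)
    map_vals[rng.random(n) < 0.03] = np.nan
    hpi_vals[rng.random(n) < 0.03] = np.nan
    return HemoSeries(
        patient_id=f"S{seed}", t=t, map_mmHg=map_vals, hpi=hpi_vals, nominal_dt=dt
    )


def make_pairs(data, variable: str = "CO") -> list:
    """Pairs from (patient_id, reference, device) triples."""
    return [
        PairedMeasurement(
            patient_id=pid, t=float(i), variable=variable, reference=r, device=d
        )
        for i, (pid, r, d) in enumerate(data)
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient cohort reused by the heavier statistics tests."""
    from hemoval.synth import SynthConfig, simulate_cohort

    cfg = SynthConfig(n_patients=12, duration=4 * 3600.0, seed=42)
    return simulate_cohort(cfg)
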