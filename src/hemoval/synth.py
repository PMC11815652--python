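"""Synthetic-cohort generator with the structure the analyses assume.

The generator emulates a 23-patient liver-transplant cohort monitored
for roughly 30 hours (surgery plus the first post-operative day):

* MAP follows a stationary AR(1) (discrete Ornstein-Uhlenbeck) path
  around a baseline, with additive smooth hypotensive excursions whose
  onsets form a Poisson process; depth and duration are truncated
  normals. Only the threshold-crossing structure matters downstream,
  so no physiological waveform is modelled.
* HPI is constructed from *future* MAP: a saturating increasing
  function of (65 − min MAP over the next ``hpi_lead`` seconds), plus
  observation noise and spurious alert bursts at a tunable rate. With
  zero noise and zero false-alert rate, every hypotension onset is
  preceded by HPI ≥ 85 throughout the lead window, so downstream
  sensitivity is exactly 1 — prediction performance is a dial, not an
  emergent property.
* Paired CO/SVR measurements follow a variance-components model:
  patient truth u ~ N(true_mean, between_sd); reference = u + noise;
  device = device_scale·u + device_bias + noise. The shipped presets
  ``co_like`` (device reads lower) and ``svr_like`` (device reads
  higher) match the observed pooled means/SDs of the two devices.

All stochastic output is a deterministic function of (seed,
patient_id); regenerating with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

from hemoval.io import Cohort, HemoSeries, PairedMeasurement, write_pairs, write_series

_STREAM = {"map": 0, "dips": 1, "hpi_noise": 2, "false_alerts": 3, "CO": 4, "SVR": 5}


@dataclass(frozen=True)
class VariableSpec:
    """Variance-components model for one paired variable.

    reference = u + N(0, ref_noise_sd), device = device_scale·u +
    device_bias + N(0, device_noise_sd) with patient truth
    u ~ N(true_mean, between_sd). The analytic difference
    (reference − device) has mean (1 − device_scale)·true_mean −
    device_bias, between-patient variance (1 − device_scale)²·
    between_sd² and within-patient variance ref_noise_sd² +
    device_noise_sd².
    """

    true_mean: float
    between_sd: float
    device_bias: float
    device_scale: float
    ref_noise_sd: float
    device_noise_sd: float

    @property
    def analytic_bias(self) -> float:
        return (1.0 - self.device_scale) * self.true_mean - self.device_bias

    @property
    def analytic_var_between(self) -> float:
        return (1.0 - self.device_scale) ** 2 * self.between_sd**2

    @property
    def analytic_var_within(self) -> float:
        return self.ref_noise_sd**2 + self.device_noise_sd**2

    @property
    def analytic_sd(self) -> float:
        return float(np.sqrt(self.analytic_var_between + self.analytic_var_within))

    @property
    def analytic_ccc(self) -> float:
        """Population CCC of (reference, device) under the model."""
        s2b = self.between_sd**2
        sxy = self.device_scale * s2b
        sx2 = s2b + self.ref_noise_sd**2
        sy2 = self.device_scale**2 * s2b + self.device_noise_sd**2
        dmu = self.true_mean - (self.device_scale * self.true_mean + self.device_bias)
        return 2.0 * sxy / (sx2 + sy2 + dmu**2)


def co_like() -> VariableSpec:
    """Cardiac output preset: device reads lower than the reference.

    Tuned so pooled reference ≈ 10.4 ± 3.1 L·min⁻¹, device ≈ 8.1 ±
    2.3, difference ≈ 2.3 ± 2.6, population CCC ≈ 0.39.
    """
    return VariableSpec(
        true_mean=10.4,
        between_sd=2.8,
        device_bias=2.9,
        device_scale=0.5,
        ref_noise_sd=1.3,
        device_noise_sd=1.82,
    )


def svr_like() -> VariableSpec:
    """Systemic vascular resistance preset: device reads higher.

    Tuned so pooled reference ≈ 531 ± 228 dynes·s·cm⁻⁵, device ≈
    657 ± 260, difference ≈ −126 ± 219, population CCC ≈ 0.53.
    """
    return VariableSpec(
        true_mean=531.0,
        between_sd=212.0,
        device_bias=232.2,
        device_scale=0.8,
        ref_noise_sd=84.0,
        device_noise_sd=197.0,
    )


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generation parameters (defaults emulate the study setting).

    Units: seconds for times, mmHg for pressures, events/hour for
    rates, index points for HPI noise.
    """

    n_patients: int = 23
    duration: float = 30.0 * 3600.0  # surgery + first post-op day
    dt: float = 20.0
    map_mean: float = 78.0
    map_sd: float = 7.0
    ou_phi: float = 0.97  # lag-1 autocorrelation at 20-s sampling
    dip_rate: float = 0.9  # hypotensive excursions per hour
    dip_depth_mean: float = 18.0
    dip_depth_sd: float = 6.0
    dip_duration_mean: float = 300.0
    dip_duration_sd: float = 120.0
    hpi_lead: float = 300.0  # index rises this long before a MAP crossing
    hpi_noise_sd: float = 5.0
    false_alert_rate: float = 1.8  # spurious alert episodes per hour
    pairs_per_patient_range: tuple = (2, 11)
    variables: dict = field(
        default_factory=lambda: {"CO": co_like(), "SVR": svr_like()}
    )
    seed: int = 0
    map_floor: float = 20.0  # physiological floor after excursions

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if not 0.0 < self.ou_phi < 1.0:
            raise ValueError("ou_phi must lie in (0, 1)")
        for name in (
            "map_sd",
            "dip_rate",
            "dip_depth_sd",
            "dip_duration_sd",
            "hpi_noise_sd",
            "false_alert_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.pairs_per_patient_range
        if not (1 <= lo <= hi):
            raise ValueError("pairs_per_patient_range must be a non-empty [min, max]")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pairs_per_patient_range"] = list(self.pairs_per_patient_range)
        d["variables"] = {k: dataclasses.asdict(v) for k, v in self.variables.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "variables" in d:
            d["variables"] = {
                k: v if isinstance(v, VariableSpec) else VariableSpec(**v)
                for k, v in d["variables"].items()
            }
        if "pairs_per_patient_range" in d:
            d["pairs_per_patient_range"] = tuple(d["pairs_per_patient_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def study_defaults() -> SynthConfig:
    """The default cohort preset (23 patients, 30-h monitoring)."""
    return SynthConfig()


def _rng(cfg: SynthConfig, patient_id: str, stream: str) -> np.random.Generator:
    """Independent generator per (seed, patient, stream)."""
    return np.random.default_rng(
        [cfg.seed, zlib.crc32(patient_id.encode()), _STREAM[stream]]
    )


def _positive_normal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at 0 by redrawing (sd may be 0)."""
    if sd == 0.0:
        return np.full(size, max(mean, 0.0))
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# Time-series simulation


def simulate_map_series(cfg: SynthConfig, patient_id: str):
    """Simulate one patient's MAP path; returns (t, map_mmHg) arrays.

    Stationary AR(1) around ``map_mean`` with lag-1 coefficient
    ``ou_phi`` and marginal SD ``map_sd``, plus half-sine hypotensive
    excursions at Poisson onsets.
    """
    n = int(round(cfg.duration / cfg.dt))
    t = np.arange(n) * cfg.dt
    rng = _rng(cfg, patient_id, "map")
    innov_sd = cfg.map_sd * np.sqrt(1.0 - cfg.ou_phi**2)
    e = rng.normal(0.0, innov_sd, n)
    if n:
        e[0] = rng.normal(0.0, cfg.map_sd)  # stationary start
    x = lfilter([1.0], [1.0, -cfg.ou_phi], e)
    path = cfg.map_mean + x

    rng_d = _rng(cfg, patient_id, "dips")
    n_dips = rng_d.poisson(cfg.dip_rate * cfg.duration / 3600.0)
    onsets = rng_d.uniform(0.0, cfg.duration, n_dips)
    depths = _positive_normal(rng_d, cfg.dip_depth_mean, cfg.dip_depth_sd, n_dips)
    durations = _positive_normal(
        rng_d, cfg.dip_duration_mean, cfg.dip_duration_sd, n_dips
    )
    for onset, depth, dur in zip(onsets, depths, durations):
        if dur <= 0:
            continue
        i0 = int(np.ceil((onset - 0.0) / cfg.dt))
        i1 = int(np.floor((onset + dur) / cfg.dt))
        i0, i1 = max(i0, 0), min(i1, n - 1)
        if i1 < i0:
            continue
        u = (t[i0 : i1 + 1] - onset) / dur
        path[i0 : i1 + 1] -= depth * np.sin(np.pi * u)
    return t, np.maximum(path, cfg.map_floor)


def simulate_hpi_series(
    t: np.ndarray, map_mmHg: np.ndarray, cfg: SynthConfig, patient_id: str
) -> np.ndarray:
    """Construct the prediction index from the future of the MAP path.

    Let d(t) = 65 − min MAP over (t, t + hpi_lead]. The deterministic
    index is 88 + 9·tanh(d/20) when d > 0 (an impending or ongoing
    crossing ⇒ index at or above the alert threshold 85) and
    75·expit(d/6) otherwise (saturating rise toward ~37 as MAP
    approaches the threshold, far below 85). Observation noise and
    spurious bursts are then added and the result clipped to [0, 100].
    """
    n = len(map_mmHg)
    if n == 0:
        return np.array([])
    lead = max(1, int(round(cfg.hpi_lead / cfg.dt)))
    padded = np.concatenate([map_mmHg[1:], np.full(lead, np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, lead)[:n]
    d = 65.0 - windows.min(axis=1)
    hpi = np.where(d > 0.0, 88.0 + 9.0 * np.tanh(d / 20.0), 75.0 * expit(d / 6.0))

    if cfg.hpi_noise_sd > 0:
        rng_n = _rng(cfg, patient_id, "hpi_noise")
        hpi = hpi + rng_n.normal(0.0, cfg.hpi_noise_sd, n)

    if cfg.false_alert_rate > 0:
        rng_f = _rng(cfg, patient_id, "false_alerts")
        n_bursts = rng_f.poisson(cfg.false_alert_rate * cfg.duration / 3600.0)
        for _ in range(n_bursts):
            i0 = int(rng_f.integers(0, n))
            length = int(rng_f.integers(2, 7))
            vals = rng_f.normal(92.0, 2.0, min(length, n - i0))
            hpi[i0 : i0 + length] = np.maximum(hpi[i0 : i0 + length], vals)
    return np.clip(hpi, 0.0, 100.0)


def simulate_series(cfg: SynthConfig, patient_id: str) -> HemoSeries:
    """Simulate one patient's full MAP + HPI series."""
    t, m = simulate_map_series(cfg, patient_id)
    h = simulate_hpi_series(t, m, cfg, patient_id)
    return HemoSeries(
        patient_id=patient_id, t=t, map_mmHg=m, hpi=h, nominal_dt=cfg.dt
    )


# ---------------------------------------------------------------------------
# Paired measurements


def simulate_pairs(
    cfg: SynthConfig, patient_id: str, variable: str
) -> list[PairedMeasurement]:
    """Simulate one patient's paired (reference, device) measurements.

    The replicate count is uniform on ``pairs_per_patient_range``;
    measurement times are uniform over the monitored span. Values are
    redrawn while non-positive (a negligible truncation for the
    shipped presets).
    """
    spec = cfg.variables[variable]
    rng = _rng(cfg, patient_id, variable)
    u = float(_positive_normal(rng, spec.true_mean, spec.between_sd, 1)[0])
    lo, hi = cfg.pairs_per_patient_range
    n_rep = int(rng.integers(lo, hi + 1))
    times = np.sort(rng.uniform(0.0, cfg.duration, n_rep))
    out = []
    for tt in times:
        ref = float(_positive_normal(rng, u, spec.ref_noise_sd, 1)[0])
        dev = float(
            _positive_normal(
                rng, spec.device_scale * u + spec.device_bias, spec.device_noise_sd, 1
            )[0]
        )
        out.append(
            PairedMeasurement(
                patient_id=patient_id,
                t=float(tt),
                variable=variable,
                reference=ref,
                device=dev,
            )
        )
    return out


def simulate_cohort(cfg: SynthConfig, out_dir=None) -> Cohort:
    """Simulate a full cohort; optionally write series.csv and pairs.csv."""
    width = max(2, len(str(cfg.n_patients)))
    ids = [f"P{i + 1:0{width}d}" for i in range(cfg.n_patients)]
    series = [simulate_series(cfg, pid) for pid in ids]
    pairs: list[PairedMeasurement] = []
    for pid in ids:
        for variable in cfg.variables:
            pairs.extend(simulate_pairs(cfg, pid, variable))
    cohort = Cohort(series=series, pairs=pairs)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_series(series, out / "series.csv")
        write_pairs(pairs, out / "pairs.csv")
    return cohort


def simulate_pairs_cohort(
    cfg: SynthConfig, variable: str, n_patients: Optional[int] = None
) -> list[PairedMeasurement]:
    """Pairs-only cohort for one variable (agreement-statistics studies)."""
    n = n_patients if n_patients is not None else cfg.n_patients
    width = max(2, len(str(n)))
    out: list[PairedMeasurement] = []
    for i in range(n):
        out.extend(simulate_pairs(cfg, f"P{i + 1:0{width}d}", variable))
    return out
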