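"""Repeated-measures method-comparison statistics.

Given paired same-timepoint measurements of one hemodynamic variable
from a reference device (pulmonary artery catheter) and a test device,
with 2-11 replicates per patient, this module computes:

* the relative difference |(reference − device)/reference|·100 and the
  proportion of pairs within a 20% tolerance, with a cluster-robust
  confidence interval from an intercept-only GEE (exchangeable working
  correlation, patient clusters);
* Lin's concordance correlation coefficient (CCC) pooled over pairs,
  with a percentile confidence interval from a patient-level bootstrap
  (clustering enters only through the bootstrap);
* repeated-measures Bland-Altman bias and SD, the 95% limits of
  agreement bias ± 1.96·SD, and MOVER confidence intervals for the
  limits;
* an overall agreement verdict against a clinically acceptable
  difference (CAD: ±1 L·min⁻¹ for CO, ±200 dynes·s·cm⁻⁵ for SVR).

The bias is the unweighted mean of per-patient mean differences; the
SD combines between- and within-patient variance components from a
one-way ANOVA of the differences with unequal replicate counts.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from hemoval.io import DEFAULT_CAD, PairedMeasurement

Z_95 = 1.959963984540054


# ---------------------------------------------------------------------------
# Relative difference and GEE proportion-within-tolerance


def relative_difference(pair_or_reference, device: Optional[float] = None) -> float:
    """Percent relative difference |(reference − device)/reference|·100.

    Accepts either a :class:`PairedMeasurement` or two scalars.
    """
    if isinstance(pair_or_reference, PairedMeasurement):
        ref, dev = pair_or_reference.reference, pair_or_reference.device
    else:
        ref, dev = float(pair_or_reference), float(device)
    if not ref > 0:
        raise ValueError(f"reference must be > 0 for a relative difference (got {ref})")
    return abs((ref - dev) / ref) * 100.0


@dataclass(frozen=True)
class ProportionResult:
    """Proportion-within-tolerance with a cluster-robust 95% CI."""

    proportion: float
    ci: tuple
    se: float
    n: int
    n_patients: int
    method: str

    def to_dict(self) -> dict:
        return {
            "proportion": self.proportion,
            "ci": list(self.ci),
            "se": self.se,
            "n": self.n,
            "n_patients": self.n_patients,
            "method": self.method,
        }


def prop_within_gee(
    pairs: Sequence[PairedMeasurement],
    tolerance_pct: float = 20.0,
    link: str = "identity",
) -> ProportionResult:
    """Proportion of pairs with relative difference < tolerance, GEE CI.

    The binary indicator 1{relative difference < tolerance} is
    regressed on an intercept only, with exchangeable working
    correlation over patient clusters and a robust sandwich standard
    error; CI = estimate ± 1.96·SE clipped to [0, 1]. For an
    intercept-only model the Gaussian and binomial identity-link
    estimating equations coincide (the variance function is constant
    across observations), so the identity link is fitted as Gaussian.
    ``link="logit"`` fits a binomial-logit GEE and back-transforms the
    CI. A single-patient input falls back to a binomial Wald CI with a
    warning.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs supplied")
    y = np.array([1.0 if relative_difference(p) < tolerance_pct else 0.0 for p in pairs])
    groups = np.array([p.patient_id for p in pairs])
    n_pat = len(set(groups.tolist()))
    n = len(y)
    if n_pat < 2:
        warnings.warn(
            "fewer than 2 patients: falling back to binomial Wald CI", stacklevel=2
        )
        p = float(y.mean())
        se = math.sqrt(p * (1 - p) / n)
        return ProportionResult(
            p,
            (max(0.0, p - Z_95 * se), min(1.0, p + Z_95 * se)),
            se,
            n,
            n_pat,
            "binomial-wald",
        )
    if y.std() == 0.0:  # all indicators identical; GEE is degenerate
        p = float(y[0])
        return ProportionResult(p, (p, p), 0.0, n, n_pat, f"gee-{link}-degenerate")
    X = np.ones((n, 1))
    if link == "identity":
        family = sm.families.Gaussian()
    elif link == "logit":
        family = sm.families.Binomial()
    else:
        raise ValueError(f"unknown link {link!r}")
    model = sm.GEE(y, X, groups=groups, family=family, cov_struct=sm.cov_struct.Exchangeable())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    b = float(res.params[0])
    se = float(res.bse[0])
    if link == "logit":
        from scipy.special import expit

        p = float(expit(b))
        lo, hi = float(expit(b - Z_95 * se)), float(expit(b + Z_95 * se))
        se_p = se * p * (1 - p)  # delta method, reported for reference
        return ProportionResult(p, (lo, hi), se_p, n, n_pat, "gee-logit")
    lo = max(0.0, b - Z_95 * se)
    hi = min(1.0, b + Z_95 * se)
    return ProportionResult(b, (lo, hi), se, n, n_pat, "gee-identity")


# ---------------------------------------------------------------------------
# Lin's concordance correlation coefficient


def _xy(pairs_or_x, y=None) -> tuple:
    if y is None:
        x = np.array([p.reference for p in pairs_or_x], dtype=float)
        yv = np.array([p.device for p in pairs_or_x], dtype=float)
        return x, yv
    return np.asarray(pairs_or_x, dtype=float), np.asarray(y, dtype=float)


def lin_ccc(pairs_or_x, y=None) -> float:
    """Lin's concordance correlation coefficient of pooled pairs.

    ccc = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with biased (1/n) moments.
    Measures departure of the (x, y) cloud from the 45-degree identity
    line; 1 means perfect concordance. Undefined (raises) when both
    margins are constant and equal.
    """
    x, yv = _xy(pairs_or_x, y)
    if len(x) < 2 or len(x) != len(yv):
        raise ValueError("need >= 2 pairs of equal length")
    mx, my = x.mean(), yv.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((yv - my) ** 2))
    sxy = float(np.mean((x - mx) * (yv - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: both margins constant and equal")
    return 2.0 * sxy / denom


def bootstrap_ccc_ci(
    pairs: Sequence[PairedMeasurement],
    n_boot: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    conf: float = 0.95,
) -> tuple:
    """Percentile CI for the CCC from a patient-level bootstrap.

    Patients are resampled with replacement (as many draws as observed
    patients); all pairs of a patient drawn k times enter k times. The
    CI is the (2.5th, 97.5th) percentile of the ``n_boot`` resampled
    CCCs. Resamples with an undefined CCC are redrawn, up to a cap.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; percentile CI will be unstable")
    by_patient: dict[str, list] = {}
    for p in pairs:
        by_patient.setdefault(p.patient_id, []).append(p)
    ids = sorted(by_patient)
    if len(ids) < 2:
        raise ValueError("patient-level bootstrap needs >= 2 distinct patients")
    xs = {pid: np.array([p.reference for p in pl]) for pid, pl in by_patient.items()}
    ys = {pid: np.array([p.device for p in pl]) for pid, pl in by_patient.items()}
    if rng is None:
        rng = np.random.default_rng(seed)
    k = len(ids)
    cccs = np.empty(n_boot)
    max_redraws = 100 * n_boot
    draws = 0
    i = 0
    while i < n_boot:
        if draws >= max_redraws:
            warnings.warn("bootstrap redraw cap reached; CI from fewer resamples")
            cccs = cccs[:i]
            break
        draws += 1
        chosen = rng.choice(k, size=k, replace=True)
        x = np.concatenate([xs[ids[j]] for j in chosen])
        yv = np.concatenate([ys[ids[j]] for j in chosen])
        try:
            cccs[i] = lin_ccc(x, yv)
        except ValueError:
            continue
        i += 1
    a = (1.0 - conf) / 2.0
    lo, hi = np.percentile(cccs, [100 * a, 100 * (1 - a)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Repeated-measures Bland-Altman


@dataclass(frozen=True)
class BAResult:
    """Bias and SD of paired differences with variance components.

    ``bias`` is the unweighted mean of per-patient mean differences
    (reference − device). ``sd`` = √(between + within variance
    components); the mean squares, degrees of freedom and ``n0`` (the
    effective replicate count for unbalanced one-way ANOVA) are kept
    for the MOVER interval construction.
    """

    bias: float
    sd: float
    var_between: float
    var_within: float
    ms_between: float
    ms_within: float
    df_between: int
    df_within: int
    n0: float
    n_patients: int
    n_pairs: int
    replicates: tuple
    sd_method: str = "anova"

    @property
    def se_bias(self) -> float:
        """SE of the unweighted mean of patient means."""
        k = self.n_patients
        inv = sum(1.0 / ni for ni in self.replicates)
        return math.sqrt(self.var_between / k + self.var_within * inv / k**2)


def ba_repeated(
    pairs: Sequence[PairedMeasurement], sd_method: str = "anova"
) -> BAResult:
    """Bland-Altman bias and SD for repeated measures per patient.

    Differences d = reference − device are decomposed by a one-way
    ANOVA with patient as the grouping factor and unequal replicate
    counts: MSW estimates the within-patient variance, and the
    between-patient component is (MSB − MSW)/n0 with
    n0 = (N − Σnᵢ²/N)/(k − 1), truncated at zero. The reported SD is
    √(between + within). ``sd_method="simple"`` instead takes the
    sample SD of the pooled raw differences (sensitivity analysis).
    Patients with a single replicate contribute to the bias and the
    between-group sum of squares only. If every patient has one
    replicate, the SD falls back to the sample SD of the patient means
    with a warning.
    """
    if sd_method not in ("anova", "simple"):
        raise ValueError(f"unknown sd_method {sd_method!r}")
    by_patient: dict[str, list] = {}
    for p in pairs:
        by_patient.setdefault(p.patient_id, []).append(p.difference)
    k = len(by_patient)
    if k < 2:
        raise ValueError("repeated-measures Bland-Altman needs >= 2 patients")
    groups = [np.asarray(v, dtype=float) for v in by_patient.values()]
    n_i = np.array([len(g) for g in groups])
    N = int(n_i.sum())
    means = np.array([g.mean() for g in groups])
    bias = float(means.mean())  # unweighted across patients

    grand = float(np.concatenate(groups).mean())
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    df_b = k - 1
    msb = ssb / df_b
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_w = N - k
    n0 = (N - float(np.sum(n_i**2)) / N) / df_b

    if df_w == 0:
        warnings.warn(
            "all patients have a single replicate: SD is the sample SD "
            "of patient means (no within-patient component)"
        )
        var_b = float(means.var(ddof=1))
        var_w = 0.0
        msw = 0.0
    else:
        msw = ssw / df_w
        var_w = msw
        var_b = max(0.0, (msb - msw) / n0)

    if sd_method == "simple":
        pooled = np.concatenate(groups)
        sd = float(pooled.std(ddof=1))
    else:
        sd = math.sqrt(var_b + var_w)
    return BAResult(
        bias=bias,
        sd=sd,
        var_between=var_b,
        var_within=var_w,
        ms_between=msb,
        ms_within=msw,
        df_between=df_b,
        df_within=df_w,
        n0=n0,
        n_patients=k,
        n_pairs=N,
        replicates=tuple(int(v) for v in n_i),
        sd_method=sd_method,
    )


@dataclass(frozen=True)
class LoaResult:
    """95% limits of agreement with MOVER confidence intervals."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple
    loa_upper_ci: tuple
    z: float = Z_95

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd": self.sd,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "loa_lower_ci": list(self.loa_lower_ci),
            "loa_upper_ci": list(self.loa_upper_ci),
        }


def _mover_limits(
    bias: float,
    sd: float,
    se_bias: float,
    df_mean: float,
    sd_df: float,
    z: float = Z_95,
    conf: float = 0.95,
) -> LoaResult:
    """Combine a t CI for the mean with a χ² CI for z·sd into LOA CIs.

    For the upper limit U = bias + z·sd with component CIs
    (l_m, u_m) for the mean and (l_s, u_s) for z·sd:

        lower CI of U = U − √((bias − l_m)² + (z·sd − l_s)²)
        upper CI of U = U + √((u_m − bias)² + (u_s − z·sd)²)

    and symmetrically for the lower limit, where the sd term enters
    with opposite sign. The χ² CI for the sd uses ``sd_df`` degrees of
    freedom (Satterthwaite for variance-component SDs, n−1 for the
    single-level case).
    """
    a = 1.0 - conf
    if sd == 0.0 and se_bias == 0.0:
        pt = (bias, bias)
        return LoaResult(bias, sd, bias, bias, pt, pt)
    tq = stats.t.ppf(1 - a / 2, df_mean) if df_mean > 0 else float("inf")
    l_m = bias - tq * se_bias
    u_m = bias + tq * se_bias
    if sd > 0.0 and sd_df > 0:
        chi_lo = stats.chi2.ppf(1 - a / 2, sd_df)
        chi_hi = stats.chi2.ppf(a / 2, sd_df)
        l_s = z * sd * math.sqrt(sd_df / chi_lo)
        u_s = z * sd * math.sqrt(sd_df / chi_hi)
    else:
        l_s = u_s = z * sd
    zsd = z * sd
    loa_u = bias + zsd
    loa_l = bias - zsd
    u_lo = loa_u - math.sqrt((bias - l_m) ** 2 + (zsd - l_s) ** 2)
    u_hi = loa_u + math.sqrt((u_m - bias) ** 2 + (u_s - zsd) ** 2)
    l_lo = loa_l - math.sqrt((bias - l_m) ** 2 + (u_s - zsd) ** 2)
    l_hi = loa_l + math.sqrt((u_m - bias) ** 2 + (zsd - l_s) ** 2)
    return LoaResult(bias, sd, loa_l, loa_u, (l_lo, l_hi), (u_lo, u_hi), z)


def loa_with_mover(ba: BAResult, z: float = Z_95, conf: float = 0.95) -> LoaResult:
    """LOA = bias ± z·sd with MOVER CIs for the repeated-measures case.

    The SD's χ² degrees of freedom come from a Satterthwaite
    approximation for the variance σ̂² = MSB/n0 + (1 − 1/n0)·MSW;
    the mean's t interval uses k − 1 degrees of freedom.
    """
    if ba.df_within == 0:
        # single replicate per patient: sd estimated from patient means
        return _mover_limits(
            ba.bias,
            ba.sd,
            ba.se_bias,
            df_mean=ba.df_between,
            sd_df=ba.df_between,
            z=z,
            conf=conf,
        )
    c1 = 1.0 / ba.n0
    c2 = 1.0 - c1
    var_hat = c1 * ba.ms_between + c2 * ba.ms_within
    if var_hat > 0:
        denom = (c1 * ba.ms_between) ** 2 / ba.df_between + (
            c2 * ba.ms_within
        ) ** 2 / ba.df_within
        sd_df = var_hat**2 / denom if denom > 0 else ba.df_between
    else:
        sd_df = ba.df_between
    return _mover_limits(
        ba.bias, ba.sd, ba.se_bias, df_mean=ba.df_between, sd_df=sd_df, z=z, conf=conf
    )


def loa_mover_single(
    mean: float, sd: float, n: int, z: float = Z_95, conf: float = 0.95
) -> LoaResult:
    """MOVER LOA CIs for independent differences (no clustering).

    The mean gets a t interval with n−1 df and SE sd/√n; the sd gets
    the exact χ² interval with n−1 df.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    return _mover_limits(mean, sd, sd / math.sqrt(n), df_mean=n - 1, sd_df=n - 1, z=z, conf=conf)


# ---------------------------------------------------------------------------
# Composite report


@dataclass
class AgreementReport:
    """All agreement statistics for one variable, against its CAD."""

    variable: str
    n_pairs: int
    n_patients: int
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple
    loa_upper_ci: tuple
    ccc: float
    ccc_ci: tuple
    prop_within: float
    prop_ci: tuple
    cad: float
    agrees_point: bool = field(init=False)
    agrees_ci: bool = field(init=False)
    agrees: bool = field(init=False)

    def __post_init__(self) -> None:
        self.agrees_point = (-self.cad <= self.loa_lower) and (self.loa_upper <= self.cad)
        self.agrees_ci = (-self.cad <= self.loa_lower_ci[0]) and (
            self.loa_upper_ci[1] <= self.cad
        )
        self.agrees = self.agrees_point and self.agrees_ci

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n_pairs": self.n_pairs,
            "n_patients": self.n_patients,
            "bias": self.bias,
            "sd": self.sd,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "loa_lower_ci": list(self.loa_lower_ci),
            "loa_upper_ci": list(self.loa_upper_ci),
            "ccc": self.ccc,
            "ccc_ci": list(self.ccc_ci),
            "prop_within": self.prop_within,
            "prop_ci": list(self.prop_ci),
            "cad": self.cad,
            "agrees_point": self.agrees_point,
            "agrees_ci": self.agrees_ci,
            "agrees": self.agrees,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        return cls(
            variable=d["variable"],
            n_pairs=d["n_pairs"],
            n_patients=d["n_patients"],
            bias=d["bias"],
            sd=d["sd"],
            loa_lower=d["loa_lower"],
            loa_upper=d["loa_upper"],
            loa_lower_ci=tuple(d["loa_lower_ci"]),
            loa_upper_ci=tuple(d["loa_upper_ci"]),
            ccc=d["ccc"],
            ccc_ci=tuple(d["ccc_ci"]),
            prop_within=d["prop_within"],
            prop_ci=tuple(d["prop_ci"]),
            cad=d["cad"],
        )


def agreement_report(
    pairs: Sequence[PairedMeasurement],
    variable: str,
    cad: Optional[float] = None,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    tolerance_pct: float = 20.0,
    sd_method: str = "anova",
    gee_link: str = "identity",
) -> AgreementReport:
    """Full agreement analysis of one variable's pairs against its CAD."""
    sel = [p for p in pairs if p.variable == variable]
    if not sel:
        raise ValueError(f"no pairs for variable {variable!r}")
    if cad is None:
        cad = DEFAULT_CAD[variable]
    ba = ba_repeated(sel, sd_method=sd_method)
    loa = loa_with_mover(ba)
    ccc = lin_ccc(sel)
    ccc_ci = bootstrap_ccc_ci(sel, n_boot=n_boot, seed=seed)
    prop = prop_within_gee(sel, tolerance_pct=tolerance_pct, link=gee_link)
    return AgreementReport(
        variable=variable,
        n_pairs=ba.n_pairs,
        n_patients=ba.n_patients,
        bias=ba.bias,
        sd=ba.sd,
        loa_lower=loa.loa_lower,
        loa_upper=loa.loa_upper,
        loa_lower_ci=loa.loa_lower_ci,
        loa_upper_ci=loa.loa_upper_ci,
        ccc=ccc,
        ccc_ci=ccc_ci,
        prop_within=prop.proportion,
        prop_ci=prop.ci,
        cad=cad,
    )
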