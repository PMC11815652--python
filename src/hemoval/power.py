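"""Simulation-based power to conclude agreement under Bland-Altman limits.

"Concluding agreement" means demonstrating, from n paired differences,
that the 95% limits of agreement lie inside a pre-specified clinically
acceptable difference ±CAD. The default conclusion rule requires the
outer two-sided 95% confidence bounds of both limits to fall inside
±CAD, with the classical Bland-Altman approximate interval for a limit
(SE = s·√(1/n + z²/(2(n−1))), normal quantile) — the construction
standard sample-size tools for agreement studies use. Alternatives:

``ci_method="mover"``
    exact-t/χ² MOVER intervals for the limits (single-level case);
``criterion="point"``
    only the limit point estimates must fall inside ±CAD.

Differences are simulated as independent normals (no clustering): the
power question is posed for n pairs with a given mean and SD only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

Z_95 = 1.959963984540054


@dataclass(frozen=True)
class PowerSpec:
    """Scenario for the agreement power simulation.

    ``true_mean_diff`` and ``true_sd`` are in the variable's units
    (L·min⁻¹ for CO, dynes·s·cm⁻⁵ for SVR), as is ``cad``.
    """

    n_pairs: int
    true_mean_diff: float
    true_sd: float
    cad: float
    alpha: float = 0.05
    n_sims: int = 10_000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_pairs < 3:
            raise ValueError("n_pairs must be >= 3")
        if self.true_sd < 0:
            raise ValueError("true_sd must be >= 0")
        if self.cad <= 0:
            raise ValueError("cad must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


@dataclass(frozen=True)
class PowerResult:
    """Estimated power with its Monte-Carlo standard error."""

    power: float
    mc_se: float
    n_sims: int
    criterion: str
    ci_method: str

    def to_dict(self) -> dict:
        return {
            "power": self.power,
            "mc_se": self.mc_se,
            "n_sims": self.n_sims,
            "criterion": self.criterion,
            "ci_method": self.ci_method,
        }


def agreement_power(
    spec: PowerSpec,
    criterion: str = "ci",
    ci_method: str = "ba",
    rng: Optional[np.random.Generator] = None,
) -> PowerResult:
    """Monte-Carlo power of concluding agreement within ±CAD.

    Each simulation draws ``n_pairs`` independent
    Normal(true_mean_diff, true_sd) differences, forms the 95% limits
    of agreement mean ± 1.96·s, and (for ``criterion="ci"``) their
    two-sided (1 − alpha) confidence bounds; agreement is concluded
    when the lower bound of the lower limit ≥ −CAD and the upper bound
    of the upper limit ≤ +CAD. Power is the fraction of simulations
    concluding agreement; ``mc_se`` = √(p(1−p)/n_sims).
    """
    if criterion not in ("ci", "point"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if ci_method not in ("ba", "mover"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    n = spec.n_pairs
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    x = rng.normal(spec.true_mean_diff, spec.true_sd, size=(spec.n_sims, n))
    m = x.mean(axis=1)
    s = x.std(axis=1, ddof=1)
    zsd = Z_95 * s
    upper = m + zsd
    lower = m - zsd

    if criterion == "point":
        ok = (lower >= -spec.cad) & (upper <= spec.cad)
    elif ci_method == "ba":
        z_ci = float(stats.norm.ppf(1 - spec.alpha / 2))
        se_loa = s * math.sqrt(1.0 / n + Z_95**2 / (2.0 * (n - 1)))
        ok = (lower - z_ci * se_loa >= -spec.cad) & (upper + z_ci * se_loa <= spec.cad)
    else:  # MOVER with exact t / chi-square components
        tq = float(stats.t.ppf(1 - spec.alpha / 2, n - 1))
        chi_hi = float(stats.chi2.ppf(spec.alpha / 2, n - 1))
        u_s = zsd * math.sqrt((n - 1) / chi_hi)
        se_m = s / math.sqrt(n)
        half = np.sqrt((tq * se_m) ** 2 + (u_s - zsd) ** 2)
        ok = (lower - half >= -spec.cad) & (upper + half <= spec.cad)

    p = float(np.mean(ok))
    mc_se = math.sqrt(max(p * (1 - p), 1e-12) / spec.n_sims)
    return PowerResult(
        power=p,
        mc_se=mc_se,
        n_sims=spec.n_sims,
        criterion=criterion,
        ci_method="-" if criterion == "point" else ci_method,
    )
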