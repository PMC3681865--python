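"""Synthetic benthic survey generator with the Richibucto study's structure.

Generated datasets mimic the design the model targets: 18 estuary sites, 13
sampled in September and 5 in October, with 2-3 replicate grab samples per
site; the five AMBI metric categories; and an abiotic covariate table whose
collinearity pattern matches the study system - salinity generated as a
linear response of distance downstream (DD) with noise scaled so the
DD-salinity sample correlation targets ~0.88, and log-depth / log-silt-clay
drawn with weak correlations to DD (targets 0.16 and -0.47).

Latent health is drawn from the health regression, and counts from the
group multinomials.  Because the fitted likelihood treats the two group
multinomials as overlapping (their shared baseline is double counted), a
single coherent grab sample cannot be drawn from the likelihood itself;
instead the generator first splits each grab into the plus-group metrics
versus remainder, then allocates the minus-group metrics from within that
remainder using the minus-group probabilities renormalised to it.  The mild
mismatch with the fitted two-multinomial likelihood is accepted; parameter
recovery under the fitted model is the arbiter of its harmlessness.

The generating parameter values travel with every dataset as a
:class:`SyntheticTruth` so recovery tests can score CI coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import (
    AMBI_SCHEME,
    BenthicDataset,
    CenteredDesign,
    CovariateTable,
    MetricScheme,
    build_centered_design,
)
from .model import _group_log_probabilities

__all__ = [
    "RICHIBUCTO_DD_KM",
    "RICHIBUCTO_MONTHS",
    "SyntheticTruth",
    "SyntheticScenario",
    "model3_recovery_scenario",
    "richibucto_like_covariates",
    "simulate_latent",
    "simulate_counts",
    "simulate_dataset",
]

# Distance downstream (km) of the 18 Richibucto sites, by perpendicular
# projection onto the straight line from the most upstream site (site 1) to
# the most downstream site (site 18).
RICHIBUCTO_DD_KM = np.array(
    [0.0, 1.164, 1.298, 1.731, 2.179, 1.686, 2.463, 2.970, 3.433,
     3.790, 3.358, 3.880, 4.119, 3.642, 4.179, 4.701, 5.060, 5.448]
)

# Sites 1-3 and 9-18 were sampled in September; sites 4-8 in October.
RICHIBUCTO_MONTHS = tuple(
    "Oct" if 4 <= s <= 8 else "Sep" for s in range(1, 19)
)

# Target sample correlations with DD for the generated covariates.
_TARGET_CORR = {"salinity": 0.88, "log_depth": 0.16, "log_sc": -0.47}


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameter values, stored alongside every dataset.

    Default effect sizes sit in the regime the model is designed for:
    regression slopes of a few tenths to ~1 and error standard deviations
    of ~0.6-1.1 on the latent health scale.  ``beta`` is keyed by covariate
    term name (see :mod:`lhfi.data`).
    """

    beta0: float = 0.0
    beta: Mapping[str, float] = field(default_factory=lambda: {"dd": 0.5})
    delta_minus: float = 0.3
    gamma: tuple[float, ...] = (0.2, -0.1, 0.15, -0.25, 0.0)
    sigma_eps: float = 0.7
    sigma_gamma: float = 0.5
    b0: float = 0.0
    b1: float = 0.77
    sigma_s: float | None = None  # None: derived from the correlation target
    rho: float | None = None

    def as_dict(self) -> dict:
        d = {
            "beta0": self.beta0,
            "delta_minus": self.delta_minus,
            "sigma_eps": self.sigma_eps,
            "sigma_gamma": self.sigma_gamma,
            "b0": self.b0,
            "b1": self.b1,
            "sigma_s": self.sigma_s,
        }
        for k, v in self.beta.items():
            d[f"beta[{k}]"] = v
        for m, g in enumerate(self.gamma, start=1):
            d[f"gamma[{m}]"] = g
        if self.rho is not None:
            d["rho"] = self.rho
        return d


@dataclass(frozen=True)
class SyntheticScenario:
    """Study-design settings for one synthetic dataset.

    Defaults reproduce the Richibucto design: 18 sites (13 September / 5
    October), replicate counts alternating 3, 2, 3, ... per site, and total
    organism counts per grab drawn uniformly from 150-400 (plausible grab
    totals for a soft-bottom estuarine macrofauna sample; the study does not
    publish its totals, so this is a scenario parameter).
    """

    n_sites: int = 18
    truth: SyntheticTruth = field(default_factory=SyntheticTruth)
    seed: int = 0
    total_range: tuple[int, int] = (150, 400)
    replicates: tuple[int, ...] | None = None  # None: fixed 3,2,3,2,... pattern
    dd_salinity_corr: float = _TARGET_CORR["salinity"]

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("need at least two sites")
        if self.total_range[0] < 1:
            raise ValueError("totals must be >= 1")

    def replicate_counts(self) -> np.ndarray:
        if self.replicates is not None:
            if len(self.replicates) != self.n_sites:
                raise ValueError("replicates pattern length must equal n_sites")
            return np.asarray(self.replicates, dtype=int)
        return np.array([3 if i % 2 == 0 else 2 for i in range(self.n_sites)])

    def months(self) -> tuple[str, ...]:
        if self.n_sites == 18:
            return RICHIBUCTO_MONTHS
        n_oct = max(1, round(self.n_sites * 5 / 18))
        return tuple(
            "Oct" if 0 < i - 2 <= n_oct else "Sep" for i in range(self.n_sites)
        ) if self.n_sites > 3 else ("Sep",) * self.n_sites


def model3_recovery_scenario(seed: int = 0) -> SyntheticScenario:
    """Two-level scenario whose true error-variance ratio is exactly 0.5.

    Salinity noise is derived from the 0.88 correlation target; the latent
    error s.d. is then set to |beta_sal| * sigma_s so that
    sigma_eps^2 / (sigma_eps^2 + beta_sal^2 sigma_s^2) = 1/2.
    """
    b1 = 0.77
    beta_sal = 1.0
    dd = RICHIBUCTO_DD_KM
    sigma_s = _salinity_noise_sd(dd, b1, _TARGET_CORR["salinity"])
    truth = SyntheticTruth(
        beta={"salinity": beta_sal},
        b1=b1,
        sigma_s=sigma_s,
        sigma_eps=abs(beta_sal) * sigma_s,
    )
    return SyntheticScenario(truth=truth, seed=seed)


def _salinity_noise_sd(dd: np.ndarray, b1: float, target_corr: float) -> float:
    """Noise s.d. making corr(dd, b0 + b1*dd + noise) equal target_corr in expectation."""
    sd_dd = float(np.std(dd))
    return abs(b1) * sd_dd * np.sqrt(1.0 / target_corr**2 - 1.0)


def _correlated_noise(rng: np.random.Generator, base: np.ndarray, r: float, sd: float) -> np.ndarray:
    """Draw with population correlation ``r`` to ``base`` and s.d. ``sd``."""
    z = (base - base.mean()) / base.std()
    eps = rng.standard_normal(len(base))
    return sd * (r * z + np.sqrt(1.0 - r**2) * eps)


def richibucto_like_covariates(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> CovariateTable:
    """Per-site covariate table with the study system's collinearity.

    DD is fixed to the 18 published site distances when ``n_sites == 18``
    (else equally spaced on the same span).  Salinity responds linearly to
    DD; depth and silt-clay are generated so their log transforms carry the
    weak target correlations with DD.  Raw units: salinity ppt around 20,
    depth m around 3, silt-clay fraction in (0, 1].
    """
    if rng is None:
        rng = np.random.default_rng([scenario.seed, 1])
    n = scenario.n_sites
    dd = RICHIBUCTO_DD_KM.copy() if n == 18 else np.linspace(0.0, RICHIBUCTO_DD_KM[-1], n)
    t = scenario.truth
    sigma_s = t.sigma_s if t.sigma_s is not None else _salinity_noise_sd(
        dd, t.b1, scenario.dd_salinity_corr
    )
    salinity = 20.0 + t.b0 + t.b1 * dd + sigma_s * rng.standard_normal(n)
    log_depth = np.log(3.0) + _correlated_noise(rng, dd, _TARGET_CORR["log_depth"], 0.5)
    log_sc = np.log(0.4) + _correlated_noise(rng, dd, _TARGET_CORR["log_sc"], 0.6)
    log_sc = np.minimum(log_sc, 0.0)  # silt-clay is a fraction
    months = scenario.months()
    frame = pd.DataFrame(
        {
            "site": np.arange(1, n + 1),
            "month": months,
            "depth_m": np.exp(log_depth),
            "temp_c": 15.0 + rng.normal(0.0, 1.5, n),
            "salinity_ppt": salinity,
            "silt_clay": np.exp(log_sc),
            "median_grain": np.exp(5.0 + rng.normal(0.0, 0.4, n)),
            "sorting": 1.5 + rng.normal(0.0, 0.2, n),
            "organic_pct": np.exp(rng.normal(0.7, 0.3, n)),
            "dd_km": dd,
        }
    )
    return CovariateTable(frame)


def simulate_latent(
    cov: CovariateTable,
    truth: SyntheticTruth,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, CenteredDesign]:
    """Draw per-site latent health from the health regression.

    The centered design is built with this dataset's own covariate means,
    exactly as a fit to the same data would build it.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    terms = tuple(truth.beta)
    design = build_centered_design(cov, terms)
    beta = np.array([truth.beta[t] for t in terms])
    mu = truth.beta0 + design.matrix @ beta
    H = mu + truth.sigma_eps * rng.standard_normal(cov.n_sites)
    return H, design


def simulate_counts(
    H: np.ndarray,
    truth: SyntheticTruth,
    scheme: MetricScheme,
    totals: np.ndarray,
    site_index: np.ndarray,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw metric counts for each grab: plus group first, minus from its remainder.

    ``totals`` and ``site_index`` are per record; returns an
    (n_records, 5) count matrix in metric order 1..5.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    totals = np.asarray(totals, dtype=int)
    if (totals <= 0).any():
        raise ValueError("totals must be positive")
    gamma = np.asarray(truth.gamma, dtype=float)
    plus = [m - 1 for m in scheme.metrics_in("plus")]
    minus = [m - 1 for m in scheme.metrics_in("minus")]
    H = np.asarray(H, dtype=float)
    eta_p = gamma[plus][None, :] + H[:, None]
    eta_m = truth.delta_minus + gamma[minus][None, :] - H[:, None]
    p_plus = np.exp(_group_log_probabilities(eta_p))  # (S, 3): m1, m2, remainder
    p_minus = np.exp(_group_log_probabilities(eta_m))  # (S, 4): m3, m4, m5, remainder
    counts = np.zeros((len(totals), 5), dtype=int)
    for r, (n, s) in enumerate(zip(totals, site_index)):
        plus_draw = rng.multinomial(n, p_plus[s])
        counts[r, plus] = plus_draw[:-1]
        left = plus_draw[-1]
        if left > 0:
            minus_draw = rng.multinomial(left, p_minus[s])
            counts[r, minus] = minus_draw[:-1]
    return counts


def simulate_dataset(
    scenario: SyntheticScenario, scheme: MetricScheme = AMBI_SCHEME
) -> tuple[BenthicDataset, CovariateTable, SyntheticTruth]:
    """End-to-end generation of one synthetic survey.

    Deterministic in ``scenario.seed``; the returned truth is the scenario's
    (with the derived salinity noise s.d. filled in).
    """
    rng = np.random.default_rng([scenario.seed, 0])
    cov = richibucto_like_covariates(scenario, np.random.default_rng([scenario.seed, 1]))
    truth = scenario.truth
    if truth.sigma_s is None:
        dd = cov.column("dd_km")
        truth = SyntheticTruth(
            **{**truth.__dict__, "sigma_s": _salinity_noise_sd(dd, truth.b1, scenario.dd_salinity_corr)}
        )
    H, _ = simulate_latent(cov, truth, np.random.default_rng([scenario.seed, 2]))
    reps = scenario.replicate_counts()
    months = scenario.months()
    site_index = np.repeat(np.arange(scenario.n_sites), reps)
    totals = rng.integers(scenario.total_range[0], scenario.total_range[1] + 1, len(site_index))
    counts = simulate_counts(
        H, truth, scheme, totals, site_index, np.random.default_rng([scenario.seed, 3])
    )
    rows = []
    rec = 0
    for i in range(scenario.n_sites):
        for rep in range(1, reps[i] + 1):
            rows.append(
                {
                    "site": i + 1,
                    "month": months[i],
                    "replicate": rep,
                    **{f"m{m + 1}": counts[rec, m] for m in range(5)},
                    "total": totals[rec],
                }
            )
            rec += 1
    data = BenthicDataset(pd.DataFrame(rows))
    return data, cov, truth
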