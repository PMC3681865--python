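"""Convergence diagnostics, posterior summaries, DIC, and health reporting.

Convergence is monitored with the interval-based Brooks-Gelman-Rubin (BGR)
statistic: on successive windows, the width of the central credible interval
of the pooled draws is compared with the mean within-chain interval width;
their ratio approaches 1 from above as chains mix (and the two widths
approach a common constant).  The classic ratio-of-variances PSRF is also
reported as a scalar cross-check.

Model comparison uses the deviance information criterion with the deviance
focused on the observed metric counts (and, for two-level models, observed
salinity), conditional on the latent quantities plugged in at their
posterior means: DIC = Dbar + pD with pD = Dbar - D(posterior means).

Credible intervals are equal-tailed quantile intervals (numpy's default
linear / "type 7" quantile estimator); a slope or correlation is flagged
"credible" when its interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AMBI_SCHEME, BenthicDataset, CenteredDesign, CovariateTable, MetricScheme
from .model import LikelihoodWorkspace, ModelSpec, variance_ratio
from .inference import PosteriorDraws

__all__ = [
    "BGRResult",
    "bgr_statistic",
    "max_rhat",
    "posterior_summary",
    "DICResult",
    "dic",
    "dic_from_deviance",
    "health_table",
    "ci_overlap_fraction",
    "variance_ratio_posterior",
]


@dataclass
class BGRResult:
    """Interval-based BGR series plus final statistics for one parameter."""

    series: pd.DataFrame  # columns: iteration, rhat, pooled_width, within_width
    rhat: float  # final interval-based R-hat
    psrf: float  # ratio-of-variances scalar R-hat


def _interval_width(x: np.ndarray, prob: float) -> float:
    # inverted-CDF quantiles depend only on the empirical distribution, so
    # pooling identical chains leaves the width unchanged and R-hat is
    # exactly 1 for identical chains.
    lo = (1.0 - prob) / 2.0
    q = np.quantile(x, [lo, 1.0 - lo], method="inverted_cdf")
    return float(q[1] - q[0])


def _interval_rhat(chains: np.ndarray, prob: float) -> tuple[float, float, float]:
    pooled = _interval_width(chains.reshape(-1), prob)
    within = float(np.mean([_interval_width(c, prob) for c in chains]))
    if within == 0.0:
        r = 1.0 if pooled == 0.0 else np.inf
    else:
        # sampling noise can push the raw ratio marginally below 1; floor it
        r = max(pooled / within, 1.0)
    return r, pooled, within


def _psrf(chains: np.ndarray) -> float:
    m, n = chains.shape
    if n < 2:
        return np.nan
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    v_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(np.sqrt(v_hat / W))


def bgr_statistic(chains: np.ndarray, n_bins: int = 20, prob: float = 0.80) -> BGRResult:
    """Brooks-Gelman-Rubin diagnostic over successive windows.

    ``chains`` is (n_chains, n_iterations) for a single parameter.  For each
    window end ``t`` (``n_bins`` evenly spaced values), the statistic uses
    the second half of draws 1..t, mirroring the running three-curve BGR
    plot: pooled-interval width, mean within-chain width, and their ratio.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.shape[0] < 2:
        raise ValueError("BGR requires at least two chains")
    n = chains.shape[1]
    ends = np.unique(np.linspace(max(4, n // n_bins), n, num=min(n_bins, n), dtype=int))
    rows = []
    for t in ends:
        window = chains[:, t // 2 : t]
        r, pooled, within = _interval_rhat(window, prob)
        rows.append((t, r, pooled, within))
    series = pd.DataFrame(rows, columns=["iteration", "rhat", "pooled_width", "within_width"])
    final_r, _, _ = _interval_rhat(chains[:, n // 2 :], prob)
    return BGRResult(series=series, rhat=final_r, psrf=_psrf(chains))


def max_rhat(draws: PosteriorDraws, prob: float = 0.80) -> float:
    """Largest final interval-based R-hat across all parameters."""
    worst = 1.0
    for name in draws.names:
        arr = draws.params[name]
        if not np.all(np.isfinite(arr)):
            return np.inf
        r, _, _ = _interval_rhat(arr[:, arr.shape[1] // 2 :], prob)
        worst = max(worst, r)
    return worst


def posterior_summary(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter mean, median, equal-tailed CI, and credible flag.

    ``credible`` is True when the CI excludes 0 - the significance rule used
    for slope and correlation parameters.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("credible level must be in (0, 1)")
    lo = (1.0 - level) / 2.0
    rows = []
    for name in draws.names:
        x = draws.pooled(name)
        qlo, qhi = np.quantile(x, [lo, 1.0 - lo])
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(x)),
                "median": float(np.median(x)),
                "ci_lower": float(qlo),
                "ci_upper": float(qhi),
                "credible": bool(qlo > 0.0 or qhi < 0.0),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class DICResult:
    dic: float
    dbar: float
    pd: float
    n_excluded: int = 0


def dic_from_deviance(deviances: np.ndarray, deviance_at_mean: float) -> DICResult:
    """DIC from per-draw deviances and the plug-in deviance at posterior means."""
    deviances = np.asarray(deviances, dtype=float)
    ok = np.isfinite(deviances)
    n_excluded = int((~ok).sum())
    dbar = float(np.mean(deviances[ok]))
    p_d = dbar - deviance_at_mean
    return DICResult(dic=dbar + p_d, dbar=dbar, pd=p_d, n_excluded=n_excluded)


def _salinity_deviance_part(
    design: CenteredDesign, b0: float, b1: float, sigma_s: float
) -> float:
    resid = design.centered_salinity - (b0 + b1 * design.centered_dd)
    n = len(resid)
    return float(
        -0.5 * n * np.log(2.0 * np.pi) - n * np.log(sigma_s) - 0.5 * (resid / sigma_s) @ (resid / sigma_s)
    )


def dic(
    draws: PosteriorDraws,
    data: BenthicDataset,
    design: CenteredDesign,
    cov: CovariateTable,
    spec: ModelSpec,
    scheme: MetricScheme = AMBI_SCHEME,
    thin: int = 1,
) -> DICResult:
    """Deviance information criterion focused on the observed data.

    The deviance is -2 times the log-likelihood of the metric counts (plus
    the salinity regression for two-level models) conditional on the latent
    quantities; pD plugs those quantities in at their posterior means.
    Draws with non-finite deviance are excluded and counted.
    """
    ws = LikelihoodWorkspace(data, scheme)
    sites = data.sites
    h_names = [f"H[{s}]" for s in sites]
    g_names = [f"gamma[{m}]" for m in range(1, 6)]
    H = np.stack([draws.pooled(n)[::thin] for n in h_names], axis=1)
    G = np.stack([draws.pooled(n)[::thin] for n in g_names], axis=1)
    delta = draws.pooled("delta_minus")[::thin]
    n_draws = H.shape[0]
    dev = np.empty(n_draws)
    for i in range(n_draws):
        ll = float(ws.site_logliks(H[i], delta[i], G[i]).sum())
        if spec.two_level:
            ll += _salinity_deviance_part(
                design,
                draws.pooled("b0")[::thin][i],
                draws.pooled("b1")[::thin][i],
                draws.pooled("sigma_s")[::thin][i],
            )
        dev[i] = -2.0 * ll
    ll_bar = float(ws.site_logliks(H.mean(axis=0), float(delta.mean()), G.mean(axis=0)).sum())
    if spec.two_level:
        ll_bar += _salinity_deviance_part(
            design,
            float(draws.pooled("b0")[::thin].mean()),
            float(draws.pooled("b1")[::thin].mean()),
            float(draws.pooled("sigma_s")[::thin].mean()),
        )
    return dic_from_deviance(dev, -2.0 * ll_bar)


def health_table(
    draws: PosteriorDraws, site_labels: list | None = None, level: float = 0.95
) -> pd.DataFrame:
    """Per-site latent health score (posterior mean of H) with CI and rank.

    Rank 1 is the site with the lowest posterior mean health.  Sorted by
    site label.
    """
    h_names = draws.matching("H")
    if not h_names:
        raise ValueError("no latent health parameters in draws")
    labels = site_labels or [n[2:-1] for n in h_names]
    lo = (1.0 - level) / 2.0
    rows = []
    for name, lab in zip(h_names, labels):
        x = draws.pooled(name)
        qlo, qhi = np.quantile(x, [lo, 1.0 - lo])
        rows.append(
            {
                "site": lab,
                "lhfi": float(np.mean(x)),
                "median": float(np.median(x)),
                "ci_lower": float(qlo),
                "ci_upper": float(qhi),
            }
        )
    df = pd.DataFrame(rows)
    df["rank"] = df["lhfi"].rank(method="first").astype(int)
    return df


def ci_overlap_fraction(table: pd.DataFrame) -> float:
    """Fraction of site pairs whose health CIs overlap."""
    lo = table["ci_lower"].to_numpy()
    hi = table["ci_upper"].to_numpy()
    n = len(table)
    if n < 2:
        return 1.0
    overlaps = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if lo[i] <= hi[j] and lo[j] <= hi[i]:
                overlaps += 1
    return overlaps / total


def variance_ratio_posterior(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Posterior of sigma_eps^2 / (sigma_eps^2 + beta_sal^2 sigma_s^2).

    Requires a two-level fit (salinity regressed on distance); the ratio is
    computed draw by draw and summarised like any other parameter.
    """
    needed = ["sigma_eps", "beta[salinity]", "sigma_s"]
    missing = [n for n in needed if n not in draws.names]
    if missing:
        raise ValueError(f"not a two-level fit: missing {missing}")
    ratio = variance_ratio(
        draws.pooled("sigma_eps"), draws.pooled("beta[salinity]"), draws.pooled("sigma_s")
    )
    wrapped = PosteriorDraws(
        params={"variance_ratio": np.atleast_2d(ratio)}, metadata=dict(draws.metadata)
    )
    return posterior_summary(wrapped, level=level)
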