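"""Latent Health Factor Index model: likelihoods, priors, joint posterior.

The LHFI is a hierarchical ANOCOVA GLMM.  At the observation level, the
counts of each metric group in a grab sample follow a multinomial whose
category probabilities come from a generalized-logit (softmax with a fixed
baseline) link on the linear predictor

    eta_{g,m,i} = delta_g + gamma_{g,m} + s_g * H_i,

where ``H_i`` is the latent health of site ``i``, ``delta_g`` a fixed group
effect (the plus group is the baseline, ``delta_plus = 0``), ``gamma_{g,m}``
a random metric effect, and ``s_g = +1`` for the health-positive group and
``-1`` for the health-negative group (an "inverted" generalized logit), so
that abundant opportunist taxa indicate poor health.  The baseline category
of each group's multinomial is the remainder of the grab not classified into
that group's metrics; the two groups' multinomials share this remainder and
overlap, a dependency accounted for only crudely through delta and gamma,
and both are included in the likelihood.

At the latent level, health is regressed on centered abiotic covariates:

    H_i = beta0 + x_i' beta + eps_i,     eps_i ~ N(0, sigma_eps^2),

optionally with month-specific error variance.  The two-level extension
additionally regresses (centered) salinity on (centered) distance
downstream,

    s_i = b0 + b1 * d_i + e_i,           e_i ~ N(0, sigma_s^2),

with salinity replacing distance in the health regression; marginalising
salinity collapses the two regressions into a single one on distance with
intercept ``beta0 + beta_sal*b0``, slope ``beta_sal*b1`` and total error
variance ``sigma_eps^2 + beta_sal^2 sigma_s^2``, of which the fraction
``sigma_eps^2 / (sigma_eps^2 + beta_sal^2 sigma_s^2)`` is NOT attributable
to the implicit salinity covariate.

Priors: N(0, 100) on fixed effects and regression coefficients, IG(1, 1) on
variances, and - when metric effects are correlated rather than iid -
inverse-Wishart(dim + 1, I) on each covariance block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import gammaln
from scipy.stats import invwishart

from .data import AMBI_SCHEME, BenthicDataset, CenteredDesign, CovariateTable, MetricScheme

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "ParamState",
    "model_preset",
    "PRESET_NAMES",
    "linear_predictor",
    "group_probabilities",
    "observation_loglik",
    "latent_health_loglik",
    "salinity_loglik",
    "metric_effect_logprior",
    "log_prior",
    "log_posterior",
    "collapse_two_level",
    "variance_ratio",
    "assemble_sigma",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant is fitted.

    ``health_covariates`` are the terms of the latent health regression, in
    order.  With ``two_level`` set, salinity is itself regressed on distance
    downstream and must appear among the health covariates while distance
    must not.
    """

    health_covariates: tuple[str, ...]
    two_level: bool = False
    metric_cov_structure: str = "iid"  # iid | block_diagonal | unstructured
    b_bivariate: bool = False
    month_specific_variance: bool = False
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.metric_cov_structure not in ("iid", "block_diagonal", "unstructured"):
            raise ValueError(f"unknown metric_cov_structure {self.metric_cov_structure!r}")
        if self.two_level:
            if "salinity" not in self.health_covariates:
                raise ValueError("two-level model requires salinity among health covariates")
            if "dd" in self.health_covariates:
                raise ValueError("two-level model must exclude dd from health covariates")
        if self.b_bivariate and not self.two_level:
            raise ValueError("bivariate (b0, b1) prior requires the two-level structure")

    @property
    def n_beta(self) -> int:
        return len(self.health_covariates)


_PRESETS: dict[str, ModelSpec] = {
    # The five named variants reported for the Richibucto analysis:
    # (1) distance downstream only; (2) salinity only; (3) salinity-on-
    # distance two-level; (4) as (3) with correlated (b0, b1); (5) as (3)
    # plus log-depth, log-silt-clay and their interaction.
    "model1": ModelSpec(("dd",), name="model1"),
    "model2": ModelSpec(("salinity",), name="model2"),
    "model3": ModelSpec(("salinity",), two_level=True, name="model3"),
    "model4": ModelSpec(("salinity",), two_level=True, b_bivariate=True, name="model4"),
    "model5": ModelSpec(
        ("log_depth", "log_sc", "log_depth:log_sc", "salinity"),
        two_level=True,
        name="model5",
    ),
}
PRESET_NAMES = tuple(_PRESETS)


def model_preset(name: str) -> ModelSpec:
    """Return one of the named model variants (``model1`` .. ``model5``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}") from None


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the (diffuse) priors."""

    normal_variance: float = 100.0
    ig_shape: float = 1.0
    ig_scale: float = 1.0
    wishart_df_offset: int = 1  # df = block dimension + offset
    wishart_scale: float = 1.0  # identity multiplier of the scale matrix

    def __post_init__(self) -> None:
        if self.normal_variance <= 0 or self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("prior hyperparameters must be positive")


@dataclass
class ParamState:
    """All unknowns of the model, in natural (unconstrained-support) form.

    ``sigma_*`` are standard deviations; the IG(1, 1) priors apply to the
    corresponding variances.  Covariance blocks are present only for the
    correlated metric-effect structures; ``rho`` only for the bivariate
    (b0, b1) prior.  ``sigma_eps`` is a scalar, or an array of two (Sep,
    Oct) when the health-regression error variance is month-specific.
    """

    H: np.ndarray  # (n_sites,)
    delta_minus: float
    gamma: np.ndarray  # (5,) in metric order 1..5
    beta0: float
    beta: np.ndarray  # (n_terms,) aligned with ModelSpec.health_covariates
    sigma_eps: float | np.ndarray
    sigma_gamma: float | None = None
    b0: float | None = None
    b1: float | None = None
    sigma_s: float | None = None
    Sigma_pp: np.ndarray | None = None  # (2, 2)
    Sigma_mm: np.ndarray | None = None  # (3, 3)
    Sigma_pm: np.ndarray | None = None  # (2, 3), unstructured only
    rho: float | None = None

    def copy(self) -> "ParamState":
        return replace(
            self,
            H=np.array(self.H, dtype=float),
            gamma=np.array(self.gamma, dtype=float),
            beta=np.array(self.beta, dtype=float),
            sigma_eps=np.array(self.sigma_eps, dtype=float)
            if isinstance(self.sigma_eps, np.ndarray)
            else self.sigma_eps,
            Sigma_pp=None if self.Sigma_pp is None else np.array(self.Sigma_pp),
            Sigma_mm=None if self.Sigma_mm is None else np.array(self.Sigma_mm),
            Sigma_pm=None if self.Sigma_pm is None else np.array(self.Sigma_pm),
        )


def linear_predictor(H_i: float, delta_g: float, gamma_gm: float, sign_g: int) -> float:
    """eta = delta_g + gamma_gm + sign_g * H_i."""
    return delta_g + gamma_gm + sign_g * H_i


def group_probabilities(etas: np.ndarray) -> np.ndarray:
    """Generalized-logit probabilities for one group's metrics plus remainder.

    Given linear predictors ``etas`` for the metrics of one group, returns
    ``(p_1, ..., p_M, p_0)`` where ``p_m = exp(eta_m) / (1 + sum exp(eta))``
    and the baseline remainder has ``p_0 = 1 / (1 + sum exp(eta))``.
    Computed with max-subtraction so finite inputs never produce NaN.
    """
    etas = np.asarray(etas, dtype=float)
    if not np.all(np.isfinite(etas)):
        raise ValueError("non-finite linear predictor")
    full = np.append(etas, 0.0)  # remainder has eta = 0
    full = full - full.max()
    ex = np.exp(full)
    return ex / ex.sum()


def _group_log_probabilities(etas: np.ndarray) -> np.ndarray:
    """Log of :func:`group_probabilities`, vectorised over leading axes.

    ``etas`` has shape (..., M); the result has shape (..., M + 1) with the
    remainder log-probability last.
    """
    full = np.concatenate([etas, np.zeros(etas.shape[:-1] + (1,))], axis=-1)
    m = full.max(axis=-1, keepdims=True)
    lse = m + np.log(np.exp(full - m).sum(axis=-1, keepdims=True))
    return full - lse


def _multinomial_logpmf(counts: np.ndarray, logp: np.ndarray) -> np.ndarray:
    """Row-wise multinomial log-pmf; counts (..., K), logp (..., K)."""
    n = counts.sum(axis=-1)
    coef = gammaln(n + 1) - gammaln(counts + 1).sum(axis=-1)
    # 0 * log 0 = 0 by convention; logp is finite here for finite etas.
    return coef + (counts * logp).sum(axis=-1)


class LikelihoodWorkspace:
    """Precomputed count arrays for fast repeated likelihood evaluation.

    Splits each record's counts into the plus-group multinomial
    ``(y_1, y_2, total - y_1 - y_2)`` and the minus-group multinomial
    ``(y_3, y_4, y_5, total - y_3 - y_4 - y_5)`` and caches the multinomial
    coefficients and the record-to-site map.
    """

    def __init__(self, data: BenthicDataset, scheme: MetricScheme = AMBI_SCHEME):
        self.scheme = scheme
        counts = data.counts()
        totals = data.totals()
        plus = [m - 1 for m in scheme.metrics_in("plus")]
        minus = [m - 1 for m in scheme.metrics_in("minus")]
        self.plus_idx = np.array(plus)
        self.minus_idx = np.array(minus)
        yp = counts[:, plus]
        ym = counts[:, minus]
        self.Yp = np.column_stack([yp, totals - yp.sum(axis=1)])
        self.Ym = np.column_stack([ym, totals - ym.sum(axis=1)])
        if (self.Yp < 0).any() or (self.Ym < 0).any():
            raise ValueError("group counts exceed total")
        self.coef_p = gammaln(totals + 1) - gammaln(self.Yp + 1).sum(axis=1)
        self.coef_m = gammaln(totals + 1) - gammaln(self.Ym + 1).sum(axis=1)
        self.site_index = data.site_index()
        self.n_sites = data.n_sites
        # Per-site sufficient statistics: sum of group count vectors and
        # multinomial coefficients over that site's replicates.
        S = self.n_sites
        self.Yp_site = np.zeros((S, self.Yp.shape[1]))
        self.Ym_site = np.zeros((S, self.Ym.shape[1]))
        np.add.at(self.Yp_site, self.site_index, self.Yp)
        np.add.at(self.Ym_site, self.site_index, self.Ym)
        self.coef_site = np.zeros(S)
        np.add.at(self.coef_site, self.site_index, self.coef_p + self.coef_m)

    def site_logliks(self, H: np.ndarray, delta_minus: float, gamma: np.ndarray) -> np.ndarray:
        """(n_sites,) observation log-likelihood per site (both groups)."""
        lp, lm = self.group_logprobs(H, delta_minus, gamma)
        return self.coef_site + (self.Yp_site * lp).sum(axis=1) + (self.Ym_site * lm).sum(axis=1)

    def group_logprobs(
        self, H: np.ndarray, delta_minus: float, gamma: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-site log category probabilities for each group (incl. remainder)."""
        H = np.asarray(H, dtype=float)
        eta_p = gamma[self.plus_idx][None, :] + H[:, None]  # delta_plus = 0
        eta_m = delta_minus + gamma[self.minus_idx][None, :] - H[:, None]
        return _group_log_probabilities(eta_p), _group_log_probabilities(eta_m)

    def plus_loglik(self, H: np.ndarray, delta_minus: float, gamma: np.ndarray) -> float:
        eta = gamma[self.plus_idx][None, :] + np.asarray(H, dtype=float)[:, None]
        lp = _group_log_probabilities(eta)
        return float(self.coef_p.sum() + (self.Yp_site * lp).sum())

    def minus_loglik(self, H: np.ndarray, delta_minus: float, gamma: np.ndarray) -> float:
        eta = delta_minus + gamma[self.minus_idx][None, :] - np.asarray(H, dtype=float)[:, None]
        lm = _group_log_probabilities(eta)
        return float(self.coef_m.sum() + (self.Ym_site * lm).sum())


def observation_loglik(
    data: BenthicDataset, scheme: MetricScheme, state: ParamState
) -> float:
    """Multinomial log-likelihood of the metric counts, summed over both groups.

    Each group contributes a full multinomial over its metrics plus the
    remainder of the grab; the overlap of the two remainders is deliberately
    double-counted, mirroring the model's crude treatment of between-group
    dependency through the group and metric effects.
    """
    ws = LikelihoodWorkspace(data, scheme)
    return float(ws.site_logliks(state.H, state.delta_minus, state.gamma).sum())


def _normal_logpdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray | float) -> np.ndarray:
    z = (np.asarray(x) - mean) / sd
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * z * z


def health_means(state: ParamState, design: CenteredDesign) -> np.ndarray:
    return state.beta0 + design.matrix @ state.beta


def latent_health_loglik(
    state: ParamState,
    design: CenteredDesign,
    spec: ModelSpec,
    site_months: np.ndarray | None = None,
) -> float:
    """Gaussian log-density of latent health about its regression mean.

    With ``month_specific_variance`` the error s.d. is indexed by each
    site's sampling month (``sigma_eps`` then holds the Sep and Oct values).
    """
    if len(state.beta) != design.matrix.shape[1]:
        raise ValueError(
            f"beta has {len(state.beta)} entries but design has {design.matrix.shape[1]} columns"
        )
    mu = health_means(state, design)
    if spec.month_specific_variance:
        if site_months is None:
            raise ValueError("month-specific variance requires per-site months")
        sig = np.asarray(state.sigma_eps)
        sd = np.where(np.asarray(site_months) == "Sep", sig[0], sig[1])
    else:
        sd = float(np.asarray(state.sigma_eps).reshape(()))
    return float(_normal_logpdf(state.H, mu, sd).sum())


def salinity_loglik(
    cov: CovariateTable, design: CenteredDesign, state: ParamState
) -> float:
    """Gaussian log-density of centered salinity about b0 + b1 * centered dd."""
    if state.b0 is None or state.b1 is None or state.sigma_s is None:
        raise ValueError("salinity regression parameters absent (two-level model inactive)")
    mu = state.b0 + state.b1 * design.centered_dd
    return float(_normal_logpdf(design.centered_salinity, mu, state.sigma_s).sum())


def assemble_sigma(state: ParamState, scheme: MetricScheme = AMBI_SCHEME) -> np.ndarray:
    """Full 5x5 metric-effect covariance from the stored blocks.

    Metric order is 1..5 (plus group first).  The cross block is zero for
    the block-diagonal structure.
    """
    p = len(scheme.metrics_in("plus"))
    m = len(scheme.metrics_in("minus"))
    S = np.zeros((p + m, p + m))
    S[:p, :p] = state.Sigma_pp
    S[p:, p:] = state.Sigma_mm
    if state.Sigma_pm is not None:
        S[:p, p:] = state.Sigma_pm
        S[p:, :p] = state.Sigma_pm.T
    return S


def _mvn_logpdf_zero_mean(x: np.ndarray, cov: np.ndarray) -> float:
    """MVN(0, cov) log-density; raises on non-positive-definite cov."""
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance not positive definite") from exc
    z = np.linalg.solve(L, x)
    return float(
        -0.5 * len(x) * np.log(2.0 * np.pi) - np.log(np.diag(L)).sum() - 0.5 * z @ z
    )


def metric_effect_logprior(
    gamma: np.ndarray, state: ParamState, spec: ModelSpec, scheme: MetricScheme = AMBI_SCHEME
) -> float:
    """Log-prior of the metric effects under the chosen covariance structure."""
    gamma = np.asarray(gamma, dtype=float)
    if spec.metric_cov_structure == "iid":
        if state.sigma_gamma is None or state.sigma_gamma <= 0:
            return -np.inf
        return float(_normal_logpdf(gamma, 0.0, state.sigma_gamma).sum())
    p = len(scheme.metrics_in("plus"))
    if spec.metric_cov_structure == "block_diagonal":
        return _mvn_logpdf_zero_mean(gamma[:p], state.Sigma_pp) + _mvn_logpdf_zero_mean(
            gamma[p:], state.Sigma_mm
        )
    return _mvn_logpdf_zero_mean(gamma, assemble_sigma(state, scheme))


def _ig_logpdf(v: float, shape: float, scale: float) -> float:
    """Inverse-gamma log-density at v (on the variance scale)."""
    if v <= 0:
        return -np.inf
    return float(shape * np.log(scale) - gammaln(shape) - (shape + 1) * np.log(v) - scale / v)


def log_prior(
    state: ParamState,
    spec: ModelSpec,
    priors: PriorSpec = PriorSpec(),
    scheme: MetricScheme = AMBI_SCHEME,
) -> float:
    """Joint log-prior over all non-latent unknowns.

    N(0, normal_variance) for delta_minus, beta0, beta, and (b0, b1) - the
    latter jointly bivariate normal with correlation ``rho ~ Uniform(-1, 1)``
    when the bivariate option is on; IG(shape, scale) for each error
    variance (and for sigma_gamma^2 under iid metric effects);
    inverse-Wishart(dim + offset, scale * I) for each active covariance
    block; and the metric-effect prior for gamma.  Out-of-support states
    return -inf.
    """
    v0 = priors.normal_variance
    sd0 = np.sqrt(v0)
    lp = float(_normal_logpdf(np.array([state.delta_minus, state.beta0]), 0.0, sd0).sum())
    lp += float(_normal_logpdf(state.beta, 0.0, sd0).sum())

    sig = np.atleast_1d(np.asarray(state.sigma_eps, dtype=float))
    if (sig <= 0).any():
        return -np.inf
    for s in sig:
        lp += _ig_logpdf(s * s, priors.ig_shape, priors.ig_scale)

    if spec.two_level:
        if state.sigma_s is None or state.sigma_s <= 0:
            return -np.inf
        lp += _ig_logpdf(state.sigma_s**2, priors.ig_shape, priors.ig_scale)
        b = np.array([state.b0, state.b1], dtype=float)
        if spec.b_bivariate:
            rho = state.rho
            if rho is None or not (-1.0 < rho < 1.0):
                return -np.inf
            C = v0 * np.array([[1.0, rho], [rho, 1.0]])
            # flat Uniform(-1, 1) on rho contributes only a constant
            lp += _mvn_logpdf_zero_mean(b, C)
        else:
            lp += float(_normal_logpdf(b, 0.0, sd0).sum())

    if spec.metric_cov_structure == "iid":
        if state.sigma_gamma is None or state.sigma_gamma <= 0:
            return -np.inf
        lp += _ig_logpdf(state.sigma_gamma**2, priors.ig_shape, priors.ig_scale)
    elif spec.metric_cov_structure == "block_diagonal":
        for block in (state.Sigma_pp, state.Sigma_mm):
            d = block.shape[0]
            try:
                lp += float(
                    invwishart.logpdf(
                        block, df=d + priors.wishart_df_offset, scale=priors.wishart_scale * np.eye(d)
                    )
                )
            except (np.linalg.LinAlgError, ValueError):
                return -np.inf
    else:  # unstructured: one inverse-Wishart on the assembled 5x5
        full = assemble_sigma(state, scheme)
        d = full.shape[0]
        try:
            lp += float(
                invwishart.logpdf(
                    full, df=d + priors.wishart_df_offset, scale=priors.wishart_scale * np.eye(d)
                )
            )
        except (np.linalg.LinAlgError, ValueError):
            return -np.inf

    try:
        lp += metric_effect_logprior(state.gamma, state, spec, scheme)
    except ValueError:
        return -np.inf
    return lp


def log_posterior(
    state: ParamState,
    data: BenthicDataset,
    design: CenteredDesign,
    cov: CovariateTable,
    spec: ModelSpec,
    priors: PriorSpec = PriorSpec(),
    scheme: MetricScheme = AMBI_SCHEME,
) -> float:
    """Unnormalised joint log-posterior of the full model."""
    lp = log_prior(state, spec, priors, scheme)
    if not np.isfinite(lp):
        return -np.inf
    months = data.month_of_site() if spec.month_specific_variance else None
    lp += latent_health_loglik(state, design, spec, months)
    lp += observation_loglik(data, scheme, state)
    if spec.two_level:
        lp += salinity_loglik(cov, design, state)
    return lp


def collapse_two_level(
    beta0: float, beta_sal: float, b0: float, b1: float, sigma_eps: float, sigma_s: float
) -> tuple[float, float, float]:
    """Marginalise salinity out of the two-level health regression.

    Returns the collapsed intercept ``beta0 + beta_sal * b0``, distance
    slope ``beta_sal * b1`` and total error variance
    ``sigma_eps^2 + beta_sal^2 * sigma_s^2``.
    """
    return (
        beta0 + beta_sal * b0,
        beta_sal * b1,
        sigma_eps**2 + beta_sal**2 * sigma_s**2,
    )


def variance_ratio(sigma_eps: float, beta_sal: float, sigma_s: float) -> float:
    """Fraction of collapsed error variance not explained by implicit salinity."""
    ve = sigma_eps**2
    return ve / (ve + beta_sal**2 * sigma_s**2)
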