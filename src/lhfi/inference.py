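"""Posterior sampling by Metropolis-within-Gibbs with hierarchical centering.

The sampler exploits the model's conditional structure:

* latent health ``H_i`` and the metric/group effects (``gamma``,
  ``delta_minus``) face the multinomial likelihood and are updated by
  adaptive random-walk Metropolis (per-site proposals for ``H``, scalar
  proposals for the effects), with step sizes tuned toward ~44% acceptance
  during burn-in only;
* everything else is conjugate and Gibbs-updated exactly: the health
  regression coefficients (multivariate normal), all error variances
  (inverse-gamma), the iid metric-effect variance (inverse-gamma), the
  metric-effect covariance blocks (inverse-Wishart), and the salinity-on-
  distance coefficients (bivariate normal);
* the prior correlation ``rho`` of (b0, b1), when active, gets a scalar
  random-walk update on (-1, 1).

``H`` is sampled in the hierarchically *centered* parameterisation - around
its regression mean, with the regression coefficients Gibbs-updated given
``H`` - which is what makes the chain mix despite the strong coupling
between the latent factor and its regression.  The centering bijection is
exposed as :func:`hierarchical_center` for testing and diagnostics.

The target density is the joint posterior of :func:`lhfi.model.log_posterior`;
the kernel is an implementation detail and any correct kernel would do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .data import AMBI_SCHEME, BenthicDataset, CenteredDesign, CovariateTable, MetricScheme
from .model import (
    LikelihoodWorkspace,
    ModelSpec,
    ParamState,
    PriorSpec,
    _normal_logpdf,
    metric_effect_logprior,
)

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "initialize_state",
    "hierarchical_center",
    "run_chains",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain-length and tuning settings.

    ``burn_in="auto"`` discards the first half of each chain and then checks
    convergence (max interval-based R-hat < 1.1); a violation is flagged in
    the output metadata rather than silently extending the run.  ``thin``
    applies to traces *persisted to disk*; in-memory summaries use every
    post-burn-in draw.
    """

    n_chains: int = 2
    n_iter: int = 50_000
    burn_in: int | str = "auto"
    thin: int = 100
    seed: int = 0
    step_h: float = 0.25
    step_effect: float = 0.15
    step_rho: float = 0.3
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if isinstance(self.burn_in, int) and not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must lie in [0, n_iter)")

    def burn(self) -> int:
        return self.n_iter // 2 if self.burn_in == "auto" else int(self.burn_in)


@dataclass
class PosteriorDraws:
    """Named post-burn-in MCMC draws, one array (n_chains, n_draws) per scalar.

    Parameter names follow the model notation: ``H[site]``, ``gamma[m]``,
    ``beta0``, ``beta[term]``, ``delta_minus``, ``sigma_eps``,
    ``sigma_gamma``, ``b0``, ``b1``, ``sigma_s``, ``rho``,
    ``Sigma_pp[i,j]`` etc.  ``metadata`` records the model spec, seed,
    chain settings, centering constants, and convergence flags.
    """

    params: dict[str, np.ndarray]
    metadata: dict

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.params.values()}
        if len(shapes) > 1:
            raise ValueError("all parameters must share (n_chains, n_draws) shape")

    @property
    def names(self) -> list[str]:
        return list(self.params)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All chains' draws of one parameter, concatenated."""
        return self.params[name].reshape(-1)

    def matching(self, prefix: str) -> list[str]:
        return [n for n in self.names if n == prefix or n.startswith(prefix + "[")]

    def save(self, out_dir: str | Path) -> None:
        """Persist thinned traces (CSV per chain) plus a JSON metadata file."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        thin = int(self.metadata.get("thin", 1))
        for c in range(self.n_chains):
            df = pd.DataFrame({n: self.params[n][c, ::thin] for n in self.names})
            df.insert(0, "iteration", np.arange(0, self.n_draws, thin))
            df.to_csv(out / f"chain{c}.csv", index=False)
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)

    @classmethod
    def load(cls, out_dir: str | Path) -> "PosteriorDraws":
        out = Path(out_dir)
        with open(out / "metadata.json") as fh:
            meta = json.load(fh)
        frames = []
        c = 0
        while (out / f"chain{c}.csv").exists():
            frames.append(pd.read_csv(out / f"chain{c}.csv"))
            c += 1
        if not frames:
            raise FileNotFoundError(f"no chain CSVs under {out}")
        names = [n for n in frames[0].columns if n != "iteration"]
        params = {n: np.stack([f[n].to_numpy() for f in frames]) for n in names}
        meta = dict(meta)
        meta["thin"] = 1  # already thinned on disk
        return cls(params=params, metadata=meta)


def initialize_state(
    spec: ModelSpec,
    data: BenthicDataset,
    design: CenteredDesign,
    seed: int,
    scheme: MetricScheme = AMBI_SCHEME,
) -> ParamState:
    """Dispersed but valid starting values (unit variances, N(0,1) jitter)."""
    rng = np.random.default_rng(seed)
    S = data.n_sites
    p = spec.n_beta
    state = ParamState(
        H=rng.standard_normal(S),
        delta_minus=float(rng.standard_normal()),
        gamma=0.5 * rng.standard_normal(5),
        beta0=float(rng.standard_normal()),
        beta=rng.standard_normal(p),
        sigma_eps=np.ones(2) if spec.month_specific_variance else 1.0,
        sigma_gamma=1.0 if spec.metric_cov_structure == "iid" else None,
    )
    if spec.metric_cov_structure != "iid":
        state.Sigma_pp = np.eye(2)
        state.Sigma_mm = np.eye(3)
        if spec.metric_cov_structure == "unstructured":
            state.Sigma_pm = np.zeros((2, 3))
    if spec.two_level:
        state.b0 = float(rng.standard_normal())
        state.b1 = float(rng.standard_normal())
        state.sigma_s = 1.0
        if spec.b_bivariate:
            state.rho = 0.0
    return state


def hierarchical_center(
    state: ParamState, design: CenteredDesign
) -> tuple[ParamState, Callable[[ParamState], ParamState]]:
    """Express latent health as deviations about its regression mean.

    Returns the reparameterised state (``H`` replaced by
    ``H - (beta0 + x'beta)``) and the inverse map.  The transform is a pure
    location shift, so densities carry over with unit Jacobian; round-trip
    recovers the original state exactly up to floating point.
    """
    mu = state.beta0 + design.matrix @ state.beta
    centered = state.copy()
    centered.H = state.H - mu

    def uncenter(s: ParamState) -> ParamState:
        out = s.copy()
        out.H = s.H + (s.beta0 + design.matrix @ s.beta)
        return out

    return centered, uncenter


def _sample_invgamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return float(scale / rng.gamma(shape))


class _ChainSampler:
    """One chain of the Metropolis-within-Gibbs sampler."""

    def __init__(
        self,
        data: BenthicDataset,
        design: CenteredDesign,
        cov: CovariateTable,
        spec: ModelSpec,
        priors: PriorSpec,
        config: MCMCConfig,
        rng: np.random.Generator,
        init: ParamState,
        fixed: Mapping[str, np.ndarray | float] | None = None,
        scheme: MetricScheme = AMBI_SCHEME,
    ):
        self.spec = spec
        self.priors = priors
        self.config = config
        self.rng = rng
        self.scheme = scheme
        self.fixed = dict(fixed or {})
        self.ws = LikelihoodWorkspace(data, scheme)
        self.S = data.n_sites
        self.X = np.column_stack([np.ones(self.S), design.matrix])
        self.design = design
        self.months = data.month_of_site()
        self.month_code = (self.months != "Sep").astype(int)  # 0 = Sep, 1 = Oct
        self.state = init.copy()
        for name, value in self.fixed.items():
            setattr(self.state, name, np.array(value, dtype=float) if np.ndim(value) else float(value))
        # adaptive RW steps
        self.step_h = np.full(self.S, config.step_h)
        self.step_delta = config.step_effect
        self.step_gamma = np.full(5, config.step_effect)
        self.step_rho = config.step_rho
        self.step_shift = np.array([0.3, 0.3])  # translation moves A, B
        self.acc_h = np.zeros(self.S)
        self.acc_delta = 0.0
        self.acc_gamma = np.zeros(5)
        self.acc_rho = 0.0
        self.acc_shift = np.zeros(2)
        self.n_adapt = 0
        self.diverged = False

    # -- conditional pieces -------------------------------------------------

    def _sigma_site(self) -> np.ndarray:
        st = self.state
        if self.spec.month_specific_variance:
            sig = np.asarray(st.sigma_eps)
            return sig[self.month_code]
        return np.full(self.S, float(np.asarray(st.sigma_eps).reshape(())))

    def _update_H(self) -> None:
        st = self.state
        sd = self._sigma_site()
        mu = self.X @ np.concatenate([[st.beta0], st.beta])
        cur = self.ws.site_logliks(st.H, st.delta_minus, st.gamma)
        cur += _normal_logpdf(st.H, mu, sd)
        prop = st.H + self.step_h * self.rng.standard_normal(self.S)
        new = self.ws.site_logliks(prop, st.delta_minus, st.gamma)
        new += _normal_logpdf(prop, mu, sd)
        accept = np.log(self.rng.random(self.S)) < new - cur
        st.H = np.where(accept, prop, st.H)
        self.acc_h += accept

    def _update_delta(self) -> None:
        st = self.state
        sd0 = np.sqrt(self.priors.normal_variance)
        cur = self.ws.minus_loglik(st.H, st.delta_minus, st.gamma) + float(
            _normal_logpdf(np.array(st.delta_minus), 0.0, sd0)
        )
        prop = st.delta_minus + self.step_delta * self.rng.standard_normal()
        new = self.ws.minus_loglik(st.H, prop, st.gamma) + float(
            _normal_logpdf(np.array(prop), 0.0, sd0)
        )
        if np.log(self.rng.random()) < new - cur:
            st.delta_minus = prop
            self.acc_delta += 1

    def _update_gamma(self) -> None:
        st = self.state
        n_plus = len(self.scheme.metrics_in("plus"))
        cur_ll = {
            True: self.ws.plus_loglik(st.H, st.delta_minus, st.gamma),
            False: self.ws.minus_loglik(st.H, st.delta_minus, st.gamma),
        }
        cur_prior = metric_effect_logprior(st.gamma, st, self.spec, self.scheme)
        for m in range(5):
            in_plus = m < n_plus
            loglik = self.ws.plus_loglik if in_plus else self.ws.minus_loglik
            prop = st.gamma.copy()
            prop[m] += self.step_gamma[m] * self.rng.standard_normal()
            try:
                new_prior = metric_effect_logprior(prop, st, self.spec, self.scheme)
            except ValueError:
                continue
            new_ll = loglik(st.H, st.delta_minus, prop)
            if np.log(self.rng.random()) < new_ll + new_prior - cur_ll[in_plus] - cur_prior:
                st.gamma = prop
                cur_ll[in_plus] = new_ll
                cur_prior = new_prior
                self.acc_gamma[m] += 1

    def _update_translations(self) -> None:
        """Metropolis moves along the likelihood-invariant ridge directions.

        The observation likelihood and the health-regression residuals are
        exactly invariant under (H, beta0, delta_minus, gamma_plus) ->
        (H + c, beta0 + c, delta_minus + c, gamma_plus - c) and under
        (delta_minus, gamma_minus) -> (delta_minus - d, gamma_minus + d);
        only the shrinkage priors constrain these directions, so plain
        componentwise updates mix very slowly along them.  Joint proposals
        need only the prior ratio.
        """
        st = self.state
        sd0 = np.sqrt(self.priors.normal_variance)
        prior_g = lambda g: metric_effect_logprior(g, st, self.spec, self.scheme)
        # move A: shift the latent-health level
        c = self.step_shift[0] * self.rng.standard_normal()
        g_new = st.gamma.copy()
        g_new[self.ws.plus_idx] -= c
        try:
            logr = (
                prior_g(g_new)
                - prior_g(st.gamma)
                + float(_normal_logpdf(np.array(st.delta_minus + c), 0.0, sd0))
                - float(_normal_logpdf(np.array(st.delta_minus), 0.0, sd0))
                + float(_normal_logpdf(np.array(st.beta0 + c), 0.0, sd0))
                - float(_normal_logpdf(np.array(st.beta0), 0.0, sd0))
            )
        except ValueError:
            logr = -np.inf
        if np.log(self.rng.random()) < logr:
            st.H = st.H + c
            st.beta0 += c
            st.delta_minus += c
            st.gamma = g_new
            self.acc_shift[0] += 1
        # move B: trade the minus-group effect against its metric effects
        d = self.step_shift[1] * self.rng.standard_normal()
        g_new = st.gamma.copy()
        g_new[self.ws.minus_idx] += d
        try:
            logr = (
                prior_g(g_new)
                - prior_g(st.gamma)
                + float(_normal_logpdf(np.array(st.delta_minus - d), 0.0, sd0))
                - float(_normal_logpdf(np.array(st.delta_minus), 0.0, sd0))
            )
        except ValueError:
            logr = -np.inf
        if np.log(self.rng.random()) < logr:
            st.gamma = g_new
            st.delta_minus -= d
            self.acc_shift[1] += 1

    def _update_beta(self) -> None:
        st = self.state
        w = 1.0 / self._sigma_site() ** 2
        A = (self.X * w[:, None]).T @ self.X + np.eye(self.X.shape[1]) / self.priors.normal_variance
        mean = np.linalg.solve(A, self.X.T @ (w * st.H))
        L = np.linalg.cholesky(np.linalg.inv(A))
        draw = mean + L @ self.rng.standard_normal(len(mean))
        st.beta0 = float(draw[0])
        st.beta = draw[1:]

    def _update_sigma_eps(self) -> None:
        st = self.state
        resid = st.H - self.X @ np.concatenate([[st.beta0], st.beta])
        a, b = self.priors.ig_shape, self.priors.ig_scale
        if self.spec.month_specific_variance:
            out = np.empty(2)
            for t in (0, 1):
                r = resid[self.month_code == t]
                out[t] = np.sqrt(_sample_invgamma(self.rng, a + len(r) / 2, b + 0.5 * r @ r))
            st.sigma_eps = out
        else:
            st.sigma_eps = float(
                np.sqrt(_sample_invgamma(self.rng, a + self.S / 2, b + 0.5 * resid @ resid))
            )

    def _update_gamma_scale(self) -> None:
        st = self.state
        a, b = self.priors.ig_shape, self.priors.ig_scale
        if self.spec.metric_cov_structure == "iid":
            if "sigma_gamma" in self.fixed:
                return
            st.sigma_gamma = float(
                np.sqrt(_sample_invgamma(self.rng, a + 2.5, b + 0.5 * st.gamma @ st.gamma))
            )
        elif self.spec.metric_cov_structure == "block_diagonal":
            gp, gm = st.gamma[:2], st.gamma[2:]
            off, sc = self.priors.wishart_df_offset, self.priors.wishart_scale
            st.Sigma_pp = invwishart.rvs(
                df=2 + off + 1, scale=sc * np.eye(2) + np.outer(gp, gp), random_state=self.rng
            )
            st.Sigma_mm = invwishart.rvs(
                df=3 + off + 1, scale=sc * np.eye(3) + np.outer(gm, gm), random_state=self.rng
            )
        else:
            off, sc = self.priors.wishart_df_offset, self.priors.wishart_scale
            g = st.gamma
            full = invwishart.rvs(
                df=5 + off + 1, scale=sc * np.eye(5) + np.outer(g, g), random_state=self.rng
            )
            st.Sigma_pp = full[:2, :2]
            st.Sigma_mm = full[2:, 2:]
            st.Sigma_pm = full[:2, 2:]

    def _update_salinity_block(self) -> None:
        st = self.state
        d = self.design.centered_dd
        s = self.design.centered_salinity
        D = np.column_stack([np.ones(len(d)), d])
        v0 = self.priors.normal_variance
        if self.spec.b_bivariate:
            rho = st.rho
            C = v0 * np.array([[1.0, rho], [rho, 1.0]])
            Cinv = np.linalg.inv(C)
        else:
            Cinv = np.eye(2) / v0
        A = D.T @ D / st.sigma_s**2 + Cinv
        mean = np.linalg.solve(A, D.T @ s / st.sigma_s**2)
        L = np.linalg.cholesky(np.linalg.inv(A))
        draw = mean + L @ self.rng.standard_normal(2)
        st.b0, st.b1 = float(draw[0]), float(draw[1])
        resid = s - D @ draw
        a, b = self.priors.ig_shape, self.priors.ig_scale
        st.sigma_s = float(
            np.sqrt(_sample_invgamma(self.rng, a + len(s) / 2, b + 0.5 * resid @ resid))
        )
        if self.spec.b_bivariate:
            self._update_rho()

    def _update_rho(self) -> None:
        st = self.state
        v0 = self.priors.normal_variance
        b = np.array([st.b0, st.b1])

        def target(r: float) -> float:
            C = v0 * np.array([[1.0, r], [r, 1.0]])
            sign, logdet = np.linalg.slogdet(C)
            return -0.5 * logdet - 0.5 * b @ np.linalg.solve(C, b)

        prop = st.rho + self.step_rho * self.rng.standard_normal()
        if -1.0 < prop < 1.0:
            if np.log(self.rng.random()) < target(prop) - target(st.rho):
                st.rho = prop
                self.acc_rho += 1

    def _adapt(self, n_done: int) -> None:
        k = self.config.adapt_interval
        f = np.exp((self.acc_h / k - 0.44).clip(-1, 1) * 0.5)
        self.step_h = np.clip(self.step_h * f, 1e-3, 10.0)
        self.step_delta *= np.exp((self.acc_delta / k - 0.44) * 0.5)
        self.step_gamma *= np.exp((self.acc_gamma / k - 0.44).clip(-1, 1) * 0.5)
        if self.spec.b_bivariate:
            self.step_rho *= np.exp((self.acc_rho / k - 0.44) * 0.5)
        self.step_shift = np.clip(
            self.step_shift * np.exp((self.acc_shift / k - 0.44) * 0.5), 1e-3, 10.0
        )
        self.acc_h[:] = 0
        self.acc_delta = 0.0
        self.acc_gamma[:] = 0
        self.acc_rho = 0.0
        self.acc_shift[:] = 0

    # -- main loop ----------------------------------------------------------

    def run(self, record: Callable[[ParamState], None]) -> None:
        cfg = self.config
        burn = cfg.burn()
        for it in range(cfg.n_iter):
            if "H" not in self.fixed:
                self._update_H()
            if "delta_minus" not in self.fixed:
                self._update_delta()
            if "gamma" not in self.fixed:
                self._update_gamma()
            if not ({"H", "delta_minus", "gamma"} & self.fixed.keys()):
                self._update_translations()
            self._update_beta()
            self._update_sigma_eps()
            self._update_gamma_scale()
            if self.spec.two_level:
                self._update_salinity_block()
            if it < burn and (it + 1) % cfg.adapt_interval == 0:
                self._adapt(it + 1)
            if not np.all(np.isfinite(self.state.H)):
                self.diverged = True
                break
            if it >= burn:
                record(self.state)


def _flatten_names(spec: ModelSpec, data: BenthicDataset) -> list[tuple[str, Callable]]:
    """(name, extractor) pairs defining the flattened trace layout."""
    sites = data.sites
    out: list[tuple[str, Callable]] = []
    for k, s in enumerate(sites):
        out.append((f"H[{s}]", lambda st, k=k: st.H[k]))
    out.append(("delta_minus", lambda st: st.delta_minus))
    for m in range(5):
        out.append((f"gamma[{m + 1}]", lambda st, m=m: st.gamma[m]))
    out.append(("beta0", lambda st: st.beta0))
    for j, term in enumerate(spec.health_covariates):
        out.append((f"beta[{term}]", lambda st, j=j: st.beta[j]))
    if spec.month_specific_variance:
        out.append(("sigma_eps[Sep]", lambda st: np.asarray(st.sigma_eps)[0]))
        out.append(("sigma_eps[Oct]", lambda st: np.asarray(st.sigma_eps)[1]))
    else:
        out.append(("sigma_eps", lambda st: float(np.asarray(st.sigma_eps).reshape(()))))
    if spec.metric_cov_structure == "iid":
        out.append(("sigma_gamma", lambda st: st.sigma_gamma))
    else:
        for i in range(2):
            for j in range(i, 2):
                out.append((f"Sigma_pp[{i + 1},{j + 1}]", lambda st, i=i, j=j: st.Sigma_pp[i, j]))
        for i in range(3):
            for j in range(i, 3):
                out.append((f"Sigma_mm[{i + 1},{j + 1}]", lambda st, i=i, j=j: st.Sigma_mm[i, j]))
        if spec.metric_cov_structure == "unstructured":
            for i in range(2):
                for j in range(3):
                    out.append(
                        (f"Sigma_pm[{i + 1},{j + 1}]", lambda st, i=i, j=j: st.Sigma_pm[i, j])
                    )
    if spec.two_level:
        out.append(("b0", lambda st: st.b0))
        out.append(("b1", lambda st: st.b1))
        out.append(("sigma_s", lambda st: st.sigma_s))
        if spec.b_bivariate:
            out.append(("rho", lambda st: st.rho))
    return out


def run_chains(
    data: BenthicDataset,
    design: CenteredDesign,
    cov: CovariateTable,
    spec: ModelSpec,
    priors: PriorSpec = PriorSpec(),
    config: MCMCConfig = MCMCConfig(),
    fixed: Mapping[str, np.ndarray | float] | None = None,
    scheme: MetricScheme = AMBI_SCHEME,
) -> PosteriorDraws:
    """Run independent MCMC chains and collect post-burn-in draws.

    ``fixed`` clamps named blocks (``H``, ``delta_minus``, ``gamma``,
    ``sigma_gamma``) at given values, excluding them from updating - useful
    for conditional-posterior validation.  Identical (seed, inputs) give
    bit-identical output.
    """
    layout = _flatten_names(spec, data)
    names = [n for n, _ in layout]
    burn = config.burn()
    n_keep = config.n_iter - burn
    traces = np.empty((config.n_chains, n_keep, len(layout)))
    diverged = []
    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c])
        init = initialize_state(spec, data, design, seed=int(rng.integers(2**31)), scheme=scheme)
        sampler = _ChainSampler(
            data, design, cov, spec, priors, config, rng, init, fixed=fixed, scheme=scheme
        )
        row = {"i": 0}

        def record(st: ParamState, c=c, row=row) -> None:
            traces[c, row["i"], :] = [f(st) for _, f in layout]
            row["i"] += 1

        sampler.run(record)
        if sampler.diverged:
            diverged.append(c)
            traces[c, row["i"] :, :] = np.nan

    params = {n: traces[:, :, k].copy() for k, (n, _) in enumerate(layout)}
    meta = {
        "model": spec.name,
        "spec": {
            "health_covariates": list(spec.health_covariates),
            "two_level": spec.two_level,
            "metric_cov_structure": spec.metric_cov_structure,
            "b_bivariate": spec.b_bivariate,
            "month_specific_variance": spec.month_specific_variance,
        },
        "seed": config.seed,
        "n_iter": config.n_iter,
        "burn_in": burn,
        "thin": config.thin,
        "n_chains": config.n_chains,
        "centering_constants": dict(design.centering_constants),
        "fixed": sorted(fixed) if fixed else [],
        "diverged_chains": diverged,
    }
    draws = PosteriorDraws(params=params, metadata=meta)
    # convergence flag (interval-based BGR); import here to avoid a cycle
    from .diagnostics import max_rhat

    rhat = max_rhat(draws)
    meta["max_rhat"] = rhat
    meta["converged"] = bool(rhat < 1.1) and not diverged
    return draws
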