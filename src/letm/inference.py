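"""Bayesian estimation of the threshold model by Gibbs sampling.

Augmented model. With liability l_i = eta_i - theta_i the observation rule
Y_i = 1{l_i > 0} becomes a sign constraint on l, and the joint over
(l, a, mu_theta, sigma_A^2, sigma_eta^2) has fully tractable conditionals:

* l_i | rest ~ Normal(X_i - mu_theta - a_i, sigma_eta^2) truncated to
  (0, inf) when Y_i = 1 and (-inf, 0] when Y_i = 0 — equivalently the latent
  cue eta_i = l_i + theta_i is Normal(X_i, sigma_eta^2) truncated at theta_i.
* writing z = X - l, z | a, mu ~ Normal(mu + a, sigma_eta^2 I), a plain
  Gaussian animal model; a | rest is multivariate normal and is drawn jointly.
* variance conditionals are truncated inverse gammas under the uniform
  standard-deviation priors.

The joint a-draw uses the spectral factorization A = U D U^T computed once:
in the rotated basis b = U^T a the prior is independent Normal(0,
sigma_A^2 d_j) and the full conditional stays diagonal because the residual
covariance is isotropic, so each sweep costs two matrix-vector products.

X is standardized internally for conditioning; every stored draw is
back-transformed to grams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from letm.model import heritability, validate_cohort
from letm.pedigree import RelatednessMatrix

_VAR_FLOOR = 1e-12  # lower floor on variance draws, avoids degenerate truncations
_U_EPS = 1e-15  # keep inverse-CDF arguments strictly inside (0, 1)

SCALAR_PARAMETERS = ("mu_theta", "sigma_a", "sigma_eta", "h2")


@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters, on the gram scale of the observable cue.

    ``None`` fields are resolved from the data when sampling starts:
    mu_theta ~ Normal(mean(X), (10 sd(X))^2), sigma_A and sigma_eta ~
    Uniform(0, 10 sd(X)) — weakly informative on the anchored cue scale.
    """

    mu_mean: float | None = None
    mu_sd: float | None = None
    sigma_a_upper: float | None = None
    sigma_eta_upper: float | None = None

    def resolve(self, x: np.ndarray) -> "Priors":
        if x.size >= 2 and np.std(x) > 0:
            m, s = float(np.mean(x)), float(np.std(x))
        else:
            m, s = (float(np.mean(x)) if x.size else 0.0), 1.0
        return Priors(
            mu_mean=self.mu_mean if self.mu_mean is not None else m,
            mu_sd=self.mu_sd if self.mu_sd is not None else 10.0 * s,
            sigma_a_upper=self.sigma_a_upper if self.sigma_a_upper is not None else 10.0 * s,
            sigma_eta_upper=(
                self.sigma_eta_upper if self.sigma_eta_upper is not None else 10.0 * s
            ),
        )


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler run configuration.

    Defaults follow the study protocol: two independent chains, burn-in of
    5000 sweeps, then 20000 sweeps recorded every 100 -> 200 saved draws per
    chain. ``sigma_a_fixed`` pins the additive standard deviation (0 gives
    the no-genetics probit limit of the model).
    """

    n_chains: int = 2
    burn_in: int = 5000
    n_records: int = 200
    thin: int = 100
    seed: int = 0
    priors: Priors = field(default_factory=Priors)
    sigma_a_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.burn_in < 0 or self.n_records < 1 or self.thin < 1:
            raise ValueError("chain/iteration counts must be positive (burn_in >= 0)")
        if self.sigma_a_fixed is not None and self.sigma_a_fixed < 0:
            raise ValueError("sigma_a_fixed must be >= 0")


@dataclass(frozen=True)
class LETMPosterior:
    """Posterior draws, all on the gram scale.

    Scalar parameters are (n_chains, n_draws) arrays; per-individual latent
    draws (additive effect a, threshold theta, cue eta) are
    (n_chains, n_draws, n_individuals), aligned with ``ids``.
    """

    ids: list[str]
    mu_theta: np.ndarray
    sigma_a: np.ndarray
    sigma_eta: np.ndarray
    a: np.ndarray = field(repr=False)
    eta: np.ndarray = field(repr=False)

    @property
    def n_chains(self) -> int:
        return self.mu_theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu_theta.shape[1]

    @property
    def theta(self) -> np.ndarray:
        return self.mu_theta[:, :, None] + self.a

    @property
    def h2(self) -> np.ndarray:
        va, ve = self.sigma_a**2, self.sigma_eta**2
        return va / (va + ve)

    def parameter(self, name: str) -> np.ndarray:
        """Draws for a scalar parameter, shape (n_chains, n_draws)."""
        if name not in SCALAR_PARAMETERS:
            raise KeyError(f"unknown scalar parameter {name!r}; have {SCALAR_PARAMETERS}")
        return getattr(self, name)

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated into one flat vector."""
        return self.parameter(name).reshape(-1)

    def family_offsets(self, cohort: pd.DataFrame) -> dict[str, float]:
        """Posterior-mean additive effect per family (curve centring offsets)."""
        males = validate_cohort(cohort)
        pos = {i: k for k, i in enumerate(self.ids)}
        a_mean = self.a.mean(axis=(0, 1))
        out: dict[str, float] = {}
        for fam, grp in males.groupby("family_id", sort=True):
            idx = [pos[i] for i in grp["individual_id"].astype(str) if i in pos]
            if idx:
                out[str(fam)] = float(a_mean[idx].mean())
        return out

    def theta_draws_for(self, individual_ids) -> np.ndarray:
        """Pooled posterior threshold draws for a set of individuals, flattened."""
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = [pos[str(i)] for i in individual_ids]
        return self.theta[:, :, idx].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Scalar draws in long format: chain, iteration, parameter, value."""
        rows = []
        for name in SCALAR_PARAMETERS:
            vals = self.parameter(name)
            for c in range(self.n_chains):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(self.n_draws),
                            "parameter": name,
                            "value": vals[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _sample_truncnorm(rng, mean, sd, positive, u_draw=None) -> np.ndarray:
    """Vectorized truncated-normal draw at cutpoint 0 by inverse CDF.

    positive=True restricts to (0, inf), False to (-inf, 0]. Arguments are
    clipped away from {0, 1} so extreme truncations stay finite.
    """
    alpha = ndtr((0.0 - mean) / sd)  # P(untruncated < 0)
    u = rng.random(mean.shape) if u_draw is None else u_draw
    lo = np.where(positive, alpha, 0.0)
    hi = np.where(positive, 1.0, alpha)
    p = np.clip(lo + u * (hi - lo), _U_EPS, 1.0 - _U_EPS)
    return mean + sd * ndtri(p)


def _slice_sample(rng, logp, current: float, lo: float, hi: float, max_shrink: int = 100) -> float:
    """One slice-sampling update on a bounded interval (shrinkage procedure)."""
    y = logp(current) - rng.exponential()
    left, right = lo, hi
    for _ in range(max_shrink):
        prop = rng.uniform(left, right)
        if logp(prop) >= y:
            return prop
        if prop < current:
            left = prop
        else:
            right = prop
    return current


def _run_chain(rng, x, y, eig_u, eig_d, cfg: MCMCConfig, priors: Priors):
    """One partially collapsed Gibbs chain on the standardized scale.

    Sweep order: (1) liability l given everything; (2) mu_theta, sigma_eta,
    sigma_A from the marginal with the additive effects integrated out —
    the marginal covariance sigma_A^2 D + sigma_eta^2 I is diagonal in the
    eigenbasis of A, so these collapsed updates are O(n); (3) exact joint
    redraw of the additive effects. Collapsing removes the mu <-> mean(a)
    and sigma_A <-> a posterior couplings that throttle plain Gibbs mixing
    in small-family designs.
    """
    n = x.size
    fixed_sa = cfg.sigma_a_fixed
    # standardized prior hyperparameters are supplied by the caller via `priors`
    m0, s0 = priors.mu_mean, priors.mu_sd
    ua, ue = priors.sigma_a_upper, priors.sigma_eta_upper

    eig_d = np.maximum(eig_d, 0.0)
    pos_d = eig_d > 1e-10  # eigenvalue support of the relatedness matrix
    v = eig_u.T @ np.ones(n) if n else np.zeros(0)  # rotated intercept column

    # overdispersed chain starts
    mu = m0 if n == 0 else float(np.mean(x)) + rng.normal(0.0, 0.5)
    var_e = float(rng.uniform(0.5, 1.5))
    var_a = fixed_sa**2 if fixed_sa is not None else float(rng.uniform(0.1, 1.0))
    a = np.zeros(n)
    sd_floor = np.sqrt(_VAR_FLOOR)

    draws_mu = np.empty(cfg.n_records)
    draws_sa = np.empty(cfg.n_records)
    draws_se = np.empty(cfg.n_records)
    draws_a = np.empty((cfg.n_records, n))
    draws_eta = np.empty((cfg.n_records, n))

    positive = y == 1
    total = cfg.burn_in + cfg.n_records * cfg.thin
    rec = 0
    for it in range(total):
        if n:
            # liability l = eta - theta, sign-constrained by the observed status
            l = _sample_truncnorm(rng, x - mu - a, np.sqrt(var_e), positive)
            z = x - l  # Gaussian pseudo-data: z ~ N(mu + a, var_e I)
            w_tilde = eig_u.T @ z  # rotated data; marginal cov is diagonal here

            # mu_theta | z, sigmas with a integrated out
            s_diag = np.maximum(var_a * eig_d + var_e, _VAR_FLOOR)
            prec = float(np.sum(v * v / s_diag)) + 1.0 / s0**2
            mean = (float(np.sum(v * w_tilde / s_diag)) + m0 / s0**2) / prec
            mu = mean + rng.normal(0.0, 1.0 / np.sqrt(prec))

            # sigma_eta, sigma_A | z, mu with a integrated out (slice updates
            # of the diagonalized Gaussian marginal; uniform priors = bounds)
            r = w_tilde - mu * v

            def logp_se(sd: float, _r2=r * r) -> float:
                s = np.maximum(var_a * eig_d + sd * sd, _VAR_FLOOR)
                return -0.5 * float(np.sum(np.log(s) + _r2 / s))

            var_e = max(_slice_sample(rng, logp_se, np.sqrt(var_e), sd_floor, ue), sd_floor) ** 2
            if fixed_sa is None:

                def logp_sa(sd: float, _r2=r * r) -> float:
                    s = np.maximum(sd * sd * eig_d + var_e, _VAR_FLOOR)
                    return -0.5 * float(np.sum(np.log(s) + _r2 / s))

                var_a = _slice_sample(rng, logp_sa, np.sqrt(var_a), 0.0, ua) ** 2

            # exact joint additive-effect draw in the eigenbasis of A
            if var_a > 0:
                prior_var = var_a * eig_d
                with np.errstate(divide="ignore"):
                    post_var = np.where(
                        pos_d, 1.0 / (1.0 / var_e + 1.0 / np.maximum(prior_var, _VAR_FLOOR)), 0.0
                    )
                b = post_var / var_e * r + np.sqrt(post_var) * rng.standard_normal(n)
                b[~pos_d] = 0.0
                a = eig_u @ b
            else:
                a = np.zeros(n)
        else:
            # no data: conditionals collapse to the prior
            mu = m0 + s0 * rng.standard_normal()
            var_e = float(rng.uniform(0.0, ue)) ** 2
            var_a = fixed_sa**2 if fixed_sa is not None else float(rng.uniform(0.0, ua)) ** 2
            l = np.zeros(0)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == cfg.thin - 1:
            draws_mu[rec] = mu
            draws_sa[rec] = np.sqrt(var_a)
            draws_se[rec] = np.sqrt(var_e)
            draws_a[rec] = a
            draws_eta[rec] = l + mu + a  # eta = l + theta; sign(eta - theta) = Y
            rec += 1
    return draws_mu, draws_sa, draws_se, draws_a, draws_eta


def sample_posterior(
    cohort: pd.DataFrame, A: RelatednessMatrix, config: MCMCConfig | None = None
) -> LETMPosterior:
    """Draw from the joint posterior of the threshold model.

    Parameters
    ----------
    cohort : DataFrame
        Phenotype records (individual_id, family_id, environment_id, sex, X,
        Y); only male records with known status are used.
    A : RelatednessMatrix
        Additive relationship matrix covering every cohort individual (it may
        also contain parents; it is restricted internally).
    config : MCMCConfig, optional
        Chains, run length, seed, priors. Fixed seed gives bit-identical
        draws.

    Returns
    -------
    LETMPosterior
        Recorded post-burn-in draws per chain, back-transformed to grams.
    """
    cfg = config or MCMCConfig()
    males = validate_cohort(cohort)
    ids = males["individual_id"].astype(str).tolist()
    x_raw = males["X"].to_numpy(dtype=float)
    y = males["Y"].to_numpy(dtype=int)
    n = len(ids)

    missing = sorted(set(ids) - set(A.ids))
    if missing:
        raise ValueError(f"cohort/pedigree id mismatch: not in relatedness matrix: {missing}")

    if n and (y.min() == y.max()):
        warnings.warn(
            "all individuals share one status; the mean threshold is only "
            "bounded by its prior",
            UserWarning,
            stacklevel=2,
        )
    if n == 0:
        warnings.warn("empty cohort: sampling from the prior", UserWarning, stacklevel=2)

    if n:
        a_sub = A.restrict(ids).values
        eig_d, eig_u = np.linalg.eigh(a_sub)
        if eig_d.min() < -1e-8 * max(eig_d.max(), 1.0):
            raise ValueError("relatedness matrix is not positive semi-definite")
        eig_d = np.clip(eig_d, 0.0, None)
    else:
        eig_d, eig_u = np.zeros(0), np.zeros((0, 0))

    priors_g = cfg.priors.resolve(x_raw)  # gram scale
    # standardize X; priors and fixed values move to the standardized scale
    if n >= 2 and np.std(x_raw) > 0:
        x_loc, x_scale = float(np.mean(x_raw)), float(np.std(x_raw))
    else:
        x_loc, x_scale = 0.0, 1.0
    x = (x_raw - x_loc) / x_scale
    priors_s = Priors(
        mu_mean=(priors_g.mu_mean - x_loc) / x_scale,
        mu_sd=priors_g.mu_sd / x_scale,
        sigma_a_upper=priors_g.sigma_a_upper / x_scale,
        sigma_eta_upper=priors_g.sigma_eta_upper / x_scale,
    )
    cfg_s = cfg
    if cfg.sigma_a_fixed is not None:
        cfg_s = replace(cfg, sigma_a_fixed=cfg.sigma_a_fixed / x_scale)

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    per_chain = [
        _run_chain(np.random.default_rng(s), x, y, eig_u, eig_d, cfg_s, priors_s) for s in seeds
    ]

    mu = np.stack([x_loc + x_scale * c[0] for c in per_chain])
    sa = np.stack([x_scale * c[1] for c in per_chain])
    se = np.stack([x_scale * c[2] for c in per_chain])
    a = np.stack([x_scale * c[3] for c in per_chain])
    eta = np.stack([x_loc + x_scale * c[4] for c in per_chain])
    return LETMPosterior(ids=ids, mu_theta=mu, sigma_a=sa, sigma_eta=se, a=a, eta=eta)


def gelman_rubin(posterior: LETMPosterior, parameter: str) -> float:
    """Potential scale reduction factor (split R-hat) for a scalar parameter.

    Values near 1 indicate the chains agree; values well above 1 flag
    nonconvergence. Returns NaN (with a warning) for degenerate
    constant chains, where the statistic is undefined.
    """
    draws = posterior.parameter(parameter)
    if draws.shape[0] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if draws.shape[1] < 10:
        raise ValueError("R-hat requires at least 10 draws per chain")
    if np.ptp(draws) == 0:
        warnings.warn(
            f"R-hat undefined for constant draws of {parameter!r}", UserWarning, stacklevel=2
        )
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(az.convert_to_dataset({parameter: draws}), method="split")[parameter])


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing `prob` of the draws (highest posterior density)."""
    flat = np.asarray(draws, dtype=float).reshape(-1)
    if flat.size < 2 or np.ptp(flat) == 0:
        c = float(flat[0])
        return (c, c)
    lo, hi = np.asarray(az.hdi(flat, hdi_prob=prob)).reshape(-1)
    return float(lo), float(hi)


def posterior_summary(posterior: LETMPosterior, prob: float = 0.95) -> pd.DataFrame:
    """Median and HPD interval for mu_theta, sigma_a, sigma_eta and H^2.

    The HPD is the narrowest interval containing `prob` of the pooled draws;
    medians pool all chains (invariant to chain concatenation order).
    """
    total = posterior.n_chains * posterior.n_draws
    if total < 40:
        raise ValueError(f"too few draws for a {prob:.0%} interval: {total} < 40")
    rows = []
    for name in SCALAR_PARAMETERS:
        flat = posterior.stacked(name)
        lo, hi = hpd_interval(flat, prob)
        rows.append(
            {
                "parameter": name,
                "median": float(np.median(flat)),
                "hpd_lower": lo,
                "hpd_upper": hi,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
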