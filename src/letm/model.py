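"""Mathematical core of the latent environmental threshold model.

The dichotomous phenotype is Y_i = 1{eta_i > theta_i}: the alternative tactic
is expressed when the proximate cue exceeds the individual threshold. The cue
is latent, tied to the observable proxy X_i by eta_i ~ Normal(X_i,
sigma_eta^2); the threshold decomposes as theta_i = mu_theta + a_i with
a ~ MVN(0, sigma_A^2 * A). All quantities live on the scale of the observable
cue (grams of spring body weight).

Composing the three pieces at a fixed cue value x gives the closed-form
maturation reaction norm

    p(x) = Phi((x - mu_theta) / sqrt(sigma_eta^2 + sigma_A^2)),

the probability that a male with observed cue x expresses the tactic. The
liability-scale heritability is H^2 = sigma_A^2 / (sigma_A^2 + sigma_eta^2):
the share of latent-scale variance attributable to additive threshold
variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class LETMParameters:
    """Population-level model parameters, on the observable-cue scale (grams).

    Attributes
    ----------
    mu_theta : float
        Population mean threshold.
    sigma_a : float
        Additive genetic standard deviation of thresholds (>= 0).
    sigma_eta : float
        Residual standard deviation of the latent cue around the observable
        proxy (> 0).
    """

    mu_theta: float
    sigma_a: float
    sigma_eta: float

    def __post_init__(self) -> None:
        if not self.sigma_a >= 0:
            raise ValueError(f"sigma_a must be >= 0, got {self.sigma_a}")
        if not self.sigma_eta > 0:
            raise ValueError(f"sigma_eta must be > 0, got {self.sigma_eta}")

    @property
    def heritability(self) -> float:
        return heritability(self.sigma_a, self.sigma_eta)


@dataclass(frozen=True)
class LatentState:
    """Per-individual latent quantities: cue eta, additive effect a, threshold theta."""

    eta: np.ndarray
    a: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.eta) == len(self.a) == len(self.theta)):
            raise ValueError("eta, a, theta must have equal length")


#: columns required of a cohort phenotype table
COHORT_COLUMNS = ["individual_id", "family_id", "environment_id", "sex", "X", "Y"]


def validate_cohort(frame: pd.DataFrame, males_only: bool = True) -> pd.DataFrame:
    """Check a cohort phenotype table and return the analyzable male records.

    Requires columns individual_id, family_id, environment_id, sex, X, Y;
    X strictly positive, Y in {0, 1}. Status is only defined for males, so
    with ``males_only`` the returned frame is restricted to sex == 'M'.
    """
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    out = frame.copy()
    if males_only:
        out = out[out["sex"].astype(str).str.upper().str.startswith("M")].copy()
    out["X"] = out["X"].astype(float)
    out["Y"] = out["Y"].astype(int)
    if (out["X"] <= 0).any():
        bad = out.loc[out["X"] <= 0, "individual_id"].tolist()
        raise ValueError(f"non-positive cue X for individuals {bad}")
    if not out["Y"].isin([0, 1]).all():
        raise ValueError("status Y must be 0 (immature) or 1 (mature)")
    if out["individual_id"].duplicated().any():
        dup = out.loc[out["individual_id"].duplicated(), "individual_id"].tolist()
        raise ValueError(f"duplicate individual ids in cohort: {dup}")
    return out.reset_index(drop=True)


def classify(eta, theta):
    """Tactic from cue vs threshold: 1 iff eta > theta, else 0.

    The tie eta == theta is classified 0 (immature); the event has measure
    zero under the continuous model so the convention is inconsequential.
    Accepts scalars or arrays (broadcast).
    """
    eta = np.asarray(eta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(eta)) and np.all(np.isfinite(theta))):
        raise ValueError("classify requires finite cue and threshold values")
    out = (eta > theta).astype(int)
    return int(out) if out.ndim == 0 else out


def liability_logdensity(eta, x, sigma_eta: float):
    """Log density of the latent cue given the observable proxy.

    log Normal(eta; mean x, sd sigma_eta), vectorized over eta and x.
    """
    if not sigma_eta > 0:
        raise ValueError(f"sigma_eta must be > 0, got {sigma_eta}")
    eta = np.asarray(eta, dtype=float)
    x = np.asarray(x, dtype=float)
    z = (eta - x) / sigma_eta
    out = -0.5 * z * z - np.log(sigma_eta) - 0.5 * _LOG_2PI
    return float(out) if out.ndim == 0 else out


def heritability(sigma_a, sigma_eta):
    """Liability-scale heritability H^2 = sigma_A^2 / (sigma_A^2 + sigma_eta^2).

    Additive threshold variance over total latent-scale variance. Vectorized;
    scale-invariant (multiplying both sds by c > 0 leaves H^2 unchanged).
    """
    sigma_a = np.asarray(sigma_a, dtype=float)
    sigma_eta = np.asarray(sigma_eta, dtype=float)
    if np.any(sigma_a < 0) or np.any(sigma_eta < 0):
        raise ValueError("standard deviations must be non-negative")
    va, ve = sigma_a**2, sigma_eta**2
    total = va + ve
    if np.any(total == 0):
        raise ValueError("heritability undefined when both variances are zero")
    out = va / total
    return float(out) if out.ndim == 0 else out


def reaction_norm(
    params: LETMParameters,
    x_grid,
    family_offset: float = 0.0,
    within_family: bool = False,
):
    """Probability of expressing the tactic as a function of the observable cue.

    p(x) = Phi((x - (mu_theta + family_offset)) / sqrt(sigma_eta^2 + V_theta))

    where V_theta is the threshold variance around the curve's centre:
    the full additive variance sigma_A^2 for a population-level curve, or the
    within-full-sib-family segregation variance sigma_A^2 / 2 when the curve
    is conditioned on a family's mean additive effect (``within_family``).

    Parameters
    ----------
    params : LETMParameters
    x_grid : array-like
        Cue values (grams); must be finite and non-empty.
    family_offset : float
        Mean additive effect of the family the curve conditions on; 0 for the
        population-level norm.
    within_family : bool
        Use sigma_A^2 / 2 as residual threshold variance (full-sib family
        conditional curve).

    Returns
    -------
    ndarray
        p(x) over the grid; a proper CDF in x (non-decreasing, limits 0 and 1).
    """
    x = np.atleast_1d(np.asarray(x_grid, dtype=float))
    if x.size == 0:
        raise ValueError("empty cue grid")
    if not np.all(np.isfinite(x)):
        raise ValueError("cue grid must be finite")
    v_theta = params.sigma_a**2 * (0.5 if within_family else 1.0)
    scale = float(np.sqrt(params.sigma_eta**2 + v_theta))
    return ndtr((x - (params.mu_theta + family_offset)) / scale)
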