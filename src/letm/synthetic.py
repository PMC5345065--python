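"""Synthetic cohorts with the crossing-design structure the analysis assumes.

The generator emulates a split-family salmon crossing experiment: each of two
wild-caught dams is crossed with one anadromous sire and one mature-parr
sire, giving four full-sib families nested in two maternal half-sib arrays;
offspring of every family are reared in two contrasting channel reaches
(environments) that differ in growth, hence in the observable cue
distribution. Generation follows the model's own equations in the forward
direction — a ~ MVN(0, sigma_A^2 A) via Cholesky, theta = mu_theta +
sire_shift + a, eta ~ Normal(X, sigma_eta^2), Y = 1{eta > theta} — so the
hidden truth is available for recovery testing.

Spring weight is log-normal within each environment by default (weights are
positive and right-skewed); a normal option exists for tests that need exact
closed forms. The generator emits the final analyzed cohort directly; field
mortality and trap removal are not simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from letm.model import classify
from letm.pedigree import (
    PedigreeTable,
    RelatednessMatrix,
    build_additive_relationship,
    validate_pedigree,
)

ANADROMOUS = "anadromous"
MATURE_PARR = "mature_parr"


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameter set: design, cue model, and threshold genetics.

    Attributes
    ----------
    dams : tuple of str
    sires : tuple of (sire_id, dam_id, sire_type)
        One family per entry; sire_type in {anadromous, mature_parr}.
    environments : tuple of str
    n_males : int
        Male offspring per family x environment cell.
    cue_mean, cue_sd : dict
        Per-environment mean and sd of spring weight X (grams, on the
        natural scale even when the cue is log-normal).
    cue_distribution : 'lognormal' or 'normal'
    mu_theta : float
        Population mean threshold (grams).
    sigma_a : float
        Additive genetic sd of thresholds (grams).
    sigma_eta : float
        Residual sd of the latent cue around X (grams).
    sire_shift : dict
        Threshold shift (grams) added to the offspring of each sire type,
        mimicking the lower maturation threshold transmitted by mature-parr
        sires. Keys are sire types; missing keys shift by 0.
    seed : int
    """

    dams: tuple[str, ...] = ("F2", "F3")
    sires: tuple[tuple[str, str, str], ...] = (
        ("MM2", "F2", ANADROMOUS),
        ("MP4", "F2", MATURE_PARR),
        ("MM3", "F3", ANADROMOUS),
        ("MP3", "F3", MATURE_PARR),
    )
    environments: tuple[str, ...] = ("upstream", "downstream")
    n_males: int = 80
    cue_mean: dict = field(default_factory=lambda: {"upstream": 4.0, "downstream": 4.93})
    cue_sd: dict = field(default_factory=lambda: {"upstream": 1.0, "downstream": 1.1})
    cue_distribution: str = "lognormal"
    mu_theta: float = 5.0
    sigma_a: float = 1.5
    sigma_eta: float = 0.5
    sire_shift: dict = field(default_factory=lambda: {MATURE_PARR: -2.5})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males <= 0:
            raise ValueError("n_males must be positive")
        if self.sigma_a < 0 or self.sigma_eta <= 0:
            raise ValueError("sigma_a must be >= 0 and sigma_eta > 0")
        dams = set(self.dams)
        for sire_id, dam_id, stype in self.sires:
            if dam_id not in dams:
                raise ValueError(f"sire {sire_id} crossed with unknown dam {dam_id}")
            if stype not in (ANADROMOUS, MATURE_PARR):
                raise ValueError(f"unknown sire type {stype!r}")
        for env in self.environments:
            if env not in self.cue_mean or env not in self.cue_sd:
                raise ValueError(f"cue parameters missing for environment {env!r}")
            if self.cue_sd[env] <= 0 or self.cue_mean[env] <= 0:
                raise ValueError("cue means and sds must be positive")
        if self.cue_distribution not in ("lognormal", "normal"):
            raise ValueError("cue_distribution must be 'lognormal' or 'normal'")

    @property
    def families(self) -> list[tuple[str, str, str, str]]:
        """(family_id, dam, sire, sire_type), family_id = '<dam>x<sire>'."""
        return [(f"{dam}x{sire}", dam, sire, stype) for sire, dam, stype in self.sires]

    @property
    def heritability(self) -> float:
        va, ve = self.sigma_a**2, self.sigma_eta**2
        return va / (va + ve)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list) + "\n")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated records plus the hidden truth retained for oracle tests."""

    phenotypes: pd.DataFrame
    pedigree: PedigreeTable
    relatedness: RelatednessMatrix
    truth: SyntheticTruth
    latent: pd.DataFrame  # individual_id, a, theta, eta

    def write(self, outdir: str | Path, sep: str = "\t") -> dict[str, Path]:
        """Write phenotype/pedigree tables and the truth sidecar; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "phenotypes": outdir / "phenotypes.tsv",
            "pedigree": outdir / "pedigree.tsv",
            "truth": outdir / "truth.json",
            "latent": outdir / "latent_truth.tsv",
        }
        self.phenotypes.to_csv(paths["phenotypes"], sep=sep, index=False)
        self.pedigree.to_frame().to_csv(paths["pedigree"], sep=sep, index=False)
        self.truth.to_json(paths["truth"])
        self.latent.to_csv(paths["latent"], sep=sep, index=False)
        return paths


def make_crossing_design(
    n_males: int = 80,
    mu_theta: float = 5.0,
    h2: float = 0.9,
    sigma_eta: float | None = None,
    sire_shift: float = -2.5,
    seed: int = 0,
    cue_distribution: str = "lognormal",
) -> SyntheticTruth:
    """Default truth for the 2-dam x 4-sire, 2-environment crossing design.

    Two dams each crossed with one anadromous and one mature-parr sire (4
    full-sib families in 2 maternal half-sib arrays), `n_males` male
    offspring per family x environment. The downstream reach grows ~0.93 g
    heavier than upstream. Threshold genetics are parameterized by the
    liability-scale heritability ``h2``: with sigma_eta fixed (default
    0.5 g), sigma_a = sigma_eta * sqrt(h2 / (1 - h2)). Mature-parr-sired
    families get their threshold shifted by ``sire_shift`` grams (negative:
    their offspring mature at smaller sizes).
    """
    if not 0 <= h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    s_eta = 0.5 if sigma_eta is None else sigma_eta
    s_a = s_eta * float(np.sqrt(h2 / (1.0 - h2)))
    return SyntheticTruth(
        n_males=n_males,
        mu_theta=mu_theta,
        sigma_a=s_a,
        sigma_eta=s_eta,
        sire_shift={MATURE_PARR: sire_shift},
        seed=seed,
        cue_distribution=cue_distribution,
    )


def _draw_cue(rng, mean: float, sd: float, size: int, distribution: str) -> np.ndarray:
    if distribution == "normal":
        return rng.normal(mean, sd, size)
    # log-normal parameterized by its natural-scale mean and sd
    s2 = np.log1p((sd / mean) ** 2)
    return rng.lognormal(np.log(mean) - 0.5 * s2, np.sqrt(s2), size)


def simulate_cohort(truth: SyntheticTruth) -> SyntheticCohort:
    """Generate one cohort from the model's equations in the forward direction.

    Builds the design pedigree (founder parents + male offspring), draws
    a ~ MVN(0, sigma_A^2 A) for the whole pedigree via Cholesky, assigns
    thresholds theta = mu_theta + sire_shift + a, draws the observable cue X
    per environment and the latent cue eta ~ Normal(X, sigma_eta^2), and
    classifies Y = 1{eta > theta}. Seeded and reproducible.
    """
    rng = np.random.default_rng(truth.seed)
    families = truth.families

    records = [(d, "0", "0") for d in truth.dams]
    records += [(s, "0", "0") for s, _, _ in truth.sires]
    offspring: list[tuple[str, str, str, str, str]] = []  # id, dam, sire, family, env
    for fam_id, dam, sire, _stype in families:
        for env in truth.environments:
            for k in range(truth.n_males):
                oid = f"{fam_id}_{env}_{k:03d}"
                records.append((oid, dam, sire))
                offspring.append((oid, dam, sire, fam_id, env))
    ped = validate_pedigree(records)
    rel = build_additive_relationship(ped)

    # additive effects for the whole pedigree: a = sigma_A * L z, A = L L^T
    n_all = len(ped.ids)
    if truth.sigma_a > 0:
        chol = np.linalg.cholesky(rel.values + 1e-10 * np.eye(n_all))
        a_all = truth.sigma_a * (chol @ rng.standard_normal(n_all))
    else:
        a_all = np.zeros(n_all)
    a_by_id = dict(zip(ped.ids, a_all))

    shift_by_family = {
        fam_id: float(truth.sire_shift.get(stype, 0.0)) for fam_id, _, _, stype in families
    }
    stype_by_family = {fam_id: stype for fam_id, _, _, stype in families}

    rows, latent_rows = [], []
    for env in truth.environments:  # draw X per environment for exchangeability
        env_offspring = [o for o in offspring if o[4] == env]
        x_env = _draw_cue(
            rng,
            truth.cue_mean[env],
            truth.cue_sd[env],
            len(env_offspring),
            truth.cue_distribution,
        )
        eta_env = x_env + truth.sigma_eta * rng.standard_normal(len(env_offspring))
        for (oid, _dam, _sire, fam_id, _env), x_i, eta_i in zip(env_offspring, x_env, eta_env):
            a_i = float(a_by_id[oid])
            theta_i = truth.mu_theta + shift_by_family[fam_id] + a_i
            y_i = classify(eta_i, theta_i)
            rows.append(
                {
                    "individual_id": oid,
                    "family_id": fam_id,
                    "environment_id": env,
                    "sex": "M",
                    "sire_type": stype_by_family[fam_id],
                    "X": float(x_i),
                    "Y": int(y_i),
                }
            )
            latent_rows.append(
                {"individual_id": oid, "a": a_i, "theta": float(theta_i), "eta": float(eta_i)}
            )

    phen = pd.DataFrame(rows).sort_values("individual_id", ignore_index=True)
    latent = pd.DataFrame(latent_rows).sort_values("individual_id", ignore_index=True)
    return SyntheticCohort(
        phenotypes=phen, pedigree=ped, relatedness=rel, truth=truth, latent=latent
    )
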