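"""Pipeline orchestration and publication-style outputs.

Stages: simulate (synthetic cohort to disk), fit (posterior draws), summarize
(median + 95% HPD for mu_theta, sigma_a, sigma_eta, H^2), norms (per family x
environment: cue histogram, pooled posterior threshold draws, and the
maturation reaction norm with a pointwise 95% credibility band), plus
incidence tables. Every stage persists delimited tables; a JSON manifest
records seeds, package version and a content hash per artifact so any report
number can be recomputed from the persisted draw files. Plots are optional
and headless-safe; every figure is backed by an exported grid.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import letm
from letm.cohort import incidence_table
from letm.inference import (
    LETMPosterior,
    MCMCConfig,
    SCALAR_PARAMETERS,
    gelman_rubin,
    hpd_interval,
    posterior_summary,
    sample_posterior,
)
from letm.model import validate_cohort
from letm.pedigree import build_additive_relationship, read_pedigree
from letm.synthetic import SyntheticTruth, make_crossing_design, simulate_cohort

_FLOAT_FMT = "%.17g"  # shortest-exact is version-dependent; fix a round-trippable format


class StageError(RuntimeError):
    """Pipeline failure carrying the identity of the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see CLI for the file format)."""

    outdir: Path
    seed: int = 0
    truth: SyntheticTruth | None = None
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    phenotype_path: Path | None = None
    pedigree_path: Path | None = None
    grouping: tuple[str, ...] = ("family_id", "environment_id")
    grid_points: int = 101
    plot: bool = False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, seeds: dict, extra: dict | None = None) -> Path:
    """List every artifact in `outdir` with a sha256 content hash."""
    outdir = Path(outdir)
    files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "letm",
        "version": letm.__version__,
        "seeds": seeds,
        "artifacts": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------- persistence


def save_posterior(posterior: LETMPosterior, outdir: str | Path) -> dict[str, Path]:
    """Write draws: scalars in long format, latent states as wide tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scalars": outdir / "draws_scalars.tsv",
        "a": outdir / "draws_a.tsv",
        "eta": outdir / "draws_eta.tsv",
    }
    posterior.to_frame().to_csv(paths["scalars"], sep="\t", index=False, float_format=_FLOAT_FMT)
    for key in ("a", "eta"):
        arr = getattr(posterior, key)
        c, d, n = arr.shape
        frame = pd.DataFrame(arr.reshape(c * d, n), columns=posterior.ids)
        frame.insert(0, "chain", np.repeat(np.arange(c), d))
        frame.insert(1, "iteration", np.tile(np.arange(d), c))
        frame.to_csv(paths[key], sep="\t", index=False, float_format=_FLOAT_FMT)
    return paths


def load_posterior(outdir: str | Path) -> LETMPosterior:
    """Rebuild an LETMPosterior from files written by :func:`save_posterior`."""
    outdir = Path(outdir)
    scalars = pd.read_csv(outdir / "draws_scalars.tsv", sep="\t", float_precision="round_trip")
    wide = {}
    for key in ("a", "eta"):
        frame = pd.read_csv(outdir / f"draws_{key}.tsv", sep="\t", float_precision="round_trip")
        chains = int(frame["chain"].max()) + 1
        draws = int(frame["iteration"].max()) + 1
        ids = [c for c in frame.columns if c not in ("chain", "iteration")]
        wide[key] = frame[ids].to_numpy().reshape(chains, draws, len(ids))
    per_param = {}
    for name in SCALAR_PARAMETERS:
        sub = scalars[scalars["parameter"] == name]
        chains = int(sub["chain"].max()) + 1
        per_param[name] = sub.sort_values(["chain", "iteration"])["value"].to_numpy().reshape(
            chains, -1
        )
    return LETMPosterior(
        ids=ids,
        mu_theta=per_param["mu_theta"],
        sigma_a=per_param["sigma_a"],
        sigma_eta=per_param["sigma_eta"],
        a=wide["a"],
        eta=wide["eta"],
    )


def summarize_posterior(posterior: LETMPosterior, outdir: str | Path) -> dict:
    """Posterior summary (median + 95% HPD) and convergence report as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = posterior_summary(posterior)
    report = {
        "parameters": {
            name: {
                "median": table.loc[name, "median"],
                "hpd95_lower": table.loc[name, "hpd_lower"],
                "hpd95_upper": table.loc[name, "hpd_upper"],
            }
            for name in table.index
        }
    }
    if posterior.n_chains >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report["rhat"] = {
                name: gelman_rubin(posterior, name) for name in SCALAR_PARAMETERS
            }
    (outdir / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


# ------------------------------------------------------------- reaction norms


def reaction_norm_draws(
    posterior: LETMPosterior,
    x_grid: np.ndarray,
    member_ids: list[str] | None = None,
) -> np.ndarray:
    """Per-draw reaction-norm curves p(x), shape (n_total_draws, len(grid)).

    Population-level curves use the full additive variance; family-conditional
    curves (``member_ids`` given) centre each draw's curve on that draw's mean
    additive effect over the family members and keep the within-full-sib
    segregation variance sigma_A^2 / 2 around it.
    """
    from scipy.special import ndtr

    mu = posterior.mu_theta.reshape(-1)
    sa = posterior.sigma_a.reshape(-1)
    se = posterior.sigma_eta.reshape(-1)
    if member_ids is None:
        centre = mu
        v_theta = sa**2
    else:
        pos = {i: k for k, i in enumerate(posterior.ids)}
        idx = [pos[str(i)] for i in member_ids]
        offsets = posterior.a[:, :, idx].mean(axis=2).reshape(-1)
        centre = mu + offsets
        v_theta = 0.5 * sa**2
    scale = np.sqrt(se**2 + v_theta)
    return ndtr((x_grid[None, :] - centre[:, None]) / scale[:, None])


def render_reaction_norm_report(
    posterior: LETMPosterior,
    cohort: pd.DataFrame,
    outdir: str | Path,
    grid_points: int = 101,
    plot: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per family x environment: cue histogram, threshold density, reaction norm.

    Writes three delimited tables. The reaction-norm band is the pointwise
    2.5/97.5% quantile of the curve over posterior draws; threshold densities
    are summaries of the pooled posterior draws of the family members'
    individual thresholds theta_i.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    males = validate_cohort(cohort)
    known = set(posterior.ids)
    missing_fams = sorted(
        str(f)
        for f, grp in males.groupby("family_id")
        if not set(grp["individual_id"].astype(str)) & known
    )
    if missing_fams:
        raise KeyError(f"families absent from posterior: {missing_fams}")

    x_all = males["X"].to_numpy(dtype=float)
    grid = np.linspace(0.0, float(x_all.max()) * 1.3, grid_points)
    bins = np.histogram_bin_edges(x_all, bins=20)

    norm_rows, hist_rows, theta_rows = [], [], []
    for (fam, env), grp in males.groupby(["family_id", "environment_id"], sort=True):
        ids = [i for i in grp["individual_id"].astype(str) if i in known]
        curves = reaction_norm_draws(posterior, grid, member_ids=ids)
        med = np.median(curves, axis=0)
        lo, hi = np.quantile(curves, [0.025, 0.975], axis=0)
        norm_rows.append(
            pd.DataFrame(
                {
                    "family_id": str(fam),
                    "environment_id": str(env),
                    "x": grid,
                    "p": med,
                    "lower95": lo,
                    "upper95": hi,
                }
            )
        )
        counts, _ = np.histogram(grp["X"].to_numpy(dtype=float), bins=bins)
        hist_rows.append(
            pd.DataFrame(
                {
                    "family_id": str(fam),
                    "environment_id": str(env),
                    "bin_left": bins[:-1],
                    "bin_right": bins[1:],
                    "count": counts,
                }
            )
        )
        theta = posterior.theta_draws_for(ids)
        t_lo, t_hi = hpd_interval(theta)
        theta_rows.append(
            {
                "family_id": str(fam),
                "environment_id": str(env),
                "theta_median": float(np.median(theta)),
                "theta_hpd95_lower": t_lo,
                "theta_hpd95_upper": t_hi,
                "theta_sd": float(np.std(theta)),
            }
        )

    tables = {
        "reaction_norms": pd.concat(norm_rows, ignore_index=True),
        "cue_histograms": pd.concat(hist_rows, ignore_index=True),
        "threshold_summaries": pd.DataFrame(theta_rows),
    }
    for name, frame in tables.items():
        frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    if plot:
        _plot_reaction_norms(tables, males, outdir)
    return tables


def _plot_reaction_norms(tables: dict, males: pd.DataFrame, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    norms = tables["reaction_norms"]
    fams = sorted(norms["family_id"].unique())
    fig, axes = plt.subplots(1, len(fams), figsize=(4 * len(fams), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    colors = {"upstream": "#1f3d7a", "downstream": "#4dac8d"}
    for ax, fam in zip(axes, fams):
        for env, sub in norms[norms["family_id"] == fam].groupby("environment_id"):
            c = colors.get(str(env), None)
            ax.plot(sub["x"], sub["p"], color=c, label=str(env))
            ax.plot(sub["x"], sub["lower95"], ls="--", lw=0.8, color=c)
            ax.plot(sub["x"], sub["upper95"], ls="--", lw=0.8, color=c)
            xs = males.query("family_id == @fam and environment_id == @env")["X"]
            ax.hist(xs, bins=15, density=True, alpha=0.3, color=c)
        ax.set_title(fam)
        ax.set_xlabel("spring weight (g)")
    axes[0].set_ylabel("P(mature)")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(outdir / "reaction_norms.png", dpi=150)
    plt.close(fig)


# ------------------------------------------------------------------- pipeline


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> fit -> summarize -> norms -> incidence, with a manifest.

    When ``config.truth`` is set the cohort is simulated; otherwise phenotype
    and pedigree paths must point to existing delimited files. Returns the
    manifest dictionary. Errors carry the stage identity.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        if config.truth is not None:
            stage = "simulate"
            truth = config.truth
            cohort_obj = simulate_cohort(truth)
            cohort_obj.write(outdir / "data")
            phenotypes = cohort_obj.phenotypes
            rel = cohort_obj.relatedness
        else:
            stage = "load"
            if config.phenotype_path is None or config.pedigree_path is None:
                raise ValueError("need phenotype and pedigree paths when not simulating")
            phenotypes = pd.read_csv(config.phenotype_path, sep=None, engine="python")
            ped = read_pedigree(config.pedigree_path)
            rel = build_additive_relationship(ped)

        stage = "fit"
        posterior = sample_posterior(phenotypes, rel, config.mcmc)
        save_posterior(posterior, outdir / "posterior")

        stage = "summarize"
        summary = summarize_posterior(posterior, outdir)

        stage = "norms"
        render_reaction_norm_report(
            posterior, phenotypes, outdir / "norms", config.grid_points, config.plot
        )

        stage = "incidence"
        inc = incidence_table(phenotypes, config.grouping)
        inc.to_csv(outdir / "incidence.tsv", sep="\t", index=False)
        if "sire_type" in phenotypes.columns:
            incidence_table(phenotypes, "sire_type").to_csv(
                outdir / "incidence_by_sire_type.tsv", sep="\t", index=False
            )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage identity
        raise StageError(stage, str(exc)) from exc

    stage = "manifest"
    seeds = {"mcmc": config.mcmc.seed}
    if config.truth is not None:
        seeds["simulate"] = config.truth.seed
    write_manifest(outdir, seeds, extra={"summary": summary})
    return json.loads((outdir / "manifest.json").read_text())


def default_run_config(outdir: str | Path, seed: int = 0, **mcmc_kwargs) -> RunConfig:
    """Convenience: simulate the default crossing design and fit it."""
    mcmc = MCMCConfig(seed=seed, **mcmc_kwargs)
    return RunConfig(outdir=Path(outdir), seed=seed, truth=make_crossing_design(seed=seed), mcmc=mcmc)
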