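"""Pipeline orchestration, persistence round-trips and reaction-norm reports."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from letm.cli import main as cli_main
from letm.inference import MCMCConfig, sample_posterior
from letm.reporting import (
    RunConfig,
    StageError,
    load_posterior,
    render_reaction_norm_report,
    run_pipeline,
    save_posterior,
    summarize_posterior,
)
from letm.synthetic import make_crossing_design, simulate_cohort

FAST = MCMCConfig(n_chains=2, burn_in=200, n_records=60, thin=3, seed=1)


@pytest.fixture(scope="module")
def small_fit(tmp_path_factory):
    cohort = simulate_cohort(make_crossing_design(n_males=25, seed=8))
    posterior = sample_posterior(cohort.phenotypes, cohort.relatedness, FAST)
    return cohort, posterior


class TestPersistence:
    def test_posterior_roundtrip_exact(self, small_fit, tmp_path):
        _, posterior = small_fit
        save_posterior(posterior, tmp_path)
        back = load_posterior(tmp_path)
        np.testing.assert_array_equal(back.mu_theta, posterior.mu_theta)
        np.testing.assert_array_equal(back.sigma_eta, posterior.sigma_eta)
        np.testing.assert_array_equal(back.a, posterior.a)
        assert back.ids == posterior.ids

    def test_summarize_reproducible_from_saved_draws(self, small_fit, tmp_path):
        _, posterior = small_fit
        save_posterior(posterior, tmp_path)
        s1 = summarize_posterior(posterior, tmp_path / "r1")
        s2 = summarize_posterior(load_posterior(tmp_path), tmp_path / "r2")
        assert s1 == s2

    def test_rerun_same_seed_byte_identical_draw_files(self, tmp_path):
        cohort = simulate_cohort(make_crossing_design(n_males=10, seed=3))
        for d in ("a", "b"):
            post = sample_posterior(cohort.phenotypes, cohort.relatedness, FAST)
            save_posterior(post, tmp_path / d)
        for name in ("draws_scalars.tsv", "draws_a.tsv", "draws_eta.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


class TestReactionNormReport:
    def test_report_tables_and_band_contains_point_curve(self, small_fit, tmp_path):
        cohort, posterior = small_fit
        tables = render_reaction_norm_report(posterior, cohort.phenotypes, tmp_path)
        norms = tables["reaction_norms"]
        assert set(norms["family_id"]) == set(cohort.phenotypes["family_id"])
        assert ((norms["lower95"] <= norms["p"]) & (norms["p"] <= norms["upper95"])).all()
        # curves are proper probabilities, non-decreasing per group
        for _, sub in norms.groupby(["family_id", "environment_id"]):
            assert np.all(np.diff(sub["p"].to_numpy()) >= -1e-12)
        assert (tmp_path / "reaction_norms.tsv").exists()
        assert (tmp_path / "threshold_summaries.tsv").exists()
        assert (tmp_path / "cue_histograms.tsv").exists()

    def test_sire_shift_pattern(self, tmp_path):
        """With a strong mature-parr threshold shift: parr-sired families show
        lower median thresholds within each dam, and threshold estimates are
        nearly identical across environments within family."""
        cohort = simulate_cohort(make_crossing_design(n_males=60, seed=20))
        posterior = sample_posterior(
            cohort.phenotypes,
            cohort.relatedness,
            MCMCConfig(n_chains=2, burn_in=600, n_records=120, thin=5, seed=2),
        )
        tables = render_reaction_norm_report(posterior, cohort.phenotypes, tmp_path)
        th = tables["threshold_summaries"].set_index(["family_id", "environment_id"])
        med = th["theta_median"]
        fam_med = med.groupby("family_id").mean()
        sire_type = (
            cohort.phenotypes.drop_duplicates("family_id")
            .set_index("family_id")["sire_type"]
        )
        for dam in ("F2", "F3"):
            fams = [f for f in fam_med.index if f.startswith(dam)]
            parr = [f for f in fams if sire_type[f] == "mature_parr"]
            anad = [f for f in fams if sire_type[f] == "anadromous"]
            assert fam_med[parr[0]] < fam_med[anad[0]]
        # within family, environments agree (thresholds are genetic, not
        # environmental): gap small relative to the between-family spread
        spread = fam_med.max() - fam_med.min()
        for fam in fam_med.index:
            envs = med.loc[fam]
            assert abs(envs.iloc[0] - envs.iloc[1]) < 0.35 * spread

    def test_family_absent_from_posterior_raises(self, small_fit, tmp_path):
        cohort, posterior = small_fit
        extra = cohort.phenotypes.copy()
        extra.loc[len(extra)] = {
            "individual_id": "ghost",
            "family_id": "ghostfam",
            "environment_id": "upstream",
            "sex": "M",
            "sire_type": "anadromous",
            "X": 4.0,
            "Y": 0,
        }
        with pytest.raises(KeyError, match="ghostfam"):
            render_reaction_norm_report(posterior, extra, tmp_path)


class TestPipeline:
    def test_simulate_fit_summarize_smoke_and_manifest(self, tmp_path):
        config = RunConfig(
            outdir=tmp_path / "run",
            truth=make_crossing_design(n_males=15, seed=5),
            mcmc=FAST,
        )
        manifest = run_pipeline(config)
        assert manifest["seeds"] == {"mcmc": 1, "simulate": 5}
        listed = set(manifest["artifacts"])
        for expected in (
            "data/phenotypes.tsv",
            "posterior/draws_scalars.tsv",
            "summary.json",
            "norms/reaction_norms.tsv",
            "incidence.tsv",
        ):
            assert expected in listed
        # every listed artifact exists and hashes are well-formed
        for rel, digest in manifest["artifacts"].items():
            assert (tmp_path / "run" / rel).exists()
            assert len(digest) == 64

    def test_stage_identity_on_failure(self, tmp_path):
        config = RunConfig(outdir=tmp_path, phenotype_path=None, pedigree_path=None)
        with pytest.raises(StageError, match=r"\[stage load\]"):
            run_pipeline(config)

    def test_fit_stage_reports_id_mismatch(self, tmp_path):
        cohort = simulate_cohort(make_crossing_design(n_males=5, seed=9))
        paths = cohort.write(tmp_path / "data")
        phen = pd.read_csv(paths["phenotypes"], sep="\t")
        phen.loc[0, "individual_id"] = "rogue"
        phen.to_csv(paths["phenotypes"], sep="\t", index=False)
        config = RunConfig(
            outdir=tmp_path / "run",
            phenotype_path=paths["phenotypes"],
            pedigree_path=paths["pedigree"],
            mcmc=FAST,
        )
        with pytest.raises(StageError, match="rogue"):
            run_pipeline(config)


class TestCLI:
    def test_simulate_fit_summarize_commands(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        r = runner.invoke(
            cli_main, ["simulate", "--out", str(data), "--seed", "4", "--n-males", "10"]
        )
        assert r.exit_code == 0, r.output
        cfg = tmp_path / "mcmc.yaml"
        cfg.write_text("n_chains: 2\nburn_in: 150\nn_records: 50\nthin: 2\nseed: 3\n")
        run = tmp_path / "run"
        r = runner.invoke(
            cli_main,
            [
                "fit",
                "--phenotypes", str(data / "phenotypes.tsv"),
                "--pedigree", str(data / "pedigree.tsv"),
                "--out", str(run),
                "--config", str(cfg),
            ],
        )
        assert r.exit_code == 0, r.output
        summary = json.loads((run / "summary.json").read_text())
        assert set(summary["parameters"]) == {"mu_theta", "sigma_a", "sigma_eta", "h2"}
        r = runner.invoke(cli_main, ["summarize", "--run", str(run)])
        assert r.exit_code == 0 and "mu_theta" in r.output
        r = runner.invoke(
            cli_main,
            [
                "norms",
                "--run", str(run),
                "--phenotypes", str(data / "phenotypes.tsv"),
                "--out", str(tmp_path / "norms"),
            ],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "norms" / "reaction_norms.tsv").exists()

    def test_incidence_command(self, tmp_path):
        data = tmp_path / "data"
        simulate_cohort(make_crossing_design(n_males=10, seed=1)).write(data)
        runner = CliRunner()
        out = tmp_path / "inc.tsv"
        r = runner.invoke(
            cli_main,
            ["incidence", "--phenotypes", str(data / "phenotypes.tsv"),
             "--by", "sire_type", "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        table = pd.read_csv(out, sep="\t")
        assert set(table["sire_type"]) == {"anadromous", "mature_parr"}

    def test_match_command(self, tmp_path):
        cols = {"id": ["a", "b"]}
        for k in range(12):
            cols[f"L{k}_1"] = ["100", "200"]
            cols[f"L{k}_2"] = ["104", "204"]
        spring = pd.DataFrame(cols)
        fall = spring.copy()
        fall["id"] = ["x", "y"]
        fall.loc[1, "L0_1"] = "202"  # one allele off -> still a recapture
        spring.to_csv(tmp_path / "spring.tsv", sep="\t", index=False)
        fall.to_csv(tmp_path / "fall.tsv", sep="\t", index=False)
        runner = CliRunner()
        out = tmp_path / "matches.tsv"
        r = runner.invoke(
            cli_main,
            ["match", "--spring", str(tmp_path / "spring.tsv"),
             "--fall", str(tmp_path / "fall.tsv"), "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        pairs = pd.read_csv(out, sep="\t")
        assert len(pairs) == 2
        assert sorted(pairs["distance"]) == [0, 1]
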