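import subprocess

import numpy as np
import pandas as pd
import pytest

from snpmeth import (
    CohortDesign,
    SimulationParams,
    call_dms,
    compute_delta_beta,
    fit_two_group_moderated,
    generate_cohort,
    generate_methylation,
    probe_stats,
    region_distribution,
    sample_correlation,
)

from oracles import pearson_sum_formula


def _random_matrix(rng, n_probes, n_case, n_control):
    samples = [f"C{i}" for i in range(n_case)] + [f"K{i}" for i in range(n_control)]
    design = CohortDesign(samples, ["case"] * n_case + ["control"] * n_control)
    mat = pd.DataFrame(
        rng.uniform(0.05, 0.95, (n_probes, n_case + n_control)),
        index=[f"cg{i:05d}" for i in range(n_probes)],
        columns=samples,
    )
    return mat, design


class TestCorrelation:
    def test_duplicated_sample_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        mat, _ = _random_matrix(rng, 50, 3, 2)
        mat["K1"] = mat["C0"]
        corr, _ = sample_correlation(mat)
        assert corr.loc["C0", "K1"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_independent_noise_has_near_zero_offdiagonal(self):
        rng = np.random.default_rng(1)
        mat, _ = _random_matrix(rng, 1000, 5, 5)
        corr, _ = sample_correlation(mat)
        off = corr.to_numpy()[~np.eye(10, dtype=bool)]
        assert (np.abs(off) < 0.1).mean() >= 0.95

    def test_matches_sum_formula_oracle(self):
        rng = np.random.default_rng(2)
        mat, _ = _random_matrix(rng, 5, 2, 1)
        corr, _ = sample_correlation(mat)
        x, y = mat["C0"].to_numpy(), mat["K0"].to_numpy()
        assert corr.loc["C0", "K0"] == pytest.approx(pearson_sum_formula(x, y), abs=1e-12)

    def test_zero_variance_sample_flagged_not_nan_everywhere(self):
        rng = np.random.default_rng(3)
        mat, design = _random_matrix(rng, 20, 3, 2)
        mat["C1"] = 0.5
        corr, flagged = sample_correlation(mat, design)
        assert "C1" in flagged
        assert np.isfinite(corr.loc["C0", "K0"])


@pytest.fixture(scope="module")
def data():
    rng = np.random.default_rng(7)
    return _random_matrix(rng, 400, 11, 5)


class TestModeratedFit:
    def test_d0_zero_equals_classical_pooled_t(self, data):
        mat, design = data
        fit = fit_two_group_moderated(mat, design, d0_override=0)
        x1 = mat[design.case_samples].to_numpy()
        x2 = mat[design.control_samples].to_numpy()
        n1, n2 = x1.shape[1], x2.shape[1]
        s2 = (
            ((x1 - x1.mean(1, keepdims=True)) ** 2).sum(1)
            + ((x2 - x2.mean(1, keepdims=True)) ** 2).sum(1)
        ) / (n1 + n2 - 2)
        t_classic = (x1.mean(1) - x2.mean(1)) / np.sqrt(s2 * (1 / n1 + 1 / n2))
        assert np.abs(fit["t_mod"].to_numpy() - t_classic).max() < 1e-10

    def test_d0_infinite_uses_prior_variance_everywhere(self, data):
        mat, design = data
        fit = fit_two_group_moderated(mat, design, d0_override=np.inf)
        assert np.allclose(fit["s2_post"], fit["s0_2"].iloc[0])
        # with a common denominator, |t| ranks match |mean_diff| ranks
        r_t = fit["t_mod"].abs().rank()
        r_d = fit["mean_diff"].abs().rank()
        assert (r_t == r_d).all()

    def test_estimated_d0_between_limits(self, data):
        mat, design = data
        fit = fit_two_group_moderated(mat, design)
        d0 = fit["d0"].iloc[0]
        assert d0 > 0
        classic = fit_two_group_moderated(mat, design, d0_override=0)
        # shrinkage pulls the posterior variances towards s0^2
        spread_mod = np.log(fit["s2_post"]).std()
        spread_classic = np.log(classic["s2_post"]).std()
        assert spread_mod < spread_classic

    def test_zero_variance_probe_gets_finite_t(self):
        rng = np.random.default_rng(11)
        mat, design = _random_matrix(rng, 50, 4, 4)
        mat.iloc[0, :4] = 0.8
        mat.iloc[0, 4:] = 0.2
        fit = fit_two_group_moderated(mat, design)
        assert bool(fit["zero_variance"].iloc[0])
        assert np.isfinite(fit["t_mod"].iloc[0])

    def test_needs_two_samples_per_group(self):
        rng = np.random.default_rng(12)
        mat, _ = _random_matrix(rng, 10, 2, 1)
        design = CohortDesign(list(mat.columns), ["case", "case", "control"])
        with pytest.raises(ValueError):
            fit_two_group_moderated(mat, design)

    def test_matches_limma_oracle(self, tmp_path):
        """Independent cross-check of the empirical-Bayes fit against the
        reference R implementation on a small matrix."""
        rng = np.random.default_rng(19)
        mat, design = _random_matrix(rng, 60, 6, 4)
        mat.to_csv(tmp_path / "m.tsv", sep="\t")
        n1, n2 = 6, 4
        script = f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.table("{tmp_path}/m.tsv", sep="\\t", header=TRUE, row.names=1))
        design <- cbind(Intercept=1, Case=c(rep(1,{n1}), rep(0,{n2})))
        fit <- eBayes(lmFit(m, design))
        out <- data.frame(t=fit$t[,"Case"], p=fit$p.value[,"Case"], d0=fit$df.prior)
        write.table(out, "{tmp_path}/limma.tsv", sep="\\t", quote=FALSE)
        """
        (tmp_path / "s.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "s.R")], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        fit = fit_two_group_moderated(mat, design)
        assert fit["d0"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-9)
        assert np.abs(fit["t_mod"].to_numpy() - ref["t"].to_numpy()).max() < 1e-9
        assert np.abs(fit["p"].to_numpy() - ref["p"].to_numpy()).max() < 1e-9

    def test_null_calibration(self):
        """On null logit-normal data (11 vs 5), the p<0.01 fraction stays
        near nominal across seeds."""
        fracs = []
        for seed in range(5):
            params = SimulationParams(
                seed=seed, n_genes=50, n_probes=5000, meth_case_n=11, meth_control_n=5
            )
            _, _, truth = generate_cohort(params)
            mat, _, design = generate_methylation(params, truth)
            fit = fit_two_group_moderated(mat, design)
            fracs.append((fit["p"] < 0.01).mean())
        assert all(0.003 <= f <= 0.025 for f in fracs)


class TestDeltaBeta:
    def test_formula(self, two_group_design):
        design = two_group_design(1, 1)
        mat = pd.DataFrame([[0.6, 0.4]], index=["cg1"], columns=design.samples)
        delta = compute_delta_beta(mat, design)
        assert delta.loc["cg1", "delta_beta"] == pytest.approx(0.2, abs=1e-15)

    def test_identical_groups_zero_delta(self):
        rng = np.random.default_rng(23)
        mat, design = _random_matrix(rng, 30, 3, 3)
        mat[design.control_samples] = mat[design.case_samples].to_numpy()
        delta = compute_delta_beta(mat, design)
        assert np.abs(delta["delta_beta"]).max() == 0.0

    def test_identity_holds_exactly(self):
        rng = np.random.default_rng(29)
        mat, design = _random_matrix(rng, 200, 11, 5)
        stats_df = probe_stats(mat, design)
        resid = stats_df["delta_beta"] - (stats_df["beta_case"] - stats_df["beta_control"])
        assert (resid == 0.0).all()


class TestCallDMS:
    def test_thresholds_are_strict(self):
        stats_df = pd.DataFrame(
            {
                "delta_beta": [0.10, 0.100001, -0.3, 0.2],
                "p": [1e-5, 1e-5, 1e-4, 0.01],
            },
            index=["a", "b", "c", "d"],
        )
        dms = call_dms(stats_df)
        assert list(dms.index) == ["b", "c"]
        assert dms.loc["c", "direction"] == "hypo"

    def test_equals_brute_force_row_filter(self):
        rng = np.random.default_rng(31)
        mat, design = _random_matrix(rng, 500, 11, 5)
        stats_df = probe_stats(mat, design)
        dms = call_dms(stats_df, delta_min=0.05, p_max=0.2)
        expected = [
            probe
            for probe, row in stats_df.iterrows()
            if abs(row["delta_beta"]) > 0.05 and row["p"] < 0.2
        ]
        assert list(dms.index) == expected
        assert (dms["direction"] == "hyper").sum() + (dms["direction"] == "hypo").sum() == len(dms)

    def test_missing_manifest_probe_is_error(self):
        stats_df = pd.DataFrame({"delta_beta": [0.5], "p": [1e-6]}, index=["cgX"])
        manifest = pd.DataFrame(
            {"probe": ["cgY"], "chrom": ["chr1"], "pos": [1], "gene": ["G"],
             "feature": ["Body"], "island_relation": ["Island"]}
        )
        with pytest.raises(KeyError, match="cgX"):
            call_dms(stats_df, manifest)


class TestRegionDistribution:
    @pytest.fixture()
    def manifest(self):
        rng = np.random.default_rng(37)
        n = 200
        return pd.DataFrame(
            {
                "probe": [f"cg{i:05d}" for i in range(n)],
                "chrom": "chr1",
                "pos": np.arange(n) + 1,
                "gene": "G",
                "feature": rng.choice(["TSS200", "Body", "IGR"], n),
                "island_relation": rng.choice(["Island", "OpenSea"], n),
            }
        )

    def test_dms_equal_background_gives_unit_ratios(self, manifest):
        dms = pd.DataFrame(
            {"delta_beta": 0.5, "p": 1e-9, "direction": "hyper"},
            index=manifest["probe"],
        )
        dist = region_distribution(dms, manifest)
        all_rows = dist[dist["direction"] == "all"]
        assert np.allclose(all_rows["ratio"], 1.0)

    def test_empty_dms_no_division_error(self, manifest):
        dms = pd.DataFrame({"delta_beta": [], "p": [], "direction": []})
        dist = region_distribution(dms, manifest)
        assert (dist["n_dms"] == 0).all()

    def test_planted_island_tss_spikes_have_max_enrichment(self, manifest):
        target = manifest[(manifest.feature == "TSS200") & (manifest.island_relation == "Island")]
        dms = pd.DataFrame(
            {"delta_beta": 0.5, "p": 1e-9, "direction": "hyper"},
            index=target["probe"],
        )
        dist = region_distribution(dms, manifest)
        all_rows = dist[(dist["direction"] == "all") & (dist["n_dms"] > 0)]
        best = all_rows.loc[all_rows["ratio"].idxmax()]
        assert (best["island_relation"], best["feature"]) == ("Island", "TSS200")
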