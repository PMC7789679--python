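"""Mixed-model fold-change estimation: exact limits, invariances, oracles."""

import subprocess
import textwrap
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from secretoscope.containers import SampleDesign
from secretoscope.differential import (
    PeptideMixedModelDifferential,
    SignificanceRule,
    fit_protein,
    membership_table,
    run_differential,
    select_significant,
)
from secretoscope.normalize import normalize
from secretoscope.simulate import SimulationConfig, simulate_peptide_table

from conftest import make_design, make_table


def _noise_free_sim(effects):
    fc = {}
    for pid, val in effects.items():
        if val != 0:
            for cond in ("healthy", "traumatic", "degenerative", "IL1b"):
                fc[(pid, cond)] = val
    cfg = SimulationConfig(
        n_proteins=len(effects),
        noise_sd=0.0,
        donor_sd=0.0,
        missing_mcar_rate=0.0,
        missing_mnar_scale=0.0,
        true_log2fc=fc,
        seed=21,
    )
    return simulate_peptide_table(cfg)


class TestExactLimits:
    def test_noise_free_toy_recovered_to_1e6(self):
        table, design, _ = _noise_free_sim({"P0001": 0.0, "P0002": 1.0, "P0003": -1.0})
        effects = run_differential(table.log2(), design)
        for pid, val in [("P0001", 0.0), ("P0002", 1.0), ("P0003", -1.0)]:
            sub = effects[effects.protein == pid]
            np.testing.assert_allclose(sub["log2fc"], val, atol=1e-6)
        # zero-variance-of-effect protein: no evidence against 0
        assert (effects.loc[effects.protein == "P0001", "p"] == 1.0).all()
        assert (effects.loc[effects.protein == "P0002", "p"] < 1e-6).all()

    def test_constant_input_gives_zero_fc_p_one(self):
        design = make_design({"baseline": 3, "t": 3})
        table = make_table(
            {
                ("P1", "a"): {s: 7.0 for s in design.samples},
                ("P1", "b"): {s: 7.0 for s in design.samples},
            },
            log2=True,
        )
        eff = fit_protein(table.intensities, design)
        assert (eff["log2fc"] == 0).all()
        assert (eff["p"] == 1.0).all()


class TestInvariances:
    def test_sample_order_invariance(self, default_sim):
        _, table, design, _ = default_sim
        normed, _ = normalize(table.log2())
        eff1 = run_differential(normed, design)
        rng = np.random.default_rng(0)
        perm = rng.permutation(normed.sample_ids)
        shuffled = type(normed)(normed.intensities[list(perm)], is_log2=True)
        design2 = SampleDesign(design.frame.loc[list(perm)], design.reference)
        eff2 = run_differential(shuffled, design2)
        merged = eff1.merge(eff2, on=["protein", "condition"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["log2fc_a"], merged["log2fc_b"], atol=1e-8)

    def test_estimates_invariant_to_normalization_location(self, default_sim):
        _, table, design, _ = default_sim
        with_loc, _ = normalize(table.log2(), add_location=True)
        without, _ = normalize(table.log2(), add_location=False)
        e1 = run_differential(with_loc, design)
        e2 = run_differential(without, design)
        merged = e1.merge(e2, on=["protein", "condition"], suffixes=("_a", "_b"))
        # tolerance covers optimizer noise on flat boundary likelihoods
        # (inputs differ at float rounding); a genuine location leak would
        # scale with the pooled mean (~24 log2 units), orders larger
        np.testing.assert_allclose(merged["log2fc_a"], merged["log2fc_b"], atol=5e-3)
        assert (merged["fit_note_a"] == merged["fit_note_b"]).all()

    def test_contrast_antisymmetry_under_label_swap(self):
        cfg = SimulationConfig(
            n_proteins=3,
            conditions=("baseline", "treated"),
            batches={"batch1": ("baseline", "treated")},
            true_log2fc={("P0001", "treated"): 1.5},
            seed=4,
        )
        table, design, _ = simulate_peptide_table(cfg)
        eff = run_differential(table.log2(), design)
        swapped = SampleDesign(
            design.frame.assign(
                condition=design.frame.condition.map(
                    {"baseline": "treated", "treated": "baseline"}
                )
            ),
            reference="baseline",
        )
        eff_swapped = run_differential(table.log2(), swapped)
        merged = eff.merge(eff_swapped, on="protein", suffixes=("_a", "_b"))
        np.testing.assert_allclose(
            merged["log2fc_a"], -merged["log2fc_b"], atol=1e-6
        )


class TestStochasticRecovery:
    def test_estimate_within_two_se_of_truth(self):
        # protein with 6 peptides, 12 donors, true effect +2.0
        hits = 0
        n_reps = 50
        for rep in range(n_reps):
            cfg = SimulationConfig(
                n_proteins=1,
                fixed_peptides=6,
                donor_sd=0.3,
                noise_sd=0.4,
                missing_mcar_rate=0.0,
                missing_mnar_scale=0.0,
                true_log2fc={
                    ("P0001", c): 2.0
                    for c in ("healthy", "traumatic", "degenerative", "IL1b")
                },
                seed=5000 + rep,
            )
            table, design, _ = simulate_peptide_table(cfg)
            eff = fit_protein(table.log2().intensities, design)
            row = eff[eff.condition == "traumatic"].iloc[0]
            if abs(row.log2fc - 2.0) <= 2 * row.se:
                hits += 1
        assert hits >= int(0.9 * n_reps)

    def test_rmse_decreases_with_more_donors(self):
        def rmse(n_donors):
            errs = []
            for rep in range(12):
                cfg = SimulationConfig(
                    n_proteins=1, n_donors=n_donors, fixed_peptides=4,
                    missing_mcar_rate=0.0, missing_mnar_scale=0.0,
                    true_log2fc={
                        ("P0001", c): 1.0
                        for c in ("healthy", "traumatic", "degenerative", "IL1b")
                    },
                    seed=7000 + rep,
                )
                table, design, _ = simulate_peptide_table(cfg)
                eff = fit_protein(table.log2().intensities, design)
                errs.append(eff.loc[eff.condition == "traumatic", "log2fc"].iloc[0] - 1.0)
            return float(np.sqrt(np.mean(np.square(errs))))

        assert rmse(12) < rmse(3)

    def test_full_random_effect_structure_used_on_rich_protein(self):
        cfg = SimulationConfig(
            n_proteins=1, fixed_peptides=6, seed=2,
            missing_mcar_rate=0.0, missing_mnar_scale=0.0,
        )
        table, design, _ = simulate_peptide_table(cfg)
        eff = fit_protein(table.log2().intensities, design)
        assert set(eff["fit_note"]) == {"full"}


class TestAgainstLmerTest:
    def test_matches_lmertest_on_one_protein(self, tmp_path, default_sim):
        _, table, design, _ = default_sim
        sub = table.log2().intensities.loc[["P0003"]]
        eff = fit_protein(sub, design).set_index("condition")
        long = (
            sub.droplevel("protein")
            .reset_index()
            .melt(id_vars="sequence", var_name="sample", value_name="y")
            .dropna()
            .join(design.frame, on="sample")
            .rename(columns={"sequence": "peptide"})
        )
        csv = tmp_path / "protein.csv"
        long.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            d$condition <- relevel(factor(d$condition), ref="baseline")
            m <- lmer(y ~ condition + batch + (1|donor) + (1|peptide), data=d, REML=TRUE)
            co <- coef(summary(m))
            rows <- grep("^condition", rownames(co))
            out <- data.frame(condition=sub("condition", "", rownames(co)[rows]),
                              est=co[rows, "Estimate"], se=co[rows, "Std. Error"],
                              df=co[rows, "df"], p=co[rows, "Pr(>|t|)"])
            write.csv(out, "{tmp_path / 'lmer.csv'}", row.names=FALSE)
            """
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "lmer.csv").set_index("condition")
        for cond in ref.index:
            assert eff.loc[cond, "log2fc"] == pytest.approx(ref.loc[cond, "est"], abs=1e-4)
            assert eff.loc[cond, "se"] == pytest.approx(ref.loc[cond, "se"], rel=1e-3)
            assert eff.loc[cond, "df"] == pytest.approx(ref.loc[cond, "df"], rel=0.05)
            assert eff.loc[cond, "p"] == pytest.approx(ref.loc[cond, "p"], rel=0.05, abs=1e-12)


class TestSelection:
    def test_boundary_inclusive_fc_and_strict_alpha(self):
        effects = pd.DataFrame(
            {
                "protein": ["A", "B", "C"],
                "condition": ["t", "t", "t"],
                "log2fc": [1.5, 1.49, 1.6],
                "p": [0.049, 0.001, 0.05],
                "q": [np.nan] * 3,
            }
        )
        sel = select_significant(effects, SignificanceRule())
        assert sel["t"] == {"A"}  # 1.5 inclusive; p=0.05 excluded; 1.49 excluded

    def test_matches_brute_force_on_random_effects(self):
        rng = np.random.default_rng(7)
        effects = pd.DataFrame(
            {
                "protein": [f"P{i}" for i in range(300)],
                "condition": rng.choice(["a", "b"], size=300),
                "log2fc": rng.normal(0, 2, size=300),
                "p": rng.random(300),
                "q": rng.random(300),
            }
        )
        rule = SignificanceRule(alpha=0.05, fc_threshold=1.5, use_absolute=True)
        sel = select_significant(effects, rule)
        for row in effects.itertuples():
            expected = row.p < 0.05 and abs(row.log2fc) >= 1.5
            assert (row.protein in sel[row.condition]) == expected

    def test_membership_table_shape(self):
        sel = {"healthy": {"A", "B"}, "traumatic": {"B"}}
        mt = membership_table(sel)
        assert list(mt.columns) == ["protein", "conditions"]
        assert mt.set_index("protein").loc["B", "conditions"] == "healthy,traumatic"

    def test_positive_only_mode_excludes_downregulated(self):
        effects = pd.DataFrame(
            {
                "protein": ["up", "down"],
                "condition": ["t", "t"],
                "log2fc": [2.0, -2.0],
                "p": [0.01, 0.01],
                "q": [np.nan, np.nan],
            }
        )
        assert select_significant(effects, SignificanceRule(use_absolute=False))["t"] == {"up"}


def test_bh_adjustment_within_contrast(default_sim):
    _, table, design, _ = default_sim
    effects = run_differential(table.log2(), design)
    assert (effects["q"].dropna() >= effects["p"].dropna() - 1e-12).all()
    for _, sub in effects.groupby("condition"):
        # BH never reorders: sorted p gives sorted q up to the running-min step
        srt = sub.sort_values("p")
        assert (np.diff(np.maximum.accumulate(srt["q"].to_numpy())) >= -1e-12).all()
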