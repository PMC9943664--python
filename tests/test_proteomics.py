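import numpy as np
import pandas as pd
import pytest

from tsrnakit import simulate as sim
from tsrnakit.proteomics import (
    DEFAULT_ANCHORS,
    ProteomicsError,
    anchor_normalize,
    combine_fractions,
    default_groups,
    enrich_pipeline,
    enrichment,
    impute_missing,
    log2_transform,
)

SAMPLES = [f"{g}_{i}" for g in ("control", "stress") for i in (1, 2, 3)]


def wide_matrix(rows):
    return pd.DataFrame(rows, columns=SAMPLES).rename_axis("protein_id")


class TestCombineFractions:
    def test_sum_of_four_fractions(self):
        table = pd.DataFrame(
            {f"{s}__f{k}": [float(k)] for s in SAMPLES for k in (1, 2, 3, 4)},
            index=["p1"],
        )
        out = combine_fractions(table)
        assert (out.loc["p1"] == 10.0).all()

    def test_all_zero(self):
        table = pd.DataFrame(
            {f"{s}__f{k}": [0.0] for s in SAMPLES for k in (1, 2, 3, 4)},
            index=["p1"],
        )
        assert (combine_fractions(table) == 0).all().all()

    def test_random_matrix_matches_summation_oracle(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.uniform(0, 100, size=(20, 24)),
            index=[f"p{i}" for i in range(20)],
            columns=[f"{s}__f{k}" for s in SAMPLES for k in (1, 2, 3, 4)],
        )
        out = combine_fractions(table)
        for s in SAMPLES:
            manual = sum(table[f"{s}__f{k}"] for k in (1, 2, 3, 4))
            assert np.allclose(out[s], manual)


class TestAnchorNormalize:
    def anchored(self, scale_sample=None, factor=2.0):
        rows = {a: [100.0] * 6 for a in DEFAULT_ANCHORS}
        rows["p1"] = [50.0] * 6
        m = pd.DataFrame(rows).T
        m.columns = SAMPLES
        if scale_sample:
            m[scale_sample] = m[scale_sample] * factor
        return m

    def test_identical_anchors_unchanged(self):
        m = self.anchored()
        out = anchor_normalize(m)
        assert np.allclose(out, m)

    def test_doubled_sample_halved(self):
        m = self.anchored(scale_sample="control_2")
        out = anchor_normalize(m)
        # grand anchor mean in controls = (100+200+100)/3; column 2 rescaled
        grand = (100 + 200 + 100) / 3
        assert out.loc["p1", "control_2"] == pytest.approx(100 * grand / 200)
        anchors_c2 = out.loc[list(DEFAULT_ANCHORS), "control_2"].mean()
        assert anchors_c2 == pytest.approx(grand)

    def test_anchor_means_equalized_within_group(self):
        rng = np.random.default_rng(3)
        m = self.anchored()
        m.loc[:, :] = m.values * rng.uniform(0.5, 2.0, size=6)
        out = anchor_normalize(m)
        for samples in default_groups().values():
            means = out.loc[list(DEFAULT_ANCHORS), samples].mean(axis=0)
            assert np.allclose(means, means.iloc[0])

    def test_missing_anchors_rejected(self):
        m = wide_matrix({"p1": [1.0] * 6}).T
        m = pd.DataFrame([[1.0] * 6], index=["p1"], columns=SAMPLES)
        with pytest.raises(ProteomicsError):
            anchor_normalize(m)


class TestLog2AndImputation:
    def test_log2_values_and_zero_guard(self):
        m = pd.DataFrame([[8.0, 1.0, 0.0, 4.0, 2.0, 16.0]], index=["p1"], columns=SAMPLES)
        out = log2_transform(m)
        assert out.loc["p1", "control_1"] == 3.0
        assert out.loc["p1", "control_2"] == 0.0
        assert np.isnan(out.loc["p1", "control_3"])  # zero -> missing, not -inf

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(20, 2, (10, 6)),
                         index=[f"p{i}" for i in range(10)], columns=SAMPLES)
        out, flags = impute_missing(m, seed=0)
        assert out.equals(m) and not flags.any().any()

    def test_downshifted_distribution(self):
        """Imputed values follow Normal(mean - 1.8 sd, (0.3 sd)^2): over 1e4
        draws the empirical mean sits within 3 SE of the target."""
        rng = np.random.default_rng(2)
        n = 20_000
        col = pd.Series(rng.normal(25.0, 2.0, n))
        col.iloc[: n // 2] = np.nan
        m = pd.DataFrame({"control_1": col})
        m[[s for s in SAMPLES if s != "control_1"]] = 25.0
        observed = m["control_1"].dropna()
        mu, sd = observed.mean(), observed.std(ddof=1)
        out, flags = impute_missing(m, seed=7)
        imputed = out.loc[flags["control_1"], "control_1"]
        target = mu - 1.8 * sd
        se = 0.3 * sd / np.sqrt(len(imputed))
        assert abs(imputed.mean() - target) < 3 * se
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.05)

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(20, 2, (8, 6)),
                         index=[f"p{i}" for i in range(8)], columns=SAMPLES)
        m.iloc[0, 0] = np.nan
        m.iloc[3, 4] = np.nan
        a, _ = impute_missing(m, seed=5)
        b, _ = impute_missing(m, seed=5)
        c, _ = impute_missing(m, seed=6)
        assert a.equals(b)
        assert not a.equals(c)


class TestEnrichment:
    def test_identical_groups_zero(self):
        m = log2_transform(pd.DataFrame([[4.0] * 6], index=["p1"], columns=SAMPLES))
        table = enrichment(m)
        assert table.loc["p1", "log2_enrichment"] == 0.0

    def test_fourfold_is_exactly_two(self):
        m = pd.DataFrame([[10.0] * 3 + [40.0] * 3], index=["p1"], columns=SAMPLES)
        table = enrichment(log2_transform(m))
        assert table.loc["p1", "log2_enrichment"] == pytest.approx(2.0)

    def test_validity_filter(self):
        rows = {
            "one_each": [5.0, np.nan, np.nan, 7.0, np.nan, np.nan],
            "two_in_stress": [np.nan, np.nan, np.nan, 7.0, 7.0, np.nan],
            "complete": [5.0] * 6,
        }
        m = pd.DataFrame(rows).T
        m.columns = SAMPLES
        table = enrichment(m.astype(float))
        assert "one_each" not in table.index  # 1 valid per group: excluded
        assert {"two_in_stress", "complete"} <= set(table.index)

    def test_full_missing_in_controls_retained_via_stress(self):
        # the worked rule: a protein absent from all controls survives when
        # the stress group holds >= 2 valid values
        m = pd.DataFrame(
            [[np.nan, np.nan, np.nan, 8.0, 8.0, 8.0]], index=["p1"], columns=SAMPLES
        )
        assert "p1" in enrichment(m).index


class TestPipelineEndToEnd:
    def test_noiseless_recovery_is_exact(self):
        table, truth = sim.simulate_intensity_matrix(
            n_proteins=40, n_enriched=10, effect_log2=2.0,
            missing_rate_low_intensity=0.0, noise_sd_log2=0.0,
            sample_scale_sd_log2=0.0, seed=0,
        )
        result = enrich_pipeline(table, seed=0)
        for pid, effect in truth.proteomics_effects.items():
            assert result.table.loc[pid, "log2_enrichment"] == pytest.approx(effect, abs=1e-9)

    def test_anchor_enrichment_zero_with_complete_anchors(self):
        # anchors are measured without dropout; with the two groups' grand
        # anchor levels equal, normalization zeroes anchor enrichment by
        # construction (a residual between-group day effect would survive,
        # since cross-group anchor levels are deliberately not forced equal)
        table, _ = sim.simulate_intensity_matrix(
            n_proteins=60, n_enriched=15, missing_rate_low_intensity=0.2,
            sample_scale_sd_log2=0.0, seed=1,
        )
        result = enrich_pipeline(table, seed=1)
        for a in DEFAULT_ANCHORS:
            assert abs(result.table.loc[a, "log2_enrichment"]) < 0.01

    def test_enriched_rank_above_background(self):
        """Planted 2-fold proteins separate from background with AUC > 0.95
        at the fixture's noise level (no dropout: the check isolates the
        enrichment statistic's ranking; imputation bias has its own tests)."""
        table, truth = sim.simulate_intensity_matrix(
            effect_log2=1.0, missing_rate_low_intensity=0.0, seed=2
        )
        result = enrich_pipeline(table, seed=2)
        scores = result.table["log2_enrichment"]
        enriched = [p for p, e in truth.proteomics_effects.items()
                    if e > 0 and p in scores.index]
        background = [p for p, e in truth.proteomics_effects.items()
                      if e == 0 and p in scores.index]
        pos = scores.loc[enriched].to_numpy()
        neg = scores.loc[background].to_numpy()
        # Mann-Whitney AUC
        auc = (pos[:, None] > neg[None, :]).mean() + 0.5 * (pos[:, None] == neg[None, :]).mean()
        assert auc > 0.95
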