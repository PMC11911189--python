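"""Synthetic cohort generator: determinism, marginals, planted ground truth,
and the reconstructed baseline-table fixture."""

import numpy as np
import pandas as pd
import pytest

import lymphrisk as lr
from lymphrisk.evaluate import chisq_test, logrank_test
from lymphrisk.synthetic import (
    SyntheticConfig,
    generate_clinical,
    generate_cohort,
    generate_slide,
    generate_survival,
)
from lymphrisk.table1 import TABLE1_COUNTS, crosstab_counts, reconstruct_table1_fixture


class TestConfigValidation:
    def test_invalid_prevalence(self):
        with pytest.raises(ValueError, match="prevalence"):
            SyntheticConfig(prevalence=1.5)

    def test_density_contrast_required(self):
        with pytest.raises(ValueError, match="density"):
            SyntheticConfig(nucleus_density_signal=5, nucleus_density_background=10)

    def test_slide_must_hold_two_patches(self):
        with pytest.raises(ValueError, match="2x patch"):
            SyntheticConfig(slide_width=512, slide_height=512)


class TestSlides:
    def test_no_blobs_gives_near_white_slide(self, tiny_config, rng):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, n_blobs=0)
        image, signal, tissue = generate_slide(0, cfg, rng)
        mask = lr.compute_tissue_mask(image)
        assert mask.mask.sum() == 0
        assert len(signal) == 0 and len(tissue) == 0

    def test_negative_slide_with_zero_rate_has_no_signal(self, tiny_config, rng):
        image, signal, tissue = generate_slide(0, tiny_config, rng)
        assert len(signal) == 0
        assert len(tissue) > 0

    def test_background_unsaturated_tissue_saturated(self, one_slide):
        image, _, tissue = one_slide
        x0, y0 = tissue[0]
        tissue_px = image[y0 + 10, x0 + 10].astype(float)
        sat = (tissue_px.max() - tissue_px.min()) / tissue_px.max() * 255
        assert sat >= 35
        corner = image[0, 0].astype(float)  # background
        sat_bg = (corner.max() - corner.min()) / max(corner.max(), 1) * 255
        assert sat_bg < 35


class TestClinical:
    def test_zero_missing_rate_leaves_no_gaps(self, rng):
        cfg = SyntheticConfig(missing_rate=0.0)
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        table = generate_clinical(labels, cfg, rng)
        assert not table.isna().any().any()

    def test_schema_kinds_are_all_present(self, rng):
        cfg = SyntheticConfig()
        labels = np.r_[np.ones(30, int), np.zeros(30, int)]
        table = generate_clinical(labels, cfg, rng)
        schema = lr.default_clinical_schema(cfg)
        kinds = {schema[c].kind for c in table.columns}
        assert {"binary", "multicategory", "continuous"} <= kinds
        # no outcome-like variables generated
        assert all(not schema[c].is_outcome for c in table.columns)

    def test_null_effects_give_unit_odds_ratio(self):
        cfg = SyntheticConfig(
            missing_rate=0.0,
            clinical_effects={k: 0.0 for k in SyntheticConfig().clinical_effects},
        )
        labels = np.r_[np.ones(1000, int), np.zeros(1000, int)]
        table = generate_clinical(labels, cfg, np.random.default_rng(77))
        x = (table["ldh_elevated"] == "Yes").to_numpy()
        a = ((x == 1) & (labels == 1)).sum() * ((x == 0) & (labels == 0)).sum()
        b = ((x == 1) & (labels == 0)).sum() * ((x == 0) & (labels == 1)).sum()
        assert 0.75 < a / b < 1.33  # Monte-Carlo window around OR = 1

    def test_log3_effect_recovers_odds_ratio_near_three(self):
        effects = {k: 0.0 for k in SyntheticConfig().clinical_effects}
        effects["ldh_elevated"] = np.log(3.0)
        cfg = SyntheticConfig(missing_rate=0.0, clinical_effects=effects)
        labels = np.r_[np.ones(1000, int), np.zeros(1000, int)]
        table = generate_clinical(labels, cfg, np.random.default_rng(5))
        x = (table["ldh_elevated"] == "Yes").to_numpy()
        a = ((x == 1) & (labels == 1)).sum() * ((x == 0) & (labels == 0)).sum()
        b = ((x == 1) & (labels == 0)).sum() * ((x == 0) & (labels == 1)).sum()
        assert 2.2 < a / b < 4.0

    def test_effects_must_cover_every_variable(self, rng):
        cfg = SyntheticConfig()
        cfg.clinical_effects = {"gender": 0.0}
        with pytest.raises(ValueError, match="missing"):
            generate_clinical(np.array([0, 1]), cfg, rng)


class TestSurvival:
    def test_enormous_censor_time_gives_all_events(self, rng):
        cfg = SyntheticConfig(censor_time=1e9)
        labels = np.r_[np.ones(40, int), np.zeros(40, int)]
        surv = generate_survival(labels, cfg, rng)
        assert (surv["event"] == 1).all()
        assert (surv["time"] > 0).all()

    def test_null_hazard_ratio_gives_null_logrank(self):
        cfg = SyntheticConfig(hazard_ratio=1.0)
        labels = np.r_[np.ones(60, int), np.zeros(60, int)]
        ps = []
        for seed in range(40):
            surv = generate_survival(labels, cfg, np.random.default_rng(seed))
            _, p = logrank_test(
                surv["time"][labels == 1], surv["event"][labels == 1],
                surv["time"][labels == 0], surv["event"][labels == 0],
            )
            ps.append(p)
        assert 0.2 < float(np.mean(ps)) < 0.8  # roughly uniform p under null

    def test_strong_hazard_ratio_detected(self):
        cfg = SyntheticConfig(hazard_ratio=4.0)
        labels = np.r_[np.ones(150, int), np.zeros(150, int)]
        hits = 0
        for seed in range(20):
            surv = generate_survival(labels, cfg, np.random.default_rng(seed))
            _, p = logrank_test(
                surv["time"][labels == 1], surv["event"][labels == 1],
                surv["time"][labels == 0], surv["event"][labels == 0],
            )
            hits += p < 0.01
        assert hits >= 19


class TestCohort:
    def test_label_share_follows_rounding_rule(self, rng):
        cfg = SyntheticConfig(n_patients=10, prevalence=0.5, seed=7)
        from lymphrisk.synthetic import _cohort_labels

        labels = _cohort_labels(cfg, rng)
        assert labels.sum() == 5

    def test_feature_cohort_deterministic(self, tiny_config, tiny_cohort):
        again = lr.build_feature_cohort(tiny_config)
        assert again.patient_ids == tiny_cohort.patient_ids
        np.testing.assert_array_equal(again.labels, tiny_cohort.labels)
        for b1, b2 in zip(again.bags, tiny_cohort.bags):
            np.testing.assert_array_equal(b1.features, b2.features)
        pd.testing.assert_frame_equal(again.clinical, tiny_cohort.clinical)

    def test_written_cohort_round_trips_and_is_reproducible(self, tmp_path, tiny_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, n_patients=3)
        rec1 = generate_cohort(cfg, tmp_path / "a")
        rec2 = generate_cohort(cfg, tmp_path / "b")
        assert len(rec1) == 3
        for r1, r2 in zip(rec1, rec2):
            assert r1.label == r2.label
            assert r1.clinical == r2.clinical or (
                # NaN != NaN; compare with pandas semantics
                pd.Series(r1.clinical).equals(pd.Series(r2.clinical))
            )
            b1 = (tmp_path / "a" / "slides" / f"{r1.patient_id}.png").read_bytes()
            b2 = (tmp_path / "b" / "slides" / f"{r2.patient_id}.png").read_bytes()
            assert b1 == b2  # byte-identical slides
        manifest = pd.read_csv(tmp_path / "a" / "manifest.csv")
        assert len(manifest) == 3
        assert {"patient_id", "label", "slide_path", "survival_time", "event"}.issubset(
            manifest.columns
        )

    def test_planted_signal_fraction_matches_rate(self):
        cfg = SyntheticConfig(
            n_patients=40, slide_width=2048, slide_height=2048,
            n_blobs=2, blob_cells=6,
            signal_rate_pos=0.3, signal_rate_neg=0.05, seed=21,
        )
        co = lr.build_feature_cohort(cfg)
        fracs = [
            len(co.signal_coords[i]) / len(co.tissue_coords[i])
            for i in range(40)
            if co.labels[i] == 1
        ]
        assert abs(float(np.mean(fracs)) - 0.3) < 0.1


class TestTable1Fixture:
    def test_row_and_label_counts(self):
        df = reconstruct_table1_fixture()
        assert len(df) == 227
        assert (df["label"] == 1).sum() == 118
        assert (df["label"] == 0).sum() == 109

    def test_double_expression_crosstab(self):
        df = reconstruct_table1_fixture()
        np.testing.assert_array_equal(
            crosstab_counts(df, "double_expression"), [[40, 19], [78, 90]]
        )

    def test_tumor_stage_crosstab(self):
        df = reconstruct_table1_fixture()
        np.testing.assert_array_equal(
            crosstab_counts(df, "tumor_stage"),
            [[28, 38], [31, 39], [31, 19], [28, 13]],
        )

    def test_every_published_cell_reproduced(self):
        df = reconstruct_table1_fixture()
        for var, levels in TABLE1_COUNTS.items():
            obs = crosstab_counts(df, var, drop_unknown=False)
            expected = [[n_rr, n_non] for _, n_rr, n_non in levels]
            np.testing.assert_array_equal(obs, expected, err_msg=var)

    def test_fixture_supports_published_chi_square(self):
        df = reconstruct_table1_fixture()
        _, _, p = chisq_test(crosstab_counts(df, "double_expression"))
        assert round(p, 4) == pytest.approx(0.0047)
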