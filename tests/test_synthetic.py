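"""Synthetic-cohort generator: calibration, determinism, marginal structure."""
import dataclasses
import math

import numpy as np
import pytest
from scipy import optimize

from crcpathways.cohort import CohortError, apply_exclusions, write_cohort
from crcpathways.synthetic import (
    NormalMixture,
    TruncNormal,
    TrueSurvivalParameters,
    generate_cohort,
    generate_current_status_dataset,
    generate_raw_cohort,
    reference_calibration,
)


class TestReferenceCalibration:
    def test_side_model_effects_are_log_odds_ratios(self, calibration):
        cfg, _ = calibration
        assert math.exp(cfg.true_side_model["b_ida"]) == pytest.approx(10.61)
        assert math.exp(cfg.true_side_model["b_bcsp"]) == pytest.approx(0.95)
        assert math.exp(cfg.true_side_model["b_female"]) == pytest.approx(1.94)
        assert math.exp(cfg.true_stage_model["b_ida"]) == pytest.approx(1.65)
        assert math.exp(cfg.true_stage_model["b_bcsp"]) == pytest.approx(2.42)

    def test_survival_truth_matches_closed_form_and_root_finder(self, calibration):
        _, truth = calibration
        assert math.exp(truth.beta) == pytest.approx(0.66)
        # closed-form inversion of the Weibull-PH median
        k_closed = math.log(1 / 0.66) / math.log(75 / 70)
        assert truth.shape == pytest.approx(k_closed, rel=1e-12)
        assert truth.scale == pytest.approx(70 / math.log(2) ** (1 / k_closed), rel=1e-12)
        # independent numeric root of the two median equations
        def med(x, k, s):
            return s * (math.log(2) * math.exp(-truth.beta * x)) ** (1 / k)

        k_num = optimize.brentq(
            lambda k: med(1, k, 70 / math.log(2) ** (1 / k)) - 75.0, 1.5, 50.0
        )
        assert truth.shape == pytest.approx(k_num, rel=1e-9)
        assert truth.median_onset(1) == pytest.approx(75.0)
        assert truth.median_onset(0) == pytest.approx(70.0)

    def test_intercepts_hit_marginal_proportions(self, calibration):
        cfg, _ = calibration
        # direct expectation over pathway x sex cells
        from scipy.special import expit

        n_tot = sum(cfg.group_sizes.values())
        side = cfg.true_side_model
        total = 0.0
        for p, n in cfg.group_sizes.items():
            pf = 1 / (1 + cfg.sex_ratios_m_f[p])
            lin = side["intercept"]
            lin += side["b_ida"] if p == "IDA" else side["b_bcsp"] if p == "BCSP" else 0.0
            total += n / n_tot * ((1 - pf) * expit(lin) + pf * expit(lin + side["b_female"]))
        assert total == pytest.approx(0.39, abs=1e-9)


class TestGenerateCohort:
    def test_default_sizes(self, calibration):
        cfg, _ = calibration
        cohort = generate_cohort(cfg, seed=5)
        assert len(cohort) == 1138
        df = cohort.to_dataframe()
        assert (df["pathway"] == "IDA").sum() == 171
        assert (df["pathway"] == "BCSP").sum() == 187

    def test_same_seed_gives_identical_csv(self, calibration, tmp_path):
        cfg, _ = calibration
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(generate_cohort(cfg, seed=11), p1)
        write_cohort(generate_cohort(cfg, seed=11), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_null_effects_equalise_side_across_pathways(self, calibration):
        cfg, _ = calibration
        null_side = dict(cfg.true_side_model, b_ida=0.0, b_bcsp=0.0, b_female=0.0)
        null_cfg = dataclasses.replace(cfg, true_side_model=null_side)
        props = {p: [] for p in ("IDA", "BCSP", "SYMPTOMATIC")}
        for s in range(30):
            df = generate_cohort(null_cfg, seed=s).to_dataframe()
            for p in props:
                sub = df[df["pathway"] == p]
                props[p].append((sub["side"] == "right").mean())
        means = [np.mean(v) for v in props.values()]
        assert max(means) - min(means) < 0.04

    def test_ida_right_sided_marginal_calibration(self, calibration):
        """Mean right-sided proportion in the IDA group across replicates
        stays within 3 points of the printed 82.5%."""
        cfg, _ = calibration
        props = []
        for s in range(500):
            df = generate_cohort(cfg, seed=10_000 + s).to_dataframe()
            ida = df[df["pathway"] == "IDA"]
            props.append((ida["side"] == "right").mean())
        assert abs(np.mean(props) - 0.825) < 0.03

    def test_increasing_ida_effect_increases_right_sided_count(self, calibration):
        cfg, _ = calibration
        bigger = dataclasses.replace(
            cfg, true_side_model=dict(cfg.true_side_model, b_ida=cfg.true_side_model["b_ida"] + 1.0)
        )
        base_counts, big_counts = [], []
        for s in range(20):
            dfb = generate_cohort(cfg, seed=s).to_dataframe()
            dfB = generate_cohort(bigger, seed=s).to_dataframe()
            base_counts.append(((dfb["pathway"] == "IDA") & (dfb["side"] == "right")).sum())
            big_counts.append(((dfB["pathway"] == "IDA") & (dfB["side"] == "right")).sum())
        assert np.mean(big_counts) > np.mean(base_counts)

    def test_blood_count_split_partitions_ida_group(self, calibration):
        from crcpathways.cohort import classify_blood_count_history

        cfg, _ = calibration
        cohort = generate_cohort(cfg, seed=3)
        ida = [r for r in cohort if r.pathway == "IDA"]
        classes = [classify_blood_count_history(r) for r in ida]
        assert len(classes) == 171
        counts = {c: classes.count(c) for c in set(classes)}
        assert sum(counts.values()) == 171


def test_raw_cohort_exclusion_round_trip(calibration):
    cfg, _ = calibration
    raw = generate_raw_cohort(cfg, seed=9)
    assert len(raw) == 1258
    clean, report = apply_exclusions(raw)
    assert len(clean) == 1138
    assert report.counts == cfg.exclusion_counts


class TestCurrentStatusGeneration:
    def test_degenerate_p_tested(self, generator_truth):
        data = generate_current_status_dataset(generator_truth, 50, p_tested=0.0, seed=1)
        assert all(r.tested == 0 for r in data)

    def test_invalid_probability_rejected(self, generator_truth):
        with pytest.raises(CohortError):
            generate_current_status_dataset(generator_truth, 50, p_tested=1.5, seed=1)

    def test_determinism(self, generator_truth):
        a = generate_current_status_dataset(generator_truth, 100, seed=7)
        b = generate_current_status_dataset(generator_truth, 100, seed=7)
        assert a == b

    def test_near_exponential_special_case(self):
        """At shape ~ 1 and beta = 0 the onset is exponential, so the
        late-stage fraction matches 1 - E[exp(-C/sigma)] over the diagnosis
        ages."""
        dist = NormalMixture(((1.0, TruncNormal(75.0, 10.0, 40.0, 100.0)),))
        truth = TrueSurvivalParameters(
            shape=1.0 + 1e-9,
            scale=80.0,
            beta=0.0,
            diag_age_tested=dist,
            diag_age_untested=dist,
            p_tested=0.5,
        )
        data = generate_current_status_dataset(truth, 40_000, seed=13)
        frac = np.mean([r.late_stage for r in data])
        expected = dist.expect(lambda c: 1.0 - math.exp(-c / 80.0))
        assert frac == pytest.approx(expected, abs=0.01)

    def test_late_fraction_matches_observed_ida_split(self, generator_truth):
        """Monte-Carlo late-stage fraction at the analysis-consistent truth is
        close to the observed IDA fraction 1 - 89/171."""
        fracs = []
        for s in range(50):
            data = generate_current_status_dataset(generator_truth, 171, seed=500 + s)
            fracs.append(np.mean([r.late_stage for r in data]))
        assert np.mean(fracs) == pytest.approx(1 - 89 / 171, abs=0.05)


def test_analysis_consistent_truth_respects_prior_constraint(generator_truth):
    assert generator_truth.shape > 1.0
    assert generator_truth.scale > 0.0
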