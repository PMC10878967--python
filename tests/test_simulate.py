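import time
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import special

from sweptrial import (
    GeneratorConfig,
    babies_table,
    classify_frame,
    default_design,
    generate_trial,
    read_dataset,
    solve_variance_components,
    write_dataset,
)
from sweptrial.exceptions import SchemaError, ValidationError
from sweptrial.simulate import _solve_offset, validate_dataset


class TestVarianceComponents:
    def test_zero_icc_means_no_random_effects(self):
        assert solve_variance_components(0.0, 0.9, 0.4) == (0.0, 0.0)

    def test_unit_cac_puts_all_variance_between_clusters(self):
        sc, scp = solve_variance_components(0.02, 1.0, 0.4)
        assert scp == 0.0
        assert sc > 0.0

    def test_zero_cac_puts_all_variance_within_periods(self):
        sc, scp = solve_variance_components(0.02, 0.0, 0.4)
        assert sc == 0.0
        assert scp > 0.0

    def test_induced_correlations_match_targets_by_simulation(self):
        """Monte-Carlo check of the quadrature solver: draw latent
        effects directly and measure the outcome-scale correlations."""
        icc, cac, p = 0.02, 0.90, 0.40
        sc, scp = solve_variance_components(icc, cac, p)
        eta0 = _solve_offset(p, sc, scp)
        rng = np.random.default_rng(99)
        u = rng.normal(0, sc, size=(20000, 1))
        v = rng.normal(0, scp, size=(20000, 200))
        probs = special.expit(eta0 + u + v)
        pi = probs.mean()
        bern = pi * (1 - pi)
        # same cluster-period: two women share (u, v)
        icc_within = (np.mean(probs**2) - pi**2) / bern
        # same cluster, different periods: share u only
        g = probs.mean(axis=1)
        icc_between = (np.mean(g**2) - pi**2) / bern
        assert icc_within == pytest.approx(icc, abs=1e-3)
        assert icc_between == pytest.approx(icc * cac, abs=1e-3)

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValidationError):
            solve_variance_components(1.0, 0.9, 0.4)
        with pytest.raises(ValidationError):
            solve_variance_components(0.02, 1.1, 0.4)
        with pytest.raises(ValidationError):
            solve_variance_components(0.02, 0.9, 0.0)


class TestGenerateTrial:
    def test_same_seed_byte_identical_csv(self, tmp_path, design):
        cfg = GeneratorConfig(
            design=design, seed=7, cluster_size_mean_per_period=120
        )
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_dataset(generate_trial(cfg), a)
        write_dataset(generate_trial(cfg), b)
        assert a.read_bytes() == b.read_bytes()

    def test_every_record_passes_profile_validation(self, trial_data):
        # classify_frame revalidates the obstetric columns and must
        # agree with the stored group
        got = classify_frame(trial_data)
        assert (got == trial_data["robson_group"].to_numpy()).all()
        validate_dataset(trial_data)

    def test_group1_share_matches_study_population(self, trial_data):
        share = 100.0 * (trial_data["robson_group"] == 1).mean()
        assert 25.0 <= share <= 35.0

    def test_denominator_logic(self, trial_data):
        spont = trial_data["labor_onset"] == "spontaneous"
        assert trial_data["augmentation"].notna().equals(spont)
        assert trial_data["arm_rupture"].notna().equals(spont)
        vaginal = trial_data["cesarean"] == 0
        assert trial_data["episiotomy"].notna().equals(vaginal)
        assert trial_data["operative_vaginal"].notna().equals(vaginal)
        # survey restricted to Robson 1 or 3 with a liveborn baby
        eligible = trial_data["survey_eligible"] == 1
        assert trial_data.loc[eligible, "robson_group"].isin((1, 3)).all()
        assert (
            trial_data.loc[eligible, "n_stillbirths"]
            < trial_data.loc[eligible, "n_fetuses"]
        ).all()
        assert trial_data["labor_companion"].notna().equals(eligible)
        # prelabor cesarean is always a cesarean birth
        prelabor = trial_data["labor_onset"] == "prelabor_cesarean"
        assert (trial_data.loc[prelabor, "cesarean"] == 1).all()

    def test_null_generator_recovers_baseline(self, design):
        cfg = GeneratorConfig.uniform_cohort(
            design=design, baseline_p=0.40, intervention_rr=1.0,
            icc=0.0, cac=0.9, cluster_size_mean_per_period=600,
            cluster_size_cv=0.0, seed=31,
        )
        df = generate_trial(cfg)
        g1 = df[df["robson_group"] == 1]
        rate = g1["cesarean"].mean()
        n = len(g1)
        assert abs(rate - 0.40) < 3 * np.sqrt(0.4 * 0.6 / n)

    def test_empirical_icc_matches_target(self, design):
        """Pooled over 30 independent replicates, the within-period
        ICC of generated outcomes should hit the 0.02 target within
        0.005, and the between-period within-cluster correlation the
        0.018 (= icc * cac) target."""
        icc, cac, p = 0.02, 0.90, 0.40
        base = GeneratorConfig.uniform_cohort(
            design=design, baseline_p=p, intervention_rr=1.0,
            icc=icc, cac=cac, cluster_size_mean_per_period=400,
            cluster_size_cv=0.0, seed=0,
        )
        full_periods = list(range(1, 7))  # equal-sized, untruncated
        m_per = 400.0
        prop_frames = []
        for s in range(30):
            df = generate_trial(replace(base, seed=1000 + s))
            df = df[df["period"].isin(full_periods)]
            props = (
                df.groupby(["cluster", "period"])["cesarean"]
                .mean()
                .unstack()
            )
            prop_frames.append(props.to_numpy())
        props = np.vstack(prop_frames)  # (30 * 4 clusters) x 6 periods
        pi = float(props.mean())
        bern = pi * (1 - pi)
        # Var(p_hat_ct) = bern * (icc + (1 - icc) / m)
        var_phat = float(props.var(ddof=1))
        icc_within = (var_phat - bern / m_per) / (bern * (1 - 1 / m_per))
        # Cov(p_hat_ct, p_hat_ct') = bern * icc * cac for t != t'
        prods = [
            (props[:, t1] - pi) * (props[:, t2] - pi)
            for t1 in range(6)
            for t2 in range(t1 + 1, 6)
        ]
        icc_between = float(np.mean(prods)) / bern
        assert icc_within == pytest.approx(icc, abs=0.005)
        assert icc_between == pytest.approx(icc * cac, abs=0.005)

    def test_probability_overflow_clamped_with_count(self, design):
        cfg = GeneratorConfig.uniform_cohort(
            design=design, baseline_p=0.8, intervention_rr=1.5,
            icc=0.0, cac=0.9, cluster_size_mean_per_period=50,
            cluster_size_cv=0.0, seed=2,
        )
        df = generate_trial(cfg)
        assert df.attrs["n_clamped"] > 0
        exp_rate = df.loc[df["condition"] == "intervention", "cesarean"]
        assert exp_rate.mean() > 0.95


class TestBabies:
    def test_expansion_counts(self, trial_data):
        babies = babies_table(trial_data)
        assert len(babies) == trial_data["n_fetuses"].sum()
        assert babies["stillbirth"].sum() == trial_data[
            "n_stillbirths"
        ].sum()
        assert babies["neonatal_death"].sum() == trial_data[
            "n_neonatal_deaths"
        ].sum()
        assert not (
            (babies["stillbirth"] == 1) & (babies["neonatal_death"] == 1)
        ).any()


class TestRoundTrip:
    def test_write_read_lossless(self, tmp_path, trial_data):
        path = tmp_path / "births.csv"
        write_dataset(trial_data, path)
        back = read_dataset(path)
        pd.testing.assert_frame_equal(
            trial_data.reset_index(drop=True), back
        )
        assert path.with_suffix(".dict.json").exists()

    def test_missing_column_raises_schema_error(self, tmp_path, trial_data):
        path = tmp_path / "bad.csv"
        trial_data.drop(columns=["parity"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="parity"):
            read_dataset(path)

    def test_unknown_column_raises_schema_error(self, tmp_path, trial_data):
        path = tmp_path / "bad.csv"
        trial_data.assign(extra=1).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="extra"):
            read_dataset(path)

    def test_trial_sized_dataset_round_trips_quickly(self, tmp_path):
        cfg = GeneratorConfig(seed=12)  # trial-scale: ~26,000+ women
        df = generate_trial(cfg)
        assert len(df) > 20_000
        start = time.perf_counter()
        path = tmp_path / "big.csv"
        write_dataset(df, path)
        back = read_dataset(path)
        assert time.perf_counter() - start < 10.0
        assert len(back) == len(df)
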