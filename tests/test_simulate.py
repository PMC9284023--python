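import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import tissuecage as tc
from tissuecage import pgem as pgem_mod
from tissuecage import pk, simulate
from tissuecage.simulate import (
    DATASET_COLUMNS,
    DatasetError,
    TrialDesign,
    make_default_design,
    read_dataset,
    simulate_pgem,
    simulate_trial,
    write_dataset,
    write_monolix,
)


class TestDesign:
    def test_defaults_match_study_layout(self):
        d = make_default_design(0)
        assert d.n_sheep == 7
        assert d.cage_lengths_cm == (3.0, 6.0, 10.0, 14.0, 18.0)
        assert len(d.sampling_times_h) == 14
        assert d.n_periods == 2
        assert len(d.carrageenan_side_by_sheep) == 7
        assert set(d.carrageenan_side_by_sheep) <= {"left", "right"}

    def test_side_assignment_deterministic(self):
        assert make_default_design(4) == make_default_design(4)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            TrialDesign(sampling_times_h=(1.0, 1.0, 2.0))
        with pytest.raises(ValueError):
            TrialDesign(carrageenan_period=3)
        with pytest.raises(ValueError):
            TrialDesign(carrageenan_side_by_sheep=("up",) * 7)
        with pytest.raises(ValueError):
            TrialDesign(missing_rate=1.5)


class TestSimulateTrial:
    def test_record_count(self, trial, design):
        # n_sheep * n_periods * (14 plasma + 10 cages * 14 times)
        assert len(trial) == design.n_sheep * 2 * (14 + 10 * 14)
        per_length = trial[(trial.matrix == "cage") & (trial.length_cm == 3)]
        assert len(per_length) == 392  # 28 cage-series of 14 samples

    def test_deterministic_under_seed(self, design, model):
        a = simulate_trial(design, model, 12)
        b = simulate_trial(design, model, 12)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_trial(design, model, 13)
        assert not a.conc_ug_ml.equals(c.conc_ug_ml)

    def test_noise_free_equals_closed_form(self, noise_free_trial, noise_free_model, design):
        post = noise_free_trial[~noise_free_trial.below_dose_time]
        plasma = post[post.matrix == "plasma"]
        for (sheep, period), grp in plasma.groupby(["sheep_id", "period"]):
            carr = period == design.carrageenan_period
            p, _ = pk.apply_covariates(noise_free_model, 0.0, False, carr, False)
            np.testing.assert_allclose(
                grp.conc_ug_ml.to_numpy(),
                pk.plasma_conc(p, 4.0, grp.time_h.to_numpy()),
                rtol=1e-12,
            )
        cage = post[post.matrix == "cage"]
        for (sheep, period, side, length), grp in cage.groupby(
            ["sheep_id", "period", "side", "length_cm"]
        ):
            carr_sheep = period == design.carrageenan_period
            carr_cage = bool(grp.carr_cage.iloc[0])
            p, c = pk.apply_covariates(
                noise_free_model, length, carr_cage, carr_sheep, side == "right"
            )
            np.testing.assert_allclose(
                grp.conc_ug_ml.to_numpy(),
                pk.cage_conc(p, c, 4.0, grp.time_h.to_numpy()),
                rtol=1e-12,
            )

    def test_covariate_flags_span_design_exactly(self, trial, design):
        # carrageenan only in its period, only cage records on the drawn side
        assert (trial.carr_sheep == (trial.period == design.carrageenan_period)).all()
        carr = trial[trial.carr_cage]
        assert (carr.matrix == "cage").all()
        sides = dict(zip(range(1, 8), design.carrageenan_side_by_sheep))
        assert all(r.side == sides[r.sheep_id] for r in carr.itertuples())
        # exactly 5 inflamed cages per sheep
        assert (
            carr.groupby("sheep_id")[["side", "length_cm"]].nunique()["length_cm"] == 5
        ).all()

    def test_predose_records_zero_and_flagged(self, trial):
        pre = trial[trial.time_h < 0]
        assert pre.below_dose_time.all()
        assert (pre.conc_ug_ml == 0).all()
        assert not trial[trial.time_h >= 0].below_dose_time.any()

    def test_proportional_error_cv(self, design, noise_free_model, model):
        """Residual CV of plasma observations matches b_plasma."""
        noisy_model = tc.PopulationModel(
            plasma=model.plasma, cage=model.cage, covariates=model.covariates,
            omegas=tc.RandomEffectSDs(0, 0, 0, 0), error=model.error,
        )
        noisy = simulate_trial(design, noisy_model, 41)
        clean = simulate_trial(design, tc.PopulationModel(
            plasma=model.plasma, cage=model.cage, covariates=model.covariates,
            omegas=tc.RandomEffectSDs(0, 0, 0, 0), error=tc.ErrorModel(0, 0)), 41)
        sel = (noisy.matrix == "plasma") & (~noisy.below_dose_time)
        ratio = noisy.loc[sel, "conc_ug_ml"].to_numpy() / clean.loc[sel, "conc_ug_ml"].to_numpy()
        cv = np.std(ratio)
        n = sel.sum()
        assert cv == pytest.approx(0.136, abs=3 * 0.136 / np.sqrt(2 * n))

    def test_missingness_drops_only_cage_records(self, design, model):
        d = replace(design, missing_rate=0.2)
        df = simulate_trial(d, model, 3)
        full = simulate_trial(design, model, 3)
        assert (df.matrix == "plasma").sum() == (full.matrix == "plasma").sum()
        n_cage = (df.matrix == "cage").sum()
        assert n_cage < (full.matrix == "cage").sum()
        assert n_cage == pytest.approx(0.8 * 1960, abs=4 * np.sqrt(1960 * 0.2 * 0.8))


class TestSimulatePgem:
    def test_sampling_imbalance(self, design):
        df = simulate_pgem(design, pgem_mod.reference_pgem_model(), 8)
        n_carr = df.carr_cage.sum()
        assert n_carr == 7 * 5 * 6  # every inflamed series fully assayed
        assert 40 <= (~df.carr_cage).sum() <= 110  # ~74 expected
        assert (df.pgem_pg_ml > 0).all()

    def test_noise_free_linear_predictor(self, design):
        m = pgem_mod.reference_pgem_model()
        m = pgem_mod.PgemModel(
            beta0=m.beta0, beta_time=m.beta_time, beta_size=m.beta_size,
            beta_interaction=m.beta_interaction, sd_sheep=0.0, sd_resid=1e-12,
        )
        df = simulate_pgem(design, m, 3)
        ref = df[(df.length_cm == 3) & (df.time_h == 0.5)]
        assert np.log10(ref.pgem_pg_ml).iloc[0] == pytest.approx(1.55 + 0.00731 * 0.5, abs=1e-6)
        six = df[df.length_cm == 6].sort_values("time_h")
        slope = np.polyfit(six.time_h, np.log10(six.pgem_pg_ml), 1)[0]
        assert slope == pytest.approx(0.00731 + 0.00800, rel=1e-6)

    def test_variance_calibration_targets_reported_r2(self, design):
        df = simulate_pgem(design, pgem_mod.reference_pgem_model(), 5)
        used = df.attrs["pgem_model"]
        mu = used.linear_predictor(df.length_cm.to_numpy(), df.time_h.to_numpy())
        var_f = float(np.var(mu))
        tot = var_f + used.sd_sheep**2 + used.sd_resid**2
        assert var_f / tot == pytest.approx(0.27, abs=1e-9)
        assert (var_f + used.sd_sheep**2) / tot == pytest.approx(0.42, abs=1e-9)

    def test_variance_decomposition_monte_carlo(self, design):
        m = pgem_mod.PgemModel(
            beta0=1.0, beta_time=0.0,
            beta_size={6: 0, 10: 0, 14: 0, 18: 0},
            beta_interaction={6: 0, 10: 0, 14: 0, 18: 0},
            sd_sheep=0.3, sd_resid=0.2,
        )
        big = replace(design, n_sheep=200, carrageenan_side_by_sheep=())
        df = simulate_pgem(big, m, 9, noncarr_fraction=1.0)
        y = np.log10(df.pgem_pg_ml)
        between = df.assign(y=y).groupby("sheep_id")["y"].mean().var()
        within = df.assign(y=y).groupby("sheep_id")["y"].transform(lambda v: v - v.mean()).var()
        assert within == pytest.approx(0.04, rel=0.1)
        assert between == pytest.approx(0.09 + 0.04 / 120, rel=0.25)


class TestDatasetIO:
    def test_round_trip(self, trial, tmp_path):
        path = tmp_path / "trial.csv"
        write_dataset(trial, path)
        back = read_dataset(path)
        pd.testing.assert_frame_equal(back, trial[DATASET_COLUMNS])

    def test_empty_dataset_header_only(self, trial, tmp_path):
        path = tmp_path / "empty.csv"
        write_dataset(trial.iloc[:0], path)
        text = path.read_text().strip().splitlines()
        assert len(text) == 1
        assert text[0].split(",") == DATASET_COLUMNS

    def test_hand_written_csv_parses(self, tmp_path):
        path = tmp_path / "hand.csv"
        path.write_text(
            "sheep_id,period,matrix,side,length_cm,carr_cage,carr_sheep,"
            "time_h,conc_ug_ml,below_dose_time\n"
            "1,1,plasma,none,0,False,False,0.5,40.1,False\n"
            "1,2,cage,left,6,True,True,8,12.5,False\n"
            "2,1,cage,right,18,False,False,-1,0,True\n"
        )
        df = read_dataset(path)
        assert len(df) == 3
        assert df.carr_cage.tolist() == [False, True, False]
        assert df.below_dose_time.tolist() == [False, False, True]

    def test_malformed_csv_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sheep_id,period\n1,1\n")
        with pytest.raises(DatasetError):
            read_dataset(path)
        path.write_text(
            "sheep_id,period,matrix,side,length_cm,carr_cage,carr_sheep,"
            "time_h,conc_ug_ml,below_dose_time\n"
            "1,1,plasma,left,0,False,False,0.5,40.1,False\n"  # plasma with a side
        )
        with pytest.raises(DatasetError):
            read_dataset(path)

    def test_monolix_export(self, trial, tmp_path):
        path = tmp_path / "monolix.csv"
        write_monolix(trial, path, 4.0)
        df = pd.read_csv(path)
        assert set(df.columns) == {
            "ID", "TIME", "DV", "AMT", "OBSID", "SIDE", "LENGTH", "CARRCAGE", "CARRSHEEP"
        }
        dosing = df[df.AMT != "."]
        assert len(dosing) == 14  # one per sheep-period
        assert (dosing.TIME == 0).all()
        n_obs = (~trial.below_dose_time).sum()
        assert len(df) == n_obs + 14
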