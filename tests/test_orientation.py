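import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from gesse.orientation import (
    MODEL_VARIANTS,
    bin_by_sin4,
    comparison_table,
    compute_alpha,
    compute_dbar,
    fit_model,
    model_comparison,
    select_voxels,
    sin4_alpha,
)
from gesse.phantom import generate_voxel_table

from conftest import TABLE1_FIT3


def _table(voxels: dict) -> pd.DataFrame:
    n = len(voxels["R2"])
    base = {
        "voxel_id": np.arange(n),
        "FA": 0.5,
        "tract_id": 0,
        "tract_prob": 0.5,
        "pev_x": 0.0,
        "pev_y": 0.0,
        "pev_z": 1.0,
        "diameter_um": 4.0,
    }
    base.update(voxels)
    return pd.DataFrame(base)


class TestComputeAlpha:
    def test_parallel(self):
        assert compute_alpha([0, 0, 1]) == pytest.approx(0.0)
        assert sin4_alpha([0, 0, 1]) == pytest.approx(0.0)

    def test_perpendicular(self):
        assert compute_alpha([1, 0, 0]) == pytest.approx(90.0)
        assert sin4_alpha([0, 1, 0]) == pytest.approx(1.0)

    def test_45_degrees(self):
        v = [1, 0, 1]
        assert compute_alpha(v) == pytest.approx(45.0)
        assert sin4_alpha(v) == pytest.approx(0.25)

    def test_sign_flip_invariance(self, rng):
        for _ in range(20):
            v = rng.normal(size=3)
            assert compute_alpha(v) == pytest.approx(compute_alpha(-v), abs=1e-9)

    def test_joint_rotation_invariance(self, rng):
        for _ in range(20):
            v = rng.normal(size=3)
            b0 = rng.normal(size=3)
            R = Rotation.random(random_state=rng).as_matrix()
            assert compute_alpha(v, b0) == pytest.approx(
                compute_alpha(R @ v, R @ b0), abs=1e-8
            )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="non-zero"):
            compute_alpha([0, 0, 0])
        with pytest.raises(ValueError, match="b0"):
            compute_alpha([0, 0, 1], [0, 0, 0])

    def test_unnormalised_inputs_ok(self):
        assert compute_alpha([0, 0, 5], [0, 0, 0.1]) == pytest.approx(0.0)


class TestSelectVoxels:
    def test_all_pass_identity(self):
        tab = _table({"R2": np.full(10, 25.0)})
        out = select_voxels(tab)
        assert len(out) == 10

    def test_boundary_is_strict(self):
        tab = _table({"R2": [25.0, 25.0], "FA": [0.4, 0.41], "tract_prob": [0.5, 0.25]})
        out = select_voxels(tab)
        assert len(out) == 0  # FA == 0.4 excluded; prob == 0.25 excluded
        tab2 = _table({"R2": [25.0], "FA": [0.41], "tract_prob": [0.26]})
        assert len(select_voxels(tab2)) == 1

    def test_against_brute_force_oracle(self, rng):
        n = 2000
        tab = _table(
            {
                "R2": rng.uniform(15, 35, n),
                "FA": rng.uniform(0, 1, n),
                "tract_prob": rng.uniform(0, 1, n),
            }
        )
        survivors = sum(
            1
            for fa, p in zip(tab["FA"], tab["tract_prob"])
            if fa > 0.4 and p > 0.25
        )
        assert len(select_voxels(tab)) == survivors


class TestComputeDbar:
    def test_single_tract(self):
        tab = _table({"R2": np.full(5, 25.0), "diameter_um": 3.7})
        assert compute_dbar(tab) == pytest.approx(3.7)

    def test_weighted_hand_arithmetic(self):
        # 100 voxels at 4 um, 300 voxels at 6 um -> 5.5 um
        tab = _table(
            {
                "R2": np.full(400, 25.0),
                "tract_id": np.repeat([0, 1], [100, 300]),
                "diameter_um": np.repeat([4.0, 6.0], [100, 300]),
            }
        )
        assert compute_dbar(tab) == pytest.approx(5.5, abs=1e-12)

    def test_row_order_invariance(self, rng):
        tab = _table(
            {
                "R2": np.full(400, 25.0),
                "tract_id": np.repeat([0, 1], [100, 300]),
                "diameter_um": np.repeat([4.0, 6.0], [100, 300]),
            }
        )
        shuffled = tab.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert compute_dbar(shuffled) == pytest.approx(compute_dbar(tab), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_dbar(_table({"R2": np.array([])}))


class TestBinBySin4:
    def test_single_bin_single_tract(self):
        # all voxels at sin4 = 0.05 -> one observation in bin 0
        alpha = np.degrees(np.arcsin(0.05**0.25))
        pev_x = np.sin(np.radians(alpha))
        pev_z = np.cos(np.radians(alpha))
        tab = _table({"R2": np.full(50, 25.0), "pev_x": pev_x, "pev_z": pev_z})
        obs = bin_by_sin4(tab)
        assert len(obs) == 1
        assert obs["bin_index"].iloc[0] == 0
        assert obs["n_members"].iloc[0] == 50
        assert obs["bin_sin4_mean"].iloc[0] == pytest.approx(0.05, abs=1e-9)

    def test_upper_edge_closed(self):
        tab = _table({"R2": [25.0], "pev_x": 1.0, "pev_z": 0.0})
        obs = bin_by_sin4(tab)
        assert obs["bin_index"].iloc[0] == 9

    def test_uniform_sin4_multinomial_counts(self, rng):
        """sin4 uniform on [0,1]: each of the 10 bins holds ~10^4 of 10^5."""
        n = 10**5
        s4 = rng.uniform(0, 1, n)
        alpha = np.arcsin(s4**0.25)
        tab = _table(
            {
                "R2": np.full(n, 25.0),
                "pev_x": np.sin(alpha),
                "pev_z": np.cos(alpha),
            }
        )
        obs = bin_by_sin4(tab)
        assert len(obs) == 10
        assert np.all(np.abs(obs["n_members"].to_numpy() - n / 10) < 0.03 * n / 10)

    def test_member_count_preserved(self, default_table):
        obs = bin_by_sin4(default_table)
        assert obs["n_members"].sum() == len(default_table)

    def test_se_definition(self):
        tab = _table({"R2": [24.0, 25.0, 26.0], "pev_x": 1.0, "pev_z": 0.0})
        obs = bin_by_sin4(tab)
        assert obs["R2_se"].iloc[0] == pytest.approx(1.0 / np.sqrt(3))

    def test_per_tract_binning(self, noiseless_table):
        obs = bin_by_sin4(noiseless_table)
        # one diameter per tract carried through
        for tract_id, grp in obs.groupby("tract_id"):
            assert grp["d"].nunique() == 1


class TestFitModel:
    def test_exact_plane_recovery(self, noiseless_table):
        tab = noiseless_table
        d_bar = compute_dbar(tab)
        obs = bin_by_sin4(tab)
        res = fit_model(obs, d_bar, terms=("a1", "a2"))
        a0, a1, a2, _ = TABLE1_FIT3
        assert res.a0 == pytest.approx(a0, abs=1e-9)
        assert res.a1 == pytest.approx(a1, abs=1e-9)
        assert res.a2 == pytest.approx(a2, abs=1e-9)
        assert res.R2_stat == pytest.approx(1.0, abs=1e-12)

    def test_interaction_term_null_when_absent(self, default_table):
        tab = default_table  # generated with a3 = 0
        d_bar = compute_dbar(tab)
        res = fit_model(bin_by_sin4(tab), d_bar, terms=("a1", "a2", "a3"))
        assert abs(res.a3) < 2 * res.se["a3"]

    def test_single_tract_with_a1_rejected(self):
        tab = _table({"R2": np.linspace(20, 30, 40), "pev_x": 1.0, "pev_z": 0.0})
        obs = bin_by_sin4(tab)
        with pytest.raises(ValueError):
            fit_model(obs, 4.0, terms=("a1",))

    def test_too_few_observations_rejected(self):
        tab = _table({"R2": [25.0, 26.0], "pev_x": [1.0, 0.0], "pev_z": [0.0, 1.0]})
        obs = bin_by_sin4(tab)  # 2 observations
        with pytest.raises(ValueError, match="more observations"):
            fit_model(obs, 4.0, terms=("a1", "a2", "a3"))

    def test_adjusted_r2_below_r2(self, default_table):
        d_bar = compute_dbar(default_table)
        res = fit_model(bin_by_sin4(default_table), d_bar)
        assert 0.0 <= res.R2_stat <= 1.0
        assert res.adjR2_stat <= res.R2_stat

    def test_weighted_option_runs(self, default_table):
        d_bar = compute_dbar(default_table)
        obs = bin_by_sin4(default_table)
        res_w = fit_model(obs, d_bar, weighted=True)
        res_u = fit_model(obs, d_bar, weighted=False)
        assert res_w.a2 != res_u.a2  # weighting changes the estimate


class TestModelComparison:
    def test_four_variants(self, default_table):
        d_bar = compute_dbar(default_table)
        results = model_comparison(bin_by_sin4(default_table), d_bar)
        assert [r.included_terms for r in results] == list(MODEL_VARIANTS)

    def test_nested_r2_monotonicity(self, default_table):
        d_bar = compute_dbar(default_table)
        r = model_comparison(bin_by_sin4(default_table), d_bar)
        assert r[0].R2_stat <= r[2].R2_stat <= r[3].R2_stat + 1e-12
        assert r[1].R2_stat <= r[2].R2_stat

    def test_no_orientation_effect_makes_fit2_match_fit3(self, small_tracts):
        tab = generate_voxel_table((24.08, -7.33, 0.0, 0.0), small_tracts, sigma=0.5, seed=3)
        d_bar = compute_dbar(tab)
        r = model_comparison(bin_by_sin4(tab), d_bar)
        assert r[2].R2_stat - r[1].R2_stat < 0.02

    def test_comparison_table_shape(self, default_table):
        d_bar = compute_dbar(default_table)
        table = comparison_table(model_comparison(bin_by_sin4(default_table), d_bar))
        assert list(table["fit_no"]) == [1, 2, 3, 4]
        assert table["sin4_alpha"].isna().iloc[1]
        assert table["d_minus_dbar"].isna().iloc[0]


class TestFullRecoveryProperty:
    def test_mean_recovery_and_ci_coverage(self):
        """Over seeded replicates of the fit-3 truth, mean estimates land
        within 2% and 95% CI coverage stays in [90%, 99%]."""
        from scipy import stats

        truth = TABLE1_FIT3
        n_rep = 100
        est = np.zeros((n_rep, 3))
        cover = np.zeros(3)
        for seed in range(n_rep):
            tab = generate_voxel_table(truth, sigma=1.5, seed=seed)
            sel = select_voxels(tab)
            d_bar = compute_dbar(sel)
            res = fit_model(bin_by_sin4(sel), d_bar, terms=("a1", "a2"))
            est[seed] = (res.a0, res.a1, res.a2)
            tcrit = stats.t.ppf(0.975, res.n_obs - 3)
            for i, name in enumerate(("a0", "a1", "a2")):
                cover[i] += abs(est[seed, i] - truth[i]) <= tcrit * res.se[name]
        rel_err = np.abs(est.mean(axis=0) - truth[:3]) / np.abs(truth[:3])
        assert np.all(rel_err < 0.02)
        assert np.all(cover / n_rep >= 0.90 - 1e-9)
        assert np.all(cover / n_rep <= 0.99 + 1e-9)
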