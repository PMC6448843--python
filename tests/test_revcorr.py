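import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from provoc import (
    Kernel,
    ObserverModel,
    compute_first_order_kernel,
    double_pass_agreement,
    estimate_internal_noise,
    kernel_convergence,
    mixed_anova,
    normalize_kernel,
    read_response_table,
    rm_anova,
    simulate_experiment,
)


def make_frame(a, b, choices, pass_tag="main"):
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    cols = {"participant": "p1", "trial": np.arange(len(a))}
    for j in range(a.shape[1]):
        cols[f"A_{j}"] = a[:, j]
    for j in range(b.shape[1]):
        cols[f"B_{j}"] = b[:, j]
    cols["choice"] = choices
    cols["pass_tag"] = pass_tag
    return pd.DataFrame(cols)


class TestFirstOrderKernel:
    def test_single_trial_log_domain(self):
        frame = make_frame([[2.0]], [[0.5]], ["A"])
        k = compute_first_order_kernel(frame, domain="log")
        assert k.values[0] == pytest.approx(np.log(2.0) - np.log(0.5), abs=1e-9)
        assert k.values[0] == pytest.approx(1.3863, abs=1e-4)

    def test_coin_flip_kernel_near_zero(self):
        rng = np.random.default_rng(0)
        n, k = 10_000, 6
        frame = make_frame(rng.normal(0, 100, (n, k)), rng.normal(0, 100, (n, k)),
                           np.where(rng.random(n) < 0.5, "A", "B"))
        kern = compute_first_order_kernel(frame)
        se = 100.0 * np.sqrt(2.0 / n) * np.sqrt(2.0)  # two means, two intervals
        assert np.all(np.abs(kern.values) < 3 * se)

    def test_template_observer_recovery(self):
        template = np.array([0.1, -0.1, 0.0, 0.2, 1.0, -0.3])
        observer = ObserverModel(template=template, internal_noise_sd=1.0)
        frame = simulate_experiment("case1", observer, n_trials=700, seed=7,
                                    double_pass=0)
        k = normalize_kernel(compute_first_order_kernel(frame))
        r = np.corrcoef(k.values, template)[0, 1]
        assert r > 0.9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_first_order_kernel(make_frame(np.empty((0, 2)), np.empty((0, 2)), []))

    def test_log_domain_rejects_nonpositive(self):
        frame = make_frame([[1.0, -1.0]], [[1.0, 1.0]], ["A"])
        with pytest.raises(ValueError):
            compute_first_order_kernel(frame, domain="log")

    def test_sign_equivariance(self):
        rng = np.random.default_rng(1)
        frame = make_frame(rng.normal(size=(50, 4)), rng.normal(size=(50, 4)),
                           np.where(rng.random(50) < 0.5, "A", "B"))
        k1 = compute_first_order_kernel(frame).values
        flipped = frame.copy()
        flipped["choice"] = np.where(frame["choice"] == "A", "B", "A")
        k2 = compute_first_order_kernel(flipped).values
        assert np.allclose(k1, -k2)

    def test_interval_relabel_invariance(self):
        rng = np.random.default_rng(2)
        frame = make_frame(rng.normal(size=(50, 4)), rng.normal(size=(50, 4)),
                           np.where(rng.random(50) < 0.5, "A", "B"))
        k1 = compute_first_order_kernel(frame).values
        swapped = frame.copy()
        for j in range(4):
            swapped[f"A_{j}"], swapped[f"B_{j}"] = (frame[f"B_{j}"], frame[f"A_{j}"])
        swapped["choice"] = np.where(frame["choice"] == "A", "B", "A")
        k2 = compute_first_order_kernel(swapped).values
        assert np.allclose(k1, k2)


class TestNormalizeKernel:
    def test_basic(self):
        k = normalize_kernel(Kernel(np.array([2.0, -2.0])))
        assert np.allclose(k.values, [0.5, -0.5])
        assert k.normalized

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_kernel(Kernel(np.zeros(3)))

    def test_unit_absolute_sum(self, rng):
        k = normalize_kernel(Kernel(rng.normal(size=9)))
        assert np.sum(np.abs(k.values)) == pytest.approx(1.0, abs=1e-12)


def brute_force_rm_anova(x):
    """Textbook sums-of-squares decomposition via explicit loops."""
    n, s = x.shape
    grand = x.mean()
    ss_seg = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(s))
    ss_subj = sum(s * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(s))
    ss_err = ss_total - ss_seg - ss_subj
    return (ss_seg / (s - 1)) / (ss_err / ((s - 1) * (n - 1)))


class TestRmAnova:
    def test_identical_columns_f_zero(self):
        x = np.tile(np.random.default_rng(0).normal(size=(4, 1)), (1, 5))
        f, _, _ = rm_anova(x)
        assert f == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(size=(5, 7))
            f, (d1, d2), _ = rm_anova(x)
            assert f == pytest.approx(brute_force_rm_anova(x), abs=1e-10)
            assert (d1, d2) == (6, 24)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 7))
        f, (d1, d2), p = rm_anova(x)
        long = pd.DataFrame({
            "y": x.ravel(),
            "subj": np.repeat(np.arange(5), 7),
            "seg": np.tile(np.arange(7), 5),
        })
        ref = pg.rm_anova(data=long, dv="y", within="seg", subject="subj")
        assert f == pytest.approx(ref["F"].iloc[0], abs=1e-9)
        assert p == pytest.approx(ref["p_unc"].iloc[0], abs=1e-9)

    def test_missing_cells_rejected(self):
        x = np.ones((3, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova(x)


class TestMixedAnova:
    def test_identical_groups_interaction_zero(self):
        rows = np.random.default_rng(5).normal(size=(4, 5))
        x = np.vstack([rows, rows])
        labels = ["a"] * 4 + ["b"] * 4
        res = mixed_anova(x, labels)
        assert res["interaction"]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 6))
        labels = np.array(["m"] * 5 + ["n"] * 7)
        res = mixed_anova(x, labels)
        long = pd.DataFrame({
            "y": x.ravel(),
            "subj": np.repeat(np.arange(12), 6),
            "seg": np.tile(np.arange(6), 12),
            "grp": np.repeat(labels, 6),
        })
        ref = pg.mixed_anova(data=long, dv="y", within="seg", subject="subj",
                             between="grp")
        f_seg = ref.loc[ref["Source"] == "seg", "F"].iloc[0]
        f_int = ref.loc[ref["Source"] == "Interaction", "F"].iloc[0]
        assert res["within"]["F"] == pytest.approx(f_seg, abs=1e-9)
        assert res["interaction"]["F"] == pytest.approx(f_int, abs=1e-9)

    def test_small_table_brute_force(self):
        # 4 subjects x 3 segments, 2 groups of 2
        x = np.array([[1.0, 2.0, 3.0], [2.0, 2.5, 3.5],
                      [3.0, 1.0, 2.0], [2.5, 1.5, 2.5]])
        labels = ["g1", "g1", "g2", "g2"]
        res = mixed_anova(x, labels)
        long = pd.DataFrame({
            "y": x.ravel(),
            "subj": np.repeat(np.arange(4), 3),
            "seg": np.tile(np.arange(3), 4),
            "grp": np.repeat(labels, 3),
        })
        ref = pg.mixed_anova(data=long, dv="y", within="seg", subject="subj",
                             between="grp")
        f_int = ref.loc[ref["Source"] == "Interaction", "F"].iloc[0]
        assert res["interaction"]["F"] == pytest.approx(f_int, abs=1e-10)

    def test_permutation_null_interaction(self):
        # permuting group labels: mean interaction F ~ E[F] = df2/(df2-2)
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 4))
        fs = []
        for _ in range(200):
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            fs.append(mixed_anova(x, labels)["interaction"]["F"])
        assert 0.6 < np.mean(fs) < 1.6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            mixed_anova(np.ones((3, 4)), ["a", "a", "b"])


class TestDoublePass:
    def test_identical_choices(self):
        frame = pd.concat([
            make_frame(np.ones((5, 2)), np.zeros((5, 2)), ["A"] * 5, "pass1"),
            make_frame(np.ones((5, 2)), np.zeros((5, 2)), ["A"] * 5, "pass2"),
        ])
        agreement, bias = double_pass_agreement(frame)
        assert agreement == 1.0
        assert bias == 1.0

    def test_reversed_choices(self):
        frame = pd.concat([
            make_frame(np.ones((4, 2)), np.zeros((4, 2)), ["A"] * 4, "pass1"),
            make_frame(np.ones((4, 2)), np.zeros((4, 2)), ["B"] * 4, "pass2"),
        ])
        agreement, bias = double_pass_agreement(frame)
        assert agreement == 0.0
        assert bias == 0.5

    def test_noiseless_observer_full_agreement(self):
        observer = ObserverModel(template=np.array([1.0, -1.0, 0.5]))
        frame = simulate_experiment("case1", observer, n_trials=33, seed=3,
                                    double_pass=33)
        agreement, _ = double_pass_agreement(frame)
        assert agreement == 1.0

    def test_unpaired_rejected(self):
        frame = make_frame(np.ones((3, 2)), np.zeros((3, 2)), ["A"] * 3, "pass1")
        with pytest.raises(ValueError):
            double_pass_agreement(frame)


class TestInternalNoise:
    def test_noiseless_limit(self):
        est = estimate_internal_noise(1.0, 0.5)
        assert est.sigma < 0.05
        assert est.reliable

    def test_sigma_one_recovery(self):
        template = np.array([0.1, -0.1, 0.0, 0.2, 1.0, -0.3])
        observer = ObserverModel(template=template, internal_noise_sd=1.0)
        estimates = []
        for s in range(200):
            frame = simulate_experiment("case2", observer, n_trials=33,
                                        seed=1000 + s, double_pass=33)
            agreement, bias = double_pass_agreement(frame)
            estimates.append(estimate_internal_noise(agreement, bias).sigma)
        assert 0.8 <= np.mean(estimates) <= 1.2

    def test_below_chance_flagged(self):
        est = estimate_internal_noise(0.3, 0.5)
        assert not est.reliable

    def test_input_validation(self):
        with pytest.raises(ValueError):
            estimate_internal_noise(1.5, 0.5)


class TestKernelConvergence:
    def test_final_point_is_one(self):
        observer = ObserverModel(template=np.array([0.0, 0.5, 1.0, -0.5]),
                                 internal_noise_sd=1.0)
        frame = simulate_experiment("case1", observer, n_trials=100, seed=5,
                                    double_pass=0)
        curve = kernel_convergence(frame, step=20)
        assert curve[-1][0] == 100
        assert curve[-1][1] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_convergence_trend(self):
        template = np.array([0.1, -0.1, 0.0, 0.2, 1.0, -0.3])
        observer = ObserverModel(template=template, internal_noise_sd=1.0)
        wins = 0
        reps = 100
        for s in range(reps):
            frame = simulate_experiment("case1", observer, n_trials=700,
                                        seed=2000 + s, double_pass=0)
            curve = dict((int(n), r) for n, r in kernel_convergence(frame, step=70))
            if curve[350] > curve[70]:
                wins += 1
        assert wins >= 0.95 * reps

    def test_degenerate_kernel_flagged(self):
        frame = make_frame(np.ones((10, 3)), np.ones((10, 3)), ["A"] * 10)
        with pytest.raises(ValueError, match="degenerate"):
            kernel_convergence(frame, step=5)

    def test_too_few_trials_rejected(self):
        frame = make_frame(np.ones((3, 2)), np.zeros((3, 2)), ["A"] * 3)
        with pytest.raises(ValueError):
            kernel_convergence(frame, step=2)


class TestResponseTableIO:
    def test_roundtrip_with_column_map(self, tmp_path):
        observer = ObserverModel(template=np.array([1.0, -1.0]))
        frame = simulate_experiment("case1", observer, n_trials=10, seed=1,
                                    double_pass=0)
        frame = frame.rename(columns={"choice": "resp", "participant": "subj"})
        path = tmp_path / "responses.csv"
        frame.to_csv(path, index=False)
        back = read_response_table(path, column_map={"resp": "choice",
                                                     "subj": "participant"})
        assert "choice" in back.columns
        k = compute_first_order_kernel(back)
        assert len(k.values) == 2
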