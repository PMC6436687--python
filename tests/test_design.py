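"""PC-score models, factorial design points, greedy selection and quotas."""

import numpy as np
import pandas as pd
import pytest

from famsieve.design import (
    DesignPoint,
    StratumError,
    allocate_quota,
    design_points,
    filter_eligible,
    pc_scores,
    select_samples,
    standardize,
)


def gaussian_table(seed, n=40, p=5):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        columns=[f"v{j}" for j in range(p)],
        index=[f"S{i:03d}" for i in range(n)],
    )


class TestPcScores:
    def test_perfectly_correlated_variables_load_on_pc1(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        scores = pc_scores(df)
        assert np.allclose(scores["PC2"], 0, atol=1e-10)  # PC1 explains 100%
        assert scores["PC1"].std() > 0

    def test_scores_zero_mean(self):
        scores = pc_scores(gaussian_table(1))
        assert np.allclose(scores.mean(), 0, atol=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        """Scores agree with a full eigendecomposition of the covariance."""
        df = gaussian_table(2, n=5, p=3)
        scores = pc_scores(df)
        z = standardize(df).to_numpy()
        cov = z.T @ z / len(z)
        w, vecs = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1][:2]
        comps = vecs[:, order].T
        for k in range(2):
            if comps[k, np.argmax(np.abs(comps[k]))] < 0:
                comps[k] = -comps[k]
        oracle = z @ comps.T
        assert np.allclose(scores.to_numpy(), oracle, atol=1e-8)

    def test_missing_values_imputed_to_mean(self):
        df = gaussian_table(3)
        df.iloc[0, 0] = np.nan
        scores = pc_scores(df)
        assert np.isfinite(scores.to_numpy()).all()

    def test_degenerate_strata_rejected(self):
        with pytest.raises(StratumError, match="3 samples"):
            pc_scores(gaussian_table(4, n=2), stratum="tiny")
        constant = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [3.0, 1, 2, 5]})
        with pytest.raises(StratumError, match="variables"):
            pc_scores(constant, stratum="flat")


class TestDesignPoints:
    def test_baseline_is_five_points(self):
        pts = design_points("baseline", level=1.5)
        assert len(pts) == 5
        roles = [p.role for p in pts]
        assert roles.count("corner") == 4 and roles.count("center") == 1

    def test_center_at_origin(self):
        center = [p for p in design_points("baseline") if p.role == "center"][0]
        assert (center.x, center.y) == (0.0, 0.0)

    def test_reinforced_is_twentyfive_points(self):
        pts = design_points("reinforced", level=2.0)
        assert len(pts) == 25
        roles = [p.role for p in pts]
        assert roles.count("corner") == 4
        assert roles.count("sub_corner") == 16
        assert roles.count("center") + roles.count("sub_center") == 5

    def test_sub_corners_at_half_level(self):
        pts = design_points("reinforced", level=2.0)
        subs = {(p.x, p.y) for p in pts if p.role == "sub_corner"}
        assert (3.0, 3.0) in subs and (1.0, 1.0) in subs

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            design_points("baseline", level=0)
        with pytest.raises(ValueError):
            design_points("hexagonal")


class TestSelectSamples:
    def test_samples_exactly_at_points(self):
        pts = design_points("baseline", 1.0)
        scores = pd.DataFrame(
            {"PC1": [p.x for p in pts], "PC2": [p.y for p in pts]},
            index=[f"S{i}" for i in range(5)],
        )
        sel = select_samples(scores, pts)
        assert list(sel["sample"]) == [f"S{i}" for i in range(5)]
        assert np.allclose(sel["distance"], 0)

    def test_all_selected_when_counts_match(self):
        scores = pd.DataFrame(
            {"PC1": np.arange(5.0), "PC2": np.zeros(5)},
            index=[f"S{i}" for i in range(5)],
        )
        sel = select_samples(scores, design_points("baseline", 1.0))
        assert set(sel["sample"]) == set(scores.index)

    def test_greedy_trace_with_contested_sample(self):
        """Two points nearest to the same sample: first point wins it, the
        second takes the runner-up (hand-traced)."""
        pts = [DesignPoint(0.0, 0.0, "center"), DesignPoint(0.1, 0.0, "corner")]
        scores = pd.DataFrame(
            {"PC1": [0.05, 1.0], "PC2": [0.0, 0.0]}, index=["near", "far"]
        )
        sel = select_samples(scores, pts)
        assert list(sel["sample"]) == ["near", "far"]

    def test_never_selects_twice(self):
        rng = np.random.default_rng(7)
        scores = pd.DataFrame(
            rng.normal(size=(30, 2)),
            columns=["PC1", "PC2"],
            index=[f"S{i}" for i in range(30)],
        )
        sel = select_samples(scores, design_points("reinforced", 1.5))
        assert sel["sample"].is_unique
        assert len(sel) == 25

    def test_partial_selection_warns(self):
        scores = pd.DataFrame(
            {"PC1": [0.0, 1.0], "PC2": [0.0, 0.0]}, index=["a", "b"]
        )
        with pytest.warns(UserWarning, match="exhausted"):
            sel = select_samples(scores, design_points("baseline", 1.0))
        assert len(sel) == 2

    def test_diversity_exceeds_random_selection(self):
        """Design-point selection spans a larger score hull than random picks."""
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(11)
        scores = pd.DataFrame(
            rng.normal(size=(200, 2)),
            columns=["PC1", "PC2"],
            index=[f"S{i:03d}" for i in range(200)],
        )
        sel = select_samples(scores, design_points("baseline", 1.5))
        area = ConvexHull(scores.loc[sel["sample"]].to_numpy()).volume
        random_areas = [
            ConvexHull(
                scores.iloc[rng.choice(200, size=5, replace=False)].to_numpy()
            ).volume
            for _ in range(200)
        ]
        assert area >= np.mean(random_areas)


class TestAllocateQuota:
    STRATA = [f"M{i:02d}" for i in range(15)]

    def test_baseline_half_spread_evenly(self):
        q = allocate_quota(
            total=300,
            strata=self.STRATA,
            reinforced_strata=self.STRATA[:3],
            per_stratum_base=5,
        )
        assert int(q["quota"].sum()) == 300
        baseline = q[~q["stratum"].isin(self.STRATA[:3])]
        assert (baseline["quota"] == 5).all()  # 12 strata x 2 genders x 5 = 120
        by_gender = q.groupby("gender")["quota"].sum()
        assert (by_gender == 150).all()

    def test_single_reinforced_stratum_takes_remainder(self):
        q = allocate_quota(
            total=300,
            strata=self.STRATA,
            reinforced_strata=[self.STRATA[0]],
            per_stratum_base=5,
        )
        top = q[q["stratum"] == self.STRATA[0]]["quota"].sum()
        assert top == 2 * 5 + 150

    def test_gender_balance_within_stratum(self):
        q = allocate_quota(300, self.STRATA, self.STRATA[:3], 5)
        pivot = q.pivot(index="stratum", columns="gender", values="quota")
        assert (pivot["female"] == pivot["male"]).all()

    def test_weights_respected(self):
        q = allocate_quota(
            300,
            self.STRATA,
            self.STRATA[:2],
            5,
            weights={self.STRATA[0]: 2.0, self.STRATA[1]: 1.0},
        )
        a = q[q["stratum"] == self.STRATA[0]]["quota"].sum()
        b = q[q["stratum"] == self.STRATA[1]]["quota"].sum()
        assert a - 10 == 2 * (b - 10)

    def test_infeasible_config(self):
        with pytest.raises(ValueError):
            allocate_quota(299, self.STRATA, [], 5)  # odd total
        with pytest.raises(ValueError):
            allocate_quota(100, self.STRATA, [], 5)  # baseline exceeds total


class TestEligibility:
    def test_declarative_row_filter(self):
        df = pd.DataFrame(
            {"age": [85, 70, 90], "cancer": [0, 0, 1]}, index=["a", "b", "c"]
        )
        kept = filter_eligible(df, {"age": (">=", 80), "cancer": ("==", 0)})
        assert list(kept.index) == ["a"]
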