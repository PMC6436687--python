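"""The successive filtering strategy and its relaxations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from famsieve.filtering import (
    FilterConfig,
    local_control_filter,
    public_maf_filter,
    relaxation_matrix,
    run_pipeline,
    segregation_filter,
    unknown_status_filter,
)
from famsieve.variants import FrequencyResource, GenotypeMatrix, VariantKey

from conftest import make_matrix


def resource(name, af_by_key, mode="maf_threshold", threshold=0.01, carriers=None):
    return FrequencyResource(
        name=name,
        mode=mode,
        threshold=threshold,
        entries=af_by_key,
        carrier_counts=carriers or {},
        allele_counts={k: 1 for k in af_by_key},
    )


V = [VariantKey("chr1", 1000 + i, "A", "T") for i in range(10)]


class TestPublicMafFilter:
    def test_common_in_one_of_six_removed(self):
        resources = [resource(f"r{i}", {}) for i in range(5)]
        resources.append(resource("r5", {V[0]: 0.02}))
        assert public_maf_filter([V[0], V[1]], resources, 0.01) == [V[1]]

    def test_absent_everywhere_retained(self):
        assert public_maf_filter([V[0]], [resource("r", {})], 0.01) == [V[0]]

    def test_zero_threshold_removes_any_presence(self):
        res = resource("r", {V[0]: 0.0001})
        assert public_maf_filter([V[0]], [res], 0.0) == []

    def test_folded_maf(self):
        res = resource("r", {V[0]: 0.999})
        assert public_maf_filter([V[0]], [res], 0.01, folded=False) == []
        assert public_maf_filter([V[0]], [res], 0.01, folded=True) == [V[0]]


class TestLocalControlFilter:
    def test_presence_removes_single_allele(self):
        ctrl = resource("ctrl", {V[0]: 0.001})
        assert local_control_filter([V[0], V[1]], ctrl, "presence", 0) == [V[1]]

    def test_maf_threshold_retains_rare(self):
        ctrl = resource("ctrl", {V[0]: 0.005})
        assert local_control_filter([V[0]], ctrl, "maf_threshold", 0.01) == [V[0]]

    def test_max_carriers_boundary(self):
        ctrl = resource(
            "ctrl", {V[0]: 0.01, V[1]: 0.01}, carriers={V[0]: 1, V[1]: 2}
        )
        assert local_control_filter([V[0]], ctrl, "max_carriers", 1) == [V[0]]
        assert local_control_filter([V[1]], ctrl, "max_carriers", 1) == []

    def test_genotype_matrix_control(self):
        ctrl = make_matrix([[0, 1], [0, 0]], ["C1", "C2"])
        kept = local_control_filter(ctrl.variants, ctrl, "presence", 0)
        assert kept == [ctrl.variants[1]]


class TestSegregationFilter:
    def test_strict_requires_all_affected(self):
        m = make_matrix([[1, 1, 1], [1, 0, 1]], ["A1", "A2", "A3"])
        assert segregation_filter(m, ["A1", "A2", "A3"], 0) == [m.variants[0]]

    def test_phenocopy_allowance(self):
        # 11 affected, p=2: retained iff >= 9 carriers
        carriers9 = [1] * 9 + [0] * 2
        carriers8 = [1] * 8 + [0] * 3
        m = make_matrix([carriers9, carriers8], [f"A{i}" for i in range(11)])
        assert segregation_filter(m, m.samples, 2) == [m.variants[0]]

    def test_missing_consumes_phenocopy_allowance(self):
        m = make_matrix([[1, -1, 1]], ["A1", "A2", "A3"])
        assert segregation_filter(m, m.samples, 0) == []
        assert segregation_filter(m, m.samples, 1) == m.variants
        assert segregation_filter(m, m.samples, 0, missing_as_noncarrier=False) == m.variants

    def test_matches_exhaustive_enumeration(self):
        """p=1 on all 2^3 affected carrier patterns equals brute force."""
        patterns = list(itertools.product([0, 1], repeat=3))
        m = make_matrix(patterns, ["A1", "A2", "A3"])
        kept = segregation_filter(m, m.samples, 1)
        expected = [
            m.variants[i] for i, pat in enumerate(patterns) if pat.count(0) <= 1
        ]
        assert kept == expected


class TestUnknownStatusFilter:
    def test_full_allowance_is_noop(self):
        m = make_matrix([[1, 1], [0, 1]], ["U1", "U2"])
        assert unknown_status_filter(m, m.samples, 2) == m.variants

    def test_zero_allowance(self):
        m = make_matrix([[0, 1]], ["U1", "U2"])
        assert unknown_status_filter(m, m.samples, 0) == []

    def test_nine_of_twentyseven_boundary(self):
        ten = [1] * 10 + [0] * 17
        nine = [1] * 9 + [0] * 18
        m = make_matrix([ten, nine], [f"U{i}" for i in range(27)])
        assert unknown_status_filter(m, m.samples, 9) == [m.variants[1]]


class TestRelaxationMatrix:
    def _instance(self, seed, n_variants=50, n_affected=4, n_controls=6):
        rng = np.random.default_rng(seed)
        fam = make_matrix(
            rng.integers(0, 2, size=(n_variants, n_affected)),
            [f"A{i}" for i in range(n_affected)],
        )
        ctrl = make_matrix(
            (rng.random((n_variants, n_controls)) < 0.3).astype(int),
            [f"C{i}" for i in range(n_controls)],
        )
        return fam, ctrl

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_recount(self, seed):
        fam, ctrl = self._instance(seed)
        rm = relaxation_matrix(fam, fam.samples, ctrl, p_max=3, c_max=4)
        for p in range(4):
            for c in range(5):
                expected = 0
                for i, v in enumerate(fam.variants):
                    non_aff = int((fam.dosage[i] == 0).sum())
                    j = ctrl.variant_index(v)
                    carriers = int((ctrl.dosage[j] > 0).sum())
                    if non_aff <= p and carriers <= c:
                        expected += 1
                assert rm[p, c] == expected

    def test_corner_equals_total(self):
        fam, ctrl = self._instance(3)
        rm = relaxation_matrix(fam, fam.samples, ctrl, p_max=4, c_max=6)
        assert rm[4, 6] == fam.n_variants

    def test_monotone_rows_and_columns(self):
        fam, ctrl = self._instance(4)
        rm = relaxation_matrix(fam, fam.samples, ctrl, p_max=3, c_max=3)
        grid = rm.counts.to_numpy()
        assert (np.diff(grid, axis=0) >= 0).all()
        assert (np.diff(grid, axis=1) >= 0).all()


class TestRunPipeline:
    def _inputs(self):
        # 4 samples: 3 affected + 1 unknown; 5 variants
        fam = make_matrix(
            [
                [1, 1, 1, 0],  # v0: perfect segregation, absent in control
                [1, 1, 1, 0],  # v1: common in a public resource
                [1, 1, 1, 1],  # v2: present in control
                [1, 0, 1, 0],  # v3: one affected non-carrier
                [0, 0, 1, 0],  # v4: fails segregation badly
            ],
            ["A1", "A2", "A3", "U1"],
        )
        ctrl = make_matrix(
            [[0, 0], [0, 0], [1, 0], [0, 0], [0, 0]], ["C1", "C2"]
        )
        public = resource("1000g", {fam.variants[1]: 0.2})
        return fam, ctrl, public

    def test_strict_waterfall(self):
        fam, ctrl, public = self._inputs()
        res = run_pipeline(
            FilterConfig(), fam, [public], ctrl, affected=["A1", "A2", "A3"]
        )
        assert res.candidates == [fam.variants[0]]
        counts = [n for _, n in res.steps]
        assert counts == sorted(counts, reverse=True)  # waterfall monotone
        assert res.step_counts["public_maf"] == 4
        assert res.step_counts["local_control"] == 3

    def test_matches_relaxation_matrix_origin(self):
        fam, ctrl, public = self._inputs()
        affected = ["A1", "A2", "A3"]
        res = run_pipeline(FilterConfig(), fam, [public], ctrl, affected=affected)
        pre = fam.subset_variants(
            public_maf_filter(fam.variants, [public], 0.01)
        )
        rm = relaxation_matrix(pre, affected, ctrl, p_max=2, c_max=2)
        assert rm[0, 0] == len(res.candidates)

    def test_relaxed_supersets_strict(self):
        fam, ctrl, public = self._inputs()
        affected = ["A1", "A2", "A3"]
        strict = set(
            run_pipeline(FilterConfig(), fam, [public], ctrl, affected).candidates
        )
        relaxed = set(
            run_pipeline(
                FilterConfig(
                    max_phenocopies=1,
                    local_mode="max_carriers",
                    max_control_carriers=1,
                ),
                fam,
                [public],
                ctrl,
                affected,
            ).candidates
        )
        assert strict <= relaxed
        assert fam.variants[3] in relaxed  # phenocopy allowance admits v3

    def test_unknown_status_step(self):
        fam, ctrl, public = self._inputs()
        res = run_pipeline(
            FilterConfig(max_phenocopies=1, max_unknown_carriers=0),
            fam,
            [public],
            None,
            affected=["A1", "A2", "A3"],
            unknown_ids=["U1"],
        )
        assert fam.variants[2] not in res.candidates  # carried by U1

    def test_empty_input(self):
        fam, ctrl, public = self._inputs()
        empty = fam.subset_variants(np.zeros(5, dtype=bool))
        res = run_pipeline(FilterConfig(), empty, [public], ctrl, ["A1", "A2", "A3"])
        assert res.candidates == []
        assert all(n == 0 for _, n in res.steps)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_filters_are_order_invariant(self, seed):
        """Applying the per-variant filters in any order yields the same set."""
        rng = np.random.default_rng(seed)
        n = 30
        fam = make_matrix(
            rng.integers(0, 2, size=(n, 3)), ["A1", "A2", "A3"]
        )
        ctrl = make_matrix(
            (rng.random((n, 4)) < 0.2).astype(int), [f"C{i}" for i in range(4)]
        )
        public = resource(
            "pub",
            {
                fam.variants[i]: float(rng.random())
                for i in rng.choice(n, size=10, replace=False)
            },
        )
        filters = {
            "public": lambda vs: set(public_maf_filter(list(vs), [public], 0.01)),
            "local": lambda vs: set(local_control_filter(list(vs), ctrl, "presence", 0)),
            "segregation": lambda vs: set(
                segregation_filter(fam, fam.samples, 1)
            ) & set(vs),
        }
        results = []
        for order in itertools.permutations(filters):
            vs = set(fam.variants)
            for name in order:
                vs = filters[name](vs)
            results.append(vs)
        assert all(r == results[0] for r in results)
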