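import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stagespec.expression import GroupScheme, SampleGroup
from stagespec.screen import (
    ScreenError,
    compare_reference_stats,
    screen,
    screen_oracle,
    summarize,
)
from tests.conftest import make_matrix, random_matrix


def verdicts(results):
    return {r.gene_id: r.selected for r in results}


class TestScreenVerdicts:
    def test_gene_silent_everywhere_else_is_selected(self, oyster_scheme, oyster_samples):
        rows = {"g1": [100.0, 80.0] + [0.0] * 8}
        results = screen(make_matrix(rows, oyster_samples), oyster_scheme)
        assert results[0].selected
        assert results[0].reference_level == 100.0

    def test_exact_strict_boundary_is_rejected(self, oyster_scheme, oyster_samples):
        # One strict sample at exactly 20% of R=100: "less than 20%" is strict.
        rows = {"g1": [100.0, 50.0, 0.0, 0.0, 20.0, 0.0, 0.0, 0.0, 0.0, 0.0]}
        results = screen(make_matrix(rows, oyster_samples), oyster_scheme)
        assert not results[0].selected
        assert results[0].first_failing_group == "other"

    def test_just_below_strict_boundary_is_selected(self, oyster_scheme, oyster_samples):
        rows = {"g1": [100.0, 50.0, 0.0, 0.0, 19.999, 0.0, 0.0, 0.0, 0.0, 0.0]}
        assert screen(make_matrix(rows, oyster_samples), oyster_scheme)[0].selected

    def test_exact_relaxed_boundary_is_rejected(self, oyster_scheme, oyster_samples):
        rows = {"g1": [100.0, 50.0, 70.0, 0.0] + [0.0] * 6}
        results = screen(make_matrix(rows, oyster_samples), oyster_scheme)
        assert not results[0].selected
        assert results[0].first_failing_group == "late_umbo"

    def test_zero_reference_level_excluded_with_nan_ratios(
        self, oyster_scheme, oyster_samples
    ):
        rows = {"g1": [0.0, 0.0] + [5.0] * 8}
        result = screen(make_matrix(rows, oyster_samples), oyster_scheme)[0]
        assert not result.selected
        assert result.first_failing_group == "reference"
        assert all(math.isnan(v) for v in result.worst_ratio_per_group.values())

    def test_all_zero_gene_never_selected(self, oyster_scheme, oyster_samples):
        rows = {"g1": [0.0] * 10}
        assert not screen(make_matrix(rows, oyster_samples), oyster_scheme)[0].selected

    def test_reference_stat_max_uses_larger_reference_sample(
        self, oyster_scheme, oyster_samples
    ):
        # Strict sample at 15: below 20% of max(P1,P2)=100 but not of min=50.
        rows = {"g1": [50.0, 100.0, 0.0, 0.0, 15.0] + [0.0] * 5}
        matrix = make_matrix(rows, oyster_samples)
        assert screen(matrix, oyster_scheme)[0].selected
        assert not screen(
            matrix, oyster_scheme.replace(reference_stat="min")
        )[0].selected

    def test_missing_scheme_sample_errors(self, oyster_scheme):
        matrix = make_matrix({"g1": [1.0, 2.0]}, ["P1", "P2"])
        with pytest.raises(ScreenError, match="LU1"):
            screen(matrix, oyster_scheme)

    def test_empty_matrix_yields_empty_results(self, oyster_scheme, oyster_samples):
        matrix = make_matrix({}, oyster_samples)
        assert len(screen(matrix, oyster_scheme)) == 0


class TestSummarize:
    def test_fraction_to_four_decimals(self, oyster_scheme, oyster_samples):
        selected = {"g%d" % i: [100.0, 80.0] + [0.0] * 8 for i in range(59)}
        rejected = {
            "b%d" % i: [100.0] * 10 for i in range(27902 - 59)
        }
        matrix = make_matrix({**selected, **rejected}, oyster_samples)
        summary = summarize(screen(matrix, oyster_scheme))
        assert summary.n_genes_total == 27902
        assert summary.n_selected == 59
        assert round(summary.fraction_selected, 4) == 0.0021

    def test_empty_results_fraction_is_nan(self, oyster_scheme, oyster_samples):
        summary = summarize(screen(make_matrix({}, oyster_samples), oyster_scheme))
        assert summary.n_genes_total == 0
        assert math.isnan(summary.fraction_selected)

    def test_one_of_three(self, oyster_scheme, oyster_samples):
        rows = {
            "g1": [100.0, 80.0] + [0.0] * 8,
            "g2": [100.0] * 10,
            "g3": [0.0] * 10,
        }
        summary = summarize(screen(make_matrix(rows, oyster_samples), oyster_scheme))
        assert summary.n_selected == 1
        assert summary.fraction_selected == pytest.approx(1 / 3)

    def test_first_failure_counts_cover_all_rejections(
        self, oyster_scheme, oyster_samples
    ):
        rng = np.random.default_rng(5)
        matrix = random_matrix(rng, 100, oyster_samples)
        summary = summarize(screen(matrix, oyster_scheme))
        assert (
            sum(summary.first_failures_per_group.values())
            == summary.n_genes_total - summary.n_selected
        )


class TestOracleEquivalence:
    def test_seeded_random_matrix_matches_oracle(self, oyster_scheme, oyster_samples):
        rng = np.random.default_rng(42)
        matrix = random_matrix(rng, 200, oyster_samples)
        assert verdicts(screen(matrix, oyster_scheme)) == verdicts(
            screen_oracle(matrix, oyster_scheme)
        )

    @pytest.mark.parametrize("stat", ["max", "min", "mean"])
    def test_oracle_agrees_for_every_reference_stat(
        self, stat, oyster_scheme, oyster_samples
    ):
        rng = np.random.default_rng(7)
        matrix = random_matrix(rng, 50, oyster_samples)
        scheme = oyster_scheme.replace(reference_stat=stat)
        fast, slow = screen(matrix, scheme), screen_oracle(matrix, scheme)
        for a, b in zip(fast, slow):
            assert a.selected == b.selected
            assert a.reference_level == pytest.approx(b.reference_level)
            assert a.first_failing_group == b.first_failing_group


# Module-level scheme for the hypothesis properties (function-scoped pytest
# fixtures don't mix with @given).
SCHEME = GroupScheme(
    groups=(
        SampleGroup("pediveliger", ("P1", "P2"), "reference"),
        SampleGroup("late_umbo", ("LU1", "LU2"), "relaxed"),
        SampleGroup("other", ("E", "U1", "S", "J", "Gill", "Mantle"), "strict"),
    )
)
SAMPLES = list(SCHEME.all_samples())


@st.composite
def gene_rows(draw):
    n_samples = 10
    return draw(
        st.lists(
            st.one_of(
                st.just(0.0),
                st.floats(
                    min_value=0.0,
                    max_value=1e6,
                    allow_nan=False,
                    allow_infinity=False,
                ),
            ),
            min_size=n_samples,
            max_size=n_samples,
        )
    )


class TestScreenProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        c=st.floats(min_value=1e-6, max_value=1e6, allow_nan=False),
    )
    def test_scale_invariance(self, seed, c):
        # Continuous random values: genes never sit exactly on the ratio
        # boundary, where scale invariance is not meaningful in floats.
        rng = np.random.default_rng(seed)
        matrix = random_matrix(rng, 10, SAMPLES)
        scaled = make_matrix(
            {
                g: [v * c for v in matrix.values.loc[g]]
                for g in matrix.gene_ids
            },
            SAMPLES,
        )
        assert verdicts(screen(matrix, SCHEME)) == verdicts(screen(scaled, SCHEME))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(row=gene_rows(), idx=st.integers(min_value=2, max_value=9))
    def test_decreasing_non_reference_never_deselects(self, row, idx):
        before = screen(make_matrix({"g": row}, SAMPLES), SCHEME)[0]
        lowered = list(row)
        lowered[idx] = lowered[idx] / 2.0
        after = screen(make_matrix({"g": lowered}, SAMPLES), SCHEME)[0]
        if before.selected:
            assert after.selected

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_selected_set_grows_with_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        matrix = random_matrix(rng, 30, SAMPLES)
        tight = set(screen(matrix, SCHEME).selected_ids())
        loose = set(
            screen(
                matrix,
                SCHEME.replace(strict_threshold=0.5, relaxed_threshold=0.9),
            ).selected_ids()
        )
        assert tight <= loose


class TestDiagnostics:
    def test_reference_stat_comparison_localizes_difference(
        self, oyster_scheme, oyster_samples
    ):
        # Selected under max but not under min: the diagnostic must name it.
        rows = {"g1": [50.0, 100.0, 0.0, 0.0, 15.0] + [0.0] * 5}
        table = compare_reference_stats(make_matrix(rows, oyster_samples), oyster_scheme)
        by_stat = table.set_index("reference_stat")
        assert by_stat.at["max", "n_selected"] == 1
        assert by_stat.at["min", "n_selected"] == 0
        assert "g1" in by_stat.at["min", "lost_vs_configured"]
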