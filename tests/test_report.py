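import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comoyld import (
    SimulationConfig,
    SynthSpec,
    aggregate,
    generate_registry,
    percent_change,
    percentile_ci,
    ranking_changes,
    run_stratum,
    stratum_slice,
)


class TestPercentChange:
    @pytest.mark.parametrize(
        "unadjusted, adjusted, printed",
        [(2285.6, 2029.8, -11.2), (139.9, 120.6, -13.8)],
    )
    def test_published_all_age_and_group_cells(self, unadjusted, adjusted, printed):
        assert round(percent_change(unadjusted, adjusted), 1) == printed

    def test_identity_is_zero(self):
        assert percent_change(123.4, 123.4) == 0.0

    def test_zero_unadjusted_is_undefined(self):
        assert math.isnan(percent_change(0.0, 5.0))

    @given(
        st.floats(1e-6, 1e6),
        st.floats(0.0, 1e6),
        st.floats(1e-6, 1e6),
    )
    def test_scale_invariance(self, unadjusted, adjusted, c):
        base = percent_change(unadjusted, adjusted)
        scaled = percent_change(c * unadjusted, c * adjusted)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestPercentileCi:
    def test_constant_values_give_degenerate_interval(self):
        assert percentile_ci([4.2] * 10, 0.95) == (4.2, 4.2)

    def test_linear_interpolation_on_integer_sequence(self):
        lo, hi = percentile_ci(list(range(1, 1001)), 0.95)
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    @pytest.mark.parametrize("bad_level", [0.0, 1.0, -0.5])
    def test_rejects_degenerate_level(self, bad_level):
        with pytest.raises(ValueError):
            percentile_ci([1.0, 2.0], bad_level)

    def test_rejects_fewer_than_two_values(self):
        with pytest.raises(ValueError):
            percentile_ci([1.0], 0.95)


@pytest.fixture(scope="module")
def small_run():
    """A 2-cause × 2-sequela registry run through the engine on all strata."""
    spec = SynthSpec(
        causes_per_group=2, sequelae_per_cause=2, seed=21,
        base_prevalence_per_1000=20.0,
    )
    reg = generate_registry(spec)
    cfg = SimulationConfig(n_simulants=400, n_repetitions=12, master_seed=4)
    results = [
        run_stratum(stratum_slice(reg, s), cfg, s) for s in reg.strata()
    ]
    return reg, results


class TestAggregate:
    def test_additivity_across_levels(self, small_run):
        """Sequela→cause→group→total sums agree for both rate columns."""
        reg, results = small_run
        frames = {
            level: aggregate(results, reg, level)
            for level in ("sequela", "cause", "group", "total")
        }
        for col in ("unadjusted_per_1000", "adjusted_per_1000",
                    "prevalence_per_1000"):
            per_stratum = {
                level: frames[level].groupby(["sex", "age_group", "year"])[col].sum()
                for level in frames
            }
            base = per_stratum["sequela"]
            for level in ("cause", "group", "total"):
                assert np.allclose(per_stratum[level], base, atol=1e-9)

    def test_group_with_single_cause_equals_cause_row(self, small_run):
        reg, results = small_run
        one = [results[0]]
        cause = aggregate(one, reg, "cause")
        group = aggregate(one, reg, "group")
        mds_causes = cause[cause["key"].str.startswith("mds")]
        mds_group = group[group["key"] == "MDs"]
        assert mds_group["unadjusted_per_1000"].iloc[0] == pytest.approx(
            mds_causes["unadjusted_per_1000"].sum(), abs=1e-9
        )

    def test_ci_bounds_bracket_point_estimate(self, small_run):
        reg, results = small_run
        frame = aggregate(results, reg, "total")
        assert (frame["ci_low"] <= frame["adjusted_per_1000"] + 1e-9).all()
        assert (frame["adjusted_per_1000"] <= frame["ci_high"] + 1e-9).all()
        assert (frame["pct_change"] <= 0.0).all()  # correction can only lower

    def test_ci_requires_retained_rep_means(self, small_run):
        import dataclasses

        reg, results = small_run
        stripped = dataclasses.replace(results[0], rep_means=None)
        with pytest.raises(ValueError, match="rep_means"):
            aggregate([stripped], reg, "cause", ci=True)
        frame = aggregate([stripped], reg, "cause", ci=False)
        assert frame["ci_low"].isna().all()

    def test_unweighted_margin_is_flagged_and_averaged(self, small_run):
        reg, results = small_run
        frame = aggregate(results, reg, "total", margins=("age_group",))
        assert set(frame["weighting"]) == {"unweighted"}
        assert set(frame["age_group"]) == {"all"}
        per_stratum = aggregate(results, reg, "total")
        for _, row in frame.iterrows():
            cell = per_stratum[
                (per_stratum["sex"] == row["sex"])
                & (per_stratum["year"] == row["year"])
            ]
            assert row["unadjusted_per_1000"] == pytest.approx(
                cell["unadjusted_per_1000"].mean(), abs=1e-9
            )

    def test_population_weighted_margin(self, small_run):
        reg, results = small_run
        weights = {s: float(i + 1) for i, s in enumerate(reg.strata())}
        frame = aggregate(
            results, reg, "total", margins=("age_group", "sex"),
            population_weights=weights,
        )
        assert set(frame["weighting"]) == {"population"}
        per_stratum = aggregate(results, reg, "total")
        w = per_stratum.apply(
            lambda r: weights[
                [s for s in reg.strata()
                 if (s.sex, s.age_group, s.year)
                 == (r["sex"], r["age_group"], r["year"])][0]
            ],
            axis=1,
        )
        expected = (per_stratum["unadjusted_per_1000"] * w).sum() / w.sum()
        assert frame["unadjusted_per_1000"].iloc[0] == pytest.approx(
            expected, abs=1e-9
        )


class TestRankingChanges:
    def test_identical_rankings_are_silent(self):
        rates = {"a": 5.0, "b": 4.0, "c": 3.0}
        assert ranking_changes(rates, rates) == []

    def test_constructed_three_step_promotion(self):
        unadj = {"a": 50.0, "b": 40.0, "c": 30.0, "d": 20.0, "e": 10.0}
        adj = {"a": 50.0, "b": 40.0, "c": 30.0, "d": 20.0, "e": 45.0}
        changes = ranking_changes(unadj, adj, threshold=3)
        assert len(changes) == 1
        (change,) = changes
        assert change.cause_id == "e"
        assert (change.rank_unadjusted, change.rank_adjusted) == (5, 2)
        assert change.delta == 3 and change.direction == "up"

    def test_threshold_one_flags_any_swap(self):
        unadj = {"a": 2.0, "b": 1.0}
        adj = {"a": 1.0, "b": 2.0}
        assert len(ranking_changes(unadj, adj, threshold=1)) == 2

    def test_uniform_scaling_preserves_order(self):
        rng = np.random.default_rng(0)
        unadj = {f"c{i}": float(r) for i, r in enumerate(rng.random(20))}
        adj = {k: 0.9 * v for k, v in unadj.items()}
        assert ranking_changes(unadj, adj, threshold=1) == []

    def test_mismatched_cause_sets_rejected(self):
        with pytest.raises(ValueError, match="symmetric difference"):
            ranking_changes({"a": 1.0}, {"b": 1.0})

    def test_ties_broken_by_cause_id(self):
        unadj = {"a": 1.0, "b": 1.0, "c": 1.0}
        changes = ranking_changes(unadj, dict(unadj), threshold=1)
        assert changes == []
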