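import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from h2020index import (
    AggregationPolicy,
    TargetIndex,
    compute_index_table,
    geometric_mean,
    overall_index,
    resolve_reference_years,
    target_index,
)
from h2020index.errors import CountryUnscorableError, ValidationError
from conftest import make_raw

positive_lists = st.lists(st.floats(1.0, 100.0), min_size=1, max_size=16)


class TestGeometricMean:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([4.0, 9.0], 6.0),
            ([7.3], 7.3),
            ([25.0, 100.0, 1.0], 13.572088082974531),  # (25*100*1)**(1/3)
            ([50.0] * 5, 50.0),
        ],
    )
    def test_known_values(self, values, expected):
        assert geometric_mean(values) == pytest.approx(expected, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            geometric_mean([])

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            geometric_mean([4.0, 0.0])
        with pytest.raises(ValidationError):
            geometric_mean([4.0, -1.0])

    @settings(max_examples=150, deadline=None)
    @given(values=positive_lists)
    def test_agrees_with_scipy_and_product_oracle(self, values):
        gm = geometric_mean(values)
        assert gm == pytest.approx(stats.gmean(values), rel=1e-12)
        assert gm == pytest.approx(
            float(np.prod(values)) ** (1.0 / len(values)), rel=1e-9
        )

    @settings(max_examples=150, deadline=None)
    @given(values=positive_lists)
    def test_mean_inequalities(self, values):
        """GM lies within [min, max] and between the harmonic and arithmetic means."""
        gm = geometric_mean(values)
        assert min(values) - 1e-12 <= gm <= max(values) + 1e-12
        assert gm <= np.mean(values) + 1e-9
        assert gm >= stats.hmean(values) - 1e-9

    @settings(max_examples=120, deadline=None)
    @given(values=positive_lists, c=st.floats(1.0, 10.0))
    def test_partial_substitutability(self, values, c):
        """Scaling one component by c scales the GM by c**(1/n)."""
        scaled = list(values)
        scaled[0] *= c
        assert geometric_mean(scaled) == pytest.approx(
            geometric_mean(values) * c ** (1.0 / len(values)), rel=1e-9
        )


class TestTargetIndex:
    def test_all_indicators_present(self, registry):
        # target 5 members in the default registry: 13, 15, 16, 17
        indices = {13: 40.0, 15: 60.0, 16: 80.0, 17: 90.0}
        t = target_index(indices, registry, 5)
        assert not t.excluded and t.n_indicators_used == 4
        assert t.index == pytest.approx(geometric_mean(list(indices.values())))

    def test_missing_indicator_drops_out(self, registry):
        t = target_index({13: 40.0, 15: 60.0}, registry, 5)
        assert t.n_indicators_used == 2
        assert t.index == pytest.approx(geometric_mean([40.0, 60.0]))

    def test_no_indicator_excludes_target(self, registry):
        t = target_index({1: 50.0}, registry, 5)
        assert t.excluded and t.index is None and t.n_indicators_used == 0

    def test_dropping_indicator_at_the_gm_is_neutral(self, registry):
        indices = {13: 40.0, 15: 90.0}
        gm = target_index(indices, registry, 5).index
        indices[16] = gm  # a member indicator exactly at the target GM
        assert target_index(indices, registry, 5).index == pytest.approx(gm, abs=1e-9)


class TestOverallIndex:
    @staticmethod
    def targets(values):
        return [
            TargetIndex("AA", t + 1, 2015, v, 1, v is None)
            for t, v in enumerate(values)
        ]

    def test_three_of_five_targets(self):
        o = overall_index(self.targets([17.0, None, 32.0, None, 3.0]))
        assert o.n_targets_used == 3
        assert o.index == pytest.approx((17.0 * 32.0 * 3.0) ** (1 / 3), rel=1e-9)

    def test_equal_targets_preserved(self):
        assert overall_index(self.targets([50.0] * 5)).index == pytest.approx(50.0)

    def test_log_mean_matches_product_oracle(self):
        values = [17.0, 100.0, 32.0, 1.0, 3.0]
        o = overall_index(self.targets(values))
        assert o.index == pytest.approx(float(np.prod(values)) ** 0.2, rel=1e-9)

    def test_all_excluded_is_unscorable(self):
        with pytest.raises(CountryUnscorableError):
            overall_index(self.targets([None] * 5))

    def test_min_targets_policy(self):
        policy = AggregationPolicy(min_targets_per_country=4)
        with pytest.raises(CountryUnscorableError):
            overall_index(self.targets([50.0, 60.0, None, None, 70.0]), policy)


class TestComputeIndexTable:
    def test_complete_panel_scores_everyone(self, registry, roster_index):
        included = set(roster_index.inclusion.included)
        at_2015 = roster_index.overall[roster_index.overall.reference_year == 2015]
        assert set(at_2015.country) == included

    def test_overall_reproducible_from_stored_targets(self, registry, roster_index):
        tgt = roster_index.target_indices
        for _, row in roster_index.overall.iterrows():
            parts = tgt[
                (tgt.country == row["country"])
                & (tgt.reference_year == row["reference_year"])
                & (~tgt.excluded)
            ]["index"]
            assert row["index"] == pytest.approx(geometric_mean(list(parts)), abs=1e-9)
            assert row["n_targets_used"] == len(parts)

    def test_row_order_permutation_is_irrelevant(self, registry, roster):
        table, meta = roster
        long = meta["long_table"]
        shuffled = long.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = compute_index_table(resolve_reference_years(long), registry)
        b = compute_index_table(resolve_reference_years(shuffled), registry)
        assert a.overall.equals(b.overall)
        assert a.target_indices.equals(b.target_indices)

    def test_sparse_country_scored_on_remaining_targets(self, registry):
        """A country with no data on two targets keeps an index from the rest."""
        from h2020index import indicators_for_target

        # targets 1/2/5 share no indicator with targets 3/4 in the default registry
        keep_targets = {1, 2, 5}
        rows = []
        for t in registry.quantitative_target_ids:
            for ind in indicators_for_target(registry, t):
                if t in keep_targets:
                    rows.append(("AA", ind.indicator_id, 2015, 50.0 + ind.indicator_id))
                rows.append(("BB", ind.indicator_id, 2015, 40.0 + ind.indicator_id))
                rows.append(("CC", ind.indicator_id, 2015, 60.0 + ind.indicator_id))
        table = resolve_reference_years(make_raw(rows))
        result = compute_index_table(table, registry, max_missing=15)
        aa_targets = result.target_indices[
            (result.target_indices.country == "AA")
            & (result.target_indices.reference_year == 2015)
        ]
        assert set(aa_targets[~aa_targets.excluded].target_id) == keep_targets
        aa_overall = result.overall[result.overall.country == "AA"]
        assert aa_overall.n_targets_used.iloc[0] == 3

    def test_monotone_in_any_indicator(self, registry):
        """Raising one raw indicator (direction-adjusted) never lowers the overall index."""
        from h2020index import quantitative_indicators, Direction

        rng = np.random.default_rng(11)
        q = quantitative_indicators(registry)
        base_rows = [
            (c, ind.indicator_id, 2015, float(rng.uniform(10, 90)))
            for c in ("AA", "BB", "CC")
            for ind in q
        ]
        base = compute_index_table(
            resolve_reference_years(make_raw(base_rows)), registry
        )
        for ind in (q[0], q[5]):
            bumped_rows = [
                (c, k, y, v + (5.0 if (c == "AA" and k == ind.indicator_id) else 0.0)
                 * (1 if ind.direction is Direction.higher_better else -1))
                for (c, k, y, v) in base_rows
            ]
            bumped = compute_index_table(
                resolve_reference_years(make_raw(bumped_rows)), registry
            )
            before = base.overall[base.overall.country == "AA"]["index"].iloc[0]
            after = bumped.overall[bumped.overall.country == "AA"]["index"].iloc[0]
            assert after >= before - 1e-9
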