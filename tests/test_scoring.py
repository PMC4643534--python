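import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungwater.layout import RatSite, Scheme, build_layout
from lungwater.scoring import (
    Mode,
    SpaceObservation,
    round_half_away,
    score_animal,
    score_space,
    score_zone,
)

SITES = build_layout(Scheme.RAT_4X7).sites


def a_pattern(site=SITES[0]):
    return SpaceObservation(site=site, mode=Mode.A_PATTERN)


def discrete(count, site=SITES[0]):
    return SpaceObservation(site=site, mode=Mode.DISCRETE, count=count)


def confluent(segments, width, site=SITES[0]):
    return SpaceObservation(
        site=site, mode=Mode.CONFLUENT, segments=tuple(segments), space_width=width
    )


@st.composite
def observations_strategy(draw, min_size=0, max_size=28):
    n = draw(st.integers(min_size, max_size))
    sites = draw(st.permutations(list(SITES)))[:n]
    obs = []
    for site in sites:
        kind = draw(st.sampled_from(["a", "d", "c"]))
        if kind == "a":
            obs.append(a_pattern(site))
        elif kind == "d":
            obs.append(discrete(draw(st.integers(0, 10)), site))
        else:
            width = draw(st.floats(0.2, 3.0))
            frac = draw(st.floats(0.01, 1.0))
            obs.append(confluent([frac * width], width, site))
    return obs


class TestScoreSpace:
    @pytest.mark.parametrize(
        "obs,expected",
        [
            (discrete(3), 3.0),  # three discrete B lines
            (confluent([0.45], 0.9), 5.0),  # half-occupied rib space
            (a_pattern(), 0.0),  # aerated lung
            (confluent([0.3, 0.4], 0.7), 10.0),  # full occupancy saturates
            (discrete(0), 0.0),
            (discrete(10), 10.0),
        ],
    )
    def test_per_space_rules(self, obs, expected):
        assert score_space(obs) == pytest.approx(expected)

    def test_invalid_confluent_rejected(self):
        with pytest.raises(ValueError):
            confluent([0.5], 0.0)
        with pytest.raises(ValueError):
            confluent([0.5, 0.6], 0.9)  # segments exceed the rib space
        with pytest.raises(ValueError):
            confluent([], 0.9)

    def test_invalid_discrete_rejected(self):
        with pytest.raises(ValueError):
            discrete(11)
        with pytest.raises(ValueError):
            discrete(-1)

    @given(st.floats(0.1, 5.0), st.floats(0.0, 1.0))
    def test_confluent_score_bounded_and_proportional(self, width, frac):
        if frac == 0.0:
            return
        obs = confluent([frac * width], width)
        score = score_space(obs)
        assert 0.0 <= score <= 10.0
        assert score == pytest.approx(min(10.0, frac * 10.0), rel=1e-9)


class TestScoreZone:
    def test_all_a_pattern_scores_zero(self):
        obs = [a_pattern(s) for s in SITES if s.zone == 1]
        assert score_zone(obs, 1) == 0.0

    def test_confluent_zone_follows_the_stated_formula(self):
        """Three confluent spaces 0.7, 0.7, 0.6 cm in 2.8 cm rib spaces
        sum to 50/7 ≈ 7.14 — the occupied-fraction formula's value, which
        differs from a commonly miscomputed 10.15 for the same inputs."""
        zone1 = [s for s in SITES if s.zone == 1]
        obs = [
            confluent([0.7], 2.8, zone1[0]),
            confluent([0.7], 2.8, zone1[1]),
            confluent([0.6], 2.8, zone1[2]),
        ] + [a_pattern(s) for s in zone1[3:]]
        total = score_zone(obs, 1)
        assert total == pytest.approx(50.0 / 7.0, abs=1e-9)
        assert abs(total - 10.15) > 2.9  # the formula does not yield 10.15

    def test_zone_maximum_is_70(self):
        obs = [discrete(10, s) for s in SITES if s.zone == 2]
        assert score_zone(obs, 2) == 70.0

    def test_duplicate_site_rejected(self):
        s = SITES[0]
        with pytest.raises(ValueError, match="duplicate"):
            score_zone([discrete(1, s), discrete(2, s)], s.zone)

    def test_wrong_zone_rejected(self):
        with pytest.raises(ValueError):
            score_zone([discrete(1, SITES[0])], 2)


class TestScoreAnimal:
    def test_all_a_pattern_total_zero(self):
        res = score_animal([a_pattern(s) for s in SITES])
        assert res.total == 0 and res.total_raw == 0.0

    def test_global_maximum_280(self):
        res = score_animal([discrete(10, s) for s in SITES])
        assert res.total == 280

    def test_single_confluent_space_propagates_to_total(self):
        obs = [confluent([0.45], 0.9, SITES[0])]
        obs += [a_pattern(s) for s in SITES[1:]]
        res = score_animal(obs)
        assert res.total == 5
        assert res.total_raw == pytest.approx(5.0)

    def test_missing_sites_score_zero_and_are_reported(self):
        res = score_animal([discrete(4, SITES[0])])
        assert res.total == 4
        assert len(res.missing_sites) == 27

    def test_duplicate_site_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            score_animal([discrete(1, SITES[0]), discrete(2, SITES[0])])

    def test_per_zone_sums_match_total(self):
        obs = [discrete(i % 11, s) for i, s in enumerate(SITES)]
        res = score_animal(obs)
        assert sum(res.per_zone.values()) == pytest.approx(res.total_raw)
        assert res.total == round_half_away(res.total_raw)

    @given(observations_strategy())
    def test_matches_brute_force_site_summation(self, obs):
        """Independent oracle: re-derive every per-space score from the
        raw fields and sum, bypassing the aggregation code path."""
        expected = 0.0
        for o in obs:
            if o.mode is Mode.A_PATTERN:
                expected += 0.0
            elif o.mode is Mode.DISCRETE:
                expected += o.count
            else:
                expected += min(10.0, sum(o.segments) / o.space_width * 10.0)
        res = score_animal(obs)
        assert res.total_raw == pytest.approx(expected, abs=1e-9)

    @given(observations_strategy(min_size=1))
    def test_permutation_invariance(self, obs):
        res1 = score_animal(obs)
        res2 = score_animal(list(reversed(obs)))
        assert res1.total_raw == res2.total_raw
        assert res1.total == res2.total

    @given(observations_strategy(min_size=1), st.data())
    def test_monotonicity_in_b_line_burden(self, obs, data):
        """Adding a B line or lengthening a confluent band never
        decreases the whole-animal raw score."""
        idx = data.draw(st.integers(0, len(obs) - 1))
        target = obs[idx]
        before = score_animal(obs).total_raw
        if target.mode is Mode.DISCRETE:
            if target.count == 10:
                return
            bumped = discrete(target.count + 1, target.site)
        elif target.mode is Mode.CONFLUENT:
            room = target.space_width - sum(target.segments)
            if room <= 1e-9:
                return
            bumped = confluent(
                [target.segments[0] + room / 2, *target.segments[1:]],
                target.space_width,
                target.site,
            )
        else:
            bumped = discrete(1, target.site)
        after = score_animal(obs[:idx] + [bumped] + obs[idx + 1 :]).total_raw
        assert after >= before - 1e-12


@pytest.mark.parametrize(
    "x,expected",
    [(0.4, 0), (0.5, 1), (10.15, 10), (2.5, 3), (-2.5, -3), (-0.4, 0), (7.0, 7)],
)
def test_round_half_away_from_zero(x, expected):
    assert round_half_away(x) == expected


def test_discrete_and_confluent_agree_at_the_extremes():
    assert score_space(discrete(10)) == score_space(confluent([0.9], 0.9))
    assert score_space(discrete(0)) == score_space(a_pattern())
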