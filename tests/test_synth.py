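import numpy as np
import pytest

from lungwater.agreement import PairedSeries, concordance, pearson
from lungwater.gravimetry import compute_evlw
from lungwater.layout import Scheme, build_layout
from lungwater.scoring import Mode, round_half_away, score_animal, score_space
from lungwater.synth import (
    EVLWI_CALIBRATION,
    SCORE_CALIBRATION,
    CohortConfig,
    GravimetricNoise,
    GroupParams,
    ObserverNoise,
    generate_cohort,
    replicate_reading,
    score_link_coefficients,
)

SILENT_OBSERVER = ObserverNoise(0.0, 0.0, 0.0, 0.0, 0.0)


def noise_free_config(seed=0, n_control=5, n_oa=5):
    return CohortConfig(
        n_control=n_control,
        n_oa=n_oa,
        control=GroupParams(2.02, 0.3, 0.0, 0.0),
        oa=GroupParams(3.92, 0.5, 0.0, 0.0),
        observer=SILENT_OBSERVER,
        gravimetric_noise=GravimetricNoise(0.0, 0.0, 0.0),
        seed=seed,
    )


def cohort_scores_and_evlwi(animals):
    x = [score_animal(a.observations).total for a in animals]
    y = [compute_evlw(a.gravimetry).evlw_index for a in animals]
    return np.array(x, float), np.array(y, float)


class TestGenerateCohort:
    def test_empty_cohort(self):
        cfg = CohortConfig.calibrated(n_control=0, n_oa=0)
        assert generate_cohort(cfg) == []

    def test_fixed_seed_is_deterministic(self):
        c1 = generate_cohort(CohortConfig.calibrated(seed=42))
        c2 = generate_cohort(CohortConfig.calibrated(seed=42))
        assert c1 == c2
        c3 = generate_cohort(CohortConfig.calibrated(seed=43))
        assert c1 != c3

    def test_noise_free_round_trip_through_scoring_and_gravimetry(self):
        animals = generate_cohort(noise_free_config(seed=7, n_control=10, n_oa=10))
        for a in animals:
            res = score_animal(a.observations)
            assert res.total == round_half_away(a.expected_score)
            grav = compute_evlw(a.gravimetry)
            assert grav.evlw == pytest.approx(a.evlw_true_g, abs=1e-10)
            assert a.evlwi_true == pytest.approx(a.severity)

    def test_observations_satisfy_scoring_invariants(self):
        layout = build_layout(Scheme.RAT_4X7)
        animals = generate_cohort(CohortConfig.calibrated(seed=3, n_control=3, n_oa=3))
        for a in animals:
            sites = [o.site for o in a.observations]
            assert len(sites) == 28 and len(set(sites)) == 28
            for o in a.observations:
                assert o.site in layout
                assert 0.0 <= score_space(o) <= 10.0
            assert a.evlw_true_g >= 0

    def test_group_labels_and_sizes(self):
        animals = generate_cohort(CohortConfig.calibrated(n_control=4, n_oa=6, seed=1))
        assert sum(a.group == "control" for a in animals) == 4
        assert sum(a.group == "oa" for a in animals) == 6

    def test_infeasible_score_link_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            CohortConfig(
                control=GroupParams(2.0, 0.1, 0.0, 0.0),
                oa=GroupParams(4.0, 0.1, 0.0, 0.0),
                score_link=(-50.0, 1.0),
            )

    def test_confluent_rendering_preserves_allocated_score(self):
        """High-count sites are rendered as confluent bands; both
        renderings must score identically."""
        severe = CohortConfig(
            n_control=0,
            n_oa=8,
            control=GroupParams(2.0, 0.1, 0.0, 0.0),
            oa=GroupParams(30.0, 1.0, 0.0, 0.0),  # ~210 expected → dense sites
            seed=11,
        )
        animals = generate_cohort(severe)
        confluent_seen = 0
        for a in animals:
            for o in a.observations:
                if o.mode is Mode.CONFLUENT:
                    confluent_seen += 1
                    assert score_space(o) == pytest.approx(
                        round(score_space(o)), abs=1e-9
                    )
        assert confluent_seen > 0


class TestCalibration:
    def test_group_means_and_sds_match_targets_over_seeds(self):
        """Simulated score and EVLWI group summaries should sit within
        2 study-scale standard errors (SD/√15) of the calibration
        targets when averaged over 100 seeds."""
        totals = {"control": [], "oa": []}
        evlwi = {"control": [], "oa": []}
        for seed in range(100):
            animals = generate_cohort(CohortConfig.calibrated(seed=seed))
            for a in animals:
                totals[a.group].append(score_animal(a.observations).total)
                evlwi[a.group].append(compute_evlw(a.gravimetry).evlw_index)
        for grp in ("control", "oa"):
            sc_mean, sc_sd = SCORE_CALIBRATION[grp]
            ev_mean, ev_sd = EVLWI_CALIBRATION[grp]
            assert np.mean(totals[grp]) == pytest.approx(
                sc_mean, abs=2 * sc_sd / np.sqrt(15)
            )
            assert np.std(totals[grp], ddof=1) == pytest.approx(
                sc_sd, abs=2 * sc_sd / np.sqrt(2 * 15)
            )
            assert np.mean(evlwi[grp]) == pytest.approx(
                ev_mean, abs=2 * ev_sd / np.sqrt(15)
            )
            assert np.std(evlwi[grp], ddof=1) == pytest.approx(
                ev_sd, abs=2 * ev_sd / np.sqrt(2 * 15)
            )

    def test_correlation_decreases_with_coupling_noise(self):
        means = []
        for sigma_c in (0.5, 2.5, 8.0):
            rs = []
            for seed in range(40):
                cfg = CohortConfig.calibrated(
                    n_control=12, n_oa=12, coupling_noise_sd=sigma_c, seed=seed
                )
                x, y = cohort_scores_and_evlwi(generate_cohort(cfg))
                rs.append(
                    pearson(PairedSeries.from_arrays(range(24), x, y))[0]
                )
            means.append(np.mean(rs))
        assert means[0] > means[1] > means[2]


class TestReplicateReading:
    def test_zero_observer_noise_intra_reading_scores_identically(self):
        animals = generate_cohort(noise_free_config(seed=5))
        for a in animals:
            rep = replicate_reading(a, "intra", seed=1, observer=SILENT_OBSERVER)
            assert score_animal(rep).total == score_animal(a.observations).total

    def test_inter_bias_adds_one_per_nonzero_space_cap_respecting(self):
        observer = ObserverNoise(0.0, 0.0, inter_bias=1.0, inter_sd=0.0,
                                 inter_fp_prob=0.0)
        animals = generate_cohort(CohortConfig.calibrated(n_control=0, n_oa=5, seed=9))
        for a in animals:
            base_scores = [score_space(o) for o in a.observations]
            expected_delta = sum(
                min(round_half_away(c) + 1, 10) - round_half_away(c)
                for c in base_scores
                if c > 0
            )
            rep = replicate_reading(a, "inter", seed=2, observer=observer)
            delta = score_animal(rep).total - score_animal(a.observations).total
            assert delta == expected_delta

    def test_default_intra_noise_yields_imperfect_positive_concordance(self):
        cfg = CohortConfig.calibrated(n_control=0, n_oa=15, seed=21)
        animals = generate_cohort(cfg)
        x, y = [], []
        for i, a in enumerate(animals):
            x.append(score_animal(a.observations).total)
            y.append(score_animal(replicate_reading(a, "intra", seed=100 + i)).total)
        ccc, _, _ = concordance(PairedSeries.from_arrays(range(15), x, y))
        assert 0.0 < ccc < 1.0

    def test_unknown_mode_rejected(self):
        animals = generate_cohort(CohortConfig.calibrated(n_control=1, n_oa=0, seed=0))
        with pytest.raises(ValueError):
            replicate_reading(animals[0], "extra", seed=0)

    def test_replicate_is_deterministic_in_seed(self):
        animals = generate_cohort(CohortConfig.calibrated(n_control=0, n_oa=1, seed=2))
        r1 = replicate_reading(animals[0], "intra", seed=77)
        r2 = replicate_reading(animals[0], "intra", seed=77)
        assert r1 == r2


def test_score_link_interpolates_group_calibration_means():
    a, b = score_link_coefficients()
    assert a + b * EVLWI_CALIBRATION["control"][0] == pytest.approx(
        SCORE_CALIBRATION["control"][0]
    )
    assert a + b * EVLWI_CALIBRATION["oa"][0] == pytest.approx(
        SCORE_CALIBRATION["oa"][0]
    )
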