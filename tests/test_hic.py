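"""ICE balancing, distance decay, P'max, insulation and anchor aggregation."""

import numpy as np
import pytest

import bindloop as bl


def random_symmetric(n, seed=0, offset=0.1):
    rng = np.random.default_rng(seed)
    A = rng.random((n, n)) + offset
    return (A + A.T) / 2


class TestIce:
    def test_equal_row_sums_is_a_fixed_point(self):
        A = np.full((20, 20), 2.0)
        bal, bias = bl.ice_balance(bl.ContactMatrix(A, 10_000))
        assert np.allclose(bias, bias[0])
        assert np.allclose(bal.counts / bal.counts[0, 0], A / A[0, 0])

    def test_row_sum_cv_converges(self):
        m = bl.ContactMatrix(random_symmetric(50, seed=1), 10_000)
        bal, _ = bl.ice_balance(m)
        rs = bal.counts.sum(axis=1)
        assert rs.std() / rs.mean() < 1e-6

    def test_bias_vector_reconstructs_raw(self):
        A = random_symmetric(30, seed=2)
        bal, bias = bl.ice_balance(bl.ContactMatrix(A, 10_000))
        assert np.allclose(np.outer(bias, bias) * bal.counts, A, atol=1e-10)

    def test_zero_row_masked_rest_balanced(self):
        A = random_symmetric(30, seed=3)
        A[4, :] = 0.0
        A[:, 4] = 0.0
        bal, bias = bl.ice_balance(bl.ContactMatrix(A, 10_000))
        assert np.all(bal.counts[4] == 0)
        rs = np.delete(bal.counts.sum(axis=1), 4)
        assert rs.std() / rs.mean() < 1e-6

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            bl.ice_balance(bl.ContactMatrix(np.zeros((10, 10)), 10_000))

    def test_output_symmetric(self):
        bal, _ = bl.ice_balance(bl.ContactMatrix(random_symmetric(40, 4), 10_000))
        assert np.allclose(bal.counts, bal.counts.T, atol=0)


class TestRcp:
    def test_per_diagonal_means_match_brute_force(self):
        m = bl.ContactMatrix(random_symmetric(50, seed=5), 10_000)
        rcp = bl.contact_probability_curve(m, log_bins_per_decade=None)
        oracle = np.array([m.counts.diagonal(d).mean() for d in range(1, 50)])
        assert np.array_equal(rcp.mean_count, oracle)
        assert np.array_equal(rcp.probability, oracle / oracle.sum())

    def test_power_law_slope(self):
        m = bl.simulate_contact_matrix(200, 10_000, decay_exponent=-1.0, sample=False)
        rcp = bl.contact_probability_curve(m)
        slope = np.polyfit(np.log10(rcp.distance_bp), np.log10(rcp.probability), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.01)

    def test_uniform_matrix_slope_zero(self):
        A = np.ones((200, 200))
        rcp = bl.contact_probability_curve(bl.ContactMatrix(A, 10_000))
        slope = np.polyfit(np.log10(rcp.distance_bp), np.log10(rcp.probability), 1)[0]
        assert slope == pytest.approx(0.0, abs=0.01)

    def test_scale_invariance(self):
        m = bl.simulate_contact_matrix(80, 10_000, seed=6)
        a = bl.contact_probability_curve(m)
        b = bl.contact_probability_curve(bl.ContactMatrix(m.counts * 10, 10_000))
        assert np.allclose(a.probability, b.probability, atol=1e-12, rtol=0)

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            bl.contact_probability_curve(bl.ContactMatrix(np.ones((5, 5)), 10_000))

    def test_balancing_preserves_decay_slope(self):
        m = bl.simulate_contact_matrix(200, 10_000, decay_exponent=-1.0, sample=False)
        bal, _ = bl.ice_balance(m)
        rcp = bl.contact_probability_curve(bal)
        slope = np.polyfit(np.log10(rcp.distance_bp), np.log10(rcp.probability), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.02)


def analytic_bump_curve(n_points=60):
    s = np.logspace(4, 6.5, n_points)
    p = s**-1 * (1 + 0.5 * np.exp(-((np.log(s) - np.log(2e5)) ** 2) / 0.5))
    return bl.RcpCurve(distance_bp=s, probability=p / p.sum(), n_pairs=np.ones(n_points))


def bump_oracle_argmax():
    x = np.linspace(4, 6.5, 20000)
    s = 10**x
    p = s**-1 * (1 + 0.5 * np.exp(-((np.log(s) - np.log(2e5)) ** 2) / 0.5))
    d = np.gradient(np.log10(p), x)
    mask = (s >= 5e4) & (s <= 2e6)
    return s[mask][np.argmax(d[mask])]


class TestPmax:
    def test_pure_power_law_has_no_peak(self):
        s = np.logspace(4, 6.5, 60)
        rcp = bl.RcpCurve(distance_bp=s, probability=(s**-1) / (s**-1).sum(), n_pairs=np.ones(60))
        assert bl.estimate_pmax(rcp).no_peak

    def test_analytic_bump_location_within_one_grid_bin(self):
        rcp = analytic_bump_curve()
        est = bl.estimate_pmax(rcp)
        assert not est.no_peak
        grid_ratio = 10 ** (2.5 / 59)
        oracle = bump_oracle_argmax()
        assert oracle / grid_ratio**1.5 <= est.pmax_distance_bp <= oracle * grid_ratio**1.5

    @pytest.mark.parametrize("span", [0.2, 0.3, 0.4])
    def test_stable_across_loess_spans(self, span):
        rcp = analytic_bump_curve()
        ref = bl.estimate_pmax(rcp, loess_span=0.3).pmax_distance_bp
        est = bl.estimate_pmax(rcp, loess_span=span).pmax_distance_bp
        grid_ratio = 10 ** (2.5 / 59)
        assert ref / grid_ratio**1.5 <= est <= ref * grid_ratio**1.5

    def test_depth_scaling_invariance(self):
        rcp = analytic_bump_curve()
        scaled = bl.RcpCurve(
            distance_bp=rcp.distance_bp,
            probability=rcp.probability,  # already normalized; scaling cancels
            n_pairs=rcp.n_pairs,
        )
        assert bl.estimate_pmax(scaled).pmax_distance_bp == bl.estimate_pmax(rcp).pmax_distance_bp


class TestInsulation:
    def test_uniform_matrix_scores_zero_no_boundaries(self):
        track = bl.insulation_track(bl.ContactMatrix(np.ones((80, 80)), 10_000), 100_000)
        assert np.allclose(track.score[track.valid], 0.0, atol=1e-12)
        assert track.boundaries == []

    def test_two_block_boundary_found(self):
        A = np.full((100, 100), 1.0)
        A[:50, :50] = 10.0
        A[50:, 50:] = 10.0
        track = bl.insulation_track(bl.ContactMatrix(A, 10_000), 100_000)
        valid_idx = np.flatnonzero(track.valid)
        global_min = valid_idx[np.argmin(track.score[track.valid])]
        assert abs(global_min - 50) <= 1
        assert len(track.boundaries) == 1
        assert abs(track.boundaries[0] - 50) <= 1

    def test_diamond_means_match_brute_force(self):
        A = random_symmetric(60, seed=8)
        w = 5
        track = bl.insulation_track(bl.ContactMatrix(A, 10_000), w * 10_000)
        dm = [A[i - w : i, i : i + w].mean() for i in range(w, 60 - w + 1)]
        expected = np.log2(np.array(dm) / np.mean(dm))
        assert np.allclose(track.score[track.valid], expected, atol=1e-12)

    def test_window_equal_to_span_rejected(self):
        m = bl.ContactMatrix(np.ones((40, 40)), 10_000)
        with pytest.raises(ValueError):
            bl.insulation_track(m, 400_000)

    def test_scale_invariance(self):
        A = random_symmetric(60, seed=9)
        a = bl.insulation_track(bl.ContactMatrix(A, 10_000), 50_000)
        b = bl.insulation_track(bl.ContactMatrix(A * 10, 10_000), 50_000)
        assert np.allclose(a.score[a.valid], b.score[b.valid], atol=1e-12)


class TestAggregate:
    def test_single_interior_anchor_returns_its_window(self):
        m = bl.ContactMatrix(random_symmetric(60, seed=10), 10_000)
        pile, n = bl.aggregate_around_anchors(m, [(200_000, 400_000)], 30_000)
        assert n == 1
        assert np.array_equal(pile, m.counts[17:24, 37:44])

    def test_edge_anchors_excluded_and_counted(self):
        m = bl.ContactMatrix(random_symmetric(60, seed=11), 10_000)
        anchors = [(10_000, 100_000), (200_000, 400_000)]  # first is too close to the edge
        pile, n = bl.aggregate_around_anchors(m, anchors, 50_000)
        assert n == 1

    def test_zero_usable_anchors_rejected(self):
        m = bl.ContactMatrix(random_symmetric(60, seed=12), 10_000)
        with pytest.raises(ValueError):
            bl.aggregate_around_anchors(m, [(0, 10_000)], 50_000)

    def test_track_profile_mean_of_windows(self):
        A = random_symmetric(80, seed=13)
        track = bl.insulation_track(bl.ContactMatrix(A, 10_000), 50_000)
        profile, n = bl.aggregate_around_anchors(track, [300_000, 500_000], 30_000)
        assert n == 2
        b1, b2, f = 30, 50, 3
        manual = np.nanmean(
            [
                np.where(track.valid, track.score, np.nan)[b - f : b + f + 1]
                for b in (b1, b2)
            ],
            axis=0,
        )
        assert np.allclose(profile, manual, equal_nan=True)

    def test_loop_pileup_enriched_at_center(self):
        for seed in range(5):
            pos_rng = np.random.default_rng(seed + 2000)
            pos = pos_rng.integers(10, 150, size=20)
            loops = [(int(p), int(p) + 30, 2.0, 1.5) for p in pos]
            m = bl.simulate_contact_matrix(
                200, 10_000, decay_exponent=-1.0, loops=loops, depth=1e6, seed=seed
            )
            anchors = [((p + 0.5) * 10_000, (p + 30.5) * 10_000) for p in pos]
            pile, n = bl.aggregate_around_anchors(m, anchors, 50_000)
            corners = np.mean(
                [
                    pile[:3, :3].mean(),
                    pile[:3, -3:].mean(),
                    pile[-3:, :3].mean(),
                    pile[-3:, -3:].mean(),
                ]
            )
            assert pile[5, 5] / corners > 1.5


class TestDownsample:
    def test_thinning_hits_target_and_stays_symmetric(self):
        m = bl.simulate_contact_matrix(80, 10_000, depth=2e5, seed=14)
        thin = bl.downsample_matrix(m, 1e5, seed=0)
        assert np.array_equal(thin.counts, thin.counts.T)
        assert thin.counts.sum() == pytest.approx(1e5, rel=0.02)
        again = bl.downsample_matrix(m, 1e5, seed=0)
        assert np.array_equal(thin.counts, again.counts)
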