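"""Half-dataset statistics, frame triage and scans."""

import numpy as np
import pandas as pd
import pytest

from ssrox.crystal import PointGroup
from ssrox.merging import monte_carlo_merge
from ssrox.stats import (
    ScanResult,
    cc_ano,
    cc_half,
    cumulative_curve,
    frame_i_over_sigma,
    frame_table,
    hit_find,
    r_split,
    rejection_scan,
    resolution_cutoff,
    sort_frames,
    split_halves,
)

PG1 = PointGroup(name="1")


def merged_from(hkl, i, friedel=None, sigma=None):
    hkl = np.atleast_2d(hkl)
    n = len(hkl)
    return pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "friedel": np.ones(n, dtype=int) if friedel is None else friedel,
            "i_merged": np.asarray(i, dtype=float),
            "sigma_merged": np.ones(n) if sigma is None else sigma,
            "multiplicity": np.full(n, 2),
        }
    )


TRIPLES = [(1, 1, 1), (2, 1, 1), (3, 1, 1)]


class TestHitRule:
    def test_two_low_resolution_spots_is_no_hit(self):
        assert hit_find([8.0, 8.0]) is False

    def test_three_spots_at_six_angstrom_is_hit(self):
        assert hit_find([6.0, 6.0, 6.0]) is True

    def test_many_high_resolution_spots_is_no_hit(self):
        assert hit_find([2.0] * 10) is False

    def test_mixed(self):
        assert hit_find([2.0, 2.0, 5.5, 7.0, 12.0]) is True


class TestFrameIsigma:
    def test_single_observation(self):
        obs = pd.DataFrame({"intensity": [10.0], "sigma": [5.0]})
        assert frame_i_over_sigma(obs) == pytest.approx(2.0)

    def test_mean_of_two(self):
        obs = pd.DataFrame({"intensity": [10.0, 0.0], "sigma": [5.0, 10.0]})
        assert frame_i_over_sigma(obs) == pytest.approx(1.0)

    def test_order_invariant(self):
        obs = pd.DataFrame({"intensity": [1.0, 5.0, 9.0], "sigma": [1.0, 2.0, 3.0]})
        assert frame_i_over_sigma(obs) == pytest.approx(
            frame_i_over_sigma(obs.iloc[::-1])
        )


class TestSortFrames:
    def make_stats(self, values):
        return pd.DataFrame(
            {"mean_i_over_sigma": values, "n_obs": 1},
            index=pd.Index(range(len(values)), name="frame_id"),
        )

    def test_descending_order(self):
        assert sort_frames(self.make_stats([0.3, 0.9, 0.5])).tolist() == [1, 2, 0]

    def test_sorted_input_unchanged(self):
        assert sort_frames(self.make_stats([0.9, 0.5, 0.3])).tolist() == [0, 1, 2]

    def test_ties_break_by_frame_id(self):
        assert sort_frames(self.make_stats([0.5, 0.5, 0.5])).tolist() == [0, 1, 2]


class TestSplitHalves:
    def test_even_split(self):
        a, b = split_halves(list(range(10)), seed=0)
        assert len(a) == 5 and len(b) == 5
        assert sorted(np.concatenate([a, b])) == list(range(10))

    def test_odd_split(self):
        a, b = split_halves(list(range(11)), seed=0)
        assert sorted([len(a), len(b)]) == [5, 6]

    def test_deterministic(self):
        a1, b1 = split_halves(list(range(20)), seed=7)
        a2, b2 = split_halves(list(range(20)), seed=7)
        assert a1.tolist() == a2.tolist() and b1.tolist() == b2.tolist()


class TestCCHalf:
    def test_identical_halves_give_exactly_one(self):
        m = merged_from(TRIPLES, [1.0, 2.0, 3.0])
        assert cc_half(m, m) == 1.0

    def test_reversed_gives_minus_one(self):
        a = merged_from(TRIPLES, [1.0, 2.0, 3.0])
        b = merged_from(TRIPLES, [3.0, 2.0, 1.0])
        assert cc_half(a, b) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        a = merged_from(TRIPLES, [1.0, 2.0, 3.0])
        b = merged_from(TRIPLES, [1.0, 2.0, 4.0])
        assert cc_half(a, b) == pytest.approx(0.982, abs=5e-4)

    def test_too_few_common_reflections_is_nan(self):
        a = merged_from([(1, 1, 1)], [1.0])
        assert np.isnan(cc_half(a, a.copy()))

    def test_affine_rescale_invariance(self):
        rng = np.random.default_rng(0)
        hkl = np.column_stack([np.arange(1, 31), np.ones(30, int), np.ones(30, int)])
        a = merged_from(hkl, rng.exponential(5, 30))
        b = merged_from(hkl, a["i_merged"].to_numpy() + rng.normal(0, 1, 30))
        base = cc_half(a, b)
        a2, b2 = a.copy(), b.copy()
        a2["i_merged"] = a2["i_merged"] * 3.0 + 10.0
        b2["i_merged"] = b2["i_merged"] * 3.0 + 10.0
        assert cc_half(a2, b2) == pytest.approx(base, abs=1e-12)

    def test_friedel_mates_averaged(self):
        # same triple with +/- mates: CC1/2 sees their mean
        a = merged_from([(1, 1, 1), (1, 1, 1), (2, 1, 1), (3, 1, 1)],
                        [10.0, 20.0, 5.0, 8.0], friedel=[1, -1, 1, 1])
        b = merged_from([(1, 1, 1), (2, 1, 1), (3, 1, 1)], [15.0, 5.0, 8.0])
        assert cc_half(a, b) == 1.0


class TestCCAno:
    def pair_set(self, deltas):
        rows = []
        for i, dI in enumerate(deltas):
            rows.append(((i + 1, 1, 2), 100 + dI / 2, 1))
            rows.append(((i + 1, 1, 2), 100 - dI / 2, -1))
        hkl = [r[0] for r in rows]
        return merged_from(hkl, [r[1] for r in rows], friedel=[r[2] for r in rows])

    def test_identical_delta_vectors(self):
        m = self.pair_set([5.0, -3.0, 8.0])
        assert cc_ano(m, m.copy()) == pytest.approx(1.0)

    def test_negated_delta_vectors(self):
        a = self.pair_set([5.0, -3.0, 8.0])
        b = self.pair_set([-5.0, 3.0, -8.0])
        assert cc_ano(a, b) == pytest.approx(-1.0)

    def test_null_distribution(self):
        """No anomalous signal: |CCano| stays within 3/sqrt(n)."""
        vals = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 400
            a = self.pair_set(rng.normal(0, 1, n))
            b = self.pair_set(rng.normal(0, 1, n))
            vals.append(abs(cc_ano(a, b)))
        assert np.median(vals) < 3 / np.sqrt(400)

    def test_unpaired_reflections_excluded(self):
        a = merged_from([(1, 1, 2), (1, 1, 2), (2, 1, 2)], [10, 6, 9], friedel=[1, -1, 1])
        b = merged_from([(1, 1, 2), (1, 1, 2)], [11, 5], friedel=[1, -1])
        # only one complete pair in both halves -> below MIN_COMMON
        assert np.isnan(cc_ano(a, b))


class TestRsplit:
    def test_identical_halves(self):
        m = merged_from(TRIPLES, [1.0, 2.0, 3.0])
        assert r_split(m, m) == 0.0

    def test_single_reflection_plugin(self):
        a = merged_from([(1, 1, 1)], [10.0])
        b = merged_from([(1, 1, 1)], [12.0])
        assert r_split(a, b) == pytest.approx(2 / (11 * np.sqrt(2)))

    def test_homogeneous_under_common_scale(self):
        rng = np.random.default_rng(1)
        hkl = np.column_stack([np.arange(1, 21), np.ones(20, int), np.ones(20, int)])
        a = merged_from(hkl, rng.exponential(10, 20))
        b = merged_from(hkl, rng.exponential(10, 20))
        base = r_split(a, b)
        a["i_merged"] *= 5.3
        b["i_merged"] *= 5.3
        assert r_split(a, b) == pytest.approx(base, rel=1e-12)


class TestResolutionCutoff:
    def shells(self, cc):
        n = len(cc)
        return pd.DataFrame(
            {
                "d_low": np.linspace(20, 4, n),
                "d_high": np.linspace(18, 2, n),
                "cc_half": cc,
            }
        )

    def test_threshold_walk(self):
        df = self.shells([0.99, 0.8, 0.5, 0.3])
        assert resolution_cutoff(df, "cc_half", 0.5) == pytest.approx(df["d_high"][2])

    def test_all_pass(self):
        df = self.shells([0.9, 0.8, 0.7])
        assert resolution_cutoff(df, "cc_half", 0.5) == pytest.approx(df["d_high"].iloc[-1])

    def test_first_shell_fails(self):
        df = self.shells([0.3, 0.2])
        assert resolution_cutoff(df, "cc_half", 0.5) is None

    def test_monotone_threshold_property(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            cc = np.sort(rng.uniform(0, 1, 8))[::-1]
            df = self.shells(cc)
            cuts = [resolution_cutoff(df, "cc_half", t) for t in (0.2, 0.5, 0.8)]
            res = [0.0 if c is None else 1.0 / c for c in cuts]
            # higher threshold -> cutoff at lower resolution (larger d, smaller 1/d)
            assert all(a >= b for a, b in zip(res, res[1:]))


class TestScans:
    def small_obs(self):
        rng = np.random.default_rng(0)
        rows = []
        for f in range(12):
            hkl = np.column_stack(
                [rng.integers(1, 6, 20), np.ones(20, int), np.ones(20, int)]
            )
            rows.append(
                pd.DataFrame(
                    {
                        "frame_id": f,
                        "h": hkl[:, 0],
                        "k": hkl[:, 1],
                        "l": hkl[:, 2],
                        "intensity": rng.exponential(10, 20),
                        "sigma": np.ones(20),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_cumulative_multiplicity_non_decreasing(self):
        obs = self.small_obs()

        def mult(sel):
            return monte_carlo_merge(sel, PG1)["multiplicity"].mean()

        res = cumulative_curve(obs, np.arange(12), step=3, metric_fn=mult)
        assert np.all(np.diff(res.metric) >= 0)

    def test_final_point_equals_full_merge(self):
        obs = self.small_obs()

        def nuniq(sel):
            return float(len(monte_carlo_merge(sel, PG1)))

        res = cumulative_curve(obs, np.arange(12), step=5, metric_fn=nuniq)
        assert res.axis[-1] == 12
        assert res.metric[-1] == nuniq(obs)

    def test_rejection_scan_low_threshold_is_full_merge(self):
        obs = self.small_obs()
        ft = frame_table(obs)

        def nobs(sel):
            return float(len(sel))

        res = rejection_scan(obs, ft, [-10.0, 1e9], nobs)
        assert res.metric[0] == len(obs)
        assert np.isnan(res.metric[1])  # threshold above every frame

    def test_scanresult_validation(self):
        with pytest.raises(ValueError):
            ScanResult(axis=[1.0, 1.0], metric=[0.0, 0.0], argmax=1.0)
        with pytest.raises(ValueError):
            ScanResult(axis=[1.0, 2.0], metric=[0.0], argmax=1.0)
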