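import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import pairladder as pl
from pairladder.merging import (
    cc_half,
    cc_significance,
    cc_star,
    completeness,
    merge_intensities,
    merging_table,
    r_metrics,
)
from pairladder.reflections import friedel_reduce

from conftest import random_unmerged


def brute_force_merging(uset, shells):
    """Naive per-unique loops: the independent oracle for all shell statistics."""
    keys = [tuple(k) for k in friedel_reduce(uset.hkl)]
    groups = {}
    for key, i, s in zip(keys, uset.intensity, uset.sigma):
        groups.setdefault(key, []).append((i, s))
    rows = {}
    for key, obs in groups.items():
        ints = np.array([o[0] for o in obs])
        sigs = np.array([o[1] for o in obs])
        n = len(ints)
        d = uset.cell.d_spacing(key)
        rows[key] = dict(
            d=d,
            n=n,
            mean=ints.mean(),
            sig=np.sqrt((sigs**2).sum()) / n,
            dev=np.abs(ints - ints.mean()).sum(),
            isum=ints.sum(),
            half_a=ints[0] if n == 2 else None,
            half_b=ints[1] if n == 2 else None,
        )
    out = []
    for i in range(shells.n_shells):
        hi, lo = shells.bounds(i)
        inshell = [
            r for r in rows.values() if (lo <= r["d"] < hi) or (r["d"] == shells.d_max and i == 0)
        ]
        multi = [r for r in inshell if r["n"] >= 2]
        denom = sum(r["isum"] for r in multi)
        if multi and denom != 0:
            rmerge = sum(r["dev"] for r in multi) / denom
            rmeas = sum(r["dev"] * np.sqrt(r["n"] / (r["n"] - 1)) for r in multi) / denom
            rpim = sum(r["dev"] * np.sqrt(1.0 / (r["n"] - 1)) for r in multi) / denom
        else:
            rmerge = rmeas = rpim = np.nan
        pairs = [r for r in multi if r["n"] == 2]
        if len(pairs) >= 3:
            a = np.array([r["half_a"] for r in pairs])
            b = np.array([r["half_b"] for r in pairs])
            cc = np.corrcoef(a, b)[0, 1] if a.std() > 0 and b.std() > 0 else np.nan
        else:
            cc = np.nan
        out.append(
            dict(
                n_unique=len(inshell),
                n_obs=sum(r["n"] for r in inshell),
                iosig=np.mean([r["mean"] / r["sig"] for r in inshell]) if inshell else np.nan,
                r_merge=rmerge,
                r_meas=rmeas,
                r_pim=rpim,
                cc_half=cc,
            )
        )
    return out


class TestMergeIntensities:
    def test_hand_example(self, cubic_cell):
        u = pl.UnmergedSet(cubic_cell, [(1, 0, 0)] * 2, [10.0, 12.0], [1.0, 1.0])
        m = merge_intensities(u)
        assert m.i_mean[0] == pytest.approx(11.0)
        assert m.sigma[0] == pytest.approx(np.sqrt(2) / 2)
        assert m.n_obs[0] == 2

    def test_single_observation(self, cubic_cell):
        u = pl.UnmergedSet(cubic_cell, [(1, 0, 0)], [10.0], [2.0])
        m = merge_intensities(u)
        assert m.i_mean[0] == 10.0 and m.sigma[0] == 2.0 and m.n_obs[0] == 1

    def test_friedel_mates_merge(self, cubic_cell):
        u = pl.UnmergedSet(
            cubic_cell, [(1, 0, 0), (-1, 0, 0)], [10.0, 12.0], [1.0, 1.0]
        )
        m = merge_intensities(u)
        assert len(m) == 1 and m.i_mean[0] == pytest.approx(11.0)


class TestRMetrics:
    def test_hand_example_n2(self, cubic_cell):
        u = pl.UnmergedSet(cubic_cell, [(1, 0, 0)] * 2, [10.0, 12.0], [1.0, 1.0])
        sch = pl.make_shells(11.0, 9.0, width=2.0)
        r = r_metrics(u, sch)
        assert r.r_merge.iloc[-1] == pytest.approx(2 / 22)
        assert r.r_meas.iloc[-1] == pytest.approx(2 * np.sqrt(2) / 22)
        assert r.r_pim.iloc[-1] == pytest.approx(2 / 22)

    def test_identical_observations_give_zero(self, cubic_cell):
        u = pl.UnmergedSet(cubic_cell, [(1, 0, 0)] * 3, [5.0] * 3, [1.0] * 3)
        sch = pl.make_shells(11.0, 9.0, width=2.0)
        r = r_metrics(u, sch)
        assert r.iloc[-1].tolist() == [0.0, 0.0, 0.0]

    def test_ordering_invariants(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            u = random_unmerged(rng)
            sch = pl.make_shells(float(u.d_spacings().max()) + 1e-9, 1.2, width=0.8)
            r = r_metrics(u, sch).dropna()
            assert (r.r_pim <= r.r_meas + 1e-15).all()
            assert (r.r_merge <= r.r_meas + 1e-15).all()


class TestCCHalf:
    def test_hand_pearson_three_pairs(self, cubic_cell):
        hkl = [(1, 0, 0), (1, 0, 0), (0, 1, 0), (0, 1, 0), (0, 0, 1), (0, 0, 1)]
        ints = [10.0, 12.0, 5.0, 5.0, 1.0, 3.0]
        u = pl.UnmergedSet(cubic_cell, hkl, ints, [1.0] * 6)
        sch = pl.make_shells(11.0, 9.0, width=2.0)
        cc = cc_half(u, sch, seed=0)
        # deterministic n=2 split: A=(10,5,1), B=(12,5,3)
        assert cc.cc_half.iloc[-1] == pytest.approx(0.9699, abs=1e-4)

    def test_duplicated_halves_give_unity(self, cubic_cell):
        hkl = [(1, 0, 0)] * 2 + [(0, 1, 0)] * 2 + [(0, 0, 1)] * 2
        ints = [10.0, 10.0, 5.0, 5.0, 1.0, 1.0]
        u = pl.UnmergedSet(cubic_cell, hkl, ints, [1.0] * 6)
        sch = pl.make_shells(11.0, 9.0, width=2.0)
        assert cc_half(u, sch, seed=0).cc_half.iloc[-1] == pytest.approx(1.0)

    def test_two_uniques_is_missing(self, cubic_cell):
        hkl = [(1, 0, 0)] * 2 + [(0, 1, 0)] * 2
        u = pl.UnmergedSet(cubic_cell, hkl, [1.0, 2.0, 3.0, 4.0], [1.0] * 4)
        sch = pl.make_shells(11.0, 9.0, width=2.0)
        assert np.isnan(cc_half(u, sch, seed=0).cc_half.iloc[-1])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        u = random_unmerged(rng, n_obs=50)
        sch = pl.make_shells(float(u.d_spacings().max()) + 1e-9, 1.2, width=5.0)
        a = cc_half(u, sch, seed=3)
        b = cc_half(u, sch, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestCCSignificance:
    def test_extreme_cases(self):
        assert cc_significance(0.99, 100) is True
        assert cc_significance(0.0, 50) is False
        assert cc_significance(0.5, 2) is None

    def test_matches_t_tail(self):
        cc, n = 0.5, 30
        t = cc * np.sqrt((n - 2) / (1 - cc**2))
        p = sps.t.sf(t, n - 2)
        assert cc_significance(cc, n) is bool(p < 0.001)


class TestCCStar:
    @pytest.mark.parametrize(
        "cc12, expected",
        [(1.0, 1.0), (0.5, np.sqrt(1 / 1.5)), (0.179, 0.551)],
    )
    def test_values(self, cc12, expected):
        assert cc_star(cc12) == pytest.approx(expected, abs=5e-4)

    def test_negative_is_missing_and_below_range_raises(self):
        assert np.isnan(cc_star(-0.1))
        with pytest.raises(ValueError):
            cc_star(-1.0)

    def test_monotone_with_fixed_points(self):
        x = np.linspace(0, 1, 101)
        y = cc_star(x)
        assert y[0] == 0.0 and y[-1] == 1.0
        assert np.all(np.diff(y) > 0)


class TestCompleteness:
    def test_full_sphere_is_complete(self, noise_free_bundle):
        cfg, _, _, unmerged = noise_free_bundle
        sch = pl.make_shells(float(unmerged.d_spacings().max()) + 1e-9, cfg.d_min, width=0.2)
        comp = completeness(unmerged, sch)
        # shells whose d-range admits no index at all carry NaN, not 0
        filled = comp.completeness.dropna()
        assert len(filled) > 10
        assert np.allclose(filled, 100.0)
        assert comp.completeness.iloc[-1] == pytest.approx(100.0)

    def test_removing_half_a_shell(self, cubic_cell):
        uniq = pl.reflections.enumerate_unique_indices(cubic_cell, 2.5)
        sch = pl.make_shells(11.0, 2.5, edges=[2.5])
        n = len(uniq)
        kept = uniq[: n - n // 2]
        m = pl.MergedSet(
            cubic_cell, kept, np.ones(len(kept)), np.ones(len(kept)), np.zeros(len(kept), int)
        )
        comp = completeness(m, sch)
        assert comp.completeness.iloc[0] == pytest.approx(100.0 * len(kept) / n)

    def test_empty_set_zero(self, cubic_cell):
        m = pl.MergedSet(cubic_cell, [(5, 0, 0)], [1.0], [1.0], [0])  # d = 2
        sch = pl.make_shells(10.0, 5.0, edges=[5.0])  # set's record is outside
        assert completeness(m, sch).completeness.iloc[0] == 0.0


class TestMergingTable:
    def test_row_count_and_consistency(self):
        rng = np.random.default_rng(12)
        u = random_unmerged(rng, n_obs=50)
        sch = pl.make_shells(float(u.d_spacings().max()) + 1e-9, 1.2, width=2.0)
        tab = merging_table(u, sch, seed=0)
        assert len(tab) == sch.n_shells + 1
        body = tab.iloc[:-1]
        nz = body[body.n_unique > 0]
        assert np.allclose(nz.multiplicity * nz.n_unique, nz.n_obs)
        # overall row pools the shells
        assert tab.n_obs.iloc[-1] == body.n_obs.sum()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        u = random_unmerged(rng, n_obs=50)
        sch = pl.make_shells(float(u.d_spacings().max()) + 1e-9, 1.2, width=2.0)
        pd.testing.assert_frame_equal(
            merging_table(u, sch, seed=9), merging_table(u, sch, seed=9)
        )

    def test_matches_brute_force_oracle(self):
        """All shell statistics equal naive loops on random small sets."""
        rng = np.random.default_rng(99)
        for _ in range(25):
            u = random_unmerged(rng, n_obs=int(rng.integers(10, 50)))
            sch = pl.make_shells(float(u.d_spacings().max()) + 1e-9, 1.2, width=1.5)
            tab = merging_table(u, sch, seed=0)
            oracle = brute_force_merging(u, sch)
            for i, row in enumerate(oracle):
                got = tab.iloc[i]
                assert got.n_unique == row["n_unique"]
                assert got.n_obs == row["n_obs"]
                for col in ("r_merge", "r_meas", "r_pim"):
                    if np.isnan(row[col]):
                        assert np.isnan(got[col])
                    else:
                        assert got[col] == pytest.approx(row[col], abs=1e-12)
                if row["n_unique"]:
                    assert got.mean_i_over_sigma == pytest.approx(row["iosig"], abs=1e-12)


def test_i_over_sigma_declines_with_noise(small_config):
    """<I/sigma> falls as the planted noise fractions grow (trend over seeds)."""
    import dataclasses

    lo, hi = [], []
    for seed in range(3):
        for target, (a, b) in zip((lo, hi), ((0.02, 0.02), (0.3, 0.5))):
            cfg = dataclasses.replace(
                small_config, noise_rel=a, noise_shell=b, seed=seed
            )
            truth = pl.generate_truth(cfg)
            _, unmerged = pl.generate_data(truth, cfg)
            sch = pl.make_shells(
                float(unmerged.d_spacings().max()) + 1e-9, cfg.d_min, width=5.0
            )
            tab = merging_table(unmerged, sch, seed=seed)
            target.append(tab.mean_i_over_sigma.iloc[-1])
    assert np.mean(lo) > np.mean(hi)
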