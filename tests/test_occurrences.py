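"""Record cleaning: summer filter, snapping, thinning, weighting, folds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mtenm.binning import TimeBinning
from mtenm.exceptions import AllMaskedError, EmptyAgeMassError, MissingMonthError
from mtenm.occurrences import (
    assign_bins,
    assign_folds,
    extract_environment,
    filter_summer,
    fossil_pseudo_replicates,
    snap_to_ocean,
    spatial_thin,
)


def rec(id, x=5, y=5, era="contemporary", stock="bering", year=2000.0, month=7,
        age_mass=None, weight=1.0, bin=None):
    r = dict(id=id, x=x, y=y, era=era, stock=stock, year=year, month=month,
             age_mass=age_mass, weight=weight)
    if bin is not None:
        r["bin"] = bin
    return r


def frame(rows):
    df = pd.DataFrame(rows)
    df["month"] = df["month"].astype("Int64")
    return df


class TestSummerFilter:
    def test_retention_rules(self):
        df = frame([
            rec("a", era="historical", year=1800, month=7),
            rec("b", era="contemporary", month=12),
            rec("c", era="fossil", year=1200, month=None,
                age_mass={0: 1.0}),
        ])
        out = filter_summer(df)
        assert list(out["id"]) == ["a", "c"]

    def test_missing_month_raises_named_error(self):
        df = frame([rec("a", month=None)])
        with pytest.raises(MissingMonthError):
            filter_summer(df)


class TestSnapToOcean:
    def make_mask(self):
        mask = np.ones((6, 6), dtype=bool)
        mask[:, :2] = False  # land in the two west columns
        return mask

    def test_ocean_record_unchanged(self):
        df = frame([rec("a", x=4, y=3)])
        out, log = snap_to_ocean(df, self.make_mask())
        assert (out.loc[0, ["x", "y"]] == [4, 3]).all() and log.empty

    def test_land_record_moves_to_brute_force_nearest(self):
        mask = self.make_mask()
        df = frame([rec("a", x=1, y=3)])
        out, _ = snap_to_ocean(df, mask)
        # brute-force nearest-ocean search
        best = min(
            ((x, y) for y in range(6) for x in range(6) if mask[y, x]),
            key=lambda c: (c[0] - 1) ** 2 + (c[1] - 3) ** 2,
        )
        assert (out.loc[0, "x"], out.loc[0, "y"]) == best

    def test_far_land_record_dropped(self):
        # nearest ocean is 2 cells = 180 km away: beyond the 170 km rule
        df = frame([rec("a", x=0, y=3)])
        out, log = snap_to_ocean(df, self.make_mask())
        assert out.empty
        assert log.loc[0, "nearest_ocean_km"] == pytest.approx(180.0)


class TestSpatialThin:
    def test_same_cell_same_bin_keeps_one(self):
        df = frame([rec("a", year=1995), rec("b", year=1990)])
        df = assign_bins(df, TimeBinning(4))
        out = spatial_thin(df)
        assert list(out["id"]) == ["b"]  # earliest year survives

    def test_adjacent_bins_both_kept(self):
        df = frame([rec("a", year=2000), rec("b", year=1960)])
        df = assign_bins(df, TimeBinning(4))
        assert len(spatial_thin(df)) == 2

    def test_matches_brute_force_groupby_oracle(self):
        rng = np.random.default_rng(0)
        rows = [
            rec(f"r{i:03d}", x=int(rng.integers(5)), y=int(rng.integers(5)),
                year=float(rng.uniform(1880, 2019)))
            for i in range(80)
        ]
        df = assign_bins(frame(rows), TimeBinning(4))
        out = spatial_thin(df)
        # oracle: per (cell, bin), min by (year, id)
        expected = {
            min(grp.itertuples(), key=lambda r: (r.year, r.id)).id
            for _, grp in df.groupby(["x", "y", "bin"])
        }
        assert set(out["id"]) == expected

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(1)
        rows = [
            rec(f"r{i}", x=int(rng.integers(4)), y=int(rng.integers(4)),
                year=float(rng.uniform(1900, 2019)))
            for i in range(60)
        ]
        df = assign_bins(frame(rows), TimeBinning(4))
        once = spatial_thin(df)
        twice = spatial_thin(once)
        assert list(once["id"]) == list(twice["id"])
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert set(spatial_thin(shuffled)["id"]) == set(once["id"])

    def test_separate_thinning_when_fossils_do_not_compete(self):
        df = frame([
            rec("f1#b0", era="fossil", year=None, month=None, weight=0.5, bin=0),
            rec("c1", year=2000, bin=0),
        ])
        assert len(spatial_thin(df, compete=True)) == 1
        assert len(spatial_thin(df, compete=False)) == 2


class TestFossilPseudoReplicates:
    def test_single_bin_mass(self):
        df = frame([rec("f", era="fossil", month=None, age_mass={3: 1.0})])
        out = fossil_pseudo_replicates(df)
        assert len(out) == 1
        assert out.loc[0, "id"] == "f#b3"
        assert out.loc[0, "weight"] == 1.0

    def test_uniform_interval_split_70_30(self):
        # uniform age density over an interval overlapping two bins 70%/30%:
        # the per-bin masses are the overlap fractions
        df = frame([rec("f", era="fossil", month=None,
                        age_mass={0: 0.7, 1: 0.3})])
        out = fossil_pseudo_replicates(df)
        assert list(out["weight"]) == [0.7, 0.3]

    def test_weights_sum_to_one(self, sampled_records):
        _, records = sampled_records
        fossils = records[records["era"] == "fossil"]
        out = fossil_pseudo_replicates(fossils)
        parent = out["id"].str.split("#").str[0]
        sums = out.groupby(parent)["weight"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_empty_age_mass_raises(self):
        df = frame([rec("f", era="fossil", month=None, age_mass={})])
        with pytest.raises(EmptyAgeMassError):
            fossil_pseudo_replicates(df)

    def test_total_weight_conserved(self, sampled_records):
        _, records = sampled_records
        out = fossil_pseudo_replicates(records)
        n_fossil = (records["era"] == "fossil").sum()
        n_other = (records["era"] != "fossil").sum()
        assert out["weight"].sum() == pytest.approx(n_fossil + n_other)


class TestExtractEnvironment:
    def make_world(self, field):
        import xarray as xr

        ny, nx = field.shape
        mask = np.ones((ny, nx), dtype=np.int8)
        return xr.Dataset(
            {
                **{v: (("bin", "y", "x"), field[None]) for v in ("sic", "sst", "sss", "bathy")},
                "mask": (("y", "x"), mask),
            }
        )

    def test_uniform_field(self):
        world = self.make_world(np.full((5, 5), 7.0))
        env, n = extract_environment(2, 2, 0, world)
        assert env["sst"] == 7.0 and n == 9

    def test_center_plus_neighbors_mean(self):
        field = np.ones((5, 5))
        field[2, 2] = 10.0
        world = self.make_world(field)
        env, n = extract_environment(2, 2, 0, world)
        assert env["sic"] == pytest.approx(2.0)  # (10 + 8) / 9

    def test_coastal_cell_uses_ocean_neighbors_only(self):
        field = np.full((5, 5), 4.0)
        world = self.make_world(field)
        world["mask"].values[0:3, 0] = 0  # 3 land neighbours west of (1, 1)
        env, n = extract_environment(1, 1, 0, world)
        assert n == 6 and env["sss"] == 4.0

    def test_all_masked_raises(self):
        world = self.make_world(np.full((5, 5), 1.0))
        world["mask"].values[:] = 0
        with pytest.raises(AllMaskedError):
            extract_environment(2, 2, 0, world)


class TestAssignFolds:
    def test_single_stratum_balance(self):
        df = frame([rec(f"r{i:03d}") for i in range(100)])
        folds = assign_folds(df, k=10, seed=0)
        counts = folds.value_counts()
        assert (counts == 10).all()

    def test_two_strata_each_fold_has_one_of_each(self):
        rows = [rec(f"a{i}", stock="bering") for i in range(10)]
        rows += [rec(f"b{i}", stock="okhotsk") for i in range(10)]
        df = frame(rows)
        folds = assign_folds(df, k=10, seed=1)
        merged = df.merge(folds.rename("fold"), left_on="id", right_index=True)
        per = merged.groupby(["fold", "stock"]).size()
        assert (per == 1).all()

    def test_deterministic_and_order_invariant(self):
        df = frame([rec(f"r{i}", stock="bering" if i % 2 else "okhotsk") for i in range(37)])
        f1 = assign_folds(df, k=10, seed=5)
        f2 = assign_folds(df.sample(frac=1.0, random_state=2), k=10, seed=5)
        pd.testing.assert_series_equal(f1.sort_index(), f2.sort_index())

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(frame([rec("a")]), k=1)

    @given(st.lists(st.sampled_from(["bering", "okhotsk", "svalbard"]), min_size=12, max_size=60))
    def test_fold_balance_within_every_stratum(self, stocks):
        df = frame([rec(f"r{i:03d}", stock=s) for i, s in enumerate(stocks)])
        folds = assign_folds(df, k=10, seed=3)
        merged = df.merge(folds.rename("fold"), left_on="id", right_index=True)
        for _, grp in merged.groupby("stock"):
            sizes = grp.groupby("fold").size()
            # count folds that received 0 within the stratum as size 0
            full = sizes.reindex(range(1, 11), fill_value=0)
            assert full.max() - full.min() <= 1
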