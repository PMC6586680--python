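import numpy as np
import pandas as pd
import pytest

from agrosdm import (altitudinal_profile, area_change_percent, classify_change,
                     portfolio_richness, replacement_analysis,
                     species_area_change_table)
from agrosdm.change import GAIN, INVALID, LOSS, NEVER, REMAIN


def toy_pair():
    """3x3 maps: baseline 5 presences; future keeps 3, adds 2 new."""
    baseline = np.array([[1, 1, 1], [1, 1, 0], [0, 0, 0]], dtype=float)
    future = np.array([[1, 1, 1], [0, 0, 0], [1, 1, 0]], dtype=float)
    return baseline, future


def random_map_pair(rng, shape=(8, 8)):
    b = (rng.uniform(size=shape) > 0.5).astype(float)
    f = (rng.uniform(size=shape) > 0.5).astype(float)
    mask = rng.uniform(size=shape) < 0.1
    b[mask] = np.nan
    f[mask] = np.nan
    return b, f


class TestClassifyChange:
    def test_identity_has_no_loss_or_gain(self):
        b, _ = toy_pair()
        cm = classify_change(b, b)
        assert cm.count(LOSS) == 0 and cm.count(GAIN) == 0
        assert cm.count(REMAIN) == int(np.nansum(b))

    def test_toy_enumeration(self):
        cm = classify_change(*toy_pair())
        assert (cm.count(REMAIN), cm.count(LOSS), cm.count(GAIN)) == (3, 2, 2)

    def test_partition_identities_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            b, f = random_map_pair(rng)
            cm = classify_change(b, f)
            valid = ~np.isnan(b)
            assert cm.count(REMAIN) + cm.count(LOSS) == int(np.nansum(b))
            assert cm.count(REMAIN) + cm.count(GAIN) == int(np.nansum(f))
            total = sum(cm.count(c) for c in (NEVER, REMAIN, LOSS, GAIN))
            assert total == int(valid.sum())
            assert np.all((cm.categories == INVALID) == ~valid)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_change(np.zeros((2, 2)), np.zeros((2, 3)))


class TestAreaChange:
    def test_identity_percentages(self):
        b, _ = toy_pair()
        pct = area_change_percent(classify_change(b, b))
        assert pct == {"loss_pct": 0.0, "gain_pct": 0.0, "remain_pct": 100.0}

    def test_total_loss(self):
        b, _ = toy_pair()
        pct = area_change_percent(classify_change(b, np.zeros_like(b)))
        assert pct["loss_pct"] == 100.0 and pct["remain_pct"] == 0.0

    def test_toy_arithmetic(self):
        pct = area_change_percent(classify_change(*toy_pair()))
        assert pct["loss_pct"] == pytest.approx(40.0)
        assert pct["gain_pct"] == pytest.approx(40.0)
        assert pct["remain_pct"] == pytest.approx(60.0)

    def test_loss_plus_remain_is_hundred_under_cos_weighting(self, grid):
        rng = np.random.default_rng(1)
        b, f = random_map_pair(rng, grid.shape)
        pct = area_change_percent(classify_change(b, f), area_mode="cos_lat_km2",
                                  grid=grid)
        assert pct["loss_pct"] + pct["remain_pct"] == pytest.approx(100.0)

    def test_empty_baseline_is_error(self):
        cm = classify_change(np.zeros((3, 3)), np.ones((3, 3)))
        with pytest.raises(ValueError, match="baseline"):
            area_change_percent(cm)


class TestAltitudinalProfile:
    def test_single_elevation_occupies_one_bin(self):
        b, f = toy_pair()
        elev = np.full((3, 3), 523.0)
        prof = altitudinal_profile(classify_change(b, f), elev, bin_width=100)
        assert len(prof.bins) == 1
        assert prof.bins.iloc[0]["bin_lo"] == 500.0

    def test_bin_totals_partition_classified_cells(self):
        rng = np.random.default_rng(2)
        b, f = random_map_pair(rng)
        elev = rng.uniform(0, 2500, size=b.shape)
        cm = classify_change(b, f)
        prof = altitudinal_profile(cm, elev, bin_width=100)
        total = prof.bins[["never", "remain", "loss", "gain"]].to_numpy().sum()
        assert total == int(np.sum(cm.categories != INVALID))

    def test_named_bands_reported(self):
        b, f = toy_pair()
        prof = altitudinal_profile(classify_change(b, f), np.full((3, 3), 2000.0))
        bands = prof.bands.set_index("band")
        assert bands.loc[">1800 m"][["never", "remain", "loss", "gain"]].sum() == 9
        assert bands.loc["0-300 m"][["never", "remain", "loss", "gain"]].sum() == 0


class TestReplacement:
    def test_empty_alternative_crop(self):
        cm = classify_change(*toy_pair())
        rm = replacement_analysis(cm, np.zeros((3, 3)))
        assert np.sum(rm.categories == 1) == 0             # replaceable
        assert np.sum(rm.categories == 3) == cm.count(LOSS)  # no_alternative

    def test_superset_alternative_gives_full_replacement(self):
        cm = classify_change(*toy_pair())
        rm = replacement_analysis(cm, np.ones((3, 3)))
        assert rm.replaceable_fraction == pytest.approx(100.0)

    def test_toy_three_of_four_loss_cells(self):
        baseline = np.array([[1.0, 1, 1, 1, 0]])
        future_a = np.array([[0.0, 0, 0, 0, 0]])          # 4 loss cells
        future_b = np.array([[1.0, 1, 1, 0, 0]])          # covers 3 of them
        rm = replacement_analysis(classify_change(baseline, future_a), future_b)
        assert rm.replaceable_fraction == pytest.approx(75.0)

    def test_replaceable_and_no_alternative_partition_loss(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            b, f = random_map_pair(rng)
            fb = (rng.uniform(size=b.shape) > 0.5).astype(float)
            fb[np.isnan(b)] = np.nan
            cm = classify_change(b, f)
            rm = replacement_analysis(cm, fb)
            n_rep = np.sum(rm.categories == 1)
            n_noalt = np.sum(rm.categories == 3)
            assert n_rep + n_noalt == cm.count(LOSS)

    def test_band_fractions_with_elevation(self):
        baseline = np.array([[1.0, 1], [1, 1]])
        future_a = np.zeros((2, 2))
        future_b = np.array([[1.0, 0], [1, 0]])
        elev = np.array([[100.0, 100], [500, 500]])
        rm = replacement_analysis(classify_change(baseline, future_a), future_b,
                                  elevation=elev)
        bands = rm.band_fractions.set_index("band")
        assert bands.loc["0-300 m", "replaceable_pct"] == pytest.approx(50.0)
        assert bands.loc["400-700 m", "replaceable_pct"] == pytest.approx(50.0)


class TestPortfolio:
    def build_species_maps(self):
        """5 cells: 31 balanced / 31 unbalanced / 10 / 3 / 0 species."""
        groups = {}
        names = []
        for g, n in (("fruit", 12), ("nfixing", 12), ("timber", 11)):
            for i in range(n):
                nm = f"{g}{i}"
                names.append(nm)
                groups[nm] = g
        per_cell = {
            0: {"fruit": 11, "nfixing": 10, "timber": 10},   # 31, balanced -> high
            1: {"fruit": 12, "nfixing": 12, "timber": 7},    # 31, timber < 10
            2: {"fruit": 4, "nfixing": 3, "timber": 3},      # 10 species
            3: {"fruit": 3, "nfixing": 0, "timber": 0},      # 3 -> low
            4: {"fruit": 0, "nfixing": 0, "timber": 0},      # 0 -> low
        }
        maps = {}
        for nm in names:
            arr = np.zeros((1, 5))
            grp = groups[nm]
            rank = int(nm[len(grp):])
            for cell, spec in per_cell.items():
                if rank < spec[grp]:
                    arr[0, cell] = 1.0
            maps[nm] = arr
        return maps, groups

    def test_toy_option_classes(self):
        maps, groups = self.build_species_maps()
        crop = np.ones((1, 5))
        pm = portfolio_richness(maps, groups, crop, rich_total=30,
                                rich_per_group=10, low_cutoff=3)
        assert pm.total_richness.ravel().tolist() == [31, 31, 10, 3, 0]
        assert np.sum(pm.classes == 1) == 1    # high_option: only the balanced cell
        assert np.sum(pm.classes == 2) == 2    # low_option: the 3- and 0-species cells
        assert pm.fractions["high_option_pct"] == pytest.approx(20.0)
        assert pm.fractions["low_option_pct"] == pytest.approx(40.0)

    def test_richness_bounded_by_species_count(self):
        maps, groups = self.build_species_maps()
        pm = portfolio_richness(maps, groups, np.ones((1, 5)))
        assert np.nanmax(pm.total_richness) <= len(maps)
        assert 0 <= pm.fractions["high_option_pct"] <= 100

    def test_missing_group_is_error(self):
        with pytest.raises(ValueError, match="group"):
            portfolio_richness({"sp": np.ones((1, 1))}, {}, np.ones((1, 1)))


class TestSpeciesTable:
    def engineered_changes(self):
        shifts = {-60: None, -40: None, -20: None, -16: None, -10: None,
                  0: None, 10: None, 16: None, 20: None, 40: None}
        changes, groups = {}, {}
        for i, pct in enumerate(sorted(shifts)):
            base, fut = 50, int(round(50 * (1 + pct / 100)))
            remain = min(base, fut)
            cat = np.full((1, 120), NEVER, dtype=np.int8)
            cat[0, :remain] = REMAIN
            cat[0, remain:base] = LOSS if fut < base else NEVER
            if fut > base:
                cat[0, base:fut] = GAIN
            from agrosdm.change import ChangeMap
            name = f"sp{i:02d}"
            changes[name] = ChangeMap(categories=cat)
            groups[name] = "fruit"
        return changes, groups

    def test_counts_beyond_fifteen_percent(self):
        changes, groups = self.engineered_changes()
        table, counts = species_area_change_table(changes, groups)
        row = counts.set_index("group").loc["fruit"]
        assert row["n_losing_gt_cutoff"] == 4   # -60, -40, -20, -16
        assert row["n_gaining_gt_cutoff"] == 3  # +16, +20, +40
        assert set(table["pct_change"].round(0)) == {-60, -40, -20, -16, -10, 0,
                                                     10, 16, 20, 40}

    def test_all_static_species_have_zero_change(self):
        b = np.ones((2, 2))
        from agrosdm import classify_change
        cm = classify_change(b, b)
        table, counts = species_area_change_table({"a": cm, "b": cm},
                                                  {"a": "fruit", "b": "timber"})
        assert (table["pct_change"] == 0).all()
        assert counts["n_losing_gt_cutoff"].sum() == 0

    def test_halved_range_is_minus_fifty(self):
        baseline = np.ones((1, 10))
        future = np.concatenate([np.ones((1, 5)), np.zeros((1, 5))], axis=1)
        from agrosdm import classify_change
        cm = classify_change(baseline, future)
        table, _ = species_area_change_table({"x": cm}, {"x": "timber"})
        assert table.loc[0, "pct_change"] == pytest.approx(-50.0)

    def test_empty_baseline_logged_as_undefined(self):
        from agrosdm import classify_change
        cm_ok = classify_change(np.ones((1, 4)), np.ones((1, 4)))
        cm_empty = classify_change(np.zeros((1, 4)), np.ones((1, 4)))
        table, counts = species_area_change_table(
            {"ok": cm_ok, "none": cm_empty}, {"ok": "fruit", "none": "fruit"})
        assert table.set_index("species").loc["none", "pct_change"] != \
            table.set_index("species").loc["none", "pct_change"]  # NaN
        assert counts.set_index("group").loc["fruit", "n_species"] == 1
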