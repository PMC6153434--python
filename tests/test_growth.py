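"""Spheroid growth: seeding, division with radial displacement, hypoxic
death and whole-growth properties."""

import numpy as np
import pytest

import hapabm as H
from hapabm.core import STATE_NECROTIC, STATE_VIABLE, VACANT, check_occupancy
from hapabm.growth import (GrowthParams, crop_to_spheroid, divide,
                           equivalent_diameter, grow_step, grow_to_day,
                           seed_spheroid)


class TestSeeding:
    def test_zero_fraction_gives_all_targets(self, toy_lines):
        grid, cells = seed_spheroid(200, 0.0, toy_lines, seed=1)
        assert cells.counts_by_line()["ACT"] == 0
        assert cells.counts_by_line()["TGT"] == 200

    def test_realized_fraction_within_binomial_ci(self, toy_lines):
        # n = 2000, p = 0.5: 99% CI half-width = 2.576*sqrt(p(1-p)/n) = 0.029
        grid, cells = seed_spheroid(2000, 0.5, toy_lines, seed=7)
        frac = cells.counts_by_line()["ACT"] / 2000
        assert abs(frac - 0.5) < 0.029

    def test_seeded_ball_is_compact(self, toy_lines):
        grid, cells = seed_spheroid(500, 0.5, toy_lines, seed=3)
        r = grid.radii(cells.site)
        ball_r = grid.dx * (3 * 500 / (4 * np.pi)) ** (1 / 3)
        assert r.max() < ball_r + 2 * grid.dx

    def test_small_seeding_gives_larger_between_run_variance(self, toy_lines):
        # local activator density is far noisier for 20 than for 2000 seeds
        fracs20, fracs2000 = [], []
        for s in range(12):
            _, c20 = seed_spheroid(20, 0.10, toy_lines, seed=s)
            _, c2k = seed_spheroid(2000, 0.10, toy_lines, seed=s)
            fracs20.append(c20.counts_by_line()["ACT"] / 20)
            fracs2000.append(c2k.counts_by_line()["ACT"] / 2000)
        assert np.std(fracs20) > np.std(fracs2000)

    def test_capacity_check(self, toy_lines):
        with pytest.raises(ValueError, match="capacity"):
            seed_spheroid(10 ** 6, 0.5, toy_lines, seed=0, max_radius=30.0)


class TestDivision:
    def test_adjacent_vacancy_used_without_moving_others(self, toy_lines):
        grid, cells = seed_spheroid(2, 0.0, toy_lines, seed=0,
                                    volume_jitter=False)
        sites_before = set(cells.site.tolist())
        rng = np.random.default_rng(0)
        divide(grid, cells, 0, rng)
        assert len(cells) == 3
        assert sites_before <= set(cells.site.tolist()) | {cells.site[0]}
        check_occupancy(grid, cells)

    def test_volume_halved_between_mother_and_daughter(self, toy_lines):
        grid, cells = seed_spheroid(1, 0.0, toy_lines, seed=0,
                                    volume_jitter=False)
        cells.volume[0] = 3500.0
        divide(grid, cells, 0, np.random.default_rng(0))
        assert cells.volume[0] == pytest.approx(1750.0)
        assert cells.volume[1] == pytest.approx(1750.0)

    def test_lineage_inherited(self, toy_lines):
        grid, cells = seed_spheroid(1, 1.0, toy_lines, seed=0)
        divide(grid, cells, 0, np.random.default_rng(0))
        assert cells.line_idx[1] == cells.line_idx[0]

    def test_radial_push_conserves_cells_and_lineages(self, toy_lines):
        grid, cells = seed_spheroid(123, 0.4, toy_lines, seed=5)
        counts_before = cells.counts_by_line()
        rng = np.random.default_rng(1)
        # divide an interior cell (its neighbourhood is fully occupied)
        r = grid.radii(cells.site)
        inner = int(np.argmin(r))
        divide(grid, cells, inner, rng)
        counts_after = cells.counts_by_line()
        gained = cells.line_idx[len(cells) - 1]
        for i, name in enumerate(("ACT", "TGT")):
            expect = counts_before[name] + (1 if gained == i else 0)
            assert counts_after[name] == expect
        check_occupancy(grid, cells)


class TestGrowStep:
    def test_one_cell_doubles_in_one_doubling_time(self, toy_lines):
        grid, cells = seed_spheroid(1, 0.0, toy_lines, seed=0,
                                    volume_jitter=False)
        params = GrowthParams(o2_scaling=lambda o2: np.ones_like(
            np.asarray(o2, dtype=float)))
        rng = np.random.default_rng(0)
        td = toy_lines[0].doubling_time
        nsteps = 31
        for _ in range(nsteps):
            grow_step(grid, cells, np.full(len(cells), 1e6), params,
                      td / nsteps, rng)
        assert len(cells) == 2

    def test_no_growth_without_oxygen_scaling(self, toy_lines):
        grid, cells = seed_spheroid(10, 0.0, toy_lines, seed=0)
        v0 = cells.volume.copy()
        grow_step(grid, cells, np.zeros(10), GrowthParams(), 3600.0,
                  np.random.default_rng(0))
        assert np.allclose(cells.volume, v0)

    def test_sustained_severe_hypoxia_leads_to_necrosis(self, toy_lines):
        grid, cells = seed_spheroid(5, 0.0, toy_lines, seed=0)
        params = GrowthParams()
        rng = np.random.default_rng(0)
        O2 = np.zeros(5)  # below the 0.15 uM severe threshold
        for _ in range(49):  # 49 h > 24 h tagging + 24 h lysis
            grow_step(grid, cells, O2, params, 3600.0, rng)
        assert np.all(cells.state == STATE_NECROTIC)
        assert grid.n_occupied() == 0

    def test_hypoxic_death_can_be_disabled(self, toy_lines):
        grid, cells = seed_spheroid(5, 0.0, toy_lines, seed=0)
        params = GrowthParams(hypoxic_death=False)
        rng = np.random.default_rng(0)
        for _ in range(49):
            grow_step(grid, cells, np.zeros(len(cells)), params, 3600.0, rng)
        assert np.all(cells.state == STATE_VIABLE)


class TestGrowToDay:
    def test_population_growth_matches_exponential(self, reg, toy_lines):
        # abundant O2 and no death: N(t) = N0 * 2^(t/td) within 2% over 2 d
        from dataclasses import replace
        lines = (replace(toy_lines[0], doubling_time=16 * 3600.0),
                 replace(toy_lines[1], doubling_time=16 * 3600.0))
        params = GrowthParams(hypoxic_death=False,
                              o2_scaling=lambda o2: np.ones_like(
                                  np.asarray(o2, dtype=float)))
        res = grow_to_day(2.0, 100, 0.5, lines, seed=2, reg=reg,
                          params=params)
        expected = 100 * 2 ** (48 / 16)
        assert res.cells.n_viable == pytest.approx(expected, rel=0.02)

    def test_day0_diameter_matches_geometry(self, toy_lines):
        grid, cells = seed_spheroid(3000, 0.5, toy_lines, seed=0)
        d = equivalent_diameter(grid)
        expected = (6 * 3000 * grid.site_volume / np.pi) ** (1 / 3)
        assert d == pytest.approx(expected, rel=1e-12)

    def test_slower_line_ends_below_seeded_fraction(self, reg, lines):
        # POR-G doubles in 38 h vs 31 h: after 4 days its share of a 50:50
        # co-culture falls towards 2^(96/38) / (2^(96/38) + 2^(96/31))
        res = grow_to_day(4.0, 500, 0.5, (lines["POR-G"], lines["PORko-R"]),
                          seed=4, reg=reg)
        frac = res.counts["POR-G"] / sum(res.counts.values())
        assert frac < 0.5
        ratio = 2 ** (96 / 38) / (2 ** (96 / 38) + 2 ** (96 / 31))
        assert frac == pytest.approx(ratio, abs=0.06)

    def test_equal_doubling_keeps_seeded_fraction(self, reg, lines):
        res = grow_to_day(2.0, 1000, 0.5,
                          (lines["POR-R"], lines["PORko-G"]), seed=9, reg=reg)
        frac = res.counts["POR-R"] / sum(res.counts.values())
        assert abs(frac - 0.5) < 0.045  # binomial 99% CI + drift

    def test_radial_oxygen_monotone_decreasing_inward(self, reg, lines):
        res = grow_to_day(3.0, 1000, 0.5,
                          (lines["POR-R"], lines["PORko-G"]), seed=6, reg=reg)
        prof = res.o2_profile
        inside = res.o2_radii < res.diameter / 2
        assert np.all(np.diff(prof[inside]) > -1e-9)

    def test_cell_count_never_decreases_without_necrosis(self, reg, toy_lines):
        params = GrowthParams(hypoxic_death=False)
        res = grow_to_day(1.0, 200, 0.5, toy_lines, seed=1, reg=reg,
                          params=params)
        assert res.cells.n_viable >= 200

    def test_stop_at_cells(self, reg, toy_lines):
        res = grow_to_day(30.0, 20, 0.1, toy_lines, seed=3, reg=reg,
                          params=GrowthParams(hypoxic_death=False),
                          stop_at_cells=1000)
        assert 1000 <= res.cells.n_viable < 1300

    def test_determinism_given_seed(self, reg, toy_lines):
        a = grow_to_day(1.0, 100, 0.5, toy_lines, seed=11, reg=reg)
        b = grow_to_day(1.0, 100, 0.5, toy_lines, seed=11, reg=reg)
        assert np.array_equal(a.cells.site, b.cells.site)
        assert np.array_equal(a.cells.line_idx, b.cells.line_idx)


class TestCrop:
    def test_crop_preserves_cells_and_occupancy(self, reg, toy_lines):
        res = grow_to_day(1.0, 300, 0.5, toy_lines, seed=2, reg=reg)
        sub, cells = crop_to_spheroid(res.grid, res.cells)
        assert sub.n_sites < res.grid.n_sites
        assert len(cells) == len(res.cells)
        check_occupancy(sub, cells)
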