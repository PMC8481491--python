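"""Dispersal timing draws, epoch tables, lineage-area frequency, windowed rates."""

import numpy as np
import pytest

from biogeodiv.branch_rates import (BranchRateSeries, MappedRegime,
                                    RateRegime, constant_regime,
                                    rates_on_grid)
from biogeodiv.combine import (AreaMerge, EpochTable, draw_event_times,
                               epoch_dispersal_percentages,
                               lineage_area_frequency, nine_to_five,
                               nine_to_six, windowed_regional_rates)
from biogeodiv.dec import AreaScheme, DispersalEvent, NINE_AREAS
from biogeodiv.phylo import parse_newick


@pytest.fixture(scope="module")
def scheme9():
    return AreaScheme(NINE_AREAS)


def _event(branch=0, source=0b1, gained=1, old=10.0, young=6.0):
    return DispersalEvent(branch=branch, source_mask=source,
                          gained_area=gained, old_age=old, young_age=young)


class TestMerge:
    def test_nine_to_six_mapping(self, scheme9):
        m = nine_to_six(scheme9)
        assert m.regions == ("Nearctic", "Palearctic", "Neotropics",
                             "Afrotropics", "SEAsia", "Australasia")
        assert m.region_of_area(scheme9.names.index("WNearctic")) == \
            m.region_of_area(scheme9.names.index("ENearctic"))
        assert m.region_of_area(scheme9.names.index("India")) == \
            m.region_of_area(scheme9.names.index("SEAsia"))
        # total and surjective by construction
        assert set(m.assignment) == set(range(6))

    def test_nine_to_five_combines_sea_australasia(self, scheme9):
        m = nine_to_five(scheme9)
        i = scheme9.names.index
        assert m.region_of_area(i("SEAsia")) == m.region_of_area(i("Australasia"))
        assert m.n_regions == 5


class TestDrawTimes:
    def test_draws_inside_interval_and_reproducible(self):
        evs = [_event(), _event(young=2.0, old=3.0)]
        draw_event_times(evs, 500, seed=11)
        assert np.all((evs[0].times > 6.0) & (evs[0].times < 10.0))
        t1 = evs[0].times.copy()
        draw_event_times(evs, 500, seed=11)
        assert np.array_equal(evs[0].times, t1)

    def test_degenerate_interval(self):
        ev = _event(young=4.0, old=4.0)
        draw_event_times([ev], 10, seed=0)
        assert np.all(ev.times == 4.0)

    def test_mean_matches_uniform(self):
        ev = _event(young=6.0, old=10.0)
        draw_event_times([ev], 100000, seed=1)
        # Monte-Carlo CI: sd = 4/sqrt(12)/sqrt(n) ~ 0.0037
        assert abs(ev.times.mean() - 8.0) < 0.02


class TestEpochPercentages:
    def test_single_cell_is_100(self, scheme9):
        i = scheme9.names.index
        evs = [_event(source=1 << i("SEAsia"), gained=i("Australasia"),
                      old=20.0, young=10.0) for _ in range(10)]
        draw_event_times(evs, 50, seed=2)
        res = epoch_dispersal_percentages(evs)
        m = res.merge
        p = res.table.period_of(15.0)
        src = m.regions.index("SEAsia")
        dst = m.regions.index("Australasia")
        assert res.mean[p, src, dst] == pytest.approx(100.0)

    def test_replicate_matrices_sum_to_100(self, scheme9):
        rng = np.random.default_rng(5)
        evs = []
        for _ in range(40):
            src = int(rng.integers(1, 2 ** 9))
            gained = int(rng.integers(9))
            old = float(rng.uniform(5, 60))
            young = old - float(rng.uniform(0.5, 5))
            evs.append(_event(source=src, gained=gained, old=old,
                              young=max(young, 0.0)))
        draw_event_times(evs, 200, seed=3)
        res = epoch_dispersal_percentages(evs)
        sums = np.nansum(res.per_replicate, axis=(2, 3))
        has_events = ~np.isnan(res.per_replicate).all(axis=(2, 3))
        assert np.allclose(sums[has_events], 100.0, atol=1e-9)

    def test_fractional_source_attribution(self, scheme9):
        i = scheme9.names.index
        src = (1 << i("Neotropics")) | (1 << i("Afrotropics"))
        ev = _event(source=src, gained=i("SEAsia"), old=20.0, young=10.0)
        draw_event_times([ev], 5, seed=4)
        res = epoch_dispersal_percentages([ev])
        m = res.merge
        p = res.table.period_of(15.0)
        dst = m.regions.index("SEAsia")
        assert res.mean[p, m.regions.index("Neotropics"), dst] == \
            pytest.approx(50.0)
        assert res.mean[p, m.regions.index("Afrotropics"), dst] == \
            pytest.approx(50.0)


class TestLineageAreaFrequency:
    def test_single_lineage_single_region(self, scheme9):
        t = parse_newick("(A:5,B:5);")
        masks = np.full(t.n_nodes, 1 << scheme9.names.index("Neotropics"))
        df = lineage_area_frequency(t, masks, nine_to_six(scheme9), 0.5)
        assert np.allclose(df["Neotropics"], 1.0)
        assert np.allclose(df[[c for c in df.columns
                               if c not in ("age", "n_lineages",
                                            "Neotropics")]], 0.0)

    def test_proportions_sum_to_one(self):
        scheme = AreaScheme(("A", "B", "C"))
        merge = AreaMerge(source=scheme, regions=("A", "B", "C"),
                          assignment=(0, 1, 2))
        t = parse_newick("((A:2,B:2):2,C:4);")
        masks = np.array([0b001, 0b011, 0b010, 0b001, 0b100])
        df = lineage_area_frequency(t, masks, merge, 0.5)
        share = df[["A", "B", "C"]].to_numpy()
        assert np.allclose(share.sum(axis=1), 1.0)
        assert np.all((share >= 0) & (share <= 1))

    def test_midpoint_convention(self):
        """A gain on a branch from age 10 to 4 applies from age 7."""
        scheme = AreaScheme(("A", "B"))
        merge = AreaMerge(source=scheme, regions=("A", "B"),
                          assignment=(0, 1))
        t = parse_newick("(X:10,Y:10);")
        idx = t.tip_index()
        masks = np.zeros(t.n_nodes, dtype=int)
        masks[t.root] = 0b01
        masks[idx["X"]] = 0b11   # gained B somewhere on the branch
        masks[idx["Y"]] = 0b01
        # restrict X's branch to [4, 10] by pruning? simpler: bin checks
        df = lineage_area_frequency(t, masks, merge, 0.5)
        b_share = df.set_index("age")["B"]
        # ages above the midpoint (5.0): parent range {A}; below: {A,B}
        assert b_share.loc[5.25] == 0.0
        assert b_share.loc[4.75] > 0.0

    def test_bad_bin_rejected(self, scheme9):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            lineage_area_frequency(t, np.ones(3, dtype=int),
                                   nine_to_six(scheme9), 0.0)


class TestWindowedRates:
    def _setup(self):
        scheme = AreaScheme(("A", "B"))
        merge = AreaMerge(source=scheme, regions=("A", "B"),
                          assignment=(0, 1))
        t = parse_newick("((A:4,B:4):6,(C:7,D:7):3);")
        return scheme, merge, t

    def test_constant_rates_give_constant_windows(self):
        scheme, merge, t = self._setup()
        series = rates_on_grid(t, constant_regime(t, 0.1, 0.02), dt=0.5)
        masks = np.full(t.n_nodes, 0b01)
        res = windowed_regional_rates(t, series, masks, merge=merge,
                                      n_rep=5, seed=0)
        a = res.lam[:, 0, :]
        assert np.allclose(a[~np.isnan(a)], 0.1, atol=1e-12)
        net = res.net[:, 0, :]
        assert np.allclose(net[~np.isnan(net)], 0.08, atol=1e-12)

    def test_weighted_mean_two_segments(self):
        """Segments of length 2 (rate .1) and 1 (rate .4) -> mean 0.2."""
        scheme, merge, t = self._setup()
        idx = t.tip_index()
        vA, vB = idx["A"], idx["B"]
        series = {}
        # craft two co-occupying branch series inside the window [0, 4]
        series[vA] = BranchRateSeries(
            branch=vA, ages=np.array([1.0]), cell_young=np.array([0.0]),
            cell_old=np.array([2.0]), lam=np.array([0.1]),
            mu=np.array([0.0]), mean_net=0.1)
        series[vB] = BranchRateSeries(
            branch=vB, ages=np.array([0.5]), cell_young=np.array([0.0]),
            cell_old=np.array([1.0]), lam=np.array([0.4]),
            mu=np.array([0.0]), mean_net=0.4)
        masks = np.zeros(t.n_nodes, dtype=int)
        masks[:] = 0b01
        res = windowed_regional_rates(t, series, masks, merge=merge,
                                      window=4.0, step=4.0, n_rep=2, seed=0)
        # first window [0,4]: (0.1*2 + 0.4*1) / 3 = 0.2
        assert res.lam[0, 0, 0] == pytest.approx(0.2, abs=1e-12)

    def test_refinement_invariance(self):
        """Splitting a branch's series at a cell edge leaves rates unchanged."""
        scheme, merge, t = self._setup()
        series = rates_on_grid(t, constant_regime(t, 0.23, 0.07), dt=0.5)
        masks = np.full(t.n_nodes, 0b01)
        base = windowed_regional_rates(t, series, masks, merge=merge,
                                       n_rep=3, seed=1)
        idx = t.tip_index()
        v = idx["C"]   # branch 7 -> 0, 14 cells
        s = series[v]
        k = 6
        split = dict(series)
        split.pop(v)
        split[v] = BranchRateSeries(branch=v, ages=s.ages[:k],
                                    cell_young=s.cell_young[:k],
                                    cell_old=s.cell_old[:k],
                                    lam=s.lam[:k], mu=s.mu[:k],
                                    mean_net=s.mean_net)
        split[-1] = BranchRateSeries(branch=-1, ages=s.ages[k:],
                                     cell_young=s.cell_young[k:],
                                     cell_old=s.cell_old[k:],
                                     lam=s.lam[k:], mu=s.mu[k:],
                                     mean_net=s.mean_net)
        # emulate the collinear split by handing the two halves to the
        # averaging with the same occupancy; branch -1 has no tree entry, so
        # attach it via a masks/occupancy trick: both halves belong to branch
        # v's interval, and occupancy is whole-branch, so summing the two
        # halves must reproduce the original integrals
        res2 = windowed_regional_rates(t, split, masks, merge=merge,
                                       n_rep=3, seed=1)
        a, b = base.lam, res2.lam
        mask = ~(np.isnan(a) | np.isnan(b))
        assert np.allclose(a[mask], b[mask], atol=1e-9)

    def test_single_region_occupancy_matches_global_mean(self):
        """When every lineage occupies one region, the occupancy-weighted
        mean over regions equals the tree-wide branch-length-weighted mean
        (algebraic identity, time-varying rates)."""
        scheme, merge, t = self._setup()
        reg = MappedRegime(t.root, RateRegime(t.root_age, 0.3, -0.1, 0.05))
        series = rates_on_grid(t, [reg], dt=0.5)
        idx = t.tip_index()
        masks = np.full(t.n_nodes, 0b01)
        for lab in ("C", "D"):
            masks[idx[lab]] = 0b10
        masks[t.mrca(["C", "D"])] = 0b10
        # the only anagenetic change sits on the branch into the (C,D) clade
        # (ages 7-10); inside the window [0, 3] every lineage occupies
        # exactly one region for the window's full duration
        res = windowed_regional_rates(t, series, masks, merge=merge,
                                      window=3.0, step=3.0, n_rep=1, seed=0)
        lam = res.lam[0, :, 0]
        num = np.zeros(2)
        den = np.zeros(2)
        g_num = g_den = 0.0
        for v, s in series.items():
            regions = merge.region_indices(int(masks[v]))
            for k in range(len(s.ages)):
                a = max(float(s.cell_young[k]), 0.0)
                b = min(float(s.cell_old[k]), 3.0)
                if b <= a:
                    continue
                g_num += s.lam[k] * (b - a)
                g_den += b - a
                for r0 in regions:
                    num[r0] += s.lam[k] * (b - a)
                    den[r0] += b - a
        assert lam == pytest.approx(num / den, abs=1e-12)
        weighted = float(np.sum(lam * den) / den.sum())
        assert weighted == pytest.approx(g_num / g_den, abs=1e-9)

    def test_spread_shrinks_with_more_replicates(self):
        import warnings

        scheme, merge, t = self._setup()
        reg = MappedRegime(t.root, RateRegime(t.root_age, 0.3, -0.1, 0.05))
        series = rates_on_grid(t, [reg], dt=0.5)
        idx = t.tip_index()
        masks = np.full(t.n_nodes, 0b01)
        masks[idx["C"]] = 0b11   # one gain with random timing
        spreads = []
        for n_rep in (10, 100):
            means = []
            for seed in range(5):
                res = windowed_regional_rates(t, series, masks, merge=merge,
                                              n_rep=n_rep, seed=seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    means.append(np.nanmean(res.lam[:, 1, :], axis=0))
            # seed-to-seed scatter of the replicate-averaged window means
            spreads.append(np.nanmean(np.nanstd(np.array(means), axis=0)))
        assert spreads[1] < spreads[0]
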