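import itertools

import numpy as np
import pytest

from formucomet.formulation import ComponentClass, Formulation, FormulationError
from formucomet.grids import (
    BASE_RATIO,
    DesignGrid,
    MolarRatio,
    all_molar_compositions,
    campaign_grid,
    campaign_part_manifests,
    enumerate_dual_il,
    enumerate_single_il,
    enumerate_sweeps,
    enumerate_virtual_library,
    exclude_near_hits,
    sweep_compositions,
    thirteen_base_ratios,
    virtual_library_count,
)


def _grid(n_il=2, n_st=1, n_hl=1, n_pg=1, n_ratios=3, **kw):
    ratios = [MolarRatio("BASE", BASE_RATIO)]
    for i in range(1, n_ratios):
        v = 35.0 - 5 * i
        rest = 100.0 - v - 16.0 - 2.5
        ratios.append(MolarRatio(f"R{i}", (v, 16.0, rest, 2.5)))
    return DesignGrid(
        catalogues={
            ComponentClass.IONIZABLE: [f"il{i}" for i in range(n_il)],
            ComponentClass.STEROL: [f"st{i}" for i in range(n_st)],
            ComponentClass.HELPER: [f"hl{i}" for i in range(n_hl)],
            ComponentClass.PEG: [f"pg{i}" for i in range(n_pg)],
        },
        molar_ratios=ratios,
        **kw,
    )


class TestEnumeration:
    def test_single_il_minimal(self):
        g = _grid(1, 1, 1, 1, 1)
        assert sum(1 for _ in enumerate_single_il(g)) == 1

    def test_single_il_closed_form(self):
        g = _grid(2, 2, 2, 2, n_ratios=2)
        forms = list(enumerate_single_il(g))
        assert len(forms) == 2 * 2 * 2 * 2 * 2
        # all distinct and each sums to 100
        assert len({f.components for f in forms}) == len(forms)
        for f in forms:
            assert sum(f.molar_percents) == pytest.approx(100.0)

    def test_dual_il_counts(self):
        g = _grid(3, 1, 1, 1, n_ratios=2, dual_ionizable=True)
        forms = list(enumerate_dual_il(g))
        assert len(forms) == 9 * 2
        g1 = _grid(1, 1, 1, 1, 1, dual_ionizable=True)
        (only,) = list(enumerate_dual_il(g1))
        # self-pair collapses to a single ionizable entry
        assert len(only.components) == 4

    def test_dual_split_allocation(self):
        g = _grid(2, 1, 1, 1, 1, dual_ionizable=True)
        mixed = [f for f in enumerate_dual_il(g) if len(f.components) == 5]
        for f in mixed:
            il_pcts = sorted((p for _, p in f.components[:2]), reverse=True)
            assert il_pcts[0] / (il_pcts[0] + il_pcts[1]) == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_match_brute_force_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        g = _grid(
            int(rng.integers(1, 4)),
            int(rng.integers(1, 3)),
            int(rng.integers(1, 3)),
            int(rng.integers(1, 3)),
            n_ratios=int(rng.integers(1, 4)),
            np_ratios=[6.0] * int(rng.integers(1, 3)),
            aq_org_ratios=["3:1", "1:1"][: int(rng.integers(1, 3))],
            dual_ionizable=bool(rng.integers(0, 2)),
        )
        assert virtual_library_count(g) == sum(1 for _ in enumerate_virtual_library(g))

    def test_stream_order_deterministic(self):
        g = _grid(2, 2, 1, 1, 2, dual_ionizable=True)
        a = [f.components for f in enumerate_virtual_library(g)]
        b = [f.components for f in enumerate_virtual_library(g)]
        assert a == b
        assert g.content_hash() == g.content_hash()

    def test_empty_class_rejected(self):
        with pytest.raises(FormulationError, match="empty catalogue"):
            DesignGrid(
                catalogues={
                    ComponentClass.IONIZABLE: [],
                    ComponentClass.STEROL: ["s"],
                    ComponentClass.HELPER: ["h"],
                    ComponentClass.PEG: ["p"],
                },
                molar_ratios=[MolarRatio("BASE", BASE_RATIO)],
            )

    def test_huge_grid_count_is_exact_int(self):
        g = _grid(3, 3, 2, 2, 3)
        g.np_ratios = list(np.linspace(1, 30, 100))
        g.aq_org_ratios = ["3:1", "1:1"]
        n = virtual_library_count(g)
        assert isinstance(n, int)
        assert n == 3 * 3 * 2 * 2 * 3 * 100 * 2


class TestSweeps:
    def test_sweep_endpoints_and_count(self):
        vecs = enumerate_sweeps(ComponentClass.IONIZABLE, 10.0, 80.0, 24)
        assert len(vecs) == 24
        assert vecs[0][0] == pytest.approx(10.0)
        assert vecs[-1][0] == pytest.approx(80.0)
        for v in vecs:
            assert sum(v) == pytest.approx(100.0)

    def test_proportional_rebalancing(self):
        (vec,) = [enumerate_sweeps(ComponentClass.IONIZABLE, 35.0, 70.0, 2)[0]]
        # at the BASE value the other classes keep their BASE shares
        assert vec == pytest.approx(BASE_RATIO)

    def test_invalid_ranges(self):
        with pytest.raises(FormulationError):
            enumerate_sweeps(ComponentClass.IONIZABLE, 80.0, 10.0, 24)
        with pytest.raises(FormulationError):
            enumerate_sweeps(ComponentClass.IONIZABLE, 10.0, 80.0, 1)

    def test_three_class_sweeps_plus_bases_give_85(self):
        grid = campaign_grid()
        assert len(sweep_compositions()) == 72
        assert len(all_molar_compositions(grid)) == 85


class TestCampaignCounts:
    def test_part_counts(self):
        grid = campaign_grid()
        assert grid.lipid_combination_count == 84
        assert sum(1 for _ in enumerate_single_il(grid)) == 1092
        assert sum(1 for _ in enumerate_dual_il(grid)) == 637

    def test_manifest_arithmetic(self):
        parts = campaign_part_manifests()
        assert parts[0].possible == 1092
        assert parts[0].unique == 1066 - 91 == 975
        assert sum(p.unique for p in parts) == 3028

    def test_thirteen_ratios_sum(self):
        ratios = thirteen_base_ratios()
        assert len(ratios) == 13
        for r in ratios:
            assert sum(r.values) == pytest.approx(100.0)
        assert len({r.values for r in ratios}) == 13


class TestExcludeNearHits:
    def _f(self, pcts, ids=("a", "b", "c", "d")):
        return Formulation(components=tuple(zip(ids, pcts)), np_ratio=6.0)

    def test_boundary_inclusive(self):
        hit = self._f((35, 16, 46.5, 2.5))
        cand = self._f((40, 16, 41.5, 2.5))  # distance exactly 10
        assert list(exclude_near_hits([cand], [hit], radius=10.0)) == []
        assert list(exclude_near_hits([cand], [hit], radius=9.99)) == [cand]

    def test_radius_zero_removes_exact_duplicates_only(self):
        hit = self._f((35, 16, 46.5, 2.5))
        dup = self._f((35, 16, 46.5, 2.5))
        near = self._f((35.5, 16, 46.0, 2.5))
        out = list(exclude_near_hits([dup, near], [hit], radius=0.0))
        assert out == [near]

    def test_different_lipid_sets_never_near(self):
        hit = self._f((35, 16, 46.5, 2.5))
        other = self._f((35, 16, 46.5, 2.5), ids=("a", "b", "c", "e"))
        assert list(exclude_near_hits([other], [hit], radius=50.0)) == [other]

    def test_small_radius_keeps_library(self):
        lib = [self._f((35.0 + i, 16, 46.5 - i, 2.5)) for i in range(1, 5)]
        hits = [self._f((10, 16, 71.5, 2.5))]
        assert list(exclude_near_hits(lib, hits, radius=1.0)) == lib
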