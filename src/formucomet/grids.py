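"""Declarative design grids and formulation enumeration.

A :class:`DesignGrid` names the molecule catalogue per component class,
a set of named molar-composition vectors, the synthesis-parameter axes
(N/P or weight ratio, aqueous/organic phase ratio) and an optional
dual-ionizable configuration.  Enumerators stream formulations in a
deterministic odometer order (axes varied from the right) so that
top-k tie-breaks and funnel runs are reproducible.

The bundled four-part screening-campaign grid mirrors a high-throughput
LNP study design: 7 ionizable x 3 sterol x 2 helper x 2 PEG lipids, 13
base molar ratios, dual-ionizable 60:40 splits, weight-ratio/phase
variation, and 24-point molar sweeps per lipid class.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .formulation import (
    CANONICAL_LIPID_CLASSES,
    Catalogue,
    ComponentClass,
    Formulation,
    FormulationError,
    l1_molar_distance,
)

#: Reference BASE composition (ionizable, helper, sterol, PEG), molar %.
BASE_RATIO: tuple[float, float, float, float] = (35.0, 16.0, 46.5, 2.5)

#: Order in which composition vectors list the lipid classes.
RATIO_CLASS_ORDER: tuple[ComponentClass, ...] = (
    ComponentClass.IONIZABLE,
    ComponentClass.HELPER,
    ComponentClass.STEROL,
    ComponentClass.PEG,
)


@dataclass(frozen=True)
class MolarRatio:
    """A named four-class molar composition summing to 100."""

    name: str
    values: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.values) - 100.0) > 1e-6:
            raise FormulationError(f"ratio {self.name!r} sums to {sum(self.values):g}")


def thirteen_base_ratios() -> list[MolarRatio]:
    """The 13 named base compositions: a BASE ratio plus single-class
    variations (ionizable I1-I4, sterol-vs-helper C1-C3, PEG P1-P3) and
    two multi-class variants, each rebalanced to sum to 100."""
    b_i, b_h, b_s, b_p = BASE_RATIO
    ratios: list[MolarRatio] = [MolarRatio("BASE", BASE_RATIO)]

    def rebalance(swept: ComponentClass, value: float, keep: ComponentClass | None = None):
        """Set one class to `value`; rescale the others proportionally
        (optionally pinning `keep` at its BASE value)."""
        base = dict(zip(RATIO_CLASS_ORDER, BASE_RATIO))
        others = [c for c in RATIO_CLASS_ORDER if c is not swept and c is not keep]
        fixed = base[keep] if keep is not None else 0.0
        rest = 100.0 - value - fixed
        total_others = sum(base[c] for c in others)
        out = dict(base)
        out[swept] = value
        for c in others:
            out[c] = base[c] * rest / total_others
        return tuple(round(out[c], 6) for c in RATIO_CLASS_ORDER)

    for i, v in enumerate((20.0, 30.0, 45.0, 55.0), start=1):
        ratios.append(MolarRatio(f"I{i}", rebalance(ComponentClass.IONIZABLE, v)))
    for i, v in enumerate((30.0, 38.0, 55.0), start=1):
        # sterol adjusted, compensated by helper lipid only
        d = v - b_s
        ratios.append(
            MolarRatio(f"C{i}", (b_i, round(b_h - d, 6), v, b_p))
        )
    for i, v in enumerate((1.0, 5.0, 10.0), start=1):
        ratios.append(MolarRatio(f"P{i}", rebalance(ComponentClass.PEG, v)))
    ratios.append(MolarRatio("M1", (25.0, 25.0, 47.5, 2.5)))
    ratios.append(MolarRatio("M2", (45.0, 10.0, 40.0, 5.0)))
    assert len(ratios) == 13
    return ratios


@dataclass
class DesignGrid:
    """Enumeration space for a formulation library.

    ``catalogues`` maps component class -> list of molecule ids; the
    four canonical lipid classes must be non-empty.  ``molar_ratios``
    are named composition vectors; ``np_ratios`` / ``weight_ratios``
    and ``aq_org_ratios`` are synthesis-parameter axes.
    """

    catalogues: dict[ComponentClass, list[str]]
    molar_ratios: list[MolarRatio]
    np_ratios: list[float] = field(default_factory=lambda: [6.0])
    weight_ratios: list[float] = field(default_factory=list)
    aq_org_ratios: list[str] = field(default_factory=lambda: ["3:1"])
    dual_ionizable: bool = False
    dual_split: tuple[float, float] = (60.0, 40.0)

    def __post_init__(self) -> None:
        for cls in CANONICAL_LIPID_CLASSES:
            if not self.catalogues.get(cls):
                raise FormulationError(f"empty catalogue for class {cls.value}")
        for r in self.molar_ratios:
            if abs(sum(r.values) - 100.0) > 1e-6:
                raise FormulationError(f"ratio {r.name} does not sum to 100")
        if abs(sum(self.dual_split) - 100.0) > 1e-6:
            raise FormulationError("dual_split must sum to 100")

    # -- identity ----------------------------------------------------
    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "catalogues": {c.value: ids for c, ids in sorted(self.catalogues.items())},
                "ratios": [(r.name, r.values) for r in self.molar_ratios],
                "np": self.np_ratios,
                "wr": self.weight_ratios,
                "aq": self.aq_org_ratios,
                "dual": [self.dual_ionizable, self.dual_split],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @property
    def lipid_combination_count(self) -> int:
        n = 1
        for cls in CANONICAL_LIPID_CLASSES:
            n *= len(self.catalogues[cls])
        return n


def _synthesis_axes(grid: DesignGrid) -> list[tuple[float | None, float | None, str]]:
    """(np_ratio, weight_ratio, aq_org) triples in odometer order."""
    np_axis: list[tuple[float | None, float | None]]
    if grid.np_ratios and grid.weight_ratios:
        np_axis = [(v, None) for v in grid.np_ratios] + [(None, w) for w in grid.weight_ratios]
    elif grid.np_ratios:
        np_axis = [(v, None) for v in grid.np_ratios]
    else:
        np_axis = [(None, w) for w in grid.weight_ratios]
    return [(n, w, aq) for (n, w) in np_axis for aq in grid.aq_org_ratios]


def enumerate_single_il(grid: DesignGrid) -> Iterator[Formulation]:
    """Every (ionizable x sterol x helper x PEG) lipid combination at
    every molar ratio, using the grid's first synthesis setting.

    Count = |I| * |S| * |H| * |P| * |ratios|.
    """
    syn = _synthesis_axes(grid)[0]
    cls_order = (
        ComponentClass.IONIZABLE,
        ComponentClass.STEROL,
        ComponentClass.HELPER,
        ComponentClass.PEG,
    )
    ratio_value = {
        ComponentClass.IONIZABLE: 0,
        ComponentClass.HELPER: 1,
        ComponentClass.STEROL: 2,
        ComponentClass.PEG: 3,
    }
    for combo in itertools.product(*(grid.catalogues[c] for c in cls_order)):
        for ratio in grid.molar_ratios:
            comps = tuple(
                (mol, ratio.values[ratio_value[cls]]) for mol, cls in zip(combo, cls_order)
            )
            yield Formulation(
                components=comps,
                np_ratio=syn[0],
                il_rna_weight_ratio=syn[1],
                aqueous_organic_ratio=syn[2],
            )


def enumerate_dual_il(grid: DesignGrid) -> Iterator[Formulation]:
    """Dual-ionizable formulations: every ordered (major, minor) pair of
    ionizable lipids -- self-pairs included -- with the ionizable molar
    allocation split per ``grid.dual_split`` (default 60:40), over each
    molar ratio.  Count = |I|^2 * |ratios|.
    """
    if not grid.dual_ionizable:
        raise FormulationError("dual_ionizable not enabled on this grid")
    syn = _synthesis_axes(grid)[0]
    ion = grid.catalogues[ComponentClass.IONIZABLE]
    helper = grid.catalogues[ComponentClass.HELPER][0]
    sterol = grid.catalogues[ComponentClass.STEROL][0]
    peg = grid.catalogues[ComponentClass.PEG][0]
    maj, minr = grid.dual_split
    for a, b in itertools.product(ion, repeat=2):
        for ratio in grid.molar_ratios:
            i_pct, h_pct, s_pct, p_pct = ratio.values
            if a == b:
                comps = ((a, i_pct),)
            else:
                comps = ((a, i_pct * maj / 100.0), (b, i_pct * minr / 100.0))
            comps = comps + ((helper, h_pct), (sterol, s_pct), (peg, p_pct))
            yield Formulation(
                components=comps,
                np_ratio=syn[0],
                il_rna_weight_ratio=syn[1],
                aqueous_organic_ratio=syn[2],
            )


def enumerate_sweeps(
    swept: ComponentClass,
    lo: float,
    hi: float,
    n_points: int,
    base: Sequence[float] = BASE_RATIO,
) -> list[tuple[float, ...]]:
    """``n_points`` evenly spaced molar-% values of one lipid class from
    ``lo`` to ``hi``; the remaining classes are rescaled proportionally
    from the BASE composition so each vector sums to 100."""
    if not lo < hi:
        raise FormulationError("need lo < hi")
    if n_points < 2:
        raise FormulationError("need n_points >= 2")
    idx = RATIO_CLASS_ORDER.index(swept)
    base = tuple(base)
    others_total = 100.0 - base[idx]
    out = []
    for v in np.linspace(lo, hi, n_points):
        rest = 100.0 - v
        if rest < 0:
            raise FormulationError(f"swept value {v} exceeds 100%")
        vec = list(base)
        for j in range(len(vec)):
            if j != idx:
                vec[j] = base[j] * rest / others_total
                if vec[j] < 0:
                    raise FormulationError("sweep leaves negative share for a class")
        vec[idx] = float(v)
        out.append(tuple(vec))
    return out


def sweep_compositions(
    classes: Iterable[ComponentClass] = (
        ComponentClass.IONIZABLE,
        ComponentClass.STEROL,
        ComponentClass.HELPER,
    ),
    lo: float = 10.0,
    hi: float = 80.0,
    n_points: int = 24,
) -> list[tuple[float, ...]]:
    """The fine molar sweeps: 24 points from 10% to 80% for each of the
    ionizable, sterol and helper classes (72 vectors by default)."""
    vecs: list[tuple[float, ...]] = []
    for cls in classes:
        vecs.extend(enumerate_sweeps(cls, lo, hi, n_points))
    return vecs


def all_molar_compositions(grid: DesignGrid) -> list[tuple[float, ...]]:
    """Distinct molar compositions: the grid's named base ratios plus
    the three-class fine sweeps (13 + 72 = 85 for the campaign grid)."""
    seen: dict[tuple[float, ...], None] = {}
    for r in grid.molar_ratios:
        seen.setdefault(tuple(round(v, 6) for v in r.values))
    for vec in sweep_compositions():
        seen.setdefault(tuple(round(v, 6) for v in vec))
    return list(seen)


def virtual_library_count(grid: DesignGrid) -> int:
    """Exact library size as a product of axis cardinalities (python
    ints are arbitrary precision, so huge grids cannot overflow)."""
    n = grid.lipid_combination_count * len(grid.molar_ratios)
    n *= max(len(grid.np_ratios) + len(grid.weight_ratios), 1)
    n *= max(len(grid.aq_org_ratios), 1)
    if grid.dual_ionizable:
        n_il = len(grid.catalogues[ComponentClass.IONIZABLE])
        dual = n_il * n_il * len(grid.molar_ratios)
        dual *= max(len(grid.np_ratios) + len(grid.weight_ratios), 1)
        dual *= max(len(grid.aq_org_ratios), 1)
        n += dual
    return n


def enumerate_virtual_library(grid: DesignGrid) -> Iterator[Formulation]:
    """Stream the full Cartesian library (never materialized): lipid
    choices x molar ratios x synthesis settings, plus the dual-ionizable
    block when enabled.  Order is a fixed odometer over declared axes."""
    cls_order = (
        ComponentClass.IONIZABLE,
        ComponentClass.STEROL,
        ComponentClass.HELPER,
        ComponentClass.PEG,
    )
    ratio_idx = {
        ComponentClass.IONIZABLE: 0,
        ComponentClass.HELPER: 1,
        ComponentClass.STEROL: 2,
        ComponentClass.PEG: 3,
    }
    for combo in itertools.product(*(grid.catalogues[c] for c in cls_order)):
        for ratio in grid.molar_ratios:
            for np_r, wr, aq in _synthesis_axes(grid):
                comps = tuple(
                    (mol, ratio.values[ratio_idx[cls]]) for mol, cls in zip(combo, cls_order)
                )
                yield Formulation(
                    components=comps,
                    np_ratio=np_r,
                    il_rna_weight_ratio=wr,
                    aqueous_organic_ratio=aq,
                )
    if grid.dual_ionizable:
        ion = grid.catalogues[ComponentClass.IONIZABLE]
        maj, minr = grid.dual_split
        for a, b in itertools.product(ion, repeat=2):
            for ratio in grid.molar_ratios:
                for np_r, wr, aq in _synthesis_axes(grid):
                    i_pct, h_pct, s_pct, p_pct = ratio.values
                    if a == b:
                        il_part: tuple[tuple[str, float], ...] = ((a, i_pct),)
                    else:
                        il_part = ((a, i_pct * maj / 100.0), (b, i_pct * minr / 100.0))
                    comps = il_part + (
                        (grid.catalogues[ComponentClass.STEROL][0], s_pct),
                        (grid.catalogues[ComponentClass.HELPER][0], h_pct),
                        (grid.catalogues[ComponentClass.PEG][0], p_pct),
                    )
                    yield Formulation(
                        components=comps,
                        np_ratio=np_r,
                        il_rna_weight_ratio=wr,
                        aqueous_organic_ratio=aq,
                    )


def exclude_near_hits(
    library: Iterable[Formulation],
    hits: Sequence[Formulation],
    radius: float,
) -> Iterator[Formulation]:
    """Drop library candidates whose molar composition lies within
    ``radius`` (inclusive) L1 distance of any hit *with the same lipid
    set*; candidates built from different lipids are never "near"."""
    if radius < 0:
        raise FormulationError("radius must be >= 0")
    hits_by_lipids: dict[frozenset[str], list[Formulation]] = {}
    for h in hits:
        hits_by_lipids.setdefault(frozenset(h.molecule_ids), []).append(h)
    for cand in library:
        key = frozenset(cand.molecule_ids)
        near = False
        for h in hits_by_lipids.get(key, ()):
            if l1_molar_distance(cand, h) <= radius:
                near = True
                break
        if not near:
            yield cand


@dataclass(frozen=True)
class PartManifest:
    """Counts for one part of a four-part screening campaign.

    ``tested`` and ``overlap`` are measured-campaign facts supplied by
    the user; ``unique`` is derived arithmetic."""

    name: str
    possible: int
    tested: int
    overlap: int = 0

    @property
    def unique(self) -> int:
        return self.tested - self.overlap


def campaign_catalogue_ids() -> dict[ComponentClass, list[str]]:
    """Molecule-id layout of the bundled campaign grid (7/3/2/2)."""
    from .synthetic import DEFAULT_CLASS_COUNTS, sample_catalogue

    cat = sample_catalogue(DEFAULT_CLASS_COUNTS, seed=0)
    return {cls: [r.id for r in cat.by_class(cls)] for cls in CANONICAL_LIPID_CLASSES}


def campaign_grid(dual: bool = True) -> DesignGrid:
    """The bundled four-part campaign grid: 7 ionizable x 3 sterol x 2
    helper x 2 PEG, the 13 named molar ratios, 60:40 dual splits."""
    return DesignGrid(
        catalogues=campaign_catalogue_ids(),
        molar_ratios=thirteen_base_ratios(),
        np_ratios=[6.0],
        aq_org_ratios=["3:1"],
        dual_ionizable=dual,
    )


def campaign_part_manifests() -> list[PartManifest]:
    """Part counts of the bundled campaign: possible counts are derived
    from the grid, tested/overlap counts are campaign facts."""
    grid = campaign_grid()
    n_ratios = len(grid.molar_ratios)
    n_il = len(grid.catalogues[ComponentClass.IONIZABLE])
    part1_possible = grid.lipid_combination_count * n_ratios
    return [
        PartManifest("part1_lipid_choice", possible=part1_possible, tested=1066, overlap=91),
        PartManifest("part2_dual_ionizable", possible=n_il * n_il * n_ratios, tested=637),
        PartManifest("part3_synthesis_parameters", possible=924, tested=924),
        PartManifest("part4_molar_sweeps", possible=492, tested=492),
    ]
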