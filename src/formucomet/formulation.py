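"""Core domain types for multi-component nanoparticle formulations.

A formulation is a set of molecular components, each present at a molar
percentage, together with formulation-wide synthesis parameters: the N/P
ratio (moles of ionizable amine nitrogen per mole of RNA backbone
phosphate) and the aqueous/organic volumetric mixing ratio.  Efficacy
labels are plate-normalized, log-transformed luminescence values scaled
to [0, 1].

This module owns validation, label normalization, the weight-ratio to
N/P conversion, the L1 composition distance used throughout screening,
and the lyophilization degradation label.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default average molar mass of one RNA nucleotide (g/mol), used to count
#: backbone phosphates when converting a lipid/RNA weight ratio to N/P.
RNA_NT_MOLAR_MASS = 330.0

MOLAR_SUM_TOL = 1e-6
MOLAR_SUM_RENORM_LIMIT = 0.01


class ComponentClass(str, Enum):
    """Roles a molecule can play in a formulation."""

    IONIZABLE = "ionizable"
    HELPER = "helper"
    STEROL = "sterol"
    PEG = "peg"
    PBAE_REPEAT = "pbae_repeat"
    PBAE_BRANCH = "pbae_branch"


#: Canonical class ordering used for type embeddings and slot vectors.
COMPONENT_CLASSES: tuple[ComponentClass, ...] = tuple(ComponentClass)

#: The four lipid classes every conventional LNP contains.
CANONICAL_LIPID_CLASSES: tuple[ComponentClass, ...] = (
    ComponentClass.IONIZABLE,
    ComponentClass.HELPER,
    ComponentClass.STEROL,
    ComponentClass.PEG,
)


class FormulationError(ValueError):
    """Raised when a formulation or label table violates an invariant."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A catalogue entry: one molecule and its role.

    Parameters
    ----------
    id : str
        Unique identifier within a catalogue.
    smiles : str
        Structure as SMILES; must be parseable by RDKit.
    component_class : ComponentClass
        Role of this molecule in formulations.
    amine_count : int, optional
        Ionizable amine nitrogens per molecule.  Required before any
        weight-ratio to N/P conversion involving this molecule.
    molar_mass : float, optional
        Molar mass in g/mol (> 0).
    """

    id: str
    smiles: str
    component_class: ComponentClass
    amine_count: int | None = None
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        if self.amine_count is not None and self.amine_count < 0:
            raise FormulationError(f"amine_count must be >= 0 for {self.id}")
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise FormulationError(f"molar_mass must be > 0 for {self.id}")


class Catalogue:
    """An ordered, id-unique collection of :class:`MoleculeRecord`."""

    def __init__(self, records: Iterable[MoleculeRecord]):
        self._records: dict[str, MoleculeRecord] = {}
        for rec in records:
            if rec.id in self._records:
                raise FormulationError(f"duplicate molecule id {rec.id!r}")
            self._records[rec.id] = rec

    def __getitem__(self, mol_id: str) -> MoleculeRecord:
        try:
            return self._records[mol_id]
        except KeyError:
            raise FormulationError(f"unknown molecule id {mol_id!r}") from None

    def __contains__(self, mol_id: str) -> bool:
        return mol_id in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def ids(self) -> list[str]:
        return list(self._records)

    def by_class(self, cls: ComponentClass) -> list[MoleculeRecord]:
        return [r for r in self._records.values() if r.component_class is cls]

    def slot_order(self) -> list[str]:
        """Deterministic component-slot ordering: sorted molecule ids."""
        return sorted(self._records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": r.id,
                "smiles": r.smiles,
                "component_class": r.component_class.value,
                "amine_count": r.amine_count,
                "molar_mass": r.molar_mass,
            }
            for r in self._records.values()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Formulation:
    """A multi-component formulation.

    ``components`` is a sequence of ``(molecule_id, molar_percent)``
    pairs.  Molar percentages are on the 0-100 scale and sum to 100.
    Dual-ionizable formulations simply carry two ionizable entries.
    Exactly one of ``np_ratio`` / ``il_rna_weight_ratio`` may be absent.
    """

    components: tuple[tuple[str, float], ...]
    np_ratio: float | None = None
    il_rna_weight_ratio: float | None = None
    aqueous_organic_ratio: str = "3:1"
    labels: Mapping[str, float] = field(default_factory=dict)
    id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple((str(m), float(p)) for m, p in self.components))

    @property
    def molecule_ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.components)

    @property
    def molar_percents(self) -> tuple[float, ...]:
        return tuple(p for _, p in self.components)

    def molar_percent_of(self, mol_id: str) -> float:
        return sum(p for m, p in self.components if m == mol_id)

    def with_labels(self, labels: Mapping[str, float]) -> "Formulation":
        return replace(self, labels=dict(labels))

    def slot_vector(self, slot_order: Sequence[str]) -> np.ndarray:
        """Molar-% vector over a shared component-slot ordering."""
        vec = np.zeros(len(slot_order))
        index = {m: i for i, m in enumerate(slot_order)}
        for m, p in self.components:
            vec[index[m]] += p
        return vec


@dataclass
class LabelSet:
    """Raw luminescence readings for one task, grouped by assay plate.

    Each plate carries a 'standard' formulation whose luminescence is
    used to normalize away plate-to-plate variation.
    """

    task_id: str
    formulation_ids: list[str]
    raw_values: list[float]  # replicate-mean raw luminescence per formulation
    plate_ids: list[str]
    standard_values: dict[str, float]  # plate_id -> standard luminescence

    def __post_init__(self) -> None:
        n = len(self.formulation_ids)
        if not (len(self.raw_values) == len(self.plate_ids) == n):
            raise FormulationError("LabelSet columns must have equal length")
        for plate, std in self.standard_values.items():
            if std <= 0:
                raise FormulationError(f"standard_value must be > 0 on plate {plate!r}")
        for plate in self.plate_ids:
            if plate not in self.standard_values:
                raise FormulationError(f"plate {plate!r} has no standard value")


@dataclass(frozen=True)
class DegradationLabel:
    """Pre/post-lyophilization efficacy pair and their difference."""

    pre_value: float
    post_value: float

    @property
    def degradation(self) -> float:
        return self.pre_value - self.post_value


def validate_formulation(f: Formulation, catalogue: Catalogue) -> Formulation:
    """Validate a formulation against its catalogue.

    Checks membership of every component, the molar-percentage sum
    (renormalizing with a warning for deviations below 0.01, rejecting
    beyond), component count, role uniqueness outside the ionizable
    class, and presence of at least one of N/P or weight ratio.

    Returns the (possibly renormalized) formulation.
    """
    if len(f.components) < 2:
        raise FormulationError("formulation needs >= 2 components")
    for mol_id, pct in f.components:
        if mol_id not in catalogue:
            raise FormulationError(f"unknown molecule id {mol_id!r}")
        if not (0.0 <= pct <= 100.0):
            raise FormulationError(f"molar percent {pct} out of [0, 100] for {mol_id!r}")
    seen: set[tuple[str, ComponentClass]] = set()
    for mol_id, _ in f.components:
        key = (mol_id, catalogue[mol_id].component_class)
        if key in seen:
            raise FormulationError(f"molecule {mol_id!r} appears twice in the same role")
        seen.add(key)
    total = sum(f.molar_percents)
    if abs(total - 100.0) > MOLAR_SUM_TOL:
        if abs(total - 100.0) <= MOLAR_SUM_RENORM_LIMIT:
            logger.warning(
                "renormalizing molar percentages of %s (sum %.6f)", f.id or "<anon>", total
            )
            comps = tuple((m, p * 100.0 / total) for m, p in f.components)
            f = replace(f, components=comps)
        else:
            raise FormulationError(f"molar sum {total:g} != 100")
    if f.np_ratio is None and f.il_rna_weight_ratio is None:
        raise FormulationError("need at least one of np_ratio / il_rna_weight_ratio")
    if f.np_ratio is not None and f.np_ratio <= 0:
        raise FormulationError("np_ratio must be > 0")
    if f.il_rna_weight_ratio is not None and f.il_rna_weight_ratio <= 0:
        raise FormulationError("il_rna_weight_ratio must be > 0")
    return f


def normalize_labels(
    label_set: LabelSet, *, log_base: float = 10.0
) -> dict[str, float]:
    """Plate-normalize, log-transform and min-max scale raw labels.

    Per plate, each replicate-mean raw value is divided by the plate
    standard; the ratios are log-transformed (base 10 by default; any
    base yields the same result after min-max) and globally min-max
    scaled so the smallest value maps to 0 and the largest to 1.

    Returns a mapping formulation id -> label in [0, 1].
    """
    ratios = []
    for fid, raw, plate in zip(
        label_set.formulation_ids, label_set.raw_values, label_set.plate_ids
    ):
        if raw <= 0:
            raise FormulationError(f"nonpositive raw value for {fid!r}")
        ratios.append(raw / label_set.standard_values[plate])
    logged = np.log(np.asarray(ratios)) / math.log(log_base)
    lo, hi = float(logged.min()), float(logged.max())
    if len(logged) < 2 or hi - lo <= 0:
        raise FormulationError("degenerate range: labels cannot be min-max scaled")
    scaled = (logged - lo) / (hi - lo)
    return dict(zip(label_set.formulation_ids, scaled.tolist()))


def weight_ratio_to_np(
    f: Formulation,
    catalogue: Catalogue,
    *,
    rna_nt_molar_mass: float = RNA_NT_MOLAR_MASS,
) -> float:
    """Convert an ionizable-lipid/RNA weight ratio to an N/P ratio.

    N/P = (moles of ionizable amine N) / (moles of RNA phosphate)
        = sum_il(mass_il / MW_il * amines_il) / (mass_RNA / per-nt mass).

    For dual-ionizable formulations the total ionizable mass is split
    between the two lipids in proportion to their molar contributions
    (moles ∝ molar %, mass ∝ molar % × MW).
    """
    if f.il_rna_weight_ratio is None:
        raise FormulationError("formulation has no il_rna_weight_ratio")
    ils = [
        (catalogue[m], p)
        for m, p in f.components
        if catalogue[m].component_class is ComponentClass.IONIZABLE
    ]
    if not ils:
        raise FormulationError("formulation has no ionizable component")
    for rec, _ in ils:
        if rec.amine_count is None or rec.molar_mass is None:
            raise FormulationError(
                f"molecule {rec.id!r} needs amine_count and molar_mass for N/P conversion"
            )
    # Split total ionizable mass by molar proportion: mole fraction x_i
    # gives mass fraction x_i*MW_i / sum_j x_j*MW_j.
    mws = np.array([rec.molar_mass for rec, _ in ils])
    amines = np.array([rec.amine_count for rec, _ in ils])
    fracs = np.array([p for _, p in ils])
    mass_fracs = fracs * mws / float(np.sum(fracs * mws))
    mass_rna = 1.0
    mass_il = f.il_rna_weight_ratio * mass_rna
    moles_amine = float(np.sum(mass_il * mass_fracs / mws * amines))
    moles_phosphate = mass_rna / rna_nt_molar_mass
    return moles_amine / moles_phosphate


def l1_molar_distance(
    a: Formulation, b: Formulation, slot_order: Sequence[str] | None = None
) -> float:
    """L1 distance between molar-% vectors over a shared slot ordering.

    Absent slots count as 0%.  When ``slot_order`` is omitted the sorted
    union of the two formulations' molecule ids is used.
    """
    if slot_order is None:
        slot_order = sorted(set(a.molecule_ids) | set(b.molecule_ids))
    return float(np.abs(a.slot_vector(slot_order) - b.slot_vector(slot_order)).sum())


def degradation_label(pre: float, post: float) -> float:
    """Efficacy lost to lyophilization: pre minus post, sign preserved."""
    return pre - post
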