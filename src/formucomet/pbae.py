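"""Branched poly(beta-amino ester) (PBAE) support.

A PBAE polymer is represented by two catalogue molecules: its
diacrylate-amine repeating unit (a fifth molar component type, carrying
the polymer's molar percentage) and its branching agent (identity
information only, molar percentage 0).  The polymer's molar
contribution is estimated from its mass and the repeat-unit molar
mass; total molar percentages of PBAE and lipids sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .formulation import (
    Catalogue,
    ComponentClass,
    Formulation,
    FormulationError,
    MoleculeRecord,
)


@dataclass(frozen=True)
class PbaeRecord:
    """One PBAE polymer: repeat unit, branching agent, and masses."""

    pbae_id: str
    repeat_unit: MoleculeRecord
    branch_agent: MoleculeRecord
    repeat_unit_molar_mass: float
    polymer_mass_mg: float = 0.0

    def __post_init__(self) -> None:
        if self.repeat_unit_molar_mass <= 0:
            raise FormulationError("repeat_unit_molar_mass must be > 0")
        if self.repeat_unit.component_class is not ComponentClass.PBAE_REPEAT:
            raise FormulationError("repeat_unit must have class pbae_repeat")
        if self.branch_agent.component_class is not ComponentClass.PBAE_BRANCH:
            raise FormulationError("branch_agent must have class pbae_branch")


def pbae_moles(p: PbaeRecord) -> float:
    """Repeat-unit moles from polymer mass: mass / repeat-unit MW (mmol)."""
    return p.polymer_mass_mg / p.repeat_unit_molar_mass


def pbae_molar_percent(p: PbaeRecord, lipid_moles: float) -> float:
    """PBAE molar % over (lipids + PBAE), so the total sums to 100."""
    if lipid_moles < 0:
        raise FormulationError("lipid_moles must be >= 0")
    moles = pbae_moles(p)
    total = moles + lipid_moles
    if total == 0:
        return 0.0
    return 100.0 * moles / total


def pbae_formulation(
    p: PbaeRecord,
    lipid_components: tuple[tuple[str, float], ...],
    lipid_moles: float,
    np_ratio: float | None = None,
    il_rna_weight_ratio: float | None = None,
    aqueous_organic_ratio: str = "3:1",
) -> Formulation:
    """Assemble a polymer-lipid hybrid formulation.

    ``lipid_components`` are (molecule_id, molar % of the lipid part);
    the lipid percentages are rescaled so lipids + PBAE repeat unit sum
    to 100.  The branching agent is appended at 0 molar % -- it
    contributes a token (identity information) but no molar share.
    """
    pct = pbae_molar_percent(p, lipid_moles)
    scale = (100.0 - pct) / 100.0
    comps = tuple((m, v * scale) for m, v in lipid_components)
    comps = comps + ((p.repeat_unit.id, pct), (p.branch_agent.id, 0.0))
    return Formulation(
        components=comps,
        np_ratio=np_ratio,
        il_rna_weight_ratio=il_rna_weight_ratio,
        aqueous_organic_ratio=aqueous_organic_ratio,
    )


def read_pbae_catalogue(path: str | Path) -> tuple[list[PbaeRecord], Catalogue]:
    """Read a PBAE catalogue CSV (pbae_id, repeat_unit_smiles,
    branch_smiles, repeat_unit_mw [, polymer_mass_mg]) and return the
    records plus a Catalogue of their component molecules."""
    df = pd.read_csv(path)
    records, molecules = [], []
    for _, row in df.iterrows():
        repeat = MoleculeRecord(
            id=f"{row['pbae_id']}-repeat",
            smiles=str(row["repeat_unit_smiles"]),
            component_class=ComponentClass.PBAE_REPEAT,
            molar_mass=float(row["repeat_unit_mw"]),
        )
        branch = MoleculeRecord(
            id=f"{row['pbae_id']}-branch",
            smiles=str(row["branch_smiles"]),
            component_class=ComponentClass.PBAE_BRANCH,
        )
        records.append(
            PbaeRecord(
                pbae_id=str(row["pbae_id"]),
                repeat_unit=repeat,
                branch_agent=branch,
                repeat_unit_molar_mass=float(row["repeat_unit_mw"]),
                polymer_mass_mg=float(row.get("polymer_mass_mg", 0.0) or 0.0),
            )
        )
        molecules.extend([repeat, branch])
    return records, Catalogue(molecules)
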