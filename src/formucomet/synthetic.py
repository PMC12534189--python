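"""Synthetic formulation datasets with a known ground-truth oracle.

The generator emulates the structure of a four-part high-throughput
LNP screening campaign -- a 7 ionizable x 3 sterol x 2 helper x 2 PEG
catalogue, 13 base molar ratios, dual-ionizable 60:40 splits -- and a
plate-based bioluminescence label pipeline: a latent efficacy oracle
(lipid potencies, quadratic molar-% optima, dual-ionizable synergy, an
N/P bump and a phase-by-helper interaction), exponentiated to raw
luminescence, multiplied by per-plate gain and lognormal handling
noise, divided by each plate's standard, log-transformed and min-max
normalized to [0, 1].

The hidden oracle values are returned separately from the labelled
table so recovery tests can compare model rankings against noiseless
ground truth without leaking it into features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formulation import (
    Catalogue,
    ComponentClass,
    Formulation,
    FormulationError,
    LabelSet,
    MoleculeRecord,
    normalize_labels,
)
from .grids import DesignGrid, enumerate_virtual_library, virtual_library_count

#: Campaign-shaped catalogue sizes.
DEFAULT_CLASS_COUNTS: dict[ComponentClass, int] = {
    ComponentClass.IONIZABLE: 7,
    ComponentClass.STEROL: 3,
    ComponentClass.HELPER: 2,
    ComponentClass.PEG: 2,
}

# Bundled fixture pool: representative structures for each component
# class (PEG-lipid chains truncated to a few ethylene-oxide units to
# keep records compact).  SMILES are parseable stand-ins named after
# the lipid families they represent; amine counts refer to ionizable
# nitrogens of the drawn structure.
_FIXTURE_POOL: dict[ComponentClass, list[tuple[str, str, int]]] = {
    ComponentClass.IONIZABLE: [
        ("IL-ALC0315", "CCCCCCCCC(CCCCCCCC)COC(=O)CCCCCN(CCO)CCCCCC(=O)OC(CCCCCCCC)CCCCCCCC", 1),
        ("IL-SM102", "CCCCCCCCCCC(=O)OCCCCCCCCN(CCO)CCCCCCCC(=O)OC(CCCCCC)CCCCCC", 1),
        ("IL-MC3", "CCCCCC=CCC=CCCCCCCCCC(CCCCCCCCC=CCC=CCCCCC)OC(=O)CCCN(C)C", 1),
        ("IL-KC2", "CCCCCC=CCC=CCCCCCCCCC1(CCCCCCCCC=CCC=CCCCCC)OCC(CN(C)C)O1", 1),
        ("IL-C12-200", "OCC(O)CN(CCCCCCCCCCCC)CCN(CC(O)CCCCCCCCCC)CCN(CC(O)CCCCCCCCCC)CCCCCCCCCCCC", 3),
        ("IL-CKK-E12", "CCCCCCCCCCCCC(O)CN(C)CCCCN(CC(O)CCCCCCCCCCCC)C(=O)C1CCCN1CC(O)CCCCCCCCCCCC", 3),
        ("IL-L319", "CCCCCCCCC=CCCCCCCCC(=O)OCCOC(=O)CCCCCCCC=CCCCCCCCC", 0),
    ],
    ComponentClass.STEROL: [
        ("ST-CHOL", "CC(C)CCCC(C)C1CCC2C1(CCC3C2CC=C4C3(CCC(C4)O)C)C", 0),
        ("ST-BSITO", "CCC(CCC(C)C1CCC2C1(CCC3C2CC=C4C3(CCC(C4)O)C)C)C(C)C", 0),
        ("ST-DCCHOL", "CC(C)CCCC(C)C1CCC2C1(CCC3C2CC=C4C3(CCC(C4)OC(=O)NCCN(C)C)C)C", 1),
    ],
    ComponentClass.HELPER: [
        ("HL-DOPE", "CCCCCCCCC=CCCCCCCCC(=O)OCC(COP(=O)(O)OCCN)OC(=O)CCCCCCCC=CCCCCCCCC", 0),
        ("HL-DSPC", "CCCCCCCCCCCCCCCCCC(=O)OCC(COP(=O)([O-])OCC[N+](C)(C)C)OC(=O)CCCCCCCCCCCCCCCCC", 0),
    ],
    ComponentClass.PEG: [
        ("PEG-C14", "CCCCCCCCCCCCCC(=O)OCC(COCCOCCOCCOCCOC)OC(=O)CCCCCCCCCCCCC", 0),
        ("PEG-C18", "CCCCCCCCCCCCCCCCCC(=O)OCC(COCCOCCOCCOCCOC)OC(=O)CCCCCCCCCCCCCCCCC", 0),
    ],
}


def _molar_mass(smiles: str) -> float:
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - pool is validated by tests
        raise FormulationError(f"unparseable fixture SMILES {smiles!r}")
    return float(Descriptors.MolWt(mol))


def sample_catalogue(
    n_per_class: Mapping[ComponentClass, int] = DEFAULT_CLASS_COUNTS,
    seed: int = 0,
) -> Catalogue:
    """Draw a deterministic molecule catalogue.

    Takes the first ``n`` structures of each class from the bundled
    pool; requests beyond the pool size are padded with enumerated
    chain-extended variants of pool members.  Molar masses come from
    the drawn structure.
    """
    del seed  # the draw is deterministic; kept for interface stability
    records: list[MoleculeRecord] = []
    for cls, n in n_per_class.items():
        if n < 1:
            raise FormulationError(f"need >= 1 molecule for class {cls.value}")
        pool = _FIXTURE_POOL.get(cls, _FIXTURE_POOL[ComponentClass.IONIZABLE])
        for i in range(n):
            if i < len(pool):
                name, smiles, amines = pool[i]
            else:
                base_name, base_smiles, amines = pool[i % len(pool)]
                # chain-extended enumerated variant
                ext = i // len(pool)
                name = f"{base_name}-v{ext}"
                smiles = "C" * ext + base_smiles
            records.append(
                MoleculeRecord(
                    id=name,
                    smiles=smiles,
                    component_class=cls,
                    amine_count=amines,
                    molar_mass=round(_molar_mass(smiles), 2),
                )
            )
    return Catalogue(records)


@dataclass
class OracleConfig:
    """Latent ground-truth efficacy surface.

    Additive terms: per-molecule potency (class-scaled), quadratic
    penalties around per-class molar-% optima, a dual-ionizable synergy
    matrix over ordered pairs, a Gaussian N/P bump and a phase-ratio by
    helper-% interaction.  ``noise_sd`` is the lognormal handling noise
    in log10 decades applied by :func:`generate_dataset`.
    """

    seed: int = 0
    class_effect_scale: Mapping[str, float] = field(
        default_factory=lambda: {
            "ionizable": 1.0,
            "helper": 0.5,
            "sterol": 0.4,
            "peg": 0.6,
            "pbae_repeat": 0.8,
            "pbae_branch": 0.3,
        }
    )
    molar_optimum: Mapping[str, float] = field(
        default_factory=lambda: {
            "ionizable": 40.0,
            "helper": 18.0,
            "sterol": 38.0,
            "peg": 3.0,
            "pbae_repeat": 40.0,
        }
    )
    molar_width: Mapping[str, float] = field(
        default_factory=lambda: {
            "ionizable": 25.0,
            "helper": 18.0,
            "sterol": 25.0,
            "peg": 5.0,
            "pbae_repeat": 25.0,
        }
    )
    synergy_scale: float = 0.5
    np_optimum: float = 12.0
    np_width: float = 8.0
    np_amplitude: float = 0.5
    phase_helper_coef: Mapping[str, float] = field(
        default_factory=lambda: {"3:1": 0.4, "1:1": -0.2}
    )
    noise_sd: float = 0.1
    label_span_decades: float = 2.5

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.molar_width.values()) or self.np_width <= 0:
            raise FormulationError("oracle widths must be > 0")


class EfficacyOracle:
    """Deterministic latent efficacy function over a catalogue."""

    def __init__(self, catalogue: Catalogue, config: OracleConfig | None = None):
        self.catalogue = catalogue
        self.config = config or OracleConfig()
        rng = np.random.default_rng(self.config.seed)
        self.potency: dict[str, float] = {}
        for rec in catalogue:
            scale = self.config.class_effect_scale.get(rec.component_class.value, 0.5)
            self.potency[rec.id] = float(rng.normal(0.0, 1.0)) * scale
        ion = [r.id for r in catalogue.by_class(ComponentClass.IONIZABLE)]
        self.synergy: dict[tuple[str, str], float] = {
            (a, b): float(rng.normal(0.0, 1.0)) * self.config.synergy_scale
            for a in ion
            for b in ion
            if a != b
        }

    def __call__(self, f: Formulation) -> float:
        oc = self.config
        value = 0.0
        class_pct: dict[str, float] = {}
        ion_ids: list[str] = []
        for mol_id, pct in f.components:
            rec = self.catalogue[mol_id]
            cls = rec.component_class.value
            value += self.potency[mol_id] * (pct / 100.0 + 0.5)
            class_pct[cls] = class_pct.get(cls, 0.0) + pct
            if rec.component_class is ComponentClass.IONIZABLE:
                ion_ids.append(mol_id)
        for cls, pct in class_pct.items():
            if cls in oc.molar_optimum:
                d = (pct - oc.molar_optimum[cls]) / oc.molar_width[cls]
                value -= d * d
        if len(ion_ids) == 2:
            value += self.synergy.get((ion_ids[0], ion_ids[1]), 0.0)
        np_ratio = f.np_ratio
        if np_ratio is None:
            from .formulation import weight_ratio_to_np

            np_ratio = weight_ratio_to_np(f, self.catalogue)
        d = (np_ratio - oc.np_optimum) / oc.np_width
        value += oc.np_amplitude * float(np.exp(-d * d))
        coef = oc.phase_helper_coef.get(f.aqueous_organic_ratio, 0.0)
        value += coef * class_pct.get("helper", 0.0) / 100.0
        return value


def oracle_efficacy(f: Formulation, oracle: EfficacyOracle) -> float:
    return oracle(f)


def _reservoir_sample(stream: Iterable[Formulation], n: int, rng) -> list[Formulation]:
    sample: list[Formulation] = []
    for i, f in enumerate(stream):
        if i < n:
            sample.append(f)
        else:
            j = int(rng.integers(0, i + 1))
            if j < n:
                sample[j] = f
    return sample


def generate_dataset(
    grid: DesignGrid,
    catalogue: Catalogue,
    oracles: Mapping[str, EfficacyOracle] | EfficacyOracle,
    n: int,
    plate_size: int = 95,
    seed: int = 0,
    noise_sd: float | None = None,
) -> tuple[list[Formulation], dict[str, dict[str, float]]]:
    """Sample ``n`` labelled formulations from a design grid.

    Returns ``(formulations, hidden)`` where formulations carry one
    label in [0, 1] per task and ``hidden[task][formulation_id]`` holds
    the noiseless oracle value used to create it.
    """
    if isinstance(oracles, EfficacyOracle):
        oracles = {"efficacy": oracles}
    if n > virtual_library_count(grid):
        raise FormulationError("n exceeds the grid size")
    rng = np.random.default_rng(seed)
    sample = _reservoir_sample(enumerate_virtual_library(grid), n, rng)
    sample = [
        Formulation(
            components=f.components,
            np_ratio=f.np_ratio,
            il_rna_weight_ratio=f.il_rna_weight_ratio,
            aqueous_organic_ratio=f.aqueous_organic_ratio,
            id=f"SYN{i:06d}",
        )
        for i, f in enumerate(sample)
    ]
    hidden: dict[str, dict[str, float]] = {}
    labels_by_task: dict[str, dict[str, float]] = {}
    n_plates = int(np.ceil(n / plate_size))
    plate_ids = [f"plate{i // plate_size:03d}" for i in range(n)]
    for task, oracle in oracles.items():
        sd = oracle.config.noise_sd if noise_sd is None else noise_sd
        latent = np.array([oracle(f) for f in sample])
        hidden[task] = {f.id: float(v) for f, v in zip(sample, latent)}
        span = latent.max() - latent.min()
        if span == 0:
            raise FormulationError("degenerate oracle: constant latent efficacy")
        # scale latent to the configured dynamic range (log10 decades)
        log_raw = oracle.config.label_span_decades * (latent - latent.min()) / span
        gains = {f"plate{p:03d}": float(rng.normal(0.0, 0.5)) for p in range(n_plates)}
        noise = rng.normal(0.0, sd, size=n)
        raw = 10.0 ** (log_raw + noise + np.array([gains[p] for p in plate_ids]))
        standards = {p: 10.0 ** gains[p] for p in gains}  # standard LNP, unit latent
        label_set = LabelSet(
            task_id=task,
            formulation_ids=[f.id for f in sample],
            raw_values=raw.tolist(),
            plate_ids=plate_ids,
            standard_values=standards,
        )
        labels_by_task[task] = normalize_labels(label_set)
    labelled = [
        f.with_labels({t: labels_by_task[t][f.id] for t in labels_by_task})
        for f in sample
    ]
    return labelled, hidden
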