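"""Turning formulations into the token inputs of the scoring network.

Each component contributes one token built from three pieces:

* a frozen 512-d molecular embedding of its structure (pluggable; the
  default is a deterministic circular-substructure fingerprint),
* a 128-d Gaussian radial-basis embedding of its molar percentage
  (shared across components, learnable centres/widths),
* a 128-d component-type embedding derived from its class one-hot,

concatenated (768-d) and projected by a two-layer MLP to a 256-d token.
Formulation-wide features add an N/P token (256-d Gaussian embedding)
and a phase token (one-hot aqueous/organic category embedding), and
each prediction task appends one learned CLS token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .formulation import (
    COMPONENT_CLASSES,
    Catalogue,
    ComponentClass,
    Formulation,
    FormulationError,
)

D_MOL = 512
D_COMP = 128
D_TYPE = 128
D_TOKEN = 256

MolecularEncoder = Callable[[str], np.ndarray]

_ENCODER_REGISTRY: dict[str, MolecularEncoder] = {}


def register_molecular_encoder(name: str, fn: MolecularEncoder) -> None:
    """Register a molecular encoder plug-in under ``name``.

    An encoder maps a SMILES string to a fixed 512-d vector and must be
    deterministic; encoders are frozen by contract (no gradients flow
    into them).
    """
    _ENCODER_REGISTRY[name] = fn


def get_molecular_encoder(name: str) -> MolecularEncoder:
    try:
        return _ENCODER_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown molecular encoder {name!r}; registered: {sorted(_ENCODER_REGISTRY)}"
        ) from None


def default_molecular_encoder(smiles: str) -> np.ndarray:
    """Deterministic, parameter-free 512-d molecular embedding.

    A count-based Morgan (circular-substructure) fingerprint of radius
    2 folded to 512 buckets, square-root-damped and cast to floats.
    Counts rather than bits are essential for lipids: homologous
    structures (e.g. C14- versus C18-tailed PEG lipids) share every
    substructure *identity* and differ only in substructure *counts*.
    Frozen by construction, so it also serves as the reference
    implementation of the frozen-encoder contract.  Raises on
    unparseable SMILES.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormulationError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=D_MOL)
    fp = gen.GetCountFingerprint(mol)
    arr = np.zeros(D_MOL, dtype=np.float32)
    for bit, count in fp.GetNonzeroElements().items():
        arr[bit] = count
    return np.sqrt(arr)


register_molecular_encoder("morgan512", default_molecular_encoder)


@dataclass
class GaussianScalarEncoder:
    """Gaussian radial-basis embedding of a scalar feature.

    ``dim`` basis functions with centres ``mu`` spread evenly over the
    feature range and widths ``sigma`` initialized to the grid spacing;
    both are learnable in the network.  ``encode`` evaluates
    e_j = exp(-(v - mu_j)^2 / (2 sigma_j^2)), all entries in (0, 1].
    """

    dim: int
    lo: float
    hi: float
    mu: np.ndarray = field(init=False)
    sigma: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mu = np.linspace(self.lo, self.hi, self.dim).astype(np.float32)
        spacing = (self.hi - self.lo) / max(self.dim - 1, 1)
        self.sigma = np.full(self.dim, max(spacing, 1e-3), dtype=np.float32)

    def encode(self, v: float | np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=np.float32)
        if not np.all(np.isfinite(v)):
            raise FormulationError("scalar encoder input must be finite")
        x = v[..., None] - self.mu
        return np.exp(-(x**2) / (2.0 * self.sigma**2))


def molar_percent_encoder(dim: int = D_COMP) -> GaussianScalarEncoder:
    return GaussianScalarEncoder(dim=dim, lo=0.0, hi=100.0)


def np_ratio_encoder(dim: int = D_TOKEN, max_np: float = 30.0) -> GaussianScalarEncoder:
    """N/P encoder: centres span [0, 2 x max observed N/P]."""
    return GaussianScalarEncoder(dim=dim, lo=0.0, hi=2.0 * max_np)


def class_one_hot(cls: ComponentClass) -> np.ndarray:
    vec = np.zeros(len(COMPONENT_CLASSES), dtype=np.float32)
    vec[COMPONENT_CLASSES.index(cls)] = 1.0
    return vec


@dataclass
class FormulationTokens:
    """Numeric per-formulation inputs for the network.

    Arrays are per component: ``mol_embed`` (L, 512), ``molar_percent``
    (L,), ``class_index`` (L,).  ``np_value`` and ``phase_index`` are
    formulation-wide; ``tasks`` names the CLS tokens to append.  The
    token sequence length is ``n_components + 2 + len(tasks)``.
    """

    mol_embed: np.ndarray
    molar_percent: np.ndarray
    class_index: np.ndarray
    np_value: float
    phase_index: int
    tasks: tuple[str, ...]

    @property
    def n_components(self) -> int:
        return len(self.molar_percent)

    @property
    def n_tokens(self) -> int:
        return self.n_components + 2 + len(self.tasks)


class FormulationTokenizer:
    """Maps :class:`Formulation` objects to :class:`FormulationTokens`.

    Holds the catalogue, the (frozen) molecular encoder with a
    per-molecule cache, the closed phase-category vocabulary and the
    component-class vocabulary.  Pure: repeated calls on the same
    formulation produce bit-identical arrays.
    """

    def __init__(
        self,
        catalogue: Catalogue,
        phase_vocab: Sequence[str] = ("3:1", "1:1"),
        encoder_name: str = "morgan512",
        class_vocab: Sequence[ComponentClass] = COMPONENT_CLASSES,
    ):
        self.catalogue = catalogue
        self.phase_vocab = list(phase_vocab)
        self.class_vocab = list(class_vocab)
        self.encoder_name = encoder_name
        self._encode = get_molecular_encoder(encoder_name)
        self._cache: dict[str, np.ndarray] = {}

    def molecular_embedding(self, mol_id: str) -> np.ndarray:
        if mol_id not in self._cache:
            self._cache[mol_id] = np.asarray(
                self._encode(self.catalogue[mol_id].smiles), dtype=np.float32
            )
            if self._cache[mol_id].shape != (D_MOL,):
                raise FormulationError(
                    f"molecular encoder must return a {D_MOL}-d vector"
                )
        return self._cache[mol_id]

    def tokenize(
        self,
        f: Formulation,
        tasks: Sequence[str],
        catalogue: Catalogue | None = None,
    ) -> FormulationTokens:
        cat = catalogue or self.catalogue
        if f.np_ratio is not None:
            np_value = float(f.np_ratio)
        elif f.il_rna_weight_ratio is not None:
            from .formulation import weight_ratio_to_np

            np_value = weight_ratio_to_np(f, cat)
        else:
            raise FormulationError("formulation has neither N/P nor weight ratio")
        if f.aqueous_organic_ratio not in self.phase_vocab:
            raise FormulationError(
                f"unknown phase category {f.aqueous_organic_ratio!r}; "
                f"vocabulary: {self.phase_vocab}"
            )
        class_idx = []
        for mol_id, _ in f.components:
            cls = cat[mol_id].component_class
            if cls not in self.class_vocab:
                raise FormulationError(
                    f"component class {cls.value!r} not in the model's class vocabulary"
                )
            class_idx.append(self.class_vocab.index(cls))
        return FormulationTokens(
            mol_embed=np.stack([self.molecular_embedding(m) for m in f.molecule_ids]),
            molar_percent=np.asarray(f.molar_percents, dtype=np.float32),
            class_index=np.asarray(class_idx, dtype=np.int64),
            np_value=np_value,
            phase_index=self.phase_vocab.index(f.aqueous_organic_ratio),
            tasks=tuple(tasks),
        )

    def collate(
        self, toks: Sequence[FormulationTokens]
    ) -> dict[str, np.ndarray]:
        """Pad a list of tokenized formulations into batch arrays.

        Returns mol (B, L, 512), molar (B, L), class one-hots
        (B, L, C), component mask (B, L), np values (B,), phase
        one-hots (B, P).
        """
        if not toks:
            raise FormulationError("empty batch")
        B = len(toks)
        L = max(t.n_components for t in toks)
        C = len(self.class_vocab)
        P = len(self.phase_vocab)
        mol = np.zeros((B, L, D_MOL), dtype=np.float32)
        molar = np.zeros((B, L), dtype=np.float32)
        cls_oh = np.zeros((B, L, C), dtype=np.float32)
        mask = np.zeros((B, L), dtype=np.float32)
        np_val = np.zeros(B, dtype=np.float32)
        phase_oh = np.zeros((B, P), dtype=np.float32)
        for i, t in enumerate(toks):
            n = t.n_components
            mol[i, :n] = t.mol_embed
            molar[i, :n] = t.molar_percent
            cls_oh[i, np.arange(n), t.class_index] = 1.0
            mask[i, :n] = 1.0
            np_val[i] = t.np_value
            phase_oh[i, t.phase_index] = 1.0
        return {
            "mol": mol,
            "molar": molar,
            "class_onehot": cls_oh,
            "mask": mask,
            "np": np_val,
            "phase_onehot": phase_oh,
        }
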