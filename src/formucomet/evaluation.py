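"""Splits, ranking metrics, classical baselines and robustness probes.

The hits-test split emulates prospective discovery: the top decile of
formulations by label is withheld for testing together with a random
tenth of the non-hits, so the model never trains on any top performer.
Leave-chemistry-out excludes every formulation containing named
molecules from training.  Identity corruption shuffles lipid
identities (optionally across classes, optionally also synthesis
parameters) in a fraction of training samples while leaving labels
untouched -- a model that learns real structure-activity relationships
degrades monotonically with the corrupted fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .formulation import Catalogue, ComponentClass, Formulation, FormulationError


@dataclass
class SplitSpec:
    kind: str = "random"  # random | hits_test | leave_chemistry_out
    seed: int = 0
    task: str = "efficacy"
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    hit_quantile: float = 0.9
    excluded_molecules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("random", "hits_test", "leave_chemistry_out"):
            raise FormulationError(f"unknown split kind {self.kind!r}")


@dataclass
class Split:
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray


def make_split(dataset: Sequence[Formulation], spec: SplitSpec) -> Split:
    """Deterministic train/valid/test index split.

    random: 70/10/20 by shuffled permutation.  hits_test: test = top
    ceil(0.1 N) by label plus a random floor(0.1 (N - hits)) non-hits;
    the remainder is split 7:1 into train and valid.
    leave_chemistry_out: formulations containing any excluded molecule
    go to test; the rest split 7:1.
    """
    n = len(dataset)
    if n < 10:
        raise FormulationError("dataset too small to split")
    rng = np.random.default_rng(spec.seed)
    idx = np.arange(n)
    if spec.kind == "random":
        perm = rng.permutation(idx)
        n_train = int(round(spec.fractions[0] * n))
        n_valid = int(round(spec.fractions[1] * n))
        return Split(
            train=np.sort(perm[:n_train]),
            valid=np.sort(perm[n_train : n_train + n_valid]),
            test=np.sort(perm[n_train + n_valid :]),
        )
    if spec.kind == "hits_test":
        labels = np.array([f.labels[spec.task] for f in dataset])
        q = 1.0 - spec.hit_quantile
        n_hits = math.ceil(q * n - 1e-9)
        hit_idx = idx[np.argsort(-labels, kind="stable")[:n_hits]]
        non_hits = np.setdiff1d(idx, hit_idx)
        n_rand = int(np.floor(q * len(non_hits) + 1e-9))
        rand_nh = rng.choice(non_hits, size=n_rand, replace=False)
        test = np.sort(np.concatenate([hit_idx, rand_nh]))
        rest = np.setdiff1d(idx, test)
        perm = rng.permutation(rest)
        n_valid = max(1, len(rest) // 8)
        return Split(
            train=np.sort(perm[n_valid:]), valid=np.sort(perm[:n_valid]), test=test
        )
    # leave_chemistry_out
    excluded = set(spec.excluded_molecules)
    test_mask = np.array(
        [bool(excluded & set(f.molecule_ids)) for f in dataset], dtype=bool
    )
    test = idx[test_mask]
    rest = idx[~test_mask]
    if len(rest) < 2:
        raise FormulationError("exclusion empties the training split")
    perm = rng.permutation(rest)
    n_valid = max(1, len(rest) // 8)
    return Split(train=np.sort(perm[n_valid:]), valid=np.sort(perm[:n_valid]), test=test)


def rank_metrics(pred: Sequence[float], truth: Sequence[float]) -> dict[str, float]:
    """Spearman and Pearson correlations (ties mid-ranked)."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if len(pred) < 3:
        raise FormulationError("need >= 3 points for rank metrics")
    if np.std(pred) == 0 or np.std(truth) == 0:
        return {"spearman": float("nan"), "pearson": float("nan")}
    return {
        "spearman": float(stats.spearmanr(pred, truth).statistic),
        "pearson": float(stats.pearsonr(pred, truth).statistic),
    }


def top_half_hit_accuracy(pred: Sequence[float], hit_mask: Sequence[bool]) -> float:
    """Fraction of true hits ranked in the top ceil(N/2) predictions."""
    pred = np.asarray(pred, float)
    hit_mask = np.asarray(hit_mask, bool)
    if not hit_mask.any():
        raise FormulationError("hit mask selects no formulation")
    n_top = math.ceil(len(pred) / 2)
    top = set(np.argsort(-pred, kind="stable")[:n_top].tolist())
    hits = np.flatnonzero(hit_mask)
    return float(np.mean([i in top for i in hits]))


def formulation_features(
    dataset: Sequence[Formulation],
    catalogue: Catalogue,
    phase_vocab: Sequence[str] = ("3:1", "1:1"),
) -> np.ndarray:
    """Flat feature matrix for classical baselines: per-slot molar %,
    per-slot presence indicator, N/P ratio and phase one-hot."""
    slots = catalogue.slot_order()
    rows = []
    for f in dataset:
        vec = f.slot_vector(slots)
        presence = (vec > 0).astype(float)
        np_ratio = f.np_ratio
        if np_ratio is None:
            from .formulation import weight_ratio_to_np

            np_ratio = weight_ratio_to_np(f, catalogue)
        phase = [1.0 if f.aqueous_organic_ratio == p else 0.0 for p in phase_vocab]
        rows.append(np.concatenate([vec, presence, [np_ratio], phase]))
    return np.stack(rows)


def baseline_models(
    dataset: Sequence[Formulation],
    split: Split,
    task: str,
    catalogue: Catalogue,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """k-NN (k = 5) and random forest (100 trees) regression baselines
    on the flattened formulation features, scored with the same rank
    metrics as the transformer.  Degenerate predictions yield NaN."""
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.neighbors import KNeighborsRegressor

    X = formulation_features(dataset, catalogue)
    y = np.array([f.labels[task] for f in dataset])
    tr = np.concatenate([split.train, split.valid])  # baselines need no valid set
    results = {}
    for name, est in (
        ("knn", KNeighborsRegressor(n_neighbors=5)),
        ("random_forest", RandomForestRegressor(n_estimators=100, random_state=seed)),
    ):
        est.fit(X[tr], y[tr])
        pred = est.predict(X[split.test])
        results[name] = rank_metrics(pred, y[split.test])
    return results


def corrupt_identities(
    dataset: Sequence[Formulation],
    catalogue: Catalogue,
    fraction: float,
    mode: str = "within-class",
    seed: int = 0,
) -> list[Formulation]:
    """Shuffle lipid identities in a fraction of samples, labels kept.

    within-class: each component is replaced by a random molecule of
    the same class.  cross-class: the formulation's molecules are
    replaced by random molecules of random classes (ionizable slot
    stays ionizable-free draw).  plus-parameters: cross-class plus
    shuffled N/P, molar % and phase ratios.
    """
    if not 0 <= fraction <= 1:
        raise FormulationError("fraction must be in [0, 1]")
    if mode not in ("within-class", "cross-class", "plus-parameters"):
        raise FormulationError(f"unknown corruption mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    corrupt = set(rng.choice(n, size=int(round(fraction * n)), replace=False).tolist())
    lipid_classes = [c for c in ComponentClass if catalogue.by_class(c)]
    out = []
    for i, f in enumerate(dataset):
        if i not in corrupt:
            out.append(f)
            continue
        new_comps = []
        for mol_id, pct in f.components:
            if mode == "within-class":
                cls = catalogue[mol_id].component_class
            else:
                cls = lipid_classes[int(rng.integers(0, len(lipid_classes)))]
            pool = [r.id for r in catalogue.by_class(cls)]
            choices = [m for m in pool if m != mol_id] or pool
            new_comps.append((choices[int(rng.integers(0, len(choices)))], pct))
        g = replace(f, components=tuple(new_comps))
        if mode == "plus-parameters":
            pcts = np.array([p for _, p in g.components])
            rng.shuffle(pcts)
            g = replace(
                g,
                components=tuple((m, float(p)) for (m, _), p in zip(g.components, pcts)),
                np_ratio=None if g.np_ratio is None else float(g.np_ratio * 10 ** rng.normal(0, 0.3)),
                aqueous_organic_ratio="1:1" if g.aqueous_organic_ratio == "3:1" else "3:1",
            )
        out.append(g)
    return out
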