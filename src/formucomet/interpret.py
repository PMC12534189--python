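"""Integrated-gradients attribution and representation export.

Attribution is computed in embedding space: the leaves are the frozen
molecular embeddings, the molar percentages and N/P ratio entering the
Gaussian encoders, and the phase one-hot.  Gradients are integrated
along the straight path from a reference baseline (feature means over
a reference dataset, matched per component class) to the input with a
midpoint Riemann rule, multiplied by (input - baseline), and summed
into named feature groups: molecule choice per class, molar % per
class, N/P ratio and phase.  The completeness axiom -- attributions
sum to f(input) - f(baseline) -- is checked to hold within 1%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .autodiff import Tensor
from .formulation import ComponentClass, Formulation, FormulationError
from .model import CometModel


@dataclass
class Baseline:
    """Reference embedding-space means, per component class.

    Scalar features are averaged after Gaussian encoding, so the
    attribution path stays in the (smooth) embedded space the network
    actually consumes.
    """

    mol_by_class: dict[str, np.ndarray]  # class -> mean 512-d embedding
    molar_embed_by_class: dict[str, np.ndarray]  # class -> mean encoded molar %
    np_embed: np.ndarray  # mean encoded N/P
    phase_onehot: np.ndarray


def reference_baseline(
    model: CometModel, reference: Sequence[Formulation]
) -> Baseline:
    """Embedding means over a reference dataset (conventional lipid-only
    formulations), grouped by component class."""
    tok = model.tokenizer
    mol_sums: dict[str, list[np.ndarray]] = {}
    molar_sums: dict[str, list[np.ndarray]] = {}
    np_vals, phases = [], []
    for f in reference:
        t = tok.tokenize(f, model.config.tasks)
        molar_emb = model.molar_embedding(t.molar_percent)
        for k, mol_id in enumerate(f.molecule_ids):
            cls = tok.catalogue[mol_id].component_class.value
            mol_sums.setdefault(cls, []).append(t.mol_embed[k])
            molar_sums.setdefault(cls, []).append(molar_emb[k])
        np_vals.append(model.np_embedding(t.np_value))
        ph = np.zeros(len(tok.phase_vocab))
        ph[t.phase_index] = 1.0
        phases.append(ph)
    return Baseline(
        mol_by_class={c: np.mean(v, axis=0) for c, v in mol_sums.items()},
        molar_embed_by_class={c: np.mean(v, axis=0) for c, v in molar_sums.items()},
        np_embed=np.mean(np_vals, axis=0),
        phase_onehot=np.mean(phases, axis=0),
    )


@dataclass
class AttributionReport:
    """Per-feature-group attributions for one formulation and task."""

    groups: dict[str, float]
    prediction: float
    baseline_prediction: float
    completeness_residual: float  # |sum(attr) - (f(x) - f(b))| / |f(x) - f(b)|

    def normalized(self) -> dict[str, float]:
        """Scaled so the largest |attribution| is exactly 1."""
        peak = max((abs(v) for v in self.groups.values()), default=0.0)
        if peak == 0:
            return dict(self.groups)
        return {k: v / peak for k, v in self.groups.items()}


def integrated_gradients(
    model: CometModel,
    f: Formulation,
    task: str,
    baseline: Baseline,
    n_steps: int = 512,
) -> AttributionReport:
    """Path-integral attribution of one formulation's score."""
    if n_steps < 16:
        raise FormulationError("n_steps must be >= 16")
    tok = model.tokenizer
    t = tok.tokenize(f, model.config.tasks)
    batch = tok.collate([t])
    L = t.n_components
    classes = [tok.catalogue[m].component_class.value for m in f.molecule_ids]
    d_comp = model.config.d_comp
    b_mol = np.stack(
        [baseline.mol_by_class.get(c, np.zeros(batch["mol"].shape[-1])) for c in classes]
    )[None]
    b_molar = np.stack(
        [baseline.molar_embed_by_class.get(c, np.zeros(d_comp)) for c in classes]
    )[None].astype(np.float32)
    b_np = baseline.np_embed.reshape(1, -1).astype(np.float32)
    b_phase = baseline.phase_onehot[None].astype(np.float32)

    x = {
        "mol": batch["mol"],
        "molar_embed": model.molar_embedding(batch["molar"]),
        "np_embed": model.np_embedding(batch["np"]),
        "phase_onehot": batch["phase_onehot"],
    }
    b = {"mol": b_mol, "molar_embed": b_molar, "np_embed": b_np, "phase_onehot": b_phase}
    grads = {k: np.zeros_like(np.asarray(v, np.float32)) for k, v in x.items()}
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    for a in alphas:
        leaves = {
            k: Tensor(b[k] + a * (np.asarray(x[k], np.float32) - b[k]), requires_grad=True)
            for k in x
        }
        step_batch = dict(batch)
        step_batch.update(leaves)
        score = model.forward_collated(step_batch, [task])[task]
        model.zero_grad()
        score.backward(np.ones(1, np.float32))
        for k in grads:
            if leaves[k].grad is not None:
                grads[k] += leaves[k].grad
    attr = {
        k: (np.asarray(x[k], np.float64) - b[k]) * grads[k] / n_steps for k in grads
    }

    groups: dict[str, float] = {}
    for k in range(L):
        cls = classes[k]
        groups[f"molecule_choice:{cls}"] = groups.get(f"molecule_choice:{cls}", 0.0) + float(
            attr["mol"][0, k].sum()
        )
        groups[f"molar_percent:{cls}"] = groups.get(f"molar_percent:{cls}", 0.0) + float(
            attr["molar_embed"][0, k].sum()
        )
    groups["np_ratio"] = float(attr["np_embed"].sum())
    groups["phase"] = float(attr["phase_onehot"].sum())

    pred = float(model.forward_collated(batch, [task])[task].data[0])
    base_batch = dict(batch)
    base_batch.update({k: Tensor(v) for k, v in b.items()})
    base_pred = float(model.forward_collated(base_batch, [task])[task].data[0])
    total = sum(groups.values())
    denom = abs(pred - base_pred)
    residual = abs(total - (pred - base_pred)) / denom if denom > 1e-9 else 0.0
    return AttributionReport(
        groups=groups,
        prediction=pred,
        baseline_prediction=base_pred,
        completeness_residual=residual,
    )


def ensemble_attribution(
    models: Sequence[CometModel],
    f: Formulation,
    task: str,
    baselines: Sequence[Baseline],
    n_steps: int = 512,
) -> dict[str, float]:
    """Per-model attributions normalized to max = 1, then averaged."""
    acc: dict[str, float] = {}
    for model, base in zip(models, baselines):
        rep = integrated_gradients(model, f, task, base, n_steps)
        for k, v in rep.normalized().items():
            acc[k] = acc.get(k, 0.0) + v / len(models)
    return acc


def feature_importance_summary(
    reports: Sequence[AttributionReport],
) -> list[tuple[str, float]]:
    """Mean absolute attribution per feature group, ranked descending.

    All-zero attributions yield uniform ranks with a warning.
    """
    if not reports:
        raise FormulationError("need at least one attribution report")
    acc: dict[str, list[float]] = {}
    for rep in reports:
        for k, v in rep.groups.items():
            acc.setdefault(k, []).append(abs(v))
    table = sorted(
        ((k, float(np.mean(v))) for k, v in acc.items()), key=lambda kv: -kv[1]
    )
    if all(v == 0 for _, v in table):
        warnings.warn("all attributions are zero; ranks are uninformative")
    return table


def export_representations(
    models: Sequence[CometModel],
    formulations: Sequence[Formulation],
    task: str,
    ensemble_scores: Sequence[float],
    per_class: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], int]:
    """CLS representations for embedding visualization (t-SNE etc.).

    Selects the single ensemble member whose scores correlate best
    (Spearman) with the ensemble scores on the probe set and emits its
    CLS vectors.  With ``per_class`` set, a class-balanced subsample by
    ionizable-lipid identity is drawn (dual-ionizable formulations form
    their own class).  Returns (matrix, class labels, model index).
    """
    if not formulations:
        raise FormulationError("empty probe set")
    ens = np.asarray(ensemble_scores, float)
    best_i, best_rho = 0, -np.inf
    for i, m in enumerate(models):
        pred = m.forward_batch(formulations, task)
        rho = stats.spearmanr(pred, ens).statistic if len(set(pred)) > 1 else -np.inf
        if np.isfinite(rho) and rho > best_rho:
            best_i, best_rho = i, rho
    model = models[best_i]
    tok = model.tokenizer

    def class_of(f: Formulation) -> str:
        ions = [
            m
            for m in f.molecule_ids
            if tok.catalogue[m].component_class is ComponentClass.IONIZABLE
        ]
        return "dual-ionizable" if len(ions) > 1 else (ions[0] if ions else "none")

    labels = [class_of(f) for f in formulations]
    keep = np.arange(len(formulations))
    if per_class is not None:
        rng = np.random.default_rng(seed)
        chosen = []
        for cls in sorted(set(labels)):
            members = [i for i, c in enumerate(labels) if c == cls]
            k = min(per_class, len(members))
            chosen.extend(rng.choice(members, size=k, replace=False).tolist())
        keep = np.sort(np.array(chosen))
    subset = [formulations[i] for i in keep]
    reps = model.extract_cls_representation(subset, task)
    return np.asarray(reps), [labels[i] for i in keep], best_i
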