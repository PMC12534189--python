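"""Pairwise ranking training with label margin, noise augmentation and
conflict-averse multitask gradient combination.

The ranking objective on a pair (higher-labelled x_h, lower-labelled
x_l) is

    L = -log sigmoid( f(x_h) - f(x_l) - lambda_margin * (y_h - y_l) )

so the model is pushed to score the empirically better formulation
higher, by an amount that grows with the label gap.  A batch of 64
labelled formulations contributes all C(64, 2) = 2,016 ordered pairs
(exact label ties are dropped).  Molar percentages are perturbed with
zero-mean Gaussian noise whose standard deviation is 10% of the value,
mimicking fluid-handling variability.  In multitask runs the per-task
gradients are combined with CAGrad (coefficient 0.2 by default).
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .autodiff import Tensor
from .formulation import Formulation
from .model import CometConfig, CometModel


@dataclass(frozen=True)
class RankPair:
    """An ordered formulation pair: x_h has the strictly higher label."""

    x_h: Formulation
    x_l: Formulation
    y_h: float
    y_l: float

    def __post_init__(self) -> None:
        if not self.y_h > self.y_l:
            raise ValueError("RankPair requires y_h > y_l")


@dataclass
class TrainConfig:
    batch_size: int = 64
    lambda_margin: float = 0.01
    noise_sd_fraction: float = 0.10
    cagrad_c: float = 0.2
    learning_rate: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    max_epochs: int = 60
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 2 or self.learning_rate <= 0 or self.max_epochs < 1:
            raise ValueError("invalid training configuration")


def make_pairs(batch: Sequence[Formulation], task: str) -> list[RankPair]:
    """All unordered pairs of a labelled batch, ordered by label.

    Exact label ties are excluded; 64 distinct labels yield 2,016 pairs.
    """
    if len(batch) < 2:
        raise ValueError("need at least 2 formulations to form pairs")
    pairs = []
    for i in range(len(batch)):
        for j in range(i + 1, len(batch)):
            yi, yj = batch[i].labels[task], batch[j].labels[task]
            if yi == yj:
                continue
            if yi > yj:
                pairs.append(RankPair(batch[i], batch[j], yi, yj))
            else:
                pairs.append(RankPair(batch[j], batch[i], yj, yi))
    return pairs


def _pair_indices(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (h, l) of all non-tied pairs, label-ordered."""
    i, j = np.triu_indices(len(labels), k=1)
    yi, yj = labels[i], labels[j]
    keep = yi != yj
    i, j, yi, yj = i[keep], j[keep], yi[keep], yj[keep]
    swap = yj > yi
    h = np.where(swap, j, i)
    l = np.where(swap, i, j)
    return h, l


def ranking_loss(
    s_h, s_l, y_h, y_l, lambda_margin: float = 0.01
):
    """Margin ranking loss; accepts numpy arrays or AD tensors.

    With ``lambda_margin = 0`` this is the plain pairwise logistic
    ranking loss; at zero score gap it equals ln 2.
    """
    if isinstance(s_h, Tensor) or isinstance(s_l, Tensor):
        margin = Tensor(np.asarray(y_h, np.float32) - np.asarray(y_l, np.float32))
        gap = s_h - s_l - margin * lambda_margin
        return -(gap.log_sigmoid()).mean()
    gap = np.asarray(s_h, float) - np.asarray(s_l, float) - lambda_margin * (
        np.asarray(y_h, float) - np.asarray(y_l, float)
    )
    # stable -log sigmoid
    loss = np.where(gap >= 0, np.log1p(np.exp(-gap)), -gap + np.log1p(np.exp(gap)))
    return float(np.mean(loss))


def regression_loss(s, y):
    """Squared error, used only by the regression-objective ablation."""
    if isinstance(s, Tensor):
        d = s - Tensor(np.asarray(y, np.float32))
        return (d * d).mean()
    return float(np.mean((np.asarray(s, float) - np.asarray(y, float)) ** 2))


def augment_molar_noise(
    f: Formulation, rng: np.random.Generator, sd_fraction: float = 0.10
) -> Formulation:
    """Perturb each molar % m by N(0, (sd_fraction * m)^2), clipped at 0.

    The composition is deliberately not renormalized (pipetting noise
    does not conserve the total) and labels are untouched.
    """
    if sd_fraction == 0:
        return f
    comps = tuple(
        (m, max(0.0, p + rng.normal(0.0, sd_fraction * p))) for m, p in f.components
    )
    return replace(f, components=comps)


def cagrad_combine(task_grads: Sequence[np.ndarray], c: float = 0.2) -> np.ndarray:
    """Conflict-averse combination of per-task gradients.

    Solves  max_d min_i <g_i, d>  subject to  ||d - g_0|| <= c ||g_0||,
    where g_0 is the average gradient.  Via its dual this reduces to
    minimizing  F(w) = <g_w, g_0> + sqrt(phi) ||g_w||  over the simplex
    (g_w = sum_i w_i g_i, phi = c^2 ||g_0||^2), and the update is
    d = (g_0 + sqrt(phi) / ||g_w*|| * g_w*) / (1 + c).  The 1/(1+c)
    factor is a step-size convention only (the direction is what the
    optimizer consumes): it makes identical task gradients pass
    through unchanged.  A single task returns its gradient; c = 0
    returns the average gradient.
    """
    grads = [np.asarray(g, dtype=np.float64) for g in task_grads]
    if not grads:
        raise ValueError("need at least one task gradient")
    dims = {g.shape for g in grads}
    if len(dims) != 1:
        raise ValueError("task gradients must share a dimension")
    if len(grads) == 1:
        return grads[0]
    G = np.stack(grads)  # (T, D)
    g0 = G.mean(axis=0)
    if c == 0:
        return g0
    GG = G @ G.T
    g0_norm = float(np.linalg.norm(g0))
    if g0_norm == 0:
        return g0
    phi = (c * g0_norm) ** 2
    T = len(grads)
    b = GG.mean(axis=1)  # <g_i, g0>

    def objective(w):
        gw_sq = float(w @ GG @ w)
        return float(w @ b) + math.sqrt(phi * max(gw_sq, 1e-18))

    cons = ({"type": "eq", "fun": lambda w: w.sum() - 1.0},)
    bounds = [(0.0, 1.0)] * T
    best = None
    for start in range(T + 1):
        w0 = np.full(T, 1.0 / T) if start == T else np.eye(T)[start]
        res = optimize.minimize(
            objective, w0, bounds=bounds, constraints=cons, method="SLSQP"
        )
        if best is None or res.fun < best.fun:
            best = res
    w = np.clip(best.x, 0, 1)
    w = w / w.sum()
    gw = w @ G
    gw_norm = float(np.linalg.norm(gw))
    if gw_norm < 1e-12:
        return g0
    return (g0 + math.sqrt(phi) / gw_norm * gw) / (1.0 + c)


class _Adam:
    def __init__(self, params: dict[str, Tensor], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = {k: np.zeros_like(p.data, dtype=np.float32) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data, dtype=np.float32) for k, p in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        b1, b2 = self.cfg.adam_betas
        self.t += 1
        lr = self.cfg.learning_rate * math.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            self.params[k].data -= lr * self.m[k] / (np.sqrt(self.v[k]) + self.cfg.adam_eps)


def _flatten(grads: dict[str, np.ndarray], order: list[str]) -> np.ndarray:
    return np.concatenate([grads[k].ravel() for k in order])


def _unflatten(vec: np.ndarray, params: dict[str, Tensor], order: list[str]) -> dict[str, np.ndarray]:
    out, ofs = {}, 0
    for k in order:
        n = params[k].data.size
        out[k] = vec[ofs : ofs + n].reshape(params[k].data.shape).astype(np.float32)
        ofs += n
    return out


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_spearman: float = float("-inf")

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(e) for e in self.epochs)


def train(
    dataset: Sequence[Formulation],
    tasks: Sequence[str],
    config: TrainConfig | None = None,
    model_config: CometConfig | None = None,
    tokenizer=None,
    val_fraction: float = 0.2,
    val_indices: Sequence[int] | None = None,
    objective: str = "ranking",
    log=None,
) -> tuple[CometModel, TrainHistory]:
    """Train a scoring model on labelled formulations.

    Each step samples one batch per task, applies molar noise, computes
    the all-pairs ranking loss (or squared error for the regression
    ablation), backpropagates per task, combines task gradients with
    CAGrad and takes an Adam step.  Early stopping monitors validation
    Spearman (mean over tasks) with the configured patience; the best
    parameters are restored.  Fully deterministic under a fixed seed.
    """
    config = config or TrainConfig()
    tasks = list(tasks)
    rng = np.random.default_rng(config.seed)
    if tokenizer is None:
        raise ValueError("a FormulationTokenizer is required")
    if model_config is None:
        model_config = CometConfig(tasks=tasks, seed=config.seed)
    model = CometModel(model_config, tokenizer)

    idx_all = np.arange(len(dataset))
    if val_indices is not None:
        val_idx = np.asarray(sorted(val_indices))
        train_idx = np.setdiff1d(idx_all, val_idx)
    else:
        perm = rng.permutation(idx_all)
        n_val = max(1, int(round(val_fraction * len(dataset))))
        val_idx, train_idx = np.sort(perm[:n_val]), np.sort(perm[n_val:])
    per_task_train = {
        t: [i for i in train_idx if t in dataset[i].labels] for t in tasks
    }
    per_task_val = {t: [i for i in val_idx if t in dataset[i].labels] for t in tasks}
    for t in tasks:
        labels = {dataset[i].labels[t] for i in per_task_train[t]}
        if len(labels) < 2:
            raise ValueError(f"task {t!r} needs >= 2 distinct labels in the train split")

    # Pre-tokenize once; noise augmentation re-tokenizes only molar %.
    opt = _Adam(model.params, config)
    order = list(model.params)
    history = TrainHistory()
    best_params: dict[str, np.ndarray] | None = None
    steps_per_epoch = max(
        1,
        min(
            math.ceil(len(per_task_train[t]) / config.batch_size)
            for t in tasks
        ),
    )

    def batch_loss(indices: list[int], task: str) -> tuple[Tensor, float]:
        fs = [dataset[i] for i in indices]
        if model.training and config.noise_sd_fraction > 0:
            fs = [augment_molar_noise(f, rng, config.noise_sd_fraction) for f in fs]
        toks = [tokenizer.tokenize(f, tasks) for f in fs]
        batch = tokenizer.collate(toks)
        scores = model.forward_collated(batch, [task])[task]
        y = np.array([dataset[i].labels[task] for i in indices], dtype=np.float64)
        if objective == "regression":
            loss = regression_loss(scores, y)
        else:
            h, l = _pair_indices(y)
            if len(h) == 0:
                return None, 0.0
            s_h = scores.gather(h)
            s_l = scores.gather(l)
            loss = ranking_loss(s_h, s_l, y[h], y[l], config.lambda_margin)
        return loss, float(loss.data)

    start = time.time()
    since_best = 0
    for epoch in range(config.max_epochs):
        model.training = True
        task_losses = {t: [] for t in tasks}
        task_batches = {}
        for t in tasks:
            ids = np.array(per_task_train[t])
            rng.shuffle(ids)
            task_batches[t] = [
                ids[k * config.batch_size : (k + 1) * config.batch_size].tolist()
                for k in range(steps_per_epoch)
            ]
        for step in range(steps_per_epoch):
            grads_per_task = []
            losses = {}
            for t in tasks:
                indices = task_batches[t][step % len(task_batches[t])]
                if len(indices) < 2:
                    continue
                model.zero_grad()
                loss, loss_val = batch_loss(indices, t)
                if loss is None:
                    continue
                if not np.isfinite(loss_val):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, task {t}: {loss_val}"
                    )
                loss.backward()
                grads_per_task.append(
                    _flatten(
                        {
                            k: (p.grad if p.grad is not None else np.zeros_like(p.data))
                            for k, p in model.params.items()
                        },
                        order,
                    )
                )
                losses[t] = loss_val
                task_losses[t].append(loss_val)
            if not grads_per_task:
                continue
            if len(grads_per_task) == 1:
                combined = grads_per_task[0]
            else:
                combined = cagrad_combine(grads_per_task, config.cagrad_c)
            opt.step(_unflatten(combined, model.params, order))
        model.training = False
        val_sp = []
        for t in tasks:
            ids = per_task_val[t]
            if len(ids) < 3:
                continue
            preds = _predict(model, dataset, ids, tasks, tokenizer, t)
            truth = [dataset[i].labels[t] for i in ids]
            rho = stats.spearmanr(preds, truth).statistic
            if np.isfinite(rho):
                val_sp.append(float(rho))
        mean_val = float(np.mean(val_sp)) if val_sp else float("nan")
        record = {
            "epoch": epoch,
            "losses": {t: float(np.mean(v)) if v else None for t, v in task_losses.items()},
            "val_spearman": mean_val,
            "elapsed_s": round(time.time() - start, 2),
        }
        history.epochs.append(record)
        if log is not None:
            log(json.dumps(record))
        if np.isfinite(mean_val) and mean_val > history.best_val_spearman:
            history.best_val_spearman = mean_val
            history.best_epoch = epoch
            best_params = {k: p.data.copy() for k, p in model.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_params is not None:
        for k, p in model.params.items():
            p.data = best_params[k]
    return model, history


def _predict(model, dataset, ids, tasks, tokenizer, task, chunk: int = 256):
    preds = []
    for k in range(0, len(ids), chunk):
        fs = [dataset[i] for i in ids[k : k + chunk]]
        preds.extend(model.forward_batch(fs, task).tolist())
    return preds
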