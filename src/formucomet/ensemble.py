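"""Ensembling, uncertainty filtering and the in silico screening funnel.

A deployment ensemble is five models trained on fivefold 80/20
train/validation splits.  Because raw scores of a ranking model have
arbitrary scale, each model's scores are normalized by the mean and
standard deviation of its scores on a fixed reference set (the
training-campaign formulations), which makes ensemble selections
invariant to any per-model affine rescaling.  The ensemble score is
the mean of normalized scores; uncertainty is the across-model
standard deviation divided by the ensemble score shifted to be
non-negative (subtracting the reference-set minimum ensemble score);
candidates whose shifted score is negative are dropped outright.

The screening funnel chains: enumerate -> exclude near-hits ->
top-fraction by ensemble score -> drop the most uncertain half ->
K-means diversity selection.  All stages are deterministic under a
fixed seed and grid; standard deviations are population (divide by N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .formulation import Catalogue, Formulation, FormulationError
from .grids import DesignGrid, exclude_near_hits
from .model import CometConfig, CometModel
from .training import TrainConfig, train


@dataclass
class EnsembleScore:
    """Scores for one candidate across an ensemble."""

    raw: np.ndarray  # per-model raw scores
    normalized: np.ndarray  # per-model reference-normalized scores
    ensemble: float  # mean of normalized scores
    shifted: float  # ensemble minus reference-set minimum ensemble score
    sigma: float  # population std across models
    u_rel: float | None  # sigma / shifted, None when dropped
    dropped: bool


@dataclass
class FunnelReport:
    """Counts and selections at each stage of the screening funnel."""

    enumerated: int = 0
    after_exclusion: int = 0
    top_fraction: int = 0
    after_uncertainty_drop: int = 0
    after_uncertainty_half: int = 0
    selected: int = 0
    hits: list[tuple[Formulation, float]] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "enumerated": self.enumerated,
            "after_exclusion": self.after_exclusion,
            "top_fraction": self.top_fraction,
            "after_uncertainty_drop": self.after_uncertainty_drop,
            "after_uncertainty_half": self.after_uncertainty_half,
            "selected": self.selected,
        }


def fivefold_ensemble(
    dataset: Sequence[Formulation],
    tasks: Sequence[str],
    config: TrainConfig | None = None,
    model_config: CometConfig | None = None,
    tokenizer=None,
    n_models: int = 5,
    log=None,
) -> list[CometModel]:
    """Train an ensemble on disjoint validation folds.

    The dataset is split into ``n_models`` folds; model i validates on
    fold i and trains on the rest (80/20 at the default five models).
    Models use distinct seeds derived from the training seed.
    """
    config = config or TrainConfig()
    if len(dataset) < n_models:
        raise FormulationError("dataset smaller than the number of folds")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(dataset))
    folds = np.array_split(perm, n_models)
    models = []
    for i, fold in enumerate(folds):
        seed_i = (config.seed * 1000 + i) % (2**31 - 1)
        cfg_i = TrainConfig(**{**config.__dict__, "seed": seed_i})
        mcfg = model_config or CometConfig(tasks=list(tasks))
        mcfg_i = CometConfig(**{**mcfg.__dict__, "seed": seed_i})
        model, _ = train(
            dataset,
            tasks,
            cfg_i,
            mcfg_i,
            tokenizer=tokenizer,
            val_indices=fold.tolist(),
            log=log,
        )
        models.append(model)
    return models


def reference_statistics(
    models: Sequence[CometModel],
    reference: Sequence[Formulation],
    task: str,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-model (mean, population std) of reference-set scores, plus
    the reference minimum ensemble score used for shifting."""
    ref_scores = np.stack([m.forward_batch(reference, task) for m in models])
    means = ref_scores.mean(axis=1)
    stds = ref_scores.std(axis=1)  # population (N) for determinism
    if np.any(stds == 0):
        raise FormulationError("reference set has zero score variance for a model")
    ref_norm = (ref_scores - means[:, None]) / stds[:, None]
    ref_ensemble_min = float(ref_norm.mean(axis=0).min())
    return means, stds, ref_ensemble_min


def normalize_scores(
    raw: np.ndarray, ref_means: np.ndarray, ref_stds: np.ndarray
) -> np.ndarray:
    """(y' - mean_i) / std_i per model; raw is (n_models, n_candidates)."""
    return (raw - ref_means[:, None]) / ref_stds[:, None]


def ensemble_score(normalized: np.ndarray) -> np.ndarray:
    """Arithmetic mean of normalized scores across models (axis 0)."""
    return np.asarray(normalized).mean(axis=0)


def relative_uncertainty(
    normalized: np.ndarray, ref_ensemble_min: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-candidate (u_rel, dropped, shifted).

    shifted = mean(normalized) - reference minimum ensemble score;
    u_rel = population std across models / shifted.  Candidates with
    shifted <= 0 are flagged dropped and get u_rel = inf.
    """
    normalized = np.asarray(normalized)
    if normalized.shape[0] < 2:
        raise FormulationError("relative uncertainty needs >= 2 models")
    shifted = normalized.mean(axis=0) - ref_ensemble_min
    sigma = normalized.std(axis=0)
    dropped = shifted <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u_rel = np.where(dropped, np.inf, sigma / np.where(dropped, 1.0, shifted))
    return u_rel, dropped, shifted


def score_candidates(
    models: Sequence[CometModel],
    candidates: Sequence[Formulation],
    task: str,
    ref_means: np.ndarray,
    ref_stds: np.ndarray,
    chunk: int = 512,
) -> np.ndarray:
    """Normalized scores (n_models, n_candidates), chunked for memory."""
    cols = []
    for k in range(0, len(candidates), chunk):
        part = candidates[k : k + chunk]
        raw = np.stack([m.forward_batch(part, task) for m in models])
        cols.append(normalize_scores(raw, ref_means, ref_stds))
    return np.concatenate(cols, axis=1)


def top_fraction_count(n: int, fraction: float) -> int:
    """Floor semantics: how many candidates the top-fraction stage keeps."""
    if not 0 < fraction <= 1:
        raise FormulationError("fraction must be in (0, 1]")
    return int(np.floor(fraction * n))


def select_top_fraction(
    scored: Sequence[tuple[Formulation, float]], fraction: float
) -> list[tuple[Formulation, float]]:
    """Keep the floor(fraction * N) highest-scoring candidates; ties are
    broken by enumeration order (stable sort on negated score)."""
    if not scored:
        raise FormulationError("empty candidate stream")
    k = top_fraction_count(len(scored), fraction)
    order = np.argsort([-s for _, s in scored], kind="stable")
    return [scored[i] for i in order[:k]]


def drop_uncertain_half(
    candidates: Sequence[tuple[Formulation, float, float]]
) -> list[tuple[Formulation, float, float]]:
    """Retain the floor(N/2) candidates with the lowest relative
    uncertainty (ties by stable order); input is (formulation, score,
    u_rel) with dropped-flagged candidates already removed."""
    k = len(candidates) // 2
    order = np.argsort([u for _, _, u in candidates], kind="stable")
    return [candidates[i] for i in order[:k]]


def diverse_hits(
    candidates: Sequence[tuple[Formulation, float]],
    catalogue: Catalogue,
    k: int = 10,
    n_restarts: int = 1000,
    seed: int = 0,
) -> list[tuple[Formulation, float]]:
    """Pick ``k`` chemically diverse high scorers.

    K-means (best of ``n_restarts`` seeded runs by inertia) on the
    molar-% slot vectors -- one slot per catalogue molecule, zeros for
    absent lipids (14-d for the campaign catalogue) -- then the
    highest-scoring candidate of each cluster.
    """
    from sklearn.cluster import KMeans

    if k > len(candidates):
        raise FormulationError("k exceeds the number of candidates")
    if k == len(candidates):
        return list(candidates)
    slots = catalogue.slot_order()
    X = np.stack([f.slot_vector(slots) for f, _ in candidates])
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(X)
    picks = []
    for c in range(k):
        members = np.flatnonzero(assign == c)
        if len(members) == 0:
            continue
        best = members[int(np.argmax([candidates[i][1] for i in members]))]
        picks.append(candidates[best])
    return picks


def run_screening_funnel(
    models: Sequence[CometModel],
    grid_stream: Iterable[Formulation],
    reference: Sequence[Formulation],
    task: str,
    catalogue: Catalogue,
    known_hits: Sequence[Formulation] = (),
    exclusion_radius: float = 10.0,
    top_fraction: float = 0.001,
    k: int = 10,
    n_restarts: int = 1000,
    seed: int = 0,
    chunk: int = 2048,
) -> FunnelReport:
    """Execute the full screening funnel on a streamed library.

    The stream is scored in chunks and only a bounded pool of current
    top candidates is kept, so libraries far larger than memory can be
    screened; counts at each stage are recorded in the report.
    """
    report = FunnelReport()
    ref_means, ref_stds, ref_min = reference_statistics(models, reference, task)

    filtered = exclude_near_hits(grid_stream, known_hits, exclusion_radius)
    # two-pass-free streaming: keep a growing pool capped at 4x the
    # expected selection size, rescored lazily
    pool: list[tuple[Formulation, np.ndarray]] = []
    n_seen = 0
    buf: list[Formulation] = []

    def flush(buf):
        nonlocal pool
        if not buf:
            return
        norm = score_candidates(models, buf, task, ref_means, ref_stds, chunk=chunk)
        for j, f in enumerate(buf):
            pool.append((f, norm[:, j]))

    for f in filtered:
        buf.append(f)
        n_seen += 1
        if len(buf) >= chunk:
            flush(buf)
            buf = []
            cap = max(64, int(4 * top_fraction * n_seen) + 64)
            if len(pool) > cap:
                pool.sort(key=lambda t: -float(t[1].mean()))
                pool = pool[:cap]
    flush(buf)
    report.enumerated = n_seen  # post-exclusion stream length
    report.after_exclusion = n_seen

    n_top = top_fraction_count(n_seen, top_fraction)
    pool.sort(key=lambda t: -float(t[1].mean()))
    top = pool[:n_top]
    report.top_fraction = len(top)

    norm = np.stack([v for _, v in top], axis=1) if top else np.zeros((len(models), 0))
    u_rel, dropped, shifted = relative_uncertainty(norm, ref_min)
    kept = [
        (top[i][0], float(norm[:, i].mean()), float(u_rel[i]))
        for i in range(len(top))
        if not dropped[i]
    ]
    report.after_uncertainty_drop = len(kept)
    retained = drop_uncertain_half(kept)
    report.after_uncertainty_half = len(retained)

    scored = [(f, s) for f, s, _ in retained]
    hits = diverse_hits(scored, catalogue, k=min(k, len(scored)) or 1, n_restarts=n_restarts, seed=seed) if scored else []
    report.hits = hits
    report.selected = len(hits)
    return report


def lead_optimization_segments(
    lead: Formulation,
    candidates: Iterable[Formulation],
    score_fn,
    radius: float = 20.0,
    mode: str = "lipid",
) -> dict[str, tuple[Formulation, float] | None]:
    """Best candidate per neighbourhood zone around a lead.

    Zones (pairwise disjoint, lead excluded): ``molar`` -- same lipids,
    within ``radius`` L1 molar distance, same N/P; ``substitute`` -- at
    least one different lipid, within ``radius``; and either ``np``
    (lipid mode: same lipids and composition, different N/P) or
    ``dual`` (polymer mode: a second ionizable lipid added).  Empty
    zones map to ``None``.
    """
    if mode not in ("lipid", "pbae"):
        raise FormulationError("mode must be 'lipid' or 'pbae'")
    lead_lipids = frozenset(lead.molecule_ids)
    third = "np" if mode == "lipid" else "dual"
    best: dict[str, tuple[Formulation, float] | None] = {
        "molar": None,
        "substitute": None,
        third: None,
    }

    def consider(zone: str, f: Formulation, s: float) -> None:
        if best[zone] is None or s > best[zone][1]:
            best[zone] = (f, s)

    from .formulation import l1_molar_distance

    for f in candidates:
        if (
            frozenset(f.molecule_ids) == lead_lipids
            and f.components == lead.components
            and f.np_ratio == lead.np_ratio
        ):
            continue  # the lead itself
        same_lipids = frozenset(f.molecule_ids) == lead_lipids
        dist = l1_molar_distance(f, lead)
        s = score_fn(f)
        if mode == "lipid" and same_lipids and f.np_ratio != lead.np_ratio:
            if dist == 0:
                consider("np", f, s)
            continue
        if same_lipids and dist <= radius and dist > 0:
            consider("molar", f, s)
        elif not same_lipids and dist <= radius:
            if mode == "pbae" and len(
                [m for m in f.molecule_ids if m not in lead_lipids]
            ) and _is_dual_extension(f, lead):
                consider("dual", f, s)
            else:
                consider("substitute", f, s)
    return best


def _is_dual_extension(f: Formulation, lead: Formulation) -> bool:
    """True when f adds a second ionizable lipid to the lead's set."""
    return set(lead.molecule_ids) < set(f.molecule_ids)
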