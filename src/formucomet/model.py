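"""The set-transformer scoring function f_theta: formulation -> score.

Tokens (component tokens, an N/P token, a phase token, one CLS token
per task) pass through ``n_blocks`` Pre-LayerNorm transformer blocks
(layernorm -> multi-head self-attention -> MLP, residual connections,
no positional encoding -- the token set is unordered, which makes the
score permutation invariant over components).  The per-task score is a
two-layer MLP readout of that task's CLS token.

Weights live in a flat name -> Tensor dict; construction is
reproducible from a seed, and checkpoints store config + weights +
catalogue hash.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat
from .encoders import (
    D_COMP,
    D_MOL,
    D_TOKEN,
    FormulationTokenizer,
    molar_percent_encoder,
    np_ratio_encoder,
)
from .formulation import Formulation, FormulationError


@dataclass
class CometConfig:
    """Architecture hyperparameters.

    Defaults are sized for desk-scale CPU training; every field is
    configurable.  ``d_token`` must be divisible by ``n_heads``.
    """

    tasks: list[str] = field(default_factory=lambda: ["efficacy"])
    d_token: int = D_TOKEN
    n_blocks: int = 2
    n_heads: int = 8
    mlp_hidden: int = 512
    head_hidden: int = 128
    d_mol: int = D_MOL
    d_comp: int = D_COMP
    d_type: int = 128
    n_classes: int = 6
    n_phases: int = 2
    max_np: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_token % self.n_heads != 0:
            raise FormulationError("d_token must be divisible by n_heads")


class CometModel:
    """Scoring network over formulation token sets."""

    def __init__(self, config: CometConfig, tokenizer: FormulationTokenizer):
        self.config = config
        self.tokenizer = tokenizer
        if len(tokenizer.phase_vocab) != config.n_phases:
            config.n_phases = len(tokenizer.phase_vocab)
        if len(tokenizer.class_vocab) != config.n_classes:
            config.n_classes = len(tokenizer.class_vocab)
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(config.seed))
        self.training = False

    # -- parameters ---------------------------------------------------
    def _add(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True)

    def _rng(self, name: str) -> np.random.Generator:
        # Per-parameter stream keyed by (seed, name): adding parameters
        # (e.g. extra component-class embedding rows) leaves every other
        # parameter's draw unchanged.
        import zlib

        return np.random.default_rng(
            (self.config.seed * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)
        )

    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.config

        def dense(name, d_in, d_out):
            scale = np.sqrt(2.0 / (d_in + d_out))
            self._add(f"{name}.W", self._rng(name).normal(0.0, scale, (d_in, d_out)))
            self._add(f"{name}.b", np.zeros(d_out))

        # Gaussian scalar encoders (learnable centres/widths)
        molar_enc = molar_percent_encoder(c.d_comp)
        self._add("molar.mu", molar_enc.mu)
        self._add("molar.log_sigma", np.log(molar_enc.sigma))
        np_enc = np_ratio_encoder(c.d_token, c.max_np)
        self._add("np.mu", np_enc.mu)
        self._add("np.log_sigma", np.log(np_enc.sigma))
        # type and phase embeddings (one-hot derived)
        self._add("type.embed", self._rng("type.embed").normal(0.0, 0.02, (c.n_classes, c.d_type)))
        self._add("phase.embed", self._rng("phase.embed").normal(0.0, 0.02, (c.n_phases, c.d_token)))
        # component MLP: concat(512 + 128 + 128) -> 256 -> 256
        dense("comp_mlp.0", c.d_mol + c.d_comp + c.d_type, c.d_token)
        dense("comp_mlp.1", c.d_token, c.d_token)
        # CLS tokens
        for t in c.tasks:
            self._add(f"cls.{t}", self._rng(f"cls.{t}").normal(0.0, 0.02, (c.d_token,)))
        # transformer blocks
        for i in range(c.n_blocks):
            p = f"block{i}"
            self._add(f"{p}.ln1.g", np.ones(c.d_token))
            self._add(f"{p}.ln1.b", np.zeros(c.d_token))
            dense(f"{p}.q", c.d_token, c.d_token)
            dense(f"{p}.k", c.d_token, c.d_token)
            dense(f"{p}.v", c.d_token, c.d_token)
            dense(f"{p}.o", c.d_token, c.d_token)
            self._add(f"{p}.ln2.g", np.ones(c.d_token))
            self._add(f"{p}.ln2.b", np.zeros(c.d_token))
            dense(f"{p}.mlp.0", c.d_token, c.mlp_hidden)
            dense(f"{p}.mlp.1", c.mlp_hidden, c.d_token)
        # per-task prediction heads
        for t in c.tasks:
            dense(f"head.{t}.0", c.d_token, c.head_hidden)
            dense(f"head.{t}.1", c.head_hidden, 1)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    # -- building blocks ---------------------------------------------
    def _linear(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.W"] + self.params[f"{name}.b"]

    def _gauss(self, prefix: str, v: Tensor) -> Tensor:
        """exp(-(v - mu)^2 / (2 sigma^2)) over the basis axis."""
        mu = self.params[f"{prefix}.mu"]
        sigma = self.params[f"{prefix}.log_sigma"].exp()
        diff = v - mu
        return (-(diff * diff) / (sigma * sigma * 2.0)).exp()

    def component_tokens(
        self,
        mol: Tensor,
        molar: Tensor,
        class_onehot: Tensor,
        molar_embed: Tensor | None = None,
    ) -> Tensor:
        """Build (B, L, d_token) component tokens.

        ``mol`` (B, L, 512) frozen molecular embeddings, ``molar``
        (B, L) percentages on the 0-100 scale, ``class_onehot``
        (B, L, C).  Concat width is d_mol + d_comp + d_type = 768
        before the two-layer MLP.  ``molar_embed`` overrides the
        Gaussian encoding (used by attribution paths in encoded space).
        """
        B, L = molar.shape[0], molar.shape[1]
        comp = (
            molar_embed
            if molar_embed is not None
            else self._gauss("molar", molar.reshape(B, L, 1))
        )
        typ = class_onehot @ self.params["type.embed"]
        x = concat([mol, comp, typ], axis=-1)
        h = self._linear("comp_mlp.0", x).relu()
        return self._linear("comp_mlp.1", h)

    def _encode_batch(
        self, batch: dict[str, np.ndarray | Tensor], tasks: Sequence[str]
    ) -> tuple[Tensor, np.ndarray, int]:
        """Assemble the token sequence [CLS_t..., components, np, phase]."""
        c = self.config
        tens = {
            k: v if isinstance(v, Tensor) else Tensor(v)
            for k, v in batch.items()
        }
        mol, molar, cls_oh = tens["mol"], tens["molar"], tens["class_onehot"]
        mask = batch["mask"]
        mask = mask.data if isinstance(mask, Tensor) else mask
        B, L = molar.shape
        comp_tokens = self.component_tokens(
            mol, molar, cls_oh, molar_embed=tens.get("molar_embed")
        )
        np_embed = tens.get("np_embed")
        if np_embed is None:
            np_embed = self._gauss("np", tens["np"].reshape(B, 1))
        np_token = np_embed.reshape(B, 1, c.d_token)
        phase_token = (tens["phase_onehot"] @ self.params["phase.embed"]).reshape(
            B, 1, c.d_token
        )
        cls_tokens = [
            (self.params[f"cls.{t}"] * Tensor(np.ones((B, 1, 1), dtype=np.float32))).reshape(
                B, 1, c.d_token
            )
            for t in tasks
        ]
        seq = concat(cls_tokens + [comp_tokens, np_token, phase_token], axis=1)
        T = len(tasks)
        full_mask = np.concatenate(
            [np.ones((B, T), np.float32), mask, np.ones((B, 2), np.float32)], axis=1
        )
        return seq, full_mask, T

    def _attention(self, prefix: str, x: Tensor, key_mask: np.ndarray) -> Tensor:
        c = self.config
        B, S, _ = x.shape
        H, dk = c.n_heads, c.d_token // c.n_heads

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, S, H, dk).transpose(0, 2, 1, 3)

        q = heads(self._linear(f"{prefix}.q", x))
        k = heads(self._linear(f"{prefix}.k", x))
        v = heads(self._linear(f"{prefix}.v", x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        bias = (1.0 - key_mask)[:, None, None, :] * -1e9
        attn = (scores + Tensor(bias.astype(np.float32))).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, S, c.d_token)
        return self._linear(f"{prefix}.o", out)

    def _blocks(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        for i in range(self.config.n_blocks):
            p = f"block{i}"
            h = x.layer_norm(self.params[f"{p}.ln1.g"], self.params[f"{p}.ln1.b"])
            x = x + self._attention(p, h, key_mask)
            h = x.layer_norm(self.params[f"{p}.ln2.g"], self.params[f"{p}.ln2.b"])
            h = self._linear(f"{p}.mlp.0", h).relu()
            x = x + self._linear(f"{p}.mlp.1", h)
        return x

    def _head(self, task: str, cls_vec: Tensor) -> Tensor:
        h = self._linear(f"head.{task}.0", cls_vec).relu()
        return self._linear(f"head.{task}.1", h)

    def molar_embedding(self, values: np.ndarray) -> np.ndarray:
        """Gaussian-encoded molar percentages, (...,) -> (..., d_comp)."""
        v = Tensor(np.asarray(values, np.float32)[..., None])
        return self._gauss("molar", v).data

    def np_embedding(self, values: np.ndarray) -> np.ndarray:
        """Gaussian-encoded N/P ratios, (...,) -> (..., d_token)."""
        v = Tensor(np.asarray(values, np.float32)[..., None])
        return self._gauss("np", v).data

    # -- public forward ----------------------------------------------
    def forward_collated(
        self, batch: dict[str, np.ndarray | Tensor], tasks: Sequence[str] | None = None
    ) -> dict[str, Tensor]:
        """Score a collated batch; returns task -> (B,) score Tensor."""
        tasks = list(tasks) if tasks is not None else list(self.config.tasks)
        for t in tasks:
            if t not in self.config.tasks:
                raise FormulationError(f"unknown task {t!r}")
        seq, full_mask, T = self._encode_batch(batch, tasks)
        out = self._blocks(seq, full_mask)
        B = out.shape[0]
        scores = {}
        for j, t in enumerate(tasks):
            cls_vec = out.slice_axis1(j, j + 1).reshape(B, self.config.d_token)
            scores[t] = self._head(t, cls_vec).reshape(B)
        return scores

    def forward_batch(
        self, formulations: Sequence[Formulation], task: str
    ) -> np.ndarray:
        """Score a list of formulations for one task (inference)."""
        if not formulations:
            raise FormulationError("empty formulation list")
        toks = [self.tokenizer.tokenize(f, self.config.tasks) for f in formulations]
        batch = self.tokenizer.collate(toks)
        return self.forward_collated(batch, [task])[task].data.astype(np.float64)

    def forward_score(self, f: Formulation, task: str) -> float:
        return float(self.forward_batch([f], task)[0])

    def extract_cls_representation(
        self, formulations: Sequence[Formulation] | Formulation, task: str
    ) -> np.ndarray:
        """The post-block CLS vector(s) entering the prediction head."""
        single = isinstance(formulations, Formulation)
        fs = [formulations] if single else list(formulations)
        if task not in self.config.tasks:
            raise FormulationError(f"unknown task {task!r}")
        toks = [self.tokenizer.tokenize(f, self.config.tasks) for f in fs]
        batch = self.tokenizer.collate(toks)
        tasks = [task]
        seq, full_mask, _ = self._encode_batch(batch, tasks)
        out = self._blocks(seq, full_mask)
        B = out.shape[0]
        reps = out.slice_axis1(0, 1).reshape(B, self.config.d_token).data
        return reps[0] if single else reps

    # -- checkpointing ------------------------------------------------
    def save(self, path: str | Path, catalogue_hash: str | None = None) -> None:
        path = Path(path)
        meta = {
            "config": asdict(self.config),
            "tasks": self.config.tasks,
            "catalogue_hash": catalogue_hash or _catalogue_hash(self.tokenizer),
            "phase_vocab": self.tokenizer.phase_vocab,
            "format_version": 1,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            for name, p in self.params.items():
                import io as _io

                buf = _io.BytesIO()
                np.save(buf, p.data)
                zf.writestr(f"params/{name}.npy", buf.getvalue())

    @classmethod
    def load(
        cls,
        path: str | Path,
        tokenizer: FormulationTokenizer,
        force: bool = False,
    ) -> "CometModel":
        with zipfile.ZipFile(Path(path)) as zf:
            meta = json.loads(zf.read("meta.json"))
            if not force and meta["catalogue_hash"] != _catalogue_hash(tokenizer):
                raise FormulationError(
                    "checkpoint catalogue hash mismatch (pass force=True to override)"
                )
            cfg = CometConfig(**meta["config"])
            model = cls(cfg, tokenizer)
            import io as _io

            for name in model.params:
                data = np.load(_io.BytesIO(zf.read(f"params/{name}.npy")))
                model.params[name] = Tensor(data, requires_grad=True)
        return model


def _catalogue_hash(tokenizer: FormulationTokenizer) -> str:
    import hashlib

    payload = json.dumps(
        [(r.id, r.smiles, r.component_class.value) for r in tokenizer.catalogue],
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
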