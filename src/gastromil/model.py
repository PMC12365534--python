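"""The attention-MIL grading network.

One slide is a bag of patch feature vectors.  The network maps each
1,024-d instance through a feature module (linear + ReLU) to a 512-d
embedding, scores every embedding with a gated attention module
(tanh x sigmoid branches), pools the bag as the attention-weighted sum
(dot product of scores and embeddings), and classifies the pooled
vector through a 128-wide penultimate layer into K ordinal grades
(K = 3 for inflammation/activity, K = 4 for atrophy/intestinal
metaplasia).  Slide-level outputs are therefore permutation invariant
in the bag order, and the per-instance attention weights are the raw
material for whole-slide heatmaps.

The implementation is plain NumPy (float32) with hand-derived
gradients; everything is a pure function of (params, input), which
keeps reference-mode runs bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ContractViolationError, FormatError, InvalidInputError
from .features import FeatureBag

CHECKPOINT_SCHEMA = "gastromil-ckpt-1"

TASK_NAMES = {1: "inflammation", 2: "activity", 3: "atrophy", 4: "intestinal_metaplasia"}


@dataclass(frozen=True)
class GradingScheme:
    """Ordinal class list for one of the four grading tasks.

    Tasks 1-2 (inflammation, activity) are ternary because fully normal
    mucosa is essentially never biopsied; tasks 3-4 (atrophy, IM) are
    quaternary with a ``normal`` grade.
    """

    task_id: int
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.task_id not in (1, 2, 3, 4):
            raise InvalidInputError("task_id must be 1..4")
        expected = 3 if self.task_id in (1, 2) else 4
        if len(self.class_names) != expected:
            raise InvalidInputError(
                f"task {self.task_id} requires {expected} classes, got {len(self.class_names)}"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(self.n_classes)

    @property
    def name(self) -> str:
        return TASK_NAMES[self.task_id]

    @classmethod
    def for_task(cls, task_id: int) -> "GradingScheme":
        if task_id in (1, 2):
            return cls(task_id, ("mild", "moderate", "severe"))
        return cls(task_id, ("normal", "mild", "moderate", "severe"))


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``input_dim`` matches the backbone output (1,024 for a ResNet50
    trunk); ``embed_dim``/``attn_dim``/``hidden_dim`` follow standard
    attention-MIL sizing (1024 -> 512, gated attention 256, penultimate
    128).  ``gated`` toggles the tanh x sigmoid attention variant.
    """

    input_dim: int = 1024
    embed_dim: int = 512
    attn_dim: int = 256
    hidden_dim: int = 128
    n_classes: int = 4
    gated: bool = True
    dropout: float = 0.25
    input_dropout: float = 0.5  # per-feature dropout on the raw bag matrix
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_dim", "embed_dim", "attn_dim", "hidden_dim", "n_classes"):
            if getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be >= 1")
        if self.n_classes not in (3, 4):
            raise InvalidInputError("n_classes must be 3 or 4")
        if not 0.0 <= self.dropout < 1.0 or not 0.0 <= self.input_dropout < 1.0:
            raise InvalidInputError("dropout rates must lie in [0, 1)")


@dataclass
class AttentionMap:
    """Normalized per-patch attention aligned to patch coordinates."""

    slide_id: str
    weights: np.ndarray
    raw_scores: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-6:
            raise InvalidInputError("attention weights must be a probability vector")
        if len(self.weights) != len(self.raw_scores) or len(self.weights) != len(self.coords):
            raise ContractViolationError("attention/raw/coords lengths disagree")


@dataclass
class GradePrediction:
    """Per-class probabilities and the predicted ordinal grade."""

    slide_id: str
    task_id: int
    probabilities: np.ndarray
    logits: np.ndarray
    predicted_rank: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
            raise InvalidInputError("probabilities must be a probability vector")


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def init_params(config: ModelConfig) -> dict[str, np.ndarray]:
    """He/Xavier-initialized parameter dict, float32, seeded."""
    rng = np.random.default_rng(config.seed)
    D, E, A, P, K = (
        config.input_dim,
        config.embed_dim,
        config.attn_dim,
        config.hidden_dim,
        config.n_classes,
    )

    def lin(fan_in, shape, gain=2.0):
        return (rng.standard_normal(shape) * np.sqrt(gain / fan_in)).astype(np.float32)

    return {
        "W1": lin(D, (D, E)),
        "b1": np.zeros(E, np.float32),
        "Wv": lin(E, (E, A), gain=1.0),
        "bv": np.zeros(A, np.float32),
        "Wu": lin(E, (E, A), gain=1.0),
        "bu": np.zeros(A, np.float32),
        "wa": lin(A, (A,), gain=1.0),
        "ba": np.zeros(1, np.float32),
        "W2": lin(E, (E, P)),
        "b2": np.zeros(P, np.float32),
        "W3": lin(P, (P, K), gain=1.0),
        "b3": np.zeros(K, np.float32),
    }


# ---------------------------------------------------------------------------
# functional pieces (spec-level operations)
# ---------------------------------------------------------------------------

def embed(X: np.ndarray, params: dict, config: ModelConfig) -> np.ndarray:
    """Per-instance feature module: ReLU(X W1 + b1); no cross-instance mixing."""
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 2 or X.shape[1] != config.input_dim:
        raise ContractViolationError(
            f"bag dim {X.shape} incompatible with input_dim {config.input_dim}"
        )
    return np.maximum(X @ params["W1"] + params["b1"], 0.0)


def attention_scores(
    H: np.ndarray, params: dict, config: ModelConfig,
    slide_id: str = "slide", coords: np.ndarray | None = None,
) -> AttentionMap:
    """Softmax-normalized attention over the bag (gated when configured)."""
    if len(H) < 1:
        raise InvalidInputError("attention needs at least one instance")
    V = np.tanh(H @ params["Wv"] + params["bv"])
    if config.gated:
        G = 1.0 / (1.0 + np.exp(-(H @ params["Wu"] + params["bu"])))
        s = (V * G) @ params["wa"] + params["ba"][0]
    else:
        s = V @ params["wa"] + params["ba"][0]
    a = softmax(s.astype(np.float64))
    if coords is None:
        coords = np.zeros((len(H), 2), dtype=np.int64)
    return AttentionMap(slide_id=slide_id, weights=a, raw_scores=s, coords=coords)


def pool(H: np.ndarray, attn: AttentionMap) -> np.ndarray:
    """Attention-weighted sum of embeddings: z = sum_i a_i H_i."""
    if len(H) != len(attn.weights):
        raise ContractViolationError("attention length does not match bag size")
    return attn.weights.astype(np.float32) @ H


def classify(
    z: np.ndarray, params: dict, config: ModelConfig,
    slide_id: str = "slide", task_id: int = 3,
) -> GradePrediction:
    """Penultimate ReLU layer + linear head + softmax over K grades.

    Argmax ties break toward the lowest (least severe) rank.
    """
    q = np.maximum(z @ params["W2"] + params["b2"], 0.0)
    logits = q @ params["W3"] + params["b3"]
    probs = softmax(logits.astype(np.float64))
    return GradePrediction(
        slide_id=slide_id,
        task_id=task_id,
        probabilities=probs,
        logits=logits,
        predicted_rank=int(np.argmax(probs)),  # first max = lowest rank
    )


def _forward_cache(
    X: np.ndarray,
    params: dict,
    config: ModelConfig,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Training-mode forward pass caching every intermediate for backprop."""
    X = np.asarray(X, dtype=np.float32)
    if dropout_rng is not None and config.input_dropout > 0:
        keep = 1.0 - config.input_dropout
        in_drop = (dropout_rng.random(X.shape[1]) < keep).astype(np.float32) / keep
        X = X * in_drop
    pre1 = X @ params["W1"] + params["b1"]
    H = np.maximum(pre1, 0.0)
    drop = None
    if dropout_rng is not None and config.dropout > 0:
        keep = 1.0 - config.dropout
        drop = (dropout_rng.random(H.shape) < keep).astype(np.float32) / keep
        H = H * drop
    V = np.tanh(H @ params["Wv"] + params["bv"])
    if config.gated:
        G = 1.0 / (1.0 + np.exp(-(H @ params["Wu"] + params["bu"])))
        VG = V * G
    else:
        G = None
        VG = V
    s = VG @ params["wa"] + params["ba"][0]
    a = softmax(s.astype(np.float64)).astype(np.float32)
    z = a @ H
    pre2 = z @ params["W2"] + params["b2"]
    q = np.maximum(pre2, 0.0)
    logits = q @ params["W3"] + params["b3"]
    cache = dict(X=X, pre1=pre1, H=H, drop=drop, V=V, G=G, VG=VG, a=a, z=z, pre2=pre2, q=q)
    return logits, cache


def _backward(dlogits: np.ndarray, cache: dict, params: dict, config: ModelConfig) -> dict:
    """Gradients of a scalar loss wrt every parameter, given dL/dlogits."""
    X, H, a, z, q = cache["X"], cache["H"], cache["a"], cache["z"], cache["q"]
    dlogits = dlogits.astype(np.float32)
    grads = {}
    grads["W3"] = np.outer(q, dlogits)
    grads["b3"] = dlogits
    dq = (params["W3"] @ dlogits) * (cache["pre2"] > 0)
    grads["W2"] = np.outer(z, dq)
    grads["b2"] = dq
    dz = params["W2"] @ dq
    da = H @ dz
    dH = np.outer(a, dz)
    ds = a * (da - float(a @ da))
    V, G, VG = cache["V"], cache["G"], cache["VG"]
    grads["wa"] = VG.T @ ds
    grads["ba"] = np.array([ds.sum()], dtype=np.float32)
    dVG = np.outer(ds, params["wa"])
    if config.gated:
        dV = dVG * G
        dG = dVG * V
        dpreG = dG * G * (1.0 - G)
        grads["Wu"] = H.T @ dpreG
        grads["bu"] = dpreG.sum(axis=0)
        dH += dpreG @ params["Wu"].T
    else:
        dV = dVG
        grads["Wu"] = np.zeros_like(params["Wu"])
        grads["bu"] = np.zeros_like(params["bu"])
    dpreV = dV * (1.0 - V * V)
    grads["Wv"] = H.T @ dpreV
    grads["bv"] = dpreV.sum(axis=0)
    dH += dpreV @ params["Wv"].T
    if cache["drop"] is not None:
        dH = dH * cache["drop"]
    dpre1 = dH * (cache["pre1"] > 0)
    grads["W1"] = X.T @ dpre1
    grads["b1"] = dpre1.sum(axis=0)
    return grads


class MILModel:
    """Config + parameters + forward pass for one grading task."""

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray] | None = None,
                 task_id: int | None = None):
        self.config = config
        self.params = params if params is not None else init_params(config)
        self.task_id = task_id if task_id is not None else (3 if config.n_classes == 4 else 1)

    def copy(self) -> "MILModel":
        return MILModel(self.config, {k: v.copy() for k, v in self.params.items()}, self.task_id)

    def forward(self, bag: FeatureBag) -> tuple[GradePrediction, AttentionMap]:
        """Full inference pass: embed -> attend -> pool -> classify."""
        H = embed(bag.features, self.params, self.config)
        attn = attention_scores(
            H, self.params, self.config, slide_id=bag.slide_id, coords=bag.coords
        )
        z = pool(H, attn)
        pred = classify(z, self.params, self.config, slide_id=bag.slide_id, task_id=self.task_id)
        return pred, attn

    def predict_proba(self, bags: list[FeatureBag]) -> np.ndarray:
        return np.stack([self.forward(b)[0].probabilities for b in bags])

    def save(self, path: str | Path) -> None:
        cfg = json.dumps(asdict(self.config))
        with open(path, "wb") as fh:  # file handle: numpy must not append .npz
            np.savez(
                fh,
                __schema__=CHECKPOINT_SCHEMA,
                __config__=cfg,
                __task__=self.task_id,
                **self.params,
            )

    @classmethod
    def load(cls, path: str | Path) -> "MILModel":
        try:
            with np.load(path, allow_pickle=False) as data:
                if str(data["__schema__"]) != CHECKPOINT_SCHEMA:
                    raise FormatError(f"unsupported checkpoint schema {data['__schema__']}")
                config = ModelConfig(**json.loads(str(data["__config__"])))
                params = {
                    k: data[k] for k in data.files if not k.startswith("__")
                }
                return cls(config, params, task_id=int(data["__task__"]))
        except (OSError, KeyError, ValueError) as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"cannot read checkpoint {path}: {exc}") from exc


def predictions_to_frame(preds: list[GradePrediction]):
    """Tabulate predictions as slide_id, task, p_0..p_{K-1}, predicted_rank."""
    import pandas as pd

    rows = []
    for p in preds:
        row = {"slide_id": p.slide_id, "task": p.task_id}
        row.update({f"p_{i}": p.probabilities[i] for i in range(len(p.probabilities))})
        row["predicted_rank"] = p.predicted_rank
        rows.append(row)
    return pd.DataFrame(rows)
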