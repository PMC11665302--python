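"""Attention-based MIL model variants.

Three permutation-invariant bag classifiers over instance embeddings:

* ``amil`` — attention pooling. A two-layer scorer
  :math:`\\psi_a(h_i) = w^\\top \\tanh(V h_i^\\top)` produces one logit per
  instance; a softmax over instances yields attention weights
  :math:`a_i`; the weighted sum :math:`z = \\sum_i a_i h_i` goes through a
  bag classifier :math:`\\psi_p` to give class logits.
* ``admil`` — additive MIL. Same scorer shape but with LeakyReLU in place of
  tanh; instead of pooling first, a patch score layer is applied to every
  attention-scaled instance, :math:`\\psi_p(a_i h_i)`, giving an explicit
  per-patch, per-class contribution logit; the bag logits are the sum of the
  patch logits.
* ``admil_tanh`` — the hybrid: additive head of ``admil`` with the tanh
  attention of ``amil``. The tanh scorer compresses its input, so attention
  spreads over more instances, while LeakyReLU lets large positive scores
  dominate the softmax and concentrates attention on few instances.

Parameters are stored as float32; forward passes accumulate in float64 and
are pure functions of (bag, parameters), invariant to instance order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .bags import Bag

VARIANTS = ("amil", "admil", "admil_tanh")

#: attention activation used by each variant
VARIANT_ACTIVATION = {"amil": "tanh", "admil": "leaky_relu", "admil_tanh": "tanh"}

#: variants whose head is the additive patch score layer
ADDITIVE_VARIANTS = ("admil", "admil_tanh")

LEAKY_SLOPE = 0.01


class ConfigurationError(ValueError):
    """Raised for invalid variant / model configuration."""


class Polarity(str, Enum):
    INHIBITORY = "inhibitory"
    EXCITATORY = "excitatory"


@dataclass
class AttentionParams:
    """Trainable parameters of the instance scorer ``w^T act(V h^T)``."""

    V: np.ndarray  # (D, d)
    w: np.ndarray  # (D,)
    activation: str = "tanh"

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=np.float32)
        self.w = np.asarray(self.w, dtype=np.float32)
        if self.V.ndim != 2:
            raise ValueError(f"V must be 2-D (D, d), got shape {self.V.shape}")
        if self.w.shape != (self.V.shape[0],):
            raise ValueError(
                f"w length {self.w.shape} incompatible with V shape {self.V.shape}"
            )
        if self.activation not in ("tanh", "leaky_relu"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class BagPrediction:
    """Output of one forward pass.

    ``patch_logits`` is present only for additive variants, where
    ``bag_logits`` equals its column sum by construction.
    """

    class_probabilities: np.ndarray  # (C,)
    attention: np.ndarray  # (n,)
    bag_logits: np.ndarray  # (C,)
    patch_logits: np.ndarray | None = None  # (n, C)


@dataclass
class BoundedContribution:
    """Sigmoid-bounded patch contribution scores in (0, 1).

    Scores above 0.5 push toward the positive class (excitatory); scores at
    or below 0.5 push against it (inhibitory).
    """

    values: np.ndarray  # (n, C)
    polarity: list[Polarity]  # per instance, for the positive class


@dataclass
class MILModel:
    """A trainable MIL model: attention scorer plus classification head.

    The head is a single affine layer producing ``C`` logits — applied to the
    pooled vector (amil) or to each attention-scaled instance (additive
    variants).
    """

    variant: str
    d: int
    D: int
    C: int
    attention: AttentionParams
    W: np.ndarray  # (C, d) head weight
    b: np.ndarray  # (C,)  head bias
    seed: int | None = None

    @property
    def is_additive(self) -> bool:
        return self.variant in ADDITIVE_VARIANTS

    def parameters(self) -> dict[str, np.ndarray]:
        return {"V": self.attention.V, "w": self.attention.w, "W": self.W, "b": self.b}

    def copy(self) -> "MILModel":
        return MILModel(
            variant=self.variant,
            d=self.d,
            D=self.D,
            C=self.C,
            attention=AttentionParams(
                self.attention.V.copy(), self.attention.w.copy(),
                self.attention.activation,
            ),
            W=self.W.copy(),
            b=self.b.copy(),
            seed=self.seed,
        )


def _activate(t: np.ndarray, activation: str) -> np.ndarray:
    if activation == "tanh":
        return np.tanh(t)
    return np.where(t > 0, t, LEAKY_SLOPE * t)


def activation_grad(t: np.ndarray, activation: str) -> np.ndarray:
    """Derivative of the attention activation, used by the trainer."""
    if activation == "tanh":
        th = np.tanh(t)
        return 1.0 - th * th
    return np.where(t > 0, 1.0, LEAKY_SLOPE).astype(t.dtype)


def attention_logits(H: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Instance scores ``psi_a(h_i) = w^T act(V h_i^T)`` for each row of H.

    Parameters are stored in float32; the computation is carried out in
    float64 so forward passes agree with exact arithmetic to ~1e-9.
    """
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError(f"H must be a non-empty (n, d) matrix, got shape {H.shape}")
    if params.V.shape[1] != H.shape[1]:
        raise ValueError(
            f"dimension mismatch: V is {params.V.shape}, H rows have length "
            f"{H.shape[1]}"
        )
    t = H @ params.V.T.astype(np.float64)  # (n, D)
    return _activate(t, params.activation) @ params.w.astype(np.float64)


def attention_normalize(logits: np.ndarray) -> np.ndarray:
    """Softmax over the instance axis; output is on the probability simplex.

    Normalization is carried out in float64 so the simplex constraint holds
    to near machine precision even for large bags.
    """
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim != 1 or logits.size < 1:
        raise ValueError("attention logits must be a non-empty 1-D vector")
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _check_variant(model: MILModel, allowed: tuple[str, ...]) -> None:
    if model.variant not in allowed:
        raise ConfigurationError(
            f"model variant {model.variant!r} not valid here (expected one of "
            f"{allowed})"
        )


def amil_forward(bag: Bag, model: MILModel) -> BagPrediction:
    """Attention-pooled forward pass: head applied to ``sum_i a_i h_i``."""
    _check_variant(model, ("amil",))
    H = bag.instances.astype(np.float64)
    a = attention_normalize(attention_logits(H, model.attention))
    pooled = a @ H  # (d,)
    logits = model.W.astype(np.float64) @ pooled + model.b
    return BagPrediction(
        class_probabilities=softmax(logits),
        attention=a,
        bag_logits=logits,
    )


def admil_forward(bag: Bag, model: MILModel) -> BagPrediction:
    """Additive forward pass: per-patch logits ``psi_p(a_i h_i)``, summed."""
    _check_variant(model, ADDITIVE_VARIANTS)
    H = bag.instances.astype(np.float64)
    a = attention_normalize(attention_logits(H, model.attention))
    scaled = a[:, None] * H  # (n, d)
    patch_logits = scaled @ model.W.T.astype(np.float64) + model.b  # (n, C)
    bag_logits = patch_logits.sum(axis=0)
    return BagPrediction(
        class_probabilities=softmax(bag_logits),
        attention=a,
        bag_logits=bag_logits,
        patch_logits=patch_logits,
    )


def forward(bag: Bag, model: MILModel) -> BagPrediction:
    """Dispatch to the variant's forward pass."""
    if model.variant == "amil":
        return amil_forward(bag, model)
    return admil_forward(bag, model)


def bound_contributions(patch_logits: np.ndarray) -> BoundedContribution:
    """Sigmoid-bound patch logits into (0, 1) contribution scores.

    Polarity is read off the positive class (column 1, or column 0 for a
    single-column input): > 0.5 excitatory, <= 0.5 inhibitory.
    """
    pl = np.atleast_2d(np.asarray(patch_logits, dtype=np.float64))
    if not np.all(np.isfinite(pl)):
        raise ValueError("patch logits must be finite")
    values = 1.0 / (1.0 + np.exp(-pl))
    pos_col = 1 if values.shape[1] > 1 else 0
    polarity = [
        Polarity.EXCITATORY if v > 0.5 else Polarity.INHIBITORY
        for v in values[:, pos_col]
    ]
    return BoundedContribution(values=values.astype(np.float32), polarity=polarity)


def build_model(
    variant: str,
    d: int,
    seed: int,
    D: int = 128,
    C: int = 2,
) -> MILModel:
    """Deterministically initialize a model for the given seed.

    Weights use uniform fan-in initialization ``U(-1/sqrt(fan_in),
    1/sqrt(fan_in))``; the same (variant, d, seed, D, C) always yields
    identical parameters.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if d < 1 or D < 1 or C < 1:
        raise ConfigurationError("d, D and C must all be >= 1")
    rng = np.random.default_rng(seed)
    lim_v = 1.0 / np.sqrt(d)
    lim_w = 1.0 / np.sqrt(D)
    V = rng.uniform(-lim_v, lim_v, size=(D, d)).astype(np.float32)
    w = rng.uniform(-lim_w, lim_w, size=D).astype(np.float32)
    W = rng.uniform(-lim_v, lim_v, size=(C, d)).astype(np.float32)
    b = np.zeros(C, dtype=np.float32)
    return MILModel(
        variant=variant,
        d=d,
        D=D,
        C=C,
        attention=AttentionParams(V, w, VARIANT_ACTIVATION[variant]),
        W=W,
        b=b,
        seed=seed,
    )


def save_checkpoint(model: MILModel, path: str | Path) -> None:
    """Write parameters to ``<path>`` (npz) plus a JSON sidecar ``<path>.json``."""
    path = Path(path)
    np.savez(
        path,
        V=model.attention.V,
        w=model.attention.w,
        W=model.W,
        b=model.b,
    )
    # np.savez appends .npz when missing; mirror that for the sidecar
    target = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "variant": model.variant,
        "d": model.d,
        "D": model.D,
        "C": model.C,
        "seed": model.seed,
    }
    Path(str(target) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> MILModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    meta = json.loads(Path(str(path) + ".json").read_text())
    with np.load(path) as data:
        return MILModel(
            variant=meta["variant"],
            d=meta["d"],
            D=meta["D"],
            C=meta["C"],
            attention=AttentionParams(
                data["V"], data["w"], VARIANT_ACTIVATION[meta["variant"]]
            ),
            W=data["W"],
            b=data["b"],
            seed=meta["seed"],
        )
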