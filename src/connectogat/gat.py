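"""Two-layer multi-head graph attention network with top-k readout.

The model follows the standard graph-attention formulation: per head, node
features are linearly projected (W), attention logits
e_ij = LeakyReLU(a^T [W h_i || W h_j]) are computed for first-order
neighbors j of i (self-loops included), normalized with a softmax over the
neighborhood, and node outputs are the attention-weighted sums of projected
neighbor features passed through an ELU. Hidden-layer heads are
concatenated; the output layer has a single head. Graph-level embeddings
are formed by concatenating the k node embeddings with the largest L2
norm, and a small fully connected network with a terminal softmax produces
class probabilities.

Default architecture: 6 heads of width 8 in layer 1, one head of width 8
in layer 2, k = 20, and a [64, 16, 2] classifier with dropout 0.5.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, log_softmax, masked_softmax

__all__ = [
    "GATConfig",
    "GATModel",
    "ForwardResult",
    "attention_coefficients",
    "gat_layer_forward",
    "topk_readout",
    "classify",
]


@dataclass
class GATConfig:
    n_features: int = 24
    hidden: int = 8  # F' per head in layer 1
    heads1: int = 6
    out_features: int = 8  # width of the single layer-2 head
    readout_k: int = 20
    mlp_hidden: tuple[int, ...] = (64, 16)
    n_classes: int = 2
    dropout: float = 0.5
    leaky_slope: float = 0.2
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps({"schema": 1, **asdict(self)})

    @classmethod
    def from_json(cls, s: str) -> "GATConfig":
        d = json.loads(s)
        schema = d.pop("schema", 1)
        if schema != 1:
            raise ValueError(f"unsupported checkpoint schema {schema}")
        d["mlp_hidden"] = tuple(d["mlp_hidden"])
        return cls(**d)


@dataclass
class ForwardResult:
    probabilities: np.ndarray  # (n_classes,)
    log_probs: Tensor
    input_tensor: Tensor
    selected_nodes: np.ndarray  # readout node indices, descending score
    attention: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    @property
    def predicted(self) -> int:
        return int(np.argmax(self.probabilities))


def _with_self_loops(adjacency: np.ndarray) -> np.ndarray:
    a = (np.asarray(adjacency) != 0).astype(float)
    np.fill_diagonal(a, 1.0)
    return a


def attention_coefficients(
    h: np.ndarray,
    W: np.ndarray,
    a: np.ndarray,
    adjacency: np.ndarray,
    leaky_slope: float = 0.2,
) -> np.ndarray:
    """Normalized attention coefficients alpha_ij for one head (pure numpy).

    ``W`` is (F', F); ``a`` is the length-2F' attention vector, split into
    its source and destination halves. ``adjacency`` is binary; self-loops
    are added. Rows sum to 1 over each node's neighborhood and are zero
    outside it.
    """
    mask = _with_self_loops(adjacency)
    wh = h @ W.T
    fp = W.shape[0]
    src = wh @ a[:fp]
    dst = wh @ a[fp:]
    e = src[:, None] + dst[None, :]
    e = np.where(e > 0, e, leaky_slope * e)
    e = np.where(mask > 0, e, -np.inf)
    e -= e.max(axis=1, keepdims=True)
    ex = np.exp(e) * mask
    return ex / ex.sum(axis=1, keepdims=True)


def gat_layer_forward(
    h: np.ndarray,
    heads: list[tuple[np.ndarray, np.ndarray]],
    adjacency: np.ndarray,
    leaky_slope: float = 0.2,
    concat_heads: bool = True,
) -> np.ndarray:
    """Pure-numpy layer forward: per head ELU(alpha @ W h); heads
    concatenated (hidden layers) or averaged before the ELU (output)."""
    mask = _with_self_loops(adjacency)
    outs = []
    for W, a in heads:
        alpha = attention_coefficients(h, W, a, adjacency, leaky_slope)
        agg = alpha @ (h @ W.T)
        outs.append(agg)
    if concat_heads:
        return np.concatenate([_elu(o) for o in outs], axis=1)
    return _elu(np.mean(outs, axis=0))


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(x))


def topk_readout(H: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Select the k node embeddings with the largest L2 norm.

    Returns (graph embedding of length k * F_out, selected node indices in
    descending-score order). Ties break toward the lower node index.
    """
    n = H.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    norms = np.linalg.norm(H, axis=1)
    order = np.argsort(-norms, kind="stable")
    idx = order[:k]
    return H[idx].reshape(-1), idx


def classify(embedding: np.ndarray, mlp: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Pure-numpy MLP head: ReLU hidden layers, softmax output."""
    z = np.asarray(embedding, dtype=float)
    for i, (W, b) in enumerate(mlp):
        z = z @ W.T + b
        if i < len(mlp) - 1:
            z = np.maximum(z, 0.0)
    z -= z.max()
    ez = np.exp(z)
    return ez / ez.sum()


class GATModel:
    """Parameter container + differentiable forward pass."""

    def __init__(self, config: GATConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(config.seed))

    # -- initialization ----------------------------------------------------
    def _glorot(self, rng, shape) -> Tensor:
        fan = sum(shape) if len(shape) > 1 else shape[0] + 1
        limit = np.sqrt(6.0 / fan)
        return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)

    def _init_params(self, rng) -> None:
        c = self.config
        for p in range(c.heads1):
            self.params[f"l1h{p}.W"] = self._glorot(rng, (c.hidden, c.n_features))
            self.params[f"l1h{p}.a"] = self._glorot(rng, (2 * c.hidden,))
        width1 = c.heads1 * c.hidden
        self.params["l2h0.W"] = self._glorot(rng, (c.out_features, width1))
        self.params["l2h0.a"] = self._glorot(rng, (2 * c.out_features,))
        sizes = [c.readout_k * c.out_features, *c.mlp_hidden, c.n_classes]
        for i, (fin, fout) in enumerate(zip(sizes, sizes[1:])):
            self.params[f"fc{i}.W"] = self._glorot(rng, (fout, fin))
            self.params[f"fc{i}.b"] = Tensor(np.zeros(fout), requires_grad=True)

    @property
    def n_mlp_layers(self) -> int:
        return len(self.config.mlp_hidden) + 1

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()

    # -- forward -----------------------------------------------------------
    def _head_forward(
        self,
        h: Tensor,
        name: str,
        mask: np.ndarray,
        masked: bool,
        mask_mode: str,
    ) -> tuple[Tensor, np.ndarray]:
        c = self.config
        W, a = self.params[f"{name}.W"], self.params[f"{name}.a"]
        fp = W.shape[0]
        wh = h @ W.T
        src = wh @ a.take_rows(range(fp))
        dst = wh @ a.take_rows(range(fp, 2 * fp))
        n = mask.shape[0]
        e = src.reshape(n, 1) + dst.reshape(1, n)
        alpha = masked_softmax(e.leaky_relu(c.leaky_slope), mask, axis=1)
        if masked:
            if mask_mode == "uniform":
                alpha = Tensor(mask / mask.sum(axis=1, keepdims=True))
            elif mask_mode == "zero":
                alpha = Tensor(np.zeros_like(mask))
            else:
                raise ValueError(f"unknown mask_mode {mask_mode!r}")
        return (alpha @ wh).elu(), alpha.data

    def forward(
        self,
        x: np.ndarray,
        adjacency: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        record_attention: bool = False,
        mask_head: tuple[int, int] | None = None,
        mask_mode: str = "uniform",
        input_grad: bool = False,
    ) -> ForwardResult:
        """Full forward pass on one graph.

        ``mask_head=(layer, head)`` (0-based) replaces that head's learned
        attention with a head-agnostic form (uniform over the neighborhood,
        or zero), used by the fidelity analysis. ``input_grad=True`` makes
        the input a leaf tensor so that saliency gradients can be taken.
        """
        c = self.config
        x = np.asarray(x, dtype=float)
        n = x.shape[0]
        if x.shape[1] != c.n_features:
            raise ValueError(
                f"expected {c.n_features} input features, got {x.shape[1]}"
            )
        if c.readout_k > n:
            raise ValueError(f"readout_k = {c.readout_k} exceeds n = {n} nodes")
        if training and c.dropout > 0 and rng is None:
            raise ValueError("training forward with dropout needs an rng")
        mask = _with_self_loops(adjacency)
        xt = Tensor(x, requires_grad=input_grad)
        attention: dict[tuple[int, int], np.ndarray] = {}

        outs = []
        for p in range(c.heads1):
            o, alpha = self._head_forward(
                xt, f"l1h{p}", mask, mask_head == (0, p), mask_mode
            )
            outs.append(o)
            if record_attention:
                attention[(0, p)] = alpha
        h1 = concat(outs, axis=1)
        h2, alpha2 = self._head_forward(
            h1, "l2h0", mask, mask_head == (1, 0), mask_mode
        )
        if record_attention:
            attention[(1, 0)] = alpha2

        norms = np.linalg.norm(h2.data, axis=1)
        idx = np.argsort(-norms, kind="stable")[: c.readout_k]
        z = h2.take_rows(idx).reshape(-1)

        keep = 1.0 - c.dropout
        for i in range(self.n_mlp_layers):
            z = z @ self.params[f"fc{i}.W"].T + self.params[f"fc{i}.b"]
            if i < self.n_mlp_layers - 1:
                z = z.relu()
                if training and c.dropout > 0:
                    drop = (rng.uniform(size=z.shape) < keep) / keep
                    z = z * Tensor(drop)
        logp = log_softmax(z)
        return ForwardResult(
            probabilities=np.exp(logp.data),
            log_probs=logp,
            input_tensor=xt,
            selected_nodes=idx,
            attention=attention,
        )

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(path, __config__=np.frombuffer(
            self.config.to_json().encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GATModel":
        with np.load(Path(path) if str(path).endswith(".npz") else f"{path}") as z:
            cfg = GATConfig.from_json(bytes(z["__config__"]).decode())
            model = cls(cfg)
            for k in model.params:
                model.params[k] = Tensor(z[k], requires_grad=True)
        return model
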