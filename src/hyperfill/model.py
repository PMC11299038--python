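"""Dual-scale hyperedge scoring.

Every reaction hyperedge is modelled as a heterogeneous complete graph on
its substrate and product vertices and decomposed into three complete
subgraphs: substrate-substrate and product-product (homogeneous scale) and
the substrate-product bipartite graph (heterogeneous scale).  Symmetrically
normalized graph convolutions run on each scale, the resulting vertex
features are fused with the initial stoichiometry-derived embeddings via a
softmax attention over the three views, and norm / max-min pooling followed
by a two-layer MLP yields a sigmoid score in (0, 1).

Two execution paths are provided and kept numerically identical:

* per-edge operations (:func:`decompose_hyperedge`,
  :func:`normalize_adjacency`, :func:`intra_message_passing`, ...) that
  materialise the normalized adjacencies — the reference semantics;
* a padded, batched forward pass (:func:`forward_scores`) that exploits the
  closed form of convolution on complete graphs (the normalized adjacency
  of K_k is A/(k-1), so aggregation is "mean of the other same-role rows")
  and runs on large candidate batches through plain matrix products.

The batched path is written in ``autograd.numpy`` so the training loop can
differentiate through it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import autograd.numpy as anp
import numpy as np

from .errors import ContractError, DimensionError

_POOL_EPS = 1e-12  # keeps sqrt differentiable at an all-zero feature row
_MASK_BIG = 1e9


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class AblationFlags:
    """Forward-pass variants used in the ablation study.

    ``no_hetero`` collapses the dual-scale decomposition into a single
    graph convolution over the complete graph on all edge vertices;
    ``no_feat_init`` drops the substrate/product characteristic matrices
    from the initial embeddings (stoichiometry map only); ``no_attention``
    replaces the softmax attention fusion by an unweighted sum.  The
    single-layer-GCN baseline is all three flags together.
    """

    no_hetero: bool = False
    no_feat_init: bool = False
    no_attention: bool = False


@dataclass(frozen=True)
class ModelConfig:
    embed_dim: int = 256
    mlp_hidden: int = 128
    dropout: float = 0.2
    use_bias: bool = True
    # participation variant (h < 0) by default: the literal h <= 0 rule
    # makes the substrate characteristic matrix near-all-ones, whose
    # common-mode gradients destabilise training at scale
    zeros_as_substrates: bool = False
    ablation: AblationFlags = field(default_factory=AblationFlags)


# ---------------------------------------------------------------------------
# hyperedge and decomposition


@dataclass(frozen=True)
class Hyperedge:
    """One reaction: disjoint substrate and product vertex index tuples."""

    substrates: tuple[int, ...]
    products: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.substrates) & set(self.products):
            raise ContractError("substrate and product sets must be disjoint")
        if not self.substrates and not self.products:
            raise ContractError("hyperedge must have at least one vertex")

    @property
    def k(self) -> int:
        return len(self.substrates)

    @property
    def l(self) -> int:
        return len(self.products)

    @property
    def size(self) -> int:
        return self.k + self.l

    @property
    def vertices(self) -> tuple[int, ...]:
        return self.substrates + self.products

    def key(self) -> tuple[frozenset, frozenset]:
        """Identity of the edge: the unordered (V_S, V_P) pair."""
        return (frozenset(self.substrates), frozenset(self.products))


@dataclass
class EdgeDecomposition:
    """Adjacencies of the three complete subgraphs of one hyperedge."""

    A_S: np.ndarray  # (k, k) complete, zero diagonal
    A_P: np.ndarray  # (l, l)
    A_SP: np.ndarray  # (k, l) all ones
    A: np.ndarray  # (k+l, k+l) bipartite block matrix
    D_S: np.ndarray  # degree vectors
    D_P: np.ndarray
    D: np.ndarray


def decompose_hyperedge(edge: Hyperedge) -> EdgeDecomposition:
    """Decompose the heterogeneous complete graph on an edge's vertices.

    Returns the substrate-substrate and product-product complete subgraphs
    and the substrate-product complete bipartite subgraph; together their
    edge sets partition the edge set of K_{k+l}.
    """
    k, l = edge.k, edge.l
    A_S = np.ones((k, k)) - np.eye(k)
    A_P = np.ones((l, l)) - np.eye(l)
    A_SP = np.ones((k, l))
    A = np.zeros((k + l, k + l))
    A[:k, k:] = A_SP
    A[k:, :k] = A_SP.T
    return EdgeDecomposition(
        A_S=A_S,
        A_P=A_P,
        A_SP=A_SP,
        A=A,
        D_S=A_S.sum(axis=1),
        D_P=A_P.sum(axis=1),
        D=A.sum(axis=1),
    )


def normalize_adjacency(A: np.ndarray, D: np.ndarray | None = None) -> np.ndarray:
    """Symmetric normalization D^{-1/2} A D^{-1/2} with a zero-degree guard.

    Vertices of degree zero receive all-zero rows and columns instead of a
    division error.  For the complete graph K_k this reduces to A/(k-1).
    """
    A = np.asarray(A, dtype=float)
    if D is None:
        D = A.sum(axis=1)
    D = np.asarray(D, dtype=float)
    # a single division by sqrt(d_i d_j) is exact for complete graphs
    # (integer products have exact square roots), unlike two successive
    # multiplications by d^{-1/2}
    denom = np.sqrt(np.outer(D, D))
    out = np.zeros_like(A)
    np.divide(A, denom, out=out, where=denom > 0)
    return out


def _htanh(x):
    return anp.clip(x, -1.0, 1.0)


def intra_message_passing(
    X_S: np.ndarray,
    X_P: np.ndarray,
    dec: EdgeDecomposition,
    W_S: np.ndarray,
    W_P: np.ndarray,
) -> np.ndarray:
    """Homogeneous-scale convolution inside each vertex role.

    Substrates exchange messages only with the other substrates of the same
    edge, products only with the other products; no self-loops, so a
    single-member side receives a zero message.  Returns the row
    concatenation [X_S', X_P'] of shape (k+l, d).
    """
    if X_S.shape[0] != dec.A_S.shape[0] or X_P.shape[0] != dec.A_P.shape[0]:
        raise DimensionError("feature row counts do not match the decomposition")
    if X_S.shape[1] != W_S.shape[0] or X_P.shape[1] != W_P.shape[0]:
        raise DimensionError("feature width does not match weight shape")
    out_S = _htanh(normalize_adjacency(dec.A_S, dec.D_S) @ X_S @ W_S)
    out_P = _htanh(normalize_adjacency(dec.A_P, dec.D_P) @ X_P @ W_P)
    return np.vstack([out_S, out_P])


def inter_message_passing(
    X_S: np.ndarray,
    X_P: np.ndarray,
    dec: EdgeDecomposition,
    W_inter: np.ndarray,
) -> np.ndarray:
    """Heterogeneous-scale convolution over the bipartite block matrix.

    Substrate rows aggregate only product rows and vice versa; if one side
    is empty the other side receives zero messages.
    """
    X = np.vstack([X_S, X_P])
    if X.shape[1] != W_inter.shape[0]:
        raise DimensionError("feature width does not match W_inter")
    return _htanh(normalize_adjacency(dec.A, dec.D) @ X @ W_inter)


def fuse_attention(
    X_init_e: np.ndarray,
    X_intra: np.ndarray,
    X_inter: np.ndarray,
    weights: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """Softmax-attention fusion of the three per-vertex feature views.

    Each view contributes one scalar attention score: a learned linear
    functional (``weights['attn_a']`` row, plus ``weights['attn_b']``) of
    the view's mean vertex row; the initial embeddings pass through a
    linear pre-map first.  Returns (fused table, betas).
    """
    L_init = X_init_e @ weights["W_attn_pre"] + weights["b_attn_pre"]
    tables = [L_init, X_intra, X_inter]
    if not all(t.shape == L_init.shape for t in tables):
        raise DimensionError("fusion inputs must share one shape")
    scores = anp.array(
        [t.mean(axis=0) @ weights["attn_a"][i] + weights["attn_b"][i] for i, t in enumerate(tables)]
    )
    betas = _softmax_1d(scores)
    X = betas[0] * L_init + betas[1] * X_intra + betas[2] * X_inter
    return X, betas


def _mm_last(X3, W):
    """(B, P, d) @ (d, h) via a flat 2-D matmul.

    Keeps the autograd adjoint of the weight a plain gemm; the broadcast
    batched form would materialise a (B, d, h) adjoint tensor.
    """
    B, P, d = X3.shape
    return anp.reshape(anp.reshape(X3, (B * P, d)) @ W, (B, P, W.shape[1]))


def _softmax_1d(s):
    z = anp.exp(s - anp.max(s))
    return z / anp.sum(z)


def pool_norm(X: np.ndarray) -> np.ndarray:
    """Elementwise root-mean-square over the vertex rows of an edge."""
    X = anp.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ContractError("pooling requires at least one vertex row")
    return anp.sqrt(anp.mean(X**2, axis=0) + _POOL_EPS)


def pool_maxmin(X: np.ndarray) -> np.ndarray:
    """Elementwise max minus min over the vertex rows of an edge."""
    X = anp.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ContractError("pooling requires at least one vertex row")
    return anp.max(X, axis=0) - anp.min(X, axis=0)


def mlp_forward(z, params: dict, dropout_mask=None, return_logit: bool = False):
    """Two-layer perceptron on pooled features; sigmoid output.

    ``dropout_mask`` (already scaled by 1/(1-p)) is applied to the hidden
    activations during training; ``None`` means evaluation mode.  With
    ``return_logit`` the pre-sigmoid value is returned (the ranking loss
    is computed on that scale — see the training module).
    """
    # leaky rectifier: the grouped ranking loss pushes all logits down
    # early in training, and a hard ReLU layer can die wholesale
    a = z @ params["W_mlp1"] + params["b_mlp1"]
    h = anp.maximum(a, 0.0) + 0.01 * anp.minimum(a, 0.0)
    if dropout_mask is not None:
        h = h * dropout_mask
    logit = h @ params["W_mlp2"] + params["b_mlp2"]
    logit = anp.squeeze(logit, axis=-1) if logit.ndim > 1 else logit[0]
    return logit if return_logit else _sigmoid(logit)


def _sigmoid(x):
    return anp.exp(-anp.logaddexp(0.0, -x))  # overflow-safe, stable gradient


def score_hyperedge(y_norm: np.ndarray, y_maxmin: np.ndarray, params: dict) -> float:
    """Score one edge from its pooled features; deterministic (dropout off)."""
    if y_norm.shape != y_maxmin.shape:
        raise DimensionError("pooled vectors must share one width")
    z = anp.concatenate([y_norm, y_maxmin])
    return float(np.asarray(mlp_forward(z[None, :], params)).reshape(-1)[0])


# ---------------------------------------------------------------------------
# parameters


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(rng: np.random.Generator, m_features: int, cfg: ModelConfig) -> dict:
    """Glorot-uniform parameter tables for features, convolutions and MLP.

    ``m_features`` is the number of reaction columns of the stoichiometric
    matrix the initial embeddings are built from.
    """
    d, h = cfg.embed_dim, cfg.mlp_hidden
    params = {
        # the characteristic-matrix maps start at zero: X_init begins as
        # the stoichiometry view and the role views train in, instead of
        # adding random-projection noise at initialisation
        "W_H": _glorot(rng, m_features, d),
        "b_H": np.zeros(d),
        "W_HS": np.zeros((m_features, d)),
        "b_HS": np.zeros(d),
        "W_HP": np.zeros((m_features, d)),
        "b_HP": np.zeros(d),
        # identity-initialised propagation (LightGCN-style parameter-free
        # start): the convolution views begin as meaningful smoothed
        # embeddings instead of random projections and train from there
        "W_S": np.eye(d),
        "W_P": np.eye(d),
        "W_inter": np.eye(d),
        "W_homo": np.eye(d),
        # residual-style identity init: the fused features start as the
        # (informative) initial embeddings while the convolution views
        # train in, which markedly speeds early learning
        "W_attn_pre": np.eye(d),
        "b_attn_pre": np.zeros(d),
        "attn_a": _glorot(rng, 3, d),
        "attn_b": np.zeros(3),
        "W_mlp1": _glorot(rng, 2 * d, h),
        "b_mlp1": np.zeros(h),
        "W_mlp2": _glorot(rng, h, 1),
        "b_mlp2": np.zeros(1),
    }
    return params


# ---------------------------------------------------------------------------
# batched execution


@dataclass
class EdgeBatch:
    """Edges padded to a common vertex count with role masks.

    Padded slots are excluded from adjacency aggregation, attention means,
    pooling and the loss, so batched scores equal unbatched scores.
    """

    verts: np.ndarray  # (B, P) int, padded with 0
    mask_S: np.ndarray  # (B, P) float
    mask_P: np.ndarray  # (B, P)
    ks: np.ndarray  # (B,)
    ls: np.ndarray  # (B,)

    @property
    def batch_size(self) -> int:
        return self.verts.shape[0]

    @property
    def valid(self) -> np.ndarray:
        return self.mask_S + self.mask_P


def build_batch(edges: list[Hyperedge]) -> EdgeBatch:
    if not edges:
        raise ContractError("cannot build an empty batch")
    P = max(e.size for e in edges)
    B = len(edges)
    verts = np.zeros((B, P), dtype=int)
    mask_S = np.zeros((B, P))
    mask_P = np.zeros((B, P))
    for i, e in enumerate(edges):
        verts[i, : e.size] = e.vertices
        mask_S[i, : e.k] = 1.0
        mask_P[i, e.k : e.size] = 1.0
    return EdgeBatch(
        verts=verts,
        mask_S=mask_S,
        mask_P=mask_P,
        ks=mask_S.sum(axis=1),
        ls=mask_P.sum(axis=1),
    )


def forward_scores(
    params: dict,
    X_init: anp.ndarray,
    batch: EdgeBatch,
    cfg: ModelConfig,
    dropout_mask: np.ndarray | None = None,
    return_logit: bool = False,
) -> anp.ndarray:
    """Score a batch of edges; autograd-differentiable.

    Aggregation uses the complete-graph closed forms: within a role of size
    k each vertex receives the mean of the other k-1 rows ((rowsum - x) /
    (k-1), zero when k <= 1); across roles each substrate receives
    sum(products)/sqrt(k*l) and symmetrically (degrees are l and k).
    """
    mS = batch.mask_S[:, :, None]
    mP = batch.mask_P[:, :, None]
    valid = mS + mP
    ks = batch.ks[:, None, None]
    ls = batch.ls[:, None, None]

    X = X_init[batch.verts] * valid  # (B, P, d)
    Xs = X * mS
    Xp = X * mP
    sum_S = anp.sum(Xs, axis=1, keepdims=True)
    sum_P = anp.sum(Xp, axis=1, keepdims=True)

    # mask/degree coefficients are data-independent: fold them into single
    # (B, P, 1) factors outside the autograd graph.  Padded and single-
    # member rows aggregate to zero, so no re-masking is needed after the
    # convolution (Htanh(0) = 0 and the maps are bias-free).
    if cfg.ablation.no_hetero:
        # plain single-layer GCN feature extractor: the pooled features
        # are the convolution output alone (no fusion views)
        tot = ks + ls
        coef = (tot > 1.0) * valid / np.maximum(tot - 1.0, 1.0)
        agg = coef * (sum_S + sum_P - X)
        X_fused = _htanh(_mm_last(agg, params["W_homo"]))
    else:
        coef_S = (ks > 1.0) * mS / np.maximum(ks - 1.0, 1.0)
        coef_P = (ls > 1.0) * mP / np.maximum(ls - 1.0, 1.0)
        agg_S = coef_S * (sum_S - Xs)
        agg_P = coef_P * (sum_P - Xp)
        X_intra = _htanh(_mm_last(agg_S, params["W_S"]) + _mm_last(agg_P, params["W_P"]))
        inv_kl = np.where(ks * ls > 0, 1.0 / np.sqrt(np.maximum(ks * ls, 1.0)), 0.0)
        agg_inter = (inv_kl * mS) * sum_P + (inv_kl * mP) * sum_S
        X_inter = _htanh(_mm_last(agg_inter, params["W_inter"]))
        X_fused = _fuse_batched(params, (X, X_intra, X_inter), valid, cfg)

    sizes = (batch.ks + batch.ls)[:, None]
    y_norm = anp.sqrt(anp.sum(X_fused**2 * valid, axis=1) / sizes + _POOL_EPS)
    big = (1.0 - valid) * _MASK_BIG
    y_maxmin = anp.max(X_fused - big, axis=1) - anp.min(X_fused + big, axis=1)
    z = anp.concatenate([y_norm, y_maxmin], axis=1)
    return mlp_forward(z, params, dropout_mask=dropout_mask, return_logit=return_logit)


def _fuse_batched(params, tables, valid, cfg: ModelConfig):
    X_raw, X_a, X_b = tables
    L_init = (_mm_last(X_raw, params["W_attn_pre"]) + params["b_attn_pre"]) * valid
    views = [L_init, X_a, X_b]
    if cfg.ablation.no_attention:
        return sum(views)
    sizes = anp.sum(valid, axis=1)  # (B, 1)
    means = [anp.sum(v, axis=1) / sizes for v in views]  # each (B, d)
    scores = anp.stack(
        [m @ params["attn_a"][i] + params["attn_b"][i] for i, m in enumerate(means)],
        axis=1,
    )  # (B, n_views)
    z = anp.exp(scores - anp.max(scores, axis=1, keepdims=True))
    betas = z / anp.sum(z, axis=1, keepdims=True)
    fused = 0.0
    for i, v in enumerate(views):
        fused = fused + betas[:, i][:, None, None] * v
    return fused


def score_edge_reference(
    params: dict, X_init: np.ndarray, edge: Hyperedge, cfg: ModelConfig
) -> float:
    """Unbatched reference scorer built from the per-edge operations.

    Used to validate the batched path; semantics identical by construction.
    """
    X_e = X_init[list(edge.vertices)]
    if cfg.ablation.no_hetero:
        A = np.ones((edge.size, edge.size)) - np.eye(edge.size)
        X = _htanh(normalize_adjacency(A) @ X_e @ params["W_homo"])
    else:
        dec = decompose_hyperedge(edge)
        X_S, X_P = X_e[: edge.k], X_e[edge.k :]
        X_intra = intra_message_passing(X_S, X_P, dec, params["W_S"], params["W_P"])
        X_inter = inter_message_passing(X_S, X_P, dec, params["W_inter"])
        if cfg.ablation.no_attention:
            X = (
                X_e @ params["W_attn_pre"]
                + params["b_attn_pre"]
                + X_intra
                + X_inter
            )
        else:
            X, _ = fuse_attention(
                X_e,
                X_intra,
                X_inter,
                {
                    "W_attn_pre": params["W_attn_pre"],
                    "b_attn_pre": params["b_attn_pre"],
                    "attn_a": params["attn_a"],
                    "attn_b": params["attn_b"],
                },
            )
    return score_hyperedge(pool_norm(X), pool_maxmin(X), params)


def score_edges(
    params: dict,
    X_init: np.ndarray,
    edges: list[Hyperedge] | EdgeBatch,
    cfg: ModelConfig,
) -> np.ndarray:
    """Deterministically score edges in evaluation mode (dropout off)."""
    batch = edges if isinstance(edges, EdgeBatch) else build_batch(list(edges))
    return np.asarray(forward_scores(params, X_init, batch, cfg))


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str | Path, params: dict, cfg: ModelConfig, seed: int) -> Path:
    """Self-describing checkpoint: parameter arrays + config JSON + seed."""
    path = Path(path)
    meta = {
        "config": {
            "embed_dim": cfg.embed_dim,
            "mlp_hidden": cfg.mlp_hidden,
            "dropout": cfg.dropout,
            "use_bias": cfg.use_bias,
            "zeros_as_substrates": cfg.zeros_as_substrates,
            "ablation": {
                "no_hetero": cfg.ablation.no_hetero,
                "no_feat_init": cfg.ablation.no_feat_init,
                "no_attention": cfg.ablation.no_attention,
            },
        },
        "seed": seed,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **params)
    return path


def load_checkpoint(path: str | Path) -> tuple[dict, ModelConfig, int]:
    with np.load(Path(path) if str(path).endswith(".npz") else f"{path}") as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    c = meta["config"]
    cfg = ModelConfig(
        embed_dim=c["embed_dim"],
        mlp_hidden=c["mlp_hidden"],
        dropout=c["dropout"],
        use_bias=c["use_bias"],
        zeros_as_substrates=c["zeros_as_substrates"],
        ablation=AblationFlags(**c["ablation"]),
    )
    return params, cfg, meta["seed"]
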