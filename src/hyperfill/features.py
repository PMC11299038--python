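"""Initial vertex embeddings from the signed stoichiometric matrix.

The signed matrix H is split into a substrate characteristic matrix HS
(1 where h_ij <= 0) and a product characteristic matrix HP (1 where
h_ij > 0); the two cases are exhaustive, so HS + HP is the all-ones
matrix.  Each of H, HS, HP passes through its own single-layer linear map
to ``embed_dim`` (default 256) columns, and the three embedded matrices
are summed into the initial per-vertex embedding table X_init.

The literal "h_ij <= 0 means substrate" rule also flags every metabolite
that does not participate in a reaction (h_ij = 0).  The
:func:`split_characteristics` primitive implements that rule verbatim by
default (``strict=True``); the model pipeline defaults to the
participation variant h_ij < 0 (``ModelConfig.zeros_as_substrates=False``),
under which non-participants contribute nothing and metabolites absent
from every reaction receive bias-only embeddings.  See the methods note
for why the literal rule destabilises training at scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
import scipy.sparse as sp

from .errors import DimensionError
from .model import ModelConfig


@dataclass
class CharacteristicMatrices:
    """H with its binary substrate/product views (dense float arrays)."""

    H: np.ndarray
    HS: np.ndarray
    HP: np.ndarray


def split_characteristics(H, strict: bool = True) -> CharacteristicMatrices:
    """Split signed H into substrate and product characteristic matrices.

    ``strict=True`` applies the literal case rule hs_ij = 1 iff h_ij <= 0
    (so HS + HP is all ones); ``strict=False`` uses h_ij < 0.
    """
    H = np.asarray(H.todense() if sp.issparse(H) else H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise DimensionError("H must be finite")
    HS = (H <= 0).astype(float) if strict else (H < 0).astype(float)
    HP = (H > 0).astype(float)
    return CharacteristicMatrices(H=H, HS=HS, HP=HP)


@dataclass
class InitEmbedding:
    """The three embedded matrices and their sum X_init (each n x d)."""

    X_H: np.ndarray
    X_HS: np.ndarray
    X_HP: np.ndarray
    X_init: np.ndarray


def compute_X_init(params: dict, cm: CharacteristicMatrices, cfg: ModelConfig):
    """X_init = linear(H) + linear(HS) + linear(HP); autograd-compatible.

    Under the ``no_feat_init`` ablation only the stoichiometry map
    linear(H) is kept.  Biases are dropped when ``cfg.use_bias`` is false.
    """
    if params["W_H"].shape[0] != cm.H.shape[1]:
        raise DimensionError(
            f"weight rows {params['W_H'].shape[0]} != reaction columns {cm.H.shape[1]}"
        )
    X_H = anp.dot(cm.H, params["W_H"])
    if cfg.use_bias:
        X_H = X_H + params["b_H"]
    if cfg.ablation.no_feat_init:
        return X_H
    X_HS = anp.dot(cm.HS, params["W_HS"])
    X_HP = anp.dot(cm.HP, params["W_HP"])
    if cfg.use_bias:
        X_HS = X_HS + params["b_HS"]
        X_HP = X_HP + params["b_HP"]
    return X_H + X_HS + X_HP


def init_embeddings(cm: CharacteristicMatrices, params: dict, cfg: ModelConfig | None = None) -> InitEmbedding:
    """Materialise the three embedded matrices and their sum."""
    cfg = cfg or ModelConfig()
    if params["W_H"].shape[0] != cm.H.shape[1]:
        raise DimensionError("weight shape does not match H")
    bH = params["b_H"] if cfg.use_bias else 0.0
    bS = params["b_HS"] if cfg.use_bias else 0.0
    bP = params["b_HP"] if cfg.use_bias else 0.0
    X_H = cm.H @ params["W_H"] + bH
    X_HS = cm.HS @ params["W_HS"] + bS
    X_HP = cm.HP @ params["W_HP"] + bP
    return InitEmbedding(X_H=X_H, X_HS=X_HS, X_HP=X_HP, X_init=X_H + X_HS + X_HP)
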