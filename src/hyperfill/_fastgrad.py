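"""Hand-fused forward/backward pass for the training loop.

The autograd route (``model.forward_scores`` + ``autograd.value_and_grad``)
is the reference semantics, but its per-primitive tracing overhead
dominates on minibatch-sized tensors.  This module computes the identical
minibatch loss and parameter gradients with plain numpy, reusing
intermediates.  Equality with the autograd route (to float tolerance, all
ablation combinations) is asserted in the test suite; the maths here is a
line-for-line transcription of the forward pass in ``model.py``.
"""

from __future__ import annotations

import numpy as np

from .features import CharacteristicMatrices
from .model import EdgeBatch, ModelConfig, _MASK_BIG, _POOL_EPS


def _mm(X3: np.ndarray, W: np.ndarray) -> np.ndarray:
    B, P, d = X3.shape
    return (X3.reshape(B * P, d) @ W).reshape(B, P, W.shape[1])


def _mm_T(X3: np.ndarray, G3: np.ndarray) -> np.ndarray:
    """Weight adjoint of _mm: X^T @ G over flattened rows."""
    B, P, d = X3.shape
    return X3.reshape(B * P, d).T @ G3.reshape(B * P, -1)


def loss_and_grad(
    params: dict,
    cm: CharacteristicMatrices,
    cfg: ModelConfig,
    batch: EdgeBatch,
    n_pos: int,
    npp: int,
    dropout_mask: np.ndarray | None,
    score_space: bool = False,
) -> tuple[float, dict]:
    """Minibatch ranking loss and gradients for all params.

    ``score_space=True`` computes the softplus margin on sigmoid scores
    (the published form); the default uses pre-sigmoid logits.
    """
    mS = batch.mask_S[:, :, None]
    mP = batch.mask_P[:, :, None]
    valid = mS + mP
    ks = batch.ks[:, None, None]
    ls = batch.ls[:, None, None]
    sizes2 = (batch.ks + batch.ls)[:, None]  # (B, 1)
    V = batch.verts
    B, P = V.shape
    use_bias = cfg.use_bias
    no_feat = cfg.ablation.no_feat_init
    no_het = cfg.ablation.no_hetero
    no_att = cfg.ablation.no_attention

    # ---- forward -----------------------------------------------------
    Xi = cm.H @ params["W_H"]
    if use_bias:
        Xi = Xi + params["b_H"]
    if not no_feat:
        Xi = Xi + cm.HS @ params["W_HS"] + cm.HP @ params["W_HP"]
        if use_bias:
            Xi = Xi + params["b_HS"] + params["b_HP"]

    X = Xi[V] * valid
    Xs = X * mS
    Xp = X * mP
    sS = Xs.sum(axis=1, keepdims=True)
    sP = Xp.sum(axis=1, keepdims=True)

    if no_het:
        tot = ks + ls
        coefH = (tot > 1.0) * valid / np.maximum(tot - 1.0, 1.0)
        aH = coefH * (sS + sP - X)
        U1 = _mm(aH, params["W_homo"])
        views = None
        F = np.clip(U1, -1.0, 1.0)
        L = betas = mus = None
        U2 = aI = None
    else:
        coefS = (ks > 1.0) * mS / np.maximum(ks - 1.0, 1.0)
        coefP = (ls > 1.0) * mP / np.maximum(ls - 1.0, 1.0)
        aS = coefS * (sS - Xs)
        aP = coefP * (sP - Xp)
        U1 = _mm(aS, params["W_S"]) + _mm(aP, params["W_P"])
        inv_kl = np.where(ks * ls > 0, 1.0 / np.sqrt(np.maximum(ks * ls, 1.0)), 0.0)
        cIS = inv_kl * mS
        cIP = inv_kl * mP
        aI = cIS * sP + cIP * sS
        U2 = _mm(aI, params["W_inter"])
        views = [None, np.clip(U1, -1.0, 1.0), np.clip(U2, -1.0, 1.0)]
        L = (_mm(X, params["W_attn_pre"]) + params["b_attn_pre"]) * valid
        views[0] = L
        if no_att:
            betas = mus = None
            F = views[0] + views[1] + views[2]
        else:
            mus = [t.sum(axis=1) / sizes2 for t in views]  # (B, d)
            s = np.stack(
                [mu @ params["attn_a"][i] + params["attn_b"][i] for i, mu in enumerate(mus)],
                axis=1,
            )
            z_ = np.exp(s - s.max(axis=1, keepdims=True))
            betas = z_ / z_.sum(axis=1, keepdims=True)  # (B, 3)
            F = betas[:, 0][:, None, None] * views[0]
            for i in (1, 2):
                F += betas[:, i][:, None, None] * views[i]

    q = (F**2 * valid).sum(axis=1) / sizes2  # (B, d)
    ynorm = np.sqrt(q + _POOL_EPS)
    big = (1.0 - valid) * _MASK_BIG
    Fhi = F - big
    Flo = F + big
    ymax = Fhi.max(axis=1)  # (B, d)
    ymin = Flo.min(axis=1)
    ymm = ymax - ymin
    z = np.concatenate([ynorm, ymm], axis=1)  # (B, 2d)
    a1 = z @ params["W_mlp1"] + params["b_mlp1"]
    h = np.maximum(a1, 0.0) + 0.01 * np.minimum(a1, 0.0)
    hd = h * dropout_mask if dropout_mask is not None else h
    logit = (hd @ params["W_mlp2"] + params["b_mlp2"])[:, 0]

    if score_space:
        S = np.exp(-np.logaddexp(0.0, -logit))  # sigmoid
    else:
        S = logit
    S_pos = S[:n_pos]
    S_neg = S[n_pos:].reshape(n_pos, npp)
    marg = S_neg.mean(axis=1) - S_pos
    loss = float(np.mean(np.logaddexp(0.0, marg)))

    # ---- backward ----------------------------------------------------
    dmarg = np.exp(-np.logaddexp(0.0, -marg)) / n_pos  # sigmoid(marg)/n
    dlogit = np.empty(B)
    dlogit[:n_pos] = -dmarg
    dlogit[n_pos:] = np.repeat(dmarg / npp, npp)
    if score_space:
        dlogit *= S * (1.0 - S)

    grads = {k: None for k in params}
    grads["b_mlp2"] = np.array([dlogit.sum()])
    grads["W_mlp2"] = hd.T @ dlogit[:, None]
    dhd = dlogit[:, None] * params["W_mlp2"].T  # (B, h)
    dh = dhd * dropout_mask if dropout_mask is not None else dhd
    da1 = dh * np.where(a1 > 0, 1.0, 0.01)
    grads["W_mlp1"] = z.T @ da1
    grads["b_mlp1"] = da1.sum(axis=0)
    dz = da1 @ params["W_mlp1"].T
    d = ynorm.shape[1]
    dynorm = dz[:, :d]
    dymm = dz[:, d:]

    # ties share the max/min gradient evenly (matches autograd and the
    # symmetric finite difference; exact ties do occur, e.g. 1-1 edges
    # whose two fused rows coincide under identity-initialised maps)
    max_mask = Fhi == ymax[:, None, :]
    min_mask = Flo == ymin[:, None, :]
    dF = max_mask * (dymm / max_mask.sum(axis=1))[:, None, :]
    dF -= min_mask * (dymm / min_mask.sum(axis=1))[:, None, :]
    dq = dynorm * (0.5 / ynorm)  # (B, d)
    dF += (2.0 * F * valid) * (dq / sizes2)[:, None, :]

    dsS = np.zeros((B, 1, d))
    dsP = np.zeros((B, 1, d))
    if no_het:
        dU1 = dF * (np.abs(U1) < 1.0)
        grads["W_homo"] = _mm_T(aH, dU1)
        daH = _mm(dU1, params["W_homo"].T)
        t1 = coefH * daH
        dcommon = t1.sum(axis=1, keepdims=True)
        dsS += dcommon
        dsP += dcommon
        dX = -t1
        dXs = np.broadcast_to(dsS, X.shape) * 1.0
        dXp = np.broadcast_to(dsP, X.shape) * 1.0
    else:
        dviews = [None, None, None]
        if no_att:
            for i in range(3):
                dviews[i] = dF.copy()
        else:
            dbeta = np.stack([(dF * views[i]).sum(axis=(1, 2)) for i in range(3)], axis=1)
            ds = betas * (dbeta - (betas * dbeta).sum(axis=1, keepdims=True))  # (B, 3)
            grads["attn_a"] = np.zeros_like(params["attn_a"])
            grads["attn_b"] = np.zeros_like(params["attn_b"])
            for i in range(3):
                dviews[i] = betas[:, i][:, None, None] * dF
                dmu = ds[:, i][:, None] * params["attn_a"][i][None, :]  # (B, d)
                grads["attn_a"][i] = (mus[i] * ds[:, i][:, None]).sum(axis=0)
                grads["attn_b"][i] = ds[:, i].sum()
                dviews[i] += (dmu / sizes2)[:, None, :]

        dL = dviews[0] * valid
        grads["W_attn_pre"] = _mm_T(X, dL)
        grads["b_attn_pre"] = dL.sum(axis=(0, 1))
        dX = _mm(dL, params["W_attn_pre"].T)

        dU1 = dviews[1] * (np.abs(U1) < 1.0)
        grads["W_S"] = _mm_T(aS, dU1)
        grads["W_P"] = _mm_T(aP, dU1)
        daS = _mm(dU1, params["W_S"].T)
        daP = _mm(dU1, params["W_P"].T)
        dU2 = dviews[2] * (np.abs(U2) < 1.0)
        grads["W_inter"] = _mm_T(aI, dU2)
        daI = _mm(dU2, params["W_inter"].T)
        tS = coefS * daS
        tP = coefP * daP
        dsS += tS.sum(axis=1, keepdims=True) + (cIP * daI).sum(axis=1, keepdims=True)
        dsP += tP.sum(axis=1, keepdims=True) + (cIS * daI).sum(axis=1, keepdims=True)
        dXs = np.broadcast_to(dsS, X.shape) - tS
        dXp = np.broadcast_to(dsP, X.shape) - tP

    dX = dX + dXs * mS + dXp * mP
    dX *= valid

    dXi = np.zeros_like(Xi)
    np.add.at(dXi, V.ravel(), dX.reshape(B * P, -1))

    grads["W_H"] = cm.H.T @ dXi
    if use_bias:
        grads["b_H"] = dXi.sum(axis=0)
    if not no_feat:
        grads["W_HS"] = cm.HS.T @ dXi
        grads["W_HP"] = cm.HP.T @ dXi
        if use_bias:
            grads["b_HS"] = dXi.sum(axis=0)
            grads["b_HP"] = dXi.sum(axis=0)

    for k in params:
        if grads[k] is None:
            grads[k] = np.zeros_like(params[k])
    return loss, grads
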