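"""Training loop: two-stage negative sampling, ranking loss, Adam.

Positives are the draft model's reaction hyperedges.  Each epoch every
positive receives a fresh group of negative hyperedges built by swapping
vertices for uniform non-members (role-preserving).  The curriculum has
two stages: early epochs swap about half of each edge's vertices (easy,
structurally distant negatives); from ``stage2_start_epoch`` onwards a
single vertex is swapped, producing near-miss negatives that force the
model to learn fine structure.  The loss averages, over positives, the
softplus of (mean negative-group score minus positive score), and is
minimised with Adam under a global gradient-norm clip.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import autograd.numpy as anp
import numpy as np
from ._fastgrad import loss_and_grad
from .errors import ConfigError, ContractError, TrainingError
from .features import CharacteristicMatrices, compute_X_init, split_characteristics
from .gem_io import UniverseIndex
from .model import (
    AblationFlags,
    Hyperedge,
    ModelConfig,
    build_batch,
    forward_scores,
    init_params,
)
from .synth import perturb_edge

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters; the published defaults are lr=0.01, 35 epochs,
    dropout 0.2 and a 2-layer MLP."""

    lr: float = 0.01
    epochs: int = 35
    dropout: float = 0.2
    mlp_layers: int = 2
    negatives_per_positive: int = 20
    stage2_start_epoch: int = 18
    seed: int = 0
    embed_dim: int = 256
    mlp_hidden: int = 128
    zeros_as_substrates: bool = False
    use_bias: bool = True
    val_fraction: float = 0.1
    clip_norm: float = 5.0
    loss_on: str = "logit"  # "logit" (stable) or "score" (published form)
    val_negatives_per_positive: int = 5
    lr_decay: str = "cosine"  # "cosine" or "none" (lr is the initial rate)
    calibrate: bool = True  # Platt-fit scores on the validation split
    ablation: AblationFlags = field(default_factory=AblationFlags)

    batch_positives: int = 16

    def __post_init__(self) -> None:
        if self.mlp_layers != 2:
            raise ConfigError("only the published 2-layer MLP head is supported")
        if self.negatives_per_positive < 1:
            raise ConfigError("need at least one negative per positive")
        if self.batch_positives < 1:
            raise ConfigError("batch_positives must be positive")

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            embed_dim=self.embed_dim,
            mlp_hidden=self.mlp_hidden,
            dropout=self.dropout,
            use_bias=self.use_bias,
            zeros_as_substrates=self.zeros_as_substrates,
            ablation=self.ablation,
        )


@dataclass
class TrainHistory:
    losses: list[float]
    val_auroc: list[float]
    val_aupr: list[float]
    best_epoch: int
    seeds: dict


@dataclass
class TrainedModel:
    """Best-epoch parameters plus everything needed to score new edges."""

    params: dict
    params_final: dict
    cfg: ModelConfig
    cm: CharacteristicMatrices
    history: TrainHistory
    seed: int

    def x_init(self) -> np.ndarray:
        return np.asarray(compute_X_init(self.params, self.cm, self.cfg))

    def score(self, edges: list[Hyperedge], chunk_size: int = 2048) -> np.ndarray:
        """Deterministic evaluation-mode scores in (0, 1)."""
        edges = list(edges)
        X_init = self.x_init()
        out = []
        for lo in range(0, len(edges), chunk_size):
            out.append(
                np.asarray(forward_scores(self.params, X_init, build_batch(edges[lo : lo + chunk_size]), self.cfg))
            )
        return np.concatenate(out)


def stage_n_swap(edge: Hyperedge, epoch: int, config: TrainConfig) -> int:
    if epoch < config.stage2_start_epoch:
        return max(1, math.ceil(edge.size / 2))
    return 1


def sample_negatives(
    E: list[Hyperedge],
    universe: UniverseIndex,
    config: TrainConfig,
    epoch: int,
) -> list[list[Hyperedge]]:
    """One group of ``negatives_per_positive`` negatives per positive edge.

    Stage 1 (epoch < stage2_start_epoch) swaps ceil(|e|/2) vertices per
    negative; stage 2 swaps one.  Negatives never coincide with a positive.
    Fully determined by (config.seed, epoch).
    """
    rng = np.random.default_rng([config.seed, epoch])
    pos_keys = {e.key() for e in E}
    n_vertices = universe.n_vertices
    groups = []
    for e in E:
        n_swap = stage_n_swap(e, epoch, config)
        groups.append(
            [perturb_edge(e, n_vertices, pos_keys, n_swap, rng) for _ in range(config.negatives_per_positive)]
        )
    return groups


def compute_loss(S_pos, S_neg_groups):
    """Grouped ranking loss: mean over positives of softplus(mean(F) - S+).

    ``S_neg_groups`` is an (n_pos, group_size) array or a list of per-
    positive score arrays; every group must be nonempty.  Computed
    overflow-safely via logaddexp.
    """
    S_pos = anp.asarray(S_pos, dtype=float) if not hasattr(S_pos, "_value") else S_pos
    if isinstance(S_neg_groups, (list, tuple)):
        if any(len(g) == 0 for g in S_neg_groups):
            raise ContractError("every positive needs a nonempty negative group")
        means = anp.array([anp.mean(anp.asarray(g, dtype=float)) for g in S_neg_groups])
    else:
        if S_neg_groups.shape[-1] == 0:
            raise ContractError("every positive needs a nonempty negative group")
        means = anp.mean(S_neg_groups, axis=-1)
    return anp.mean(anp.logaddexp(0.0, means - S_pos))


def _grad_norm(grads: dict) -> float:
    return math.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))


class Adam:
    """Plain Adam over a dict of parameter arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m.get(k, 0.0) + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v.get(k, 0.0) + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            out[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def _platt_calibrate(params: dict, cm, cfg, val_pos, val_neg) -> dict:
    """Fold a logistic calibration of the output logit into the MLP head.

    The grouped ranking loss constrains only score differences, so the
    absolute logit level can drift; a one-dimensional logistic fit on the
    validation split restores probability-like scores (threshold 0.5
    meaningful).  Folding slope and intercept into W_mlp2/b_mlp2 keeps
    every downstream consumer unchanged.  Skipped if the fitted slope is
    not positive (an inverted validation fit must not flip rankings).
    """
    from sklearn.linear_model import LogisticRegression

    X_init = compute_X_init(params, cm, cfg)
    logits = np.asarray(
        forward_scores(params, X_init, build_batch(val_pos + val_neg), cfg, return_logit=True)
    )
    y = np.array([1] * len(val_pos) + [0] * len(val_neg))
    # balanced weighting: the validation set has several negatives per
    # positive and an unweighted fit would bias all scores low
    fit = LogisticRegression(C=100.0, class_weight="balanced", solver="lbfgs").fit(
        logits[:, None], y
    )
    a = float(fit.coef_[0, 0])
    b = float(fit.intercept_[0])
    if a <= 0:
        logger.warning("calibration slope %.3f not positive; leaving scores raw", a)
        return params
    out = dict(params)
    out["W_mlp2"] = params["W_mlp2"] * a
    out["b_mlp2"] = params["b_mlp2"] * a + b
    return out


def _val_metrics(params, cm, cfg, val_pos, val_neg):
    from .evaluation import compute_metrics

    X_init = compute_X_init(params, cm, cfg)
    scores = np.asarray(forward_scores(params, X_init, build_batch(val_pos + val_neg), cfg))
    labels = np.array([1] * len(val_pos) + [0] * len(val_neg))
    rep = compute_metrics(scores, labels)
    return rep.auroc, rep.aupr


def train(
    universe: UniverseIndex,
    config: TrainConfig,
    train_edges: list[Hyperedge] | None = None,
    val_edges: list[Hyperedge] | None = None,
    feature_reactions: list[int] | None = None,
    init: dict | None = None,
) -> TrainedModel:
    """Train a scorer on a universe's draft hyperedges.

    ``train_edges``/``val_edges`` default to a seeded edge-wise split of
    the draft reactions (``val_fraction`` held out for best-checkpoint
    selection).  ``feature_reactions`` restricts the stoichiometric columns
    the initial embeddings see (used by the experiment harnesses to keep
    test reactions out of the features).  All randomness — initialisation,
    negative sampling, dropout, splits — derives from ``config.seed``.
    """
    cfg = config.model_config()
    positives = list(universe.draft_edges) if train_edges is None else list(train_edges)
    if len(positives) < 10:
        raise ContractError("training requires at least 10 positive edges")

    rng = np.random.default_rng([config.seed, 0xFEED])
    if val_edges is None and config.val_fraction > 0:
        order = rng.permutation(len(positives))
        n_val = max(1, int(round(config.val_fraction * len(positives))))
        val_edges = [positives[i] for i in order[:n_val]]
        positives = [positives[i] for i in order[n_val:]]
    val_edges = list(val_edges) if val_edges else []

    H = universe.universe_H()
    if feature_reactions is not None:
        H = H[:, feature_reactions]
    cm = split_characteristics(H, strict=cfg.zeros_as_substrates)
    params = init if init is not None else init_params(rng, cm.H.shape[1], cfg)

    val_neg = []
    if val_edges:
        known = universe.known_edge_keys()
        val_neg = [
            perturb_edge(e, universe.n_vertices, known, max(1, math.ceil(e.size / 2)), rng)
            for e in val_edges
            for _ in range(max(1, config.val_negatives_per_positive))
        ]

    n_pos = len(positives)
    npp = config.negatives_per_positive
    opt = Adam(config.lr)
    losses, val_auroc, val_aupr = [], [], []
    best = (-np.inf, 0, {k: v.copy() for k, v in params.items()})

    # one Adam update per minibatch of positives (plus their negative
    # groups); this also bounds the autograd graph — a whole-epoch batch
    # would hold every intermediate (B, P, d) tensor in memory at once
    bs = config.batch_positives

    for epoch in range(config.epochs):
        groups = sample_negatives(positives, universe, config, epoch)
        epoch_rng = np.random.default_rng([config.seed, 0xD0, epoch])
        keep = 1.0 - config.dropout
        order = epoch_rng.permutation(n_pos)

        loss_sum = 0.0
        for lo in range(0, n_pos, bs):
            idx = order[lo : lo + bs]
            nc = len(idx)
            batch = build_batch(
                [positives[i] for i in idx] + [n for i in idx for n in groups[i]]
            )
            mask = (
                (epoch_rng.random((batch.batch_size, cfg.mlp_hidden)) < keep).astype(float) / keep
                if config.dropout > 0
                else None
            )

            # the ranking loss runs on the pre-sigmoid scale: with scores
            # squashed to (0,1) the softplus margin saturates and
            # gradients vanish once all scores collect near an endpoint
            # (ranking is unchanged, sigmoid is monotone); the hand-fused
            # gradient path is asserted equal to the autograd route in
            # the test suite
            val, grads = loss_and_grad(
                params, cm, cfg, batch, nc, npp, mask,
                score_space=(config.loss_on == "score"),
            )
            if not np.isfinite(float(val)):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            gnorm = _grad_norm(grads)
            if config.clip_norm and gnorm > config.clip_norm:
                scale = config.clip_norm / gnorm
                grads = {k: g * scale for k, g in grads.items()}
            if config.lr_decay == "cosine":
                opt.lr = config.lr * 0.5 * (1.0 + math.cos(math.pi * epoch / config.epochs))
            params = opt.step(params, grads)
            loss_sum += float(val) * nc

        loss = loss_sum / n_pos
        losses.append(loss)

        if val_edges:
            auroc, aupr = _val_metrics(params, cm, cfg, val_edges, val_neg)
            val_auroc.append(auroc)
            val_aupr.append(aupr)
            # ties prefer the later epoch: with small validation sets the
            # AUROC plateaus while the margin keeps improving
            if auroc is not None and auroc >= best[0]:
                best = (auroc, epoch, {k: v.copy() for k, v in params.items()})
            logger.info("epoch=%d loss=%.4f val_auroc=%.3f val_aupr=%.3f", epoch, loss, auroc, aupr)
        else:
            logger.info("epoch=%d loss=%.4f", epoch, loss)

    if not val_edges:
        best = (np.nan, config.epochs - 1, params)
    best_params = best[2]
    if val_edges and config.calibrate:
        best_params = _platt_calibrate(best_params, cm, cfg, val_edges, val_neg)
    history = TrainHistory(
        losses=losses,
        val_auroc=val_auroc,
        val_aupr=val_aupr,
        best_epoch=best[1],
        seeds={"seed": config.seed},
    )
    return TrainedModel(
        params=best_params,
        params_final=params,
        cfg=cfg,
        cm=cm,
        history=history,
        seed=config.seed,
    )


def with_seed(config: TrainConfig, seed: int) -> TrainConfig:
    return replace(config, seed=seed)
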