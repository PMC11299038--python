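"""Metrics and the two experiment harnesses.

AUROC (probability a random positive outscores a random negative, ties
half credit) and AUPR (step-integrated precision-recall area) are the
primary metrics; recall, F1 and accuracy at a fixed threshold are
auxiliary.  ``internal_prediction_experiment`` measures how well the model
re-predicts known reactions under an edge-wise train/val/test split;
``recovery_experiment`` measures how many deliberately removed reactions
are recovered from a candidate pool at various k, with and without the
two-round similarity filter.  Experiments repeat with distinct seeds and
report the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    recall_score,
    roc_auc_score,
)

from .errors import ContractError, ExperimentError
from .gem_io import UniverseIndex
from .synth import SynthOutput, perturb_edge
from .training import TrainConfig, train

DEFAULT_SPLIT = (0.6, 0.2, 0.2)


@dataclass
class MetricsReport:
    """Primary (AUROC, AUPR) and auxiliary (F1, ACC, RE) metrics.

    All metrics are ``None`` (``defined=False``) when either class is
    absent rather than raising.
    """

    auroc: float | None
    aupr: float | None
    f1: float | None
    acc: float | None
    re: float | None
    n_pos: int
    n_neg: int

    @property
    def defined(self) -> bool:
        return self.auroc is not None


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Score a binary classification at a threshold (default 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ContractError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return MetricsReport(None, None, None, None, None, n_pos, n_neg)
    preds = (scores > threshold).astype(int)
    return MetricsReport(
        auroc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
        f1=float(f1_score(labels, preds, zero_division=0)),
        acc=float(accuracy_score(labels, preds)),
        re=float(recall_score(labels, preds, zero_division=0)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


@dataclass
class ExperimentResult:
    reports: list[MetricsReport]
    mean: dict
    value_range: dict
    seeds: list[int]


def _aggregate(reports: list[MetricsReport]) -> tuple[dict, dict]:
    mean, rng = {}, {}
    for name in ("auroc", "aupr", "f1", "acc", "re"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        mean[name] = float(np.mean(vals)) if vals else None
        rng[name] = (float(min(vals)), float(max(vals))) if vals else None
    return mean, rng


def internal_prediction_experiment(
    universe: UniverseIndex,
    config: TrainConfig,
    split_seed: int = 0,
    repeats: int = 5,
    split: tuple[float, float, float] = DEFAULT_SPLIT,
) -> ExperimentResult:
    """Re-predict known reactions under an edge-wise split.

    Per repeat: shuffle the draft hyperedges, split train/val/test
    (default 60/20/20), build features from the training columns only,
    train, and score the test positives against an equal number of
    perturbed negatives generated once per repeat.
    """
    edges = list(universe.draft_edges)
    if len(edges) < 50:
        raise ExperimentError("internal prediction needs at least 50 positive edges")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ExperimentError("split fractions must sum to 1")
    reports, seeds = [], []
    for rep in range(repeats):
        seed = split_seed + rep
        seeds.append(seed)
        rng = np.random.default_rng([seed, 0x5EED])
        order = rng.permutation(len(edges))
        n = len(edges)
        n_train = int(round(split[0] * n))
        n_val = int(round(split[1] * n))
        train_idx = order[:n_train]
        val_idx = order[n_train : n_train + n_val]
        test_idx = order[n_train + n_val :]
        train_e = [edges[i] for i in train_idx]
        val_e = [edges[i] for i in val_idx]
        test_e = [edges[i] for i in test_idx]

        trained = train(
            universe,
            replace(config, seed=seed),
            train_edges=train_e,
            val_edges=val_e,
            feature_reactions=[int(i) for i in train_idx],
        )
        known = universe.known_edge_keys()
        test_neg = [
            perturb_edge(e, universe.n_vertices, known, max(1, math.ceil(e.size / 2)), rng)
            for e in test_e
        ]
        scores = trained.score(test_e + test_neg)
        labels = np.array([1] * len(test_e) + [0] * len(test_neg))
        reports.append(compute_metrics(scores, labels))
    mean, value_range = _aggregate(reports)
    return ExperimentResult(reports=reports, mean=mean, value_range=value_range, seeds=seeds)


@dataclass
class RecoveryResult:
    ks: list[int]
    recovery_topk: dict
    recovery_filtered: dict
    n_holdout: int
    n_pool: int
    ranking: object  # the full candidate ranking frame


def recovery_experiment(
    output: SynthOutput,
    config: TrainConfig,
    ks: tuple[int, ...] = (50, 100, 150, 200),
    first_round: int = 300,
    score_threshold: float = 0.5,
) -> RecoveryResult:
    """Recover planted holdout reactions from a holdout+decoy pool.

    Trains on the training reactions, scores the pool, and reports the
    fraction of holdouts inside the top-k (pure score order) and inside
    the two-round-filtered selection at each k.
    """
    from .gapfill import GapFillConfig, score_pool, select_candidates, two_round_select

    if not output.holdout:
        raise ExperimentError("recovery requires a nonempty holdout set")
    universe = output.to_universe()
    if not universe.pool_edges:
        raise ExperimentError("recovery requires a nonempty pool")
    trained = train(universe, config)
    scores = score_pool(trained, universe)
    holdout_ids = {r.id for r in output.holdout}

    order = scores.rename_axis("id").reset_index()
    order = order.sort_values(["score", "id"], ascending=[False, True], kind="mergesort")
    ranked_ids = list(order["id"])
    n_hold = len(holdout_ids)
    recovery_topk = {
        k: len(set(ranked_ids[:k]) & holdout_ids) / n_hold for k in ks
    }

    # the similarity ordering of the first-round candidates is k-independent:
    # compute it once, then the two-round selection at k is its first k entries
    vidx = universe.vertex_index()
    fr = max(first_round, max(ks))
    cfg = GapFillConfig(
        score_threshold=score_threshold,
        k_top=fr,
        first_round=fr,
        similarity_metric="distance_correlation",
    )
    cands = select_candidates(scores, cfg)
    recovery_filtered = {}
    ranking = None
    if len(cands) == 0:
        recovery_filtered = {k: 0.0 for k in ks}
    else:
        df = two_round_select(cands, universe.draft.reactions, cfg, universe.pool_reactions, vidx)
        ranking = df
        ordered = df.reset_index().sort_values(
            ["similarity", "score", "id"], ascending=[True, False, True], kind="mergesort"
        )["id"]
        for k in ks:
            selected = set(ordered.head(k))
            recovery_filtered[k] = len(selected & holdout_ids) / n_hold
    return RecoveryResult(
        ks=list(ks),
        recovery_topk=recovery_topk,
        recovery_filtered=recovery_filtered,
        n_holdout=n_hold,
        n_pool=len(universe.pool_edges),
        ranking=ranking,
    )
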