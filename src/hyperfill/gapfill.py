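"""Candidate ranking and two-round similarity-filtered gap-filling.

A trained scorer assigns each pool reaction a probability-like score.
Candidates with scores above the threshold (default 0.5) are ranked and
the top ``first_round`` (default 300) kept; a second round computes each
candidate's similarity to the reactions already in the draft GEM and keeps
the ``k_top`` (default 200) *least similar* ones, so high-scoring
near-duplicates of existing reactions are not re-added.  Similarity is the
maximum, over known reactions, of either the distance correlation between
signed incidence vectors over the universe vertex set or the Jaccard
overlap of vertex sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, IntegrityError
from .gem_io import GemModel, ReactionRecord, UniverseIndex, _build_gem, MetaboliteRecord
from .training import TrainedModel

SIMILARITY_METRICS = ("distance_correlation", "jaccard")


@dataclass(frozen=True)
class GapFillConfig:
    score_threshold: float = 0.5
    k_top: int = 200
    first_round: int = 300
    similarity_metric: str = "distance_correlation"

    def __post_init__(self) -> None:
        if not (0.0 < self.score_threshold < 1.0):
            raise ConfigError("score_threshold must lie in (0, 1)")
        if self.first_round < self.k_top:
            raise ConfigError("first_round must be >= k_top")
        if self.similarity_metric not in SIMILARITY_METRICS:
            raise ConfigError(f"unknown similarity metric {self.similarity_metric!r}")


def score_pool(trained: TrainedModel, universe: UniverseIndex) -> pd.Series:
    """Deterministic evaluation-mode score per pool reaction (indexed by id)."""
    if not universe.pool_edges:
        raise ContractError("the reaction pool is empty")
    n = universe.n_vertices
    for e, r in zip(universe.pool_edges, universe.pool_reactions):
        if any(v < 0 or v >= n for v in e.vertices):
            raise IntegrityError(f"pool reaction {r.id!r} references an unknown vertex")
    scores = trained.score(universe.pool_edges)
    return pd.Series(scores, index=[r.id for r in universe.pool_reactions], name="score")


def select_candidates(scores: pd.Series, config: GapFillConfig) -> pd.Series:
    """First-round selection: scores above threshold, best first.

    Sorted by descending score with id-lexicographic tie-break, truncated
    at ``first_round``; may return fewer entries.
    """
    above = scores[scores > config.score_threshold]
    df = above.rename("score").rename_axis("id").reset_index()
    df = df.sort_values(["score", "id"], ascending=[False, True], kind="mergesort")
    df = df.head(config.first_round)
    return pd.Series(df["score"].values, index=df["id"].values, name="score")


# ---------------------------------------------------------------------------
# distance correlation on sparse signed incidence vectors


def _compressed_joint(xd: dict[int, float], yd: dict[int, float], n: int):
    """Joint value distribution of two sparse vectors of length n."""
    support = sorted(set(xd) | set(yd))
    pairs: dict[tuple[float, float], int] = {}
    for i in support:
        key = (xd.get(i, 0.0), yd.get(i, 0.0))
        pairs[key] = pairs.get(key, 0) + 1
    n_zero = n - len(support)
    if n_zero:
        pairs[(0.0, 0.0)] = pairs.get((0.0, 0.0), 0) + n_zero
    vals = np.array(list(pairs.keys()), dtype=float)  # (t, 2)
    w = np.array(list(pairs.values()), dtype=float) / n
    return vals[:, 0], vals[:, 1], w


def _weighted_dcov2(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    am = a @ w
    bm = b @ w
    ga = w @ am
    gb = w @ bm
    A = a - am[:, None] - am[None, :] + ga
    B = b - bm[:, None] - bm[None, :] + gb
    return float(w @ (A * B) @ w)


def distance_correlation_sparse(xd: dict[int, float], yd: dict[int, float], n: int) -> float:
    """Distance correlation of two length-n vectors given as sparse dicts.

    Exploits the tiny value support of incidence vectors: pairwise distance
    matrices are computed over the joint value categories with counts as
    weights, which is exact and O(t^2) for t distinct value pairs.
    """
    x, y, w = _compressed_joint(xd, yd, n)
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    vx = _weighted_dcov2(a, a, w)
    vy = _weighted_dcov2(b, b, w)
    if vx <= 0 or vy <= 0:
        return 0.0
    c2 = _weighted_dcov2(a, b, w) / np.sqrt(vx * vy)
    return float(np.sqrt(max(c2, 0.0)))


def _signed_incidence(r: ReactionRecord, vertex_index: dict[str, int]) -> dict[int, float]:
    out = {}
    for mid, c in r.stoichiometry.items():
        if mid in vertex_index:
            out[vertex_index[mid]] = -1.0 if c <= 0 else 1.0
    return out


def reaction_similarity(
    candidate: ReactionRecord,
    known: list[ReactionRecord],
    metric: str = "distance_correlation",
    vertex_index: dict[str, int] | None = None,
) -> float:
    """Maximum similarity of a candidate to any known reaction, in [0, 1].

    ``distance_correlation`` compares signed incidence vectors (+1 product,
    -1 substrate) over the universe vertex set; ``jaccard`` compares
    participant sets.  An exact copy of a known reaction scores 1.0.
    """
    if not known:
        raise ContractError("similarity requires a nonempty known-reaction list")
    if metric not in SIMILARITY_METRICS:
        raise ConfigError(f"unknown similarity metric {metric!r}")
    if vertex_index is None:
        ids = sorted({m for r in [candidate, *known] for m in r.stoichiometry})
        vertex_index = {mid: i for i, mid in enumerate(ids)}
    if metric == "jaccard":
        cset = set(candidate.stoichiometry)
        best = 0.0
        for r in known:
            rset = set(r.stoichiometry)
            inter = len(cset & rset)
            union = len(cset | rset)
            best = max(best, inter / union if union else 0.0)
        return best
    n = len(vertex_index)
    cvec = _signed_incidence(candidate, vertex_index)
    best = 0.0
    for r in known:
        best = max(best, distance_correlation_sparse(cvec, _signed_incidence(r, vertex_index), n))
    return best


def two_round_select(
    candidates: pd.Series,
    known: list[ReactionRecord],
    config: GapFillConfig,
    pool_reactions: list[ReactionRecord],
    vertex_index: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Second-round selection: keep the ``k_top`` least similar candidates.

    ``candidates`` is the first-round series (id -> score).  Similarities
    to the known reactions are computed per candidate; candidates sort
    ascending by similarity (ties: higher score first, then id) and the
    first ``k_top`` are marked selected.  Returns a frame with columns
    score, score_rank, similarity, selected for every candidate.
    """
    by_id = {r.id: r for r in pool_reactions}
    rows = []
    for rank, (rid, score) in enumerate(candidates.items(), start=1):
        if rid not in by_id:
            raise IntegrityError(f"candidate {rid!r} not present in the pool")
        sim = reaction_similarity(
            by_id[rid], known, metric=config.similarity_metric, vertex_index=vertex_index
        )
        rows.append((rid, float(score), rank, sim))
    df = pd.DataFrame(rows, columns=["id", "score", "score_rank", "similarity"]).set_index("id")
    order = df.reset_index().sort_values(
        ["similarity", "score", "id"], ascending=[True, False, True], kind="mergesort"
    )
    selected_ids = set(order["id"].head(config.k_top))
    df["selected"] = [rid in selected_ids for rid in df.index]
    return df


def rank_and_select(
    trained: TrainedModel, universe: UniverseIndex, config: GapFillConfig | None = None
) -> pd.DataFrame:
    """Full pipeline: score the pool, two-round select, return the ranking."""
    config = config or GapFillConfig()
    scores = score_pool(trained, universe)
    cands = select_candidates(scores, config)
    vidx = universe.vertex_index()
    if len(cands) == 0:
        return pd.DataFrame(columns=["score", "score_rank", "similarity", "selected"])
    return two_round_select(cands, universe.draft.reactions, config, universe.pool_reactions, vidx)


def fill_gaps(draft: GemModel, ranking: pd.DataFrame, pool: GemModel) -> GemModel:
    """Append the selected pool reactions (and any new metabolites) to the draft."""
    selected_ids = list(ranking.index[ranking["selected"]]) if len(ranking) else []
    by_id = {r.id: r for r in pool.reactions}
    draft_ids = {r.id for r in draft.reactions}
    added = []
    for rid in selected_ids:
        if rid in draft_ids:
            raise IntegrityError(f"reaction id {rid!r} already present in the draft")
        if rid not in by_id:
            raise IntegrityError(f"selected reaction {rid!r} not found in the pool")
        added.append(by_id[rid])
    mets = list(draft.metabolites)
    have = {m.id for m in mets}
    pool_mets = {m.id: m for m in pool.metabolites}
    for r in added:
        for mid in r.stoichiometry:
            if mid not in have:
                src = pool_mets[mid]
                mets.append(MetaboliteRecord(id=src.id, name=src.name, index=len(mets)))
                have.add(mid)
    return _build_gem(mets, list(draft.reactions) + added)
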