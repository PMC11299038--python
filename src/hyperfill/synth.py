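"""Seeded synthetic GEM hypergraphs with planted missing reactions.

The generator emulates the structural features the scoring model relies
on: a sparse signed stoichiometric matrix, hyperedges with small disjoint
substrate/product sets (1-4 vertices per side by default), community
structure (each reaction draws its participants preferentially from one
metabolite group) and degree heterogeneity (within a community,
metabolites are picked with Zipf-like 1/rank weights, producing hub
"currency" metabolites).  A held-out reaction subset plays the role of
true missing reactions and decoy reactions — single/double vertex swaps
of training reactions — populate the candidate pool as realistic
negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, SamplingError
from .gem_io import GemModel, MetaboliteRecord, ReactionRecord, UniverseIndex, _build_gem, merge_pool
from .model import Hyperedge

_MAX_TRIES = 100


@dataclass(frozen=True)
class SynthConfig:
    n_metabolites: int = 300
    n_reactions: int = 400
    substrate_count_range: tuple[int, int] = (1, 4)
    product_count_range: tuple[int, int] = (1, 4)
    n_communities: int = 4
    holdout_fraction: float = 0.0
    n_decoys: int = 0
    mixing_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.substrate_count_range[0] < 1 or self.product_count_range[0] < 1:
            raise ConfigError("cardinality ranges must start at 1")
        max_size = self.substrate_count_range[1] + self.product_count_range[1]
        if max_size > self.n_metabolites:
            raise ConfigError("substrate+product counts exceed metabolite count")
        if self.holdout_fraction and round(self.holdout_fraction * self.n_reactions) < 1:
            raise ConfigError("holdout requested but holdout_fraction * n_reactions < 1")


@dataclass
class SynthOutput:
    model: GemModel  # training reactions only
    holdout: list[ReactionRecord]
    decoys: list[ReactionRecord]
    config: SynthConfig = field(repr=False, default=None)

    def pool_model(self) -> GemModel:
        """Holdout + decoy reactions as a pool GEM (deterministic interleave)."""
        rng = np.random.default_rng((self.config.seed if self.config else 0) + 7)
        pool = list(self.holdout) + list(self.decoys)
        order = rng.permutation(len(pool))
        mets = [
            MetaboliteRecord(id=m.id, name=m.name, index=m.index)
            for m in self.model.metabolites
        ]
        return _build_gem(mets, [pool[i] for i in order])

    def to_universe(self) -> UniverseIndex:
        return merge_pool(self.model, self.pool_model())


def _record_key(r: ReactionRecord):
    return (frozenset(r.substrate_ids()), frozenset(r.product_ids()))


def _community_weights(sizes: list[int]) -> list[np.ndarray]:
    weights = []
    for s in sizes:
        w = 1.0 / np.arange(1, s + 1)
        weights.append(w / w.sum())
    return weights


def generate(config: SynthConfig) -> SynthOutput:
    """Generate a seeded synthetic GEM with planted holdout and decoys.

    Identical config (including seed) yields bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_metabolites, config.n_reactions
    mets = [
        MetaboliteRecord(id=f"syn{i:04d}_c", name=f"synthetic metabolite {i}", index=i)
        for i in range(n)
    ]
    bounds = np.linspace(0, n, config.n_communities + 1).astype(int)
    communities = [np.arange(bounds[c], bounds[c + 1]) for c in range(config.n_communities)]
    weights = _community_weights([len(c) for c in communities])

    def draw_members(home: int, count: int, taken: set[int]) -> list[int]:
        out: list[int] = []
        for _ in range(count):
            for _try in range(_MAX_TRIES):
                c = home if rng.random() >= config.mixing_prob else rng.integers(config.n_communities)
                v = int(rng.choice(communities[c], p=weights[c]))
                if v not in taken:
                    taken.add(v)
                    out.append(v)
                    break
            else:  # pragma: no cover - would need pathological configs
                raise SamplingError("could not draw distinct reaction members")
        return out

    reactions: list[ReactionRecord] = []
    seen_keys: set = set()
    for j in range(m):
        for _try in range(_MAX_TRIES):
            home = int(rng.integers(config.n_communities))
            k = int(rng.integers(config.substrate_count_range[0], config.substrate_count_range[1] + 1))
            l = int(rng.integers(config.product_count_range[0], config.product_count_range[1] + 1))
            taken: set[int] = set()
            subs = draw_members(home, k, taken)
            prods = draw_members(home, l, taken)
            stoich = {mets[v].id: -float(rng.integers(1, 3)) for v in subs}
            stoich.update({mets[v].id: float(rng.integers(1, 3)) for v in prods})
            rec = ReactionRecord(id=f"R{j:04d}", stoichiometry=stoich, reversible=False)
            if _record_key(rec) not in seen_keys:
                seen_keys.add(_record_key(rec))
                reactions.append(rec)
                break
        else:
            raise SamplingError("could not generate a unique reaction")

    n_hold = round(config.holdout_fraction * m) if config.holdout_fraction else 0
    hold_idx = set(rng.choice(m, size=n_hold, replace=False).tolist()) if n_hold else set()
    training = [r for j, r in enumerate(reactions) if j not in hold_idx]
    holdout = [r for j, r in enumerate(reactions) if j in hold_idx]
    # every holdout reaction must stay recoverable: it shares >= 1 metabolite
    # with the training set (always true here since hubs dominate, but checked)
    train_mets = {mid for r in training for mid in r.stoichiometry}
    for r in holdout:
        if not set(r.stoichiometry) & train_mets:  # pragma: no cover - defensive
            raise SamplingError("holdout reaction shares no metabolite with training set")

    model = _build_gem(mets, training)
    known_keys = set(seen_keys)
    decoys: list[ReactionRecord] = []
    for d in range(config.n_decoys):
        for _try in range(_MAX_TRIES):
            src = training[int(rng.integers(len(training)))]
            n_swap = int(rng.integers(1, 3))
            cand = _perturb_record(src, [mm.id for mm in mets], known_keys, n_swap, rng)
            cand = ReactionRecord(id=f"D{d:04d}", stoichiometry=cand.stoichiometry, reversible=False)
            if _record_key(cand) not in known_keys:
                known_keys.add(_record_key(cand))
                decoys.append(cand)
                break
        else:
            raise SamplingError("could not generate a unique decoy")
    return SynthOutput(model=model, holdout=holdout, decoys=decoys, config=config)


# ---------------------------------------------------------------------------
# perturbation primitive (negative constructor)


def perturb_edge(
    edge: Hyperedge,
    n_vertices: int,
    known_keys: set,
    n_swap: int,
    rng: np.random.Generator,
    max_tries: int = _MAX_TRIES,
) -> Hyperedge:
    """Swap ``n_swap`` vertices of an edge for uniform non-members, same role.

    The result is rejected and resampled (up to ``max_tries``) while it
    matches any key in ``known_keys``; exhaustion raises
    :class:`~hyperfill.errors.SamplingError`.
    """
    if n_swap < 1 or n_swap > edge.size:
        raise ConfigError("n_swap must be in [1, |V_S| + |V_P|]")
    members = set(edge.vertices)
    for _try in range(max_tries):
        positions = rng.choice(edge.size, size=n_swap, replace=False)
        subs, prods = list(edge.substrates), list(edge.products)
        used = set(members)
        ok = True
        for pos in positions:
            for _vtry in range(max_tries):
                v = int(rng.integers(n_vertices))
                if v not in used:
                    used.add(v)
                    break
            else:  # pragma: no cover
                ok = False
                break
            if pos < edge.k:
                subs[pos] = v
            else:
                prods[pos - edge.k] = v
        if not ok:
            continue
        cand = Hyperedge(substrates=tuple(subs), products=tuple(prods))
        if cand.key() not in known_keys and cand.key() != edge.key():
            return cand
    raise SamplingError(f"perturbation resampling exhausted after {max_tries} tries")


def _perturb_record(
    r: ReactionRecord,
    vertex_ids: list[str],
    known_keys: set,
    n_swap: int,
    rng: np.random.Generator,
) -> ReactionRecord:
    idx = {vid: i for i, vid in enumerate(vertex_ids)}
    subs = r.substrate_ids()
    prods = r.product_ids()
    edge = Hyperedge(
        substrates=tuple(idx[s] for s in subs), products=tuple(idx[p] for p in prods)
    )
    known_idx = {
        (frozenset(idx[s] for s in ks), frozenset(idx[p] for p in kp))
        for ks, kp in known_keys
    }
    new = perturb_edge(edge, len(vertex_ids), known_idx, n_swap, rng)
    stoich = {}
    for mid_old, v_new in zip(subs + prods, new.substrates + new.products):
        stoich[vertex_ids[v_new]] = r.stoichiometry[mid_old]
    return ReactionRecord(id=f"{r.id}_pert", stoichiometry=stoich, reversible=r.reversible)


def perturb_reaction(
    r: ReactionRecord, universe: UniverseIndex, n_swap: int, seed: int
) -> ReactionRecord:
    """Seeded single-reaction perturbation over a universe's vertex set.

    Replaces ``n_swap`` participants by uniformly sampled non-member
    metabolites of the same role (substrates stay substrates, products stay
    products, coefficients carried over) and guarantees the result differs
    from every known draft/pool reaction.
    """
    rng = np.random.default_rng(seed)
    vid = universe.vertex_ids
    known = {
        (frozenset(vid[i] for i in ks), frozenset(vid[i] for i in kp))
        for ks, kp in universe.known_edge_keys()
    }
    return _perturb_record(r, vid, known, n_swap, rng)
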