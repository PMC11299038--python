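"""Reading, writing and merging GEMs as signed stoichiometric hypergraphs.

Models are parsed with COBRApy (SBML Level 3 and BiGG-style JSON) and
exposed as a :class:`GemModel`: an ordered metabolite list, an ordered
reaction list and the signed sparse stoichiometric matrix ``H`` (rows =
metabolites, columns = reactions; negative coefficients consume, positive
coefficients produce).  :func:`merge_pool` builds the joint vertex universe
of a draft model and a universal reaction pool, deduplicating pool
reactions that already exist in the draft.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import EmptyModelError, FormatError, IntegrityError
from .model import Hyperedge

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetaboliteRecord:
    """One metabolite vertex (BiGG-style id, compartment suffix included)."""

    id: str
    name: str
    index: int


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: signed stoichiometry over metabolite ids.

    Negative coefficients are substrates, positive coefficients products.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise IntegrityError(f"reaction {self.id!r} has empty stoichiometry")
        if all(v == 0 for v in self.stoichiometry.values()):
            raise IntegrityError(f"reaction {self.id!r} has no nonzero coefficient")

    def substrate_ids(self) -> tuple[str, ...]:
        # net-zero participants are classified as substrates, matching the
        # characteristic-matrix rule that flags h_ij <= 0 as substrate
        return tuple(mid for mid, c in self.stoichiometry.items() if c <= 0)

    def product_ids(self) -> tuple[str, ...]:
        return tuple(mid for mid, c in self.stoichiometry.items() if c > 0)


@dataclass
class GemModel:
    """A GEM as an ordered vertex list, reaction list and signed H matrix."""

    metabolites: list[MetaboliteRecord]
    reactions: list[ReactionRecord]
    H: sp.csc_matrix

    @property
    def n(self) -> int:
        return len(self.metabolites)

    @property
    def m(self) -> int:
        return len(self.reactions)

    def metabolite_index(self) -> dict[str, int]:
        return {met.id: met.index for met in self.metabolites}

    def hyperedges(self) -> list[Hyperedge]:
        """One hyperedge per reaction over this model's vertex indices."""
        idx = self.metabolite_index()
        return [reaction_to_hyperedge(r, idx) for r in self.reactions]


def reaction_to_hyperedge(reaction: ReactionRecord, index_of: dict[str, int]) -> Hyperedge:
    try:
        subs = tuple(index_of[mid] for mid in reaction.substrate_ids())
        prods = tuple(index_of[mid] for mid in reaction.product_ids())
    except KeyError as exc:  # pragma: no cover - guarded by callers
        raise IntegrityError(
            f"reaction {reaction.id!r} references unknown metabolite {exc.args[0]!r}"
        ) from exc
    return Hyperedge(substrates=subs, products=prods)


def _build_gem(records_m, records_r) -> GemModel:
    index_of = {m.id: m.index for m in records_m}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(records_r):
        for mid, coeff in rxn.stoichiometry.items():
            if mid not in index_of:
                raise IntegrityError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                )
            if coeff != 0:
                rows.append(index_of[mid])
                cols.append(j)
                vals.append(float(coeff))
    H = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(records_m), len(records_r)), dtype=float
    )
    return GemModel(metabolites=list(records_m), reactions=list(records_r), H=H)


def _from_cobra(cmodel, allow_empty: bool = False) -> GemModel:
    mets = [
        MetaboliteRecord(id=m.id, name=m.name or m.id, index=i)
        for i, m in enumerate(cmodel.metabolites)
    ]
    rxns = []
    for r in cmodel.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        rxns.append(ReactionRecord(id=r.id, stoichiometry=stoich, reversible=r.reversibility))
    if not rxns and not allow_empty:
        raise EmptyModelError("model contains no reactions")
    return _build_gem(mets, rxns)


def read_model(path: str | Path, format: str = "auto", allow_empty: bool = False) -> GemModel:
    """Read an SBML or BiGG-style JSON model into a :class:`GemModel`.

    Metabolite and reaction order follows file order so vertex indices are
    deterministic.  ``format="auto"`` dispatches on the file extension.
    ``allow_empty`` accepts a zero-reaction file (useful for empty pools).
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such model file: {path}")
    if format == "auto":
        format = "bigg_json" if path.suffix.lower() == ".json" else "sbml"
    if format not in {"sbml", "bigg_json"}:
        raise FormatError(f"unknown model format {format!r}")
    try:
        if format == "sbml":
            cmodel = cobra.io.read_sbml_model(str(path))
        else:
            cmodel = cobra.io.load_json_model(str(path))
    except EmptyModelError:
        raise
    except Exception as exc:
        raise FormatError(f"failed to parse {path} as {format}: {exc}") from exc
    return _from_cobra(cmodel, allow_empty=allow_empty)


def _compartment_of(met_id: str) -> str:
    # BiGG convention: trailing "_c", "_e", ... names the compartment
    if "_" in met_id and 1 <= len(met_id.rsplit("_", 1)[1]) <= 2:
        return met_id.rsplit("_", 1)[1]
    return "c"


def write_model(
    model: GemModel,
    added: list[ReactionRecord],
    path: str | Path,
    new_metabolites: list[MetaboliteRecord] | tuple = (),
) -> Path:
    """Write the model plus ``added`` reactions as SBML Level 3.

    Added reactions must reference metabolites resolvable in ``model`` or
    listed in ``new_metabolites``; anything else raises
    :class:`~hyperfill.errors.IntegrityError`.
    """
    import cobra
    import cobra.io

    known = {m.id for m in model.metabolites}
    extra = {m.id: m for m in new_metabolites}
    for rxn in added:
        for mid in rxn.stoichiometry:
            if mid not in known and mid not in extra:
                raise IntegrityError(
                    f"added reaction {rxn.id!r} cites unknown metabolite {mid!r}"
                )

    cmodel = cobra.Model("hyperfill_model")
    cmets = {}
    for rec in list(model.metabolites) + [extra[k] for k in extra]:
        cm = cobra.Metabolite(rec.id, name=rec.name, compartment=_compartment_of(rec.id))
        cmets[rec.id] = cm
    crxns = []
    seen_ids = set()
    for rxn in list(model.reactions) + list(added):
        if rxn.id in seen_ids:
            raise IntegrityError(f"duplicate reaction id {rxn.id!r}")
        seen_ids.add(rxn.id)
        cr = cobra.Reaction(rxn.id)
        cr.bounds = (-1000.0, 1000.0) if rxn.reversible else (0.0, 1000.0)
        crxns.append(cr)
        # add_metabolites must run after the reaction joins the model
    cmodel.add_metabolites(list(cmets.values()))
    cmodel.add_reactions(crxns)
    for cr, rxn in zip(crxns, list(model.reactions) + list(added)):
        cr.add_metabolites({cmets[mid]: c for mid, c in rxn.stoichiometry.items()})
    path = Path(path)
    cobra.io.write_sbml_model(cmodel, str(path))
    return path


@dataclass
class UniverseIndex:
    """Joint vertex universe of a draft GEM and a reaction pool.

    ``vertex_ids`` assigns one global index to every metabolite of either
    model (draft metabolites first, in draft order).  ``draft_edges`` and
    ``pool_edges`` are hyperedges over that global index; pool reactions
    whose (substrate set, product set) pair duplicates a draft reaction are
    excluded from ``pool_edges``.
    """

    vertex_ids: list[str]
    draft: GemModel
    draft_edges: list[Hyperedge]
    pool_edges: list[Hyperedge]
    pool_reactions: list[ReactionRecord]
    draft_index_map: dict[int, int] = field(default_factory=dict)
    pool_index_map: dict[int, int] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    def vertex_index(self) -> dict[str, int]:
        return {vid: i for i, vid in enumerate(self.vertex_ids)}

    def known_edge_keys(self) -> set:
        return {e.key() for e in self.draft_edges} | {e.key() for e in self.pool_edges}

    def universe_H(self) -> sp.csc_matrix:
        """Draft H lifted to universe rows (pool-only metabolites: zero rows)."""
        H = self.draft.H.tocoo()
        rows = np.array([self.draft_index_map[i] for i in H.row], dtype=int)
        return sp.csc_matrix(
            (H.data, (rows, H.col)), shape=(self.n_vertices, self.draft.m)
        )


def merge_pool(draft: GemModel, pool: GemModel) -> UniverseIndex:
    """Union the vertex sets of a draft GEM and a reaction pool.

    Returns the global universe with draft and pool hyperedges re-indexed;
    pool duplicates of draft reactions (identical substrate and product
    vertex sets) are dropped.  An empty pool yields empty ``pool_edges``.
    """
    vertex_ids = [m.id for m in draft.metabolites]
    vidx = {v: i for i, v in enumerate(vertex_ids)}
    draft_index_map = {m.index: vidx[m.id] for m in draft.metabolites}
    pool_index_map = {}
    for m in pool.metabolites:
        if m.id not in vidx:
            vidx[m.id] = len(vertex_ids)
            vertex_ids.append(m.id)
        pool_index_map[m.index] = vidx[m.id]

    draft_edges = [reaction_to_hyperedge(r, vidx) for r in draft.reactions]
    draft_keys = {e.key() for e in draft_edges}
    pool_edges, pool_reactions = [], []
    for r in pool.reactions:
        e = reaction_to_hyperedge(r, vidx)
        if e.key() in draft_keys:
            logger.debug("pool reaction %s duplicates a draft reaction; dropped", r.id)
            continue
        pool_edges.append(e)
        pool_reactions.append(r)
    return UniverseIndex(
        vertex_ids=vertex_ids,
        draft=draft,
        draft_edges=draft_edges,
        pool_edges=pool_edges,
        pool_reactions=pool_reactions,
        draft_index_map=draft_index_map,
        pool_index_map=pool_index_map,
    )
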