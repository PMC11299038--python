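"""Candidate selection, similarity filtering and model filling."""

import numpy as np
import pandas as pd
import pytest

from hyperfill.errors import ConfigError, ContractError, IntegrityError
from hyperfill.gapfill import (
    GapFillConfig,
    distance_correlation_sparse,
    fill_gaps,
    reaction_similarity,
    select_candidates,
    two_round_select,
)
from hyperfill.gem_io import MetaboliteRecord, ReactionRecord, _build_gem


def brute_force_dcor(x: np.ndarray, y: np.ndarray) -> float:
    """Doubly centered distance-matrix definition, computed densely."""
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
    B = b - b.mean(0) - b.mean(1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    vx, vy = (A * A).mean(), (B * B).mean()
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(vx * vy)))


class TestDistanceCorrelation:
    def test_exact_copy_is_one(self):
        xd = {0: -1.0, 3: 1.0, 7: 1.0}
        assert distance_correlation_sparse(xd, dict(xd), 20) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_sparse_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        x = np.zeros(n)
        y = np.zeros(n)
        for v in (x, y):
            idx = rng.choice(n, size=rng.integers(2, 7), replace=False)
            v[idx] = rng.choice([-2.0, -1.0, 1.0, 2.0], size=len(idx))
        xd = {i: x[i] for i in np.flatnonzero(x)}
        yd = {i: y[i] for i in np.flatnonzero(y)}
        got = distance_correlation_sparse(xd, yd, n)
        assert got == pytest.approx(brute_force_dcor(x, y), abs=1e-12)

    def test_constant_vector_is_zero(self):
        assert distance_correlation_sparse({}, {0: 1.0}, 10) == 0.0


def _mk_reaction(rid, subs, prods):
    st = {f"m{i}_c": -1.0 for i in subs}
    st.update({f"m{i}_c": 1.0 for i in prods})
    return ReactionRecord(rid, st)


class TestReactionSimilarity:
    def test_identical_reaction_scores_one(self):
        r = _mk_reaction("r", [0, 1], [2])
        for metric in ("distance_correlation", "jaccard"):
            assert reaction_similarity(r, [_mk_reaction("k", [0, 1], [2])], metric) == pytest.approx(1.0)

    def test_disjoint_jaccard_zero(self):
        r = _mk_reaction("r", [0], [1])
        k = _mk_reaction("k", [5], [6])
        vidx = {f"m{i}_c": i for i in range(8)}
        assert reaction_similarity(r, [k], "jaccard", vidx) == 0.0

    def test_max_reduction_over_known(self):
        r = _mk_reaction("r", [0, 1], [2])
        known = [_mk_reaction("far", [7], [8]), _mk_reaction("same", [0, 1], [2])]
        vidx = {f"m{i}_c": i for i in range(10)}
        assert reaction_similarity(r, known, "distance_correlation", vidx) == pytest.approx(1.0)

    def test_empty_known_rejected(self):
        with pytest.raises(ContractError):
            reaction_similarity(_mk_reaction("r", [0], [1]), [])


class TestSelectCandidates:
    def test_threshold_and_truncation(self):
        scores = pd.Series(
            [0.9, 0.4, 0.8, 0.51, 0.2], index=[f"r{i}" for i in range(5)], name="score"
        )
        cfg = GapFillConfig(k_top=2, first_round=3)
        out = select_candidates(scores, cfg)
        assert list(out.index) == ["r0", "r2", "r3"]

    def test_all_below_threshold(self):
        scores = pd.Series([0.1, 0.5], index=["a", "b"])
        assert len(select_candidates(scores, GapFillConfig(k_top=1, first_round=1))) == 0

    def test_tie_break_lexicographic(self):
        scores = pd.Series([0.9, 0.9, 0.9], index=["zeta", "alpha", "mid"])
        out = select_candidates(scores, GapFillConfig(k_top=3, first_round=3))
        assert list(out.index) == ["alpha", "mid", "zeta"]

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            GapFillConfig(k_top=300, first_round=200)
        with pytest.raises(ConfigError):
            GapFillConfig(score_threshold=1.5)


class TestTwoRoundSelect:
    def _setup(self):
        known = [_mk_reaction(f"k{i}", [3 * i, 3 * i + 1], [3 * i + 2]) for i in range(4)]
        pool = [
            _mk_reaction("dup0", [0, 1], [2]),  # exact copy of k0
            _mk_reaction("novel1", [20], [21]),
            _mk_reaction("novel2", [22, 23], [24]),
            _mk_reaction("novel3", [25], [26, 27]),
        ]
        scores = pd.Series([0.99, 0.8, 0.7, 0.6], index=[r.id for r in pool])
        vidx = {f"m{i}_c": i for i in range(30)}
        return known, pool, scores, vidx

    def test_duplicate_of_known_never_selected_when_alternatives_exist(self):
        known, pool, scores, vidx = self._setup()
        cfg = GapFillConfig(k_top=3, first_round=4)
        df = two_round_select(scores, known, cfg, pool, vidx)
        assert not df.loc["dup0", "selected"]
        assert df["selected"].sum() == 3
        assert df.loc["dup0", "similarity"] == pytest.approx(1.0)

    def test_fewer_candidates_than_k_top_all_selected(self):
        known, pool, scores, vidx = self._setup()
        cfg = GapFillConfig(k_top=200, first_round=300)
        df = two_round_select(scores, known, cfg, pool, vidx)
        assert df["selected"].all()

    def test_similarity_ordering_ties_resolved_by_score(self):
        known = [_mk_reaction("k0", [0], [1])]
        pool = [_mk_reaction("a", [10], [11]), _mk_reaction("b", [12], [13])]
        scores = pd.Series([0.7, 0.9], index=["a", "b"])
        vidx = {f"m{i}_c": i for i in range(14)}
        df = two_round_select(scores, known, GapFillConfig(k_top=1, first_round=2), known + pool, vidx)
        # both have equal (zero-ish) similarity; higher score wins
        assert df.loc["b", "selected"] and not df.loc["a", "selected"]


class TestFillGaps:
    def _models(self):
        mets = [MetaboliteRecord(f"m{i}_c", f"M{i}", i) for i in range(6)]
        draft = _build_gem(mets[:4], [_mk_reaction("d0", [0, 1], [2]), _mk_reaction("d1", [2], [3])])
        pool = _build_gem(mets, [_mk_reaction("p0", [3], [4]), _mk_reaction("p1", [4], [5])])
        return draft, pool

    def _ranking(self, ids, selected):
        return pd.DataFrame(
            {
                "score": 0.9,
                "score_rank": range(1, len(ids) + 1),
                "similarity": 0.1,
                "selected": [i in selected for i in ids],
            },
            index=pd.Index(ids, name="id"),
        )

    def test_appends_selected_and_new_metabolites(self):
        draft, pool = self._models()
        filled = fill_gaps(draft, self._ranking(["p0", "p1"], {"p0", "p1"}), pool)
        assert filled.m == 4
        assert "m5_c" in filled.metabolite_index()

    def test_empty_selection_identity(self):
        draft, pool = self._models()
        filled = fill_gaps(draft, self._ranking(["p0"], set()), pool)
        assert filled.m == draft.m

    def test_duplicate_id_rejected(self):
        draft, pool = self._models()
        filled = fill_gaps(draft, self._ranking(["p0"], {"p0"}), pool)
        with pytest.raises(IntegrityError):
            fill_gaps(filled, self._ranking(["p0"], {"p0"}), pool)
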