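"""The six similarity-search engines and their shared machinery.

Every engine ranks database compounds against one query fingerprint and
returns the top ~1% as a hit list.  They differ in how the query's
reference neighborhood is used:

========  ==================================================================
engine    scoring rule
========  ==================================================================
css       Tanimoto(query, db) — conventional single-query search
pbss      Tanimoto(AVE profile of {query + active neighbors}, db)
iss       MAX over {query + active neighbors} of Tanimoto(unit, db)
isc       iss score, but a compound whose best inactive-neighbor similarity
          reaches its best active-neighbor similarity is rejected outright
pbiss     iss with active neighbors compressed into per-cluster AVE
          profiles (Taylor-Butina at cutoff 0.4)
pbisc     isc with all neighbors clustered; pure clusters give one profile,
          mixed clusters one profile per label
========  ==================================================================

The neighbor list holds reference-set compounds with Tanimoto strictly
greater than 0.3 to the query, split by label.  The query's own fingerprint
always participates as an active unit, so with an empty neighbor list every
engine degenerates to the conventional search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from profsearch.clustering import taylor_butina
from profsearch.similarity import (
    Profile,
    bulk_tanimoto_binary,
    bulk_tanimoto_continuous,
    make_profile,
)

ENGINES = ("css", "pbss", "iss", "pbiss", "isc", "pbisc")

NEIGHBOR_CUTOFF = 0.3
CLUSTER_CUTOFF = 0.4
TOP_FRACTION = 0.01


@dataclass
class NeighborList:
    """Reference compounds with similarity > cutoff to one query."""

    query_id: str
    cutoff: float
    active_ids: list[str]
    active_fps: np.ndarray  # (n_act, M)
    inactive_ids: list[str]
    inactive_fps: np.ndarray  # (n_inact, M)

    @property
    def n_active(self) -> int:
        return self.active_fps.shape[0]

    @property
    def n_inactive(self) -> int:
        return self.inactive_fps.shape[0]


@dataclass
class HitList:
    """Descending-score ranking truncated to the top k.

    Ties are broken by ascending compound id; query/reference compounds are
    excluded upstream.
    """

    entries: list[tuple[str, float]]
    k: int

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def scores(self) -> list[float]:
        return [e[1] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ReferenceModel:
    """The units an iterative engine fuses over, plus compression stats.

    In fingerprint mode the units are the (query + neighbor) fingerprints
    themselves; in profile mode they are per-cluster AVE profiles.  The
    compression ratio is total references per unit and is >= 1.
    """

    mode: str  # "fingerprints" or "profiles"
    active_units: list = field(default_factory=list)
    inactive_units: list = field(default_factory=list)
    n_references: int = 0

    @property
    def n_units(self) -> int:
        return len(self.active_units) + len(self.inactive_units)

    @property
    def compression_ratio(self) -> float:
        if self.n_units == 0:
            return 1.0
        return self.n_references / self.n_units


@dataclass
class SearchResult:
    """One engine's full output for one query.

    ``scores``/``kept`` cover every database compound (kept is False only
    for compounds rejected by the neighbor-classification rule), so ROC
    curves can be computed over the full ranking, not just the truncated
    hit list.
    """

    engine: str
    query_id: str
    hits: HitList
    db_ids: list[str]
    scores: np.ndarray
    kept: np.ndarray
    neighbor_list: NeighborList | None = None
    model: ReferenceModel | None = None


def default_k(db_size: int, top_fraction: float = TOP_FRACTION) -> int:
    """Hit-list size: floor(top_fraction × database size), at least 1."""
    return max(int(math.floor(top_fraction * db_size)), 1)


def build_neighbor_list(
    query_id: str,
    query_fp: np.ndarray,
    reference_ids: list[str],
    reference_fps: np.ndarray,
    reference_labels: np.ndarray,
    cutoff: float = NEIGHBOR_CUTOFF,
) -> NeighborList:
    """References with Tanimoto similarity strictly greater than ``cutoff``.

    An empty neighbor list is a valid state; every engine falls back to
    conventional search there.
    """
    reference_fps = np.asarray(reference_fps)
    labels = np.asarray(reference_labels)
    if reference_fps.shape[0] == 0:
        M = query_fp.shape[0]
        empty = np.zeros((0, M), dtype=reference_fps.dtype)
        return NeighborList(query_id, cutoff, [], empty, [], empty.copy())
    sims = bulk_tanimoto_binary(query_fp, reference_fps)
    keep = sims > cutoff
    act = keep & (labels == "active")
    inact = keep & (labels == "inactive")
    ref_ids = np.asarray(reference_ids, dtype=object)
    return NeighborList(
        query_id=query_id,
        cutoff=cutoff,
        active_ids=list(ref_ids[act]),
        active_fps=reference_fps[act],
        inactive_ids=list(ref_ids[inact]),
        inactive_fps=reference_fps[inact],
    )


def build_profile_units(
    nl: NeighborList,
    mode: str,
    query_fp: np.ndarray | None = None,
    cluster_cutoff: float = CLUSTER_CUTOFF,
) -> ReferenceModel:
    """Cluster the neighbor list and compress each cluster to an AVE profile.

    ``pbiss`` clusters only the active references (the query fingerprint
    included); ``pbisc`` clusters actives and inactives together — a pure
    cluster yields a single profile, a mixed cluster yields one profile per
    label so that the active/inactive vote stays separable.
    """
    if mode not in {"pbiss", "pbisc"}:
        raise ValueError(f"profile mode must be 'pbiss' or 'pbisc', got {mode!r}")
    act = nl.active_fps
    if query_fp is not None:
        act = np.concatenate([query_fp[None, :], act]) if act.shape[0] else query_fp[None, :]
    model = ReferenceModel(mode="profiles")
    if mode == "pbiss":
        pool = act
        labels = np.array(["active"] * pool.shape[0])
    else:
        pool = np.concatenate([act, nl.inactive_fps]) if nl.n_inactive else act
        labels = np.array(["active"] * act.shape[0] + ["inactive"] * nl.n_inactive)
    model.n_references = pool.shape[0]
    if pool.shape[0] == 0:
        return model
    clustering = taylor_butina(pool, cluster_cutoff)
    for cl in clustering.clusters:
        members = np.array(cl.members)
        for lab in ("active", "inactive"):
            sel = members[labels[members] == lab]
            if sel.size == 0:
                continue
            prof = make_profile(pool[sel], label=lab)
            (model.active_units if lab == "active" else model.inactive_units).append(prof)
    return model


def _fingerprint_units(nl: NeighborList, query_fp: np.ndarray) -> ReferenceModel:
    act = [query_fp] + [fp for fp in nl.active_fps]
    inact = [fp for fp in nl.inactive_fps]
    return ReferenceModel(
        mode="fingerprints",
        active_units=act,
        inactive_units=inact,
        n_references=len(act) + len(inact),
    )


class _PreparedDB:
    """Float view of the database with cached popcounts (binary rows)."""

    def __init__(self, X: np.ndarray):
        self.Xf = np.asarray(X, dtype=np.float64)
        self.rowsum = self.Xf.sum(axis=1)  # popcount == sum of squares

    def sims(self, v, binary: bool) -> np.ndarray:
        if not binary and isinstance(v, Profile) and v.counts is not None:
            # Scaled-integer form: with v == counts / n the score against a
            # binary row b is n·(counts·b) / (Σcounts² + n²·Σb² − n·counts·b),
            # all integers exact in float64, so the division is correctly
            # rounded and equal rational scores give bitwise-equal floats.
            s, n = v.counts, float(v.n_members)
            dot = self.Xf @ s
            num = n * dot
            denom = float(s @ s) + (n * n) * self.rowsum - num
        else:
            vf = v.values if isinstance(v, Profile) else np.asarray(v, dtype=np.float64)
            dot = self.Xf @ vf
            num = dot
            if binary:
                denom = self.rowsum + vf.sum() - dot
            else:
                denom = self.rowsum + float(vf @ vf) - dot
        out = np.zeros(self.Xf.shape[0])
        np.divide(num, denom, out=out, where=denom != 0)
        return out

    def max_fusion(self, units, binary: bool) -> np.ndarray:
        scores = self.sims(units[0], binary)
        for u in units[1:]:
            np.maximum(scores, self.sims(u, binary), out=scores)
        return scores


def score_css(query_fp: np.ndarray, db: np.ndarray | _PreparedDB) -> np.ndarray:
    """Conventional similarity search scores: plain binary Tanimoto."""
    if isinstance(db, _PreparedDB):
        return db.sims(query_fp, binary=True)
    return bulk_tanimoto_binary(query_fp, db)


def score_pbss(query_fp: np.ndarray, nl: NeighborList, db) -> np.ndarray:
    """Single-profile search: AVE of the query and its active neighbors."""
    if nl.n_active == 0:
        return score_css(query_fp, db)
    prof = make_profile(np.concatenate([query_fp[None, :], nl.active_fps]))
    if isinstance(db, _PreparedDB):
        return db.sims(prof, binary=False)
    return bulk_tanimoto_continuous(prof, db)


def score_iss(model: ReferenceModel, db) -> np.ndarray:
    """MAX group fusion over the active units (fingerprints or profiles)."""
    binary = model.mode == "fingerprints"
    if isinstance(db, _PreparedDB):
        return db.max_fusion(model.active_units, binary)
    X = np.asarray(db)
    from profsearch.similarity import max_fusion

    return max_fusion(model.active_units, X, continuous=not binary)


def classify_and_score_isc(model: ReferenceModel, db) -> tuple[np.ndarray, np.ndarray]:
    """ISC scoring: MAX fusion plus the neighbor-classification rejection.

    A database compound is kept only when its best active-unit similarity
    strictly exceeds its best inactive-unit similarity; ties are rejected.
    With no inactive units the result is identical to the plain iterative
    search (everything kept).
    """
    scores = score_iss(model, db)
    if not model.inactive_units:
        return scores, np.ones(scores.shape[0], dtype=bool)
    binary = model.mode == "fingerprints"
    if isinstance(db, _PreparedDB):
        inact = db.max_fusion(model.inactive_units, binary)
    else:
        from profsearch.similarity import max_fusion

        inact = max_fusion(model.inactive_units, np.asarray(db), continuous=not binary)
    return scores, scores > inact


def rank_hits(db_ids: list[str], scores: np.ndarray, k: int, kept: np.ndarray | None = None) -> HitList:
    """Sort by descending score (ties: ascending id) and truncate to k."""
    if k <= 0:
        raise ValueError(f"hit-list size k must be positive, got {k}")
    idx = np.arange(len(db_ids))
    if kept is not None:
        idx = idx[kept]
    pairs = sorted(((db_ids[i], float(scores[i])) for i in idx), key=lambda e: (-e[1], e[0]))
    return HitList(entries=pairs[:k], k=k)


def run_search(
    engine: str,
    query_id: str,
    query_fp: np.ndarray,
    db_ids: list[str],
    db_fps: np.ndarray,
    reference_ids: list[str],
    reference_fps: np.ndarray,
    reference_labels: np.ndarray,
    k: int | None = None,
    neighbor_cutoff: float = NEIGHBOR_CUTOFF,
    cluster_cutoff: float = CLUSTER_CUTOFF,
    top_fraction: float = TOP_FRACTION,
    exclude_ids: set[str] | None = None,
) -> SearchResult:
    """Run one engine for one query and return the ranked, truncated hits.

    Query and reference compounds must not be scored; any db entry whose id
    is the query's, a reference's, or in ``exclude_ids`` is dropped before
    ranking.  ``k`` defaults to floor(top_fraction × |db|) after exclusion.
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")
    banned = {query_id, *reference_ids, *(exclude_ids or ())}
    mask = np.array([i not in banned for i in db_ids])
    db_ids = [i for i, m in zip(db_ids, mask) if m]
    db = _PreparedDB(np.asarray(db_fps)[mask])
    if k is None:
        k = default_k(len(db_ids), top_fraction)

    nl = build_neighbor_list(
        query_id, query_fp, reference_ids, reference_fps, reference_labels, neighbor_cutoff
    )
    model: ReferenceModel | None = None
    kept = np.ones(len(db_ids), dtype=bool)
    if engine == "css":
        scores = score_css(query_fp, db)
    elif engine == "pbss":
        scores = score_pbss(query_fp, nl, db)
        if nl.n_active > 0:
            prof = make_profile(np.concatenate([query_fp[None, :], nl.active_fps]))
            model = ReferenceModel(
                mode="profiles", active_units=[prof], n_references=nl.n_active + 1
            )
    elif engine == "iss":
        model = _fingerprint_units(nl, query_fp)
        scores = score_iss(model, db)
    elif engine == "isc":
        model = _fingerprint_units(nl, query_fp)
        scores, kept = classify_and_score_isc(model, db)
    elif engine == "pbiss":
        model = build_profile_units(nl, "pbiss", query_fp=query_fp, cluster_cutoff=cluster_cutoff)
        scores = score_iss(model, db)
    else:  # pbisc
        model = build_profile_units(nl, "pbisc", query_fp=query_fp, cluster_cutoff=cluster_cutoff)
        scores, kept = classify_and_score_isc(model, db)
    hits = rank_hits(db_ids, scores, k, kept=kept)
    return SearchResult(
        engine=engine,
        query_id=query_id,
        hits=hits,
        db_ids=db_ids,
        scores=scores,
        kept=kept,
        neighbor_list=nl,
        model=model,
    )
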