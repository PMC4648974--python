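"""Independent brute-force reimplementation of the six search engines.

Everything here is deliberately naive: pure-Python loops over bit lists,
exact rational arithmetic via fractions.Fraction, no numpy, no early
exits, no shared code with the package under test.  It exists solely as a
cross-check oracle for small databases.
"""

from __future__ import annotations

from fractions import Fraction


def tanimoto(a: list[int], b: list[int]) -> Fraction:
    assert len(a) == len(b)
    ca = sum(1 for x in a if x)
    cb = sum(1 for x in b if x)
    cc = sum(1 for x, y in zip(a, b) if x and y)
    denom = ca + cb - cc
    if denom == 0:
        return Fraction(0)
    return Fraction(cc, denom)


def tanimoto_cont(a: list[Fraction], b: list[Fraction]) -> Fraction:
    assert len(a) == len(b)
    dot = sum((x * y for x, y in zip(a, b)), Fraction(0))
    denom = sum((x * x + y * y - x * y for x, y in zip(a, b)), Fraction(0))
    if denom == 0:
        return Fraction(0)
    return dot / denom


def average_profile(members: list[list]) -> list[Fraction]:
    n = len(members)
    assert n > 0
    return [sum((Fraction(m[i]) for m in members), Fraction(0)) / n for i in range(len(members[0]))]


def butina(fps: list[list[int]], cutoff: Fraction) -> list[list[int]]:
    """Sphere-exclusion clustering; returns clusters as index lists
    (centroid first), in formation order."""
    n = len(fps)
    neighbors = [
        [j for j in range(n) if j != i and tanimoto(fps[i], fps[j]) >= cutoff]
        for i in range(n)
    ]
    order = sorted(range(n), key=lambda i: (-len(neighbors[i]), i))
    assigned = [False] * n
    clusters = []
    for i in order:
        if assigned[i]:
            continue
        members = [i] + [j for j in neighbors[i] if not assigned[j]]
        for j in members:
            assigned[j] = True
        clusters.append(members)
    return clusters


def _neighbor_list(query, ref_fps, ref_labels, cutoff: Fraction):
    act, inact = [], []
    for fp, lab in zip(ref_fps, ref_labels):
        if tanimoto(query, fp) > cutoff:
            (act if lab == "active" else inact).append(fp)
    return act, inact


def _units(mode, query, act_nbrs, inact_nbrs, cluster_cutoff: Fraction):
    """Active and inactive unit vectors (fingerprints or profiles)."""
    act_pool = [query] + act_nbrs
    if mode == "fingerprints":
        return (
            [[Fraction(x) for x in fp] for fp in act_pool],
            [[Fraction(x) for x in fp] for fp in inact_nbrs],
        )
    if mode == "pbiss":
        pool, labels = act_pool, ["active"] * len(act_pool)
    else:  # pbisc
        pool = act_pool + inact_nbrs
        labels = ["active"] * len(act_pool) + ["inactive"] * len(inact_nbrs)
    act_units, inact_units = [], []
    for members in butina(pool, cluster_cutoff):
        for lab, dest in (("active", act_units), ("inactive", inact_units)):
            sel = [pool[i] for i in members if labels[i] == lab]
            if sel:
                dest.append(average_profile(sel))
    return act_units, inact_units


def search(
    engine: str,
    query_id: str,
    query: list[int],
    db_ids: list[str],
    db_fps: list[list[int]],
    ref_fps: list[list[int]],
    ref_labels: list[str],
    k: int,
    neighbor_cutoff: Fraction = Fraction(3, 10),
    cluster_cutoff: Fraction = Fraction(2, 5),
) -> list[tuple[str, Fraction]]:
    """Ranked, truncated hit list [(id, exact score)] for one engine."""
    act_nbrs, inact_nbrs = _neighbor_list(query, ref_fps, ref_labels, neighbor_cutoff)
    qf = [Fraction(x) for x in query]

    if engine == "css":
        act_units, inact_units = [qf], []
    elif engine == "pbss":
        act_units = [average_profile([query] + act_nbrs)] if act_nbrs else [qf]
        inact_units = []
    elif engine == "iss":
        act_units, _ = _units("fingerprints", query, act_nbrs, inact_nbrs, cluster_cutoff)
        inact_units = []
    elif engine == "isc":
        act_units, inact_units = _units("fingerprints", query, act_nbrs, inact_nbrs, cluster_cutoff)
    elif engine == "pbiss":
        act_units, _ = _units("pbiss", query, act_nbrs, [], cluster_cutoff)
        inact_units = []
    elif engine == "pbisc":
        act_units, inact_units = _units("pbisc", query, act_nbrs, inact_nbrs, cluster_cutoff)
    else:
        raise ValueError(engine)

    scored = []
    for cid, fp in zip(db_ids, db_fps):
        fpf = [Fraction(x) for x in fp]
        best_act = max(tanimoto_cont(u, fpf) for u in act_units)
        if inact_units:
            best_inact = max(tanimoto_cont(u, fpf) for u in inact_units)
            if not best_act > best_inact:
                continue
        scored.append((cid, best_act))
    scored.sort(key=lambda e: (-e[1], e[0]))
    return scored[:k]
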