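"""Tanimoto coefficients and average (AVE) profiles.

The numeric core shared by every search engine.  Two forms of the Tanimoto
coefficient are provided: the binary form

    Tc(A, B) = c / (a + b - c)

with ``a``, ``b`` the popcounts and ``c`` the intersection popcount, and the
continuous form

    Tc(A, B) = Σ aᵢbᵢ / Σ (aᵢ² + bᵢ² - aᵢbᵢ)

for real-valued profiles.  On binary inputs the two coincide exactly: the
popcount of a 0/1 vector equals its sum of squares and the intersection
popcount equals the dot product, so the same float division is performed.

A profile is the element-wise mean of a set of member fingerprints — the
simple average (AVE) consensus used to compress a group of structurally
related references into a single comparable unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Profile:
    """Element-wise mean of ``n_members`` fingerprints.

    ``values`` lies in [0, 1]^M; a profile built from a single fingerprint
    is numerically identical to that fingerprint.  ``n_members`` is kept so
    that compression ratios remain computable after clustering.
    """

    values: np.ndarray
    n_members: int
    label: str = "active"
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.n_members <= 0:
            raise ValueError("a profile needs at least one member")
        if self.counts is None:
            # Recover integer member-bit counts when the mean values permit
            # it; scoring then uses exact integer arithmetic (see
            # bulk_tanimoto_continuous) so that equal rational scores give
            # bitwise-equal floats.
            c = self.values * self.n_members
            r = np.rint(c)
            if np.allclose(c, r, atol=1e-9):
                self.counts = r
        else:
            self.counts = np.asarray(self.counts, dtype=np.float64)

    def __len__(self) -> int:
        return self.values.shape[0]


def _as_vector(x) -> np.ndarray:
    if isinstance(x, Profile):
        return x.values
    return np.asarray(x, dtype=np.float64)


def tanimoto_binary(a: np.ndarray, b: np.ndarray) -> float:
    """Binary Tanimoto coefficient c/(a+b-c) between two bit vectors.

    Two all-zero fingerprints return 0.0 by convention (the expression is
    0/0 there; a featureless molecule should not match everything).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    af = a.astype(np.float64)
    bf = b.astype(np.float64)
    c = float(af @ bf)
    denom = float(af.sum()) + float(bf.sum()) - c
    if denom == 0.0:
        return 0.0
    return c / denom


def _counts_scale(x) -> tuple[np.ndarray, int] | None:
    """Exact integer representation ``x == counts / scale``, if one exists."""
    if isinstance(x, Profile):
        if x.counts is None:
            return None
        return x.counts, x.n_members
    v = np.asarray(x, dtype=np.float64)
    if np.array_equal(v, np.rint(v)):
        return v, 1
    return None


def tanimoto_continuous(a, b) -> float:
    """Continuous Tanimoto coefficient between profiles and/or fingerprints.

    Binary fingerprints are promoted to real vectors of 0/1, so on two
    binary inputs this equals :func:`tanimoto_binary` exactly.

    When both operands have exact integer representations (bit vectors, or
    profiles with integer member-bit counts), the score is evaluated on
    integers scaled by the member counts.  The single float division is then
    correctly rounded, so the result depends only on the exact rational
    score — equal rationals give bitwise-equal floats, which keeps ranking
    tie-breaks deterministic.
    """
    av = _as_vector(a)
    bv = _as_vector(b)
    if av.shape != bv.shape:
        raise ValueError(f"vector length mismatch: {av.shape} vs {bv.shape}")
    ca, cb = _counts_scale(a), _counts_scale(b)
    if ca is not None and cb is not None:
        sa, na = ca
        sb, nb = cb
        dot = float(sa @ sb)
        num = na * nb * dot
        denom = nb * nb * float(sa @ sa) + na * na * float(sb @ sb) - num
    else:
        dot = float(av @ bv)
        num = dot
        denom = float(av @ av) + float(bv @ bv) - dot
    if denom == 0.0:
        return 0.0
    return num / denom


def make_profile(members, label: str = "active") -> Profile:
    """AVE profile: element-wise arithmetic mean of a nonempty member set.

    ``members`` is a sequence of equal-length fingerprints/vectors or a 2-D
    array with one member per row.
    """
    M = np.asarray(members, dtype=np.float64)
    if M.size == 0:
        raise ValueError("cannot build a profile from an empty member list")
    if M.ndim == 1:
        M = M[None, :]
    counts = M.sum(axis=0)
    n = M.shape[0]
    if not np.array_equal(counts, np.rint(counts)):
        counts = None
    return Profile(values=M.sum(axis=0) / n, n_members=n, label=label, counts=counts)


# ---------------------------------------------------------------------------
# Vectorized forms used by the search engines.  These apply the same float64
# expressions row-wise, so single-pair results agree with the scalar
# functions above.

def bulk_tanimoto_binary(q: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Binary Tanimoto of one fingerprint against every row of a bit matrix."""
    qf = np.asarray(q, dtype=np.float64)
    Xf = np.asarray(X, dtype=np.float64)
    if Xf.shape[1] != qf.shape[0]:
        raise ValueError("fingerprint length mismatch")
    c = Xf @ qf
    denom = Xf.sum(axis=1) + qf.sum() - c
    out = np.zeros(Xf.shape[0])
    np.divide(c, denom, out=out, where=denom != 0)
    return out


def bulk_tanimoto_continuous(v, X: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto of one profile/fingerprint against matrix rows.

    Uses the scaled-integer form of :func:`tanimoto_continuous` when both
    the unit and the database rows are exactly representable as integers
    over a common scale, so scores are correctly rounded rationals.
    """
    vf = _as_vector(v)
    Xf = np.asarray(X, dtype=np.float64)
    if Xf.shape[1] != vf.shape[0]:
        raise ValueError("vector length mismatch")
    cv = _counts_scale(v)
    sq = (Xf * Xf).sum(axis=1)
    if cv is not None and np.array_equal(Xf, np.rint(Xf)):
        s, n = cv
        dot = Xf @ s
        num = n * dot
        denom = float(s @ s) + (n * n) * sq - num
    else:
        dot = Xf @ vf
        num = dot
        denom = sq + float(vf @ vf) - dot
    out = np.zeros(Xf.shape[0])
    np.divide(num, denom, out=out, where=denom != 0)
    return out


def max_fusion(units, X: np.ndarray, continuous: bool = False) -> np.ndarray:
    """MAX group-fusion score of every database row against a unit set.

    ``score(db) = max over units of Tc(unit, db)`` — the group-fusion rule
    that lets multiple references (or profiles) vote for a database
    compound by its single best match.
    """
    Xf = np.asarray(X, dtype=np.float64)
    if len(units) == 0:
        raise ValueError("max_fusion needs at least one unit")
    sim = bulk_tanimoto_continuous if continuous else bulk_tanimoto_binary
    scores = sim(units[0], Xf)
    for u in units[1:]:
        np.maximum(scores, sim(u, Xf), out=scores)
    return scores
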