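"""Activity-class curation, query/reference/test splitting, and the
synthetic activity-class generator.

The curation stage turns raw bioactivity end-point tables (compound id,
activity-class id, assay measure, concentration in μM or an explicit label)
into benchmark-ready activity classes:

1. concentration end points are labeled active below 10 μM and inactive
   above 30 μM (the 10–30 μM band stays undetermined); explicit labels pass
   through unchanged;
2. classes where more than 5 % of end points conflict (the same compound
   measured both active and inactive) are discarded as noisy;
3. remaining conflicted compounds are removed;
4. classes are retained only when both actives and inactives number > 70.

Each retained class is split into a query set (the Taylor-Butina cluster
centroids of the actives), a reference set and a test set; inactive
reference counts are capped at one fourth of the class total when a class
has more than 20,000 inactives.

The synthetic generator stands in for a public bioactivity extraction: it
plants scaffold families of near-duplicate active fingerprints, activity
cliff decoys (inactives perturbed from the same scaffold prototypes),
unrelated far inactives, and a large unknown-label background database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from profsearch.clustering import diversity_index, taylor_butina

ACTIVE_BELOW_UM = 10.0
INACTIVE_ABOVE_UM = 30.0
CONFLICT_FRACTION = 0.05
MIN_CLASS_SIZE = 70
INACTIVE_CAP_THRESHOLD = 20_000

CONCENTRATION_MEASURES = {"IC50", "EC50", "Ki"}


def label_endpoint(
    measure: str,
    value_uM: float | None = None,
    label: str | None = None,
    active_below_uM: float = ACTIVE_BELOW_UM,
    inactive_above_uM: float = INACTIVE_ABOVE_UM,
) -> str:
    """Label one bioactivity end point as active / inactive / undetermined.

    Concentration end points (IC50, EC50, Ki) are active strictly below
    ``active_below_uM`` and inactive strictly above ``inactive_above_uM``;
    the band in between is undetermined.  ``explicit_label`` end points keep
    their original annotation.
    """
    if measure == "explicit_label":
        if label not in {"active", "inactive", "undetermined"}:
            raise ValueError(f"explicit label must be active/inactive/undetermined, got {label!r}")
        return label
    if measure not in CONCENTRATION_MEASURES:
        raise ValueError(f"unknown end-point measure: {measure!r}")
    if value_uM is None or value_uM <= 0:
        raise ValueError(f"concentration end point needs a positive value, got {value_uM!r}")
    if value_uM < active_below_uM:
        return "active"
    if value_uM > inactive_above_uM:
        return "inactive"
    return "undetermined"


def label_endpoints(df: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Apply :func:`label_endpoint` to an end-point table.

    Expects columns ``compound_id, class_id, measure`` and, per measure,
    ``value_uM`` or ``label``.  Returns a copy with a ``label`` column.
    """
    out = df.copy()
    out["label"] = [
        label_endpoint(
            row.measure,
            value_uM=getattr(row, "value_uM", None),
            label=getattr(row, "label", None),
            **kwargs,
        )
        for row in df.itertuples()
    ]
    return out


def filter_classes(
    df: pd.DataFrame,
    max_conflict_fraction: float = CONFLICT_FRACTION,
    min_actives: int = MIN_CLASS_SIZE,
    min_inactives: int = MIN_CLASS_SIZE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Curate a labeled end-point table into per-class compound labels.

    A compound with both active and inactive end points within one class is
    a conflict.  Classes whose conflicting end points exceed
    ``max_conflict_fraction`` of all their end points are dropped; in the
    remaining classes the conflicted compounds are removed; finally only
    classes with strictly more than ``min_actives`` actives and
    ``min_inactives`` inactives are retained, in input order.

    Returns
    -------
    (compounds, summary)
        ``compounds``: one row per retained (class_id, compound_id) with the
        consolidated ``label``.  ``summary``: per input class, its end-point
        count, conflict fraction, active/inactive counts and fate.
    """
    records: list[pd.DataFrame] = []
    summary_rows = []
    for class_id in df["class_id"].drop_duplicates():
        sub = df[df["class_id"] == class_id]
        per_compound = sub.groupby("compound_id")["label"].agg(set)
        conflicted = per_compound.index[per_compound.apply(lambda s: {"active", "inactive"} <= s)]
        n_conflict_eps = int(
            sub["compound_id"].isin(conflicted).sum() if len(conflicted) else 0
        )
        conflict_frac = n_conflict_eps / len(sub)
        if conflict_frac > max_conflict_fraction:
            summary_rows.append((class_id, len(sub), conflict_frac, 0, 0, "dropped_noisy"))
            continue
        clean = sub[~sub["compound_id"].isin(conflicted)]
        labels = clean.groupby("compound_id", sort=False)["label"].agg(
            lambda s: "active" if "active" in set(s) else ("inactive" if "inactive" in set(s) else "undetermined")
        )
        labels = labels[labels != "undetermined"]
        n_act = int((labels == "active").sum())
        n_inact = int((labels == "inactive").sum())
        if n_act > min_actives and n_inact > min_inactives:
            records.append(
                pd.DataFrame(
                    {"class_id": class_id, "compound_id": labels.index, "label": labels.values}
                )
            )
            fate = "retained"
        else:
            fate = "dropped_small"
        summary_rows.append((class_id, len(sub), conflict_frac, n_act, n_inact, fate))
    summary = pd.DataFrame(
        summary_rows,
        columns=["class_id", "n_endpoints", "conflict_fraction", "n_actives", "n_inactives", "fate"],
    )
    compounds = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["class_id", "compound_id", "label"])
    )
    return compounds, summary


@dataclass
class ActivityClass:
    """All curated actives and inactives against one target."""

    class_id: str
    active_ids: list[str]
    active_fps: np.ndarray  # (n_actives, M)
    inactive_ids: list[str]
    inactive_fps: np.ndarray  # (n_inactives, M)

    def diversity_index(self, cutoff: float) -> float:
        """Structural diversity H of the actives at a Taylor-Butina cutoff."""
        return diversity_index(taylor_butina(self.active_fps, cutoff))


@dataclass
class SplitDataset:
    """Query / reference / test partition of one activity class.

    The query set holds the Taylor-Butina cluster centroids of the actives;
    reference and test sets carry both labels.  The unknown-label background
    database travels alongside.
    """

    class_id: str
    query_ids: list[str]
    query_fps: np.ndarray
    reference_ids: list[str]
    reference_fps: np.ndarray
    reference_labels: np.ndarray  # array of "active"/"inactive"
    test_ids: list[str]
    test_fps: np.ndarray
    test_labels: np.ndarray
    background_ids: list[str] = field(default_factory=list)
    background_fps: np.ndarray | None = None


def split_class(
    ac: ActivityClass,
    div_cutoff: float,
    seed: int,
    inactive_cap_threshold: int = INACTIVE_CAP_THRESHOLD,
    reference_fraction: float = 0.5,
    max_inactive_ratio: float | None = None,
    background: tuple[list[str], np.ndarray] | None = None,
) -> SplitDataset:
    """Split an activity class into query / reference / test sets.

    The query set is the set of Taylor-Butina cluster centroids of the
    actives at ``div_cutoff``.  Remaining actives are shuffled (seeded) and
    split ``reference_fraction`` / rest into reference and test; inactives
    likewise, except that when the class has more than
    ``inactive_cap_threshold`` inactives the reference share is capped at
    one fourth of the total, the remainder going to the test set.

    ``max_inactive_ratio``, when set (e.g. 5.0), subsamples inactive
    references beyond that multiple of the active reference count —
    an optional rebalancing step, off by default.
    """
    rng = np.random.default_rng(seed)
    clustering = taylor_butina(ac.active_fps, div_cutoff)
    centroid_idx = sorted(clustering.centroid_indices())
    centroid_set = set(centroid_idx)
    rest_idx = np.array([i for i in range(len(ac.active_ids)) if i not in centroid_set], dtype=int)
    if rest_idx.size < 2:
        raise ValueError(
            f"class {ac.class_id}: only {rest_idx.size} non-centroid actives; "
            "cannot populate both reference and test sets"
        )
    rng.shuffle(rest_idx)
    n_ref_act = int(round(len(rest_idx) * reference_fraction))
    n_ref_act = min(max(n_ref_act, 1), len(rest_idx) - 1)
    ref_act, test_act = rest_idx[:n_ref_act], rest_idx[n_ref_act:]

    inact_idx = rng.permutation(len(ac.inactive_ids))
    n_total_inact = len(inact_idx)
    n_ref_inact = int(round(n_total_inact * reference_fraction))
    if n_total_inact > inactive_cap_threshold:
        n_ref_inact = min(n_ref_inact, n_total_inact // 4)
    ref_inact, test_inact = inact_idx[:n_ref_inact], inact_idx[n_ref_inact:]
    if max_inactive_ratio is not None:
        cap = int(max_inactive_ratio * len(ref_act))
        if len(ref_inact) > cap:
            keep = rng.choice(len(ref_inact), size=cap, replace=False)
            dropped = np.delete(ref_inact, keep)
            ref_inact = ref_inact[np.sort(keep)]
            test_inact = np.concatenate([test_inact, dropped])

    a_ids, i_ids = ac.active_ids, ac.inactive_ids
    ref_ids = [a_ids[i] for i in ref_act] + [i_ids[i] for i in ref_inact]
    ref_fps = np.concatenate([ac.active_fps[ref_act], ac.inactive_fps[ref_inact]])
    ref_labels = np.array(["active"] * len(ref_act) + ["inactive"] * len(ref_inact))
    test_ids = [a_ids[i] for i in test_act] + [i_ids[i] for i in test_inact]
    test_fps = np.concatenate([ac.active_fps[test_act], ac.inactive_fps[test_inact]])
    test_labels = np.array(["active"] * len(test_act) + ["inactive"] * len(test_inact))
    bg_ids, bg_fps = background if background is not None else ([], None)
    return SplitDataset(
        class_id=ac.class_id,
        query_ids=[a_ids[i] for i in centroid_idx],
        query_fps=ac.active_fps[centroid_idx],
        reference_ids=ref_ids,
        reference_fps=ref_fps,
        reference_labels=ref_labels,
        test_ids=test_ids,
        test_fps=test_fps,
        test_labels=test_labels,
        background_ids=list(bg_ids),
        background_fps=bg_fps,
    )


def _flip_bits(rng: np.random.Generator, proto: np.ndarray, n: int, flip_rate: float) -> np.ndarray:
    flips = rng.random((n, proto.shape[0])) < flip_rate
    return np.where(flips, 1 - proto[None, :], proto[None, :]).astype(np.uint8)


def _member_rates(rng: np.random.Generator, n: int, flip_rate: float, spread: float) -> np.ndarray:
    # per-compound flip rates, uniform in flip_rate*(1 ± spread); exactly 0 stays 0
    return flip_rate * (1.0 + spread * (2.0 * rng.random(n) - 1.0))


def generate_synthetic_class(
    n_scaffolds: int = 4,
    actives_per_scaffold: int = 36,
    n_near_inactives: int = 1200,
    n_far_inactives: int = 600,
    n_background: int = 10_000,
    M: int = 1024,
    flip_rate: float = 0.035,
    flip_spread: float = 0.8,
    near_flip_rate: float = 0.03,
    n_subfamilies: int = 3,
    sub_flip_rate: float = 0.02,
    bit_density: float = 55 / 1024,
    seed: int = 0,
    class_id: str = "synthetic",
) -> tuple[ActivityClass, tuple[list[str], np.ndarray]]:
    """Synthetic activity class of scaffold families plus a decoy background.

    ``n_scaffolds`` prototype fingerprints are drawn with independent bits
    set at ``bit_density`` (≈55 on-bits at M=1024, a realistic popcount for
    hashed circular fingerprints of drug-like molecules).  Each scaffold
    branches into ``n_subfamilies`` sub-prototypes (the prototype with an
    extra ``sub_flip_rate`` of bit flips), emulating the related analogue
    series that different assays contribute to one target: members of
    sibling sub-series are only weakly similar to each other, so a single
    query covers its own series well but reaches siblings only through
    reference neighbors — the situation the MAX-fusion engines exploit.
    Each active is a sub-prototype copy with every bit flipped
    independently; the per-compound flip probability is drawn uniformly
    from ``flip_rate*(1 ± flip_spread)`` so series mix close and distant
    members (``flip_rate=0`` with ``sub_flip_rate=0`` gives exact copies).

    Near-inactives model activity cliffs: each scaffold prototype is
    offset once by an extra ``near_flip_rate`` of bit flips into a "cliff
    prototype", and near-inactives are drawn around these cliff prototypes
    with the same per-compound flip distribution as the actives — a
    structurally coherent inactive series sitting right next to each active
    series, so that an inactive decoy really is more similar to inactive
    references than to active ones (the situation the neighbor
    classification rule exploits).  Far inactives and the unknown-label
    background are independent random fingerprints with the same expected
    popcount.  Fully reproducible from ``seed``.
    """
    if not (0 <= flip_rate < 0.5):
        raise ValueError("flip_rate must be in [0, 0.5)")
    if not (0 <= near_flip_rate < 0.5):
        raise ValueError("near_flip_rate must be in [0, 0.5)")
    if not (0 <= flip_spread <= 1):
        raise ValueError("flip_spread must be in [0, 1]")
    if n_subfamilies < 1:
        raise ValueError("n_subfamilies must be >= 1")
    rng = np.random.default_rng(seed)
    protos = (rng.random((max(n_scaffolds, 1), M)) < bit_density).astype(np.uint8)

    actives = []
    for s in range(n_scaffolds):
        sub_protos = _flip_bits(rng, protos[s], n_subfamilies, sub_flip_rate)
        rates = _member_rates(rng, actives_per_scaffold, flip_rate, flip_spread)
        members = [
            _flip_bits(rng, sub_protos[j % n_subfamilies], 1, rates[j])[0]
            for j in range(actives_per_scaffold)
        ]
        if members:
            actives.append(np.stack(members))
    active_fps = (
        np.concatenate(actives) if actives else np.zeros((0, M), dtype=np.uint8)
    )
    active_ids = [f"{class_id}_act{j}" for j in range(active_fps.shape[0])]

    cliff_protos = np.stack(
        [_flip_bits(rng, protos[s], 1, near_flip_rate)[0] for s in range(max(n_scaffolds, 1))]
    )
    near_rates = _member_rates(rng, n_near_inactives, flip_rate, flip_spread)
    near = [
        _flip_bits(rng, cliff_protos[j % len(cliff_protos)], 1, near_rates[j])[0]
        for j in range(n_near_inactives)
    ]
    far = (rng.random((n_far_inactives, M)) < bit_density).astype(np.uint8)
    inactive_fps = (
        np.concatenate([np.array(near, dtype=np.uint8).reshape(-1, M), far])
        if (near or n_far_inactives)
        else np.zeros((0, M), dtype=np.uint8)
    )
    inactive_ids = [f"{class_id}_inact{j}" for j in range(inactive_fps.shape[0])]

    bg_fps = (rng.random((n_background, M)) < bit_density).astype(np.uint8)
    bg_ids = [f"{class_id}_bg{j}" for j in range(n_background)]

    ac = ActivityClass(
        class_id=class_id,
        active_ids=active_ids,
        active_fps=active_fps,
        inactive_ids=inactive_ids,
        inactive_fps=inactive_fps,
    )
    return ac, (bg_ids, bg_fps)
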