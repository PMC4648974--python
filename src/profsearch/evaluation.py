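"""Recall, precision, ROC-AUC and enrichment metrics, plus paired
engine-vs-engine comparisons.

The recall rate of one query is the fraction of test-set actives present in
its truncated hit list:

    RR = count(active_hit) / count(active_testset)

The precision rate counts only explicitly annotated hits — database
compounds of unknown bioactivity are excluded from both numerator and
denominator, because an unannotated hit is neither a success nor a failure:

    PR = count(active_hit) / (count(active_hit) + count(inactive_hit))

ROC AUC is the rank statistic (probability that a random test active
outscores a random annotated test inactive, ties counted ½) computed over
the full ranking; compounds rejected by the neighbor-classification rule
carry a score of -inf so that falsely rejecting an active lowers the AUC.

Undefined metrics (no actives in the test set, no labeled hits, no
inactives) propagate as NaN and are excluded from class means, never
silently reported as 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from profsearch.search import HitList, SearchResult


def recall_rate(hits: HitList, test_labels: dict[str, str]) -> float:
    """Fraction of test-set actives retrieved in the hit list.

    ``test_labels`` maps compound id -> "active"/"inactive" for the test
    set; hits without an entry are unknown-label and ignored.  NaN when the
    test set has no actives.
    """
    n_test_actives = sum(1 for lab in test_labels.values() if lab == "active")
    if n_test_actives == 0:
        return float("nan")
    n_hit = sum(1 for cid in hits.ids if test_labels.get(cid) == "active")
    return n_hit / n_test_actives


def precision_rate(hits: HitList, test_labels: dict[str, str]) -> float:
    """Active hits over labeled (active + inactive) hits; NaN if none labeled."""
    n_act = sum(1 for cid in hits.ids if test_labels.get(cid) == "active")
    n_inact = sum(1 for cid in hits.ids if test_labels.get(cid) == "inactive")
    if n_act + n_inact == 0:
        return float("nan")
    return n_act / (n_act + n_inact)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random active outscores random inactive), ties ½.

    ``labels`` holds "active"/"inactive"; anything else is excluded.
    Infinite scores (e.g. -inf for rejected compounds) are handled by the
    rank formulation.  NaN when either label class is empty.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    sel = (labels == "active") | (labels == "inactive")
    scores, labels = scores[sel], labels[sel]
    pos = labels == "active"
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties as ½ wins
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def enrichment_factor(hits: HitList, test_labels: dict[str, str], db_size: int) -> float:
    """Top-k enrichment: active hit-rate divided by active prevalence.

    ``EF = (active_hits / |hits|) / (test_actives / db_size)`` with
    ``db_size`` the number of screened database compounds.  NaN when the
    prevalence or the hit list is empty.
    """
    n_test_actives = sum(1 for lab in test_labels.values() if lab == "active")
    if n_test_actives == 0 or db_size == 0 or len(hits) == 0:
        return float("nan")
    n_hit = sum(1 for cid in hits.ids if test_labels.get(cid) == "active")
    return (n_hit / len(hits)) / (n_test_actives / db_size)


def query_metrics(result: SearchResult, test_labels: dict[str, str]) -> dict:
    """All per-query metrics for one engine run.

    The AUC is computed over the full ranking restricted to labeled test
    compounds, with rejected compounds at -inf.
    """
    scores = np.where(result.kept, result.scores, -np.inf)
    labels = np.array([test_labels.get(cid, "unknown") for cid in result.db_ids])
    hits = result.hits
    n_act = sum(1 for cid in hits.ids if test_labels.get(cid) == "active")
    n_inact = sum(1 for cid in hits.ids if test_labels.get(cid) == "inactive")
    return {
        "engine": result.engine,
        "query_id": result.query_id,
        "rr": recall_rate(hits, test_labels),
        "pr": precision_rate(hits, test_labels),
        "auc": roc_auc(scores, labels),
        "ef": enrichment_factor(hits, test_labels, len(result.db_ids)),
        "n_active_hits": n_act,
        "n_inactive_hits": n_inact,
        "compression_ratio": result.model.compression_ratio if result.model else 1.0,
    }


def summarize_classes(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-(class, engine) means: ARR, APR, mean AUC, AEF.

    NaN per-query values are excluded from the means; the count of excluded
    queries is reported per row.
    """
    def agg(group: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "arr": group["rr"].mean(),
                "apr": group["pr"].mean(),
                "mean_auc": group["auc"].mean(),
                "aef": group["ef"].mean(),
                "mean_compression": group["compression_ratio"].mean(),
                "n_queries": len(group),
                "n_undefined": int(group[["rr", "pr", "auc", "ef"]].isna().any(axis=1).sum()),
            }
        )

    out = (
        metrics.groupby(["class_id", "engine"], sort=False)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    return out


def compare_engines(metrics: pd.DataFrame, engine_a: str, engine_b: str) -> pd.DataFrame:
    """Paired per-class comparison of two engines.

    For each class: ΔARR, ΔAPR, ΔAUC (A − B) and a two-sided Mann–Whitney U
    test on the per-query value distributions.  Both engines must have run
    on exactly the same classes (and the same queries, which a shared split
    guarantees).
    """
    a = metrics[metrics["engine"] == engine_a]
    b = metrics[metrics["engine"] == engine_b]
    classes_a, classes_b = set(a["class_id"]), set(b["class_id"])
    if classes_a != classes_b:
        raise ValueError(
            f"engines ran on different class sets: {sorted(classes_a ^ classes_b)}"
        )
    rows = []
    for class_id in a["class_id"].drop_duplicates():
        ga = a[a["class_id"] == class_id]
        gb = b[b["class_id"] == class_id]
        row = {"class_id": class_id, "engine_a": engine_a, "engine_b": engine_b}
        for col, name in (("auc", "d_auc"), ("rr", "d_arr"), ("pr", "d_apr")):
            row[name] = ga[col].mean() - gb[col].mean()
        va, vb = ga["rr"].dropna(), gb["rr"].dropna()
        if len(va) and len(vb) and (va.nunique() > 1 or vb.nunique() > 1 or va.iloc[0] != vb.iloc[0]):
            row["u_pvalue"] = float(mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        else:
            row["u_pvalue"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
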