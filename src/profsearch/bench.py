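"""Config-driven benchmark orchestration over many activity classes.

A benchmark run takes a set of activity classes (synthetic by default),
splits each into query / reference / test sets, runs every configured
engine for every query, and writes three CSV files plus a run manifest:

* ``metrics.csv``   — one row per (class, query, engine)
* ``summary.csv``   — per-(class, engine) ARR / APR / mean AUC / AEF
* ``comparison.csv`` — paired engine-vs-engine deltas with Mann–Whitney p

All randomness derives from the config seed; each class gets its own
child seed, so results are independent of processing order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from profsearch.curation import generate_synthetic_class, split_class
from profsearch.evaluation import compare_engines, query_metrics, summarize_classes
from profsearch.search import ENGINES, run_search

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkConfig:
    engines: list[str] = field(default_factory=lambda: list(ENGINES))
    n_classes: int = 20
    neighbor_cutoff: float = 0.3
    cluster_cutoff: float = 0.4
    div_cutoff: float = 0.35  # query-set clustering cutoff
    top_fraction: float = 0.01
    seed: int = 0
    # synthetic-class parameters (see curation.generate_synthetic_class)
    synthetic: dict = field(default_factory=dict)
    max_queries_per_class: int | None = None

    def __post_init__(self) -> None:
        for name in ("neighbor_cutoff", "cluster_cutoff", "div_cutoff", "top_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        unknown = set(self.engines) - set(ENGINES)
        if unknown:
            raise ValueError(f"unknown engines in config: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _class_seed(seed: int, index: int) -> int:
    # per-class child seed; independent of worker count / processing order
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def run_class(config: BenchmarkConfig, class_index: int) -> pd.DataFrame:
    """Generate, split and screen one synthetic class with every engine."""
    seed = _class_seed(config.seed, class_index)
    ac, (bg_ids, bg_fps) = generate_synthetic_class(
        seed=seed, class_id=f"class{class_index}", **config.synthetic
    )
    split = split_class(ac, div_cutoff=config.div_cutoff, seed=(seed + 1) % 2**31, background=(bg_ids, bg_fps))
    db_ids = list(split.background_ids) + list(split.test_ids)
    db_fps = np.concatenate([split.background_fps, split.test_fps])
    test_labels = dict(zip(split.test_ids, split.test_labels))

    query_ids = split.query_ids
    query_fps = split.query_fps
    if config.max_queries_per_class is not None and len(query_ids) > config.max_queries_per_class:
        rng = np.random.default_rng((seed + 2) % 2**31)
        pick = np.sort(rng.choice(len(query_ids), config.max_queries_per_class, replace=False))
        query_ids = [query_ids[i] for i in pick]
        query_fps = query_fps[pick]

    rows = []
    for qid, qfp in zip(query_ids, query_fps):
        for engine in config.engines:
            result = run_search(
                engine,
                qid,
                qfp,
                db_ids,
                db_fps,
                split.reference_ids,
                split.reference_fps,
                split.reference_labels,
                neighbor_cutoff=config.neighbor_cutoff,
                cluster_cutoff=config.cluster_cutoff,
                top_fraction=config.top_fraction,
                exclude_ids=set(query_ids),
            )
            row = query_metrics(result, test_labels)
            row["class_id"] = ac.class_id
            rows.append(row)
        logger.debug("class %s query %s done", ac.class_id, qid)
    logger.info("class %s: %d queries × %d engines", ac.class_id, len(query_ids), len(config.engines))
    return pd.DataFrame(rows)


def run_benchmark(config: BenchmarkConfig, out_dir: str | Path | None = None):
    """Run the full benchmark; optionally write CSVs and a run manifest.

    Returns ``(metrics, summary, comparison)`` DataFrames.  Per-class
    failures are logged and skipped; the manifest records how many.
    """
    frames = []
    n_failed = 0
    for ci in range(config.n_classes):
        try:
            frames.append(run_class(config, ci))
        except Exception:
            logger.exception("class %d failed; skipping", ci)
            n_failed += 1
    metrics = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    front = ["class_id", "query_id", "engine"]
    metrics = metrics[front + [c for c in metrics.columns if c not in front]]
    summary = summarize_classes(metrics)
    comparisons = [
        compare_engines(metrics, a, b) for a, b in combinations(config.engines, 2)
    ]
    comparison = pd.concat(comparisons, ignore_index=True) if comparisons else pd.DataFrame()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out_dir / "metrics.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
        comparison.to_csv(out_dir / "comparison.csv", index=False)
        cfg = asdict(config)
        manifest = {
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "seed": config.seed,
            "n_classes_failed": n_failed,
            "versions": _versions(),
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return metrics, summary, comparison


def _versions() -> dict:
    import numpy
    import pandas
    import scipy

    import profsearch

    return {
        "profsearch": profsearch.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
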