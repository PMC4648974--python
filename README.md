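# profsearch

Target-class–enhanced 2D similarity searching for virtual screening.

Conventional ligand-based virtual screening ranks a compound database by the
Tanimoto similarity of each compound's binary fingerprint to a single query
molecule. When other known actives (and known inactives) for the same target
are available, they can be folded into the search: as extra search units
fused by their best match, as averaged consensus profiles that compress
structurally related references, and as a rejection filter that discards
database compounds resembling inactives more than actives. `profsearch`
implements this family of six search engines together with the supporting
machinery — activity-class curation and splitting, sphere-exclusion
clustering, a synthetic activity-class generator, and a benchmarking and
evaluation harness — so the whole pipeline can be exercised end to end
without any proprietary data.

## The six engines

| Engine  | Search units                         | Inactive rejection |
|---------|--------------------------------------|--------------------|
| `css`   | query fingerprint only               | no  |
| `pbss`  | one averaged profile of query + active neighbors | no  |
| `iss`   | query + each active neighbor, MAX fusion | no  |
| `pbiss` | per-cluster averaged profiles, MAX fusion | no  |
| `isc`   | query + active neighbors vs. inactive neighbors | yes |
| `pbisc` | per-cluster profiles of both labels  | yes |

All engines share the same pipeline: known references with Tanimoto
similarity to the query strictly above the neighbor cutoff (default 0.3)
form the neighbor list; profile engines compress that list with
Taylor–Butina clustering at the cluster cutoff (default 0.4) and replace
each cluster with the element-wise mean of its member fingerprints; the
database is scored by MAX group fusion over the active units; rejection
engines additionally discard any database compound whose best inactive-unit
similarity is at least its best active-unit similarity. The hit list is the
top 1% of the database (ties broken by ascending compound id).

## Quick start (Python API)

Generate a synthetic activity class, split it into query / reference /
test sets, and compare three engines on one query:

```python
import numpy as np
from profsearch import generate_synthetic_class, split_class, run_search
from profsearch.evaluation import recall_rate, roc_auc

ac, background = generate_synthetic_class(seed=7)
split = split_class(ac, div_cutoff=0.35, seed=7, background=background)

db_ids = list(split.background_ids) + list(split.test_ids)
db_fps = np.concatenate([split.background_fps, split.test_fps])
test_labels = dict(zip(split.test_ids, split.test_labels))

query_id, query_fp = split.query_ids[0], split.query_fps[0]
for engine in ("css", "iss", "isc"):
    result = run_search(
        engine, query_id, query_fp, db_ids, db_fps,
        split.reference_ids, split.reference_fps, split.reference_labels,
        exclude_ids=set(split.query_ids),
    )
    scores = np.where(result.kept, result.scores, -np.inf)
    labels = np.array([test_labels.get(i, "unknown") for i in result.db_ids])
    print(f"{engine}: recall={recall_rate(result.hits, test_labels):.3f} "
          f"auc={roc_auc(scores, labels):.3f} hits={len(result.hits)}")
```

Output:

```
css: recall=0.215 auc=0.622 hits=109
iss: recall=0.277 auc=0.658 hits=109
isc: recall=0.277 auc=0.641 hits=109
```

Reference-enhanced fusion (`iss`) recovers test actives that the single
query fingerprint misses, and rejection (`isc`) keeps that recall while
filtering compounds that look more like known inactives.

## Command line

```sh
# screen a database with one engine
profsearch run --engine isc --query q.smi --db db.smi \
    --refs refs.csv --out hits.csv

# run the full synthetic benchmark from a YAML config
profsearch bench --config bench.yaml --out results/

# materialize synthetic activity classes as fingerprint files
profsearch synth --config synth.yaml --out classes/
```

`--refs` is a CSV with `compound_id,label` columns (labels `active` /
`inactive`); reference structures come from the same file when it carries
a `smiles` column, or from a separate fingerprint file via `--refs-fps`.
Query/database files may be SMILES (`.smi`), SDF (`.sdf`, needs the `chem`
extra) or precomputed fingerprint tables (`id<TAB>bitstring`).

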