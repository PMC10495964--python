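# jscore

Clustering-accuracy measurement via **bidirectional Jaccard set matching**.

When a dataset's true class labels are known, the quality of a clustering
result can be judged by how well the hypothetical clusters recover the
classes. Unidirectional set-matching scores (H-score, F-score) match each
class to one best cluster and then ignore every cluster that was not chosen —
so two partitions that differ only by such "stray" clusters receive identical
scores. The J-score closes that gap by matching in both directions.

## The measure

For `N` samples with class labels `t ∈ T` and cluster assignments `k ∈ K`,
let `V_t` and `V_k` be the corresponding sample sets. Each class/cluster pair
gets a Jaccard index

```
I(t,k) = |V_t ∩ V_k| / |V_t ∪ V_k|
```

Each class takes its best cluster, `I_t = max_k I(t,k)`, and each cluster its
best class, `I_k = max_t I(t,k)`. The size-weighted sums

```
R = Σ_t (|V_t|/N) · I_t        P = Σ_k (|V_k|/N) · I_k
```

are recall- and precision-like aggregates, and

```
J = 2RP / (R + P)
```

is their harmonic mean. `J` is bounded in (0, 1], reaches 1 exactly when the
two partitions coincide, and — because every cluster contributes to `P` —
strictly penalises stray clusters. Under random (independent) cluster
assignment the score has an analytic chance baseline `J₀`, which reduces to
`1/(|T|+|K|−1)` when all classes and clusters have equal sizes
(`jscore.expected_baseline`, `jscore.uniform_baseline`).

The package also implements, from their standard formulas, the measures J is
usually compared with — H-score, F-score, Rand index and adjusted Rand index,
NMI, normalised variation of information and V-measure — plus partition
simulators (predetermined, uniformly random, split/merge of the true
classes) and the Iris/Wine K-means and Ward-hierarchical benchmark
protocols, so the full behaviour of all measures can be reproduced end to
end.

## Worked example

The canonical stray-cluster configuration: 100 samples in three classes of
10/30/60; clusters `K1` and `K2` reproduce the first two classes, while the
60-sample class is cut into `K3` (40 samples) and `K4` (20 samples).

```python
from jscore import worked_example_pair, score_all
report = score_all(worked_example_pair("stray"))
print(report.scores)   # ScoreReport(R=0.8, P=0.7333..., J=0.7652...)
```

or, from a two-column label file on the command line:

```
$ jscore score demo_labels.tsv
{
  "J": 0.7652173913043478,
  "R": 0.7999999999999999,
  "P": 0.7333333333333334,
  "H": 0.2,
  "F": 0.88,
  ...
  "matches": {
    ...
    "stray_clusters": ["K4"],
    "split_classes": ["Tc"]
  }
}
```

Reading the numbers: classes `Ta` and `Tb` are recovered perfectly and the
large class `Tc` matches `K3` at Jaccard 2/3, giving `R = 0.8`; in the
reverse direction the stray cluster `K4` drags `P` down to 0.7333, and
`J = 0.77` (2 d.p.). The unidirectional scores never see `K4`: `H = 0.20`
and `F = 0.88`. Splitting `K4` into two clusters of 10
(`worked_example_pair("stray-split")`) leaves H and F **unchanged** while J
drops to 0.75 — the behaviour the bidirectional design exists to provide.

Other entry points:

```
jscore match similarity.csv            # bidirectional matching of any similarity table
jscore simulate classnum --classes 10 --reps 50 --seed 1 --out-prefix out/cn
jscore simulate baseline --n 1000 --kmin 2 --kmax 50 --seed 1 --out-prefix out/bl
jscore benchmark --dataset iris --method kmeans --reps 100 --seed 1 --out-prefix out/iris
```

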