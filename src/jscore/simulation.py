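"""Partition-structure simulators and the two simulation experiments.

Ground truth is drawn from narrow Gaussians, one per class, so class
membership is unambiguous; hypothetical partitions are then simulated three
ways, none of which runs a clustering algorithm:

* **predetermined** — an explicit point-to-cluster assignment (used for the
  worked examples with stray clusters);
* **random** — cluster sizes drawn uniformly over the positive compositions
  of N into K parts (stars and bars), then the ordered label list is permuted;
* **split/merge** — starting from the true classes, clusters are recursively
  split at uniform ratios (or merged) until K clusters remain, so the
  hypothetical partition stays nested around the truth.

``class_number_experiment`` sweeps K with split/merge partitions to ask which
measures peak at the true class count; ``baseline_experiment`` scores pairs of
independent random partitions (or a random partition against fixed truth) to
chart each measure's chance baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparison import SIMILARITY_METRICS, similarity_panel
from .core import LabelPair

__all__ = [
    "ClassSpec",
    "ExperimentResult",
    "gaussian_classes",
    "worked_example_truth",
    "worked_example_pair",
    "WORKED_EXAMPLE_VARIANTS",
    "predetermined_partition",
    "random_partition",
    "split_merge_partition",
    "class_number_experiment",
    "baseline_experiment",
]


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ClassSpec:
    """Sizes and Gaussian means of the true classes; shared sd defaults to 0.05."""

    sizes: tuple[int, ...]
    means: tuple[float, ...]
    sd: float = 0.05

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.means):
            raise ValueError("sizes and means must have equal length")
        if len(self.sizes) == 0:
            raise ValueError("at least one class required")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("class sizes must be positive")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    @property
    def n(self) -> int:
        return int(sum(self.sizes))


def gaussian_classes(
    spec: ClassSpec, seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one value per sample from its class Gaussian G(mean, sd).

    Returns ``(values, true_labels)`` with labels ``T1, T2, ...`` in class
    order; samples of a class are contiguous, mirroring index-based cluster
    constructions. Only the labels feed the accuracy measures — the values
    exist to make demos and sanity checks concrete.
    """
    rng = _as_rng(seed)
    values = np.concatenate(
        [rng.normal(m, spec.sd, size=s) for s, m in zip(spec.sizes, spec.means)]
    )
    labels = np.concatenate(
        [np.full(s, f"T{i + 1}", dtype=object) for i, s in enumerate(spec.sizes)]
    )
    return values, labels


# ---------------------------------------------------------------------------
# worked examples: 100 points in three classes of 10/30/60
# ---------------------------------------------------------------------------

WORKED_EXAMPLE_VARIANTS = ("stray", "stray-split", "merged", "merged-split")


def worked_example_truth() -> np.ndarray:
    """True labels of the worked example: classes Ta/Tb/Tc of sizes 10/30/60."""
    return np.concatenate(
        [np.full(10, "Ta", dtype=object), np.full(30, "Tb", dtype=object), np.full(60, "Tc", dtype=object)]
    )


def _worked_example_clusters(variant: str) -> dict[str, list[int]]:
    a = list(range(0, 10))
    b = list(range(10, 40))
    c = list(range(40, 100))
    if variant == "stray":
        # K1=Ta, K2=Tb, K3=first 40 of Tc, K4=last 20 of Tc (K4 is stray)
        return {"K1": a, "K2": b, "K3": c[:40], "K4": c[40:]}
    if variant == "stray-split":
        # the stray K4 split into two clusters of 10
        return {"K1": a, "K2": b, "K3": c[:40], "K4.1": c[40:50], "K4.2": c[50:]}
    if variant == "merged":
        # K1 mixes 70% of every class (7/21/42 points); K2 holds the rest
        k1 = a[:7] + b[:21] + c[:42]
        k2 = a[7:] + b[21:] + c[42:]
        return {"K1": k1, "K2": k2}
    if variant == "merged-split":
        # as "merged" but the stray K2 split into two equal halves; points are
        # dealt alternately so each half keeps K2's class mix (a contiguous cut
        # would hand one half a class majority and change the best matches)
        k1 = a[:7] + b[:21] + c[:42]
        k2 = a[7:] + b[21:] + c[42:]
        return {"K1": k1, "K2.1": k2[0::2], "K2.2": k2[1::2]}
    raise ValueError(f"unknown variant {variant!r}; choose from {WORKED_EXAMPLE_VARIANTS}")


def worked_example_pair(variant: str = "stray") -> LabelPair:
    """One of the four canonical stray-cluster configurations.

    ``stray``: four clusters, the truth except the largest class is cut 40/20,
    leaving a stray cluster. ``stray-split``: its stray cluster split in two —
    a strictly worse partition that unidirectional scores cannot tell apart
    from ``stray``. ``merged``: two clusters mixing 70%/30% of every class.
    ``merged-split``: the 30% cluster split in half.
    """
    truth = worked_example_truth()
    clusters = predetermined_partition(_worked_example_clusters(variant), n=100)
    return LabelPair(truth, clusters)


def predetermined_partition(assignment: dict[str, list[int]], n: int) -> np.ndarray:
    """Cluster labels from an explicit cluster -> point-indices map.

    The index lists must partition ``range(n)``; clusters must be non-empty.
    """
    labels = np.full(n, None, dtype=object)
    total = 0
    for name, idx in assignment.items():
        if len(idx) == 0:
            raise ValueError(f"cluster {name!r} is empty")
        for i in idx:
            if not (0 <= i < n):
                raise ValueError(f"index {i} out of range for N={n}")
            if labels[i] is not None:
                raise ValueError(f"index {i} assigned to two clusters")
            labels[i] = name
        total += len(idx)
    if total != n:
        raise ValueError(f"cluster sizes sum to {total}, expected N={n}")
    return labels


def random_composition(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """A uniform draw from the positive compositions of n into k parts.

    Stars and bars: choose k-1 distinct cut points among the n-1 gaps.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= K <= N, got K={k}, N={n}")
    cuts = np.sort(rng.choice(n - 1, size=k - 1, replace=False)) + 1
    return np.diff(np.concatenate([[0], cuts, [n]])).astype(np.int64)


def random_partition(
    n: int, k: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Random partition of n points into k non-empty clusters.

    Cluster sizes are a uniform positive composition of n; the ordered label
    list (label ``Kj`` repeated size_j times) is then permuted.
    """
    rng = _as_rng(seed)
    sizes = random_composition(n, k, rng)
    ordered = np.concatenate(
        [np.full(s, f"K{j + 1}", dtype=object) for j, s in enumerate(sizes)]
    )
    return rng.permutation(ordered)


def split_merge_partition(
    true_labels: np.ndarray,
    k: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Partition obtained from the true classes by random splits or merges.

    While fewer than ``k`` clusters exist, a uniformly chosen cluster of size
    >= 2 is split at a uniform ratio (split size uniform on 1..size-1, member
    points chosen at random); while more than ``k`` exist, a uniformly chosen
    pair is merged.  Splitting is recursive, so any ``k`` up to N is reachable.
    At ``k`` equal to the number of true classes the truth is returned intact.
    """
    rng = _as_rng(seed)
    true_labels = np.asarray(true_labels, dtype=object)
    n = len(true_labels)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= K <= N, got K={k}, N={n}")
    order = sorted(set(true_labels), key=str)
    groups: list[np.ndarray] = [np.flatnonzero(true_labels == lab) for lab in order]
    while len(groups) < k:
        eligible = [i for i, g in enumerate(groups) if len(g) >= 2]
        i = eligible[rng.integers(len(eligible))]
        g = rng.permutation(groups[i])
        s = int(rng.integers(1, len(g)))
        groups[i] = g[:s]
        groups.append(g[s:])
    while len(groups) > k:
        i, j = rng.choice(len(groups), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        groups[i] = np.concatenate([groups[i], groups[j]])
        del groups[j]
    labels = np.empty(n, dtype=object)
    for j, g in enumerate(groups):
        labels[g] = f"K{j + 1}"
    return labels


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentResult:
    """Tidy per-replicate scores, per-K summaries, and per-metric peak K.

    ``scores`` has columns (metric, K, replicate, value); ``summary`` has
    (metric, K, mean, sd); ``peaks`` maps each similarity-direction metric to
    the K with the highest mean score (smallest K on ties).
    """

    scores: pd.DataFrame
    summary: pd.DataFrame
    peaks: dict[str, int]

    def to_summary_dict(self) -> dict:
        return {
            "peaks": self.peaks,
            "mean_by_k": {
                m: dict(zip(g["K"].astype(int), g["mean"]))
                for m, g in self.summary.groupby("metric")
            },
        }


def _summarise(rows: list[dict], peak_metrics: list[str]) -> ExperimentResult:
    scores = pd.DataFrame(rows, columns=["metric", "K", "replicate", "value"])
    summary = (
        scores.groupby(["metric", "K"], sort=True)["value"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    peaks: dict[str, int] = {}
    for m in peak_metrics:
        sub = summary[summary["metric"] == m].sort_values("K")
        if len(sub):
            # smallest K on ties: idxmax returns the first of the K-sorted rows
            peaks[m] = int(sub.loc[sub["mean"].idxmax(), "K"])
    return ExperimentResult(scores, summary, peaks)


def _equal_class_labels(n_classes: int, n: int) -> np.ndarray:
    sizes = np.full(n_classes, n // n_classes, dtype=int)
    sizes[: n % n_classes] += 1
    return np.concatenate(
        [np.full(s, f"T{i + 1}", dtype=object) for i, s in enumerate(sizes)]
    )


def class_number_experiment(
    n_classes: int,
    n: int = 1000,
    k_range: range | list[int] | None = None,
    reps: int = 50,
    seed: int | np.random.Generator | None = None,
    metrics: list[str] | None = None,
) -> ExperimentResult:
    """Sweep K with split/merge partitions of equal-size true classes.

    For each K in ``k_range`` (default 1..50), ``reps`` split/merge partitions
    are generated and scored against the truth; a measure fit for inferring
    the class count should peak, in mean, at K = ``n_classes``.
    """
    rng = _as_rng(seed)
    if k_range is None:
        k_range = range(1, 51)
    metrics = list(metrics) if metrics is not None else list(SIMILARITY_METRICS)
    truth = _equal_class_labels(n_classes, n)
    rows: list[dict] = []
    for k in k_range:
        for rep in range(reps):
            clusters = split_merge_partition(truth, k, rng)
            panel = similarity_panel(LabelPair(truth, clusters), metrics=metrics)
            rows.extend(
                {"metric": m, "K": int(k), "replicate": rep, "value": v}
                for m, v in panel.items()
            )
    return _summarise(rows, [m for m in metrics if m in SIMILARITY_METRICS])


def baseline_experiment(
    n: int = 1000,
    k_range: range | list[int] | None = None,
    reps: int = 50,
    seed: int | np.random.Generator | None = None,
    metrics: list[str] | None = None,
    true_labels: np.ndarray | None = None,
) -> ExperimentResult:
    """Chance-baseline sweep: similarity of independent random partitions.

    With ``true_labels`` unset, each replicate scores two independent random
    partitions of n points into K clusters against each other; with
    ``true_labels`` given, one random partition is scored against that fixed
    truth (the real-data baseline mode).  A measure with a stable baseline
    should flatten out as K grows.
    """
    rng = _as_rng(seed)
    if k_range is None:
        k_range = range(2, 51)
    metrics = list(metrics) if metrics is not None else list(SIMILARITY_METRICS)
    if true_labels is not None:
        true_labels = np.asarray(true_labels, dtype=object)
        if len(true_labels) != n:
            raise ValueError("true_labels length must equal n")
    rows: list[dict] = []
    for k in k_range:
        for rep in range(reps):
            right = random_partition(n, k, rng)
            left = true_labels if true_labels is not None else random_partition(n, k, rng)
            panel = similarity_panel(LabelPair(left, right), metrics=metrics)
            rows.extend(
                {"metric": m, "K": int(k), "replicate": rep, "value": v}
                for m, v in panel.items()
            )
    return _summarise(rows, [m for m in metrics if m in SIMILARITY_METRICS])
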