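"""J-score: clustering accuracy through bidirectional Jaccard set matching.

Given ``N`` samples carrying a true class label and a hypothetical cluster
assignment, the J-score quantifies how well the clusters recover the classes.
For each class/cluster pair the Jaccard index

    I(t, k) = |V_t ∩ V_k| / |V_t ∪ V_k|

is computed, where ``V_t`` and ``V_k`` are the sample sets of class ``t`` and
cluster ``k``.  Each class is matched to its best cluster (``I_t = max_k
I(t,k)``) and, reversing direction, each cluster to its best class (``I_k =
max_t I(t,k)``).  The size-weighted sums

    R = Σ_t (|V_t|/N) · I_t        P = Σ_k (|V_k|/N) · I_k

are recall- and precision-like aggregates, and the J-score is their harmonic
mean ``J = 2RP/(R+P)``.  Because matching is bidirectional, "stray" clusters —
clusters that no class selects — still feed the score through ``P``, which is
what distinguishes J from unidirectional matching scores (H-score, F-score).

The module also provides the analytic chance baseline ``J0`` obtained by
plugging the expected cell counts under independent labels into the Jaccard
ratio, and a generic bidirectional-matching utility for arbitrary similarity
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabelPair",
    "ContingencyTable",
    "JaccardMatrix",
    "MatchResult",
    "ScoreReport",
    "BaselineSpec",
    "BaselineResult",
    "build_contingency",
    "jaccard_matrix",
    "bidirectional_match",
    "j_score",
    "match_similarity_table",
    "expected_baseline",
    "uniform_baseline",
    "round_score",
]

Label = Hashable


def _sorted_labels(values: Sequence[Label]) -> list[Label]:
    """Distinct labels in lexicographic order of their string form.

    This order is the deterministic tie-break used everywhere a best match is
    selected; weighted sums are order-independent but match reports are not.
    """
    return sorted(set(values), key=str)


def round_score(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.765 -> 0.77), for printed-value comparisons.

    Scores are stored at full precision; this is only for display and for
    matching conventionally rounded reference values, where banker's rounding
    would disagree.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LabelPair:
    """Paired true-class and cluster labels for N samples.

    Parameters
    ----------
    true_labels, cluster_labels:
        Equal-length sequences of hashable labels (strings or integers).
        Missing values (None/NaN) are rejected: silently dropping them would
        change N and every size weight.
    """

    true_labels: np.ndarray
    cluster_labels: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.true_labels, dtype=object)
        k = np.asarray(self.cluster_labels, dtype=object)
        if t.ndim != 1 or k.ndim != 1:
            raise ValueError("label columns must be one-dimensional")
        if len(t) != len(k):
            raise ValueError(
                f"label columns differ in length: {len(t)} vs {len(k)}"
            )
        if len(t) == 0:
            raise ValueError("empty partition")
        for name, col in (("true", t), ("cluster", k)):
            mask = pd.isna(col)
            if mask.any():
                i = int(np.flatnonzero(mask)[0])
                raise ValueError(f"missing {name} label at row {i}")
        object.__setattr__(self, "true_labels", t)
        object.__setattr__(self, "cluster_labels", k)

    @property
    def n(self) -> int:
        return len(self.true_labels)

    @property
    def classes(self) -> list[Label]:
        return _sorted_labels(self.true_labels)

    @property
    def clusters(self) -> list[Label]:
        return _sorted_labels(self.cluster_labels)

    def swapped(self) -> "LabelPair":
        """The pair with the two label columns exchanged."""
        return LabelPair(self.cluster_labels, self.true_labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LabelPair":
        """Build from the first two columns of a data frame (true, cluster)."""
        if df.shape[1] < 2:
            raise ValueError("label table needs two columns: true, cluster")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


@dataclass(frozen=True)
class ContingencyTable:
    """Class-by-cluster intersection counts |V_t ∩ V_k|.

    Rows follow the sorted class labels, columns the sorted cluster labels;
    row sums are class sizes, column sums cluster sizes, grand total N.
    """

    counts: np.ndarray
    row_labels: list[Label]
    col_labels: list[Label]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def class_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def cluster_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass(frozen=True)
class JaccardMatrix:
    """Pairwise Jaccard indices I(t,k), same row/column order as the counts."""

    values: np.ndarray
    row_labels: list[Label]
    col_labels: list[Label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)


@dataclass(frozen=True)
class MatchResult:
    """Bidirectional best-match correspondence between classes and clusters.

    ``class_to_cluster`` maps every class to its best cluster and I_t;
    ``cluster_to_class`` maps every cluster to its best class and I_k.
    ``stray_clusters`` are clusters never selected by a class;
    ``split_classes`` are classes selected by two or more clusters.
    """

    class_to_cluster: dict[Label, tuple[Label, float]]
    cluster_to_class: dict[Label, tuple[Label, float]]
    stray_clusters: set[Label] = field(default_factory=set)
    split_classes: set[Label] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "class_to_cluster": {
                str(t): {"cluster": str(k), "jaccard": v}
                for t, (k, v) in self.class_to_cluster.items()
            },
            "cluster_to_class": {
                str(k): {"class": str(t), "jaccard": v}
                for k, (t, v) in self.cluster_to_class.items()
            },
            "stray_clusters": sorted(map(str, self.stray_clusters)),
            "split_classes": sorted(map(str, self.split_classes)),
        }


@dataclass(frozen=True)
class ScoreReport:
    """The weighted sums R (class side), P (cluster side) and J = 2RP/(R+P)."""

    R: float
    P: float
    J: float

    def to_dict(self) -> dict:
        return {"J": self.J, "R": self.R, "P": self.P}


def build_contingency(pair: LabelPair) -> ContingencyTable:
    """Tabulate |V_t ∩ V_k| for every class/cluster pair.

    Label order is the deterministic sorted order; every row and column is
    non-empty by construction.
    """
    rows = pair.classes
    cols = pair.clusters
    ri = {lab: i for i, lab in enumerate(rows)}
    ci = {lab: j for j, lab in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    t_idx = np.fromiter((ri[x] for x in pair.true_labels), dtype=np.intp, count=pair.n)
    k_idx = np.fromiter((ci[x] for x in pair.cluster_labels), dtype=np.intp, count=pair.n)
    np.add.at(counts, (t_idx, k_idx), 1)
    return ContingencyTable(counts, rows, cols)


def jaccard_matrix(ct: ContingencyTable) -> JaccardMatrix:
    """I(t,k) = n_tk / (|V_t| + |V_k| - n_tk); denominators are positive."""
    n = ct.counts.astype(float)
    union = ct.class_sizes[:, None] + ct.cluster_sizes[None, :] - n
    return JaccardMatrix(n / union, ct.row_labels, ct.col_labels)


def _argmax_maps(
    values: np.ndarray, row_labels: Sequence[Label], col_labels: Sequence[Label]
) -> tuple[dict, dict, set, set]:
    """Row-wise and column-wise best matches with first-in-sorted-order ties."""
    row_best = {
        row_labels[i]: (col_labels[int(np.argmax(values[i]))], float(values[i].max()))
        for i in range(values.shape[0])
    }
    col_best = {
        col_labels[j]: (row_labels[int(np.argmax(values[:, j]))], float(values[:, j].max()))
        for j in range(values.shape[1])
    }
    chosen_cols = {k for k, _ in row_best.values()}
    stray = {k for k in col_labels if k not in chosen_cols}
    picked_rows = [t for t, _ in col_best.values()]
    split = {t for t in set(picked_rows) if picked_rows.count(t) >= 2}
    return row_best, col_best, stray, split


def bidirectional_match(jm: JaccardMatrix) -> MatchResult:
    """Match each class to its best cluster and each cluster to its best class.

    Equal Jaccard maxima are resolved in favour of the first label in sorted
    order so results are platform-independent.
    """
    c2k, k2c, stray, split = _argmax_maps(jm.values, jm.row_labels, jm.col_labels)
    return MatchResult(c2k, k2c, stray, split)


def match_similarity_table(
    table: pd.DataFrame | np.ndarray,
    row_labels: Sequence[Label] | None = None,
    col_labels: Sequence[Label] | None = None,
) -> MatchResult:
    """Bidirectional best-match correspondence for an arbitrary similarity table.

    Accepts any rectangular table of finite real similarities (rows = classes,
    columns = clusters); returns the same correspondence report as
    :func:`bidirectional_match` but computes no weighted scores, so it works
    with similarity measures other than the Jaccard index (centroid
    distances converted to similarities, per-pair F1, ...).
    """
    if isinstance(table, pd.DataFrame):
        values = table.to_numpy(dtype=float)
        row_labels = list(table.index)
        col_labels = list(table.columns)
    else:
        values = np.asarray(table, dtype=float)
        if values.ndim != 2:
            raise ValueError("similarity table must be two-dimensional")
        row_labels = list(row_labels) if row_labels is not None else list(range(values.shape[0]))
        col_labels = list(col_labels) if col_labels is not None else list(range(values.shape[1]))
    if values.size == 0:
        raise ValueError("empty similarity table")
    if not np.all(np.isfinite(values)):
        raise ValueError("similarity table contains non-finite values")
    c2k, k2c, stray, split = _argmax_maps(values, row_labels, col_labels)
    return MatchResult(c2k, k2c, stray, split)


def _scores_from_jaccard(jm: JaccardMatrix, ct: ContingencyTable) -> ScoreReport:
    w_t = ct.class_sizes / ct.n
    w_k = ct.cluster_sizes / ct.n
    r = float(w_t @ jm.values.max(axis=1))
    p = float(w_k @ jm.values.max(axis=0))
    return ScoreReport(R=r, P=p, J=2.0 * r * p / (r + p))


def j_score(pair: LabelPair) -> ScoreReport:
    """J-score of a label pair, with its R and P components.

    Swapping the two label columns swaps R and P and leaves J unchanged; J is
    bounded in (0, 1] and equals 1 exactly when the two columns induce the
    same partition.
    """
    ct = build_contingency(pair)
    return _scores_from_jaccard(jaccard_matrix(ct), ct)


@dataclass(frozen=True)
class BaselineSpec:
    """Class and cluster size vectors for the analytic chance baseline."""

    class_sizes: np.ndarray
    cluster_sizes: np.ndarray
    n: int

    def __post_init__(self) -> None:
        a = np.asarray(self.class_sizes, dtype=np.int64)
        b = np.asarray(self.cluster_sizes, dtype=np.int64)
        if a.size == 0 or b.size == 0:
            raise ValueError("size vectors must be non-empty")
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("sizes must be positive")
        if a.sum() != self.n or b.sum() != self.n:
            raise ValueError(
                f"size vectors must both sum to N={self.n} "
                f"(got {int(a.sum())} and {int(b.sum())})"
            )
        object.__setattr__(self, "class_sizes", a)
        object.__setattr__(self, "cluster_sizes", b)

    @classmethod
    def from_pair(cls, pair: LabelPair) -> "BaselineSpec":
        ct = build_contingency(pair)
        return cls(ct.class_sizes, ct.cluster_sizes, ct.n)


@dataclass(frozen=True)
class BaselineResult:
    """Chance-baseline components: per-class I0t, per-cluster I0k, R0, P0, J0."""

    i0t: np.ndarray
    i0k: np.ndarray
    R0: float
    P0: float
    J0: float


def expected_baseline(spec: BaselineSpec) -> BaselineResult:
    """Analytic chance baseline of the J-score for given size vectors.

    Under independent class and cluster labels the expected intersection count
    is |V_t||V_k|/N.  Substituting that expectation into the Jaccard ratio and
    maximising (the ratio is increasing in the partner's size, so the largest
    cluster/class always wins) gives the closed forms

        I0t = |V_t||V_k_max| / ((N-|V_t|)|V_k_max| + N|V_t|)
        I0k = |V_k||V_t_max| / ((N-|V_k|)|V_t_max| + N|V_k|)

    and J0 as the harmonic mean of the size-weighted sums R0, P0.  This is a
    plug-in expectation (expected counts substituted into a ratio), not the
    exact expectation of J; Monte-Carlo shuffles agree closely for moderate N.
    """
    a = spec.class_sizes.astype(float)
    b = spec.cluster_sizes.astype(float)
    n = float(spec.n)
    b_max = b.max()
    a_max = a.max()
    i0t = a * b_max / ((n - a) * b_max + n * a)
    i0k = b * a_max / ((n - b) * a_max + n * b)
    r0 = float((a / n) @ i0t)
    p0 = float((b / n) @ i0k)
    return BaselineResult(i0t, i0k, r0, p0, 2.0 * r0 * p0 / (r0 + p0))


def uniform_baseline(n_classes: int, n_clusters: int) -> float:
    """Chance baseline 1/(|T|+|K|-1) when all classes and clusters are equal-sized.

    Strictly decreasing in both arguments: the baseline maximises (at 1) for a
    single class vs a single cluster and shrinks as either partition refines.
    """
    if n_classes < 1 or n_clusters < 1:
        raise ValueError("n_classes and n_clusters must be positive")
    return 1.0 / (n_classes + n_clusters - 1)
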