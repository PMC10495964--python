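"""Comparison panel of external cluster-validity measures.

Implements, from their standard published formulas, the measures the J-score
is usually weighed against:

* **H-score** — after matching each class to the cluster sharing the most
  points, the fraction of points left unmatched (a distance; 1-H is the
  similarity form).
* **F-score** — class-size-weighted sum of each class's best F1 over clusters
  (precision n/|V_k|, recall n/|V_t|).
* **RI / ARI** — pair-counting agreement over all C(N,2) sample pairs and its
  chance-corrected (permutation-model) form.
* **NMI** — mutual information normalised by the geometric mean of the two
  partition entropies.
* **NVI** — variation of information normalised to [0,1] by the joint entropy
  (NVI = 1 - I(T;K)/H(T,K)); a distance, with 1-NVI the similarity form.
* **V-measure** — harmonic mean of homogeneity and completeness.

All entropies use the natural log (the normalised quantities are
base-invariant).  Every function accepts a :class:`~jscore.core.LabelPair`;
``score_all`` computes the whole panel plus the J-score report from a single
shared contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ContingencyTable,
    LabelPair,
    MatchResult,
    ScoreReport,
    _scores_from_jaccard,
    bidirectional_match,
    build_contingency,
    jaccard_matrix,
)

__all__ = [
    "MetricPanel",
    "ClusteringReport",
    "h_score",
    "f_score",
    "rand_index",
    "adjusted_rand_index",
    "nmi",
    "nvi",
    "v_measure",
    "score_all",
    "similarity_panel",
    "SIMILARITY_METRICS",
]

# similarity-direction metric names used by the experiment runners
SIMILARITY_METRICS = ["J", "F", "1-H", "RI", "ARI", "NMI", "1-NVI", "V"]


@dataclass(frozen=True)
class MetricPanel:
    """The seven comparison measures, with distance forms alongside 1-x."""

    h: float
    one_minus_h: float
    f: float
    ri: float
    ari: float
    nmi: float
    nvi: float
    one_minus_nvi: float
    v_measure: float

    def to_dict(self) -> dict:
        return {
            "H": self.h,
            "1-H": self.one_minus_h,
            "F": self.f,
            "RI": self.ri,
            "ARI": self.ari,
            "NMI": self.nmi,
            "NVI": self.nvi,
            "1-NVI": self.one_minus_nvi,
            "V": self.v_measure,
        }


@dataclass(frozen=True)
class ClusteringReport:
    """J-score report, comparison panel and match diagnostics for one pair."""

    scores: ScoreReport
    panel: MetricPanel
    matches: MatchResult

    def to_dict(self) -> dict:
        out = self.scores.to_dict()
        out.update(self.panel.to_dict())
        out["matches"] = self.matches.to_dict()
        return out


def _h_from_ct(ct: ContingencyTable) -> float:
    # per class, the best cluster is the one sharing the most points
    return float((ct.class_sizes - ct.counts.max(axis=1)).sum() / ct.n)


def _f_from_ct(ct: ContingencyTable) -> float:
    n = ct.counts.astype(float)
    prec = n / ct.cluster_sizes[None, :]
    rec = n / ct.class_sizes[:, None]
    denom = prec + rec
    with np.errstate(invalid="ignore"):
        f1 = np.where(denom > 0, 2.0 * prec * rec / np.where(denom > 0, denom, 1.0), 0.0)
    w = ct.class_sizes / ct.n
    return float(w @ f1.max(axis=1))


def _comb2(x: np.ndarray | float) -> np.ndarray | float:
    return x * (x - 1) / 2.0


def _ri_from_ct(ct: ContingencyTable) -> float:
    n = ct.n
    if n < 2:
        raise ValueError("pair-counting indices need at least two samples")
    total = _comb2(float(n))
    same_both = _comb2(ct.counts.astype(float)).sum()
    same_t = _comb2(ct.class_sizes.astype(float)).sum()
    same_k = _comb2(ct.cluster_sizes.astype(float)).sum()
    # agreements = pairs together in both + pairs apart in both
    agree = total + 2.0 * same_both - same_t - same_k
    return float(agree / total)


def _ari_from_ct(ct: ContingencyTable) -> float:
    n = ct.n
    if n < 2:
        raise ValueError("pair-counting indices need at least two samples")
    total = _comb2(float(n))
    index = _comb2(ct.counts.astype(float)).sum()
    sum_t = _comb2(ct.class_sizes.astype(float)).sum()
    sum_k = _comb2(ct.cluster_sizes.astype(float)).sum()
    expected = sum_t * sum_k / total
    max_index = 0.5 * (sum_t + sum_k)
    if max_index == expected:
        # both partitions trivial (all-in-one or all-singletons): perfect agreement
        return 1.0
    return float((index - expected) / (max_index - expected))


def _entropies(ct: ContingencyTable) -> tuple[float, float, float, float]:
    """(H(T), H(K), I(T;K), H(T,K)) in nats, by direct summation."""
    n = float(ct.n)
    p_t = ct.class_sizes / n
    p_k = ct.cluster_sizes / n
    h_t = float(-(p_t @ np.log(p_t)))
    h_k = float(-(p_k @ np.log(p_k)))
    nz = ct.counts > 0
    p_tk = ct.counts[nz] / n
    h_joint = float(-(p_tk @ np.log(p_tk)))
    mi = h_t + h_k - h_joint
    return h_t, h_k, max(mi, 0.0), h_joint


def _nmi_from_ct(ct: ContingencyTable) -> float:
    h_t, h_k, mi, _ = _entropies(ct)
    if h_t == 0.0 and h_k == 0.0:
        return 1.0  # both partitions trivial and therefore identical
    if h_t == 0.0 or h_k == 0.0:
        return 0.0  # one side carries no information to share
    return float(np.clip(mi / np.sqrt(h_t * h_k), 0.0, 1.0))


def _nvi_from_ct(ct: ContingencyTable) -> float:
    _, _, mi, h_joint = _entropies(ct)
    if h_joint == 0.0:
        return 0.0  # single class and single cluster: identical partitions
    return float(np.clip(1.0 - mi / h_joint, 0.0, 1.0))


def _v_from_ct(ct: ContingencyTable) -> float:
    h_t, h_k, mi, _ = _entropies(ct)
    homogeneity = 1.0 if h_t == 0.0 else mi / h_t
    completeness = 1.0 if h_k == 0.0 else mi / h_k
    if homogeneity + completeness == 0.0:
        return 0.0
    return float(2.0 * homogeneity * completeness / (homogeneity + completeness))


def h_score(pair: LabelPair) -> float:
    """Fraction of points unmatched after class-to-cluster shared-count matching."""
    return _h_from_ct(build_contingency(pair))


def f_score(pair: LabelPair) -> float:
    """Class-size-weighted sum of each class's best F1 over clusters."""
    return _f_from_ct(build_contingency(pair))


def rand_index(pair: LabelPair) -> float:
    """Fraction of sample pairs grouped consistently in both partitions."""
    return _ri_from_ct(build_contingency(pair))


def adjusted_rand_index(pair: LabelPair) -> float:
    """Rand index corrected for chance under the permutation model."""
    return _ari_from_ct(build_contingency(pair))


def nmi(pair: LabelPair) -> float:
    """Mutual information over the geometric mean of the partition entropies."""
    return _nmi_from_ct(build_contingency(pair))


def nvi(pair: LabelPair) -> float:
    """Variation of information normalised by the joint entropy (a distance)."""
    return _nvi_from_ct(build_contingency(pair))


def v_measure(pair: LabelPair) -> float:
    """Harmonic mean of homogeneity and completeness."""
    return _v_from_ct(build_contingency(pair))


def score_all(pair: LabelPair) -> ClusteringReport:
    """Every measure, computed once from one shared contingency table."""
    ct = build_contingency(pair)
    jm = jaccard_matrix(ct)
    scores = _scores_from_jaccard(jm, ct)
    h = _h_from_ct(ct)
    v_nvi = _nvi_from_ct(ct)
    panel = MetricPanel(
        h=h,
        one_minus_h=1.0 - h,
        f=_f_from_ct(ct),
        ri=_ri_from_ct(ct) if ct.n >= 2 else float("nan"),
        ari=_ari_from_ct(ct) if ct.n >= 2 else float("nan"),
        nmi=_nmi_from_ct(ct),
        nvi=v_nvi,
        one_minus_nvi=1.0 - v_nvi,
        v_measure=_v_from_ct(ct),
    )
    return ClusteringReport(scores, panel, bidirectional_match(jm))


def similarity_panel(pair: LabelPair, metrics: list[str] | None = None) -> dict[str, float]:
    """Similarity-direction values keyed by metric name.

    Keys: ``J R P F H 1-H RI ARI NMI NVI 1-NVI V``; ``metrics`` restricts the
    output (and skips unneeded computation for the expensive experiment loops).
    """
    ct = build_contingency(pair)
    wanted = set(metrics) if metrics is not None else None

    def want(*names: str) -> bool:
        return wanted is None or bool(wanted & set(names))

    out: dict[str, float] = {}
    if want("J", "R", "P"):
        s = _scores_from_jaccard(jaccard_matrix(ct), ct)
        out.update({"J": s.J, "R": s.R, "P": s.P})
    if want("H", "1-H"):
        h = _h_from_ct(ct)
        out.update({"H": h, "1-H": 1.0 - h})
    if want("F"):
        out["F"] = _f_from_ct(ct)
    if want("RI"):
        out["RI"] = _ri_from_ct(ct)
    if want("ARI"):
        out["ARI"] = _ari_from_ct(ct)
    if want("NMI"):
        out["NMI"] = _nmi_from_ct(ct)
    if want("NVI", "1-NVI"):
        x = _nvi_from_ct(ct)
        out.update({"NVI": x, "1-NVI": 1.0 - x})
    if want("V"):
        out["V"] = _v_from_ct(ct)
    if wanted is not None:
        out = {k: v for k, v in out.items() if k in wanted}
    return out
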