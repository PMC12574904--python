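"""Benchmark metrics for inferred gene regulatory networks.

Evaluation follows the standard single-cell GRN benchmarking protocol:
every ordered (TF, gene) pair — including a TF paired with itself — is a
candidate edge; the inferred network scores each candidate (here, by
absolute adjacency weight) and the reference network labels it. Because
true edges are vastly outnumbered by non-edges, the primary metrics are
ratios against a random scorer:

* AUPRC ratio — average precision divided by the positive-class fraction
  (the expected average precision of a random scorer).
* Early precision ratio (EPR) — precision within the top-k candidates,
  k = number of true edges, divided by the ground-truth edge density.

AUROC (probability that a random true edge outscores a random non-edge) is
provided for comparability. Average precision uses the non-interpolated
discrete sum with tied scores handled as a block; EPR handles a tie at the
k-th rank pro-rata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import GroundTruthNetwork
from .model import AdjacencyMatrix

__all__ = ["EdgeScoreSet", "candidate_universe", "score_edges", "auprc",
           "auprc_ratio", "early_precision", "early_precision_ratio",
           "auroc", "grn_metrics"]


@dataclass
class EdgeScoreSet:
    """Scored, labeled candidate edges."""

    pairs: list[tuple[str, str]]
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not (len(self.pairs) == len(self.scores) == len(self.labels)):
            raise ValueError("pairs, scores and labels must have equal length")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("candidate pairs must be unique")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    @property
    def n_positives(self) -> int:
        return int(self.labels.sum())


def candidate_universe(gene_names: Sequence[str], tf_names: Iterable[str],
                       ) -> list[tuple[str, str]]:
    """All ordered (TF, gene) pairs, TF self-pairs included.

    Self-pairs are part of the universe by convention — e.g. 410 TFs over
    1,410 genes yield exactly 410 x 1,410 = 578,100 candidates.
    """
    tf_set = set(tf_names)
    if not tf_set:
        raise ValueError("empty TF set")
    missing = tf_set - set(gene_names)
    if missing:
        raise ValueError(f"TFs absent from gene list: {sorted(missing)[:5]}")
    tfs = [g for g in gene_names if g in tf_set]
    return [(tf, g) for tf in tfs for g in gene_names]


def score_edges(adj: AdjacencyMatrix, truth: GroundTruthNetwork) -> EdgeScoreSet:
    """Score the candidate universe with |adjacency| and label it with truth.

    Ground-truth edges whose endpoints are missing from the adjacency's
    genes were already dropped when the truth was loaded against the gene
    universe; TF self-pairs score normally but can never be labeled true
    (the adjacency diagonal is structurally zero).
    """
    idx = {g: i for i, g in enumerate(adj.gene_names)}
    tfs = [t for t in truth.tf_names if t in idx]
    pairs = candidate_universe(adj.gene_names, tfs)
    w = np.abs(adj.weights)
    scores = np.array([w[idx[a], idx[b]] for a, b in pairs])
    edge_set = truth.edges
    labels = np.array([(a, b) in edge_set for a, b in pairs])
    return EdgeScoreSet(pairs=pairs, scores=scores, labels=labels)


def _check_positives(s: EdgeScoreSet) -> None:
    if s.n_positives == 0:
        raise ValueError("metric undefined without positive labels")


def auprc(s: EdgeScoreSet) -> float:
    """Average precision (non-interpolated AUPRC, block tie handling)."""
    _check_positives(s)
    return float(average_precision_score(s.labels, s.scores))


def auprc_ratio(s: EdgeScoreSet) -> float:
    """Average precision divided by the random-scorer baseline (pos fraction)."""
    _check_positives(s)
    baseline = s.n_positives / len(s.labels)
    return auprc(s) / baseline


def early_precision(s: EdgeScoreSet) -> float:
    """Fraction of true edges within the top-k candidates, k = #positives.

    If the k-th score is tied, the tied block contributes its positives
    pro-rata, so the value is the expectation over random tie orderings.
    """
    _check_positives(s)
    k = s.n_positives
    order = np.argsort(-s.scores, kind="stable")
    sorted_scores = s.scores[order]
    sorted_labels = s.labels[order]
    kth = sorted_scores[k - 1]
    strictly_above = sorted_scores > kth
    n_above = int(strictly_above.sum())
    pos_above = int(sorted_labels[strictly_above].sum())
    tied = s.scores == kth
    n_tied = int(tied.sum())
    pos_tied = int(s.labels[tied].sum())
    take = k - n_above
    return (pos_above + pos_tied * take / n_tied) / k


def early_precision_ratio(s: EdgeScoreSet) -> float:
    """Early precision divided by the ground-truth edge density."""
    density = s.n_positives / len(s.labels)
    return early_precision(s) / density


def auroc(s: EdgeScoreSet) -> float:
    """Mann-Whitney AUROC; ties count one half."""
    _check_positives(s)
    if s.n_positives == len(s.labels):
        raise ValueError("metric undefined without negative labels")
    return float(roc_auc_score(s.labels, s.scores))


def grn_metrics(weights_abs: np.ndarray, truth_adj: np.ndarray,
                tf_mask: np.ndarray | None = None) -> dict[str, float]:
    """Index-space convenience: metrics of |weights| against a true adjacency.

    ``truth_adj`` is the (possibly signed) generating adjacency; an edge is
    any nonzero off-diagonal entry. Candidates are all (TF, gene) pairs
    where TFs are rows flagged by ``tf_mask`` (default: rows with at least
    one true outgoing edge), self-pairs included.
    """
    m = truth_adj.shape[0]
    offdiag = ~np.eye(m, dtype=bool)
    true_edges = (truth_adj != 0) & offdiag
    if tf_mask is None:
        tf_mask = true_edges.any(axis=1)
    if not tf_mask.any():
        raise ValueError("no TF rows")
    rows = np.where(tf_mask)[0]
    scores = weights_abs[rows, :].ravel()
    labels = true_edges[rows, :].ravel()
    pairs = [(f"r{i}", f"t{j}") for i in rows for j in range(m)]
    s = EdgeScoreSet(pairs=pairs, scores=scores, labels=labels)
    return {"auprc": auprc(s), "auprc_ratio": auprc_ratio(s),
            "ep": early_precision(s), "epr": early_precision_ratio(s),
            "auroc": auroc(s)}
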