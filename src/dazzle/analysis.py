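"""Post-inference network analyses: regulation scores, local neighborhoods,
and cross-condition weight scaling.

These are the operations used to read an inferred network biologically:
rank genes by how strongly they are regulated (summed absolute incoming
edge weight above the reporting threshold), pull out the strongest in- and
out-edges around a gene of interest, and compare edge weights across a
series of conditions (e.g. developmental time points) after min-max
scaling within each condition. Absolute weights are used throughout — the
model ranks regulatory strength but does not sign it.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AdjacencyMatrix, extract_edges

__all__ = ["NetworkSeries", "regulation_score", "top_regulated",
           "local_network", "minmax_scale"]

DEFAULT_THRESHOLD = 0.001


@dataclass
class NetworkSeries:
    """Ordered (condition label, adjacency) pairs; labels must be unique."""

    conditions: list[tuple[str, AdjacencyMatrix]]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.conditions]


def regulation_score(adj: AdjacencyMatrix,
                     threshold: float = DEFAULT_THRESHOLD) -> pd.Series:
    """Per-gene regulation score: sum of incoming |weights| above threshold."""
    w = np.abs(adj.weights)
    w = np.where(w > threshold, w, 0.0)
    return pd.Series(w.sum(axis=0), index=adj.gene_names, name="regulation_score")


def top_regulated(adj: AdjacencyMatrix, n: int = 10,
                  threshold: float = DEFAULT_THRESHOLD) -> pd.Series:
    """The n most-regulated genes, ties broken by gene name."""
    scores = regulation_score(adj, threshold)
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return scores.loc[order[:n]]


def local_network(adj: AdjacencyMatrix, center: str, top_k: int,
                  threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """The strongest ``top_k`` in-edges and ``top_k`` out-edges of a gene.

    Edges below the reporting threshold are excluded; rows carry a
    ``direction`` column ("in" or "out"). Ties break lexicographically.
    """
    if center not in adj.gene_names:
        close = difflib.get_close_matches(center, adj.gene_names, n=3)
        hint = f"; did you mean {close}?" if close else ""
        raise KeyError(f"unknown gene {center!r}{hint}")
    edges = extract_edges(adj, threshold)
    incoming = edges[edges["target"] == center].head(top_k).copy()
    incoming["direction"] = "in"
    outgoing = edges[edges["regulator"] == center].head(top_k).copy()
    outgoing["direction"] = "out"
    return pd.concat([incoming, outgoing], ignore_index=True)


def minmax_scale(series: NetworkSeries,
                 edges: list[tuple[str, str]]) -> pd.DataFrame:
    """Min-max scale |weights| of selected edges within each condition.

    Returns a table with one row per edge and one column per condition;
    within a condition, values map to [0, 1] via (w - min) / (max - min)
    over the selected edges only. A condition where all selected weights
    are equal maps to 0. An edge whose endpoints are absent from a
    condition's genes contributes raw weight 0 there.
    """
    if not series.conditions:
        raise ValueError("need at least one condition")
    out = {}
    for label, adj in series.conditions:
        idx = {g: i for i, g in enumerate(adj.gene_names)}
        raw = np.array([abs(adj.weights[idx[a], idx[b]])
                        if a in idx and b in idx else 0.0
                        for a, b in edges])
        lo, hi = raw.min(), raw.max()
        out[label] = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    index = pd.Index([f"{a}->{b}" for a, b in edges], name="edge")
    return pd.DataFrame(out, index=index)
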