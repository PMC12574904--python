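"""Independent brute-force metric oracles used by the test suite.

These deliberately avoid the library code paths (and sklearn): plain loops
over sorted unique scores and over positive x negative pairs.
"""

import numpy as np


def ap_oracle(scores, labels):
    """Non-interpolated average precision, tied scores as one block."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    total_pos = labels.sum()
    ap, tp, seen, prev_recall = 0.0, 0, 0, 0.0
    for s in sorted(set(scores), reverse=True):
        block = scores == s
        tp += labels[block].sum()
        seen += block.sum()
        recall = tp / total_pos
        precision = tp / seen
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def auroc_oracle(scores, labels):
    """Exhaustive positive x negative pair counting, ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def ep_oracle(scores, labels):
    """Expected precision in the top-k (k = positives) over tie orderings."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    k = int(labels.sum())
    kth = sorted(scores, reverse=True)[k - 1]
    above = scores > kth
    tied = scores == kth
    slots = k - above.sum()
    exp_pos = labels[above].sum() + labels[tied].sum() * slots / tied.sum()
    return exp_pos / k
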