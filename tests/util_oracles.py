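"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: coverage counts are
recomputed from per-base depth, start-end probabilities from an explicit
weighted mean, the EM optimum from a dense grid search over the simplex, and
average precision from an exhaustive threshold sweep.
"""

from __future__ import annotations

import itertools

import numpy as np


def per_base_segment_counts(length: int, spans, bin_width: int) -> np.ndarray:
    """Segment counts as (summed per-base depth in the segment) / (segment length)."""
    depth = np.zeros(length)
    for start, end in spans:
        depth[start:end] += 1
    bounds = [(s, min(s + bin_width, length)) for s in range(0, length, bin_width)]
    return np.array([depth[s:e].sum() / (e - s) for s, e in bounds])


def weighted_span_probability(length: int, bin_width: int, probs, span) -> float:
    """Convex combination of segment probabilities weighted by overlapped segment fraction."""
    start, end = span
    weights, values = [], []
    for i, seg_start in enumerate(range(0, length, bin_width)):
        seg_end = min(seg_start + bin_width, length)
        overlap = min(end, seg_end) - max(start, seg_start)
        if overlap > 0:
            weights.append(overlap / (seg_end - seg_start))
            values.append(probs[i])
    weights = np.asarray(weights)
    return float(weights @ np.asarray(values) / weights.sum())


def simplex_grid(n_dims: int, resolution: float) -> np.ndarray:
    """All simplex points with coordinates on a grid of the given resolution."""
    steps = int(round(1.0 / resolution))
    if n_dims == 1:
        return np.array([[1.0]])
    if n_dims == 2:
        a = np.arange(steps + 1) / steps
        return np.column_stack([a, 1.0 - a])
    if n_dims == 3:
        pts = []
        for i in range(steps + 1):
            j = np.arange(steps - i + 1)
            block = np.column_stack(
                [np.full(len(j), i), j, steps - i - j]
            )
            pts.append(block)
        return np.vstack(pts) / steps
    raise NotImplementedError("grid oracle supports up to 3 dimensions")


def grid_search_loglik(q_rows: list[dict[int, float]], n_txp: int, resolution: float = 1e-3):
    """Max log-likelihood over the theta grid for tiny instances.

    ``q_rows[n]`` maps transcript index -> conditional probability for read n.
    """
    grid = simplex_grid(n_txp, resolution)
    total = np.zeros(len(grid))
    for row in q_rows:
        idx = np.fromiter(row.keys(), dtype=int)
        q = np.fromiter(row.values(), dtype=float)
        with np.errstate(divide="ignore"):
            total += np.log(grid[:, idx] @ q)
    best = int(np.nanargmax(np.where(np.isfinite(total), total, -np.inf)))
    return float(total[best]), grid[best]


def brute_force_average_precision(scores, labels) -> float:
    """AP = sum over ranked positives of (recall step) * (precision at that rank)."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    labels = np.asarray(labels, dtype=bool)[order]
    n_pos = labels.sum()
    ap = 0.0
    tp = 0
    # walk distinct score thresholds; ties enter together
    sorted_scores = np.asarray(scores, dtype=float)[order]
    k = 0
    prev_recall = 0.0
    while k < len(labels):
        k2 = k
        while k2 < len(labels) and sorted_scores[k2] == sorted_scores[k]:
            k2 += 1
        tp += labels[k:k2].sum()
        precision = tp / k2
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        k = k2
    return float(ap)
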