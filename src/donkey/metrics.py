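"""Ground-truth clustering evaluation: homogeneity, completeness, V-measure.

All three scores are entropy ratios built from the class-by-cluster
contingency table.  Homogeneity is high when each cluster contains members
of a single class; completeness is high when each class lands in a single
cluster; the V-measure is their harmonic mean.  Natural logarithms are used
throughout — the scores are ratios, so the base cancels.
"""

from __future__ import annotations

import numpy as np

__all__ = ["contingency_table", "homogeneity_completeness_v"]


def contingency_table(truth_labels, cluster_labels) -> np.ndarray:
    """Counts matrix with one row per class and one column per cluster."""
    truth = np.asarray(truth_labels)
    clust = np.asarray(cluster_labels)
    if truth.shape != clust.shape or truth.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    _, ti = np.unique(truth, return_inverse=True)
    _, ci = np.unique(clust, return_inverse=True)
    table = np.zeros((ti.max() + 1, ci.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, ci), 1)
    return table


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy (nats) of a count vector, with 0 log 0 = 0."""
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def homogeneity_completeness_v(truth_labels, cluster_labels):
    """Homogeneity, completeness and V-measure of a labeling, each in [0, 1].

    ``h = 1 - H(class|cluster)/H(class)`` (defined as 1 when the class
    entropy vanishes), ``c = 1 - H(cluster|class)/H(cluster)`` (likewise),
    and ``v = 2hc/(h+c)`` (0 when both vanish).
    """
    table = contingency_table(truth_labels, cluster_labels)
    n = table.sum()
    h_class = _entropy(table.sum(axis=1))
    h_clust = _entropy(table.sum(axis=0))

    # conditional entropies from the joint table
    def conditional(joint, marginal_axis):
        # H(X|Y) = H(X, Y) - H(Y), with Y the margin along marginal_axis
        joint_p = joint[joint > 0] / n
        h_joint = float(-(joint_p * np.log(joint_p)).sum())
        return h_joint - _entropy(joint.sum(axis=marginal_axis))

    h = 1.0 if h_class == 0 else 1.0 - conditional(table, 0) / h_class
    c = 1.0 if h_clust == 0 else 1.0 - conditional(table, 1) / h_clust
    h = float(np.clip(h, 0.0, 1.0))
    c = float(np.clip(c, 0.0, 1.0))
    v = 0.0 if (h + c) == 0 else 2.0 * h * c / (h + c)
    return h, c, v
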