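"""Candidate reduction: RMSD deduplication, uncertainty acceptance, energy discard.

Attack candidates are filtered before the expensive oracle call:

1. near-duplicate structures are merged by agglomerative clustering of the
   pairwise RMSD matrix cut at a distance threshold, keeping one
   representative (the most force-uncertain member) per cluster;
2. only candidates the in-domain classifier marks as *out*-of-domain — i.e.
   committee variance at or above the calibrated threshold — are kept, since
   points the committee already trusts are uninformative;
3. after oracle labeling, samples above an optional energy cap are dropped
   (relevant for torsional systems, where some CV displacements land in
   sterically impossible regions).

Operators never mutate configurations; they only filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .committee import CommitteeResults, InDomainClassifier
from .data import Configuration, LabeledSample

__all__ = [
    "SelectionConfig",
    "pairwise_rmsd",
    "deduplicate",
    "uncertainty_accept",
    "energy_discard",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the selection pipeline.

    ``rmsd_threshold`` cuts the hierarchical-clustering dendrogram;
    ``uncertainty_percentile`` calibrates the in-domain threshold on the
    current training set; ``max_energy_discard`` (None = keep all) caps the
    oracle energy of accepted samples; ``alignment`` optionally removes rigid
    rotations/translations before the RMSD (molecules only); ``linkage``
    picks the agglomeration rule.
    """

    rmsd_threshold: float = 0.02
    uncertainty_percentile: float = 80.0
    max_energy_discard: Optional[float] = None
    alignment: str = "none"
    linkage: str = "average"

    def __post_init__(self):
        if self.rmsd_threshold <= 0:
            raise ValueError("rmsd_threshold must be positive")
        if not 0 < self.uncertainty_percentile < 100:
            raise ValueError("uncertainty_percentile must lie in (0, 100)")
        if self.alignment not in ("none", "optimal-superposition"):
            raise ValueError("alignment must be 'none' or 'optimal-superposition'")
        if self.linkage not in ("average", "single", "complete"):
            raise ValueError("linkage must be average, single or complete")


def _rmsd_pair(a: Configuration, b: Configuration, alignment: str) -> float:
    # coordinate-wise mean convention: sqrt(mean over all scalar components)
    if alignment == "optimal-superposition" and a.kind == "molecule":
        P = a.coords - a.coords.mean(axis=0)
        Q = b.coords - b.coords.mean(axis=0)
        rot, _ = Rotation.align_vectors(P, Q)
        diff = P - rot.apply(Q)
        return float(np.sqrt(np.mean(diff**2)))
    diff = a.flat - b.flat
    return float(np.sqrt(np.mean(diff**2)))


def pairwise_rmsd(configs: Sequence[Configuration], alignment: str = "none") -> np.ndarray:
    """Symmetric zero-diagonal RMSD matrix.

    RMSD is the root of the coordinate-wise mean squared difference — for a
    d-vector this is the Euclidean distance divided by sqrt(d), and for a
    molecule the conventional n-atom RMSD.  With ``optimal-superposition``
    each pair is rigidly aligned (Kabsch) first.
    """
    kinds = {c.kind for c in configs}
    dofs = {c.dof for c in configs}
    if len(kinds) > 1 or len(dofs) > 1:
        raise ValueError("pairwise RMSD requires a homogeneous composition")
    n = len(configs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _rmsd_pair(configs[i], configs[j], alignment)
    return D


def deduplicate(
    configs: Sequence[Configuration],
    committee: Optional[CommitteeResults],
    cfg: SelectionConfig,
) -> List[Configuration]:
    """Merge configurations within ``rmsd_threshold`` by hierarchical clustering.

    One representative survives per cluster: the member with the largest
    committee force variance (the most informative point), or the first
    member when no committee is given.  Output order follows representative
    input order; the result is always a subset of the input.
    """
    if len(configs) == 0:
        raise ValueError("deduplicate needs at least one configuration")
    if len(configs) == 1:
        return list(configs)
    D = pairwise_rmsd(configs, cfg.alignment)
    Z = linkage(squareform(D, checks=False), method=cfg.linkage)
    labels = fcluster(Z, t=cfg.rmsd_threshold, criterion="distance")
    if committee is not None:
        X = np.stack([c.flat for c in configs])
        score = committee.variance_statistic(X, "force_variance")
    else:
        score = -np.arange(len(configs), dtype=float)
    keep = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        keep.append(idx[np.argmax(score[idx])])
    return [configs[i] for i in sorted(keep)]


def uncertainty_accept(
    candidates: Sequence[Configuration],
    committee: CommitteeResults,
    classifier: InDomainClassifier,
) -> List[Configuration]:
    """Keep only candidates classified out-of-domain (variance >= threshold).

    These are the high-uncertainty, informative points worth sending to the
    oracle; in-domain candidates are already well represented in training.
    """
    if len(candidates) == 0:
        return []
    X = np.stack([c.flat for c in candidates])
    values = committee.variance_statistic(X, classifier.statistic)
    return [c for c, v in zip(candidates, values) if classifier.classify_value(v) == 0]


def energy_discard(
    labeled: Sequence[LabeledSample], e_max: Optional[float]
) -> List[LabeledSample]:
    """Drop oracle-labeled samples with energy above ``e_max`` (None = no-op)."""
    if e_max is None:
        return list(labeled)
    kept = [s for s in labeled if s.energy <= e_max]
    if labeled and not kept:
        warnings.warn("energy_discard removed every candidate")
    return kept
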