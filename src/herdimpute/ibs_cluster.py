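"""Pairwise identity-by-state distances and constrained agglomerative clustering.

The similarity between two animals is the classic DST statistic,
``(N_IBS2 + 0.5 * N_IBS1) / N`` over loci non-missing in both: IBS2 means the
genotypes are identical, IBS1 that they share one allele, IBS0 none. The
clustering distance is ``1 - DST``. When the features are window-haplotype
count vectors (quasi-genotypes), the shared-allele count within each window —
``sum_h min(count_a, count_b)`` in {0, 1, 2} — plays the same role, so
genotype- and haplotype-based clustering share one code path.

Animals are merged agglomeratively from singletons, always joining the
closest pair of clusters, down to a fixed cluster count k; k is then reduced
from a starting value until the smallest cluster reaches the required size
(reference populations below ~150 animals are too small to impute from).
PLINK's additional significance-based merge restrictions are not reproduced;
the explicit constraints — fixed k, minimum cluster size — are honoured
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .errors import ConstraintError, IncomparablePairError, ParameterError
from .genodata import MISSING, GenotypeMatrix
from .distances import DistanceMatrix
from .phasing_windows import QuasiGenotypeMatrix


@dataclass
class ClusterAssignment:
    """Mapping of each animal to one cluster label."""

    assignment: dict[str, int]
    k: int

    @property
    def min_size(self) -> int:
        return min(self.sizes().values())

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for lab in self.assignment.values():
            out[lab] = out.get(lab, 0) + 1
        return out

    def members(self, label: int) -> list[str]:
        return [s for s, lab in self.assignment.items() if lab == label]

    def labels_for(self, ids) -> np.ndarray:
        return np.array([self.assignment[i] for i in ids], dtype=int)


def ibs_distance_matrix(features) -> DistanceMatrix:
    """1 - DST distance over genotypes or quasi-genotypes."""
    if isinstance(features, GenotypeMatrix):
        return _ibs_genotypes(features)
    if isinstance(features, QuasiGenotypeMatrix):
        return _ibs_quasi(features)
    raise ParameterError(f"unsupported feature container {type(features).__name__}")


def _ibs_genotypes(gm: GenotypeMatrix) -> DistanceMatrix:
    if gm.n_samples < 2:
        raise ParameterError("need at least 2 samples")
    d = gm.dosage
    valid = (d != MISSING).astype(float)
    shared = valid @ valid.T
    n = gm.n_samples
    if (shared <= 0).any():
        i, j = np.argwhere((shared <= 0) & ~np.eye(n, dtype=bool))[0]
        raise IncomparablePairError(
            f"samples {gm.sample_ids[i]!r} and {gm.sample_ids[j]!r} share no loci"
        )
    # shared alleles at a locus = 2 - |g_a - g_b|, so 1 - DST = mean |diff| / 2
    i0 = ((d == 0) * 1.0)
    i1 = ((d == 1) * 1.0)
    i2 = ((d == 2) * 1.0)
    absdiff = 2.0 * (i0 @ i2.T + i2 @ i0.T) + (i1 @ (i0 + i2).T + (i0 + i2) @ i1.T)
    dist = absdiff / (2.0 * shared)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(list(gm.sample_ids), dist)


def _ibs_quasi(qm: QuasiGenotypeMatrix) -> DistanceMatrix:
    if len(qm.sample_ids) < 2:
        raise ParameterError("need at least 2 samples")
    c = np.asarray(qm.counts, dtype=float)
    # per-window shared alleles = 2 - L1/2, so 1 - DST = total L1 / (4 * n_windows)
    dist = cdist(c, c, metric="cityblock") / (4.0 * qm.n_windows)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(list(qm.sample_ids), dist)


def agglomerate(
    dm: DistanceMatrix,
    k: int,
    min_size: int = 1,
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Cut an agglomerative tree (average linkage by default) at k clusters.

    Merging proceeds from singletons, always joining the pair of clusters at
    the smallest linkage distance; equal-height merges follow a fixed
    deterministic order, so repeated runs agree. Raises
    :class:`ConstraintError` when the resulting partition violates
    ``min_size`` or when (k, min_size) is infeasible outright.
    """
    n = len(dm.ids)
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} outside [1, {n}]")
    if linkage_method not in ("average", "complete", "single"):
        raise ParameterError(f"unsupported linkage {linkage_method!r}")
    if k * min_size > n:
        raise ConstraintError(f"k={k} clusters of >= {min_size} need > {n} samples")
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        z = linkage(squareform(dm.values, checks=False), method=linkage_method)
        labels = fcluster(z, t=k, criterion="maxclust")
    assignment = {s: int(lab) for s, lab in zip(dm.ids, labels)}
    ca = ClusterAssignment(assignment=assignment, k=len(set(labels)))
    if ca.min_size < min_size:
        raise ConstraintError(
            f"smallest cluster has {ca.min_size} < {min_size} animals at k={k}"
        )
    return ca


def choose_k(
    dm: DistanceMatrix,
    start_k: int = 6,
    min_size: int = 150,
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Reduce k from ``start_k`` until no cluster is smaller than ``min_size``.

    Mirrors the fixed-cluster-count search used to size reference
    populations: try k = start_k, start_k - 1, ... and accept the first
    partition whose smallest cluster reaches ``min_size``.
    """
    if start_k < 1:
        raise ParameterError("start_k must be >= 1")
    n = len(dm.ids)
    if n < min_size:
        raise ConstraintError(
            f"only {n} samples; even a single cluster is below min_size={min_size}"
        )
    last_err: ConstraintError | None = None
    for k in range(min(start_k, n), 0, -1):
        try:
            return agglomerate(dm, k, min_size=min_size, linkage_method=linkage_method)
        except ConstraintError as exc:
            last_err = exc
    raise ConstraintError(f"no k in [1, {start_k}] satisfies min_size={min_size}: {last_err}")
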