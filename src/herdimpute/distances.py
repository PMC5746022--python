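"""Euclidean distances between animals, on genotypes or window-haplotype counts.

The distance between animals with feature vectors q and p is
``sqrt(sum_i (q_i - p_i)^2)`` over loci — raw dosage differences, no
per-locus standardisation (an optional centering flag exists for exploratory
use). It proxies genomic relatedness: an animal whose minimum distance to the
sequenced reference is large has no close relative there and is expected to
impute poorly.

With missing data the squared sum runs over pairwise-complete loci and is
rescaled by n_total/n_shared before the square root, keeping distances
comparable across pairs with different missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import HerdimputeError, IncomparablePairError, ParameterError
from .genodata import MISSING, GenotypeMatrix
from .phasing_windows import QuasiGenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ParameterError("distance matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ParameterError("distance matrix not symmetric")
        if not np.isfinite(self.values).all():
            raise ParameterError("distance matrix has non-finite entries")
        np.fill_diagonal(self.values, 0.0)

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        lookup = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([lookup[i] for i in ids], dtype=int)
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)].copy())


@dataclass(frozen=True)
class DistanceSummary:
    """Minimum / mean / maximum distance of one animal to a reference set (self excluded)."""

    sample_id: str
    d_min: float
    d_mean: float
    d_max: float

    def __post_init__(self):
        if not (self.d_min <= self.d_mean + 1e-12 and self.d_mean <= self.d_max + 1e-12):
            raise ParameterError("summary violates d_min <= d_mean <= d_max")


def _feature_array(features) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Extract (ids, float matrix, validity mask) from either feature container."""
    if isinstance(features, GenotypeMatrix):
        x = features.dosage.astype(float)
        valid = features.dosage != MISSING
        x[~valid] = 0.0
        return list(features.sample_ids), x, valid
    if isinstance(features, QuasiGenotypeMatrix):
        x = np.asarray(features.counts, dtype=float)
        return list(features.sample_ids), x, np.ones_like(x, dtype=bool)
    raise ParameterError(f"unsupported feature container {type(features).__name__}")


def euclidean_matrix(features, center: bool = False) -> DistanceMatrix:
    """All-pairs Euclidean distance over genotype dosages or quasi-genotype counts.

    For quasi-genotypes the coordinates are the per-window haplotype count
    vectors concatenated across windows. Pairs sharing zero non-missing loci
    raise :class:`IncomparablePairError`.
    """
    ids, x, valid = _feature_array(features)
    n = len(ids)
    if n < 2:
        raise ParameterError("need at least 2 samples")
    if center:
        mu = np.where(valid, x, np.nan)
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(mu, axis=0)
        mu = np.nan_to_num(mu)
        x = np.where(valid, x - mu, 0.0)

    v = valid.astype(float)
    shared = v @ v.T
    if (shared <= 0).any():
        i, j = np.argwhere((shared <= 0) & ~np.eye(n, dtype=bool))[0]
        raise IncomparablePairError(
            f"samples {ids[i]!r} and {ids[j]!r} share no non-missing loci"
        )
    x2 = x * x
    # sum over shared loci of (q - p)^2, computed with masked cross terms
    sq = x2 @ v.T + v @ x2.T - 2.0 * (x @ x.T)
    sq = np.maximum(sq, 0.0)
    n_total = x.shape[1]
    sq *= n_total / shared
    d = np.sqrt(sq)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d)


def distance_summaries(
    dm: DistanceMatrix,
    reference_ids,
    target_ids=None,
) -> list[DistanceSummary]:
    """Per-target min/mean/max distance to ``reference_ids`` (self always excluded)."""
    lookup = {s: i for i, s in enumerate(dm.ids)}
    ref = [r for r in reference_ids]
    targets = list(target_ids) if target_ids is not None else list(dm.ids)
    for s in ref + targets:
        if s not in lookup:
            raise HerdimputeError(f"sample {s!r} not in distance matrix")
    ref_idx = {lookup[r] for r in ref}
    out = []
    for t in targets:
        ti = lookup[t]
        cols = sorted(ref_idx - {ti})
        if not cols:
            raise HerdimputeError(f"empty reference set for target {t!r} after self-exclusion")
        row = dm.values[ti, cols]
        out.append(
            DistanceSummary(
                sample_id=t,
                d_min=float(row.min()),
                d_mean=float(row.mean()),
                d_max=float(row.max()),
            )
        )
    return out
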