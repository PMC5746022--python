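"""Flagging of predicted-poorly-imputed animals and reference augmentation.

Animals far from the sequenced reference — a mean or minimum Euclidean
distance at least ``k_sd`` standard deviations above the population mean of
that statistic — are expected to impute poorly. For those animals the
reference population is enlarged with the imputed sequences of the
first-wave animals closest to the reference (lowest minimum distance), the
haplotype library is rebuilt, and the flagged animals are re-imputed. The
minimum-distance statistic is the default flag: an animal with no close
relative in the reference benefits most from a richer haplotype library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceSummary
from .errors import ParameterError
from .evaluate import concordance
from .genodata import GenotypeMatrix
from .imputer import HaplotypeLibrary, build_library, impute


def flag_poorly_imputed(
    summaries: list[DistanceSummary],
    statistic: str = "min",
    k_sd: float = 2.0,
) -> set[str]:
    """Ids whose chosen distance statistic is >= mean + k_sd * SD of that statistic.

    The boundary is inclusive ("k or greater standard deviations above the
    mean"). The SD is the sample (n-1) standard deviation. When every value
    is identical the SD is zero and no outlier is definable, so the result
    is empty. Scale-equivariant: rescaling all distances by a positive
    constant leaves the flagged set unchanged.
    """
    if statistic not in ("mean", "min"):
        raise ParameterError(f"statistic must be 'mean' or 'min', got {statistic!r}")
    if len(summaries) < 2:
        raise ParameterError("need at least 2 summaries")
    vals = np.array(
        [s.d_mean if statistic == "mean" else s.d_min for s in summaries], dtype=float
    )
    sd = vals.std(ddof=1)
    if sd == 0:
        return set()
    cut = vals.mean() + k_sd * sd
    return {s.sample_id for s, v in zip(summaries, vals) if v >= cut}


@dataclass
class AugmentationReport:
    """Before/after accuracy comparison for the re-imputed animals."""

    per_animal: pd.DataFrame  # sample_id, before, after, delta
    n_improved: int
    n_worsened: int
    n_unchanged: int
    added_ids: list[str]

    @property
    def mean_before(self) -> float:
        return float(self.per_animal["before"].mean())

    @property
    def mean_after(self) -> float:
        return float(self.per_animal["after"].mean())


def select_added_animals(
    summaries: list[DistanceSummary], first_wave_ids: set[str], n_added: int
) -> list[str]:
    """The n_added first-wave animals with the lowest minimum Euclidean distance."""
    pool = [s for s in summaries if s.sample_id in first_wave_ids]
    if n_added > len(pool):
        raise ParameterError(
            f"n_added={n_added} exceeds the {len(pool)} available first-wave animals"
        )
    pool.sort(key=lambda s: (s.d_min, s.sample_id))
    return [s.sample_id for s in pool[:n_added]]


def stepwise_augmented_imputation(
    flagged_targets: GenotypeMatrix,
    first_wave_imputed: GenotypeMatrix,
    true_reference: GenotypeMatrix,
    summaries: list[DistanceSummary],
    n_added: int,
    truth: GenotypeMatrix | None = None,
    baseline_imputed: GenotypeMatrix | None = None,
    seed: int | None = None,
    top_m: int | None = 50,
    library_builder=None,
) -> tuple[GenotypeMatrix, AugmentationReport | None]:
    """Re-impute flagged animals with imputed sequences added to the reference.

    ``flagged_targets`` hold the flagged animals' observed low-density
    genotypes; ``first_wave_imputed`` the sequence-density imputed genotypes
    of the (disjoint) first-wave animals; ``summaries`` their distance
    summaries, from which the ``n_added`` lowest-minimum-distance animals
    are appended to ``true_reference``. With ``n_added=0`` the result equals
    imputation against the unaugmented reference.

    When ``truth`` and ``baseline_imputed`` are supplied, the report compares
    per-animal concordance before vs after and counts improved / worsened /
    unchanged animals (the three counts partition the flagged set).
    ``library_builder`` may replace :func:`~herdimpute.imputer.build_library`
    (same signature) to reuse precomputed phasings.
    """
    flagged = set(flagged_targets.sample_ids)
    first_wave = set(first_wave_imputed.sample_ids)
    if flagged & first_wave:
        raise ParameterError("flagged ids must be disjoint from first-wave ids")
    if true_reference.site_keys() != first_wave_imputed.site_keys():
        raise ParameterError("first-wave and reference matrices must share sites")

    added = select_added_animals(summaries, first_wave, n_added)
    if added:
        add_gm = first_wave_imputed.subset_samples(added)
        reference = GenotypeMatrix(
            sample_ids=true_reference.sample_ids + add_gm.sample_ids,
            sites=true_reference.sites,
            dosage=np.concatenate([true_reference.dosage, add_gm.dosage], axis=0),
        )
    else:
        reference = true_reference

    builder = library_builder or build_library
    library: HaplotypeLibrary = builder(reference, seed=seed)
    after = impute(flagged_targets, library, seed=seed, top_m=top_m)

    report = None
    if truth is not None and baseline_imputed is not None:
        truth_f = truth.subset_samples(after.sample_ids)
        base_f = baseline_imputed.subset_samples(after.sample_ids)
        rec_after = concordance(after, truth_f)
        rec_before = concordance(base_f, truth_f)
        before = np.array([r.concordance for r in rec_before])
        after_v = np.array([r.concordance for r in rec_after])
        df = pd.DataFrame(
            {
                "sample_id": after.sample_ids,
                "before": before,
                "after": after_v,
                "delta": after_v - before,
            }
        )
        report = AugmentationReport(
            per_animal=df,
            n_improved=int((df["delta"] > 0).sum()),
            n_worsened=int((df["delta"] < 0).sum()),
            n_unchanged=int((df["delta"] == 0).sum()),
            added_ids=added,
        )
    return after, report
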