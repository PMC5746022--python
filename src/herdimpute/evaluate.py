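"""Imputation-accuracy metrics and the five-group within-breed validation design.

Accuracy is judged per animal against the true sequence genotypes:

* **Concordance rate** — the mean of exact-genotype-match indicators; a call
  is correct (1) only when the full genotype matches, so calling a
  heterozygote where the truth is homozygous (or vice versa) scores 0.
* **Rare-site concordance** — the same, restricted to sites with minor
  allele frequency strictly below a threshold (0.05 by default) in a
  designated frequency source; rare variants are the hardest to impute.
* **Allelic R²** — per-animal squared Pearson correlation of imputed on true
  dosages across sites (undefined, hence missing, when either vector is
  constant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParameterError
from .genodata import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AccuracyRecord:
    sample_id: str
    concordance: float
    concordance_rare: float | None
    allelic_r2: float | None
    n_sites: int
    n_rare_sites: int


@dataclass
class ValidationGroups:
    """Group label (0..n_groups-1) per sample."""

    assignment: dict[str, int]
    n_groups: int

    def members(self, g: int) -> list[str]:
        return [s for s, lab in self.assignment.items() if lab == g]


def _check_aligned(imputed: GenotypeMatrix, truth: GenotypeMatrix):
    if imputed.sample_ids != truth.sample_ids:
        raise AlignmentError("imputed and truth matrices have different samples/order")
    if imputed.site_keys() != truth.site_keys():
        raise AlignmentError("imputed and truth matrices have different sites/order")


def concordance(
    imputed: GenotypeMatrix,
    truth: GenotypeMatrix,
    maf_threshold: float = 0.05,
    maf_source: GenotypeMatrix | None = None,
) -> list[AccuracyRecord]:
    """Per-animal concordance, rare-site concordance, and allelic R².

    ``maf_source`` supplies the genotypes from which site MAFs are computed
    for the rare subset; by default the true genotypes of the evaluated
    animals are used, but passing the full reference population's truth
    matrix mirrors a study frame where the gold standard defines frequency.
    Sites where the truth is missing are excluded from numerator and
    denominator alike.
    """
    _check_aligned(imputed, truth)
    src = maf_source if maf_source is not None else truth
    if src.site_keys() != truth.site_keys():
        raise AlignmentError("maf_source sites do not match truth sites")
    freqs = src.allele_frequencies()
    maf = np.minimum(freqs, 1.0 - freqs)
    rare = maf < maf_threshold  # strictly below the threshold

    r2 = allelic_r2(imputed, truth)
    records = []
    t = truth.dosage
    m = imputed.dosage
    valid = (t != MISSING) & (m != MISSING)
    match = (t == m) & valid
    for i, sid in enumerate(truth.sample_ids):
        nv = int(valid[i].sum())
        conc = float(match[i].sum() / nv) if nv else float("nan")
        vr = valid[i] & rare
        nr = int(vr.sum())
        conc_rare = float((match[i] & rare).sum() / nr) if nr else None
        records.append(
            AccuracyRecord(
                sample_id=sid,
                concordance=conc,
                concordance_rare=conc_rare,
                allelic_r2=r2[i],
                n_sites=nv,
                n_rare_sites=nr,
            )
        )
    return records


def allelic_r2(imputed: GenotypeMatrix, truth: GenotypeMatrix) -> list[float | None]:
    """Per-animal squared correlation of imputed on true dosage (None when undefined)."""
    _check_aligned(imputed, truth)
    out: list[float | None] = []
    for i, sid in enumerate(truth.sample_ids):
        t = truth.dosage[i]
        m = imputed.dosage[i]
        valid = (t != MISSING) & (m != MISSING)
        tv = t[valid].astype(float)
        mv = m[valid].astype(float)
        if tv.size < 2 or tv.std() == 0 or mv.std() == 0:
            logger.warning("allelic R2 undefined for %s (constant vector)", sid)
            out.append(None)
            continue
        r = np.corrcoef(mv, tv)[0, 1]
        out.append(float(r * r))
    return out


def accuracy_table(records: list[AccuracyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "concordance": [r.concordance for r in records],
            "concordance_rare": [r.concordance_rare for r in records],
            "allelic_r2": [r.allelic_r2 for r in records],
            "n_sites": [r.n_sites for r in records],
            "n_rare_sites": [r.n_rare_sites for r in records],
        }
    )


def regional_accuracy(
    imputed: GenotypeMatrix,
    truth: GenotypeMatrix,
    region_size_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Concordance pooled over animals within consecutive physical windows.

    Returns a table with chrom, window start/end (bp), pooled concordance
    and site count; windows containing no sites are omitted.
    """
    _check_aligned(imputed, truth)
    if region_size_bp < 1:
        raise ParameterError("region_size_bp must be >= 1")
    t = truth.dosage
    m = imputed.dosage
    valid = (t != MISSING) & (m != MISSING)
    match = (t == m) & valid
    rows = []
    keys = truth.site_keys()
    chroms = np.array([k[0] for k in keys])
    pos = np.array([k[1] for k in keys])
    for chrom in dict.fromkeys(chroms):
        on = chroms == chrom
        bins = (pos[on] - 1) // region_size_bp
        for b in np.unique(bins):
            cols = np.flatnonzero(on)[bins == b]
            nv = int(valid[:, cols].sum())
            if nv == 0:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(b * region_size_bp + 1),
                    "end": int((b + 1) * region_size_bp),
                    "concordance": float(match[:, cols].sum() / nv),
                    "n_sites": len(cols),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "concordance", "n_sites"])


def make_validation_groups(
    sample_ids: list[str],
    breeds: list[str],
    n_groups: int = 5,
    seed: int = 0,
) -> ValidationGroups:
    """Randomly split animals into validation groups, balanced within breed.

    Within each breed the animals are shuffled and dealt round-robin into
    ``n_groups`` subgroups (sizes differ by at most one); the breed subgroups
    are then combined across breeds at random to form the final groups.
    Reproducible for a given seed.
    """
    if n_groups < 2:
        raise ParameterError("n_groups must be >= 2")
    if len(sample_ids) != len(breeds):
        raise ParameterError("sample_ids and breeds must have the same length")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    by_breed: dict[str, list[str]] = {}
    for sid, b in zip(sample_ids, breeds):
        by_breed.setdefault(b, []).append(sid)
    for breed in sorted(by_breed):
        members = sorted(by_breed[breed])
        rng.shuffle(members)
        # deal round-robin into subgroups, then scramble which subgroup
        # feeds which final group for this breed
        relabel = rng.permutation(n_groups)
        for i, sid in enumerate(members):
            assignment[sid] = int(relabel[i % n_groups])
    return ValidationGroups(assignment=assignment, n_groups=n_groups)
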