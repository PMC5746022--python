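"""End-to-end experiment orchestration.

Runs the full reference-design study on one population: mask sequence calls
to nested panels, filter rare alleles, cluster animals (none / genotype IBS
/ haplotype IBS), impute every animal through the two-step design within
five random within-breed validation groups, evaluate per-animal accuracy,
flag and re-impute poorly related animals with an augmented reference, and
fit the accuracy-prediction models. All randomness flows from one top-level
seed through named substreams per stage, so a config+seed pair reproduces a
report exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .acc_model import (
    FULL_CANDIDATES,
    PredictionModel,
    backward_select,
    build_features,
    fit_reduced_model,
    model_to_dict,
)
from .augment import flag_poorly_imputed, select_added_animals
from .distances import distance_summaries, euclidean_matrix
from .errors import ConfigError
from .evaluate import accuracy_table, concordance, make_validation_groups
from .genodata import GenotypeMatrix, filter_min_allele_count, mask_to_panel
from .ibs_cluster import ClusterAssignment, choose_k, ibs_distance_matrix
from .imputer import HaplotypeLibrary, impute, phase_matrix
from .phasing_windows import quasi_genotypes
from .synthpop import SimConfig, simulate_panels, simulate_population

logger = logging.getLogger(__name__)

CLUSTER_MODES = ("all", "plink_geno", "plink_hap")


def _substream(seed: int, name: str) -> int:
    """Deterministic named child seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    """Knobs for one end-to-end run."""

    sim: SimConfig = field(default_factory=SimConfig)
    cluster_mode: str = "plink_hap"
    start_k: int = 6
    # desk-scale analogue of the full study's 150-animal floor: ~20% of the
    # default 200-animal population
    min_cluster_size: int = 40
    n_groups: int = 5
    min_allele_count: int = 4
    maf_threshold: float = 0.05
    flag_statistic: str = "min"
    flag_k_sd: float = 2.0
    n_added: int | None = None  # default: half the non-flagged animals
    window_size: int = 4  # quasi-genotype window for clustering/distances
    top_m: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.cluster_mode not in CLUSTER_MODES:
            raise ConfigError(
                f"cluster_mode must be one of {CLUSTER_MODES}, got {self.cluster_mode!r}"
            )
        if self.n_groups < 2:
            raise ConfigError("n_groups must be >= 2")

    def content_hash(self) -> str:
        payload = {k: v for k, v in sorted(vars(self).items()) if k != "sim"}
        payload["sim"] = dict(sorted(vars(self.sim).items()))
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ExperimentReport:
    """Everything a run produced, with provenance."""

    config: ExperimentConfig
    scenario_table: pd.DataFrame  # per-scenario mean concordance / rare / R2
    per_animal: pd.DataFrame  # accuracy + features + predictions per animal
    clusters: ClusterAssignment | None
    cluster_ari: float | None
    flagged_ids: set[str]
    augmentation: pd.DataFrame | None  # before/after for flagged animals
    n_improved: int | None
    n_worsened: int | None
    n_unchanged: int | None
    full_model: PredictionModel
    reduced_model: PredictionModel
    runs_logged: list[dict]
    timings: dict[str, float]
    provenance: dict[str, Any]

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "scenario_table": self.scenario_table.to_dict(orient="records"),
            "cluster_ari": self.cluster_ari,
            "n_flagged": len(self.flagged_ids),
            "augmentation": {
                "n_improved": self.n_improved,
                "n_worsened": self.n_worsened,
                "n_unchanged": self.n_unchanged,
            },
            "full_model": model_to_dict(self.full_model),
            "reduced_model": model_to_dict(self.reduced_model),
            "runs_logged": self.runs_logged,
            "timings": self.timings,
        }


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Simulate a population and run the whole design on it."""
    timings: dict[str, float] = {}
    runs: list[dict] = []
    seed = config.seed

    def tick(stage):
        timings[stage] = time.time()

    def tock(stage):
        timings[stage] = round(time.time() - timings[stage], 3)
        logger.info("stage %s: %.2fs", stage, timings[stage])

    # -- simulate ----------------------------------------------------------
    tick("simulate")
    sim_cfg = SimConfig(**{**vars(config.sim), "seed": _substream(seed, "simulate")})
    pop = simulate_population(sim_cfg)
    panels, _ = simulate_panels(pop.calls, sim_cfg)
    tock("simulate")

    # -- filter + mask -----------------------------------------------------
    tick("filter")
    calls, removed = filter_min_allele_count(pop.calls, config.min_allele_count)
    # the filtered sequence calls are the study's gold standard ("true sequence")
    truth = calls
    keep_keys = set(s.key for s in calls.sites)
    panel_mid = _restrict_panel(panels["mock777K"], keep_keys)
    panel_low = _restrict_panel(panels["mock50K"], keep_keys)
    low = mask_to_panel(calls, panel_low)
    mid_truth = mask_to_panel(calls, panel_mid)
    tock("filter")
    logger.info("filtered %d rare sites; %d remain", len(removed), calls.n_sites)

    # -- cluster on the 50K view ------------------------------------------
    tick("cluster")
    qg_low = quasi_genotypes(low, window_size=config.window_size)
    if config.cluster_mode == "plink_hap":
        feat = qg_low
    else:
        feat = low
    clusters = None
    ari = None
    if config.cluster_mode != "all":
        dm_ibs = ibs_distance_matrix(feat)
        clusters = choose_k(dm_ibs, start_k=config.start_k, min_size=config.min_cluster_size)
        from sklearn.metrics import adjusted_rand_score

        ari = float(
            adjusted_rand_score(pop.breeds, clusters.labels_for(pop.sample_ids))
        )
    tock("cluster")

    # -- validation groups -------------------------------------------------
    groups = make_validation_groups(
        pop.sample_ids, pop.breeds, n_groups=config.n_groups,
        seed=_substream(seed, "groups"),
    )

    # -- phase everything once per density, subset per reference group -----
    tick("phase")
    phase_seed = _substream(seed, "phase")
    ph_seq = phase_matrix(calls, seed=phase_seed)
    ph_mid = phase_matrix(mid_truth, seed=phase_seed)
    tock("phase")

    # -- two-step imputation per validation group (and per cluster) --------
    tick("impute")
    id_to_row = {s: i for i, s in enumerate(pop.sample_ids)}
    imputed_rows = np.zeros_like(truth.dosage)
    impute_seed = _substream(seed, "impute")
    for g in range(config.n_groups):
        members = sorted(groups.members(g))
        if not members:
            continue
        ref_pool = [s for s in pop.sample_ids if groups.assignment[s] != g]
        if clusters is None:
            ref_sets = {0: ref_pool}
            tgt_sets = {0: members}
        else:
            ref_sets = {}
            tgt_sets = {}
            for lab in sorted(set(clusters.assignment.values())):
                ref_sets[lab] = [s for s in ref_pool if clusters.assignment[s] == lab]
                tgt_sets[lab] = [s for s in members if clusters.assignment[s] == lab]
        for lab, tgts in tgt_sets.items():
            if not tgts:
                continue
            refs = ref_sets[lab]
            if not refs:  # pathological tiny cluster: fall back to full pool
                refs = ref_pool
            ref_rows = np.array([id_to_row[s] for s in refs])
            lib_mid = HaplotypeLibrary.from_phased(ph_mid[ref_rows], mid_truth.sites)
            lib_seq = HaplotypeLibrary.from_phased(ph_seq[ref_rows], calls.sites)
            t0 = time.time()
            step1 = impute(low.subset_samples(tgts), lib_mid,
                           seed=impute_seed, top_m=config.top_m)
            final = impute(step1, lib_seq, seed=impute_seed, top_m=config.top_m)
            for sid, row in zip(final.sample_ids, final.dosage):
                imputed_rows[id_to_row[sid]] = row
            runs.append(
                {
                    "group": g,
                    "cluster": int(lab),
                    "n_targets": len(tgts),
                    "n_reference": len(refs),
                    "seconds": round(time.time() - t0, 3),
                }
            )
    imputed = GenotypeMatrix(pop.sample_ids, truth.sites, imputed_rows,
                             breeds=list(pop.breeds))
    tock("impute")

    # -- evaluate ----------------------------------------------------------
    tick("evaluate")
    records = concordance(imputed, truth, maf_threshold=config.maf_threshold,
                          maf_source=truth)
    acc = accuracy_table(records).set_index("sample_id")
    tock("evaluate")

    # -- distances on the 50K view ----------------------------------------
    tick("distances")
    dm_geno = euclidean_matrix(low)
    dm_hap = euclidean_matrix(qg_low)
    sum_geno = distance_summaries(dm_geno, pop.sample_ids)
    sum_hap = distance_summaries(dm_hap, pop.sample_ids)
    tock("distances")

    # -- augmentation round ------------------------------------------------
    tick("augment")
    flagged = flag_poorly_imputed(sum_geno, statistic=config.flag_statistic,
                                  k_sd=config.flag_k_sd)
    aug_df = None
    n_imp = n_wor = n_unc = None
    if flagged:
        first_wave = [s for s in pop.sample_ids if s not in flagged]
        n_added = config.n_added
        if n_added is None:
            n_added = len(first_wave) // 2
        n_added = min(n_added, len(first_wave))
        added = select_added_animals(sum_geno, set(first_wave), n_added)
        flagged_sorted = sorted(flagged)
        f_rows = np.array([id_to_row[s] for s in flagged_sorted])
        ref_ids = [s for s in first_wave]
        ref_rows = np.array([id_to_row[s] for s in ref_ids])
        added_rows = np.array([id_to_row[s] for s in added])
        # reference = true sequences of non-flagged + imputed sequences of added
        aug_ref = GenotypeMatrix(
            ref_ids + [f"imp:{s}" for s in added],
            calls.sites,
            np.concatenate([calls.dosage[ref_rows], imputed.dosage[added_rows]]),
        )
        lib_aug = HaplotypeLibrary.from_phased(
            phase_matrix(aug_ref, seed=_substream(seed, "augment-phase")),
            calls.sites,
        )
        step1f = impute(low.subset_samples(flagged_sorted),
                        HaplotypeLibrary.from_phased(ph_mid[ref_rows], mid_truth.sites),
                        seed=impute_seed, top_m=config.top_m)
        re_imputed = impute(step1f, lib_aug, seed=impute_seed, top_m=config.top_m)
        before = acc.loc[flagged_sorted, "concordance"].to_numpy()
        rec_after = concordance(re_imputed, truth.subset_samples(flagged_sorted),
                                maf_threshold=config.maf_threshold, maf_source=truth)
        after = np.array([r.concordance for r in rec_after])
        aug_df = pd.DataFrame(
            {"sample_id": flagged_sorted, "before": before, "after": after,
             "delta": after - before}
        )
        n_imp = int((aug_df["delta"] > 0).sum())
        n_wor = int((aug_df["delta"] < 0).sum())
        n_unc = int((aug_df["delta"] == 0).sum())
    tock("augment")

    # -- accuracy prediction models ---------------------------------------
    tick("model")
    if clusters is not None:
        clusters_for_model = clusters
    else:
        dm_ibs_hap = ibs_distance_matrix(qg_low)
        try:
            clusters_for_model = choose_k(dm_ibs_hap, start_k=config.start_k,
                                          min_size=config.min_cluster_size)
        except Exception:
            clusters_for_model = ClusterAssignment(
                {s: 1 for s in pop.sample_ids}, k=1
            )
    features = build_features(
        dist_geno=sum_geno,
        dist_hap=sum_hap,
        clusters_hap=clusters_for_model,
        pedigree=pop.pedigree,
        breeds=pop.breed_of(),
        sequenced_ids=set(pop.sample_ids),
    )
    features = features.loc[acc.index]
    y = acc["concordance"]
    model_seed = _substream(seed, "model")
    cands = [t for t in FULL_CANDIDATES if t in features.columns]
    full_model = backward_select(features, y, cands, seed=model_seed)
    reduced_model = fit_reduced_model(features, y, seed=model_seed)
    preds = full_model.predict(features)
    acc["predicted_full"] = preds
    acc["predicted_reduced"] = reduced_model.predict(features)
    tock("model")

    per_animal = acc.join(features)
    per_animal["breed_label"] = [pop.breed_of()[s] for s in per_animal.index]
    per_animal["group"] = [groups.assignment[s] for s in per_animal.index]

    scen = pd.DataFrame(
        [
            {
                "scenario": config.cluster_mode,
                "concordance": float(acc["concordance"].mean()),
                "concordance_rare": float(acc["concordance_rare"].dropna().mean()),
                "allelic_r2": float(acc["allelic_r2"].dropna().mean()),
                "n_animals": len(acc),
            }
        ]
    )

    provenance = {
        "version": __version__,
        "seed": seed,
        "config_hash": config.content_hash(),
        "n_animals": len(pop.sample_ids),
        "n_sites_filtered": calls.n_sites,
    }
    return ExperimentReport(
        config=config,
        scenario_table=scen,
        per_animal=per_animal,
        clusters=clusters,
        cluster_ari=ari,
        flagged_ids=flagged,
        augmentation=aug_df,
        n_improved=n_imp,
        n_worsened=n_wor,
        n_unchanged=n_unc,
        full_model=full_model,
        reduced_model=reduced_model,
        runs_logged=runs,
        timings=timings,
        provenance=provenance,
    )


def _restrict_panel(panel, keep_keys):
    from .genodata import PanelDefinition

    return PanelDefinition(
        panel.name, tuple(s for s in panel.sites if s.key in keep_keys)
    )
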