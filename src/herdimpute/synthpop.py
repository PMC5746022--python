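"""Synthetic multi-breed diploid populations with nested SNP-panel densities.

The generator emulates the structure the reference-design pipeline needs from
real cattle data without requiring any download: several diverged pure
breeds plus crossbreds, shared haplotype structure arising from a shallow
pedigree with recombination, a "sequence-call" copy of the truth carrying
random miscalls, and nested mock 50K / mock 777K / sequence site lists.

Breed divergence follows the Balding-Nichols model: an ancestral allele
frequency p is drawn per site from a U-shaped Beta(0.5, 0.5), and each
breed's frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) with F the divergence
parameter — the simplest parametric model with a tunable FST. Founder
haplotypes are drawn site-wise from the breed frequencies; descendants are
recombined parental mosaics (crossover count per chromosome ~ Poisson);
crossbreds take one parent from each of two breeds. Everything is
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .genodata import GenotypeMatrix, PanelDefinition, Pedigree, Site, mask_to_panel

CROSSBRED_LABEL = "crossbred"


@dataclass
class SimConfig:
    """Study conditions for the synthetic population.

    Defaults are desk-scale: 3 breeds x 60 animals plus 20 crossbreds
    (200 animals) on one chromosome of 20,000 sequence sites, with the mock
    777K panel a 25% subsample of sequence sites and the mock 50K a 5%
    subsample nested inside it (mirroring the real panels' relative
    densities), moderate breed divergence (F = 0.15), one expected crossover
    per chromosome per meiosis, a two-generation pedigree, and a 0.1%
    sequencing miscall rate.
    """

    n_breeds: int = 3
    n_per_breed: int = 60
    n_crossbred: int = 20
    divergence: float = 0.15
    n_sites_sequence: int = 20_000
    frac_mid: float = 0.25  # mock 777K fraction of sequence sites
    frac_low: float = 0.05  # mock 50K fraction of sequence sites (nested in mid)
    switch_rate: float = 1.0  # expected crossovers per chromosome per gamete
    pedigree_depth: int = 2
    error_rate: float = 0.001
    n_chromosomes: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.divergence < 1:
            raise ConfigError("divergence must be in (0, 1)")
        if not 0 < self.frac_low < self.frac_mid < 1:
            raise ConfigError("need 0 < frac_low < frac_mid < 1 (nested panels)")
        if not 0 <= self.error_rate <= 1:
            raise ConfigError("error_rate must be in [0, 1]")
        if self.switch_rate < 0:
            raise ConfigError("switch_rate must be >= 0")
        if self.n_breeds < 1 or self.n_per_breed < 4:
            raise ConfigError("need >= 1 breed with >= 4 animals each")
        if self.pedigree_depth < 0:
            raise ConfigError("pedigree_depth must be >= 0")
        if self.pedigree_depth > 0 and self.n_per_breed < 2 * (self.pedigree_depth + 1):
            raise ConfigError("pedigree too deep for the per-breed count (too few founders)")
        if int(self.n_sites_sequence * self.frac_low) < 10:
            raise ConfigError("frac_low yields fewer than 10 mock-50K sites")


@dataclass
class SimPopulation:
    """Everything the pipeline consumes, plus the generating truth."""

    truth: GenotypeMatrix  # error-free sequence genotypes
    calls: GenotypeMatrix  # truth with sequencing miscalls applied
    haplotypes: np.ndarray  # (n, 2, n_sites) true phase
    pedigree: Pedigree
    breeds: list[str]
    config: SimConfig

    @property
    def sample_ids(self) -> list[str]:
        return self.truth.sample_ids

    def breed_of(self) -> dict[str, str]:
        return dict(zip(self.truth.sample_ids, self.breeds))


def _sites(cfg: SimConfig, rng: np.random.Generator) -> list[Site]:
    per_chrom = [cfg.n_sites_sequence // cfg.n_chromosomes] * cfg.n_chromosomes
    per_chrom[-1] += cfg.n_sites_sequence - sum(per_chrom)
    bases = np.array(list("ACGT"))
    sites: list[Site] = []
    for c, m in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(np.arange(1, 10 * m + 1), size=m, replace=False))
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            sites.append(Site(chrom=str(c), pos=int(p),
                              ref_allele=str(bases[ref]), alt_allele=str(bases[alt])))
    return sites


def _gamete(hap_pair: np.ndarray, chrom_slices: list[slice],
            switch_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Recombined mosaic of one parent's two haplotypes."""
    L = hap_pair.shape[1]
    out = np.empty(L, dtype=np.int8)
    for sl in chrom_slices:
        m = sl.stop - sl.start
        strand = rng.integers(2)
        n_x = rng.poisson(switch_rate)
        cuts = np.sort(rng.integers(1, m, size=n_x)) if n_x and m > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [m]])
        for k in range(len(bounds) - 1):
            seg = slice(sl.start + bounds[k], sl.start + bounds[k + 1])
            out[seg] = hap_pair[(strand + k) % 2, seg]
    return out


def simulate_population(cfg: SimConfig) -> SimPopulation:
    """Draw a full synthetic population under ``cfg`` (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    sites = _sites(cfg, rng)
    L = len(sites)
    chrom_slices = []
    start = 0
    for c in range(L):
        if c == L - 1 or sites[c + 1].chrom != sites[c].chrom:
            chrom_slices.append(slice(start, c + 1))
            start = c + 1

    p_anc = rng.beta(0.5, 0.5, size=L).clip(0.01, 0.99)
    F = cfg.divergence
    shape = (1.0 - F) / F
    breed_freqs = [
        rng.beta(p_anc * shape, (1.0 - p_anc) * shape).clip(0.0, 1.0)
        for _ in range(cfg.n_breeds)
    ]

    sample_ids: list[str] = []
    breeds: list[str] = []
    haps: list[np.ndarray] = []
    ped_entries: dict[str, tuple[str | None, str | None]] = {}
    by_breed_gen: dict[int, list[list[int]]] = {}  # breed -> generations -> row indices

    def add_animal(sid, breed_label, hap, sire, dam):
        sample_ids.append(sid)
        breeds.append(breed_label)
        haps.append(hap)
        ped_entries[sid] = (sire, dam)
        return len(sample_ids) - 1

    depth = cfg.pedigree_depth
    for b in range(cfg.n_breeds):
        gens: list[list[int]] = [[] for _ in range(depth + 1)]
        # split the breed's animals across generations, founders taking the
        # remainder so every generation has at least two potential parents
        per_gen = max(2, cfg.n_per_breed // (depth + 1)) if depth else cfg.n_per_breed
        counts = [per_gen] * (depth + 1)
        counts[0] += cfg.n_per_breed - sum(counts)
        freq = breed_freqs[b]
        for g in range(depth + 1):
            for i in range(counts[g]):
                sid = f"B{b}_{g}_{i:03d}"
                if g == 0:
                    hap = (rng.random((2, L)) < freq).astype(np.int8)
                    row = add_animal(sid, f"breed{b}", hap, None, None)
                else:
                    si, di = rng.choice(gens[g - 1], size=2, replace=False)
                    hap = np.stack(
                        [
                            _gamete(haps[si], chrom_slices, cfg.switch_rate, rng),
                            _gamete(haps[di], chrom_slices, cfg.switch_rate, rng),
                        ]
                    )
                    row = add_animal(sid, f"breed{b}", hap, sample_ids[si], sample_ids[di])
                gens[g].append(row)
        by_breed_gen[b] = gens

    for i in range(cfg.n_crossbred):
        if cfg.n_breeds < 2:
            raise ConfigError("crossbreds require at least 2 breeds")
        b1, b2 = rng.choice(cfg.n_breeds, size=2, replace=False)
        si = int(rng.choice([r for g in by_breed_gen[b1] for r in g]))
        di = int(rng.choice([r for g in by_breed_gen[b2] for r in g]))
        hap = np.stack(
            [
                _gamete(haps[si], chrom_slices, cfg.switch_rate, rng),
                _gamete(haps[di], chrom_slices, cfg.switch_rate, rng),
            ]
        )
        add_animal(f"X_{i:03d}", CROSSBRED_LABEL, hap, sample_ids[si], sample_ids[di])

    hap_arr = np.stack(haps)  # (n, 2, L)
    dosage = hap_arr.sum(axis=1).astype(np.int8)
    truth = GenotypeMatrix(sample_ids, sites, dosage, breeds=list(breeds))

    # mock sequence calls: per-allele miscall flips
    flips = rng.random(hap_arr.shape) < cfg.error_rate
    called = np.where(flips, 1 - hap_arr, hap_arr)
    calls = GenotypeMatrix(
        sample_ids, sites, called.sum(axis=1).astype(np.int8), breeds=list(breeds)
    )

    return SimPopulation(
        truth=truth,
        calls=calls,
        haplotypes=hap_arr,
        pedigree=Pedigree(dict(ped_entries)),
        breeds=breeds,
        config=cfg,
    )


def simulate_panels(
    truth: GenotypeMatrix, cfg: SimConfig
) -> tuple[dict[str, PanelDefinition], dict[str, GenotypeMatrix]]:
    """Nested mock panels sampled from the sequence sites, plus masked matrices.

    The mock 777K panel is a uniform subsample of the sequence sites and the
    mock 50K a uniform subsample of the mock 777K, so nesting holds by
    construction. Sampling is driven by the config seed (offset so it does
    not replay the population stream).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    L = truth.n_sites
    n_mid = int(round(L * cfg.frac_mid))
    n_low = int(round(L * cfg.frac_low))
    if n_low < 10:
        raise ConfigError("panel fraction yields fewer than 10 sites")
    mid_idx = np.sort(rng.choice(L, size=n_mid, replace=False))
    low_idx = np.sort(rng.choice(mid_idx, size=n_low, replace=False))
    panels = {
        "sequence": PanelDefinition("sequence", tuple(truth.sites)),
        "mock777K": PanelDefinition("mock777K", tuple(truth.sites[i] for i in mid_idx)),
        "mock50K": PanelDefinition("mock50K", tuple(truth.sites[i] for i in low_idx)),
    }
    masked = {name: mask_to_panel(truth, panel) for name, panel in panels.items()}
    return panels, masked
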