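"""Haplotype reconstruction in short SNP windows via an EM algorithm.

Genotypes are cut into non-overlapping windows of a few SNPs (4 by default)
per chromosome, haplotype frequencies inside each window are estimated with
the classic haplotype-frequency EM (Excoffier-Slatkin style: the E-step
weights each individual's compatible diplotypes by f(h1)*f(h2), doubled for
heterodiplotypes; the M-step re-estimates frequencies from the expected
haplotype counts), and each animal's window is summarised as a count vector
over the window's haplotype alleles. Those count vectors — "quasi-genotypes",
multi-allelic pseudo-markers summing to 2 per window — are what the
clustering and distance stages consume.

Phasing is done across all animals jointly: small breeds carry too few
animals to phase within breed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateWindowError, ParameterError
from .genodata import MISSING, GenotypeMatrix, Site


@dataclass(frozen=True)
class Window:
    """A contiguous run of site indices on one chromosome."""

    index: int
    site_indices: tuple[int, ...]
    chrom: str

    def __len__(self) -> int:
        return len(self.site_indices)


@dataclass
class WindowHaplotypeModel:
    """EM-estimated haplotype alleles and frequencies for one window.

    ``haplotypes`` holds the distinct binary allele strings (rows of a
    (H, window_len) 0/1 array), each consistent with at least one observed
    genotype; ``frequencies`` is the matching probability vector.
    ``log_likelihoods`` records the EM trajectory (non-decreasing).
    """

    window: Window
    haplotypes: np.ndarray
    frequencies: np.ndarray
    log_likelihoods: list[float]
    # per-individual compatible diplotype bookkeeping, kept for posterior queries
    pair_ind: np.ndarray
    pair_h1: np.ndarray
    pair_h2: np.ndarray
    n_samples: int

    def posterior_pair_weights(self) -> np.ndarray:
        """Posterior probability of each compatible diplotype, normalised per individual."""
        f = self.frequencies
        w = f[self.pair_h1] * f[self.pair_h2] * np.where(self.pair_h1 == self.pair_h2, 1.0, 2.0)
        totals = np.zeros(self.n_samples)
        np.add.at(totals, self.pair_ind, w)
        return w / totals[self.pair_ind]

    def expected_counts(self) -> np.ndarray:
        """(n_samples, H) posterior-expected haplotype copy counts (rows sum to 2)."""
        w = self.posterior_pair_weights()
        out = np.zeros((self.n_samples, len(self.frequencies)))
        np.add.at(out, (self.pair_ind, self.pair_h1), w)
        np.add.at(out, (self.pair_ind, self.pair_h2), w)
        return out

    def hard_diplotypes(self) -> np.ndarray:
        """(n_samples, 2) indices of each individual's most probable diplotype.

        Ties break toward the first-listed pair (haplotypes are in discovery
        order, which is deterministic), so output is reproducible.
        """
        w = self.posterior_pair_weights()
        # sort by (individual, -weight, discovery order); the first row per
        # individual is then its best pair with deterministic tie-breaking
        order = np.lexsort((np.arange(len(w)), -w, self.pair_ind))
        first = np.searchsorted(self.pair_ind[order], np.arange(self.n_samples), side="left")
        best = order[first]
        return np.stack([self.pair_h1[best], self.pair_h2[best]], axis=1)


@dataclass
class QuasiGenotypeMatrix:
    """Per-window haplotype-allele counts for every animal.

    ``counts`` concatenates the per-window count vectors along axis 1;
    ``window_slices`` maps each window to its column slice. Every
    sample-window block sums to 2 (diploid); hard mode yields integers.
    """

    sample_ids: list[str]
    windows: list[Window]
    counts: np.ndarray
    window_slices: list[slice]
    haplotype_labels: list[str]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_counts(self, w: int) -> np.ndarray:
        return self.counts[:, self.window_slices[w]]


def make_windows(sites: list[Site], window_size: int = 4) -> list[Window]:
    """Tile each chromosome left-to-right with non-overlapping windows.

    Windows never span a chromosome boundary; leftover sites at a
    chromosome's end form a final shorter window rather than being dropped,
    so every site is covered exactly once.
    """
    if window_size < 1:
        raise ParameterError("window_size must be >= 1")
    windows: list[Window] = []
    i = 0
    n = len(sites)
    while i < n:
        chrom = sites[i].chrom
        j = i
        while j < n and sites[j].chrom == chrom:
            j += 1
        for start in range(i, j, window_size):
            stop = min(start + window_size, j)
            windows.append(
                Window(index=len(windows), site_indices=tuple(range(start, stop)), chrom=chrom)
            )
        i = j
    return windows


def _compatible_pairs(geno_window: np.ndarray):
    """Enumerate each individual's compatible diplotypes in one window.

    Missing sites contribute marginally: every haplotype completion at a
    missing site is allowed. Returns the distinct haplotypes (H, w) and flat
    (ind, h1, h2) arrays with h1 <= h2.
    """
    n, w = geno_window.shape
    hap_index: dict[tuple, int] = {}
    haps: list[tuple] = []
    pair_ind: list[int] = []
    pair_h1: list[int] = []
    pair_h2: list[int] = []

    def hap_id(h: tuple) -> int:
        k = hap_index.get(h)
        if k is None:
            k = len(haps)
            hap_index[h] = k
            haps.append(h)
        return k

    for ind in range(n):
        g = geno_window[ind]
        # build the per-site list of (a1, a2) allele assignments
        site_opts: list[list[tuple[int, int]]] = []
        for gs in g:
            if gs == MISSING:
                site_opts.append([(0, 0), (0, 1), (1, 0), (1, 1)])
            elif gs == 0:
                site_opts.append([(0, 0)])
            elif gs == 2:
                site_opts.append([(1, 1)])
            else:
                site_opts.append([(0, 1), (1, 0)])
        # expand, deduplicating unordered haplotype pairs
        combos = [((), ())]
        for opts in site_opts:
            combos = [(h1 + (a1,), h2 + (a2,)) for h1, h2 in combos for a1, a2 in opts]
        seen = set()
        for h1, h2 in combos:
            if (h2, h1) in seen or (h1, h2) in seen:
                continue
            seen.add((h1, h2))
            a, b = sorted((hap_id(h1), hap_id(h2)))
            pair_ind.append(ind)
            pair_h1.append(a)
            pair_h2.append(b)

    return (
        np.array(haps, dtype=np.int8).reshape(len(haps), w),
        np.asarray(pair_ind, dtype=np.int64),
        np.asarray(pair_h1, dtype=np.int64),
        np.asarray(pair_h2, dtype=np.int64),
    )


def em_phase_window(
    geno_window: np.ndarray,
    window: Window | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int | None = None,
    n_restarts: int = 0,
) -> WindowHaplotypeModel:
    """Estimate haplotype frequencies in one window by EM.

    ``geno_window`` is the (n_samples, window_len) dosage slice; windows of
    up to ~8 sites keep the haplotype space enumerable. Initialisation is
    uniform over observed-compatible haplotypes, which makes the run
    deterministic; ``seed`` only matters when ``n_restarts`` random restarts
    are requested. Iteration stops when the largest frequency change falls
    below ``tol``. The log-likelihood is non-decreasing by construction of EM
    and is recorded per iteration.
    """
    geno_window = np.asarray(geno_window)
    if window is None:
        window = Window(0, tuple(range(geno_window.shape[1])), chrom="?")
    if geno_window.shape[1] > 12:
        raise ParameterError("window too wide to enumerate haplotypes (> 12 sites)")
    if (geno_window == MISSING).all():
        raise DegenerateWindowError(f"window {window.index}: all genotypes missing")

    haps, pair_ind, pair_h1, pair_h2 = _compatible_pairs(geno_window)
    n, _ = geno_window.shape
    H = haps.shape[0]

    def run(f0: np.ndarray):
        f = f0.copy()
        lls: list[float] = []
        mult = np.where(pair_h1 == pair_h2, 1.0, 2.0)
        for _ in range(max_iter):
            w = f[pair_h1] * f[pair_h2] * mult
            totals = np.zeros(n)
            np.add.at(totals, pair_ind, w)
            lls.append(float(np.log(totals).sum()))
            w = w / totals[pair_ind]
            counts = np.zeros(H)
            np.add.at(counts, pair_h1, w)
            np.add.at(counts, pair_h2, w)
            f_new = counts / (2.0 * n)
            delta = np.abs(f_new - f).max()
            f = f_new
            if delta < tol:
                break
        # final log-likelihood at the converged frequencies
        w = f[pair_h1] * f[pair_h2] * mult
        totals = np.zeros(n)
        np.add.at(totals, pair_ind, w)
        lls.append(float(np.log(totals).sum()))
        return f, lls

    f, lls = run(np.full(H, 1.0 / H))
    if n_restarts:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            f0 = rng.dirichlet(np.ones(H))
            f_r, lls_r = run(f0)
            if lls_r[-1] > lls[-1]:
                f, lls = f_r, lls_r

    return WindowHaplotypeModel(
        window=window,
        haplotypes=haps,
        frequencies=f,
        log_likelihoods=lls,
        pair_ind=pair_ind,
        pair_h1=pair_h1,
        pair_h2=pair_h2,
        n_samples=n,
    )


def quasi_genotypes(
    gm: GenotypeMatrix,
    window_size: int = 4,
    mode: str = "expected",
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> QuasiGenotypeMatrix:
    """Phase every window and emit per-animal haplotype-allele counts.

    ``mode='expected'`` (default) emits posterior-expected copy counts —
    soft assignments, still summing to 2 per window; ``mode='hard'`` emits
    the most probable diplotype's integer counts.
    """
    if mode not in ("expected", "hard"):
        raise ParameterError(f"mode must be 'expected' or 'hard', got {mode!r}")
    windows = make_windows(gm.sites, window_size)
    blocks: list[np.ndarray] = []
    slices: list[slice] = []
    labels: list[str] = []
    col = 0
    for w in windows:
        idx = np.array(w.site_indices, dtype=int)
        try:
            model = em_phase_window(gm.dosage[:, idx], window=w,
                                    max_iter=max_iter, tol=tol, seed=seed)
        except DegenerateWindowError as exc:
            raise DegenerateWindowError(f"window {w.index} on {w.chrom}: {exc}") from exc
        if mode == "expected":
            block = model.expected_counts()
        else:
            dip = model.hard_diplotypes()
            block = np.zeros((gm.n_samples, model.haplotypes.shape[0]))
            np.add.at(block, (np.arange(gm.n_samples), dip[:, 0]), 1.0)
            np.add.at(block, (np.arange(gm.n_samples), dip[:, 1]), 1.0)
        blocks.append(block)
        slices.append(slice(col, col + block.shape[1]))
        col += block.shape[1]
        labels.extend(
            f"w{w.index}:" + "".join(str(int(a)) for a in h) for h in model.haplotypes
        )
    counts = np.concatenate(blocks, axis=1) if blocks else np.zeros((gm.n_samples, 0))
    return QuasiGenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        windows=windows,
        counts=counts,
        window_slices=slices,
        haplotype_labels=labels,
    )
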