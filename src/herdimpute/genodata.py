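"""Genotype data model, standard-format I/O, panel masking, and variant filtering.

The central container is :class:`GenotypeMatrix`: animals x ordered sites, with
each entry counting copies of the alternate allele (0, 1, 2) or ``MISSING``.
Sites are identified by ``(chrom, pos)`` throughout; marker names are carried
but never used as keys, because SNP-panel site lists frequently lack them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateSiteError,
    FormatError,
    HerdimputeError,
    MissingSiteError,
    ParameterError,
)

#: Sentinel for a missing diploid genotype in the dosage matrix.
MISSING: int = -1


def _chrom_sort_key(chrom: str):
    """Sort numerically named chromosomes numerically, others lexically after."""
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


@dataclass(frozen=True)
class Site:
    """A biallelic SNP locus at a 1-based physical position."""

    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    id: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ParameterError(f"site position must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class PanelDefinition:
    """A named SNP panel: an ordered list of sites (e.g. a mock 50K chip)."""

    name: str
    sites: tuple[Site, ...]

    def __post_init__(self):
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise DuplicateSiteError(f"panel {self.name!r} has duplicate (chrom,pos)")
        ordered = sorted(keys, key=lambda k: (_chrom_sort_key(k[0]), k[1]))
        if keys != ordered:
            raise FormatError(f"panel {self.name!r} sites are not sorted by (chrom,pos)")

    def __len__(self) -> int:
        return len(self.sites)

    def keys(self) -> list[tuple[str, int]]:
        return [s.key for s in self.sites]

    def is_subset_of(self, other: "PanelDefinition") -> bool:
        return set(self.keys()) <= set(other.keys())


@dataclass
class Pedigree:
    """Three-column pedigree: (id, sire or None, dam or None)."""

    entries: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    def __post_init__(self):
        self._check_no_ancestor_cycles()

    def _check_no_ancestor_cycles(self):
        # DFS from each id through parent links; an id reachable from itself
        # would make an individual its own ancestor.
        state: dict[str, int] = {}

        def visit(node: str):
            state[node] = 1
            for parent in self.entries.get(node, (None, None)):
                if parent is None:
                    continue
                if state.get(parent) == 1:
                    raise FormatError(f"pedigree cycle involving {parent!r}")
                if parent not in state:
                    visit(parent)
            state[node] = 2

        for node in list(self.entries):
            if node not in state:
                visit(node)

    def parents_of(self, sample_id: str) -> list[str]:
        sire, dam = self.entries.get(sample_id, (None, None))
        return [p for p in (sire, dam) if p is not None]

    def progeny_of(self, sample_id: str) -> list[str]:
        return [
            child
            for child, (sire, dam) in self.entries.items()
            if sample_id in (sire, dam)
        ]


@dataclass
class GenotypeMatrix:
    """Animals x sites alternate-allele dosage matrix.

    Parameters
    ----------
    sample_ids
        Ordered unique sample labels (rows).
    sites
        Ordered :class:`Site` list (columns), sorted by (chrom, pos).
    dosage
        ``(n_samples, n_sites)`` integer array with entries in {0, 1, 2}
        or :data:`MISSING`.
    breeds
        Optional per-sample breed label, aligned with ``sample_ids``.
    """

    sample_ids: list[str]
    sites: list[Site]
    dosage: np.ndarray
    breeds: list[str] | None = None

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.sites = list(self.sites)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.sites)):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise DuplicateSiteError("duplicate (chrom,pos) in site list")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("dosage entries must be in {0,1,2} or missing")
        if self.breeds is not None:
            self.breeds = list(self.breeds)
            if len(self.breeds) != len(self.sample_ids):
                raise FormatError("breeds length does not match sample count")

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> list[tuple[str, int]]:
        return [s.key for s in self.sites]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            sites=self.sites,
            dosage=self.dosage[idx].copy(),
            breeds=[self.breeds[i] for i in idx] if self.breeds else None,
        )

    def subset_sites(self, col_idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            sites=[self.sites[i] for i in col_idx],
            dosage=self.dosage[:, col_idx].copy(),
            breeds=list(self.breeds) if self.breeds else None,
        )

    def allele_frequencies(self) -> np.ndarray:
        """Per-site alternate-allele frequency over non-missing genotypes (NaN if none)."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0

    def minor_allele_counts(self) -> np.ndarray:
        """Per-site copy count of the minor allele over non-missing genotypes.

        The minor allele is whichever of REF/ALT is rarer at that site in the
        observed data, independent of labelling.
        """
        valid = self.dosage != MISSING
        alt = np.where(valid, self.dosage, 0).sum(axis=0)
        total = 2 * valid.sum(axis=0)
        return np.minimum(alt, total - alt)


# ---------------------------------------------------------------------------
# readers


def read_vcf(path: str | os.PathLike, *, drop_multiallelic: bool = False) -> GenotypeMatrix:
    """Read GT fields of a VCF v4.x file into a :class:`GenotypeMatrix`.

    Phased (``|``) and unphased (``/``) separators are both accepted; any
    genotype with a missing allele becomes :data:`MISSING`. Multi-allelic
    records raise :class:`FormatError` unless ``drop_multiallelic`` is set,
    in which case they are silently skipped. Sites are returned sorted by
    (chrom, pos).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(os.fspath(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    sites: list[Site] = []
    columns: list[np.ndarray] = []
    seen: set[tuple[str, int]] = set()
    for v in vcf:
        if len(v.ALT) != 1:
            if drop_multiallelic:
                continue
            raise FormatError(
                f"multi-allelic record at {v.CHROM}:{v.POS}; "
                "split it or pass drop_multiallelic=True"
            )
        key = (str(v.CHROM), int(v.POS))
        if key in seen:
            raise DuplicateSiteError(f"duplicate site {key[0]}:{key[1]}")
        seen.add(key)
        col = np.empty(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise FormatError(
                    f"non-diploid genotype for sample {sample_ids[i]} at {key[0]}:{key[1]}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                col[i] = MISSING
            else:
                col[i] = alleles[0] + alleles[1]
        sites.append(
            Site(chrom=key[0], pos=key[1], ref_allele=v.REF, alt_allele=v.ALT[0],
                 id=v.ID if v.ID not in (None, ".") else None)
        )
        columns.append(col)
    vcf.close()

    if not sites:
        return GenotypeMatrix(sample_ids, [], np.zeros((len(sample_ids), 0), dtype=np.int8))
    order = sorted(range(len(sites)), key=lambda i: (_chrom_sort_key(sites[i].chrom), sites[i].pos))
    dosage = np.stack([columns[i] for i in order], axis=1)
    return GenotypeMatrix(sample_ids, [sites[i] for i in order], dosage)


def read_plink_text(map_path: str | os.PathLike, geno_path: str | os.PathLike) -> GenotypeMatrix:
    """Read a PLINK-style .map file plus a whitespace-delimited genotype table.

    The map file has 3-5 columns: ``chrom id [cM] pos [ref alt]`` — the cM
    column is detected by column count. The genotype table has one row per
    sample: ``sample_id`` followed by one field per site, each either an
    allele pair like ``A G`` (two whitespace-separated characters, requiring
    ref/alt in the map; ``0 0`` means missing, the PLINK convention) or a
    single dosage in {0,1,2} (``NA``/``-1`` missing).
    """
    sites: list[Site] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 3:
                chrom, marker, pos = parts
                ref, alt = "A", "G"
            elif len(parts) == 4:
                chrom, marker, _cm, pos = parts
                ref, alt = "A", "G"
            elif len(parts) in (5, 6):
                if len(parts) == 6:
                    chrom, marker, _cm, pos, ref, alt = parts
                else:
                    chrom, marker, pos, ref, alt = parts
            else:
                raise FormatError(f"{map_path} line {ln}: expected 3-6 columns")
            sites.append(Site(chrom=chrom, pos=int(pos), ref_allele=ref,
                              alt_allele=alt, id=marker))
    keys = [s.key for s in sites]
    if len(set(keys)) != len(keys):
        raise DuplicateSiteError("duplicate (chrom,pos) in map file")

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(geno_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            sample_ids.append(parts[0])
            fields = parts[1:]
            if len(fields) == 2 * len(sites):
                row = _allele_pairs_to_dosage(fields, sites, geno_path, ln)
            elif len(fields) == len(sites):
                row = _dosage_fields(fields, geno_path, ln)
            else:
                raise FormatError(
                    f"{geno_path} line {ln}: {len(fields)} genotype fields for "
                    f"{len(sites)} sites (expected {len(sites)} dosages or "
                    f"{2 * len(sites)} alleles)"
                )
            rows.append(row)

    dosage = (np.stack(rows, axis=0) if rows
              else np.zeros((0, len(sites)), dtype=np.int8))
    order = sorted(range(len(sites)), key=lambda i: (_chrom_sort_key(sites[i].chrom), sites[i].pos))
    gm = GenotypeMatrix(sample_ids, sites, dosage)
    return gm.subset_sites(np.array(order, dtype=int)) if order != list(range(len(sites))) else gm


def _allele_pairs_to_dosage(fields, sites, path, ln) -> np.ndarray:
    row = np.empty(len(sites), dtype=np.int8)
    for j, site in enumerate(sites):
        a, b = fields[2 * j], fields[2 * j + 1]
        if a == "0" or b == "0":
            row[j] = MISSING
            continue
        dose = 0
        for allele in (a, b):
            if allele == site.alt_allele:
                dose += 1
            elif allele != site.ref_allele:
                raise FormatError(
                    f"{path} line {ln}: allele {allele!r} is neither ref "
                    f"{site.ref_allele!r} nor alt {site.alt_allele!r} at {site.chrom}:{site.pos}"
                )
        row[j] = dose
    return row


def _dosage_fields(fields, path, ln) -> np.ndarray:
    row = np.empty(len(fields), dtype=np.int8)
    for j, f in enumerate(fields):
        if f.upper() in ("NA", ".", "-1"):
            row[j] = MISSING
        elif f in ("0", "1", "2"):
            row[j] = int(f)
        else:
            raise FormatError(f"{path} line {ln}: bad dosage field {f!r}")
    return row


def read_panel_tsv(path: str | os.PathLike, name: str | None = None) -> PanelDefinition:
    """Read a 2-column (chrom, pos) site list; header optional; sorts sites."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"panel file {path} needs >= 2 columns (chrom, pos)")
    if not df.iloc[0, 1].lstrip("-").isdigit():  # header row
        df = df.iloc[1:]
    recs = sorted(
        ((str(c), int(p)) for c, p in zip(df.iloc[:, 0], df.iloc[:, 1])),
        key=lambda k: (_chrom_sort_key(k[0]), k[1]),
    )
    return PanelDefinition(
        name=name or os.path.basename(os.fspath(path)),
        sites=tuple(Site(chrom=c, pos=p) for c, p in recs),
    )


def read_pedigree_tsv(path: str | os.PathLike) -> Pedigree:
    """Read a 3-column (id, sire, dam) pedigree; '0' marks an unknown parent."""
    entries: dict[str, tuple[str | None, str | None]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].lower() == "id":
                continue
            if len(parts) < 3:
                raise FormatError(f"{path} line {ln}: expected id sire dam")
            ind, sire, dam = parts[:3]
            if ind in entries:
                raise FormatError(f"{path} line {ln}: duplicate id {ind!r}")
            entries[ind] = (None if sire == "0" else sire, None if dam == "0" else dam)
    return Pedigree(entries)


# ---------------------------------------------------------------------------
# transforms


def mask_to_panel(gm: GenotypeMatrix, panel: PanelDefinition) -> GenotypeMatrix:
    """Restrict ``gm`` to exactly the panel's sites, in panel order.

    Emulates filtering sequence calls down to the loci present on a SNP chip.
    Every panel site must exist in ``gm`` (matched on (chrom, pos));
    otherwise a :class:`MissingSiteError` lists the offenders.
    """
    lookup = {s.key: i for i, s in enumerate(gm.sites)}
    missing = [k for k in panel.keys() if k not in lookup]
    if missing:
        shown = ", ".join(f"{c}:{p}" for c, p in missing[:10])
        raise MissingSiteError(
            f"{len(missing)} panel site(s) absent from genotype matrix: {shown}"
            + ("..." if len(missing) > 10 else "")
        )
    idx = np.array([lookup[k] for k in panel.keys()], dtype=int)
    return gm.subset_sites(idx)


def filter_min_allele_count(
    gm: GenotypeMatrix, min_count: int = 4
) -> tuple[GenotypeMatrix, list[Site]]:
    """Drop sites whose minor-allele copy count across all animals is below ``min_count``.

    A site is retained when its minor allele occurs at least ``min_count``
    times over all non-missing genotypes ("less than four" removals are
    strict, so a count of exactly ``min_count`` stays). Returns the filtered
    matrix and the list of removed sites. Idempotent.
    """
    if min_count < 1:
        raise ParameterError("min_count must be >= 1")
    mac = gm.minor_allele_counts()
    keep = mac >= min_count
    removed = [s for s, k in zip(gm.sites, keep) if not k]
    return gm.subset_sites(np.flatnonzero(keep)), removed


# ---------------------------------------------------------------------------
# writers


def write_genotypes(gm: GenotypeMatrix, path: str | os.PathLike, format: str = "vcf") -> None:
    """Write a matrix as a GT-only VCF v4.2 or a site-by-sample TSV.

    Both formats round-trip exactly through :func:`read_vcf` /
    :func:`read_genotypes_tsv` (sample ids, sites, dosages; breed labels are
    not serialized here).
    """
    if format == "vcf":
        _write_vcf(gm, path)
    elif format == "tsv":
        _write_tsv(gm, path)
    else:
        raise ParameterError(f"unknown format {format!r}; use 'vcf' or 'tsv'")


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(gm: GenotypeMatrix, path) -> None:
    try:
        fh = open(path, "w")
    except OSError as exc:
        raise HerdimputeError(f"cannot write {path}: {exc}") from exc
    with fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in gm.sites):
            length = max(s.pos for s in gm.sites if s.chrom == chrom) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j, site in enumerate(gm.sites):
            gts = "\t".join(_GT[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.id or '.'}\t{site.ref_allele}\t"
                f"{site.alt_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


def _write_tsv(gm: GenotypeMatrix, path) -> None:
    try:
        fh = open(path, "w")
    except OSError as exc:
        raise HerdimputeError(f"cannot write {path}: {exc}") from exc
    with fh:
        fh.write("chrom\tpos\tid\tref\talt\t" + "\t".join(gm.sample_ids) + "\n")
        for j, site in enumerate(gm.sites):
            vals = "\t".join(
                "NA" if d == MISSING else str(int(d)) for d in gm.dosage[:, j]
            )
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.id or '.'}\t{site.ref_allele}\t"
                f"{site.alt_allele}\t{vals}\n"
            )


def read_genotypes_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    """Read the TSV layout produced by :func:`write_genotypes`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    meta = ["chrom", "pos", "id", "ref", "alt"]
    if list(df.columns[:5]) != meta:
        raise FormatError(f"{path}: expected columns {meta} first")
    sample_ids = list(df.columns[5:])
    sites = [
        Site(chrom=str(r.chrom), pos=int(r.pos),
             ref_allele=r.ref, alt_allele=r.alt,
             id=None if r.id == "." else r.id)
        for r in df.itertuples()
    ]
    if df.shape[0]:
        vals = df.iloc[:, 5:].to_numpy(dtype=object)
        dosage = np.where(vals == "NA", MISSING, vals).astype(np.int8).T
    else:
        dosage = np.zeros((len(sample_ids), 0), dtype=np.int8)
    order = sorted(range(len(sites)), key=lambda i: (_chrom_sort_key(sites[i].chrom), sites[i].pos))
    gm = GenotypeMatrix(sample_ids, sites, dosage)
    if order != list(range(len(sites))):
        gm = gm.subset_sites(np.array(order, dtype=int))
    return gm


def write_panel_tsv(panel: PanelDefinition, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\n")
        for s in panel.sites:
            fh.write(f"{s.chrom}\t{s.pos}\n")


def write_pedigree_tsv(ped: Pedigree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\n")
        for ind, (sire, dam) in ped.entries.items():
            fh.write(f"{ind}\t{sire or 0}\t{dam or 0}\n")
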