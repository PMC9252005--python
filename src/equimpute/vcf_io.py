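"""VCF and marker-panel input/output and basic variant statistics.

Genotypes are held as a samples x variants matrix of alternate-allele counts
(0, 1, 2) with ``MISSING = -1`` as the missing sentinel; a phased matrix
additionally carries a 2*samples x variants haplotype view.  Chromosome labels
are opaque strings ordered by first appearance in the input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

MISSING = -1

#: transition pairs among single nucleotides (purine<->purine, pyrimidine<->pyrimidine)
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class VcfParseError(ValueError):
    """Malformed VCF or panel input."""


@dataclass(frozen=True)
class VariantRecord:
    """One variant site.

    ``pos`` is the 1-based VCF coordinate.  ``impact`` is a functional
    annotation class (``"HIGH"``, ``"OTHER"`` or ``None``); ``info_dr2``
    carries an upstream imputer's dosage R-squared when present.
    """

    chrom: str
    pos: int
    id: str | None
    ref: str
    alts: tuple[str, ...]
    impact: str | None = None
    info_dr2: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if len(self.alts) < 1:
            raise ValueError("at least one ALT allele required")

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def is_snp(self) -> bool:
        """Biallelic single-nucleotide substitution."""
        return (
            not self.is_multiallelic
            and len(self.ref) == 1
            and len(self.alts[0]) == 1
        )

    @property
    def is_indel(self) -> bool:
        """Biallelic length-changing variant."""
        return not self.is_multiallelic and len(self.ref) != len(self.alts[0])


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele counts with optional haplotypes.

    Invariants: values of ``gt`` lie in {0, 1, 2, MISSING}; variants are
    sorted by (chromosome appearance order, position); when phased, ``gt``
    equals the sum of the two haplotype rows of each sample.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    gt: np.ndarray
    phased: bool = False
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int8)
        n, m = self.gt.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise ValueError("gt shape does not match sample/variant lists")
        bad = ~np.isin(self.gt, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("gt values outside {0,1,2,missing}")
        if self.phased:
            if self.haplotypes is None:
                raise ValueError("phased matrix requires haplotypes")
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * n, m):
                raise ValueError("haplotypes must be 2*samples x variants")
            obs = self.gt != MISSING
            summed = self.haplotypes[0::2] + self.haplotypes[1::2]
            if not np.array_equal(summed[obs], self.gt[obs]):
                raise ValueError("haplotypes inconsistent with genotypes")
        self._check_sorted()

    # -- derived views -------------------------------------------------
    def _check_sorted(self) -> None:
        order: dict[str, int] = {}
        for v in self.variants:
            order.setdefault(v.chrom, len(order))
        keys = [(order[v.chrom], v.pos) for v in self.variants]
        if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("variants not sorted by (chrom, pos)")
        self._chrom_order = list(order)

    @property
    def n_samples(self) -> int:
        return self.gt.shape[0]

    @property
    def n_variants(self) -> int:
        return self.gt.shape[1]

    @property
    def chrom_order(self) -> list[str]:
        return list(self._chrom_order)

    @property
    def chroms(self) -> np.ndarray:
        return np.asarray([v.chrom for v in self.variants], dtype=object)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([v.pos for v in self.variants], dtype=np.int64)

    def site_index(self) -> dict[tuple[str, int], int]:
        return {(v.chrom, v.pos): j for j, v in enumerate(self.variants)}

    # -- subsetting ----------------------------------------------------
    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.asarray([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None
        haps = None
        if self.phased and self.haplotypes is not None:
            hidx = np.empty(2 * len(idx), dtype=np.intp)
            hidx[0::2] = 2 * idx
            hidx[1::2] = 2 * idx + 1
            haps = self.haplotypes[hidx]
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=list(self.variants),
            gt=self.gt[idx],
            phased=self.phased,
            haplotypes=haps,
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(np.intp)
        haps = self.haplotypes[:, idx] if self.haplotypes is not None else None
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[j] for j in idx],
            gt=self.gt[:, idx],
            phased=self.phased,
            haplotypes=haps,
        )

    # -- statistics ----------------------------------------------------
    def alt_frequency(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing genotypes
        (NaN where every genotype is missing)."""
        obs = self.gt != MISSING
        cnt = np.where(obs, self.gt, 0).sum(axis=0).astype(float)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, cnt / denom, np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered, deduplicated set of (chrom, pos) array sites."""

    name: str
    sites: tuple[tuple[str, int], ...]

    @staticmethod
    def from_sites(name: str, sites: Iterable[tuple[str, int]]) -> "MarkerPanel":
        """Deduplicate and sort by (chromosome first-appearance, position)."""
        seen: dict[str, int] = {}
        uniq = []
        for chrom, pos in sites:
            seen.setdefault(chrom, len(seen))
            uniq.append((str(chrom), int(pos)))
        uniq = sorted(set(uniq), key=lambda s: (seen[s[0]], s[1]))
        return MarkerPanel(name=name, sites=tuple(uniq))

    def __len__(self) -> int:
        return len(self.sites)

    def site_set(self) -> set[tuple[str, int]]:
        return set(self.sites)

    def mask(self, gm: GenotypeMatrix) -> np.ndarray:
        """Boolean mask over ``gm`` variants that lie on this panel."""
        s = self.site_set()
        return np.fromiter(
            ((v.chrom, v.pos) in s for v in gm.variants), bool, count=gm.n_variants
        )

    def is_subset_of(self, other: "MarkerPanel") -> bool:
        return self.site_set() <= other.site_set()


@dataclass(frozen=True)
class VariantStats:
    """Counts and the transition/transversion ratio of a variant set."""

    n_sites: int
    n_snps: int
    n_indels: int
    n_multiallelic: int
    ti: int
    tv: int

    @property
    def titv(self) -> float:
        return self.ti / self.tv if self.tv > 0 else float("nan")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    lo, hi = span.split("-", 1)
    return chrom, int(lo), int(hi)


def read_vcf(path: str | os.PathLike, region: str | None = None) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    Phase is preserved when every genotype in the file is phased and called;
    otherwise the matrix is returned unphased.  Multiallelic records are
    retained (flagged through ``VariantRecord.is_multiallelic``); their gt
    entries count non-reference alleles.
    """
    from cyvcf2 import VCF

    want = _parse_region(region) if region is not None else None
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        variants: list[VariantRecord] = []
        rows: list[np.ndarray] = []
        all_phased = True
        for rec in vcf:
            if want is not None:
                chrom, lo, hi = want
                if rec.CHROM != chrom:
                    continue
                if lo is not None and not (lo <= rec.POS <= hi):
                    continue
            impact = rec.INFO.get("IMPACT")
            dr2 = rec.INFO.get("DR2")
            variants.append(
                VariantRecord(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    id=None if rec.ID in (None, ".") else rec.ID,
                    ref=rec.REF,
                    alts=tuple(rec.ALT),
                    impact=str(impact) if impact is not None else None,
                    info_dr2=float(dr2) if dr2 is not None else None,
                )
            )
            col = np.empty(2 * len(samples), dtype=np.int8)
            for i, g in enumerate(rec.genotypes):
                a, b = g[0], g[1]
                col[2 * i] = a if a >= 0 else MISSING
                col[2 * i + 1] = b if b >= 0 else MISSING
                if not g[2]:
                    all_phased = False
            rows.append(col)
        vcf.close()
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"failed to parse {path}: {exc}") from exc

    m = len(variants)
    n = len(samples)
    alleles = (
        np.stack(rows, axis=1) if m else np.zeros((2 * n, 0), dtype=np.int8)
    )
    miss = (alleles[0::2] == MISSING) | (alleles[1::2] == MISSING)
    gt = np.where(alleles[0::2] > 0, 1, 0) + np.where(alleles[1::2] > 0, 1, 0)
    gt = np.where(miss, MISSING, gt).astype(np.int8)
    phased = all_phased and not miss.any() and m > 0
    haps = np.clip(alleles, 0, 1).astype(np.int8) if phased else None
    return GenotypeMatrix(
        sample_ids=samples, variants=variants, gt=gt, phased=phased, haplotypes=haps
    )


def read_dosage_vcf(path: str | os.PathLike):
    """Read a VCF carrying DS format fields (and optional INFO/DR2).

    Returns ``(gm, ds, dr2)`` with ``ds`` as samples x variants float dosages
    (NaN where absent) and ``dr2`` the per-variant INFO value (NaN where
    absent).  Used to ingest an external imputer's output for evaluation.
    """
    from cyvcf2 import VCF

    gm = read_vcf(path)
    vcf = VCF(str(path))
    cols = []
    dr2 = []
    for rec in vcf:
        try:
            d = rec.format("DS")
        except KeyError:
            d = None
        if d is None:
            cols.append(np.full(len(vcf.samples), np.nan))
        else:
            cols.append(np.asarray(d, dtype=float).reshape(-1))
        v = rec.INFO.get("DR2")
        dr2.append(float(v) if v is not None else np.nan)
    vcf.close()
    ds = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((gm.n_samples, 0), dtype=float)
    )
    return gm, ds, np.asarray(dr2, dtype=float)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike, dosages=None) -> None:
    """Write a matrix to an uncompressed VCF 4.2 file.

    Round-trips genotype values, phase and site order exactly.  When
    ``dosages`` (an object with ``ds`` and ``dr2`` arrays aligned to ``gm``)
    is given, DS is emitted per sample and DR2 as an INFO field.
    """
    ds = dr2 = None
    if dosages is not None:
        ds = np.asarray(dosages.ds, dtype=float)
        dr2 = np.asarray(dosages.dr2, dtype=float)
        if ds.shape != gm.gt.shape:
            raise ValueError("dosage shape does not match genotype matrix")
    lines = ["##fileformat=VCFv4.2", "##source=equimpute"]
    lines.append(
        '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Predicted functional impact class">'
    )
    lines.append(
        '##INFO=<ID=DR2,Number=1,Type=Float,Description="Estimated squared correlation between imputed and true dose">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if ds is not None:
        lines.append(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alternate allele dosage">'
        )
    for chrom in gm.chrom_order:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids)
    )
    sep = "|" if gm.phased else "/"
    fmt = "GT:DS" if ds is not None else "GT"
    for j, v in enumerate(gm.variants):
        info = []
        if v.impact is not None:
            info.append(f"IMPACT={v.impact}")
        if dr2 is not None and np.isfinite(dr2[j]):
            info.append(f"DR2={dr2[j]:.4f}")
        elif v.info_dr2 is not None:
            info.append(f"DR2={v.info_dr2:.4f}")
        cells = []
        for i in range(gm.n_samples):
            g = gm.gt[i, j]
            if g == MISSING:
                gt_s = f".{sep}."
            elif gm.phased and gm.haplotypes is not None:
                gt_s = f"{gm.haplotypes[2 * i, j]}{sep}{gm.haplotypes[2 * i + 1, j]}"
            else:
                gt_s = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}[int(g)]
            if ds is not None:
                gt_s += f":{ds[i, j]:.4f}"
            cells.append(gt_s)
        lines.append(
            "\t".join(
                [
                    v.chrom,
                    str(v.pos),
                    v.id or ".",
                    v.ref,
                    ",".join(v.alts),
                    ".",
                    ".",
                    ";".join(info) or ".",
                    fmt,
                ]
                + cells
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# statistics & panels
# ---------------------------------------------------------------------------

def compute_variant_stats(gm: GenotypeMatrix) -> VariantStats:
    """Count SNPs, indels and multiallelic sites and the SNP Ti/Tv ratio.

    Multiallelic and mixed-type records are tallied separately and excluded
    from the SNP/indel counts and from Ti/Tv.
    """
    n_snps = n_indels = n_multi = ti = tv = 0
    for v in gm.variants:
        if v.is_multiallelic:
            n_multi += 1
            continue
        if v.is_snp:
            n_snps += 1
            if (v.ref.upper(), v.alts[0].upper()) in _TRANSITIONS:
                ti += 1
            else:
                tv += 1
        elif v.is_indel:
            n_indels += 1
    return VariantStats(
        n_sites=gm.n_variants,
        n_snps=n_snps,
        n_indels=n_indels,
        n_multiallelic=n_multi,
        ti=ti,
        tv=tv,
    )


def load_marker_panel(path: str | os.PathLike, name: str | None = None) -> MarkerPanel:
    """Load array positions from a 2-column chrom/pos TSV (1-based) or a BED.

    Files ending in ``.bed`` are parsed as 0-based half-open single-base
    intervals (``chrom  pos-1  pos``); wider BED intervals are rejected.
    Duplicates are removed and sites sorted.
    """
    path = os.fspath(path)
    is_bed = path.endswith(".bed")
    sites: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                if is_bed:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                else:
                    chrom, start, end = fields[0], int(fields[1]) - 1, int(fields[1])
            except (ValueError, IndexError) as exc:
                raise VcfParseError(f"{path}:{lineno}: bad panel line: {line!r}") from exc
            if end != start + 1:
                raise VcfParseError(f"{path}:{lineno}: BED interval wider than one base")
            sites.append((chrom, end))
    return MarkerPanel.from_sites(name or os.path.basename(path), sites)


def with_impacts(gm: GenotypeMatrix, impacts: Sequence[str | None]) -> GenotypeMatrix:
    """Return a copy of ``gm`` whose variants carry the given impact labels."""
    if len(impacts) != gm.n_variants:
        raise ValueError("impact list length mismatch")
    variants = [replace(v, impact=imp) for v, imp in zip(gm.variants, impacts)]
    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        variants=variants,
        gt=gm.gt.copy(),
        phased=gm.phased,
        haplotypes=None if gm.haplotypes is None else gm.haplotypes.copy(),
    )
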