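"""Synthetic phased multi-breed sequence panels.

The generator emulates the statistical structure the downstream analyses
assume: ancestral allele frequencies from a Beta site-frequency spectrum,
breed divergence under the Balding-Nichols model at three relationship tiers
around a target cluster, local linkage disequilibrium from mosaic copying of
breed-founder haplotypes, nested medium/high marker panels with array
coverage gaps, HIGH-impact annotation labels, and an optional planted
recessive-lethal variant with zero alternate homozygotes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rand import substream
from .vcf_io import GenotypeMatrix, MarkerPanel, VariantRecord

__all__ = [
    "BreedGroupSpec",
    "SimConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "design_marker_panels",
    "annotate_impacts",
    "hudson_fst",
]

_NUC = np.array(list("ACGT"))
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class BreedGroupSpec:
    """One breed: its relationship tier (1 = target cluster, 2 = related,
    3 = distant), Balding-Nichols divergence F, and sample count."""

    label: str
    tier: int
    F: float
    n_individuals: int

    def __post_init__(self) -> None:
        if not 0 <= self.F < 1:
            raise ValueError("F must lie in [0, 1)")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual per breed")
        if self.tier not in (1, 2, 3):
            raise ValueError("tier must be 1, 2 or 3")


def _default_breeds() -> list[BreedGroupSpec]:
    return [
        BreedGroupSpec("warmblood", 1, 0.02, 65),
        BreedGroupSpec("related_a", 2, 0.12, 15),
        BreedGroupSpec("related_b", 2, 0.12, 15),
        BreedGroupSpec("distant_a", 3, 0.30, 13),
        BreedGroupSpec("distant_b", 3, 0.30, 12),
    ]


@dataclass
class SimConfig:
    """Study-scale simulation profile.

    Defaults give a desk-scale panel: 2 chromosomes x 10 Mb, 20,000 sites and
    120 samples, with 65 target-cluster individuals (five folds of 13), 30
    related and 25 distant ones, a 1-Mb array coverage gap, and a nested
    medium/high marker-panel pair at a ~1:9 density ratio.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 10_000_000, "2": 10_000_000}
    )
    n_variants: int = 20_000
    ancestral_sfs: tuple[float, float] = (0.5, 0.5)
    breeds: list[BreedGroupSpec] = field(default_factory=_default_breeds)
    recomb_rate: float = 1.0
    panel_sizes: tuple[int, int] = (400, 3600)  # (medium, high)
    coverage_gaps: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("1", 5_000_000, 6_000_000)]
    )
    high_impact_fraction: float = 0.001
    planted_lethal: tuple[float, tuple[int, ...]] | None = None  # (q, tier scope)
    n_founders: int = 20
    mutation_rate: float = 0.002
    panel_maf_threshold: float = 0.0
    ld_mode: str = "mosaic"  # or "independent" (no LD, site-wise draws)

    def __post_init__(self) -> None:
        med, high = self.panel_sizes
        if not med <= high <= self.n_variants:
            raise ValueError("panel sizes must satisfy medium <= high <= n_variants")
        if not 0 <= self.high_impact_fraction <= 1:
            raise ValueError("high_impact_fraction must lie in [0, 1]")
        if self.ld_mode not in ("mosaic", "independent"):
            raise ValueError("ld_mode must be 'mosaic' or 'independent'")
        ftier = {}
        for b in self.breeds:
            ftier.setdefault(b.tier, b.F)
        for lo, hi in ((1, 2), (2, 3), (1, 3)):
            if lo in ftier and hi in ftier and ftier[lo] > ftier[hi]:
                raise ValueError("tier F values must be non-decreasing with tier")


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimulatedDataset:
    """Phased truth panel plus the derived array panels and labels."""

    gm: GenotypeMatrix
    medium: MarkerPanel
    high: MarkerPanel
    breed_of: dict[str, str]
    tier_of: dict[str, int]
    lethal_site: tuple[str, int] | None
    config: SimConfig


def _draw_positions(cfg: SimConfig, rng: np.random.Generator):
    lengths = cfg.chrom_lengths
    total = sum(lengths.values())
    chroms: list[str] = []
    pos: list[np.ndarray] = []
    remaining = cfg.n_variants
    items = list(lengths.items())
    for i, (chrom, L) in enumerate(items):
        want = remaining if i == len(items) - 1 else round(cfg.n_variants * L / total)
        want = min(want, remaining)
        remaining -= want
        draw = rng.integers(1, L + 1, size=int(want * 1.2) + 16)
        uniq = np.unique(draw)
        while uniq.size < want:  # pragma: no cover - resample fallback
            extra = rng.integers(1, L + 1, size=want)
            uniq = np.unique(np.concatenate([uniq, extra]))
        p = np.sort(rng.choice(uniq, size=want, replace=False))
        chroms.extend([chrom] * want)
        pos.append(p)
    return np.asarray(chroms, dtype=object), np.concatenate(pos)


def _breed_frequencies(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    if F == 0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def _mosaic_haplotypes(
    founders: np.ndarray,
    n_haps: int,
    chrom_slices: list[slice],
    positions: np.ndarray,
    recomb_rate: float,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotypes as founder mosaics with Exp(mean 1 Mb / recomb_rate)
    segment lengths, then per-site mutation flips."""
    n_f, M = founders.shape
    mean_seg = 1e6 / recomb_rate
    haps = np.empty((n_haps, M), dtype=np.int8)
    for h in range(n_haps):
        for sl in chrom_slices:
            p = positions[sl]
            lo, hi = int(p[0]), int(p[-1])
            # breakpoints of the copying mosaic along the chromosome
            bps = []
            x = lo + rng.exponential(mean_seg)
            while x < hi:
                bps.append(x)
                x += rng.exponential(mean_seg)
            founder_ids = rng.integers(0, n_f, size=len(bps) + 1)
            seg_of_site = np.searchsorted(np.asarray(bps), p)
            haps[h, sl] = founders[founder_ids[seg_of_site], sl.start + np.arange(p.size)]
    if mutation_rate > 0:
        flips = rng.random(haps.shape) < mutation_rate
        haps ^= flips.astype(np.int8)
    return haps


def _plant_lethal(
    gm_haps: np.ndarray,
    scoped_rows: np.ndarray,
    site: int,
    q: float,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> None:
    """Overwrite one site so it carries a recessive lethal: heterozygous
    carriers only, allele frequency within 10% of the target q."""
    if not 0 < q <= 0.5:
        raise ConfigError("planted lethal frequency must lie in (0, 0.5]")
    n_scoped = scoped_rows.size // 2
    for _ in range(max_tries):
        carrier = rng.random(n_scoped) < 2.0 * q  # heterozygote probability
        freq = carrier.sum() / (2.0 * n_scoped)
        if abs(freq - q) <= 0.1 * q and carrier.any():
            break
    else:
        raise ConfigError("could not realise planted lethal frequency")
    gm_haps[:, site] = 0
    which = rng.integers(0, 2, size=n_scoped)
    for i in np.flatnonzero(carrier):
        gm_haps[scoped_rows[2 * i + which[i]], site] = 1


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate a phased multi-breed dataset; deterministic given the seed."""
    chroms, positions = _draw_positions(cfg, substream(cfg.seed, "positions"))
    M = positions.size

    a, b = cfg.ancestral_sfs
    p_anc = substream(cfg.seed, "ancestral").beta(a, b, size=M)
    p_anc = np.clip(p_anc, 0.02, 0.98)

    chrom_slices = []
    start = 0
    for i in range(1, M + 1):
        if i == M or chroms[i] != chroms[start]:
            chrom_slices.append(slice(start, i))
            start = i

    sample_ids: list[str] = []
    breed_of: dict[str, str] = {}
    tier_of: dict[str, int] = {}
    hap_blocks: list[np.ndarray] = []
    for spec in cfg.breeds:
        rng_b = substream(cfg.seed, "breed", spec.label)
        p_b = _breed_frequencies(p_anc, spec.F, rng_b)
        n_haps = 2 * spec.n_individuals
        if cfg.ld_mode == "independent":
            haps = (rng_b.random((n_haps, M)) < p_b).astype(np.int8)
        else:
            founders = (rng_b.random((cfg.n_founders, M)) < p_b).astype(np.int8)
            haps = _mosaic_haplotypes(
                founders,
                n_haps,
                chrom_slices,
                positions,
                cfg.recomb_rate,
                cfg.mutation_rate,
                rng_b,
            )
        hap_blocks.append(haps)
        for i in range(spec.n_individuals):
            sid = f"{spec.label}_{i:03d}"
            sample_ids.append(sid)
            breed_of[sid] = spec.label
            tier_of[sid] = spec.tier

    haps = np.concatenate(hap_blocks, axis=0)

    lethal_site = None
    if cfg.planted_lethal is not None:
        q, scope = cfg.planted_lethal
        scope = tuple(scope)
        rng_l = substream(cfg.seed, "lethal")
        site = int(rng_l.integers(0, M))
        rows = []
        for i, sid in enumerate(sample_ids):
            if tier_of[sid] in scope:
                rows.extend([2 * i, 2 * i + 1])
        if not rows:
            raise ConfigError("planted lethal tier scope matches no samples")
        _plant_lethal(haps, np.asarray(rows), site, q, rng_l)
        lethal_site = (str(chroms[site]), int(positions[site]))

    rng_alleles = substream(cfg.seed, "alleles")
    ref_idx = rng_alleles.integers(0, 4, size=M)
    refs = _NUC[ref_idx]
    # transition-biased alternate alleles (Ti:Tv about 2:1)
    is_ti = rng_alleles.random(M) < 2.0 / 3.0
    alts = np.empty(M, dtype=object)
    for j in range(M):
        r = refs[j]
        if is_ti[j]:
            alts[j] = _TRANSITION_OF[r]
        else:
            choices = [n for n in "ACGT" if n != r and n != _TRANSITION_OF[r]]
            alts[j] = choices[int(rng_alleles.integers(0, 2))]

    variants = [
        VariantRecord(
            chrom=str(chroms[j]),
            pos=int(positions[j]),
            id=f"{chroms[j]}_{positions[j]}",
            ref=str(refs[j]),
            alts=(str(alts[j]),),
        )
        for j in range(M)
    ]
    gt = (haps[0::2] + haps[1::2]).astype(np.int8)
    gm = GenotypeMatrix(
        sample_ids=sample_ids, variants=variants, gt=gt, phased=True, haplotypes=haps
    )

    medium, high = design_marker_panels(gm, cfg)
    impacts = annotate_impacts_labels(gm, cfg, lethal_site)
    from .vcf_io import with_impacts

    gm = with_impacts(gm, impacts)
    return SimulatedDataset(
        gm=gm,
        medium=medium,
        high=high,
        breed_of=breed_of,
        tier_of=tier_of,
        lethal_site=lethal_site,
        config=cfg,
    )


def design_marker_panels(gm: GenotypeMatrix, cfg: SimConfig):
    """Draw the nested medium/high array panels.

    The high panel is a MAF-weighted sample without replacement of eligible
    sites (polymorphic, outside coverage gaps, MAF >= the configured
    threshold); the medium panel is a nested MAF-weighted subsample of it.
    """
    maf = gm.maf()
    eligible = np.isfinite(maf) & (maf > max(cfg.panel_maf_threshold, 0.0))
    if cfg.panel_maf_threshold > 0:
        eligible &= maf >= cfg.panel_maf_threshold
    chroms = gm.chroms
    positions = gm.positions
    for chrom, lo, hi in cfg.coverage_gaps:
        in_gap = (chroms == chrom) & (positions >= lo) & (positions < hi)
        eligible &= ~in_gap
    idx = np.flatnonzero(eligible)
    n_med, n_high = cfg.panel_sizes
    if idx.size < n_high:
        raise ConfigError(
            f"only {idx.size} eligible sites for a high panel of {n_high}"
        )
    rng = substream(cfg.seed, "panels")
    w = maf[idx] / maf[idx].sum()
    high_idx = rng.choice(idx, size=n_high, replace=False, p=w, shuffle=False)
    w2 = maf[high_idx] / maf[high_idx].sum()
    med_idx = rng.choice(high_idx, size=n_med, replace=False, p=w2, shuffle=False)
    sites_high = [(str(chroms[j]), int(positions[j])) for j in np.sort(high_idx)]
    sites_med = [(str(chroms[j]), int(positions[j])) for j in np.sort(med_idx)]
    return (
        MarkerPanel.from_sites("medium", sites_med),
        MarkerPanel.from_sites("high", sites_high),
    )


def annotate_impacts_labels(
    gm: GenotypeMatrix, cfg: SimConfig, lethal_site: tuple[str, int] | None
) -> list[str]:
    """HIGH/OTHER impact labels: each site HIGH independently with the
    configured probability; a planted lethal is always HIGH."""
    rng = substream(cfg.seed, "impacts")
    high = rng.random(gm.n_variants) < cfg.high_impact_fraction
    labels = ["HIGH" if h else "OTHER" for h in high]
    if lethal_site is not None:
        j = gm.site_index()[lethal_site]
        labels[j] = "HIGH"
    return labels


def annotate_impacts(gm: GenotypeMatrix, cfg: SimConfig, lethal_site=None) -> GenotypeMatrix:
    """Return a copy of ``gm`` with seeded HIGH/OTHER impact annotations."""
    from .vcf_io import with_impacts

    return with_impacts(gm, annotate_impacts_labels(gm, cfg, lethal_site))


def hudson_fst(gm: GenotypeMatrix, groups: dict[str, str]) -> float:
    """Mean pairwise Hudson FST (ratio-of-averages) across groups.

    Used as the simulator's divergence calibration statistic.
    """
    labels = sorted(set(groups.values()))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    idx_of = {
        lab: [i for i, s in enumerate(gm.sample_ids) if groups[s] == lab]
        for lab in labels
    }
    vals = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            g1 = gm.gt[idx_of[labels[i]]]
            g2 = gm.gt[idx_of[labels[j]]]
            n1 = 2.0 * g1.shape[0]
            n2 = 2.0 * g2.shape[0]
            p1 = g1.sum(axis=0) / n1
            p2 = g2.sum(axis=0) / n2
            num = (
                (p1 - p2) ** 2
                - p1 * (1 - p1) / (n1 - 1)
                - p2 * (1 - p2) / (n2 - 1)
            )
            den = p1 * (1 - p2) + p2 * (1 - p1)
            keep = den > 0
            vals.append(num[keep].sum() / den[keep].sum())
    return float(np.mean(vals))
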