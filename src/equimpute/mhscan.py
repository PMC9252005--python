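"""Missing-homozygosity scan for recessive-lethal candidates.

Under Hardy-Weinberg equilibrium an allele at frequency q yields homozygotes
with probability q^2; a complete absence (or deficit) of homozygotes among n
genotyped individuals is tested with a one-sided binomial test,
Bonferroni-corrected over the number of HIGH-impact variants examined.  The
module also provides the analytic design calculators: the smallest sample
size at which zero homozygotes is significant for a given allele frequency,
and the smallest frequency detectable at a given sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .vcf_io import MISSING, GenotypeMatrix

__all__ = [
    "ScanResult",
    "homozygote_deficit_pvalue",
    "scan_missing_homozygosity",
    "minimal_sample_size",
    "minimal_maf",
]


@dataclass
class ScanResult:
    """Scan output: one row per tested variant, sorted by corrected p-value.

    ``table`` columns: chrom, pos, id, q (tested allele frequency), n
    (genotyped individuals), k (observed homozygotes of the tested allele),
    p_raw, p_bonf, significant.  ``m`` is the number of tests;
    ``max_q_zero_hom`` is the largest tested frequency among variants with
    no observed homozygotes (NaN when there is none).
    """

    table: pd.DataFrame
    m: int
    alpha: float
    max_q_zero_hom: float


def homozygote_deficit_pvalue(k: int, n: int, q: float) -> float:
    """One-sided P(X <= k) for X ~ Binomial(n, q^2).

    ``q`` is the frequency of the allele whose homozygotes are counted and
    must not exceed 0.5 (test the less frequent allele).  For k = 0 the
    closed form (1 - q^2)^n is used.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 <= q <= 0.5:
        raise ValueError("q must lie in [0, 0.5]: test the minor allele")
    if q == 0:
        return 1.0
    if k == 0:
        return (1.0 - q * q) ** n
    return float(binom.cdf(k, n, q * q))


def scan_missing_homozygosity(gm: GenotypeMatrix, alpha: float = 0.05) -> ScanResult:
    """Test every biallelic HIGH-impact variant for a homozygote deficit.

    The tested allele is the cohort minor allele, its frequency estimated
    from the same cohort's allele counts; p-values are Bonferroni-corrected
    by the number of variants tested (each variant counted once).
    """
    if not any(v.impact is not None for v in gm.variants):
        raise ValueError("impact annotations are required for the scan")
    rows = []
    for j, v in enumerate(gm.variants):
        if v.impact != "HIGH" or v.is_multiallelic:
            continue
        col = gm.gt[:, j]
        obs = col != MISSING
        n = int(obs.sum())
        if n == 0:
            continue
        f_alt = float(col[obs].sum()) / (2.0 * n)
        if f_alt <= 0.5:
            q = f_alt
            k = int((col[obs] == 2).sum())
        else:
            q = 1.0 - f_alt
            k = int((col[obs] == 0).sum())
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "id": v.id,
                "q": q,
                "n": n,
                "k": k,
                "p_raw": homozygote_deficit_pvalue(k, n, q),
            }
        )
    if not rows:
        import warnings

        warnings.warn("no biallelic HIGH-impact variants to test", stacklevel=2)
        empty = pd.DataFrame(
            columns=["chrom", "pos", "id", "q", "n", "k", "p_raw", "p_bonf", "significant"]
        )
        return ScanResult(table=empty, m=0, alpha=alpha, max_q_zero_hom=float("nan"))
    tab = pd.DataFrame(rows)
    m = len(tab)
    tab["p_bonf"] = np.minimum(1.0, m * tab["p_raw"])
    tab["significant"] = tab["p_bonf"] <= alpha
    tab = tab.sort_values("p_bonf", kind="stable").reset_index(drop=True)
    zero = tab[tab["k"] == 0]
    max_q0 = float(zero["q"].max()) if len(zero) else float("nan")
    return ScanResult(table=tab, m=m, alpha=alpha, max_q_zero_hom=max_q0)


def minimal_sample_size(q: float, m: int, alpha: float = 0.05) -> int:
    """Smallest integer n with (1 - q^2)^n <= alpha/m.

    This is the cohort size at which complete absence of homozygotes for an
    allele at frequency q reaches family-wise significance over m tests.
    The analytic bound is verified by stepping across the boundary.
    """
    if not 0 < q <= 0.5:
        raise ValueError("q must lie in (0, 0.5]")
    if m < 1:
        raise ValueError("need m >= 1")
    thresh = alpha / m
    if thresh >= 1.0:
        return 0
    log_term = math.log1p(-q * q)
    n = max(0, math.ceil(math.log(thresh) / log_term))
    while n > 0 and (1.0 - q * q) ** (n - 1) <= thresh:
        n -= 1
    while (1.0 - q * q) ** n > thresh:
        n += 1
    return n


def minimal_maf(n: int, m: int, alpha: float = 0.05) -> float:
    """Smallest allele frequency q with (1 - q^2)^n <= alpha/m,
    i.e. q* = sqrt(1 - (alpha/m)^(1/n))."""
    if n < 1 or m < 1:
        raise ValueError("need n >= 1 and m >= 1")
    thresh = alpha / m
    if thresh >= 1.0:
        return 0.0
    return math.sqrt(1.0 - thresh ** (1.0 / n))
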