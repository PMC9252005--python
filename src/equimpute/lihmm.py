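"""Diploid Li-Stephens haplotype-copying imputation.

Each chromosome copy of an unphased target is modelled as an imperfect mosaic
of the K phased reference haplotypes.  Between adjacent sites separated by
genetic distance ``d`` Morgans, each copy switches to a uniformly chosen
haplotype (including itself) with probability ``1 - exp(-4*Ne*d/K)``; at a
typed site each copied allele is observed through an allele-error channel
with mismatch probability ``err``.  Forward-backward over ordered
haplotype pairs yields posterior expected alternate-allele dosages and
posterior dosage variances at every sequence site; the per-variant dosage
R-squared (DR2) is the estimated-over-total dosage variance ratio.

The transition operator factorises per copy as ``(1-theta)*I + (theta/K)*J``,
so one forward/backward step costs O(K^2); sites with no observation are
bridged by composing interval survival probabilities, which is exact for
this operator family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vcf_io import MISSING, GenotypeMatrix, VariantRecord

__all__ = [
    "HmmParams",
    "ImputedDosages",
    "build_genetic_map",
    "impute_sample",
    "impute_panel",
    "compute_dr2",
]


@dataclass(frozen=True)
class HmmParams:
    """Copying-model parameters.

    ne
        Effective population size scaling the switch rate (default 1000).
    err
        Allele-mismatch emission probability (default 1e-3).
    recomb_rate
        Constant genetic-map rate in cM/Mb used to convert bp gaps to
        Morgans (default 1.0).
    min_switch
        Floor on the per-interval switch probability, avoiding degenerate
        zero-recombination intervals (default 1e-8).
    """

    ne: float = 1000.0
    err: float = 1e-3
    recomb_rate: float = 1.0
    min_switch: float = 1e-8

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError("ne must be positive")
        if not 0 < self.err < 0.5:
            raise ValueError("err must lie in (0, 0.5)")
        if self.recomb_rate <= 0:
            raise ValueError("recomb_rate must be positive")


@dataclass
class ImputedDosages:
    """Posterior expected dosages with per-variant quality.

    ``ds`` holds samples x variants expected alternate-allele dosages in
    [0, 2], ``post_var`` the matching posterior dosage variances, and ``dr2``
    the per-variant dosage R-squared in [0, 1].
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    ds: np.ndarray
    post_var: np.ndarray
    dr2: np.ndarray

    def __post_init__(self) -> None:
        self.ds = np.asarray(self.ds, dtype=float)
        self.post_var = np.asarray(self.post_var, dtype=float)
        self.dr2 = np.asarray(self.dr2, dtype=float)
        fin = np.isfinite(self.ds)
        if ((self.ds[fin] < -1e-9) | (self.ds[fin] > 2 + 1e-9)).any():
            raise ValueError("dosages must lie in [0, 2]")
        if (self.post_var[np.isfinite(self.post_var)] < -1e-9).any():
            raise ValueError("posterior variances must be non-negative")


def build_genetic_map(positions, rate: float) -> np.ndarray:
    """Cumulative genetic map in Morgans from bp positions at a constant
    cM/Mb rate (1 cM/Mb = 1e-8 Morgan/bp)."""
    pos = np.asarray(positions, dtype=float)
    if (np.diff(pos) < 0).any():
        raise ValueError("positions must be sorted ascending")
    return pos * rate * 1e-8


def _emission_table(err: float) -> np.ndarray:
    """em[g, s] = P(observed genotype g | copied allele sum s).

    Each copied allele is mis-read independently with probability ``err``;
    the observed genotype is the sum of the two read alleles.
    """
    e, c = err, 1.0 - err
    return np.array(
        [
            [c * c, c * e, e * e],
            [2 * c * e, c * c + e * e, 2 * c * e],
            [e * e, c * e, c * c],
        ]
    )


def _pair_transition(F: np.ndarray, theta: float, K: int) -> np.ndarray:
    """Apply the per-copy transition (1-theta)I + (theta/K)J to both indices
    of the K x K pair-state array F in O(K^2)."""
    c = 1.0 - theta
    d = theta / K
    r = F.sum(axis=1)
    s = F.sum(axis=0)
    tot = r.sum()
    return c * c * F + c * d * (r[:, None] + s[None, :]) + d * d * tot


def _site_moments(P: np.ndarray, h: np.ndarray):
    """First and second moments of the copied-allele sum under pair-state
    weights P (unnormalised) and site alleles h in {0,1}."""
    Z = P.sum()
    if Z <= 0:
        return np.nan, np.nan
    r = P.sum(axis=1)
    s = P.sum(axis=0)
    e1 = float(r @ h) / Z
    e2 = float(s @ h) / Z
    e12 = float(h @ P @ h) / Z
    ds = e1 + e2
    var = e1 * (1 - e1) + e2 * (1 - e2) + 2.0 * (e12 - e1 * e2)
    return ds, max(var, 0.0)


def _impute_chrom(g, H, pos, params: HmmParams):
    """Forward-backward posteriors for one chromosome of one sample.

    g : (M,) int genotypes with MISSING at masked/untyped sites
    H : (K, M) reference haplotype alleles in {0, 1}
    """
    K, M = H.shape
    Hf = H.astype(float)
    gmap = build_genetic_map(pos, params.recomb_rate)
    gaps = np.diff(gmap)
    theta = 1.0 - np.exp(-4.0 * params.ne * gaps / K)
    # keep theta inside (0, 1): the floor avoids degenerate zero-recombination
    # intervals, the cap keeps the log-survival arithmetic finite
    theta = np.clip(theta, params.min_switch, 1.0 - 1e-12)
    # log survival (no-switch) probability cumulated over elementary intervals
    logsurv = np.concatenate([[0.0], np.cumsum(np.log1p(-theta))])

    def theta_between(a: int, b: int) -> float:
        return -np.expm1(logsurv[b] - logsurv[a])

    em = _emission_table(params.err)
    obs = np.flatnonzero(g != MISSING)
    ds = np.empty(M)
    var = np.empty(M)

    if obs.size == 0:
        m = Hf.mean(axis=0)
        ds[:] = 2.0 * m
        var[:] = 2.0 * m * (1.0 - m)
        return ds, var

    def emission(j: int) -> np.ndarray:
        s = H[:, j][:, None] + H[None, :, j]
        return em[g[j]][s]

    # forward over observed sites (normalised after each step)
    T = obs.size
    F_list = np.empty((T, K, K))
    F = np.full((K, K), 1.0 / (K * K))
    F *= emission(obs[0])
    F /= F.sum()
    F_list[0] = F
    for t in range(1, T):
        F = _pair_transition(F, theta_between(obs[t - 1], obs[t]), K)
        F *= emission(obs[t])
        F /= F.sum()
        F_list[t] = F

    # backward; G_t = emission_t * B_t, the quantity needed both for the
    # recursion and for bridging unobserved sites
    G = emission(obs[T - 1]).copy()  # B_{T-1} = 1
    G_right = G

    # sites strictly after the last observed site
    for i in range(obs[-1] + 1, M):
        P = _pair_transition(F_list[T - 1], theta_between(obs[-1], i), K)
        ds[i], var[i] = _site_moments(P, Hf[:, i])
    # walk intervals right-to-left
    for t in range(T - 1, 0, -1):
        a, b = obs[t - 1], obs[t]
        # posterior at observed site b
        # F_list[t] already includes emission at b; B_b = G_right / emission_b
        # but F*B = F_list[t] * B_b; use F_pre * G_right instead:
        F_pre = _pair_transition(F_list[t - 1], theta_between(a, b), K)
        P_b = F_pre * G_right
        ds[b], var[b] = _site_moments(P_b, Hf[:, b])
        # unobserved sites inside (a, b)
        for i in range(b - 1, a, -1):
            A = _pair_transition(F_list[t - 1], theta_between(a, i), K)
            Bp = _pair_transition(G_right, theta_between(i, b), K)
            ds[i], var[i] = _site_moments(A * Bp, Hf[:, i])
        # recursion: B_a = T(G_b); G_a = emission_a * B_a
        B_a = _pair_transition(G_right, theta_between(a, b), K)
        G_right = emission(a) * B_a
    # first observed site and everything before it
    P0 = np.full((K, K), 1.0 / (K * K)) * G_right
    ds[obs[0]], var[obs[0]] = _site_moments(P0, Hf[:, obs[0]])
    for i in range(obs[0] - 1, -1, -1):
        P = _pair_transition(G_right, theta_between(i, obs[0]), K)
        ds[i], var[i] = _site_moments(P, Hf[:, i])
    np.clip(ds, 0.0, 2.0, out=ds)  # guard against floating-point overshoot
    return ds, var


def impute_sample(
    target_gt,
    ref_haps,
    typed_mask,
    params: HmmParams,
    positions,
    chroms=None,
):
    """Impute one unphased sample against a phased reference.

    Parameters
    ----------
    target_gt
        Genotypes (0/1/2, MISSING allowed) at the typed sites, in typed-site
        order.
    ref_haps
        (K, M) reference haplotype alleles over all sequence sites.
    typed_mask
        Boolean mask of length M marking the typed sites.
    positions
        bp positions of all M sequence sites.
    chroms
        Optional chromosome label per site; the chain restarts at each
        chromosome change.  Omitted means a single chromosome.

    Returns
    -------
    (ds, post_var)
        Posterior expected dosage and dosage variance at every sequence site.
    """
    H = np.asarray(ref_haps, dtype=np.int8)
    K, M = H.shape
    if K < 1:
        raise ValueError("need at least one reference haplotype")
    typed_mask = np.asarray(typed_mask, dtype=bool)
    if typed_mask.shape != (M,):
        raise ValueError("typed_mask length mismatch")
    positions = np.asarray(positions, dtype=np.int64)
    tgt = np.asarray(target_gt)
    if tgt.shape[0] != int(typed_mask.sum()):
        raise ValueError("target genotypes must match the typed-site count")
    g = np.full(M, MISSING, dtype=np.int16)
    g[typed_mask] = tgt
    ds = np.empty(M)
    var = np.empty(M)
    if chroms is None:
        blocks = [np.arange(M)]
    else:
        chroms = np.asarray(chroms, dtype=object)
        blocks = []
        start = 0
        for i in range(1, M + 1):
            if i == M or chroms[i] != chroms[start]:
                blocks.append(np.arange(start, i))
                start = i
    for idx in blocks:
        d, v = _impute_chrom(g[idx], H[:, idx], positions[idx], params)
        ds[idx] = d
        var[idx] = v
    return ds, var


def compute_dr2(ds: np.ndarray, post_var: np.ndarray) -> np.ndarray:
    """Per-variant dosage R-squared.

    ``Var_samples(ds) / (Var_samples(ds) + mean_samples(post_var))``, clamped
    to [0, 1]; a variant with zero dosage variance and zero mean posterior
    variance gets DR2 = 0.
    """
    ds = np.asarray(ds, dtype=float)
    pv = np.asarray(post_var, dtype=float)
    if ds.shape[0] < 2:
        raise ValueError("DR2 needs at least two samples")
    v = ds.var(axis=0)
    m = pv.mean(axis=0)
    denom = v + m
    with np.errstate(invalid="ignore", divide="ignore"):
        dr2 = np.where(denom > 0, v / denom, 0.0)
    return np.clip(dr2, 0.0, 1.0)


def impute_panel(
    ref_gm: GenotypeMatrix,
    target_gm: GenotypeMatrix,
    typed_mask,
    params: HmmParams | None = None,
) -> ImputedDosages:
    """Impute every sample of ``target_gm`` against the phased ``ref_gm``.

    Both matrices must cover the same ordered sequence sites; targets use
    only their genotypes on ``typed_mask`` sites.  Samples are imputed
    independently, so results do not depend on target order.
    """
    params = params or HmmParams()
    if not ref_gm.phased or ref_gm.haplotypes is None:
        raise ValueError("reference panel must be phased")
    if ref_gm.n_variants != target_gm.n_variants:
        raise ValueError("reference and target must share the sequence site list")
    overlap = set(ref_gm.sample_ids) & set(target_gm.sample_ids)
    if overlap:
        raise ValueError(f"reference and target samples overlap: {sorted(overlap)[:3]}")
    typed_mask = np.asarray(typed_mask, dtype=bool)
    H = ref_gm.haplotypes
    pos = ref_gm.positions
    chroms = ref_gm.chroms
    n, M = target_gm.n_samples, target_gm.n_variants
    ds = np.empty((n, M))
    pv = np.empty((n, M))
    for i in range(n):
        tgt = target_gm.gt[i, typed_mask]
        ds[i], pv[i] = impute_sample(tgt, H, typed_mask, params, pos, chroms)
    dr2 = compute_dr2(ds, pv) if n >= 2 else np.full(M, np.nan)
    return ImputedDosages(
        sample_ids=list(target_gm.sample_ids),
        variants=list(target_gm.variants),
        ds=ds,
        post_var=pv,
        dr2=dr2,
    )
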