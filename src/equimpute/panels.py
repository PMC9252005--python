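"""Genetic relationships and nested reference-panel construction.

Pairwise identity-by-state (IBS) distances on array markers feed a classical
(Torgerson) multidimensional scaling; samples are then assigned to three
relationship tiers around a target cluster, and the tiers define nested
reference panels RP1 (tier 1) subset of RP2 (tiers 1-2) subset of RP3 (all).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vcf_io import MISSING, GenotypeMatrix, MarkerPanel

__all__ = [
    "DistanceMatrix",
    "MdsCoordinates",
    "ReferencePanelSpec",
    "ibs_distance",
    "classical_mds",
    "assign_relationship_groups",
    "build_reference_panels",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with entries in [0, 1]."""

    sample_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.sample_ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix is not symmetric")
        if (self.D < -1e-12).any() or (self.D > 1 + 1e-12).any():
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class MdsCoordinates:
    """Classical-MDS sample coordinates with non-increasing eigenvalues."""

    sample_ids: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class ReferencePanelSpec:
    """Nested reference panels derived from relationship tiers."""

    target_cluster: list[str]
    rp1: list[str]
    rp2: list[str]
    rp3: list[str]
    group_of: dict[str, int]

    def __post_init__(self) -> None:
        if not (set(self.rp1) <= set(self.rp2) <= set(self.rp3)):
            raise ValueError("reference panels must be nested rp1 <= rp2 <= rp3")
        if set(self.target_cluster) != set(self.rp1):
            raise ValueError("target cluster must equal rp1")


def ibs_distance(gm: GenotypeMatrix, panel: MarkerPanel | None = None) -> DistanceMatrix:
    """1 - IBS distance between all sample pairs over panel markers.

    For samples a, b the distance is ``1 - mean((2 - |g_a - g_b|)/2)`` over
    the panel sites where both genotypes are called; sites missing in either
    sample are skipped pairwise.
    """
    if gm.n_samples < 2:
        raise ValueError("IBS distance needs at least two samples")
    sub = gm if panel is None else gm.subset_sites(panel.mask(gm))
    if sub.n_variants == 0:
        raise ValueError("no overlap between panel and variant sites")
    G = sub.gt.astype(float)
    obs = sub.gt != MISSING
    G = np.where(obs, G, 0.0)
    O = obs.astype(float)
    # sum over shared sites of |ga-gb| via the identity
    # |ga-gb| expanded is awkward to vectorize exactly; do it blockwise.
    n = sub.n_samples
    D = np.zeros((n, n))
    for a in range(n):
        both = obs[a] & obs  # (n, m)
        diff = np.abs(sub.gt[a].astype(int) - sub.gt.astype(int))
        diff = np.where(both, diff, 0)
        m = both.sum(axis=1)
        if (m == 0).any():
            b = int(np.flatnonzero(m == 0)[0])
            raise ValueError(
                f"no overlapping called sites for pair "
                f"({sub.sample_ids[a]!r}, {sub.sample_ids[b]!r})"
            )
        sim = (2.0 * m - diff.sum(axis=1)) / (2.0 * m)
        D[a] = 1.0 - sim
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(sample_ids=list(sub.sample_ids), D=np.clip(D, 0.0, 1.0))


def classical_mds(dist: DistanceMatrix, k: int = 2) -> MdsCoordinates:
    """Torgerson scaling: eigendecomposition of the double-centered -D^2/2.

    Negative eigenvalues (non-Euclidean distance matrices) are truncated to
    zero-width dimensions rather than raised as errors.
    """
    n = len(dist.sample_ids)
    if not 1 <= k < n:
        raise ValueError("need 1 <= k < n_samples")
    D2 = dist.D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1][:k]
    w = w[order]
    V = V[:, order]
    lam = np.clip(w, 0.0, None)
    coords = V * np.sqrt(lam)[None, :]
    return MdsCoordinates(sample_ids=list(dist.sample_ids), coords=coords, eigenvalues=w)


def assign_relationship_groups(
    mds: MdsCoordinates,
    target_ids,
    t1: float | None = None,
    t2: float | None = None,
    dims: int = 2,
) -> dict[str, int]:
    """Assign each sample a relationship tier (1, 2, 3) around a target cluster.

    The centroid of ``target_ids`` in the first ``dims`` MDS dimensions defines
    the origin; distance <= t1 maps to tier 1, <= t2 to tier 2, beyond to
    tier 3 (boundaries inclusive low).  Default radii: t1 = 1.1x the maximum
    target-to-centroid distance, t2 = 3*t1.  Target samples are always tier 1.
    """
    target_ids = list(target_ids)
    if not target_ids:
        raise ValueError("target cluster must be non-empty")
    dims = min(dims, mds.coords.shape[1])
    lookup = {s: i for i, s in enumerate(mds.sample_ids)}
    for s in target_ids:
        if s not in lookup:
            raise KeyError(f"target sample {s!r} absent from MDS coordinates")
    X = mds.coords[:, :dims]
    tidx = [lookup[s] for s in target_ids]
    c = X[tidx].mean(axis=0)
    dist = np.linalg.norm(X - c, axis=1)
    if t1 is None:
        t1 = 1.1 * float(dist[tidx].max())
        if t1 == 0.0:
            t1 = 1e-12
    if t2 is None:
        t2 = 3.0 * t1
    if not 0 < t1 < t2:
        raise ValueError("radii must satisfy 0 < t1 < t2")
    tiers = np.where(dist <= t1, 1, np.where(dist <= t2, 2, 3))
    tiers[tidx] = 1
    return {s: int(t) for s, t in zip(mds.sample_ids, tiers)}


def build_reference_panels(tiers: dict[str, int]) -> ReferencePanelSpec:
    """Build nested RP1/RP2/RP3 sample sets from per-sample tier labels."""
    bad = {s: t for s, t in tiers.items() if t not in (1, 2, 3)}
    if bad:
        raise ValueError(f"tier labels must be 1, 2 or 3: {bad}")
    rp1 = [s for s, t in tiers.items() if t == 1]
    rp2 = rp1 + [s for s, t in tiers.items() if t == 2]
    rp3 = rp2 + [s for s, t in tiers.items() if t == 3]
    if not rp1:
        raise ValueError("tier 1 (target cluster) is empty")
    return ReferencePanelSpec(
        target_cluster=list(rp1), rp1=list(rp1), rp2=rp2, rp3=rp3, group_of=dict(tiers)
    )
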