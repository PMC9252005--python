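"""Monte Carlo analysis of variance between marker panels.

Quantifies the proportion of the genotypic variation in one panel (e.g. the
sequence data) that is captured by another (e.g. a 60K array or an imputed
panel): repeatedly draw a focal variant from panel A, regress its genotype
vector on the panel-B variants within a local window around it, and average
the adjusted R-squared over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vcf_io import GenotypeMatrix

__all__ = ["McAnovaConfig", "ExplainedVariance", "mc_anova", "explained_variance_matrix"]


@dataclass(frozen=True)
class McAnovaConfig:
    """Replicates, window width (bp) and seed for the Monte Carlo ANOVA."""

    window_bp: int = 1_000_000
    replicates: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.window_bp <= 0:
            raise ValueError("need replicates >= 1 and window_bp > 0")


@dataclass
class ExplainedVariance:
    """Mean adjusted R-squared of `from_panel` variation on `to_panel`
    predictors, with its Monte Carlo standard error."""

    from_panel: str
    to_panel: str
    proportion: float
    mc_se: float
    n_replicates: int


def _adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted R-squared of y on X (both centered), floored at 0, capped
    at 1; exact fits snap to 1."""
    n = y.size
    p = X.shape[1]
    if p == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(y @ y)
    if sst <= 0:
        return 0.0
    sse = float(resid @ resid)
    r2 = 1.0 - sse / sst
    if sse <= 1e-10 * sst:
        return 1.0
    if n - p - 1 <= 0:
        return max(0.0, min(1.0, r2))
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return max(0.0, min(1.0, adj))


def mc_anova(A: GenotypeMatrix, B: GenotypeMatrix, cfg: McAnovaConfig) -> ExplainedVariance:
    """Proportion of panel-A variation explained by panel B.

    Per replicate a focal variant is drawn uniformly from A's polymorphic
    sites and its centered genotype vector is regressed on the centered
    genotypes of B's sites within +-window/2 of the focal position (same
    chromosome).  Predictors are capped at n-2 by strongest-correlation
    screening; an empty window contributes 0.  Deterministic given the seed.
    """
    if A.sample_ids != B.sample_ids:
        raise ValueError("panels must cover the same samples in the same order")
    n = A.n_samples
    if n < 3:
        raise ValueError("need at least three samples")
    GA = A.gt.astype(float)
    GB = B.gt.astype(float)
    GA -= GA.mean(axis=0)
    GB -= GB.mean(axis=0)
    poly = np.flatnonzero(GA.var(axis=0) > 0)
    if poly.size == 0:
        raise ValueError("panel A has no polymorphic site")
    chromsA, posA = A.chroms, A.positions
    chromsB, posB = B.chroms, B.positions
    half = cfg.window_bp / 2.0
    rng = np.random.default_rng(cfg.seed)
    vals = np.empty(cfg.replicates)
    for rep in range(cfg.replicates):
        j = int(rng.choice(poly))
        y = GA[:, j]
        sel = (chromsB == chromsA[j]) & (np.abs(posB - posA[j]) <= half)
        X = GB[:, sel]
        keep = X.var(axis=0) > 0
        X = X[:, keep]
        if X.shape[1] > n - 2:
            yn = y / np.linalg.norm(y)
            norms = np.linalg.norm(X, axis=0)
            corr = np.abs(X.T @ yn) / norms
            top = np.argsort(corr)[::-1][: n - 2]
            X = X[:, np.sort(top)]
        vals[rep] = _adjusted_r2(y, X)
    prop = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(cfg.replicates)) if cfg.replicates > 1 else 0.0
    return ExplainedVariance(
        from_panel="A",
        to_panel="B",
        proportion=prop,
        mc_se=se,
        n_replicates=cfg.replicates,
    )


def explained_variance_matrix(
    panels: dict[str, GenotypeMatrix], cfg: McAnovaConfig
) -> dict[tuple[str, str], ExplainedVariance]:
    """MC-ANOVA for every ordered pair of labelled panels."""
    labels = list(panels)
    if len(labels) < 2:
        raise ValueError("need at least two panels")
    first = panels[labels[0]].sample_ids
    for lab in labels[1:]:
        if panels[lab].sample_ids != first:
            raise ValueError("all panels must cover the same samples")
    out: dict[tuple[str, str], ExplainedVariance] = {}
    for a in labels:
        for b in labels:
            if a == b:
                continue
            ev = mc_anova(panels[a], panels[b], cfg)
            ev.from_panel, ev.to_panel = a, b
            out[(a, b)] = ev
    return out
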