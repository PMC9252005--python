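"""Cross-validated imputation scenarios and accuracy scoring.

The target cluster (RP1 samples) is split into k folds; one fold is masked
down to an array panel and imputed back to sequence level from a reference
built out of the remaining folds (optionally only the cyclically following
two or three folds, or additionally the tier-2/tier-3 samples of RP2/RP3).
Per-variant accuracy r is the Pearson correlation between true genotypes and
imputed dosages pooled over validation samples, with multiallelic sites and
sites lacking variation in any single validation fold excluded.  A two-step
scenario first imputes medium-to-high density (optionally filtering step-one
sites by DR2) and then high-to-sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lihmm import HmmParams, ImputedDosages, impute_panel
from .panels import ReferencePanelSpec
from .vcf_io import MISSING, GenotypeMatrix, MarkerPanel

__all__ = [
    "FoldAssignment",
    "ScenarioConfig",
    "AggregateAccuracy",
    "make_folds",
    "select_cyclic_folds",
    "mask_to_panel",
    "run_scenario",
    "accuracy_per_variant",
    "reference_maf",
    "aggregate_accuracy",
]


class ScenarioError(ValueError):
    """Inconsistent scenario configuration."""


@dataclass
class FoldAssignment:
    """Deterministic k-fold split with fold sizes differing by at most one."""

    fold_of: dict[str, int]
    k: int
    seed: int

    def samples_in(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f == fold]

    def samples_in_folds(self, folds) -> list[str]:
        want = set(folds)
        return [s for s, f in self.fold_of.items() if f in want]


@dataclass
class ScenarioConfig:
    """One imputation scenario.

    ``reference_mode`` is ``"rp1"`` (cyclically following ``ref_folds`` of
    the target cluster, ``ref_folds`` in {2, 3, 4}), ``"rp2"`` or ``"rp3"``
    (all remaining folds plus the tier-2 / tier-2+3 samples).  ``density``
    picks the array panel the targets keep.  ``two_step`` runs
    medium-to-high then high-to-sequence, with an optional DR2 threshold on
    the step-one output.  ``joint_target`` imputes the whole target cluster
    at once from a tier-2/3-only reference (information-content scenario).
    """

    validation_fold: int = 0
    reference_mode: str = "rp1"
    ref_folds: int = 4
    density: str = "medium"
    two_step: bool = False
    dr2_threshold: float | None = None
    joint_target: bool = False
    hmm: HmmParams = field(default_factory=HmmParams)

    def __post_init__(self) -> None:
        if self.reference_mode not in ("rp1", "rp2", "rp3"):
            raise ScenarioError("reference_mode must be rp1, rp2 or rp3")
        if self.density not in ("medium", "high"):
            raise ScenarioError("density must be medium or high")
        if self.two_step and self.density != "medium":
            raise ScenarioError("two-step imputation starts from medium density")
        if self.dr2_threshold is not None and not self.two_step:
            raise ScenarioError("dr2_threshold applies to two-step scenarios only")
        if self.dr2_threshold is not None and not 0 <= self.dr2_threshold <= 1:
            raise ScenarioError("dr2_threshold must lie in [0, 1]")


def make_folds(ids, k: int, seed: int) -> FoldAssignment:
    """Split ids into k folds by a seeded permutation cut into contiguous
    blocks; block sizes differ by at most one."""
    ids = list(ids)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > len(ids):
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    fold_of: dict[str, int] = {}
    for f, block in enumerate(np.array_split(np.arange(len(ids)), k)):
        for i in block:
            fold_of[perm[i]] = f
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed)


def select_cyclic_folds(
    validation_fold: int, m: int, direction: str = "following", k: int = 5
) -> list[int]:
    """The m folds cyclically after (or before) the validation fold."""
    if not 1 <= m <= k - 1:
        raise ValueError("need 1 <= m <= k-1")
    if direction == "following":
        return [(validation_fold + i) % k for i in range(1, m + 1)]
    if direction == "previous":
        return [(validation_fold - m + i) % k for i in range(m)]
    raise ValueError("direction must be 'following' or 'previous'")


def mask_to_panel(gm: GenotypeMatrix, panel: MarkerPanel) -> GenotypeMatrix:
    """Set genotypes outside the panel to missing, keeping all sites in the
    matrix so they remain imputation targets.  Idempotent."""
    keep = panel.mask(gm)
    gt = np.where(keep[None, :], gm.gt, MISSING).astype(np.int8)
    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        variants=list(gm.variants),
        gt=gt,
        phased=False,
        haplotypes=None,
    )


def _reference_samples(
    rp: ReferencePanelSpec, folds: FoldAssignment, sc: ScenarioConfig
) -> list[str]:
    v = sc.validation_fold
    if sc.reference_mode == "rp1":
        ref_folds = select_cyclic_folds(v, sc.ref_folds, "following", folds.k)
        return folds.samples_in_folds(ref_folds)
    base = folds.samples_in_folds([f for f in range(folds.k) if f != v])
    tier2 = [s for s in rp.rp2 if s not in set(rp.rp1)]
    if sc.reference_mode == "rp2":
        return base + tier2
    tier3 = [s for s in rp.rp3 if s not in set(rp.rp2)]
    return base + tier2 + tier3


def run_scenario(
    data,
    rp: ReferencePanelSpec,
    folds: FoldAssignment,
    sc: ScenarioConfig,
) -> ImputedDosages:
    """Impute the scenario's validation samples to sequence level.

    ``data`` is a :class:`~equimpute.popsim.SimulatedDataset` (or any object
    with ``gm``, ``medium`` and ``high`` attributes); reference haplotypes
    come from its phased truth matrix.
    """
    gm: GenotypeMatrix = data.gm
    if sc.joint_target:
        targets = list(rp.rp1)
        ref_ids = [s for s in gm.sample_ids if s in set(rp.rp3) - set(rp.rp1)]
    else:
        targets = folds.samples_in(sc.validation_fold)
        ref_ids = _reference_samples(rp, folds, sc)
    if set(targets) & set(ref_ids):
        raise ScenarioError("reference and validation sample sets overlap")

    panel = data.medium if sc.density == "medium" else data.high
    target_gm = mask_to_panel(gm.subset_samples(targets), panel)

    if not sc.two_step:
        ref_gm = gm.subset_samples(ref_ids)
        return impute_panel(ref_gm, target_gm, panel.mask(gm), sc.hmm)

    # --- two-step: medium -> high, then high -> sequence -----------------
    prev = folds.samples_in_folds(
        select_cyclic_folds(sc.validation_fold, 2, "previous", folds.k)
    )
    nxt = folds.samples_in_folds(
        select_cyclic_folds(sc.validation_fold, 2, "following", folds.k)
    )
    high_mask = data.high.mask(gm)
    # step 1 runs on the high-panel site space
    gm_high = gm.subset_sites(high_mask)
    ref1 = gm_high.subset_samples(prev)
    tgt1 = mask_to_panel(gm_high.subset_samples(targets), data.medium)
    step1 = impute_panel(ref1, tgt1, data.medium.mask(gm_high), sc.hmm)

    keep1 = np.ones(gm_high.n_variants, dtype=bool)
    if sc.dr2_threshold is not None:
        keep1 = step1.dr2 >= sc.dr2_threshold
    # best-guess genotypes from step-1 dosages feed step 2
    bg = np.rint(step1.ds).clip(0, 2).astype(np.int8)

    typed2 = np.zeros(gm.n_variants, dtype=bool)
    high_idx = np.flatnonzero(high_mask)
    typed2[high_idx[keep1]] = True
    tgt2_gt = np.full((len(targets), gm.n_variants), MISSING, dtype=np.int8)
    tgt2_gt[:, typed2] = bg[:, keep1]
    tgt2 = GenotypeMatrix(
        sample_ids=list(targets), variants=list(gm.variants), gt=tgt2_gt
    )
    ref2 = gm.subset_samples(nxt)
    return impute_panel(ref2, tgt2, typed2, sc.hmm)


def reference_maf(gm: GenotypeMatrix, rp1_ids) -> np.ndarray:
    """Per-variant minor allele frequency from the RP1 sequence genotypes
    (NaN where all RP1 genotypes are missing)."""
    rp1_ids = list(rp1_ids)
    if not rp1_ids:
        raise ValueError("RP1 sample set is empty")
    return gm.subset_samples(rp1_ids).maf()


def accuracy_per_variant(
    observed: GenotypeMatrix,
    dosages: ImputedDosages,
    folds: FoldAssignment,
    maf: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant imputation accuracy with the study's exclusion rules.

    r is the Pearson correlation between true genotypes and dosages pooled
    over all provided validation samples.  A variant is excluded when it is
    multiallelic, when its dosages are absent (``not_imputed``), or when the
    observed genotypes or the dosages show no variation within any single
    validation fold.  Columns: chrom, pos, maf, r, included, reason.
    """
    if observed.sample_ids != dosages.sample_ids:
        observed = observed.subset_samples(dosages.sample_ids)
    n = observed.n_samples
    if n < 2:
        raise ValueError("need at least two pooled validation samples")
    gt = observed.gt.astype(float)
    gt[observed.gt == MISSING] = np.nan
    ds = dosages.ds
    fold_groups = {}
    for i, s in enumerate(observed.sample_ids):
        fold_groups.setdefault(folds.fold_of[s], []).append(i)
    rows = []
    for j, v in enumerate(observed.variants):
        reason = "ok"
        r = np.nan
        if v.is_multiallelic:
            reason = "multiallelic"
        elif not np.all(np.isfinite(ds[:, j])):
            reason = "not_imputed"
        else:
            for idx in fold_groups.values():
                o = gt[idx, j]
                o = o[np.isfinite(o)]
                if o.size == 0 or np.ptp(o) == 0:
                    reason = "no_variation_obs"
                    break
                if np.ptp(ds[idx, j]) == 0:
                    reason = "no_variation_dosage"
                    break
        if reason == "ok":
            mask = np.isfinite(gt[:, j])
            r = float(np.corrcoef(gt[mask, j], ds[mask, j])[0, 1])
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "maf": np.nan if maf is None else float(maf[j]),
                "r": r,
                "included": reason == "ok",
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AggregateAccuracy:
    """Mean accuracy overall and by chromosome, genomic window and MAF bin,
    plus an optional OLS of window accuracy on window marker density."""

    overall_r: float
    by_chromosome: pd.DataFrame
    by_window: pd.DataFrame
    by_maf_bin: pd.DataFrame
    density_regression: dict | None = None


def aggregate_accuracy(
    tab: pd.DataFrame,
    window_bp: int = 1_000_000,
    maf_bins=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    panel: MarkerPanel | None = None,
) -> AggregateAccuracy:
    """Aggregate an accuracy table over chromosomes, half-open windows
    [start, start + window_bp) and half-open MAF bins (x, y].

    When ``panel`` is given, an ordinary least-squares regression of mean
    window accuracy on window marker density (markers per Mb) is reported as
    slope, intercept and adjusted R-squared.
    """
    if window_bp <= 0:
        raise ValueError("window width must be positive")
    inc = tab[tab["included"]].copy()
    if inc.empty:
        raise ValueError("no included variants to aggregate")
    overall = float(inc["r"].mean())
    by_chrom = (
        inc.groupby("chrom", sort=False)["r"].agg(["mean", "count"]).reset_index()
    ).rename(columns={"mean": "mean_r", "count": "n"})
    inc["win_start"] = ((inc["pos"] - 1) // window_bp) * window_bp + 1
    by_window = (
        inc.groupby(["chrom", "win_start"], sort=False)["r"]
        .agg(["mean", "count"])
        .reset_index()
    ).rename(columns={"mean": "mean_r", "count": "n"})

    edges = np.asarray(maf_bins, dtype=float)
    with_maf = inc[np.isfinite(inc["maf"]) & (inc["maf"] > edges[0])]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = with_maf[(with_maf["maf"] > lo) & (with_maf["maf"] <= hi)]
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "mean_r": float(sel["r"].mean()) if len(sel) else np.nan,
                "n": len(sel),
            }
        )
    by_maf = pd.DataFrame(rows)

    regression = None
    if panel is not None and len(by_window) >= 3:
        counts = {}
        for chrom, pos in panel.sites:
            key = (chrom, ((pos - 1) // window_bp) * window_bp + 1)
            counts[key] = counts.get(key, 0) + 1
        dens = np.array(
            [
                counts.get((c, w), 0) / (window_bp / 1e6)
                for c, w in zip(by_window["chrom"], by_window["win_start"])
            ]
        )
        y = by_window["mean_r"].to_numpy()
        X = np.column_stack([np.ones_like(dens), dens])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sst = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 1.0
        if r2 > 1 - 1e-12:
            r2 = 1.0
        n_w = len(y)
        adj = 1.0 - (1.0 - r2) * (n_w - 1) / (n_w - 2)
        regression = {
            "slope": float(beta[1]),
            "intercept": float(beta[0]),
            "adj_r2": float(adj),
        }
    return AggregateAccuracy(
        overall_r=overall,
        by_chromosome=by_chrom,
        by_window=by_window,
        by_maf_bin=by_maf,
        density_regression=regression,
    )
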