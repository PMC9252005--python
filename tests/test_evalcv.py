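from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from equimpute.evalcv import (
    FoldAssignment,
    ScenarioConfig,
    ScenarioError,
    _reference_samples,
    accuracy_per_variant,
    aggregate_accuracy,
    make_folds,
    mask_to_panel,
    reference_maf,
    run_scenario,
    select_cyclic_folds,
)
from equimpute.lihmm import ImputedDosages
from equimpute.panels import build_reference_panels
from equimpute.vcf_io import MISSING, MarkerPanel

from conftest import make_gm


# ---------------------------------------------------------------------------
# fold bookkeeping
# ---------------------------------------------------------------------------

def test_sixty_five_samples_five_folds_of_thirteen():
    ids = [f"h{i}" for i in range(65)]
    folds = make_folds(ids, 5, seed=42)
    sizes = sorted(len(folds.samples_in(f)) for f in range(5))
    assert sizes == [13] * 5


def test_folds_deterministic_and_balanced():
    ids = [f"h{i}" for i in range(7)]
    a = make_folds(ids, 3, seed=1)
    b = make_folds(ids, 3, seed=1)
    assert a.fold_of == b.fold_of
    sizes = sorted((len(a.samples_in(f)) for f in range(3)), reverse=True)
    assert sizes == [3, 2, 2]
    with pytest.raises(ValueError):
        make_folds(ids, 8, seed=1)


@pytest.mark.parametrize(
    "v, m, direction, expected",
    [
        (2, 2, "following", [3, 4]),   # validation (c) -> (d), (e)
        (2, 3, "following", [3, 4, 0]),  # validation (c) -> (d), (e), (a)
        (1, 2, "previous", [4, 0]),    # validation (b) -> (e), (a)
    ],
)
def test_cyclic_fold_selection_worked_examples(v, m, direction, expected):
    assert select_cyclic_folds(v, m, direction, k=5) == expected


def test_cyclic_fold_selection_bounds():
    with pytest.raises(ValueError):
        select_cyclic_folds(0, 5, "following", k=5)


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def test_mask_to_panel_counts_and_idempotence():
    gm = make_gm(np.ones((2, 10), dtype=np.int8), positions=range(100, 1100, 100))
    panel = MarkerPanel.from_sites("p", [("1", 100), ("1", 300), ("1", 500)])
    masked = mask_to_panel(gm, panel)
    assert (masked.gt == MISSING).all(axis=0).sum() == 7
    twice = mask_to_panel(masked, panel)
    assert np.array_equal(twice.gt, masked.gt)
    empty = mask_to_panel(gm, MarkerPanel.from_sites("e", []))
    assert (empty.gt == MISSING).all()


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

def _dosages_for(gm, ds):
    ds = np.asarray(ds, dtype=float)
    return ImputedDosages(
        sample_ids=list(gm.sample_ids),
        variants=list(gm.variants),
        ds=ds,
        post_var=np.zeros_like(ds),
        dr2=np.ones(ds.shape[1]),
    )


def _two_fold_assignment(ids):
    half = len(ids) // 2
    return FoldAssignment(
        fold_of={s: (0 if i < half else 1) for i, s in enumerate(ids)}, k=2, seed=0
    )


def test_perfect_dosages_r_one():
    gt = np.array([[0, 1], [1, 0], [2, 2], [1, 0]], dtype=np.int8)
    gm = make_gm(gt)
    folds = _two_fold_assignment(gm.sample_ids)
    tab = accuracy_per_variant(gm, _dosages_for(gm, gt.astype(float)), folds)
    assert tab["included"].all()
    assert np.allclose(tab["r"], 1.0)


def test_constant_truth_in_one_fold_excluded():
    # fold 0 = samples 0,1 ; fold 1 = samples 2,3; variant 0 constant in fold 1
    gt = np.array([[0, 1], [1, 0], [1, 2], [1, 0]], dtype=np.int8)
    gm = make_gm(gt)
    folds = _two_fold_assignment(gm.sample_ids)
    ds = np.array([[0.1, 1], [0.9, 0], [1.2, 2], [0.8, 0.1]])
    tab = accuracy_per_variant(gm, _dosages_for(gm, ds), folds)
    assert not tab.loc[0, "included"]
    assert tab.loc[0, "reason"] == "no_variation_obs"
    assert tab.loc[1, "included"]


def test_constant_dosage_in_one_fold_excluded():
    gt = np.array([[0], [1], [1], [2]], dtype=np.int8)
    gm = make_gm(gt)
    folds = _two_fold_assignment(gm.sample_ids)
    ds = np.array([[0.5], [0.5], [1.0], [2.0]])
    tab = accuracy_per_variant(gm, _dosages_for(gm, ds), folds)
    assert tab.loc[0, "reason"] == "no_variation_dosage"


def test_multiallelic_excluded():
    gm = make_gm(np.array([[0, 1], [1, 0], [2, 1], [0, 0]], dtype=np.int8),
                 alts=[("G", "T"), ("G",)])
    folds = _two_fold_assignment(gm.sample_ids)
    ds = np.array([[0.0, 1], [1, 0], [2, 1], [0, 0.2]], dtype=float)
    tab = accuracy_per_variant(gm, _dosages_for(gm, ds), folds)
    assert tab.loc[0, "reason"] == "multiallelic"


def test_pooled_pearson_hand_example():
    """r for truth (0,0,1,2) vs dosages (0.2,0.1,0.9,1.7), computed here from
    the raw definition."""
    t = np.array([0.0, 0.0, 1.0, 2.0])
    d = np.array([0.2, 0.1, 0.9, 1.7])
    ct, cd = t - t.mean(), d - d.mean()
    expected = (ct @ cd) / math.sqrt((ct @ ct) * (cd @ cd))
    gm = make_gm(t.reshape(-1, 1).astype(np.int8))
    folds = FoldAssignment(fold_of={s: 0 for s in gm.sample_ids}, k=1, seed=0)
    tab = accuracy_per_variant(gm, _dosages_for(gm, d.reshape(-1, 1)), folds)
    assert tab.loc[0, "r"] == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.998343, abs=1e-6)


def test_exclusion_reasons_match_bruteforce():
    rng = np.random.default_rng(8)
    n, m = 8, 40
    gt = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    gm = make_gm(gt)
    folds = _two_fold_assignment(gm.sample_ids)
    ds = gt + rng.normal(0, 0.3, size=(n, m))
    ds = np.clip(ds, 0, 2)
    tab = accuracy_per_variant(gm, _dosages_for(gm, ds), folds)
    groups = [list(range(4)), list(range(4, 8))]
    for j in range(m):
        expected = "ok"
        for idx in groups:
            if len(set(gt[idx, j])) == 1:
                expected = "no_variation_obs"
                break
            if len(set(ds[idx, j])) == 1:
                expected = "no_variation_dosage"
                break
        assert tab.loc[j, "reason"] == expected


# ---------------------------------------------------------------------------
# MAF from RP1
# ---------------------------------------------------------------------------

def test_reference_maf_all_heterozygous():
    gm = make_gm(np.ones((4, 1), dtype=np.int8))
    assert reference_maf(gm, gm.sample_ids)[0] == 0.5


def test_reference_maf_thirteen_of_130_alleles():
    gt = np.zeros((65, 1), dtype=np.int8)
    gt[:13] = 1
    gm = make_gm(gt)
    assert reference_maf(gm, gm.sample_ids)[0] == pytest.approx(0.1)


def test_reference_maf_ignores_non_rp1_samples():
    gt = np.array([[1], [1], [0], [0]], dtype=np.int8)
    gm = make_gm(gt)
    before = reference_maf(gm, ["s0", "s1"])
    gt2 = gt.copy()
    gt2[2:] = 2
    gm2 = make_gm(gt2)
    after = reference_maf(gm2, ["s0", "s1"])
    assert before[0] == after[0]


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_aggregate_single_variant():
    tab = pd.DataFrame(
        [{"chrom": "1", "pos": 500, "maf": 0.3, "r": 0.7, "included": True,
          "reason": "ok"}]
    )
    agg = aggregate_accuracy(tab, window_bp=1000)
    assert agg.overall_r == 0.7
    assert agg.by_window.loc[0, "mean_r"] == 0.7


def test_maf_bin_half_open_convention():
    rows = [
        {"chrom": "1", "pos": 100, "maf": 0.2, "r": 0.5, "included": True, "reason": "ok"},
        {"chrom": "1", "pos": 200, "maf": 0.21, "r": 0.9, "included": True, "reason": "ok"},
    ]
    agg = aggregate_accuracy(pd.DataFrame(rows), maf_bins=(0.1, 0.2, 0.3))
    # maf = 0.2 belongs to (0.1, 0.2], maf = 0.21 to (0.2, 0.3]
    assert agg.by_maf_bin.loc[0, "mean_r"] == 0.5
    assert agg.by_maf_bin.loc[1, "mean_r"] == 0.9


def test_density_regression_recovers_exact_line():
    rows = []
    panel_sites = []
    window_bp = 1_000_000
    for w, n_markers in enumerate([5, 10, 20, 40]):
        start = w * window_bp
        density = n_markers / (window_bp / 1e6)
        r = 0.1 + 0.02 * density
        rows.append({"chrom": "1", "pos": start + 1, "maf": 0.3, "r": r,
                     "included": True, "reason": "ok"})
        for i in range(n_markers):
            panel_sites.append(("1", start + 10 + i))
    panel = MarkerPanel.from_sites("p", panel_sites)
    agg = aggregate_accuracy(pd.DataFrame(rows), window_bp=window_bp, panel=panel)
    reg = agg.density_regression
    assert reg["slope"] == pytest.approx(0.02, abs=1e-12)
    assert reg["intercept"] == pytest.approx(0.1, abs=1e-9)
    assert reg["adj_r2"] == pytest.approx(1.0)


def test_aggregate_empty_table_errors():
    tab = pd.DataFrame(
        [{"chrom": "1", "pos": 1, "maf": 0.1, "r": np.nan, "included": False,
          "reason": "multiallelic"}]
    )
    with pytest.raises(ValueError):
        aggregate_accuracy(tab)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def test_scenario_config_invariants():
    with pytest.raises(ScenarioError):
        ScenarioConfig(two_step=True, density="high")
    with pytest.raises(ScenarioError):
        ScenarioConfig(dr2_threshold=0.4, two_step=False)


def test_dr2_threshold_keeps_boundary_site():
    dr2 = np.array([0.39, 0.40, 0.80])
    keep = dr2 >= 0.4
    assert list(keep) == [False, True, True]


def test_reference_sample_set_arithmetic(small_dataset):
    d = small_dataset
    rp = build_reference_panels(d.tier_of)
    folds = make_folds(rp.rp1, 5, seed=0)
    n_t2 = sum(1 for t in d.tier_of.values() if t == 2)
    n_t3 = sum(1 for t in d.tier_of.values() if t == 3)
    n_rp1_4folds = len(rp.rp1) - len(folds.samples_in(0))
    sc = ScenarioConfig(0, "rp3", 4, "medium")
    ref = _reference_samples(rp, folds, sc)
    assert len(ref) == n_rp1_4folds + n_t2 + n_t3
    sc2 = ScenarioConfig(0, "rp1", 2, "medium")
    assert len(_reference_samples(rp, folds, sc2)) == len(
        folds.samples_in(1)
    ) + len(folds.samples_in(2))


def test_run_scenario_leakage_oracle(small_dataset):
    """With the validation haplotypes leaked into the reference and a tiny
    error rate, dosages reproduce the truth almost exactly (contract-violation
    oracle, not a supported configuration)."""
    from equimpute.lihmm import HmmParams, impute_panel

    d = small_dataset
    rp = build_reference_panels(d.tier_of)
    targets = rp.rp1[:2]
    ref = d.gm.subset_samples(rp.rp1)  # includes the targets: leakage
    tgt = mask_to_panel(d.gm.subset_samples(targets), d.high)
    renamed = ref
    renamed.sample_ids = [f"ref_{s}" for s in ref.sample_ids]
    dos = impute_panel(renamed, tgt, d.high.mask(d.gm), HmmParams(err=1e-8))
    truth = d.gm.subset_samples(targets).gt
    assert np.mean(np.abs(dos.ds - truth)) < 0.05


def test_two_step_scenario_runs_and_is_bounded(small_dataset):
    d = small_dataset
    rp = build_reference_panels(d.tier_of)
    folds = make_folds(rp.rp1, 5, seed=1)
    sc = ScenarioConfig(1, "rp1", 4, "medium", two_step=True, dr2_threshold=0.4)
    dos = run_scenario(d, rp, folds, sc)
    assert dos.ds.shape == (len(folds.samples_in(1)), d.gm.n_variants)
    assert (dos.ds >= 0).all() and (dos.ds <= 2).all()


def test_joint_target_scenario_uses_outside_reference(small_dataset):
    """The information-content scenario imputes the whole target cluster at
    once with only tier-2/3 animals as reference."""
    d = small_dataset
    rp = build_reference_panels(d.tier_of)
    folds = make_folds(rp.rp1, 5, seed=2)
    sc = ScenarioConfig(0, "rp1", 4, "medium", joint_target=True)
    dos = run_scenario(d, rp, folds, sc)
    assert dos.sample_ids == rp.rp1
    assert dos.ds.shape == (len(rp.rp1), d.gm.n_variants)
    assert (dos.dr2 >= 0).all() and (dos.dr2 <= 1).all()


def test_run_scenario_rejects_reference_target_overlap(small_dataset):
    d = small_dataset
    rp = build_reference_panels(d.tier_of)
    folds = make_folds(rp.rp1, 5, seed=1)
    # force an overlap by marking every sample fold 0 and asking for rp1 refs
    bad = FoldAssignment(fold_of={s: 0 for s in rp.rp1}, k=5, seed=0)
    with pytest.raises((ScenarioError, ValueError)):
        run_scenario(d, rp, bad, ScenarioConfig(0, "rp1", 4, "medium"))
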