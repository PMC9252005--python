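from __future__ import annotations

import numpy as np
import pytest

from equimpute.popsim import BreedGroupSpec, SimConfig, simulate_dataset
from equimpute.vcf_io import GenotypeMatrix, VariantRecord


def make_gm(gt, positions=None, chrom="1", sample_ids=None, phased=False, haps=None,
            refs=None, alts=None, impacts=None):
    """Build a small GenotypeMatrix from a samples x variants array."""
    gt = np.asarray(gt, dtype=np.int8)
    n, m = gt.shape
    if positions is None:
        positions = list(range(100, 100 + 100 * m, 100))
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    variants = [
        VariantRecord(
            chrom=chrom,
            pos=int(positions[j]),
            id=None,
            ref=(refs[j] if refs else "A"),
            alts=tuple(alts[j]) if alts else ("G",),
            impact=(impacts[j] if impacts else None),
        )
        for j in range(m)
    ]
    return GenotypeMatrix(
        sample_ids=list(sample_ids), variants=variants, gt=gt,
        phased=phased, haplotypes=haps,
    )


def random_phased_gm(rng, n_samples=4, n_variants=8, chrom="1"):
    haps = rng.integers(0, 2, size=(2 * n_samples, n_variants)).astype(np.int8)
    gt = haps[0::2] + haps[1::2]
    pos = np.sort(rng.choice(np.arange(100, 100000), size=n_variants, replace=False))
    return make_gm(gt, positions=pos, chrom=chrom, phased=True, haps=haps)


def small_sim_config(seed=0, **overrides):
    """A miniature simulation profile for fast functional tests."""
    kwargs = dict(
        seed=seed,
        chrom_lengths={"1": 2_000_000},
        n_variants=1500,
        panel_sizes=(50, 400),
        breeds=[
            BreedGroupSpec("wb", 1, 0.02, 20),
            BreedGroupSpec("rel", 2, 0.12, 8),
            BreedGroupSpec("far", 3, 0.30, 8),
        ],
        coverage_gaps=[],
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_sim_config(seed=11))
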