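import numpy as np
import pandas as pd
import pytest

from chipscan.containers import DosageMatrix


def make_dosage(values, positions=None, chrom="1", sample_prefix="S",
                counted=None, other=None):
    """Small DosageMatrix from a literal array."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    positions = positions or [1000 + 100 * j for j in range(m)]
    counted = counted or ["A"] * m
    other = other or ["G"] * m
    variants = pd.DataFrame({
        "variant_id": [f"{chrom}:{p}:{o}:{c}"
                       for p, o, c in zip(positions, other, counted)],
        "chrom": chrom,
        "pos": positions,
        "counted_allele": counted,
        "other_allele": other,
    })
    return DosageMatrix(sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
                        variants=variants, values=values)


def make_sumstats(dm: DosageMatrix, beta, pvalue, gene_id="GENE", tss=1000):
    v = dm.variants
    return pd.DataFrame({
        "gene_id": gene_id,
        "variant_id": v["variant_id"],
        "chrom": v["chrom"],
        "pos": v["pos"],
        "effect_allele": v["counted_allele"],
        "other_allele": v["other_allele"],
        "eaf": np.nanmean(dm.values, axis=0) / 2,
        "beta": np.asarray(beta, dtype=float),
        "se": 0.1,
        "pvalue": np.asarray(pvalue, dtype=float),
        "n": 1000,
        "tss": tss,
    })


@pytest.fixture
def dosage_factory():
    return make_dosage


@pytest.fixture
def sumstats_factory():
    return make_sumstats
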