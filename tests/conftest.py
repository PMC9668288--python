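import math

import numpy as np
import pandas as pd
import pytest

from rvburden.simulate import (
    BinaryPhenotypeConfig,
    GeneConfig,
    HaplotypeConfig,
    QuantitativePhenotypeConfig,
    SimulationConfig,
    generate_cohort,
)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Independent exact-rational enumeration of the two-sided Fisher p.

    Probabilities come from the factorial form of the hypergeometric pmf
    in ``Fraction`` arithmetic, so tie comparisons are exact.
    """
    from fractions import Fraction
    from math import factorial

    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if n == 0 or 0 in (r1, r2) or c1 in (0, n):
        return 1.0

    def prob(x: int) -> Fraction:
        return Fraction(
            factorial(r1) * factorial(r2) * factorial(c1) * factorial(c2),
            factorial(n) * factorial(x) * factorial(r1 - x) * factorial(c1 - x)
            * factorial(r2 - c1 + x),
        )

    lo, hi = max(0, c1 - r2), min(c1, r1)
    p_obs = prob(a)
    return float(sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs))


def recessive_scan_oracle(dosage, qv_idx, is_male, on_x, positions):
    """Brute-force per-sample recessive carrier scan."""
    n = dosage.shape[0]
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        hom = False
        het_positions = set()
        for j in qv_idx:
            d = dosage[i, j]
            if d == 2:
                hom = True
            elif d == 1:
                het_positions.add(positions[j])
        out[i] = hom or len(het_positions) >= 2
    return out


@pytest.fixture(scope="session")
def demo_cohort():
    """Mid-sized multi-ancestry cohort reused across read-only tests."""
    cfg = SimulationConfig(
        n_samples={"EUR": 2500, "SAS": 600},
        genes=[
            GeneConfig("GENE_X", chrom="X", n_variants=10, carrier_freq=0.02,
                       zygosity="recessive", log_or={"diabetes": math.log(0.7)},
                       beta={"hba1c": -0.14}),
            GeneConfig("GENE_A", chrom="2", n_variants=6, carrier_freq=0.02,
                       zygosity="dominant", log_or={"diabetes": 0.6}),
            GeneConfig("GENE_NULL", chrom="3", n_variants=5, carrier_freq=0.015),
        ],
        haplotypes=[
            HaplotypeConfig("HAP17", frequency=0.3, log_or={"diabetes": math.log(1.37)},
                            interactions={"GENE_X": {"diabetes": 0.9}})
        ],
        binary_phenotypes=[BinaryPhenotypeConfig("diabetes", prevalence=0.2)],
        quantitative_phenotypes=[QuantitativePhenotypeConfig("hba1c")],
    )
    return generate_cohort(cfg, seed=7)


@pytest.fixture()
def toy_variants():
    """Hand-written annotation rows covering every consequence class."""
    rows = [
        dict(chrom="1", pos=100, ref="A", alt="G", gene="G1",
             consequence="stop_gained", maf_internal=0.0005, maf_external=0.0002,
             revel_score=np.nan, mtr_percentile=40.0),
        dict(chrom="1", pos=110, ref="A", alt="G", gene="G1",
             consequence="missense_variant", maf_internal=0.0005, maf_external=0.0,
             revel_score=0.8, mtr_percentile=20.0),
        dict(chrom="1", pos=120, ref="A", alt="G", gene="G1",
             consequence="synonymous_variant", maf_internal=0.0004, maf_external=0.0004,
             revel_score=np.nan, mtr_percentile=90.0),
        dict(chrom="1", pos=130, ref="A", alt="G", gene="G1",
             consequence="missense_variant", maf_internal=0.02, maf_external=0.03,
             revel_score=0.9, mtr_percentile=10.0),
    ]
    return pd.DataFrame(rows)
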