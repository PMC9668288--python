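"""Synthetic exome-cohort generator.

Produces cohorts with ancestry strata, rare autosomal and X-linked
variants at specified carrier frequencies, per-call sequencing metrics,
binary phenotypes drawn from a logistic model (intercept solved to hit a
configured prevalence) and quantitative traits with effects in SD units,
plus an optional common risk haplotype whose carriers modify gene effects
through a log-odds interaction term. Phased haplotypes are retained
internally so linkage-disequilibrium and compound-heterozygote truth are
known exactly. A truth table records every generative parameter.

Genotypes follow Hardy-Weinberg proportions within ancestry except on X
in males, where calls are hemizygous (dosage 0 or 2). Two-QV females are
arranged in trans by default; ``cis_fraction`` places a configurable
share of them in cis to probe phase-blind compound-het coding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

DEFAULT_CONSEQUENCE_WEIGHTS = {
    "missense_variant": 0.55,
    "stop_gained": 0.20,
    "frameshift_variant": 0.15,
    "splice_acceptor_variant": 0.05,
    "conservative_inframe_deletion": 0.05,
}

_INDEL_TERMS = {
    "frameshift_variant",
    "conservative_inframe_deletion",
    "conservative_inframe_insertion",
    "disruptive_inframe_deletion",
    "disruptive_inframe_insertion",
}


@dataclass
class GeneConfig:
    """One simulated gene: variant spectrum plus its phenotype effects."""

    name: str
    chrom: str = "1"
    n_variants: int = 8
    n_synonymous: int = 2
    carrier_freq: float | dict = 0.01  # target carrier frequency (per ancestry if a dict)
    zygosity: str = "dominant"
    log_or: dict = field(default_factory=dict)  # binary phenotype -> true log-OR
    beta: dict = field(default_factory=dict)  # quantitative trait -> true effect (SD units)
    cis_fraction: float = 0.0
    #: allele-frequency spectrum skew; per-variant weights ~ rank^-exponent
    spectrum_exponent: float = 0.75
    consequence_weights: dict = field(default_factory=lambda: dict(DEFAULT_CONSEQUENCE_WEIGHTS))

    def __post_init__(self):
        if self.zygosity not in ("dominant", "recessive"):
            raise ValueError(f"gene {self.name}: bad zygosity {self.zygosity!r}")
        if self.n_variants < 1:
            raise ValueError(f"gene {self.name}: need at least one variant")


@dataclass
class HaplotypeConfig:
    """A common tag variant standing in for a risk haplotype."""

    name: str
    chrom: str = "17"
    pos: int = 7_041_768
    frequency: float | dict = 0.3  # allele frequency (per ancestry if a dict)
    log_or: dict = field(default_factory=dict)
    beta: dict = field(default_factory=dict)
    # interaction on the log-odds/SD scale added for haplotype carriers,
    # keyed gene -> {phenotype -> delta}
    interactions: dict = field(default_factory=dict)


@dataclass
class BinaryPhenotypeConfig:
    name: str
    prevalence: float = 0.1
    sex_log_or: float = 0.0  # male vs female
    age_log_or: float = 0.0  # per SD of age


@dataclass
class QuantitativePhenotypeConfig:
    name: str
    sex_beta: float = 0.0
    age_beta: float = 0.0
    noise_sd: float = 1.0


@dataclass
class SimulationConfig:
    n_samples: dict = field(default_factory=lambda: {"EUR": 1000})
    female_fraction: float = 0.5
    age_range: tuple = (40, 70)
    n_pcs: int = 5
    genes: list = field(default_factory=list)
    haplotypes: list = field(default_factory=list)
    binary_phenotypes: list = field(default_factory=list)
    quantitative_phenotypes: list = field(default_factory=list)
    with_call_metrics: bool = True
    mean_depth: float = 40.0
    bad_call_fraction: float = 0.002
    missing_rate: float = 0.001
    external_absent_fraction: float = 0.2

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        conv = {
            "genes": GeneConfig,
            "haplotypes": HaplotypeConfig,
            "binary_phenotypes": BinaryPhenotypeConfig,
            "quantitative_phenotypes": QuantitativePhenotypeConfig,
        }
        for key, klass in conv.items():
            raw[key] = [klass(**item) if isinstance(item, dict) else item for item in raw.get(key, [])]
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)

    def validate(self) -> None:
        pheno_names = {p.name for p in self.binary_phenotypes} | {
            p.name for p in self.quantitative_phenotypes
        }
        gene_names = [g.name for g in self.genes]
        if len(set(gene_names)) != len(gene_names):
            raise ValueError("duplicate gene names")
        for g in self.genes:
            for key in list(g.log_or) + list(g.beta):
                if key not in pheno_names:
                    raise ValueError(f"gene {g.name}: effect on unknown phenotype {key!r}")
        for h in self.haplotypes:
            for key in list(h.log_or) + list(h.beta):
                if key not in pheno_names:
                    raise ValueError(f"haplotype {h.name}: effect on unknown phenotype {key!r}")
            for gene, per_pheno in h.interactions.items():
                if gene not in gene_names:
                    raise ValueError(f"haplotype {h.name}: interaction with unknown gene {gene!r}")
                for key in per_pheno:
                    if key not in pheno_names:
                        raise ValueError(
                            f"haplotype {h.name}: interaction on unknown phenotype {key!r}"
                        )


@dataclass
class GenotypeMatrix:
    """Dosages plus phased truth and per-call metrics.

    ``dosage`` is (n_samples x n_variants) with -1 for missing; X-male
    alternate calls are coded 2 (hemizygous). ``a1``/``a2`` are the
    phased per-haplotype alleles (males on X carry the same value twice).
    """

    dosage: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None
    ad_alt: np.ndarray | None = None


@dataclass
class SimulatedCohort:
    samples: pd.DataFrame
    variants: pd.DataFrame
    genotypes: GenotypeMatrix
    truth: pd.DataFrame
    truth_carriers: dict  # gene -> bool array (generative-truth carrier status)


# --------------------------------------------------------------------------
# carrier-frequency calibration


def _per_variant_freqs(scale: float, weights: np.ndarray) -> np.ndarray:
    # 1 - prod(1 - p_i) == scale exactly when p_i = 1 - (1-scale)^w_i
    return 1.0 - np.power(1.0 - scale, weights)


def _carrier_prob(scale: float, weights: np.ndarray, male_frac: float, on_x: bool, zygosity: str) -> float:
    p = _per_variant_freqs(scale, weights)
    q = 1.0 - np.prod(1.0 - p)  # P(a haplotype carries >= 1 QV)
    p0 = np.prod((1.0 - p) ** 2)  # P(zero copies across both haplotypes)
    p1 = float(np.sum(2 * p * (1 - p) * np.prod((1 - p) ** 2) / (1 - p) ** 2))
    ge1 = 1.0 - p0
    ge2 = 1.0 - p0 - p1
    if zygosity == "dominant":
        female = ge1
        male = q if on_x else ge1
    else:
        female = ge2
        male = q if on_x else ge2
    return male_frac * male + (1.0 - male_frac) * female


def _solve_scale(target: float, weights: np.ndarray, male_frac: float, on_x: bool, zygosity: str) -> float:
    if not 0.0 < target < 1.0:
        raise ValueError(f"carrier frequency {target} outside (0, 1)")
    f = lambda s: _carrier_prob(s, weights, male_frac, on_x, zygosity) - target
    return brentq(f, 1e-12, 1.0 - 1e-9, xtol=1e-14)


def _ancestry_value(value, ancestry: str) -> float:
    return float(value[ancestry]) if isinstance(value, dict) else float(value)


# --------------------------------------------------------------------------
# generation


def generate_cohort(config: SimulationConfig, seed: int) -> SimulatedCohort:
    """Simulate samples, variants, genotypes, phenotypes and a truth table.

    One global seed; per-component substreams are derived deterministically
    from it, so any component is reproducible in isolation.
    """
    config.validate()
    ss = np.random.SeedSequence(seed)
    rng_samples, rng_alleles, rng_annot, rng_metrics, rng_pheno = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    samples = _make_samples(config, rng_samples)
    n = len(samples)
    is_male = (samples["sex"] == "male").to_numpy()
    ancestries = samples["ancestry"].to_numpy()

    variant_rows: list[dict] = []
    a1_cols: list[np.ndarray] = []
    a2_cols: list[np.ndarray] = []
    truth_rows: list[dict] = []
    truth_carriers: dict[str, np.ndarray] = {}
    gene_qv_slices: dict[str, slice] = {}

    pos_base = 1_000_000
    for gi, gene in enumerate(config.genes):
        on_x = gene.chrom.upper() in ("X", "CHRX")
        weights = (np.arange(1, gene.n_variants + 1, dtype=float)) ** -gene.spectrum_exponent
        weights /= weights.sum()
        a1 = np.zeros((n, gene.n_variants), dtype=np.int8)
        a2 = np.zeros((n, gene.n_variants), dtype=np.int8)
        target_by_anc = {}
        for anc, count in config.n_samples.items():
            in_anc = ancestries == anc
            target = _ancestry_value(gene.carrier_freq, anc)
            target_by_anc[anc] = target
            if target * count < 1:
                warnings.warn(
                    f"gene {gene.name}, ancestry {anc}: expected carrier count "
                    f"{target * count:.2f} < 1",
                    stacklevel=2,
                )
            male_frac = float(is_male[in_anc].mean()) if in_anc.any() else 0.5
            scale = _solve_scale(target, weights, male_frac, on_x, gene.zygosity)
            p = _per_variant_freqs(scale, weights)
            m_anc = int(in_anc.sum())
            draw1 = (rng_alleles.random((m_anc, gene.n_variants)) < p).astype(np.int8)
            draw2 = (rng_alleles.random((m_anc, gene.n_variants)) < p).astype(np.int8)
            if on_x:
                male_rows = is_male[in_anc]
                draw2[male_rows] = draw1[male_rows]
            a1[in_anc] = draw1
            a2[in_anc] = draw2
        _arrange_phase(a1, a2, is_male if on_x else None, gene.cis_fraction, rng_alleles)

        start = len(variant_rows)
        for v in range(gene.n_variants):
            variant_rows.append(
                _variant_row(gene, v, pos_base, rng_annot, config, synonymous=False)
            )
        gene_qv_slices[gene.name] = slice(start, start + gene.n_variants)
        a1_cols.append(a1)
        a2_cols.append(a2)

        for v in range(gene.n_synonymous):
            p_syn = 10 ** rng_annot.uniform(-4.5, -3.0)
            col1 = (rng_alleles.random(n) < p_syn).astype(np.int8)
            col2 = (rng_alleles.random(n) < p_syn).astype(np.int8)
            if on_x:
                col2[is_male] = col1[is_male]
            a1_cols.append(col1[:, None])
            a2_cols.append(col2[:, None])
            variant_rows.append(
                _variant_row(gene, gene.n_variants + v, pos_base, rng_annot, config, synonymous=True)
            )
        pos_base += 100_000

        carrier = _truth_carrier(a1, a2, is_male if on_x else None, gene.zygosity)
        truth_carriers[gene.name] = carrier
        truth_rows.append(
            {
                "kind": "gene",
                "name": gene.name,
                "chrom": gene.chrom,
                "zygosity": gene.zygosity,
                "target_carrier_freq": json.dumps(target_by_anc),
                "realized_carrier_freq": float(carrier.mean()),
                "log_or": json.dumps(gene.log_or),
                "beta": json.dumps(gene.beta),
                "cis_fraction": gene.cis_fraction,
                "seed": seed,
            }
        )

    hap_carriers: dict[str, np.ndarray] = {}
    for hap in config.haplotypes:
        a1 = np.zeros(n, dtype=np.int8)
        a2 = np.zeros(n, dtype=np.int8)
        freq_by_anc = {}
        for anc in config.n_samples:
            in_anc = ancestries == anc
            p = _ancestry_value(hap.frequency, anc)
            freq_by_anc[anc] = p
            a1[in_anc] = rng_alleles.random(int(in_anc.sum())) < p
            a2[in_anc] = rng_alleles.random(int(in_anc.sum())) < p
        a1_cols.append(a1[:, None])
        a2_cols.append(a2[:, None])
        variant_rows.append(
            {
                "chrom": hap.chrom, "pos": hap.pos, "ref": "G", "alt": "T",
                "gene": hap.name, "consequence": "missense_variant",
                "is_snv": True, "maf_internal": np.nan, "maf_external": float(np.mean([*freq_by_anc.values()])),
                "revel_score": 0.1, "mtr_percentile": 80.0, "in_ccds": True,
                "fs": 3.0, "mq": 60.0, "qual": 900.0, "rprs": 0.3, "mqrs": 0.1,
                "filter_status": "PASS", "external_coverage_fraction": 0.98,
                "external_z": 1.0, "external_mq": 60.0, "external_pass_fraction": 0.98,
            }
        )
        carrier = (a1 + a2) >= 1
        hap_carriers[hap.name] = carrier
        truth_rows.append(
            {
                "kind": "haplotype",
                "name": hap.name,
                "chrom": hap.chrom,
                "zygosity": "dominant",
                "target_carrier_freq": json.dumps(freq_by_anc),
                "realized_carrier_freq": float(carrier.mean()),
                "log_or": json.dumps(hap.log_or),
                "beta": json.dumps(hap.beta),
                "interactions": json.dumps(hap.interactions),
                "seed": seed,
            }
        )

    variants = pd.DataFrame(variant_rows)
    a1 = np.hstack(a1_cols) if a1_cols else np.zeros((n, 0), dtype=np.int8)
    a2 = np.hstack(a2_cols) if a2_cols else np.zeros((n, 0), dtype=np.int8)
    dosage = (a1 + a2).astype(np.int8)

    # internal MAF from realized allele counts (folded)
    if len(variants):
        on_x_col = variants["chrom"].astype(str).str.upper().isin(["X", "CHRX"]).to_numpy()
        n_alleles = np.where(on_x_col, (~is_male).sum() * 2 + is_male.sum(), 2 * n)
        alt_counts = a1.sum(axis=0) + a2.sum(axis=0)
        if is_male.any():
            # X males carry one copy: remove the duplicated allele
            alt_counts = alt_counts - np.where(on_x_col, a1[is_male].sum(axis=0), 0)
        af = alt_counts / n_alleles
        variants["maf_internal"] = np.minimum(af, 1 - af)

    phenos, intercepts = _make_phenotypes(
        config, samples, is_male, truth_carriers, hap_carriers, rng_pheno
    )
    for name, values in phenos.items():
        samples[name] = values
    for name, value in intercepts.items():
        truth_rows.append(
            {"kind": "phenotype", "name": name, "target_carrier_freq": "",
             "realized_carrier_freq": np.nan, "log_or": json.dumps({"intercept": value}),
             "beta": "", "seed": seed}
        )

    dp = gq = ad = None
    if config.with_call_metrics:
        dp, gq, ad = _make_call_metrics(dosage, is_male, variants, config, rng_metrics)
    if config.missing_rate > 0 and dosage.size:
        missing = rng_metrics.random(dosage.shape) < config.missing_rate
        dosage = dosage.copy()
        dosage[missing] = -1

    truth = pd.DataFrame(truth_rows)
    genotypes = GenotypeMatrix(dosage=dosage, a1=a1, a2=a2, dp=dp, gq=gq, ad_alt=ad)
    return SimulatedCohort(samples, variants, genotypes, truth, truth_carriers)


def _make_samples(config: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    counter = 0
    for anc, count in config.n_samples.items():
        female = rng.random(count) < config.female_fraction
        ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=count)
        for k in range(count):
            counter += 1
            rows.append(
                {
                    "sample_id": f"S{counter:07d}",
                    "sex": "female" if female[k] else "male",
                    "age": int(ages[k]),
                    "ancestry": anc,
                }
            )
    samples = pd.DataFrame(rows)
    n = len(samples)
    anc_index = {anc: i for i, anc in enumerate(config.n_samples)}
    offsets = samples["ancestry"].map(anc_index).to_numpy()
    for j in range(1, config.n_pcs + 1):
        pc = rng.normal(size=n)
        if j <= 2:  # first PCs separate ancestries
            pc = pc + offsets * (3.0 if j == 1 else -2.0)
        samples[f"pc{j}"] = pc
    samples["bmi"] = rng.normal(27.0, 4.0, size=n).clip(15, 60)
    samples["antihypertensive"] = (rng.random(n) < 0.2).astype(int)
    return samples


def _variant_row(gene: GeneConfig, v: int, pos_base: int, rng, config, *, synonymous: bool) -> dict:
    if synonymous:
        consequence = "synonymous_variant"
    else:
        terms = list(gene.consequence_weights)
        w = np.array([gene.consequence_weights[t] for t in terms], dtype=float)
        consequence = rng.choice(terms, p=w / w.sum())
    is_snv = consequence not in _INDEL_TERMS
    maf_external = 0.0
    if rng.random() >= config.external_absent_fraction:
        maf_external = float(10 ** rng.uniform(-5, -3.2))
    return {
        "chrom": gene.chrom,
        "pos": pos_base + 10 * v + 1,
        "ref": "A" if is_snv else "AT",
        "alt": "G" if is_snv else "A",
        "gene": gene.name,
        "consequence": consequence,
        "is_snv": is_snv,
        "maf_internal": np.nan,  # filled from realized counts
        "maf_external": maf_external,
        "revel_score": float(rng.beta(2, 2)) if consequence in ("missense_variant",) else np.nan,
        "mtr_percentile": float(rng.uniform(0, 100)),
        "in_ccds": True,
        "fs": float(abs(rng.normal(5, 3))),
        "mq": float(rng.normal(60, 1)),
        "qual": float(rng.uniform(300, 3000)),
        "rprs": float(rng.normal(0.2, 0.5)),
        "mqrs": float(rng.normal(0.0, 0.5)),
        "filter_status": "PASS",
        "external_coverage_fraction": float(rng.uniform(0.85, 1.0)),
        "external_z": float(rng.normal(1.0, 0.5)),
        "external_mq": float(rng.normal(60, 2)),
        "external_pass_fraction": float(rng.uniform(0.9, 1.0)),
    }


def _arrange_phase(a1: np.ndarray, a2: np.ndarray, is_male_x, cis_fraction: float, rng) -> None:
    """Force two-QV samples into trans (default) or cis configurations.

    Operates in place on the phased allele matrices; genotype dosages are
    untouched. Hemizygous X males are skipped.
    """
    copies = a1.astype(int) + a2.astype(int)
    hom = (a1 == 1) & (a2 == 1)
    multi = (copies.sum(axis=1) >= 2) & ~hom.any(axis=1)
    if is_male_x is not None:
        multi &= ~np.asarray(is_male_x, dtype=bool)
    for i in np.nonzero(multi)[0]:
        var_idx = np.nonzero(copies[i] > 0)[0]
        if var_idx.size < 2:
            continue
        a1[i, :] = 0
        a2[i, :] = 0
        if rng.random() < cis_fraction:
            a1[i, var_idx] = 1
        else:
            half = var_idx.size // 2
            a1[i, var_idx[:max(half, 1)]] = 1
            a2[i, var_idx[max(half, 1):]] = 1


def _truth_carrier(a1: np.ndarray, a2: np.ndarray, is_male_x, zygosity: str) -> np.ndarray:
    any1 = (a1 == 1).any(axis=1)
    any2 = (a2 == 1).any(axis=1)
    if zygosity == "dominant":
        return any1 | any2
    carrier = any1 & any2  # trans: a qualifying allele on each haplotype
    if is_male_x is not None:
        male = np.asarray(is_male_x, dtype=bool)
        carrier = np.where(male, any1, carrier)
    return carrier


def _make_phenotypes(config, samples, is_male, truth_carriers, hap_carriers, rng):
    n = len(samples)
    age = samples["age"].to_numpy(dtype=float)
    age_z = (age - age.mean()) / (age.std() if age.std() > 0 else 1.0)
    male = is_male.astype(float)
    phenos: dict[str, np.ndarray] = {}
    intercepts: dict[str, float] = {}

    def effect_sum(getter, pheno_name):
        eta = np.zeros(n)
        for gene in config.genes:
            val = getter(gene).get(pheno_name, 0.0)
            if val:
                eta += val * truth_carriers[gene.name]
        for hap in config.haplotypes:
            val = getter(hap).get(pheno_name, 0.0)
            if val:
                eta += val * hap_carriers[hap.name]
            if isinstance(hap, HaplotypeConfig):
                for gene_name, per_pheno in hap.interactions.items():
                    delta = per_pheno.get(pheno_name, 0.0)
                    if delta:
                        eta += delta * (hap_carriers[hap.name] & truth_carriers[gene_name])
        return eta

    for spec in config.binary_phenotypes:
        eta = spec.sex_log_or * male + spec.age_log_or * age_z
        eta = eta + effect_sum(lambda obj: obj.log_or, spec.name)
        lo, hi = -30.0, 30.0
        c = brentq(lambda c0: expit(c0 + eta).mean() - spec.prevalence, lo, hi, xtol=1e-12)
        phenos[spec.name] = (rng.random(n) < expit(c + eta)).astype(int)
        intercepts[spec.name] = float(c)

    for spec in config.quantitative_phenotypes:
        mu = spec.sex_beta * male + spec.age_beta * age_z
        mu = mu + effect_sum(lambda obj: obj.beta, spec.name)
        phenos[spec.name] = mu + rng.normal(scale=spec.noise_sd, size=n)

    return phenos, intercepts


def _make_call_metrics(dosage, is_male, variants, config, rng):
    n, m = dosage.shape
    dp = np.maximum(rng.poisson(config.mean_depth, size=(n, m)), 1).astype(np.int16)
    gq = np.full((n, m), 99, dtype=np.int16)
    het = dosage == 1
    homalt = dosage == 2
    ad = np.zeros((n, m), dtype=np.int16)
    ad[het] = rng.binomial(dp[het], 0.5)
    ad[homalt] = rng.binomial(dp[homalt], 0.97)
    ref = ~het & ~homalt
    ad[ref] = rng.binomial(dp[ref], 0.005)
    if config.bad_call_fraction > 0:
        bad = rng.random((n, m)) < config.bad_call_fraction
        which = rng.integers(0, 3, size=(n, m))
        dp[bad & (which == 0)] = rng.integers(1, 10, size=int((bad & (which == 0)).sum()))
        gq[bad & (which == 1)] = rng.integers(0, 20, size=int((bad & (which == 1)).sum()))
        skew = bad & (which == 2) & het
        ad[skew] = rng.binomial(dp[skew], 0.05)
    return dp, gq, ad


__all__ = [
    "BinaryPhenotypeConfig",
    "GeneConfig",
    "GenotypeMatrix",
    "HaplotypeConfig",
    "QuantitativePhenotypeConfig",
    "SimulatedCohort",
    "SimulationConfig",
    "generate_cohort",
]
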