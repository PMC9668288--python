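"""Variant-level exome-wide association tests.

Binary traits: allelic (alt vs ref allele), dominant and recessive 2x2
tables tested with the exact two-sided test. Quantitative traits: linear
regression with the allelic model replaced by a genotypic (dosage) test.
Only variants carried by at least six individuals are tested. Hemizygous
X-male genotypes (dosage 2) contribute one allele under the allelic model
and count as homozygous alternate under the recessive model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .collapsing import linear_model
from .exact import fisher_exact_2x2, odds_ratio_woolf

MIN_CARRIERS = 6

BINARY_MODELS = ("allelic", "dominant", "recessive")
QUANT_MODELS = ("genotypic", "dominant", "recessive")


@dataclass
class VariantTestResult:
    variant: str
    genetic_model: str
    phenotype: str = ""
    n_carriers: int = 0
    table: tuple[int, int, int, int] | None = None  # (a, b, c, d): case vs control
    estimate: float = float("nan")  # OR or beta
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p: float = float("nan")
    skipped: str | None = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["table"] = ",".join(map(str, self.table)) if self.table else ""
        return d


def _carrier_count(dosage: np.ndarray) -> int:
    return int((dosage > 0).sum())


def _skip(variant, model, phenotype, dosage, reason) -> VariantTestResult:
    return VariantTestResult(
        variant=variant, genetic_model=model, phenotype=phenotype,
        n_carriers=_carrier_count(dosage), skipped=reason,
    )


def allele_counts(dosage: np.ndarray, hemizygous: np.ndarray | None = None) -> tuple[int, int]:
    """(alt, ref) allele tallies; hemizygous samples carry one allele."""
    called = dosage >= 0
    hemi = np.zeros(dosage.shape, dtype=bool) if hemizygous is None else np.asarray(hemizygous, bool)
    alt = dosage.copy().astype(int)
    alt[hemi & (dosage == 2)] = 1
    total = np.where(hemi, 1, 2)
    return int(alt[called].sum()), int((total - alt)[called].sum())


def variant_binary_tests(
    dosage: np.ndarray,
    is_case: np.ndarray,
    *,
    variant: str = "",
    phenotype: str = "",
    hemizygous: np.ndarray | None = None,
) -> list[VariantTestResult]:
    """Allelic / dominant / recessive exact tests for one variant."""
    dosage = np.asarray(dosage)
    is_case = np.asarray(is_case, dtype=bool)
    called = dosage >= 0
    results = []
    n_carriers = _carrier_count(dosage)
    monomorphic = np.unique(dosage[called]).size < 2
    for model in BINARY_MODELS:
        if n_carriers < MIN_CARRIERS:
            results.append(_skip(variant, model, phenotype, dosage, "fewer_than_6_carriers"))
            continue
        if monomorphic:
            results.append(_skip(variant, model, phenotype, dosage, "monomorphic"))
            continue
        if model == "allelic":
            a, b = allele_counts(dosage[is_case & called],
                                 None if hemizygous is None else hemizygous[is_case & called])
            c, d = allele_counts(dosage[~is_case & called],
                                 None if hemizygous is None else hemizygous[~is_case & called])
        else:
            ind = (dosage >= 1) if model == "dominant" else (dosage == 2)
            a = int((ind & is_case & called).sum())
            b = int((~ind & is_case & called).sum())
            c = int((ind & ~is_case & called).sum())
            d = int((~ind & ~is_case & called).sum())
        if (a + c == 0) or (b + d == 0):
            # the genetic-model indicator collapses to one column
            # (e.g. recessive with no homozygotes): null test, OR undefined
            results.append(
                VariantTestResult(
                    variant=variant, genetic_model=model, phenotype=phenotype,
                    n_carriers=n_carriers, table=(a, b, c, d), p=1.0,
                )
            )
            continue
        orr = odds_ratio_woolf(a, b, c, d)
        results.append(
            VariantTestResult(
                variant=variant, genetic_model=model, phenotype=phenotype,
                n_carriers=n_carriers, table=(a, b, c, d),
                estimate=orr.estimate, ci_low=orr.ci_low, ci_high=orr.ci_high,
                p=fisher_exact_2x2(a, b, c, d),
            )
        )
    return results


def variant_quantitative_tests(
    dosage: np.ndarray,
    phenotype_values: np.ndarray,
    covariates: pd.DataFrame | None = None,
    *,
    variant: str = "",
    phenotype: str = "",
) -> list[VariantTestResult]:
    """Genotypic / dominant / recessive linear-model tests for one variant.

    The genotypic model regresses the phenotype on dosage {0, 1, 2};
    dominant and recessive regress on the respective indicator. Beta is
    in SD units when the phenotype is inverse-normal transformed.
    """
    dosage = np.asarray(dosage)
    y = np.asarray(phenotype_values, dtype=float)
    called = dosage >= 0
    ok = called & ~np.isnan(y)
    cov = covariates if covariates is not None else pd.DataFrame(index=range(y.size))
    if len(cov.columns):
        ok &= ~cov.isna().any(axis=1).to_numpy()
    results = []
    n_carriers = _carrier_count(dosage)
    for model in QUANT_MODELS:
        if n_carriers < MIN_CARRIERS:
            results.append(_skip(variant, model, phenotype, dosage, "fewer_than_6_carriers"))
            continue
        if model == "genotypic":
            x = dosage[ok].astype(float)
        elif model == "dominant":
            x = (dosage[ok] >= 1).astype(float)
        else:
            x = (dosage[ok] == 2).astype(float)
        if x.min() == x.max():
            results.append(_skip(variant, model, phenotype, dosage, "monomorphic"))
            continue
        names = ["intercept", "dosage"] + list(cov.columns)
        X = np.column_stack(
            [np.ones(int(ok.sum())), x] + [cov[c].to_numpy(dtype=float)[ok] for c in cov.columns]
        )
        fit = linear_model(y[ok], X, names).set_index("term").loc["dosage"]
        results.append(
            VariantTestResult(
                variant=variant, genetic_model=model, phenotype=phenotype,
                n_carriers=n_carriers,
                estimate=float(fit["estimate"]), ci_low=float(fit["ci_low"]),
                ci_high=float(fit["ci_high"]), p=float(fit["p"]),
            )
        )
    return results


def run_exwas(
    samples: pd.DataFrame,
    variants: pd.DataFrame,
    dosage: np.ndarray,
    phenotypes,
    *,
    transform_quantitative: bool = True,
) -> pd.DataFrame:
    """All variants x genetic models x phenotypes; one row each."""
    from .collapsing import int_transform

    is_male = samples["sex"].to_numpy() == "male"
    on_x = variants["chrom"].astype(str).str.upper().isin(["X", "CHRX"]).to_numpy()
    rows = []
    for j in range(len(variants)):
        key = f"{variants.iloc[j]['chrom']}-{variants.iloc[j]['pos']}-{variants.iloc[j]['ref']}-{variants.iloc[j]['alt']}"
        hemi = is_male & on_x[j]
        for pheno in phenotypes:
            values = samples[pheno.name].to_numpy()
            if pheno.kind == "binary":
                mask = ~pd.isna(values)
                res = variant_binary_tests(
                    dosage[mask, j], values[mask].astype(float) > 0,
                    variant=key, phenotype=pheno.name, hemizygous=hemi[mask],
                )
            else:
                y = values.astype(float)
                if transform_quantitative:
                    y = int_transform(y)
                cov_cols = [c for c in pheno.covariate_columns() if c != "sex"]
                covs = samples[cov_cols].astype(float).copy() if cov_cols else pd.DataFrame(index=samples.index)
                if "sex" in pheno.covariate_columns():
                    covs["sex"] = is_male.astype(float)
                res = variant_quantitative_tests(
                    dosage[:, j], y, covs, variant=key, phenotype=pheno.name
                )
            rows.extend(r.to_dict() for r in res)
    return pd.DataFrame(rows)


__all__ = [
    "BINARY_MODELS",
    "MIN_CARRIERS",
    "QUANT_MODELS",
    "VariantTestResult",
    "allele_counts",
    "run_exwas",
    "variant_binary_tests",
    "variant_quantitative_tests",
]
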