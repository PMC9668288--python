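"""Gene-level collapsing burden tests.

Qualifying variants are aggregated to a per-sample carrier indicator per
gene x model. Binary traits use Fisher's exact two-sided test on the
carrier-by-case 2x2 table; quantitative traits use a covariate-adjusted
ordinary-least-squares model on the (inverse-normal-transformed)
phenotype. Recessive carriers are homozygotes, hemizygous X males, and
phase-blind putative compound heterozygotes (>= 2 distinct heterozygous
QVs in the gene).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import qvmodels
from .exact import fisher_exact_2x2, odds_ratio_woolf, wald_ci

logger = logging.getLogger(__name__)

SIGNIFICANCE_THRESHOLD = 1e-8  # study-wide flag; no FDR machinery


# --------------------------------------------------------------------------
# result containers


@dataclass
class BurdenResult:
    """Per gene x model x phenotype association output."""

    gene: str
    model: str
    phenotype: str
    kind: str  # "binary" | "quantitative"
    n_case_carrier: int = 0
    n_case_noncarrier: int = 0
    n_ctrl_carrier: int = 0
    n_ctrl_noncarrier: int = 0
    n_carrier: int = 0
    n_noncarrier: int = 0
    estimate: float = float("nan")  # OR (binary) or beta in SD units
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p: float = float("nan")
    f_case: float = float("nan")
    f_ctrl: float = float("nan")
    flags: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p == self.p and self.p < SIGNIFICANCE_THRESHOLD

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["flags"] = ";".join(self.flags)
        d["significant"] = self.significant
        return d


@dataclass(frozen=True)
class PhenotypeSpec:
    """How a phenotype column is analysed."""

    name: str
    kind: str  # "binary" | "quantitative"
    covariates: tuple[str, ...] = ("age", "sex")
    sex_match: bool = True  # binary traits: sex-match controls when needed
    medication_indicator: str | None = None  # extra covariate column

    def __post_init__(self):
        if self.kind not in ("binary", "quantitative"):
            raise ValueError(f"phenotype {self.name}: bad kind {self.kind!r}")

    def covariate_columns(self) -> tuple[str, ...]:
        cols = self.covariates
        if self.medication_indicator:
            cols = cols + (self.medication_indicator,)
        return cols


# --------------------------------------------------------------------------
# carrier matrices


@dataclass
class CarrierMatrix:
    """Carrier indicators for one gene under one model."""

    gene: str
    model: str
    zygosity: str
    carrier: np.ndarray  # bool, per sample
    basis: np.ndarray | None = None  # recessive only: "", "homozygous", "hemizygous", "compound_het"


def compute_qv_sets(
    variants: pd.DataFrame, registry: dict[str, qvmodels.QVModelSpec]
) -> dict[tuple[str, str], np.ndarray]:
    """Variant indices qualifying per (gene, model)."""
    out: dict[tuple[str, str], np.ndarray] = {}
    genes = variants["gene"].to_numpy()
    for model_name, spec in registry.items():
        flags = np.array(
            [qvmodels.qualifies(variants.iloc[j], spec)[0] for j in range(len(variants))]
        )
        for gene in pd.unique(genes):
            idx = np.nonzero(flags & (genes == gene))[0]
            if idx.size:
                out[(gene, model_name)] = idx
    return out


def build_carrier_matrix(
    dosage: np.ndarray,
    qv_idx: np.ndarray,
    zygosity: str,
    *,
    gene: str = "",
    model: str = "",
    is_male: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> CarrierMatrix:
    """Aggregate QV dosages to a per-sample carrier indicator.

    ``dosage`` is the full (n x m) matrix with -1 for missing; missing
    calls contribute nothing. Hemizygous X-male genotypes are coded as
    dosage 2, so they are recessive carriers by the homozygote rule; the
    ``basis`` array distinguishes them when ``is_male`` is given.
    Heterozygous QVs at the same position are counted once for the
    putative compound-het rule (phase-blind, trans assumed).
    """
    n = dosage.shape[0]
    qv_idx = np.asarray(qv_idx, dtype=int)
    if qv_idx.size == 0:
        return CarrierMatrix(gene, model, zygosity, np.zeros(n, dtype=bool))
    sub = dosage[:, qv_idx]
    called = sub > 0
    if zygosity == "dominant":
        return CarrierMatrix(gene, model, zygosity, called.any(axis=1))
    if zygosity != "recessive":
        raise ValueError(f"unknown zygosity {zygosity!r}")

    two_copy = (sub == 2).any(axis=1)
    het = sub == 1
    if positions is not None:
        pos = np.asarray(positions)[qv_idx]
        uniq = pd.unique(pos)
        if uniq.size != pos.size:
            het_by_pos = np.zeros((n, uniq.size), dtype=bool)
            for k, p in enumerate(uniq):
                het_by_pos[:, k] = het[:, pos == p].any(axis=1)
            het = het_by_pos
    distinct_het = het.sum(axis=1)
    compound = distinct_het >= 2
    carrier = two_copy | compound

    basis = np.full(n, "", dtype=object)
    basis[compound] = "compound_het"
    basis[two_copy] = "homozygous"
    if is_male is not None:
        basis[two_copy & np.asarray(is_male, dtype=bool)] = "hemizygous"
    return CarrierMatrix(gene, model, zygosity, carrier, basis)


# --------------------------------------------------------------------------
# control sex-matching


def sex_match_controls(
    case_is_female: np.ndarray,
    control_is_female: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Down-sample controls of the over-represented sex.

    If the case/control female-fraction difference is not significant
    (Fisher two-sided p >= 0.05) the controls are returned unchanged
    (a full True mask). Otherwise the majority sex among controls is
    randomly down-sampled (seeded) so the control female fraction matches
    the case fraction to within one sample.
    """
    case_is_female = np.asarray(case_is_female, dtype=bool)
    control_is_female = np.asarray(control_is_female, dtype=bool)
    keep = np.ones(control_is_female.size, dtype=bool)
    cf, cm = int(case_is_female.sum()), int((~case_is_female).sum())
    kf, km = int(control_is_female.sum()), int((~control_is_female).sum())
    if cf == 0 and cm == 0:
        return keep
    if (cf == 0 or cm == 0) and (kf == 0 or km == 0):
        warnings.warn("single-sex input; sex matching skipped", stacklevel=2)
        return keep
    if fisher_exact_2x2(cf, cm, kf, km) >= 0.05:
        return keep

    frac = cf / (cf + cm)
    rng = np.random.default_rng(seed)
    if kf / (kf + km) > frac:
        # too many female controls: keep all males, trim females
        target_f = int(round(frac / (1 - frac) * km)) if frac < 1 else kf
        drop_n = max(kf - target_f, 0)
        female_idx = np.nonzero(control_is_female)[0]
        keep[rng.choice(female_idx, size=drop_n, replace=False)] = False
    else:
        target_m = int(round((1 - frac) / frac * kf)) if frac > 0 else km
        drop_n = max(km - target_m, 0)
        male_idx = np.nonzero(~control_is_female)[0]
        keep[rng.choice(male_idx, size=drop_n, replace=False)] = False
    return keep


# --------------------------------------------------------------------------
# association tests


def fisher_burden(
    carrier: np.ndarray,
    is_case: np.ndarray,
    *,
    gene: str = "",
    model: str = "",
    phenotype: str = "",
) -> BurdenResult:
    """Fisher's exact two-sided test of carrier proportion, cases vs controls."""
    carrier = np.asarray(carrier, dtype=bool)
    is_case = np.asarray(is_case, dtype=bool)
    a = int((carrier & is_case).sum())  # case carriers
    b = int((~carrier & is_case).sum())
    c = int((carrier & ~is_case).sum())
    d = int((~carrier & ~is_case).sum())
    if a + b == 0 or c + d == 0:
        raise ValueError("need at least one case and one control")
    res = BurdenResult(
        gene=gene, model=model, phenotype=phenotype, kind="binary",
        n_case_carrier=a, n_case_noncarrier=b,
        n_ctrl_carrier=c, n_ctrl_noncarrier=d,
        n_carrier=a + c, n_noncarrier=b + d,
        f_case=a / (a + b), f_ctrl=c / (c + d),
    )
    if a + c == 0:
        res.p = 1.0
        res.flags = ("no_carriers", "or_undefined")
        return res
    res.p = fisher_exact_2x2(a, b, c, d)
    orr = odds_ratio_woolf(a, b, c, d)
    res.estimate, res.ci_low, res.ci_high = orr.estimate, orr.ci_low, orr.ci_high
    if orr.corrected:
        res.flags = ("haldane_corrected",)
    if not orr.defined:
        res.flags = res.flags + ("or_undefined",)
    return res


def int_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets.

    Scores are normal quantiles of ``(r - 3/8) / (n + 1/4)`` where ``r``
    is the (tie-averaged) rank among non-missing values; missing values
    stay missing and order is preserved.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need >= 2 non-missing values")
    if np.nanmax(x) == np.nanmin(x):
        raise ValueError("constant input: inverse-normal transform undefined")
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal offending subset by greedy elimination
        keep: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
                keep.append(j)
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        raise ValueError(f"collinear design columns: {dropped}")


def linear_model(y: np.ndarray, X: np.ndarray, names: list[str]) -> pd.DataFrame:
    """OLS fit; returns per-column estimate, SE, CI, p (normal theory)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough observations for the design")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    tcrit = stats.t.ppf(0.975, dof)
    return pd.DataFrame(
        {
            "term": names,
            "estimate": beta,
            "se": se,
            "ci_low": beta - tcrit * se,
            "ci_high": beta + tcrit * se,
            "p": p,
        }
    )


def quantitative_burden(
    carrier: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    *,
    gene: str = "",
    model: str = "",
    phenotype_name: str = "",
) -> BurdenResult:
    """Carrier-vs-noncarrier mean difference by covariate-adjusted OLS.

    The phenotype is expected to be inverse-normal transformed already, so
    the carrier coefficient is in SD units. Rows with a missing phenotype
    or covariate are dropped (complete-case).
    """
    carrier = np.asarray(carrier, dtype=bool)
    y = np.asarray(phenotype, dtype=float)
    cov = covariates if covariates is not None else pd.DataFrame(index=range(y.size))
    ok = ~np.isnan(y)
    if len(cov.columns):
        ok &= ~cov.isna().any(axis=1).to_numpy()
    res = BurdenResult(
        gene=gene, model=model, phenotype=phenotype_name, kind="quantitative",
        n_carrier=int(carrier[ok].sum()), n_noncarrier=int((~carrier[ok]).sum()),
    )
    if res.n_carrier == 0:
        res.flags = ("no_carriers",)
        return res
    names = ["intercept", "carrier"] + list(cov.columns)
    X = np.column_stack(
        [np.ones(int(ok.sum())), carrier[ok].astype(float)]
        + [cov[c].to_numpy(dtype=float)[ok] for c in cov.columns]
    )
    fit = linear_model(y[ok], X, names)
    row = fit.set_index("term").loc["carrier"]
    res.estimate, res.ci_low, res.ci_high, res.p = (
        float(row["estimate"]), float(row["ci_low"]), float(row["ci_high"]), float(row["p"])
    )
    return res


# --------------------------------------------------------------------------
# top-level driver


def run_collapsing(
    samples: pd.DataFrame,
    variants: pd.DataFrame,
    dosage: np.ndarray,
    phenotypes: list[PhenotypeSpec],
    registry: dict[str, qvmodels.QVModelSpec] | None = None,
    *,
    seed: int = 0,
    transform_quantitative: bool = True,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """One burden test per gene x model x phenotype, plus per-model lambda.

    ``samples`` must carry ``sex`` plus every phenotype and covariate
    column; ``variants`` must carry ``gene``, ``chrom``, ``pos`` and the
    annotation columns used by the QV models. Missing genotypes count as
    noncarrier contributions (logged), samples are never dropped for
    missingness.
    """
    from .meta import genomic_lambda  # local import to avoid a cycle

    registry = registry if registry is not None else qvmodels.load_model_registry()
    is_male = (samples["sex"].to_numpy() == "male")
    positions = variants["pos"].to_numpy()
    on_x = variants["chrom"].astype(str).str.upper().isin(["X", "CHRX"]).to_numpy()

    qv_sets = compute_qv_sets(variants, registry)
    rows: list[dict] = []
    pvals_by_model: dict[str, list[float]] = {name: [] for name in registry}

    for (gene, model_name), qv_idx in sorted(qv_sets.items()):
        spec = registry[model_name]
        cm = build_carrier_matrix(
            dosage, qv_idx, spec.zygosity, gene=gene, model=model_name,
            is_male=is_male, positions=positions,
        )
        for pheno in phenotypes:
            values = samples[pheno.name].to_numpy()
            cov_cols = [c for c in pheno.covariate_columns() if c != "sex"]
            covs = samples[cov_cols].astype(float).copy() if cov_cols else pd.DataFrame(index=samples.index)
            if "sex" in pheno.covariate_columns():
                covs["sex"] = is_male.astype(float)
            if pheno.kind == "binary":
                mask = ~pd.isna(values)
                is_case = np.zeros(len(samples), dtype=bool)
                is_case[mask] = values[mask].astype(float) > 0
                analyzed = mask.copy()
                if pheno.sex_match:
                    ctrl_idx = np.nonzero(mask & ~is_case)[0]
                    keep = sex_match_controls(
                        ~is_male[mask & is_case], ~is_male[ctrl_idx], seed=seed
                    )
                    analyzed[ctrl_idx[~keep]] = False
                result = fisher_burden(
                    cm.carrier[analyzed], is_case[analyzed],
                    gene=gene, model=model_name, phenotype=pheno.name,
                )
            else:
                y = values.astype(float)
                if transform_quantitative:
                    y = int_transform(y)
                result = quantitative_burden(
                    cm.carrier, y, covs,
                    gene=gene, model=model_name, phenotype_name=pheno.name,
                )
            if model_name == qvmodels.SYNONYMOUS_MODEL:
                result.flags = result.flags + ("negative_control",)
            rows.append(result.to_dict())
            if result.p == result.p:
                pvals_by_model[model_name].append(result.p)

    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["gene", "model", "phenotype"], kind="mergesort").reset_index(drop=True)
    lambdas = {
        name: genomic_lambda(np.array(ps), warn_below=0)
        for name, ps in pvals_by_model.items()
        if ps
    }
    return table, lambdas


__all__ = [
    "BurdenResult",
    "CarrierMatrix",
    "PhenotypeSpec",
    "SIGNIFICANCE_THRESHOLD",
    "build_carrier_matrix",
    "compute_qv_sets",
    "fisher_burden",
    "int_transform",
    "linear_model",
    "quantitative_burden",
    "run_collapsing",
    "sex_match_controls",
]
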