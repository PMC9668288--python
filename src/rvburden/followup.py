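"""Secondary analyses: joint conditional regressions, leave-variants-out
collapsing, risk-modifier stratification with heterogeneity, and pairwise
linkage-disequilibrium statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .collapsing import BurdenResult, build_carrier_matrix, fisher_burden, linear_model, quantitative_burden
from .meta import heterogeneity_test


# --------------------------------------------------------------------------
# joint / conditional regression


@dataclass(frozen=True)
class JointModelSpec:
    outcome: str
    indicators: tuple[str, ...]
    covariates: tuple[str, ...] = ("age", "sex")
    family: str = "logistic"  # or "linear"

    def __post_init__(self):
        if self.family not in ("logistic", "linear"):
            raise ValueError(f"unknown model family {self.family!r}")
        if len(set(self.indicators)) != len(self.indicators):
            raise ValueError("indicator names must be distinct")


def _design(data: pd.DataFrame, columns: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(data))]
    for c in columns:
        if c == "sex" and data[c].dtype == object:
            cols.append((data[c].to_numpy() == "male").astype(float))
        else:
            cols.append(data[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def conditional_joint_regression(spec: JointModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Fit all carrier indicators simultaneously; one row per indicator.

    Logistic (binary outcome) or linear (quantitative outcome) maximum
    likelihood. Perfect separation is flagged per indicator (estimate
    direction recorded, no silent divergence); identical/collinear
    indicator columns raise ``ValueError``.
    """
    for ind in spec.indicators:
        if data[ind].sum() < 1:
            raise ValueError(f"indicator {ind!r} has no carriers")
    names = ["intercept"] + list(spec.indicators) + list(spec.covariates)
    X = _design(data, spec.indicators + spec.covariates)
    # distinct-column check before fitting so collinear indicators fail loudly
    if np.linalg.matrix_rank(X) < X.shape[1]:
        from .collapsing import _check_design

        _check_design(X, names)
    y = data[spec.outcome].to_numpy(dtype=float)

    if spec.family == "linear":
        fit = linear_model(y, X, names)
        out = fit[fit["term"].isin(spec.indicators)].reset_index(drop=True)
        out["flag"] = ""
        return out

    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning):
            return _separation_fallback(spec, data, names)
    conf = res.conf_int()
    rows = []
    for i, name in enumerate(names):
        if name not in spec.indicators:
            continue
        flag = ""
        if abs(res.params[i]) > 15 or not np.isfinite(res.bse[i]):
            flag = "separation_" + ("positive" if res.params[i] > 0 else "negative")
        rows.append(
            {
                "term": name,
                "estimate": float(res.params[i]),
                "se": float(res.bse[i]),
                "ci_low": float(conf[i][0]),
                "ci_high": float(conf[i][1]),
                "p": float(res.pvalues[i]),
                "or": float(np.exp(res.params[i])),
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def _separation_fallback(spec, data, names) -> pd.DataFrame:
    """Flag separated indicators with their direction instead of diverging."""
    y = data[spec.outcome].to_numpy(dtype=float) > 0
    rows = []
    for ind in spec.indicators:
        x = data[ind].to_numpy(dtype=float) > 0
        a, b = int((x & y).sum()), int((x & ~y).sum())
        direction = "positive" if b == 0 else "negative"
        rows.append(
            {
                "term": ind, "estimate": math.inf if direction == "positive" else -math.inf,
                "se": math.nan, "ci_low": math.nan, "ci_high": math.nan,
                "p": math.nan, "or": math.nan, "flag": f"separation_{direction}",
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# leave-variants-out collapsing


def leave_out_collapsing(
    dosage: np.ndarray,
    qv_idx: np.ndarray,
    excluded_idx,
    zygosity: str,
    outcome: np.ndarray,
    *,
    kind: str = "binary",
    covariates: pd.DataFrame | None = None,
    is_male: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    gene: str = "",
    model: str = "",
    phenotype: str = "",
) -> BurdenResult:
    """Re-run the gene burden on the QV set minus ``excluded_idx``.

    Raises if an excluded variant is not in the gene's QV set; flags (and
    skips the test) when the exclusion empties the set. The excluded
    indices are echoed in the result flags.
    """
    qv_idx = np.asarray(qv_idx, dtype=int)
    excluded = np.asarray(sorted(set(map(int, excluded_idx))), dtype=int)
    missing = set(excluded) - set(qv_idx.tolist())
    if missing:
        raise ValueError(f"excluded variants {sorted(missing)} not in the QV set")
    remaining = np.array([i for i in qv_idx if i not in set(excluded.tolist())], dtype=int)
    echo = ("excluded=" + ",".join(map(str, excluded.tolist())),)
    if remaining.size == 0:
        res = BurdenResult(gene=gene, model=model, phenotype=phenotype, kind=kind)
        res.flags = echo + ("empty_qv_set",)
        return res
    cm = build_carrier_matrix(
        dosage, remaining, zygosity, gene=gene, model=model,
        is_male=is_male, positions=positions,
    )
    if kind == "binary":
        res = fisher_burden(cm.carrier, outcome, gene=gene, model=model, phenotype=phenotype)
    else:
        res = quantitative_burden(
            cm.carrier, outcome, covariates, gene=gene, model=model, phenotype_name=phenotype
        )
    res.flags = res.flags + echo
    return res


# --------------------------------------------------------------------------
# dominant single-variant logistic model


def dominant_snp_model(
    dosage: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    *,
    min_call_rate: float = 0.9,
) -> dict:
    """Logistic regression of a binary outcome on carrier status (dosage >= 1)."""
    dosage = np.asarray(dosage)
    called = dosage >= 0
    if called.mean() < min_call_rate:
        raise ValueError(f"call rate {called.mean():.3f} below {min_call_rate}")
    carrier = (dosage >= 1) & called
    if carrier[called].all() or not carrier[called].any():
        return {"flag": "monomorphic", "or": math.nan, "p": math.nan}
    y = np.asarray(outcome, dtype=float)[called]
    cov = covariates.iloc[called].reset_index(drop=True) if covariates is not None else None
    data = pd.DataFrame({"outcome": y, "carrier": carrier[called].astype(float)})
    cov_names: tuple[str, ...] = ()
    if cov is not None:
        for c in cov.columns:
            data[c] = cov[c].to_numpy()
        cov_names = tuple(cov.columns)
    spec = JointModelSpec("outcome", ("carrier",), cov_names, family="logistic")
    row = conditional_joint_regression(spec, data).iloc[0]
    return {
        "or": float(row["or"]), "ci_low": float(np.exp(row["ci_low"])),
        "ci_high": float(np.exp(row["ci_high"])), "p": float(row["p"]),
        "estimate": float(row["estimate"]), "se": float(row["se"]), "flag": row["flag"],
    }


# --------------------------------------------------------------------------
# stratified effect modification


@dataclass
class StratifiedEffect:
    stratum_labels: tuple[str, str]
    estimates: tuple[float, float]  # log-OR or beta
    ses: tuple[float, float]
    cis: tuple[tuple[float, float], tuple[float, float]]
    ps: tuple[float, float]
    q: float | None
    q_p: float | None
    flags: tuple[str, ...] = ()


def stratified_effect_modification(
    carrier: np.ndarray,
    modifier: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    *,
    kind: str = "binary",
    labels: tuple[str, str] = ("modifier_noncarrier", "modifier_carrier"),
) -> StratifiedEffect:
    """Fit the carrier effect separately in modifier strata, then test
    heterogeneity of the two log-scale estimates (chi-squared, 1 df).

    Binary outcomes use logistic regression; quantitative use OLS. A
    stratum with zero carriers is flagged and the heterogeneity test is
    skipped.
    """
    carrier = np.asarray(carrier, dtype=bool)
    modifier = np.asarray(modifier, dtype=bool)
    outcome = np.asarray(outcome, dtype=float)
    if not (~modifier).any() or not modifier.any():
        raise ValueError("both modifier strata must be non-empty")
    estimates, ses, cis, ps, flags = [], [], [], [], []
    for in_stratum in (~modifier, modifier):
        idx = np.nonzero(in_stratum)[0]
        if not carrier[idx].any():
            estimates.append(math.nan); ses.append(math.nan)
            cis.append((math.nan, math.nan)); ps.append(math.nan)
            flags.append("zero_carriers")
            continue
        data = pd.DataFrame({"outcome": outcome[idx], "carrier": carrier[idx].astype(float)})
        cov_names: tuple[str, ...] = ()
        if covariates is not None:
            for c in covariates.columns:
                data[c] = covariates[c].to_numpy()[idx]
            cov_names = tuple(covariates.columns)
        family = "logistic" if kind == "binary" else "linear"
        spec = JointModelSpec("outcome", ("carrier",), cov_names, family=family)
        row = conditional_joint_regression(spec, data).iloc[0]
        estimates.append(float(row["estimate"]))
        ses.append(float(row["se"]))
        cis.append((float(row["ci_low"]), float(row["ci_high"])))
        ps.append(float(row["p"]))
        flags.append(row["flag"])
    q = q_p = None
    if not any(f == "zero_carriers" or f.startswith("separation") for f in flags):
        q, _, q_p = heterogeneity_test(estimates[0], ses[0], estimates[1], ses[1])
    return StratifiedEffect(
        stratum_labels=labels,
        estimates=(estimates[0], estimates[1]),
        ses=(ses[0], ses[1]),
        cis=(cis[0], cis[1]),
        ps=(ps[0], ps[1]),
        q=q, q_p=q_p,
        flags=tuple(f for f in flags if f),
    )


# --------------------------------------------------------------------------
# linkage disequilibrium


@dataclass
class LDResult:
    d: float
    d_prime: float
    r2: float
    haplotype_freqs: dict[str, float]
    method: str  # "phased" | "em"
    iterations: int = 0


def _ld_from_hap_freqs(p_ab: float, p_a: float, p_b: float, method: str, iters: int = 0) -> LDResult:
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = d * d / denom if denom > 0 else 0.0
    freqs = {
        "AB": p_ab,
        "Ab": p_a - p_ab,
        "aB": p_b - p_ab,
        "ab": 1 - p_a - p_b + p_ab,
    }
    return LDResult(d, d_prime, r2, freqs, method, iters)


def ld_from_haplotypes(hap1: np.ndarray, hap2: np.ndarray) -> LDResult:
    """Closed-form D, D', r^2 from phased haplotypes of two variants.

    ``hap1``/``hap2`` are 0/1 allele arrays over haplotypes (one entry per
    chromosome copy), aligned.
    """
    h1 = np.asarray(hap1, dtype=float)
    h2 = np.asarray(hap2, dtype=float)
    if h1.shape != h2.shape:
        raise ValueError("haplotype arrays must align")
    p_a, p_b = h1.mean(), h2.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("both variants must be polymorphic")
    p_ab = float((h1 * h2).mean())
    return _ld_from_hap_freqs(p_ab, float(p_a), float(p_b), "phased")


def ld_from_genotypes(
    dos1: np.ndarray, dos2: np.ndarray, *, max_iter: int = 1000, tol: float = 1e-10
) -> LDResult:
    """EM maximum-likelihood haplotype frequencies from unphased genotypes.

    Starts from linkage equilibrium; stops when the log-likelihood change
    falls below ``tol`` or raises after ``max_iter`` iterations, reporting
    the final log-likelihood.
    """
    d1 = np.asarray(dos1)
    d2 = np.asarray(dos2)
    ok = (d1 >= 0) & (d2 >= 0)
    d1, d2 = d1[ok].astype(int), d2[ok].astype(int)
    if d1.size == 0 or len(np.unique(d1)) < 2 or len(np.unique(d2)) < 2:
        raise ValueError("both variants must be polymorphic")
    counts = np.zeros((3, 3))
    for g1, g2 in zip(d1, d2):
        counts[g1, g2] += 1
    n = counts.sum()
    p_a = (counts[1].sum() + 2 * counts[2].sum()) / (2 * n)
    p_b = (counts[:, 1].sum() + 2 * counts[:, 2].sum()) / (2 * n)
    # haplotype frequencies: f[0]=AB, f[1]=Ab, f[2]=aB, f[3]=ab
    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    n_dh = counts[1, 1]  # double heterozygotes are the only phase-ambiguous class
    loglik_prev = -np.inf
    for it in range(1, max_iter + 1):
        denom = f[0] * f[3] + f[1] * f[2]
        frac_cis = f[0] * f[3] / denom if denom > 0 else 0.5
        hap_counts = np.zeros(4)
        hap_counts[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + n_dh * frac_cis
        hap_counts[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + n_dh * (1 - frac_cis)
        hap_counts[2] = 2 * counts[0, 2] + counts[1, 2] + counts[0, 1] + n_dh * (1 - frac_cis)
        hap_counts[3] = 2 * counts[0, 0] + counts[1, 0] + counts[0, 1] + n_dh * frac_cis
        f = hap_counts / hap_counts.sum()
        loglik = _ld_loglik(counts, f)
        if abs(loglik - loglik_prev) < tol:
            return _ld_from_hap_freqs(float(f[0]), float(f[0] + f[1]), float(f[0] + f[2]), "em", it)
        loglik_prev = loglik
    raise RuntimeError(f"EM did not converge in {max_iter} iterations (loglik={loglik_prev:.6f})")


def _ld_loglik(counts: np.ndarray, f: np.ndarray) -> float:
    # genotype probabilities from haplotype pairs under random mating;
    # f = (AB, Ab, aB, ab) haplotype frequencies
    pairs = {
        (2, 2): f[0] ** 2, (2, 1): 2 * f[0] * f[1], (2, 0): f[1] ** 2,
        (1, 2): 2 * f[0] * f[2], (1, 1): 2 * (f[0] * f[3] + f[1] * f[2]),
        (1, 0): 2 * f[1] * f[3],
        (0, 2): f[2] ** 2, (0, 1): 2 * f[2] * f[3], (0, 0): f[3] ** 2,
    }
    ll = 0.0
    for (g1, g2), prob in pairs.items():
        if counts[g1, g2] > 0:
            ll += counts[g1, g2] * math.log(max(prob, 1e-300))
    return ll


def ld_stats(arg1, arg2, *, phased: bool) -> LDResult:
    """Pairwise LD; see :func:`ld_from_haplotypes` / :func:`ld_from_genotypes`."""
    return ld_from_haplotypes(arg1, arg2) if phased else ld_from_genotypes(arg1, arg2)


__all__ = [
    "JointModelSpec",
    "LDResult",
    "StratifiedEffect",
    "conditional_joint_regression",
    "dominant_snp_model",
    "ld_from_genotypes",
    "ld_from_haplotypes",
    "ld_stats",
    "leave_out_collapsing",
    "stratified_effect_modification",
]
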