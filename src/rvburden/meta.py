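"""Stratified meta-analysis and calibration diagnostics.

Cochran-Mantel-Haenszel combination of per-stratum 2x2 carrier-by-case
tables (no continuity correction by default), a two-estimate chi-squared
heterogeneity test, genomic-inflation lambda, and the pooled pan-ancestry
quantitative model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

from .collapsing import BurdenResult, quantitative_burden
from .exact import odds_ratio_woolf


@dataclass
class MetaResult:
    """CMH-combined association across strata."""

    or_pooled: float
    ci_low: float
    ci_high: float
    chi2: float
    df: int
    p: float
    stratum_labels: tuple[str, ...]
    stratum_ors: tuple[float, ...]


def chi2_tail(statistic: float, df: int = 1) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if statistic < 0:
        raise ValueError("chi-squared statistic must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(statistic, df))


def _degenerate(t: np.ndarray) -> bool:
    return (
        t.sum() == 0
        or t[0].sum() == 0
        or t[1].sum() == 0
        or t[:, 0].sum() == 0
        or t[:, 1].sum() == 0
    )


def cmh_test(strata, *, correction: bool = False) -> MetaResult:
    """Mantel-Haenszel common OR and CMH chi-squared over 2x2xN strata.

    ``strata`` is a sequence of ``(label, table)`` pairs or bare 2x2
    tables, rows = carrier/noncarrier, columns = case/control (any
    consistent orientation works). Strata with a zero margin carry no
    information and are dropped; if all are degenerate a ``ValueError``
    is raised. The CI is the Robins-Breslow-Greenland interval on the
    pooled log OR.
    """
    labels: list[str] = []
    tables: list[np.ndarray] = []
    for i, item in enumerate(strata):
        if isinstance(item, tuple) and len(item) == 2 and isinstance(item[0], str):
            label, table = item
        else:
            label, table = str(i), item
        t = np.asarray(table, dtype=float)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError(f"stratum {label}: need a nonnegative 2x2 table")
        labels.append(str(label))
        tables.append(t)
    if not tables:
        raise ValueError("no strata given")
    kept = [(l, t) for l, t in zip(labels, tables) if not _degenerate(t)]
    if not kept:
        raise ValueError("all strata degenerate (zero margins)")
    labels = [l for l, _ in kept]
    tables = [t for _, t in kept]

    st = StratifiedTable(tables)
    or_pooled = float(st.oddsratio_pooled)
    ci_low, ci_high = (float(x) for x in st.oddsratio_pooled_confint())
    test = st.test_null_odds(correction=correction)
    chi2 = float(test.statistic)
    p = float(test.pvalue)
    stratum_ors = tuple(
        odds_ratio_woolf(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])).estimate
        for t in tables
    )
    return MetaResult(or_pooled, ci_low, ci_high, chi2, 1, p, tuple(labels), stratum_ors)


def heterogeneity_test(
    estimate1: float, se1: float, estimate2: float, se2: float
) -> tuple[float, int, float]:
    """Two-estimate chi-squared heterogeneity test on a common scale.

    Q = (b1 - b2)^2 / (SE1^2 + SE2^2), referred to chi-squared with 1 df.
    Estimates must be on the same (typically log-OR or beta) scale.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    q = (estimate1 - estimate2) ** 2 / (se1**2 + se2**2)
    return float(q), 1, chi2_tail(q, 1)


_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # ~0.4549


def genomic_lambda(pvalues, *, warn_below: int = 100) -> float:
    """Genomic inflation factor from a vector of p-values.

    lambda = median of the chi-squared(1) quantiles at (1 - p), divided
    by the chi-squared(1) median. Invariant to duplicating the input.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values given")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < warn_below:
        warnings.warn(
            f"genomic lambda computed from only {p.size} tests", stacklevel=2
        )
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_MEDIAN)


def pan_ancestry_quantitative(
    samples: pd.DataFrame,
    carrier: np.ndarray,
    phenotype: str,
    *,
    covariates: tuple[str, ...] = ("age", "sex"),
    ancestry_column: str = "ancestry",
    pc_columns: tuple[str, ...] = ("pc1", "pc2", "pc3", "pc4", "pc5"),
    gene: str = "",
    model: str = "",
) -> BurdenResult:
    """Pooled linear model with categorical ancestry dummies plus PCs.

    Reduces exactly to :func:`quantitative_burden` when a single ancestry
    is present (the dummies then vanish).
    """
    missing = [c for c in pc_columns if c not in samples.columns]
    if missing:
        raise ValueError(f"missing principal-component columns: {missing}")
    cov = pd.DataFrame(index=samples.index)
    for c in covariates:
        if c == "sex":
            cov["sex"] = (samples["sex"].to_numpy() == "male").astype(float)
        else:
            cov[c] = samples[c].astype(float)
    levels = sorted(samples[ancestry_column].unique())
    for level in levels[1:]:  # first level is the reference
        cov[f"ancestry_{level}"] = (samples[ancestry_column] == level).astype(float)
    for c in pc_columns:
        cov[c] = samples[c].astype(float)
    carrier = np.asarray(carrier, dtype=bool)
    for level in levels:
        in_level = (samples[ancestry_column] == level).to_numpy()
        if carrier[in_level].all() or not carrier[in_level].any():
            warnings.warn(
                f"stratum {level!r} has zero variance in the carrier indicator",
                stacklevel=2,
            )
    return quantitative_burden(
        carrier, samples[phenotype].to_numpy(dtype=float), cov,
        gene=gene, model=model, phenotype_name=phenotype,
    )


def combine_burden_tables(tables: list[tuple[str, pd.DataFrame]]) -> pd.DataFrame:
    """CMH-combine per-stratum binary burden tables.

    Each input is ``(stratum_label, burden table)`` as produced by
    ``run_collapsing``. Rows are combined per (gene, model, phenotype)
    across the strata where the test is present; quantitative rows are
    ignored (the pooled-regression path covers those).
    """
    keys: dict[tuple, list[tuple[str, np.ndarray]]] = {}
    for label, df in tables:
        binary = df[df["kind"] == "binary"]
        for _, row in binary.iterrows():
            key = (row["gene"], row["model"], row["phenotype"])
            table = np.array(
                [
                    [row["n_case_carrier"], row["n_case_noncarrier"]],
                    [row["n_ctrl_carrier"], row["n_ctrl_noncarrier"]],
                ]
            )
            keys.setdefault(key, []).append((label, table))
    rows = []
    for (gene, model, phenotype), strata in sorted(keys.items()):
        try:
            res = cmh_test(strata)
        except ValueError as exc:
            rows.append(
                {"gene": gene, "model": model, "phenotype": phenotype,
                 "n_strata": len(strata), "or_pooled": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "chi2": np.nan, "p": np.nan, "flag": str(exc)}
            )
            continue
        rows.append(
            {"gene": gene, "model": model, "phenotype": phenotype,
             "n_strata": len(res.stratum_labels), "or_pooled": res.or_pooled,
             "ci_low": res.ci_low, "ci_high": res.ci_high, "chi2": res.chi2,
             "p": res.p, "flag": ""}
        )
    return pd.DataFrame(rows)


def qq_data(pvalues) -> pd.DataFrame:
    """Expected vs observed -log10 p for QQ plotting, smallest last."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    return pd.DataFrame({"expected": expected[::-1], "observed": observed[::-1]})


__all__ = [
    "MetaResult",
    "chi2_tail",
    "cmh_test",
    "combine_burden_tables",
    "genomic_lambda",
    "heterogeneity_test",
    "pan_ancestry_quantitative",
    "qq_data",
]
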