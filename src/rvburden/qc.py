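"""Per-genotype and per-site quality-control filters.

Two preset threshold profiles are provided: ``collapsing`` (gene-level
burden analysis) and ``exwas`` (variant-level association). Failing
genotypes are set to missing downstream; failing sites are dropped from
the analysis. All criteria are evaluated (never short-circuited), so the
pass flag and the fail-reason set depend only on the metric values.

The homozygous alternate-read-fraction rule is printed as an upper bound
("at most 80% alternate reads in homozygous genotypes"), which is inverted
relative to the usual intent; both readings are implemented behind
``hom_ab_rule`` and the printed one is the default.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical ordering of fail reasons (evaluation-order independence)
GENOTYPE_REASONS = (
    "coverage",
    "genotype_quality",
    "het_alt_fraction",
    "het_binomial",
    "hom_alt_fraction",
)
SITE_REASONS = (
    "fs",
    "mq",
    "qual",
    "rprs",
    "mqrs",
    "caller_status",
    "ccds",
    "external_coverage",
    "external_z",
    "external_mq",
    "external_pass_fraction",
    "missingness",
    "fail_fraction",
)


def binomial_het_test(alt_reads: int, total_reads: int) -> float:
    """Exact two-sided binomial test of alt-read proportion against 0.5.

    Two-sided by the minimum-likelihood rule: the sum of outcome
    probabilities not exceeding that of the observed count.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not 0 <= alt_reads <= total_reads:
        raise ValueError(f"alt_reads {alt_reads} outside [0, {total_reads}]")
    return float(stats.binomtest(alt_reads, total_reads, 0.5).pvalue)


@dataclass(frozen=True)
class QCThresholds:
    """One named threshold per Methods filter; see module docstring."""

    name: str
    min_dp: int = 10
    min_gq: int = 20
    het_ab_min: float = 0.25
    het_ab_max: float | None = 0.8
    het_binom_p_min: float = 1e-6
    hom_ab_max: float | None = 0.8
    hom_ab_rule: str = "as_printed"  # or "conventional": require ab >= 1 - hom_ab_max
    fs_max_snv: float = 60.0
    fs_max_indel: float = 200.0
    mq_min: float = 40.0
    qual_min: float = 30.0
    rprs_min: float = -2.0
    mqrs_min: float = -8.0
    require_pass_status: bool = True
    require_ccds: bool = False
    external_coverage_min: float = 0.25
    external_z_min: float | None = -2.0
    external_mq_min: float | None = 30.0
    external_pass_fraction_min: float | None = None
    missingness_max: float | None = None
    fail_fraction_max: float | None = None

    def with_overrides(self, **kwargs) -> "QCThresholds":
        return replace(self, **kwargs)


COLLAPSING_THRESHOLDS = QCThresholds(name="collapsing", require_ccds=True)

EXWAS_THRESHOLDS = QCThresholds(
    name="exwas",
    het_ab_min=0.2,
    het_ab_max=None,
    hom_ab_max=None,
    require_ccds=False,
    external_coverage_min=0.30,
    external_z_min=None,
    external_mq_min=None,
    external_pass_fraction_min=0.5,
    missingness_max=0.10,
    fail_fraction_max=0.05,
)

PROFILES = {"collapsing": COLLAPSING_THRESHOLDS, "exwas": EXWAS_THRESHOLDS}


def get_profile(profile) -> QCThresholds:
    if isinstance(profile, QCThresholds):
        return profile
    try:
        return PROFILES[profile]
    except KeyError:
        raise ValueError(f"unknown QC profile {profile!r}; expected one of {sorted(PROFILES)}")


def apply_genotype_filters(
    dosage: int,
    dp: int,
    gq: int,
    alt_reads: int,
    profile="collapsing",
) -> tuple[bool, tuple[str, ...]]:
    """Evaluate the per-call criteria for one genotype call.

    ``dosage`` is the called allele count (1 = heterozygous, 2 =
    homozygous/hemizygous alternate). Returns ``(passed, fail_reasons)``
    with reasons in canonical order. A failing call should be set to
    missing by the caller, not removed from the site.
    """
    thr = get_profile(profile)
    reasons: set[str] = set()
    if dp < thr.min_dp:
        reasons.add("coverage")
    if gq < thr.min_gq:
        reasons.add("genotype_quality")
    if dosage == 1 and dp >= 1:
        ab = alt_reads / dp
        if ab < thr.het_ab_min or (thr.het_ab_max is not None and ab > thr.het_ab_max):
            reasons.add("het_alt_fraction")
        if binomial_het_test(alt_reads, dp) <= thr.het_binom_p_min:
            reasons.add("het_binomial")
    if dosage == 2 and dp >= 1 and thr.hom_ab_max is not None:
        ab = alt_reads / dp
        if thr.hom_ab_rule == "as_printed":
            if ab > thr.hom_ab_max:
                reasons.add("hom_alt_fraction")
        elif thr.hom_ab_rule == "conventional":
            if ab < 1.0 - thr.hom_ab_max:
                reasons.add("hom_alt_fraction")
        else:
            raise ValueError(f"unknown hom_ab_rule {thr.hom_ab_rule!r}")
    ordered = tuple(r for r in GENOTYPE_REASONS if r in reasons)
    return (not ordered, ordered)


def _require(site, key: str):
    try:
        value = site[key]
    except (KeyError, IndexError):
        raise KeyError(f"site metric {key!r} missing") from None
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise KeyError(f"site metric {key!r} missing")
    return value


def _optional(site, key: str):
    try:
        value = site[key]
    except (KeyError, IndexError):
        return None
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return value


def apply_site_filters(site, profile="collapsing") -> tuple[bool, tuple[str, ...]]:
    """Evaluate the per-site criteria for one variant.

    ``site`` is a mapping/row carrying: ``is_snv``, ``fs``, ``mq``,
    ``qual``, ``rprs``, ``mqrs``, ``filter_status``; optionally
    ``in_ccds``, ``external_coverage_fraction``, ``external_z``,
    ``external_mq``, ``external_pass_fraction``, ``maf_external`` (> 0
    means externally observed), ``missingness``, ``fail_fraction``.

    Core caller metrics are required (missing -> ``KeyError`` naming the
    metric); external-reference columns, when absent, skip their criteria
    with a warning.
    """
    thr = get_profile(profile)
    reasons: set[str] = set()

    fs_max = thr.fs_max_snv if bool(_require(site, "is_snv")) else thr.fs_max_indel
    if _require(site, "fs") > fs_max:
        reasons.add("fs")
    if _require(site, "mq") < thr.mq_min:
        reasons.add("mq")
    if _require(site, "qual") < thr.qual_min:
        reasons.add("qual")
    if _require(site, "rprs") < thr.rprs_min:
        reasons.add("rprs")
    if _require(site, "mqrs") < thr.mqrs_min:
        reasons.add("mqrs")
    if thr.require_pass_status and _require(site, "filter_status") != "PASS":
        reasons.add("caller_status")

    if thr.require_ccds:
        in_ccds = _optional(site, "in_ccds")
        if in_ccds is None:
            warnings.warn("in_ccds column absent; CCDS criterion skipped", stacklevel=2)
        elif not in_ccds:
            reasons.add("ccds")

    cov = _optional(site, "external_coverage_fraction")
    if cov is None:
        warnings.warn("external_coverage_fraction absent; criterion skipped", stacklevel=2)
    elif cov < thr.external_coverage_min:
        reasons.add("external_coverage")

    maf_ext = _optional(site, "maf_external")
    externally_observed = maf_ext is not None and maf_ext > 0.0
    if externally_observed:
        if thr.external_z_min is not None:
            z = _optional(site, "external_z")
            if z is None:
                warnings.warn("external_z absent; criterion skipped", stacklevel=2)
            elif z < thr.external_z_min:
                reasons.add("external_z")
        if thr.external_mq_min is not None:
            xmq = _optional(site, "external_mq")
            if xmq is None:
                warnings.warn("external_mq absent; criterion skipped", stacklevel=2)
            elif xmq < thr.external_mq_min:
                reasons.add("external_mq")
        if thr.external_pass_fraction_min is not None:
            pf = _optional(site, "external_pass_fraction")
            if pf is None:
                warnings.warn("external_pass_fraction absent; criterion skipped", stacklevel=2)
            elif pf < thr.external_pass_fraction_min:
                reasons.add("external_pass_fraction")

    if thr.missingness_max is not None and _require(site, "missingness") >= thr.missingness_max:
        reasons.add("missingness")
    if thr.fail_fraction_max is not None and _require(site, "fail_fraction") >= thr.fail_fraction_max:
        reasons.add("fail_fraction")

    ordered = tuple(r for r in SITE_REASONS if r in reasons)
    return (not ordered, ordered)


def apply_qc(dosage, dp, gq, ad_alt, variants, profile="collapsing"):
    """Vectorised cohort-level QC.

    Sets failing genotype calls to missing (-1) and returns
    ``(clean_dosage, site_pass, report)`` where ``site_pass`` is a boolean
    array over variants and ``report`` is a list of
    ``(variant_index, sample_index or None, reasons)`` records
    (``sample_index None`` marks a site-level failure).

    ``missingness`` / ``fail_fraction`` per site are computed over the
    cohort from the call-level results before site filters are applied.
    """
    thr = get_profile(profile)
    dosage = np.asarray(dosage)
    dp = np.asarray(dp)
    gq = np.asarray(gq)
    ad_alt = np.asarray(ad_alt)
    n, m = dosage.shape
    clean = dosage.copy()
    report: list[tuple[int, int | None, tuple[str, ...]]] = []

    called = dosage >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(dp >= 1, ad_alt / np.maximum(dp, 1), np.nan)
    het = called & (dosage == 1) & (dp >= 1)
    hom = called & (dosage == 2) & (dp >= 1)

    fail_any = called & (dp < thr.min_dp)
    fail_any |= called & (gq < thr.min_gq)
    het_ab_bad = het & (ab < thr.het_ab_min)
    if thr.het_ab_max is not None:
        het_ab_bad |= het & (ab > thr.het_ab_max)
    fail_any |= het_ab_bad
    # cheap one-sided tail bound: the two-sided minimum-likelihood p can
    # only dip below the threshold if the smaller tail already does
    k = np.minimum(ad_alt, dp - ad_alt)
    tail = stats.binom.cdf(k, np.maximum(dp, 1), 0.5)
    binom_candidates = het & (tail <= thr.het_binom_p_min)
    if thr.hom_ab_max is not None:
        if thr.hom_ab_rule == "as_printed":
            fail_any |= hom & (ab > thr.hom_ab_max)
        elif thr.hom_ab_rule == "conventional":
            fail_any |= hom & (ab < 1.0 - thr.hom_ab_max)
        else:
            raise ValueError(f"unknown hom_ab_rule {thr.hom_ab_rule!r}")

    call_fail = np.zeros((n, m), dtype=bool)
    for i, j in zip(*np.nonzero(fail_any | binom_candidates)):
        ok, reasons = apply_genotype_filters(
            int(dosage[i, j]), int(dp[i, j]), int(gq[i, j]), int(ad_alt[i, j]), thr
        )
        if not ok:
            call_fail[i, j] = True
            clean[i, j] = -1
            report.append((int(j), int(i), reasons))

    site_pass = np.ones(m, dtype=bool)
    for j in range(m):
        site = dict(variants.iloc[j])
        site["missingness"] = 1.0 - called[:, j].mean() if n else 0.0
        site["fail_fraction"] = call_fail[:, j].mean() if n else 0.0
        ok, reasons = apply_site_filters(site, thr)
        if not ok:
            site_pass[j] = False
            report.append((j, None, reasons))
    return clean, site_pass, report


__all__ = [
    "COLLAPSING_THRESHOLDS",
    "EXWAS_THRESHOLDS",
    "GENOTYPE_REASONS",
    "PROFILES",
    "QCThresholds",
    "SITE_REASONS",
    "apply_genotype_filters",
    "apply_qc",
    "apply_site_filters",
    "binomial_het_test",
    "get_profile",
]
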