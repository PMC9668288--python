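"""Consequence classes and qualifying-variant (QV) model definitions.

A collapsing model is a named rule set deciding which annotated variants
"qualify" for a gene burden: allowed consequence classes, internal/external
minor-allele-frequency ceilings, optional deleteriousness-score conditions,
and a zygosity mode (dominant or recessive).

Term sets follow the SnpEff vocabulary. The per-model frequency/score
parameters of the default registry are documented repository conventions
(config-overridable); every results file echoes the registry actually used.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, fields

import yaml

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# consequence classes

PTV_TERMS = frozenset(
    {
        "exon_loss_variant",
        "frameshift_variant",
        "start_lost",
        "stop_gained",
        "stop_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "gene_fusion",
        "bidirectional_gene_fusion",
        "rare_amino_acid_variant",
        "transcript_ablation",
    }
)

MISSENSE_TERMS = frozenset(
    {
        "missense_variant_splice_region_variant",
        "missense_variant",
    }
)

#: full nonsynonymous vocabulary; PTV and missense terms are subsets
NONSYNONYMOUS_TERMS = PTV_TERMS | MISSENSE_TERMS | frozenset(
    {
        "conservative_inframe_deletion",
        "conservative_inframe_insertion",
        "disruptive_inframe_insertion",
        "disruptive_inframe_deletion",
        "protein_altering_variant",
    }
)

SYNONYMOUS_TERMS = frozenset({"synonymous_variant"})

CONSEQUENCE_CLASSES = ("PTV", "missense", "nonsynonymous", "synonymous", "other")


def classify_consequence(term: str) -> str:
    """Map a consequence term to its most specific class.

    Returns one of ``PTV``, ``missense``, ``nonsynonymous`` (a
    nonsynonymous term that is neither PTV nor missense), ``synonymous``
    or ``other`` (unknown terms, logged at debug level).
    """
    if term in PTV_TERMS:
        return "PTV"
    if term in MISSENSE_TERMS:
        return "missense"
    if term in NONSYNONYMOUS_TERMS:
        return "nonsynonymous"
    if term in SYNONYMOUS_TERMS:
        return "synonymous"
    logger.debug("unknown consequence term %r -> other", term)
    return "other"


def is_nonsynonymous(term: str) -> bool:
    return term in NONSYNONYMOUS_TERMS


# --------------------------------------------------------------------------
# model specs


@dataclass(frozen=True)
class QVModelSpec:
    """A named qualifying-variant rule set.

    ``classes`` uses class names; ``nonsynonymous`` means *any*
    nonsynonymous term (including PTV and missense). MAF comparisons are
    strict (``<``). Score conditions (``revel_min``,
    ``mtr_percentile_max``) apply to missense variants only; PTVs are
    exempt.
    """

    name: str
    classes: frozenset[str]
    maf_internal_max: float = 1.0
    maf_external_max: float = 1.0
    require_external_absent: bool = False
    revel_min: float | None = None
    mtr_percentile_max: float | None = None
    zygosity: str = "dominant"

    def __post_init__(self) -> None:
        if self.zygosity not in ("dominant", "recessive"):
            raise ValueError(f"model {self.name}: bad zygosity {self.zygosity!r}")
        for ceiling in (self.maf_internal_max, self.maf_external_max):
            if not 0.0 <= ceiling <= 1.0:
                raise ValueError(f"model {self.name}: MAF ceiling {ceiling} outside [0, 1]")
        unknown = self.classes - set(CONSEQUENCE_CLASSES)
        if unknown:
            raise ValueError(f"model {self.name}: unknown classes {sorted(unknown)}")

    def _class_allowed(self, cls: str) -> bool:
        if cls in self.classes:
            return True
        # "nonsynonymous" admits the specific subclasses as well
        return "nonsynonymous" in self.classes and cls in ("PTV", "missense", "nonsynonymous")


def qualifies(variant, model: QVModelSpec) -> tuple[bool, str | None]:
    """Decide whether an annotated variant is a QV under ``model``.

    ``variant`` is any mapping/row with fields ``consequence``,
    ``maf_internal``, ``maf_external`` and (optionally) ``revel_score``,
    ``mtr_percentile``. Returns ``(flag, first_failed_criterion)``.
    """
    cls = classify_consequence(variant["consequence"])
    if not model._class_allowed(cls):
        return False, "consequence_class"
    if not variant["maf_internal"] < model.maf_internal_max:
        return False, "maf_internal"
    maf_ext = variant["maf_external"]
    if model.require_external_absent:
        if maf_ext > 0.0:
            return False, "external_presence"
    elif not maf_ext < model.maf_external_max:
        return False, "maf_external"
    if cls == "missense":
        if model.revel_min is not None:
            revel = variant.get("revel_score") if hasattr(variant, "get") else variant["revel_score"]
            if revel is None or revel != revel or not revel >= model.revel_min:
                return False, "revel"
        if model.mtr_percentile_max is not None:
            mtr = variant.get("mtr_percentile") if hasattr(variant, "get") else variant["mtr_percentile"]
            if mtr is None or mtr != mtr or not mtr <= model.mtr_percentile_max:
                return False, "mtr"
    return True, None


# --------------------------------------------------------------------------
# default registry: 9 dominant nonsynonymous models, 1 recessive model,
# plus a synonymous empirical negative control (11 total).

_NS = frozenset({"nonsynonymous"})


def _default_models() -> dict[str, QVModelSpec]:
    specs = [
        QVModelSpec("syn", frozenset({"synonymous"}), 0.001, 0.001),
        QVModelSpec("ptv", frozenset({"PTV"}), 0.001, 0.001),
        QVModelSpec("ptv5pcnt", frozenset({"PTV"}), 0.05, 0.05),
        QVModelSpec("UR", _NS, 0.001, require_external_absent=True),
        QVModelSpec("URmtr", frozenset({"missense"}), 0.001, require_external_absent=True,
                    mtr_percentile_max=50.0),
        QVModelSpec("raredmg", frozenset({"missense"}), 0.005, 0.005, revel_min=0.25),
        QVModelSpec("raredmgmtr", frozenset({"missense"}), 0.005, 0.005, revel_min=0.25,
                    mtr_percentile_max=50.0),
        QVModelSpec("flexdmg", frozenset({"PTV", "missense"}), 0.005, 0.005, revel_min=0.5),
        QVModelSpec("flexnonsynmtr", _NS, 0.005, 0.005, mtr_percentile_max=50.0),
        QVModelSpec("ptvraredmg", frozenset({"PTV", "missense"}), 0.001, 0.001, revel_min=0.5),
        QVModelSpec("rec", _NS, 0.01, 0.01, zygosity="recessive"),
    ]
    return {s.name: s for s in specs}


DEFAULT_REGISTRY: dict[str, QVModelSpec] = _default_models()

DOMINANT_MODELS = tuple(n for n, s in DEFAULT_REGISTRY.items()
                        if s.zygosity == "dominant" and n != "syn")
RECESSIVE_MODEL = "rec"
SYNONYMOUS_MODEL = "syn"


def load_model_registry(source=None) -> dict[str, QVModelSpec]:
    """Return the model registry.

    ``source`` may be ``None`` (built-in defaults), a path to a YAML file,
    or a parsed mapping ``{name: {field: value, ...}}``. Duplicate names
    or malformed entries raise ``ValueError`` naming the offending model.
    """
    if source is None:
        return copy.deepcopy(DEFAULT_REGISTRY)
    if isinstance(source, (str, bytes)) or hasattr(source, "read_text"):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = source
    if not isinstance(raw, dict):
        raise ValueError("model registry config must be a mapping of name -> spec")
    registry: dict[str, QVModelSpec] = {}
    allowed = {f.name for f in fields(QVModelSpec)} - {"name"}
    for name, body in raw.items():
        if name in registry:
            raise ValueError(f"duplicate model name {name!r}")
        if not isinstance(body, dict):
            raise ValueError(f"model {name!r}: spec must be a mapping")
        bad = set(body) - allowed
        if bad:
            raise ValueError(f"model {name!r}: unknown fields {sorted(bad)}")
        body = dict(body)
        if "classes" in body:
            body["classes"] = frozenset(body["classes"])
        try:
            registry[name] = QVModelSpec(name=name, **body)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"model {name!r}: {exc}") from exc
    return registry


def registry_header_lines(registry: dict[str, QVModelSpec]) -> list[str]:
    """Verbatim echo of a registry, for embedding in results-file headers."""
    lines = []
    for name in sorted(registry):
        s = registry[name]
        lines.append(
            f"##model={name} classes={','.join(sorted(s.classes))} "
            f"maf_internal_max={s.maf_internal_max} maf_external_max={s.maf_external_max} "
            f"require_external_absent={s.require_external_absent} revel_min={s.revel_min} "
            f"mtr_percentile_max={s.mtr_percentile_max} zygosity={s.zygosity}"
        )
    return lines


__all__ = [
    "CONSEQUENCE_CLASSES",
    "DEFAULT_REGISTRY",
    "DOMINANT_MODELS",
    "MISSENSE_TERMS",
    "NONSYNONYMOUS_TERMS",
    "PTV_TERMS",
    "QVModelSpec",
    "RECESSIVE_MODEL",
    "SYNONYMOUS_MODEL",
    "SYNONYMOUS_TERMS",
    "classify_consequence",
    "is_nonsynonymous",
    "load_model_registry",
    "qualifies",
    "registry_header_lines",
]
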