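"""End-to-end orchestration: simulate-or-load -> qc -> qv -> collapse
(-> exwas), with a run manifest for provenance.

Re-running with the same config and seed reproduces byte-identical
outputs (no timestamps enter the result files; stage timings go to the
log only).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, qvmodels
from .collapsing import PhenotypeSpec, run_collapsing
from .exwas import run_exwas
from .meta import qq_data
from .qc import apply_qc, get_profile
from .simulate import SimulationConfig, generate_cohort
from .vcfio import read_table, read_vcf, write_cohort

logger = logging.getLogger(__name__)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _phenospecs(config: dict, samples: pd.DataFrame) -> list[PhenotypeSpec]:
    specs = []
    for raw in config.get("phenotypes", []):
        spec = PhenotypeSpec(
            name=raw["name"],
            kind=raw["kind"],
            covariates=tuple(raw.get("covariates", ("age", "sex"))),
            sex_match=raw.get("sex_match", True),
            medication_indicator=raw.get("medication_indicator"),
        )
        for col in (spec.name, *spec.covariate_columns()):
            if col != "sex" and col not in samples.columns:
                raise ValueError(f"phenotype column {col!r} missing from the cohort table")
        specs.append(spec)
    if not specs:
        raise ValueError("no phenotypes configured")
    return specs


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config, out_dir) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Config keys: ``seed``; either ``simulate`` (a
    :class:`SimulationConfig` mapping) or ``inputs`` (paths ``vcf``,
    ``annotations``, ``phenotypes``); ``qc_profile``; ``models`` (subset
    of registry names) / ``models_config``; ``phenotypes`` (list of
    PhenotypeSpec mappings); ``run_exwas`` (bool).
    """
    config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}, "inputs": {}}

    t0 = time.perf_counter()
    stage = "simulate" if "simulate" in config else "load"
    try:
        if stage == "simulate":
            sim = generate_cohort(SimulationConfig.from_dict(config["simulate"]), seed)
            samples, variants, genotypes = sim.samples, sim.variants, sim.genotypes
            paths = write_cohort(samples, variants, genotypes, out_dir / "cohort", truth=sim.truth)
            manifest["inputs"] = {k: str(v) for k, v in paths.items()}
        else:
            inputs = config["inputs"]
            variants_vcf, genotypes, sample_ids = read_vcf(inputs["vcf"])
            samples = read_table(inputs["phenotypes"])
            if list(samples["sample_id"]) != sample_ids:
                raise ValueError("phenotype table sample order does not match the VCF")
            variants = read_table(inputs["annotations"])
            if len(variants) != genotypes.dosage.shape[1]:
                raise ValueError("annotation table does not match the VCF variant count")
            manifest["inputs"] = {k: str(v) for k, v in inputs.items()}
        manifest["stages"][stage] = {
            "n_samples": int(len(samples)),
            "n_variants": int(len(variants)),
        }
    except Exception as exc:  # noqa: BLE001 - aborts carry the stage name
        raise StageError(stage, exc) from exc
    logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    phenotypes = _phenospecs(config, samples)
    profile = get_profile(config.get("qc_profile", "collapsing"))

    t0 = time.perf_counter()
    try:
        dosage, site_pass, report = apply_qc(
            genotypes.dosage, genotypes.dp, genotypes.gq, genotypes.ad_alt, variants, profile
        )
        fail_rows = [
            {
                "variant_index": j,
                "sample_id": "" if i is None else samples["sample_id"].iloc[i],
                "scope": "site" if i is None else "genotype",
                "reasons": ";".join(reasons),
            }
            for j, i, reasons in report
        ]
        pd.DataFrame(
            fail_rows, columns=["variant_index", "sample_id", "scope", "reasons"]
        ).to_csv(out_dir / "qc_failures.tsv", sep="\t", index=False)
        manifest["stages"]["qc"] = {
            "profile": profile.name,
            "sites_passing": int(site_pass.sum()),
            "failures": len(fail_rows),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("qc", exc) from exc
    logger.info("stage qc done in %.2fs", time.perf_counter() - t0)

    registry = qvmodels.load_model_registry(config.get("models_config"))
    if config.get("models"):
        missing = set(config["models"]) - set(registry)
        if missing:
            raise StageError("collapse", ValueError(f"unknown models {sorted(missing)}"))
        registry = {k: v for k, v in registry.items() if k in config["models"]}

    t0 = time.perf_counter()
    try:
        kept = np.nonzero(site_pass)[0]
        table, lambdas = run_collapsing(
            samples, variants.iloc[kept].reset_index(drop=True), dosage[:, kept],
            phenotypes, registry, seed=seed,
        )
        _write_results_tsv(out_dir / "collapsing.tsv", table, registry, profile, seed)
        pd.DataFrame(
            sorted(lambdas.items()), columns=["model", "lambda"]
        ).to_csv(out_dir / "lambdas.tsv", sep="\t", index=False)
        if len(table):
            qq = qq_data(table["p"].dropna().to_numpy())
            qq.to_csv(out_dir / "qq.tsv", sep="\t", index=False)
        manifest["stages"]["collapse"] = {"n_tests": int(len(table))}
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("collapse", exc) from exc
    logger.info("stage collapse done in %.2fs", time.perf_counter() - t0)

    if config.get("run_exwas", False):
        t0 = time.perf_counter()
        try:
            ex = run_exwas(samples, variants.iloc[kept].reset_index(drop=True), dosage[:, kept], phenotypes)
            ex.to_csv(out_dir / "exwas.tsv", sep="\t", index=False)
            manifest["stages"]["exwas"] = {"n_tests": int(len(ex))}
        except Exception as exc:  # noqa: BLE001
            raise StageError("exwas", exc) from exc
        logger.info("stage exwas done in %.2fs", time.perf_counter() - t0)

    for key, path in list(manifest["inputs"].items()):
        path = Path(path)
        try:  # keep the manifest relocatable (and reruns byte-identical)
            shown = path.relative_to(out_dir)
        except ValueError:
            shown = path
        manifest["inputs"][key] = {"path": str(shown), "sha256": sha256_of(path)}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write_results_tsv(path, table: pd.DataFrame, registry, profile, seed: int) -> None:
    header = [
        f"##rvburden_version={__version__}",
        f"##seed={seed}",
        f"##qc_profile={profile.name}",
        *qvmodels.registry_header_lines(registry),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_results_tsv(path) -> tuple[list[str], pd.DataFrame]:
    header = []
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("##"):
            header.append(line.rstrip("\n"))
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t")
    return header, table


__all__ = ["StageError", "load_config", "read_results_tsv", "run_pipeline", "sha256_of"]
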