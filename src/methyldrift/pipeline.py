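"""End-to-end orchestration: simulate/load -> QC -> context -> differential
-> MDI -> enrichment -> survival, with a machine-readable summary.

A run is driven by a single config (YAML on disk or a dict). Identical
config + seed produces a byte-identical summary.json: the summary contains
no timestamps, keys are sorted and floats are serialised by repr.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as mio
from .context import classify_context, stratify_by_context
from .differential import (
    CLASSIFICATION_MODES,
    ModelSpec,
    classify_cpgs,
    run_differential,
)
from .enrichment import run_enrichment
from .mdi import compare_mdi_groups, mdi_table
from .qc import run_qc
from .simulate import (
    SimulationConfig,
    generate_manifest,
    generate_paired_cohort,
    generate_survival,
)
from .survival import km_by_group
from .types import BetaMatrix, PairedDesign

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a run config fails validation (exit code 2 in the CLI)."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails (exit code 1 in the CLI)."""


DEFAULT_THRESHOLDS = {
    "detection_p": 0.05,
    "probe_mask_fraction": 0.05,
    "sample_drop_fraction": 0.30,
    "delta_beta": 0.2,
    "q_value": 0.05,
}


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    seed: int = 0
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    classification_mode: str = "fdr_and_delta"
    covariates: tuple[str, ...] = ("age", "sex", "preparation", "slide")
    simulate: dict | None = None          # SimulationConfig overrides, or None
    manifest_args: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # paths when not simulating
    analysis_group: str | None = "treated"  # pairs entering the differential fit
    gene_sets: str | None = None
    enrichment_direction: str = "hyper"
    survival: dict | None = None          # {median_days, censor_rate, n} per group

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        thresholds = dict(DEFAULT_THRESHOLDS)
        thresholds.update(self.thresholds or {})
        self.thresholds = thresholds
        for key, value in self.thresholds.items():
            if not 0.0 <= float(value) <= 1.0:
                raise ConfigError(f"threshold {key}={value} outside [0,1]")
        if self.classification_mode not in CLASSIFICATION_MODES:
            raise ConfigError(
                f"unknown classification mode {self.classification_mode!r}")
        if self.enrichment_direction not in ("hyper", "hypo", "both"):
            raise ConfigError(
                f"unknown enrichment direction {self.enrichment_direction!r}")
        self.covariates = tuple(self.covariates)
        if self.simulate is None and not self.inputs:
            raise ConfigError("config must provide either 'simulate' or 'inputs'")
        for key, path in (self.inputs or {}).items():
            if not Path(path).exists():
                raise ConfigError(f"input {key}={path} does not exist")
        if self.gene_sets is not None and not Path(self.gene_sets).exists():
            raise ConfigError(f"gene_sets file {self.gene_sets} does not exist")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "thresholds": self.thresholds,
            "classification_mode": self.classification_mode,
            "covariates": list(self.covariates),
            "analysis_group": self.analysis_group,
            "simulate": self.simulate,
            "manifest_args": self.manifest_args,
            "inputs": self.inputs,
            "gene_sets": self.gene_sets,
            "enrichment_direction": self.enrichment_direction,
            "survival": self.survival,
        }

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not serialisable: {type(o)}")


def _clean_floats(obj):
    """Replace non-finite floats with strings so JSON stays portable."""
    if isinstance(obj, dict):
        return {k: _clean_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean_floats(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return "NR" if obj > 0 else "-Inf" if obj < 0 else "NaN"
    return obj


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage in fixed order; write stage TSVs and summary.json."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "config_hash": config.hash(),
                     "seed": config.seed}

    stage = "simulate"
    try:
        if config.simulate is not None:
            man_args = dict(n_cpgs=None, n_islands=30, genes_per_chromosome=5)
            man_args.update(config.manifest_args or {})
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            sim = SimulationConfig(**sim_kwargs)
            if man_args["n_cpgs"] is None:
                man_args["n_cpgs"] = sim.n_cpgs
            manifest, islands = generate_manifest(seed=sim.seed, **man_args)
            intensities, sheet, design, truth = generate_paired_cohort(
                manifest, sim, islands)
            from .qc import beta_from_intensities
            beta = beta_from_intensities(intensities)
            detp = intensities.detection_p
            truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t",
                                    index_label="probe_id", float_format="%.10g")
        else:
            inp = config.inputs
            manifest = mio.read_manifest(inp["manifest"])
            islands = mio.read_islands(inp["islands"]) if "islands" in inp else {}
            sheet = mio.read_sample_sheet(inp["sample_sheet"])
            design = mio.read_pairs(inp["pairs"], sheet)
            if "beta" in inp:
                beta = mio.read_beta_matrix(inp["beta"])
                detp = (mio.read_intensities(inp["methylated"], inp["unmethylated"],
                                             inp["detection_p"]).detection_p
                        if "detection_p" in inp else
                        pd.DataFrame(0.0, index=beta.probe_ids,
                                     columns=beta.sample_ids))
            else:
                intensities = mio.read_intensities(
                    inp["methylated"], inp["unmethylated"], inp["detection_p"])
                from .qc import beta_from_intensities
                beta = beta_from_intensities(intensities)
                detp = intensities.detection_p
            truth = None

        stage = "qc"
        th = config.thresholds
        cleaned, qc_report = run_qc(
            beta, detp, manifest, sheet,
            detection_threshold=th["detection_p"],
            probe_mask_fraction=th["probe_mask_fraction"],
            sample_drop_fraction=th["sample_drop_fraction"])
        mio.write_beta_matrix(cleaned, outdir / "beta_clean.tsv")
        (outdir / "qc_report.json").write_text(
            json.dumps(_clean_floats(qc_report.to_dict()), sort_keys=True,
                       indent=1, default=_json_default))
        sheet = sheet.subset([s for s in sheet.sample_ids
                              if s in cleaned.sample_ids])
        design = PairedDesign(tuple(
            p for p in design
            if p.primary_sample_id in cleaned.sample_ids
            and p.followup_sample_id in cleaned.sample_ids))
        summary["qc"] = {
            "n_retained_probes": len(qc_report.retained_probes),
            "n_retained_samples": len(qc_report.retained_samples),
            "dropped_samples": sorted(qc_report.dropped_samples),
        }

        stage = "context"
        assignment = classify_context(manifest, islands)
        assignment.to_csv(outdir / "context_assignments.tsv", sep="\t",
                          index_label="probe_id")

        stage = "differential"
        spec = ModelSpec(covariates=config.covariates)
        diff_design = design
        if config.analysis_group is not None and "group" in sheet.table.columns:
            in_group = tuple(
                p for p in design
                if sheet.table.at[p.primary_sample_id, "group"] == config.analysis_group)
            if in_group:
                diff_design = PairedDesign(in_group)
            else:
                logger.warning("analysis_group %r matches no pairs; using all",
                               config.analysis_group)
        results = run_differential(
            cleaned, sheet, diff_design, spec=spec, mode=config.classification_mode,
            delta_threshold=th["delta_beta"], q_threshold=th["q_value"],
            context_assignment=assignment)
        results.to_csv(outdir / "cpg_results.tsv", sep="\t",
                       index_label="probe_id", float_format="%.6g")
        _, counts = classify_cpgs(results, delta_threshold=th["delta_beta"],
                                  q_threshold=th["q_value"],
                                  mode=config.classification_mode)
        summary["differential"] = counts
        hyper_delta = results.loc[results["direction"] == "hyper", "delta_beta"]
        if len(hyper_delta):
            strat = stratify_by_context(hyper_delta, assignment)
            summary["hyper_context_counts"] = {
                c: int(strat.at[c, "count"]) for c in strat.index}

        stage = "mdi"
        mdi_df = mdi_table(cleaned, design, sheet, assignment)
        mdi_df.to_csv(outdir / "mdi.tsv", sep="\t", float_format="%.6g")
        groups = sorted(mdi_df["group"].unique()) if "group" in mdi_df else []
        summary["mdi"] = {
            "per_group_mean": {g: float(mdi_df.loc[mdi_df["group"] == g, "mdi"].mean())
                               for g in groups}}
        if len(groups) == 2:
            a = mdi_df.loc[mdi_df["group"] == groups[0], "mdi"]
            b = mdi_df.loc[mdi_df["group"] == groups[1], "mdi"]
            comp = compare_mdi_groups(a, b)
            summary["mdi"]["comparison"] = {
                "groups": groups, "statistic": comp["statistic"],
                "p_value": comp["p_value"], "method": comp["method"]}

        stage = "enrichment"
        direction = config.enrichment_direction
        if direction == "both":
            sig = results.index[results["direction"].isin(("hyper", "hypo"))]
        else:
            sig = results.index[results["direction"] == direction]
        if config.gene_sets is not None:
            gene_sets = mio.read_gene_sets(config.gene_sets)
        else:
            gene_sets = _default_gene_sets(manifest, qc_report.retained_probes)
        if gene_sets:
            enr = run_enrichment(manifest, sig, gene_sets,
                                 surviving_probe_ids=qc_report.retained_probes)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", float_format="%.6g")
            top = enr.sort_values(["p_bias_corrected", "set_id"]
                                  if "set_id" in enr.columns else "p_bias_corrected")
            summary["enrichment_top_sets"] = [
                {"set_id": str(i), "p_bias_corrected": float(r["p_bias_corrected"]),
                 "q_value": float(r["q_value"])}
                for i, r in top.head(5).iterrows()]

        stage = "survival"
        if config.survival is not None:
            sv = dict(config.survival)
            if "path" in sv:
                surv = mio.read_survival(sv["path"])
            else:
                frames = []
                for gi, g in enumerate(sv.get("groups", {"treated": {}, "control": {}})):
                    spec_g = sv["groups"][g] if isinstance(sv.get("groups"), dict) else {}
                    frames.append(generate_survival(
                        n=int(spec_g.get("n", sv.get("n", 14))),
                        median_days=float(spec_g.get("median_days",
                                                     sv.get("median_days", 285.0))),
                        censor_rate=float(spec_g.get("censor_rate",
                                                     sv.get("censor_rate", 0.1))),
                        seed=config.seed + 101 + gi, group=g))
                surv = pd.concat(frames, ignore_index=True)
            mio.write_survival(surv, outdir / "survival.csv")
            group_col = "group" if "group" in surv.columns else None
            if group_col:
                estimates = km_by_group(surv, group_col)
            else:
                from .survival import km_estimate
                estimates = {"all": km_estimate(surv["time_days"], surv["event"])}
            summary["km"] = {
                g: {"median_days": est.median,
                    "median_ci": list(est.median_ci),
                    "n": est.n, "n_events": est.n_events}
                for g, est in estimates.items()}

        if truth is not None:
            recovered = set(results.index[results["direction"] != "unchanged"])
            injected = set(truth.drifted.index[truth.drifted])
            tp = len(recovered & injected)
            summary["ground_truth"] = {
                "n_injected": len(injected),
                "n_recovered": len(recovered),
                "recall": tp / len(injected) if injected else float("nan"),
                "precision": tp / len(recovered) if recovered else float("nan"),
            }
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))
    summary_text = json.dumps(_clean_floats(summary), sort_keys=True, indent=1,
                              default=_json_default)
    (outdir / "summary.json").write_text(summary_text + "\n")
    return summary


def _default_gene_sets(manifest, retained_probes, n_sets: int = 5,
                       size: int = 4) -> dict[str, set[str]]:
    """Deterministic gene sets over the manifest's own gene symbols."""
    genes = sorted(set().union(*manifest.table.loc[retained_probes, "genes"])
                   if len(retained_probes) else set())
    if len(genes) < size:
        return {}
    sets = {}
    for i in range(n_sets):
        members = genes[i::n_sets][:size]
        if len(members) >= 2:
            sets[f"SET{i + 1}"] = set(members)
    return sets
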