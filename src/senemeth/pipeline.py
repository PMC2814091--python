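"""End-to-end orchestration: simulate -> preprocess -> contrasts ->
concordance -> enrichment -> integration, with plain-file handoff between
stages and a machine-readable run report.

Every stage writes its outputs as TSV/JSON under the configured output
directory, so any stage can be re-run standalone from the files of the
previous one (and measured data can enter at the preprocess stage).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from senemeth import __version__, io_formats
from senemeth import concordance as conc
from senemeth import diffmeth, enrichment, integration, preprocess
from senemeth import synthetic_data as synth
from senemeth.io_formats import BetaMatrix, StudyDesign

__all__ = ["PipelineConfig", "ConfigError", "validate_config",
           "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


@dataclass
class Thresholds:
    delta: float = diffmeth.DELTA_THRESHOLD
    shared_delta: float = diffmeth.SHARED_DELTA_THRESHOLD
    p: float | None = diffmeth.P_THRESHOLD
    det_alpha: float = 0.01
    max_fail_fraction: float = 0.0
    present_min_fraction: float = integration.PRESENT_MIN_FRACTION
    bins: tuple[float, ...] = integration.DEFAULT_BINS
    min_set_size: int = 2


@dataclass
class Options:
    paired: bool = False
    continuity_correction: bool = False
    skip_normalize: bool = False
    quiet: bool = False


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "senemeth_out"
    simulation: synth.SimulationParams | None = None
    inputs: dict[str, Any] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    options: Options = field(default_factory=Options)

    def validate(self) -> None:
        errors = []
        if self.simulation is None and not self.inputs:
            errors.append("config: either [simulation] or [inputs] required")
        th = self.thresholds
        for key, lo, hi in (("delta", 0.0, 1.0), ("shared_delta", 0.0, 1.0)):
            v = getattr(th, key)
            if not lo < v <= hi:
                errors.append(f"thresholds.{key}: {v} outside ({lo}, {hi}]")
        if th.p is not None and not 0.0 < th.p <= 1.0:
            errors.append(f"thresholds.p: {th.p} outside (0, 1]")
        for key in ("det_alpha", "max_fail_fraction", "present_min_fraction"):
            v = getattr(th, key)
            if not 0.0 <= v <= 1.0:
                errors.append(f"thresholds.{key}: {v} outside [0, 1]")
        edges = list(th.bins)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            errors.append("thresholds.bins: must be strictly increasing")
        if errors:
            raise ConfigError("; ".join(errors))

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "outdir": self.outdir,
            "thresholds": dataclasses.asdict(self.thresholds),
            "options": dataclasses.asdict(self.options),
        }
        d["thresholds"]["bins"] = list(self.thresholds.bins)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            for k, v in sim.items():
                if isinstance(v, tuple):
                    sim[k] = list(v)
            d["simulation"] = sim
        if self.inputs:
            d["inputs"] = dict(self.inputs)
        return d


_INPUT_KEYS = {"beta", "design", "annotation", "gene_sets", "expression",
               "pyro", "detection"}


def _build_config(raw: dict) -> PipelineConfig:
    known = {"seed", "outdir", "simulation", "inputs", "thresholds", "options"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    def section(name: str, cls):
        data = raw.get(name, {})
        if not isinstance(data, dict):
            raise ConfigError(f"{name}: expected a table/mapping")
        fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - fields
        if bad:
            raise ConfigError(f"{name}: unknown keys {sorted(bad)}")
        for key in ("bins",):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        for key in ("mixture_weights", "mixture_means", "n_dm_culture",
                    "n_dm_aging", "effect_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        try:
            return cls(**data)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{name}: {exc}") from exc

    sim = None
    if "simulation" in raw:
        sim = section("simulation", synth.SimulationParams)
    inputs = raw.get("inputs", {})
    if not isinstance(inputs, dict):
        raise ConfigError("inputs: expected a table/mapping")
    bad = set(inputs) - _INPUT_KEYS
    if bad:
        raise ConfigError(f"inputs: unknown keys {sorted(bad)}")
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "senemeth_out")),
        simulation=sim,
        inputs=inputs,
        thresholds=section("thresholds", Thresholds),
        options=section("options", Options),
    )
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a TOML or YAML pipeline configuration file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".toml", ".tml"):
        try:
            raw = tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    else:
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return _build_config(raw)


def validate_config(path: str | Path) -> PipelineConfig:
    """Alias of :func:`load_config` (parse + full validation)."""
    return load_config(path)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _simulate_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    params = cfg.simulation.with_(seed=cfg.seed)
    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(0, 2**31 - 1, size=4)
    annotation, sets = synth.generate_annotation(params)
    beta, design, truth = synth.generate_methylation_study(params)
    expr = synth.generate_expression(
        beta, annotation, slope=params.expression_slope,
        intercept=params.expression_intercept,
        noise_sd=params.expression_noise_sd, seed=int(seeds[0]))
    dm_targets = list(truth.true_positives("culture"))[:6]
    profiles = synth.generate_pyro_profiles(
        beta, annotation,
        target_cpgs=dm_targets if len(dm_targets) >= 2 else None,
        seed=int(seeds[1]))

    fixtures = outdir / "fixtures"
    fixtures.mkdir(parents=True, exist_ok=True)
    io_formats.write_beta_tsv(beta, fixtures / "beta.tsv")
    io_formats.write_design_tsv(design, fixtures / "design.tsv")
    io_formats.write_annotation_tsv(annotation, fixtures / "annotation.tsv")
    io_formats.write_gmt(sets, fixtures / "gene_sets.gmt")
    io_formats.write_expression_tsv(expr, fixtures / "expression.tsv")
    io_formats.write_pyro_csv(profiles, fixtures / "pyro.csv")
    truth.write_tsv(fixtures / "truth.tsv")
    return {"beta": beta, "design": design, "annotation": annotation,
            "sets": sets, "expression": expr, "profiles": profiles,
            "truth": truth}


def _load_stage(cfg: PipelineConfig) -> dict:
    inp = cfg.inputs
    data: dict[str, Any] = {
        "beta": io_formats.read_beta_tsv(inp["beta"]),
        "design": io_formats.read_design_tsv(inp["design"]),
        "annotation": io_formats.read_annotation_tsv(inp["annotation"]),
    }
    sets = io_formats.GeneSetCollection()
    for gmt in inp.get("gene_sets", []):
        for gs in io_formats.read_gmt(gmt).sets.values():
            sets.sets[gs.name] = gs
    data["sets"] = sets
    data["expression"] = (io_formats.read_expression_tsv(inp["expression"])
                          if "expression" in inp else None)
    data["profiles"] = (io_formats.read_pyro_csv(inp["pyro"])
                        if "pyro" in inp else None)
    data["truth"] = None
    return data


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the run report (also written as JSON)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th, opt = cfg.thresholds, cfg.options

    report: dict[str, Any] = {"version": __version__,
                              "config": cfg.to_dict(), "stages": {}}
    with open(outdir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    data = _simulate_stage(cfg, outdir) if cfg.simulation is not None \
        else _load_stage(cfg)
    beta: BetaMatrix = data["beta"]
    design: StudyDesign = data["design"]

    # --- preprocess
    n_in = beta.shape[0]
    beta, removed_missing = preprocess.filter_missing(beta)
    removed_det: list[str] = []
    if cfg.inputs.get("detection"):
        det = preprocess.DetectionMatrix(
            io_formats.read_beta_tsv(cfg.inputs["detection"]).values)
        beta, removed_det = preprocess.filter_by_detection(
            beta, preprocess.DetectionMatrix(
                det.values.loc[beta.cpg_ids, beta.sample_ids]),
            th.det_alpha, th.max_fail_fraction)
    if not opt.skip_normalize:
        beta = preprocess.quantile_normalize(beta)
    io_formats.write_beta_tsv(beta, outdir / "beta_normalized.tsv")
    report["stages"]["preprocess"] = {
        "cpgs_in": n_in,
        "removed_missing": len(removed_missing),
        "removed_detection": len(removed_det),
        "cpgs_retained": beta.shape[0],
    }
    logger.info("preprocess: %d/%d CpGs retained", beta.shape[0], n_in)

    # --- contrasts
    culture_spec = dataclasses.replace(diffmeth.CULTURE_CONTRAST,
                                       paired=opt.paired)
    results = {}
    for spec in (culture_spec, diffmeth.AGING_CONTRAST):
        res = diffmeth.contrast_stats(beta, design, spec)
        diffmeth.classify_dm(res, th.delta, th.p)
        res.write_tsv(outdir / f"contrast_{spec.name}.tsv")
        results[spec.name] = res
        report["stages"][f"contrast_{spec.name}"] = {
            "n_tested": len(res.table),
            "n_hyper": int((res.table["dm_label"] == "hyper").sum()),
            "n_hypo": int((res.table["dm_label"] == "hypo").sum()),
            "delta_threshold": th.delta,
            "p_threshold": th.p,
        }
        logger.info("contrast %s: %d hyper, %d hypo (|delta|>%g, p<=%s)",
                    spec.name,
                    report["stages"][f"contrast_{spec.name}"]["n_hyper"],
                    report["stages"][f"contrast_{spec.name}"]["n_hypo"],
                    th.delta, th.p)
        dm = res.dm_cpgs()
        if len(dm) >= 2:
            tree = diffmeth.hierarchical_cluster(beta.subset_cpgs(dm), "cpgs")
            (outdir / f"cluster_order_{spec.name}.txt").write_text(
                "\n".join(tree.leaf_order) + "\n")

    # --- concordance
    joined = conc.join_contrasts(results["culture"], results["aging"])
    joined.to_csv(outdir / "joined_deltas.tsv", sep="\t",
                  float_format="%.6g")
    selected = conc.select_shared_dm(joined, th.shared_delta)
    stage: dict[str, Any] = {
        "n_joined": len(joined),
        "n_selected_strict": len(conc.select_shared_dm(joined, th.delta)),
        "n_selected": len(selected),
    }
    if len(selected) >= 2:
        cres = conc.concordance_stats(selected, th.shared_delta,
                                      opt.continuity_correction)
        stage.update(cres.to_dict())
        with open(outdir / "concordance.json", "w") as fh:
            json.dump(cres.to_dict(), fh, indent=2)
    subgroups = conc.subgroup_dm_counts(beta, design, culture_spec,
                                        delta_threshold=th.delta)
    stage["subgroup_counts"] = subgroups
    report["stages"]["concordance"] = stage

    # --- enrichment
    universe = enrichment.gene_universe(beta.cpg_ids, data["annotation"])
    collections = {"sets": data["sets"],
                   "bands": enrichment.band_sets(data["annotation"])}
    enr_counts = {}
    for cname, coll in collections.items():
        if not len(coll):
            continue
        frames = []
        for contrast, res in results.items():
            for direction in ("hyper", "hypo"):
                genes = enrichment.genes_from_cpgs(res, data["annotation"],
                                                   direction)
                genes = sorted(set(genes) & universe)
                if not genes:
                    continue
                df = enrichment.overrepresentation(
                    genes, coll, universe,
                    direction=f"{contrast}_{direction}",
                    min_set_size=th.min_set_size)
                frames.append(df)
        if frames:
            import pandas as pd
            table = pd.concat(frames, ignore_index=True)
            table.to_csv(outdir / f"enrichment_{cname}.tsv", sep="\t",
                         index=False, float_format="%.6g")
            enr_counts[cname] = len(table)
    report["stages"]["enrichment"] = {"tables": enr_counts,
                                      "universe_size": len(universe)}

    # --- integration
    if data["expression"] is not None:
        expr = data["expression"]
        retained = integration.present_filter(expr, th.present_min_fraction)
        mapping = integration.match_by_symbol(data["annotation"], expr,
                                              retained)
        istage: dict[str, Any] = {
            "probes_present": len(retained),
            "cpgs_matched": len(mapping),
        }
        if not mapping.empty:
            early = design.samples_where(passage_group="early")
            late = design.samples_where(passage_group="late")
            expr_samples = set(expr.sample_ids)
            e_early = [s for s in early if s in expr_samples]
            e_late = [s for s in late if s in expr_samples]
            if len(e_early) >= 2 and len(e_late) >= 2:
                linked = integration.link_genes(
                    beta, expr, mapping, (early, late), (e_early, e_late))
                linked.drop(columns=["cpg_ids", "probe_ids"]).to_csv(
                    outdir / "linked_genes.tsv", sep="\t",
                    float_format="%.6g")
                summary = integration.methylation_expression_summary(
                    linked, th.bins)
                summary.to_csv(outdir / "expression_by_meth_bin.tsv",
                               sep="\t", float_format="%.6g")
                candidates = list(
                    linked["delta_beta"].abs().sort_values().index[-6:])
                dve = integration.delta_vs_expression(linked, candidates)
                istage.update({
                    "n_linked_genes": len(linked),
                    "delta_expression_correlation": dve["correlation"],
                    "candidate_agreement": dve["agreement_fraction"],
                })
        report["stages"]["integration"] = istage

    if data["profiles"]:
        early = design.samples_where(passage_group="early")
        late = design.samples_where(passage_group="late")
        platform = integration.compare_platforms(beta, data["profiles"],
                                                 (early, late))
        platform["per_cpg"].to_csv(outdir / "platform_comparison.tsv",
                                   sep="\t", float_format="%.6g")
        report["stages"]["platforms"] = {
            "n_targets": len(platform["per_cpg"]),
            "delta_correlation": platform["delta_correlation"],
            "mean_offset": platform["mean_offset"],
        }

    def _jsonsafe(obj):
        if isinstance(obj, dict):
            return {k: _jsonsafe(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonsafe(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            f = float(obj)
            return None if np.isnan(f) else f
        if isinstance(obj, np.integer):
            return int(obj)
        return obj

    report = _jsonsafe(report)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
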