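"""File-mediated analysis pipeline: simulate -> psth -> components ->
validate -> graphpaths -> stats -> report.

Every stage reads its upstream TSV and writes its own output file into
the run directory, so each analysis is independently runnable and
re-runnable (no hidden in-memory state).  All randomness flows from one
master seed.  Re-running with the same config and seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .components import unit_components
from .graphpaths import component_paths, path_rate_correlation
from .psth import build_psth, pooled_mean_rates
from .stats import (category_ks_matrix, category_proportions,
                    nonstationarity_distribution, timing_regression)
from .synthetic import (PopulationSpec, CellSpec, default_population,
                        generate_population, population_config_dict)
from .validation import extract_segment, peakiness, validate_component

logger = logging.getLogger(__name__)

STAGES = ("simulate", "psth", "components", "validate", "graphpaths", "stats",
          "report")
_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Analysis parameters (defaults follow the study conventions)."""

    outdir: str = "psthcomp_run"
    seed: int = 0
    window_ms: float = 50.0
    bin_ms: float = 1.0
    merge_gap: float = 5.0
    min_support: int = 1
    max_scope: str = "row"           # 25% filter reference: row | unit
    peakiness_variant: str = "literal"
    t_test_equal_var: bool = True
    k_paths: int = 3
    epsilon: float = 1e-3
    alpha_levels: tuple[float, ...] = (0.05, 0.01)
    raster_path: str | None = None   # analyse an existing Raster TSV instead
    simulate: dict = field(default_factory=dict)  # population overrides
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.alpha_levels, list):
            cfg.alpha_levels = tuple(cfg.alpha_levels)
        return cfg


def _population_spec(cfg: PipelineConfig) -> PopulationSpec:
    opts = dict(cfg.simulate)
    cells = opts.pop("cells", None)
    n_per_cell = opts.pop("n_units_per_cell", 25)
    stimulus = opts.pop("stimulus", "contact")
    pop = default_population(n_units_per_cell=n_per_cell, stimulus=stimulus,
                             master_seed=cfg.seed)
    if cells is not None:
        pop.cells = [CellSpec(**c) for c in cells]
    for key, val in opts.items():
        if not hasattr(pop, key):
            raise ValueError(f"unknown simulate option {key!r}")
        setattr(pop, key, tuple(val) if isinstance(val, list) else val)
    pop.master_seed = cfg.seed
    return pop


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    pop = _population_spec(cfg)
    rasters, ground_truth, unit_table = generate_population(pop)
    pio.write_rasters(rasters, outdir / "rasters.tsv")
    _write_tsv(ground_truth, outdir / "ground_truth.tsv")
    _write_tsv(unit_table, outdir / "unit_table.tsv")
    (outdir / "population_config.yaml").write_text(
        yaml.safe_dump(_jsonify(population_config_dict(pop)), sort_keys=True),
        encoding="utf-8")
    logger.info("simulate: %d units -> %s", len(rasters), outdir / "rasters.tsv")


def stage_psth(cfg: PipelineConfig, outdir: Path) -> None:
    src = Path(cfg.raster_path) if cfg.raster_path else outdir / "rasters.tsv"
    rasters = pio.read_rasters(src)
    psths = [build_psth(r, window_ms=cfg.window_ms, bin_ms=cfg.bin_ms)
             for r in rasters]
    pio.write_psths(psths, outdir / "psth.tsv")
    logger.info("psth: %d units -> %s", len(psths), outdir / "psth.tsv")


def stage_components(cfg: PipelineConfig, outdir: Path) -> None:
    psths = pio.read_psths(outdir / "psth.tsv", bin_ms=cfg.bin_ms)
    rows = []
    for p in psths:
        cs = unit_components(p, merge_gap=cfg.merge_gap,
                             min_support=cfg.min_support,
                             max_scope=cfg.max_scope)
        if not cs.component_times:
            rows.append({"unit_id": p.unit_id, "layer": p.layer,
                         "condition": p.condition, "stimulus": p.stimulus,
                         "category": cs.category, "component_index": 0,
                         "component_time_ms": np.nan,
                         "supporting_intensities": ""})
        for i, (t, sup) in enumerate(zip(cs.component_times, cs.supports), 1):
            rows.append({"unit_id": p.unit_id, "layer": p.layer,
                         "condition": p.condition, "stimulus": p.stimulus,
                         "category": cs.category, "component_index": i,
                         "component_time_ms": t,
                         "supporting_intensities": ",".join(map(str, sorted(sup)))})
    _write_tsv(pd.DataFrame(rows), outdir / "components.tsv")
    logger.info("components: %d units -> %s", len(psths),
                outdir / "components.tsv")


def stage_validate(cfg: PipelineConfig, outdir: Path) -> None:
    psths = {p.unit_id: p for p in pio.read_psths(outdir / "psth.tsv",
                                                  bin_ms=cfg.bin_ms)}
    comps = pd.read_csv(outdir / "components.tsv", sep="\t")
    rows = []
    for _, c in comps.iterrows():
        if c["component_index"] == 0 or pd.isna(c["component_time_ms"]):
            continue
        pooled = pooled_mean_rates(psths[c["unit_id"]])
        b = int(c["component_time_ms"])
        v_lit = validate_component(pooled, b, variant="literal",
                                   equal_var=cfg.t_test_equal_var)
        v_norm = peakiness(extract_segment(pooled, b), variant="normalized")
        rows.append({"unit_id": c["unit_id"], "component_time_ms": b,
                     "peakiness_literal": v_lit.peakiness,
                     "peakiness_normalized": v_norm,
                     "t": v_lit.t_statistic, "p": v_lit.p_value,
                     "computable_flag": v_lit.computable})
    df = pd.DataFrame(rows, columns=["unit_id", "component_time_ms",
                                     "peakiness_literal", "peakiness_normalized",
                                     "t", "p", "computable_flag"])
    _write_tsv(df, outdir / "validation.tsv")
    logger.info("validate: %d components -> %s", len(df),
                outdir / "validation.tsv")


def stage_graphpaths(cfg: PipelineConfig, outdir: Path) -> None:
    psths = pio.read_psths(outdir / "psth.tsv", bin_ms=cfg.bin_ms)
    path_rows, corr_rows = [], []
    for p in psths:
        paths = component_paths(p, k=cfg.k_paths, epsilon=cfg.epsilon)
        for cp in paths:
            for z, t, rate in cp.per_row:
                path_rows.append({
                    "unit_id": p.unit_id, "layer": p.layer,
                    "condition": p.condition, "stimulus": p.stimulus,
                    "path_rank": cp.rank, "total_weight": cp.total_weight,
                    "median_time_ms": cp.median_time_bin,
                    "nonstationarity_ms": cp.nonstationarity_ms,
                    "row": z, "time_ms": t, "rate_hz": rate,
                })
        for i in range(len(paths)):
            for j in range(i + 1, len(paths)):
                r, pv, ok = path_rate_correlation(paths[i], paths[j])
                corr_rows.append({"unit_id": p.unit_id,
                                  "rank_a": paths[i].rank,
                                  "rank_b": paths[j].rank,
                                  "r": r, "p": pv, "computable_flag": ok})
    _write_tsv(pd.DataFrame(path_rows, columns=[
        "unit_id", "layer", "condition", "stimulus", "path_rank",
        "total_weight", "median_time_ms", "nonstationarity_ms", "row",
        "time_ms", "rate_hz"]), outdir / "paths.tsv")
    _write_tsv(pd.DataFrame(corr_rows, columns=[
        "unit_id", "rank_a", "rank_b", "r", "p", "computable_flag"]),
        outdir / "path_correlations.tsv")
    logger.info("graphpaths -> %s", outdir / "paths.tsv")


def stage_stats(cfg: PipelineConfig, outdir: Path) -> None:
    comps = pd.read_csv(outdir / "components.tsv", sep="\t",
                        dtype={"category": str})
    units = comps.drop_duplicates("unit_id")[
        ["unit_id", "layer", "condition", "stimulus", "category"]]
    report: dict = {"alpha_levels": list(cfg.alpha_levels)}
    report["proportions"] = category_proportions(units).to_dict("records")
    report["category_ks"] = category_ks_matrix(units).to_dict("records")

    # second-on-first timing regressions per (layer, condition, stimulus)
    regressions = []
    multi = comps[comps["component_index"] > 0]
    for keys, sub in multi.groupby(["layer", "condition", "stimulus"],
                                   sort=True):
        pairs = []
        for _, u in sub.groupby("unit_id"):
            times = sorted(u["component_time_ms"].dropna())
            if len(times) >= 2:
                pairs.append((times[0], times[1]))
        if len(pairs) >= 3:
            res = timing_regression([a for a, _ in pairs],
                                    [b for _, b in pairs],
                                    label="/".join(map(str, keys)),
                                    alpha=cfg.alpha_levels[0])
            regressions.append(asdict(res))
    report["timing_regressions"] = regressions

    paths_file = outdir / "paths.tsv"
    if paths_file.exists():
        paths = pd.read_csv(paths_file, sep="\t")
        primary = paths[paths["path_rank"] == 1].drop_duplicates("unit_id")
        if len(primary):
            hist, ks = nonstationarity_distribution(primary)
            report["nonstationarity_hist"] = hist.to_dict("records")
            report["nonstationarity_ks"] = ks.to_dict("records")
        corr_file = outdir / "path_correlations.tsv"
        corr = pd.read_csv(corr_file, sep="\t")
        valid = corr[corr["computable_flag"] == True]  # noqa: E712
        report["path_correlations"] = {
            "n": int(len(valid)),
            "n_significant_positive": int(((valid["p"] < cfg.alpha_levels[0])
                                           & (valid["r"] > 0)).sum()),
            "n_significant_negative": int(((valid["p"] < cfg.alpha_levels[0])
                                           & (valid["r"] < 0)).sum()),
        }

    val_file = outdir / "validation.tsv"
    if val_file.exists():
        val = pd.read_csv(val_file, sep="\t")
        if len(val):
            ok = val[val["computable_flag"] == True]  # noqa: E712
            report["validation_summary"] = {
                "n_components": int(len(val)),
                "frac_peakiness_ge_1.25":
                    float((val["peakiness_literal"] >= 1.25).mean()),
                "frac_peakiness_ge_1.5":
                    float((val["peakiness_literal"] >= 1.5).mean()),
                **{f"frac_ttest_sig_at_{a}": float((ok["p"] < a).mean())
                   for a in cfg.alpha_levels},
            }

    (outdir / "stats_report.json").write_text(
        json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    logger.info("stats -> %s", outdir / "stats_report.json")


def stage_report(cfg: PipelineConfig, outdir: Path) -> None:
    data = json.loads((outdir / "stats_report.json").read_text())
    lines = ["# PSTH component analysis report", ""]
    lines.append("## Category proportions (units with 0/1/2/3+ components)")
    for row in data.get("proportions", []):
        lines.append(
            f"- {row['layer']}/{row['condition']}/{row['stimulus']} "
            f"(n={row['n_units']}): " +
            ", ".join(f"{c}: {row[f'prop_{c}']:.2f}"
                      for c in ("0", "1", "2", "3plus")))
    lines.append("")
    lines.append("## First-vs-second component timing regressions")
    for r in data.get("timing_regressions", []):
        mark = "" if r["significant"] else " #"
        lines.append(f"- {r['label']} (n={r['n']}): intercept "
                     f"{r['intercept']:.3f} ± {r['intercept_se']:.3f}{mark}")
    lines.append("")
    if "validation_summary" in data:
        v = data["validation_summary"]
        lines.append("## Component validation")
        lines.append(f"- {v['n_components']} components; "
                     f"peakiness ≥1.25: {v['frac_peakiness_ge_1.25']:.0%}; "
                     f"≥1.5: {v['frac_peakiness_ge_1.5']:.0%}")
        lines.append("")
    if "nonstationarity_hist" in data:
        lines.append("## Non-stationarity of primary component paths")
        for row in data["nonstationarity_hist"]:
            lines.append(
                f"- {row['layer']}/{row['condition']} (n={row['n_units']}): " +
                ", ".join(f"{b}ms: {row[f'prop_{b}']:.2f}"
                          for b in ("0", "1", "2", "3", "4", "5plus")))
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
    logger.info("report -> %s", outdir / "report.md")


_STAGE_FUNCS = {
    "simulate": stage_simulate, "psth": stage_psth,
    "components": stage_components, "validate": stage_validate,
    "graphpaths": stage_graphpaths, "stats": stage_stats,
    "report": stage_report,
}


def run(cfg: PipelineConfig, stages=None) -> Path:
    """Run the pipeline (all stages by default) into ``cfg.outdir``."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), "INFO"))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    selected = list(STAGES) if stages is None else list(stages)
    unknown = set(selected) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    if cfg.raster_path and "simulate" in selected and stages is None:
        selected.remove("simulate")  # analysing provided data, not simulating
    for name in STAGES:
        if name in selected:
            _STAGE_FUNCS[name](cfg, outdir)
    _write_manifest(cfg, outdir)
    return outdir


def _write_manifest(cfg: PipelineConfig, outdir: Path) -> None:
    checksums = {}
    for f in sorted(outdir.glob("*.tsv")):
        checksums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {
        "config": _jsonify(asdict(cfg)),
        "seed": cfg.seed,
        "psthcomp_version": __version__,
        "versions": {m.__name__: m.__version__
                     for m in _version_modules()},
        "checksums": checksums,
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _version_modules():
    import networkx
    import scipy
    import statsmodels
    return (np, pd, scipy, networkx, statsmodels)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
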