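"""File-based pipeline orchestration: generate -> diff -> enrich -> network -> assoc.

Stages communicate only through tab-separated files in a run directory,
so each stage is independently runnable, resumable and byte-for-byte
reproducible: re-running with an identical resolved configuration
reproduces identical outputs.  The resolved configuration (defaults
merged with the user file) is written alongside the outputs as a YAML
sidecar, and every stage logs the SHA-256 of the inputs it consumed.
"""

from __future__ import annotations

import copy
import difflib
import hashlib
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd

from . import io as mio
from .association import ContingencyTable2x2, associate, load_marker_tables, percent_positive
from .enrichment import enrich_mirna_targets
from .expression import differential_mirnas
from .network import correlation_network, hub_ranking, pathway_synergy_network, tf_synergy_network
from .simulate import SimulationConfig, simulate_annotations, simulate_expression

__all__ = ["DEFAULT_CONFIG", "ConfigError", "PipelineError", "validate_config", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "diff", "enrich", "network", "hubs", "assoc")

#: A stage may only run when all the stages it reads from have run
#: (or their output files already exist in the run directory).
STAGE_DEPENDENCIES: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "diff": ("simulate",),
    "enrich": ("simulate", "diff"),
    "network": ("simulate", "diff", "enrich"),
    "hubs": ("network",),
    "assoc": (),
}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 42,
    "stages": {s: True for s in STAGES},
    "simulate": {
        "n_mirnas": 830,
        "n_pairs": 6,
        "n_up": 40,
        "n_down": 8,
        "effect_log2fc": 1.5,
        "adenoma_effect_fraction": 0.5,
        "noise_sd": 0.3,
        "corr_strength": 0.8,
        "n_genes": 400,
        "n_pathways": 20,
    },
    "diff": {
        "class_a": "normal",
        "class_b": "carcinoma",
        "fc_threshold": 1.0,
        "alpha": 0.05,
        "adjust": "none",
    },
    "enrich": {"p_threshold": 0.05, "kappa_threshold": 0.3},
    "network": {"min_abs_r": 0.7, "method": "pearson", "tissue_class": "normal"},
    "assoc": {"test": "fisher", "level": 0.95},
}


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` lists every failure."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _check_value(section: str, key: str, value: Any, errors: list[str]) -> None:
    positive = {"n_mirnas", "n_pairs", "n_genes", "n_pathways"}
    nonneg = {"n_up", "n_down", "effect_log2fc", "noise_sd", "fc_threshold"}
    unit = {"alpha", "corr_strength", "min_abs_r", "p_threshold", "level",
            "adenoma_effect_fraction"}
    name = f"{section}.{key}"
    if key in positive and (not isinstance(value, int) or value <= 0):
        errors.append(f"{name} must be a positive integer, got {value!r}")
    elif key in nonneg and (not isinstance(value, (int, float)) or value < 0):
        errors.append(f"{name} must be non-negative, got {value!r}")
    elif key in unit and (not isinstance(value, (int, float)) or not 0 <= value <= 1):
        errors.append(f"{name} must lie in [0, 1], got {value!r}")
    elif key == "adjust" and value not in ("none", "holm", "bh"):
        errors.append(f"{name} must be one of none/holm/bh, got {value!r}")
    elif key == "method" and value not in ("pearson", "spearman"):
        errors.append(f"{name} must be pearson or spearman, got {value!r}")
    elif key == "test" and value not in ("fisher", "chi2", "chi2_yates"):
        errors.append(f"{name} must be fisher/chi2/chi2_yates, got {value!r}")


def validate_config(path: str | Path | None = None,
                    overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    """Merge a YAML config file over the defaults and validate it.

    Unknown keys are reported by name with a closest-match suggestion;
    all validation failures are collected into one :class:`ConfigError`
    rather than stopping at the first.  An empty (or absent) file yields
    the pure defaults.
    """
    user: dict[str, Any] = {}
    if path is not None:
        user = mio.read_yaml_config(path)
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict):
                user.setdefault(key, {}).update(val)
            else:
                user[key] = val

    config = copy.deepcopy(DEFAULT_CONFIG)
    errors: list[str] = []
    for key, val in user.items():
        if key not in config:
            hint = difflib.get_close_matches(key, list(config), n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown key {key!r}{suggestion}")
            continue
        if key == "seed":
            if not isinstance(val, int):
                errors.append(f"seed must be an integer, got {val!r}")
            else:
                config["seed"] = val
            continue
        if not isinstance(val, dict):
            errors.append(f"section {key!r} must be a mapping, got {val!r}")
            continue
        for sub, subval in val.items():
            if sub not in config[key]:
                hint = difflib.get_close_matches(sub, list(config[key]), n=1)
                suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
                errors.append(f"unknown key {key}.{sub!r}{suggestion}")
                continue
            if key == "stages":
                if not isinstance(subval, bool):
                    errors.append(f"stages.{sub} must be boolean, got {subval!r}")
                    continue
            else:
                _check_value(key, sub, subval, errors)
            config[key][sub] = subval
    if errors:
        raise ConfigError(errors)
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _require(outdir: Path, stage: str, dependency: str, filenames: list[str]) -> list[Path]:
    paths = [outdir / f for f in filenames]
    missing = [p.name for p in paths if not p.exists()]
    if missing:
        raise PipelineError(
            f"stage {stage!r} requires outputs of stage {dependency!r} "
            f"(missing: {', '.join(missing)})"
        )
    return paths


def _log_stage(stage: str, t0: float, inputs: list[Path]) -> None:
    hashes = " ".join(f"{p.name}={_sha256(p)}" for p in inputs)
    log.info("stage=%s wall_time=%.2fs inputs[%s]", stage, time.perf_counter() - t0, hashes)


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> Path:
    """Execute the enabled stages in dependency order into ``outdir``.

    Returns the run directory.  A failing stage aborts the run with a
    :class:`PipelineError` naming the stage, and leaves an INCOMPLETE
    marker file listing it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    marker = outdir / "INCOMPLETE"
    mio.write_yaml_config(config, outdir / "config.yaml")

    current = "?"
    try:
        for stage in STAGES:
            if not stages.get(stage, False):
                continue
            current = stage
            marker.write_text(stage + "\n")
            t0 = time.perf_counter()
            if stage == "simulate":
                _stage_simulate(config, outdir)
                _log_stage(stage, t0, [outdir / "config.yaml"])
            elif stage == "diff":
                inputs = _require(outdir, stage, "simulate", ["expression.tsv", "samples.tsv"])
                _stage_diff(config, outdir)
                _log_stage(stage, t0, inputs)
            elif stage == "enrich":
                inputs = _require(outdir, stage, "simulate", ["targets.tsv", "pathways.gmt"])
                inputs += _require(outdir, stage, "diff", ["diff_table.tsv"])
                _stage_enrich(config, outdir)
                _log_stage(stage, t0, inputs)
            elif stage == "network":
                inputs = _require(outdir, stage, "enrich", ["enrichment.tsv"])
                inputs += _require(outdir, stage, "simulate",
                                   ["expression.tsv", "samples.tsv", "tfs.tsv"])
                _stage_network(config, outdir)
                _log_stage(stage, t0, inputs)
            elif stage == "hubs":
                inputs = _require(outdir, stage, "network", ["network_pathway.graphml"])
                _stage_hubs(outdir)
                _log_stage(stage, t0, inputs)
            elif stage == "assoc":
                _stage_assoc(config, outdir)
                _log_stage(stage, t0, [])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc
    marker.unlink(missing_ok=True)
    return outdir


def _stage_simulate(config: dict[str, Any], outdir: Path) -> None:
    sim = config["simulate"]
    sim_config = SimulationConfig(
        n_mirnas=sim["n_mirnas"], n_pairs=sim["n_pairs"], n_up=sim["n_up"],
        n_down=sim["n_down"], effect_log2fc=sim["effect_log2fc"],
        adenoma_effect_fraction=sim["adenoma_effect_fraction"],
        noise_sd=sim["noise_sd"], corr_strength=sim["corr_strength"],
        seed=config["seed"],
    )
    expr = simulate_expression(sim_config)
    mio.write_expression(expr, outdir / "expression.tsv", outdir / "samples.tsv")
    bundle = simulate_annotations(
        sim_config, n_genes=sim["n_genes"], n_pathways=sim["n_pathways"], seed=config["seed"]
    )
    mio.write_target_map(bundle.target_map, outdir / "targets.tsv")
    mio.write_gmt(bundle.pathway_db, outdir / "pathways.gmt")
    mio.write_tf_map(bundle.tf_map, outdir / "tfs.tsv")


def _stage_diff(config: dict[str, Any], outdir: Path) -> None:
    expr = mio.read_expression(outdir / "expression.tsv", outdir / "samples.tsv")
    table = differential_mirnas(expr, **config["diff"])
    table.to_csv(outdir / "diff_table.tsv", sep="\t", index=False)


def _deregulated(outdir: Path) -> set[str]:
    diff = pd.read_csv(outdir / "diff_table.tsv", sep="\t")
    return set(diff.loc[diff["call"] != "ns", "mirna"])


def _stage_enrich(config: dict[str, Any], outdir: Path) -> None:
    targets = mio.read_target_map(outdir / "targets.tsv")
    pathways = mio.read_gmt(outdir / "pathways.gmt")
    dereg = _deregulated(outdir)
    selected = {m: t for m, t in targets.items() if m in dereg}
    if not selected:
        raise PipelineError("stage 'enrich' failed: no deregulated miRNA has target annotation")
    table = enrich_mirna_targets(selected, pathways,
                                 p_threshold=config["enrich"]["p_threshold"])
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)


def _stage_network(config: dict[str, Any], outdir: Path) -> None:
    net_cfg = config["network"]
    enrichment = pd.read_csv(outdir / "enrichment.tsv", sep="\t")
    pathway_net = pathway_synergy_network(enrichment)
    mio.write_network(pathway_net, outdir / "network_pathway.graphml", "graphml")
    mio.write_network(pathway_net, outdir / "network_pathway.tsv", "edgelist")

    tf_map = mio.read_tf_map(outdir / "tfs.tsv")
    mirnas = sorted(enrichment["mirna"].unique())
    tf_net = tf_synergy_network(tf_map, mirnas)
    mio.write_network(tf_net, outdir / "network_tf.graphml", "graphml")
    mio.write_network(tf_net, outdir / "network_tf.tsv", "edgelist")

    expr = mio.read_expression(outdir / "expression.tsv", outdir / "samples.tsv")
    corr_net = correlation_network(
        expr, tissue_class=net_cfg["tissue_class"], method=net_cfg["method"],
        min_abs_r=net_cfg["min_abs_r"],
    )
    mio.write_network(corr_net, outdir / "network_correlation.graphml", "graphml")
    mio.write_network(corr_net, outdir / "network_correlation.tsv", "edgelist")


def _stage_hubs(outdir: Path) -> None:
    net = mio.read_network_graphml(outdir / "network_pathway.graphml")
    ranking = hub_ranking(net)
    pd.DataFrame(ranking, columns=["mirna", "hub_score"]).to_csv(
        outdir / "hub_ranking.tsv", sep="\t", index=False
    )


def _stage_assoc(config: dict[str, Any], outdir: Path) -> None:
    rows = []
    for marker, table in load_marker_tables().items():
        res = associate(table, test=config["assoc"]["test"], level=config["assoc"]["level"])
        rows.append(
            {
                "marker": marker,
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "pct_a": percent_positive(table.a, table.n),
                "odds_ratio": round(res.odds_ratio, 2),
                "ci_low": round(res.ci_low, 2),
                "ci_high": round(res.ci_high, 2),
                "p_value": res.p_value,
                "method": res.method,
                "test": res.test,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "association.tsv", sep="\t", index=False)
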