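"""End-to-end orchestration: preprocess -> GARCH -> PIT -> R-vine -> network,
with the spectral-Granger baseline, per task condition.

One threshold is shared across conditions: the degree curves K(t) of the
individual condition networks are averaged before the K >= 2 ln N rule is
applied.  Every artifact (tau heatmap matrix, vine JSON, tree-1 summary,
threshold curve, binary networks, metrics, GC baseline) is written as
plain text (TSV/JSON/DOT) plus a run manifest recording versions, seed and
every selection the pipeline made.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .copulas import DEFAULT_FAMILIES
from .garch import ArGjrGarch
from .granger import gc_matrix
from .network import (
    ConnectivityGraph,
    graph_metrics,
    normalize_blocks,
    select_threshold_from_curve,
    tau_matrix,
    threshold_select,
)
from .preproc import ChannelMatrix, PreprocConfig, epoch_trials, load_signals, preprocess
from .rvine import build_rvine

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("vinecmc")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage and condition context."""


@dataclass
class RunConfig:
    conditions: dict  # condition name -> input CSV/TSV/EDF path or ChannelMatrix
    manifest: object = None  # mapping id -> modality, or YAML path
    fs: float = 1000.0
    preproc: PreprocConfig | None = None
    apply_preproc: bool = True
    epoch_length: int | None = None
    epoch_onsets: list | None = None
    candidates: tuple = DEFAULT_FAMILIES
    criterion: str = "aic"
    trunc_level: int | None = None
    threshold_step: float = 0.05
    gc_band: tuple = (8.0, 30.0)
    gc_max_order: int = 20
    run_gc: bool = True
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("at least one task condition is required")
        if not 0.0 < self.threshold_step <= 0.5:
            raise ValueError("threshold step must be in (0, 0.5]")


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f)
    pp = raw.pop("preproc", None)
    cfg = RunConfig(**raw)
    if pp:
        cfg.preproc = PreprocConfig(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in pp.items()
            }
        )
    return cfg


def _condition_matrix(cfg: RunConfig, name, source) -> ChannelMatrix:
    if isinstance(source, ChannelMatrix):
        return source
    if cfg.manifest is None:
        raise PipelineError(f"condition {name}: file input requires a manifest")
    return load_signals(source, cfg.manifest, fs=cfg.fs)


def _pit_matrix(cm: ChannelMatrix, cfg: RunConfig, name: str):
    """Fit the marginal model per channel per epoch and concatenate the PIT
    series across epochs (dependence estimation pools trials)."""
    if cfg.epoch_onsets is not None and cfg.epoch_length:
        epochs = epoch_trials(cm, cfg.epoch_onsets, cfg.epoch_length)
    else:
        epochs = [cm]
    cols = []
    margins = []
    for ch in range(cm.n_channels):
        pits = []
        recs = []
        for ep in epochs:
            x = ep.data[ch]
            if np.ptp(x) == 0:
                raise PipelineError(
                    f"condition {name}: constant channel {cm.channel_ids[ch]}"
                )
            res = ArGjrGarch(x).fit(compute_bse=False)
            if not res.converged:
                log.warning(
                    "condition %s channel %s: GARCH fit did not converge",
                    name,
                    cm.channel_ids[ch],
                )
            pits.append(res.pit())
            recs.append(res.to_dict())
        cols.append(np.concatenate(pits))
        margins.append({"channel": cm.channel_ids[ch], "epochs": recs})
    return np.column_stack(cols), margins


def _write_tsv(path, M, labels):
    pd.DataFrame(M, index=labels, columns=labels).to_csv(path, sep="\t")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns (and optionally writes) all artifacts.

    The returned dict maps condition name -> per-condition results plus the
    shared ``threshold``, ``degree_curve`` and a ``manifest`` record.
    """
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    per_cond = {}
    stage = "load"
    try:
        for name, source in cfg.conditions.items():
            stage = f"load[{name}]"
            cm = _condition_matrix(cfg, name, source)
            if cfg.apply_preproc:
                stage = f"preprocess[{name}]"
                cm = preprocess(cm, cfg.preproc)
            stage = f"garch[{name}]"
            U, margins = _pit_matrix(cm, cfg, name)
            stage = f"tau[{name}]"
            tau = tau_matrix(U)
            stage = f"vine[{name}]"
            vine = build_rvine(
                U,
                candidates=cfg.candidates,
                criterion=cfg.criterion,
                trunc_level=cfg.trunc_level,
            )
            Wn = normalize_blocks(tau, cm.modalities)
            per_cond[name] = {
                "cm": cm,
                "U": U,
                "margins": margins,
                "tau": tau,
                "Wn": Wn,
                "vine": vine,
                "tree1": vine.first_tree_summary(
                    modalities=cm.modalities, labels=cm.channel_ids
                ),
            }
            if cfg.run_gc:
                stage = f"granger[{name}]"
                D = gc_matrix(
                    cm.data, fs=cm.fs, band=cfg.gc_band, max_order=cfg.gc_max_order
                )
                Wgc = np.maximum(D, D.T)
                per_cond[name]["gc_directed"] = D
                per_cond[name]["gc_Wn"] = normalize_blocks(Wgc, cm.modalities)

        stage = "threshold"
        thr, curve, sd = threshold_select(
            [per_cond[n]["Wn"] for n in per_cond], step=cfg.threshold_step
        )
        results = {
            "threshold": thr,
            "degree_curve": curve,
            "degree_sd": sd,
            "conditions": {},
        }
        for name, d in per_cond.items():
            stage = f"network[{name}]"
            cm = d["cm"]
            g = ConnectivityGraph.build(
                d["tau"], cm.modalities, thr, node_labels=cm.channel_ids
            )
            entry = {
                "tau": d["tau"],
                "Wn": d["Wn"],
                "vine": d["vine"],
                "tree1": d["tree1"],
                "network": g,
                "metrics": g.metrics,
                "margins": d["margins"],
            }
            if cfg.run_gc:
                gc_thr = select_threshold_from_curve(
                    threshold_select([d["gc_Wn"]], step=cfg.threshold_step)[1],
                    cm.n_channels,
                )
                ggc = ConnectivityGraph.build(
                    np.maximum(d["gc_directed"], d["gc_directed"].T),
                    cm.modalities,
                    gc_thr,
                    node_labels=cm.channel_ids,
                )
                entry["gc_network"] = ggc
                entry["gc_metrics"] = ggc.metrics
            results["conditions"][name] = entry
    except Exception as err:
        if out_dir:
            (out_dir / "FAILED").write_text(f"stage {stage}: {err}\n")
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(f"stage {stage}: {err}") from err

    results["manifest"] = {
        "vinecmc_version": __version__,
        "seed": cfg.seed,
        "criterion": cfg.criterion,
        "candidates": list(cfg.candidates),
        "threshold_step": cfg.threshold_step,
        "threshold": thr,
        "conditions": list(cfg.conditions),
        "gc_band": list(cfg.gc_band),
    }

    if out_dir:
        _write_artifacts(results, out_dir)
    return results


def _metrics_json(m):
    return {
        "L": m["L"],
        "C": m["C"],
        "C_i": np.asarray(m["C_i"]).tolist(),
        "K_i": np.asarray(m["K_i"]).tolist(),
        "n_disconnected_pairs": m["n_disconnected_pairs"],
    }


def _write_artifacts(results, out_dir: Path):
    (out_dir / "run_manifest.json").write_text(
        json.dumps(results["manifest"], indent=2, sort_keys=True) + "\n"
    )
    curve = {
        "threshold": results["threshold"],
        "K": results["degree_curve"],
        "K_sd": results["degree_sd"],
    }
    (out_dir / "threshold_curve.json").write_text(
        json.dumps(curve, indent=2, sort_keys=True) + "\n"
    )
    for name, d in results["conditions"].items():
        g = d["network"]
        labels = g.node_labels
        _write_tsv(out_dir / f"{name}_tau.tsv", d["tau"], labels)
        _write_tsv(out_dir / f"{name}_Wn.tsv", d["Wn"], labels)
        _write_tsv(out_dir / f"{name}_adjacency.tsv", g.A, labels)
        (out_dir / f"{name}_vine.json").write_text(d["vine"].model.to_json() + "\n")
        (out_dir / f"{name}_tree1.json").write_text(
            json.dumps(d["tree1"], indent=2, default=str) + "\n"
        )
        (out_dir / f"{name}_tree1.dot").write_text(
            d["vine"].model.tree1_dot(labels) + "\n"
        )
        (out_dir / f"{name}_network.dot").write_text(g.to_dot() + "\n")
        payload = {"metrics": _metrics_json(d["metrics"])}
        if "gc_metrics" in d:
            payload["gc_metrics"] = _metrics_json(d["gc_metrics"])
        (out_dir / f"{name}_metrics.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
    log.info("artifacts written to %s", out_dir)
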