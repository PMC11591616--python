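"""File formats, run configuration and the pipeline driver.

Evoked ERPs travel as delimited text (one header row of channel labels,
one row per sample, µV) with a JSON sidecar carrying the metadata
(sfreq, t0_ms, subject_id, language, embodiment, units).  Montages are
whitespace-delimited ``label x y z`` lines.  All times written to output
files are milliseconds relative to stimulus onset; sample indexing is
0-based and windows are half-open [start, end).

A run is described by a strict YAML config; every run writes the fully
resolved config next to its outputs so the directory is self-describing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth
from .preprocess import PreprocParams
from .segmentation import SegmentationParams, SegmentationResult, _runs
from .stats import FullAnalysisResult, run_full_analysis
from .topography import EvokedERP, Montage

__all__ = [
    "read_erp_matrix",
    "write_erp_matrix",
    "read_montage",
    "write_montage",
    "RunConfig",
    "load_config",
    "run_pipeline",
    "segmentation_to_json",
]

logger = logging.getLogger(__name__)

_SIDECAR_KEYS = {"sfreq", "t0_ms", "subject_id", "language", "embodiment", "units"}
_UNIT_SCALE = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6}


def write_erp_matrix(erp: EvokedERP, path: str | Path, sidecar_path: str | Path) -> None:
    path = Path(path)
    labels = (
        erp.montage.labels
        if erp.montage is not None
        else tuple(f"E{i + 1:03d}" for i in range(erp.n_channels))
    )
    df = pd.DataFrame(erp.data.T, columns=list(labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "sfreq": erp.sfreq,
        "t0_ms": erp.t0_ms,
        "subject_id": erp.subject_id,
        "language": erp.language,
        "embodiment": erp.embodiment,
        "units": "uV",
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_erp_matrix(
    path: str | Path, sidecar_path: str | Path, montage: Montage | None = None
) -> EvokedERP:
    """Read a delimited ERP matrix + JSON sidecar into an EvokedERP.

    Values declared in other units are converted to µV.  Non-numeric
    cells and montage/header mismatches raise specific errors naming
    the offending location.
    """
    path = Path(path)
    sidecar = json.loads(Path(sidecar_path).read_text())
    missing = _SIDECAR_KEYS - sidecar.keys()
    if missing:
        raise ValueError(f"sidecar {sidecar_path} missing keys: {sorted(missing)}")
    units = sidecar["units"]
    if units not in _UNIT_SCALE:
        raise ValueError(f"unknown units {units!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    labels = tuple(df.columns)
    if montage is not None and labels != montage.labels:
        raise ValueError(f"{path}: header does not match the montage labels")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for r in range(df.shape[0]):
            for c, col in enumerate(df.columns):
                try:
                    float(df.iat[r, c])
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {r}, column {col!r}"
                    ) from None
        raise
    return EvokedERP(
        data=values.T * _UNIT_SCALE[units],
        sfreq=float(sidecar["sfreq"]),
        t0_ms=float(sidecar["t0_ms"]),
        subject_id=str(sidecar["subject_id"]),
        language=sidecar["language"],
        embodiment=sidecar["embodiment"],
        montage=montage,
    )


def write_montage(montage: Montage, path: str | Path) -> None:
    lines = [
        f"{lab}\t{x:.9f}\t{y:.9f}\t{z:.9f}"
        for lab, (x, y, z) in zip(montage.labels, montage.positions)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_montage(path: str | Path) -> Montage:
    """Read ``label x y z`` lines; positions off the unit sphere by more
    than 1e-3 are renormalized with a warning."""
    labels, positions = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"montage line {ln}: expected 'label x y z'")
        labels.append(parts[0])
        positions.append([float(v) for v in parts[1:]])
    if len(labels) < 8:
        raise ValueError("montage must have at least 8 channels")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels in montage")
    pos = np.asarray(positions)
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length electrode position")
    if np.any(np.abs(norms - 1.0) > 1e-3):
        logger.warning("montage positions off the unit sphere; renormalizing")
    pos = pos / norms[:, None]
    return Montage(labels=tuple(labels), positions=pos)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "seed",
    "out_dir",
    "input_dir",
    "log_level",
    "simulate",
    "preprocess",
    "segmentation",
    "backfit",
}
_SIM_KEYS = {
    "n_subjects",
    "n_channels",
    "sfreq",
    "epoch_ms",
    "subject_sd",
    "rho",
    "noise_sd",
    "noise_spatial_smooth",
}
_SEG_KEYS = {"k_max", "min_segment_ms", "analysis_window_ms", "criteria"}
_PRE_KEYS = {"band", "filter_order", "epoch_ms", "baseline_ms", "reject_peak_to_peak_uV"}
_FIT_KEYS = {"fit_scope"}


class RunConfig:
    """Validated run configuration (strict: unknown keys rejected)."""

    def __init__(self, raw: dict):
        _check_keys(raw, _TOP_KEYS, "top level")
        self.seed = int(raw.get("seed", 0))
        self.out_dir = Path(raw.get("out_dir", "topomicro_out"))
        self.input_dir = Path(raw["input_dir"]) if "input_dir" in raw else None
        self.log_level = str(raw.get("log_level", "INFO"))
        sim = raw.get("simulate")
        if sim is not None:
            _check_keys(sim, _SIM_KEYS, "simulate")
            sim = dict(sim)
            if "epoch_ms" in sim:
                sim["epoch_ms"] = tuple(sim["epoch_ms"])
            self.simulate = synth.SynthConfig(seed=self.seed, **sim)
        else:
            self.simulate = None
        pre = dict(raw.get("preprocess") or {})
        _check_keys(pre, _PRE_KEYS, "preprocess")
        for key in ("band", "epoch_ms", "baseline_ms"):
            if key in pre:
                pre[key] = tuple(pre[key])
        self.preprocess = PreprocParams(**pre)
        seg = dict(raw.get("segmentation") or {})
        _check_keys(seg, _SEG_KEYS, "segmentation")
        for key in ("analysis_window_ms", "criteria"):
            if key in seg:
                seg[key] = tuple(seg[key])
        self.segmentation = SegmentationParams(**seg)
        fit = dict(raw.get("backfit") or {})
        _check_keys(fit, _FIT_KEYS, "backfit")
        self.fit_scope = fit.get("fit_scope", "epoch")

    def resolved(self) -> dict:
        out: dict = {
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "log_level": self.log_level,
            "segmentation": _plain(asdict(self.segmentation)),
            "preprocess": _plain(asdict(self.preprocess)),
            "backfit": {"fit_scope": self.fit_scope},
        }
        if self.input_dir is not None:
            out["input_dir"] = str(self.input_dir)
        if self.simulate is not None:
            sim = asdict(self.simulate)
            sim.pop("effect_multipliers")
            out["simulate"] = _plain(sim)
        return out


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys at {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return RunConfig(raw)


# ---------------------------------------------------------------------------
# Serialization of results
# ---------------------------------------------------------------------------


def segmentation_to_json(result: SegmentationResult) -> dict:
    """SegmentationResult as a JSON-ready dict.

    Templates as channel-ordered number lists; labels run-length encoded
    as half-open spans in ms per condition.
    """
    frames = result.frames
    spans = {}
    for ci, cell in enumerate(frames.cells):
        sel = frames.condition == ci
        labels = result.labels[sel]
        t = frames.time_ms[sel]
        dt = 1000.0 / frames.sfreq
        cell_spans = [
            {"map_id": lab, "t_start_ms": float(t[a]), "t_end_ms": float(t[b - 1] + dt)}
            for lab, a, b in _runs(labels)
            if lab >= 0
        ]
        spans["/".join(cell)] = cell_spans
    sol = result.solutions[result.selected_k]
    return {
        "selected_k": result.selected_k,
        "gev_total": sol.gev_total,
        "gev_total_constrained": result.gev_total_constrained,
        "criterion_scores": {
            name: {str(k): v for k, v in scores.items()}
            for name, scores in result.criterion_scores.items()
        },
        "templates": [
            {"map_id": t.map_id, "vector": [float(v) for v in t.vector]}
            for t in sol.templates
        ],
        "segments": spans,
    }


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def _load_erps_from_dir(input_dir: Path) -> list[EvokedERP]:
    erps = []
    for matrix in sorted(input_dir.glob("*.tsv")):
        sidecar = matrix.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar for {matrix}")
        erps.append(read_erp_matrix(matrix, sidecar))
    if not erps:
        raise FileNotFoundError(f"no .tsv ERP matrices in {input_dir}")
    return erps


def run_pipeline(config: RunConfig) -> FullAnalysisResult:
    """Execute simulate (optional) → analyze → write artifacts.

    Writes segmentation.json, backfit.tsv, anova.tsv, the resolved
    config and a structured log with stage timings under
    ``config.out_dir``.  Raises with a stage-tagged message on failure.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    stage_log: list[dict] = []

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"[stage: {name}] {exc}") from exc
        stage_log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
        return result

    if config.simulate is not None:
        dataset = _stage("simulate", lambda: synth.simulate_dataset(config.simulate))
        erps = list(dataset.erps)
        truth = {
            "seed": config.seed,
            "multipliers": [
                {"map_id": mid, "cell": list(cell), "multiplier": mult}
                for (mid, cell), mult in dataset.multipliers.items()
            ],
            "timeline": [asdict(e) for e in dataset.timeline.entries],
            "templates": [
                {"map_id": t.map_id, "vector": [float(v) for v in t.vector]}
                for t in dataset.timeline.templates
            ],
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    elif config.input_dir is not None:
        erps = _stage("load", lambda: _load_erps_from_dir(config.input_dir))
    else:
        raise RuntimeError("[stage: load] config needs 'simulate' or 'input_dir'")

    result = _stage(
        "analyze",
        lambda: run_full_analysis(erps, config.segmentation, fit_scope=config.fit_scope),
    )
    _stage(
        "write",
        lambda: _write_artifacts(result, config, out, stage_log),
    )
    return result


def _write_artifacts(
    result: FullAnalysisResult, config: RunConfig, out: Path, stage_log: list[dict]
) -> None:
    (out / "segmentation.json").write_text(
        json.dumps(segmentation_to_json(result.segmentation), indent=1)
    )
    result.backfit.to_csv(out / "backfit.tsv", sep="\t", index=False)
    result.anova.to_csv(out / "anova.tsv", sep="\t", index=False)
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(config.resolved()))
    (out / "run_log.json").write_text(json.dumps({"stages": stage_log}, indent=1))
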