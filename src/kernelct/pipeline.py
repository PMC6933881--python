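"""End-to-end pipeline: simulate -> segment -> measure -> analyse.

One :class:`PipelineConfig` drives the whole chain with a single integer
seed; rerunning with the same config and seed reproduces every CSV byte
for byte. Outputs per run: the simulated cohort's volumes and truth labels
(optional), predicted labels, a one-row-per-kernel morphometry CSV, the
correlation screen, the stepwise report and the path-coefficient table,
plus a JSON manifest echoing the config, seed, package version and
per-stage voxel counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, morphometry, phantom, stats
from .phantom import CohortDesign, KernelPhantomSpec
from .segmentation import KernelSegmenter, SegmentationConfig

__all__ = ["PipelineConfig", "run_pipeline", "stats_report"]


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    output_dir: Path = Path("kernelct_run")
    cohort: CohortDesign = field(default_factory=CohortDesign)
    phantom_template: KernelPhantomSpec = field(default_factory=KernelPhantomSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    response: str = "BR"
    alpha_in: float = 0.05
    alpha_out: float = 0.05
    rng_seed: int = 0
    write_volumes: bool = False
    use_truth_grey_levels: bool = True

    def config_hash(self) -> str:
        # paths excluded: the hash identifies the scientific configuration,
        # not where its outputs land
        payload = {k: v for k, v in _jsonable(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write_csv(df: pd.DataFrame, path: Path, header_comment: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        fh.write(header_comment)
        df.to_csv(fh)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain and return a manifest of what was produced.

    Stage failures abort with the stage name and kernel id in the message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = dataclasses.replace(config.cohort, rng_seed=config.rng_seed)
    header = f"# kernelct {__version__} seed={config.rng_seed} config={config.config_hash()}\n"

    phantoms, cohort_truth = phantom.generate_cohort(
        design, phantom_template=config.phantom_template
    )

    seg_cfg = dataclasses.replace(config.segmentation)
    if config.use_truth_grey_levels:
        seg_cfg.threshold_method = "midpoint"
        seg_cfg.grey_levels = dict(config.phantom_template.grey_levels)
        seg_cfg.coat_thickness_mm = config.phantom_template.coat_thickness_mm
    segmenter = KernelSegmenter(**{k: getattr(seg_cfg, k) for k in vars(seg_cfg)})

    rows = []
    stage_counts = []
    for (vol, truth), (_, meta) in zip(phantoms, cohort_truth.iterrows()):
        kid = f"{meta['variety']}_r{int(meta['replicate'])}"
        try:
            pred = segmenter.segment(vol)
        except Exception as exc:  # noqa: BLE001 - annotate stage + kernel
            raise RuntimeError(f"segmentation failed for kernel {kid}: {exc}") from exc
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params = morphometry.compute_all_parameters(pred, truth.mass_mg)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"morphometry failed for kernel {kid}: {exc}") from exc
        row = {"variety": meta["variety"], "replicate": int(meta["replicate"])}
        row.update(params.as_dict())
        row["BR"] = meta["BR"]
        rows.append(row)
        stage_counts.append({
            "kernel": kid,
            "foreground_vox": int(pred.grain_mask.sum()),
            "cavity_vox": int(np.isin(pred.labels, (4, 5, 6)).sum()),
        })
        if config.write_volumes:
            io.write_volume(vol, out / "volumes" / f"{kid}.tif")
            io.write_labels(truth.label_volume, out / "truth" / f"{kid}.tif")
            io.write_labels(pred, out / "labels" / f"{kid}.tif")

    measured = pd.DataFrame(rows).set_index(["variety", "replicate"])
    _write_csv(measured, out / "morphometry.csv", header)
    _write_csv(cohort_truth.set_index(["variety", "replicate"]),
               out / "cohort_truth.csv", header)

    report = stats_report(
        measured.reset_index(), response=config.response,
        alpha_in=config.alpha_in, alpha_out=config.alpha_out,
    )
    _write_csv(report["correlations"], out / "correlations.csv", header)
    _write_csv(report["path_table"], out / "path_coefficients.csv", header)
    with (out / "stepwise.json").open("w") as fh:
        json.dump(report["stepwise"], fh, indent=2, sort_keys=True)

    manifest = {
        "version": __version__,
        "seed": config.rng_seed,
        "config_hash": config.config_hash(),
        "config": _jsonable(config),
        "n_kernels": len(rows),
        "stage_counts": stage_counts,
        "outputs": ["morphometry.csv", "cohort_truth.csv", "correlations.csv",
                    "path_coefficients.csv", "stepwise.json"],
    }
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with (out / "config.yaml").open("w") as fh:
        yaml.safe_dump(_jsonable(config), fh, sort_keys=True)
    return manifest


def stats_report(
    table: pd.DataFrame,
    response: str = "BR",
    predictors: list[str] | None = None,
    alpha_in: float = 0.05,
    alpha_out: float = 0.05,
) -> dict:
    """Correlation screen + stepwise selection + path analysis on one table.

    Works on any cohort table with numeric parameter columns and a
    response column — the packaged six-variety dataset, a simulated
    cohort, or measurements of real scans.
    """
    if predictors is None:
        skip = {response, "replicate", "br_out_of_range", "BR_pct", "moisture_pct"}
        predictors = [
            c for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])
            and table[c].notna().all() and np.ptp(table[c].to_numpy()) > 0
        ]
    screen = stats.spearman_screen(table, response, predictors)
    y = table[response].to_numpy(dtype=float)
    X = table[predictors]
    sel = stats.stepwise_select(y, X, alpha_in=alpha_in, alpha_out=alpha_out)
    stepwise_payload = {
        "selected": sel.selected,
        "trace": [list(t) for t in sel.trace],
        "alpha_in": alpha_in,
        "alpha_out": alpha_out,
    }
    if sel.fit is not None:
        stepwise_payload.update({
            "intercept": sel.fit.intercept,
            "coefficients": sel.fit.coef,
            "std_coefficients": sel.fit.std_coef,
            "p_values": sel.fit.pvalues,
            "r_squared": sel.fit.r_squared,
        })
        path = stats.path_analysis(y, table[sel.selected])
        path_table = path.to_table()
    else:
        path_table = pd.DataFrame()
    return {
        "correlations": screen,
        "stepwise": stepwise_payload,
        "path_table": path_table,
    }
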