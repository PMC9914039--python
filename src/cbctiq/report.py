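"""Assessment orchestration and summary tables.

Runs the full task-based protocol over (mode, reconstruction) pairs — NPS on
the uniform module, circular-edge TTF and contrast per insert on the
sensitometry module, NPWE d' per 10-mm lesion task — and assembles a summary
table with FBP-vs-IR percent-change statistics (mean +/- SD over the four
inserts), mirroring the layout such studies report.

Percent values are rounded to integers only in the human-readable report;
machine-readable output keeps full precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as image_io
from .io import ImageStack
from .nps import NpsResult, compute_nps, default_roi_layout
from .npwe import DetectabilityResult, TaskSpec, ViewingConditions, compute_dprime
from .phantom import (
    NoiseModel,
    PhantomConfig,
    default_inserts,
    generate_insert_module,
    generate_uniform_module,
)
from .ttf import InsertSpec, TtfResult, compute_ttf

__all__ = [
    "SeriesConfig",
    "AssessmentConfig",
    "SummaryTable",
    "percent_change",
    "mean_change_over_inserts",
    "run_assessment",
    "synthetic_series",
    "load_assessment_config",
]


def percent_change(fbp_value: float, ir_value: float) -> float:
    """Relative change of IR vs FBP in percent: 100 * (ir - fbp) / fbp."""
    if fbp_value == 0:
        raise ValueError("percent change undefined for a zero reference value")
    return 100.0 * (ir_value - fbp_value) / fbp_value


def mean_change_over_inserts(
    values_fbp: Sequence[float], values_ir: Sequence[float]
) -> tuple[float, float]:
    """Mean and sample SD of the four per-insert percent changes."""
    if len(values_fbp) != 4 or len(values_ir) != 4:
        raise ValueError("exactly four paired insert values are required")
    changes = [percent_change(f, i) for f, i in zip(values_fbp, values_ir)]
    return float(np.mean(changes)), float(np.std(changes, ddof=1))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SeriesConfig:
    """One (mode, reconstruction) pair with its uniform- and insert-module
    stack sources (filesystem paths or synthetic phantom configurations)."""

    mode: str
    reconstruction: str
    uniform: object
    inserts: object
    stack_format: str = "raw_stack"


@dataclass
class AssessmentConfig:
    series: list[SeriesConfig]
    roi_side_px: int = 82
    roi_offset_mm: float = 50.0
    nps_slices: int | None = None
    ttf_slices: int | None = None
    insert_specs: list[InsertSpec] | None = None
    task_diameter_mm: float = 10.0
    viewing: ViewingConditions = field(default_factory=ViewingConditions)
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("at least one series is required")
        labels = [(s.mode, s.reconstruction) for s in self.series]
        if len(set(labels)) != len(labels):
            raise ValueError("(mode, reconstruction) labels must be unique")


@dataclass
class SeriesResult:
    mode: str
    reconstruction: str
    nps: NpsResult
    ttf: dict[str, TtfResult]
    dprime: dict[str, DetectabilityResult]


@dataclass
class SummaryTable:
    """Long-format metric table plus per-mode FBP-vs-IR change statistics."""

    metrics: pd.DataFrame  # columns: mode, reconstruction, metric, insert, value
    changes: pd.DataFrame  # columns: mode, metric, change_pct / mean_pct / sd_pct
    series_results: list[SeriesResult] = field(default_factory=list, repr=False)

    def wide(self) -> pd.DataFrame:
        m = self.metrics.copy()
        m["row"] = np.where(
            m["insert"].isna() | (m["insert"] == ""),
            m["metric"],
            m["metric"] + " " + m["insert"].fillna(""),
        )
        return m.pivot_table(
            index="row", columns=["mode", "reconstruction"], values="value", sort=False
        )

    def human_report(self) -> str:
        """Plain-text report; percent changes rounded to integers."""
        lines = ["== Task-based image quality summary ==", "", self.wide().to_string(), ""]
        if len(self.changes):
            lines.append("== IR vs FBP percent changes ==")
            for _, r in self.changes.iterrows():
                if np.isfinite(r.get("sd_pct", np.nan)):
                    lines.append(
                        f"{r['mode']:>12s}  {r['metric']:<18s} "
                        f"{r['mean_pct']:+.0f}% +/- {r['sd_pct']:.0f}%"
                    )
                else:
                    lines.append(
                        f"{r['mode']:>12s}  {r['metric']:<18s} {r['mean_pct']:+.0f}%"
                    )
        return "\n".join(lines) + "\n"

    def export(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
        self.changes.to_csv(out / "changes.tsv", sep="\t", index=False)
        (out / "report.txt").write_text(self.human_report())
        for sr in self.series_results:
            tag = f"{sr.mode}_{sr.reconstruction}"
            sr.nps.export(out, prefix=f"nps_{tag}")
            for name, t in sr.ttf.items():
                (out / f"ttf_{tag}_{name}.tsv").write_text(
                    t.ttf.to_text("frequency_mm-1", "ttf")
                )


# ---------------------------------------------------------------------------
# synthetic configuration helpers
# ---------------------------------------------------------------------------

def synthetic_series(
    mode: str,
    reconstruction: str,
    noise_sigma_hu: float,
    noise_family: str,
    noise_peak_mm: float,
    psf_sigma_mm: float,
    *,
    matrix_size: int = 512,
    pixel_spacing_mm: float = 0.55,
    nps_slices: int = 85,
    ttf_slices: int = 40,
    cupping_amplitude_hu: float = 0.0,
    background_hu: float = 0.0,
    seed: int = 0,
) -> SeriesConfig:
    """Build a synthetic (mode, reconstruction) series emulating one scanner
    condition: a prescribed radial NPS for the uniform module and the same
    noise plus four blurred contrast inserts for the sensitometry module."""
    noise = NoiseModel(
        target_sigma_hu=noise_sigma_hu, family=noise_family, peak_frequency_mm=noise_peak_mm
    )
    base = PhantomConfig(
        matrix_size=matrix_size,
        pixel_spacing_mm=pixel_spacing_mm,
        background_hu=background_hu,
        psf_sigma_mm=psf_sigma_mm,
        noise_model=noise,
        cupping_amplitude_hu=cupping_amplitude_hu,
        seed=seed % (2**31),
    )
    uniform = replace(base, n_slices=nps_slices)
    inserts = replace(
        base,
        n_slices=ttf_slices,
        insert_specs=tuple(default_inserts()),
        seed=(seed + 1) % (2**31),
    )
    return SeriesConfig(
        mode=mode, reconstruction=reconstruction, uniform=uniform, inserts=inserts
    )


def load_assessment_config(path: str | Path) -> AssessmentConfig:
    """Build an :class:`AssessmentConfig` from a YAML file describing
    synthetic modes (see README for the schema)."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    seed = int(doc.get("seed", 0))
    series = []
    for i, mode in enumerate(doc["modes"]):
        for j, recon in enumerate(("FBP", "IR")):
            key = recon.lower()
            if key not in mode:
                continue
            m = mode[key]
            series.append(
                synthetic_series(
                    mode["name"],
                    recon,
                    noise_sigma_hu=float(m["sigma"]),
                    noise_family=m.get("family", "fbp" if recon == "FBP" else "ir"),
                    noise_peak_mm=float(m["peak"]),
                    psf_sigma_mm=float(m.get("psf_sigma_mm", 0.0)),
                    matrix_size=int(mode.get("matrix_size", 512)),
                    pixel_spacing_mm=float(mode.get("pixel_spacing_mm", 0.55)),
                    nps_slices=int(doc.get("nps_slices", 85)),
                    ttf_slices=int(doc.get("ttf_slices", 40)),
                    cupping_amplitude_hu=float(mode.get("cupping_hu", 0.0)),
                    seed=seed + 101 * i + 13 * j,
                )
            )
    return AssessmentConfig(
        series=series,
        roi_side_px=int(doc.get("roi_side_px", 82)),
        nps_slices=doc.get("nps_slices"),
        ttf_slices=doc.get("ttf_slices"),
        output_dir=doc.get("output_dir"),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _resolve_stack(source, fmt: str, generator) -> ImageStack:
    if isinstance(source, PhantomConfig):
        return generator(source)
    return image_io.read_stack(source, format=fmt)


def _insert_specs_for(stack: ImageStack, config: AssessmentConfig) -> list[InsertSpec]:
    if config.insert_specs is not None:
        return list(config.insert_specs)
    inserts = stack.meta.get("inserts")
    if not inserts:
        raise ValueError(
            "no insert specifications: provide AssessmentConfig.insert_specs for "
            "non-synthetic stacks"
        )
    return [
        InsertSpec(
            name=d["name"],
            approx_center_px=tuple(d["center_px"]),
            insert_diameter_mm=d["diameter_mm"],
        )
        for d in inserts
    ]


def run_assessment(config: AssessmentConfig) -> SummaryTable:
    """Run the full protocol and assemble the summary table.

    For each (mode, reconstruction): NPS on the uniform stack, TTF and
    contrast per insert on the insert stack, then d' per 10-mm task whose
    contrast equals that insert's measured contrast, using that pair's TTF
    and NPS.
    """
    rows = []
    change_rows = []
    series_results = []
    for s in config.series:
        uniform = _resolve_stack(s.uniform, s.stack_format, generate_uniform_module)
        insert_stack = _resolve_stack(s.inserts, s.stack_format, generate_insert_module)
        nps_sl = (
            list(range(min(config.nps_slices, uniform.n_slices)))
            if config.nps_slices
            else None
        )
        ttf_sl = (
            list(range(min(config.ttf_slices, insert_stack.n_slices)))
            if config.ttf_slices
            else None
        )
        rois = [
            replace(r, slice_indices=tuple(nps_sl) if nps_sl is not None else None)
            for r in default_roi_layout(uniform, config.roi_side_px, config.roi_offset_mm)
        ]
        nps_res = compute_nps(uniform, rois)
        specs = _insert_specs_for(insert_stack, config)
        ttf_res: dict[str, TtfResult] = {}
        dprime_res: dict[str, DetectabilityResult] = {}
        for spec in specs:
            t = compute_ttf(insert_stack, spec, slices=ttf_sl)
            ttf_res[spec.name] = t
            task = TaskSpec(
                contrast_hu=t.contrast_hu, lesion_diameter_mm=config.task_diameter_mm
            )
            dprime_res[spec.name] = compute_dprime(t, nps_res, task, config.viewing)

        rows.append((s.mode, s.reconstruction, "noise_magnitude_hu", "", nps_res.noise_magnitude_hu))
        for k, p in enumerate(nps_res.peak_freqs_mm):
            rows.append((s.mode, s.reconstruction, f"f_peak_mm-1_{k}", "", p))
        for name, t in ttf_res.items():
            rows.append((s.mode, s.reconstruction, "f50_mm-1", name, t.f50_mm))
            rows.append((s.mode, s.reconstruction, "contrast_hu", name, t.contrast_hu))
            rows.append((s.mode, s.reconstruction, "dprime", name, dprime_res[name].dprime))
        series_results.append(
            SeriesResult(s.mode, s.reconstruction, nps_res, ttf_res, dprime_res)
        )

    metrics = pd.DataFrame(
        rows, columns=["mode", "reconstruction", "metric", "insert", "value"]
    )

    for mode in metrics["mode"].unique():
        sub = metrics[metrics["mode"] == mode]
        recons = set(sub["reconstruction"])
        if not {"FBP", "IR"} <= recons:
            continue

        def val(metric, recon, insert=""):
            sel = sub[
                (sub["metric"] == metric)
                & (sub["reconstruction"] == recon)
                & (sub["insert"] == insert)
            ]["value"]
            return float(sel.iloc[0])

        change_rows.append(
            {
                "mode": mode,
                "metric": "noise_magnitude_hu",
                "mean_pct": percent_change(
                    val("noise_magnitude_hu", "FBP"), val("noise_magnitude_hu", "IR")
                ),
                "sd_pct": np.nan,
            }
        )
        insert_names = sorted(set(sub[sub["insert"] != ""]["insert"]))
        for metric in ("f50_mm-1", "contrast_hu", "dprime"):
            fbp = [val(metric, "FBP", n) for n in insert_names]
            ir = [val(metric, "IR", n) for n in insert_names]
            if len(insert_names) == 4:
                mean, sd = mean_change_over_inserts(fbp, ir)
            else:
                ch = [percent_change(f, i) for f, i in zip(fbp, ir)]
                mean = float(np.mean(ch))
                sd = float(np.std(ch, ddof=1)) if len(ch) > 1 else np.nan
            change_rows.append(
                {"mode": mode, "metric": metric, "mean_pct": mean, "sd_pct": sd}
            )

    changes = pd.DataFrame(change_rows, columns=["mode", "metric", "mean_pct", "sd_pct"])
    table = SummaryTable(metrics=metrics, changes=changes, series_results=series_results)
    if config.output_dir is not None:
        table.export(config.output_dir)
        _write_manifest(config, Path(config.output_dir))
    return table


def _write_manifest(config: AssessmentConfig, out: Path) -> None:
    """Run manifest: configuration repr hash and seeds, for reproducibility."""
    desc = repr(config)
    seeds = [
        getattr(src, "seed", None)
        for s in config.series
        for src in (s.uniform, s.inserts)
    ]
    manifest = {
        "config_sha256": hashlib.sha256(desc.encode()).hexdigest(),
        "seeds": seeds,
        "series": [[s.mode, s.reconstruction] for s in config.series],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
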