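"""Reading and writing the toolkit's on-disk formats.

Traces travel as tidy CSV (time_h, value, channel, treatment), image stacks
as multi-page TIFF with a JSON sidecar, actograms as CSV plus a JSON
schedule, and expression data as TSV matrices with a TSV annotation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behaviour import ActivityRecord, LightSegment
from .expression import ExpressionMatrix
from .rhythm import Trace

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_stack", "read_stack",
    "write_actogram", "read_actogram",
    "write_expression", "read_expression",
]


# --- traces ---------------------------------------------------------------

def write_trace_csv(trace: Trace, path: str | Path, channel: str = "lum") -> None:
    df = pd.DataFrame({
        "time_h": trace.t,
        "value": trace.y,
        "channel": channel,
        "treated": (trace.treatment_time_h is not None)
                   & (trace.t >= (trace.treatment_time_h or 0.0)),
    })
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path, treatment_time_h: float | None = None) -> Trace:
    df = pd.read_csv(path)
    if treatment_time_h is None and "treated" in df and df["treated"].any():
        treatment_time_h = float(df.loc[df["treated"], "time_h"].iloc[0])
    return Trace(df["time_h"].to_numpy(), df["value"].to_numpy(),
                 treatment_time_h=treatment_time_h, label=str(path))


# --- image stacks ---------------------------------------------------------

def write_stack(stack: np.ndarray, path: str | Path,
                sidecar: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack))
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> tuple[np.ndarray, dict | None]:
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = None
    if path.with_suffix(".json").exists():
        sidecar = json.loads(path.with_suffix(".json").read_text())
    return stack, sidecar


# --- actograms ------------------------------------------------------------

def write_actogram(record: ActivityRecord, counts_path: str | Path,
                   schedule_path: str | Path | None = None) -> None:
    bin_h = record.bin_h
    pd.DataFrame({
        "bin_start_h": np.arange(len(record.counts)) * bin_h,
        "counts": record.counts.astype(int),
    }).to_csv(counts_path, index=False)
    if schedule_path is not None and record.schedule is not None:
        payload = {"bin_min": record.bin_min,
                   "segments": [dataclasses.asdict(s) for s in record.schedule]}
        Path(schedule_path).write_text(json.dumps(payload, indent=2))


def read_actogram(counts_path: str | Path,
                  schedule_path: str | Path | None = None) -> ActivityRecord:
    df = pd.read_csv(counts_path)
    bin_min = int(round((df["bin_start_h"].iloc[1] - df["bin_start_h"].iloc[0]) * 60))
    schedule = None
    if schedule_path is not None:
        payload = json.loads(Path(schedule_path).read_text())
        bin_min = payload.get("bin_min", bin_min)
        schedule = [LightSegment(**s) for s in payload["segments"]]
    return ActivityRecord(df["counts"].to_numpy(), bin_min=bin_min,
                          schedule=schedule)


# --- expression -----------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     annot_path: str | Path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t")
    annot = pd.DataFrame(index=matrix.values.index)
    if matrix.gene_annotation is not None:
        annot["cre_category"] = matrix.gene_annotation
    for s in matrix.values.columns:
        annot[f"detection_p:{s}"] = matrix.detection_p[s]
    annot.to_csv(annot_path, sep="\t", index_label="gene")
    groups_path = Path(matrix_path).with_suffix(".groups.tsv")
    matrix.groups.rename_axis("sample").to_frame().to_csv(groups_path, sep="\t")


def read_expression(matrix_path: str | Path, annot_path: str | Path,
                    groups_path: str | Path | None = None) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    annot = pd.read_csv(annot_path, sep="\t", index_col="gene")
    det_cols = [c for c in annot.columns if c.startswith("detection_p:")]
    detection = annot[det_cols].copy()
    detection.columns = [c.split(":", 1)[1] for c in det_cols]
    detection = detection[values.columns]
    gene_annotation = annot["cre_category"] if "cre_category" in annot else None
    if groups_path is None:
        groups_path = Path(matrix_path).with_suffix(".groups.tsv")
    groups = pd.read_csv(groups_path, sep="\t", index_col="sample")["group"]
    return ExpressionMatrix(values=values, detection_p=detection,
                            groups=groups, gene_annotation=gene_annotation)
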