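"""Readers and writers for the package's on-disk formats.

Image stacks go to multi-page TIFF with acquisition metadata in the image
description (JSON); traces, beat series, OCR assays and micropost recordings
go to tidy CSV; cell x gene counts go to Matrix Market (MTX) with barcode and
feature TSVs; presets go to YAML.  All writers round-trip losslessly through
the matching reader (floats are serialized at full precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from .datatypes import FluorescenceTrace, ImageStack
from .microposts import MicropostRecording
from .mito_flux import MITOSTRESS_SEGMENTS, PALMITATE_SEGMENTS, OCRAssay
from .presets import Preset, PresetParameter
from .rhythm import BeatSeries

__all__ = [
    "write_stack", "read_stack",
    "write_trace", "read_trace",
    "write_beats", "read_beats",
    "write_ocr", "read_ocr",
    "write_counts", "read_counts",
    "write_micropost", "read_micropost",
    "write_preset", "read_preset",
]

_FLOAT_FMT = "%.17g"


def write_stack(path: str | Path, stack: ImageStack) -> None:
    meta = {"frame_rate": stack.frame_rate, "pixel_size": stack.pixel_size}
    tifffile.imwrite(str(path), stack.frames, description=json.dumps(meta))


def read_stack(path: str | Path) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    return ImageStack(
        frames, frame_rate=meta["frame_rate"], pixel_size=meta["pixel_size"]
    )


def write_trace(path: str | Path, trace: FluorescenceTrace) -> None:
    df = pd.DataFrame({"time_s": trace.time, "value": trace.value})
    with open(path, "w") as fh:
        fh.write(f"# background_corrected={int(trace.background_corrected)}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_trace(path: str | Path) -> FluorescenceTrace:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, float_precision="round_trip")
    corrected = header.endswith("=1")
    return FluorescenceTrace(
        df["time_s"].to_numpy(), df["value"].to_numpy(),
        background_corrected=corrected,
    )


def write_beats(path: str | Path, series: BeatSeries) -> None:
    pd.DataFrame({"beat_time_s": series.beat_times}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_beats(path: str | Path) -> BeatSeries:
    return BeatSeries(
        pd.read_csv(path, float_precision="round_trip")["beat_time_s"].to_numpy()
    )


def write_ocr(path: str | Path, assay: OCRAssay) -> None:
    df = assay.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# per_cell={int(assay.per_cell)}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_ocr(path: str | Path) -> OCRAssay:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, float_precision="round_trip")
    per_cell = header.endswith("=1")
    wells = list(dict.fromkeys(df["well"]))
    pivot = df.pivot(index="well", columns="time_s", values="value").loc[wells]
    time = pivot.columns.to_numpy(dtype=float)
    first = df[df["well"] == wells[0]].sort_values("time_s")
    segments = list(first["segment"])
    if df["cell_count"].notna().all():
        counts = df.groupby("well", sort=False)["cell_count"].first().loc[wells]
        cell_counts = counts.to_numpy(dtype=float)
    else:
        cell_counts = None
    order = (
        MITOSTRESS_SEGMENTS
        if segments[0] in MITOSTRESS_SEGMENTS
        else PALMITATE_SEGMENTS
    )
    return OCRAssay(
        wells=wells,
        time=time,
        ocr=pivot.to_numpy(dtype=float),
        segments=segments,
        cell_counts=cell_counts,
        per_cell=per_cell,
        segment_order=order,
    )


def write_counts(outdir: str | Path, adata: AnnData) -> None:
    """Write a cells x genes count matrix as MTX + barcodes/features TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    spio.mmwrite(str(outdir / "matrix.mtx"), x.T.tocoo())  # genes x cells, 10x-style
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    features = pd.DataFrame({"name": adata.var_names})
    if "mito" in adata.var:
        features["mito"] = np.asarray(adata.var["mito"], dtype=int)
    features.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)


def read_counts(outdir: str | Path) -> AnnData:
    outdir = Path(outdir)
    x = sparse.csr_matrix(spio.mmread(str(outdir / "matrix.mtx")).T)
    barcodes = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(outdir / "features.tsv", sep="\t", header=None)
    adata = AnnData(X=x)
    adata.obs_names = barcodes.astype(str).tolist()
    adata.var_names = features[0].astype(str).tolist()
    if features.shape[1] > 1:
        adata.var["mito"] = features[1].astype(bool).to_numpy()
    return adata


def write_micropost(path: str | Path, rec: MicropostRecording) -> None:
    n_frames, n_posts, _ = rec.positions.shape
    frames = np.repeat(np.arange(n_frames), n_posts)
    posts = np.tile(np.arange(n_posts), n_frames)
    df = pd.DataFrame(
        {
            "frame": frames,
            "post": posts,
            "x_um": rec.positions[frames, posts, 0],
            "y_um": rec.positions[frames, posts, 1],
        }
    )
    if rec.rest_positions is not None:
        rest = pd.DataFrame(
            {
                "frame": -1,
                "post": np.arange(n_posts),
                "x_um": rec.rest_positions[:, 0],
                "y_um": rec.rest_positions[:, 1],
            }
        )
        df = pd.concat([rest, df], ignore_index=True)
    with open(path, "w") as fh:
        fh.write(
            f"# frame_rate={rec.frame_rate!r} k_post={rec.k_post!r} "
            f"spacing={rec.spacing!r}\n"
        )
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_micropost(path: str | Path) -> MicropostRecording:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        df = pd.read_csv(fh, float_precision="round_trip")
    meta = dict(item.split("=") for item in header.split())
    rest_df = df[df["frame"] < 0].sort_values("post")
    body = df[df["frame"] >= 0]
    n_posts = body["post"].nunique()
    n_frames = body["frame"].nunique()
    positions = (
        body.sort_values(["frame", "post"])[["x_um", "y_um"]]
        .to_numpy()
        .reshape(n_frames, n_posts, 2)
    )
    rest = rest_df[["x_um", "y_um"]].to_numpy() if len(rest_df) else None
    return MicropostRecording(
        positions=positions,
        frame_rate=float(meta["frame_rate"]),
        rest_positions=rest,
        k_post=float(meta["k_post"]),
        spacing=float(meta["spacing"]),
    )


def write_preset(path: str | Path, preset: Preset) -> None:
    payload = {
        "name": preset.name,
        "modality": preset.modality,
        "source": preset.source,
        "parameters": {
            k: {"value": p.value, "units": p.units}
            for k, p in preset.parameters.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_preset(path: str | Path) -> Preset:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return Preset(
        name=payload["name"],
        modality=payload["modality"],
        source=payload.get("source", ""),
        parameters={
            k: PresetParameter(float(p["value"]), str(p["units"]))
            for k, p in payload["parameters"].items()
        },
    )
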