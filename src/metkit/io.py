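"""File formats: HDF5/CSV trace sets, TIFF movies and stacks, TSV gene
tables, JSON landmark annotations and ground-truth sidecars.

Conventions
-----------
* Trace sets: HDF5 with one group per voltage step holding datasets
  ``current_pA`` and ``driver_V`` and attributes ``v_mV``, ``buffer``,
  ``sample_rate`` (plus cell metadata).  CSV fallback is long format with
  columns ``time_s, current_pA, driver_V, v_mV``.
* Movies and stacks: multi-page TIFF with resolution tags carrying the
  pixel size (pixels per centimeter); ground truth and stimulus records go
  to a JSON sidecar next to the TIFF.
* Gene tables: TSV with columns ``gene_id, log2FC, lfcSE, padj``; gene
  panels are one identifier per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .bundle_motion import Kymograph
from .confocal import ConfocalStack, Landmark
from .genesets import GeneSet
from .met_traces import CurrentTrace
from .synthetic import BundleMovie

__all__ = [
    "save_traces_h5",
    "load_traces_h5",
    "save_traces_csv",
    "load_traces_csv",
    "save_movie_tiff",
    "load_movie_tiff",
    "save_stack_tiff",
    "load_stack_tiff",
    "save_landmarks_json",
    "load_landmarks_json",
    "save_gene_table_tsv",
    "load_gene_table_tsv",
    "load_gene_panel",
]

_NM_PER_CM = 1e7


def save_traces_h5(path, traces: "list[CurrentTrace]") -> None:
    with h5py.File(path, "w") as f:
        for i, tr in enumerate(traces):
            g = f.create_group(f"step{i:03d}")
            g.create_dataset("current_pA", data=tr.samples)
            g.create_dataset("driver_V", data=tr.driver)
            g.attrs["v_mV"] = tr.v_m
            g.attrs["buffer"] = tr.buffer_label
            g.attrs["sample_rate"] = tr.sample_rate
            g.attrs["cell_id"] = tr.cell_id
            g.attrs["genotype"] = tr.genotype
            g.attrs["age"] = tr.age
            if tr.stim_onset_s is not None:
                g.attrs["stim_onset_s"] = tr.stim_onset_s
            if tr.stim_offset_s is not None:
                g.attrs["stim_offset_s"] = tr.stim_offset_s


def load_traces_h5(path) -> "list[CurrentTrace]":
    traces = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            traces.append(
                CurrentTrace(
                    samples=g["current_pA"][:],
                    sample_rate=float(g.attrs["sample_rate"]),
                    driver=g["driver_V"][:],
                    v_m=float(g.attrs["v_mV"]),
                    buffer_label=str(g.attrs.get("buffer", "EGTA_1mM")),
                    cell_id=str(g.attrs.get("cell_id", "cell0")),
                    genotype=str(g.attrs.get("genotype", "control")),
                    age=str(g.attrs.get("age", "P20")),
                    stim_onset_s=(float(g.attrs["stim_onset_s"])
                                  if "stim_onset_s" in g.attrs else None),
                    stim_offset_s=(float(g.attrs["stim_offset_s"])
                                   if "stim_offset_s" in g.attrs else None),
                )
            )
    return traces


def save_traces_csv(path, traces: "list[CurrentTrace]") -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.time,
                    "current_pA": tr.samples,
                    "driver_V": tr.driver,
                    "v_mV": tr.v_m,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_traces_csv(path, **metadata) -> "list[CurrentTrace]":
    """Long-format CSV loader; the sample rate is recovered from the time
    column.  Metadata lost by the CSV format (buffer, cell annotations)
    may be supplied as keyword arguments."""
    df = pd.read_csv(path)
    traces = []
    for v, sub in df.groupby("v_mV", sort=True):
        t = sub["time_s"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t)))
        traces.append(
            CurrentTrace(
                samples=sub["current_pA"].to_numpy(),
                sample_rate=fs,
                driver=sub["driver_V"].to_numpy(),
                v_m=float(v),
                **metadata,
            )
        )
    return traces


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def save_movie_tiff(path, movie: BundleMovie, truth: dict | None = None) -> None:
    ppcm = _NM_PER_CM / movie.pixel_size
    tifffile.imwrite(
        path,
        movie.frames.astype(np.float32),
        resolution=(ppcm, ppcm),
        resolutionunit="CENTIMETER",
    )
    meta = {
        "pixel_size_nm": movie.pixel_size,
        "frame_rate_hz": movie.frame_rate,
        "stimulus_force_nN": np.asarray(movie.stimulus_force).tolist(),
    }
    if truth is not None:
        meta["ground_truth"] = truth
    _sidecar(path).write_text(json.dumps(meta))


def load_movie_tiff(path, pixel_size: float | None = None) -> BundleMovie:
    """Read a movie TIFF; pixel size comes from the resolution tag unless
    overridden, frame rate and stimulus from the JSON sidecar."""
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray().astype(float)
        page = tf.pages[0]
        if pixel_size is None:
            num, den = page.tags["XResolution"].value
            pixel_size = _NM_PER_CM / (num / den)
    meta = json.loads(_sidecar(path).read_text())
    return BundleMovie(
        frames=frames,
        pixel_size=float(pixel_size),
        frame_rate=float(meta["frame_rate_hz"]),
        stimulus_force=np.asarray(meta["stimulus_force_nN"], dtype=float),
    )


def save_stack_tiff(path, stack: ConfocalStack, truth: dict | None = None) -> None:
    data = np.stack([stack.myo7a, stack.actin]).astype(np.float32)  # (2, z, y, x)
    vx, vy, vz = stack.voxel_size
    tifffile.imwrite(
        path,
        data,
        resolution=(_NM_PER_CM / vx, _NM_PER_CM / vy),
        resolutionunit="CENTIMETER",
    )
    meta = {"voxel_size_nm": list(stack.voxel_size),
            "channels": ["myo7a", "actin"]}
    if truth is not None:
        meta["ground_truth"] = truth
    _sidecar(path).write_text(json.dumps(meta))


def load_stack_tiff(path) -> ConfocalStack:
    data = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    vx, vy, vz = meta["voxel_size_nm"]
    return ConfocalStack(data[0], data[1], (vx, vy, vz))


def save_landmarks_json(path, cell_id: str, landmarks: "list[Landmark]") -> None:
    doc = {
        "cell_id": cell_id,
        "landmarks": [
            {"name": lm.name, "x_nm": lm.position[0], "y_nm": lm.position[1],
             "z_nm": lm.position[2], "sigma_xy_nm": lm.sigma_xy,
             "sigma_z_nm": lm.sigma_z}
            for lm in landmarks
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_landmarks_json(path) -> tuple[str, "list[Landmark]"]:
    doc = json.loads(Path(path).read_text())
    landmarks = [
        Landmark(
            name=d["name"],
            position=(d["x_nm"], d["y_nm"], d["z_nm"]),
            sigma_xy=d.get("sigma_xy_nm"),
            sigma_z=d.get("sigma_z_nm"),
        )
        for d in doc["landmarks"]
    ]
    return doc.get("cell_id", "cell0"), landmarks


def save_gene_table_tsv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_gene_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_gene_panel(path, label: str | None = None) -> GeneSet:
    """One gene identifier per line; blank lines and '#' comments ignored."""
    lines = Path(path).read_text().splitlines()
    genes = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    return GeneSet.from_iterable(label or Path(path).stem, genes)
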