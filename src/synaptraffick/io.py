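"""File-format helpers: TIFF images with JSON truth sidecars, CSV/TSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .frap import FRAPTrace
from .puncta import ChannelImage, ClusterSet
from .scenes import SceneTruth
from .vesicles import Spot, SpotSet


def write_scene(path, images: dict[str, ChannelImage],
                truth: SceneTruth | None = None) -> None:
    """Write channels as a multi-page TIFF (+ JSON sidecar with the truth)."""
    path = Path(path)
    names = list(images)
    stack = np.stack([images[n].pixels for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={
        "channels": names,
        "pixel_size_um": images[names[0]].pixel_size_um,
    })
    if truth is not None:
        path.with_suffix(".json").write_text(truth.to_json())


def read_scene(path) -> dict[str, ChannelImage]:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    names = meta.get("channels") or [f"ch{i}" for i in range(stack.shape[0])]
    px = float(meta.get("pixel_size_um", 0.1))
    if stack.ndim == 2:
        stack = stack[None]
    return {n: ChannelImage(pixels=stack[i].astype(float), pixel_size_um=px,
                            channel=n)
            for i, n in enumerate(names)}


def read_roi_json(path) -> list[dict]:
    """ROIs as JSON: list of {role, vertices (row, col pixel coords)}."""
    return json.loads(Path(path).read_text())


def write_traces(path, traces: list[FRAPTrace]) -> None:
    rows = []
    for tr in traces:
        for t, v in zip(tr.t_min, tr.intensity):
            rows.append({"synapse_id": tr.synapse_id, "site": tr.site,
                         "t_min": t, "intensity": v,
                         "pre_bleach": tr.pre_bleach})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces(path) -> list[FRAPTrace]:
    from .frap import traces_from_frame
    return traces_from_frame(pd.read_csv(path))


def write_clusters(path, cs: ClusterSet) -> None:
    rows = []
    for c in cs.clusters:
        row = {"id": c.id, "area_um2": c.area_um2,
               "centroid_row": c.centroid[0], "centroid_col": c.centroid[1],
               "synaptic": c.synaptic}
        for name, s in c.channel_sum.items():
            row[f"sum_{name}"] = s
            row[f"mean_{name}"] = c.channel_mean[name]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_spots(path, ss: SpotSet) -> None:
    pd.DataFrame([{"id": s.id, "x_um": s.x_um, "y_um": s.y_um,
                   "diameter_um": s.diameter_um, "peak": s.peak}
                  for s in ss.spots]).to_csv(path, index=False)


def read_spots(path) -> SpotSet:
    df = pd.read_csv(path)
    return SpotSet(spots=[Spot(**row) for row in df.to_dict("records")])


def read_count_tables(counts_path, peptides_path, meta_path):
    """Read the three interactome TSVs into a SpectralCountTable."""
    from .interactome import SpectralCountTable
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    peptides = pd.read_csv(peptides_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return SpectralCountTable(counts=counts, unique_peptides=peptides,
                              sample_meta=meta)


def read_annotation_tsv(path) -> dict[str, set[str]]:
    """Two-column TSV (term, protein) -> term -> protein set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "protein"])
    out: dict[str, set[str]] = {}
    for term, sub in df.groupby("term"):
        out[str(term)] = set(sub["protein"].astype(str))
    return out
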