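"""Text formats for patterns, RDMs, maps and frame streams; NIfTI ROI access.

All artifacts are plain text.  Pattern tables and RDMs are tab-delimited;
semantic maps are JSON (Python float repr round-trips exactly, so maps and
projection bases survive serialization bit-for-bit); feedback frames are
line-delimited JSON so a display process can tail the stream while it is
being written.
"""

from __future__ import annotations

import csv
import json
import time

import numpy as np
import pandas as pd

from . import __version__
from .feedback import FeedbackFrame
from .mapping import SemanticMap
from .rsa import RDM, AnchorSet

__all__ = ["write_patterns", "read_patterns", "write_rdm", "read_rdm",
           "write_map", "read_map", "FrameWriter", "read_frames",
           "read_nifti_roi", "write_nifti_pair", "write_manifest",
           "read_manifest"]

_FLOAT_FMT = "%.17g"  # shortest round-trip precision for doubles


# ---------------------------------------------------------------------------
# pattern tables
# ---------------------------------------------------------------------------

def write_patterns(path, anchors: AnchorSet | tuple[np.ndarray, list[str]]) -> None:
    """Write patterns as a TSV: first column voxel index, one column per
    condition/trial label."""
    if isinstance(anchors, AnchorSet):
        labels, P = anchors.labels, anchors.patterns
    else:
        P, labels = anchors
        P = np.asarray(P, dtype=float)
    df = pd.DataFrame(np.asarray(P).T, columns=list(labels))
    df.index.name = "voxel"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_patterns(path, source: str | None = None) -> AnchorSet:
    """Read a pattern TSV back into an :class:`AnchorSet`."""
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter="\t"))
    labels = header[1:]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate condition labels in header: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"ragged or non-numeric rows in {path}")
    return AnchorSet(labels=tuple(labels), patterns=df.to_numpy().T,
                     source=source or str(path))


def read_trial_table(path) -> tuple[np.ndarray, list[str]]:
    """Read a trial TSV (duplicate labels allowed) as (trials x voxels, labels)."""
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter="\t"))
    labels = header[1:]
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    df.columns = range(len(labels))
    if df.isna().any().any():
        raise ValueError(f"ragged or non-numeric rows in {path}")
    return df.to_numpy().T, labels


def write_trial_table(path, patterns: np.ndarray, labels) -> None:
    write_patterns(path, (np.asarray(patterns), list(labels)))


# ---------------------------------------------------------------------------
# RDM
# ---------------------------------------------------------------------------

def write_rdm(path, rdm: RDM) -> None:
    df = pd.DataFrame(rdm.matrix, index=list(rdm.labels), columns=list(rdm.labels))
    df.index.name = f"metric={rdm.metric}"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_rdm(path) -> RDM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    metric = "correlation"
    if df.index.name and df.index.name.startswith("metric="):
        metric = df.index.name.split("=", 1)[1]
    M = df.to_numpy(dtype=float)
    labels = tuple(df.columns)
    if not np.allclose(M, M.T, atol=1e-10):
        i, j = np.unravel_index(np.argmax(np.abs(M - M.T)), M.shape)
        raise ValueError(
            f"RDM in {path} is not symmetric: worst cell "
            f"({labels[i]!r}, {labels[j]!r}) differs by {abs(M[i, j] - M[j, i]):.3g}")
    return RDM(labels=labels, matrix=M, metric=metric)


# ---------------------------------------------------------------------------
# semantic map
# ---------------------------------------------------------------------------

def write_map(path, smap: SemanticMap) -> None:
    doc = {
        "format": "semnf-map/1",
        "labels": list(smap.labels),
        "dims": smap.dims,
        "coords": smap.coords.tolist(),
        "eigenvalues": smap.eigenvalues.tolist(),
        "eigenvectors": smap.eigenvectors.tolist(),
        "sqdist_col_means": smap.sqdist_col_means.tolist(),
        "rotation": smap.rotation.tolist(),
        "metric": smap.metric,
        "metric_options": smap.metric_options,
        "orientation": smap.orientation,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_map(path) -> SemanticMap:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "semnf-map/1":
        raise ValueError(f"{path} is not a semnf map file")
    return SemanticMap(
        labels=tuple(doc["labels"]), coords=np.array(doc["coords"], dtype=float),
        dims=int(doc["dims"]), eigenvalues=np.array(doc["eigenvalues"], dtype=float),
        eigenvectors=np.array(doc["eigenvectors"], dtype=float),
        sqdist_col_means=np.array(doc["sqdist_col_means"], dtype=float),
        rotation=np.array(doc["rotation"], dtype=float),
        metric=doc["metric"], metric_options=doc["metric_options"],
        orientation=doc["orientation"])


# ---------------------------------------------------------------------------
# frame streams
# ---------------------------------------------------------------------------

class FrameWriter:
    """Append-only line-delimited JSON frame stream, flushed per frame so a
    display process can tail the file live."""

    def __init__(self, path):
        self._fh = open(path, "a")

    def write(self, frame: FeedbackFrame) -> None:
        self._fh.write(json.dumps(frame.to_dict()) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_frames(path) -> tuple[list[FeedbackFrame], bool]:
    """Read a frame stream; returns (complete frames, partial_tail_flag).

    A truncated final line (a write in progress) is tolerated and flagged
    rather than raised.
    """
    frames, partial = [], False
    with open(path) as fh:
        text = fh.read()
    lines = text.split("\n")
    tail = lines.pop()  # '' when the file ends with a newline
    if tail.strip():
        try:
            frames_tail = FeedbackFrame.from_dict(json.loads(tail))
        except (json.JSONDecodeError, KeyError):
            partial = True
            frames_tail = None
        if frames_tail is not None:
            frames.append(frames_tail)
    out = []
    for ln in lines:
        if not ln.strip():
            continue
        try:
            out.append(FeedbackFrame.from_dict(json.loads(ln)))
        except (json.JSONDecodeError, KeyError):
            partial = True
    out.extend(frames)
    return out, partial


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def read_nifti_roi(series_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    """Extract a T x V matrix from a 4-D series restricted to a 3-D mask.

    Voxel ordering is the ascending linear (C-order) index within the mask
    and is returned alongside the data so projection bases — which are
    ordering-sensitive — can be tied to it in a manifest.
    """
    import nibabel as nib
    img = nib.load(str(series_path))
    msk = nib.load(str(mask_path))
    if img.shape[:3] != msk.shape[:3]:
        raise ValueError(
            f"grid mismatch: series {img.shape[:3]} vs mask {msk.shape[:3]}")
    if not np.allclose(img.affine, msk.affine, atol=1e-4):
        raise ValueError("series and mask affines differ")
    mask = np.asarray(msk.dataobj) > 0
    if not mask.any():
        raise ValueError("ROI mask is empty")
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    voxel_index = np.flatnonzero(mask.ravel(order="C"))
    return data[mask].T, voxel_index


def write_nifti_pair(series_path, mask_path, volumes: np.ndarray,
                     shape: tuple[int, int, int] | None = None) -> None:
    """Pack a T x V matrix into a 4-D NIfTI plus matching ROI mask.

    The first V C-order voxels of the grid form the mask, so
    :func:`read_nifti_roi` recovers the matrix exactly.
    """
    import nibabel as nib
    X = np.asarray(volumes, dtype=float)
    T, V = X.shape
    if shape is None:
        side = int(np.ceil(V ** (1 / 3)))
        shape = (side, side, max(1, int(np.ceil(V / side**2))))
    if int(np.prod(shape)) < V:
        raise ValueError(f"grid {shape} holds {int(np.prod(shape))} voxels < {V}")
    mask = np.zeros(int(np.prod(shape)), dtype=np.uint8)
    mask[:V] = 1
    mask = mask.reshape(shape)
    vol = np.zeros((*shape, T))
    flat = vol.reshape(-1, T)
    flat[:V] = X.T
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(vol, affine), str(series_path))
    nib.save(nib.Nifti1Image(mask, affine), str(mask_path))


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(path, command: str, config: dict, seeds: dict,
                   inputs: dict, outputs: dict, extra: dict | None = None) -> dict:
    """Write the run manifest that makes a CLI run reproducible."""
    doc = {
        "format": "semnf-manifest/1",
        "command": command,
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": config,
        "seeds": seeds,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=str)
        fh.write("\n")
    return doc


def read_manifest(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "semnf-manifest/1":
        raise ValueError(f"{path} is not a semnf manifest")
    return doc
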