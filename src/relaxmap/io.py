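"""Series and map I/O.

Native on-disk dialect for an acquisition series is a NIfTI stack
(rows x cols x n_images) plus a JSON sidecar holding the per-image
(TR, TE) tags and provenance. DICOM series are supported read-only via the
RepetitionTime (0018,0080) and EchoTime (0018,0081) attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .models import AcquisitionGrid, SeriesMode
from .phantom import AcquisitionSeries

__all__ = [
    "write_series",
    "read_series",
    "read_dicom_series",
    "write_map",
    "export_map_png",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an on-disk series lacks required structure or tags."""


def _stem(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii", ".json"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)])
    return p


def write_series(path: str | Path, series: AcquisitionSeries) -> tuple[Path, Path]:
    """Write ``series`` as ``<stem>.nii.gz`` + ``<stem>.json`` sidecar.

    The round trip through :func:`read_series` is lossless (pixel-exact,
    tag-exact). Returns the two paths written.
    """
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    nii_path = stem.with_name(stem.name + ".nii.gz")
    json_path = stem.with_name(stem.name + ".json")

    # NIfTI convention: spatial axes first, series axis last
    data = np.moveaxis(series.images, 0, -1)
    img = nib.Nifti1Image(data.astype(np.float64), affine=np.eye(4))
    nib.save(img, nii_path)

    sidecar = {
        "tr_ms": [tr for tr, _ in series.tags],
        "te_ms": [te for _, te in series.tags],
        "grid": series.grid.to_dict(),
        "provenance": series.provenance,
    }
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return nii_path, json_path


def read_series(path: str | Path) -> AcquisitionSeries:
    """Read a series written by :func:`write_series` (stem or either file)."""
    stem = _stem(path)
    nii_path = stem.with_name(stem.name + ".nii.gz")
    if not nii_path.exists():
        nii_path = stem.with_name(stem.name + ".nii")
    json_path = stem.with_name(stem.name + ".json")
    if not nii_path.exists():
        raise FormatError(f"missing NIfTI stack for {stem}")
    if not json_path.exists():
        raise FormatError(f"missing JSON sidecar {json_path}")

    sidecar = json.loads(json_path.read_text())
    for key in ("tr_ms", "te_ms", "grid"):
        if key not in sidecar:
            raise FormatError(f"sidecar {json_path} lacks required key {key!r}")
    data = np.asarray(nib.load(nii_path).get_fdata(), dtype=float)
    images = np.moveaxis(data, -1, 0)
    tags = [
        (float(tr), float(te))
        for tr, te in zip(sidecar["tr_ms"], sidecar["te_ms"])
    ]
    grid = AcquisitionGrid.from_dict(sidecar["grid"])
    return AcquisitionSeries(
        images=images,
        tags=tags,
        grid=grid,
        provenance=sidecar.get("provenance", {}),
    )


def read_dicom_series(directory: str | Path) -> AcquisitionSeries:
    """Read a directory of single-slice DICOM files into a series.

    Every file must carry RepetitionTime and EchoTime. The series mode is
    inferred from which tag varies; images are sorted by the varying tag in
    ascending order (TR for a T1 series, TE for a T2 series).
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FormatError(f"no files in {directory}")

    entries = []
    for f in files:
        ds = pydicom.dcmread(f)
        tr = getattr(ds, "RepetitionTime", None)
        te = getattr(ds, "EchoTime", None)
        if tr is None:
            raise FormatError(f"{f} lacks RepetitionTime (0018,0080)")
        if te is None:
            raise FormatError(f"{f} lacks EchoTime (0018,0081)")
        entries.append((float(tr), float(te), ds.pixel_array.astype(float)))

    trs = sorted({tr for tr, _, _ in entries})
    tes = sorted({te for _, te, _ in entries})
    if len(trs) > 1 and len(tes) == 1:
        mode = SeriesMode.T1_SERIES
        entries.sort(key=lambda e: e[0])
        grid = AcquisitionGrid(mode, tuple(trs), (tes[0],))
    elif len(tes) > 1 and len(trs) == 1:
        mode = SeriesMode.T2_SERIES
        entries.sort(key=lambda e: e[1])
        grid = AcquisitionGrid(mode, (trs[0],), tuple(tes))
    else:
        raise FormatError(
            f"cannot infer series mode in {directory}: "
            f"{len(trs)} distinct TR and {len(tes)} distinct TE values"
        )

    images = np.stack([img for _, _, img in entries])
    tags = [(tr, te) for tr, te, _ in entries]
    return AcquisitionSeries(
        images=images,
        tags=tags,
        grid=grid,
        provenance={"source": "dicom", "directory": str(directory)},
    )


def write_map(path: str | Path, rmap) -> list[Path]:
    """Persist a RelaxationMap as NIfTI volumes (value, R², mask) + JSON meta."""
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    written = []
    volumes = {
        "value": rmap.value_map,
        "r2": rmap.r2_map,
        "mask": rmap.mask.astype(np.uint8),
    }
    for name, vol in volumes.items():
        p = stem.with_name(f"{stem.name}_{name}.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), np.eye(4)), p)
        written.append(p)
    meta_path = stem.with_name(stem.name + "_meta.json")
    meta_path.write_text(
        json.dumps(
            {"kind": rmap.kind, "fit_meta": rmap.fit_meta, "qc": rmap.qc},
            indent=1,
            sort_keys=True,
        )
    )
    written.append(meta_path)
    return written


def export_map_png(path: str | Path, rmap, vmin: float | None = None,
                   vmax: float | None = None) -> Path:
    """Colour-coded relaxation-map panel (viridis ramp, fixed value window).

    The window used is recorded in a JSON sidecar so panels from different
    samples are comparable.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.where(rmap.mask, rmap.value_map, np.nan)
    if vmin is None:
        vmin = float(np.nanmin(data)) if rmap.mask.any() else 0.0
    if vmax is None:
        vmax = float(np.nanmax(data)) if rmap.mask.any() else 1.0
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(data, cmap="viridis", vmin=vmin, vmax=vmax)
    ax.set_title(f"{rmap.kind} map (ms)")
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.8, label="ms")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    path.with_suffix(".json").write_text(
        json.dumps({"kind": rmap.kind, "vmin": vmin, "vmax": vmax})
    )
    return path
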