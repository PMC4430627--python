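"""Volume file IO: MetaImage (.mhd/.raw), multi-page TIFF, DICOM series.

MetaImage is the canonical interchange format (explicit spacing, raw
streamable payload; write→read round-trips are bit-exact).  TIFF and DICOM
are convenience readers.  All spacings are micrometres internally; DICOM
stores millimetres and is converted at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .volume import GreyVolume, LabelVolume, VALID_LABELS

_SPACING_RTOL = 1e-3  # tolerated anisotropy when reading


def _as_volume(data: np.ndarray, spacing: float, origin, kind: str):
    if kind == "labels":
        return LabelVolume(data.astype(np.uint8), spacing, origin)
    if kind == "grey":
        return GreyVolume(data, spacing, origin)
    # auto: small non-negative integers spanning the label set → labels
    if np.issubdtype(data.dtype, np.integer) and data.min() >= 0 and data.max() <= max(VALID_LABELS):
        return LabelVolume(data.astype(np.uint8), spacing, origin)
    return GreyVolume(data.astype(np.float64), spacing, origin)


def _check_isotropic(spacing_zyx) -> float:
    s = np.asarray(spacing_zyx, dtype=float)
    if not np.allclose(s, s[0], rtol=_SPACING_RTOL):
        raise ValueError(f"anisotropic spacing {s.tolist()} not supported")
    return float(s[0])


def read_volume(path, spacing: float | None = None, kind: str = "auto"):
    """Read a volume from MetaImage, TIFF stack, or a DICOM series directory.

    ``spacing`` (µm) overrides/supplies missing metadata; TIFF files without
    spacing metadata require it.  ``kind`` is ``auto`` (labels if the data
    are small non-negative integers), ``grey`` or ``labels``.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path, kind)
    suffix = path.suffix.lower()
    if suffix in (".mhd", ".mha"):
        return _read_metaimage(path, spacing, kind)
    if suffix in (".tif", ".tiff"):
        return _read_tiff(path, spacing, kind)
    raise ValueError(f"unknown volume format: {path}")


def _read_metaimage(path, spacing, kind):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    sp = spacing if spacing is not None else _check_isotropic(img.GetSpacing()[::-1])
    origin = tuple(img.GetOrigin()[::-1])
    return _as_volume(data, sp, origin, kind)


def _read_tiff(path, spacing, kind):
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        if spacing is None:
            meta = tif.imagej_metadata or {}
            if "spacing" in meta:
                spacing = float(meta["spacing"])
    if data.ndim != 3:
        raise ValueError(f"expected a 3D TIFF stack, got shape {data.shape}")
    if spacing is None:
        raise ValueError("TIFF stack has no spacing metadata; pass spacing explicitly")
    return _as_volume(data, spacing, (0.0, 0.0, 0.0), kind)


def _read_dicom_series(path, kind):
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.suffix.lower() in (".dcm", ""))
    slices = []
    for f in files:
        if f.is_file():
            try:
                ds = pydicom.dcmread(str(f))
            except Exception:
                continue
            if hasattr(ds, "PixelData"):
                slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM images found in {path}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    dz = np.diff(zpos)
    if len(dz) and not np.allclose(dz, dz[0], rtol=_SPACING_RTOL):
        raise ValueError("inconsistent DICOM slice spacing")
    px = np.asarray(slices[0].PixelSpacing, dtype=float)
    spacing_mm = np.array([dz[0] if len(dz) else px[0], px[0], px[1]])
    spacing = _check_isotropic(spacing_mm) * 1000.0  # mm → µm
    data = np.stack([ds.pixel_array for ds in slices])
    return _as_volume(data, spacing, (0.0, 0.0, 0.0), kind)


def write_volume(vol, path) -> None:
    """Write to MetaImage (.mhd, little-endian raw) or multi-page TIFF
    (spacing recorded as ImageJ metadata)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".mhd", ".mha"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data))
        img.SetSpacing((vol.spacing,) * 3)
        img.SetOrigin(tuple(vol.origin[::-1]))
        sitk.WriteImage(img, str(path))
    elif suffix in (".tif", ".tiff"):
        import tifffile

        data = vol.data
        if np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)  # ImageJ TIFF has no float64
        elif data.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
            data = data.astype(np.uint16)
        tifffile.imwrite(
            str(path),
            np.ascontiguousarray(data),
            imagej=True,
            metadata={"spacing": vol.spacing, "unit": "um"},
        )
    else:
        raise ValueError(f"unknown volume format: {path}")


def write_phantom(grey, labels, true_contact_fraction, spec, outdir, fmt="mhd") -> None:
    """Write a generated phantom (grey + labels) plus a JSON sidecar with the
    generator parameters and the ground-truth contact fraction."""
    from dataclasses import asdict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".mhd" if fmt == "mhd" else ".tif"
    write_volume(grey, outdir / f"grey{ext}")
    write_volume(labels, outdir / f"labels{ext}")
    sidecar = {
        "spec": asdict(spec),
        "true_contact_fraction": true_contact_fraction,
        "spacing_um": grey.spacing,
    }
    with open(outdir / "phantom.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
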