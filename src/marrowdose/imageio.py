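"""Planar image containers and I/O.

A :class:`PlanarImage` is a 2-D grid of gamma-camera counts plus the
acquisition metadata the conjugate-view method needs (view, time
post-injection, duration, pixel size).  Images are written as TIFF with a
JSON sidecar so they stay human-inspectable; DICOM NM files with
anterior/posterior detectors can be read as well.

Image frame convention: row 0 is cranial and column 0 is the patient's
right side *in the anterior view*.  Posterior images are stored as acquired
and mirrored left-right when combined into a geometric-mean image, so a
focus at column ``c`` in the anterior view sits at column ``width-1-c`` in
the raw posterior grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import PairingError, SchemaError

VIEWS = ("anterior", "posterior")

_SIDECAR_FIELDS = ("view", "time_pi", "duration", "pixel_size")


@dataclass
class PlanarImage:
    """One planar acquisition.

    Parameters
    ----------
    counts
        2-D non-negative grid.  Poisson-noised acquisitions are integer;
        noise-free simulated images carry expected (float) counts.
    view
        ``"anterior"`` or ``"posterior"``.
    time_pi
        Time post-injection in hours.
    duration
        Acquisition duration in seconds.
    pixel_size
        Pixel side in cm (square pixels).
    """

    counts: np.ndarray
    view: str
    time_pi: float
    duration: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise SchemaError("counts must be a 2-D grid")
        if np.any(self.counts < 0):
            raise SchemaError("counts must be non-negative")
        if self.view not in VIEWS:
            raise SchemaError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.duration <= 0:
            raise SchemaError("duration must be positive")
        if self.pixel_size <= 0:
            raise SchemaError("pixel_size must be positive")

    @property
    def rate(self) -> np.ndarray:
        """Count-rate grid (counts/s)."""
        return self.counts / self.duration

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class GeometricMeanImage:
    """Pixelwise sqrt(anterior x mirrored-posterior) count-rate image."""

    values: np.ndarray
    time_pi: float
    pixel_size: float
    duration: float = field(default=0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def geometric_mean(ant: PlanarImage, post: PlanarImage,
                   time_tolerance: float = 0.5) -> GeometricMeanImage:
    """Combine opposed views into a geometric-mean count-rate image.

    The posterior grid is mirrored left-right before combination and both
    images are normalised to count rates by their acquisition durations, so
    acquisitions of different length pair correctly.
    """
    if ant.view != "anterior" or post.view != "posterior":
        raise PairingError("expected one anterior and one posterior image")
    if ant.shape != post.shape:
        raise PairingError(f"shape mismatch: {ant.shape} vs {post.shape}")
    if abs(ant.time_pi - post.time_pi) > time_tolerance:
        raise PairingError(
            f"time mismatch: {ant.time_pi} h vs {post.time_pi} h")
    if abs(ant.pixel_size - post.pixel_size) > 1e-9:
        raise PairingError("pixel size mismatch")
    gm = np.sqrt(ant.rate * post.rate[:, ::-1])
    return GeometricMeanImage(values=gm, time_pi=ant.time_pi,
                              pixel_size=ant.pixel_size,
                              duration=0.5 * (ant.duration + post.duration))


def write_planar(image: PlanarImage, path: str | Path) -> Path:
    """Write a planar image as TIFF plus a JSON metadata sidecar.

    Integer grids are stored as 16- or 32-bit unsigned TIFF; float grids
    (noise-free expected counts) as 32-bit float.  Returns the TIFF path;
    the sidecar sits next to it with suffix ``.json``.
    """
    path = Path(path)
    counts = image.counts
    if np.issubdtype(counts.dtype, np.integer) or np.all(counts == np.round(counts)):
        dtype = np.uint16 if counts.max(initial=0) < 2 ** 16 else np.uint32
        data = counts.astype(dtype)
    else:
        data = counts.astype(np.float32)
    tifffile.imwrite(path, data)
    sidecar = {"view": image.view, "time_pi": image.time_pi,
               "duration": image.duration, "pixel_size": image.pixel_size}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_planar(path: str | Path) -> PlanarImage:
    """Read a TIFF + JSON-sidecar planar image written by :func:`write_planar`."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"image file not found: {path}")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"metadata sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for fld in _SIDECAR_FIELDS:
        if fld not in meta:
            raise SchemaError(f"sidecar missing required field {fld!r}")
    counts = tifffile.imread(path)
    return PlanarImage(counts=counts, view=meta["view"], time_pi=meta["time_pi"],
                       duration=meta["duration"], pixel_size=meta["pixel_size"])


def read_dicom_nm(path: str | Path, time_pi: float | None = None) -> list[PlanarImage]:
    """Read a DICOM NM file with one frame per detector.

    Views are taken from the detector information sequence's view code
    meanings (``Anterior``/``Posterior``), duration from
    ``ActualFrameDuration`` (ms) and pixel size from ``PixelSpacing`` (mm).
    ``time_pi`` overrides the time post-injection when the DICOM timing
    module is absent.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    frames = ds.pixel_array
    if frames.ndim == 2:
        frames = frames[None]
    dets = getattr(ds, "DetectorInformationSequence", None)
    if dets is None or len(dets) != len(frames):
        raise SchemaError("DICOM NM file lacks per-frame detector information")
    duration_s = float(getattr(ds, "ActualFrameDuration", 0)) / 1000.0
    if duration_s <= 0:
        raise SchemaError("DICOM NM file lacks ActualFrameDuration")
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise SchemaError("DICOM NM file lacks PixelSpacing")
    pixel_cm = float(spacing[0]) / 10.0
    if time_pi is None:
        raise SchemaError("time post-injection must be supplied for DICOM input")
    images = []
    for frame, det in zip(frames, dets):
        try:
            meaning = det.ViewCodeSequence[0].CodeMeaning.lower()
        except (AttributeError, IndexError) as exc:
            raise SchemaError("detector lacks a view code") from exc
        if "ant" in meaning:
            view = "anterior"
        elif "post" in meaning:
            view = "posterior"
        else:
            raise SchemaError(f"unrecognised view code meaning {meaning!r}")
        images.append(PlanarImage(counts=np.asarray(frame), view=view,
                                  time_pi=time_pi, duration=duration_s,
                                  pixel_size=pixel_cm))
    return images
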