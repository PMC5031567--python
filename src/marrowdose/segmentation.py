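"""Automated two-compartment segmentation of geometric-mean images.

The whole-body region of interest comes from a low-pass-filtered copy of
the geometric-mean image (order-2 radial Butterworth, cutoff 0.03
cycles/pixel): the largest connected component above a contour level, holes
filled, transposed back onto the *unfiltered* image for everything
downstream.

Inside the body the uptake is split into high and low compartments by a
threshold sweep: for every distinct pixel value ``C_thr`` from the maximum
``C_max`` down to 0, pixels >= C_thr are binarised and connected uptake
foci counted (NUF).  Expressed against the threshold index

    ThI = (C_max - C_thr) / C_max

the focus count rises gently while real organs appear, then explodes once
noise speckle is included.  The normalised count nNUF = NUF/max(NUF)
crosses a cutoff (default 0.1) just before that explosion; the chosen
``C_thr`` is the largest threshold with nNUF >= cutoff, and pixels at or
above it form the high-uptake compartment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError, SegmentationError
from .imageio import GeometricMeanImage

#: 8-connectivity structuring element (standard for blob counting on
#: planar scintigrams); 4-connectivity available via ``connectivity=4``
_STRUCTS = {4: ndimage.generate_binary_structure(2, 1),
            8: ndimage.generate_binary_structure(2, 2)}


def _values(image) -> np.ndarray:
    return image.values if isinstance(image, GeometricMeanImage) else np.asarray(image)


def lowpass_filter(image, order: int = 2, cutoff: float = 0.03,
                   clip_negative: bool = False):
    """Radially symmetric Butterworth low-pass filter in the frequency domain.

    Gain is ``1 / (1 + (rho/cutoff)**(2*order))`` with ``rho`` the radial
    spatial frequency in cycles/pixel (0.5 = Nyquist), so the gain at the
    cutoff is exactly 0.5 and the DC gain exactly 1 (image sum preserved).
    Negative ringing is kept by default so the sum is preserved;
    ``clip_negative`` floors the output at 0.
    """
    if not (0 < cutoff <= 0.5):
        raise ParameterError("cutoff must be in (0, 0.5] cycles/pixel")
    if order < 1:
        raise ParameterError("order must be >= 1")
    vals = _values(image)
    if vals.size == 0:
        raise ParameterError("image is empty")
    fr = np.fft.fftfreq(vals.shape[0])[:, None]
    fc = np.fft.fftfreq(vals.shape[1])[None, :]
    rho = np.hypot(fr, fc)
    gain = 1.0 / (1.0 + (rho / cutoff) ** (2 * order))
    out = np.real(np.fft.ifft2(np.fft.fft2(vals) * gain))
    if clip_negative:
        out = np.clip(out, 0.0, None)
    if isinstance(image, GeometricMeanImage):
        return GeometricMeanImage(values=out, time_pi=image.time_pi,
                                  pixel_size=image.pixel_size,
                                  duration=image.duration)
    return out


def whole_body_roi(filtered_image, level_fraction: float | None = None) -> np.ndarray:
    """Whole-body mask from a filtered image via a contour-line threshold.

    By default the contour level is half the body-plateau estimate (the
    median of filtered values above 2% of the maximum): the low-pass blur
    turns the body edge into a smooth ramp that crosses half its plateau at
    the true boundary, so this contour hugs the body instead of including
    the blur halo.  Pass ``level_fraction`` to use a plain fraction of the
    filtered maximum instead.  The largest connected component above the
    level is kept and its holes filled.
    """
    vals = _values(filtered_image)
    if vals.size == 0 or np.nanmax(vals) <= 0:
        raise SegmentationError("filtered image has no positive values")
    if level_fraction is None:
        rough = vals >= 0.02 * np.nanmax(vals)
        level = 0.5 * float(np.median(vals[rough]))
    else:
        level = level_fraction * float(np.nanmax(vals))
    above = vals >= level
    labels, n = ndimage.label(above, structure=_STRUCTS[8])
    if n == 0:
        raise SegmentationError("no connected region above the contour level")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    body = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(body)


def count_foci(values: np.ndarray, mask: np.ndarray, threshold: float,
               connectivity: int = 8) -> int:
    """Number of connected uptake foci with value >= threshold inside mask."""
    binary = mask & (values >= threshold)
    _, n = ndimage.label(binary, structure=_STRUCTS[connectivity])
    return int(n)


@dataclass
class NufCurve:
    """Focus count versus threshold over the full sweep.

    Thresholds run over every distinct pixel value in the body (descending,
    0 always included); for integer images this carries exactly the
    information of the per-integer sweep, which :meth:`at_integer_thresholds`
    reconstructs (NUF is constant between consecutive distinct values).
    """

    thresholds: np.ndarray               # C_thr, descending
    thi: np.ndarray                      # (C_max - C_thr)/C_max
    nuf: np.ndarray                      # connected foci count
    nnuf: np.ndarray                     # NUF / max(NUF)
    c_max: float
    connectivity: int = 8

    def at_integer_thresholds(self) -> tuple[np.ndarray, np.ndarray]:
        """(thresholds, NUF) at every integer from floor(C_max) down to 0."""
        ints = np.arange(int(np.floor(self.c_max)), -1, -1)
        # mask {v >= t} equals mask {v >= u_j} for the smallest distinct
        # value u_j >= t; searchsorted on the ascending threshold list
        asc = self.thresholds[::-1]
        idx = np.searchsorted(asc, ints, side="left")
        nuf = np.where(idx < asc.size, self.nuf[::-1][np.minimum(idx, asc.size - 1)], 0)
        return ints, nuf.astype(int)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"c_thr": self.thresholds, "thi": self.thi,
                             "nuf": self.nuf, "nnuf": self.nnuf})


def nuf_curve(gm_image, body_mask: np.ndarray, connectivity: int = 8,
              merge_rtol: float = 1e-9) -> NufCurve:
    """Sweep all thresholds and count connected uptake foci at each.

    Pixel values closer than ``merge_rtol * C_max`` are treated as one
    threshold (guards float round-off; a no-op for integer count grids).
    """
    vals = _values(gm_image)
    if not body_mask.any():
        raise SegmentationError("body mask is empty")
    in_body = vals[body_mask]
    c_max = float(in_body.max())
    if c_max <= 0:
        raise SegmentationError("no positive counts inside the body")
    uniq = np.unique(in_body)[::-1]                  # descending
    # merge near-equal values, keeping the smallest of each group so the
    # threshold includes every pixel of the group
    merged = []
    group_min = uniq[0]
    for v in uniq[1:]:
        if group_min - v <= merge_rtol * c_max:
            group_min = v
        else:
            merged.append(group_min)
            group_min = v
    merged.append(group_min)
    thresholds = np.asarray(merged)
    if thresholds[-1] > 0:
        thresholds = np.append(thresholds, 0.0)
    nuf = np.asarray([count_foci(vals, body_mask, t, connectivity)
                      for t in thresholds])
    thi = (c_max - thresholds) / c_max
    return NufCurve(thresholds=thresholds, thi=thi, nuf=nuf,
                    nnuf=nuf / nuf.max(), c_max=c_max, connectivity=connectivity)


@dataclass
class CompartmentMasks:
    """Body partition into high- and low-uptake compartments."""

    body: np.ndarray
    high: np.ndarray
    low: np.ndarray
    nnuf_cutoff: float
    c_thr: float
    curve: NufCurve | None = field(default=None, repr=False)


def compartment_masks(gm_image, body_mask: np.ndarray,
                      nnuf_cutoff: float = 0.1,
                      connectivity: int = 8) -> CompartmentMasks:
    """Split the body into high/low compartments at the nNUF cutoff.

    The chosen ``C_thr`` is the largest threshold on the rising flank of
    the sweep's focus-count maximum with nNUF >= cutoff: walking up in
    threshold from the maximum (where noise speckle dominates), the last
    threshold before nNUF drops below the cutoff — i.e. the last threshold
    before the focus count explodes into noise.  Anchoring the crossing to
    the flank of the global maximum ignores small secondary humps from
    speckle inside the hot organs themselves.  When the curve never reaches
    the cutoff the threshold falls back to ``C_max`` with a warning
    (single-pixel high compartment); when the chosen threshold captures the
    entire body (an image with no high-uptake contrast) the high
    compartment degenerates to empty with a warning.
    """
    curve = nuf_curve(gm_image, body_mask, connectivity=connectivity)
    candidates = np.nonzero(curve.nnuf >= nnuf_cutoff)[0]
    if candidates.size:
        # thresholds descend; walk from the first (largest-threshold) index
        # attaining the maximum toward larger thresholds while the curve
        # stays at or above the cutoff
        j = int(np.argmax(curve.nuf))
        while j > 0 and curve.nnuf[j - 1] >= nnuf_cutoff:
            j -= 1
        c_thr = float(curve.thresholds[j])
    else:
        warnings.warn("nNUF never reaches the cutoff; falling back to C_max")
        c_thr = curve.c_max
    vals = _values(gm_image)
    high = body_mask & (vals >= c_thr)
    if high.sum() == body_mask.sum():
        warnings.warn("no high-uptake contrast: high compartment degenerates "
                      "to empty")
        high = np.zeros_like(body_mask)
    low = body_mask & ~high
    return CompartmentMasks(body=body_mask, high=high, low=low,
                            nnuf_cutoff=nnuf_cutoff, c_thr=c_thr, curve=curve)


#: contour-filter cutoff in physical units: 0.125 cycles/cm equals the
#: 0.03 cycles/pixel of typical ~2.4 mm whole-body scintigram pixels
CONTOUR_CUTOFF_CYCLES_PER_CM = 0.125


def segment(gm_image, nnuf_cutoff: float = 0.1, order: int = 2,
            cutoff: float | None = None, level_fraction: float | None = None,
            connectivity: int = 8) -> CompartmentMasks:
    """Full segmentation: filter -> body ROI -> threshold sweep -> masks.

    The body-contour filter cutoff defaults to 0.125 cycles/cm converted to
    cycles/pixel via the image pixel size (capped at 0.45), so the amount of
    physical smoothing is pixel-size independent; pass ``cutoff`` (in
    cycles/pixel) to override.  The threshold sweep itself always runs on
    the unfiltered image.
    """
    if cutoff is None:
        pixel = getattr(gm_image, "pixel_size", 1.0)
        cutoff = min(CONTOUR_CUTOFF_CYCLES_PER_CM * pixel, 0.45)
    filtered = lowpass_filter(gm_image, order=order, cutoff=cutoff)
    body = whole_body_roi(filtered, level_fraction=level_fraction)
    return compartment_masks(gm_image, body, nnuf_cutoff=nnuf_cutoff,
                             connectivity=connectivity)
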