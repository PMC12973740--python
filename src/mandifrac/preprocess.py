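"""Trabecular ROI preprocessing (Rudolph-White chain).

Turns a 64x64 greyscale region of interest cropped from a panoramic
radiograph into a skeletonized binary trabecular pattern, through the
classic sequence used for dental fractal analysis:

1. estimate the low-frequency brightness background with a wide Gaussian
   blur (sigma = 35 px), which captures soft-tissue / bone-thickness
   shading but none of the trabecular texture;
2. subtract the background from the original and re-centre at grey 128,
   so flat regions sit exactly at mid-grey;
3. binarize at threshold 128 (values >= 128 are white);
4. morphologically open (erode then dilate, 3x3 square) the white phase
   to suppress single-pixel radiographic noise;
5. invert, so the originally dark (trabecular) phase becomes foreground;
6. thin the foreground to a one-pixel-wide, 8-connected skeleton.

Each binary stage is tagged and the stage order is enforced: calling an
operation on a patch in the wrong stage raises
:class:`~mandifrac.errors.PipelineOrderError` instead of silently
producing a plausible-looking pattern.

Conventions fixed here (the chain's published description leaves them
open): threshold ties go to white, because after step 2 flat background
sits exactly at 128; the Gaussian uses reflective padding so a 64 px
patch is not darkened at its borders by a sigma that exceeds the patch
size; rounding after subtraction is half-away-from-zero, matching 8-bit
integer pipelines; erosion pads with white and dilation with black, so
an all-white patch survives opening unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import (
    DimensionError,
    InvalidParameterError,
    PipelineOrderError,
    RoiBoundsError,
)

__all__ = [
    "GreyPatch",
    "BinaryPatch",
    "RoiSpec",
    "PreprocessResult",
    "Stage",
    "crop_roi",
    "gaussian_background",
    "subtract_offset",
    "binarize",
    "morpho_clean",
    "invert",
    "skeletonize",
    "preprocess",
]

REGIONS = ("anterior", "premolar", "molar")
SIDES = ("right", "left")


class Stage:
    """Tags for the binary pipeline stages, in required order."""

    THRESHOLDED = "thresholded"
    CLEANED = "cleaned"
    INVERTED = "inverted"
    SKELETONIZED = "skeletonized"
    SYNTHETIC = "synthetic"  # generator output, not yet in the chain

    ORDER = (THRESHOLDED, CLEANED, INVERTED, SKELETONIZED)


@dataclass
class GreyPatch:
    """Square 8-bit greyscale pixel grid, the unit of texture analysis."""

    pixels: np.ndarray
    provenance: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise InvalidParameterError(
                f"GreyPatch requires a 2-D grid, got ndim={arr.ndim}"
            )
        if arr.dtype != np.uint8:
            if np.any((arr < 0) | (arr > 255)):
                raise InvalidParameterError(
                    "grey values must lie in [0, 255]"
                )
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryPatch:
    """Boolean pixel grid with a pipeline stage tag."""

    pixels: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise InvalidParameterError(
                f"BinaryPatch requires a 2-D grid, got ndim={arr.ndim}"
            )
        self.pixels = arr.astype(bool)
        valid = Stage.ORDER + (Stage.SYNTHETIC,)
        if self.stage not in valid:
            raise InvalidParameterError(
                f"unknown stage {self.stage!r}; expected one of {valid}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def foreground_fraction(self) -> float:
        return float(self.pixels.mean())


@dataclass(frozen=True)
class RoiSpec:
    """Placement of one region of interest in a source radiograph."""

    region: str
    side: str
    origin: tuple[int, int]  # (row, col), 0-based top-left
    size: int = 64

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise InvalidParameterError(
                f"region must be one of {REGIONS}, got {self.region!r}"
            )
        if self.side not in SIDES:
            raise InvalidParameterError(
                f"side must be one of {SIDES}, got {self.side!r}"
            )
        if self.size < 1:
            raise InvalidParameterError("ROI size must be positive")


@dataclass
class PreprocessResult:
    """Output of the full chain plus an audit trail.

    ``foreground_fractions`` records the white/foreground fraction after
    each stage so users can audit which phase is being analysed;
    ``degenerate`` is set when the patch carried no texture (constant
    input, empty or full threshold result) and the skeleton must not be
    fed to a fractal estimator.
    """

    skeleton: BinaryPatch
    foreground_fractions: dict = field(default_factory=dict)
    degenerate: bool = False


def _require_stage(patch: BinaryPatch, expected: str, op: str) -> None:
    if patch.stage != expected:
        raise PipelineOrderError(
            f"{op} expects a {expected!r}-stage patch, got {patch.stage!r}"
        )


def crop_roi(image: np.ndarray | GreyPatch, roi: RoiSpec) -> GreyPatch:
    """Extract the exact ROI sub-grid; no resampling.

    Raises :class:`RoiBoundsError` naming the offending coordinate when
    the ROI is not fully inside the image.
    """
    arr = image.pixels if isinstance(image, GreyPatch) else np.asarray(image)
    r0, c0 = roi.origin
    r1, c1 = r0 + roi.size, c0 + roi.size
    h, w = arr.shape
    if r0 < 0 or c0 < 0:
        raise RoiBoundsError(f"ROI origin {roi.origin} has a negative coordinate")
    if r1 > h:
        raise RoiBoundsError(
            f"ROI bottom row {r1} exceeds image height {h} (origin row {r0})"
        )
    if c1 > w:
        raise RoiBoundsError(
            f"ROI right column {c1} exceeds image width {w} (origin col {c0})"
        )
    src = None
    if isinstance(image, GreyPatch):
        src = image.provenance
    prov = f"{src or 'image'}[{r0}:{r1},{c0}:{c1}] {roi.region}/{roi.side}"
    return GreyPatch(arr[r0:r1, c0:c1].copy(), provenance=prov)


def gaussian_background(patch: GreyPatch, sigma: float = 35.0) -> np.ndarray:
    """Low-frequency brightness estimate: Gaussian blur, reflective padding.

    Returns a float grid; a constant input maps to the same constant and
    the kernel is normalized (mass conserving under reflection).
    """
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
    return ndimage.gaussian_filter(
        patch.pixels.astype(np.float64), sigma=sigma, mode="reflect"
    )


def subtract_offset(
    original: GreyPatch, blurred: np.ndarray, offset: int = 128
) -> GreyPatch:
    """original - blurred + offset, rounded half-away-from-zero, clamped."""
    blurred = np.asarray(blurred, dtype=np.float64)
    if blurred.shape != original.shape:
        raise DimensionError(
            f"shape mismatch: original {original.shape}, blurred {blurred.shape}"
        )
    diff = original.pixels.astype(np.float64) - blurred + float(offset)
    rounded = np.trunc(diff + np.copysign(0.5, diff))
    return GreyPatch(
        np.clip(rounded, 0, 255).astype(np.uint8),
        provenance=original.provenance,
    )


def binarize(patch: GreyPatch, threshold: int = 128) -> BinaryPatch:
    """Threshold at ``threshold``; ties (value == threshold) go to white."""
    return BinaryPatch(patch.pixels >= threshold, stage=Stage.THRESHOLDED)


_SE3 = np.ones((3, 3), dtype=bool)


def morpho_clean(patch: BinaryPatch) -> BinaryPatch:
    """One 3x3 erosion then one 3x3 dilation (opening) on the white phase.

    Erosion pads with white, dilation with black, so an all-white patch
    is preserved while isolated speckle (anything thinner than 3 px) is
    removed.
    """
    _require_stage(patch, Stage.THRESHOLDED, "morpho_clean")
    eroded = ndimage.binary_erosion(patch.pixels, structure=_SE3, border_value=1)
    opened = ndimage.binary_dilation(eroded, structure=_SE3, border_value=0)
    return BinaryPatch(opened, stage=Stage.CLEANED)


def invert(patch: BinaryPatch) -> BinaryPatch:
    """Logical complement; foreground becomes the originally dark phase."""
    _require_stage(patch, Stage.CLEANED, "invert")
    return BinaryPatch(~patch.pixels, stage=Stage.INVERTED)


_NEIGHBOUR_OFFSETS = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


def _break_2x2_blocks(pixels: np.ndarray) -> np.ndarray:
    """Delete one simple pixel from every remaining 2x2 foreground block.

    Zhang-Suen thinning can leave 2x2 staircase blocks; a pixel is
    removable without changing local topology when its 8-neighbourhood
    has exactly one 0->1 transition (crossing number 1). Pixels are
    removed in scan order until no block remains; if a block has no
    simple pixel its top-left corner is removed (last resort, keeps
    termination guaranteed).
    """
    out = np.pad(pixels.copy(), 1)

    def crossing_number(r: int, c: int) -> int:
        ring = [out[r + dr, c + dc] for dr, dc in _NEIGHBOUR_OFFSETS]
        return sum(
            (not a) and b for a, b in zip(ring, ring[1:] + ring[:1])
        )

    while True:
        core = out[1:-1, 1:-1]
        blocks = core[:-1, :-1] & core[1:, :-1] & core[:-1, 1:] & core[1:, 1:]
        coords = np.argwhere(blocks)
        if coords.size == 0:
            break
        progressed = False
        for r0, c0 in coords:
            r0, c0 = int(r0) + 1, int(c0) + 1
            corners = [(r0, c0), (r0, c0 + 1), (r0 + 1, c0), (r0 + 1, c0 + 1)]
            if not all(out[r, c] for r, c in corners):
                continue  # already broken by an earlier deletion
            for r, c in corners:
                if crossing_number(r, c) == 1:
                    out[r, c] = False
                    progressed = True
                    break
            else:
                out[r0, c0] = False
                progressed = True
        if not progressed:  # pragma: no cover - termination safety net
            break
    return out[1:-1, 1:-1]


def skeletonize(patch: BinaryPatch) -> BinaryPatch:
    """Thin the foreground to a 1 px wide, 8-connected skeleton.

    Zhang-Suen-type iterative thinning followed by a block-breaking
    pass, repeated to a fixed point: the result is a subset of the
    input foreground, contains no 2x2 all-foreground block, and is
    idempotent by construction.
    """
    _require_stage(patch, Stage.INVERTED, "skeletonize")
    current = patch.pixels
    while True:
        thinned = _break_2x2_blocks(_sk_skeletonize(current, method="zhang"))
        if np.array_equal(thinned, current):
            break
        current = thinned
    return BinaryPatch(current, stage=Stage.SKELETONIZED)


def preprocess(
    patch: GreyPatch,
    *,
    sigma: float = 35.0,
    offset: int = 128,
    threshold: int = 128,
) -> PreprocessResult:
    """Run the full chain and report per-stage foreground fractions.

    A patch whose thresholded stage is constant (all white or all black)
    carries no trabecular texture; the result is flagged ``degenerate``
    and downstream fractal estimation must refuse it rather than return
    a silent FD.
    """
    background = gaussian_background(patch, sigma=sigma)
    flattened = subtract_offset(patch, background, offset=offset)
    thresholded = binarize(flattened, threshold=threshold)
    fractions = {"thresholded": thresholded.foreground_fraction()}
    degenerate = fractions["thresholded"] in (0.0, 1.0)
    cleaned = morpho_clean(thresholded)
    fractions["cleaned"] = cleaned.foreground_fraction()
    inverted = invert(cleaned)
    fractions["inverted"] = inverted.foreground_fraction()
    skeleton = skeletonize(inverted)
    fractions["skeletonized"] = skeleton.foreground_fraction()
    if fractions["skeletonized"] in (0.0, 1.0):
        degenerate = True
    return PreprocessResult(
        skeleton=skeleton,
        foreground_fractions=fractions,
        degenerate=degenerate,
    )
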