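"""Core myelin-wrapping scoring for pillar arrays.

For every pillar cross-section a 1-pixel external outline is traced and
compared to the myelin mask to measure the fraction of the circumference
ensheathed.  A pillar is "fully wrapped" when it carries a contiguous
axial segment longer than 6 µm in which every slice exceeds 80%
circumferential coverage; the wrapping index (WI) of a field is the number
of fully wrapped pillars divided by the number of cell nuclei.

Conventions, fixed here and surfaced as parameters:

* coverage thresholds are strict (``> 0.8``, ``> 6 µm``), exactly as the
  classification rule is stated;
* a segment of n qualifying adjacent slices has length ``n * z_step`` (each
  slice owns one z-step of height), so at a 2 µm step ">6 µm" requires at
  least 4 adjacent qualifying slices.  The alternative ``(n-1) * z_step``
  convention is selectable but non-default;
* myelin counts as covering an outline pixel when it lies within
  ``contact_radius_px`` (Chebyshev distance, default 1) of it, tolerating
  one pixel of thresholding erosion without crediting distant MBP+ somata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .stack_io import ImageStack
from . import segmentation as seg

THETA_C_DEFAULT = 0.8  # coverage fraction a slice must exceed
L_MIN_UM_DEFAULT = 6.0  # sheath length (µm) a pillar must exceed

_OFFSETS8 = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.intp,
)


class WrappingError(ValueError):
    pass


@dataclass
class WrapProfile:
    """Per-slice circumference-coverage fractions for one pillar."""

    pillar_id: int
    coverage: np.ndarray  # one value per z slice, in [0, 1]
    z_step_um: float

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.coverage.ndim != 1:
            raise WrappingError("coverage must be 1-D (one value per slice)")
        if np.any((self.coverage < 0) | (self.coverage > 1)):
            raise WrappingError("coverage values must lie in [0, 1]")
        if self.z_step_um <= 0:
            raise WrappingError("z_step_um must be > 0")


@dataclass(frozen=True)
class SheathSegment:
    """A maximal run of adjacent qualifying slices."""

    slice_start: int
    slice_end: int  # inclusive
    length_um: float


@dataclass
class FieldMetrics:
    """Per-field wrapping summary plus the per-pillar table."""

    n_pillars: int
    n_fully_wrapped: int
    n_nuclei: int
    wi: float  # NaN when undefined (no nuclei)
    wi_valid: bool
    sheath_lengths_um: list[float]  # max contiguous sheath per wrapped pillar
    per_pillar: pd.DataFrame = field(repr=False, default=None)
    field_id: str = ""
    well_id: str = ""
    condition: str = ""


@dataclass
class QuantParams:
    """Everything tunable between raw stack and FieldMetrics."""

    axon_threshold: str = "otsu"
    myelin_threshold: str = "mad:6"  # sparse channel: robust background rule
    nuclei_threshold: str = "mad:6"
    min_pillar_area_px: int = 30
    max_link_dist_px: float | None = None  # default: 10 px
    border_policy: Literal["exclude", "keep"] = "exclude"
    min_presence: float = 0.5
    nuclei_min_diameter_um: float = 4.0
    theta_c: float = THETA_C_DEFAULT
    l_min_um: float = L_MIN_UM_DEFAULT
    contact_radius_px: int = 1
    length_convention: Literal["slices", "gaps"] = "slices"


def max_run_length(qualifies: Sequence[bool] | np.ndarray) -> int:
    """Length (in slices) of the longest run of True values."""
    best = cur = 0
    for q in np.asarray(qualifies, dtype=bool):
        cur = cur + 1 if q else 0
        best = max(best, cur)
    return best


def trace_outline(cross_section: np.ndarray) -> np.ndarray:
    """External 1-pixel outline of a cross-section, as set algebra.

    ``cross_section`` is either an (N, 2) array of (y, x) pixel coordinates
    or a 2-D boolean mask.  Returns the (M, 2) sorted array of pixels
    8-adjacent to the set but not in it.  No image bounds are applied; the
    caller clips if needed.
    """
    cs = np.asarray(cross_section)
    if cs.ndim == 2 and cs.dtype == bool:
        cs = np.argwhere(cs)
    if cs.size == 0:
        raise WrappingError("cannot trace the outline of an empty cross-section")
    cs = cs.astype(np.intp)
    # set algebra on a local bitmap: dilate by the 3x3 footprint, subtract
    y0, x0 = cs.min(axis=0) - 1
    local = np.zeros((cs[:, 0].max() - y0 + 2, cs[:, 1].max() - x0 + 2), dtype=bool)
    local[cs[:, 0] - y0, cs[:, 1] - x0] = True
    ring = binary_dilation(local, structure=np.ones((3, 3), dtype=bool)) & ~local
    out = np.argwhere(ring)
    out[:, 0] += y0
    out[:, 1] += x0
    return out


def dilate_mask(mask2d: np.ndarray, contact_radius_px: int) -> np.ndarray:
    """Chebyshev dilation of a binary image by ``contact_radius_px``."""
    if contact_radius_px <= 0:
        return mask2d.astype(bool)
    size = 2 * contact_radius_px + 1
    return binary_dilation(mask2d, structure=np.ones((size, size), dtype=bool))


def wrap_fraction(
    outline: np.ndarray,
    myelin_slice: np.ndarray,
    contact_radius_px: int = 1,
    _dilated: np.ndarray | None = None,
) -> float:
    """Fraction of outline pixels whose neighborhood intersects the myelin mask.

    An outline pixel counts as covered when any myelin pixel lies within the
    ``(2*contact_radius_px + 1)``-square centred on it.  Outline pixels
    outside the image count as uncovered.
    """
    outline = np.asarray(outline, dtype=np.intp)
    if outline.size == 0:
        raise WrappingError("outline is empty")
    dil = _dilated if _dilated is not None else dilate_mask(myelin_slice, contact_radius_px)
    h, w = dil.shape
    ok = (
        (outline[:, 0] >= 0)
        & (outline[:, 0] < h)
        & (outline[:, 1] >= 0)
        & (outline[:, 1] < w)
    )
    covered = np.zeros(len(outline), dtype=bool)
    covered[ok] = dil[outline[ok, 0], outline[ok, 1]]
    return float(covered.sum() / len(outline))


def wrap_fraction_bins(
    outline: np.ndarray,
    centroid: tuple[float, float],
    myelin_slice: np.ndarray,
    contact_radius_px: int = 1,
    n_bins: int = 36,
) -> float:
    """Angular-bin variant of the coverage fraction, for cross-checking.

    The outline is divided into ``n_bins`` angular bins around the centroid;
    a bin counts as covered when more than half of its outline pixels are
    myelin-covered.  Not the scored quantity.
    """
    outline = np.asarray(outline, dtype=np.intp)
    dil = dilate_mask(myelin_slice, contact_radius_px)
    h, w = dil.shape
    ang = np.arctan2(outline[:, 0] - centroid[0], outline[:, 1] - centroid[1]) % (2 * math.pi)
    bins = np.minimum((ang / (2 * math.pi) * n_bins).astype(int), n_bins - 1)
    ok = (
        (outline[:, 0] >= 0) & (outline[:, 0] < h)
        & (outline[:, 1] >= 0) & (outline[:, 1] < w)
    )
    covered = np.zeros(len(outline), dtype=bool)
    covered[ok] = dil[outline[ok, 0], outline[ok, 1]]
    present = np.bincount(bins, minlength=n_bins)
    hit = np.bincount(bins, weights=covered, minlength=n_bins)
    nonempty = present > 0
    return float(np.mean(hit[nonempty] / present[nonempty] > 0.5))


def sheath_segments(
    profile: WrapProfile,
    theta_c: float = THETA_C_DEFAULT,
    length_convention: Literal["slices", "gaps"] = "slices",
) -> list[SheathSegment]:
    """Maximal runs of consecutive slices with coverage strictly above theta_c."""
    q = profile.coverage > theta_c
    segments: list[SheathSegment] = []
    start = None
    for z, flag in enumerate(q):
        if flag and start is None:
            start = z
        elif not flag and start is not None:
            segments.append(_make_segment(start, z - 1, profile.z_step_um, length_convention))
            start = None
    if start is not None:
        segments.append(_make_segment(start, len(q) - 1, profile.z_step_um, length_convention))
    return segments


def _make_segment(
    start: int, end: int, z_step_um: float, convention: str
) -> SheathSegment:
    n = end - start + 1
    length = n * z_step_um if convention == "slices" else (n - 1) * z_step_um
    return SheathSegment(slice_start=start, slice_end=end, length_um=length)


def classify_fully_wrapped(
    profile: WrapProfile,
    theta_c: float = THETA_C_DEFAULT,
    l_min_um: float = L_MIN_UM_DEFAULT,
    length_convention: Literal["slices", "gaps"] = "slices",
) -> bool:
    """True iff the longest qualifying sheath is strictly longer than l_min_um."""
    segs = sheath_segments(profile, theta_c, length_convention)
    if not segs:
        return False
    return max(s.length_um for s in segs) > l_min_um


def wrapping_index(n_fully_wrapped: int, n_nuclei: int) -> float:
    """WI = fully wrapped pillars / nuclei.  Undefined without nuclei."""
    if n_nuclei <= 0:
        raise WrappingError(
            "wrapping index undefined for a field with no nuclei; "
            "flag the field and exclude it from aggregation"
        )
    if not (0 <= n_fully_wrapped):
        raise WrappingError("n_fully_wrapped must be >= 0")
    return n_fully_wrapped / n_nuclei


def compute_field_metrics(stack: ImageStack, params: QuantParams | None = None) -> FieldMetrics:
    """Full per-field pipeline: threshold -> detect -> score -> WI.

    The myelin and nuclei channels fall back to an empty mask when they are
    constant (no signal at all); a constant axon channel is an error since
    nothing can be scored without pillars.  A field with no countable nuclei
    gets ``wi = NaN`` and ``wi_valid = False`` so aggregation can exclude it.
    """
    p = params or QuantParams()
    axon_mask, axon_rec = seg.threshold_channel(stack, "axon", p.axon_threshold)
    try:
        myelin_mask, myelin_rec = seg.threshold_channel(stack, "myelin", p.myelin_threshold)
    except seg.ThresholdError:
        myelin_mask, myelin_rec = np.zeros_like(axon_mask), ("constant-empty", math.nan)
    try:
        nuclei_mask, nuclei_rec = seg.threshold_channel(stack, "nuclei", p.nuclei_threshold)
    except seg.ThresholdError:
        nuclei_mask, nuclei_rec = np.zeros_like(axon_mask), ("constant-empty", math.nan)
    seg.BinaryMasks(axon_mask, myelin_mask, nuclei_mask,
                    {"axon": axon_rec, "myelin": myelin_rec, "nuclei": nuclei_rec})

    link_dist = p.max_link_dist_px if p.max_link_dist_px is not None else 10.0
    traces = seg.detect_pillars(
        axon_mask,
        min_area_px=p.min_pillar_area_px,
        max_link_dist_px=link_dist,
        border_policy=p.border_policy,
        min_presence=p.min_presence,
    )

    n_slices = stack.n_slices
    dilated = [dilate_mask(myelin_mask[z], p.contact_radius_px) for z in range(n_slices)]

    rows = []
    sheath_lengths: list[float] = []
    n_wrapped = 0
    for tr in traces:
        coverage = np.zeros(n_slices)
        for e in tr.entries:
            outline = trace_outline(e.pixels)
            coverage[e.z] = wrap_fraction(
                outline, myelin_mask[e.z], p.contact_radius_px, _dilated=dilated[e.z]
            )
        profile = WrapProfile(tr.pillar_id, coverage, stack.z_step_um)
        segs = sheath_segments(profile, p.theta_c, p.length_convention)
        max_seg = max((s.length_um for s in segs), default=0.0)
        wrapped = max_seg > p.l_min_um
        if wrapped:
            n_wrapped += 1
            sheath_lengths.append(max_seg)
        rows.append(
            {
                "pillar_id": tr.pillar_id,
                "centroid_y_px": tr.first_centroid()[0],
                "centroid_x_px": tr.first_centroid()[1],
                "diameter_um": seg.measure_diameter(tr, stack.pixel_size_um),
                "max_segment_um": max_seg,
                "fully_wrapped": wrapped,
            }
        )
    per_pillar = pd.DataFrame(
        rows,
        columns=["pillar_id", "centroid_y_px", "centroid_x_px",
                 "diameter_um", "max_segment_um", "fully_wrapped"],
    )

    min_area = seg.default_nuclei_min_area_px(stack.pixel_size_um, p.nuclei_min_diameter_um)
    n_nuclei = seg.count_nuclei(nuclei_mask, min_area_px=min_area)
    if n_nuclei > 0:
        wi, wi_valid = wrapping_index(n_wrapped, n_nuclei), True
    else:
        wi, wi_valid = math.nan, False

    return FieldMetrics(
        n_pillars=len(traces),
        n_fully_wrapped=n_wrapped,
        n_nuclei=n_nuclei,
        wi=wi,
        wi_valid=wi_valid,
        sheath_lengths_um=sheath_lengths,
        per_pillar=per_pillar,
        field_id=stack.field_id,
        well_id=stack.well_id,
        condition=stack.condition,
    )
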