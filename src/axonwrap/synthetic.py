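"""Synthetic confocal fields, photomasks and AFM curves with exact ground truth.

The generator emulates the imaging scenario the pipeline is built for:
vertical hydrogel micropillars ("artificial axons") on a square grid,
imaged top-down as a short confocal z-stack (default 8 slices at a 2 µm
step with a 20x-class 0.31 µm/px calibration).  Myelin is rendered as an
annular arc hugging each pillar's circumference over a contiguous run of
slices, with a controlled angular coverage — the quantity the wrapping
pipeline must recover.  Nuclei are scattered blobs in the inter-pillar
space.  Blur and noise are applied after rasterization, and the ground
truth (per-slice coverage, sheath run lengths, fully-wrapped flags and the
expected wrapping index) is computed analytically from the field spec, so
every downstream stage can be verified without experimental data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .mechanics import ForceCurve, hertz_force
from .stack_io import ImageStack

# rendered intensities, arbitrary 8-bit-like units
BACKGROUND = 10.0
AXON_INTENSITY = 180.0
MYELIN_INTENSITY = 200.0
NUCLEI_INTENSITY = 160.0
DYNAMIC_RANGE = 255.0

# classification thresholds mirrored from the wrapping module defaults
from .wrapping import THETA_C_DEFAULT, L_MIN_UM_DEFAULT, max_run_length


class GeometryError(ValueError):
    """Raised when requested geometry cannot be rendered without overlap."""


@dataclass(frozen=True)
class WrapEvent:
    """A contiguous myelin sheath on one pillar.

    ``slice_start``/``slice_end`` are inclusive z indices; ``angular_coverage``
    is the fraction of the circumference covered (0..1) starting at
    ``angular_offset`` radians (measured from the +x axis).
    """

    pillar_index: int
    slice_start: int
    slice_end: int
    angular_coverage: float
    angular_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.slice_start < 0 or self.slice_end < self.slice_start:
            raise ValueError(f"bad slice range [{self.slice_start}, {self.slice_end}]")
        if not (0.0 <= self.angular_coverage <= 1.0):
            raise ValueError(f"angular_coverage must be in [0,1]: {self.angular_coverage}")


@dataclass
class SyntheticFieldSpec:
    """Full parameterization of one synthetic field of view.

    Defaults reproduce the study's acquisition geometry: 8 slices at a
    2 µm step, 0.31 µm/px, pillar diameter 10 µm on a 20 µm grid pitch,
    myelin 0.6 µm thick, nuclei 8 µm across.
    """

    grid_rows: int = 3
    grid_cols: int = 3
    spacing_um: float = 20.0
    pillar_diameter_um: float = 10.0
    n_slices: int = 8
    z_step_um: float = 2.0
    pixel_size_um: float = 0.31
    wrap_events: Sequence[WrapEvent] = field(default_factory=tuple)
    myelin_thickness_um: float = 0.6
    n_nuclei: int = 10
    nucleus_diameter_um: float = 8.0
    blur_sigma_um: float = 0.4
    gaussian_sd: float = 5.0
    poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_um <= self.pillar_diameter_um + 2 * self.myelin_thickness_um:
            raise GeometryError(
                "spacing_um must exceed pillar_diameter_um + 2*myelin_thickness_um"
            )
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.z_step_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("z_step_um and pixel_size_um must be > 0")
        for n in (self.grid_rows, self.grid_cols, self.n_nuclei):
            if n < 0:
                raise ValueError("counts must be >= 0")
        for ev in self.wrap_events:
            if ev.slice_end >= self.n_slices:
                raise ValueError(f"wrap event exceeds n_slices={self.n_slices}: {ev}")
            if not (0 <= ev.pillar_index < self.grid_rows * self.grid_cols):
                raise ValueError(f"wrap event pillar_index out of range: {ev}")

    @property
    def n_pillars(self) -> int:
        return self.grid_rows * self.grid_cols

    def pillar_centers_um(self) -> np.ndarray:
        """(n_pillars, 2) array of (y, x) centers in µm, row-major order."""
        margin = self.spacing_um / 2.0
        ys = margin + np.arange(self.grid_rows) * self.spacing_um
        xs = margin + np.arange(self.grid_cols) * self.spacing_um
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        return np.column_stack([yy.ravel(), xx.ravel()])

    def image_shape(self) -> tuple[int, int]:
        h = int(math.ceil(self.grid_rows * self.spacing_um / self.pixel_size_um))
        w = int(math.ceil(self.grid_cols * self.spacing_um / self.pixel_size_um))
        return h, w

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticFieldSpec":
        d = dict(d)
        events = [
            ev if isinstance(ev, WrapEvent) else WrapEvent(**ev)
            for ev in d.pop("wrap_events", [])
        ]
        return cls(wrap_events=tuple(events), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticFieldSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        d = asdict(self)
        d["wrap_events"] = [asdict(ev) for ev in self.wrap_events]
        return json.dumps(d, indent=2)


@dataclass
class GroundTruth:
    """Analytic truth for one synthetic field, computed before blur/noise.

    ``coverage`` is an (n_pillars, n_slices) array of true circumferential
    coverage fractions; ``table`` summarizes each pillar (centroid, diameter,
    longest qualifying sheath run, fully-wrapped flag).
    """

    coverage: np.ndarray
    table: pd.DataFrame
    n_nuclei: int
    expected_wi: float
    theta_c: float
    l_min_um: float

    @property
    def n_fully_wrapped(self) -> int:
        return int(self.table["fully_wrapped"].sum())

    def write(self, csv_path: str | Path, spec: SyntheticFieldSpec | None = None) -> None:
        """Write the per-pillar table as CSV plus a JSON sidecar of the spec."""
        csv_path = Path(csv_path)
        self.table.to_csv(csv_path, index=False)
        if spec is not None:
            csv_path.with_suffix(".json").write_text(spec.to_json())


def _arc_union_fraction(arcs: list[tuple[float, float]]) -> float:
    """Fraction of the circle covered by a union of arcs (offset, coverage)."""
    if not arcs:
        return 0.0
    if any(cov >= 1.0 for _, cov in arcs):
        return 1.0
    # unwrap each arc into [start, end) on the circle, split at 2*pi
    segs: list[tuple[float, float]] = []
    two_pi = 2.0 * math.pi
    for off, cov in arcs:
        if cov <= 0.0:
            continue
        a = off % two_pi
        b = a + cov * two_pi
        if b <= two_pi:
            segs.append((a, b))
        else:
            segs.append((a, two_pi))
            segs.append((0.0, b - two_pi))
    if not segs:
        return 0.0
    segs.sort()
    total = 0.0
    cur_a, cur_b = segs[0]
    for a, b in segs[1:]:
        if a > cur_b:
            total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    total += cur_b - cur_a
    return min(total / two_pi, 1.0)


def true_coverage_matrix(spec: SyntheticFieldSpec) -> np.ndarray:
    """Per-pillar, per-slice true coverage implied by the wrap events."""
    cov = np.zeros((spec.n_pillars, spec.n_slices))
    by_pillar: dict[int, list[WrapEvent]] = {}
    for ev in spec.wrap_events:
        by_pillar.setdefault(ev.pillar_index, []).append(ev)
    for p, events in by_pillar.items():
        for z in range(spec.n_slices):
            arcs = [
                (ev.angular_offset, ev.angular_coverage)
                for ev in events
                if ev.slice_start <= z <= ev.slice_end
            ]
            cov[p, z] = _arc_union_fraction(arcs)
    return cov


def compute_ground_truth(
    spec: SyntheticFieldSpec,
    theta_c: float = THETA_C_DEFAULT,
    l_min_um: float = L_MIN_UM_DEFAULT,
) -> GroundTruth:
    """Analytic ground truth under the >theta_c coverage / >l_min sheath rule."""
    cov = true_coverage_matrix(spec)
    centers_px = spec.pillar_centers_um() / spec.pixel_size_um
    rows = []
    for p in range(spec.n_pillars):
        qualifying = cov[p] > theta_c
        max_len = max_run_length(qualifying) * spec.z_step_um
        rows.append(
            {
                "pillar_index": p,
                "centroid_y_px": centers_px[p, 0],
                "centroid_x_px": centers_px[p, 1],
                "true_diameter_um": spec.pillar_diameter_um,
                "max_contiguous_length_um": max_len,
                "fully_wrapped": bool(max_len > l_min_um),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "pillar_index", "centroid_y_px", "centroid_x_px",
            "true_diameter_um", "max_contiguous_length_um", "fully_wrapped",
        ],
    )
    n_wrapped = int(table["fully_wrapped"].sum()) if len(table) else 0
    wi = n_wrapped / spec.n_nuclei if spec.n_nuclei > 0 else float("nan")
    return GroundTruth(
        coverage=cov,
        table=table,
        n_nuclei=spec.n_nuclei,
        expected_wi=wi,
        theta_c=theta_c,
        l_min_um=l_min_um,
    )


def _render_channels(spec: SyntheticFieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterize noiseless, unblurred (3, Z, Y, X) channels: axon, myelin, nuclei."""
    h, w = spec.image_shape()
    px = spec.pixel_size_um
    vol = np.full((3, spec.n_slices, h, w), BACKGROUND, dtype=np.float32)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    centers_px = spec.pillar_centers_um() / px
    r_px = spec.pillar_diameter_um / 2.0 / px
    t_px = spec.myelin_thickness_um / px

    # axon channel: filled disks at every grid node in every slice
    axon2d = np.zeros((h, w), dtype=bool)
    dist = np.empty((spec.n_pillars, h, w))
    theta = np.empty((spec.n_pillars, h, w))
    for p, (cy, cx) in enumerate(centers_px):
        dy, dx = yy - cy, xx - cx
        dist[p] = np.hypot(dy, dx)
        theta[p] = np.arctan2(dy, dx) % (2.0 * math.pi)
        axon2d |= dist[p] <= r_px
    vol[0, :, axon2d] = AXON_INTENSITY

    # myelin channel: annular arcs per wrap event
    for ev in spec.wrap_events:
        if ev.angular_coverage <= 0.0:
            continue
        d = dist[ev.pillar_index]
        annulus = (d > r_px) & (d <= r_px + t_px)
        if ev.angular_coverage >= 1.0:
            arc = annulus
        else:
            rel = (theta[ev.pillar_index] - ev.angular_offset) % (2.0 * math.pi)
            arc = annulus & (rel < ev.angular_coverage * 2.0 * math.pi)
        for z in range(ev.slice_start, ev.slice_end + 1):
            vol[1, z][arc] = MYELIN_INTENSITY

    # nuclei channel: non-overlapping spheres in the inter-pillar space
    nr_um = spec.nucleus_diameter_um / 2.0
    nr_px = nr_um / px
    placed: list[tuple[float, float]] = []
    keepout = r_px + t_px + nr_px + 0.5 / px  # pillar+myelin footprint plus margin
    # nuclei must stay resolvable after the PSF: keep a blur-scaled gap
    sep_px = 2 * nr_px + 4.0 * spec.blur_sigma_um / px + 2.0
    max_attempts = 1000 * max(spec.n_nuclei, 1)
    attempts = 0
    while len(placed) < spec.n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise GeometryError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei in "
                f"{attempts} attempts; field too crowded"
            )
        cy = rng.uniform(nr_px, h - 1 - nr_px)
        cx = rng.uniform(nr_px, w - 1 - nr_px)
        if np.any(np.hypot(centers_px[:, 0] - cy, centers_px[:, 1] - cx) < keepout):
            continue
        if any(np.hypot(py - cy, px_ - cx) < sep_px for py, px_ in placed):
            continue
        placed.append((cy, cx))
        zc = rng.uniform(0, spec.n_slices - 1)
        for z in range(spec.n_slices):
            dz_um = (z - zc) * spec.z_step_um
            if abs(dz_um) >= nr_um:
                continue
            rz_px = math.sqrt(nr_um**2 - dz_um**2) / px
            blob = np.hypot(yy - cy, xx - cx) <= rz_px
            vol[2, z][blob] = NUCLEI_INTENSITY
    return vol


def generate_field(spec: SyntheticFieldSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one synthetic field and its analytic ground truth.

    Blur (isotropic in-plane Gaussian) and noise (optional Poisson shot noise
    followed by additive Gaussian read noise, clipped to the dynamic range)
    are applied after rasterization; the ground truth reflects the noiseless
    geometry.  Identical spec and seed give bit-identical voxels.
    """
    rng = np.random.default_rng(spec.seed)
    truth = compute_ground_truth(spec)
    vol = _render_channels(spec, rng)

    if spec.blur_sigma_um > 0:
        sigma_px = spec.blur_sigma_um / spec.pixel_size_um
        for c in range(vol.shape[0]):
            for z in range(vol.shape[1]):
                vol[c, z] = gaussian_filter(vol[c, z], sigma=sigma_px)
    if spec.poisson:
        vol = rng.poisson(np.clip(vol, 0, None)).astype(np.float32)
    if spec.gaussian_sd > 0:
        vol = vol + rng.normal(0.0, spec.gaussian_sd, size=vol.shape).astype(np.float32)
    vol = np.clip(vol, 0.0, DYNAMIC_RANGE).astype(np.float32)

    stack = ImageStack(
        voxels=vol,
        channel_roles={"axon": 0, "myelin": 1, "nuclei": 2},
        pixel_size_um=spec.pixel_size_um,
        z_step_um=spec.z_step_um,
    )
    return stack, truth


def render_noise_free(spec: SyntheticFieldSpec) -> np.ndarray:
    """The raw rasterization (no blur, no noise) as a (3, Z, Y, X) array.

    Used as the pixel-wise oracle for thresholding and coverage checks.
    """
    rng = np.random.default_rng(spec.seed)
    return _render_channels(spec, rng)


def generate_photomask(
    n_arrays: int,
    rows: int,
    cols: int,
    dot_radius_px: float,
    pitch_px: float,
) -> tuple[np.ndarray, int]:
    """Render a digital photomask: white dots on black, arrays tiled on a grid.

    Each of the ``n_arrays`` sub-arrays is ``rows x cols`` dots at ``pitch_px``
    spacing; dots are filled circles of the given radius (pixels strictly
    inside the radius).  Returns the boolean raster and the total dot count.

    Raises
    ------
    GeometryError
        If ``pitch_px <= 2 * dot_radius_px`` (dots would overlap or touch).
    """
    if n_arrays < 1 or rows < 1 or cols < 1:
        raise ValueError("n_arrays, rows, cols must all be >= 1")
    if pitch_px <= 2 * dot_radius_px:
        raise GeometryError(
            f"pitch {pitch_px} px would overlap dots of radius {dot_radius_px} px"
        )
    arr_rows = int(math.floor(math.sqrt(n_arrays)))
    arr_cols = int(math.ceil(n_arrays / arr_rows))
    tile_h = rows * pitch_px
    tile_w = cols * pitch_px
    h = int(math.ceil(arr_rows * tile_h))
    w = int(math.ceil(arr_cols * tile_w))
    mask = np.zeros((h, w), dtype=bool)

    yy, xx = np.mgrid[0 : int(2 * dot_radius_px) + 3, 0 : int(2 * dot_radius_px) + 3]
    c0 = dot_radius_px + 1
    template = np.hypot(yy - c0, xx - c0) < dot_radius_px
    ty, tx = np.nonzero(template)

    count = 0
    for a in range(n_arrays):
        ar, ac = divmod(a, arr_cols)
        oy = ar * tile_h + pitch_px / 2.0
        ox = ac * tile_w + pitch_px / 2.0
        for i in range(rows):
            for j in range(cols):
                cy = int(round(oy + i * pitch_px))
                cx = int(round(ox + j * pitch_px))
                mask[ty + cy - int(c0), tx + cx - int(c0)] = True
                count += 1
    return mask, count


def random_field_spec(
    seed: int,
    grid_rows: int = 3,
    grid_cols: int = 3,
    p_event: float = 0.6,
    n_nuclei_range: tuple[int, int] = (5, 12),
    noise: bool = True,
) -> SyntheticFieldSpec:
    """A randomized field spec for recovery studies.

    Each pillar independently receives at most one sheath with probability
    ``p_event``.  Sheath coverage is drawn from a bimodal mixture — half
    "abortive contact" (uniform 0.05-0.6 of the circumference) and half
    "processive wrapping" (uniform 0.85-1.0) — reflecting that ensheathment
    is cooperative: intermediate coverage right at the 80% classification
    boundary is transient and rare in fixed samples, and at pixel resolution
    a coverage exactly at the boundary is inherently undecidable.  Sheath
    axial extent is a uniformly random slice range; nuclei counts are
    uniform over ``n_nuclei_range`` (what fits a field this size).
    """
    rng = np.random.default_rng(seed)
    n_pillars = grid_rows * grid_cols
    n_slices = 8
    events = []
    for p in range(n_pillars):
        if rng.random() >= p_event:
            continue
        if rng.random() < 0.5:
            cov = rng.uniform(0.05, 0.6)
        else:
            cov = rng.uniform(0.85, 1.0)
        start = int(rng.integers(0, n_slices))
        end = int(rng.integers(start, n_slices))
        events.append(
            WrapEvent(p, start, end, float(cov), float(rng.uniform(0, 2 * math.pi)))
        )
    lo, hi = n_nuclei_range
    return SyntheticFieldSpec(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        wrap_events=tuple(events),
        n_nuclei=int(rng.integers(lo, hi + 1)),
        blur_sigma_um=0.4 if noise else 0.0,
        gaussian_sd=5.0 if noise else 0.0,
        poisson=noise,
        seed=seed,
    )


def match_pillars(per_pillar: pd.DataFrame, truth: GroundTruth) -> pd.DataFrame:
    """Join detected pillars to ground-truth pillars by nearest centroid.

    Returns the per-pillar table with ``true_index``, ``true_fully_wrapped``
    and ``centroid_error_px`` columns appended.  Raises if the matching is
    not one-to-one (a detection failure).
    """
    det = per_pillar[["centroid_y_px", "centroid_x_px"]].to_numpy(float)
    tru = truth.table[["centroid_y_px", "centroid_x_px"]].to_numpy(float)
    d = np.hypot(det[:, None, 0] - tru[None, :, 0], det[:, None, 1] - tru[None, :, 1])
    nearest = d.argmin(axis=1)
    if len(set(nearest.tolist())) != len(nearest):
        raise ValueError("pillar matching is not one-to-one")
    out = per_pillar.copy()
    out["true_index"] = truth.table["pillar_index"].to_numpy()[nearest]
    out["true_fully_wrapped"] = truth.table["fully_wrapped"].to_numpy()[nearest]
    out["centroid_error_px"] = d[np.arange(len(det)), nearest]
    return out


def generate_force_curve(
    E: float,
    nu: float = 0.5,
    R: float = 0.75e-6,
    depth_max: float = 200e-9,
    n_points: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    spring_constant: float = 0.1,
    label: str = "",
) -> ForceCurve:
    """Sample a spherical-Hertz force-indentation curve with optional noise.

    F(delta) = (4/3) * E/(1-nu^2) * sqrt(R) * delta^(3/2) on [0, depth_max],
    plus additive zero-mean Gaussian noise of standard deviation ``noise_sd``
    (newtons).  Seed-reproducible.
    """
    if E <= 0 or R <= 0:
        raise ValueError(f"E and R must be > 0 (got E={E}, R={R})")
    if not (0.0 <= nu <= 0.5):
        raise ValueError(f"Poisson ratio must be in [0, 0.5]: {nu}")
    if depth_max <= 0 or n_points < 10:
        raise ValueError("need depth_max > 0 and n_points >= 10")
    depth = np.linspace(0.0, depth_max, n_points)
    force = hertz_force(depth, E, nu, R)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd, size=force.shape)
    return ForceCurve(
        depth=depth,
        force=force,
        probe_radius=R,
        spring_constant=spring_constant,
        label=label,
    )
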