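"""Design and rasterisation of the oriented-Gabor pRF-mapping stimulus.

The mapping stimulus is a pack of Gabor patches confined to a ring- or
wedge-shaped aperture that drifts across the visual field once per 24-s
cycle, stepping in sync with the fMRI acquisition (one step per 1.5-s TR).
Gabor envelope size grows linearly with eccentricity; carrier spatial
frequency falls logarithmically.  The forward model downstream consumes only
the binary aperture indicator s(x, y, t) — the union of the 2-sigma envelope
discs active in each frame — so the carrier (orientation, phase, sub-TR
flicker) is carried as metadata and never rasterised.

The published eccentricity/size ladders are shipped as canonical constants;
the generative rules that produce them (used by the tests) are exposed
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ScanConfig", "RingLayout", "WedgeLayout", "StimulusMovie", "ProbeLadder",
    "RING_ECCENTRICITIES_DEG", "RING_MINOR_RADII_DEG",
    "WEDGE_ECCENTRICITIES_SET1_DEG", "WEDGE_ECCENTRICITIES_SET2_DEG",
    "WEDGE_GABOR_RADII_SET1_DEG", "WEDGE_GABOR_RADII_SET2_DEG",
    "ring_layout", "wedge_layout", "gabor_size_at", "wedge_gabor_size_at",
    "spatial_frequency_at", "generated_ring_eccentricities",
    "rasterize_movie", "probe_ladder", "visual_angle_deg",
]

# ---------------------------------------------------------------------------
# Canonical design constants
# ---------------------------------------------------------------------------

#: Ring-scan aperture centre eccentricities (degrees of visual angle).
RING_ECCENTRICITIES_DEG = (
    1.00, 1.30, 1.63, 1.95, 2.31, 2.67, 3.05, 3.44,
    3.86, 4.29, 4.75, 5.21, 5.71, 6.21, 6.76, 7.30,
)

#: Matching ring minor radii = 2 sigma of the Gabor contrast envelope.
RING_MINOR_RADII_DEG = (
    0.30, 0.31, 0.33, 0.34, 0.36, 0.37, 0.39, 0.40,
    0.42, 0.44, 0.46, 0.48, 0.50, 0.52, 0.55, 0.57,
)

#: Wedge-scan Gabor eccentricities: two interleaved (zigzag) sets.
WEDGE_ECCENTRICITIES_SET1_DEG = (1.00, 1.65, 2.39, 3.24, 4.22, 5.35, 6.64)
WEDGE_ECCENTRICITIES_SET2_DEG = (1.30, 1.99, 2.78, 3.70, 4.74, 5.95)
WEDGE_GABOR_RADII_SET1_DEG = (0.30, 0.35, 0.40, 0.46, 0.52, 0.60, 0.69)
WEDGE_GABOR_RADII_SET2_DEG = (0.32, 0.37, 0.42, 0.49, 0.56, 0.65)

#: Anchors of the linear envelope-size rules (eccentricity deg -> radius deg).
_RING_SIZE_ANCHORS = ((1.0, 0.30), (7.30, 0.57))
_WEDGE_SIZE_ANCHORS = ((1.0, 0.30), (6.64, 0.69))

#: Angular step of the rotating wedge (polar-angle degrees per TR).
WEDGE_STEP_DEG = 11.25

ApertureKind = Literal["ring_expand", "ring_contract", "wedge_cw", "wedge_ccw"]
OrientationCondition = Literal["radial", "tangential"]


@dataclass(frozen=True)
class ScanConfig:
    """Timing and geometry of one traveling-aperture scan."""

    tr_seconds: float = 1.5
    cycle_seconds: float = 24.0
    n_cycles: int = 9
    field_radius_deg: float = 7.9
    grid_step_deg: float = 0.1
    aperture_kind: ApertureKind = "ring_expand"
    orientation_condition: OrientationCondition = "radial"

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.grid_step_deg <= 0:
            raise ValueError("grid_step_deg must be positive")
        n = self.cycle_seconds / self.tr_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError("cycle_seconds must be an integer multiple of tr_seconds")

    @property
    def frames_per_cycle(self) -> int:
        return int(round(self.cycle_seconds / self.tr_seconds))

    @property
    def n_frames(self) -> int:
        return self.n_cycles * self.frames_per_cycle


@dataclass(frozen=True)
class RingLayout:
    eccentricities_deg: tuple = RING_ECCENTRICITIES_DEG
    minor_radii_deg: tuple = RING_MINOR_RADII_DEG
    n_packs: int = 4

    def __post_init__(self):
        e = np.asarray(self.eccentricities_deg)
        r = np.asarray(self.minor_radii_deg)
        if e.size != r.size:
            raise ValueError("eccentricity and radius sequences differ in length")
        if np.any(np.diff(e) <= 0) or np.any(np.diff(r) < 0):
            raise ValueError("ring ladder must increase with eccentricity")


@dataclass(frozen=True)
class WedgeLayout:
    eccentricity_set_1: tuple = WEDGE_ECCENTRICITIES_SET1_DEG
    eccentricity_set_2: tuple = WEDGE_ECCENTRICITIES_SET2_DEG
    gabor_radii_1: tuple = WEDGE_GABOR_RADII_SET1_DEG
    gabor_radii_2: tuple = WEDGE_GABOR_RADII_SET2_DEG
    step_deg: float = WEDGE_STEP_DEG

    def __post_init__(self):
        if len(self.eccentricity_set_1) != len(self.gabor_radii_1):
            raise ValueError("set 1 sequences differ in length")
        if len(self.eccentricity_set_2) != len(self.gabor_radii_2):
            raise ValueError("set 2 sequences differ in length")
        # the two sets must interleave in eccentricity (zigzag arrangement)
        merged = np.sort(np.r_[self.eccentricity_set_1, self.eccentricity_set_2])
        zig = np.empty_like(merged)
        zig[0::2] = self.eccentricity_set_1
        zig[1::2] = self.eccentricity_set_2
        if not np.allclose(merged, zig):
            raise ValueError("eccentricity sets must interleave")


@dataclass
class StimulusMovie:
    """Binary aperture indicator s(x, y, t) on a square raster grid."""

    grid_x: np.ndarray          # (nx,) degrees, fixation at 0
    grid_y: np.ndarray          # (ny,) degrees
    frames: np.ndarray          # (T, ny, nx) values in {0, 1}
    frame_duration: float       # seconds (= TR)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frames_flat(self) -> np.ndarray:
        return self.frames.reshape(self.n_frames, -1)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames, compression="gzip")
            f.create_dataset("grid_x", data=self.grid_x)
            f.create_dataset("grid_y", data=self.grid_y)
            f.attrs["frame_duration"] = self.frame_duration

    @classmethod
    def load_hdf5(cls, path) -> "StimulusMovie":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                grid_x=f["grid_x"][:], grid_y=f["grid_y"][:],
                frames=f["frames"][:],
                frame_duration=float(f.attrs["frame_duration"]),
            )


@dataclass(frozen=True)
class ProbeLadder:
    """Probe aspect-ratio levels of the circularity-judgment task."""

    ar_values: tuple

    def __post_init__(self):
        v = np.asarray(self.ar_values)
        if not np.allclose(np.log(v) + np.log(v[::-1]), 0.0, atol=1e-9):
            raise ValueError("ladder must be log-symmetric about 1")


# ---------------------------------------------------------------------------
# Layout rules
# ---------------------------------------------------------------------------

def _linear_radius(ecc, anchors):
    (e0, r0), (e1, r1) = anchors
    slope = (r1 - r0) / (e1 - e0)
    return r0 + slope * (np.asarray(ecc, dtype=float) - e0)


def gabor_size_at(eccentricity_deg: float) -> float:
    """Ring-scan Gabor minor radius (= 2 sigma of the envelope), degrees.

    Linear in eccentricity, anchored at (1 deg, 0.30 deg) and
    (7.30 deg, 0.57 deg).
    """
    e = float(eccentricity_deg)
    if not (_RING_SIZE_ANCHORS[0][0] - 1e-9 <= e <= _RING_SIZE_ANCHORS[1][0] + 1e-9):
        raise ValueError(f"eccentricity {e} outside the stimulated range [1, 7.3]")
    return float(_linear_radius(e, _RING_SIZE_ANCHORS))


def wedge_gabor_size_at(eccentricity_deg: float) -> float:
    """Wedge-scan Gabor minor radius, anchored at (1, 0.30) and (6.64, 0.69)."""
    e = float(eccentricity_deg)
    if not (_WEDGE_SIZE_ANCHORS[0][0] - 1e-9 <= e <= _WEDGE_SIZE_ANCHORS[1][0] + 1e-9):
        raise ValueError(f"eccentricity {e} outside the wedge range [1, 6.64]")
    return float(_linear_radius(e, _WEDGE_SIZE_ANCHORS))


def spatial_frequency_at(eccentricity_deg, sf_fovea: float = 3.0):
    """Carrier spatial frequency (cycles/deg): SF = SF_fovea - (5/6) ln(e).

    Natural logarithm; the rule yields 3 cpd at 1 deg and 1.34 cpd at 7.3 deg.
    """
    e = np.asarray(eccentricity_deg, dtype=float)
    if np.any(e <= 0):
        raise ValueError("eccentricity must be positive")
    return sf_fovea - (5.0 / 6.0) * np.log(e)


def generated_ring_eccentricities(n: int = 16) -> np.ndarray:
    """Regenerate the ring eccentricity ladder from its stepping rule.

    Each aperture shifts outward by its own half-width (= the Gabor minor
    radius); the implicit step is resolved with the radius evaluated midway
    between consecutive centres, which reproduces the canonical ladder to
    better than 0.02 deg.
    """
    (e0, r0), (e1, r1) = _RING_SIZE_ANCHORS
    b = (r1 - r0) / (e1 - e0)
    a = r0 - b * e0
    ecc = [1.0]
    for _ in range(n - 1):
        e_prev = ecc[-1]
        # solve e = e_prev + a + b * (e_prev + e) / 2
        ecc.append((e_prev * (1 + b / 2) + a) / (1 - b / 2))
    return np.asarray(ecc)


def ring_layout() -> RingLayout:
    """Canonical 16-position ring layout."""
    return RingLayout()


def wedge_layout() -> WedgeLayout:
    """Canonical two-set (7 + 6 eccentricities) wedge layout."""
    return WedgeLayout()


def probe_ladder(n: int = 9, lo: float = 0.5, hi: float = 2.0) -> ProbeLadder:
    """Probe aspect ratios, equally spaced between 0.5 and 2 on a log scale."""
    return ProbeLadder(tuple(np.geomspace(lo, hi, n)))


def visual_angle_deg(extent_cm: float, distance_cm: float) -> float:
    """Full visual angle subtended by a flat extent viewed centrally."""
    return float(2.0 * np.degrees(np.arctan(extent_cm / 2.0 / distance_cm)))


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------

def _make_grid(config: ScanConfig):
    n = int(np.floor(config.field_radius_deg / config.grid_step_deg))
    axis = np.arange(-n, n + 1) * config.grid_step_deg
    return axis, axis.copy()


def _ring_disc_centers(ecc: float, radius: float, phase: float):
    """Equally spaced Gabor centres tiling one ring aperture.

    The count is the largest multiple of four (one slot per pack) whose
    chord spacing keeps neighbouring discs from overlapping; within a single
    pack (every 4th slot) the separation then exceeds three Gabor radii.
    """
    ratio = min(radius / ecc, 1.0)
    n_max = int(np.floor(np.pi / np.arcsin(ratio)))
    n = max(4 * (n_max // 4), 4)
    angles = phase + 2.0 * np.pi * np.arange(n) / n
    return ecc * np.cos(angles), ecc * np.sin(angles)


def _paint_disc(mask, grid_x, grid_y, cx, cy, radius):
    step = grid_x[1] - grid_x[0]
    ix0 = max(int(np.searchsorted(grid_x, cx - radius) - 1), 0)
    ix1 = min(int(np.searchsorted(grid_x, cx + radius) + 1), grid_x.size)
    iy0 = max(int(np.searchsorted(grid_y, cy - radius) - 1), 0)
    iy1 = min(int(np.searchsorted(grid_y, cy + radius) + 1), grid_y.size)
    xs = grid_x[ix0:ix1] - cx
    ys = grid_y[iy0:iy1] - cy
    sub = (ys[:, None] ** 2 + xs[None, :] ** 2) <= radius ** 2
    mask[iy0:iy1, ix0:ix1] |= sub


def _ring_cycle_frames(config: ScanConfig, layout: RingLayout, grid_x, grid_y):
    n_pos = len(layout.eccentricities_deg)
    if config.frames_per_cycle != n_pos:
        raise ValueError(
            f"ring layout has {n_pos} positions but the cycle holds "
            f"{config.frames_per_cycle} frames")
    order = range(n_pos)
    if config.aperture_kind == "ring_contract":
        order = reversed(list(order))
    frames = []
    for step_idx, pos in enumerate(order):
        ecc = layout.eccentricities_deg[pos]
        radius = layout.minor_radii_deg[pos]
        mask = np.zeros((grid_y.size, grid_x.size), dtype=bool)
        # all four packs appear within each TR (sequential 300-ms slots), so
        # the per-TR indicator is the union over the full disc set; the phase
        # staggers slot boundaries between consecutive eccentricity steps
        cx, cy = _ring_disc_centers(ecc, radius, phase=0.5 * step_idx * radius / ecc)
        for x, y in zip(cx, cy):
            _paint_disc(mask, grid_x, grid_y, x, y, radius)
        frames.append(mask)
    return frames


def _wedge_cycle_frames(config: ScanConfig, layout: WedgeLayout, grid_x, grid_y):
    n_pos = config.frames_per_cycle
    step = np.radians(layout.step_deg)
    if abs(layout.step_deg * n_pos - 180.0) > 1e-6:
        raise ValueError("wedge steps must cover a half-turn per cycle")
    sign = -1.0 if config.aperture_kind == "wedge_cw" else 1.0
    half = step / 2.0
    frames = []
    for pos in range(n_pos):
        phi = sign * pos * step
        mask = np.zeros((grid_y.size, grid_x.size), dtype=bool)
        for mirror in (0.0, np.pi):    # bowtie: wedge plus its mirror image
            for eccs, radii, zig in (
                (layout.eccentricity_set_1, layout.gabor_radii_1, -half),
                (layout.eccentricity_set_2, layout.gabor_radii_2, +half),
            ):
                ang = phi + mirror + zig
                for ecc, radius in zip(eccs, radii):
                    _paint_disc(mask, grid_x, grid_y,
                                ecc * np.cos(ang), ecc * np.sin(ang), radius)
        frames.append(mask)
    return frames


def rasterize_movie(config: ScanConfig, layout) -> StimulusMovie:
    """Rasterise one scan into a binary aperture movie, one frame per TR.

    A pixel is set iff it falls inside the 2-sigma envelope disc of any
    Gabor active in that frame.  The movie is identical between the radial
    and tangential orientation conditions: only the carrier differs, and the
    carrier is not rasterised.
    """
    grid_x, grid_y = _make_grid(config)
    if isinstance(layout, RingLayout):
        smallest = min(layout.minor_radii_deg)
    elif isinstance(layout, WedgeLayout):
        smallest = min(min(layout.gabor_radii_1), min(layout.gabor_radii_2))
    else:
        raise TypeError("layout must be a RingLayout or WedgeLayout")
    if config.grid_step_deg >= smallest:
        raise ValueError(
            f"grid step {config.grid_step_deg} deg cannot resolve the smallest "
            f"Gabor radius {smallest} deg")

    if isinstance(layout, RingLayout):
        cycle = _ring_cycle_frames(config, layout, grid_x, grid_y)
    else:
        cycle = _wedge_cycle_frames(config, layout, grid_x, grid_y)

    frames = np.asarray(cycle * config.n_cycles, dtype=np.uint8)
    return StimulusMovie(grid_x=grid_x, grid_y=grid_y, frames=frames,
                         frame_duration=config.tr_seconds)
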