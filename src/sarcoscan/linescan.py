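"""Line scans: sample profiles along paths and turn binary transitions into
sub-pixel band centers and widths — the objective points of reference.

Profiles from intensity images are sampled with bilinear interpolation;
profiles from binary masks use nearest-neighbor sampling so no sub-threshold
values are invented — sub-pixel precision comes from a fine sample step
(default 0.25 px). A 0->1 transition between consecutive samples places an
``enter`` edge at the midpoint of the two sample positions (1->0 an ``exit``),
and an enter/exit pair delimits one band. Runs truncated by the scan ends are
flagged incomplete and excluded from downstream statistics.

Positions along a profile are absolute coordinates (nm) along the path
direction: the projection of the physical sample point onto the unit path
direction. For a horizontal scan of an unrotated lattice these coincide with
the lattice coordinates, so band centers are directly comparable to ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal.windows import hann

from .preprocess import BinaryMask
from .synthio import Image2D, ParameterError

__all__ = [
    "PathOutsideImageError",
    "NoStriationError",
    "LineScanPath",
    "Profile",
    "CrossingEvent",
    "Band",
    "extract_profile",
    "detect_crossings",
    "bands_from_crossings",
    "scan_bands",
    "estimate_orientation",
    "auto_paths",
]


class PathOutsideImageError(ValueError):
    """A scan path leaves the image; the message names the endpoint."""


class NoStriationError(RuntimeError):
    """No spectral peak above the noise floor: no striation detected."""


@dataclass(frozen=True)
class LineScanPath:
    """A straight scan path in pixel coordinates (sub-pixel allowed).

    ``start``/``end`` are ``(x, y)`` in the pixel-center convention (the
    point ``(i, j)`` is the center of pixel column i, row j).
    """

    start: tuple[float, float]
    end: tuple[float, float]
    sample_step_px: float = 0.25

    def __post_init__(self) -> None:
        if self.length_px <= 0:
            raise ParameterError("path length must be > 0")
        if self.sample_step_px <= 0:
            raise ParameterError("sample_step_px must be > 0")

    @property
    def length_px(self) -> float:
        dx = self.end[0] - self.start[0]
        dy = self.end[1] - self.start[1]
        return float(np.hypot(dx, dy))

    @property
    def direction(self) -> tuple[float, float]:
        dx = self.end[0] - self.start[0]
        dy = self.end[1] - self.start[1]
        n = np.hypot(dx, dy)
        return (dx / n, dy / n)

    def reversed(self) -> "LineScanPath":
        return LineScanPath(self.end, self.start, self.sample_step_px)


@dataclass
class Profile:
    """Samples along a path: strictly increasing positions (nm) and values."""

    positions_nm: np.ndarray
    values: np.ndarray
    source: str  # "image" | "mask"
    channel: str = ""

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_nm.shape != self.values.shape:
            raise ParameterError("positions and values must have equal length")
        if self.positions_nm.size < 2:
            raise ParameterError("profile needs at least two samples")
        if not np.all(np.diff(self.positions_nm) > 0):
            raise ParameterError("positions must be strictly increasing")

    @property
    def step_nm(self) -> float:
        return float(self.positions_nm[1] - self.positions_nm[0])

    @property
    def span_nm(self) -> float:
        return float(self.positions_nm[-1] - self.positions_nm[0])


@dataclass(frozen=True)
class CrossingEvent:
    position_nm: float
    kind: str  # "enter" | "exit"
    real: bool = True  # False for synthetic edges at scan ends


@dataclass(frozen=True)
class Band:
    """One fluorescent stripe on a scan: enter/exit edges, center, width."""

    enter_nm: float
    exit_nm: float
    channel: str = ""
    complete: bool = True

    def __post_init__(self) -> None:
        if not self.exit_nm > self.enter_nm:
            raise ParameterError("band exit must exceed enter")

    @property
    def center_nm(self) -> float:
        return 0.5 * (self.enter_nm + self.exit_nm)

    @property
    def width_nm(self) -> float:
        return self.exit_nm - self.enter_nm


def _sample_points(path: LineScanPath) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arc-length positions (px) and x/y pixel coordinates of the samples."""
    n = int(np.floor(path.length_px / path.sample_step_px + 1e-9)) + 1
    arc = np.arange(n) * path.sample_step_px
    dx, dy = path.direction
    xs = path.start[0] + arc * dx
    ys = path.start[1] + arc * dy
    return arc, xs, ys


def extract_profile(
    img_or_mask: Image2D | BinaryMask, path: LineScanPath
) -> Profile:
    """Sample an image or mask at uniform arc-length steps along a path.

    Intensity images are sampled bilinearly; binary masks nearest-neighbor.
    Raises :class:`PathOutsideImageError` if either endpoint leaves the grid.
    """
    is_mask = isinstance(img_or_mask, BinaryMask)
    pix = img_or_mask.pixels.astype(float)
    p = img_or_mask.pixel_size_nm
    h, w = pix.shape
    for name, (x, y) in (("start", path.start), ("end", path.end)):
        if not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
            raise PathOutsideImageError(
                f"path {name} point ({x:.2f}, {y:.2f}) outside {w}x{h} image"
            )
    arc, xs, ys = _sample_points(path)
    order = 0 if is_mask else 1
    values = ndimage.map_coordinates(pix, [ys, xs], order=order, mode="nearest")
    dx, dy = path.direction
    # absolute coordinate of the start point along the path direction
    s0 = ((path.start[0] + 0.5) * dx + (path.start[1] + 0.5) * dy) * p
    positions = s0 + arc * p
    return Profile(
        positions,
        values,
        source="mask" if is_mask else "image",
        channel=getattr(img_or_mask, "channel", ""),
    )


def detect_crossings(profile: Profile) -> list[CrossingEvent]:
    """Locate 0->1 / 1->0 transitions of a binary profile at sample midpoints.

    A leading 1-run opens with a synthetic ``enter`` at the first sample
    (flagged not real); a trailing 1-run closes likewise. An all-zero profile
    yields an empty list.
    """
    v = profile.values
    if not np.all((v == 0) | (v == 1)):
        raise ParameterError("detect_crossings requires a binary (0/1) profile")
    pos = profile.positions_nm
    events: list[CrossingEvent] = []
    if v[0] == 1:
        events.append(CrossingEvent(float(pos[0]), "enter", real=False))
    diff = np.diff(v)
    for i in np.flatnonzero(diff != 0):
        mid = 0.5 * (pos[i] + pos[i + 1])
        kind = "enter" if diff[i] > 0 else "exit"
        events.append(CrossingEvent(float(mid), kind))
    if v[-1] == 1:
        events.append(CrossingEvent(float(pos[-1]), "exit", real=False))
    return events


def bands_from_crossings(events: list[CrossingEvent], channel: str = "") -> list[Band]:
    """Pair alternating enter/exit events into bands, ordered by center.

    A band is complete only if both its edges are real transitions. A
    non-alternating event stream indicates an upstream bug and raises.
    """
    bands: list[Band] = []
    pending: CrossingEvent | None = None
    for ev in events:
        if ev.kind == "enter":
            if pending is not None:
                raise RuntimeError("internal error: consecutive enter events")
            pending = ev
        else:
            if pending is None:
                raise RuntimeError("internal error: exit without enter")
            bands.append(
                Band(
                    pending.position_nm,
                    ev.position_nm,
                    channel=channel,
                    complete=pending.real and ev.real,
                )
            )
            pending = None
    if pending is not None:
        raise RuntimeError("internal error: unmatched enter event")
    return sorted(bands, key=lambda b: b.center_nm)


def scan_bands(mask: BinaryMask, path: LineScanPath, channel: str = "") -> list[Band]:
    """Convenience: profile a mask along a path and return its bands."""
    profile = extract_profile(mask, path)
    return bands_from_crossings(detect_crossings(profile), channel=channel)


# ---------------------------------------------------------------------------
# Automatic scan placement
# ---------------------------------------------------------------------------

def estimate_orientation(img: Image2D | BinaryMask, snr: float = 3.0) -> float:
    """Stripe-normal direction (degrees) from the 2D power-spectrum peak.

    The dominant non-DC peak of the Hann-windowed power spectrum gives the
    spatial frequency of the striation; its direction is the stripe normal.
    Ties within floating tolerance break toward the lower spatial frequency.
    Raises :class:`NoStriationError` if no peak exceeds ``snr`` times the
    median spectral magnitude.
    """
    pix = img.pixels.astype(float)
    h, w = pix.shape
    win = np.outer(hann(h), hann(w))
    spec = np.abs(np.fft.fftshift(np.fft.fft2((pix - pix.mean()) * win)))
    fy = np.fft.fftshift(np.fft.fftfreq(h))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(w))[None, :]
    radius = np.hypot(fy, fx)
    # suppress DC and the windowing leakage immediately around it
    dc_guard = radius < 1.5 / min(h, w)
    spec_m = np.where(dc_guard, 0.0, spec)
    floor = np.median(spec_m[~dc_guard])
    peak_val = spec_m.max()
    # the expected maximum of n featureless (Rayleigh) bins is
    # median * sqrt(ln n / ln 2); a real striation peak must clear it
    n_bins = int((~dc_guard).sum())
    noise_ceiling = floor * np.sqrt(np.log(max(n_bins, 2)) / np.log(2.0))
    if floor > 0 and peak_val < snr * noise_ceiling:
        raise NoStriationError("no striation detected")
    near = spec_m >= peak_val * (1.0 - 1e-9)
    cand = np.argwhere(near)
    best = cand[np.argmin(radius[near])]
    ang = np.rad2deg(np.arctan2(float(fy[best[0], 0]), float(fx[0, best[1]])))
    # a stripe normal is an axis: fold into (-90, 90]
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return float(ang)


def _clip_line_to_rect(
    point: tuple[float, float],
    direction: tuple[float, float],
    w: int,
    h: int,
    margin: float = 0.5,
) -> tuple[tuple[float, float], tuple[float, float]] | None:
    """Liang-Barsky clip of an infinite line to the image rectangle."""
    x0, y0 = point
    dx, dy = direction
    tmin, tmax = -np.inf, np.inf
    for p0, d, lo, hi in (
        (x0, dx, margin, w - 1 - margin),
        (y0, dy, margin, h - 1 - margin),
    ):
        if abs(d) < 1e-12:
            if not (lo <= p0 <= hi):
                return None
        else:
            t1, t2 = (lo - p0) / d, (hi - p0) / d
            tmin = max(tmin, min(t1, t2))
            tmax = min(tmax, max(t1, t2))
    if tmax <= tmin:
        return None
    return (
        (x0 + tmin * dx, y0 + tmin * dy),
        (x0 + tmax * dx, y0 + tmax * dy),
    )


def auto_paths(
    img: Image2D | BinaryMask,
    n_scans: int = 5,
    min_separation_px: float = 8.0,
    seed: int = 0,
    sample_step_px: float = 0.25,
) -> list[LineScanPath]:
    """Place parallel scan paths along the estimated stripe normal.

    Paths span the field, are pairwise separated by at least
    ``min_separation_px`` perpendicular to the scan direction, and are
    deterministic for a fixed seed (the seed jitters the path offsets within
    their allotted slots).
    """
    if n_scans < 1:
        raise ParameterError("n_scans must be >= 1")
    theta = np.deg2rad(estimate_orientation(img))
    d = (float(np.cos(theta)), float(np.sin(theta)))
    e = (-d[1], d[0])  # perpendicular: offsets between parallel paths
    h, w = img.pixels.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    # usable half-extent of the field along the offset direction
    half = (w / 2.0 - 1.0) * abs(e[0]) + (h / 2.0 - 1.0) * abs(e[1])
    span = 2.0 * 0.9 * half
    sep = span / n_scans
    if sep < min_separation_px:
        sep = min_separation_px
        span = sep * n_scans
        if span > 2.0 * half:
            raise ParameterError(
                f"cannot place {n_scans} paths {min_separation_px} px apart "
                f"in a field with {2 * half:.0f} px of usable extent"
            )
    rng = np.random.default_rng(seed)
    jitter_amp = max(0.0, (sep - min_separation_px) / 2.0)
    paths: list[LineScanPath] = []
    for i in range(n_scans):
        offset = (i - (n_scans - 1) / 2.0) * sep
        offset += rng.uniform(-jitter_amp, jitter_amp) if jitter_amp > 0 else 0.0
        point = (cx + offset * e[0], cy + offset * e[1])
        clipped = _clip_line_to_rect(point, d, w, h)
        if clipped is None:  # pragma: no cover - offsets stay inside the field
            raise ParameterError("scan path fell outside the image")
        paths.append(LineScanPath(clipped[0], clipped[1], sample_step_px))
    return paths
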