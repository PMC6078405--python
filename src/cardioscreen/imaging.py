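"""Cardiac diameter extraction from beating-heart fluorescence movies.

The heart tube appears as two bright wall bands flanking a dark lumen.
Two measurement routes are provided, mirroring the two stages of the screen:

* **Primary-screen route** — flatten the movie into a single frame (robust
  low-percentile projection over time), whose dark transverse gap spans every
  position the lumen ever occupied, i.e. the *diastolic* lumen; threshold the
  profile to obtain the diastolic diameter DD.
* **Validation route** — build an M-mode (kymograph) by stacking the intensity
  profile along one fixed transverse line over time, trace the lumen diameter
  frame by frame, and segment beats to obtain EDD (end-diastolic diameter),
  ESD (end-systolic diameter) and fractional shortening
  FS = 100·(EDD − ESD)/EDD.

All diameters are measured between the *inner* wall edges, located at the
half-range intensity crossing of a lightly smoothed profile, with sub-pixel
linear interpolation of the crossing position. Pixel indices are 0-based;
physical units are µm via ``pixel_size``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "MovieStack",
    "MModeImage",
    "DiameterTrace",
    "CardiacMeasures",
    "ImagingError",
    "EdgeNotFoundError",
    "TraceRejectedError",
    "UndefinedFSError",
    "default_line_position",
    "build_mmode",
    "flatten_frames",
    "estimate_dd",
    "trace_diameters",
    "estimate_heart_rate",
    "measure_cardiac",
    "measure_movie",
]

FLAG_OK = "ok"
FLAG_EDGE_NOT_FOUND = "edge_not_found"
FLAG_INTERPOLATED = "interpolated"


class ImagingError(Exception):
    """Base class for measurement failures."""


class EdgeNotFoundError(ImagingError):
    """No dark lumen run could be located in an intensity profile."""


class TraceRejectedError(ImagingError):
    """Too many M-mode rows were unresolvable for a trustworthy trace."""


class UndefinedFSError(ImagingError):
    """Fractional shortening is undefined (EDD = ESD = 0)."""


@dataclass(frozen=True)
class MovieStack:
    """A time-ordered stack of 2D fluorescence frames.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity rasters, time-major.
    frame_rate : float
        Frames per second.
    pixel_size : float
        µm per pixel (isotropic).
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {frames.shape}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration(self) -> float:
        """Movie duration in seconds."""
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class MModeImage:
    """Space–time image: row *t* is frame *t*'s profile along one fixed line."""

    rows: np.ndarray  # (T, W)
    line_position: int
    frame_rate: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows)
        if rows.ndim != 2:
            raise ValueError("rows must be a 2D (time x width) array")
        object.__setattr__(self, "rows", rows)

    @property
    def n_frames(self) -> int:
        return self.rows.shape[0]


@dataclass(frozen=True)
class DiameterTrace:
    """Per-frame lumen diameter along a fixed transverse line, in µm."""

    values: np.ndarray  # (T,), µm
    frame_rate: float
    quality_flags: np.ndarray = field(default=None)  # (T,) of {ok, edge_not_found, interpolated}

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        flags = self.quality_flags
        if flags is None:
            flags = np.full(values.shape, FLAG_OK, dtype="<U16")
        flags = np.asarray(flags)
        if flags.shape != values.shape:
            raise ValueError("quality_flags must match values in length")
        if np.any(values < 0):
            raise ValueError("diameters must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "quality_flags", flags)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate


@dataclass(frozen=True)
class CardiacMeasures:
    """Per-fly cardiac readouts.

    DD is the primary-screen diastolic estimate (flattened-frame method);
    EDD/ESD/FS come from the beat-resolved trace. ``FS`` is in percent.
    """

    EDD: float
    ESD: float
    FS: float
    DD: float | None = None
    n_beats: int | None = None

    def __post_init__(self) -> None:
        if self.ESD > self.EDD + 1e-9:
            raise ValueError("ESD must not exceed EDD")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# M-mode construction and projections
# ---------------------------------------------------------------------------

def default_line_position(movie: MovieStack) -> int:
    """Auto-locate the beating region: the frame row of maximal temporal variance."""
    var = movie.frames.var(axis=0)  # (H, W)
    return int(np.argmax(var.mean(axis=1)))


def build_mmode(movie: MovieStack, line_position: int | None = None) -> MModeImage:
    """Stack the intensity profile at ``line_position`` across all frames.

    Row *t* of the result is frame *t*'s profile along the chosen transverse
    line; wall motion appears as oscillating bright bands.
    """
    if line_position is None:
        line_position = default_line_position(movie)
    height = movie.frames.shape[1]
    if not 0 <= line_position < height:
        raise IndexError(
            f"line_position {line_position} outside frame height {height}"
        )
    rows = movie.frames[:, line_position, :].copy()
    return MModeImage(
        rows=rows,
        line_position=int(line_position),
        frame_rate=movie.frame_rate,
        pixel_size=movie.pixel_size,
    )


def flatten_frames(
    movie: MovieStack, method: str = "percentile", percentile: float = 5.0
) -> np.ndarray:
    """Project the movie onto a single frame for diastolic-diameter estimation.

    With bright walls and a dark lumen, the pixel-wise minimum over time is
    dark at every position the lumen ever occupied — the union of lumen
    positions, whose width is the diastolic lumen. The default is a robust
    5th-percentile projection, which tolerates isolated dark/corrupt frames;
    ``method="min"`` gives the strict minimum projection.
    """
    if movie.n_frames < 2:
        raise ValueError("flattening requires at least 2 frames")
    if method == "min":
        return movie.frames.min(axis=0)
    if method == "percentile":
        return np.percentile(movie.frames, percentile, axis=0)
    raise ValueError(f"unknown projection method {method!r}")


# ---------------------------------------------------------------------------
# Edge detection on 1D profiles
# ---------------------------------------------------------------------------

def _central_dark_run(
    profile: np.ndarray, threshold_fraction: float, smooth_sigma: float
) -> tuple[float, float] | None:
    """Locate the central sub-threshold (dark) run of a wall/lumen profile.

    The profile is Gaussian-smoothed, thresholded at
    ``min + threshold_fraction * (max - min)``, and the dark run lying between
    bright segments that contains the interior intensity minimum is returned
    as sub-pixel ``(left, right)`` crossing positions. Returns None when no
    interior dark run exists (edge not found).
    """
    prof = np.asarray(profile, dtype=float)
    if smooth_sigma > 0:
        prof = gaussian_filter1d(prof, smooth_sigma, mode="nearest")
    lo, hi = prof.min(), prof.max()
    if hi <= lo:
        return None
    thr = lo + threshold_fraction * (hi - lo)
    bright = prof > thr
    idx = np.flatnonzero(bright)
    if idx.size == 0:
        return None
    first, last = idx[0], idx[-1]
    interior = np.arange(first, last + 1)
    dark_interior = interior[~bright[first : last + 1]]
    if dark_interior.size == 0:
        return None
    # split dark interior pixels into runs
    breaks = np.flatnonzero(np.diff(dark_interior) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [dark_interior.size - 1]))
    runs = [(dark_interior[s], dark_interior[e]) for s, e in zip(starts, ends)]
    # pick the run containing the darkest interior pixel; fall back to widest
    dark_vals = prof[dark_interior]
    darkest = dark_interior[int(np.argmin(dark_vals))]
    chosen = None
    for a, b in runs:
        if a <= darkest <= b:
            chosen = (a, b)
            break
    if chosen is None:  # pragma: no cover - darkest always lies in some run
        chosen = max(runs, key=lambda r: r[1] - r[0])
    a, b = chosen
    # sub-pixel threshold crossings just outside the run
    left = float(a)
    if a > 0:
        denom = prof[a - 1] - prof[a]
        if denom > 0:
            left = (a - 1) + (prof[a - 1] - thr) / denom
    right = float(b)
    if b < len(prof) - 1:
        denom = prof[b + 1] - prof[b]
        if denom > 0:
            right = (b + 1) - (prof[b + 1] - thr) / denom
    return left, right


def estimate_dd(
    flattened: np.ndarray,
    line_position: int,
    pixel_size: float = 1.0,
    threshold_fraction: float = 0.5,
    smooth_sigma: float = 1.0,
) -> float:
    """Diastolic diameter (µm) from a flattened-frame projection.

    Extracts the profile at ``line_position``, smooths it, thresholds at
    ``threshold_fraction`` of its dynamic range and returns the width of the
    central dark run — the diastolic lumen — in µm.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    flattened = np.asarray(flattened)
    if not 0 <= line_position < flattened.shape[0]:
        raise IndexError("line_position outside flattened image")
    run = _central_dark_run(flattened[line_position], threshold_fraction, smooth_sigma)
    if run is None:
        raise EdgeNotFoundError(
            f"no dark lumen run found at line {line_position}"
        )
    left, right = run
    return (right - left) * pixel_size


def trace_diameters(
    mmode: MModeImage,
    threshold_fraction: float = 0.5,
    smooth_sigma: float = 1.0,
    max_bad_fraction: float = 0.2,
) -> DiameterTrace:
    """Per-frame lumen diameter from an M-mode image.

    Each row is edge-detected as in :func:`estimate_dd`; rows without a
    detectable lumen gap are linearly interpolated from neighbouring frames
    and flagged ``interpolated``. The trace is rejected when more than
    ``max_bad_fraction`` of rows are unresolvable.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    n = mmode.n_frames
    values = np.full(n, np.nan)
    flags = np.full(n, FLAG_OK, dtype="<U16")
    for t in range(n):
        run = _central_dark_run(mmode.rows[t], threshold_fraction, smooth_sigma)
        if run is None:
            flags[t] = FLAG_EDGE_NOT_FOUND
        else:
            values[t] = (run[1] - run[0]) * mmode.pixel_size
    bad = np.isnan(values)
    if bad.mean() > max_bad_fraction:
        raise TraceRejectedError(
            f"{int(bad.sum())}/{n} rows unresolvable "
            f"(> {max_bad_fraction:.0%}); trace rejected"
        )
    if bad.any():
        good = np.flatnonzero(~bad)
        values[bad] = np.interp(np.flatnonzero(bad), good, values[good])
        flags[bad] = FLAG_INTERPOLATED
    return DiameterTrace(values=values, frame_rate=mmode.frame_rate, quality_flags=flags)


# ---------------------------------------------------------------------------
# Beat segmentation and cardiac measures
# ---------------------------------------------------------------------------

def estimate_heart_rate(trace: DiameterTrace) -> float | None:
    """Heart rate (beats/s) from the trace autocorrelation; None if aperiodic."""
    x = trace.values - trace.values.mean()
    n = len(x)
    if n < 4 or np.allclose(x, 0):
        return None
    ac = np.correlate(x, x, mode="full")[n - 1 :]
    ac = ac / ac[0]
    # first prominent autocorrelation peak at lag >= 2 gives the beat period
    peaks, props = find_peaks(ac[1:], height=0.1)
    peaks = peaks + 1
    peaks = peaks[(peaks >= 2) & (peaks <= n // 2)]
    if peaks.size == 0:
        return None
    lag = int(peaks[np.argmax(ac[peaks])])
    return trace.frame_rate / lag


def measure_cardiac(
    trace: DiameterTrace,
    smooth_sigma: float | None = None,
    min_beats: int = 3,
) -> CardiacMeasures:
    """EDD, ESD and FS from a diameter trace.

    EDD is the mean of beat-wise diastolic peaks and ESD the mean of systolic
    troughs of the (lightly smoothed) trace; beats are segmented with a
    minimum peak separation of half the autocorrelation-estimated beat
    period. When fewer than ``min_beats`` beats are detected the estimates
    fall back to the 95th/5th percentiles of the trace, which guards
    arrhythmic or short recordings. FS = 100·(EDD − ESD)/EDD.
    """
    values = trace.values
    rate = estimate_heart_rate(trace)
    period = trace.frame_rate / rate if rate else None
    if smooth_sigma is None:
        # scale smoothing with the beat period so short-period traces survive
        smooth_sigma = 0.0 if period is None else max(0.0, period / 20.0)
    smoothed = (
        gaussian_filter1d(values, smooth_sigma, mode="nearest")
        if smooth_sigma > 0
        else values
    )
    n_beats = 0
    if period is not None:
        distance = max(1, int(round(period / 2)))
        # prominence guard: noise dips on the flat diastolic plateau must not
        # count as systolic troughs
        prominence = 0.25 * np.ptp(smoothed)
        peaks, _ = find_peaks(smoothed, distance=distance, prominence=prominence)
        troughs, _ = find_peaks(-smoothed, distance=distance, prominence=prominence)
        n_beats = min(len(peaks), len(troughs))
    if n_beats >= min_beats:
        edd = float(smoothed[peaks].mean())
        esd = float(smoothed[troughs].mean())
    else:
        edd = float(np.percentile(smoothed, 95))
        esd = float(np.percentile(smoothed, 5))
    esd = min(esd, edd)
    if edd <= 0:
        raise UndefinedFSError("flat zero trace: fractional shortening undefined")
    fs = 100.0 * (edd - esd) / edd
    return CardiacMeasures(EDD=edd, ESD=esd, FS=fs, n_beats=n_beats or None)


def measure_movie(
    movie: MovieStack,
    line_position: int | None = None,
    threshold_fraction: float = 0.5,
    smooth_sigma: float = 1.0,
    projection: str = "percentile",
) -> CardiacMeasures:
    """Full per-fly measurement: DD from the flattened frame, EDD/ESD/FS from the trace."""
    if line_position is None:
        line_position = default_line_position(movie)
    flattened = flatten_frames(movie, method=projection)
    dd = estimate_dd(
        flattened,
        line_position,
        pixel_size=movie.pixel_size,
        threshold_fraction=threshold_fraction,
        smooth_sigma=smooth_sigma,
    )
    mmode = build_mmode(movie, line_position)
    trace = trace_diameters(
        mmode, threshold_fraction=threshold_fraction, smooth_sigma=smooth_sigma
    )
    meas = measure_cardiac(trace)
    return CardiacMeasures(
        EDD=meas.EDD, ESD=meas.ESD, FS=meas.FS, DD=dd, n_beats=meas.n_beats
    )
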