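"""Resolution accounting.

Fourier shell correlation, threshold crossing, Rosenthal–Henderson
(ResLog) B-factor fits, detection of the Ewald-correction gain onset,
magnification-anisotropy estimation from defocus pairs, movie frame-range
selection and B-factor sharpening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._fft import cfftn, icfftn, radius_grid
from .phantom import Volume

__all__ = [
    "FSCCurve",
    "ResLogTable",
    "fsc",
    "resolution_at_threshold",
    "reslog_fit_bfactor",
    "gain_onset",
    "estimate_anisotropy_from_defoci",
    "select_frame_range",
    "sharpen_map",
]


@dataclass
class FSCCurve:
    """Per-shell correlation between two volumes.

    shell_frequencies are shell centres in 1/A, spaced 1/(box·pixel);
    shell k covers voxel radii [k, k+1).
    """

    shell_frequencies: np.ndarray
    correlations: np.ndarray
    shell_counts: np.ndarray | None = None

    def __post_init__(self):
        self.shell_frequencies = np.asarray(self.shell_frequencies, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if self.shell_frequencies.shape != self.correlations.shape:
            raise ValueError("frequency and correlation arrays must match")
        if np.any(np.diff(self.shell_frequencies) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")
        if np.any(np.abs(self.correlations) > 1.0 + 1e-6):
            raise ValueError("correlations must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.shell_frequencies)

    @property
    def shell_width(self) -> float:
        return float(self.shell_frequencies[1] - self.shell_frequencies[0])


def fsc(v1: Volume, v2: Volume) -> FSCCurve:
    """Fourier shell correlation between two volumes on matched grids.

    Shells are the half-open voxel-radius bins [k, k+1), k = 0..box/2-1;
    the reported frequency of shell k is its centre (k+0.5)/(box·pixel).
    """
    if v1.grid.shape != v2.grid.shape:
        raise ValueError("volumes must share the same box")
    if not math.isclose(v1.pixel_size, v2.pixel_size, rel_tol=1e-6):
        raise ValueError("volumes must share the same pixel size")
    box = v1.box
    f1 = cfftn(v1.grid)
    f2 = cfftn(v2.grid)
    r = radius_grid(f1.shape)
    shells = np.floor(r).astype(int).ravel()
    nshells = box // 2
    valid = shells < nshells
    shells = shells[valid]
    a = f1.ravel()[valid]
    b = f2.ravel()[valid]

    cross = np.bincount(shells, weights=(a * np.conj(b)).real, minlength=nshells)
    p1 = np.bincount(shells, weights=np.abs(a) ** 2, minlength=nshells)
    p2 = np.bincount(shells, weights=np.abs(b) ** 2, minlength=nshells)
    counts = np.bincount(shells, minlength=nshells)
    denom = np.sqrt(p1 * p2)
    corr = np.divide(cross, denom, out=np.zeros(nshells), where=denom > 0)
    corr = np.clip(corr, -1.0, 1.0)
    freqs = (np.arange(nshells) + 0.5) / (box * v1.pixel_size)
    return FSCCurve(freqs, corr, counts)


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.143) -> tuple[float, bool]:
    """Resolution (A) at the first downward threshold crossing of an FSC curve.

    Linearly interpolates the crossing frequency between shells.  If the
    curve never drops below the threshold, returns the last shell's
    resolution with the ``at_nyquist`` flag set.

    Returns
    -------
    (resolution_A, at_nyquist)
    """
    if len(curve) == 0:
        raise ValueError("empty FSC curve")
    f = curve.shell_frequencies
    c = curve.correlations
    for k in range(1, len(c)):
        if c[k] < threshold <= c[k - 1]:
            frac = (c[k - 1] - threshold) / (c[k - 1] - c[k])
            freq = f[k - 1] + frac * (f[k] - f[k - 1])
            return 1.0 / freq, False
    if c[0] < threshold:
        return 1.0 / f[0], False
    return 1.0 / f[-1], True


@dataclass
class ResLogTable:
    """(particle count, replicate, resolution) series for a B-factor fit."""

    n_particles: np.ndarray
    resolutions: np.ndarray
    replicates: np.ndarray | None = None
    fitted_bfactor: float | None = None
    fit_intercept: float | None = None

    def __post_init__(self):
        self.n_particles = np.asarray(self.n_particles, dtype=float)
        self.resolutions = np.asarray(self.resolutions, dtype=float)
        if self.n_particles.shape != self.resolutions.shape:
            raise ValueError("n_particles and resolutions must match")
        if np.any(self.n_particles < 1):
            raise ValueError("particle counts must be >= 1")
        if np.any(self.resolutions <= 0):
            raise ValueError("resolutions must be positive")
        if self.replicates is None:
            self.replicates = np.zeros(len(self.n_particles), dtype=int)


def reslog_fit_bfactor(
    table: ResLogTable, residual_limit: float = 0.2
) -> tuple[float, float]:
    """Rosenthal–Henderson fit ln(N) = (B/2)·(1/d²) + c over the linear regime.

    Points are sorted by particle count and the fit is restricted to the
    first linear portion: the largest prefix of distinct N values whose
    least-squares residual RMS (in ln N units) stays below
    ``residual_limit``.  Returns (B, intercept) with B in A².
    """
    n = table.n_particles
    d = table.resolutions
    distinct = np.unique(n)
    if len(distinct) < 3:
        raise ValueError("need at least 3 distinct particle counts")
    order = np.argsort(n)
    n, d = n[order], d[order]

    def _fit(mask):
        x = 1.0 / d[mask] ** 2
        y = np.log(n[mask])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        return slope, intercept, float(np.sqrt(np.mean(resid**2)))

    best = None
    for k in range(len(distinct), 2, -1):
        mask = n <= distinct[k - 1]
        slope, intercept, rms = _fit(mask)
        if rms <= residual_limit:
            best = (slope, intercept)
            break
    if best is None:  # no prefix met the limit; fall back to the smallest
        mask = n <= distinct[2]
        slope, intercept, _ = _fit(mask)
        best = (slope, intercept)
    slope, intercept = best
    b = 2.0 * slope
    table.fitted_bfactor = float(b)
    table.fit_intercept = float(intercept)
    return float(b), float(intercept)


def gain_onset(
    fsc_corrected: FSCCurve,
    fsc_uncorrected: FSCCurve,
    min_gain: float = 0.02,
    min_run: int = 3,
) -> float | None:
    """Lowest frequency (1/A) of a sustained correction gain, or None.

    The onset is the first shell from which (corrected - uncorrected) >=
    min_gain holds for at least min_run consecutive shells.  "Noticeable"
    is operationalised by the two parameters; the defaults flag a 0.02 FSC
    gain sustained over 3 shells.
    """
    if len(fsc_corrected) != len(fsc_uncorrected) or not np.allclose(
        fsc_corrected.shell_frequencies, fsc_uncorrected.shell_frequencies
    ):
        raise ValueError("FSC curves must share the same shells")
    diff = fsc_corrected.correlations - fsc_uncorrected.correlations
    good = diff >= min_gain
    run = 0
    for k in range(len(good)):
        run = run + 1 if good[k] else 0
        if run >= min_run:
            return float(fsc_corrected.shell_frequencies[k - min_run + 1])
    return None


def estimate_anisotropy_from_defoci(pairs) -> float:
    """Magnification anisotropy (percent) from (defocusU, defocusV, angle) rows.

    A scale distortion of alpha percent makes the astigmatism estimate
    |defocusU - defocusV| grow linearly with the defocus magnitude; the
    least-squares slope of (defocusU - defocusV) against the mean defocus,
    times 100, estimates alpha.  The sign reports which axis is magnified.
    """
    arr = np.asarray([(p[0], p[1]) for p in pairs], dtype=float)
    if arr.shape[0] < 10:
        raise ValueError("need at least 10 defocus pairs")
    du, dv = arr[:, 0], arr[:, 1]
    mean = 0.5 * (du + dv)
    if np.ptp(mean) <= 0:
        raise ValueError("degenerate defocus range: all mean defoci equal")
    diff = du - dv
    slope = np.polyfit(mean, diff, 1)[0]
    return float(slope * 100.0)


def select_frame_range(
    per_frame_quality, cutoff: float
) -> tuple[int, int] | None:
    """Maximal contiguous run of movie frames better than a resolution cutoff.

    ``per_frame_quality`` is a list of (frame, resolution_A); a frame
    qualifies when its resolution is strictly better (smaller) than
    ``cutoff``.  Ties between equally long runs break toward earlier
    frames.  Returns (first, last) frame numbers, or None when no frame
    qualifies.
    """
    if not per_frame_quality:
        raise ValueError("empty per-frame quality list")
    items = sorted(per_frame_quality)
    best: tuple[int, int] | None = None
    cur_start = None
    prev_frame = None
    for frame, res in items:
        ok = res < cutoff
        contiguous = prev_frame is not None and frame == prev_frame + 1
        if ok:
            if cur_start is None or not contiguous:
                cur_start = frame
            if best is None or (frame - cur_start) > (best[1] - best[0]):
                best = (cur_start, frame)
        else:
            cur_start = None
        prev_frame = frame
    return best


def sharpen_map(
    v: Volume, bfactor: float, flatten_band: tuple[float, float] | None = None
) -> Volume:
    """B-factor sharpening with optional spectral flattening.

    Fourier amplitudes are multiplied by exp(-B s²/4) (negative B
    sharpens).  When ``flatten_band=(low_A, high_A)`` is given, the
    rotationally averaged amplitude spectrum inside the band is first
    normalised to flat (each shell divided by its mean amplitude).
    """
    if not np.isfinite(bfactor):
        raise ValueError("bfactor must be finite")
    box = v.box
    f = cfftn(v.grid)
    r = radius_grid(f.shape)
    shells = np.floor(r).astype(int)
    s = r / (box * v.pixel_size)
    if flatten_band is not None:
        low_a, high_a = max(flatten_band), min(flatten_band)
        nshells = box // 2
        amp = np.abs(f)
        mean_amp = np.bincount(
            shells.ravel().clip(max=nshells), weights=amp.ravel(), minlength=nshells + 1
        ) / np.maximum(np.bincount(shells.ravel().clip(max=nshells), minlength=nshells + 1), 1)
        scale = np.ones(nshells + 1)
        freqs = (np.arange(nshells + 1) + 0.5) / (box * v.pixel_size)
        with np.errstate(divide="ignore"):
            in_band = (freqs >= 1.0 / low_a) & (freqs <= 1.0 / high_a) & (mean_amp > 0)
        scale[in_band] = 1.0 / mean_amp[in_band]
        f = f * scale[shells.clip(max=nshells)]
    f = f * np.exp(-bfactor * s * s / 4.0)
    out = icfftn(f)
    return Volume(out.real, v.pixel_size)
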