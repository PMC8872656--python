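"""Beat segmentation, ensemble averaging and fiducial-point detection.

A pulse period carries the percussion (main) wave h1, the tidal
(predicrotic) wave h3, the dicrotic notch h4 and the dicrotic wave h5
(Fig.-1-style nomenclature of time-domain pulse analysis).  All amplitudes
are measured relative to the beat onset except h5, which is measured as
the rise of the dicrotic wave above the notch level — this allows values
near zero or negative when the dicrotic wave is absent, matching how the
feature behaves clinically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import DegenerateBeatError, InsufficientDataError


@dataclass
class Waveform:
    """A 1-D amplitude sequence at a fixed sampling rate."""

    amplitudes: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1 or len(self.amplitudes) < 2:
            raise ValueError("waveform needs at least 2 samples")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("waveform contains non-finite values")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.amplitudes)

    @property
    def duration(self) -> float:
        return len(self.amplitudes) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.amplitudes)) / self.fs


@dataclass
class BeatSegmentation:
    """Beat feet (onset sample indices) and the valid inter-onset slices."""

    onsets: np.ndarray
    fs: float
    slices: list[tuple[int, int]] = field(default_factory=list)
    status: str = "ok"

    @property
    def n_beats(self) -> int:
        return len(self.slices)


@dataclass
class MRPWSelection:
    """The most representative pulse wave: the beat best matching the APW."""

    beat_index: int
    mrpw: Waveform
    cc: float
    window: tuple[int, int]
    all_cc: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class FiducialSet:
    """Times (s from beat onset) and amplitudes (relative to onset) of one beat.

    ``h5`` is relative to the notch level.  ``t1``/``t4`` are onset-to-peak and
    onset-to-notch times, ``t5`` is notch-to-end, ``w`` the main-wave width at
    the one-third-below-peak level.
    """

    t_h1: float
    h1: float
    t_h4: float
    h4: float
    t: float
    w: float
    t_h3: float = np.nan
    h3: float = np.nan
    t_h5: float = np.nan
    h5: float = 0.0
    has_h3: bool = False
    has_h5: bool = False
    h3_method: str | None = None  # 'peak' | 'inflection' | None
    h4_method: str = "minimum"  # 'minimum' | 'curvature' | 'window_min'
    t_onset: float = 0.0

    @property
    def t1(self) -> float:
        return self.t_h1

    @property
    def t4(self) -> float:
        return self.t_h4

    @property
    def t5(self) -> float:
        return self.t - self.t_h4


def segment_beats(
    signal: Waveform, min_hr_bpm: float = 40.0, max_hr_bpm: float = 180.0
) -> BeatSegmentation:
    """Locate beat feet: local minima immediately preceding steep upstrokes.

    The upstroke detector thresholds the first difference at an adaptive
    level; candidate onsets closer than the refractory interval (one beat at
    ``max_hr_bpm``) are merged, and only inter-onset gaps consistent with
    [min_hr, max_hr] become beat slices.
    """
    x = signal.amplitudes
    fs = signal.fs
    if np.ptp(x) == 0.0:
        return BeatSegmentation(np.array([], dtype=int), fs, [], status="constant signal")
    d = np.diff(x)
    pos = d[d > 0]
    if len(pos) == 0:
        return BeatSegmentation(np.array([], dtype=int), fs, [], status="no upstrokes")
    thr = 0.5 * np.percentile(pos, 98)
    refractory = int(round(fs * 60.0 / max_hr_bpm))
    # steep-upstroke events, one per beat
    events, _ = find_peaks(d, height=thr, distance=max(refractory, 1))
    onsets = []
    for ev in events:
        i = ev
        # walk back to the local minimum (or plateau edge) preceding the upstroke
        while i > 0 and x[i - 1] < x[i]:
            i -= 1
        if not onsets or i - onsets[-1] >= refractory:
            onsets.append(i)
    onsets_arr = np.asarray(onsets, dtype=int)
    if len(onsets_arr) == 0:
        warnings.warn("no beats found", stacklevel=2)
        return BeatSegmentation(onsets_arr, fs, [], status="no beats")
    min_len = fs * 60.0 / max_hr_bpm
    max_len = fs * 60.0 / min_hr_bpm
    slices = [
        (int(a), int(b))
        for a, b in zip(onsets_arr[:-1], onsets_arr[1:])
        if min_len <= b - a <= max_len
    ]
    if not slices and len(onsets_arr) == 1:
        # single beat: close the slice at the end of the decaying limb
        end = min(len(x), onsets_arr[0] + int(max_len))
        if end - onsets_arr[0] >= min_len:
            slices = [(int(onsets_arr[0]), int(end))]
    return BeatSegmentation(onsets_arr, fs, slices)


def _resample(beat: np.ndarray, n_out: int) -> np.ndarray:
    if len(beat) == n_out:
        return beat.astype(float)
    src = np.linspace(0.0, 1.0, len(beat))
    dst = np.linspace(0.0, 1.0, n_out)
    return np.interp(dst, src, beat)


def compute_apw(signal: Waveform, seg: BeatSegmentation) -> Waveform:
    """Average pulse wave: beats linearly resampled to the median beat length
    and averaged pointwise."""
    if seg.n_beats < 2:
        raise InsufficientDataError("need at least 2 complete beats for the APW")
    beats = [signal.amplitudes[a:b] for a, b in seg.slices]
    med_len = int(round(float(np.median([len(b) for b in beats]))))
    stack = np.vstack([_resample(b, med_len) for b in beats])
    return Waveform(stack.mean(axis=0), fs=signal.fs)


def select_mrpw(signal: Waveform, seg: BeatSegmentation, apw: Waveform) -> MRPWSelection:
    """Pick the beat with maximal Pearson correlation against the APW.

    Beats are resampled to the APW length for the correlation; the returned
    waveform is the original, un-resampled beat.  Zero-variance beats are
    excluded with a warning; ties go to the earliest beat.
    """
    if seg.n_beats < 2:
        raise InsufficientDataError("need at least 2 beats to select an MRPW")
    template = apw.amplitudes
    ccs = np.full(seg.n_beats, -np.inf)
    for k, (a, b) in enumerate(seg.slices):
        beat = _resample(signal.amplitudes[a:b], len(template))
        if np.std(beat) == 0.0 or np.std(template) == 0.0:
            warnings.warn(f"beat {k} has zero variance; excluded from MRPW", stacklevel=2)
            continue
        ccs[k] = np.corrcoef(beat, template)[0, 1]
    if not np.any(np.isfinite(ccs)):
        raise InsufficientDataError("no beat with finite correlation")
    best = int(np.argmax(ccs))  # argmax takes the earliest on ties
    a, b = seg.slices[best]
    return MRPWSelection(
        beat_index=best,
        mrpw=Waveform(signal.amplitudes[a:b].copy(), fs=signal.fs),
        cc=float(ccs[best]),
        window=(a, b),
        all_cc=ccs,
    )


def _noise_sigma(x: np.ndarray, window: int) -> float:
    """Robust noise estimate from the residual of a quadratic local fit."""
    if len(x) <= window:
        return 0.0
    resid = x - savgol_filter(x, window, 2)
    return 1.4826 * float(np.median(np.abs(resid)))


def _savgol_noise_gain(window: int) -> float:
    """White-noise standard-deviation gain of quadratic Savitzky-Golay
    smoothing (L2 norm of the central convolution coefficients)."""
    from scipy.signal import savgol_coeffs

    return float(np.linalg.norm(savgol_coeffs(window, 2)))


def _smooth_if_noisy(x: np.ndarray, fs: float) -> np.ndarray:
    """Savitzky-Golay smoothing for extremum localization, applied only when
    the high-frequency residual indicates real noise (clean beats unchanged)."""
    window = max(5, int(round(0.07 * fs)) | 1)
    if len(x) <= window + 2:
        return x
    if _noise_sigma(x, window) > 0.003 * np.ptp(x):
        return savgol_filter(x, window, 2)
    return x


def _main_peak(x: np.ndarray) -> int:
    """Index of the percussion (main) wave.

    The earliest local maximum within 15% of the global maximum: heavy
    low-pass filtering can merge the tidal and dicrotic waves into a hump
    that marginally exceeds the percussion peak, and a near-equal peak that
    comes earlier is always the percussion wave.  For a clean beat this is
    exactly the global maximum.
    """
    i_max = int(np.argmax(x))
    peaks, _ = find_peaks(x)
    onset = x[0]
    candidates = [p for p in peaks if x[p] - onset >= 0.85 * (x[i_max] - onset)]
    return int(candidates[0]) if candidates else i_max


def width_at_fraction(beat: Waveform, level_fraction: float) -> float:
    """Width (s) of the main-wave lobe at ``level_fraction``·h1 above onset,
    with sub-sample linear interpolation at the two crossings."""
    if not (0 < level_fraction < 1):
        raise ValueError("level_fraction must lie in (0, 1)")
    x = beat.amplitudes
    i1 = _main_peak(x)
    h1 = x[i1] - x[0]
    if h1 <= 0:
        raise DegenerateBeatError("beat has no rise above its onset level")
    level = x[0] + level_fraction * h1
    # left crossing
    j = i1
    while j > 0 and x[j - 1] >= level:
        j -= 1
    if j == 0:
        t_left = 0.0
    else:
        t_left = (j - 1) + (level - x[j - 1]) / (x[j] - x[j - 1])
    # right crossing
    k = i1
    while k < len(x) - 1 and x[k + 1] >= level:
        k += 1
    if k == len(x) - 1:
        t_right = float(k)
    else:
        t_right = k + (x[k] - level) / (x[k] - x[k + 1])
    return (t_right - t_left) / beat.fs


def detect_fiducials(
    beat: Waveform,
    notch_window_fraction: float = 0.6,
    width_level: float = 2.0 / 3.0,
    smooth: bool | None = None,
) -> FiducialSet:
    """Detect h1/h3/h4/h5 and the timing parameters on a single-beat waveform.

    The beat must span one full period with its onset at index 0.  Detection:
    h1 at the percussion peak (the global maximum, or the earliest
    near-equal local maximum when filtering has merged the later waves
    into a comparable hump); h4 at the lowest local minimum within 0.6·t
    after the peak (bounding systole); h3 as the largest local maximum
    between peak and notch, falling back to the strongest concave-to-convex
    inflection of the descending limb when the tidal wave is merged into the
    main wave; h5 as the largest local maximum after the notch, measured
    above the notch level.  When the record is noisy, extrema are localized
    on a Savitzky-Golay-smoothed copy, candidates must clear a prominence
    gate scaled to the residual noise, and the most prominent candidate is
    preferred over the most extreme one (a chance dip can be deep but never
    prominent).
    """
    x = np.asarray(beat.amplitudes, dtype=float)
    fs = beat.fs
    n = len(x)
    window = max(5, int(round(0.07 * fs)) | 1)
    sigma = _noise_sigma(x, window)
    smoothed = False
    if smooth is None:
        xs = _smooth_if_noisy(x, fs)
        smoothed = xs is not x
    elif smooth:
        xs = savgol_filter(x, window, 2) if n > window + 2 else x
        smoothed = xs is not x
    else:
        xs = x
    # residual noise after smoothing still produces spurious local extrema;
    # demand prominence above the residual noise floor (clean beats: none)
    sigma_residual = sigma * _savgol_noise_gain(window) if smoothed else sigma
    noisy = sigma > 0.003 * np.ptp(x)
    prominence = 3.0 * sigma_residual if noisy else None
    onset_level = xs[0]
    i1 = _main_peak(xs)
    h1 = float(xs[i1] - onset_level)
    if h1 <= 0:
        raise DegenerateBeatError("no maximum above the onset level")
    t = n / fs

    # --- dicrotic notch: lowest local minimum in (i1, i1 + 0.6 n]
    # A true notch is followed by the dicrotic wave; on noisy records,
    # candidate minima must therefore be followed by a rise the residual
    # noise cannot produce, which excludes chance dips in the decaying tail
    # (and the shallow percussion-tidal dip, which precedes no wave).
    end4 = min(n, i1 + int(round(notch_window_fraction * n)) + 1)
    seg = xs[i1:end4]
    minima, _ = find_peaks(-seg, prominence=prominence)
    # the notch sits on the descending limb above the diastolic foot
    minima = minima[seg[minima] > onset_level]
    if noisy and len(minima) > 0:
        min_rise = max(3.0 * sigma_residual, 0.05 * h1)
        rises = np.array([np.max(seg[m:]) - seg[m] for m in minima])
        minima = minima[rises >= min_rise]
    h4_method = "minimum"
    if len(minima) > 0:
        i4 = i1 + int(minima[np.argmin(seg[minima])])
    else:
        # Heavy filtering can flatten the notch into a plateau with no local
        # minimum.  The notch then maps to the strongest convex bend (local
        # maximum of the second difference) of the descending limb -- valid
        # only if a concave bend follows, which separates a true diastolic
        # plateau/hump from plain monotone decay.
        i4 = _curvature_notch(xs, i1, end4, onset_level)
        if i4 is not None:
            h4_method = "curvature"
        else:
            i4 = i1 + int(np.argmin(seg))  # monotone decay: window minimum
            h4_method = "window_min"
    has_notch = h4_method != "window_min"
    h4 = float(xs[i4] - onset_level)

    # --- tidal wave between peak and notch
    t_h3 = np.nan
    h3 = np.nan
    h3_method: str | None = None
    if has_notch and i4 - i1 > 2:
        inner = xs[i1 : i4 + 1]
        peaks, _ = find_peaks(inner, prominence=prominence)
        if len(peaks) > 0:
            i3 = i1 + int(peaks[np.argmax(inner[peaks])])
            h3_method = "peak"
        else:
            # merged tidal wave: strongest concave->convex transition of the
            # descending limb (negative-to-positive crossing of the 2nd diff)
            i3 = _strongest_inflection(xs, i1, i4)
            h3_method = "inflection" if i3 is not None else None
        if h3_method is not None:
            t_h3 = i3 / fs
            h3 = float(xs[i3] - onset_level)

    # --- dicrotic wave after the notch
    t_h5 = np.nan
    h5 = 0.0
    has_h5 = False
    if has_notch and n - i4 > 2:
        tail = xs[i4:]
        peaks, _ = find_peaks(tail, prominence=prominence)
        if len(peaks) > 0:
            i5 = i4 + int(peaks[np.argmax(tail[peaks])])
            t_h5 = i5 / fs
            h5 = float(xs[i5] - xs[i4])
            has_h5 = True

    w = width_at_fraction(Waveform(xs, fs), width_level)
    t_h1 = i1 / fs
    t_h4 = i4 / fs
    if noisy:
        # sub-sample refinement: quadratic vertex over the extremum
        # neighbourhood averages out residual noise jitter
        t_h1 = _refine_extremum(xs, i1, fs)
        t_h4 = _refine_extremum(xs, i4, fs)
        if h3_method == "peak":
            t_h3 = _refine_extremum(xs, i3, fs)
        if has_h5:
            t_h5 = _refine_extremum(xs, i5, fs)
    return FiducialSet(
        t_h1=t_h1,
        h1=h1,
        t_h3=t_h3,
        h3=h3,
        t_h4=t_h4,
        h4=h4,
        t_h5=t_h5,
        h5=h5,
        t=t,
        w=w,
        has_h3=h3_method is not None,
        has_h5=has_h5,
        h3_method=h3_method,
        h4_method=h4_method,
    )


def _refine_extremum(x: np.ndarray, i: int, fs: float, half: int = 3) -> float:
    """Vertex (s) of a least-squares parabola through x[i-half : i+half+1];
    falls back to the sample time when the fit is flat or the vertex strays."""
    lo = max(0, i - half)
    hi = min(len(x), i + half + 1)
    if hi - lo < 3:
        return i / fs
    k = np.arange(lo, hi, dtype=float)
    a, b, _ = np.polyfit(k, x[lo:hi], 2)
    if a == 0.0:
        return i / fs
    vertex = -b / (2.0 * a)
    if abs(vertex - i) > half:
        return i / fs
    return float(vertex) / fs


def _curvature_notch(
    x: np.ndarray, i1: int, end4: int, onset_level: float
) -> int | None:
    """Notch estimate for plateau-shaped descending limbs.

    Returns the interior index of the largest positive second difference in
    (i1, end4), provided the curvature turns negative again afterwards
    (i.e. a diastolic hump or plateau end exists); None for monotone decay.
    """
    d2 = np.diff(x, 2)  # d2[k] is curvature at sample k + 1
    lo, hi = i1, min(end4 - 1, len(d2))
    if hi - lo < 2:
        return None
    window = d2[lo : hi - 1]  # curvatures at samples lo+1 .. hi-1
    k = int(np.argmax(window))
    if window[k] <= 0:
        return None
    idx = lo + 1 + k
    if x[idx] <= onset_level:
        return None
    if not np.any(d2[idx:] < 0):
        return None
    return idx


def _strongest_inflection(x: np.ndarray, i_from: int, i_to: int) -> int | None:
    """Strongest negative-to-positive zero crossing of the second difference
    in the open interval (i_from, i_to)."""
    d2 = np.diff(x, 2)  # d2[k] is curvature at sample k+1
    best, best_mag = None, 0.0
    for k in range(max(i_from - 1, 0), min(i_to - 1, len(d2) - 1)):
        idx = k + 1
        if i_from < idx < i_to and d2[k] < 0 <= d2[k + 1]:
            mag = d2[k + 1] - d2[k]
            if mag > best_mag:
                best, best_mag = idx, mag
    return best
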