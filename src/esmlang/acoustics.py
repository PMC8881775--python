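"""Acoustic voice-feature extraction from WAV clips.

A deliberately transparent reimplementation of the 13 voice parameters used
in the analyses: five pitch (F0) statistics on a semitone scale anchored at
27.5 Hz, three loudness statistics from an RMS intensity proxy, three voice
quality measures (jitter, shimmer, harmonics-to-noise ratio) and two
temporal measures (voiced segments per second, mean unvoiced segment
length).  The eGeMAPS internals of openSMILE are *not* reproduced; every
step here is a defined, testable algorithm:

* framing at 40 ms windows / 10 ms hop (long enough for a 55 Hz period);
* per-frame normalized autocorrelation over a 55-500 Hz search band with
  parabolic peak interpolation; a frame is voiced iff its peak is >= 0.45
  and its RMS is at most 60 dB below the clip peak;
* jitter and shimmer from pitch-period marks found by peak picking inside
  voiced segments;
* HNR from the normalized autocorrelation peak, ``10 log10(r/(1-r))``.

All pitch statistics are reported in semitones, ``12 log2(f / 27.5)``.
The loudness proxy is linear in signal amplitude, so scaling a clip changes
only the loudness family; F0, jitter, shimmer and HNR are scale invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "ACOUSTIC_FEATURES",
    "AudioClip",
    "VoicingTrack",
    "AcousticFeatureVector",
    "hz_to_semitone",
    "read_wav",
    "write_wav",
    "detect_voicing_and_f0",
    "extract_acoustic_features",
]

#: The 13 acoustic parameters, in reporting order.
ACOUSTIC_FEATURES = (
    "f0_mean", "f0_sd_norm", "f0_range", "f0_rise_slope", "f0_fall_slope",
    "loudness_mean", "loudness_rise_slope", "loudness_fall_slope",
    "jitter_mean", "shimmer_mean", "hnr_mean",
    "voiced_segments_per_second", "mean_unvoiced_segment_length",
)

TARGET_RATE = 16_000
F0_MIN, F0_MAX = 55.0, 500.0
VOICING_THRESHOLD = 0.45        # normalized autocorrelation peak
ENERGY_FLOOR_DB = 60.0          # below clip peak amplitude
FRAME_LEN, HOP = 0.040, 0.010   # seconds
_SEMITONE_TOL = 0.02            # contour flat-tolerance for slope runs


def hz_to_semitone(f_hz):
    """Semitone scale anchored at 27.5 Hz: ``12 * log2(f / 27.5)``."""
    f = np.asarray(f_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive for the semitone scale")
    out = 12.0 * np.log2(f / 27.5)
    return float(out) if np.isscalar(f_hz) else out


@dataclass(frozen=True)
class AudioClip:
    """Mono audio with samples in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def resampled(self, rate: int = TARGET_RATE) -> "AudioClip":
        if rate == self.sample_rate:
            return self
        g = math.gcd(rate, self.sample_rate)
        y = resample_poly(self.samples, rate // g, self.sample_rate // g)
        return AudioClip(samples=y, sample_rate=rate)


def read_wav(path: str | Path, resample_to: int | None = TARGET_RATE) -> AudioClip:
    """Read a PCM RIFF WAV file (8/16/32-bit or float), mono-mixing if needed."""
    rate, data = wavfile.read(path)
    x = np.asarray(data)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if x.dtype == np.int16:
        x = x / 32768.0
    elif x.dtype == np.uint8:
        x = (x.astype(float) - 128.0) / 128.0
    elif x.dtype == np.int32:
        x = x / 2147483648.0
    else:
        x = x.astype(float)
    clip = AudioClip(samples=x, sample_rate=rate)
    if resample_to is not None:
        clip = clip.resampled(resample_to)
    return clip


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write 16-bit PCM."""
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate, np.rint(x * 32767.0).astype(np.int16))


@dataclass(frozen=True)
class VoicingTrack:
    """Per-frame voicing decision, F0 and energy."""

    times: np.ndarray        # frame-center times, s
    voiced: np.ndarray       # bool
    f0: np.ndarray           # Hz on voiced frames, NaN elsewhere
    energy: np.ndarray       # frame RMS
    ac_peak: np.ndarray      # normalized autocorrelation peak, NaN if none
    frame_len: float
    hop: float
    clip_duration: float


def detect_voicing_and_f0(clip: AudioClip,
                          frame_len: float = FRAME_LEN,
                          hop: float = HOP,
                          f0_min: float = F0_MIN,
                          f0_max: float = F0_MAX,
                          voicing_threshold: float = VOICING_THRESHOLD,
                          energy_floor_db: float = ENERGY_FLOOR_DB) -> VoicingTrack:
    """Autocorrelation pitch tracking with voiced/unvoiced decision.

    For every frame the normalized autocorrelation is evaluated over lags in
    the F0 search band.  Among local maxima within 0.01 of the global band
    maximum the *shortest* lag wins (suppressing octave-down errors on
    strongly periodic signals), refined by parabolic interpolation.
    """
    clip = clip.resampled(TARGET_RATE)
    fs = clip.sample_rate
    x = np.asarray(clip.samples, dtype=float)
    L = int(round(frame_len * fs))
    H = int(round(hop * fs))
    if len(x) < L:
        raise ValueError("clip shorter than one analysis frame")
    n_frames = 1 + (len(x) - L) // H
    idx = np.arange(L)[None, :] + H * np.arange(n_frames)[:, None]
    frames = x[idx]
    frames = frames - frames.mean(axis=1, keepdims=True)

    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    peak_amp = np.max(np.abs(x)) if len(x) else 0.0
    floor = peak_amp * 10.0 ** (-energy_floor_db / 20.0)

    lag_min = max(2, int(np.ceil(fs / f0_max)))
    lag_max = min(L - 2, int(np.floor(fs / f0_min)))
    nfft = 1
    while nfft < L + lag_max + 1:
        nfft *= 2
    spec = np.fft.rfft(frames, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:, : lag_max + 2]

    csum = np.cumsum(frames ** 2, axis=1)
    total = csum[:, -1]
    lags = np.arange(lag_max + 2)
    # energy of x[0:L-tau] and x[tau:L]
    e_head = csum[:, L - 1 - lags]            # (F, lags)
    e_tail = total[:, None] - np.concatenate(
        [np.zeros((n_frames, 1)), csum[:, lags[1:] - 1]], axis=1)
    denom = np.sqrt(np.maximum(e_head * e_tail, 1e-300))
    r = ac / denom

    band = r[:, lag_min : lag_max + 1]
    # local maxima inside the band (using full-array neighbours)
    left = r[:, lag_min - 1 : lag_max]
    right = r[:, lag_min + 1 : lag_max + 2]
    is_peak = (band >= left) & (band >= right)
    band_max = band.max(axis=1)
    # prefer the shortest near-best lag: on jittered pulse trains the
    # *relative* period perturbation shrinks at multiples of the true lag,
    # so r(2T) can slightly exceed r(T) and a strict argmax halves F0
    near_best = is_peak & (band >= band_max[:, None] - 0.10)
    has_peak = near_best.any(axis=1)
    first = np.argmax(near_best, axis=1)          # shortest qualifying lag
    lag0 = first + lag_min

    # parabolic interpolation of the chosen peak
    rm = r[np.arange(n_frames), lag0 - 1]
    r0 = r[np.arange(n_frames), lag0]
    rp = r[np.arange(n_frames), lag0 + 1]
    denom2 = rm - 2.0 * r0 + rp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(np.abs(denom2) > 1e-12, 0.5 * (rm - rp) / denom2, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    lag_ref = lag0 + delta
    peak_val = r0 - 0.25 * (rm - rp) * delta

    voiced = has_peak & (peak_val >= voicing_threshold) & (rms >= floor) & (rms > 0)
    f0 = np.full(n_frames, np.nan)
    f0[voiced] = fs / lag_ref[voiced]
    ac_peak = np.full(n_frames, np.nan)
    ac_peak[has_peak] = np.clip(peak_val[has_peak], 0.0, 1.0 - 1e-6)
    voiced, f0 = _clean_voicing(voiced, f0)

    times = (np.arange(n_frames) * H + L / 2) / fs
    return VoicingTrack(times=times, voiced=voiced, f0=f0, energy=rms,
                        ac_peak=ac_peak, frame_len=frame_len, hop=hop,
                        clip_duration=len(x) / fs)


def _clean_voicing(voiced: np.ndarray, f0: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Smooth the voicing mask and the F0 contour.

    Single-frame unvoiced gaps inside voiced stretches are filled (F0
    interpolated), voiced runs shorter than 3 frames are discarded, and the
    contour is median-filtered with a 5-frame window inside each run to
    suppress isolated tracking errors.
    """
    voiced = voiced.copy()
    f0 = f0.copy()
    n = len(voiced)
    for i in range(1, n - 1):
        if not voiced[i] and voiced[i - 1] and voiced[i + 1]:
            voiced[i] = True
            f0[i] = 0.5 * (f0[i - 1] + f0[i + 1])
    for a, b in _runs(voiced):
        if b - a < 3:
            voiced[a:b] = False
            f0[a:b] = np.nan
    for a, b in _runs(voiced):
        seg = f0[a:b]
        sm = np.empty_like(seg)
        for i in range(len(seg)):
            sm[i] = np.median(seg[max(0, i - 2): i + 3])
        f0[a:b] = sm
    return voiced, f0


@dataclass(frozen=True)
class AcousticFeatureVector:
    """The 13 acoustic parameters; NaN marks a missing (unvoiced) statistic."""

    f0_mean: float
    f0_sd_norm: float
    f0_range: float
    f0_rise_slope: float
    f0_fall_slope: float
    loudness_mean: float
    loudness_rise_slope: float
    loudness_fall_slope: float
    jitter_mean: float
    shimmer_mean: float
    hnr_mean: float
    voiced_segments_per_second: float
    mean_unvoiced_segment_length: float
    n_voiced_frames: int = 0

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in ACOUSTIC_FEATURES}


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True."""
    out = []
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _monotone_run_slopes(contour: np.ndarray, hop: float, tol: float
                         ) -> tuple[list[float], list[float]]:
    """Mean slopes over maximal rising / falling runs of a contour.

    A run extends while consecutive differences stay on the same side of
    ``+-tol``; runs spanning fewer than two differences are ignored.  Falling
    slopes are returned as magnitudes.
    """
    rising, falling = [], []
    d = np.diff(contour)
    sign = np.where(d > tol, 1, np.where(d < -tol, -1, 0))
    i = 0
    while i < len(sign):
        s = sign[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j < len(sign) and sign[j] == s:
            j += 1
        if j - i >= 2:
            slope = (contour[j] - contour[i]) / ((j - i) * hop)
            (rising if s > 0 else falling).append(abs(slope))
        i = j
    return rising, falling


def _pulse_marks(x: np.ndarray, fs: float, f0_of_sample, start: int, stop: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pitch-period peak positions (fractional samples) and amplitudes.

    Peak picking: start from the largest positive sample of the segment and
    march outwards one estimated period at a time, snapping to the local
    maximum within a +-35% period window, with parabolic refinement.
    """
    seg = x[start:stop]
    if len(seg) < 8:
        return np.array([]), np.array([])
    anchor = int(np.argmax(seg)) + start
    positions = [float(anchor)]
    for direction in (+1, -1):
        pos = float(anchor)
        while True:
            f0_here = f0_of_sample(int(round(pos)))
            if not np.isfinite(f0_here) or f0_here <= 0:
                break
            period = fs / f0_here
            centre = pos + direction * period
            lo = int(round(centre - 0.35 * period))
            hi = int(round(centre + 0.35 * period))
            lo = max(lo, start)
            hi = min(hi, stop - 1)
            if hi - lo < 3:
                break
            k = int(np.argmax(x[lo : hi + 1])) + lo
            if k <= start or k >= stop - 1:
                break
            positions.append(float(k))
            pos = float(k)
            if direction * (pos - anchor) > (stop - start):
                break
    positions = np.sort(np.array(positions))
    # parabolic refinement of position and amplitude
    k = positions.astype(int)
    k = k[(k > 0) & (k < len(x) - 1)]
    if len(k) < 2:
        return np.array([]), np.array([])
    ym, y0, yp = x[k - 1], x[k], x[k + 1]
    denom = ym - 2 * y0 + yp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (ym - yp) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    pos_ref = k + delta
    # raw peak sample for the amplitude: parabolic smoothing across cycle
    # boundaries with unequal neighbours would bias shimmer downward
    amp_ref = y0
    # spurious low-amplitude marks (noise near segment edges) would fake
    # period irregularity; their dropped 2T gaps are filtered downstream
    positive = amp_ref[amp_ref > 0]
    if len(positive) == 0:
        return np.array([]), np.array([])
    keep = amp_ref > 0.25 * float(np.median(positive))
    return pos_ref[keep], amp_ref[keep]


def extract_acoustic_features(clip: AudioClip,
                              track: VoicingTrack | None = None
                              ) -> AcousticFeatureVector:
    """Compute the 13-parameter acoustic feature vector of one clip.

    F0 statistics (semitone scale, voiced frames only): mean, normalized SD
    (SD/mean), range as the 80th minus 20th percentile, and mean slopes over
    maximal rising/falling runs of the contour.  Loudness statistics use the
    per-frame RMS analogously.  Jitter is the mean absolute consecutive
    period difference over the mean period; shimmer the mean absolute dB
    ratio of consecutive period peak amplitudes; HNR the mean of
    ``10 log10(r/(1-r))`` over voiced frames.  Temporal statistics count
    maximal voiced runs per second and average the *internal* unvoiced run
    lengths.  With zero voiced frames all voice-dependent fields are NaN.
    """
    clip = clip.resampled(TARGET_RATE)
    if track is None:
        track = detect_voicing_and_f0(clip)
    fs = clip.sample_rate
    hop, L = track.hop, track.frame_len
    voiced = track.voiced
    vruns = _runs(voiced)
    duration = track.clip_duration

    nan = float("nan")
    out = dict.fromkeys(ACOUSTIC_FEATURES, nan)
    out["voiced_segments_per_second"] = len(vruns) / duration if duration > 0 else 0.0
    if len(vruns) >= 2:
        gaps = [(vruns[i + 1][0] - vruns[i][1]) * hop for i in range(len(vruns) - 1)]
        out["mean_unvoiced_segment_length"] = float(np.mean(gaps))

    n_voiced = int(voiced.sum())
    if n_voiced == 0:
        return AcousticFeatureVector(**out, n_voiced_frames=0)

    st_all = hz_to_semitone(track.f0[voiced])
    out["f0_mean"] = float(np.mean(st_all))
    if n_voiced >= 2:
        sd = float(np.std(st_all, ddof=1))
        out["f0_sd_norm"] = sd / out["f0_mean"] if out["f0_mean"] != 0 else nan
        p20, p80 = np.percentile(st_all, [20, 80])
        out["f0_range"] = float(p80 - p20)

    rms_voiced = track.energy[voiced]
    out["loudness_mean"] = float(np.mean(rms_voiced))

    f0_rise, f0_fall, loud_rise, loud_fall = [], [], [], []
    loud_tol = 0.02 * float(np.median(rms_voiced))
    for a, b in vruns:
        st = hz_to_semitone(track.f0[a:b])
        r_up, r_dn = _monotone_run_slopes(st, hop, _SEMITONE_TOL)
        f0_rise += r_up
        f0_fall += r_dn
        l_up, l_dn = _monotone_run_slopes(track.energy[a:b], hop, loud_tol)
        loud_rise += l_up
        loud_fall += l_dn
    if f0_rise:
        out["f0_rise_slope"] = float(np.mean(f0_rise))
    if f0_fall:
        out["f0_fall_slope"] = float(np.mean(f0_fall))
    if loud_rise:
        out["loudness_rise_slope"] = float(np.mean(loud_rise))
    if loud_fall:
        out["loudness_fall_slope"] = float(np.mean(loud_fall))

    r = track.ac_peak[voiced]
    r = r[np.isfinite(r)]           # gap-filled frames carry no peak value
    r = np.clip(r, 1e-6, 1.0 - 1e-6)
    if len(r):
        out["hnr_mean"] = float(np.mean(10.0 * np.log10(r / (1.0 - r))))

    # jitter & shimmer from pitch-period marks inside each voiced run
    x = np.asarray(clip.samples, dtype=float)
    Hs = int(round(hop * fs))
    Ls = int(round(L * fs))
    f0_frames = track.f0

    def f0_of_sample(s: int) -> float:
        fi = int(np.clip((s - Ls // 2) / Hs, 0, len(f0_frames) - 1))
        v = f0_frames[fi]
        if np.isnan(v):
            vi = np.where(voiced)[0]
            v = f0_frames[vi[np.argmin(np.abs(vi - fi))]]
        return v

    jits, shims, wj, ws = [], [], [], []
    for a, b in vruns:
        s0 = a * Hs
        s1 = min(len(x), (b - 1) * Hs + Ls // 2)   # stop at last frame centre
        pos, amp = _pulse_marks(x, fs, f0_of_sample, s0, s1)
        if len(pos) >= 3:
            periods = np.diff(pos) / fs
            med = np.median(periods)
            ok = (periods > 0.5 * med) & (periods < 1.8 * med)
            periods = periods[ok]
            if len(periods) >= 2:
                jit = float(np.mean(np.abs(np.diff(periods))) / np.mean(periods))
                jits.append(jit)
                wj.append(len(periods))
        if len(amp) >= 3:
            ratio_db = np.abs(20.0 * np.log10(amp[1:] / amp[:-1]))
            shims.append(float(np.mean(ratio_db)))
            ws.append(len(ratio_db))
    if jits:
        out["jitter_mean"] = float(np.average(jits, weights=wj))
    if shims:
        out["shimmer_mean"] = float(np.average(shims, weights=ws))

    return AcousticFeatureVector(**out, n_voiced_frames=n_voiced)
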