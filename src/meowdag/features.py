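"""Frame-level acoustic features: MFCC (+energy, +Δ/ΔΔ/ΔΔΔ) and temporal
modulation, on a shared 30 ms / 10 ms frame grid.

The MFCC stream is the classical chain: Hamming window, 512-point FFT,
23-filter triangular mel bank, log, DCT-II, coefficients 1..12 kept and the
log frame energy appended (13 dims), then first/second/third regression
derivatives (52 dims).

The temporal-modulation stream captures the slow amplitude fluctuations of
cochlear-style spectral subbands: subband magnitude envelopes sampled at the
frame rate, windowed, mean-removed and Fourier-transformed; energies are
pooled into log-spaced modulation-frequency bands.  A harmonic event drives
all its subbands with one shared envelope, so its modulation patterns are
redundant across bands — the property that motivates the representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct

from .audio import AudioClip, frame_signal

LOG_FLOOR = 1e-10


@dataclass
class FrameGrid:
    frame_s: float = 0.030
    shift_s: float = 0.010
    fft_size: int = 512
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.fft_size & (self.fft_size - 1):
            raise ValueError("fft_size must be a power of two")

    def frame_len(self, sample_rate: int) -> int:
        n = int(round(self.frame_s * sample_rate))
        if n > self.fft_size:
            raise ValueError(f"frame of {n} samples exceeds fft_size "
                             f"{self.fft_size}")
        return n

    @classmethod
    def literal_overlap(cls) -> "FrameGrid":
        """Literal 10 ms-overlap framing: a 20 ms shift for the 30 ms window."""
        return cls(frame_s=0.030, shift_s=0.020)


@dataclass
class MfccConfig:
    n_mel_filters: int = 23
    n_kept_coeffs: int = 12
    include_energy: bool = True
    derivative_orders: int = 3

    @property
    def base_dim(self) -> int:
        return self.n_kept_coeffs + int(self.include_energy)

    @property
    def full_dim(self) -> int:
        return self.base_dim * (1 + self.derivative_orders)


@dataclass
class ModulationConfig:
    n_subbands: int = 8
    envelope_rate: float = 100.0      # Hz; 1 / frame shift
    mod_window_s: float = 0.25
    mod_shift_s: float = 0.10
    mod_fft_size: int = 64
    mod_freq_max: float = 32.0        # Hz
    n_mod_bands: int = 6              # log-spaced bands up to mod_freq_max
    mod_freq_min: float = 2.0

    def __post_init__(self) -> None:
        if self.mod_freq_max > self.envelope_rate / 2:
            raise ValueError("mod_freq_max must be <= envelope_rate / 2")

    @property
    def dim(self) -> int:
        return self.n_subbands * self.n_mod_bands

    @property
    def min_clip_s(self) -> float:
        return self.mod_window_s


@dataclass
class FeatureSequence:
    """Frames x dims observation matrix with its frame timing."""

    data: np.ndarray
    stream: str                        # "mfcc" | "tm" | "fused"
    frame_times: np.ndarray            # frame-center times, seconds
    clip_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("features must be finite")
        if len(self.frame_times) != len(self.data):
            raise ValueError("frame_times length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def dim(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# mel filterbank
# ---------------------------------------------------------------------------

def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(sample_rate: int, fft_size: int, n_filters: int
                   ) -> np.ndarray:
    """Triangular mel filters, shape (n_filters, fft_size // 2 + 1).

    Centers are equally spaced on the mel scale from 0 to Nyquist; each
    triangle is evaluated at the FFT bin frequencies, so neighbouring
    filters overlap and every interior bin has positive weight somewhere.
    """
    n_bins = fft_size // 2 + 1
    if n_filters < 1:
        raise ValueError("need at least one filter")
    if n_filters > n_bins - 2:
        raise ValueError(f"{n_filters} filters exceed the {n_bins} usable bins")
    edges_hz = mel_to_hz(np.linspace(0.0, hz_to_mel(sample_rate / 2.0),
                                     n_filters + 2))
    bin_hz = np.arange(n_bins) * sample_rate / fft_size
    fb = np.zeros((n_filters, n_bins))
    for k in range(n_filters):
        lo, c, hi = edges_hz[k], edges_hz[k + 1], edges_hz[k + 2]
        up = (bin_hz - lo) / (c - lo)
        down = (hi - bin_hz) / (hi - c)
        fb[k] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def _stft_power(clip: AudioClip, grid: FrameGrid) -> tuple[np.ndarray, np.ndarray]:
    """Power spectra (n_frames, n_bins) and raw frame energies."""
    frames = frame_signal(clip.samples, clip.sample_rate, grid.frame_s,
                          grid.shift_s)
    energy = np.sum(frames ** 2, axis=1)
    win = np.hamming(frames.shape[1])
    spec = np.fft.rfft(frames * win, n=grid.fft_size, axis=1)
    return np.abs(spec) ** 2, energy


def delta(x: np.ndarray, context: int = 2) -> np.ndarray:
    """Regression derivative over +/- ``context`` frames, edge-replicated."""
    t = np.arange(1, context + 1, dtype=np.float64)
    denom = 2.0 * np.sum(t ** 2)
    pad = np.concatenate([np.repeat(x[:1], context, axis=0), x,
                          np.repeat(x[-1:], context, axis=0)], axis=0)
    out = np.zeros_like(x)
    for n in range(1, context + 1):
        out += n * (pad[context + n:len(pad) - context + n]
                    - pad[context - n:len(pad) - context - n])
    return out / denom


def log_mel_energies(clip: AudioClip, grid: FrameGrid | None = None,
                     n_filters: int = 23) -> np.ndarray:
    """Log mel-filterbank energies per frame (pre-DCT stage), for diagnostics."""
    grid = grid or FrameGrid()
    power, _ = _stft_power(clip, grid)
    fb = mel_filterbank(clip.sample_rate, grid.fft_size, n_filters)
    return np.log(np.maximum(power @ fb.T, LOG_FLOOR))


def extract_mfcc(clip: AudioClip, grid: FrameGrid | None = None,
                 cfg: MfccConfig | None = None) -> FeatureSequence:
    """MFCC + log-energy + derivative stream for one (silence-trimmed) clip."""
    grid = grid or FrameGrid()
    cfg = cfg or MfccConfig()
    power, energy = _stft_power(clip, grid)
    fb = mel_filterbank(clip.sample_rate, grid.fft_size, cfg.n_mel_filters)
    logmel = np.log(np.maximum(power @ fb.T, LOG_FLOOR))
    cep = dct(logmel, type=2, norm="ortho", axis=1)
    feats = cep[:, 1:cfg.n_kept_coeffs + 1]          # drop c0, keep 1..12
    if cfg.include_energy:
        feats = np.hstack([feats, np.log(np.maximum(energy, LOG_FLOOR))[:, None]])
    blocks = [feats]
    for _ in range(cfg.derivative_orders):
        blocks.append(delta(blocks[-1]))
    out = np.hstack(blocks)
    shift = int(round(grid.shift_s * clip.sample_rate))
    frame = grid.frame_len(clip.sample_rate)
    times = (np.arange(len(out)) * shift + frame / 2) / clip.sample_rate
    return FeatureSequence(out, "mfcc", times, clip_id=clip.clip_id,
                           label=clip.label)


# ---------------------------------------------------------------------------
# temporal modulation
# ---------------------------------------------------------------------------

def subband_envelopes(clip: AudioClip, grid: FrameGrid | None = None,
                      n_subbands: int = 8) -> np.ndarray:
    """Magnitude envelopes of equal-width spectral subbands, sampled at the
    frame rate; shape (n_envelope_samples, n_subbands)."""
    grid = grid or FrameGrid()
    power, _ = _stft_power(clip, grid)
    n_bins = power.shape[1]
    edges = np.linspace(0, n_bins, n_subbands + 1).astype(int)
    env = np.stack([np.sqrt(power[:, a:b].sum(axis=1))
                    for a, b in zip(edges[:-1], edges[1:])], axis=1)
    return env


def modulation_spectrogram(clip: AudioClip, cfg: ModulationConfig | None = None,
                           grid: FrameGrid | None = None) -> tuple[np.ndarray,
                                                                   np.ndarray]:
    """Full-resolution modulation representation.

    Returns ``(M, mod_freqs)`` where M has shape
    (n_mod_frames, n_subbands, n_mod_freq_bins): per modulation window and
    subband, the magnitude spectrum of the mean-removed envelope.
    """
    cfg = cfg or ModulationConfig()
    grid = grid or FrameGrid(shift_s=1.0 / cfg.envelope_rate)
    env = subband_envelopes(clip, grid, cfg.n_subbands)
    win_n = int(round(cfg.mod_window_s * cfg.envelope_rate))
    shift_n = max(1, int(round(cfg.mod_shift_s * cfg.envelope_rate)))
    if len(env) < win_n:
        need = cfg.mod_window_s + grid.frame_s
        raise ValueError(f"clip too short for modulation analysis: needs "
                         f">= {need:.2f} s after trimming")
    n_frames_mod = (len(env) - win_n) // shift_n + 1
    freqs = np.fft.rfftfreq(cfg.mod_fft_size, d=1.0 / cfg.envelope_rate)
    keep = freqs <= cfg.mod_freq_max
    M = np.empty((n_frames_mod, cfg.n_subbands, int(keep.sum())))
    for i in range(n_frames_mod):
        seg = env[i * shift_n:i * shift_n + win_n]
        seg = seg - seg.mean(axis=0, keepdims=True)
        spec = np.fft.rfft(seg, n=cfg.mod_fft_size, axis=0)
        M[i] = np.abs(spec[keep]).T
    return M, freqs[keep]


def extract_modulation(clip: AudioClip, cfg: ModulationConfig | None = None,
                       grid: FrameGrid | None = None) -> FeatureSequence:
    """Per-frame temporal-modulation features: log energies of each subband
    in log-spaced modulation-frequency bands (dim = n_subbands * n_mod_bands)."""
    cfg = cfg or ModulationConfig()
    M, freqs = modulation_spectrogram(clip, cfg, grid)
    band_edges = np.geomspace(cfg.mod_freq_min, cfg.mod_freq_max,
                              cfg.n_mod_bands + 1)
    feats = np.empty((M.shape[0], cfg.n_subbands, cfg.n_mod_bands))
    for b, (lo, hi) in enumerate(zip(band_edges[:-1], band_edges[1:])):
        sel = (freqs >= lo) & (freqs < hi) if b < cfg.n_mod_bands - 1 else \
              (freqs >= lo) & (freqs <= hi)
        if not sel.any():                       # resolution coarser than band
            sel = np.argmin(np.abs(freqs - np.sqrt(lo * hi)))
        feats[:, :, b] = np.log(np.maximum(
            (M[:, :, sel] ** 2).sum(axis=-1) if np.ndim(sel) else
            M[:, :, sel] ** 2, LOG_FLOOR))
    out = feats.reshape(M.shape[0], -1)
    times = cfg.mod_window_s / 2 + cfg.mod_shift_s * np.arange(len(out))
    return FeatureSequence(out, "tm", times, clip_id=clip.clip_id,
                           label=clip.label)


# ---------------------------------------------------------------------------
# fusion and normalization
# ---------------------------------------------------------------------------

def fuse_streams(mfcc: FeatureSequence, tm: FeatureSequence) -> FeatureSequence:
    """Concatenate the two streams per frame on the MFCC grid.

    The slower TM stream is resampled by nearest-frame lookup.  Both inputs
    must come from the same clip.  Normalization is NOT applied here — the
    cross-validation harness fits per-dimension statistics on training folds
    only (see :class:`Normalizer`).
    """
    if mfcc.clip_id != tm.clip_id:
        raise ValueError(f"stream clip ids differ: "
                         f"{mfcc.clip_id!r} vs {tm.clip_id!r}")
    idx = np.abs(mfcc.frame_times[:, None] - tm.frame_times[None, :]).argmin(axis=1)
    data = np.hstack([mfcc.data, tm.data[idx]])
    return FeatureSequence(data, "fused", mfcc.frame_times,
                           clip_id=mfcc.clip_id, label=mfcc.label)


class Normalizer:
    """Per-dimension z-normalization with statistics from training data only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, sequences: list[np.ndarray]) -> "Normalizer":
        X = np.vstack(sequences)
        self.mean_ = X.mean(axis=0)
        self.sd_ = np.maximum(X.std(axis=0), 1e-8)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Normalizer must be fit before transform")
        return (X - self.mean_) / self.sd_
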