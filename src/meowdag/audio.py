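"""Audio I/O and vocalization-activity detection.

Clips are mono waveforms in [-1, 1] at 8 kHz (the Bluetooth HFP/HSP chain
used to record the corpus samples at 8 kHz with a-law companding, leaving a
usable band of 0-4 kHz).  Silence is removed before feature extraction with
a statistical-model detector: a per-frequency-bin Gaussian likelihood-ratio
test between a noise hypothesis and a signal-plus-noise hypothesis, smoothed
by a hangover, so the classifiers only ever see the structure of the sound
event itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger("meowdag")

TARGET_RATE = 8000

#: default framing shared with the feature extractor: 30 ms window, 10 ms shift
FRAME_S = 0.030
SHIFT_S = 0.010


class NoEventError(RuntimeError):
    """Raised when a clip contains no detectable vocalization."""


class AudioFormatError(RuntimeError):
    """Raised when a file cannot be read as RIFF PCM audio."""


@dataclass
class AudioClip:
    """A mono waveform with its sampling rate and label metadata."""

    samples: np.ndarray
    sample_rate: int = TARGET_RATE
    source_path: str = ""
    label: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip requires a mono (1-D) sample array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def clip_id(self) -> str:
        return self.meta.get("clip_id", self.source_path)


@dataclass
class VadParams:
    """Parameters of the likelihood-ratio silence detector.

    ``prior_snr`` is the fixed a-priori SNR xi of the signal hypothesis;
    the per-bin log likelihood ratio is ``gamma*xi/(1+xi) - log(1+xi)`` with
    gamma the a-posteriori SNR.  The frame decision compares the geometric
    mean of the per-bin ratios against ``threshold``.
    """

    frame_s: float = FRAME_S
    shift_s: float = SHIFT_S
    threshold: float = 1.0
    hangover: int = 3
    noise_init_s: float = 0.2
    prior_snr: float = 31.6          # ~15 dB
    mode: str = "lrt"                # "lrt" | "energy"
    energy_margin_db: float = 6.0    # energy fallback: active above noise + margin
    trim_mode: str = "all"           # "all" | "edges"


@dataclass
class ActivityMask:
    """Per-frame voice-activity decisions on a fixed frame grid."""

    active: np.ndarray               # bool, one entry per frame
    frame_s: float
    shift_s: float
    noise_psd: np.ndarray | None = None   # the noise estimate used

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.active)

    def to_csv(self, path: str) -> None:
        """Dump the per-frame decisions as ``frame_index,active``."""
        with open(path, "w") as fh:
            fh.write("frame_index,active\n")
            for i, a in enumerate(self.active):
                fh.write(f"{i},{int(a)}\n")


def n_frames(n_samples: int, sample_rate: int, frame_s: float = FRAME_S,
             shift_s: float = SHIFT_S) -> int:
    """Frame count: floor((L - frame_length)/shift) + 1, or 0 if too short."""
    frame = int(round(frame_s * sample_rate))
    shift = int(round(shift_s * sample_rate))
    if n_samples < frame:
        return 0
    return (n_samples - frame) // shift + 1


def frame_signal(x: np.ndarray, sample_rate: int, frame_s: float = FRAME_S,
                 shift_s: float = SHIFT_S) -> np.ndarray:
    """Slice ``x`` into overlapping frames, shape (n_frames, frame_len)."""
    frame = int(round(frame_s * sample_rate))
    shift = int(round(shift_s * sample_rate))
    n = n_frames(len(x), sample_rate, frame_s, shift_s)
    if n == 0:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one {frame}-sample frame")
    idx = np.arange(frame)[None, :] + shift * np.arange(n)[:, None]
    return x[idx]


def read_wav(path: str) -> AudioClip:
    """Read a RIFF PCM file as a normalized 8 kHz mono clip.

    Integer PCM is scaled to [-1, 1]; stereo input is downmixed by channel
    mean; any sampling rate other than 8 kHz is resampled, both with a log
    record.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise AudioFormatError(f"cannot read {path!r} as RIFF PCM: {exc}") from exc
    data = np.asarray(data)
    if data.dtype.kind == "i":
        x = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit unsigned PCM
        info = np.iinfo(data.dtype)
        x = (data.astype(np.float64) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        logger.info("downmixing %d-channel file %s to mono", x.shape[1], path)
        x = x.mean(axis=1)
    if rate != TARGET_RATE:
        logger.info("resampling %s from %d Hz to %d Hz", path, rate, TARGET_RATE)
        g = np.gcd(int(rate), TARGET_RATE)
        x = resample_poly(x, TARGET_RATE // g, int(rate) // g)
    x = np.clip(x, -1.0, 1.0)
    return AudioClip(x, TARGET_RATE, source_path=str(path))


def write_wav(path: str, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM RIFF."""
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate, (x * 32767.0).astype(np.int16))


def _frame_power_spectra(clip: AudioClip, params: VadParams) -> np.ndarray:
    frames = frame_signal(clip.samples, clip.sample_rate, params.frame_s,
                          params.shift_s)
    win = np.hamming(frames.shape[1])
    spec = np.fft.rfft(frames * win, n=512, axis=1)
    return np.abs(spec) ** 2


def detect_activity(clip: AudioClip, params: VadParams | None = None,
                    noise_psd: np.ndarray | None = None) -> ActivityMask:
    """Label each frame of ``clip`` active or silent.

    Noise statistics default to the elementwise minimum of the mean spectrum
    over the first ``noise_init_s`` seconds (the corpus clips carry 0.5 s of
    leading background noise) and a low per-bin quantile over the whole clip.
    A clip that is voiced edge to edge offers no silence to estimate noise
    from; pass an external ``noise_psd`` reference in that case.
    """
    params = params or VadParams()
    psd = _frame_power_spectra(clip, params)
    n = psd.shape[0]
    if n < 3:
        raise ValueError("clip must span at least 3 frames for activity detection")

    if noise_psd is None:
        noise_psd = clip.meta.get("noise_psd")   # e.g. set by a prior trim
    if noise_psd is None:
        n_init = max(1, int(round(params.noise_init_s / params.shift_s)))
        init_est = psd[: min(n_init, n)].mean(axis=0)
        # periodogram bins are ~exponential: the 20% quantile estimates the
        # mean after dividing by -ln(0.8)
        quant_est = np.quantile(psd, 0.20, axis=0) / 0.2231435513
        noise_psd = np.minimum(init_est, quant_est)
    noise_psd = np.maximum(np.asarray(noise_psd, dtype=np.float64), 1e-30)

    if params.mode == "energy":
        frame_db = 10.0 * np.log10(np.maximum(psd.sum(axis=1), 1e-30))
        noise_db = 10.0 * np.log10(noise_psd.sum())
        raw = frame_db > noise_db + params.energy_margin_db
    elif params.mode == "lrt":
        gamma = psd / noise_psd
        xi = params.prior_snr
        log_lr = gamma * (xi / (1.0 + xi)) - np.log1p(xi)
        raw = log_lr.mean(axis=1) > np.log(params.threshold)
    else:
        raise ValueError(f"unknown VAD mode {params.mode!r}")

    active = raw.copy()
    # hangover: hold activity for a few frames after each raw-active frame
    for k in range(1, params.hangover + 1):
        active[k:] |= raw[:-k]

    # guarantee: when any frame clearly exceeds the noise floor, at least the
    # globally strongest frame is kept active
    energies = psd.sum(axis=1)
    if not active.any() and energies.max() > 2.0 * noise_psd.sum():
        active[int(np.argmax(energies))] = True

    if not active.any():
        logger.info("no event detected in %s", clip.clip_id or "<clip>")
    return ActivityMask(active, params.frame_s, params.shift_s,
                        noise_psd=noise_psd)


def trim_silence(clip: AudioClip, mask: ActivityMask,
                 trim_mode: str = "all") -> AudioClip:
    """Concatenate the active regions of ``clip``.

    ``trim_mode="all"`` removes every inactive frame (internal pauses
    included); ``"edges"`` removes leading/trailing silence only.  An empty
    mask raises :class:`NoEventError` — such clips are excluded from
    training, mirroring the discarding of non-meow recordings.
    """
    expected = n_frames(len(clip.samples), clip.sample_rate, mask.frame_s,
                        mask.shift_s)
    if mask.n_frames != expected:
        raise ValueError(
            f"mask has {mask.n_frames} frames, clip framing implies {expected}")
    if not mask.active.any():
        raise NoEventError(f"no event in clip {clip.clip_id or '<clip>'}")

    frame = int(round(mask.frame_s * clip.sample_rate))
    shift = int(round(mask.shift_s * clip.sample_rate))
    active = mask.active
    if trim_mode == "edges":
        first, last = np.flatnonzero(active)[[0, -1]]
        active = np.zeros_like(active)
        active[first:last + 1] = True
    elif trim_mode != "all":
        raise ValueError(f"unknown trim_mode {trim_mode!r}")

    # union of active frame intervals -> sample spans
    spans: list[tuple[int, int]] = []
    for i in np.flatnonzero(active):
        start, stop = i * shift, i * shift + frame
        if spans and start <= spans[-1][1]:
            spans[-1] = (spans[-1][0], max(spans[-1][1], stop))
        else:
            spans.append((start, stop))
    if active[-1]:   # keep the tail remainder not covered by a full frame
        spans[-1] = (spans[-1][0], len(clip.samples))
    out = np.concatenate([clip.samples[a:b] for a, b in spans])
    return replace(clip, samples=out)


def trim_clip(clip: AudioClip, params: VadParams | None = None) -> AudioClip:
    """Convenience: detect activity then trim, with the same parameters.

    The noise estimate is carried on the trimmed clip's metadata so a
    second pass reuses the original reference (trimming is idempotent even
    though the trimmed clip no longer contains silence to estimate from).
    """
    params = params or VadParams()
    mask = detect_activity(clip, params)
    trimmed = trim_silence(clip, mask, trim_mode=params.trim_mode)
    trimmed.meta = dict(trimmed.meta, noise_psd=mask.noise_psd)
    return trimmed
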