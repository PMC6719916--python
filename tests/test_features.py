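"""MFCC and temporal-modulation feature extraction."""

import numpy as np
import pytest

from meowdag.audio import AudioClip
from meowdag.features import (FrameGrid, MfccConfig, ModulationConfig,
                              Normalizer, extract_mfcc, extract_modulation,
                              fuse_streams, hz_to_mel, log_mel_energies,
                              mel_filterbank, mel_to_hz,
                              modulation_spectrogram)
from meowdag.synthetic import ClassProfile, synthesize_clip


def tone(freq, dur=1.0, sr=8000, amp=0.5, am_rate=None, am_depth=1.0):
    t = np.arange(int(dur * sr)) / sr
    x = amp * np.sin(2 * np.pi * freq * t)
    if am_rate is not None:
        x = x * (1.0 - am_depth / 2 + (am_depth / 2) * np.sin(
            2 * np.pi * am_rate * t))
    return AudioClip(x, sr, meta={"clip_id": f"tone{freq}"})


# ---------------------------------------------------------------------------
# mel filterbank
# ---------------------------------------------------------------------------

def test_mel_filterbank_shape():
    fb = mel_filterbank(8000, 512, 23)
    assert fb.shape == (23, 257)


def test_mel_filterbank_triangles():
    fb = mel_filterbank(8000, 512, 23)
    assert np.all(fb >= 0)
    for row in fb:
        peak = row.argmax()
        nz = np.flatnonzero(row)
        # single peak: nondecreasing up to it, nonincreasing after
        assert np.all(np.diff(row[nz[0]:peak + 1]) >= -1e-12)
        assert np.all(np.diff(row[peak:nz[-1] + 1]) <= 1e-12)


def test_mel_filterbank_coverage():
    fb = mel_filterbank(8000, 512, 23)
    support = fb.sum(axis=0)
    assert np.all(support[2:-1] > 0)   # every interior bin touched


def test_mel_center_spacing_closed_form():
    """Centers recomputed independently from mel(f) = 2595 log10(1+f/700)."""
    n = 23
    fb = mel_filterbank(8000, 512, n)
    expected_mels = np.linspace(0, hz_to_mel(4000.0), n + 2)[1:-1]
    bin_hz = np.arange(257) * 8000 / 512
    centers_hz = bin_hz[fb.argmax(axis=1)]
    assert np.allclose(hz_to_mel(centers_hz), expected_mels,
                       atol=hz_to_mel(4000.0) / 256)
    assert np.allclose(mel_to_hz(hz_to_mel(centers_hz)), centers_hz)


def test_mel_filterbank_too_many_filters():
    with pytest.raises(ValueError):
        mel_filterbank(8000, 512, 300)


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def test_mfcc_dimensions():
    clip = tone(500)
    base = extract_mfcc(clip, cfg=MfccConfig(derivative_orders=0))
    full = extract_mfcc(clip)
    assert base.dim == 13
    assert full.dim == 52
    assert full.n_frames == base.n_frames
    assert np.all(np.isfinite(full.data))


def test_mfcc_stationary_tone_has_zero_deltas():
    clip = tone(700, dur=1.0)
    feats = extract_mfcc(clip)
    deltas = feats.data[5:-5, 13:]            # interior frames only
    assert np.max(np.abs(deltas)) < 1e-6


def test_tone_lands_in_matching_mel_filter():
    """Filterbank oracle: a pure tone maximises the filter containing it."""
    fb = mel_filterbank(8000, 512, 23)
    bin_hz = np.arange(257) * 8000 / 512
    for k in (5, 10, 15, 20):
        center = bin_hz[fb[k].argmax()]
        clip = tone(center, dur=0.5)
        logmel = log_mel_energies(clip)
        assert logmel.mean(axis=0).argmax() == k


def test_mfcc_gain_invariance():
    """Global gain moves only the energy column, by log(gain^2)."""
    clip = tone(600, amp=0.3)
    gained = AudioClip(clip.samples * 2.0, clip.sample_rate,
                       meta=dict(clip.meta))
    f1 = extract_mfcc(clip).data
    f2 = extract_mfcc(gained).data
    cep_cols = [c for c in range(52) if c % 13 != 12]
    assert np.allclose(f1[:, cep_cols], f2[:, cep_cols], atol=1e-8)
    energy_shift = f2[:, 12] - f1[:, 12]
    assert np.allclose(energy_shift, np.log(4.0), atol=1e-8)
    # energy deltas are differences of a uniformly shifted column
    assert np.allclose(f1[:, 25], f2[:, 25], atol=1e-8)


def test_mfcc_too_short_clip():
    with pytest.raises(ValueError):
        extract_mfcc(AudioClip(np.zeros(100), 8000))


# ---------------------------------------------------------------------------
# temporal modulation
# ---------------------------------------------------------------------------

def test_modulation_peak_at_am_rate():
    """1 kHz carrier AM-modulated at 8 Hz: modulation spectrum peaks at
    8 Hz in the subband containing the carrier."""
    clip = tone(1000, dur=2.0, am_rate=8.0)
    cfg = ModulationConfig()
    M, freqs = modulation_spectrogram(clip, cfg)
    subband = int(1000 / (4000 / cfg.n_subbands))
    spectrum = M[:, subband, :].mean(axis=0)
    resolution = cfg.envelope_rate / cfg.mod_fft_size
    assert abs(freqs[spectrum.argmax()] - 8.0) <= resolution + 1e-9


def test_unmodulated_tone_has_no_modulation_energy():
    clip = tone(1000, dur=2.0)
    cfg = ModulationConfig()
    M, freqs = modulation_spectrogram(clip, cfg)
    subband = int(1000 / (4000 / cfg.n_subbands))
    # DC power of the envelope for reference (the spectrogram removes it)
    from meowdag.features import subband_envelopes
    env = subband_envelopes(clip, FrameGrid(), cfg.n_subbands)[:, subband]
    win = int(cfg.mod_window_s * cfg.envelope_rate)
    dc_power = (env.mean() * win) ** 2
    above_2hz = (M[:, subband, freqs >= 2.0] ** 2).sum(axis=1).mean()
    assert above_2hz < 0.01 * dc_power      # < -20 dB relative to DC


def test_harmonic_redundancy_across_subbands():
    """All partials share one AM envelope, so subband modulation patterns
    are strongly correlated — the property motivating the representation."""
    profile = ClassProfile("food", f0_base=300.0, f0_contour="flat",
                           n_harmonics=8, am_rate=6.0, am_depth=0.9,
                           noise_snr=np.inf, duration_mean=1.5,
                           duration_var=1e-4, f0_jitter=0.0,
                           am_rate_jitter=0.0, harmonic_rolloff=0.3,
                           level_db_range=0.0)
    clip = synthesize_clip(profile, seed=1, alaw=False)
    cfg = ModulationConfig()
    M, freqs = modulation_spectrogram(clip, cfg)
    # subbands 0..4 contain partials (f0..8*f0 = 0.3-2.4 kHz)
    patterns = M[:, :5, :].mean(axis=0)
    corr = np.corrcoef(patterns)
    off_diag = corr[np.triu_indices(5, 1)]
    assert np.all(off_diag > 0.9)


def test_modulation_too_short():
    with pytest.raises(ValueError, match="too short"):
        extract_modulation(tone(500, dur=0.1))


def test_modulation_dimensions():
    clip = tone(500, dur=1.0, am_rate=5.0)
    cfg = ModulationConfig()
    feats = extract_modulation(clip, cfg)
    assert feats.dim == cfg.n_subbands * cfg.n_mod_bands == 48
    assert np.all(np.isfinite(feats.data))


# ---------------------------------------------------------------------------
# fusion and normalization
# ---------------------------------------------------------------------------

def test_fuse_streams_dimensions():
    clip = tone(800, dur=1.0, am_rate=5.0)
    m = extract_mfcc(clip)
    tm = extract_modulation(clip)
    fused = fuse_streams(m, tm)
    assert fused.dim == m.dim + tm.dim
    assert fused.n_frames == m.n_frames


def test_fuse_stream_with_itself():
    clip = tone(800, dur=1.0)
    m = extract_mfcc(clip)
    fused = fuse_streams(m, m)
    assert fused.dim == 2 * m.dim
    assert fused.n_frames == m.n_frames


def test_fuse_mismatched_ids():
    a = extract_mfcc(tone(500))
    b = extract_mfcc(tone(900))
    with pytest.raises(ValueError, match="clip ids differ"):
        fuse_streams(a, b)


def test_normalizer_moments():
    rng = np.random.default_rng(0)
    seqs = [rng.normal(3.0, 2.5, (50, 7)) for _ in range(20)]
    norm = Normalizer().fit(seqs)
    X = np.vstack([norm.transform(s) for s in seqs])
    assert np.max(np.abs(X.mean(axis=0))) < 1e-8
    assert np.max(np.abs(X.std(axis=0) - 1.0)) < 1e-6


def test_literal_overlap_grid():
    grid = FrameGrid.literal_overlap()
    assert grid.shift_s == pytest.approx(0.020)
    clip = tone(500, dur=1.0)
    default = extract_mfcc(clip)
    literal = extract_mfcc(clip, grid)
    assert literal.n_frames < default.n_frames
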