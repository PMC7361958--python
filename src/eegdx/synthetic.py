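"""Class-conditioned synthetic EEG generation.

Every pipeline stage is testable without clinical data: the generator
produces segments whose sub-band power profile, background noise,
transient spike content and ocular artifacts are all controlled.

A generated channel is the sum of

* one band-limited oscillator per conventional EEG band (delta, theta,
  alpha, beta, gamma) at its canonical centre frequency (2, 6, 10, 20,
  40 Hz) with a random phase and slight frequency jitter, scaled so the
  oscillator powers match the requested relative band powers;
* 1/f^a background noise ("pink" at a = 1) at a configurable RMS;
* optional Poisson-distributed biphasic spikes (a crude stand-in for
  epileptiform transients — high amplitude, short duration, which is
  what drives kurtosis and broadband detail-coefficient power);
* optionally, eye-blink transients (400 ms raised cosine, ~5x the
  background SD) mixed into every channel and emitted cleanly on a
  synthetic EOG reference channel.

All generation is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .io_signals import DatasetManifest, ManifestEntry, RawRecording, Segment

#: Canonical band centres (Hz).  The DWT tree defines the analysis
#: bands; these are the synthesis-side constants.
BAND_CENTERS = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 40.0}

BLINK_DURATION_S = 0.4
BLINK_AMPLITUDE_SD = 5.0  # blink peak in units of background SD
SPIKE_DURATION_S = 0.07
SPIKE_AMPLITUDE_FACTOR = 6.0  # spike peak relative to amplitude_uv


@dataclass
class ClassSpectrumSpec:
    """Target spectral profile for one diagnostic class."""

    class_label: str
    band_powers: dict[str, float]
    spike_rate_hz: float = 0.0
    noise_exponent: float = 1.0
    amplitude_uv: float = 30.0
    noise_uv: float = 5.0

    def __post_init__(self) -> None:
        unknown = set(self.band_powers) - set(BAND_CENTERS)
        if unknown:
            raise ParameterError(f"unknown bands {sorted(unknown)}")
        if not any(v > 0 for v in self.band_powers.values()):
            raise ParameterError("at least one band power must be positive")
        if any(v < 0 for v in self.band_powers.values()):
            raise ParameterError("band powers must be non-negative")
        if self.spike_rate_hz < 0 or self.amplitude_uv < 0 or self.noise_uv < 0:
            raise ParameterError("rates and amplitudes must be non-negative")


#: Presets used throughout the tests: an alpha-dominant neurotypical
#: profile, a spike-rich slow-wave epileptic profile, and an autistic
#: profile with elevated low-frequency and reduced alpha power.
NEUROTYPICAL_SPEC = ClassSpectrumSpec(
    class_label="neurotypical",
    band_powers={"delta": 1.0, "theta": 0.8, "alpha": 2.5, "beta": 0.6, "gamma": 0.3},
)
EPILEPSY_SPEC = ClassSpectrumSpec(
    class_label="epilepsy",
    band_powers={"delta": 2.0, "theta": 1.5, "alpha": 0.8, "beta": 0.6, "gamma": 0.5},
    spike_rate_hz=2.0,
)
AUTISM_SPEC = ClassSpectrumSpec(
    class_label="autism",
    band_powers={"delta": 2.2, "theta": 1.8, "alpha": 0.8, "beta": 0.9, "gamma": 0.8},
)


@dataclass
class SimSpec:
    """A full synthetic-dataset recipe."""

    classes: list[ClassSpectrumSpec]
    n_segments_per_class: int = 100
    n_channels: int = 1
    fs: float = 256.0
    duration_s: float = 50.0
    blink_rate_hz: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ParameterError("at least one class spectrum spec required")
        if self.n_segments_per_class < 1:
            raise ParameterError("n_segments_per_class must be >= 1")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ParameterError("fs and duration_s must be positive")
        if self.blink_rate_hz < 0:
            raise ParameterError("blink_rate_hz must be non-negative")


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS noise with power spectral density proportional to 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _spike_train(
    rng: np.random.Generator, n: int, fs: float, rate_hz: float, amplitude: float
) -> np.ndarray:
    """Poisson-placed biphasic transients (one-cycle sine bursts)."""
    out = np.zeros(n)
    n_spikes = rng.poisson(rate_hz * n / fs)
    width = max(int(SPIKE_DURATION_S * fs), 4)
    shape = np.sin(2 * np.pi * np.arange(width) / width)
    shape *= np.hanning(width)
    for _ in range(n_spikes):
        t0 = rng.integers(0, max(n - width, 1))
        out[t0 : t0 + width] += amplitude * rng.uniform(0.7, 1.3) * shape
    return out


def blink_template(fs: float, duration_s: float = BLINK_DURATION_S) -> np.ndarray:
    """The stereotyped eye-blink waveform: a raised-cosine bump."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / n
    return 0.5 * (1 - np.cos(2 * np.pi * t))


def _blink_train(
    rng: np.random.Generator, n: int, fs: float, rate_hz: float, amplitude: float
) -> np.ndarray:
    out = np.zeros(n)
    tmpl = blink_template(fs) * amplitude
    width = len(tmpl)
    n_blinks = rng.poisson(rate_hz * n / fs)
    for _ in range(n_blinks):
        t0 = rng.integers(0, max(n - width, 1))
        out[t0 : t0 + width] += tmpl
    return out


def generate_segment(
    spec: ClassSpectrumSpec,
    n_channels: int = 1,
    fs: float = 256.0,
    duration_s: float = 50.0,
    seed: int = 0,
) -> Segment:
    """Generate one labeled synthetic segment.

    Deterministic per seed.  Raises if a requested band's centre
    frequency is at or above Nyquist.
    """
    for band, p in spec.band_powers.items():
        if p > 0 and BAND_CENTERS[band] >= fs / 2:
            raise ParameterError(
                f"band {band!r} centred at {BAND_CENTERS[band]} Hz cannot be "
                f"represented at fs={fs} (Nyquist {fs / 2} Hz)"
            )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    total_p = sum(spec.band_powers.values())
    channels = []
    for _ in range(n_channels):
        x = np.zeros(n)
        for band, p in spec.band_powers.items():
            if p <= 0:
                continue
            # oscillator power A^2/2; distribute amplitude_uv^2 over bands
            amp = np.sqrt(2.0 * spec.amplitude_uv**2 * p / total_p)
            f0 = BAND_CENTERS[band] * rng.uniform(0.97, 1.03)
            phase = rng.uniform(0, 2 * np.pi)
            x += amp * np.sin(2 * np.pi * f0 * t + phase)
        if spec.noise_uv > 0:
            x += spec.noise_uv * _pink_noise(rng, n, spec.noise_exponent)
        if spec.spike_rate_hz > 0:
            x += _spike_train(
                rng, n, fs, spec.spike_rate_hz,
                SPIKE_AMPLITUDE_FACTOR * spec.amplitude_uv,
            )
        channels.append(x)
    return Segment(
        samples=np.asarray(channels),
        fs=fs,
        duration_s=n / fs,
        class_label=spec.class_label,
        subject_id=f"sim-{spec.class_label}-{seed}",
        segment_index=0,
    )


def generate_blink_recording(
    n_channels: int = 4,
    fs: float = 256.0,
    duration_s: float = 20.0,
    blink_rate_hz: float = 0.5,
    base_spec: ClassSpectrumSpec = NEUROTYPICAL_SPEC,
    seed: int = 0,
) -> tuple[RawRecording, np.ndarray]:
    """A multi-channel recording with a planted blink source plus an EOG
    reference channel carrying the same source.

    Returns the recording and the blink source time course, so callers
    can measure how much of the artifact survives cleaning.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    background = generate_segment(
        base_spec, n_channels=n_channels, fs=fs, duration_s=duration_s,
        seed=int(rng.integers(2**31)),
    )
    bg_sd = float(background.samples.std())
    blink = _blink_train(rng, n, fs, blink_rate_hz, BLINK_AMPLITUDE_SD * bg_sd)
    gains = rng.uniform(0.5, 1.0, size=n_channels)
    eeg = background.samples + gains[:, None] * blink[None, :]
    eog = blink + 0.05 * bg_sd * rng.standard_normal(n)
    labels = tuple(f"EEG{i + 1}" for i in range(n_channels)) + ("EOG1",)
    rec = RawRecording(
        samples=np.vstack([eeg, eog[None, :]]),
        fs=fs,
        channel_labels=labels,
        eog_labels=("EOG1",),
        subject_id=f"sim-blink-{seed}",
        class_label=base_spec.class_label,
    )
    return rec, blink


def generate_dataset(spec: SimSpec) -> tuple[list[Segment], DatasetManifest]:
    """Generate ``n_segments_per_class`` labeled segments per class.

    With ``blink_rate_hz > 0`` every segment gains blink transients on
    all channels plus a synthetic ``EOG1`` reference channel.  The
    manifest lists one EDF filename per segment (materialized by
    :func:`write_dataset_edf`).
    """
    root = np.random.SeedSequence(spec.seed)
    segments: list[Segment] = []
    entries: list[ManifestEntry] = []
    child_seeds = root.generate_state(len(spec.classes) * spec.n_segments_per_class * 2)
    si = 0
    for cls in spec.classes:
        for i in range(spec.n_segments_per_class):
            seg = generate_segment(
                cls,
                n_channels=spec.n_channels,
                fs=spec.fs,
                duration_s=spec.duration_s,
                seed=int(child_seeds[si] % (2**31)),
            )
            si += 1
            if spec.blink_rate_hz > 0:
                rng = np.random.default_rng(int(child_seeds[si] % (2**31)))
                bg_sd = float(seg.samples.std())
                blink = _blink_train(
                    rng, seg.n_samples, spec.fs, spec.blink_rate_hz,
                    BLINK_AMPLITUDE_SD * bg_sd,
                )
                gains = rng.uniform(0.5, 1.0, size=seg.n_channels)
                eeg = seg.samples + gains[:, None] * blink[None, :]
                eog = blink + 0.05 * bg_sd * rng.standard_normal(seg.n_samples)
                seg = Segment(
                    samples=np.vstack([eeg, eog[None, :]]),
                    fs=seg.fs,
                    duration_s=seg.duration_s,
                    class_label=seg.class_label,
                    subject_id=seg.subject_id,
                    segment_index=i,
                    channel_labels=tuple(seg.channel_labels) + ("EOG1",),
                )
            else:
                seg = replace(seg, segment_index=i)
            si += 1
            seg.subject_id = f"sim-{cls.class_label}-{i}"
            segments.append(seg)
            entries.append(
                ManifestEntry(
                    path=f"{cls.class_label}-{i:04d}.edf",
                    dialect="edf",
                    class_label=cls.class_label,
                    subject_id=seg.subject_id,
                )
            )
    return segments, DatasetManifest(entries=entries)


# ---------------------------------------------------------------------------
# Minimal EDF writer for fixtures.  Nothing in the installed stack writes
# EDF, and the format is simple: an ASCII header plus little-endian int16
# data records with a per-channel physical/digital scaling.
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    b = str(value).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, samples_uv: np.ndarray, fs: float,
              channel_labels: Sequence[str]) -> None:
    """Write a (n_channels, n_samples) microvolt array as a valid EDF file.

    Values are quantized to 16 bits over each channel's observed range,
    so the round-trip error is bounded by (max - min) / 65535 per
    channel.  The sampling rate must be an integer (one-second data
    records); non-integer-rate data belongs in the ASCII dialect.
    """
    samples_uv = np.atleast_2d(np.asarray(samples_uv, dtype=float))
    n_ch, n_samp = samples_uv.shape
    if len(channel_labels) != n_ch:
        raise ParameterError("one label per channel required")
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError(
            f"EDF writer requires an integer sampling rate, got {fs}"
        )
    fs = int(round(fs))
    n_rec = int(np.ceil(n_samp / fs))
    padded = np.pad(samples_uv, ((0, 0), (0, n_rec * fs - n_samp)))

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-6
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    # write and re-parse the physical range so scaling matches the header
    pmin_s = [f"{v:.6g}"[:8] for v in pmin]
    pmax_s = [f"{v:.6g}"[:8] for v in pmax]
    pmin_w = np.array([float(s) for s in pmin_s])
    pmax_w = np.array([float(s) for s in pmax_s])
    pmin_w = np.minimum(pmin_w, pmin)
    pmax_w = np.maximum(pmax_w, pmax)

    hdr = b""
    hdr += _edf_field("0", 8)
    hdr += _edf_field("X X X X", 80)
    hdr += _edf_field("Startdate 01-JAN-2000 X X X", 80)
    hdr += _edf_field("01.01.00", 8)
    hdr += _edf_field("00.00.00", 8)
    hdr += _edf_field(256 * (1 + n_ch), 8)
    hdr += _edf_field("", 44)
    hdr += _edf_field(n_rec, 8)
    hdr += _edf_field("1", 8)
    hdr += _edf_field(n_ch, 4)
    for lab in channel_labels:
        hdr += _edf_field(lab, 16)
    for _ in channel_labels:
        hdr += _edf_field("", 80)  # transducer
    for _ in channel_labels:
        hdr += _edf_field("uV", 8)
    for s in pmin_w:
        hdr += _edf_field(f"{s:.6g}"[:8], 8)
    for s in pmax_w:
        hdr += _edf_field(f"{s:.6g}"[:8], 8)
    for _ in channel_labels:
        hdr += _edf_field(-32768, 8)
    for _ in channel_labels:
        hdr += _edf_field(32767, 8)
    for _ in channel_labels:
        hdr += _edf_field("", 80)  # prefiltering
    for _ in channel_labels:
        hdr += _edf_field(fs, 8)
    for _ in channel_labels:
        hdr += _edf_field("", 32)

    pmin_f = np.array([float(f"{s:.6g}"[:8]) for s in pmin_w])
    pmax_f = np.array([float(f"{s:.6g}"[:8]) for s in pmax_w])
    scale = (pmax_f - pmin_f) / 65535.0
    dig = np.clip(
        np.round((padded - pmin_f[:, None]) / scale[:, None]) - 32768,
        -32768, 32767,
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for i in range(n_ch):
                fh.write(dig[i, r * fs : (r + 1) * fs].tobytes())


def write_fixture_edf(segments: Sequence[Segment], path: str | Path) -> None:
    """Concatenate segments with a uniform layout into one EDF file."""
    if not segments:
        raise ParameterError("no segments to write")
    fs = segments[0].fs
    labels = segments[0].channel_labels
    for s in segments[1:]:
        if s.fs != fs or s.channel_labels != labels:
            raise ParameterError("segments have heterogeneous layouts")
    data = np.concatenate([s.samples for s in segments], axis=1)
    write_edf(path, data, fs, labels)


def write_dataset_edf(
    segments: Sequence[Segment],
    manifest: DatasetManifest,
    out_dir: str | Path,
) -> DatasetManifest:
    """Write one EDF per segment under ``out_dir`` plus the manifest CSV.

    Returns a manifest whose paths point at the written files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(segments) != len(manifest.entries):
        raise ParameterError("one manifest entry per segment required")
    entries = []
    for seg, entry in zip(segments, manifest.entries):
        target = out_dir / entry.path
        write_fixture_edf([seg], target)
        entries.append(replace_entry_path(entry, str(target)))
    new_manifest = DatasetManifest(entries=entries)
    new_manifest.write_csv(out_dir / "manifest.csv")
    return new_manifest


def replace_entry_path(entry: ManifestEntry, path: str) -> ManifestEntry:
    return ManifestEntry(
        path=path,
        dialect=entry.dialect,
        class_label=entry.class_label,
        subject_id=entry.subject_id,
    )
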