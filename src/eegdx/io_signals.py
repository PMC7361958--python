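"""Recording I/O and segmentation.

Two input dialects are supported:

* plain-text single-channel signals, one sample per line (the layout used
  by the Bonn University epilepsy sets A-E, nominally 173.61 Hz), and
* multi-channel EDF/EDF+ recordings (the layout of clinical scalp EEG,
  e.g. 23 channels at 256 Hz), read through :mod:`mne`.

Recordings are cut into fixed-duration, non-overlapping segments; the
segment is the unit all downstream feature extraction operates on.
Channel order is file order everywhere and is part of the contract:
feature-vector ordering depends on it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import ContractError, FormatError, ParameterError

CLASS_LABELS = ("neurotypical", "epilepsy", "autism", "unknown")

TailPolicy = Literal["drop", "keep-short", "whole-if-shorter"]


@dataclass
class RawRecording:
    """A multi- or single-channel sampled signal.

    ``samples`` is a (n_channels, n_samples) float array in nominal
    microvolts.  ``eog_labels`` flags the subset of channels that are
    ocular references for artifact removal.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    eog_labels: tuple[str, ...] = ()
    subject_id: str = ""
    class_label: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        self.eog_labels = tuple(self.eog_labels)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ContractError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ContractError("channel labels must be unique")
        unknown = set(self.eog_labels) - set(self.channel_labels)
        if unknown:
            raise ContractError(f"eog_labels not among channels: {sorted(unknown)}")
        if self.class_label not in CLASS_LABELS:
            raise ParameterError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Segment:
    """One fixed-duration window of a recording; the unit of feature
    extraction.  ``short_tail`` marks a segment shorter than the nominal
    window (see :func:`segment_recording`)."""

    samples: np.ndarray
    fs: float
    duration_s: float
    class_label: str = "unknown"
    subject_id: str = ""
    segment_index: int = 0
    channel_labels: tuple[str, ...] = ()
    short_tail: bool = False

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not self.channel_labels:
            self.channel_labels = tuple(
                f"ch{i}" for i in range(self.samples.shape[0])
            )
        self.channel_labels = tuple(self.channel_labels)
        if self.class_label not in CLASS_LABELS:
            raise ParameterError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        if not self.short_tail:
            expect = round(self.duration_s * self.fs)
            if self.samples.shape[1] != expect:
                raise ContractError(
                    f"segment has {self.samples.shape[1]} samples per channel, "
                    f"expected round({self.duration_s} * {self.fs}) = {expect}"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class ManifestEntry:
    path: str
    dialect: str  # "ascii_single" | "edf"
    class_label: str
    subject_id: str


@dataclass
class DatasetManifest:
    """List of recording files with their dialect and labels."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        paths = [e.path for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ContractError("manifest paths must be unique")
        for e in self.entries:
            if e.dialect not in ("ascii_single", "edf"):
                raise ParameterError(f"unknown dialect {e.dialect!r}")

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["path", "dialect", "class_label", "subject_id"])
            for e in self.entries:
                w.writerow([e.path, e.dialect, e.class_label, e.subject_id])

    @classmethod
    def read_csv(cls, path: str | Path) -> "DatasetManifest":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    ManifestEntry(
                        path=row["path"],
                        dialect=row["dialect"],
                        class_label=row["class_label"],
                        subject_id=row["subject_id"],
                    )
                )
        return cls(entries=entries)


def read_ascii_single_channel(
    path: str | Path,
    fs: float,
    class_label: str = "unknown",
    subject_id: str = "",
) -> RawRecording:
    """Read a one-sample-per-line plain-text signal.

    Blank lines are ignored; values must use a decimal point.  Raises
    :class:`FormatError` naming the first unparseable line, or on an
    empty file.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                values.append(float(s))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: cannot parse {s!r} as a number"
                ) from None
    if not values:
        raise FormatError(f"{path}: no samples (empty file)")
    return RawRecording(
        samples=np.asarray(values, dtype=float)[np.newaxis, :],
        fs=fs,
        channel_labels=(path.stem,),
        class_label=class_label,
        subject_id=subject_id,
    )


def write_ascii_single_channel(rec: RawRecording, path: str | Path) -> None:
    """Write a single-channel recording in the one-sample-per-line dialect."""
    if rec.n_channels != 1:
        raise ContractError("ascii dialect holds exactly one channel")
    with open(path, "w") as fh:
        for v in rec.samples[0]:
            fh.write(f"{float(v)!r}\n")


def read_edf(
    path: str | Path,
    eog_labels: Sequence[str] = (),
    class_label: str = "unknown",
    subject_id: str = "",
) -> RawRecording:
    """Read a multi-channel EDF/EDF+ file via :mod:`mne`.

    Channels come back in file order, in microvolts, with the sampling
    rate taken from the header.  Channels whose labels appear in
    ``eog_labels`` are flagged as ocular references on the returned
    recording.  Files mixing sampling rates are rejected (mne would
    silently resample them).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # mne resamples mixed-rate EDFs to the highest rate; detect and refuse.
    rates = set()
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        n_sig = int(hdr[252:256].decode("ascii").strip())
        fh.seek(256 + n_sig * (16 + 80 + 8 * 5 + 80))
        rec_dur = float(hdr[244:252].decode("ascii").strip())
        for i in range(n_sig):
            nspr = int(fh.read(8).decode("ascii").strip())
            rates.add(nspr / rec_dur)
    if len(rates) > 1:
        raise FormatError(
            f"{path}: channels with mixed sampling rates {sorted(rates)} "
            "are not supported"
        )
    data = raw.get_data(units="uV")
    labels = tuple(raw.ch_names)
    eog = tuple(l for l in labels if l in set(eog_labels))
    return RawRecording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        eog_labels=eog,
        class_label=class_label,
        subject_id=subject_id,
    )


def read_manifest_recordings(
    manifest: DatasetManifest,
    ascii_fs: float = 173.61,
    eog_labels: Sequence[str] = (),
) -> list[RawRecording]:
    """Materialize every manifest entry as a RawRecording."""
    recs = []
    for e in manifest.entries:
        if e.dialect == "ascii_single":
            recs.append(
                read_ascii_single_channel(
                    e.path, fs=ascii_fs,
                    class_label=e.class_label, subject_id=e.subject_id,
                )
            )
        else:
            recs.append(
                read_edf(
                    e.path, eog_labels=eog_labels,
                    class_label=e.class_label, subject_id=e.subject_id,
                )
            )
    return recs


def segment_recording(
    rec: RawRecording,
    window_s: float,
    policy: TailPolicy = "whole-if-shorter",
) -> list[Segment]:
    """Cut a recording into consecutive non-overlapping windows.

    Tail policies:

    * ``drop`` — discard any trailing partial window;
    * ``keep-short`` — keep the trailing partial window, flagged
      ``short_tail``;
    * ``whole-if-shorter`` (default) — like ``drop``, except that a
      recording shorter than one window yields a single flagged segment
      covering the whole recording.  This is what makes ~23.6 s signals
      usable under a 50 s nominal window.
    """
    if window_s <= 0:
        raise ParameterError(f"window_s must be positive, got {window_s}")
    if policy not in ("drop", "keep-short", "whole-if-shorter"):
        raise ParameterError(f"unknown tail policy {policy!r}")
    win = round(window_s * rec.fs)
    n = rec.n_samples
    n_full = n // win
    segments: list[Segment] = []
    for i in range(n_full):
        segments.append(
            Segment(
                samples=rec.samples[:, i * win : (i + 1) * win],
                fs=rec.fs,
                duration_s=window_s,
                class_label=rec.class_label,
                subject_id=rec.subject_id,
                segment_index=i,
                channel_labels=rec.channel_labels,
            )
        )
    tail = n - n_full * win
    keep_tail = policy == "keep-short" and tail > 0
    keep_whole = policy == "whole-if-shorter" and n_full == 0 and tail > 0
    if keep_tail or keep_whole:
        segments.append(
            Segment(
                samples=rec.samples[:, n_full * win :],
                fs=rec.fs,
                duration_s=tail / rec.fs,
                class_label=rec.class_label,
                subject_id=rec.subject_id,
                segment_index=n_full,
                channel_labels=rec.channel_labels,
                short_tail=True,
            )
        )
    return segments
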