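"""Reading, writing and windowing of paired LV/RV electrogram recordings.

The on-disk dialect is a plain whitespace-delimited ASCII table with optional
``# key=value`` header lines::

    # patient=P01
    # fs=200
    0.000000 0.104321 -0.221008
    0.005000 0.110442 -0.215500
    ...

Columns are ``time_s  LV  RV``.  Amplitudes are kept in recorded units (device
gain is not assumed calibrated), sampling rate defaults to 200 Hz when the
header omits it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: Analysis windows in seconds, half-open [start, end).
WINDOWS: dict[str, tuple[float, float]] = {"W1": (0.0, 3.0), "W2": (3.0, 6.0)}

CHANNELS = ("LV", "RV")


@dataclass(frozen=True)
class EGMRecording:
    """One channel's uniformly sampled voltage trace.

    Parameters
    ----------
    patient_id:
        Free-form patient label, e.g. ``"P07"``.
    channel:
        Either ``"LV"`` or ``"RV"``.
    samples:
        Voltage samples in recorded units (nominally mV, uncalibrated gain).
    fs:
        Sampling rate in Hz; the recording platform digitizes at 200 Hz.
    """

    patient_id: str
    channel: str
    samples: np.ndarray
    fs: float = 200.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.channel not in CHANNELS:
            raise ValidationError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based)."""
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class EGMPair:
    """Simultaneously recorded LV and RV channels sharing one time base."""

    lv: EGMRecording
    rv: EGMRecording

    def __post_init__(self) -> None:
        if self.lv.channel != "LV" or self.rv.channel != "RV":
            raise ValidationError("pair must hold an LV recording and an RV recording")
        if self.lv.n_samples != self.rv.n_samples:
            raise ValidationError(
                f"channel lengths differ: LV {self.lv.n_samples} vs RV {self.rv.n_samples}"
            )
        if self.lv.fs != self.rv.fs:
            raise ValidationError("channels must share the sampling rate")
        if self.lv.patient_id != self.rv.patient_id:
            raise ValidationError("channels must share the patient id")

    @property
    def patient_id(self) -> str:
        return self.lv.patient_id

    @property
    def fs(self) -> float:
        return self.lv.fs

    @property
    def n_samples(self) -> int:
        return self.lv.n_samples

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns ``time_s``, ``LV``, ``RV``."""
        return pd.DataFrame(
            {"time_s": self.lv.times, "LV": self.lv.samples, "RV": self.rv.samples}
        )


def read_egm_ascii(path: str | Path) -> EGMPair:
    """Read a paired recording from the ASCII dialect described above.

    Raises
    ------
    ParseError
        On ragged rows, non-numeric cells or a missing channel column; the
        message names the 1-based line number.
    """
    path = Path(path)
    header: dict[str, str] = {}
    times: list[float] = []
    lv: list[float] = []
    rv: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    header[key.strip()] = value.strip()
                continue
            cells = line.split()
            if len(cells) != 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 3 columns (time LV RV), got {len(cells)}"
                )
            try:
                t, x_lv, x_rv = (float(c) for c in cells)
            except ValueError:
                raise ParseError(f"{path.name}:{lineno}: non-numeric cell in {cells!r}") from None
            times.append(t)
            lv.append(x_lv)
            rv.append(x_rv)
    if not lv:
        raise ParseError(f"{path.name}:1: file contains no data rows")
    try:
        fs = float(header.get("fs", 200.0))
    except ValueError:
        raise ParseError(f"{path.name}: malformed fs header {header['fs']!r}") from None
    patient = header.get("patient", path.stem)
    return EGMPair(
        lv=EGMRecording(patient, "LV", np.asarray(lv), fs),
        rv=EGMRecording(patient, "RV", np.asarray(rv), fs),
    )


def write_egm_ascii(pair: EGMPair, path: str | Path, precision: int = 6) -> Path:
    """Write a pair in the ASCII dialect; lossless to ``precision`` decimals."""
    path = Path(path)
    fmt = f"%.{precision}f"
    with path.open("w") as fh:
        fh.write(f"# patient={pair.patient_id}\n")
        fh.write(f"# fs={pair.fs:g}\n")
        for t, a, b in zip(pair.lv.times, pair.lv.samples, pair.rv.samples):
            fh.write(f"{fmt % t} {fmt % a} {fmt % b}\n")
    return path


def write_egm_csv(pair: EGMPair, path: str | Path) -> Path:
    """CSV export of a pair (columns time_s, LV, RV)."""
    path = Path(path)
    pair.to_frame().to_csv(path, index=False)
    return path


def segment_window(pair: EGMPair, window: str) -> EGMPair:
    """Extract one analysis window (``"W1"`` = [0, 3) s, ``"W2"`` = [3, 6) s).

    Windows are half-open in time so that at 200 Hz each holds exactly 600
    samples and W1/W2 partition the first six seconds with no shared sample.
    """
    if window not in WINDOWS:
        raise ValidationError(f"unknown window {window!r}; expected one of {sorted(WINDOWS)}")
    start_s, end_s = WINDOWS[window]
    i0 = int(round(start_s * pair.fs))
    i1 = int(round(end_s * pair.fs))
    if pair.n_samples < i1:
        raise ValidationError(
            f"recording too short for {window}: needs {end_s:g} s "
            f"({i1} samples at {pair.fs:g} Hz), only {pair.lv.duration:g} s available"
        )
    return EGMPair(
        lv=EGMRecording(pair.patient_id, "LV", pair.lv.samples[i0:i1], pair.fs),
        rv=EGMRecording(pair.patient_id, "RV", pair.rv.samples[i0:i1], pair.fs),
    )
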