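"""Tone-pip stimulation protocol.

A :class:`StimulusProtocol` is the frequency x intensity x trial grid shared by
the synthetic generator and every analysis stage.  The default protocol is the
classic rat AI mapping design: 66 pure tones spanning 1-70 kHz (geometric
spacing, ~0.094 octave per step), eight sound levels from 0 to 70 dB SPL in
10-dB increments, three trials per tone-level pair, 25-ms tones with 5-ms
ramps presented at 2/s, and spikes binned at 1 ms.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import ValidationError

DEFAULT_N_FREQS = 66
DEFAULT_FREQ_RANGE_HZ = (1_000.0, 70_000.0)
DEFAULT_INTENSITIES_DB = tuple(float(i) for i in range(0, 80, 10))


def _check_strictly_increasing(name: str, values: tuple[float, ...]) -> None:
    if len(values) == 0:
        raise ValidationError(f"{name}: must be non-empty")
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: values must be finite")
    if len(arr) > 1 and not np.all(np.diff(arr) > 0):
        raise ValidationError(f"{name}: must be strictly increasing")


@dataclass(frozen=True)
class StimulusProtocol:
    """Immutable description of the tone-pip grid.

    Attributes
    ----------
    frequencies_hz : tuple of float
        Tone frequencies in Hz, strictly increasing.
    intensities_db : tuple of float
        Sound levels in dB SPL, strictly increasing.
    n_trials : int
        Presentations per (frequency, intensity) pair.
    tone_ms, ramp_ms, isi_ms, bin_ms : float
        Tone duration, onset/offset ramp, stimulus period and PSTH bin width,
        all in milliseconds.  ``bin_ms`` must divide ``isi_ms``.
    """

    frequencies_hz: tuple[float, ...]
    intensities_db: tuple[float, ...]
    n_trials: int = 3
    tone_ms: float = 25.0
    ramp_ms: float = 5.0
    isi_ms: float = 500.0
    bin_ms: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies_hz",
                           tuple(float(f) for f in self.frequencies_hz))
        object.__setattr__(self, "intensities_db",
                           tuple(float(i) for i in self.intensities_db))
        _check_strictly_increasing("frequencies_hz", self.frequencies_hz)
        _check_strictly_increasing("intensities_db", self.intensities_db)
        if min(self.frequencies_hz) <= 0:
            raise ValidationError("frequencies_hz: must be positive")
        if not isinstance(self.n_trials, (int, np.integer)) or self.n_trials < 1:
            raise ValidationError("n_trials: must be an integer >= 1")
        for name in ("tone_ms", "ramp_ms", "isi_ms", "bin_ms"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name}: must be finite and non-negative")
        if self.bin_ms <= 0:
            raise ValidationError("bin_ms: must be positive")
        ratio = self.isi_ms / self.bin_ms
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError("bin_ms: must divide isi_ms")

    # -- derived views -----------------------------------------------------
    @property
    def n_freqs(self) -> int:
        return len(self.frequencies_hz)

    @property
    def n_intensities(self) -> int:
        return len(self.intensities_db)

    @property
    def freq_array(self) -> np.ndarray:
        return np.asarray(self.frequencies_hz, dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.asarray(self.intensities_db, dtype=float)

    @property
    def freq_octaves(self) -> np.ndarray:
        """Frequencies as octaves above the lowest tested tone."""
        f = self.freq_array
        return np.log2(f / f[0])

    @property
    def freq_step_oct(self) -> float:
        """Median octave step between neighboring tones."""
        return float(np.median(np.diff(self.freq_octaves)))

    def nearest_frequency(self, hz: float) -> float:
        """Snap an arbitrary frequency to the closest protocol tone (log scale)."""
        if hz <= 0:
            raise ValidationError("frequency must be positive")
        i = int(np.argmin(np.abs(np.log2(self.freq_array / hz))))
        return self.frequencies_hz[i]

    def nearest_intensity(self, db: float) -> float:
        i = int(np.argmin(np.abs(self.intensity_array - db)))
        return self.intensities_db[i]

    def freq_index(self, hz: float) -> int:
        d = np.abs(np.log2(self.freq_array / hz))
        i = int(np.argmin(d))
        if d[i] > 1e-9:
            raise ValidationError(f"frequency {hz} Hz not on the protocol grid")
        return i

    def intensity_index(self, db: float) -> int:
        d = np.abs(self.intensity_array - db)
        i = int(np.argmin(d))
        if d[i] > 1e-6:
            raise ValidationError(f"intensity {db} dB not on the protocol grid")
        return i

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frequencies_hz"] = list(d["frequencies_hz"])
        d["intensities_db"] = list(d["intensities_db"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        allowed = {"frequencies_hz", "intensities_db", "n_trials", "tone_ms",
                   "ramp_ms", "isi_ms", "bin_ms"}
        unknown = set(d) - allowed
        if unknown:
            raise ValidationError(f"unknown protocol keys: {sorted(unknown)}")
        return cls(**d)


def make_protocol(**overrides) -> StimulusProtocol:
    """Build a protocol; with no overrides, the default 66 x 8 x 3 design.

    Overrides use :class:`StimulusProtocol` field names and are validated.
    """
    fields = {
        "frequencies_hz": tuple(
            np.geomspace(DEFAULT_FREQ_RANGE_HZ[0], DEFAULT_FREQ_RANGE_HZ[1],
                         DEFAULT_N_FREQS)
        ),
        "intensities_db": DEFAULT_INTENSITIES_DB,
    }
    unknown = set(overrides) - {
        "frequencies_hz", "intensities_db", "n_trials", "tone_ms", "ramp_ms",
        "isi_ms", "bin_ms"}
    if unknown:
        raise ValidationError(f"unknown protocol overrides: {sorted(unknown)}")
    fields.update(overrides)
    return StimulusProtocol(**fields)
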