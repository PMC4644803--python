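"""In-memory container for one recording site's binned spike counts."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .protocol import StimulusProtocol


@dataclass
class SiteRecording:
    """Binned multiunit spike counts for one cortical site.

    ``counts`` has shape (n_freqs, n_intensities, n_trials, n_bins) where the
    time axis covers ``pre_ms`` of pre-stimulus baseline (negative bin
    offsets) followed by ``post_ms`` after tone onset.  Bin *b* starts at
    ``-pre_ms + b * bin_ms`` relative to onset.
    """

    site_id: str
    x_um: float
    y_um: float
    counts: np.ndarray
    pre_ms: float = 50.0
    post_ms: float = 100.0
    penetration_id: int = 0
    animal_id: str = ""
    group: str = ""

    def validate(self, protocol: StimulusProtocol) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 4:
            raise ValidationError("counts: expected 4-D (freq, intensity, trial, bin)")
        f, i, t, b = c.shape
        if f != protocol.n_freqs or i != protocol.n_intensities:
            raise ValidationError("counts: grid does not match the protocol")
        if t != protocol.n_trials:
            raise ValidationError("counts: trial axis does not match the protocol")
        if b != self.n_bins(protocol.bin_ms):
            raise ValidationError("counts: time axis does not match the window")
        if np.any(c < 0):
            raise ValidationError("counts: negative spike counts")
        if self.n_baseline_bins(protocol.bin_ms) < 1:
            raise ValidationError("pre_ms: at least one baseline bin required")

    def n_bins(self, bin_ms: float) -> int:
        return int(round((self.pre_ms + self.post_ms) / bin_ms))

    def n_baseline_bins(self, bin_ms: float) -> int:
        return int(round(self.pre_ms / bin_ms))

    def bin_offsets_ms(self, bin_ms: float) -> np.ndarray:
        """Start time of every bin relative to tone onset (ms)."""
        n = self.n_bins(bin_ms)
        return -self.pre_ms + bin_ms * np.arange(n)
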