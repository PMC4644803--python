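"""Frequency-intensity receptive-field (FRA) reconstruction and metrics.

From one site's binned spike counts this module builds the evoked-response
matrix with a per-cell significance mask, then extracts the classic tuning
metrics: characteristic frequency (CF, the tip of the tuning curve),
intensity threshold, BW10 (octave span of responsive frequencies 10 dB above
threshold), onset latency (first PSTH bins exceeding baseline mean + 4 SD),
the receptive-field irregularity index, and the tuning-curve shape class
(single v-shaped, multi-peaked, or flat).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, signal, stats

from .config import RunConfig
from .errors import ValidationError
from .protocol import StimulusProtocol
from .recording import SiteRecording

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class FRA:
    """Evoked-response matrix with significance mask and baseline statistics.

    ``evoked[f, i]`` is the baseline-corrected mean evoked count per
    presentation (floored at 0); ``sig_mask`` marks cells whose response-window
    count clears a Poisson upper-tail test against the pooled baseline rate
    and belongs to a 4-connected cluster of at least ``min_cluster_size``
    significant cells.  Baseline statistics are spikes/bin pooled over the
    pre-stimulus bins of every presentation.
    """

    evoked: np.ndarray
    sig_mask: np.ndarray
    baseline_mean: float
    baseline_sd: float

    @property
    def responsive(self) -> bool:
        return bool(self.sig_mask.any())


@dataclass
class IrregularityTerms:
    """Autocorrelation terms of the significance mask."""

    c00: float
    c10: float
    c01: float


@dataclass
class SiteMetrics:
    """All per-site receptive-field metrics; None encodes "undefined"."""

    site_id: str
    responsive: bool
    cf_hz: Optional[float] = None
    threshold_db: Optional[float] = None
    bw10_oct: Optional[float] = None
    latency_ms: Optional[float] = None
    irregularity: Optional[float] = None
    shape: Optional[str] = None
    max_sig_db: Optional[float] = None
    in_ai: Optional[bool] = None


def build_fra(rec: SiteRecording, protocol: StimulusProtocol,
              config: Optional[RunConfig] = None) -> FRA:
    """Reconstruct the FRA of one site.

    The response window (default 5-50 ms after onset) is compared, per
    (frequency, intensity) cell and pooled over trials, against a Poisson null
    with the pooled pre-stimulus baseline rate.
    """
    config = config or RunConfig()
    rec.validate(protocol)
    counts = np.asarray(rec.counts, dtype=float)
    nb = rec.n_baseline_bins(protocol.bin_ms)
    offsets = rec.bin_offsets_ms(protocol.bin_ms)

    baseline = counts[:, :, :, :nb]
    baseline_mean = float(baseline.mean())
    baseline_sd = float(baseline.std())

    lo, hi = config.response_window_ms
    resp_idx = (offsets >= lo) & (offsets < hi)
    n_resp_bins = int(resp_idx.sum())
    if n_resp_bins == 0:
        raise ValidationError("response_window_ms: no bins inside the recording window")

    total = counts[:, :, :, resp_idx].sum(axis=(2, 3))  # pooled over trials
    mu = baseline_mean * n_resp_bins * protocol.n_trials
    pvals = stats.poisson.sf(total - 1, mu)
    evoked = np.maximum(0.0, total / protocol.n_trials
                        - baseline_mean * n_resp_bins)
    sig = (pvals < config.alpha) & (evoked > 0)

    if sig.any() and config.min_cluster_size > 1:
        labels, n = ndimage.label(sig, structure=_CROSS)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= config.min_cluster_size
        keep[0] = False
        sig = keep[labels]

    return FRA(evoked=evoked, sig_mask=sig, baseline_mean=baseline_mean,
               baseline_sd=baseline_sd)


def extract_cf_threshold(fra: FRA, protocol: StimulusProtocol
                         ) -> tuple[Optional[float], Optional[float]]:
    """CF and intensity threshold from the significance mask.

    Threshold is the lowest intensity with any significant cell.  CF is the
    significant frequency at that intensity; with several (a flat tip) the
    median frequency is used (lower median for even counts).  When the
    threshold row holds several disjoint runs of significant frequencies the
    lowest-frequency run is used, which breaks apex ties toward lower
    frequencies; a higher apex with a strictly lower threshold wins outright
    because it alone defines the threshold row.
    """
    if not fra.responsive:
        return None, None
    sig = fra.sig_mask
    i_thr = int(np.flatnonzero(sig.any(axis=0))[0])
    threshold = protocol.intensities_db[i_thr]
    cols = np.flatnonzero(sig[:, i_thr])
    # first contiguous run (lowest frequencies)
    breaks = np.flatnonzero(np.diff(cols) > 1)
    run = cols[: breaks[0] + 1] if breaks.size else cols
    median_col = int(run[(len(run) - 1) // 2])
    return protocol.frequencies_hz[median_col], threshold


def compute_bw10(fra: FRA, threshold_db: Optional[float],
                 protocol: StimulusProtocol) -> Optional[float]:
    """Octave span of significant frequencies 10 dB above threshold.

    0 when exactly one cell responds in that row; None when threshold + 10 dB
    exceeds the tested range or the row holds no significant cell.
    """
    if threshold_db is None:
        return None
    target = threshold_db + 10.0
    d = np.abs(protocol.intensity_array - target)
    i10 = int(np.argmin(d))
    if d[i10] > 1e-6:
        return None
    cols = np.flatnonzero(fra.sig_mask[:, i10])
    if cols.size == 0:
        return None
    if cols.size == 1:
        return 0.0
    freqs = protocol.freq_array
    return float(np.log2(freqs[cols[-1]] / freqs[cols[0]]))


def estimate_latency(rec: SiteRecording, protocol: StimulusProtocol,
                     threshold_db: Optional[float],
                     config: Optional[RunConfig] = None) -> Optional[float]:
    """Onset latency from the pooled PSTH.

    The PSTH (mean spikes/bin) pools every presentation at or above the site
    threshold.  Latency is the start of the first run of
    ``latency_min_consecutive_bins`` bins at or above baseline mean +
    ``latency_sd_criterion`` * SD (baseline statistics from the PSTH's own
    pre-stimulus bins), searched inside ``latency_window_ms``.  None when the
    criterion is never met.
    """
    config = config or RunConfig()
    if threshold_db is None:
        return None
    counts = np.asarray(rec.counts, dtype=float)
    nb = rec.n_baseline_bins(protocol.bin_ms)
    offsets = rec.bin_offsets_ms(protocol.bin_ms)

    sel = protocol.intensity_array >= threshold_db - 1e-9
    psth = counts[:, sel, :, :].mean(axis=(0, 1, 2))

    base = psth[:nb]
    base_mean = float(base.mean())
    base_sd = float(base.std())
    crit = base_mean + config.latency_sd_criterion * base_sd

    lo, hi = config.latency_window_ms
    search = np.flatnonzero((offsets >= lo) & (offsets < hi))
    k = config.latency_min_consecutive_bins
    above = (psth >= crit) & (psth > base_mean)
    for b in search:
        if b + k <= len(psth) and above[b:b + k].all():
            return float(offsets[b])
    return None


def irregularity_index(fra_or_mask) -> tuple[Optional[IrregularityTerms],
                                             Optional[float]]:
    """Receptive-field irregularity from mask autocorrelation terms.

    With M the 0/1 significance mask, the central term c00 = sum(M^2) and the
    one-step terms c10, c01 (frequency and intensity shifts) give the index
    (c00 - (c10 + c01) / 2) / sqrt(c00) - 3.  Compact fields score low,
    fragmented fields high; values above 2 are conventionally "irregular".
    Accepts an :class:`FRA` or a boolean matrix; empty masks yield (None, None).
    """
    mask = fra_or_mask.sig_mask if isinstance(fra_or_mask, FRA) else fra_or_mask
    m = np.asarray(mask, dtype=float)
    c00 = float((m * m).sum())
    if c00 == 0:
        return None, None
    c10 = float((m[1:, :] * m[:-1, :]).sum())
    c01 = float((m[:, 1:] * m[:, :-1]).sum())
    index = (c00 - (c10 + c01) / 2.0) / np.sqrt(c00) - 3.0
    return IrregularityTerms(c00, c10, c01), float(index)


def _column_thresholds(sig: np.ndarray, protocol: StimulusProtocol
                       ) -> np.ndarray:
    """Lowest significant intensity per frequency column (NaN if none)."""
    thr = np.full(protocol.n_freqs, np.nan)
    has = sig.any(axis=1)
    idx = np.argmax(sig, axis=1)
    thr[has] = protocol.intensity_array[idx[has]]
    return thr


def classify_shape(fra: FRA, protocol: StimulusProtocol,
                   config: Optional[RunConfig] = None) -> Optional[str]:
    """Tuning-curve shape: ``single_v``, ``multi`` or ``flat``.

    The per-column threshold curve (undefined columns ignored) is median
    filtered over 3 columns for apex finding; apexes are local minima with
    >= 10 dB prominence separated by >= 0.3 octave.  More than one apex is
    multi-peaked.  Otherwise the minimal-threshold plateau is measured on the
    *raw* curve (the filter erases single-column tips); a plateau wider than
    1 octave is flat, anything else single v-shaped.
    """
    config = config or RunConfig()
    if not fra.responsive:
        return None
    thr = _column_thresholds(fra.sig_mask, protocol)
    defined = np.flatnonzero(~np.isnan(thr))
    raw = thr[defined]
    octs = protocol.freq_octaves[defined]

    filt = ndimage.median_filter(raw, size=3, mode="nearest") \
        if raw.size >= 3 else raw
    step = protocol.freq_step_oct
    distance = max(1, int(round(config.apex_min_separation_oct / step)))
    peaks, _ = signal.find_peaks(-filt, prominence=config.apex_prominence_db,
                                 distance=distance)
    if len(peaks) >= 2:
        return "multi"

    # minimal-threshold plateau around the raw global minimum
    min_thr = raw.min()
    at_min = np.isclose(raw, min_thr)
    pos = int(np.argmin(raw))
    left = pos
    while left > 0 and at_min[left - 1] and defined[left - 1] == defined[left] - 1:
        left -= 1
    right = pos
    while (right < len(raw) - 1 and at_min[right + 1]
           and defined[right + 1] == defined[right] + 1):
        right += 1
    span = octs[right] - octs[left]
    return "flat" if span > config.flat_plateau_oct else "single_v"


def analyze_site(rec: SiteRecording, protocol: StimulusProtocol,
                 config: Optional[RunConfig] = None) -> SiteMetrics:
    """Full per-site pipeline: FRA, CF/threshold, BW10, latency, shape."""
    config = config or RunConfig()
    fra = build_fra(rec, protocol, config)
    if not fra.responsive:
        return SiteMetrics(site_id=rec.site_id, responsive=False)
    cf, thr = extract_cf_threshold(fra, protocol)
    bw10 = compute_bw10(fra, thr, protocol)
    latency = estimate_latency(rec, protocol, thr, config)
    _, irregularity = irregularity_index(fra)
    shape = classify_shape(fra, protocol, config)
    rows = np.flatnonzero(fra.sig_mask.any(axis=0))
    max_sig = protocol.intensities_db[int(rows[-1])]
    return SiteMetrics(site_id=rec.site_id, responsive=True, cf_hz=cf,
                       threshold_db=thr, bw10_oct=bw10, latency_ms=latency,
                       irregularity=irregularity, shape=shape,
                       max_sig_db=max_sig)
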