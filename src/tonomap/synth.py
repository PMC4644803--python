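"""Synthetic multiunit-recording generator with known ground truth.

Emulates an acute mapping experiment: two 8 x 8 microelectrode penetrations
per animal (375 um column pitch, 500 um row pitch, 128 sites), a rostro-caudal
log-frequency gradient with controllable jitter, and Poisson multiunit spiking
whose tone-evoked component is shaped by each site's true characteristic
frequency (CF), intensity threshold, BW10, onset latency and tuning-curve
shape.  Condition presets encode the receptive-field statistics of a control
cortex and of a VPA-exposed (autism-model) cortex so downstream estimators can
be tested against exact truth.

The evoked firing model is a V-shaped intensity threshold in log-frequency,
thr(f) = thr + (20 / bw10) * |log2(f / cf)|, so that the supra-threshold
frequency span measured 10 dB above the tip equals bw10 exactly.  Inside the
supra-threshold region the rate is evoked_gain * (I - thr(f) + 10 dB), capped
at 100 Hz, confined to the window [latency, latency + tone + 10 ms]; the
+10 dB offset makes the response at the threshold intensity itself detectable,
which is what lets estimators recover the true threshold on a 10-dB grid.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Iterator, Optional

import numpy as np

from .errors import ValidationError
from .protocol import StimulusProtocol, make_protocol
from .recording import SiteRecording

RATE_CAP_HZ = 100.0
THRESHOLD_BUMP_DB = 10.0
EVOKED_TAIL_MS = 10.0

SHAPE_SINGLE = "single_v"
SHAPE_MULTI = "multi"
SHAPE_FLAT = "flat"
SHAPES = (SHAPE_SINGLE, SHAPE_MULTI, SHAPE_FLAT)


@dataclass(frozen=True)
class ConditionPreset:
    """Receptive-field statistics of one experimental condition.

    ``thr_mean_db``/``thr_sd_db`` describe the normal from which per-site
    thresholds are drawn before rounding to the intensity grid;
    ``p_thr_above50`` is the resulting fraction above 50 dB SPL implied by
    those two numbers and is kept in the preset as the documented target.
    """

    name: str
    cf_jitter_oct_sd: float
    bw10_mean_oct: float
    bw10_sd_oct: float
    thr_mean_db: float
    thr_sd_db: float
    p_thr_above50: float
    latency_mean_ms: float
    latency_sd_ms: float
    p_single: float
    p_multi: float
    p_flat: float
    baseline_rate_hz: float = 2.0
    evoked_gain: float = 5.0  # Hz per dB above threshold, saturating
    hi_freq_bias: float = 0.0  # probability a site's CF is resampled in 10-50 kHz

    def __post_init__(self) -> None:
        for name in ("cf_jitter_oct_sd", "bw10_sd_oct", "thr_sd_db",
                     "latency_sd_ms"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: SD must be >= 0")
        probs = (self.p_single, self.p_multi, self.p_flat)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("shape probabilities must be in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError("p_single + p_multi + p_flat must equal 1")
        for name in ("p_thr_above50", "hi_freq_bias"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name}: must be in [0, 1]")
        if self.bw10_mean_oct <= 0:
            raise ValidationError("bw10_mean_oct: must be positive")
        if self.baseline_rate_hz < 0 or self.evoked_gain < 0:
            raise ValidationError("rates must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


# Group means from the mapping study this generator emulates; threshold
# normals are parameterized so that P(rounded threshold > 50 dB) equals the
# printed high-threshold fraction (see docs/methods.md).
CONTROL_PRESET = ConditionPreset(
    name="control",
    cf_jitter_oct_sd=0.25,
    bw10_mean_oct=1.24, bw10_sd_oct=0.30,
    thr_mean_db=30.0, thr_sd_db=19.51, p_thr_above50=0.0999,
    latency_mean_ms=14.97, latency_sd_ms=1.5,
    p_single=0.9347, p_multi=0.0327, p_flat=0.0326,
    baseline_rate_hz=2.0, evoked_gain=5.0, hi_freq_bias=0.135,
)

VPA_PRESET = ConditionPreset(
    name="vpa",
    cf_jitter_oct_sd=0.80,
    bw10_mean_oct=3.02, bw10_sd_oct=0.60,
    thr_mean_db=50.0, thr_sd_db=15.79, p_thr_above50=0.3758,
    latency_mean_ms=10.27, latency_sd_ms=1.5,
    p_single=0.7625, p_multi=0.12, p_flat=0.1175,
    baseline_rate_hz=2.0, evoked_gain=5.0, hi_freq_bias=0.36,
)

PRESETS = {"control": CONTROL_PRESET, "vpa": VPA_PRESET}


@dataclass(frozen=True)
class MapGeometry:
    """Grid position of one recording site."""

    site_id: str
    penetration_id: int
    x_um: float
    y_um: float


@dataclass
class SiteTruth:
    """Ground-truth receptive-field parameters for one site."""

    true_cf_hz: Optional[float]
    true_thr_db: Optional[float]
    true_bw10_oct: Optional[float]
    true_latency_ms: Optional[float]
    true_shape: Optional[str]
    is_ai: bool
    is_responsive: bool
    # shape-specific extras
    true_cf2_hz: Optional[float] = None
    true_thr2_db: Optional[float] = None
    true_flat_span_oct: Optional[float] = None


def _grid_geometry(n_penetrations: int, n_rows: int, n_cols: int,
                   col_pitch_um: float, row_pitch_um: float,
                   penetration_gap_um: float) -> list[MapGeometry]:
    sites = []
    for p in range(n_penetrations):
        x0 = p * ((n_cols - 1) * col_pitch_um + penetration_gap_um)
        for c in range(n_cols):
            for r in range(n_rows):
                sites.append(MapGeometry(
                    site_id=f"p{p}c{c}r{r}",
                    penetration_id=p,
                    x_um=x0 + c * col_pitch_um,
                    y_um=r * row_pitch_um,
                ))
    return sites


def _perimeter_mask(n_rows: int, n_cols: int) -> np.ndarray:
    m = np.zeros((n_cols, n_rows), dtype=bool)
    m[0, :] = m[-1, :] = True
    m[:, 0] = m[:, -1] = True
    return m


def _sample_shape_params(shape: str, cf_hz: float, thr_db: float,
                         bw10: float, preset: ConditionPreset,
                         protocol: StimulusProtocol,
                         rng: np.random.Generator) -> dict:
    extra: dict = {}
    intens = protocol.intensity_array
    if shape == SHAPE_MULTI:
        # Narrow arms and a fixed +10 dB secondary threshold keep the saddle
        # at least one intensity step above the secondary apex, which is what
        # the prominence rule needs to see two peaks.
        sep = rng.uniform(1.6, 2.4)
        lo, hi = math.log2(protocol.frequencies_hz[0]), \
            math.log2(protocol.frequencies_hz[-1])
        c = math.log2(cf_hz)
        up_room = hi - c
        down_room = c - lo
        direction = 1.0 if up_room >= down_room else -1.0
        sep = min(sep, max(up_room, down_room) - 0.1)
        cf2 = protocol.nearest_frequency(2.0 ** (c + direction * max(sep, 1.0)))
        thr2 = min(thr_db + 10.0, intens[-1])
        extra["true_cf2_hz"] = cf2
        extra["true_thr2_db"] = float(thr2)
    elif shape == SHAPE_FLAT:
        extra["true_flat_span_oct"] = float(rng.uniform(1.2, 2.5))
    return extra


def sample_map(preset: ConditionPreset,
               rng: np.random.Generator,
               protocol: Optional[StimulusProtocol] = None,
               *,
               n_penetrations: int = 2,
               n_rows: int = 8,
               n_cols: int = 8,
               col_pitch_um: float = 375.0,
               row_pitch_um: float = 500.0,
               penetration_gap_um: float = 375.0,
               gradient_oct_per_mm: Optional[float] = None,
               cf0_khz: float = 1.0,
               ai_border_frac: float = 0.15) -> list[tuple[MapGeometry, SiteTruth]]:
    """Sample site geometry and ground truth for one animal's map.

    True CF follows a rostro-caudal gradient, log2(cf_kHz) =
    log2(cf0) + gradient * x_mm + eps with eps ~ N(0, cf_jitter_oct_sd),
    optionally resampled into 10-50 kHz with probability ``hi_freq_bias``,
    clipped to the protocol range and snapped to the tone grid.  A border
    fraction of sites (drawn from the grid perimeter) is non-AI: half respond
    only above 50 dB SPL, half are unresponsive.  When ``gradient_oct_per_mm``
    is None it is chosen so the noiseless gradient spans 1-63 kHz across the
    map, matching the normalization range of the tonotopic index.
    """
    if protocol is None:
        protocol = make_protocol()
    if not 0 <= ai_border_frac <= 1:
        raise ValidationError("ai_border_frac: must be in [0, 1]")
    geom = _grid_geometry(n_penetrations, n_rows, n_cols, col_pitch_um,
                          row_pitch_um, penetration_gap_um)
    xs = np.array([g.x_um for g in geom])
    span_mm = (xs.max() - xs.min()) / 1000.0
    if gradient_oct_per_mm is None:
        gradient_oct_per_mm = math.log2(63.0) / span_mm if span_mm > 0 else 1.0
    if gradient_oct_per_mm <= 0:
        raise ValidationError("gradient_oct_per_mm: must be positive")

    fmin, fmax = protocol.frequencies_hz[0], protocol.frequencies_hz[-1]
    intens = protocol.intensity_array

    # choose non-AI border sites per penetration
    per_pen = n_rows * n_cols
    n_border = int(round(ai_border_frac * per_pen))
    border_kind: dict[str, str] = {}
    for p in range(n_penetrations):
        perim = [g.site_id for g in geom
                 if g.penetration_id == p and _is_perimeter(g, p, n_rows, n_cols,
                                                            col_pitch_um,
                                                            row_pitch_um,
                                                            penetration_gap_um)]
        k = min(n_border, len(perim))
        chosen = rng.choice(len(perim), size=k, replace=False) if k else []
        for j, idx in enumerate(np.sort(np.asarray(chosen, dtype=int))):
            border_kind[perim[int(idx)]] = "hi_thr" if j % 2 == 0 else "unresponsive"

    out: list[tuple[MapGeometry, SiteTruth]] = []
    for g in geom:
        kind = border_kind.get(g.site_id)
        if kind == "unresponsive":
            out.append((g, SiteTruth(None, None, None, None, None,
                                     is_ai=False, is_responsive=False)))
            continue

        log2cf = math.log2(cf0_khz) + gradient_oct_per_mm * (g.x_um / 1000.0) \
            + rng.normal(0.0, preset.cf_jitter_oct_sd)
        if rng.random() < preset.hi_freq_bias:
            log2cf = rng.uniform(math.log2(10.0), math.log2(50.0))
        cf = float(np.clip(1000.0 * 2.0 ** log2cf, fmin, fmax))
        cf = protocol.nearest_frequency(cf)

        thr = float(protocol.nearest_intensity(
            np.clip(rng.normal(preset.thr_mean_db, preset.thr_sd_db),
                    intens[0], intens[-1])))
        bw10 = float(max(0.2, rng.normal(preset.bw10_mean_oct,
                                         preset.bw10_sd_oct)))
        lat = float(np.clip(rng.normal(preset.latency_mean_ms,
                                       preset.latency_sd_ms), 6.0, 20.0))
        shape = str(rng.choice(SHAPES,
                               p=(preset.p_single, preset.p_multi,
                                  preset.p_flat)))

        if kind == "hi_thr":
            thr = float(rng.choice([i for i in intens if i > 50.0]
                                   or [intens[-1]]))
            is_ai = False
        else:
            is_ai = True

        extra = _sample_shape_params(shape, cf, thr, bw10, preset, protocol,
                                     rng)
        out.append((g, SiteTruth(cf, thr, bw10, lat, shape,
                                 is_ai=is_ai, is_responsive=True, **extra)))
    return out


def _is_perimeter(g: MapGeometry, pen: int, n_rows: int, n_cols: int,
                  col_pitch: float, row_pitch: float, gap: float) -> bool:
    x0 = pen * ((n_cols - 1) * col_pitch + gap)
    c = int(round((g.x_um - x0) / col_pitch))
    r = int(round(g.y_um / row_pitch))
    return c in (0, n_cols - 1) or r in (0, n_rows - 1)


def _threshold_curve(truth: SiteTruth, protocol: StimulusProtocol) -> np.ndarray:
    """Frequency-dependent intensity threshold thr(f) in dB (continuous)."""
    f_oct = np.log2(protocol.freq_array / truth.true_cf_hz)
    bw = truth.true_bw10_oct
    slope = 20.0 / bw
    if truth.true_shape == SHAPE_FLAT:
        half = truth.true_flat_span_oct / 2.0
        excess = np.maximum(0.0, np.abs(f_oct) - half)
        thr_f = truth.true_thr_db + slope * excess
    else:
        thr_f = truth.true_thr_db + slope * np.abs(f_oct)
        if truth.true_shape == SHAPE_MULTI:
            # narrow secondary (and primary) arms; see module docstring
            arm = 20.0 / min(bw, 1.0)
            v1 = truth.true_thr_db + arm * np.abs(f_oct)
            f2 = np.log2(protocol.freq_array / truth.true_cf2_hz)
            v2 = truth.true_thr2_db + arm * np.abs(f2)
            thr_f = np.minimum(v1, v2)
    return thr_f


def expected_rate_surface(truth: SiteTruth,
                          protocol: StimulusProtocol,
                          preset: ConditionPreset,
                          *,
                          pre_ms: float = 50.0,
                          post_ms: float = 100.0) -> np.ndarray:
    """Analytic firing-rate surface (Hz) over frequency x intensity x bin.

    Unresponsive truths yield an all-baseline surface.
    """
    n_bins = int(round((pre_ms + post_ms) / protocol.bin_ms))
    surface = np.full((protocol.n_freqs, protocol.n_intensities, n_bins),
                      preset.baseline_rate_hz, dtype=float)
    if not truth.is_responsive:
        return surface

    thr_f = _threshold_curve(truth, protocol)
    intensity = protocol.intensity_array[None, :]
    supra = intensity >= thr_f[:, None]
    evoked = np.where(
        supra,
        np.minimum(RATE_CAP_HZ,
                   preset.evoked_gain * (intensity - thr_f[:, None]
                                         + THRESHOLD_BUMP_DB)),
        0.0,
    )

    # fraction of each bin covered by the evoked window
    starts = -pre_ms + protocol.bin_ms * np.arange(n_bins)
    w0 = truth.true_latency_ms
    w1 = truth.true_latency_ms + protocol.tone_ms + EVOKED_TAIL_MS
    overlap = np.clip(np.minimum(starts + protocol.bin_ms, w1)
                      - np.maximum(starts, w0), 0.0, protocol.bin_ms)
    profile = overlap / protocol.bin_ms

    surface += evoked[:, :, None] * profile[None, None, :]
    return surface


def simulate_site(truth: SiteTruth,
                  protocol: StimulusProtocol,
                  preset: ConditionPreset,
                  rng: np.random.Generator,
                  *,
                  geometry: Optional[MapGeometry] = None,
                  pre_ms: float = 50.0,
                  post_ms: float = 100.0) -> SiteRecording:
    """Draw Poisson spike counts for one site under the stimulus protocol."""
    rate = expected_rate_surface(truth, protocol, preset,
                                 pre_ms=pre_ms, post_ms=post_ms)
    lam = rate * (protocol.bin_ms / 1000.0)
    shape = (protocol.n_freqs, protocol.n_intensities, protocol.n_trials,
             lam.shape[-1])
    counts = rng.poisson(np.broadcast_to(lam[:, :, None, :], shape)
                         ).astype(np.int16)
    g = geometry or MapGeometry("site", 0, 0.0, 0.0)
    return SiteRecording(site_id=g.site_id, x_um=g.x_um, y_um=g.y_um,
                         counts=counts, pre_ms=pre_ms, post_ms=post_ms,
                         penetration_id=g.penetration_id)


def animal_seed_sequences(master_seed: int, n_animals: int) -> list[np.random.SeedSequence]:
    """Deterministic per-animal seed sequences from one master seed."""
    return np.random.SeedSequence(master_seed).spawn(n_animals)


def simulate_animal(preset: ConditionPreset,
                    seed_seq: np.random.SeedSequence,
                    protocol: Optional[StimulusProtocol] = None,
                    **map_kwargs) -> tuple[list[tuple[MapGeometry, SiteTruth]],
                                           Iterator[SiteRecording]]:
    """Sample one animal's truth table and a lazy stream of its recordings."""
    if protocol is None:
        protocol = make_protocol()
    truth_rng = np.random.default_rng(seed_seq)
    sites = sample_map(preset, truth_rng, protocol, **map_kwargs)
    site_seqs = seed_seq.spawn(len(sites))

    def recordings() -> Iterator[SiteRecording]:
        for (g, t), ss in zip(sites, site_seqs):
            yield simulate_site(t, protocol, preset,
                                np.random.default_rng(ss), geometry=g)

    return sites, recordings()
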