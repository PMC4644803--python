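"""Dataset directory format and results writing.

A dataset directory holds:

* ``protocol.json`` — the stimulus protocol, recording window and a format
  version string;
* ``sites.csv`` — site_id, animal_id, group, penetration_id, x_um, y_um;
* ``spikes.csv`` — sparse long-format spike counts (only nonzero bins):
  site_id, freq_hz, intensity_db, trial, bin_ms_offset, count.  Bin offsets
  are bin start times in ms relative to tone onset; baseline bins are
  negative.  Dense reconstruction fills every absent (freq, intensity, trial,
  bin) with zero;
* optional ``truth.csv`` — generator ground truth, one row per site.

All files are UTF-8 CSV/JSON; missing values are empty cells.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import IntegrityError, TonomapError, ValidationError
from .protocol import StimulusProtocol
from .recording import SiteRecording

FORMAT_VERSION = "1.0"

SITES_COLUMNS = ["site_id", "animal_id", "group", "penetration_id",
                 "x_um", "y_um"]
SPIKES_COLUMNS = ["site_id", "freq_hz", "intensity_db", "trial",
                  "bin_ms_offset", "count"]


@dataclass
class Dataset:
    """In-memory view of a dataset directory."""

    protocol: StimulusProtocol
    sites: pd.DataFrame
    spikes: pd.DataFrame
    truth: Optional[pd.DataFrame] = None
    pre_ms: float = 50.0
    post_ms: float = 100.0

    @property
    def animal_ids(self) -> list[str]:
        return list(dict.fromkeys(self.sites["animal_id"]))

    def recordings(self, animal_id: str) -> Iterator[SiteRecording]:
        """Densely reconstructed recordings for one animal, in sites order."""
        p = self.protocol
        n_bins = int(round((self.pre_ms + self.post_ms) / p.bin_ms))
        freqs = p.freq_array
        rows = self.sites[self.sites["animal_id"] == animal_id]
        by_site = dict(tuple(self.spikes.groupby("site_id", sort=False)))
        for _, s in rows.iterrows():
            counts = np.zeros((p.n_freqs, p.n_intensities, p.n_trials, n_bins),
                              dtype=np.int32)
            sub = by_site.get(s["site_id"])
            if sub is not None and len(sub):
                fi = np.searchsorted(freqs, sub["freq_hz"].to_numpy() * (1 - 1e-12))
                fi = np.clip(fi, 0, p.n_freqs - 1)
                # snap to nearest of the two candidates
                lower = np.clip(fi - 1, 0, p.n_freqs - 1)
                pick_lower = (np.abs(freqs[lower] - sub["freq_hz"].to_numpy())
                              < np.abs(freqs[fi] - sub["freq_hz"].to_numpy()))
                fi = np.where(pick_lower, lower, fi)
                ii = np.searchsorted(p.intensity_array,
                                     sub["intensity_db"].to_numpy() - 1e-9)
                ti = sub["trial"].to_numpy(dtype=int)
                bi = np.round((sub["bin_ms_offset"].to_numpy() + self.pre_ms)
                              / p.bin_ms).astype(int)
                counts[fi, ii, ti, bi] = sub["count"].to_numpy(dtype=int)
            yield SiteRecording(
                site_id=str(s["site_id"]), x_um=float(s["x_um"]),
                y_um=float(s["y_um"]), counts=counts, pre_ms=self.pre_ms,
                post_ms=self.post_ms, penetration_id=int(s["penetration_id"]),
                animal_id=str(s["animal_id"]), group=str(s["group"]))


def write_dataset(ds: Dataset, path: str | Path, overwrite: bool = False
                  ) -> Path:
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise TonomapError(f"output directory {path} exists and is not empty "
                           "(pass overwrite=True to replace)")
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "protocol": ds.protocol.to_dict(),
        "window_ms": {"pre": ds.pre_ms, "post": ds.post_ms},
    }
    with open(path / "protocol.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    ds.sites.to_csv(path / "sites.csv", index=False)
    ds.spikes.to_csv(path / "spikes.csv", index=False)
    if ds.truth is not None:
        ds.truth.to_csv(path / "truth.csv", index=False)
    return path


def _check_grid(values: np.ndarray, grid: np.ndarray, label: str,
                log_scale: bool = False) -> None:
    v = np.unique(values)
    if log_scale:
        ok = np.array([np.min(np.abs(np.log2(grid / x))) < 1e-9 for x in v])
    else:
        ok = np.array([np.min(np.abs(grid - x)) < 1e-6 for x in v])
    if not ok.all():
        bad = v[~ok][0]
        raise IntegrityError(f"spikes.csv: {label} {bad} is not on the "
                             "protocol grid")


def read_dataset(path: str | Path) -> Dataset:
    """Load and validate a dataset directory.

    Checks the format version, referential integrity (every spike row must
    reference a site) and that every stimulus lies on the protocol grid.
    """
    path = Path(path)
    for fname in ("protocol.json", "sites.csv", "spikes.csv"):
        if not (path / fname).exists():
            raise IntegrityError(f"dataset at {path}: missing {fname}")
    with open(path / "protocol.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    version = str(meta.get("format_version", ""))
    if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise IntegrityError(
            f"protocol.json: unsupported format version {version!r}")
    protocol = StimulusProtocol.from_dict(meta["protocol"])
    window = meta.get("window_ms", {"pre": 50.0, "post": 100.0})

    sites = pd.read_csv(path / "sites.csv")
    missing = set(SITES_COLUMNS) - set(sites.columns)
    if missing:
        raise IntegrityError(f"sites.csv: missing columns {sorted(missing)}")
    spikes = pd.read_csv(path / "spikes.csv")
    missing = set(SPIKES_COLUMNS) - set(spikes.columns)
    if missing:
        raise IntegrityError(f"spikes.csv: missing columns {sorted(missing)}")

    known = set(sites["site_id"])
    orphan = ~spikes["site_id"].isin(known)
    if orphan.any():
        row = int(np.flatnonzero(orphan.to_numpy())[0]) + 2  # 1-based + header
        raise IntegrityError(
            f"spikes.csv row {row}: unknown site_id "
            f"{spikes.loc[orphan.idxmax(), 'site_id']!r}")
    if len(spikes):
        counts = spikes["count"].to_numpy()
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise IntegrityError("spikes.csv: counts must be non-negative integers")
        _check_grid(spikes["freq_hz"].to_numpy(dtype=float),
                    protocol.freq_array, "frequency", log_scale=True)
        _check_grid(spikes["intensity_db"].to_numpy(dtype=float),
                    protocol.intensity_array, "intensity")
        trials = spikes["trial"].to_numpy(dtype=int)
        if trials.min() < 0 or trials.max() >= protocol.n_trials:
            raise IntegrityError("spikes.csv: trial index outside the protocol")

    truth = None
    if (path / "truth.csv").exists():
        truth = pd.read_csv(path / "truth.csv")

    return Dataset(protocol=protocol, sites=sites, spikes=spikes, truth=truth,
                   pre_ms=float(window["pre"]), post_ms=float(window["post"]))


def recording_to_sparse(rec: SiteRecording, protocol: StimulusProtocol
                        ) -> pd.DataFrame:
    """Long-format nonzero spike counts for one recording."""
    counts = np.asarray(rec.counts)
    f, i, t, b = np.nonzero(counts)
    offsets = rec.bin_offsets_ms(protocol.bin_ms)
    return pd.DataFrame({
        "site_id": rec.site_id,
        "freq_hz": protocol.freq_array[f],
        "intensity_db": protocol.intensity_array[i],
        "trial": t,
        "bin_ms_offset": offsets[b],
        "count": counts[f, i, t, b],
    })


def write_results(out_path: str | Path,
                  site_metrics: pd.DataFrame,
                  map_summary: pd.DataFrame,
                  animal_summaries: pd.DataFrame,
                  comparisons: pd.DataFrame,
                  config: RunConfig,
                  log_lines: Optional[list[str]] = None) -> Path:
    """Write the standard result files to ``out_path``.

    Emits site_metrics.csv, map_summary.csv, animal_summaries.csv,
    group_comparisons.csv, the resolved config.json and run.log.  Missing
    values become empty cells; reruns on identical inputs are byte-identical
    (the log carries no timestamps).
    """
    out = Path(out_path)
    if out.exists() and not out.is_dir():
        raise TonomapError(f"output path {out} is not a directory")
    out.mkdir(parents=True, exist_ok=True)
    site_metrics.to_csv(out / "site_metrics.csv", index=False)
    map_summary.to_csv(out / "map_summary.csv", index=False)
    animal_summaries.to_csv(out / "animal_summaries.csv", index=False)
    comparisons.to_csv(out / "group_comparisons.csv", index=False)
    config.to_json(out / "config.json")
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        for line in log_lines or []:
            fh.write(line.rstrip("\n") + "\n")
    return out
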