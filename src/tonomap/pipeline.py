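"""End-to-end pipelines: simulate cohorts, analyze datasets, compare groups.

Two execution paths share the same per-site analysis:

* disk path — ``generate_cohort`` writes a dataset directory which
  ``analyze_dataset`` reads back (what the CLI uses);
* streaming path — ``simulate_cohort_analysis`` analyzes each simulated site
  as it is drawn and keeps only the metrics, so large cohorts never
  materialize their spike tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cohort import AnimalSummary, comparison_table, summarize_animal
from .config import RunConfig
from .errors import TonomapError
from .io import Dataset, recording_to_sparse, write_dataset, write_results
from .protocol import StimulusProtocol, make_protocol
from .receptive_field import SiteMetrics, analyze_site
from .recording import SiteRecording
from .synth import (ConditionPreset, MapGeometry, PRESETS, SiteTruth,
                    simulate_animal, simulate_site)
from .tonotopy import TonotopyResult, compute_tonotopy, delineate_ai

METRIC_COLUMNS = ["site_id", "animal_id", "group", "penetration_id", "x_um",
                  "y_um", "responsive", "cf_hz", "threshold_db", "bw10_oct",
                  "latency_ms", "irregularity", "shape", "max_sig_db",
                  "in_ai"]


@dataclass
class AnimalResult:
    animal_id: str
    group: str
    metrics: pd.DataFrame
    tonotopy: Optional[TonotopyResult]
    summary: AnimalSummary


@dataclass
class CohortResult:
    site_metrics: pd.DataFrame
    map_summary: pd.DataFrame
    animal_summaries: pd.DataFrame
    comparisons: pd.DataFrame
    animals: list[AnimalResult] = field(default_factory=list)


def _metrics_row(m: SiteMetrics, rec: SiteRecording, animal_id: str,
                 group: str) -> dict:
    return {
        "site_id": m.site_id, "animal_id": animal_id, "group": group,
        "penetration_id": rec.penetration_id, "x_um": rec.x_um,
        "y_um": rec.y_um, "responsive": m.responsive, "cf_hz": m.cf_hz,
        "threshold_db": m.threshold_db, "bw10_oct": m.bw10_oct,
        "latency_ms": m.latency_ms, "irregularity": m.irregularity,
        "shape": m.shape, "max_sig_db": m.max_sig_db, "in_ai": m.in_ai,
    }


def analyze_animal(recordings: Iterable[SiteRecording],
                   protocol: StimulusProtocol, animal_id: str, group: str,
                   config: Optional[RunConfig] = None) -> AnimalResult:
    """Per-site metrics, AI delineation, tonotopy and summary for one animal."""
    config = config or RunConfig()
    rows = []
    for rec in recordings:
        m = analyze_site(rec, protocol, config)
        rows.append(_metrics_row(m, rec, animal_id, group))
    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    ai_mask = delineate_ai(metrics, config)
    metrics["in_ai"] = ai_mask
    tono = compute_tonotopy(metrics, ai_mask, config)
    summary = summarize_animal(
        metrics, animal_id, group,
        tonotopic_index=tono.tonotopic_index if tono else None,
        config=config)
    return AnimalResult(animal_id, group, metrics, tono, summary)


def _collect(results: list[AnimalResult]) -> CohortResult:
    site_metrics = pd.concat([r.metrics for r in results], ignore_index=True) \
        if results else pd.DataFrame(columns=METRIC_COLUMNS)
    map_rows = []
    for r in results:
        map_rows.append({
            "animal_id": r.animal_id, "group": r.group,
            "n_sites": len(r.metrics),
            "n_responsive": int(r.metrics["responsive"].astype(bool).sum()),
            "n_ai": int(r.metrics["in_ai"].fillna(False).astype(bool).sum()),
            "tonotopic_index": r.tonotopy.tonotopic_index if r.tonotopy
            else float("nan"),
        })
    map_summary = pd.DataFrame(map_rows)
    summaries = pd.DataFrame([r.summary.to_row() for r in results])
    groups = list(dict.fromkeys(summaries["group"])) if len(summaries) else []
    if len(groups) == 2:
        comparisons = comparison_table(summaries)
    else:
        comparisons = pd.DataFrame(
            columns=["metric", "group_a", "group_b", "mean_a", "mean_b",
                     "sem_a", "sem_b", "n_a", "n_b", "t", "df", "p"])
    return CohortResult(site_metrics, map_summary, summaries, comparisons,
                        animals=results)


def analyze_dataset(ds: Dataset, config: Optional[RunConfig] = None
                    ) -> CohortResult:
    """Analyze every animal in a loaded dataset."""
    config = config or RunConfig()
    results = []
    for animal_id in ds.animal_ids:
        group = str(ds.sites.loc[ds.sites["animal_id"] == animal_id,
                                 "group"].iloc[0])
        results.append(analyze_animal(ds.recordings(animal_id), ds.protocol,
                                      animal_id, group, config))
    return _collect(results)


def generate_cohort(n_control: int, n_vpa: int, seed: int,
                    out_dir: Optional[str | Path] = None,
                    presets: Optional[dict[str, ConditionPreset]] = None,
                    protocol: Optional[StimulusProtocol] = None,
                    overwrite: bool = False,
                    **map_kwargs) -> Dataset:
    """Simulate a two-group cohort; optionally write it as a dataset directory.

    Animals are named ``<group><index>``; per-animal seeds derive
    deterministically from the master seed, so identical seeds give
    byte-identical datasets.
    """
    if n_control < 0 or n_vpa < 0 or n_control + n_vpa == 0:
        raise TonomapError("cohort must contain at least one animal")
    presets = presets or PRESETS
    protocol = protocol or make_protocol()
    plan = [("control", i, presets["control"]) for i in range(n_control)] \
        + [("vpa", i, presets["vpa"]) for i in range(n_vpa)]
    seqs = np.random.SeedSequence(seed).spawn(len(plan))

    site_rows, truth_rows, spike_frames = [], [], []
    for (group, idx, preset), ss in zip(plan, seqs):
        animal_id = f"{group}{idx + 1}"
        sites, recs = simulate_animal(preset, ss, protocol, **map_kwargs)
        for (g, t), rec in zip(sites, recs):
            site_rows.append({
                "site_id": f"{animal_id}_{g.site_id}", "animal_id": animal_id,
                "group": group, "penetration_id": g.penetration_id,
                "x_um": g.x_um, "y_um": g.y_um})
            truth_rows.append({
                "site_id": f"{animal_id}_{g.site_id}", "animal_id": animal_id,
                "group": group, "is_ai": t.is_ai,
                "is_responsive": t.is_responsive, "true_shape": t.true_shape,
                "true_cf_hz": t.true_cf_hz, "true_thr_db": t.true_thr_db,
                "true_bw10_oct": t.true_bw10_oct,
                "true_latency_ms": t.true_latency_ms,
                "true_cf2_hz": t.true_cf2_hz, "true_thr2_db": t.true_thr2_db,
                "true_flat_span_oct": t.true_flat_span_oct})
            rec.site_id = f"{animal_id}_{g.site_id}"
            rec.animal_id = animal_id
            rec.group = group
            spike_frames.append(recording_to_sparse(rec, protocol))

    ds = Dataset(
        protocol=protocol,
        sites=pd.DataFrame(site_rows),
        spikes=pd.concat(spike_frames, ignore_index=True) if spike_frames
        else pd.DataFrame(columns=["site_id", "freq_hz", "intensity_db",
                                   "trial", "bin_ms_offset", "count"]),
        truth=pd.DataFrame(truth_rows))
    if out_dir is not None:
        write_dataset(ds, out_dir, overwrite=overwrite)
    return ds


def simulate_cohort_analysis(n_control: int, n_vpa: int, seed: int,
                             presets: Optional[dict[str, ConditionPreset]] = None,
                             protocol: Optional[StimulusProtocol] = None,
                             config: Optional[RunConfig] = None,
                             **map_kwargs
                             ) -> tuple[CohortResult, pd.DataFrame]:
    """Streaming simulate-and-analyze; returns results plus the truth table.

    Spike counts are analyzed site by site and discarded, so memory stays flat
    regardless of cohort size.  Seeding matches :func:`generate_cohort`.
    """
    presets = presets or PRESETS
    protocol = protocol or make_protocol()
    config = config or RunConfig(seed=seed)
    plan = [("control", i, presets["control"]) for i in range(n_control)] \
        + [("vpa", i, presets["vpa"]) for i in range(n_vpa)]
    seqs = np.random.SeedSequence(seed).spawn(len(plan))

    results, truth_rows = [], []
    for (group, idx, preset), ss in zip(plan, seqs):
        animal_id = f"{group}{idx + 1}"
        sites, recs = simulate_animal(preset, ss, protocol, **map_kwargs)
        rows = []
        for (g, t), rec in zip(sites, recs):
            rec.site_id = f"{animal_id}_{g.site_id}"
            m = analyze_site(rec, protocol, config)
            rows.append(_metrics_row(m, rec, animal_id, group))
            truth_rows.append({
                "site_id": rec.site_id, "animal_id": animal_id,
                "group": group, "is_ai": t.is_ai,
                "is_responsive": t.is_responsive, "true_shape": t.true_shape,
                "true_cf_hz": t.true_cf_hz, "true_thr_db": t.true_thr_db,
                "true_bw10_oct": t.true_bw10_oct,
                "true_latency_ms": t.true_latency_ms})
        metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)
        ai_mask = delineate_ai(metrics, config)
        metrics["in_ai"] = ai_mask
        tono = compute_tonotopy(metrics, ai_mask, config)
        summary = summarize_animal(
            metrics, animal_id, group,
            tonotopic_index=tono.tonotopic_index if tono else None,
            config=config)
        results.append(AnimalResult(animal_id, group, metrics, tono, summary))
    return _collect(results), pd.DataFrame(truth_rows)


def run_demo(out_dir: str | Path, seed: int = 0,
             config: Optional[RunConfig] = None) -> CohortResult:
    """Seeded 2-vs-2 miniature cohort, generated, analyzed and written."""
    out = Path(out_dir)
    config = config or RunConfig(seed=seed)
    ds = generate_cohort(2, 2, seed, out_dir=out / "dataset", overwrite=True)
    result = analyze_dataset(ds, config)
    log = [f"demo cohort: 2 control vs 2 vpa animals, seed {seed}",
           f"sites analyzed: {len(result.site_metrics)}"]
    write_results(out / "results", result.site_metrics, result.map_summary,
                  result.animal_summaries, result.comparisons, config,
                  log_lines=log)
    return result
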