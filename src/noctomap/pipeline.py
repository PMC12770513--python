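"""End-to-end pipeline: simulate/load -> detect -> classify -> sleep-score ->
cardio -> stats, with all outputs written as CSV/JSON plus a Markdown report.

Every tunable constant lives in :class:`PipelineConfig` and defaults to the
value used throughout the analysis (20/15 mg thresholds, 0.5 s merge gap,
5 s / 5 deg / 5 min sleep constants, -19..+40 s response window with a
-19..-9 s baseline, 30 s isolation, 10 s artifact cut, 30 deg postural
angle, -0.66 g upright rule). A run is reproducible from its archived
config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cardio, detection, sleep, stats, synthetic, taxonomy
from .io_sync import DiaryRecord, Segment, TriaxialRecording, read_diary, read_recording
from .synthetic import NightDataset, SimConfig

log = logging.getLogger("noctomap")


@dataclass
class PipelineConfig:
    threshold_wrist_mg: float = 20.0
    threshold_ankle_mg: float = 15.0
    threshold_trunk_mg: float = 15.0
    band_low_hz: float = 0.1
    band_high_hz: float = 10.0
    envelope_group_window_s: float = 1.0
    merge_gap_s: float = 0.5
    sleep_epoch_s: float = 5.0
    sleep_angle_deg: float = 5.0
    sleep_min_bout_s: float = 300.0
    cardio_window_s: tuple[float, float] = (-19.0, 40.0)
    baseline_s: tuple[float, float] = (-19.0, -9.0)
    isolation_s: float = 30.0
    artifact_cut_s: float = 10.0
    peak_search_s: tuple[float, float] = (0.0, 40.0)
    postural_angle_deg: float = 30.0
    upright_threshold_g: float = -0.66
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def threshold_for(self, seg: Segment) -> float:
        if seg in (Segment.LW, Segment.RW):
            return self.threshold_wrist_mg
        if seg in (Segment.LA, Segment.RA):
            return self.threshold_ankle_mg
        return self.threshold_trunk_mg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        if sim_raw:
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            cfg.sim = SimConfig(**{k: v for k, v in sim_raw.items() if k in sim_known})
        return cfg


def analyze_night(ds: NightDataset, cfg: PipelineConfig,
                  subject: str = "s0") -> dict:
    """Run the full single-night analysis on an in-memory dataset.

    Returns a dict of DataFrames / objects: detected bursts, composites,
    sleep labels and metrics, event-locked matrices, response tables.
    """
    # movement detection per segment
    per_segment: dict[Segment, list[detection.MovementBurst]] = {}
    for seg, rec in ds.recordings.items():
        per_segment[seg] = detection.detect_segment(
            rec, threshold_mg=cfg.threshold_for(seg),
            band=(cfg.band_low_hz, cfg.band_high_hz),
            group_window=cfg.envelope_group_window_s,
            merge_gap=cfg.merge_gap_s)

    # sleep scoring on the non-dominant wrist
    wrist = ds.recordings[ds.diary.nondominant_wrist]
    sw_series, sw_metrics = sleep.score_night(
        wrist, ds.diary,
        angle_threshold=cfg.sleep_angle_deg,
        min_bout=cfg.sleep_min_bout_s,
        epoch_len=cfg.sleep_epoch_s)

    # composites, posture, state tagging
    trunk = ds.recordings.get(Segment.T)
    upright = taxonomy.detect_upright(trunk, threshold_g=cfg.upright_threshold_g) \
        if trunk is not None else []
    composites = taxonomy.merge_segments(per_segment, min_gap=cfg.merge_gap_s)
    composites = taxonomy.annotate(
        composites, trunk, state_lookup=sw_series.state_at,
        dspt_midpoint=ds.diary.midpoint, upright_intervals=upright)

    exposure = sleep.exposure_hours(sw_series)
    summary = taxonomy.summarize(composites, exposure)
    halves = taxonomy.half_indices(
        composites, (ds.diary.duration / 7200.0, ds.diary.duration / 7200.0))

    # cardio
    hr = cardio.hr_from_rpeaks(ds.r_peak_times)
    pwa = cardio.pwa_from_fiducials(ds.ppg_peak_t, ds.ppg_peak_amp,
                                    ds.ppg_foot_t, ds.ppg_foot_amp)
    discarded = hr.discarded_intervals + pwa.discarded_intervals
    isolated = cardio.select_isolated(composites, isolation_s=cfg.isolation_s,
                                      discarded_intervals=discarded,
                                      window=cfg.cardio_window_s)
    locked = {}
    tables = {}
    for kind, series in (("hr", hr), ("pwa", pwa)):
        m = cardio.event_lock(series, isolated, window=cfg.cardio_window_s,
                              baseline=cfg.baseline_s)
        m.meta["subject"] = subject
        locked[kind] = m
        tables[kind] = cardio.response_table(m, search=cfg.peak_search_s)

    event_cols = ["subject", "onset", "category", "state", "magnitude_mg",
                  "hr_peak_pct", "hr_peak_latency_s", "pwa_trough_pct",
                  "pwa_trough_latency_s"]
    if len(tables["hr"]) and len(tables["pwa"]):
        events = tables["hr"].rename(columns={
            "peak_pct": "hr_peak_pct", "peak_latency_s": "hr_peak_latency_s"})
        events = events[["subject", "onset", "category", "state", "magnitude_mg",
                         "hr_peak_pct", "hr_peak_latency_s"]]
        pw = tables["pwa"].rename(columns={
            "trough_pct": "pwa_trough_pct",
            "trough_latency_s": "pwa_trough_latency_s"})
        events = events.merge(
            pw[["onset", "pwa_trough_pct", "pwa_trough_latency_s"]],
            on="onset", how="inner")
    else:
        events = pd.DataFrame(columns=event_cols)

    return {
        "per_segment": per_segment,
        "composites": composites,
        "sleep_series": sw_series,
        "sleep_metrics": sw_metrics,
        "summary": summary,
        "halves": halves,
        "upright": upright,
        "hr": hr, "pwa": pwa,
        "isolated": isolated,
        "locked": locked,
        "events": events,
    }


def load_night(in_dir: str | Path) -> NightDataset:
    """Load a night previously written by :func:`synthetic.write_night`."""
    d = Path(in_dir)
    recordings = {seg: read_recording(d / f"acc_{seg.value}.csv", seg)
                  for seg in Segment}
    r = pd.read_csv(d / "r_peaks.csv")["time"].to_numpy()
    ppg = pd.read_csv(d / "ppg_fiducials.csv")
    diary = read_diary(d / "diary.json")
    return NightDataset(config=SimConfig(), recordings=recordings,
                        r_peak_times=r,
                        ppg_peak_t=ppg["peak_t"].to_numpy(),
                        ppg_peak_amp=ppg["peak_amp"].to_numpy(),
                        ppg_foot_t=ppg["foot_t"].to_numpy(),
                        ppg_foot_amp=ppg["foot_amp"].to_numpy(),
                        diary=diary, events=[], wake_bouts=[], upright_bouts=[])


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 simulate: bool = True, in_dir: str | Path | None = None,
                 n_subjects: int = 1) -> Path:
    """Full run producing the table/curve analogues; returns the run dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    cfg_dict = cfg.to_dict()
    cfg_text = json.dumps(cfg_dict, sort_keys=True, default=str)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:12]
    log.info("noctomap %s run, config hash %s, seed %d",
             __version__, cfg_hash, cfg.seed)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg_dict, default_flow_style=None))

    all_events = []
    all_comps = []
    summaries = []
    hr_curves = pwa_curves = None
    locked_hr = []
    locked_pwa = []
    sleep_rows = []
    for s in range(n_subjects):
        subject = f"s{s}"
        if simulate:
            sim = dataclasses.replace(cfg.sim, seed=cfg.seed + s)
            ds = synthetic.generate_night(sim)
        else:
            if in_dir is None:
                raise ValueError("in_dir required when not simulating")
            ds = load_night(in_dir)
        res = analyze_night(ds, cfg, subject=subject)
        all_events.append(res["events"])
        df = taxonomy.composites_to_frame(res["composites"])
        df["subject"] = subject
        all_comps.append(df)
        sm = res["sleep_metrics"]
        sleep_rows.append({"subject": subject, **dataclasses.asdict(sm)})
        locked_hr.append(res["locked"]["hr"])
        locked_pwa.append(res["locked"]["pwa"])
        summ = res["summary"]
        summ["subject"] = subject
        summaries.append(summ)

    events = pd.concat(all_events, ignore_index=True)
    comps = pd.concat(all_comps, ignore_index=True)
    summary = pd.concat(summaries, ignore_index=True)
    comps.to_csv(out / "movements.csv", index=False)
    events.to_csv(out / "events.csv", index=False)
    pd.DataFrame(sleep_rows).to_csv(out / "sleep.csv", index=False)
    summary.to_csv(out / "summary.csv", index=False)
    summary.groupby(["state", "category"], sort=False)[
        ["index_per_h", "mean_duration_s", "mean_magnitude_mg"]
    ].mean().reset_index().to_json(out / "summary.json", orient="records", indent=1)

    def _stack(mats):
        mats = [m for m in mats if m.n_events > 0]
        if not mats:
            return None
        rows = np.vstack([m.rows for m in mats])
        meta = pd.concat([m.meta for m in mats], ignore_index=True)
        return cardio.EventLockedMatrix(kind=mats[0].kind, grid=mats[0].grid,
                                        rows=rows, meta=meta)

    models = pd.DataFrame()
    for kind, mats in (("hr", locked_hr), ("pwa", locked_pwa)):
        big = _stack(mats)
        if big is None:
            continue
        wide = pd.concat([big.meta.reset_index(drop=True),
                          pd.DataFrame(big.rows, columns=[f"t{int(t)}" for t in big.grid])],
                         axis=1)
        wide.to_csv(out / f"eventlocked_{kind}.csv", index=False)
        if big.meta["subject"].nunique() >= 2:
            ga = cardio.grand_average(big)
            ga.to_csv(out / f"grandavg_{kind}.csv", index=False)
            if kind == "hr":
                hr_curves = ga
            else:
                pwa_curves = ga
    if len(events) >= 3:
        models = stats.correlation_report(events)
        models.to_csv(out / "models.csv", index=False)
        models.to_json(out / "models.json", orient="records", indent=1)

    _write_report(out, cfg_hash, cfg, summary, pd.DataFrame(sleep_rows),
                  events, hr_curves, pwa_curves, models)
    return out


def _write_report(out: Path, cfg_hash: str, cfg: PipelineConfig,
                  summary: pd.DataFrame, sleep_df: pd.DataFrame,
                  events: pd.DataFrame, hr_curves, pwa_curves,
                  models: pd.DataFrame) -> None:
    lines = ["# noctomap run report", "",
             f"version {__version__}, config hash `{cfg_hash}`, seed {cfg.seed}", ""]
    lines += ["## Sleep metrics", "", sleep_df.round(2).to_markdown(index=False), ""]
    agg = summary.groupby(["state", "category"], sort=False)[
        ["index_per_h", "mean_duration_s", "mean_magnitude_mg"]].mean().round(2)
    lines += ["## Movement metrics (mean across subjects)", "",
              agg.reset_index().to_markdown(index=False), ""]
    if len(events):
        topo = events.groupby(["category", "state"]).size().rename("n").reset_index()
        lines += ["## Isolated movements entering cardio analysis", "",
                  topo.to_markdown(index=False), ""]
    for name, ga in (("HR", hr_curves), ("PWA", pwa_curves)):
        if ga is None:
            continue
        post = ga[ga["t"] >= 0]
        lines += [f"## {name} grand average",
                  "",
                  f"peak {post['mean_pct'].max():+.1f}% at "
                  f"{post.loc[post['mean_pct'].idxmax(), 't']:.0f} s; "
                  f"trough {post['mean_pct'].min():+.1f}% at "
                  f"{post.loc[post['mean_pct'].idxmin(), 't']:.0f} s", ""]
    if len(models):
        lines += ["## Mixed-model correlation table", "",
                  models.round(3).to_markdown(index=False), ""]
    (out / "report.md").write_text("\n".join(lines))
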