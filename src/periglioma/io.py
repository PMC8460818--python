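"""Reading and writing of cohort artifacts and result tables.

Cohort directories contain plain CSV tables (subjects, volumes,
progression, peritumoral locations, atlas), a JSON ground-truth file
when the cohort is synthetic, and an HDF5 container with one
regions x samples dataset per subject.  Result tables are written as
CSV with a fixed float format so that identical runs produce
byte-identical files, plus a human-readable markdown report.
"""

from __future__ import annotations

import json
import os
from typing import Dict

import h5py
import numpy as np
import pandas as pd
import yaml

from .atlas import RegionAtlas
from .cohort import Cohort, CohortConfig
from .regional import PeritumoralSelection
from .spectral import RegionalTimeSeries
from .volumetrics import VolumeSeries

__all__ = ["write_cohort", "write_report", "load_cohort_dir", "DiskCohort",
           "load_cohort_config", "write_timeseries_h5",
           "read_timeseries_h5"]

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# Cohort artifacts
# ---------------------------------------------------------------------------

def write_timeseries_h5(path: str, series: Dict[str, RegionalTimeSeries]
                        ) -> None:
    """One dataset per subject with sampling-rate/region-id attributes."""
    with h5py.File(path, "w") as f:
        for sid, ts in series.items():
            d = f.create_dataset(sid, data=ts.data)
            d.attrs["sampling_rate"] = ts.sampling_rate
            if ts.region_ids is not None:
                d.attrs["region_ids"] = [str(r) for r in ts.region_ids]


def read_timeseries_h5(path: str) -> Dict[str, RegionalTimeSeries]:
    out = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            d = f[sid]
            region_ids = [r.decode() if isinstance(r, bytes) else str(r)
                          for r in d.attrs.get("region_ids", [])] or None
            out[sid] = RegionalTimeSeries(
                sid, d[()], float(d.attrs["sampling_rate"]),
                region_ids=region_ids)
    return out


def _atlas_frame(atlas: RegionAtlas) -> pd.DataFrame:
    return pd.DataFrame({
        "region_id": atlas.region_ids,
        "hemisphere": atlas.hemispheres,
        "x": atlas.centroids[:, 0],
        "y": atlas.centroids[:, 1],
        "z": atlas.centroids[:, 2],
        "homologue_id": [atlas.region_ids[h] for h in atlas.homologues]})


def _atlas_from_frame(df: pd.DataFrame) -> RegionAtlas:
    ids = tuple(df["region_id"])
    index = {r: i for i, r in enumerate(ids)}
    return RegionAtlas(
        ids, df["hemisphere"].to_numpy(),
        df[["x", "y", "z"]].to_numpy(dtype=float),
        np.array([index[r] for r in df["homologue_id"]], dtype=int))


def write_cohort(cohort: Cohort, out_dir: str,
                 write_timeseries: bool = True) -> None:
    """Persist a cohort: CSV tables, ground truth JSON, optional HDF5."""
    os.makedirs(out_dir, exist_ok=True)
    j = os.path.join
    cohort.subjects.to_csv(j(out_dir, "subjects.csv"), index=False,
                           float_format=_FLOAT_FMT)
    vol_rows = [{"subject_id": sid, "scan_day": d, "volume_ml": v,
                 "meg_day": s.meg_day}
                for sid, s in cohort.volumes.items()
                for d, v in zip(s.scan_days, s.volumes)]
    pd.DataFrame(vol_rows, columns=["subject_id", "scan_day", "volume_ml",
                                    "meg_day"]).to_csv(
        j(out_dir, "volumes.csv"), index=False, float_format=_FLOAT_FMT)
    cohort.progression.to_csv(j(out_dir, "progression.csv"), index=False,
                              float_format=_FLOAT_FMT)
    _atlas_frame(cohort.atlas).to_csv(j(out_dir, "atlas.csv"), index=False,
                                      float_format=_FLOAT_FMT)
    loc_rows = [{"subject_id": sid,
                 "region_id": cohort.atlas.region_ids[idx],
                 "x": xyz[0], "y": xyz[1], "z": xyz[2],
                 "tumor_x": sel.tumor_centroid[0],
                 "tumor_y": sel.tumor_centroid[1],
                 "tumor_z": sel.tumor_centroid[2],
                 "tumor_radius_mm": sel.tumor_radius_mm,
                 "max_distance": sel.max_distance}
                for sid, sel in cohort.peritumoral.items()
                for idx, xyz in zip(sel.region_indices, sel.coordinates)]
    pd.DataFrame(loc_rows, columns=[
        "subject_id", "region_id", "x", "y", "z", "tumor_x", "tumor_y",
        "tumor_z", "tumor_radius_mm", "max_distance"]).to_csv(
        j(out_dir, "locations.csv"), index=False, float_format=_FLOAT_FMT)

    gt = cohort.ground_truth
    gt_json = {
        "config": cohort.config.to_dict(),
        "subject_ids": gt.subject_ids,
        "offsets": gt.offsets.tolist(),
        "slopes": gt.slopes.tolist(),
        "knees": gt.knees.tolist(),
        "alpha": {sid: {k: float(v) for k, v in row.items()}
                  for sid, row in gt.alpha.iterrows()},
        "artifact_epochs": {sid: np.asarray(lab).astype(int).tolist()
                            for sid, lab in gt.artifact_epochs.items()},
        "archetypes": gt.archetypes,
        "hazard_multiplier": {k: float(v)
                              for k, v in gt.hazard_multiplier.items()},
    }
    with open(j(out_dir, "ground_truth.json"), "w") as f:
        json.dump(gt_json, f, indent=1, sort_keys=True)
    if write_timeseries:
        write_timeseries_h5(j(out_dir, "timeseries.h5"),
                            {sid: cohort.timeseries(sid)
                             for sid in cohort.subject_ids})


class _LoadedConfig(dict):
    """Dict-backed stand-in for CohortConfig on loaded real data."""

    def __getattr__(self, name):
        try:
            return self[name]
        except KeyError as err:
            raise AttributeError(name) from err

    def to_dict(self):
        return dict(self)


class DiskCohort:
    """Cohort interface backed by a directory of input files.

    Exposes the same surface :func:`~periglioma.pipeline.analyze_cohort`
    needs from a synthetic cohort: ``subjects``, ``atlas``,
    ``peritumoral``, ``volumes``, ``progression``, ``config`` and
    ``timeseries(subject_id)``.
    """

    def __init__(self, directory: str):
        j = os.path.join
        self.directory = directory
        self.subjects = pd.read_csv(j(directory, "subjects.csv"))
        self.atlas = _atlas_from_frame(pd.read_csv(j(directory,
                                                     "atlas.csv")))
        vols = pd.read_csv(j(directory, "volumes.csv"))
        self.volumes = {}
        for sid, sub in vols.groupby("subject_id"):
            sub = sub.sort_values("scan_day")
            self.volumes[sid] = VolumeSeries(
                sid, sub["scan_day"].to_numpy(),
                sub["volume_ml"].to_numpy(),
                int(sub["meg_day"].iloc[0]))
        prog_path = j(directory, "progression.csv")
        self.progression = pd.read_csv(prog_path) \
            if os.path.exists(prog_path) else pd.DataFrame(
                columns=["subject_id", "time_weeks", "event"])
        self.peritumoral = self._load_locations(j(directory,
                                                  "locations.csv"))
        self._h5_path = j(directory, "timeseries.h5")
        cfg = {"seed": None, "epoch_duration": 13.1,
               "source": os.path.abspath(directory)}
        gt_path = j(directory, "ground_truth.json")
        if os.path.exists(gt_path):
            with open(gt_path) as f:
                stored = json.load(f).get("config", {})
            cfg.update(stored)
        self.config = _LoadedConfig(cfg)

    def _load_locations(self, path: str) -> Dict[str, PeritumoralSelection]:
        if not os.path.exists(path):
            return {}
        df = pd.read_csv(path)
        index = {r: i for i, r in enumerate(self.atlas.region_ids)}
        out = {}
        for sid, sub in df.groupby("subject_id"):
            out[sid] = PeritumoralSelection(
                subject_id=sid,
                region_indices=np.array([index[r]
                                         for r in sub["region_id"]]),
                coordinates=sub[["x", "y", "z"]].to_numpy(dtype=float),
                tumor_centroid=sub[["tumor_x", "tumor_y",
                                    "tumor_z"]].iloc[0].to_numpy(dtype=float),
                tumor_radius_mm=float(sub["tumor_radius_mm"].iloc[0]),
                max_distance=float(sub["max_distance"].iloc[0]))
        return out

    @property
    def subject_ids(self):
        return list(self.subjects["subject_id"])

    def timeseries(self, subject_id: str) -> RegionalTimeSeries:
        with h5py.File(self._h5_path, "r") as f:
            d = f[subject_id]
            region_ids = [r.decode() if isinstance(r, bytes) else str(r)
                          for r in d.attrs.get("region_ids", [])] or None
            return RegionalTimeSeries(subject_id, d[()],
                                      float(d.attrs["sampling_rate"]),
                                      region_ids=region_ids)


def load_cohort_dir(directory: str) -> DiskCohort:
    return DiskCohort(directory)


def load_cohort_config(path: str) -> CohortConfig:
    """Read a YAML/JSON cohort configuration (all fields defaulted)."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return CohortConfig.from_dict(data)


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def _df_to_markdown(df: pd.DataFrame, max_rows: int = 60) -> str:
    if not len(df):
        return "*(empty)*\n"
    show = df.head(max_rows)
    cols = [str(c) for c in show.columns]

    def fmt(v):
        if isinstance(v, float):
            return "" if np.isnan(v) else f"{v:.4g}"
        return str(v)

    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in show.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    if len(df) > max_rows:
        lines.append(f"\n*... {len(df) - max_rows} more rows in the CSV.*")
    return "\n".join(lines) + "\n"


def write_report(report, out_dir: str) -> None:
    """Write every result table as CSV plus manifest.json and report.md."""
    os.makedirs(out_dir, exist_ok=True)
    j = os.path.join
    names = {"cohort_table": "cohort_table.csv",
             "activity": "activity_summaries.csv",
             "growth": "growth_classes.csv",
             "correlations": "correlation_table.csv",
             "groups": "group_table.csv",
             "paired": "paired_table.csv",
             "survival": "survival_table.csv",
             "exclusions": "exclusions.csv"}
    for attr, fname in names.items():
        getattr(report, attr).to_csv(j(out_dir, fname), index=False,
                                     float_format=_FLOAT_FMT)
    with open(j(out_dir, "manifest.json"), "w") as f:
        json.dump(report.manifest, f, indent=1, sort_keys=True, default=str)
    sections = [
        ("Cohort characteristics", report.cohort_table),
        ("Growth classification", report.growth),
        ("Activity-growth correlations", report.correlations),
        ("Group comparisons", report.groups),
        ("Peritumoral vs contralateral (paired)", report.paired),
        ("Survival models", report.survival),
        ("Exclusions", report.exclusions),
    ]
    md = ["# Brain activity and radiological growth - analysis report", ""]
    md.append(f"Seed: {report.manifest.get('seed')} | config sha256: "
              f"{report.manifest.get('config_sha256', '')[:12]} | "
              f"n input: {report.manifest.get('n_input')} | "
              f"n analyzed: {report.manifest.get('n_analyzed')}")
    md.append("")
    for title, df in sections:
        md.append(f"## {title}\n")
        md.append(_df_to_markdown(df))
    with open(j(out_dir, "report.md"), "w") as f:
        f.write("\n".join(md))
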