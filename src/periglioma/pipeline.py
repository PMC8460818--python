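"""End-to-end orchestration: spectra -> spatial summaries -> growth
classes -> group statistics and survival, with exclusion accounting.

``analyze_cohort`` consumes any object with the :class:`~periglioma.\
cohort.Cohort` interface (synthetic or loaded from disk) and returns an
:class:`AnalysisReport` whose tables mirror the structure of a clinical
brain-activity study report: a cohort characteristics table, activity-
vs-growth correlations, group comparisons (stable vs increasing volume;
patients vs healthy controls), paired peritumoral-vs-contralateral
comparisons with distance subgroups, and Cox/Kaplan-Meier survival
models on control-referenced activity z-scores.

Multiplicity is controlled per test family with Benjamini-Hochberg FDR.
All randomness flows from the cohort seed; rerunning with the same
configuration reproduces every table byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .regional import (distance_subgroups, map_contralateral_homologues,
                       mean_euclidean_distance, normalize_by_contralateral,
                       summarize_hemispheres)
from .spectral import (InsufficientCleanEpochsError, broadband_power,
                       compute_psd_welch, fit_aperiodic, flag_artifact_epochs,
                       segment_epochs, select_epochs_first_clean,
                       select_epochs_max_alpha, summarize_activity)
from .stats_survival import (cohens_d, cohens_d_paired, cox_ph, fdr_adjust,
                             km_median_split, mann_whitney_u, spearman_corr,
                             wilcoxon_signed_rank, zscore_vs_controls)
from .volumetrics import MissingScanError, classify_growth, volume_change

__all__ = ["MEASURES", "RunConfig", "ValidationReport", "AnalysisReport",
           "analyze_subject", "analyze_cohort", "run_pipeline",
           "validate_inputs"]

#: The three brain-activity measures, as column names.
MEASURES = ("broadband_power", "offset", "slope")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: Optional[object] = None       # CohortConfig for simulation
    input_dir: Optional[str] = None       # or a directory of input files
    out_dir: str = "periglioma_out"
    n_epochs: int = 10
    selection: str = "first_clean"        # or 'max_alpha'
    knee_mode: str = "fixed"
    fdr_q: float = 0.05
    write_timeseries: bool = False

    def validate(self) -> None:
        if (self.cohort is None) == (self.input_dir is None):
            raise ValueError("exactly one of a simulation config or an "
                             "input directory must be given")
        if self.selection not in ("first_clean", "max_alpha"):
            raise ValueError("selection must be first_clean or max_alpha")
        if self.knee_mode not in ("fixed", "free"):
            raise ValueError("knee_mode must be fixed or free")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")


@dataclass
class ValidationReport:
    """Schema/invariant check outcomes, split by severity."""

    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class AnalysisReport:
    """All result tables of one pipeline run plus a provenance manifest."""

    cohort_table: pd.DataFrame
    activity: pd.DataFrame        # per subject x level measures
    growth: pd.DataFrame          # per patient volume change + class
    correlations: pd.DataFrame
    groups: pd.DataFrame
    paired: pd.DataFrame
    survival: pd.DataFrame
    exclusions: pd.DataFrame
    manifest: dict
    km_curves: dict = field(default_factory=dict)

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {"cohort_table": self.cohort_table, "activity": self.activity,
                "growth": self.growth, "correlations": self.correlations,
                "groups": self.groups, "paired": self.paired,
                "survival": self.survival, "exclusions": self.exclusions}


# ---------------------------------------------------------------------------
# Per-subject spectral analysis
# ---------------------------------------------------------------------------

def analyze_subject(ts, atlas, peritumoral=None, tumor_hemisphere=None,
                    n_epochs: int = 10, selection: str = "first_clean",
                    knee_mode: str = "fixed", epoch_duration: float = 13.1,
                    welch_nperseg: Optional[int] = None) -> list:
    """Spectral measures for one subject at every applicable level.

    Returns a list of :class:`~periglioma.spectral.ActivitySummary`:
    global for everyone; hemisphere, peritumoral, contralateral and
    normalized levels when a tumor hemisphere / peritumoral selection is
    known.  Raises ``InsufficientCleanEpochsError`` when the recording
    does not offer ``n_epochs`` clean epochs.
    """
    epochs = segment_epochs(ts, epoch_duration)
    flags = flag_artifact_epochs(epochs)
    if selection == "first_clean":
        chosen = select_epochs_first_clean(epochs, flags, n=n_epochs)
    else:
        chosen = select_epochs_max_alpha(epochs, n=n_epochs)
    spectrum = compute_psd_welch(chosen, nperseg=welch_nperseg)
    powers = broadband_power(spectrum)
    fits = fit_aperiodic(spectrum, knee_mode=knee_mode)
    meta = dict(n_epochs=chosen.n_epochs,
                selection_label=chosen.selection_label)
    out = [summarize_activity(fits, powers, np.arange(ts.n_regions),
                              "global", subject_id=ts.subject_id, **meta)]
    if tumor_hemisphere is not None:
        tumor_side, contra_side = summarize_hemispheres(
            fits, powers, atlas, tumor_hemisphere, subject_id=ts.subject_id)
        out += [tumor_side, contra_side]
    if peritumoral is not None:
        pairing = map_contralateral_homologues(peritumoral, atlas)
        peri = summarize_activity(fits, powers, pairing.peritumoral_indices,
                                  "peritumoral", subject_id=ts.subject_id,
                                  **meta)
        contra = summarize_activity(fits, powers,
                                    pairing.contralateral_indices,
                                    "contralateral",
                                    subject_id=ts.subject_id, **meta)
        out += [peri, contra, normalize_by_contralateral(peri, contra)]
    return out


# ---------------------------------------------------------------------------
# Cohort-level analysis
# ---------------------------------------------------------------------------

def _activity_frame(summaries) -> pd.DataFrame:
    rows = [{"subject_id": s.subject_id, "level": s.level,
             "broadband_power": s.broadband_power, "offset": s.offset,
             "slope": s.slope, "n_regions": s.n_regions,
             "n_epochs": s.n_epochs, "selection_label": s.selection_label}
            for s in summaries]
    return pd.DataFrame(rows)


def _pivot_levels(activity: pd.DataFrame) -> dict:
    """Cache {(level, measure): Series indexed by subject} once."""
    piv = {}
    for level, sub in activity.groupby("level"):
        idx = sub["subject_id"].to_numpy()
        for m in MEASURES:
            piv[(level, m)] = pd.Series(sub[m].to_numpy(), index=idx)
    return piv


def _cohort_table(subjects: pd.DataFrame, growth: pd.DataFrame
                  ) -> pd.DataFrame:
    pats = subjects[subjects["group"] == "patient"]
    rows = [("patients_n", len(pats)),
            ("controls_n", (subjects["group"] == "control").sum()),
            ("age_mean", subjects["age"].mean()),
            ("age_sd", subjects["age"].std(ddof=1)),
            ("male_n", (subjects["sex"] == "M").sum())]
    if len(pats):
        for g in (2, 3, 4):
            rows.append((f"who_grade_{g}_n", (pats["who_grade"] == g).sum()))
        rows.append(("epilepsy_n", pats["epilepsy"].sum()))
    if len(growth):
        for label in ("stable", "increasing"):
            rows.append((f"{label}_volume_n",
                         (growth["label"] == label).sum()))
    return pd.DataFrame(rows, columns=["characteristic", "value"])


def _fdr_by_family(table: pd.DataFrame, q: float) -> pd.DataFrame:
    """Add BH-adjusted p and reject columns within each test family."""
    table = table.copy()
    table["adjusted_p"] = np.nan
    table["reject"] = False
    for fam, idx in table.groupby("family").groups.items():
        sub = table.loc[idx]
        usable = sub["p_value"].notna()
        if fam.startswith("uncorrected"):
            table.loc[idx, "adjusted_p"] = sub["p_value"]
            table.loc[idx, "reject"] = sub["p_value"] < q
            continue
        if usable.any():
            rej, adj = fdr_adjust(sub.loc[usable, "p_value"].to_numpy(), q=q)
            table.loc[sub.index[usable], "adjusted_p"] = adj
            table.loc[sub.index[usable], "reject"] = rej
    return table


def analyze_cohort(cohort, n_epochs: int = 10, selection: str = "first_clean",
                   knee_mode: str = "fixed", fdr_q: float = 0.05,
                   survival: bool = True,
                   epoch_duration: Optional[float] = None,
                   welch_nperseg: Optional[int] = None) -> AnalysisReport:
    """Run the full analysis on a (synthetic or loaded) cohort."""
    cfg = cohort.config
    if epoch_duration is None:
        epoch_duration = getattr(cfg, "epoch_duration", 13.1)
    subjects = cohort.subjects
    exclusions: List[dict] = []
    summaries = []
    for _, row in subjects.iterrows():
        sid = row["subject_id"]
        try:
            ts = cohort.timeseries(sid)
            summaries += analyze_subject(
                ts, cohort.atlas,
                peritumoral=cohort.peritumoral.get(sid),
                tumor_hemisphere=row["tumor_hemisphere"]
                if row["group"] == "patient" else None,
                n_epochs=n_epochs, selection=selection, knee_mode=knee_mode,
                epoch_duration=epoch_duration, welch_nperseg=welch_nperseg)
        except InsufficientCleanEpochsError as err:
            exclusions.append({"subject_id": sid, "stage": "spectral",
                               "reason": str(err)})
    activity = _activity_frame(summaries)
    analyzed = set(activity["subject_id"]) if len(activity) else set()

    # growth classification
    growth_rows = []
    for sid, series in cohort.volumes.items():
        if sid not in analyzed:
            continue
        try:
            change = volume_change(series)
        except MissingScanError as err:
            exclusions.append({"subject_id": sid, "stage": "volumetrics",
                               "reason": str(err)})
            continue
        label = classify_growth(series, change)
        growth_rows.append({
            "subject_id": sid, "delta_ml": change.delta_ml,
            "delta_pct": np.nan if change.delta_pct is None
            else change.delta_pct,
            "pre_volume": change.pre_volume,
            "post_volume": change.post_volume,
            "label": label.label, "rationale": label.rationale})
    growth = pd.DataFrame(growth_rows, columns=[
        "subject_id", "delta_ml", "delta_pct", "pre_volume", "post_volume",
        "label", "rationale"])

    patients = subjects[(subjects["group"] == "patient")
                        & subjects["subject_id"].isin(analyzed)]
    controls = subjects[(subjects["group"] == "control")
                        & subjects["subject_id"].isin(analyzed)]
    pat_ids = list(patients["subject_id"])
    ctl_ids = list(controls["subject_id"])

    piv = _pivot_levels(activity)
    correlations = _correlation_table(piv, growth, fdr_q)
    groups = _group_table(piv, growth, pat_ids, ctl_ids, fdr_q)
    paired, distances = _paired_table(cohort, piv, pat_ids, fdr_q)
    survival_table, km_curves = (
        _survival_table(cohort, piv, pat_ids, ctl_ids, patients)
        if survival else (pd.DataFrame(), {}))

    manifest = _manifest(cohort, exclusions, analyzed, n_epochs, selection,
                         knee_mode, fdr_q)
    return AnalysisReport(
        cohort_table=_cohort_table(subjects, growth),
        activity=activity, growth=growth, correlations=correlations,
        groups=groups, paired=paired, survival=survival_table,
        exclusions=pd.DataFrame(exclusions,
                                columns=["subject_id", "stage", "reason"]),
        manifest=manifest, km_curves=km_curves)


def _correlation_table(piv, growth, fdr_q) -> pd.DataFrame:
    """Spearman correlations of activity with volume change, per level
    and change type; patients lacking a percent change (pre volume of
    0 ml) drop out of the percent correlations pairwise."""
    rows = []
    columns = ["family", "level", "measure", "change", "statistic",
               "p_value", "n"]
    if not len(growth):
        return _fdr_by_family(pd.DataFrame(columns=columns), fdr_q)
    gids = growth["subject_id"].to_numpy()
    changes = {c: growth[c].to_numpy(dtype=float)
               for c in ("delta_ml", "delta_pct")}
    for level in ("global", "peritumoral", "normalized"):
        if (level, MEASURES[0]) not in piv:
            continue
        for change in ("delta_ml", "delta_pct"):
            y = changes[change]
            for measure in MEASURES:
                x = piv[(level, measure)].reindex(gids).to_numpy()
                try:
                    res = spearman_corr(x, y)
                    rows.append({"family": f"corr_{level}_{change}",
                                 "level": level, "measure": measure,
                                 "change": change, "statistic": res.statistic,
                                 "p_value": res.p_value, "n": res.n[0]})
                except ValueError:
                    rows.append({"family": f"corr_{level}_{change}",
                                 "level": level, "measure": measure,
                                 "change": change, "statistic": np.nan,
                                 "p_value": np.nan, "n": len(x)})
    return _fdr_by_family(pd.DataFrame(rows, columns=columns), fdr_q)


def _group_table(piv, growth, pat_ids, ctl_ids, fdr_q) -> pd.DataFrame:
    """Mann-Whitney comparisons of global activity between groups."""
    rows = []
    gidx = growth.set_index("subject_id") if len(growth) else None

    def compare(family, name_a, ids_a, name_b, ids_b, measure):
        vals = piv[("global", measure)]
        a = vals.reindex(ids_a).dropna().to_numpy()
        b = vals.reindex(ids_b).dropna().to_numpy()
        row = {"family": family, "measure": measure, "group_a": name_a,
               "group_b": name_b, "n_a": len(a), "n_b": len(b),
               "statistic": np.nan, "p_value": np.nan,
               "effect_size": np.nan}
        if len(a) and len(b):
            res = mann_whitney_u(a, b)
            row.update(statistic=res.statistic, p_value=res.p_value)
            if len(a) > 1 and len(b) > 1:
                try:
                    row["effect_size"] = cohens_d(a, b)
                except ValueError:
                    pass
        rows.append(row)

    if gidx is not None and len(gidx):
        stable = [s for s in pat_ids if s in gidx.index
                  and gidx.loc[s, "label"] == "stable"]
        increasing = [s for s in pat_ids if s in gidx.index
                      and gidx.loc[s, "label"] == "increasing"]
        for m in MEASURES:
            compare("stable_vs_increasing", "stable", stable,
                    "increasing", increasing, m)
        if ctl_ids:
            for m in MEASURES:
                compare("patient_groups_vs_controls", "stable", stable,
                        "controls", ctl_ids, m)
                compare("patient_groups_vs_controls", "increasing",
                        increasing, "controls", ctl_ids, m)
    if ctl_ids and pat_ids:
        for m in MEASURES:
            compare("patients_vs_controls", "patients", pat_ids,
                    "controls", ctl_ids, m)
    return _fdr_by_family(pd.DataFrame(rows, columns=[
        "family", "measure", "group_a", "group_b", "n_a", "n_b",
        "statistic", "p_value", "effect_size"]), fdr_q)


def _paired_table(cohort, piv, pat_ids, fdr_q):
    """Peritumoral vs contralateral Wilcoxon tests, overall and within
    long/short homologue-distance subgroups (the latter uncorrected)."""
    rows = []
    distances = {}
    for sid in pat_ids:
        sel = cohort.peritumoral.get(sid)
        if sel is None:
            continue
        pairing = map_contralateral_homologues(sel, cohort.atlas)
        distances[sid] = mean_euclidean_distance(pairing)

    def paired_test(family, ids, subgroup):
        for m in MEASURES:
            if ("peritumoral", m) not in piv:
                continue
            peri = piv[("peritumoral", m)].reindex(ids)
            contra = piv[("contralateral", m)].reindex(ids)
            ok = peri.notna() & contra.notna()
            a, b = peri[ok].to_numpy(), contra[ok].to_numpy()
            row = {"family": family, "subgroup": subgroup, "measure": m,
                   "n": int(ok.sum()), "statistic": np.nan,
                   "p_value": np.nan, "effect_size": np.nan}
            try:
                res = wilcoxon_signed_rank(a, b)
                row.update(statistic=res.statistic, p_value=res.p_value,
                           effect_size=cohens_d_paired(a, b))
            except ValueError:
                pass
            rows.append(row)

    with_sel = [s for s in pat_ids if s in distances]
    if with_sel:
        paired_test("peritumoral_vs_contralateral", with_sel, "all")
        if len(distances) >= 4:
            subgroups = distance_subgroups(distances)
            for name in ("long", "short"):
                if subgroups[name]:
                    paired_test(f"uncorrected_subgroup_{name}",
                                subgroups[name], name)
    return _fdr_by_family(pd.DataFrame(rows, columns=[
        "family", "subgroup", "measure", "n", "statistic", "p_value",
        "effect_size"]), fdr_q), distances


def _survival_table(cohort, piv, pat_ids, ctl_ids, patients):
    """Cox models (activity z-score + age + grade) and KM median splits."""
    rows, km_curves = [], {}
    prog = cohort.progression
    if prog is None or not len(prog) or not ctl_ids:
        return pd.DataFrame(columns=[
            "measure", "covariate", "hazard_ratio", "ci_low", "ci_high",
            "p_value", "n", "n_events", "note"]), km_curves
    prog = prog.set_index("subject_id")
    for m in MEASURES:
        vals = piv[("global", m)]
        ids = [s for s in pat_ids if s in prog.index and s in vals.index]
        if len(ids) < 3:
            continue
        z = zscore_vs_controls(vals.reindex(ids).to_numpy(),
                               vals.reindex(ctl_ids).dropna().to_numpy())
        meta = patients.set_index("subject_id").reindex(ids)
        df = pd.DataFrame({
            "time_weeks": prog.reindex(ids)["time_weeks"].to_numpy(),
            "event": prog.reindex(ids)["event"].to_numpy(dtype=bool),
            "activity_z": z,
            "age": meta["age"].to_numpy(dtype=float),
            "grade": meta["who_grade"].to_numpy(dtype=float)})
        try:
            est = cox_ph(df, ["activity_z", "age", "grade"])
            for cov, he in est.items():
                rows.append({"measure": m, "covariate": cov,
                             "hazard_ratio": he.hazard_ratio,
                             "ci_low": he.ci_95[0], "ci_high": he.ci_95[1],
                             "p_value": he.p_value, "n": len(df),
                             "n_events": he.n_events, "note": ""})
        except (ValueError, RuntimeError) as err:
            rows.append({"measure": m, "covariate": "activity_z",
                         "hazard_ratio": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan, "n": len(df),
                         "n_events": int(df["event"].sum()),
                         "note": f"cox_failed: {err}"})
        try:
            km_curves[m], _ = km_median_split(df, df["activity_z"])
        except ValueError:
            pass
    return pd.DataFrame(rows, columns=[
        "measure", "covariate", "hazard_ratio", "ci_low", "ci_high",
        "p_value", "n", "n_events", "note"]), km_curves


def _manifest(cohort, exclusions, analyzed, n_epochs, selection, knee_mode,
              fdr_q) -> dict:
    cfg = cohort.config
    cfg_dict = cfg.to_dict() if hasattr(cfg, "to_dict") else dict(cfg)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    n_input = len(cohort.subjects)
    excluded_ids = {e["subject_id"] for e in exclusions
                    if e["stage"] == "spectral"}
    return {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": getattr(cfg, "seed", None),
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "analysis": {"n_epochs": n_epochs, "selection": selection,
                     "knee_mode": knee_mode, "fdr_q": fdr_q},
        "n_input": n_input,
        "n_analyzed": len(analyzed),
        "n_excluded_spectral": len(excluded_ids),
        "exclusion_reasons": sorted(
            {e["reason"] for e in exclusions}) if exclusions else [],
    }


# ---------------------------------------------------------------------------
# Input validation and the full run
# ---------------------------------------------------------------------------

def validate_inputs(subjects: pd.DataFrame, volumes: pd.DataFrame,
                    atlas=None, n_regions_seen: Optional[dict] = None
                    ) -> ValidationReport:
    """Schema and invariant checks on tabular inputs.

    Violations are enumerated (not raised one by one): impossible values
    (negative volumes, unordered scan days, unknown groups, region-count
    mismatches) are hard errors; analyzable-but-incomplete records
    (patients without a post-MEG scan, who will be excluded with a
    reason) are warnings.
    """
    rep = ValidationReport()
    need = {"subject_id", "group"}
    if not need.issubset(subjects.columns):
        rep.errors.append(f"subjects table missing columns "
                          f"{sorted(need - set(subjects.columns))}")
        return rep
    bad_group = ~subjects["group"].isin(["patient", "control"])
    for sid in subjects.loc[bad_group, "subject_id"]:
        rep.errors.append(f"subject {sid}: unknown group label")
    vneed = {"subject_id", "scan_day", "volume_ml", "meg_day"}
    if not vneed.issubset(volumes.columns):
        rep.errors.append(f"volumes table missing columns "
                          f"{sorted(vneed - set(volumes.columns))}")
        return rep
    neg = volumes["volume_ml"] < 0
    for i in volumes.index[neg]:
        rep.errors.append(
            f"volumes row {i} (subject "
            f"{volumes.loc[i, 'subject_id']}): negative volume")
    for sid, sub in volumes.groupby("subject_id"):
        days = sub["scan_day"].to_numpy()
        if np.any(np.diff(days) <= 0):
            rep.errors.append(f"subject {sid}: scan days not strictly "
                              "increasing")
            continue
        meg = sub["meg_day"].iloc[0]
        if not (days > meg).any():
            rep.warnings.append(f"subject {sid}: no post-MEG scan; will be "
                                "excluded from growth analyses")
        if not (days <= meg).any():
            rep.warnings.append(f"subject {sid}: no pre-MEG scan; will be "
                                "excluded from growth analyses")
    if atlas is not None and n_regions_seen:
        for sid, n in n_regions_seen.items():
            if n != atlas.n_regions:
                rep.errors.append(
                    f"subject {sid}: {n} regions, atlas has "
                    f"{atlas.n_regions}")
    return rep


def run_pipeline(run_config: RunConfig) -> AnalysisReport:
    """Simulate or load a cohort, validate, analyze, and persist results.

    Writes the cohort artifact files, every report table as CSV, a
    provenance manifest and a markdown report into ``out_dir``.  Outputs
    are deterministic for a fixed configuration and seed.
    """
    from . import io as pio
    from .cohort import generate_cohort

    run_config.validate()
    if run_config.cohort is not None:
        cohort = generate_cohort(run_config.cohort)
    else:
        cohort = pio.load_cohort_dir(run_config.input_dir)

    vol_rows = [{"subject_id": sid, "scan_day": d, "volume_ml": v,
                 "meg_day": s.meg_day}
                for sid, s in cohort.volumes.items()
                for d, v in zip(s.scan_days, s.volumes)]
    volumes_df = pd.DataFrame(vol_rows, columns=["subject_id", "scan_day",
                                                 "volume_ml", "meg_day"])
    validation = validate_inputs(cohort.subjects, volumes_df, cohort.atlas)
    if not validation.ok:
        raise ValueError("input validation failed:\n  "
                         + "\n  ".join(validation.errors))

    report = analyze_cohort(cohort, n_epochs=run_config.n_epochs,
                            selection=run_config.selection,
                            knee_mode=run_config.knee_mode,
                            fdr_q=run_config.fdr_q)
    report.manifest["validation_warnings"] = validation.warnings
    pio.write_cohort(cohort, run_config.out_dir,
                     write_timeseries=run_config.write_timeseries)
    pio.write_report(report, run_config.out_dir)
    return report
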