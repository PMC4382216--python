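"""End-to-end analysis pipeline and its configuration.

Chains the full analysis in field order: triangulate and filter bearing
pairs, deduplicate and sessionize fixes, estimate per-bat home ranges and
focus areas, build per-bat availability and run the design-III selection
analysis, derive daily ranges and fit the all-subset mixed-model set, and
compare near/far focus-area composition with Fisher tests.  Reports mirror
the field study's table structures.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, box

from . import __version__
from . import io as ftio
from .habitat import (
    CATEGORIES,
    availability_circle,
    fisher_exact_rxc,
    holm_bonferroni,
    selection_ratios,
)
from .homerange import (
    DegenerateGeometryError,
    InsufficientDataError,
    daily_ranges,
    home_range,
)
from .models import TERMS, all_subsets, center_covariates, conditional_r2, \
    model_average, vif
from .telemetry import (
    Track,
    assign_sessions,
    deduplicate_stationary,
    infer_sessions,
    select_sessions,
    triangulate,
)

__all__ = ["PipelineConfig", "ReportBundle", "analyze_study", "run_pipeline"]

_SYNODIC_DAYS = 29.53


def default_moon_fraction(day: float) -> float:
    """Illuminated moon fraction proxy from the sampling day (synodic cycle)."""
    return 0.5 * (1.0 + math.sin(2.0 * math.pi * day / _SYNODIC_DAYS))


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; defaults are the analysis' standard settings."""

    projection: str = "local-transverse-mercator"
    sep_min: float = 15.0
    sep_max: float = 165.0
    max_range: float = 400.0
    stationary_radius: float = 50.0
    declination: float = 0.0
    mcp_level: float = 95.0
    locoh_fraction: float = 0.5
    k_rounding: str = "round"
    locoh_include_root: bool = True
    merge_radius: float = 0.0
    min_contact_fraction: float = 0.85
    n_daily_sessions: int = 3
    alpha: float = 0.05
    used_mode: str = "fixes"  # fixes | area
    scope: str = "delta2"     # delta2 | all
    averaging_mode: str = "conditional"  # conditional | full
    ci_multiplier: float = 1.96
    aicc_cutoff: float = 2.0
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        checks = [
            (0 <= self.sep_min < self.sep_max <= 180, "separation bounds"),
            (self.max_range > 0, "max_range"),
            (self.stationary_radius >= 0, "stationary_radius"),
            (0 < self.mcp_level <= 100, "mcp_level"),
            (0 < self.locoh_fraction <= 1, "locoh_fraction"),
            (self.k_rounding in ("round", "floor"), "k_rounding"),
            (0 < self.alpha < 1, "alpha"),
            (self.used_mode in ("fixes", "area"), "used_mode"),
            (self.scope in ("delta2", "all"), "scope"),
            (self.averaging_mode in ("conditional", "full"), "averaging_mode"),
            (self.ci_multiplier > 0, "ci_multiplier"),
            (0 < self.min_contact_fraction <= 1, "min_contact_fraction"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"invalid pipeline parameter: {name}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()


@dataclass
class ReportBundle:
    fixes: list
    rejections: list
    tracks: dict[str, Track]
    home_ranges: dict
    homerange_table: pd.DataFrame
    selection: object | None
    selection_table: pd.DataFrame | None
    model_set: object | None
    modelset_table: pd.DataFrame | None
    averaged: object | None
    coefficients_table: pd.DataFrame | None
    vif_table: pd.Series | None
    daily_table: pd.DataFrame
    focus_table: pd.DataFrame
    fisher_table: pd.DataFrame
    warnings: list = field(default_factory=list)


def _covered_by_any(polys, points: np.ndarray) -> np.ndarray:
    if not polys or len(points) == 0:
        return np.zeros(len(points), dtype=bool)
    pts = shapely.points(points)
    mask = np.zeros(len(points), dtype=bool)
    for p in polys:
        mask |= shapely.covers(p, pts)
    return mask


def analyze_study(bearings, landcover, roosts: dict[str, list],
                  sexes: dict[str, str] | None = None,
                  config: PipelineConfig | None = None,
                  moon_fraction=default_moon_fraction) -> ReportBundle:
    """Run the full analysis on in-memory inputs.

    ``bearings`` is a list of BearingRecord; ``roosts`` maps bat id to its
    roost coordinates; ``sexes`` optionally maps bat id to 'm'/'f'.  Bats
    whose filtered tracks are too sparse for an estimator are excluded from
    that stage with a warning, and the run continues.
    """
    cfg = (config or PipelineConfig()).validate()
    notes: list[str] = []
    sexes = sexes or {}

    by_bat: dict[str, list] = {}
    for r in bearings:
        by_bat.setdefault(r.bat_id, []).append(r)

    all_fixes, all_rej = [], []
    tracks: dict[str, Track] = {}
    raw_tracks: dict[str, Track] = {}
    for bat_id, recs in by_bat.items():
        recs = sorted(recs, key=lambda r: r.timestamp)
        fixes, rej = triangulate(recs, max_range=cfg.max_range,
                                 sep_bounds=(cfg.sep_min, cfg.sep_max),
                                 declination=cfg.declination)
        all_rej.extend(rej)
        if not fixes:
            notes.append(f"{bat_id}: no accepted fixes, excluded")
            continue
        sessions = infer_sessions(fixes)
        assigned = assign_sessions(fixes, sessions)
        dedup = []
        for sid in range(len(sessions)):
            dedup.extend(deduplicate_stationary(
                [f for f in assigned if f.session_id == sid],
                cfg.stationary_radius))
        all_fixes.extend(dedup)
        tracks[bat_id] = Track(bat_id, dedup, sessions,
                               roosts=list(roosts.get(bat_id, [])))
        raw_tracks[bat_id] = Track(bat_id, assigned, sessions,
                                   roosts=list(roosts.get(bat_id, [])))

    # -- per-bat home ranges ------------------------------------------------
    home_ranges = {}
    hr_rows = []
    for bat_id, track in tracks.items():
        try:
            hr = home_range(track, mcp_level=cfg.mcp_level,
                            locoh_fraction=cfg.locoh_fraction,
                            k_rounding=cfg.k_rounding,
                            include_root=cfg.locoh_include_root)
        except (InsufficientDataError, DegenerateGeometryError) as e:
            notes.append(f"{bat_id}: home range skipped ({e})")
            continue
        home_ranges[bat_id] = hr
        hr_rows.append({"bat_id": bat_id, "hr_tot_ha": hr.hr_tot_ha,
                        "n_fixes": hr.n_fixes, "compactness": hr.compactness,
                        "n_focus_areas": hr.n_focus_areas})
    homerange_table = pd.DataFrame(hr_rows)

    # -- habitat selection --------------------------------------------------
    extent_box = box(*landcover.extent) if hasattr(landcover, "extent") and \
        landcover.extent is not None else None
    used_rows, avail_rows, sel_bats = [], [], []
    for bat_id, hr in home_ranges.items():
        track = tracks[bat_id]
        if not track.roosts:
            notes.append(f"{bat_id}: no roost, excluded from selection")
            continue
        center, radius = availability_circle(track.roosts, hr.mcp95)
        circle = Point(center).buffer(radius, quad_segs=128)
        if extent_box is not None:
            circle = circle.intersection(extent_box)
        avail = landcover.composition(circle)
        pts = track.positions()
        inside = _covered_by_any(hr.isopleth50, pts)
        if cfg.used_mode == "area":
            cell = getattr(landcover, "cellsize", 10.0)
            counts = dict.fromkeys(CATEGORIES, 0)
            for poly in hr.isopleth50:
                comp = landcover.composition(poly)
                for c in CATEGORIES:
                    counts[c] += comp[c] * poly.area / cell ** 2
            counts = {c: int(round(v)) for c, v in counts.items()}
        else:
            cats = landcover.classify_points(pts[inside])
            counts = {c: int((cats == c).sum()) for c in CATEGORIES}
        if sum(counts.values()) == 0:
            notes.append(f"{bat_id}: no used fixes, excluded from selection")
            continue
        used_rows.append(counts)
        avail_rows.append(avail)
        sel_bats.append(bat_id)

    selection = selection_table = None
    if len(sel_bats) >= 2:
        used_df = pd.DataFrame(used_rows, index=sel_bats)[list(CATEGORIES)]
        avail_df = pd.DataFrame(avail_rows, index=sel_bats)[list(CATEGORIES)]
        selection = selection_ratios(used_df, avail_df, alpha=cfg.alpha)
        selection_table = selection.table.reset_index()
    else:
        notes.append("fewer than 2 bats usable for selection analysis")

    # -- daily ranges and mixed models -------------------------------------
    daily_rows = []
    for bat_id, track in tracks.items():
        try:
            chosen = select_sessions(raw_tracks[bat_id],
                                     min_contact_fraction=cfg.min_contact_fraction,
                                     n_sessions=cfg.n_daily_sessions)
        except ValueError:
            continue
        if chosen.flagged:
            notes.append(f"{bat_id}: fewer than {cfg.n_daily_sessions} "
                         "sessions reach the contact threshold")
        keep = {w: i for i, w in enumerate(chosen.sessions)}
        sub_fixes = [f for f in track.fixes
                     if track.sessions[f.session_id] in keep]
        if not sub_fixes:
            continue
        from dataclasses import replace as _replace
        sub_fixes = [_replace(f, session_id=keep[track.sessions[f.session_id]])
                     for f in sub_fixes]
        sub = Track(bat_id, sorted(sub_fixes, key=lambda f: f.timestamp),
                    list(chosen.sessions), roosts=track.roosts)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            drs = daily_ranges(sub, level=cfg.mcp_level)
            notes.extend(str(w.message) for w in caught)
        for dr in drs:
            comp = landcover.composition(dr.polygon) \
                if dr.polygon.area > 0 else dict.fromkeys(CATEGORIES, 0.0)
            dr.composition = comp
            day = sub.sessions[dr.session_id][0] / 86400.0
            daily_rows.append({
                "bat_id": bat_id, "session_id": dr.session_id,
                "area_m2": dr.area, "log_area": dr.log_area,
                "disturbance": comp["degraded"],
                "day": day, "moon": moon_fraction(day),
                "sex": 1.0 if sexes.get(bat_id, "m") == "m" else 0.0,
            })
    daily_table = pd.DataFrame(daily_rows)

    model_set = modelset_table = averaged = coefficients_table = vif_table = None
    if len(daily_table) >= 6 and daily_table["bat_id"].nunique() >= 2:
        candidates = [t for t in TERMS
                      if daily_table[t].nunique() > 1]
        dropped = [t for t in TERMS if t not in candidates]
        if dropped:
            notes.append(f"constant covariates dropped from the model set: {dropped}")
        # the largest subset must keep AICc defined: n - K - 1 > 0
        while candidates and len(daily_table) - (len(candidates) + 3) - 1 <= 0:
            notes.append(f"too few daily ranges for term {candidates[-1]!r}; dropped")
            candidates = candidates[:-1]
        if candidates:
            centered, _means = center_covariates(daily_table, terms=candidates)
            model_set = all_subsets(centered, terms=tuple(candidates),
                                    cutoff=cfg.aicc_cutoff)
            modelset_table = model_set.summary()
            averaged = model_average(model_set, scope=cfg.scope,
                                     mode=cfg.averaging_mode,
                                     terms=tuple(candidates),
                                     ci_multiplier=cfg.ci_multiplier)
            coefficients_table = averaged.table.reset_index()
            if len(candidates) >= 2:
                vif_table = vif(centered, terms=tuple(candidates))
    else:
        notes.append("too few daily ranges for the mixed-model stage")

    # -- focus-area composition and near/far tests -------------------------
    focus_rows, fisher_rows = [], []
    for bat_id, hr in home_ranges.items():
        track = tracks[bat_id]
        pts = track.positions()
        if not hr.isopleth50:
            continue
        if hr.n_focus_areas >= 2 and track.roosts:
            roost = np.asarray(track.roosts, dtype=float).mean(axis=0)
            dists = [Point(roost).distance(p) for p in hr.isopleth50]
            near_i = int(np.argmin(dists))
            groups = {"near": [hr.isopleth50[near_i]],
                      "far": [p for i, p in enumerate(hr.isopleth50) if i != near_i]}
        else:
            groups = {"single": hr.isopleth50}
        counts_by_label = {}
        for label, polys in groups.items():
            inside = _covered_by_any(polys, pts)
            cats = landcover.classify_points(pts[inside])
            counts = {c: int((cats == c).sum()) for c in CATEGORIES}
            counts_by_label[label] = counts
            for c in CATEGORIES:
                focus_rows.append({"bat_id": bat_id, "focus": label,
                                   "category": c, "n_fixes": counts[c]})
        if set(counts_by_label) == {"near", "far"}:
            t = np.array([[counts_by_label["near"][c] for c in CATEGORIES],
                          [counts_by_label["far"][c] for c in CATEGORIES]])
            if t.sum(axis=1).min() > 0:
                res = fisher_exact_rxc(t, seed=cfg.seed)
                fisher_rows.append({"bat_id": bat_id, "p": res.p,
                                    "method": res.method})
    fisher_table = pd.DataFrame(fisher_rows)
    if len(fisher_table):
        reject, thresh = holm_bonferroni(fisher_table["p"].to_numpy(),
                                         alpha=cfg.alpha)
        fisher_table["reject"] = reject
        fisher_table["holm_threshold"] = thresh

    return ReportBundle(
        fixes=all_fixes, rejections=all_rej, tracks=tracks,
        home_ranges=home_ranges, homerange_table=homerange_table,
        selection=selection, selection_table=selection_table,
        model_set=model_set, modelset_table=modelset_table,
        averaged=averaged, coefficients_table=coefficients_table,
        vif_table=vif_table, daily_table=daily_table,
        focus_table=pd.DataFrame(focus_rows), fisher_table=fisher_table,
        warnings=notes,
    )


def write_reports(bundle: ReportBundle, outdir, config: PipelineConfig) -> dict:
    """Write the six report files plus fixes/rejections and a run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ftio.write_fixes(out / "fixes.csv", bundle.fixes)
    ftio.write_rejections(out / "rejections.csv", bundle.rejections)
    bundle.homerange_table.to_csv(out / "homerange.csv", index=False)
    (bundle.selection_table if bundle.selection_table is not None
     else pd.DataFrame(columns=["category", "wi", "se", "ci_low", "ci_high"])
     ).to_csv(out / "selection.csv", index=False)
    (bundle.modelset_table if bundle.modelset_table is not None
     else pd.DataFrame()).to_csv(out / "modelset.csv", index=False)
    (bundle.coefficients_table if bundle.coefficients_table is not None
     else pd.DataFrame()).to_csv(out / "coefficients.csv", index=False)
    bundle.focus_table.to_csv(out / "focus_composition.csv", index=False)
    bundle.fisher_table.to_csv(out / "fisher_tests.csv", index=False)

    files = ["fixes.csv", "rejections.csv", "homerange.csv", "selection.csv",
             "modelset.csv", "coefficients.csv", "focus_composition.csv",
             "fisher_tests.csv"]
    digest = hashlib.sha256()
    for name in files:
        digest.update((out / name).read_bytes())
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "selection_chi2": None if bundle.selection is None else {
            "chi2": bundle.selection.chi2, "df": bundle.selection.df,
            "p": bundle.selection.p},
        "warnings": bundle.warnings,
        "content_sha256": digest.hexdigest(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_pipeline(config: PipelineConfig, bearings_path, landcover_path,
                 roosts_path, outdir) -> dict:
    """File-based entry point: read inputs, analyze, write the report bundle."""
    bearings = ftio.read_bearings(bearings_path)
    landcover = ftio.read_landcover(landcover_path)
    roost_df = ftio.read_roosts(roosts_path)
    roosts: dict[str, list] = {}
    sexes: dict[str, str] = {}
    for _, row in roost_df.iterrows():
        roosts.setdefault(str(row["bat_id"]), []).append(
            (float(row["x"]), float(row["y"])))
        if "sex" in roost_df.columns and isinstance(row["sex"], str):
            sexes[str(row["bat_id"])] = row["sex"]
    bundle = analyze_study(bearings, landcover, roosts, sexes, config)
    return write_reports(bundle, outdir, config)
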