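"""End-to-end experiment: cohort -> 4x3 condition grid -> long-format results
-> summary tables and statistical comparisons.

Each subject is posed at flexion 100/110/120/130 deg; at each pose the
maximum transverse drill angle (MTA) is determined and tunnels are drilled at
MTA, MTA-10 deg and MTA-20 deg. Per condition the tunnel length, the short
flag (< 25 mm), the wall-breakage class and the graft bending angle at full
extension are recorded. Infeasible conditions are data (flagged rows), never
batch aborts. The long-format table is the single source of truth; summaries
and statistics derive from it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .drilling import (DRILL_DIAMETER_MM, PORTAL_ANTERIOR_OFFSET_MM, DrillError,
                       drill_tunnel, find_mta, portal_at_angle)
from .kinematics import flex_knee
from .landmarks import LandmarkError, compute_landmarks
from .metrics import graft_bending_angle
from .stats import BinaryRepeated, RepeatedMeasures, TestResult, bonferroni_pairs, cochran_q, rm_anova
from .synthetic import KneeModel

__all__ = [
    "FLEXION_ANGLES",
    "DRILL_OFFSETS",
    "DrillCondition",
    "default_conditions",
    "run_grid",
    "summarize",
    "SummaryTables",
    "analyze",
    "render_report",
]

log = logging.getLogger("kneedrill")

FLEXION_ANGLES = (100.0, 110.0, 120.0, 130.0)
DRILL_OFFSETS = (0.0, -10.0, -20.0)

RESULT_COLUMNS = [
    "subject_id", "flexion_deg", "offset_from_mta", "mta_angle_deg",
    "transverse_angle_deg", "length_mm", "short", "breakage",
    "bending_angle_deg", "status",
]


@dataclass(frozen=True)
class DrillCondition:
    flexion_deg: float
    offset_from_mta: float


def default_conditions() -> list[DrillCondition]:
    """The twelve flexion x drill-angle conditions."""
    return [DrillCondition(f, o) for f, o in product(FLEXION_ANGLES, DRILL_OFFSETS)]


def run_grid(cohort: list[KneeModel],
             conditions: list[DrillCondition] | None = None,
             diameter_mm: float | None = None,
             anterior_offset_mm: float | None = None,
             femoral_frac_along: float | None = None,
             femoral_frac_perp: float | None = None,
             tibial_frac_ap: float | None = None,
             tibial_frac_ml: float | None = None,
             config: "RunConfig | None" = None) -> pd.DataFrame:
    """Drill the full condition grid for every subject.

    Returns a long-format DataFrame with one row per subject x condition.
    Rows that cannot be produced carry an error code in ``status`` and NaN
    measurements. Explicit keyword arguments override ``config``, which
    overrides the package defaults.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    from .config import RunConfig

    cfg = config or RunConfig()
    if conditions is None:
        conditions = cfg.conditions() if config is not None else default_conditions()
    diameter_mm = diameter_mm if diameter_mm is not None else cfg.diameter_mm
    anterior_offset_mm = (anterior_offset_mm if anterior_offset_mm is not None
                          else cfg.anterior_offset_mm)
    height_mm = cfg.portal_height_mm
    breakage_kwargs = dict(a_cap=cfg.aperture_allowance_mm, step=cfg.wall_step_mm,
                           n_theta=cfg.n_wall_generators, margin=cfg.end_margin_mm)
    lm_kwargs = {
        "femoral_frac_along": (femoral_frac_along if femoral_frac_along is not None
                               else cfg.femoral_frac_along),
        "femoral_frac_perp": (femoral_frac_perp if femoral_frac_perp is not None
                              else cfg.femoral_frac_perp),
        "tibial_frac_ap": (tibial_frac_ap if tibial_frac_ap is not None
                           else cfg.tibial_frac_ap),
        "tibial_frac_ml": (tibial_frac_ml if tibial_frac_ml is not None
                           else cfg.tibial_frac_ml),
    }

    flexions = sorted({c.flexion_deg for c in conditions})
    rows = []
    for model in cohort:
        t0 = time.perf_counter()
        canon = model.canonical()
        try:
            lm = compute_landmarks(canon.femur, canon.tibia, **lm_kwargs)
        except LandmarkError as err:
            log.warning("%s: landmarks failed: %s", model.subject_id, err)
            for c in conditions:
                rows.append(_failed_row(model.subject_id, c, f"landmarks: {err}"))
            continue
        F = lm.femoral_fp
        A = lm.tibial_fp
        per_flex: dict[float, tuple] = {}
        for flex in flexions:
            try:
                posed = flex_knee(canon, lm, flex)
                mta = find_mta(posed, F, diameter_mm, anterior_offset_mm,
                               height_mm=height_mm)
                per_flex[flex] = (posed, mta, None)
            except DrillError as err:
                per_flex[flex] = (None, None, str(err))
        for c in conditions:
            posed, mta, err = per_flex[c.flexion_deg]
            if err is not None:
                rows.append(_failed_row(model.subject_id, c, f"infeasible: {err}"))
                continue
            try:
                if c.offset_from_mta == 0.0:
                    sol = mta
                else:
                    sol = portal_at_angle(posed, F,
                                          mta.transverse_angle_deg + c.offset_from_mta,
                                          mta, anterior_offset_mm,
                                          height_mm=height_mm)
                tunnel = drill_tunnel(posed, sol, F, diameter_mm, **breakage_kwargs)
                bend = graft_bending_angle(A, F, tunnel.exit_point)
                rows.append({
                    "subject_id": model.subject_id,
                    "flexion_deg": c.flexion_deg,
                    "offset_from_mta": c.offset_from_mta,
                    "mta_angle_deg": mta.transverse_angle_deg,
                    "transverse_angle_deg": sol.transverse_angle_deg,
                    "length_mm": tunnel.length_mm,
                    "short": bool(tunnel.short),
                    "breakage": tunnel.breakage,
                    "bending_angle_deg": bend,
                    "status": "ok",
                })
            except DrillError as err:
                rows.append(_failed_row(model.subject_id, c, f"infeasible: {err}"))
        log.info("%s: grid done in %.1f s", model.subject_id, time.perf_counter() - t0)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    dup = df.duplicated(subset=["subject_id", "flexion_deg", "offset_from_mta"])
    assert not dup.any(), "duplicate subject x condition rows"
    return df


def _failed_row(subject_id: str, c: DrillCondition, status: str) -> dict:
    return {
        "subject_id": subject_id, "flexion_deg": c.flexion_deg,
        "offset_from_mta": c.offset_from_mta, "mta_angle_deg": np.nan,
        "transverse_angle_deg": np.nan, "length_mm": np.nan, "short": None,
        "breakage": None, "bending_angle_deg": np.nan, "status": status,
    }


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass
class SummaryTables:
    """Per-cell summaries over the cohort (cells = flexion x drill offset)."""

    length_mean: pd.DataFrame
    length_sd: pd.DataFrame
    length_range: pd.DataFrame          # "min~max" strings
    short_counts: pd.DataFrame
    short_proportions: pd.DataFrame
    breakage_counts: pd.DataFrame       # columns (offset, EB|MB|TB)
    breakage_proportions: pd.DataFrame
    bending_mean: pd.DataFrame
    bending_sd: pd.DataFrame
    cell_n: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def summarize(results: pd.DataFrame) -> SummaryTables:
    """Cell summaries: mean, SD (n-1), range for the continuous variables;
    counts/proportions for short tunnels; EB/MB/TB split for breakage
    (TB = EB + MB by construction)."""
    ok = results[results["status"] == "ok"].copy()
    warnings = []
    n_bad = len(results) - len(ok)
    if n_bad:
        warnings.append(f"{n_bad} rows not ok; cells summarised with reduced n")

    def cell_frame(fn):
        return ok.pivot_table(index="flexion_deg", columns="offset_from_mta",
                              values=fn[0], aggfunc=fn[1], observed=True, dropna=False)

    length_mean = cell_frame(("length_mm", "mean"))
    length_sd = cell_frame(("length_mm", lambda s: s.std(ddof=1)))
    lo = cell_frame(("length_mm", "min"))
    hi = cell_frame(("length_mm", "max"))
    length_range = lo.copy().astype(object)
    for i in length_range.index:
        for j in length_range.columns:
            length_range.loc[i, j] = f"{lo.loc[i, j]:.1f}~{hi.loc[i, j]:.1f}"
    ok["short_i"] = ok["short"].astype(int)
    short_counts = ok.pivot_table(index="flexion_deg", columns="offset_from_mta",
                                  values="short_i", aggfunc="sum", observed=True, dropna=False)
    cell_n = ok.pivot_table(index="flexion_deg", columns="offset_from_mta",
                            values="short_i", aggfunc="count", observed=True, dropna=False)
    short_props = short_counts / cell_n

    ok["eb"] = (ok["breakage"] == "entrance").astype(int)
    ok["mb"] = (ok["breakage"] == "mid_tunnel").astype(int)
    ok["tb"] = ok["eb"] + ok["mb"]
    pieces = {}
    for name in ("eb", "mb", "tb"):
        pieces[name.upper()] = ok.pivot_table(index="flexion_deg",
                                              columns="offset_from_mta",
                                              values=name, aggfunc="sum",
                                              observed=True, dropna=False)
    breakage_counts = pd.concat(pieces, axis=1).swaplevel(axis=1).sort_index(axis=1)
    breakage_props = breakage_counts / pd.concat(
        {k: cell_n for k in ("EB", "MB", "TB")}, axis=1
    ).swaplevel(axis=1).sort_index(axis=1)

    bending_mean = cell_frame(("bending_angle_deg", "mean"))
    bending_sd = cell_frame(("bending_angle_deg", lambda s: s.std(ddof=1)))
    return SummaryTables(
        length_mean=length_mean, length_sd=length_sd, length_range=length_range,
        short_counts=short_counts, short_proportions=short_props,
        breakage_counts=breakage_counts, breakage_proportions=breakage_props,
        bending_mean=bending_mean, bending_sd=bending_sd, cell_n=cell_n,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# statistics over the grid
# ---------------------------------------------------------------------------


def _complete_wide(results: pd.DataFrame, value: str, index: str, columns: str,
                   fixed: tuple[str, float]) -> RepeatedMeasures | None:
    sub = results[(results["status"] == "ok") & (results[fixed[0]] == fixed[1])]
    wide = sub.pivot(index="subject_id", columns=columns, values=value).dropna()
    if wide.shape[0] < 3 or wide.shape[1] < 2:
        return None
    return RepeatedMeasures(wide.to_numpy(dtype=float),
                            [str(c) for c in wide.columns])


def analyze(results: pd.DataFrame) -> dict:
    """The study's comparisons: for tunnel length and bending angle, RM-ANOVA
    plus Bonferroni post hoc across flexion angles (per fixed drill offset:
    6 pairs) and across drill offsets (per fixed flexion: 3 pairs); Cochran's
    Q for short-tunnel and breakage proportions along the same families."""
    out: dict = {"length": {}, "bending": {}, "short": {}, "breakage": {}}
    offsets = sorted(results["offset_from_mta"].unique(), reverse=True)
    flexions = sorted(results["flexion_deg"].unique())

    for metric, key in (("length_mm", "length"), ("bending_angle_deg", "bending")):
        by_flex = {}
        for off in offsets:
            rm = _complete_wide(results, metric, "subject_id", "flexion_deg",
                                ("offset_from_mta", off))
            if rm is not None:
                by_flex[off] = {"anova": rm_anova(rm), "pairs": bonferroni_pairs(rm)}
        by_off = {}
        for flex in flexions:
            rm = _complete_wide(results, metric, "subject_id", "offset_from_mta",
                                ("flexion_deg", flex))
            if rm is not None:
                by_off[flex] = {"anova": rm_anova(rm), "pairs": bonferroni_pairs(rm)}
        out[key] = {"across_flexion": by_flex, "across_offset": by_off}

    ok = results[results["status"] == "ok"].copy()
    ok["short_i"] = ok["short"].astype(int)
    ok["broken_i"] = (ok["breakage"] != "none").astype(int)
    for metric, key in (("short_i", "short"), ("broken_i", "breakage")):
        by_flex = {}
        for off in offsets:
            sub = ok[ok["offset_from_mta"] == off]
            wide = sub.pivot(index="subject_id", columns="flexion_deg",
                             values=metric).dropna()
            if len(wide) >= 2:
                by_flex[off] = cochran_q(BinaryRepeated(wide.to_numpy(),
                                                        [str(c) for c in wide.columns]))
        by_off = {}
        for flex in flexions:
            sub = ok[ok["flexion_deg"] == flex]
            wide = sub.pivot(index="subject_id", columns="offset_from_mta",
                             values=metric).dropna()
            if len(wide) >= 2:
                by_off[flex] = cochran_q(BinaryRepeated(wide.to_numpy(),
                                                        [str(c) for c in wide.columns]))
        out[key] = {"across_flexion": by_flex, "across_offset": by_off}
    return out


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def _fmt_p(p: float) -> str:
    return "<.001" if p < 0.001 else f"{p:.3f}"


def render_report(results: pd.DataFrame) -> str:
    """Markdown report: per-cell summaries shaped like the study's tables and
    the test families' p-values."""
    s = summarize(results)
    an = analyze(results)
    lines = ["# Virtual drilling report", ""]
    offsets = list(s.length_mean.columns)

    def offset_name(o):
        return "MTA" if o == 0 else f"MTA{int(o)}"

    lines += ["## Tunnel length (mm), mean +/- SD (range)", ""]
    header = "| Flexion | " + " | ".join(offset_name(o) for o in offsets) + " |"
    lines += [header, "|" + "---|" * (len(offsets) + 1)]
    for flex in s.length_mean.index:
        cells = [
            f"{s.length_mean.loc[flex, o]:.1f} +/- {s.length_sd.loc[flex, o]:.1f}"
            f" ({s.length_range.loc[flex, o]})"
            for o in offsets
        ]
        lines.append(f"| {flex:.0f} | " + " | ".join(cells) + " |")
    lines += ["", "## Short tunnels (< 25 mm), n (%)", "", header,
              "|" + "---|" * (len(offsets) + 1)]
    for flex in s.short_counts.index:
        cells = [f"{int(s.short_counts.loc[flex, o])} "
                 f"({100 * s.short_proportions.loc[flex, o]:.1f}%)" for o in offsets]
        lines.append(f"| {flex:.0f} | " + " | ".join(cells) + " |")
    lines += ["", "## Wall breakage, n per cell (EB / MB / TB)", "", header,
              "|" + "---|" * (len(offsets) + 1)]
    for flex in s.short_counts.index:
        cells = []
        for o in offsets:
            eb = int(s.breakage_counts.loc[flex, (o, "EB")])
            mb = int(s.breakage_counts.loc[flex, (o, "MB")])
            tb = int(s.breakage_counts.loc[flex, (o, "TB")])
            cells.append(f"{eb} / {mb} / {tb}")
        lines.append(f"| {flex:.0f} | " + " | ".join(cells) + " |")
    lines += ["", "## Graft bending angle (deg), mean +/- SD", "", header,
              "|" + "---|" * (len(offsets) + 1)]
    for flex in s.bending_mean.index:
        cells = [f"{s.bending_mean.loc[flex, o]:.1f} +/- {s.bending_sd.loc[flex, o]:.1f}"
                 for o in offsets]
        lines.append(f"| {flex:.0f} | " + " | ".join(cells) + " |")

    for key, title in (("length", "tunnel length"), ("bending", "graft bending angle")):
        lines += ["", f"## Post hoc ({title}), Bonferroni-adjusted p", ""]
        fam = an[key]["across_flexion"]
        if fam:
            pair_labels = [t.label for t in next(iter(fam.values()))["pairs"]]
            lines += ["| Pairwise comparison | " +
                      " | ".join(offset_name(o) for o in fam) + " |",
                      "|" + "---|" * (len(fam) + 1)]
            for i, lbl in enumerate(pair_labels):
                cells = [_fmt_p(fam[o]["pairs"][i].adjusted_p) for o in fam]
                lines.append(f"| {lbl} | " + " | ".join(cells) + " |")
    if s.warnings:
        lines += ["", "## Warnings", ""] + [f"- {w}" for w in s.warnings]
    return "\n".join(lines) + "\n"
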