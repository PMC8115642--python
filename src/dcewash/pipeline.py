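"""End-to-end orchestration: lesion analysis, cohort reports, reproduction.

The functions here compose the lower-level modules into the three
deliverables a study analyst needs: a per-lesion kinetic report from
NIfTI volumes, a cohort-level statistical report (diagnostic
performance, stratified Fisher tests, rank correlations, group
comparisons and survival), and a reproduction report that recomputes
the published summary statistics from the packaged fixture tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import kinetics, lesion_image, response, stats, survival
from .errors import NotEvaluableError
from .kinetics import CurveClass, KineticSample
from .synthetic_data import paper_fixtures

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Tunable thresholds and run options, overridable from YAML."""

    ratio_threshold: float = kinetics.ENHANCEMENT_RATIO_THRESHOLD
    wi_threshold: float = kinetics.WASHOUT_INDEX_THRESHOLD
    size_stratum_mm: float = response.SIZE_STRATUM_MM
    roi_diameter_mm: float = lesion_image.DEFAULT_ROI_DIAMETER_MM
    roi_planes: str = "all"  # "all" | "axial"
    roi_fallback: Optional[str] = None  # None | "voxel"
    cox_ties: str = "efron"
    welch: bool = False
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if min(self.ratio_threshold, self.wi_threshold, self.size_stratum_mm,
               self.roi_diameter_mm) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def analyze_lesion(
    pre_path, early_path, delay_path, mask_path, config: RunConfig | None = None
) -> dict:
    """Per-lesion report: size, best WI, enhancement ratio, curve class.

    An empty mask reports size 0, no curve, and a positive pathologic-
    response prediction (lesion disappearance).
    """
    config = config or RunConfig()
    for p, name in [(pre_path, "pre"), (early_path, "early"), (delay_path, "delay"),
                    (mask_path, "mask")]:
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"missing {name} input: {p}")
    pre = lesion_image.load_phase_volume(pre_path, lesion_image.Phase.PRE)
    early = lesion_image.load_phase_volume(early_path, lesion_image.Phase.EARLY)
    delay = lesion_image.load_phase_volume(delay_path, lesion_image.Phase.DELAY)
    mask = lesion_image.load_mask(mask_path)

    if mask.is_empty:
        return {
            "size_mm": 0.0,
            "curve_class": "none",
            "wi": None,
            "enhancement_ratio": None,
            "n_placements": 0,
            "predict_pathresponse": True,
            "roi": None,
        }
    size = lesion_image.longest_diameter(mask)
    lk = lesion_image.lesion_max_wi(
        pre, early, delay, mask,
        diameter=config.roi_diameter_mm,
        planes=config.roi_planes,
        fallback=config.roi_fallback,
        ratio_threshold=config.ratio_threshold,
        wi_threshold=config.wi_threshold,
    )
    obs = response.TimepointObservation(
        timepoint=response.Timepoint.MID, size_mm=size, kinetics=lk
    )
    return {
        "size_mm": float(size),
        "curve_class": lk.best_result.curve_class.value,
        "wi": lk.best_result.wi,
        "enhancement_ratio": lk.best_result.enhancement_ratio,
        "n_placements": lk.n_placements,
        "predict_pathresponse": response.predict_pathresponse(obs),
        "roi": {
            "plane_axis": lk.best_placement.plane_axis,
            "slice_index": lk.best_placement.slice_index,
            "center_mm": list(lk.best_placement.center),
        },
    }


# ---------------------------------------------------------------------------
# Cohort-level report


def _confusion_from_cohort(
    df: pd.DataFrame, timepoint: str, endpoint: str, predictor: str
) -> tuple[stats.ConfusionMatrix, int]:
    """Build a confusion matrix for one (timepoint, endpoint, predictor).

    ``endpoint`` is "pcr" or "rcb_le1"; ``predictor`` is "wi_or_size"
    or "size".  Returns the matrix and the number of excluded rows
    (missing size, missing endpoint, or residual lesion without WI for
    the kinetic predictor).
    """
    tp = fp = fn = tn = excluded = 0
    for _, row in df.iterrows():
        obs = response.observation_from_row(row, response.Timepoint(timepoint))
        truth_raw = row.get("pcr") if endpoint == "pcr" else None
        if endpoint == "rcb_le1":
            rc = row.get("rcb_class")
            truth_raw = None if pd.isna(rc) else int(rc) <= 1
        if obs is None or truth_raw is None or (
            isinstance(truth_raw, float) and np.isnan(truth_raw)
        ):
            excluded += 1
            continue
        truth = bool(truth_raw)
        try:
            if predictor == "wi_or_size":
                pred = response.predict_pathresponse(obs)
            else:
                pred = response.predict_by_size(obs)
        except NotEvaluableError:
            excluded += 1
            continue
        if pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif not pred and truth:
            fn += 1
        else:
            tn += 1
    return stats.ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn), excluded


def _fisher_rows(df: pd.DataFrame, config: RunConfig) -> dict:
    """Table-3-style stratified Fisher tests (imaging stratum vs pCR/RD)."""
    out = {}
    ok_pcr = df["pcr"].notna()

    def table_from(stratum: pd.Series, valid: pd.Series, name: str) -> None:
        v = valid & ok_pcr & stratum.notna()
        excluded = int((~v).sum())
        s = stratum[v].astype(bool)
        p = df.loc[v, "pcr"].astype(bool)
        t = stats.ContingencyTable2x2(
            a=int((s & p).sum()), b=int((s & ~p).sum()),
            c=int((~s & p).sum()), d=int((~s & ~p).sum()),
        )
        out[name] = {
            "table": t,
            "p_value": stats.fisher_exact_two_sided(t),
            "n": t.n,
            "excluded": excluded,
        }

    if "lesion_type" in df:
        table_from(df["lesion_type"].eq("mass").where(df["lesion_type"].notna()),
                   df["lesion_type"].notna(), "lesion_type")
    for tpname in ("pre", "mid", "post"):
        size = df[f"size_{tpname}"]
        table_from(size < config.size_stratum_mm, size.notna(), f"size_{tpname}")
    for tpname in ("mid", "post"):
        curve = df[f"curve_{tpname}"]
        has_curve = curve.notna() & (curve != "")
        table_from(curve.eq(CurveClass.FAST_WASHOUT.value).where(has_curve),
                   has_curve, f"curve_{tpname}")
    return out


def _survival_block(
    df: pd.DataFrame, timepoint: str, config: RunConfig, figure_path=None
) -> dict:
    """Three-group DDFS comparison at one timepoint."""
    valid = df["ddfs_years"].notna() & (df["ddfs_years"] > 0) & df["ddfs_event"].notna()
    groups: dict[str, list[survival.SurvivalRecord]] = {}
    excluded = int((~valid).sum())
    for _, row in df[valid].iterrows():
        obs = response.observation_from_row(row, response.Timepoint(timepoint))
        if obs is None:
            excluded += 1
            continue
        try:
            g = response.survival_group(obs).value
        except NotEvaluableError:
            excluded += 1
            continue
        groups.setdefault(g, []).append(
            survival.SurvivalRecord(
                time=float(row["ddfs_years"]), event=bool(row["ddfs_event"]), group=g
            )
        )
    if figure_path is not None and groups:
        from .plots import plot_km

        plot_km(groups, figure_path,
                title=f"DDFS by imaging group at {timepoint}")
    block: dict = {"excluded": excluded, "groups": {}}
    for g, recs in groups.items():
        curve = survival.km_estimate(recs)
        block["groups"][g] = {
            "n": len(recs),
            "events": int(sum(r.event for r in recs)),
            "five_year_ddfs": 100.0 * survival.five_year_ddfs(curve),
        }
    if len(groups) >= 2:
        chi2, p = survival.log_rank(groups)
        block["log_rank"] = {"chi2": chi2, "p_value": p, "df": len(groups) - 1}
    fast = groups.get(response.SurvivalGroup.RD_FAST_WASHOUT.value, [])
    other = groups.get(response.SurvivalGroup.RD_OTHER.value, [])
    if fast and other:
        recs = fast + other
        x = [0.0] * len(fast) + [1.0] * len(other)  # 1 = RD without fast washout
        try:
            cox = survival.cox_ph(recs, covariate=x, ties=config.cox_ties)
            block["cox_rd_other_vs_fast"] = {
                "hr": cox.hr,
                "ci95": list(cox.ci95),
                "p_value": cox.p_value,
                "log_hr": cox.log_hr,
                "se": cox.se,
            }
        except survival.ConvergenceError as exc:
            block["cox_rd_other_vs_fast"] = {"error": str(exc)}
    return block


def cohort_report(
    cohort: pd.DataFrame | str | Path, config: RunConfig | None = None
) -> dict:
    """Full cohort-level statistical report.

    Produces diagnostic performance of both predictors against both
    pathological endpoints at mid/post, stratified Fisher tests,
    Spearman correlations of WI and size against the RCB index and the
    pathological tumour size, pairwise group t-tests of WI, and the
    three-group DDFS analysis (Kaplan-Meier five-year estimates,
    log-rank, Cox hazard ratio).  Per-analysis exclusion counts are
    reported alongside every block.
    """
    config = config or RunConfig()
    df = cohort if isinstance(cohort, pd.DataFrame) else response.read_cohort(cohort)
    missing = [c for c in response.COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise response.SchemaError(f"cohort table is missing columns: {missing}")

    report: dict = {"n_patients": int(len(df))}

    diag = {}
    for endpoint in ("pcr", "rcb_le1"):
        for predictor in ("wi_or_size", "size"):
            for tpname in ("mid", "post"):
                cm, excluded = _confusion_from_cohort(df, tpname, endpoint, predictor)
                perf = stats.diagnostic_performance(cm)
                diag[f"{endpoint}_{predictor}_{tpname}"] = {
                    "matrix": dataclasses.asdict(cm),
                    "n": cm.n,
                    "excluded": excluded,
                    **dataclasses.asdict(perf),
                }
    report["diagnostic_performance"] = diag

    report["fisher"] = {
        k: {
            "table": dataclasses.asdict(v["table"]),
            "p_value": v["p_value"],
            "n": v["n"],
            "excluded": v["excluded"],
        }
        for k, v in _fisher_rows(df, config).items()
    }

    corr = {}
    for tpname in ("mid", "post"):
        for xcol, ycol, name in [
            (f"wi_{tpname}", "rcb_index", f"wi_{tpname}_vs_rcb"),
            (f"size_{tpname}", "rcb_index", f"size_{tpname}_vs_rcb"),
            (f"size_{tpname}", "pt_mm", f"size_{tpname}_vs_pt"),
        ]:
            sub = df[[xcol, ycol]].dropna()
            if name.endswith("_vs_pt"):  # published convention: RD lesions only
                sub = sub[df.loc[sub.index, "pcr"] == False]  # noqa: E712
            if len(sub) >= 3 and sub[xcol].nunique() > 1 and sub[ycol].nunique() > 1:
                r = stats.spearman_rho(sub[xcol], sub[ycol])
                corr[name] = {"rho": r.rho, "p_value": r.p_value, "n": r.n,
                              "excluded": int(len(df) - len(sub))}
    report["spearman"] = corr

    # WI group comparisons (pCR vs RD-no-recurrence vs RD-recurrence)
    ttests = {}
    recur = df["ddfs_event"].fillna(False).astype(bool)
    for tpname in ("pre", "mid", "post"):
        wi = df[f"wi_{tpname}"]
        ok = wi.notna() & df["pcr"].notna()
        g = {
            "pcr": wi[ok & df["pcr"].astype(bool)],
            "rd_norecur": wi[ok & ~df["pcr"].astype(bool) & ~recur],
            "rd_recur": wi[ok & ~df["pcr"].astype(bool) & recur],
        }
        for a, b in [("pcr", "rd_norecur"), ("pcr", "rd_recur"),
                     ("rd_norecur", "rd_recur")]:
            if len(g[a]) >= 2 and len(g[b]) >= 2:
                t, p = stats.two_sample_t(g[a], g[b], welch=config.welch)
                ttests[f"wi_{tpname}_{a}_vs_{b}"] = {
                    "t": t, "p_value": p, "n": [int(len(g[a])), int(len(g[b]))],
                    "means": [float(g[a].mean()), float(g[b].mean())],
                }
    report["t_tests"] = ttests

    outdir = Path(config.output_dir) if config.output_dir else None
    report["survival"] = {
        tpname: _survival_block(
            df, tpname, config,
            figure_path=outdir / f"km_{tpname}.png" if outdir else None,
        )
        for tpname in ("mid", "post")
    }
    if outdir is not None:
        from .plots import plot_wi_groups

        for tpname in ("pre", "mid", "post"):
            wi = df[f"wi_{tpname}"]
            ok = wi.notna() & df["pcr"].notna()
            plot_wi_groups(
                {
                    "pCR": wi[ok & df["pcr"].astype(bool)],
                    "RD no recurrence": wi[ok & ~df["pcr"].astype(bool) & ~recur],
                    "RD recurrence": wi[ok & ~df["pcr"].astype(bool) & recur],
                },
                outdir / f"wi_{tpname}.png",
                title=f"Washout index at {tpname}",
            )
    return report


# ---------------------------------------------------------------------------
# Reproduction report


def reproduce_paper(config: RunConfig | None = None) -> dict:
    """Recompute the published summary statistics from packaged fixtures.

    Re-runs Fisher's exact test on the six published contingency
    tables, diagnostic performance on the reconstructed confusion
    matrices, and the fast-washout boundary examples, and compares each
    computed value with the published one at its printed rounding.
    """
    config = config or RunConfig()
    fx = paper_fixtures()
    report: dict = {"fisher": {}, "diagnostic": {}, "kinetics": {}}

    for name, item in fx["contingency"].items():
        p = stats.fisher_exact_two_sided(item["table"])
        printed = item["printed_p"]
        decimals = 4 if printed not in (1.0,) else 1
        report["fisher"][name] = {
            "computed_p": p,
            "printed_p": printed,
            "pass": round(p, 4) == round(printed, 4),
        }

    for name, item in fx["confusion"].items():
        perf = stats.diagnostic_performance(item["matrix"])
        computed = {k: getattr(perf, k) for k in item["printed"]}
        ok = all(round(computed[k], 1) == item["printed"][k] for k in item["printed"])
        report["diagnostic"][name] = {
            "computed": computed,
            "printed": item["printed"],
            "pass": ok,
        }

    boundary = {
        "ratio_at_200_is_other": kinetics.classify_curve(
            KineticSample(100.0, 200.0, 150.0),
            ratio_threshold=config.ratio_threshold,
            wi_threshold=config.wi_threshold,
        ).curve_class,
        "wi_at_10_with_ratio_above_200_is_fast": kinetics.classify_curve(
            KineticSample(100.0, 250.0, 240.0),
            ratio_threshold=config.ratio_threshold,
            wi_threshold=config.wi_threshold,
        ).curve_class,
        "wi_below_10_is_other": kinetics.classify_curve(
            KineticSample(100.0, 250.0, 241.0),
            ratio_threshold=config.ratio_threshold,
            wi_threshold=config.wi_threshold,
        ).curve_class,
    }
    expected = {
        "ratio_at_200_is_other": CurveClass.OTHER,
        "wi_at_10_with_ratio_above_200_is_fast": CurveClass.FAST_WASHOUT,
        "wi_below_10_is_other": CurveClass.OTHER,
    }
    report["kinetics"] = {
        k: {"computed": v.value, "expected": expected[k].value,
            "pass": v is expected[k]}
        for k, v in boundary.items()
    }
    report["all_pass"] = all(
        item["pass"]
        for section in ("fisher", "diagnostic", "kinetics")
        for item in report[section].values()
    )
    return report


def write_report(report: dict, path) -> None:
    """Write a machine-readable JSON report (full precision)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=str, sort_keys=True)
        fh.write("\n")
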