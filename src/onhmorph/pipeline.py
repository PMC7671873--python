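"""Reproducible simulate -> morphometry -> stats -> report orchestration.

The report bundle is TSV/JSON only and is byte-identical for identical
config + seed: every machine-readable output carries the config hash, and
wall-clock timings go to the log file only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    ChangeTable,
    baseline_contrasts,
    change_from_baseline,
    group_compare,
    multiple_ols,
    ols,
    repeatability,
)
from .errors import AnalysisError, OnhMorphError
from .scan_model import TIME_LABELS
from .synthetic import CohortSimSpec, default_cohort_params, simulate_cohort

log = logging.getLogger("onhmorph.pipeline")

MORPHOMETRY_PARAMS = (
    "mrw", "bmo_height", "alcsd", "bmo_area",
    "trt250", "trt500", "trt1000", "trt1500",
    "rnflt_27", "rnflt_35", "rnflt_42", "rnflt_49",
    "choroidt_27", "choroidt_35", "choroidt_42", "choroidt_49",
)
ALL_PARAMS = ("iop", "onsd", "map", "mopp") + MORPHOMETRY_PARAMS


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    arm: str = "seated"            # seated | hdt | both
    n_subjects: int = 30
    n_female: int = 15
    out_dir: str = "out"
    param_overrides: dict = field(default_factory=dict)  # {param: {field: value}}

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        """Fingerprint of the analytic configuration (output location is
        excluded so relocated reruns stay byte-identical)."""
        data = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_sim_spec(config: RunConfig) -> CohortSimSpec:
    params = default_cohort_params()
    for name, fields in config.param_overrides.items():
        if name not in params:
            raise AnalysisError(f"unknown parameter override {name!r}")
        params[name] = replace(params[name], **fields)
    return CohortSimSpec(
        n_subjects=config.n_subjects,
        n_female=config.n_female,
        seed=config.seed,
        params=params,
    )


# ---------------------------------------------------------------------------
# Stats stages (operate on a cohort table; reused by the stats CLI)
# ---------------------------------------------------------------------------

def repeatability_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Within-subject repeatability from the duplicate 7 a.m. seated scans."""
    dup = cohort[
        (cohort["time_label"] == "7a")
        & (cohort["posture"] == "SEATED")
        & (cohort.get("arm", "seated") == "seated")
    ]
    counts = dup.groupby("subject_id").size()
    subjects = counts[counts == 2].index
    rows = []
    for param in MORPHOMETRY_PARAMS:
        if param not in dup.columns:
            continue
        wide = (
            dup[dup["subject_id"].isin(subjects)]
            .pivot(index="subject_id", columns="replicate", values=param)
            .to_numpy(dtype=float)
        )
        r = repeatability(wide, parameter=param)
        rows.append({
            "parameter": param, "n": r.n_subjects, "sw": r.sw,
            "repeatability": r.repeatability, "cv_percent": r.cv_percent,
        })
    if not rows:
        raise AnalysisError("no duplicate 7 a.m. seated sessions in cohort")
    return pd.DataFrame(rows)


def baseline_table(cohort: pd.DataFrame) -> pd.DataFrame:
    base = cohort[
        (cohort["time_label"] == "7a")
        & (cohort["posture"] == "SEATED")
        & (cohort["replicate"] == 1)
    ]
    rows = []
    for arm in sorted(base.get("arm", pd.Series(["seated"] * len(base))).unique()):
        sub = base[base["arm"] == arm] if "arm" in base.columns else base
        for param in ALL_PARAMS:
            if param not in sub.columns:
                continue
            v = sub[param].dropna()
            rows.append({
                "arm": arm, "parameter": param, "n": len(v),
                "mean": float(v.mean()), "sd": float(v.std(ddof=1)),
            })
    return pd.DataFrame(rows)


def _sessions_for_arm(arm: str) -> list[tuple[str, str]]:
    if arm == "seated":
        return [(tl, "SEATED") for tl in TIME_LABELS[1:]]
    return [(tl, "HDT") for tl in TIME_LABELS]


def contrast_tables(cohort: pd.DataFrame, arm: str) -> tuple[ChangeTable, pd.DataFrame]:
    """Change-from-baseline summaries and per-time-point many-to-one
    contrasts for one experiment arm."""
    sub = cohort[cohort["arm"] == arm] if "arm" in cohort.columns else cohort
    params = [p for p in ALL_PARAMS if p in sub.columns]
    changes = change_from_baseline(sub, params)
    rows = []
    order = _sessions_for_arm(arm)
    for param in params:
        try:
            res = baseline_contrasts(sub, param, order)
        except AnalysisError as exc:
            log.warning("contrasts skipped for %s (%s): %s", param, arm, exc)
            continue
        for (tl, posture), diff, t, p in zip(
            order, res.mean_differences, res.t_statistics, res.p_adjusted
        ):
            rows.append({
                "parameter": param, "time_label": tl, "posture": posture,
                "mean_diff": diff, "t": t, "p_adjusted": p,
                "f_statistic": res.f_statistic, "p_anova": res.p_anova,
                "n": res.n_subjects,
            })
    return changes, pd.DataFrame(rows)


def regression_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Between-parameter relationships on the seated arm (endpoint changes)."""
    sub = cohort[cohort["arm"] == "seated"] if "arm" in cohort.columns else cohort
    params = [p for p in ALL_PARAMS if p in sub.columns]
    changes = change_from_baseline(sub, params).deltas
    base = sub[
        (sub["time_label"] == "7a") & (sub["posture"] == "SEATED")
        & (sub["replicate"] == 1)
    ].set_index("subject_id")

    def _delta(param: str, tl: str) -> pd.Series:
        d = changes[(changes["parameter"] == param) & (changes["time_label"] == tl)]
        return d.set_index("subject_id")["delta"]

    rows = []

    def _ols_row(name, x, y):
        x, y = x.align(y, join="inner")
        try:
            r = ols(x.to_numpy(), y.to_numpy())
        except AnalysisError as exc:
            log.warning("regression %s skipped: %s", name, exc)
            return
        rows.append({"relationship": name, "kind": "ols", "slope": r.slope,
                     "intercept": r.intercept, "r2": r.r2, "p": r.p_value, "n": r.n})

    _ols_row("d_choroidt_42_1p~d_bmo_height_1p",
             _delta("choroidt_42", "1p"), _delta("bmo_height", "1p"))
    _ols_row("baseline_mrw~d_mrw_7p", base["mrw"], _delta("mrw", "7p"))
    _ols_row("d_mrw_7p~d_trt250_7p", _delta("mrw", "7p"), _delta("trt250", "7p"))

    y = _delta("mrw", "7p")
    x1 = _delta("iop", "7p")
    x2 = _delta("onsd", "7p")
    common = y.index.intersection(x1.index).intersection(x2.index)
    try:
        m = multiple_ols(y.loc[common], x1.loc[common], x2.loc[common])
        rows.append({
            "relationship": "d_mrw_7p~d_iop_7p+d_onsd_7p", "kind": "multiple_ols",
            "slope": m.coefficients[1], "intercept": m.coefficients[0],
            "r2": m.r2, "p": m.f_p_value, "n": m.n,
        })
    except AnalysisError as exc:
        log.warning("multiple regression skipped: %s", exc)

    d7 = _delta("mrw", "7p")
    sex = base["sex"].reindex(d7.index)
    try:
        g = group_compare(d7.to_numpy(), sex.to_numpy())
        rows.append({
            "relationship": "d_mrw_7p~sex", "kind": "unpaired_t",
            "slope": g.mean_difference, "intercept": float("nan"),
            "r2": float("nan"), "p": g.p_value, "n": g.n1 + g.n2,
        })
    except AnalysisError as exc:
        log.warning("sex comparison skipped: %s", exc)
    return pd.DataFrame(rows)


def paired_posture_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Paired seated-vs-HDT comparison of change from baseline, per time
    point, for subjects with both experiment days."""
    if "arm" not in cohort.columns:
        raise AnalysisError("paired comparison requires an 'arm' column")
    params = [p for p in ALL_PARAMS if p in cohort.columns]
    seated = change_from_baseline(cohort[cohort["arm"] == "seated"], params).deltas
    hdt = change_from_baseline(cohort[cohort["arm"] == "hdt"], params).deltas
    hdt = hdt[hdt["posture"] == "HDT"]
    rows = []
    for param in params:
        for tl in TIME_LABELS[1:]:
            a = seated[(seated["parameter"] == param) & (seated["time_label"] == tl)]
            b = hdt[(hdt["parameter"] == param) & (hdt["time_label"] == tl)]
            merged = a.merge(b, on="subject_id", suffixes=("_seated", "_hdt"))
            merged = merged.dropna(subset=["delta_seated", "delta_hdt"])
            if len(merged) < 2:
                continue
            vals = np.concatenate([merged["delta_seated"], merged["delta_hdt"]])
            grp = ["seated"] * len(merged) + ["hdt"] * len(merged)
            subj = np.tile(merged["subject_id"].to_numpy(), 2)
            g = group_compare(vals, grp, paired=True, subjects=subj)
            rows.append({
                "parameter": param, "time_label": tl,
                "mean_diff_hdt_minus_seated": -g.mean_difference,
                "t": g.t_statistic, "p": g.p_value, "n_pairs": g.n1,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundle writing
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full simulate -> stats -> report pipeline.

    Returns the machine-readable summary (also written to
    ``out/summary.json``).  Raises on any stage failure after flagging the
    partial outputs in the summary.
    """
    out = Path(config.out_dir)
    for sub in ("tables", "logs", "meta"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "logs" / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    chash = config.config_hash
    summary: dict = {
        "config_hash": chash,
        "seed": config.seed,
        "arm": config.arm,
        "version": __version__,
        "tables": {},
        "stages": {},
    }
    try:
        t0 = time.perf_counter()
        spec = build_sim_spec(config)
        sim_arm = "both" if config.arm == "hdt" else config.arm
        cohort = simulate_cohort(spec, arm=sim_arm)
        log.info("simulate: %d rows in %.2fs", len(cohort), time.perf_counter() - t0)
        summary["stages"]["simulate"] = {"rows": int(len(cohort))}
        _write_tsv(cohort, out / "tables" / "cohort.tsv", chash)

        arms = sorted(cohort["arm"].unique())

        rep = repeatability_table(cohort)
        _write_tsv(rep, out / "tables" / "repeatability.tsv", chash)
        summary["tables"]["repeatability"] = "tables/repeatability.tsv"
        summary["repeatability_mrw_um"] = float(
            rep.loc[rep["parameter"] == "mrw", "repeatability"].iloc[0]
        )

        bl = baseline_table(cohort)
        _write_tsv(bl, out / "tables" / "baseline.tsv", chash)
        summary["tables"]["baseline"] = "tables/baseline.tsv"

        for arm in arms:
            changes, contrasts = contrast_tables(cohort, arm)
            _write_tsv(changes.summary, out / "tables" / f"change_{arm}.tsv", chash)
            _write_tsv(contrasts, out / "tables" / f"contrasts_{arm}.tsv", chash)
            summary["tables"][f"change_{arm}"] = f"tables/change_{arm}.tsv"
            summary["tables"][f"contrasts_{arm}"] = f"tables/contrasts_{arm}.tsv"
            if arm == "seated":
                mrow = changes.summary[
                    (changes.summary["parameter"] == "mrw")
                    & (changes.summary["time_label"] == "7p")
                ]
                summary["mean_mrw_change_7p_um"] = float(mrow["mean"].iloc[0])
            log.info("stats arm=%s: %d contrast rows", arm, len(contrasts))

        reg = regression_table(cohort)
        _write_tsv(reg, out / "tables" / "regression.tsv", chash)
        summary["tables"]["regression"] = "tables/regression.tsv"

        if set(arms) >= {"seated", "hdt"}:
            paired = paired_posture_table(cohort)
            _write_tsv(paired, out / "tables" / "paired_seated_vs_hdt.tsv", chash)
            summary["tables"]["paired_seated_vs_hdt"] = "tables/paired_seated_vs_hdt.tsv"

        meta = {"config": config.to_dict(), "config_hash": chash,
                "version": __version__}
        with open(out / "meta" / "config.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
            fh.write("\n")
        summary["status"] = "ok"
    except OnhMorphError:
        summary["status"] = "failed"
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        log.removeHandler(handler)
        handler.close()
        raise
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.removeHandler(handler)
    handler.close()
    return summary
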