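"""End-to-end pipeline: simulate -> events -> match -> survival -> mri -> report.

Each stage reads and writes only the published CSV/JSON schemas, so the
modelling stages run identically on simulated or user-supplied cohorts. A
run manifest records the config hash, seed, per-stage timings and row
counts for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import GROUPS, SimulationConfig, config_hash
from .events import build_survival_records, detect_events
from .longitudinal import (
    analyze_prl,
    apc_frame,
    fit_apc_model,
    fit_dti_suite,
    run_bvl_sensitivity_suite,
)
from .matching import (
    DEFAULT_COVARIATES,
    SeparationError,
    balance_table,
    fit_propensity,
    match_1to1,
    pairs_frame,
    smd_series,
    MatchedPair,
)
from .survival import CoxResult, km_estimate, km_frame, run_endpoint_suite
from .synthetic import Cohort, read_cohort, simulate_cohort, write_cohort
from .config import VOLUMETRIC_OUTCOMES

log = logging.getLogger("smoldercmp")

ALL_STAGES = ("simulate", "events", "match", "survival", "mri", "report")


@dataclass
class PipelineConfig:
    """Validated top-level configuration (unknown keys rejected)."""

    seed: int = 0
    out_dir: str = "smoldercmp_out"
    stages: tuple = ALL_STAGES
    input_dir: Optional[str] = None  # read an existing cohort instead of simulating
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    confirmation_window: int = 180
    sustained: bool = True
    pre_window: int = 90
    indeterminate_as_event: bool = False
    caliper_sd: float = 0.2
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    tie_method: str = "efron"
    apc_spec: str = "log_outcome"
    run_dti: bool = True
    run_prl: bool = True
    run_bvl_sensitivity: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        sim = d.pop("simulation", {})
        cfg = cls(**d)
        if isinstance(sim, SimulationConfig):
            cfg.simulation = sim
        else:
            sim = dict(sim)
            sim.setdefault("seed", cfg.seed)
            cfg.simulation = SimulationConfig.from_dict(sim)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update(overrides)
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _validate_schema(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing required column(s) {missing}")


def _endpoint_masks(cohort: Cohort) -> dict[str, pd.Series]:
    """Data-availability eligibility per endpoint cohort."""
    pts = cohort.patients
    clinical = pd.Series(True, index=pts.index)
    mri = cohort.mri
    def has(col):
        if mri.empty:
            return pd.Series(False, index=pts.index)
        ok = set(mri.dropna(subset=[col])["patient_id"])
        return pts["patient_id"].isin(ok)

    return {
        "clinical": clinical,
        "atrophy": has("brain_ml"),
        "dti": has("fa_nawm"),
        "prl": has("prl_count"),
    }


def match_endpoint(
    cohort: Cohort, mask: pd.Series, cfg: PipelineConfig
) -> tuple[list[MatchedPair], pd.DataFrame]:
    """Propensity fit + 1:1 matching restricted to an eligibility mask."""
    pts = cohort.patients[mask]
    model = fit_propensity(pts, cfg.covariates)
    pairs = match_1to1(pts, model.scores, cfg.caliper_sd, seed=cfg.seed)
    return pairs, pts


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings, rows = {}, {}
    manifest_cfg = cfg.to_dict()

    def clock(name):
        return _StageTimer(name, timings)

    # --- cohort ------------------------------------------------------------
    with clock("simulate"):
        if cfg.input_dir is not None:
            cohort = read_cohort(cfg.input_dir)
        else:
            cohort = simulate_cohort(cfg.simulation)
        _validate_schema(
            cohort.patients,
            ["patient_id", "group", "last_visit_day"],
            "patients.csv",
        )
        _validate_schema(cohort.visits, ["patient_id", "day", "edss"], "visits.csv")
        if "simulate" in cfg.stages:
            write_cohort(cohort, out)
    rows["patients"] = len(cohort.patients)
    rows["visits"] = len(cohort.visits)
    rows["relapses"] = len(cohort.relapses)
    rows["mri"] = len(cohort.mri)

    events = None
    if "events" in cfg.stages:
        with clock("events"):
            events = detect_events(
                cohort.visits,
                cohort.relapses,
                cohort.mri,
                confirmation_window=cfg.confirmation_window,
                sustained=cfg.sustained,
                pre_window=cfg.pre_window,
            )
            events.to_csv(out / "events.csv", index=False, lineterminator="\n")
            survival_records = build_survival_records(
                cohort.patients,
                events,
                endpoint="pira",
                visits=cohort.visits,
            )
            survival_records.to_csv(
                out / "survival.csv", index=False, lineterminator="\n"
            )
        rows["events"] = len(events)

    pairs_by_endpoint: dict[str, list[MatchedPair]] = {}
    if "match" in cfg.stages:
        with clock("match"):
            masks = _endpoint_masks(cohort)
            all_pairs, all_balance = [], []
            for endpoint, mask in masks.items():
                if mask.sum() < 20:
                    log.warning("endpoint %s: too few eligible patients", endpoint)
                    continue
                try:
                    pairs, pts = match_endpoint(cohort, mask, cfg)
                except SeparationError as e:
                    log.warning("endpoint %s: propensity fit degenerate (%s); "
                                "left unmatched", endpoint, e)
                    continue
                pairs_by_endpoint[endpoint] = pairs
                all_pairs.append(pairs_frame(pairs, endpoint))
                if pairs:
                    tbl = balance_table(pts, pairs, cfg.covariates, endpoint)
                    pre = smd_series(
                        pts,
                        list(pts.loc[pts["group"] == "teriflunomide", "patient_id"]),
                        list(pts.loc[pts["group"] == "ocrelizumab", "patient_id"]),
                        cfg.covariates,
                    )
                    tbl.insert(
                        tbl.columns.get_loc("smd"),
                        "smd_prematch",
                        tbl["variable"].map(pre).to_numpy(),
                    )
                    all_balance.append(tbl)
            pd.concat(all_pairs, ignore_index=True).to_csv(
                out / "pairs.csv", index=False, lineterminator="\n"
            ) if all_pairs else None
            if all_balance:
                pd.concat(all_balance, ignore_index=True).to_csv(
                    out / "balance.csv", index=False, lineterminator="\n"
                )
        rows["pairs"] = sum(len(v) for v in pairs_by_endpoint.values())

    if "survival" in cfg.stages and events is not None:
        with clock("survival"):
            pairs = pairs_by_endpoint.get("clinical", [])
            results = run_endpoint_suite(
                cohort.patients,
                events,
                pairs,
                tie_method=cfg.tie_method,
                indeterminate_as_event=cfg.indeterminate_as_event,
            )
            payload = {
                k: (v.to_dict() if isinstance(v, CoxResult) else v)
                for k, v in results.items()
            }
            (out / "cox_results.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True)
            )
            matched_ids = {p.teri_id for p in pairs} | {p.ocre_id for p in pairs}
            rec = build_survival_records(
                cohort.patients[
                    cohort.patients["patient_id"].astype(str).isin(matched_ids)
                ],
                events,
            )
            if len(rec):
                km_frame(km_estimate(rec)).to_csv(
                    out / "km_curves.csv", index=False, lineterminator="\n"
                )
        rows["cox_analyses"] = len(results)

    apc_results = []
    prl_result = None
    if "mri" in cfg.stages and not cohort.mri.empty:
        with clock("mri"):
            merged = cohort.mri.merge(
                cohort.patients[["patient_id", "group"]], on="patient_id"
            )

            def subset(endpoint):
                ps = pairs_by_endpoint.get(endpoint)
                if not ps:
                    return merged
                ids = {p.teri_id for p in ps} | {p.ocre_id for p in ps}
                return merged[merged["patient_id"].astype(str).isin(ids)]

            atrophy = subset("atrophy").dropna(subset=["brain_ml"])
            if len(atrophy):
                for outcome in VOLUMETRIC_OUTCOMES:
                    apc_results.append(
                        fit_apc_model(atrophy, outcome, spec=cfg.apc_spec)
                    )
                if cfg.run_bvl_sensitivity:
                    apc_results.extend(
                        run_bvl_sensitivity_suite(
                            atrophy.drop(columns=["group"]),
                            cohort.patients,
                            cohort.relapses,
                            spec=cfg.apc_spec,
                        )
                    )
            if cfg.run_dti:
                dti = subset("dti").dropna(subset=["fa_nawm"])
                if len(dti):
                    apc_results.extend(fit_dti_suite(dti, spec=cfg.apc_spec))
            if cfg.run_prl:
                prl = subset("prl").dropna(subset=["prl_count"])
                if len(prl):
                    prl_result = analyze_prl(prl)
                    (out / "prl_results.json").write_text(
                        json.dumps(
                            {
                                "n_new": prl_result.n_new,
                                "n_resolving": prl_result.n_resolving,
                                "group_sizes": prl_result.group_sizes,
                                "interaction_p": prl_result.interaction_p,
                                "note": prl_result.note,
                            },
                            indent=2,
                            sort_keys=True,
                        )
                    )
            if apc_results:
                apc_frame(apc_results).to_csv(
                    out / "apc_results.csv", index=False, lineterminator="\n"
                )
        rows["apc_models"] = len(apc_results)

    if "report" in cfg.stages:
        with clock("report"):
            render_reports(out, cohort)

    manifest = {
        "config_hash": config_hash(manifest_cfg),
        "seed": cfg.seed,
        "version": __version__,
        "stage_seconds": timings,
        "row_counts": rows,
    }
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(out / "manifest.json")
    return manifest


class _StageTimer:
    def __init__(self, name, sink):
        self.name, self.sink = name, sink

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, *exc):
        self.sink[self.name] = round(time.perf_counter() - self.t0, 3)
        log.info("stage %s: %.2fs", self.name, self.sink[self.name])
        return False


# ---------------------------------------------------------------------------
# reports

TABLE1_ROWS = [
    ("age", "Age, mean (SD), years"),
    ("sex", "Females, No. (%)"),
    ("disease_duration_years", "Disease duration, median [IQR], years"),
    ("edss_baseline", "EDSS, median [IQR]"),
    ("n_prior_dmts", "Number of previous DMTs, median [IQR]"),
    ("time_under_treatment_years", "Time under current treatment, median [IQR], years"),
    ("snfl_pg_ml", "sNfL, median [IQR], pg/ml"),
    ("snfl_z", "sNfL Z-score, median [IQR]"),
    ("t2_volume_ml", "T2LV, median [IQR], ml"),
    ("t2_count", "T2L count, median [IQR]"),
]


def baseline_characteristics(patients: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics table: mean (SD) for age, n (%) for sex,
    median [IQR] otherwise."""
    rows = [("n", str(len(patients)))]
    for col, label in TABLE1_ROWS:
        if col == "age":
            v = patients[col]
            rows.append((label, f"{v.mean():.1f} ({v.std(ddof=1):.1f})"))
        elif col == "sex":
            n_f = int((patients[col] == "F").sum())
            rows.append((label, f"{n_f} ({100 * n_f / len(patients):.1f})"))
        else:
            v = patients[col].astype(float)
            q1, q2, q3 = np.percentile(v.dropna(), [25, 50, 75])
            rows.append((label, f"{q2:.1f} [{q1:.1f}; {q3:.1f}]"))
    return pd.DataFrame(rows, columns=["characteristic", "value"])


def render_reports(out: Path, cohort: Cohort) -> list[Path]:
    """Render the report tables + Kaplan-Meier figure from emitted files."""
    out = Path(out)
    written = []
    rep = out / "reports"
    rep.mkdir(exist_ok=True)

    t1 = baseline_characteristics(cohort.patients)
    p = rep / "table1_baseline.csv"
    t1.to_csv(p, index=False, lineterminator="\n")
    written.append(p)

    for name in ("balance.csv", "apc_results.csv"):
        src = out / name
        if not src.exists():
            log.warning("report: missing upstream file %s; skipped", name)

    km_path = out / "km_curves.csv"
    if km_path.exists():
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        km = pd.read_csv(km_path)
        fig, ax = plt.subplots(figsize=(6, 4))
        for g, sub in km.groupby("group"):
            ax.step(sub["time_years"], sub["survival"], where="post", label=g)
        ax.set_xlabel("Years since treatment start")
        ax.set_ylabel("PIRA-free survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        fig.tight_layout()
        fp = rep / "km_pira.png"
        fig.savefig(fp, dpi=120)
        plt.close(fig)
        written.append(fp)

    prl_path = out / "prl_results.json"
    summary = rep / "table3_longitudinal.csv"
    apc_path = out / "apc_results.csv"
    if apc_path.exists():
        apc = pd.read_csv(apc_path)
        apc["cell"] = apc.apply(
            lambda r: (
                "not estimable"
                if pd.isna(r["apc"])
                else f"{r['apc']:.2f} ({r['ci_low']:.2f}; {r['ci_high']:.2f})"
            ),
            axis=1,
        )
        wide = apc.pivot_table(
            index=["outcome", "variant", "interaction_p"],
            columns="group",
            values="cell",
            aggfunc="first",
        ).reset_index()
        wide.to_csv(summary, index=False, lineterminator="\n")
        written.append(summary)
    elif prl_path.exists():
        pass
    return written
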