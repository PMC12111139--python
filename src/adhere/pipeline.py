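"""End-to-end orchestration: configuration, stage wiring, report rendering.

``run_pipeline`` is a pure function of (input files, configuration): the same
claims file, formulary and config produce byte-identical reports.  Outputs
are flat CSVs mirroring the analysis stages — cohort cascade, monthly plots
with their reassignment audit, PDC assessment periods, adherence summaries,
PDD, exact-test and logistic-regression reports — plus four formatted
summary tables (population groups by adherence/gender/therapy/diagnostic
code; TAG month proportions; PDC/PDD by therapy arm; overall MPH PDC/PDD).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .claims_io import (
    ANTIDEPRESSANT_CLASSES,
    DrugClass,
    Formulary,
    patient_age,
    read_claims,
    write_rejects,
)
from .cohort import (
    CohortConfig,
    CohortStatus,
    build_cohort,
    filter_tricyclic_misuse,
)
from .monthly_plot import (
    DrugType,
    PlotConfig,
    build_monthly_grid,
    classify_tag,
    drug_type_of,
)
from .pdc_engine import PdcConfig, average_pdc, compute_pdd, coverage_intervals, segment_periods
from .stats import (
    ContingencyTable2x2,
    age_band,
    fisher_exact,
    fit_tag_logistic,
    month_proportions,
)

__all__ = ["RunConfig", "run_pipeline", "render_group_table", "percentage", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    claims: str = "claims.csv"
    formulary: str = ""  # blank = packaged default
    out_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"
    study_start: dt.date = dt.date(2012, 1, 1)
    study_end: dt.date = dt.date(2016, 12, 31)
    index_year: int = 2015
    min_age: int = 18
    max_age: int = 40
    tca_short_term_days: int = 14
    mood_icd_prefixes: str = "F32,F33,F34,F38,F39,F41"
    tag_policy: str = "AND"
    tag_total_min: int = 12
    tag_window_min: int = 7
    tag_window_months: int = 12
    rule1_min_gap_days: int = 21
    rule2_tolerance: float = 0.20
    short_supply_days: int = 14
    pdc_cap: bool = False
    pdc_threshold: float = 0.80
    mph_ddd_mg: float = 30.0

    _DATES = ("study_start", "study_end")
    _INTS = (
        "seed", "index_year", "min_age", "max_age", "tca_short_term_days",
        "tag_total_min", "tag_window_min", "tag_window_months",
        "rule1_min_gap_days", "short_supply_days",
    )
    _FLOATS = ("rule2_tolerance", "pdc_threshold", "mph_ddd_mg")
    _BOOLS = ("pdc_cap",)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = cls()
        known = {f.name for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
            setattr(cfg, key, cls._coerce(key, value))
        return cfg

    @classmethod
    def _coerce(cls, key, value):
        if key in cls._DATES:
            return dt.date.fromisoformat(value)
        if key in cls._INTS:
            return int(value)
        if key in cls._FLOATS:
            return float(value)
        if key in cls._BOOLS:
            return value.lower() in ("1", "true", "yes", "on")
        return value

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, dt.date):
                v = v.isoformat()
            lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            study_start=self.study_start,
            study_end=self.study_end,
            index_year=self.index_year,
            min_age=self.min_age,
            max_age=self.max_age,
            tca_short_term_days=self.tca_short_term_days,
            mood_icd_prefixes=tuple(
                p.strip() for p in self.mood_icd_prefixes.split(",") if p.strip()
            ),
        )

    def plot_config(self) -> PlotConfig:
        return PlotConfig(
            study_start=self.study_start,
            study_end=self.study_end,
            rule1_min_gap_days=self.rule1_min_gap_days,
            rule2_tolerance=self.rule2_tolerance,
            short_supply_days=self.short_supply_days,
            tag_policy=self.tag_policy,
            tag_total_min=self.tag_total_min,
            tag_window_min=self.tag_window_min,
            tag_window_months=self.tag_window_months,
        )

    def pdc_config(self) -> PdcConfig:
        return PdcConfig(
            cap_pdc=self.pdc_cap,
            database_end=self.study_end + dt.timedelta(days=1),
        )


def percentage(numerator: int, denominator: int) -> Optional[float]:
    """Two-decimal percentage; None (rendered blank) for an empty denominator."""
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, 2)


def _mean(values) -> Optional[float]:
    vals = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not vals:
        return None
    return sum(vals) / len(vals)


def _pooled_intervals(claims):
    """Coverage intervals for a therapy type, dose estimated per drug code."""
    by_code: dict[str, list] = {}
    for c in claims:
        by_code.setdefault(c.drug_code, []).append(c)
    out = []
    for cs in by_code.values():
        out.extend(coverage_intervals(cs))
    return sorted(out, key=lambda iv: iv.start)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write all reports into the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    formulary = (
        Formulary.from_csv(config.formulary) if config.formulary else Formulary.default()
    )

    # --- read ---------------------------------------------------------------
    try:
        result = read_claims(
            config.claims, formulary,
            study_start=config.study_start, study_end=config.study_end,
        )
    except (OSError, ValueError) as err:
        raise PipelineError("claims_io", "read_failed", str(err)) from err
    write_rejects(result.rejects, out / "rejects.csv")
    records = sorted(result.records, key=lambda r: r.patient_id)

    # --- cohort -------------------------------------------------------------
    assignments, gates = build_cohort(records, config.cohort_config())
    by_id = {r.patient_id: r for r in records}
    pd.DataFrame(
        [
            {
                "patient_id": a.patient_id,
                "status": a.status.value,
                "group": a.group.value,
                "reasons": "; ".join(a.reasons),
            }
            for a in assignments
        ]
    ).to_csv(out / "cohort_report.csv", index=False)
    pd.DataFrame([gates.as_dict()]).to_csv(out / "gate_counts.csv", index=False)
    included = [a for a in assignments if a.status is CohortStatus.INCLUDED]

    # --- monthly plotting + PDC per patient ---------------------------------
    plot_cfg = config.plot_config()
    pdc_cfg = config.pdc_config()
    cohort_cfg = config.cohort_config()
    plot_rows, audit_rows, period_rows, summary_rows, tca_rows = [], [], [], [], []
    patients_df_rows = []
    tag_month_rows = []

    for a in included:
        rec = by_id[a.patient_id]
        ad_claims = rec.claims_of_class(ANTIDEPRESSANT_CLASSES)
        kept_ad, dropped_ad = filter_tricyclic_misuse(
            ad_claims, formulary,
            short_term_days=cohort_cfg.tca_short_term_days,
            mood_icd_prefixes=cohort_cfg.mood_icd_prefixes,
        )
        for c in dropped_ad:
            tca_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "dispense_date": c.dispense_date.isoformat(),
                    "drug_code": c.drug_code,
                    "strength_mg": c.strength_mg,
                    "quantity_units": c.quantity_units,
                    "icd10_codes": ";".join(c.icd10_codes),
                }
            )

        plots = {}
        for dtype, claims in (
            (DrugType.MPH, [c for c in rec.claims if drug_type_of(c.drug_class) is DrugType.MPH]),
            (DrugType.AD, kept_ad),
        ):
            plot = build_monthly_grid(rec, dtype, plot_cfg, claims=claims)
            plots[dtype] = plot
            for i, cell in enumerate(plot.months):
                if cell.units_assigned == 0:
                    continue
                y = config.study_start.year + i // 12
                m = i % 12 + 1
                plot_rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "drug_type": dtype.value,
                        "month": f"{y:04d}-{m:02d}",
                        "units": cell.units_assigned,
                        "short_supply": cell.short_supply_flag,
                        "reassigned": cell.reassigned,
                    }
                )
            for d in plot.decisions:
                audit_rows.append(
                    {
                        "patient_id": d.patient_id,
                        "drug_type": d.drug_type.value,
                        "dispense_date": d.claim.dispense_date.isoformat(),
                        "original_month": d.original_month,
                        "assigned_month": d.assigned_month,
                        "rule": d.rule.value,
                        "rationale": d.rationale,
                    }
                )
        tag = classify_tag(plots.values(), plot_cfg)

        per_type = {}
        for dtype, claims in (
            (DrugType.MPH, [c for c in rec.claims if drug_type_of(c.drug_class) is DrugType.MPH]),
            (DrugType.AD, kept_ad),
        ):
            intervals = _pooled_intervals(claims)
            periods = segment_periods(intervals, pdc_cfg)
            avg = average_pdc(periods)
            cov_total = sum(p.covered for p in periods)
            per_type[dtype] = (periods, avg, cov_total)
            for p in periods:
                period_rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "drug_type": dtype.value,
                        "start": p.start.isoformat(),
                        "end": p.end.isoformat(),
                        "duration_days": p.duration_days,
                        "covered_days": p.covered,
                        "pdc": round(p.pdc, 4),
                        "rule_applied": p.rule.value,
                    }
                )

        mph_claims = [c for c in rec.claims if c.drug_class is DrugClass.MPH]
        pdd = compute_pdd(
            mph_claims, per_type[DrugType.MPH][2],
            patient_id=rec.patient_id, drug_type="MPH", ddd_mg=config.mph_ddd_mg,
        )
        months_supplied = {d: sum(p.issue_months()) for d, p in plots.items()}
        for dtype in (DrugType.MPH, DrugType.AD):
            periods, avg, cov_total = per_type[dtype]
            summary_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "drug_type": dtype.value,
                    "n_periods": len(periods),
                    "months_supplied": months_supplied[dtype],
                    "tag": tag.tag,
                    "average_pdc": None if avg is None else round(avg, 4),
                    "total_mg": sum(c.total_mg for c in (
                        mph_claims if dtype is DrugType.MPH else kept_ad)),
                    "pdd_mg_per_day": (
                        round(pdd.pdd_mg_per_day, 2) if dtype is DrugType.MPH and pdd else None
                    ),
                    "ratio_to_ddd": (
                        round(pdd.ratio_to_ddd, 3)
                        if dtype is DrugType.MPH and pdd and pdd.ratio_to_ddd
                        else None
                    ),
                }
            )
        if tag.tag:
            tag_month_rows.append(
                (rec.patient_id, months_supplied[DrugType.MPH], months_supplied[DrugType.AD])
            )
        ref_age = patient_age(rec, dt.date(config.index_year, 7, 1))
        patients_df_rows.append(
            {
                "patient_id": rec.patient_id,
                "gender": rec.gender,
                "group": a.group.value,
                "age_band": age_band(ref_age),
                "tag": tag.tag,
                "on_ad": bool(kept_ad),
                "mph_pdc": per_type[DrugType.MPH][1],
                "ad_pdc": per_type[DrugType.AD][1],
                "mph_pdd": pdd.pdd_mg_per_day if pdd else None,
            }
        )

    pd.DataFrame(plot_rows).to_csv(out / "monthly_plot.csv", index=False)
    pd.DataFrame(audit_rows).to_csv(out / "reassignment_audit.csv", index=False)
    pd.DataFrame(tca_rows).to_csv(out / "tca_excluded.csv", index=False)
    pd.DataFrame(period_rows).to_csv(out / "periods.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(out / "adherence_summary.csv", index=False)

    patients = pd.DataFrame(patients_df_rows)

    # --- statistics ----------------------------------------------------------
    fisher_rows = []
    if len(patients):
        thr = config.pdc_threshold
        comparisons = [
            ("mph_adherent_x_f90", "mph_pdc", patients["group"] == "F90"),
            ("mph_adherent_x_ad_cotherapy", "mph_pdc", patients["on_ad"]),
            ("ad_adherent_x_f90", "ad_pdc", patients["group"] == "F90"),
        ]
        for name, col, grouping in comparisons:
            sub = patients.dropna(subset=[col])
            if not len(sub):
                continue
            grp = grouping.loc[sub.index].astype(bool)
            adherent = sub[col] >= thr
            table = ContingencyTable2x2(
                a=int((grp & adherent).sum()),
                b=int((grp & ~adherent).sum()),
                c=int((~grp & adherent).sum()),
                d=int((~grp & ~adherent).sum()),
            )
            fisher_rows.append(
                {
                    "comparison": name, "a": table.a, "b": table.b,
                    "c": table.c, "d": table.d,
                    "p_value": fisher_exact(table), "method": "fisher_exact_two_sided",
                }
            )
    pd.DataFrame(fisher_rows).to_csv(out / "stats_fisher.csv", index=False)

    logit_rows = []
    if len(patients) >= 20 and patients["tag"].nunique() == 2:
        design = patients[["gender", "group", "on_ad", "age_band"]].rename(
            columns={"on_ad": "ad_cotherapy"}
        )
        fit = fit_tag_logistic(design, patients["tag"].tolist())
        for term in fit.coefficients:
            logit_rows.append(
                {
                    "term": term,
                    "coefficient": round(fit.coefficients[term], 6),
                    "odds_ratio": round(fit.odds_ratios[term], 6),
                    "wald_chisq": round(fit.wald_chisq[term], 6),
                    "wald_p": round(fit.wald_p[term], 6),
                    "lrt_p": "",
                    "status": fit.status,
                }
            )
        for term, p in fit.type3_lrt_p.items():
            logit_rows.append(
                {
                    "term": f"type3:{term}", "coefficient": "", "odds_ratio": "",
                    "wald_chisq": "", "wald_p": "", "lrt_p": round(p, 6),
                    "status": fit.status,
                }
            )
    pd.DataFrame(
        logit_rows,
        columns=["term", "coefficient", "odds_ratio", "wald_chisq", "wald_p", "lrt_p", "status"],
    ).to_csv(out / "logistic_summary.csv", index=False)

    # --- summary tables -------------------------------------------------------
    render_group_table(patients).to_csv(out / "table_population_groups.csv", index=False)
    _tag_proportion_table(patients, tag_month_rows).to_csv(
        out / "table_tag_month_proportions.csv", index=False
    )
    _therapy_table(patients).to_csv(out / "table_therapy_pdc_pdd.csv", index=False)
    _overall_mph_table(patients).to_csv(out / "table_mph_overall.csv", index=False)

    # --- manifest -------------------------------------------------------------
    cfg_text = config.to_text()
    (out / "config_used.cfg").write_text(cfg_text)
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "n_patients": len(records),
        "n_included": len(included),
        "n_rejected_rows": len(result.rejects),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def render_group_table(patients: pd.DataFrame) -> pd.DataFrame:
    """Population-group table: counts, two-decimal percentages, mean PDCs.

    ``patients`` carries one row per included patient with ``group``,
    ``gender``, ``tag`` (regular use), ``on_ad`` (antidepressant co-therapy)
    and the per-type mean PDCs.  Empty cells keep a zero count and a blank
    PDC, never 0.0.
    """
    rows = []

    def cell(label, sub: pd.DataFrame, denom: int):
        rows.append(
            {
                "row": label,
                "n": len(sub),
                "denominator": denom,
                "percent": percentage(len(sub), denom),
                "mean_ad_pdc": _mean(sub["ad_pdc"]) if len(sub) else None,
                "mean_mph_pdc": _mean(sub["mph_pdc"]) if len(sub) else None,
            }
        )

    if not len(patients):
        return pd.DataFrame(
            rows, columns=["row", "n", "denominator", "percent", "mean_ad_pdc", "mean_mph_pdc"]
        )
    total = len(patients)
    tag_all = patients[patients["tag"]]
    cell("tag_total", tag_all, total)
    for grp in ("F90", "NON_F90"):
        g = patients[patients["group"] == grp]
        cell(f"{grp.lower()}_share_of_tag", tag_all[tag_all["group"] == grp], len(tag_all))
        gtag = g[g["tag"]]
        cell(f"{grp.lower()}_tag_on_both_share", gtag[gtag["on_ad"]], len(gtag))
        for regular in (True, False):
            for on_ad in (True, False):
                sub = g[(g["tag"] == regular) & (g["on_ad"] == on_ad)]
                label = (
                    f"{grp.lower()}_{'regular' if regular else 'irregular'}_"
                    f"{'mph_and_ad' if on_ad else 'mph_alone'}"
                )
                cell(label, sub, len(g))
        for gender in ("F", "M"):
            gg = g[g["gender"] == gender]
            for regular in (True, False):
                for on_ad in (True, False):
                    sub = gg[(gg["tag"] == regular) & (gg["on_ad"] == on_ad)]
                    label = (
                        f"{grp.lower()}_{gender}_{'regular' if regular else 'irregular'}_"
                        f"{'mph_and_ad' if on_ad else 'mph_alone'}"
                    )
                    cell(label, sub, len(gg))
    cell("mph_without_ad_share", patients[~patients["on_ad"]], total)
    return pd.DataFrame(rows)


def _tag_proportion_table(patients: pd.DataFrame, tag_month_rows) -> pd.DataFrame:
    """TAG drug-type month shares (mean per-patient proportions) with PDCs."""
    props, _, _, _ = month_proportions(tag_month_rows)
    shares = {p.patient_id: p for p in props}
    tag_pat = patients[patients["tag"] & patients["patient_id"].isin(shares)]
    out = []

    def block(label, sub: pd.DataFrame):
        ps = [shares[pid] for pid in sub["patient_id"]]
        if not ps:
            out.append({"subset": label, "n": 0, "ad_share_pct": None, "ad_pdc": None,
                        "mph_share_pct": None, "mph_pdc": None})
            return
        out.append(
            {
                "subset": label,
                "n": len(ps),
                "ad_share_pct": round(100 * sum(p.ad_share for p in ps) / len(ps), 2),
                "ad_pdc": _mean(sub["ad_pdc"]),
                "mph_share_pct": round(100 * sum(p.mph_share for p in ps) / len(ps), 2),
                "mph_pdc": _mean(sub["mph_pdc"]),
            }
        )

    block("all_regular", tag_pat)
    for gender in ("F", "M"):
        block(f"all_{gender}", tag_pat[tag_pat["gender"] == gender])
    for grp in ("F90", "NON_F90"):
        g = tag_pat[tag_pat["group"] == grp]
        block(f"{grp.lower()}_regular", g)
        for gender in ("F", "M"):
            block(f"{grp.lower()}_{gender}", g[g["gender"] == gender])
    return pd.DataFrame(out)


def _therapy_table(patients: pd.DataFrame) -> pd.DataFrame:
    out = []
    pops = [("all", patients)] + [
        (grp.lower(), patients[patients["group"] == grp]) for grp in ("F90", "NON_F90")
    ]
    for pop_name, pop in pops:
        for arm, sub in (("concurrent_ad", pop[pop["on_ad"]]),
                         ("mph_monotherapy", pop[~pop["on_ad"]])):
            for gname, gsub in (("overall", sub),
                                ("M", sub[sub["gender"] == "M"]),
                                ("F", sub[sub["gender"] == "F"])):
                out.append(
                    {
                        "population": pop_name, "arm": arm, "gender": gname,
                        "n": len(gsub),
                        "ad_pdc": _mean(gsub["ad_pdc"]) if arm == "concurrent_ad" else None,
                        "mph_pdc": _mean(gsub["mph_pdc"]),
                        "mph_pdd_mg": _mean(gsub["mph_pdd"]),
                    }
                )
    return pd.DataFrame(out)


def _overall_mph_table(patients: pd.DataFrame) -> pd.DataFrame:
    out = []
    pops = [("all", patients)] + [
        (grp.lower(), patients[patients["group"] == grp]) for grp in ("F90", "NON_F90")
    ]
    for pop_name, pop in pops:
        for gname, gsub in (("overall", pop),
                            ("F", pop[pop["gender"] == "F"]),
                            ("M", pop[pop["gender"] == "M"])):
            mean_pdc = _mean(gsub["mph_pdc"])
            out.append(
                {
                    "population": pop_name,
                    "gender": gname,
                    "n": len(gsub),
                    "mph_pdc_pct": None if mean_pdc is None else round(100 * mean_pdc, 2),
                    "mph_pdd_mg": _mean(gsub["mph_pdd"]),
                }
            )
    return pd.DataFrame(out)
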