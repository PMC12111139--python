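"""Inferential battery: exact 2x2 tests, TAG logistic regression, proportions.

Fisher's exact test uses the two-sided probability-mass convention (sum of
all tables, at fixed margins, whose hypergeometric probability does not
exceed the observed table's).  The treatment-adherent-group (TAG) logistic
model regresses the binary TAG flag on gender, diagnostic group,
antidepressant co-therapy and reference-year age band (youngest band as the
base level), reporting per-term odds ratios, Wald chi-square p-values and
Type-3 likelihood-ratio p-values (full model versus the model dropping the
term).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.stats import chi2

__all__ = [
    "ContingencyTable2x2",
    "LogisticFit",
    "MonthProportion",
    "fisher_exact",
    "dichotomise_pdc",
    "fit_tag_logistic",
    "month_proportions",
    "age_band",
    "AGE_BANDS",
]

AGE_BANDS = ("20-24", "25-29", "30-34", "35-39")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = grouping factor, columns = outcome (e.g. adherent / not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(table: ContingencyTable2x2, alternative: str = "two_sided") -> float:
    """Two-sided Fisher exact p-value; a zero margin returns 1 by convention."""
    if alternative != "two_sided":
        raise ValueError("only the two-sided alternative is supported")
    arr = table.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        return 1.0
    return float(scipy.stats.fisher_exact(arr, alternative="two-sided")[1])


def dichotomise_pdc(
    pdc_by_patient: pd.Series,
    grouping: pd.Series,
    threshold: float = 0.80,
) -> tuple[ContingencyTable2x2, int]:
    """Cross adherent (average PDC >= threshold, inclusive) with a binary factor.

    Both inputs are indexed by patient id; patients with a missing PDC are
    dropped and their count returned alongside the table.  The grouping
    series must be boolean (True row first).
    """
    joined = pd.DataFrame({"pdc": pdc_by_patient, "grp": grouping}).dropna(subset=["grp"])
    n_missing = int(joined["pdc"].isna().sum())
    joined = joined.dropna(subset=["pdc"])
    adherent = joined["pdc"] >= threshold
    grp = joined["grp"].astype(bool)
    return (
        ContingencyTable2x2(
            a=int((grp & adherent).sum()),
            b=int((grp & ~adherent).sum()),
            c=int((~grp & adherent).sum()),
            d=int((~grp & ~adherent).sum()),
        ),
        n_missing,
    )


@dataclass
class LogisticFit:
    status: str  # "ok", "separation", "degenerate_outcome", "too_few"
    n: int = 0
    coefficients: dict[str, float] = field(default_factory=dict)
    odds_ratios: dict[str, float] = field(default_factory=dict)
    wald_chisq: dict[str, float] = field(default_factory=dict)
    wald_p: dict[str, float] = field(default_factory=dict)
    type3_lrt_p: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def age_band(age_years: float) -> str:
    """Reference-year age band; ages outside 20-39 clip to the nearest band."""
    a = int(age_years)
    if a < 25:
        return AGE_BANDS[0]
    if a < 30:
        return AGE_BANDS[1]
    if a < 35:
        return AGE_BANDS[2]
    return AGE_BANDS[3]


def _design_matrix(design: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand the covariate frame into numeric columns grouped by model term."""
    cols: dict[str, pd.Series] = {}
    terms: dict[str, list[str]] = {}
    for name in design.columns:
        s = design[name]
        if name == "age_band":
            levels = [b for b in AGE_BANDS if b in set(s)]
            ref = levels[0] if levels else None  # youngest as base level
            names = []
            for lv in levels[1:]:
                cname = f"age_band[{lv}]"
                cols[cname] = (s == lv).astype(float)
                names.append(cname)
            terms[name] = names
        elif s.dtype == bool or set(s.dropna().unique()) <= {0, 1, True, False}:
            cols[name] = s.astype(float)
            terms[name] = [name]
        elif s.dtype == object:
            levels = sorted(s.dropna().unique())
            names = []
            for lv in levels[1:]:
                cname = f"{name}[{lv}]"
                cols[cname] = (s == lv).astype(float)
                names.append(cname)
            terms[name] = names
        else:
            cols[name] = s.astype(float)
            terms[name] = [name]
    X = pd.DataFrame(cols, index=design.index)
    X.insert(0, "Intercept", 1.0)
    return X, terms


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    import warnings

    import statsmodels.api as sm

    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        # convergence / separation are detected and surfaced via fit status
        warnings.simplefilter("ignore")
        return model.fit(disp=0, maxiter=200, method="newton")


def fit_tag_logistic(design: pd.DataFrame, outcome: Sequence[bool]) -> LogisticFit:
    """Maximum-likelihood logistic fit of the TAG flag on patient covariates.

    Degenerate inputs (constant outcome, too few observations) and separation
    are reported through ``status`` rather than raised.
    """
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    if n < 20:
        return LogisticFit(status="too_few", n=n)
    if y.min() == y.max():
        return LogisticFit(status="degenerate_outcome", n=n)
    X, terms = _design_matrix(design)
    # drop constant columns (unidentifiable)
    keep = [c for c in X.columns if c == "Intercept" or X[c].nunique() > 1]
    X = X[keep]
    terms = {t: [c for c in cs if c in keep] for t, cs in terms.items()}

    fit = LogisticFit(status="ok", n=n)
    try:
        res = _fit_logit(y, X)
    except Exception as err:  # separation raises PerfectSeparationError
        return LogisticFit(status="separation", n=n, warnings=[str(err)])
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 15:
        fit.status = "separation"
        fit.warnings.append("fit did not converge or coefficients diverged")
    llf_full = res.llf
    for col in X.columns:
        if col == "Intercept":
            continue
        beta = float(res.params[col])
        se = float(res.bse[col])
        fit.coefficients[col] = beta
        fit.odds_ratios[col] = math.exp(beta)
        w = (beta / se) ** 2 if se > 0 else float("inf")
        fit.wald_chisq[col] = w
        fit.wald_p[col] = float(chi2.sf(w, 1))
    for term, cols in terms.items():
        if not cols:
            continue
        reduced_cols = [c for c in X.columns if c not in cols]
        try:
            res0 = _fit_logit(y, X[reduced_cols])
            lr = 2.0 * (llf_full - res0.llf)
            fit.type3_lrt_p[term] = float(chi2.sf(max(lr, 0.0), df=len(cols)))
        except Exception as err:
            fit.warnings.append(f"type-3 refit failed for {term}: {err}")
    return fit


@dataclass(frozen=True)
class MonthProportion:
    patient_id: str
    mph_months: int
    ad_months: int

    @property
    def total(self) -> int:
        return self.mph_months + self.ad_months

    @property
    def mph_share(self) -> float:
        return self.mph_months / self.total

    @property
    def ad_share(self) -> float:
        return self.ad_months / self.total


def month_proportions(
    rows: Iterable[tuple[str, int, int]],
) -> tuple[list[MonthProportion], Optional[float], Optional[float], int]:
    """Per-patient therapy-type month shares for TAG members, plus group means.

    ``rows`` yields (patient_id, mph_months, ad_months).  Patients with zero
    months of both types are excluded; their count is returned.  Returns
    (per-patient list, mean MPH share, mean AD share, n excluded).
    """
    props: list[MonthProportion] = []
    n_excluded = 0
    for pid, mph, ad in rows:
        if mph + ad == 0:
            n_excluded += 1
            continue
        props.append(MonthProportion(pid, mph, ad))
    if not props:
        return props, None, None, n_excluded
    mean_mph = sum(p.mph_share for p in props) / len(props)
    mean_ad = sum(p.ad_share for p in props) / len(props)
    return props, mean_mph, mean_ad, n_excluded
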