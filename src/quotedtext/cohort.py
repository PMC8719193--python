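"""Cohort derivation and association statistics for quote presence.

Starting from a patient registry (one row per patient: demographics,
deprivation score, ICD-10 primary diagnosis, service-use fields, and a
has-quote flag), this module derives the categorical analysis variables —
five-group ethnicity, age bands, IMD tertile-style bands, ICD-10 chapter
groups, contact-count bands, referral-year bands — and computes the
association statistics: Pearson χ² with the missing category excluded and
no continuity correction, a one-degree-of-freedom linear trend (Cochran–
Armitage, in its Mantel–Haenszel (N−1)·r² form) for ordinal variables,
unadjusted 2×2 odds ratios with Wald 95% CIs, and unadjusted/adjusted
logistic regressions on complete cases, with ordinal variables entered as
ascending integer scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "EffectEstimate",
    "LogisticFit",
    "map_ethnicity",
    "map_icd10",
    "bin_age",
    "bin_imd",
    "bin_contacts",
    "bin_referral_year",
    "derive_cohort",
    "crosstab",
    "pearson_chi2",
    "trend_chi2",
    "odds_ratio_2x2",
    "fit_logistic",
    "fit_logistic_grouped",
    "distribution_report",
    "MISSING",
    "CATEGORY_ORDERS",
    "ORDINAL_VARIABLES",
    "REFERENCE_LEVELS",
]

MISSING = "missing"

_ETHNICITY_MAP = {
    "british": "White European",
    "irish": "White European",
    "any other white background": "White European",
    "african": "Black",
    "white and black african": "Black",
    "caribbean": "Black",
    "white and black caribbean": "Black",
    "any other black background": "Black",
    "bangladeshi": "Asian",
    "indian": "Asian",
    "pakistani": "Asian",
    "chinese": "Asian",
    "any other asian background": "Asian",
    "white and asian": "Asian",
    "any other mixed background": "Other",
    "any other ethnic group": "Other",
}

AGE_BANDS = ["1–15", "16–25", "26–35", "36–45", "46–55", "56–65", "66–75", "76–85", "86+"]
IMD_BANDS = ["0≤x≤20", "20<x≤30", "30<x≤93"]
DX_GROUPS = [f"F{i}x" for i in range(10)] + ["Zx", "Any other letter x", "Not recorded"]
CONTACTS_BANDS = ["0", "1–7", "8–14", "15–21", "22–28", "29–42", "43+"]
REFERRAL_BANDS_TABLE3 = [
    "Before 2007",
    "2007–2008",
    "2009–2010",
    "2011–2012",
    "2013–2014",
    "2015–2016",
    "2017–2018",
    "2019–2020",
]
REFERRAL_BANDS_TABLE2 = ["1918–2014", "2015–2020"]

CATEGORY_ORDERS: dict[str, list[str]] = {
    "gender": ["Female", "Male"],
    "ethnicity5": ["White European", "Black", "Asian", "Other"],
    "age_group": AGE_BANDS,
    "imd_band": IMD_BANDS,
    "dx_group": DX_GROUPS,
    "inpatient_12m": ["no", "yes"],
    "contacts_band": CONTACTS_BANDS,
    "referral_band": REFERRAL_BANDS_TABLE3,
}

#: variables analysed as a 1-df linear trend rather than an omnibus χ²
ORDINAL_VARIABLES = ("age_group", "imd_band", "contacts_band", "referral_band")

REFERENCE_LEVELS = {
    "gender": "Female",
    "ethnicity5": "White European",
    "dx_group": "F2x",
    "inpatient_12m": "no",
}



def _exp(x: float) -> float:
    """exp() that saturates instead of overflowing (separated fits can
    produce huge coefficients before the non-convergence flag is set)."""
    return math.exp(min(max(x, -745.0), 709.0))

def map_ethnicity(raw: object) -> str:
    """Collapse a fine-grained ethnicity category into the five analysis
    groups (White European / Black / Asian / Other / missing)."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or not str(raw).strip():
        return MISSING
    return _ETHNICITY_MAP.get(str(raw).strip().lower(), MISSING)


def map_icd10(code: object) -> str:
    """ICD-10 chapter grouping by leading letter (and digit for F codes)."""
    if code is None or (isinstance(code, float) and math.isnan(code)):
        return "Not recorded"
    text = str(code).strip().upper()
    if not text:
        return "Not recorded"
    if text[0] == "F" and len(text) >= 2 and text[1].isdigit():
        return f"F{text[1]}x"
    if text[0] == "Z":
        return "Zx"
    if text[0].isalpha():
        return "Any other letter x"
    return "Not recorded"


def bin_age(age: object) -> str:
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return MISSING
    age = int(age)
    edges = [(1, 15), (16, 25), (26, 35), (36, 45), (46, 55), (56, 65), (66, 75), (76, 85)]
    for label, (lo, hi) in zip(AGE_BANDS, edges):
        if lo <= age <= hi:
            return label
    return "86+" if age >= 86 else MISSING  # age 0 falls outside the printed bands


def bin_imd(score: object) -> str:
    """IMD percentile → tertile-style band, upper boundaries inclusive
    (a score of exactly 20 is in the most-deprived band)."""
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return MISSING
    s = float(score)
    if 0 <= s <= 20:
        return IMD_BANDS[0]
    if 20 < s <= 30:
        return IMD_BANDS[1]
    if 30 < s <= 93:
        return IMD_BANDS[2]
    return MISSING


def bin_contacts(n: object) -> str:
    if n is None or (isinstance(n, float) and math.isnan(n)):
        return MISSING
    n = int(n)
    if n == 0:
        return "0"
    for label, (lo, hi) in zip(
        CONTACTS_BANDS[1:-1], [(1, 7), (8, 14), (15, 21), (22, 28), (29, 42)]
    ):
        if lo <= n <= hi:
            return label
    return "43+"


def bin_referral_year(year: object, scheme: str = "table3") -> str:
    if year is None or (isinstance(year, float) and math.isnan(year)):
        return MISSING
    y = int(year)
    if scheme == "table2":
        if y <= 2014:
            return "1918–2014"
        return "2015–2020"
    if scheme != "table3":
        raise ValueError(f"unknown referral banding scheme {scheme!r}")
    if y < 2007:
        return "Before 2007"
    for label, (lo, hi) in zip(
        REFERRAL_BANDS_TABLE3[1:],
        [(2007, 2008), (2009, 2010), (2011, 2012), (2013, 2014), (2015, 2016), (2017, 2018), (2019, 2020)],
    ):
        if lo <= y <= hi:
            return label
    return MISSING


def derive_cohort(registry: pd.DataFrame, referral_scheme: str = "table3") -> pd.DataFrame:
    """Derive the categorical analysis variables from a raw registry table.

    Expects columns patient_id, gender, ethnicity_raw, age_years, imd_score,
    icd10_code, inpatient_12m, contacts_12m, first_referral_year, has_quote.
    Returns one row per patient with the banded variables; every missing or
    unmappable source value becomes the explicit category "missing" (or
    "Not recorded" for diagnosis).
    """
    def norm_gender(g: object) -> str:
        if g is None or (isinstance(g, float) and math.isnan(g)):
            return MISSING
        t = str(g).strip().lower()
        return {"female": "Female", "f": "Female", "male": "Male", "m": "Male"}.get(t, MISSING)

    def norm_inpatient(v: object) -> str:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return MISSING
        t = str(v).strip().lower()
        return {"yes": "yes", "y": "yes", "true": "yes", "1": "yes",
                "no": "no", "n": "no", "false": "no", "0": "no"}.get(t, MISSING)

    out = pd.DataFrame(
        {
            "patient_id": registry["patient_id"],
            "gender": registry["gender"].map(norm_gender),
            "ethnicity5": registry["ethnicity_raw"].map(map_ethnicity),
            "age_group": registry["age_years"].map(bin_age),
            "imd_band": registry["imd_score"].map(bin_imd),
            "dx_group": registry["icd10_code"].map(map_icd10),
            "inpatient_12m": registry["inpatient_12m"].map(norm_inpatient),
            "contacts_band": registry["contacts_12m"].map(bin_contacts),
            "referral_band": registry["first_referral_year"].map(
                lambda y: bin_referral_year(y, referral_scheme)
            ),
            "has_quote": registry["has_quote"].astype(bool),
        }
    )
    return out


@dataclass
class ContingencyTable:
    """Exposure-category × quote-presence counts.

    ``counts`` has one row per exposure label and two columns
    (with quote, without quote).  A "missing" row may be present; tests
    exclude it.  ``ordinal_scores`` carries the integer scores of the
    non-missing rows for trend testing.
    """

    variable: str
    exposure_labels: list[str]
    counts: np.ndarray
    ordinal_scores: list[float] | None = None
    missing_excluded: bool = False

    def nonmissing(self) -> "ContingencyTable":
        keep = [i for i, lab in enumerate(self.exposure_labels) if lab not in (MISSING, "Not recorded")]
        scores = None
        if self.ordinal_scores is not None:
            scores = [self.ordinal_scores[i] for i in keep]
        return ContingencyTable(
            variable=self.variable,
            exposure_labels=[self.exposure_labels[i] for i in keep],
            counts=self.counts[keep],
            ordinal_scores=scores,
            missing_excluded=True,
        )

    def to_frame(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            pct = np.where(tot > 0, 100.0 * self.counts[:, 0] / tot, np.nan)
        return pd.DataFrame(
            {
                "category": self.exposure_labels,
                "n_total": tot,
                "n_quote": self.counts[:, 0],
                "pct_quote": pct,
            }
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class EffectEstimate:
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float


@dataclass
class LogisticFit:
    terms: dict[str, dict]  # name -> coefficient, se, odds_ratio, ci_low, ci_high
    n_used: int
    converged: bool
    reference_levels: dict[str, str] = field(default_factory=dict)
    log_likelihood: float | None = None


def crosstab(cohort: pd.DataFrame, variable: str) -> ContingencyTable:
    """Cross-tabulate one derived variable against quote presence.

    Category order follows the published table layout; the missing category
    is retained in the table (flagged), and excluded later by the tests.
    """
    if variable not in cohort.columns:
        raise KeyError(f"no such variable: {variable}")
    order = [c for c in CATEGORY_ORDERS.get(variable, sorted(cohort[variable].unique()))]
    present = set(cohort[variable])
    labels = [c for c in order if c in present]
    extra = sorted(present - set(order))
    labels += [c for c in extra if c not in (MISSING, "Not recorded")]
    for tail in (MISSING, "Not recorded"):
        if tail in present and tail not in labels:
            labels.append(tail)
    counts = np.zeros((len(labels), 2), dtype=np.int64)
    grouped = cohort.groupby([variable, "has_quote"], observed=True).size()
    for i, lab in enumerate(labels):
        counts[i, 0] = int(grouped.get((lab, True), 0))
        counts[i, 1] = int(grouped.get((lab, False), 0))
    scores = None
    if variable in ORDINAL_VARIABLES:
        base = CATEGORY_ORDERS[variable]
        scores = [float(base.index(lab) + 1) if lab in base else math.nan for lab in labels]
    return ContingencyTable(variable=variable, exposure_labels=labels, counts=counts, ordinal_scores=scores)


def pearson_chi2(table: ContingencyTable) -> ChiSquareResult:
    """Pearson χ² of independence, no continuity correction, missing rows
    excluded before the margins are formed."""
    t = table if table.missing_excluded else table.nonmissing()
    O = t.counts.astype(float)
    if O.shape[0] < 2:
        raise ValueError("need ≥2 non-missing exposure categories")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    for i, r in enumerate(row):
        if r == 0:
            raise ValueError(f"zero row margin for category {t.exposure_labels[i]!r}")
    for j, c in enumerate(col):
        if c == 0:
            raise ValueError(f"zero column margin (column {j})")
    E = np.outer(row, col) / O.sum()
    stat = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return ChiSquareResult(statistic=stat, df=df, p_value=float(chi2_dist.sf(stat, df)))


def trend_chi2(table: ContingencyTable) -> ChiSquareResult:
    """Linear-trend χ² with 1 df in the Mantel–Haenszel form (N−1)·r².

    r is the Pearson correlation between the ordinal row score and the
    binary outcome over the N non-missing subjects, computed in closed form
    from the grouped counts.
    """
    t = table if table.missing_excluded else table.nonmissing()
    if t.ordinal_scores is None:
        raise ValueError("trend test requires ordinal scores")
    s = np.asarray(t.ordinal_scores, dtype=float)
    if t.counts.shape[0] < 2:
        raise ValueError("need ≥2 non-missing exposure categories")
    if np.allclose(s, s[0]):
        raise ValueError("ordinal scores are constant")
    n_i = t.counts.sum(axis=1).astype(float)
    e_i = t.counts[:, 0].astype(float)
    N = n_i.sum()
    E = e_i.sum()
    sxy = float((s * e_i).sum() - (s * n_i).sum() * E / N)
    sxx = float((s**2 * n_i).sum() - (s * n_i).sum() ** 2 / N)
    syy = float(E - E**2 / N)
    if sxx == 0 or syy == 0:
        stat = 0.0
    else:
        stat = (N - 1) * sxy**2 / (sxx * syy)
    return ChiSquareResult(statistic=stat, df=1, p_value=float(chi2_dist.sf(stat, 1)))


def odds_ratio_2x2(a: float, b: float, c: float, d: float, haldane: bool = False) -> EffectEstimate:
    """Unadjusted odds ratio for a 2×2 table with a Wald 95% CI.

    Cells are (exposed with outcome, exposed without, unexposed with,
    unexposed without).  A zero cell raises unless ``haldane`` adds 0.5 to
    every cell.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be nonnegative")
    if any(x == 0 for x in cells):
        if not haldane:
            raise ValueError("zero cell; pass haldane=True for the 0.5 correction")
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    log_or = math.log((a / b) / (c / d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se),
        log_or=log_or,
        se_log_or=se,
    )


def fit_logistic_grouped(
    scores: Sequence[float], totals: Sequence[float], events: Sequence[float]
) -> LogisticFit:
    """Single-predictor logistic regression on grouped (score, total, event)
    rows: logit P(quote) = β₀ + β₁·score, fit by IRLS."""
    x = np.asarray(scores, dtype=float)
    n = np.asarray(totals, dtype=float)
    y = np.asarray(events, dtype=float)
    X = sm.add_constant(x)
    model = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    def term(i: int) -> dict:
        coef = float(res.params[i])
        se = float(res.bse[i])
        return {
            "coefficient": coef,
            "se": se,
            "odds_ratio": _exp(coef),
            "ci_low": _exp(coef - 1.96 * se),
            "ci_high": _exp(coef + 1.96 * se),
        }

    return LogisticFit(
        terms={"intercept": term(0), "score": term(1)},
        n_used=int(n.sum()),
        converged=bool(res.converged),
        log_likelihood=float(res.llf),
    )


def _design_matrix(
    cohort: pd.DataFrame, variables: Sequence[str]
) -> tuple[pd.DataFrame, list[str], dict[str, str]]:
    """Dummy/score encoding per the analysis conventions.

    Ordinal variables become one ascending-integer-score column; nominal
    variables become dummies against their stated reference level.  Rows
    with a missing/Not-recorded value in any ordinal variable cannot be
    scored and are dropped by the caller's complete-case mask.
    """
    cols: dict[str, pd.Series] = {}
    names: list[str] = []
    refs: dict[str, str] = {}
    for var in variables:
        order = CATEGORY_ORDERS[var]
        if var in ORDINAL_VARIABLES:
            score = cohort[var].map({lab: i + 1 for i, lab in enumerate(order)})
            cols[var] = score
            names.append(var)
        else:
            ref = REFERENCE_LEVELS.get(var, order[0])
            refs[var] = ref
            levels = [lab for lab in order if lab != ref]
            if var == "dx_group":
                levels = [lab for lab in DX_GROUPS if lab != ref]
            for lab in levels:
                name = f"{var}[{lab}]"
                cols[name] = (cohort[var] == lab).astype(float)
                # rows at an unmappable/missing level are excluded via the mask
                names.append(name)
    X = pd.DataFrame(cols)
    return X, names, refs


def _complete_mask(cohort: pd.DataFrame, variables: Sequence[str]) -> pd.Series:
    mask = pd.Series(True, index=cohort.index)
    for var in variables:
        if var == "dx_group":
            # "Not recorded" is an analysis category of its own, not missingness
            continue
        mask &= ~cohort[var].isin([MISSING])
    return mask


def fit_logistic(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    complete_case: bool = True,
) -> LogisticFit:
    """Logistic regression of quote presence on one or more derived
    variables, maximum likelihood via IRLS (tolerance 1e-8, ≤100 iterations).

    Nominal predictors are dummy-coded against the conventional references
    (Female, White European, F2x, no inpatient care); ordinal predictors
    enter as ascending integer scores.  With ``complete_case`` (the
    default), any subject missing a value on a modelled variable is dropped.
    Non-convergence (e.g. perfect separation) is flagged, not raised.
    """
    if not variables:
        raise ValueError("need at least one predictor variable")
    data = cohort
    if complete_case:
        data = cohort[_complete_mask(cohort, variables)]
    X, names, refs = _design_matrix(data, variables)
    valid = ~X.isna().any(axis=1)
    X = X[valid]
    y = data.loc[X.index, "has_quote"].astype(float)
    if X.empty:
        raise ValueError("no usable rows after complete-case filtering")
    Xmat = sm.add_constant(X[names], has_constant="add")
    model = sm.GLM(y, Xmat, family=sm.families.Binomial())
    converged = True
    try:
        res = model.fit(maxiter=100, tol=1e-8)
        # separation diagnostic: IRLS "converges" onto the boundary with
        # coefficients drifting to ±inf and exploding standard errors
        separated = bool(np.any(np.abs(res.params) > 15) or np.any(res.bse > 100))
        converged = bool(res.converged) and np.all(np.isfinite(res.bse)) and not separated
    except Exception:
        return LogisticFit(terms={}, n_used=int(len(y)), converged=False, reference_levels=refs)
    terms: dict[str, dict] = {}
    for name in ["const"] + names:
        coef = float(res.params[name])
        se = float(res.bse[name])
        terms["intercept" if name == "const" else name] = {
            "coefficient": coef,
            "se": se,
            "odds_ratio": _exp(coef),
            "ci_low": _exp(coef - 1.96 * se),
            "ci_high": _exp(coef + 1.96 * se),
        }
    return LogisticFit(
        terms=terms,
        n_used=int(len(y)),
        converged=converged,
        reference_levels=refs,
        log_likelihood=float(res.llf),
    )


ANALYSIS_VARIABLES = [
    "gender",
    "ethnicity5",
    "age_group",
    "imd_band",
    "dx_group",
    "inpatient_12m",
    "contacts_band",
    "referral_band",
]


def distribution_report(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Assemble the full distribution analysis.

    Returns three tables: per-variable counts with the appropriate χ²
    (omnibus for nominal, 1-df linear trend for ordinal, missing excluded),
    unadjusted effects (2×2 ORs for nominal levels, per-category ORs for
    ordinals), and the adjusted complete-case logistic model.  A variable
    whose non-missing part is degenerate is skipped with a logged reason.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    count_rows: list[dict] = []
    effect_rows: list[dict] = []
    skipped: list[str] = []
    for var in ANALYSIS_VARIABLES:
        tab = crosstab(cohort, var)
        frame = tab.to_frame()
        nm = tab.nonmissing()
        if nm.counts.shape[0] < 2 or (nm.counts.sum(axis=0) == 0).any():
            skipped.append(var)
            for _, r in frame.iterrows():
                count_rows.append({"variable": var, **r.to_dict(), "chi2": np.nan, "df": np.nan, "p": np.nan})
            continue
        if var in ORDINAL_VARIABLES:
            chi = trend_chi2(nm)
        else:
            chi = pearson_chi2(nm)
        for _, r in frame.iterrows():
            count_rows.append(
                {"variable": var, **r.to_dict(), "chi2": chi.statistic, "df": chi.df, "p": chi.p_value}
            )
        # unadjusted effects
        if var in ORDINAL_VARIABLES:
            fit = fit_logistic(cohort, [var])
            t = fit.terms[var]
            effect_rows.append(
                {
                    "variable": var,
                    "level": "per category",
                    "odds_ratio": t["odds_ratio"],
                    "ci_low": t["ci_low"],
                    "ci_high": t["ci_high"],
                    "model": "unadjusted",
                }
            )
        else:
            ref = REFERENCE_LEVELS.get(var, nm.exposure_labels[0])
            labels = tab.exposure_labels
            ridx = labels.index(ref)
            for i, lab in enumerate(labels):
                if lab == ref or (lab == MISSING):
                    continue
                a, b = tab.counts[i]
                c, d = tab.counts[ridx]
                if min(a, b, c, d) == 0:
                    continue
                est = odds_ratio_2x2(a, b, c, d)
                effect_rows.append(
                    {
                        "variable": var,
                        "level": lab,
                        "odds_ratio": est.odds_ratio,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "model": "unadjusted",
                    }
                )
    usable = [v for v in ANALYSIS_VARIABLES if v not in skipped]
    adj_rows: list[dict] = []
    if usable:
        adj = fit_logistic(cohort, usable, complete_case=True)
        for name, t in adj.terms.items():
            adj_rows.append(
                {
                    "term": name,
                    "odds_ratio": t["odds_ratio"],
                    "ci_low": t["ci_low"],
                    "ci_high": t["ci_high"],
                    "n_used": adj.n_used,
                    "converged": adj.converged,
                }
            )
    report = {
        "counts": pd.DataFrame(count_rows),
        "unadjusted": pd.DataFrame(effect_rows),
        "adjusted": pd.DataFrame(adj_rows),
    }
    report["skipped"] = pd.DataFrame({"variable": skipped, "reason": ["degenerate after missing exclusion"] * len(skipped)})
    return report
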