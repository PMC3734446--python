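"""Birth-record eligibility, case classification, aggregation and the
missing-POBW sensitivity analyses.

Case definition: a birth is a *poor fetal growth* case when its Proportion
of Optimal Birth Weight (POBW, observed birthweight over the weight expected
from gestation, sex, parity and maternal height) is strictly below 0.80.
Small-for-gestational-age (SGA, birthweight strictly below the sex-by-
gestation 10th centile) serves as an alternative outcome, unadjusted for
parity and height, for checking that POBW missingness is ignorable:

* a 2x2 odds ratio of SGA for POBW-null versus non-null records (Woolf CI);
* a Breslow-Day homogeneity test of that odds ratio across SES quintiles;
* a Pearson goodness-of-fit of SGA cases among POBW-null records per suburb
  against the probabilities fitted by the random-effects model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_eligible",
    "classify_poor_fetal_growth",
    "classify_sga",
    "aggregate_to_suburbs",
    "standardize_ses",
    "incidence_percent",
    "odds_ratio_2x2",
    "breslow_day",
    "chi_square_upper_tail",
    "pobw_null_gof",
    "SensitivityReport",
]

POBW_THRESHOLD = 0.80
MIN_GESTATION = 33  # completed weeks; births below are excluded

NOT_LIVEBORN = "not-liveborn"
NOT_SINGLETON = "not-singleton"
PRETERM = "gestation-below-33-weeks"
NULL_POBW = "null-pobw"
ELIGIBLE = "eligible"
_FILTER_ORDER = (NOT_LIVEBORN, NOT_SINGLETON, PRETERM, NULL_POBW)


def filter_eligible(records: pd.DataFrame):
    """Restrict to liveborn singletons of >= 33 completed weeks with POBW
    present; each excluded record is counted under the first failing rule.

    Returns ``(eligible_records, counts)`` where counts is a dict keyed by
    exclusion reason plus ``"eligible"``; the counts partition the input.
    """
    if records.empty:
        return records.copy(), {r: 0 for r in (*_FILTER_ORDER, ELIGIBLE)}
    reason = pd.Series(ELIGIBLE, index=records.index)
    reason[records["pobw"].isna()] = NULL_POBW
    reason[records["gestation"] < MIN_GESTATION] = PRETERM
    reason[~records["singleton"].astype(bool)] = NOT_SINGLETON
    reason[~records["liveborn"].astype(bool)] = NOT_LIVEBORN
    counts = {r: int((reason == r).sum()) for r in (*_FILTER_ORDER, ELIGIBLE)}
    return records[reason == ELIGIBLE].copy(), counts


def classify_poor_fetal_growth(pobw) -> np.ndarray | bool:
    """True iff POBW < 0.80 (strict: a birth at exactly 80% is not a case)."""
    arr = np.asarray(pobw, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("POBW is null; filter records before classifying")
    out = arr < POBW_THRESHOLD
    return bool(out) if np.isscalar(pobw) else out


def classify_sga(birthweight, sex, gestation, reference_table) -> bool:
    """True iff birthweight is strictly below the (sex, gestation) 10th
    centile of ``reference_table`` (mapping (sex, gestation) -> grams)."""
    key = (sex, int(gestation))
    if key not in reference_table:
        raise KeyError(f"reference table does not cover {key}")
    return float(birthweight) < float(reference_table[key])


def aggregate_to_suburbs(records: pd.DataFrame,
                         ses_by_suburb: pd.Series) -> pd.DataFrame:
    """Suburb table of births N_i, poor-fetal-growth cases R_i and SES.

    ``ses_by_suburb`` holds raw index values indexed by suburb id; they are
    standardised across the suburbs present.  Every record's suburb must be
    in the SES table.
    """
    unknown = set(records["suburb_id"]) - set(ses_by_suburb.index)
    if unknown:
        raise KeyError(f"records reference suburbs without SES: {sorted(unknown)}")
    case = classify_poor_fetal_growth(records["pobw"].to_numpy())
    grp = records.assign(case=case).groupby("suburb_id")
    tab = grp.agg(births=("case", "size"), cases=("case", "sum")).reset_index()
    tab["ses_raw"] = tab["suburb_id"].map(ses_by_suburb).astype(float)
    tab["ses_std"] = standardize_ses(tab["ses_raw"].to_numpy())
    return tab


def standardize_ses(values) -> np.ndarray:
    """Standardise to mean 0, SD 1 (population SD, divisor n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need at least two distinct values to standardise")
    return (x - x.mean()) / x.std()


def incidence_percent(cases: int, births: int, decimals: int = 1) -> float:
    """Incidence as a percentage, rounded for reporting."""
    if births <= 0:
        raise ValueError("births must be positive")
    return round(100.0 * cases / births, decimals)


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------

def odds_ratio_2x2(a, b, c, d, continuity_correction: bool = False):
    """Odds ratio ad/(bc) with the Woolf (log-normal) 95% CI.

    Cell layout: a = exposed cases, b = exposed non-cases, c = unexposed
    cases, d = unexposed non-cases.  Zero cells raise unless
    ``continuity_correction`` adds 0.5 to every cell.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (cells == 0).any():
        if not continuity_correction:
            raise ValueError("zero cell; set continuity_correction=True")
        cells = cells + 0.5
    a, b, c, d = cells
    oratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(oratio) + np.array([-1, 1]) * 1.96 * se)
    return float(oratio), (float(lo), float(hi))


def _bd_expected_a(a, b, c, d, psi):
    """Expected count in cell a given margins and common odds ratio psi."""
    r1, c1, n2 = a + b, a + c, c + d
    if abs(psi - 1.0) < 1e-12:
        return r1 * c1 / (r1 + n2)
    # x solves x(n2-c1+x) = psi (r1-x)(c1-x)
    qa = 1.0 - psi
    qb = (n2 - c1) + psi * (r1 + c1)
    qc = -psi * r1 * c1
    disc = np.sqrt(qb * qb - 4 * qa * qc)
    roots = [(-qb + disc) / (2 * qa), (-qb - disc) / (2 * qa)]
    lo, hi = max(0.0, c1 - n2), min(r1, c1)
    for x in roots:
        if lo - 1e-9 <= x <= hi + 1e-9:
            return float(np.clip(x, lo, hi))
    raise ArithmeticError("no admissible root for Breslow-Day expectation")


def breslow_day(tables):
    """Breslow-Day homogeneity test of the odds ratio across strata.

    ``tables`` is a sequence of (a, b, c, d) 2x2 tables.  The statistic
    compares each stratum's cell a with its expectation under the
    Mantel-Haenszel common odds ratio; df = strata - 1.

    Returns ``(chi2, df, p)``.
    """
    tabs = [tuple(float(x) for x in t) for t in tables]
    if len(tabs) < 2:
        raise ValueError("need at least two strata")
    for k, (a, b, c, d) in enumerate(tabs):
        if min(a + b, c + d, a + c, b + d) <= 0:
            raise ValueError(f"stratum {k} has a zero margin")
    num = sum(a * d / (a + b + c + d) for a, b, c, d in tabs)
    den = sum(b * c / (a + b + c + d) for a, b, c, d in tabs)
    psi = num / den
    chi2 = 0.0
    for a, b, c, d in tabs:
        ea = _bd_expected_a(a, b, c, d, psi)
        r1, c1, n2 = a + b, a + c, c + d
        var = 1.0 / (1.0 / ea + 1.0 / (r1 - ea) + 1.0 / (c1 - ea)
                     + 1.0 / (n2 - c1 + ea))
        chi2 += (a - ea) ** 2 / var
    df = len(tabs) - 1
    return float(chi2), df, chi_square_upper_tail(chi2, df)


def chi_square_upper_tail(x: float, df: int) -> float:
    """P(chi2_df > x) via the regularised incomplete gamma function."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("statistic must be non-negative")
    return float(stats.chi2.sf(x, df))


def pobw_null_gof(null_records: pd.DataFrame, fitted_p: pd.Series):
    """Goodness-of-fit of SGA cases among POBW-null records to model-fitted
    poor-fetal-growth probabilities.

    Observed: SGA cases among POBW-null records per suburb.  Expected:
    n_null,i x fitted p_i.  Each contributing suburb (at least one null
    record) enters as a binomial 2-cell Pearson term,
    ``(O - E)^2 / (E (1 - p_i))``, which keeps the statistic calibrated
    against its chi-square reference; df = contributing suburbs - 1.
    Suburbs with zero expected count are dropped with a warning.
    """
    grp = null_records.groupby("suburb_id")["sga"].agg(["size", "sum"])
    missing = set(grp.index) - set(fitted_p.index)
    if missing:
        raise KeyError(f"no fitted probability for suburbs: {sorted(missing)}")
    n_null = grp["size"].astype(float)
    observed = grp["sum"].astype(float)
    p_i = fitted_p.reindex(grp.index).astype(float).clip(upper=1 - 1e-12)
    expected = n_null * p_i
    bad = expected <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} suburb(s) with zero expected "
                      "count from goodness-of-fit")
        observed, expected, p_i = observed[~bad], expected[~bad], p_i[~bad]
    chi2 = float(((observed - expected) ** 2 / (expected * (1 - p_i))).sum())
    df = len(expected) - 1
    return chi2, df, chi_square_upper_tail(chi2, df)


@dataclass
class SensitivityReport:
    """Bundle of the missing-POBW sensitivity checks."""

    odds_ratio: float
    odds_ratio_ci: tuple
    breslow_day_chi2: float
    breslow_day_df: int
    breslow_day_p: float
    gof_chi2: float
    gof_df: int
    gof_p: float

    def to_dict(self) -> dict:
        return {
            "sga_or_null_vs_nonnull": self.odds_ratio,
            "sga_or_ci95": list(self.odds_ratio_ci),
            "breslow_day": {"chi2": self.breslow_day_chi2,
                            "df": self.breslow_day_df,
                            "p": self.breslow_day_p},
            "pobw_null_gof": {"chi2": self.gof_chi2, "df": self.gof_df,
                              "p": self.gof_p},
        }

    def __str__(self) -> str:
        lo, hi = self.odds_ratio_ci
        return (
            "Missing-POBW sensitivity analysis\n"
            f"  SGA odds ratio (POBW null vs non-null): {self.odds_ratio:.2f} "
            f"(95% CI {lo:.2f} to {hi:.2f})\n"
            f"  Breslow-Day homogeneity across SES quintiles: "
            f"chi2 = {self.breslow_day_chi2:.2f}, df = {self.breslow_day_df}, "
            f"p = {self.breslow_day_p:.2f}\n"
            f"  Goodness-of-fit of SGA among POBW-null records: "
            f"chi2 = {self.gof_chi2:.2f}, df = {self.gof_df}, "
            f"p = {self.gof_p:.2f}"
        )


def sensitivity_analysis(records: pd.DataFrame,
                         fitted_p: pd.Series) -> SensitivityReport:
    """Run all three missing-POBW checks on a birth-record table.

    Records must carry ``pobw`` (with nulls), ``sga`` and ``ses_quintile``.
    Only liveborn singletons of >= 33 weeks are used; the POBW-null rule is
    *not* applied (nulls are the exposure of interest here).
    """
    keep = (records["liveborn"].astype(bool)
            & records["singleton"].astype(bool)
            & (records["gestation"] >= MIN_GESTATION))
    rec = records[keep]
    is_null = rec["pobw"].isna()
    sga = rec["sga"].astype(bool)
    a = int((is_null & sga).sum())
    b = int((is_null & ~sga).sum())
    c = int((~is_null & sga).sum())
    d = int((~is_null & ~sga).sum())
    oratio, ci = odds_ratio_2x2(a, b, c, d, continuity_correction=True)
    tables = []
    for _, stratum in rec.groupby("ses_quintile"):
        sn = stratum["pobw"].isna()
        sg = stratum["sga"].astype(bool)
        tables.append((max(0.5, (sn & sg).sum()), max(0.5, (sn & ~sg).sum()),
                       max(0.5, (~sn & sg).sum()), max(0.5, (~sn & ~sg).sum())))
    bd_chi2, bd_df, bd_p = breslow_day(tables)
    g_chi2, g_df, g_p = pobw_null_gof(rec[is_null], fitted_p)
    return SensitivityReport(oratio, ci, bd_chi2, bd_df, bd_p, g_chi2, g_df, g_p)
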