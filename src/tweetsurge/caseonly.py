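"""Case-only interaction estimators.

The case-only design estimates multiplicative effect modification
between a day-level binary exposure (a surge day) and an individual
characteristic using only the cases: under independence of the
characteristic and the exposure in the base population, the interaction
coefficient beta3 of the Poisson count model equals the log odds ratio
of the exposure x characteristic cross-tabulation among cases.

Reported numbers come from the closed forms (cross-product ratios with
delta-method standard errors).  Each estimator optionally re-fits the
corresponding maximum-likelihood model (binary logistic, multinomial
logistic, or the saturated Poisson log-linear model) and asserts
agreement to 1e-6 relative — an internal verification of the estimating
identity, never the reported path.
"""

from __future__ import annotations

import contextlib
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import apply_exclusions, derive_age_group, merge_with_lag, select_cause
from .exposure import ExposureCalendar

logger = logging.getLogger(__name__)

__all__ = [
    "Z_95",
    "CharacteristicCoding",
    "DEFAULT_CODINGS",
    "CaseOnlyTable",
    "InteractionEstimate",
    "ZeroCellError",
    "crosstab",
    "caseonly_or_binary",
    "caseonly_rrr_multinomial",
    "poisson_oracle",
    "run_analysis",
]

#: two-sided 95% normal quantile used for all Wald intervals
Z_95 = 1.959964

_ML_RTOL = 1e-6


class ZeroCellError(ValueError):
    """A table cell needed by the estimator is zero."""


@contextlib.contextmanager
def _quiet_saturated_fit():
    """Saturated models have zero residual df; statsmodels warns about the
    resulting perfect prediction, which is expected here."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            from statsmodels.tools.sm_exceptions import (
                ConvergenceWarning,
                PerfectSeparationWarning,
            )

            warnings.simplefilter("ignore", PerfectSeparationWarning)
            # Newton stalls at float precision below ~1e-12; the 1e-6
            # identity assertion is the real convergence check
            warnings.simplefilter("ignore", ConvergenceWarning)
        except ImportError:
            pass
        yield


@dataclass(frozen=True)
class CharacteristicCoding:
    """Analysis coding of one characteristic: the column to tabulate, its
    ordered levels and the reference (base) level."""

    name: str
    levels: tuple
    reference: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.reference not in self.levels:
            raise ValueError(
                f"{self.name}: reference {self.reference!r} not among levels"
            )


#: the study's standard codings; base levels: >40 years, female,
#: self-employed, married, rural
DEFAULT_CODINGS = (
    CharacteristicCoding("age_group", ("old", "young"), "old"),
    CharacteristicCoding("sex", ("female", "male"), "female"),
    CharacteristicCoding(
        "occupation",
        ("self-employed", "agriculture", "corporate", "other", "unemployed"),
        "self-employed",
    ),
    CharacteristicCoding(
        "marital_status", ("married", "unmarried", "widowed", "divorced"), "married"
    ),
    CharacteristicCoding("area", ("rural", "urban"), "rural"),
)


@dataclass
class CaseOnlyTable:
    """Exposure x characteristic-level count table among cases.

    ``counts[e][j]`` is the number of cases with exposure e (0 non-surge
    day, 1 surge day) at level j, in the order of ``levels``.
    """

    name: str
    levels: tuple
    reference: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.levels = tuple(self.levels)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, len(self.levels)):
            raise ValueError("counts must be a 2 x n_levels array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.reference not in self.levels:
            raise ValueError(f"reference {self.reference!r} not among levels")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def column(self, level: str) -> np.ndarray:
        return self.counts[:, self.levels.index(level)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=["non-surge", "surge"], columns=list(self.levels)
        )


@dataclass
class InteractionEstimate:
    """A point estimate of exp(beta3) for one level with its Wald CI."""

    level: str
    estimate: float
    se_log: float
    ci_low: float
    ci_high: float
    p_value: float
    estimator: str  # closed_form | ml | poisson_oracle
    corrected: bool = False
    n: float = 0.0

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _wald(level, log_est, se, estimator, corrected, n) -> InteractionEstimate:
    z = log_est / se if se > 0 else np.inf * np.sign(log_est)
    p = 2.0 * stats.norm.sf(abs(z))
    return InteractionEstimate(
        level=level,
        estimate=float(np.exp(log_est)),
        se_log=float(se),
        ci_low=float(np.exp(log_est - Z_95 * se)),
        ci_high=float(np.exp(log_est + Z_95 * se)),
        p_value=float(p),
        estimator=estimator,
        corrected=corrected,
        n=n,
    )


def crosstab(rows: pd.DataFrame, coding: CharacteristicCoding) -> CaseOnlyTable:
    """Exact exposure x level cross-tabulation of analysis rows.

    Every row must have a defined boolean ``exposed`` and a value of the
    characteristic among the coding's levels.
    """
    counts = np.zeros((2, len(coding.levels)))
    if len(rows):
        col = rows[coding.name]
        unknown = set(col.unique()) - set(coding.levels)
        if unknown:
            raise ValueError(
                f"{coding.name}: values {sorted(unknown)} outside coded levels"
            )
        e = rows["exposed"].to_numpy().astype(int)
        j = (
            col.map({lv: i for i, lv in enumerate(coding.levels)})
            .to_numpy()
            .astype(int)
        )
        np.add.at(counts, (e, j), 1)
    return CaseOnlyTable(coding.name, coding.levels, coding.reference, counts)


def _prepare(table: CaseOnlyTable, cols: Sequence[int], correction: bool) -> tuple:
    counts = table.counts
    sub = counts[:, cols]
    if (sub == 0).any():
        if not correction:
            raise ZeroCellError(
                f"{table.name}: zero cell in exposure x level table "
                f"{sub.tolist()}; pass correction=True to add 0.5 to all cells"
            )
        counts = counts + 0.5
        return counts, True
    return counts, False


def _check_ml(closed: float, ml: float, what: str) -> None:
    rel = abs(ml - closed) / max(abs(closed), 1e-300)
    if rel > _ML_RTOL:
        raise AssertionError(
            f"{what}: ML estimate {ml!r} disagrees with closed form {closed!r} "
            f"(relative difference {rel:.2e})"
        )


def caseonly_or_binary(
    table: CaseOnlyTable,
    correction: bool = False,
    verify_ml: bool = True,
) -> InteractionEstimate:
    """Case-only odds ratio for a binary characteristic.

    OR = (n11 * n00) / (n10 * n01) with the non-reference level as
    "success"; SE on the log scale is sqrt of the summed reciprocal
    cells; the 95% CI is Wald on the log scale.  A zero cell raises
    ZeroCellError unless ``correction`` adds 0.5 to every cell (the
    estimate is then tagged ``corrected``).  With ``verify_ml`` the
    one-predictor binary logistic is also fitted by maximum likelihood
    and must agree with the closed form to 1e-6 relative.
    """
    if len(table.levels) != 2:
        raise ValueError("caseonly_or_binary needs a 2x2 table")
    counts, corrected = _prepare(table, [0, 1], correction)
    ref = table.levels.index(table.reference)
    alt = 1 - ref
    log_or = (
        np.log(counts[1, alt])
        + np.log(counts[0, ref])
        - np.log(counts[1, ref])
        - np.log(counts[0, alt])
    )
    se = np.sqrt((1.0 / counts).sum())
    if verify_ml and not corrected:  # corrected cells have no ML counterpart
        # grouped binomial logistic: level vs exposure, saturated
        endog = np.column_stack([counts[:, alt], counts[:, ref]])
        exog = sm.add_constant(np.array([0.0, 1.0]))
        with _quiet_saturated_fit():
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        _check_ml(float(np.exp(log_or)), float(np.exp(fit.params[1])), "binary OR")
    est = _wald(
        table.levels[alt], log_or, se, "closed_form", corrected, table.total
    )
    return est


def caseonly_rrr_multinomial(
    table: CaseOnlyTable,
    correction: bool = False,
    verify_ml: bool = True,
) -> list[InteractionEstimate]:
    """Relative risk ratios for a multi-level characteristic.

    Each non-reference level j is contrasted with the base level:
    RRR_j = (n1j * n0b) / (n0j * n1b), SE_j = sqrt(1/n1j + 1/n0j +
    1/n1b + 1/n0b).  With ``verify_ml`` a multinomial logistic
    regression of the level on the exposure indicator is fitted on the
    expanded rows and must reproduce every RRR to 1e-6 relative.
    """
    if len(table.levels) < 2:
        raise ValueError("need at least 2 levels")
    base = table.levels.index(table.reference)
    others = [j for j in range(len(table.levels)) if j != base]
    counts, corrected = _prepare(table, [base] + others, correction)

    log_rrr = {}
    out = []
    for j in others:
        lr = (
            np.log(counts[1, j])
            + np.log(counts[0, base])
            - np.log(counts[0, j])
            - np.log(counts[1, base])
        )
        se = np.sqrt(
            1.0 / counts[1, j]
            + 1.0 / counts[0, j]
            + 1.0 / counts[1, base]
            + 1.0 / counts[0, base]
        )
        log_rrr[j] = lr
        out.append(
            _wald(table.levels[j], lr, se, "closed_form", corrected, table.total)
        )

    if verify_ml and not corrected:  # corrected cells have no ML counterpart
        ml = _fit_mnlogit(counts, base, others)
        for j in others:
            _check_ml(
                float(np.exp(log_rrr[j])),
                float(np.exp(ml[j])),
                f"RRR[{table.levels[j]}]",
            )
    return out


def _fit_mnlogit(counts: np.ndarray, base: int, others: list[int]) -> dict:
    """ML multinomial logit of level on exposure, fitted on expanded
    individual rows; returns the exposure coefficient per non-base level."""
    cells = np.rint(counts).astype(int)
    n_e = cells.sum(axis=1)
    exog = sm.add_constant(np.repeat([0.0, 1.0], n_e).reshape(-1, 1), has_constant="add")
    # outcome codes: base level first so it is the MNLogit reference
    order = [base] + others
    recode = {lvl: k for k, lvl in enumerate(order)}
    y = np.concatenate(
        [
            np.repeat([recode[j] for j in range(cells.shape[1])], cells[e])
            for e in (0, 1)
        ]
    )
    with _quiet_saturated_fit():
        fit = sm.MNLogit(y, exog).fit(method="newton", maxiter=200, tol=1e-10, disp=False)
    params = np.asarray(fit.params)  # shape (2, J-1): rows const, exposure
    return {j: float(params[1, k - 1]) for k, j in enumerate(order) if k > 0}


def poisson_oracle(
    rows_or_table,
    coding: Optional[CharacteristicCoding] = None,
    correction: bool = False,
) -> InteractionEstimate:
    """Interaction from the saturated Poisson log-linear model.

    Aggregates analysis rows to the four exposure x level totals of a
    binary characteristic and fits counts ~ 1 + E + C + E:C by Poisson
    maximum likelihood; returns exp(beta3-hat) with its Wald SE.  On an
    all-positive table this equals the case-only closed form exactly
    (saturated-model identity).
    """
    if isinstance(rows_or_table, CaseOnlyTable):
        table = rows_or_table
    else:
        if coding is None:
            raise ValueError("a coding is required when passing analysis rows")
        table = crosstab(rows_or_table, coding)
    if len(table.levels) != 2:
        raise ValueError("poisson_oracle needs a binary characteristic")
    counts, corrected = _prepare(table, [0, 1], correction)
    ref = table.levels.index(table.reference)
    alt = 1 - ref
    endog = np.array(
        [counts[0, ref], counts[0, alt], counts[1, ref], counts[1, alt]]
    )
    E = np.array([0.0, 0.0, 1.0, 1.0])
    C = np.array([0.0, 1.0, 0.0, 1.0])
    exog = np.column_stack([np.ones(4), E, C, E * C])
    with _quiet_saturated_fit():
        fit = sm.GLM(endog, exog, family=sm.families.Poisson()).fit()
    return _wald(
        table.levels[alt],
        float(fit.params[3]),
        float(fit.bse[3]),
        "poisson_oracle",
        corrected,
        table.total,
    )


def run_analysis(
    records: pd.DataFrame,
    calendar: ExposureCalendar,
    lags: Sequence[int] = (3, 7),
    codings: Sequence[CharacteristicCoding] = DEFAULT_CODINGS,
    mode: str = "suicide",
    correction: bool = False,
    verify_ml: bool = True,
) -> pd.DataFrame:
    """Full case-only analysis over lags and characteristics.

    Applies cause selection and exclusions, recodes age, merges with the
    calendar at each lag, and estimates the interaction for every
    characteristic: binary codings via the case-only OR, multi-level
    codings via multinomial RRRs against the coded base level.

    Returns a tidy table with one row per (lag, characteristic,
    non-reference level): estimate, 95% CI, Wald p-value and a
    significance flag at p < .05.
    """
    if not len(lags):
        raise ValueError("lags must be non-empty")
    selected = select_cause(records, mode)
    kept, drops = apply_exclusions(selected)
    if len(kept) and "age_group" in [c.name for c in codings]:
        kept = kept.copy()
        kept["age_group"] = derive_age_group(kept["age"])
    out = []
    for lag in lags:
        rows, n_dropped = merge_with_lag(kept, calendar, lag)
        for coding in codings:
            try:
                table = crosstab(rows, coding)
                if len(coding.levels) == 2:
                    ests = [caseonly_or_binary(table, correction, verify_ml)]
                else:
                    ests = caseonly_rrr_multinomial(table, correction, verify_ml)
            except (ZeroCellError, ValueError) as err:
                raise type(err)(f"lag={lag}, characteristic={coding.name}: {err}") from err
            for est in ests:
                out.append(
                    {
                        "characteristic": coding.name,
                        "level": est.level,
                        "reference": coding.reference,
                        "lag_days": lag,
                        "estimate": est.estimate,
                        "se_log": est.se_log,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "p_value": est.p_value,
                        "significant": est.significant,
                        "estimator": est.estimator,
                        "corrected": est.corrected,
                        "n_rows": int(len(rows)),
                    }
                )
    return pd.DataFrame(
        out,
        columns=[
            "characteristic", "level", "reference", "lag_days", "estimate",
            "se_log", "ci_low", "ci_high", "p_value", "significant",
            "estimator", "corrected", "n_rows",
        ],
    )
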