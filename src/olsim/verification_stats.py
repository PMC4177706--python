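"""Statistical verification of sweep output.

Three layers, matching how the simulated data are analysed: descriptive
per-cell aggregation (min/max/mean over replicates), directional ordinary
least-squares checks of the posited relationships A-G on the cell means,
and a logistic regression for whether any advisor was available.

Only coefficient *signs* are asserted, and only for relationships where the
predictor is expected to be clearly resolved; magnitudes depend on modelling
choices that are not part of the contract and are reported, never asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .experiments import SWEEP_EXTRA_COLUMNS, SWEEP_FACTORS
from .model_core import ConfigurationError, TickRecord

__all__ = [
    "SIGN_RELATIONSHIPS",
    "SignCheck",
    "SignCheckReport",
    "SeparationError",
    "DegenerateRegressorError",
    "summarize_sweep",
    "run_sign_checks",
    "fit_availability_logistic",
]


class DegenerateRegressorError(ValueError):
    """A regression predictor has zero variance."""


class SeparationError(ValueError):
    """The logistic outcome is constant or perfectly separated."""


FACTOR_COLUMNS = tuple(SWEEP_FACTORS)
COUNT_COLUMNS = TickRecord.COUNT_FIELDS


def summarize_sweep(
    sweep: pd.DataFrame, expected_replicates: Optional[int] = None
) -> pd.DataFrame:
    """Aggregate a sweep table to one row per design cell.

    For each of the nine count variables the minimum, maximum and mean over
    replicates are computed (columns ``<var>_min``/``<var>_max``/
    ``<var>_mean``); the extra observables are averaged.  Exact arithmetic
    on the table — no resampling.
    """
    missing = [c for c in FACTOR_COLUMNS if c not in sweep.columns]
    if missing:
        raise ConfigurationError(f"sweep table lacks factor columns: {missing}")
    grouped = sweep.groupby(list(FACTOR_COLUMNS), sort=True)
    sizes = grouped.size()
    if expected_replicates is not None:
        short = sizes[sizes != expected_replicates]
        if not short.empty:
            cell = dict(zip(FACTOR_COLUMNS, short.index[0]))
            raise ConfigurationError(
                f"cell {cell} has {int(short.iloc[0])} replicates, "
                f"expected {expected_replicates}"
            )
    elif sizes.nunique() > 1:
        cell = dict(zip(FACTOR_COLUMNS, sizes.idxmin()))
        raise ConfigurationError(
            f"unbalanced sweep table: cell {cell} has {int(sizes.min())} "
            f"replicates while others have {int(sizes.max())}"
        )

    agg = {}
    for name in COUNT_COLUMNS:
        agg[f"{name}_min"] = (name, "min")
        agg[f"{name}_max"] = (name, "max")
        agg[f"{name}_mean"] = (name, "mean")
    for name in SWEEP_EXTRA_COLUMNS:
        if name in sweep.columns:
            agg[f"{name}_mean"] = (name, "mean")
    summary = grouped.agg(**agg).reset_index()
    summary.insert(len(FACTOR_COLUMNS), "n_replicates", sizes.values)
    return summary


@dataclass(frozen=True)
class _Predictor:
    column: str
    expected_sign: int  # +1 or -1
    asserted: bool  # non-significant relationships are reported only


@dataclass(frozen=True)
class _Relationship:
    label: str
    description: str
    outcome: str
    predictors: tuple


#: The posited relationships, on cell-mean columns.  ``asserted=False``
#: predictors were not clearly resolved in the source analysis and are
#: fitted but not sign-checked.
SIGN_RELATIONSHIPS: Sequence[_Relationship] = (
    _Relationship(
        "A",
        "motives and prior beliefs predict visibility",
        "visible_mean",
        (
            _Predictor("mean_prior_belief", +1, True),
            _Predictor("mean_motives", -1, True),
        ),
    ),
    _Relationship(
        "B",
        "visibility and authority predict credibility",
        "obs_mean_credibility_mean",
        (
            _Predictor("mean_earned_authority", +1, True),
            _Predictor("visible_mean", -1, True),
        ),
    ),
    _Relationship(
        "C",
        "prior beliefs and evidence predict new beliefs",
        "obs_mean_new_belief_mean",
        (
            _Predictor("mean_prior_belief", +1, True),
            _Predictor("mean_evidence", +1, True),
        ),
    ),
    _Relationship(
        "D",
        "visible agents and the credibility threshold predict availability",
        "available_mean",
        (
            _Predictor("visible_mean", +1, True),
            _Predictor("credibility_threshold", -1, True),
        ),
    ),
    _Relationship(
        "E",
        "prior beliefs, evidence and announcer credibility predict need for advice",
        "need_advice_mean",
        (
            _Predictor("mean_prior_belief", +1, False),
            _Predictor("mean_evidence", -1, False),
            _Predictor("announcer_credibility_mean", -1, True),
        ),
    ),
    _Relationship(
        "F",
        "revised assessments predict beliefs revised on advice",
        "revised_via_advice_mean",
        (
            _Predictor("revised_evidence_assessment_mean", -1, False),
            _Predictor("revised_credibility_assessment_mean", +1, True),
        ),
    ),
    _Relationship(
        "G",
        "giving and needing advice predict beliefs revised on advice",
        "revised_via_advice_mean",
        (
            _Predictor("gave_advice_mean", +1, True),
            _Predictor("need_advice_mean", +1, True),
        ),
    ),
)


@dataclass
class SignCheck:
    label: str
    description: str
    outcome: str
    predictor: str
    expected_sign: int
    coefficient: float
    p_value: float
    asserted: bool

    @property
    def observed_sign(self) -> int:
        return int(np.sign(self.coefficient))

    @property
    def passed(self) -> bool:
        return (not self.asserted) or self.observed_sign == self.expected_sign

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "description": self.description,
            "outcome": self.outcome,
            "predictor": self.predictor,
            "expected_sign": self.expected_sign,
            "observed_sign": self.observed_sign,
            "coefficient": self.coefficient,
            "p_value": self.p_value,
            "asserted": self.asserted,
            "pass": self.passed,
        }


@dataclass
class SignCheckReport:
    checks: list

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list:
        return [c for c in self.checks if not c.passed]

    def to_records(self) -> list:
        return [c.to_dict() for c in self.checks]

    def to_text(self) -> str:
        lines = ["sign checks (asserted predictors marked *):"]
        for c in self.checks:
            mark = "*" if c.asserted else " "
            verdict = "ok" if c.passed else "FAIL"
            lines.append(
                f"  [{c.label}]{mark} {c.outcome} ~ {c.predictor}: "
                f"coef={c.coefficient:+.4g} (p={c.p_value:.3g}) "
                f"expected {'+' if c.expected_sign > 0 else '-'} -> {verdict}"
            )
        lines.append(
            "overall: " + ("PASS" if self.all_passed else "FAIL")
        )
        return "\n".join(lines)


def _fit_ols(summary: pd.DataFrame, outcome: str, predictors: Sequence[str]):
    for col in (outcome, *predictors):
        if col not in summary.columns:
            raise ConfigurationError(f"summary table lacks column {col!r}")
    X = summary[list(predictors)].astype(float)
    degenerate = [c for c in predictors if X[c].nunique() <= 1]
    if degenerate:
        raise DegenerateRegressorError(
            f"zero-variance regressors: {degenerate}"
        )
    model = sm.OLS(summary[outcome].astype(float), sm.add_constant(X))
    return model.fit()


def run_sign_checks(summary: pd.DataFrame) -> SignCheckReport:
    """Fit each posited relationship on cell means and check coefficient signs."""
    checks = []
    for rel in SIGN_RELATIONSHIPS:
        result = _fit_ols(
            summary, rel.outcome, [p.column for p in rel.predictors]
        )
        for pred in rel.predictors:
            checks.append(
                SignCheck(
                    label=rel.label,
                    description=rel.description,
                    outcome=rel.outcome,
                    predictor=pred.column,
                    expected_sign=pred.expected_sign,
                    coefficient=float(result.params[pred.column]),
                    p_value=float(result.pvalues[pred.column]),
                    asserted=pred.asserted,
                )
            )
    return SignCheckReport(checks)


AVAILABILITY_PREDICTORS = (
    "mean_prior_belief",
    "mean_earned_authority",
    "credibility_threshold",
    "n_staff",
    "mean_evidence",
    "mean_motives",
    "n_educators",
)


@dataclass
class LogisticReport:
    coefficients: pd.Series
    p_values: pd.Series
    n_rows: int
    outcome_rate: float

    def to_records(self) -> dict:
        return {
            name: {
                "coefficient": float(self.coefficients[name]),
                "p_value": float(self.p_values[name]),
            }
            for name in self.coefficients.index
        }


def fit_availability_logistic(sweep: pd.DataFrame) -> LogisticReport:
    """Logistic regression of any-advisor-available on the design factors.

    The binary outcome is ``available > 0`` per sweep row.  A constant
    outcome (or perfect separation) is raised as :class:`SeparationError`
    rather than silently regularized.
    """
    for col in (*AVAILABILITY_PREDICTORS, "available"):
        if col not in sweep.columns:
            raise ConfigurationError(f"sweep table lacks column {col!r}")
    y = (sweep["available"] > 0).astype(float)
    if y.nunique() <= 1:
        raise SeparationError(
            "availability outcome is constant; logistic fit is degenerate"
        )
    X = sweep[list(AVAILABILITY_PREDICTORS)].astype(float)
    degenerate = [c for c in AVAILABILITY_PREDICTORS if X[c].nunique() <= 1]
    if degenerate:
        raise DegenerateRegressorError(f"zero-variance regressors: {degenerate}")
    model = sm.Logit(y, sm.add_constant(X))
    try:
        result = model.fit(disp=False, maxiter=200)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not result.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge (separation?)")
    return LogisticReport(
        coefficients=result.params.drop("const"),
        p_values=result.pvalues.drop("const"),
        n_rows=len(sweep),
        outcome_rate=float(y.mean()),
    )
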