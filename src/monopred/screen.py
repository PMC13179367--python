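"""Threshold-combination screening of quantitative indicators.

Each patient i carries indicator values x_ik (k in {A, B, C}) and a binary
outcome y_i (1 = pCR/MPR responder).  For every indicator the candidate
threshold range is [L_k, U_k] with L_k the responder-group minimum and U_k
the non-responder-group maximum.  A combination S of indicators with
thresholds tau predicts a patient responder iff x_ik >= tau_k for ALL k in S
(the inequality is inclusive).  The screen exhaustively evaluates every
threshold grid point for every allowed combination and ranks configurations
by a selection score, by default accuracy / sqrt(n_pass) as printed for this
screening procedure.  Note this score decreases with coverage at fixed
accuracy even though the procedure is motivated as an accuracy/coverage
balance — it is implemented verbatim; `accuracy * sqrt(n_pass)` is available
behind an explicit flag.

Two coverage notions are reported: responder coverage (responders passing /
all responders — the headline definition) and prediction coverage (patients
receiving a prediction / all patients, relevant when indicators are missing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd

__all__ = [
    "candidate_range",
    "build_grid",
    "predict",
    "metrics",
    "selection_score",
    "grid_search",
    "validate_external",
    "ThresholdScreen",
    "ScreenResult",
    "ScreenResults",
    "DEFAULT_COMBINATIONS",
]

#: The allowed combination set: the three singles and the three pairs.
DEFAULT_COMBINATIONS = (("A",), ("B",), ("C",), ("A", "B"), ("A", "C"), ("B", "C"))


def candidate_range(x_k, y) -> tuple[float, float, bool]:
    """Candidate threshold range [L_k, U_k] for one indicator.

    L_k = min of x_k over responders (y=1), U_k = max over non-responders
    (y=0), missing values ignored.  Returns (L, U, degenerate): degenerate
    marks perfect separation (L > U, empty interior).
    """
    x_k = np.asarray(x_k, dtype=float)
    y = np.asarray(y)
    pos = x_k[(y == 1) & np.isfinite(x_k)]
    neg = x_k[(y == 0) & np.isfinite(x_k)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("range unavailable: a class has no non-missing values")
    lo, hi = float(pos.min()), float(neg.max())
    return lo, hi, lo > hi


def build_grid(x_k, y, step: float | None = None) -> np.ndarray:
    """Candidate thresholds for one indicator.

    Default grid: sorted unique observed values of x_k inside [L_k, U_k],
    always including L_k (for step-function metrics the observed values are
    exhaustive).  With ``step`` set, a fixed-step grid over [L_k, U_k] is
    used instead.  A degenerate (perfectly separating) range yields the
    single point L_k.
    """
    lo, hi, degenerate = candidate_range(x_k, y)
    if degenerate:
        return np.array([lo])
    if step is not None:
        if step <= 0:
            raise ValueError("step must be positive")
        grid = np.arange(lo, hi + step / 2, step)
    else:
        x = np.asarray(x_k, dtype=float)
        x = x[np.isfinite(x)]
        grid = np.unique(np.concatenate([[lo], x[(x >= lo) & (x <= hi)]]))
    return grid


def predict(S, tau, X: pd.DataFrame) -> pd.Series:
    """Per-patient prediction under the AND rule x_ik >= tau_k for all k in S.

    Returns 1.0 (predicted responder), 0.0, or NaN for patients missing a
    required indicator (unassigned).
    """
    S = tuple(S)
    if not S:
        raise ValueError("combination S must be non-empty")
    tau = dict(zip(S, np.atleast_1d(tau))) if not isinstance(tau, dict) else tau
    missing = [k for k in S if k not in tau]
    if missing:
        raise ValueError(f"no threshold for indicator(s) {missing}")
    vals = X[list(S)].to_numpy(dtype=float)
    taus = np.array([tau[k] for k in S], dtype=float)
    passed = (vals >= taus).all(axis=1).astype(float)
    passed[np.isnan(vals).any(axis=1)] = np.nan
    return pd.Series(passed, index=X.index, name="predicted")


def metrics(pred: pd.Series, y) -> dict:
    """Coverage/accuracy metrics of a prediction against the outcome.

    n_pass counts patients passing all thresholds; coverage (headline) is
    responders passing / all evaluable responders; prediction_coverage is
    the fraction of patients receiving a prediction; accuracy is responders
    passing / n_pass, None (unavailable) when nobody passes.  Patients with
    missing indicators enter neither numerator nor denominator but are
    counted in n_unassigned.
    """
    y = np.asarray(pd.Series(y).reindex(pred.index) if hasattr(y, "reindex") else y)
    p = pred.to_numpy(dtype=float)
    assigned = ~np.isnan(p)
    n_pass = int((p[assigned] == 1).sum())
    tp = int(((p == 1) & (y == 1) & assigned).sum())
    n_pos = int((y[assigned] == 1).sum())
    return {
        "n": int(p.size),
        "n_unassigned": int((~assigned).sum()),
        "n_pass": n_pass,
        "true_positives": tp,
        "coverage": tp / n_pos if n_pos else None,
        "prediction_coverage": assigned.sum() / p.size if p.size else None,
        "accuracy": tp / n_pass if n_pass else None,
    }


def selection_score(accuracy: float, n_pass: int, variant: str = "ratio-sqrt") -> float:
    """Quality score of a threshold configuration.

    "ratio-sqrt" (default): accuracy / sqrt(n_pass), the printed criterion.
    "times-sqrt": accuracy * sqrt(n_pass), an alternative that rewards
    coverage; opt-in only.
    """
    if n_pass < 1:
        raise ValueError("score unavailable when n_pass = 0")
    if variant == "ratio-sqrt":
        return accuracy / np.sqrt(n_pass)
    if variant == "times-sqrt":
        return accuracy * np.sqrt(n_pass)
    raise ValueError(f"unknown score variant {variant!r}")


@dataclass(frozen=True)
class ScreenResult:
    """One evaluated (combination, thresholds) configuration."""

    combination: tuple[str, ...]
    thresholds: dict[str, float]
    n_pass: int
    coverage: float | None
    prediction_coverage: float | None
    accuracy: float | None
    score: float | None
    degenerate: tuple[str, ...] = ()

    def sort_key(self):
        # score desc, then fewer indicators, higher accuracy, higher
        # coverage, lexicographic S, ascending thresholds — deterministic.
        return (
            -(self.score if self.score is not None else -np.inf),
            len(self.combination),
            -(self.accuracy if self.accuracy is not None else -np.inf),
            -(self.coverage if self.coverage is not None else -np.inf),
            self.combination,
            tuple(self.thresholds[k] for k in self.combination),
        )


@dataclass
class ScreenResults:
    """Ranked screening results with the data context of the fit."""

    ranked: list[ScreenResult]
    n_patients: int
    n_responders: int
    score_variant: str

    @property
    def best(self) -> ScreenResult:
        return self.ranked[0]

    def to_frame(self, top: int | None = None) -> pd.DataFrame:
        rows = self.ranked[: top if top is not None else len(self.ranked)]
        return pd.DataFrame(
            {
                "combination": ["+".join(r.combination) for r in rows],
                "thresholds": [
                    ";".join(f"{k}>={v:g}" for k, v in r.thresholds.items()) for r in rows
                ],
                "n_pass": [r.n_pass for r in rows],
                "coverage": [r.coverage for r in rows],
                "accuracy": [r.accuracy for r in rows],
                "score": [r.score for r in rows],
            }
        )

    def summary(self, top: int = 5) -> str:
        b = self.best
        head = (
            f"Threshold screen over {self.n_patients} patients "
            f"({self.n_responders} responders), score = {self.score_variant}\n"
            f"Best: {'+'.join(b.combination)} at "
            + ", ".join(f"{k} >= {v:g}" for k, v in b.thresholds.items())
            + f" | n_pass={b.n_pass} coverage={b.coverage:.3f} "
            f"accuracy={b.accuracy:.3f} score={b.score:.4f}\n"
        )
        return head + self.to_frame(top).to_string(index=False)


class ThresholdScreen:
    """Exhaustive threshold-combination screen of an indicator matrix.

    Parameters
    ----------
    X : DataFrame
        One row per patient, one column per indicator; NaN = missing.
    y : array-like
        Binary outcome aligned with ``X`` (1 = responder).
    combinations : iterable of tuple, optional
        Allowed indicator subsets; default is all singles and pairs of the
        first three columns (``include_triple`` adds the full panel).
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        combinations_: tuple[tuple[str, ...], ...] | None = None,
        include_triple: bool = False,
        grid_step: float | None = None,
        score_variant: str = "ratio-sqrt",
    ):
        self.X = X
        self.y = np.asarray(pd.Series(y).reindex(X.index) if hasattr(y, "reindex") else y)
        cols = list(X.columns)
        if combinations_ is None:
            combos = [tuple([c]) for c in cols]
            combos += [tuple(s) for s in combinations(cols, 2)]
            if include_triple and len(cols) >= 3:
                combos += [tuple(s) for s in combinations(cols, 3)]
            combinations_ = tuple(combos)
        if not combinations_:
            raise ValueError("need at least one combination")
        self.combinations_ = tuple(tuple(s) for s in combinations_)
        self.grid_step = grid_step
        self.score_variant = score_variant

    def fit(self) -> ScreenResults:
        grids: dict[str, np.ndarray] = {}
        degenerate: set[str] = set()
        for k in self.X.columns:
            try:
                grids[k] = build_grid(self.X[k], self.y, step=self.grid_step)
                if candidate_range(self.X[k], self.y)[2]:
                    degenerate.add(k)
            except ValueError:
                warnings.warn(f"indicator {k!r}: range unavailable, skipped")
        results: list[ScreenResult] = []
        for S in self.combinations_:
            if any(k not in grids for k in S):
                continue
            if any(g.size == 0 for g in (grids[k] for k in S)):
                raise ValueError(f"empty grid for combination {S}")
            for taus in product(*(grids[k] for k in S)):
                tau = dict(zip(S, (float(t) for t in taus)))
                m = metrics(predict(S, tau, self.X), self.y)
                score = (
                    selection_score(m["accuracy"], m["n_pass"], self.score_variant)
                    if m["n_pass"]
                    else None
                )
                results.append(
                    ScreenResult(
                        combination=S, thresholds=tau, n_pass=m["n_pass"],
                        coverage=m["coverage"],
                        prediction_coverage=m["prediction_coverage"],
                        accuracy=m["accuracy"], score=score,
                        degenerate=tuple(k for k in S if k in degenerate),
                    )
                )
        results.sort(key=ScreenResult.sort_key)
        return ScreenResults(
            ranked=results, n_patients=len(self.X),
            n_responders=int((self.y == 1).sum()), score_variant=self.score_variant,
        )


def grid_search(
    X: pd.DataFrame,
    y,
    combinations_=None,
    include_triple: bool = False,
    grid_step: float | None = None,
    score_variant: str = "ratio-sqrt",
) -> ScreenResults:
    """Exhaustively evaluate all combinations x threshold grid points; see
    :class:`ThresholdScreen`."""
    return ThresholdScreen(
        X, y, combinations_=combinations_, include_triple=include_triple,
        grid_step=grid_step, score_variant=score_variant,
    ).fit()


def validate_external(rule: ScreenResult, X: pd.DataFrame, y) -> ScreenResult:
    """Apply a fixed, previously chosen rule to a held-out indicator matrix.

    No refitting: the combination and thresholds are used as-is.  Indicators
    absent from the validation table cause the rule to be skipped with a
    warning (returns None).
    """
    missing = [k for k in rule.combination if k not in X.columns]
    if missing:
        warnings.warn(f"indicator(s) {missing} absent from validation table; rule skipped")
        return None
    m = metrics(predict(rule.combination, rule.thresholds, X), y)
    score = (
        selection_score(m["accuracy"], m["n_pass"]) if m["n_pass"] else None
    )
    return ScreenResult(
        combination=rule.combination, thresholds=dict(rule.thresholds),
        n_pass=m["n_pass"], coverage=m["coverage"],
        prediction_coverage=m["prediction_coverage"], accuracy=m["accuracy"],
        score=score,
    )
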