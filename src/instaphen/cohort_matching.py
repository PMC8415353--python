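"""1:1 case-control matching on age, sex and race via propensity scores.

A logistic model of case membership on {age, sex, race dummies} yields a
propensity score per record; cases are then paired greedily to the nearest
unused control on the logit scale, processing cases in descending propensity
(hardest-to-match first).  This transparent greedy matcher is a deliberate
simplification of genetic/optimal matching packages: the scientific content
is the matched design, not the matcher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .archive_io import RACE_LEVELS, DemographicRecord

#: covariate columns used by the propensity model and the balance report
COVARIATES = ("age", "sex_male") + tuple(
    f"race_{lvl.split('/')[0].split()[0].lower()}" for lvl in RACE_LEVELS[1:]
)


def _design(records: list[DemographicRecord]) -> np.ndarray:
    """Covariate matrix: age, male dummy, race dummies (first level reference)."""
    rows = []
    for rec in records:
        race = [1.0 if rec.race == lvl else 0.0 for lvl in RACE_LEVELS[1:]]
        rows.append([rec.age, 1.0 if rec.sex == "male" else 0.0, *race])
    return np.asarray(rows, dtype=np.float64)


def _smd(x_case: np.ndarray, x_ctrl: np.ndarray) -> np.ndarray:
    """Absolute standardized mean difference per covariate column."""
    mc, mk = x_case.mean(axis=0), x_ctrl.mean(axis=0)
    vc = x_case.var(axis=0, ddof=1) if len(x_case) > 1 else np.zeros(x_case.shape[1])
    vk = x_ctrl.var(axis=0, ddof=1) if len(x_ctrl) > 1 else np.zeros(x_ctrl.shape[1])
    pooled = np.sqrt((vc + vk) / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        smd = np.abs(mc - mk) / pooled
    return np.where(pooled == 0, 0.0, smd)


@dataclass(frozen=True)
class MatchResult:
    pairs: tuple[tuple[str, str], ...]
    unmatched_controls: tuple[str, ...]
    #: covariate -> (abs SMD before matching, abs SMD after matching)
    balance_report: dict[str, tuple[float, float]]
    seed: int

    def control_ids(self) -> tuple[str, ...]:
        return tuple(c for _, c in self.pairs)


def propensity_match(
    cases: list[DemographicRecord],
    controls: list[DemographicRecord],
    seed: int = 0,
) -> MatchResult:
    """Match each case 1:1 without replacement to the nearest control.

    Requires at least as many controls as cases.  Deterministic given the
    input order (ties on the logit are broken by input order); ``seed`` is
    recorded for provenance.
    """
    if len(controls) < len(cases):
        raise ValueError(
            f"need |controls| >= |cases|, got {len(controls)} < {len(cases)}"
        )
    x_case, x_ctrl = _design(cases), _design(controls)
    x = np.vstack([x_case, x_ctrl])
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    # light ridge keeps the fit defined under complete separation
    model = LogisticRegression(C=1e3, max_iter=2000, solver="lbfgs")
    model.fit((x - x.mean(0)) / np.where(x.std(0) == 0, 1, x.std(0)), y)
    xs = (x - x.mean(0)) / np.where(x.std(0) == 0, 1, x.std(0))
    logit = xs @ model.coef_.ravel() + model.intercept_[0]
    logit_case, logit_ctrl = logit[: len(cases)], logit[len(cases):]

    order = sorted(range(len(cases)), key=lambda i: (-logit_case[i], i))
    used: set[int] = set()
    pairs: list[tuple[str, str]] = []
    matched_idx: list[int] = []
    for i in order:
        best, best_d = -1, np.inf
        for j in range(len(controls)):
            if j in used:
                continue
            d = abs(logit_case[i] - logit_ctrl[j])
            if d < best_d - 1e-15:
                best, best_d = j, d
        used.add(best)
        pairs.append((cases[i].participant_id, controls[best].participant_id))
        matched_idx.append(best)

    pairs.sort(key=lambda pc: [c.participant_id for c in cases].index(pc[0]))
    x_matched = x_ctrl[matched_idx]
    before = _smd(x_case, x_ctrl)
    after = _smd(x_case, x_matched)
    balance = {
        cov: (float(b), float(a)) for cov, b, a in zip(COVARIATES, before, after)
    }
    unmatched = tuple(
        controls[j].participant_id for j in range(len(controls)) if j not in used
    )
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_controls=unmatched,
        balance_report=balance,
        seed=seed,
    )
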