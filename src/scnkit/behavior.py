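"""Y-maze spontaneous alternation scoring and group-level tests.

Animals run consecutive forced-choice trials between two goal arms; an
alternation is a trial whose chosen arm differs from the previous trial's.
The percent-alternation index is the working-memory readout: under random
responding it sits at the 50% chance level when scored over trials-1
adjacent pairs.  Group effects are tested with a one-way ANOVA on the
percent scores and, because 7-trial proportions are neither normal nor
continuous, with a joint Wald test in a binomial (logistic) regression on
the alternation counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TrialRecord",
    "AlternationScore",
    "AnovaResult",
    "WaldResult",
    "score_alternation",
    "group_anova",
    "group_wald_logistic",
]

DenominatorRule = Literal["trials_minus_one", "trials"]


@dataclass(frozen=True)
class TrialRecord:
    """Ordered goal-arm choices for one animal (two-arm alphabet)."""

    animal_id: str
    choices: str
    group: str | None = None

    def __post_init__(self) -> None:
        if len(self.choices) < 2:
            raise ValueError(f"{self.animal_id}: need at least 2 trials")
        symbols = set(self.choices)
        if len(symbols) > 2:
            raise ValueError(
                f"{self.animal_id}: more than 2 distinct arm labels: {sorted(symbols)}"
            )


@dataclass(frozen=True)
class AlternationScore:
    animal_id: str
    n_alternations: int
    n_scorable: int
    percent: float
    group: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_alternations <= self.n_scorable:
            raise ValueError("alternation count outside [0, n_scorable]")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class WaldResult:
    chi2: float
    df: int
    p: float
    converged: bool = True


def score_alternation(
    record: TrialRecord, denominator_rule: DenominatorRule = "trials_minus_one"
) -> AlternationScore:
    """Count adjacent-trial arm switches and convert to percent alternation.

    ``n_alternations`` counts trials (from the second on) whose choice
    differs from the immediately preceding one.  The default denominator is
    trials-1 — the number of scorable adjacent pairs, which puts random
    responding at exactly 50% — while ``"trials"`` divides by the raw trial
    count instead.
    """
    c = record.choices
    n_alt = sum(1 for a, b in zip(c, c[1:]) if a != b)
    if denominator_rule == "trials_minus_one":
        n_scorable = len(c) - 1
    elif denominator_rule == "trials":
        n_scorable = len(c)
    else:
        raise ValueError(f"unknown denominator rule {denominator_rule!r}")
    return AlternationScore(
        animal_id=record.animal_id,
        n_alternations=n_alt,
        n_scorable=n_scorable,
        percent=100.0 * n_alt / n_scorable,
        group=record.group,
    )


def _by_group(items, groups: Sequence[str] | None):
    if groups is None:
        groups = [getattr(x, "group") for x in items]
        if any(g is None for g in groups):
            raise ValueError("group labels required (on records or as argument)")
    if len(groups) != len(items):
        raise ValueError("one group label per record required")
    out: dict[str, list] = {}
    for x, g in zip(items, groups):
        out.setdefault(g, []).append(x)
    return out

def group_anova(
    scores: Sequence[AlternationScore], groups: Sequence[str] | None = None
) -> AnovaResult:
    """One-way fixed-effects ANOVA on percent-alternation scores.

    A design with zero within-group variance is reported as degenerate
    (F and p NaN, ``degenerate=True``) rather than propagating NaN from a
    0/0 variance ratio.
    """
    grouped = _by_group(scores, groups)
    if len(grouped) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    samples = []
    for g, items in grouped.items():
        if len(items) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 animals")
        samples.append(np.array([s.percent for s in items]))
    df_b = len(samples) - 1
    df_w = sum(len(s) for s in samples) - len(samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ss_within == 0:
        return AnovaResult(float("nan"), df_b, df_w, float("nan"), degenerate=True)
    F, p = stats.f_oneway(*samples)
    return AnovaResult(float(F), df_b, df_w, float(p))


def group_wald_logistic(
    trials: Sequence[TrialRecord],
    groups: Sequence[str] | None = None,
    denominator_rule: DenominatorRule = "trials_minus_one",
) -> WaldResult:
    """Joint Wald chi-square for the group factor in a binomial regression.

    Per-animal alternation counts (out of scorable trials) are regressed on
    group indicator dummies; the statistic tests all group coefficients
    jointly with df = n_groups - 1.  Separation or a failed fit is flagged
    non-convergent instead of reporting a fabricated p.
    """
    import statsmodels.api as sm

    grouped = _by_group(trials, groups)
    labels = sorted(grouped)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for a group contrast")
    rows, endog = [], []
    for gi, g in enumerate(labels):
        for rec in grouped[g]:
            s = score_alternation(rec, denominator_rule)
            endog.append([s.n_alternations, s.n_scorable - s.n_alternations])
            rows.append(gi)
    endog = np.asarray(endog, dtype=float)
    dummies = np.zeros((len(rows), len(labels) - 1))
    for i, gi in enumerate(rows):
        if gi > 0:
            dummies[i, gi - 1] = 1.0
    X = sm.add_constant(dummies)
    try:
        fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        if not np.isfinite(fit.bse).all():
            raise FloatingPointError("infinite standard errors (separation)")
        k = len(labels) - 1
        contrast = np.zeros((k, k + 1))
        contrast[:, 1:] = np.eye(k)
        wt = fit.wald_test(contrast, scalar=True)
        return WaldResult(chi2=float(wt.statistic), df=k, p=float(wt.pvalue))
    except Exception:
        return WaldResult(float("nan"), len(labels) - 1, float("nan"), converged=False)


def scores_to_counts(
    scores: Sequence[AlternationScore],
) -> dict[str, tuple[int, int]]:
    """Map animal id -> (alternations, scorable trials) for association models."""
    return {s.animal_id: (s.n_alternations, s.n_scorable) for s in scores}


def read_trials(path) -> list[TrialRecord]:
    """Read a delimited trials file: animal_id, group, choices (e.g. ABBABAB)."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    need = {"animal_id", "group", "choices"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return [
        TrialRecord(animal_id=r.animal_id, choices=r.choices, group=r.group)
        for r in df.itertuples()
    ]


def write_trials(records: Sequence[TrialRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "group": [r.group for r in records],
            "choices": [r.choices for r in records],
        }
    ).to_csv(path, index=False)
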