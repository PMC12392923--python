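"""Questionnaire scoring and behavioral performance metrics.

Implements the two self-report instruments used around a mental-arithmetic
stress session — the Brief Mood Introspection Scale (BMIS; 16 adjectives,
1-4 Likert, mood = positive sum minus negative sum) and the Primary
Appraisal Secondary Appraisal scale (PASA; 16 items, 1-6 Likert, four
subscales with five reverse-scored items, global index = primary minus
secondary appraisal) — plus error-rate / response-time summaries of the
trial-level event table.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: BMIS adjectives, 8 positive + 8 negative, rated 1-4.
BMIS_POSITIVE = ("happy", "lively", "caring", "content",
                 "peppy", "loving", "active", "calm")
BMIS_NEGATIVE = ("sad", "tired", "jittery", "drowsy",
                 "fed_up", "gloomy", "grouchy", "nervous")

#: PASA subscales -> (item key, reverse-scored flag), four items each.
#: Reverse-scored items are answered as 7 - x. The reversed counts per
#: subscale are 2 (threat), 2 (challenge), 1 (self-efficacy), 0 (control
#: expectancy).
PASA_ITEMS: dict[str, tuple[tuple[str, bool], ...]] = {
    "threat": (
        ("threat_1", True),    # "I do not feel threatened ..."
        ("threat_2", False),
        ("threat_3", True),    # "I do not feel worried ..."
        ("threat_4", False),
    ),
    "challenge": (
        ("challenge_1", False),
        ("challenge_2", True),  # "I do not care ..."
        ("challenge_3", True),  # "... not a challenge for me"
        ("challenge_4", False),
    ),
    "self_efficacy": (
        ("self_efficacy_1", False),
        ("self_efficacy_2", True),  # "I have no idea what I should do"
        ("self_efficacy_3", False),
        ("self_efficacy_4", False),
    ),
    "control_expectancy": (
        ("control_expectancy_1", False),
        ("control_expectancy_2", False),
        ("control_expectancy_3", False),
        ("control_expectancy_4", False),
    ),
}

PASA_ITEM_KEYS = tuple(k for items in PASA_ITEMS.values() for k, _ in items)


def score_bmis(items: Mapping[str, int] | Iterable[int]) -> int:
    """BMIS mood score: sum of positive minus sum of negative adjectives.

    ``items`` is either a mapping keyed by adjective or a 16-vector ordered
    positive-then-negative. Range is -24 (all negative at 4, positive at 1)
    to +24.
    """
    if isinstance(items, Mapping):
        missing = [a for a in BMIS_POSITIVE + BMIS_NEGATIVE if a not in items]
        if missing:
            raise ValueError(f"missing BMIS items: {missing}")
        pos = [int(items[a]) for a in BMIS_POSITIVE]
        neg = [int(items[a]) for a in BMIS_NEGATIVE]
    else:
        vals = [int(v) for v in items]
        if len(vals) != 16:
            raise ValueError("BMIS requires exactly 16 item scores")
        pos, neg = vals[:8], vals[8:]
    for v in pos + neg:
        if not 1 <= v <= 4:
            raise ValueError(f"BMIS item score {v} outside 1-4")
    return sum(pos) - sum(neg)


def score_pasa(items: Mapping[str, float] | Iterable[float],
               aggregate: str = "mean") -> pd.Series:
    """Score one PASA administration.

    Reverse-scored items are mapped to ``7 - x`` first. Each subscale is then
    the mean (default) or sum of its four items; primary appraisal combines
    threat and challenge, secondary appraisal combines self-efficacy and
    control expectancy, and the global stress index is primary - secondary.

    Returns a Series with threat, challenge, self_efficacy,
    control_expectancy, primary, secondary and index.
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    if not isinstance(items, Mapping):
        vals = list(items)
        if len(vals) != 16:
            raise ValueError("PASA requires exactly 16 item scores")
        items = dict(zip(PASA_ITEM_KEYS, vals))

    out: dict[str, float] = {}
    for subscale, defs in PASA_ITEMS.items():
        scored = []
        for key, reverse in defs:
            if key not in items:
                raise ValueError(f"missing PASA item {key}")
            x = float(items[key])
            if not 1.0 <= x <= 6.0:
                raise ValueError(f"PASA item {key}={x} outside 1-6")
            scored.append(7.0 - x if reverse else x)
        out[subscale] = float(np.sum(scored) if aggregate == "sum"
                              else np.mean(scored))
    combine = (lambda a, b: a + b) if aggregate == "sum" else \
              (lambda a, b: 0.5 * (a + b))
    out["primary"] = combine(out["threat"], out["challenge"])
    out["secondary"] = combine(out["self_efficacy"], out["control_expectancy"])
    out["index"] = out["primary"] - out["secondary"]
    return pd.Series(out)


def score_pasa_table(responses: pd.DataFrame,
                     aggregate: str = "mean") -> pd.DataFrame:
    """Score a long PASA table (participant, phase, one column per item)."""
    rows = []
    for _, row in responses.iterrows():
        scores = score_pasa({k: row[k] for k in PASA_ITEM_KEYS}, aggregate)
        scores["participant"] = row["participant"]
        scores["phase"] = row["phase"]
        rows.append(scores)
    cols = ["participant", "phase", "threat", "challenge", "self_efficacy",
            "control_expectancy", "primary", "secondary", "index"]
    return pd.DataFrame(rows)[cols]


def behavior_metrics(events: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Run- and phase-level performance summaries from the event table.

    Unanswered trials are already coded incorrect with the maximum allotted
    time as response time, so plain means are the intended estimators.

    Returns ``{"run": ..., "phase": ...}``; the run table has error_rate and
    mean_rt per participant x phase x run, the phase table adds relative_rt
    (participant phase mean RT divided by the cross-participant mean RT of
    that phase).
    """
    ev = events.copy()
    ev["error"] = 1.0 - ev["correct"].astype(float)

    run = (ev.groupby(["participant", "sex", "phase", "phase_code", "run"],
                      sort=True, observed=True)
             .agg(error_rate=("error", "mean"),
                  mean_rt=("response_time", "mean"),
                  n_trials=("trial", "size"))
             .reset_index())

    phase = (ev.groupby(["participant", "sex", "phase", "phase_code"],
                        sort=True, observed=True)
               .agg(error_rate=("error", "mean"),
                    mean_rt=("response_time", "mean"),
                    n_trials=("trial", "size"))
               .reset_index())
    cohort_rt = phase.groupby("phase", observed=True)["mean_rt"].transform("mean")
    phase["relative_rt"] = phase["mean_rt"] / cohort_rt
    return {"run": run, "phase": phase}


def phase_duration(mean_rt: float, n_trials: int) -> float:
    """Approximate task-time of one phase in minutes (one decimal).

    Excludes inter-run fixation breaks and questionnaire time: simply
    ``n_trials * mean_rt / 60``.
    """
    if mean_rt <= 0 or n_trials <= 0:
        raise ValueError("mean_rt and n_trials must be positive")
    return round(n_trials * mean_rt / 60.0, 1)
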