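"""Harmonization of heterogeneous current-smoking questions.

Surveys ask about smoking in three ways: the WHO current-smoking question
(any tobacco, daily or occasionally), a daily-smoking question, and a bare
conventional question ("Do you smoke in the present?") whose reading of
occasional smoking is ambiguous.  This module maps each variant onto a
common current-smoker flag and quantifies the definitional discrepancies:
the share of current smokers who smoke only occasionally, and the
understatement induced by restricting the WHO question to respondents with
at least 100 lifetime cigarettes.

The conventional question's ambiguity is modelled as a Bernoulli capture:
each occasional smoker answers "yes" with a configurable probability
(default 0.5), so the conventional prevalence sits between the daily and
WHO definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

VARIANTS = ("who_current", "daily", "conventional")


@dataclass(frozen=True)
class SmokingDefinition:
    variant: str = "who_current"
    capture_prob: float = 0.5  # P(occasional smoker answers yes) — conventional only

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown smoking-question variant {self.variant!r}")
        if not 0.0 <= self.capture_prob <= 1.0:
            raise ConfigurationError("capture probability must be in [0,1]")


def _check_flags(daily, occasional):
    if np.any(np.asarray(daily) & np.asarray(occasional)):
        raise DataError("records flagged both daily and occasional")


def harmonize_records(records: pd.DataFrame, definition: SmokingDefinition,
                      seed: int = 0) -> pd.DataFrame:
    """Return a copy with a harmonized boolean ``current_smoker`` column.

    who_current: daily or occasional.  daily: daily only.  conventional:
    daily always; occasional smokers captured with the definition's
    probability (deterministic given ``seed`` and record order).
    """
    daily = records["smokes_daily"].to_numpy(dtype=bool)
    occ = records["smokes_occasionally"].to_numpy(dtype=bool)
    _check_flags(daily, occ)
    if definition.variant == "who_current":
        cur = daily | occ
    elif definition.variant == "daily":
        cur = daily
    else:
        rng = np.random.default_rng(seed)
        captured = rng.random(len(records)) < definition.capture_prob
        cur = daily | (occ & captured)
    out = records.copy()
    out["current_smoker"] = cur
    return out


def classify_current(record, definition: SmokingDefinition, seed: int = 0) -> bool:
    """Classify a single record (a mapping with the smoking flags)."""
    daily = bool(record["smokes_daily"])
    occ = bool(record["smokes_occasionally"])
    if daily and occ:
        raise DataError("record flagged both daily and occasional")
    if definition.variant == "who_current":
        return daily or occ
    if definition.variant == "daily":
        return daily
    if daily:
        return True
    if occ:
        return bool(np.random.default_rng(seed).random() < definition.capture_prob)
    return False


def occasional_share(records: pd.DataFrame) -> float:
    """Share of WHO-current smokers who do not smoke daily."""
    daily = records["smokes_daily"].to_numpy(dtype=bool)
    occ = records["smokes_occasionally"].to_numpy(dtype=bool)
    _check_flags(daily, occ)
    n_current = int(daily.sum() + occ.sum())
    if n_current == 0:
        raise DataError("occasional share undefined: no current smokers")
    return float(occ.sum() / n_current)


def filter_effect_100cig(records: pd.DataFrame) -> float:
    """Understatement (percentage points) of WHO-current prevalence when the
    question is restricted to respondents with >= 100 lifetime cigarettes
    (others classified non-smokers).  Never negative."""
    flag = records["lifetime_cigarettes_ge_100"]
    if flag.isna().any():
        raise DataError("lifetime_cigarettes_ge_100 has missing values; "
                        "refusing to impute")
    flag = flag.to_numpy(dtype=bool)
    daily = records["smokes_daily"].to_numpy(dtype=bool)
    occ = records["smokes_occasionally"].to_numpy(dtype=bool)
    _check_flags(daily, occ)
    who = daily | occ
    n = len(records)
    if n == 0:
        raise DataError("no records")
    return 100.0 * float(who.mean() - (who & flag).mean())
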