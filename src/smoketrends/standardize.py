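"""Direct standardization of survey smoking prevalence.

Survey samples differ in age and educational composition, both across
studies and over time; crude prevalences are therefore not comparable.
Standardized prevalence is the weighted average of stratum-specific
prevalences with weights from a fixed external standard: the 1976 European
standard population for age (5-year groups) and a fixed three-level
education structure (emulating the RLMS 1996-98 educational composition,
which the source series uses as its education standard; the exact
proportions are configurable).

Standard errors follow the binomial/normal approximation:
SE^2 = sum_i w_i^2 p_i (1 - p_i) / n_i.

Strata with no observations are dropped and the remaining weights are
renormalized; the estimate records the fraction of standard weight
actually covered, so callers can exclude narrow-age-range surveys from
standardized tables (the convention the source tables follow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

# 1976 European standard population, weight per 5-year age group (per 100k).
# 15-19 is split pro rata when the survey floor is 18.
_ESP1976 = {
    (15, 19): 7000, (20, 24): 7000, (25, 29): 7000, (30, 34): 7000,
    (35, 39): 7000, (40, 44): 7000, (45, 49): 7000, (50, 54): 7000,
    (55, 59): 6000, (60, 64): 5000, (65, 69): 4000, (70, 74): 3000,
    (75, 79): 2000,
}


@dataclass(frozen=True)
class StandardWeights:
    """Ordered stratum labels with nonnegative weights, normalized to 1."""

    labels: tuple
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(self.labels) != w.size:
            raise ConfigurationError("labels and weights length mismatch")
        if np.any(w < 0):
            raise ConfigurationError("weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ConfigurationError("weights sum to zero")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "weights", w / total)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.labels), name="weight")

    @classmethod
    def from_csv(cls, path) -> "StandardWeights":
        df = pd.read_csv(path)
        if not {"stratum", "weight"} <= set(df.columns):
            raise DataError("weights CSV needs columns: stratum, weight")
        return cls(labels=tuple(df["stratum"].astype(str)),
                   weights=df["weight"].to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame({"stratum": list(self.labels),
                      "weight": self.weights}).to_csv(path, index=False)


@dataclass(frozen=True)
class PrevalenceEstimate:
    value: float
    se: float
    n: int
    strata_used: tuple
    coverage: float = 1.0  # share of standard weight over populated strata

    def __post_init__(self):
        if not (0.0 <= self.value <= 1.0) or self.se < 0:
            raise ConfigurationError("invalid prevalence estimate")


def age_group(ages, width: int = 5, floor: int = 18, ceil: int = 79):
    """5-year age-group labels ('20-24', ...); first group may be clipped
    by the survey floor (e.g. '18-19')."""
    ages = np.asarray(ages)
    lo0 = (ages // width) * width
    hi = np.minimum(lo0 + width - 1, ceil)
    lo = np.clip(lo0, floor, None)
    return np.char.add(np.char.add(lo.astype(int).astype(str), "-"),
                       hi.astype(int).astype(str))


def european_standard_1976(age_min: int = 18, age_max: int = 79) -> StandardWeights:
    """Age weights from the 1976 European standard population restricted to
    [age_min, age_max]; partially covered groups get pro-rata weight and a
    clipped label (so '18-19' carries 2/5 of the 15-19 weight)."""
    labels, weights = [], []
    for (lo, hi), w in _ESP1976.items():
        a, b = max(lo, age_min), min(hi, age_max)
        if a > b:
            continue
        labels.append(f"{a}-{b}")
        weights.append(w * (b - a + 1) / (hi - lo + 1))
    return StandardWeights(labels=tuple(labels), weights=np.array(weights))


def education_standard(low: float = 0.30, secondary: float = 0.50,
                       high: float = 0.20) -> StandardWeights:
    """Three-level education standard (defaults emulate a mid-1990s Russian
    adult educational structure; override to match another standard)."""
    return StandardWeights(labels=("low", "secondary", "high"),
                           weights=np.array([low, secondary, high]))


def stratum_prevalence(records: pd.DataFrame, by,
                       outcome: str = "current_smoker") -> pd.DataFrame:
    """Per-stratum prevalence with binomial SE = sqrt(p(1-p)/n).

    ``by`` is a column name or list of names; only populated strata appear
    (empty strata are the caller's renormalization concern, flagged via
    coverage in :func:`direct_standardize`)."""
    if outcome not in records.columns:
        raise DataError(f"harmonized outcome column {outcome!r} missing")
    by = [by] if isinstance(by, str) else list(by)
    g = records.groupby(by, observed=True)[outcome]
    out = g.agg(n="size", smokers="sum").reset_index()
    out["value"] = out["smokers"] / out["n"]
    out["se"] = np.sqrt(out["value"] * (1 - out["value"]) / out["n"])
    return out


def direct_standardize(estimates: pd.DataFrame, weights: StandardWeights,
                       stratum_col=None) -> PrevalenceEstimate:
    """Weighted average of stratum prevalences under an external standard.

    Strata present in the standard but absent from ``estimates`` are
    dropped and weights renormalized; ``coverage`` records the retained
    share of standard weight.  Raises if no weighted stratum has data.
    """
    if stratum_col is None:
        meta = [c for c in estimates.columns
                if c not in ("n", "smokers", "value", "se")]
        if len(meta) != 1:
            raise DataError(f"ambiguous stratum columns {meta}; pass stratum_col")
        stratum_col = meta[0]
    est = estimates.set_index(stratum_col)
    wser = weights.as_series()
    present = [s for s in wser.index if s in est.index]
    if not present:
        raise DataError("no weighted stratum has observations")
    w = wser.loc[present].to_numpy()
    coverage = float(w.sum())
    w = w / w.sum()
    p = est.loc[present, "value"].to_numpy(dtype=float)
    n = est.loc[present, "n"].to_numpy(dtype=float)
    value = float(w @ p)
    se = float(np.sqrt(np.sum(w ** 2 * p * (1 - p) / n)))
    return PrevalenceEstimate(value=value, se=se, n=int(n.sum()),
                              strata_used=tuple(present), coverage=coverage)


def joint_weights(age_weights: StandardWeights,
                  edu_weights: StandardWeights) -> StandardWeights:
    """Joint age x education standard as the product of the marginals
    (the two standards come from unrelated sources, so independence is the
    only defensible joint)."""
    labels, weights = [], []
    for a, wa in zip(age_weights.labels, age_weights.weights):
        for e, we in zip(edu_weights.labels, edu_weights.weights):
            labels.append(f"{a}|{e}")
            weights.append(wa * we)
    return StandardWeights(labels=tuple(labels), weights=np.array(weights))


def double_standardize(records: pd.DataFrame, age_weights: StandardWeights,
                       edu_weights: StandardWeights,
                       outcome: str = "current_smoker",
                       age_col: str = "age",
                       edu_col: str = "education") -> PrevalenceEstimate:
    """Age-and-education standardized prevalence over the joint strata."""
    df = records.copy()
    df["_stratum"] = np.char.add(
        np.char.add(np.asarray(age_group(df[age_col].to_numpy()), dtype=str), "|"),
        df[edu_col].to_numpy(dtype=str))
    est = stratum_prevalence(df, "_stratum", outcome=outcome)
    return direct_standardize(est, joint_weights(age_weights, edu_weights),
                              stratum_col="_stratum")
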