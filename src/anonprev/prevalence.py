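"""Contamination-adjusted prevalence estimation and summary tables.

The adjusted prevalence of a substance is

    100 × n_positive / (n_total − n_contaminated)

where contaminated samples — those whose detection is indistinguishable from
tubing carryover — are excluded from both numerator and denominator.
Confidence intervals use the large-sample normal approximation (Wald)
for a single binomial proportion, clipped to [0, 100] on the percent scale.

Whole-sample shares (positive / negative / contaminated) are plain
proportions of the total analysed, with the same interval form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import Status
from .panel import ConfigurationError, SubstancePanel

__all__ = [
    "PrevalenceEstimate",
    "UndefinedEstimateError",
    "wald_ci",
    "substance_prevalence",
    "sample_level_rates",
    "class_prevalence",
    "combination_table",
    "combination_class_share",
    "concentration_summary",
]


class UndefinedEstimateError(ZeroDivisionError):
    """Raised when the effective denominator of a proportion is zero."""


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Adjusted prevalence for one label (substance, class, or sample level)."""

    label: str
    n_total: int
    n_contaminated: int
    n_positive: int
    prevalence_pct: float
    ci_low_pct: float
    ci_high_pct: float
    level: float = 0.95

    @property
    def n_effective(self) -> int:
        return self.n_total - self.n_contaminated

    def rounded(self, decimals: int = 1) -> tuple[float, float, float]:
        """(estimate, low, high) rounded for table display."""
        return (
            round(self.prevalence_pct, decimals),
            round(self.ci_low_pct, decimals),
            round(self.ci_high_pct, decimals),
        )


def wald_ci(
    n_positive: int, n_effective: int, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided normal-approximation CI for a proportion, percent scale.

    Returns unrounded ``(low, high)`` in percent, clipped to [0, 100].
    Bounds are computed from the unrounded proportion; callers round for
    display.
    """
    if n_effective < 1:
        raise UndefinedEstimateError(
            "confidence interval undefined: effective sample size is 0"
        )
    if not 0 <= n_positive <= n_effective:
        raise ValueError(
            f"n_positive must be in [0, {n_effective}], got {n_positive}"
        )
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level!r}")
    p = n_positive / n_effective
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n_effective)
    low = max(0.0, (p - half) * 100.0)
    high = min(100.0, (p + half) * 100.0)
    return low, high


def _estimate(
    label: str, n_positive: int, n_contaminated: int, n_total: int, level: float
) -> PrevalenceEstimate:
    n_eff = n_total - n_contaminated
    if n_eff < 1:
        raise UndefinedEstimateError(
            f"no uncontaminated samples to estimate {label!r} prevalence"
        )
    low, high = wald_ci(n_positive, n_eff, level)
    return PrevalenceEstimate(
        label=label,
        n_total=n_total,
        n_contaminated=n_contaminated,
        n_positive=n_positive,
        prevalence_pct=100.0 * n_positive / n_eff,
        ci_low_pct=low,
        ci_high_pct=high,
        level=level,
    )


_SAMPLE_KEY = ["site_id", "cassette_id", "slot"]


def _n_samples(substance_status: pd.DataFrame) -> int:
    return len(substance_status[_SAMPLE_KEY].drop_duplicates())


def substance_prevalence(
    substance_status: pd.DataFrame,
    substance: str,
    level: float = 0.95,
) -> PrevalenceEstimate:
    """Adjusted prevalence of one substance over a per-(sample, substance)
    status frame.

    ``n_total`` is the number of samples analysed; ``n_contaminated`` counts
    samples contaminated *for this substance*.
    """
    if substance not in set(substance_status["substance"]):
        raise KeyError(f"unknown substance {substance!r}")
    n_total = _n_samples(substance_status)
    rows = substance_status[substance_status["substance"] == substance]
    n_pos = int((rows["status"] == Status.POSITIVE.value).sum())
    n_con = int((rows["status"] == Status.CONTAMINATED.value).sum())
    return _estimate(substance, n_pos, n_con, n_total, level)


def sample_level_rates(
    sample_status: pd.DataFrame, level: float = 0.95
) -> dict[str, PrevalenceEstimate]:
    """Positive / negative / contaminated shares of all samples analysed.

    Unlike the per-substance estimate, these shares use the unadjusted
    denominator ``n_total`` and sum to 100% before rounding.
    """
    n_total = len(sample_status)
    if n_total == 0:
        raise UndefinedEstimateError("empty dataset: no samples to summarise")
    out: dict[str, PrevalenceEstimate] = {}
    for status in (Status.POSITIVE, Status.NEGATIVE, Status.CONTAMINATED):
        n = int((sample_status["status"] == status.value).sum())
        out[status.value] = _estimate(status.value, n, 0, n_total, level)
    return out


def class_prevalence(
    substance_status: pd.DataFrame,
    drug_class: str,
    panel: SubstancePanel,
    level: float = 0.95,
) -> PrevalenceEstimate:
    """Adjusted prevalence of a drug class.

    A sample is class-positive if any member substance is positive
    (regardless of other members possibly contaminating it), and
    class-contaminated if no member is positive but at least one is
    contaminated.
    """
    members = panel.class_members(drug_class)
    rows = substance_status[substance_status["substance"].isin(members)]
    per_sample = rows.groupby(_SAMPLE_KEY, sort=False)["status"].agg(
        lambda col: classify_class(col.tolist())
    )
    n_total = _n_samples(substance_status)
    n_pos = int((per_sample == Status.POSITIVE.value).sum())
    n_con = int((per_sample == Status.CONTAMINATED.value).sum())
    return _estimate(drug_class, n_pos, n_con, n_total, level)


def classify_class(statuses: list[str]) -> str:
    """Any-member aggregation used for class rows (same logic as per sample)."""
    if Status.POSITIVE.value in statuses:
        return Status.POSITIVE.value
    if Status.CONTAMINATED.value in statuses:
        return Status.CONTAMINATED.value
    return Status.NEGATIVE.value


def combination_table(
    substance_status: pd.DataFrame,
    n_total: int | None = None,
) -> pd.DataFrame:
    """Co-occurrence table of samples positive for at least two substances.

    Input should already have co-detected metabolites collapsed. Each
    qualifying sample contributes its exact set of positive substances as
    one row key; counts are tabulated per site and pooled, with the pooled
    percentage of ``n_total`` (default: number of samples in the frame).
    Returns a DataFrame with columns ``substances`` (tuple, panel order of
    first appearance), one count column per site, ``pooled`` and
    ``pooled_pct``; ``df.attrs["grand_total"]`` holds the number of
    multi-substance samples.
    """
    if n_total is None:
        n_total = _n_samples(substance_status)
    pos = substance_status[substance_status["status"] == Status.POSITIVE.value]
    sets = (
        pos.groupby(_SAMPLE_KEY, sort=False)["substance"]
        .agg(lambda col: tuple(sorted(col)))
        .reset_index(name="substances")
    )
    multi = sets[sets["substances"].map(len) >= 2].copy()
    sites = sorted(substance_status["site_id"].unique())
    if multi.empty:
        table = pd.DataFrame(
            columns=["substances", *sites, "pooled", "pooled_pct"]
        )
        table.attrs["grand_total"] = 0
        return table
    counts = (
        multi.groupby(["substances", "site_id"], sort=False)
        .size()
        .unstack("site_id", fill_value=0)
        .reindex(columns=sites, fill_value=0)
    )
    counts["pooled"] = counts.sum(axis=1)
    counts["pooled_pct"] = (100.0 * counts["pooled"] / n_total).round(1)
    table = (
        counts.sort_values("pooled", ascending=False, kind="stable")
        .reset_index()
    )
    table.attrs["grand_total"] = int(len(multi))
    return table


def combination_class_share(
    table: pd.DataFrame,
    required: str,
    companion_class_members: list[str],
    n_total: int,
) -> float:
    """Pooled percent of samples combining ``required`` with any companion.

    E.g. acetazolamide together with at least one hypnotic. Percent of the
    unadjusted total, one decimal.
    """
    companions = set(companion_class_members)
    count = 0
    for _, row in table.iterrows():
        subs = set(row["substances"])
        if required in subs and subs & companions:
            count += int(row["pooled"])
    return round(100.0 * count / n_total, 1)


def concentration_summary(
    dataset: pd.DataFrame,
    substance_status: pd.DataFrame,
    substance: str,
) -> dict:
    """Concentration moments among positive samples of one substance.

    Contaminated detections are excluded. Returns a dict with keys
    ``substance, n, mean, sd, min, max`` (ng/ml); ``sd`` is None when
    n < 2, everything but ``n`` is None when there are no positives.
    """
    rows = substance_status[
        (substance_status["substance"] == substance)
        & (substance_status["status"] == Status.POSITIVE.value)
    ]
    if rows.empty:
        return {
            "substance": substance, "n": 0,
            "mean": None, "sd": None, "min": None, "max": None,
        }
    merged = rows.merge(
        dataset[_SAMPLE_KEY + ["substance", "concentration_ng_ml"]],
        on=_SAMPLE_KEY + ["substance"],
        how="left",
        validate="one_to_one",
    )
    conc = merged["concentration_ng_ml"].to_numpy(dtype=float)
    n = len(conc)
    return {
        "substance": substance,
        "n": n,
        "mean": float(conc.mean()),
        "sd": float(conc.std(ddof=1)) if n >= 2 else None,
        "min": float(conc.min()),
        "max": float(conc.max()),
    }
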