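"""Sequential carryover classification of assay results.

Because consecutive samples within a cassette share suction tubing, a
detection whose concentration is less than or equal to the one measured in
the previous sample of the same cassette cannot be distinguished from
residual-volume carryover. The conservative rule labels such detections
*contaminated* rather than positive; contaminated samples are later excluded
from both numerator and denominator of the prevalence.

Statuses exist at two levels. Per substance: negative (not detected),
positive (detected, cannot be carryover) or contaminated. Per sample:
positive if any substance is positive (regardless of other substances
possibly contaminating the sample), negative if nothing was detected at all,
contaminated otherwise.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .panel import ConfigurationError, SubstancePanel

__all__ = [
    "Status",
    "classify_substance_sequence",
    "classify_sample",
    "collapse_metabolites",
    "classify_dataset",
    "collapse_metabolites_frame",
]


class Status(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    CONTAMINATED = "contaminated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_substance_sequence(
    concs: Sequence[float], lod: float = 0.0
) -> list[Status]:
    """Classify one substance's concentrations along one cassette.

    ``concs`` must be ordered by slot. Slot *k* is negative when nothing was
    detected (concentration 0 or below ``lod``); otherwise contaminated when
    the previous slot of the same cassette had a detected concentration and
    the current one is less than or equal to it; otherwise positive. Slot 1
    is never contaminated — the tube is rinsed between cassettes.

    A detected sample following an *undetected* one is positive: carryover
    from a source with no measurable signal is impossible under the rule.
    The comparison is against the previous slot's measured value regardless
    of that slot's own status, so chains decay — after a contaminated slot,
    a higher concentration is again positive. Ties are contaminated
    (exact ``<=``, no tolerance).
    """
    if lod < 0:
        raise ValueError(f"lod must be >= 0, got {lod!r}")
    statuses: list[Status] = []
    prev_conc = 0.0
    prev_detected = False
    for i, conc in enumerate(concs):
        conc = float(conc)
        if conc < 0:
            raise ValueError(f"negative concentration {conc!r} at position {i}")
        detected = conc > 0.0 and conc >= lod
        if not detected:
            statuses.append(Status.NEGATIVE)
        elif prev_detected and conc <= prev_conc:
            statuses.append(Status.CONTAMINATED)
        else:
            statuses.append(Status.POSITIVE)
        prev_conc = conc
        prev_detected = detected
    return statuses


def classify_sample(statuses: Mapping[str, Status] | Iterable[Status]) -> Status:
    """Aggregate per-substance statuses of one sample to a whole-sample status.

    Positive if at least one substance is positive, regardless of other
    substances possibly contaminating the sample; negative if no substance
    was detected and none contaminated; contaminated otherwise.
    """
    values = list(
        statuses.values() if isinstance(statuses, Mapping) else statuses
    )
    if not values:
        raise ValueError("cannot classify a sample with no substance statuses")
    values = [Status(v) for v in values]
    if Status.POSITIVE in values:
        return Status.POSITIVE
    if Status.CONTAMINATED in values:
        return Status.CONTAMINATED
    return Status.NEGATIVE


def collapse_metabolites(
    statuses: Mapping[str, Status], panel: SubstancePanel
) -> dict[str, Status]:
    """Fold co-detected metabolites into their primary substance.

    When a linked pair (e.g. prednisone → prednisolone) is positive in the
    same sample, only the primary substance is recorded as positive; the
    co-detected metabolite is set negative so the pair counts once. A
    metabolite positive on its own passes through unchanged. Idempotent.
    """
    out = {name: Status(st) for name, st in statuses.items()}
    for primary, metabolite in panel.metabolite_links:
        if (
            out.get(primary) is Status.POSITIVE
            and out.get(metabolite) is Status.POSITIVE
        ):
            out[metabolite] = Status.NEGATIVE
    return out


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{what} is missing columns {missing}")


def classify_dataset(
    dataset: pd.DataFrame, panel: SubstancePanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the sequential rule over a long-format dataset.

    Returns ``(substance_status, sample_status)``. The first has one row
    per (sample, substance) with columns ``site_id, cassette_id, slot,
    substance, status``; the second one row per sample with columns
    ``site_id, cassette_id, slot, status``.
    """
    _require_columns(
        dataset,
        ["site_id", "cassette_id", "slot", "substance", "concentration_ng_ml"],
        "dataset",
    )
    lod_by_substance = {s.name: s.lod for s in panel.substances}
    unknown = set(dataset["substance"]) - set(lod_by_substance)
    if unknown:
        raise ConfigurationError(
            f"dataset contains substances absent from the panel: {sorted(unknown)}"
        )

    pieces = []
    grouped = dataset.sort_values("slot", kind="stable").groupby(
        ["site_id", "cassette_id", "substance"], sort=False
    )
    for (site, cassette, substance), grp in grouped:
        concs = grp["concentration_ng_ml"].to_numpy()
        statuses = classify_substance_sequence(concs, lod_by_substance[substance])
        pieces.append(
            pd.DataFrame(
                {
                    "site_id": site,
                    "cassette_id": cassette,
                    "slot": grp["slot"].to_numpy(),
                    "substance": substance,
                    "status": [s.value for s in statuses],
                }
            )
        )
    substance_status = (
        pd.concat(pieces, ignore_index=True)
        .sort_values(["site_id", "cassette_id", "slot", "substance"],
                     kind="stable")
        .reset_index(drop=True)
    )

    sample_status = (
        substance_status.groupby(["site_id", "cassette_id", "slot"], sort=False)[
            "status"
        ]
        .agg(lambda col: classify_sample(col.tolist()).value)
        .reset_index()
    )
    return substance_status, sample_status


def collapse_metabolites_frame(
    substance_status: pd.DataFrame, panel: SubstancePanel
) -> pd.DataFrame:
    """Vectorised :func:`collapse_metabolites` over a status frame."""
    _require_columns(
        substance_status,
        ["site_id", "cassette_id", "slot", "substance", "status"],
        "substance_status",
    )
    out = substance_status.copy()
    key = ["site_id", "cassette_id", "slot"]
    wide = out.pivot_table(
        index=key, columns="substance", values="status", aggfunc="first"
    )
    for primary, metabolite in panel.metabolite_links:
        if primary not in wide.columns or metabolite not in wide.columns:
            continue
        both = (wide[primary] == Status.POSITIVE.value) & (
            wide[metabolite] == Status.POSITIVE.value
        )
        if both.any():
            folded = wide.loc[both, metabolite].index
            mask = (
                out.set_index(key).index.isin(folded)
                & (out["substance"] == metabolite).to_numpy()
            )
            out.loc[mask, "status"] = Status.NEGATIVE.value
    return out
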