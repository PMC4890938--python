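"""Substance panel: screened substances, drug classes and metabolite links.

A panel describes the multi-analyte screen applied to every urine sample:
which substances are assayed, which pharmacological class each belongs to,
its detection/reporting limit, and — for the simulator — the latent
per-visitor use probability and the log-normal urinary-concentration model.

Metabolite links record primary→co-detected pairs (e.g. prednisone is
always accompanied by prednisolone in the same sample); such pairs are
counted once, under the primary name, when tabulating combinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SubstanceSpec",
    "SubstancePanel",
    "ConfigurationError",
    "default_panel",
    "DEFAULT_METABOLITE_LINKS",
]


class ConfigurationError(ValueError):
    """Invalid panel or simulation configuration; message names the field."""


@dataclass(frozen=True)
class SubstanceSpec:
    """One assayed substance and its generative parameters.

    Parameters
    ----------
    name
        Substance name, unique within a panel.
    drug_class
        Pharmacological class label (``"diuretics"``, ``"hypnotics"``, ...).
    use_probability
        Latent probability that a visitor excretes this substance, in [0, 1].
    conc_log_mean, conc_log_sd
        Location and spread (natural-log scale) of the log-normal urinary
        concentration among users, in ng/ml.
    lod
        Detection/reporting limit in ng/ml; measured concentrations strictly
        below it are recorded as not detected.
    """

    name: str
    drug_class: str
    use_probability: float = 0.0
    conc_log_mean: float = 5.0
    conc_log_sd: float = 1.5
    lod: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.use_probability <= 1.0:
            raise ConfigurationError(
                f"use_probability must be in [0, 1], got {self.use_probability!r}"
                f" for substance {self.name!r}"
            )
        if not self.conc_log_sd > 0.0:
            raise ConfigurationError(
                f"conc_log_sd must be > 0, got {self.conc_log_sd!r}"
                f" for substance {self.name!r}"
            )
        if self.lod < 0.0:
            raise ConfigurationError(
                f"lod must be >= 0, got {self.lod!r} for substance {self.name!r}"
            )


@dataclass(frozen=True)
class SubstancePanel:
    """The full screen: substances plus primary→co-detected metabolite links."""

    substances: tuple[SubstanceSpec, ...]
    metabolite_links: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        names = [s.name for s in self.substances]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate substance names in panel: {dupes}")
        known = set(names)
        seen_metabolites: set[str] = set()
        for primary, metabolite in self.metabolite_links:
            for end in (primary, metabolite):
                if end not in known:
                    raise ConfigurationError(
                        f"metabolite link references unknown substance {end!r}"
                    )
            if metabolite in seen_metabolites:
                raise ConfigurationError(
                    f"substance {metabolite!r} is co-detected in more than one link"
                )
            seen_metabolites.add(metabolite)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.substances]

    @property
    def classes(self) -> list[str]:
        out: list[str] = []
        for s in self.substances:
            if s.drug_class not in out:
                out.append(s.drug_class)
        return out

    def spec(self, name: str) -> SubstanceSpec:
        for s in self.substances:
            if s.name == name:
                return s
        raise KeyError(f"unknown substance {name!r}")

    def class_members(self, drug_class: str) -> list[str]:
        members = [s.name for s in self.substances if s.drug_class == drug_class]
        if not members:
            raise ConfigurationError(f"drug class {drug_class!r} has no members")
        return members


def _lognormal_params(conc_min: float, conc_max: float) -> tuple[float, float]:
    # Centre at the geometric midpoint; spread so the printed min–max is ~±3 SD.
    log_min, log_max = math.log(conc_min), math.log(conc_max)
    return (log_min + log_max) / 2.0, max((log_max - log_min) / 6.0, 0.3)


DEFAULT_METABOLITE_LINKS: tuple[tuple[str, str], ...] = (
    ("prednisone", "prednisolone"),
    ("codeine", "morphine"),
    ("metoprolol", "metoprolol acid"),
)

# (name, class, use probability, observed concentration range ng/ml, lod ng/ml)
# Use probabilities follow the two-hut screening study this package models;
# concentration ranges bracket the printed per-substance min–max spans.
_DEFAULT_ROWS: tuple[tuple[str, str, float, float, float, float], ...] = (
    ("acetazolamide", "diuretics", 0.206, 20.0, 491_100.0, 20.0),
    ("hydrochlorothiazide", "diuretics", 0.016, 4.0, 10_048.0, 4.0),
    ("zolpidem", "hypnotics", 0.084, 0.1, 127.0, 0.1),
    ("oxazepam", "hypnotics", 0.016, 3.0, 222.0, 3.0),
    ("zopiclone", "hypnotics", 0.013, 11.0, 739.0, 5.0),
    ("prednisone", "glucocorticoids", 0.019, 11.0, 776.0, 10.0),
    ("prednisolone", "glucocorticoids", 0.016, 11.0, 3_823.0, 10.0),
    ("betamethasone", "glucocorticoids", 0.007, 13.0, 42.0, 10.0),
    ("caffeine", "stimulants", 0.009, 7_000.0, 8_300.0, 5_000.0),
    ("benzoylecgonine", "stimulants", 0.007, 68.0, 439.0, 50.0),
    ("THC", "cannabinoids", 0.038, 8.0, 152.0, 8.0),
    ("codeine", "narcotics", 0.019, 11.0, 1_297.0, 10.0),
    ("morphine", "narcotics", 0.019, 6.0, 274.0, 5.0),
    ("metoprolol", "beta-blockers", 0.005, 34.0, 54.0, 10.0),
    ("metoprolol acid", "beta-blockers", 0.005, 17.0, 200.0, 10.0),
)


def default_panel() -> SubstancePanel:
    """Panel calibrated to the two-hut screening study.

    Use probabilities are the published adjusted prevalences of the more
    common substances; log-normal concentration parameters are set so the
    simulated among-user concentration range brackets the printed min–max
    span for each substance.
    """
    substances = []
    for name, drug_class, p_use, cmin, cmax, lod in _DEFAULT_ROWS:
        mu, sd = _lognormal_params(cmin, cmax)
        substances.append(
            SubstanceSpec(
                name=name,
                drug_class=drug_class,
                use_probability=p_use,
                conc_log_mean=mu,
                conc_log_sd=sd,
                lod=lod,
            )
        )
    return SubstancePanel(
        substances=tuple(substances), metabolite_links=DEFAULT_METABOLITE_LINKS
    )


def single_substance_panel(
    name: str = "acetazolamide",
    use_probability: float = 0.206,
    *,
    drug_class: str = "diuretics",
    conc_log_mean: float = 8.0,
    conc_log_sd: float = 1.7,
    lod: float = 0.0,
) -> SubstancePanel:
    """One-substance panel, the workhorse of the recovery experiments."""
    return SubstancePanel(
        substances=(
            SubstanceSpec(
                name=name,
                drug_class=drug_class,
                use_probability=use_probability,
                conc_log_mean=conc_log_mean,
                conc_log_sd=conc_log_sd,
                lod=lod,
            ),
        )
    )
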