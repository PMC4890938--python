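"""Synthetic event simulator for the automated urinal sampler.

The generative model mirrors the physical collection process: an automatic
sampler draws one urine sample per urination event into the next slot of a
24-slot cassette. Residual liquid in the suction tubing (a few ml against a
~67 ml draw) carries a fraction of the previous sample's mixed concentration
into the next slot of the *same* cassette; the tube is rinsed when a fresh
cassette is inserted, so slot 1 is always carryover-free.

Each visitor has latent per-substance use flags; users excrete log-normal
concentrations. A visitor may return on consecutive nights (redundancy),
contributing several samples with the same latent flags. Measured
concentrations below a substance's detection limit are recorded as 0 with an
explicit below-LOD flag.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .panel import ConfigurationError, SubstancePanel, default_panel

__all__ = [
    "CarryoverModel",
    "SimulationConfig",
    "simulate_study",
    "simulate_titration",
    "mont_blanc_study_config",
]

#: Long-format dataset columns emitted by :func:`simulate_study`.
DATASET_COLUMNS = [
    "site_id",
    "cassette_id",
    "slot",
    "timestamp",
    "substance",
    "concentration_ng_ml",
    "below_lod",
]

TRUTH_COLUMNS = [
    "site_id",
    "cassette_id",
    "slot",
    "visitor_id",
    "substance",
    "true_use",
    "true_conc_ng_ml",
]


@dataclass(frozen=True)
class CarryoverModel:
    """Residual-volume carryover between consecutive slots of one cassette.

    The transferred fraction defaults to the volumetric ratio
    ``residual / (residual + sample)`` — ~4 ml of retained liquid diluted
    into a ~67 ml draw gives ~5.6%. Set ``carryover_fraction`` to override,
    or ``distribution="uniform"`` to draw a fresh fraction per transfer from
    ``Uniform(0, 2 × fraction)`` (mean-preserving jitter for titration
    experiments).
    """

    residual_volume_ml: float = 4.0
    sample_volume_ml: float = 67.0
    carryover_fraction: float | None = None
    distribution: str = "fixed"

    def __post_init__(self) -> None:
        if self.distribution not in ("fixed", "uniform"):
            raise ConfigurationError(
                f"distribution must be 'fixed' or 'uniform', got {self.distribution!r}"
            )
        if self.residual_volume_ml < 0 or self.sample_volume_ml <= 0:
            raise ConfigurationError(
                "residual_volume_ml must be >= 0 and sample_volume_ml > 0"
            )
        f = self.fraction
        if not 0.0 <= f < 1.0:
            raise ConfigurationError(
                f"carryover_fraction must be in [0, 1), got {f!r}"
            )

    @property
    def fraction(self) -> float:
        """Mean fraction of the previous measured concentration transferred."""
        if self.carryover_fraction is not None:
            return float(self.carryover_fraction)
        return self.residual_volume_ml / (
            self.residual_volume_ml + self.sample_volume_ml
        )

    def draw_fractions(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.distribution == "uniform":
            return rng.uniform(0.0, 2.0 * self.fraction, size=n)
        return np.full(n, self.fraction)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated collection campaign.

    ``sites`` maps site id → number of cassettes run there (one per night).
    ``events_per_cassette`` is an int (fixed), ``("poisson", mean)``
    (truncated to [1, slots_per_cassette]), or an explicit sequence with one
    count per cassette in site order. ``revisit_mean`` is the expected number
    of samples per visitor (geometric, placed on consecutive nights).
    """

    panel: SubstancePanel
    sites: dict[str, int]
    seed: int
    slots_per_cassette: int = 24
    events_per_cassette: object = 24
    revisit_mean: float = 1.0
    carryover: CarryoverModel = field(default_factory=CarryoverModel)
    start_date: str = "2013-07-15"

    def __post_init__(self) -> None:
        if self.slots_per_cassette < 1:
            raise ConfigurationError("slots_per_cassette must be >= 1")
        if self.revisit_mean < 1.0:
            raise ConfigurationError("revisit_mean must be >= 1")
        if not self.sites:
            raise ConfigurationError("sites must name at least one site")
        if any(n < 1 for n in self.sites.values()):
            raise ConfigurationError("each site needs >= 1 cassette")
        self._resolve_events(np.random.default_rng(0))  # validate shape early

    @property
    def n_cassettes(self) -> int:
        return sum(self.sites.values())

    def _resolve_events(self, rng: np.random.Generator) -> list[int]:
        spec = self.events_per_cassette
        k, cap = self.n_cassettes, self.slots_per_cassette
        if isinstance(spec, int):
            if not 1 <= spec <= cap:
                raise ConfigurationError(
                    f"events_per_cassette must be in [1, {cap}], got {spec}"
                )
            return [spec] * k
        if isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "poisson":
            mean = float(spec[1])
            if mean <= 0:
                raise ConfigurationError(
                    f"events_per_cassette poisson mean must be > 0, got {mean}"
                )
            draws = rng.poisson(mean, size=k)
            return [int(min(max(d, 1), cap)) for d in draws]
        if isinstance(spec, (list, np.ndarray)):
            counts = [int(c) for c in spec]
            if len(counts) != k:
                raise ConfigurationError(
                    f"events_per_cassette list has {len(counts)} entries"
                    f" for {k} cassettes"
                )
            if any(not 1 <= c <= cap for c in counts):
                raise ConfigurationError(
                    f"events_per_cassette entries must be in [1, {cap}]"
                )
            return counts
        raise ConfigurationError(
            f"events_per_cassette: unrecognised spec {spec!r}"
        )


def mont_blanc_study_config(
    panel: SubstancePanel | None = None,
    seed: int = 0,
    *,
    carryover: CarryoverModel | None = None,
    revisit_mean: float = 1.0,
) -> SimulationConfig:
    """Two-site campaign sized like the published study: 274 + 156 = 430 samples.

    Goûter ran 12 cassettes (11 full + one of 10), Cosmiques 7 (6 full + one
    of 12); cassette counts are chosen so totals match the published per-hut
    sample sizes exactly.
    """
    events = [24] * 11 + [10] + [24] * 6 + [12]
    return SimulationConfig(
        panel=panel if panel is not None else default_panel(),
        sites={"gouter": 12, "cosmiques": 7},
        seed=seed,
        events_per_cassette=events,
        revisit_mean=revisit_mean,
        carryover=carryover if carryover is not None else CarryoverModel(),
    )


def simulate_study(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a collection campaign.

    Returns
    -------
    dataset : DataFrame
        Long format, one row per (sample, substance): ``site_id,
        cassette_id, slot, timestamp, substance, concentration_ng_ml,
        below_lod``. Concentrations below the substance's LOD are recorded
        as 0 with ``below_lod = 1``.
    truth : DataFrame
        Parallel latent truth, one row per (sample, substance): visitor id,
        true-use flag and the pre-carryover concentration.

    The same config (including seed) reproduces the output exactly. The
    random event stream (visitors, use flags, concentrations, timestamps)
    does not depend on the carryover fraction, so holding the seed fixed and
    increasing carryover changes measured concentrations monotonically.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    n_sub = len(panel.substances)
    use_p = np.array([s.use_probability for s in panel.substances])
    mu = np.array([s.conc_log_mean for s in panel.substances])
    sigma = np.array([s.conc_log_sd for s in panel.substances])
    lod = np.array([s.lod for s in panel.substances])
    f = config.carryover.fraction
    events = config._resolve_events(rng)
    start = datetime.fromisoformat(config.start_date)

    data_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    visitor_counter = 0
    cassette_idx = 0
    for site_id, n_cassettes in config.sites.items():
        # visitors with remaining visits, waiting for the next night
        pending: deque[tuple[int, np.ndarray, int]] = deque()
        for night in range(n_cassettes):
            n_events = events[cassette_idx]
            cassette_id = f"{site_id}-c{night + 1:02d}"
            cassette_idx += 1

            visitors: list[tuple[int, np.ndarray]] = []
            returning = []
            while pending and len(visitors) < n_events:
                vid, flags, remaining = pending.popleft()
                visitors.append((vid, flags))
                if remaining - 1 > 0:
                    returning.append((vid, flags, remaining - 1))
            while len(visitors) < n_events:
                flags = rng.random(n_sub) < use_p
                n_visits = int(rng.geometric(1.0 / config.revisit_mean))
                visitors.append((visitor_counter, flags))
                if n_visits - 1 > 0:
                    returning.append((visitor_counter, flags, n_visits - 1))
                visitor_counter += 1
            pending.extend(returning)
            # interleave returning and first-time visitors across slots
            order = rng.permutation(n_events)
            visitors = [visitors[i] for i in order]

            vids = np.array([v for v, _ in visitors])
            use = np.array([flags for _, flags in visitors])  # (events, n_sub)
            raw = rng.lognormal(mu, sigma, size=(n_events, n_sub))
            true_conc = np.where(use, raw, 0.0)

            measured = np.empty_like(true_conc)
            measured[0] = true_conc[0]
            for k in range(1, n_events):
                measured[k] = true_conc[k] + f * measured[k - 1]

            below = measured < np.maximum(lod, np.nextafter(0.0, 1.0))
            recorded = np.where(below, 0.0, measured)

            night_start = start + timedelta(days=night, hours=1, minutes=30)
            gaps_min = rng.exponential(scale=20.0, size=n_events)
            stamps = [
                (night_start + timedelta(minutes=float(t))).isoformat(
                    timespec="seconds"
                )
                for t in np.cumsum(gaps_min)
            ]

            slots = np.arange(1, n_events + 1)
            idx = pd.MultiIndex.from_product(
                [slots, panel.names], names=["slot", "substance"]
            )
            block = pd.DataFrame(index=idx).reset_index()
            block.insert(0, "cassette_id", cassette_id)
            block.insert(0, "site_id", site_id)
            block["timestamp"] = np.repeat(stamps, n_sub)
            block["concentration_ng_ml"] = recorded.ravel()
            block["below_lod"] = below.ravel().astype(int)
            data_frames.append(block[DATASET_COLUMNS])

            tblock = block[["site_id", "cassette_id", "slot", "substance"]].copy()
            tblock["visitor_id"] = np.repeat(
                [f"v{v:05d}" for v in vids], n_sub
            )
            tblock["true_use"] = use.ravel().astype(int)
            tblock["true_conc_ng_ml"] = true_conc.ravel()
            truth_frames.append(tblock[TRUTH_COLUMNS])

    dataset = pd.concat(data_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return dataset, truth


def simulate_titration(
    carryover: CarryoverModel,
    titrated_conc: float,
    lod: float,
    n_pairs: int,
    seed: int = 0,
) -> float:
    """Emulate the two-sample titration experiment.

    Pairs of consecutive draws — the first titrated at ``titrated_conc``
    ng/ml, the second blank — share tubing; the observed carryover rate is
    the fraction of blank follow-ups whose carried concentration reaches the
    detection limit. With a fixed carryover fraction the result is exactly
    0.0 or 1.0; with a stochastic fraction it is a Monte-Carlo estimate of
    the threshold-crossing probability.
    """
    if titrated_conc <= 0:
        raise ConfigurationError("titrated_conc must be > 0")
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be >= 1")
    if lod < 0:
        raise ConfigurationError("lod must be >= 0")
    rng = np.random.default_rng(seed)
    fractions = carryover.draw_fractions(rng, n_pairs)
    carried = fractions * titrated_conc
    detected = (carried > 0.0) & (carried >= lod)
    return float(detected.mean())
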