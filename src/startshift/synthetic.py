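"""Synthetic primer-extension lanes and growth-score panels.

The generators emulate the two data types the analysis consumes:

* **Lane signals.**  A promoter is a set of discrete start positions with
  base usage weights.  A mutant's defect is modeled as a polar tilt of the
  initiation *probability* across those already-usable positions: weights are
  re-weighted by ``exp(theta * z)`` where ``z`` is the position coordinate
  standardized over the promoter, so ``theta < 0`` shifts usage upstream and
  ``theta > 0`` downstream while never creating new start sites.  Band
  intensities carry multiplicative lognormal noise (the standard model for
  densitometry band intensities) plus an optional additive background.

* **Growth panels.**  Each strain has a relative fitness per medium in
  [0, 1]; a double mutant's fitness is the product of its singles' fitnesses
  times ``exp(epsilon)``, so ``epsilon = 0`` reproduces the multiplicative
  null exactly and negative/positive ``epsilon`` plant aggravating/alleviating
  interactions.  Fitness maps to the integer 0-5 plate score as
  ``round(5 * f)`` (half-up) clamped to [0, 5]; a strain whose fitness on the
  permissive control medium falls below a threshold is marked INVIABLE.

All generators are pure functions of their inputs and an explicit integer
seed; replicates use deterministic child streams spawned from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import LaneSignal, LowReplicateWarning
from .scores import INVIABLE, RawScoreTable, SCORE_MAX, SCORE_MIN

__all__ = [
    "PromoterModel",
    "ShiftModel",
    "NoiseModel",
    "GrowthModel",
    "tilt_distribution",
    "usage_of",
    "additive_usage",
    "simulate_lane",
    "simulate_replicates",
    "simulate_growth_panel",
    "default_promoter",
]


@dataclass(frozen=True)
class PromoterModel:
    """Discrete start positions of one promoter with base usage weights.

    Positions are integers on a promoter-local axis increasing downstream and
    must be strictly increasing with at least six distinct values; weights are
    non-negative with a positive sum and are stored normalized to sum 1.
    """

    positions: np.ndarray
    base_weights: np.ndarray
    name: str = "promoter"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=int)
        w = np.asarray(self.base_weights, dtype=float)
        if pos.ndim != 1 or pos.size < 6:
            raise ValueError("promoter needs at least 6 positions")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if w.shape != pos.shape:
            raise ValueError("one base weight per position required")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("base weights must be >= 0 with positive sum")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "base_weights", w / w.sum())

    def standardized_positions(self) -> np.ndarray:
        """Position coordinates centered and scaled to unit (population) SD."""
        pos = self.positions.astype(float)
        return (pos - pos.mean()) / pos.std()


@dataclass(frozen=True)
class ShiftModel:
    """Signed tilt strength: negative shifts usage upstream, positive
    downstream; zero is the identity."""

    theta: float = 0.0


@dataclass(frozen=True)
class NoiseModel:
    """Band-noise model: per-band multiplicative lognormal noise of log-scale
    SD ``sigma``, additive non-negative ``background`` per position, and the
    expected ``total_signal`` of a lane (arbitrary intensity units)."""

    sigma: float = 0.1
    background: float = 0.0
    total_signal: float = 10_000.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.total_signal <= 0:
            raise ValueError("total_signal must be > 0")


def default_promoter() -> PromoterModel:
    """A synthetic multi-TSS promoter: eight start positions over a ~56 nt
    window with a unimodal usage profile, mimicking a multi-start yeast
    promoter.  (Purely synthetic; not a reconstruction of any real promoter.)"""
    return PromoterModel(
        positions=np.array([25, 34, 42, 49, 55, 62, 70, 81]),
        base_weights=np.array([0.05, 0.10, 0.20, 0.25, 0.18, 0.12, 0.07, 0.03]),
        name="synthetic_multi_tss",
    )


def tilt_distribution(promoter: PromoterModel, shift: ShiftModel) -> np.ndarray:
    """Per-position usage probabilities after a polar tilt.

    ``w_i \\propto base_i * exp(theta * z_i)`` with ``z`` the standardized
    position coordinate; the output sums to 1 and zero-weight positions stay
    zero (the tilt redistributes probability among usable sites only).
    """
    z = promoter.standardized_positions()
    base = promoter.base_weights
    logw = np.full(base.shape, -np.inf)
    support = base > 0
    logw[support] = np.log(base[support]) + shift.theta * z[support]
    logw -= logw[support].max()  # overflow-safe
    w = np.exp(logw)
    return w / w.sum()


def usage_of(promoter: PromoterModel, shift: "ShiftModel | np.ndarray") -> np.ndarray:
    """Resolve a shift specification to per-position usage probabilities:
    either a :class:`ShiftModel` tilt or an explicit probability vector."""
    if isinstance(shift, ShiftModel):
        return tilt_distribution(promoter, shift)
    p = np.asarray(shift, dtype=float)
    if p.shape != promoter.positions.shape or np.any(p < 0) or p.sum() <= 0:
        raise ValueError("explicit usage must be non-negative, one value per position")
    return p / p.sum()


def additive_usage(
    promoter: PromoterModel, shift_a: ShiftModel, shift_b: ShiftModel
) -> np.ndarray:
    """Plant a double mutant's usage under the additive model.

    The double's per-position usage is the wild-type usage plus each single's
    usage change, ``p_ref + (p_A - p_ref) + (p_B - p_ref)``, clipped at zero
    and renormalized — the generative counterpart of the additive null the
    interaction caller tests against.
    """
    p_ref = promoter.base_weights
    p = p_ref + (usage_of(promoter, shift_a) - p_ref) + (usage_of(promoter, shift_b) - p_ref)
    p = np.clip(p, 0.0, None)
    if p.sum() <= 0:
        raise ValueError("additive composition degenerated to zero mass")
    return p / p.sum()


def simulate_lane(
    promoter: PromoterModel,
    shift: "ShiftModel | np.ndarray",
    noise: NoiseModel,
    seed: int | np.random.SeedSequence,
    strain: str = "strain",
    replicate: str = "1",
) -> LaneSignal:
    """Simulate one primer-extension lane.

    ``intensity_i = total_signal * p_i * exp(g_i) + background`` with ``p``
    the tilted probabilities (or an explicitly planted usage vector) and
    ``g_i`` i.i.d. normal(0, sigma) deviates.  Identical seed and inputs give
    an identical lane.
    """
    rng = np.random.default_rng(seed)
    p = usage_of(promoter, shift)
    g = rng.normal(0.0, noise.sigma, size=p.size) if noise.sigma > 0 else np.zeros(p.size)
    intensities = noise.total_signal * p * np.exp(g) + noise.background
    return LaneSignal(
        positions=promoter.positions,
        intensities=intensities,
        strain=strain,
        replicate=replicate,
    )


def simulate_replicates(
    promoter: PromoterModel,
    shift: "ShiftModel | np.ndarray",
    noise: NoiseModel,
    n: int,
    seed: int | np.random.SeedSequence,
    strain: str = "strain",
) -> list[LaneSignal]:
    """Simulate ``n`` independent lanes with child streams spawned
    deterministically from ``seed``.  Fewer than three replicates triggers
    :class:`~startshift.quant.LowReplicateWarning`."""
    if n <= 0:
        raise ValueError("replicate count must be positive")
    if n < 3:
        warnings.warn(
            f"simulating {n} replicate(s); the quantification scheme expects "
            "at least three independent determinations",
            LowReplicateWarning,
            stacklevel=2,
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n)
    return [
        simulate_lane(promoter, shift, noise, child, strain=strain, replicate=str(i + 1))
        for i, child in enumerate(children)
    ]


def fitness_to_score(f: float) -> int:
    """Map relative fitness in [0, 1] to the integer 0-5 plate score:
    ``round(5 * f)`` with deterministic half-up rounding, clamped to [0, 5]."""
    return int(min(max(np.floor(5.0 * f + 0.5), 0), 5))


@dataclass
class GrowthModel:
    """Planted fitness structure for a growth panel.

    ``fitness`` maps each single strain to per-medium relative fitness in
    [0, 1] (a ``"default"`` key supplies the fallback value for media not
    listed); ``doubles`` maps a double-mutant label to its two single parents;
    ``epsilon`` maps an unordered strain pair to a per-medium log-scale
    interaction term (``"default"`` fallback, 0 if absent).  A double's
    fitness on a medium is ``fA * fB * exp(epsilon)``.  A strain whose fitness
    on ``permissive_medium`` is below ``inviable_threshold`` is INVIABLE.
    ``jitter_prob`` is the per-cell probability of a seeded +/-1 integer
    scoring error (0 disables it).
    """

    fitness: Mapping[str, Mapping[str, float]]
    doubles: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    epsilon: Mapping[frozenset, Mapping[str, float]] = field(default_factory=dict)
    wt: str = "WT"
    permissive_medium: str = "SC-Leu"
    inviable_threshold: float = 0.05
    jitter_prob: float = 0.0
    #: known media vocabulary; None accepts any medium via "default" fallbacks
    media: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.wt not in self.fitness:
            raise ValueError(f"WT strain {self.wt!r} missing from fitness map")
        for strain, per_medium in self.fitness.items():
            for medium, f in per_medium.items():
                if not 0.0 <= float(f) <= 1.0:
                    raise ValueError(
                        f"fitness {f} for ({strain}, {medium}) outside [0, 1]"
                    )
        for double, (a, b) in self.doubles.items():
            if a not in self.fitness or b not in self.fitness:
                raise ValueError(
                    f"double {double!r} references unknown single(s): {a!r}, {b!r}"
                )
        if not 0.0 <= self.jitter_prob <= 1.0:
            raise ValueError("jitter_prob must be a probability")

    def single_fitness(self, strain: str, medium: str) -> float:
        if self.media is not None and medium != self.permissive_medium and medium not in self.media:
            raise ValueError(f"unknown medium {medium!r}")
        per_medium = self.fitness.get(strain)
        if per_medium is None:
            raise ValueError(f"unknown strain {strain!r}")
        if medium in per_medium:
            return float(per_medium[medium])
        if "default" in per_medium:
            return float(per_medium["default"])
        raise ValueError(f"no fitness for strain {strain!r} on medium {medium!r}")

    def pair_epsilon(self, a: str, b: str, medium: str) -> float:
        per_medium = self.epsilon.get(frozenset((a, b)), {})
        return float(per_medium.get(medium, per_medium.get("default", 0.0)))

    def fitness_of(self, strain: str, medium: str) -> float:
        """Relative fitness of a single or double strain on a medium; doubles
        follow the multiplicative model with the planted interaction term."""
        if strain in self.doubles:
            a, b = self.doubles[strain]
            f = (
                self.single_fitness(a, medium)
                * self.single_fitness(b, medium)
                * float(np.exp(self.pair_epsilon(a, b, medium)))
            )
            return float(min(f, 1.0))
        return self.single_fitness(strain, medium)

    def is_inviable(self, strain: str) -> bool:
        return self.fitness_of(strain, self.permissive_medium) < self.inviable_threshold


def simulate_growth_panel(
    growth: GrowthModel,
    strains: Sequence[str],
    media: Sequence[str],
    seed: int | np.random.SeedSequence,
) -> RawScoreTable:
    """Generate a strain-by-media raw 0-5 score table from a growth model.

    Inviable strains (fitness below threshold on the permissive control
    medium) get the INVIABLE marker on every medium.  With ``jitter_prob > 0``
    each remaining cell independently suffers a +/-1 scoring error with that
    probability, clamped to the score range; the draw order is fixed by the
    given strain and media order, so the panel is a pure function of
    (model, strains, media, seed).
    """
    for strain in strains:
        if strain not in growth.fitness and strain not in growth.doubles:
            raise ValueError(f"unknown strain {strain!r}")
    rng = np.random.default_rng(seed)
    rows = {}
    for strain in strains:
        if growth.is_inviable(strain):
            rows[strain] = {medium: INVIABLE for medium in media}
            continue
        row = {}
        for medium in media:
            score = fitness_to_score(growth.fitness_of(strain, medium))
            if growth.jitter_prob > 0 and rng.random() < growth.jitter_prob:
                score = int(min(max(score + rng.choice((-1, 1)), SCORE_MIN), SCORE_MAX))
            row[medium] = score
        rows[strain] = row
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=object)
    table = table.loc[list(strains), list(media)]
    return RawScoreTable(table=table, wt=growth.wt)
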