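"""Double-mutant interaction calling and relationship-class assignment.

Two null models are evaluated for every (single A, single B, double AB)
genotype triple:

* **TSS defects — additive null.**  The expected double-mutant usage change is
  the sum of the singles' per-bin changes; the observed change is compared by
  Euclidean distance to the additive expectation and to each single's profile
  (epistasis = the double resembling one single).  Polarity annotations follow
  the single mutants' shift directions: opposite-polarity singles whose double
  shifts less than the stronger single are mutually suppressive; same-polarity
  singles whose double shifts more than either are exacerbating.

* **Growth — multiplicative null.**  Expected double fitness is the product of
  single fitnesses (scores mapped linearly to fitness, ``f = score / 5``).
  Deviations beyond a tolerance ``tau`` are called synthetic sick/lethal
  (below the product), suppression or epistasis (above it).

Panels of such calls for one genetic interactor across a set of Pol II
active-site alleles are then summarized into three relationship classes:
Class I — the interactor shifts start sites on its own and combines additively
(or suppressively, by polarity) with Pol II alleles; Class II — the interactor
shows epistasis with at least one Pol II allele class for both TSS and growth
defects; Class III — the interactor has no start-site defect of its own and
never modulates the Pol II single's profile, despite showing growth
interactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .quant import NONE, ShiftProfile, TSSDistribution

__all__ = [
    "GenotypeTriple",
    "TSSInteractionCall",
    "GrowthInteractionCall",
    "PairEvidence",
    "RelationshipClass",
    "tss_expected_additive",
    "call_tss_interaction",
    "growth_expected_multiplicative",
    "call_growth_interaction",
    "classify_relationship",
    "fitness_from_score",
    "ADDITIVE",
    "EPISTATIC_TO_A",
    "EPISTATIC_TO_B",
    "OTHER",
    "DEFAULT_TSS_TOLERANCE",
    "DEFAULT_TAU",
]

# TSS interaction categories
ADDITIVE = "additive"
EPISTATIC_TO_A = "epistatic_to_A"
EPISTATIC_TO_B = "epistatic_to_B"
OTHER = "other"

# polarity annotations
MUTUALLY_SUPPRESSIVE = "mutually_suppressive"
EXACERBATING = "exacerbating"
MIXED = "mixed"
POLARITY_NONE = "none"

# growth interaction categories
SYNTHETIC_LETHAL = "synthetic_lethal"
SYNTHETIC_SICK = "synthetic_sick"
NO_INTERACTION = "no_interaction"
SUPPRESSION_MUTUAL = "suppression_mutual"
SUPPRESSION_DIRECTIONAL = "suppression_directional"
EPISTASIS = "epistasis"

GROWTH_ENHANCING = frozenset({SYNTHETIC_SICK, SYNTHETIC_LETHAL})

#: Euclidean-distance tolerance on bin-delta profiles when no replicate
#: standard errors are available.
DEFAULT_TSS_TOLERANCE = 0.15
#: Fitness-scale tolerance: half a score unit on the 0-5 scale.
DEFAULT_TAU = 0.1


def fitness_from_score(score) -> tuple[float, bool]:
    """Linear fitness mapping ``f = score / 5``; the INVIABLE marker maps to
    fitness 0 with the inviable flag set."""
    from .scores import is_marker

    if is_marker(score):
        return 0.0, True
    f = float(score) / 5.0
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"score {score} outside the 0-5 range")
    return f, False


@dataclass
class GenotypeTriple:
    """Single mutants A and B and their double AB, with optional TSS shift
    profiles and per-strain fitness on the medium used for growth calls."""

    a: str
    b: str
    ab: str
    profile_a: ShiftProfile | None = None
    profile_b: ShiftProfile | None = None
    profile_ab: ShiftProfile | None = None
    fitness_a: float | None = None
    fitness_b: float | None = None
    fitness_ab: float | None = None
    ab_inviable: bool = False

    def __post_init__(self) -> None:
        for name in ("fitness_a", "fitness_b", "fitness_ab"):
            f = getattr(self, name)
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}={f} outside [0, 1]")
        if self.ab_inviable and self.fitness_ab not in (None, 0.0):
            raise ValueError("an inviable double must have fitness 0")


@dataclass(frozen=True)
class TSSInteractionCall:
    """Category, polarity, and distances to each null for one triple."""

    a: str
    b: str
    ab: str
    category: str
    polarity: str
    d_additive: float
    d_a: float
    d_b: float
    tolerance: float

    def __post_init__(self) -> None:
        if self.category not in (ADDITIVE, EPISTATIC_TO_A, EPISTATIC_TO_B, OTHER):
            raise ValueError(f"unknown category {self.category!r}")
        if self.polarity not in (
            MUTUALLY_SUPPRESSIVE,
            EXACERBATING,
            MIXED,
            POLARITY_NONE,
        ):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class GrowthInteractionCall:
    """Growth category with the multiplicative expectation it was tested
    against."""

    a: str
    b: str
    ab: str
    category: str
    expected: float
    observed: float
    tau: float


@dataclass(frozen=True)
class PairEvidence:
    """One Pol II allele's calls within an interactor panel; ``pol2_class`` is
    optional gof/lof metadata."""

    pol2: str
    tss: TSSInteractionCall | None = None
    growth: GrowthInteractionCall | None = None
    pol2_class: str | None = None


@dataclass(frozen=True)
class RelationshipClass:
    """Assigned relationship class with the supporting evidence strings."""

    interactor: str
    cls: str  # "I", "II", "III", or "unclassified"
    evidence: tuple[str, ...] = ()


def tss_expected_additive(
    profile_a: ShiftProfile,
    profile_b: ShiftProfile,
    reference: TSSDistribution,
) -> tuple[TSSDistribution, float]:
    """Additive-null expectation for a double mutant's TSS distribution.

    Expected fractions are ``reference + deltaA + deltaB``; any mass pushed
    below zero is clipped and the result renormalized to the simplex.  Returns
    the expected distribution and the clipped mass (0 when the raw sum was
    already a valid distribution).
    """
    if profile_a.scheme != profile_b.scheme or profile_a.scheme != reference.scheme:
        raise ValueError("profiles and reference use different bin schemes")
    raw = reference.fractions + profile_a.deltas + profile_b.deltas
    clipped = float(-raw[raw < 0].sum()) if np.any(raw < 0) else 0.0
    exp = np.clip(raw, 0.0, None)
    if exp.sum() <= 0:
        raise ValueError("additive expectation degenerated to zero mass")
    exp = exp / exp.sum()
    dist = TSSDistribution(fractions=exp, scheme=reference.scheme, strain="expected")
    return dist, clipped


def _polarity(
    profile_a: ShiftProfile, profile_b: ShiftProfile, profile_ab: ShiftProfile
) -> str:
    dir_a, dir_b = profile_a.direction, profile_b.direction
    if dir_a == NONE or dir_b == NONE:
        return POLARITY_NONE
    max_single = max(abs(profile_a.index), abs(profile_b.index))
    if dir_a != dir_b:  # opposite-polarity singles
        return MUTUALLY_SUPPRESSIVE if abs(profile_ab.index) < max_single else MIXED
    return EXACERBATING if abs(profile_ab.index) > max_single else MIXED


def _default_tss_tolerance(triple: GenotypeTriple) -> float:
    ses = [p.se for p in (triple.profile_a, triple.profile_b, triple.profile_ab)]
    if any(se is None for se in ses):
        return DEFAULT_TSS_TOLERANCE
    return float(2.0 * np.sqrt(sum(np.sum(se**2) for se in ses)))


def call_tss_interaction(
    triple: GenotypeTriple, tolerance: float | None = None
) -> TSSInteractionCall:
    """Call the TSS interaction category of a triple against the additive and
    single-mutant (epistasis) nulls.

    Euclidean distances of the double's delta profile to each null are
    compared; the nearest null wins if it is within ``tolerance``, otherwise
    the call is ``other``.  Exact ties resolve to ``additive`` (the weakest
    claim).  The default tolerance is twice the pooled standard error of the
    three delta profiles when replicate SDs are available, else
    ``DEFAULT_TSS_TOLERANCE``.
    """
    if triple.profile_a is None or triple.profile_b is None or triple.profile_ab is None:
        raise ValueError(f"triple ({triple.a}, {triple.b}, {triple.ab}) lacks a profile")
    pa, pb, pab = triple.profile_a, triple.profile_b, triple.profile_ab
    if pa.scheme != pb.scheme or pa.scheme != pab.scheme:
        raise ValueError("profiles use different bin schemes")
    if tolerance is None:
        tolerance = _default_tss_tolerance(triple)
    d_add = float(np.linalg.norm(pab.deltas - (pa.deltas + pb.deltas)))
    d_a = float(np.linalg.norm(pab.deltas - pa.deltas))
    d_b = float(np.linalg.norm(pab.deltas - pb.deltas))
    if d_add <= min(d_a, d_b):
        nearest, d_min = ADDITIVE, d_add
    elif d_a <= d_b:
        nearest, d_min = EPISTATIC_TO_A, d_a
    else:
        nearest, d_min = EPISTATIC_TO_B, d_b
    category = nearest if d_min < tolerance else OTHER
    return TSSInteractionCall(
        a=triple.a,
        b=triple.b,
        ab=triple.ab,
        category=category,
        polarity=_polarity(pa, pb, pab),
        d_additive=d_add,
        d_a=d_a,
        d_b=d_b,
        tolerance=tolerance,
    )


def growth_expected_multiplicative(fa: float, fb: float) -> float:
    """Multiplicative null: expected double-mutant fitness is the product of
    the single-mutant fitnesses."""
    for f in (fa, fb):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fitness {f} outside [0, 1]")
    return fa * fb


def call_growth_interaction(
    triple: GenotypeTriple, tau: float = DEFAULT_TAU
) -> GrowthInteractionCall:
    """Call the growth interaction of a triple against the multiplicative null.

    With ``E = fA * fB``: an inviable double with ``E > tau`` is synthetic
    lethal; ``fAB < E - tau`` synthetic sick; ``|fAB - E| <= tau`` no
    interaction.  Above the expectation, a double growing better than either
    single (beyond ``tau``) is mutual suppression; one matching a single
    mutant's fitness within ``tau`` is epistasis; the remaining above-expected
    cases are directional suppression (a boundary the source phenotypes do not
    pin down; flagged in output metadata by the writers).
    """
    if triple.fitness_a is None or triple.fitness_b is None:
        raise ValueError("single-mutant fitness missing")
    if triple.fitness_ab is None and not triple.ab_inviable:
        raise ValueError("double-mutant fitness missing")
    fa, fb = triple.fitness_a, triple.fitness_b
    fab = 0.0 if triple.ab_inviable else float(triple.fitness_ab)
    expected = growth_expected_multiplicative(fa, fb)
    if triple.ab_inviable and expected > tau:
        category = SYNTHETIC_LETHAL
    elif fab < expected - tau:
        category = SYNTHETIC_SICK
    elif abs(fab - expected) <= tau:
        category = NO_INTERACTION
    elif fab > max(fa, fb) + tau:
        category = SUPPRESSION_MUTUAL
    elif min(abs(fab - fa), abs(fab - fb)) <= tau:
        category = EPISTASIS
    else:
        category = SUPPRESSION_DIRECTIONAL
    return GrowthInteractionCall(
        a=triple.a,
        b=triple.b,
        ab=triple.ab,
        category=category,
        expected=expected,
        observed=fab,
        tau=tau,
    )


def classify_relationship(
    interactor: str,
    own_profile: ShiftProfile | None,
    panel: Sequence[PairEvidence],
) -> RelationshipClass:
    """Assign a relationship class to one interactor from its calls across a
    panel of Pol II alleles (convention: within each triple, A is the Pol II
    allele and B the interactor; only viable doubles contribute TSS evidence).

    * Class I — the interactor shifts TSSs on its own and a strict majority of
      its TSS calls are additive (suppressive or exacerbating by polarity).
    * Class II — the interactor shifts TSSs on its own and at least one triple
      is TSS-epistatic with a matching epistatic or enhancing growth call.
    * Class III — the interactor has no TSS defect of its own, every double's
      profile stays within tolerance of the Pol II single's (no modulation),
      and at least one growth call is non-trivial.
    Panels matching none of these are unclassified, with the evidence listed.
    """
    tss_calls = [e for e in panel if e.tss is not None]
    if not tss_calls:
        raise ValueError(f"panel for {interactor!r} has no TSS evidence")
    growth_calls = [e.growth for e in panel if e.growth is not None]
    own_defect = own_profile is not None and own_profile.direction != NONE

    evidence: list[str] = []
    if own_profile is not None:
        evidence.append(
            f"own TSS shift: {own_profile.direction} (index {own_profile.index:+.3f})"
        )
    for e in panel:
        bits = [f"vs {e.pol2}" + (f" [{e.pol2_class}]" if e.pol2_class else "")]
        if e.tss is not None:
            bits.append(f"tss={e.tss.category}/{e.tss.polarity}")
        if e.growth is not None:
            bits.append(f"growth={e.growth.category}")
        evidence.append(" ".join(bits))

    n_additive = sum(e.tss.category == ADDITIVE for e in tss_calls)
    epistatic_with_growth = [
        e
        for e in tss_calls
        if e.tss.category in (EPISTATIC_TO_A, EPISTATIC_TO_B)
        and e.growth is not None
        and e.growth.category in (GROWTH_ENHANCING | {EPISTASIS})
    ]
    no_modulation = all(e.tss.d_a < e.tss.tolerance for e in tss_calls)
    nontrivial_growth = any(c.category != NO_INTERACTION for c in growth_calls)

    if own_defect and n_additive * 2 > len(tss_calls):
        cls = "I"
    elif own_defect and epistatic_with_growth:
        cls = "II"
    elif not own_defect and no_modulation and nontrivial_growth:
        cls = "III"
    else:
        cls = "unclassified"
    return RelationshipClass(interactor=interactor, cls=cls, evidence=tuple(evidence))
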