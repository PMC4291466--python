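"""Quantification of transcription start site (TSS) usage from primer-extension lanes.

Yeast promoters initiate transcription from many discrete positions spread over
tens of nucleotides.  A primer-extension lane reports one band per used start
position, with band intensity proportional to usage.  The quantification scheme
implemented here divides the start positions of a promoter into ``K`` ordered
bins (six by default), normalizes the per-bin signal to the lane total, and
expresses a mutant's defect as the per-bin difference in normalized usage
relative to a reference (wild-type) distribution.  A signed scalar shift index
summarizes the polarity of that difference: negative values indicate usage
moving upstream (promoter-proximal), positive values downstream.

Coordinates are integers on a promoter-local axis increasing downstream; bin
intervals are closed-open ``[start, end)`` and contiguous, so every position is
in at most one bin and adjacent bins share a boundary unambiguously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LowReplicateWarning",
    "BinScheme",
    "LaneSignal",
    "TSSDistribution",
    "ShiftProfile",
    "bin_lane",
    "normalize_bins",
    "quantify_lane",
    "aggregate_replicates",
    "relative_change",
    "shift_index",
    "classify_direction",
    "UPSTREAM",
    "DOWNSTREAM",
    "NONE",
]

#: Direction labels for shift classification.
UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
NONE = "none"

#: Fallback half-width for direction classification when replicate standard
#: deviations are unavailable (fewer than two replicates on either side).
FALLBACK_DIRECTION_TOLERANCE = 0.05

DEFAULT_K = 6


class LowReplicateWarning(UserWarning):
    """Emitted when fewer than three independent determinations are combined."""


@dataclass(frozen=True)
class BinScheme:
    """Ordered partition of promoter positions into ``K`` contiguous bins.

    Parameters
    ----------
    boundaries
        ``K`` integer pairs ``(start, end)``; each bin covers ``[start, end)``.
        Bins are numbered 1 (most upstream) to ``K`` (most downstream) and must
        be contiguous: each bin's ``end`` equals the next bin's ``start``.
    """

    boundaries: tuple[tuple[int, int], ...]

    def __init__(self, boundaries: Iterable[Sequence[int]]):
        bnds = tuple((int(s), int(e)) for s, e in boundaries)
        if not bnds:
            raise ValueError("bin scheme needs at least one bin")
        for i, (s, e) in enumerate(bnds):
            if e <= s:
                raise ValueError(f"bin {i + 1} is empty or inverted: [{s}, {e})")
        for i in range(len(bnds) - 1):
            if bnds[i][1] != bnds[i + 1][0]:
                raise ValueError(
                    f"bins {i + 1} and {i + 2} are not contiguous: "
                    f"[{bnds[i][0]}, {bnds[i][1]}) then [{bnds[i + 1][0]}, {bnds[i + 1][1]})"
                )
        object.__setattr__(self, "boundaries", bnds)
        if self.K != DEFAULT_K:
            warnings.warn(
                f"bin scheme has K={self.K}, not the default six-bin scheme",
                UserWarning,
                stacklevel=2,
            )

    @property
    def K(self) -> int:
        return len(self.boundaries)

    @property
    def edges(self) -> np.ndarray:
        """The ``K + 1`` shared interval edges, ascending."""
        return np.array([s for s, _ in self.boundaries] + [self.boundaries[-1][1]])

    @property
    def is_default(self) -> bool:
        return self.K == DEFAULT_K

    def bin_of(self, position: int) -> int:
        """Return the 0-based bin index containing ``position``.

        Raises
        ------
        ValueError
            If the position lies outside every bin.
        """
        edges = self.edges
        idx = int(np.searchsorted(edges, position, side="right")) - 1
        if idx < 0 or idx >= self.K or position >= edges[-1]:
            raise ValueError(
                f"position {position} falls outside the bin scheme "
                f"[{edges[0]}, {edges[-1]})"
            )
        return idx

    def centered_ranks(self) -> np.ndarray:
        """Bin ranks centered at zero: ``b - (K + 1) / 2`` for bins 1..K."""
        return np.arange(1, self.K + 1) - (self.K + 1) / 2.0


@dataclass(frozen=True)
class LaneSignal:
    """Per-position band intensities for one strain/replicate at one promoter."""

    positions: np.ndarray
    intensities: np.ndarray
    strain: str = "strain"
    replicate: str = "1"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=int)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or inten.ndim != 1 or pos.size != inten.size:
            raise ValueError("positions and intensities must be 1-D and equal length")
        if pos.size == 0:
            raise ValueError("lane has no positions")
        if len(np.unique(pos)) != pos.size:
            raise ValueError("lane positions must be unique")
        if np.any(inten < 0):
            bad = pos[inten < 0][0]
            raise ValueError(f"negative intensity at position {bad}")
        if not np.any(inten > 0):
            raise ValueError("lane has no positive signal")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    @property
    def total(self) -> float:
        return float(self.intensities.sum())


@dataclass(frozen=True)
class TSSDistribution:
    """Normalized TSS usage over the bins of one scheme.

    ``fractions`` sum to 1; ``sd`` holds per-bin sample standard deviations
    across replicates and is present only when ``n_replicates >= 2``.
    """

    fractions: np.ndarray
    scheme: BinScheme
    strain: str = ""
    n_replicates: int = 1
    sd: np.ndarray | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        if frac.size != self.scheme.K:
            raise ValueError("fraction vector length must equal bin count")
        if np.any(frac < -1e-12) or np.any(frac > 1 + 1e-12):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.sd is not None:
            if self.n_replicates < 2:
                raise ValueError("sd requires at least two replicates")
            object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        object.__setattr__(self, "fractions", frac)

    @property
    def se(self) -> np.ndarray | None:
        """Per-bin standard error of the mean fraction, if sd is available."""
        if self.sd is None:
            return None
        return self.sd / np.sqrt(self.n_replicates)


@dataclass(frozen=True)
class ShiftProfile:
    """Per-bin usage change of a mutant versus a reference distribution.

    ``deltas`` (mutant fraction minus reference fraction, per bin) sum to zero;
    ``index`` is the centered-rank-weighted sum of the deltas, negative for an
    upstream shift; ``direction`` is the classification of ``index`` against
    ``tolerance``.  ``se`` carries per-bin standard errors of the deltas
    propagated from replicate standard deviations, when both sides had
    replication.
    """

    deltas: np.ndarray
    scheme: BinScheme
    strain: str = ""
    reference: str = ""
    index: float = 0.0
    direction: str = NONE
    tolerance: float = FALLBACK_DIRECTION_TOLERANCE
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        deltas = np.asarray(self.deltas, dtype=float)
        if deltas.size != self.scheme.K:
            raise ValueError("delta vector length must equal bin count")
        if abs(deltas.sum()) > 1e-9:
            raise ValueError("deltas must sum to 0")
        if self.direction not in (UPSTREAM, DOWNSTREAM, NONE):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == UPSTREAM and self.index >= 0:
            raise ValueError("upstream direction requires a negative index")
        if self.direction == DOWNSTREAM and self.index <= 0:
            raise ValueError("downstream direction requires a positive index")
        object.__setattr__(self, "deltas", deltas)
        if self.se is not None:
            object.__setattr__(self, "se", np.asarray(self.se, dtype=float))


def bin_lane(lane: LaneSignal, scheme: BinScheme) -> np.ndarray:
    """Sum lane intensities into the scheme's bins.

    Every lane position must fall inside exactly one bin; a position outside
    the scheme raises ``ValueError`` naming the position.  The bin totals
    preserve the lane total exactly (it is a partition of the same addends).
    """
    edges = scheme.edges
    idx = np.searchsorted(edges, lane.positions, side="right") - 1
    outside = (idx < 0) | (idx >= scheme.K) | (lane.positions >= edges[-1])
    if np.any(outside):
        bad = int(lane.positions[outside][0])
        raise ValueError(
            f"position {bad} in lane {lane.strain}/{lane.replicate} "
            f"falls outside the bin scheme [{edges[0]}, {edges[-1]})"
        )
    sums = np.zeros(scheme.K)
    np.add.at(sums, idx, lane.intensities)
    return sums


def normalize_bins(
    raw_sums: np.ndarray, scheme: BinScheme, strain: str = ""
) -> TSSDistribution:
    """Normalize raw bin sums to the lane total, yielding usage fractions."""
    sums = np.asarray(raw_sums, dtype=float)
    total = sums.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero lane")
    return TSSDistribution(fractions=sums / total, scheme=scheme, strain=strain)


def quantify_lane(lane: LaneSignal, scheme: BinScheme) -> TSSDistribution:
    """Bin and normalize a single lane in one step."""
    return normalize_bins(bin_lane(lane, scheme), scheme, strain=lane.strain)


def aggregate_replicates(
    distributions: Sequence[TSSDistribution],
) -> TSSDistribution:
    """Average independent per-replicate distributions.

    Per-bin means are renormalized to sum exactly to 1 and per-bin sample
    standard deviations (ddof=1) are attached.  Combining fewer than three
    determinations emits :class:`LowReplicateWarning` and flags the result.
    """
    if len(distributions) == 0:
        raise ValueError("no distributions to aggregate")
    scheme = distributions[0].scheme
    if any(d.scheme != scheme for d in distributions):
        raise ValueError("replicates quantified under different bin schemes")
    stack = np.vstack([d.fractions for d in distributions])
    mean = stack.mean(axis=0)
    mean = mean / mean.sum()
    n = len(distributions)
    sd = stack.std(axis=0, ddof=1) if n >= 2 else None
    flags: tuple[str, ...] = ()
    if n < 3:
        warnings.warn(
            f"only {n} replicate(s); at least three independent determinations "
            "are expected",
            LowReplicateWarning,
            stacklevel=2,
        )
        flags = ("low_replicate",)
    return TSSDistribution(
        fractions=mean,
        scheme=scheme,
        strain=distributions[0].strain,
        n_replicates=n,
        sd=sd,
        flags=flags,
    )


def shift_index(deltas: np.ndarray) -> float:
    """Signed scalar summary of a per-bin change profile.

    ``index = sum_b delta_b * (b - (K + 1) / 2)`` with bins numbered 1 (most
    upstream) to K (most downstream): positive means usage moved downstream,
    negative upstream.  Negating the profile negates the index exactly.
    """
    deltas = np.asarray(deltas, dtype=float)
    K = deltas.size
    ranks = np.arange(1, K + 1) - (K + 1) / 2.0
    return float(np.dot(deltas, ranks))


def classify_direction(
    index: float, tolerance: float = FALLBACK_DIRECTION_TOLERANCE
) -> str:
    """Classify a shift index as upstream, downstream, or none.

    Strict inequalities: an index exactly at the tolerance boundary is ``none``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if index < -tolerance:
        return UPSTREAM
    if index > tolerance:
        return DOWNSTREAM
    return NONE


def _propagated_index_se(
    mutant: TSSDistribution, reference: TSSDistribution
) -> tuple[np.ndarray | None, float | None]:
    """Per-bin delta SEs and the propagated SE of the shift index."""
    se_m, se_r = mutant.se, reference.se
    if se_m is None or se_r is None:
        return None, None
    se_b = np.sqrt(se_m**2 + se_r**2)
    ranks = mutant.scheme.centered_ranks()
    return se_b, float(np.sqrt(np.sum((ranks * se_b) ** 2)))


def relative_change(
    mutant: TSSDistribution,
    reference: TSSDistribution,
    tolerance: float | None = None,
) -> ShiftProfile:
    """Per-bin change in normalized TSS usage of a mutant versus a reference.

    The default direction tolerance is twice the standard error of the shift
    index propagated from replicate standard deviations of both strains; when
    either side lacks replication it falls back to
    ``FALLBACK_DIRECTION_TOLERANCE`` (0.05).
    """
    if mutant.scheme != reference.scheme:
        raise ValueError("mutant and reference use different bin schemes")
    deltas = mutant.fractions - reference.fractions
    deltas = deltas - deltas.sum() / deltas.size  # exact zero-sum against fp drift
    index = shift_index(deltas)
    se_b, index_se = _propagated_index_se(mutant, reference)
    if tolerance is None:
        tolerance = (
            2.0 * index_se if index_se is not None else FALLBACK_DIRECTION_TOLERANCE
        )
    direction = classify_direction(index, tolerance)
    return ShiftProfile(
        deltas=deltas,
        scheme=mutant.scheme,
        strain=mutant.strain,
        reference=reference.strain,
        index=index,
        direction=direction,
        tolerance=tolerance,
        se=se_b,
    )
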