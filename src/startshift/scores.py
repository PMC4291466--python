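"""Growth-phenotype score normalization and heatmap construction.

Spot-dilution growth of each strain on each medium is scored on an integer
0-5 scale.  On general media and the MPA medium, 5 is wild-type-like growth;
on the reporter media (galactose-resistance and Spt- readouts) the convention
inverts: 0 is wild-type growth and 5 the strongest mutant phenotype.  Raw
scores are turned into a heatmap-ready matrix by three media-class-specific
normalizations:

* general media — subtraction: ``mutant score - WT score`` on the same plate;
* MPA medium — net sensitivity: the general-media difference on the MPA plate
  minus the difference on its paired control plate;
* reporter media — the reporter score divided by the ratio of WT growth to
  mutant growth on the paired general-growth control, discounting reporter
  signal by the mutant's underlying growth defect.

Inviable double mutants carry an ``INVIABLE`` marker that propagates through
every derived quantity and never enters arithmetic; a degenerate reporter
divisor (mutant control score 0) yields a ``MISSING`` marker instead of an
infinity so the heatmap stays renderable.  The net-MPA formula cannot report
sensitivity beyond a mutant's floor: when the mutant's MPA score is already 0
the net value understates true sensitivity, so such cells are flagged with a
machine-readable zero-growth caveat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "INVIABLE",
    "MISSING",
    "is_marker",
    "MediaPanel",
    "RawScoreTable",
    "NormalizedScoreTable",
    "general_diff",
    "mpa_net",
    "reporter_normalized",
    "build_heatmap_matrix",
    "render_heatmap",
    "GENERAL",
    "MPA",
    "REPORTER",
]

GENERAL = "general"
MPA = "mpa"
REPORTER = "reporter"

SCORE_MIN, SCORE_MAX = 0, 5


class _Marker:
    """Inert cell marker.  Supports no arithmetic: any attempt to use a marker
    in a numeric expression raises ``TypeError``, so markers cannot silently
    leak into derived values."""

    __slots__ = ("token",)

    def __init__(self, token: str):
        self.token = token

    def __repr__(self) -> str:
        return self.token

    def __deepcopy__(self, memo):  # markers are singletons
        return self


INVIABLE = _Marker("INVIABLE")
MISSING = _Marker("MISSING")


def is_marker(value) -> bool:
    return isinstance(value, _Marker)


@dataclass(frozen=True)
class MediaPanel:
    """Declares each medium's class and, for MPA/reporter media, its paired
    general-growth control medium."""

    classes: Mapping[str, str]
    controls: Mapping[str, str]

    def __post_init__(self) -> None:
        for medium, cls in self.classes.items():
            if cls not in (GENERAL, MPA, REPORTER):
                raise ValueError(f"unknown media class {cls!r} for {medium!r}")
            if cls in (MPA, REPORTER):
                if medium not in self.controls:
                    raise ValueError(f"{cls} medium {medium!r} declares no control")
                ctrl = self.controls[medium]
                if self.classes.get(ctrl) != GENERAL:
                    raise ValueError(
                        f"control {ctrl!r} of {medium!r} is not a general medium"
                    )
        for medium in self.controls:
            if self.classes.get(medium) not in (MPA, REPORTER):
                raise ValueError(f"control declared for non-conditional medium {medium!r}")

    @classmethod
    def default(cls) -> "MediaPanel":
        """The study's media panel: four general media, net-MPA versus SC-Leu,
        and the two reporter media paired with their standard-growth controls."""
        return cls(
            classes={
                "YPD": GENERAL,
                "YPD37": GENERAL,
                "YPRaf": GENERAL,
                "SC-Leu": GENERAL,
                "SC-Leu+MPA": MPA,
                "YPRafGal": REPORTER,
                "SC-Lys": REPORTER,
            },
            controls={
                "SC-Leu+MPA": "SC-Leu",
                "YPRafGal": "YPD",
                "SC-Lys": "SC-Leu",
            },
        )

    def media_of_class(self, cls: str) -> list[str]:
        return [m for m, c in self.classes.items() if c == cls]


def _validate_score(value, where: str):
    if is_marker(value):
        return value
    if isinstance(value, (bool, float)) and not float(value).is_integer():
        raise ValueError(f"non-integer score {value!r} at {where}")
    score = int(value)
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise ValueError(f"score {score} at {where} outside [0, 5]")
    return score


@dataclass
class RawScoreTable:
    """Strain-by-media integer 0-5 scores with an INVIABLE marker and a
    designated wild-type reference strain.  Row order is preserved as given."""

    table: pd.DataFrame
    wt: str

    def __post_init__(self) -> None:
        if self.wt not in self.table.index:
            raise ValueError(f"WT strain {self.wt!r} absent from score table")
        cleaned = self.table.copy()
        for strain in cleaned.index:
            for medium in cleaned.columns:
                cleaned.loc[strain, medium] = _validate_score(
                    cleaned.loc[strain, medium], f"({strain}, {medium})"
                )
            if any(is_marker(v) for v in cleaned.loc[strain]) and strain == self.wt:
                raise ValueError("WT strain cannot be INVIABLE")
        self.table = cleaned.astype(object)

    @property
    def strains(self) -> list[str]:
        return list(self.table.index)

    @property
    def media(self) -> list[str]:
        return list(self.table.columns)

    def score(self, strain: str, medium: str):
        return self.table.loc[strain, medium]

    def is_inviable(self, strain: str) -> bool:
        return any(is_marker(v) for v in self.table.loc[strain])


@dataclass
class NormalizedScoreTable:
    """Heatmap-ready normalized values; cells are floats or the INVIABLE /
    MISSING markers.  ``caveats`` lists (strain, medium) cells whose net-MPA
    value is floored by zero mutant growth on the MPA plate."""

    table: pd.DataFrame
    wt: str
    caveats: tuple[tuple[str, str], ...] = ()

    def numeric(self) -> pd.DataFrame:
        """Float view with markers as NaN (for plotting/statistics)."""
        return self.table.map(lambda v: np.nan if is_marker(v) else float(v))


def general_diff(score_mutant, score_wt):
    """Same-plate WT-normalized growth: ``mutant - WT``.  Negative = slower
    growth than WT, positive = faster.  INVIABLE propagates."""
    if is_marker(score_wt):
        raise ValueError("WT score cannot be a marker")
    if score_mutant is INVIABLE:
        return INVIABLE
    if score_mutant is MISSING:
        return MISSING
    return float(score_mutant - score_wt)


def mpa_net(diff_on_mpa, diff_on_control):
    """Net growth difference due to MPA sensitivity/resistance: the WT-relative
    difference on the MPA plate minus the difference on the paired control.
    Negative = MPA-sensitive, positive = MPA-resistant."""
    for d in (diff_on_mpa, diff_on_control):
        if is_marker(d):
            return d
    return float(diff_on_mpa - diff_on_control)


def reporter_normalized(score_reporter, score_wt_control, score_mutant_control):
    """Reporter phenotype discounted by the mutant's general growth defect:
    ``reporter / (WT control / mutant control)``.  A mutant control score of 0
    makes the divisor degenerate and yields MISSING."""
    if score_reporter is INVIABLE or score_mutant_control is INVIABLE:
        return INVIABLE
    if is_marker(score_reporter) or is_marker(score_mutant_control):
        return MISSING
    if is_marker(score_wt_control):
        raise ValueError("WT control score cannot be a marker")
    if score_wt_control == 0:
        raise ValueError("WT control score of 0 leaves the reporter ratio undefined")
    if score_mutant_control == 0:
        return MISSING
    return float(score_reporter / (score_wt_control / score_mutant_control))


def build_heatmap_matrix(raw: RawScoreTable, panel: MediaPanel) -> NormalizedScoreTable:
    """Apply the media-class-specific normalizations to a raw score table.

    Strain order is preserved; INVIABLE rows stay INVIABLE in every cell and
    degenerate reporter ratios become MISSING.  Cells where the net-MPA value
    is floored (mutant MPA score 0) are recorded in ``caveats``.
    """
    unknown = [m for m in raw.media if m not in panel.classes]
    if unknown:
        raise ValueError(f"media without a declared class: {unknown}")
    out = pd.DataFrame(index=raw.table.index, columns=raw.table.columns, dtype=object)
    caveats: list[tuple[str, str]] = []
    for strain in raw.strains:
        inviable = raw.is_inviable(strain)
        for medium in raw.media:
            if inviable:
                out.loc[strain, medium] = INVIABLE
                continue
            cls = panel.classes[medium]
            mut = raw.score(strain, medium)
            wt = raw.score(raw.wt, medium)
            if cls == GENERAL:
                out.loc[strain, medium] = general_diff(mut, wt)
            elif cls == MPA:
                ctrl = panel.controls[medium]
                value = mpa_net(
                    general_diff(mut, wt),
                    general_diff(raw.score(strain, ctrl), raw.score(raw.wt, ctrl)),
                )
                out.loc[strain, medium] = value
                if not is_marker(mut) and mut == 0:
                    caveats.append((strain, medium))
            else:  # reporter
                ctrl = panel.controls[medium]
                out.loc[strain, medium] = reporter_normalized(
                    mut, raw.score(raw.wt, ctrl), raw.score(strain, ctrl)
                )
    return NormalizedScoreTable(table=out, wt=raw.wt, caveats=tuple(caveats))


def render_heatmap(matrix: NormalizedScoreTable, path) -> None:
    """Render the normalized matrix as a diverging blue-white-red heatmap.

    The color scale is symmetric about 0 so equal-magnitude growth gains and
    losses are equally saturated; INVIABLE cells are dark gray, MISSING cells
    light gray with hatching.  Output format follows the file extension.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.numeric().to_numpy(dtype=float)
    nrow, ncol = values.shape
    finite = values[np.isfinite(values)]
    vmax = float(np.max(np.abs(finite))) if finite.size and np.max(np.abs(finite)) > 0 else 1.0

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.6 * ncol + 2.0), max(3.0, 0.35 * nrow + 1.5))
    )
    masked = np.ma.masked_invalid(values)
    cmap = plt.get_cmap("bwr").copy()
    im = ax.imshow(masked, cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
    for i, strain in enumerate(matrix.table.index):
        for j, medium in enumerate(matrix.table.columns):
            cell = matrix.table.loc[strain, medium]
            if cell is INVIABLE:
                ax.add_patch(
                    plt.Rectangle((j - 0.5, i - 0.5), 1, 1, color="0.25", lw=0)
                )
            elif cell is MISSING:
                ax.add_patch(
                    plt.Rectangle(
                        (j - 0.5, i - 0.5), 1, 1,
                        facecolor="0.85", edgecolor="0.5", hatch="//", lw=0,
                    )
                )
    ax.set_xticks(range(ncol), labels=list(matrix.table.columns), rotation=45, ha="right")
    ax.set_yticks(range(nrow), labels=list(matrix.table.index))
    fig.colorbar(im, ax=ax, label="normalized growth score")
    fig.tight_layout()
    fig.savefig(path, metadata=_no_date_metadata(str(path)))
    plt.close(fig)


def _no_date_metadata(path: str) -> dict | None:
    """Strip volatile timestamps from saved figures so reruns are comparable."""
    if path.endswith(".png"):
        return {"Software": "startshift"}
    if path.endswith(".svg") or path.endswith(".pdf"):
        return {"Date": None}
    return None
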