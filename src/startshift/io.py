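"""Tab-separated file formats and run configuration.

All tables are plain TSV with a stable column order and a metadata header of
comment lines beginning ``#`` (``# key=value``); readers ignore those lines.
Markers are written as the literal tokens ``INVIABLE`` and ``MISSING``.
Writers never embed timestamps, so re-running a seeded pipeline reproduces
byte-identical files.

The run configuration is a strict YAML document: unknown keys anywhere are
rejected, and a single top-level seed feeds every stochastic stage.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .interactions import GrowthInteractionCall, RelationshipClass, TSSInteractionCall
from .quant import BinScheme, LaneSignal, ShiftProfile, TSSDistribution
from .scores import (
    INVIABLE,
    MISSING,
    MediaPanel,
    NormalizedScoreTable,
    RawScoreTable,
    is_marker,
)
from .synthetic import GrowthModel, NoiseModel, PromoterModel

__all__ = [
    "RunConfig",
    "load_config",
    "default_config_path",
    "write_lane_table",
    "read_lane_table",
    "write_score_table",
    "read_score_table",
    "write_normalized_table",
    "read_normalized_table",
    "write_quant_table",
    "read_quant_table",
    "write_interaction_calls",
    "write_relationship_classes",
]

_FLOAT_FMT = "%.10g"


def _fmt(value) -> str:
    if is_marker(value):
        return value.token
    if isinstance(value, float):
        return _FLOAT_FMT % value
    return str(value)


def _header_lines(meta: Mapping[str, object]) -> list[str]:
    lines = [f"# startshift={__version__}"]
    for key, value in meta.items():
        lines.append(f"# {key}={value}")
    return lines


def _read_rows(path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Read a TSV skipping '#' comment lines; returns (header, [(lineno, row)])."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not line or (line[0].startswith("#")):
                continue
            if header is None:
                header = line
            else:
                rows.append((lineno, line))
    if header is None:
        raise ValueError(f"{path}: no header line found")
    return header, rows


# ---------------------------------------------------------------------------
# lane tables

def write_lane_table(
    lanes: Sequence[LaneSignal], path, meta: Mapping[str, object] | None = None
) -> None:
    """Write lanes as TSV with columns strain/replicate/position/intensity."""
    with open(path, "w", newline="") as fh:
        for line in _header_lines(meta or {}):
            fh.write(line + "\n")
        fh.write("strain\treplicate\tposition\tintensity\n")
        for lane in lanes:
            for pos, inten in zip(lane.positions, lane.intensities):
                fh.write(
                    f"{lane.strain}\t{lane.replicate}\t{pos}\t{_FLOAT_FMT % inten}\n"
                )


def read_lane_table(path) -> list[LaneSignal]:
    """Read a lane table, grouping rows into one LaneSignal per
    (strain, replicate).  Malformed rows and negative intensities raise with
    the offending line number; a header-only file returns an empty list with
    a warning."""
    header, rows = _read_rows(path)
    expected = ["strain", "replicate", "position", "intensity"]
    if header != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {header}")
    if not rows:
        warnings.warn(f"{path}: lane table is empty", UserWarning, stacklevel=2)
        return []
    groups: dict[tuple[str, str], list[tuple[int, float]]] = {}
    order: list[tuple[str, str]] = []
    for lineno, row in rows:
        if len(row) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 fields, found {len(row)}")
        strain, replicate, pos_s, inten_s = row
        try:
            pos, inten = int(pos_s), float(inten_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
        if inten < 0:
            raise ValueError(
                f"{path}:{lineno}: negative intensity {inten} at position {pos}"
            )
        key = (strain, replicate)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append((pos, inten))
    lanes = []
    for strain, replicate in order:
        pairs = sorted(groups[(strain, replicate)])
        lanes.append(
            LaneSignal(
                positions=np.array([p for p, _ in pairs]),
                intensities=np.array([i for _, i in pairs]),
                strain=strain,
                replicate=replicate,
            )
        )
    return lanes


# ---------------------------------------------------------------------------
# score tables

def write_score_table(
    raw: RawScoreTable, path, meta: Mapping[str, object] | None = None
) -> None:
    """Write a raw strain-by-media score table (integer scores or INVIABLE)."""
    meta = dict(meta or {})
    meta.setdefault("wt", raw.wt)
    with open(path, "w", newline="") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("strain\t" + "\t".join(raw.media) + "\n")
        for strain in raw.strains:
            cells = [_fmt(raw.table.loc[strain, m]) for m in raw.media]
            fh.write(strain + "\t" + "\t".join(cells) + "\n")


def _read_matrix(path, parse_cell):
    header, rows = _read_rows(path)
    if not header or header[0] != "strain":
        raise ValueError(f"{path}: first column must be 'strain'")
    media = header[1:]
    wt = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# wt="):
                wt = line.strip().split("=", 1)[1]
    data, index = [], []
    for lineno, row in rows:
        if len(row) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, found {len(row)}"
            )
        index.append(row[0])
        data.append([parse_cell(cell, lineno) for cell in row[1:]])
    table = pd.DataFrame(data, index=index, columns=media, dtype=object)
    return table, wt


def read_score_table(path) -> RawScoreTable:
    def parse(cell: str, lineno: int):
        if cell == INVIABLE.token:
            return INVIABLE
        try:
            return int(cell)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed score {cell!r}") from None

    table, wt = _read_matrix(path, parse)
    if wt is None:
        raise ValueError(f"{path}: missing '# wt=' metadata line")
    return RawScoreTable(table=table, wt=wt)


def write_normalized_table(
    norm: NormalizedScoreTable, path, meta: Mapping[str, object] | None = None
) -> None:
    meta = dict(meta or {})
    meta.setdefault("wt", norm.wt)
    for strain, medium in norm.caveats:
        meta[f"caveat_zero_growth_mpa.{strain}.{medium}"] = (
            "net MPA value floored: mutant MPA score is 0"
        )
    with open(path, "w", newline="") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        media = list(norm.table.columns)
        fh.write("strain\t" + "\t".join(media) + "\n")
        for strain in norm.table.index:
            cells = [_fmt(norm.table.loc[strain, m]) for m in media]
            fh.write(strain + "\t" + "\t".join(cells) + "\n")


def read_normalized_table(path) -> NormalizedScoreTable:
    def parse(cell: str, lineno: int):
        if cell == INVIABLE.token:
            return INVIABLE
        if cell == MISSING.token:
            return MISSING
        try:
            return float(cell)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed value {cell!r}") from None

    table, wt = _read_matrix(path, parse)
    caveats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# caveat_zero_growth_mpa."):
                key = line[2:].split("=", 1)[0]
                _, strain, medium = key.split(".", 2)
                caveats.append((strain, medium))
    return NormalizedScoreTable(
        table=table, wt=wt or "", caveats=tuple(caveats)
    )


# ---------------------------------------------------------------------------
# quantification tables

def write_quant_table(
    results: Mapping[str, tuple[TSSDistribution, ShiftProfile | None]],
    path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write per-strain distributions and shift profiles.

    Columns: strain, bin, fraction, sd, n, delta, se, index, direction
    (index/direction repeated on each of the strain's K rows; empty fields
    where a quantity is undefined, e.g. sd with one replicate or delta for
    the reference strain itself)."""
    with open(path, "w", newline="") as fh:
        for line in _header_lines(meta or {}):
            fh.write(line + "\n")
        fh.write("strain\tbin\tfraction\tsd\tn\tdelta\tse\tindex\tdirection\n")
        for strain, (dist, profile) in results.items():
            K = dist.scheme.K
            for b in range(K):
                sd = _FLOAT_FMT % dist.sd[b] if dist.sd is not None else ""
                delta = _FLOAT_FMT % profile.deltas[b] if profile is not None else ""
                se = (
                    _FLOAT_FMT % profile.se[b]
                    if profile is not None and profile.se is not None
                    else ""
                )
                index = _FLOAT_FMT % profile.index if profile is not None else ""
                direction = profile.direction if profile is not None else ""
                fh.write(
                    f"{strain}\t{b + 1}\t{_FLOAT_FMT % dist.fractions[b]}\t{sd}\t"
                    f"{dist.n_replicates}\t{delta}\t{se}\t{index}\t{direction}\n"
                )


def read_quant_table(
    path, scheme: BinScheme
) -> dict[str, tuple[TSSDistribution, ShiftProfile | None]]:
    """Reconstruct per-strain distributions/profiles written by
    :func:`write_quant_table` under a known bin scheme."""
    header, rows = _read_rows(path)
    expected = ["strain", "bin", "fraction", "sd", "n", "delta", "se", "index", "direction"]
    if header != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {header}")
    per_strain: dict[str, list[tuple[int, list[str]]]] = {}
    order: list[str] = []
    for lineno, row in rows:
        strain = row[0]
        if strain not in per_strain:
            per_strain[strain] = []
            order.append(strain)
        per_strain[strain].append((lineno, row))
    out: dict[str, tuple[TSSDistribution, ShiftProfile | None]] = {}
    for strain in order:
        entries = sorted(per_strain[strain], key=lambda e: int(e[1][1]))
        if len(entries) != scheme.K:
            raise ValueError(
                f"{path}: strain {strain!r} has {len(entries)} bins, expected {scheme.K}"
            )
        fractions = np.array([float(r[2]) for _, r in entries])
        sds = [r[3] for _, r in entries]
        n = int(entries[0][1][4])
        sd = np.array([float(s) for s in sds]) if all(s != "" for s in sds) else None
        dist = TSSDistribution(
            fractions=fractions, scheme=scheme, strain=strain, n_replicates=n, sd=sd
        )
        deltas = [r[5] for _, r in entries]
        profile = None
        if all(d != "" for d in deltas):
            ses = [r[6] for _, r in entries]
            se = np.array([float(s) for s in ses]) if all(s != "" for s in ses) else None
            index = float(entries[0][1][7])
            direction = entries[0][1][8]
            tol = abs(index) if direction != "none" else max(abs(index), 1e-12)
            # direction was classified at write time; rebuild with a tolerance
            # consistent with the stored call
            profile = ShiftProfile(
                deltas=np.array([float(d) for d in deltas]),
                scheme=scheme,
                strain=strain,
                index=index,
                direction=direction,
                tolerance=_tolerance_consistent_with(index, direction),
                se=se,
            )
        out[strain] = (dist, profile)
    return out


def _tolerance_consistent_with(index: float, direction: str) -> float:
    """A tolerance value under which classify_direction(index) reproduces the
    stored direction (the original tolerance is not serialized per bin row)."""
    if direction == "none":
        return max(abs(index) * 1.000001, 1e-12)
    return abs(index) / 2.0


# ---------------------------------------------------------------------------
# interaction outputs

def write_interaction_calls(
    calls: Sequence[tuple[TSSInteractionCall | None, GrowthInteractionCall | None]],
    path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """One row per triple: TSS category/polarity/distances and growth
    category/expected/observed."""
    meta = dict(meta or {})
    meta.setdefault(
        "note_suppression_directional",
        "above-expectation calls not matching mutual suppression or "
        "single-mutant epistasis; boundary is a package heuristic",
    )
    cols = [
        "a", "b", "ab",
        "tss_category", "tss_polarity", "d_additive", "d_a", "d_b", "tss_tolerance",
        "growth_category", "expected_fitness", "observed_fitness", "tau",
    ]
    with open(path, "w", newline="") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("\t".join(cols) + "\n")
        for tss, growth in calls:
            ref = tss or growth
            if ref is None:
                continue
            row = [ref.a, ref.b, ref.ab]
            if tss is not None:
                row += [
                    tss.category,
                    tss.polarity,
                    _FLOAT_FMT % tss.d_additive,
                    _FLOAT_FMT % tss.d_a,
                    _FLOAT_FMT % tss.d_b,
                    _FLOAT_FMT % tss.tolerance,
                ]
            else:
                row += [""] * 6
            if growth is not None:
                row += [
                    growth.category,
                    _FLOAT_FMT % growth.expected,
                    _FLOAT_FMT % growth.observed,
                    _FLOAT_FMT % growth.tau,
                ]
            else:
                row += [""] * 4
            fh.write("\t".join(row) + "\n")


def write_relationship_classes(
    classes: Sequence[RelationshipClass], path, meta: Mapping[str, object] | None = None
) -> None:
    with open(path, "w", newline="") as fh:
        for line in _header_lines(meta or {}):
            fh.write(line + "\n")
        fh.write("interactor\tclass\tevidence\n")
        for rc in classes:
            fh.write(f"{rc.interactor}\t{rc.cls}\t{'; '.join(rc.evidence)}\n")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class GrowthSpec:
    """Growth-panel section of a run configuration."""

    model: GrowthModel
    panel: MediaPanel
    media: tuple[str, ...]
    call_medium: str


@dataclass
class RunConfig:
    """Validated run configuration; the single source of every seed."""

    seed: int
    replicates: int
    promoter: PromoterModel
    noise: NoiseModel
    scheme: BinScheme
    #: strain -> ("theta", x) | ("additive", a, b) | ("copy", a)
    tss_specs: dict[str, tuple]
    growth: GrowthSpec
    triples: tuple[tuple[str, str, str], ...]
    pol2_classes: dict[str, str]
    interactors: tuple[str, ...]
    wt: str
    tss_tolerance: float | None = None
    tau: float = 0.1
    direction_tolerance: float | None = None
    verbosity: int = 0

    def flat_items(self) -> list[tuple[str, object]]:
        """Flattened key/value pairs echoed into output headers."""
        items: list[tuple[str, object]] = [
            ("seed", self.seed),
            ("replicates", self.replicates),
            ("promoter.name", self.promoter.name),
            ("promoter.positions", ",".join(map(str, self.promoter.positions))),
            ("noise.sigma", self.noise.sigma),
            ("noise.background", self.noise.background),
            ("noise.total_signal", self.noise.total_signal),
            ("bins", ",".join(f"[{s},{e})" for s, e in self.scheme.boundaries)),
            ("wt", self.wt),
            ("tau", self.tau),
        ]
        for strain, spec in self.tss_specs.items():
            if spec[0] == "theta":
                items.append((f"tss.{strain}", spec[1]))
            elif spec[0] == "additive":
                items.append((f"tss.{strain}", f"additive_of({spec[1]},{spec[2]})"))
            else:
                items.append((f"tss.{strain}", f"copy_of({spec[1]})"))
        return items


def _require_keys(section: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown configuration key(s) in {where}: {sorted(unknown)}")


def default_config_path() -> Path:
    """Path of the demo configuration shipped with the package."""
    return Path(__file__).parent / "data" / "demo_config.yaml"


def load_config(path) -> RunConfig:
    """Load and strictly validate a YAML run configuration.

    Unknown keys anywhere in the document are rejected; the WT strain must be
    declared in both the TSS and growth sections; WT fitness must be 1 on all
    general media.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    _require_keys(
        doc,
        {
            "seed", "replicates", "promoter", "noise", "bins", "tss_strains",
            "growth", "triples", "pol2_classes", "tolerances", "verbosity",
        },
        "top level",
    )
    for key in ("seed", "promoter", "bins", "tss_strains", "growth"):
        if key not in doc:
            raise ValueError(f"{path}: missing required section {key!r}")

    prom_sec = doc["promoter"]
    _require_keys(prom_sec, {"name", "positions", "base_weights"}, "promoter")
    promoter = PromoterModel(
        positions=np.array(prom_sec["positions"]),
        base_weights=np.array(prom_sec["base_weights"]),
        name=str(prom_sec.get("name", "promoter")),
    )

    noise_sec = doc.get("noise", {})
    _require_keys(noise_sec, {"sigma", "background", "total_signal"}, "noise")
    noise = NoiseModel(
        sigma=float(noise_sec.get("sigma", 0.1)),
        background=float(noise_sec.get("background", 0.0)),
        total_signal=float(noise_sec.get("total_signal", 10_000.0)),
    )

    bins_sec = doc["bins"]
    _require_keys(bins_sec, {"boundaries"}, "bins")
    scheme = BinScheme(bins_sec["boundaries"])

    tss_specs: dict[str, tuple] = {}
    for strain, spec in doc["tss_strains"].items():
        strain = str(strain)
        if isinstance(spec, (int, float)):
            tss_specs[strain] = ("theta", float(spec))
        elif isinstance(spec, dict):
            _require_keys(spec, {"theta", "additive_of", "copy_of"}, f"tss_strains.{strain}")
            if len(spec) != 1:
                raise ValueError(
                    f"tss_strains.{strain}: give exactly one of theta/additive_of/copy_of"
                )
            if "theta" in spec:
                tss_specs[strain] = ("theta", float(spec["theta"]))
            elif "additive_of" in spec:
                a, b = spec["additive_of"]
                tss_specs[strain] = ("additive", str(a), str(b))
            else:
                tss_specs[strain] = ("copy", str(spec["copy_of"]))
        else:
            raise ValueError(f"tss_strains.{strain}: malformed shift specification")
    for strain, spec in tss_specs.items():
        for parent in spec[1:] if spec[0] != "theta" else ():
            if tss_specs.get(parent, ("",))[0] != "theta":
                raise ValueError(
                    f"tss_strains.{strain}: parent {parent!r} must be a theta-specified strain"
                )

    growth_sec = doc["growth"]
    _require_keys(
        growth_sec,
        {
            "wt", "permissive_medium", "call_medium", "inviable_threshold",
            "jitter_prob", "media_panel", "fitness", "epsilon",
        },
        "growth",
    )
    wt = str(growth_sec["wt"])
    panel_sec = growth_sec["media_panel"]
    _require_keys(panel_sec, {"general", "mpa", "reporter"}, "growth.media_panel")
    classes: dict[str, str] = {}
    controls: dict[str, str] = {}
    for medium in panel_sec.get("general", []):
        classes[str(medium)] = "general"
    for medium, ctrl in (panel_sec.get("mpa") or {}).items():
        classes[str(medium)] = "mpa"
        controls[str(medium)] = str(ctrl)
    for medium, ctrl in (panel_sec.get("reporter") or {}).items():
        classes[str(medium)] = "reporter"
        controls[str(medium)] = str(ctrl)
    panel = MediaPanel(classes=classes, controls=controls)
    media = tuple(classes)

    fitness = {
        str(strain): {str(m): float(f) for m, f in per.items()}
        for strain, per in growth_sec["fitness"].items()
    }
    for medium in panel.media_of_class("general"):
        if fitness.get(wt, {}).get(medium, fitness.get(wt, {}).get("default")) != 1.0:
            raise ValueError(f"WT fitness must be 1 on general medium {medium!r}")

    triples_raw = doc.get("triples", [])
    triples = tuple((str(a), str(b), str(ab)) for a, b, ab in triples_raw)
    doubles = {ab: (a, b) for a, b, ab in triples}

    epsilon: dict[frozenset, dict[str, float]] = {}
    for entry in growth_sec.get("epsilon", []):
        _require_keys(entry, {"pair", "value", "media"}, "growth.epsilon entry")
        a, b = entry["pair"]
        per: dict[str, float] = {}
        if "value" in entry:
            per["default"] = float(entry["value"])
        for m, v in (entry.get("media") or {}).items():
            per[str(m)] = float(v)
        epsilon[frozenset((str(a), str(b)))] = per

    model = GrowthModel(
        fitness=fitness,
        doubles=doubles,
        epsilon=epsilon,
        wt=wt,
        permissive_medium=str(growth_sec.get("permissive_medium", "SC-Leu")),
        inviable_threshold=float(growth_sec.get("inviable_threshold", 0.05)),
        jitter_prob=float(growth_sec.get("jitter_prob", 0.0)),
        media=media,
    )
    call_medium = str(growth_sec.get("call_medium", "YPD"))
    if call_medium not in classes:
        raise ValueError(f"call_medium {call_medium!r} not in the media panel")

    if wt not in tss_specs:
        raise ValueError(f"WT strain {wt!r} missing from tss_strains")
    for a, b, ab in triples:
        for s in (a, b, ab):
            if s not in tss_specs:
                raise ValueError(f"triple strain {s!r} missing from tss_strains")

    tol_sec = doc.get("tolerances", {}) or {}
    _require_keys(tol_sec, {"tss_call", "tau", "direction"}, "tolerances")

    pol2_classes = {str(k): str(v) for k, v in (doc.get("pol2_classes") or {}).items()}
    interactors = tuple(dict.fromkeys(b for _, b, _ in triples))

    return RunConfig(
        seed=int(doc["seed"]),
        replicates=int(doc.get("replicates", 3)),
        promoter=promoter,
        noise=noise,
        scheme=scheme,
        tss_specs=tss_specs,
        growth=GrowthSpec(model=model, panel=panel, media=media, call_medium=call_medium),
        triples=triples,
        pol2_classes=pol2_classes,
        interactors=interactors,
        wt=wt,
        tss_tolerance=(None if tol_sec.get("tss_call") is None else float(tol_sec["tss_call"])),
        tau=float(tol_sec.get("tau", 0.1)),
        direction_tolerance=(
            None if tol_sec.get("direction") is None else float(tol_sec["direction"])
        ),
        verbosity=int(doc.get("verbosity", 0)),
    )
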