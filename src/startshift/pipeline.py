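"""End-to-end seeded pipeline: simulate -> quantify -> score -> interact.

Every stage writes its TSV artifact into the output directory; the whole run
is a pure function of (configuration, seed), so re-running a config produces
byte-identical TSV outputs.  Stage failures abort with the stage name and the
offending input in the message.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__, io
from .interactions import (
    GenotypeTriple,
    PairEvidence,
    call_growth_interaction,
    call_tss_interaction,
    classify_relationship,
    fitness_from_score,
)
from .quant import aggregate_replicates, quantify_lane, relative_change
from .scores import build_heatmap_matrix, render_heatmap
from .synthetic import (
    ShiftModel,
    additive_usage,
    simulate_growth_panel,
    simulate_replicates,
    usage_of,
)

__all__ = ["PipelineError", "run_pipeline"]

log = logging.getLogger("startshift")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _stage(stage: str):
    """Decorator converting stage exceptions into stage-tagged errors."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc

        return inner

    return wrap


def _resolve_shift(config: io.RunConfig, strain: str):
    """Resolve a strain's shift spec to a ShiftModel or planted usage vector.

    Singles carry a tilt strength theta; doubles may instead plant a
    mechanism: ``additive`` composes the parents' usage changes under the
    additive model, ``copy`` reuses one parent's usage (planted epistasis).
    """
    spec = config.tss_specs[strain]
    if spec[0] == "theta":
        return ShiftModel(spec[1])
    if spec[0] == "additive":
        sa = ShiftModel(config.tss_specs[spec[1]][1])
        sb = ShiftModel(config.tss_specs[spec[2]][1])
        return additive_usage(config.promoter, sa, sb)
    return usage_of(config.promoter, ShiftModel(config.tss_specs[spec[1]][1]))


@_stage("simulate")
def _simulate(config: io.RunConfig, outdir: Path):
    """Simulate growth panel and primer-extension lanes for every strain.

    Inviable doubles (decided on the growth model's permissive medium) are
    excluded from lane simulation: there is no strain to extract RNA from.
    """
    strains = list(config.tss_specs)
    raw = simulate_growth_panel(
        config.growth.model,
        strains=[s for s in strains if s in config.growth.model.fitness or s in config.growth.model.doubles],
        media=list(config.growth.media),
        seed=np.random.SeedSequence(config.seed, spawn_key=(0,)),
    )
    lanes = []
    viable = [s for s in strains if not (s in raw.strains and raw.is_inviable(s))]
    lane_root = np.random.SeedSequence(config.seed, spawn_key=(1,))
    substreams = lane_root.spawn(len(viable))
    for strain, ss in zip(viable, substreams):
        lanes.extend(
            simulate_replicates(
                config.promoter,
                _resolve_shift(config, strain),
                config.noise,
                n=config.replicates,
                seed=ss,
                strain=strain,
            )
        )
    meta = dict(config.flat_items())
    io.write_lane_table(lanes, outdir / "lanes.tsv", meta=meta)
    io.write_score_table(raw, outdir / "raw_scores.tsv", meta=meta)
    return lanes, raw


@_stage("quantify")
def _quantify(config: io.RunConfig, lanes, outdir: Path):
    by_strain: dict[str, list] = {}
    for lane in lanes:
        by_strain.setdefault(lane.strain, []).append(lane)
    if config.wt not in by_strain:
        raise ValueError(f"no lanes for WT strain {config.wt!r}")
    dists = {
        strain: aggregate_replicates(
            [quantify_lane(lane, config.scheme) for lane in strain_lanes]
        )
        for strain, strain_lanes in by_strain.items()
    }
    reference = dists[config.wt]
    results = {}
    for strain, dist in dists.items():
        profile = (
            relative_change(dist, reference, tolerance=config.direction_tolerance)
            if strain != config.wt
            else None
        )
        results[strain] = (dist, profile)
    io.write_quant_table(
        results, outdir / "quant.tsv", meta={"seed": config.seed, "wt": config.wt}
    )
    return results


@_stage("score")
def _score(config: io.RunConfig, raw, outdir: Path):
    norm = build_heatmap_matrix(raw, config.growth.panel)
    io.write_normalized_table(norm, outdir / "normalized_scores.tsv", meta={"seed": config.seed})
    render_heatmap(norm, outdir / "heatmap.png")
    return norm


@_stage("interact")
def _interact(config: io.RunConfig, quant_results, raw, outdir: Path):
    medium = config.growth.call_medium

    def fitness_and_flag(strain):
        return fitness_from_score(raw.score(strain, medium))

    calls = []
    per_interactor: dict[str, list[PairEvidence]] = {}
    for a, b, ab in config.triples:
        fa, a_inviable = fitness_and_flag(a)
        fb, b_inviable = fitness_and_flag(b)
        fab, ab_inviable = fitness_and_flag(ab)
        if a_inviable or b_inviable:
            raise ValueError(f"single mutant of triple ({a}, {b}, {ab}) is inviable")
        triple = GenotypeTriple(
            a=a,
            b=b,
            ab=ab,
            profile_a=quant_results.get(a, (None, None))[1],
            profile_b=quant_results.get(b, (None, None))[1],
            profile_ab=quant_results.get(ab, (None, None))[1],
            fitness_a=fa,
            fitness_b=fb,
            fitness_ab=0.0 if ab_inviable else fab,
            ab_inviable=ab_inviable,
        )
        tss_call = None
        if triple.profile_ab is not None:  # viable doubles only
            tss_call = call_tss_interaction(triple, tolerance=config.tss_tolerance)
        growth_call = call_growth_interaction(triple, tau=config.tau)
        calls.append((tss_call, growth_call))
        per_interactor.setdefault(b, []).append(
            PairEvidence(
                pol2=a,
                tss=tss_call,
                growth=growth_call,
                pol2_class=config.pol2_classes.get(a),
            )
        )
    io.write_interaction_calls(
        calls, outdir / "interaction_calls.tsv", meta={"seed": config.seed, "medium": medium}
    )
    classes = [
        classify_relationship(
            interactor,
            quant_results.get(interactor, (None, None))[1],
            panel,
        )
        for interactor, panel in per_interactor.items()
    ]
    io.write_relationship_classes(
        classes, outdir / "relationship_classes.tsv", meta={"seed": config.seed}
    )
    return calls, classes


def run_pipeline(config: io.RunConfig, outdir) -> Path:
    """Run the full pipeline into ``outdir`` and return that path.

    Stages: simulate (lanes + growth panel), quantify (six-bin distributions
    and shift profiles vs WT), score (normalized heatmap matrix + figure),
    interact (TSS/growth interaction calls and relationship classes), plus a
    run log recording version, seed, and parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.wt not in config.tss_specs or config.wt not in config.growth.model.fitness:
        raise PipelineError("validate", f"WT strain {config.wt!r} not declared")
    log.info("simulating lanes and growth panel (seed %d)", config.seed)
    lanes, raw = _simulate(config, outdir)
    log.info("quantifying %d lanes", len(lanes))
    quant_results = _quantify(config, lanes, outdir)
    _score(config, raw, outdir)
    _interact(config, quant_results, raw, outdir)
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"startshift {__version__}\n")
        for key, value in config.flat_items():
            fh.write(f"{key} = {value}\n")
    return outdir
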