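"""The full comparison pipeline: fit every model variant, build the
comparison table, reconstruct ancestral ranges under the best model, and run
the parsimony summaries.

A "variant" pairs a DEC-family model (DEC, DEC+J, DEC+x, DEC+J+x) with a
dispersal-constraint scheme (unconstrained, adjacency-only, or adjacency
with free dispersal within a named island chain).  The standard set of 12
variants, each run time-stratified and unstratified, yields the 24-row
comparison table.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .errors import DecGeoError
from .geography import StateSpace, StratifiedScenario, adjacency_constraint
from .inference import (OptimizerConfig, PruningEngine, fit_model,
                        model_spec)
from .model_selection import comparison_table
from .parsimony import (count_dispersal_events, fitch_parsimony,
                        lineage_accumulation, resolve)
from .trees import DatedTree


class PipelineStageError(DecGeoError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class ModelVariant:
    family: str
    scheme: str

    @property
    def label(self) -> str:
        if self.scheme == "unconstrained":
            suffix = " allDist unconstrained" if "x" in self.family else ""
        elif self.scheme == "adjacent_only":
            suffix = " constraints"
        else:
            suffix = " constraints Lesser Sunda open"
        return self.family + suffix


def standard_variants() -> tuple[ModelVariant, ...]:
    """The 12 family x constraint combinations of the standard comparison."""
    ordered = [
        ModelVariant("DEC", "unconstrained"),
        ModelVariant("DEC+J", "unconstrained"),
        ModelVariant("DEC", "adjacent_only"),
        ModelVariant("DEC+J", "adjacent_only"),
        ModelVariant("DEC", "adjacent_except_arc"),
        ModelVariant("DEC+J", "adjacent_except_arc"),
        ModelVariant("DEC+x", "unconstrained"),
        ModelVariant("DEC+J+x", "unconstrained"),
        ModelVariant("DEC+x", "adjacent_only"),
        ModelVariant("DEC+J+x", "adjacent_only"),
        ModelVariant("DEC+x", "adjacent_except_arc"),
        ModelVariant("DEC+J+x", "adjacent_except_arc"),
    ]
    return tuple(ordered)


def apply_scheme(
    scenario: StratifiedScenario,
    space: StateSpace,
    scheme: str,
    adjacency=None,
    arc_areas=None,
) -> StratifiedScenario:
    """Overlay a constraint scheme on every epoch's dispersal multipliers."""
    constraint = adjacency_constraint(space.areas, scheme, adjacency, arc_areas)
    return StratifiedScenario(tuple(
        ep.with_multiplier(ep.multiplier * constraint) for ep in scenario.epochs
    ))


@dataclass
class PipelineResult:
    comparison: pd.DataFrame
    fits: dict
    best: tuple
    marginals: np.ndarray | None
    parsimony_total_changes: int | None
    outdir: Path


def run_pipeline(
    tree: DatedTree,
    tips: dict,
    space: StateSpace,
    stratified: StratifiedScenario,
    unstratified: StratifiedScenario,
    outdir,
    adjacency=None,
    arc_areas=None,
    variants: tuple = None,
    n: int | None = None,
    optimizer: OptimizerConfig | None = None,
    seed: int | None = None,
    bin_width: float = 2.0,
) -> PipelineResult:
    """Fit every variant under both stratification regimes and write the
    comparison table, best-model ancestral marginals, parsimony node sets,
    dispersal-event counts, lineage-accumulation table, and a structured log.

    Deterministic: outputs depend only on the inputs and configuration.
    A failing stage raises :class:`PipelineStageError`; outputs written by
    earlier stages are retained.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants = variants or standard_variants()
    n = n or tree.n_tips
    optimizer = optimizer or OptimizerConfig()

    fits: dict = {}
    comparisons = {}
    try:
        for analysis, base in (("stratified", stratified),
                               ("unstratified", unstratified)):
            analysis_fits = []
            scheme_cache: dict = {}
            for var in variants:
                if var.scheme not in scheme_cache:
                    scheme_cache[var.scheme] = apply_scheme(
                        base, space, var.scheme, adjacency, arc_areas
                    )
                scen = scheme_cache[var.scheme]
                engine = PruningEngine(tree, tips, scen, space)
                spec = model_spec(var.family)
                spec = type(spec)(var.label, spec.free, spec.fixed)
                fit = fit_model(tree, tips, scen, space, spec,
                                optimizer=optimizer, engine=engine)
                analysis_fits.append(fit)
                fits[(analysis, var.label)] = (fit, scen)
            comparisons[analysis] = comparison_table(analysis_fits, n)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("fit", exc) from exc

    try:
        blocks = []
        for analysis, comp in comparisons.items():
            block = comp.table.copy()
            block.insert(0, "analysis", analysis)
            blocks.append(block)
        comparison = pd.concat(blocks, ignore_index=True)
        comparison.to_csv(outdir / "comparison.tsv", sep="\t", index=False,
                          float_format="%.10g")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("comparison", exc) from exc

    try:
        best_idx = comparison["AICc"].idxmin()
        best = (str(comparison.loc[best_idx, "analysis"]),
                str(comparison.loc[best_idx, "model"]))
        best_fit, best_scen = fits[best]
        engine = PruningEngine(tree, tips, best_scen, space)
        marg = engine.marginals(best_fit.params)
        labels = space.state_labels()[space.nonnull_slice()]
        mdf = pd.DataFrame(marg, columns=labels)
        mdf.insert(0, "node", np.arange(tree.n_tips, tree.n_nodes))
        mdf.insert(1, "age", tree.ages[tree.n_tips:])
        mdf.to_csv(outdir / "ancestral_marginals.tsv", sep="\t", index=False,
                   float_format="%.6g")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("ancestors", exc) from exc

    try:
        tip_area = {}
        for lab, r in tips.items():
            idx = r.area_indices()
            if len(idx) != 1:
                raise DecGeoError(
                    f"parsimony stage needs single-area tips; {lab!r} has {len(idx)}"
                )
            tip_area[lab] = idx[0]
        rec = fitch_parsimony(tree, tip_area)
        states = resolve(rec, "deltran")
        area_names = [a.name for a in space.areas]
        nodes_df = pd.DataFrame({
            "node": np.arange(tree.n_nodes),
            "age": tree.ages,
            "mpr_states": ["|".join(area_names[a] for a in sorted(s))
                           for s in rec.state_sets],
            "deltran_state": [area_names[a] for a in states],
        })
        nodes_df.to_csv(outdir / "parsimony_nodes.tsv", sep="\t", index=False)
        summary = count_dispersal_events(rec, "deltran")
        summary.to_frame(area_names).to_csv(
            outdir / "dispersal_events.tsv", sep="\t", index=False
        )
        ltt = lineage_accumulation(tree, states, bin_width)
        ltt["area"] = [area_names[a] for a in ltt["area"]]
        ltt.to_csv(outdir / "area_ltt.tsv", sep="\t", index=False)
        total_changes = rec.total_changes
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("parsimony", exc) from exc

    log = {
        "seed": seed,
        "n_tips": tree.n_tips,
        "aicc_n": n,
        "n_models": len(comparison),
        "best": {"analysis": best[0], "model": best[1],
                 "params": fits[best][0].estimates(), "lnL": fits[best][0].lnl},
        "optimizer": {"full_grid": optimizer.full_grid,
                      "maxiter": optimizer.maxiter, "ftol": optimizer.ftol},
        "versions": {"decgeo": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__},
        "wall_time_s": round(time.time() - t0, 3),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return PipelineResult(comparison, fits, best, marg, total_changes, outdir)


# ---------------------------------------------------------------------------
# config-file driven runs


@dataclass(frozen=True)
class RunConfig:
    """A full pipeline run described by a structured text config.

    ``epochs`` is a list of dicts (old to young) with keys ``start_age``,
    ``end_age``, ``distance`` (TSV path) and optional ``multiplier`` (TSV
    path) and ``allowed`` (area-name list); the youngest epoch must end at
    the present.  ``variants`` is either the string ``"standard"`` (all 12
    family x constraint combinations) or a list of
    ``{family, scheme}`` dicts.
    """

    tree: Path
    geog: Path
    epochs: tuple
    outdir: Path
    max_range_size: int = 3
    unstratified_distance: Path | None = None
    adjacency: tuple = ()
    arc_areas: tuple = ()
    variants: object = "standard"
    seed: int | None = None
    optimizer: OptimizerConfig = OptimizerConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def resolve(p):
            return (base / p).resolve() if p is not None else None

        epochs = tuple(raw.get("epochs", ()))
        if not epochs:
            raise PipelineStageError(
                "config", ValueError("at least one epoch is required")
            )
        bounds = [float(e["end_age"]) for e in epochs]
        if bounds[-1] != 0 or any(a <= b for a, b in zip(bounds, bounds[1:])):
            raise PipelineStageError(
                "config",
                ValueError("epoch end ages must decrease strictly to 0"),
            )
        epochs = tuple(
            {**e,
             "distance": resolve(e["distance"]),
             "multiplier": resolve(e.get("multiplier"))}
            for e in epochs
        )
        opt = raw.get("optimizer", {})
        cfg = cls(
            tree=resolve(raw["tree"]),
            geog=resolve(raw["geog"]),
            epochs=epochs,
            outdir=(base / raw.get("outdir", "output")).resolve(),
            max_range_size=int(raw.get("max_range_size", 3)),
            unstratified_distance=resolve(raw.get("unstratified_distance")),
            adjacency=tuple(tuple(p) for p in raw.get("adjacency", ())),
            arc_areas=tuple(raw.get("arc_areas", ())),
            variants=raw.get("variants", "standard"),
            seed=raw.get("seed"),
            optimizer=OptimizerConfig(
                full_grid=bool(opt.get("full_grid", False)),
                maxiter=int(opt.get("maxiter", 200)),
            ),
        )
        for f in (cfg.tree, cfg.geog, *(e["distance"] for e in cfg.epochs)):
            if not Path(f).exists():
                raise PipelineStageError(
                    "config", FileNotFoundError(f"missing input file {f}")
                )
        return cfg


def run_from_config(config: RunConfig) -> PipelineResult:
    """Load every input named in a :class:`RunConfig` and run the pipeline."""
    import math

    from .geography import build_state_space, load_epoch_geography, make_areas
    from .io import read_geog, read_newick, read_matrix_tsv

    tree = read_newick(config.tree)
    header = Path(config.geog).read_text().splitlines()[0]
    names = header.split("(", 1)[1].rsplit(")", 1)[0].split()
    space = build_state_space(make_areas(names), config.max_range_size)
    tips = read_geog(config.geog, space)

    epochs = []
    for i, e in enumerate(config.epochs):
        start = float(e.get("start_age", math.inf)) if i else math.inf
        epochs.append(load_epoch_geography(
            e["distance"], e.get("multiplier"), e.get("allowed"),
            interval=(start, float(e["end_age"])), areas=space.areas,
        ))
    stratified = StratifiedScenario(tuple(epochs))

    unstrat_path = config.unstratified_distance or config.epochs[-1]["distance"]
    _, dist = read_matrix_tsv(unstrat_path)
    from .geography import EpochGeography
    import numpy as _np
    unstratified = StratifiedScenario.single(EpochGeography(
        math.inf, 0.0, dist, _np.ones_like(dist),
        _np.ones(len(names), dtype=bool),
    ))

    if config.variants == "standard":
        variants = standard_variants()
    else:
        variants = tuple(ModelVariant(v["family"], v["scheme"])
                         for v in config.variants)
    return run_pipeline(
        tree, tips, space, stratified, unstratified, config.outdir,
        adjacency=config.adjacency or None,
        arc_areas=config.arc_areas or None,
        variants=variants, seed=config.seed, optimizer=config.optimizer,
    )
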