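"""Forward simulation of dated trees and geographic-range histories.

The generator emulates the statistical structure the inference assumes: a
birth–death chronogram with tips at the present; single-area microendemic
tips scattered along a linear island arc whose inter-island distances are a
few hundred km; and epoch-limited availability (young volcanic islands do
not exist in the oldest time slice).  Range histories are drawn by Gillespie
simulation of the anagenetic CTMC along branches (epoch-switched at
boundaries) with cladogenetic outcomes drawn at each node, and the full
event log is kept so that any downstream summary can be checked against the
exact history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dec import CladogenesisBuilder, DecParams, QBuilder
from .errors import DataError, InvalidConfigurationError
from .geography import (EpochGeography, GeographicRange, StateSpace,
                        StratifiedScenario, build_state_space, make_areas)
from .inference import (DecModelSpec, OptimizerConfig, PruningEngine,
                        fit_model)
from .model_selection import aicc
from .trees import DatedTree

#: Nearest-neighbour gaps (km) cycled along the default arc.
DEFAULT_GAPS_KM = (150.0, 250.0, 120.0, 280.0, 200.0, 160.0, 240.0)


def linear_arc_geography(
    n_areas: int,
    gaps_km=None,
    start_age: float = math.inf,
    end_age: float = 0.0,
    unavailable=(),
    rescale: bool = True,
) -> EpochGeography:
    """A linear island arc: distances are cumulative nearest-neighbour gaps.

    With ``rescale=True`` the distance matrix is expressed relative to the
    longest inter-island distance (maximum = 1), the convention under which
    the distance exponent acts on dimensionless ratios; by the rescaling
    invariance d -> d * c**(-x) this is equivalent to raw kilometres with a
    rescaled dispersal rate.
    """
    if gaps_km is None:
        gaps_km = [DEFAULT_GAPS_KM[i % len(DEFAULT_GAPS_KM)]
                   for i in range(n_areas - 1)]
    gaps = np.asarray(gaps_km, dtype=float)
    if gaps.shape != (n_areas - 1,):
        raise InvalidConfigurationError("need n_areas - 1 nearest-neighbour gaps")
    pos = np.concatenate([[0.0], np.cumsum(gaps)])
    dist = np.abs(pos[:, None] - pos[None, :])
    if rescale:
        dist = dist / dist.max()
    allowed = np.ones(n_areas, dtype=bool)
    for a in unavailable:
        allowed[a] = False
    return EpochGeography(start_age, end_age, dist,
                          np.ones((n_areas, n_areas)), allowed)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic island-arc datasets.

    Defaults mimic the empirical setting qualitatively: an 8-island linear
    arc with nearest-neighbour gaps of 100–300 km, the two youngest islands
    unavailable in the oldest epoch, and a moderate founder-event weight with
    distance-limited dispersal.
    """

    seed: int
    n_tips: int = 100
    birth: float = 0.4          # speciations / Myr
    death: float = 0.0
    n_areas: int = 8
    gaps_km: tuple | None = None
    max_range_size: int = 3
    params: DecParams = field(default_factory=lambda: DecParams(0.02, 0.005, 0.2, -1.0))
    epoch_boundary: float | None = 10.0   # Ma; None = unstratified
    unavailable_in_oldest: tuple = (-2, -1)
    rescale_distances: bool = True
    tip_mode: str = "as_is"     # as_is | reject | collapse
    jump_distance_scaling: bool = True
    max_tries: int = 1000

    def area_names(self) -> tuple[str, ...]:
        return tuple(f"A{i + 1}" for i in range(self.n_areas))

    def state_space(self) -> StateSpace:
        return build_state_space(make_areas(self.area_names()),
                                 min(self.max_range_size, self.n_areas),
                                 include_null=True)

    def scenario(self) -> StratifiedScenario:
        if self.epoch_boundary is None:
            return StratifiedScenario.single(
                linear_arc_geography(self.n_areas, self.gaps_km,
                                     rescale=self.rescale_distances)
            )
        unavailable = [i % self.n_areas for i in self.unavailable_in_oldest]
        old = linear_arc_geography(self.n_areas, self.gaps_km,
                                   start_age=math.inf,
                                   end_age=self.epoch_boundary,
                                   unavailable=unavailable,
                                   rescale=self.rescale_distances)
        young = linear_arc_geography(self.n_areas, self.gaps_km,
                                     start_age=self.epoch_boundary, end_age=0.0,
                                     rescale=self.rescale_distances)
        return StratifiedScenario((old, young))


# ---------------------------------------------------------------------------
# birth–death trees


def simulate_tree(
    n_tips: int,
    birth: float,
    death: float = 0.0,
    rng: np.random.Generator | None = None,
    max_tries: int = 1000,
) -> DatedTree:
    """Constant-rate birth–death tree conditioned on its extant tip count.

    Forward simulation from a crown split: waiting times are exponential with
    total rate N(birth + death); the simulation stops when N extant lineages
    are first reached and the tips are extended by one further waiting time
    (so the final speciation does not sit exactly at the present).  Fully
    extinct replicates are discarded and retried.
    """
    if rng is None:
        raise InvalidConfigurationError("an explicit seeded Generator is required")
    if not birth > death >= 0:
        raise InvalidConfigurationError("need birth > death >= 0")
    if n_tips < 2:
        raise InvalidConfigurationError("need at least two tips")
    for _ in range(max_tries):
        # per lineage: (parent_event, start_time); events: (time, lineage)
        parent_event = [-1, -1]
        start = [0.0, 0.0]
        alive: list[int] = [0, 1]
        dead: set[int] = set()
        event_time = [0.0]        # event 0 = crown split at t 0
        event_children: list[list[int]] = [[0, 1]]
        t = 0.0
        while 0 < len(alive) < n_tips:
            total = len(alive) * (birth + death)
            t += rng.exponential(1.0 / total)
            lin = alive[rng.integers(len(alive))]
            if rng.random() < birth / (birth + death):
                ev = len(event_time)
                event_time.append(t)
                event_children.append([])
                alive.remove(lin)
                for _k in range(2):
                    new = len(parent_event)
                    parent_event.append(ev)
                    start.append(t)
                    event_children[ev].append(new)
                    alive.append(new)
                # link the event to the lineage it terminates
                event_children[ev].append(lin)
            else:
                alive.remove(lin)
                dead.add(lin)
        if not alive:
            continue
        t += rng.exponential(1.0 / (len(alive) * (birth + death)))
        try:
            return _assemble_tree(alive, event_time, event_children, t)
        except DataError:
            continue
    raise DataError("all birth–death replicates went extinct; raise the budget")


def _assemble_tree(alive, event_time, event_children, present) -> DatedTree:
    # Prune extinct lineages from the event graph, suppress single-child
    # events, and emit the survivors as a DatedTree (children before parents).
    alive_set = set(alive)
    event_of_lineage: dict[int, int] = {}
    for ev in range(1, len(event_time)):
        *_children, terminated = event_children[ev]
        event_of_lineage[terminated] = ev

    def collect(lineage):
        if lineage in event_of_lineage:
            ev = event_of_lineage[lineage]
            sub = [collect(c) for c in event_children[ev][:2]]
            sub = [s for s in sub if s is not None]
            if not sub:
                return None
            if len(sub) == 1:
                return sub[0]
            return ("node", event_time[ev], sub)
        return ("tip",) if lineage in alive_set else None

    roots = [collect(c) for c in event_children[0][:2]]
    roots = [r for r in roots if r is not None]
    tree = ("node", 0.0, roots) if len(roots) == 2 else roots[0]
    if tree[0] == "tip":
        raise DataError("degenerate single-tip survivor")

    def count_tips(node):
        return 1 if node[0] == "tip" else sum(count_tips(c) for c in node[2])

    n_tips = count_tips(tree)
    labels: list[str] = []
    rows: list[tuple[int, int]] = []
    ages_internal: list[float] = []

    def build(node):
        if node[0] == "tip":
            labels.append(f"t{len(labels) + 1}")
            return len(labels) - 1
        a = build(node[2][0])
        b = build(node[2][1])
        rows.append((a, b))
        ages_internal.append(present - node[1])
        return n_tips + len(rows) - 1

    build(tree)
    ages = [0.0] * n_tips + ages_internal
    return DatedTree(tuple(labels), np.array(rows, dtype=np.intp),
                     np.array(ages))


# ---------------------------------------------------------------------------
# range histories


@dataclass(frozen=True)
class RangeEvent:
    """One event of the simulated history.

    ``node`` is the id of the branch's child end; cladogenetic events are
    recorded once per daughter branch at the age of the parent node.
    """

    age: float
    node: int
    from_bits: int
    to_bits: int
    kind: str  # expansion | contraction | extinction | sympatry | subset | vicariance | jump


@dataclass(frozen=True)
class SimulatedHistory:
    tree: DatedTree
    space: StateSpace
    root_bits: int
    tip_bits: dict
    events: tuple

    def tip_ranges(self) -> dict:
        n = self.space.n_areas
        return {lab: GeographicRange(bits, n) for lab, bits in self.tip_bits.items()}

    def _branch_events(self):
        by_node: dict[int, list[RangeEvent]] = {}
        for ev in self.events:
            by_node.setdefault(ev.node, []).append(ev)
        for evs in by_node.values():
            evs.sort(key=lambda e: -e.age)
        return by_node

    def state_at(self, node: int, age: float) -> int:
        """Range bits of the lineage subtending ``node`` at ``age``."""
        by_node = self._branch_events()
        bits = self.root_bits
        for ev in by_node.get(node, []):
            if ev.age >= age:
                bits = ev.to_bits
        return bits

    def replay(self) -> dict:
        """Re-derive tip ranges from the event log alone (chain-checked)."""
        by_node = self._branch_events()
        tree = self.tree
        state = {tree.root: self.root_bits}
        for node in reversed(range(tree.n_nodes - 1)):
            p = int(tree.parent[node])
            bits = state[p]
            for ev in by_node.get(node, []):
                if ev.from_bits != bits:
                    raise AssertionError("event log chain broken")
                bits = ev.to_bits
            state[node] = bits
        return {tree.labels[i]: state[i] for i in range(tree.n_tips)}


def _clado_kind(parent_bits: int, l_bits: int, r_bits: int) -> str:
    if l_bits == r_bits == parent_bits:
        return "sympatry"
    if (l_bits | r_bits) == parent_bits and (l_bits & r_bits) == 0:
        return "vicariance"
    if (l_bits | r_bits) == parent_bits:
        return "subset"
    return "jump"


def simulate_ranges(
    tree: DatedTree,
    scenario: StratifiedScenario,
    space: StateSpace,
    params: DecParams,
    rng: np.random.Generator,
    root_bits: int | None = None,
    tip_mode: str = "as_is",
    jump_distance_scaling: bool = True,
    max_tries: int = 1000,
) -> SimulatedHistory:
    """Gillespie simulation of the range CTMC over a dated tree.

    A lineage contracting out of its last area goes extinct (null range);
    since the tree is conditioned on its extant tips, such replicates are
    redrawn.  ``tip_mode='reject'`` additionally redraws histories with any
    widespread tip (microendemic datasets); ``'collapse'`` instead contracts
    each widespread tip to one of its areas, chosen uniformly.
    """
    if tip_mode not in ("as_is", "reject", "collapse"):
        raise InvalidConfigurationError(f"unknown tip_mode {tip_mode!r}")
    Qs = [QBuilder(space, ep).build(params) for ep in scenario.epochs]
    tables = [CladogenesisBuilder(space, ep, jump_distance_scaling).build(params)
              for ep in scenario.epochs]
    table_rows = []
    for tbl in tables:
        rows = {}
        for k in range(len(tbl.parent)):
            rows.setdefault(int(tbl.parent[k]), []).append(k)
        table_rows.append(rows)
    root_age = tree.single_root_age if tree.n_tips == 1 else tree.root_age
    oldest = scenario.epoch_index_at(min(root_age, scenario.oldest_age))
    allowed_root = [
        i for i, s in enumerate(space.states)
        if s.size == 1 and scenario.state_mask(space, oldest)[i]
    ]

    for _ in range(max_tries):
        if root_bits is None:
            start_idx = allowed_root[rng.integers(len(allowed_root))]
            start_bits = space.states[start_idx].bits
        else:
            start_bits = root_bits
        events: list[RangeEvent] = []
        state: dict[int, int] = {}
        failed = False

        def evolve_branch(node: int, bits: int, top_age: float, bot_age: float) -> int:
            age = top_age
            while True:
                ep = _epoch_below(scenario, age)
                floor = max(scenario.epochs[ep].end_age, bot_age)
                i = space.index(bits)
                rate = -Qs[ep][i, i]
                if rate <= 0:
                    age = floor
                else:
                    age -= rng.exponential(1.0 / rate)
                    if age <= floor:
                        age = floor
                    else:
                        row = Qs[ep][i].copy()
                        row[i] = 0.0
                        j = rng.choice(len(row), p=row / row.sum())
                        to_bits = space.states[j].bits
                        kind = ("expansion"
                                if space.states[j].size > space.states[i].size
                                else ("extinction" if to_bits == 0 else "contraction"))
                        events.append(RangeEvent(age, node, bits, to_bits, kind))
                        bits = to_bits
                        if bits == 0:
                            return 0
                        continue
                if age <= bot_age:
                    return bits
                # crossed an epoch boundary: continue in the next epoch

        def recurse(node: int, bits: int, top_age: float) -> bool:
            bits = evolve_branch(node, bits, top_age, float(tree.ages[node]))
            if bits == 0:
                return False
            state[node] = bits
            if tree.is_tip(node):
                return True
            ep = _epoch_below(scenario, float(tree.ages[node])) \
                if tree.ages[node] > 0 else len(scenario.epochs) - 1
            tbl, rows = tables[ep], table_rows[ep]
            ks = rows[space.index(bits)]
            probs = tbl.prob[ks]
            k = ks[rng.choice(len(ks), p=probs / probs.sum())]
            l_bits = space.states[tbl.left[k]].bits
            r_bits = space.states[tbl.right[k]].bits
            kind = _clado_kind(bits, l_bits, r_bits)
            c1, c2 = tree.children[node - tree.n_tips]
            age = float(tree.ages[node])
            events.append(RangeEvent(age, int(c1), bits, l_bits, kind))
            events.append(RangeEvent(age, int(c2), bits, r_bits, kind))
            return recurse(int(c1), l_bits, age) and recurse(int(c2), r_bits, age)

        root = tree.root
        state[root] = start_bits
        if tree.n_tips == 1:
            bits = evolve_branch(0, start_bits, root_age, 0.0)
            ok = bits != 0
            if ok:
                state[0] = bits
        else:
            c1, c2 = tree.children[root - tree.n_tips]
            ep = _epoch_below(scenario, root_age) if root_age > 0 \
                else len(scenario.epochs) - 1
            tbl, rows = tables[ep], table_rows[ep]
            ks = rows[space.index(start_bits)]
            probs = tbl.prob[ks]
            k = ks[rng.choice(len(ks), p=probs / probs.sum())]
            l_bits = space.states[tbl.left[k]].bits
            r_bits = space.states[tbl.right[k]].bits
            kind = _clado_kind(start_bits, l_bits, r_bits)
            events.append(RangeEvent(root_age, int(c1), start_bits, l_bits, kind))
            events.append(RangeEvent(root_age, int(c2), start_bits, r_bits, kind))
            ok = recurse(int(c1), l_bits, root_age) and recurse(int(c2), r_bits, root_age)
        if not ok:
            continue
        tip_bits = {tree.labels[i]: state[i] for i in range(tree.n_tips)}
        if tip_mode == "reject" and any(
            space.states[space.index(b)].size > 1 for b in tip_bits.values()
        ):
            continue
        if tip_mode == "collapse":
            for i in range(tree.n_tips):
                lab = tree.labels[i]
                r = GeographicRange(tip_bits[lab], space.n_areas)
                if r.size > 1:
                    keep = r.area_indices()[rng.integers(r.size)]
                    events.append(RangeEvent(0.0, i, r.bits, 1 << keep, "contraction"))
                    tip_bits[lab] = 1 << keep
        return SimulatedHistory(tree, space, start_bits, tip_bits, tuple(events))
    raise DataError("range simulation exhausted its retry budget")


def _epoch_below(scenario: StratifiedScenario, age: float) -> int:
    """Epoch governing the open interval immediately below ``age``."""
    if age <= 0:
        return len(scenario.epochs) - 1
    for i in range(len(scenario.epochs) - 1, -1, -1):
        ep = scenario.epochs[i]
        if ep.end_age < age <= ep.start_age:
            return i
    raise InvalidConfigurationError(f"age {age} outside scenario")


def simulate_dataset(config: SimulationConfig):
    """Tree + ranges + geography drawn under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    scenario = config.scenario()
    space = config.state_space()
    for _ in range(config.max_tries):
        tree = simulate_tree(config.n_tips, config.birth, config.death, rng)
        try:
            hist = simulate_ranges(
                tree, scenario, space, config.params, rng,
                tip_mode=config.tip_mode,
                jump_distance_scaling=config.jump_distance_scaling,
                max_tries=config.max_tries,
            )
        except DataError:
            continue
        return tree, hist, scenario, space
    raise DataError("dataset simulation exhausted its retry budget")


# ---------------------------------------------------------------------------
# parameter-recovery harness


@dataclass(frozen=True)
class RecoveryReport:
    replicates: pd.DataFrame
    summary: dict


def recovery_experiment(
    config: SimulationConfig,
    model_specs: list[DecModelSpec],
    n_replicates: int,
    optimizer: OptimizerConfig | None = None,
) -> RecoveryReport:
    """Simulate, refit, and tabulate estimator behaviour.

    For each replicate every candidate model is fitted and scored by AICc
    (n = tip count); the summary reports per-parameter bias, RMSE and median
    relative error for the true generating model's free parameters, plus
    AICc selection frequencies.  Deterministic given ``config.seed``.
    """
    if n_replicates < 1:
        raise InvalidConfigurationError("need at least one replicate")
    seeds = np.random.SeedSequence(config.seed).spawn(n_replicates)
    truth = config.params
    rows = []
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        scenario = config.scenario()
        space = config.state_space()
        tree = hist = None
        for _ in range(config.max_tries):
            tree = simulate_tree(config.n_tips, config.birth, config.death, rng)
            try:
                hist = simulate_ranges(tree, scenario, space, truth, rng,
                                       tip_mode=config.tip_mode,
                                       jump_distance_scaling=config.jump_distance_scaling)
                break
            except DataError:
                hist = None
        if hist is None:
            raise DataError(f"replicate {rep} failed to simulate")
        tips = hist.tip_ranges()
        engine = PruningEngine(tree, tips, scenario, space,
                               config.jump_distance_scaling)
        fits = [fit_model(tree, tips, scenario, space, spec,
                          optimizer=optimizer, engine=engine)
                for spec in model_specs]
        aiccs = [aicc(f.lnl, f.k, tree.n_tips) for f in fits]
        best = int(np.argmin(aiccs))
        for m, (f, a) in enumerate(zip(fits, aiccs)):
            rows.append({"replicate": rep, "model": f.model, "k": f.k,
                         "lnL": f.lnl, "AICc": a, "selected": m == best,
                         **{p: v for p, v in f.estimates().items()}})
    table = pd.DataFrame(rows)
    truth_vals = {"d": truth.d, "e": truth.e, "j": truth.j, "x": truth.x}
    richest = max(model_specs, key=lambda s: s.k)
    sel = table[table["model"] == richest.name]
    summary: dict = {"n_replicates": n_replicates,
                     "selection_freq": table[table["selected"]]["model"]
                     .value_counts(normalize=True).to_dict()}
    summary["plus_j_selected_frac"] = float(
        table[table["selected"]]["model"].str.contains(r"\+J").mean()
    )
    for p in richest.free:
        est = sel[p].to_numpy(dtype=float)
        tv = truth_vals[p]
        summary[p] = {
            "truth": tv,
            "bias": float(np.mean(est - tv)),
            "rmse": float(np.sqrt(np.mean((est - tv) ** 2))),
        }
        if tv != 0:
            summary[p]["median_rel_err"] = float(
                np.median(np.abs(est - tv) / abs(tv))
            )
    return RecoveryReport(table, summary)
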