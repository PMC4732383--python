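"""Likelihood, maximum-likelihood fitting, and ancestral-range marginals.

The likelihood is computed by Felsenstein pruning over the dated tree: tip
conditional vectors are indicators of the observed range, daughter vectors
are carried up their branches through (epoch-stratified) transition kernels,
and combined at each node through the cladogenesis table of the epoch the
node falls in.  The root likelihood averages over all range states valid at
the root age (a uniform root prior); a likelihood-weighted alternative is
available.

Per-node marginal probabilities ("pie charts") come from the standard
up–down algorithm and refer to the state AT the node, i.e. immediately
before its cladogenesis event.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .dec import (CladogenesisBuilder, DecParams, EpochPropagator, QBuilder,
                  segments)
from .errors import DataError, InvalidConfigurationError
from .geography import GeographicRange, StateSpace, StratifiedScenario
from .trees import DatedTree

_LOG_SCALE_FLOOR = 1e-300


@dataclass(frozen=True)
class DecModelSpec:
    """Which DEC-family parameters are free and what the fixed ones equal."""

    name: str
    free: tuple[str, ...]
    fixed: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.free)

    def params(self, values: dict) -> DecParams:
        merged = {"j": 0.0, "x": 0.0}
        merged.update(self.fixed)
        merged.update(values)
        return DecParams(**merged)


def model_spec(name: str) -> DecModelSpec:
    """Named member of the model family: DEC, DEC+J, DEC+x, DEC+J+x."""
    key = name.replace(" ", "").upper()
    table = {
        "DEC": ("d", "e"),
        "DEC+J": ("d", "e", "j"),
        "DEC+X": ("d", "e", "x"),
        "DEC+J+X": ("d", "e", "j", "x"),
    }
    if key not in table:
        raise InvalidConfigurationError(
            f"unknown model {name!r}; expected one of {sorted(table)}"
        )
    return DecModelSpec(name, table[key])


class PruningEngine:
    """Caches the tree/scenario structure so repeated likelihood evaluations
    (as in ML search) only rebuild the parameter-dependent pieces."""

    def __init__(
        self,
        tree: DatedTree,
        tips: dict,
        scenario: StratifiedScenario,
        space: StateSpace,
        jump_distance_scaling: bool = True,
        root_prior: str = "uniform",
    ):
        if root_prior not in ("uniform", "likelihood_weighted"):
            raise InvalidConfigurationError(f"unknown root prior {root_prior!r}")
        self.tree = tree
        self.space = space
        self.scenario = scenario
        self.root_prior = root_prior
        root_age = tree.single_root_age if tree.n_tips == 1 else tree.root_age
        if root_age > scenario.oldest_age:
            raise InvalidConfigurationError(
                f"root age {root_age} Ma exceeds scenario coverage"
            )
        self.root_age = root_age
        # tip states
        self.tip_state = np.empty(tree.n_tips, dtype=np.intp)
        present = scenario.state_mask(space, scenario.epoch_index_at(0.0))
        for i, lab in enumerate(tree.labels):
            if lab not in tips:
                raise DataError(f"tip {lab!r} absent from the range table")
            r = tips[lab]
            bits = r.bits if isinstance(r, GeographicRange) else int(r)
            if bits not in space.index_of:
                raise DataError(f"tip {lab!r} range is not in the state space")
            idx = space.index(bits)
            if bits == 0:
                raise DataError(f"tip {lab!r} has an empty range")
            if not present[idx]:
                raise DataError(
                    f"tip {lab!r} occupies an area unavailable at the present"
                )
            self.tip_state[i] = idx
        extra = set(tips) - set(tree.labels)
        if extra:
            raise DataError(f"range table rows with no matching tip: {sorted(extra)}")
        # per-branch epoch segments (old->young) and per-node epoch index
        parent = tree.parent
        self.branch_segs: list[list[tuple[int, float]]] = []
        for node in range(tree.n_nodes):
            p = parent[node]
            if p < 0:
                self.branch_segs.append([])
            else:
                self.branch_segs.append(
                    segments(scenario, float(tree.ages[p]), float(tree.ages[node]))
                )
        self.node_epoch = np.array(
            [scenario.epoch_index_at(min(float(a), scenario.oldest_age))
             for a in tree.ages], dtype=np.intp
        )
        self.root_mask = scenario.state_mask(
            space, scenario.epoch_index_at(self.root_age)
        ).copy()
        if space.include_null:
            self.root_mask[space.null_index] = False
        self._qb = [QBuilder(space, ep) for ep in scenario.epochs]
        self._cb = [CladogenesisBuilder(space, ep, jump_distance_scaling)
                    for ep in scenario.epochs]
        self._masks = [scenario.state_mask(space, i)
                       for i in range(len(scenario.epochs))]
        self.n_eval = 0

    # ------------------------------------------------------------------
    def _propagators(self, params: DecParams) -> list[EpochPropagator]:
        return [EpochPropagator(qb.build(params), m)
                for qb, m in zip(self._qb, self._masks)]

    def _lift(self, props, node: int, v: np.ndarray) -> np.ndarray:
        """Carry a conditional vector from a node to the bottom of its parent."""
        for epoch_idx, dt in reversed(self.branch_segs[node]):
            v = props[epoch_idx].apply(v, dt)
        return v

    def _prune(self, params: DecParams):
        tree, space = self.tree, self.space
        props = self._propagators(params)
        tables = [cb.build(params) for cb in self._cb]
        S = space.n_states
        below = np.zeros((tree.n_nodes, S))
        lifted = np.zeros((tree.n_nodes, S))
        log_scale = 0.0
        for i in range(tree.n_tips):
            below[i, self.tip_state[i]] = 1.0
        for node in tree.internal_nodes():
            c1, c2 = tree.children[node - tree.n_tips]
            u1 = self._lift(props, c1, below[c1])
            u2 = self._lift(props, c2, below[c2])
            lifted[c1], lifted[c2] = u1, u2
            tbl = tables[self.node_epoch[node]]
            comb = np.zeros(S)
            np.add.at(comb, tbl.parent, tbl.prob * u1[tbl.left] * u2[tbl.right])
            scale = comb.max()
            if scale <= _LOG_SCALE_FLOOR:
                return below, lifted, props, tables, -math.inf
            below[node] = comb / scale
            log_scale += math.log(scale)
        if tree.n_tips == 1:
            # degenerate one-tip tree: carry the indicator to the root age
            segs = segments(self.scenario, self.root_age, 0.0)
            v = below[0]
            for epoch_idx, dt in reversed(segs):
                v = props[epoch_idx].apply(v, dt)
            below = below.copy()
            below[0] = v
        return below, lifted, props, tables, log_scale

    def lnl(self, params: DecParams) -> float:
        self.n_eval += 1
        below, _, _, _, log_scale = self._prune(params)
        if log_scale == -math.inf:
            return -math.inf
        root_l = below[self.tree.root][self.root_mask]
        if self.root_prior == "uniform":
            total = root_l.mean()
        else:  # likelihood_weighted: weights proportional to the likelihoods
            s = root_l.sum()
            total = (root_l ** 2).sum() / s if s > 0 else 0.0
        if total <= 0:
            return -math.inf
        return math.log(total) + log_scale

    # ------------------------------------------------------------------
    def marginals(self, params: DecParams) -> np.ndarray:
        """Per-internal-node marginal over non-null states (rows sum to 1)."""
        tree, space = self.tree, self.space
        below, lifted, props, tables, log_scale = self._prune(params)
        if log_scale == -math.inf:
            raise DataError("data have zero likelihood under these parameters")
        S = space.n_states
        outside = np.zeros((tree.n_nodes, S))
        prior = np.zeros(S)
        prior[self.root_mask] = 1.0 / self.root_mask.sum()
        outside[tree.root] = prior
        for node in reversed(tree.internal_nodes()):
            c1, c2 = tree.children[node - tree.n_tips]
            tbl = tables[self.node_epoch[node]]
            op = outside[node]
            w = op[tbl.parent] * tbl.prob
            for child, sib_lift, side in (
                (c1, lifted[c2], tbl.left),
                (c2, lifted[c1], tbl.right),
            ):
                sib = tbl.right if side is tbl.left else tbl.left
                post = np.zeros(S)
                np.add.at(post, side, w * sib_lift[sib])
                for epoch_idx, dt in self.branch_segs[child]:
                    post = props[epoch_idx].apply_transpose(post, dt)
                top = post.max()
                if top > 0:
                    post /= top
                outside[child] = post
        sl = space.nonnull_slice()
        n_internal = tree.n_nodes - tree.n_tips
        out = np.zeros((max(n_internal, 1), space.n_nonnull))
        if n_internal == 0:  # single-tip tree: root marginal is the tip state
            v = below[0] * np.where(self.root_mask, 1.0, 0.0)
            out[0] = (v / v.sum())[sl]
            return out
        for node in tree.internal_nodes():
            v = below[node] * outside[node]
            total = v.sum()
            if total <= 0:
                raise DataError(f"zero marginal mass at node {node}")
            out[node - tree.n_tips] = (v / total)[sl]
        return out


def tree_likelihood(
    tree: DatedTree,
    tips: dict,
    scenario: StratifiedScenario,
    space: StateSpace,
    params: DecParams,
    jump_distance_scaling: bool = True,
    root_prior: str = "uniform",
) -> float:
    """Natural-log likelihood of the tip ranges under the DEC-family model."""
    eng = PruningEngine(tree, tips, scenario, space,
                        jump_distance_scaling, root_prior)
    return eng.lnl(params)


def ancestral_marginals(
    tree: DatedTree,
    tips: dict,
    scenario: StratifiedScenario,
    space: StateSpace,
    params: DecParams,
    jump_distance_scaling: bool = True,
) -> np.ndarray:
    """Marginal ancestral-range probabilities per internal node.

    Row ``i`` corresponds to internal node ``n_tips + i`` (the root is the
    last row); columns follow the non-null state ordering of ``space``.
    """
    eng = PruningEngine(tree, tips, scenario, space, jump_distance_scaling)
    return eng.marginals(params)


def apply_node_overrides(
    marginals: np.ndarray,
    tree: DatedTree,
    space: StateSpace,
    overrides: dict,
) -> np.ndarray:
    """Pin chosen internal nodes to a fixed range.

    ``overrides`` maps internal node id -> range (a GeographicRange, bit
    pattern, or iterable of area names).  The returned copy of the marginal
    table has those rows replaced by indicator vectors.  No plausibility
    heuristic is applied; which nodes to pin is the analyst's call.
    """
    out = np.array(marginals, copy=True)
    offset = 1 if space.include_null else 0
    for node, r in overrides.items():
        if not tree.n_tips <= node < tree.n_nodes:
            raise InvalidConfigurationError(f"node {node} is not internal")
        if isinstance(r, GeographicRange):
            bits = r.bits
        elif isinstance(r, int):
            bits = r
        else:
            bits = space.range_from_names(r).bits
        row = np.zeros(out.shape[1])
        row[space.index(bits) - offset] = 1.0
        out[node - tree.n_tips] = row
    return out


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


@dataclass(frozen=True)
class FitResult:
    model: str
    params: DecParams
    k: int
    lnl: float
    converged: bool
    n_eval: int

    def estimates(self) -> dict:
        return {"d": self.params.d, "e": self.params.e,
                "j": self.params.j, "x": self.params.x}


#: Search bounds per parameter (d, e, j are optimized on a log scale).
BOUNDS = {"d": (1e-12, 5.0), "e": (1e-12, 5.0), "j": (1e-6, 3.0), "x": (-10.0, 2.0)}
_LOG_SCALE_PARAMS = ("d", "e", "j")

_DE_STARTS = [(0.01, 0.01), (0.1, 0.01), (0.01, 0.1)]
_J_STARTS = [0.01, 0.5]
_X_STARTS = [0.0, -1.0]


@dataclass(frozen=True)
class OptimizerConfig:
    """Deterministic multi-start bounded quasi-Newton search settings.

    ``full_grid`` starts from the complete product of the d/e, j and x start
    values (up to 12 starts for DEC+J+x); the default start set covers every
    grid value at least once in 3–4 starts, which is ample for the unimodal
    surfaces these data produce and much cheaper.
    """

    full_grid: bool = False
    maxiter: int = 200
    ftol: float = 1e-9

    def starts(self, spec: DecModelSpec) -> list[dict]:
        if self.full_grid:
            prod = itertools.product(
                _DE_STARTS,
                _J_STARTS if "j" in spec.free else [None],
                _X_STARTS if "x" in spec.free else [None],
            )
            combos = [
                {"d": de[0], "e": de[1], **({"j": j} if j is not None else {}),
                 **({"x": x} if x is not None else {})}
                for de, j, x in prod
            ]
        else:
            picks = [
                ((0.01, 0.01), 0.01, 0.0),
                ((0.1, 0.01), 0.5, -1.0),
                ((0.01, 0.1), 0.5, 0.0),
                ((0.01, 0.01), 0.01, -1.0),
            ]
            combos = []
            for de, j, x in picks:
                c = {"d": de[0], "e": de[1]}
                if "j" in spec.free:
                    c["j"] = j
                if "x" in spec.free:
                    c["x"] = x
                if c not in combos:
                    combos.append(c)
        return combos


def fit_model(
    tree: DatedTree,
    tips: dict,
    scenario: StratifiedScenario,
    space: StateSpace,
    spec: DecModelSpec,
    optimizer: OptimizerConfig | None = None,
    jump_distance_scaling: bool = True,
    root_prior: str = "uniform",
    engine: PruningEngine | None = None,
) -> FitResult:
    """Maximize the pruning likelihood over the model's free parameters.

    Runs a bounded L-BFGS-B search from several deterministic starting
    points and keeps the best; a failure to converge is flagged on the
    result, not raised.
    """
    optimizer = optimizer or OptimizerConfig()
    eng = engine or PruningEngine(tree, tips, scenario, space,
                                  jump_distance_scaling, root_prior)
    free = spec.free

    def to_internal(values: dict) -> np.ndarray:
        out = []
        for p in free:
            v = values[p]
            out.append(math.log(v) if p in _LOG_SCALE_PARAMS else v)
        return np.array(out)

    def from_internal(z: np.ndarray) -> dict:
        return {
            p: (math.exp(z[i]) if p in _LOG_SCALE_PARAMS else float(z[i]))
            for i, p in enumerate(free)
        }

    bounds = [
        tuple(math.log(b) for b in BOUNDS[p]) if p in _LOG_SCALE_PARAMS
        else BOUNDS[p]
        for p in free
    ]

    def objective(z: np.ndarray) -> float:
        lnl = eng.lnl(spec.params(from_internal(z)))
        return 1e12 if not np.isfinite(lnl) else -lnl

    best = None
    any_success = False
    n0 = eng.n_eval
    for start in optimizer.starts(spec):
        res = scipy.optimize.minimize(
            objective,
            to_internal(start),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": optimizer.maxiter, "ftol": optimizer.ftol},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = spec.params(from_internal(best.x))
    return FitResult(spec.name, params, spec.k, -float(best.fun),
                     any_success, eng.n_eval - n0)
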