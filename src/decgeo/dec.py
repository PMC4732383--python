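"""Dispersal–Extinction–Cladogenesis rate matrices and transition kernels.

Anagenesis: a range expands into area ``b`` at rate
``sum_{a in R} d * multiplier[a, b] * distance[a, b] ** x`` and loses any of
its areas at rate ``e`` per area (a singleton contracts to the absorbing null
range).  The distance exponent ``x`` (the "+x" extension) is 0 by default,
which makes all distance matrices irrelevant.

Cladogenesis: classic DEC events — sympatric copying for singletons, subset
sympatry and narrow vicariance for widespread ranges — each with fixed weight
1, plus founder-event "jump" dispersal to an outside singleton with weight
``j`` scaled by the same multiplier/distance modifier (the "+J" extension).
Per-parent weights are normalized to probabilities, and every unordered
daughter outcome is split equally between the two ordered daughter
assignments.

Because maximum-likelihood search rebuilds these objects thousands of times,
the combinatorial structure (which transitions exist) is enumerated once by
:class:`QBuilder` / :class:`CladogenesisBuilder` and only the
parameter-dependent weights are recomputed per evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import InvalidConfigurationError
from .geography import EpochGeography, StateSpace, StratifiedScenario


@dataclass(frozen=True)
class DecParams:
    """Free parameters of the DEC family.

    d : per-area range-expansion (dispersal) rate, events/Myr
    e : per-area range-contraction (local extinction) rate, events/Myr
    j : founder-event weight at cladogenesis (dimensionless; 0 disables +J)
    x : distance exponent (dimensionless; 0 disables +x, expected <= 0)
    """

    d: float
    e: float
    j: float = 0.0
    x: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0 or self.j < 0:
            raise InvalidConfigurationError("rates d, e and weight j must be >= 0")

    def replace(self, **kwargs) -> "DecParams":
        cur = {"d": self.d, "e": self.e, "j": self.j, "x": self.x}
        cur.update(kwargs)
        return DecParams(**cur)


def _modifier(x: float, multiplier: np.ndarray, distance: np.ndarray,
              allowed: np.ndarray) -> np.ndarray:
    """multiplier[a,b] * distance[a,b]**x with disallowed targets zeroed."""
    mod = np.array(multiplier, dtype=float, copy=True)
    if x != 0.0:
        dist = np.array(distance, dtype=float, copy=True)
        np.fill_diagonal(dist, 1.0)  # diagonal never used; avoid 0**negative
        mod = mod * dist ** x
    mod[:, ~allowed] = 0.0
    np.fill_diagonal(mod, 0.0)
    return mod


def _distance_modifier(x: float, geo: EpochGeography) -> np.ndarray:
    return _modifier(x, geo.multiplier, geo.distance_km, geo.allowed)


def _relative_distance(distance: np.ndarray) -> np.ndarray:
    """Distances divided by the mean off-diagonal distance (dimensionless).

    Cladogenetic jump weights compete with the fixed unit weights of
    sympatry/vicariance, so their distance modifier must be dimensionless;
    using relative distances keeps the likelihood invariant under rescaling
    the distance matrix with d -> d * c**(-x).
    """
    d = np.asarray(distance, dtype=float)
    off = ~np.eye(d.shape[0], dtype=bool)
    mean = d[off].mean() if off.any() else 1.0
    return d / mean if mean > 0 else d


def dispersal_rate(
    from_area: int, to_area: int, params: DecParams, geo: EpochGeography
) -> float:
    """Per-source-area rate of expansion from ``from_area`` into ``to_area``."""
    if from_area == to_area:
        raise InvalidConfigurationError("dispersal requires distinct areas")
    if not geo.allowed[to_area]:
        return 0.0
    rate = params.d * geo.multiplier[from_area, to_area]
    if params.x != 0.0:
        rate *= float(geo.distance_km[from_area, to_area]) ** params.x
    return float(rate)


class QBuilder:
    """Enumerates the anagenetic transition structure of one epoch once.

    Expansion transitions exist between ranges differing by one added allowed
    area (respecting the maximum range size); contraction transitions drop one
    area, with singletons contracting to the null range.  ``build`` fills in
    the rates for a given parameter set.
    """

    def __init__(self, space: StateSpace, geo: EpochGeography):
        if not space.include_null:
            raise InvalidConfigurationError(
                "the anagenetic matrix requires a state space with the null range"
            )
        self.space = space
        self.geo = geo
        rows, cols, pair_id, pair_a, pair_b = [], [], [], [], []
        con_rows, con_cols = [], []
        for i, state in enumerate(space.states):
            if state.is_null:
                continue
            members = state.area_indices()
            if state.size < space.max_range_size:
                for b in range(space.n_areas):
                    if state.contains(b) or not geo.allowed[b]:
                        continue
                    tid = len(rows)
                    rows.append(i)
                    cols.append(space.index(state.bits | 1 << b))
                    for a in members:
                        pair_id.append(tid)
                        pair_a.append(a)
                        pair_b.append(b)
            for a in members:
                con_rows.append(i)
                con_cols.append(space.index(state.bits & ~(1 << a)))
        self._rows = np.asarray(rows, dtype=np.intp)
        self._cols = np.asarray(cols, dtype=np.intp)
        self._pair_id = np.asarray(pair_id, dtype=np.intp)
        self._pair_a = np.asarray(pair_a, dtype=np.intp)
        self._pair_b = np.asarray(pair_b, dtype=np.intp)
        self._con = (np.asarray(con_rows, dtype=np.intp), np.asarray(con_cols, dtype=np.intp))

    def build(self, params: DecParams) -> np.ndarray:
        S = self.space.n_states
        Q = np.zeros((S, S))
        if len(self._rows):
            mod = _distance_modifier(params.x, self.geo)
            rates = np.zeros(len(self._rows))
            np.add.at(rates, self._pair_id, mod[self._pair_a, self._pair_b])
            np.add.at(Q, (self._rows, self._cols), params.d * rates)
        if params.e > 0:
            np.add.at(Q, self._con, params.e)
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q


def build_Q(space: StateSpace, params: DecParams, geo: EpochGeography) -> np.ndarray:
    """Dense anagenetic rate matrix over the full state space (null included)."""
    return QBuilder(space, geo).build(params)


@dataclass(frozen=True)
class CladogenesisTable:
    """Sparse per-parent table of cladogenetic outcomes.

    Parallel arrays of (parent, left daughter, right daughter, probability)
    state indices; probabilities sum to one within each parent.  Unordered
    outcomes appear as two ordered entries with half weight each.
    """

    parent: np.ndarray
    left: np.ndarray
    right: np.ndarray
    prob: np.ndarray
    n_states: int

    def outcomes_for(self, parent_index: int):
        sel = self.parent == parent_index
        return list(zip(self.left[sel], self.right[sel], self.prob[sel]))


class CladogenesisBuilder:
    """Enumerates cladogenetic outcome structure for one epoch once.

    Jump weights from a widespread parent use the mean over its areas of the
    per-source modifier, which reduces to ``multiplier * rel_dist**x`` for
    singleton parents; jump modifiers use relative (mean-normalized)
    distances because they compete with the dimensionless unit weights of
    the other cladogenetic events.
    """

    def __init__(self, space: StateSpace, geo: EpochGeography,
                 jump_distance_scaling: bool = True):
        self.space = space
        self.geo = geo
        self.jump_distance_scaling = jump_distance_scaling
        parent, left, right, factor, jump_id = [], [], [], [], []
        pair_event, pair_a, pair_b, inv_size = [], [], [], []

        def add(p: int, l_bits: int, r_bits: int, jid: int) -> None:
            li, ri = space.index(l_bits), space.index(r_bits)
            if li == ri:
                parent.append(p); left.append(li); right.append(ri)
                factor.append(1.0); jump_id.append(jid)
            else:
                for a, b in ((li, ri), (ri, li)):
                    parent.append(p); left.append(a); right.append(b)
                    factor.append(0.5); jump_id.append(jid)

        for i, state in enumerate(space.states):
            if state.is_null:
                continue
            members = state.area_indices()
            if state.size == 1:
                add(i, state.bits, state.bits, -1)  # sympatric copy
            else:
                for a in members:
                    abit = 1 << a
                    add(i, abit, state.bits, -1)          # subset sympatry
                    add(i, abit, state.bits & ~abit, -1)  # narrow vicariance
            for b in range(space.n_areas):
                if state.contains(b) or not geo.allowed[b]:
                    continue
                jid = len(inv_size)
                inv_size.append(1.0 / state.size)
                for a in members:
                    pair_event.append(jid); pair_a.append(a); pair_b.append(b)
                add(i, 1 << b, state.bits, jid)

        self._parent = np.asarray(parent, dtype=np.intp)
        self._left = np.asarray(left, dtype=np.intp)
        self._right = np.asarray(right, dtype=np.intp)
        self._factor = np.asarray(factor)
        self._jump_id = np.asarray(jump_id, dtype=np.intp)
        self._pair_event = np.asarray(pair_event, dtype=np.intp)
        self._pair_a = np.asarray(pair_a, dtype=np.intp)
        self._pair_b = np.asarray(pair_b, dtype=np.intp)
        self._inv_size = np.asarray(inv_size)

    def build(self, params: DecParams) -> CladogenesisTable:
        base = np.ones(len(self._parent))
        if len(self._inv_size):
            x = params.x if self.jump_distance_scaling else 0.0
            mod = _modifier(x, self.geo.multiplier,
                            _relative_distance(self.geo.distance_km),
                            self.geo.allowed)
            sums = np.zeros(len(self._inv_size))
            np.add.at(sums, self._pair_event, mod[self._pair_a, self._pair_b])
            jump_w = params.j * sums * self._inv_size
            is_jump = self._jump_id >= 0
            base[is_jump] = jump_w[self._jump_id[is_jump]]
        w = self._factor * base
        keep = w > 0
        parent, left, right, w = (self._parent[keep], self._left[keep],
                                  self._right[keep], w[keep])
        totals = np.zeros(self.space.n_states)
        np.add.at(totals, parent, w)
        return CladogenesisTable(parent, left, right, w / totals[parent],
                                 self.space.n_states)


def cladogenesis_table(
    space: StateSpace,
    params: DecParams,
    geo: EpochGeography,
    jump_distance_scaling: bool = True,
) -> CladogenesisTable:
    """Cladogenetic outcomes with normalized per-parent probabilities."""
    return CladogenesisBuilder(space, geo, jump_distance_scaling).build(params)


def branch_transition(Q: np.ndarray, t: float) -> np.ndarray:
    """CTMC transition-probability matrix expm(Q t) for a branch of length t."""
    if t < 0:
        raise InvalidConfigurationError(f"branch length must be >= 0, got {t}")
    if t == 0:
        return np.eye(Q.shape[0])
    return scipy.linalg.expm(Q * t)


class EpochPropagator:
    """Fast repeated application of expm(Q t) via eigendecomposition.

    The DEC generator is generically diagonalizable; if the decomposition
    reconstructs Q poorly the propagator silently falls back to scipy's expm.
    An optional state mask zeroes states invalid in this epoch on both sides
    of every application (mass is lost, never renormalized).
    """

    def __init__(self, Q: np.ndarray, state_mask: np.ndarray | None = None):
        self.Q = Q
        self.mask = None if state_mask is None else np.asarray(state_mask, dtype=bool)
        self._use_eig = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                w, V = scipy.linalg.eig(Q)
                Vinv = scipy.linalg.inv(V)
            err = np.abs((V * w) @ Vinv - Q).max()
            if err <= 1e-9 * max(1.0, np.abs(Q).max()):
                self.w, self.V, self.Vinv = w, V, Vinv
                self._use_eig = True
        except scipy.linalg.LinAlgError:
            pass

    def _mask_vec(self, v: np.ndarray) -> np.ndarray:
        return v if self.mask is None else np.where(self.mask, v, 0.0)

    def apply(self, v: np.ndarray, t: float) -> np.ndarray:
        """Return (masked) expm(Q t) @ v."""
        v = self._mask_vec(v)
        if t > 0:
            if self._use_eig:
                v = (self.V @ (np.exp(self.w * t) * (self.Vinv @ v))).real
            else:
                v = scipy.linalg.expm(self.Q * t) @ v
            v = self._mask_vec(np.maximum(v, 0.0))
        return v

    def apply_transpose(self, v: np.ndarray, t: float) -> np.ndarray:
        """Return (masked) expm(Q t).T @ v."""
        v = self._mask_vec(v)
        if t > 0:
            if self._use_eig:
                v = (self.Vinv.T @ (np.exp(self.w * t) * (self.V.T @ v))).real
            else:
                v = scipy.linalg.expm(self.Q * t).T @ v
            v = self._mask_vec(np.maximum(v, 0.0))
        return v

    def matrix(self, t: float) -> np.ndarray:
        P = branch_transition(self.Q, t)
        if self.mask is not None:
            P = np.where(self.mask[:, None] & self.mask[None, :], P, 0.0)
        return P


def segments(
    scenario: StratifiedScenario, older_age: float, younger_age: float
) -> list[tuple[int, float]]:
    """Cut [younger, older] at epoch boundaries; (epoch index, duration), old->young."""
    if younger_age > older_age:
        raise InvalidConfigurationError("older_age must be >= younger_age")
    if older_age > scenario.oldest_age or younger_age < 0:
        raise InvalidConfigurationError("interval outside scenario coverage")
    segs: list[tuple[int, float]] = []
    top = older_age
    for idx, ep in enumerate(scenario.epochs):
        lo = max(ep.end_age, younger_age)
        hi = min(ep.start_age, top)
        if hi > lo:
            segs.append((idx, hi - lo))
            top = lo
    return segs


def stratified_branch_transition(
    scenario: StratifiedScenario,
    space: StateSpace,
    params: DecParams,
    older_age: float,
    younger_age: float,
) -> np.ndarray:
    """Transition matrix across epoch boundaries, old state -> young state.

    Per-segment matrices are multiplied in old-to-young order.  In each
    epoch, rows and columns of states containing unavailable areas are
    zeroed (masked, not renormalized): probability mass routed through an
    impossible state is lost, representing lineages that could not have
    existed there.
    """
    S = space.n_states
    P = np.eye(S)
    for epoch_idx, dt in segments(scenario, older_age, younger_age):
        geo = scenario.epochs[epoch_idx]
        mask = scenario.state_mask(space, epoch_idx)
        seg = branch_transition(build_Q(space, params, geo), dt)
        seg = np.where(mask[:, None] & mask[None, :], seg, 0.0)
        P = P @ seg
    return P
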