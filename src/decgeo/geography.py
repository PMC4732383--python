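"""Areas, geographic-range state spaces, and per-epoch geography.

A geographic range is a non-empty subset of discrete areas, encoded as a
fixed-width bit pattern.  The state space of the range-evolution CTMC is the
set of all ranges of at most ``max_range_size`` areas, optionally prefixed by
the null (empty) range, which acts as an internal absorbing state reachable by
extinction from singletons and is never valid as observed data.

Each geological epoch carries its own inter-area distance matrix (km), a
dispersal-multiplier matrix in [0, 1], and a per-area availability mask, so
that analyses can be stratified over changing paleogeography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, InvalidConfigurationError

#: Distance (km) conventionally used to mark a crossing that is possible but
#: highly unlikely; treated as a genuine distance, not infinity, so a negative
#: distance exponent makes dispersal negligible rather than forbidden.
SENTINEL_DISTANCE_KM = 9999.0

#: The twelve areas of the Sunda Arc study system, in their conventional order.
SUNDA_AREAS = (
    "Bali", "Borneo", "Flores", "E-Java", "W-Java", "Lombok",
    "Moluccas", "New-Guinea", "Sulawesi", "Sumatra", "Sumbawa", "Philippines",
)

#: The six islands of the Sunda Arc chain among which dispersal is left open
#: under the "adjacency except arc" constraint scheme.
SUNDA_ARC_CHAIN = ("W-Java", "E-Java", "Bali", "Lombok", "Sumbawa", "Flores")


@dataclass(frozen=True)
class Area:
    """A discrete geographic unit (an island or island part)."""

    name: str
    index: int


@dataclass(frozen=True, order=True)
class GeographicRange:
    """A subset of areas as a bit pattern over a fixed area ordering."""

    bits: int
    n_areas: int

    def __post_init__(self) -> None:
        if self.bits < 0 or self.bits >> self.n_areas:
            raise InvalidConfigurationError(
                f"range bits {self.bits:b} exceed {self.n_areas} areas"
            )

    @property
    def size(self) -> int:
        return self.bits.bit_count()

    @property
    def is_null(self) -> bool:
        return self.bits == 0

    def area_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n_areas) if self.bits >> i & 1)

    def contains(self, area_index: int) -> bool:
        return bool(self.bits >> area_index & 1)

    @classmethod
    def from_indices(cls, indices: Iterable[int], n_areas: int) -> "GeographicRange":
        bits = 0
        for i in indices:
            bits |= 1 << i
        return cls(bits, n_areas)

    def labels(self, areas: Sequence[Area]) -> str:
        if self.is_null:
            return "-"
        return "+".join(areas[i].name for i in self.area_indices())


def make_areas(names: Sequence[str]) -> tuple[Area, ...]:
    """Build an ordered Area tuple, enforcing unique names."""
    if len(set(names)) != len(names):
        raise InvalidConfigurationError("area names must be unique")
    return tuple(Area(name, i) for i, name in enumerate(names))


@dataclass(frozen=True)
class StateSpace:
    """The ordered list of geographic ranges the CTMC runs over.

    Non-null states are ordered by range size, then lexicographically on the
    contained area indices; the null range, if included, sits at index 0.
    This ordering is deterministic, so serialized state lists are
    byte-identical across runs.
    """

    areas: tuple[Area, ...]
    max_range_size: int
    include_null: bool
    states: tuple[GeographicRange, ...]
    index_of: dict = field(repr=False)

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_nonnull(self) -> int:
        return len(self.states) - (1 if self.include_null else 0)

    @property
    def null_index(self) -> int | None:
        return 0 if self.include_null else None

    def nonnull_slice(self) -> slice:
        return slice(1, None) if self.include_null else slice(0, None)

    def index(self, r: GeographicRange | int) -> int:
        bits = r.bits if isinstance(r, GeographicRange) else r
        return self.index_of[bits]

    def range_from_names(self, names: Iterable[str]) -> GeographicRange:
        lookup = {a.name: a.index for a in self.areas}
        try:
            idx = [lookup[n] for n in names]
        except KeyError as exc:
            raise InvalidConfigurationError(f"unknown area name {exc}") from exc
        return GeographicRange.from_indices(idx, self.n_areas)

    def state_labels(self) -> list[str]:
        return [s.labels(self.areas) for s in self.states]

    def serialize(self) -> str:
        """Deterministic one-line-per-state text form of the ordering."""
        return "\n".join(
            f"{i}\t{s.bits:0{self.n_areas}b}\t{s.labels(self.areas)}"
            for i, s in enumerate(self.states)
        )

    def area_membership(self) -> np.ndarray:
        """Boolean (n_states, n_areas) matrix: state i contains area a."""
        out = np.zeros((self.n_states, self.n_areas), dtype=bool)
        for i, s in enumerate(self.states):
            for a in s.area_indices():
                out[i, a] = True
        return out


def build_state_space(
    areas: Sequence[Area] | Sequence[str],
    max_range_size: int,
    include_null: bool = True,
) -> StateSpace:
    """Enumerate all ranges of at most ``max_range_size`` areas.

    The non-null state count is sum_{k=1..m} C(A, k); for the 12-area,
    max-3 Sunda configuration this gives 298 states.
    """
    if areas and isinstance(areas[0], str):
        areas = make_areas(areas)  # type: ignore[arg-type]
    areas = tuple(areas)  # type: ignore[assignment]
    n = len(areas)
    if not 1 <= max_range_size <= n:
        raise InvalidConfigurationError(
            f"max_range_size must be in [1, {n}], got {max_range_size}"
        )
    states: list[GeographicRange] = []
    if include_null:
        states.append(GeographicRange(0, n))
    for k in range(1, max_range_size + 1):
        for combo in combinations(range(n), k):
            states.append(GeographicRange.from_indices(combo, n))
    index_of = {s.bits: i for i, s in enumerate(states)}
    return StateSpace(areas, max_range_size, include_null, tuple(states), index_of)


@dataclass(frozen=True)
class EpochGeography:
    """Geography of one time slice: distances, multipliers, availability.

    Ages are in Ma with the present at 0; ``start_age`` is the older bound
    (may be ``inf`` for an open-ended oldest epoch).
    """

    start_age: float
    end_age: float
    distance_km: np.ndarray
    multiplier: np.ndarray
    allowed: np.ndarray  # bool, per area

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_km, dtype=float)
        m = np.asarray(self.multiplier, dtype=float)
        allowed = np.asarray(self.allowed, dtype=bool)
        object.__setattr__(self, "distance_km", d)
        object.__setattr__(self, "multiplier", m)
        object.__setattr__(self, "allowed", allowed)
        if not self.start_age > self.end_age >= 0:
            raise InvalidConfigurationError(
                f"epoch ages must satisfy start > end >= 0, got "
                f"({self.start_age}, {self.end_age})"
            )
        n = d.shape[0]
        if d.shape != (n, n) or m.shape != (n, n) or allowed.shape != (n,):
            raise InvalidConfigurationError("epoch matrix shapes disagree")
        _validate_distance(d)
        if (m < 0).any() or (m > 1).any():
            raise InvalidConfigurationError("multipliers must lie in [0, 1]")

    @property
    def n_areas(self) -> int:
        return self.distance_km.shape[0]

    @property
    def soft_excluded(self) -> np.ndarray:
        """Pairs carrying the 9,999 km sentinel: dispersal possible but
        negligible under a negative distance exponent, never a hard zero."""
        return self.distance_km >= SENTINEL_DISTANCE_KM

    def contains_age(self, age: float) -> bool:
        return self.end_age <= age <= self.start_age

    def with_multiplier(self, multiplier: np.ndarray) -> "EpochGeography":
        return EpochGeography(
            self.start_age, self.end_age, self.distance_km, multiplier, self.allowed
        )

    @classmethod
    def uniform(
        cls,
        n_areas: int,
        start_age: float = math.inf,
        end_age: float = 0.0,
        distance: float = 1.0,
    ) -> "EpochGeography":
        d = np.full((n_areas, n_areas), float(distance))
        np.fill_diagonal(d, 0.0)
        return cls(start_age, end_age, d, np.ones((n_areas, n_areas)),
                   np.ones(n_areas, dtype=bool))


def _validate_distance(d: np.ndarray) -> None:
    n = d.shape[0]
    if not np.allclose(np.diag(d), 0.0):
        raise FormatError("distance diagonal must be 0")
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if d[i, j] < 0:
                raise FormatError(f"negative distance at cell ({i}, {j})")
            if d[i, j] == 0:
                raise FormatError(f"off-diagonal distance 0 at cell ({i}, {j})")
    asym = np.abs(d - d.T)
    scale = max(1.0, float(np.abs(d).max()))
    if (asym > 1e-6 * scale).any():
        i, j = np.unravel_index(int(np.argmax(asym)), d.shape)
        raise FormatError(f"distance matrix asymmetric at cell ({i}, {j})")


@dataclass(frozen=True)
class StratifiedScenario:
    """Ordered old-to-young epochs covering the analysis time span."""

    epochs: tuple[EpochGeography, ...]

    def __post_init__(self) -> None:
        eps = tuple(self.epochs)
        object.__setattr__(self, "epochs", eps)
        if not eps:
            raise InvalidConfigurationError("scenario needs at least one epoch")
        if eps[-1].end_age != 0:
            raise InvalidConfigurationError("youngest epoch must end at the present")
        for older, younger in zip(eps, eps[1:]):
            if not math.isclose(older.end_age, younger.start_age, abs_tol=1e-9):
                raise InvalidConfigurationError(
                    f"epochs not contiguous at {older.end_age}/{younger.start_age} Ma"
                )

    @property
    def n_areas(self) -> int:
        return self.epochs[0].n_areas

    @property
    def oldest_age(self) -> float:
        return self.epochs[0].start_age

    @property
    def boundaries(self) -> tuple[float, ...]:
        """Internal epoch boundaries, old to young."""
        return tuple(e.end_age for e in self.epochs[:-1])

    def epoch_index_at(self, age: float) -> int:
        """Epoch containing ``age``; boundaries belong to the younger epoch."""
        if age > self.oldest_age or age < 0:
            raise InvalidConfigurationError(
                f"age {age} Ma outside scenario coverage [0, {self.oldest_age}]"
            )
        for i in range(len(self.epochs) - 1, -1, -1):
            if self.epochs[i].contains_age(age):
                return i
        raise InvalidConfigurationError(f"age {age} Ma not covered")  # pragma: no cover

    def epoch_at(self, age: float) -> EpochGeography:
        return self.epochs[self.epoch_index_at(age)]

    def state_mask(self, space: StateSpace, epoch_index: int) -> np.ndarray:
        """Boolean mask over states valid in an epoch.

        A state is valid iff it contains no unavailable area; the null range
        is vacuously valid (it is the absorbing extinction state, not a
        location, and never contributes to observable likelihood anyway).
        """
        allowed = self.epochs[epoch_index].allowed
        mask = np.empty(space.n_states, dtype=bool)
        for i, s in enumerate(space.states):
            mask[i] = all(allowed[a] for a in s.area_indices())
        return mask

    @classmethod
    def single(cls, geo: EpochGeography) -> "StratifiedScenario":
        if geo.end_age != 0:
            raise InvalidConfigurationError("single-epoch scenario must end at 0")
        return cls((geo,))


def load_epoch_geography(
    distance_file,
    multiplier_file=None,
    allowed_areas: Sequence[str] | None = None,
    interval: tuple[float, float] = (math.inf, 0.0),
    areas: Sequence[Area] | None = None,
) -> EpochGeography:
    """Read one epoch's distance (and optional multiplier) TSV matrices.

    Files carry area names as the first row and first column; "." or 0 on the
    diagonal.  The 9,999 km sentinel passes through unchanged.  A rescaled
    distance file (all entries divided by a constant) yields an epoch whose
    relative distances equal the raw file's.
    """
    from .io import read_matrix_tsv  # local import to avoid a cycle

    names, dist = read_matrix_tsv(distance_file)
    if areas is not None:
        expected = [a.name for a in areas]
        if list(names) != expected:
            raise FormatError(
                f"distance file area order {list(names)} != expected {expected}"
            )
    if multiplier_file is not None:
        mnames, mult = read_matrix_tsv(multiplier_file)
        if list(mnames) != list(names):
            raise FormatError("multiplier file area order differs from distance file")
    else:
        mult = np.ones_like(dist)
    if allowed_areas is None:
        allowed = np.ones(len(names), dtype=bool)
    else:
        unknown = set(allowed_areas) - set(names)
        if unknown:
            raise FormatError(f"allowed areas not in matrix header: {sorted(unknown)}")
        allowed = np.array([n in set(allowed_areas) for n in names])
    return EpochGeography(interval[0], interval[1], dist, mult, allowed)


_SCHEMES = ("unconstrained", "adjacent_only", "adjacent_except_arc")


def adjacency_constraint(
    areas: Sequence[Area],
    scheme: str,
    adjacency: Iterable[tuple[str, str]] | None = None,
    arc_areas: Sequence[str] | None = None,
) -> np.ndarray:
    """Build a 0/1 dispersal-multiplier matrix for a named constraint scheme.

    ``adjacent_only`` keeps only user-supplied adjacent pairs (adjacency is
    geological knowledge, not inferred from distances); ``adjacent_except_arc``
    additionally opens all pairs among the named arc islands, mirroring the
    constraint where dispersal is free within the Sunda Arc chain.
    """
    if scheme not in _SCHEMES:
        raise InvalidConfigurationError(
            f"unknown constraint scheme {scheme!r}; expected one of {_SCHEMES}"
        )
    n = len(areas)
    index = {a.name: a.index for a in areas}
    if scheme == "unconstrained":
        m = np.ones((n, n))
        np.fill_diagonal(m, 0.0)
        return m
    if adjacency is None:
        raise InvalidConfigurationError(f"scheme {scheme!r} requires an adjacency list")
    m = np.zeros((n, n))
    for a, b in adjacency:
        if a not in index or b not in index:
            raise InvalidConfigurationError(f"adjacency pair ({a}, {b}) names unknown area")
        m[index[a], index[b]] = m[index[b], index[a]] = 1.0
    if scheme == "adjacent_except_arc":
        if not arc_areas:
            raise InvalidConfigurationError(
                "adjacent_except_arc requires the list of open arc areas"
            )
        idx = [index[a] for a in arc_areas]
        for i in idx:
            for j in idx:
                if i != j:
                    m[i, j] = 1.0
    np.fill_diagonal(m, 0.0)
    return m
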