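"""Readers and writers for the on-disk formats.

Trees travel as Newick with branch lengths in Myr; geographic ranges as a
Lagrange-style "geog" file (header ``n_taxa n_areas (name1 name2 ...)``, then
one ``label<TAB>0/1-string`` row per taxon); distance and multiplier matrices
as TSV with area names on the first row and column and ``.`` or 0 on the
diagonal.  All writers round-trip losslessly through their readers.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .errors import DataError, FormatError
from .geography import GeographicRange, StateSpace
from .trees import DatedTree


def read_newick(source) -> DatedTree:
    """Parse a Newick file or string into a validated dated tree."""
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    return DatedTree.from_newick(text)


def write_newick(tree: DatedTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# geog files

_GEOG_HEADER = re.compile(r"^\s*(\d+)\s+(\d+)\s*\(([^)]*)\)\s*$")


def read_geog(path, space: StateSpace) -> dict:
    """Read a presence/absence range file into tip -> GeographicRange.

    Each row's 0/1 string is interpreted against the state space's area
    ordering; all-zero rows and ranges wider than the state space's maximum
    are rejected with their line number.
    """
    lines = Path(path).read_text().splitlines()
    body = [(i + 1, l) for i, l in enumerate(lines) if l.strip()]
    if not body:
        raise FormatError("empty geog file")
    m = _GEOG_HEADER.match(body[0][1])
    if not m:
        raise FormatError("geog header must be 'n_taxa n_areas (names...)'")
    n_taxa, n_areas = int(m.group(1)), int(m.group(2))
    names = m.group(3).split()
    if len(names) != n_areas:
        raise FormatError("geog header area-name count disagrees with n_areas")
    expected = [a.name for a in space.areas]
    if names != expected:
        raise FormatError(f"geog areas {names} != state space areas {expected}")
    rows = body[1:]
    if len(rows) != n_taxa:
        raise FormatError(f"geog header promises {n_taxa} taxa, file has {len(rows)}")
    out: dict = {}
    for lineno, line in rows:
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected 'label 0/1-string'")
        label, bits_str = parts
        if len(bits_str) != n_areas or set(bits_str) - {"0", "1"}:
            raise FormatError(
                f"line {lineno}: range string must be {n_areas} chars of 0/1"
            )
        if label in out:
            raise FormatError(f"line {lineno}: duplicate taxon {label!r}")
        idx = [i for i, c in enumerate(bits_str) if c == "1"]
        if not idx:
            raise DataError(f"line {lineno}: taxon {label!r} occupies no area")
        if len(idx) > space.max_range_size:
            raise DataError(
                f"line {lineno}: taxon {label!r} occupies {len(idx)} areas, "
                f"more than the maximum range size {space.max_range_size}"
            )
        out[label] = GeographicRange.from_indices(idx, n_areas)
    return out


def write_geog(path, tips: dict, space: StateSpace) -> None:
    names = " ".join(a.name for a in space.areas)
    lines = [f"{len(tips)}\t{space.n_areas}\t({names})"]
    for label in tips:
        r = tips[label]
        bits = r.bits if isinstance(r, GeographicRange) else int(r)
        s = "".join("1" if bits >> i & 1 else "0" for i in range(space.n_areas))
        lines.append(f"{label}\t{s}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# matrices


def read_matrix_tsv(path):
    """Read an area-labelled square matrix; returns (names, ndarray)."""
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    header = lines[0].split("\t")
    names = [h for h in header if h.strip()]
    n = len(lines) - 1
    if len(names) == n + 1:  # corner label present
        names = names[1:]
    if len(names) != n:
        raise FormatError(f"matrix header has {len(names)} names for {n} rows")
    out = np.empty((n, n))
    for r, line in enumerate(lines[1:]):
        parts = line.split("\t")
        if parts[0] != names[r]:
            raise FormatError(
                f"row {r + 1} is labelled {parts[0]!r}, expected {names[r]!r}"
            )
        vals = parts[1:]
        if len(vals) != n:
            raise FormatError(f"row {names[r]!r} has {len(vals)} cells, expected {n}")
        for c, v in enumerate(vals):
            v = v.strip()
            if v == ".":
                if r != c:
                    raise FormatError(f"'.' outside the diagonal at ({names[r]}, {names[c]})")
                out[r, c] = 0.0
            else:
                try:
                    out[r, c] = float(v)
                except ValueError as exc:
                    raise FormatError(
                        f"non-numeric cell at ({names[r]}, {names[c]}): {v!r}"
                    ) from exc
    return names, out


def write_matrix_tsv(path, names, matrix) -> None:
    matrix = np.asarray(matrix)
    lines = ["\t" + "\t".join(names)]
    for r, name in enumerate(names):
        cells = [name]
        for c in range(len(names)):
            cells.append("." if r == c else f"{matrix[r, c]:.10g}")
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
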