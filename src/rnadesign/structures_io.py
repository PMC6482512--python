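"""Parsing and validation of target structures in dot-bracket notation.

A target secondary structure is abstracted as a set of base pairs over
positions ``1..n``. Crossing pairs (pseudoknots) are expressed in the input
by distinct bracket families: ``()``, ``[]``, ``{}``, ``<>`` and then the
letter pairs ``Aa`` .. ``Zz``. The union of the pair sets of all target
structures defines the base pair dependency graph, the simplest form of the
dependency structure the sampling algorithms operate on.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

__all__ = [
    "TargetStructure",
    "DependencyGraph",
    "StructureParseError",
    "parse_structures",
    "parse_structure",
    "serialize_structure",
    "base_pair_dependency_graph",
]

# opening -> closing bracket, in family priority order
_FAMILIES: list[tuple[str, str]] = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")] + [
    (u, u.lower()) for u in string.ascii_uppercase
]
_OPEN = {o: c for o, c in _FAMILIES}
_CLOSE = {c: o for o, c in _FAMILIES}
_UNPAIRED = "."


class StructureParseError(ValueError):
    """Raised on malformed dot-bracket input; carries line and column (1-based)."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.column = column


@dataclass(frozen=True)
class TargetStructure:
    """A secondary structure: a set of base pairs (i, j), 1 <= i < j <= length.

    Every position occurs in at most one pair; crossing pairs are allowed.
    """

    length: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"structure length must be >= 1, got {self.length}")
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"invalid pair ({i},{j}) for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"position occurs in more than one pair: ({i},{j})")
            seen.update((i, j))

    @property
    def paired_positions(self) -> frozenset[int]:
        return frozenset(p for ij in self.pairs for p in ij)

    def stacks(self) -> list[tuple[int, int]]:
        """Outer pairs (i, j) such that (i+1, j-1) is also a pair (a base-pair stack)."""
        ps = self.pairs
        return sorted((i, j) for (i, j) in ps if (i + 1, j - 1) in ps)


@dataclass(frozen=True)
class DependencyGraph:
    """Graph on positions 1..n with one edge per base pair of any target structure."""

    n: int
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "edges", frozenset(tuple(sorted(e)) for e in self.edges))
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at position {i}")
            if not (1 <= i <= self.n and 1 <= j <= self.n):
                raise ValueError(f"edge ({i},{j}) outside 1..{self.n}")


def parse_structure(line: str, lineno: int = 1) -> TargetStructure:
    """Parse one dot-bracket string into a :class:`TargetStructure`."""
    stacks: dict[str, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for col, ch in enumerate(line, start=1):
        if ch == _UNPAIRED:
            continue
        if ch in _OPEN:
            stacks.setdefault(ch, []).append(col)
        elif ch in _CLOSE:
            opener = _CLOSE[ch]
            st = stacks.get(opener)
            if not st:
                raise StructureParseError(
                    f"unbalanced '{ch}': no matching '{opener}'", lineno, col
                )
            pairs.add((st.pop(), col))
        else:
            raise StructureParseError(f"unknown character {ch!r}", lineno, col)
    for opener, st in stacks.items():
        if st:
            raise StructureParseError(
                f"unbalanced '{opener}': never closed", lineno, st[-1]
            )
    return TargetStructure(length=len(line), pairs=frozenset(pairs))


def parse_structures(text: str) -> list[TargetStructure]:
    """Parse multi-line dot-bracket input into a list of structures.

    Blank lines and FASTA-style header/comment lines (starting with '>' or
    '#') are skipped. All structure lines must have equal length.
    """
    structures: list[TargetStructure] = []
    length: int | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", ">")):
            continue
        if length is None:
            length = len(line)
        elif len(line) != length:
            raise StructureParseError(
                f"structure length {len(line)} differs from previous length {length}",
                lineno,
            )
        structures.append(parse_structure(line, lineno))
    if not structures:
        raise StructureParseError("no structure lines found")
    return structures


def serialize_structure(structure: TargetStructure) -> str:
    """Render a structure as a dot-bracket string.

    Pairs are greedily assigned to the first bracket family in which they do
    not cross any pair already placed there; parsing the result recovers the
    same pair set.
    """
    families: list[list[tuple[int, int]]] = []
    out = [_UNPAIRED] * structure.length
    for i, j in sorted(structure.pairs):
        placed = False
        for fam_idx, fam_pairs in enumerate(families):
            if all(not (a < i < b < j or i < a < j < b) for a, b in fam_pairs):
                fam_pairs.append((i, j))
                o, c = _FAMILIES[fam_idx]
                out[i - 1], out[j - 1] = o, c
                placed = True
                break
        if not placed:
            if len(families) >= len(_FAMILIES):
                raise ValueError("structure needs more bracket families than available")
            families.append([(i, j)])
            o, c = _FAMILIES[len(families) - 1]
            out[i - 1], out[j - 1] = o, c
    return "".join(out)


def base_pair_dependency_graph(structures: list[TargetStructure]) -> DependencyGraph:
    """Union of the pair sets of all structures, as a graph on positions 1..n."""
    if not structures:
        raise ValueError("need at least one structure")
    n = structures[0].length
    for s in structures:
        if s.length != n:
            raise ValueError(f"structure lengths differ: {s.length} != {n}")
    edges = frozenset(p for s in structures for p in s.pairs)
    return DependencyGraph(n=n, edges=edges)
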