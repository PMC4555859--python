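"""Face-centred-cubic lattice geometry and relative-encoded chain conformations.

A protein of n residues lives on the FCC lattice: integer points (x, y, z)
where two points are nearest neighbours iff every coordinate differs by at
most 1 and the L1 distance is exactly 2.  Each point has 12 such neighbours,
generated by the 12 basis vectors below.  A conformation is stored in
*relative encoding*: a string of n-1 direction indices (1..12), each an FCC
basis vector stepping from the previous residue.  Decoding anchors residue 1
at the origin; because every basis vector has even coordinate sum, x+y+z is
even at every residue of a decoded chain.

Indices at the public interface are 1-based (residues 1..n, directions
1..12); internal storage is 0-based.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

#: The 12 FCC basis vectors, in their conventional printed order v1..v12.
#: The set is closed under negation (v2 = -v1, v4 = -v3, ...).
BASIS_VECTORS: tuple[tuple[int, int, int], ...] = (
    (1, 1, 0), (-1, -1, 0), (-1, 1, 0), (1, -1, 0),
    (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
    (1, 0, 1), (-1, 0, 1), (1, 0, -1), (-1, 0, -1),
)

#: vector -> 1-based direction index
DIRECTION_INDEX: dict[tuple[int, int, int], int] = {
    v: i + 1 for i, v in enumerate(BASIS_VECTORS)
}

Point = tuple[int, int, int]


class InvalidEncodingError(ValueError):
    """A direction index outside 1..12, or a degenerate chain length."""


@dataclass(frozen=True)
class Conformation:
    """A lattice chain in relative encoding.

    Parameters
    ----------
    directions
        n-1 direction indices, each in 1..12.  The chain has n >= 2 residues.
    """

    directions: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "directions", tuple(self.directions))
        if len(self.directions) < 1:
            raise InvalidEncodingError("a chain needs at least 2 residues")
        for d in self.directions:
            if not 1 <= d <= 12:
                raise InvalidEncodingError(f"direction index {d} outside 1..12")

    @property
    def n(self) -> int:
        """Residue count."""
        return len(self.directions) + 1

    def decode(self, origin: Point = (0, 0, 0)) -> list[Point]:
        """Decode to absolute coordinates (no self-avoidance check)."""
        return decode_conformation(self, origin)

    @classmethod
    def from_coords(cls, coords: Sequence[Point]) -> "Conformation":
        """Re-encode a coordinate chain; raises if steps are not FCC moves."""
        dirs = []
        for p, q in zip(coords, coords[1:]):
            step = (q[0] - p[0], q[1] - p[1], q[2] - p[2])
            try:
                dirs.append(DIRECTION_INDEX[step])
            except KeyError:
                raise InvalidEncodingError(f"step {step} is not an FCC basis vector")
        return cls(tuple(dirs))

    def to_string(self, sep: str = " ") -> str:
        """Serialize as whitespace/comma separated direction tokens."""
        return sep.join(str(d) for d in self.directions)

    @classmethod
    def from_string(cls, text: str) -> "Conformation":
        tokens = text.replace(",", " ").split()
        return cls(tuple(int(t) for t in tokens))


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of a self-avoidance check; falsy when the walk collides."""

    valid: bool
    message: str = "valid"
    collision: Optional[tuple[int, int]] = None  # 1-based residue indices

    def __bool__(self) -> bool:
        return self.valid


def decode_conformation(conf: Conformation, origin: Point = (0, 0, 0)) -> list[Point]:
    """Decode a relative encoding to n absolute lattice points.

    Chain adjacency holds by construction; self-avoidance is *not* checked
    here (see :func:`validate`).
    """
    x, y, z = origin
    points = [origin]
    for d in conf.directions:
        vx, vy, vz = BASIS_VECTORS[d - 1]
        x, y, z = x + vx, y + vy, z + vz
        points.append((x, y, z))
    return points


def is_adjacent(p: Point, q: Point) -> bool:
    """True iff p and q are FCC nearest neighbours.

    Requires |dx|,|dy|,|dz| <= 1 and |dx|+|dy|+|dz| = 2.
    """
    dx = abs(p[0] - q[0])
    dy = abs(p[1] - q[1])
    dz = abs(p[2] - q[2])
    return dx <= 1 and dy <= 1 and dz <= 1 and dx + dy + dz == 2


def neighbors(p: Point) -> set[Point]:
    """The 12 FCC nearest neighbours of p."""
    x, y, z = p
    return {(x + v[0], y + v[1], z + v[2]) for v in BASIS_VECTORS}


def validate(conf: Conformation, origin: Point = (0, 0, 0)) -> ValidationResult:
    """Self-avoiding-walk check: decoded points must be pairwise distinct.

    Violations are reported as return values, never raised.
    """
    seen: dict[Point, int] = {}
    for i, p in enumerate(decode_conformation(conf, origin)):
        if p in seen:
            return ValidationResult(
                False,
                f"residues {seen[p] + 1} and {i + 1} occupy {p}",
                (seen[p] + 1, i + 1),
            )
        seen[p] = i
    return ValidationResult(True)


def is_contact(seq_index_a: int, seq_index_b: int, coords: Sequence[Point]) -> bool:
    """True iff residues a and b (1-based) form a topological contact.

    A contact requires FCC adjacency in space and non-adjacency in sequence
    (|a - b| > 1): chain neighbours never count.
    """
    n = len(coords)
    for idx in (seq_index_a, seq_index_b):
        if not 1 <= idx <= n:
            raise IndexError(f"residue index {idx} outside 1..{n}")
    if abs(seq_index_a - seq_index_b) <= 1:
        return False
    return is_adjacent(coords[seq_index_a - 1], coords[seq_index_b - 1])


def contacts_from_coords(coords: Sequence[Point]) -> list[tuple[int, int]]:
    """All contact pairs (a, b), a < b, 1-based, from decoded coordinates.

    Uses the occupancy hash, O(12 n); assumes the chain is self-avoiding.
    """
    occupancy = {p: i for i, p in enumerate(coords)}
    pairs = []
    for i, p in enumerate(coords):
        x, y, z = p
        for v in BASIS_VECTORS:
            j = occupancy.get((x + v[0], y + v[1], z + v[2]))
            if j is not None and j > i + 1:
                pairs.append((i + 1, j + 1))
    pairs.sort()
    return pairs


def enumerate_contacts(conf: Conformation) -> list[tuple[int, int]]:
    """All contact pairs of a valid conformation, sorted, no duplicates."""
    result = validate(conf)
    if not result:
        raise ValueError(f"invalid conformation: {result.message}")
    return contacts_from_coords(decode_conformation(conf))


class ChainGrowthError(RuntimeError):
    """Chain-growth initialization exhausted its restart budget."""


def chain_growth_init(
    n: int,
    rng: random.Random,
    max_restarts: int = 1000,
) -> Conformation:
    """Random self-avoiding chain of n residues by chain growth.

    Each step samples uniformly among the direction choices leading to
    unoccupied points; a dead end restarts the whole chain.  Raises
    :class:`ChainGrowthError` after ``max_restarts`` failed attempts.
    The result depends only on the state of ``rng``.
    """
    if n < 2:
        raise InvalidEncodingError("chain growth needs n >= 2")
    for _ in range(max_restarts):
        pos: Point = (0, 0, 0)
        occupied = {pos}
        dirs: list[int] = []
        dead_end = False
        while len(dirs) < n - 1:
            options = []
            for d, v in enumerate(BASIS_VECTORS, start=1):
                q = (pos[0] + v[0], pos[1] + v[1], pos[2] + v[2])
                if q not in occupied:
                    options.append((d, q))
            if not options:
                dead_end = True
                break
            d, pos = options[rng.randrange(len(options))]
            occupied.add(pos)
            dirs.append(d)
        if not dead_end:
            return Conformation(tuple(dirs))
    raise ChainGrowthError(f"no self-avoiding chain of length {n} "
                           f"found in {max_restarts} restarts")
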