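"""The four genetic operators and their exhaustive-application wrappers.

Crossover recombines direction strings; pull, diagonal and rotation are
mutational moves on the lattice chain.  ``exhaustive_apply`` enumerates an
operator's full parameter space for one individual and returns the
minimum-energy valid candidate (ties broken by enumeration order:
residue index ascending, then target in basis-vector order), which is the
"apply in all possible ways, keep the best-fit" scheme.

Every candidate scored ticks the objective-evaluation counter exactly once,
whether the score is computed from scratch or as an incremental delta from
the parent's cached energy.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .energy_models import ContactEnergyMatrix, pair_energy_table
from .fcc_lattice import (
    BASIS_VECTORS,
    Conformation,
    Point,
    is_adjacent,
    validate,
)

Coords = list[Point]


@dataclass(frozen=True)
class MoveResult:
    """Best candidate found by an operator application."""

    conformation: Conformation
    coords: tuple[Point, ...]
    energy: float
    operator: str
    params: Optional[tuple]  # cut point / (residue, end, target) / start
    candidates: int  # feasible candidates enumerated (0 = input returned)


def occupancy(coords: Sequence[Point]) -> dict[Point, int]:
    return {p: i for i, p in enumerate(coords)}


def _free_neighbors(p: Point, occ: dict[Point, int]) -> list[Point]:
    """Unoccupied FCC neighbours of p, in basis-vector order."""
    out = []
    for v in BASIS_VECTORS:
        q = (p[0] + v[0], p[1] + v[1], p[2] + v[2])
        if q not in occ:
            out.append(q)
    return out


# ---------------------------------------------------------------------------
# objective-evaluation accounting: every candidate scoring passes through
# _count_eval exactly once (tests intercept this to audit the counter)

def _count_eval(counter) -> None:
    if counter is not None:
        counter.tick()


def score_full(coords: Sequence[Point], pair_energy: Sequence[Sequence[float]],
               counter=None) -> float:
    """Score a candidate from scratch (one objective evaluation).

    ``pair_energy`` is the position-pair table from
    :func:`gwfold.energy_models.pair_energy_table`.
    """
    _count_eval(counter)
    occ = {p: i for i, p in enumerate(coords)}
    total = 0.0
    for i, (x, y, z) in enumerate(coords):
        row = pair_energy[i]
        for vx, vy, vz in BASIS_VECTORS:
            j = occ.get((x + vx, y + vy, z + vz))
            if j is not None and j > i + 1:
                total += row[j]
    return total


def score_delta(base_energy: float, coords: Sequence[Point],
                new_positions: dict[int, Point], occ: dict[Point, int],
                pair_energy: Sequence[Sequence[float]], counter=None) -> float:
    """Score a candidate incrementally (still one objective evaluation).

    ``new_positions`` maps the 0-based indices of moved residues to their
    new points; all other residues keep their position in ``coords``.
    """
    _count_eval(counter)
    moved = new_positions.keys()
    new_inv = {p: i for i, p in new_positions.items()}
    occ_get = occ.get
    inv_get = new_inv.get

    delta = 0.0
    seen_old: set[tuple[int, int]] = set()
    seen_new: set[tuple[int, int]] = set()
    for i in moved:
        row = pair_energy[i]
        x, y, z = coords[i]
        for vx, vy, vz in BASIS_VECTORS:
            j = occ_get((x + vx, y + vy, z + vz))
            if j is not None and abs(i - j) > 1:
                pair = (i, j) if i < j else (j, i)
                if pair not in seen_old:
                    seen_old.add(pair)
                    delta -= row[j]
        x, y, z = new_positions[i]
        for vx, vy, vz in BASIS_VECTORS:
            q = (x + vx, y + vy, z + vz)
            j = inv_get(q)
            if j is None:
                j = occ_get(q)
                if j is not None and j in moved:
                    j = None
            if j is not None and abs(i - j) > 1:
                pair = (i, j) if i < j else (j, i)
                if pair not in seen_new:
                    seen_new.add(pair)
                    delta += row[j]
    return base_energy + delta


# ---------------------------------------------------------------------------
# crossover

def crossover(parent1: Conformation, parent2: Conformation, cut: int):
    """Swap direction-string suffixes at ``cut`` (1 <= cut <= n-2).

    Returns ``((child1, valid1), (child2, valid2))``; children may violate
    self-avoidance, which the attached validation verdicts report.
    """
    d1, d2 = parent1.directions, parent2.directions
    if len(d1) != len(d2):
        raise ValueError("crossover parents must have equal length")
    if not 1 <= cut <= len(d1) - 1:
        raise ValueError(f"cut {cut} outside 1..{len(d1) - 1}")
    c1 = Conformation(d1[:cut] + d2[cut:])
    c2 = Conformation(d2[:cut] + d1[cut:])
    return (c1, validate(c1)), (c2, validate(c2))


# ---------------------------------------------------------------------------
# pull move

def pull_targets(coords: Sequence[Point], residue: int, end: str,
                 occ: Optional[dict[Point, int]] = None) -> list[Point]:
    """Candidate target points for pulling ``residue`` (1-based) toward ``end``.

    Targets are the free neighbours of the anchor-side chain neighbour's
    position (of the residue itself for a terminal pull), in basis order.
    """
    if occ is None:
        occ = occupancy(coords)
    i0 = residue - 1
    anchor = i0 - 1 if end == "tail" else i0 + 1
    base = coords[anchor] if 0 <= anchor < len(coords) else coords[i0]
    return _free_neighbors(base, occ)


def pull_move(coords: Sequence[Point], residue: int, end: str, target: Point,
              occ: Optional[dict[Point, int]] = None):
    """Pull ``residue`` (1-based) to ``target``, dragging toward ``end``.

    The pulled residue relocates to a free point adjacent to its anchor-side
    neighbour; each successive residue toward the free end steps into the
    position its predecessor just vacated, stopping as soon as chain
    adjacency is restored.  Every shifted position pair was adjacent in the
    old chain, so the result is always a valid self-avoiding chain.

    Returns ``(new_coords, moved)`` with ``moved`` mapping 0-based indices
    to new points, or ``None`` when the move is infeasible.
    """
    if end not in ("head", "tail"):
        raise ValueError("end must be 'head' or 'tail'")
    n = len(coords)
    if not 1 <= residue <= n:
        raise IndexError(f"residue {residue} outside 1..{n}")
    if occ is None:
        occ = occupancy(coords)
    if target in occ:
        return None
    i0 = residue - 1
    step = 1 if end == "tail" else -1
    anchor = i0 - step
    if 0 <= anchor < n and not is_adjacent(target, coords[anchor]):
        return None
    new = list(coords)
    new[i0] = target
    moved = {i0: target}
    j = i0 + step
    while 0 <= j < n:
        if is_adjacent(coords[j], new[j - step]):
            break  # chain adjacency restored, rest of the chain stays
        slot = coords[j - step]  # position the predecessor just vacated
        if not is_adjacent(slot, new[j - step]):
            return None  # target not diagonal to the old position
        new[j] = slot
        moved[j] = slot
        j += step
    return new, moved


def random_pull(coords: Coords, rng: random.Random,
                max_tries: int = 30) -> Optional[Coords]:
    """One random feasible pull move, or None after ``max_tries`` attempts."""
    n = len(coords)
    occ = occupancy(coords)
    for _ in range(max_tries):
        residue = rng.randrange(1, n + 1)
        end = "head" if rng.random() < 0.5 else "tail"
        targets = pull_targets(coords, residue, end, occ)
        if not targets:
            continue
        target = targets[rng.randrange(len(targets))]
        res = pull_move(coords, residue, end, target, occ)
        if res is not None:
            return res[0]
    return None


# ---------------------------------------------------------------------------
# diagonal move (kink jump / corner flip)

def diagonal_targets(coords: Sequence[Point], residue: int,
                     occ: Optional[dict[Point, int]] = None) -> list[Point]:
    """Free points adjacent to all chain neighbours of ``residue`` (1-based).

    A middle residue can move only to a free common neighbour of its two
    chain neighbours (two FCC-adjacent points share exactly 4 common
    neighbours, so there are at most 4 candidates); a terminal residue may
    take any free neighbour of its single chain neighbour.
    """
    if occ is None:
        occ = occupancy(coords)
    i0 = residue - 1
    n = len(coords)
    if i0 == 0:
        return _free_neighbors(coords[1], occ)
    if i0 == n - 1:
        return _free_neighbors(coords[n - 2], occ)
    left, right = coords[i0 - 1], coords[i0 + 1]
    return [q for q in _free_neighbors(left, occ) if is_adjacent(q, right)]


def diagonal_move(coords: Sequence[Point], residue: int, target: Point,
                  occ: Optional[dict[Point, int]] = None):
    """Relocate ``residue`` (1-based) to ``target`` keeping chain adjacency.

    Returns ``(new_coords, moved)`` or ``None`` if infeasible (occupied
    target or broken adjacency).  The move is its own inverse.
    """
    n = len(coords)
    if not 1 <= residue <= n:
        raise IndexError(f"residue {residue} outside 1..{n}")
    if occ is None:
        occ = occupancy(coords)
    if target in occ:
        return None
    i0 = residue - 1
    for nb in (i0 - 1, i0 + 1):
        if 0 <= nb < n and not is_adjacent(target, coords[nb]):
            return None
    new = list(coords)
    new[i0] = target
    return new, {i0: target}


# ---------------------------------------------------------------------------
# rotation

def rotation(conf: Conformation, start: int, rng: random.Random,
             retries: int = 50) -> Optional[Conformation]:
    """Re-sample directions at positions >= ``start`` (1-based) uniformly.

    The coordinates of residues 1..start are unchanged.  Re-sampling is
    retried until the whole conformation validates, up to ``retries``
    attempts; returns None when the budget is exhausted.
    """
    dirs = conf.directions
    if not 1 <= start <= len(dirs):
        raise ValueError(f"start {start} outside 1..{len(dirs)}")
    prefix = dirs[:start - 1]
    k = len(dirs) - len(prefix)
    # decode the fixed prefix once; each retry walks the re-sampled suffix
    # against the occupancy set, aborting at the first collision (same
    # acceptance region as resample-then-validate, fewer draws)
    x = y = z = 0
    occupied = {(0, 0, 0)}
    for d in prefix:
        vx, vy, vz = BASIS_VECTORS[d - 1]
        x, y, z = x + vx, y + vy, z + vz
        occupied.add((x, y, z))
    rand = rng.random
    for _ in range(retries):
        px, py, pz = x, y, z
        suffix: list[int] = []
        walked: set[Point] = set()
        ok = True
        for _ in range(k):
            d = int(rand() * 12) + 1
            vx, vy, vz = BASIS_VECTORS[d - 1]
            px, py, pz = px + vx, py + vy, pz + vz
            p = (px, py, pz)
            if p in occupied or p in walked:
                ok = False
                break
            walked.add(p)
            suffix.append(d)
        if ok:
            return Conformation(prefix + tuple(suffix))
    return None


# ---------------------------------------------------------------------------
# exhaustive application

OPERATORS = ("pull", "crossover", "diagonal", "rotation")


def exhaustive_apply(
    op_tag: str,
    coords: Sequence[Point],
    energy: float,
    seq: str,
    matrix: ContactEnergyMatrix,
    rng: random.Random,
    mate_coords: Optional[Sequence[Point]] = None,
    counter=None,
    rotation_retries: int = 50,
    pair_energy: Optional[Sequence[Sequence[float]]] = None,
) -> MoveResult:
    """Apply an operator in all possible ways; return the best-fit candidate.

    Enumeration spaces: pull — every residue x both ends x every candidate
    target; diagonal — every residue x every candidate target; rotation —
    every start index, one uniform re-sample each (enumerating all suffixes
    would be exponential); crossover — every cut point with the given mate,
    both children.  If no feasible candidate exists the input is returned
    unchanged with ``candidates=0``.
    """
    coords = list(coords)
    n = len(coords)
    if pair_energy is None:
        pair_energy = pair_energy_table(seq, matrix)
    best_energy = None
    best_coords = None
    best_params = None
    feasible = 0
    occ = occupancy(coords)

    if op_tag == "pull":
        for residue in range(1, n + 1):
            for end in ("head", "tail"):
                for target in pull_targets(coords, residue, end, occ):
                    res = pull_move(coords, residue, end, target, occ)
                    if res is None:
                        continue
                    new, moved = res
                    e = score_delta(energy, coords, moved, occ, pair_energy,
                                    counter)
                    feasible += 1
                    if best_energy is None or e < best_energy:
                        best_energy, best_coords = e, new
                        best_params = (residue, end, target)
    elif op_tag == "diagonal":
        for residue in range(1, n + 1):
            for target in diagonal_targets(coords, residue, occ):
                res = diagonal_move(coords, residue, target, occ)
                if res is None:
                    continue
                new, moved = res
                e = score_delta(energy, coords, moved, occ, pair_energy,
                                counter)
                feasible += 1
                if best_energy is None or e < best_energy:
                    best_energy, best_coords = e, new
                    best_params = (residue, target)
    elif op_tag == "rotation":
        conf = Conformation.from_coords(coords)
        for start in range(1, n):
            cand = rotation(conf, start, rng, retries=rotation_retries)
            if cand is None:
                continue
            new = cand.decode()
            e = score_full(new, pair_energy, counter)
            feasible += 1
            if best_energy is None or e < best_energy:
                best_energy, best_coords, best_params = e, new, (start,)
    elif op_tag == "crossover":
        if mate_coords is None:
            raise ValueError("crossover needs a mate")
        p1 = Conformation.from_coords(coords)
        p2 = Conformation.from_coords(list(mate_coords))
        for cut in range(1, n - 1):
            for child, verdict in crossover(p1, p2, cut):
                if not verdict:
                    continue
                new = child.decode()
                e = score_full(new, pair_energy, counter)
                feasible += 1
                if best_energy is None or e < best_energy:
                    best_energy, best_coords, best_params = e, new, (cut,)
    else:
        raise ValueError(f"unknown operator {op_tag!r}")

    if best_coords is None:
        return MoveResult(Conformation.from_coords(coords), tuple(coords),
                          energy, op_tag, None, 0)
    return MoveResult(Conformation.from_coords(best_coords),
                      tuple(best_coords), best_energy, op_tag, best_params,
                      feasible)


def apply_random(
    op_tag: str,
    coords: Sequence[Point],
    energy: float,
    seq: str,
    matrix: ContactEnergyMatrix,
    rng: random.Random,
    mate_coords: Optional[Sequence[Point]] = None,
    counter=None,
    rotation_retries: int = 50,
    pair_energy: Optional[Sequence[Sequence[float]]] = None,
) -> MoveResult:
    """Single random application of an operator (the non-exhaustive variant).

    One parameter choice is drawn uniformly; an infeasible draw returns the
    input unchanged and scores nothing.
    """
    coords = list(coords)
    n = len(coords)
    if pair_energy is None:
        pair_energy = pair_energy_table(seq, matrix)
    occ = occupancy(coords)
    if op_tag == "pull":
        residue = rng.randrange(1, n + 1)
        end = "head" if rng.random() < 0.5 else "tail"
        targets = pull_targets(coords, residue, end, occ)
        if targets:
            target = targets[rng.randrange(len(targets))]
            res = pull_move(coords, residue, end, target, occ)
            if res is not None:
                new, moved = res
                e = score_delta(energy, coords, moved, occ, pair_energy,
                                counter)
                return MoveResult(Conformation.from_coords(new), tuple(new),
                                  e, op_tag, (residue, end, target), 1)
    elif op_tag == "diagonal":
        residue = rng.randrange(1, n + 1)
        targets = diagonal_targets(coords, residue, occ)
        if targets:
            target = targets[rng.randrange(len(targets))]
            res = diagonal_move(coords, residue, target, occ)
            if res is not None:
                new, moved = res
                e = score_delta(energy, coords, moved, occ, pair_energy,
                                counter)
                return MoveResult(Conformation.from_coords(new), tuple(new),
                                  e, op_tag, (residue, target), 1)
    elif op_tag == "rotation":
        start = rng.randrange(1, n)
        cand = rotation(Conformation.from_coords(coords), start, rng,
                        retries=rotation_retries)
        if cand is not None:
            new = cand.decode()
            e = score_full(new, pair_energy, counter)
            return MoveResult(cand, tuple(new), e, op_tag, (start,), 1)
    elif op_tag == "crossover":
        if mate_coords is None:
            raise ValueError("crossover needs a mate")
        if n >= 3:
            cut = rng.randrange(1, n - 1)
            p1 = Conformation.from_coords(coords)
            p2 = Conformation.from_coords(list(mate_coords))
            (c1, v1), (c2, v2) = crossover(p1, p2, cut)
            child, verdict = (c1, v1) if rng.random() < 0.5 else (c2, v2)
            if verdict:
                new = child.decode()
                e = score_full(new, pair_energy, counter)
                return MoveResult(child, tuple(new), e, op_tag, (cut,), 1)
    else:
        raise ValueError(f"unknown operator {op_tag!r}")
    return MoveResult(Conformation.from_coords(coords), tuple(coords),
                      energy, op_tag, None, 0)
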