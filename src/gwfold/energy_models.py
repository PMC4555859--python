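"""Contact potentials and the contact-based energy objective.

Three 20x20 pairwise potentials are supported:

* **BM** — an empirical pairwise contact potential in the style of
  quasi-chemical knowledge-based energies (Berrera-type).  The table
  bundled with this package (``contact_energies_bm_synthetic.tsv``) is a
  *synthetic* stand-in with the documented spectral properties (symmetric,
  magnitudes up to |E|x10^3 = 3477, hydrophobic pairs strongest, like
  charges repulsive); any real table in the same TSV layout can be supplied
  instead.
* **HP** — the hydrophobic/polar simplification: -1 for H-H contacts, 0
  otherwise.
* **GW** — the group-weighted potential derived from BM: energy levels are
  banded by magnitude and each band m is scaled by the multiplier
  g_m = 1 + m(m+1)/2.  The scaling widens the separation between strong and
  weak interactions without reordering magnitudes inside a band, which is
  what makes it a more informative search guidance than raw BM.

The energy of a conformation is the sum of matrix entries over all
topological contacts (sequence separation > 1, FCC-adjacent in space).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .fcc_lattice import (
    Conformation,
    Point,
    contacts_from_coords,
    decode_conformation,
    validate,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Default hydrophobic set for the HP model.  Calibrated so that the H-H
#: potential-contact count of the 1CTF benchmark sequence matches the
#: reference value 149 (the alanine-inclusive variant gives 582).
DEFAULT_HYDROPHOBIC = frozenset("CFILMVWY")


def validate_sequence(seq: str) -> str:
    """Return ``seq`` upper-cased if it is a valid 20-letter sequence."""
    s = seq.strip().upper()
    if len(s) < 2:
        raise ValueError("a protein sequence needs at least 2 residues")
    for pos, ch in enumerate(s, start=1):
        if ch not in _AA_INDEX:
            raise ValueError(f"illegal residue {ch!r} at position {pos}")
    return s


@dataclass(frozen=True)
class ContactEnergyMatrix:
    """Symmetric 20x20 map from unordered residue pairs to contact energy."""

    values: np.ndarray
    label: str = "BM"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 20):
            raise ValueError(f"expected a 20x20 table, got {v.shape}")
        if not np.allclose(v, v.T, atol=0):
            raise ValueError("contact energy matrix must be symmetric")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        """Energy of the unordered pair {a, b}."""
        return float(self.values[_AA_INDEX[a], _AA_INDEX[b]])

    def max_magnitude(self) -> float:
        return float(np.max(np.abs(self.values)))

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = ["\t".join([""] + list(AMINO_ACIDS))]
        for i, a in enumerate(AMINO_ACIDS):
            lines.append("\t".join([a] + [f"{self.values[i, j]:.3f}"
                                          for j in range(20)]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path], label: str = "BM") -> "ContactEnergyMatrix":
        """Read a tab-separated 20x20 table with one-letter headers.

        Accepts a full square table or a lower triangle (missing upper
        entries are mirrored).
        """
        lines = [ln for ln in Path(path).read_text().splitlines()
                 if ln.strip() and not ln.lstrip().startswith("#")]
        header = lines[0].split("\t")
        cols = [c.strip() for c in header[1:] if c.strip()]
        if sorted(cols) != sorted(AMINO_ACIDS):
            raise ValueError("header must list the 20 amino-acid letters")
        v = np.full((20, 20), np.nan)
        for ln in lines[1:]:
            parts = ln.split("\t")
            a = parts[0].strip()
            for c, cell in zip(cols, parts[1:]):
                cell = cell.strip()
                if cell:
                    v[_AA_INDEX[a], _AA_INDEX[c]] = float(cell)
        missing = np.isnan(v)
        v[missing] = v.T[missing]  # mirror a lower triangle
        if np.isnan(v).any():
            raise ValueError("matrix incomplete: some pairs missing")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        return cls(np.asarray((v + v.T) / 2.0), label=label)


@dataclass(frozen=True)
class Band:
    """One magnitude band of a group scheme, edges in units of |E|x10^3."""

    group: int
    lower: float
    upper: float
    lower_inclusive: bool
    upper_inclusive: bool

    def contains(self, magnitude_milli: float) -> bool:
        lo = (magnitude_milli >= self.lower if self.lower_inclusive
              else magnitude_milli > self.lower)
        hi = (magnitude_milli <= self.upper if self.upper_inclusive
              else magnitude_milli < self.upper)
        return lo and hi


def group_multiplier(m: int) -> int:
    """Group multiplier g_m = 1 + m(m+1)/2 for group number m >= 0."""
    if m < 0:
        raise ValueError("group number must be non-negative")
    return 1 + m * (m + 1) // 2


@dataclass(frozen=True)
class GroupScheme:
    """Ordered magnitude bands used to derive the GW potential from BM.

    The default six-group scheme bands |E|x10^3 as
    [0,100], (100,500], (500,1000], (1000,1500], (1500,2000), [2000,3477]:
    the printed integer ranges share the value 2000 between the top two
    bands, and the tie goes to the higher group.
    """

    bands: tuple[Band, ...]

    @property
    def count(self) -> int:
        return len(self.bands)

    def assign_group(self, bm_energy: float) -> int:
        """Band (group number) containing |bm_energy| x 10^3."""
        mag = abs(bm_energy) * 1000.0
        # ties at shared printed edges go to the higher group
        for band in reversed(self.bands):
            if band.contains(mag):
                return band.group
        raise ValueError(
            f"|E|x10^3 = {mag:g} outside the scheme's covered range "
            f"[0, {self.bands[-1].upper:g}]")

    def multiplier_for(self, bm_energy: float) -> int:
        return group_multiplier(self.assign_group(bm_energy))

    @classmethod
    def default_six_group(cls) -> "GroupScheme":
        edges = [
            (0.0, 100.0, True, True),
            (100.0, 500.0, False, True),
            (500.0, 1000.0, False, True),
            (1000.0, 1500.0, False, True),
            (1500.0, 2000.0, False, False),
            (2000.0, 3477.0, True, True),
        ]
        return cls(tuple(Band(m, lo, hi, li, ui)
                         for m, (lo, hi, li, ui) in enumerate(edges)))

    @classmethod
    def single_group(cls, upper: float = float("inf")) -> "GroupScheme":
        """One band covering everything; derivation is then the identity."""
        return cls((Band(0, 0.0, upper, True, True),))


@dataclass(frozen=True)
class HPClassification:
    """Binary hydrophobic/polar split of the 20-letter alphabet."""

    hydrophobic: frozenset[str] = DEFAULT_HYDROPHOBIC

    def __post_init__(self) -> None:
        h = frozenset(self.hydrophobic)
        if not h or not h < frozenset(AMINO_ACIDS):
            raise ValueError("hydrophobic set must be a nonempty proper "
                             "subset of the 20 amino acids")
        object.__setattr__(self, "hydrophobic", h)


def assign_group(bm_energy: float, scheme: GroupScheme) -> int:
    """Group number of a BM energy value under ``scheme`` (by magnitude)."""
    return scheme.assign_group(bm_energy)


def derive_gw_matrix(bm: ContactEnergyMatrix,
                     scheme: Optional[GroupScheme] = None) -> ContactEnergyMatrix:
    """Group-weighted potential: each entry scaled by its band multiplier.

    Signs are preserved; grouping is by magnitude, so positive (repulsive)
    levels are amplified the same way as negative ones.  A single-group
    scheme returns a matrix identical to the input.
    """
    if scheme is None:
        scheme = GroupScheme.default_six_group()
    out = np.empty_like(bm.values)
    for i in range(20):
        for j in range(i, 20):
            e = bm.values[i, j]
            out[i, j] = out[j, i] = scheme.multiplier_for(e) * e
    return ContactEnergyMatrix(out, label="GW")


def hp_matrix(cls: Optional[HPClassification] = None) -> ContactEnergyMatrix:
    """HP potential: -1 for hydrophobic-hydrophobic pairs, else 0."""
    if cls is None:
        cls = HPClassification()
    v = np.zeros((20, 20))
    for a in cls.hydrophobic:
        for b in cls.hydrophobic:
            v[_AA_INDEX[a], _AA_INDEX[b]] = -1.0
    return ContactEnergyMatrix(v, label="HP")


def evaluate_energy(
    conf: Union[Conformation, Sequence[Point]],
    seq: str,
    matrix: ContactEnergyMatrix,
    counter=None,
) -> float:
    """Contact energy of a conformation: sum over all topological contacts.

    ``conf`` may be a :class:`Conformation` (validated) or pre-decoded
    coordinates of a self-avoiding chain.  When ``counter`` is given its
    ``tick()`` is called once — one objective-function evaluation.
    """
    if isinstance(conf, Conformation):
        if conf.n != len(seq):
            raise ValueError(f"conformation has {conf.n} residues, "
                             f"sequence has {len(seq)}")
        res = validate(conf)
        if not res:
            raise ValueError(f"invalid conformation: {res.message}")
        coords = decode_conformation(conf)
    else:
        coords = conf
        if len(coords) != len(seq):
            raise ValueError(f"{len(coords)} coordinates for "
                             f"{len(seq)} residues")
    if counter is not None:
        counter.tick()
    total = 0.0
    for a, b in contacts_from_coords(coords):
        total += matrix.get(seq[a - 1], seq[b - 1])
    return total


def pair_energy_table(seq: str, matrix: ContactEnergyMatrix) -> list[list[float]]:
    """n x n table of contact energies by residue *position* pair.

    Hot-path helper: scoring a candidate then needs only integer indexing,
    no alphabet lookups.  Entry [i][j] is the matrix energy of the residue
    types at 0-based positions i and j.
    """
    idx = [_AA_INDEX[a] for a in seq]
    v = matrix.values
    return [[float(v[a, b]) for b in idx] for a in idx]


def count_potential_contacts(n: int) -> int:
    """Residue pairs with sequence separation > 1: (n-1)(n-2)/2."""
    if n < 3:
        return 0
    return (n - 1) * (n - 2) // 2


def count_contact_types(seq: str) -> int:
    """Distinct unordered residue-type pairs over all potential contacts."""
    s = validate_sequence(seq)
    n = len(s)
    types: set[frozenset[str]] = set()
    for a in range(n):
        for b in range(a + 2, n):
            types.add(frozenset((s[a], s[b])))
    return len(types)


def energy_distribution(
    seq: str,
    matrix: ContactEnergyMatrix,
    normalized: bool = False,
) -> list[tuple[float, int]]:
    """(energy level, potential-contact count) pairs, sorted by level.

    Counts partition all (n-1)(n-2)/2 potential contacts of the sequence.
    With ``normalized`` the levels are divided by the largest-magnitude
    level present.
    """
    s = validate_sequence(seq)
    n = len(s)
    tally: dict[float, int] = {}
    for a in range(n):
        for b in range(a + 2, n):
            e = matrix.get(s[a], s[b])
            tally[e] = tally.get(e, 0) + 1
    levels = sorted(tally.items())
    if normalized:
        scale = max((abs(e) for e, _ in levels), default=0.0)
        if scale > 0:
            levels = [(e / scale, c) for e, c in levels]
    return levels
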