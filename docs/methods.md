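# Methods

## Model

`gwfold` performs ab initio folding simulation in a reduced lattice model:
each residue of a protein sequence s = s₁…sₙ (sᵢ in the 20-letter alphabet)
occupies one point of the face-centred-cubic (FCC) lattice. Two lattice
points are adjacent when every coordinate differs by at most one and the L1
distance is exactly two; each point therefore has 12 neighbours, generated
by 12 integer basis vectors of even coordinate sum. A conformation is a
self-avoiding walk: consecutive residues are adjacent (chain constraint)
and no two residues share a point. Conformations are stored in relative
encoding — a string of n−1 direction indices into the basis-vector set —
so every genetic operator acts on a compact, always-connected
representation. Because all basis vectors have even coordinate sum, any
chain anchored at the origin stays on the even-parity sublattice; absolute
coordinates exchanged with other software should note this convention.

A *contact* is a residue pair (a, b) with |a − b| > 1 whose points are
lattice-adjacent. The energy of a conformation φ is the sum of pairwise
contact energies

    E(φ) = Σ_{i<j−1} contact(φ(sᵢ), φ(sⱼ)) · energy(sᵢ, sⱼ)

under one of three interchangeable 20×20 potentials:

* **BM** — an empirical (knowledge-based) contact potential in the
  quasi-chemical style. **The bundled table is a synthetic stand-in** (see
  *Synthetic data*, below); any real table in the same TSV format can be
  supplied.
* **HP** — hydrophobic/polar: −1 for H–H contacts, 0 otherwise.
* **GW** — the group-weighted derivation, the core of the package.

## The group-weighted potential

A raw empirical potential gives a search algorithm little help in telling
one large-magnitude interaction from an accumulation of small ones, so
searches guided by it stall in local minima. The GW derivation sorts the
BM energy levels by magnitude |E|, bands them into groups m = 0, 1, …, and
multiplies every entry of band m by

    g_m = 1 + m(m + 1) / 2,

preserving sign. Within a band, relative magnitudes are untouched; across
bands, separation widens monotonically (the scaling can never invert the
cross-band magnitude order, which the test suite checks). Banding is by
magnitude, so strongly repulsive (positive) levels are amplified as much
as strongly attractive ones — favourable contacts are promoted and
unfavourable ones inhibited.

The default scheme has six groups with band edges, in units of |E|×10³:
[0, 100], (100, 500], (500, 1000], (1000, 1500], (1500, 2000), [2000, 3477],
giving multipliers {1, 2, 4, 7, 11, 16}. The printed integer ranges of this
scheme share the value 2000 between the top two bands; assignment is made
deterministic by treating bands as half-open above and sending ties at a
shared edge to the higher group. A single-group scheme collapses GW onto
BM exactly — the identity is an array-equality test, not an approximation.

Search is guided by GW (or whichever potential is configured), but results
are always re-scored and reported on the raw BM scale, so energies are
comparable across guidance modes.

## Genetic search

The search is a generational genetic algorithm over a fixed population of
50 relative-encoded individuals (Algorithm overview: initialize, iterate,
diversify on stagnation, stop on budget):

* **Initialization** — random chain growth: each step samples uniformly
  among directions leading to unoccupied points; a dead end restarts the
  whole chain (up to 1000 restarts, then an error). Simple and unbiased
  enough for start structures.
* **Operators** — one operator is drawn per generation from a fixed
  non-uniform distribution: pull move 0.40, crossover 0.25, diagonal move
  (kink jump / corner flip) 0.20, rotation 0.15. By default each operator
  is applied *exhaustively* to an individual — the full parameter space is
  enumerated and the best-fit valid candidate kept:
  * *pull move*: the pulled residue relocates to a free neighbour of its
    anchor-side neighbour's position; successive residues toward the free
    end step into the position their predecessor just vacated until chain
    adjacency is restored. Every shifted position pair was adjacent in the
    old chain, so results are valid by construction. Enumeration is over
    residue × pulling direction × candidate target.
  * *diagonal move*: single-residue relocation to a free point adjacent to
    both chain neighbours (at most 4 candidates for a middle residue; any
    free neighbour of the anchor for a terminal one). Self-inverse.
  * *rotation*: directions from a start index onward are re-sampled
    uniformly until the chain validates (50 retries per start index);
    "exhaustive" means one re-sample per start index, since enumerating
    all 12^(n−start) suffixes is intractable.
  * *crossover*: a mate is drawn uniformly from the population; both
    children of every cut point are candidates, and the surviving child
    competes against the first parent's slot.
  Ties in the arg-min are broken by enumeration order (residue ascending,
  then basis-vector order), which keeps runs bit-reproducible.
* **Selection** — strictly elitist per slot: a candidate replaces its
  parent only when strictly lower in guidance energy; ties keep the parent.
  The global best is archived outside the population and is therefore
  non-increasing over generations.
* **Stagnation recovery** — after more than a threshold number of
  consecutive non-improving generations, every individual receives
  k = shuffleParameter × max(1, n/10) successive random feasible pull
  moves and is re-scored once; the non-improvement counter resets to zero.
  If two consecutive recoveries bracket no new global best, the shuffle
  parameter is incremented, diversifying harder. The per-length default
  thresholds follow the benchmark table (50 down to 15 as n grows from 54
  to 279, step lookup on the printed rows; note n = 64 already uses 45).
  The k rule and the reset-to-zero semantics are this package's choices
  where the procedure is otherwise underdetermined.
* **Stopping** — wall-clock budget, generation budget, or
  objective-evaluation budget, whichever is configured and hit first. The
  evaluation budget makes runs hardware-independent; it is checked between
  generations, so a run may overshoot by at most one generation's
  candidates.

Cost is accounted as the number of candidate conformations scored — one
tick per candidate, whether the score is computed from scratch or as an
incremental delta over the residues a move displaced. Incremental scoring
is an optimization only; the suite verifies it against from-scratch
evaluation to 1e-9 and audits the counter by call interception.

## Evaluation metrics

* **dRMSD** — superposition-free structural distance: the root mean square
  difference of all n(n−1)/2 intra-structure pairwise Euclidean distances
  (note this runs over *all* pairs, j ≥ i+1, unlike the energy sum which
  starts at j = i+2). Lattice coordinates are compared against native
  α-carbon coordinates (read from PDB files, first model, CA atoms only)
  without rescaling by default; an optional uniform scale factor is
  available.
* **Relative improvement** — R.I. = (E_t − E_r)/E_r × 100 %, positive when
  a (negative) target energy is lower than the reference.
* **Speed-up** — ratio of average objective-evaluation counts,
  reference / target.
* **Trend line** — ordinary least squares by the closed forms
  m = (nΣxy − ΣxΣy)/(nΣx² − (Σx)²), c = (Σy − mΣx)/n.

Report output is conventionally rounded to 2 decimal places; full
precision is kept internally.

## Synthetic data

Two bundled fixtures define the study conditions:

* `benchmarks.tsv` — the 17 benchmark sequences (54–279 residues, PDB and
  CASP9 sets) with their stagnation thresholds, transcribed from the
  printed table and pinned by checksum. The combinatorial anchors of the
  74-residue 1CTF sequence — 2628 potential contacts and 101 distinct
  residue-type pairs over them — follow from the sequence by direct
  enumeration.
* `contact_energies_bm_synthetic.tsv` — a **synthetic** BM-style matrix,
  because the original empirical table is not redistributable here. It is
  constructed once (fixed seed, frozen file) to match the documented
  spectral facts of the real table: symmetric over all 210 unordered
  pairs; magnitudes spanning (0, 3.477] so the six-group scheme's top band
  edge |E|×10³ = 3477 is the strongest contact (Cys–Cys); hydrophobic and
  aromatic pairs strongest, like-charge pairs repulsive (positive),
  opposite-charge pairs moderately attractive; all six magnitude bands
  populated; near-linear sorted-magnitude profile. Absolute energies from
  this table are therefore *not* comparable with published values computed
  under the real table; the package's quantitative claims are confined to
  quantities independent of the table (combinatorics, metric identities)
  and to *relative* comparisons made under one and the same table (GW
  versus BM guidance).

The default HP classification is H = {C, F, I, L, M, V, W, Y}. The split
is calibrated against a published reference count — 149 H–H potential
contacts in 1CTF — which this set reproduces exactly (the
alanine-inclusive variant gives 582); it remains configurable.

What passing tests show, and what they do not: the suite demonstrates the
algorithmic contracts (validity, elitism, determinism, accounting), the GW
derivation's algebra, and the directional benefit of GW guidance under the
synthetic table at desk scale. It does not demonstrate agreement with
published absolute energies, nor native-like folding accuracy — on this
model class the correlation between contact energy and dRMSD to native
structures is known to be weak.

## Problem sizes used in the checked benchmark

The published benchmark campaigns (50 independent runs × 1–2 h per
protein) are out of desk scale. The package's own smoke benchmark runs the
4RXN sequence (n = 54, population 50, GW vs BM guidance) for 5 fixed seeds
at a deterministic budget of 500 000 objective evaluations per run —
roughly a quarter of the evaluation count of a published single run, sized
so stagnation dynamics are reached while the whole comparison stays in the
minutes range. Pass conditions are directional, matching the scale: mean
relative improvement of the GW-guided best over its random initialization
of at least 30 %, and a lower BM-scored best energy than BM guidance under
identical seeds in at least 4 of 5 seeds.

## Numerical choices and edge cases

* Energies are plain double sums of table entries; incremental deltas are
  exact to rounding and are cross-checked against full re-evaluation.
* Equal-energy candidates: the first in enumeration order wins; an equal
  child never replaces its parent.
* Degenerate inputs: chains need n ≥ 2 (relative encoding requires at
  least one direction); potential-contact counts are 0 for n < 3;
  single-residue pulls whose target neighbours both chain neighbours
  reduce to a one-residue relocation; crossover needs n ≥ 3 for a
  non-empty cut range.
* Validation failures are return values (with the first colliding residue
  pair), not exceptions; errors are reserved for malformed input.
* The lattice is unbounded: occupancy is a hash of points, no bounding box.

## Known limitations

* Rotation's "exhaustive" mode samples one suffix per start index; it is
  stochastic by design and the only operator whose enumeration is not
  literally complete.
* The pull-move set is not proven reversible or complete on the FCC
  lattice (a known open point for this move family); the search does not
  rely on ergodicity guarantees.
* With the synthetic table, absolute energies are package-internal
  quantities; swap in a real empirical table for externally comparable
  numbers.
* Wall-clock stopping makes trajectories hardware-dependent; use the
  generation or evaluation budgets for reproducible experiments.
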