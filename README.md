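# gwfold

Ab initio protein folding simulation on the face-centred-cubic (FCC)
lattice, for people studying conformational search and contact-based
energy models: a genetic algorithm with pull-move, diagonal-move, rotation
and crossover operators minimizes a pairwise contact energy over
self-avoiding walks, guided by a **group-weighted (GW)** rescaling of a
20×20 empirical contact potential.

## The idea

Each residue occupies one FCC lattice point (12 neighbours per point); a
conformation φ is a self-avoiding walk stored as a string of n−1 direction
indices. Residues a, b with |a−b| > 1 whose points are lattice-adjacent
form a contact, and the objective is

    E(φ) = Σ_{i<j−1} contact(φ(sᵢ), φ(sⱼ)) · energy(sᵢ, sⱼ).

Raw empirical potentials ("BM") make poor search guidance: they give the
optimizer no way to prefer one strong interaction over a pile of weak
ones, so searches stall in local minima. The GW derivation bands the
energy levels by magnitude into groups m = 0, 1, … and scales each band by

    g_m = 1 + m(m+1)/2   (six default bands → multipliers 1, 2, 4, 7, 11, 16),

preserving signs and within-band order while widening the separation
between strong and weak interactions. The search runs on the GW scale;
results are always re-scored on the BM scale for reporting. A
hydrophobic/polar (HP) potential and raw BM guidance are available as
comparators, and a single-group GW scheme is exactly BM.

The bundled contact table is a **synthetic stand-in** with the documented
spectral properties of the real empirical potential (see
`docs/methods.md`); supply your own TSV for externally comparable
energies.

## Worked example

Fold the 54-residue rubredoxin benchmark (4RXN) with GW guidance under a
deterministic evaluation budget, then score the result:

    $ gwfold fold --benchmark 4RXN --guidance gw --seed 1 \
        --max-evaluations 100000 --out-dir run1
    folding 4RXN: n=54 guidance=GW seed=1
    best BM energy -134.81 (12 generations, 101159 evaluations)

    $ gwfold score --conformation run1/4RXN.best.conf --benchmark 4RXN
    residues:            54
    contacts:            103
    potential contacts:  1378
    contact types:       132
    energy BM:           -134.807
    energy GW:           -1689.986
    energy HP:           -36.000

Reading: the best conformation found within 101 159 scored candidates
forms 103 contacts out of the 1378 residue pairs that could ever form one
(pairs with sequence separation > 1), with energy −134.81 on the BM scale
— the reporting scale — and −1689.99 on the amplified GW scale that
actually guided the search. The run log (`run1/4RXN.log.jsonl`) holds one
deterministic record per generation:

    {"generation": 1, "operator": "rotation", "best_energy": -855.765..., "best_bm_energy": -70.282, "evaluations": 1300}
    {"generation": 2, "operator": "crossover", "best_energy": -936.643..., "best_bm_energy": -76.526, "evaluations": 4415}

Identical flags and seed reproduce these files byte for byte. Add
`--native file.pdb` to `gwfold score` to report the superposition-free
distance-matrix RMSD against native α-carbon coordinates. The same
machinery is available as a library:

```python
from gwfold import GAConfig, load_bm_matrix, run_search, get_benchmark

stats = run_search(get_benchmark("4RXN").sequence,
                   GAConfig(seed=1, guidance="GW", max_evaluations=100_000),
                   load_bm_matrix())
print(stats.best_bm_energy, stats.evaluation_count)
```

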