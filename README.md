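# shellmut

Conservation- and coordination-shell-guided mutation design for
metalloenzymes, plus the enzymology quantitation that goes with validating
the designed mutants.

## The problem

Engineering a multicopper oxidase such as a bacterial laccase usually means
finding a handful of single-site substitutions — out of hundreds of residues
— that raise catalytic efficiency or thermostability. Two signals make that
search tractable:

1. **Evolutionary consensus.** Across a family of homologs, a position where
   the wild-type residue is rare and some other residue dominates is a
   natural substitution candidate. `shellmut` builds a *position-specific
   amino acid probability* (PSAP) matrix: for every query position *i* and
   amino acid *a*, `P_i(a)` is the frequency of *a* among homologs projected
   onto the query frame (gaps excluded from the denominator). Each position
   gets a difference value

   `Δ_i = max_a P_i(a) − P_i(wt_i)`,

   and positions with `Δ > cutoff` (default 0.02) yield candidate mutations
   toward the consensus residue.

2. **Distance to the catalytic metals.** Residues are binned by the minimum
   distance from any of their heavy atoms to any catalytic Cu ion:
   first shell `[0, 5)` Å, second `[5, 8)` Å, third `[8, 12)` Å, outside
   `[12, ∞)`. Candidates outside the third shell are discarded; the shell
   label travels with each design so the spatial distribution of hits can be
   analysed.

Beneficial singles (activity above the wild type) are then combined into
position-disjoint double/triple mutants, and the package quantifies the
assay side: specific activity from A420 readings (`ε = 38 000 M⁻¹ cm⁻¹`,
1 U = 1 µmol product/min), Michaelis–Menten fits (`v = Vmax·[S]/(Km+[S])`,
`kcat = Vmax/[E]`, efficiency `kcat/Km` with delta-method SEs), fold
changes, relative activity/pH profiles, residual-activity time courses,
ΔTm/ΔΔG tables, and HPLC-based degradation percentages.

Seeded synthetic generators (homolog families with planted consensus
shifts, toy structures with residues at planted metal distances, noisy
kinetic data) make every stage testable end to end without external data.

## Worked example

```python
from shellmut import (QuerySequence, filter_homologs, compute_psap,
                      select_candidates, FamilySpec, generate_family,
                      KineticSimSpec, generate_kinetics,
                      fit_michaelis_menten, fold_change)

wt = "MKTAYIAKQRDISFVKSHFSRQLEERLGLIEVQAPILSRV"
members, truth = generate_family(FamilySpec(
    wt_sequence=wt, n_members=500, background_rate=0.0,
    planted_shifts=[(11, "E", 0.9)], seed=1))
query = QuerySequence("WT", wt)
homologs = filter_homologs(query, members, min_identity=0.4,
                           min_coverage=0.5, pre_aligned=True)
matrix = compute_psap(homologs)
for cand in select_candidates(matrix, cutoff=0.02):
    print(cand.name, round(cand.delta, 3))

data = generate_kinetics(KineticSimSpec(Km=0.874, kcat=6.413,
                                        noise_sigma=0.0, replicates=3, seed=1))
print(fit_michaelis_menten(data).summary())
print(f"fold vs WT efficiency: {fold_change(39.786, 7.424):.2f}")
```

prints

```
D11E 0.804
Michaelis-Menten fit: simulated
  n obs             24
  Km     (mM)       0.874 +/- 0.000
  kcat   (min^-1)   6.413 +/- 0.000
  kcat/Km (mM^-1 min^-1) 7.338 +/- 0.000
fold vs WT efficiency: 5.36
```

The family was simulated with a consensus glutamate planted at position 11
(probability 0.9) over a wild-type aspartate, so the realised difference
value ≈ 0.9 − 0.1 = 0.8 and the proposed mutation is `D11E`. The kinetic
fit recovers the generating parameters exactly on noiseless data, and the
fold change compares two catalytic efficiencies (here 39.786 vs
7.424 mM⁻¹ min⁻¹ → 5.36×).

The same operations are available from the shell:

```bash
shellmut psap --query q.fasta --homologs h.fasta --cutoff 0.02 -o out/
shellmut shells --structure model.pdb --metals CU --bounds 5 8 12
shellmut kinetics --data rates.tsv --enzyme-conc 0.1
shellmut run --config run.yaml          # full pipeline, all stages
```

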