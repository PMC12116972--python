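# Methods

## Conservation scoring (PSAP)

Homologs are brought onto the query frame by pairwise global alignment with
`Bio.Align.PairwiseAligner` (BLOSUM62, gap open −11, extend −1). Alignment
columns that are insertions relative to the query are deleted; query
positions with no aligned homolog residue become gaps. This reproduces a
"spliced to the query length" multiple alignment deterministically without
depending on an external MSA tool; a pre-aligned input path (`pre_aligned`
flag / equal-length FASTA) bypasses alignment entirely. Filtering keeps a
candidate when identity (matches / aligned residue–residue columns) and
coverage (aligned query positions / L) are *strictly greater* than the
thresholds (defaults 0.40 and 0.50). Sequences containing ambiguity codes
(B, Z, X, U, O) are rejected with a warning; everything is upper-cased.

The PSAP matrix uses raw frequencies with no pseudocounts, and the
denominator at each column is the number of non-gap observations, so sparse
columns are not biased toward low probabilities; all-gap columns are inert
(zero probabilities, Δ = 0, never selected). The query itself is excluded
from the counts by default (`include_query` reverses this), since the
matrix is meant to describe the homolog family, not the query.

The difference value is Δ = P(argmax residue) − P(wild-type residue). A
higher Δ means the wild type deviates more from the family consensus at
that position — the substitution toward the consensus is then the
candidate. Ties: the argmax is the alphabetically first residue attaining
the maximum, and any tie that includes the wild type forces Δ = 0 (the
position is never selected). `select_candidates` returns, for each position
with Δ > cutoff, the `top_k` most frequent non-wild-type residues
(rank 1 = argmax; residues never observed at the column are not proposed),
sorted by Δ descending with ties broken by position then residue code. The
criterion by which a real campaign proposes two residues at one position is
a judgement call, so `top_k` is configuration (default 1) rather than a
hard-wired rule.

## Coordination shells

A residue's distance to the catalytic metals is the minimum Euclidean
distance over all its non-hydrogen atoms to all metal sites. Heavy-atom
minimum (rather than Cα) is the default because shell membership at the
5–12 Å scale is a side-chain-scale notion; a `ca_only` mode exists for
sensitivity checks. Shell bins are half-open — `[0,5)`, `[5,8)`, `[8,12)`,
`[12,∞)` Å by default — so a residue at exactly a boundary belongs to the
outer bin; the bounds are configurable as a strictly increasing triple.
Metal sites are hetero atoms of configured elements (default CU) in file
order; metal-coordinating residues (e.g. the Cu-binding histidines) are
*not* excluded from assignment, since first-shell positions can still be
legitimate candidates. Structures are read with gemmi: first model only,
alternate conformations resolved to the highest-occupancy atom per atom
name; residues with no heavy atoms are skipped with a warning.

## Design

Candidates are intersected with the shell table (an optional integer offset
reconciles sequence vs author numbering; by default they are assumed
identical); anything outside the outermost bound is dropped, and a
candidate position missing from the structure is an error rather than a
silent drop. "Beneficial" singles are those with measured activity strictly
above a threshold that defaults to the wild-type activity. Combinations are
all position-disjoint tuples of sizes 2..`max_order` over the `top_n`
beneficial singles ranked by activity (defaults 3 and 3, giving the classic
three-pairs-plus-one-triple plan); names are hyphen-joined in ascending
position order, e.g. `I88L-D511E`.

## Enzymology

Specific activity follows Beer–Lambert: µmol product/min =
(ΔA/t)/(ε·ℓ) · V · 10⁶ · dilution, divided by enzyme mass. Defaults:
ε = 38 000 M⁻¹ cm⁻¹ (ABTS at 420 nm), path length 1 cm, reaction volume
1.0 mL — the standard cuvette-scale laccase assay.

Michaelis–Menten fitting is positivity-bounded nonlinear least squares
(`scipy.optimize.curve_fit`, tolerances 1e-14 so noiseless data converges
to machine precision) initialised at Km₀ = median [S], Vmax₀ = max rate.
kcat = Vmax / (enzyme concentration × reaction volume) converts the
per-reaction Vmax (µmol/min) into a turnover number (min⁻¹). The
efficiency kcat/Km is reported with a delta-method SE from the (Km, Vmax)
covariance. Published kinetic tables sometimes print an efficiency that is
the mean of replicate ratios rather than the ratio of the printed means, so
the results object can carry a replicate-ratio mean alongside the
point-estimate ratio; the two need not agree.

Relative activity profiles divide by the maximum (×100); a tied maximum
resolves to the lowest condition and is flagged. Residual activity is
percent of the t = 0 reference. Stability tables pass the stored ΔΔG values
through verbatim and add a recomputed ΔG_mut − ΔG_wt column with a
consistency flag (tolerance 0.005 J, i.e. the rounding of a 2-decimal
table) — published energy tables are not always self-consistent, and the
package flags rather than reconciles. Degradation percent is
(1 − treated/control)·100 from HPLC peak areas, clamped to [0, 100] with a
warning when the treated peak exceeds the control.

## Synthetic data

`generate_family` copies the wild type, applies i.i.d. background
substitutions (default rate 0.02 per position — a mildly diverged family;
closed-loop recovery tests use 0 so the planted positions are the only
signal), and at planted positions draws the consensus residue with the
stated probability (wild type otherwise). The ground-truth table records
the Δ implied by the *realised* counts via an independent counting loop, so
matrix construction can be checked cell-for-cell. Deletion-type indels are
available (`indel_rate`) to exercise the projection path but default off to
keep the ground truth exact. With 1000 members and a planted consensus
probability of 0.9, the realised Δ concentrates within ±0.05 of the nominal
0.8 (binomial standard error ≈ 0.013).

`generate_structure` plants minimal alanine-like residues (N, CA, C, O, CB)
along rays from their metal site, with CA — the nearest heavy atom — at the
target distance (optionally jittered radially, σ in Å); residues attach to
metals round-robin, directed away from the other metals so the planted
distance is also the global minimum. Target distances under 1 Å are
rejected as clashes. The PDB text is syntactically valid for any standard
parser; the residues are chemically meaningless by design. `write_demo_inputs`
assembles a complete pipeline input set (family, structure, activity/
kinetics/stability tables) from these generators; its assay numbers sit on
the U/g and mM⁻¹ min⁻¹ scales of a laccase ABTS assay.

`generate_kinetics` draws rates v = Vmax·[S]/(Km+[S])·exp(σZ) on a substrate
grid spanning 0.1×–10× Km (8 log-spaced levels, 3 replicates, σ = 0.05 by
default). Under these defaults the median relative error of fitted Km is
~3–4% and of kcat ~1–2% over 200 seeded replicates.

What passing these closed-loop tests shows — and does not. The generators
match the *assumptions* of each stage (i.i.d. columns, exact planted
geometry, multiplicative noise). Real homolog families have phylogenetic
correlation (no weighting is applied here), real structures have packing
constraints and model error, and real rate data can have substrate
inhibition; recovery on synthetic data demonstrates correctness of the
computations, not robustness to those effects. Structure-dependent counts
from any particular engineering campaign (how many residues fall within
12 Å, how candidates split across shells) depend on the structural model
used and are not reproducible without it.

## Pipeline

`run_pipeline` executes conservation → shells → design → combinations →
kinetics/stability as configured from a single YAML file in which every
threshold is explicit (identity 0.40, coverage 0.50, cutoff 0.02, bounds
5/8/12 Å, top_k/top_n/max_order). Any stage error aborts with the stage
name and the offending input path. Outputs are TSV tables plus a summary;
the run log records parameters and per-stage in/out counts. Runs are
byte-reproducible under a fixed config and seed; the only timestamp lives
in the log. Problem sizes in the test suite and acceptance script (families
of 300–1000 members × 40–80 residues, structures of ≤ 40 residues, 200
kinetic replicates) were chosen so the whole closed loop, including the
recovery statistics, completes in seconds while keeping the binomial and
noise margins comfortably resolved.
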