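"""Seeded synthetic-data generators for closed-loop testing.

Three generators emulate the statistical structure each pipeline stage
consumes:

* :func:`generate_family` — a homolog family as copies of a wild-type
  sequence with i.i.d. background substitutions, plus *planted* consensus
  shifts at chosen positions (the family consensus residue differs from the
  wild type with a controlled probability), with a ground-truth table of the
  per-position difference values implied by the realised counts.
* :func:`generate_structure` — a minimal but syntactically valid PDB with
  metal ions and pseudo-residues whose nearest heavy atom sits at a planted
  distance from its metal, with ground-truth shell labels.
* :func:`generate_kinetics` — Michaelis-Menten rate data with multiplicative
  log-normal noise.

All generators are bitwise reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import AMINO_ACIDS
from .enzymology import KineticDataset

_AA = np.array(list(AMINO_ACIDS))


@dataclass
class FamilySpec:
    """Parameters of a synthetic homolog family.

    background_rate is the per-position probability that a member carries a
    random non-wild-type residue (uniform over the other 19); at planted
    positions the consensus residue is drawn with consensus_probability and
    the wild-type residue otherwise.  indel_rate deletes member positions
    independently, producing unaligned sequences that exercise the
    projection path; it defaults to 0 so ground truth stays exact.
    """

    wt_sequence: str
    n_members: int
    background_rate: float = 0.02
    planted_shifts: list[tuple[int, str, float]] = field(default_factory=list)
    # (1-based position, consensus residue, consensus probability)
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.wt_sequence = self.wt_sequence.upper()
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2")
        if not 0 <= self.background_rate < 1:
            raise ValueError("background_rate must be in [0, 1)")
        if not 0 <= self.indel_rate < 1:
            raise ValueError("indel_rate must be in [0, 1)")
        L = len(self.wt_sequence)
        seen = set()
        for pos, res, p in self.planted_shifts:
            if not 1 <= pos <= L:
                raise ValueError(f"planted position {pos} outside 1..{L}")
            if pos in seen:
                raise ValueError(f"duplicate planted position {pos}")
            if res not in AMINO_ACIDS:
                raise ValueError(f"planted residue {res!r} not canonical")
            if not 0 < p <= 1:
                raise ValueError("consensus probability must be in (0, 1]")
            seen.add(pos)


def generate_family(spec: FamilySpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate a homolog family and its exact realised difference values.

    Returns ``(members, ground_truth)`` where members is a list of
    (id, sequence) pairs and ground_truth has one row per position with the
    realised consensus residue and difference value, computed by direct
    counting over the realised (pre-indel) residues.
    """
    rng = np.random.default_rng(spec.seed)
    L = len(spec.wt_sequence)
    wt = np.array(list(spec.wt_sequence))
    planted = {pos - 1: (res, p) for pos, res, p in spec.planted_shifts}

    matrix = np.tile(wt, (spec.n_members, 1))
    for j in range(L):
        if j in planted:
            res, p = planted[j]
            hit = rng.random(spec.n_members) < p
            matrix[hit, j] = res
            # non-hit members keep the wild-type residue
        elif spec.background_rate > 0:
            hit = rng.random(spec.n_members) < spec.background_rate
            if hit.any():
                others = _AA[_AA != wt[j]]
                matrix[hit, j] = rng.choice(others, size=int(hit.sum()))

    # ground truth by direct counting over realised residues (pre-indel)
    rows = []
    for j in range(L):
        col = matrix[:, j]
        residues, counts = np.unique(col, return_counts=True)
        freqs = dict(zip(residues, counts / spec.n_members))
        wt_p = freqs.get(wt[j], 0.0)
        top = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        delta = 0.0 if wt_p >= top[1] else top[1] - wt_p
        rows.append(
            {
                "position": j + 1,
                "wt": wt[j],
                "consensus": top[0],
                "consensus_prob": top[1],
                "wt_prob": wt_p,
                "delta": delta,
                "planted": j in planted,
            }
        )
    truth = pd.DataFrame(rows)

    members = []
    for i in range(spec.n_members):
        seq = matrix[i]
        if spec.indel_rate > 0:
            keep = rng.random(L) >= spec.indel_rate
            seq = seq[keep]
        members.append((f"member_{i:04d}", "".join(seq)))
    return members, truth


def family_to_fasta(members: list[tuple[str, str]]) -> str:
    return "".join(f">{name}\n{seq}\n" for name, seq in members)


@dataclass
class ToyStructureSpec:
    """Parameters of a toy metalloprotein structure.

    Each planted residue is a minimal alanine-like residue (backbone N, CA,
    C, O plus a CB pseudo-atom) placed radially so that its CA — the nearest
    heavy atom — sits at the target distance (plus radial Gaussian jitter)
    from its metal site.
    """

    metal_positions: list[tuple[float, float, float]]
    planted_residues: list[tuple[str, float]] = field(default_factory=list)
    # (3-letter residue name, target min distance in angstrom)
    jitter_sigma: float = 0.0
    metal_element: str = "CU"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.metal_positions:
            raise ValueError("at least one metal position required")
        for _, d in self.planted_residues:
            if d < 1.0:
                raise ValueError(f"target distance {d} inside hard-sphere clash (< 1 A)")


def _pdb_atom(serial, name, resname, chain, resseq, xyz, element, hetatm=False):
    rec = "HETATM" if hetatm else "ATOM  "
    aname = name if len(name) == 4 else f" {name:<3s}"
    x, y, z = xyz
    return (
        f"{rec}{serial:5d} {aname:<4s} {resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def generate_structure(spec: ToyStructureSpec) -> tuple[str, pd.DataFrame]:
    """Emit PDB text plus a ground-truth table of intended shells.

    Residue i is attached to metal ``i mod n_metals`` along a direction
    pointing away from the other metals, so the planted distance is also the
    minimum over all metal sites whenever the planted distances are smaller
    than the inter-metal separations.
    """
    rng = np.random.default_rng(spec.seed)
    metals = np.asarray(spec.metal_positions, dtype=float)
    lines = []
    truth_rows = []
    serial = 1

    for i, (resname, target) in enumerate(spec.planted_residues):
        m = i % len(metals)
        anchor = metals[m]
        if len(metals) > 1:
            away = anchor - np.delete(metals, m, axis=0).mean(axis=0)
            if np.linalg.norm(away) < 1e-9:
                away = rng.normal(size=3)
        else:
            away = rng.normal(size=3)
        # random tilt keeps residues from stacking on one axis
        direction = away / np.linalg.norm(away) + 0.3 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        d0 = target + (rng.normal(0.0, spec.jitter_sigma) if spec.jitter_sigma else 0.0)
        d0 = max(d0, 1.0)
        # CA nearest; other heavy atoms strictly farther out along the ray
        resseq = i + 1
        for name, extra in (("N", 1.5), ("CA", 0.0), ("C", 2.0), ("O", 3.0), ("CB", 1.2)):
            xyz = anchor + (d0 + extra) * direction
            element = name[0]
            lines.append(_pdb_atom(serial, name, resname, "A", resseq, xyz, element))
            serial += 1
        truth_rows.append(
            {
                "position": resseq,
                "resname": resname,
                "target_distance_A": target,
                "realized_distance_A": d0,
                "shell": _implied_shell(d0),
                "nearest_metal": f"{spec.metal_element.upper()}{m + 1}",
            }
        )

    for m, pos in enumerate(metals):
        lines.append(
            _pdb_atom(
                serial,
                spec.metal_element.upper(),
                spec.metal_element.upper(),
                "B",
                m + 1,
                pos,
                spec.metal_element.upper(),
                hetatm=True,
            )
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n", pd.DataFrame(truth_rows)


def _implied_shell(d: float, bounds=(5.0, 8.0, 12.0)) -> str:
    b1, b2, b3 = bounds
    if d < b1:
        return "first"
    if d < b2:
        return "second"
    if d < b3:
        return "third"
    return "outside"


@dataclass
class KineticSimSpec:
    """Parameters of a simulated Michaelis-Menten experiment.

    The default substrate grid spans 0.1x to 10x Km on a log scale (8
    levels), the classic design for resolving both parameters; noise is
    multiplicative log-normal with sigma on the log scale.
    """

    Km: float  # mM
    kcat: float  # min^-1
    enzyme_concentration: float = 0.1  # uM
    reaction_volume: float = 1.0e-3  # L
    substrate: np.ndarray | None = None  # mM
    noise_sigma: float = 0.05
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("Km", "kcat", "enzyme_concentration", "reaction_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.substrate is None:
            self.substrate = np.geomspace(0.1 * self.Km, 10 * self.Km, 8)
        self.substrate = np.asarray(self.substrate, dtype=float)


DEMO_WT = "MKTAYIAKQRDISFVKSHFSRQLEERLGLIEVQAPILSRV"
# planted consensus shifts: (1-based position, consensus residue, probability)
DEMO_SHIFTS = [(5, "L", 0.9), (11, "E", 0.9), (20, "K", 0.9), (33, "F", 0.9)]
# one residue per query position; positions 5/11/20 inside the shells,
# position 33 outside, the rest spread over 4-14 angstrom
DEMO_DISTANCES = {5: 3.0, 11: 6.0, 20: 9.0, 33: 13.0}


def write_demo_inputs(outdir, seed: int = 0, n_members: int = 300) -> dict[str, str]:
    """Write a complete synthetic input set for an end-to-end pipeline run.

    Produces query/homolog FASTA with planted consensus shifts, a toy
    structure placing each query position at a controlled distance from a
    Cu ion, and assay tables (single-mutant activities, noiseless
    Michaelis-Menten rate data, melting temperatures).  Returns the file
    paths keyed by pipeline config field name.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    members, truth = generate_family(
        FamilySpec(
            wt_sequence=DEMO_WT,
            n_members=n_members,
            background_rate=0.0,
            planted_shifts=DEMO_SHIFTS,
            seed=int(rng.integers(2**31)),
        )
    )
    (outdir / "query.fasta").write_text(f">WT\n{DEMO_WT}\n")
    (outdir / "homologs.fasta").write_text(family_to_fasta(members))
    truth.to_csv(outdir / "family_truth.tsv", sep="\t", index=False)

    L = len(DEMO_WT)
    planted = [
        ("ALA", DEMO_DISTANCES.get(pos, 4.0 + 10.0 * (pos % 7) / 6.0))
        for pos in range(1, L + 1)
    ]
    pdb_text, struct_truth = generate_structure(
        ToyStructureSpec(
            metal_positions=[(0.0, 0.0, 0.0)],
            planted_residues=planted,
            seed=int(rng.integers(2**31)),
        )
    )
    (outdir / "structure.pdb").write_text(pdb_text)
    struct_truth.to_csv(outdir / "structure_truth.tsv", sep="\t", index=False)

    # single-mutant activities for the three in-shell planted candidates,
    # on the U/g scale of a laccase ABTS assay
    singles = []
    for (pos, res, _), act in zip(DEMO_SHIFTS[:3], (811.38, 794.72, 732.87)):
        singles.append((f"{DEMO_WT[pos - 1]}{pos}{res}", act))
    lines = ["enzyme\tactivity_U_per_g", "WT\t255.95"]
    lines += [f"{name}\t{act}" for name, act in singles]
    (outdir / "activities.tsv").write_text("\n".join(lines) + "\n")

    kin_rows = ["enzyme\tsubstrate_mM\trate_umol_min\tenzyme_conc_uM"]
    for enzyme, km, kcat in (("WT", 0.874, 6.413), ("MUT", 0.405, 16.100)):
        data = generate_kinetics(
            KineticSimSpec(Km=km, kcat=kcat, noise_sigma=0.0, replicates=3, seed=0)
        )
        for s, v in zip(data.substrate, data.rates):
            kin_rows.append(f"{enzyme}\t{s:.6f}\t{v:.9e}\t{data.enzyme_concentration}")
    (outdir / "kinetics.tsv").write_text("\n".join(kin_rows) + "\n")

    (outdir / "stability.tsv").write_text(
        "enzyme\tTm_C\tdG_J\tddG_J\n"
        "WT\t66.07\t379.14\t\n"
        "MUT\t69.40\t378.53\t-0.39\n"
    )

    return {
        "query_fasta": str(outdir / "query.fasta"),
        "homologs_fasta": str(outdir / "homologs.fasta"),
        "structure": str(outdir / "structure.pdb"),
        "activities": str(outdir / "activities.tsv"),
        "kinetics": str(outdir / "kinetics.tsv"),
        "stability": str(outdir / "stability.tsv"),
    }


def generate_kinetics(spec: KineticSimSpec) -> KineticDataset:
    """Simulate noisy rate measurements from true (Km, kcat)."""
    rng = np.random.default_rng(spec.seed)
    s = np.repeat(spec.substrate, spec.replicates)
    vmax = spec.kcat * spec.enzyme_concentration * spec.reaction_volume  # umol/min
    v = vmax * s / (spec.Km + s)
    if spec.noise_sigma > 0:
        v = v * np.exp(rng.normal(0.0, spec.noise_sigma, size=s.size))
    return KineticDataset(
        substrate=s,
        rates=v,
        enzyme_concentration=spec.enzyme_concentration,
        reaction_volume=spec.reaction_volume,
        enzyme_id="simulated",
    )
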