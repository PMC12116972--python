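import numpy as np
import pytest

from shellmut.conservation import (
    AMINO_ACIDS,
    HomologMember,
    HomologSet,
    QuerySequence,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_homolog_set(query_seq: str, member_seqs: list[str]) -> HomologSet:
    """Build a HomologSet directly from query-frame sequences (test shortcut)."""
    query = QuerySequence("query", query_seq)
    members = [
        HomologMember(f"m{i}", seq, identity=1.0, coverage=1.0)
        for i, seq in enumerate(member_seqs)
    ]
    return HomologSet(query, members, min_identity=0.4, min_coverage=0.5)


def random_alignment(rng, n_members: int, length: int, gap_rate: float = 0.0):
    """Random query + query-frame member sequences over the 20 AA codes."""
    aa = list(AMINO_ACIDS)
    query = "".join(rng.choice(aa, size=length))
    members = []
    for _ in range(n_members):
        seq = rng.choice(aa, size=length)
        if gap_rate > 0:
            gaps = rng.random(length) < gap_rate
            seq = np.where(gaps, "-", seq)
        members.append("".join(seq))
    return query, members


@pytest.fixture
def toy_structure_file(tmp_path):
    """PDB with one Cu and four residues planted at 3/6/9/13 angstrom."""
    from shellmut.synthdata import ToyStructureSpec, generate_structure

    spec = ToyStructureSpec(
        metal_positions=[(0.0, 0.0, 0.0)],
        planted_residues=[("ALA", 3.0), ("ALA", 6.0), ("ALA", 9.0), ("ALA", 13.0)],
        seed=11,
    )
    pdb_text, truth = generate_structure(spec)
    path = tmp_path / "toy.pdb"
    path.write_text(pdb_text)
    return path, truth
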