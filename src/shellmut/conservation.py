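"""Position-specific amino acid probability (PSAP) analysis.

Builds a per-column probability distribution over the 20 canonical amino
acids from a family of homologs projected onto the query frame, scores each
query position by the *difference value*

    delta(i) = P(argmax residue at column i) - P(wild-type residue at i),

and proposes candidate substitutions at positions where delta exceeds a
cutoff.  A large delta means the wild-type residue deviates strongly from
the family consensus at that position, making the consensus residue a
natural substitution candidate.

Homologs are brought onto the query frame by pairwise global alignment
(BLOSUM62, affine gaps): alignment columns that are insertions relative to
the query are dropped, and query positions with no aligned homolog residue
become gaps.  All positions are reported 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"


class NoHomologsRetainedError(ValueError):
    """All candidate sequences fell below the identity/coverage thresholds."""


@dataclass(frozen=True)
class QuerySequence:
    """A query protein sequence in one-letter code, positions 1-based."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        object.__setattr__(self, "residues", seq)
        if len(seq) == 0:
            raise ValueError("query sequence must be non-empty")
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"query {self.id!r} contains non-canonical residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HomologMember:
    """A homolog projected onto the query frame (length L over 20 AA + gap)."""

    id: str
    sequence: str
    identity: float
    coverage: float


@dataclass
class HomologSet:
    """Query plus the homologs that passed filtering, all on the query frame."""

    query: QuerySequence
    members: list[HomologMember]
    min_identity: float
    min_coverage: float

    def __post_init__(self) -> None:
        L = len(self.query)
        for m in self.members:
            if len(m.sequence) != L:
                raise ValueError(
                    f"member {m.id!r} has projected length {len(m.sequence)} != {L}"
                )

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PSAPMatrix:
    """Per-position amino-acid probabilities with consensus-deviation scores.

    Attributes
    ----------
    probs : (L, 20) ndarray
        Column-normalised residue frequencies; rows with no non-gap
        observations are all zero and flagged via ``n_effective == 0``.
    n_effective : (L,) ndarray of int
        Non-gap observation count per column.
    wt_prob, diff : (L,) ndarray
        Probability of the query residue, and the difference value delta.
    argmax_residue : (L,) array of str
        Highest-probability residue per column (lexicographic tie-break).
    """

    query: QuerySequence
    probs: np.ndarray
    n_effective: np.ndarray
    wt_prob: np.ndarray
    diff: np.ndarray
    argmax_residue: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per position with the 20 AA columns plus scores."""
        df = pd.DataFrame(self.probs, columns=list(AMINO_ACIDS))
        df.insert(0, "position", np.arange(1, len(self.query) + 1))
        df.insert(1, "wt", list(self.query.residues))
        df["n_effective"] = self.n_effective
        df["wt_prob"] = self.wt_prob
        df["argmax"] = self.argmax_residue
        df["delta"] = self.diff
        return df


@dataclass(frozen=True)
class CandidateMutation:
    """A proposed single-site substitution, e.g. D511E."""

    position: int  # 1-based
    wt_residue: str
    proposed_residue: str
    delta: float
    rank_in_column: int  # 1 = column argmax

    def __post_init__(self) -> None:
        if self.proposed_residue == self.wt_residue:
            raise ValueError("proposed residue equals wild type")

    @property
    def name(self) -> str:
        return f"{self.wt_residue}{self.position}{self.proposed_residue}"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _validate_candidate(seq_id: str, seq: str) -> str | None:
    seq = seq.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        logger.warning(
            "rejecting sequence %r: non-canonical characters %s", seq_id, sorted(bad)
        )
        return None
    return seq


def _project(query: str, candidate: str, aligner: Align.PairwiseAligner):
    """Globally align candidate to query and project onto the query frame.

    Returns (projected sequence of length L, identity, coverage) where
    identity = matches / aligned residue-residue columns and coverage =
    query positions aligned to a homolog residue / L.
    """
    alignment = aligner.align(query, candidate)[0]
    L = len(query)
    projected = [GAP] * L
    matches = 0
    aligned_pairs = 0
    for (qs, qe), (cs, ce) in zip(*alignment.aligned):
        for qi, ci in zip(range(qs, qe), range(cs, ce)):
            projected[qi] = candidate[ci]
            aligned_pairs += 1
            if query[qi] == candidate[ci]:
                matches += 1
    identity = matches / aligned_pairs if aligned_pairs else 0.0
    coverage = aligned_pairs / L
    return "".join(projected), identity, coverage


def _stats_pre_aligned(query: str, candidate: str):
    matches = 0
    aligned = 0
    for q, c in zip(query, candidate):
        if c != GAP:
            aligned += 1
            if q == c:
                matches += 1
    identity = matches / aligned if aligned else 0.0
    return identity, aligned / len(query)


def filter_homologs(
    query: QuerySequence,
    candidates,
    min_identity: float = 0.40,
    min_coverage: float = 0.50,
    pre_aligned: bool = False,
) -> HomologSet:
    """Retain candidates exceeding identity and coverage thresholds.

    Parameters
    ----------
    candidates : iterable of (id, sequence)
        Unaligned homolog sequences, or query-frame sequences of length L
        (possibly with ``-`` gaps) when ``pre_aligned`` is true.
    min_identity, min_coverage : float in (0, 1]
        A candidate is kept only if its pairwise-alignment identity and
        query coverage are *strictly greater* than these thresholds.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate collection is empty")
    for thr, name in ((min_identity, "min_identity"), (min_coverage, "min_coverage")):
        if not 0 < thr <= 1:
            raise ValueError(f"{name} must lie in (0, 1], got {thr}")

    aligner = None if pre_aligned else _make_aligner()
    L = len(query)
    members: list[HomologMember] = []
    for seq_id, raw in candidates:
        if pre_aligned:
            seq = raw.upper()
            bad = set(seq) - set(AMINO_ACIDS) - {GAP}
            if bad:
                logger.warning(
                    "rejecting sequence %r: non-canonical characters %s",
                    seq_id, sorted(bad),
                )
                continue
            if len(seq) != L:
                raise ValueError(
                    f"pre-aligned sequence {seq_id!r} has length {len(seq)}, expected {L}"
                )
            projected = seq
            identity, coverage = _stats_pre_aligned(query.residues, seq)
        else:
            seq = _validate_candidate(seq_id, raw.replace(GAP, ""))
            if seq is None:
                continue
            if not seq:
                logger.warning("rejecting empty sequence %r", seq_id)
                continue
            projected, identity, coverage = _project(query.residues, seq, aligner)
        if identity > min_identity and coverage > min_coverage:
            members.append(HomologMember(seq_id, projected, identity, coverage))

    if not members:
        raise NoHomologsRetainedError(
            f"no homologs retained at identity > {min_identity} "
            f"and coverage > {min_coverage}"
        )
    return HomologSet(query, members, min_identity, min_coverage)


def compute_psap(homologs: HomologSet, include_query: bool = False) -> PSAPMatrix:
    """Count residue frequencies per query column and score consensus deviation.

    Gaps are excluded from the denominator, so ``probs[i]`` is conditioned on
    the column being observed; all-gap columns carry zero probabilities and
    delta = 0.  The query itself is excluded from counts unless
    ``include_query`` is set.
    """
    L = len(homologs.query)
    counts = np.zeros((L, len(AMINO_ACIDS)), dtype=np.int64)
    sequences = [m.sequence for m in homologs.members]
    if include_query:
        sequences.append(homologs.query.residues)
    for seq in sequences:
        for i, aa in enumerate(seq):
            if aa != GAP:
                counts[i, AA_INDEX[aa]] += 1

    n_eff = counts.sum(axis=1)
    probs = np.zeros_like(counts, dtype=float)
    populated = n_eff > 0
    probs[populated] = counts[populated] / n_eff[populated, None]

    wt_idx = np.array([AA_INDEX[aa] for aa in homologs.query.residues])
    wt_prob = probs[np.arange(L), wt_idx]
    # lexicographic tie-break: argmax on a stable scan returns the first
    # (alphabetically smallest) residue attaining the maximum
    argmax_idx = probs.argmax(axis=1)
    max_prob = probs[np.arange(L), argmax_idx]
    # delta = 0 whenever the WT residue attains the column maximum (incl. ties)
    wt_attains_max = np.isclose(wt_prob, max_prob)
    diff = np.where(populated & ~wt_attains_max, max_prob - wt_prob, 0.0)
    argmax_residue = np.array([AMINO_ACIDS[j] for j in argmax_idx])
    argmax_residue[~populated] = GAP

    return PSAPMatrix(
        query=homologs.query,
        probs=probs,
        n_effective=n_eff,
        wt_prob=wt_prob,
        diff=diff,
        argmax_residue=argmax_residue,
    )


def select_candidates(
    matrix: PSAPMatrix, cutoff: float = 0.02, top_k: int = 1
) -> list[CandidateMutation]:
    """Propose substitutions at every position with delta > cutoff.

    At each selected position the ``top_k`` highest-probability non-wild-type
    residues are proposed (rank 1 = column argmax).  Results are sorted by
    delta descending, then position ascending, then residue code.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")

    out: list[CandidateMutation] = []
    for i in np.flatnonzero(matrix.diff > cutoff):
        wt = matrix.query.residues[i]
        ranked = sorted(
            (aa for aa in AMINO_ACIDS if aa != wt),
            key=lambda aa: (-matrix.probs[i, AA_INDEX[aa]], aa),
        )
        for rank, aa in enumerate(ranked[:top_k], start=1):
            if matrix.probs[i, AA_INDEX[aa]] == 0:
                break  # never propose an unobserved residue
            out.append(
                CandidateMutation(
                    position=int(i) + 1,
                    wt_residue=wt,
                    proposed_residue=aa,
                    delta=float(matrix.diff[i]),
                    rank_in_column=rank,
                )
            )
    out.sort(key=lambda c: (-c.delta, c.position, c.proposed_residue))
    return out


def candidates_to_frame(candidates: list[CandidateMutation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mutation": c.name,
                "position": c.position,
                "wt": c.wt_residue,
                "proposed": c.proposed_residue,
                "delta": c.delta,
                "rank_in_column": c.rank_in_column,
            }
            for c in candidates
        ],
        columns=["mutation", "position", "wt", "proposed", "delta", "rank_in_column"],
    )
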