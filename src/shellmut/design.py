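"""Mutation design: intersect conservation candidates with coordination shells
and build multi-site combinations from beneficial single mutants.

Mutation names follow the standard one-letter convention WT+position+proposed
(e.g. ``D511E``); combination names join single names with hyphens in
ascending position order (``I88L-D511E``).
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .conservation import CandidateMutation
from .shells import ShellAssignment

logger = logging.getLogger(__name__)

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutation(name: str) -> tuple[str, int, str]:
    """Parse 'D511E' -> ('D', 511, 'E')."""
    m = _MUTATION_RE.match(name)
    if not m:
        raise ValueError(f"malformed mutation name: {name!r}")
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass(frozen=True)
class DesignRow:
    candidate: CandidateMutation
    assignment: ShellAssignment
    mutation_name: str


@dataclass
class DesignTable:
    rows: list[DesignRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mutation": r.mutation_name,
                    "position": r.candidate.position,
                    "wt": r.candidate.wt_residue,
                    "proposed": r.candidate.proposed_residue,
                    "delta": r.candidate.delta,
                    "rank_in_column": r.candidate.rank_in_column,
                    "shell": r.assignment.shell,
                    "min_distance_A": r.assignment.min_distance,
                    "nearest_metal": r.assignment.nearest_metal,
                }
                for r in self.rows
            ],
            columns=[
                "mutation", "position", "wt", "proposed", "delta",
                "rank_in_column", "shell", "min_distance_A", "nearest_metal",
            ],
        )

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class CombinationPlan:
    """Beneficial singles and the multi-site combinations built from them."""

    beneficial_singles: list[tuple[str, float]]  # (mutation name, activity U/g)
    combos: list[tuple[str, ...]] = field(default_factory=list)

    @staticmethod
    def combo_name(combo: tuple[str, ...]) -> str:
        return "-".join(sorted(combo, key=lambda n: parse_mutation(n)[1]))

    @property
    def combo_names(self) -> list[str]:
        return [self.combo_name(c) for c in self.combos]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"combo": self.combo_name(c), "order": len(c)} for c in self.combos],
            columns=["combo", "order"],
        )


def intersect_candidates(
    candidates: list[CandidateMutation],
    assignments: list[ShellAssignment],
    numbering_offset: int = 0,
) -> DesignTable:
    """Keep candidates that fall inside the outermost shell bound.

    ``numbering_offset`` is added to candidate (sequence) positions to obtain
    structure numbering, for models whose author numbering is shifted.
    Candidates assigned ``outside`` are dropped; candidates at positions
    absent from the structure raise.
    """
    by_pos = {a.resnum: a for a in assignments}
    missing = sorted(
        {c.position + numbering_offset for c in candidates} - set(by_pos)
    )
    if missing:
        raise KeyError(f"candidate positions absent from structure: {missing}")

    rows = []
    for c in candidates:
        a = by_pos[c.position + numbering_offset]
        if a.shell == "outside":
            continue
        rows.append(DesignRow(candidate=c, assignment=a, mutation_name=c.name))
    return DesignTable(rows)


def build_combinations(
    singles: list[tuple[str, float]],
    activity_threshold: float,
    top_n: int = 3,
    max_order: int = 3,
) -> CombinationPlan:
    """Enumerate position-disjoint combinations of the best beneficial singles.

    Parameters
    ----------
    singles : list of (mutation name, measured activity U/g)
    activity_threshold : float
        A single is *beneficial* if its activity is strictly greater than
        this value (typically the wild-type activity).
    top_n : int
        Number of top beneficial singles, ranked by activity, to combine.
    max_order : int
        Largest combination size; all sizes 2..max_order are produced.
    """
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    if max_order < 2:
        raise ValueError("max_order must be >= 2")

    beneficial = sorted(
        (s for s in singles if s[1] > activity_threshold),
        key=lambda s: -s[1],
    )
    plan = CombinationPlan(beneficial_singles=beneficial)
    if len(beneficial) < 2:
        logger.warning(
            "fewer than 2 beneficial singles (threshold %.2f); no combinations",
            activity_threshold,
        )
        return plan

    pool = [name for name, _ in beneficial[:top_n]]
    for k in range(2, max_order + 1):
        for combo in itertools.combinations(pool, k):
            positions = [parse_mutation(n)[1] for n in combo]
            if len(set(positions)) == len(positions):  # no repeated positions
                plan.combos.append(combo)
    return plan
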