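"""End-to-end orchestration: conservation -> shells -> design -> enzymology.

A single config object carries every threshold as an explicit value (query
identity/coverage filters, difference-value cutoff, shell bounds, combination
sizes) so a run is fully described by its config and seed.  Outputs are
plain TSV tables plus a human-readable summary; the run log records all
parameters and per-stage counts.  Given the same config and seed, all report
files are byte-identical across runs (only the log carries a timestamp).
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import conservation, design, enzymology, shells
from .io import read_fasta, read_tsv, write_tsv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    query_fasta: str
    homologs_fasta: str
    structure: str | None = None
    activities: str | None = None  # TSV: enzyme, activity_U_per_g
    kinetics: str | None = None  # TSV: enzyme, substrate_mM, rate_umol_min, enzyme_conc_uM
    stability: str | None = None  # TSV: enzyme, Tm_C, dG_J, ddG_J
    wt_id: str = "WT"
    min_identity: float = 0.40
    min_coverage: float = 0.50
    cutoff: float = 0.02
    shell_bounds: tuple[float, float, float] = (5.0, 8.0, 12.0)
    metals: tuple[str, ...] = ("CU",)
    top_k: int = 1
    top_n: int = 3
    max_order: int = 3
    pre_aligned: bool = False
    include_query: bool = False
    seed: int = 0
    output_dir: str = "shellmut_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.shell_bounds = tuple(cfg.shell_bounds)
        cfg.metals = tuple(cfg.metals)
        return cfg

    def validate(self) -> None:
        if not 0 < self.min_identity <= 1 or not 0 < self.min_coverage <= 1:
            raise PipelineError("config: identity/coverage thresholds must be in (0, 1]")
        if self.cutoff < 0:
            raise PipelineError("config: cutoff must be >= 0")
        b1, b2, b3 = self.shell_bounds
        if not 0 < b1 < b2 < b3:
            raise PipelineError(f"config: bad shell bounds {self.shell_bounds}")
        for name in ("query_fasta", "homologs_fasta", "structure", "activities",
                     "kinetics", "stability"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise PipelineError(f"config: {name} file not found: {path}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the in-memory result bundle."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"started: {datetime.datetime.now().isoformat()}", "parameters:"]
    for key, val in vars(config).items():
        log_lines.append(f"  {key}: {val}")
    bundle: dict = {}

    # --- conservation ---------------------------------------------------
    try:
        query_records = read_fasta(config.query_fasta)
        if not query_records:
            raise ValueError("query FASTA is empty")
        qid, qseq = query_records[0]
        query = conservation.QuerySequence(qid, qseq)
        candidates_raw = read_fasta(config.homologs_fasta)
        homologs = conservation.filter_homologs(
            query,
            candidates_raw,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            pre_aligned=config.pre_aligned,
        )
        matrix = conservation.compute_psap(homologs, include_query=config.include_query)
        cands = conservation.select_candidates(
            matrix, cutoff=config.cutoff, top_k=config.top_k
        )
    except Exception as exc:
        raise PipelineError(
            f"conservation stage failed on {config.homologs_fasta}: {exc}"
        ) from exc
    write_tsv(matrix.to_frame(), outdir / "psap.tsv")
    bundle["matrix"] = matrix
    bundle["candidates"] = cands
    log_lines += [
        f"conservation: {len(candidates_raw)} sequences in, {len(homologs)} retained",
        f"conservation: {len(cands)} candidate mutations at delta > {config.cutoff}",
    ]

    # --- shells + design ------------------------------------------------
    table = None
    if config.structure is not None:
        try:
            structure = shells.read_structure(config.structure)
            metal_sites = shells.find_metal_sites(structure, config.metals)
            assignments = shells.assign_shells(
                structure, metal_sites, bounds=config.shell_bounds
            )
            table = design.intersect_candidates(cands, assignments)
        except Exception as exc:
            raise PipelineError(
                f"shells/design stage failed on {config.structure}: {exc}"
            ) from exc
        write_tsv(shells.assignments_to_frame(assignments), outdir / "shells.tsv")
        write_tsv(table.to_frame(), outdir / "candidates.tsv")
        bundle["assignments"] = assignments
        bundle["design_table"] = table
        counts = shells.shell_summary(assignments)
        log_lines += [
            f"shells: {len(metal_sites)} metal sites, {len(assignments)} residues assigned",
            f"shells: per-shell counts {counts}",
            f"design: {len(table)} candidates inside {config.shell_bounds[2]} A",
        ]
    else:
        write_tsv(conservation.candidates_to_frame(cands), outdir / "candidates.tsv")

    # --- combinations ---------------------------------------------------
    plan = None
    if config.activities is not None:
        try:
            adf = read_tsv(config.activities)
            wt_rows = adf[adf["enzyme"] == config.wt_id]
            if wt_rows.empty:
                raise ValueError(f"wild-type id {config.wt_id!r} absent from activities")
            wt_activity = float(wt_rows["activity_U_per_g"].iloc[0])
            singles = [
                (row["enzyme"], float(row["activity_U_per_g"]))
                for _, row in adf.iterrows()
                if row["enzyme"] != config.wt_id
            ]
            plan = design.build_combinations(
                singles, wt_activity, top_n=config.top_n, max_order=config.max_order
            )
        except Exception as exc:
            raise PipelineError(
                f"combination stage failed on {config.activities}: {exc}"
            ) from exc
        write_tsv(plan.to_frame(), outdir / "combos.tsv")
        bundle["plan"] = plan
        log_lines.append(
            f"design: {len(plan.beneficial_singles)} beneficial singles, "
            f"{len(plan.combos)} combinations"
        )

    # --- enzymology -----------------------------------------------------
    kin_df = None
    if config.kinetics is not None:
        try:
            kdf = read_tsv(config.kinetics)
            fits = {}
            for enzyme, grp in kdf.groupby("enzyme", sort=True):
                data = enzymology.KineticDataset(
                    substrate=grp["substrate_mM"].to_numpy(),
                    rates=grp["rate_umol_min"].to_numpy(),
                    enzyme_concentration=float(grp["enzyme_conc_uM"].iloc[0]),
                    enzyme_id=str(enzyme),
                )
                fits[str(enzyme)] = enzymology.fit_michaelis_menten(data)
            wt_eff = fits[config.wt_id].efficiency if config.wt_id in fits else None
            rows = []
            for enzyme in sorted(fits):
                f = fits[enzyme]
                rows.append(
                    {
                        "enzyme": enzyme,
                        "Km_mM": f.Km,
                        "Km_se": f.Km_se,
                        "kcat_min": f.kcat,
                        "kcat_se": f.kcat_se,
                        "efficiency_mM_min": f.efficiency,
                        "efficiency_se": f.efficiency_se,
                        "efficiency_fold_vs_wt": (
                            round(enzymology.fold_change(f.efficiency, wt_eff), 2)
                            if wt_eff else float("nan")
                        ),
                    }
                )
            kin_df = pd.DataFrame(rows)
        except Exception as exc:
            raise PipelineError(
                f"enzymology stage failed on {config.kinetics}: {exc}"
            ) from exc
        write_tsv(kin_df, outdir / "kinetics.tsv")
        bundle["kinetics"] = kin_df
        log_lines.append(f"enzymology: fitted {len(kin_df)} enzymes")

    stab_df = None
    if config.stability is not None:
        try:
            sdf = read_tsv(config.stability)
            records = [
                enzymology.StabilityRecord(
                    enzyme=str(r["enzyme"]),
                    Tm=float(r["Tm_C"]),
                    dG_stability=float(r["dG_J"]),
                    ddG_vs_wt=(None if pd.isna(r.get("ddG_J")) else float(r["ddG_J"])),
                )
                for _, r in sdf.iterrows()
            ]
            stab_df = enzymology.stability_deltas(records, config.wt_id)
        except Exception as exc:
            raise PipelineError(
                f"stability stage failed on {config.stability}: {exc}"
            ) from exc
        write_tsv(stab_df, outdir / "stability.tsv")
        bundle["stability"] = stab_df

    _write_summary(outdir / "summary.md", config, bundle)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    bundle["output_dir"] = outdir
    return bundle


def _write_summary(path: Path, config: RunConfig, bundle: dict) -> None:
    lines = ["# shellmut run summary", ""]
    cands = bundle["candidates"]
    lines.append(f"Candidate mutations (delta > {config.cutoff}): {len(cands)}")
    if "design_table" in bundle:
        table = bundle["design_table"]
        per_shell: dict[str, int] = {}
        for row in table.rows:
            per_shell[row.assignment.shell] = per_shell.get(row.assignment.shell, 0) + 1
        inside = ", ".join(
            f"{per_shell.get(s, 0)} {s}" for s in ("first", "second", "third")
        )
        lines.append(f"Candidates within {config.shell_bounds[2]} A: {len(table)} ({inside})")
        lines.append("")
        lines.append("```\n" + table.to_frame().round(3).to_string(index=False) + "\n```")
    if "plan" in bundle and bundle["plan"] is not None:
        plan = bundle["plan"]
        lines += ["", f"Beneficial singles: {len(plan.beneficial_singles)}",
                  f"Combinations: {', '.join(plan.combo_names) or '(none)'}"]
    if "kinetics" in bundle and bundle["kinetics"] is not None:
        lines += ["", "## Kinetics", "", "```\n" + bundle["kinetics"].round(3).to_string(index=False) + "\n```"]
    if "stability" in bundle and bundle["stability"] is not None:
        lines += ["", "## Stability", "", "```\n" + bundle["stability"].round(3).to_string(index=False) + "\n```"]
    path.write_text("\n".join(lines) + "\n")
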