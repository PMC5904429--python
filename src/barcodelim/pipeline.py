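"""End-to-end orchestration: distances -> tree -> diagnostics -> reports.

:func:`run_all` executes every stage on one dataset (read from disk or
simulated) and writes the full set of report files to an output directory.
All randomness flows from a single seed, so a rerun with the same inputs is
byte-identical apart from timestamps in the log.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diagnostics import classify_sites, diagnostic_report, pure_diagnostic_sites
from .distance import barcode_gap, distance_matrix, summaries_to_frame, summarize_species
from .seqio import read_alignment, write_distance_matrix, write_newick
from .synthetic import study_config, simulate_dataset, write_dataset
from .tree import (
    TRIVIALLY_MONOPHYLETIC,
    bootstrap_support,
    clade_support_by_species,
    root_with_outgroup,
)

__all__ = ["RunConfig", "RunSummary", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: either file inputs or simulation, never both."""

    alignment: Path | None = None
    metadata: Path | None = None
    simulate: bool = False
    outgroup_species: tuple[str, ...] = ()
    bootstrap_replicates: int = 1000
    seed: int = 0
    support_min_display: int = 50
    outdir: Path = Path("barcodelim_out")

    def __post_init__(self) -> None:
        file_mode = self.alignment is not None or self.metadata is not None
        if file_mode == self.simulate:
            raise ValueError(
                "choose exactly one of file inputs (--alignment/--metadata) "
                "or --simulate"
            )
        if file_mode and (self.alignment is None or self.metadata is None):
            raise ValueError("file mode needs both an alignment and a metadata table")


@dataclass
class RunSummary:
    """What a run produced: output paths and per-species verdicts."""

    outputs: dict[str, Path]
    verdicts: pd.DataFrame
    tree_built: bool


def _setup_run_logger(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    logging.getLogger("barcodelim").addHandler(handler)
    return handler


def run_all(config: RunConfig) -> RunSummary:
    """Run every stage and write the report files.

    Outputs (in ``config.outdir``): distances.tsv/.phy, species_summary.tsv,
    barcode_gap.tsv, tree.nwk, clade_support.tsv, site_classification.tsv,
    diagnostics.tsv, diagnostic_grid.tsv, diagnostic_mask.tsv, verdicts.tsv
    and run.log.  With fewer than 3 specimens the tree stage is skipped with
    a warning; distances and diagnostics are still produced.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logger(outdir)
    outputs: dict[str, Path] = {"run_log": outdir / "run.log"}
    try:
        logger.info("barcodelim %s, seed %d", __version__, config.seed)
        if config.simulate:
            logger.info("stage input: simulating dataset")
            aln, truth = simulate_dataset(study_config(seed=config.seed))
            ds = write_dataset(aln, truth, outdir / "simulated")
            outputs.update({f"simulated_{k}": v for k, v in ds.items()})
        else:
            logger.info("stage input: reading %s", config.alignment)
            aln = read_alignment(config.alignment, config.metadata)
        labels = aln.species_labels
        outgroup = tuple(config.outgroup_species)
        unknown = set(outgroup) - set(aln.species_set)
        if unknown:
            raise ValueError(f"outgroup species not in dataset: {sorted(unknown)}")

        # --- distances -----------------------------------------------------
        logger.info("stage distances: %d specimens", len(aln))
        dm = distance_matrix(aln)
        outputs["distances"] = outdir / "distances.tsv"
        write_distance_matrix(dm, outputs["distances"])
        outputs["distances_phylip"] = outdir / "distances.phy"
        summaries = summarize_species(dm, labels, outgroup)
        outputs["species_summary"] = outdir / "species_summary.tsv"
        summaries_to_frame(summaries).to_csv(
            outputs["species_summary"], sep="\t", index=False
        )
        gap = barcode_gap(summaries)
        gap_rows = [
            {"species": sp, "gap": "NA" if g is None else f"{g:.4f}"}
            for sp, g in gap.gaps.items()
        ]
        outputs["barcode_gap"] = outdir / "barcode_gap.tsv"
        pd.DataFrame(gap_rows).to_csv(outputs["barcode_gap"], sep="\t", index=False)

        # --- tree ----------------------------------------------------------
        tree_built = False
        clade_support: dict[str, int | str] = {}
        if len(aln) >= 3:
            logger.info(
                "stage tree: NJ + %d bootstrap replicates", config.bootstrap_replicates
            )
            tree = bootstrap_support(
                aln, replicates=config.bootstrap_replicates, seed=config.seed
            )
            if outgroup:
                og_ids = [i for i in aln.ids if labels[i] in outgroup]
                tree = root_with_outgroup(tree, og_ids)
            outputs["tree"] = outdir / "tree.nwk"
            write_newick(tree, outputs["tree"], config.support_min_display)
            clade_support = {
                sp: v
                for sp, v in clade_support_by_species(tree, labels).items()
                if sp not in outgroup
            }
            outputs["clade_support"] = outdir / "clade_support.tsv"
            pd.DataFrame(
                [{"species": sp, "support": v} for sp, v in clade_support.items()]
            ).to_csv(outputs["clade_support"], sep="\t", index=False)
            tree_built = True
        else:
            logger.warning("stage tree skipped: fewer than 3 specimens")

        # --- sites & diagnostics -------------------------------------------
        logger.info("stage diagnostics")
        sc = classify_sites(aln)
        outputs["site_classification"] = outdir / "site_classification.tsv"
        pd.DataFrame(
            [
                {
                    "n_sites": sc.n_sites,
                    "n_constant": sc.n_constant,
                    "n_variable": sc.n_variable,
                    "n_parsimony_informative": sc.n_parsimony_informative,
                }
            ]
        ).to_csv(outputs["site_classification"], sep="\t", index=False)
        diag = pure_diagnostic_sites(aln, labels, outgroup)
        outputs["diagnostics"] = outdir / "diagnostics.tsv"
        diag.to_frame().to_csv(outputs["diagnostics"], sep="\t", index=False)
        grid, mask = diagnostic_report(diag, aln, labels, outgroup)
        outputs["diagnostic_grid"] = outdir / "diagnostic_grid.tsv"
        outputs["diagnostic_mask"] = outdir / "diagnostic_mask.tsv"
        grid.to_csv(outputs["diagnostic_grid"], sep="\t")
        mask.to_csv(outputs["diagnostic_mask"], sep="\t")

        # --- verdicts ------------------------------------------------------
        rows = []
        for s in summaries:
            sp = s.species
            mono = clade_support.get(sp)
            if not tree_built:
                mono_txt = "tree skipped"
            elif mono == TRIVIALLY_MONOPHYLETIC:
                mono_txt = "yes (trivial)"
            elif isinstance(mono, int):
                mono_txt = "yes"
            else:
                mono_txt = "no"
            g = gap.gaps.get(sp)
            rows.append(
                {
                    "species": sp,
                    "monophyletic": mono_txt,
                    "clade_support": mono if isinstance(mono, int) else "NA",
                    "n_pure_diagnostics": len(diag.by_species.get(sp, [])),
                    "has_diagnostic": bool(diag.by_species.get(sp)),
                    "barcode_gap_positive": "NA" if g is None else bool(g > 0),
                }
            )
        verdicts = pd.DataFrame(rows)
        outputs["verdicts"] = outdir / "verdicts.tsv"
        verdicts.to_csv(outputs["verdicts"], sep="\t", index=False)
        logger.info("run complete: %d species verdicts", len(verdicts))
        return RunSummary(outputs=outputs, verdicts=verdicts, tree_built=tree_built)
    except Exception as err:  # annotate the failing stage for the CLI
        logger.error("run aborted: %s", err)
        raise
    finally:
        logging.getLogger("barcodelim").removeHandler(handler)
        handler.close()
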