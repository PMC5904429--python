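"""Site classification and pure diagnostic nucleotide characters.

A *pure* diagnostic character for species S is an alignment column where
every non-missing specimen of S carries one fixed state and no non-missing
specimen of any other species carries that state (the "pure simple"
character of character-based delimitation).  Missing residues — gaps, N,
IUPAC ambiguity codes — neither support nor contradict a diagnosis: a
species entirely missing at a column cannot be diagnosed there, and a
specimen missing at a column does not veto an otherwise fixed state.

Positions are 1-based alignment coordinates throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqio import BarcodeAlignment

__all__ = [
    "SiteClassification",
    "DiagnosticTable",
    "classify_sites",
    "pure_diagnostic_sites",
    "private_nonfixed_sites",
    "diagnostic_report",
]

CONSTANT = "constant"
VARIABLE_UNINFORMATIVE = "variable_uninformative"
PARSIMONY_INFORMATIVE = "parsimony_informative"
ALL_MISSING = "all_missing"


@dataclass
class SiteClassification:
    """Column-wise classification of an alignment.

    A column's non-missing states determine its class: zero distinct states
    -> all_missing; one -> constant; two or more -> variable, and
    parsimony-informative when at least two states each occur in at least
    two specimens.
    """

    n_sites: int
    n_constant: int
    n_variable: int
    n_parsimony_informative: int
    per_site: list[str]


def classify_sites(aln: BarcodeAlignment) -> SiteClassification:
    """Classify every alignment column; counts match the per-site labels."""
    enc = aln.encoded()
    per_site: list[str] = []
    n_const = n_var = n_pi = 0
    for col in enc.T:
        states = col[col >= 0]
        if states.size == 0:
            per_site.append(ALL_MISSING)
            continue
        vals, counts = np.unique(states, return_counts=True)
        if len(vals) == 1:
            per_site.append(CONSTANT)
            n_const += 1
        elif int((counts >= 2).sum()) >= 2:
            per_site.append(PARSIMONY_INFORMATIVE)
            n_var += 1
            n_pi += 1
        else:
            per_site.append(VARIABLE_UNINFORMATIVE)
            n_var += 1
    return SiteClassification(
        n_sites=aln.length,
        n_constant=n_const,
        n_variable=n_var,
        n_parsimony_informative=n_pi,
        per_site=per_site,
    )


@dataclass
class DiagnosticTable:
    """Pure diagnostic sites per species.

    ``by_species`` maps species -> list of (1-based position, fixed state);
    ``positions`` is the sorted union of diagnostic positions.
    """

    by_species: dict[str, list[tuple[int, str]]]
    positions: list[int] = field(init=False)

    def __post_init__(self) -> None:
        pos: set[int] = set()
        for sites in self.by_species.values():
            pos.update(p for p, _ in sites)
        self.positions = sorted(pos)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": sp, "position": p, "state": s}
            for sp, sites in self.by_species.items()
            for p, s in sites
        ]
        return pd.DataFrame(rows, columns=["species", "position", "state"])


_BASES = "ACGT"


def pure_diagnostic_sites(
    aln: BarcodeAlignment,
    labels: Mapping[str, str] | None = None,
    outgroup_species: Iterable[str] = (),
) -> DiagnosticTable:
    """Scan every column for states fixed in one species and absent elsewhere.

    ``labels`` defaults to the alignment's own species labels; specimens of
    ``outgroup_species`` are excluded from the scan entirely.  A species may
    legitimately have zero diagnostics (empty list).
    """
    if labels is None:
        labels = aln.species_labels
    out_sp = set(outgroup_species)
    keep = [k for k, sid in enumerate(aln.ids) if labels[sid] not in out_sp]
    species = [s for s in aln.species_set if s not in out_sp]
    if len(species) < 2:
        raise ValueError("diagnostic scan needs at least 2 (ingroup) species")
    enc = aln.encoded()[keep]
    sp_of_row = np.array([species.index(labels[aln.ids[k]]) for k in keep])
    by_species: dict[str, list[tuple[int, str]]] = {s: [] for s in species}
    n_sp = len(species)
    for j in range(enc.shape[1]):
        col = enc[:, j]
        present = col >= 0
        if not present.any():
            continue
        states = np.unique(col[present])
        if len(states) < 2:
            continue  # a constant column is never diagnostic
        for si in range(n_sp):
            mine = sp_of_row == si
            mine_present = mine & present
            if not mine_present.any():
                continue  # species entirely missing here
            my_states = np.unique(col[mine_present])
            if len(my_states) != 1:
                continue  # not fixed within the species
            x = my_states[0]
            others_present = ~mine & present
            if np.any(col[others_present] == x):
                continue  # state occurs outside the species
            by_species[species[si]].append((j + 1, _BASES[x]))
    return DiagnosticTable(by_species=by_species)


def private_nonfixed_sites(
    aln: BarcodeAlignment,
    labels: Mapping[str, str] | None = None,
    outgroup_species: Iterable[str] = (),
) -> dict[str, list[tuple[int, str]]]:
    """Secondary category: states private to one species but not fixed in it.

    Kept separate from :func:`pure_diagnostic_sites`; these columns carry a
    state found only within one species yet not shared by all its
    (non-missing) specimens, so they are suggestive rather than diagnostic.
    """
    if labels is None:
        labels = aln.species_labels
    out_sp = set(outgroup_species)
    keep = [k for k, sid in enumerate(aln.ids) if labels[sid] not in out_sp]
    species = [s for s in aln.species_set if s not in out_sp]
    enc = aln.encoded()[keep]
    sp_of_row = np.array([species.index(labels[aln.ids[k]]) for k in keep])
    out: dict[str, list[tuple[int, str]]] = {s: [] for s in species}
    for j in range(enc.shape[1]):
        col = enc[:, j]
        present = col >= 0
        for si, sp in enumerate(species):
            mine = (sp_of_row == si) & present
            others = (sp_of_row != si) & present
            if not mine.any():
                continue
            my_states = set(col[mine].tolist())
            other_states = set(col[others].tolist())
            private = my_states - other_states
            for x in sorted(private):
                if len(my_states) > 1:  # not fixed -> private only
                    out[sp].append((j + 1, _BASES[x]))
    return out


def diagnostic_report(
    table: DiagnosticTable, aln: BarcodeAlignment,
    labels: Mapping[str, str] | None = None,
    outgroup_species: Iterable[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Specimen-by-position state grid plus a boolean diagnostic mask.

    Rows are specimens grouped by species; columns are the sorted union of
    diagnostic positions; cells show the residue or ``-`` for missing.  The
    mask flags cells lying at a position diagnostic for that specimen's
    species (the machine-readable stand-in for shading).
    """
    if labels is None:
        labels = aln.species_labels
    out_sp = set(outgroup_species)
    positions = table.positions
    diag_pos = {
        sp: {p for p, _ in sites} for sp, sites in table.by_species.items()
    }
    seq_of = dict(zip(aln.ids, aln.sequences))
    rows, mask_rows, index = [], [], []
    for sp in aln.species_set:
        if sp in out_sp:
            continue
        for sid in aln.ids:
            if labels[sid] != sp:
                continue
            seq = seq_of[sid]
            cells, flags = [], []
            for p in positions:
                ch = seq[p - 1]
                cells.append(ch if ch in _BASES else "-")
                flags.append(ch in _BASES and p in diag_pos.get(sp, set()))
            rows.append([sp] + cells)
            mask_rows.append([sp] + flags)
            index.append(sid)
    cols = ["species"] + [str(p) for p in positions]
    grid = pd.DataFrame(rows, columns=cols, index=index)
    mask = pd.DataFrame(mask_rows, columns=cols, index=index)
    grid.index.name = "specimen_id"
    mask.index.name = "specimen_id"
    return grid, mask
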