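"""Reading and writing barcode alignments, distance matrices and trees.

The central container is :class:`BarcodeAlignment`: an aligned set of
specimen sequences, each tied to a :class:`SpecimenRecord` carrying the
species label used throughout the delimitation pipeline.  Sequences are
normalised on ingest (upper-case, ``U`` mapped to ``T``); every residue
outside the four canonical bases — ``N``, IUPAC ambiguity codes, ``-``,
``?`` — is treated as a single "missing" class by all downstream
computation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SpecimenRecord",
    "BarcodeAlignment",
    "AlignmentLengthError",
    "UnknownSpecimenError",
    "DuplicateSpecimenError",
    "read_alignment",
    "write_alignment",
    "write_distance_matrix",
    "write_newick",
    "encode_sequences",
    "MISSING",
]

#: Integer codes for the four canonical bases; everything else is missing.
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
#: Code used for any residue outside {A, C, G, T} (gaps, N, IUPAC ambiguity).
MISSING = -1

_SEX_VALUES = {"male", "female", "unknown"}


class AlignmentLengthError(ValueError):
    """Raised when input sequences do not all share one alignment length."""


class UnknownSpecimenError(KeyError):
    """Raised when a FASTA record id has no row in the metadata table."""


class DuplicateSpecimenError(ValueError):
    """Raised when a specimen id occurs more than once."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One voucher specimen: id, species label and optional provenance."""

    specimen_id: str
    species: str
    sex: str = "unknown"
    accession: str | None = None
    locality: str | None = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        if not self.species:
            raise ValueError(f"species label empty for specimen {self.specimen_id!r}")
        if self.sex not in _SEX_VALUES:
            raise ValueError(
                f"sex must be one of {sorted(_SEX_VALUES)}, got {self.sex!r}"
            )


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class BarcodeAlignment:
    """An aligned set of barcode sequences with per-specimen species labels.

    ``records`` preserves input order; every sequence has exactly ``length``
    residues.  Residues are upper-cased and ``U`` is mapped to ``T`` on
    construction.
    """

    records: list[tuple[SpecimenRecord, str]]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 records")
        norm: list[tuple[SpecimenRecord, str]] = []
        length = len(self.records[0][1])
        seen: set[str] = set()
        for rec, seq in self.records:
            seq = _normalise(seq)
            if len(seq) != length:
                raise AlignmentLengthError(
                    f"record {rec.specimen_id!r} has length {len(seq)}, "
                    f"expected {length}"
                )
            if rec.specimen_id in seen:
                raise DuplicateSpecimenError(
                    f"duplicate specimen id {rec.specimen_id!r}"
                )
            seen.add(rec.specimen_id)
            norm.append((rec, seq))
        self.records = norm
        self.length = length

    # -- convenience views -------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [rec.specimen_id for rec, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    @property
    def species_labels(self) -> dict[str, str]:
        """Mapping specimen_id -> species label."""
        return {rec.specimen_id: rec.species for rec, _ in self.records}

    @property
    def species_set(self) -> list[str]:
        """Distinct species labels in first-appearance order."""
        out: list[str] = []
        for rec, _ in self.records:
            if rec.species not in out:
                out.append(rec.species)
        return out

    def __len__(self) -> int:
        return len(self.records)

    def encoded(self) -> np.ndarray:
        """(n_specimens, length) int8 matrix; missing residues are -1."""
        return encode_sequences(self.sequences)

    def subset(self, ids: Iterable[str]) -> "BarcodeAlignment":
        wanted = set(ids)
        kept = [(r, s) for r, s in self.records if r.specimen_id in wanted]
        missing = wanted - {r.specimen_id for r, _ in kept}
        if missing:
            raise UnknownSpecimenError(f"ids not in alignment: {sorted(missing)}")
        return BarcodeAlignment(kept)


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode aligned sequences as int8: A,C,G,T -> 0..3, anything else -> -1."""
    lut = np.full(256, MISSING, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        lut[ord(base)] = code
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return lut[arr].reshape(len(seqs), -1)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = ("specimen_id", "species")


def read_metadata(path: str | Path) -> dict[str, SpecimenRecord]:
    """Read the specimen metadata TSV (header required).

    Required columns: ``specimen_id``, ``species``; optional: ``sex``,
    ``accession``, ``locality``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _METADATA_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"metadata {path} lacks required column {col!r}")
    out: dict[str, SpecimenRecord] = {}
    for _, row in df.iterrows():
        rec = SpecimenRecord(
            specimen_id=row["specimen_id"],
            species=row["species"],
            sex=row.get("sex", "unknown") or "unknown",
            accession=row.get("accession") or None,
            locality=row.get("locality") or None,
        )
        if rec.specimen_id in out:
            raise DuplicateSpecimenError(
                f"duplicate specimen id {rec.specimen_id!r} in metadata"
            )
        out[rec.specimen_id] = rec
    return out


def read_alignment(fasta_path: str | Path, metadata_path: str | Path) -> BarcodeAlignment:
    """Assemble a :class:`BarcodeAlignment` from an aligned FASTA + metadata TSV.

    The join key is the FASTA record id up to the first whitespace.  All
    sequences must share one length; every FASTA id must resolve to a
    metadata row.
    """
    meta = read_metadata(metadata_path)
    records: list[tuple[SpecimenRecord, str]] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sid = rec.id.split()[0]
        if sid not in meta:
            raise UnknownSpecimenError(
                f"FASTA record {sid!r} has no metadata row in {metadata_path}"
            )
        records.append((meta[sid], str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return BarcodeAlignment(records)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_alignment(
    aln: BarcodeAlignment, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Write the alignment back out in the same FASTA + TSV dialect we read."""
    with open(fasta_path, "w") as fh:
        for rec, seq in aln.records:
            fh.write(f">{rec.specimen_id}\n{seq}\n")
    rows = [
        {
            "specimen_id": rec.specimen_id,
            "species": rec.species,
            "sex": rec.sex,
            "accession": rec.accession or "",
            "locality": rec.locality or "",
        }
        for rec, _ in aln.records
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def write_distance_matrix(matrix, path: str | Path) -> None:
    """Write a distance matrix as a square TSV plus lower-triangular PHYLIP text.

    ``path`` receives the TSV; a sibling file with suffix ``.phy`` receives
    the relaxed-PHYLIP lower triangle.  Values are printed with 4 decimals.
    """
    ids = list(matrix.ids)
    if len(ids) == 0:
        raise ValueError("cannot write an empty distance matrix")
    d = np.asarray(matrix.d, dtype=float)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("specimen_id\t" + "\t".join(ids) + "\n")
        for i, sid in enumerate(ids):
            fh.write(sid + "\t" + "\t".join(f"{v:.4f}" for v in d[i]) + "\n")
    phy = path.with_suffix(".phy")
    with open(phy, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for i, sid in enumerate(ids):
            cells = "  ".join(f"{d[i, j]:.4f}" for j in range(i))
            fh.write(f"{sid}  {cells}".rstrip() + "\n")


def newick_string(tree, support_min_display: int = 50) -> str:
    """Render a :class:`~barcodelim.tree.PhyloTree` as Newick.

    Internal-node labels carry bootstrap percentages; supports below
    ``support_min_display`` are omitted from the rendered label only — the
    in-memory tree keeps every support value.
    """
    support = tree.split_support or {}
    all_leaves = frozenset(tree.leaf_names())

    def canon(side: frozenset) -> frozenset:
        ref = min(all_leaves)
        return side if ref not in side else all_leaves - side

    def render(node) -> str:
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else (node.label or "")
            out = _quote_newick_label(label)
        else:
            inner = ",".join(render(c) for c in node.child_nodes())
            label = ""
            side = frozenset(
                lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
            )
            key = canon(side)
            if key in support and support[key] >= support_min_display:
                label = str(support[key])
            out = f"({inner}){label}"
        el = node.edge.length
        if el is not None and node.parent_node is not None:
            out += f":{el:.6f}"
        return out

    return render(tree.tree.seed_node) + ";"


def _quote_newick_label(label: str) -> str:
    if re.search(r"[\s()\[\]{}:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree, path: str | Path, support_min_display: int = 50) -> None:
    """Write a tree as Newick; see :func:`newick_string` for the label rules."""
    with open(path, "w") as fh:
        fh.write(newick_string(tree, support_min_display=support_min_display) + "\n")
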