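"""Uncorrected p-distances and per-species distance summaries.

The p-distance between two aligned sequences is the proportion of differing
sites among the sites comparable in that pair.  Comparability uses
*pairwise deletion*: a column is dropped for a pair only when either member
is missing (gap, ``N`` or ambiguity code) at that column, so different pairs
may be compared over different site counts.

Per-species summaries mirror the usual barcoding table: for each species,
min/max/mean/SD of the distances over all conspecific pairs (intraspecific)
and over all pairs between that species and every other ingroup specimen
(interspecific).  The SD is the sample standard deviation (denominator
n - 1) of those pairwise values; single-pair species get ``NA``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import BarcodeAlignment, encode_sequences

__all__ = [
    "UndefinedDistanceError",
    "DistanceMatrix",
    "SpeciesDistanceSummary",
    "GapReport",
    "p_distance",
    "distance_matrix",
    "summarize_species",
    "summaries_to_frame",
    "barcode_gap",
    "bootstrap_se_of_means",
]

logger = logging.getLogger(__name__)


class UndefinedDistanceError(ValueError):
    """A pair of sequences shares zero comparable sites (disjoint coverage)."""


@dataclass
class DistanceMatrix:
    """Symmetric specimen-by-specimen p-distance matrix.

    ``d[i, j]`` is the proportion of differing sites for the pair;
    ``n_sites[i, j]`` is the number of sites compared after pairwise
    deletion.
    """

    ids: list[str]
    d: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        self.n_sites = np.asarray(self.n_sites, dtype=int)
        if self.d.shape != (n, n) or self.n_sites.shape != (n, n):
            raise ValueError("matrix shapes must match id count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.d < 0) or np.any(self.d > 1):
            raise ValueError("p-distances must lie in [0, 1]")

    def pair(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)], self.n_sites[np.ix_(idx, idx)])


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Uncorrected p-distance between two aligned sequences.

    Returns ``(distance, sites_compared)``.  Columns where either residue
    is missing are excluded; raises :class:`UndefinedDistanceError` if no
    comparable column remains.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    enc = encode_sequences([seq_a, seq_b])
    a, b = enc[0], enc[1]
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites between the pair")
    mism = int(((a != b) & valid).sum())
    return mism / n, n


def _pair_tables(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Per-pair per-column mismatch and validity tables.

    Returns boolean arrays of shape (n_pairs, n_columns) for mismatches and
    comparable columns, plus the (i, j) pair index list (i < j).  These
    tables let the bootstrap re-score resampled columns without touching
    the raw sequences again.
    """
    n = enc.shape[0]
    pairs = list(combinations(range(n), 2))
    valid = enc >= 0
    mm = np.empty((len(pairs), enc.shape[1]), dtype=bool)
    vv = np.empty_like(mm)
    for k, (i, j) in enumerate(pairs):
        v = valid[i] & valid[j]
        vv[k] = v
        mm[k] = (enc[i] != enc[j]) & v
    return mm, vv, pairs


def distances_from_tables(
    mm: np.ndarray, vv: np.ndarray, pairs: list[tuple[int, int]], n: int,
    columns: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble square (d, n_sites) matrices from pair tables.

    ``columns`` optionally selects (with repetition) the alignment columns
    to score — the bootstrap path.  Raises :class:`UndefinedDistanceError`
    if any pair has zero comparable columns.
    """
    if columns is not None:
        mmc = mm[:, columns].sum(axis=1)
        vvc = vv[:, columns].sum(axis=1)
    else:
        mmc = mm.sum(axis=1)
        vvc = vv.sum(axis=1)
    if np.any(vvc == 0):
        k = int(np.argmax(vvc == 0))
        raise UndefinedDistanceError(
            f"no comparable sites for pair index {pairs[k]}"
        )
    d = np.zeros((n, n), dtype=float)
    ns = np.zeros((n, n), dtype=int)
    for k, (i, j) in enumerate(pairs):
        d[i, j] = d[j, i] = mmc[k] / vvc[k]
        ns[i, j] = ns[j, i] = vvc[k]
    return d, ns


def distance_matrix(aln: BarcodeAlignment) -> DistanceMatrix:
    """All-pairs p-distance matrix for an alignment (pairwise deletion)."""
    enc = aln.encoded()
    mm, vv, pairs = _pair_tables(enc)
    try:
        d, ns = distances_from_tables(mm, vv, pairs, len(aln))
    except UndefinedDistanceError as err:
        # name the offending specimen pair, not just its index
        msg = str(err)
        for k, (i, j) in enumerate(pairs):
            if (vv[k].sum()) == 0:
                msg = (
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
                break
        raise UndefinedDistanceError(msg) from None
    # diagonal: a self-comparison spans every non-missing site of the specimen
    np.fill_diagonal(ns, (enc >= 0).sum(axis=1))
    return DistanceMatrix(aln.ids, d, ns)


# ---------------------------------------------------------------------------
# per-species summaries
# ---------------------------------------------------------------------------


@dataclass
class SpeciesDistanceSummary:
    """One species' row of the intra/interspecific distance table.

    Fields are ``None`` (rendered ``NA``) when undefined: intra statistics
    need >= 2 specimens, the intra SD needs >= 2 conspecific pairs, and
    inter statistics need at least one heterospecific ingroup pair.
    """

    species: str
    n_seqs: int
    intra_min: float | None
    intra_max: float | None
    intra_mean: float | None
    intra_sd: float | None
    inter_min: float | None
    inter_max: float | None
    inter_mean: float | None
    inter_sd: float | None


def _stats(values: list[float]) -> tuple[float | None, ...]:
    if not values:
        return (None, None, None, None)
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) >= 2 else None
    return (float(arr.min()), float(arr.max()), float(arr.mean()), sd)


def summarize_species(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    outgroup_species: Iterable[str] = (),
) -> list[SpeciesDistanceSummary]:
    """Per-species intra/interspecific distance summaries (ingroup only).

    ``labels`` maps specimen id -> species.  Each heterospecific pair
    contributes to both species' interspecific rows; outgroup specimens are
    excluded entirely.
    """
    out_sp = set(outgroup_species)
    ids = [i for i in matrix.ids if labels[i] not in out_sp]
    species_order: list[str] = []
    for i in ids:
        if labels[i] not in species_order:
            species_order.append(labels[i])
    idx = {i: matrix.ids.index(i) for i in ids}
    summaries: list[SpeciesDistanceSummary] = []
    for sp in species_order:
        members = [i for i in ids if labels[i] == sp]
        others = [i for i in ids if labels[i] != sp]
        if not members:
            logger.warning("species %r has no specimens; skipped", sp)
            continue
        intra = [
            float(matrix.d[idx[a], idx[b]]) for a, b in combinations(members, 2)
        ]
        inter = [
            float(matrix.d[idx[a], idx[b]]) for a in members for b in others
        ]
        i_min, i_max, i_mean, i_sd = _stats(intra)
        e_min, e_max, e_mean, e_sd = _stats(inter)
        summaries.append(
            SpeciesDistanceSummary(
                species=sp,
                n_seqs=len(members),
                intra_min=i_min,
                intra_max=i_max,
                intra_mean=i_mean,
                intra_sd=i_sd,
                inter_min=e_min,
                inter_max=e_max,
                inter_mean=e_mean,
                inter_sd=e_sd,
            )
        )
    return summaries


_SUMMARY_COLS = [
    "species", "N", "intra_min", "intra_max", "intra_mean", "intra_sd",
    "inter_min", "inter_max", "inter_mean", "inter_sd",
]


def summaries_to_frame(summaries: list[SpeciesDistanceSummary]) -> pd.DataFrame:
    """Tabulate summaries; proportions at 4 decimals, undefined cells ``NA``."""

    def fmt(v: float | None) -> str:
        return "NA" if v is None else f"{v:.4f}"

    rows = [
        {
            "species": s.species,
            "N": s.n_seqs,
            "intra_min": fmt(s.intra_min),
            "intra_max": fmt(s.intra_max),
            "intra_mean": fmt(s.intra_mean),
            "intra_sd": fmt(s.intra_sd),
            "inter_min": fmt(s.inter_min),
            "inter_max": fmt(s.inter_max),
            "inter_mean": fmt(s.inter_mean),
            "inter_sd": fmt(s.inter_sd),
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=_SUMMARY_COLS)


@dataclass
class GapReport:
    """Per-species barcode gap plus the global gap extremes.

    ``gaps`` maps species -> inter_min - intra_max (``None`` when either
    side is undefined).  ``global_max_intra`` is (value, species attaining
    it); ``global_min_inter`` is (value, species tuple attaining it).
    """

    gaps: dict[str, float | None]
    global_max_intra: tuple[float, str] | None
    global_min_inter: tuple[float, tuple[str, ...]] | None


def barcode_gap(summaries: list[SpeciesDistanceSummary]) -> GapReport:
    """Barcode-gap report: separation between intra and inter distances."""
    gaps: dict[str, float | None] = {}
    for s in summaries:
        if s.intra_max is None or s.inter_min is None:
            gaps[s.species] = None
        else:
            gaps[s.species] = s.inter_min - s.intra_max
    intra = [(s.intra_max, s.species) for s in summaries if s.intra_max is not None]
    inter = [(s.inter_min, s.species) for s in summaries if s.inter_min is not None]
    gmax = max(intra) if intra else None
    gmin: tuple[float, tuple[str, ...]] | None = None
    if inter:
        val = min(v for v, _ in inter)
        attaining = tuple(sp for v, sp in inter if math.isclose(v, val, abs_tol=1e-12))
        gmin = (val, attaining)
    return GapReport(gaps=gaps, global_max_intra=gmax, global_min_inter=gmin)


def bootstrap_se_of_means(
    aln: BarcodeAlignment,
    labels: Mapping[str, str],
    outgroup_species: Iterable[str] = (),
    replicates: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap standard errors of the per-species mean distances.

    Site-resampling alternative to the pairwise-value SD printed in the
    summary table: resample alignment columns with replacement
    ``replicates`` times, recompute each species' intra/inter mean distance,
    and report the standard deviation of those replicate means.
    """
    enc = aln.encoded()
    mm, vv, pairs = _pair_tables(enc)
    rng = np.random.default_rng(seed)
    n = len(aln)
    sp_of = dict(labels)
    out_sp = set(outgroup_species)
    species = [s for s in aln.species_set if s not in out_sp]
    intra_means = {s: [] for s in species}
    inter_means = {s: [] for s in species}
    L = enc.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        try:
            d, _ = distances_from_tables(mm, vv, pairs, n, columns=cols)
        except UndefinedDistanceError:
            continue
        dm = DistanceMatrix(aln.ids, d, np.ones((n, n), dtype=int) - np.eye(n, dtype=int))
        for s in summarize_species(dm, sp_of, out_sp):
            if s.intra_mean is not None:
                intra_means[s.species].append(s.intra_mean)
            if s.inter_mean is not None:
                inter_means[s.species].append(s.inter_mean)
    rows = []
    for sp in species:
        rows.append(
            {
                "species": sp,
                "intra_mean_se": float(np.std(intra_means[sp], ddof=1))
                if len(intra_means[sp]) >= 2 else float("nan"),
                "inter_mean_se": float(np.std(inter_means[sp], ddof=1))
                if len(inter_means[sp]) >= 2 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
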