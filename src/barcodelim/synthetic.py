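"""Synthetic barcode datasets with planted species structure.

The generator emulates the statistical shape of a small-group COI barcoding
study: a handful of species, a few specimens each, interspecific p-distances
well above intraspecific ones, at least a few fixed diagnostic sites per
species, and missing-data runs at sequence ends.

Procedure (all randomness from one seed):

1. draw a root sequence uniformly over {A, C, G, T};
2. evolve one ancestral sequence per species down a random binary species
   tree, substituting each non-reserved site with probability
   ``interspecific_divergence`` on tip branches and half that on internal
   branches (uniformly to one of the 3 other bases) — long tips keep even
   sister species well separated while bounding the deepest divergences;
3. overwrite ``n_planted_diagnostics`` reserved columns per species with a
   state unique to that species at that column (reserved columns never
   mutate, so uniqueness is guaranteed by construction);
4. per specimen, copy the species ancestor and apply Poisson-many
   substitutions at non-reserved columns;
5. optionally mask a terminal run of each sequence as ``-``.

The reserved-column convention is a deliberate simplification: it keeps the
planted truth unambiguous so recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import BarcodeAlignment, SpecimenRecord, write_alignment

__all__ = ["SimulationConfig", "TruthTable", "simulate_dataset", "study_config"]

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults match a small COI barcoding study.

    ``interspecific_divergence`` is the per-site substitution probability on
    tip branches of the species tree (internal branches use half of it);
    ``intraspecific_rate`` is the Poisson
    mean number of private substitutions per specimen; ``missing_block`` is
    (probability a sequence gets a terminal missing run, max run length).
    """

    n_species: int = 9
    specimens_per_species: tuple[int, ...] = (7, 3, 2, 6, 3, 2, 2, 5, 5)
    seq_length: int = 662
    interspecific_divergence: float = 0.025
    intraspecific_rate: float = 2.0
    n_planted_diagnostics: int = 3
    missing_block: tuple[float, int] = (0.3, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.specimens_per_species) != self.n_species:
            raise ValueError(
                "specimens_per_species must list one count per species"
            )
        if any(c < 1 for c in self.specimens_per_species):
            raise ValueError("every species needs at least one specimen")
        if self.seq_length < self.n_species * self.n_planted_diagnostics:
            raise ValueError(
                "seq_length too short: reserved diagnostic columns collide"
            )
        for p in (self.interspecific_divergence, self.missing_block[0]):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.intraspecific_rate < 0:
            raise ValueError("intraspecific_rate must be non-negative")


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset.

    ``diagnostics`` holds the planted (species, 1-based position, state)
    triples; ``ancestors`` the per-species ancestral sequences (before
    intraspecific mutation and masking); ``expected`` the divergence targets
    the configuration implies.
    """

    diagnostics: list[tuple[str, int, str]]
    ancestors: dict[str, str]
    expected: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.diagnostics, columns=["species", "position", "state"]
        )


def _random_species_tree(labels: list[str], rng: np.random.Generator):
    """Random binary tree over species labels as nested tuples.

    Built by balanced random bipartition, so tree depth is ~log2(n) and
    leaf-to-leaf paths span 2..2*depth branches.
    """
    if len(labels) == 1:
        return labels[0]
    order = list(rng.permutation(len(labels)))
    half = len(labels) // 2
    left = [labels[i] for i in order[:half]]
    right = [labels[i] for i in order[half:]]
    return (_random_species_tree(left, rng), _random_species_tree(right, rng))


def _evolve(seq: np.ndarray, p: float, mutable: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One branch of evolution: substitute each mutable site w.p. ``p``."""
    child = seq.copy()
    hits = np.where(mutable & (rng.random(seq.size) < p))[0]
    if hits.size:
        # uniform over the 3 alternative bases
        child[hits] = (child[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return child


def simulate_dataset(config: SimulationConfig) -> tuple[BarcodeAlignment, TruthTable]:
    """Generate a labelled alignment plus its ground truth. Deterministic."""
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    species = [f"species_{i + 1:02d}" for i in range(config.n_species)]

    # reserved, non-overlapping diagnostic columns per species
    k = config.n_planted_diagnostics
    reserved_all = rng.choice(L, size=config.n_species * k, replace=False)
    reserved_of = {
        sp: np.sort(reserved_all[i * k : (i + 1) * k])
        for i, sp in enumerate(species)
    }
    mutable = np.ones(L, dtype=bool)
    mutable[reserved_all] = False

    root = rng.integers(0, 4, size=L).astype(np.int8)
    topo = _random_species_tree(species, rng)
    ancestors: dict[str, np.ndarray] = {}

    def descend(node, seq: np.ndarray) -> None:
        if isinstance(node, str):
            ancestors[node] = seq
            return
        for child in node:
            # tip branches carry the full divergence, internal ones half
            p = config.interspecific_divergence
            if not isinstance(child, str):
                p *= 0.5
            descend(child, _evolve(seq, p, mutable, rng))

    descend(topo, root)

    # plant the diagnostics: the owner gets a state differing from the root
    # state shared by everyone else at that (never-mutated) column
    diagnostics: list[tuple[str, int, str]] = []
    for sp in species:
        anc = ancestors[sp].copy()
        for pos in reserved_of[sp]:
            alt = (root[pos] + rng.integers(1, 4)) % 4
            anc[pos] = alt
            diagnostics.append((sp, int(pos) + 1, _BASES[alt]))
        ancestors[sp] = anc

    # specimens: ancestor + Poisson-many private substitutions
    mutable_idx = np.where(mutable)[0]
    records: list[tuple[SpecimenRecord, str]] = []
    prob_miss, max_run = config.missing_block
    for sp, n_spec in zip(species, config.specimens_per_species):
        for s in range(n_spec):
            seq = ancestors[sp].copy()
            n_mut = rng.poisson(config.intraspecific_rate)
            n_mut = min(n_mut, mutable_idx.size)
            if n_mut:
                sites = rng.choice(mutable_idx, size=n_mut, replace=False)
                seq[sites] = (seq[sites] + rng.integers(1, 4, size=n_mut)) % 4
            chars = ["ACGT"[c] for c in seq]
            if prob_miss > 0 and rng.random() < prob_miss:
                run = int(rng.integers(1, max_run + 1))
                if rng.random() < 0.5:
                    chars[:run] = "-" * run
                else:
                    chars[L - run :] = "-" * run
            sid = f"{sp}-{s + 1}"
            records.append(
                (SpecimenRecord(specimen_id=sid, species=sp), "".join(chars))
            )

    aln = BarcodeAlignment(records)
    expected = {
        "intra_pairwise_mean": 2.0 * config.intraspecific_rate / L,
        "per_branch_divergence": config.interspecific_divergence,
    }
    truth = TruthTable(
        diagnostics=diagnostics,
        ancestors={sp: "".join("ACGT"[c] for c in a) for sp, a in ancestors.items()},
        expected=expected,
    )
    return aln, truth


def study_config(seed: int = 1, masking: bool = True) -> SimulationConfig:
    """Configuration shaped like the motivating 35-sequence COI study.

    Nine species with specimen counts (7, 3, 2, 6, 3, 2, 2, 5, 5) summing
    to 35, 662 alignment columns, and divergence tuned so intraspecific
    p-distances fall around 0-3% and interspecific around 5-14%.
    """
    return SimulationConfig(
        n_species=9,
        specimens_per_species=(7, 3, 2, 6, 3, 2, 2, 5, 5),
        seq_length=662,
        interspecific_divergence=0.025,
        intraspecific_rate=2.0,
        n_planted_diagnostics=3,
        missing_block=(0.3, 60) if masking else (0.0, 0),
        seed=seed,
    )


def write_dataset(
    aln: BarcodeAlignment, truth: TruthTable, outdir: str | Path
) -> dict[str, Path]:
    """Emit FASTA + metadata TSV (the dialect the readers accept) + truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "alignment.fasta",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_alignment(aln, paths["fasta"], paths["metadata"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
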