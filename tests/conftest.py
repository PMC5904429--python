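import numpy as np
import pytest

from barcodelim.seqio import BarcodeAlignment, SpecimenRecord


def make_alignment(seq_by_id: dict[str, str], species_by_id: dict[str, str]) -> BarcodeAlignment:
    """Build an alignment from {id: seq} + {id: species} (insertion order kept)."""
    return BarcodeAlignment(
        [
            (SpecimenRecord(specimen_id=i, species=species_by_id[i]), s)
            for i, s in seq_by_id.items()
        ]
    )


@pytest.fixture
def toy_two_species() -> BarcodeAlignment:
    """4 specimens x 8 columns; site 3 separates species X (G) from Y (C).

    Site 8 varies within X (T vs A) so it is not fixed there.
    """
    return make_alignment(
        {
            "x1": "ACGTACGT",
            "x2": "ACGTACGA",
            "y1": "ACCTACGT",
            "y2": "ACCTACGT",
        },
        {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"},
    )


def brute_force_p_distance(a: str, b: str) -> tuple[float, int]:
    """Column-by-column oracle for the p-distance (pairwise deletion)."""
    bases = set("ACGT")
    mism = comp = 0
    for ca, cb in zip(a.upper(), b.upper()):
        if ca in bases and cb in bases:
            comp += 1
            if ca != cb:
                mism += 1
    if comp == 0:
        raise ZeroDivisionError("no comparable sites")
    return mism / comp, comp


def brute_force_diagnostics(
    seqs: dict[str, str], species: dict[str, str]
) -> dict[str, set[tuple[int, str]]]:
    """Independent triple loop (species x column x specimens) oracle."""
    bases = set("ACGT")
    all_species = sorted(set(species.values()))
    length = len(next(iter(seqs.values())))
    out: dict[str, set[tuple[int, str]]] = {sp: set() for sp in all_species}
    for sp in all_species:
        mine = [i for i in seqs if species[i] == sp]
        rest = [i for i in seqs if species[i] != sp]
        for col in range(length):
            my_states = {seqs[i][col] for i in mine if seqs[i][col] in bases}
            other_states = {seqs[i][col] for i in rest if seqs[i][col] in bases}
            if len(my_states) == 1:
                (x,) = my_states
                if x not in other_states and other_states:
                    out[sp].add((col + 1, x))
    return out


def random_alignment(rng: np.random.Generator, n: int, length: int, n_species: int,
                     missing_frac: float = 0.1) -> BarcodeAlignment:
    """Random alignment with random species labels and scattered missing data."""
    alphabet = np.array(list("ACGT-N"))
    probs = np.array([1, 1, 1, 1, 0, 0], dtype=float)
    probs[4] = probs[5] = missing_frac * 2
    probs /= probs.sum()
    seqs = {}
    species = {}
    for i in range(n):
        sid = f"s{i}"
        seqs[sid] = "".join(rng.choice(alphabet, size=length, p=probs))
        species[sid] = f"sp{rng.integers(0, n_species)}"
    return make_alignment(seqs, species), seqs, species
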