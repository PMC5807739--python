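"""Synthetic proteomes with planted composition biases.

Proteins are built as alternating domain/linker blocks flanked by terminal
tails. Domain blocks are sampled from a family-specific residue distribution
obtained by planting a relative enrichment rho on top of realistic background
frequencies; linker blocks may carry their own bias (polar residues, echoing
what real linkers show); tails and domain-free proteins use the plain
background. Annotations are emitted for every domain block with 1-based
inclusive coordinates, and the dictionary holds every family with its
description, so a generated dataset always passes strict input validation.

Planting is exact on the biased letters: an amino acid with relative
enrichment rho ends up at exactly background * (1 + rho) in the family
distribution, and the unbiased letters are scaled down to keep the vector a
distribution. This makes the planted effect directly recoverable: for a
family holding a share s of all domain residues, the expected mean fold
deviation of the planted amino acid is rho * (1 - s) / (1 + s * rho).

A single integer seed drives all randomness through one numpy Generator;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seq_io import (
    STANDARD_AMINO_ACIDS,
    DictionaryEntry,
    DomainAnnotation,
    ProteinRecord,
    Proteome,
)

#: Background amino-acid frequencies (%) close to the Swiss-Prot average,
#: renormalized at use. Keys follow the standard one-letter alphabet.
DEFAULT_BACKGROUND = {
    "A": 8.25, "C": 1.38, "D": 5.46, "E": 6.72, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.91, "K": 5.80, "L": 9.65,
    "M": 2.41, "N": 4.06, "P": 4.74, "Q": 3.93, "R": 5.53,
    "S": 6.63, "T": 5.35, "V": 6.86, "W": 1.10, "Y": 2.92,
}

_LETTERS = np.array(list(STANDARD_AMINO_ACIDS))


@dataclass(frozen=True)
class PlantedFamily:
    """A synthetic domain family with a planted composition bias.

    ``relative_enrichment`` maps amino-acid letters to rho, the relative
    excess over background (0.5 = 50% more frequent than background).
    ``domains_per_protein_rate`` is the Poisson mean of this family's domain
    blocks per multi-domain protein.
    """

    name: str
    description: str
    relative_enrichment: Mapping[str, float] = field(default_factory=dict)
    domains_per_protein_rate: float = 1.0


@dataclass
class GeneratorSpec:
    """Everything that defines one synthetic study.

    Block lengths (domains, linkers, tails) are uniform integers over
    ``length_distribution``. ``p_no_domain`` and ``p_single_domain`` are the
    rates of domain-free and single-domain proteins, exercising the discard
    and no-linker paths; remaining proteins carry at least two domains so
    linkers always exist.
    """

    n_species: int = 5
    proteins_per_species: int = 500
    length_distribution: tuple[int, int] = (40, 120)
    background_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND)
    )
    planted_families: Sequence[PlantedFamily] = ()
    linker_bias: Mapping[str, float] | None = None
    p_no_domain: float = 0.08
    p_single_domain: float = 0.12
    seed: int = 0


def _normalized(freqs: Mapping[str, float]) -> np.ndarray:
    arr = np.array([float(freqs[aa]) for aa in STANDARD_AMINO_ACIDS])
    if np.any(arr < 0):
        raise ValueError("background frequencies must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("background frequencies sum to zero")
    return arr / total


def planted_distribution(
    background: np.ndarray, rho: Mapping[str, float]
) -> np.ndarray:
    """Apply relative enrichments to a background distribution.

    Biased letters are set exactly to background * (1 + rho); the unbiased
    letters are rescaled so the vector still sums to one. Raises when the
    biased letters alone would exceed unit mass or a rho drops a frequency
    below zero.
    """
    if not rho:
        return background.copy()
    out = background.copy()
    idx = {aa: i for i, aa in enumerate(STANDARD_AMINO_ACIDS)}
    biased = np.zeros(len(out), dtype=bool)
    for aa, r in rho.items():
        if aa not in idx:
            raise ValueError(f"unknown amino acid {aa!r} in enrichment map")
        i = idx[aa]
        out[i] = background[i] * (1.0 + float(r))
        if out[i] < 0:
            raise ValueError(f"enrichment {r} drives {aa} frequency below zero")
        biased[i] = True
    biased_mass = out[biased].sum()
    if biased_mass >= 1.0:
        raise ValueError("planted enrichments exceed unit probability mass")
    free = ~biased
    free_mass = background[free].sum()
    if free_mass <= 0:
        out /= out.sum()
    else:
        out[free] = background[free] * (1.0 - biased_mass) / free_mass
    assert abs(out.sum() - 1.0) < 1e-9
    return out


class _BlockSampler:
    """Bulk residue sampler: one big draw per distribution, then sliced."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.needs: dict[str, int] = {}
        self.pools: dict[str, np.ndarray] = {}
        self.cursors: dict[str, int] = {}

    def request(self, key: str, n: int) -> None:
        self.needs[key] = self.needs.get(key, 0) + n

    def materialize(self, distributions: Mapping[str, np.ndarray]) -> None:
        for key in sorted(self.needs):
            n = self.needs[key]
            draws = self.rng.choice(len(_LETTERS), size=n, p=distributions[key])
            self.pools[key] = _LETTERS[draws]
            self.cursors[key] = 0

    def take(self, key: str, n: int) -> str:
        c = self.cursors[key]
        self.cursors[key] = c + n
        return "".join(self.pools[key][c : c + n])


def generate(
    spec: GeneratorSpec,
) -> tuple[dict[str, Proteome], list[DomainAnnotation], dict[str, DictionaryEntry]]:
    """Generate proteomes, matching annotations, and the domain dictionary."""
    if not spec.planted_families:
        raise ValueError("spec needs at least one planted family")
    background = _normalized(spec.background_frequencies)
    distributions = {"__background__": background}
    distributions["__linker__"] = (
        planted_distribution(background, spec.linker_bias)
        if spec.linker_bias
        else background.copy()
    )
    for fam in spec.planted_families:
        distributions[fam.name] = planted_distribution(
            background, fam.relative_enrichment
        )

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_distribution
    rates = np.array([f.domains_per_protein_rate for f in spec.planted_families])
    fam_names = [f.name for f in spec.planted_families]
    weights = rates / rates.sum()

    proteomes: dict[str, Proteome] = {}
    annotations: list[DomainAnnotation] = []
    dictionary = {
        f.name: DictionaryEntry(domain_name=f.name, description=f.description)
        for f in spec.planted_families
    }

    def block_len() -> int:
        return int(rng.integers(lo, hi + 1))

    for si in range(spec.n_species):
        species = f"sp{si:02d}"
        sampler = _BlockSampler(rng)
        # first pass: fix every protein's block structure (rng order matters)
        structures = []  # list of (protein_id, [(dist_key, length, domain_name|None)])
        for pi in range(spec.proteins_per_species):
            protein_id = f"{species}_p{pi:04d}"
            u = rng.random()
            blocks: list[tuple[str, int, str | None]] = []
            if u < spec.p_no_domain:
                n_len = sum(block_len() for _ in range(4))
                blocks.append(("__background__", n_len, None))
            else:
                if u < spec.p_no_domain + spec.p_single_domain:
                    families = [fam_names[rng.choice(len(fam_names), p=weights)]]
                else:
                    counts = rng.poisson(rates)
                    while counts.sum() < 2:
                        counts[rng.choice(len(fam_names), p=weights)] += 1
                    families = [
                        name
                        for name, c in zip(fam_names, counts)
                        for _ in range(int(c))
                    ]
                    rng.shuffle(families)
                blocks.append(("__background__", block_len(), None))  # N tail
                for j, fam in enumerate(families):
                    if j > 0:
                        blocks.append(("__linker__", block_len(), None))
                    blocks.append((fam, block_len(), fam))
                blocks.append(("__background__", block_len(), None))  # C tail
            structures.append((protein_id, blocks))
            for key, n, _ in blocks:
                sampler.request(key, n)
        sampler.materialize(distributions)

        proteome = Proteome(species=species)
        for protein_id, blocks in structures:
            parts = []
            pos = 1
            for key, n, domain_name in blocks:
                parts.append(sampler.take(key, n))
                if domain_name is not None:
                    annotations.append(
                        DomainAnnotation(
                            species=species,
                            protein_id=protein_id,
                            domain_name=domain_name,
                            start=pos,
                            end=pos + n - 1,
                        )
                    )
                pos += n
            proteome.add(
                ProteinRecord(
                    protein_id=protein_id, species=species, sequence="".join(parts)
                )
            )
        proteomes[species] = proteome
    return proteomes, annotations, dictionary


def default_study_spec(seed: int = 0, arg_enrichment: float = 0.5) -> GeneratorSpec:
    """The package's reference synthetic study.

    Five species; one DNA-binding domain family with arginine planted at
    ``arg_enrichment`` relative excess, held to a small share (~7%) of all
    domain residues so it behaves like one functional family against the
    whole-domain background; one large unbiased family providing that
    background; linkers mildly enriched in proline and glutamine, as real
    inter-domain linkers are.
    """
    return GeneratorSpec(
        n_species=5,
        proteins_per_species=500,
        length_distribution=(40, 120),
        planted_families=(
            PlantedFamily(
                name="ZnF_DB",
                description="zinc finger DNA-binding domain",
                relative_enrichment={"R": arg_enrichment},
                domains_per_protein_rate=0.45,
            ),
            PlantedFamily(
                name="GLOB",
                description="globular fold of mixed enzymatic function",
                relative_enrichment={},
                domains_per_protein_rate=5.95,
            ),
        ),
        linker_bias={"P": 0.3, "Q": 0.2},
        seed=seed,
    )


def worked_example_fixture() -> tuple[
    dict[str, Proteome], list[DomainAnnotation], dict[str, DictionaryEntry]
]:
    """A tiny hand-written two-species dataset for unit and end-to-end tests.

    Covers every structural case: a two-domain protein with a homopolymeric
    linker, an all-twenty-letter protein guaranteeing non-zero backgrounds, a
    single-domain protein (no linker), and unannotated proteins (discarded
    from the domain/linker study). The dictionary includes descriptions
    matching the query "DNA-binding|DNA binding".
    """
    all20 = STANDARD_AMINO_ACIDS          # ACDEFGHIKLMNPQRSTVWY
    all20_rev = all20[::-1]

    def make(species, entries):
        proteome = Proteome(species=species)
        for pid, seq in entries:
            proteome.add(ProteinRecord(protein_id=pid, species=species, sequence=seq))
        return proteome

    proteomes = {
        "spA": make(
            "spA",
            [
                ("pA1", "K" * 10 + "L" * 10 + "K" * 10),
                ("pA2", all20 * 3),
                ("pA3", "MSTAYWQ"),
                ("pA4", "GGGGG" + "PPPPP" + "WWWWW"),
            ],
        ),
        "spB": make(
            "spB",
            [
                ("pB1", "R" * 10 + "G" * 10 + "R" * 10),
                ("pB2", all20_rev * 3),
                ("pB3", "AC"),
            ],
        ),
    }
    annotations = [
        DomainAnnotation("spA", "pA1", "HLH", 1, 10),
        DomainAnnotation("spA", "pA1", "ZnF", 21, 30),
        DomainAnnotation("spA", "pA2", "HLH", 1, 20),
        DomainAnnotation("spA", "pA2", "PH", 41, 60),
        DomainAnnotation("spA", "pA4", "Kinase", 6, 10),
        DomainAnnotation("spB", "pB1", "ZnF", 1, 10),
        DomainAnnotation("spB", "pB1", "HLH", 21, 30),
        DomainAnnotation("spB", "pB2", "PH", 1, 20),
        DomainAnnotation("spB", "pB2", "HLH", 41, 60),
    ]
    dictionary = {
        "HLH": DictionaryEntry("HLH", "helix loop helix DNA binding domain"),
        "ZnF": DictionaryEntry("ZnF", "zinc finger DNA-binding domain"),
        "PH": DictionaryEntry("PH", "pleckstrin homology domain"),
        "Kinase": DictionaryEntry("Kinase", "serine/threonine protein kinase catalytic domain"),
    }
    return proteomes, annotations, dictionary


def write_dataset(
    out_dir: str | Path,
    proteomes: Mapping[str, Proteome],
    annotations: Sequence[DomainAnnotation],
    dictionary: Mapping[str, DictionaryEntry],
    wrap: int = 60,
) -> dict[str, Path]:
    """Write a dataset in the exact formats the readers consume.

    Produces one FASTA per species, annotations.tsv, dictionary.tsv and a
    manifest.tsv (species to FASTA path). Output is deterministic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    manifest_rows = []
    for species in sorted(proteomes):
        fasta = out_dir / f"{species}.fasta"
        with open(fasta, "w") as fh:
            for pid in sorted(proteomes[species].proteins):
                seq = proteomes[species].proteins[pid].sequence
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")
        paths[species] = fasta
        manifest_rows.append(f"{species}\t{fasta.name}")

    ann_path = out_dir / "annotations.tsv"
    with open(ann_path, "w") as fh:
        fh.write("species\tprotein_id\tdomain_name\tstart\tend\n")
        for ann in sorted(
            annotations, key=lambda a: (a.species, a.protein_id, a.start, a.end)
        ):
            fh.write(
                f"{ann.species}\t{ann.protein_id}\t{ann.domain_name}\t"
                f"{ann.start}\t{ann.end}\n"
            )
    dict_path = out_dir / "dictionary.tsv"
    with open(dict_path, "w") as fh:
        fh.write("domain_name\tdescription\n")
        for name in sorted(dictionary):
            fh.write(f"{name}\t{dictionary[name].description}\n")
    manifest_path = out_dir / "manifest.tsv"
    manifest_path.write_text(
        "species\tpath\n" + "\n".join(manifest_rows) + "\n"
    )
    paths["annotations"] = ann_path
    paths["dictionary"] = dict_path
    paths["manifest"] = manifest_path
    return paths
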