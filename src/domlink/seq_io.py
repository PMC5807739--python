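"""Input/output for proteome FASTA files, domain annotation tables and domain dictionaries.

Conventions enforced here and documented in the README:

* domain coordinates are 1-based and inclusive on both ends (UniProt feature
  convention);
* sequences are upper-cased on read; the ambiguity letters ``B J O U X Z`` are
  accepted at parse time and only excluded later, at counting time, so parsing
  never silently alters composition;
* all tabular outputs are TSV with a fixed column order, rows sorted by the
  schema's key columns, and floats rendered with 6 significant digits, so
  repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetically by one-letter code.
STANDARD_AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard letters tolerated in input sequences but ignored
#: when counting composition.
AMBIGUOUS_LETTERS: str = "BJOUXZ"

_ALLOWED = frozenset(STANDARD_AMINO_ACIDS + AMBIGUOUS_LETTERS)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


class AnnotationError(ValueError):
    """Raised for invalid domain annotation rows."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence tagged with its species of origin."""

    protein_id: str
    species: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """All proteins of one species, keyed by protein id."""

    species: str
    proteins: dict[str, ProteinRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins.values())

    def add(self, record: ProteinRecord) -> None:
        if record.protein_id in self.proteins:
            raise FastaParseError(
                f"duplicate protein id {record.protein_id!r} in species {self.species!r}"
            )
        self.proteins[record.protein_id] = record


@dataclass(frozen=True)
class DomainAnnotation:
    """A named domain interval on a protein; 1-based, inclusive ends."""

    species: str
    protein_id: str
    domain_name: str
    start: int
    end: int


@dataclass(frozen=True)
class DictionaryEntry:
    """One domain-dictionary row: a domain name plus free-text description."""

    domain_name: str
    description: str


def _validate_sequence(protein_id: str, seq: str) -> None:
    bad = set(seq) - _ALLOWED
    if bad:
        ch = sorted(bad)[0]
        raise FastaParseError(
            f"protein {protein_id!r} contains disallowed character {ch!r}"
        )


def read_fasta(path: str | Path, species_code: str) -> Proteome:
    """Read a multi-FASTA file into a :class:`Proteome`.

    The protein id is the first whitespace-delimited token of the header line;
    sequences are upper-cased. Duplicate ids, empty sequences, characters
    outside the standard + ambiguity alphabet, and sequence data before the
    first header are all errors.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break

    proteome = Proteome(species=species_code)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) == 0:
            raise FastaParseError(f"protein {rec.id!r} has an empty sequence")
        _validate_sequence(rec.id, seq)
        proteome.add(ProteinRecord(protein_id=rec.id, species=species_code, sequence=seq))
    return proteome


_ANNOTATION_COLUMNS = ["species", "protein_id", "domain_name", "start", "end"]


def read_annotations(
    path: str | Path,
    proteomes: Mapping[str, Proteome],
    strict: bool = True,
) -> list[DomainAnnotation]:
    """Read a domain-annotation TSV and validate it against the proteomes.

    Expected columns (header row, exact names): species, protein_id,
    domain_name, start, end. Coordinates are 1-based inclusive and are checked
    against the referenced protein's length. Rows referencing an unknown
    species or protein are an error in strict mode and are dropped (with a
    logged count) in lenient mode.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing annotation columns: {missing}")

    annotations: list[DomainAnnotation] = []
    n_dropped = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        species, protein_id, domain_name = row.species, row.protein_id, row.domain_name
        if not domain_name or pd.isna(domain_name):
            raise AnnotationError(f"{path}: row {idx}: empty domain name")
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise AnnotationError(
                f"{path}: row {idx}: non-integer coordinates "
                f"({row.start!r}, {row.end!r})"
            ) from None
        proteome = proteomes.get(species)
        record = proteome.proteins.get(protein_id) if proteome is not None else None
        if record is None:
            if strict:
                raise AnnotationError(
                    f"{path}: row {idx}: unknown protein {species}/{protein_id}"
                )
            n_dropped += 1
            continue
        if not (1 <= start <= end):
            raise AnnotationError(
                f"{path}: row {idx}: invalid interval start={start} end={end} "
                f"(need 1 <= start <= end)"
            )
        if end > len(record):
            raise AnnotationError(
                f"{path}: row {idx}: end={end} exceeds length {len(record)} "
                f"of protein {protein_id}"
            )
        annotations.append(
            DomainAnnotation(
                species=species,
                protein_id=protein_id,
                domain_name=str(domain_name),
                start=start,
                end=end,
            )
        )
    if n_dropped:
        logger.warning("dropped %d annotation rows referencing unknown proteins", n_dropped)
    return annotations


def read_dictionary(path: str | Path) -> dict[str, DictionaryEntry]:
    """Read the domain dictionary TSV (columns: domain_name, description)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("domain_name", "description") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing dictionary columns: {missing}")
    entries: dict[str, DictionaryEntry] = {}
    for row in df.itertuples(index=False):
        if row.domain_name in entries:
            raise ValueError(f"{path}: duplicate dictionary entry {row.domain_name!r}")
        entries[row.domain_name] = DictionaryEntry(
            domain_name=row.domain_name, description=row.description
        )
    if not entries:
        logger.warning("%s: dictionary is empty", path)
    return entries


# --- tabular output -------------------------------------------------------

# schema name -> (column order, sort-key columns)
TABLE_SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "composition_long": (
        ("species", "feature_class", "amino_acid", "count", "percentage"),
        ("species", "feature_class", "amino_acid"),
    ),
    "pairwise_usage": (
        ("species", "amino_acid", "pct_linker", "pct_domain", "fold_class"),
        ("species", "amino_acid"),
    ),
    "raccoon_stats": (
        (
            "feature",
            "amino_acid",
            "direction_of_enrichment",
            "enrichment_sign",
            "mean_fold_deviation",
            "mean_abundance",
            "dispersion_feature",
            "dispersion_background",
            "n_species",
            "min_match_count",
            "warning_color_summary",
        ),
        ("feature", "amino_acid"),
    ),
    "dotplot_data": (
        (
            "feature",
            "amino_acid",
            "species",
            "feature_pct",
            "background_pct",
            "match_count",
            "color",
        ),
        ("feature", "amino_acid", "species"),
    ),
    "segments": (
        ("species", "protein_id", "feature_class", "start", "end"),
        ("species", "protein_id", "start"),
    ),
}


def _format_value(v) -> str:
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def write_table(
    records: Iterable[Mapping] | pd.DataFrame,
    path: str | Path,
    schema_name: str,
) -> None:
    """Write records as a deterministic TSV under a named schema.

    Column order is fixed by the schema, rows are sorted by the schema's key
    columns and floats use 6 significant digits, so identical records always
    produce byte-identical files.
    """
    if schema_name not in TABLE_SCHEMAS:
        raise ValueError(
            f"unknown table schema {schema_name!r}; "
            f"expected one of {sorted(TABLE_SCHEMAS)}"
        )
    columns, keys = TABLE_SCHEMAS[schema_name]
    df = pd.DataFrame(list(records) if not isinstance(records, pd.DataFrame) else records)
    if df.empty:
        df = pd.DataFrame(columns=list(columns))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"records for schema {schema_name!r} lack columns {missing}")
    df = df[list(columns)]
    if len(df):
        df = df.sort_values(list(keys), kind="mergesort").reset_index(drop=True)
    out = df.map(_format_value)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` with typed columns."""
    if schema_name not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema_name!r}")
    return pd.read_csv(path, sep="\t")
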