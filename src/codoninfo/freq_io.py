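"""Reading and writing species codon-frequency datasets.

A dataset is a collection of species records, each carrying a unique
label (group key plus sequential number, e.g. ``An587``), a scientific
name, a taxonomic group and a vector of 64 codon frequencies in the
canonical codon order.  Frequencies are treated as weights: counts,
per-mille values and proportions all yield the same relative codon
frequencies (RCF) after normalization, and all downstream measures
depend only on the RCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import (
    CODONS,
    GeneticCode,
    MalformedCodonError,
    normalize_codon,
    standard_code,
)

__all__ = [
    "GROUPS",
    "SpeciesRecord",
    "Dataset",
    "ColumnMap",
    "SchemaError",
    "DegenerateRecordError",
    "read_codon_csv",
    "write_codon_csv",
    "normalize",
    "count_codons_from_cds",
    "CdsTally",
    "write_matrix",
    "read_matrix",
]

#: Closed group vocabulary: full name -> two-letter key.
GROUPS: dict[str, str] = {
    "Animal": "An",
    "Archaea": "Ar",
    "EnteroBac": "Eb",
    "Plant": "Pl",
    "Fungus": "Fu",
    "Virus": "Vi",
    "Protist": "Pr",
    "OtherBac": "Ob",
}

_KEY_TO_GROUP = {v: k for k, v in GROUPS.items()}


class SchemaError(ValueError):
    """Input table does not match the expected codon-frequency schema."""


class DegenerateRecordError(ValueError):
    """A record whose frequencies carry no usable information (zero total)."""


def canonical_group(name: str, allow_other: bool = False) -> str:
    """Map a group name or key to its canonical key (e.g. Archaea -> Ar)."""
    s = str(name).strip()
    if s in _KEY_TO_GROUP:
        return s
    if s in GROUPS:
        return GROUPS[s]
    for full, key in GROUPS.items():
        if s.lower() == full.lower() or s.lower() == key.lower():
            return key
    if allow_other:
        return "Other"
    raise SchemaError(
        f"unknown group {name!r}; expected one of {sorted(GROUPS)} "
        f"or keys {sorted(GROUPS.values())}"
    )


@dataclass
class SpeciesRecord:
    """One species: identity metadata plus 64 codon frequencies.

    ``freqs`` follows the canonical codon order (T<C<A<G lexicographic)
    and may hold counts or relative frequencies; use :meth:`rcf` for the
    normalized vector.
    """

    label: str
    freqs: np.ndarray
    group: str = "Other"
    scientific_name: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (64,):
            raise SchemaError(
                f"{self.label}: expected 64 codon frequencies, got shape {f.shape}"
            )
        if np.any(f < 0) or not np.all(np.isfinite(f)):
            raise SchemaError(f"{self.label}: frequencies must be finite and >= 0")
        if f.sum() <= 0:
            raise DegenerateRecordError(f"{self.label}: all-zero frequency vector")
        self.freqs = f

    def rcf(self) -> np.ndarray:
        """Relative codon frequencies (sums to 1)."""
        return normalize(self.freqs)


def normalize(freqs: np.ndarray) -> np.ndarray:
    """Rescale a non-negative 64-vector to sum to 1.

    Exactly idempotent: a vector already summing to 1 within 1e-12 is
    returned unchanged, so normalizing counts and normalizing an RCF of
    the same species give bit-identical results.
    """
    f = np.asarray(freqs, dtype=float)
    total = f.sum()
    if total <= 0:
        raise DegenerateRecordError("cannot normalize an all-zero vector")
    if abs(total - 1.0) <= 1e-12:
        return f
    return f / total


@dataclass
class Dataset:
    """Ordered collection of species records with unique labels."""

    records: list[SpeciesRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise SchemaError("dataset must contain at least one record")
        labels = [r.label for r in self.records]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise SchemaError(f"duplicate species labels: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def groups(self) -> pd.Series:
        return pd.Series([r.group for r in self.records], index=self.labels)

    def rcf_matrix(self) -> pd.DataFrame:
        """Species x 64 matrix of relative codon frequencies."""
        return pd.DataFrame(
            [r.rcf() for r in self.records], index=self.labels, columns=CODONS
        )

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "label": self.labels,
                "scientific_name": [r.scientific_name for r in self.records],
                "group": [r.group for r in self.records],
            }
        )
        freqs = pd.DataFrame([r.freqs for r in self.records], columns=CODONS)
        return pd.concat([meta, freqs], axis=1)


@dataclass
class ColumnMap:
    """Names of the metadata columns in a codon-frequency CSV.

    Codon columns are located by header: any column whose name is a valid
    codon (case-insensitive, U tolerated) is taken as that codon's
    frequency column.  All 64 must be present.
    """

    label: str = "label"
    scientific_name: str | None = "scientific_name"
    group: str | None = "group"


def _codon_columns(columns: Iterable[str]) -> dict[str, str]:
    """Map canonical codon -> CSV column name; raises if any are missing."""
    found: dict[str, str] = {}
    for col in columns:
        try:
            c = normalize_codon(str(col))
        except MalformedCodonError:
            continue
        if c in found:
            raise SchemaError(f"duplicate codon column for {c}: {found[c]!r}, {col!r}")
        found[c] = col
    missing = [c for c in CODONS if c not in found]
    if missing:
        raise SchemaError(f"missing codon columns: {', '.join(missing)}")
    return found


def read_codon_csv(
    path: str | Path,
    column_map: ColumnMap | None = None,
    allow_other_groups: bool = False,
) -> Dataset:
    """Read a one-row-per-species codon-frequency CSV.

    Rows that fail validation (non-numeric or all-zero frequencies) are
    rejected with a message naming the offending row number.
    """
    column_map = column_map or ColumnMap()
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    codon_cols = _codon_columns(df.columns)

    def meta(row, col, default=""):
        if col is not None and col in df.columns:
            return str(row[col])
        return default

    records = []
    errors = []
    for i, (_, row) in enumerate(df.iterrows()):
        rownum = i + 2  # 1-based, after the header line
        try:
            vals = np.array(
                [float(row[codon_cols[c]]) for c in CODONS], dtype=float
            )
        except (TypeError, ValueError) as e:
            errors.append(f"row {rownum}: non-numeric frequency ({e})")
            continue
        label = meta(row, column_map.label, default=f"sp{i + 1}")
        try:
            group = canonical_group(
                meta(row, column_map.group, default="Other"),
                allow_other=allow_other_groups,
            )
            records.append(
                SpeciesRecord(
                    label=label,
                    freqs=vals,
                    group=group,
                    scientific_name=meta(row, column_map.scientific_name),
                )
            )
        except (SchemaError, DegenerateRecordError) as e:
            errors.append(f"row {rownum}: {e}")
    if errors and not records:
        raise SchemaError(f"{path}: no valid rows; first error: {errors[0]}")
    ds = Dataset(
        records=records,
        provenance={"path": str(path), "row_errors": errors},
    )
    return ds


def write_codon_csv(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset in the same schema :func:`read_codon_csv` accepts."""
    dataset.to_frame().to_csv(path, index=False)


@dataclass
class CdsTally:
    """Result of tabulating codons from coding sequences."""

    record: SpeciesRecord
    n_sequences: int
    skipped_triplets: int  # triplets containing non-ACGTU characters
    trimmed_sequences: int  # sequences truncated to the last complete codon
    rejected_sequences: int  # only under frame_policy="reject"


def count_codons_from_cds(
    fasta_path: str | Path,
    label: str = "cds",
    group: str = "Other",
    scientific_name: str = "",
    frame_policy: str = "truncate",
) -> CdsTally:
    """Tabulate in-frame codon counts from a FASTA of coding sequences.

    Reads non-overlapping triplets from position 1 of each sequence.
    Triplets containing characters outside {A, C, G, T, U} are skipped
    and tallied.  Sequences whose length is not a multiple of 3 are
    truncated to the last complete codon (``frame_policy="truncate"``,
    default) or dropped entirely (``"reject"``).
    """
    if frame_policy not in ("truncate", "reject"):
        raise ValueError(f"frame_policy must be 'truncate' or 'reject', got {frame_policy!r}")
    counts = np.zeros(64)
    n_seq = skipped = trimmed = rejected = 0
    from .genetic_code import CODON_INDEX

    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        rem = len(seq) % 3
        if rem:
            if frame_policy == "reject":
                rejected += 1
                continue
            seq = seq[: len(seq) - rem]
            trimmed += 1
        n_seq += 1
        for i in range(0, len(seq), 3):
            idx = CODON_INDEX.get(seq[i : i + 3])
            if idx is None:
                skipped += 1
            else:
                counts[idx] += 1
    if counts.sum() == 0:
        raise DegenerateRecordError(f"{fasta_path}: no usable codons")
    record = SpeciesRecord(
        label=label, freqs=counts, group=group, scientific_name=scientific_name
    )
    return CdsTally(
        record=record,
        n_sequences=n_seq,
        skipped_triplets=skipped,
        trimmed_sequences=trimmed,
        rejected_sequences=rejected,
    )


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled numeric matrix to CSV, round-trippable at full precision."""
    if df.shape[1] == 0:
        raise ValueError("matrix has no columns")
    # %.17g guarantees doubles survive the text round trip exactly
    df.to_csv(path, index=True, index_label="label", float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="label", float_precision="round_trip")
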