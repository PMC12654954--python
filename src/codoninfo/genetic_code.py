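"""Standard genetic code and the dissection of codons into functional parts.

A codon ``FST`` is an ordered triplet of DNA bases: F (first), S (second)
and T (third, the wobble position).  Beyond the codon itself and the
amino-acid signal it encodes, we treat each base position and each of the
three ordered duplets (FS, FT, ST) as a *codon part* — a deterministic
function of the codon with its own instance set and maximum entropy.

The amino-acid alphabet has 21 signals: the 20 amino acids plus the stop
signal, which is always retained as a first-class outcome.

Codons are indexed lexicographically over the base order T < C < A < G
(the classic codon-table order); every 64-vector in this package follows
that ordering.
"""

from __future__ import annotations

import csv
import enum
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Data import CodonTable

__all__ = [
    "BASES",
    "CODONS",
    "CODON_INDEX",
    "STOP",
    "CodonPart",
    "GeneticCode",
    "MalformedCodonError",
    "normalize_codon",
    "translate",
    "extract_part",
    "distinct_signals_by_class",
    "determinacy_ratio",
]

#: Base order used for all codon indexing (classic codon-table order).
BASES = "TCAG"

#: The 64 codons in lexicographic order over T < C < A < G.
CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(BASES, repeat=3)
)

#: Codon string -> position in :data:`CODONS`.
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: Label of the stop signal (the 21st amino-acid signal).
STOP = "Stop"

# one-letter -> three-letter amino-acid codes
_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

_POSITIONS = {"F": (0,), "S": (1,), "T": (2,), "FS": (0, 1), "FT": (0, 2), "ST": (1, 2)}


class MalformedCodonError(ValueError):
    """Raised for strings that are not a valid three-base codon."""


def normalize_codon(codon: str, rna_ok: bool = True) -> str:
    """Return the canonical DNA form of *codon* (uppercase, U mapped to T).

    Raises :class:`MalformedCodonError` if the result is not three
    characters over {T, C, A, G}.
    """
    c = codon.strip().upper()
    if rna_ok:
        c = c.replace("U", "T")
    if len(c) != 3 or any(b not in BASES for b in c):
        raise MalformedCodonError(f"not a valid codon: {codon!r}")
    return c


class CodonPart(enum.Enum):
    """A functional part of the codon: a deterministic map codon -> instance.

    Each part carries its instance count *k* and the maximum attainable
    Shannon entropy log2(k) in bits.
    """

    F = "F"
    S = "S"
    T = "T"
    FS = "FS"
    FT = "FT"
    ST = "ST"
    CODON = "codon"
    AA = "aa"

    @property
    def cardinality(self) -> int:
        return {
            CodonPart.F: 4, CodonPart.S: 4, CodonPart.T: 4,
            CodonPart.FS: 16, CodonPart.FT: 16, CodonPart.ST: 16,
            CodonPart.CODON: 64, CodonPart.AA: 21,
        }[self]

    @property
    def max_entropy(self) -> float:
        """log2(k), the entropy of the uniform distribution, in bits."""
        return math.log2(self.cardinality)

    @property
    def positions(self) -> tuple[int, ...] | None:
        """Zero-based codon positions read by this part; None for AA."""
        if self is CodonPart.CODON:
            return (0, 1, 2)
        return _POSITIONS.get(self.value.upper())

    def contains(self, other: "CodonPart") -> bool:
        """True if *other* is a positional coordinate of this part.

        CODON contains every other part; a duplet contains its two single
        positions.  AA contains nothing (it is a many-to-one image), and
        nothing but CODON contains AA.
        """
        if self is other:
            return False
        if self is CodonPart.CODON:
            return True
        if self.positions is None or other.positions is None:
            return False
        return set(other.positions) <= set(self.positions)


@dataclass(frozen=True)
class GeneticCode:
    """A code table mapping each of the 64 codons to an amino-acid signal.

    Signals use three-letter amino-acid codes plus :data:`STOP`.  The
    default is the standard nuclear code (NCBI translation table 1).
    """

    table: Mapping[str, str]
    id: str = "standard"

    def __post_init__(self) -> None:
        missing = [c for c in CODONS if c not in self.table]
        if missing:
            raise ValueError(f"code table missing codons: {missing[:5]}...")
        if len(self.table) != 64:
            extra = set(self.table) - set(CODONS)
            raise ValueError(f"unexpected codon keys: {sorted(extra)[:5]}")

    @property
    def signals(self) -> tuple[str, ...]:
        """Distinct signals in a fixed order: sorted amino acids, Stop last."""
        sig = sorted(set(self.table.values()) - {STOP})
        if STOP in self.table.values():
            sig.append(STOP)
        return tuple(sig)

    def family(self, signal: str) -> tuple[str, ...]:
        """The synonymous family: all codons translating to *signal*."""
        fam = tuple(c for c in CODONS if self.table[c] == signal)
        if not fam:
            raise KeyError(f"unknown signal: {signal!r}")
        return fam

    def family_sizes(self) -> dict[str, int]:
        return {s: len(self.family(s)) for s in self.signals}

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard nuclear code (NCBI translation table 1)."""
        return cls.from_ncbi_id(1, id="standard")

    @classmethod
    def from_ncbi_id(cls, ncbi_id: int, id: str | None = None) -> "GeneticCode":
        tab = CodonTable.unambiguous_dna_by_id[ncbi_id]
        table = {c: _AA3[a] for c, a in tab.forward_table.items()}
        for c in tab.stop_codons:
            table[c] = STOP
        return cls(table=table, id=id or f"ncbi-{ncbi_id}")

    @classmethod
    def from_csv(cls, path: str | Path, id: str | None = None) -> "GeneticCode":
        """Read a two-column ``codon,signal`` CSV (header optional)."""
        table: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].lower() in ("codon", ""):
                    continue
                table[normalize_codon(row[0])] = row[1].strip()
        return cls(table=table, id=id or Path(path).stem)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["codon", "signal"])
            for c in CODONS:
                w.writerow([c, self.table[c]])


_STANDARD: GeneticCode | None = None


def standard_code() -> GeneticCode:
    """Cached standard nuclear code (translation table 1)."""
    global _STANDARD
    if _STANDARD is None:
        _STANDARD = GeneticCode.standard()
    return _STANDARD


def translate(codon: str, code: GeneticCode | None = None) -> str:
    """Amino-acid signal assigned to *codon* by *code* (default standard)."""
    code = code or standard_code()
    return code.table[normalize_codon(codon)]


def extract_part(codon: str, part: CodonPart, code: GeneticCode | None = None) -> str:
    """The instance of *part* realised by *codon*.

    Single positions return one base, duplets the ordered base pair,
    CODON the codon itself and AA the translated signal.
    """
    c = normalize_codon(codon)
    if part is CodonPart.CODON:
        return c
    if part is CodonPart.AA:
        return translate(c, code)
    return "".join(c[i] for i in part.positions)


def part_instances(part: CodonPart, code: GeneticCode | None = None) -> tuple[str, ...]:
    """All instances of *part* in canonical order (base order T<C<A<G)."""
    code = code or standard_code()
    if part is CodonPart.CODON:
        return CODONS
    if part is CodonPart.AA:
        return code.signals
    n = len(part.positions)
    return tuple("".join(p) for p in itertools.product(BASES, repeat=n))


_POSITION_NAMES = {"first": 0, "second": 1, "third": 2}


def distinct_signals_by_class(
    position: str, code: GeneticCode | None = None
) -> dict[str, int]:
    """Distinct amino-acid signals reachable with one base fixed.

    For each base ``b``, counts the distinct signals among the 16 codons
    carrying ``b`` at *position* ("first", "second" or "third").  With the
    standard code, fixing G first allows only 5 signals (Ala, Asp, Glu,
    Gly, Val) while fixing G third still allows 14 — the structural root
    of the wobble position's weak determinacy.
    """
    code = code or standard_code()
    try:
        pos = _POSITION_NAMES[position]
    except KeyError:
        raise ValueError(
            f"position must be one of {sorted(_POSITION_NAMES)}, got {position!r}"
        ) from None
    return {
        b: len({code.table[c] for c in CODONS if c[pos] == b}) for b in BASES
    }


def determinacy_ratio(code: GeneticCode | None = None) -> float:
    """Mean distinct-signal count over third-base classes / first-base classes.

    Under equal use of all 64 codons this quantifies how much less
    determinant the third base is than the first for signal codification;
    2.375 for the standard nuclear code.
    """
    first = distinct_signals_by_class("first", code)
    third = distinct_signals_by_class("third", code)
    mean_first = sum(first.values()) / len(first)
    mean_third = sum(third.values()) / len(third)
    return mean_third / mean_first
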