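"""Entropy, conditional entropy and standardized mutual information of codon parts.

Every measure here is a function of a single species' relative codon
frequencies (RCF).  The RCF induces a probability distribution over the
instances of each codon part (base positions F/S/T, duplets FS/FT/ST,
the codon itself, and the 21 amino-acid signals) by summing the
frequencies of the codons mapping to each instance.  Shannon entropies
are in bits (log base 2); a probability below 1e-15 is treated as a
structural zero, so 0*log2(0) = 0 throughout.

Mutual information between two parts X, Y is standardized as

    sI(X;Y) = I(X;Y) / min(H(X), H(Y)),

which is 0 at independence and exactly 1 when either part determines
the other.  Alternative normalizers (sqrt, max, joint) are available.

Pairs where one part is a positional coordinate of the other (e.g.
F and FS) are *redundant*: their mutual information trivially equals
the smaller entropy.  Over the seven parts {aa, F, S, T, FS, FT, ST}
this leaves 15 non-redundant pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .genetic_code import (
    CODONS,
    CodonPart,
    GeneticCode,
    extract_part,
    part_instances,
    standard_code,
)

__all__ = [
    "Distribution",
    "JointDistribution",
    "marginalize",
    "joint",
    "entropy",
    "joint_entropy",
    "conditional_entropy",
    "mutual_information",
    "standardized_mi",
    "non_redundant_pairs",
    "pair_label",
    "Measure",
    "MeasureRegistry",
    "registry_preset",
    "compute_measure_vector",
    "measure_matrix",
    "MAIN_MEASURES",
]

#: Treat probabilities below this as structural zeros (avoids -inf logs).
ZERO_TOL = 1e-15

#: Tolerance for validating that distributions sum to one.
SUM_TOL = 1e-9

#: Canonical names of the eight main entropy measures.
MAIN_MEASURES = (
    "H(codon)", "H(aa)", "H(FS)", "H(FT)", "H(ST)", "H(F)", "H(S)", "H(T)",
)

_PART_BY_NAME = {
    "codon": CodonPart.CODON, "aa": CodonPart.AA,
    "F": CodonPart.F, "S": CodonPart.S, "T": CodonPart.T,
    "FS": CodonPart.FS, "FT": CodonPart.FT, "ST": CodonPart.ST,
}


def part_name(part: CodonPart) -> str:
    return part.value


# ---------------------------------------------------------------------------
# distributions

@dataclass
class Distribution:
    """Probabilities over the instances of one codon part."""

    part: CodonPart
    labels: tuple[str, ...]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        k = self.part.cardinality
        if len(self.labels) != k or self.p.shape != (k,):
            raise ValueError(
                f"{self.part}: expected {k} instances, got {self.p.shape}"
            )
        if np.any(self.p < -ZERO_TOL):
            raise ValueError(f"{self.part}: negative probability")
        if abs(self.p.sum() - 1.0) > SUM_TOL:
            raise ValueError(
                f"{self.part}: probabilities sum to {self.p.sum()!r}, not 1"
            )


@dataclass
class JointDistribution:
    """Joint probabilities over instance pairs of two distinct codon parts."""

    part_x: CodonPart
    part_y: CodonPart
    labels_x: tuple[str, ...]
    labels_y: tuple[str, ...]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        kx, ky = self.part_x.cardinality, self.part_y.cardinality
        if self.p.shape != (kx, ky):
            raise ValueError(f"joint matrix shape {self.p.shape}, expected {(kx, ky)}")
        if np.any(self.p < -ZERO_TOL):
            raise ValueError("negative joint probability")
        if abs(self.p.sum() - 1.0) > SUM_TOL:
            raise ValueError(f"joint probabilities sum to {self.p.sum()!r}, not 1")

    def marginal_x(self) -> Distribution:
        return Distribution(self.part_x, self.labels_x, self.p.sum(axis=1))

    def marginal_y(self) -> Distribution:
        return Distribution(self.part_y, self.labels_y, self.p.sum(axis=0))


# codon -> instance index arrays, cached per code table identity
_INDEX_CACHE: dict[tuple[int, CodonPart], tuple[tuple[str, ...], np.ndarray]] = {}


def _part_index(part: CodonPart, code: GeneticCode) -> tuple[tuple[str, ...], np.ndarray]:
    key = (id(code.table), part)
    hit = _INDEX_CACHE.get(key)
    if hit is None:
        labels = part_instances(part, code)
        pos = {inst: i for i, inst in enumerate(labels)}
        idx = np.array([pos[extract_part(c, part, code)] for c in CODONS])
        hit = (labels, idx)
        _INDEX_CACHE[key] = hit
    return hit


def _check_rcf(rcf: np.ndarray) -> np.ndarray:
    r = np.asarray(rcf, dtype=float)
    if r.shape != (64,):
        raise ValueError(f"RCF must be a 64-vector, got shape {r.shape}")
    if np.any(r < -ZERO_TOL):
        raise ValueError("RCF has negative entries")
    if abs(r.sum() - 1.0) > SUM_TOL:
        raise ValueError(f"RCF sums to {r.sum()!r}; normalize first")
    return r


def marginalize(
    rcf: np.ndarray, part: CodonPart, code: GeneticCode | None = None
) -> Distribution:
    """Distribution of *part* induced by summing RCF over its preimages."""
    code = code or standard_code()
    r = _check_rcf(rcf)
    labels, idx = _part_index(part, code)
    p = np.bincount(idx, weights=r, minlength=len(labels))
    return Distribution(part, labels, p)


def joint(
    rcf: np.ndarray,
    part_x: CodonPart,
    part_y: CodonPart,
    code: GeneticCode | None = None,
) -> JointDistribution:
    """Joint distribution of two distinct parts under one RCF."""
    if part_x is part_y:
        raise ValueError(f"joint distribution requires two distinct parts, got {part_x}")
    code = code or standard_code()
    r = _check_rcf(rcf)
    labels_x, ix = _part_index(part_x, code)
    labels_y, iy = _part_index(part_y, code)
    kx, ky = len(labels_x), len(labels_y)
    p = np.bincount(ix * ky + iy, weights=r, minlength=kx * ky).reshape(kx, ky)
    return JointDistribution(part_x, part_y, labels_x, labels_y, p)


# ---------------------------------------------------------------------------
# entropies

def _entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < -ZERO_TOL):
        raise ValueError("negative probability")
    nz = p[p > ZERO_TOL]
    return float(-(nz * np.log2(nz)).sum())


def entropy(d: Distribution | np.ndarray) -> float:
    """Shannon entropy -sum p log2 p, in bits."""
    if isinstance(d, Distribution):
        return _entropy_bits(d.p)
    return _entropy_bits(np.asarray(d))


def joint_entropy(j: JointDistribution) -> float:
    """H(X,Y): entropy of the flattened joint distribution, in bits."""
    return _entropy_bits(j.p)


def conditional_entropy(j: JointDistribution) -> float:
    """H(X|Y) = H(X,Y) - H(Y), in bits."""
    return joint_entropy(j) - entropy(j.marginal_y())


def mutual_information(j: JointDistribution) -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y), in bits (clamped at 0)."""
    i = entropy(j.marginal_x()) + entropy(j.marginal_y()) - joint_entropy(j)
    return max(i, 0.0)


_NORMALIZERS: dict[str, Callable[[float, float, float], float]] = {
    "min": lambda hx, hy, hxy: min(hx, hy),
    "max": lambda hx, hy, hxy: max(hx, hy),
    "sqrt": lambda hx, hy, hxy: float(np.sqrt(hx * hy)),
    "joint": lambda hx, hy, hxy: hxy,
}


def standardized_mi(
    rcf: np.ndarray,
    part_x: CodonPart,
    part_y: CodonPart,
    code: GeneticCode | None = None,
    normalizer: str = "min",
) -> float:
    """Standardized mutual information sI(X;Y) in [0, 1].

    Defined only for non-redundant part pairs; requesting a redundant
    pair (one part a coordinate of the other) raises, since its value is
    identically 1 regardless of the species.
    """
    if part_x.contains(part_y) or part_y.contains(part_x):
        raise ValueError(
            f"redundant pair: {part_name(part_x)} and {part_name(part_y)} "
            "(one is a positional coordinate of the other)"
        )
    try:
        norm = _NORMALIZERS[normalizer]
    except KeyError:
        raise ValueError(
            f"normalizer must be one of {sorted(_NORMALIZERS)}, got {normalizer!r}"
        ) from None
    j = joint(rcf, part_x, part_y, code)
    hx, hy = entropy(j.marginal_x()), entropy(j.marginal_y())
    hxy = joint_entropy(j)
    denom = norm(hx, hy, hxy)
    if denom <= ZERO_TOL:
        return 0.0
    return float(np.clip((hx + hy - hxy) / denom, 0.0, 1.0))


# ---------------------------------------------------------------------------
# the 15 non-redundant pairs

# canonical display order of parts within a pair: aa first, then duplets,
# then single bases (matches the aa.T / ST.F label style)
_PAIR_ORDER = {
    CodonPart.AA: 0,
    CodonPart.FS: 1, CodonPart.FT: 2, CodonPart.ST: 3,
    CodonPart.F: 4, CodonPart.S: 5, CodonPart.T: 6,
}


def non_redundant_pairs() -> list[tuple[CodonPart, CodonPart]]:
    """The 15 unordered part pairs with non-trivial mutual information.

    All C(7,2) = 21 pairs over {aa, FS, FT, ST, F, S, T} minus the six
    containment pairs (F-FS, F-FT, S-FS, S-ST, T-FT, T-ST).
    """
    parts = sorted(_PAIR_ORDER, key=_PAIR_ORDER.get)
    pairs = []
    for x, y in itertools.combinations(parts, 2):
        if x.contains(y) or y.contains(x):
            continue
        pairs.append((x, y))
    return pairs


def pair_label(part_x: CodonPart, part_y: CodonPart) -> str:
    """Compact dendrogram label for a part pair, e.g. ``aa.T`` or ``ST.F``."""
    x, y = sorted((part_x, part_y), key=_PAIR_ORDER.get)
    return f"{part_name(x)}.{part_name(y)}"


# ---------------------------------------------------------------------------
# measure registry

@dataclass(frozen=True)
class Measure:
    """A named per-species scalar: an entropy-type or sI-type quantity."""

    name: str
    kind: str  # marginal | joint | conditional | mutual_information | standardized_mi
    parts: tuple[CodonPart, ...]
    max_value: float | None = None

    def compute(self, rcf: np.ndarray, code: GeneticCode, normalizer: str = "min") -> float:
        if self.kind == "marginal":
            return entropy(marginalize(rcf, self.parts[0], code))
        j = joint(rcf, self.parts[0], self.parts[1], code)
        if self.kind == "joint":
            return joint_entropy(j)
        if self.kind == "conditional":
            return conditional_entropy(j)
        if self.kind == "mutual_information":
            return mutual_information(j)
        if self.kind == "standardized_mi":
            return standardized_mi(rcf, self.parts[0], self.parts[1], code, normalizer)
        raise ValueError(f"unknown measure kind {self.kind!r}")


@dataclass
class MeasureRegistry:
    """An ordered, named collection of measures computed for every species."""

    name: str
    measures: list[Measure]

    def __post_init__(self) -> None:
        names = [m.name for m in self.measures]
        if len(set(names)) != len(names):
            raise ValueError("duplicate measure names in registry")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.measures]

    def __len__(self) -> int:
        return len(self.measures)

    def __getitem__(self, name: str) -> Measure:
        for m in self.measures:
            if m.name == name:
                return m
        raise KeyError(name)


def _marginal(part: CodonPart) -> Measure:
    return Measure(
        name=f"H({part_name(part)})",
        kind="marginal",
        parts=(part,),
        max_value=part.max_entropy,
    )


def _pair_sorted(x: CodonPart, y: CodonPart) -> tuple[CodonPart, CodonPart]:
    return tuple(sorted((x, y), key=_PAIR_ORDER.get))  # type: ignore[return-value]


def registry_preset(name: str = "extended54") -> MeasureRegistry:
    """Built-in registries.

    ``main8``
        The eight marginal entropies H(codon), H(aa), H(FS), H(FT),
        H(ST), H(F), H(S), H(T).
    ``extended54``
        main8 + the 15 joint entropies and 30 directed conditional
        entropies over the non-redundant pairs + H(codon|aa), the
        within-family codon-choice uncertainty; 54 measures in all.
    ``sI15``
        The 15 standardized mutual-information measures.
    """
    marginals = [
        _marginal(p)
        for p in (
            CodonPart.CODON, CodonPart.AA,
            CodonPart.FS, CodonPart.FT, CodonPart.ST,
            CodonPart.F, CodonPart.S, CodonPart.T,
        )
    ]
    if name == "main8":
        return MeasureRegistry("main8", marginals)
    pairs = non_redundant_pairs()
    if name == "sI15":
        return MeasureRegistry(
            "sI15",
            [
                Measure(
                    name=f"sI({part_name(x)};{part_name(y)})",
                    kind="standardized_mi",
                    parts=(x, y),
                    max_value=1.0,
                )
                for x, y in pairs
            ],
        )
    if name == "extended54":
        measures = list(marginals)
        for x, y in pairs:
            measures.append(
                Measure(
                    name=f"H({part_name(x)},{part_name(y)})",
                    kind="joint",
                    parts=(x, y),
                )
            )
        for x, y in pairs:
            measures.append(
                Measure(
                    name=f"H({part_name(x)}|{part_name(y)})",
                    kind="conditional",
                    parts=(x, y),
                    max_value=x.max_entropy,
                )
            )
            measures.append(
                Measure(
                    name=f"H({part_name(y)}|{part_name(x)})",
                    kind="conditional",
                    parts=(y, x),
                    max_value=y.max_entropy,
                )
            )
        measures.append(
            Measure(
                name="H(codon|aa)",
                kind="conditional",
                parts=(CodonPart.CODON, CodonPart.AA),
            )
        )
        return MeasureRegistry("extended54", measures)
    raise ValueError(f"unknown registry preset {name!r}")


@dataclass
class MeasureVector:
    """All registered measures for one species."""

    label: str
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def compute_measure_vector(
    rcf: np.ndarray,
    registry: MeasureRegistry | None = None,
    code: GeneticCode | None = None,
    label: str = "",
    normalizer: str = "min",
) -> MeasureVector:
    """Evaluate every measure in *registry* on one species' RCF."""
    registry = registry or registry_preset("extended54")
    code = code or standard_code()
    r = _check_rcf(rcf)
    values = {m.name: m.compute(r, code, normalizer) for m in registry.measures}
    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite measures for {label or 'species'}: {bad}")
    return MeasureVector(label=label, values=values)


def measure_matrix(
    dataset,
    registry: MeasureRegistry | None = None,
    code: GeneticCode | None = None,
    normalizer: str = "min",
) -> pd.DataFrame:
    """Species x measures matrix for a whole dataset.

    Rows follow dataset order; columns follow registry order.
    """
    registry = registry or registry_preset("extended54")
    code = code or standard_code()
    rows = [
        compute_measure_vector(
            rec.rcf(), registry, code, label=rec.label, normalizer=normalizer
        ).values
        for rec in dataset
    ]
    return pd.DataFrame(rows, index=[r.label for r in dataset], columns=registry.names)
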