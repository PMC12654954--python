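"""Seeded generator of codon-frequency datasets with controlled structure.

Each synthetic species is built hierarchically, mirroring how codon
usage decomposes in real genomes:

1. an amino-acid (signal) composition drawn from a symmetric Dirichlet
   over the 21 signals — its concentration controls how tightly a group
   clusters around uniform usage;
2. within every synonymous family, a codon-choice distribution drawn
   from a Dirichlet whose base weights tilt the *third* (wobble) base
   only — first and second positions carry no within-family freedom;
3. the codon distribution p(c) = p(aa) * p(c | aa);
4. an optional GC tilt that reweights codon choice *within* each family
   by exp(gamma * gc_count(c)), leaving the amino-acid composition
   untouched, so gamma tunes the species' GC content.

By default the three six-fold families (Leu, Ser, Arg), whose codons
also differ at positions 1-2, are collapsed to their majority four-codon
block.  With that collapse the first base is a deterministic function of
the signal in every family, hence H(F|aa) = 0 exactly while H(T|aa) > 0
almost surely: every generated species satisfies the wobble-excess
property Diff = H(T|aa) - H(F|aa) > 0 by construction.

Randomness is hierarchical: (dataset seed, group key, species index)
determines each species independently, so any subset is reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .freq_io import Dataset, SpeciesRecord
from .genetic_code import CODONS, CODON_INDEX, GeneticCode, standard_code

__all__ = [
    "GroupSpec",
    "generate_species",
    "generate_dataset",
    "paperlike_specs",
    "sampling_families",
]

_BASE_INDEX = {"T": 0, "C": 1, "A": 2, "G": 3}


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one group of synthetic species.

    wobble_tilt is in base order (T, C, A, G); it multiplies the
    Dirichlet base weight of each within-family codon according to its
    third base.  gc_tilt is the exponential tilt gamma applied to codon
    choice within families; 0 leaves GC unbiased.
    """

    key: str
    n_species: int
    aa_concentration: float = 40.0
    family_concentration: float = 10.0
    wobble_tilt: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    gc_tilt: float = 0.0
    collapse_sixfold: bool = True

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError(f"{self.key}: n_species must be >= 1")
        if self.aa_concentration <= 0 or self.family_concentration <= 0:
            raise ValueError(f"{self.key}: concentrations must be > 0")
        if len(self.wobble_tilt) != 4 or any(w <= 0 for w in self.wobble_tilt):
            raise ValueError(f"{self.key}: wobble_tilt needs 4 positive weights")


def sampling_families(
    code: GeneticCode | None = None, collapse_sixfold: bool = True
) -> dict[str, tuple[str, ...]]:
    """Codon support per signal used by the generator.

    With ``collapse_sixfold`` (default), families whose codons differ at
    positions 1-2 (the six-fold Leu/Ser/Arg) are restricted to their
    largest block of codons sharing the first two bases — ties broken by
    canonical codon order.  All other families are kept whole; note the
    stop family (TAA/TAG/TGA) varies at position 2 but shares its first
    base, so it never threatens H(F|aa) = 0.
    """
    code = code or standard_code()
    fams: dict[str, tuple[str, ...]] = {}
    for sig in code.signals:
        fam = code.family(sig)
        if collapse_sixfold and len(fam) == 6:
            blocks: dict[str, list[str]] = {}
            for c in fam:
                blocks.setdefault(c[:2], []).append(c)
            best = max(
                sorted(blocks, key=lambda p: min(CODON_INDEX[c] for c in blocks[p])),
                key=lambda p: len(blocks[p]),
            )
            fam = tuple(blocks[best])
        fams[sig] = tuple(fam)
    return fams


_GC_COUNT = np.array([sum(b in "GC" for b in c) for c in CODONS], dtype=float)


def _species_rng(seed: int, key: str, index: int) -> np.random.Generator:
    # hierarchical seeding: any (seed, group, index) triple is independent
    ss = np.random.SeedSequence([int(seed), zlib.crc32(key.encode()), int(index)])
    return np.random.default_rng(ss)


def generate_species(
    spec: GroupSpec,
    index: int,
    seed: int = 0,
    code: GeneticCode | None = None,
) -> SpeciesRecord:
    """Draw one synthetic species; deterministic given (seed, key, index)."""
    code = code or standard_code()
    rng = _species_rng(seed, spec.key, index)
    fams = sampling_families(code, spec.collapse_sixfold)
    signals = code.signals

    p_aa = rng.dirichlet(np.full(len(signals), spec.aa_concentration))
    freqs = np.zeros(64)
    tilt = np.asarray(spec.wobble_tilt, dtype=float)
    for sig, pa in zip(signals, p_aa):
        fam = fams[sig]
        if len(fam) == 1:
            within = np.array([1.0])
        else:
            w = np.array([tilt[_BASE_INDEX[c[2]]] for c in fam])
            alpha = spec.family_concentration * w / w.mean()
            within = rng.dirichlet(alpha)
            if spec.gc_tilt != 0.0:
                gc = np.array([_GC_COUNT[CODON_INDEX[c]] for c in fam])
                within = within * np.exp(spec.gc_tilt * gc)
                within = within / within.sum()
        for c, pc in zip(fam, within):
            freqs[CODON_INDEX[c]] = pa * pc
    return SpeciesRecord(
        label=f"{spec.key}{index}",
        freqs=freqs,
        group=spec.key,
        scientific_name=f"Synthetic {spec.key} {index}",
    )


def generate_dataset(
    specs: list[GroupSpec],
    seed: int = 0,
    code: GeneticCode | None = None,
) -> Dataset:
    """Concatenate generated groups into one dataset with key+index labels."""
    if not specs:
        raise ValueError("need at least one group spec")
    keys = [s.key for s in specs]
    if len(set(keys)) != len(keys):
        raise ValueError(f"duplicate group keys: {keys}")
    records = [
        generate_species(spec, i, seed=seed, code=code)
        for spec in specs
        for i in range(1, spec.n_species + 1)
    ]
    return Dataset(
        records=records,
        provenance={
            "generator": "codoninfo.synthetic",
            "seed": int(seed),
            "groups": {s.key: s.n_species for s in specs},
        },
    )


def paperlike_specs(scale: float = 1.0) -> list[GroupSpec]:
    """The shipped multi-group preset.

    Emulates a broad taxonomic sample: an Archaea-like group with weak
    concentrations (widest spread of Diff and of the aa-base
    dependencies), compact animal- and plant-like groups, and
    group-specific GC tilts.  Group sizes mirror the 652/435/126/122/
    71/21/4/3 proportions of a broad eight-group species panel, scaled
    down tenfold (times *scale*, minimum one species per group).
    """
    base = [
        GroupSpec("An", 65, aa_concentration=60, family_concentration=12,
                  wobble_tilt=(1.0, 1.1, 0.8, 1.1), gc_tilt=0.1),
        GroupSpec("Ar", 44, aa_concentration=15, family_concentration=1.5,
                  wobble_tilt=(1.0, 0.8, 1.2, 0.7), gc_tilt=0.0),
        GroupSpec("Eb", 13, aa_concentration=40, family_concentration=8,
                  wobble_tilt=(0.9, 1.0, 0.9, 1.2), gc_tilt=0.2),
        GroupSpec("Pl", 12, aa_concentration=60, family_concentration=12,
                  wobble_tilt=(1.1, 0.9, 1.0, 0.9), gc_tilt=-0.1),
        GroupSpec("Fu", 7, aa_concentration=40, family_concentration=8,
                  wobble_tilt=(1.0, 1.0, 0.9, 1.0), gc_tilt=0.0),
        GroupSpec("Vi", 2, aa_concentration=25, family_concentration=5,
                  wobble_tilt=(1.1, 0.8, 1.2, 0.8), gc_tilt=-0.2),
        GroupSpec("Pr", 1, aa_concentration=25, family_concentration=6,
                  wobble_tilt=(1.0, 0.9, 1.1, 0.9), gc_tilt=-0.1),
        GroupSpec("Ob", 1, aa_concentration=40, family_concentration=8,
                  wobble_tilt=(0.9, 1.0, 1.0, 1.1), gc_tilt=0.1),
    ]
    if scale == 1.0:
        return base
    return [
        replace(s, n_species=max(1, round(s.n_species * scale))) for s in base
    ]
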