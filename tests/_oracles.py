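"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles — plain Python
loops over the 64 codons, the code table taken directly from Biopython —
and deliberately shares no code with the package under test.
"""

import itertools
import math

from Bio.Data import CodonTable

BASES = "TCAG"
CODONS = ["".join(p) for p in itertools.product(BASES, repeat=3)]

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def standard_table() -> dict:
    """Codon -> three-letter signal for NCBI translation table 1."""
    tab = CodonTable.unambiguous_dna_by_id[1]
    code = {c: _AA3[a] for c, a in tab.forward_table.items()}
    for c in tab.stop_codons:
        code[c] = "Stop"
    return code


_CODE = standard_table()

_PART_POSITIONS = {
    "F": (0,), "S": (1,), "T": (2,),
    "FS": (0, 1), "FT": (0, 2), "ST": (1, 2),
}


def part_instance(codon: str, part: str) -> str:
    """Instance of a named part realised by a codon (string ops only)."""
    if part == "codon":
        return codon
    if part == "aa":
        return _CODE[codon]
    return "".join(codon[i] for i in _PART_POSITIONS[part])


def entropy_bits(probs) -> float:
    return -sum(p * math.log2(p) for p in probs if p > 1e-15)


def marginal_probs(rcf, part: str) -> dict:
    """Distribution of a part by direct summation over all 64 codons."""
    out: dict = {}
    for c, p in zip(CODONS, rcf):
        k = part_instance(c, part)
        out[k] = out.get(k, 0.0) + p
    return out


def joint_probs(rcf, part_x: str, part_y: str) -> dict:
    out: dict = {}
    for c, p in zip(CODONS, rcf):
        k = (part_instance(c, part_x), part_instance(c, part_y))
        out[k] = out.get(k, 0.0) + p
    return out


def measure(rcf, name: str) -> float:
    """Evaluate a canonical measure name, e.g. H(T|aa) or sI(aa;S)."""
    if name.startswith("sI(") and name.endswith(")"):
        x, y = name[3:-1].split(";")
        hx = entropy_bits(marginal_probs(rcf, x).values())
        hy = entropy_bits(marginal_probs(rcf, y).values())
        hxy = entropy_bits(joint_probs(rcf, x, y).values())
        denom = min(hx, hy)
        if denom <= 1e-15:
            return 0.0
        return (hx + hy - hxy) / denom
    assert name.startswith("H(") and name.endswith(")")
    inner = name[2:-1]
    if "|" in inner:
        x, y = inner.split("|")
        hxy = entropy_bits(joint_probs(rcf, x, y).values())
        hy = entropy_bits(marginal_probs(rcf, y).values())
        return hxy - hy
    if "," in inner:
        x, y = inner.split(",")
        return entropy_bits(joint_probs(rcf, x, y).values())
    return entropy_bits(marginal_probs(rcf, inner).values())


def complete_linkage_merges(labels, dist):
    """Naive O(n^3) complete-linkage agglomeration.

    dist: dict mapping frozenset({a, b}) -> distance over leaf labels.
    Returns the merge list [(sorted member tuple, height), ...] with the
    same lexicographic tie-break contract as the implementation: among
    pairs at the minimal linkage distance, merge the one whose combined
    sorted member list is smallest.
    """
    clusters = [tuple([l]) for l in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            link = max(
                dist[frozenset({x, y})] for x in a for y in b
            )
            key = (link, sorted(a + b))
            if best is None or key < best[0]:
                best = (key, a, b)
        (link, members), a, b = best
        merged = tuple(sorted(a + b))
        merges.append((merged, link))
        clusters = [c for c in clusters if c not in (a, b)] + [merged]
    return merges
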