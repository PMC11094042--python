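"""Single-nucleotide reachability between amino acids under the standard genetic code.

An amino-acid substitution ref->alt is *SNV-reachable* when some sense codon
encoding ref differs at exactly one nucleotide from a sense codon encoding
alt.  This partitions the 380 ordered non-identity pairs into those a single
nucleotide variant can produce and those requiring two or more nucleotide
changes — the partition used to restrict per-residue and per-pair score
averages to substitutions a real SNV dataset can contain.

Only the standard nuclear code (NCBI translation table 1) is implemented;
transitions through stop codons are excluded.
"""

from __future__ import annotations

from functools import lru_cache

BASES = "TCAG"

# NCBI translation table 1 in canonical TCAG nesting order
# (first base outermost): TTT, TTC, TTA, TTG, TCT, ...
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: _AA_ORDER[16 * i + 4 * j + k]
    for i, b1 in enumerate(BASES)
    for j, b2 in enumerate(BASES)
    for k, b3 in enumerate(BASES)
}

STOP_CODONS: frozenset[str] = frozenset(c for c, a in CODON_TABLE.items() if a == "*")
SENSE_CODONS: dict[str, str] = {c: a for c, a in CODON_TABLE.items() if a != "*"}

#: The 20 standard amino acids, one-letter codes, alphabetical.
AA20: str = "".join(sorted(set(SENSE_CODONS.values())))
AA_SET: frozenset[str] = frozenset(AA20)

CODONS_OF: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in SENSE_CODONS.items() if a == aa)) for aa in AA20
}


def _check_codon(codon: str) -> None:
    if not isinstance(codon, str) or len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}: expected 3 letters over A/C/G/T")


def _check_aa(aa: str) -> None:
    if aa not in AA_SET:
        raise ValueError(f"invalid amino acid {aa!r}: expected one of {AA20}")


def codon_neighbors(codon: str) -> list[str]:
    """All 9 codons differing from `codon` at exactly one position."""
    _check_codon(codon)
    return [
        codon[:i] + b + codon[i + 1 :]
        for i in range(3)
        for b in BASES
        if b != codon[i]
    ]


@lru_cache(maxsize=1)
def snv_reachable_substitutions() -> frozenset[tuple[str, str]]:
    """Ordered amino-acid pairs (ref, alt), ref != alt, reachable by one SNV.

    Reachability is generic over codons: the pair is included when *any*
    sense codon of ref has a single-nucleotide sense neighbour coding alt.
    """
    pairs: set[tuple[str, str]] = set()
    for codon, aa in SENSE_CODONS.items():
        for neighbor in codon_neighbors(codon):
            alt = SENSE_CODONS.get(neighbor)
            if alt is not None and alt != aa:
                pairs.add((aa, alt))
    return frozenset(pairs)


def is_snv_reachable(ref_aa: str, alt_aa: str) -> bool:
    """Whether ref->alt is achievable by a single nucleotide change.

    Identity substitutions are a contract violation, not a False.
    """
    _check_aa(ref_aa)
    _check_aa(alt_aa)
    if ref_aa == alt_aa:
        raise ValueError(f"identity substitution {ref_aa}->{alt_aa} is not a variant")
    return (ref_aa, alt_aa) in snv_reachable_substitutions()


def reachable_from_codon(codon: str) -> frozenset[str]:
    """Codon-specific mode: amino acids reachable by one SNV from this exact codon.

    Used when the actual coding sequence is known; excludes the codon's own
    amino acid and stop codons.
    """
    _check_codon(codon)
    if codon in STOP_CODONS:
        raise ValueError(f"{codon} is a stop codon")
    ref = SENSE_CODONS[codon]
    return frozenset(
        alt
        for n in codon_neighbors(codon)
        if (alt := SENSE_CODONS.get(n)) is not None and alt != ref
    )
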