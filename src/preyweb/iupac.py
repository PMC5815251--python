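"""IUPAC nucleotide code tables and consensus-code helpers."""

from __future__ import annotations

# Code -> set of unambiguous bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# Base set -> minimal covering code.
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

GAP = "-"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def base_set(code: str) -> frozenset[str]:
    """Return the unambiguous base set an IUPAC code stands for.

    Raises KeyError for characters that are not IUPAC nucleotide codes.
    """
    return IUPAC_SETS[code.upper()]


def code_for(bases: frozenset[str] | set[str]) -> str:
    """Return the minimal IUPAC code covering exactly `bases`."""
    return SET_TO_CODE[frozenset(bases)]


def is_degenerate(code: str) -> bool:
    return code.upper() not in "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def matches(primer_code: str, site_base: str, strict_n: bool = True) -> bool:
    """Set-membership IUPAC match of a site base against a primer code.

    A gap in the site never matches.  In strict mode an 'N' in the site
    matches nothing (uncertain reference bases are scored conservatively);
    in lenient mode 'N' matches any primer code.
    """
    site_base = site_base.upper()
    if site_base == GAP:
        return False
    if site_base == "N":
        return not strict_n
    try:
        site_set = IUPAC_SETS[site_base]
    except KeyError:
        return False
    return bool(site_set & IUPAC_SETS[primer_code.upper()])
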