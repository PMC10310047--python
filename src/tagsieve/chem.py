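"""Monoisotopic residue masses and flank-mass arithmetic.

This table is the single source of truth for residue masses, shared by the
tag matcher and the synthetic-data simulator so that tags generated from a
peptide always resolve against the same protein under zero noise.

Mass-gap convention: a gap is the plain sum of monoisotopic residue masses of
the unsequenced flank *within* the peptide — no water, no proton.  Terminal
group offsets are exposed as configurable constants on
:class:`tagsieve.tag_matcher.MatchParams` and default to 0.
"""

from __future__ import annotations

from typing import Mapping, Optional

#: Monoisotopic masses of the 20 standard amino-acid residues (Da).
MONOISOTOPIC: Mapping[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Ambiguity / non-standard letters tolerated in sequences but excluded from
#: any mass computation (they have no defined monoisotopic mass here).
AMBIGUOUS_RESIDUES = frozenset("BZXUO")

#: Common modification deltas (Da).
CARBAMIDOMETHYL = 57.02146   # fixed on C
OXIDATION = 15.99491         # variable on M
ACETYL = 42.01057            # variable on the protein N-terminus

STANDARD_AA = "".join(sorted(MONOISOTOPIC))


def flank_mass(seq: str, fixed: Optional[Mapping[str, float]] = None) -> Optional[float]:
    """Summed residue mass of a flank, with fixed modification deltas applied.

    Returns ``None`` when the flank contains a residue with no defined mass
    (ambiguity letters), mirroring the matcher's branch-abandon behaviour.
    """
    total = 0.0
    for ch in seq:
        m = MONOISOTOPIC.get(ch)
        if m is None:
            return None
        total += m
        if fixed is not None:
            total += fixed.get(ch, 0.0)
    return total
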