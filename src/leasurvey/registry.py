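"""Shared constants: the seven-group Pfam schema and the cis-element registry.

The LEA family is partitioned into seven groups, each diagnosed by a single
Pfam profile.  The cis-element registry holds the short stress-responsive
promoter motifs scanned by :mod:`leasurvey.promoters`; degenerate positions
use one-letter IUPAC nucleotide codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Pfam accession -> LEA group name.
PROFILE_TO_GROUP: dict[str, str] = {
    "PF03760": "LEA_1",
    "PF03168": "LEA_2",
    "PF03242": "LEA_3",
    "PF02987": "LEA_4",
    "PF00477": "LEA_5",
    "PF00257": "DEHYDRIN",
    "PF04927": "SMP",
}

GROUP_TO_PROFILE: dict[str, str] = {g: p for p, g in PROFILE_TO_GROUP.items()}

#: Canonical ordering of the seven groups, used in reports.
GROUPS: tuple[str, ...] = (
    "LEA_1",
    "LEA_2",
    "LEA_3",
    "LEA_4",
    "LEA_5",
    "DEHYDRIN",
    "SMP",
)

#: The lysine-rich dehydrin K-segment, a conserved 15-residue motif.
K_SEGMENT = "EKKGIMDKIKEKLPG"

#: IUPAC nucleotide degeneracy codes.
IUPAC_DNA: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifRegistry:
    """Named promoter cis-elements as IUPAC degenerate DNA strings.

    Defaults cover the four stress-responsive elements scanned in the
    1 kb promoter analysis: the ABA-responsive element (ABRE), the
    dehydration-responsive element / C-repeat (DRE/CRT, with its leading
    G-or-A encoded as R), the MYB binding site (MYBS) and the
    low-temperature-responsive element (LTRE).  Note that every DRE/CRT
    occurrence necessarily contains an LTRE occurrence; the scanner counts
    the two elements independently.
    """

    entries: dict[str, str] = field(
        default_factory=lambda: {
            "ABRE": "ACGTG",
            "DRE_CRT": "RCCGAC",
            "MYBS": "TAACTG",
            "LTRE": "CCGAC",
        }
    )

    def __post_init__(self) -> None:
        seen = set()
        for name, pattern in self.entries.items():
            if name in seen:
                raise ValueError(f"duplicate motif name {name!r}")
            seen.add(name)
            if len(pattern) < 4:
                raise ValueError(f"motif {name!r} shorter than 4 nt")
            bad = set(pattern) - set(IUPAC_DNA)
            if bad:
                raise ValueError(f"motif {name!r} has non-IUPAC symbols {bad}")

    def __iter__(self):
        return iter(self.entries.items())


DEFAULT_REGISTRY = MotifRegistry()
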