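"""Physicochemical profiling of proteins: molecular weight and GRAVY.

Molecular weight follows the ProtParam convention (average isotopic masses
of the free amino acids, minus one water per peptide bond).  GRAVY (grand
average of hydropathy) is the mean Kyte-Doolittle hydropathy over all
residues; positive values indicate hydrophobic proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqUtils import molecular_weight as _bp_molecular_weight
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .errors import SequenceError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# Kyte J & Doolittle RF (1982) J Mol Biol 157:105-132, Table 1.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def _validate(seq: str) -> str:
    if not seq:
        raise SequenceError("empty protein sequence")
    seq = seq.upper()
    for i, aa in enumerate(seq, start=1):
        if aa not in STANDARD_AA:
            raise SequenceError(f"unknown residue {aa!r} at position {i}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average-isotopic molecular weight of a peptide, in daltons."""
    return float(_bp_molecular_weight(_validate(seq), seq_type="protein"))


def gravy(seq: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value per residue)."""
    return float(ProteinAnalysis(_validate(seq)).gravy())


@dataclass(frozen=True)
class PhyschemRecord:
    protein_id: str
    length: int
    mw: float
    gravy: float


def profile(proteins: Mapping[str, str]) -> list[PhyschemRecord]:
    """Compute a :class:`PhyschemRecord` for every protein in the mapping."""
    out = []
    for pid, seq in proteins.items():
        out.append(
            PhyschemRecord(pid, len(seq), molecular_weight(seq), gravy(seq))
        )
    return out


def records_frame(records: Iterable[PhyschemRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.protein_id, r.length, r.mw, r.gravy) for r in records],
        columns=["protein_id", "length", "mw_da", "gravy"],
    )


def summarize_groups(
    records: Iterable[PhyschemRecord], group_of: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group summary: MW range, mean GRAVY and hydrophobic fraction.

    ``group_of`` maps protein id -> group name and must cover every record.
    Groups absent from the input are absent from the output.
    """
    rows = []
    for r in records:
        if r.protein_id not in group_of:
            raise KeyError(f"no group assignment for protein {r.protein_id!r}")
        rows.append((group_of[r.protein_id], r.mw, r.gravy))
    if not rows:
        return pd.DataFrame(
            columns=["group", "n", "min_mw_da", "max_mw_da",
                     "mean_gravy", "frac_gravy_positive"]
        ).set_index("group")
    df = pd.DataFrame(rows, columns=["group", "mw", "gravy"])
    out = df.groupby("group", sort=True).agg(
        n=("mw", "size"),
        min_mw_da=("mw", "min"),
        max_mw_da=("mw", "max"),
        mean_gravy=("gravy", "mean"),
        frac_gravy_positive=("gravy", lambda s: float((s > 0).mean())),
    )
    return out
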