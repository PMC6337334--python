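"""Amino-acid composition profiling.

Collagen-like adhesive proteins are argued from composition: glycine near or
above 25% and proline near 11% are consistent with triple-helix-forming
Gly-X-Y repeats, and cysteine richness signals disulfide-bonding potential.
This module computes per-residue fractions over the 20 standard amino acids
and raises configurable composition flags.

Fractions are computed over the standard-residue denominator: ambiguity and
non-standard symbols (B, J, O, U, X, Z, ``*``, ``-``) are counted separately
and excluded, since published percentages are conventionally over identified
residues.  Reported percentages round to one decimal; stored fractions keep
full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

#: The 20 standard residues, in alphabetical one-letter order.
STANDARD_RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Symbols tolerated but excluded from the denominator: ambiguity codes,
#: the rare translated residues selenocysteine/pyrrolysine, stops and gaps.
NONSTANDARD_SYMBOLS = frozenset("BJOUXZ*-")

#: Default composition flags: thresholds are inclusive (>=).
DEFAULT_FLAG_RULES: dict[str, tuple[str, float]] = {
    "collagen-like glycine": ("G", 0.20),
    "collagen-like proline": ("P", 0.10),
    "cysteine-rich": ("C", 0.05),
}


class CompositionError(ValueError):
    """Raised for empty or invalid amino-acid sequences."""


@dataclass(frozen=True)
class CompositionProfile:
    """Per-residue fractions of one protein sequence.

    ``fractions`` maps each standard one-letter residue to its fraction of
    ``length_standard`` (the count of standard residues); fractions sum to 1
    when ``length_standard > 0``.  ``n_nonstandard`` counts symbols outside
    the 20-letter alphabet.
    """

    protein_id: str
    length_standard: int
    fractions: Mapping[str, float]
    n_nonstandard: int

    def fraction(self, residue: str) -> float:
        return self.fractions[residue.upper()]

    def percent(self, residue: str) -> float:
        """Fraction as a percentage rounded to one decimal."""
        return round(self.fraction(residue) * 100.0, 1)


def composition_profile(
    sequence: str, protein_id: str = ""
) -> CompositionProfile:
    """Profile one amino-acid sequence (case-insensitive, whitespace ignored).

    Raises :class:`CompositionError` for an empty sequence or for symbols
    that are neither standard residues nor tolerated non-standard symbols.
    """
    cleaned = "".join(sequence.split()).upper()
    if not cleaned:
        raise CompositionError(f"{protein_id or 'sequence'}: empty sequence")
    counts = {r: 0 for r in STANDARD_RESIDUES}
    n_nonstandard = 0
    for symbol in cleaned:
        if symbol in counts:
            counts[symbol] += 1
        elif symbol in NONSTANDARD_SYMBOLS:
            n_nonstandard += 1
        else:
            raise CompositionError(
                f"{protein_id or 'sequence'}: invalid symbol {symbol!r}"
            )
    length = sum(counts.values())
    fractions = {
        r: (counts[r] / length if length else 0.0) for r in STANDARD_RESIDUES
    }
    return CompositionProfile(
        protein_id=protein_id,
        length_standard=length,
        fractions=fractions,
        n_nonstandard=n_nonstandard,
    )


def flag_composition(
    profile: CompositionProfile,
    rules: Mapping[str, tuple[str, float]] = DEFAULT_FLAG_RULES,
) -> list[str]:
    """Return the names of all flags whose residue fraction meets its minimum.

    ``rules`` maps flag name to ``(residue, minimum fraction)``; the bound is
    inclusive.  Flags are returned in rule-declaration order.
    """
    return [
        name
        for name, (residue, minimum) in rules.items()
        if profile.fraction(residue) >= minimum
    ]


def batch_composition(fasta_path: str | Path) -> list[CompositionProfile]:
    """Profile every record of a FASTA file, preserving record order.

    Record IDs are the first whitespace-delimited token of the header.
    Duplicate IDs are an error.
    """
    fasta_path = Path(fasta_path)
    profiles: list[CompositionProfile] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in seen:
            raise CompositionError(
                f"{fasta_path}: duplicate record ID {record.id!r}"
            )
        seen.add(record.id)
        profiles.append(composition_profile(str(record.seq), record.id))
    return profiles


def composition_table(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    """Tabulate profiles: ID, standard length, 20 fraction columns, flags."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "protein_id": p.protein_id,
            "length_standard": p.length_standard,
        }
        for residue in STANDARD_RESIDUES:
            row[f"frac_{residue}"] = p.fractions[residue]
        row["n_nonstandard"] = p.n_nonstandard
        row["flags"] = ";".join(flag_composition(p))
        rows.append(row)
    columns = (
        ["protein_id", "length_standard"]
        + [f"frac_{r}" for r in STANDARD_RESIDUES]
        + ["n_nonstandard", "flags"]
    )
    return pd.DataFrame(rows, columns=columns)


def write_composition_table(
    profiles: Iterable[CompositionProfile], path: str | Path
) -> None:
    composition_table(profiles).to_csv(path, sep="\t", index=False)
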