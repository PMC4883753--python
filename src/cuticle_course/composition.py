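"""Amino-acid composition screening for candidate cuticle proteins.

Cuticle proteins are often short (< 200 aa) and compositionally biased —
missing residues entirely (commonly Trp or Cys) or dominated by a single
residue (> 20% Ala or Val, occasionally > 30%), whereas a typical protein
holds no residue above ~10%.  The screen reports exact per-residue fractions
and flags each protein against configurable thresholds.

Non-standard letters (X, U, B, Z, ...) are excluded from the denominator and
reported, never silently dropped into a standard bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io_model import STANDARD_AA, ProteinSet

__all__ = ["CompositionReport", "compose", "screen_candidates"]

#: three-letter display names for flag reporting
AA_NAMES = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}


@dataclass
class CompositionReport:
    """Exact composition of one protein over the 20 standard residues."""

    protein_id: str
    length: int                       # standard residues counted
    fractions: dict[str, float]       # residue -> fraction; sums to 1
    nonstandard: dict[str, int]       # excluded letters and their counts
    short_len: int = 200
    high_single_frac: float = 0.20

    @property
    def absent_residues(self) -> frozenset[str]:
        return frozenset(a for a in STANDARD_AA if self.fractions[a] == 0)

    @property
    def max_residue(self) -> str:
        return max(STANDARD_AA, key=lambda a: (self.fractions[a], a))

    @property
    def max_fraction(self) -> float:
        return self.fractions[self.max_residue]

    @property
    def is_short(self) -> bool:
        return self.length < self.short_len

    @property
    def has_high_single_residue(self) -> bool:
        return self.max_fraction >= self.high_single_frac


def compose(sequence: str, protein_id: str = "", short_len: int = 200,
            high_single_frac: float = 0.20) -> CompositionReport:
    """Exact residue counts and fractions for one amino-acid sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {a: 0 for a in STANDARD_AA}
    nonstandard: dict[str, int] = {}
    for c in seq:
        if c in counts:
            counts[c] += 1
        else:
            nonstandard[c] = nonstandard.get(c, 0) + 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("sequence contains no standard residues")
    fractions = {a: counts[a] / n for a in STANDARD_AA}
    return CompositionReport(protein_id, n, fractions, nonstandard,
                             short_len, high_single_frac)


def screen_candidates(proteins: ProteinSet, short_len: int = 200,
                      high_frac: float = 0.20, very_high_frac: float = 0.30,
                      avg_cap: float = 0.10
                      ) -> tuple[pd.DataFrame, dict[str, object]]:
    """Composition flags per protein plus flag counts across the set.

    Flags: ``short`` (< ``short_len`` aa), ``lacks_<Res>`` per absent
    residue, ``high_<Res>`` (fraction >= ``high_frac``), ``very_high_<Res>``
    (>= ``very_high_frac``), ``exceeds_avg_cap`` (max fraction >
    ``avg_cap``, the "average protein" ceiling).
    """
    for f in (high_frac, very_high_frac, avg_cap):
        if not 0 < f < 1:
            raise ValueError("fraction thresholds must lie in (0, 1)")
    rows = []
    lacks_counts = {a: 0 for a in STANDARD_AA}
    high_counts = {a: 0 for a in STANDARD_AA}
    very_high_counts = {a: 0 for a in STANDARD_AA}
    n_short = n_cap = 0
    for pid, seq in proteins.records.items():
        rep = compose(seq, pid, short_len, high_frac)
        absent = rep.absent_residues
        high = {a for a in STANDARD_AA if rep.fractions[a] >= high_frac}
        very_high = {a for a in STANDARD_AA if rep.fractions[a] >= very_high_frac}
        for a in absent:
            lacks_counts[a] += 1
        for a in high:
            high_counts[a] += 1
        for a in very_high:
            very_high_counts[a] += 1
        n_short += rep.is_short
        exceeds = rep.max_fraction > avg_cap
        n_cap += exceeds
        rows.append({
            "protein_id": pid,
            "length": rep.length,
            "short": rep.is_short,
            "max_residue": AA_NAMES[rep.max_residue],
            "max_fraction": rep.max_fraction,
            "absent_residues": ",".join(sorted(AA_NAMES[a] for a in absent)),
            "high_residues": ",".join(sorted(AA_NAMES[a] for a in high)),
            "very_high_residues": ",".join(sorted(AA_NAMES[a] for a in very_high)),
            "exceeds_avg_cap": exceeds,
            "nonstandard": ",".join(sorted(rep.nonstandard)),
        })
    summary = {
        "n_proteins": len(proteins),
        "n_short": n_short,
        "n_exceeds_avg_cap": n_cap,
        "lacking": {AA_NAMES[a]: c for a, c in lacks_counts.items() if c},
        "high": {AA_NAMES[a]: c for a, c in high_counts.items() if c},
        "very_high": {AA_NAMES[a]: c for a, c in very_high_counts.items() if c},
    }
    return pd.DataFrame(rows), summary
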