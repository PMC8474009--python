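"""In-silico tryptic digestion.

Trypsin cleaves C-terminal to lysine (K) and arginine (R).  By default no
proline suppression is applied: cleavage before P is allowed, so e.g. the
bond K|P is cut.  This matters for short-peptide rescue cases where the fully
cleaved form ends at a K immediately followed by P in the protein.  Pass
``suppress_proline=True`` for the classical KP/RP-protected rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import STANDARD_RESIDUES


class DigestError(ValueError):
    """Raised for invalid protein sequences or digestion parameters."""


@dataclass(frozen=True)
class ProteinEntry:
    """One proteome entry; ``sequence`` uses uppercase one-letter codes."""

    gene_symbol: str
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DigestError(f"{self.gene_symbol}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise DigestError(
                f"{self.gene_symbol}: non-standard residue(s) {sorted(bad)!r}"
            )


@dataclass
class CandidatePeptide:
    """A tryptic peptide window of a protein, 1-based inclusive coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    phospho_positions: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def cleavage_sites(sequence: str, suppress_proline: bool = False) -> list[int]:
    """0-based indices i such that the bond after ``sequence[i]`` is cut.

    The protein C-terminus is not a cleavage site (nothing follows it).
    """
    sites = []
    for i, res in enumerate(sequence[:-1]):
        if res in "KR":
            if suppress_proline and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(
    protein: ProteinEntry,
    max_missed: int = 2,
    suppress_proline: bool = False,
) -> list[CandidatePeptide]:
    """All tryptic peptides of ``protein`` with up to ``max_missed`` missed cleavages.

    Returns peptides ordered by start coordinate then length.  The 0-missed
    peptides tile the protein exactly.
    """
    if not 0 <= max_missed <= 2:
        raise DigestError(f"max_missed must be in 0..2, got {max_missed}")
    seq = protein.sequence
    sites = cleavage_sites(seq, suppress_proline)
    # Fragment boundaries: start offsets of fully cleaved peptides.
    starts = [0] + [i + 1 for i in sites]
    ends = [i for i in sites] + [len(seq) - 1]  # 0-based inclusive ends
    n_frag = len(starts)
    peptides = []
    for a in range(n_frag):
        for missed in range(max_missed + 1):
            b = a + missed
            if b >= n_frag:
                break
            s, e = starts[a], ends[b]
            peptides.append(
                CandidatePeptide(
                    sequence=seq[s : e + 1],
                    start=s + 1,
                    end=e + 1,
                    missed_cleavages=missed,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides
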