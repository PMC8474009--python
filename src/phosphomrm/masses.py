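"""Monoisotopic mass and m/z arithmetic for modified peptides.

A ``ModifiedPeptide`` carries phosphate and stable-isotope-label modifications
at 1-based positions.  Fragment ions follow the b/y convention:

    b_i = sum of the first i residue masses (+ mods inside) + charge * proton
    y_i = sum of the last  i residue masses (+ mods inside) + water + charge * proton

each divided by the charge.  For singly charged fragments this gives the
complementarity identity m(b_i) + m(y_{n-i}) - 2*proton = monoisotopic mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import HEAVY_DELTA, PHOSPHO, PROTON, RESIDUE_MASS, WATER


class MassError(ValueError):
    pass


MOD_KINDS = ("phospho", "heavy_K", "heavy_R", "heavy_L", "heavy_P")


@dataclass(frozen=True)
class ModifiedPeptide:
    """Peptide sequence with (kind, 1-based position) modifications."""

    sequence: str
    mods: tuple[tuple[str, int], ...] = ()
    charge: int = 2
    label: str = "light"

    def __post_init__(self) -> None:
        for res in self.sequence:
            if res not in RESIDUE_MASS:
                raise MassError(f"unknown residue {res!r}")
        n_heavy = 0
        for kind, pos in self.mods:
            if kind not in MOD_KINDS:
                raise MassError(f"unknown modification kind {kind!r}")
            if not 1 <= pos <= len(self.sequence):
                raise MassError(f"modification position {pos} outside peptide")
            res = self.sequence[pos - 1]
            if kind == "phospho" and res not in "STY":
                raise MassError(f"phospho on non-acceptor residue {res!r} at {pos}")
            if kind.startswith("heavy_"):
                n_heavy += 1
                if res != kind[-1]:
                    raise MassError(
                        f"heavy label {kind} does not match residue {res!r} at {pos}"
                    )
        if self.label == "heavy" and n_heavy != 1:
            raise MassError("heavy peptide must carry exactly one labeled residue")

    @property
    def phospho_positions(self) -> list[int]:
        return [pos for kind, pos in self.mods if kind == "phospho"]


def _mod_delta(kind: str) -> float:
    if kind == "phospho":
        return PHOSPHO
    return HEAVY_DELTA[kind[-1]]


def monoisotopic_mass(peptide: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass in Da, including all modifications."""
    mass = WATER + sum(RESIDUE_MASS[r] for r in peptide.sequence)
    mass += sum(_mod_delta(kind) for kind, _ in peptide.mods)
    return mass


def precursor_mz(peptide: ModifiedPeptide, charge: int | None = None) -> float:
    charge = peptide.charge if charge is None else charge
    if charge < 1:
        raise MassError(f"charge must be >= 1, got {charge}")
    return (monoisotopic_mass(peptide) + charge * PROTON) / charge


def fragment_mz(
    peptide: ModifiedPeptide, series: str, index: int, charge: int = 1
) -> float:
    """m/z of the b- or y-series fragment at the given index and charge."""
    n = len(peptide.sequence)
    if series not in ("b", "y"):
        raise MassError(f"series must be 'b' or 'y', got {series!r}")
    if not 1 <= index <= n - 1:
        raise MassError(f"fragment index {index} out of range for length {n}")
    if charge < 1:
        raise MassError(f"charge must be >= 1, got {charge}")
    if series == "b":
        span = range(1, index + 1)
        base = 0.0
    else:
        span = range(n - index + 1, n + 1)
        base = WATER
    positions = set(span)
    mass = base + sum(RESIDUE_MASS[peptide.sequence[p - 1]] for p in span)
    mass += sum(_mod_delta(kind) for kind, pos in peptide.mods if pos in positions)
    return (mass + charge * PROTON) / charge


def fragment_span(sequence_length: int, series: str, index: int) -> range:
    """1-based residue positions covered by a fragment."""
    if series == "b":
        return range(1, index + 1)
    return range(sequence_length - index + 1, sequence_length + 1)


@dataclass
class Transition:
    """One precursor -> product ion pair monitored by the instrument."""

    precursor_mz: float
    product_series: str
    product_index: int
    product_charge: int
    product_mz: float
    collision_energy: float = 0.0
    rank: int = 0
    site_determining: bool = False

    @property
    def fragment_ion(self) -> str:
        name = f"{self.product_series}{self.product_index}"
        if self.product_charge > 1:
            name += f"^{self.product_charge}"
        return name
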