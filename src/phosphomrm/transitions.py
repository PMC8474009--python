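"""Transition selection, site-determining calls and collision energies.

The manual curation step of targeted-assay development — pick the best 3-6
transitions, preferring y-ions above the precursor m/z and ions that
localize the phosphosite — is replaced here by a deterministic tiered sort
over the spectral library.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import CE_COEFFICIENTS
from .masses import (
    MassError,
    ModifiedPeptide,
    Transition,
    fragment_mz,
    fragment_span,
    precursor_mz,
)


class TransitionError(ValueError):
    pass


@dataclass
class SpectralLibraryEntry:
    """Relative fragment intensities and retention time for one peptide."""

    peptide: ModifiedPeptide
    fragment_intensities: dict[tuple[str, int, int], float]  # (series, index, charge)
    retention_time: float  # minutes

    def __post_init__(self) -> None:
        if len(self.fragment_intensities) < 3:
            raise TransitionError("spectral library entry needs >= 3 fragments")
        if any(v < 0 for v in self.fragment_intensities.values()):
            raise TransitionError("negative library intensity")


def site_determining(peptide: ModifiedPeptide, series: str, index: int) -> bool:
    """Whether a fragment helps localize the phosphosite.

    True when the fragment span contains a phosphorylated residue, or when the
    fragment boundary separates the phosphosite from an alternative S/T/Y
    acceptor (the fragment mass then distinguishes positional isomers).
    """
    phospho = peptide.phospho_positions
    if not phospho:
        return False
    span = set(fragment_span(len(peptide.sequence), series, index))
    if any(p in span for p in phospho):
        return True
    acceptors = [
        i for i, r in enumerate(peptide.sequence, start=1)
        if r in "STY" and i not in phospho
    ]
    # Phosphosite outside the span: informative iff an alternative acceptor is inside.
    return any(a in span for a in acceptors)


def rank_transitions(
    entry: SpectralLibraryEntry,
    n_min: int = 3,
    n_max: int = 6,
) -> list[Transition]:
    """Deterministic tiered ranking of library fragments.

    Tier 1: y-ions with product m/z above the precursor m/z.
    Tier 2: site-determining ions of any series not already in tier 1.
    Tier 3: remaining y-ions.  Tier 4: b-ions.
    Within a tier, sort by library intensity descending; ties by higher
    product m/z, y before b, lower index.  All of tiers 1-2 are taken up to
    ``n_max``; tiers 3-4 pad the list up to ``n_min``.
    """
    if not 1 <= n_min <= n_max:
        raise TransitionError("need 1 <= n_min <= n_max")
    pep = entry.peptide
    pre_mz = precursor_mz(pep)
    scored = []
    for (series, index, charge), intensity in entry.fragment_intensities.items():
        try:
            mz = fragment_mz(pep, series, index, charge)
        except MassError as exc:
            raise TransitionError(str(exc)) from exc
        sd = site_determining(pep, series, index)
        if series == "y" and mz > pre_mz:
            tier = 1
        elif sd:
            tier = 2
        elif series == "y":
            tier = 3
        else:
            tier = 4
        scored.append((tier, -intensity, -mz, 0 if series == "y" else 1, index, series, charge, mz, sd))
    scored.sort()
    chosen = []
    for s in scored:
        tier, _, _, _, index, series, charge, mz, sd = s
        if tier <= 2:
            if len(chosen) < n_max:
                chosen.append((series, index, charge, mz, sd))
        elif len(chosen) < n_min:
            chosen.append((series, index, charge, mz, sd))
    transitions = [
        Transition(
            precursor_mz=pre_mz,
            product_series=series,
            product_index=index,
            product_charge=charge,
            product_mz=mz,
            rank=i + 1,
            site_determining=sd,
        )
        for i, (series, index, charge, mz, sd) in enumerate(chosen)
    ]
    return transitions


def calc_ce(
    precursor_mz_value: float,
    charge: int,
    coefficients: dict[int, tuple[float, float]] | None = None,
) -> float:
    """Linear instrument collision energy, rounded to 0.1 eV."""
    coefficients = coefficients or CE_COEFFICIENTS
    if charge not in coefficients:
        raise TransitionError(f"no CE coefficients for charge {charge}+")
    slope, intercept = coefficients[charge]
    return round(slope * precursor_mz_value + intercept, 1)


def ce_schedule(center_ce: float, n_each_side: int = 5, step: float = 2.0) -> list[float]:
    """The optimization ramp: the calculated CE plus ``n_each_side`` values
    below and above in ``step`` increments, clipped at 0 (duplicates kept;
    instrument export de-duplicates)."""
    values = [
        max(0.0, center_ce + step * k)
        for k in range(-n_each_side, n_each_side + 1)
    ]
    return values
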