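"""Phosphopeptide panel construction.

Turns a proteome plus a list of nominated phosphosites into a vetted panel of
phosphopeptides following a fixed, deterministic decision procedure:

1. map each site onto every tryptic peptide window containing it;
2. drop forms longer than 40 residues;
3. rescue sub-6-residue fully cleaved forms via observed missed-cleaved forms;
4. among surviving forms prefer the most frequently observed one (ties: fewest
   missed cleavages, then shortest);
5. prefer the singly phosphorylated form unless the doubly phosphorylated form
   is markedly more prevalent (ratio >= ``prevalence_factor``, default 3);
6. keep rejected sites with an explicit reason rather than dropping them.

Site labels follow the "<GENE> p<Residue><Position>" convention with 1-based
protein coordinates, e.g. "LATS2 pS380"; modified sequences are written like
"RD(pS)LQKPGLEAPPR".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .digest import CandidatePeptide, ProteinEntry


class PanelError(ValueError):
    pass


VALID_ROUTES = ("IMAC", "pY", "IMACpY")
REJECTION_REASONS = (
    "too_long",
    "too_short_no_rescue",
    "not_observed",
    "synthesis_fail",
    "none",
)

MIN_LENGTH = 6
MAX_LENGTH = 40


@dataclass(frozen=True)
class SiteNomination:
    """A nominated phosphosite: gene, residue (S/T/Y) and 1-based position."""

    gene_symbol: str
    residue: str
    position: int
    source: str = "nominated"  # or "discovery"

    def __post_init__(self) -> None:
        if self.residue not in "STY":
            raise PanelError(
                f"{self.gene_symbol} position {self.position}: phosphosite residue "
                f"must be S, T or Y, got {self.residue!r}"
            )

    @property
    def label_suffix(self) -> str:
        return f"p{self.residue}{self.position}"


@dataclass
class EvidenceRecord:
    """Observation history for one modified peptide form."""

    count: int = 0
    routes: frozenset[str] = frozenset()


class ObservationEvidence:
    """Map of modified-peptide form -> historical observation evidence.

    Keys are modified-sequence strings in the "D(pS)LQK" notation.
    """

    def __init__(self, records: dict[str, EvidenceRecord] | None = None):
        self.records: dict[str, EvidenceRecord] = dict(records or {})

    def add(self, modified_sequence: str, count: int, routes=()) -> None:
        if count < 0:
            raise PanelError(f"negative observation count for {modified_sequence}")
        self.records[modified_sequence] = EvidenceRecord(
            count=count, routes=frozenset(routes)
        )

    def count(self, modified_sequence: str) -> int:
        rec = self.records.get(modified_sequence)
        return rec.count if rec else 0

    def routes(self, modified_sequence: str) -> frozenset[str]:
        rec = self.records.get(modified_sequence)
        return rec.routes if rec else frozenset()

    def doubly_forms(self, sequence: str, offset: int) -> list[tuple[str, int]]:
        """Observed doubly phosphorylated forms of ``sequence`` that include a
        phosphate at 1-based peptide ``offset``.  Returns (form, count) pairs."""
        out = []
        for form, rec in self.records.items():
            seq, offsets = parse_modified(form)
            if seq == sequence and len(offsets) == 2 and offset in offsets:
                out.append((form, rec.count))
        return out


@dataclass
class PanelEntry:
    """One selected (or rejected) phosphopeptide panel row."""

    site_labels: list[str]
    modified_sequence: str
    sequence: str
    phospho_offsets: list[int]  # 1-based within peptide
    gene_symbol: str
    status: str = "selected"
    rejection_reason: str = "none"
    enrichment_route: str = ""
    shared_genes: list[str] = field(default_factory=list)
    heavy_label_residue: str = ""  # e.g. "K14"
    missed_cleavages: int = 0
    start: int = 0
    end: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_selected(self) -> bool:
        return self.status == "selected"


def format_modified(sequence: str, phospho_offsets: list[int]) -> str:
    """Render "DSLQK" with phosphate at offset 2 as "D(pS)LQK"."""
    marked = set(phospho_offsets)
    out = []
    for i, res in enumerate(sequence, start=1):
        out.append(f"(p{res})" if i in marked else res)
    return "".join(out)


_MOD_TOKEN = re.compile(r"\(p([STY])\)|([A-Z])")


def parse_modified(modified_sequence: str) -> tuple[str, list[int]]:
    """Inverse of :func:`format_modified`."""
    seq, offsets, pos = [], [], 0
    for m in _MOD_TOKEN.finditer(modified_sequence):
        pos += 1
        if m.group(1):
            seq.append(m.group(1))
            offsets.append(pos)
        else:
            seq.append(m.group(2))
    return "".join(seq), offsets


def map_site(
    site: SiteNomination,
    peptides: list[CandidatePeptide],
    protein: ProteinEntry | None = None,
) -> list[CandidatePeptide]:
    """Peptide windows containing the site, sorted by missed cleavages.

    Each returned candidate is a copy with ``phospho_positions`` set to the
    site's 1-based offset within the peptide.
    """
    if protein is not None:
        if not 1 <= site.position <= len(protein.sequence):
            raise PanelError(
                f"{site.gene_symbol} {site.label_suffix}: position outside protein "
                f"(length {len(protein.sequence)})"
            )
        actual = protein.sequence[site.position - 1]
        if actual != site.residue:
            raise PanelError(
                f"{site.gene_symbol} {site.label_suffix}: sequence has {actual!r} "
                f"at position {site.position}"
            )
    hits = []
    for pep in peptides:
        if pep.start <= site.position <= pep.end:
            offset = site.position - pep.start + 1
            hits.append(
                CandidatePeptide(
                    sequence=pep.sequence,
                    start=pep.start,
                    end=pep.end,
                    missed_cleavages=pep.missed_cleavages,
                    phospho_positions=[offset],
                )
            )
    hits.sort(key=lambda p: (p.missed_cleavages, p.length))
    return hits


def _singly_form(pep: CandidatePeptide) -> str:
    return format_modified(pep.sequence, pep.phospho_positions)


def select_peptide(
    candidates: list[CandidatePeptide],
    evidence: ObservationEvidence,
    site: SiteNomination,
    include_unobserved: bool = False,
    prevalence_factor: float = 3.0,
) -> PanelEntry:
    """Apply the length / evidence / multiplicity selection rules to the
    candidate forms of one site and return a selected or rejected entry."""
    if not candidates:
        raise PanelError(f"{site.gene_symbol} {site.label_suffix}: no candidates")
    label = f"{site.gene_symbol} {site.label_suffix}"

    def rejected(reason: str, pep: CandidatePeptide) -> PanelEntry:
        return PanelEntry(
            site_labels=[label],
            modified_sequence=_singly_form(pep),
            sequence=pep.sequence,
            phospho_offsets=list(pep.phospho_positions),
            gene_symbol=site.gene_symbol,
            status="rejected",
            rejection_reason=reason,
            missed_cleavages=pep.missed_cleavages,
            start=pep.start,
            end=pep.end,
        )

    within_max = [p for p in candidates if p.length <= MAX_LENGTH]
    if not within_max:
        shortest = min(candidates, key=lambda p: p.length)
        return rejected("too_long", shortest)

    in_range = [p for p in within_max if p.length >= MIN_LENGTH]
    if not in_range:
        # Only sub-6-residue forms exist at all.
        return rejected("too_short_no_rescue", within_max[0])

    fully_cleaved = min(within_max, key=lambda p: p.missed_cleavages)
    needs_rescue = fully_cleaved.length < MIN_LENGTH
    if needs_rescue:
        observed = [p for p in in_range if evidence.count(_singly_form(p)) > 0]
        if not observed:
            return rejected("too_short_no_rescue", fully_cleaved)
        pool = observed
    else:
        pool = in_range

    best = min(
        pool,
        key=lambda p: (-evidence.count(_singly_form(p)), p.missed_cleavages, p.length),
    )
    singly_count = evidence.count(_singly_form(best))
    if singly_count == 0 and not include_unobserved:
        return rejected("not_observed", best)

    # Singly vs doubly phosphorylated form of the winning peptide window.
    offsets = list(best.phospho_positions)
    modified = _singly_form(best)
    doubly = evidence.doubly_forms(best.sequence, best.phospho_positions[0])
    if doubly:
        dform, dcount = max(doubly, key=lambda fc: fc[1])
        if dcount >= prevalence_factor * max(singly_count, 1):
            modified = dform
            offsets = parse_modified(dform)[1]

    entry = PanelEntry(
        site_labels=[label],
        modified_sequence=modified,
        sequence=best.sequence,
        phospho_offsets=offsets,
        gene_symbol=site.gene_symbol,
        status="selected",
        missed_cleavages=best.missed_cleavages,
        start=best.start,
        end=best.end,
    )
    entry.heavy_label_residue = assign_heavy_label(entry)
    return entry


def assign_heavy_label(entry: PanelEntry, protein_length: int | None = None) -> str:
    """Pick the stable-isotope labeled residue for synthesis.

    C-terminal K/R is labeled when present (the tryptic norm).  Peptides from
    a protein C-terminus lack one; fall back to an N-terminal K/R, then to an
    internal L or P.
    """
    seq = entry.sequence
    if seq[-1] in "KR":
        return f"{seq[-1]}{len(seq)}"
    if seq[0] in "KR":
        return f"{seq[0]}1"
    for i, res in enumerate(seq, start=1):
        if res in "LP":
            return f"{res}{i}"
    return ""


def annotate_uniqueness(
    entry: PanelEntry, proteome: list[ProteinEntry]
) -> list[str]:
    """All genes whose sequence contains the unmodified peptide verbatim.

    Exact substring matching, no I/L folding.  Sets ``entry.shared_genes``.
    """
    if not proteome:
        raise PanelError("empty proteome")
    genes = sorted(
        {p.gene_symbol for p in proteome if entry.sequence in p.sequence}
    )
    entry.shared_genes = genes
    return genes


def assign_route(entry: PanelEntry, evidence: ObservationEvidence) -> str:
    """Enrichment route: pS/pT-only -> IMAC; pY-containing -> pY, or IMACpY
    when historically detected under both enrichments."""
    has_py = any(entry.sequence[o - 1] == "Y" for o in entry.phospho_offsets)
    if not has_py:
        route = "IMAC"
    else:
        seen = evidence.routes(entry.modified_sequence)
        route = "IMACpY" if {"IMAC", "pY"} <= seen else "pY"
    entry.enrichment_route = route
    return route


def check_conservation(entry: PanelEntry, other_proteome: list[ProteinEntry]) -> bool:
    """True iff the unmodified peptide occurs verbatim in the other proteome."""
    if not other_proteome:
        raise PanelError("empty proteome")
    return any(entry.sequence in p.sequence for p in other_proteome)


def build_panel(
    proteome: list[ProteinEntry],
    sites: list[SiteNomination],
    evidence: ObservationEvidence,
    max_missed: int = 2,
    prevalence_factor: float = 3.0,
    include_unobserved: set[str] | None = None,
    suppress_proline: bool = False,
) -> list[PanelEntry]:
    """Run the whole selection for every nominated site.

    ``include_unobserved`` lists "<GENE> p<Res><Pos>" labels that are kept in
    the panel despite lacking historical observation.
    """
    from .digest import digest

    include_unobserved = include_unobserved or set()
    by_gene = {p.gene_symbol: p for p in proteome}
    entries: list[PanelEntry] = []
    for site in sites:
        protein = by_gene.get(site.gene_symbol)
        if protein is None:
            raise PanelError(f"unknown gene {site.gene_symbol!r}")
        peptides = digest(protein, max_missed, suppress_proline=suppress_proline)
        candidates = map_site(site, peptides, protein)
        label = f"{site.gene_symbol} {site.label_suffix}"
        entry = select_peptide(
            candidates,
            evidence,
            site,
            include_unobserved=label in include_unobserved,
            prevalence_factor=prevalence_factor,
        )
        if entry.is_selected:
            annotate_uniqueness(entry, proteome)
            assign_route(entry, evidence)
        entries.append(entry)
    return entries


def qc_summary(
    n_synthesized: int, n_config_failed: int, n_enrichment_failed: int
) -> dict[str, float]:
    """Panel QC bookkeeping: survivors and detection success rate.

    ``success_rate_pct`` is surviving / synthesized as a percentage.
    """
    surviving = n_synthesized - n_config_failed - n_enrichment_failed
    if surviving < 0:
        raise PanelError("more failures than synthesized peptides")
    return {
        "n_synthesized": n_synthesized,
        "n_surviving": surviving,
        "success_rate_pct": 100.0 * surviving / n_synthesized,
    }


def quantification_rate(n_quantified: int, n_detected: int) -> float:
    """Percentage of detected peptides that were quantified."""
    if n_detected <= 0:
        raise PanelError("n_detected must be positive")
    if n_quantified > n_detected:
        raise PanelError("quantified cannot exceed detected")
    return 100.0 * n_quantified / n_detected


def assay_unique_sites(n_detected: int, n_overlap_full: int, n_overlap_partial: int) -> int:
    """Sites seen by the targeted assay but absent from a discovery dataset."""
    unique = n_detected - n_overlap_full - n_overlap_partial
    if unique < 0:
        raise PanelError("overlap exceeds detected sites")
    return unique
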