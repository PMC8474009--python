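"""File formats, run configuration and panel validation.

All tables are UTF-8 with "." decimal separators; TSV for panel/evidence/
chromatogram/quant/manifest tables, CSV for instrument-facing transition
lists.  m/z values are written with 5 decimals.  FASTA headers are parsed as
"accession|gene".
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import constants
from .digest import ProteinEntry
from .masses import Transition
from .method import Mixture
from .panel import (
    ObservationEvidence,
    PanelEntry,
    SiteNomination,
    parse_modified,
)
from .quant import ChromTrace, QuantRecord


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Numeric knobs of the whole pipeline with the assay's defaults."""

    py_threshold: float = constants.HEIGHT_THRESHOLD["pY"]
    imac_threshold: float = constants.HEIGHT_THRESHOLD["IMAC"]
    rt_window: float = constants.RT_WINDOW_MIN
    imac_mixture_min: int = constants.MIXTURE_BOUNDS["IMAC"][0]
    imac_mixture_max: int = constants.MIXTURE_BOUNDS["IMAC"][1]
    py_mixture_min: int = constants.MIXTURE_BOUNDS["pY"][0]
    py_mixture_max: int = constants.MIXTURE_BOUNDS["pY"][1]
    ce_slope_2: float = constants.CE_COEFFICIENTS[2][0]
    ce_intercept_2: float = constants.CE_COEFFICIENTS[2][1]
    ce_slope_3: float = constants.CE_COEFFICIENTS[3][0]
    ce_intercept_3: float = constants.CE_COEFFICIENTS[3][1]
    interference_cutoff: float = 0.2
    alpha_cell_line: float = 0.05
    alpha_tissue: float = 0.1
    prevalence_factor: float = 3.0
    max_missed: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("py_threshold", "imac_threshold", "rt_window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def height_thresholds(self) -> dict[str, float]:
        return {"pY": self.py_threshold, "IMAC": self.imac_threshold}

    @property
    def mixture_bounds(self) -> dict[str, tuple[int, int]]:
        return {
            "IMAC": (self.imac_mixture_min, self.imac_mixture_max),
            "pY": (self.py_mixture_min, self.py_mixture_max),
            "IMACpY": constants.MIXTURE_BOUNDS["IMACpY"],
        }

    @property
    def ce_coefficients(self) -> dict[int, tuple[float, float]]:
        return {
            2: (self.ce_slope_2, self.ce_intercept_2),
            3: (self.ce_slope_3, self.ce_intercept_3),
        }


def read_config(path) -> RunConfig:
    """TOML config -> RunConfig; absent keys default, unknown keys reject."""
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# FASTA and design tables
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinEntry]:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, _, gene = rec.id.partition("|")
        entries.append(
            ProteinEntry(gene_symbol=gene or accession, accession=accession,
                         sequence=str(rec.seq).upper())
        )
    return entries


def write_fasta(proteome: list[ProteinEntry], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=f"{p.accession}|{p.gene_symbol}", description="")
        for p in proteome
    ]
    SeqIO.write(records, str(path), "fasta")


def read_nominations(path) -> list[SiteNomination]:
    df = pd.read_csv(path, sep="\t")
    _require(df, {"gene", "residue", "position"}, path)
    return [
        SiteNomination(
            gene_symbol=row["gene"],
            residue=row["residue"],
            position=int(row["position"]),
            source=row.get("source", "nominated"),
        )
        for _, row in df.iterrows()
    ]


def write_nominations(sites: list[SiteNomination], path) -> None:
    pd.DataFrame(
        [
            {"gene": s.gene_symbol, "residue": s.residue,
             "position": s.position, "source": s.source}
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def read_evidence(path) -> ObservationEvidence:
    df = pd.read_csv(path, sep="\t")
    _require(df, {"modified_sequence", "count"}, path)
    ev = ObservationEvidence()
    for _, row in df.iterrows():
        routes = row.get("routes", "")
        routes = set(str(routes).split("/")) - {"", "nan"} if pd.notna(routes) else set()
        ev.add(row["modified_sequence"], int(row["count"]), routes)
    return ev


def write_evidence(evidence: ObservationEvidence, path) -> None:
    pd.DataFrame(
        [
            {"modified_sequence": k, "count": r.count,
             "routes": "/".join(sorted(r.routes))}
            for k, r in sorted(evidence.records.items())
        ]
    ).to_csv(path, sep="\t", index=False)


PANEL_COLUMNS = [
    "site_labels", "gene", "modified_sequence", "sequence", "phospho_offsets",
    "status", "rejection_reason", "enrichment_route", "shared_genes",
    "heavy_label_residue", "missed_cleavages", "start", "end",
]


def write_panel(entries: list[PanelEntry], path) -> None:
    rows = [
        {
            "site_labels": "/".join(e.site_labels),
            "gene": e.gene_symbol,
            "modified_sequence": e.modified_sequence,
            "sequence": e.sequence,
            "phospho_offsets": "/".join(map(str, e.phospho_offsets)),
            "status": e.status,
            "rejection_reason": e.rejection_reason,
            "enrichment_route": e.enrichment_route,
            "shared_genes": "/".join(e.shared_genes),
            "heavy_label_residue": e.heavy_label_residue,
            "missed_cleavages": e.missed_cleavages,
            "start": e.start,
            "end": e.end,
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel(path) -> list[PanelEntry]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require(df, {"site_labels", "gene", "modified_sequence", "status"}, path)
    entries = []
    for _, row in df.iterrows():
        seq, offsets = parse_modified(row["modified_sequence"])
        entries.append(
            PanelEntry(
                site_labels=str(row["site_labels"]).split("/"),
                modified_sequence=row["modified_sequence"],
                sequence=row.get("sequence", seq) or seq,
                phospho_offsets=offsets,
                gene_symbol=row["gene"],
                status=row["status"],
                rejection_reason=row.get("rejection_reason", "none") or "none",
                enrichment_route=row.get("enrichment_route", ""),
                shared_genes=[g for g in str(row.get("shared_genes", "")).split("/") if g],
                heavy_label_residue=row.get("heavy_label_residue", ""),
                missed_cleavages=int(row.get("missed_cleavages", 0) or 0),
                start=int(row.get("start", 0) or 0),
                end=int(row.get("end", 0) or 0),
            )
        )
    return entries


def validate_panel_file(path) -> pd.DataFrame:
    """Per-row invariant diagnostics for a panel TSV.

    Empty result means a clean file.  Checked: selected length in [6, 40],
    phospho count in {1, 2}, valid route and status values.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require(df, {"modified_sequence", "status"}, path)
    problems = []
    for i, row in df.iterrows():
        seq, offsets = parse_modified(row["modified_sequence"])
        if row["status"] not in ("selected", "rejected"):
            problems.append((i, f"invalid status {row['status']!r}"))
            continue
        if row["status"] != "selected":
            continue
        if not 6 <= len(seq) <= 40:
            problems.append((i, f"selected peptide length {len(seq)} outside [6, 40]"))
        if not 1 <= len(offsets) <= 2:
            problems.append((i, f"phospho count {len(offsets)} not in {{1, 2}}"))
        route = row.get("enrichment_route", "")
        if route not in ("IMAC", "pY", "IMACpY"):
            problems.append((i, f"invalid route {route!r}"))
    return pd.DataFrame(problems, columns=["row", "problem"])


# ---------------------------------------------------------------------------
# Instrument-facing exports
# ---------------------------------------------------------------------------

def write_transitions(
    rows: list[tuple[PanelEntry, str, Transition, float, float, float]], path
) -> None:
    """Transition-list CSV: (entry, label, transition, rt, win_start, win_end)."""
    table = pd.DataFrame(
        [
            {
                "protein": e.gene_symbol,
                "modified_sequence": e.modified_sequence,
                "precursor_mz": f"{t.precursor_mz:.5f}",
                "precursor_charge": 2,
                "product_mz": f"{t.product_mz:.5f}",
                "product_charge": t.product_charge,
                "fragment_ion": t.fragment_ion,
                "collision_energy": t.collision_energy,
                "rt": rt,
                "rt_window_start": lo,
                "rt_window_end": hi,
                "isotope_label": label,
            }
            for e, label, t, rt, lo, hi in rows
        ]
    )
    table.to_csv(path, index=False)


def write_ce_optimization(
    rows: list[tuple[PanelEntry, Transition, list[float]]], path
) -> None:
    """CE-optimization CSV: one row per (transition x CE value)."""
    table = pd.DataFrame(
        [
            {
                "protein": e.gene_symbol,
                "modified_sequence": e.modified_sequence,
                "precursor_mz": f"{t.precursor_mz:.5f}",
                "product_mz": f"{t.product_mz:.5f}",
                "fragment_ion": t.fragment_ion,
                "collision_energy": ce,
            }
            for e, t, schedule in rows
            for ce in schedule
        ]
    )
    table.to_csv(path, index=False)


def write_mixtures(mixtures: list[Mixture], path) -> None:
    pd.DataFrame(
        [
            {
                "mixture_name": m.name,
                "route": m.route,
                "gene": e.gene_symbol,
                "modified_sequence": e.modified_sequence,
                "concentration_pmol_per_ul": m.concentration,
            }
            for m in mixtures
            for e in m.members
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Chromatograms and quantification tables
# ---------------------------------------------------------------------------

def read_chromatograms(path_or_df) -> dict[tuple[str, str], dict[str, list[ChromTrace]]]:
    """Long-format chromatogram TSV -> {(sample, peptide): {label: traces}}."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    _require(df, {"sample", "peptide", "fragment_ion", "isotope_label",
                  "time_min", "intensity"}, "chromatograms")
    out: dict[tuple[str, str], dict[str, list[ChromTrace]]] = {}
    keys = ["sample", "peptide", "fragment_ion", "isotope_label"]
    for (sample, peptide, frag, label), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_min")
        series = frag[0]
        index = int(frag[1:].split("^")[0])
        charge = int(frag.split("^")[1]) if "^" in frag else 1
        trace = ChromTrace(
            peptide=peptide,
            transition=(series, index, charge),
            label=label,
            times=grp["time_min"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
        )
        out.setdefault((sample, peptide), {}).setdefault(label, []).append(trace)
    return out


def quant_records_frame(records: list[QuantRecord]) -> pd.DataFrame:
    def frag_name(key):
        if key is None:
            return ""
        series, index, charge = key
        return f"{series}{index}" + (f"^{charge}" if charge > 1 else "")

    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "peptide": r.peptide,
                "route": r.route,
                "reporting_transition": frag_name(r.reporting_transition),
                "light_area": r.light_areas.get(r.reporting_transition, 0.0),
                "heavy_area": r.heavy_areas.get(r.reporting_transition, 0.0),
                "light_height": r.light_height,
                "par": r.par,
                "detected": r.detected,
                "category": r.category,
            }
            for r in records
        ]
    )


def write_quant(records: list[QuantRecord], path) -> None:
    quant_records_frame(records).to_csv(path, sep="\t", index=False)


def _require(df: pd.DataFrame, columns: set[str], source) -> None:
    missing = columns - set(df.columns)
    if missing:
        raise ConfigError(f"{source}: missing column(s) {sorted(missing)}")
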