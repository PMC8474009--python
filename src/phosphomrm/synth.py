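"""Synthetic inputs with known ground truth for the whole pipeline.

Three generators, each a pure function of (design, seed):

* :func:`make_proteome` — a small proteome with nomination scenarios embedded
  by construction (short-peptide rescue, shared peptides, over-long peptides,
  pY sites, doubly phosphorylated forms) plus matching evidence tables;
* :func:`simulate_chromatograms` — MRM traces with Gaussian elution peaks,
  known light/heavy amount ratios, additive truncated-normal noise and a
  light-signal censoring rule;
* :func:`simulate_study` — group-structured log2 ratio matrices with a known
  fraction of truly differential rows and category labels.

The generators emulate the downstream signal consequences of enrichment
(via censoring), not the enrichment chemistry itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import ProteinEntry
from .panel import (
    ObservationEvidence,
    PanelEntry,
    SiteNomination,
    format_modified,
)
from .stats import RatioMatrix


class SynthError(ValueError):
    pass


#: Residues used for filler sequence (no K/R so cleavage points are explicit,
#: no S/T/Y so nominated sites are unambiguous, no P so both trypsin rules agree).
_FILLER = "ADEFGHILMNQVW"


@dataclass
class SimulationDesign:
    """Study conditions for the generators (all defaults are the package's
    stated simulation conditions; see the methods note)."""

    n_proteins: int = 12
    n_sites: dict[str, int] = field(
        default_factory=lambda: {
            "plain": 3,
            "short_rescue": 1,
            "shared_peptide": 1,
            "too_long": 1,
            "pY": 2,
            "doubly_phospho": 2,
        }
    )
    heavy_amount: float = 30.0          # fmol spiked per peptide
    heavy_apex_counts: float = 10_000.0  # apex at the default spike amount
    peak_sigma: float = 0.1             # min, Gaussian elution peak
    noise_sd_frac: float = 0.05         # fraction of heavy apex
    grid_step: float = 0.05             # min, sampling interval
    censor_amount: float = 0.0          # light amounts below this are zeroed
    gradient: tuple[float, float] = (10.0, 150.0)  # usable RT range, min
    n_transitions: int = 3


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_FILLER), size=n))


def _segment(rng: np.random.Generator, length: int, terminal: str = "K") -> str:
    """A tryptic segment: filler residues ending in K or R."""
    return _rand_seq(rng, length - 1) + terminal


def make_proteome(
    design: SimulationDesign, seed: int = 0
) -> tuple[list[ProteinEntry], list[SiteNomination], ObservationEvidence]:
    """Synthetic proteome + nominations + observation evidence.

    Every scenario class in ``design.n_sites`` is embedded deterministically;
    remaining proteins are site-free filler.  Raises if the scenario count
    exceeds ``n_proteins`` (shared-peptide scenarios need two proteins each).
    """
    rng = np.random.default_rng(seed)
    counts = design.n_sites
    needed = sum(counts.values()) + counts.get("shared_peptide", 0)
    if needed > design.n_proteins:
        raise SynthError(
            f"{needed} scenario proteins exceed n_proteins={design.n_proteins}"
        )
    proteome: list[ProteinEntry] = []
    sites: list[SiteNomination] = []
    evidence = ObservationEvidence()
    gene_no = 0

    def next_gene() -> str:
        nonlocal gene_no
        gene_no += 1
        return f"SYN{gene_no:03d}"

    def log_uniform_count() -> int:
        return int(round(10 ** rng.uniform(0.5, 2.5)))

    for _ in range(counts.get("plain", 0)):
        gene = next_gene()
        pre = _segment(rng, rng.integers(6, 12), "R")
        core = _rand_seq(rng, 4) + "S" + _rand_seq(rng, rng.integers(3, 8)) + "K"
        post = _segment(rng, rng.integers(6, 12), "K")
        seq = pre + core + post
        pos = len(pre) + 5
        proteome.append(ProteinEntry(gene, f"ACC_{gene}", seq))
        sites.append(SiteNomination(gene, "S", pos))
        evidence.add(
            format_modified(core, [5]), log_uniform_count(), routes={"IMAC"}
        )

    for _ in range(counts.get("short_rescue", 0)):
        gene = next_gene()
        pre = _segment(rng, rng.integers(6, 12), "R")
        short = _rand_seq(rng, 1) + "S" + _rand_seq(rng, 2) + "K"  # 5-mer
        post = _segment(rng, rng.integers(7, 12), "R")
        seq = pre + short + post
        pos = len(pre) + 2
        proteome.append(ProteinEntry(gene, f"ACC_{gene}", seq))
        sites.append(SiteNomination(gene, "S", pos))
        # Only the missed-cleaved extension is observed, never the 5-mer.
        rescued = short + post
        evidence.add(format_modified(rescued, [2]), log_uniform_count(), routes={"IMAC"})

    for _ in range(counts.get("shared_peptide", 0)):
        gene_a, gene_b = next_gene(), next_gene()
        shared_core = _rand_seq(rng, 3) + "T" + _rand_seq(rng, 5) + "K"
        offset = 4
        for gene in (gene_a, gene_b):
            pre = _segment(rng, rng.integers(6, 12), "K")
            post = _segment(rng, rng.integers(6, 12), "R")
            proteome.append(ProteinEntry(gene, f"ACC_{gene}", pre + shared_core + post))
        pos = proteome[-2].sequence.index(shared_core) + offset
        sites.append(SiteNomination(gene_a, "T", pos))
        evidence.add(
            format_modified(shared_core, [offset]), log_uniform_count(), routes={"IMAC"}
        )

    for _ in range(counts.get("too_long", 0)):
        gene = next_gene()
        pre = _segment(rng, rng.integers(6, 12), "K")
        long_core = _rand_seq(rng, 20) + "S" + _rand_seq(rng, 24) + "R"  # 46-mer
        seq = pre + long_core + _segment(rng, 8, "K")
        pos = len(pre) + 21
        proteome.append(ProteinEntry(gene, f"ACC_{gene}", seq))
        sites.append(SiteNomination(gene, "S", pos))

    for i in range(counts.get("pY", 0)):
        gene = next_gene()
        pre = _segment(rng, rng.integers(6, 12), "R")
        core = _rand_seq(rng, 3) + "Y" + _rand_seq(rng, rng.integers(4, 9)) + "R"
        seq = pre + core + _segment(rng, 8, "K")
        pos = len(pre) + 4
        proteome.append(ProteinEntry(gene, f"ACC_{gene}", seq))
        sites.append(SiteNomination(gene, "Y", pos))
        # Alternate plain-pY and dual-enrichment (IMACpY) history.
        routes = {"pY"} if i % 2 == 0 else {"pY", "IMAC"}
        evidence.add(format_modified(core, [4]), log_uniform_count(), routes=routes)

    for i in range(counts.get("doubly_phospho", 0)):
        gene = next_gene()
        pre = _segment(rng, rng.integers(6, 12), "K")
        core = _rand_seq(rng, 2) + "S" + _rand_seq(rng, 2) + "T" + _rand_seq(rng, 3) + "K"
        seq = pre + core + _segment(rng, 8, "R")
        pos = len(pre) + 3
        proteome.append(ProteinEntry(gene, f"ACC_{gene}", seq))
        sites.append(SiteNomination(gene, "S", pos))
        singly = max(2, log_uniform_count())
        # Even-indexed: doubly form dominates (>= 3x); odd: singly wins.
        doubly = singly * 4 if i % 2 == 0 else max(1, singly // 2)
        evidence.add(format_modified(core, [3]), singly, routes={"IMAC"})
        evidence.add(format_modified(core, [3, 6]), doubly, routes={"IMAC"})

    while len(proteome) < design.n_proteins:
        gene = next_gene()
        seq = "".join(_segment(rng, rng.integers(6, 14), rng.choice(["K", "R"]))
                      for _ in range(rng.integers(3, 6)))
        proteome.append(ProteinEntry(gene, f"ACC_{gene}", seq))

    return proteome, sites, evidence


def _gaussian(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def simulate_chromatograms(
    entries: list[PanelEntry],
    design: SimulationDesign,
    light_amounts: dict[str, float],
    seed: int = 0,
    sample: str = "S1",
    interference: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format MRM traces plus the ground-truth table.

    ``light_amounts`` maps modified sequence -> endogenous amount (same units
    as ``design.heavy_amount``; the true ratio is their quotient).
    ``interference`` optionally maps modified sequence -> transition index to
    contaminate with a co-eluting off-pattern peak on the light channel.

    Apex heights are linear in amount, calibrated so the heavy spike amount
    produces ``heavy_apex_counts`` on the most intense transition.
    """
    rng = np.random.default_rng(seed)
    interference = interference or {}
    lo, hi = design.gradient
    rows = []
    truth = []
    scale = design.heavy_apex_counts / design.heavy_amount
    for entry in entries:
        if not entry.is_selected:
            continue
        key = entry.modified_sequence
        rt = float(rng.uniform(lo, hi))
        rel = rng.dirichlet(np.ones(design.n_transitions))
        rel = rel / rel.max()  # most intense transition has weight 1
        light_amount = light_amounts.get(key, 0.0)
        censored = light_amount < design.censor_amount
        t = np.arange(rt - 1.5, rt + 1.5 + 1e-9, design.grid_step)
        heavy_apex = design.heavy_amount * scale
        noise_sd = design.noise_sd_frac * heavy_apex
        shape = _gaussian(t, rt, design.peak_sigma)
        for j in range(design.n_transitions):
            frag = f"y{j + 3}"
            for label, amount in (("light", light_amount), ("heavy", design.heavy_amount)):
                apex = amount * scale * rel[j]
                if label == "light" and censored:
                    apex = 0.0
                y = apex * shape
                if label == "light" and interference.get(key) == j:
                    y = y + 5.0 * heavy_apex * rel[j] * _gaussian(
                        t, rt + 0.05, design.peak_sigma
                    )
                if noise_sd > 0:
                    y = np.maximum(0.0, y + rng.normal(0.0, noise_sd, size=t.size))
                for ti, yi in zip(t, y):
                    rows.append(
                        {
                            "sample": sample,
                            "peptide": key,
                            "fragment_ion": frag,
                            "isotope_label": label,
                            "time_min": round(float(ti), 4),
                            "intensity": float(yi),
                        }
                    )
        expected = 3 if censored else 1
        truth.append(
            {
                "sample": sample,
                "peptide": key,
                "true_ratio": light_amount / design.heavy_amount,
                "rt": rt,
                "expected_category": expected,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)


@dataclass
class StudyDesign:
    """Group structure for ratio-matrix simulation."""

    n_rows: int = 500
    groups: dict[str, int] = field(default_factory=lambda: {"drug": 2, "vehicle": 2})
    base_mean: float = 0.0
    within_sd: float = 0.5
    effect_size: float = 1.0
    effect_fraction: float = 0.1
    censor_quantile: float = 0.05   # lowest cells -> category 3 (missing)
    low_quantile: float = 0.10      # next-lowest -> category 2


def simulate_study(
    design: StudyDesign, seed: int = 0
) -> tuple[RatioMatrix, pd.DataFrame]:
    """Group-structured log2 ratio matrix with known differential rows.

    The first ``effect_fraction`` of rows carry ``effect_size`` added to the
    first group.  Cells under the ``censor_quantile`` of the value
    distribution become category 3 (missing); the next ``low_quantile`` band
    becomes category 2.  Returns the matrix and a per-row truth table.
    """
    rng = np.random.default_rng(seed)
    group_names = list(design.groups)
    cols, col_group = [], []
    for g, n in design.groups.items():
        for r in range(1, n + 1):
            cols.append(f"{g}_{r}")
            col_group.append(g)
    n_eff = int(round(design.effect_fraction * design.n_rows))
    truth_effect = np.zeros(design.n_rows)
    truth_effect[:n_eff] = design.effect_size
    values = rng.normal(design.base_mean, design.within_sd,
                        size=(design.n_rows, len(cols)))
    first_group = group_names[0]
    for j, g in enumerate(col_group):
        if g == first_group:
            values[:, j] += truth_effect
    flat = values.ravel()
    q3 = np.quantile(flat, design.censor_quantile) if design.censor_quantile > 0 else -np.inf
    q2 = np.quantile(flat, design.censor_quantile + design.low_quantile)
    categories = np.ones(values.shape, dtype=int)
    categories[values <= q2] = 2
    categories[values <= q3] = 3
    vals = values.copy()
    vals[categories == 3] = np.nan
    index = [f"row{i:04d}" for i in range(design.n_rows)]
    matrix = RatioMatrix(
        pd.DataFrame(vals, index=index, columns=cols),
        pd.DataFrame(categories, index=index, columns=cols),
    )
    truth = pd.DataFrame(
        {"true_effect": truth_effect, "is_differential": truth_effect != 0},
        index=index,
    )
    return matrix, truth
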