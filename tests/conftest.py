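import numpy as np
import pytest

from phosphomrm.digest import ProteinEntry
from phosphomrm.panel import PanelEntry


@pytest.fixture
def lats2_like() -> ProteinEntry:
    """Protein embedding the short-peptide rescue motif: the fully cleaved
    peptide containing the site is the 5-mer DSLQK, whose 2-missed-cleavage
    extension RDSLQKPGLEAPPR is 14 residues."""
    return ProteinEntry("LATS2L", "ACC1", "AKRDSLQKPGLEAPPRW")


def make_entry(i: int, gene: str | None = None, route: str = "IMAC") -> PanelEntry:
    """Minimal selected panel entry with a unique letter-only sequence."""
    suffix = "".join("GAVLIFWMNQ"[int(c)] for c in f"{i:03d}")
    seq = f"S{suffix}EPK"
    return PanelEntry(
        site_labels=[f"{gene or f'GEN{i:03d}'} pS1"],
        modified_sequence=f"(pS){suffix}EPK",
        sequence=seq,
        phospho_offsets=[1],
        gene_symbol=gene or f"GEN{i:03d}",
        enrichment_route=route,
        status="selected",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
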