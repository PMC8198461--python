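"""Packaged thyroid-cancer gene signatures.

Three TCGA-derived signatures describe complementary axes of thyroid tumor
biology: a 52-gene MAPK transcriptional output set (pathway activation), a
16-gene thyroid differentiation set (iodide handling and hormone synthesis),
and a 71-gene BRAF-RAS signaling set whose up members are high in RAS-like
and down members high in BRAF-like tumors. Gene membership was transcribed
from the published signature literature with symbols harmonized to current
HGNC usage.
"""

from __future__ import annotations

from importlib import resources

from .containers import GeneSignature
from .io import read_gene_sets

__all__ = ["load_tcga_signatures", "MAPK_OUTPUT", "THYROID_DIFFERENTIATION", "BRAF_RAS"]

MAPK_OUTPUT = "MAPK_OUTPUT"
THYROID_DIFFERENTIATION = "THYROID_DIFFERENTIATION"
BRAF_RAS = "BRAF_RAS"


def load_tcga_signatures() -> dict[str, GeneSignature]:
    """Load the packaged MAPK output (52), TD (16) and BRAF-RAS (71) signatures."""
    ref = resources.files("thyrosig").joinpath("data/tcga_thyroid_signatures.gmt")
    with resources.as_file(ref) as path:
        sigs = read_gene_sets(path)
    return {s.name: s for s in sigs}
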