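"""mRNA half-life calibration, mean lifetimes and absolute protein yield.

Relative mRNA half-lives (arbitrary linear units, as delivered by
genome-wide decay measurements) are put on an absolute scale through a
single anchor gene whose absolute half-life is known independently.  The
default anchor is HIS3 (YOR202W), whose measured half-life ranges from
7 min (24 C) to 11 min (30 C); the packaged default anchors its half-life
at the 9 min midpoint.

Treating mRNA as an exponentially decaying species, the mean lifetime is
``m = h / ln 2``.  Under steady-state turnover each transcript hosts one
initiation every ``I`` seconds, so it yields ``b = m / I`` protein
molecules during its life (kept fractional), and a gene with ``x``
transcript copies yields ``B = b * x`` molecules.  Protein degradation is
not modelled: B counts molecules produced, not molecules present.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

__all__ = [
    "DEFAULT_ANCHOR_GENE",
    "DEFAULT_ANCHOR_SECONDS",
    "anchor_from_bounds",
    "calibrate_half_lives",
    "mean_lifetime",
    "protein_yield",
    "translate_cds",
    "protein_mass_da",
    "proteome_mass",
    "AVOGADRO",
]

DEFAULT_ANCHOR_GENE = "YOR202W"

AVOGADRO = 6.02214076e23


def anchor_from_bounds(low_minutes: float = 7.0, high_minutes: float = 11.0) -> float:
    """Anchor half-life in seconds as the midpoint of two printed bounds."""
    return (low_minutes + high_minutes) / 2.0 * 60.0


DEFAULT_ANCHOR_SECONDS = anchor_from_bounds()


def calibrate_half_lives(
    t0: pd.Series,
    anchor_gene: str = DEFAULT_ANCHOR_GENE,
    anchor_seconds: float = DEFAULT_ANCHOR_SECONDS,
) -> pd.Series:
    """Absolute half-lives (s) from relative ones via the anchor gene.

    ``h_i = t0_i * anchor_seconds / t0_anchor``; the anchor gene maps
    exactly to ``anchor_seconds``.  The result is invariant to rescaling
    the whole relative table.
    """
    if anchor_gene not in t0.index:
        raise ValueError(f"anchor gene {anchor_gene} missing from half-life table")
    t0_anchor = float(t0.loc[anchor_gene])
    if not t0_anchor > 0:
        raise ValueError(f"anchor gene {anchor_gene} has non-positive relative half-life")
    return t0 * (anchor_seconds / t0_anchor)


def mean_lifetime(h):
    """Mean lifetime of an exponentially decaying species: ``h / ln 2``."""
    return h / math.log(2.0)


def protein_yield(m, I, x):
    """(b, B): proteins per transcript lifetime and per gene.

    ``b = m / I`` initiation events during the mean lifetime (fractional;
    a transcript outlived by its initiation interval yields b < 1), and
    ``B = b * x`` over the gene's transcript copies.
    """
    b = m / I
    return b, b * x


def translate_cds(cds: str, gene: str = "?") -> str:
    """Translate a CDS to its protein sequence (terminal stop dropped)."""
    from .times import cds_codons

    codons = cds_codons(cds, gene)
    return str(Seq("".join(codons)).translate())


def protein_mass_da(protein: str) -> float:
    """Average molecular weight (Da) of a protein sequence."""
    return float(molecular_weight(protein, seq_type="protein"))


def proteome_mass(B: pd.Series, proteins: Mapping[str, str]) -> float:
    """Total mass (grams) of the protein molecules produced.

    Sums ``B * MW / N_A`` over genes; genes with undefined B (no
    half-life data) contribute nothing.
    """
    total = 0.0
    for gene, b in B.items():
        if pd.isna(b):
            continue
        total += float(b) * protein_mass_da(proteins[gene])
    return total / AVOGADRO
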