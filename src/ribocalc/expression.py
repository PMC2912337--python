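"""Absolute transcript copy numbers, ribosome loads and densities.

Relative read densities from a ribosome-profiling experiment (paired
mRNA-seq and footprint libraries) are converted into absolute per-cell
quantities using three global constants: the total number of transcripts
X, the total number of ribosomes W and the active fraction q.

* mRNA RPKM is proportional to transcript concentration, so the RPKM
  fraction of a gene is both its relative ribosome-binding rate Pz and
  its share of the X transcripts: ``x = Pz * X``.
* The raw footprint count fraction of a gene allocates the ``W * q`` busy
  ribosomes across transcript types; dividing by copy number gives the
  per-transcript ribosome load ``w``.
* Ribosome density is ``g = 100 * w / L`` ribosomes per 100 codons; a
  ribosome covers ten codons, so ``g > 10`` is physically impossible and
  marks a record for exclusion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cell import CellModel

__all__ = [
    "relative_binding_rate",
    "transcript_copy_number",
    "ribosome_load",
    "ribosome_density",
    "rpkm",
    "validate_rpkm",
    "transcriptome_summary",
    "MAX_DENSITY",
]

logger = logging.getLogger(__name__)

#: Physical packing limit: one ribosome covers ten codons.
MAX_DENSITY = 10.0


def relative_binding_rate(d_mrna: pd.Series) -> pd.Series:
    """Pz: mRNA RPKM as a fraction of the summed RPKM; sums to 1."""
    total = float(d_mrna.sum())
    if not total > 0.0:
        raise ValueError("sum of mRNA read densities must be positive")
    return d_mrna / total


def transcript_copy_number(pz: pd.Series, cell: CellModel) -> pd.Series:
    """x = Pz * X transcripts per cell, kept fractional."""
    return pz * cell.total_transcripts


def ribosome_load(r_fp: pd.Series, x: pd.Series, cell: CellModel) -> pd.Series:
    """w: ribosomes per transcript copy.

    The raw footprint fraction of each gene allocates the W*q translating
    ribosomes across transcript types; dividing by the copy number x gives
    the load per transcript.  Genes without footprints have no measurable
    load and come back NaN (they are removed by the no-footprint filter).
    """
    total = float(r_fp.sum())
    if not total > 0.0:
        raise ValueError("sum of raw footprint counts must be positive")
    w = (r_fp / total) * cell.busy_ribosomes / x
    return w.where(r_fp > 0)


def ribosome_density(w: pd.Series, L: pd.Series) -> pd.Series:
    """g = 100 * w / L ribosomes per 100 codons."""
    return 100.0 * w / L


def rpkm(raw_reads: pd.Series, cds_length_nt: pd.Series) -> pd.Series:
    """Reads per kilobase of CDS per million CDS-aligned reads."""
    total = float(raw_reads.sum())
    if not total > 0.0:
        raise ValueError("sum of raw reads must be positive")
    return raw_reads * 1e9 / (cds_length_nt * total)


def validate_rpkm(
    raw_reads: pd.Series,
    cds_length_nt: pd.Series,
    given_rpkm: pd.Series,
    rtol: float = 0.2,
) -> pd.Series:
    """Check supplied RPKM against RPKM recomputed from raw counts.

    The supplied column is authoritative (it encodes the upstream
    mappability normalisation); recomputation is a data-quality check
    only.  Genes disagreeing by more than ``rtol`` are logged and flagged
    False in the returned mask.
    """
    recomputed = rpkm(raw_reads, cds_length_nt)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(recomputed - given_rpkm) / given_rpkm.where(given_rpkm > 0)
    ok = ~(rel > rtol)
    bad = int((~ok).sum())
    if bad:
        logger.warning(
            "RPKM consistency: %d gene(s) deviate by more than %.0f%% from "
            "counts-derived RPKM", bad, 100 * rtol,
        )
    return ok


def transcriptome_summary(x: pd.Series, L: pd.Series, cell: CellModel) -> dict:
    """Cell-wide summary of the quantified transcriptome.

    Returns the mean ribosome density over all transcript copies, the
    total length of transcribed coding sequence (copy-number weighted, in
    nucleotides) and the expected total transcriptome length from
    RNA-mass bookkeeping.
    """
    codons = float((x * L).sum())
    return {
        "mean_density": cell.busy_ribosomes / codons * 100.0,
        "total_cds_length_nt": 3.0 * codons,
        "expected_transcriptome_length_nt": cell.expected_transcriptome_length,
    }
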