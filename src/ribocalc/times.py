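"""Per-gene elongation, initiation and total translation times.

Total translation time decomposes as ``T = I + E``.  The elongation time
``E`` is the sum of per-codon times over the CDS (terminal stop
excluded).  The initiation time ``I`` is read off the steady-state
ribosome spacing: with ``w`` ribosomes on ``L`` codons the mean
inter-ribosome gap is ``L / w`` codons, and since the codon identities
within a gap are unknowable the gap is translated at the mean codon time,
giving ``I = mean_E * L / w = E / w``.  Its inverse ``P = 1 / I`` is the
initiation frequency.  Normalising P by the relative ribosome-binding
rate Pz removes the concentration dependence and leaves the relative
scanning success rate Ps, comparable only within one analysis.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .trna import GENETIC_CODE, STOP_CODONS

__all__ = [
    "cds_codons",
    "elongation_time",
    "initiation_time",
    "scanning_efficiency",
]


def cds_codons(cds: str, gene: str = "?") -> list[str]:
    """Split a CDS into its sense codons, validating the reading frame.

    The terminal stop codon, when present, is dropped (it is not
    elongated).  Internal stop codons and ambiguous bases are errors, and
    the offending codon position (1-based) is reported.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) == 0 or len(cds) % 3 != 0:
        raise ValueError(f"{gene}: CDS length {len(cds)} is not a positive multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        raise ValueError(f"{gene}: CDS contains only a stop codon")
    for pos, codon in enumerate(codons, start=1):
        if codon in STOP_CODONS:
            raise ValueError(f"{gene}: internal stop codon {codon} at codon {pos}")
        if codon not in GENETIC_CODE:
            raise ValueError(f"{gene}: ambiguous or invalid codon {codon!r} at codon {pos}")
    return codons


def elongation_time(cds: str, codon_times: Mapping[str, float], gene: str = "?") -> tuple[float, float]:
    """(E, mean_E): summed and per-codon mean elongation time in seconds."""
    codons = cds_codons(cds, gene)
    E = float(sum(codon_times[c] for c in codons))
    return E, E / len(codons)


def initiation_time(E: float, w: float) -> tuple[float, float]:
    """(I, P): initiation time ``E / w`` and its inverse frequency."""
    if not w > 0:
        raise ValueError("ribosome load w must be positive")
    I = E / w
    return I, 1.0 / I


def scanning_efficiency(P: pd.Series, Pz: pd.Series) -> tuple[pd.Series, pd.Series]:
    """(Ps_raw, Ps): initiation frequency normalised by binding rate.

    ``Ps_raw = P / Pz``; the returned Ps is Ps_raw scaled by the cohort
    maximum, so the best-initiating gene gets exactly 1.  Values are
    relative to the analysed cohort and not portable across analyses.
    """
    if len(P) == 0:
        raise ValueError("empty cohort")
    if (Pz <= 0).any():
        raise ValueError("Pz must be positive for all genes")
    ps_raw = P / Pz
    return ps_raw, ps_raw / ps_raw.max()
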