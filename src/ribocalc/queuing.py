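"""Deterministic simulation of ribosome traffic along one transcript.

Ribosomes are launched at the start codon every ``I`` seconds and step
codon by codon, dwelling the codon's elongation time at each position,
subject to excluded volume: a ribosome covers ``footprint`` codons ending
at its current (A-site) position, and a trailing ribosome may advance
only when the target codon is not covered by the ribosome ahead (adjacent
packing, with consecutive A sites ``footprint`` codons apart, is
allowed).  A stalled ribosome finishes its dwell clock but waits; the
waiting time counts toward its cumulative traversal time, which is what
makes trailing ribosomes slower than the leader when queuing occurs.

Classification of a transcript:

* 0 - every simulated ribosome traverses the CDS in the same cumulative
  time: no queuing.
* 1 - trailing ribosomes are slower than the first: queuing.
* 2 - an attachment attempt found the initiation region still covered by
  the previous ribosome: the 5' end is blocked by slow early codons, a
  particular case of queuing.

The engine is event-driven and exact: the time a ribosome leaves codon
``k`` satisfies ``leave[k] = max(leave[k-1] + dwell[k], prev_leave[k +
footprint])`` (the second term is the time the ribosome ahead uncovers
the target codon), a recurrence solved in closed form per ribosome.
Simultaneous release/advance events resolve downstream-most first, which
the recurrence encodes by accepting equality.  There is no randomness:
identical inputs give identical results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["QueueResult", "simulate_transcript", "classify_cohort", "FOOTPRINT_CODONS"]

logger = logging.getLogger(__name__)

#: Codons covered by one ribosome.
FOOTPRINT_CODONS = 10

#: Relative tolerance when comparing cumulative traversal times; blocking
#: delays are of the order of a codon dwell, many orders larger.
_REL_TOL = 1e-9


@dataclass(frozen=True)
class QueueResult:
    """Outcome of simulating one transcript."""

    gene: str
    klass: int  # 0 no queuing, 1 queuing, 2 blocked 5' end
    cumulative_times: tuple[float, ...]
    n_simulated: int


def default_horizon(w: float) -> int:
    """Number of ribosomes to traverse before classifying.

    ``max(2 * ceil(w) + 3, 5)``: roughly twice the steady-state ribosome
    complement, enough for launch-interval interference to express itself
    while staying bounded.
    """
    return max(2 * math.ceil(max(w, 0.0)) + 3, 5)


def simulate_transcript(
    dwell_times: Sequence[float],
    initiation_interval: float,
    footprint: int = FOOTPRINT_CODONS,
    n_ribosomes: int | None = None,
    gene: str = "?",
) -> QueueResult:
    """Simulate ribosome traffic and classify the transcript.

    Parameters
    ----------
    dwell_times
        Per-codon elongation times (seconds) over the CDS sense codons.
    initiation_interval
        I, seconds between successive attachment attempts at the start
        codon.  Attempts occur at t = 0, I, 2I, ...
    footprint
        Codons covered by one ribosome.
    n_ribosomes
        Ribosomes to simulate; defaults to 5.
    """
    d = np.asarray(dwell_times, dtype=float)
    L = d.size
    if footprint >= L:
        raise ValueError(f"{gene}: CDS of {L} codons is shorter than the "
                         f"{footprint}-codon ribosome footprint")
    if not initiation_interval > 0:
        raise ValueError("initiation interval must be positive")
    if not (d > 0).all():
        raise ValueError("all positional dwell times must be positive")
    n = 5 if n_ribosomes is None else int(n_ribosomes)

    S = np.cumsum(d)  # unobstructed elapsed time through codon k
    # guard against float-noise ties: genuine blocking delays are at least
    # one codon dwell, many orders above accumulated rounding error
    eps = _REL_TOL * (float(S[-1]) + n * initiation_interval)
    cumulative: list[float] = []
    prev_leave: np.ndarray | None = None
    for i in range(n):
        start = i * initiation_interval
        if prev_leave is not None and prev_leave[footprint - 1] > start + eps:
            # initiation region still covered: blocked 5' end
            return QueueResult(gene, 2, tuple(cumulative), len(cumulative))
        if prev_leave is None:
            leave = start + S
        else:
            # constraint[k]: when the ribosome ahead uncovers codon k+1
            constraint = prev_leave[np.minimum(np.arange(L) + footprint, L - 1)]
            slack = np.maximum.accumulate(constraint - eps - S)
            leave = S + np.maximum(start, slack)
        cumulative.append(float(leave[-1] - start))
        prev_leave = leave

    base = cumulative[0]
    queued = any(
        not math.isclose(c, base, rel_tol=_REL_TOL, abs_tol=0.0) for c in cumulative
    )
    return QueueResult(gene, 1 if queued else 0, tuple(cumulative), n)


def classify_cohort(
    cds_by_gene: Mapping[str, str],
    I: pd.Series,
    w: pd.Series,
    codon_times: Mapping[str, float],
    footprint: int = FOOTPRINT_CODONS,
) -> pd.Series:
    """Queue class {0, 1, 2} for every gene in ``I``'s index.

    Transcripts no longer than the footprint cannot be simulated; they are
    logged and reported as class 0 (no interference is expressible).
    """
    from .times import cds_codons

    out = {}
    for gene in I.index:
        codons = cds_codons(cds_by_gene[gene], gene)
        if footprint >= len(codons):
            logger.warning("%s: too short to simulate queuing (L=%d)", gene, len(codons))
            out[gene] = 0
            continue
        dwell = [codon_times[c] for c in codons]
        res = simulate_transcript(
            dwell,
            float(I.loc[gene]),
            footprint=footprint,
            n_ribosomes=default_horizon(float(w.loc[gene])),
            gene=gene,
        )
        out[gene] = res.klass
    return pd.Series(out, name="queue").loc[I.index]
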