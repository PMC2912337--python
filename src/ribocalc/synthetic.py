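"""Self-consistent synthetic cohorts with known ground truth.

The generator emulates the structure of a genome-wide ribosome-profiling
count table together with matching CDS sequences and a relative
half-life table, by sampling a ground truth (transcript copies, ribosome
loads, codon compositions, half-lives) and evaluating the forward model
to produce the read counts the pipeline takes as input.  Running the
pipeline on a noiseless cohort must return the ground truth exactly;
with Poisson noise the counts are Poisson draws around their expected
values (sequencing has no error model beyond counting noise here).

What is emulated: the log-normal CDS length regime of the yeast
transcriptome, heavy-tailed transcript abundances, per-gene codon
optimality spanning the observed per-transcript mean codon time range,
ribosome loads respecting the ten-codon packing limit and (unless a
queue gene is requested) the no-queuing sufficient condition
``I >= footprint * max codon dwell``.  Not emulated: mappability and
ligation biases, footprint-length variation, UTRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell import CellModel, Config, DEFAULT_WALKER_SIZE, kinetic_constants
from .trna import (
    SENSE_CODONS,
    WalkerSpace,
    build_trna_inventory,
    codon_times_table,
    load_trna_table,
)

__all__ = ["SyntheticCohort", "generate_cohort"]

#: Anchor gene name used in generated half-life tables.
ANCHOR_GENE = "YOR202W"

#: CDS length regime: log-normal around the yeast transcriptome
#: (median ~430 codons, mean ~513), truncated to the observed range.
_LEN_MU, _LEN_SIGMA = math.log(430.0), 0.594
_LEN_RANGE = (37, 4911)

#: Per-transcript mean codon time window the generator enforces, matching
#: the span observed across real transcripts at 30 C.
_MEAN_E_WINDOW = (0.105, 0.350)

_STOP = "TAA"
_FOOTPRINT = 10


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated inputs plus the ground truth that produced them."""

    counts: pd.DataFrame
    cds: dict[str, str]
    halflives: pd.Series
    truth: pd.DataFrame
    cell: CellModel
    config: Config
    seed: int
    noise: str


def _sample_cds(rng, L, weights, codons, codon_time, max_tries=40):
    """CDS of L sense codons starting with ATG; resampled until its mean
    codon time falls inside the enforced window."""
    idx_atg = codons.index("ATG")
    t = np.array([codon_time[c] for c in codons])
    body_n = L - 1
    for _ in range(max_tries):
        body = rng.choice(len(codons), size=body_n, p=weights)
        mean_t = (t[idx_atg] + t[body].sum()) / L
        if _MEAN_E_WINDOW[0] <= mean_t <= _MEAN_E_WINDOW[1]:
            break
    return "ATG" + "".join(codons[i] for i in body) + _STOP


def _queue_cds(L, codon_time):
    """CDS with a cluster of the slowest codon mid-sequence and the
    fastest codon elsewhere: a rare-codon cluster that stalls traffic."""
    ordered = sorted(codon_time, key=codon_time.get)
    fast, slow = ordered[0], ordered[-1]
    mid = L // 2
    body = [fast] * (L - 1)
    for k in range(mid, mid + _FOOTPRINT):
        body[k] = slow
    return "ATG" + "".join(body) + _STOP


def _water_fill(w_raw, x, caps, target):
    """Scale raw loads so that sum(w * x) == target, respecting per-gene
    caps exactly (iterative proportional fill)."""
    w = np.minimum(w_raw, caps)
    free = np.ones(len(w), dtype=bool)
    for _ in range(len(w) + 1):
        budget = target - float((caps[~free] * x[~free]).sum())
        if budget <= 0 or not free.any():
            raise ValueError("infeasible ribosome budget: caps too tight")
        scale = budget / float((w_raw[free] * x[free]).sum())
        w[free] = w_raw[free] * scale
        over = free & (w > caps)
        if not over.any():
            break
        free &= ~over
        w[over] = caps[over]
    else:
        raise ValueError("ribosome budget allocation did not converge")
    return w


def generate_cohort(
    n_genes: int = 200,
    cell: CellModel | None = None,
    seed: int = 0,
    noise: str = "none",
    depth_mrna: float = 1_000_000,
    depth_fp: float = 1_000_000,
    n_queue_genes: int = 0,
    n_zero_footprint: int = 0,
    walker_size: float = DEFAULT_WALKER_SIZE,
) -> SyntheticCohort:
    """Generate a cohort of ``n_genes`` genes with known ground truth.

    Parameters
    ----------
    noise
        ``"none"``: counts are the forward-model expected values and the
        pipeline recovers the truth exactly.  ``"poisson"``: counts are
        Poisson draws around those expectations.
    n_queue_genes
        Number of genes engineered with a slow-codon cluster and a launch
        interval short enough to cause ribosome queuing.
    n_zero_footprint
        Number of genes carrying mRNA mass but no footprints (removed by
        the first filter).
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    if n_queue_genes + n_zero_footprint > n_genes - 1:
        raise ValueError("too many special genes requested")
    if cell is None:
        cell = CellModel()
    config = Config(cell=cell, walker_size=walker_size)
    rng = np.random.default_rng(seed)

    inventory = build_trna_inventory(load_trna_table(), cell, walker_size=walker_size)
    space = WalkerSpace(cell.cytoplasm_volume, walker_size)
    kin = codon_times_table(inventory, kinetic_constants(cell.temperature), space)
    ct = {c: k.time for c, k in kin.items()}
    codons = list(SENSE_CODONS)
    copies = np.array(
        [sum(s.gene_copies for s in inventory if c in s.cognate_codons) for c in codons],
        dtype=float,
    )

    genes = [f"SYN{i:04d}" for i in range(1, n_genes + 1)]
    queue_idx = list(range(n_queue_genes))
    zero_idx = list(range(n_genes - n_zero_footprint, n_genes))
    # anchor must survive all filters
    anchor_idx = n_queue_genes
    genes[anchor_idx] = ANCHOR_GENE

    # CDS: per-gene codon optimality spreads transcripts across the
    # observed mean codon time range
    L = np.rint(
        np.exp(rng.normal(_LEN_MU, _LEN_SIGMA, size=n_genes))
    ).clip(*_LEN_RANGE).astype(int)
    cds: dict[str, str] = {}
    for i, gene in enumerate(genes):
        if i in queue_idx:
            L[i] = max(L[i], 200)
            cds[gene] = _queue_cds(L[i], ct)
        else:
            s = rng.beta(2.0, 2.0)
            wts = copies**s
            cds[gene] = _sample_cds(rng, L[i], wts / wts.sum(), codons, ct)

    E = np.empty(n_genes)
    max_dwell = np.empty(n_genes)
    for i, gene in enumerate(genes):
        dwell = [ct[cds[gene][k : k + 3]] for k in range(3, 3 * L[i], 3)]
        dwell = [ct[cds[gene][0:3]]] + dwell
        E[i] = float(np.sum(dwell))
        max_dwell[i] = float(np.max(dwell))

    # abundances: heavy-tailed transcript fractions; resampled with a
    # flatter concentration if the draw leaves too little ribosome
    # capacity under the packing and no-queue caps (see below)
    caps_per_codon = 0.9 * np.minimum(
        1.0 / 10.0, E / (L * _FOOTPRINT * max_dwell)
    )  # cap on w / L
    alpha = 0.6
    for _ in range(10):
        pz = rng.dirichlet(np.full(n_genes, alpha))
        pz = np.maximum(pz, 1e-7)
        pz /= pz.sum()
        x = pz * cell.total_transcripts
        capacity = float((caps_per_codon * L * x).sum())
        if capacity > 1.1 * cell.busy_ribosomes:
            break
        alpha *= 1.6
    else:
        raise ValueError(
            "infeasible cohort: transcript abundances cannot carry the "
            "busy-ribosome pool under the packing and no-queue caps"
        )

    # ribosome loads: conserve sum(w x) = W q, respect packing and
    # no-queue caps; queue genes get a launch interval inside the stall
    caps = 0.9 * np.minimum(L / 10.0, E / (_FOOTPRINT * max_dwell))
    w_raw = np.exp(rng.normal(math.log(3.0), 0.7, size=n_genes))
    slow_time = max(ct.values())
    fixed = np.zeros(n_genes)
    fixed_mask = np.zeros(n_genes, dtype=bool)
    for i in queue_idx:
        # launch interval I = E / w of eight slow-codon dwells: shorter
        # than the ten-dwell cluster service time, so trailing ribosomes
        # queue at the cluster, but the backlog stays clear of the 5' end
        fixed[i] = min(E[i] / (8.0 * slow_time), 0.9 * L[i] / 10.0)
        fixed_mask[i] = True
    for i in zero_idx:
        fixed_mask[i] = True  # w = 0, no footprints
    target = cell.busy_ribosomes - float((fixed * x)[fixed_mask].sum())
    w = np.zeros(n_genes)
    free = ~fixed_mask
    w[free] = _water_fill(w_raw[free], x[free], caps[free], target)
    w[fixed_mask] = fixed[fixed_mask]

    g = 100.0 * w / L
    I = np.divide(E, w, out=np.full(n_genes, np.nan), where=w > 0)
    P = 1.0 / I

    # forward model: uniform mRNA-seq reads over transcribed CDS mass,
    # footprints proportional to resident ribosomes
    len_nt = 3.0 * L + 3.0  # annotation length includes the stop
    mrna_mass = x * len_nt
    lam_mrna = depth_mrna * mrna_mass / mrna_mass.sum()
    fp_mass = w * x
    lam_fp = depth_fp * fp_mass / fp_mass.sum()
    if noise == "poisson":
        r_mrna = rng.poisson(lam_mrna).astype(float)
        r_fp = rng.poisson(lam_fp).astype(float)
    else:
        r_mrna, r_fp = lam_mrna, lam_fp
    with np.errstate(divide="ignore", invalid="ignore"):
        d_mrna = np.where(r_mrna > 0, r_mrna * 1e9 / (len_nt * r_mrna.sum()), 0.0)
        d_fp = np.where(r_fp > 0, r_fp * 1e9 / (len_nt * r_fp.sum()), 0.0)
    counts = pd.DataFrame(
        {
            "gene": genes,
            "r_mrna": r_mrna,
            "d_mrna": d_mrna,
            "r_fp": r_fp,
            "d_fp": d_fp,
        }
    )

    # relative half-lives in arbitrary units
    t0 = pd.Series(
        np.exp(rng.normal(math.log(20.0), 0.8, size=n_genes)), index=genes, name="t0"
    )
    h = t0.to_numpy() * (config.anchor_seconds / t0.loc[ANCHOR_GENE])
    m = h / math.log(2.0)
    b = m / I
    B = b * x

    mean_E = E / L
    retained = np.ones(n_genes, dtype=bool)
    retained[queue_idx] = False
    retained[zero_idx] = False
    ps_raw = np.divide(P, pz, out=np.full(n_genes, np.nan), where=retained)
    ps = ps_raw / np.nanmax(ps_raw[retained])

    truth = pd.DataFrame(
        {
            "gene": genes,
            "L": L,
            "x": x,
            "Pz": pz,
            "w": w,
            "g": g,
            "E": E,
            "mean_E": mean_E,
            "I": I,
            "P": P,
            "T": I + E,
            "Ps": ps,
            "h": h,
            "m": m,
            "b": b,
            "B": B,
            "queue_gene": ~retained & ~np.isin(np.arange(n_genes), zero_idx),
            "zero_footprint": np.isin(np.arange(n_genes), zero_idx),
        }
    )
    return SyntheticCohort(
        counts=counts,
        cds=cds,
        halflives=t0,
        truth=truth,
        cell=cell,
        config=config,
        seed=seed,
        noise=noise,
    )
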