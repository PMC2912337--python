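"""End-to-end computation: readers, the filter cascade and the results table.

The pipeline applies, in order:

1. drop genes whose footprint count is zero (no measurable ribosome load);
2. compute x, Pz, w, g and drop genes with g > 10 (a ribosome covers ten
   codons, so more than ten per hundred codons is physically impossible);
3. compute per-codon times and the per-gene times E, I and the frequency P;
4. simulate ribosome traffic and drop transcripts with queuing (class 1)
   or a blocked 5' end (class 2);
5. normalise the scanning efficiency Ps over the retained genes;
6. optionally calibrate half-lives and compute m, b and B for covered genes;
7. emit the results table.

Normalisation bases: zero-footprint genes still carry mRNA mass, so they
are included in the mRNA-density denominator (Pz, x), but they carry no
ribosomes and are excluded from the footprint allocation.  This choice is
recorded in the run summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import expression, proteins, queuing, times
from .cell import CellModel, Config, kinetic_constants
from .trna import WalkerSpace, build_trna_inventory, codon_times_table, load_trna_table

__all__ = [
    "FilterLedger",
    "PipelineResult",
    "run_pipeline",
    "read_counts",
    "read_cds_fasta",
    "read_halflives",
    "read_results",
    "write_results",
    "format_minsec",
    "parse_minsec",
    "format_hms",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene", "L", "x", "b", "B", "g", "w", "P", "Pz", "Ps",
    "T", "I", "E", "mean_E", "h", "m", "queue",
]


@dataclass(frozen=True)
class FilterLedger:
    """Bookkeeping of the filter cascade."""

    n_input: int
    n_no_footprints: int
    n_density_excess: int
    n_queue: int
    n_blocked: int

    def __post_init__(self) -> None:
        if self.n_retained < 0:
            raise ValueError("filter ledger counts exceed the input size")

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.n_no_footprints
            - self.n_density_excess
            - self.n_queue
            - self.n_blocked
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_no_footprints": self.n_no_footprints,
            "n_density_excess": self.n_density_excess,
            "n_queue": self.n_queue,
            "n_blocked": self.n_blocked,
            "n_retained": self.n_retained,
        }


@dataclass(frozen=True)
class PipelineResult:
    table: pd.DataFrame
    ledger: FilterLedger
    summary: dict


def run_pipeline(
    counts: pd.DataFrame,
    cds_by_gene: Mapping[str, str],
    trna_rows=None,
    halflives: pd.Series | None = None,
    config: Config | None = None,
    footprint: int = queuing.FOOTPRINT_CODONS,
    keep_flagged: bool = False,
) -> PipelineResult:
    """Run the full computation.

    Parameters
    ----------
    counts
        One row per gene with columns ``gene``, ``r_mrna``, ``d_mrna``,
        ``r_fp``, ``d_fp`` (raw counts and RPKM for the mRNA-seq and
        footprint libraries).
    cds_by_gene
        CDS (DNA) per gene; genes counted but missing a CDS are logged
        and skipped before the cascade.
    trna_rows
        tRNA decoding table rows; defaults to the packaged yeast table.
    halflives
        Optional relative half-lives indexed by gene.  When absent the
        h/m/b/B columns are left empty.
    keep_flagged
        When True, queue-flagged genes stay in the output table with
        their queue class (their parameters may be unreliable); the
        ledger and the Ps normalisation are unaffected.
    """
    if config is None:
        config = Config(cell=CellModel())
    cell = config.cell
    constants = kinetic_constants(cell.temperature)
    if trna_rows is None:
        trna_rows = load_trna_table()

    counts = counts.copy()
    if counts["gene"].duplicated().any():
        dupes = counts.loc[counts["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene identifiers in counts: {dupes[:5]}")
    counts = counts.set_index("gene")

    missing = [g for g in counts.index if g not in cds_by_gene]
    if missing:
        logger.warning("skipping %d gene(s) without a CDS: %s ...", len(missing), missing[:5])
        counts = counts.drop(index=missing)
    n_input = len(counts)

    df = counts.copy()
    df["L"] = pd.Series({g: len(times.cds_codons(cds_by_gene[g], g)) for g in df.index})

    # (1)-(2) absolute abundances; Pz over all genes carrying mRNA mass
    df["Pz"] = expression.relative_binding_rate(df["d_mrna"])
    df["x"] = expression.transcript_copy_number(df["Pz"], cell)
    no_fp = df["r_fp"] <= 0
    n_no_footprints = int(no_fp.sum())
    df["w"] = expression.ribosome_load(df["r_fp"], df["x"], cell)
    df["g"] = expression.ribosome_density(df["w"], df["L"])
    stage = df.loc[~no_fp]
    excess = stage["g"] > expression.MAX_DENSITY
    n_density_excess = int(excess.sum())
    stage = stage.loc[~excess]

    # (3) absolute times
    inventory = build_trna_inventory(trna_rows, cell, walker_size=config.walker_size)
    space = WalkerSpace(cell.cytoplasm_volume, config.walker_size)
    kin = codon_times_table(inventory, constants, space)
    ct = {codon: k.time for codon, k in kin.items()}
    E = {}
    mean_E = {}
    for g in stage.index:
        E[g], mean_E[g] = times.elongation_time(cds_by_gene[g], ct, g)
    stage = stage.assign(E=pd.Series(E), mean_E=pd.Series(mean_E))
    stage["I"] = stage["E"] / stage["w"]
    stage["P"] = 1.0 / stage["I"]
    stage["T"] = stage["I"] + stage["E"]

    # (4) ribosome traffic
    klass = queuing.classify_cohort(cds_by_gene, stage["I"], stage["w"], ct, footprint)
    n_queue = int((klass == 1).sum())
    n_blocked = int((klass == 2).sum())
    retained = stage.loc[klass == 0].copy()
    retained["queue"] = 0

    # (5) scanning efficiency over retained genes
    _, retained["Ps"] = times.scanning_efficiency(retained["P"], retained["Pz"])

    # (6) protein output
    for col in ("h", "m", "b", "B"):
        retained[col] = np.nan
    if halflives is not None and len(halflives) > 0:
        h = proteins.calibrate_half_lives(
            halflives, config.anchor_gene, config.anchor_seconds
        )
        covered = retained.index.intersection(h.index)
        retained.loc[covered, "h"] = h.loc[covered]
        retained.loc[covered, "m"] = proteins.mean_lifetime(retained.loc[covered, "h"])
        b, B = proteins.protein_yield(
            retained.loc[covered, "m"], retained.loc[covered, "I"], retained.loc[covered, "x"]
        )
        retained.loc[covered, "b"] = b
        retained.loc[covered, "B"] = B

    ledger = FilterLedger(
        n_input=n_input,
        n_no_footprints=n_no_footprints,
        n_density_excess=n_density_excess,
        n_queue=n_queue,
        n_blocked=n_blocked,
    )

    table = retained.reset_index().rename(columns={"index": "gene"})
    if keep_flagged:
        flagged = stage.loc[klass != 0].copy()
        flagged["queue"] = klass.loc[flagged.index]
        max_raw = (retained["P"] / retained["Pz"]).max()
        flagged["Ps"] = (flagged["P"] / flagged["Pz"]) / max_raw
        for col in ("h", "m", "b", "B"):
            flagged[col] = np.nan
        table = pd.concat([table, flagged.reset_index().rename(columns={"index": "gene"})])
    table = table[RESULT_COLUMNS].reset_index(drop=True)

    summary = expression.transcriptome_summary(
        retained["x"], retained["L"], cell
    )
    summary.update(
        {
            "temperature": cell.temperature,
            "n_retained": ledger.n_retained,
            "mean_codon_time_s": float(
                (retained["mean_E"] * retained["w"] * retained["x"]).sum()
                / (retained["w"] * retained["x"]).sum()
            ),
            "pz_denominator": "all input genes (zero-footprint genes carry mRNA mass)",
            "turnover_caveat": (
                "steady-state turnover assumed; protein degradation not modelled"
            ),
        }
    )
    if halflives is not None and len(halflives) > 0:
        prot = {g: proteins.translate_cds(cds_by_gene[g], g) for g in retained.index}
        summary["proteome_mass_g"] = proteins.proteome_mass(retained["B"], prot)
    return PipelineResult(table=table, ledger=ledger, summary=summary)


# ---------------------------------------------------------------------------
# readers / writers

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read the per-gene count table (TSV/CSV by extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = ["gene", "r_mrna", "d_mrna", "r_fp", "d_fp"]
    miss = [c for c in required if c not in df.columns]
    if miss:
        raise ValueError(f"counts table missing columns: {miss}")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene identifiers in counts table")
    return df


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """CDS sequences keyed by record id, upper-cased."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate gene identifier in FASTA: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def read_halflives(path: str | Path) -> pd.Series:
    """Relative half-life table: columns ``gene`` and ``t0``."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene identifiers in half-life table")
    return df.set_index("gene")["t0"]


def format_minsec(seconds: float) -> str:
    """Seconds -> ``min:sec`` (e.g. 6788 -> ``113:08``)."""
    if pd.isna(seconds):
        return ""
    total = int(round(seconds))
    return f"{total // 60}:{total % 60:02d}"


def parse_minsec(text: str) -> float:
    """``min:sec`` -> seconds (exact inverse of :func:`format_minsec`)."""
    m, s = text.split(":")
    return float(int(m) * 60 + int(s))


def format_hms(seconds: float) -> str:
    """Seconds -> ``h:min:sec``."""
    if pd.isna(seconds):
        return ""
    total = int(round(seconds))
    return f"{total // 3600}:{(total % 3600) // 60:02d}:{total % 60:02d}"


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write the results table as CSV.

    Time columns are numeric SI seconds; human-readable companions are
    appended (``min:sec`` for T, I, E and ``h:min:sec`` for h, m).
    """
    out = table.copy()
    for col in ("T", "I", "E"):
        out[col + "_minsec"] = out[col].map(format_minsec)
    for col in ("h", "m"):
        out[col + "_hms"] = out[col].map(format_hms)
    out.to_csv(path, index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    df = pd.read_csv(path)
    return df[RESULT_COLUMNS]
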