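"""Cell-level constants and elongation kinetic constants.

The model converts relative sequencing read densities into absolute
per-cell quantities.  Doing so requires a handful of organism-level
constants: the total number of mRNA molecules in a cell (X), the total
number of ribosomes (W), the fraction of ribosomes engaged in translation
at the moment of observation (q), and the RNA-composition constants used
to size the cellular tRNA pool.  The defaults describe an exponentially
growing *Saccharomyces cerevisiae* cell.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "CellModel",
    "KineticConstants",
    "kinetic_constants",
    "SUPPORTED_TEMPERATURES",
    "load_config",
    "DEFAULT_WALKER_SIZE",
]

#: Edge length (m) of a cubic cytoplasmic occupation site, matching the
#: linear dimension of an aminoacyl-tRNA ternary complex treated as a
#: diffusing random walker.  Changing it rescales the number of walker
#: sites only; see :class:`ribocalc.trna.WalkerSpace`.
DEFAULT_WALKER_SIZE = 5.9e-9


@dataclass(frozen=True)
class CellModel:
    """Organism/cell-level constants of the translation model.

    Parameters
    ----------
    total_transcripts
        X, mRNA molecules per cell.
    total_ribosomes
        W, ribosomes per cell.
    active_fraction
        q, fraction of ribosomes translating at the moment of observation.
    genome_size
        Genome size in nucleotides used for RNA-mass bookkeeping.
    rna_dna_ratio
        Total cellular RNA mass relative to DNA mass.
    mrna_fraction, trna_fraction
        Fractions of total RNA that are mRNA and tRNA respectively.
    mean_trna_length
        Mean tRNA length in nucleotides, used to convert tRNA mass into a
        molecule count.
    temperature
        Growth temperature in Celsius; selects the elongation kinetic
        constants (see :func:`kinetic_constants`).
    cytoplasm_volume
        V, cytoplasm volume in cubic metres.
    """

    total_transcripts: float = 36_000.0
    total_ribosomes: float = 200_000.0
    active_fraction: float = 0.85
    genome_size: float = 2.8e7
    rna_dna_ratio: float = 50.0
    mrna_fraction: float = 0.05
    trna_fraction: float = 0.15
    mean_trna_length: float = 74.5
    temperature: int = 30
    cytoplasm_volume: float = 4.2e-17

    def __post_init__(self) -> None:
        if not (0.0 < self.active_fraction <= 1.0):
            raise ValueError("active_fraction must be in (0, 1]")
        for name in (
            "total_transcripts",
            "total_ribosomes",
            "genome_size",
            "rna_dna_ratio",
            "mrna_fraction",
            "trna_fraction",
            "mean_trna_length",
            "cytoplasm_volume",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def busy_ribosomes(self) -> float:
        """W*q, the number of ribosomes engaged in translation."""
        return self.total_ribosomes * self.active_fraction

    @property
    def total_trna_molecules(self) -> int:
        """Cellular tRNA molecule count from RNA-mass bookkeeping.

        Total tRNA nucleotides = genome_size * rna_dna_ratio * trna_fraction,
        divided by the mean tRNA length and rounded to the nearest molecule.
        """
        nt = self.genome_size * self.rna_dna_ratio * self.trna_fraction
        return round(nt / self.mean_trna_length)

    @property
    def expected_transcriptome_length(self) -> float:
        """Expected total transcriptome length in nucleotides."""
        return self.mrna_fraction * self.rna_dna_ratio * self.genome_size


@dataclass(frozen=True)
class KineticConstants:
    """Per-temperature elongation kinetics (all times in seconds).

    tau1 is the average time to insert an amino acid from a cognate
    aa-tRNA once it has arrived at the A site; tau2 and tau3 are the
    average delays caused by a futile binding attempt of a near-cognate
    and a non-cognate aa-tRNA respectively.
    """

    temperature: int
    tau1: float
    tau2: float
    tau3: float

    def __post_init__(self) -> None:
        if not (self.tau1 > self.tau3 > 0.0) or self.tau2 <= 0.0:
            raise ValueError("kinetic constants must satisfy tau1 > tau3 > 0, tau2 > 0")


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("ribocalc").joinpath("data", name)))


def _load_kinetics() -> dict[int, KineticConstants]:
    table: dict[int, KineticConstants] = {}
    with open(_data_path("kinetics.tsv")) as fh:
        header = fh.readline().split()
        assert header == ["temperature", "tau1_ms", "tau2_ms", "tau3_ms"]
        for line in fh:
            t, t1, t2, t3 = line.split()
            temp = int(t)
            table[temp] = KineticConstants(
                temperature=temp,
                tau1=float(t1) / 1000.0,
                tau2=float(t2) / 1000.0,
                tau3=float(t3) / 1000.0,
            )
    return table


_KINETICS: dict[int, KineticConstants] | None = None


def kinetic_constants(temperature: int = 30) -> KineticConstants:
    """Return the elongation kinetic constants for a supported temperature.

    Only 20, 24, 30 and 37 Celsius are supported; the constants were
    derived for these temperatures and no interpolation scheme is offered.
    """
    global _KINETICS
    if _KINETICS is None:
        _KINETICS = _load_kinetics()
    try:
        return _KINETICS[int(temperature)]
    except KeyError:
        raise ValueError(
            f"unsupported temperature {temperature!r}; "
            f"supported: {sorted(_KINETICS)}"
        ) from None


SUPPORTED_TEMPERATURES = (20, 24, 30, 37)


@dataclass(frozen=True)
class Config:
    """Bundle of run-time configuration: cell constants plus walker size
    and the half-life anchor."""

    cell: CellModel
    walker_size: float = DEFAULT_WALKER_SIZE
    anchor_gene: str = "YOR202W"
    anchor_minutes: float = 9.0

    @property
    def anchor_seconds(self) -> float:
        return self.anchor_minutes * 60.0


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config; with no path, return the packaged defaults.

    User files may override any subset of keys; unspecified keys fall back
    to the packaged ``cell_model.yaml``.
    """
    with open(_data_path("cell_model.yaml")) as fh:
        raw = yaml.safe_load(fh)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        raw["cell"].update(user.get("cell", {}))
        for key in ("walker_size", "anchor_gene", "anchor_minutes"):
            if key in user:
                raw[key] = user[key]
    cell_kwargs = {}
    for key, val in raw["cell"].items():
        # YAML 1.1 treats exponents without a sign ("2.8e7") as strings
        cell_kwargs[key] = int(val) if key == "temperature" else float(val)
    cell = CellModel(**cell_kwargs)
    return Config(
        cell=cell,
        walker_size=float(raw["walker_size"]),
        anchor_gene=str(raw["anchor_gene"]),
        anchor_minutes=float(raw["anchor_minutes"]),
    )
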