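"""Cellular tRNA inventory and per-codon elongation times.

The elongation time of a codon is modelled as diffusion-limited
competition between its cognate, near-cognate and non-cognate aa-tRNAs
for the ribosomal A site, following the random-walker formulation of
Fluitt, Jackson & Viljoen (2007, Comput. Biol. Chem. 31:335) adapted to
yeast.  The cytoplasm of volume ``V`` is divided into ``N = V / delta^3``
occupation sites, where ``delta`` is the walker (aa-tRNA ternary complex)
size.  A walker species ``j`` with ``n_j`` molecules and characteristic
hop time ``t_j = delta^2 / (6 D_j)`` occupies a fraction ``p_j = n_j / N``
of the sites, so the mean time before one of its members first arrives at
a vacant A site is ``t_j / p_j``.

The time to translate codon ``c`` is then::

    t_c = 1 / sum(cognate arrival frequencies)      # wait for a cognate
          + tau1                                    # cognate insertion
          + R_near * tau2 + R_non * tau3            # futile sampling

where ``R_near`` (``R_non``) is the summed arrival frequency of
near-cognate (non-cognate) species divided by that of the cognates:
between consecutive cognate arrivals the A site is sampled on average
``R_near`` times by near-cognates and ``R_non`` times by non-cognates,
each attempt wasting ``tau2`` or ``tau3`` seconds.  Transpeptidation and
translocation are fast compared with A-site selection and contribute
nothing.

Cognate assignments are taken from a decoding table (the packaged yeast
table follows the decoding specificities of Percudani, Pavesi & Ottonello
1997, J. Mol. Biol. 268:322), not recomputed from base-pairing rules.
Near-cognates are species whose anticodon pairs with the codon with a
single mismatch in the 2nd or 3rd codon position; species that decode the
codon through a wobble (3rd-position) mismatch are cognate and are
excluded from the near-cognate set.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .cell import CellModel, KineticConstants, _data_path

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "GENETIC_CODE",
    "TRNASpecies",
    "WalkerSpace",
    "CodonKinetics",
    "anticodon_to_codon",
    "near_cognate_codons",
    "load_trna_table",
    "load_diffusion_table",
    "build_trna_inventory",
    "classify_codon",
    "arrival_time",
    "arrival_frequency",
    "competition_ratios",
    "codon_time",
    "codon_times_table",
    "DEFAULT_DIFFUSION_COEFF",
]

#: Default aa-tRNA cytoplasmic diffusion coefficient (m^2/s), used for any
#: amino acid missing from the diffusion table.
DEFAULT_DIFFUSION_COEFF = 8.3e-13

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

GENETIC_CODE: dict[str, str] = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, a in GENETIC_CODE.items() if a != "*")
)
STOP_CODONS: frozenset[str] = frozenset(
    c for c, a in GENETIC_CODE.items() if a == "*"
)

_RNA_TO_DNA_COMPLEMENT = {"A": "T", "U": "A", "G": "C", "C": "G"}


def anticodon_to_codon(anticodon: str) -> str:
    """Watson-Crick codon (DNA) read by an RNA anticodon (5'->3')."""
    try:
        return "".join(_RNA_TO_DNA_COMPLEMENT[b] for b in reversed(anticodon.upper()))
    except KeyError:
        raise ValueError(f"invalid RNA anticodon {anticodon!r}") from None


def near_cognate_codons(anticodon: str, cognates: Iterable[str]) -> frozenset[str]:
    """Sense codons pairing with ``anticodon`` with a single mismatch in
    the 2nd or 3rd codon position, excluding codons the species decodes.

    A species that is cognate for a codon via a 3rd-position wobble
    mismatch is, by this exclusion, never also a near-cognate for it.
    """
    wc = anticodon_to_codon(anticodon)
    cognates = frozenset(c.upper() for c in cognates)
    out = set()
    for codon in SENSE_CODONS:
        mismatches = [p for p in range(3) if codon[p] != wc[p]]
        if len(mismatches) == 1 and mismatches[0] in (1, 2) and codon not in cognates:
            out.add(codon)
    return frozenset(out)


@dataclass(frozen=True)
class TRNASpecies:
    """One tRNA isoacceptor and its cellular abundance."""

    anticodon: str
    amino_acid: str
    gene_copies: int
    cognate_codons: frozenset[str]
    near_cognates: frozenset[str]
    molecules: int = 0
    walker_size: float = 5.9e-9
    diffusion_coeff: float = DEFAULT_DIFFUSION_COEFF

    def __post_init__(self) -> None:
        if self.gene_copies <= 0:
            raise ValueError(f"{self.anticodon}: gene_copies must be positive")
        if self.molecules < 0:
            raise ValueError(f"{self.anticodon}: molecules must be >= 0")
        if self.cognate_codons & self.near_cognates:
            raise ValueError(
                f"{self.anticodon}: cognate and near-cognate sets overlap"
            )

    @property
    def characteristic_time(self) -> float:
        """t_j, mean time of one diffusive hop between occupation sites (s)."""
        return self.walker_size**2 / (6.0 * self.diffusion_coeff)


@dataclass(frozen=True)
class WalkerSpace:
    """Discretisation of the cytoplasm into walker occupation sites."""

    cytoplasm_volume: float
    walker_size: float

    def __post_init__(self) -> None:
        if self.cytoplasm_volume <= 0 or self.walker_size <= 0:
            raise ValueError("volume and walker size must be positive")

    @property
    def n_sites(self) -> int:
        """N, number of occupation sites (volume / walker_size^3)."""
        return math.floor(self.cytoplasm_volume / self.walker_size**3)


@dataclass(frozen=True)
class CodonKinetics:
    """Competition ratios and elongation time of one codon."""

    codon: str
    R_near: float
    R_non: float
    time: float


def load_diffusion_table(path: str | Path | None = None) -> dict[str, float]:
    """Per-amino-acid aa-tRNA diffusion coefficients (m^2/s)."""
    path = _data_path("diffusion.tsv") if path is None else Path(path)
    out: dict[str, float] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["amino_acid"]] = float(row["diffusion_coeff"])
    return out


def load_trna_table(path: str | Path | None = None) -> list[dict]:
    """Read a tRNA decoding table.

    Expected TSV columns: ``anticodon`` (RNA), ``amino_acid`` (1-letter),
    ``gene_copies``, ``cognate_codons`` and ``near_cognate_codons``
    (comma-separated DNA triplets; the near column may be empty).  With no
    path, the packaged yeast table is returned.
    """
    path = _data_path("trna_yeast.tsv") if path is None else Path(path)
    rows: list[dict] = []
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
        reader = csv.DictReader(lines, delimiter="\t")
        for row in reader:
            rows.append(
                {
                    "anticodon": row["anticodon"].strip().upper(),
                    "amino_acid": row["amino_acid"].strip().upper(),
                    "gene_copies": int(row["gene_copies"]),
                    "cognate_codons": frozenset(
                        c.strip().upper()
                        for c in row["cognate_codons"].split(",")
                        if c.strip()
                    ),
                    "near_cognate_codons": frozenset(
                        c.strip().upper()
                        for c in row.get("near_cognate_codons", "").split(",")
                        if c.strip()
                    ),
                }
            )
    return rows


def _largest_remainder(total: int, weights: Sequence[float], keys: Sequence[str]) -> list[int]:
    """Apportion ``total`` integer units proportionally to ``weights``,
    conserving the total exactly (largest-remainder rounding; ties broken
    by key for determinism)."""
    wsum = float(sum(weights))
    quotas = [total * w / wsum for w in weights]
    base = [math.floor(q) for q in quotas]
    short = total - sum(base)
    order = sorted(
        range(len(weights)), key=lambda i: (-(quotas[i] - base[i]), keys[i])
    )
    for i in order[:short]:
        base[i] += 1
    return base


def build_trna_inventory(
    trna_rows: Iterable[Mapping],
    cell: CellModel,
    walker_size: float = 5.9e-9,
    diffusion: Mapping[str, float] | None = None,
) -> list[TRNASpecies]:
    """Build the absolute cellular tRNA inventory.

    The total molecule count comes from RNA-mass bookkeeping
    (:attr:`CellModel.total_trna_molecules`) and is divided among species
    proportionally to their gene-copy fraction, on the observation that
    yeast tRNA abundance closely tracks tRNA gene copy number.
    """
    rows = list(trna_rows)
    if not rows:
        raise ValueError("empty tRNA table")
    anticodons = [r["anticodon"] for r in rows]
    if len(set(anticodons)) != len(anticodons):
        dupes = sorted({a for a in anticodons if anticodons.count(a) > 1})
        raise ValueError(f"duplicate anticodons in tRNA table: {dupes}")
    copies = [int(r["gene_copies"]) for r in rows]
    if sum(copies) <= 0:
        raise ValueError("total tRNA gene copies must be positive")
    if diffusion is None:
        diffusion = load_diffusion_table()
    molecules = _largest_remainder(cell.total_trna_molecules, copies, anticodons)
    inventory = []
    for row, n in zip(rows, molecules):
        aa = row["amino_acid"]
        near = row.get("near_cognate_codons")
        if near is None:
            near = near_cognate_codons(row["anticodon"], row["cognate_codons"])
        inventory.append(
            TRNASpecies(
                anticodon=row["anticodon"],
                amino_acid=aa,
                gene_copies=int(row["gene_copies"]),
                cognate_codons=frozenset(row["cognate_codons"]),
                near_cognates=frozenset(near),
                molecules=n,
                walker_size=walker_size,
                diffusion_coeff=diffusion.get(aa, DEFAULT_DIFFUSION_COEFF),
            )
        )
    return inventory


def _check_codon(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no elongation time")
    if codon not in GENETIC_CODE:
        raise ValueError(f"invalid codon {codon!r}")
    return codon


def classify_codon(
    codon: str, inventory: Sequence[TRNASpecies]
) -> tuple[list[TRNASpecies], list[TRNASpecies], list[TRNASpecies]]:
    """Partition the inventory into (cognates, near-cognates, non-cognates)
    for a sense codon.  Stop codons are rejected."""
    codon = _check_codon(codon)
    cog, near, non = [], [], []
    for sp in inventory:
        if codon in sp.cognate_codons:
            cog.append(sp)
        elif codon in sp.near_cognates:
            near.append(sp)
        else:
            non.append(sp)
    return cog, near, non


def arrival_time(species: TRNASpecies, space: WalkerSpace) -> float:
    """Mean waiting time (s) before a member of ``species`` first arrives
    at a vacant A site.

    Equals ``t_j / p_j`` where ``p_j = n_j / N`` is the per-hop arrival
    probability; infinite when the species has no molecules.
    """
    if species.molecules == 0:
        return math.inf
    p = species.molecules / space.n_sites
    return species.characteristic_time / p


def arrival_frequency(species: TRNASpecies, space: WalkerSpace) -> float:
    t = arrival_time(species, space)
    return 0.0 if math.isinf(t) else 1.0 / t


def competition_ratios(
    codon: str, inventory: Sequence[TRNASpecies], space: WalkerSpace
) -> tuple[float, float]:
    """(R_near, R_non): summed near-/non-cognate arrival frequencies as
    fractions of the summed cognate arrival frequency."""
    cog, near, non = classify_codon(codon, inventory)
    fcog = sum(arrival_frequency(s, space) for s in cog)
    if not cog or fcog <= 0.0:
        raise ValueError(f"codon {codon} has no cognate tRNA in the inventory")
    fnear = sum(arrival_frequency(s, space) for s in near)
    fnon = sum(arrival_frequency(s, space) for s in non)
    return fnear / fcog, fnon / fcog


def codon_time(
    codon: str,
    inventory: Sequence[TRNASpecies],
    constants: KineticConstants,
    space: WalkerSpace,
) -> float:
    """Average time (s) to add the amino acid coded by ``codon``."""
    cog, near, non = classify_codon(codon, inventory)
    fcog = sum(arrival_frequency(s, space) for s in cog)
    if not cog or fcog <= 0.0:
        raise ValueError(f"codon {codon} has no cognate tRNA in the inventory")
    fnear = sum(arrival_frequency(s, space) for s in near)
    fnon = sum(arrival_frequency(s, space) for s in non)
    r_near, r_non = fnear / fcog, fnon / fcog
    return 1.0 / fcog + constants.tau1 + r_near * constants.tau2 + r_non * constants.tau3


def codon_times_table(
    inventory: Sequence[TRNASpecies],
    constants: KineticConstants,
    space: WalkerSpace,
) -> dict[str, CodonKinetics]:
    """Competition ratios and elongation times for all 61 sense codons."""
    if space.n_sites < sum(s.molecules for s in inventory):
        raise ValueError("walker space has fewer sites than tRNA molecules")
    freqs = {s.anticodon: arrival_frequency(s, space) for s in inventory}
    out: dict[str, CodonKinetics] = {}
    for codon in SENSE_CODONS:
        cog, near, non = classify_codon(codon, inventory)
        fcog = sum(freqs[s.anticodon] for s in cog)
        if not cog or fcog <= 0.0:
            raise ValueError(f"codon {codon} has no cognate tRNA in the inventory")
        r_near = sum(freqs[s.anticodon] for s in near) / fcog
        r_non = sum(freqs[s.anticodon] for s in non) / fcog
        t = 1.0 / fcog + constants.tau1 + r_near * constants.tau2 + r_non * constants.tau3
        out[codon] = CodonKinetics(codon=codon, R_near=r_near, R_non=r_non, time=t)
    return out
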