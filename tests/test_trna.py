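"""tRNA inventory, codon classification and elongation-time kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ribocalc.cell import CellModel, kinetic_constants
from ribocalc.trna import (
    SENSE_CODONS,
    TRNASpecies,
    WalkerSpace,
    anticodon_to_codon,
    arrival_time,
    build_trna_inventory,
    classify_codon,
    codon_time,
    codon_times_table,
    competition_ratios,
    load_trna_table,
    near_cognate_codons,
    _largest_remainder,
)


def _species(anticodon, aa, copies, cognates, molecules, near=None, **kw):
    near = near_cognate_codons(anticodon, cognates) if near is None else frozenset(near)
    return TRNASpecies(
        anticodon=anticodon,
        amino_acid=aa,
        gene_copies=copies,
        cognate_codons=frozenset(cognates),
        near_cognates=near,
        molecules=molecules,
        **kw,
    )


class TestInventory:
    def test_cell_trna_total_from_rna_mass(self, cell):
        # genome 2.8e7 nt * RNA:DNA 50 * tRNA fraction 0.15 / 74.5 nt
        assert cell.total_trna_molecules == 2_818_792

    def test_inventory_conserves_cell_total(self, cell, inventory):
        assert sum(s.molecules for s in inventory) == cell.total_trna_molecules

    def test_single_species_gets_everything(self, cell):
        rows = [dict(anticodon="GAA", amino_acid="F", gene_copies=4,
                     cognate_codons=frozenset({"TTT", "TTC"}))]
        inv = build_trna_inventory(rows, cell)
        assert inv[0].molecules == cell.total_trna_molecules

    def test_proportional_split(self):
        assert _largest_remainder(1000, [3, 1], ["a", "b"]) == [750, 250]

    @given(
        st.lists(st.integers(min_value=1, max_value=40), min_size=1, max_size=50),
        st.integers(min_value=0, max_value=10**7),
    )
    def test_largest_remainder_conserves_total(self, copies, total):
        keys = [str(i) for i in range(len(copies))]
        alloc = _largest_remainder(total, copies, keys)
        assert sum(alloc) == total
        assert all(a >= 0 for a in alloc)
        # never off by more than one unit from the exact quota
        s = sum(copies)
        for a, c in zip(alloc, copies):
            assert abs(a - total * c / s) < 1.0

    def test_duplicate_anticodons_rejected(self, cell):
        rows = 2 * [dict(anticodon="GAA", amino_acid="F", gene_copies=1,
                         cognate_codons=frozenset({"TTT"}))]
        with pytest.raises(ValueError, match="duplicate"):
            build_trna_inventory(rows, cell)

    def test_nonpositive_gene_copies_rejected(self, cell):
        rows = [dict(anticodon="GAA", amino_acid="F", gene_copies=0,
                     cognate_codons=frozenset({"TTT"}))]
        with pytest.raises(ValueError):
            build_trna_inventory(rows, cell)


class TestClassification:
    def test_three_way_partition_covers_inventory(self, inventory):
        for codon in SENSE_CODONS:
            cog, near, non = classify_codon(codon, inventory)
            assert len(cog) + len(near) + len(non) == len(inventory)
            names = [s.anticodon for s in cog + near + non]
            assert len(set(names)) == len(names)

    def test_every_sense_codon_has_a_cognate(self, inventory):
        for codon in SENSE_CODONS:
            cog, _, _ = classify_codon(codon, inventory)
            assert cog, codon

    def test_wobble_cognate_not_listed_near(self):
        # alanine UGC decodes GCA (Watson-Crick) and GCG (wobble); GCG
        # differs from GCA only in position 3, so without the exclusion it
        # would count as near-cognate too
        sp = _species("UGC", "A", 5, ["GCA", "GCG"], 100)
        assert "GCG" not in sp.near_cognates
        cog, near, non = classify_codon("GCG", [sp])
        assert [s.anticodon for s in cog] == ["UGC"] and not near and not non

    def test_near_rule_positions_2_and_3_only(self):
        # phenylalanine GAA pairs exactly with TTC; single mismatches in
        # position 2 (TAC) or 3 (TTA, TTG) are near-cognate, a decoded
        # wobble codon (TTT) is not, and a 1st-position mismatch (CTC)
        # falls through to non-cognate under the stated rule
        sp = _species("GAA", "F", 10, ["TTT", "TTC"], 100)
        assert {"TAC", "TTA", "TTG"} <= sp.near_cognates
        assert "TTT" not in sp.near_cognates
        assert "CTC" not in sp.near_cognates

    def test_packaged_near_column_matches_rule(self):
        for row in load_trna_table():
            expected = near_cognate_codons(row["anticodon"], row["cognate_codons"])
            assert row["near_cognate_codons"] == expected, row["anticodon"]

    def test_stop_codon_rejected(self, inventory):
        with pytest.raises(ValueError, match="stop"):
            classify_codon("TAA", inventory)

    def test_anticodon_decoding_geometry(self):
        assert anticodon_to_codon("GAA") == "TTC"
        assert anticodon_to_codon("CAU") == "ATG"


class TestArrival:
    def test_more_molecules_arrive_sooner(self, space):
        a = _species("GAA", "F", 1, ["TTT"], 1000)
        b = _species("GAA", "F", 1, ["TTT"], 2000)
        assert arrival_time(b, space) == pytest.approx(arrival_time(a, space) / 2)

    def test_full_occupancy_gives_characteristic_time(self):
        space = WalkerSpace(cytoplasm_volume=1e-21, walker_size=1e-8)
        sp = _species("GAA", "F", 1, ["TTT"], space.n_sites, walker_size=1e-8)
        assert arrival_time(sp, space) == pytest.approx(sp.characteristic_time)

    def test_zero_molecules_never_arrive(self, space):
        sp = _species("GAA", "F", 1, ["TTT"], 0)
        assert math.isinf(arrival_time(sp, space))

    def test_against_monte_carlo_occupancy(self):
        # N sites, n walkers: arrival at a fixed vacant site is a
        # geometric trial with per-hop success n/N, so the mean waiting
        # time is t_j * N / n; simulate the geometric process directly
        N, n = 1000, 10
        space = WalkerSpace(cytoplasm_volume=N * (1e-8) ** 3, walker_size=1e-8)
        assert space.n_sites == N
        sp = _species("GAA", "F", 1, ["TTT"], n, walker_size=1e-8)
        rng = np.random.default_rng(42)
        reps = 4000
        waits = sp.characteristic_time * rng.geometric(n / N, size=reps)
        se = waits.std(ddof=1) / math.sqrt(reps)
        assert abs(arrival_time(sp, space) - waits.mean()) < 3 * se


class TestCompetition:
    def _toy(self):
        # TTT query: one cognate, one near-cognate (AUA pairs with TAT,
        # one 2nd-position mismatch away from TTT), one non-cognate
        return [
            _species("GAA", "F", 1, ["TTT", "TTC"], 1000),
            _species("AUA", "Y", 1, ["TAT"], 500),
            _species("CAU", "M", 1, ["ATG"], 2000),
        ]

    def test_partition_sizes_on_toy(self):
        cog, near, non = classify_codon("TTT", self._toy())
        assert (len(cog), len(near), len(non)) == (1, 1, 1)

    def test_ratios_equal_summed_frequency_quotients(self, space):
        from ribocalc.trna import arrival_frequency

        inv = self._toy()
        r_near, r_non = competition_ratios("TTT", inv, space)
        f = [arrival_frequency(s, space) for s in inv]
        assert r_near == pytest.approx(f[1] / f[0])
        assert r_non == pytest.approx(f[2] / f[0])

    def test_no_competitors_means_zero_ratios(self, space):
        inv = [_species("GAA", "F", 1, ["TTT", "TTC"], 1000)]
        assert competition_ratios("TTT", inv, space) == (0.0, 0.0)

    def test_equal_frequencies_give_unit_ratio(self, space):
        inv = [
            _species("GAA", "F", 1, ["TTT", "TTC"], 1000),
            _species("AUA", "Y", 1, ["TAT"], 1000),
        ]
        r_near, _ = competition_ratios("TTT", inv, space)
        assert r_near == pytest.approx(1.0)

    def test_missing_cognate_is_an_error(self, space):
        inv = [_species("CAU", "M", 1, ["ATG"], 1000)]
        with pytest.raises(ValueError, match="no cognate"):
            competition_ratios("TTT", inv, space)


class TestCodonTime:
    def test_reduces_to_tau1_without_competition(self):
        # a single cognate species saturating the walker space arrives in
        # one characteristic hop (~microseconds), so the time collapses
        # to the insertion time tau1
        space = WalkerSpace(cytoplasm_volume=1e-18, walker_size=1e-8)
        sp = _species("GAA", "F", 1, ["TTT", "TTC"], space.n_sites, walker_size=1e-8)
        t = codon_time("TTT", [sp], kinetic_constants(30), space)
        assert t == pytest.approx(0.0161, rel=1e-2)
        assert t > 0.0161

    def test_all_yeast_codons_within_physical_bounds(self, codon_times):
        for codon, t in codon_times.items():
            assert 0.0161 <= t <= 2.0, codon

    def test_temperature_ordering(self, inventory, space):
        times = {
            T: codon_time("CCG", inventory, kinetic_constants(T), space)
            for T in (20, 24, 30, 37)
        }
        assert times[20] > times[24] > times[30] > times[37]

    def test_unsupported_temperature_rejected(self):
        with pytest.raises(ValueError, match="unsupported temperature"):
            kinetic_constants(25)

    def test_monotone_in_competitor_abundance(self, space):
        const = kinetic_constants(30)

        def t(near_molecules):
            inv = [
                _species("GAA", "F", 1, ["TTT", "TTC"], 1000),
                _species("GUA", "Y", 1, ["TAT", "TAC"], near_molecules),
            ]
            return codon_time("TTT", inv, const, space)

        assert t(100) < t(1000) < t(10000)

    def test_monotone_decreasing_in_cognate_abundance(self, space):
        const = kinetic_constants(30)

        def t(cognate_molecules):
            inv = [
                _species("GAA", "F", 1, ["TTT", "TTC"], cognate_molecules),
                _species("GUA", "Y", 1, ["TAT", "TAC"], 500),
            ]
            return codon_time("TTT", inv, const, space)

        assert t(10000) < t(1000) < t(100)

    def test_table_has_all_sense_codons(self, codon_table):
        assert set(codon_table) == set(SENSE_CODONS)
        for k in codon_table.values():
            assert k.R_near >= 0 and k.R_non >= 0
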