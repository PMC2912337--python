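"""Relative densities to absolute copy numbers, loads and densities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ribocalc.cell import CellModel
from ribocalc.expression import (
    relative_binding_rate,
    ribosome_density,
    ribosome_load,
    rpkm,
    transcript_copy_number,
    transcriptome_summary,
    validate_rpkm,
)

positive_tables = st.lists(
    st.floats(min_value=1e-3, max_value=1e6, allow_nan=False), min_size=1, max_size=50
)


class TestBindingRate:
    def test_single_gene_takes_all(self):
        pz = relative_binding_rate(pd.Series([7.0]))
        assert pz.iloc[0] == 1.0

    def test_exact_fractions(self):
        pz = relative_binding_rate(pd.Series([2.0, 1.0, 1.0]))
        assert list(pz) == [0.5, 0.25, 0.25]

    @given(positive_tables)
    def test_sums_to_one(self, vals):
        pz = relative_binding_rate(pd.Series(vals))
        assert pz.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pz >= 0).all()

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_binding_rate(pd.Series([0.0, 0.0]))

    @given(positive_tables, st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, vals, k):
        d = pd.Series(vals)
        base = relative_binding_rate(d)
        scaled = relative_binding_rate(d * k)
        assert np.allclose(base, scaled, rtol=1e-12)


class TestCopyNumber:
    def test_single_gene_gets_whole_transcriptome(self, cell):
        x = transcript_copy_number(pd.Series([1.0]), cell)
        assert x.iloc[0] == 36_000.0

    def test_two_to_one_split(self, cell):
        x = transcript_copy_number(
            relative_binding_rate(pd.Series([2.0, 1.0])), cell
        )
        assert list(x) == pytest.approx([24_000.0, 12_000.0])

    @given(positive_tables)
    def test_sum_is_cell_total(self, cell, vals):
        x = transcript_copy_number(relative_binding_rate(pd.Series(vals)), cell)
        assert x.sum() == pytest.approx(cell.total_transcripts, rel=1e-12)


class TestRibosomeLoad:
    def test_one_gene_one_copy_gets_all_busy_ribosomes(self, cell):
        w = ribosome_load(pd.Series([100.0]), pd.Series([1.0]), cell)
        assert w.iloc[0] == pytest.approx(170_000.0)

    def test_equal_footprints_invert_copy_numbers(self, cell):
        w = ribosome_load(pd.Series([50.0, 50.0]), pd.Series([1.0, 4.0]), cell)
        assert w.iloc[0] / w.iloc[1] == pytest.approx(4.0)

    @given(positive_tables)
    def test_total_load_conserved(self, cell, vals):
        r_fp = pd.Series(vals)
        x = pd.Series(np.linspace(1, 9, len(vals)))
        w = ribosome_load(r_fp, x, cell)
        assert (w * x).sum() == pytest.approx(cell.busy_ribosomes, rel=1e-12)

    def test_zero_footprint_flagged_not_computed(self, cell):
        w = ribosome_load(pd.Series([10.0, 0.0]), pd.Series([1.0, 1.0]), cell)
        assert np.isnan(w.iloc[1])


class TestDensity:
    def test_one_ribosome_per_hundred_codons(self):
        assert ribosome_density(pd.Series([1.0]), pd.Series([100])).iloc[0] == 1.0

    def test_one_ribosome_per_156_nt(self):
        # one ribosome per 52 codons
        g = ribosome_density(pd.Series([1.0]), pd.Series([52])).iloc[0]
        assert g == pytest.approx(1.92, abs=0.005)

    def test_packing_limit(self):
        g = ribosome_density(pd.Series([30.0]), pd.Series([300])).iloc[0]
        assert g == 10.0


class TestRPKM:
    def test_recomputed_matches_definition(self):
        raw = pd.Series([100.0, 300.0])
        length = pd.Series([1000.0, 3000.0])
        d = rpkm(raw, length)
        assert d.iloc[0] == pytest.approx(100.0 * 1e9 / (1000.0 * 400.0))

    def test_consistent_table_passes(self):
        raw = pd.Series([100.0, 300.0])
        length = pd.Series([1000.0, 3000.0])
        assert validate_rpkm(raw, length, rpkm(raw, length)).all()

    def test_discrepancy_flagged(self, caplog):
        raw = pd.Series([100.0, 300.0])
        length = pd.Series([1000.0, 3000.0])
        given_d = rpkm(raw, length)
        given_d.iloc[0] *= 2.0
        with caplog.at_level("WARNING"):
            ok = validate_rpkm(raw, length, given_d)
        assert not ok.iloc[0] and ok.iloc[1]
        assert "RPKM consistency" in caplog.text


class TestSummary:
    def test_uniform_cohort_closed_form(self, cell):
        x = pd.Series([100.0] * 360)  # 36,000 transcripts
        L = pd.Series([500] * 360)
        s = transcriptome_summary(x, L, cell)
        assert s["mean_density"] == pytest.approx(170_000.0 / (36_000 * 500) * 100)

    def test_expected_transcriptome_length(self, cell):
        s = transcriptome_summary(pd.Series([1.0]), pd.Series([100]), cell)
        # 5% mRNA of 50:1 RNA:DNA over a 2.8e7 nt genome
        assert s["expected_transcriptome_length_nt"] == pytest.approx(7.0e7)
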