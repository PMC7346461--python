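"""Trait derivation from tooth rows: RPTL, composites, CSV round-trips."""

import math

import numpy as np
import pytest

from snakedent import (
    Tooth,
    ToothRow,
    UndefinedTraitError,
    aggregate_specimens,
    derive_dental_traits,
    log_transform_counts,
    read_tooth_table,
    relative_posterior_tooth_length,
    trait_table,
    write_tooth_table,
)
from conftest import make_tooth_row


def linear_lengths(n, base=1.0, slope=0.1, posterior_offset=0.0):
    out = [base + slope * pos for pos in range(1, n + 1)]
    for i in (-1, -2, -3):
        out[i] += posterior_offset
    return out


class TestRPTL:
    @pytest.mark.parametrize("c", [-1.0, 0.0, 0.5, 2.0])
    def test_planted_offset_recovered_exactly(self, c):
        row = make_tooth_row(linear_lengths(10, posterior_offset=c))
        assert relative_posterior_tooth_length(row) == pytest.approx(c, abs=1e-12)

    def test_hand_ols_case(self):
        """Anterior (1.1, 1.3, 1.2, 1.4, 1.5) at positions 1-5, posterior
        (2.0, 2.4, 2.2) at 6-8: OLS slope 0.09, intercept 1.03, residuals
        (0.43, 0.74, 0.45), median 0.45."""
        row = make_tooth_row([1.1, 1.3, 1.2, 1.4, 1.5, 2.0, 2.4, 2.2])
        assert relative_posterior_tooth_length(row) == pytest.approx(0.45, abs=1e-10)

    def test_position_translation_invariance(self):
        base = make_tooth_row(linear_lengths(9, posterior_offset=1.2))
        shifted = make_tooth_row(
            linear_lengths(9, posterior_offset=1.2),
            positions=list(range(11, 20)),
        )
        assert relative_posterior_tooth_length(base) == pytest.approx(
            relative_posterior_tooth_length(shifted), abs=1e-10
        )

    def test_additive_in_posterior_lengths(self):
        lengths = linear_lengths(8, posterior_offset=0.3)
        r0 = relative_posterior_tooth_length(make_tooth_row(lengths))
        bumped = lengths[:-3] + [x + 0.7 for x in lengths[-3:]]
        r1 = relative_posterior_tooth_length(make_tooth_row(bumped))
        assert r1 - r0 == pytest.approx(0.7, abs=1e-10)

    def test_missing_posterior_tooth_uses_remaining(self):
        row = make_tooth_row(linear_lengths(10, posterior_offset=2.0), missing={9})
        assert relative_posterior_tooth_length(row) == pytest.approx(2.0, abs=1e-10)

    def test_too_few_anterior_teeth_rejected(self):
        row = make_tooth_row([1.0, 2.0, 2.1, 2.2], missing={1})
        with pytest.raises(UndefinedTraitError, match="anterior"):
            relative_posterior_tooth_length(row)

    def test_all_posterior_missing_rejected(self):
        row = make_tooth_row(linear_lengths(8), missing={6, 7, 8})
        with pytest.raises(UndefinedTraitError, match="posterior"):
            relative_posterior_tooth_length(row)


class TestDeriveTraits:
    def test_socket_inferred_count(self):
        row = make_tooth_row(linear_lengths(12), missing={3, 7})
        traits = derive_dental_traits(row)
        assert traits.n_maxillary_teeth == 12
        assert traits.log_n_maxillary_teeth == pytest.approx(math.log(12))

    def test_fang_size_and_position(self):
        row = make_tooth_row([1.0, 1.0, 3.0, 1.0])
        traits = derive_dental_traits(row)
        assert traits.fang_size_mm == 3.0
        assert traits.largest_tooth_position == 3

    def test_largest_tooth_tie_goes_posterior(self):
        row = make_tooth_row([1.0, 3.0, 1.0, 3.0, 1.0])
        with pytest.warns(UserWarning, match="tie"):
            traits = derive_dental_traits(row)
        assert traits.largest_tooth_position == 4

    def test_groove_width_is_semilandmark_mean(self):
        row = make_tooth_row(
            [1.0, 1.1, 1.2, 1.3, 1.4, 2.0],
            grooved={6},
            groove_widths=(0.10, 0.12, 0.14, 0.12, 0.12),
        )
        traits = derive_dental_traits(row)
        assert traits.has_grooves
        assert traits.mean_groove_width_mm == pytest.approx(0.12)

    def test_groove_flag_matches_groove_width_presence(self):
        plain = derive_dental_traits(make_tooth_row(linear_lengths(8)))
        assert not plain.has_grooves and plain.mean_groove_width_mm is None

    def test_empty_tooth_row_rejected(self):
        row = ToothRow("sp", "s1", 30.0, 10.0, teeth=[])
        with pytest.raises(ValueError):
            derive_dental_traits(row)


class TestLogCounts:
    def test_values(self):
        np.testing.assert_allclose(
            log_transform_counts([25, 1]), [math.log(25), 0.0]
        )
        # mean of ln 3, ln 4, ln 5 = 4.094345/3
        assert float(np.mean(log_transform_counts([3, 4, 5]))) == pytest.approx(
            1.3647815207, abs=1e-9
        )

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            log_transform_counts([0, 5])


class TestAggregate:
    def test_single_specimen_identity(self):
        row = make_tooth_row(linear_lengths(10, posterior_offset=1.0))
        single = derive_dental_traits(row)
        agg = aggregate_specimens([row])
        assert agg == single

    def test_continuous_traits_averaged(self):
        r1 = make_tooth_row(linear_lengths(10), maxilla=4.0)
        r2 = make_tooth_row(linear_lengths(10), maxilla=6.0)
        assert aggregate_specimens([r1, r2]).maxilla_length_mm == pytest.approx(5.0)

    def test_counts_take_mode(self):
        rows = [make_tooth_row(linear_lengths(n)) for n in (11, 12, 12)]
        assert aggregate_specimens(rows).n_maxillary_teeth == 12

    def test_count_tie_goes_larger(self):
        rows = [make_tooth_row(linear_lengths(n)) for n in (11, 12)]
        assert aggregate_specimens(rows).n_maxillary_teeth == 12

    def test_mixed_species_rejected(self):
        rows = [
            make_tooth_row(linear_lengths(8), species="a"),
            make_tooth_row(linear_lengths(8), species="b"),
        ]
        with pytest.raises(ValueError, match="mixed"):
            aggregate_specimens(rows)


class TestCSVRoundTrip:
    def test_write_read_derive(self, tmp_path):
        rows = [
            make_tooth_row(
                linear_lengths(10, posterior_offset=1.5),
                species="sp_a",
                grooved={9, 10},
                missing={4},
            ),
            make_tooth_row(linear_lengths(14), species="sp_b"),
        ]
        path = tmp_path / "teeth.csv"
        write_tooth_table(rows, path)
        back = read_tooth_table(path)
        assert [r.species for r in back] == ["sp_a", "sp_b"]
        for orig, rt in zip(rows, back):
            assert derive_dental_traits(orig) == derive_dental_traits(rt)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("species,position\nx,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_tooth_table(path)

    def test_trait_table_indexed_by_species(self, tmp_path):
        rows = [
            make_tooth_row(linear_lengths(9), species="sp_a"),
            make_tooth_row(linear_lengths(9), species="sp_a"),
            make_tooth_row(linear_lengths(12), species="sp_b"),
        ]
        df = trait_table(rows)
        assert list(df.index) == ["sp_a", "sp_b"]
        assert df.loc["sp_b", "n_maxillary_teeth"] == 12
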