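"""Colony-array scoring: filters, pairing, frequencies, classification."""

import numpy as np
import pandas as pd
import pytest

from recscreen.errors import ConfigError
from recscreen.pinscore import (
    ScreenConfig,
    classify,
    filter_circularity,
    score_colonies,
    score_permissive,
    score_selective,
    strain_frequencies,
)
from tests.conftest import make_colonies


def _perm(plate, col, strain, area, circ=0.95, row=1):
    return (plate, row, col, strain, "permissive", area, circ)


def _sel(plate, col, strain, area, circ=0.95, row=1):
    return (plate, row, col, strain, "selective", area, circ)


class TestCircularityFilter:
    def test_boundary_is_strict(self, default_screen_config):
        df = make_colonies([
            _perm("P", 1, "a", 100, circ=0.80),
            _perm("P", 2, "a", 100, circ=0.81),
        ])
        kept = filter_circularity(df, default_screen_config)
        assert kept.col.tolist() == [2]

    def test_empty_input_empty_output(self, default_screen_config):
        df = make_colonies([])
        assert len(filter_circularity(df, default_screen_config)) == 0

    def test_order_preserved(self, default_screen_config):
        df = make_colonies([
            _perm("P", c, "a", 100, circ=0.9 if c % 2 else 0.5) for c in range(1, 9)
        ])
        kept = filter_circularity(df, default_screen_config)
        assert kept.col.tolist() == sorted(kept.col.tolist())


class TestPermissiveScoring:
    def test_plate_mean_rule_hand_example(self, default_screen_config):
        # areas (100,100,100,20): mean 80, threshold 40 -> 3 scored
        df = make_colonies([
            _perm("P", i, "a", a) for i, a in enumerate([100, 100, 100, 20], 1)
        ])
        scored = score_permissive(df, default_screen_config)
        assert scored.scored.tolist() == [True, True, True, False]

    def test_all_equal_all_scored(self, default_screen_config):
        df = make_colonies([_perm("P", i, "a", 250) for i in range(1, 5)])
        assert score_permissive(df, default_screen_config).scored.all()

    def test_single_colony_scored(self, default_screen_config):
        df = make_colonies([_perm("P", 1, "a", 1)])
        assert score_permissive(df, default_screen_config).scored.tolist() == [True]

    def test_mean_is_per_plate_not_global(self, default_screen_config):
        # plate Q is uniformly small: its colonies still score against Q's mean
        df = make_colonies(
            [_perm("P", i, "a", 400) for i in range(1, 5)]
            + [_perm("Q", i, "a", 40) for i in range(1, 5)]
        )
        assert score_permissive(df, default_screen_config).scored.all()


class TestSelectiveScoring:
    def _scored(self, perm_rows, sel_rows, config):
        df = make_colonies(perm_rows + sel_rows)
        perm = score_permissive(df, config)
        return score_selective(df, perm, config)

    def test_ten_percent_strain_mean_rule(self, default_screen_config):
        # strain mean scored permissive area 400 -> threshold 40 (strict)
        perm = [_perm("P", i, "a", 400) for i in range(1, 4)]
        sel = [_sel("P", 1, "a", 41), _sel("P", 2, "a", 40), _sel("P", 3, "a", 39)]
        out = self._scored(perm, sel, default_screen_config)
        assert out.scored.tolist() == [True, False, False]

    def test_failed_permissive_partner_blocks_scoring(self, default_screen_config):
        perm = [_perm("P", 1, "a", 400), _perm("P", 2, "a", 10)]  # mean 205 -> 2nd fails
        sel = [_sel("P", 1, "a", 300), _sel("P", 2, "a", 300)]
        out = self._scored(perm, sel, default_screen_config)
        assert out.scored.tolist() == [True, False]

    def test_unpaired_selective_never_scored(self, default_screen_config):
        perm = [_perm("P", 1, "a", 400)]
        sel = [_sel("P", 1, "a", 300), _sel("P", 9, "a", 300)]
        out = self._scored(perm, sel, default_screen_config)
        assert out.scored.tolist() == [True, False]

    def test_strain_without_scored_permissive_unscored(self, default_screen_config):
        perm = [_perm("P", 1, "a", 400), _perm("P", 2, "b", 10)]
        sel = [_sel("P", 2, "b", 500)]
        out = self._scored(perm, sel, default_screen_config)
        assert not out.scored.any()


class TestStrainFrequencies:
    def test_toy_plate_frequency(self, toy_plate, default_screen_config):
        cfg = ScreenConfig(min_colonies=1)
        perm, sel = score_colonies(toy_plate, cfg)
        out = strain_frequencies(perm, sel, cfg)
        row = out.iloc[0]
        assert (row.n_total, row.n_recombinant) == (3, 2)
        assert row.frequency == pytest.approx(2 / 3)
        assert not row.excluded

    def test_too_few_colonies_excluded(self, default_screen_config):
        perm = make_colonies([_perm("P", i, "a", 100) for i in range(1, 10)])
        perm = score_permissive(perm, default_screen_config)
        sel = score_selective(make_colonies([]), perm, default_screen_config)
        out = strain_frequencies(perm, sel, default_screen_config)
        assert out.iloc[0].n_total == 9
        assert out.iloc[0].excluded
        assert out.iloc[0].exclusion_reason == "too-few-colonies"

    def test_exclusion_list_keeps_frequency(self):
        cfg = ScreenConfig(min_colonies=10, exclusion_strains=frozenset({"a"}))
        rows = [_perm("P", i, "a", 100) for i in range(1, 41)]
        rows += [_sel("P", i, "a", 100) for i in range(1, 31)]
        perm, sel = score_colonies(make_colonies(rows), cfg)
        out = strain_frequencies(perm, sel, cfg)
        row = out.iloc[0]
        assert row.excluded and row.exclusion_reason == "msh3-list"
        assert row.frequency == pytest.approx(0.75)

    def test_frequency_bounded_by_pairing(self, default_screen_config):
        # selective colonies exist at every position; frequency cannot pass 1
        rows = [_perm("P", i, "a", 100) for i in range(1, 21)]
        rows += [_sel("P", i, "a", 500) for i in range(1, 21)]
        perm, sel = score_colonies(make_colonies(rows), default_screen_config)
        out = strain_frequencies(perm, sel, default_screen_config)
        assert (out.frequency <= 1).all()

    def test_raising_circularity_min_never_raises_n_total(self, toy_plate):
        totals = []
        for cmin in (0.5, 0.8, 0.94, 0.99):
            cfg = ScreenConfig(circularity_min=cmin, min_colonies=1)
            perm, sel = score_colonies(toy_plate, cfg)
            out = strain_frequencies(perm, sel, cfg)
            totals.append(int(out.n_total.sum()) if len(out) else 0)
        assert totals == sorted(totals, reverse=True)

    def test_idempotent_refiltering(self, toy_plate, default_screen_config):
        once = filter_circularity(toy_plate, default_screen_config)
        twice = filter_circularity(once, default_screen_config)
        pd.testing.assert_frame_equal(once, twice)


class TestClassify:
    @pytest.mark.parametrize(
        "freq,expected",
        [(0.92, "hyper"), (0.87, "hyper"), (0.56, "unclassified"),
         (0.292, "hypo"), (0.33, "hypo")],
    )
    def test_cutoff_classification(self, freq, expected, default_screen_config):
        df = pd.DataFrame({
            "strain_id": ["s"], "n_total": [48],
            "n_recombinant": [int(freq * 48)], "frequency": [freq],
            "excluded": [False], "exclusion_reason": ["none"],
        })
        out = classify(df, default_screen_config)
        assert out["class"].tolist() == [expected]

    def test_excluded_strains_not_called(self, default_screen_config):
        df = pd.DataFrame({
            "strain_id": ["s"], "n_total": [5], "n_recombinant": [5],
            "frequency": [1.0], "excluded": [True],
            "exclusion_reason": ["too-few-colonies"],
        })
        assert classify(df, default_screen_config)["class"].tolist() == ["excluded"]


class TestScreenConfig:
    def test_cutoff_ordering_enforced(self):
        with pytest.raises(ConfigError):
            ScreenConfig(hyper_cutoff=0.3, hypo_cutoff=0.5)

    def test_fraction_domains(self):
        with pytest.raises(ConfigError):
            ScreenConfig(perm_area_frac=0.0)
        with pytest.raises(ConfigError):
            ScreenConfig(min_colonies=0)
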