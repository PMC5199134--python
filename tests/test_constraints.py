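"""Slider semantics, panel logic, ordinal selection, and oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_panel, brute_force_select
from conftest import random_contrib_table, random_intervals

from sliderselect import (
    ConstraintPanel,
    ConstraintSet,
    ContributionIndex,
    ContributionMatrix,
    OrdinalConstraint,
    SliderConstraint,
    apply_ordinal,
    apply_panel,
    constraint_set_from_config,
    constraint_set_to_config,
    count_selected,
    select,
    select_dual,
)
from sliderselect.errors import ConfigurationError, DataError


def panel(name="tissues", enabled=True, **intervals):
    return ConstraintPanel.from_dict(name, intervals, enabled=enabled)


class TestSliderConstraint:
    def test_invalid_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            SliderConstraint("brain", 60, 40)
        with pytest.raises(ConfigurationError):
            SliderConstraint("brain", -1, 50)

    def test_default_detection(self):
        assert SliderConstraint("x").is_default
        assert not SliderConstraint("x", 0, 99.9).is_default

    def test_duplicate_facet_in_panel_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            ConstraintPanel("p", (SliderConstraint("a", 1, 2),
                                  SliderConstraint("a", 3, 4)))


class TestApplyPanelFigureSemantics:
    """The three caption selections on the demonstration matrix."""

    @pytest.mark.parametrize(
        "intervals,expected",
        [
            ({"brain": (80, 100)}, ("g1",)),
            ({"blood": (30, 45), "heart": (30, 45)}, ("g2",)),
            ({"brain": (0, 0), "liver": (50, 100)}, ("g3",)),
        ],
        ids=["brain-specific", "blood-and-heart", "liver-not-brain"],
    )
    def test_each_selection_picks_one_gene(self, fig1_contrib, intervals, expected):
        assert apply_panel(fig1_contrib, panel(**intervals)).selected_ids == expected

    def test_default_sliders_select_everything(self, fig1_contrib):
        assert apply_panel(fig1_contrib, panel()).selected_ids == ("g1", "g2", "g3")

    def test_disabled_panel_is_vacuous(self, fig1_contrib):
        p = panel(enabled=False, brain=(100, 100))
        assert apply_panel(fig1_contrib, p).count == 3

    def test_unknown_facet_named_in_error(self, fig1_contrib):
        with pytest.raises(ConfigurationError, match="kidney"):
            apply_panel(fig1_contrib, panel(kidney=(10, 20)))


class TestZeroSumFeatures:
    @pytest.fixture()
    def contrib_with_undefined(self):
        pct = pd.DataFrame([[100.0, 0.0], [0.0, 0.0]], index=["g", "gz"],
                           columns=["a", "b"])
        return ContributionMatrix(pct, pd.Series([True, False], index=["g", "gz"]))

    def test_included_when_all_sliders_default(self, contrib_with_undefined):
        assert apply_panel(contrib_with_undefined, panel()).count == 2

    def test_excluded_under_any_real_constraint(self, contrib_with_undefined):
        # even an exclusion slider the zero row would numerically satisfy
        sel = apply_panel(contrib_with_undefined, panel(b=(0, 0)))
        assert sel.selected_ids == ("g",)


class TestSelectCombiner:
    @pytest.fixture()
    def contribs(self):
        pct = pd.DataFrame(
            [[90.0, 10.0], [50.0, 50.0], [10.0, 90.0]],
            index=["g1", "g2", "g3"], columns=["a", "b"],
        )
        cm = ContributionMatrix(pct)
        return {"P": cm, "Q": cm}

    def test_and_is_intersection(self, contribs):
        cset = ConstraintSet((panel("P", a=(40, 100)), panel("Q", b=(40, 100))), "AND")
        assert select(contribs, cset).selected_ids == ("g2",)

    def test_or_is_union(self, contribs):
        cset = ConstraintSet((panel("P", a=(80, 100)), panel("Q", b=(80, 100))), "OR")
        assert select(contribs, cset).selected_ids == ("g1", "g3")

    def test_disabled_panel_drops_out_of_and(self, contribs):
        cset = ConstraintSet(
            (panel("P", a=(40, 100)), panel("Q", enabled=False, b=(100, 100))), "AND"
        )
        assert select(contribs, cset).selected_ids == ("g1", "g2")

    def test_no_enabled_panels_selects_all(self, contribs):
        cset = ConstraintSet((panel("P", enabled=False, a=(0, 0)),), "AND")
        assert select(contribs, cset).count == 3

    def test_universe_mismatch_error_mode(self, contribs):
        other = ContributionMatrix(
            pd.DataFrame([[100.0, 0.0]], index=["gX"], columns=["a", "b"])
        )
        cset = ConstraintSet((panel("P", a=(0, 100), b=(0, 50)),
                              panel("Q", b=(0, 100), a=(0, 50))), "AND")
        contribs2 = {"P": contribs["P"], "Q": other}
        with pytest.raises(DataError, match="universes"):
            select(contribs2, cset, universe_mismatch="error")
        # default mode: intersection is empty, so nothing is selected
        assert select(contribs2, cset).count == 0


class TestOracleEquivalence:
    def test_select_matches_brute_force_on_random_cases(self, rng):
        """Vectorized selection equals a per-feature scan on 500 random
        (matrix, constraint-set) draws with exclusions and undefined rows."""
        for trial in range(50):
            n_f = int(rng.integers(1, 200))
            n_k = int(rng.integers(1, 20))
            contrib, pct, defined = random_contrib_table(rng, n_f, n_k)
            facets = list(contrib.percentages.columns)
            for _ in range(10):
                n_panels = int(rng.integers(1, 4))
                panels, oracle_panels = [], []
                for pi in range(n_panels):
                    intervals = random_intervals(rng, facets,
                                                 int(rng.integers(0, 4)))
                    enabled = bool(rng.random() > 0.2)
                    panels.append(ConstraintPanel.from_dict(
                        f"p{pi}", intervals, enabled=enabled))
                    oracle_panels.append((enabled, dict(intervals)))
                combiner = "AND" if rng.random() < 0.5 else "OR"
                cset = ConstraintSet(tuple(panels), combiner)
                got = select({p.panel_name: contrib for p in panels}, cset)
                want = brute_force_select(pct, defined, oracle_panels, combiner)
                assert list(got.selected_ids) == want
                assert count_selected(
                    {p.panel_name: contrib for p in panels}, cset) == len(want)

    def test_monotonicity_and_set_algebra(self, rng):
        """Tightening a slider never grows the selection; AND ⊆ panel ⊆ OR."""
        for trial in range(40):
            contrib, pct, defined = random_contrib_table(
                rng, int(rng.integers(5, 150)), int(rng.integers(2, 15)))
            facets = list(contrib.percentages.columns)
            for _ in range(5):
                iv = random_intervals(rng, facets, int(rng.integers(1, 4)))
                p1 = ConstraintPanel.from_dict("A", iv)
                base = set(apply_panel(contrib, p1).selected_ids)
                # tighten one interval
                facet = list(iv)[int(rng.integers(0, len(iv)))]
                lo, hi = iv[facet]
                tighter = dict(iv)
                tighter[facet] = (min(100.0, lo + rng.uniform(0, 100 - lo)),
                                  hi) if rng.random() < 0.5 else (
                                      lo, max(lo, hi - rng.uniform(0, hi - lo)))
                if tighter[facet][0] > tighter[facet][1]:
                    continue
                tight_sel = set(apply_panel(
                    contrib, ConstraintPanel.from_dict("A", tighter)).selected_ids)
                assert tight_sel <= base
                # set algebra across two panels
                iv2 = random_intervals(rng, facets, int(rng.integers(1, 4)))
                p2 = ConstraintPanel.from_dict("B", iv2)
                s1 = set(apply_panel(contrib, p1).selected_ids)
                s2 = set(apply_panel(contrib, p2).selected_ids)
                both = {"A": contrib, "B": contrib}
                s_and = set(select(both, ConstraintSet((p1, p2), "AND")).selected_ids)
                s_or = set(select(both, ConstraintSet((p1, p2), "OR")).selected_ids)
                assert s_and <= s1 <= s_or and s_and <= s2 <= s_or
                assert s_and == s1 & s2 and s_or == s1 | s2

    def test_exclusion_selects_exactly_zero_contributors(self, rng):
        contrib, pct, defined = random_contrib_table(rng, 100, 6, zero_frac=0.0)
        facet = contrib.percentages.columns[0]
        sel = apply_panel(contrib, panel(**{facet: (0, 0)}))
        expected = [f for f in pct if defined[f] and pct[f][facet] <= 1e-9]
        assert list(sel.selected_ids) == expected


class TestContributionIndex:
    def test_single_slider_counts_match_full_scan(self, rng):
        contrib, pct, defined = random_contrib_table(rng, 150, 8)
        idx = ContributionIndex(contrib)
        facets = list(contrib.percentages.columns)
        for _ in range(100):
            facet = facets[int(rng.integers(0, len(facets)))]
            lo, hi = np.sort(rng.uniform(0, 100, size=2))
            c = SliderConstraint(facet, float(lo), float(hi))
            want = len(brute_force_panel(pct, defined, True, {facet: (lo, hi)}))
            assert idx.count_single(c) == want
            assert idx.count_panel(ConstraintPanel("p", (c,))) == want

    def test_default_constraint_counts_everything(self, rng):
        contrib, _, _ = random_contrib_table(rng, 40, 4)
        idx = ContributionIndex(contrib)
        assert idx.count_single(SliderConstraint("t0")) == 40

    def test_multi_constraint_panel_falls_back_to_scan(self, fig1_contrib):
        idx = ContributionIndex(fig1_contrib)
        p = panel(blood=(30, 45), heart=(30, 45))
        assert idx.count_panel(p) == 1


class TestOrdinalSelection:
    @pytest.fixture()
    def levels(self):
        return pd.DataFrame(
            {"liver": ["High", "Low", None, "None"],
             "brain": ["None", "Medium", "High", None]},
            index=["gA", "gB", "gC", "gD"],
        )

    def test_interval_on_ordinal_scale(self, levels):
        sel = apply_ordinal(levels, [OrdinalConstraint("liver", "Medium", "High")])
        assert sel.selected_ids == ("gA",)

    def test_none_interval_excludes_low(self, levels):
        sel = apply_ordinal(levels, [OrdinalConstraint("liver", "None", "None")])
        assert sel.selected_ids == ("gD",)

    def test_full_interval_requires_recorded_level(self, levels):
        sel = apply_ordinal(levels, [OrdinalConstraint("liver", "None", "High")])
        assert sel.selected_ids == ("gA", "gB", "gD")  # gC has no liver call

    def test_missing_level_fails_constraint(self, levels):
        sel = apply_ordinal(levels, [OrdinalConstraint("brain", "Low", "High"),
                                     OrdinalConstraint("liver", "Low", "High")])
        assert sel.selected_ids == ("gB",)

    def test_empty_ordinal_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            OrdinalConstraint("liver", "High", "Low")

    def test_unknown_level_label_rejected(self, levels):
        from sliderselect.errors import FormatError
        bad = levels.copy()
        bad.loc["gA", "liver"] = "Strong"
        with pytest.raises(FormatError, match="Strong"):
            apply_ordinal(bad, [OrdinalConstraint("liver", "Low", "High")])


class TestDualSelection:
    @pytest.fixture()
    def rna(self):
        pct = pd.DataFrame([[80.0, 20.0], [60.0, 40.0], [10.0, 90.0]],
                           index=["gA", "gB", "gX"], columns=["liver", "brain"])
        return ContributionMatrix(pct)

    @pytest.fixture()
    def prot(self):
        return pd.DataFrame({"liver": ["None", "High", "High"]},
                            index=["gA", "gB", "gC"])

    def test_conjunction_of_rna_and_protein(self, rna, prot):
        cset = ConstraintSet((panel("rna", liver=(50, 100)),))
        sel = select_dual(rna, cset, prot,
                          [OrdinalConstraint("liver", "Low", "High")])
        assert sel.selected_ids == ("gB",)  # gA fails protein, gC has no RNA

    def test_no_protein_constraints_is_rna_on_shared_genes(self, rna, prot):
        cset = ConstraintSet((panel("rna", liver=(50, 100)),))
        sel = select_dual(rna, cset, prot, [])
        assert sel.selected_ids == ("gA", "gB")

    def test_disjoint_universes_rejected(self, rna):
        prot = pd.DataFrame({"liver": ["High"]}, index=["other"])
        with pytest.raises(DataError):
            select_dual(rna, ConstraintSet(), prot, [])


class TestConfigRoundTrip:
    def test_defaults_omitted_and_round_trippable(self):
        cset = ConstraintSet(
            (ConstraintPanel("cells", (SliderConstraint("neutrophil", 20, 100),
                                       SliderConstraint("t_cell", 0, 5),
                                       SliderConstraint("monocyte")),),
             ConstraintPanel("tissues", (), enabled=False)),
            "OR",
        )
        cfg = constraint_set_to_config(cset)
        assert "monocyte" not in cfg["panels"]["cells"]["constraints"]
        assert cfg["panels"]["tissues"] == {"enabled": False}
        back = constraint_set_to_config(constraint_set_from_config(cfg))
        assert back == cfg

    def test_bad_interval_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            constraint_set_from_config(
                {"panels": {"p": {"constraints": {"a": [1, 2, 3]}}}})
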