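"""Coverage summaries and six-group DPA/PKA concordance."""

import numpy as np
import pandas as pd
import pytest

from phagepst import errors
from phagepst.host_range import (CONCORDANT_GROUPS, concordance_classify,
                                 concordance_summary, coverage_by_category,
                                 coverage_summary, round_half_up)
from phagepst.io_tables import (LYSIS, NO_LYSIS, REDUCED_GROWTH,
                                HostRangeMatrix, PhageMetadata)

L, R, N = LYSIS, REDUCED_GROWTH, NO_LYSIS


def _matrix(cols: dict, assay="DPA", strain_meta=None):
    strains = [f"s{i+1}" for i in range(len(next(iter(cols.values()))))]
    df = pd.DataFrame(cols, index=strains).astype(object)
    df = df.where(pd.notna(df), None)
    return HostRangeMatrix(list(cols), strains, df, assay, strain_meta)


class TestCoverage:
    def test_direct_counts(self):
        m = _matrix({"A": [L, L, R, N]})
        (c,) = coverage_summary(m)
        assert (c.n_lysis, c.n_reduced, c.n_no_lysis, c.n_total) == (2, 1, 1, 4)
        assert c.pct_lysis == pytest.approx(50.0)
        assert c.pct_lysis_int == 50

    def test_panel_scale_percentage(self):
        m = _matrix({"A": [L] * 63 + [N] * 78})  # 63 of 141 lysed
        (c,) = coverage_summary(m)
        assert c.n_total == 141
        assert c.pct_lysis_int == 45

    def test_all_no_lysis(self):
        (c,) = coverage_summary(_matrix({"A": [N, N, N]}))
        assert c.pct_lysis == 0.0

    def test_missing_cells_excluded_from_denominator(self):
        m = _matrix({"A": [L, None, N, None]})
        (c,) = coverage_summary(m)
        assert c.n_total == 2 and c.pct_lysis == pytest.approx(50.0)

    def test_empty_matrix_rejected(self):
        m = _matrix({"A": [L]})
        m.strains, m.calls = [], m.calls.iloc[0:0]
        with pytest.raises(errors.ValidationError):
            coverage_summary(m)


class TestCoverageByCategory:
    def test_per_category_percent(self):
        meta = {"s1": "wound", "s2": "wound", "s3": "wound", "s4": "wound",
                "s5": "urine"}
        m = _matrix({"A": [L, L, N, N, L]}, strain_meta=meta)
        tab = coverage_by_category(m)
        assert tab.at["A", "wound"] == pytest.approx(50.0)
        assert tab.at["A", "urine"] == pytest.approx(100.0)

    def test_unannotated_strains_pool_as_not_available(self):
        m = _matrix({"A": [L, N]}, strain_meta={"s1": "wound"})
        tab = coverage_by_category(m)
        assert tab.at["A", "not available"] == pytest.approx(0.0)

    def test_category_with_no_tested_strain_is_missing(self):
        meta = {"s1": "wound", "s2": "urine"}
        m = _matrix({"A": [L, None]}, strain_meta=meta)
        tab = coverage_by_category(m)
        assert np.isnan(tab.at["A", "urine"])

    def test_requires_metadata(self):
        with pytest.raises(errors.ValidationError):
            coverage_by_category(_matrix({"A": [L]}))


class TestConcordanceGroups:
    @pytest.mark.parametrize("dpa,pka,group", [
        (N, N, 1), (R, N, 2), (L, N, 3), (N, L, 4), (R, L, 5), (L, L, 6),
    ])
    def test_fixed_mapping(self, dpa, pka, group):
        assert concordance_classify(dpa, pka) == group

    def test_reduced_growth_invalid_as_pka(self):
        with pytest.raises(errors.ValidationError):
            concordance_classify(L, R)


class TestConcordanceSummary:
    def test_direct_fractions(self):
        # pairs (L,L),(L,L),(N,N),(R,L),(L,N) in one 5-strain column
        dpa = _matrix({"A": [L, L, N, R, L]})
        pka = _matrix({"A": [L, L, N, L, N]}, assay="PKA")
        s = concordance_summary(dpa, pka)
        assert s.group_fractions[6] == pytest.approx(0.4)
        assert s.group_fractions[1] == pytest.approx(0.2)
        assert s.group_fractions[5] == pytest.approx(0.2)
        assert s.group_fractions[3] == pytest.approx(0.2)
        assert s.concordance == pytest.approx(0.6)

    def test_identical_all_lysis_fully_concordant(self):
        dpa = _matrix({"A": [L, L]})
        pka = _matrix({"A": [L, L]}, assay="PKA")
        assert concordance_summary(dpa, pka).concordance == pytest.approx(1.0)

    def test_reduced_vs_no_lysis_is_not_concordant(self):
        """Group 2 (reduced growth / no lysis) is ambiguous, not agreement."""
        dpa = _matrix({"A": [R, R, R]})
        pka = _matrix({"A": [N, N, N]}, assay="PKA")
        s = concordance_summary(dpa, pka)
        assert s.group_fractions[2] == pytest.approx(1.0)
        assert s.concordance == 0.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        dpa = _matrix({p: rng.choice([L, R, N], 20).tolist() for p in "ABC"})
        pka = _matrix({p: rng.choice([L, N], 20).tolist() for p in "ABC"},
                      assay="PKA")
        s = concordance_summary(dpa, pka)
        assert sum(s.group_fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_genus_fractions_recompose_global(self):
        rng = np.random.default_rng(11)
        phages = ["A", "B", "C", "D"]
        dpa = _matrix({p: rng.choice([L, R, N], 15).tolist() for p in phages})
        pka = _matrix({p: rng.choice([L, N], 15).tolist() for p in phages},
                      assay="PKA")
        meta = {p: PhageMetadata(p, g, "myovirus", "lytic", True)
                for p, g in zip(phages, ["g1", "g1", "g2", "g3"])}
        s = concordance_summary(dpa, pka, meta)
        for g in range(1, 7):
            recomposed = sum(row[f"group_{g}"] * row["n_pairs"]
                             for _, row in s.by_genus.iterrows()) / s.n_pairs
            assert recomposed == pytest.approx(s.group_fractions[g], abs=1e-12)

    def test_intersection_with_warning(self):
        dpa = _matrix({"A": [L, L], "B": [N, N]})
        pka = _matrix({"A": [L, L]}, assay="PKA")
        with pytest.warns(UserWarning, match="intersection"):
            s = concordance_summary(dpa, pka)
        assert s.n_pairs == 2

    def test_empty_intersection_rejected(self):
        dpa = _matrix({"A": [L]})
        pka = _matrix({"B": [L]}, assay="PKA")
        with pytest.raises(errors.ValidationError):
            concordance_summary(dpa, pka)


@pytest.mark.parametrize("x,expected", [(0.5, 1), (1.5, 2), (2.5, 3),
                                        (44.6, 45), (17.4, 17)])
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected


def test_concordant_groups_are_one_and_six():
    assert CONCORDANT_GROUPS == (1, 6)
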