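import numpy as np
import pandas as pd
import pytest

from rhythmscan.core import Detector, RhythmCall
from rhythmscan.orthologs import (
    OrthologPair,
    category_table,
    match_rhythmic_orthologs,
    phase_concordance,
)


def _call(probe, q, phase=None, period_ok=True):
    return RhythmCall(probe_id=probe, detector=Detector.JTK, statistic=q,
                      period_hr=24.0, peak_phase_hr=phase, period_ok=period_ok)


def _homology(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pct_identity"])


class TestMatchOrthologs:
    def test_highest_identity_rhythmic_homologue_chosen(self):
        calls_a = [_call("gA", 0.01, 4.0)]
        calls_b = [_call("b1", 0.5, None), _call("b2", 0.01, 16.0)]
        hom = _homology([("gA", "b1", 90.0), ("gA", "b2", 80.0)])
        pairs = match_rhythmic_orthologs(calls_a, calls_b, hom)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.gene_b, p.pct_identity, p.rhythmic_b) == ("b2", 80.0, True)
        assert p.phase_b == 16.0

    def test_single_arrhythmic_homologue(self):
        calls_a = [_call("gA", 0.01, 4.0)]
        calls_b = [_call("b1", 0.8)]
        hom = _homology([("gA", "b1", 75.0)])
        p = match_rhythmic_orthologs(calls_a, calls_b, hom)[0]
        assert p.gene_b == "b1"
        assert not p.rhythmic_b
        assert p.phase_b is None

    def test_missing_homologue_recorded(self):
        pairs = match_rhythmic_orthologs([_call("gA", 0.01)], [], _homology([]))
        assert pairs[0].gene_b is None
        assert not pairs[0].rhythmic_b

    def test_arrhythmic_species_a_gene_skipped(self):
        pairs = match_rhythmic_orthologs([_call("gA", 0.5)], [], _homology([]))
        assert pairs == []

    def test_lowest_q_probe_collapses_genes(self):
        calls_a = [_call("p1", 0.04, 4.0), _call("p2", 0.01, 16.0)]
        calls_b = [_call("b1", 0.01, 2.0)]
        hom = _homology([("g", "b1", 90.0)])
        pairs = match_rhythmic_orthologs(
            calls_a, calls_b, hom, gene_map_a={"p1": "g", "p2": "g"})
        assert pairs[0].phase_a == 16.0

    def test_identity_tie_breaks_lexicographically(self):
        calls_a = [_call("gA", 0.01)]
        calls_b = [_call("bX", 0.01, 1.0), _call("bA", 0.01, 2.0)]
        hom = _homology([("gA", "bX", 80.0), ("gA", "bA", 80.0)])
        assert match_rhythmic_orthologs(calls_a, calls_b, hom)[0].gene_b == "bA"

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="pct_identity"):
            match_rhythmic_orthologs([], [], pd.DataFrame({"gene_a": [], "gene_b": []}))

    def test_shared_fraction_recovered_in_simulation(self):
        # species B rhythmic for a known fraction of A's genes
        rng = np.random.default_rng(0)
        f = 0.6
        n = 300
        calls_a, calls_b, rows = [], [], []
        shared = rng.random(n) < f
        for i in range(n):
            calls_a.append(_call(f"a{i}", 0.001, float(rng.uniform(0, 24))))
            calls_b.append(_call(f"b{i}", 0.001 if shared[i] else 0.9,
                                 float(rng.uniform(0, 24)) if shared[i] else None))
            rows.append((f"a{i}", f"b{i}", 90.0))
        pairs = match_rhythmic_orthologs(calls_a, calls_b, _homology(rows))
        got = np.mean([p.rhythmic_b for p in pairs])
        se = np.sqrt(f * (1 - f) / n)
        assert abs(got - shared.mean()) < 1e-12
        assert abs(got - f) < 4 * se


class TestCategoryTable:
    def _pairs(self):
        return [
            OrthologPair("g1", "h1", 90.0, True, True, 4.0, 6.0),
            OrthologPair("g2", "h2", 80.0, True, False, 4.0, None),
            OrthologPair("g3", None, None, True, False, 4.0, None),
        ]

    def test_hand_counted_row(self):
        table = category_table(self._pairs(), {"g1": "Cat", "g2": "Cat", "g3": "Cat"})
        row = table[table.category == "Cat"].iloc[0]
        assert (row.rhythmic_a, row.homologues, row.rhythmic_homologues) == (3, 2, 1)

    def test_totals_are_column_sums(self):
        cats = {"g1": "X", "g2": "Y", "g3": "X"}
        table = category_table(self._pairs(), cats)
        body = table[table.category != "Totals"]
        totals = table[table.category == "Totals"].iloc[0]
        for col in ("rhythmic_a", "homologues", "rhythmic_homologues"):
            assert totals[col] == body[col].sum()

    def test_empty_map_all_unknown(self):
        table = category_table(self._pairs(), {})
        assert set(table.category) == {"Unknown", "Totals"}

    def test_row_inequalities(self):
        table = category_table(self._pairs(), {"g1": "A"})
        assert (table.rhythmic_homologues <= table.homologues).all()
        assert (table.homologues <= table.rhythmic_a).all()


class TestPhaseConcordance:
    def test_antiphase_pair(self):
        pairs = [OrthologPair("a", "b", 90.0, True, True, 12.0, 0.0)]
        summary = phase_concordance(pairs)
        assert summary["differences_hr"] == [12.0]
        assert abs(summary["circular_mean_hr"]) == pytest.approx(12.0)

    def test_identical_phases(self):
        pairs = [OrthologPair("a", "b", 90.0, True, True, 7.0, 7.0)]
        assert phase_concordance(pairs)["circular_mean_hr"] == pytest.approx(0.0)

    def test_no_doubly_rhythmic_pairs(self):
        pairs = [OrthologPair("a", "b", 90.0, True, False, 7.0, None)]
        assert phase_concordance(pairs)["n"] == 0

    def test_simulated_antiphase_family(self):
        rng = np.random.default_rng(1)
        pairs = []
        for i in range(50):
            ph = float(rng.uniform(0, 24))
            jitter = float(rng.normal(0, 0.5))
            pairs.append(OrthologPair(f"a{i}", f"b{i}", 90.0, True, True,
                                      ph, (ph + 12.0 + jitter) % 24.0))
        summary = phase_concordance(pairs)
        assert abs(abs(summary["circular_mean_hr"]) - 12.0) < 0.5
        assert summary["concentration"] > 0.9

    def test_common_shift_equivariance(self):
        rng = np.random.default_rng(2)
        base = [OrthologPair(f"a{i}", f"b{i}", 90.0, True, True,
                             float(rng.uniform(0, 24)), float(rng.uniform(0, 24)))
                for i in range(20)]
        shifted = [OrthologPair(p.gene_a, p.gene_b, p.pct_identity, True, True,
                                (p.phase_a + 5.0) % 24.0, (p.phase_b + 5.0) % 24.0)
                   for p in base]
        s0 = phase_concordance(base)
        s1 = phase_concordance(shifted)
        assert s1["circular_mean_hr"] == pytest.approx(s0["circular_mean_hr"], abs=1e-9)
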