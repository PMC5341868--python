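"""Enrichment statistics against exact rational / hand-computed oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from mirsynergy.enrichment import (
    enrich_mirna_targets,
    group_terms,
    holm_adjust,
    hypergeom_right_pvalue,
    kappa_score,
)


def exact_right_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Independent oracle: rational hypergeometric right-tail sum."""
    total = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(total, comb(N, n))


@st.composite
def hypergeom_args(draw):
    N = draw(st.integers(min_value=1, max_value=80))
    K = draw(st.integers(min_value=0, max_value=N))
    n = draw(st.integers(min_value=0, max_value=N))
    k = draw(st.integers(min_value=0, max_value=min(K, n)))
    return k, K, n, N


class TestHypergeom:
    def test_right_tail_at_zero_is_one(self):
        assert hypergeom_right_pvalue(0, 5, 7, 20) == 1.0

    def test_exact_small_instances(self):
        assert hypergeom_right_pvalue(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)
        expected = float(exact_right_tail(3, 6, 7, 20))
        assert hypergeom_right_pvalue(3, 6, 7, 20) == pytest.approx(expected, rel=1e-12)

    @given(hypergeom_args())
    @settings(max_examples=300, derandomize=True)
    def test_matches_rational_enumeration(self, args):
        k, K, n, N = args
        expected = float(exact_right_tail(k, K, n, N))
        assert hypergeom_right_pvalue(k, K, n, N) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("args", [(6, 5, 7, 20), (2, 5, 1, 20), (1, 25, 5, 20),
                                      (-1, 5, 5, 10), (0.5, 5, 5, 10)])
    def test_inconsistent_counts_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeom_right_pvalue(*args)


class TestHolm:
    def test_hand_computed_example(self):
        assert list(holm_adjust([0.01, 0.02, 0.03])) == pytest.approx([0.03, 0.04, 0.04])

    def test_single_p_and_cap_at_one(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])
        assert list(holm_adjust([0.5, 0.5, 0.5])) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    @settings(max_examples=200, derandomize=True)
    def test_agrees_with_statsmodels_and_is_bounded_by_bonferroni(self, ps):
        ours = holm_adjust(ps)
        reference = multipletests(ps, method="holm")[1]
        assert ours == pytest.approx(reference, abs=1e-12)
        bonferroni = np.minimum(1.0, np.asarray(ps) * len(ps))
        assert (ours <= bonferroni + 1e-12).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(ours[order]) >= -1e-12).all()


class TestKappa:
    UNIVERSE = {f"g{i}" for i in range(1, 11)}

    def test_identical_sets_score_one(self):
        a = {"g1", "g2"}
        assert kappa_score(a, a, self.UNIVERSE) == 1.0
        assert kappa_score(set(), set(), self.UNIVERSE) == 1.0

    def test_balanced_complements_score_minus_one(self):
        a = {"g1", "g2", "g3", "g4", "g5"}
        assert kappa_score(a, self.UNIVERSE - a, self.UNIVERSE) == pytest.approx(-1.0)

    def test_hand_computed_agreement_table(self):
        a = {"g1", "g2", "g3", "g4"}
        b = {"g1", "g2", "g3", "g5"}
        # 2x2 agreement table (3, 1, 1, 5): p_o = 0.8, p_e = 0.52
        assert kappa_score(a, b, self.UNIVERSE) == pytest.approx((0.8 - 0.52) / 0.48)

    @given(st.sets(st.integers(min_value=0, max_value=14)),
           st.sets(st.integers(min_value=0, max_value=14)))
    @settings(max_examples=100, derandomize=True)
    def test_symmetry_and_relabel_invariance(self, ia, ib):
        universe = {f"g{i}" for i in range(15)}
        a, b = {f"g{i}" for i in ia}, {f"g{i}" for i in ib}
        forward = kappa_score(a, b, universe)
        assert forward == pytest.approx(kappa_score(b, a, universe))
        relabel = {f"g{i}": f"h{(i * 7) % 15}" for i in range(15)}
        assert kappa_score({relabel[x] for x in a}, {relabel[x] for x in b},
                           set(relabel.values())) == pytest.approx(forward)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            kappa_score(set(), set(), set())


def brute_force_enrichment(target_map, pathway_db, universe, p_threshold=0.05):
    """Independent oracle: rational tails + hand-stepped Holm per miRNA."""
    rows = {}
    for mirna, raw_targets in target_map.items():
        targets = set(raw_targets) & universe
        if not targets:
            continue
        ps = {}
        for pathway, genes in pathway_db.items():
            K = len(genes & universe)
            k = len(targets & genes)
            ps[pathway] = exact_right_tail(k, K, len(targets), len(universe))
        m = len(ps)
        ordered = sorted(ps, key=lambda q: (ps[q], q))
        adj, running = {}, Fraction(0)
        for i, pathway in enumerate(ordered):
            running = max(running, (m - i) * ps[pathway])
            adj[pathway] = min(Fraction(1), running)
        rows[mirna] = {
            p: (float(ps[p]), float(adj[p]), adj[p] <= Fraction(p_threshold).limit_denominator())
            for p in ps
        }
    return rows


class TestEnrichMirnaTargets:
    def toy(self):
        universe = {f"g{i}" for i in range(1, 21)}
        pathway_db = {
            "P1": {"g1", "g2", "g3", "g4"},
            "P2": {"g3", "g4", "g5", "g6", "g7"},
            "P3": {"g10", "g11", "g12"},
            "P4": {"g13", "g14", "g15", "g16", "g17", "g18"},
        }
        target_map = {
            "m1": {"g1", "g2", "g3", "g4", "g9"},
            "m2": {"g3", "g4", "g5", "g6", "g7", "g19"},
            "m3": {"g10", "g11", "g12"},
        }
        return target_map, pathway_db, universe

    def test_matches_brute_force_oracle(self):
        target_map, pathway_db, universe = self.toy()
        table = enrich_mirna_targets(target_map, pathway_db, universe)
        oracle = brute_force_enrichment(target_map, pathway_db, universe)
        assert len(table) == len(target_map) * len(pathway_db)
        for _, row in table.iterrows():
            p_raw, p_adj, enriched = oracle[row["mirna"]][row["pathway"]]
            assert row["p_raw"] == pytest.approx(p_raw, rel=1e-10)
            assert row["p_adj"] == pytest.approx(p_adj, rel=1e-10)
            assert row["enriched"] == enriched

    def test_full_overlap_dominates_family(self):
        universe = {f"g{i}" for i in range(60)}
        pathway_db = {f"P{j}": {f"g{j * 3}", f"g{j * 3 + 1}", f"g{j * 3 + 2}"}
                      for j in range(10)}
        table = enrich_mirna_targets({"m": set(pathway_db["P4"])}, pathway_db, universe)
        best = table.loc[table["p_adj"].idxmin(), "pathway"]
        assert best == "P4"

    def test_disjoint_targets_not_enriched(self):
        target_map, pathway_db, universe = self.toy()
        table = enrich_mirna_targets({"m": {"g19", "g20"}}, pathway_db, universe)
        assert not table["enriched"].any()

    def test_empty_pathway_db_rejected(self):
        with pytest.raises(ValueError):
            enrich_mirna_targets({"m": {"g1"}}, {}, {"g1"})

    def test_mirna_outside_universe_skipped_with_warning(self, caplog):
        target_map, pathway_db, universe = self.toy()
        with caplog.at_level("WARNING"):
            table = enrich_mirna_targets({"m": {"zzz"}}, pathway_db, universe)
        assert table.empty
        assert "skipped" in caplog.text

    def test_null_targets_keep_family_error_rate_nominal(self):
        """Uniformly drawn target sets should almost never be called enriched."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(120)]
        universe = set(genes)
        pathway_db = {f"P{j}": set(rng.choice(genes, size=12, replace=False))
                      for j in range(15)}
        target_map = {f"m{i}": set(rng.choice(genes, size=20, replace=False))
                      for i in range(40)}
        table = enrich_mirna_targets(target_map, pathway_db, universe)
        families = table.groupby("mirna")["enriched"].any()
        assert families.mean() <= 0.05


class TestGroupTerms:
    def enriched_frame(self, pathways, p_adjs):
        import pandas as pd

        return pd.DataFrame(
            {
                "mirna": "m",
                "pathway": pathways,
                "p_adj": p_adjs,
                "enriched": True,
            }
        )

    def test_identical_pathways_form_one_group(self):
        db = {"A": {"g1", "g2"}, "B": {"g1", "g2"}}
        universe = {f"g{i}" for i in range(1, 9)}
        groups = group_terms(self.enriched_frame(["A", "B"], [0.01, 0.02]), db, universe)
        assert len(groups) == 1
        assert groups[0].members == ("A", "B")
        assert groups[0].representative == "A"

    def test_dissimilar_pathways_stay_singletons(self):
        db = {"A": {"g1", "g2"}, "B": {"g5", "g6"}}
        universe = {f"g{i}" for i in range(1, 9)}
        groups = group_terms(self.enriched_frame(["A", "B"], [0.01, 0.02]), db, universe)
        assert [g.members for g in groups] == [("A",), ("B",)]

    def test_single_linkage_chains_components(self):
        universe = {f"g{i}" for i in range(40)}
        a = {f"g{i}" for i in range(0, 10)}
        b = {f"g{i}" for i in range(4, 14)}       # close to both A and C
        c = {f"g{i}" for i in range(8, 18)}
        db = {"A": a, "B": b, "C": c}
        kab = kappa_score(a, b, universe)
        kbc = kappa_score(b, c, universe)
        kac = kappa_score(a, c, universe)
        threshold = (max(kac, 0) + min(kab, kbc)) / 2
        assert kab >= threshold and kbc >= threshold and kac < threshold
        groups = group_terms(self.enriched_frame(["A", "B", "C"], [0.03, 0.01, 0.02]),
                             db, universe, kappa_threshold=threshold)
        assert len(groups) == 1
        assert groups[0].members == ("A", "B", "C")
        assert groups[0].representative == "B"

    def test_requires_an_enriched_row(self):
        frame = self.enriched_frame(["A"], [0.5])
        frame["enriched"] = False
        with pytest.raises(ValueError):
            group_terms(frame, {"A": {"g1"}}, {"g1", "g2"})
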