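"""Population panels: harmonization, Gst/Fst, NJ, PCA, allele scans."""

import numpy as np
import pandas as pd
import pytest

from hlapop.panel import (
    PopulationPanel,
    fst_corrected_distance,
    gst_distance,
    harmonize,
    heatmap_prep,
    neighbor_joining,
    pca_scores,
    rare_absent_scan,
    unique_alleles,
)


def make_rows(entries):
    """entries: (population, locus, allele, frequency[, n[, standard]])."""
    rows = []
    for e in entries:
        pop, locus, allele, f = e[:4]
        n = e[4] if len(e) > 4 else 100
        std = e[5] if len(e) > 5 else "Gold"
        rows.append(
            {
                "population": pop, "region": "R", "sample_n": n,
                "standard": std, "locus": locus, "allele": allele,
                "frequency": f,
            }
        )
    return pd.DataFrame(rows)


def panel_from_freqs(freqs, sample_n=None):
    """freqs: {population: {full allele name: frequency}}."""
    f = pd.DataFrame.from_dict(freqs, orient="index").fillna(0.0)
    f.index.name = "population"
    meta = pd.DataFrame(
        {
            "region": "R",
            "sample_n": [
                (sample_n or {}).get(p, 100) for p in f.index
            ],
            "standard": "Gold",
        },
        index=f.index,
    )
    return PopulationPanel(f, meta)


class TestHarmonize:
    def test_trim_and_sum(self):
        p = harmonize(
            make_rows(
                [("pop1", "A", "01:01:01G", 0.10), ("pop1", "A", "01:01", 0.05)]
            )
        )
        assert p.frequencies.loc["pop1", "A*01:01"] == pytest.approx(0.15)
        assert list(p.frequencies.columns) == ["A*01:01"]

    def test_sample_size_filter(self):
        rows = make_rows(
            [("big", "A", "01:01", 0.5, 200), ("small", "A", "01:01", 0.5, 50)]
        )
        p = harmonize(rows, apply_filters=True)
        assert p.populations == ["big"]
        p2 = harmonize(rows, apply_filters=False)
        assert set(p2.populations) == {"big", "small"}
        assert not p2.meta.loc["small", "passes_filters"]

    def test_idempotent(self):
        rows = make_rows(
            [("pop1", "A", "01:01", 0.4), ("pop1", "A", "02:01", 0.6)]
        )
        p1 = harmonize(rows)
        back = pd.DataFrame(
            [
                {
                    "population": pop, "region": "R", "sample_n": 100,
                    "standard": "Gold", "locus": c.split("*")[0],
                    "allele": c, "frequency": p1.frequencies.loc[pop, c],
                }
                for pop in p1.populations
                for c in p1.frequencies.columns
            ]
        )
        p2 = harmonize(back)
        pd.testing.assert_frame_equal(p1.frequencies, p2.frequencies)

    def test_bad_frequency_named(self):
        with pytest.raises(ValueError) as e:
            harmonize(make_rows([("pop1", "A", "01:01", 1.5)]))
        assert "pop1" in str(e.value)


class TestHeatmapPrep:
    def test_filters_and_adjacency(self):
        freqs = {
            "p1": {"A*01:01": 0.6, "A*02:01": 0.4, "A*03:01": 0.1},
            "p2": {"A*01:01": 0.6, "A*02:01": 0.4, "A*03:01": 0.1},
            "p3": {"A*01:01": 0.1, "A*02:01": 0.9, "A*03:01": 0.1},
            "lowsum": {"A*01:01": 0.2, "A*02:01": 0.1, "A*03:01": 0.1},
        }
        panel = panel_from_freqs(freqs)
        m, row_order, col_order = heatmap_prep(panel, var_min=0.001,
                                               pop_sum_min=0.9)
        # constant-frequency allele column removed
        assert "A*03:01" not in m.columns
        # population failing the frequency-sum filter removed
        assert "lowsum" not in m.index
        # identical populations are adjacent in the clustered order
        i1, i2 = row_order.index("p1"), row_order.index("p2")
        assert abs(i1 - i2) == 1

    def test_everything_filtered_raises(self):
        panel = panel_from_freqs({"p1": {"A*01:01": 0.5},
                                  "p2": {"A*01:01": 0.5}})
        with pytest.raises(ValueError):
            heatmap_prep(panel, var_min=0.5, pop_sum_min=0.9)


class TestGst:
    def test_identical_populations_zero(self):
        panel = panel_from_freqs(
            {"p1": {"A*01:01": 0.7, "A*02:01": 0.3},
             "p2": {"A*01:01": 0.7, "A*02:01": 0.3}}
        )
        d = gst_distance(panel, ["A"])
        assert d.loc["p1", "p2"] == 0.0

    def test_fixed_for_different_alleles(self):
        panel = panel_from_freqs(
            {"p1": {"A*01:01": 1.0, "A*02:01": 0.0},
             "p2": {"A*01:01": 0.0, "A*02:01": 1.0}}
        )
        d = gst_distance(panel, ["A"])
        assert d.loc["p1", "p2"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # p1 {0.7, 0.3}, p2 {0.3, 0.7}:
        # Hs = 1 - (0.49+0.09) = 0.42 for both; xbar = {0.5, 0.5}, Ht = 0.5
        # Gst = (0.5 - 0.42)/0.5 = 0.16
        panel = panel_from_freqs(
            {"p1": {"A*01:01": 0.7, "A*02:01": 0.3},
             "p2": {"A*01:01": 0.3, "A*02:01": 0.7}}
        )
        d = gst_distance(panel, ["A"])
        assert d.loc["p1", "p2"] == pytest.approx(0.16)

    def test_zero_iff_identical_and_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            f1 = rng.dirichlet(np.ones(4))
            f2 = rng.dirichlet(np.ones(4))
            names = [f"A*{i + 1:02d}:01" for i in range(4)]
            panel = panel_from_freqs(
                {"p1": dict(zip(names, f1)), "p2": dict(zip(names, f2))}
            )
            g = gst_distance(panel, ["A"]).loc["p1", "p2"]
            assert 0.0 <= g <= 1.0
            if np.allclose(f1, f2):
                assert g == 0.0
            else:
                assert g > 0.0

    def test_symmetry_zero_diagonal(self):
        panel = panel_from_freqs(
            {"p1": {"A*01:01": 0.7, "A*02:01": 0.3},
             "p2": {"A*01:01": 0.3, "A*02:01": 0.7},
             "p3": {"A*01:01": 0.5, "A*02:01": 0.5}}
        )
        d = gst_distance(panel, ["A"])
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)


class TestFstCorrected:
    def test_identical_equal_n_zero(self):
        panel = panel_from_freqs(
            {"p1": {"A*01:01": 0.7, "A*02:01": 0.3},
             "p2": {"A*01:01": 0.7, "A*02:01": 0.3}},
            sample_n={"p1": 50, "p2": 50},
        )
        d = fst_corrected_distance(panel, ["A"])
        assert d.loc["p1", "p2"] == 0.0  # clamped unbiased estimate

    def test_converges_to_gst_large_n(self):
        freqs = {"p1": {"A*01:01": 0.7, "A*02:01": 0.3},
                 "p2": {"A*01:01": 0.3, "A*02:01": 0.7}}
        gst = gst_distance(panel_from_freqs(freqs), ["A"]).loc["p1", "p2"]
        fst_big = fst_corrected_distance(
            panel_from_freqs(freqs, sample_n={"p1": 10**7, "p2": 10**7}),
            ["A"],
        ).loc["p1", "p2"]
        assert fst_big == pytest.approx(gst, abs=1e-5)

    def test_biallelic_toy_matches_documented_estimator(self):
        # direct arithmetic oracle for n1 = n2 = 20
        p1, p2, n = 0.7, 0.4, 20
        h1 = 2 * n / (2 * n - 1) * (1 - (p1**2 + (1 - p1) ** 2))
        h2 = 2 * n / (2 * n - 1) * (1 - (p2**2 + (1 - p2) ** 2))
        hs = (h1 + h2) / 2
        x = (p1 + p2) / 2
        ht = 1 - (x**2 + (1 - x) ** 2) + hs / (4 * n)
        expected = (ht - hs) / ht
        panel = panel_from_freqs(
            {"p1": {"A*01:01": p1, "A*02:01": 1 - p1},
             "p2": {"A*01:01": p2, "A*02:01": 1 - p2}},
            sample_n={"p1": n, "p2": n},
        )
        d = fst_corrected_distance(panel, ["A"])
        assert d.loc["p1", "p2"] == pytest.approx(expected, abs=1e-12)

    def test_missing_sample_n_errors(self):
        panel = panel_from_freqs(
            {"p1": {"A*01:01": 1.0}, "p2": {"A*01:01": 1.0}},
            sample_n={"p1": 0, "p2": 10},
        )
        with pytest.raises(ValueError):
            fst_corrected_distance(panel, ["A"])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 2, 3], [2, 0, 4], [3, 4, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = neighbor_joining(d)
        assert tree.newick() == "(A:0.5,B:1.5,C:2.5);"

    def test_additive_five_leaf_recovery(self):
        """Distances generated from a random tree are recovered exactly."""
        import dendropy

        rng = np.random.default_rng(10)
        for rep in range(5):
            bl = rng.uniform(0.3, 2.5, size=7)
            la, lb, lc, ld, le, lu, lv = bl
            paths = {
                ("A", "B"): la + lb, ("C", "D"): lc + ld,
                ("A", "C"): la + lu + lv + lc,
                ("A", "D"): la + lu + lv + ld,
                ("B", "C"): lb + lu + lv + lc,
                ("B", "D"): lb + lu + lv + ld,
                ("A", "E"): la + lu + le, ("B", "E"): lb + lu + le,
                ("C", "E"): lc + lv + le, ("D", "E"): ld + lv + le,
            }
            taxa = list("ABCDE")
            m = np.zeros((5, 5))
            for (x, y), v in paths.items():
                i, j = taxa.index(x), taxa.index(y)
                m[i, j] = m[j, i] = v
            d = pd.DataFrame(m, index=taxa, columns=taxa)
            tree = dendropy.Tree.get(
                data=neighbor_joining(d).newick(), schema="newick"
            )
            pdm = tree.phylogenetic_distance_matrix()
            for t1 in tree.taxon_namespace:
                for t2 in tree.taxon_namespace:
                    if t1.label < t2.label:
                        assert pdm.distance(t1, t2) == pytest.approx(
                            d.loc[t1.label, t2.label], abs=1e-9
                        )

    def test_label_permutation_invariance(self):
        import dendropy

        rng = np.random.default_rng(3)
        n = 6
        base = rng.uniform(1, 5, size=(n, n))
        m = (base + base.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = [f"P{i}" for i in range(n)]
        d1 = pd.DataFrame(m, index=labels, columns=labels)
        perm = rng.permutation(n)
        d2 = d1.iloc[perm, perm]
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=neighbor_joining(d1).newick(),
                               schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=neighbor_joining(d2).newick(),
                               schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(
            t1, t2
        ) == 0

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame(
            [[0, 1, 2], [9, 0, 1], [2, 1, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        with pytest.raises(ValueError):
            neighbor_joining(d)

    def test_too_few_taxa(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"),
                         columns=list("AB"), dtype=float)
        with pytest.raises(ValueError):
            neighbor_joining(d)


class TestPCA:
    def test_identical_populations_identical_scores(self):
        panel = panel_from_freqs(
            {"p1": {"A*01:01": 0.7, "A*02:01": 0.3},
             "p2": {"A*01:01": 0.7, "A*02:01": 0.3},
             "p3": {"A*01:01": 0.1, "A*02:01": 0.9}}
        )
        scores, _ = pca_scores(panel, 1)
        assert scores.loc["p1", "PC1"] == pytest.approx(
            scores.loc["p2", "PC1"]
        )

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(8)
        freqs = {
            f"p{i}": {f"A*{j + 1:02d}:01": v
                      for j, v in enumerate(rng.dirichlet(np.ones(6)))}
            for i in range(8)
        }
        _, evr = pca_scores(panel_from_freqs(freqs), 5)
        assert evr.sum() <= 1.0 + 1e-12
        assert all(a >= b - 1e-12 for a, b in zip(evr, evr[1:]))

    def test_matches_eigendecomposition_oracle(self):
        freqs = {
            "p1": {"A*01:01": 0.6, "A*02:01": 0.3, "A*03:01": 0.1},
            "p2": {"A*01:01": 0.2, "A*02:01": 0.5, "A*03:01": 0.3},
            "p3": {"A*01:01": 0.1, "A*02:01": 0.2, "A*03:01": 0.7},
        }
        panel = panel_from_freqs(freqs)
        scores, evr = pca_scores(panel, 2)
        x = panel.frequencies.to_numpy()
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for c in range(2):
            vec = v[:, c]
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
            np.testing.assert_allclose(
                scores.iloc[:, c].to_numpy(), xc @ vec, atol=1e-10
            )
        np.testing.assert_allclose(evr, w[:2] / w.sum(), atol=1e-12)

    def test_rank_truncation_warns(self, caplog):
        panel = panel_from_freqs(
            {"p1": {"A*01:01": 0.7, "A*02:01": 0.3},
             "p2": {"A*01:01": 0.3, "A*02:01": 0.7}}
        )
        with caplog.at_level("WARNING"):
            scores, _ = pca_scores(panel, 5)
        assert scores.shape[1] == 1
        assert "truncating" in caplog.text


class TestAlleleScans:
    def test_unique_alleles_disjoint_and_identical(self):
        rep = unique_alleles(
            {"A": {"01:01": 0.3}}, {"A": {"02:01": 0.3}}, ["A"]
        )
        assert rep.cohort_only == {"A*01:01": 0.3}
        assert rep.reference_only == {"A*02:01": 0.3}
        rep2 = unique_alleles(
            {"A": {"01:01": 0.3}}, {"A": {"01:01": 0.5}}, ["A"]
        )
        assert rep2.cohort_only == {} and rep2.reference_only == {}

    def test_unique_alleles_max_entry(self):
        rep = unique_alleles(
            {"A": {"01:01": 0.10, "03:02": 0.02}},
            {"A": {"01:01": 0.2}},
            ["A"],
        )
        assert rep.cohort_only == {"A*03:02": 0.02}
        assert rep.cohort_max == ("A*03:02", 0.02)

    def test_rare_absent_scan(self):
        panel = panel_from_freqs(
            {"p1": {"A*01:01": 0.5, "A*05:01": 0.04},
             "p2": {"A*01:01": 0.5, "A*05:01": 0.0}}
        )
        cohort = {
            "A": {"01:01": 0.5, "02:07": 0.001, "03:09": 0.01,
                  "05:01": 0.001}
        }
        hits = rare_absent_scan(cohort, panel, af_max=0.003)
        # 02:07 is rare and absent -> listed; 03:09 fails the AF bound;
        # 05:01 is present in the panel -> excluded
        assert hits == [("A*02:07", 0.001)]
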