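import itertools

import numpy as np
import pandas as pd
import pytest

from cophylochem.chem_similarity import (Chemogram, CompoundTable,
                                         SimilarityMatrix, Spectrum,
                                         SpectrumSet, build_chemogram,
                                         build_compound_similarity,
                                         chemogram_to_distance,
                                         classify_compound,
                                         combine_class_matrices,
                                         match_shared_compounds,
                                         modified_cosine, read_feature_csv,
                                         read_mgf, species_similarity,
                                         species_similarity_matrix, write_mgf)


class TestClassify:
    @pytest.mark.parametrize("mz,rt,expected", [
        (600, 20, "saponin"),
        (500, 20, "phenolic"),   # heavy enough RT but light ion
        (600, 18, "phenolic"),   # boundary: rule is strict
        (580, 20, "phenolic"),
        (600.001, 18.001, "saponin"),
    ])
    def test_rule(self, mz, rt, expected):
        assert classify_compound(mz, rt) == expected


def _table(rows):
    df = pd.DataFrame(rows).set_index("compound")
    return CompoundTable(df)


class TestMatching:
    def _mini(self, specs):
        rows = [{"compound": f"c{i}", "mz": mz, "rt": rt, "cls": "phenolic",
                 "sp": 1.0} for i, (mz, rt) in enumerate(specs)]
        return _table(rows)

    def test_identical_tables_match_perfectly(self):
        t = self._mini([(200.0, 5.0), (300.0, 6.0)])
        pairs = match_shared_compounds(t, t)
        assert sorted(pairs) == [("c0", "c0"), ("c1", "c1")]

    def test_outside_tolerance_unmatched(self):
        a = self._mini([(200.00, 5.0)])
        b = self._mini([(200.02, 5.0)])
        assert match_shared_compounds(a, b, mz_tol=0.01) == []

    def test_greedy_matches_min_cost_assignment_on_small_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            mz_a = rng.uniform(200, 200.05, 3)
            mz_b = rng.uniform(200, 200.05, 3)
            a = self._mini([(m, 5.0) for m in mz_a])
            b = self._mini([(m, 5.0) for m in mz_b])
            pairs = match_shared_compounds(a, b, mz_tol=0.05, rt_tol=1.0)
            # oracle: exhaustive assignment minimizing total |dmz|,
            # restricted to within-tolerance pairs, maximal cardinality
            best = None
            for perm in itertools.permutations(range(3)):
                cand = [(i, j) for i, j in enumerate(perm)
                        if abs(mz_a[i] - mz_b[j]) <= 0.05]
                cost = sum(abs(mz_a[i] - mz_b[j]) for i, j in cand)
                key = (-len(cand), cost)
                if best is None or key < best[0]:
                    best = (key, cand)
            assert len(pairs) == len(best[1])


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        s = Spectrum(400.0, [[100.0, 5.0], [150.0, 2.0], [200.0, 1.0]])
        assert modified_cosine(s, s) == pytest.approx(1.0)

    def test_disjoint_fragments_equal_precursor(self):
        a = Spectrum(400.0, [[100.0, 1.0], [150.0, 1.0]])
        b = Spectrum(400.0, [[120.0, 1.0], [170.0, 1.0]])
        assert modified_cosine(a, b, frag_tol=0.02) == 0.0

    def test_single_shared_peak_of_two_equal_peaks(self):
        # sqrt intensities normalized: each peak weight 1/sqrt(2);
        # one match contributes exactly 0.5
        a = Spectrum(400.0, [[100.0, 1.0], [150.0, 1.0]])
        b = Spectrum(400.0, [[100.0, 1.0], [180.0, 1.0]])
        assert modified_cosine(a, b) == pytest.approx(0.5)

    def test_precursor_shifted_match(self):
        # fragments offset exactly by the precursor delta count as matches
        a = Spectrum(400.0, [[100.0, 1.0]])
        b = Spectrum(410.0, [[110.0, 1.0]])
        assert modified_cosine(a, b) == pytest.approx(1.0)

    def test_matches_exhaustive_matching_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            prec_a, prec_b = 400.0, 400.0 + rng.uniform(-5, 5)
            pa = np.column_stack([rng.uniform(100, 300, 3),
                                  rng.uniform(0.5, 3.0, 3)])
            pb = np.column_stack([pa[:, 0] + rng.choice([0.0, 0.005, 1.7], 3),
                                  rng.uniform(0.5, 3.0, 3)])
            a, b = Spectrum(prec_a, pa), Spectrum(prec_b, pb)
            got = modified_cosine(a, b, frag_tol=0.02)
            # oracle: best score over all one-to-one peak matchings
            wa = np.sqrt(pa[:, 1]) / np.linalg.norm(np.sqrt(pa[:, 1]))
            wb = np.sqrt(pb[:, 1]) / np.linalg.norm(np.sqrt(pb[:, 1]))
            shift = prec_a - prec_b
            best = 0.0
            for k in range(4):
                for ia in itertools.permutations(range(3), k):
                    for ib in itertools.permutations(range(3), k):
                        ok = all(abs(pa[x, 0] - pb[y, 0]) <= 0.02
                                 or abs(pa[x, 0] - pb[y, 0] - shift) <= 0.02
                                 for x, y in zip(ia, ib))
                        if ok:
                            best = max(best, sum(wa[x] * wb[y]
                                                 for x, y in zip(ia, ib)))
            # greedy is optimal or near-optimal on these tiny spectra
            assert got <= best + 1e-12
            assert got >= best - 0.05

    def test_agrees_with_independent_reference_implementation(self):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(4)
        for _ in range(10):
            prec_a, prec_b = 500.0, 500.0 + rng.uniform(-20, 20)
            na, nb = rng.integers(3, 8), rng.integers(3, 8)
            pa = np.column_stack([np.sort(rng.uniform(100, 450, na)),
                                  rng.uniform(0.2, 5.0, na)])
            pb = np.column_stack([np.sort(rng.uniform(100, 450, nb)),
                                  rng.uniform(0.2, 5.0, nb)])
            # plant some direct and shifted matches
            pb[0, 0] = pa[0, 0]
            pb[1, 0] = min(pa[1, 0] + (prec_a - prec_b), 450.0)
            ours = modified_cosine(Spectrum(prec_a, pa), Spectrum(prec_b, pb),
                                   frag_tol=0.02)
            sa = matchms.Spectrum(mz=pa[:, 0].copy(),
                                  intensities=np.sqrt(pa[:, 1]),
                                  metadata={"precursor_mz": prec_a},
                                  metadata_harmonization=False)
            sb = matchms.Spectrum(mz=np.sort(pb[:, 0]).copy(),
                                  intensities=np.sqrt(pb[:, 1][np.argsort(pb[:, 0])]),
                                  metadata={"precursor_mz": prec_b},
                                  metadata_harmonization=False)
            ref = float(ModifiedCosine(tolerance=0.02).pair(sa, sb)["score"])
            assert ours == pytest.approx(ref, abs=1e-6)


class TestCompoundSimilarityMatrix:
    def _spectra(self):
        peaks = [[100.0, 1.0], [150.0, 1.0]]
        return SpectrumSet({f"c{i}": Spectrum(400.0, peaks) for i in range(3)})

    def test_identical_spectra_all_ones(self):
        eps = build_compound_similarity(self._spectra())
        assert np.allclose(eps.values, 1.0)

    def test_floor_zeroes_weak_pairs(self):
        a = Spectrum(400.0, [[100.0, 1.0], [150.0, 1.0], [200.0, 1.0],
                             [250.0, 1.0], [300.0, 1.0]])
        b = Spectrum(400.0, [[100.0, 1.0], [151.0, 1.0], [201.0, 1.0],
                             [251.0, 1.0], [301.0, 1.0]])
        raw = modified_cosine(a, b)
        assert raw == pytest.approx(0.2)  # one shared of five equal peaks
        eps = build_compound_similarity(SpectrumSet({"a": a, "b": b}),
                                        score_floor=0.25)
        assert eps.get("a", "b") == 0.0

    def test_missing_spectrum_scores_zero_off_diagonal(self):
        eps = build_compound_similarity(self._spectra(),
                                        compounds=["c0", "c1", "c2", "c3"])
        assert eps.get("c3", "c0") == 0.0 and eps.get("c3", "c3") == 1.0


class TestSpeciesSimilarity:
    def _fixture(self, eps_12=0.0):
        t = _table([
            {"compound": "c1", "mz": 200.0, "rt": 5.0, "cls": "phenolic",
             "A": 1.0, "B": 0.5},
            {"compound": "c2", "mz": 300.0, "rt": 6.0, "cls": "phenolic",
             "A": 0.0, "B": 0.5},
        ])
        E = np.array([[1.0, eps_12], [eps_12, 1.0]])
        return t, SimilarityMatrix(["c1", "c2"], E)

    def test_hand_computed_case(self):
        # raw(A,B)=0.5, raw(A,A)=1, raw(B,B)=0.5 -> S = 0.5
        t, eps = self._fixture(0.0)
        assert species_similarity(t, eps, "A", "B") == pytest.approx(0.5)

    def test_identical_profiles(self):
        t = _table([{"compound": "c1", "mz": 200.0, "rt": 5.0,
                     "cls": "phenolic", "A": 0.3, "B": 0.3},
                    {"compound": "c2", "mz": 300.0, "rt": 6.0,
                     "cls": "phenolic", "A": 0.7, "B": 0.7}])
        eps = SimilarityMatrix(["c1", "c2"], np.eye(2))
        assert species_similarity(t, eps, "A", "B") == pytest.approx(1.0)

    def test_disjoint_profiles_zero(self):
        t = _table([{"compound": "c1", "mz": 200.0, "rt": 5.0,
                     "cls": "phenolic", "A": 1.0, "B": 0.0},
                    {"compound": "c2", "mz": 300.0, "rt": 6.0,
                     "cls": "phenolic", "A": 0.0, "B": 1.0}])
        eps = SimilarityMatrix(["c1", "c2"], np.eye(2))
        assert species_similarity(t, eps, "A", "B") == 0.0

    def test_monotone_in_cross_compound_similarity(self):
        t, _ = self._fixture()
        vals = [species_similarity(t, self._fixture(e)[1], "A", "B")
                for e in (0.0, 0.3, 0.6, 0.9)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_duplicate_split_invariance(self):
        # splitting c1 into two identical halves with eps=1 between them
        t1 = _table([{"compound": "c1", "mz": 200.0, "rt": 5.0,
                      "cls": "phenolic", "A": 1.0, "B": 0.5},
                     {"compound": "c2", "mz": 300.0, "rt": 6.0,
                      "cls": "phenolic", "A": 0.0, "B": 0.5}])
        e1 = SimilarityMatrix(["c1", "c2"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        t2 = _table([{"compound": "c1a", "mz": 200.0, "rt": 5.0,
                      "cls": "phenolic", "A": 0.5, "B": 0.25},
                     {"compound": "c1b", "mz": 200.0, "rt": 5.0,
                      "cls": "phenolic", "A": 0.5, "B": 0.25},
                     {"compound": "c2", "mz": 300.0, "rt": 6.0,
                      "cls": "phenolic", "A": 0.0, "B": 0.5}])
        E2 = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        e2 = SimilarityMatrix(["c1a", "c1b", "c2"], E2)
        s1 = species_similarity(t1, e1, "A", "B")
        s2 = species_similarity(t2, e2, "A", "B")
        assert s2 == pytest.approx(s1, abs=1e-12)

    def test_matrix_agrees_with_pairwise_and_double_sum(self):
        rng = np.random.default_rng(7)
        n_c, n_sp = 6, 4
        ab = rng.dirichlet(np.ones(n_c), size=n_sp).T
        E = np.clip(rng.uniform(0, 1, (n_c, n_c)), 0, 1)
        E = 0.5 * (E + E.T)
        np.fill_diagonal(E, 1.0)
        rows = []
        for i in range(n_c):
            row = {"compound": f"c{i}", "mz": 200.0 + i, "rt": 5.0,
                   "cls": "phenolic"}
            row.update({f"sp{j}": ab[i, j] for j in range(n_sp)})
            rows.append(row)
        t = _table(rows)
        eps = SimilarityMatrix([f"c{i}" for i in range(n_c)], E)
        S = species_similarity_matrix(t, eps)
        for x in range(n_sp):
            for y in range(x + 1, n_sp):
                # oracle: explicit double sum
                raw = {}
                for u, v in [(x, y), (x, x), (y, y)]:
                    raw[(u, v)] = sum(ab[i, u] * ab[j, v] * E[i, j]
                                      for i in range(n_c) for j in range(n_c))
                expect = raw[(x, y)] / max(raw[(x, x)], raw[(y, y)])
                assert S.values[x, y] == pytest.approx(expect, abs=1e-12)
                assert S.values[x, y] == pytest.approx(
                    species_similarity(t, eps, f"sp{x}", f"sp{y}"), abs=1e-12)


class TestCombine:
    def _sim(self, vals):
        return SimilarityMatrix(["A", "B"], np.array([[1.0, vals], [vals, 1.0]]))

    def test_equal_matrices_unchanged(self):
        out = combine_class_matrices([self._sim(0.4), self._sim(0.4)])
        assert out.get("A", "B") == pytest.approx(0.4)

    def test_two_classes_average(self):
        out = combine_class_matrices([self._sim(1.0), self._sim(0.0)])
        assert out.get("A", "B") == pytest.approx(0.5)

    def test_equal_tyrosine_gives_all_ones_third_matrix(self):
        out = combine_class_matrices([self._sim(0.0)], tyrosine={"A": 5.0, "B": 5.0})
        # mean of [0, 1] = 0.5
        assert out.get("A", "B") == pytest.approx(0.5)

    def test_species_mismatch_rejected(self):
        other = SimilarityMatrix(["A", "C"], np.eye(2))
        with pytest.raises(ValueError, match="different species"):
            combine_class_matrices([self._sim(0.1), other])


class TestChemogram:
    def _block_table(self, n_per=3, n_comp=4):
        """Two clades with private, internally identical compounds."""
        rows = []
        species = [f"s{i}" for i in range(2 * n_per)]
        for c in range(2 * n_comp):
            clade = c < n_comp
            row = {"compound": f"c{c}", "mz": 200.0 + 10 * c, "rt": 5.0,
                   "cls": "phenolic"}
            for i, sp in enumerate(species):
                row[sp] = (1.0 / n_comp) if (i < n_per) == clade else 0.0
            rows.append(row)
        t = _table(rows)
        E = np.zeros((2 * n_comp, 2 * n_comp))
        E[:n_comp, :n_comp] = 1.0
        E[n_comp:, n_comp:] = 1.0
        eps = SimilarityMatrix([f"c{c}" for c in range(2 * n_comp)], E)
        return t, eps, species

    def test_block_structure_gets_full_support(self):
        t, eps, species = self._block_table()
        chem = build_chemogram(table=t, eps=eps, n_boot=50, seed=0)
        left = frozenset(species[:3])
        right = frozenset(species[3:])
        assert chem.supports[left] == 1.0
        assert chem.supports[right] == 1.0

    def test_single_bootstrap_supports_are_binary(self):
        t, eps, _ = self._block_table()
        chem = build_chemogram(table=t, eps=eps, n_boot=1, seed=1)
        assert set(chem.supports.values()) <= {0.0, 1.0}

    def test_needs_three_species(self):
        S = SimilarityMatrix(["A", "B"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        with pytest.raises(ValueError, match="3 species"):
            build_chemogram(similarity=S)

    def test_cophenetic_matches_lca_height_oracle(self):
        t, eps, species = self._block_table()
        chem = build_chemogram(table=t, eps=eps)
        D = chemogram_to_distance(chem)
        # oracle: walk the linkage to find the merge height of each pair
        from scipy.cluster.hierarchy import cut_tree

        Z = chem.linkage_matrix
        n = len(species)
        for i in range(n):
            for j in range(i + 1, n):
                h = None
                members = {k: {k} for k in range(n)}
                for step, (a, b, height, _) in enumerate(Z):
                    merged = members[int(a)] | members[int(b)]
                    members[n + step] = merged
                    if h is None and i in merged and j in merged:
                        h = height
                assert D.values[i, j] == pytest.approx(h)

    def test_ultrametric_tree_conversion(self):
        t, eps, _ = self._block_table()
        chem = build_chemogram(table=t, eps=eps)
        tree = chem.to_tree()
        assert tree.is_ultrametric(rel_tol=1e-8)


def test_mgf_round_trip(tmp_path):
    spectra = SpectrumSet({
        "cA": Spectrum(400.5, [[100.1, 3.0], [200.2, 1.5]]),
        "cB": Spectrum(650.0, [[320.7, 2.0]]),
    })
    write_mgf(spectra, tmp_path / "s.mgf")
    back = read_mgf(tmp_path / "s.mgf")
    assert set(back.compound_ids) == {"cA", "cB"}
    np.testing.assert_allclose(back["cA"].peaks, spectra["cA"].peaks)
    assert back["cB"].precursor_mz == pytest.approx(650.0)


def test_feature_csv_round_trip_with_class_rule(tmp_path):
    df = pd.DataFrame({
        "compound": ["c1", "c2"], "mz": [600.0, 500.0], "rt": [20.0, 20.0],
        "spA": [0.6, 0.4], "spB": [0.1, 0.9],
    })
    df.to_csv(tmp_path / "f.csv", index=False)
    table = read_feature_csv(tmp_path / "f.csv")
    assert list(table.df["cls"]) == ["saponin", "phenolic"]
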