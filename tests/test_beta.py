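import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gradcomm.beta import (
    Dendrogram,
    baselga_multisite,
    baselga_pair,
    carvalho_multisite,
    carvalho_pair,
    distance_decay,
    turnover_fraction,
    upgma,
)
from gradcomm.data_model import IncidenceMatrix
from gradcomm.datasets import nui_chua
from gradcomm.errors import InputError, ParameterError
from gradcomm.similarity import PairCounts, pair_counts
from gradcomm.synthetic import generate_gradient_community, nui_chua_default_config

from conftest import make_table, random_incidence


def sets_to_matrix(sets):
    species = sorted(set().union(*sets))
    cells = np.array([[1 if s in ss else 0 for ss in sets] for s in species], dtype=np.int8)
    return IncidenceMatrix(species, [f"u{i}" for i in range(len(sets))], cells)


class TestBaselgaPair:
    def test_identical(self):
        d = baselga_pair(PairCounts(5, 0, 0))
        assert (d.total, d.turnover, d.nestedness_or_richness) == (0.0, 0.0, 0.0)

    def test_pure_nestedness(self):
        d = baselga_pair(PairCounts(5, 0, 5))
        assert d.turnover == 0.0
        assert d.total == pytest.approx(1 / 3)
        assert d.nestedness_or_richness == pytest.approx(1 / 3)

    def test_hand_value(self):
        # a=9, b=14, c=43: derived from richness 23 vs 52 with 9 shared
        d = baselga_pair(PairCounts(9, 14, 43))
        assert d.total == pytest.approx(0.760, abs=5e-4)
        assert d.turnover == pytest.approx(0.609, abs=5e-4)
        assert d.nestedness_or_richness == pytest.approx(0.151, abs=5e-4)
        # cross-check: total = 1 - printed Sørensen similarity 0.240
        assert d.total == pytest.approx(1 - 0.240, abs=5e-4)

    def test_empty_pair(self):
        with pytest.raises(InputError):
            baselga_pair(PairCounts(0, 0, 0))


class TestCarvalhoPair:
    def test_hand_value(self):
        d = carvalho_pair(PairCounts(9, 14, 43))
        assert d.total == pytest.approx(0.864, abs=5e-4)
        assert d.turnover == pytest.approx(0.424, abs=5e-4)
        assert d.nestedness_or_richness == pytest.approx(0.439, abs=5e-4)

    def test_equal_richness_no_richness_component(self):
        d = carvalho_pair(PairCounts(4, 3, 3))
        assert d.nestedness_or_richness == 0.0

    def test_identical(self):
        d = carvalho_pair(PairCounts(5, 0, 0))
        assert (d.total, d.turnover, d.nestedness_or_richness) == (0.0, 0.0, 0.0)

    def test_sorensen_family(self):
        d = carvalho_pair(PairCounts(2, 1, 3), family="sorensen")
        assert d.total == pytest.approx(4 / 8)
        assert d.family == "carvalho_sorensen"


class TestAdditivityProperty:
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=300, deadline=None)
    def test_exact_additivity_all_families(self, a, b, c):
        if a + b + c == 0:
            return
        for d in (
            baselga_pair(PairCounts(a, b, c)),
            carvalho_pair(PairCounts(a, b, c)),
            carvalho_pair(PairCounts(a, b, c), family="sorensen"),
        ):
            assert d.total == pytest.approx(d.turnover + d.nestedness_or_richness, abs=1e-12)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=200, deadline=None)
    def test_jaccard_total_geq_sorensen_total(self, a, b, c):
        if a + b + c == 0:
            return
        assert (
            carvalho_pair(PairCounts(a, b, c)).total
            >= baselga_pair(PairCounts(a, b, c)).total - 1e-12
        )

    def test_nested_pairs_have_zero_turnover(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 20))
            k = int(rng.integers(1, n + 1))
            big = set(range(n))
            small = set(rng.choice(n, size=k, replace=False).tolist())
            d = baselga_pair(pair_counts(small, big))
            assert d.turnover == 0.0


class TestBaselgaMultisite:
    def test_two_sites_reduces_to_pair(self, rng):
        X = random_incidence(rng, 10, 2)
        pc = pair_counts(X.species_set("u0"), X.species_set("u1"))
        dm = baselga_multisite(X)
        dp = baselga_pair(pc)
        assert dm.total == pytest.approx(dp.total)
        assert dm.turnover == pytest.approx(dp.turnover)

    def test_identical_sites(self):
        X = sets_to_matrix([{"a", "b"}, {"a", "b"}, {"a", "b"}])
        d = baselga_multisite(X)
        assert (d.total, d.turnover, d.nestedness_or_richness) == (0.0, 0.0, 0.0)

    def test_three_site_toy(self):
        # sites {A,B}, {B,C}, {C,A}: sum_min = sum_max = 3, core = 3
        X = sets_to_matrix([{"A", "B"}, {"B", "C"}, {"C", "A"}])
        d = baselga_multisite(X)
        assert d.total == pytest.approx(0.5)
        assert d.turnover == pytest.approx(0.5)
        assert d.nestedness_or_richness == pytest.approx(0.0)

    def test_brute_force_oracle(self, rng):
        for _ in range(20):
            X = random_incidence(rng, 10, int(rng.integers(3, 7)))
            sets = [X.species_set(u) for u in X.units]
            smin = smax = 0
            for x, y in itertools.combinations(sets, 2):
                bij, bji = len(x - y), len(y - x)
                smin += min(bij, bji)
                smax += max(bij, bji)
            core = sum(len(s) for s in sets) - len(set().union(*sets))
            d = baselga_multisite(X)
            assert d.turnover == pytest.approx(smin / (core + smin) if core + smin else 0.0)
            assert d.total == pytest.approx(
                (smin + smax) / (2 * core + smin + smax) if (2 * core + smin + smax) else 0.0
            )

    def test_carvalho_multisite_is_mean_of_pairs(self, rng):
        X = random_incidence(rng, 10, 4)
        sets = [X.species_set(u) for u in X.units]
        parts = [carvalho_pair(pair_counts(x, y)) for x, y in itertools.combinations(sets, 2)]
        d = carvalho_multisite(X)
        assert d.total == pytest.approx(np.mean([p.total for p in parts]))
        assert d.total == pytest.approx(d.turnover + d.nestedness_or_richness, abs=1e-12)


class TestTurnoverFraction:
    def test_derived_value(self):
        d = baselga_pair(PairCounts(9, 14, 43))
        assert turnover_fraction(d) == pytest.approx(0.801, abs=2e-3)

    def test_pure_nestedness_zero(self):
        assert turnover_fraction(baselga_pair(PairCounts(5, 0, 5))) == 0.0

    def test_pure_turnover_one(self):
        assert turnover_fraction(baselga_pair(PairCounts(3, 4, 4))) == pytest.approx(1.0)

    def test_zero_total_errors(self):
        with pytest.raises(ParameterError):
            turnover_fraction(baselga_pair(PairCounts(5, 0, 0)))


class TestUpgma:
    def test_two_leaves(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        dend = upgma(D, ["a", "b"])
        assert dend.merges == [(0, 1, 0.4)]
        assert dend.to_newick() == "(a:0.2,b:0.2);"

    def test_non_symmetric_rejected(self):
        with pytest.raises(ParameterError):
            upgma(np.array([[0.0, 1.0], [0.5, 0.0]]), ["a", "b"])

    def test_first_merge_on_published_similarity(self):
        paths = ["AH", "DD", "MN", "NO", "ST"]
        D = np.zeros((5, 5))
        for (a, b), s in nui_chua.SORENSEN_BY_PATH_PAIR.items():
            i, j = paths.index(a), paths.index(b)
            D[i, j] = D[j, i] = 1.0 - s
        dend = upgma(D, paths)
        assert set(dend.first_merge_leaves()) == {"NO", "ST"}

    def test_ultrametric_input_reproduced_by_cophenetic(self):
        # build an ultrametric matrix from a known tree:
        # ((a,b):h1, (c,d):h2) joined at h3
        h1, h2, h3 = 0.2, 0.3, 0.8
        D = np.zeros((4, 4))
        labels = ["a", "b", "c", "d"]
        D[0, 1] = D[1, 0] = h1
        D[2, 3] = D[3, 2] = h2
        for i in (0, 1):
            for j in (2, 3):
                D[i, j] = D[j, i] = h3
        dend = upgma(D, labels)
        assert np.allclose(dend.cophenetic(), D)

    def test_textbook_oracle_random_matrices(self, rng):
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        for _ in range(15):
            n = int(rng.integers(3, 9))
            M = rng.random((n, n))
            D = (M + M.T) / 2.0
            np.fill_diagonal(D, 0.0)
            dend = upgma(D, [f"l{i}" for i in range(n)])
            Z = average(squareform(D, checks=False))
            coph = squareform(cophenet(Z))
            assert np.allclose(squareform(dend.cophenetic(), checks=False),
                               squareform(coph, checks=False))

    def test_heights_non_decreasing(self, rng):
        for _ in range(10):
            n = 6
            M = rng.random((n, n))
            D = (M + M.T) / 2.0
            np.fill_diagonal(D, 0.0)
            dend = upgma(D)
            heights = [h for _, _, h in dend.merges]
            assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))


class TestDistanceDecay:
    @staticmethod
    def _line_table(n_units=4, window=8, step=2):
        """Localities on the equator; Sørensen decays exactly linearly."""
        rows = []
        for i in range(n_units):
            for k in range(window):
                rows.append(
                    dict(
                        species=f"sp{i * step + k}",
                        locality=f"L{i}",
                        path="L",
                        lat=0.0,
                        lon=0.1 * i,
                        elevation=10.0,
                    )
                )
        return make_table(rows)

    def test_exact_linear_decay_recovered(self):
        table = self._line_table()
        dd = distance_decay(table, "h1")
        # shared species between units i,j: window - step*|i-j| ->
        # Sørensen = 1 - (step/window)*|i-j|; distance = |i-j| * 11.1195 km
        km_per_step = 0.1 * np.pi * 6371.0088 / 180.0
        expected_slope = -(2 / 8) / km_per_step
        assert dd.slope == pytest.approx(expected_slope, rel=1e-9)
        assert dd.intercept == pytest.approx(1.0, rel=1e-9)

    def test_identical_compositions_slope_zero(self):
        rows = []
        for i in range(4):
            for sp in ("A", "B"):
                rows.append(dict(species=sp, locality=f"L{i}", path="L",
                                 lat=0.0, lon=0.05 * i, elevation=10.0))
        dd = distance_decay(make_table(rows), "h1")
        assert dd.slope == pytest.approx(0.0, abs=1e-12)
        assert all(s == 1.0 for *_x, s in dd.pairs)

    def test_generator_output_negative_slope(self):
        negatives = 0
        for seed in range(5):
            cfg = nui_chua_default_config(seed=seed)
            table, _ = generate_gradient_community(cfg)
            dd = distance_decay(table, "bptp")
            negatives += dd.slope < 0
        assert negatives >= 4

    def test_identical_distances_error(self):
        rows = [
            dict(species="A", locality="L1", lat=0.0, lon=0.0, elevation=10.0),
            dict(species="B", locality="L2", lat=0.0, lon=0.1, elevation=10.0),
            dict(species="C", locality="L3", lat=0.0, lon=0.1, elevation=10.0),
        ]
        # L2 and L3 coincide; distances L1-L2 == L1-L3 but L2-L3 = 0, so fit works;
        # collapse all three to force the error
        rows2 = [dict(r, lon=0.0) for r in rows]
        with pytest.raises(InputError):
            distance_decay(make_table(rows2), "h1")
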