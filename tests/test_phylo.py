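"""Presence matrices, clade classification, pITH, Hamming/NJ trees and the
sector-subsampling statistics."""

import io as std_io

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonarch import phylo
from clonarch.phylo import (
    PresenceMatrix,
    build_presence_matrix,
    burden_gain,
    classify_mutations,
    compute_pith,
    hamming_distances,
    neighbor_joining,
    subsample_trunk_ratio,
)
from conftest import (
    exhaustive_burden_gain_stats,
    exhaustive_trunk_stats,
    make_variant,
    random_additive_tree,
    random_presence_matrix,
)


def pm(data, sectors=None, patient="P1"):
    arr = np.asarray(data, dtype=bool)
    df = pd.DataFrame(
        arr,
        index=[f"m{i}" for i in range(arr.shape[0])],
        columns=sectors or [f"S{j}" for j in range(arr.shape[1])],
    )
    return PresenceMatrix(patient_id=patient, matrix=df)


class TestBuildMatrix:
    def test_presence_follows_validation(self):
        recs = [
            make_variant(sector_id=s, assay="deepseq", pos=100) for s in ("S1", "S2")
        ] + [make_variant(sector_id="S3", assay="deepseq", pos=100, t_alt=0, t_ref=100)]
        m = build_presence_matrix(
            recs, sectors=["S1", "S2", "S3"], present=lambda v: v.t_alt > 0
        )
        assert m.matrix.values.tolist() == [[True, True, False]]

    def test_mutation_failing_everywhere_has_no_row(self):
        recs = [make_variant(sector_id=s, assay="deepseq") for s in ("S1", "S2")]
        m = build_presence_matrix(recs, present=lambda v: False)
        assert m.n_mutations == 0

    def test_hand_built_five_by_three(self):
        recs = []
        truth = {
            100: {"S1", "S2", "S3"},
            200: {"S1"},
            300: {"S2", "S3"},
            400: {"S3"},
            500: {"S1", "S2", "S3"},
        }
        for pos, carriers in truth.items():
            for s in ("S1", "S2", "S3"):
                recs.append(
                    make_variant(pos=pos, sector_id=s, assay="deepseq",
                                 t_alt=50 if s in carriers else 0,
                                 t_ref=50 if s in carriers else 100)
                )
        m = build_presence_matrix(recs, sectors=["S1", "S2", "S3"],
                                  present=lambda v: v.t_alt > 0)
        expected = pd.DataFrame(
            {pos: [s in c for s in ("S1", "S2", "S3")] for pos, c in truth.items()}
        ).T
        assert (m.matrix.values == expected.values).all()

    def test_fewer_than_two_sectors_is_an_error(self):
        with pytest.raises(ValueError, match=">=2 sectors"):
            build_presence_matrix([make_variant(assay="deepseq")], sectors=["S1"])


class TestClassifyAndPith:
    def test_trunk_branch_private_labels(self):
        m = pm([[1, 1, 1, 1], [1, 0, 0, 0], [1, 1, 0, 0]])
        c = classify_mutations(m)
        assert list(c.labels) == ["trunk", "private", "branch"]
        assert (c.n_trunk, c.n_branch, c.n_private) == (1, 1, 1)

    def test_counts_on_twelve_row_matrix(self):
        rows = [[1, 1, 1]] * 6 + [[1, 1, 0]] * 4 + [[0, 0, 1]] * 2
        c = classify_mutations(pm(rows))
        assert (c.n_trunk, c.n_branch, c.n_private) == (6, 4, 2)
        assert compute_pith(c) == pytest.approx(50.0)

    def test_pith_extremes_and_missing(self):
        assert compute_pith(classify_mutations(pm([[1, 1]] * 4))) == 0.0
        assert compute_pith(classify_mutations(pm([[1, 0]] * 4))) == 100.0
        empty = pm(np.zeros((0, 2)))
        assert compute_pith(classify_mutations(empty)) is None


@settings(derandomize=True, max_examples=100, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_pith_plus_trunk_percent_is_exactly_100(seed):
    rng = np.random.default_rng(seed)
    df = random_presence_matrix(rng, n_mut=int(rng.integers(1, 40)),
                                n_sectors=int(rng.integers(2, 8)))
    c = classify_mutations(PresenceMatrix("P", df))
    pith = compute_pith(c)
    trunk_pct = 100.0 * c.n_trunk / c.total
    assert pith + trunk_pct == pytest.approx(100.0, abs=1e-12)


class TestHamming:
    def test_identical_sectors_distance_zero_and_normal_is_burden(self):
        m = pm([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        labels, d = hamming_distances(m, include_normal=True)
        i, j, k, n = (labels.index(x) for x in ("S0", "S1", "S2", "normal"))
        assert d[i, j] == 0
        assert d[i, n] == 2  # S0 carries 2 mutations
        assert d[k, n] == 1

    def test_two_discordant_mutations_give_distance_two(self):
        m = pm([[1, 1], [1, 0], [0, 1]])
        labels, d = hamming_distances(m, include_normal=False)
        assert d[0, 1] == 2

    def test_triangle_inequality(self, rng):
        for _ in range(20):
            df = random_presence_matrix(rng, 25, 5)
            _, d = hamming_distances(PresenceMatrix("P", df))
            n = d.shape[0]
            for a in range(n):
                for b in range(n):
                    for c in range(n):
                        assert d[a, b] <= d[a, c] + d[c, b] + 1e-9


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # leaf edge lengths a,b,c give d = [[0,a+b,a+c],[...,0,b+c],...]
        a, b, c = 1.0, 2.0, 5.0
        d = np.array([[0, a + b, a + c], [a + b, 0, b + c], [a + c, b + c, 0]])
        tree = neighbor_joining(["A", "B", "C"], d)
        lengths = {t.name: t.length for t in tree.tips()}
        # tip-to-tip path lengths must reproduce the input exactly
        assert tree.find("A").distance(tree.find("B")) == pytest.approx(a + b)
        assert tree.find("A").distance(tree.find("C")) == pytest.approx(a + c)
        assert tree.find("B").distance(tree.find("C")) == pytest.approx(b + c)
        assert lengths["A"] == pytest.approx(a)

    def test_all_zero_distances_give_zero_length_star(self):
        tree = neighbor_joining(["A", "B", "C"], np.zeros((3, 3)))
        assert all((t.length or 0.0) == 0.0 for t in tree.tips())

    def test_additive_matrix_recovers_topology_vs_reference_nj(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            true_newick, labels, dist = random_additive_tree(rng, n)
            ours = neighbor_joining(labels, dist)

            tns = dendropy.TaxonNamespace()
            t_true = dendropy.Tree.get(data=true_newick, schema="newick",
                                       taxon_namespace=tns)
            t_ours = dendropy.Tree.get(data=str(ours), schema="newick",
                                       taxon_namespace=tns)
            rf = dendropy.calculate.treecompare.symmetric_difference(t_true, t_ours)
            assert rf == 0

            # independent reference NJ implementation agrees too
            csv = "," + ",".join(labels) + "\n" + "\n".join(
                labels[i] + "," + ",".join(str(x) for x in dist[i]) for i in range(n)
            )
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                std_io.StringIO(csv), taxon_namespace=tns, delimiter=","
            )
            t_ref = pdm.nj_tree()
            rf_ref = dendropy.calculate.treecompare.symmetric_difference(t_ref, t_ours)
            assert rf_ref == 0


class TestSubsampling:
    def test_k_equals_n_matches_full_matrix(self):
        m = pm([[1, 1, 1]] * 3 + [[1, 0, 1]] * 2 + [[0, 1, 0]])
        r = subsample_trunk_ratio(m, k=3, n_iter=5, seed=0)
        assert r == pytest.approx(3 / 6)

    def test_all_trunk_matrix(self):
        m = pm([[1, 1, 1, 1]] * 5)
        assert subsample_trunk_ratio(m, 2, seed=0) == 1.0
        assert burden_gain(m, 3, seed=0) == 0.0

    def test_k_out_of_range(self):
        m = pm([[1, 1]])
        with pytest.raises(ValueError):
            subsample_trunk_ratio(m, 3)
        with pytest.raises(ValueError):
            burden_gain(m, 5)

    def test_k1_burden_gain_is_zero(self):
        m = pm([[1, 0], [0, 1]])
        assert burden_gain(m, k=1) == 0.0

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        for _ in range(5):
            df = random_presence_matrix(rng, n_mut=25,
                                        n_sectors=int(rng.integers(4, 7)))
            m = PresenceMatrix("P", df)
            for k in (2, 3):
                n_iter = 60
                mu, sd = exhaustive_trunk_stats(df, k)
                est = subsample_trunk_ratio(m, k, n_iter=n_iter, rng=rng)
                assert abs(est - mu) <= 3 * sd / np.sqrt(n_iter) + 1e-12

                mu_g, sd_g = exhaustive_burden_gain_stats(df, k)
                est_g = burden_gain(m, k, n_iter=n_iter, rng=rng)
                assert abs(est_g - mu_g) <= 3 * sd_g / np.sqrt(n_iter) + 1e-9

    def test_trunk_ratio_shrinks_with_more_sectors_in_expectation(self, rng):
        df = random_presence_matrix(rng, 40, 6)
        means = [exhaustive_trunk_stats(df, k)[0] for k in (2, 3, 4, 5, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))
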