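"""The four stability statistics and the rank-aggregation layer."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from refquant import (
    bestkeeper_stability,
    comprehensive_ranking,
    delta_ct_stability,
    genorm_stability,
    normfinder_stability,
    rank_scores,
    stability_table,
    summary_score,
)

from conftest import make_matrix

ct_frames = hnp.arrays(
    float,
    st.tuples(st.integers(3, 6), st.integers(4, 8)),
    elements=st.floats(18.0, 32.0, allow_nan=False),
).map(
    lambda a: pd.DataFrame(
        a,
        index=[f"G{i}" for i in range(a.shape[0])],
        columns=[f"S{j}" for j in range(a.shape[1])],
    )
)


# -- comparative delta-Ct ----------------------------------------------------


def test_delta_ct_identical_genes_score_zero():
    frame = pd.DataFrame(
        [[24, 25, 26, 27], [24, 25, 26, 27]], index=["A", "B"], dtype=float
    )
    assert delta_ct_stability(frame).tolist() == [0.0, 0.0]


def test_delta_ct_against_brute_force_enumeration():
    """Three-gene fixture checked against exhaustive pairwise-SD
    enumeration (the definition, written long-hand)."""
    frame = pd.DataFrame(
        [[24, 25, 26, 27], [24, 25, 26, 27], [30, 30, 30, 30]],
        index=["A", "B", "C"],
        dtype=float,
    )
    scores = delta_ct_stability(frame)

    def sd(v):
        m = sum(v) / len(v)
        return (sum((x - m) ** 2 for x in v) / (len(v) - 1)) ** 0.5

    expected = {}
    for g in frame.index:
        sds = [
            sd((frame.loc[g] - frame.loc[h]).tolist())
            for h in frame.index
            if h != g
        ]
        expected[g] = sum(sds) / len(sds)
    for g in frame.index:
        assert scores[g] == pytest.approx(expected[g], abs=1e-12)
    assert scores["A"] == scores["B"] == pytest.approx(0.6455, abs=1e-4)
    assert scores["C"] == pytest.approx(1.29099, abs=1e-4)
    assert scores["C"] == scores.max()


def test_delta_ct_requires_two_genes_and_no_gaps():
    one = pd.DataFrame([[24, 25, 26]], index=["A"], dtype=float)
    with pytest.raises(ValueError, match="at least 2"):
        delta_ct_stability(one)
    gap = pd.DataFrame(
        [[24, 25, np.nan], [24, 25, 26]], index=["A", "B"], dtype=float
    )
    with pytest.raises(ValueError, match="undetermined"):
        delta_ct_stability(gap)


# -- BestKeeper --------------------------------------------------------------


def test_bestkeeper_closed_form():
    frame = pd.DataFrame(
        [[25, 25, 25, 25], [24, 25, 26, 27]], index=["flat", "ramp"], dtype=float
    )
    bk = bestkeeper_stability(frame)
    assert bk.loc["flat", "score"] == 0.0
    assert bk.loc["ramp", "score"] == pytest.approx(1.2910, abs=1e-4)
    assert bk.loc["ramp", "cv"] == pytest.approx(100 * 1.29099 / 25.5, abs=1e-3)


# -- NormFinder --------------------------------------------------------------

NF_FIXTURE = pd.DataFrame(
    [
        [24.0, 24.3, 23.8, 24.1, 24.6, 23.9],
        [26.2, 26.0, 25.7, 26.1, 26.4, 25.8],
        [21.5, 22.4, 21.1, 22.0, 22.9, 21.3],
        [28.1, 28.2, 27.9, 28.0, 28.4, 27.8],
    ],
    index=list("ABCD"),
    columns=[f"s{j}" for j in range(6)],
)


def test_normfinder_matches_long_hand_anova_decomposition():
    """Implementation equals an independent loop-wise two-way ANOVA
    variance decomposition on a printed 4x6 fixture."""
    x = NF_FIXTURE.to_numpy()
    k, n = x.shape
    gm = x.mean()
    resid = np.empty_like(x)
    for i in range(k):
        for j in range(n):
            resid[i, j] = x[i, j] - x[i].mean() - x[:, j].mean() + gm
    v = np.array([(resid[i] ** 2).sum() / (n - 1) for i in range(k)])
    expected = np.sqrt(
        np.maximum(
            0.0,
            [(k / (k - 2)) * (v[i] - v.sum() / (k * (k - 1))) for i in range(k)],
        )
    )
    got = normfinder_stability(NF_FIXTURE)
    np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-12)
    # frozen values from the long-hand computation
    np.testing.assert_allclose(
        got.to_numpy(), [0.0, 0.180739, 0.471169, 0.141421], atol=1e-6
    )


def test_normfinder_exchangeable_genes_score_alike():
    """Equal-noise genes with no gene-specific effects get nearly equal
    scores at large n."""
    rng = np.random.default_rng(5)
    n = 400
    base = np.array([22.0, 24.0, 26.0, 23.0, 25.0])[:, None]
    x = base + rng.normal(0, 0.3, size=(5, n)) + rng.normal(0, 0.5, size=(1, n))
    scores = normfinder_stability(pd.DataFrame(x))
    assert scores.max() - scores.min() < 0.06


def test_normfinder_flags_the_noisy_gene():
    """A gene with 10x the noise SD of its peers receives the largest
    stability value in >=95 of 100 seeded replicates."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = np.zeros((6, 50))
        x[0] = 24 + rng.normal(0, 1.0, 50)
        for i in range(1, 6):
            x[i] = 20 + 2 * i + rng.normal(0, 0.1, 50)
        scores = normfinder_stability(pd.DataFrame(x))
        hits += scores.idxmax() == 0
    assert hits >= 95


def test_normfinder_needs_three_genes():
    with pytest.raises(ValueError, match="at least 3"):
        normfinder_stability(NF_FIXTURE.iloc[:2])


# -- geNorm ------------------------------------------------------------------


@settings(max_examples=40, deadline=None)
@given(frame=ct_frames)
def test_genorm_first_pass_equals_delta_ct(frame):
    """The geNorm M on the full gene set is, gene for gene, exactly the
    comparative-ΔCt score: both are the mean pairwise-difference SD."""
    res = genorm_stability(frame)
    dct = delta_ct_stability(frame)
    for g in frame.index:
        assert res.first_pass_m[g] == dct[g]  # bitwise identical


def test_genorm_identical_pair_survives():
    frame = pd.DataFrame(
        [[24, 25, 26, 27], [24, 25, 26, 27], [30, 31, 29, 33]],
        index=["A", "B", "C"],
        dtype=float,
    )
    res = genorm_stability(frame)
    assert set(res.exclusion_rank[res.exclusion_rank <= 2].index) == {"A", "B"}
    # final pair: SD of their (zero) difference
    assert res.m["A"] == res.m["B"] == 0.0
    assert res.m["C"] > 0


def test_genorm_final_pair_reports_equal_m(hkg_matrix):
    res = genorm_stability(hkg_matrix.ct)
    pair = res.exclusion_rank[res.exclusion_rank <= 2].index
    assert res.m[pair[0]] == res.m[pair[1]]


def test_genorm_pairwise_variation_series(hkg_matrix):
    res = genorm_stability(hkg_matrix.ct)
    n = len(hkg_matrix.assay_ids)
    assert list(res.pairwise_variation.index) == list(range(2, n))
    assert (res.pairwise_variation > 0).all()


# -- rank aggregation --------------------------------------------------------


def test_rank_scores_orders_and_breaks_ties_by_panel_order():
    assert rank_scores({"A": 0.5, "B": 0.3, "C": 0.9}).to_dict() == {
        "A": 2, "B": 1, "C": 3
    }
    tied = pd.Series({"Y": 0.4, "X": 0.4})
    assert rank_scores(tied, panel_order=["X", "Y"]).to_dict() == {"X": 1, "Y": 2}
    with pytest.raises(ValueError, match="non-finite"):
        rank_scores({"A": float("nan"), "B": 1.0})


@pytest.mark.parametrize(
    "ranks,expected",
    [
        ((2, 1, 2, 1), 1.41),
        ((1, 9, 1, 4), 2.45),
        ((2, 2, 2, 1), 1.68),
        ((1, 1, 1, 1), 1.00),
    ],
)
def test_comprehensive_ranking_examples(ranks, expected):
    df = pd.DataFrame(
        [ranks], columns=["delta_ct", "bestkeeper", "normfinder", "genorm"],
        index=["g"],
    )
    assert round(float(comprehensive_ranking(df)["g"]), 2) == expected


def test_comprehensive_of_uniform_rank_k_is_k():
    for k in (1, 3, 7):
        df = pd.DataFrame(
            [[k] * 4], columns=["delta_ct", "bestkeeper", "normfinder", "genorm"]
        )
        assert float(comprehensive_ranking(df).iloc[0]) == pytest.approx(k)


def test_comprehensive_requires_all_methods():
    df = pd.DataFrame([[1, 2, 3]], columns=["delta_ct", "bestkeeper", "normfinder"])
    with pytest.raises(ValueError, match="missing method"):
        comprehensive_ranking(df)


def test_summary_score_sums_and_selects():
    a = pd.Series({"X": 1.41, "Y": 3.98})
    b = pd.Series({"X": 1.68, "Y": 1.97})
    sr = summary_score(a, b, panel_order=["X", "Y"])
    assert sr.table.loc["X", "summary"] == pytest.approx(3.09)
    assert sr.table.loc["Y", "summary"] == pytest.approx(5.95)
    assert sr.selected_reference == "X"
    with pytest.raises(ValueError, match="gene sets differ"):
        summary_score(a, pd.Series({"X": 1.0, "Z": 2.0}))


def test_summary_equal_conditions_doubles():
    a = pd.Series({"X": 2.0, "Y": 5.0})
    sr = summary_score(a, a)
    assert sr.table["summary"].to_dict() == {"X": 4.0, "Y": 10.0}


# -- whole-table invariants --------------------------------------------------


@settings(max_examples=25, deadline=None)
@given(frame=ct_frames, offsets=hnp.arrays(float, 8, elements=st.floats(-3, 3)))
def test_per_sample_offsets_move_only_bestkeeper(frame, offsets):
    """Adding a loading offset per sample leaves ΔCt, NormFinder and
    geNorm scores unchanged (pairwise/centered math cancels it) while
    BestKeeper, built on raw Ct spread, is free to move."""
    shifted = frame.add(pd.Series(offsets[: frame.shape[1]], index=frame.columns), axis=1)
    pd.testing.assert_series_equal(
        delta_ct_stability(frame), delta_ct_stability(shifted), atol=1e-9, rtol=0
    )
    pd.testing.assert_series_equal(
        normfinder_stability(frame), normfinder_stability(shifted), atol=1e-6, rtol=0
    )
    pd.testing.assert_series_equal(
        genorm_stability(frame).m, genorm_stability(shifted).m, atol=1e-9, rtol=0
    )


def test_bestkeeper_is_offset_sensitive(hkg_matrix):
    frame = hkg_matrix.ct
    offs = pd.Series(
        np.linspace(-2, 2, frame.shape[1]), index=frame.columns
    )
    moved = bestkeeper_stability(frame.add(offs, axis=1))["score"]
    orig = bestkeeper_stability(frame)["score"]
    assert (moved - orig).abs().max() > 0.1


def test_gene_relabeling_permutes_outputs(hkg_matrix):
    frame = hkg_matrix.ct
    perm = ["G3", "G1", "G5", "G2", "G6", "G4"]
    permuted = frame.loc[perm]
    for fn in (delta_ct_stability, normfinder_stability):
        pd.testing.assert_series_equal(
            fn(frame).loc[perm], fn(permuted), atol=1e-12, rtol=0
        )
    pd.testing.assert_series_equal(
        genorm_stability(frame, panel_order=perm).m.loc[perm],
        genorm_stability(permuted, panel_order=perm).m,
        atol=1e-12,
        rtol=0,
    )


def test_stability_table_ranks_are_permutations(hkg_matrix):
    st_ = stability_table(hkg_matrix, "control")
    n = len(hkg_matrix.assay_ids)
    for m in ("delta_ct", "bestkeeper", "normfinder", "genorm"):
        assert sorted(st_.table[f"{m}_rank"]) == list(range(1, n + 1))
    comp = st_.table["comprehensive"]
    expected = (
        st_.table[[f"{m}_rank" for m in ("delta_ct", "bestkeeper", "normfinder", "genorm")]]
        .prod(axis=1) ** 0.25
    )
    np.testing.assert_allclose(comp, expected, rtol=1e-12)
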