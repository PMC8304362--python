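"""Exact plug-in quantities and canonical distributions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import redinfo as ri
from redinfo.pmf import JointPMF


def fair_coin():
    return JointPMF(((0, 1),), (0, 1), {(0, 0): 0.25, (0, 1): 0.25, (1, 0): 0.25, (1, 1): 0.25})


# ---------------------------------------------------------------- entropies

def test_entropy_fair_coin_and_point_mass():
    pmf = fair_coin()
    assert ri.entropy_bits(pmf, "x1") == pytest.approx(1.0, abs=1e-12)
    point = JointPMF(((0,),), (1,), {(0, 1): 1.0})
    assert ri.entropy_bits(point, "y") == pytest.approx(0.0, abs=1e-12)


def test_entropy_and_marginal_of_y():
    # -0.75 log2 0.75 - 0.25 log2 0.25
    expected = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
    pmf = ri.make_canonical("AND")
    assert ri.entropy_bits(pmf, "y") == pytest.approx(expected, abs=1e-12)


def test_entropy_rejects_empty_and_unknown_subsets():
    pmf = fair_coin()
    with pytest.raises(ValueError):
        ri.entropy_bits(pmf, [])
    with pytest.raises(ValueError):
        ri.entropy_bits(pmf, "x7")


# ------------------------------------------------------- mutual information

@pytest.mark.parametrize(
    "task,pair,expected",
    [
        ("AND", ("x1", "y"), 0.311278),
        ("AND", ("x2", "y"), 0.311278),
        ("RDNXOR", ("x1", "y"), 1.0),
        ("IMPERFECTRDN", ("x1", "y"), 1.0),
    ],
)
def test_mutual_information_canonical_values(canonical_pmfs, task, pair, expected):
    assert ri.mutual_information_bits(canonical_pmfs[task], *pair) == pytest.approx(
        expected, abs=1e-5
    )


def test_mutual_information_independent_bits_is_zero():
    assert ri.mutual_information_bits(fair_coin(), "x1", "y") == pytest.approx(0.0, abs=1e-12)


def test_mutual_information_rejects_overlapping_subsets():
    with pytest.raises(ValueError):
        ri.mutual_information_bits(fair_coin(), "x1", ["x1", "y"])


def test_conditional_mi_markov_chain_is_zero():
    # A -> C -> B: B is a noisy copy of C, A independent of B given C
    table = {}
    for a in (0, 1):
        for c in (0, 1):
            for b in (0, 1):
                p_b = 0.9 if b == c else 0.1
                table[(a, c, b)] = 0.25 * p_b
    pmf = JointPMF(((0, 1), (0, 1)), (0, 1), table)
    assert ri.conditional_mi_bits(pmf, "x1", "y", "x2") == pytest.approx(0.0, abs=1e-12)


def test_conditional_mi_canonical_values(canonical_pmfs):
    assert ri.conditional_mi_bits(
        canonical_pmfs["RDNXOR"], "x1", "y", "x2"
    ) == pytest.approx(1.0, abs=1e-10)
    assert ri.conditional_mi_bits(
        canonical_pmfs["AND"], "x1", "y", "x2"
    ) == pytest.approx(0.5, abs=1e-10)


def test_chain_rule_on_all_canonical_pmfs(canonical_pmfs):
    for pmf in canonical_pmfs.values():
        joint = ri.mutual_information_bits(pmf, ["x1", "x2"], "y")
        chained = ri.mutual_information_bits(pmf, "x1", "y") + ri.conditional_mi_bits(
            pmf, "x2", "y", "x1"
        )
        assert joint == pytest.approx(chained, abs=1e-10)


# ------------------------------------------------------------- construction

def test_make_canonical_tables_are_normalised(canonical_pmfs):
    for pmf in canonical_pmfs.values():
        assert sum(pmf.table.values()) == pytest.approx(1.0, abs=1e-12)


def test_imperfectrdn_reference_values(canonical_pmfs):
    pmf = canonical_pmfs["IMPERFECTRDN"]
    assert round(ri.mutual_information_bits(pmf, "x2", "y"), 2) == 0.99
    assert ri.mutual_information_bits(pmf, "x1", "y") == pytest.approx(1.0, abs=1e-12)


def test_make_canonical_unknown_task():
    with pytest.raises(ValueError, match="unknown canonical task"):
        ri.make_canonical("XORQ")


def test_pmf_validation_errors():
    with pytest.raises(ValueError, match="sum"):
        JointPMF(((0, 1),), (0, 1), {(0, 0): 0.7})
    with pytest.raises(ValueError, match="negative"):
        JointPMF(((0, 1),), (0, 1), {(0, 0): 1.5, (1, 1): -0.5})
    with pytest.raises(ValueError, match="alphabet"):
        JointPMF(((0, 1),), (0, 1), {(2, 0): 1.0})


def test_pmf_csv_roundtrip(canonical_pmfs, tmp_path):
    for name, pmf in canonical_pmfs.items():
        path = tmp_path / f"{name}.csv"
        pmf.to_csv(path)
        back = JointPMF.from_csv(path)
        assert ri.entropy_bits(back, "y") == pytest.approx(
            ri.entropy_bits(pmf, "y"), abs=1e-9
        )
        assert ri.i_cap_wedge_bits(back) == pytest.approx(
            ri.i_cap_wedge_bits(pmf), abs=1e-9
        )


# ------------------------------------------------------------------ sampling

def test_sample_dataset_empty_draw(canonical_pmfs):
    ds = ri.sample_dataset(canonical_pmfs["RDNXOR"], 0, seed=1)
    assert ds.n_samples == 0
    assert [s.shape for s in ds.sources] == [(0, 2), (0, 2)]
    assert ds.n_classes == 4


def test_sample_dataset_seed_determinism(canonical_pmfs):
    a = ri.sample_dataset(canonical_pmfs["AND"], 500, seed=42)
    b = ri.sample_dataset(canonical_pmfs["AND"], 500, seed=42)
    for sa, sb in zip(a.sources, b.sources):
        np.testing.assert_array_equal(sa, sb)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_sample_dataset_negative_n(canonical_pmfs):
    with pytest.raises(ValueError):
        ri.sample_dataset(canonical_pmfs["AND"], -1, seed=0)


def test_sample_dataset_frequencies_match_masses(canonical_pmfs):
    pmf = canonical_pmfs["RDNXOR"]
    n = 100_000
    ds = ri.sample_dataset(pmf, n, seed=7)
    # reconstruct support-point counts from the encoded rows
    keys = pmf.support()
    enc = {
        tuple(np.concatenate([np.atleast_1d(k[0]), np.atleast_1d(k[1])])): pmf.table[k]
        for k in keys
    }
    rows = np.hstack([ds.sources[0], ds.sources[1]])
    for key, p in enc.items():
        count = (rows == np.array(key)).all(axis=1).sum()
        se = math.sqrt(n * p * (1 - p))
        assert abs(count - n * p) < 3 * se + 1


# ------------------------------------------------------- property tests

@st.composite
def random_pmfs(draw, n_sources=2):
    sizes = [draw(st.integers(2, 3)) for _ in range(n_sources)]
    k = draw(st.integers(2, 3))
    keys = [
        tuple(list(xs) + [y])
        for xs in np.ndindex(*sizes)
        for y in range(k)
    ]
    weights = draw(
        st.lists(st.integers(0, 8), min_size=len(keys), max_size=len(keys)).filter(
            lambda w: sum(w) > 0
        )
    )
    total = sum(weights)
    table = {key: w / total for key, w in zip(keys, weights) if w}
    return JointPMF(
        tuple(tuple(range(s)) for s in sizes), tuple(range(k)), table
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_pmfs())
def test_information_inequalities(pmf):
    h_y = ri.entropy_bits(pmf, "y")
    assert 0.0 <= h_y <= math.log2(len(pmf.target_alphabet)) + 1e-9
    mi = ri.mutual_information_bits(pmf, "x1", "y")
    assert mi >= -1e-9
    assert mi == pytest.approx(ri.mutual_information_bits(pmf, "y", "x1"), abs=1e-10)
    # redundancy is bounded by each source's information
    wedge = ri.i_cap_wedge_bits(pmf)
    assert wedge <= min(
        ri.mutual_information_bits(pmf, "x1", "y"),
        ri.mutual_information_bits(pmf, "x2", "y"),
    ) + 1e-9


@settings(max_examples=40, deadline=None, derandomize=True)
@given(random_pmfs())
def test_wedge_invariant_under_source_permutation(pmf):
    swapped = JointPMF(
        (pmf.source_alphabets[1], pmf.source_alphabets[0]),
        pmf.target_alphabet,
        {(k[1], k[0], k[2]): p for k, p in pmf.table.items()},
    )
    assert ri.i_cap_wedge_bits(swapped) == pytest.approx(
        ri.i_cap_wedge_bits(pmf), abs=1e-10
    )
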