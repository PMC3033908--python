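"""Unit and property tests for the bias-corrected histogram MI estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gpcrmi as g
from gpcrmi.errors import DegenerateSampleError, InsufficientSample
from gpcrmi.mi import LN2, ContingencyTable, mi_from_table


def table_from_counts(counts):
    counts = np.asarray(counts, dtype=np.int64)
    return ContingencyTable(
        counts, np.arange(counts.shape[0]), np.arange(counts.shape[1])
    )


def kl_form_mi(counts):
    """Independent oracle: direct sum of p(x,y) log2[p(x,y)/(p(x)p(y))]."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                total += p[i, j] * math.log2(p[i, j] / (px[i, 0] * py[0, j]))
    return total


def random_tables(n_tables, seed=1234, max_rows=6, max_cols=6, max_count=30):
    rng = np.random.default_rng(seed)
    for _ in range(n_tables):
        r = rng.integers(1, max_rows + 1)
        c = rng.integers(1, max_cols + 1)
        counts = rng.integers(0, max_count, size=(r, c))
        if counts.sum() == 0:
            counts[0, 0] = 1
        yield counts


@pytest.mark.parametrize(
    "counts,expected",
    [
        ([1, 1, 1, 1], 2.0),       # uniform over 4 symbols
        ([5], 0.0),                # single symbol
        ([2, 1, 1], 1.5),          # 0.5*1 + 2*0.25*2
    ],
)
def test_entropy_closed_forms(counts, expected):
    assert g.entropy(counts) == pytest.approx(expected, abs=1e-12)


def test_entropy_of_empty_counts_rejected():
    with pytest.raises(DegenerateSampleError):
        g.entropy([0, 0])


def test_contingency_counting_and_bins():
    sample = g.PairedSample(np.array(["A", "A", "C"]), np.array([1, 1, 2]))
    t = g.build_contingency(sample)
    assert t.n == 3 and t.b_x == 2 and t.b_y == 2 and t.b_xy == 2
    assert t.counts[0, 0] == 2 and t.counts[1, 1] == 1


def test_contingency_gap_policy():
    sample = g.PairedSample(np.array(["A", "-"]), np.array([1, 2]))
    t = g.build_contingency(sample, gap_policy="drop")
    assert t.n == 1 and t.b_xy == 1
    t = g.build_contingency(sample, gap_policy="keep")
    assert t.n == 2 and t.b_x == 2


def test_empty_sample_is_degenerate():
    with pytest.raises(DegenerateSampleError):
        g.PairedSample(np.array([]), np.array([]))
    with pytest.raises(DegenerateSampleError):
        g.build_contingency(g.PairedSample(np.array(["-"]), np.array([1])), "drop")


@pytest.mark.parametrize(
    "counts,expected",
    [
        ([[5, 0], [0, 5]], 1.0),            # perfect association: I = H_X = H_Y
        ([[25, 25], [25, 25]], 0.0),        # exact independence
        ([[3, 1], [1, 3]], 0.18872187554086706),
    ],
)
def test_mutual_information_worked_values(counts, expected):
    assert g.mutual_information(table_from_counts(counts)) == pytest.approx(
        expected, abs=1e-6
    )


@pytest.mark.parametrize(
    "counts,expected",
    [
        ([[25, 25], [25, 25]], 1.0 / (200.0 * LN2)),   # 4 occupied bins, N=100
        ([[7]], 0.0),                                   # B_XY=B_X=B_Y=1
        ([[9, 9], [8, 8], [8, 8]], 2.0 / (100.0 * LN2)),  # 3x2 full, N=50
    ],
)
def test_bias_correction_worked_values(counts, expected):
    assert g.bias_correction(table_from_counts(counts)) == pytest.approx(
        expected, abs=1e-9
    )


def test_corrected_mi_composition():
    x = np.repeat(["A", "C"], 5)
    y = np.repeat([0, 1], 5)  # realizes [[5,0],[0,5]], N=10
    res = g.corrected_mi(g.PairedSample(x, y), k_min=1)
    assert res.i_raw == pytest.approx(1.0, abs=1e-12)
    # perfect association occupies only the diagonal: B_XY = B_X = B_Y = 2,
    # so the correction (B_XY - B_X - B_Y + 1)/(2N ln 2) is *negative* here
    assert res.b_xy == 2
    assert res.i_corrected == pytest.approx(1.0 + 1.0 / (20.0 * LN2), abs=1e-9)


def test_constant_descriptor_gives_exact_zero():
    x = np.array(list("ACDEACDE"))
    y = np.zeros(8, dtype=int)
    res = g.corrected_mi(g.PairedSample(x, y), k_min=1)
    # B_XY = B_X and B_Y = 1, so the correction vanishes with the MI
    assert res.i_raw == 0.0 and res.bias == 0.0 and res.i_corrected == 0.0


def test_small_sample_raises_skip_signal():
    sample = g.PairedSample(np.array(["A", "C", "A", "C", "A"]), np.arange(5))
    with pytest.raises(InsufficientSample):
        g.corrected_mi(sample, k_min=20)
    assert g.corrected_mi(sample, k_min=5).n == 5


def test_h_form_equals_kl_form_on_random_tables():
    """The two textbook MI expressions agree to near machine precision."""
    for counts in random_tables(1000):
        t = table_from_counts(counts)
        assert g.mutual_information(t) == pytest.approx(kl_form_mi(counts), abs=1e-12)


def test_symmetry_bounds_and_transpose_on_random_tables():
    for counts in random_tables(500, seed=77):
        t = table_from_counts(counts)
        i_xy = g.mutual_information(t)
        i_yx = g.mutual_information(table_from_counts(np.asarray(counts).T))
        assert i_xy == pytest.approx(i_yx, abs=1e-12)
        h_x = g.entropy(t.x_marginal)
        h_y = g.entropy(t.y_marginal)
        assert -1e-12 <= i_xy <= min(h_x, h_y) + 1e-12
        assert g.entropy(t.counts) <= h_x + h_y + 1e-12
        assert i_xy >= 0.0  # clamped exactly at independence


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.integers(0, 9), min_size=2, max_size=60))
def test_self_information_equals_marginal_entropy(xs):
    """A variable carries exactly its own entropy about itself."""
    x = np.asarray(xs)
    res = g.corrected_mi(g.PairedSample(x, x.copy()), k_min=1)
    assert res.i_raw == pytest.approx(res.h_x, abs=1e-12)


def test_bias_correction_removes_most_positive_bias():
    """Under independence the corrected estimate is centred far closer to 0."""
    rng = np.random.default_rng(42)
    raw, corr = [], []
    for _ in range(1000):
        x = rng.integers(0, 5, 60)
        y = rng.integers(0, 5, 60)
        res = g.corrected_mi(g.PairedSample(x, y), k_min=1)
        raw.append(res.i_raw)
        corr.append(res.i_corrected)
    assert np.mean(raw) > 0.05  # the plug-in bias is material at this K
    # the leading-order correction removes most (not all) of the bias
    assert abs(np.mean(corr)) < 0.5 * np.mean(raw)


def test_corrected_mi_may_be_negative_and_is_not_clamped():
    rng = np.random.default_rng(0)
    vals = [
        g.corrected_mi(
            g.PairedSample(rng.integers(0, 4, 50), rng.integers(0, 4, 50)), k_min=1
        ).i_corrected
        for _ in range(200)
    ]
    assert min(vals) < 0.0
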