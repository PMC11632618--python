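import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphfm import AlphabetOrder, SARange, build_fm_index, rank
from graphfm.fm import suffix_array

from conftest import naive_occurrences, naive_suffix_array

FIX_ORDER = AlphabetOrder(("$", "(", ")", "0", "1", "A", "C", "T"))
FIX_TEXT = "(TA)0(C)1$"


@pytest.fixture(scope="module")
def fix_fm():
    return build_fm_index(FIX_TEXT, FIX_ORDER, sa_period=1)


def test_fixture_suffix_array_matches_naive_sort(fix_fm):
    sa = suffix_array(FIX_ORDER.encode(FIX_TEXT))
    assert list(sa) == naive_suffix_array(FIX_TEXT, FIX_ORDER.chars)
    assert list(sa) == [9, 5, 0, 3, 7, 4, 8, 2, 6, 1]
    assert fix_fm.bwt == "10$AC))T(("


def test_two_character_text():
    fm = build_fm_index("A$", AlphabetOrder(("$", "A")), sa_period=1)
    assert fm.bwt == "A$"
    assert fm.locate_linear("A") == [0]


@pytest.mark.parametrize("seed", range(8))
def test_doubling_suffix_array_equals_naive(seed):
    rng = np.random.default_rng(seed)
    chars = "ABCDEF"[: int(rng.integers(2, 7))]
    order = AlphabetOrder(("$",) + tuple(chars))
    text = "".join(rng.choice(list(chars), size=int(rng.integers(1, 200)))) + "$"
    sa = suffix_array(order.encode(text))
    assert list(sa) == naive_suffix_array(text, order.chars)


def test_rank_is_inclusive():
    assert rank("ABAB", "A", 0) == 1
    assert rank("ABAB", "B", 3) == 2
    assert rank("ABAB", "C", 3) == 0
    with pytest.raises(IndexError):
        rank("ABAB", "A", 4)


def test_advance_range_fixture_steps(fix_fm):
    # suffixes prefixed by 'C' occupy rows [8, 9)
    assert fix_fm.advance_range(fix_fm.full_range(), "C") == SARange(8, 9)
    # prepending 'A' to the ")0..." suffix at rows [3,4) lands on "A)0..."
    assert fix_fm.advance_range(SARange(3, 4), "A") == SARange(7, 8)
    # empty in, empty out
    assert fix_fm.advance_range(SARange(2, 2), "A").empty


def test_lf_is_a_bijection_and_inverts_bwt(fix_fm):
    rows = sorted(fix_fm.lf(i) for i in range(fix_fm.text_length))
    assert rows == list(range(fix_fm.text_length))
    assert fix_fm.reconstruct_text() == FIX_TEXT


def test_count_and_locate_on_plain_text():
    order = AlphabetOrder(("$", "A", "C", "G", "T"))
    fm = build_fm_index("ACGTACGT$", order, sa_period=4)
    assert fm.count("ACGT") == 2
    assert fm.locate_linear("ACGT") == [0, 4]
    assert fm.count("GGG") == 0
    assert fm.locate_linear("GGG") == []


@settings(max_examples=120, derandomize=True, deadline=None)
@given(
    data=st.data(),
    text=st.text(alphabet="ABCDEF", min_size=1, max_size=200),
)
def test_count_locate_equal_naive_scan(data, text):
    """Backward search agrees with a direct substring scan on random texts."""
    order = AlphabetOrder(("$", "A", "B", "C", "D", "E", "F"))
    fm = build_fm_index(text + "$", order, sa_period=8, rank_period=16)
    q = data.draw(st.text(alphabet="ABCDEF", min_size=1, max_size=8))
    expected = naive_occurrences(text + "$", q)
    assert fm.count(q) == len(expected)
    assert fm.locate_linear(q) == expected


@pytest.mark.parametrize("period", [1, 4, 32])
def test_sa_decode_independent_of_sampling_period(period):
    order = AlphabetOrder(("$", "A", "C", "G", "T"))
    rng = np.random.default_rng(3)
    text = "".join(rng.choice(list("ACGT"), size=150)) + "$"
    fm = build_fm_index(text, order, sa_period=period)
    full = fm.sa_decode(fm.full_range())
    assert sorted(full) == list(range(len(text)))
    assert fm.locate_linear("A") == naive_occurrences(text, "A")


def test_fixture_sa_decode(fix_fm):
    assert fix_fm.sa_decode(SARange(7, 8)) == [2]
    assert fix_fm.sa_decode(SARange(4, 4)) == []


def test_sentinel_must_terminate_text():
    order = AlphabetOrder(("$", "A"))
    with pytest.raises(ValueError):
        build_fm_index("A", order)
    with pytest.raises(ValueError):
        build_fm_index("$A$", order)
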