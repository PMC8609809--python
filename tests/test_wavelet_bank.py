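"""Wavelet bank: registry contents, transform correctness, invariants."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from wfcnseg.wavelet_bank import (DimensionError, KernelMismatchError,
                                  KernelRegistryError, available_kernels,
                                  dwt2, get_kernel, registry_from_json,
                                  registry_to_json, wavedec2, waverec2)

MANDATORY = ([f"db{i}" for i in range(1, 11)]
             + [f"sym{i}" for i in range(2, 9)]
             + ["bior1.1", "bior1.3", "bior2.2", "bior3.1", "bior4.4",
                "rbio1.1", "rbio2.2"])


# -- registry --------------------------------------------------------------

def test_registry_covers_mandatory_kernels():
    assert set(MANDATORY) <= set(available_kernels())


def test_haar_filter_is_analytic_and_aliases_db1():
    db1 = get_kernel("db1")
    np.testing.assert_allclose(db1.dec_lo, [1 / np.sqrt(2)] * 2, atol=1e-15)
    haar = get_kernel("haar")
    for attr in ("dec_lo", "dec_hi", "rec_lo", "rec_hi"):
        np.testing.assert_array_equal(getattr(haar, attr), getattr(db1, attr))


@pytest.mark.parametrize("name", MANDATORY)
def test_filter_tables_match_reference_library(name):
    """Embedded coefficient tables agree with the reference implementation
    to near machine precision for all four filters."""
    ours, ref = get_kernel(name), pywt.Wavelet(name)
    assert ours.filter_length == len(ref.dec_lo)
    for attr in ("dec_lo", "dec_hi", "rec_lo", "rec_hi"):
        np.testing.assert_allclose(getattr(ours, attr), getattr(ref, attr),
                                   atol=1e-12)


def test_orthogonal_kernels_have_unit_mean_lowpass_and_zero_mean_highpass():
    for name in MANDATORY:
        k = get_kernel(name)
        assert k.orthogonal == name.startswith(("db", "sym"))
        if k.orthogonal:
            assert abs(k.dec_lo.sum() - np.sqrt(2)) < 1e-10
            assert abs(k.dec_hi.sum()) < 1e-10


def test_unknown_kernel_lists_available():
    with pytest.raises(KernelRegistryError, match="db1"):
        get_kernel("morl")


def test_registry_json_round_trip():
    doc = registry_to_json(["db2", "bior3.1"])
    loaded = registry_from_json(doc)
    assert set(loaded) == {"db2", "bior3.1"}
    np.testing.assert_array_equal(loaded["db2"].dec_lo, get_kernel("db2").dec_lo)
    assert loaded["bior3.1"].orthogonal is False


# -- single-level transform ------------------------------------------------

def test_constant_image_gives_flat_approximation_and_zero_details():
    sb = dwt2(np.ones((4, 4)), "db1")
    np.testing.assert_allclose(sb.approximation, 2.0, atol=1e-12)
    for g in (sb.horizontal, sb.vertical, sb.diagonal):
        np.testing.assert_allclose(g, 0.0, atol=1e-12)


@pytest.mark.parametrize("name", ["db1", "db2", "db3", "db4",
                                  "sym2", "sym3", "sym4", "bior2.2"])
def test_dwt2_matches_reference_library(name, rng):
    x = rng.normal(size=(64, 64))
    sb = dwt2(x, name)
    ca, (ch, cv, cd) = pywt.dwt2(x, name, mode="periodization")
    for ours, ref in zip(sb.grids(), (ca, ch, cv, cd)):
        assert np.abs(ours - ref).max() < 1e-10


def test_dwt2_halves_the_240_side_to_120():
    sb = dwt2(np.zeros((240, 240)), "db1")
    assert sb.approximation.shape == (120, 120)


def test_dwt2_rejects_odd_and_undersized_inputs(rng):
    with pytest.raises(DimensionError, match="odd"):
        dwt2(rng.normal(size=(6, 7)), "db1")
    with pytest.raises(DimensionError, match="filter"):
        dwt2(rng.normal(size=(4, 4)), "db4")  # filter length 8 > side 4


def test_dwt2_linearity(rng):
    x, y = rng.normal(size=(2, 32, 32))
    a, b = 1.7, -0.3
    lhs = dwt2(a * x + b * y, "db3")
    rx, ry = dwt2(x, "db3"), dwt2(y, "db3")
    for l, gx, gy in zip(lhs.grids(), rx.grids(), ry.grids()):
        assert np.abs(l - (a * gx + b * gy)).max() < 1e-10


# -- multilevel ------------------------------------------------------------

def test_wavedec2_dyadic_size_chain_matches_injection_sizes(rng):
    dec = wavedec2(rng.normal(size=(240, 240)), "db1", 4)
    assert dec.approximation_sides() == [120, 60, 30, 15]
    for k, sb in enumerate(dec.levels, start=1):
        assert sb.shape == (240 >> k, 240 >> k)
        assert sb.level == k


def test_wavedec2_single_level_equals_dwt2(rng):
    x = rng.normal(size=(32, 32))
    dec = wavedec2(x, "sym3", 1)
    sb = dwt2(x, "sym3")
    for a, b in zip(dec.levels[0].grids(), sb.grids()):
        np.testing.assert_array_equal(a, b)


def test_wavedec2_matches_reference_multilevel(rng):
    x = rng.normal(size=(64, 64))
    dec = wavedec2(x, "db2", 3)
    ref = pywt.wavedec2(x, "db2", mode="periodization", level=3)
    assert np.abs(dec.levels[-1].approximation - ref[0]).max() < 1e-10
    # ref details are ordered coarsest -> finest
    for sb, (ch, cv, cd) in zip(dec.levels, reversed(ref[1:])):
        assert np.abs(sb.horizontal - ch).max() < 1e-10
        assert np.abs(sb.vertical - cv).max() < 1e-10
        assert np.abs(sb.diagonal - cd).max() < 1e-10


def test_wavedec2_rejects_indivisible_sides(rng):
    with pytest.raises(DimensionError, match="2\\^"):
        wavedec2(rng.normal(size=(48, 48)), "db1", 5)  # 48 = 16*3


def test_orthogonal_energy_conservation(rng):
    x = rng.normal(size=(64, 64))
    dec = wavedec2(x, "db4", 3)
    energy = sum(float((g ** 2).sum())
                 for sb in dec.levels for g in sb.grids()[1:])
    energy += float((dec.levels[-1].approximation ** 2).sum())
    assert abs(energy - (x ** 2).sum()) / (x ** 2).sum() < 1e-8


# -- reconstruction --------------------------------------------------------

@pytest.mark.parametrize("name", ["db1", "db4", "sym4", "bior3.1", "rbio2.2"])
def test_round_trip_reconstruction(name, rng):
    x = rng.normal(size=(64, 64))
    assert np.abs(waverec2(wavedec2(x, name, 2), name) - x).max() < 1e-8


def test_waverec2_rejects_kernel_mismatch(rng):
    dec = wavedec2(rng.normal(size=(16, 16)), "db2", 1)
    with pytest.raises(KernelMismatchError):
        waverec2(dec, "db3")


def test_zeroed_details_reconstruct_with_reduced_energy(rng):
    from wfcnseg.wavelet_bank import MultilevelDecomposition, SubbandSet

    x = rng.normal(size=(64, 64))
    dec = wavedec2(x, "db2", 2)
    smoothed_levels = tuple(
        SubbandSet(approximation=sb.approximation,
                   horizontal=np.zeros_like(sb.horizontal),
                   vertical=np.zeros_like(sb.vertical),
                   diagonal=np.zeros_like(sb.diagonal), level=sb.level)
        for sb in dec.levels)
    smooth = waverec2(MultilevelDecomposition("db2", smoothed_levels,
                                              dec.input_shape), "db2")
    assert (smooth ** 2).sum() <= (x ** 2).sum()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000),
       name=st.sampled_from(["db1", "db2", "sym3", "bior2.2"]))
def test_round_trip_property(seed, name):
    """Perfect reconstruction holds for arbitrary random inputs."""
    x = np.random.default_rng(seed).normal(size=(16, 16))
    assert np.abs(waverec2(wavedec2(x, name, 1), name) - x).max() < 1e-8
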