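"""Embedded parameter tables and their affine loop fits."""

import dataclasses

import numpy as np
import pytest

from duplexscan import (
    Vintage,
    fit_affine_bulge,
    fit_affine_interior,
    load_params,
)
from duplexscan.params import INF, PAIR_INDEX, affine_model, dump_params_tsv


def test_unknown_vintage_rejected():
    with pytest.raises(ValueError, match="vintage"):
        load_params("t86")


def test_loading_is_deterministic_and_idempotent():
    a, b = load_params("t04"), load_params(Vintage.T04)
    assert a is b  # cached
    assert np.array_equal(a.stack, load_params("t04").stack)


@pytest.mark.parametrize("vintage", ["t99", "t04"])
def test_stack_table_properties(vintage):
    p = load_params(vintage)
    # strand-flip symmetry: 5'WX/3'ZY is the same quartet as 5'YZ/3'XW
    assert np.array_equal(p.stack, p.stack.T)
    # Watson-Crick-on-Watson-Crick stacks are stabilizing
    wc = [PAIR_INDEX[x] for x in ("CG", "GC", "AU", "UA")]
    assert (p.stack[np.ix_(wc, wc)] < 0).all()
    # the paper's example: CG stacked on GC
    assert p.stack_energy("CG", "GC") < 0


@pytest.mark.parametrize("vintage", ["t99", "t04"])
def test_loop_initiations_positive(vintage):
    p = load_params(vintage)
    bulge = p.bulge_init[1:31]
    interior = p.intloop_init[2:31]
    assert (bulge[bulge < INF] > 0).all()
    assert (interior[interior < INF] > 0).all()


def test_duplex_initiation_rounds_to_published_value(t04):
    assert round(t04.duplex_init / 100.0, 1) == 4.1


@pytest.mark.parametrize("vintage", ["t99", "t04"])
def test_affine_bulge_exact_for_sizes_2_to_6(vintage):
    p = load_params(vintage)
    opening, ext = fit_affine_bulge(p)
    for k in range(2, 7):
        assert opening + k * ext == pytest.approx(p.bulge_init[k] / 100.0, abs=1e-9)
    # ext is the table's own common difference
    diffs = np.diff(p.bulge_init[2:7]) / 100.0
    assert ext == pytest.approx(diffs[0])


def test_bulge_extension_value_t04(t04):
    _, ext = fit_affine_bulge(t04)
    assert ext == pytest.approx(0.4)
    # finite-difference identity on the embedded table
    assert t04.bulge_init[2] - t04.bulge_init[6] == -4 * int(round(100 * ext))


def test_affine_bulge_detects_corrupt_table(t04):
    tampered = t04.bulge_init.copy()
    tampered[4] += 10
    broken = dataclasses.replace(t04, bulge_init=tampered)
    with pytest.raises(ValueError, match="not affine"):
        fit_affine_bulge(broken)


@pytest.mark.parametrize("vintage,expected", [("t04", 0.6), ("t99", 0.48)])
def test_asymmetric_interior_extension_anchor(vintage, expected):
    _, _, ext_asym = fit_affine_interior(load_params(vintage))
    assert ext_asym == pytest.approx(expected)


@pytest.mark.parametrize("vintage", ["t99", "t04"])
def test_interior_fit_overpenalizes_large_loops(vintage):
    p = load_params(vintage)
    opening, ext_sym, _ = fit_affine_interior(p)
    for s in range(16, 31, 2):
        affine = opening + (s / 2.0) * ext_sym
        assert affine >= p.intloop_init[s] / 100.0


@pytest.mark.parametrize("vintage", ["t99", "t04"])
def test_fitted_parameters_strictly_positive(vintage):
    aff = affine_model(load_params(vintage))
    assert aff.bulge_open > 0 and aff.bulge_ext > 0
    assert aff.intloop_open > 0 and aff.intloop_ext_sym > 0 and aff.intloop_ext_asym > 0


def test_single_nt_bulge_costs_the_affine_opening(t04):
    aff = affine_model(t04)
    # under the affine model a 1-nt bulge pays the opening of the gap run,
    # not the tabulated 1-nt bulge initiation
    assert aff.bulge_cost(1) == pytest.approx(aff.bulge_open + aff.bulge_ext)
    assert aff.bulge_cost(1) != pytest.approx(float(t04.bulge_init[1]))


def test_params_dump_lists_scalars(t04):
    text = dump_params_tsv(t04)
    assert "duplex_init\t410" in text
    assert "bulge_init\t2\t280" in text
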