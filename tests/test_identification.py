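import math
from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wineomics.identification import (
    LibraryEntry,
    formula_candidates,
    fragment_ppm,
    identify,
    match_factor,
    rt_penalty_weight,
)
from wineomics.io_formats import LibraryFile
from wineomics.synthetic_data import catalog_to_library, make_standards_catalog


@dataclass
class FakeComponent:
    spectrum: np.ndarray
    apex_rt: float  # s


# --------------------------------------------------------------------------
# match factor
# --------------------------------------------------------------------------

def test_self_match_is_100():
    spec = np.array([[50.0, 100.0], [75.0, 40.0], [120.0, 10.0]])
    assert match_factor(spec, spec) == pytest.approx(100.0, abs=1e-9)


def test_disjoint_spectra_score_zero():
    a = np.array([[50.0, 100.0], [60.0, 50.0]])
    b = np.array([[70.0, 100.0], [80.0, 50.0]])
    assert match_factor(a, b) == 0.0


def test_match_factor_against_direct_formula_oracle():
    """Independent evaluation of the weighted-cosine definition on a pair
    with one shared and one unshared peak."""
    a = np.array([[100.0, 100.0], [150.0, 50.0]])
    b = np.array([[100.0, 100.0]])
    wa = [math.sqrt(100.0) * 100.0, math.sqrt(50.0) * 150.0]
    wb = [math.sqrt(100.0) * 100.0]
    expected = 100.0 * (wa[0] * wb[0]) ** 2 / ((wa[0] ** 2 + wa[1] ** 2) * wb[0] ** 2)
    assert match_factor(a, b) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(47.0588, abs=1e-3)


@given(
    mzs=st.lists(st.floats(40.0, 380.0), min_size=1, max_size=8, unique=True),
    seed=st.integers(0, 10_000),
)
def test_match_factor_symmetric_and_bounded(mzs, seed):
    rng = np.random.default_rng(seed)
    a = np.column_stack([sorted(mzs), rng.uniform(1, 100, len(mzs))])
    keep = rng.uniform(size=len(mzs)) < 0.6
    b = a.copy()
    b[:, 1] = rng.uniform(1, 100, len(mzs))
    b = b[keep] if keep.any() else a
    mf_ab = match_factor(a, b)
    mf_ba = match_factor(b, a)
    assert mf_ab == pytest.approx(mf_ba, abs=1e-6)
    assert 0.0 <= mf_ab <= 100.0 + 1e-9


def test_empty_spectrum_rejected():
    with pytest.raises(ValueError):
        match_factor(np.empty((0, 2)), np.array([[50.0, 100.0]]))


# --------------------------------------------------------------------------
# accurate-mass gate
# --------------------------------------------------------------------------

def test_fragment_ppm_arithmetic():
    obs = np.array([[136.1247, 100.0]])
    lib = np.array([[136.1252, 100.0]])
    assert fragment_ppm(obs, lib) == pytest.approx(3.67, abs=0.01)


def test_identical_masses_zero_ppm():
    spec = np.array([[88.0524, 100.0], [101.0603, 50.0]])
    assert fragment_ppm(spec, spec) == 0.0


def test_fragments_below_30_mz_ignored_by_gate():
    obs = np.array([[29.5, 100.0], [88.0, 50.0]])
    lib = np.array([[29.5008, 100.0], [88.0, 50.0]])  # 27 ppm error, but below 30 m/z
    assert fragment_ppm(obs, lib) == pytest.approx(0.0, abs=1e-9)
    only_low = fragment_ppm(np.array([[29.5, 100.0]]), np.array([[29.5, 100.0]]))
    assert only_low is None  # no gate-eligible fragment -> gate fails


# --------------------------------------------------------------------------
# retention-time penalty
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "delta, weight",
    [(0.0, 1.0), (12.0, 1.0), (15.0, 0.5), (18.0, 0.0), (20.0, 0.0)],
)
def test_trapezoidal_penalty_weights(delta, weight):
    assert rt_penalty_weight(delta) == pytest.approx(weight)


def test_negative_delta_rejected():
    with pytest.raises(ValueError):
        rt_penalty_weight(-1.0)


# --------------------------------------------------------------------------
# identification
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def standards_library():
    return catalog_to_library(make_standards_catalog(seed=0), name="standards")


def test_every_library_entry_identifies_as_itself(standards_library):
    for entry in standards_library:
        comp = FakeComponent(spectrum=entry.spectrum.copy(), apex_rt=entry.rt_min * 60.0)
        res = identify(comp, [standards_library], component_ri=entry.ri)
        assert res.passed and res.name == entry.name
        assert res.penalized_mf == pytest.approx(100.0, abs=1e-9)


def test_pinene_isomers_never_cross_assigned(standards_library):
    alpha = standards_library.get("alpha-Pinene")
    beta = standards_library.get("beta-Pinene")
    assert match_factor(alpha.spectrum, beta.spectrum) < 70.0
    comp = FakeComponent(spectrum=alpha.spectrum.copy(), apex_rt=alpha.rt_min * 60.0)
    res = identify(comp, [standards_library], component_ri=alpha.ri)
    assert res.name == "alpha-Pinene"


def test_delta_ri_gate_rejects_at_31(standards_library):
    entry = standards_library.get("p-Cymene")
    comp = FakeComponent(spectrum=entry.spectrum.copy(), apex_rt=entry.rt_min * 60.0)
    hit = identify(comp, [standards_library], component_ri=entry.ri + 28.0)
    assert hit.passed and hit.delta_ri == pytest.approx(28.0)
    miss = identify(comp, [standards_library], component_ri=entry.ri + 31.0)
    assert miss.is_unknown and not miss.passed


def test_rt_penalty_drops_match_below_floor(standards_library):
    entry = standards_library.get("2-Undecanone")
    # a perfect spectrum 16 s away: weight (18-16)/6 = 1/3 -> penalized 33 < 70
    comp = FakeComponent(spectrum=entry.spectrum.copy(),
                         apex_rt=entry.rt_min * 60.0 + 16.0)
    res = identify(comp, [standards_library], component_ri=entry.ri)
    assert res.is_unknown
    # without the penalty (external library usage) the same component passes
    res2 = identify(comp, [standards_library], component_ri=entry.ri,
                    use_rt_penalty=False)
    assert res2.passed and res2.name == "2-Undecanone"


def test_unknown_naming_and_formula_attachment(standards_library):
    spec = np.array([[116.0837, 100.0], [71.0491, 60.0], [43.0184, 30.0], [88.0757, 20.0]])
    comp = FakeComponent(spectrum=spec, apex_rt=13.2265 * 60.0)
    res = identify(comp, [standards_library], component_ri=1093.0)
    assert res.name == "Unknown 13.2265"
    assert res.id_level == 4
    assert res.exact_mass == pytest.approx(116.0837)
    assert "C6H12O2" in [f for f, _ in res.formulas]


def test_standard_match_is_level_1(standards_library):
    entry = standards_library.get("p-Cymene")
    comp = FakeComponent(spectrum=entry.spectrum.copy(), apex_rt=entry.rt_min * 60.0)
    res = identify(comp, [standards_library], component_ri=entry.ri,
                   standards={"p-Cymene"})
    assert res.id_level == 1


# --------------------------------------------------------------------------
# formula search
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mass, expected",
    [(116.0837, "C6H12O2"), (136.1252, "C10H16"), (186.1620, "C11H22O2")],
)
def test_formula_candidates_contain_true_formula(mass, expected):
    hits = formula_candidates(mass, ppm=10.0)
    names = [f for f, _ in hits]
    assert expected in names
    # ranking is by |ppm|: the exact-mass formula is the top hit
    assert hits[0][0] == expected


def test_formula_candidates_respect_tolerance():
    assert formula_candidates(30.9, ppm=1e-9) == []


def test_formula_search_bounds():
    with pytest.raises(ValueError):
        formula_candidates(20.0)
    with pytest.raises(ValueError):
        formula_candidates(600.0)


def test_rdbe_constraint_excludes_overhydrogenated():
    # CH6O (34.0419) would match 34.0419 but has RDBE = -1
    hits = formula_candidates(34.0419, ppm=5.0) if True else []
    assert all(f != "CH6O" for f, _ in hits)
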