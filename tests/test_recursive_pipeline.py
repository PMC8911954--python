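from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from wineomics.deconvolution import deconvolve
from wineomics.entities import EntityTable
from wineomics.io_formats import RunMetadata
from wineomics.recursive_pipeline import (
    build_internal_library,
    recursive_identify,
    relative_abundance,
    replicate_filter,
)
from wineomics.retention_index import calibrate
from wineomics.synthetic_data import (
    NoiseModel,
    catalog_to_library,
    make_catalog,
    simulate_alkane_run,
    simulate_run,
)


def _table(values: dict, groups: dict):
    names = list(next(iter(values.values())).keys()) if values else []
    idx = pd.Index(sorted({n for col in values.values() for n in col}), name="entity")
    ab = pd.DataFrame({s: [values[s].get(n, np.nan) for n in idx] for s in values},
                      index=idx)
    entities = pd.DataFrame(
        {"rt_min": 10.0, "ri": 1000.0, "id_level": 2, "cas": "", "formula": ""},
        index=idx,
    )
    return EntityTable(entities=entities, abundance=ab, sample_groups=groups)


# --------------------------------------------------------------------------
# replicate rule and relative abundance
# --------------------------------------------------------------------------

def test_replicate_rule_mean_nd_and_drop():
    groups = {f"w_r{i}": "Wine" for i in (1, 2, 3)}
    table = _table(
        {
            "w_r1": {"full": 10.0, "partial": 5.0},
            "w_r2": {"full": 12.0, "partial": 6.0},
            "w_r3": {"full": 14.0},
        },
        groups,
    )
    out = replicate_filter(table)
    assert out.abundance.loc["full", "Wine"] == pytest.approx(12.0)  # mean of 3/3
    # 2/3 detection -> ND -> entity absent everywhere -> dropped
    assert list(out.abundance.index) == ["full"]


def test_replicate_rule_requires_balanced_groups():
    groups = {"w_r1": "Wine", "w_r2": "Wine"}
    table = _table({"w_r1": {"a": 1.0}, "w_r2": {"a": 2.0}}, groups)
    with pytest.raises(ValueError, match="replicates"):
        replicate_filter(table)
    out = replicate_filter(table, allow_unbalanced=True)
    assert out.abundance.loc["a", "Wine"] == pytest.approx(1.5)


def test_relative_abundance_tops_at_100(table1):
    rel = relative_abundance(table1)
    for col in rel.columns:
        assert rel[col].max() == pytest.approx(100.0)
    # the largest LaChanga2017 entity is 2-Phenylethanol; Ethyl acetate at
    # 9.2e8 / 1.4e9 ~ 66%
    assert rel.loc["2-Phenylethanol", "LaChanga2017"] == pytest.approx(100.0)
    assert rel.loc["Ethyl acetate", "LaChanga2017"] == pytest.approx(65.7, abs=1.0)


def test_relative_abundance_all_equal_gives_all_100():
    groups = {"s1": "g"}
    table = _table({"s1": {"a": 5.0, "b": 5.0}}, groups)
    rel = relative_abundance(table)
    assert (rel["s1"] == 100.0).all()


# --------------------------------------------------------------------------
# internal library construction
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_study():
    """40 planted compounds: 30 in the QC pool, 10 sample-only; one wine
    group in triplicate; default noise."""
    catalog = make_catalog(seed=3, n_compounds=40)
    noise = NoiseModel()
    qc_compounds = [(c, 5e6) for c in catalog[:30]]
    all_compounds = [(c, 4e6) for c in catalog]
    qc_runs = [
        simulate_run(qc_compounds, RunMetadata(run_id=f"PW_r{i}", sample_role="qc_pool",
                                               replicate=i), noise, seed=[31, i])[0]
        for i in (1, 2, 3)
    ]
    sample_runs = [
        simulate_run(all_compounds,
                     RunMetadata(run_id=f"W_r{i}", sample_role="sample",
                                 vineyard="W", vintage="X", replicate=i),
                     noise, seed=[37, i])[0]
        for i in (1, 2, 3)
    ]
    cal = calibrate(deconvolve(simulate_alkane_run(seed=5)))
    external = catalog_to_library(catalog, name="ext", with_rt=False)
    return catalog, qc_runs, sample_runs, cal, external


def test_internal_library_covers_qc_compounds(small_study):
    catalog, qc_runs, _, cal, external = small_study
    lib = build_internal_library(qc_runs, external, cal)
    names = {e.name for e in lib.entries}
    assert names == {c.name for c in catalog[:30]}
    for e in lib.entries:
        assert e.rt_min is not None and e.ri is not None
        assert lib.provenance[e.name]["source"] == "qc_pool"


def test_internal_library_blacklist_removes_artifacts(small_study):
    catalog, qc_runs, _, cal, external = small_study
    # masquerade one library compound as a siloxane artifact
    renamed = catalog_to_library(catalog, name="ext", with_rt=False)
    victim = catalog[5].name
    renamed.get(victim).name = "Hexamethylcyclotrisiloxane"
    lib = build_internal_library(qc_runs, renamed, cal)
    names = {e.name for e in lib.entries}
    assert "Hexamethylcyclotrisiloxane" not in names
    assert len(names) == 29


def test_unmatched_qc_component_becomes_unknown(small_study):
    catalog, qc_runs, _, cal, external = small_study
    # drop one compound from the external library: its component must be
    # stored as "Unknown <RT>"
    victim = catalog[10].name
    reduced = catalog_to_library(
        [c for c in catalog if c.name != victim], name="ext", with_rt=False
    )
    lib = build_internal_library(qc_runs, reduced, cal)
    unknowns = [
        e for e in lib.entries
        if lib.provenance[e.name]["source"] == "new_unknown"
    ]
    assert len(unknowns) == 1
    assert unknowns[0].id_level == 4
    assert unknowns[0].name.startswith("Unknown ")
    rt = float(unknowns[0].name.split()[1])
    assert rt * 60.0 == pytest.approx(catalog[10].target_rt_s, abs=10)


def test_empty_qc_rejected(small_study):
    *_, cal, external = small_study
    with pytest.raises(ValueError):
        build_internal_library([], external, cal)


# --------------------------------------------------------------------------
# recursive identification
# --------------------------------------------------------------------------

def test_end_to_end_recovery_and_provenance(small_study):
    catalog, qc_runs, sample_runs, cal, external = small_study
    internal = build_internal_library(qc_runs, external, cal)
    table, lib = recursive_identify(sample_runs, internal, external, cal)
    grouped = replicate_filter(table)
    planted = {c.name for c in catalog}
    recovered = set(grouped.entities.index)
    # >= 95% of the 40 planted entities recovered, no spurious extras
    assert len(planted & recovered) >= 0.95 * len(planted)
    assert not (recovered - planted)
    # compounds absent from QC arrive via the external pass
    sample_only = {c.name for c in catalog[30:]} & recovered
    assert sample_only
    for name in sample_only:
        assert lib.provenance[name]["source"] == "external_hit"


def test_recursive_identify_is_idempotent(small_study):
    catalog, qc_runs, sample_runs, cal, external = small_study
    internal = build_internal_library(qc_runs, external, cal)
    table1_, lib1 = recursive_identify(sample_runs, internal, external, cal)
    table2_, lib2 = recursive_identify(sample_runs, lib1, external, cal)
    assert len(lib2) == len(lib1)
    pd.testing.assert_frame_equal(table2_.abundance, table1_.abundance)


def test_rt_drift_within_trapezoid_merges_beyond_splits(small_study):
    catalog, qc_runs, _, cal, external = small_study
    internal = build_internal_library(qc_runs, external, cal)
    spec = catalog[0]
    noise = NoiseModel(rt_jitter_sd=0.0)
    # +6 s drift: inside the penalty-free band -> same entity
    near = replace(spec, target_ri=spec.target_ri + 6.0 / 1.05)
    run_near, _ = simulate_run([(near, 5e6)],
                               RunMetadata(run_id="near", sample_role="sample"),
                               noise, seed=[41, 1])
    t_near, _ = recursive_identify([run_near], internal, external, cal)
    assert list(t_near.entities.index) == [spec.name]
    # +25 s drift: beyond the 18 s trapezoid; the internal entry cannot
    # claim it, and it resurfaces as a separate (external-hit) observation
    far = replace(spec, target_ri=spec.target_ri + 25.0 / 1.05)
    run_far, _ = simulate_run([(far, 5e6)],
                              RunMetadata(run_id="far", sample_role="sample"),
                              noise, seed=[41, 2])
    t_far, lib_far = recursive_identify([run_far], internal, external, cal)
    [entity] = t_far.entities.index
    assert entity.startswith(f"{spec.name} @")  # flagged as a second elution
    entry = lib_far.library.get(entity)
    drt = abs(entry.rt_min * 60.0 - internal.library.get(spec.name).rt_min * 60.0)
    assert drt > 18.0
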