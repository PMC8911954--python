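"""Canned, seeded end-to-end scenarios binding generator and pipeline.

Each scenario is fully reproducible from its seed and asserts recovery of
*planted* truths — the generator's design — not instrument-dependent
numbers, which would require real raw data. Scenario outputs are the
substrate of the acceptance checks and the worked examples in the docs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .deconvolution import deconvolve
from .differential_analysis import venn_summary
from .entities import EntityTable
from .identification import fragment_ppm, identify
from .recursive_pipeline import (
    build_internal_library,
    recursive_identify,
    replicate_filter,
)
from .retention_index import calibrate, compute_ri
from .validation_qc import QCReport, ValidationReport, compute_validation_report, qc_pca_report

__all__ = [
    "ValidationScenarioResult",
    "scenario_validation",
    "ReplayScenarioResult",
    "scenario_table1_replay",
    "scenario_qc_drift",
]


# --------------------------------------------------------------------------
# validation scenario
# --------------------------------------------------------------------------

@dataclass
class ValidationScenarioResult:
    report: ValidationReport
    measurements: pd.DataFrame  # one row per (injection, standard)
    n_runs: int


def scenario_validation(
    seed: int = 42, noise: sd.NoiseModel | None = None
) -> ValidationScenarioResult:
    """Simulate the validation design and push it through the full pipeline.

    Four standards, five-level curves (day 1 in triplicate; day 2 levels
    1/3/5 in triplicate; ten L1 injections over three days), plus an alkane
    ladder for retention indexing. Every run is deconvolved; components are
    identified against the standards library; per-injection area, RT, match
    factor and the worst mass error over the five most abundant fragments
    feed the validation report.
    """
    noise = noise or sd.NoiseModel()
    standards = sd.make_standards_catalog(seed=0)
    runs, truths, manifest = sd.simulate_validation_runs(seed=seed, noise=noise)
    alkane = sd.simulate_alkane_run(seed=seed)
    cal = calibrate(deconvolve(alkane))
    library = sd.catalog_to_library(standards, name="standards")
    rows = []
    for rid, run in runs.items():
        md = run.metadata
        for comp in deconvolve(run):
            res = identify(
                comp,
                [library],
                component_ri=compute_ri(comp.apex_rt, cal),
                use_rt_penalty=True,
                standards={c.name for c in standards},
            )
            if not res.passed:
                continue
            spec = comp.spectrum
            top5 = spec[np.argsort(spec[:, 1])[::-1][:5]]
            ppm5 = fragment_ppm(top5, res.entry.spectrum)
            rows.append(
                {
                    "run_id": rid,
                    "standard": res.name,
                    "day": md.day,
                    "level": md.level,
                    "replicate": md.replicate,
                    "area": comp.total_area,
                    "rt_s": comp.apex_rt,
                    "mf": res.match_factor,
                    "max_ppm5": ppm5,
                }
            )
    measurements = pd.DataFrame(rows)
    report = compute_validation_report(measurements, sd.STANDARD_LEVELS_NG_L)
    return ValidationScenarioResult(
        report=report, measurements=measurements, n_runs=len(runs)
    )


# --------------------------------------------------------------------------
# study replay scenario
# --------------------------------------------------------------------------

@dataclass
class ReplayScenarioResult:
    planted_presence: pd.DataFrame  # entity x group booleans
    recovered_presence: pd.DataFrame
    recovered_table: EntityTable  # group-level (after replicate rule)
    replicate_table: EntityTable  # per-injection
    planted_venn: dict
    recovered_venn: dict
    exact_match: bool
    mismatches: pd.DataFrame  # rows where recovered != planted


def scenario_table1_replay(
    seed: int = 42,
    noise: sd.NoiseModel | None = None,
    n_compounds: int | None = None,
) -> ReplayScenarioResult:
    """Plant the bundled wine table's presence/abundance design, run the
    full recursive pipeline, and compare recovered presence to the plant.

    The study: 4 wine groups x 3 replicates plus a 3-injection QC pool and
    an alkane ladder. The internal library is built from the QC pool against
    an RT-free external library; samples then go through the two-pass
    recursive identification and the 3-replicate rule.
    """
    noise = noise or sd.NoiseModel()
    catalog = sd.make_catalog(seed=seed, n_compounds=n_compounds)
    study = sd.simulate_study(
        seed=seed,
        noise=noise,
        catalog=catalog,
        include_standards=False,
        include_spiked_qc=False,
        include_blank=False,
    )
    cal = calibrate(deconvolve(study.runs["alkane"]))
    external = sd.catalog_to_library(catalog, name="external", with_rt=False)
    qc_ids = study.manifest.loc[study.manifest["role"] == "qc_pool", "run_id"]
    internal = build_internal_library([study.runs[r] for r in qc_ids], external, cal)
    sample_ids = study.manifest.loc[study.manifest["role"] == "sample", "run_id"]
    replicate_table, _ = recursive_identify(
        [study.runs[r] for r in sample_ids], internal, external, cal
    )
    grouped = replicate_filter(replicate_table)
    planted = study.presence
    recovered = pd.DataFrame(False, index=planted.index, columns=planted.columns)
    rec_pres = grouped.presence_sets()
    for g in recovered.columns:
        for name in rec_pres.get(g, ()):
            if name in recovered.index:
                recovered.loc[name, g] = True
    extra_entities = sorted(set(grouped.entities.index) - set(planted.index))
    mismatch_mask = (recovered != planted).any(axis=1)
    mismatches = pd.DataFrame(
        {
            "planted": planted[mismatch_mask].apply(
                lambda r: ",".join(c for c in planted.columns if r[c]), axis=1
            ),
            "recovered": recovered[mismatch_mask].apply(
                lambda r: ",".join(c for c in recovered.columns if r[c]), axis=1
            ),
        }
    )
    exact = bool(not mismatch_mask.any() and not extra_entities)
    planted_table = EntityTable(
        entities=pd.DataFrame(index=planted.index,
                              columns=["rt_min", "ri", "id_level", "cas", "formula"]),
        abundance=pd.DataFrame(
            {
                g: [
                    c.group_abundances.get(g, np.nan)
                    for c in catalog
                ]
                for g in planted.columns
            },
            index=planted.index,
        ),
        sample_groups={g: g for g in planted.columns},
    )
    return ReplayScenarioResult(
        planted_presence=planted,
        recovered_presence=recovered,
        recovered_table=grouped,
        replicate_table=replicate_table,
        planted_venn=venn_summary(planted_table),
        recovered_venn=venn_summary(grouped),
        exact_match=exact,
        mismatches=mismatches,
    )


# --------------------------------------------------------------------------
# QC drift scenario
# --------------------------------------------------------------------------

def scenario_qc_drift(
    seed: int = 42,
    n_entities: int = 60,
    qc_cv: float = 0.05,
    sample_cv: float = 0.10,
    group_effect: float = 2.0,
    n_qc: int = 6,
    qc_compositional_scale: float = 0.0,
) -> QCReport:
    """QC clustering diagnostic on a synthetic entity table.

    Samples carry group effects (a subset of entities shifted
    ``group_effect``-fold per wine group) plus ``sample_cv`` replicate
    noise; the QC pool re-injections vary only by ``qc_cv`` injection noise
    (half the sample noise by default, no group structure), which is what a
    homogeneous pooled material shows. ``qc_compositional_scale`` > 0 mixes
    a random fraction of the group-effect structure into each QC injection
    (1.0 makes QC injections scatter like random samples — the drifting-QC
    stress case, which must withhold the high-quality flag). Generated
    directly in entity space — the raw-signal chain is exercised by the
    other scenarios.
    """
    rng = np.random.default_rng([seed, 17])
    groups = ["LaChanga2017", "LaChanga2018", "LosDolores2017", "LosDolores2018"]
    base = 10 ** rng.uniform(5.5, 8.5, size=n_entities)
    effect = {}
    for k, g in enumerate(groups):
        mult = np.ones(n_entities)
        idx = rng.choice(n_entities, size=n_entities // 4, replace=False)
        mult[idx] = group_effect ** rng.choice([-1, 1], size=idx.size)
        effect[g] = mult
    cols = {}
    sample_groups = {}
    for g in groups:
        for rep in range(1, 4):
            col = f"{g}_r{rep}"
            cols[col] = base * effect[g] * np.exp(rng.normal(0, sample_cv, n_entities))
            sample_groups[col] = g
    pool = base * np.mean([effect[g] for g in groups], axis=0)
    for rep in range(1, n_qc + 1):
        col = f"PW_r{rep}"
        inj = pool * np.exp(rng.normal(0, qc_cv, n_entities))
        if qc_compositional_scale > 0:
            g = groups[int(rng.integers(0, len(groups)))]
            drift = (effect[g] / np.mean([effect[h] for h in groups], axis=0))
            inj = inj * drift**qc_compositional_scale
        cols[col] = inj
        sample_groups[col] = "qc_pool"
    idx = pd.Index([f"entity_{i:03d}" for i in range(n_entities)], name="entity")
    table = EntityTable(
        entities=pd.DataFrame(index=idx,
                              columns=["rt_min", "ri", "id_level", "cas", "formula"]),
        abundance=pd.DataFrame(cols, index=idx),
        sample_groups=sample_groups,
    )
    return qc_pca_report(table)
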