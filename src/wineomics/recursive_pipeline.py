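"""Two-pass recursive identification across a study.

The recursive strategy reduces false positives/negatives in untargeted
GC-MS data:

1. A QC pool (a mix of all study wines) is deconvolved and identified
   against external libraries to build an **internal library** whose entries
   carry the observed retention time and retention index.
2. Each sample is identified against the internal library *with* the
   trapezoidal RT penalty (tight alignment); leftovers are searched in the
   external libraries *without* RT (external entries carry none); new hits
   and new Unknowns are appended to the internal library with their observed
   RT/RI, and a final re-pass aligns every sample against the augmented
   library so late-discovered entities are back-filled in earlier samples
   (making the result order-independent and the procedure idempotent).
3. The **replicate rule**: an entity counts as present in a wine only when
   found in all three replicate injections; its abundance is the replicate
   mean, otherwise the cell is ND.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconvolution import Component, deconvolve
from .entities import ENTITY_COLUMNS, EntityTable
from .identification import LibraryEntry, MatchResult, identify, make_unknown_name
from .io_formats import LibraryFile, RawRun
from .retention_index import RICalibration, compute_ri

logger = logging.getLogger(__name__)

__all__ = [
    "InternalLibrary",
    "build_internal_library",
    "recursive_identify",
    "replicate_filter",
    "relative_abundance",
    "DEFAULT_BLACKLIST",
]

#: name fragments of fiber / column / plasticiser artifacts removed from
#: internal libraries
DEFAULT_BLACKLIST = ("siloxane", "silox", "silanol", "silane", "phthalate")


@dataclass
class InternalLibrary:
    """A spectral library with provenance per entry."""

    library: LibraryFile
    provenance: dict[str, dict] = field(default_factory=dict)
    # provenance[name] = {"source": qc_pool|external_hit|new_unknown,
    #                     "first_seen": run_id}

    @property
    def entries(self) -> list[LibraryEntry]:
        return self.library.entries

    def __len__(self) -> int:
        return len(self.library)

    def add(self, entry: LibraryEntry, source: str, first_seen: str) -> None:
        if self.library.get(entry.name) is not None:
            return
        if entry.rt_min is None or entry.ri is None:
            raise ValueError("internal-library entries must carry RT and RI")
        self.library.entries.append(entry)
        self.provenance[entry.name] = {"source": source, "first_seen": first_seen}

    def copy(self) -> "InternalLibrary":
        return InternalLibrary(
            library=LibraryFile(
                entries=list(self.library.entries),
                name=self.library.name,
                version=self.library.version,
            ),
            provenance={k: dict(v) for k, v in self.provenance.items()},
        )


def _is_blacklisted(name: str, blacklist: tuple[str, ...]) -> bool:
    low = name.lower()
    return any(b in low for b in blacklist)


def _entry_from_component(
    comp: Component,
    name: str,
    ri: float | None,
    template: LibraryEntry | None = None,
    id_level: int = 4,
) -> LibraryEntry:
    return LibraryEntry(
        name=name,
        spectrum=comp.spectrum.copy(),
        cas=template.cas if template else "",
        formula=template.formula if template else "",
        exact_mass=template.exact_mass if template else comp.base_mz,
        rt_min=comp.apex_rt_min,
        ri=ri,
        id_level=template.id_level if template else id_level,
    )


def _deconvolved(runs, deconvolve_kwargs) -> dict[str, tuple[RawRun, list[Component]]]:
    out = {}
    for run in runs:
        out[run.metadata.run_id] = (run, deconvolve(run, **(deconvolve_kwargs or {})))
    return out


def build_internal_library(
    qc_runs: list[RawRun],
    external_library: LibraryFile,
    rtcal: RICalibration,
    blacklist: tuple[str, ...] = DEFAULT_BLACKLIST,
    mf_min: float = 70.0,
    deconvolve_kwargs: dict | None = None,
) -> InternalLibrary:
    """Deconvolve the QC pool injections and distil an internal library.

    Components are identified against the external library (no RT penalty —
    external libraries carry no retention time); hits are stored under their
    library name with the *observed* RT/RI and spectrum, non-hits as Unknown
    entries. An entry is kept only when its compound is found in **every**
    QC injection (Unknowns are matched across injections by spectrum and a
    12 s RT window). Fiber/column artifacts are removed by name blacklist.
    """
    if not qc_runs:
        raise ValueError("at least one QC run is required")
    per_run = _deconvolved(qc_runs, deconvolve_kwargs)
    for rid, (_, comps) in per_run.items():
        if not comps:
            raise ValueError(f"QC run {rid} yielded no components")

    # per run: name -> (component, result); unknowns keyed per occurrence
    named: list[dict[str, tuple[Component, MatchResult]]] = []
    unknowns: list[list[Component]] = []
    run_ids = list(per_run)
    for rid in run_ids:
        _, comps = per_run[rid]
        hits: dict[str, tuple[Component, MatchResult]] = {}
        unk: list[Component] = []
        for comp in comps:
            res = identify(
                comp,
                [external_library],
                component_ri=compute_ri(comp.apex_rt, rtcal),
                mf_min=mf_min,
                use_rt_penalty=False,
            )
            if res.passed:
                prev = hits.get(res.name)
                if prev is None or res.penalized_mf > prev[1].penalized_mf:
                    hits[res.name] = (comp, res)
            else:
                unk.append(comp)
        named.append(hits)
        unknowns.append(unk)

    lib = InternalLibrary(library=LibraryFile(entries=[], name="internal"))
    common = set(named[0])
    for hits in named[1:]:
        common &= set(hits)
    for name in sorted(common):
        if _is_blacklisted(name, blacklist):
            logger.info("excluding blacklisted QC component %r", name)
            continue
        comp, res = named[0][name]
        rts = [h[name][0].apex_rt_min for h in named]
        ris = [compute_ri(h[name][0].apex_rt, rtcal) for h in named]
        entry = _entry_from_component(comp, name, float(np.mean(ris)), template=res.entry)
        entry.rt_min = float(np.mean(rts))
        lib.add(entry, source="qc_pool", first_seen=run_ids[0])

    # unknowns must recur in every QC injection: match by spectrum + RT
    from .identification import match_factor

    for comp in unknowns[0]:
        matched_all = True
        partners = [comp]
        for others in unknowns[1:]:
            part = None
            for o in others:
                if abs(o.apex_rt - comp.apex_rt) <= 12.0 and match_factor(
                    comp.spectrum, o.spectrum
                ) >= mf_min:
                    part = o
                    break
            if part is None:
                matched_all = False
                break
            partners.append(part)
        if not matched_all:
            continue
        rt_mean = float(np.mean([p.apex_rt for p in partners]))
        name = make_unknown_name(rt_mean / 60.0)
        if _is_blacklisted(name, blacklist) or lib.library.get(name):
            continue
        entry = _entry_from_component(comp, name, compute_ri(rt_mean, rtcal))
        entry.rt_min = rt_mean / 60.0
        lib.add(entry, source="new_unknown", first_seen=run_ids[0])
    return lib


def recursive_identify(
    sample_runs: list[RawRun],
    internal_lib: InternalLibrary,
    external_lib: LibraryFile,
    rtcal: RICalibration,
    mf_min: float = 70.0,
    standards: set[str] | frozenset[str] = frozenset(),
    deconvolve_kwargs: dict | None = None,
) -> tuple[EntityTable, InternalLibrary]:
    """Identify every sample against the internal library, augmenting it
    with external hits and new Unknowns, then re-align all samples against
    the final library (back-fill pass).

    Returns the per-sample entity table (abundance = component total area)
    and the augmented internal library.
    """
    if len(internal_lib) == 0:
        raise ValueError("internal library is empty")
    lib = internal_lib.copy()
    per_run = _deconvolved(sample_runs, deconvolve_kwargs)

    # pass 1+2: grow the library
    for rid, (_, comps) in per_run.items():
        for comp in comps:
            c_ri = compute_ri(comp.apex_rt, rtcal)
            res = identify(
                comp, [lib.library], component_ri=c_ri, mf_min=mf_min,
                use_rt_penalty=True, standards=standards,
            )
            if res.passed:
                continue
            res2 = identify(
                comp, [external_lib], component_ri=c_ri, mf_min=mf_min,
                use_rt_penalty=False, standards=standards,
            )
            if res2.passed:
                name = res2.name
                if lib.library.get(name) is not None:
                    # same library compound already anchored at another RT
                    # (pass 1 rejected it on the trapezoid): a drifted or
                    # duplicate elution becomes its own entity, flagged by
                    # an RT suffix
                    name = f"{res2.name} @{comp.apex_rt_min:.4f}"
                if lib.library.get(name) is None:
                    entry = _entry_from_component(comp, name, c_ri, template=res2.entry)
                    lib.add(entry, source="external_hit", first_seen=rid)
            else:
                entry = _entry_from_component(comp, res2.name, c_ri)
                if lib.library.get(entry.name) is None:
                    lib.add(entry, source="new_unknown", first_seen=rid)

    # back-fill pass against the final library
    abundance: dict[str, dict[str, float]] = {}
    best_mf: dict[tuple[str, str], float] = {}
    for rid, (_, comps) in per_run.items():
        for comp in comps:
            c_ri = compute_ri(comp.apex_rt, rtcal)
            res = identify(
                comp, [lib.library], component_ri=c_ri, mf_min=mf_min,
                use_rt_penalty=True, standards=standards,
            )
            if not res.passed:
                continue
            key = (res.name, rid)
            if res.penalized_mf > best_mf.get(key, -1.0):
                best_mf[key] = res.penalized_mf
                abundance.setdefault(res.name, {})[rid] = comp.total_area

    order = sorted(lib.entries, key=lambda e: e.rt_min)
    names = [e.name for e in order if e.name in abundance]
    run_ids = list(per_run)
    meta = pd.DataFrame(
        {
            "rt_min": [lib.library.get(n).rt_min for n in names],
            "ri": [lib.library.get(n).ri for n in names],
            "id_level": [lib.library.get(n).id_level for n in names],
            "cas": [lib.library.get(n).cas for n in names],
            "formula": [lib.library.get(n).formula for n in names],
        },
        index=pd.Index(names, name="entity"),
    )
    ab = pd.DataFrame(
        {rid: [abundance[n].get(rid, np.nan) for n in names] for rid in run_ids},
        index=meta.index,
    )
    groups = {
        rid: (per_run[rid][0].metadata.group or per_run[rid][0].metadata.sample_role)
        for rid in run_ids
    }
    table = EntityTable(
        entities=meta,
        abundance=ab,
        sample_groups=groups,
        spectra={n: lib.library.get(n).spectrum.copy() for n in names},
    )
    return table, lib


def replicate_filter(
    table: EntityTable, n_replicates: int = 3, allow_unbalanced: bool = False
) -> EntityTable:
    """Collapse replicate columns to group columns under the 3-replicate rule.

    An entity is present in a wine group only when detected in **all**
    replicates of that group; its group abundance is then the replicate
    mean, otherwise ND. Entities absent from every group are dropped.
    """
    groups = table.groups
    for g in groups:
        n = len(table.samples_of(g))
        if n != n_replicates and not allow_unbalanced:
            raise ValueError(
                f"group {g!r} has {n} replicates, expected {n_replicates} "
                "(pass allow_unbalanced=True to override)"
            )
    ab = pd.DataFrame(index=table.abundance.index)
    for g in groups:
        cols = table.abundance[table.samples_of(g)]
        present = cols.notna().all(axis=1)
        ab[g] = np.where(present, cols.mean(axis=1), np.nan)
    keep = ab.notna().any(axis=1)
    return EntityTable(
        entities=table.entities.loc[keep, ENTITY_COLUMNS].copy(),
        abundance=ab.loc[keep],
        sample_groups={g: g for g in groups},
        spectra={n: s for n, s in table.spectra.items() if n in set(ab.index[keep])},
    )


def relative_abundance(table: EntityTable) -> pd.DataFrame:
    """Per-column relative abundance: 100 x abundance / column maximum."""
    ab = table.abundance
    out = pd.DataFrame(index=ab.index)
    for col in ab.columns:
        top = ab[col].max()
        if pd.isna(top):
            raise ValueError(f"group {col!r} has no detected entity")
        out[col] = 100.0 * ab[col] / top
    return out
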