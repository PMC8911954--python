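"""Readers and writers for every external artifact of the pipeline.

Formats
-------
* **Runs** — a columnar text dialect (one ``SCAN <index> <time_s>`` header per
  scan followed by ``mz<TAB>intensity`` lines) chosen so tests and fixtures
  need no binary dependency. mzML is read through pyteomics when installed.
* **Spectral libraries** — a minimal XML dialect mirroring
  :class:`~wineomics.identification.LibraryEntry`, plus a flat CSV twin for
  diffability. Vendor library schemas are proprietary and not reproduced.
* **RT calibration** — the four-column CSV (``Compound name``, ``CAS#``,
  ``Retention Index``, ``Retention Time``) used to compute retention indices.
* **CEF export** — a self-defined Compound Exchange Format XML dialect
  carrying, per entity per sample: retention time (min), area, best-hit name
  and up to 10 spectrum peaks. The vendor CEF schema is not public; only the
  fields this pipeline produces are written.
* **Reference wine table** — a bundled 101-compound table of volatiles
  annotated in Cabernet Sauvignon wines from two vineyards x two vintages,
  used as ground-truth design and as the substrate of the presence/Venn and
  differential analyses.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .entities import ENTITY_COLUMNS, EntityTable
from .identification import LibraryEntry

logger = logging.getLogger(__name__)

__all__ = [
    "Scan",
    "RunMetadata",
    "RawRun",
    "read_run",
    "write_run",
    "LibraryFile",
    "read_library",
    "write_library",
    "write_library_csv",
    "read_library_csv",
    "RTCalibrationTable",
    "read_rt_calibration",
    "write_rt_calibration",
    "export_cef",
    "read_cef",
    "load_table1_fixture",
    "TABLE1_GROUPS",
]


class ParseError(ValueError):
    """Raised for malformed artifact files, naming the offending location."""


# --------------------------------------------------------------------------
# raw runs
# --------------------------------------------------------------------------

@dataclass
class Scan:
    time: float  # seconds
    mz: np.ndarray  # Th, ascending
    intensity: np.ndarray  # counts, >= 0


@dataclass
class RunMetadata:
    run_id: str = "run"
    sample_role: str = "sample"  # sample|qc_pool|qc_spiked|standard_level|alkane|blank
    mass_range: tuple[float, float] = (30.0, 400.0)
    scan_rate_hz: float = 2.5
    vineyard: str | None = None
    vintage: str | None = None
    replicate: int | None = None
    day: int | None = None
    level: int | None = None  # standard curve level, 1..5
    extra: dict = field(default_factory=dict)

    @property
    def group(self) -> str | None:
        if self.vineyard and self.vintage:
            return f"{self.vineyard}{self.vintage}"
        return None


_ROLES = {"sample", "qc_pool", "qc_spiked", "standard_level", "alkane", "blank"}


@dataclass
class RawRun:
    scans: list[Scan]
    metadata: RunMetadata

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.metadata.sample_role not in _ROLES:
            raise ValueError(f"unknown sample_role {self.metadata.sample_role!r}")
        times = np.array([s.time for s in self.scans], dtype=float)
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError(f"scan times must be strictly increasing in {self.metadata.run_id}")
        for k, s in enumerate(self.scans):
            s.mz = np.asarray(s.mz, dtype=float)
            s.intensity = np.asarray(s.intensity, dtype=float)
            if s.mz.shape != s.intensity.shape:
                raise ValueError(f"scan {k}: mz/intensity length mismatch")
            if np.any(s.intensity < 0):
                raise ValueError(f"scan {k}: negative intensity")
            if s.mz.size and np.any(np.diff(s.mz) < 0):
                warnings.warn(f"scan {k}: m/z not sorted; re-sorting", stacklevel=2)
                order = np.argsort(s.mz)
                s.mz = s.mz[order]
                s.intensity = s.intensity[order]

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.scans], dtype=float)

    def tic(self) -> np.ndarray:
        return np.array([float(s.intensity.sum()) for s in self.scans])


_META_FIELDS = ("run_id", "sample_role", "vineyard", "vintage", "replicate", "day", "level")


def write_run(run: RawRun, path: str | Path) -> None:
    """Serialize a run in the columnar text dialect (see module docstring)."""
    md = run.metadata
    with open(path, "w") as fh:
        fh.write("# wineomics-run 1\n")
        for name in _META_FIELDS:
            value = getattr(md, name)
            if value is not None:
                fh.write(f"# {name}\t{value}\n")
        fh.write(f"# mass_range\t{md.mass_range[0]}\t{md.mass_range[1]}\n")
        fh.write(f"# scan_rate_hz\t{md.scan_rate_hz}\n")
        for i, s in enumerate(run.scans):
            fh.write(f"SCAN {i} {s.time:.6f}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.6f}\t{inten:.4f}\n")


def _read_run_text(path: str | Path) -> RawRun:
    md = RunMetadata()
    scans: list[Scan] = []
    cur_mz: list[float] = []
    cur_int: list[float] = []
    cur_time: float | None = None

    def flush() -> None:
        nonlocal cur_mz, cur_int, cur_time
        if cur_time is not None:
            scans.append(Scan(cur_time, np.array(cur_mz), np.array(cur_int)))
        cur_mz, cur_int, cur_time = [], [], None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                key = parts[0]
                if key in ("run_id", "sample_role", "vineyard", "vintage") and len(parts) > 1:
                    setattr(md, key, parts[1])
                elif key in ("replicate", "day", "level") and len(parts) > 1:
                    setattr(md, key, int(parts[1]))
                elif key == "mass_range" and len(parts) > 2:
                    md.mass_range = (float(parts[1]), float(parts[2]))
                elif key == "scan_rate_hz" and len(parts) > 1:
                    md.scan_rate_hz = float(parts[1])
                continue
            if line.startswith("SCAN"):
                flush()
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError(f"{path}:{lineno}: malformed SCAN header {line!r}")
                cur_time = float(parts[2])
                continue
            parts = line.split("\t")
            if len(parts) != 2 or cur_time is None:
                raise ParseError(f"{path}:{lineno}: malformed point line {line!r}")
            cur_mz.append(float(parts[0]))
            cur_int.append(float(parts[1]))
    flush()
    if not scans:
        raise ParseError(f"{path}: run contains no scans")
    return RawRun(scans=scans, metadata=md)


def _read_run_mzml(path: str | Path) -> RawRun:
    from pyteomics import mzml  # optional dependency

    scans: list[Scan] = []
    with mzml.read(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            t = spec["scanList"]["scan"][0]["scan start time"]
            t_s = float(t) * 60.0 if getattr(t, "unit_info", "minute") == "minute" else float(t)
            scans.append(Scan(t_s, np.asarray(spec["m/z array"]), np.asarray(spec["intensity array"])))
    if not scans:
        raise ParseError(f"{path}: mzML file contains no MS1 spectra")
    return RawRun(scans=scans, metadata=RunMetadata(run_id=Path(path).stem))


def read_run(path: str | Path, dialect: str = "auto") -> RawRun:
    """Read a run; ``dialect`` in {auto, columnar_text, mzml}."""
    if dialect == "auto":
        dialect = "mzml" if str(path).lower().endswith(".mzml") else "columnar_text"
    if dialect == "columnar_text":
        return _read_run_text(path)
    if dialect == "mzml":
        return _read_run_mzml(path)
    raise ValueError(f"unknown run dialect {dialect!r}")


# --------------------------------------------------------------------------
# spectral libraries
# --------------------------------------------------------------------------

@dataclass
class LibraryFile:
    entries: list[LibraryEntry]
    name: str = "library"
    version: str = "1"

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate library entry names: {sorted(dup)}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> LibraryEntry | None:
        for e in self.entries:
            if e.name == name:
                return e
        return None


def write_library(lib: LibraryFile, path: str | Path) -> None:
    root = ET.Element("library", name=lib.name, version=lib.version)
    for e in lib.entries:
        attrs = {"name": e.name, "id_level": str(e.id_level)}
        if e.cas:
            attrs["cas"] = e.cas
        if e.formula:
            attrs["formula"] = e.formula
        if e.exact_mass is not None:
            attrs["exact_mass"] = f"{e.exact_mass:.6f}"
        if e.rt_min is not None:
            attrs["rt_min"] = f"{e.rt_min:.6f}"
        if e.ri is not None:
            attrs["ri"] = f"{e.ri:.2f}"
        el = ET.SubElement(root, "entry", **attrs)
        for mz, inten in e.spectrum:
            ET.SubElement(el, "peak", mz=f"{mz:.6f}", intensity=f"{inten:.4f}")
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def read_library(path: str | Path) -> LibraryFile:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if root.tag != "library":
        raise ParseError(f"{path}: root element is {root.tag!r}, expected 'library'")
    entries = []
    for el in root.findall("entry"):
        peaks = [(float(p.get("mz")), float(p.get("intensity"))) for p in el.findall("peak")]
        if not peaks:
            raise ParseError(f"{path}: entry {el.get('name')!r} has no peaks")
        entries.append(
            LibraryEntry(
                name=el.get("name"),
                spectrum=np.array(peaks),
                cas=el.get("cas", ""),
                formula=el.get("formula", ""),
                exact_mass=float(el.get("exact_mass")) if el.get("exact_mass") else None,
                rt_min=float(el.get("rt_min")) if el.get("rt_min") else None,
                ri=float(el.get("ri")) if el.get("ri") else None,
                id_level=int(el.get("id_level", "2")),
            )
        )
    return LibraryFile(entries=entries, name=root.get("name", "library"), version=root.get("version", "1"))


def write_library_csv(lib: LibraryFile, path: str | Path) -> None:
    """Flat CSV twin of the XML library (peaks packed as mz:int;mz:int...)."""
    rows = []
    for e in lib.entries:
        rows.append(
            {
                "name": e.name,
                "cas": e.cas,
                "formula": e.formula,
                "exact_mass": e.exact_mass,
                "rt_min": e.rt_min,
                "ri": e.ri,
                "id_level": e.id_level,
                "peaks": ";".join(f"{mz:.6f}:{i:.4f}" for mz, i in e.spectrum),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_library_csv(path: str | Path, name: str = "library") -> LibraryFile:
    df = pd.read_csv(path)
    entries = []
    for _, row in df.iterrows():
        peaks = np.array(
            [[float(x) for x in pair.split(":")] for pair in str(row["peaks"]).split(";")]
        )
        entries.append(
            LibraryEntry(
                name=row["name"],
                spectrum=peaks,
                cas="" if pd.isna(row.get("cas")) else str(row["cas"]),
                formula="" if pd.isna(row.get("formula")) else str(row["formula"]),
                exact_mass=None if pd.isna(row.get("exact_mass")) else float(row["exact_mass"]),
                rt_min=None if pd.isna(row.get("rt_min")) else float(row["rt_min"]),
                ri=None if pd.isna(row.get("ri")) else float(row["ri"]),
                id_level=int(row["id_level"]),
            )
        )
    return LibraryFile(entries=entries, name=name)


# --------------------------------------------------------------------------
# RT calibration CSV
# --------------------------------------------------------------------------

RT_CAL_COLUMNS = ["Compound name", "CAS#", "Retention Index", "Retention Time"]


@dataclass
class RTCalibrationTable:
    """Alkane-ladder calibration rows: RI vs retention time (minutes)."""

    table: pd.DataFrame  # columns per RT_CAL_COLUMNS

    def __post_init__(self) -> None:
        t = self.table
        ri = t["Retention Index"].to_numpy(dtype=float)
        rt = t["Retention Time"].to_numpy(dtype=float)
        bad_ri = np.where(np.diff(ri) <= 0)[0]
        bad_rt = np.where(np.diff(rt) <= 0)[0]
        if len(bad_ri) or len(bad_rt):
            rows = sorted(set(bad_ri.tolist()) | set(bad_rt.tolist()))
            raise ParseError(
                "retention index / time must be strictly increasing; "
                f"offending rows (0-based, vs next): {rows}"
            )

    @property
    def carbon_numbers(self) -> np.ndarray:
        return self.table["Retention Index"].to_numpy(dtype=float) / 100.0

    @property
    def rt_seconds(self) -> np.ndarray:
        return self.table["Retention Time"].to_numpy(dtype=float) * 60.0


def read_rt_calibration(path: str | Path) -> RTCalibrationTable:
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[: len(RT_CAL_COLUMNS)] != RT_CAL_COLUMNS:
        missing = [c for c in RT_CAL_COLUMNS if c not in cols]
        if missing:
            raise ParseError(f"{path}: missing required columns {missing}")
        raise ParseError(f"{path}: columns must start with {RT_CAL_COLUMNS}, got {cols}")
    if len(cols) > len(RT_CAL_COLUMNS):
        warnings.warn(
            f"{path}: ignoring extra columns {cols[len(RT_CAL_COLUMNS):]}", stacklevel=2
        )
        df = df[RT_CAL_COLUMNS]
    return RTCalibrationTable(table=df)


def write_rt_calibration(cal: "RTCalibrationTable", path: str | Path) -> None:
    cal.table.to_csv(path, index=False)


# --------------------------------------------------------------------------
# CEF export
# --------------------------------------------------------------------------

MAX_CEF_PEAKS = 10


def export_cef(entities: EntityTable, path: str | Path) -> None:
    """Write an entity table as compound-exchange XML (one Compound per
    entity per sample in which it was detected; at most the 10 most abundant
    spectrum peaks are stored)."""
    if len(entities.entities) == 0:
        raise ValueError("cannot export an empty entity table")
    root = ET.Element("CEF", version="wineomics-1")
    for sample in entities.samples:
        sl = ET.SubElement(
            root, "CompoundList", sample=sample, group=entities.sample_groups[sample]
        )
        for name, area in entities.abundance[sample].items():
            if pd.isna(area):
                continue
            meta = entities.entities.loc[name]
            comp = ET.SubElement(
                sl,
                "Compound",
                name=str(name),
                rt_min=f"{float(meta['rt_min']):.6f}",
                area=f"{float(area):.4f}",
            )
            if not pd.isna(meta.get("ri")):
                comp.set("ri", f"{float(meta['ri']):.2f}")
            if not pd.isna(meta.get("id_level")):
                comp.set("id_level", str(int(meta["id_level"])))
            spec = entities.spectra.get(str(name))
            if spec is not None:
                spec = np.asarray(spec, dtype=float).reshape(-1, 2)
                top = spec[np.argsort(spec[:, 1])[::-1][:MAX_CEF_PEAKS]]
                top = top[np.argsort(top[:, 0])]
                spectrum = ET.SubElement(comp, "Spectrum")
                for mz, inten in top:
                    ET.SubElement(spectrum, "p", x=f"{mz:.6f}", y=f"{inten:.4f}")
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def read_cef(path: str | Path) -> EntityTable:
    """Re-import a CEF document written by :func:`export_cef`."""
    root = ET.parse(path).getroot()
    if root.tag != "CEF":
        raise ParseError(f"{path}: not a CEF document")
    meta: dict[str, dict] = {}
    abundance: dict[str, dict[str, float]] = {}
    groups: dict[str, str] = {}
    spectra: dict[str, np.ndarray] = {}
    for sl in root.findall("CompoundList"):
        sample = sl.get("sample")
        groups[sample] = sl.get("group", sample)
        for comp in sl.findall("Compound"):
            name = comp.get("name")
            meta.setdefault(
                name,
                {
                    "rt_min": float(comp.get("rt_min")),
                    "ri": float(comp.get("ri")) if comp.get("ri") else np.nan,
                    "id_level": int(comp.get("id_level")) if comp.get("id_level") else np.nan,
                    "cas": "",
                    "formula": "",
                },
            )
            abundance.setdefault(name, {})[sample] = float(comp.get("area"))
            spectrum = comp.find("Spectrum")
            if spectrum is not None and name not in spectra:
                spectra[name] = np.array(
                    [[float(p.get("x")), float(p.get("y"))] for p in spectrum.findall("p")]
                )
    names = sorted(meta, key=lambda n: meta[n]["rt_min"])
    entities = pd.DataFrame(
        [meta[n] for n in names], index=pd.Index(names, name="entity")
    )[ENTITY_COLUMNS]
    ab = pd.DataFrame(
        {s: [abundance[n].get(s, np.nan) for n in names] for s in groups},
        index=entities.index,
    )
    return EntityTable(entities=entities, abundance=ab, sample_groups=groups, spectra=spectra)


# --------------------------------------------------------------------------
# reference wine-volatiles table (bundled fixture)
# --------------------------------------------------------------------------

TABLE1_GROUPS = ["LaChanga2017", "LaChanga2018", "LosDolores2017", "LosDolores2018"]
_TABLE1_ABUNDANCE_COLS = {
    "ab_lachanga_2017": "LaChanga2017",
    "ab_lachanga_2018": "LaChanga2018",
    "ab_losdolores_2017": "LosDolores2017",
    "ab_losdolores_2018": "LosDolores2018",
}
_TABLE1_SHA256 = "336f731ff25bb874a03f0df0985148b94f493731b20bb543acd6cf58cbe7ead0"
#: fixture changelog: row 94 (4-Ethylphenol) carries RI 5197 in the source
#: table, violating RI-vs-RT monotonicity between its neighbours (2194, 2274);
#: the loader repairs it to 2197 and logs the repair.
_TABLE1_RI_REPAIRS = {94: 2197.0}


def load_table1_fixture() -> EntityTable:
    """Load the bundled 101-compound wine-volatiles reference table.

    Returns an :class:`EntityTable` with one abundance column per wine group
    (2 vineyards x 2 vintages); ND cells become NaN (missing, never zero).
    The file's checksum is verified before parsing and known transcription
    artifacts are repaired with a log record.
    """
    ref = resources.files("wineomics.data") / "table1_wine_volatiles.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise ValueError(
            f"reference table checksum mismatch: {digest} != {_TABLE1_SHA256}"
        )
    import io

    df = pd.read_csv(io.BytesIO(raw))
    if len(df) != 101:
        raise ValueError(f"reference table must have 101 rows, found {len(df)}")
    for num, fixed in _TABLE1_RI_REPAIRS.items():
        old = float(df.loc[df["num"] == num, "ri"].iloc[0])
        df.loc[df["num"] == num, "ri"] = fixed
        logger.info("repaired RI of row %d: %s -> %s (monotonicity)", num, old, fixed)
    entities = pd.DataFrame(
        {
            "rt_min": df["rt_min"].astype(float).values,
            "ri": df["ri"].astype(float).values,
            "id_level": df["id_level"].astype(int).values,
            "cas": df["cas"].replace("-", "").values,
            "formula": df["formula"].replace("-", "").values,
        },
        index=pd.Index(df["name"], name="entity"),
    )
    ab = pd.DataFrame(index=entities.index)
    for col, group in _TABLE1_ABUNDANCE_COLS.items():
        vals = df[col].replace("ND", np.nan).astype(float).values
        ab[group] = vals
    return EntityTable(
        entities=entities,
        abundance=ab,
        sample_groups={g: g for g in TABLE1_GROUPS},
    )
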