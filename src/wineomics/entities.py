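"""The entity/abundance table shared by QC and differential analysis.

An *entity* is an aligned chromatographic feature (ideally one compound)
observed across samples. Abundances are component areas (counts*s); a cell
that is NaN means *not detected* (ND) — absence under the replicate rule,
never zero signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: entity metadata columns, in canonical order
ENTITY_COLUMNS = ["rt_min", "ri", "id_level", "cas", "formula"]


@dataclass
class EntityTable:
    """Entities x samples abundance matrix with per-entity annotation.

    Attributes
    ----------
    entities:
        DataFrame indexed by entity name with columns ``rt_min``, ``ri``,
        ``id_level``, ``cas``, ``formula`` (missing values allowed).
    abundance:
        DataFrame indexed like ``entities``; one column per sample (or per
        group after replicate aggregation). NaN encodes ND.
    sample_groups:
        Maps each abundance column to its group label (vineyard+vintage for
        wine samples, or a QC role). Group columns map to themselves.
    spectra:
        Optional per-entity spectrum ``(n, 2)`` array of (m/z, rel intensity,
        base peak = 100); carried along so exports can emit peak lists.
    """

    entities: pd.DataFrame
    abundance: pd.DataFrame
    sample_groups: dict[str, str] = field(default_factory=dict)
    spectra: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entities.index.equals(self.abundance.index):
            self.abundance = self.abundance.reindex(self.entities.index)
        if not self.entities.index.is_unique:
            dup = self.entities.index[self.entities.index.duplicated()].tolist()
            raise ValueError(f"duplicate entity names: {dup}")
        bad = self.abundance.le(0.0)
        if bool(bad.any().any()):
            raise ValueError("non-ND abundances must be positive")
        for col in self.abundance.columns:
            self.sample_groups.setdefault(col, col)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples:
            g = self.sample_groups[c]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, group: str) -> list[str]:
        return [c for c in self.samples if self.sample_groups[c] == group]

    def presence(self) -> pd.DataFrame:
        """Boolean entities x samples detection matrix (non-ND)."""
        return self.abundance.notna()

    def presence_sets(self) -> dict[str, set[str]]:
        """Per group: the set of entity names detected in *every* sample of
        that group (for group-level columns this is simply non-ND)."""
        pres = self.presence()
        out: dict[str, set[str]] = {}
        for g in self.groups:
            cols = self.samples_of(g)
            mask = pres[cols].all(axis=1)
            out[g] = set(self.entities.index[mask])
        return out

    def subset_samples(self, samples: list[str]) -> "EntityTable":
        return EntityTable(
            entities=self.entities.copy(),
            abundance=self.abundance[samples].copy(),
            sample_groups={s: self.sample_groups[s] for s in samples},
            spectra=dict(self.spectra),
        )

    def copy(self) -> "EntityTable":
        return EntityTable(
            entities=self.entities.copy(),
            abundance=self.abundance.copy(),
            sample_groups=dict(self.sample_groups),
            spectra=dict(self.spectra),
        )
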