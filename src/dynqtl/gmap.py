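"""Genetic map container: ordered linkage groups with cM marker positions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeneticMap:
    """Ordered genetic map.

    Parameters
    ----------
    table:
        DataFrame with columns ``marker``, ``group``, ``cm``.  Rows must be
        ordered by linkage group and, within a group, by non-decreasing
        position.  Marker labels must be unique.
    """

    table: pd.DataFrame
    _pos: dict = field(init=False, repr=False)
    _grp: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "group", "cm"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"map table lacks columns: {sorted(missing)}")
        t = t.reset_index(drop=True)
        if t["marker"].duplicated().any():
            dups = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker labels in map: {dups[:5]}")
        if (t["cm"] < 0).any():
            raise ValueError("negative cM positions in map")
        for g, sub in t.groupby("group", sort=False):
            if not np.all(np.diff(sub["cm"].to_numpy()) >= 0):
                raise ValueError(f"positions not non-decreasing in group {g}")
        if t["group"].nunique() < 1:
            raise ValueError("map must contain at least one linkage group")
        self.table = t
        self._pos = dict(zip(t["marker"], t["cm"].astype(float)))
        self._grp = dict(zip(t["marker"], t["group"]))

    # -- basic accessors ---------------------------------------------------
    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.table["marker"])

    @property
    def groups(self) -> list:
        """Linkage-group labels in map order."""
        return list(dict.fromkeys(self.table["group"]))

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def position(self, marker: str) -> float:
        return self._pos[marker]

    def group(self, marker: str) -> str:
        return self._grp[marker]

    def has_marker(self, marker: str) -> bool:
        return marker in self._pos

    def group_table(self, group) -> pd.DataFrame:
        return self.table[self.table["group"] == group]

    def within_window(self, a: str, b: str, window_cm: float) -> bool:
        """True if two markers lie on one group within ``window_cm`` cM."""
        if self._grp[a] != self._grp[b]:
            return False
        return abs(self._pos[a] - self._pos[b]) <= window_cm

    # -- construction helpers ---------------------------------------------
    @classmethod
    def from_arrays(cls, markers, groups, positions) -> "GeneticMap":
        return cls(pd.DataFrame({"marker": markers, "group": groups,
                                 "cm": positions}))

    @classmethod
    def uniform(cls, group_sizes: dict, length_cm: float = 140.0) -> "GeneticMap":
        """Evenly spaced markers: ``group_sizes`` maps group -> n markers."""
        rows = []
        for g, n in group_sizes.items():
            pos = np.linspace(0.0, length_cm, n)
            for i, p in enumerate(pos):
                rows.append((f"{g}_{i:02d}", g, float(p)))
        return cls(pd.DataFrame(rows, columns=["marker", "group", "cm"]))
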