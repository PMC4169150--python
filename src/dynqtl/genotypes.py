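"""Genotype matrix for DH lines: 0/1 calls, missing mask, family labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Lines x markers biallelic genotype calls.

    ``calls`` is a float array with values in {0.0, 1.0, NaN}; NaN encodes a
    missing call.  DH lines are fully homozygous, so a single allele dose per
    marker suffices.  ``families`` assigns every line to exactly one family.
    """

    calls: np.ndarray
    lines: pd.Index
    markers: pd.Index
    families: pd.Series  # index = lines, values = family labels
    _col: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        self.lines = pd.Index(self.lines)
        self.markers = pd.Index(self.markers)
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError("calls shape does not match lines x markers")
        if self.lines.duplicated().any():
            raise ValueError("duplicate line ids")
        if self.markers.duplicated().any():
            raise ValueError("duplicate marker labels")
        ok = np.isnan(self.calls) | (self.calls == 0.0) | (self.calls == 1.0)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"non-binary genotype at line {self.lines[i]} "
                f"marker {self.markers[j]}")
        self.families = pd.Series(self.families).reindex(self.lines)
        if self.families.isna().any():
            missing = list(self.families.index[self.families.isna()])[:5]
            raise ValueError(f"lines without family assignment: {missing}")
        self._col = {m: j for j, m in enumerate(self.markers)}

    # -- shape / access ----------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.calls).any())

    def column(self, marker: str) -> np.ndarray:
        return self.calls[:, self._col[marker]]

    def columns(self, markers) -> np.ndarray:
        idx = [self._col[m] for m in markers]
        return self.calls[:, idx]

    def marker_index(self, marker: str) -> int:
        return self._col[marker]

    def subset_lines(self, lines) -> "GenotypeMatrix":
        idx = self.lines.get_indexer(lines)
        if (idx < 0).any():
            raise KeyError("unknown line ids in subset")
        return GenotypeMatrix(self.calls[idx], pd.Index(lines), self.markers,
                              self.families.loc[lines])

    def polymorphic_mask(self) -> np.ndarray:
        """Boolean per marker: at least two distinct non-missing calls."""
        with np.errstate(invalid="ignore"):
            mn = np.nanmin(self.calls, axis=0)
            mx = np.nanmax(self.calls, axis=0)
        return ~np.isnan(mn) & (mx > mn)

    def impute_family_mean(self) -> np.ndarray:
        """Calls with missing entries replaced by the family allele frequency.

        Used only for cofactor screening; inference fits stay complete-case.
        """
        out = self.calls.copy()
        fam = self.families.to_numpy()
        for f in pd.unique(fam):
            rows = fam == f
            block = out[rows]
            mu = np.nanmean(np.where(np.isnan(block), np.nan, block), axis=0)
            mu = np.where(np.isnan(mu), np.nanmean(out, axis=0), mu)
            nanmask = np.isnan(block)
            block[nanmask] = np.broadcast_to(mu, block.shape)[nanmask]
            out[rows] = block
        # Columns missing everywhere fall back to 0.5.
        out[np.isnan(out)] = 0.5
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.lines, columns=self.markers)
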