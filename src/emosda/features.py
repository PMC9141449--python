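"""Named feature table with per-feature family provenance."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Known feature families (provenance tags).
FAMILIES = ("stats", "hjorth", "nsi", "fd", "hoc", "powerlaw", "bandpower",
            "hos", "msce", "dasm", "rasm", "dwt", "hhs", "code", "pca")


@dataclass
class FeatureTable:
    """Instances x named features, each feature tagged with its family."""

    values: np.ndarray            # (n_instances, n_features)
    names: list[str]
    family: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names length must match column count")
        if len(self.family) != self.values.shape[1]:
            raise ValueError("family length must match column count")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def impute_median(self) -> "FeatureTable":
        """Replace NaNs with the column median (all-NaN columns become 0)."""
        vals = self.values.copy()
        for j in range(vals.shape[1]):
            col = vals[:, j]
            bad = ~np.isfinite(col)
            if bad.any():
                good = col[~bad]
                fill = float(np.median(good)) if good.size else 0.0
                col[bad] = fill
        return FeatureTable(vals, list(self.names), list(self.family))

    def select(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(self.values[:, mask],
                            [n for n, m in zip(self.names, mask) if m],
                            [f for f, m in zip(self.family, mask) if m])

    def hstack(self, other: "FeatureTable") -> "FeatureTable":
        if other.n_instances != self.n_instances:
            raise ValueError("instance counts differ")
        return FeatureTable(np.hstack([self.values, other.values]),
                            self.names + other.names,
                            self.family + other.family)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def family_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.family:
            out[f] = out.get(f, 0) + 1
        return out
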