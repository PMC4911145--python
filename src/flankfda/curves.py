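"""Shared curve/scalar containers and their TSV round-trips."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MEASURES = ("content", "count", "weighted_average")


def window_labels(k: int) -> list[str]:
    """Window labels ``-K/2 .. -1, +1 .. +K/2`` around the integration site."""
    if k % 2 != 0 or k < 2:
        raise ValueError("number of windows must be even and >= 2")
    half = k // 2
    return [str(i) for i in range(-half, 0)] + [f"+{i}" for i in range(1, half + 1)]


@dataclass
class CurveMatrix:
    """Per-region, per-window signal of one feature.

    ``values`` is an (n_regions, K) matrix; window order follows the
    element orientation (upstream windows first, then downstream).
    """

    feature_name: str
    measure: str
    values: np.ndarray
    region_ids: list[str]
    window_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, k = self.values.shape
        if len(self.region_ids) != n:
            raise ValueError("region_ids length does not match values")
        if not self.window_labels:
            self.window_labels = window_labels(k)
        elif len(self.window_labels) != k:
            raise ValueError("window_labels length does not match values")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def validate_measure(self) -> None:
        """Check the matrix against its measure's value bounds."""
        v = self.values
        if not np.isfinite(v).all():
            raise ValueError(f"{self.feature_name}: non-finite values")
        if self.measure == "content" and ((v < 0) | (v > 1)).any():
            raise ValueError(f"{self.feature_name}: content outside [0, 1]")
        if self.measure == "count" and ((v < 0) | (v != np.round(v))).any():
            raise ValueError(f"{self.feature_name}: counts must be integers >= 0")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.window_labels)
        df.insert(0, "region_id", self.region_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, feature_name: str | None = None, measure: str = "weighted_average"
    ) -> "CurveMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
        if "region_id" not in df.columns:
            raise ValueError(f"{path}: missing region_id column")
        ids = df.pop("region_id").tolist()
        name = feature_name if feature_name is not None else Path(path).stem
        return cls(
            feature_name=name,
            measure=measure,
            values=df.to_numpy(dtype=float),
            region_ids=ids,
            window_labels=list(df.columns),
        )


@dataclass
class ScalarFeatureTable:
    """One value per region for a low-resolution feature."""

    feature_name: str
    values: np.ndarray
    region_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.region_ids) != len(self.values):
            raise ValueError("region_ids length does not match values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region_id": self.region_ids, self.feature_name: self.values}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScalarFeatureTable":
        df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
        cols = [c for c in df.columns if c != "region_id"]
        if len(cols) != 1:
            raise ValueError(f"{path}: expected exactly one value column")
        return cls(
            feature_name=cols[0],
            values=df[cols[0]].to_numpy(dtype=float),
            region_ids=df["region_id"].astype(str).tolist(),
        )
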