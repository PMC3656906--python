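"""Source-space time-series container and its on-disk CSV + JSON format.

A :class:`SourceTimeSeries` holds a regions × samples matrix of source
waveforms with its sampling rate and study labels. On disk it is a CSV
(rows = regions, first column = region label, remaining columns =
samples) plus a JSON sidecar carrying sampling rate, band tag and
subject/condition metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BandDefinition, get_band


@dataclass
class SourceTimeSeries:
    """Multichannel source time series (regions × samples)."""

    data: np.ndarray
    fs: float
    region_labels: list[str]
    band: BandDefinition | None = None  # None = broadband / unfiltered
    subject_id: str | None = None
    group: str | None = None
    condition: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D, got shape {self.data.shape}")
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} region labels for "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"non-finite sample at region {self.region_labels[r]!r} "
                f"(row {r}), sample column {c}"
            )
        if self.band is not None:
            self.band.validate_for_fs(self.fs)

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, *, band: BandDefinition | None = None,
                  fs: float | None = None) -> "SourceTimeSeries":
        """Copy carrying new samples (and optionally a new band/fs tag)."""
        return replace(
            self,
            data=data,
            band=self.band if band is None else band,
            fs=self.fs if fs is None else fs,
        )

    def trim(self, n_edge: int) -> "SourceTimeSeries":
        """Drop ``n_edge`` samples from each end (filter settling)."""
        if n_edge < 0 or 2 * n_edge >= self.n_samples:
            raise ValueError(
                f"cannot trim {n_edge} samples from each end of "
                f"{self.n_samples} samples"
            )
        if n_edge == 0:
            return self
        return self.with_data(self.data[:, n_edge:-n_edge])

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> Path:
        """Write CSV (rows = regions) plus a ``.json`` sidecar; return CSV path."""
        path = Path(path)
        df = pd.DataFrame(self.data, index=self.region_labels)
        df.index.name = "region"
        df.to_csv(path, float_format="%.10g")
        sidecar = {
            "fs": self.fs,
            "region_labels": self.region_labels,
            "band": self.band.name if self.band is not None else None,
            "band_edges_hz": (
                [self.band.low_hz, self.band.high_hz] if self.band else None
            ),
            "subject_id": self.subject_id,
            "group": self.group,
            "condition": self.condition,
            "n_samples": self.n_samples,
            **self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SourceTimeSeries":
        """Read a CSV + JSON sidecar pair written by :meth:`to_csv`."""
        path = Path(path)
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(
                f"missing JSON sidecar {sidecar_path} for {path}"
            )
        sidecar = json.loads(sidecar_path.read_text())
        if "fs" not in sidecar:
            raise ValueError(f"sidecar {sidecar_path} lacks required field 'fs'")
        df = pd.read_csv(path, index_col=0)
        data = df.to_numpy(dtype=float)
        labels = [str(x) for x in df.index]
        if sidecar.get("region_labels") and sidecar["region_labels"] != labels:
            raise ValueError(
                f"region labels in {path} do not match sidecar "
                f"{sidecar_path}"
            )
        band = None
        if sidecar.get("band"):
            edges = sidecar.get("band_edges_hz")
            band = (BandDefinition(sidecar["band"], *edges) if edges
                    else get_band(sidecar["band"]))
        known = {"fs", "region_labels", "band", "band_edges_hz", "subject_id",
                 "group", "condition", "n_samples"}
        return cls(
            data=data,
            fs=float(sidecar["fs"]),
            region_labels=labels,
            band=band,
            subject_id=sidecar.get("subject_id"),
            group=sidecar.get("group"),
            condition=sidecar.get("condition"),
            meta={k: v for k, v in sidecar.items() if k not in known},
        )
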