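"""Degree-based hub identification on significance-masked networks.

A node is a network hub when its degree is at least one standard
deviation above the network's mean degree. Degree is the count of
nonzero incident edges by default (binary mode); a weighted mode (sum
of absolute edge values, i.e. node strength) is provided for
sensitivity analysis. The standard deviation defaults to the
population form (divisor N), the network's nodes being the full
population of interest; the sample form is available via ``sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rois import roi_of_label


def node_degrees(network: np.ndarray, mode: str = "binary") -> np.ndarray:
    """Per-node degree of a symmetric masked network (zeros = no edge).

    ``binary`` counts nonzero incident edges; ``weighted`` sums their
    absolute values (node strength). The diagonal is ignored.
    """
    m = np.asarray(network, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"network must be square, got {m.shape}")
    if not np.allclose(m, m.T):
        raise ValueError("network must be symmetric")
    off = m - np.diag(np.diag(m))
    if mode == "binary":
        return (off != 0).sum(axis=1).astype(float)
    if mode == "weighted":
        return np.abs(off).sum(axis=1)
    raise ValueError(f"unknown degree mode {mode!r}")


@dataclass
class HubConfiguration:
    """Hub set of one network: degrees, threshold and member nodes."""

    node_labels: list[str]
    degrees: np.ndarray
    mean_degree: float
    sd_degree: float
    threshold: float  # mean + 1 SD
    hubs: list[str]
    mode: str = "binary"
    sd_convention: str = "population"
    band: str | None = None
    condition: str | None = None

    @property
    def hub_rois(self) -> list[str]:
        """ROI names with at least one hub hemispheric node, in label order."""
        seen: list[str] = []
        for lab in self.hubs:
            roi = roi_of_label(lab) if "_" in lab else lab
            if roi not in seen:
                seen.append(roi)
        return seen

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": self.node_labels,
            "degree": self.degrees,
            "is_hub": [lab in self.hubs for lab in self.node_labels],
        })


def identify_hubs(
    degrees: np.ndarray,
    node_labels: list[str] | None = None,
    *,
    sd: str = "population",
    mode: str = "binary",
    band: str | None = None,
    condition: str | None = None,
) -> HubConfiguration:
    """Apply the mean-plus-one-SD hub rule to a degree vector.

    Hubs are nodes with degree >= mean + 1·SD ("at least one standard
    deviation greater than the average"). When every node has the same
    degree (SD = 0) the hub set is empty — the rule would otherwise
    degenerate to declaring every node a hub.
    """
    deg = np.asarray(degrees, dtype=float)
    if deg.ndim != 1 or deg.size < 2:
        raise ValueError("need degrees for at least 2 nodes")
    labels = node_labels or [f"node{i}" for i in range(deg.size)]
    if len(labels) != deg.size:
        raise ValueError("label count does not match degree vector")
    if sd not in ("population", "sample"):
        raise ValueError(f"unknown SD convention {sd!r}")
    mean = float(deg.mean())
    sd_val = float(deg.std(ddof=0 if sd == "population" else 1))
    threshold = mean + sd_val
    hubs = ([] if sd_val == 0.0
            else [lab for lab, d in zip(labels, deg) if d >= threshold])
    return HubConfiguration(
        node_labels=list(labels), degrees=deg, mean_degree=mean,
        sd_degree=sd_val, threshold=threshold, hubs=hubs, mode=mode,
        sd_convention=sd, band=band, condition=condition,
    )


def hubs_from_network(
    network: np.ndarray,
    node_labels: list[str],
    *,
    mode: str = "binary",
    sd: str = "population",
    band: str | None = None,
    condition: str | None = None,
) -> HubConfiguration:
    """Degrees plus hub rule in one step."""
    deg = node_degrees(network, mode=mode)
    return identify_hubs(deg, node_labels, sd=sd, mode=mode, band=band,
                         condition=condition)


def hub_configuration_table(
    configs: dict[tuple[str, str], HubConfiguration],
    bands: list[str],
    conditions: list[str],
    *,
    roi_level: bool = True,
) -> pd.DataFrame:
    """Band × condition grid of hub lists (ROI-level by default).

    ``configs`` is either a mapping (band, condition) -> HubConfiguration
    or an iterable of tagged HubConfigurations; one entry per cell.
    Duplicate (band, condition) entries are an error. Missing cells are
    filled with the marker ``"(missing)"`` rather than silently skipped.
    """
    if not isinstance(configs, dict):
        as_dict: dict[tuple[str, str], HubConfiguration] = {}
        for cfg in configs:
            key = (cfg.band, cfg.condition)
            if None in key:
                raise ValueError("untagged HubConfiguration in table input")
            if key in as_dict:
                raise ValueError(f"duplicate (band, condition) entry {key}")
            as_dict[key] = cfg
        configs = as_dict
    grid: dict[str, dict[str, str]] = {}
    for (band, cond), cfg in configs.items():
        if cfg.band is not None and cfg.band != band:
            raise ValueError(
                f"config tagged band={cfg.band!r} filed under {band!r}")
        if cfg.condition is not None and cfg.condition != cond:
            raise ValueError(
                f"config tagged condition={cfg.condition!r} filed under {cond!r}")
    for band in bands:
        row = {}
        for cond in conditions:
            cfg = configs.get((band, cond))
            if cfg is None:
                row[cond] = "(missing)"
            else:
                names = cfg.hub_rois if roi_level else cfg.hubs
                row[cond] = ", ".join(names)
        grid[band] = row
    table = pd.DataFrame.from_dict(grid, orient="index", columns=conditions)
    table.index.name = "band"
    return table
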