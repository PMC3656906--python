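"""End-to-end band-specific connectivity pipeline.

For each of the five canonical bands the pipeline band-passes every
subject's broadband record, discards the filter settling edges,
estimates each subject's 16-node partial-correlation matrix, and forms
three group networks: REST (all subjects' rest records pooled), and the
post-intervention networks of the sham ("NAP") and verum ("ST36")
groups. Each network is FDR-masked, collapsed to the 8 ROI nodes,
scanned for hubs, and the rest → post edge changes of each group are
classified with paired t-tests. Outputs are CSV/JSON/Markdown files
plus a manifest with per-file checksums; identical config + seed give
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import BAND_ORDER, CANONICAL_BANDS
from .connectivity import (
    classify_edge_changes,
    collapse_bilateral_max,
    collapse_subject_values,
    group_mean_network,
    paired_edge_comparison,
    partial_correlation_matrix,
)
from .hubs import hub_configuration_table, hubs_from_network
from .rois import ROI_ORDER
from .spectral import apply_bandpass, settle_samples
from .synthetic import PrecisionSpec, StudyBundle, StudyDesign, \
    simulate_group_study
from .timeseries import SourceTimeSeries

logger = logging.getLogger("dmnconn")

#: Display names for the three group-network columns.
CONDITION_COLUMNS = ["REST", "NAP", "ST36"]


@dataclass
class PipelineConfig:
    """All parameters that affect pipeline results.

    Either ``input_dir`` (a directory of CSV + JSON sidecar recordings)
    or ``synthetic`` (a StudyDesign, with optional planted structure)
    must be provided. Every field is serialized into the run manifest.
    """

    output_dir: str = "dmnconn-out"
    input_dir: str | None = None
    synthetic: StudyDesign | None = None
    synthetic_base: PrecisionSpec | dict[str, PrecisionSpec] | None = None
    bands: list[str] = field(default_factory=lambda: list(BAND_ORDER))
    q: float = 0.05
    paired_alpha: float = 0.05
    degree_mode: str = "binary"
    sd_convention: str = "population"
    filter_order: int = 5
    settle_cycles: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.input_dir is None and self.synthetic is None:
            raise ValueError("config needs input_dir or a synthetic design")
        unknown = set(self.bands) - set(CANONICAL_BANDS)
        if unknown:
            raise ValueError(f"unknown bands {sorted(unknown)}")
        if not (0 < self.q < 1) or not (0 < self.paired_alpha < 1):
            raise ValueError("q and paired_alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML/JSON; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("synthetic"), dict):
            syn = dict(raw["synthetic"])
            if "bands_with_effects" in syn:
                syn["bands_with_effects"] = {
                    b: {tuple(json.loads(e)) if isinstance(e, str) else
                        tuple(e): d for e, d in eff.items()}
                    for b, eff in syn["bands_with_effects"].items()
                }
            raw["synthetic"] = StudyDesign(**syn)
        if isinstance(raw.get("synthetic_base"), dict) and \
                "support" in raw["synthetic_base"]:
            sb = dict(raw["synthetic_base"])
            sb["support"] = tuple(tuple(e) for e in sb["support"])
            raw["synthetic_base"] = PrecisionSpec(**sb)
        return cls(**raw)

    def to_jsonable(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(x)
                        for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, dict):
                return {str(k): enc(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [enc(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    version: str
    checksums: dict[str, str]
    warnings: list[str]
    counts: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def read_timeseries_matrix(path: str | Path) -> SourceTimeSeries:
    """Read one CSV + JSON sidecar recording (validated)."""
    return SourceTimeSeries.from_csv(path)


def load_study(input_dir: str | Path) -> list[SourceTimeSeries]:
    """Load every ``*.csv`` recording under a directory."""
    paths = sorted(Path(input_dir).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no CSV recordings under {input_dir}")
    return [read_timeseries_matrix(p) for p in paths]


def write_study(bundle: StudyBundle, out_dir: str | Path) -> list[Path]:
    """Write every recording of a simulated study as CSV + sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in bundle.recordings:
        p = out_dir / f"{rec.subject_id}_{rec.condition}.csv"
        rec.timeseries.to_csv(p)
        paths.append(p)
    (out_dir / "ground_truth.json").write_text(
        json.dumps(bundle.ledger, indent=1))
    return paths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_matrix(path: Path, matrix: np.ndarray, labels: list[str]) -> None:
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.to_csv(path, float_format="%.6g")


def _subject_matrices(records, band, cfg) -> dict[str, np.ndarray]:
    """subject_id -> 16-node partial-correlation matrix in one band."""
    out = {}
    trim = None
    for rec in records:
        ts = apply_bandpass(rec.timeseries if hasattr(rec, "timeseries")
                            else rec, band, order=cfg.filter_order)
        if trim is None:
            trim = min(settle_samples(band, ts.fs, cfg.settle_cycles),
                       (ts.n_samples - 2) // 2)
        ts = ts.trim(trim)
        sid = rec.subject_id if hasattr(rec, "subject_id") else ts.subject_id
        out[sid] = partial_correlation_matrix(ts)
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full band-specific connectivity analysis.

    Writes, per band: the three 16-node masked group networks, their
    8-node collapsed versions, an edge-change table per group, and
    per-node degree tables; plus a hub-configuration grid and the run
    manifest. An ``INCOMPLETE`` marker exists in the output directory
    until the manifest has been written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress or aborted\n")
    warnings_log: list[str] = []
    counts: dict = {}
    checks: dict[str, str] = {}

    import warnings as _w

    def record(path: Path):
        checks[str(path.relative_to(out))] = _sha256(path)

    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        # ---- inputs ------------------------------------------------------
        if config.synthetic is not None:
            design = dataclasses.replace(config.synthetic, seed=config.seed)
            base = config.synthetic_base or PrecisionSpec(
                n_regions=len(design.region_labels), support=())
            bundle = simulate_group_study(design, base)
            recordings = bundle.recordings
            groups = list(design.groups)
            cond_rest, cond_post = design.conditions
            logger.info("simulated study: %d recordings", len(recordings))
        else:
            all_ts = load_study(config.input_dir)
            conds = sorted({t.condition for t in all_ts})
            if len(conds) != 2:
                raise ValueError(f"expected 2 conditions, found {conds}")
            cond_rest, cond_post = (
                ("rest", next(c for c in conds if c != "rest"))
                if "rest" in conds else tuple(conds))
            groups = sorted({t.group for t in all_ts})

            @dataclass
            class _Rec:
                group: str
                subject_id: str
                condition: str
                timeseries: SourceTimeSeries
            recordings = [_Rec(t.group, t.subject_id, t.condition, t)
                          for t in all_ts]
            logger.info("loaded %d recordings from %s", len(recordings),
                        config.input_dir)
        sham = next((g for g in groups if g in ("sham", "NAP")), groups[-1])
        verum = next((g for g in groups if g in ("verum", "ST36")), groups[0])
        labels = recordings[0].timeseries.region_labels

        hub_configs = {}
        # ---- per band ----------------------------------------------------
        for band_name in config.bands:
            band = CANONICAL_BANDS[band_name]
            rest_recs = [r for r in recordings if r.condition == cond_rest]
            mats_rest = _subject_matrices(rest_recs, band, config)
            group_nets = {}
            collapsed = {}
            subj_mats = {"REST": mats_rest}
            for col, sel in (("REST", None), ("NAP", sham), ("ST36", verum)):
                if col == "REST":
                    mats = mats_rest
                else:
                    recs = [r for r in recordings
                            if r.condition == cond_post and r.group == sel]
                    mats = _subject_matrices(recs, band, config)
                    subj_mats[col] = mats
                stats = group_mean_network(
                    list(mats.values()), region_labels=labels, q=config.q,
                    band=band_name, condition=col)
                group_nets[col] = stats
                collapsed[col] = collapse_bilateral_max(
                    stats.matrix(), labels, ROI_ORDER)
                p16 = out / f"{band_name}_{col}_network16.csv"
                _write_matrix(p16, stats.matrix(), labels)
                record(p16)
                p8 = out / f"{band_name}_{col}_network8.csv"
                _write_matrix(p8, collapsed[col].values, ROI_ORDER)
                record(p8)
                cfg_h = hubs_from_network(
                    stats.matrix(), labels, mode=config.degree_mode,
                    sd=config.sd_convention, band=band_name, condition=col)
                hub_configs[(band_name, col)] = cfg_h
                pdeg = out / f"{band_name}_{col}_degrees.csv"
                cfg_h.to_frame().to_csv(pdeg, index=False,
                                        float_format="%.6g")
                record(pdeg)
                logger.info(
                    "band=%s cond=%s subjects=%d edges_sig=%d hubs=%s",
                    band_name, col, stats.n_subjects,
                    int(stats.significant.sum()), cfg_h.hubs)
            # paired comparisons per group, on collapsed subject values
            table_rows = {}
            for col, grp in (("NAP", sham), ("ST36", verum)):
                prov = {}
                for key in collapsed[col].provenance:
                    prov[key] = (collapsed[col].provenance[key]
                                 or collapsed["REST"].provenance[key])
                grp_rest = [r for r in recordings
                            if r.group == grp and r.condition == cond_rest]
                sids = [r.subject_id for r in grp_rest]
                rest_vals = {
                    sid: collapse_subject_values(
                        mats_rest[sid], labels, prov, ROI_ORDER)
                    for sid in sids}
                post_vals = {
                    sid: collapse_subject_values(
                        subj_mats[col][sid], labels, prov, ROI_ORDER)
                    for sid in sids}
                paired = {}
                for a in range(len(ROI_ORDER)):
                    for b in range(a + 1, len(ROI_ORDER)):
                        key = (ROI_ORDER[a], ROI_ORDER[b])
                        rv = collapsed["REST"].values[a, b]
                        pv = collapsed[col].values[a, b]
                        if rv != 0.0 and pv != 0.0:
                            paired[key] = paired_edge_comparison(
                                [rest_vals[s][a, b] for s in sids],
                                [post_vals[s][a, b] for s in sids])
                changes = classify_edge_changes(
                    collapsed["REST"], collapsed[col], paired,
                    alpha=config.paired_alpha)
                table_rows[col] = changes
                pch = out / f"{band_name}_{col}_changes.csv"
                changes.to_csv(pch, index=False, float_format="%.6g")
                record(pch)
            # long-format band table: edge, rest, per-group post and p
            merged = table_rows["NAP"][
                ["roi_a", "roi_b", "rest", "post", "paired_p", "category"]
            ].rename(columns={"post": "NAP", "paired_p": "p_NAP",
                              "category": "category_NAP"})
            st = table_rows["ST36"]
            merged["ST36"] = st["post"]
            merged["p_ST36"] = st["paired_p"]
            merged["category_ST36"] = st["category"]
            pband = out / f"{band_name}_band_table.csv"
            merged.to_csv(pband, index=False, float_format="%.6g")
            record(pband)

        # ---- hub grid ----------------------------------------------------
        grid = hub_configuration_table(hub_configs, config.bands,
                                       CONDITION_COLUMNS)
        pgrid = out / "hub_grid.csv"
        grid.to_csv(pgrid)
        record(pgrid)
        pmd = out / "hub_grid.md"
        lines = ["| band | " + " | ".join(CONDITION_COLUMNS) + " |",
                 "|---" * (len(CONDITION_COLUMNS) + 1) + "|"]
        for b in config.bands:
            lines.append("| " + " | ".join(
                [b] + [grid.loc[b, c] or "—" for c in CONDITION_COLUMNS]) + " |")
        pmd.write_text("\n".join(lines) + "\n")
        record(pmd)
        pjson = out / "hub_grid.json"
        pjson.write_text(json.dumps(
            {b: {c: grid.loc[b, c] for c in CONDITION_COLUMNS}
             for b in config.bands}, indent=1))
        record(pjson)
        counts["n_recordings"] = len(recordings)
        counts["n_bands"] = len(config.bands)
        warnings_log.extend(str(w.message) for w in caught)

    manifest = RunManifest(
        config=config.to_jsonable(), version=__version__,
        checksums=checks, warnings=warnings_log, counts=counts,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    marker.unlink()
    return manifest
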