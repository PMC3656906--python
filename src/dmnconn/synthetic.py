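"""Synthetic study generator with known conditional-dependence structure.

The study's recordings are not deposited, so every downstream stage is
exercised on simulated data whose ground truth is known exactly. The
signal model is a zero-mean Gaussian, i.i.d. in time, whose covariance is
the inverse of a constructed sparse precision matrix; every channel is
then passed through the same zero-phase band-pass filter. A common
linear filter leaves the instantaneous cross-channel correlation — and
hence the partial-correlation structure that the estimator targets —
unchanged, while honoring the band limits of the emulated recordings.
Broadband records are the sum of five independent band components, one
per canonical band, each with its own precision matrix.

A full study mirrors the emulated design: two groups of 14 subjects
("verum" and "sham" stimulation), each recorded at rest and after the
intervention, sampled at 300 Hz. Planted post-condition effects change
selected partial correlations in selected bands in the verum group only.
The generator's default record length is a desk-scale 36 s (10,800
samples); the emulated recordings are 360 s (108,000 samples) and can be
requested by setting ``duration_s=360``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .bands import BAND_ORDER, BandDefinition, CANONICAL_BANDS, get_band
from .rois import default_region_labels
from .spectral import apply_bandpass, settle_samples
from .timeseries import SourceTimeSeries

#: SPD margin: smallest admissible eigenvalue of a constructed precision.
SPD_MARGIN = 1e-6

Edge = tuple[int, int]


def _canon_edge(edge, labels: list[str] | None, n: int) -> Edge:
    a, b = edge
    if isinstance(a, str) or isinstance(b, str):
        if labels is None:
            raise ValueError(f"string edge {edge} but no region labels")
        a = labels.index(a) if isinstance(a, str) else a
        b = labels.index(b) if isinstance(b, str) else b
    a, b = int(a), int(b)
    if a == b:
        raise ValueError(f"self-pair edge ({a}, {b}) not allowed")
    if not (0 <= a < n and 0 <= b < n):
        raise ValueError(f"edge ({a}, {b}) outside 0..{n - 1}")
    return (min(a, b), max(a, b))


@dataclass(frozen=True)
class PrecisionSpec:
    """Ground-truth sparse precision (inverse covariance) specification.

    ``support`` lists the planted direct (conditional-dependence) edges;
    ``strength`` is the theoretical partial correlation on those edges —
    a single value for all, or a per-edge mapping. Signed strengths are
    allowed; magnitudes must stay in (0, 1) and jointly feasible (the
    implied matrix must remain positive-definite).
    """

    n_regions: int = 16
    support: tuple[Edge, ...] = ()
    strength: float | dict[Edge, float] = 0.4
    region_labels: tuple[str, ...] | None = None
    seed: int = 0

    def edge_strengths(self) -> dict[Edge, float]:
        labels = list(self.region_labels) if self.region_labels else None
        if isinstance(self.strength, dict):
            out = {_canon_edge(e, labels, self.n_regions): float(s)
                   for e, s in self.strength.items()}
        else:
            out = {_canon_edge(e, labels, self.n_regions): float(self.strength)
                   for e in self.support}
        for e, s in out.items():
            if not (0.0 < abs(s) < 1.0):
                raise ValueError(
                    f"edge {e}: strength magnitude must be in (0, 1), got {s}")
        return out


def make_precision_matrix(spec: PrecisionSpec) -> np.ndarray:
    """Build the precision matrix implied by a :class:`PrecisionSpec`.

    Unit diagonal; entry (j, k) = −s_jk on planted edges, so the
    theoretical partial correlation −P_jk/√(P_jj P_kk) equals s_jk
    exactly. Raises if the requested strengths make the matrix
    non-positive-definite (infeasible spec).
    """
    n = spec.n_regions
    if n < 1:
        raise ValueError("need at least one region")
    p = np.eye(n)
    for (j, k), s in spec.edge_strengths().items():
        p[j, k] = p[k, j] = -s
    min_eig = float(np.linalg.eigvalsh(p)[0])
    if min_eig <= SPD_MARGIN:
        raise ValueError(
            f"infeasible precision spec: smallest eigenvalue {min_eig:.3g} "
            f"<= margin {SPD_MARGIN:g}; reduce strengths or edge degrees"
        )
    return p


def theoretical_partial_correlation(precision: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix implied by a precision matrix."""
    precision = np.asarray(precision, dtype=float)
    d = np.sqrt(np.diag(precision))
    r = -precision / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def _check_spd(precision: np.ndarray) -> np.ndarray:
    precision = np.asarray(precision, dtype=float)
    if precision.ndim != 2 or precision.shape[0] != precision.shape[1]:
        raise ValueError("precision must be square")
    if not np.allclose(precision, precision.T):
        raise ValueError("precision must be symmetric")
    if np.linalg.eigvalsh(precision)[0] <= 0:
        raise ValueError("precision must be positive-definite")
    return precision


def simulate_timeseries(
    precision: np.ndarray,
    n_samples: int,
    fs: float = 300.0,
    band: BandDefinition | str | None = None,
    seed: int | np.random.SeedSequence = 0,
    region_labels: list[str] | None = None,
    **labels,
) -> SourceTimeSeries:
    """Draw one record from the latent-Gaussian band-limited model.

    Samples are i.i.d. in time with covariance = precision⁻¹; when a band
    is given, every channel is passed through the same zero-phase
    band-pass and one settling length is generated beyond each end and
    discarded, so the returned record has ``n_samples`` clean samples.
    Identical seeds give bit-identical output.
    """
    precision = _check_spd(precision)
    n = precision.shape[0]
    band = get_band(band) if band is not None else None
    if band is not None:
        band.validate_for_fs(fs)
    pad = settle_samples(band, fs) if band is not None else 0
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    cov = np.linalg.inv(precision)
    chol = np.linalg.cholesky(cov)
    x = chol @ rng.standard_normal((n, n_samples + 2 * pad))
    labs = region_labels or [f"node{i}" for i in range(n)]
    ts = SourceTimeSeries(x, fs=fs, region_labels=list(labs), band=None,
                          **labels)
    if band is not None:
        ts = apply_bandpass(ts, band)
        ts = ts.with_data(ts.data[:, pad:pad + n_samples])
    return ts


def simulate_subject_timeseries(precision, design: "StudyDesign",
                                band, seed=0, **labels) -> SourceTimeSeries:
    """Record for one subject under a study design's fs and duration."""
    return simulate_timeseries(
        precision, n_samples=design.n_samples, fs=design.fs, band=band,
        seed=seed, region_labels=list(design.region_labels), **labels)


# --------------------------------------------------------------------------
# full study
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Two-group, two-condition study layout.

    ``bands_with_effects`` maps band name -> {edge: signed delta to the
    planted partial correlation in the post condition}; effects apply to
    ``effect_group`` only. 36 s at 300 Hz is the desk-scale default; the
    emulated recordings are 360 s.
    """

    n_per_group: int = 14
    groups: tuple[str, str] = ("verum", "sham")
    conditions: tuple[str, str] = ("rest", "post")
    duration_s: float = 36.0
    fs: float = 300.0
    bands_with_effects: dict[str, dict[Edge, float]] = field(
        default_factory=dict)
    effect_group: str = "verum"
    region_labels: tuple[str, ...] = tuple(default_region_labels())
    seed: int = 0

    def __post_init__(self):
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration_s * fs = {n} is not an integer sample count")
        if self.effect_group not in self.groups:
            raise ValueError(
                f"effect_group {self.effect_group!r} not in {self.groups}")
        for band in self.bands_with_effects:
            get_band(band)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class SubjectRecording:
    group: str
    subject_id: str
    condition: str
    timeseries: SourceTimeSeries


@dataclass
class StudyBundle:
    """All recordings of a simulated study plus its ground-truth ledger."""

    design: StudyDesign
    recordings: list[SubjectRecording]
    ledger: dict

    def select(self, *, group: str | None = None,
               condition: str | None = None) -> list[SubjectRecording]:
        return [r for r in self.recordings
                if (group is None or r.group == group)
                and (condition is None or r.condition == condition)]


def _band_precisions(
    design: StudyDesign,
    base: PrecisionSpec | dict[str, PrecisionSpec],
) -> dict[str, tuple[np.ndarray, np.ndarray, dict[Edge, float]]]:
    """Per band: (rest precision, post precision, rest strengths)."""
    labels = list(design.region_labels)
    n = len(labels)
    out = {}
    for name in BAND_ORDER:
        if isinstance(base, dict):
            spec = base.get(name, PrecisionSpec(n_regions=n, support=(),
                                                region_labels=tuple(labels)))
        else:
            spec = base
        if spec.n_regions != n:
            raise ValueError(
                f"band {name}: spec has {spec.n_regions} regions, design "
                f"has {n}")
        spec = replace(spec, region_labels=tuple(labels))
        rest_strengths = spec.edge_strengths()
        rest_p = make_precision_matrix(spec)
        deltas = {
            _canon_edge(e, labels, n): float(d)
            for e, d in design.bands_with_effects.get(name, {}).items()
        }
        post_strengths = dict(rest_strengths)
        for e, d in deltas.items():
            s = post_strengths.get(e, 0.0) + d
            if not (-1.0 < s < 1.0):
                raise ValueError(
                    f"band {name} edge {e}: post strength {s} outside (−1, 1)")
            if s == 0.0:
                post_strengths.pop(e, None)
            else:
                post_strengths[e] = s
        post_spec = replace(spec, support=tuple(post_strengths),
                            strength=post_strengths)
        post_p = make_precision_matrix(post_spec)
        out[name] = (rest_p, post_p, rest_strengths)
    return out


def simulate_group_study(
    design: StudyDesign,
    base: PrecisionSpec | dict[str, PrecisionSpec],
) -> StudyBundle:
    """Simulate every subject × condition broadband record of a study.

    ``base`` gives the rest-condition precision structure — one spec for
    all five bands, or a band-name -> spec mapping (unlisted bands get
    empty support, i.e. conditionally independent channels). The rest
    condition uses the base structure; the post condition applies the
    design's signed deltas, in the designated bands, for the effect
    group only. Each broadband record is the sum of the five band
    components. The returned ledger records every planted truth.

    Per-recording randomness derives from the design seed through a
    counter-based ``SeedSequence`` spawn key (group, subject, condition,
    band), so any subject is reproducible in isolation.
    """
    band_p = _band_precisions(design, base)
    labels = list(design.region_labels)
    recordings: list[SubjectRecording] = []
    for gi, group in enumerate(design.groups):
        for si in range(design.n_per_group):
            sid = f"{group}{si + 1:02d}"
            for ci, cond in enumerate(design.conditions):
                use_post = cond != design.conditions[0] and \
                    group == design.effect_group
                total = np.zeros((len(labels), design.n_samples))
                for bi, name in enumerate(BAND_ORDER):
                    rest_p, post_p, _ = band_p[name]
                    ss = np.random.SeedSequence(
                        entropy=design.seed, spawn_key=(gi, si, ci, bi))
                    comp = simulate_timeseries(
                        post_p if use_post else rest_p,
                        n_samples=design.n_samples, fs=design.fs,
                        band=CANONICAL_BANDS[name], seed=ss,
                        region_labels=labels)
                    total += comp.data
                ts = SourceTimeSeries(
                    total, fs=design.fs, region_labels=labels, band=None,
                    subject_id=sid, group=group, condition=cond,
                    meta={"seed": design.seed})
                recordings.append(SubjectRecording(group, sid, cond, ts))
    ledger = {
        "seed": design.seed,
        "n_per_group": design.n_per_group,
        "fs": design.fs,
        "duration_s": design.duration_s,
        "effect_group": design.effect_group,
        "rest_structure": {
            name: {f"{labels[a]}-{labels[b]}": s
                   for (a, b), s in band_p[name][2].items()}
            for name in BAND_ORDER
        },
        "effects": {
            name: {
                f"{labels[a]}-{labels[b]}": d
                for (a, b), d in (
                    (_canon_edge(e, labels, len(labels)), d)
                    for e, d in design.bands_with_effects.get(name, {}).items()
                )
            }
            for name in BAND_ORDER if name in design.bands_with_effects
        },
    }
    return StudyBundle(design=design, recordings=recordings, ledger=ledger)


# --------------------------------------------------------------------------
# synthetic spatial maps
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticMapSpec:
    """Specification for a bundle of synthetic component Z-maps.

    Exactly one map carries the template pattern (``in_template_z``
    inside the template spheres, plus Gaussian noise everywhere); the
    remaining ``n_components − 1`` maps are pure noise.
    """

    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 4.0
    template_regions: tuple[tuple[tuple[float, float, float], float], ...] = ()
    in_template_z: float = 2.0
    noise_sd: float = 0.5
    n_components: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("need at least one component")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_affine(grid_shape, voxel_size_mm) -> np.ndarray:
    """RAS affine with the world origin at the grid center."""
    aff = np.diag([voxel_size_mm] * 3 + [1.0]).astype(float)
    aff[:3, 3] = -voxel_size_mm * (np.asarray(grid_shape) - 1) / 2.0
    return aff


def make_synthetic_spatial_maps(spec: SyntheticMapSpec):
    """Generate component Z-maps; returns (maps, affine, patterned_index).

    ``maps`` is a list of ``n_components`` arrays of shape
    ``grid_shape``. The patterned map's index is drawn from the spec
    seed so callers cannot accidentally hard-code it.
    """
    from .dmn_selection import sphere_mask  # local: avoid import cycle

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    affine = default_affine(spec.grid_shape, spec.voxel_size_mm)
    if not spec.template_regions:
        raise ValueError("spec.template_regions is empty")
    centers = [np.asarray(c, float) for c, _ in spec.template_regions]
    radii = [float(r) for _, r in spec.template_regions]
    # sphere centers must lie inside the grid
    inv = np.linalg.inv(affine)
    for c in centers:
        v = (inv @ np.append(c, 1.0))[:3]
        if np.any(v < -0.5) or np.any(v > np.asarray(spec.grid_shape) - 0.5):
            raise ValueError(f"template center {tuple(c)} lies outside the grid")
    mask = sphere_mask(spec.grid_shape, affine, centers, radii)
    if not mask.any():
        raise ValueError("template spheres cover no voxels of the grid")
    patterned_index = int(rng.integers(spec.n_components))
    maps = []
    for i in range(spec.n_components):
        m = (rng.standard_normal(spec.grid_shape) * spec.noise_sd
             if spec.noise_sd > 0 else np.zeros(spec.grid_shape))
        if i == patterned_index:
            m = m + np.where(mask, spec.in_template_z, 0.0)
        maps.append(m)
    return maps, affine, patterned_index


def ring_support(n: int) -> tuple[Edge, ...]:
    """A degree-2 ring over n nodes — a convenient feasible planted support."""
    return tuple(sorted((min(i, (i + 1) % n), max(i, (i + 1) % n))
                        for i in range(n)))


def random_support(n: int, n_edges: int, seed: int = 0,
                   max_degree: int = 2) -> tuple[Edge, ...]:
    """Random planted support with a per-node degree cap (feasibility)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pairs = list(itertools.combinations(range(n), 2))
    rng.shuffle(pairs)
    deg = np.zeros(n, dtype=int)
    chosen: list[Edge] = []
    for a, b in pairs:
        if len(chosen) == n_edges:
            break
        if deg[a] < max_degree and deg[b] < max_degree:
            chosen.append((a, b))
            deg[a] += 1
            deg[b] += 1
    if len(chosen) < n_edges:
        raise ValueError(
            f"could not place {n_edges} edges with degree cap {max_degree}")
    return tuple(sorted(chosen))
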