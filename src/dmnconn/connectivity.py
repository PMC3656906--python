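"""Partial-correlation connectivity and group edge statistics.

The core statistic is the partial correlation between every pair of
regional sources, conditioned on all remaining regions: with sample
covariance S and precision P = S⁻¹,

    r_jk = − P_jk / sqrt(P_jj · P_kk),

whose zero pattern encodes conditional independence under Gaussianity.
Per-subject partial correlations are Fisher-transformed (arctanh),
tested edgewise against zero with one-sample t-tests across subjects,
thresholded with the Benjamini–Hochberg FDR procedure (q < 0.05), and
averaged into a group network whose non-significant edges are set to 0.
Bilateral region pairs are collapsed to an 8-node ROI network by taking
the extremum of the four hemispheric cross-connections, and
rest-versus-post condition changes are classified per ROI edge as
emerged / suspended / increased / decreased / unchanged using paired
t-tests (P < 0.05).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .rois import bilateral_pairing
from .timeseries import SourceTimeSeries

#: Condition-number threshold beyond which a ridge is added before inversion.
COND_THRESHOLD = 1e10
#: Ridge scale, in units of mean variance (trace/n).
RIDGE = 1e-6


# --------------------------------------------------------------------------
# covariance and partial correlation
# --------------------------------------------------------------------------

def sample_covariance(ts: SourceTimeSeries | np.ndarray) -> np.ndarray:
    """Sample covariance of a regions × samples matrix, divisor T.

    Entry (j, k) is the time average of centered products. The divisor-T
    (population) form matches the mean-over-time definition; the rescaled
    partial correlation is divisor-invariant regardless.
    """
    data = ts.data if isinstance(ts, SourceTimeSeries) else np.asarray(ts, float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D regions × samples matrix with T >= 2")
    centered = data - data.mean(axis=1, keepdims=True)
    return centered @ centered.T / data.shape[1]


def partial_correlation_from_covariance(cov: np.ndarray,
                                        *, cond_threshold: float = COND_THRESHOLD,
                                        ridge: float = RIDGE) -> np.ndarray:
    """Rescale the inverse covariance into a partial-correlation matrix.

    Off-diagonal (j, k) = −P_jk / sqrt(P_jj P_kk) with P the precision
    matrix; diagonal set to 1 by convention. An ill-conditioned covariance
    (condition number above ``cond_threshold``) triggers a diagonal ridge
    of ``ridge * trace/n`` with a warning; a singular matrix after that is
    an error (too few samples or collinear channels).
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square, got {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance must be symmetric")
    n = cov.shape[0]
    if np.linalg.cond(cov) > cond_threshold:
        lam = ridge * np.trace(cov) / n
        warnings.warn(
            f"ill-conditioned covariance (cond > {cond_threshold:g}); "
            f"adding ridge {lam:g} to the diagonal",
            RuntimeWarning,
            stacklevel=2,
        )
        cov = cov + lam * np.eye(n)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance is singular: too few samples or collinear channels"
        ) from exc
    d = np.sqrt(np.diag(prec))
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("precision matrix has non-positive diagonal")
    r = -prec / np.outer(d, d)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


class PartialCorrelation(BaseEstimator):
    """Partial-correlation network estimator (scikit-learn style).

    Estimates the conditional-dependence structure of multivariate data
    from the rescaled off-diagonals of the inverse sample covariance.

    Parameters
    ----------
    cond_threshold : float
        Covariance condition number above which a stabilizing diagonal
        ridge is added before inversion.
    ridge : float
        Ridge magnitude, in units of the mean channel variance.

    Attributes
    ----------
    covariance_ : ndarray of shape (n_features, n_features)
        Sample covariance (divisor n_samples).
    precision_ : ndarray of shape (n_features, n_features)
        Inverse of (possibly ridged) covariance.
    partial_correlation_ : ndarray of shape (n_features, n_features)
        Symmetric partial-correlation matrix, unit diagonal.
    """

    def __init__(self, cond_threshold: float = COND_THRESHOLD,
                 ridge: float = RIDGE):
        self.cond_threshold = cond_threshold
        self.ridge = ridge

    def fit(self, X, y=None):
        """Fit from an (n_samples, n_features) array."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        self.n_features_in_ = X.shape[1]
        self.covariance_ = sample_covariance(X.T)
        self.partial_correlation_ = partial_correlation_from_covariance(
            self.covariance_, cond_threshold=self.cond_threshold,
            ridge=self.ridge,
        )
        # precision of the covariance actually inverted (post-ridge if needed)
        try:
            self.precision_ = np.linalg.inv(self.covariance_)
        except np.linalg.LinAlgError:
            lam = self.ridge * np.trace(self.covariance_) / self.n_features_in_
            self.precision_ = np.linalg.inv(
                self.covariance_ + lam * np.eye(self.n_features_in_))
        return self


def partial_correlation_matrix(ts: SourceTimeSeries | np.ndarray) -> np.ndarray:
    """Partial-correlation matrix of a regions × samples record."""
    return partial_correlation_from_covariance(sample_covariance(ts))


# --------------------------------------------------------------------------
# edge-level statistics
# --------------------------------------------------------------------------

def fisher_r_to_z(r):
    """Fisher r-to-Z transform, z = arctanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("Fisher transform requires |r| < 1 (degenerate estimate)")
    z = np.arctanh(r)
    return z if z.ndim else float(z)


def one_sample_edge_ttest(z_values) -> tuple[float, float]:
    """One-sample t-test of per-subject Fisher-z values against zero.

    Returns (t, two-sided p), df = n − 1. Zero sample variance is an
    error (degenerate edge).
    """
    z = np.asarray(z_values, dtype=float)
    if z.ndim != 1 or z.size < 2:
        raise ValueError("need a 1-D vector of at least 2 subjects")
    if np.std(z) == 0.0:
        raise ValueError("zero variance across subjects (degenerate edge)")
    res = stats.ttest_1samp(z, 0.0)
    return float(res.statistic), float(res.pvalue)


def fdr_mask(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up significance flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def edge_list(n: int) -> list[tuple[int, int]]:
    """Upper-triangle edge index pairs (i < j) for an n-node network."""
    return list(itertools.combinations(range(n), 2))


@dataclass
class GroupEdgeStats:
    """Edgewise group statistics for one band × condition cell."""

    region_labels: list[str]
    n_subjects: int
    edges: list[tuple[int, int]]
    mean_z: np.ndarray       # mean Fisher-z per edge
    t: np.ndarray            # one-sample t per edge (nan when n == 1)
    p: np.ndarray            # two-sided p per edge (nan when n == 1)
    significant: np.ndarray  # FDR flags
    mean_r: np.ndarray       # group-mean raw partial correlation, 0 if not sig.
    q: float = 0.05
    band: str | None = None
    condition: str | None = None
    degenerate: bool = False  # single-subject input: t-test skipped

    def matrix(self) -> np.ndarray:
        """Masked group-mean network: symmetric, zero diagonal."""
        n = len(self.region_labels)
        m = np.zeros((n, n))
        for (i, j), v in zip(self.edges, self.mean_r):
            m[i, j] = m[j, i] = v
        return m

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "edge": f"{self.region_labels[i]}-{self.region_labels[j]}",
                "mean_z": mz, "t": t, "p": p,
                "significant": bool(s), "mean_r": mr,
            }
            for (i, j), mz, t, p, s, mr in zip(
                self.edges, self.mean_z, self.t, self.p,
                self.significant, self.mean_r)
        ]
        return pd.DataFrame(rows)


def group_mean_network(
    subject_matrices: list[np.ndarray],
    mask: np.ndarray | None = None,
    *,
    region_labels: list[str] | None = None,
    q: float = 0.05,
    band: str | None = None,
    condition: str | None = None,
) -> GroupEdgeStats:
    """Group edge statistics and significance-masked mean network.

    Per edge: per-subject partial correlations are Fisher-transformed and
    tested against zero across subjects; flags come from BH FDR at level
    ``q`` (or a caller-supplied ``mask`` over the same edges); the
    group-mean raw partial correlation is stored, set to 0 exactly where
    the flag is false. A single subject yields a degenerate result (means
    only, no test, nothing significant unless masked by the caller).
    """
    mats = [np.asarray(m, dtype=float) for m in subject_matrices]
    if not mats:
        raise ValueError("no subject matrices")
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise ValueError("subject matrices must share shape (mixed cohorts?)")
    labels = region_labels or [f"node{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("region label count does not match matrix size")
    edges = edge_list(n)
    r = np.array([[m[i, j] for (i, j) in edges] for m in mats])  # subj × edge
    z = fisher_r_to_z(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    z = np.atleast_2d(z)
    n_subj = len(mats)
    mean_r_all = r.mean(axis=0)
    mean_z = z.mean(axis=0)

    if n_subj == 1:
        t = np.full(len(edges), np.nan)
        p = np.full(len(edges), np.nan)
        sig = (np.zeros(len(edges), bool) if mask is None
               else np.asarray(mask, bool))
        degenerate = True
    else:
        sd = z.std(axis=0, ddof=1)
        t = np.zeros(len(edges))
        p = np.ones(len(edges))
        ok = sd > 0
        t[ok] = mean_z[ok] / (sd[ok] / np.sqrt(n_subj))
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n_subj - 1)
        # zero-variance edges: all-zero -> clearly null; constant nonzero -> sig.
        bad = ~ok
        t[bad & (mean_z != 0)] = np.inf * np.sign(mean_z[bad & (mean_z != 0)])
        p[bad & (mean_z != 0)] = 0.0
        sig = fdr_mask(p, q=q) if mask is None else np.asarray(mask, bool)
        degenerate = False

    mean_r = np.where(sig, mean_r_all, 0.0)
    return GroupEdgeStats(
        region_labels=list(labels), n_subjects=n_subj, edges=edges,
        mean_z=mean_z, t=t, p=p, significant=sig, mean_r=mean_r,
        q=q, band=band, condition=condition, degenerate=degenerate,
    )


# --------------------------------------------------------------------------
# bilateral collapse
# --------------------------------------------------------------------------

@dataclass
class CollapsedNetwork:
    """8-node ROI network collapsed from the 16-node bilateral network.

    The connectivity between two ROIs is the extremum — largest absolute
    value, sign preserved — of the 4 pairwise connections between their
    hemispheric nodes; provenance records the winning hemispheric pair.
    """

    roi_names: list[str]
    values: np.ndarray  # 8 × 8 symmetric, zero diagonal
    provenance: dict[tuple[str, str], tuple[str, str] | None] = field(
        default_factory=dict)
    sign_sensitive: list[tuple[str, str]] = field(default_factory=list)

    def value(self, roi_a: str, roi_b: str) -> float:
        i, j = self.roi_names.index(roi_a), self.roi_names.index(roi_b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.roi_names,
                            columns=self.roi_names)


def collapse_bilateral_max(
    matrix: np.ndarray,
    region_labels: list[str],
    roi_order: list[str] | None = None,
) -> CollapsedNetwork:
    """Collapse a 16-node bilateral network to 8 ROI nodes.

    For each unordered ROI pair (A, B) the four hemispheric connections
    (A_L–B_L, A_L–B_R, A_R–B_L, A_R–B_R) compete; the entry with the
    largest absolute value wins and keeps its sign. Ties break toward
    the earlier pair in that enumeration order. ROI pairs whose winning
    value is negative are recorded as sign-sensitive (a signed-maximum
    rule would have chosen differently).
    """
    matrix = np.asarray(matrix, dtype=float)
    pairing = bilateral_pairing(region_labels)
    rois = roi_order or list(pairing)
    missing = set(rois) - set(pairing)
    if missing:
        raise ValueError(f"ROIs {sorted(missing)} not present in labels")
    k = len(rois)
    out = np.zeros((k, k))
    provenance: dict[tuple[str, str], tuple[str, str] | None] = {}
    sign_sensitive: list[tuple[str, str]] = []
    for a in range(k):
        for b in range(a + 1, k):
            candidates = [
                (region_labels[i], region_labels[j], matrix[i, j])
                for i in pairing[rois[a]] for j in pairing[rois[b]]
            ]
            li, lj, v = max(candidates, key=lambda c: abs(c[2]))
            out[a, b] = out[b, a] = v
            key = (rois[a], rois[b])
            provenance[key] = (li, lj) if v != 0.0 else None
            if v < 0.0:
                sign_sensitive.append(key)
    if sign_sensitive:
        warnings.warn(
            f"bilateral collapse sign-sensitive for {sign_sensitive}: "
            "absolute-value ordering kept a negative edge",
            RuntimeWarning, stacklevel=2,
        )
    return CollapsedNetwork(list(rois), out, provenance, sign_sensitive)


def collapse_subject_values(
    subject_matrix: np.ndarray,
    region_labels: list[str],
    provenance: dict[tuple[str, str], tuple[str, str] | None],
    roi_names: list[str],
) -> np.ndarray:
    """Subject-level 8-node edge values with group-level winning pairs fixed.

    For comparability across subjects and conditions, each subject's ROI
    edge value is read at the hemispheric pair that won the group-level
    collapse, not at the subject's own maximum. Edges with no winning
    pair (all-zero group entry) fall back to the left–left pair.
    """
    idx = {lab: i for i, lab in enumerate(region_labels)}
    pairing = bilateral_pairing(region_labels)
    k = len(roi_names)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            pair = provenance.get((roi_names[a], roi_names[b]))
            if pair is None:
                i, j = pairing[roi_names[a]][0], pairing[roi_names[b]][0]
            else:
                i, j = idx[pair[0]], idx[pair[1]]
            out[a, b] = out[b, a] = subject_matrix[i, j]
    return out


# --------------------------------------------------------------------------
# condition comparison
# --------------------------------------------------------------------------

def paired_edge_comparison(rest_values, post_values) -> tuple[float, float]:
    """Paired t-test on per-subject edge values, rest vs post.

    Returns (t, two-sided p) on the post − rest differences; the caller
    applies the P < 0.05 threshold. Requires the same subjects in the
    same order in both conditions.
    """
    rest = np.asarray(rest_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if rest.shape != post.shape or rest.ndim != 1:
        raise ValueError("rest/post must be 1-D vectors of the same subjects")
    if rest.size < 2:
        raise ValueError("need at least 2 paired subjects")
    diff = post - rest
    if np.std(diff) == 0.0:
        if np.all(diff == 0.0):
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero differences (degenerate)")
    res = stats.ttest_rel(post, rest)
    return float(res.statistic), float(res.pvalue)


CHANGE_CATEGORIES = ("emerged", "suspended", "increased", "decreased",
                     "unchanged")


def classify_edge_changes(
    rest: CollapsedNetwork,
    post: CollapsedNetwork,
    paired_t: dict[tuple[str, str], tuple[float, float]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each ROI edge's rest → post change.

    emerged    : absent (0) at rest, significant post
    suspended  : significant at rest, absent post
    increased / decreased : present in both, paired P < ``alpha``, by the
        sign of the value change
    unchanged  : everything else (including absent in both)

    ``paired_t`` maps ROI edge -> (t, p) from :func:`paired_edge_comparison`
    on per-subject collapsed values; edges absent from the map get no
    paired p (reported as NaN, shown as "–" in printed tables).
    """
    if rest.roi_names != post.roi_names:
        raise ValueError("rest/post networks must share the ROI set")
    paired_t = paired_t or {}
    rows = []
    names = rest.roi_names
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            key = (names[a], names[b])
            rv, pv = rest.values[a, b], post.values[a, b]
            t_p = paired_t.get(key) or paired_t.get((key[1], key[0]))
            t, p = (t_p if t_p is not None else (np.nan, np.nan))
            if rv == 0.0 and pv != 0.0:
                cat = "emerged"
            elif rv != 0.0 and pv == 0.0:
                cat = "suspended"
            elif rv != 0.0 and pv != 0.0 and np.isfinite(p) and p < alpha:
                cat = "increased" if pv > rv else "decreased"
            else:
                cat = "unchanged"
            rows.append({
                "roi_a": key[0], "roi_b": key[1], "rest": rv, "post": pv,
                "paired_t": t, "paired_p": p, "category": cat,
            })
    return pd.DataFrame(rows)
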