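"""Microstate segmentation: GFP peaks, TAAHC clustering, back-fitting, GEV.

The central object is :class:`MicrostateSegmentation`, a scikit-learn style
clusterer. ``fit`` takes a matrix of GFP-peak topographies (pooled across
subjects) and agglomerates them bottom-up with the Topographic Atomize and
Agglomerate Hierarchical Clustering (TAAHC) scheme until ``n_states``
template maps remain; ``predict`` back-fits the learned templates to
arbitrary topographies by polarity-invariant spatial correlation.

All similarity computations ignore polarity: a scalp map and its negation
describe the same microstate because the underlying generator oscillates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .io import AVERAGE, Recording

DEFAULT_MIN_PEAK_DIST_MS = 10.0
DEFAULT_SD_MULT = 2.0
DEFAULT_SMOOTH_MS = 30.0


# ---------------------------------------------------------------------------
# global field power
# ---------------------------------------------------------------------------

@dataclass
class GfpSeries:
    """Per-sample global field power (spatial SD across channels), in µV."""

    values: np.ndarray
    fs: float


def gfp(rec: Recording) -> GfpSeries:
    """Global field power: the spatial standard deviation at each sample."""
    if rec.reference != AVERAGE:
        raise ValueError("GFP is defined on average-referenced data")
    values = np.sqrt(np.mean(rec.data ** 2, axis=0))
    return GfpSeries(values=values, fs=rec.fs)


@dataclass
class GfpPeakSet:
    """GFP peak locations and the scalp maps sampled there."""

    indices: np.ndarray          # sample indices into the source recording
    maps: np.ndarray             # (n_peaks, n_channels) topographies, µV
    gfp_values: np.ndarray       # GFP at each peak
    subject_id: str = ""

    def __len__(self) -> int:
        return len(self.indices)


def find_gfp_peaks(g: GfpSeries, min_dist_ms: float = DEFAULT_MIN_PEAK_DIST_MS,
                   sd_mult: float = DEFAULT_SD_MULT,
                   max_peaks: int | None = None) -> np.ndarray:
    """Locate GFP peaks with a minimum separation and an outlier cut.

    Local maxima closer than `min_dist_ms` are thinned (largest wins);
    peaks whose GFP exceeds mean + `sd_mult` * SD of the GFP-at-peak
    distribution are discarded as artifactual; if more than `max_peaks`
    survive, the largest-GFP peaks are kept. Returns sorted sample indices.
    """
    if min_dist_ms <= 0:
        raise ValueError("min_dist_ms must be positive")
    values = np.asarray(g.values)
    if len(values) < 3:
        return np.array([], dtype=int)
    distance = max(1, int(round(min_dist_ms * g.fs / 1000.0)))
    idx, _ = sp_signal.find_peaks(values, distance=distance)
    if len(idx) == 0:
        return idx
    peak_vals = values[idx]
    if sd_mult is not None and len(idx) > 1:
        bound = peak_vals.mean() + sd_mult * peak_vals.std()
        keep = peak_vals <= bound
        idx, peak_vals = idx[keep], peak_vals[keep]
    if max_peaks is not None and len(idx) > max_peaks:
        top = np.argsort(peak_vals)[::-1][:max_peaks]
        idx = np.sort(idx[top])
    return idx


def extract_peak_maps(rec: Recording, **peak_kwargs) -> GfpPeakSet:
    """GFP-peak detection plus topography extraction for one recording."""
    g = gfp(rec)
    idx = find_gfp_peaks(g, **peak_kwargs)
    return GfpPeakSet(indices=idx, maps=rec.data[:, idx].T.copy(),
                      gfp_values=g.values[idx], subject_id=rec.subject_id)


def pool_peaks(peak_sets: list[GfpPeakSet],
               per_subject_cap: int | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Pool peak maps across subjects with an even-contribution cap.

    Each subject contributes at most `per_subject_cap` of its largest-GFP
    peaks (``None`` or "auto" caps at the smallest subject's peak count), so
    long recordings do not dominate the pooled template estimation.

    Returns ``(maps, subject_index)`` where `subject_index[i]` is the index
    into `peak_sets` that contributed row i.
    """
    if not peak_sets:
        raise ValueError("need at least one subject's peaks")
    if per_subject_cap in (None, "auto"):
        per_subject_cap = min(len(ps) for ps in peak_sets)
    rows, owner = [], []
    for s, ps in enumerate(peak_sets):
        if len(ps) > per_subject_cap:
            top = np.argsort(ps.gfp_values)[::-1][:per_subject_cap]
            rows.append(ps.maps[np.sort(top)])
        else:
            rows.append(ps.maps)
        owner.extend([s] * min(len(ps), per_subject_cap))
    return np.concatenate(rows, axis=0), np.asarray(owner, dtype=int)


# ---------------------------------------------------------------------------
# polarity-invariant similarity
# ---------------------------------------------------------------------------

def _demean_normalise(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise zero-mean unit-norm; zero rows stay zero. Returns (U, norms)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return x / safe[:, None], norms


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Absolute spatial (Pearson) correlation between two topographies.

    Polarity-invariant: a map and its negation correlate at 1.
    """
    uu, nu = _demean_normalise(u)
    vv, nv = _demean_normalise(v)
    if nu[0] == 0 or nv[0] == 0:
        raise ValueError("spatial correlation undefined for flat topographies")
    return float(abs(uu[0] @ vv[0]))


def gmd(u: np.ndarray, v: np.ndarray) -> float:
    """Global map dissimilarity, polarity-invariant form.

    Satisfies GMD^2 = 2 (1 - r) with r the absolute spatial correlation, so
    identical or polarity-flipped maps score 0 and orthogonal maps sqrt(2).
    """
    uu, nu = _demean_normalise(u)
    vv, nv = _demean_normalise(v)
    if nu[0] == 0 or nv[0] == 0:
        raise ValueError("GMD undefined for flat topographies")
    c = uu[0] @ vv[0]
    # min over polarity of the normalised RMS difference
    return float(min(np.sqrt(max(0.0, 2.0 * (1.0 - s * c))) for s in (1, -1)))


def abs_correlation_matrix(x: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between every row of `x` and every map row."""
    xu, _ = _demean_normalise(x)
    mu, mnorm = _demean_normalise(maps)
    if np.any(mnorm == 0):
        raise ValueError("template maps must not be flat")
    return np.abs(xu @ mu.T)


# ---------------------------------------------------------------------------
# TAAHC clustering
# ---------------------------------------------------------------------------

def _first_pc(members: np.ndarray) -> np.ndarray:
    """Polarity-aligned first principal component of member topographies."""
    if members.shape[0] == 1:
        v = members[0]
        return v / np.linalg.norm(v)
    # right singular vector of the member matrix; members are row-wise
    # zero-mean so the component stays average-reference consistent
    _, _, vt = np.linalg.svd(members, full_matrices=False)
    v = vt[0]
    return v / np.linalg.norm(v)


class MicrostateSegmentation(ClusterMixin, BaseEstimator):
    """TAAHC clustering of GFP-peak topographies into microstate templates.

    Bottom-up agglomeration: every peak map starts as its own cluster; at
    each step the *worst* surviving cluster is atomized — dissolved into its
    member maps — and each freed map is reassigned to the surviving cluster
    whose prototype it correlates with best (ignoring polarity), until
    ``n_states`` clusters remain. Prototypes are the polarity-aligned first
    principal component of the member maps.

    Parameters
    ----------
    n_states : int, default 4
        Number of template maps to extract (the classical resting-state
        analysis uses 4, labelled A-D; 5 and 6 are common extensions).
    worst_criterion : {"gev", "abs_corr_sum"}, default "gev"
        How the cluster to atomize is chosen: lowest contribution to global
        explained variance, or lowest sum of absolute correlations between
        members and prototype.

    Attributes
    ----------
    maps_ : ndarray, shape (n_states, n_channels)
        Unit-norm, zero-mean template topographies.
    labels_ : ndarray, shape (n_peaks,)
        Cluster index of each training peak map.
    gev_ : float
        Fraction of GFP-weighted variance of the training peaks explained
        by their assigned templates.
    """

    def __init__(self, n_states: int = 4, worst_criterion: str = "gev"):
        self.n_states = n_states
        self.worst_criterion = worst_criterion

    def fit(self, X: np.ndarray, y=None) -> "MicrostateSegmentation":
        """Agglomerate peak topographies down to ``n_states`` templates.

        X : (n_peaks, n_channels) raw peak topographies in µV.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_peaks, n_channels)")
        n_peaks, n_ch = X.shape
        if not 2 <= self.n_states < n_peaks:
            raise ValueError(
                f"need 2 <= n_states < n_peaks, got {self.n_states} with "
                f"{n_peaks} peaks")
        if self.worst_criterion not in ("gev", "abs_corr_sum"):
            raise ValueError(f"unknown criterion {self.worst_criterion!r}")

        u, norms = _demean_normalise(X)          # unit topographies
        if np.any(norms == 0):
            raise ValueError("flat (zero-variance) peak maps cannot be "
                             "clustered")
        amp = norms / np.sqrt(n_ch)              # GFP of each peak map
        weight = amp ** 2 if self.worst_criterion == "gev" else np.ones(n_peaks)

        assign = np.arange(n_peaks)
        protos = u.copy()                        # prototype per cluster id
        active = np.ones(n_peaks, dtype=bool)
        # per-peak contribution to its cluster's quality score
        contrib = weight.copy()                  # singleton: |corr| = 1
        sums = contrib.copy()

        n_active = n_peaks
        while n_active > self.n_states:
            sums_masked = np.where(active, sums, np.inf)
            worst = int(np.argmin(sums_masked))
            freed = np.flatnonzero(assign == worst)
            active[worst] = False
            n_active -= 1

            corr = np.abs(u[freed] @ protos.T)
            corr[:, ~active] = -1.0
            new_assign = np.argmax(corr, axis=1)
            assign[freed] = new_assign

            for cid in np.unique(new_assign):
                members = np.flatnonzero(assign == cid)
                protos[cid] = _first_pc(u[members])
                contrib[members] = weight[members] * np.abs(
                    u[members] @ protos[cid]) ** 2
                sums[cid] = contrib[members].sum()

        order = np.flatnonzero(active)
        relabel = {cid: k for k, cid in enumerate(order)}
        self.maps_ = protos[order].copy()
        self.labels_ = np.array([relabel[c] for c in assign])
        gev_num = float(np.sum((amp * np.abs(
            np.einsum("ij,ij->i", u, protos[assign]))) ** 2))
        self.gev_ = gev_num / float(np.sum(amp ** 2))
        self.n_features_in_ = n_ch
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Back-fit: label each topography by maximum |spatial correlation|."""
        check_is_fitted(self, "maps_")
        corr = self.correlate(X)
        return np.argmax(corr, axis=1)

    def correlate(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_states) |correlation| of each row with each map."""
        check_is_fitted(self, "maps_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.maps_.shape[1]:
            raise ValueError("channel count does not match fitted maps")
        xu, _ = _demean_normalise(X)
        return np.abs(xu @ self.maps_.T)

    transform = correlate

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_


def taahc(peaks: np.ndarray, n_states: int,
          worst_criterion: str = "gev") -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: returns ``(template_maps, peak_assignments)``."""
    est = MicrostateSegmentation(n_states=n_states,
                                 worst_criterion=worst_criterion).fit(peaks)
    return est.maps_, est.labels_


# ---------------------------------------------------------------------------
# archetype ordering
# ---------------------------------------------------------------------------

def order_maps(maps: np.ndarray, canonical: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Match estimated maps to canonical archetypes (A, B, C, D, ...).

    Solves the one-to-one assignment maximising total absolute spatial
    correlation (Hungarian algorithm). Returns ``(reordered_maps, perm)``
    where ``reordered_maps[k]`` is the estimated map assigned to canonical
    archetype k and ``perm[k]`` its row index in the input.
    """
    maps = np.asarray(maps, dtype=float)
    canonical = np.asarray(canonical, dtype=float)
    if maps.shape != canonical.shape:
        raise ValueError("maps and canonical templates must share a shape")
    corr = abs_correlation_matrix(canonical, maps)
    rows, cols = linear_sum_assignment(-corr)
    perm = cols[np.argsort(rows)]
    return maps[perm].copy(), perm


# ---------------------------------------------------------------------------
# back-fitting, smoothing, GEV
# ---------------------------------------------------------------------------

@dataclass
class LabelSequence:
    """Per-sample microstate labels with their spatial-correlation fit."""

    labels: np.ndarray           # (n_samples,) class indices 0..K-1
    fit: np.ndarray              # (n_samples,) |corr| with the assigned map
    fs: float
    n_states: int
    boundaries: list[int] = field(default_factory=list)
    subject_id: str = ""

    def __len__(self) -> int:
        return len(self.labels)


def backfit(maps: np.ndarray, rec: Recording) -> LabelSequence:
    """Label every sample with its best-correlated template map."""
    maps = np.asarray(maps, dtype=float)
    if rec.reference != AVERAGE:
        raise ValueError("back-fitting requires average-referenced data")
    if maps.shape[1] != rec.n_channels:
        raise ValueError("channel count of maps does not match recording")
    corr = abs_correlation_matrix(rec.data.T, maps)
    labels = np.argmax(corr, axis=1)
    fit = corr[np.arange(len(labels)), labels]
    return LabelSequence(labels=labels, fit=fit, fs=rec.fs,
                         n_states=maps.shape[0],
                         boundaries=list(rec.boundaries),
                         subject_id=rec.subject_id)


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs as ``(label, start, length)`` triples."""
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    return [(int(labels[s]), int(s), int(e - s))
            for s, e in zip(starts, ends)]


def smooth_labels(ls: LabelSequence, corr: np.ndarray,
                  min_ms: float = DEFAULT_SMOOTH_MS,
                  max_passes: int = 100) -> LabelSequence:
    """Reassign sub-threshold microstate segments to their runner-up class.

    Any maximal run shorter than `min_ms` has each of its samples relabelled
    to that sample's next-best class (highest correlation excluding the
    run's current class; ties broken toward the lower class index). Passes
    repeat left-to-right until no short run remains or a pass changes
    nothing.

    `corr` is the (n_samples, n_states) absolute-correlation matrix from
    which the labels were derived.

    To guarantee termination, classes a sample has already held during
    smoothing stay excluded for that sample on later passes (otherwise a
    one-sample run wedged between two long runs of different classes would
    oscillate between its best and second-best class forever); a sample
    that has walked through every class merges into its neighbouring run
    instead. A short run therefore descends its samples' correlation
    ranking until it either grows past the threshold or is absorbed by a
    neighbour.
    """
    if min_ms < 0:
        raise ValueError("min_ms must be non-negative")
    labels = np.asarray(ls.labels).copy()
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (len(labels), ls.n_states):
        raise ValueError("corr must be (n_samples, n_states)")
    min_len = int(np.ceil(min_ms * ls.fs / 1000.0))
    if min_len <= 1 or len(labels) == 0:
        return LabelSequence(labels=labels, fit=ls.fit.copy(), fs=ls.fs,
                             n_states=ls.n_states,
                             boundaries=list(ls.boundaries),
                             subject_id=ls.subject_id)

    n = len(labels)
    excluded = np.zeros((n, ls.n_states), dtype=bool)
    for _ in range(max_passes):
        short = [(lab, s, ln) for lab, s, ln in _runs(labels)
                 if ln < min_len]
        if not short or (len(short) == 1 and short[0][2] == n):
            break  # done, or the whole sequence is one (degenerate) run
        for label, start, length in short:
            if length == n:
                continue
            sl = slice(start, start + length)
            excluded[sl, label] = True
            exhausted = excluded[sl].all(axis=1)
            seg = np.where(excluded[sl], -np.inf, corr[sl])
            new = np.argmax(seg, axis=1)
            if np.any(exhausted):
                # ranking walked dry: absorb into the adjacent run
                neighbour = (labels[start - 1] if start > 0
                             else labels[start + length])
                new[exhausted] = neighbour
            labels[sl] = new

    fit = corr[np.arange(len(labels)), labels]
    return LabelSequence(labels=labels, fit=fit, fs=ls.fs,
                         n_states=ls.n_states, boundaries=list(ls.boundaries),
                         subject_id=ls.subject_id)


def gev(rec: Recording, maps: np.ndarray, ls: LabelSequence
        ) -> tuple[float, np.ndarray]:
    """Global explained variance of a labelled recording.

    GEV = sum_t (GFP_t * r_t)^2 / sum_t GFP_t^2 where r_t is the absolute
    spatial correlation between sample t and its assigned template. Returns
    ``(total, per_class)``; the per-class values partition the total.
    """
    maps = np.asarray(maps, dtype=float)
    g = gfp(rec).values
    denom = float(np.sum(g ** 2))
    if denom == 0:
        raise ValueError("GEV undefined for all-zero data")
    corr = abs_correlation_matrix(rec.data.T, maps)
    r = corr[np.arange(len(ls.labels)), ls.labels]
    num = (g * r) ** 2
    per_class = np.array([num[ls.labels == k].sum()
                          for k in range(maps.shape[0])]) / denom
    return float(num.sum() / denom), per_class
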