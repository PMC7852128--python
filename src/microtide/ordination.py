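"""PCA on CLR values, classical PCoA, longitudinal three-mode variants, ellipses.

The three-mode ordinations handle repeated measures (subject x taxa x time).
For PCA the array is unfolded by stacking the time slices along the sample
mode, so all time points share one set of taxa loadings; scores come out per
(subject, time) pair.  For PCoA, the chosen dissimilarity is computed among all
(subject, time) samples, each time slice's sub-matrix is Gower-centered, the
centered matrices are averaged across time to fix one common set of axes, and
every (subject, time) sample is projected onto those axes.  Only subjects
observed at all time points enter (complete cases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

from .diversity import DistanceMatrix, BETA_METHODS
from .io_core import MicroSet

logger = logging.getLogger("microtide")

__all__ = [
    "OrdinationResult",
    "EllipsePath",
    "pca_clr",
    "pcoa",
    "three_mode_ordinate",
    "ordination_ellipse",
]


@dataclass
class OrdinationResult:
    """Sample scores on ordered axes with per-axis explained variance.

    ``sample_ids`` are library IDs, or "subject@time" pairs for three-mode
    results (``time_labels`` then carries the time of each row).
    """

    method: str
    scores: np.ndarray
    explained: np.ndarray
    sample_ids: list[str]
    loadings: np.ndarray | None = None
    taxa: list[str] | None = None
    time_labels: list | None = None
    negative_eigenvalues: np.ndarray | None = None

    @property
    def axis_count(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"Axis{i + 1}" for i in range(self.axis_count)]
        df = pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)
        if self.time_labels is not None:
            df["Time"] = self.time_labels
        return df


@dataclass
class EllipsePath:
    group: str
    points: np.ndarray  # closed path, first point == last
    level: float


def _fix_signs(scores: np.ndarray, loadings: np.ndarray | None) -> tuple[np.ndarray, np.ndarray | None]:
    """Deterministic sign convention: largest-|.| loading (or score) positive per axis."""
    ref = loadings if loadings is not None else scores
    for j in range(scores.shape[1]):
        col = ref[:, j]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            scores[:, j] *= -1
            if loadings is not None:
                loadings[:, j] *= -1
    return scores, loadings


def _pca_matrix(x: np.ndarray, ids: list[str], taxa: list[str],
                time_labels=None) -> OrdinationResult:
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0.0):
        raise ValueError("matrix has no variance; PCA undefined")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    keep = s > max(s.max() * 1e-12, 1e-12)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    scores = u * s
    loadings = vt.T
    scores, loadings = _fix_signs(scores, loadings)
    explained = s**2 / (s**2).sum()
    return OrdinationResult(
        method="pca", scores=scores, explained=explained,
        sample_ids=list(ids), loadings=loadings, taxa=list(taxa),
        time_labels=time_labels,
    )


def pca_clr(micro_set: MicroSet, table: str) -> OrdinationResult:
    """Principal components of the libraries x taxa CLR matrix.

    Columns are centered and decomposed by SVD; scores are the left singular
    vectors scaled by the singular values, and explained variance fractions are
    the normalized squared singular values.
    """
    clr = micro_set.wide(table, "clr")
    if clr.shape[0] < 2 or clr.shape[1] < 2:
        raise ValueError("PCA needs at least 2 libraries and 2 taxa")
    return _pca_matrix(clr.to_numpy(dtype=float), list(clr.index), list(clr.columns))


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dist: DistanceMatrix, eig_tol: float = 1e-10) -> OrdinationResult:
    """Classical principal coordinates of a dissimilarity matrix.

    The Gower-centered matrix of -D^2/2 is eigendecomposed; axes with
    eigenvalues above `eig_tol` (relative to the largest) are retained and
    scores are eigenvectors scaled by sqrt(eigenvalue).  Explained fractions
    are over the positive eigenvalues only; negative eigenvalues (from
    non-Euclidean dissimilarities) are reported as diagnostics.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    g = _gower_center(dist.matrix)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(abs(vals[0]), 1.0)
    keep = vals > eig_tol * scale
    pos = vals[vals > 0]
    negatives = vals[vals < -eig_tol * scale]
    if not keep.any():
        logger.warning("PCoA: no positive eigenvalues; zero axes retained")
        return OrdinationResult(
            method="pcoa", scores=np.zeros((n, 0)), explained=np.zeros(0),
            sample_ids=list(dist.ids), negative_eigenvalues=negatives,
        )
    lam = vals[keep]
    scores = vecs[:, keep] * np.sqrt(lam)
    scores, _ = _fix_signs(scores, None)
    explained = lam / pos.sum()
    return OrdinationResult(
        method="pcoa", scores=scores, explained=explained,
        sample_ids=list(dist.ids), negative_eigenvalues=negatives,
    )


def _complete_case_array(
    micro_set: MicroSet, table: str, subject: str, time: str, value: str
):
    """Subjects x taxa x time array of `value`; complete-case subjects only."""
    d = micro_set.table_data(table)
    for col in (subject, time):
        if col not in d.columns:
            raise KeyError(f"column {col!r} not in micro set")
    meta = d.drop_duplicates("Lib")[["Lib", subject, time]]
    times = list(pd.unique(meta[time].dropna()))
    by_subj = meta.groupby(subject, observed=True)[time].agg(
        lambda s: frozenset(s.dropna())
    )
    complete = [s for s, tset in by_subj.items() if tset == frozenset(times)]
    incomplete = [s for s in by_subj.index if s not in complete]
    if incomplete:
        logger.info(
            "three_mode_ordinate: excluding %d incomplete subjects: %s",
            len(incomplete), list(incomplete),
        )
    if not complete:
        raise ValueError("no subject observed at all time points")
    wide = micro_set.wide(table, value)
    lib_meta = meta.set_index("Lib")
    taxa = list(wide.columns)
    arr = np.empty((len(complete), len(taxa), len(times)))
    lib_grid = []
    for i, s in enumerate(complete):
        row_libs = []
        for k, t in enumerate(times):
            libs = lib_meta.index[
                (lib_meta[subject] == s) & (lib_meta[time] == t)
            ].tolist()
            if len(libs) != 1:
                raise ValueError(
                    f"subject {s!r} has {len(libs)} libraries at time {t!r}; expected 1"
                )
            arr[i, :, k] = wide.loc[libs[0]].to_numpy()
            row_libs.append(libs[0])
        lib_grid.append(row_libs)
    return arr, complete, times, taxa, lib_grid


def three_mode_ordinate(
    micro_set: MicroSet,
    table: str,
    subject: str,
    time: str,
    method: str = "pca",
    dist_method: str = "bray",
) -> OrdinationResult:
    """Ordination of repeated-measures data collapsing over the time mode.

    See the module docstring for the two algorithms.  With a single time point
    both variants reduce to the standard PCA / PCoA of that slice.
    """
    if method not in ("pca", "pcoa"):
        raise ValueError(f"method must be 'pca' or 'pcoa', got {method!r}")
    value = "clr" if method == "pca" else "cts"
    arr, subjects, times, taxa, lib_grid = _complete_case_array(
        micro_set, table, subject, time, value
    )
    n_s, n_p, n_t = arr.shape
    if n_s < 2:
        raise ValueError("need at least 2 complete-case subjects")
    ids = [f"{s}@{t}" for t in times for s in subjects]
    time_labels = [t for t in times for _ in subjects]

    if method == "pca":
        # unfold: stack time slices along the sample mode -> (S*T) x P
        stacked = np.vstack([arr[:, :, k] for k in range(n_t)])
        return _pca_matrix(stacked, ids, taxa, time_labels=time_labels)

    # pcoa: common axes from the time-averaged Gower matrices, then project
    if dist_method not in BETA_METHODS:
        raise ValueError(f"unknown dist_method {dist_method!r}")
    metric = {"bray": "braycurtis", "jaccard-binary": "jaccard",
              "euclidean-clr": "euclidean"}[dist_method]
    if dist_method == "jaccard-binary":
        slices = [(arr[:, :, k] > 0) for k in range(n_t)]
    elif dist_method == "euclidean-clr":
        clr_arr, *_ = _complete_case_array(micro_set, table, subject, time, "clr")
        slices = [clr_arr[:, :, k] for k in range(n_t)]
    else:
        slices = [arr[:, :, k] for k in range(n_t)]
    gs = [_gower_center(squareform(pdist(sl, metric=metric))) for sl in slices]
    g_mean = np.mean(gs, axis=0)
    vals, vecs = np.linalg.eigh(g_mean)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-10 * max(abs(vals[0]), 1.0)
    if not keep.any():
        raise ValueError("three-mode PCoA: no positive eigenvalues")
    lam, u = vals[keep], vecs[:, keep]
    # project each time slice onto the common axes: scores_t = G_t U / sqrt(lam)
    per_time_scores = [g @ u / np.sqrt(lam) for g in gs]
    scores = np.vstack(per_time_scores)
    scores, _ = _fix_signs(scores, None)
    explained = lam / vals[vals > 0].sum()
    return OrdinationResult(
        method="pcoa", scores=scores, explained=explained, sample_ids=ids,
        time_labels=time_labels, negative_eigenvalues=vals[vals < 0],
    )


def ordination_ellipse(scores, groups, level: float = 0.95,
                       n_points: int = 100) -> list[EllipsePath]:
    """Per-group bivariate-normal confidence ellipses in 2-D score space.

    Each ellipse is the `level` probability contour of a normal with the group
    mean and sample covariance: the covariance is scaled by the chi-square
    quantile with 2 df.  Groups with fewer than 3 points are skipped with a
    warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("scores must have at least 2 columns")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    xy = scores[:, :2]
    groups = np.asarray(groups)
    theta = np.linspace(0.0, 2 * np.pi, n_points - 1, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    radius2 = chi2.ppf(level, df=2)
    out: list[EllipsePath] = []
    for g in pd.unique(groups):
        pts = xy[groups == g]
        if len(pts) < 3:
            logger.warning("ordination_ellipse: group %r has %d < 3 points; skipped",
                           g, len(pts))
            continue
        mean = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 0.0, None)
        transform = vecs @ np.diag(np.sqrt(vals * radius2))
        path = mean + circle @ transform.T
        path = np.vstack([path, path[:1]])  # close the path
        out.append(EllipsePath(group=str(g), points=path, level=level))
    return out
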