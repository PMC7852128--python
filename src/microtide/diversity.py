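"""Alpha diversity via bootstrapped rarefaction, beta-diversity distances, PERMANOVA.

Alpha indices are computed on count vectors: observed richness, Chao1, Shannon
diversity/evenness (natural log), Simpson diversity (1-D) and evenness
((1/D)/S_obs), and Good's coverage.  :func:`alpha_div` gates libraries on raw
depth and raw Good's coverage, then averages each index over bootstrap
rarefactions (sampling reads with replacement) to the gating depth.

Beta diversity supports Bray-Curtis on counts, binary Jaccard on presence, and
Euclidean distance on CLR values (the Aitchison distance).  PERMANOVA
partitions the Gower-centered squared dissimilarities into between- and
within-group sums of squares and assesses the pseudo-F by label permutation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_core import MicroSet

logger = logging.getLogger("microtide")

__all__ = [
    "AlphaIndices",
    "AlphaTable",
    "DistanceMatrix",
    "PermanovaResult",
    "good_coverage",
    "alpha_indices",
    "rarefy",
    "alpha_div",
    "beta_dissimilarity",
    "permanova",
]

ALPHA_INDEX_NAMES = [
    "sobs", "chao1", "shannon_h", "shannon_e", "simpson_div", "simpson_e", "goods",
]


@dataclass
class AlphaIndices:
    sobs: float
    chao1: float
    shannon_h: float
    shannon_e: float
    simpson_div: float
    simpson_e: float
    goods: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in ALPHA_INDEX_NAMES])


@dataclass
class AlphaTable:
    """Per-library alpha diversity, averaged over bootstrap rarefactions.

    ``frame`` has one row per library with columns: the seven indices (NaN for
    gated-out libraries), ``raw_depth``, ``raw_goods``, and ``status`` (one of
    ``kept`` / ``dropped-low-depth`` / ``dropped-low-coverage``).
    """

    table: str
    frame: pd.DataFrame
    iterations: int
    rarefy_depth: int


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("matrix diagonal must be zero")
        if (self.matrix < -1e-12).any():
            raise ValueError("dissimilarities must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int


def good_coverage(counts) -> float:
    """Good's coverage percent: 100 * (1 - singletons / total reads)."""
    counts = np.asarray(counts)
    n = counts.sum()
    if n <= 0:
        raise ValueError("all-zero count vector")
    f1 = int((counts == 1).sum())
    return 100.0 * (1.0 - f1 / n)


def alpha_indices(counts) -> AlphaIndices:
    """All alpha diversity indices of one count vector.

    Chao1 is ``S_obs + F1^2/(2 F2)``, falling back to the bias-corrected
    ``S_obs + F1(F1-1)/2`` when there are no doubletons.  Shannon uses natural
    log; evenness is H/ln(S_obs) (defined as 1 for a single observed taxon).
    """
    counts = np.asarray(counts)
    n = counts.sum()
    if n <= 0:
        raise ValueError("all-zero count vector")
    obs = counts[counts > 0].astype(float)
    sobs = len(obs)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    chao1 = sobs + (f1 * f1 / (2.0 * f2) if f2 > 0 else f1 * (f1 - 1) / 2.0)
    p = obs / n
    shannon_h = float(-(p * np.log(p)).sum())
    shannon_e = 1.0 if sobs == 1 else shannon_h / np.log(sobs)
    d = float((p * p).sum())
    simpson_div = 1.0 - d
    simpson_e = (1.0 / d) / sobs
    return AlphaIndices(
        sobs=float(sobs), chao1=float(chao1), shannon_h=shannon_h,
        shannon_e=float(shannon_e), simpson_div=simpson_div,
        simpson_e=float(simpson_e), goods=good_coverage(counts),
    )


def rarefy(counts, depth: int, seed=None) -> np.ndarray:
    """Bootstrap-rarefy: draw `depth` reads with replacement from the library.

    Multinomial draw with probabilities proportional to the counts; the output
    sums exactly to `depth` and taxa with zero counts stay zero.
    """
    counts = np.asarray(counts, dtype=float)
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    total = counts.sum()
    if total < 1:
        raise ValueError("cannot rarefy an empty library")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(int(depth), counts / total)


def _lib_rng(seed: int | None, lib: str) -> np.random.Generator:
    # independent, order-invariant stream per library
    entropy = [0 if seed is None else int(seed), zlib.crc32(lib.encode())]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def alpha_div(
    micro_set: MicroSet,
    table: str,
    iter: int = 100,
    min_depth: int = 10_000,
    min_goods: float = 90.0,
    seed: int | None = None,
) -> AlphaTable:
    """Alpha diversity per library: gate, bootstrap-rarefy, average.

    Libraries with raw depth < `min_depth` or raw Good's coverage < `min_goods`
    are gated out (status recorded, no index values).  Each kept library is
    rarefied to `min_depth` reads `iter` times and every index is the mean
    across iterations.  Results are independent of library order: each library
    gets its own seeded random stream derived from `seed` and its ID.
    """
    if iter < 1:
        raise ValueError(f"iter must be >= 1, got {iter}")
    cts = micro_set.wide(table, "cts")
    rows = []
    for lib in cts.index:
        vec = cts.loc[lib].to_numpy()
        depth = int(vec.sum())
        raw_goods = good_coverage(vec)
        if depth < min_depth:
            status = "dropped-low-depth"
        elif raw_goods < min_goods:
            status = "dropped-low-coverage"
        else:
            status = "kept"
        rec = {"Lib": lib, "raw_depth": depth, "raw_goods": raw_goods,
               "status": status}
        if status == "kept":
            rng = _lib_rng(seed, str(lib))
            acc = np.zeros(len(ALPHA_INDEX_NAMES))
            for _ in range(iter):
                acc += alpha_indices(rarefy(vec, min_depth, rng)).as_array()
            rec.update(dict(zip(ALPHA_INDEX_NAMES, acc / iter)))
        else:
            rec.update({nm: np.nan for nm in ALPHA_INDEX_NAMES})
        rows.append(rec)
    frame = pd.DataFrame(rows).set_index("Lib")
    n_kept = int((frame["status"] == "kept").sum())
    if n_kept == 0:
        raise ValueError(
            f"no library survives gating (min_depth={min_depth}, min_goods={min_goods})"
        )
    dropped = frame.index[frame["status"] != "kept"].tolist()
    if dropped:
        logger.info("alpha_div %s: gated out %d libraries: %s", table, len(dropped), dropped)
    return AlphaTable(table=table, frame=frame, iterations=iter, rarefy_depth=min_depth)


BETA_METHODS = ("bray", "jaccard-binary", "euclidean-clr")


def beta_dissimilarity(micro_set: MicroSet, table: str, method: str = "bray") -> DistanceMatrix:
    """Pairwise dissimilarity between libraries of one table.

    ``bray`` acts on raw counts, ``jaccard-binary`` on presence/absence, and
    ``euclidean-clr`` on the CLR values (Aitchison distance).
    """
    if method not in BETA_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {BETA_METHODS}")
    if method == "bray":
        x = micro_set.wide(table, "cts").to_numpy(dtype=float)
        d = pdist(x, metric="braycurtis")
    elif method == "jaccard-binary":
        x = micro_set.wide(table, "bin").to_numpy(dtype=bool)
        d = pdist(x, metric="jaccard")
    else:
        x = micro_set.wide(table, "clr").to_numpy(dtype=float)
        d = pdist(x, metric="euclidean")
    libs = micro_set.libraries(table)
    if len(libs) < 2:
        raise ValueError("need at least 2 libraries for beta diversity")
    return DistanceMatrix(ids=list(libs), matrix=squareform(d))


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, n_groups: int) -> tuple[float, float, float]:
    """Pseudo-F from squared dissimilarities; returns (F, SSB, SSW)."""
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssb = sst - ssw
    dfb, dfw = n_groups - 1, n - n_groups
    if ssw <= 1e-300:
        f = 0.0 if ssb <= 1e-12 else np.inf
    else:
        f = (ssb / dfb) / (ssw / dfw)
        if f < 0:
            f = 0.0
    return f, ssb, ssw


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    The total and within-group sums of squares come from the squared
    dissimilarities (equivalently the Gower-centered matrix); the p-value is
    the permutation estimator ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    groups = np.asarray(pd.Categorical(np.asarray(groups)).codes)
    n = len(dist.ids)
    if len(groups) != n:
        raise ValueError("group labels do not align with the distance matrix")
    if (groups < 0).any():
        raise ValueError("missing group labels")
    n_groups = int(groups.max()) + 1
    if n_groups < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    d2 = dist.matrix ** 2
    f_obs, ssb, ssw = _pseudo_f(d2, groups, n_groups)
    sst = ssb + ssw
    r2 = 0.0 if sst <= 0 else ssb / sst
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        f_p, _, _ = _pseudo_f(d2, perm, n_groups)
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2), p=float(p), n_perm=n_perm)
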