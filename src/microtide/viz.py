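"""Plot-data builders and thin renderers for the pipeline's figure types.

Every figure has a ``*_data`` function that returns the plotted numbers as a
tidy DataFrame (these carry the scientific content and are what the tests
exercise) and a ``render_*`` function that draws it to a PNG/SVG file with
matplotlib.

Figure types: stacked bars of observed mean relative abundance, parametric
stacked bars of model-estimated abundance, Rocky Mountain plots (per-taxon
signed magnitudes ordered along the taxa axis, colored by phylum - either rank
correlations with a covariate or signed log FDR p-values from the per-taxon
models), correlation heatmaps, and forest plots of rate/odds ratios.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import MicroSet, phylum_of
from .ordination import OrdinationResult, ordination_ellipse
from .taxa_models import TaxaModelSet

logger = logging.getLogger("microtide")

__all__ = [
    "taxa_bars_data",
    "nb_bars_data",
    "rocky_mtn_cor_data",
    "rocky_mtn_model_data",
    "cor_heatmap_data",
    "forest_data",
    "render_bars",
    "render_rocky_mountain",
    "render_heatmap",
    "render_forest",
    "render_ordination",
]

OTHER = "Other"


def _order_taxa(means: pd.Series) -> list[str]:
    """Taxa by descending overall abundance, 'Other' forced last."""
    ordered = list(means.sort_values(ascending=False).index)
    if OTHER in ordered:
        ordered.remove(OTHER)
        ordered.append(OTHER)
    return ordered


def _aggregate_top(table: pd.DataFrame, top_taxa: int | None,
                   ra_cutoff: float | None) -> pd.DataFrame:
    """Merge all but the `top_taxa` most abundant columns into 'Other'.

    `table` is groups x taxa of abundances.  Taxa whose grand-mean abundance
    is at least `ra_cutoff` are exempt from merging.
    """
    grand = table.mean(axis=0)
    if top_taxa is None:
        keep = [t for t in table.columns if t != OTHER]
    else:
        ranked = [t for t in grand.sort_values(ascending=False).index if t != OTHER]
        keep = ranked[: int(top_taxa)]
        if ra_cutoff is not None:
            keep += [t for t in ranked[int(top_taxa):] if grand[t] >= ra_cutoff]
    drop = [t for t in table.columns if t not in keep and t != OTHER]
    out = table[keep].copy()
    other = table[drop].sum(axis=1)
    if OTHER in table.columns:
        other = other + table[OTHER]
    if drop or OTHER in table.columns:
        out[OTHER] = other
    order = _order_taxa(out.mean(axis=0))
    return out[order]


def taxa_bars_data(
    micro_set: MicroSet,
    table: str,
    group: str | None = None,
    top_taxa: int | None = None,
    ra_cutoff: float | None = None,
) -> pd.DataFrame:
    """Mean observed relative abundance per taxon within each group.

    Returns tidy rows (group, Taxa, abundance); each group's abundances sum to
    100.  With `top_taxa`, all but the most abundant taxa merge into 'Other'
    (taxa above `ra_cutoff` percent are exempt).
    """
    if top_taxa is not None and top_taxa < 1:
        raise ValueError("top_taxa must be >= 1")
    ra = micro_set.wide(table, "ra")
    if group is None:
        means = ra.mean(axis=0).to_frame().T
        means.index = ["All"]
    else:
        clin = micro_set.clinical_frame(table)
        if group not in clin.columns:
            raise KeyError(f"unknown group column {group!r}")
        means = ra.groupby(clin[group], observed=True).mean()
    means = _aggregate_top(means, top_taxa, ra_cutoff)
    out = means.reset_index(names="group").melt(
        id_vars="group", var_name="Taxa", value_name="abundance"
    )
    return out


def nb_bars_data(
    models: TaxaModelSet,
    covariates: list[str] | str,
    top_taxa: int | None = 5,
    grid=None,
    n_grid: int = 20,
) -> pd.DataFrame:
    """Model-estimated composition across covariate profiles (parametric bars).

    For each profile (levels of a categorical, a grid over a continuous
    covariate, or their cross), every converged taxon's mean count is
    back-transformed from its coefficients - other covariates held at
    reference/mean, the offset at the mean log depth - and normalized across
    taxa to an estimated relative abundance in percent.
    """
    if isinstance(covariates, str):
        covariates = [c for c in covariates.replace("*", ":").split(":") if c]
    if not 1 <= len(covariates) <= 2:
        raise ValueError("give one covariate or a pair")
    for c in covariates:
        if c not in models.design.variables:
            raise KeyError(f"covariate {c!r} is not in the model")
    axes = []
    for c in covariates:
        info = models.design.variables[c]
        if info["kind"] == "categorical":
            axes.append([(c, lvl) for lvl in info["levels"]])
        else:
            g = (np.asarray(grid, dtype=float) if grid is not None
                 else np.linspace(info["min"], info["max"], n_grid))
            axes.append([(c, v) for v in g])
    profiles: list[dict] = [{}]
    for axis in axes:
        profiles = [{**p, k: v} for p in profiles for k, v in axis]

    offset = models.mean_log_depth if (
        models.spec.family == "negbin" and models.spec.offset
    ) else 0.0
    taxa = [f.taxon for f in models.fits]
    mu = np.empty((len(profiles), len(taxa)))
    for i, prof in enumerate(profiles):
        x = models.design.make_row(prof)
        for j, fit in enumerate(models.fits):
            mu[i, j] = np.exp(x @ fit.beta + offset)
    ra = 100.0 * mu / mu.sum(axis=1, keepdims=True)
    idx = pd.MultiIndex.from_frame(pd.DataFrame(profiles)) if len(covariates) > 1 \
        else pd.Index([p[covariates[0]] for p in profiles], name=covariates[0])
    wide = pd.DataFrame(ra, index=idx, columns=taxa)
    wide = _aggregate_top(wide, top_taxa, None)
    out = wide.reset_index().melt(
        id_vars=covariates, var_name="Taxa", value_name="abundance"
    )
    return out


def _rank_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "kendall":
        return float(stats.kendalltau(x, y).statistic)
    raise ValueError(f"method must be 'spearman' or 'kendall', got {method!r}")


def rocky_mtn_cor_data(
    micro_set: MicroSet,
    table: str,
    covariate: str,
    method: str = "spearman",
    label_cutoff: float = 0.3,
) -> pd.DataFrame:
    """Per-taxon rank correlation between CLR values and a numeric covariate.

    Rows: (Taxa, phylum, y, labeled); `labeled` marks |correlation| at or
    above `label_cutoff`.
    """
    clin = micro_set.clinical_frame(table)
    if covariate not in clin.columns:
        raise KeyError(f"unknown covariate {covariate!r}")
    x = pd.to_numeric(clin[covariate], errors="raise").to_numpy(dtype=float)
    if np.nanstd(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    clr = micro_set.wide(table, "clr")
    rows = []
    for taxon in micro_set.tables[table]:
        r = _rank_corr(clr[taxon].to_numpy(), x, method)
        rows.append({
            "Taxa": taxon, "phylum": phylum_of(taxon), "y": r,
            "labeled": bool(abs(r) >= label_cutoff),
        })
    return pd.DataFrame(rows)


def rocky_mtn_model_data(
    estimates: pd.DataFrame,
    coefficient: str,
    log_base: str = "e",
) -> pd.DataFrame:
    """Signed log FDR p-values from the per-taxon models for one coefficient.

    y = -log(fdr_p) for positive coefficients and +log(fdr_p) for negative
    ones, i.e. sign(beta) * |log(fdr_p)|; the y-axis direction then matches
    the direction of the estimated association.  fdr_p = 0 is capped at the
    smallest positive double.
    """
    if log_base not in ("e", "10"):
        raise ValueError("log_base must be 'e' or '10'")
    sub = estimates[estimates["Coefficient"] == coefficient]
    if sub.empty:
        raise KeyError(f"coefficient {coefficient!r} not in estimate table")
    log = np.log if log_base == "e" else np.log10
    rows = []
    for _, r in sub.iterrows():
        p = r["fdr_p"]
        if p <= 0:
            p = np.finfo(float).tiny
            logger.warning("rocky_mtn_model_data: fdr_p=0 for %r capped at %.3g",
                           r["Taxa"], p)
        beta_sign = np.sign(np.log(r["ratio"]))
        y = 0.0 if beta_sign == 0 else float(beta_sign * -log(p))
        rows.append({"Taxa": r["Taxa"], "phylum": phylum_of(r["Taxa"]), "y": y,
                     "fdr_p": r["fdr_p"]})
    return pd.DataFrame(rows)


def cor_heatmap_data(
    micro_set: MicroSet,
    table: str,
    covariates: list[str],
    method: str = "spearman",
) -> pd.DataFrame:
    """Taxa x covariates matrix of rank correlations of CLR values.

    Constant covariates are dropped with a warning.
    """
    clin = micro_set.clinical_frame(table)
    clr = micro_set.wide(table, "clr")
    cols: dict[str, np.ndarray] = {}
    for c in covariates:
        if c not in clin.columns:
            raise KeyError(f"unknown covariate {c!r}")
        x = pd.to_numeric(clin[c], errors="raise").to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            logger.warning("cor_heatmap_data: dropping constant covariate %r", c)
            continue
        cols[c] = x
    out = pd.DataFrame(index=micro_set.tables[table], columns=list(cols), dtype=float)
    for c, x in cols.items():
        for taxon in out.index:
            out.loc[taxon, c] = _rank_corr(clr[taxon].to_numpy(), x, method)
    return out


def forest_data(
    estimates: pd.DataFrame,
    coefficient: str,
    top: int | None = None,
) -> pd.DataFrame:
    """Estimate rows for one coefficient, sorted by ratio (forest-plot input).

    With `top`, only the `top` taxa with the largest |log ratio| are kept.
    """
    sub = estimates[estimates["Coefficient"] == coefficient].copy()
    if sub.empty:
        raise KeyError(f"coefficient {coefficient!r} not in estimate table")
    if top is not None:
        sub = sub.iloc[
            np.argsort(-np.abs(np.log(sub["ratio"].to_numpy())), kind="stable")[:top]
        ]
    sub = sub.sort_values("ratio", kind="stable").reset_index(drop=True)
    return sub[["Taxa", "ratio", "ci_low", "ci_high", "fdr_p"]]


# ---------------------------------------------------------------------------
# rendering (thin matplotlib layer; the science lives in the *_data outputs)

def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def _short_label(taxon: str) -> str:
    return taxon.split("/")[-1]


def render_bars(bar_data: pd.DataFrame, path, title: str = "") -> None:
    """Stacked bar chart from taxa_bars_data / nb_bars_data output."""
    plt = _plt()
    id_cols = [c for c in bar_data.columns if c not in ("Taxa", "abundance")]
    wide = bar_data.pivot_table(index=id_cols, columns="Taxa",
                                values="abundance", sort=False, observed=True)
    fig, ax = plt.subplots(figsize=(8, 5))
    bottom = np.zeros(len(wide))
    xpos = np.arange(len(wide))
    for taxon in wide.columns:
        vals = wide[taxon].to_numpy()
        ax.bar(xpos, vals, bottom=bottom, label=_short_label(taxon))
        bottom += vals
    ax.set_xticks(xpos)
    ax.set_xticklabels([str(i) for i in wide.index], rotation=45, ha="right")
    ax.set_ylabel("Relative abundance (%)")
    ax.set_title(title)
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_rocky_mountain(data: pd.DataFrame, path, title: str = "",
                          label_cutoff: float | None = None) -> None:
    """Rocky Mountain plot: per-taxon signed magnitudes colored by phylum."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(9, 4))
    phyla = list(pd.unique(data["phylum"]))
    cmap = plt.get_cmap("tab10")
    for i, ph in enumerate(phyla):
        sub = data[data["phylum"] == ph]
        ax.vlines(sub.index, 0, sub["y"], color=cmap(i % 10), label=ph)
    if "labeled" in data.columns:
        for i, r in data[data["labeled"]].iterrows():
            ax.annotate(_short_label(r["Taxa"]), (i, r["y"]), fontsize=6)
    ax.axhline(0, color="black", lw=0.6)
    ax.set_xlabel("Taxa")
    ax.set_title(title)
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_heatmap(matrix: pd.DataFrame, path, title: str = "") -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(matrix))))
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels([_short_label(t) for t in matrix.index], fontsize=6)
    fig.colorbar(im, ax=ax)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_forest(data: pd.DataFrame, path, title: str = "") -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(data))))
    ypos = np.arange(len(data))
    ax.errorbar(
        data["ratio"], ypos,
        xerr=[data["ratio"] - data["ci_low"], data["ci_high"] - data["ratio"]],
        fmt="o", color="black", ecolor="gray", capsize=2,
    )
    ax.axvline(1.0, color="red", lw=0.8, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels([_short_label(t) for t in data["Taxa"]], fontsize=7)
    ax.set_xscale("log")
    ax.set_xlabel("Ratio (log scale)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_ordination(
    result: OrdinationResult, path, groups=None, level: float | None = 0.95,
    title: str = "",
) -> None:
    """Scatter of the first two ordination axes, optionally with group ellipses."""
    plt = _plt()
    if result.axis_count < 2:
        raise ValueError("need at least 2 axes to draw an ordination plot")
    xy = result.scores[:, :2]
    fig, ax = plt.subplots(figsize=(6, 5))
    if groups is None:
        ax.scatter(xy[:, 0], xy[:, 1], s=18)
    else:
        groups = np.asarray(groups)
        cmap = plt.get_cmap("tab10")
        for i, g in enumerate(pd.unique(groups)):
            pts = xy[groups == g]
            ax.scatter(pts[:, 0], pts[:, 1], s=18, color=cmap(i % 10), label=str(g))
        if level is not None:
            for ell in ordination_ellipse(xy, groups, level=level):
                ax.plot(ell.points[:, 0], ell.points[:, 1], lw=1)
        ax.legend(fontsize=7)
    pct = 100 * result.explained
    ax.set_xlabel(f"Axis 1 ({pct[0]:.1f}%)")
    if len(pct) > 1:
        ax.set_ylabel(f"Axis 2 ({pct[1]:.1f}%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
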