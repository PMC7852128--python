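"""Synthetic OTU-table and clinical fixtures with known ground truth.

Counts are Dirichlet-multinomial: each library draws its composition from a
Dirichlet around a skewed base composition (the concentration controls
overdispersion; infinite concentration degenerates to a plain multinomial) and
then draws reads multinomially at a depth uniform over ``depth_range``.
Covariate effects act as log-fold shifts of the Dirichlet mean before
renormalization, so the induced log-fold change of a focal taxon's expected
proportion - the "true beta" that count regressions should recover - is known
exactly and stored in the truth record.

The longitudinal generator gives each subject a latent composition that
random-walks across time points with a configurable drift, and can leave some
subjects without their later time points to exercise complete-case handling.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import ClinicalTable, OtuTable, write_otu_table

__all__ = ["SimSpec", "SimResult", "simulate_micro", "simulate_longitudinal", "preset"]

PHYLA = ["Firmicutes", "Proteobacteria", "Bacteroidetes", "Actinobacteria"]

AGE_REF = 65.0  # age effects are log-fold per year away from this reference


def default_base_props(n_taxa: int, decay: float = 0.65) -> np.ndarray:
    """Skewed composition typical of amplicon data: geometric decay over taxa."""
    p = decay ** np.arange(n_taxa)
    return p / p.sum()


def taxon_labels(n_taxa: int, rank: str = "Genus") -> list[str]:
    return [
        f"Bacteria/{PHYLA[i % len(PHYLA)]}/{rank}_{i + 1:02d}" for i in range(n_taxa)
    ]


@dataclass
class SimSpec:
    """Study conditions for one simulated cohort.

    ``effects`` maps taxon label -> {"group": log-fold for group Yes vs No,
    "age": log-fold per year of age above/below the reference}.
    ``overdispersion`` is the Dirichlet concentration (np.inf = multinomial).
    ``longitudinal`` is None or a dict with n_subject, n_time, drift,
    n_complete.
    """

    n_lib: int = 30
    n_taxa: int = 8
    table_name: str = "Genus"
    base_props: np.ndarray | None = None
    overdispersion: float = 50.0
    depth_range: tuple[int, int] = (1000, 5000)
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    longitudinal: dict | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.base_props is None:
            self.base_props = default_base_props(self.n_taxa)
        self.base_props = np.asarray(self.base_props, dtype=float)
        if len(self.base_props) != self.n_taxa:
            raise ValueError("base_props length must equal n_taxa")
        if abs(self.base_props.sum() - 1.0) > 1e-9:
            raise ValueError("base_props must sum to 1")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth_range")
        labels = set(taxon_labels(self.n_taxa, self.table_name))
        unknown = [t for t in self.effects if t not in labels]
        if unknown:
            raise ValueError(f"effects reference unknown taxa: {unknown}")

    @property
    def taxa(self) -> list[str]:
        return taxon_labels(self.n_taxa, self.table_name)


@dataclass
class SimResult:
    otu: OtuTable
    clinical: ClinicalTable
    truth: dict
    paths: dict = field(default_factory=dict)


def _effect_matrix(spec: SimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-taxon (group, age) log-fold vectors."""
    g = np.zeros(spec.n_taxa)
    a = np.zeros(spec.n_taxa)
    for i, t in enumerate(spec.taxa):
        eff = spec.effects.get(t, {})
        g[i] = eff.get("group", 0.0)
        a[i] = eff.get("age", 0.0)
    return g, a


def _shifted_props(spec: SimSpec, group01: float, age: float) -> np.ndarray:
    g, a = _effect_matrix(spec)
    w = spec.base_props * np.exp(g * group01 + a * (age - AGE_REF))
    return w / w.sum()


def _draw_counts(rng: np.random.Generator, props: np.ndarray, depth: int,
                 conc: float) -> np.ndarray:
    if np.isinf(conc):
        return rng.multinomial(depth, props)
    comp = rng.dirichlet(conc * props)
    return rng.multinomial(depth, comp)


def _true_betas(spec: SimSpec) -> dict:
    """Induced log-fold change of each affected taxon's expected proportion."""
    base_age = AGE_REF
    p_ref = _shifted_props(spec, 0.0, base_age)
    p_grp = _shifted_props(spec, 1.0, base_age)
    out = {}
    for t, eff in spec.effects.items():
        i = spec.taxa.index(t)
        rec = {}
        if "group" in eff:
            rec["group"] = float(np.log(p_grp[i] / p_ref[i]))
        if "age" in eff:
            p_age = _shifted_props(spec, 0.0, base_age + 1.0)
            rec["age"] = float(np.log(p_age[i] / p_ref[i]))
        out[t] = rec
    return out


def _clinical_frame(ids: list[str], group01: np.ndarray, age: np.ndarray,
                    extra: dict | None = None) -> ClinicalTable:
    frame = pd.DataFrame(index=pd.Index(ids, name="Lib"))
    frame["Group"] = pd.Categorical(
        np.where(group01 > 0, "Yes", "No"), categories=["No", "Yes"]
    )
    frame["Age"] = age
    for k, v in (extra or {}).items():
        frame[k] = v
    return ClinicalTable(id_column="Lib", frame=frame)


def _write(result: SimResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    otu_path = out / f"otu_{result.otu.name.lower()}.tsv"
    write_otu_table(result.otu, otu_path)
    clin_path = out / "clinical.csv"
    clin = result.clinical.frame.reset_index()
    clin.to_csv(clin_path, index=False)
    truth_path = out / "truth.txt"
    with open(truth_path, "w") as fh:
        for k, v in sorted(_flatten(result.truth).items()):
            fh.write(f"{k}={v}\n")
    result.paths = {"otu": str(otu_path), "clinical": str(clin_path),
                    "truth": str(truth_path)}


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict):
            out.update(_flatten(v, key))
        else:
            out[key] = v
    return out


def simulate_micro(spec: SimSpec, out_dir=None) -> SimResult:
    """Simulate one cross-sectional cohort; optionally write the fixture files.

    Fully reproducible under ``spec.seed``: the same spec always produces the
    same counts, covariates and files.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"L{i + 1:03d}" for i in range(spec.n_lib)]
    group01 = rng.binomial(1, 0.5, size=spec.n_lib).astype(float)
    age = np.round(rng.uniform(50.0, 80.0, size=spec.n_lib), 1)
    depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1,
                          size=spec.n_lib)
    counts = np.zeros((spec.n_taxa, spec.n_lib), dtype=np.int64)
    for j in range(spec.n_lib):
        props = _shifted_props(spec, group01[j], age[j])
        counts[:, j] = _draw_counts(rng, props, int(depths[j]), spec.overdispersion)
    otu = OtuTable(name=spec.table_name, taxa=spec.taxa, libraries=ids,
                   counts=counts)
    clinical = _clinical_frame(ids, group01, age)
    truth = {
        "true_beta": _true_betas(spec),
        "base_props": {t: float(p) for t, p in zip(spec.taxa, spec.base_props)},
        "overdispersion": spec.overdispersion,
        "seed": spec.seed,
    }
    result = SimResult(otu=otu, clinical=clinical, truth=truth)
    if out_dir is not None:
        _write(result, out_dir)
    return result


def simulate_longitudinal(spec: SimSpec, out_dir=None) -> SimResult:
    """Simulate a repeated-measures cohort (one library per subject x time).

    Each subject's latent log-composition takes independent Normal(0, drift)
    steps between consecutive time points; with drift 0 the expected
    composition is identical across time.  Subjects beyond ``n_complete`` lose
    a random suffix of their later time points.
    """
    if spec.longitudinal is None:
        raise ValueError("spec.longitudinal must be set")
    cfg = dict(spec.longitudinal)
    n_subject = int(cfg.get("n_subject", 24))
    n_time = int(cfg.get("n_time", 3))
    drift = float(cfg.get("drift", 0.3))
    n_complete = int(cfg.get("n_complete", n_subject))
    if n_time < 2:
        raise ValueError("need at least 2 time points")
    if not 0 <= n_complete <= n_subject:
        raise ValueError("n_complete must be in [0, n_subject]")
    rng = np.random.default_rng(spec.seed)
    group01 = rng.binomial(1, 0.5, size=n_subject).astype(float)
    age = np.round(rng.uniform(50.0, 80.0, size=n_subject), 1)
    ids, rows, subj_col, time_col, g_col, a_col = [], [], [], [], [], []
    for s in range(n_subject):
        base = _shifted_props(spec, group01[s], age[s])
        log_latent = np.log(base)
        if s < n_complete:
            t_keep = n_time
        else:
            t_keep = int(rng.integers(1, n_time))  # at least one, never all
        for t in range(n_time):
            if t > 0:
                log_latent = log_latent + rng.normal(0.0, drift, size=spec.n_taxa)
            if t >= t_keep:
                continue
            props = np.exp(log_latent)
            props = props / props.sum()
            depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
            rows.append(_draw_counts(rng, props, depth, spec.overdispersion))
            ids.append(f"S{s + 1:02d}T{t + 1}")
            subj_col.append(f"S{s + 1:02d}")
            time_col.append(f"T{t + 1}")
            g_col.append(group01[s])
            a_col.append(age[s])
    counts = np.asarray(rows).T
    otu = OtuTable(name=spec.table_name, taxa=spec.taxa, libraries=ids,
                   counts=counts)
    clinical = _clinical_frame(
        ids, np.asarray(g_col), np.asarray(a_col),
        extra={
            "Subject": pd.Categorical(subj_col, categories=sorted(set(subj_col))),
            "Time": pd.Categorical(time_col, categories=[f"T{t+1}" for t in range(n_time)]),
        },
    )
    truth = {
        "true_beta": _true_betas(spec),
        "drift": drift,
        "n_subject": n_subject,
        "n_complete": n_complete,
        "n_time": n_time,
        "seed": spec.seed,
    }
    result = SimResult(otu=otu, clinical=clinical, truth=truth)
    if out_dir is not None:
        _write(result, out_dir)
    return result


def preset(name: str, seed: int | None = None) -> SimSpec:
    """Named study conditions.

    ``small``: a quick 30-library, 8-taxon cohort with one group-affected
    taxon.  ``mrsa-like``: 52 libraries / 25 genera at deep sequencing,
    mirroring a two-arm carriage study.  ``bpd-like``: 24 subjects at 3 time
    points with 15 complete cases, mirroring a ventilated-infant cohort.
    """
    if name == "small":
        spec = SimSpec(
            n_lib=30, n_taxa=8, overdispersion=50.0, depth_range=(1000, 5000),
            seed=seed,
        )
        spec.effects = {spec.taxa[2]: {"group": 0.8}}
        return spec
    if name == "mrsa-like":
        spec = SimSpec(
            n_lib=52, n_taxa=25, overdispersion=30.0,
            depth_range=(10_000, 100_000), seed=seed,
        )
        spec.effects = {spec.taxa[3]: {"group": 0.8}, spec.taxa[7]: {"age": 0.04}}
        return spec
    if name == "bpd-like":
        spec = SimSpec(
            n_lib=0, n_taxa=12, table_name="Family", overdispersion=40.0,
            depth_range=(5_000, 20_000), seed=seed,
            longitudinal={"n_subject": 24, "n_time": 3, "drift": 0.3,
                          "n_complete": 15},
        )
        return spec
    raise ValueError(f"unknown preset {name!r}; choose small / mrsa-like / bpd-like")
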