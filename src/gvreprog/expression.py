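"""Nascent-transcriptome quantification and response classification.

Implements the sequencing-arm analyses: TPM normalization, oocyte-
inducible gene calling (nascent TPM ≥ 1 after NT), per-gene response
classification (activated / enhanced / repressed / unchanged),
reprogramming-resistant gene identification (≥4-fold lower after NT than
in other donor cell types, excluding oocyte-downregulated genes),
log-scale Pearson correlations, top-expressed gene lists and
correlation-distance hierarchical clustering for heatmap ordering.

All thresholding operates on replicate-mean TPM with a single configured
pseudocount; classes are assigned with the precedence
activated → enhanced → repressed → unchanged, which makes them mutually
exclusive and exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from gvreprog.containers import CountMatrix, ExpressionMatrix

CLASS_ORDER = ("activated", "enhanced", "repressed", "unchanged")


@dataclass
class ClassificationConfig:
    """Thresholds of the response and resistance calls.

    ``tpm_inducible`` — nascent TPM needed for a gene to count as
    oocyte-inducible; ``tpm_expressed`` — donor TPM above which a gene is
    "expressed" (below it an induced gene is *activated*, above it
    *enhanced*); ``fc_enhance``/``fc_repress`` — minimum fold changes for
    enhancement and repression; ``fc_resist`` — minimum cross-cell-type NT
    fold change for resistance; ``pseudocount`` is added to every TPM
    before ratios and logs.
    """

    tpm_inducible: float = 1.0
    tpm_expressed: float = 1.0
    fc_enhance: float = 2.0
    fc_repress: float = 2.0
    fc_resist: float = 4.0
    pseudocount: float = 1.0
    log_base: float = 2.0
    aggregate: str = "mean"  # replicate aggregation: "mean" or "median"

    def validate(self) -> None:
        for name in ("tpm_inducible", "tpm_expressed", "fc_enhance", "fc_repress", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.fc_resist < 1:
            raise ValueError("fc_resist must be >= 1")
        if self.aggregate not in ("mean", "median"):
            raise ValueError("aggregate must be 'mean' or 'median'")

    def agg(self, frame: pd.DataFrame) -> pd.Series:
        return frame.mean(axis=1) if self.aggregate == "mean" else frame.median(axis=1)

    def log(self, values):
        return np.log(values + self.pseudocount) / np.log(self.log_base)


def compute_tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Transcripts per million: TPM_g = 1e6 · (c_g/L_g) / Σ_j (c_j/L_j).

    Every sample column sums to 10^6. A sample with zero total counts has
    no defined composition and raises.
    """
    rate = counts.counts.div(counts.lengths, axis=0)
    totals = rate.sum(axis=0)
    dead = totals[totals <= 0]
    if len(dead):
        raise ValueError(f"all-zero samples: {list(dead.index)}")
    tpm = rate.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm=tpm, source=counts)


def _nt_mean(expr: ExpressionMatrix, cfg: ClassificationConfig, cell_type: str, timepoint=None):
    cols = expr.select_samples(cell_type=cell_type, condition="NT", timepoint=timepoint)
    if not cols:
        raise ValueError(f"no NT samples for cell type {cell_type}")
    return cfg.agg(expr.tpm[cols])


@dataclass
class InducibleResult:
    """Per-cell-type oocyte-inducible gene sets with Venn-region counts."""

    sets: dict[str, set[str]]
    union: set[str]
    venn: dict[str, int]  # exclusive regions keyed like "ESC&MYO"

    @property
    def sizes(self) -> dict[str, int]:
        return {ct: len(s) for ct, s in self.sets.items()}


def call_inducible(
    expr: ExpressionMatrix,
    cfg: ClassificationConfig | None = None,
    cell_types: list[str] | None = None,
    timepoint: str | None = None,
) -> InducibleResult:
    """Genes whose replicate-mean nascent TPM after NT reaches the threshold.

    Returns the per-cell-type sets, their union, and all exclusive
    Venn-region counts across the requested cell types.
    """
    cfg = cfg or ClassificationConfig()
    cfg.validate()
    if cell_types is None:
        nt_meta = expr.metadata[expr.metadata["condition"] == "NT"]
        cell_types = sorted(nt_meta["cell_type"].unique())
    sets = {}
    for ct in cell_types:
        means = _nt_mean(expr, cfg, ct, timepoint)
        sets[ct] = set(means.index[means >= cfg.tpm_inducible])
    union: set[str] = set().union(*sets.values()) if sets else set()
    venn: dict[str, int] = {}
    for r in range(1, len(cell_types) + 1):
        for combo in combinations(cell_types, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in cell_types if c not in combo), set())
            venn["&".join(combo)] = len(inside - outside)
    return InducibleResult(sets=sets, union=union, venn=venn)


def classify_response(
    expr: ExpressionMatrix,
    cfg: ClassificationConfig | None = None,
    cell_type: str = "MEF",
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Per-gene response class of one cell type after NT.

    Classes on replicate-mean TPM (d = donor, n = NT, pc = pseudocount),
    in precedence order:

    * activated — d < tpm_expressed and n ≥ tpm_inducible;
    * enhanced  — d ≥ tpm_expressed and (n+pc)/(d+pc) ≥ fc_enhance;
    * repressed — (d+pc)/(n+pc) ≥ fc_repress;
    * unchanged — otherwise.

    Returns a table with gene_id index and columns ``cell_type``,
    ``class``, ``inducible``, ``donor_tpm``, ``nt_tpm``, ``fc``.
    """
    cfg = cfg or ClassificationConfig()
    cfg.validate()
    donor_cols = expr.select_samples(cell_type=cell_type, condition="donor")
    if not donor_cols:
        raise ValueError(f"no donor samples for cell type {cell_type}")
    d = cfg.agg(expr.tpm[donor_cols])
    n = _nt_mean(expr, cfg, cell_type, timepoint)
    pc = cfg.pseudocount
    fc = (n + pc) / (d + pc)
    activated = (d < cfg.tpm_expressed) & (n >= cfg.tpm_inducible)
    enhanced = ~activated & (d >= cfg.tpm_expressed) & (fc >= cfg.fc_enhance)
    repressed = ~activated & ~enhanced & (1.0 / fc >= cfg.fc_repress)
    cls = pd.Series("unchanged", index=expr.genes, name="class")
    cls[repressed] = "repressed"
    cls[enhanced] = "enhanced"
    cls[activated] = "activated"
    return pd.DataFrame(
        {
            "cell_type": cell_type,
            "class": cls,
            "inducible": n >= cfg.tpm_inducible,
            "donor_tpm": d,
            "nt_tpm": n,
            "fc": fc,
        }
    )


def response_summary(response: pd.DataFrame) -> pd.Series:
    """Percentage of genes per response class (Table-1 style)."""
    pct = response["class"].value_counts(normalize=True) * 100
    return pct.reindex(CLASS_ORDER, fill_value=0.0).rename("percent")


def find_resistant(
    expr: ExpressionMatrix,
    responses: dict[str, pd.DataFrame],
    cfg: ClassificationConfig | None = None,
    mode: str = "mean",
    timepoint: str | None = None,
) -> dict[str, set[str]]:
    """Reprogramming-resistant gene sets per cell type.

    A gene is resistant in focal cell type X when (a) it is inducible in
    at least one other cell type, (b) its NT level is ≥ ``fc_resist``-fold
    lower than the other cell types' NT level — the mean over other cell
    types in ``mode="mean"``, any single other cell type in
    ``mode="pairwise"`` — and (c) it is not classified repressed in X
    (genes the oocyte itself downregulates are excluded).
    """
    cfg = cfg or ClassificationConfig()
    cfg.validate()
    cell_types = sorted(responses)
    if len(cell_types) < 2:
        raise ValueError("resistance needs >= 2 cell types")
    if mode not in ("mean", "pairwise"):
        raise ValueError("mode must be 'mean' or 'pairwise'")
    nt = {ct: _nt_mean(expr, cfg, ct, timepoint) for ct in cell_types}
    pc = cfg.pseudocount
    out: dict[str, set[str]] = {}
    for focal in cell_types:
        others = [c for c in cell_types if c != focal]
        inducible_elsewhere = np.zeros(len(expr.genes), dtype=bool)
        for c in others:
            inducible_elsewhere |= (nt[c] >= cfg.tpm_inducible).to_numpy()
        if mode == "mean":
            other_level = pd.concat([nt[c] for c in others], axis=1).mean(axis=1)
            low = ((other_level + pc) / (nt[focal] + pc) >= cfg.fc_resist).to_numpy()
        else:
            low = np.zeros(len(expr.genes), dtype=bool)
            for c in others:
                ratio = (nt[c] + pc) / (nt[focal] + pc)
                low |= ((ratio >= cfg.fc_resist) & (nt[c] >= cfg.tpm_inducible)).to_numpy()
        not_repressed = (responses[focal]["class"] != "repressed").to_numpy()
        keep = inducible_elsewhere & low & not_repressed
        out[focal] = set(expr.genes[keep])
    return out


def correlate_groups(
    expr: ExpressionMatrix,
    group_a: dict[str, object],
    group_b: dict[str, object],
    cfg: ClassificationConfig | None = None,
) -> float:
    """Pearson r between two sample groups on log2(TPM+pc) replicate means.

    Groups are metadata filters, e.g. ``{"cell_type": "MEF",
    "condition": "NT", "timepoint": "24h"}``.
    """
    cfg = cfg or ClassificationConfig()
    x = cfg.log(expr.group_mean(**group_a))
    y = cfg.log(expr.group_mean(**group_b))
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a correlation input")
    return float(pearsonr(x, y).statistic)


def top_expressed(
    expr: ExpressionMatrix,
    cell_type: str,
    condition: str = "NT",
    n: int = 1500,
    cfg: ClassificationConfig | None = None,
    timepoint: str | None = None,
) -> list[str]:
    """Top-``n`` genes by replicate-mean TPM, ties broken by gene id."""
    cfg = cfg or ClassificationConfig()
    if n > len(expr.genes):
        raise ValueError("n exceeds gene count")
    cols = expr.select_samples(cell_type=cell_type, condition=condition, timepoint=timepoint)
    if not cols:
        raise ValueError("no samples match")
    means = cfg.agg(expr.tpm[cols])
    order = means.sort_index().sort_values(ascending=False, kind="stable")
    return list(order.index[:n])


def cluster_order(
    expr: ExpressionMatrix,
    genes: list[str] | None = None,
    cfg: ClassificationConfig | None = None,
) -> tuple[list[str], list[str]]:
    """Average-linkage clustering on (1 − Pearson r) for heatmap ordering.

    Returns (sample leaf order, gene leaf order) over log2(TPM+pc) values
    of the chosen gene subset.
    """
    cfg = cfg or ClassificationConfig()
    sub = expr.tpm if genes is None else expr.tpm.loc[list(genes)]
    if sub.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    logx = cfg.log(sub.to_numpy(dtype=float))
    if np.allclose(logx.std(axis=0), 0) or np.allclose(logx.std(axis=1), 0):
        raise ValueError("constant matrix: correlation distance undefined")
    sample_d = pdist(logx.T, metric="correlation")
    sample_order = [sub.columns[i] for i in leaves_list(linkage(sample_d, method="average"))]
    # constant genes have undefined correlation distance: cluster the
    # variable genes and append the flat ones in input order
    variable = logx.std(axis=1) > 0
    if variable.sum() >= 2:
        gene_d = pdist(logx[variable], metric="correlation")
        var_idx = sub.index[variable]
        gene_order = [var_idx[i] for i in leaves_list(linkage(gene_d, method="average"))]
        gene_order += list(sub.index[~variable])
    else:
        gene_order = list(sub.index)
    return sample_order, gene_order
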