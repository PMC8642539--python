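"""Single-cell quantification: species assignment, QC, cell-cycle scoring,
phase binning, proportion shifts, and volcano-category classification.

The computations mirror the in-vivo analysis of the xenograft experiment:
barcodes are classified by the percentage of UMIs aligning to the human vs
mouse transcriptome (barnyard separation), filtered with the 200 / 6000
detected-gene and 10% mitochondrial thresholds, scored for S and G2/M
expression programs against expression-matched control genes, binned into
G1 / S / G2M, and compared across treatment arms as percentage-point
proportion shifts.  Differential-expression results (any log2FC + Bonferroni
p table) are classified into up / down / not-significant volcano categories.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "species_assign",
    "qc_filter",
    "normalize_log1p",
    "module_score",
    "assign_phase",
    "score_cell_cycle",
    "proportion_shift",
    "bonferroni",
    "volcano_classify",
    "rank_sum_de",
]


def _counts(adata: ad.AnnData) -> sparse.csr_matrix:
    X = adata.X
    return X.tocsr() if sparse.issparse(X) else sparse.csr_matrix(X)


# --------------------------------------------------------------------------
# species deconvolution
# --------------------------------------------------------------------------

def species_assign(
    adata: ad.AnnData,
    threshold_pct: float = 90.0,
    refine: bool = False,
) -> pd.DataFrame:
    """Classify barcodes by percent of UMIs on human- vs mouse-tagged genes.

    A barcode is ``human`` when ``pct_human >= threshold_pct``, ``mouse``
    when ``pct_mouse >= threshold_pct``, else ``ambiguous`` (excluded from
    downstream analysis).  ``refine=True`` replaces the fixed threshold with
    a two-component 1D clustering of ``pct_human`` (a stand-in for the
    cluster-guided separation used on real data).  Results are returned and
    written to ``adata.obs``.
    """
    if "species" not in adata.var.columns:
        raise ValueError("features carry no species tags")
    X = _counts(adata)
    human_mask = (adata.var["species"].to_numpy() == "human")
    total = np.asarray(X.sum(axis=1)).ravel()
    human = np.asarray(X[:, human_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_human = np.where(total > 0, 100.0 * human / total, 0.0)
    pct_mouse = 100.0 - pct_human

    if refine:
        # 2-means on pct_human; assign by nearer centre, ambiguous in between
        lo, hi = np.percentile(pct_human, [10, 90])
        c = np.array([lo, hi], dtype=float)
        for _ in range(50):
            lab = np.abs(pct_human[:, None] - c[None, :]).argmin(axis=1)
            new = np.array([pct_human[lab == k].mean() if (lab == k).any()
                            else c[k] for k in (0, 1)])
            if np.allclose(new, c):
                break
            c = new
        mid = c.mean()
        margin = 0.1 * abs(c[1] - c[0])
        label = np.where(pct_human > mid + margin, "human",
                         np.where(pct_human < mid - margin, "mouse",
                                  "ambiguous"))
    else:
        label = np.where(pct_human >= threshold_pct, "human",
                         np.where(pct_mouse >= threshold_pct, "mouse",
                                  "ambiguous"))

    out = pd.DataFrame(
        {"pct_human": pct_human, "pct_mouse": pct_mouse, "species": label},
        index=adata.obs_names,
    )
    adata.obs[["pct_human", "pct_mouse", "species"]] = out
    return out


# --------------------------------------------------------------------------
# QC filtering
# --------------------------------------------------------------------------

def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_genes: int = 6000,
    max_mito_pct: float = 10.0,
) -> pd.Series:
    """Boolean pass-filter mask per barcode under the 200/6000/10% rule.

    A cell is retained iff ``min_genes <= detected genes <= max_genes`` and
    ``pct_mito <= max_mito_pct``: the discard rules are strict ("less
    than" / "more than"), so boundary cells are kept.  Detected genes /
    mito percentages are computed from the counts and written to
    ``adata.obs`` along with ``pass_qc``.
    """
    X = _counts(adata)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    if "mito" in adata.var.columns:
        mito_mask = adata.var["mito"].to_numpy().astype(bool)
    else:
        raise ValueError("features carry no mito flags")
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(total > 0, 100.0 * mito / total, 0.0)

    keep = (n_genes >= min_genes) & (n_genes <= max_genes) \
        & (pct_mito <= max_mito_pct)
    adata.obs["n_genes_detected"] = n_genes
    adata.obs["pct_mito"] = pct_mito
    adata.obs["pass_qc"] = keep
    return pd.Series(keep, index=adata.obs_names, name="pass_qc")


# --------------------------------------------------------------------------
# module scoring (Tirosh-style)
# --------------------------------------------------------------------------

def normalize_log1p(adata: ad.AnnData, target_sum: float = 1e4) -> np.ndarray:
    """Counts-per-``target_sum`` followed by log1p, as a dense array."""
    X = _counts(adata).astype(float)
    total = np.asarray(X.sum(axis=1)).ravel()
    total[total == 0] = 1.0
    scaled = X.multiply(target_sum / total[:, None]).tocsr()
    return np.log1p(np.asarray(scaled.todense()))


def module_score(
    adata: ad.AnnData,
    program_genes,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    log_expr: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell expression score of a gene program vs matched controls.

    Genes are ranked by their population-average log-normalized expression
    and cut into ``n_bins`` equal-frequency bins; for every program gene,
    ``n_ctrl`` control genes are drawn (with replacement) from its bin.
    The score is mean(program genes) - mean(control genes) on the
    log-normalized data, so a score near 0 means "no different from
    expression-matched background".  Deterministic given ``seed``.
    Program genes missing from the panel are dropped with a warning.
    """
    program_genes = list(program_genes)
    if not program_genes:
        raise ValueError("empty gene program")
    present = [g for g in program_genes if g in adata.var_names]
    missing = sorted(set(program_genes) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} program gene(s) absent from the panel "
                      f"and dropped: {missing[:5]}...", stacklevel=2)
    if not present:
        raise ValueError("no program genes present in the panel")

    if log_expr is None:
        log_expr = normalize_log1p(adata)
    rng = np.random.default_rng(seed)
    var_index = pd.Index(adata.var_names)
    gene_avg = log_expr.mean(axis=0)

    order = pd.Series(gene_avg, index=var_index).rank(method="first")
    bins = pd.qcut(order, q=min(n_bins, len(order)), labels=False,
                   duplicates="drop")
    bin_members = {b: np.where(bins.to_numpy() == b)[0]
                   for b in np.unique(bins)}

    prog_idx = var_index.get_indexer(present)
    # per-gene control averaging keeps the bin weighting of the program
    # (a flat union of all draws would over-weight sparsely hit bins);
    # program genes are excluded from their own control pools, which
    # matters on a small panel where they can dominate a bin
    ctrl_cell_mean = np.zeros(log_expr.shape[0])
    for gi in prog_idx:
        pool = bin_members[bins.iloc[gi]]
        pool_clean = pool[~np.isin(pool, prog_idx)]
        if len(pool_clean):
            pool = pool_clean
        drawn = rng.choice(pool, size=n_ctrl, replace=True)
        ctrl_cell_mean += log_expr[:, drawn].mean(axis=1)
    ctrl_cell_mean /= len(prog_idx)

    return log_expr[:, prog_idx].mean(axis=1) - ctrl_cell_mean


def assign_phase(s_score, g2m_score) -> np.ndarray:
    """Bin cells into G1 / S / G2M from the two module scores.

    Cells with both scores <= 0 ("lower G2M and S scores") are G1;
    otherwise the phase of the larger score wins, ties going to S.
    """
    s = np.atleast_1d(np.asarray(s_score, dtype=float))
    g = np.atleast_1d(np.asarray(g2m_score, dtype=float))
    phase = np.where((s <= 0) & (g <= 0), "G1",
                     np.where(g > s, "G2M", "S"))
    return phase


def score_cell_cycle(
    adata: ad.AnnData,
    s_genes=None,
    g2m_genes=None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Convenience wrapper: S / G2M scores plus the phase call, in obs."""
    from .cell_cycle_genes import G2M_GENES, S_GENES

    s_genes = list(s_genes) if s_genes is not None else S_GENES
    g2m_genes = list(g2m_genes) if g2m_genes is not None else G2M_GENES
    log_expr = normalize_log1p(adata)
    s = module_score(adata, s_genes, n_bins, n_ctrl, seed, log_expr=log_expr)
    g = module_score(adata, g2m_genes, n_bins, n_ctrl, seed + 1,
                     log_expr=log_expr)
    out = pd.DataFrame(
        {"s_score": s, "g2m_score": g, "phase": assign_phase(s, g)},
        index=adata.obs_names,
    )
    adata.obs[["s_score", "g2m_score", "phase"]] = out
    return out


# --------------------------------------------------------------------------
# proportion shifts
# --------------------------------------------------------------------------

def proportion_shift(
    annotations: pd.DataFrame,
    category: str,
    arm_col: str = "arm",
    arms: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-category percentages per arm and their difference (arm2 - arm1).

    ``annotations`` holds one row per cell with an arm column and the
    category column (phase or cluster).  Percentages sum to 100 per arm;
    ``delta_pct`` is in percentage points.
    """
    if arms is None:
        uniq = list(pd.unique(annotations[arm_col]))
        if len(uniq) != 2:
            raise ValueError(f"expected exactly 2 arms, found {uniq}")
        arms = (uniq[0], uniq[1])
    a1, a2 = arms
    for arm in arms:
        if not (annotations[arm_col] == arm).any():
            raise ValueError(f"arm {arm!r} has no cells")

    cats = pd.unique(annotations[category])
    rows = []
    for cat in cats:
        p1 = 100.0 * np.mean(
            annotations.loc[annotations[arm_col] == a1, category] == cat)
        p2 = 100.0 * np.mean(
            annotations.loc[annotations[arm_col] == a2, category] == cat)
        rows.append({category: cat, f"pct_{a1}": p1, f"pct_{a2}": p2,
                     "delta_pct": p2 - p1})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# volcano classification
# --------------------------------------------------------------------------

def bonferroni(p, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: p * m capped at 1 (m defaults to len(p))."""
    p = np.asarray(p, dtype=float)
    m = len(p) if m is None else int(m)
    return np.minimum(1.0, p * m)


def volcano_classify(
    records: pd.DataFrame,
    fc_thresh: float = 0.23,
    p_thresh: float = 1e-8,
) -> pd.DataFrame:
    """Classify DE records into up / down / ns.

    ``up``: log2fc > fc_thresh and p_bonferroni < p_thresh (both strict);
    ``down``: log2fc < -fc_thresh and p_bonferroni < p_thresh; else ``ns``.
    """
    out = records.copy()
    fc = out["log2fc"].to_numpy(dtype=float)
    p = out["p_bonferroni"].to_numpy(dtype=float)
    sig = p < p_thresh
    out["category"] = np.where(sig & (fc > fc_thresh), "up",
                               np.where(sig & (fc < -fc_thresh), "down",
                                        "ns"))
    return out


def rank_sum_de(
    adata: ad.AnnData,
    arm_col: str = "arm",
    arms: tuple[str, str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Reference DE table: per-gene rank-sum test + Bonferroni, log2 FC.

    A simple, transparent generator of (gene, log2fc, p_bonferroni) records
    for volcano classification on synthetic data: Wilcoxon rank-sum on
    log-normalized expression, fold change of mean counts-per-10k (with a
    pseudocount), Bonferroni over all features.
    """
    if arms is None:
        uniq = list(pd.unique(adata.obs[arm_col]))
        if len(uniq) != 2:
            raise ValueError(f"expected exactly 2 arms, found {uniq}")
        arms = (uniq[0], uniq[1])
    a1 = (adata.obs[arm_col] == arms[0]).to_numpy()
    a2 = (adata.obs[arm_col] == arms[1]).to_numpy()
    log_expr = normalize_log1p(adata)
    cp10k = np.expm1(log_expr)

    m1 = cp10k[a1].mean(axis=0)
    m2 = cp10k[a2].mean(axis=0)
    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    _, p = stats.mannwhitneyu(log_expr[a2], log_expr[a1], axis=0,
                              alternative="two-sided")
    return pd.DataFrame({
        "gene": adata.var_names,
        "log2fc": log2fc,
        "p_raw": p,
        "p_bonferroni": bonferroni(p, adata.n_vars),
    })
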