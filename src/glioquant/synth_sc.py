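"""Seeded synthetic droplet scRNA-seq data with planted ground truth.

Two generators emulate the in-vivo xenograft experiment:

* :func:`generate_barnyard` — a two-species (human tumor / mouse brain)
  droplet capture with ambient cross-species contamination, for testing
  species deconvolution.
* :func:`generate_cycle_cohort` — human tumor cells across two treatment
  arms with planted G1/S/G2M phase states (cells in S or G2/M express the
  corresponding gene program at an elevated rate), optional cluster
  structure with marker genes, and arm-specific phase/cluster proportions.

Counts are negative-binomial UMIs (gamma-Poisson), library sizes are
log-normal, and every planted label is stored in ``obs`` so recovery can be
scored exactly.  Matrices are returned as :class:`anndata.AnnData` with
species / mito / program tags in ``var``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .cell_cycle_genes import G2M_GENES, MITO_GENES, S_GENES

__all__ = ["ScDesign", "generate_barnyard", "generate_cycle_cohort",
           "write_mtx", "read_mtx"]

PHASES = ("G1", "S", "G2M")


@dataclass(frozen=True)
class ScDesign:
    """Design of the synthetic single-cell experiment.

    Defaults mirror the real capture: ~10,000 cells per sample, a majority-
    human barnyard (the in-vivo capture was ~76% human after filtering), a
    treated arm whose G1 fraction is 15 percentage points above control,
    and a small (~2,000 gene) panel for desk-scale speed.
    """

    n_cells: int = 10_000               # per arm / per capture
    species_mix: float = 0.76           # fraction of barcodes that are human
    ambient_rate: float = 0.05          # cross-species fraction of each library
    phase_proportions: dict = field(default_factory=lambda: {
        "DMSO": {"G1": 0.55, "S": 0.25, "G2M": 0.20},
        "UM-002": {"G1": 0.70, "S": 0.17, "G2M": 0.13},
    })
    cluster_proportions: dict | None = None   # arm -> {cluster: fraction}
    n_genes: int = 2000
    n_mouse_genes: int = 400
    n_marker_genes: int = 20            # per cluster
    fold_effect: float = 4.0            # phase-program rate multiplier
    marker_fold: float = 4.0
    mito_rate_mult: float = 1.5         # baseline mito expression boost
    frac_high_mito: float = 0.04        # planted QC violators (mito >> 10%)
    frac_low_depth: float = 0.02        # planted QC violators (few genes)
    library_mu: float = np.log(2500.0)  # log-normal library-size params
    library_sigma: float = 0.35
    dispersion: float = 10.0            # NB size; larger = closer to Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        for arm, props in self.phase_proportions.items():
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"phase proportions for {arm!r} must sum to 1")
        if not 0.0 <= self.ambient_rate < 0.5:
            raise ValueError("ambient_rate must be in [0, 0.5)")


# --------------------------------------------------------------------------
# gene panels
# --------------------------------------------------------------------------

def _human_panel(design: ScDesign, n_clusters: int) -> pd.DataFrame:
    """Feature table for the human gene panel (program/marker/mito tags)."""
    names: list[str] = []
    program: list[str] = []
    for g in S_GENES:
        names.append(g); program.append("S")
    for g in G2M_GENES:
        names.append(g); program.append("G2M")
    for g in MITO_GENES:
        names.append(g); program.append("background")
    for c in range(n_clusters):
        for j in range(design.n_marker_genes):
            names.append(f"MARKER{c}-{j}")
            program.append(f"marker{c}")
    n_bg = design.n_genes - len(names)
    if n_bg < 0:
        raise ValueError("n_genes too small for the requested programs")
    for j in range(n_bg):
        names.append(f"BG{j:04d}")
        program.append("background")
    return pd.DataFrame({
        "gene": names,
        "species": "human",
        "mito": [g in MITO_GENES for g in names],
        "program": program,
    })


def _mouse_panel(design: ScDesign) -> pd.DataFrame:
    names = [f"Mmbg{j:04d}" for j in range(design.n_mouse_genes)]
    return pd.DataFrame({
        "gene": names, "species": "mouse",
        "mito": False, "program": "background",
    })


def _base_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    # heavy-tailed relative abundances, as in real transcriptomes
    return rng.lognormal(0.0, 1.0, size=n)


def _nb_counts(mean: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts with the given mean matrix."""
    lam = rng.gamma(dispersion, mean / dispersion)
    return rng.poisson(lam)


def _library_sizes(n: int, design: ScDesign,
                   rng: np.random.Generator) -> np.ndarray:
    return np.maximum(
        rng.lognormal(design.library_mu, design.library_sigma, size=n), 1.0
    )


# --------------------------------------------------------------------------
# barnyard generator
# --------------------------------------------------------------------------

def generate_barnyard(design: ScDesign) -> ad.AnnData:
    """Two-species capture with ambient cross-species contamination.

    Each barcode is truly human with probability ``species_mix``.  A cell
    draws ``1 - ambient_rate`` of its UMIs from its own species' gene pool
    and ``ambient_rate`` from the other species' pool (multinomial over
    fixed relative gene abundances).  Planted species labels live in
    ``obs["species_true"]``.
    """
    rng = np.random.default_rng(design.seed)
    var_h = _human_panel(design, n_clusters=0)
    var_m = _mouse_panel(design)
    var = pd.concat([var_h, var_m], ignore_index=True).set_index("gene")
    n_h, n_m = len(var_h), len(var_m)

    p_h = _base_weights(n_h, rng)
    p_h[var_h["mito"].to_numpy()] *= design.mito_rate_mult
    p_h /= p_h.sum()
    p_m = _base_weights(n_m, rng)
    p_m /= p_m.sum()

    n = design.n_cells
    is_human = rng.random(n) < design.species_mix
    libs = np.round(_library_sizes(n, design, rng)).astype(int)
    cross = rng.binomial(libs, design.ambient_rate)
    own = libs - cross

    counts = np.zeros((n, n_h + n_m), dtype=np.int32)
    hum = np.where(is_human)[0]
    mou = np.where(~is_human)[0]
    if len(hum):
        counts[hum, :n_h] += rng.multinomial(own[hum], p_h).astype(np.int32)
        counts[hum, n_h:] += rng.multinomial(cross[hum], p_m).astype(np.int32)
    if len(mou):
        counts[mou, n_h:] += rng.multinomial(own[mou], p_m).astype(np.int32)
        counts[mou, :n_h] += rng.multinomial(cross[mou], p_h).astype(np.int32)

    obs = pd.DataFrame({
        "species_true": np.where(is_human, "human", "mouse"),
        "library_size": libs,
    }, index=[f"BC{i:06d}" for i in range(n)])
    adata = ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)
    adata.uns["design"] = {"kind": "barnyard", "seed": design.seed,
                           "ambient_rate": design.ambient_rate,
                           "species_mix": design.species_mix}
    return adata


# --------------------------------------------------------------------------
# cell-cycle cohort generator
# --------------------------------------------------------------------------

def generate_cycle_cohort(design: ScDesign) -> ad.AnnData:
    """Two-arm human cohort with planted cell-cycle phases and clusters.

    Per arm, phases are drawn from ``phase_proportions[arm]``; S cells
    express the S program and G2/M cells the G2/M program at
    ``fold_effect`` times the base rate.  If ``cluster_proportions`` is
    given, cells also receive a cluster whose marker genes are elevated by
    ``marker_fold``.  Small fractions of cells are planted as QC violators
    (very high mitochondrial fraction; very shallow libraries).  All truth
    is in ``obs``; the counts alone never reveal it.
    """
    if set(S_GENES) & set(G2M_GENES):
        raise ValueError("S and G2M program gene lists overlap")
    rng = np.random.default_rng(design.seed)
    arms = list(design.phase_proportions)
    clusters = (list(next(iter(design.cluster_proportions.values())))
                if design.cluster_proportions else [0])
    var = _human_panel(design, n_clusters=len(clusters)).set_index("gene")
    n_genes = len(var)

    base = _base_weights(n_genes, rng)
    base[var["mito"].to_numpy()] *= design.mito_rate_mult
    s_mask = (var["program"] == "S").to_numpy()
    g2m_mask = (var["program"] == "G2M").to_numpy()
    mito_mask = var["mito"].to_numpy()
    marker_masks = {c: (var["program"] == f"marker{i}").to_numpy()
                    for i, c in enumerate(clusters)}

    blocks, obs_rows = [], []
    for arm in arms:
        props = design.phase_proportions[arm]
        n = design.n_cells
        phases = rng.choice(PHASES, size=n,
                            p=[props[ph] for ph in PHASES])
        if design.cluster_proportions:
            cprops = design.cluster_proportions[arm]
            cl = rng.choice(clusters, size=n,
                            p=[cprops[c] for c in clusters])
        else:
            cl = np.zeros(n, dtype=int)
        high_mito = rng.random(n) < design.frac_high_mito
        low_depth = rng.random(n) < design.frac_low_depth

        rates = np.tile(base, (n, 1))
        rates[np.ix_(phases == "S", s_mask)] *= design.fold_effect
        rates[np.ix_(phases == "G2M", g2m_mask)] *= design.fold_effect
        for c, msk in marker_masks.items():
            rates[np.ix_(cl == c, msk)] *= design.marker_fold
        rates[np.ix_(high_mito, mito_mask)] *= 20.0
        rates /= rates.sum(axis=1, keepdims=True)

        libs = _library_sizes(n, design, rng)
        libs[low_depth] = rng.uniform(20, 120, size=low_depth.sum())
        mean = rates * libs[:, None]
        counts = _nb_counts(mean, design.dispersion, rng).astype(np.int32)
        blocks.append(sparse.csr_matrix(counts))
        obs_rows.append(pd.DataFrame({
            "arm": arm,
            "phase_true": phases,
            "cluster_true": cl,
            "high_mito_true": high_mito,
            "low_depth_true": low_depth,
        }))

    obs = pd.concat(obs_rows, ignore_index=True)
    obs.index = [f"BC{i:06d}" for i in range(len(obs))]
    adata = ad.AnnData(X=sparse.vstack(blocks).tocsr(), obs=obs, var=var)
    adata.uns["design"] = {
        "kind": "cycle_cohort", "seed": design.seed,
        "fold_effect": design.fold_effect,
        "phase_proportions": design.phase_proportions,
    }
    return adata


def with_fold_effect(design: ScDesign, fold: float) -> ScDesign:
    """Convenience: same design with a different phase fold-effect."""
    return replace(design, fold_effect=fold)


__all__.append("with_fold_effect")


# --------------------------------------------------------------------------
# MTX triplet I/O
# --------------------------------------------------------------------------

def write_mtx(adata: ad.AnnData, outdir) -> None:
    """Write MTX triplet (genes x cells) + features/barcodes TSV + truth CSV."""
    from pathlib import Path

    from scipy.io import mmwrite

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(outdir / "matrix.mtx", sparse.csc_matrix(adata.X.T))
    feats = adata.var.reset_index()
    feats = feats.rename(columns={feats.columns[0]: "gene"})
    cols = ["gene"] + [c for c in ("species", "mito", "program")
                       if c in feats.columns]
    feats[cols].to_csv(outdir / "features.tsv", sep="\t", index=False,
                       header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(outdir / "truth.csv")


def read_mtx(indir) -> ad.AnnData:
    """Read the triplet written by :func:`write_mtx`."""
    from pathlib import Path

    from scipy.io import mmread

    indir = Path(indir)
    X = sparse.csr_matrix(mmread(indir / "matrix.mtx").T)
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    feats.columns = ["gene", "species", "mito", "program"][: feats.shape[1]]
    var = feats.set_index("gene")
    if "mito" in var.columns:
        var["mito"] = var["mito"].astype(bool)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.DataFrame(index=barcodes.astype(str))
    truth = indir / "truth.csv"
    if truth.exists():
        obs = pd.read_csv(truth, index_col=0)
        obs.index = obs.index.astype(str)
    return ad.AnnData(X=X.astype(np.int32), obs=obs, var=var)
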