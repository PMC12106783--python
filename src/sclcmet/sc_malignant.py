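"""Single-cell preprocessing and CNV-signal malignant-cell identification.

The workflow: compute per-cell QC metrics, drop cells with fewer than 200
detected genes or more than 40% mitochondrial counts, scale each cell to the
median library size and log1p-transform, assign compartments by marker-set
signature scores, compute a smoothed relative-expression copy-number signal
against a reference cell set re-binned to 10 Mb windows, cluster cells on
that signal (PCA, cosine kNN graph, Louvain) and flag clusters that combine
a high copy-number burden with near-pure epithelial composition as
malignant.  The cluster-level malignancy rule is an automated criterion
(burden > theta x median reference-cluster burden and epithelial fraction
>= 0.9); thresholds are recorded in ``adata.uns``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import networkx as nx
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 10_000_000


@dataclass
class CnvProfile:
    """Cell x bin smoothed log2 relative-expression matrix."""

    matrix: np.ndarray            # cells x bins
    bins: pd.DataFrame            # chrom, start, end
    cell_ids: np.ndarray
    cluster: np.ndarray | None = None
    cluster_burden: pd.Series | None = None


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def compute_qc(adata) -> None:
    """Add n_genes_detected and mito_fraction to ``adata.obs`` in place."""
    X = sp.csr_matrix(adata.X)
    adata.obs["n_genes_detected"] = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(X[:, adata.var["is_mito"].to_numpy()].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    adata.obs["mito_fraction"] = frac


def qc_filter(adata, min_genes: int = 200, max_mito: float = 0.40):
    """Retain cells with >= min_genes detected genes and <= max_mito mito fraction.

    Boundary cells (exactly at either threshold) are retained, matching the
    strict removal conditions "< 200 genes" / "> 40% mitochondrial".
    """
    if "n_genes_detected" not in adata.obs:
        compute_qc(adata)
    low_genes = adata.obs["n_genes_detected"].to_numpy() < min_genes
    high_mito = adata.obs["mito_fraction"].to_numpy() > max_mito
    keep = ~(low_genes | high_mito)
    if not keep.any():
        raise ValueError(
            f"all cells removed by QC ({int(low_genes.sum())} below {min_genes} genes, "
            f"{int(high_mito.sum())} above {max_mito:.0%} mito)"
        )
    return adata[keep].copy()


def normalize_log1p(adata):
    """Median-library-size scaling followed by log1p, into layer 'normalized'.

    Raw counts stay in ``adata.X``; the scaled pre-log layer is kept as
    'norm_linear' for downstream CNV work.
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    lib = np.asarray(X.sum(axis=1)).ravel()
    if np.any(lib == 0):
        raise ValueError("zero-count cell encountered; run qc_filter first")
    target = float(np.median(lib))
    scaled = sp.diags(target / lib) @ X
    adata.layers["norm_linear"] = scaled.tocsr()
    adata.layers["normalized"] = scaled.log1p().tocsr()
    return adata


# ---------------------------------------------------------------------------
# highly variable genes
# ---------------------------------------------------------------------------

def select_hvg(adata, n_top: int = 7000) -> list[str]:
    """Variance-stabilized HVG ranking on raw counts.

    A degree-2 polynomial trend of log10(variance) on log10(mean) predicts
    each gene's expected standard deviation; per-cell values standardized by
    it are clipped at sqrt(n_cells) and the variance of the clipped values
    ranks the genes.  Ties (and zero-mean genes) fall back to gene-id order.
    """
    n_cells, n_genes = adata.shape
    if n_top > n_genes:
        raise ValueError(f"n_top={n_top} exceeds {n_genes} genes")
    X = sp.csc_matrix(adata.X, dtype=float)
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n_cells / max(n_cells - 1, 1)

    expressed = (mean > 0) & (var > 0)
    coef = np.polyfit(np.log10(mean[expressed]), np.log10(var[expressed]), deg=2)
    sigma = np.zeros(n_genes)
    trend_var = 10 ** np.polyval(coef, np.log10(mean[expressed]))
    # counts cannot be less dispersed than Poisson; guards the trend when
    # the mean range is too narrow to constrain the fit
    sigma[expressed] = np.sqrt(np.maximum(trend_var, mean[expressed]))

    clip = np.sqrt(n_cells)
    score = np.zeros(n_genes)
    for j in np.flatnonzero(expressed):
        col = X.getcol(j)
        nz = col.data
        n_zero = n_cells - len(nz)
        z_zero = np.clip((0.0 - mean[j]) / sigma[j], -clip, clip)
        z_nz = np.clip((nz - mean[j]) / sigma[j], -clip, clip)
        s = z_nz.sum() + n_zero * z_zero
        ss = (z_nz**2).sum() + n_zero * z_zero**2
        score[j] = (ss - s**2 / n_cells) / max(n_cells - 1, 1)

    order = np.lexsort((adata.var_names.to_numpy(), -score))
    return list(adata.var_names.to_numpy()[order][:n_top])


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------

def assign_compartments(adata, markers: dict[str, list], delta: float = 0.0,
                        seed: int = 0) -> None:
    """Label each cell with the compartment of its highest marker score.

    Scores use binned-control signature scoring.  Cells with no marker
    expression at all, exact top-score ties, or a winning margin below
    ``delta`` are labelled 'unassigned'.  Writes ``adata.obs['compartment']``.
    """
    from .foxa2_association import score_gene_set

    if not markers or any(len(v) == 0 for v in markers.values()):
        raise ValueError("empty marker set")
    names = list(markers)
    scores = np.column_stack(
        [score_gene_set(adata, markers[c], seed=seed) for c in names]
    )
    X = sp.csc_matrix(adata.X)
    all_marker = sorted({g for v in markers.values() for g in v if g in adata.var_names})
    marker_counts = np.asarray(
        X[:, adata.var_names.get_indexer(all_marker)].sum(axis=1)
    ).ravel()

    top = np.argmax(scores, axis=1)
    sorted_scores = np.sort(scores, axis=1)
    margin = sorted_scores[:, -1] - sorted_scores[:, -2] if scores.shape[1] > 1 else np.inf
    labels = np.array([names[i] for i in top], dtype=object)
    labels[(marker_counts == 0) | (margin <= delta)] = "unassigned"
    adata.obs["compartment"] = labels


# ---------------------------------------------------------------------------
# CNV signal
# ---------------------------------------------------------------------------

def _genome_bins(chrom_sizes: dict[str, int], bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for start in range(0, size, bin_size):
            rows.append({"chrom": chrom, "start": start, "end": min(start + bin_size, size)})
    return pd.DataFrame(rows)


def cnv_signal(
    adata,
    reference_cells,
    window: int = 51,
    bin_size: int = DEFAULT_BIN_SIZE,
    clip: float = 3.0,
) -> CnvProfile:
    """Smoothed relative-expression copy-number signal, binned to 10 Mb.

    Per gene: log2(scaled count + 1) minus the reference-cell mean, clipped
    to +/- ``clip``, moving-average smoothed over ``window`` genes ordered by
    (chrom, start) within each chromosome, median-centered per cell, then
    mean-aggregated into half-open genomic bins.
    """
    if len(reference_cells) == 0:
        raise ValueError("reference_cells must be non-empty")
    if "norm_linear" not in adata.layers:
        raise ValueError("run normalize_log1p first")
    expr = np.log2(np.asarray(sp.csr_matrix(adata.layers["norm_linear"]).todense()) + 1.0)
    ref_idx = adata.obs_names.get_indexer(reference_cells)
    if (ref_idx < 0).any():
        raise KeyError("reference cell not present in dataset")
    rel = expr - expr[ref_idx].mean(axis=0)
    rel = np.clip(rel, -clip, clip)

    var = adata.var
    chrom_sizes = adata.uns.get("chrom_sizes")
    if chrom_sizes is None:
        chrom_sizes = var.groupby("chrom")["end"].max().to_dict()
    bins = _genome_bins({k: int(v) for k, v in chrom_sizes.items()}, bin_size)

    smooth = np.zeros_like(rel)
    order_all = []
    for chrom, sub in var.groupby("chrom", sort=True):
        cols = adata.var_names.get_indexer(sub.sort_values("start").index)
        w = min(window, len(cols))
        if w < window:
            logger.info("chromosome %s has %d genes; window shrunk to %d", chrom, len(cols), w)
        if w <= 1:
            smooth[:, cols] = rel[:, cols]
        else:
            kernel = np.ones(w) / w
            block = rel[:, cols]
            # same-length moving average with edge shrinkage
            csum = np.cumsum(np.pad(block, ((0, 0), (1, 0))), axis=1)
            half = w // 2
            n = len(cols)
            lo = np.maximum(np.arange(n) - half, 0)
            hi = np.minimum(np.arange(n) + half + 1, n)
            smooth[:, cols] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
        order_all.append(cols)

    smooth -= np.median(smooth, axis=1, keepdims=True)

    mat = np.zeros((adata.n_obs, len(bins)))
    counts = np.zeros(len(bins))
    gene_bin = np.full(adata.n_vars, -1)
    for b, row in bins.iterrows():
        in_bin = (
            (var["chrom"] == row["chrom"])
            & (var["start"] >= row["start"])
            & (var["start"] < row["end"])
        ).to_numpy()
        gene_bin[in_bin] = b
        counts[b] = in_bin.sum()
        if counts[b]:
            mat[:, b] = smooth[:, in_bin].mean(axis=1)
    keep = counts > 0
    return CnvProfile(
        matrix=mat[:, keep],
        bins=bins[keep].reset_index(drop=True),
        cell_ids=adata.obs_names.to_numpy(),
    )


# ---------------------------------------------------------------------------
# malignant calling
# ---------------------------------------------------------------------------

def call_malignant(
    profile: CnvProfile,
    adata,
    theta: float = 3.0,
    min_epi_frac: float = 0.9,
    n_pcs: int = 50,
    k_neighbors: int = 15,
    seed: int = 0,
) -> None:
    """Flag cells in high-burden, epithelial-dominated CNV clusters as malignant.

    PCA of the cell x bin matrix, cosine kNN graph, seeded Louvain
    communities; per-cluster burden = mean over cells of the mean squared
    bin value.  A cluster is malignant when burden > theta x (median burden
    of non-epithelial-dominated clusters) and its epithelial fraction is
    >= ``min_epi_frac``.  Writes ``adata.obs['malignant']`` and per-cell
    cluster ids; the rule parameters go to ``adata.uns['malignant_call']``.
    """
    if "compartment" not in adata.obs:
        raise ValueError("assign compartments before calling malignant cells")
    M = profile.matrix
    n_cells = M.shape[0]
    n_comp = min(n_pcs, M.shape[1], n_cells - 1)
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(M)

    nn = NearestNeighbors(n_neighbors=min(k_neighbors + 1, n_cells), metric="cosine")
    nn.fit(pcs)
    _, idx = nn.kneighbors(pcs)
    g = nx.Graph()
    g.add_nodes_from(range(n_cells))
    for i in range(n_cells):
        for j in idx[i, 1:]:
            g.add_edge(i, int(j))
    communities = nx.community.louvain_communities(g, seed=seed)
    cluster = np.zeros(n_cells, dtype=int)
    for c, nodes in enumerate(communities):
        cluster[list(nodes)] = c

    per_cell_burden = (M**2).mean(axis=1)
    burden = pd.Series(per_cell_burden).groupby(cluster).mean()
    epi = (adata.obs["compartment"].to_numpy() == "epithelial").astype(float)
    epi_frac = pd.Series(epi).groupby(cluster).mean()

    flagged = "ok"
    if len(burden) < 2:
        # degenerate clustering: per-cell burden thresholding
        flagged = "per_cell_fallback"
        thr = theta * np.median(per_cell_burden)
        malignant = (per_cell_burden > thr) & (epi > 0)
    else:
        ref_clusters = burden.index[epi_frac < min_epi_frac]
        ref_burden = float(
            burden.loc[ref_clusters].median() if len(ref_clusters) else burden.median()
        )
        mal_clusters = burden.index[
            (burden > theta * ref_burden) & (epi_frac >= min_epi_frac)
        ]
        malignant = np.isin(cluster, mal_clusters)

    profile.cluster = cluster
    profile.cluster_burden = burden
    adata.obs["cnv_cluster"] = cluster
    adata.obs["malignant"] = malignant
    adata.uns["malignant_call"] = {
        "theta": theta,
        "min_epi_frac": min_epi_frac,
        "k_neighbors": k_neighbors,
        "seed": seed,
        "flag": flagged,
    }
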