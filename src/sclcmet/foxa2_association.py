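"""FOXA2 dichotomization and per-patient ridge co-expression ranking.

Malignant cells are split into FOXA2+ (raw count > 0) and FOXA2- groups.
Patients with more than 200 malignant cells of which at least 10% are
FOXA2+ enter the association analysis: within each patient's malignant
cells, expression is library-size normalized, log1p-transformed and
standardized gene-wise to mean 0 / variance 1, and the standardized FOXA2
expression is regressed on the standardized highly-variable-gene matrix
with an L2 penalty (closed form via the normal equations).  The per-patient
coefficient vectors are combined into a one-sample Z-score per gene,
z = mean(beta) / (sd(beta)/sqrt(P)), which ranks genes by their association
with FOXA2.  The top-ranked genes are then cross-referenced against the
bulk Pearson correlation with FOXA2.

Signature scoring (binned-control, for compartment assignment and fetal
program scores) and the one-sided Mann-Whitney U comparison of FOXA2+ vs
FOXA2- scores live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats


@dataclass
class AssociationResult:
    """Per-gene per-patient ridge coefficients with cross-patient Z-scores."""

    coefs: pd.DataFrame        # genes x patients
    z: pd.Series               # per-gene Z-score (descending defines rank)
    rank: pd.Series            # 1..n_genes, 1 = strongest positive
    degenerate: pd.Series      # flag: sd across patients at the floor
    lam: float = 1.0


@dataclass
class ScoreComparison:
    """One-sided Mann-Whitney U comparison of two score vectors."""

    u_stat: float
    p_one_sided: float
    n1: int
    n2: int
    method: str


# ---------------------------------------------------------------------------
# dichotomization and eligibility
# ---------------------------------------------------------------------------

def dichotomize_foxa2(adata, gene: str = "FOXA2") -> pd.Series:
    """FOXA2+ boolean per cell: raw count > 0, on malignant cells only.

    Non-malignant cells are False.  ``gene`` may be a var_names id or a
    symbol present in ``adata.var['symbol']``.
    """
    col = _resolve_gene(adata, gene)
    raw = np.asarray(sp.csr_matrix(adata.X)[:, col].todense()).ravel()
    if "malignant" not in adata.obs:
        raise ValueError("malignant flags not set; run call_malignant first")
    positive = (raw > 0) & adata.obs["malignant"].to_numpy()
    return pd.Series(positive, index=adata.obs_names, name="foxa2_positive")


def _resolve_gene(adata, gene: str) -> int:
    if gene in adata.var_names:
        return adata.var_names.get_loc(gene)
    if "symbol" in adata.var:
        hits = np.flatnonzero((adata.var["symbol"] == gene).to_numpy())
        if len(hits):
            return int(hits[0])
    raise KeyError(f"gene {gene!r} not found")


def eligible_patients(
    adata,
    gene: str = "FOXA2",
    min_cells: int = 200,
    min_frac: float = 0.10,
) -> list[str]:
    """Patients with > min_cells malignant cells and >= min_frac FOXA2+ fraction.

    The cell-count bound is strict (a patient with exactly ``min_cells``
    malignant cells is excluded); the positive-fraction bound is inclusive.
    """
    pos = dichotomize_foxa2(adata, gene)
    mal = adata.obs["malignant"].to_numpy()
    out = []
    for patient, idx in adata.obs.groupby("patient", observed=True).groups.items():
        loc = adata.obs_names.get_indexer(idx)
        m = mal[loc]
        n_mal = int(m.sum())
        if n_mal <= min_cells:
            continue
        frac = pos.iloc[loc].to_numpy()[m].mean()
        if frac >= min_frac:
            out.append(str(patient))
    return sorted(out)


# ---------------------------------------------------------------------------
# ridge association
# ---------------------------------------------------------------------------

def _standardize(mat: np.ndarray) -> np.ndarray:
    """Column-wise mean 0 / variance 1; zero-variance columns become 0."""
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    out = (mat - mu) / sd_safe
    out[:, sd == 0] = 0.0
    return out


def _ridge(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge coefficients; dual form when cells < genes."""
    n, p = X.shape
    if lam == 0:
        return np.linalg.lstsq(X, y, rcond=None)[0]
    if n < p:
        alpha = np.linalg.solve(X @ X.T + lam * np.eye(n), y)
        return X.T @ alpha
    return np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)


def ridge_association(
    adata,
    gene: str = "FOXA2",
    patients: list[str] | None = None,
    hvgs: list[str] | None = None,
    lam: float = 1.0,
    min_cells_fit: int = 50,
) -> AssociationResult:
    """Per-patient ridge regression of FOXA2 on HVGs, combined by Z-score.

    Within each patient's malignant cells: library-size normalize to the
    patient median, log1p, standardize each gene, solve
    (X'X + lam I) beta = X'y.  z_g = mean_p(beta_gp) / (sd_p(beta_gp)/sqrt(P))
    with the sd floored at 1e-12 (such genes flagged degenerate); rank 1 is
    the most positive z.
    """
    if patients is None:
        patients = eligible_patients(adata, gene)
    if len(patients) < 3:
        raise ValueError("Z-score undefined: fewer than 3 eligible patients")
    qcol = _resolve_gene(adata, gene)
    qname = adata.var_names[qcol]
    if hvgs is None:
        from .sc_malignant import select_hvg

        hvgs = select_hvg(adata, n_top=min(2000, adata.n_vars))
    hvgs = [g for g in hvgs if g != qname]
    hv_idx = adata.var_names.get_indexer(hvgs)
    if (hv_idx < 0).any():
        raise KeyError("HVG not present in dataset")

    mal = adata.obs["malignant"].to_numpy()
    pat = adata.obs["patient"].to_numpy()
    X_all = sp.csr_matrix(adata.X, dtype=float)

    betas = {}
    for p in patients:
        rows = np.flatnonzero((pat == p) & mal)
        if len(rows) < min_cells_fit:
            raise ValueError(f"patient {p} has fewer than {min_cells_fit} malignant cells")
        sub = np.asarray(X_all[rows].todense())
        lib = sub.sum(axis=1)
        sub = sub * (np.median(lib) / lib)[:, None]
        sub = np.log1p(sub)
        y = _standardize(sub[:, [qcol]]).ravel()
        X = _standardize(sub[:, hv_idx])
        betas[p] = _ridge(X, y, lam)

    coefs = pd.DataFrame(betas, index=hvgs)
    mean = coefs.mean(axis=1)
    sd = coefs.std(axis=1, ddof=1)
    degenerate = sd < 1e-12
    sd = sd.clip(lower=1e-12)
    z = mean / (sd / np.sqrt(len(patients)))
    order = np.lexsort((z.index.to_numpy(), -z.to_numpy()))
    rank = pd.Series(0, index=z.index, dtype=int)
    rank.iloc[order] = np.arange(1, len(z) + 1)
    return AssociationResult(
        coefs=coefs, z=z, rank=rank, degenerate=degenerate, lam=lam
    )


def crossref_bulk(
    assoc: AssociationResult,
    bulk_r: pd.Series,
    top_k: int = 100,
) -> pd.DataFrame:
    """Re-rank the association's top genes by their bulk correlation with FOXA2.

    Takes the ``top_k`` genes by association rank, attaches the bulk Pearson
    r and sorts by it (descending).  Genes absent from the bulk table are
    flagged and placed last, ordered by association rank.
    """
    top = assoc.rank[assoc.rank <= top_k].sort_values().index
    in_bulk = top.isin(bulk_r.index)
    df = pd.DataFrame(
        {
            "gene": top,
            "z": assoc.z.loc[top].to_numpy(),
            "assoc_rank": assoc.rank.loc[top].to_numpy(),
            "bulk_r": [bulk_r.get(g, np.nan) for g in top],
            "in_bulk": in_bulk,
        }
    )
    measured = df[df["in_bulk"]].sort_values("bulk_r", ascending=False)
    missing = df[~df["in_bulk"]].sort_values("assoc_rank")
    return pd.concat([measured, missing]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# signature scoring and group comparison
# ---------------------------------------------------------------------------

def score_gene_set(
    adata,
    members,
    n_bins: int = 25,
    ctrl_per_gene: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control signature score per cell.

    Genes are grouped into ``n_bins`` equal-size bins by mean normalized
    expression; each set gene contributes ``ctrl_per_gene`` control genes
    sampled (seeded, without replacement) from its bin, excluding set genes.
    Score = mean normalized expression over the set minus the mean over the
    pooled control genes.
    """
    if "normalized" not in adata.layers:
        raise ValueError("normalized layer missing; run normalize_log1p first")
    members = [g for g in members if g in adata.var_names]
    if not members:
        raise ValueError("gene set does not intersect the dataset")
    X = sp.csc_matrix(adata.layers["normalized"])
    mean_expr = np.asarray(X.mean(axis=0)).ravel()
    order = np.argsort(mean_expr, kind="mergesort")
    bin_of = np.empty(adata.n_vars, dtype=int)
    bin_of[order] = np.minimum(
        np.arange(adata.n_vars) * n_bins // adata.n_vars, n_bins - 1
    )

    member_idx = adata.var_names.get_indexer(members)
    member_set = set(member_idx)
    rng = np.random.default_rng(seed)
    ctrl: set[int] = set()
    for gi in member_idx:
        pool = np.flatnonzero(bin_of == bin_of[gi])
        pool = pool[~np.isin(pool, list(member_set))]
        take = min(ctrl_per_gene, len(pool))
        if take:
            ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl:
        raise ValueError("empty control pool")

    set_mean = np.asarray(X[:, member_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, sorted(ctrl)].mean(axis=1)).ravel()
    return set_mean - ctrl_mean


def compare_scores(scores, groups) -> ScoreComparison:
    """One-sided Mann-Whitney U test: positive group > negative group.

    ``groups`` is boolean (True = FOXA2+).  U comes from midrank sums; the
    p-value uses exact enumeration when n1*n2 <= 100 and the tie-corrected
    normal approximation otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    x, y = scores[groups], scores[~groups]
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")

    ranks = stats.rankdata(scores)
    u = ranks[groups].sum() - n1 * (n1 + 1) / 2.0

    if n1 * n2 <= 100:
        # exact enumeration over all group assignments of the midranks
        total = comb(n1 + n2, n1)
        base = n1 * (n1 + 1) / 2.0
        count = sum(
            1
            for pick in combinations(range(n1 + n2), n1)
            if ranks[list(pick)].sum() - base >= u - 1e-12
        )
        return ScoreComparison(u, count / total, n1, n2, "exact")

    n = n1 + n2
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return ScoreComparison(u, 1.0, n1, n2, "normal_tie_degenerate")
    zval = (u - n1 * n2 / 2.0) / np.sqrt(var)
    return ScoreComparison(u, float(stats.norm.sf(zval)), n1, n2, "normal_tie")
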