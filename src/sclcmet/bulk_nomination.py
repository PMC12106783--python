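"""Bulk differential expression and candidate transcription-factor nomination.

The nomination procedure compares metastasis-associated primary tumors and
metastases against never-metastatic primaries, intersects the two
differential-expression tables, and keeps genes that clear a fold-change and
adjusted-p gate in both (default FC > 4 in either direction, P_adj < 0.05),
finally restricting to transcription factors.

Differential expression is a per-gene negative-binomial GLM with a log link,
log size-factor offset and a two-level group design, fit by iteratively
reweighted least squares vectorized across genes.  Per-gene dispersion is a
within-group method-of-moments estimate (no empirical-Bayes shrinkage); the
Wald statistic is coefficient / SE referred to a t distribution with
n_samples - 2 degrees of freedom (the residual df; with estimated
per-gene dispersion the plug-in normal reference is anticonservative at
cohort-scale sample sizes), and Benjamini-Hochberg adjustment is applied
across tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import BulkCohort

_LN2 = np.log(2.0)

# preset thresholds: (fold-change cut, adjusted-p cut)
NOMINATION_PRESET = (4.0, 0.05)
STANDARD_PRESET = (1.5, 0.01)


@dataclass
class CandidateSet:
    """Genes passing the dual-comparison gate, with the TF restriction."""

    up_genes: list[str]
    down_genes: list[str]
    tf_candidates: list[str] = field(default_factory=list)
    thresholds: tuple[float, float] = NOMINATION_PRESET
    mean_abs_wald: pd.Series | None = None


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample: median over genes expressed in every sample of
    count / geometric-mean-across-samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("cannot estimate size factors: no gene expressed in all samples")
    logs = np.log(mat[all_pos])
    log_geo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geo, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _mom_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Within-group method-of-moments dispersion, floored at 1e-8.

    alpha_g = weighted average over groups of (s^2 - mean) / mean^2 using
    (n_i - 1) weights, on size-factor-normalized counts.
    """
    num = np.zeros(norm.shape[0])
    den = 0.0
    for idx in groups:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += w * a
        den += w
    return np.maximum(num / den, 1e-8)


def nb_wald_de(
    cohort: BulkCohort,
    group_a: str,
    group_b: str,
    min_total_count: int = 10,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group_b vs group_a (log2fc > 0 = higher in b).

    Returns a DeTable: DataFrame indexed by gene with columns log2fc,
    wald_stat, p, padj, flag.  Genes below ``min_total_count`` summed counts
    (including all-zero genes) are reported with log2fc 0 and p 1 and are
    excluded from the BH universe.  Genes whose IRLS does not converge fall
    back to the ratio-of-normalized-means estimate and are flagged.
    """
    meta = cohort.sample_meta
    idx_a = np.flatnonzero((meta == group_a).to_numpy())
    idx_b = np.flatnonzero((meta == group_b).to_numpy())
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("both groups need >= 2 samples")

    cols = np.concatenate([idx_a, idx_b])
    counts = cohort.counts.iloc[:, cols]
    sf = cohort.size_factors
    if sf is None:
        sf = estimate_size_factors(counts)
        s = sf.to_numpy()
    else:
        s = sf.to_numpy()[cols]
    y = counts.to_numpy(dtype=float)
    x = np.concatenate([np.zeros(len(idx_a)), np.ones(len(idx_b))])
    offset = np.log(s)

    n_genes = y.shape[0]
    tested = y.sum(axis=1) >= min_total_count
    flags = np.array(["ok"] * n_genes, dtype=object)
    flags[~tested] = "low_count"

    log2fc = np.zeros(n_genes)
    wald = np.zeros(n_genes)
    pvals = np.ones(n_genes)

    if tested.any():
        yt = y[tested]
        norm = yt / s
        ga, gb = np.arange(len(idx_a)), np.arange(len(idx_a), len(cols))
        alpha = _mom_dispersion(norm, [ga, gb])

        ma = norm[:, ga].mean(axis=1)
        mb = norm[:, gb].mean(axis=1)
        eps = 1e-8
        b0 = np.log(np.maximum(ma, eps))
        b1 = np.log(np.maximum(mb, eps)) - b0

        conv = np.zeros(len(yt), dtype=bool)
        for _ in range(max_iter):
            eta = b0[:, None] + np.outer(b1, x) + offset[None, :]
            mu = np.exp(np.clip(eta, -30.0, 30.0))
            w = mu / (1.0 + alpha[:, None] * mu)
            z = (eta - offset[None, :]) + (yt - mu) / mu
            sw = w.sum(axis=1)
            swx = (w * x).sum(axis=1)
            swxx = swx  # x is 0/1 so x^2 = x
            swz = (w * z).sum(axis=1)
            swxz = (w * x * z).sum(axis=1)
            det = sw * swxx - swx * swx
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            nb0 = (swxx * swz - swx * swxz) / det
            nb1 = (sw * swxz - swx * swz) / det
            step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
            b0, b1 = nb0, nb1
            conv |= step < tol
            if conv.all():
                break

        eta = b0[:, None] + np.outer(b1, x) + offset[None, :]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + alpha[:, None] * mu)
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        det = sw * swx - swx * swx
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        var_b1 = sw / det
        se = np.sqrt(np.maximum(var_b1, 1e-300))

        # non-convergent genes: ratio-of-normalized-means fallback, flagged
        bad = ~conv
        if bad.any():
            fb = np.log(np.maximum(mb[bad], eps)) - np.log(np.maximum(ma[bad], eps))
            b1[bad] = fb
            tflags = flags[tested]
            tflags[bad] = "irls_fallback"
            flags[tested] = tflags

        wd = b1 / se
        log2fc[tested] = b1 / _LN2
        wald[tested] = wd
        dof = max(len(cols) - 2, 1)
        pvals[tested] = 2.0 * stats.t.sf(np.abs(wd), df=dof)

    padj = np.ones(n_genes)
    if tested.any():
        padj[tested] = bh_adjust(pvals[tested])

    return pd.DataFrame(
        {"log2fc": log2fc, "wald_stat": wald, "p": pvals, "padj": padj, "flag": flags},
        index=cohort.counts.index,
    )


def intersect_candidates(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    fc_cut: float = NOMINATION_PRESET[0],
    padj_cut: float = NOMINATION_PRESET[1],
) -> CandidateSet:
    """Genes passing the FC/P_adj gate, in the same direction, in both tables.

    ``fc_cut`` is a fold change; a "negative" fold-change cut means fold
    change below 1/fc_cut (log2fc < -log2(fc_cut)).  Inequalities are strict.
    """
    if not de_a.index.equals(de_b.index):
        missing = de_a.index.symmetric_difference(de_b.index)
        raise ValueError(
            f"mismatched gene universes; first offenders: {list(missing[:5])}"
        )
    lcut = np.log2(fc_cut)
    sig_a = de_a["padj"] < padj_cut
    sig_b = de_b["padj"] < padj_cut
    up = de_a.index[(de_a["log2fc"] > lcut) & sig_a & (de_b["log2fc"] > lcut) & sig_b]
    down = de_a.index[(de_a["log2fc"] < -lcut) & sig_a & (de_b["log2fc"] < -lcut) & sig_b]
    mean_abs_wald = (de_a["wald_stat"].abs() + de_b["wald_stat"].abs()) / 2.0
    return CandidateSet(
        up_genes=list(up),
        down_genes=list(down),
        thresholds=(fc_cut, padj_cut),
        mean_abs_wald=mean_abs_wald,
    )


def filter_tf(candidates: CandidateSet, annotation: pd.DataFrame) -> CandidateSet:
    """Restrict candidates to transcription factors.

    Ordered by descending mean |Wald| across the two comparisons, ties broken
    lexicographically by gene id.
    """
    pool = list(candidates.up_genes) + list(candidates.down_genes)
    tf = [g for g in pool if bool(annotation.loc[g, "is_tf"])]
    if candidates.mean_abs_wald is not None:
        key = candidates.mean_abs_wald
        tf = sorted(tf, key=lambda g: (-key.loc[g], g))
    else:
        tf = sorted(tf)
    return CandidateSet(
        up_genes=list(candidates.up_genes),
        down_genes=list(candidates.down_genes),
        tf_candidates=tf,
        thresholds=candidates.thresholds,
        mean_abs_wald=candidates.mean_abs_wald,
    )


def nominate(
    cohort: BulkCohort,
    annotation: pd.DataFrame,
    fc_cut: float = NOMINATION_PRESET[0],
    padj_cut: float = NOMINATION_PRESET[1],
) -> tuple[CandidateSet, pd.DataFrame, pd.DataFrame]:
    """Full nomination pipeline on a three-cohort bulk dataset.

    Runs met_primary-vs-never_met and metastasis-vs-never_met Wald tests,
    intersects them at the (fc_cut, padj_cut) gate and keeps transcription
    factors.  Returns (candidates, de_met_primary, de_metastasis).
    """
    if cohort.size_factors is None:
        cohort.size_factors = estimate_size_factors(cohort.counts)
    de_mp = nb_wald_de(cohort, "never_met", "met_primary")
    de_met = nb_wald_de(cohort, "never_met", "metastasis")
    cands = intersect_candidates(de_mp, de_met, fc_cut=fc_cut, padj_cut=padj_cut)
    return filter_tf(cands, annotation), de_mp, de_met


def bulk_correlation(cohort: BulkCohort, query_gene: str) -> pd.DataFrame:
    """Pearson correlation of every gene with the query on log2 normalized counts.

    Computed on log2(count / size_factor + 1) across samples.  Zero-variance
    genes get r = 0 with flag "zero_variance"; the query itself reports r = 1.
    """
    if cohort.counts.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    if query_gene not in cohort.counts.index:
        raise KeyError(f"query gene {query_gene!r} not in counts")
    sf = cohort.size_factors
    if sf is None:
        sf = estimate_size_factors(cohort.counts)
    expr = np.log2(cohort.counts.to_numpy(dtype=float) / sf.to_numpy() + 1.0)
    q = expr[cohort.counts.index.get_loc(query_gene)]
    qc = q - q.mean()
    xc = expr - expr.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((qc**2).sum())
    flags = np.array(["ok"] * expr.shape[0], dtype=object)
    zero = denom == 0
    flags[zero] = "zero_variance"
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(zero, 0.0, (xc @ qc) / np.where(zero, 1.0, denom))
    r[cohort.counts.index.get_loc(query_gene)] = 1.0
    return pd.DataFrame({"r": r, "flag": flags}, index=cohort.counts.index)
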