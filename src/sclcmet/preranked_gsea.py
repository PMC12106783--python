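"""Pre-ranked gene-set enrichment with a permutation null.

Genes are ranked by the signed p-value score -log10(p) * sign(log2fc).  The
enrichment score (ES) is the signed extremum of the weighted
Kolmogorov-Smirnov running sum: set members increment the sum by
|score|^w / sum_hits |score|^w and non-members decrement it by
1 / (N - N_hits).  Significance comes from a gene-set permutation null
(random same-size sets drawn from the ranked universe), the normalized
enrichment score (NES) divides the ES by the mean |null ES| of matching
sign, and add-one permutation p-values are Benjamini-Hochberg adjusted
across all sets tested in one call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bulk_nomination import bh_adjust

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass
class RankedList:
    """Strictly ordered gene ids with signed scores (descending)."""

    genes: np.ndarray
    scores: np.ndarray
    tie_rule: str = "desc |log2fc|, then gene id"

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate genes in ranked list")


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p_perm: float
    padj: float
    set_size: int
    leading_edge: list[str] = field(default_factory=list)
    flag: str = "ok"


def rank_metric(de: pd.DataFrame) -> RankedList:
    """Signed -log10(p) ranking from a DeTable.

    score = -log10(p) * sign(log2fc) with p floored at 1e-300; descending
    order, ties broken by descending |log2fc| then gene id.
    """
    p = np.maximum(de["p"].to_numpy(dtype=float), P_FLOOR)
    score = -np.log10(p) * np.sign(de["log2fc"].to_numpy(dtype=float))
    order = np.lexsort((de.index.to_numpy(), -np.abs(de["log2fc"].to_numpy()), -score))
    return RankedList(genes=de.index.to_numpy()[order], scores=score[order])


def enrichment_score(
    ranked: RankedList,
    members,
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score of a gene set in a ranked list.

    Returns (es, running_sum, leading_edge).  The leading edge is the hit
    genes at or before the extremum (at or after, for a negative ES).
    """
    members = set(members)
    n = len(ranked.genes)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=n)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if n_hits == n:
        raise ValueError("degenerate set: gene set covers the whole universe")

    w = np.abs(ranked.scores) ** weight_exponent
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all hit scores are zero: fall back to equal hit weights
        hit_w = hit.astype(float)
        total = float(n_hits)
    steps = hit_w / total - (~hit).astype(float) / (n - n_hits)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    if es >= 0:
        le = [g for g, h in zip(ranked.genes[: i_max + 1], hit[: i_max + 1]) if h]
    else:
        le = [g for g, h in zip(ranked.genes[i_min:], hit[i_min:]) if h]
    return float(es), running, le


def _null_es(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight_exponent: float,
) -> np.ndarray:
    """ES of random same-size gene sets (gene-set permutation null)."""
    n = len(ranked.genes)
    w = np.abs(ranked.scores) ** weight_exponent
    out = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        hw = np.where(hit, w, 0.0)
        total = hw.sum()
        if total == 0:
            hw = hit.astype(float)
            total = float(set_size)
        steps = hw / total - (~hit).astype(float) / (n - set_size)
        running = np.cumsum(steps)
        hi, lo = running.max(), running.min()
        out[i] = hi if hi >= -lo else lo
    return out


def permutation_test(
    ranked: RankedList,
    members,
    name: str = "",
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """Gene-set permutation test for one set.

    NES = es / mean(|null es| of matching sign); add-one p-value over the
    same-sign null draws.  ``padj`` equals ``p_perm`` here; BH across sets is
    applied by :func:`prerank`.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    members = set(members) & set(ranked.genes)
    es, _, le = enrichment_score(ranked, members, weight_exponent)
    rng = np.random.default_rng(seed)
    null = _null_es(ranked, len(members), n_perm, rng, weight_exponent)
    same = null >= 0 if es >= 0 else null < 0
    n_same = int(same.sum())
    flag = "ok"
    if n_same == 0:
        p = 1.0
        nes = 0.0
        flag = "no_same_sign_null"
    else:
        p = (1.0 + float(np.sum(np.abs(null[same]) >= abs(es)))) / (1.0 + n_same)
        denom = float(np.abs(null[same]).mean())
        nes = es / denom if denom > 0 else 0.0
    return EnrichmentResult(
        name=name, es=es, nes=nes, p_perm=p, padj=p,
        set_size=len(members), leading_edge=le, flag=flag,
    )


def prerank(
    ranked: RankedList,
    gene_sets: dict[str, set],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    padj_significance: float = 0.05,
) -> pd.DataFrame:
    """Run the permutation test for every set and BH-adjust across them.

    Returns a DataFrame (name, set_size, es, nes, p_perm, padj, significant,
    leading_edge) sorted by p.  Sets with adjusted p <= ``padj_significance``
    are marked significant.
    """
    rng = np.random.default_rng(seed)
    results = []
    for name, members in gene_sets.items():
        sub = int(rng.integers(0, 2**31 - 1))
        results.append(
            permutation_test(
                ranked, members, name=name, n_perm=n_perm, seed=sub,
                weight_exponent=weight_exponent,
            )
        )
    df = pd.DataFrame(
        {
            "name": [r.name for r in results],
            "set_size": [r.set_size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_perm": [r.p_perm for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
            "flag": [r.flag for r in results],
        }
    )
    df["padj"] = bh_adjust(df["p_perm"].to_numpy())
    df["significant"] = df["padj"] <= padj_significance
    return df.sort_values("p_perm").reset_index(drop=True)


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT file: name <tab> description <tab> genes...

    Duplicate genes within a set are de-duplicated with a log message.
    """
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, genes = parts[0], parts[2:]
            uniq = set(g for g in genes if g)
            if len(uniq) < len([g for g in genes if g]):
                logger.info("duplicate genes de-duplicated in set %s", name)
            sets[name] = uniq
    return sets


def write_gmt(gene_sets: dict[str, set], path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")
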