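"""Seeded synthetic-data generators with planted ground truth.

Every generator derives an independent random stream from one root seed, so
adding or re-ordering generators never perturbs the others, and a fixed
``(seed, config)`` pair is bit-reproducible.

The simulated world is a three-chromosome genome (120 Mb each) carrying
``n_genes`` genes placed uniformly.  Four generators emulate the study
designs the pipeline consumes:

``simulate_bulk``
    Negative-binomial bulk RNA-seq counts for three cohorts (never-met
    primary, met-associated primary, metastasis) with a small set of planted
    over-expressed driver transcription factors present in the two met
    cohorts only, plus a latent FOXA2 co-expression factor that gives the
    planted module a high bulk Pearson correlation with FOXA2.

``simulate_sc``
    Multi-patient single-cell counts with epithelial / immune / fibroblast /
    endothelial compartments, malignant epithelial clones carrying
    chromosome-segment copy-number shifts, a FOXA2+ malignant subpopulation
    co-expressing a planted gene module, per-cell mitochondrial fractions,
    and a planted fraction of low-quality cells for QC exercises.

``simulate_tma``
    Tissue-microarray records: per-patient staining-intensity percentages
    (summing to 100), H-scores, recurrence with a logistic score-risk link,
    and exponential survival times with censoring.

``simulate_peaks``
    Peak intervals with known intragenic / nearest-TSS gene assignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import anndata as ad

COHORTS = ("never_met", "met_primary", "metastasis")
COMPARTMENTS = ("epithelial", "immune", "fibroblast", "endothelial")

# three synthetic chromosomes, 120 Mb each: 36 bins of 10 Mb for CNV work
CHROM_SIZES: dict[str, int] = {"chr1": 120_000_000, "chr2": 120_000_000, "chr3": 120_000_000}

_MARKERS_PER_COMPARTMENT = 30


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions the downstream recovery oracles are
    calibrated against; see docs/methods.md for the power analysis behind
    the bulk defaults.
    """

    seed: int = 0
    # bulk
    n_genes: int = 2000
    n_tf: int = 200
    n_planted_drivers: int = 8
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: {"never_met": 8, "met_primary": 5, "metastasis": 25}
    )
    nb_dispersion: float = 0.02
    driver_log2fc: float = 2.5
    # single cell
    n_patients_sc: int = 5
    cells_per_patient: int = 1000
    compartment_mix: dict[str, float] = field(
        default_factory=lambda: {
            "epithelial": 0.5,
            "immune": 0.3,
            "fibroblast": 0.1,
            "endothelial": 0.1,
        }
    )
    # SCLC tumors are heavily aneuploid (recurrent arm-level gains and
    # losses genome-wide), so the default clone karyotype alters a large
    # share of the genome, not an isolated segment.
    cnv_segments: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: [
            ("chr1", 0, 30_000_000, 1.0),
            ("chr1", 80_000_000, 120_000_000, -1.0),
            ("chr2", 0, 50_000_000, 0.8),
            ("chr2", 60_000_000, 120_000_000, -0.8),
            ("chr3", 40_000_000, 90_000_000, 1.0),
        ]
    )
    foxa2_module_size: int = 10
    module_effect: float = 1.0
    sc_dispersion: float = 0.5
    foxa2_positive_frac: float = 0.5
    malignant_frac_epithelial: float = 0.8
    low_quality_frac: float = 0.05
    n_mito: int = 20
    # tissue microarray
    tma_n: int = 26
    tma_risk_slope: float = 0.5
    tma_true_cutpoint: float = 25.0
    # peaks
    n_peaks: int = 300

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("n_genes", "n_tf", "n_planted_drivers", "n_patients_sc",
                     "cells_per_patient", "foxa2_module_size", "n_mito", "n_peaks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0 or self.sc_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        mix = sum(self.compartment_mix.values())
        if abs(mix - 1.0) > 1e-9:
            raise ValueError(f"compartment fractions must sum to 1, got {mix}")
        for cohort, n in self.cohort_sizes.items():
            if n == 0:
                raise ValueError(f"empty cohort: {cohort}")
            if n < 0:
                raise ValueError(f"negative cohort size: {cohort}")
        for chrom, start, end, _shift in self.cnv_segments:
            if chrom not in CHROM_SIZES:
                raise ValueError(f"CNV segment on unknown chromosome {chrom}")
            if not (0 <= start < end <= CHROM_SIZES[chrom]):
                raise ValueError(f"CNV segment outside simulated genome: {chrom}:{start}-{end}")
        if self.tma_n < 4:
            raise ValueError("tma_n must be >= 4")


@dataclass
class GroundTruth:
    """Planted structures, kept apart from the data the pipeline stages see."""

    planted_driver_ids: list[str] = field(default_factory=list)
    malignant_cell_ids: list[str] = field(default_factory=list)
    foxa2_module_ids: list[str] = field(default_factory=list)
    true_cutpoint: float = float("nan")
    # auxiliary planted structure (generator-specific)
    foxa2_gene_id: str = ""
    foxa2_positive_cell_ids: list[str] = field(default_factory=list)
    low_quality_cell_ids: list[str] = field(default_factory=list)
    compartment_markers: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class BulkCohort:
    """Gene x sample raw counts with per-sample cohort labels."""

    counts: pd.DataFrame               # genes x samples, non-negative ints
    sample_meta: pd.Series             # sample -> cohort label
    size_factors: pd.Series | None = None


# ---------------------------------------------------------------------------
# shared genome / annotation
# ---------------------------------------------------------------------------

def _sub_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent child stream: stable against adding other generators."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def make_annotation(config: SimConfig) -> pd.DataFrame:
    """Gene annotation table on the synthetic genome.

    Columns: gene_id, symbol, chrom, start, end, strand, is_tf, is_mito
    (0-based half-open coordinates).  Gene placement, TF flags, the FOXA2
    gene, mito flags, planted drivers and the FOXA2 module are all decided
    here so that every generator sees the same gene universe.
    """
    config.validate()
    rng = _sub_rng(config.seed, 0)
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    chroms = rng.choice(list(CHROM_SIZES), size=n)
    lengths = rng.integers(1_000, 20_000, size=n)
    starts = np.array(
        [rng.integers(0, CHROM_SIZES[c] - L) for c, L in zip(chroms, lengths)]
    )
    strands = rng.choice(["+", "-"], size=n)

    is_tf = np.zeros(n, dtype=bool)
    tf_idx = rng.choice(n, size=config.n_tf, replace=False)
    is_tf[tf_idx] = True
    is_mito = np.zeros(n, dtype=bool)
    non_tf = np.flatnonzero(~is_tf)
    is_mito[rng.choice(non_tf, size=config.n_mito, replace=False)] = True

    symbols = gene_ids.copy()
    # FOXA2 is an explicit named TF gene, never a planted driver
    foxa2_idx = rng.choice(np.flatnonzero(is_tf))
    symbols[foxa2_idx] = "FOXA2"

    anno = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols,
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
            "is_tf": is_tf,
            "is_mito": is_mito,
        }
    ).set_index("gene_id", drop=False)
    return anno


def _planted_gene_sets(config: SimConfig, anno: pd.DataFrame) -> tuple[list[str], list[str], str]:
    """(driver ids, FOXA2-module ids, FOXA2 id); deterministic given seed."""
    rng = _sub_rng(config.seed, 1)
    foxa2_id = anno.index[anno["symbol"] == "FOXA2"][0]
    tf_pool = [g for g in anno.index[anno["is_tf"]] if g != foxa2_id]
    drivers = sorted(rng.choice(tf_pool, size=config.n_planted_drivers, replace=False))
    pool = [
        g
        for g in anno.index[~anno["is_tf"] & ~anno["is_mito"]]
        if g not in drivers
    ]
    module = sorted(rng.choice(pool, size=config.foxa2_module_size, replace=False))
    return list(drivers), list(module), foxa2_id


# ---------------------------------------------------------------------------
# bulk cohorts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with variance mean + alpha * mean^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    size = 1.0 / alpha
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_bulk(config: SimConfig) -> tuple[BulkCohort, pd.DataFrame, GroundTruth]:
    """Three-cohort bulk RNA-seq counts with planted driver TFs.

    Planted drivers have their mean multiplied by ``2**driver_log2fc`` in the
    met_primary and metastasis cohorts only.  Baseline per-gene means are
    log-normal; drivers are placed at well-expressed levels (mean in
    [100, 500]) so the planted effect is identifiable at the default cohort
    sizes.  A per-sample latent factor shared by FOXA2 and the planted module
    genes induces a strong bulk co-expression signal for the cross-reference
    stage, without any cohort dependence.
    """
    config.validate()
    anno = make_annotation(config)
    drivers, module, foxa2_id = _planted_gene_sets(config, anno)
    rng = _sub_rng(config.seed, 2)

    samples, labels = [], []
    for cohort in COHORTS:
        n = config.cohort_sizes.get(cohort, 0)
        if n == 0:
            raise ValueError(f"empty cohort: {cohort}")
        for i in range(n):
            samples.append(f"{cohort}_{i:02d}")
            labels.append(cohort)
    n_samples = len(samples)

    base = rng.lognormal(mean=np.log(30.0), sigma=1.2, size=config.n_genes)
    gene_pos = pd.Index(anno.index).get_indexer(drivers)
    base[gene_pos] = rng.uniform(100.0, 500.0, size=len(drivers))
    # the FOXA2 co-expression partners are solidly expressed genes (a
    # correlation is only measurable in bulk where counts rise above noise)
    co_idx = pd.Index(anno.index).get_indexer(module + [foxa2_id])
    base[co_idx] = rng.uniform(50.0, 200.0, size=len(co_idx))
    lib = rng.lognormal(mean=0.0, sigma=0.2, size=n_samples)

    mean = np.outer(base, lib)  # genes x samples
    is_met = np.array([lab != "never_met" for lab in labels])
    mean[np.ix_(gene_pos, np.flatnonzero(is_met))] *= 2.0 ** config.driver_log2fc

    # latent FOXA2 co-expression factor (cohort-independent)
    factor = rng.normal(0.0, 1.0, size=n_samples)
    mean[co_idx, :] *= 2.0 ** (0.8 * factor)

    counts = _nb_draw(rng, mean, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=anno.index, columns=samples)
    meta = pd.Series(labels, index=samples, name="cohort")

    truth = GroundTruth(
        planted_driver_ids=drivers,
        foxa2_module_ids=module,
        foxa2_gene_id=foxa2_id,
    )
    return BulkCohort(counts=counts_df, sample_meta=meta), anno, truth


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------

def simulate_sc(config: SimConfig) -> tuple[ad.AnnData, pd.DataFrame, GroundTruth]:
    """Multi-patient single-cell counts with planted malignant clones.

    Cells draw a compartment from ``compartment_mix``; each compartment has a
    disjoint 30-gene marker program (x20 mean).  A fraction of epithelial
    cells per patient are malignant: their genes inside ``cnv_segments`` have
    means scaled by ``2**shift``.  Half (``foxa2_positive_frac``) of malignant
    cells are FOXA2+ with a positive latent activity that also scales the
    planted module genes by ``2**(module_effect * activity)``.  A small
    planted fraction of low-quality cells (scaled-down depth, high
    mitochondrial load) exercises QC filtering.
    """
    config.validate()
    anno = make_annotation(config)
    drivers, module, foxa2_id = _planted_gene_sets(config, anno)
    rng = _sub_rng(config.seed, 3)

    n_cells = config.n_patients_sc * config.cells_per_patient
    patients = np.repeat(
        [f"P{i:02d}" for i in range(config.n_patients_sc)], config.cells_per_patient
    )
    cell_ids = np.array([f"C{i:06d}" for i in range(n_cells)])

    comps = list(config.compartment_mix)
    probs = np.array([config.compartment_mix[c] for c in comps])
    compartment = rng.choice(comps, size=n_cells, p=probs)

    # disjoint marker programs, avoiding FOXA2 / module / mito genes
    reserved = set(module) | {foxa2_id} | set(anno.index[anno["is_mito"]])
    free = [g for g in anno.index if g not in reserved]
    marker_pick = rng.choice(free, size=_MARKERS_PER_COMPARTMENT * len(COMPARTMENTS), replace=False)
    markers = {
        comp: sorted(marker_pick[i * _MARKERS_PER_COMPARTMENT:(i + 1) * _MARKERS_PER_COMPARTMENT])
        for i, comp in enumerate(COMPARTMENTS)
    }

    base = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=config.n_genes)
    gene_index = pd.Index(anno.index)
    mito_idx = np.flatnonzero(anno["is_mito"].to_numpy())
    base[mito_idx] = 0.0  # mito load is set per cell below
    foxa2_pos_idx = gene_index.get_loc(foxa2_id)
    base[foxa2_pos_idx] = 0.0  # FOXA2 expression is assigned per cell

    # malignant cells: a per-patient epithelial clone
    malignant = np.zeros(n_cells, dtype=bool)
    for p in np.unique(patients):
        epi = np.flatnonzero((patients == p) & (compartment == "epithelial"))
        n_mal = int(round(config.malignant_frac_epithelial * len(epi)))
        malignant[rng.choice(epi, size=n_mal, replace=False)] = True

    # FOXA2 status and latent activity among malignant cells
    mal_idx = np.flatnonzero(malignant)
    n_pos = int(round(config.foxa2_positive_frac * len(mal_idx)))
    pos_cells = rng.choice(mal_idx, size=n_pos, replace=False)
    is_pos = np.zeros(n_cells, dtype=bool)
    is_pos[pos_cells] = True
    activity = np.zeros(n_cells)
    activity[pos_cells] = np.clip(rng.normal(1.0, 0.4, size=n_pos), 0.1, None)

    # per-cell mean matrix assembled multiplicatively in blocks
    lib = rng.lognormal(0.0, 0.12, size=n_cells)
    lowq = rng.random(n_cells) < config.low_quality_frac
    lib[lowq] *= 0.08  # planted low-quality: shallow cells

    mean = np.broadcast_to(base, (n_cells, config.n_genes)).copy()
    for comp in COMPARTMENTS:
        rows = np.flatnonzero(compartment == comp)
        cols = gene_index.get_indexer(markers[comp])
        mean[np.ix_(rows, cols)] *= 20.0

    # CNV segments scale malignant cells' genes inside each segment
    for chrom, start, end, shift in config.cnv_segments:
        in_seg = (
            (anno["chrom"] == chrom)
            & (anno["start"] >= start)
            & (anno["start"] < end)
        ).to_numpy()
        mean[np.ix_(mal_idx, np.flatnonzero(in_seg))] *= 2.0 ** shift

    # FOXA2 and module co-expression among malignant cells.  FOXA2+ cells
    # receive 1 + NB(4 * activity) counts so positivity (count > 0) holds by
    # construction; FOXA2 itself is tightly regulated (low overdispersion).
    foxa2_counts = 1 + _nb_draw(rng, 4.0 * activity[pos_cells] * lib[pos_cells], 0.05)
    if len(mal_idx) > 1:
        act_mal = activity[mal_idx]
        sd = act_mal.std()
        z = (act_mal - act_mal.mean()) / (sd if sd > 0 else 1.0)
        z = np.clip(z, -2.0, 2.0)
        mod_cols = gene_index.get_indexer(module)
        mod_base = np.clip(base[mod_cols], 0.3, 1.0)  # detectable but small
        mean[np.ix_(mal_idx, mod_cols)] = mod_base * 2.0 ** (config.module_effect * np.outer(z, np.ones(len(module))))

        # hold per-cell total output independent of the FOXA2 program: the
        # activity-linked mass of the module + FOXA2 is balanced against a
        # single highly expressed housekeeping-like gene, so library-size
        # normalization does not couple every null gene to FOXA2
        decoy_pool = [g for g in free if g not in module and g not in marker_pick]
        decoy = decoy_pool[0]
        decoy_col = gene_index.get_loc(decoy)
        base[decoy_col] = 150.0
        mean[:, decoy_col] = 150.0
        module_mass_prelib = mean[np.ix_(mal_idx, mod_cols)].sum(axis=1)
    else:
        decoy_col = None

    # mitochondrial load: target fraction m -> mito mean = m/(1-m) * non-mito mean
    m_frac = rng.beta(2.0, 28.0, size=n_cells)
    m_frac[lowq] = rng.uniform(0.6, 0.9, size=int(lowq.sum()))
    non_mito_total = mean.sum(axis=1)
    mean[:, mito_idx] = (
        (m_frac / (1.0 - m_frac) * non_mito_total)[:, None] / len(mito_idx)
    )

    mean *= lib[:, None]
    if decoy_col is not None:
        # balance the module + FOXA2 mass (expected and realized) against
        # the decoy so the library total is independent of FOXA2 activity
        extra = np.zeros(n_cells)
        extra[mal_idx] = module_mass_prelib * lib[mal_idx]
        extra[pos_cells] += foxa2_counts
        dev = np.zeros(n_cells)
        dev[mal_idx] = extra[mal_idx] - extra[mal_idx].mean()
        mean[mal_idx, decoy_col] = np.clip(
            mean[mal_idx, decoy_col] - dev[mal_idx], 5.0, None
        )
    counts = _nb_draw(rng, mean, config.sc_dispersion)
    counts[pos_cells, foxa2_pos_idx] = foxa2_counts

    X = sp.csr_matrix(counts)
    obs = pd.DataFrame(
        {"patient": patients, "compartment_true": compartment},
        index=cell_ids,
    )
    adata = ad.AnnData(X=X, obs=obs, var=anno.copy())
    adata.uns["chrom_sizes"] = dict(CHROM_SIZES)

    truth = GroundTruth(
        planted_driver_ids=drivers,
        malignant_cell_ids=sorted(cell_ids[malignant]),
        foxa2_module_ids=module,
        foxa2_gene_id=foxa2_id,
        foxa2_positive_cell_ids=sorted(cell_ids[is_pos]),
        low_quality_cell_ids=sorted(cell_ids[lowq]),
        compartment_markers={k: list(v) for k, v in markers.items()},
    )
    return adata, anno, truth


# ---------------------------------------------------------------------------
# tissue microarray
# ---------------------------------------------------------------------------

def simulate_tma(config: SimConfig) -> pd.DataFrame:
    """Per-patient IHC intensity percentages, H-scores, recurrence, survival.

    H-scores are drawn from a zero-inflated distribution (a point mass at 0,
    as most never-recurring tumors stain negative, plus a uniform spread).
    Recurrence probability is logistic in the H-score around
    ``tma_true_cutpoint`` with slope ``tma_risk_slope``; survival times are
    exponential with a higher hazard for recurrent patients, censored
    administratively.
    """
    config.validate()
    rng = _sub_rng(config.seed, 4)
    n = config.tma_n

    h = np.where(
        rng.random(n) < 0.3,
        0.0,
        np.round(rng.uniform(2.0, 180.0, size=n)),
    )
    pct = np.zeros((n, 4))
    for i, hi in enumerate(h):
        p3 = hi / 3.0
        # shuffle intensity mass between levels without changing the H-score
        x = rng.uniform(0.0, 0.8) * p3          # level 3 -> level 1 (1:3)
        x = min(x, max(0.0, (100.0 - p3) / 2.0))
        y = rng.uniform(0.0, 0.5) * (p3 - x)    # level 3 -> level 2 (2:3)
        y = min(y, max(0.0, (100.0 - p3 - 2.0 * x) * 2.0))
        pct[i, 3] = p3 - x - y
        pct[i, 1] = 3.0 * x
        pct[i, 2] = 1.5 * y
        pct[i, 0] = 100.0 - pct[i, 1:].sum()
    assert np.allclose(pct.sum(axis=1), 100.0)

    logit = config.tma_risk_slope * (h - config.tma_true_cutpoint)
    p_rec = 1.0 / (1.0 + np.exp(-logit))
    recurrence = rng.random(n) < p_rec

    rate = np.where(recurrence, 4.0 / 60.0, 1.0 / 60.0)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(24.0, 72.0, size=n)
    time = np.minimum(t_event, t_censor)
    event = t_event <= t_censor

    return pd.DataFrame(
        {
            "patient_id": [f"T{i:02d}" for i in range(n)],
            "pct_l0": pct[:, 0],
            "pct_l1": pct[:, 1],
            "pct_l2": pct[:, 2],
            "pct_l3": pct[:, 3],
            "h_score": 1.0 * pct[:, 1] + 2.0 * pct[:, 2] + 3.0 * pct[:, 3],
            "recurrence": recurrence,
            "time_months": time,
            "event": event,
        }
    ).set_index("patient_id")


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def simulate_peaks(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Peak intervals with known gene assignments.

    Returns (peaks, annotation, truth) where ``truth`` carries the
    intragenic / nearest-TSS gene computed by a direct all-pairs scan at
    generation time.  Half the peaks are placed inside random gene bodies,
    half at random intergenic-leaning positions.
    """
    config.validate()
    anno = make_annotation(config)
    rng = _sub_rng(config.seed, 5)
    n = config.n_peaks

    rows = []
    for i in range(n):
        width = int(rng.integers(200, 800))
        if i % 2 == 0:  # aimed at a gene body
            g = anno.iloc[int(rng.integers(len(anno)))]
            lo = int(g["start"])
            hi = max(lo + 1, int(g["end"]) - width)
            start = int(rng.integers(lo, hi)) if hi > lo else lo
            chrom = g["chrom"]
        else:
            chrom = rng.choice(list(CHROM_SIZES))
            start = int(rng.integers(0, CHROM_SIZES[chrom] - width))
        summit = start + int(rng.integers(0, width))
        rows.append(
            {
                "peak_id": f"peak_{i:04d}",
                "chrom": chrom,
                "start": start,
                "end": start + width,
                "summit": summit,
                "log2fc": rng.normal(0.0, 2.0),
                "padj": rng.uniform(0.0, 1.0),
            }
        )
    peaks = pd.DataFrame(rows).set_index("peak_id", drop=False)

    truth_rows = []
    for pid, pk in peaks.iterrows():
        mid = (pk["start"] + pk["end"]) // 2
        on_chrom = anno[anno["chrom"] == pk["chrom"]]
        tss = np.where(on_chrom["strand"] == "+", on_chrom["start"], on_chrom["end"] - 1)
        overlap = on_chrom[(on_chrom["start"] < pk["end"]) & (on_chrom["end"] > pk["start"])]
        if len(overlap):
            otss = np.where(overlap["strand"] == "+", overlap["start"], overlap["end"] - 1)
            order = np.lexsort((overlap["gene_id"].to_numpy(), np.abs(otss - mid)))
            truth_rows.append({"peak_id": pid, "gene_id": overlap["gene_id"].iloc[order[0]],
                               "relation": "intragenic", "distance": 0})
        else:
            order = np.lexsort((on_chrom["gene_id"].to_numpy(), np.abs(tss - mid)))
            j = order[0]
            truth_rows.append({"peak_id": pid, "gene_id": on_chrom["gene_id"].iloc[j],
                               "relation": "nearest_tss",
                               "distance": int(abs(tss[j] - mid))})
    truth = pd.DataFrame(truth_rows).set_index("peak_id")
    return peaks, anno, truth


# ---------------------------------------------------------------------------
# writers (plain-text formats)
# ---------------------------------------------------------------------------

def write_annotation(anno: pd.DataFrame, path: str | Path) -> None:
    anno.to_csv(path, sep="\t", index=False)


def write_bulk(bulk: BulkCohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bulk.counts.to_csv(outdir / "bulk_counts.tsv", sep="\t")
    bulk.sample_meta.rename("cohort").to_csv(outdir / "bulk_meta.tsv", sep="\t")


def write_sc_mtx(adata: ad.AnnData, outdir: str | Path) -> None:
    """MatrixMarket trio (matrix.mtx, barcodes.tsv, genes.tsv), cells x genes."""
    from scipy.io import mmwrite

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(adata.X))
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(outdir / "cell_meta.tsv", sep="\t")


def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    """narrowPeak-dialect BED: chrom start end name score strand summit-offset."""
    out = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"],
            "end": peaks["end"],
            "name": peaks["peak_id"] if "peak_id" in peaks else peaks.index,
            "score": peaks["log2fc"].round(4),
            "strand": ".",
            "summit_offset": peaks["summit"] - peaks["start"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def write_tma(tma: pd.DataFrame, path: str | Path) -> None:
    tma.to_csv(path, sep="\t")
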