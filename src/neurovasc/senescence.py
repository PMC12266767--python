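"""Per-cell senescence enrichment scoring and related single-cell utilities.

The central statistic is a rank-based recovery-curve AUC (the AUCell idea):
within each cell, genes are ranked by expression; walking down the top 5%
of the ranking, the cumulative count of senescence-set genes recovered
traces a step curve whose area — normalized by the maximal achievable
area — is the cell's enrichment score in [0, 1].  Cells are then classified
senescent / non-senescent by a distribution-based threshold.  The same
scorer drives signature-based cell-type annotation (label = argmax
signature score when it exceeds 0.25).

Also here: a negative-binomial count-matrix generator with a planted
senescent subpopulation (the testbed for the scoring machinery), the
mito-fraction / unique-gene QC filter, and the flow-cytometry gating
fraction (e.g. p16-RFP+CD31+ over CD31+).

Count matrices are held as :class:`anndata.AnnData` (cells x genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import anndata as ad
import numpy as np
import pandas as pd
from scipy import signal, stats

from ._errors import DegenerateInputError, ParameterError
from ._utils import stable_cell_seed

__all__ = [
    "GeneSet",
    "GatingResult",
    "generate_expression_matrix",
    "qc_filter_cells",
    "rank_genes",
    "enrichment_score",
    "score_cells",
    "classify_senescent",
    "annotate_cell_types",
    "gating_fraction",
    "load_gene_set",
    "builtin_senescence_set",
]


@dataclass(frozen=True)
class GeneSet:
    """A named list of unique gene symbols."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ParameterError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ParameterError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GatingResult:
    fraction: float
    n_numerator: int
    n_denominator: int


def load_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a gene set from a plain-text file, one symbol per line."""
    with open(path) as fh:
        members = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    return GeneSet(name=name or str(path), members=tuple(dict.fromkeys(members)))


def builtin_senescence_set() -> GeneSet:
    """Bundled convenience senescence set (core CDK inhibitors + SASP genes).

    A small default for exploratory use; any user-supplied list (e.g.
    SenMayo) is accepted by every scoring function in its place.
    """
    text = resources.files("neurovasc.data").joinpath("senescence_core.txt").read_text()
    members = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return GeneSet(name="senescence_core", members=tuple(members))


# ---------------------------------------------------------------------------
# Synthetic count matrices
# ---------------------------------------------------------------------------


def default_gene_universe(n_genes: int, n_mito: int = 30) -> list[str]:
    """Synthetic gene symbols: ``n_mito`` mito genes (mt-*) then g0000..."""
    mito = [f"mt-{i:02d}" for i in range(n_mito)]
    rest = [f"g{i:05d}" for i in range(n_genes - n_mito)]
    return mito + rest


def default_senescence_set(n_genes: int, size: int = 100) -> GeneSet:
    """Deterministic spread-out subset of the synthetic gene universe."""
    universe = default_gene_universe(n_genes)
    non_mito = [g for g in universe if not g.startswith("mt-")]
    step = max(1, len(non_mito) // size)
    members = tuple(non_mito[::step][:size])
    return GeneSet(name="planted_senescence", members=members)


def generate_expression_matrix(
    n_cells: int = 2000,
    n_genes: int = 10000,
    senescent_fraction: float = 0.2,
    gene_set: GeneSet | None = None,
    log2_effect: float = 2.0,
    library_size_mean: float = 5000.0,
    dispersion: float = 0.3,
    mito_fraction_high_cells: float = 0.0,
    seed: int | None = 0,
) -> ad.AnnData:
    """Simulate a gene x cell count matrix with a planted senescent subset.

    Counts follow a gamma-Poisson (negative binomial) model: lognormal
    per-gene baseline abundances, lognormal per-cell library sizes, and a
    gene-level dispersion.  In planted senescent cells the gene-set members
    are shifted up by ``log2_effect`` (log2 fold change).  A
    ``mito_fraction_high_cells`` fraction of cells has its mitochondrial
    genes inflated so the mito read share exceeds the 15% QC bound.

    Returns an AnnData (cells x genes) with ``obs['senescent_truth']``,
    ``obs['high_mito_truth']`` and ``var['mito']``.  Deterministic per seed.
    """
    if not 0 <= senescent_fraction <= 1:
        raise ParameterError("senescent_fraction must lie in [0, 1]")
    if not 0 <= mito_fraction_high_cells <= 1:
        raise ParameterError("mito_fraction_high_cells must lie in [0, 1]")
    if dispersion <= 0:
        raise ParameterError("dispersion must be positive")

    genes = default_gene_universe(n_genes)
    if gene_set is None:
        gene_set = default_senescence_set(n_genes)
    missing = set(gene_set.members) - set(genes)
    if missing:
        raise ParameterError(f"gene set members absent from the gene list: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    mito_idx = np.asarray([g.startswith("mt-") for g in genes])
    # calibrate mito baseline share to ~5% of reads
    base[mito_idx] *= 0.05 * base.sum() / max(base[mito_idx].sum(), 1e-12)
    rel = base / base.sum()

    n_senescent = int(round(senescent_fraction * n_cells))
    senescent = np.zeros(n_cells, dtype=bool)
    senescent[rng.permutation(n_cells)[:n_senescent]] = True
    n_high_mito = int(round(mito_fraction_high_cells * n_cells))
    high_mito = np.zeros(n_cells, dtype=bool)
    high_mito[rng.permutation(n_cells)[:n_high_mito]] = True

    lib = rng.lognormal(mean=np.log(library_size_mean), sigma=0.3, size=n_cells)
    set_idx = np.asarray([g in set(gene_set.members) for g in genes])

    mu = np.outer(lib, rel)
    mu[np.ix_(senescent, set_idx)] *= 2.0**log2_effect
    # boost mito genes so the read share lands around 35%, safely past the
    # 15% QC bound even under counting noise
    mu[np.ix_(high_mito, mito_idx)] *= 10.0

    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(np.int32)

    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {
                "senescent_truth": senescent,
                "high_mito_truth": high_mito,
            },
            index=[f"cell{i:05d}" for i in range(n_cells)],
        ),
        var=pd.DataFrame({"mito": mito_idx}, index=genes),
    )
    adata.uns["planted_gene_set"] = list(gene_set.members)
    adata.uns["log2_effect"] = float(log2_effect)
    return adata


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter_cells(
    adata: ad.AnnData,
    max_mito: float = 0.15,
    gene_count_bounds: tuple[float, float] | str = "percentile",
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove low-quality cells; return the filtered matrix and a log.

    Rules: (1) mitochondrial read fraction strictly greater than
    ``max_mito`` (a cell at exactly the bound is retained); (2) unique-gene
    count outside ``gene_count_bounds`` — either explicit ``(lo, hi)``
    (inclusive) or ``"percentile"`` for the 1st/99th percentiles of the
    per-cell unique-gene distribution.  The log lists one row per violated
    rule per removed cell.
    """
    x = np.asarray(adata.X)
    if "mito" not in adata.var:
        raise ParameterError("var['mito'] flags are required for the mito filter")
    totals = x.sum(axis=1)
    mito_frac = np.divide(
        x[:, adata.var["mito"].to_numpy()].sum(axis=1),
        totals,
        out=np.zeros(adata.n_obs),
        where=totals > 0,
    )
    unique_genes = (x > 0).sum(axis=1)

    if gene_count_bounds == "percentile":
        lo, hi = np.percentile(unique_genes, [1, 99])
    else:
        lo, hi = gene_count_bounds

    records = []
    for i, cell in enumerate(adata.obs_names):
        if mito_frac[i] > max_mito:
            records.append({"cell_id": cell, "reason": "high_mito", "value": float(mito_frac[i])})
        if unique_genes[i] < lo:
            records.append({"cell_id": cell, "reason": "low_gene_count", "value": int(unique_genes[i])})
        elif unique_genes[i] > hi:
            records.append({"cell_id": cell, "reason": "high_gene_count", "value": int(unique_genes[i])})
    log = pd.DataFrame(records, columns=["cell_id", "reason", "value"])
    removed = set(log["cell_id"])
    keep = [c not in removed for c in adata.obs_names]
    if not any(keep):
        raise DegenerateInputError("QC removed every cell")
    return adata[keep].copy(), log


# ---------------------------------------------------------------------------
# Ranking and enrichment scoring
# ---------------------------------------------------------------------------


def rank_genes(adata: ad.AnnData, seed: int = 0) -> np.ndarray:
    """Per-cell gene ranking by descending expression.

    Returns an ``(n_cells, n_genes)`` integer array whose row i lists gene
    indices from the most to the least expressed in cell i.  Ties (notably
    the zero-count bulk) are broken by a random permutation seeded from the
    cell id, so rankings are deterministic yet unbiased across cells.
    """
    x = np.asarray(adata.X)
    n_cells, n_genes = x.shape
    order = np.empty((n_cells, n_genes), dtype=np.int32)
    for i, cell_id in enumerate(adata.obs_names):
        perm = np.random.default_rng(stable_cell_seed(seed, cell_id)).permutation(n_genes)
        # lexsort: last key is primary -> descending count, then permutation
        order[i] = np.lexsort((perm, -x[i]))
    return order


def _window_size(n_genes: int, top_fraction: float) -> int:
    if not 0 < top_fraction <= 1:
        raise ParameterError("top_fraction must lie in (0, 1]")
    return int(np.ceil(top_fraction * n_genes))


def _max_recovery_area(set_size: int, window: int) -> float:
    s = min(set_size, window)
    # all members packed at the very top: ramp then plateau
    return s * (s + 1) / 2.0 + s * (window - s)


def enrichment_score(
    ranking,
    gene_set_members,
    top_fraction: float = 0.05,
    n_genes: int | None = None,
) -> float:
    """Recovery-curve AUC of one cell's ranking against a gene set.

    ``ranking`` is the cell's full gene ordering (symbols or indices, best
    first); ``gene_set_members`` the matching identifiers.  The score is
    the area under the cumulative member-recovery step curve across the top
    ``ceil(top_fraction * n_genes)`` positions, divided by the maximal
    achievable area, giving a value in [0, 1] that depends only on member
    positions inside the window.
    """
    members = set(gene_set_members)
    if not members:
        raise ParameterError("gene set is empty")
    ranking = list(ranking)
    n = n_genes if n_genes is not None else len(ranking)
    window = _window_size(n, top_fraction)
    positions = [p + 1 for p, g in enumerate(ranking[:window]) if g in members]
    area = sum(window - p + 1 for p in positions)
    return area / _max_recovery_area(len(members), window)


def score_cells(
    adata: ad.AnnData,
    gene_set: GeneSet,
    top_fraction: float = 0.05,
    seed: int = 0,
    rankings: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell enrichment scores for one gene set (vectorized).

    Equivalent to :func:`enrichment_score` applied to every row of
    :func:`rank_genes`; precomputed ``rankings`` may be passed so multiple
    signatures reuse one ranking.
    """
    if rankings is None:
        rankings = rank_genes(adata, seed=seed)
    n_genes = rankings.shape[1]
    window = _window_size(n_genes, top_fraction)
    member_idx = set(np.flatnonzero(np.isin(adata.var_names, gene_set.members)))
    if not member_idx:
        raise ParameterError(f"no member of {gene_set.name!r} is in the matrix")
    is_member = np.zeros(n_genes, dtype=bool)
    is_member[list(member_idx)] = True

    top = rankings[:, :window]
    hits = is_member[top]  # (n_cells, window)
    pos = np.arange(1, window + 1)
    areas = ((window - pos + 1) * hits).sum(axis=1)
    return areas / _max_recovery_area(len(member_idx), window)


# ---------------------------------------------------------------------------
# Threshold classification
# ---------------------------------------------------------------------------


def _valley_threshold(scores: np.ndarray) -> float | None:
    """Minimum-density valley between the two main modes, if bimodal.

    KDE over the score range; accept a valley only when the two dominant
    peaks are both prominent and the density between them dips below half
    the smaller peak — otherwise report None so the caller falls back.
    """
    if np.ptp(scores) == 0:
        return None
    kde = stats.gaussian_kde(scores)
    grid = np.linspace(scores.min(), scores.max(), 512)
    density = kde(grid)
    peaks, _ = signal.find_peaks(density, prominence=0.05 * density.max())
    if len(peaks) < 2:
        return None
    main = peaks[np.argsort(density[peaks])[-2:]]
    lo, hi = sorted(main)
    valley = lo + int(np.argmin(density[lo : hi + 1]))
    if density[valley] > 0.5 * min(density[lo], density[hi]):
        return None
    return float(grid[valley])


def classify_senescent(
    scores: np.ndarray,
    strategy: str | float = "auto",
) -> tuple[np.ndarray, float, str]:
    """Threshold per-cell scores into senescent / non-senescent.

    Strategies: ``"auto"`` — minimum-density valley between the two main
    modes when the distribution is bimodal, otherwise mean + 2 SD;
    ``"valley"`` / ``"mean_sd"`` force one of the two; a float is used as
    an explicit threshold.  Cells with score >= threshold are called
    senescent.  Returns ``(calls, threshold, strategy_used)``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 10:
        raise ParameterError("classification needs at least 10 cells")
    if np.ptp(scores) == 0:
        raise DegenerateInputError("score distribution is constant")

    if isinstance(strategy, (int, float)) and not isinstance(strategy, bool):
        threshold, used = float(strategy), "explicit"
    elif strategy == "mean_sd":
        threshold, used = float(scores.mean() + 2 * scores.std()), "mean_sd"
    elif strategy in ("auto", "valley"):
        valley = _valley_threshold(scores)
        if valley is not None:
            threshold, used = valley, "valley"
        elif strategy == "valley":
            raise DegenerateInputError("no bimodal valley found in the score distribution")
        else:
            threshold, used = float(scores.mean() + 2 * scores.std()), "mean_sd"
    else:
        raise ParameterError(f"unknown strategy {strategy!r}")
    return scores >= threshold, threshold, used


# ---------------------------------------------------------------------------
# Signature-based annotation and cytometry gating
# ---------------------------------------------------------------------------


def annotate_cell_types(
    adata: ad.AnnData,
    signatures: dict[str, GeneSet],
    top_n: int = 20,
    auc_cutoff: float = 0.25,
    top_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each cell the best-scoring signature, or ``"unassigned"``.

    Each signature is truncated to its first ``top_n`` entries (signatures
    are assumed pre-sorted by marker strength); all signatures are scored
    with the same recovery-curve scorer and one shared ranking.  A cell is
    labelled with the argmax signature only when that score exceeds
    ``auc_cutoff``; exact ties go to the first signature in name order and
    are flagged.
    """
    if not signatures:
        raise ParameterError("at least one signature is required")
    rankings = rank_genes(adata, seed=seed)
    names = sorted(signatures)
    score_cols = {}
    for name in names:
        sig = signatures[name]
        truncated = GeneSet(name=sig.name, members=sig.members[:top_n])
        score_cols[name] = score_cells(
            adata, truncated, top_fraction=top_fraction, seed=seed, rankings=rankings
        )
    scores = pd.DataFrame(score_cols, index=adata.obs_names)

    best = scores.to_numpy().argmax(axis=1)  # first max wins -> name order
    max_score = scores.to_numpy().max(axis=1)
    tie = (scores.to_numpy() == max_score[:, None]).sum(axis=1) > 1
    labels = np.where(max_score > auc_cutoff, np.asarray(names)[best], "unassigned")
    out = scores.copy()
    out["label"] = labels
    out["max_score"] = max_score
    out["tie"] = tie
    return out


def gating_fraction(
    table: pd.DataFrame,
    numerator_markers: list[str],
    denominator_markers: list[str],
) -> GatingResult:
    """Nested-population gating fraction from a cytometry event table.

    ``table`` holds one row per event with boolean positivity columns.
    The fraction is #(events positive for all numerator markers) /
    #(events positive for all denominator markers); the numerator marker
    set must contain the denominator's (nested gates).
    """
    num = set(numerator_markers)
    den = set(denominator_markers)
    if not num >= den:
        raise ParameterError("numerator population must be nested in the denominator")
    for marker in num | den:
        if marker not in table.columns:
            raise ParameterError(f"marker {marker!r} missing from the event table")
        if table[marker].isna().any():
            raise ParameterError(f"marker {marker!r} has missing positivity values")
    den_mask = table[sorted(den)].all(axis=1) if den else pd.Series(True, index=table.index)
    num_mask = table[sorted(num)].all(axis=1)
    n_den = int(den_mask.sum())
    n_num = int(num_mask.sum())
    if n_den == 0:
        raise DegenerateInputError("denominator population is empty; fraction undefined")
    return GatingResult(fraction=n_num / n_den, n_numerator=n_num, n_denominator=n_den)
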