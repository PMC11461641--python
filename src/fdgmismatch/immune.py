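"""Molecular companion stages.

* bulk immune abundance via a coherence-filtered mean-signature score,
* single-nucleus QC filtering (detected genes, mitochondrial fraction),
* hashtag-oligo demultiplexing with per-tag two-component Gaussian mixtures,
* marker-based cell annotation and region/group counting,
* rank-based differential expression with Benjamini-Hochberg control,
* hypergeometric over-representation analysis.

Cell-level matrices are :class:`anndata.AnnData` (cells x genes); bulk
matrices are pandas gene x sample DataFrames.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as st
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ValidationError
from .signatures import MITO_GENES, SignatureSet

logger = logging.getLogger(__name__)


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


# ---------------------------------------------------------------------------
# nucleus QC


def qc_filter_nuclei(
    adata,
    min_genes: int = 200,
    max_mito: float = 0.20,
    mito_genes: tuple[str, ...] = MITO_GENES,
):
    """Retain nuclei with at least ``min_genes`` expressed genes and a
    mitochondrial fraction of at most ``max_mito`` (strictly more than the
    cutoff is removed; a nucleus at exactly 20% is retained).

    Returns the filtered AnnData (copy) and a QC report dict.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValidationError("empty matrix")
    X = _dense(adata.X)
    detected = (X > 0).sum(axis=1)
    mito_idx = [i for i, g in enumerate(adata.var_names) if g in set(mito_genes)]
    totals = X.sum(axis=1)
    mito_frac = (
        X[:, mito_idx].sum(axis=1) / np.maximum(totals, 1) if mito_idx
        else np.zeros(adata.n_obs)
    )
    low_genes = detected < min_genes
    high_mito = mito_frac > max_mito
    keep = ~low_genes & ~high_mito
    out = adata[keep].copy()
    out.obs["detected_genes"] = detected[keep]
    out.obs["mito_fraction"] = mito_frac[keep]
    report = {
        "n_input": int(adata.n_obs),
        "n_retained": int(keep.sum()),
        "n_removed_low_genes": int(low_genes.sum()),
        "n_removed_high_mito": int(high_mito.sum()),
        "n_removed_both": int((low_genes & high_mito).sum()),
        "min_genes": int(min_genes),
        "max_mito": float(max_mito),
    }
    logger.info(
        "QC: retained %d/%d nuclei (%d low-gene, %d high-mito)",
        report["n_retained"], report["n_input"],
        report["n_removed_low_genes"], report["n_removed_high_mito"],
    )
    return out, report


# ---------------------------------------------------------------------------
# hashtag demultiplexing


@dataclass
class TagFit:
    tag: str
    converged: bool
    background_mean: float
    signal_mean: float
    fallback_threshold: float | None = None


def demux_hashtags(
    tag_counts: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 200,
    posterior_cutoff: float = 0.5,
) -> tuple[pd.DataFrame, list[TagFit]]:
    """Assign each cell to a hashtag, ``negative`` or ``doublet``.

    Per tag, a two-component Gaussian mixture is fitted by EM to log1p
    counts across cells; the higher-mean component is the signal.  A cell is
    positive for a tag when the signal posterior exceeds ``posterior_cutoff``;
    exactly one positive tag gives that assignment, none gives ``negative``,
    two or more give ``doublet``.  A non-converged fit falls back to a
    threshold halfway between the two means of a 2-means split.
    """
    from sklearn.cluster import KMeans
    from sklearn.mixture import GaussianMixture

    if tag_counts.shape[1] < 2:
        raise ValidationError("need at least 2 hashtags")
    if tag_counts.shape[0] < 20:
        raise InsufficientDataError("need at least 20 cells to fit tag mixtures")

    log_counts = np.log1p(tag_counts.to_numpy(dtype=float))
    n_cells, n_tags = log_counts.shape
    positive = np.zeros((n_cells, n_tags), dtype=bool)
    posteriors = np.zeros((n_cells, n_tags))
    fits: list[TagFit] = []
    for j, tag in enumerate(tag_counts.columns):
        x = log_counts[:, j].reshape(-1, 1)
        gm = GaussianMixture(
            n_components=2, max_iter=max_iter, n_init=3, random_state=seed,
            reg_covar=1e-4,
        )
        converged = True
        try:
            gm.fit(x)
            converged = bool(gm.converged_)
        except ValueError:
            converged = False
        if converged:
            means = gm.means_.ravel()
            signal = int(np.argmax(means))
            post = gm.predict_proba(x)[:, signal]
            positive[:, j] = post > posterior_cutoff
            posteriors[:, j] = post
            fits.append(TagFit(tag, True, float(means.min()), float(means.max())))
        else:
            km = KMeans(n_clusters=2, n_init=5, random_state=seed).fit(x)
            centers = np.sort(km.cluster_centers_.ravel())
            thr = float(centers.mean())
            positive[:, j] = x.ravel() > thr
            posteriors[:, j] = (x.ravel() > thr).astype(float)
            fits.append(TagFit(tag, False, float(centers[0]), float(centers[1]), thr))
            logger.warning("tag %s: mixture fit not converged; threshold fallback", tag)

    n_pos = positive.sum(axis=1)
    assignment = np.where(
        n_pos == 0, "negative",
        np.where(n_pos >= 2, "doublet",
                 np.asarray(tag_counts.columns)[positive.argmax(axis=1)]),
    )
    result = pd.DataFrame(
        {"assignment": assignment, "n_positive": n_pos}, index=tag_counts.index
    )
    for j, tag in enumerate(tag_counts.columns):
        result[f"posterior_{tag}"] = posteriors[:, j]
    return result, fits


# ---------------------------------------------------------------------------
# bulk signature scoring


def cpm_log1p(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization followed by log1p."""
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValidationError("sample with zero total counts")
    return np.log1p(counts.div(lib, axis=1) * 1e6)


def signature_score(
    counts: pd.DataFrame,
    sigs: SignatureSet,
    coherence_cutoff: float = 0.3,
    min_genes: int = 3,
) -> dict:
    """Coherence-filtered mean-signature abundance scores on bulk counts.

    Counts are CPM/log1p transformed.  Within each signature, genes whose
    Pearson correlation with the signature's per-sample median profile falls
    below ``coherence_cutoff`` are dropped (genes with undefined correlation
    — zero variance on either side — are retained).  The score is the mean
    transformed expression of the surviving genes; the relative abundance is
    that score standardized across samples within each cell type.

    Returns a dict with ``scores`` and ``zscores`` (cell type x sample
    DataFrames), ``surviving_genes`` and ``not_scorable``.
    """
    expr = cpm_log1p(counts)
    scores, zrows, surviving, not_scorable = {}, {}, {}, []
    for cell_type in sigs.cell_types:
        genes = [g for g in sigs[cell_type] if g in expr.index]
        if len(genes) < min_genes:
            not_scorable.append(cell_type)
            continue
        sub = expr.loc[genes]
        median_profile = sub.median(axis=0)
        kept = []
        mp = median_profile.to_numpy()
        for g in genes:
            gv = sub.loc[g].to_numpy()
            if np.ptp(gv) == 0 or np.ptp(mp) == 0:
                kept.append(g)  # coherence undefined; keep by convention
                continue
            r = np.corrcoef(gv, mp)[0, 1]
            if r >= coherence_cutoff:
                kept.append(g)
        if len(kept) < min_genes:
            not_scorable.append(cell_type)
            continue
        surviving[cell_type] = kept
        score = expr.loc[kept].mean(axis=0)
        scores[cell_type] = score
        sd = score.std(ddof=0)
        zrows[cell_type] = (score - score.mean()) / sd if sd > 0 else score * 0.0
    if not scores:
        raise ValidationError("no scorable signatures")
    return {
        "scores": pd.DataFrame(scores).T,
        "zscores": pd.DataFrame(zrows).T,
        "surviving_genes": surviving,
        "not_scorable": not_scorable,
    }


# ---------------------------------------------------------------------------
# marker-based annotation and counting


def annotate_cells(
    adata, sigs: SignatureSet, margin: float = 0.25
) -> pd.Series:
    """Label each cell with the argmax marker score.

    The per-type score is the mean log1p raw count over the type's markers;
    a cell is assigned only when the best score beats the runner-up by at
    least ``margin`` log-units, otherwise it is ``unassigned``.
    """
    if not sigs.cell_types:
        raise ValidationError("no signatures provided")
    X = np.log1p(_dense(adata.X).astype(float))
    var_index = {g: i for i, g in enumerate(adata.var_names)}
    types, cols = [], []
    for cell_type in sigs.cell_types:
        idx = [var_index[g] for g in sigs[cell_type] if g in var_index]
        if not idx:
            continue
        types.append(cell_type)
        cols.append(X[:, idx].mean(axis=1))
    if not types:
        raise ValidationError("no signature genes present in the matrix")
    S = np.column_stack(cols)
    order = np.argsort(S, axis=1)
    best = order[:, -1]
    best_score = S[np.arange(S.shape[0]), best]
    runner_up = S[np.arange(S.shape[0]), order[:, -2]] if S.shape[1] > 1 else np.full(
        S.shape[0], -np.inf
    )
    labels = np.where(
        best_score - runner_up >= margin,
        np.asarray(types)[best],
        "unassigned",
    )
    return pd.Series(labels, index=adata.obs_names, name="cell_type")


def annotate_and_count(
    adata, sigs: SignatureSet, margin: float = 0.25
) -> tuple[pd.Series, pd.DataFrame]:
    """Annotate cells and tabulate counts and percentages per
    cell type x region x group (percent of the region-group total)."""
    labels = annotate_cells(adata, sigs, margin=margin)
    meta = adata.obs.copy()
    meta["cell_type"] = labels.to_numpy()
    rows = []
    for (region, group), chunk in meta.groupby(["region", "group"], observed=True):
        total = len(chunk)
        vc = chunk["cell_type"].value_counts()
        for cell_type in list(sigs.cell_types) + ["unassigned"]:
            count = int(vc.get(cell_type, 0))
            rows.append(
                {"cell_type": cell_type, "region": region, "group": group,
                 "count": count, "percent": 100.0 * count / total}
            )
    return labels, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differential expression


def normalize_per_cell(X: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Counts-per-``scale`` then log1p (single-cell convention)."""
    totals = X.sum(axis=1, keepdims=True)
    return np.log1p(X / np.maximum(totals, 1) * scale)


def de_test(
    adata,
    contrast: tuple[str, str],
    group_col: str = "group",
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum between two arms on log1p-normalized counts.

    Returns a DataFrame with ``log2fc`` (of arm means, pseudocount 1), raw
    ``p`` and BH-``p_adj`` over all tested genes.  Genes that are all-zero
    in both arms get p = 1 and fold change 0.
    """
    g1, g2 = contrast
    labels = adata.obs[group_col].to_numpy()
    m1, m2 = labels == g1, labels == g2
    if m1.sum() < min_cells or m2.sum() < min_cells:
        raise InsufficientDataError(
            f"contrast {g1} vs {g2}: need >= {min_cells} cells per arm "
            f"(got {int(m1.sum())} and {int(m2.sum())})"
        )
    X = _dense(adata.X).astype(float)
    N1, N2 = normalize_per_cell(X[m1]), normalize_per_cell(X[m2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ties/constant genes handled below
        stat, p = st.mannwhitneyu(N1, N2, axis=0, alternative="two-sided",
                                  method="asymptotic")
    p = np.asarray(p, dtype=float)
    mean1, mean2 = N1.mean(axis=0), N2.mean(axis=0)
    log2fc = np.log2((mean1 + 1.0) / (mean2 + 1.0))
    allzero = (X[m1].sum(axis=0) == 0) & (X[m2].sum(axis=0) == 0)
    constant = np.array(
        [np.ptp(np.concatenate([N1[:, j], N2[:, j]])) == 0 for j in range(X.shape[1])]
    )
    p[allzero | constant | ~np.isfinite(p)] = 1.0
    log2fc[allzero] = 0.0
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {"gene": list(adata.var_names), "log2fc": log2fc, "p": p, "p_adj": p_adj}
    )
    out["significant"] = out["p_adj"] < 0.05
    return out


# ---------------------------------------------------------------------------
# over-representation analysis


def ora_enrich(
    deg_genes: set[str],
    pathways: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each pathway in the DEG set.

    p = P(overlap >= observed) drawing |DEG| genes from the universe;
    BH adjustment across pathways; sorted by adjusted p.
    """
    if not pathways:
        raise ValidationError("no pathways supplied")
    deg = set(deg_genes)
    uni = set(universe)
    if not deg <= uni:
        raise ValidationError("DEG set must be a subset of the universe")
    if not deg:
        warnings.warn("empty DEG set: all enrichment p-values are 1", stacklevel=2)
    N, n_draw = len(uni), len(deg)
    rows = []
    for name, genes in pathways.items():
        in_uni = set(genes) & uni
        k = len(in_uni & deg)
        p = 1.0 if n_draw == 0 else float(st.hypergeom.sf(k - 1, N, len(in_uni), n_draw))
        rows.append({"pathway": name, "pathway_size": len(in_uni), "overlap": k, "p": p})
    out = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["p_adj"] = p_adj
    return out.sort_values("p_adj", kind="stable").reset_index(drop=True)
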