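"""Diameter-indexed transcriptome model.

PCA of oocyte log2 expression (genes filtered at log2(RPM+1) > 4 in at
least one cell), simple regressions of PC1/PC2 on oocyte diameter, and
reconstruction of the expected transcriptome on a diameter grid:

    R[g, bin] = mu_g + sum_k (a_k + b_k * d_bin) * L[g, k]      (K = 2)

Each observed oocyte is assigned the grid diameter whose reconstructed
profile maximizes Spearman's rs; oocytes whose observed diameter exceeds
the best match by more than the deviation cut are flagged growth-retarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class PcaModel:
    gene_ids: list[str]  # genes passing the expression filter
    mean_log2: np.ndarray  # (n_genes,)
    loadings: np.ndarray  # (n_genes, n_components), orthonormal columns
    scores: np.ndarray  # (n_cells, n_components)
    explained_variance_ratio: np.ndarray
    cell_ids: list[str] = field(default_factory=list)


@dataclass
class SizeModel:
    pca: PcaModel  # restricted to K = 2 components
    coef: np.ndarray  # (2, 2): rows = PC, columns = (intercept a_k, slope b_k)
    grid_um: np.ndarray
    reconstruction: np.ndarray  # (n_genes, n_bins)

    @property
    def gene_ids(self) -> list[str]:
        return self.pca.gene_ids


@dataclass
class MatchResult:
    table: pd.DataFrame  # per-oocyte best-match summary
    rs_matrix: np.ndarray  # (n_cells, n_bins) Spearman rs
    grid_um: np.ndarray
    deviation_cut_um: float


@dataclass
class SigmoidFit:
    lower: float
    upper: float
    steepness: float
    inflection_um: float
    rss: float
    converged: bool

    def predict(self, d: np.ndarray | float) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return self.lower + (self.upper - self.lower) / (
            1.0 + np.exp(-self.steepness * (d - self.inflection_um))
        )


@dataclass
class GeneDiameterCorr:
    r: pd.Series  # per-gene Pearson r (zero-variance genes dropped)
    positive: list[str]
    negative: list[str]


def fit_pca(
    log2_expr: np.ndarray,
    gene_ids: list[str],
    cell_ids: list[str] | None = None,
    min_log2: float = 4.0,
    n_components: int | None = None,
) -> PcaModel:
    """Centered, unscaled PCA over genes exceeding ``min_log2`` in >= 1 cell.

    Deterministic sign convention: each loading column is oriented so that
    its largest-magnitude entry is positive.
    """
    X = np.asarray(log2_expr, dtype=float)  # (genes, cells)
    if X.shape[1] < 3:
        raise ValueError("need >= 3 cells for PCA")
    keep = (X > min_log2).any(axis=1)
    if keep.sum() < 2:
        raise ValueError("expression filter leaves < 2 genes")
    X = X[keep]
    kept_ids = [g for g, k in zip(gene_ids, keep) if k]
    mu = X.mean(axis=1)
    centered = (X - mu[:, None]).T  # cells x genes
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(centered.shape) if n_components is None else min(n_components, len(s))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    loadings = vt.T  # genes x k
    scores = u * s  # cells x k
    # sign convention
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    total_var = float((s**2).sum())
    evr = s**2 / total_var if total_var > 0 else np.zeros_like(s)
    return PcaModel(
        gene_ids=kept_ids,
        mean_log2=mu,
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=evr,
        cell_ids=list(cell_ids) if cell_ids is not None else [],
    )


def pc_diameter_association(
    scores: np.ndarray, diameters: np.ndarray
) -> np.ndarray:
    """Spearman rs (average ranks for ties) of each PC score against diameter."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1 and scores.shape[1] > 1 and len(diameters) != 1:
        scores = scores.T
    d = np.asarray(diameters, dtype=float)
    if len(d) != scores.shape[0]:
        raise ValueError("diameters must match cells")
    if len(d) < 3:
        raise ValueError("need >= 3 cells")
    return np.array(
        [stats.spearmanr(scores[:, j], d).statistic for j in range(scores.shape[1])]
    )


def gene_diameter_correlations(
    log2_expr: np.ndarray,
    gene_ids: list[str],
    diameters: np.ndarray,
    pos_cut: float = 0.85,
    neg_cut: float = -0.80,
) -> GeneDiameterCorr:
    """Per-gene Pearson r of log2 level against diameter; strict cuts define
    the positively / negatively correlated sets.  Zero-variance genes are
    excluded (r undefined)."""
    X = np.asarray(log2_expr, dtype=float)
    d = np.asarray(diameters, dtype=float)
    if X.shape[1] != len(d):
        raise ValueError("diameters must match cells")
    if len(d) < 3:
        raise ValueError("need >= 3 cells")
    sd = X.std(axis=1)
    if (sd == 0).all():
        raise ValueError("all genes constant; no correlations defined")
    ok = sd > 0
    Xc = X[ok] - X[ok].mean(axis=1, keepdims=True)
    dc = d - d.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (dc**2).sum())
    r_vals = (Xc @ dc) / denom
    ids = [g for g, o in zip(gene_ids, ok) if o]
    r = pd.Series(r_vals, index=ids, name="r")
    positive = [g for g, v in r.items() if v > pos_cut]
    negative = [g for g, v in r.items() if v < neg_cut]
    return GeneDiameterCorr(r=r, positive=positive, negative=negative)


def average_zscore_profile(
    log2_expr: np.ndarray, gene_ids: list[str], gene_set: list[str]
) -> np.ndarray:
    """Mean per-gene Z score over a gene set, per cell."""
    wanted = set(gene_set)
    if not wanted:
        raise ValueError("empty gene set")
    idx = [i for i, g in enumerate(gene_ids) if g in wanted]
    X = np.asarray(log2_expr, dtype=float)[idx]
    sd = X.std(axis=1)
    X = X[sd > 0]
    if X.shape[0] == 0:
        raise ValueError("gene set empty after zero-variance removal")
    z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    return z.mean(axis=0)


def _logistic(d: np.ndarray, a: float, b: float, k: float, d0: float) -> np.ndarray:
    return a + (b - a) / (1.0 + np.exp(-np.clip(k * (d - d0), -500, 500)))


def fit_sigmoid(d: np.ndarray, y: np.ndarray) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit with multi-start initialization.

    The inflection d0 is bounded to [min(d) - 10, max(d) + 10].  If no start
    converges the best residual solution is returned with converged=False.
    """
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(d) < 5:
        raise ValueError("need >= 5 points")
    if np.ptp(d) <= 0:
        raise ValueError("diameters span no range")
    if np.ptp(y) == 0:
        c = float(y[0])
        return SigmoidFit(
            lower=c, upper=c, steepness=0.0,
            inflection_um=float(np.median(d)),
            rss=0.0, converged=True,
        )
    d0_lo, d0_hi = d.min() - 10.0, d.max() + 10.0
    rising = np.corrcoef(d, y)[0, 1] >= 0
    k_signs = [1.0, -1.0] if rising else [-1.0, 1.0]
    best: tuple[float, np.ndarray] | None = None
    converged = False
    for k0 in (0.05, 0.2, 0.5):
        for ks in k_signs:
            for d0_start in (np.quantile(d, 0.25), np.median(d), np.quantile(d, 0.75)):
                p0 = [float(y.min()), float(y.max()), ks * k0, float(d0_start)]
                try:
                    popt, _ = optimize.curve_fit(
                        _logistic, d, y, p0=p0,
                        bounds=(
                            [-np.inf, -np.inf, -np.inf, d0_lo],
                            [np.inf, np.inf, np.inf, d0_hi],
                        ),
                        maxfev=5000,
                    )
                except (RuntimeError, ValueError):
                    continue
                rss = float(np.sum((y - _logistic(d, *popt)) ** 2))
                if best is None or rss < best[0]:
                    best = (rss, popt)
                converged = True
    if best is None:
        # flat fallback
        c = float(y.mean())
        return SigmoidFit(
            lower=c, upper=c, steepness=0.0,
            inflection_um=float(np.median(d)),
            rss=float(np.sum((y - c) ** 2)), converged=False,
        )
    rss, popt = best
    a, b, k, d0 = (float(v) for v in popt)
    if k < 0:  # normalize so steepness is positive (swap asymptotes)
        a, b, k = b, a, -k
    return SigmoidFit(
        lower=a, upper=b, steepness=k, inflection_um=d0, rss=rss,
        converged=converged,
    )


def fit_size_model(
    pca: PcaModel,
    diameters: np.ndarray,
    grid_um: np.ndarray | list[float] | None = None,
) -> SizeModel:
    """Regress PC1/PC2 on diameter and reconstruct the transcriptome per bin."""
    d = np.asarray(diameters, dtype=float)
    if len(d) != pca.scores.shape[0]:
        raise ValueError("diameters must match PCA cells")
    if len(d) < 3:
        raise ValueError("need >= 3 cells with diameters")
    if np.ptp(d) == 0:
        raise ValueError("zero diameter variance")
    if pca.scores.shape[1] < 2:
        raise ValueError("size model needs 2 principal components")
    grid = (
        np.arange(10.0, 101.0, 10.0)
        if grid_um is None
        else np.asarray(list(grid_um), dtype=float)
    )
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    coef = np.zeros((2, 2))
    for k in range(2):
        b, a = np.polyfit(d, pca.scores[:, k], 1)
        coef[k] = (a, b)
    pc_grid = coef[:, 0][:, None] + coef[:, 1][:, None] * grid[None, :]  # (2, bins)
    L2 = pca.loadings[:, :2]
    recon = pca.mean_log2[:, None] + L2 @ pc_grid
    pca2 = PcaModel(
        gene_ids=pca.gene_ids,
        mean_log2=pca.mean_log2,
        loadings=L2,
        scores=pca.scores[:, :2],
        explained_variance_ratio=pca.explained_variance_ratio[:2],
        cell_ids=pca.cell_ids,
    )
    return SizeModel(pca=pca2, coef=coef, grid_um=grid, reconstruction=recon)


def match_oocytes(
    log2_expr: np.ndarray,
    gene_ids: list[str],
    cell_ids: list[str],
    observed_diameters: np.ndarray,
    model: SizeModel,
    deviation_cut_um: float = 20.0,
) -> MatchResult:
    """Best-match each oocyte to a grid bin by Spearman rs against the
    reconstruction; flag deviations beyond the cut (retarded when the match
    is smaller than the observed diameter).  Ties go to the smaller bin."""
    if list(gene_ids) != list(model.gene_ids):
        raise ValueError("expression gene list does not match the model")
    X = np.asarray(log2_expr, dtype=float)
    obs = np.asarray(observed_diameters, dtype=float)
    n_cells = X.shape[1]
    n_bins = len(model.grid_um)
    rs = np.zeros((n_cells, n_bins))
    # rank once per cell / per bin, then Pearson on ranks (= Spearman)
    cell_ranks = np.apply_along_axis(stats.rankdata, 0, X)
    bin_ranks = np.apply_along_axis(stats.rankdata, 0, model.reconstruction)
    cr = cell_ranks - cell_ranks.mean(axis=0, keepdims=True)
    br = bin_ranks - bin_ranks.mean(axis=0, keepdims=True)
    cr_norm = np.sqrt((cr**2).sum(axis=0))
    br_norm = np.sqrt((br**2).sum(axis=0))
    rs = (cr.T @ br) / np.outer(cr_norm, br_norm)
    best_idx = np.argmax(rs, axis=1)  # argmax takes the first (smaller bin) on ties
    tie = np.array(
        [np.sum(np.isclose(rs[i], rs[i, best_idx[i]], atol=1e-12)) > 1
         for i in range(n_cells)]
    )
    best = model.grid_um[best_idx]
    delta = obs - best
    deviant = np.abs(delta) > deviation_cut_um
    retarded = delta > deviation_cut_um
    table = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "observed_um": obs,
            "best_match_um": best,
            "best_rs": rs[np.arange(n_cells), best_idx],
            "delta_um": delta,
            "deviant": deviant,
            "retarded": retarded,
            "tied": tie,
        }
    ).set_index("cell_id")
    return MatchResult(
        table=table, rs_matrix=rs, grid_um=model.grid_um,
        deviation_cut_um=deviation_cut_um,
    )


def build_size_model(
    log2_expr: np.ndarray,
    gene_ids: list[str],
    cell_ids: list[str],
    diameters: np.ndarray,
    grid_um: np.ndarray | list[float] | None = None,
    min_log2: float = 4.0,
    deviation_cut_um: float = 20.0,
    refine_passes: int = 1,
) -> tuple[SizeModel, MatchResult]:
    """Filter, fit PCA, regress PCs on diameter, reconstruct and best-match.

    With ``refine_passes`` >= 1 the PC-diameter regressions are refit after
    excluding cells flagged deviant in the previous pass (their expression
    contradicts their recorded diameter, so they corrupt the linear fit);
    all cells are re-matched against the refined reconstruction.  Set
    ``refine_passes=0`` for the plain single-pass procedure.
    """
    d = np.asarray(diameters, dtype=float)
    pca = fit_pca(log2_expr, gene_ids, cell_ids, min_log2=min_log2)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    sub = np.asarray(log2_expr, dtype=float)[
        [gene_index[g] for g in pca.gene_ids], :
    ]
    model = fit_size_model(pca, d, grid_um)
    match = match_oocytes(
        sub, model.gene_ids, cell_ids, d, model, deviation_cut_um
    )
    for _ in range(refine_passes):
        keep = ~match.table["deviant"].to_numpy()
        if keep.all() or keep.sum() < 3 or np.ptp(d[keep]) == 0:
            break
        pca_kept = PcaModel(
            gene_ids=pca.gene_ids,
            mean_log2=pca.mean_log2,
            loadings=pca.loadings,
            scores=pca.scores[keep],
            explained_variance_ratio=pca.explained_variance_ratio,
            cell_ids=[c for c, k in zip(cell_ids, keep) if k],
        )
        model = fit_size_model(pca_kept, d[keep], grid_um)
        new_match = match_oocytes(
            sub, model.gene_ids, cell_ids, d, model, deviation_cut_um
        )
        if new_match.table["deviant"].equals(match.table["deviant"]):
            match = new_match
            break
        match = new_match
    return model, match


def top_loading_genes(
    pca: PcaModel, n: int = 500, component: int = 1
) -> tuple[list[str], list[str]]:
    """Top n genes with the largest positive and negative loadings on a PC
    (component is 0-based; default PC2)."""
    load = pca.loadings[:, component]
    pos_order = np.argsort(-load)
    neg_order = np.argsort(load)
    n_pos = int((load > 0).sum())
    n_neg = int((load < 0).sum())
    if n > n_pos or n > n_neg:
        raise ValueError(
            f"requested {n} genes per sign but only {n_pos} positive / {n_neg} negative"
        )
    pos = [pca.gene_ids[i] for i in pos_order[:n]]
    neg = [pca.gene_ids[i] for i in neg_order[:n]]
    return pos, neg
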