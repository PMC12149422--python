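"""Weighted gene-coexpression module analysis linking expression to the radscore.

The standard WGCNA recipe at desk scale: soft-threshold power chosen by the
scale-free topology fit, unsigned adjacency |cor|^beta, topological overlap
(TOM) similarity, average-linkage hierarchical clustering on 1 - TOM with a
height-scan tree cut enforcing a minimum module size of 100 genes, module
eigengenes (first principal component, sign-oriented), module-trait Pearson
correlations, hub-gene ranking by connectivity (or by degree in a supplied
interaction edge list), and one-sided hypergeometric over-representation
with Benjamini-Hochberg correction over a user-supplied annotation table.

Modules are labeled with the conventional color names in descending size
order; genes not assigned to any sufficiently large module are "grey".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModuleAssignment",
    "pick_soft_threshold",
    "adjacency_matrix",
    "tom_matrix",
    "detect_modules",
    "module_eigengene",
    "module_trait",
    "hub_genes",
    "hypergeom_enrichment",
]

_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan",
]


@dataclass
class ModuleAssignment:
    """Gene-to-module labels plus the network-construction trace."""

    modules: pd.Series  # gene -> color label ("grey" = unassigned)
    soft_power: int | None = None
    scale_free_r2: dict[int, float] = field(default_factory=dict)
    eigengenes: pd.DataFrame | None = None  # samples x modules
    module_trait: pd.DataFrame | None = None
    hub_genes: list[str] = field(default_factory=list)

    def module_genes(self, module: str) -> list[str]:
        return self.modules.index[self.modules == module].tolist()


def _check_expr(expr: pd.DataFrame) -> None:
    var = expr.var(axis=1)
    if (var == 0).any():
        bad = var.index[var == 0][:3].tolist()
        raise ValueError(f"zero-variance gene(s), e.g. {bad}; filter before analysis")


def adjacency_matrix(expr: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded adjacency: |cor|^beta (unsigned, default) or
    ((1 + cor)/2)^beta (signed). Diagonal is zero."""
    _check_expr(expr)
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    a = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 P(k) vs log10 k over equal-width connectivity bins."""
    k = k[k > 0]
    if k.size < n_bins or k.max() == k.min():
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r**2) if np.isfinite(r) else 0.0


def pick_soft_threshold(
    expr: pd.DataFrame,
    betas=range(1, 21),
    r2_target: float = 0.8,
    signed: bool = False,
) -> tuple[int, dict[int, float]]:
    """Smallest power with scale-free fit R^2 >= target, else the best R^2.

    Connectivity k_i = sum_j a_ij under each candidate power; the fit
    regresses log10 frequency on log10 mean connectivity over ~10 bins.
    """
    if expr.shape[1] < 30:
        warnings.warn(
            f"only {expr.shape[1]} samples; soft-threshold fit may be unstable"
        )
    _check_expr(expr)
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    base = ((1.0 + cor) / 2.0) if signed else np.abs(cor)
    np.fill_diagonal(base, 0.0)
    r2s: dict[int, float] = {}
    for beta in betas:
        k = (base**beta).sum(axis=1)
        r2s[int(beta)] = _scale_free_r2(k)
    for beta in sorted(r2s):
        if r2s[beta] >= r2_target:
            return beta, r2s
    best = max(sorted(r2s), key=lambda b: r2s[b])
    return best, r2s


def tom_matrix(adjacency: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Topological overlap similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off the
    diagonal, TOM_ii = 1. Requires a symmetric adjacency with zero diagonal
    and entries in [0, 1].
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diag(a)).max() > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a  # diagonal of a is 0, so u != i, j contribute only
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    dissimilarity: np.ndarray,
    gene_ids,
    min_module_size: int = 100,
    expr: pd.DataFrame | None = None,
    kme_threshold: float = 0.5,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a height-scan tree cut.

    The cut height is scanned over the midpoints of the dendrogram merge
    heights and the lowest height maximizing the number of clusters meeting
    ``min_module_size`` is chosen, so modules are tight cores. When the
    expression matrix is supplied, unassigned genes are then rescued by
    module membership: a grey gene joins the module whose eigengene it
    correlates with most strongly, provided |kME| >= ``kme_threshold``
    (the conventional 0.5). Remaining unassigned genes stay "grey";
    modules get conventional color names in descending size order.
    """
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    if n < 2 * min_module_size:
        raise ValueError(
            f"need >= {2 * min_module_size} genes for min_module_size={min_module_size}"
        )
    d = np.asarray(dissimilarity, dtype=float)
    Z = linkage(squareform(d, checks=False), method="average")
    heights = np.unique(Z[:, 2])
    cands = np.concatenate(
        [(heights[:-1] + heights[1:]) / 2.0, [heights[-1] + 1e-9]]
    )
    best_labels, best_count = None, -1
    for h in cands:  # ascending: lowest height with the max count wins
        lab = fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(lab)
        count = int((sizes[1:] >= min_module_size).sum())
        if count > best_count:
            best_labels, best_count = lab, count
    if best_count == 0:
        warnings.warn("no cluster reaches min_module_size; returning one module")
        return pd.Series(_COLORS[0], index=gene_ids, name="module")
    lab = best_labels
    sizes = np.bincount(lab)
    big = [c for c in np.argsort(sizes)[::-1] if c > 0 and sizes[c] >= min_module_size]
    cluster_of = pd.Series(lab, index=gene_ids)
    assignment = pd.Series(
        [c if c in big else 0 for c in lab], index=gene_ids
    )  # 0 = grey

    if expr is not None and (assignment == 0).any():
        X = expr.loc[gene_ids].to_numpy(dtype=float)
        grey_idx = np.flatnonzero(assignment.to_numpy() == 0)
        kme = np.empty((len(grey_idx), len(big)))
        for j, c in enumerate(big):
            me = module_eigengene(expr.loc[assignment.index[assignment == c]])
            v = me.to_numpy()
            for row, gi in enumerate(grey_idx):
                kme[row, j] = np.corrcoef(X[gi], v)[0, 1]
        best_mod = np.argmax(np.abs(kme), axis=1)
        ok = np.abs(kme[np.arange(len(grey_idx)), best_mod]) >= kme_threshold
        for gi, j, keep in zip(grey_idx, best_mod, ok):
            if keep:
                assignment.iloc[gi] = big[j]

    final_sizes = assignment.value_counts()
    ordered = [c for c in final_sizes.index if c != 0]
    ordered.sort(key=lambda c: (-final_sizes[c], big.index(c)))
    color_of = {c: (_COLORS[i] if i < len(_COLORS) else f"module{i + 1}")
                for i, c in enumerate(ordered)}
    labels = [color_of.get(c, "grey") for c in assignment]
    return pd.Series(labels, index=gene_ids, name="module")


def module_eigengene(expr_module: pd.DataFrame) -> pd.Series:
    """First principal component of the module's standardized expression.

    Unit-norm over samples; the sign is oriented so that the mean
    correlation with member genes is positive.
    """
    X = expr_module.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    if (Z @ v).mean() < 0:
        v = -v
    return pd.Series(v, index=expr_module.columns, name="eigengene")


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


def module_trait(
    modules: pd.Series,
    expr: pd.DataFrame,
    traits: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Eigengene-trait Pearson correlations and the most significant module.

    ``traits`` is samples x trait columns (radscore and/or candidate
    features), aligned to the expression sample IDs. Returns (eigengenes,
    long-format module-trait table, selected module); selection minimizes
    p over all module-trait pairs, ties going to the larger |r|.
    """
    if not expr.columns.equals(traits.index):
        if set(expr.columns) != set(traits.index):
            raise ValueError("expression samples and trait samples are misaligned")
        traits = traits.loc[expr.columns]
    names = [m for m in modules.unique() if m != "grey"]
    eig = pd.DataFrame(
        {m: module_eigengene(expr.loc[modules[modules == m].index]) for m in names}
    )
    rows = []
    for m in names:
        for trait in traits.columns:
            r, p = _pearson_with_p(
                eig[m].to_numpy(), traits[trait].to_numpy(dtype=float)
            )
            rows.append({"module": m, "trait": trait, "r": r, "p": p})
    mt = pd.DataFrame(rows)
    best = mt.sort_values(["p", "r"], key=lambda s: s if s.name == "p" else -s.abs())
    selected = str(best.iloc[0]["module"])
    return eig, mt, selected


def hub_genes(
    module_gene_ids,
    adjacency: pd.DataFrame | None = None,
    edge_list: pd.DataFrame | None = None,
    n_top: int = 2,
) -> list[str]:
    """Top connected genes of a module.

    With an interaction edge list (columns gene_a, gene_b), connectivity is
    the degree in the module-induced subgraph; otherwise the intramodular
    soft connectivity sum_j a_ij. Ties break lexicographically.
    """
    genes = list(module_gene_ids)
    if not genes:
        raise ValueError("empty module")
    conn: pd.Series | None = None
    if edge_list is not None:
        gs = set(genes)
        sub = edge_list[
            edge_list["gene_a"].isin(gs) & edge_list["gene_b"].isin(gs)
        ]
        if sub.empty:
            warnings.warn("edge list touches no module genes; falling back to adjacency")
        else:
            deg = pd.concat([sub["gene_a"], sub["gene_b"]]).value_counts()
            conn = deg.reindex(genes).fillna(0.0)
    if conn is None:
        if adjacency is None:
            raise ValueError("provide an adjacency matrix or an edge list")
        sub = adjacency.loc[genes, genes]
        conn = sub.sum(axis=1)
    ranked = sorted(genes, key=lambda g: (-conn[g], g))
    return ranked[:n_top]


def hypergeom_enrichment(
    module_genes,
    annotation: pd.DataFrame,
    universe,
    top_n: int = 5,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-sided hypergeometric over-representation with BH correction.

    ``annotation`` has columns term_id, term_name, gene. Returns the full
    per-term table sorted by ascending p, and the top-``top_n`` rows with
    p < ``alpha`` (the displayed report).
    """
    if annotation.empty:
        raise ValueError("empty annotation table")
    universe = set(universe)
    module = set(module_genes) & universe
    if set(module_genes) - universe:
        raise ValueError("module genes must be a subset of the universe")
    M, n = len(universe), len(module)
    rows = []
    for (term_id, term_name), grp in annotation.groupby(["term_id", "term_name"]):
        term_genes = set(grp["gene"]) & universe
        K = len(term_genes)
        k = len(term_genes & module)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "overlap": k,
                "term_size": K,
                "expected": K * n / M,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    table = table.sort_values(["p", "term_id"]).reset_index(drop=True)
    report = table[table["p"] < alpha].head(top_n)
    return table, report
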