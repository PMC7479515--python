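"""NMF program discovery and metaprogram construction.

Per sample, malignant cells are factorized with non-negative matrix
factorization on relative expression (negatives zeroed) restricted to the most
over-dispersed genes; each factor is represented by its 30 highest-weight
genes.  Programs from all samples of a compartment are scored on all of that
compartment's cells, clustered by the correlation of their score vectors
(Ward linkage on 1 - Pearson), and clusters whose members correlate on average
above 0.5 are merged into metaprograms by averaging NMF weights and taking the
top 30 genes.  A deliberately generous factor count per sample is harmless
because redundant factors collapse during merging.

The NMF solver is a multiplicative-update minimizer of the Frobenius loss with
deterministic NNDSVDa initialization, so the per-iteration reconstruction
error is available (it is non-increasing, a property the tests check) and
repeated runs are bit-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .matrix import ExpressionMatrix, require_scale

logger = logging.getLogger(__name__)

TOP_N = 30


def _ea_from_log(log_values: pd.DataFrame) -> pd.Series:
    """Recover aggregate expression Ea from E = log2(TPM/10 + 1) values."""
    tpm = (np.power(2.0, log_values) - 1.0) * 10.0
    return np.log2(tpm.mean(axis=0) + 1.0)


def overdispersed_genes(
    m: ExpressionMatrix, n: int = 10_000, n_bins: int = 20, ea: pd.Series | None = None
) -> list[str]:
    """Top ``n`` over-dispersed genes by within-bin variance z-score.

    Genes are binned into ``n_bins`` equal-frequency bins of aggregate
    expression Ea; within each bin the variance of E is z-scored, so highly
    variable genes are found at every expression level rather than only among
    the highly expressed.  Zero-variance genes are never selected while
    variable alternatives remain.
    """
    require_scale(m, "log")
    if n < 1:
        raise ValueError("n must be >= 1")
    vals = m.values
    if ea is None:
        ea = _ea_from_log(vals)
    var = vals.var(axis=0, ddof=1) if m.n_cells > 1 else vals.var(axis=0, ddof=0)

    n_bins = min(n_bins, max(1, m.n_genes))
    bins = pd.qcut(ea.rank(method="first"), n_bins, labels=False, duplicates="drop")
    z = pd.Series(0.0, index=vals.columns)
    for _, idx in pd.Series(vals.columns).groupby(bins.to_numpy()).groups.items():
        genes = vals.columns[idx]
        v = var[genes]
        sd = v.std(ddof=0)
        z[genes] = (v - v.mean()) / sd if sd > 0 else 0.0
    z[var == 0] = -np.inf

    ranked = pd.DataFrame({"z": z}).sort_values(["z"], ascending=False, kind="stable")
    ranked = ranked.loc[ranked.index.sort_values()].sort_values("z", ascending=False, kind="stable")
    return list(ranked.index[: min(n, len(ranked))])


@dataclass
class NMFProgram:
    """One NMF factor of one sample: non-negative gene weights."""

    sample_id: str
    factor_index: int
    weights: pd.Series

    @property
    def program_id(self) -> str:
        return f"{self.sample_id}.f{self.factor_index}"

    @property
    def top_genes(self) -> list[str]:
        return top_genes(self.weights, TOP_N)


@dataclass
class Metaprogram:
    """Merged set of correlated per-sample programs."""

    name: str
    member_ids: list[str]
    top_genes: list[str]
    mean_weights: pd.Series
    compartment: str | None = None


def top_genes(weights: pd.Series, n: int = TOP_N) -> list[str]:
    """The ``n`` highest-weight genes, ties broken lexicographically."""
    order = weights.to_frame("w").reset_index()
    order.columns = ["gene_id", "w"]
    order = order.sort_values(["w", "gene_id"], ascending=[False, True], kind="stable")
    return order["gene_id"].head(n).tolist()


def _nndsvda(a: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic NNDSVD init with zeros filled by the matrix mean."""
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    w = np.zeros((a.shape[0], k))
    h = np.zeros((k, a.shape[1]))
    w[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    h[0] = np.sqrt(s[0]) * np.abs(vt[0])
    for j in range(1, k):
        x, y = u[:, j], vt[j]
        xp, xn = np.clip(x, 0, None), np.clip(-x, 0, None)
        yp, yn = np.clip(y, 0, None), np.clip(-y, 0, None)
        norm_p = np.linalg.norm(xp) * np.linalg.norm(yp)
        norm_n = np.linalg.norm(xn) * np.linalg.norm(yn)
        if norm_p >= norm_n:
            sigma = s[j] * norm_p
            if norm_p > 0:
                w[:, j] = np.sqrt(sigma) * xp / np.linalg.norm(xp)
                h[j] = np.sqrt(sigma) * yp / np.linalg.norm(yp)
        else:
            sigma = s[j] * norm_n
            w[:, j] = np.sqrt(sigma) * xn / np.linalg.norm(xn)
            h[j] = np.sqrt(sigma) * yn / np.linalg.norm(yn)
    mean = a.mean()
    w[w == 0] = mean
    h[h == 0] = mean
    return w, h


def run_nmf(
    er: ExpressionMatrix,
    k: int,
    sample_id: str = "sample",
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[list[NMFProgram], np.ndarray]:
    """Factorize zeroed-negative relative expression into ``k`` programs.

    Returns the programs (gene weights = rows of H) and the per-iteration
    Frobenius reconstruction-error trace, which is non-increasing.  The
    deterministic initialization makes reruns bit-identical; ``seed`` is kept
    for interface stability but unused.
    """
    require_scale(er, "centered")
    a = np.clip(er.values.to_numpy(dtype=float), 0.0, None)
    if k > min(a.shape):
        raise ValueError(f"k={k} exceeds min(cells, genes)={min(a.shape)}")
    w, h = _nndsvda(a, k)

    eps = 1e-12
    errors = []
    prev = None
    for _ in range(max_iter):
        h *= (w.T @ a) / (w.T @ w @ h + eps)
        w *= (a @ h.T) / (w @ h @ h.T + eps)
        err = float(np.linalg.norm(a - w @ h))
        errors.append(err)
        if prev is not None and prev - err < tol * max(prev, 1.0):
            break
        prev = err

    programs = [
        NMFProgram(sample_id, j, pd.Series(h[j], index=er.gene_ids, name=f"{sample_id}.f{j}"))
        for j in range(k)
    ]
    return programs, np.asarray(errors)


def cluster_programs(
    scores: pd.DataFrame,
    min_avg_corr: float = 0.5,
    whitelist=(),
) -> list[list[str]]:
    """Group programs whose per-cell score vectors correlate.

    ``scores`` is cells x programs (each program scored over all compartment
    cells).  Programs are clustered with Ward linkage on 1 - Pearson; the tree
    is cut at the coarsest level at which every multi-member cluster has mean
    pairwise correlation above ``min_avg_corr``.  Multi-member clusters are
    retained; singletons are dropped unless whitelisted.  The result is
    invariant to the column order of ``scores``.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 programs")
    scores = scores[sorted(scores.columns)]
    ids = list(scores.columns)
    corr = np.corrcoef(scores.to_numpy().T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    tree = linkage(dist, method="ward")

    def mean_pairwise(members: list[int]) -> float:
        sub = corr[np.ix_(members, members)]
        n = len(members)
        return float((sub.sum() - n) / (n * (n - 1)))

    chosen = None
    for n_clusters in range(1, len(ids) + 1):
        labels = fcluster(tree, t=n_clusters, criterion="maxclust")
        groups = [np.flatnonzero(labels == lab).tolist() for lab in np.unique(labels)]
        if all(len(g) < 2 or mean_pairwise(g) > min_avg_corr for g in groups):
            chosen = groups
            break
    assert chosen is not None  # all-singleton cut always satisfies the rule

    whitelist = set(whitelist)
    clusters = []
    for g in chosen:
        names = [ids[i] for i in g]
        if len(names) >= 2 or names[0] in whitelist:
            clusters.append(sorted(names))
    return sorted(clusters)


def merge_to_metaprogram(
    members: list[NMFProgram], name: str, compartment: str | None = None
) -> Metaprogram:
    """Average member weight vectors and keep the top 30 genes.

    Members may live on different gene universes; absent genes count as weight
    zero.  Gene ties are broken lexicographically.
    """
    if not members:
        raise ValueError("empty program cluster")
    universe = sorted(set().union(*(p.weights.index for p in members)))
    stacked = pd.DataFrame(
        {p.program_id: p.weights.reindex(universe, fill_value=0.0) for p in members}
    )
    mean_w = stacked.mean(axis=1)
    return Metaprogram(
        name=name,
        member_ids=[p.program_id for p in members],
        top_genes=top_genes(mean_w, TOP_N),
        mean_weights=mean_w,
        compartment=compartment,
    )


def signature_genes(
    assignments: pd.Series,
    log_m: ExpressionMatrix,
    alpha: float = 0.05,
    min_log2_diff: float = 1.0,
    min_expressed_frac: float = 0.5,
    min_cells: int = 3,
) -> dict[str, list[str]]:
    """Population-specific signature genes by one-vs-rest rank-sum test.

    A gene is a signature gene of population P iff (1) its Bonferroni-adjusted
    Wilcoxon rank-sum p-value (P vs all other cells, on uncentered log values)
    is below ``alpha``, (2) mean E in P exceeds the rest by at least
    ``min_log2_diff`` (2-fold on the log2 scale), and (3) it is expressed
    (E > 0) in at least ``min_expressed_frac`` of P's cells.  Populations with
    fewer than ``min_cells`` cells are skipped with a warning.
    """
    require_scale(log_m, "log")
    vals = log_m.values
    out: dict[str, list[str]] = {}
    for pop in sorted(assignments.dropna().unique()):
        in_pop = assignments == pop
        cells_in = vals.loc[assignments.index[in_pop]]
        cells_out = vals.loc[assignments.index[~in_pop]]
        if len(cells_in) < min_cells or len(cells_out) < min_cells:
            warnings.warn(f"population {pop!r} has too few cells; skipped")
            continue
        stat = mannwhitneyu(
            cells_in.to_numpy(), cells_out.to_numpy(), axis=0, alternative="two-sided"
        )
        p_adj = np.minimum(stat.pvalue * vals.shape[1], 1.0)
        diff = cells_in.mean(axis=0) - cells_out.mean(axis=0)
        frac = (cells_in > 0).mean(axis=0)
        keep = (p_adj < alpha) & (diff >= min_log2_diff) & (frac >= min_expressed_frac)
        out[pop] = sorted(vals.columns[keep])
    return out


def discover_metaprograms(
    er_by_sample: dict[str, ExpressionMatrix],
    er_compartment: ExpressionMatrix,
    ea: pd.Series,
    k: int = 10,
    n_overdispersed: int = 10_000,
    min_avg_corr: float = 0.5,
    whitelist=(),
    compartment: str | None = None,
    seed: int = 0,
) -> tuple[list[Metaprogram], pd.DataFrame]:
    """Full compartment pipeline: per-sample NMF -> score -> cluster -> merge.

    ``er_by_sample`` maps sample id to the centered matrix of that sample's
    malignant cells (already restricted as desired); ``er_compartment`` is the
    centered matrix of all compartment cells used for program scoring.
    Returns the metaprograms (named MP1, MP2, ... in cluster order) and the
    cells x programs score matrix.
    """
    from .scoring import build_control_sets, score_cells

    programs: dict[str, NMFProgram] = {}
    for sid, er in sorted(er_by_sample.items()):
        for prog in run_nmf(er, k=k, sample_id=sid, seed=seed)[0]:
            programs[prog.program_id] = prog

    score_cols = {}
    for pid, prog in programs.items():
        genes = [g for g in prog.top_genes if g in ea.index and g in er_compartment.gene_ids]
        ctrl = build_control_sets(ea, genes)
        score_cols[pid] = score_cells(er_compartment, genes, ctrl)
    scores = pd.DataFrame(score_cols, index=er_compartment.cell_ids)

    clusters = cluster_programs(scores, min_avg_corr=min_avg_corr, whitelist=whitelist)
    metas = [
        merge_to_metaprogram([programs[pid] for pid in cl], f"MP{i + 1}", compartment)
        for i, cl in enumerate(clusters)
    ]
    return metas, scores
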