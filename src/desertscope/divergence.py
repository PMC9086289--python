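"""Transcriptomic divergence testing.

PCA on samples over a gene subset, permutation-based ("jackstraw")
component significance, per-stage pairwise Euclidean distances between
brain structures in the selected component subspace, and Wilcoxon
rank-sum tests with Bonferroni correction leading to a per-(structure,
stage) divergent call.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, SampleMetadata, STAGE_ORDER

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "JackStrawResult",
    "DivergenceResult",
    "run_pca",
    "jackstraw",
    "select_components",
    "pairwise_stage_distances",
    "divergence_test",
    "run_divergence",
    "rank_sum_p",
]


@dataclass
class PCAResult:
    """PCA with samples as observations and genes as variables.

    Genes are centered (and optionally unit-variance scaled). Component
    signs are canonicalized so the largest-magnitude loading is positive.
    """

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_fraction: np.ndarray
    centered: bool = True
    scaled: bool = False

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(
    m: ExpressionMatrix,
    scale_unit_variance: bool = False,
    n_components: int | None = None,
) -> PCAResult:
    if m.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if m.n_genes < 1:
        raise ValueError("PCA requires at least 1 gene")
    if m.scale != "log2":
        raise ValueError("PCA expects a log-scale matrix")
    X = m.values.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    if scale_unit_variance:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    k = min(X.shape) if n_components is None else min(n_components, *X.shape)
    # deterministic full SVD; no randomized solver
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # sign convention: largest-magnitude loading positive per component
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U * S
    total_var = (S**2).sum()
    denom = X.var(axis=0, ddof=0).sum() * X.shape[0]
    var_frac = (S**2) / denom if denom > 0 else np.zeros(k)
    if total_var == 0:
        var_frac = np.zeros(k)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=m.gene_ids, columns=comp_names),
        variance_fraction=var_frac,
        centered=True,
        scaled=scale_unit_variance,
    )


@dataclass
class JackStrawResult:
    component_p: np.ndarray  # per-component enrichment p-value
    gene_p: pd.DataFrame  # genes x components empirical p-values
    n_permutations: int
    permuted_fraction: float
    seed: int
    gene_p_cutoff: float = 0.05


def jackstraw(
    m: ExpressionMatrix,
    n_perm: int = 100,
    fraction: float = 0.1,
    seed: int = 0,
    n_components: int | None = None,
    gene_p_cutoff: float = 0.05,
) -> JackStrawResult:
    """Permutation test for principal-component significance.

    Each round permutes a random ``fraction`` of gene rows across samples,
    recomputes the PCA, and records the squared loadings of the permuted
    genes as null gene-component association scores. Observed squared
    loadings get empirical p-values against that null; a component's
    p-value is a one-sided binomial test for enrichment of gene-level
    p-values below ``gene_p_cutoff`` relative to the uniform expectation.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10 for a usable null")
    n_genes = m.n_genes
    n_permuted = max(1, int(round(n_genes * fraction)))
    if n_genes * fraction < 1:
        logger.warning(
            "fraction %g of %d genes < 1; permuting 1 gene per round",
            fraction, n_genes,
        )
    rng = np.random.default_rng(seed)
    obs_pca = run_pca(m, n_components=n_components)
    k = obs_pca.n_components
    obs_scores = obs_pca.loadings.to_numpy() ** 2  # genes x k

    null_scores: list[np.ndarray] = []
    X = m.values.to_numpy(dtype=float)
    for _ in range(n_perm):
        idx = rng.choice(n_genes, size=n_permuted, replace=False)
        Xp = X.copy()
        for g in idx:
            Xp[g] = Xp[g][rng.permutation(X.shape[1])]
        perm_m = ExpressionMatrix(
            pd.DataFrame(Xp, index=m.gene_ids, columns=m.sample_ids),
            scale=m.scale,
        )
        perm_pca = run_pca(perm_m, n_components=k)
        null_scores.append(perm_pca.loadings.to_numpy()[idx, :k] ** 2)
    null = np.vstack(null_scores)  # (n_perm * n_permuted) x k

    n_null = null.shape[0]
    gene_p = np.empty((n_genes, k))
    for c in range(k):
        col = np.sort(null[:, c])
        # empirical p with add-one correction
        ge = n_null - np.searchsorted(col, obs_scores[:, c], side="left")
        gene_p[:, c] = (1 + ge) / (1 + n_null)

    comp_p = np.empty(k)
    for c in range(k):
        hits = int(np.sum(gene_p[:, c] < gene_p_cutoff))
        comp_p[c] = stats.binomtest(
            hits, n_genes, gene_p_cutoff, alternative="greater"
        ).pvalue
    return JackStrawResult(
        component_p=comp_p,
        gene_p=pd.DataFrame(
            gene_p, index=m.gene_ids, columns=obs_pca.scores.columns
        ),
        n_permutations=n_perm,
        permuted_fraction=fraction,
        seed=seed,
        gene_p_cutoff=gene_p_cutoff,
    )


def select_components(
    pca: PCAResult,
    js: JackStrawResult,
    alpha: float = 0.05,
    fallback_k: int = 2,
) -> list[int]:
    """1-based indices of significant components; falls back to the first
    ``fallback_k`` (with a logged override) when fewer pass."""
    sig = [i + 1 for i, p in enumerate(js.component_p) if p < alpha]
    if len(sig) >= fallback_k:
        return sig
    k = min(fallback_k, pca.n_components)
    logger.info(
        "only %d component(s) significant at %g; overriding to first %d",
        len(sig), alpha, k,
    )
    return list(range(1, k + 1))


def pairwise_stage_distances(
    pca: PCAResult, comps: list[int], meta: SampleMetadata
) -> pd.DataFrame:
    """Euclidean distances between samples of different structures, within
    each stage, in the selected component subspace.

    Each pair appears once; downstream attribution assigns the distance to
    both endpoint structures. Stages with fewer than 2 structures are
    skipped with a log message.
    """
    cols = [f"PC{c}" for c in comps]
    missing = [c for c in cols if c not in pca.scores.columns]
    if missing:
        raise ValueError(f"components not in PCA result: {missing}")
    scores = pca.scores[cols]
    tab = meta.table.set_index("sample_id")
    rows = []
    for stage in STAGE_ORDER:
        stage_samples = tab.index[tab["stage"] == stage]
        stage_samples = [s for s in stage_samples if s in scores.index]
        structures = tab.loc[stage_samples, "structure"]
        if structures.nunique() < 2:
            logger.info("stage %s has <2 structures; skipped", stage)
            continue
        for sa, sb in itertools.combinations(stage_samples, 2):
            st_a, st_b = structures[sa], structures[sb]
            if st_a == st_b:
                continue
            d = float(
                np.linalg.norm(scores.loc[sa].to_numpy() - scores.loc[sb].to_numpy())
            )
            a, b = sorted([st_a, st_b])
            rows.append(
                {
                    "stage": stage,
                    "structure_a": a,
                    "structure_b": b,
                    "sample_a": sa if a == st_a else sb,
                    "sample_b": sb if a == st_a else sa,
                    "distance": d,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["stage", "structure_a", "structure_b", "sample_a", "sample_b", "distance"],
    )


def rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact when both groups are small and untied; normal approximation with
    continuity correction (midranks for ties) otherwise. The degenerate
    all-tied case returns 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        logger.info("all distances tied; p = 1 by convention")
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(x), len(y)) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


@dataclass
class DivergenceResult:
    """Per-stage pairwise test table and per-(structure, stage) calls."""

    pair_table: pd.DataFrame  # stage, structure_a, structure_b, raw_p, adj_p
    structure_table: pd.DataFrame  # stage, structure, mean_adj_p, divergent
    distances: pd.DataFrame
    alpha: float
    family: str = "stage"

    def divergent_cells(self) -> set[tuple[str, str]]:
        t = self.structure_table
        return {
            (r.structure, r.stage)
            for r in t.itertuples()
            if r.divergent
        }


def divergence_test(
    distances: pd.DataFrame,
    alpha: float = 0.01,
    family: str = "stage",
) -> DivergenceResult:
    """Wilcoxon rank-sum tests on attributed distance distributions.

    Per stage, for every structure pair (a, b), the distances attributed
    to a are compared against those attributed to b (two-sided). Bonferroni
    is applied over all pairs within the stage (``family='stage'``, the
    default) or over all pairs across all stages (``family='global'``).
    A structure is divergent at a stage iff every one of its pairwise
    adjusted p-values is below ``alpha``.
    """
    if family not in {"stage", "global"}:
        raise ValueError(f"unknown family {family!r}")
    pair_rows = []
    for stage, stage_df in distances.groupby("stage", sort=False):
        structures = sorted(
            set(stage_df["structure_a"]) | set(stage_df["structure_b"])
        )
        attributed = {
            s: stage_df.loc[
                (stage_df["structure_a"] == s) | (stage_df["structure_b"] == s),
                "distance",
            ].to_numpy()
            for s in structures
        }
        for a, b in itertools.combinations(structures, 2):
            if len(attributed[a]) < 2 or len(attributed[b]) < 2:
                raise ValueError(
                    f"structure with <2 attributed distances at stage {stage}"
                )
            pair_rows.append(
                {
                    "stage": stage,
                    "structure_a": a,
                    "structure_b": b,
                    "raw_p": rank_sum_p(attributed[a], attributed[b]),
                }
            )
    pair_table = pd.DataFrame(
        pair_rows, columns=["stage", "structure_a", "structure_b", "raw_p"]
    )
    if family == "stage":
        m_per_stage = pair_table.groupby("stage")["stage"].transform("size")
        pair_table["adj_p"] = np.minimum(1.0, pair_table["raw_p"] * m_per_stage)
    else:
        pair_table["adj_p"] = np.minimum(
            1.0, pair_table["raw_p"] * len(pair_table)
        )

    struct_rows = []
    for stage, stage_df in pair_table.groupby("stage", sort=False):
        structures = sorted(
            set(stage_df["structure_a"]) | set(stage_df["structure_b"])
        )
        for s in structures:
            ps = stage_df.loc[
                (stage_df["structure_a"] == s) | (stage_df["structure_b"] == s),
                "adj_p",
            ].to_numpy()
            struct_rows.append(
                {
                    "stage": stage,
                    "structure": s,
                    "mean_adj_p": float(ps.mean()),
                    "divergent": bool((ps < alpha).all()),
                }
            )
    structure_table = pd.DataFrame(
        struct_rows, columns=["stage", "structure", "mean_adj_p", "divergent"]
    )
    return DivergenceResult(
        pair_table=pair_table,
        structure_table=structure_table,
        distances=distances,
        alpha=alpha,
        family=family,
    )


def run_divergence(
    m: ExpressionMatrix,
    meta: SampleMetadata,
    alpha: float = 0.01,
    alpha_pcs: float = 0.05,
    n_perm: int = 100,
    fraction: float = 0.1,
    seed: int = 0,
    fallback_k: int = 2,
    family: str = "stage",
) -> tuple[DivergenceResult, PCAResult, JackStrawResult, list[int]]:
    """End-to-end divergence call on a (log-scale) gene-subset matrix."""
    pca = run_pca(m)
    js = jackstraw(m, n_perm=n_perm, fraction=fraction, seed=seed)
    comps = select_components(pca, js, alpha=alpha_pcs, fallback_k=fallback_k)
    dist = pairwise_stage_distances(pca, comps, meta)
    result = divergence_test(dist, alpha=alpha, family=family)
    return result, pca, js, comps
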