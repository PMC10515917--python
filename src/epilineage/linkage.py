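"""GRE-gene linkage, regulation-divergent genes, and HS-DEG overlap.

Linkage correlates pseudobulk GRE accessibility with expression of genes
within a distance window, and standardizes each correlation against a
background of GREs matched on GC content and mean accessibility.  Genes
linked to significantly more lineage-divergent GREs than random GRE draws
(with >= 2 divergent and >= 5 total links) are regulation-divergent genes
(RDGs).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _standardize_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows to zero mean / unit norm-sd; returns (z, nonzero-variance mask)."""
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    # guard against constant rows whose floating std is ~1e-16, not 0
    tol = 1e-10 * (np.abs(mu) + 1.0)
    ok = sd[:, 0] > tol[:, 0]
    sd[~ok[:, None] & (sd >= 0)] = 1.0
    return (mat - mu) / sd, ok


def candidate_pairs(gre_coords: pd.DataFrame, gene_coords: pd.DataFrame,
                    max_dist: int = 500_000) -> pd.DataFrame:
    """GRE-gene pairs with the GRE within ``max_dist`` of the gene body."""
    rows = []
    for chrom, genes in gene_coords.groupby("chrom"):
        gres = gre_coords[gre_coords["chrom"] == chrom]
        if gres.empty:
            continue
        gs = gres["start"].to_numpy()
        ge = gres["end"].to_numpy()
        gid = gres["gre_id"].to_numpy()
        for gene in genes.itertuples(index=False):
            dist = np.maximum(
                0, np.maximum(gene.start - ge + 1, gs - gene.end + 1))
            near = dist <= max_dist
            for g in gid[near]:
                rows.append((g, gene.gene_id))
    return pd.DataFrame(rows, columns=["gre_id", "gene_id"])


def link_gres_to_genes(acc: pd.DataFrame, expr: pd.DataFrame,
                       gre_coords: pd.DataFrame, gene_coords: pd.DataFrame,
                       gre_gc: pd.Series, max_dist: int = 500_000,
                       n_bg: int = 200, seed: int = 0,
                       fdr_max: float = 0.05,
                       score_min: float = 0.01) -> pd.DataFrame:
    """Correlate accessibility with expression against a matched background.

    For each candidate pair, the Pearson r is standardized by the mean/sd
    of correlations between the same gene and ``n_bg`` background GREs
    nearest the focal GRE in (GC content, mean accessibility) space;
    z yields a two-sided normal p, BH-adjusted over all tested pairs.
    Significant links require FDR < ``fdr_max`` and r > ``score_min``.
    """
    if list(acc.columns) != list(expr.columns):
        raise ValueError("accessibility and expression must share pseudobulk columns")
    n_units = acc.shape[1]
    pairs = candidate_pairs(gre_coords, gene_coords, max_dist)
    if pairs.empty:
        return pd.DataFrame(columns=["gre_id", "gene_id", "score", "z", "p",
                                     "fdr", "significant"])

    acc_z, acc_ok = _standardize_rows(acc.to_numpy(dtype=float))
    expr_z, expr_ok = _standardize_rows(expr.to_numpy(dtype=float))
    gre_index = {g: i for i, g in enumerate(acc.index)}
    gene_index = {g: i for i, g in enumerate(expr.index)}

    skipped = 0
    keep = []
    for row in pairs.itertuples(index=False):
        gi = gre_index.get(row.gre_id)
        ei = gene_index.get(row.gene_id)
        if gi is None or ei is None or not (acc_ok[gi] and expr_ok[ei]):
            skipped += 1
            continue
        keep.append((gi, ei, row.gre_id, row.gene_id))
    if skipped:
        logger.info("skipped %d zero-variance or unknown pairs", skipped)
    if not keep:
        return pd.DataFrame(columns=["gre_id", "gene_id", "score", "z", "p",
                                     "fdr", "significant"])

    # background matching on (GC, mean accessibility)
    feats = np.column_stack([
        gre_gc.reindex(acc.index).to_numpy(dtype=float),
        acc.to_numpy(dtype=float).mean(axis=1)])
    feats = (feats - feats.mean(axis=0)) / np.where(
        feats.std(axis=0) > 0, feats.std(axis=0), 1.0)
    k = min(n_bg + 1, len(acc))
    nn = NearestNeighbors(n_neighbors=k).fit(feats)
    _, nbrs = nn.kneighbors(feats)

    # all-GRE correlation with each needed gene in one matvec
    needed_genes = sorted({ei for _, ei, _, _ in keep})
    r_all = {ei: acc_z @ expr_z[ei] / n_units for ei in needed_genes}

    out = []
    for gi, ei, gre_id, gene_id in keep:
        bg = np.array([j for j in nbrs[gi] if j != gi][: k - 1])
        bg = bg[acc_ok[bg]]
        null = r_all[ei][bg]
        r = float(r_all[ei][gi])
        mu, sd = float(null.mean()), float(null.std(ddof=1))
        if sd == 0:
            z = 0.0 if r == mu else np.sign(r - mu) * np.inf
        else:
            z = (r - mu) / sd
        p = float(2 * stats.norm.sf(abs(z)))
        out.append((gre_id, gene_id, r, float(z), p))
    links = pd.DataFrame(out, columns=["gre_id", "gene_id", "score", "z", "p"])
    links["fdr"] = multipletests(links["p"].to_numpy(), method="fdr_bh")[1]
    links["significant"] = (links["fdr"] < fdr_max) & (links["score"] > score_min)
    return links


def identify_rdgs(links: pd.DataFrame, divergent: dict[str, set[str]],
                  gre_universe: list[str], n_perm: int = 1000, seed: int = 0,
                  fdr_max: float = 0.05, min_divergent: int = 2,
                  min_total: int = 5,
                  restrict_to_linked: bool = False) -> pd.DataFrame:
    """Permutation test for genes linked to excess lineage-divergent GREs.

    Per lineage the observed statistic is the gene's number of significant
    links whose GRE is divergent in that lineage; the null redraws the same
    number of GREs from the universe ``n_perm`` times and recounts.  The
    empirical p counts ties against significance (#{null >= obs}/n_perm).
    """
    sig = links[links["significant"]]
    genes = sorted(sig["gene_id"].unique())
    if not genes:
        return pd.DataFrame(columns=["gene_id", "lineage", "n_divergent_links",
                                     "n_total_links", "empirical_p", "fdr",
                                     "is_rdg"])
    universe = sorted(set(gre_universe))
    if restrict_to_linked:
        universe = sorted(set(sig["gre_id"]))
    uni_index = {g: i for i, g in enumerate(universe)}
    gene_pos = {g: i for i, g in enumerate(genes)}

    # gene x GRE membership of significant links
    link_mat = np.zeros((len(genes), len(universe)), dtype=np.float32)
    for row in sig.itertuples(index=False):
        j = uni_index.get(row.gre_id)
        if j is not None:
            link_mat[gene_pos[row.gene_id], j] = 1.0
    totals = link_mat.sum(axis=1)

    rng = np.random.default_rng(seed)
    frames = []
    for lineage in sorted(divergent):
        dset = divergent[lineage] & set(universe)
        size = len(dset)
        if size == 0:
            logger.info("lineage %s: empty divergent set, no RDGs", lineage)
            continue
        div_idx = np.array([uni_index[g] for g in sorted(dset)])
        observed = link_mat[:, div_idx].sum(axis=1)
        indic = np.zeros((len(universe), n_perm), dtype=np.float32)
        for p in range(n_perm):
            idx = rng.choice(len(universe), size=size, replace=False)
            indic[idx, p] = 1.0
        null = link_mat @ indic  # genes x n_perm
        pvals = (null >= observed[:, None]).mean(axis=1)
        fdr = multipletests(pvals, method="fdr_bh")[1]
        is_rdg = ((fdr < fdr_max)
                  & (observed >= min_divergent)
                  & (totals >= min_total))
        frames.append(pd.DataFrame({
            "gene_id": genes, "lineage": lineage,
            "n_divergent_links": observed.astype(int),
            "n_total_links": totals.astype(int),
            "empirical_p": pvals, "fdr": fdr, "is_rdg": is_rdg}))
    if not frames:
        return pd.DataFrame(columns=["gene_id", "lineage", "n_divergent_links",
                                     "n_total_links", "empirical_p", "fdr",
                                     "is_rdg"])
    return pd.concat(frames, ignore_index=True)


def hsdeg_overlap_test(rdgs: set[str], hsdegs: set[str],
                       gene_universe: set[str], n_perm: int = 1000,
                       seed: int = 0) -> dict:
    """Permutation test of RDG overlap with human-specific DE genes.

    Random same-size 'HS-DEG' sets are drawn from the gene universe; the
    empirical p is the fraction of draws whose overlap with the RDG set
    reaches the observed one.  Also reports the fraction of HS-DEGs that
    are RDGs.
    """
    if not rdgs or not hsdegs or not gene_universe:
        raise ValueError("empty input set")
    if not hsdegs <= gene_universe:
        raise ValueError("HS-DEG list must be a subset of the gene universe")
    observed = len(rdgs & hsdegs)
    rng = np.random.default_rng(seed)
    uni = sorted(gene_universe)
    k = len(hsdegs)
    in_rdg = np.array([g in rdgs for g in uni])
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        draw = rng.choice(len(uni), size=k, replace=False)
        null[i] = int(in_rdg[draw].sum())
    p = float((null >= observed).mean())
    return {"observed_overlap": observed,
            "overlap_ratio": observed / len(hsdegs),
            "null_mean": float(null.mean()),
            "empirical_p": p}
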