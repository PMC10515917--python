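"""Evolutionary classification of GREs: lineage-divergent vs conserved.

Divergence is called with three stacked cutoffs against a resampling null:

1. empirical FDR < 0.05 and fold change > 1.5 on the GRE's per-lineage
   substitution proportion versus pooled proportions of 1,000 random draws
   of 10,000 GREs;
2. z-score of the proportion across all GREs for that lineage > 1;
3. at least 2 raw substitutions in the lineage.

A GRE may be divergent in more than one lineage.  Conserved GREs sit
strictly below the median normalized rate in every lineage and are not
divergent anywhere.  The module also prepares ranked, flank-expanded BED
annotations for downstream LD-score regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ResamplingNull:
    """Background lineage proportions from repeated random GRE draws."""

    proportions: np.ndarray  # (n_iter, n_lineages)
    medians: np.ndarray      # (n_lineages,)
    lineages: tuple[str, ...]
    n_draw: int
    n_iter: int


def build_resampling_null(counts: pd.DataFrame, n_draw: int = 10_000,
                          n_iter: int = 1000, seed: int = 0) -> ResamplingNull:
    """Sample ``n_draw`` GREs ``n_iter`` times; pool counts into proportions.

    Each draw is without replacement.  If the dataset holds fewer than
    ``n_draw`` GREs the draw size is lowered to the dataset size (logged).
    """
    if counts.empty:
        raise ValueError("empty substitution count table")
    n = len(counts)
    if n_draw > n:
        logger.info("n_draw %d > %d GREs; lowering to dataset size", n_draw, n)
        n_draw = n
    rng = np.random.default_rng(seed)
    mat = counts.to_numpy(dtype=float)
    props = np.empty((n_iter, mat.shape[1]))
    for i in range(n_iter):
        idx = rng.choice(n, size=n_draw, replace=False)
        pooled = mat[idx].sum(axis=0)
        total = pooled.sum()
        props[i] = pooled / total if total > 0 else np.nan
    return ResamplingNull(props, np.median(props, axis=0),
                          tuple(counts.columns), n_draw, n_iter)


def classify_divergent(counts: pd.DataFrame, null: ResamplingNull,
                       fc_min: float = 1.5, fdr_max: float = 0.05,
                       z_min: float = 1.0, min_subs: int = 2,
                       pseudocount: bool = False) -> pd.DataFrame:
    """Per-GRE, per-lineage divergence table.

    Empirical p is the fraction of null draws whose background proportion
    exceeds the observed one (k / n_iter literally; ``pseudocount``
    switches to (k+1)/(n+1)).  BH adjustment runs within each lineage over
    GREs with defined proportions.
    """
    if tuple(counts.columns) != null.lineages:
        raise ValueError("count table lineages do not match the null")
    mat = counts.to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals[:, None] > 0, mat / totals[:, None], np.nan)

    n_iter = null.n_iter
    # p[g, l] = #{null proportions > observed} / n_iter
    exceed = np.zeros_like(props)
    for j in range(props.shape[1]):
        col = null.proportions[:, j]
        exceed[:, j] = (col[None, :] > props[:, [j]]).sum(axis=1)
    if pseudocount:
        pvals = (exceed + 1.0) / (n_iter + 1.0)
    else:
        pvals = exceed / n_iter
    pvals = np.where(np.isnan(props), np.nan, pvals)

    fc = props / null.medians[None, :]

    defined = totals > 0
    z = np.full_like(props, np.nan)
    for j in range(props.shape[1]):
        col = props[defined, j]
        sd = col.std(ddof=1)
        if sd > 0:
            z[defined, j] = (col - col.mean()) / sd

    fdr = np.full_like(pvals, np.nan)
    for j in range(pvals.shape[1]):
        mask = ~np.isnan(pvals[:, j])
        if mask.any():
            fdr[mask, j] = multipletests(pvals[mask, j], method="fdr_bh")[1]

    rows = []
    lineages = list(counts.columns)
    for g, gre in enumerate(counts.index):
        labels = []
        for j, lin in enumerate(lineages):
            divergent = (defined[g]
                         and fdr[g, j] < fdr_max
                         and fc[g, j] > fc_min
                         and z[g, j] > z_min
                         and mat[g, j] >= min_subs)
            if divergent:
                labels.append(lin)
            rows.append({
                "gre_id": gre, "lineage": lin,
                "raw_count": int(mat[g, j]),
                "proportion": props[g, j],
                "empirical_p": pvals[g, j],
                "fdr": fdr[g, j],
                "fold_change": fc[g, j],
                "z": z[g, j],
                "divergent": divergent,
            })
        cls = ";".join(f"divergent:{l}" for l in labels) or "unclassified"
        for r in rows[-len(lineages):]:
            r["class"] = cls
    return pd.DataFrame(rows)


def divergent_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Lineage -> set of divergent GRE ids, from a divergence table."""
    out: dict[str, set[str]] = {}
    for lin, sub in table[table["divergent"]].groupby("lineage"):
        out[str(lin)] = set(sub["gre_id"])
    for lin in table["lineage"].unique():
        out.setdefault(str(lin), set())
    return out


def classify_conserved(rates: pd.DataFrame,
                       divergent: dict[str, set[str]]) -> set[str]:
    """Conserved GREs: strictly below the median rate in every lineage,
    and divergent in none.

    `rates` is the tidy table from :func:`normalize_rates`.
    """
    wide = rates.pivot(index="gre_id", columns="lineage",
                       values="rate_per_my_per_kb")
    below = wide.lt(wide.median(axis=0), axis=1).all(axis=1)
    conserved = set(wide.index[below])
    for s in divergent.values():
        conserved -= s
    return conserved


def jaccard(a: set, b: set) -> float:
    """|A n B| / |A u B|; 0 for an empty union."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def conservation_score(table: pd.DataFrame) -> pd.Series:
    """Per-GRE conservation score: 1 / mean fold change across lineages.

    Higher scores mean fewer substitutions relative to the background in
    every lineage.  Undefined (NaN) where the mean fold change is 0 or
    undefined.
    """
    mean_fc = table.groupby("gre_id")["fold_change"].mean()
    with np.errstate(divide="ignore"):
        score = 1.0 / mean_fc
    return score.replace([np.inf, -np.inf], np.nan)


def ldsc_annotation_prep(gre_bed: pd.DataFrame, scores: pd.Series,
                         out_dir: str | Path, top_n: int = 20_000,
                         flank: int = 25_000, prefix: str = "top",
                         sliding_windows: bool = False,
                         window_half: int = 25_000,
                         shift_max: int = 100_000,
                         shift_step: int = 5_000) -> list[Path]:
    """Write ranked, flank-expanded BED annotations for LD-score regression.

    `gre_bed` needs columns chrom/start/end/gre_id; `scores` ranks GREs
    (descending).  Default mode writes one BED of the top ``top_n`` GREs
    expanded by ``flank`` bp each side, clipped at 0.  Sliding-window mode
    writes one BED per shift in [-shift_max, +shift_max] (step
    ``shift_step``): a window of 2*window_half centered at GRE center +
    shift — 41 files with the defaults.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bed = gre_bed.set_index("gre_id")
    ranked = scores.dropna().sort_values(ascending=False)
    if top_n > len(ranked):
        logger.info("top_n %d > %d ranked GREs; clamping", top_n, len(ranked))
        top_n = len(ranked)
    top = bed.loc[ranked.index[:top_n]]
    top.index.name = "gre_id"

    paths: list[Path] = []
    if not sliding_windows:
        expanded = top.assign(
            start=(top["start"] - flank).clip(lower=0),
            end=top["end"] + flank)
        path = out_dir / f"{prefix}_{top_n}_flank{flank}.bed"
        _write_bed(expanded.reset_index(), path)
        paths.append(path)
        return paths

    centers = (top["start"] + top["end"]) // 2
    for shift in range(-shift_max, shift_max + 1, shift_step):
        start = (centers + shift - window_half).clip(lower=0)
        end = centers + shift + window_half
        df = pd.DataFrame({"chrom": top["chrom"], "start": start, "end": end,
                           "gre_id": top.index})
        path = out_dir / f"{prefix}_{top_n}_shift{shift:+d}.bed"
        _write_bed(df, path)
        paths.append(path)
    return paths


def _write_bed(df: pd.DataFrame, path: Path) -> None:
    df[["chrom", "start", "end", "gre_id"]].to_csv(
        path, sep="\t", header=False, index=False)
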