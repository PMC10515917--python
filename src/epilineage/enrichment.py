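"""Count-based enrichment statistics.

Covers the cell-type substitution deviation test (length-share chi-square),
Fisher exact marker enrichments, length-adjusted logistic enrichment with
Wald tests, and any-overlap interval comparisons (e.g. against human
accelerated regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning


@dataclass
class MarkerSet:
    """Cell type -> GRE id sets, with total marker length per cell type."""

    sets: dict[str, set[str]]
    lengths_bp: dict[str, float]

    @classmethod
    def from_frame(cls, markers: pd.DataFrame,
                   gre_lengths: pd.Series) -> "MarkerSet":
        """Build from a tidy (cell_type, gre_id) table and per-GRE lengths."""
        sets = {str(ct): set(sub["gre_id"])
                for ct, sub in markers.groupby("cell_type")}
        lengths = {ct: float(gre_lengths.reindex(list(s)).sum())
                   for ct, s in sets.items()}
        return cls(sets, lengths)


def marker_substitution_deviation(counts: pd.DataFrame, markers: MarkerSet,
                                  branch_my: dict[str, float],
                                  fdr_max: float = 1e-5) -> pd.DataFrame:
    """Cell-type deviation of time- and length-normalized substitution load.

    Per lineage and cell type, marker GREs' time-normalized substitution
    values (count / branch MY) are summed, divided by total marker length,
    then divided by the cross-cell-type mean, yielding ratios around 1.
    Significance is a one-sided 1-df chi-square of the cell type's raw
    count against its expectation under a uniform per-bp rate (lineage
    total x cell-type length share); only excesses can be significant.
    """
    cts = sorted(markers.sets)
    if len(cts) < 2:
        raise ValueError("need at least two cell types")
    for ct in cts:
        if markers.lengths_bp[ct] <= 0:
            raise ValueError(f"cell type {ct!r} has zero marker length")
    total_len = sum(markers.lengths_bp[ct] for ct in cts)

    rows = []
    for lin in counts.columns:
        my = float(branch_my[lin])
        norm_vals = {}
        raw = {}
        for ct in cts:
            ids = [g for g in markers.sets[ct] if g in counts.index]
            c = counts.loc[ids, lin].sum()
            raw[ct] = float(c)
            norm_vals[ct] = (c / my) / markers.lengths_bp[ct]
        mean_val = np.mean(list(norm_vals.values()))
        lineage_total = sum(raw.values())
        for ct in cts:
            ratio = norm_vals[ct] / mean_val if mean_val > 0 else np.nan
            expected = lineage_total * markers.lengths_bp[ct] / total_len
            if expected > 0:
                other_o = lineage_total - raw[ct]
                other_e = lineage_total - expected
                stat = (raw[ct] - expected) ** 2 / expected
                if other_e > 0:
                    stat += (other_o - other_e) ** 2 / other_e
                p = float(stats.chi2.sf(stat, df=1)) if raw[ct] > expected else 1.0
            else:
                stat, p = np.nan, 1.0
            rows.append({"lineage": lin, "cell_type": ct,
                         "deviation_ratio": ratio, "observed": raw[ct],
                         "expected": expected, "chi2": stat, "p": p})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["label"] = np.where(
        (out["fdr"] < fdr_max) & (out["observed"] > out["expected"]),
        "enriched", "ns")
    return out


def fisher_marker_enrichment(marker_ids: set[str], class_ids: set[str],
                             universe: set[str],
                             alternative: str = "two-sided") -> dict:
    """One 2x2 Fisher exact test of marker membership vs class membership.

    The table is built over the full GRE universe; the odds ratio gets a
    0.5 continuity adjustment for display only when a cell is zero.
    A class equal to the whole universe is degenerate and flagged.
    """
    if not universe:
        raise ValueError("empty universe")
    if not class_ids <= universe:
        raise ValueError("class set must be a subset of the universe")
    m = marker_ids & universe
    a = len(m & class_ids)
    b = len(m) - a
    c = len(class_ids) - a
    d = len(universe) - a - b - c
    degenerate = class_ids == universe or not class_ids
    if degenerate:
        return {"a": a, "b": b, "c": c, "d": d, "odds_ratio": np.nan,
                "p": 1.0, "degenerate": True}
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if min(a, b, c, d) == 0:
        oratio = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        oratio = a * d / (b * c)
    return {"a": a, "b": b, "c": c, "d": d, "odds_ratio": float(oratio),
            "p": float(p), "degenerate": False}


def fisher_enrichment_batch(marker_sets: dict[str, set[str]],
                            class_sets: dict[str, set[str]],
                            universe: set[str], fdr_max: float = 0.05,
                            or_min: float = 1.0,
                            alternative: str = "two-sided") -> pd.DataFrame:
    """Fisher tests for every marker x class pair, BH-adjusted as one batch.

    Labels: enriched at FDR < fdr_max and OR > or_min; depleted at
    FDR < fdr_max and OR < 1/or_min (for or_min 1 this is OR < 1).
    """
    rows = []
    for mname, mids in marker_sets.items():
        for cname, cids in class_sets.items():
            res = fisher_marker_enrichment(mids, cids, universe, alternative)
            res.update({"marker": mname, "class": cname})
            rows.append(res)
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    lo = 1.0 / or_min if or_min != 0 else 1.0
    out["label"] = "ns"
    sig = (out["fdr"] < fdr_max) & ~out["degenerate"]
    out.loc[sig & (out["odds_ratio"] > or_min), "label"] = "enriched"
    out.loc[sig & (out["odds_ratio"] < lo), "label"] = "depleted"
    return out


def logistic_enrichment(response: np.ndarray, gre_lengths: np.ndarray,
                        predictor: np.ndarray) -> dict:
    """Length-adjusted logistic enrichment of a binary class.

    Fits logit P(response=1) = b0 + b1*length + b2*predictor by maximum
    likelihood and reports b2 with its Wald p-value, so that enrichment of,
    say, human-divergent GREs among human-specific accessibility changes is
    not confounded by GRE length.  Perfect separation is flagged instead of
    reported.
    """
    response = np.asarray(response, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    gre_lengths = np.asarray(gre_lengths, dtype=float)
    if len({response.shape[0], predictor.shape[0], gre_lengths.shape[0]}) != 1:
        raise ValueError("inputs must share length")
    if response.min() == response.max():
        raise ValueError("degenerate response")
    X = sm.add_constant(np.column_stack([gre_lengths, predictor]))
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(response, X).fit(disp=False, maxiter=100)
        except Exception:
            return {"beta": np.nan, "se": np.nan, "p": np.nan,
                    "separation": True}
    beta = float(fit.params[2])
    se = float(fit.bse[2])
    if not np.isfinite(se) or se > 1e4:
        return {"beta": beta, "se": se, "p": np.nan, "separation": True}
    z = beta / se
    return {"beta": beta, "se": se, "p": float(2 * stats.norm.sf(abs(z))),
            "separation": False}


def logistic_enrichment_batch(response_sets: dict[str, set[str]],
                              predictor_sets: dict[str, set[str]],
                              gre_lengths: pd.Series,
                              fdr_max: float = 0.05) -> pd.DataFrame:
    """Logistic enrichment for every response x predictor label pair."""
    ids = list(gre_lengths.index)
    lengths = gre_lengths.to_numpy(dtype=float)
    rows = []
    for rname, rset in response_sets.items():
        y = np.array([g in rset for g in ids], dtype=float)
        for pname, pset in predictor_sets.items():
            x = np.array([g in pset for g in ids], dtype=float)
            res = logistic_enrichment(y, lengths, x)
            res.update({"response": rname, "predictor": pname})
            rows.append(res)
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"].to_numpy(),
                                           method="fdr_bh")[1]
    out["label"] = "ns"
    sig = ok & (out["fdr"] < fdr_max)
    out.loc[sig & (out["beta"] > 0), "label"] = "enriched"
    out.loc[sig & (out["beta"] < 0), "label"] = "depleted"
    return out


def interval_overlap(set_a: pd.DataFrame, set_b: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Any-overlap (>= 1 bp) join of two 0-based half-open interval sets.

    Both frames need chrom/start/end and an id column (4th column).  Returns
    the overlap pairs and per-A-interval overlap counts.
    """
    for df in (set_a, set_b):
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
    id_a, id_b = set_a.columns[3], set_b.columns[3]
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in set_b.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e), i) for s, e, i in
            zip(sub["start"], sub["end"], sub[id_b]))
    pairs = []
    counts = []
    for row in set_a.itertuples(index=False):
        chrom, start, end, aid = row[0], int(row[1]), int(row[2]), row[3]
        hits = trees[str(chrom)].overlap(start, end) if str(chrom) in trees else set()
        counts.append(len(hits))
        for h in sorted(hits, key=lambda x: (x.begin, x.end, str(x.data))):
            pairs.append((aid, h.data))
    pairs_df = pd.DataFrame(pairs, columns=[f"{id_a}_a", f"{id_b}_b"])
    counts_s = pd.Series(counts, index=set_a[id_a].to_numpy(), name="n_overlaps")
    return pairs_df, counts_s
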