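"""TFBS gain/loss evolution across the lineage chain.

Sequences at the six chain nodes are scanned with log-odds PWMs (both
strands); a motif is *present* in a node's GRE sequence if any window
reaches the score threshold whose null exceedance probability under the
background base composition is the match p-value.  A single 0->1 or 1->0
transition of presence along the chain is a gain or loss assigned to that
transition's lineage; anything else is discarded, mirroring the
substitution caller's single-event rule.

Thresholds are computed by exact dynamic programming over the null score
distribution with scores discretized to a fixed grain, so window scoring
and threshold share one integer scale and the scan is reproducible to the
bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from epilineage.phylo import LineageChain

_CODE = {b: i for i, b in enumerate("ACGT")}
_COMP = str.maketrans("ACGTN", "TGCAN")

#: score discretization grain (log2-odds units per integer step)
GRAIN = 1e-4


@dataclass
class PWM:
    """Position weight matrix with a p-value-calibrated match threshold."""

    motif_id: str
    name: str
    pfm: np.ndarray  # (4, L) frequencies
    family: str = ""
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.8

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4 or self.pfm.shape[1] < 1:
            raise ValueError("PFM must be 4 x L")
        colsum = self.pfm.sum(axis=0)
        if np.any(colsum <= 0):
            raise ValueError("PFM column sums must be positive")
        self.pfm = self.pfm / colsum

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pfm.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """log2 odds vs background, with pseudocount/4 added per cell."""
        p = self.pfm + self.pseudocount / 4.0
        p = p / p.sum(axis=0)
        return np.log2(p / self.background[:, None])

    def int_matrix(self) -> np.ndarray:
        """(4, L) log-odds discretized to integer GRAIN steps."""
        return np.round(self.log_odds() / GRAIN).astype(np.int64)

    def score_threshold(self, match_p: float = 5e-5) -> int:
        """Smallest integer score t with P(window score >= t) <= match_p.

        Exact DP: convolve the per-column score distributions under the
        background model over the discretized score support.
        """
        return _dp_threshold(self.int_matrix(), self.background, match_p)


def _dp_threshold(int_mat: np.ndarray, background: np.ndarray,
                  match_p: float) -> int:
    cur_lo = int(int_mat[:, 0].min())
    cur_hi = int(int_mat[:, 0].max())
    dist = np.zeros(cur_hi - cur_lo + 1)
    for b in range(4):
        dist[int(int_mat[b, 0]) - cur_lo] += background[b]
    for j in range(1, int_mat.shape[1]):
        col = int_mat[:, j]
        col_lo, col_hi = int(col.min()), int(col.max())
        new = np.zeros((cur_hi + col_hi) - (cur_lo + col_lo) + 1)
        for b in range(4):
            s = int(col[b]) - col_lo
            new[s:s + dist.size] += background[b] * dist
        dist = new
        cur_lo += col_lo
        cur_hi += col_hi
    tail = np.cumsum(dist[::-1])[::-1]  # P(score >= cur_lo + i)
    idx = np.where(tail <= match_p)[0]
    if idx.size == 0:
        return cur_hi + 1  # unreachable: nothing can ever match
    # report the smallest *achievable* score with tail <= match_p
    i = int(idx[0])
    ach = np.where(dist[i:] > 1e-15)[0]
    if ach.size == 0:
        return cur_hi + 1
    return cur_lo + i + int(ach[0])


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for b, c in _CODE.items():
        codes[arr == ord(b)] = c
    return codes


def _strand_scores(codes: np.ndarray, imat: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Window scores and validity for one orientation of the matrix."""
    n, L = codes.shape[0], imat.shape[1]
    scores = np.zeros(n - L + 1, dtype=np.int64)
    ok = np.ones(n - L + 1, dtype=bool)
    for j in range(L):
        w = codes[j:j + n - L + 1]
        ok &= w != 4
        scores += imat[np.clip(w, 0, 3), j]
    return scores, ok


def match_offsets(seq: str, pwm: PWM, threshold: int) -> list[int]:
    """Forward-strand start offsets of windows matching on either strand.

    A reverse-strand occurrence at forward offset i is found by scanning
    with the reverse-complemented matrix, so all offsets are reported in
    forward coordinates.  Windows containing N never match; a motif longer
    than the sequence has no offsets.
    """
    L = pwm.length
    codes = _encode(seq)
    if codes.shape[0] < L:
        return []
    imat = pwm.int_matrix()
    hit = np.zeros(codes.shape[0] - L + 1, dtype=bool)
    for mat in (imat, imat[::-1, ::-1]):
        scores, ok = _strand_scores(codes, mat)
        hit |= ok & (scores >= threshold)
    return [int(i) for i in np.where(hit)[0]]


def scan_sequence(seq: str, pwm: PWM, threshold: int | None = None,
                  match_p: float = 5e-5) -> bool:
    """True if any window on either strand reaches the threshold."""
    if threshold is None:
        threshold = pwm.score_threshold(match_p)
    return bool(match_offsets(seq, pwm, threshold))


def scan_motifs(lineage_sequences: dict[str, dict[str, str]], pwms: list[PWM],
                chain: LineageChain, match_p: float = 5e-5) -> pd.DataFrame:
    """Binary presence matrix over gre x motif x chain node.

    ``lineage_sequences`` maps gre_id -> {node name -> sequence}.  Returns a
    tidy frame with one row per (gre_id, motif_id) and one boolean column
    per chain node.
    """
    thresholds = {p.motif_id: p.score_threshold(match_p) for p in pwms}
    rows = []
    for gre_id in sorted(lineage_sequences):
        seqs = lineage_sequences[gre_id]
        for pwm in pwms:
            row: dict = {"gre_id": gre_id, "motif_id": pwm.motif_id}
            for node in chain.nodes:
                row[node] = scan_sequence(seqs[node], pwm,
                                          thresholds[pwm.motif_id])
            rows.append(row)
    return pd.DataFrame(rows)


def call_tfbs_events(presence: pd.DataFrame, chain: LineageChain) -> pd.DataFrame:
    """Single-transition gain/loss events from the presence matrix.

    Presence vectors are read deepest to shallowest; exactly one 0->1
    transition is a gain, exactly one 1->0 a loss, at the lineage of the
    transition.  Zero or multiple transitions yield no event.
    """
    nodes = list(chain.nodes)
    mat = presence[nodes].to_numpy(dtype=bool)
    diffs = mat[:, :-1] != mat[:, 1:]
    ntrans = diffs.sum(axis=1)
    single = ntrans == 1
    rows = []
    for i in np.where(single)[0]:
        j = int(np.argmax(diffs[i]))
        direction = "gain" if (not mat[i, j] and mat[i, j + 1]) else "loss"
        rows.append({"gre_id": presence.iloc[i]["gre_id"],
                     "motif_id": presence.iloc[i]["motif_id"],
                     "lineage": chain.lineages[j],
                     "direction": direction})
    return pd.DataFrame(rows, columns=["gre_id", "motif_id", "lineage",
                                       "direction"])


def gain_loss_ratios(events: pd.DataFrame, motif_ids: list[str],
                     lineages: tuple[str, ...]) -> pd.DataFrame:
    """Per motif x lineage gain/loss counts and ratio, plus global rows.

    The ratio is missing (NaN) when losses are 0; the counts are still
    reported.  Global per-lineage rows aggregate over all motifs under
    motif_id '__all__'.
    """
    idx = pd.MultiIndex.from_product([motif_ids, list(lineages)],
                                     names=["motif_id", "lineage"])
    out = pd.DataFrame(0, index=idx, columns=["gains", "losses"])
    if not events.empty:
        g = (events.groupby(["motif_id", "lineage", "direction"])
             .size().unstack("direction", fill_value=0))
        for col, name in (("gain", "gains"), ("loss", "losses")):
            if col in g.columns:
                out[name] = out[name].add(
                    g[col].reindex(out.index, fill_value=0), fill_value=0)
    out = out.reset_index()
    glob = (out.groupby("lineage", sort=False)[["gains", "losses"]]
            .sum().reset_index())
    glob.insert(0, "motif_id", "__all__")
    out = pd.concat([out, glob], ignore_index=True)
    out["ratio"] = np.where(out["losses"] > 0,
                            out["gains"] / out["losses"], np.nan)
    return out


def _chi2_gof(gains: float, losses: float, p_gain: float) -> float:
    """1-df goodness-of-fit p of a (gains, losses) split vs expected p_gain."""
    n = gains + losses
    e_g, e_l = n * p_gain, n * (1 - p_gain)
    if e_g <= 0 or e_l <= 0:
        return 1.0
    stat = (gains - e_g) ** 2 / e_g + (losses - e_l) ** 2 / e_l
    return float(stats.chi2.sf(stat, df=1))


def _chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square on a 2x2 table, 0.5 continuity if any zero cell."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(stats.chi2.sf(stat, df=1))


def test_expansion_depletion(summary: pd.DataFrame,
                             detection: pd.DataFrame | None = None,
                             min_detect: float = 0.25,
                             fdr_max: float = 0.01,
                             min_events: int = 5) -> pd.DataFrame:
    """Flag motif x lineage expansions/depletions by the double chi-square rule.

    Test (i) compares the motif-lineage gain/loss split to the global split
    over all motifs and lineages; test (ii) compares it to the same motif's
    pooled other lineages (2x2).  A flag requires FDR < ``fdr_max`` in both
    tests with the gain fraction on the same side of both references.
    Motifs whose TF is detected in < ``min_detect`` of cells in every cell
    type are dropped; motif-lineage cells with < ``min_events`` events are
    not tested.
    """
    cols = ["motif_id", "lineage", "gains", "losses", "ratio", "gain_frac",
            "global_gain_frac", "other_gain_frac", "p_vs_global",
            "p_vs_other", "tested", "fdr_vs_global", "fdr_vs_other", "flag"]
    per = summary[summary["motif_id"] != "__all__"].copy()
    if detection is not None:
        detected = set(detection.loc[
            detection.drop(columns=["motif_id"]).max(axis=1).ge(min_detect).to_numpy(),
            "motif_id"])
        per = per[per["motif_id"].isin(detected)]
    if per.empty:
        return pd.DataFrame(columns=cols)
    g_all = per["gains"].sum()
    l_all = per["losses"].sum()
    total = g_all + l_all
    p_global = g_all / total if total > 0 else np.nan

    motif_tot = per.groupby("motif_id")[["gains", "losses"]].sum()
    rows = []
    for r in per.itertuples(index=False):
        n = r.gains + r.losses
        og = motif_tot.loc[r.motif_id, "gains"] - r.gains
        ol = motif_tot.loc[r.motif_id, "losses"] - r.losses
        tested = n >= min_events and total > 0
        if tested:
            p1 = _chi2_gof(r.gains, r.losses, p_global)
            p2 = _chi2_2x2(r.gains, r.losses, og, ol)
        else:
            p1 = p2 = np.nan
        frac = r.gains / n if n > 0 else np.nan
        frac_other = og / (og + ol) if (og + ol) > 0 else np.nan
        rows.append({"motif_id": r.motif_id, "lineage": r.lineage,
                     "gains": r.gains, "losses": r.losses, "ratio": r.ratio,
                     "gain_frac": frac, "global_gain_frac": p_global,
                     "other_gain_frac": frac_other,
                     "p_vs_global": p1, "p_vs_other": p2, "tested": tested})
    out = pd.DataFrame(rows)
    for col in ("p_vs_global", "p_vs_other"):
        ok = out[col].notna()
        out[col.replace("p_", "fdr_")] = np.nan
        if ok.any():
            out.loc[ok, col.replace("p_", "fdr_")] = multipletests(
                out.loc[ok, col].to_numpy(), method="fdr_bh")[1]
    sig = (out["fdr_vs_global"] < fdr_max) & (out["fdr_vs_other"] < fdr_max)
    above = (out["gain_frac"] > out["global_gain_frac"]) & \
            (out["gain_frac"] > out["other_gain_frac"])
    below = (out["gain_frac"] < out["global_gain_frac"]) & \
            (out["gain_frac"] < out["other_gain_frac"])
    out["flag"] = "ns"
    out.loc[sig & above, "flag"] = "expanded"
    out.loc[sig & below, "flag"] = "depleted"
    return out


def aggregate_family(events: pd.DataFrame, family_map: dict[str, str]
                     ) -> pd.DataFrame:
    """Union member-motif events into family events.

    Deduplicates per (family, gre, lineage, direction); motifs without a
    family mapping pass through under their own id.
    """
    if events.empty:
        return events.assign(family=pd.Series(dtype=str))
    ev = events.copy()
    ev["family"] = ev["motif_id"].map(lambda m: family_map.get(m, m))
    agg = (ev.drop_duplicates(["family", "gre_id", "lineage", "direction"])
           [["gre_id", "family", "lineage", "direction"]]
           .reset_index(drop=True))
    return agg


def tfbs_celltype_enrichment(events: pd.DataFrame, markers: dict[str, set[str]],
                             universe: set[str], unit_col: str = "motif_id",
                             fdr_max: float = 0.05, or_min: float = 1.3,
                             alternative: str = "greater") -> pd.DataFrame:
    """Fisher enrichment of event-carrying GREs in cell-type marker GREs.

    One test per (motif-or-family, direction, cell type); enriched at
    FDR < ``fdr_max`` and odds ratio > ``or_min``.  The tail defaults to
    one-sided greater (cell-type panels); pass 'two-sided' for
    accessibility-class style tests.
    """
    from epilineage.enrichment import fisher_marker_enrichment

    rows = []
    if events.empty:
        return pd.DataFrame(columns=[unit_col, "direction", "cell_type",
                                     "odds_ratio", "p", "fdr", "label"])
    for (unit, direction), sub in events.groupby([unit_col, "direction"]):
        event_gres = set(sub["gre_id"]) & universe
        for ct, mset in sorted(markers.items()):
            if not event_gres:
                rows.append({unit_col: unit, "direction": direction,
                             "cell_type": ct, "odds_ratio": np.nan,
                             "p": 1.0})
                continue
            res = fisher_marker_enrichment(mset & universe, event_gres,
                                           universe, alternative)
            rows.append({unit_col: unit, "direction": direction,
                         "cell_type": ct, "odds_ratio": res["odds_ratio"],
                         "p": res["p"]})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["label"] = np.where((out["fdr"] < fdr_max) & (out["odds_ratio"] > or_min),
                            "enriched", "ns")
    return out
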