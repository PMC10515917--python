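"""Lineage-specific substitution calling along the ancestor-to-human chain.

A site yields a substitution record only when (i) every chain state is a
confidently called base (no 'N'), and (ii) exactly one state transition
exists between consecutive chain nodes.  Sites with two or more transitions
cover both the multiple-occurrence and the daughter-lineage-reversal
discard rules; both reduce to "not exactly one transition".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from epilineage.phylo import BRANCH_MY, LineageChain

_VALID = set("ACGT")


@dataclass(frozen=True)
class SubstitutionRecord:
    """One single-event substitution assigned to one lineage."""

    lineage: str
    ancestral_base: str
    derived_base: str
    chrom: str
    genome_pos: int  # 0-based
    gre_id: str
    position_in_gre: int  # 0-based offset

    def __post_init__(self) -> None:
        if self.ancestral_base == self.derived_base:
            raise ValueError("ancestral and derived base must differ")
        if self.ancestral_base not in _VALID or self.derived_base not in _VALID:
            raise ValueError("bases must be A, C, G or T")


def call_site(states, chain: LineageChain):
    """Call one site from its chain states, deepest to shallowest.

    Returns (lineage, ancestral_base, derived_base) for a retained
    single-event substitution, or None for no-change / low-confidence /
    multi-transition sites.
    """
    states = [str(s).upper() for s in states]
    if len(states) != chain.n_nodes:
        raise ValueError(
            f"expected {chain.n_nodes} states, got {len(states)}")
    if any(s not in _VALID for s in states):
        return None
    transitions = [i for i in range(len(states) - 1)
                   if states[i] != states[i + 1]]
    if len(transitions) != 1:
        return None
    i = transitions[0]
    return chain.lineages[i], states[i], states[i + 1]


def call_gre(lineage_sequences: dict[str, str], chain: LineageChain,
             chrom: str, gre_start: int, gre_id: str,
             ) -> list[SubstitutionRecord]:
    """Apply the site caller across one GRE's chain sequences.

    ``lineage_sequences`` maps chain node name to its called sequence; all
    must be equal length.  Records come back sorted by position.
    """
    seqs = [lineage_sequences[n] for n in chain.nodes]
    lens = {len(s) for s in seqs}
    if len(lens) != 1:
        raise ValueError(f"{gre_id}: chain sequences have unequal lengths")
    (length,) = lens

    # vectorized transition count, then per-site confirmation
    mat = np.array([np.frombuffer(s.upper().encode(), dtype=np.uint8)
                    for s in seqs])
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8)).all(axis=0)
    ntrans = (mat[:-1] != mat[1:]).sum(axis=0)
    candidates = np.where(valid & (ntrans == 1))[0]

    records = []
    for pos in candidates:
        hit = call_site([s[pos] for s in seqs], chain)
        if hit is None:  # pragma: no cover - vectorized filter is exact
            continue
        lineage, anc, der = hit
        records.append(SubstitutionRecord(
            lineage=lineage, ancestral_base=anc, derived_base=der,
            chrom=chrom, genome_pos=gre_start + int(pos), gre_id=gre_id,
            position_in_gre=int(pos)))
    return records


def records_to_frame(records: list[SubstitutionRecord]) -> pd.DataFrame:
    cols = ["lineage", "chrom", "pos0", "gre_id", "offset",
            "ancestral", "derived"]
    rows = [(r.lineage, r.chrom, r.genome_pos, r.gre_id, r.position_in_gre,
             r.ancestral_base, r.derived_base) for r in records]
    return pd.DataFrame(rows, columns=cols)


def count_table(records: list[SubstitutionRecord], gre_ids: list[str],
                lineages: tuple[str, ...]) -> pd.DataFrame:
    """Raw substitution counts, GRE x lineage, zero-filled over the universe."""
    if records:
        df = records_to_frame(records)
        pivot = pd.crosstab(df["gre_id"], df["lineage"])
    else:
        pivot = pd.DataFrame()
    counts = pivot.reindex(index=pd.Index(gre_ids, name="gre_id"),
                           columns=list(lineages), fill_value=0)
    return counts.fillna(0).astype(int)


def normalize_rates(counts: pd.DataFrame, gre_lengths: pd.Series,
                    branch_my: dict[str, float] | None = None) -> pd.DataFrame:
    """Tidy rate table: count / branch MY, then / GRE bp * 1000.

    Yields the normalized substitution rate per million years per kilobase
    used throughout classification.  Branch times default to the fixed
    lineage divergence estimates (Human 6, Hominin 2, AfricanGreatApe 8,
    GreatApe 4, Ape 13 MY).
    """
    if branch_my is None:
        branch_my = {lin: BRANCH_MY[lin] for lin in counts.columns}
    lengths = gre_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gre_lengths missing entries for some GREs")
    if (lengths <= 0).any():
        raise ValueError("GRE lengths must be positive")
    rows = []
    for lin in counts.columns:
        my = float(branch_my[lin])
        if my <= 0:
            raise ValueError(f"branch time for {lin} must be positive")
        per_my = counts[lin] / my
        rows.append(pd.DataFrame({
            "gre_id": counts.index,
            "lineage": lin,
            "raw_count": counts[lin].to_numpy(),
            "rate_per_my": per_my.to_numpy(),
            "rate_per_my_per_kb": (per_my / lengths * 1000.0).to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def gc_conversion_ratio(records: list[SubstitutionRecord]) -> float:
    """Fraction of substitutions converting A/T (weak) to G/C (strong).

    Elevated weak-to-strong ratios are the signature of GC-biased gene
    conversion.  Undefined (NaN) for an empty record set: scoring 0 would
    bias comparisons among sparse regions.
    """
    if not records:
        return float("nan")
    ws = sum(1 for r in records
             if r.ancestral_base in "AT" and r.derived_base in "GC")
    return ws / len(records)
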