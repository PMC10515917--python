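"""End-to-end orchestration of the analysis stages.

Thin glue over the stage modules so tests, the CLI and scripts can run
alignment -> reconstruction -> substitution calling -> classification with
a few calls.
"""

from __future__ import annotations

import pandas as pd

from epilineage import divergence as div
from epilineage.ancestral import GREAlignment, reconstruct_gre
from epilineage.phylo import LineageChain, PhyloTree
from epilineage.substitutions import (SubstitutionRecord, call_gre,
                                      count_table, normalize_rates)


def reconstruct_alignments(tree: PhyloTree,
                           alignments: dict[str, GREAlignment],
                           chain: LineageChain | None = None,
                           threshold: float = 0.75,
                           reuse_tree: bool = True,
                           ) -> dict[str, dict[str, str]]:
    """Chain-node sequences for every GRE; empty dict entries are skipped.

    ``reuse_tree`` keeps the guide-tree branch lengths (the default for
    bulk runs; individual short GREs carry little length signal).
    """
    chain = chain or LineageChain()
    out: dict[str, dict[str, str]] = {}
    for gre_id in sorted(alignments):
        seqs = reconstruct_gre(tree, alignments[gre_id], chain,
                               threshold=threshold, reuse_tree=reuse_tree)
        if seqs:
            out[gre_id] = seqs
    return out


def call_substitutions(reconstructed: dict[str, dict[str, str]],
                       bed: pd.DataFrame,
                       chain: LineageChain | None = None,
                       ) -> list[SubstitutionRecord]:
    chain = chain or LineageChain()
    coords = {r.gre_id: (r.chrom, int(r.start)) for r in bed.itertuples()}
    records: list[SubstitutionRecord] = []
    for gre_id in sorted(reconstructed):
        if gre_id not in coords:
            continue
        chrom, start = coords[gre_id]
        records.extend(call_gre(reconstructed[gre_id], chain, chrom, start,
                                gre_id))
    return records


def classify_dataset(records: list[SubstitutionRecord], bed: pd.DataFrame,
                     chain: LineageChain | None = None, seed: int = 0,
                     n_draw: int = 10_000, n_iter: int = 1000,
                     ) -> tuple[pd.DataFrame, dict[str, set[str]], set[str]]:
    """Counts -> resampling null -> divergence table, divergent sets,
    conserved set."""
    chain = chain or LineageChain()
    gre_ids = list(bed["gre_id"])
    lengths = pd.Series((bed["end"] - bed["start"]).to_numpy(),
                        index=bed["gre_id"].to_numpy())
    counts = count_table(records, gre_ids, chain.lineages)
    rates = normalize_rates(counts, lengths, chain.branch_my())
    null = div.build_resampling_null(counts, n_draw=n_draw, n_iter=n_iter,
                                     seed=seed)
    table = div.classify_divergent(counts, null)
    dsets = div.divergent_sets(table)
    conserved = div.classify_conserved(rates, dsets)
    return table, dsets, conserved
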