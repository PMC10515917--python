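"""Readers/writers for the standard formats the pipeline speaks.

Multi-FASTA per GRE (Biopython), 4-column BED, newick trees, JASPAR PFMs
(Bio.motifs), and TSV matrices/tables (pandas).  All coordinates are
0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.motifs import jaspar as bio_jaspar

from epilineage.ancestral import GREAlignment
from epilineage.phylo import PhyloTree
from epilineage.tfbs import PWM


# -- alignments -------------------------------------------------------------


def write_alignments(alignments: dict[str, GREAlignment],
                     out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for gre_id in sorted(alignments):
        aln = alignments[gre_id]
        records = [SeqRecord(Seq(seq), id=taxon, description="")
                   for taxon, seq in aln.seqs.items()]
        SeqIO.write(records, out_dir / f"{gre_id}.fa", "fasta")


def read_alignments(in_dir: str | Path) -> dict[str, GREAlignment]:
    in_dir = Path(in_dir)
    out = {}
    for path in sorted(in_dir.glob("*.fa")):
        gre_id = path.stem
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(path, "fasta")}
        out[gre_id] = GREAlignment(gre_id, seqs)
    return out


def write_lineage_fastas(reconstructed: dict[str, dict[str, str]],
                         out_dir: str | Path) -> None:
    """Per-GRE chain-node sequences as multi-FASTA."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for gre_id in sorted(reconstructed):
        seqs = reconstructed[gre_id]
        records = [SeqRecord(Seq(s), id=node, description="")
                   for node, s in seqs.items()]
        SeqIO.write(records, out_dir / f"{gre_id}.fa", "fasta")


def read_lineage_fastas(in_dir: str | Path) -> dict[str, dict[str, str]]:
    in_dir = Path(in_dir)
    out = {}
    for path in sorted(in_dir.glob("*.fa")):
        out[path.stem] = {rec.id: str(rec.seq).upper()
                          for rec in SeqIO.parse(path, "fasta")}
    return out


# -- bed / tree -------------------------------------------------------------


def write_bed(bed: pd.DataFrame, path: str | Path) -> None:
    bed[["chrom", "start", "end", bed.columns[3]]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, id_col: str = "gre_id") -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", id_col])
    return bed


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_tree(path: str | Path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


# -- motifs -----------------------------------------------------------------


def write_jaspar(pwms: list[PWM], path: str | Path, scale: int = 1000) -> None:
    """JASPAR text format; frequencies scaled to pseudo-counts."""
    records = []
    for p in pwms:
        counts = {b: (p.pfm[i] * scale).tolist() for i, b in enumerate("ACGT")}
        records.append(bio_jaspar.Motif(matrix_id=p.motif_id, name=p.name,
                                        counts=counts))
    Path(path).write_text(bio_jaspar.write(records, "jaspar"))


def read_jaspar(path: str | Path,
                family_map: dict[str, str] | None = None) -> list[PWM]:
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    pwms = []
    for m in records:
        pfm = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        motif_id = m.matrix_id or m.name
        pwms.append(PWM(motif_id=motif_id, name=m.name or motif_id, pfm=pfm,
                        family=(family_map or {}).get(motif_id, "")))
    return pwms


def write_family_map(family_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(family_map.items()),
                 columns=["motif_id", "family"]).to_csv(
        path, sep="\t", index=False)


def read_family_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["motif_id"], df["family"]))


# -- matrices / tables ------------------------------------------------------


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- full dataset -----------------------------------------------------------


def write_dataset(ds, out_dir: str | Path) -> None:
    """Write every pipeline input (and the truth tables) of a simulation."""
    from epilineage.substitutions import records_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_alignments(ds.alignments, out / "alignments")
    write_bed(ds.bed, out / "gres.bed")
    write_tree(ds.tree, out / "tree.nwk")
    write_jaspar(ds.pwms, out / "motifs.jaspar")
    write_family_map(ds.family_map, out / "families.tsv")
    write_table(ds.markers, out / "markers.tsv")
    write_table(ds.detection, out / "detection.tsv")
    write_matrix(ds.accessibility, out / "accessibility.tsv")
    write_matrix(ds.expression, out / "expression.tsv")
    write_table(ds.gene_coords, out / "genes.tsv")
    ds.gre_gc.rename_axis("gre_id").reset_index().to_csv(
        out / "gre_gc.tsv", sep="\t", index=False)

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    write_table(records_to_frame(ds.truth.substitution_truth),
                truth_dir / "substitutions.tsv")
    rows = [{"lineage": lin, "gre_id": g}
            for lin in sorted(ds.truth.divergent_truth)
            for g in sorted(ds.truth.divergent_truth[lin])]
    write_table(pd.DataFrame(rows, columns=["lineage", "gre_id"]),
                truth_dir / "divergent.tsv")
    write_table(pd.DataFrame(sorted(ds.truth.link_truth),
                             columns=["gre_id", "gene_id"]),
                truth_dir / "links.tsv")
    write_table(ds.truth.motif_event_truth, truth_dir / "motif_events.tsv")
    write_table(pd.DataFrame({"gene_id": sorted(ds.truth.rdg_truth)}),
                truth_dir / "rdgs.tsv")
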