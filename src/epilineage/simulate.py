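"""Synthetic data with planted ground truth for every pipeline stage.

The generator evolves GRE alignments on a catarrhine-like guide tree under
F81, forces substitutions onto named lineage branches (homoplasy-free by
masking those sites from background mutation), elevates substitution rates
on chosen lineages to plant divergent GREs, embeds or removes motif
consensus sequences at chain nodes to plant TFBS gains/losses, and draws
pseudobulk accessibility/expression matrices with planted GRE-gene
correlations.  Everything derives from a single seed, with independent
streams per stage so stages replay identically when rerun.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from epilineage.ancestral import F81Model, GREAlignment, decode_codes
from epilineage.phylo import BRANCH_MY, CHAIN_NODES, LINEAGES, LineageChain, PhyloTree
from epilineage.substitutions import SubstitutionRecord
from epilineage.tfbs import PWM, match_offsets, scan_sequence

_BASES = "ACGT"


class ConfigurationError(ValueError):
    pass


def _default_taxa() -> dict[str, list[str]]:
    return {
        "ape": ["Human", "Chimp", "Gorilla", "Orangutan", "Gibbon"],
        "owm": ["Macaque", "Baboon"],
        "nwm": ["Marmoset", "SquirrelMonkey"],
    }


def _default_markers() -> dict[str, float]:
    return {"Microglia": 0.10, "Neuron": 0.20, "Astrocyte": 0.15}


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the output.

    Rates are substitutions per site per million years.  The default
    background rate (3e-3 against the lower-bound branch times) gives a
    500 bp GRE roughly 35-40 substitutions across the 33-MY chain — the
    regime in which per-GRE lineage proportions are informative enough for
    the resampling classifier's cutoffs to separate planted rate shifts
    from count noise (see the methods note).
    ``planted_events`` are (gre_id, lineage, position, ancestral, derived);
    ``divergent_gre_spec`` maps lineage -> (n_planted, rate_multiplier);
    ``planted_links`` are (gre_id, gene_id, correlation_target);
    ``planted_motif_events`` are (gre_id, motif_id, lineage, 'gain'|'loss').
    """

    seed: int = 0
    n_gres: int = 200
    gre_length_range: tuple[int, int] = (300, 700)
    taxa: dict[str, list[str]] = field(default_factory=_default_taxa)
    branch_lengths_my: dict[str, float] = field(
        default_factory=lambda: dict(BRANCH_MY))
    background_sub_rate: float = 3e-3
    equilibrium_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_events: list[tuple[str, str, int, str, str]] = field(default_factory=list)
    divergent_gre_spec: dict[str, tuple[int, float]] = field(default_factory=dict)
    n_pseudobulk: int = 200
    n_genes: int = 100
    planted_links: list[tuple[str, str, float]] = field(default_factory=list)
    planted_motif_events: list[tuple[str, str, str, str]] = field(default_factory=list)
    n_motifs: int = 6
    motif_length_range: tuple[int, int] = (8, 12)
    consensus_freq: float = 0.85
    match_p: float = 5e-5
    marker_spec: dict[str, float] = field(default_factory=_default_markers)
    divergent_marker_celltype: str | None = None
    low_detection_tfs: list[str] = field(default_factory=list)
    gap_injection_rate: float = 0.0
    human_gap_columns: int = 0
    chrom: str = "chrS1"
    gre_gap_bp: int = 2000

    def __post_init__(self) -> None:
        if self.background_sub_rate < 0:
            raise ConfigurationError("background_sub_rate must be >= 0")
        if any(v < 0 for v in self.branch_lengths_my.values()):
            raise ConfigurationError("branch lengths must be >= 0")
        if len(self.taxa.get("ape", [])) != 5:
            raise ConfigurationError("need exactly 5 ape taxa "
                                     "(human, chimp, gorilla, orangutan, gibbon)")
        for grp in ("owm", "nwm"):
            if len(self.taxa.get(grp, [])) < 2:
                raise ConfigurationError(f"need at least 2 {grp} taxa")
        if self.taxa["ape"][0] != "Human":
            raise ConfigurationError("first ape taxon must be 'Human'")
        for _, lin, _, anc, der in self.planted_events:
            if lin not in LINEAGES:
                raise ConfigurationError(f"unknown lineage {lin!r}")
            if anc == der or anc not in _BASES or der not in _BASES:
                raise ConfigurationError("planted event bases invalid")
        for lin in self.divergent_gre_spec:
            if lin not in LINEAGES:
                raise ConfigurationError(f"unknown lineage {lin!r}")
        for _, _, lin, direction in self.planted_motif_events:
            if lin not in LINEAGES:
                raise ConfigurationError(f"unknown lineage {lin!r}")
            if direction not in ("gain", "loss"):
                raise ConfigurationError("motif event direction must be gain|loss")
        for _, _, r in self.planted_links:
            if not -1 < r < 1:
                raise ConfigurationError("correlation target must be in (-1, 1)")
        if not 0.8 <= self.consensus_freq <= 1:
            raise ConfigurationError(
                "consensus_freq must be in [0.8, 1]: per-column max frequency "
                ">= 0.8 keeps planted consensus matches robustly above the "
                "scan threshold (a uniform PFM is uninformative)")
        if self.motif_length_range[0] < 6:
            raise ConfigurationError("motif length must be >= 6")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent deterministic stream per pipeline stage."""
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode())])

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("gre_length_range", "motif_length_range",
                    "equilibrium_freqs"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("planted_events", "planted_links", "planted_motif_events"):
            if key in d:
                d[key] = [tuple(x) for x in d[key]]
        if "divergent_gre_spec" in d:
            d["divergent_gre_spec"] = {
                k: tuple(v) for k, v in d["divergent_gre_spec"].items()}
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTables:
    """Planted ground truth, keyed to emitted ids."""

    substitution_truth: list[SubstitutionRecord]
    divergent_truth: dict[str, set[str]]
    link_truth: set[tuple[str, str]]
    motif_event_truth: pd.DataFrame
    rdg_truth: set[str]

    def validate(self, gre_ids: set[str], gene_ids: set[str]) -> None:
        for r in self.substitution_truth:
            if r.gre_id not in gre_ids:
                raise ConfigurationError(f"truth references unknown {r.gre_id}")
        sets = list(self.divergent_truth.values())
        for i, a in enumerate(sets):
            if not a <= gre_ids:
                raise ConfigurationError("divergent truth references unknown GRE")
            for b in sets[i + 1:]:
                if a & b:
                    raise ConfigurationError("divergent truth sets overlap")
        for g, gene in self.link_truth:
            if g not in gre_ids or gene not in gene_ids:
                raise ConfigurationError("link truth references unknown id")


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus the truth to score against."""

    config: SimulationConfig
    tree: PhyloTree            # branch lengths in subs/site
    tree_my: PhyloTree         # same topology, lengths in MY
    chain: LineageChain
    alignments: dict[str, GREAlignment]
    bed: pd.DataFrame
    true_chain_seqs: dict[str, dict[str, str]]
    branch_change_counts: dict[str, int]
    total_sites: int
    pwms: list[PWM]
    family_map: dict[str, str]
    markers: pd.DataFrame
    detection: pd.DataFrame
    accessibility: pd.DataFrame
    expression: pd.DataFrame
    gene_coords: pd.DataFrame
    gre_gc: pd.Series
    truth: TruthTables

    @property
    def gre_ids(self) -> list[str]:
        return list(self.bed["gre_id"])

    @property
    def gre_lengths(self) -> pd.Series:
        return pd.Series((self.bed["end"] - self.bed["start"]).to_numpy(),
                         index=self.bed["gre_id"].to_numpy())


# ---------------------------------------------------------------------------
# guide tree
# ---------------------------------------------------------------------------


def build_guide_tree(config: SimulationConfig,
                     in_million_years: bool = False) -> PhyloTree:
    """Rooted binary guide tree: apes monophyletic, OWM sister, NWM outgroup.

    Chain branch lengths come from ``branch_lengths_my``; by default the
    tree is scaled to expected substitutions per site with the background
    rate (pass ``in_million_years`` to keep MY units).
    """
    my = config.branch_lengths_my
    ape = config.taxa["ape"]
    human_depth = my["Human"]
    hom_depth = human_depth + my["Hominin"]
    aga_depth = hom_depth + my["AfricanGreatApe"]
    ga_depth = aga_depth + my["GreatApe"]
    ape_depth = ga_depth + my["Ape"]
    cat_depth = ape_depth  # catarrhine split = ape-anc depth by chain def
    root_depth = cat_depth * 1.3 + 5.0

    names: list[str] = []
    parent: list[int] = []
    lengths: list[float] = []

    def add(name: str, par: int, length: float) -> int:
        names.append(name)
        parent.append(par)
        lengths.append(max(length, 0.0))
        return len(names) - 1

    root = add("Root", -1, 0.0)
    cat = add("Catarrhine", root, root_depth - cat_depth)
    ape_n = add("Ape", cat, my["Ape"])
    ga = add("GreatApe", ape_n, my["GreatApe"])
    aga = add("AfricanGreatApe", ga, my["AfricanGreatApe"])
    hom = add("Hominin", aga, my["Hominin"])
    add(ape[0], hom, my["Human"])            # human tip
    add(ape[1], hom, human_depth)            # chimp
    add(ape[2], aga, hom_depth)              # gorilla
    add(ape[3], ga, aga_depth)               # orangutan
    add(ape[4], ape_n, ga_depth)             # gibbon

    def add_ladder(tips: list[str], crown: float, par: int,
                   par_depth: float, label: str) -> None:
        """Pectinate clade with evenly spaced split depths under `crown`."""
        k = len(tips)
        depths = [crown * (k - 1 - j) / (k - 1) for j in range(k - 1)]
        node = add(f"{label}Anc", par, par_depth - crown)
        cur_depth = crown
        for j, tip in enumerate(tips[:-1]):
            add(tip, node, cur_depth)
            if j < k - 2:
                nxt = add(f"{label}N{j + 1}", node, cur_depth - depths[j + 1])
                node, cur_depth = nxt, depths[j + 1]
        add(tips[-1], node, cur_depth)

    owm_crown = min(15.0, cat_depth * 0.45)
    nwm_crown = min(15.0, root_depth * 0.35)
    add_ladder(config.taxa["owm"], owm_crown, cat, cat_depth, "OWM")
    add_ladder(config.taxa["nwm"], nwm_crown, root, root_depth, "NWM")

    tree = PhyloTree(names, np.array(parent), np.array(lengths, dtype=float))
    if in_million_years:
        return tree
    return tree.scaled(config.background_sub_rate)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _evolve_codes(parent_codes: np.ndarray, P: np.ndarray, mask: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """One branch of F81 evolution; masked sites are copied unchanged."""
    child = parent_codes.copy()
    free = ~mask
    if free.any():
        probs = P[parent_codes[free]]
        u = rng.random(free.sum())
        child[free] = (u[:, None] < probs.cumsum(axis=1)).argmax(axis=1)
    return child


def _nonmatching_window(length: int, pwm: PWM, threshold: int,
                        rng: np.random.Generator, tries: int = 200) -> str:
    for _ in range(tries):
        s = "".join(rng.choice(list(_BASES), size=length))
        if not scan_sequence(s, pwm, threshold):
            return s
    raise ConfigurationError(
        f"could not draw a non-matching window for {pwm.motif_id}")


def simulate_alignments(tree: PhyloTree, config: SimulationConfig,
                        pwms: list[PWM] | None = None,
                        divergent_truth: dict[str, set[str]] | None = None,
                        ):
    """Evolve every GRE; plant substitutions, rate shifts and motif events.

    Returns (alignments, bed, true_chain_seqs, substitution_truth,
    motif_event_truth, branch_change_counts, total_sites).

    Planted substitution sites and motif windows are masked from background
    mutation, so each planted event is the only transition at its site
    along the chain (homoplasy-free by construction).
    """
    rng = config.rng("alignments")
    model = F81Model(np.asarray(config.equilibrium_freqs))
    chain = LineageChain()
    chain.validate_on(tree)

    lo, hi = config.gre_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_gres)
    gre_ids = [f"gre_{i}" for i in range(config.n_gres)]
    starts = np.concatenate([[0], np.cumsum(lengths + config.gre_gap_bp)[:-1]])
    bed = pd.DataFrame({"chrom": config.chrom, "start": starts,
                        "end": starts + lengths, "gre_id": gre_ids})

    events_by_gre: dict[str, list[tuple[str, int, str, str]]] = {}
    for gre_id, lin, pos, anc, der in config.planted_events:
        events_by_gre.setdefault(gre_id, []).append((lin, pos, anc, der))
    motif_by_gre: dict[str, list[tuple[str, str, str]]] = {}
    for gre_id, motif_id, lin, direction in config.planted_motif_events:
        motif_by_gre.setdefault(gre_id, []).append((motif_id, lin, direction))
    pwm_index = {p.motif_id: p for p in (pwms or [])}
    thresholds = {p.motif_id: p.score_threshold(config.match_p)
                  for p in (pwms or [])}
    divergent_truth = divergent_truth or {}
    mult_by_gre: dict[str, tuple[str, float]] = {}
    for lin, gset in divergent_truth.items():
        mult = config.divergent_gre_spec.get(lin, (0, 1.0))[1]
        for g in gset:
            mult_by_gre[g] = (lin, mult)

    # lineage -> (shallower chain node index in tree)
    lin_child = {chain.lineages[i]: tree.index(chain.nodes[i + 1])
                 for i in range(len(chain.lineages))}
    subtree_sets = {lin: set(tree.subtree(idx))
                    for lin, idx in lin_child.items()}
    chain_idx = [tree.index(n) for n in chain.nodes]
    tip_idx = tree.tip_indices
    preorder = tree.preorder()

    alignments: dict[str, GREAlignment] = {}
    true_chain: dict[str, dict[str, str]] = {}
    sub_truth: list[SubstitutionRecord] = []
    motif_truth_rows: list[dict] = []
    branch_counts: dict[str, int] = {tree.names[v] or f"node{v}": 0
                                     for v in range(tree.n_nodes)
                                     if tree.parent[v] >= 0}
    total_sites = 0

    for g, gre_id in enumerate(gre_ids):
        L = int(lengths[g])
        total_sites += L
        mask = np.zeros(L, dtype=bool)

        planted = events_by_gre.get(gre_id, [])
        for lin, pos, anc, der in planted:
            if not 0 <= pos < L:
                raise ConfigurationError(
                    f"{gre_id}: planted position {pos} outside length {L}")
            mask[pos] = True

        motif_plants = []
        used: list[tuple[int, int]] = [(p, p + 1) for _, p, _, _ in planted]
        for motif_id, lin, direction in motif_by_gre.get(gre_id, []):
            pwm = pwm_index.get(motif_id)
            if pwm is None:
                raise ConfigurationError(f"unknown motif {motif_id!r}")
            if pwm.length > L:
                raise ConfigurationError(
                    f"motif {motif_id} longer than {gre_id}")
            for _ in range(200):
                off = int(rng.integers(0, L - pwm.length + 1))
                window = (off, off + pwm.length)
                if all(window[1] <= a or window[0] >= b for a, b in used):
                    break
            else:
                raise ConfigurationError(f"{gre_id}: no room for motif plant")
            used.append(window)
            mask[window[0]:window[1]] = True
            motif_plants.append((pwm, lin, direction, off))

        # branch lengths for this GRE (divergent multiplier on one lineage)
        lens = tree.lengths.copy()
        if gre_id in mult_by_gre:
            lin, mult = mult_by_gre[gre_id]
            lens[lin_child[lin]] *= mult

        codes = np.empty((tree.n_nodes, L), dtype=np.int8)
        root = tree.root
        codes[root] = rng.choice(4, size=L, p=model.pi)
        pmats = {}
        for v in preorder:
            if v == root:
                continue
            t = float(lens[v])
            if t not in pmats:
                pmats[t] = model.transition_matrix(t)
            codes[v] = _evolve_codes(codes[tree.parent[v]], pmats[t], mask, rng)

        # force planted substitutions
        for lin, pos, anc, der in planted:
            inside = subtree_sets[lin]
            anc_c, der_c = _BASES.index(anc), _BASES.index(der)
            for v in range(tree.n_nodes):
                codes[v, pos] = der_c if v in inside else anc_c
            sub_truth.append(SubstitutionRecord(
                lineage=lin, ancestral_base=anc, derived_base=der,
                chrom=config.chrom, genome_pos=int(starts[g]) + pos,
                gre_id=gre_id, position_in_gre=pos))

        # force planted motif events
        for pwm, lin, direction, off in motif_plants:
            threshold = thresholds[pwm.motif_id]
            cons = pwm.consensus
            if not scan_sequence(cons, pwm, threshold):
                raise ConfigurationError(
                    f"consensus of {pwm.motif_id} does not reach threshold; "
                    "PFM not informative enough")
            other = _nonmatching_window(pwm.length, pwm, threshold, rng)
            inside_seq, outside_seq = ((cons, other) if direction == "gain"
                                       else (other, cons))
            inside = subtree_sets[lin]
            ic = np.array([_BASES.index(b) for b in inside_seq], dtype=np.int8)
            oc = np.array([_BASES.index(b) for b in outside_seq], dtype=np.int8)
            for v in range(tree.n_nodes):
                codes[v, off:off + pwm.length] = ic if v in inside else oc
            motif_truth_rows.append({
                "gre_id": gre_id, "motif_id": pwm.motif_id, "lineage": lin,
                "direction": direction, "offset": off})

        # scrub accidental background matches for planted (gre, motif) pairs
        for pwm, lin, direction, off in motif_plants:
            _scrub_extra_matches(codes, chain_idx, pwm,
                                 thresholds[pwm.motif_id],
                                 (off, off + pwm.length), used, rng)

        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                nm = tree.names[v] or f"node{v}"
                branch_counts[nm] += int(
                    (codes[v] != codes[tree.parent[v]]).sum())

        tip_seqs = {tree.names[v]: decode_codes(codes[v]) for v in tip_idx}
        if config.gap_injection_rate > 0:
            tip_seqs = _inject_gaps(tip_seqs, config.gap_injection_rate, rng)
        if config.human_gap_columns > 0:
            tip_seqs = _insert_human_gap_columns(
                tip_seqs, config.human_gap_columns, rng)
        alignments[gre_id] = GREAlignment(gre_id, tip_seqs)
        true_chain[gre_id] = {tree.names[i]: decode_codes(codes[i])
                              for i in chain_idx}

    motif_truth = pd.DataFrame(
        motif_truth_rows,
        columns=["gre_id", "motif_id", "lineage", "direction", "offset"])
    return (alignments, bed, true_chain, sub_truth, motif_truth,
            branch_counts, total_sites)


def _scrub_extra_matches(codes: np.ndarray, chain_idx: list[int], pwm: PWM,
                         threshold: int, window: tuple[int, int],
                         used: list[tuple[int, int]],
                         rng: np.random.Generator, max_rounds: int = 5) -> None:
    """Remove coincidental matches of a planted motif outside its window.

    Any stray match in a chain-node sequence would add a second presence
    transition and void the planted event; the offending stretch is
    overwritten with one shared non-matching sequence in every tree node
    (a constant column block: contributes no transitions anywhere).
    """
    L = codes.shape[1]
    m = pwm.length
    for _ in range(max_rounds):
        dirty = False
        for v in chain_idx:
            seq = decode_codes(codes[v])
            for start in match_offsets(seq, pwm, threshold):
                if window[0] - m < start < window[1]:
                    continue
                a, b = max(0, start), min(L, start + m)
                if any(not (b <= s or a >= e) for s, e in used):
                    continue
                repl = _nonmatching_window(b - a, pwm, threshold, rng)
                rc = np.array([_BASES.index(x) for x in repl], dtype=np.int8)
                codes[:, a:b] = rc[None, :]
                dirty = True
        if not dirty:
            return


def _inject_gaps(tip_seqs: dict[str, str], rate: float,
                 rng: np.random.Generator) -> dict[str, str]:
    """Replace random short runs in non-human taxa with gaps (missing data)."""
    out = {}
    for taxon, seq in tip_seqs.items():
        if taxon == "Human":
            out[taxon] = seq
            continue
        chars = list(seq)
        n_runs = rng.poisson(rate * len(seq) / 5.0)
        for _ in range(n_runs):
            start = int(rng.integers(0, max(1, len(chars) - 5)))
            run = int(rng.integers(1, 6))
            for i in range(start, min(len(chars), start + run)):
                chars[i] = "-"
        out[taxon] = "".join(chars)
    return out


def _insert_human_gap_columns(tip_seqs: dict[str, str], n_cols: int,
                              rng: np.random.Generator) -> dict[str, str]:
    """Insert columns gapped in human (human-specific deletions) so the
    gap-stripping path is exercised; stripping restores the originals."""
    length = len(tip_seqs["Human"])
    positions = sorted(rng.integers(0, length + 1, size=n_cols), reverse=True)
    out = {t: list(s) for t, s in tip_seqs.items()}
    for pos in positions:
        for taxon in out:
            filler = "-" if taxon == "Human" else _BASES[int(rng.integers(4))]
            out[taxon].insert(pos, filler)
    return {t: "".join(s) for t, s in out.items()}


# ---------------------------------------------------------------------------
# multiome
# ---------------------------------------------------------------------------


def simulate_multiome(config: SimulationConfig, bed: pd.DataFrame):
    """Pseudobulk accessibility/expression with planted correlations.

    Planted links share a latent factor with loading sqrt(|r|) on both the
    GRE accessibility row and the gene expression row (signed for negative
    targets), so the expected Pearson correlation equals the target.
    Every gene is anchored within 300 kb of some GRE so null pairs are
    tested too.  Returns (accessibility, expression, gene_coords).
    """
    if config.n_pseudobulk < 30:
        raise ConfigurationError("n_pseudobulk must be >= 30")
    rng = config.rng("multiome")
    n_units = config.n_pseudobulk
    gre_ids = list(bed["gre_id"])
    gene_ids = [f"gene_{i}" for i in range(config.n_genes)]
    units = [f"pb_{i}" for i in range(n_units)]

    acc = rng.standard_normal((len(gre_ids), n_units))
    expr = rng.standard_normal((config.n_genes, n_units))

    gre_pos = {r.gre_id: (r.start + r.end) // 2 for r in bed.itertuples()}
    gene_anchor: dict[str, str] = {}
    link_truth: set[tuple[str, str]] = set()
    seen_gres: set[str] = set()
    links_by_gene: dict[str, list[tuple[str, float]]] = {}
    for gre_id, gene_id, r in config.planted_links:
        if gre_id not in gre_pos or gene_id not in gene_ids:
            raise ConfigurationError(f"planted link references unknown id "
                                     f"({gre_id}, {gene_id})")
        if gre_id in seen_gres:
            raise ConfigurationError("a GRE may carry only one planted link")
        seen_gres.add(gre_id)
        links_by_gene.setdefault(gene_id, []).append((gre_id, r))

    # a gene's expression row is a pure latent factor; each linked GRE loads
    # r on it, so corr(GRE accessibility, gene expression) targets r exactly
    for gene_id in sorted(links_by_gene):
        f_lat = rng.standard_normal(n_units)
        ei = gene_ids.index(gene_id)
        expr[ei] = f_lat
        for gre_id, r in links_by_gene[gene_id]:
            gi = gre_ids.index(gre_id)
            acc[gi] = (r * f_lat
                       + np.sqrt(1 - r * r) * rng.standard_normal(n_units))
            gene_anchor.setdefault(gene_id, gre_id)
            link_truth.add((gre_id, gene_id))

    rows = []
    for gene_id in gene_ids:
        if gene_id in links_by_gene:
            # sit the gene amid its linked GREs so all pass the distance gate
            center = int(np.median([gre_pos[g] for g, _ in
                                    links_by_gene[gene_id]]))
            offset = int(rng.integers(-50_000, 50_001))
        else:
            center = gre_pos[gre_ids[int(rng.integers(len(gre_ids)))]]
            offset = int(rng.integers(-200_000, 200_001))
        start = max(0, center + offset)
        rows.append({"chrom": config.chrom, "start": start,
                     "end": start + 10_000, "gene_id": gene_id})
    gene_coords = pd.DataFrame(rows)

    acc_df = pd.DataFrame(acc, index=gre_ids, columns=units)
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=units)
    return acc_df, expr_df, gene_coords, link_truth


# ---------------------------------------------------------------------------
# motifs, markers, detection
# ---------------------------------------------------------------------------


def generate_motifs(config: SimulationConfig) -> tuple[list[PWM], dict[str, str]]:
    """Informative PFMs (consensus frequency >= 0.8) plus a family map."""
    rng = config.rng("motifs")
    lo, hi = config.motif_length_range
    if config.consensus_freq < 0.8:
        raise ConfigurationError(
            "consensus_freq < 0.8 yields uninformative PFMs")
    pwms = []
    family_map: dict[str, str] = {}
    for i in range(config.n_motifs):
        L = int(rng.integers(lo, hi + 1))
        cons = rng.integers(0, 4, size=L)
        pfm = np.full((4, L), (1 - config.consensus_freq) / 3)
        pfm[cons, np.arange(L)] = config.consensus_freq
        motif_id = f"MOTIF_{i}"
        pwms.append(PWM(motif_id=motif_id, name=f"TF{i}", pfm=pfm,
                        family=f"FAM_{i // 2}"))
        family_map[motif_id] = f"FAM_{i // 2}"
    return pwms, family_map


def generate_markers(config: SimulationConfig, gre_ids: list[str],
                     divergent_truth: dict[str, set[str]]) -> pd.DataFrame:
    """Cell-type marker GRE table: exactly floor(fraction * n_gres) per type.

    With ``divergent_marker_celltype`` set, planted divergent GREs are
    preferentially assigned to that cell type's markers (planted divergence
    enrichment); marker sets are disjoint across cell types.
    """
    rng = config.rng("markers")
    pool = list(gre_ids)
    rows = []
    target_ct = config.divergent_marker_celltype
    div_all = sorted(set().union(*divergent_truth.values())) \
        if divergent_truth else []
    for ct in sorted(config.marker_spec):
        k = int(np.floor(config.marker_spec[ct] * len(gre_ids)))
        chosen: list[str] = []
        if ct == target_ct and div_all:
            take = [g for g in div_all if g in pool][:k]
            chosen.extend(take)
        remaining = [g for g in pool if g not in chosen]
        extra = rng.choice(len(remaining), size=k - len(chosen),
                           replace=False)
        chosen.extend(remaining[int(i)] for i in sorted(extra))
        for g in chosen:
            rows.append({"cell_type": ct, "gre_id": g})
            pool.remove(g)
    return pd.DataFrame(rows, columns=["cell_type", "gre_id"])


def generate_detection(config: SimulationConfig,
                       pwms: list[PWM]) -> pd.DataFrame:
    """Per-TF, per-cell-type detection fractions.

    TFs in ``low_detection_tfs`` fall below the 25% filter everywhere.
    """
    rng = config.rng("detection")
    cts = sorted(config.marker_spec)
    rows = []
    for p in pwms:
        if p.motif_id in config.low_detection_tfs:
            vals = rng.uniform(0.01, 0.2, size=len(cts))
        else:
            vals = rng.uniform(0.3, 0.9, size=len(cts))
        rows.append({"motif_id": p.motif_id,
                     **{ct: v for ct, v in zip(cts, vals)}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full synthetic study: one call, one seed, all truth."""
    tree_my = build_guide_tree(config, in_million_years=True)
    tree = tree_my.scaled(config.background_sub_rate)
    chain = LineageChain()

    pwms, family_map = generate_motifs(config)

    # choose divergent GREs (disjoint across lineages, deterministic)
    rng = config.rng("divergent")
    gre_ids = [f"gre_{i}" for i in range(config.n_gres)]
    reserved = {g for g, *_ in config.planted_events}
    reserved |= {g for g, *_ in config.planted_motif_events}
    available = [g for g in gre_ids if g not in reserved]
    divergent_truth: dict[str, set[str]] = {}
    for lin in sorted(config.divergent_gre_spec):
        n_planted, _ = config.divergent_gre_spec[lin]
        if n_planted > len(available):
            raise ConfigurationError("not enough GREs to plant divergence")
        idx = rng.choice(len(available), size=n_planted, replace=False)
        chosen = {available[int(i)] for i in idx}
        divergent_truth[lin] = chosen
        available = [g for g in available if g not in chosen]

    (alignments, bed, true_chain, sub_truth, motif_truth,
     branch_counts, total_sites) = simulate_alignments(
        tree, config, pwms=pwms, divergent_truth=divergent_truth)

    markers = generate_markers(config, gre_ids, divergent_truth)
    detection = generate_detection(config, pwms)
    acc, expr, gene_coords, link_truth = simulate_multiome(config, bed)

    gc = {}
    for gre_id, aln in alignments.items():
        human = aln.seqs["Human"].replace("-", "")
        gc[gre_id] = ((human.count("G") + human.count("C")) / len(human)
                      if human else np.nan)
    gre_gc = pd.Series(gc, name="gc")

    # planted RDGs: genes whose planted links hit enough divergent GREs
    div_all: dict[str, set[str]] = divergent_truth
    rdg_truth: set[str] = set()
    links_by_gene: dict[str, set[str]] = {}
    for g, gene in link_truth:
        links_by_gene.setdefault(gene, set()).add(g)
    for lin, dset in div_all.items():
        for gene, gres in links_by_gene.items():
            if len(gres & dset) >= 2 and len(gres) >= 5:
                rdg_truth.add(gene)

    truth = TruthTables(sub_truth, divergent_truth, link_truth,
                        motif_truth, rdg_truth)
    truth.validate(set(gre_ids), set(expr.index))

    return SimulatedDataset(
        config=config, tree=tree, tree_my=tree_my, chain=chain,
        alignments=alignments, bed=bed, true_chain_seqs=true_chain,
        branch_change_counts=branch_counts, total_sites=total_sites,
        pwms=pwms, family_map=family_map, markers=markers,
        detection=detection, accessibility=acc, expression=expr,
        gene_coords=gene_coords, gre_gc=gre_gc, truth=truth)
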