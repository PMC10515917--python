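"""Maximum-likelihood ancestral sequence reconstruction under F81.

Per GRE: strip human gap columns from the multi-species alignment, fit the
F81 model (empirical base frequencies, branch lengths by cyclic univariate
maximization of the pruning log-likelihood), compute marginal ancestral
posteriors with the up-down pruning algorithm, and call ancestral states
with a confidence threshold (posterior > 0.75, else 'N').

Non-human gaps and N are treated as missing data (all-ones tip partials);
the human sequence itself is never reconstructed, it is read off the
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from epilineage.phylo import LineageChain, PhyloTree

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
MISSING = 4  # N or gap


class AlignmentError(ValueError):
    pass


@dataclass
class GREAlignment:
    """One GRE's taxon -> sequence map over {A,C,G,T,N,-}."""

    gre_id: str
    seqs: dict[str, str]

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.seqs.values()}
        if len(lens) > 1:
            raise AlignmentError(f"{self.gre_id}: unequal sequence lengths")

    @property
    def length(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.seqs)


def strip_human_gaps(aln: GREAlignment, human: str = "Human") -> GREAlignment:
    """Drop every column where the human record carries a gap.

    This removes human-specific deletions so that the remaining columns map
    one-to-one onto human genome positions.  Gaps in non-human taxa are
    retained (they become missing data downstream).
    """
    if human not in aln.seqs:
        raise AlignmentError(f"{aln.gre_id}: human record {human!r} missing")
    keep = [i for i, c in enumerate(aln.seqs[human]) if c != "-"]
    return GREAlignment(
        aln.gre_id,
        {t: "".join(s[i] for i in keep) for t, s in aln.seqs.items()},
    )


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N, gap) -> 4."""
    out = np.full(len(seq), MISSING, dtype=np.int8)
    for b, c in _CODE.items():
        out[np.frombuffer(seq.upper().encode(), dtype=np.uint8)
            == ord(b)] = c
    return out


def decode_codes(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.int8)].tobytes().decode()


@dataclass
class F81Model:
    """Felsenstein 1981 model: equal exchangeabilities, free base frequencies.

    beta = 1 / (1 - sum pi_i^2) normalizes the rate matrix so branch
    lengths are expected substitutions per site.
    """

    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (4,) or np.any(self.pi <= 0) or np.any(self.pi >= 1):
            raise ValueError("frequencies must be four values in (0, 1)")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    @property
    def beta(self) -> float:
        return 1.0 / (1.0 - float(self.pi @ self.pi))

    def transition_matrix(self, t: float) -> np.ndarray:
        """P[i, j] = P(j at branch end | i at branch start, length t)."""
        if t < 0:
            raise ValueError("negative branch length")
        e = np.exp(-self.beta * t)
        return e * np.eye(4) + (1.0 - e) * self.pi[None, :]


def f81_transition_prob(model: F81Model, from_base: str, to_base: str,
                        branch_length: float) -> float:
    """P(to_base | from_base, t) under F81."""
    return float(
        model.transition_matrix(branch_length)[_CODE[from_base], _CODE[to_base]]
    )


# ---------------------------------------------------------------------------
# pruning machinery
# ---------------------------------------------------------------------------


def _tip_codes(tree: PhyloTree, aln: GREAlignment) -> np.ndarray:
    """(n_nodes, n_sites) int8 codes; internal-node rows are MISSING."""
    codes = np.full((tree.n_nodes, aln.length), MISSING, dtype=np.int8)
    for i in tree.tip_indices:
        name = tree.names[i]
        if name not in aln.seqs:
            raise AlignmentError(f"{aln.gre_id}: taxon {name!r} not in alignment")
        codes[i] = encode_sequence(aln.seqs[name])
    return codes


def _compress(codes: np.ndarray, tips: list[int]):
    """Unique site patterns over tip rows: (patterns, inverse, counts)."""
    cols = codes[tips].T  # (n_sites, n_tips)
    patterns, inverse, counts = np.unique(
        cols, axis=0, return_inverse=True, return_counts=True)
    return patterns.T, inverse, counts  # (n_tips, n_patterns)


def _tip_partial(codes_row: np.ndarray) -> np.ndarray:
    """(n_patterns, 4) partial likelihoods; missing -> all ones."""
    n = codes_row.shape[0]
    part = np.zeros((n, 4))
    obs = codes_row != MISSING
    part[obs, codes_row[obs].astype(int)] = 1.0
    part[~obs] = 1.0
    return part


def _down_pass(tree: PhyloTree, model: F81Model, tip_part: dict[int, np.ndarray],
               n_patterns: int, lengths: np.ndarray | None = None):
    """Felsenstein pruning.

    Returns (partials, messages, logscale) where messages[v] is the message
    from node v to its parent and logscale is the per-pattern accumulated
    log scaling factor.
    """
    if lengths is None:
        lengths = tree.lengths
    partials: dict[int, np.ndarray] = {}
    messages: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_patterns)
    for v in tree.postorder():
        if tree.is_tip(v):
            part = tip_part[v]
        else:
            part = np.ones((n_patterns, 4))
            for c in tree.children[v]:
                part = part * messages[c]
            scale = part.max(axis=1)
            scale[scale == 0] = 1.0
            part = part / scale[:, None]
            logscale += np.log(scale)
        partials[v] = part
        if tree.parent[v] >= 0:
            P = model.transition_matrix(float(lengths[v]))
            messages[v] = part @ P.T
    return partials, messages, logscale


def site_log_likelihoods(tree: PhyloTree, model: F81Model,
                         aln: GREAlignment) -> np.ndarray:
    """Per-site log-likelihood of the alignment under (tree, model)."""
    codes = _tip_codes(tree, aln)
    tips = tree.tip_indices
    patterns, inverse, _ = _compress(codes, tips)
    tip_part = {t: _tip_partial(patterns[k]) for k, t in enumerate(tips)}
    partials, _, logscale = _down_pass(tree, model, tip_part, patterns.shape[1])
    site_l = partials[tree.root] @ model.pi
    return (np.log(site_l) + logscale)[inverse]


def log_likelihood(tree: PhyloTree, model: F81Model, aln: GREAlignment) -> float:
    return float(site_log_likelihoods(tree, model, aln).sum())


@dataclass
class AncestralPosterior:
    """Marginal state posteriors per internal node and site.

    ``probs[name]`` is an (n_sites, 4) array over A,C,G,T summing to 1 per
    site.  ``flagged`` marks sites where every tip was missing (the
    posterior there is the uninformative stationary distribution).
    """

    gre_id: str
    probs: dict[str, np.ndarray]
    flagged: np.ndarray


def marginal_ancestral_posteriors(tree: PhyloTree, model: F81Model,
                                  aln: GREAlignment) -> AncestralPosterior:
    """Marginal ancestral posteriors by the up-down pruning algorithm.

    Down pass computes subtree partials; the up pass propagates outside
    probabilities from the root, so posterior(v) ~ outside(v) * partial(v)
    marginalizes over all other internal nodes exactly.
    """
    codes = _tip_codes(tree, aln)
    tips = tree.tip_indices
    patterns, inverse, _ = _compress(codes, tips)
    npat = patterns.shape[1]
    tip_part = {t: _tip_partial(patterns[k]) for k, t in enumerate(tips)}
    partials, messages, _ = _down_pass(tree, model, tip_part, npat)

    outside: dict[int, np.ndarray] = {tree.root: np.tile(model.pi, (npat, 1))}
    for u in tree.preorder():
        for v in tree.children[u]:
            prod = outside[u].copy()
            for s in tree.children[u]:
                if s != v:
                    prod = prod * messages[s]
            P = model.transition_matrix(float(tree.lengths[v]))
            out = prod @ P
            scale = out.max(axis=1)
            scale[scale == 0] = 1.0
            outside[v] = out / scale[:, None]

    all_missing = np.all(patterns == MISSING, axis=0)
    probs: dict[str, np.ndarray] = {}
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            continue
        post = outside[v] * partials[v]
        tot = post.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        post = post / tot
        name = tree.names[v] or f"node{v}"
        probs[name] = post[inverse]
    return AncestralPosterior(aln.gre_id, probs, all_missing[inverse])


def fit_f81(tree: PhyloTree, aln: GREAlignment,
            max_cycles: int = 20, tol: float = 1e-6,
            max_branch: float = 10.0) -> tuple[PhyloTree, F81Model]:
    """Fit F81 to one alignment: empirical frequencies, ML branch lengths.

    Frequencies are fixed to the empirical base composition first; branch
    lengths are then optimized one at a time (bounded Brent) and cycled
    until the log-likelihood gain drops below `tol` or `max_cycles` is hit.
    Invariant alignments carry no length signal, so the input lengths are
    returned unchanged.
    """
    if not aln.seqs or aln.length == 0:
        raise AlignmentError(f"{aln.gre_id}: empty alignment")
    codes = _tip_codes(tree, aln)
    tips = tree.tip_indices
    obs = codes[tips][codes[tips] != MISSING]
    counts = np.bincount(obs, minlength=4).astype(float) + 0.5
    model = F81Model(counts / counts.sum())

    tip_codes = codes[tips]
    site_obs = tip_codes != MISSING
    variable = np.zeros(aln.length, dtype=bool)
    for j in range(aln.length):
        vals = tip_codes[site_obs[:, j], j]
        variable[j] = vals.size > 0 and np.unique(vals).size > 1
    if not variable.any():
        return tree, model

    patterns, _, pat_counts = _compress(codes, tips)
    npat = patterns.shape[1]
    tip_part = {t: _tip_partial(patterns[k]) for k, t in enumerate(tips)}

    lengths = tree.lengths.copy()
    free = [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]

    def total_ll(lens: np.ndarray) -> float:
        partials, _, logscale = _down_pass(tree, model, tip_part, npat, lens)
        site_l = partials[tree.root] @ model.pi
        return float(((np.log(site_l) + logscale) * pat_counts).sum())

    prev = total_ll(lengths)
    for _ in range(max_cycles):
        for v in free:
            def neg(t: float, _v=v) -> float:
                lens = lengths.copy()
                lens[_v] = t
                return -total_ll(lens)

            res = minimize_scalar(neg, bounds=(0.0, max_branch),
                                  method="bounded",
                                  options={"xatol": 1e-8})
            if -res.fun >= total_ll(lengths):
                lengths[v] = float(res.x)
        cur = total_ll(lengths)
        if cur - prev < tol:
            break
        prev = cur
    return tree.with_lengths(lengths), model


def call_ancestral_sequences(post: AncestralPosterior, chain: LineageChain,
                             aln: GREAlignment,
                             threshold: float = 0.75) -> dict[str, str]:
    """Call chain-node sequences from posteriors with a confidence cutoff.

    Per ancestral node and site the argmax base is emitted only when its
    posterior strictly exceeds `threshold`; otherwise 'N'.  The human
    sequence is copied verbatim from the alignment.
    """
    out: dict[str, str] = {}
    for name in chain.nodes:
        if name == "Human":
            out[name] = aln.seqs["Human"].upper().replace("-", "N")
            continue
        if name not in post.probs:
            raise AlignmentError(f"posterior missing for chain node {name!r}")
        p = post.probs[name]
        best = p.argmax(axis=1)
        conf = p[np.arange(p.shape[0]), best] > threshold
        codes = np.where(conf, best, MISSING).astype(np.int8)
        out[name] = decode_codes(codes)
    return out


def reconstruct_gre(tree: PhyloTree, aln: GREAlignment, chain: LineageChain,
                    threshold: float = 0.75, reuse_tree: bool = False,
                    ) -> dict[str, str]:
    """Full per-GRE reconstruction: strip gaps, (optionally) fit, call.

    With ``reuse_tree`` the supplied branch lengths are kept (sensible for
    short or invariant GREs); frequencies are still set empirically.
    """
    stripped = strip_human_gaps(aln)
    if stripped.length == 0:
        return {}
    if reuse_tree:
        tips = tree.tip_indices
        codes = _tip_codes(tree, stripped)
        obs = codes[tips][codes[tips] != MISSING]
        counts = np.bincount(obs, minlength=4).astype(float) + 0.5
        fitted, model = tree, F81Model(counts / counts.sum())
    else:
        fitted, model = fit_f81(tree, stripped)
    post = marginal_ancestral_posteriors(fitted, model, stripped)
    return call_ancestral_sequences(post, chain, stripped, threshold)
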