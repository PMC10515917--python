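"""PWM scanning, threshold DP, gain/loss events, expansion tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epilineage.phylo import LINEAGES, LineageChain
from epilineage.tfbs import (PWM, aggregate_family, call_tfbs_events,
                             gain_loss_ratios, match_offsets, scan_motifs,
                             scan_sequence, tfbs_celltype_enrichment)
from epilineage.tfbs import test_expansion_depletion as expansion_depletion

CHAIN = LineageChain()


def _informative_pwm(consensus, motif_id="M", freq=0.9):
    L = len(consensus)
    pfm = np.full((4, L), (1 - freq) / 3)
    for j, b in enumerate(consensus):
        pfm["ACGT".index(b), j] = freq
    return PWM(motif_id=motif_id, name=motif_id, pfm=pfm)


# -- threshold DP vs exhaustive enumeration --------------------------------


def oracle_threshold(pwm, match_p):
    """Enumerate all 4^L windows; find the smallest integer score whose
    tail probability under the background is <= match_p."""
    imat = pwm.int_matrix()
    bg = pwm.background
    L = pwm.length
    scores = {}
    for window in itertools.product(range(4), repeat=L):
        s = int(sum(imat[b, j] for j, b in enumerate(window)))
        p = float(np.prod([bg[b] for b in window]))
        scores[s] = scores.get(s, 0.0) + p
    keys = sorted(scores, reverse=True)
    tail = 0.0
    threshold = keys[0] + 1
    for s in keys:
        tail += scores[s]
        if tail <= match_p:
            threshold = s
        else:
            break
    return threshold


@pytest.mark.parametrize("consensus,match_p", [
    ("ACGTAC", 5e-5),
    ("TTGACA", 1e-3),
    ("ACGTACGT", 5e-5),
    ("GATTACAA", 1e-4),
])
def test_threshold_dp_matches_enumeration(consensus, match_p):
    pwm = _informative_pwm(consensus)
    assert pwm.score_threshold(match_p) == oracle_threshold(pwm, match_p)


def test_threshold_with_nonuniform_background():
    pwm = PWM(motif_id="M", name="M",
              pfm=_informative_pwm("ACGTAA").pfm,
              background=np.array([0.3, 0.2, 0.2, 0.3]))
    assert pwm.score_threshold(5e-5) == oracle_threshold(pwm, 5e-5)


# -- scanning ---------------------------------------------------------------


def test_consensus_match_and_strand_symmetry():
    pwm = _informative_pwm("ACGTACGTAC")
    cons = pwm.consensus
    rc = cons.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    background = "TTTTTTTTTTTTTTTTTTTT"
    assert scan_sequence(background + cons + background, pwm)
    assert scan_sequence(background + rc + background, pwm)
    assert not scan_sequence(background, pwm)


def test_windows_with_n_never_match():
    pwm = _informative_pwm("ACGTACGTAC")
    cons = pwm.consensus
    broken = cons[:4] + "N" + cons[5:]
    assert not scan_sequence(broken, pwm)


def test_motif_longer_than_sequence_absent():
    pwm = _informative_pwm("ACGTACGTAC")
    assert not scan_sequence("ACGT", pwm)
    assert match_offsets("ACGT", pwm, 0) == []


def test_match_offsets_reports_forward_coordinates():
    pwm = _informative_pwm("ACGTTGCATG")
    thr = pwm.score_threshold(5e-5)
    seq = "T" * 11 + pwm.consensus + "T" * 7
    assert match_offsets(seq, pwm, thr) == [11]


def test_uniform_pfm_rejected_by_generator():
    from epilineage.simulate import ConfigurationError, SimulationConfig
    with pytest.raises(ConfigurationError):
        SimulationConfig(seed=0, consensus_freq=0.25)


# -- event calling ----------------------------------------------------------


def oracle_events(vec):
    trans = [(i, vec[i], vec[i + 1]) for i in range(5) if vec[i] != vec[i + 1]]
    if len(trans) != 1:
        return None
    i, a, b = trans[0]
    return CHAIN.lineages[i], ("gain" if (not a and b) else "loss")


def test_event_caller_exhaustive_over_presence_vectors():
    """All 2^6 presence vectors against a brute-force transition count."""
    rows = []
    for k, vec in enumerate(itertools.product([False, True], repeat=6)):
        rows.append({"gre_id": f"g{k}", "motif_id": "M",
                     **dict(zip(CHAIN.nodes, vec))})
    presence = pd.DataFrame(rows)
    events = call_tfbs_events(presence, CHAIN)
    called = {r.gre_id: (r.lineage, r.direction)
              for r in events.itertuples(index=False)}
    for k, vec in enumerate(itertools.product([False, True], repeat=6)):
        assert called.get(f"g{k}") == oracle_events(vec)


def test_event_caller_worked_examples():
    vec = dict(zip(CHAIN.nodes, [False, False, False, False, True, True]))
    presence = pd.DataFrame([{"gre_id": "g", "motif_id": "M", **vec}])
    ev = call_tfbs_events(presence, CHAIN)
    assert len(ev) == 1
    assert ev.iloc[0]["lineage"] == "Hominin"
    assert ev.iloc[0]["direction"] == "gain"


# -- ratios and expansion tests --------------------------------------------


def _events(rows):
    return pd.DataFrame(rows, columns=["gre_id", "motif_id", "lineage",
                                       "direction"])


def test_gain_loss_ratios_counts_and_missing():
    ev = _events([(f"g{i}", "M1", "Human", "gain") for i in range(8)]
                 + [(f"h{i}", "M1", "Human", "loss") for i in range(4)]
                 + [(f"k{i}", "M2", "Ape", "gain") for i in range(3)])
    out = gain_loss_ratios(ev, ["M1", "M2"], LINEAGES)
    m1 = out[(out.motif_id == "M1") & (out.lineage == "Human")].iloc[0]
    assert (m1.gains, m1.losses, m1.ratio) == (8, 4, 2.0)
    m2 = out[(out.motif_id == "M2") & (out.lineage == "Ape")].iloc[0]
    assert m2.gains == 3 and np.isnan(m2.ratio)  # losses 0 -> ratio missing
    glob = out[out.motif_id == "__all__"]
    assert glob["gains"].sum() == 11
    assert glob["losses"].sum() == 4


def test_expansion_double_chi_square_flags_planted():
    """40:5 human gains vs a 1:1 global background -> expanded:Human."""
    rows = []
    rows += [(f"g{i}", "M1", "Human", "gain") for i in range(40)]
    rows += [(f"h{i}", "M1", "Human", "loss") for i in range(5)]
    for lin in ("Ape", "GreatApe", "AfricanGreatApe", "Hominin"):
        rows += [(f"{lin}g{i}", "M1", lin, "gain") for i in range(10)]
        rows += [(f"{lin}l{i}", "M1", lin, "loss") for i in range(10)]
        rows += [(f"{lin}G{i}", "M2", lin, "gain") for i in range(10)]
        rows += [(f"{lin}L{i}", "M2", lin, "loss") for i in range(10)]
    rows += [(f"x{i}", "M2", "Human", "gain") for i in range(10)]
    rows += [(f"y{i}", "M2", "Human", "loss") for i in range(10)]
    summary = gain_loss_ratios(_events(rows), ["M1", "M2"], LINEAGES)
    out = expansion_depletion(summary)
    flagged = out[(out.motif_id == "M1") & (out.lineage == "Human")].iloc[0]
    assert flagged["flag"] == "expanded"
    assert (out[(out.motif_id == "M2")]["flag"] == "ns").all()


def test_expansion_null_and_min_events():
    rows = []
    for m in ("M1", "M2"):
        for lin in LINEAGES:
            rows += [(f"{m}{lin}g{i}", m, lin, "gain") for i in range(6)]
            rows += [(f"{m}{lin}l{i}", m, lin, "loss") for i in range(6)]
    rows += [("solo", "M3", "Human", "gain")]
    summary = gain_loss_ratios(_events(rows), ["M1", "M2", "M3"], LINEAGES)
    out = expansion_depletion(summary)
    assert (out[out.motif_id != "M3"]["flag"] == "ns").all()
    m3 = out[(out.motif_id == "M3") & (out.lineage == "Human")].iloc[0]
    assert not m3["tested"]  # < 5 events


def test_expansion_detection_filter_drops_undetected():
    rows = [(f"g{i}", "M1", "Human", "gain") for i in range(40)]
    rows += [(f"h{i}", "M1", "Human", "loss") for i in range(5)]
    rows += [(f"a{i}", "M1", "Ape", "gain") for i in range(5)]
    rows += [(f"b{i}", "M1", "Ape", "loss") for i in range(5)]
    summary = gain_loss_ratios(_events(rows), ["M1"], LINEAGES)
    detection = pd.DataFrame([{"motif_id": "M1", "Neuron": 0.1,
                               "Microglia": 0.2}])
    out = expansion_depletion(summary, detection)
    assert out.empty or not (out["motif_id"] == "M1").any()


def test_chi2_statistic_closed_form():
    """One hand-computed table: (gains, losses)=(30,10) vs global p=0.5."""
    rows = [(f"g{i}", "M1", "Human", "gain") for i in range(30)]
    rows += [(f"h{i}", "M1", "Human", "loss") for i in range(10)]
    rows += [(f"a{i}", "M1", "Ape", "gain") for i in range(20)]
    rows += [(f"b{i}", "M1", "Ape", "loss") for i in range(40)]
    summary = gain_loss_ratios(_events(rows), ["M1"], LINEAGES)
    out = expansion_depletion(summary)
    human = out[(out.motif_id == "M1") & (out.lineage == "Human")].iloc[0]
    # global: 50 gains / 100 -> p=0.5; E=(20,20); chi2 = 100/20+100/20 = 10
    assert human["p_vs_global"] == pytest.approx(stats.chi2.sf(10.0, 1))


# -- families and cell-type enrichment --------------------------------------


def test_family_aggregation_dedup_and_union_bound():
    ev = _events([("g1", "M1", "Human", "gain"),
                  ("g1", "M2", "Human", "gain"),
                  ("g2", "M1", "Ape", "loss"),
                  ("g3", "M9", "Human", "gain")])
    fam = {"M1": "F", "M2": "F"}
    agg = aggregate_family(ev, fam)
    f_rows = agg[agg.family == "F"]
    assert len(f_rows) == 2  # g1 dedup + g2
    assert (agg[agg.family == "M9"]["gre_id"] == "g3").all()  # passthrough
    assert len(agg) >= len(ev.drop_duplicates(
        ["motif_id", "gre_id", "lineage", "direction"])) - 1


def test_celltype_enrichment_planted_concentration():
    rng = np.random.default_rng(0)
    universe = {f"g{i}" for i in range(400)}
    markers = {"Microglia": {f"g{i}" for i in range(40)},
               "Neuron": {f"g{i}" for i in range(200, 240)}}
    # gains concentrated in microglia markers
    ev = _events([(f"g{i}", "M1", "Human", "gain") for i in range(30)]
                 + [(f"g{i}", "M1", "Human", "gain")
                    for i in rng.integers(250, 400, 10)])
    out = tfbs_celltype_enrichment(ev, markers, universe)
    mg = out[out.cell_type == "Microglia"].iloc[0]
    assert mg["label"] == "enriched"
    assert out[out.cell_type == "Neuron"].iloc[0]["label"] == "ns"


def test_celltype_enrichment_uniform_ns():
    universe = {f"g{i}" for i in range(200)}
    markers = {"A": {f"g{i}" for i in range(50)},
               "B": {f"g{i}" for i in range(50, 100)}}
    ev = _events([(f"g{i}", "M1", "Human", "gain")
                  for i in range(0, 200, 10)])
    out = tfbs_celltype_enrichment(ev, markers, universe)
    assert (out["label"] == "ns").all()


# -- planted events through the full scanner -------------------------------


def test_planted_motif_events_recovered(small_dataset):
    ds = small_dataset
    from epilineage.pipeline import reconstruct_alignments
    rec = reconstruct_alignments(ds.tree, ds.alignments)
    presence = scan_motifs(rec, ds.pwms, CHAIN)
    events = call_tfbs_events(presence, CHAIN)
    called = set(map(tuple,
                     events[["gre_id", "motif_id", "lineage", "direction"]].values))
    planted = set(map(tuple, ds.truth.motif_event_truth[
        ["gre_id", "motif_id", "lineage", "direction"]].values))
    assert planted <= called
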