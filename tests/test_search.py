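"""Search drivers: pairing, thresholds, verification, quorum, scoring."""

import random

import pytest

from conftest import EXAMPLE_SEQUENCES
from pms5.datagen import generate_planted_instance
from pms5.neighborhood import enumerate_neighborhood
from pms5.oracle import bruteforce_motifs, bruteforce_quorum
from pms5.search import (
    motif_strings,
    pair_partition,
    pms5_find,
    qpms_find,
    score_motif,
    verify_candidate,
)
from pms5.seqcore import ProblemInstance


def test_pair_partition():
    assert pair_partition(["s2", "s3", "s4", "s5"]) == [("s2", "s3"), ("s4", "s5")]
    assert pair_partition(["s2", "s3", "s4"]) == [("s2", "s3"), ("s4", "s4")]
    assert pair_partition(["s2"]) == [("s2", "s2")]
    with pytest.raises(ValueError):
        pair_partition([])


def test_worked_example_contains_known_motifs():
    inst = ProblemInstance(EXAMPLE_SEQUENCES, l=3, d=1)
    motifs = motif_strings(pms5_find(inst))
    assert "GAT" in motifs and "GTG" in motifs
    assert motifs == sorted(motifs)
    assert set(motifs) == bruteforce_motifs(inst)


def test_single_sequence_is_union_of_window_neighborhoods():
    inst = ProblemInstance(("GCGCGAT",), l=3, d=1)
    expected = set()
    for i in range(5):
        expected |= enumerate_neighborhood("GCGCGAT"[i : i + 3], 1)
    assert set(motif_strings(pms5_find(inst))) == expected


@pytest.mark.parametrize("threshold", [1, 100, 10**9])
def test_threshold_never_changes_output(threshold, small_instances):
    for gi, _ in small_instances[:6]:
        inst = gi.to_problem()
        assert set(motif_strings(pms5_find(inst, threshold=threshold))) == (
            bruteforce_motifs(inst)
        )


def test_matches_bruteforce_oracle(small_instances):
    for gi, _ in small_instances:
        inst = gi.to_problem()
        assert set(motif_strings(pms5_find(inst))) == bruteforce_motifs(inst)
        assert gi.motif in motif_strings(pms5_find(inst))


def test_monotone_containment_in_d():
    gi = generate_planted_instance(l=5, d=1, n=5, m=25, seed=11)
    for d in range(0, 3):
        lo = set(motif_strings(pms5_find(ProblemInstance(gi.sequences, l=5, d=d))))
        hi = set(motif_strings(pms5_find(ProblemInstance(gi.sequences, l=5, d=d + 1))))
        assert lo <= hi


def test_quorum_matches_bruteforce_and_both_strategies_agree(small_instances):
    for gi, q in small_instances[:8]:
        inst = gi.to_problem(q=q)
        pooled = set(motif_strings(qpms_find(inst)))
        assert pooled == bruteforce_quorum(inst)
    # the literal per-window-triple path agrees on a small instance
    gi, _ = small_instances[2]
    small = ProblemInstance(gi.sequences[:4], l=gi.l, d=min(gi.d, 1), q=3)
    assert set(motif_strings(qpms_find(small, strategy="triples"))) == (
        set(motif_strings(qpms_find(small, strategy="pooled")))
    )
    with pytest.raises(ValueError):
        qpms_find(small, strategy="bogus")


def test_quorum_monotone_in_q():
    gi = generate_planted_instance(l=5, d=1, n=6, m=20, seed=3)
    results = {
        q: set(motif_strings(qpms_find(gi.to_problem(q=q))))
        for q in range(3, 7)
    }
    for q in range(3, 6):
        assert results[q + 1] <= results[q]


def test_quorum_below_three_uses_union_candidates():
    gi = generate_planted_instance(l=4, d=1, n=4, m=15, seed=9)
    for q in (1, 2):
        inst = gi.to_problem(q=q)
        assert set(motif_strings(qpms_find(inst))) == bruteforce_quorum(inst)


def test_quorum_equals_full_search_at_full_quorum():
    inst = ProblemInstance(EXAMPLE_SEQUENCES, l=3, d=1, q=3)
    assert motif_strings(qpms_find(inst)) == motif_strings(
        pms5_find(ProblemInstance(EXAMPLE_SEQUENCES, l=3, d=1))
    )


def test_verify_candidate():
    assert verify_candidate("GAT", [], 1)
    assert verify_candidate("GAT", list(EXAMPLE_SEQUENCES), 1)
    assert not verify_candidate("GAT", list(EXAMPLE_SEQUENCES), 0)
    rng = random.Random(1)
    gi = generate_planted_instance(l=5, d=1, n=5, m=20, seed=2)
    for _ in range(20):
        r = "".join(rng.choice("ACGT") for _ in range(5))
        assert verify_candidate(r, list(gi.sequences), 1) == all(
            score_motif(r, [s]) <= 1 for s in gi.sequences
        )


def test_score_motif_and_result_metadata():
    assert score_motif("GAT", list(EXAMPLE_SEQUENCES)) == 1  # 0 + 1 + 0
    inst = ProblemInstance(EXAMPLE_SEQUENCES, l=3, d=1)
    results = {r.motif: r for r in pms5_find(inst)}
    gat = results["GAT"]
    assert gat.score == 1
    assert gat.per_sequence[0] == (4, 0)  # exact occurrence at offset 4
    assert all(dist <= 1 for _, dist in gat.per_sequence)
    assert gat.score == sum(dist for _, dist in gat.per_sequence)
    # planted motif with exactly d mutations per sequence scores <= n*d
    gi = generate_planted_instance(l=6, d=2, n=5, m=30, seed=4)
    assert score_motif(gi.motif, list(gi.sequences)) <= 5 * 2
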