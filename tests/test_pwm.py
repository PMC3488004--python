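"""Unit tests for PWM parsing, scoring, scanning and summaries."""

import math

import numpy as np
import pytest

from cisfootprint.pwm import (
    PWMParseError,
    aggregate_group,
    family_average,
    load_jaspar,
    merge_loci,
    relative_score,
    reverse_complement,
    scan_sequence,
    summarize_hits,
    tfbs_index,
    to_score_matrix,
)
from cisfootprint.synthetic import PromoterSpec, generate_promoter

from conftest import random_dna, random_pwm


# ---------------------------------------------------------------------------
# oracle helpers (independent of the implementation under test)


def oracle_weights(counts, pseudocount=0.8, bg=(0.25, 0.25, 0.25, 0.25)):
    """Direct per-cell evaluation of the log-odds formula."""
    L = len(counts[0])
    w = [[0.0] * L for _ in range(4)]
    for j in range(L):
        colsum = sum(counts[b][j] for b in range(4))
        for b in range(4):
            num = counts[b][j] + pseudocount * bg[b]
            w[b][j] = math.log(num / (colsum + pseudocount)) - math.log(bg[b])
    return w


def oracle_rel_score(counts, subseq, pseudocount=0.8):
    w = oracle_weights(counts, pseudocount)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(counts[0])
    raw = sum(w[idx[c]][j] for j, c in enumerate(subseq))
    mn = sum(min(w[b][j] for b in range(4)) for j in range(L))
    mx = sum(max(w[b][j] for b in range(4)) for j in range(L))
    return (raw - mn) / (mx - mn)


def oracle_scan(sequence, pwm, threshold, pseudocount=0.8):
    """Exhaustive per-window scan on both strands, pure python."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    hits = set()
    L = pwm.length
    counts = pwm.counts.tolist()
    for start in range(len(sequence) - L + 1):
        window = sequence[start : start + L]
        if oracle_rel_score(counts, window, pseudocount) >= threshold:
            hits.add((start, "+"))
        rc = "".join(comp[c] for c in reversed(window))
        if oracle_rel_score(counts, rc, pseudocount) >= threshold:
            hits.add((start, "-"))
    return hits


# ---------------------------------------------------------------------------
# parsing


def test_load_jaspar_bundled(pwms):
    assert [p.tf_name for p in pwms] == ["NFKB", "REL", "p50", "p65"]
    assert all(p.length == 10 for p in pwms)
    assert all(p.consensus.startswith("GGG") for p in pwms)


def test_load_jaspar_toy_and_raw(tmp_path):
    jaspar = tmp_path / "toy.jaspar"
    jaspar.write_text(">M1 toy\nA [ 3 5 0 ]\nC [ 0 0 9 ]\nG [ 6 4 0 ]\nT [ 0 0 0 ]\n")
    (pwm,) = load_jaspar(jaspar)
    assert pwm.length == 3
    assert pwm.counts[2, 0] == 6  # G row
    raw = tmp_path / "raw.pfm"
    raw.write_text("3 5 0\n0 0 9\n6 4 0\n0 0 0\n")
    (pwm2,) = load_jaspar(raw)
    assert np.array_equal(pwm.counts, pwm2.counts)


def test_load_jaspar_empty_file(tmp_path):
    f = tmp_path / "empty.jaspar"
    f.write_text("")
    assert load_jaspar(f) == []


def test_load_jaspar_ragged_row_reports_line(tmp_path):
    f = tmp_path / "bad.jaspar"
    f.write_text(">M1 bad\nA [ 1 1 1 ]\nC [ 1 1 1 ]\nG [ 1 1 1 ]\nT [ 1 1 ]\n")
    with pytest.raises(PWMParseError, match="line 5"):
        load_jaspar(f)


def test_load_jaspar_negative_count_rejected(tmp_path):
    f = tmp_path / "neg.jaspar"
    f.write_text(">M1 neg\nA [ 1 -1 ]\nC [ 1 1 ]\nG [ 1 1 ]\nT [ 1 1 ]\n")
    with pytest.raises(PWMParseError, match="line 2"):
        load_jaspar(f)


# ---------------------------------------------------------------------------
# scoring


def test_score_matrix_matches_direct_formula(toy_pwm):
    sm = to_score_matrix(toy_pwm, pseudocount=0.8)
    expected = np.array(oracle_weights(toy_pwm.counts.tolist(), 0.8))
    assert np.allclose(sm.weights, expected)
    assert np.isclose(sm.min_score, expected.min(axis=0).sum())
    assert np.isclose(sm.max_score, expected.max(axis=0).sum())


def test_uniform_column_gives_equal_weights():
    from cisfootprint.pwm import PWM

    counts = np.array([[5.0, 9.0], [5.0, 1.0], [5.0, 0.0], [5.0, 0.0]])
    sm = to_score_matrix(PWM(id="U", tf_name="u", counts=counts))
    assert np.allclose(sm.weights[:, 0], sm.weights[0, 0])


def test_fully_uniform_matrix_is_degenerate():
    from cisfootprint.pwm import PWM

    pwm = PWM(id="U", tf_name="u", counts=np.full((4, 2), 5.0))
    with pytest.raises(ValueError):
        to_score_matrix(pwm)  # min_score == max_score


def test_single_base_column_dominates(toy_pwm):
    sm = to_score_matrix(toy_pwm, pseudocount=0.01)
    # column 2 is all-A (9,1,0,0): A has the max weight
    assert sm.weights[:, 2].argmax() == 0


def test_relative_score_definitional_extremes(toy_pwm):
    sm = to_score_matrix(toy_pwm)
    assert relative_score(sm, toy_pwm.consensus) == pytest.approx(1.0)
    worst = "".join("ACGT"[i] for i in sm.weights.argmin(axis=0))
    assert relative_score(sm, worst) == pytest.approx(0.0)


def test_relative_score_matches_enumeration(toy_pwm):
    """Exhaustive 4^L enumeration: equality of values and of ranking."""
    sm = to_score_matrix(toy_pwm)
    counts = toy_pwm.counts.tolist()
    words, ours, oracle = [], [], []
    for i in range(4 ** toy_pwm.length):
        w = ""
        k = i
        for _ in range(toy_pwm.length):
            w += "ACGT"[k % 4]
            k //= 4
        words.append(w)
        ours.append(relative_score(sm, w))
        oracle.append(oracle_rel_score(counts, w))
    assert np.allclose(ours, oracle)
    assert list(np.argsort(ours)) == list(np.argsort(oracle))


def test_relative_score_length_mismatch(toy_pwm):
    sm = to_score_matrix(toy_pwm)
    with pytest.raises(ValueError):
        relative_score(sm, "ACGT")


# ---------------------------------------------------------------------------
# scanning


def test_scan_matches_bruteforce_oracle():
    """Scan equals exhaustive-window brute force on random instances."""
    rng = np.random.default_rng(42)
    for trial in range(25):
        L = int(rng.integers(3, 9))
        pwm = random_pwm(rng, L)
        seq = random_dna(rng, int(rng.integers(L, 201)))
        threshold = float(rng.uniform(0.5, 0.95))
        hits = scan_sequence(seq, [pwm], threshold=threshold)
        got = {(h.start, h.strand) for h in hits}
        assert got == oracle_scan(seq, pwm, threshold), (trial, L, threshold)


def test_scan_recovers_planted_sites(pwms):
    spec = PromoterSpec(length=1000, n_planted_sites=3, seed=11)
    seq, truth = generate_promoter(spec, pwms)
    hits = scan_sequence(seq, pwms, threshold=0.80)
    found = {(h.pwm_id, h.start) for h in hits}
    for pwm_id, start, _, _ in truth.planted_tfbs:
        assert (pwm_id, start) in found


def test_scan_threshold_one_without_consensus(pwms):
    seq = "AC" * 50  # no GGG anywhere, so no consensus match
    assert scan_sequence(seq, pwms, threshold=1.0) == []


def test_scan_strand_symmetry(pwms):
    rng = np.random.default_rng(3)
    seq = random_dna(rng, 300)
    fwd = scan_sequence(seq, pwms, threshold=0.75)
    rev = scan_sequence(reverse_complement(seq), pwms, threshold=0.75)
    # mirror coordinates and flip strands
    n = len(seq)
    mirrored = {(n - h.end, h.pwm_id, "-" if h.strand == "+" else "+")
                for h in rev}
    assert {(h.start, h.pwm_id, h.strand) for h in fwd} == mirrored


def test_scan_threshold_monotonicity(pwms):
    rng = np.random.default_rng(4)
    seq = random_dna(rng, 500)
    counts = [len(scan_sequence(seq, pwms, threshold=t))
              for t in (0.6, 0.7, 0.8, 0.9, 1.0)]
    assert counts == sorted(counts, reverse=True)


def test_scan_skips_ambiguous_windows(pwms):
    seq = "GGGACTTTCC" + "N" * 10 + "GGGACTTTCC"
    hits = scan_sequence(seq, pwms, threshold=0.99)
    assert {h.start for h in hits} == {0, 20}


# ---------------------------------------------------------------------------
# summaries


def oracle_union(intervals):
    """O(n^2) connected components of interval overlap."""
    intervals = list(intervals)
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            if s1 < e2 and s2 < e1:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(intervals[i])
    return sorted(
        (min(s for s, _ in ivs), max(e for _, e in ivs))
        for ivs in comps.values()
    )


def test_merge_loci_matches_union_oracle():
    rng = np.random.default_rng(9)
    for _ in range(50):
        n = int(rng.integers(0, 40))
        ivs = []
        for _ in range(n):
            s = int(rng.integers(0, 200))
            ivs.append((s, s + int(rng.integers(1, 15))))
        assert merge_loci(ivs) == oracle_union(ivs)


def test_overlapping_hits_collapse_to_one_locus(pwms, toy_pwm):
    from cisfootprint.pwm import MotifHit

    hits = [MotifHit(start=i, pwm_id="TOY1", strand="+", end=i + 10,
                     seq_id="g", rel_score=0.9) for i in range(71)]
    rep = summarize_hits(hits, [toy_pwm])
    assert rep.all_total == 71
    assert rep.distinct_total == 1


def test_distant_hits_stay_distinct(toy_pwm):
    from cisfootprint.pwm import MotifHit

    hits = [
        MotifHit(start=0, pwm_id="TOY1", strand="+", end=10, seq_id="g",
                 rel_score=0.9),
        MotifHit(start=100, pwm_id="TOY1", strand="+", end=110, seq_id="g",
                 rel_score=0.9),
    ]
    rep = summarize_hits(hits, [toy_pwm])
    assert (rep.distinct_total, rep.all_total) == (2, 2)


def test_scan_report_conservation(pwms):
    rng = np.random.default_rng(17)
    seq = random_dna(rng, 800)
    hits = scan_sequence(seq, pwms, threshold=0.7)
    rep = summarize_hits(hits, pwms, seq_id="s")
    assert sum(rep.per_pwm_all.values()) == rep.all_total
    # loci partition the hit set
    covered = [sum(1 for s, e in rep.loci if s <= h.start and h.end <= e)
               for h in hits]
    assert all(c == 1 for c in covered)
    assert rep.distinct_total <= max(rep.all_total, 1)


def test_aggregate_group_participation_arithmetic(toy_pwm):
    """Per-family totals over a 43-gene dataset and a 50-sequence
    background set reproduce the expected per-sequence averages."""
    from cisfootprint.pwm import ScanReport

    def reports(totals, n):
        out = []
        for i in range(n):
            per = {f"f{j}": (totals[j] if i == 0 else 0) for j in range(4)}
            out.append(ScanReport(seq_id=f"s{i}", per_pwm_all=per,
                                  per_pwm_distinct=per,
                                  all_total=sum(per.values()),
                                  distinct_total=sum(per.values()),
                                  loci=[]))
        return out

    (summary,) = aggregate_group(reports((81, 83, 48, 49), 43), ["dataset"] * 43)
    assert summary.avg_per_sequence == 6.07
    (summary,) = aggregate_group(reports((28, 49, 15, 26), 50), ["random"] * 50)
    assert summary.avg_per_sequence == 2.36
    assert family_average((81, 83, 48, 49), 43) == 6.07


def test_aggregate_group_zero_hits(toy_pwm):
    from cisfootprint.pwm import ScanReport

    rep = ScanReport(seq_id="s", per_pwm_all={"f": 0}, per_pwm_distinct={"f": 0},
                     all_total=0, distinct_total=0, loci=[])
    (summary,) = aggregate_group([rep], ["g"])
    assert summary.avg_per_sequence == 0.0


def test_tfbs_index_is_mean_distinct():
    from cisfootprint.pwm import ScanReport

    reps = [ScanReport(seq_id=s, per_pwm_all={}, per_pwm_distinct={},
                       all_total=0, distinct_total=d, loci=[])
            for s, d in (("a", 2), ("b", 4))]
    assert tfbs_index(reps) == 3.0
    assert tfbs_index([reps[0]]) == 2.0
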