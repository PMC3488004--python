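"""Detection of AU-rich elements (AREs) in 3'UTR sequences.

AREs are A/U-rich 3'UTR elements that target mRNAs for rapid
degradation.  Three classes are recognised here, on DNA alphabet (RNA
input is transcoded U->T on entry):

* class I  -- the core pentamer ATTTA; every (possibly overlapping)
  occurrence is counted.
* class II -- chains of at least two overlapping copies of the
  destabilising nonamer TTATTTA(T/A)(T/A); consecutive nonamer starts
  less than 9 apart belong to one chain, and each maximal chain counts
  once.
* class III -- T-rich stretches containing no ATTTA: every window of a
  minimum length (default 50 nt) whose T fraction meets a threshold
  (default 0.60) and which is free of ATTTA marks its positions, and
  each maximal run of marked positions counts as one element.

The ATTT core motif is counted separately as a fourth, most permissive
signal.  All counting is done per sequence, without any alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

_PENTAMER = "ATTTA"
_CORE = "ATTT"
_NONAMER_RE = re.compile(r"(?=(TTATTTA[TA][TA]))")
_PENTAMER_RE = re.compile(r"(?=(ATTTA))")
_CORE_RE = re.compile(r"(?=(ATTT))")


@dataclass
class AREMatch:
    """One located ARE, 0-based half-open coordinates."""

    are_class: str  # "I", "II", "III" or "core"
    start: int
    end: int
    n_motifs_in_cluster: int = 1


@dataclass
class AREReport:
    seq_id: str
    count_class1: int
    count_class2: int
    count_class3: int
    count_core: int


def _transcode(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


def find_class1(sequence: str) -> list[AREMatch]:
    """All (possibly overlapping) ATTTA occurrences."""
    s = _transcode(sequence)
    return [AREMatch("I", m.start(), m.start() + 5)
            for m in _PENTAMER_RE.finditer(s)]


def find_class2(sequence: str) -> list[AREMatch]:
    """Maximal chains of >= 2 overlapping nonamers TTATTTA(T/A)(T/A).

    Nonamer starts are chained while consecutive starts differ by < 9;
    chains with at least two members yield one match each, recording the
    chain size.
    """
    s = _transcode(sequence)
    starts = [m.start() for m in _NONAMER_RE.finditer(s)]
    matches = []
    i = 0
    while i < len(starts):
        j = i
        while j + 1 < len(starts) and starts[j + 1] - starts[j] < 9:
            j += 1
        size = j - i + 1
        if size >= 2:
            matches.append(
                AREMatch("II", starts[i], starts[j] + 9, n_motifs_in_cluster=size)
            )
        i = j + 1
    return matches


def find_class3(sequence: str, min_len: int = 50, u_frac: float = 0.60) -> list[AREMatch]:
    """T-rich stretches free of the ATTTA motif.

    Every length-``min_len`` window with T fraction >= ``u_frac`` and no
    ATTTA occurrence marks its positions; maximal runs of marked
    positions are reported, one match per run.
    """
    if min_len < 10:
        raise ValueError("min_len must be >= 10")
    if not 0 < u_frac <= 1:
        raise ValueError("u_frac must be in (0, 1]")
    s = _transcode(sequence)
    n = len(s)
    if n < min_len:
        return []
    is_t = np.frombuffer(s.encode(), dtype=np.uint8) == ord("T")
    cum = np.concatenate([[0], np.cumsum(is_t)])
    w = min_len
    t_frac_ok = (cum[w:] - cum[:-w]) >= u_frac * w  # window starts 0..n-w
    # windows containing an ATTTA occurrence are disqualified
    penta_ok = np.ones(n - w + 1, dtype=bool)
    for m in _PENTAMER_RE.finditer(s):
        p = m.start()
        lo = max(0, p - w + 5)
        penta_ok[lo : p + 1] = False
    qualifying = t_frac_ok & penta_ok
    covered = np.zeros(n, dtype=bool)
    for start in np.flatnonzero(qualifying):
        covered[start : start + w] = True
    # merged coverage may straddle a pentamer no single window contains;
    # split there and drop fragments shorter than the window
    for m in _PENTAMER_RE.finditer(s):
        covered[m.start() : m.start() + 5] = False
    matches = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            if j - i >= w:
                matches.append(AREMatch("III", i, j))
            i = j
        else:
            i += 1
    return matches


def find_core(sequence: str) -> int:
    """Count of (possibly overlapping) ATTT occurrences."""
    s = _transcode(sequence)
    return sum(1 for _ in _CORE_RE.finditer(s))


def find_class1_regions(sequence: str, min_len: int = 50,
                        u_frac: float = 0.60) -> list[AREMatch]:
    """Strict-region variant of class I: T-rich stretches *containing*
    dispersed ATTTA pentamers, counted per region rather than per motif.

    Same window machinery as :func:`find_class3` but windows must contain
    at least one ATTTA.
    """
    s = _transcode(sequence)
    n = len(s)
    if n < min_len:
        return []
    is_t = np.frombuffer(s.encode(), dtype=np.uint8) == ord("T")
    cum = np.concatenate([[0], np.cumsum(is_t)])
    w = min_len
    t_frac_ok = (cum[w:] - cum[:-w]) >= u_frac * w
    has_penta = np.zeros(n - w + 1, dtype=bool)
    for m in _PENTAMER_RE.finditer(s):
        p = m.start()
        lo = max(0, p - w + 5)
        has_penta[lo : p + 1] = True
    qualifying = t_frac_ok & has_penta
    covered = np.zeros(n, dtype=bool)
    for start in np.flatnonzero(qualifying):
        covered[start : start + w] = True
    matches = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            matches.append(AREMatch("I", i, j))
            i = j
        else:
            i += 1
    return matches


def are_report(
    sequence: str,
    seq_id: str = "seq",
    min_len: int = 50,
    u_frac: float = 0.60,
    class1_mode: str = "motif",
) -> AREReport:
    """Per-sequence counts of the four ARE signals.

    ``class1_mode='motif'`` (default) counts individual ATTTA
    occurrences; ``'region'`` counts T-rich regions containing dispersed
    pentamers instead.
    """
    if class1_mode == "motif":
        c1 = len(find_class1(sequence))
    elif class1_mode == "region":
        c1 = len(find_class1_regions(sequence, min_len=min_len, u_frac=u_frac))
    else:
        raise ValueError("class1_mode must be 'motif' or 'region'")
    return AREReport(
        seq_id=seq_id,
        count_class1=c1,
        count_class2=len(find_class2(sequence)),
        count_class3=len(find_class3(sequence, min_len=min_len, u_frac=u_frac)),
        count_core=find_core(sequence),
    )
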