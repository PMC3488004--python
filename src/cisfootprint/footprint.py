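"""Phylogenetic footprinting of orthologous promoter pairs.

Orthologous promoters are globally aligned (Needleman-Wunsch with affine
gaps), a sliding-window percent-identity profile is computed over the
alignment, and regions whose identity meets a cutoff (default 40% over a
50-nt window) are called conserved.  Binding-site predictions from the
two species are then paired: two hits of the same matrix whose aligned
positions agree within a small tolerance, both lying in conserved
regions, count as one conserved site.  Aggregating the paired fraction
over ordered species pairs yields the (approximately symmetric)
cross-species conservation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .pwm import MotifHit


@dataclass
class AlignmentParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass
class PairwiseAlignment:
    """A global alignment of two sequences with coordinate maps."""

    seq_id_a: str
    seq_id_b: str
    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped strings must have equal length")
        ga = np.frombuffer(self.gapped_a.encode(), dtype=np.uint8)
        gb = np.frombuffer(self.gapped_b.encode(), dtype=np.uint8)
        gap = ord("-")
        self._not_gap_a = ga != gap
        self._not_gap_b = gb != gap
        # column -> ungapped position (gap columns map to preceding position)
        self.col_to_a = np.cumsum(self._not_gap_a) - 1
        self.col_to_b = np.cumsum(self._not_gap_b) - 1
        # ungapped position -> column
        self.pos_to_col_a = np.flatnonzero(self._not_gap_a)
        self.pos_to_col_b = np.flatnonzero(self._not_gap_b)
        self._match = (ga == gb) & self._not_gap_a & self._not_gap_b

    @property
    def length(self) -> int:
        return len(self.gapped_a)

    def ungapped_a(self) -> str:
        return self.gapped_a.replace("-", "")

    def ungapped_b(self) -> str:
        return self.gapped_b.replace("-", "")


@dataclass
class ConservationProfile:
    window: int
    per_column_identity: np.ndarray


@dataclass
class ConservedRegion:
    """Maximal run of alignment columns meeting the identity cutoff."""

    start: int  # alignment columns, half-open
    end: int
    mean_identity: float


@dataclass
class ConservedHitPair:
    hit_a: MotifHit
    hit_b: MotifHit
    offset: int  # difference of aligned start columns


def align_pair(
    seq_a: str,
    seq_b: str,
    params: AlignmentParams | None = None,
    seq_id_a: str = "a",
    seq_id_b: str = "b",
) -> PairwiseAlignment:
    """Global Needleman-Wunsch alignment with affine gap penalties.

    A gap of length k scores ``gap_open + (k - 1) * gap_extend``.  Among
    co-optimal alignments the aligner's first reported alignment is used,
    which is deterministic for fixed inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    params = params or AlignmentParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    result = aligner.align(seq_a.upper(), seq_b.upper())
    best = result[0]
    return PairwiseAlignment(
        seq_id_a=seq_id_a,
        seq_id_b=seq_id_b,
        gapped_a=str(best[0]),
        gapped_b=str(best[1]),
        score=float(best.score),
    )


def conservation_profile(aln: PairwiseAlignment, window: int = 50) -> ConservationProfile:
    """Windowed percent identity per alignment column.

    The window is centred on each column and truncated at the alignment
    ends; gap columns count as mismatches.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    m = aln._match.astype(float)
    n = m.size
    half = window // 2
    cum = np.concatenate([[0.0], np.cumsum(m)])
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) - half + window, 0, n)
    identity = (cum[hi] - cum[lo]) / (hi - lo)
    return ConservationProfile(window=window, per_column_identity=identity)


def conserved_regions(profile: ConservationProfile, cutoff: float = 0.40) -> list[ConservedRegion]:
    """Maximal runs of columns whose windowed identity >= cutoff."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    above = profile.per_column_identity >= cutoff
    regions = []
    n = above.size
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            regions.append(
                ConservedRegion(
                    start=i,
                    end=j,
                    mean_identity=float(profile.per_column_identity[i:j].mean()),
                )
            )
            i = j
        else:
            i += 1
    return regions


def _columns_inside(start_col: int, end_col: int,
                    regions: Sequence[ConservedRegion]) -> int:
    inside = 0
    for r in regions:
        inside += max(0, min(end_col, r.end) - max(start_col, r.start))
    return inside


def _hit_in_conserved(hit: MotifHit, pos_to_col: np.ndarray,
                      regions: Sequence[ConservedRegion]) -> bool:
    """A hit counts as conserved when >= 50% of its columns lie inside a
    conserved region."""
    cols = pos_to_col[hit.start : hit.end]
    start_col, end_col = int(cols[0]), int(cols[-1]) + 1
    return _columns_inside(start_col, end_col, regions) >= 0.5 * (hit.end - hit.start)


def conserved_hits(
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    aln: PairwiseAlignment,
    regions: Sequence[ConservedRegion],
    offset_tol: int = 3,
) -> list[ConservedHitPair]:
    """Pair same-matrix hits across the two aligned species.

    A pair is emitted when both hits lie (>=50% of their length) inside
    conserved regions and their aligned start columns differ by at most
    ``offset_tol``.  Pairing is greedy by smallest offset, then leftmost
    hit; each hit joins at most one pair.
    """
    if not regions:
        return []
    cons_a = [h for h in hits_a if _hit_in_conserved(h, aln.pos_to_col_a, regions)]
    cons_b = [h for h in hits_b if _hit_in_conserved(h, aln.pos_to_col_b, regions)]
    candidates = []
    for ia, ha in enumerate(cons_a):
        col_a = int(aln.pos_to_col_a[ha.start])
        for ib, hb in enumerate(cons_b):
            if ha.pwm_id != hb.pwm_id or ha.strand != hb.strand:
                continue
            col_b = int(aln.pos_to_col_b[hb.start])
            off = col_a - col_b
            if abs(off) <= offset_tol:
                candidates.append((abs(off), col_a, col_b, ia, ib, off))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, ia, ib, off in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append(ConservedHitPair(hit_a=cons_a[ia], hit_b=cons_b[ib], offset=off))
    return pairs


def conservation_matrix(
    per_species_hits: Mapping[str, Sequence[MotifHit]],
    pairwise_results: Mapping[tuple[str, str], Sequence[ConservedHitPair]],
) -> "pd.DataFrame":
    """Cross-species conserved-site fraction matrix, in percent.

    Cell (template M, other N) is the percentage of M's hits that paired
    with a hit of N when the two promoters were aligned; the denominator
    is always the template species' hit count, so the matrix is only
    approximately symmetric.  Cells with zero template hits are NaN
    (undefined), not 0.  The diagonal is 100 where defined.
    """
    import pandas as pd

    species = list(per_species_hits)
    mat = pd.DataFrame(np.nan, index=species, columns=species, dtype=float)
    missing = []
    for m in species:
        n_hits = len(per_species_hits[m])
        for s in species:
            if s == m:
                if n_hits > 0:
                    mat.loc[m, s] = 100.0
                continue
            if (m, s) not in pairwise_results:
                missing.append((m, s))
                continue
            if n_hits == 0:
                continue
            mat.loc[m, s] = 100.0 * len(pairwise_results[(m, s)]) / n_hits
    if missing:
        raise KeyError(f"missing species pairs: {missing}")
    return mat
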