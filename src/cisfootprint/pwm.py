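"""Position-weight-matrix parsing, scoring and scanning.

The four NF-kB-family motifs (NFKB heterodimer, REL/c-Rel, p50/NFKB1,
p65/RELA) are represented as nucleotide count matrices.  Counts are
converted to log-odds weights against a background composition, windows
are scored on both strands, and a window is reported as a putative
binding site when its *relative score* -- the raw log-odds score rescaled
between the matrix's minimum and maximum attainable scores -- meets a
threshold (default 0.80).

Overlapping hits from any matrix on either strand are merged into
*loci*; the number of loci ("distinct" sites) versus the number of raw
hits ("all" sites) distinguishes promoters with clustered, overlapping
site architecture from promoters with isolated sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import motifs as bio_motifs

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


class PWMParseError(ValueError):
    """Raised when a matrix file cannot be parsed."""


@dataclass(frozen=True)
class PWM:
    """A per-position nucleotide count matrix with identity metadata."""

    id: str
    tf_name: str
    counts: np.ndarray  # shape (4, L), rows in A,C,G,T order

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise PWMParseError(
                f"{self.id}: counts must be a 4xL matrix, got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise PWMParseError(f"{self.id}: negative counts are not allowed")
        if (counts.sum(axis=0) == 0).any():
            col = int(np.flatnonzero(counts.sum(axis=0) == 0)[0])
            raise PWMParseError(f"{self.id}: column {col} has zero total count")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        """Highest-count base per column (first base wins ties)."""
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class ScoreMatrix:
    """Log-odds weights of a PWM plus its attainable score range."""

    pwm_id: str
    weights: np.ndarray  # shape (4, L)
    min_score: float
    max_score: float

    @property
    def length(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True, order=True)
class MotifHit:
    """One above-threshold PWM match, in forward-strand coordinates."""

    start: int
    pwm_id: str
    strand: str
    end: int
    seq_id: str
    rel_score: float


@dataclass
class ScanReport:
    """Per-sequence summary of raw hits and overlap-merged loci."""

    seq_id: str
    per_pwm_all: dict[str, int]
    per_pwm_distinct: dict[str, int]
    all_total: int
    distinct_total: int
    loci: list[tuple[int, int]]


@dataclass
class GroupSummary:
    group: str
    per_family_totals: dict[str, int]
    n_sequences: int
    avg_per_sequence: float


# ---------------------------------------------------------------------------
# parsing


def _diagnose_jaspar(text: str) -> None:
    """Raise a PWMParseError pointing at the first malformed matrix row."""
    records: list[list[tuple[int, int]]] = []  # per record: (lineno, rowlen)
    current: list[tuple[int, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if current:
                records.append(current)
            current = []
            continue
        body = stripped
        label = body[0].upper() if body and body[0].isalpha() else None
        if label is not None:
            body = body[1:]
            if label not in _BASE_INDEX:
                raise PWMParseError(f"line {lineno}: unknown row label {label!r}")
        body = body.replace("[", " ").replace("]", " ")
        try:
            values = [float(tok) for tok in body.split()]
        except ValueError as exc:
            raise PWMParseError(f"line {lineno}: non-numeric matrix row") from exc
        if any(v < 0 for v in values):
            raise PWMParseError(f"line {lineno}: negative count in matrix row")
        current.append((lineno, len(values)))
    if current:
        records.append(current)
    for rows in records:
        lengths = {n for _, n in rows}
        if len(lengths) > 1:
            expected = rows[0][1]
            for lineno, n in rows:
                if n != expected:
                    raise PWMParseError(
                        f"line {lineno}: row has {n} values, expected {expected}"
                    )
        if len(rows) not in (0, 4):
            raise PWMParseError(
                f"line {rows[-1][0]}: matrix record has {len(rows)} rows, expected 4"
            )


def load_jaspar(path: str | Path) -> list[PWM]:
    """Load PWMs from a JASPAR file.

    Both JASPAR flavours are accepted: ``>id name`` headers followed by
    four (optionally bracketed and base-labelled) count rows, or headerless
    blocks of four raw rows in A,C,G,T order.  Parsing is delegated to
    :mod:`Bio.motifs`; malformed files raise :class:`PWMParseError` with
    the offending line number.
    """
    text = Path(path).read_text()
    if not text.strip():
        return []
    _diagnose_jaspar(text)
    pwms: list[PWM] = []
    try:
        if ">" in text:
            records = bio_motifs.parse(StringIO(text), "jaspar")
            for m in records:
                matrix_id = getattr(m, "matrix_id", None) or m.name
                counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
                pwms.append(PWM(id=matrix_id, tf_name=m.name or matrix_id, counts=counts))
        else:
            # headerless: consecutive blocks of 4 non-empty lines
            lines = [ln for ln in text.splitlines() if ln.strip()]
            if len(lines) % 4 != 0:
                raise PWMParseError(
                    f"raw matrix file has {len(lines)} rows; expected a multiple of 4"
                )
            for i in range(0, len(lines), 4):
                block = "\n".join(lines[i : i + 4]) + "\n"
                m = bio_motifs.read(StringIO(block), "pfm")
                counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
                name = f"matrix_{i // 4 + 1}"
                pwms.append(PWM(id=name, tf_name=name, counts=counts))
    except PWMParseError:
        raise
    except Exception as exc:  # Bio.motifs raises bare ValueError/KeyError
        raise PWMParseError(f"{path}: {exc}") from exc
    return pwms


def bundled_nfkb_pwms() -> list[PWM]:
    """The synthetic NF-kB-family matrix set shipped with the package.

    Four 10-nt matrices (NFKB, REL, p50, p65 labels) constructed to share
    the family's hallmark GGG-opening and C-rich tail; they are synthetic
    stand-ins, not JASPAR database entries.
    """
    return load_jaspar(Path(__file__).parent / "data" / "nfkb_family_synthetic.jaspar")


# ---------------------------------------------------------------------------
# scoring


def to_score_matrix(
    pwm: PWM,
    pseudocount: float = 0.8,
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> ScoreMatrix:
    """Convert counts to log-odds weights.

    ``weights[b, j] = log((counts[b, j] + pseudocount * background[b]) /
    (colsum_j + pseudocount)) - log(background[b])``; the pseudocount is
    distributed over bases proportionally to the background.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies summing to 1")
    counts = pwm.counts
    colsum = counts.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError(f"{pwm.id}: zero column sum")
    freqs = (counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    weights = np.log(freqs) - np.log(bg[:, None])
    min_score = float(weights.min(axis=0).sum())
    max_score = float(weights.max(axis=0).sum())
    if not max_score > min_score:
        raise ValueError(f"{pwm.id}: degenerate matrix (max_score == min_score)")
    return ScoreMatrix(pwm_id=pwm.id, weights=weights, min_score=min_score,
                       max_score=max_score)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes; non-ACGT characters become -1."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def relative_score(sm: ScoreMatrix, subseq: str) -> float:
    """Min-max rescaled log-odds score of one window, clipped to [0, 1]."""
    if len(subseq) != sm.length:
        raise ValueError(
            f"subsequence length {len(subseq)} != matrix length {sm.length}"
        )
    codes = encode_sequence(subseq)
    if (codes < 0).any():
        raise ValueError("subsequence contains non-ACGT characters")
    raw = float(sm.weights[codes, np.arange(sm.length)].sum())
    rel = (raw - sm.min_score) / (sm.max_score - sm.min_score)
    return float(np.clip(rel, 0.0, 1.0))


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Raw scores of every window; windows containing -1 codes are NaN."""
    L = weights.shape[1]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win >= 0).all(axis=1)
    scores = np.full(n, np.nan)
    if valid.any():
        scores[valid] = weights[win[valid], np.arange(L)].sum(axis=1)
    return scores


def scan_sequence(
    sequence: str,
    pwms: Iterable[PWM],
    threshold: float = 0.80,
    strands: str = "both",
    seq_id: str = "seq",
    pseudocount: float = 0.8,
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> list[MotifHit]:
    """Scan both strands of a sequence with every PWM.

    Every window whose relative score is >= ``threshold`` yields one hit;
    reverse-strand hits are reported in forward coordinates.  Windows
    containing ambiguity characters are skipped (and counted in a debug
    log line).  A window meeting the threshold on both strands yields two
    hits.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be one of 'both', '+', '-'")
    pwms = list(pwms)
    if not pwms:
        raise ValueError("no PWMs supplied")
    codes = encode_sequence(sequence)
    n_skipped = 0
    hits: list[MotifHit] = []
    for pwm in pwms:
        sm = to_score_matrix(pwm, pseudocount=pseudocount, background=background)
        span = sm.max_score - sm.min_score
        strand_weights = []
        if strands in ("both", "+"):
            strand_weights.append(("+", sm.weights))
        if strands in ("both", "-"):
            # scoring the reverse complement of each window == scanning with
            # the base- and position-reversed matrix
            strand_weights.append(("-", sm.weights[::-1, ::-1]))
        for strand, weights in strand_weights:
            raw = _window_scores(codes, weights)
            n_skipped += int(np.isnan(raw).sum())
            rel = (raw - sm.min_score) / span
            for pos in np.flatnonzero(rel >= threshold):
                hits.append(
                    MotifHit(
                        start=int(pos),
                        pwm_id=pwm.id,
                        strand=strand,
                        end=int(pos) + sm.length,
                        seq_id=seq_id,
                        rel_score=float(np.clip(rel[pos], 0.0, 1.0)),
                    )
                )
    if n_skipped:
        logger.debug("%s: skipped %d windows containing non-ACGT characters",
                     seq_id, n_skipped)
    hits.sort(key=lambda h: (h.start, h.pwm_id, h.strand))
    return hits


# ---------------------------------------------------------------------------
# summaries


def merge_loci(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Connected components of half-open interval overlap (touching
    intervals do not overlap and stay separate)."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def summarize_hits(hits: Sequence[MotifHit], pwms: Iterable[PWM],
                   seq_id: str | None = None) -> ScanReport:
    """Collapse hits of one sequence into distinct/all counts.

    ``loci`` are maximal unions of overlapping hit intervals pooled across
    all matrices and both strands; ``per_pwm_distinct`` counts, for each
    matrix, the loci containing at least one of its hits.
    """
    pwm_ids = [p.id for p in pwms]
    seq_ids = {h.seq_id for h in hits}
    if len(seq_ids) > 1:
        raise ValueError(f"hits span multiple sequences: {sorted(seq_ids)}")
    if seq_id is None:
        seq_id = seq_ids.pop() if seq_ids else "seq"
    loci = merge_loci((h.start, h.end) for h in hits)
    per_all = {pid: 0 for pid in pwm_ids}
    per_distinct = {pid: 0 for pid in pwm_ids}
    starts = [s for s, _ in loci]
    locus_pwms: list[set[str]] = [set() for _ in loci]
    for h in hits:
        per_all[h.pwm_id] = per_all.get(h.pwm_id, 0) + 1
        # rightmost locus starting at or before the hit start contains it
        idx = int(np.searchsorted(starts, h.start, side="right")) - 1
        locus_pwms[idx].add(h.pwm_id)
    for members in locus_pwms:
        for pid in members:
            per_distinct[pid] = per_distinct.get(pid, 0) + 1
    return ScanReport(
        seq_id=seq_id,
        per_pwm_all=per_all,
        per_pwm_distinct=per_distinct,
        all_total=len(hits),
        distinct_total=len(loci),
        loci=loci,
    )


def aggregate_group(reports: Sequence[ScanReport],
                    group_labels: Sequence[str]) -> list[GroupSummary]:
    """Per-group family totals and average distinct sites per sequence.

    Family totals sum ``per_pwm_distinct`` over the group's sequences;
    the per-sequence average (grand total / n) is rounded to 2 decimals.
    """
    if len(reports) != len(group_labels):
        raise ValueError("reports and group_labels differ in length")
    if not reports:
        raise ValueError("no reports to aggregate")
    groups: dict[str, list[ScanReport]] = {}
    for rep, lab in zip(reports, group_labels):
        groups.setdefault(lab, []).append(rep)
    out = []
    for lab, reps in groups.items():
        totals: dict[str, int] = {}
        for rep in reps:
            for pid, c in rep.per_pwm_distinct.items():
                totals[pid] = totals.get(pid, 0) + c
        grand = sum(totals.values())
        out.append(
            GroupSummary(
                group=lab,
                per_family_totals=totals,
                n_sequences=len(reps),
                avg_per_sequence=round(grand / len(reps), 2),
            )
        )
    return out


def family_average(per_family_totals: Sequence[float], n_sequences: int) -> float:
    """Average number of family sites per sequence, to 2 decimals."""
    if n_sequences <= 0:
        raise ValueError("n_sequences must be positive")
    return round(sum(per_family_totals) / n_sequences, 2)


def tfbs_index(reports: Sequence[ScanReport], statistic: str = "mean_distinct") -> float:
    """A per-group site-richness index.

    The published index has no recoverable definition, so this is a
    documented surrogate: the mean over genes of the distinct-locus count
    (``mean_distinct``, default) or of the raw hit count (``mean_all``).
    """
    if not reports:
        raise ValueError("empty group")
    if statistic == "mean_distinct":
        return float(np.mean([r.distinct_total for r in reports]))
    if statistic == "mean_all":
        return float(np.mean([r.all_total for r in reports]))
    raise ValueError(f"unknown statistic {statistic!r}")
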