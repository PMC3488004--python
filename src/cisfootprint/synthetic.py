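"""Synthetic promoters, orthologs, 3'UTRs and background sequences.

Everything the pipeline consumes can be generated here with known ground
truth: promoters carry planted consensus binding sites (clustered, as in
rapidly induced genes, or scattered, as in late-responding genes);
orthologs are derived by per-site substitution at different rates inside
and outside conserved blocks; 3'UTRs carry planted AU-rich elements of
classes I, II and III; background sets are i.i.d. random sequences and
letter-shuffles of real inputs.

All sampling is driven by an explicit integer seed per operation; no
global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .pwm import PWM, ALPHABET

_CLASS2_CHAIN = "TTATTTATTATTTATT"  # two nonamers, starts 0 and 7
_CLASS1_PENTAMER = "ATTTA"


class PlacementError(ValueError):
    """Raised when requested elements cannot be placed in the sequence."""


@dataclass(frozen=True)
class PromoterSpec:
    """Parameters of one synthetic promoter.

    ``n_planted_sites`` is the total number of planted sites; sites take
    the consensus of the supplied PWMs round-robin.  ``clustered`` mode
    packs all sites into one window of ``cluster_span`` nucleotides;
    ``scattered`` mode keeps >=100 nt between consecutive sites.
    """

    length: int = 1000
    n_planted_sites: int = 0
    clustering_mode: str = "clustered"
    cluster_span: int = 250
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        if self.n_planted_sites < 0:
            raise ValueError("n_planted_sites must be >= 0")
        if self.clustering_mode not in ("clustered", "scattered"):
            raise ValueError("clustering_mode must be 'clustered' or 'scattered'")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")


@dataclass(frozen=True)
class OrthologSpec:
    """Parameters of simulated divergence from an ancestral promoter."""

    sub_rate_neutral: float = 0.1
    sub_rate_conserved: float = 0.0
    indel_rate: float = 0.0
    conserved_blocks: tuple[tuple[int, int], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate_neutral", "sub_rate_conserved", "indel_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sub_rate_conserved > self.sub_rate_neutral:
            raise ValueError("sub_rate_conserved must be <= sub_rate_neutral")


@dataclass(frozen=True)
class UTRSpec:
    """Planted ARE content of one synthetic 3'UTR."""

    length: int = 2500
    n_class1: int = 0
    n_class2: int = 0
    n_class3: int = 0
    class3_len: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        for name in ("n_class1", "n_class2", "n_class3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.class3_len < 50:
            raise ValueError("class3_len must be >= 50 to satisfy the detector")


@dataclass
class GroundTruth:
    """Recoverable coordinates of every planted element (0-based, half-open)."""

    planted_tfbs: list[tuple[str, int, int, str]] = field(default_factory=list)
    planted_ares: list[tuple[str, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def _str_to_codes(s: str) -> np.ndarray:
    return np.array([ALPHABET.index(c) for c in s], dtype=np.int64)


def _place_blocks(
    rng: np.random.Generator,
    region_start: int,
    region_end: int,
    block_lengths: Sequence[int],
    min_gap: int,
) -> list[int]:
    """Random non-overlapping starts for blocks inside [region_start, region_end),
    preserving request order left to right with >= min_gap between blocks."""
    n = len(block_lengths)
    if n == 0:
        return []
    occupied = sum(block_lengths) + min_gap * (n - 1)
    slack = (region_end - region_start) - occupied
    if slack < 0:
        raise PlacementError(
            f"element 1 of {n} (length {block_lengths[0]}) does not fit: "
            f"need {occupied} nt, region has {region_end - region_start}"
        )
    # distribute the slack over the n+1 gaps uniformly at random
    gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    starts = []
    pos = region_start
    for i, L in enumerate(block_lengths):
        pos += int(gaps[i]) + (min_gap if i > 0 else 0)
        starts.append(int(pos))
        pos += L
    return starts


# ---------------------------------------------------------------------------
# promoters


def generate_promoter(spec: PromoterSpec, pwms: Sequence[PWM]) -> tuple[str, GroundTruth]:
    """Emit a promoter with planted consensus binding sites.

    Sites are the exact consensus strings of the PWMs (assigned
    round-robin), planted on the forward strand.  Background bases are
    i.i.d. at the requested GC content.
    """
    if not pwms:
        raise ValueError("pwms must be non-empty")
    if spec.length < max(p.length for p in pwms):
        raise ValueError("promoter length shorter than the longest PWM")
    rng = np.random.default_rng(spec.seed)
    codes = _random_dna(rng, spec.length, spec.gc_content)
    chosen = [pwms[i % len(pwms)] for i in range(spec.n_planted_sites)]
    lengths = [p.length for p in chosen]
    if spec.n_planted_sites:
        if spec.clustering_mode == "clustered":
            span = min(spec.cluster_span, spec.length)
            if sum(lengths) > span:
                raise PlacementError(
                    f"element 1 of {len(lengths)}: {spec.n_planted_sites} sites "
                    f"(total {sum(lengths)} nt) exceed cluster_span {span}"
                )
            cstart = int(rng.integers(0, spec.length - span + 1))
            starts = _place_blocks(rng, cstart, cstart + span, lengths, min_gap=0)
        else:
            starts = _place_blocks(rng, 0, spec.length, lengths, min_gap=100)
    else:
        starts = []
    truth = GroundTruth()
    for pwm, start in zip(chosen, starts):
        site = _str_to_codes(pwm.consensus)
        codes[start : start + pwm.length] = site
        truth.planted_tfbs.append((pwm.id, start, start + pwm.length, "+"))
    return _codes_to_str(codes), truth


# ---------------------------------------------------------------------------
# orthologs


def evolve_ortholog(
    sequence: str,
    truth: GroundTruth,
    spec: OrthologSpec,
) -> tuple[str, np.ndarray]:
    """Derive an ortholog by per-site substitution and single-base indels.

    Substitutions are Bernoulli per site at ``sub_rate_conserved`` inside
    conserved blocks and ``sub_rate_neutral`` elsewhere; a substituted
    base is replaced by a uniformly chosen *different* base, so the
    expected mismatch fraction outside blocks equals the neutral rate.
    Indels are single-base deletions/insertions (probability
    ``indel_rate`` per site, split evenly) applied outside conserved
    blocks only, so zero conserved-rate guarantees planted sites survive
    verbatim.

    Returns the derived sequence and a coordinate map: ``coord_map[i]``
    is the derived position of ancestral base ``i`` (-1 if deleted).
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("sequence must be non-empty")
    blocks = spec.conserved_blocks
    if blocks is None:
        blocks = tuple((s, e) for _, s, e, _ in truth.planted_tfbs)
    prev_end = None
    for s, e in sorted(blocks):
        if not (0 <= s <= e <= n):
            raise ValueError(f"conserved block ({s}, {e}) outside sequence")
        if prev_end is not None and s < prev_end:
            raise ValueError("conserved blocks overlap")
        prev_end = e
    rng = np.random.default_rng(spec.seed)
    codes = _str_to_codes(sequence)
    in_block = np.zeros(n, dtype=bool)
    for s, e in blocks:
        in_block[s:e] = True
    rates = np.where(in_block, spec.sub_rate_conserved, spec.sub_rate_neutral)
    sub_mask = rng.random(n) < rates
    # uniform different base: add 1..3 mod 4
    shifts = rng.integers(1, 4, size=n)
    codes = np.where(sub_mask, (codes + shifts) % 4, codes)
    # indels outside conserved blocks
    indel_draw = rng.random(n)
    delete = (~in_block) & (indel_draw < spec.indel_rate / 2)
    insert = (~in_block) & (indel_draw >= spec.indel_rate / 2) & (
        indel_draw < spec.indel_rate
    )
    inserted_bases = rng.integers(0, 4, size=n)
    out: list[int] = []
    coord_map = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if insert[i]:
            out.append(int(inserted_bases[i]))
        if not delete[i]:
            coord_map[i] = len(out)
            out.append(int(codes[i]))
    return _codes_to_str(np.array(out, dtype=np.int64)), coord_map


# ---------------------------------------------------------------------------
# 3'UTRs


def _scrub_pentamers(codes: np.ndarray, rng: np.random.Generator,
                     protected: np.ndarray) -> None:
    """Replace the middle base of accidental ATTTA occurrences (outside
    protected positions) with C until none remain."""
    s = _codes_to_str(codes)
    while True:
        pos = s.find(_CLASS1_PENTAMER)
        dirty = False
        while pos != -1:
            if not protected[pos : pos + 5].any():
                codes[pos + 2] = 1  # C
                dirty = True
            pos = s.find(_CLASS1_PENTAMER, pos + 1)
        s = _codes_to_str(codes)
        if not dirty and _find_unprotected(s, protected) is None:
            return


def _find_unprotected(s: str, protected: np.ndarray) -> int | None:
    pos = s.find(_CLASS1_PENTAMER)
    while pos != -1:
        if not protected[pos : pos + 5].any():
            return pos
        pos = s.find(_CLASS1_PENTAMER, pos + 1)
    return None


def generate_utr(spec: UTRSpec) -> tuple[str, GroundTruth]:
    """Emit a 3'UTR with planted AREs of the three classes.

    Class I elements are isolated ATTTA pentamers; class II elements are
    chains of two overlapping nonamers TTATTTA(T/A)(T/A); class III
    elements are T-rich stretches free of ATTTA.  Each element is flanked
    by C/G guard bases so planted motifs cannot fuse with the background,
    and accidental background ATTTA occurrences are scrubbed, so the ARE
    detector recovers exactly the planted counts.
    """
    rng = np.random.default_rng(spec.seed)
    elements: list[tuple[str, str]] = []  # (class label, element string)
    for _ in range(spec.n_class3):
        # T-rich, no A at all (hence no ATTTA); occasional C keeps it off poly-T
        body = "".join("C" if rng.random() < 0.1 else "T"
                       for _ in range(spec.class3_len))
        elements.append(("III", "G" + body + "G"))
    for _ in range(spec.n_class2):
        elements.append(("II", "CC" + _CLASS2_CHAIN + "CC"))
    for _ in range(spec.n_class1):
        elements.append(("I", "C" + _CLASS1_PENTAMER + "C"))
    order = rng.permutation(len(elements))
    elements = [elements[i] for i in order]
    lengths = [len(e) for _, e in elements]
    # gap > class III window length so no T-rich window can bridge elements
    starts = _place_blocks(rng, 0, spec.length, lengths, min_gap=60)
    codes = _random_dna(rng, spec.length, gc=0.5)
    protected = np.zeros(spec.length, dtype=bool)
    truth = GroundTruth()
    for (label, elem), start in zip(elements, starts):
        codes[start : start + len(elem)] = _str_to_codes(elem)
        protected[start : start + len(elem)] = True
        # inner coordinates exclude the guard bases
        guard = 1 if label in ("I", "III") else 2
        truth.planted_ares.append((label, start + guard, start + len(elem) - guard))
    _scrub_pentamers(codes, rng, protected)
    return _codes_to_str(codes), truth


# ---------------------------------------------------------------------------
# backgrounds


def generate_background(
    n: int,
    length: int,
    seed: int = 0,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> list[str]:
    """n i.i.d. random DNA strings of the given length and composition."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    p = np.asarray(composition, dtype=float)
    if p.shape != (4,) or not np.isclose(p.sum(), 1.0) or (p < 0).any():
        raise ValueError("composition must be 4 non-negative frequencies summing to 1")
    rng = np.random.default_rng(seed)
    return [_codes_to_str(rng.choice(4, size=length, p=p)) for _ in range(n)]


def generate_feature_vectors(
    seed: int = 0,
    n_early: int = 14,
    n_middle: int = 18,
    n_late: int = 11,
) -> tuple[list, list[str]]:
    """Per-gene feature vectors with the qualitative group structure of
    NF-kB-dependent genes.

    Early-like genes carry many clustered binding sites (high distinct
    and all counts, low placement dispersion) and many AREs of every
    class; Late-like genes carry few scattered sites and few AREs; the
    Middle group is an even mixture of the two profiles.  Returns the
    feature vectors and, in parallel, the latent profile of each gene
    ("early_like" or "late_like") as ground truth for clustering tests.
    """
    from .stats import GeneFeatureVector

    rng = np.random.default_rng(seed)
    vectors: list[GeneFeatureVector] = []
    profiles: list[str] = []

    def _emit(gene_id: str, group: str, profile: str) -> None:
        # The two Middle archetypes are deterministic anchor profiles; the
        # Early and Late groups fluctuate around more extreme values with
        # margins wide enough that dataset tertiles fall between profiles.
        if profile == "early_like":
            distinct = 12 + int(rng.poisson(2))
            all_tfbs = 36 + int(rng.poisson(6))
            disp = float(rng.uniform(0.05, 0.2))
            are1, are2, are3 = (10 + int(rng.poisson(2)), 4 + int(rng.poisson(1)),
                                12 + int(rng.poisson(2)))
        elif profile == "mid_early_like":
            distinct, all_tfbs, disp = 8, 24, 0.45
            are1, are2, are3 = 6, 2, 8
        elif profile == "mid_late_like":
            distinct, all_tfbs, disp = 4, 8, 0.95
            are1, are2, are3 = 4, 0, 5
        else:  # late_like
            distinct = int(rng.poisson(1))
            all_tfbs = distinct + int(rng.poisson(1))
            disp = float(rng.uniform(1.3, 1.5))
            are1, are2, are3 = (int(rng.poisson(1)), 0, int(rng.poisson(1)))
        vectors.append(
            GeneFeatureVector(gene_id=gene_id, group=group, distinct_tfbs=distinct,
                              all_tfbs=all_tfbs, dispersion=disp,
                              are1=are1, are2=are2, are3=are3)
        )
        profiles.append("early_like" if "early" in profile else "late_like")

    for i in range(n_early):
        _emit(f"Early_{i + 1:02d}", "Early", "early_like")
    for i in range(n_middle):
        profile = "mid_early_like" if i < n_middle // 2 else "mid_late_like"
        _emit(f"Middle_{i + 1:02d}", "Middle", profile)
    for i in range(n_late):
        _emit(f"Late_{i + 1:02d}", "Late", "late_like")
    return vectors, profiles


def shuffle_sequence(sequence: str, seed: int = 0) -> str:
    """A uniform random permutation of the input letters.

    Mononucleotide composition is preserved exactly.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = [i for i, c in enumerate(sequence.upper()) if c not in ALPHABET]
    if bad:
        shown = ", ".join(str(i) for i in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise ValueError(f"non-ACGT characters at positions {shown}{more}")
    rng = np.random.default_rng(seed)
    letters = np.array(list(sequence.upper()))
    return "".join(letters[rng.permutation(len(letters))])
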