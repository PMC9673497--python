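"""Degenerate short-linear pattern spaces, enrichment tests and flagging.

Two pattern families are handled:

* nucleotide patterns of length 3-5 where every position is a nonempty
  subset of ``{A,C,G,T}`` and the first/last position may not be the
  unrestricted 4-base set (written ``T[AT]AAA``, interior ``x`` = any base);
* amino-acid patterns of 3-4 fixed residues where each inter-residue gap is
  either empty or exactly one wildcard residue (written ``SxNxE``).

Class-enriched patterns are flagged with a Pearson chi-squared presence
test (no continuity correction) and Benjamini-Hochberg adjustment; the
adjustment family is the set of patterns passing the frequency cutoff.
Full-space scans work on per-sequence window-code sets so the pattern x
gene presence matrix is never materialised beyond one pattern chunk.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .protein_features import AMINO_ACIDS

__all__ = [
    "SlnPattern",
    "SlaapPattern",
    "PatternStats",
    "enumerate_slnps",
    "enumerate_slaaps",
    "pattern_present",
    "chi2_presence",
    "bh_adjust",
    "flag_slnps",
    "flag_slaaps",
    "top_k",
    "co_occurrence_count",
    "idr_conditional_frequency",
    "read_disorder_scores",
    "write_pattern_stats",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_FULL_SET = frozenset(_BASES)

# The 15 nonempty base subsets ordered by size then base order; the last
# entry is the full set, so the first 14 are the legal end-position subsets.
_SUBSETS: tuple[frozenset, ...] = tuple(
    frozenset(c)
    for size in (1, 2, 3, 4)
    for c in combinations(_BASES, size)
)
_END_SUBSETS = _SUBSETS[:14]


def _subset_text(subset: frozenset) -> str:
    if len(subset) == 4:
        return "x"
    ordered = "".join(b for b in _BASES if b in subset)
    return ordered if len(ordered) == 1 else f"[{ordered}]"


@dataclass(frozen=True)
class SlnPattern:
    """Degenerate nucleotide pattern: one base subset per position."""

    positions: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if not 3 <= len(self.positions) <= 5:
            raise ValueError("pattern length must be 3-5")
        if len(self.positions[0]) == 4 or len(self.positions[-1]) == 4:
            raise ValueError("first/last position may not be the full base set")
        for subset in self.positions:
            if not subset or not subset <= _FULL_SET:
                raise ValueError("positions must be nonempty subsets of ACGT")

    @property
    def text(self) -> str:
        return "".join(_subset_text(s) for s in self.positions)

    @classmethod
    def parse(cls, text: str) -> "SlnPattern":
        positions: list[frozenset] = []
        i = 0
        while i < len(text):
            ch = text[i]
            if ch == "[":
                j = text.index("]", i)
                positions.append(frozenset(text[i + 1 : j]))
                i = j + 1
            elif ch == "x":
                positions.append(_FULL_SET)
                i += 1
            else:
                positions.append(frozenset(ch))
                i += 1
        return cls(tuple(positions))

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SlaapPattern:
    """Gapped amino-acid pattern: fixed residues with 0/1-wildcard gaps."""

    fixed: str
    gaps: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not 3 <= len(self.fixed) <= 4:
            raise ValueError("3 or 4 fixed residues required")
        if len(self.gaps) != len(self.fixed) - 1:
            raise ValueError("one gap flag per adjacent residue pair required")
        if any(aa not in _AA_INDEX for aa in self.fixed):
            raise ValueError(f"non-standard residue in {self.fixed!r}")

    @property
    def text(self) -> str:
        parts = [self.fixed[0]]
        for aa, gap in zip(self.fixed[1:], self.gaps):
            if gap:
                parts.append("x")
            parts.append(aa)
        return "".join(parts)

    @classmethod
    def parse(cls, text: str) -> "SlaapPattern":
        fixed: list[str] = []
        gaps: list[bool] = []
        pending_gap = False
        for ch in text:
            if ch == "x":
                pending_gap = True
            else:
                if fixed:
                    gaps.append(pending_gap)
                fixed.append(ch)
                pending_gap = False
        return cls("".join(fixed), tuple(gaps))

    @property
    def span(self) -> int:
        """Window width covered by one match."""
        return len(self.fixed) + sum(self.gaps)

    @property
    def offsets(self) -> tuple[int, ...]:
        """Window offsets of the fixed residues."""
        out = [0]
        for gap in self.gaps:
            out.append(out[-1] + 1 + gap)
        return tuple(out)


@dataclass
class PatternStats:
    """Per-pattern enrichment statistics on a two-class sequence collection."""

    pattern: object
    freq_pos: float
    freq_neg: float
    a: int  # positives containing the pattern
    b: int  # positives lacking it
    c: int  # negatives containing it
    d: int  # negatives lacking it
    chi2: float
    p: float
    p_adj: float


def enumerate_slnps(length: int) -> Iterator[SlnPattern]:
    """Yield every legal nucleotide pattern of the given length exactly once.

    The space has 14 * 15^(length-2) * 14 members.
    """
    if length not in (3, 4, 5):
        raise ValueError("length must be 3, 4 or 5")
    interior = [_SUBSETS] * (length - 2)
    for combo in product(_END_SUBSETS, *interior, _END_SUBSETS):
        yield SlnPattern(tuple(combo))


def enumerate_slaaps() -> Iterator[SlaapPattern]:
    """Yield every gapped amino-acid pattern exactly once (1,312,000 total)."""
    for k in (3, 4):
        for fixed in product(AMINO_ACIDS, repeat=k):
            for gaps in product((False, True), repeat=k - 1):
                yield SlaapPattern("".join(fixed), gaps)


def _slnp_window_match(pattern: SlnPattern, window: str) -> bool:
    return all(base in subset for base, subset in zip(window, pattern.positions))


def pattern_present(pattern, sequence: str, return_spans: bool = False):
    """Test whether a pattern matches anywhere in a sequence.

    Returns a boolean, or (with ``return_spans=True``) the list of 0-based
    half-open match intervals.  Overlapping matches are all reported.
    """
    seq = sequence.upper()
    spans: list[tuple[int, int]] = []
    if isinstance(pattern, SlnPattern):
        if set(seq) - set("ACGTN"):
            raise ValueError("nucleotide pattern scanned against non-nucleotide text")
        width = len(pattern)
        for i in range(len(seq) - width + 1):
            if _slnp_window_match(pattern, seq[i : i + width]):
                if not return_spans:
                    return True
                spans.append((i, i + width))
    elif isinstance(pattern, SlaapPattern):
        width = pattern.span
        offsets = pattern.offsets
        for i in range(len(seq) - width + 1):
            window = seq[i : i + width]
            if any(aa not in _AA_INDEX for aa in window):
                continue
            if all(window[off] == aa for off, aa in zip(offsets, pattern.fixed)):
                if not return_spans:
                    return True
                spans.append((i, i + width))
    else:
        raise TypeError(f"unsupported pattern type: {type(pattern)!r}")
    return spans if return_spans else False


def chi2_presence(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 presence table, no continuity correction.

    Returns ``(statistic, p)``; a zero margin makes the statistic undefined
    and yields ``(nan, nan)``.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        return (float("nan"), float("nan"))
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return (stat, float(chi2_dist.sf(stat, 1)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# --- vectorised full-space scans -------------------------------------------


def _window_codes(seq: str, width: int, alphabet_index: dict, radix: int) -> np.ndarray:
    """Distinct base-``radix`` codes of all clean windows of ``width``."""
    idx = np.fromiter(
        (alphabet_index.get(ch, -1) for ch in seq.upper()), dtype=np.int64
    )
    if idx.size < width:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(idx, width)
    clean = (windows >= 0).all(axis=1)
    if not clean.any():
        return np.empty(0, dtype=np.int64)
    weights = radix ** np.arange(width - 1, -1, -1, dtype=np.int64)
    return np.unique(windows[clean] @ weights)


def _slnp_space_size(length: int) -> int:
    return 14 * 15 ** (length - 2) * 14


def _slnp_from_index(length: int, index: int) -> SlnPattern:
    radices = [14] + [15] * (length - 2) + [14]
    digits = []
    for r in reversed(radices):
        digits.append(index % r)
        index //= r
    digits.reverse()
    return SlnPattern(tuple(_SUBSETS[d] for d in digits))


def _slnp_presence_counts(
    seqs: Sequence[str], length: int, chunk: int = 50_000
) -> np.ndarray:
    """Number of sequences containing each pattern, over the full space.

    Works on a (n_seqs x 4^L) window-code incidence matrix multiplied by
    chunked (4^L x n_patterns) pattern-match tables, so memory stays
    bounded by the chunk size.
    """
    n_codes = 4**length
    incidence = np.zeros((len(seqs), n_codes), dtype=np.float32)
    for row, seq in enumerate(seqs):
        codes = _window_codes(seq, length, _BASE_INDEX, 4)
        incidence[row, codes] = 1.0

    # base digit of every window code at every position
    digits = np.empty((length, n_codes), dtype=np.int64)
    codes = np.arange(n_codes)
    for pos in range(length):
        digits[pos] = (codes // 4 ** (length - 1 - pos)) % 4

    # per-position membership of each base in each subset
    membership = np.zeros((len(_SUBSETS), 4), dtype=bool)
    for si, subset in enumerate(_SUBSETS):
        for base in subset:
            membership[si, _BASE_INDEX[base]] = True

    radices = [14] + [15] * (length - 2) + [14]
    total = _slnp_space_size(length)
    counts = np.empty(total, dtype=np.int64)
    for start in range(0, total, chunk):
        stop = min(start + chunk, total)
        idx = np.arange(start, stop)
        # decode subset index per position for the whole chunk
        rem = idx.copy()
        subset_idx = np.empty((length, idx.size), dtype=np.int64)
        for pos in range(length - 1, -1, -1):
            subset_idx[pos] = rem % radices[pos]
            rem //= radices[pos]
        table = np.ones((n_codes, idx.size), dtype=bool)
        for pos in range(length):
            allowed = membership[subset_idx[pos]]  # (chunk, 4)
            table &= allowed[:, digits[pos]].T
        matches = incidence @ table.astype(np.float32)
        counts[start:stop] = (matches > 0.5).sum(axis=0)
    return counts


def _rank_stats(stats: list[PatternStats]) -> list[PatternStats]:
    return sorted(stats, key=lambda s: (s.p_adj, -(s.freq_pos - s.freq_neg), s.pattern.text))


def flag_slnps(
    pos_seqs: Sequence[str],
    neg_seqs: Sequence[str],
    min_freq_diff: float = 0.05,
    alpha_adj: float = 0.01,
    lengths: Sequence[int] = (3, 4, 5),
) -> list[PatternStats]:
    """Flag nucleotide patterns enriched in the positive class.

    A pattern enters the multiple-testing family when its presence
    frequency in the positives exceeds that in the negatives by strictly
    more than ``min_freq_diff``; it is flagged when the BH-adjusted
    chi-squared p-value is below ``alpha_adj``.  Output is ranked by
    ascending adjusted p, ties broken by descending frequency difference
    then pattern text.
    """
    if not pos_seqs or not neg_seqs:
        raise ValueError("both classes must be non-empty")
    n_pos, n_neg = len(pos_seqs), len(neg_seqs)
    cand: list[tuple[int, int, int, int]] = []  # (length, index, a, c)
    for length in lengths:
        counts_pos = _slnp_presence_counts(pos_seqs, length)
        counts_neg = _slnp_presence_counts(neg_seqs, length)
        diff = counts_pos / n_pos - counts_neg / n_neg
        for index in np.nonzero(diff > min_freq_diff)[0]:
            cand.append((length, int(index), int(counts_pos[index]), int(counts_neg[index])))
    return _finalise_flags(cand, n_pos, n_neg, alpha_adj, adjusted=True, decoder="slnp")


def _finalise_flags(
    candidates: list[tuple],
    n_pos: int,
    n_neg: int,
    alpha: float,
    adjusted: bool,
    decoder: str,
) -> list[PatternStats]:
    if not candidates:
        return []
    a = np.array([c[2] for c in candidates], dtype=float)
    c_ = np.array([c[3] for c in candidates], dtype=float)
    b = n_pos - a
    d = n_neg - c_
    n = float(n_pos + n_neg)
    denom = (a + b) * (c_ + d) * (a + c_) * (b + d)
    stat = np.where(denom > 0, n * (a * d - b * c_) ** 2 / np.where(denom > 0, denom, 1), np.nan)
    p = chi2_dist.sf(stat, 1)
    p_adj = bh_adjust(np.nan_to_num(p, nan=1.0))
    select = p_adj < alpha if adjusted else p < alpha
    out: list[PatternStats] = []
    for i in np.nonzero(select)[0]:
        key = candidates[i]
        if decoder == "slnp":
            pattern: object = _slnp_from_index(key[0], key[1])
        else:
            pattern = key[0]
        out.append(
            PatternStats(
                pattern=pattern,
                freq_pos=a[i] / n_pos,
                freq_neg=c_[i] / n_neg,
                a=int(a[i]),
                b=int(b[i]),
                c=int(c_[i]),
                d=int(d[i]),
                chi2=float(stat[i]),
                p=float(p[i]),
                p_adj=float(p_adj[i]),
            )
        )
    return _rank_stats(out)


_SLAAP_SHAPES: list[tuple[int, tuple[bool, ...]]] = [
    (k, gaps) for k in (3, 4) for gaps in product((False, True), repeat=k - 1)
]


def _slaap_code_counts(seqs: Sequence[str]) -> dict[tuple[int, tuple[bool, ...]], np.ndarray]:
    """Per shape: number of sequences containing each fixed-residue code."""
    out = {}
    for k, gaps in _SLAAP_SHAPES:
        proto = SlaapPattern(AMINO_ACIDS[0] * k, gaps)
        width, offsets = proto.span, np.array(proto.offsets)
        counts = np.zeros(20**k, dtype=np.int64)
        weights = 20 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        for seq in seqs:
            idx = np.fromiter(
                (_AA_INDEX.get(ch, -1) for ch in seq.upper()), dtype=np.int64
            )
            if idx.size < width:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(idx, width)
            clean = (windows >= 0).all(axis=1)
            if not clean.any():
                continue
            codes = np.unique(windows[clean][:, offsets] @ weights)
            counts[codes] += 1
        out[(k, gaps)] = counts
    return out


def _slaap_from_code(k: int, gaps: tuple[bool, ...], code: int) -> SlaapPattern:
    residues = []
    for _ in range(k):
        residues.append(AMINO_ACIDS[code % 20])
        code //= 20
    return SlaapPattern("".join(reversed(residues)), gaps)


def flag_slaaps(
    pos_seqs: Sequence[str],
    neg_seqs: Sequence[str],
    alpha: float = 0.05,
    min_freq_diff: float = 0.0,
    use_adjusted: bool = False,
) -> list[PatternStats]:
    """Flag amino-acid patterns enriched in the positive class.

    Direction requirement: presence frequency strictly higher in positives.
    Selection is on the raw chi-squared p-value by default (BH-adjusted
    values are still computed and reported); pass ``use_adjusted=True`` to
    select on the adjusted p instead.
    """
    if not pos_seqs or not neg_seqs:
        raise ValueError("both classes must be non-empty")
    n_pos, n_neg = len(pos_seqs), len(neg_seqs)
    counts_pos = _slaap_code_counts(pos_seqs)
    counts_neg = _slaap_code_counts(neg_seqs)
    cand: list[tuple] = []
    for shape in _SLAAP_SHAPES:
        cp, cn = counts_pos[shape], counts_neg[shape]
        diff = cp / n_pos - cn / n_neg
        for code in np.nonzero(diff > min_freq_diff)[0]:
            pattern = _slaap_from_code(shape[0], shape[1], int(code))
            cand.append((pattern, None, int(cp[code]), int(cn[code])))
    return _finalise_flags(cand, n_pos, n_neg, alpha, adjusted=use_adjusted, decoder="slaap")


def top_k(flagged: Sequence[PatternStats], k: int = 100) -> list[PatternStats]:
    """First ``k`` of an already-ranked flag list (all if fewer)."""
    return list(flagged[: max(k, 0)])


def co_occurrence_count(flagged_patterns: Sequence, sequence: str) -> int:
    """Number of flagged patterns with at least one match in the sequence."""
    return sum(1 for p in flagged_patterns if pattern_present(p, sequence))


def idr_conditional_frequency(
    pattern,
    proteins: Sequence[str],
    disorder_scores: Sequence[Sequence[float]],
    threshold: float = 0.5,
    min_run: int = 1,
) -> float:
    """Fraction of pattern matches lying fully inside a disordered region.

    Disordered regions are maximal runs of residues with score >=
    ``threshold`` (at least ``min_run`` residues long).  Matches are pooled
    over all proteins that contain the pattern; a match counts as
    disordered only when its whole span sits inside one region.
    """
    total = 0
    inside = 0
    for protein, scores in zip(proteins, disorder_scores):
        if len(protein) != len(scores):
            raise ValueError("disorder scores misaligned with protein length")
        spans = pattern_present(pattern, protein, return_spans=True)
        if not spans:
            continue
        regions: list[tuple[int, int]] = []
        start = None
        for i, s in enumerate(list(scores) + [-np.inf]):
            if s >= threshold and start is None:
                start = i
            elif s < threshold and start is not None:
                if i - start >= min_run:
                    regions.append((start, i))
                start = None
        for lo, hi in spans:
            total += 1
            if any(lo >= rlo and hi <= rhi for rlo, rhi in regions):
                inside += 1
    if total == 0:
        raise ValueError("pattern matches no protein in the collection")
    return inside / total


def read_disorder_scores(path) -> dict[str, list[float]]:
    """Read per-residue disorder scores (TSV: protein_id, position, score).

    Positions are 1-based and must be contiguous from 1 for each protein.
    """
    raw: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            raw.setdefault(row["protein_id"], {})[int(row["position"])] = float(
                row["score"]
            )
    out = {}
    for pid, by_pos in raw.items():
        n = max(by_pos)
        if sorted(by_pos) != list(range(1, n + 1)):
            raise ValueError(f"non-contiguous disorder positions for {pid}")
        out[pid] = [by_pos[i] for i in range(1, n + 1)]
    return out


def write_pattern_stats(stats: Iterable[PatternStats], path) -> None:
    """Write enrichment statistics as TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["pattern", "freq_pos", "freq_neg", "chi2", "p", "p_adj"])
        for s in stats:
            writer.writerow(
                [s.pattern.text, f"{s.freq_pos:.6g}", f"{s.freq_neg:.6g}",
                 f"{s.chi2:.6g}", f"{s.p:.6g}", f"{s.p_adj:.6g}"]
            )
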