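"""Breakpoint-window dataset construction.

Builds fixed-length sequence windows around structural-variant breakpoints
(and matched background locations), computes per-window genomic annotation
features, one-hot encodes sequences, and partitions samples into
train/validation/test splits with no genomic position shared across splits.

Coordinate conventions: 0-based half-open everywhere internally; the VCF
boundary (1-based POS) is handled by :mod:`svcontext.io`.  Insertion records
have ``end == start``.  Windows for deletions/inversions join the two
breakpoint flanks, placing the junction exactly at position L/2; the
deleted/inverted interior is never part of the window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SamplingError, WindowRejected

logger = logging.getLogger(__name__)

#: one-hot channel order
BASES = "ATCG"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SVTYPES = ("INS", "DEL", "INV")
REPEAT_CLASSES = ("SINE/Alu", "LINE/L1", "Retroposon/SVA", "simple_repeat",
                  "non_repetitive", "unlabeled")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SVRecord:
    """One structural variant (0-based half-open breakpoints)."""

    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    id: str
    alt_seq: Optional[str] = None
    allele_frequency: Optional[float] = None
    repeat_class: str = "unlabeled"

    def __post_init__(self):
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.svtype in ("DEL", "INV") and self.end - self.start != self.length:
            raise ValueError(f"{self.svtype} must satisfy end - start == length")

    @property
    def breakpoints(self) -> tuple[int, ...]:
        if self.svtype == "INS":
            return (self.start,)
        return (self.start, self.end)


@dataclass
class GenomicWindow:
    """A context window of exactly ``len(seq)`` contiguous A/C/G/T bases.

    ``anchors`` holds the single centre position for insertion/background
    windows or the two breakpoints for flank-joined deletion/inversion
    windows.
    """

    seq: str
    chrom: str
    anchors: tuple[int, ...]
    label: str                      # "sv" | "background"
    source_class: str = "background"
    split: str = "unassigned"
    source_id: Optional[str] = None

    def __post_init__(self):
        if any(b not in _BASE_INDEX for b in self.seq):
            raise ValueError("window sequence must contain only A/C/G/T")
        if len(self.anchors) not in (1, 2):
            raise ValueError("windows have one or two anchors")

    @property
    def context_length(self) -> int:
        return len(self.seq)

    def spans(self) -> list[tuple[int, int]]:
        """Physical reference interval(s) the window sequence came from."""
        half = len(self.seq) // 2
        if len(self.anchors) == 1:
            c = self.anchors[0]
            return [(c - half, c + half)]
        a, b = self.anchors
        return [(a - half, a), (b, b + half)]


class IntervalSet:
    """Sorted, half-open intervals on one genome, keyed by chromosome."""

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                self.add_chrom(chrom, ivs)

    def add_chrom(self, chrom: str, ivs: Sequence[tuple[int, int]]):
        if len(ivs) == 0:
            starts = np.empty(0, dtype=np.int64)
            ends = np.empty(0, dtype=np.int64)
        else:
            arr = np.asarray(sorted(ivs), dtype=np.int64)
            starts, ends = arr[:, 0], arr[:, 1]
        self._starts[chrom] = starts
        self._ends[chrom] = ends

    def chroms(self):
        return list(self._starts)

    def intervals(self, chrom: str):
        s = self._starts.get(chrom, np.empty(0, dtype=np.int64))
        e = self._ends.get(chrom, np.empty(0, dtype=np.int64))
        return list(zip(s.tolist(), e.tolist()))

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        s = self._starts.get(chrom)
        if s is None or len(s) == 0:
            return 0
        e = self._ends[chrom]
        # interval [a,b) overlaps [start,end) iff a < end and b > start
        return int(np.count_nonzero((s < end) & (e > start)))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.count_overlapping(chrom, start, end) > 0

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        s = self._starts.get(chrom)
        if s is None or len(s) == 0:
            return 0
        e = self._ends[chrom]
        lo = np.minimum(e, end)
        hi = np.maximum(s, start)
        return int(np.maximum(lo - hi, 0).sum())

    def nearest_distance(self, chrom: str, pos: int) -> float:
        """Distance from ``pos`` to the nearest interval edge; 0 inside."""
        s = self._starts.get(chrom)
        if s is None or len(s) == 0:
            return math.inf
        e = self._ends[chrom]
        inside = (s <= pos) & (pos < e)
        if inside.any():
            return 0.0
        d = np.minimum(np.abs(s - pos), np.abs(e - 1 - pos))
        return float(d.min())


class PointSet:
    """Deduplicated sorted genomic positions keyed by chromosome."""

    def __init__(self, points: Mapping[str, Sequence[int]] | None = None):
        self._pos: dict[str, np.ndarray] = {}
        if points:
            for chrom, ps in points.items():
                self._pos[chrom] = np.unique(np.asarray(ps, dtype=np.int64))

    def chroms(self):
        return list(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        p = self.positions(chrom)
        return int(np.searchsorted(p, end) - np.searchsorted(p, start))

    def any_in(self, chrom: str, start: int, end: int) -> bool:
        return self.count_in(chrom, start, end) > 0

    def __len__(self):
        return sum(len(v) for v in self._pos.values())


class BreakpointIndex:
    """SV breakpoints with owner ids, for neighbour counts that can
    exclude the focal variant's own breakpoints."""

    def __init__(self, records: Iterable[SVRecord]):
        by_type: dict[str, dict[str, list[tuple[int, str]]]] = {t: {} for t in SVTYPES}
        for r in records:
            for bp in r.breakpoints:
                by_type[r.svtype].setdefault(r.chrom, []).append((bp, r.id))
        self._pos: dict[str, dict[str, np.ndarray]] = {}
        self._ids: dict[str, dict[str, np.ndarray]] = {}
        for t, chroms in by_type.items():
            self._pos[t], self._ids[t] = {}, {}
            for chrom, pairs in chroms.items():
                pairs.sort()
                self._pos[t][chrom] = np.array([p for p, _ in pairs], dtype=np.int64)
                self._ids[t][chrom] = np.array([i for _, i in pairs], dtype=object)

    def count_in(self, svtype: str, chrom: str, start: int, end: int,
                 exclude_id: Optional[str] = None) -> int:
        pos = self._pos.get(svtype, {}).get(chrom)
        if pos is None or len(pos) == 0:
            return 0
        lo, hi = np.searchsorted(pos, start), np.searchsorted(pos, end)
        n = int(hi - lo)
        if exclude_id is not None and n:
            n -= int(np.count_nonzero(self._ids[svtype][chrom][lo:hi] == exclude_id))
        return n

    def all_positions(self) -> dict[str, np.ndarray]:
        merged: dict[str, list] = {}
        for t in self._pos:
            for chrom, pos in self._pos[t].items():
                merged.setdefault(chrom, []).append(pos)
        return {c: np.unique(np.concatenate(v)) for c, v in merged.items()}


class ConservationTrack:
    """Step-function per-base signal (bedGraph semantics)."""

    def __init__(self, segments: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._seg: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, segs in segments.items():
            arr = sorted(segs)
            s = np.array([a for a, _, _ in arr], dtype=np.int64)
            e = np.array([b for _, b, _ in arr], dtype=np.int64)
            v = np.array([x for _, _, x in arr], dtype=np.float64)
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping bedGraph segments on {chrom}")
            self._seg[chrom] = (s, e, v)

    def chroms(self):
        return list(self._seg)

    def segments(self, chrom: str):
        s, e, v = self._seg.get(chrom, (np.empty(0), np.empty(0), np.empty(0)))
        return list(zip(s.tolist(), e.tolist(), v.tolist()))

    def mean_over(self, chrom: str, start: int, end: int) -> tuple[float, float]:
        """(mean value with uncovered bases imputed 0, covered fraction)."""
        length = end - start
        if length <= 0:
            return 0.0, 0.0
        seg = self._seg.get(chrom)
        if seg is None:
            return 0.0, 0.0
        s, e, v = seg
        lo = np.maximum(s, start)
        hi = np.minimum(e, end)
        w = np.maximum(hi - lo, 0)
        covered = int(w.sum())
        total = float((w * v).sum())
        return total / length, covered / length


@dataclass
class AnnotationBundle:
    """Everything the feature registry reads, indexed per chromosome."""

    intervals: dict[str, IntervalSet] = field(default_factory=dict)
    points: dict[str, PointSet] = field(default_factory=dict)
    sv_breakpoints: Optional[BreakpointIndex] = None
    conservation: Optional[ConservationTrack] = None


# ---------------------------------------------------------------------------
# Reference access
# ---------------------------------------------------------------------------

def get_seq(reference, chrom: str, start: int, end: int) -> str:
    """Slice a reference that is either a plain mapping of strings or a
    ``pyfaidx.Fasta`` handle."""
    seq = reference[chrom][start:end]
    return str(seq).upper()


def chrom_lengths(reference) -> dict[str, int]:
    return {c: len(reference[c]) for c in _chrom_names(reference)}


def _chrom_names(reference):
    if hasattr(reference, "keys"):
        return list(reference.keys())
    return list(reference.references)  # pyfaidx-like


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_window(reference, record_or_position, context_length: int,
                   label: str = "sv", source_class: Optional[str] = None) -> GenomicWindow:
    """Build the context window for an SV record or a plain position.

    Insertion and background windows are centred on the single anchor;
    deletion/inversion windows join the L/2 bp immediately upstream of the
    left breakpoint with the L/2 bp immediately downstream of the right
    breakpoint.  Windows that would run past a chromosome end or contain a
    non-ACGT base raise :class:`WindowRejected`.
    """
    if context_length % 2:
        raise ConfigurationError("context_length must be even")
    half = context_length // 2
    if isinstance(record_or_position, SVRecord):
        rec = record_or_position
        chrom = rec.chrom
        if rec.svtype == "INS" or rec.end == rec.start:
            anchors = (rec.start,)
        else:
            anchors = (rec.start, rec.end)
        source_class = source_class if source_class is not None else rec.repeat_class
        source_id = rec.id
    else:
        chrom, pos = record_or_position
        anchors = (int(pos),)
        source_class = source_class if source_class is not None else "background"
        source_id = None

    clen = len(reference[chrom])
    if len(anchors) == 1:
        c = anchors[0]
        if c - half < 0 or c + half > clen:
            raise WindowRejected(f"window at {chrom}:{c} runs past chromosome end")
        seq = get_seq(reference, chrom, c - half, c + half)
    else:
        a, b = anchors
        if a - half < 0 or b + half > clen:
            raise WindowRejected(f"window at {chrom}:{a}-{b} runs past chromosome end")
        seq = get_seq(reference, chrom, a - half, a) + get_seq(reference, chrom, b, b + half)
    if any(ch not in _BASE_INDEX for ch in seq):
        raise WindowRejected(f"window at {chrom}:{anchors} contains non-ACGT bases")
    return GenomicWindow(seq=seq, chrom=chrom, anchors=anchors, label=label,
                         source_class=source_class, source_id=source_id)


def extract_sv_windows(reference, records: Iterable[SVRecord],
                       context_length: int) -> tuple[list[GenomicWindow], int]:
    """Extract windows for all records, dropping rejected ones.

    Returns ``(windows, n_rejected)``.
    """
    windows, rejected = [], 0
    for rec in records:
        try:
            windows.append(extract_window(reference, rec, context_length))
        except WindowRejected:
            rejected += 1
    if rejected:
        logger.info("dropped %d windows (chromosome edge or non-ACGT)", rejected)
    return windows, rejected


def sample_background(reference, forbidden_breakpoints: Mapping[str, np.ndarray],
                      n: int, context_length: int, seed: int = 42,
                      max_tries_per_window: int = 200) -> list[GenomicWindow]:
    """Sample ``n`` background windows whose spans avoid all forbidden
    breakpoints; anchors are unique and length-weighted across chromosomes."""
    rng = np.random.default_rng(seed)
    lengths = chrom_lengths(reference)
    chroms = sorted(lengths)
    half = context_length // 2
    weights = np.array([max(lengths[c] - context_length, 0) for c in chroms], float)
    if n > 0 and weights.sum() <= 0:
        raise SamplingError("no chromosome long enough for the context length")
    weights = weights / weights.sum() if weights.sum() else weights
    forbidden = {c: np.sort(np.asarray(p, dtype=np.int64))
                 for c, p in forbidden_breakpoints.items()}
    out: list[GenomicWindow] = []
    used: set[tuple[str, int]] = set()
    tries = 0
    budget = max_tries_per_window * max(n, 1)
    while len(out) < n:
        if tries >= budget:
            raise SamplingError(
                f"placed only {len(out)}/{n} background windows after {tries} tries")
        tries += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        anchor = int(rng.integers(half, lengths[chrom] - half + 1))
        if (chrom, anchor) in used:
            continue
        fb = forbidden.get(chrom)
        if fb is not None and len(fb):
            lo = np.searchsorted(fb, anchor - half)
            hi = np.searchsorted(fb, anchor + half)
            if hi > lo:
                continue
        try:
            w = extract_window(reference, (chrom, anchor), context_length,
                               label="background")
        except WindowRejected:
            continue
        used.add((chrom, anchor))
        out.append(w)
    return out


def sample_matched_negatives(reference, sv_records: Sequence[SVRecord],
                             kind: str, context_length: int, seed: int = 42,
                             forbidden_breakpoints: Optional[Mapping[str, np.ndarray]] = None,
                             max_tries_per_window: int = 500) -> list[GenomicWindow]:
    """Breakpoint-structure-matched negatives for deletions/inversions.

    For each positive of the requested kind a simulated event length is
    drawn from the empirical length distribution of the positives, a first
    breakpoint is placed uniformly on a random chromosome, and the window is
    built by the same flank-joining rule as real events.  Neither flank may
    contain a known SV breakpoint.
    """
    if kind not in ("DEL", "INV"):
        raise ConfigurationError("matched negatives are defined for DEL and INV")
    positives = [r for r in sv_records if r.svtype == kind]
    if not positives:
        return []
    lengths_emp = np.array([r.length for r in positives], dtype=np.int64)
    rng = np.random.default_rng(seed)
    clens = chrom_lengths(reference)
    chroms = sorted(clens)
    half = context_length // 2
    if forbidden_breakpoints is None:
        forbidden_breakpoints = BreakpointIndex(sv_records).all_positions()
    forbidden = {c: np.sort(np.asarray(p, dtype=np.int64))
                 for c, p in forbidden_breakpoints.items()}
    out: list[GenomicWindow] = []
    tries, budget = 0, max_tries_per_window * len(positives)
    while len(out) < len(positives):
        if tries >= budget:
            raise SamplingError(
                f"placed only {len(out)}/{len(positives)} matched negatives")
        tries += 1
        ev_len = int(rng.choice(lengths_emp))
        chrom = chroms[int(rng.integers(len(chroms)))]
        span = clens[chrom] - ev_len - context_length
        if span <= 0:
            continue
        bp1 = int(rng.integers(half, clens[chrom] - ev_len - half + 1))
        bp2 = bp1 + ev_len
        fb = forbidden.get(chrom)
        if fb is not None and len(fb):
            hits = (np.searchsorted(fb, bp1) - np.searchsorted(fb, bp1 - half)
                    + np.searchsorted(fb, bp2 + half) - np.searchsorted(fb, bp2))
            if hits:
                continue
        try:
            seq = (get_seq(reference, chrom, bp1 - half, bp1)
                   + get_seq(reference, chrom, bp2, bp2 + half))
            w = GenomicWindow(seq=seq, chrom=chrom, anchors=(bp1, bp2),
                              label="background", source_class="background")
        except ValueError:
            continue
        out.append(w)
    return out


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def one_hot_encode(window_or_seq) -> np.ndarray:
    """One-hot encode over four channels in A,T,C,G order -> (L, 4)."""
    seq = window_or_seq.seq if isinstance(window_or_seq, GenomicWindow) else window_or_seq
    idx = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        try:
            idx[i] = _BASE_INDEX[ch]
        except KeyError:
            raise ValueError(f"cannot encode base {ch!r}") from None
    out = np.zeros((len(seq), 4), dtype=np.float32)
    out[np.arange(len(seq)), idx] = 1.0
    return out


def one_hot_decode(matrix: np.ndarray) -> str:
    return "".join(BASES[i] for i in np.argmax(matrix, axis=-1))


def encode_batch(windows: Sequence[GenomicWindow | str]) -> np.ndarray:
    """Stack windows into a CNN-ready (N, 4, L) tensor."""
    return np.stack([one_hot_encode(w).T for w in windows])


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def _count_points(window, bundle, key):
    ps = bundle.points.get(key)
    if ps is None:
        return 0.0
    return float(sum(ps.count_in(window.chrom, s, e) for s, e in window.spans()))


def _count_breakpoints(window, bundle, svtype):
    if bundle.sv_breakpoints is None:
        return 0.0
    return float(sum(bundle.sv_breakpoints.count_in(svtype, window.chrom, s, e,
                                                    exclude_id=window.source_id)
                     for s, e in window.spans()))


def _distance_to(window, bundle, key):
    ivs = bundle.intervals.get(key)
    if ivs is None:
        return float("inf")
    if any(ivs.overlaps(window.chrom, s, e) for s, e in window.spans()):
        return 0.0
    return min(ivs.nearest_distance(window.chrom, a) for a in window.anchors)


def _gc_content(window, bundle):
    return (window.seq.count("G") + window.seq.count("C")) / len(window.seq)


def _mean_conservation(window, bundle):
    if bundle.conservation is None:
        return 0.0
    vals = [bundle.conservation.mean_over(window.chrom, s, e) for s, e in window.spans()]
    return float(np.mean([m for m, _ in vals]))


def _conservation_coverage(window, bundle):
    if bundle.conservation is None:
        return 0.0
    vals = [bundle.conservation.mean_over(window.chrom, s, e) for s, e in window.spans()]
    return float(np.mean([c for _, c in vals]))


def _count_intervals(window, bundle, key):
    ivs = bundle.intervals.get(key)
    if ivs is None:
        return 0.0
    return float(sum(ivs.count_overlapping(window.chrom, s, e) for s, e in window.spans()))


FEATURE_REGISTRY = {
    "n_snp": lambda w, b: _count_points(w, b, "snp"),
    "n_small_ins": lambda w, b: _count_points(w, b, "small_ins"),
    "n_small_del": lambda w, b: _count_points(w, b, "small_del"),
    "n_large_ins": lambda w, b: _count_breakpoints(w, b, "INS"),
    "n_large_del": lambda w, b: _count_breakpoints(w, b, "DEL"),
    "n_inversion": lambda w, b: _count_breakpoints(w, b, "INV"),
    "gc_content": _gc_content,
    "mean_conservation": _mean_conservation,
    "conservation_coverage": _conservation_coverage,
    "dist_simple_repeat": lambda w, b: _distance_to(w, b, "simple_repeat"),
    "dist_alu": lambda w, b: _distance_to(w, b, "alu"),
    "dist_l1": lambda w, b: _distance_to(w, b, "l1"),
    "dist_exon": lambda w, b: _distance_to(w, b, "exon"),
    "n_genes": lambda w, b: _count_intervals(w, b, "gene"),
    "n_regulatory": lambda w, b: _count_intervals(w, b, "regulatory"),
}

DEFAULT_FEATURES = [
    "n_snp", "n_small_ins", "n_small_del", "n_large_ins", "n_large_del",
    "n_inversion", "gc_content", "mean_conservation", "conservation_coverage",
    "dist_simple_repeat", "dist_alu", "dist_l1", "dist_exon", "n_genes",
]

#: finite stand-in for "no annotated interval on this chromosome"
_MAX_DISTANCE = 1e9


def compute_features(window: GenomicWindow, bundle: AnnotationBundle,
                     registry: Sequence[str] = DEFAULT_FEATURES) -> dict[str, float]:
    """Evaluate registry features over the window's physical interval(s)."""
    out = {}
    for name in registry:
        try:
            fn = FEATURE_REGISTRY[name]
        except KeyError:
            raise ConfigurationError(f"unknown feature {name!r}") from None
        val = fn(window, bundle)
        if math.isinf(val):
            val = _MAX_DISTANCE
        out[name] = val
    return out


def build_feature_table(windows: Sequence[GenomicWindow], bundle: AnnotationBundle,
                        registry: Sequence[str] = DEFAULT_FEATURES) -> pd.DataFrame:
    """Feature table with provenance columns and a binary ``label`` column."""
    rows = []
    for w in windows:
        row = {"chrom": w.chrom, "anchor": w.anchors[0],
               "source_class": w.source_class, "split": w.split,
               "label": 1 if w.label == "sv" else 0}
        row.update(compute_features(w, bundle, registry))
        rows.append(row)
    df = pd.DataFrame(rows)
    assert not df.isna().any().any(), "feature table must be total after imputation"
    return df


# ---------------------------------------------------------------------------
# Repeat-class labelling
# ---------------------------------------------------------------------------

def label_repeat_class(record: SVRecord,
                       repeat_annotations: Mapping[str, IntervalSet],
                       threshold: float = 0.8) -> str:
    """Assign a repeat class from annotation coverage of the SV span.

    A single overlapping repeat class must cover >= 80% of the SV sequence;
    with multiple overlapping classes, the class covering >= 80% of the
    total repetitive content wins; otherwise ``non_repetitive``.  Insertion
    records (no reference span) keep their existing label.
    """
    if record.end == record.start:
        return record.repeat_class
    sv_len = record.end - record.start
    coverage = {}
    for cls, ivs in repeat_annotations.items():
        ov = ivs.overlap_length(record.chrom, record.start, record.end)
        if ov > 0:
            coverage[cls] = ov
    if not coverage:
        return "non_repetitive"
    if len(coverage) == 1:
        (cls, ov), = coverage.items()
        return cls if ov >= threshold * sv_len else "non_repetitive"
    repetitive_total = sum(coverage.values())
    cls, ov = max(coverage.items(), key=lambda kv: kv[1])
    return cls if ov >= threshold * repetitive_total else "non_repetitive"


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_dataset(n_samples: int, fractions=(0.6, 0.2, 0.2), seed: int = 42,
                  groups: Optional[Sequence] = None):
    """Partition ``range(n_samples)`` into train/val/test index arrays.

    Test size is ``ceil(f_test * n)``; validation is the ceiling of the
    corresponding fraction of the remainder (so 347,648 samples at 60/20/20
    give 208,588 / 69,530 / 69,530).  Samples sharing a group key (genomic
    anchor) always land in the same split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("fractions must sum to 1")
    f_train, f_val, f_test = fractions
    n_test = math.ceil(f_test * n_samples)
    rem = n_samples - n_test
    n_val = math.ceil(f_val / (f_train + f_val) * rem) if rem else 0
    rng = np.random.default_rng(seed)
    if groups is None:
        order = rng.permutation(n_samples)
        test = order[:n_test]
        val = order[n_test:n_test + n_val]
        train = order[n_test + n_val:]
        return np.sort(train), np.sort(val), np.sort(test)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    uniq = uniq[rng.permutation(len(uniq))]
    members = pd.Series(np.arange(n_samples)).groupby(groups, sort=False).apply(
        lambda s: s.to_numpy())
    test_idx, val_idx, train_idx = [], [], []
    n_assigned_test = n_assigned_val = 0
    for g in uniq:
        m = members[g]
        if n_assigned_test < n_test:
            test_idx.append(m)
            n_assigned_test += len(m)
        elif n_assigned_val < n_val:
            val_idx.append(m)
            n_assigned_val += len(m)
        else:
            train_idx.append(m)
    cat = lambda parts: (np.sort(np.concatenate(parts)) if parts
                         else np.empty(0, dtype=np.int64))
    return cat(train_idx), cat(val_idx), cat(test_idx)


def assign_splits(windows: Sequence[GenomicWindow], fractions=(0.6, 0.2, 0.2),
                  seed: int = 42) -> None:
    """Stamp each window's ``split`` in place, grouping by genomic anchor."""
    groups = [f"{w.chrom}:{w.anchors[0]}" for w in windows]
    train, val, test = split_dataset(len(windows), fractions, seed, groups)
    for i in train:
        windows[i].split = "train"
    for i in val:
        windows[i].split = "val"
    for i in test:
        windows[i].split = "test"
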