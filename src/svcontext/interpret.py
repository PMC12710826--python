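"""Model interpretability: k-mer enrichment and insertion scans,
microhomology pair perturbations, non-B DNA motif effects, in-silico
saturation mutagenesis, feature importances, Jensen-Shannon feature
divergence, and the Spearman correlation matrix.

All perturbation operations measure ``delta = p(modified) - p(original)``
on background windows and are pure with respect to their inputs.  Any
object exposing ``predict_proba`` over one-hot ``(N, 4, L)`` batches or a
``predict_seqs(list[str])`` method can serve as the model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .dataset import BASES, GenomicWindow, encode_batch
from .errors import ConfigurationError

__all__ = [
    "DeltaProbabilityResult", "ISMMap", "ImportanceRecord", "JSDRecord",
    "kmer_enrichment", "insert_motif", "kmer_insertion_scan",
    "pair_similarity", "microhomology_scan", "empirical_breakpoint_homology",
    "generate_nonb_motifs", "nonb_insertion_effect", "ism",
    "substitution_motif_effect", "permutation_importance", "importance_shift",
    "jsd", "jsd_from_histograms", "correlation_matrix",
]


def _seqs(windows) -> list[str]:
    return [w.seq if isinstance(w, GenomicWindow) else str(w) for w in windows]


def _predict(model, seqs: Sequence[str], batch_size: int = 1024) -> np.ndarray:
    if hasattr(model, "predict_seqs"):
        return np.asarray(model.predict_seqs(list(seqs)), dtype=np.float64)
    return model.predict_proba(encode_batch(list(seqs)), batch_size=batch_size)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class DeltaProbabilityResult:
    motif: str
    n_insertions: int
    mean_delta: float
    sd_delta: float
    deltas: Optional[np.ndarray] = None


@dataclass
class ISMMap:
    radius: int
    matrix: np.ndarray              # (2*radius+1, 4) mean deltas
    base_order: str
    n_sequences: int
    nucleotide_freqs: np.ndarray    # (2*radius+1, 4) empirical frequencies

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.radius, self.radius + 1)

    def to_pwm_text(self) -> str:
        """Position-weight-matrix style text export for logo rendering."""
        lines = ["offset\t" + "\t".join(self.base_order)]
        for off, row in zip(self.offsets, self.matrix):
            lines.append(str(off) + "\t" + "\t".join(f"{v:.6g}" for v in row))
        return "\n".join(lines) + "\n"


@dataclass
class ImportanceRecord:
    feature: str
    gini_importance: float
    permutation_mean: float
    permutation_sd: float


@dataclass
class JSDRecord:
    value: float
    n_bins: int
    bin_edges: Optional[np.ndarray] = None
    feature: str = ""
    sv_class: str = ""


# ---------------------------------------------------------------------------
# k-mer enrichment
# ---------------------------------------------------------------------------

def _count_kmers(seqs: Sequence[str], k: int):
    from collections import Counter
    counts = Counter()
    total = 0
    for s in seqs:
        total += max(len(s) - k + 1, 0)
        for i in range(len(s) - k + 1):
            counts[s[i:i + k]] += 1
    return counts, total


def kmer_enrichment(sv_windows, bg_windows, k: int, alpha: float = 0.05) -> pd.DataFrame:
    """Global sliding-window k-mer enrichment of SV vs background windows.

    ``enrichment = log2((c_sv + 1)/(c_bg + 1) * (T_bg + 4^k)/(T_sv + 4^k))``
    with a two-sided binomial test against the (pseudocounted) background
    proportion and Benjamini-Hochberg correction.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    sv, bg = _seqs(sv_windows), _seqs(bg_windows)
    if any(len(s) < k for s in sv + bg):
        raise ConfigurationError("k exceeds window length")
    c_sv, t_sv = _count_kmers(sv, k)
    c_bg, t_bg = _count_kmers(bg, k)
    n_kmers = 4 ** k
    if k <= 8:
        universe = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    else:
        universe = sorted(set(c_sv) | set(c_bg))
    rows = []
    for mer in universe:
        a, b = c_sv.get(mer, 0), c_bg.get(mer, 0)
        enr = np.log2((a + 1) / (b + 1) * (t_bg + n_kmers) / (t_sv + n_kmers))
        p0 = (b + 1) / (t_bg + n_kmers)
        pval = stats.binomtest(a, t_sv, min(p0, 1.0)).pvalue if t_sv else 1.0
        rows.append({"kmer": mer, "count_sv": a, "count_bg": b,
                     "enrichment": enr, "pvalue": pval})
    df = pd.DataFrame(rows)
    df["qvalue"] = stats.false_discovery_control(df["pvalue"], method="bh")
    df["significant"] = df["qvalue"] < alpha
    return df


# ---------------------------------------------------------------------------
# Motif insertion
# ---------------------------------------------------------------------------

def insert_motif(window, motif: str, position: int) -> str:
    """Splice ``motif`` in at ``position`` and trim back to the original
    length, trimming the end on the insertion's side so the base at the
    central coordinate stays at index L/2."""
    seq = window.seq if isinstance(window, GenomicWindow) else str(window)
    L = len(seq)
    if not 0 <= position < L:
        raise ConfigurationError("position must lie in [0, L)")
    if len(motif) >= L // 2:
        raise ConfigurationError("motif must be shorter than half the window")
    spliced = seq[:position] + motif + seq[position:]
    if position < L // 2:
        return spliced[len(motif):]
    return spliced[:L]


def kmer_insertion_scan(model, bg_windows, k: int = 5, n_positions: int = 50,
                        seed: int = 42, batch_size: int = 2048,
                        keep_deltas: bool = False) -> list[DeltaProbabilityResult]:
    """Insert every k-mer at shared random positions in each background
    window and report the mean probability change per k-mer."""
    seqs = _seqs(bg_windows)
    if not seqs:
        raise ConfigurationError("need at least one background window")
    L = len(seqs[0])
    rng = np.random.default_rng(seed)
    positions = [rng.integers(0, L, size=n_positions) for _ in seqs]
    base_p = _predict(model, seqs)
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    results = []
    for mer in kmers:
        mods, refs = [], []
        for seq, pos, p0 in zip(seqs, positions, base_p):
            for pp in pos:
                mods.append(insert_motif(seq, mer, int(pp)))
                refs.append(p0)
        deltas = _predict(model, mods, batch_size) - np.asarray(refs)
        results.append(DeltaProbabilityResult(
            motif=mer, n_insertions=len(deltas),
            mean_delta=float(deltas.mean()), sd_delta=float(deltas.std()),
            deltas=deltas if keep_deltas else None))
    return results


# ---------------------------------------------------------------------------
# Microhomology
# ---------------------------------------------------------------------------

def pair_similarity(a: str, b: str) -> float:
    """Fraction of positions with identical bases (forward strand)."""
    if len(a) != len(b):
        raise ConfigurationError("k-mers must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _mutate_positions(rng, mer: str, n_mismatch: int) -> str:
    idx = rng.choice(len(mer), size=n_mismatch, replace=False)
    out = list(mer)
    for i in idx:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _paired_insert(seq: str, m: str, m2: str, d: int) -> str:
    """Left copy ends at center-d, right copy starts at center+d; k bases
    trimmed from each end so the central base keeps its index."""
    L, k, c = len(seq), len(m), len(seq) // 2
    return seq[k:c - d] + m + seq[c - d:c + d] + m2 + seq[c + d:L - k]


def microhomology_scan(model, bg_windows, k: int, n_pairs: int = 100,
                       n_distances: int = 50, seed: int = 42,
                       batch_size: int = 2048):
    """Symmetric k-mer pair insertions around the window centre.

    Pairs sweep similarity from 0 mismatches (identity) to k mismatches;
    each pair is inserted at shared random centre distances in every
    window, both members applied before a single evaluation.  Returns
    ``(per-pair table, binned summary, (spearman_rho, pvalue))`` where the
    trend is mean delta vs pair similarity.
    """
    seqs = _seqs(bg_windows)
    if not seqs:
        raise ConfigurationError("need at least one background window")
    L = len(seqs[0])
    if L // 2 - k - 1 < 2:
        raise ConfigurationError("window too short for this k")
    rng = np.random.default_rng(seed)
    distances = rng.integers(1, L // 2 - k - 1, size=n_distances)
    base_p = _predict(model, seqs)
    rows = []
    for pi in range(n_pairs):
        n_mismatch = pi % (k + 1)
        m = "".join(rng.choice(list("ACGT"), size=k))
        m2 = m if n_mismatch == 0 else _mutate_positions(rng, m, n_mismatch)
        sim = pair_similarity(m, m2)
        mods, refs = [], []
        for seq, p0 in zip(seqs, base_p):
            for d in distances:
                mods.append(_paired_insert(seq, m, m2, int(d)))
                refs.append(p0)
        deltas = _predict(model, mods, batch_size) - np.asarray(refs)
        rows.append({"pair": pi, "kmer": m, "kmer2": m2, "similarity": sim,
                     "identity": m == m2, "n_insertions": len(deltas),
                     "mean_delta": float(deltas.mean()),
                     "sd_delta": float(deltas.std())})
    table = pd.DataFrame(rows)
    # bin by similarity; identity pairs form the final bin
    edges = np.linspace(0, 1, 6)
    labels = pd.cut(table["similarity"].where(~table["identity"], np.nan),
                    edges, include_lowest=True)
    binned = (table.assign(bin=labels.cat.add_categories(["identity"])
                           .fillna("identity"))
              .groupby("bin", observed=True)["mean_delta"]
              .agg(["mean", "std", "count"]).reset_index())
    rho, pval = stats.spearmanr(table["similarity"], table["mean_delta"])
    return table, binned, (float(rho), float(pval))


def empirical_breakpoint_homology(sv_windows, bg_windows, k: int) -> pd.DataFrame:
    """Similarity of the k-mer ending at the junction vs the k-mer
    beginning at it, histogrammed per group (frequencies sum to 1)."""
    def sims(windows):
        out = []
        for s in _seqs(windows):
            c = len(s) // 2
            out.append(pair_similarity(s[c - k:c], s[c:c + k]))
        return out

    bins = np.linspace(0, 1, k + 2)
    rows = []
    for group, windows in (("sv", sv_windows), ("background", bg_windows)):
        vals = sims(windows)
        hist, _ = np.histogram(vals, bins=bins)
        freq = hist / max(len(vals), 1)
        for lo, hi, f in zip(bins[:-1], bins[1:], freq):
            rows.append({"group": group, "sim_low": lo, "sim_high": hi,
                         "frequency": f})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Non-B DNA
# ---------------------------------------------------------------------------

_PURINES = set("AG")


def generate_nonb_motifs(kind: str, n: int = 100, seed: int = 42) -> list[str]:
    """Sequences predicted to adopt non-canonical structures.

    ``G4``: four runs of >=3 G separated by 1-7 nt loops.  ``ZDNA``:
    alternating purine-pyrimidine dinucleotide repeats (GC/CA/GT mixtures,
    >=10 units) chained so every step alternates.
    """
    rng = np.random.default_rng(seed)
    out: set[str] = set()
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 100 * n:
            raise ConfigurationError("could not generate enough distinct motifs")
        if kind == "G4":
            parts = []
            for t in range(4):
                parts.append("G" * int(rng.integers(3, 6)))
                if t < 3:
                    loop_len = int(rng.integers(1, 8))
                    parts.append("".join(rng.choice(list("ACGT"), size=loop_len)))
            out.add("".join(parts))
        elif kind == "ZDNA":
            units = ["GC", "CA", "GT"]
            # transitions keeping purine/pyrimidine alternation across joins
            follow = {"C": ["GC", "GT"], "A": ["CA"], "T": ["GC", "GT"]}
            motif = units[int(rng.integers(3))]
            for _ in range(int(rng.integers(10, 16)) - 1):
                choices = follow[motif[-1]]
                motif += choices[int(rng.integers(len(choices)))]
            out.add(motif)
        else:
            raise ConfigurationError("kind must be 'G4' or 'ZDNA'")
    return sorted(out)[:n]


def nonb_insertion_effect(model, bg_windows, motifs: Sequence[str],
                          n_positions: int = 50, seed: int = 42,
                          batch_size: int = 2048):
    """Insert each motif and a length-matched random control at the same
    positions; returns ``(motif_result, control_result)`` aggregated over
    the whole motif set."""
    seqs = _seqs(bg_windows)
    if not seqs:
        raise ConfigurationError("need at least one background window")
    L = len(seqs[0])
    rng = np.random.default_rng(seed)
    controls = ["".join(rng.choice(list("ACGT"), size=len(m))) for m in motifs]
    base_p = _predict(model, seqs)
    positions = [rng.integers(0, L, size=n_positions) for _ in seqs]

    def run(mset):
        mods, refs = [], []
        for m in mset:
            for seq, pos, p0 in zip(seqs, positions, base_p):
                for pp in pos:
                    mods.append(insert_motif(seq, m, int(pp)))
                    refs.append(p0)
        deltas = _predict(model, mods, batch_size) - np.asarray(refs)
        return DeltaProbabilityResult(motif=f"set[{len(mset)}]",
                                      n_insertions=len(deltas),
                                      mean_delta=float(deltas.mean()),
                                      sd_delta=float(deltas.std()))

    return run(list(motifs)), run(controls)


# ---------------------------------------------------------------------------
# In-silico saturation mutagenesis
# ---------------------------------------------------------------------------

def ism(model, windows, radius: int = 30, batch_size: int = 2048) -> ISMMap:
    """Substitute every base within +/-radius of the window centre and
    average the probability change over windows; reference-base cells are
    exactly 0."""
    seqs = _seqs(windows)
    if not seqs:
        raise ConfigurationError("need at least one window")
    L = len(seqs[0])
    if radius > L // 2:
        raise ConfigurationError("radius exceeds half the window")
    c = L // 2
    offsets = range(-radius, radius + 1)
    base_p = _predict(model, seqs)
    mods, keys = [], []
    for si, seq in enumerate(seqs):
        for oi, off in enumerate(offsets):
            pos = c + off
            if pos >= L:
                continue
            for bi, base in enumerate(BASES):
                if seq[pos] == base:
                    continue
                mods.append(seq[:pos] + base + seq[pos + 1:])
                keys.append((si, oi, bi))
    preds = _predict(model, mods, batch_size)
    matrix = np.zeros((2 * radius + 1, 4))
    for (si, oi, bi), p in zip(keys, preds):
        matrix[oi, bi] += p - base_p[si]
    matrix /= len(seqs)
    freqs = np.zeros((2 * radius + 1, 4))
    for seq in seqs:
        for oi, off in enumerate(offsets):
            pos = c + off
            if pos < L:
                freqs[oi, BASES.index(seq[pos])] += 1
    freqs /= len(seqs)
    return ISMMap(radius=radius, matrix=matrix, base_order=BASES,
                  n_sequences=len(seqs), nucleotide_freqs=freqs)


def substitution_motif_effect(model, bg_windows, motif_len: int = 4,
                              batch_size: int = 2048) -> pd.DataFrame:
    """In-place substitution of every ``motif_len``-mer with its second base
    at the window centre (offsets [c-1, c+motif_len-1))."""
    seqs = _seqs(bg_windows)
    if not seqs:
        raise ConfigurationError("need at least one background window")
    L = len(seqs[0])
    c = L // 2
    lo, hi = c - 1, c - 1 + motif_len
    base_p = _predict(model, seqs)
    motifs = ["".join(p) for p in itertools.product("ACGT", repeat=motif_len)]
    rows = []
    for m in motifs:
        mods = [s[:lo] + m + s[hi:] for s in seqs]
        deltas = _predict(model, mods, batch_size) - base_p
        rows.append({"motif": m, "mean_delta": float(deltas.mean()),
                     "sd_delta": float(deltas.std()), "n": len(seqs)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature importances
# ---------------------------------------------------------------------------

def _auroc(probs, labels):
    from .models import evaluate
    return evaluate(probs, labels).auroc


def permutation_importance(model, features: pd.DataFrame, labels,
                           cnn_probs=None, n_repeats: int = 5, seed: int = 42,
                           metric=_auroc, permuter=None) -> list[ImportanceRecord]:
    """Mean/sd metric drop over ``n_repeats`` column permutations.

    ``permuter(rng, n)`` may override the shuffle (e.g. identity for
    testing).  Gini importances come from the fitted forest and sum to 1.
    """
    from .models import tabular_proba
    names = list(getattr(model, "feature_names", features.columns))
    X = features[[n for n in names if n != "cnn_probability"]].to_numpy(float)
    if "cnn_probability" in names:
        if cnn_probs is None:
            raise ConfigurationError("model expects a cnn_probability column")
        X = np.column_stack([X, np.asarray(cnn_probs, float)])
    y = np.asarray(labels)
    baseline = metric(model.predict_proba(X)[:, 1], y)
    gini = getattr(model, "feature_importances_", np.full(len(names), np.nan))
    rng = np.random.default_rng(seed)
    perm = permuter if permuter is not None else (lambda r, n: r.permutation(n))
    records = []
    for j, name in enumerate(names):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[perm(rng, len(y)), j]
            drops.append(baseline - metric(model.predict_proba(Xp)[:, 1], y))
        records.append(ImportanceRecord(
            feature=name, gini_importance=float(gini[j]),
            permutation_mean=float(np.mean(drops)),
            permutation_sd=float(np.std(drops))))
    return records


def importance_shift(with_cnn: Sequence[ImportanceRecord],
                     without_cnn: Sequence[ImportanceRecord]) -> pd.DataFrame:
    """Per-feature change in permutation importance after adding the CNN
    probability feature; the cnn_probability row is reported separately."""
    w = {r.feature: r for r in with_cnn}
    wo = {r.feature: r for r in without_cnn}
    shared = set(w) - {"cnn_probability"}
    if shared != set(wo):
        raise ConfigurationError("feature sets do not align")
    rows = [{"feature": f, "with_cnn": w[f].permutation_mean,
             "without_cnn": wo[f].permutation_mean,
             "delta": w[f].permutation_mean - wo[f].permutation_mean}
            for f in sorted(shared)]
    if "cnn_probability" in w:
        rows.append({"feature": "cnn_probability",
                     "with_cnn": w["cnn_probability"].permutation_mean,
                     "without_cnn": np.nan, "delta": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distribution divergence and correlations
# ---------------------------------------------------------------------------

def jsd_from_histograms(p, q) -> float:
    """Jensen-Shannon divergence (log base 2) of two histograms."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.sum() <= 0 or q.sum() <= 0:
        raise ConfigurationError("histograms must have positive mass")
    return float(jensenshannon(p, q, base=2) ** 2)


def jsd(sample_a, sample_b, n_bins: int = 50, feature: str = "",
        sv_class: str = "") -> JSDRecord:
    """JSD between two samples over shared equal-width bins spanning the
    pooled range; empty bins contribute 0."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ConfigurationError("samples must be non-empty and finite")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return JSDRecord(value=0.0, n_bins=n_bins, feature=feature,
                         sv_class=sv_class)
    edges = np.linspace(lo, hi, n_bins + 1)
    ha, _ = np.histogram(a, bins=edges)
    hb, _ = np.histogram(b, bins=edges)
    return JSDRecord(value=jsd_from_histograms(ha, hb), n_bins=n_bins,
                     bin_edges=edges, feature=feature, sv_class=sv_class)


def correlation_matrix(table: pd.DataFrame):
    """Pairwise Spearman correlations (average ranks on ties) over all
    numeric columns; constant columns are reported as 0 and flagged.

    Returns ``(matrix DataFrame, flagged column list)``.
    """
    num = table.select_dtypes(include=[np.number])
    cols = list(num.columns)
    flagged = [c for c in cols if num[c].nunique() <= 1]
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            if ci in flagged or cj in flagged:
                rho = 0.0
            else:
                rho = float(stats.spearmanr(num[ci], num[cj]).statistic)
            mat.iloc[i, j] = mat.iloc[j, i] = rho
    return mat, flagged
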