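"""Associations between model predictions and allele frequency, per-gene
constraint scores, observed SV burden, and external per-variant scores.

All statistics are pure functions of their input tables and reproducible
from serialized TSV artifacts alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import IntervalSet, SVRecord, extract_window
from .errors import ConfigurationError, WindowRejected

logger = logging.getLogger(__name__)

__all__ = ["FrequencyStratum", "stratify_by_af", "gene_level_probability",
           "count_svs_per_gene", "correlate_gene_scores"]


@dataclass
class FrequencyStratum:
    label: str
    af_low: float
    af_high: float
    n: int
    mean_probability: float
    quartiles: tuple[float, float, float]


def stratify_by_af(predictions: Sequence[float], sv_records: Sequence[SVRecord],
                   singleton_af: float = 0.01, low_af: float = 0.05):
    """Stratify predicted probabilities by allele frequency.

    Default strata: singleton (AF <= ``singleton_af``), low (AF <
    ``low_af``), intermediate (AF >= ``low_af``).  Returns ``(strata,
    spearman trend (rho, p), pairwise Mann-Whitney table)``; records
    without AF are excluded with a logged count.
    """
    preds = np.asarray(predictions, float)
    afs = np.array([r.allele_frequency if r.allele_frequency is not None else np.nan
                    for r in sv_records])
    keep = ~np.isnan(afs)
    if (~keep).sum():
        logger.info("excluded %d records without allele frequency",
                    int((~keep).sum()))
    preds, afs = preds[keep], afs[keep]
    if len(preds) == 0:
        raise ConfigurationError("no records with allele frequency")
    bounds = [("singleton", 0.0, singleton_af),
              ("low", singleton_af, low_af),
              ("intermediate", low_af, 1.0 + 1e-12)]
    strata, groups = [], []
    for label, lo, hi in bounds:
        mask = (afs > lo) & (afs <= hi) if label != "singleton" else (afs <= hi)
        vals = preds[mask]
        groups.append(vals)
        q = (np.percentile(vals, [25, 50, 75]) if len(vals)
             else np.array([np.nan] * 3))
        strata.append(FrequencyStratum(label, lo, min(hi, 1.0), int(mask.sum()),
                                       float(vals.mean()) if len(vals) else np.nan,
                                       tuple(q)))
    if np.unique(afs).size < 2 or np.unique(preds).size < 2:
        trend = (0.0, 1.0, True)          # degenerate: flagged
    else:
        r = stats.spearmanr(afs, preds)
        trend = (float(r.statistic), float(r.pvalue), False)
    tests = []
    for (s1, g1), (s2, g2) in zip(list(zip(strata, groups))[:-1],
                                  list(zip(strata, groups))[1:]):
        if len(g1) and len(g2):
            u = stats.mannwhitneyu(g1, g2, alternative="two-sided")
            tests.append({"pair": f"{s1.label}|{s2.label}",
                          "u": float(u.statistic), "pvalue": float(u.pvalue)})
    return strata, trend, pd.DataFrame(tests)


def gene_level_probability(predict_fn, reference, genes: IntervalSet,
                           context_length: int, n_samples: int = 30,
                           seed: int = 42, max_tries: int = 5) -> pd.DataFrame:
    """Mean predicted probability over random positions in each gene body.

    ``predict_fn(windows) -> probabilities`` wraps whichever model is being
    scored.  Rejected windows are resampled up to a bound; genes yielding
    no valid window are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    gene_idx = 0
    for chrom in sorted(genes.chroms()):
        for s, e in genes.intervals(chrom):
            windows = []
            for _ in range(n_samples * max_tries):
                if len(windows) >= n_samples:
                    break
                pos = int(rng.integers(s, e))
                try:
                    windows.append(extract_window(reference, (chrom, pos),
                                                  context_length,
                                                  label="background"))
                except WindowRejected:
                    continue
            if not windows:
                logger.warning("gene %s:%d-%d yielded no valid window; dropped",
                               chrom, s, e)
                gene_idx += 1
                continue
            probs = np.asarray(predict_fn(windows), float)
            rows.append({"gene_id": f"gene_{gene_idx}", "chrom": chrom,
                         "start": s, "end": e,
                         "mean_probability": float(probs.mean()),
                         "n_positions": len(windows)})
            gene_idx += 1
    return pd.DataFrame(rows)


def count_svs_per_gene(sv_records: Sequence[SVRecord], genes: IntervalSet,
                       halo: int = 200) -> pd.DataFrame:
    """SVs with either breakpoint in ``[gene.start - halo, gene.end + halo)``."""
    rows = []
    gene_idx = 0
    for chrom in sorted(genes.chroms()):
        recs = [r for r in sv_records if r.chrom == chrom]
        for s, e in genes.intervals(chrom):
            n = sum(1 for r in recs
                    if any(s - halo <= bp < e + halo for bp in r.breakpoints))
            rows.append({"gene_id": f"gene_{gene_idx}", "chrom": chrom,
                         "start": s, "end": e, "sv_count": n})
            gene_idx += 1
    return pd.DataFrame(rows)


def correlate_gene_scores(rows: pd.DataFrame, score_column: str,
                          probability_column: str = "mean_probability",
                          outlier_percentile: float = 99.0):
    """Spearman correlation between gene-level predictions and a score.

    Rows with missing scores are excluded.  Outliers (for highlighting) are
    rows whose probability rank-regression residual exceeds the given
    percentile; the definition is a package convention, flagged as such in
    the output.  Returns ``(rho, p, n, table-with-outlier-column)``.
    """
    t = rows.dropna(subset=[score_column, probability_column]).copy()
    if len(t) < 3:
        raise ConfigurationError("need at least 3 scored rows")
    rho, p = stats.spearmanr(t[score_column], t[probability_column])
    rx = stats.rankdata(t[score_column])
    ry = stats.rankdata(t[probability_column])
    slope, intercept = np.polyfit(rx, ry, 1)
    resid = ry - (slope * rx + intercept)
    cut = np.percentile(resid, outlier_percentile)
    t["rank_residual"] = resid
    t["outlier"] = resid > cut
    t.attrs["outlier_definition"] = (
        f"rank-regression residual above the {outlier_percentile:g}th "
        "percentile (package convention)")
    return float(rho), float(p), len(t), t
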