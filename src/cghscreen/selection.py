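"""Two-stage candidate-locus selection for case-control paired CGH.

Stage 1 (penetrance differential): count, at every probe, how many pairs
carry a gain call and how many a loss call; probes where the gain/loss
call counts differ by at least ``min_diff`` (default 4) are flagged, and
maximal runs of flagged probes on a chromosome become primary candidate
loci.  An alternative "exclusive" rule requires at least ``min_diff``
calls in one direction with none in the other.

Stage 2 (global probe-wise test): at each member probe of a candidate
locus, the 48 pairs' log2 ratios are tested against zero with a two-tailed
one-sample t-test (and descriptively against normality with a
Kolmogorov-Smirnov test).  Per locus, the per-probe means are averaged and
the per-probe p-values are combined as the sum of -log10 p (the product of
p-values in the log domain); the locus passes if this cumulated quantity
clears the Bonferroni threshold -log10(alpha / n_loci), where n_loci is
the number of stage-1 loci actually tested.

The cumulated product of p-values is not a calibrated combined test for
multi-probe loci (neighbouring probes are correlated and the product is
anti-conservative); Fisher's combined chi-square p-value is therefore
reported alongside as ``fisher_p`` for each locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AberrationCall, CandidateLocus, PairRatioMatrix, ProbeMap

logger = logging.getLogger(__name__)

LOG10 = np.log(10.0)


@dataclass
class PenetranceSummary:
    """Per-probe counts of pairs calling gain (G) and loss (L)."""

    gain_count: np.ndarray
    loss_count: np.ndarray

    def __post_init__(self):
        self.gain_count = np.asarray(self.gain_count, dtype=np.int64)
        self.loss_count = np.asarray(self.loss_count, dtype=np.int64)
        if self.gain_count.shape != self.loss_count.shape:
            raise ValueError("gain_count and loss_count must have the same shape")


def penetrance_summary(
    calls: list[AberrationCall], probe_map: ProbeMap
) -> PenetranceSummary:
    """Tally gain/loss aberration calls covering each probe, across pairs.

    A pair contributes at most one count per probe per direction (its calls
    are disjoint by construction of the detector).
    """
    n = probe_map.n_probes
    G = np.zeros(n, dtype=np.int64)
    L = np.zeros(n, dtype=np.int64)
    for call in calls:
        if call.first_probe_index < 0 or call.last_probe_index >= n:
            raise ValueError(
                f"call {call.pair_id} references probe indices outside the map"
            )
        target = G if call.direction == "gain" else L
        target[call.first_probe_index : call.last_probe_index + 1] += 1
    return PenetranceSummary(gain_count=G, loss_count=L)


def _flagged_runs(flagged: np.ndarray, gap_probes: int) -> list[tuple[int, int]]:
    """Maximal runs of True, merging runs separated by <= gap_probes False."""
    idx = np.flatnonzero(flagged)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= gap_probes:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def select1_candidates(
    summary: PenetranceSummary,
    probe_map: ProbeMap,
    min_diff: int = 4,
    gap_probes: int = 0,
    rule: str = "diff",
) -> list[CandidateLocus]:
    """Primary candidate loci from the penetrance summary.

    rule="diff" flags probes with |G - L| >= min_diff; rule="exclusive"
    requires max(G, L) >= min_diff and no calls in the other direction.
    """
    if min_diff < 1:
        raise ValueError("min_diff must be >= 1")
    G, L = summary.gain_count, summary.loss_count
    if rule == "diff":
        flagged = np.abs(G - L) >= min_diff
    elif rule == "exclusive":
        flagged = (np.maximum(G, L) >= min_diff) & (np.minimum(G, L) == 0)
    else:
        raise ValueError(f"unknown select1 rule: {rule!r}")
    loci: list[CandidateLocus] = []
    for chrom, sl in probe_map.chrom_slices().items():
        for a, b in _flagged_runs(flagged[sl.start : sl.stop], gap_probes):
            idx = np.arange(sl.start + a, sl.start + b + 1)
            loci.append(
                CandidateLocus(
                    chromosome=chrom,
                    start=int(probe_map.position[idx[0]]),
                    end=int(probe_map.position[idx[-1]]),
                    probe_indices=idx,
                    stage="selection1",
                )
            )
    return loci


def probe_global_test(values: np.ndarray) -> dict:
    """One probe's global test: the pairs' log2 ratios against zero.

    Returns mean_log2, t statistic, two-tailed p_t with its -log10
    (computed in the log domain so extreme probes do not underflow), and a
    KS p-value against a Gaussian fitted with the sample mean and SD.
    All-identical values make the t-test degenerate; such probes are
    flagged and excluded from locus cumulation by the caller.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise ValueError("probe_global_test requires >= 3 non-missing values")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        return {
            "mean_log2": mean,
            "t": np.nan,
            "p_t": np.nan,
            "neglog10_p_t": np.nan,
            "p_ks": np.nan,
            "degenerate": True,
        }
    n = len(v)
    t = mean / (sd / np.sqrt(n))
    logp = np.log(2.0) + stats.t.logsf(abs(t), df=n - 1)
    p_ks = float(stats.kstest(v, "norm", args=(mean, sd)).pvalue)
    return {
        "mean_log2": mean,
        "t": float(t),
        "p_t": float(np.exp(logp)),
        "neglog10_p_t": float(-logp / LOG10),
        "p_ks": p_ks,
        "degenerate": False,
    }


def global_test(
    matrix: PairRatioMatrix, probe_indices: np.ndarray | None = None
) -> pd.DataFrame:
    """Vectorised probe-wise global test over (a subset of) the matrix.

    Returns a DataFrame indexed by global probe index with columns
    mean_log2, t, p_t, neglog10_p_t, p_ks, degenerate.
    """
    if probe_indices is None:
        probe_indices = np.arange(matrix.probe_map.n_probes)
    probe_indices = np.asarray(probe_indices, dtype=np.int64)
    V = matrix.values[probe_indices, :]
    n = np.sum(np.isfinite(V), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(V, axis=1)
        sd = np.nanstd(V, axis=1, ddof=1)
    degenerate = (sd == 0.0) | (n < 3)
    t = np.full(len(probe_indices), np.nan)
    logp = np.full(len(probe_indices), np.nan)
    ok = ~degenerate
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n[ok]))
    logp[ok] = np.log(2.0) + stats.t.logsf(np.abs(t[ok]), df=n[ok] - 1)
    p_ks = np.full(len(probe_indices), np.nan)
    for r in np.flatnonzero(ok):
        v = V[r, :]
        v = v[np.isfinite(v)]
        p_ks[r] = stats.kstest(v, "norm", args=(mean[r], np.std(v, ddof=1))).pvalue
    return pd.DataFrame(
        {
            "mean_log2": mean,
            "t": t,
            "p_t": np.exp(logp),
            "neglog10_p_t": -logp / LOG10,
            "p_ks": p_ks,
            "degenerate": degenerate,
        },
        index=pd.Index(probe_indices, name="probe_index"),
    )


def cumulate_locus(rows: pd.DataFrame) -> tuple[float, float]:
    """Combine a locus's member-probe tests.

    mean_log2 is the unweighted mean of the per-probe means; the
    cumulated statistic is the sum of -log10 p_t over non-degenerate
    probes (equivalently the -log10 of the product of p-values).
    Raises if no usable probe remains.
    """
    usable = rows[~rows["degenerate"]]
    if len(usable) == 0:
        raise ValueError("locus has no non-degenerate probes")
    return (
        float(usable["mean_log2"].mean()),
        float(usable["neglog10_p_t"].sum()),
    )


def fisher_combined_p(rows: pd.DataFrame) -> float:
    """Fisher's combined probability over the locus's member probes
    (chi-square with 2k d.f. on -2 sum(ln p)); calibrated alternative to
    the raw product of p-values, assuming independent probes."""
    usable = rows[~rows["degenerate"]]
    if len(usable) == 0:
        return float("nan")
    chi2 = 2.0 * LOG10 * float(usable["neglog10_p_t"].sum())
    return float(stats.chi2.sf(chi2, df=2 * len(usable)))


def odds_ratio(mean_log2: float) -> float:
    """Linear-scale case/control dosage fold change: 2**mean_log2."""
    if not np.isfinite(mean_log2):
        raise ValueError("mean_log2 must be finite")
    return float(2.0**mean_log2)


def bonferroni_threshold(alpha: float, n_loci: int) -> float:
    """-log10 of the per-locus significance level alpha / n_loci."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return float(-np.log10(alpha / n_loci))


def bonferroni_select(
    loci: list[CandidateLocus], alpha: float = 0.05
) -> list[CandidateLocus]:
    """Upgrade loci whose cumulated -log10 p meets the Bonferroni
    threshold computed from the number of loci actually tested.

    A locus passes iff cum_neglog10p >= -log10(alpha / n_loci); passers
    get stage "both" (they survived both selections).
    """
    if len(loci) == 0:
        return loci
    T = bonferroni_threshold(alpha, len(loci))
    for locus in loci:
        if np.isfinite(locus.cum_neglog10p) and locus.cum_neglog10p >= T:
            locus.stage = "both"
    return loci


def annotate_locus_statistics(
    loci: list[CandidateLocus], matrix: PairRatioMatrix
) -> list[CandidateLocus]:
    """Fill each locus's stage-2 statistics from the ratio matrix; loci
    with no usable (non-degenerate) probes are dropped with a warning."""
    kept = []
    for locus in loci:
        rows = global_test(matrix, locus.probe_indices)
        usable = rows[~rows["degenerate"]]
        if len(usable) == 0:
            logger.warning(
                "dropping locus %s:%d-%d: no non-degenerate probes",
                locus.chromosome,
                locus.start,
                locus.end,
            )
            continue
        locus.mean_log2, locus.cum_neglog10p = cumulate_locus(rows)
        locus.fisher_p = fisher_combined_p(rows)
        locus.odds_ratio = odds_ratio(locus.mean_log2)
        locus.frac_gaussian = float(np.mean(usable["p_ks"] >= 0.05))
        kept.append(locus)
    return kept


def select_candidates(
    matrix: PairRatioMatrix,
    calls: list[AberrationCall],
    min_diff: int = 4,
    alpha: float = 0.05,
    rule: str = "diff",
    gap_probes: int = 0,
) -> list[CandidateLocus]:
    """Full two-stage selection: penetrance filter, probe-wise global
    tests with locus cumulation, and Bonferroni control."""
    summary = penetrance_summary(calls, matrix.probe_map)
    loci = select1_candidates(
        summary, matrix.probe_map, min_diff=min_diff, gap_probes=gap_probes, rule=rule
    )
    loci = annotate_locus_statistics(loci, matrix)
    return bonferroni_select(loci, alpha=alpha)
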