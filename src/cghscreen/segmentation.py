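"""Per-pair detection of aberrant intervals from log2 ratios.

This is a documented, deterministic surrogate for proprietary
maximal-scoring-interval detectors of the ADM-2 family.  For one pair and
one chromosome it searches for contiguous probe intervals whose
quality-weighted average log ratio is inconsistent with zero:

    S(i, j) = |sum(w * x) / sum(w)| * sqrt(sum(w)) / sigma

with unit weights this is |mean| * sqrt(n) / sigma — the z-score of the
interval mean against a per-pair, per-chromosome noise scale sigma
estimated blind by DLRS (derivative log ratio spread).  Intervals are
extracted greedily: among all intervals scoring at least the sensitivity
threshold tau, take the highest-scoring one, remove its probes, and repeat
on the remaining contiguous runs; ties prefer the longer interval, then the
smaller start index.  Calls never span chromosomes.

Two corrections mirror the standard filter options:

* *centralization* — if the modal log2 ratio of a pair differs from zero by
  a significant margin, the mode is subtracted so the dominant copy state
  maps to zero;
* *fuzzy zero* — a global systematic-error term sigma_g (robust SD of
  bin means across the genome) enters the score denominator,
  S' = |mean| / sqrt(sigma^2/n + sigma_g^2), suppressing long
  low-amplitude intervals whose nominal S grows with sqrt(n) alone.
  With fuzzy zero on, an interval must clear tau on both S and S'.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import AberrationCall, ProbeMap, SegmentationParams

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-6


def _robust_sd(x: np.ndarray) -> float:
    """IQR-based SD estimate, insensitive to a few outlying values."""
    if len(x) < 2:
        return 0.0
    q75, q25 = np.percentile(x, [75, 25])
    return float((q75 - q25) / 1.349)


def dlrs(x: np.ndarray) -> float:
    """Derivative log ratio spread: robust SD of adjacent-probe
    differences divided by sqrt(2).

    Unbiased by broad copy-number segments because only the two probes
    flanking a breakpoint contribute outlying differences, which the
    IQR-based SD ignores.  Floored at 1e-6 so scores stay finite on
    constant input.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("dlrs requires at least 3 probes")
    sigma = _robust_sd(np.diff(x)) / np.sqrt(2.0)
    return max(sigma, SIGMA_FLOOR)


def centralize(
    x: np.ndarray, params: SegmentationParams, sigma: float | None = None
) -> np.ndarray:
    """Re-center a pair's log2 ratios on their modal value.

    The values are histogrammed with bin width sigma/4 (bins anchored so
    zero is a bin center); the mode is then refined as the median of the
    values within 2*sigma of the tallest bin, which localizes the
    dominant copy-state peak while ignoring distant aberrant states.  If
    |mode| * sqrt(n) / sigma >= the centralization threshold the mode is
    subtracted from all values, otherwise the input is returned
    unchanged.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("centralize requires a nonempty vector")
    if sigma is None:
        sigma = dlrs(x) if len(x) >= 3 else _robust_sd(x)
    sigma = max(float(sigma), SIGMA_FLOOR)
    width = sigma / 4.0
    lo = (np.floor(float(np.min(x)) / width - 0.5) + 0.5) * width
    n_bins = max(int(np.ceil((float(np.max(x)) - lo) / width)), 1)
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, lo + n_bins * width))
    center = 0.5 * (edges[:-1] + edges[1:])[int(np.argmax(counts))]
    local = x[np.abs(x - center) <= 2 * sigma]
    mode = float(np.median(local)) if len(local) else center
    if abs(mode) * np.sqrt(len(x)) / sigma >= params.centralization_threshold:
        return x - mode
    return x


def interval_score(
    x: np.ndarray, w: np.ndarray | None, sigma: float, i: int, j: int
) -> float:
    """Quality-weighted interval score S for probes i..j (inclusive)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if i > j:
        raise ValueError("interval start exceeds end")
    xs = np.asarray(x, dtype=float)[i : j + 1]
    ws = np.ones_like(xs) if w is None else np.asarray(w, dtype=float)[i : j + 1]
    wsum = ws.sum()
    wmean = float(np.dot(ws, xs) / wsum)
    return abs(wmean) * float(np.sqrt(wsum)) / sigma


def fuzzy_zero_score(
    x: np.ndarray,
    w: np.ndarray | None,
    sigma: float,
    sigma_g: float,
    i: int,
    j: int,
) -> float:
    """Fuzzy-zero corrected score S' = |mean| / sqrt(sigma^2/n + sigma_g^2).

    sigma_g = 0 reduces to the plain interval score; as the interval grows
    the score saturates at |mean| / sigma_g instead of rising with sqrt(n).
    """
    if sigma_g < 0:
        raise ValueError("sigma_g must be non-negative")
    xs = np.asarray(x, dtype=float)[i : j + 1]
    ws = np.ones_like(xs) if w is None else np.asarray(w, dtype=float)[i : j + 1]
    wsum = ws.sum()
    wmean = float(np.dot(ws, xs) / wsum)
    return abs(wmean) / float(np.sqrt(sigma**2 / wsum + sigma_g**2))


def estimate_sigma_g(
    x: np.ndarray, probe_map: ProbeMap, bin_size: int
) -> float:
    """Global systematic-error scale: robust SD of the means of
    consecutive non-overlapping bins of ``bin_size`` probes, bins taken
    within chromosomes.  Estimated once per pair."""
    means = []
    for _, sl in probe_map.chrom_slices().items():
        xc = np.asarray(x[sl], dtype=float)
        n_full = len(xc) // bin_size
        if n_full >= 1:
            means.append(xc[: n_full * bin_size].reshape(n_full, bin_size).mean(axis=1))
    if not means:
        return 0.0
    return _robust_sd(np.concatenate(means))


def _best_interval(
    xc: np.ndarray,
    a: int,
    b: int,
    sigma: float,
    sigma_g: float,
    params: SegmentationParams,
):
    """Highest-scoring admissible interval within probes a..b of one
    chromosome (local indices), or None.

    Scans lengths from longest to shortest so that on an exact score tie
    the longer interval wins, and within a length the smaller start wins.
    """
    c = np.concatenate(([0.0], np.cumsum(xc[a : b + 1])))
    m = b - a + 1
    best = None  # (S, i, j, mean)
    for L in range(m, 0, -1):
        sums = c[L:] - c[: m - L + 1]
        means = sums / L
        S = np.abs(means) * np.sqrt(L) / sigma
        ok = S >= params.tau
        if params.fuzzy_zero:
            s_fz = np.abs(means) / np.sqrt(sigma**2 / L + sigma_g**2)
            ok &= s_fz >= params.tau
        if not ok.any():
            continue
        S_masked = np.where(ok, S, -np.inf)
        k = int(np.argmax(S_masked))
        if best is None or S_masked[k] > best[0]:
            best = (float(S_masked[k]), a + k, a + k + L - 1, float(means[k]))
    return best


def detect_aberrations(
    x: np.ndarray,
    probe_map: ProbeMap,
    params: SegmentationParams = SegmentationParams(),
    pair_id: str = "pair",
    apply_centralization: bool = True,
) -> list[AberrationCall]:
    """Detect all aberrant intervals in one pair's log2-ratio column.

    Noise sigma is estimated per chromosome by DLRS; sigma_g once per
    pair.  Returns calls sorted by (chromosome order in the map, start
    index); an empty list is a valid result.
    """
    x = np.asarray(x, dtype=float)
    if len(x) != probe_map.n_probes:
        raise ValueError("ratio column not aligned to the probe map")
    if not np.all(np.isfinite(x)):
        # missing measurements carry no evidence either way; treat as null
        logger.warning(
            "pair %s: %d non-finite ratios replaced by 0 for interval search",
            pair_id,
            int(np.sum(~np.isfinite(x))),
        )
        x = np.where(np.isfinite(x), x, 0.0)
    slices = probe_map.chrom_slices()
    if apply_centralization:
        sigmas = [dlrs(x[sl]) for sl in slices.values() if sl.stop - sl.start >= 3]
        global_sigma = float(np.median(sigmas)) if sigmas else SIGMA_FLOOR
        x = centralize(x, params, sigma=global_sigma)
    sigma_g = estimate_sigma_g(x, probe_map, params.bin_size) if params.fuzzy_zero else 0.0

    calls: list[AberrationCall] = []
    for chrom, sl in slices.items():
        xc = x[sl]
        if len(xc) < 3:
            continue
        sigma = dlrs(xc)
        # greedy extraction: best interval, remove its probes, recurse on
        # the flanking runs (segments are independent, so per-segment
        # processing yields the same call set as global extraction)
        stack = [(0, len(xc) - 1)]
        found = []
        while stack:
            a, b = stack.pop()
            if a > b:
                continue
            hit = _best_interval(xc, a, b, sigma, sigma_g, params)
            if hit is None:
                continue
            _, i, j, mean = hit
            found.append(hit)
            stack.append((a, i - 1))
            stack.append((j + 1, b))
        for S, i, j, mean in sorted(found, key=lambda h: h[1]):
            calls.append(
                AberrationCall(
                    pair_id=pair_id,
                    chromosome=chrom,
                    first_probe_index=sl.start + i,
                    last_probe_index=sl.start + j,
                    direction="gain" if mean > 0 else "loss",
                    score=S,
                    mean_log2=mean,
                )
            )
    return calls


def detect_all_pairs(
    matrix, params: SegmentationParams = SegmentationParams()
) -> list[AberrationCall]:
    """Run the detector on every pair column of a PairRatioMatrix."""
    calls: list[AberrationCall] = []
    for k, pid in enumerate(matrix.pair_ids):
        col = matrix.values[:, k]
        calls.extend(
            detect_aberrations(col, matrix.probe_map, params, pair_id=pid)
        )
    return calls
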