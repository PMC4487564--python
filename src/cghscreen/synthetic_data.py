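"""Synthetic paired-aCGH and qPCR data with planted CNVs of known truth.

The generator emulates a direct two-color case/control hybridization design:
each array co-hybridizes one patient (numerator) against one matched control
(denominator), so the per-probe readout is log2(dose_case / dose_control)
plus Gaussian measurement noise and an optional slow baseline wave.

Somatic mosaicism is modelled through the *effective dose*: when a fraction
``f`` of cells carries ``c`` copies of a segment against a diploid
background, the apparent relative dose is ``(f*c + (1-f)*2) / 2`` — a
non-integer value for 0 < f < 1 that dilutes the log2 signal toward zero.

qPCR plates follow a single-efficiency TaqMan model: one cycle threshold
shift per halving of template, with an internal-control assay at fixed
dose 1.0 and Gaussian replicate noise on CT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CnvEventSpec,
    NoiseModel,
    PairRatioMatrix,
    ProbeMap,
    SubjectDoseTrack,
    chrom_sort_key,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

# Default per-pair noise spread: array-to-array quality varies in practice,
# so per-pair log2-ratio SDs are drawn uniformly from this range and the
# segmentation stage must recover them blind via DLRS.
DEFAULT_SIGMA_RANGE = (0.10, 0.25)
DEFAULT_N_PAIRS = 48


def make_probe_map(
    n_probes: int, chromosome_lengths: dict[str, float], seed: int
) -> ProbeMap:
    """Lay out ``n_probes`` random probe midpoints across autosomes,
    allocated proportionally to chromosome length.

    Positions are drawn uniformly, deduplicated and sorted per chromosome;
    probe ids are ``P000001`` ... in genome order.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if not chromosome_lengths:
        raise ValueError("chromosome_lengths must contain at least one chromosome")
    lengths = {
        normalize_chrom(c): float(L) for c, L in chromosome_lengths.items()
    }
    if any(L <= 0 for L in lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    chroms = sorted(lengths, key=chrom_sort_key)
    total = sum(lengths.values())
    rng = np.random.default_rng(seed)

    # largest-remainder apportionment so counts sum exactly to n_probes
    quotas = np.array([n_probes * lengths[c] / total for c in chroms])
    counts = np.floor(quotas).astype(int)
    remainder = n_probes - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - counts))
        counts[order[:remainder]] += 1

    chrom_col: list[str] = []
    pos_col: list[np.ndarray] = []
    for c, k in zip(chroms, counts):
        if k == 0:
            continue
        limit = max(int(lengths[c]), k)
        pos = rng.choice(limit, size=k, replace=False) + 1  # 1-based
        pos.sort()
        chrom_col.extend([c] * k)
        pos_col.append(pos.astype(np.int64))
    positions = np.concatenate(pos_col)
    ids = np.array([f"P{i + 1:06d}" for i in range(n_probes)], dtype=object)
    return ProbeMap(probe_id=ids, chromosome=np.array(chrom_col, dtype=object), position=positions)


def effective_dose(c: int, f: float) -> float:
    """Apparent relative dose of a segment carried at ``c`` copies by a
    cell fraction ``f`` against a diploid background: (f*c + (1-f)*2) / 2.

    f = 1 gives the constitutional values (0, 0.5, 1, 1.5, ...); f < 1
    dilutes toward 1.0.
    """
    if c < 0:
        raise ValueError("copy state c must be non-negative")
    if not (0.0 < f <= 1.0):
        raise ValueError("carrier cell fraction f must lie in (0, 1]")
    return (f * c + (1.0 - f) * 2.0) / 2.0


def plant_events(
    probe_map: ProbeMap,
    subjects: list[tuple[str, str]],
    events: list[CnvEventSpec],
) -> list[SubjectDoseTrack]:
    """Build per-subject dose tracks (baseline 1.0) with events applied.

    ``subjects`` is a list of (subject_id, group) with group in
    {case, control}.  Each carrier's dose is multiplied by the event's
    effective dose at every probe inside [start, end].  Overlapping events
    on the same subject multiply their effects (a warning is logged).
    """
    known = {sid for sid, _ in subjects}
    if len(known) != len(subjects):
        raise ValueError("duplicate subject_id in subjects")
    tracks = {
        sid: SubjectDoseTrack(sid, group, np.ones(probe_map.n_probes))
        for sid, group in subjects
    }
    touched: dict[str, np.ndarray] = {
        sid: np.zeros(probe_map.n_probes, dtype=bool) for sid in known
    }
    for ev in events:
        unknown = set(ev.subject_ids) - known
        if unknown:
            raise ValueError(f"unknown subject_id(s) in event: {sorted(unknown)}")
        mask = (probe_map.chromosome == ev.chromosome) & (
            (probe_map.position >= ev.start) & (probe_map.position <= ev.end)
        )
        dose = effective_dose(ev.copy_state, ev.carrier_cell_fraction)
        for sid in ev.subject_ids:
            if np.any(touched[sid][mask]):
                logger.warning(
                    "overlapping events for subject %s on chromosome %s; "
                    "dose effects multiply",
                    sid,
                    ev.chromosome,
                )
            tracks[sid].dose[mask] *= dose
            touched[sid][mask] = True
    return [tracks[sid] for sid, _ in subjects]


def _wave(probe_map: ProbeMap, noise: NoiseModel) -> np.ndarray:
    if noise.wave_amplitude == 0.0:
        return np.zeros(probe_map.n_probes)
    return noise.wave_amplitude * np.sin(
        2.0 * np.pi * probe_map.position / noise.wave_period_bp
    )


def simulate_pair_matrix(
    probe_map: ProbeMap,
    cases: list[SubjectDoseTrack],
    controls: list[SubjectDoseTrack],
    pairing: list[tuple[str, str]],
    noise: NoiseModel,
) -> PairRatioMatrix:
    """Two-color co-hybridization readout for each (case, control) pair.

    entry(probe p, pair k) = log2(dose_case / dose_control)
                             + wave(p) + Normal(0, sigma_pair[k]).

    The case is always the numerator (fixed dye orientation).  Bit-identical
    output for identical seed and parameters.
    """
    case_by_id = {t.subject_id: t for t in cases}
    ctrl_by_id = {t.subject_id: t for t in controls}
    if len(pairing) != len(noise.sigma_pair):
        raise ValueError(
            f"{len(pairing)} pairs but {len(noise.sigma_pair)} sigma_pair values"
        )
    used_cases = [c for c, _ in pairing]
    used_ctrls = [c for _, c in pairing]
    if len(set(used_cases)) != len(pairing) or len(set(used_ctrls)) != len(pairing):
        raise ValueError("pairing must be a perfect matching (no subject reused)")
    for t in list(case_by_id.values()) + list(ctrl_by_id.values()):
        if len(t.dose) != probe_map.n_probes:
            raise ValueError(
                f"dose track for {t.subject_id} not aligned to the probe map"
            )
    rng = np.random.default_rng(noise.seed)
    wave = _wave(probe_map, noise)
    cols = []
    pair_ids = []
    for k, (case_id, ctrl_id) in enumerate(pairing):
        if case_id not in case_by_id or ctrl_id not in ctrl_by_id:
            raise ValueError(f"pairing references unknown subjects ({case_id}, {ctrl_id})")
        signal = np.log2(case_by_id[case_id].dose / ctrl_by_id[ctrl_id].dose)
        eps = rng.normal(0.0, noise.sigma_pair[k], size=probe_map.n_probes)
        cols.append(signal + wave + eps)
        pair_ids.append(f"pair_{k + 1:02d}")
    return PairRatioMatrix(
        probe_map=probe_map, pair_ids=pair_ids, values=np.column_stack(cols)
    )


# ---------------------------------------------------------------------------
# qPCR plate simulation

TARGET_CONTROL_ASSAY = "internal_control"


def simulate_qpcr_plate(
    doses: pd.DataFrame,
    ct0: float = 26.0,
    sigma_ct: float = 0.1,
    replicates: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate TaqMan CT values for target assays plus an internal control.

    ``doses`` needs columns ``sample``, ``group``, ``region``, ``assay``,
    ``dose`` (relative to diploid, 1.0 = two copies).  For every row,
    ``replicates`` target wells are emitted with
    ``CT = ct0 - log2(dose) + Normal(0, sigma_ct)`` and, per
    (sample, region), ``replicates`` internal-control wells at dose 1.0:
    ``CT = ct0 + Normal(0, sigma_ct)``.

    Returns a long-format well table with columns
    ``sample, group, region, assay, replicate, ct``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    required = {"sample", "group", "region", "assay", "dose"}
    missing = required - set(doses.columns)
    if missing:
        raise ValueError(f"doses table missing columns: {sorted(missing)}")
    if (doses["dose"] <= 0).any():
        bad = doses.loc[doses["dose"] <= 0, "sample"].iloc[0]
        raise ValueError(f"non-positive dose for sample {bad!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in doses.iterrows():
        base = ct0 - np.log2(r["dose"])
        for rep in range(1, replicates + 1):
            rows.append(
                (
                    r["sample"],
                    r["group"],
                    r["region"],
                    r["assay"],
                    rep,
                    base + rng.normal(0.0, sigma_ct),
                )
            )
    # one internal-control assay per (sample, region), dose fixed at 1.0
    for (sample, region), grp in doses.groupby(["sample", "region"], sort=False):
        group = grp["group"].iloc[0]
        for rep in range(1, replicates + 1):
            rows.append(
                (
                    sample,
                    group,
                    region,
                    TARGET_CONTROL_ASSAY,
                    rep,
                    ct0 + rng.normal(0.0, sigma_ct),
                )
            )
    return pd.DataFrame(
        rows, columns=["sample", "group", "region", "assay", "replicate", "ct"]
    )


# ---------------------------------------------------------------------------
# Canned study designs


@dataclass(frozen=True)
class StudyDesign:
    """A complete simulated case-control aCGH study with known truth."""

    probe_map: ProbeMap
    events: tuple[CnvEventSpec, ...]
    matrix: PairRatioMatrix
    pairing: tuple[tuple[str, str], ...]
    noise: NoiseModel


def default_chromosome_lengths(n_chrom: int = 22, scale: float = 1.0) -> dict[str, float]:
    """Roughly hg-like autosome lengths (linearly shrinking 250 Mb -> 47 Mb),
    optionally scaled down for small simulations."""
    n_chrom = min(n_chrom, 22)
    lens = np.linspace(250e6, 47e6, 22)[:n_chrom] * scale
    return {str(i + 1): float(L) for i, L in enumerate(lens)}


def simulate_study(
    n_probes: int = 10_000,
    n_pairs: int = DEFAULT_N_PAIRS,
    events: list[CnvEventSpec] | None = None,
    sigma_range: tuple[float, float] = DEFAULT_SIGMA_RANGE,
    chromosome_lengths: dict[str, float] | None = None,
    wave_amplitude: float = 0.0,
    seed: int = 0,
) -> StudyDesign:
    """Convenience wrapper: probe map + subjects + planted events + matrix.

    Subjects are named ``case_01..case_N`` / ``ctrl_01..ctrl_N``; pair k
    hybridizes case_k against ctrl_k.  Per-pair noise SDs are drawn from
    ``sigma_range``; everything is reproducible from ``seed``.
    """
    if chromosome_lengths is None:
        chromosome_lengths = default_chromosome_lengths()
    rng = np.random.default_rng(seed)
    probe_map = make_probe_map(
        n_probes, chromosome_lengths, seed=int(rng.integers(2**31))
    )
    case_ids = [f"case_{i + 1:02d}" for i in range(n_pairs)]
    ctrl_ids = [f"ctrl_{i + 1:02d}" for i in range(n_pairs)]
    subjects = [(s, "case") for s in case_ids] + [(s, "control") for s in ctrl_ids]
    events = list(events or [])
    tracks = plant_events(probe_map, subjects, events)
    cases = tracks[:n_pairs]
    controls = tracks[n_pairs:]
    lo, hi = sigma_range
    sigma_pair = tuple(rng.uniform(lo, hi, size=n_pairs))
    noise = NoiseModel(
        sigma_pair=sigma_pair,
        wave_amplitude=wave_amplitude,
        seed=int(rng.integers(2**31)),
    )
    pairing = tuple(zip(case_ids, ctrl_ids))
    matrix = simulate_pair_matrix(probe_map, cases, controls, list(pairing), noise)
    return StudyDesign(
        probe_map=probe_map,
        events=tuple(events),
        matrix=matrix,
        pairing=pairing,
        noise=noise,
    )


def demo_study(seed: int = 20) -> StudyDesign:
    """The packaged small demonstration study: 1000 probes on two
    chromosomes, 8 pairs, two planted case-only events.

    * a constitutional heterozygous deletion (c=1, f=1) on chr1 carried by
      5 of 8 cases, and
    * a mosaic amplification (c=4 in half the cells, effective dose 1.5)
      on chr2 carried by 6 of 8 cases.
    """
    lengths = {"1": 100e6, "2": 100e6}
    events = [
        CnvEventSpec(
            chromosome="1",
            start=20_000_000,
            end=24_000_000,
            copy_state=1,
            carrier_cell_fraction=1.0,
            subject_ids=frozenset(f"case_{i:02d}" for i in (1, 2, 3, 4, 5)),
        ),
        CnvEventSpec(
            chromosome="2",
            start=60_000_000,
            end=66_000_000,
            copy_state=4,
            carrier_cell_fraction=0.5,
            subject_ids=frozenset(f"case_{i:02d}" for i in (1, 3, 4, 6, 7, 8)),
        ),
    ]
    return simulate_study(
        n_probes=1000,
        n_pairs=8,
        events=events,
        sigma_range=(0.10, 0.20),
        chromosome_lengths=lengths,
        seed=seed,
    )
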