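"""Core in-memory containers for the paired-CGH screening pipeline.

Coordinate conventions used throughout the package
--------------------------------------------------
* Probes are 1-based genomic midpoints.
* Event and locus intervals are 1-based and inclusive at both ends; a probe
  belongs to an interval iff ``start <= position <= end``.
* On disk, BED-style files are 0-based half-open; the conversion happens
  only in :mod:`cghscreen.cgh_io`.

Only autosomes ("1".."22") are modelled; sex chromosomes are out of scope
because dosage there is confounded by subject sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(i) for i in range(1, 23))


def normalize_chrom(label: str) -> str:
    """Strip a leading 'chr' prefix so '1' and 'chr1' compare equal."""
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


def chrom_sort_key(label: str):
    """Sort autosomes numerically, anything else lexically after them."""
    lab = normalize_chrom(label)
    return (0, int(lab)) if lab.isdigit() else (1, lab)


@dataclass(frozen=True)
class ProbeMap:
    """Ordered genomic probe positions — the coordinate frame for everything.

    Parameters
    ----------
    probe_id : array of str, unique
    chromosome : array of str, autosome labels without 'chr'
    position : int array, 1-based probe midpoints, strictly increasing
        within each chromosome
    """

    probe_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        pid = np.asarray(self.probe_id, dtype=object)
        chrom = np.asarray([normalize_chrom(c) for c in self.chromosome], dtype=object)
        pos = np.asarray(self.position, dtype=np.int64)
        if not (len(pid) == len(chrom) == len(pos)):
            raise ValueError("probe_id, chromosome and position must have equal length")
        if len(pid) == 0:
            raise ValueError("ProbeMap must contain at least one probe")
        if len(set(pid)) != len(pid):
            dup = pd.Series(pid)[pd.Series(pid).duplicated()].iloc[0]
            raise ValueError(f"duplicate probe_id: {dup!r}")
        bad = set(chrom) - set(AUTOSOMES)
        if bad:
            raise ValueError(f"non-autosomal chromosome labels: {sorted(bad)}")
        # probes must be in genome order: chromosomes contiguous in
        # karyotype order, positions strictly increasing within each
        keys = [(chrom_sort_key(c), int(p)) for c, p in zip(chrom, pos)]
        if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])):
            raise ValueError(
                "probes must be sorted by (chromosome, position) with "
                "strictly increasing positions"
            )
        object.__setattr__(self, "probe_id", pid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)

    def __len__(self) -> int:
        return len(self.probe_id)

    @property
    def n_probes(self) -> int:
        return len(self.probe_id)

    def chromosomes(self) -> list[str]:
        """Chromosome labels present, in karyotype order."""
        return sorted(set(self.chromosome), key=chrom_sort_key)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice for each chromosome (probes are stored
        grouped by chromosome in karyotype order)."""
        out: dict[str, slice] = {}
        start = 0
        for c in self.chromosomes():
            n = int(np.sum(self.chromosome == c))
            out[c] = slice(start, start + n)
            start += n
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probe_id": self.probe_id, "chrom": self.chromosome, "pos": self.position}
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProbeMap):
            return NotImplemented
        return (
            np.array_equal(self.probe_id, other.probe_id)
            and np.array_equal(self.chromosome, other.chromosome)
            and np.array_equal(self.position, other.position)
        )


@dataclass(frozen=True)
class CnvEventSpec:
    """A planted copy-number event.

    ``copy_state`` is the integer copy number carried by the affected cells
    (diploid baseline = 2); ``carrier_cell_fraction`` f in (0, 1] is the
    fraction of cells carrying it — f = 1 is a constitutional (germline)
    event, f < 1 a somatic mosaic whose aCGH signal is diluted by the
    normal-cell background.
    """

    chromosome: str
    start: int
    end: int
    copy_state: int
    carrier_cell_fraction: float
    subject_ids: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        object.__setattr__(self, "subject_ids", frozenset(self.subject_ids))
        if self.start > self.end:
            raise ValueError(f"event start {self.start} > end {self.end}")
        if self.copy_state < 0:
            raise ValueError("copy_state must be a non-negative integer")
        if not (0.0 < self.carrier_cell_fraction <= 1.0):
            raise ValueError("carrier_cell_fraction must lie in (0, 1]")


@dataclass
class SubjectDoseTrack:
    """Per-probe relative DNA dose for one subject (1.0 = diploid)."""

    subject_id: str
    group: str  # "case" or "control"
    dose: np.ndarray  # aligned to a ProbeMap; > 0 everywhere

    def __post_init__(self):
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")
        self.dose = np.asarray(self.dose, dtype=float)
        if np.any(self.dose <= 0):
            raise ValueError("dose must be positive everywhere")


@dataclass(frozen=True)
class NoiseModel:
    """Per-pair Gaussian noise on log2 ratios, plus an optional slow
    sinusoidal baseline ('wave') artifact shared by all pairs."""

    sigma_pair: tuple[float, ...]
    wave_amplitude: float = 0.0
    wave_period_bp: float = 30e6
    seed: int = 0

    def __post_init__(self):
        sp = tuple(float(s) for s in self.sigma_pair)
        if any(s < 0 for s in sp):
            raise ValueError("sigma_pair must be non-negative")
        if self.wave_amplitude < 0:
            raise ValueError("wave_amplitude must be non-negative")
        object.__setattr__(self, "sigma_pair", sp)


@dataclass
class PairRatioMatrix:
    """Per-probe log2(case / control) ratios for each case-control pair.

    ``values`` has shape (n_probes, n_pairs); NaN marks a missing
    measurement.
    """

    probe_map: ProbeMap
    pair_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.probe_map.n_probes, len(self.pair_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({self.probe_map.n_probes} probes, {len(self.pair_ids)} pairs)"
            )
        if len(set(self.pair_ids)) != len(self.pair_ids):
            raise ValueError("pair_ids must be unique")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def column(self, pair_id: str) -> np.ndarray:
        return self.values[:, self.pair_ids.index(pair_id)]


@dataclass(frozen=True)
class AberrationCall:
    """One contiguous aberrant probe interval in one pair."""

    pair_id: str
    chromosome: str
    first_probe_index: int  # global index into the ProbeMap, inclusive
    last_probe_index: int
    direction: str  # "gain" | "loss"
    score: float
    mean_log2: float

    def __post_init__(self):
        if self.first_probe_index > self.last_probe_index:
            raise ValueError("first_probe_index > last_probe_index")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain/loss, got {self.direction!r}")

    @property
    def n_probes(self) -> int:
        return self.last_probe_index - self.first_probe_index + 1


@dataclass(frozen=True)
class SegmentationParams:
    """Interval-detection filter settings (ADM-2-style defaults)."""

    tau: float = 6.0  # sensitivity threshold on the interval score
    fuzzy_zero: bool = True  # suppress long low-amplitude intervals
    bin_size: int = 10  # probes per bin for the systematic-error estimate
    centralization_threshold: float = 6.0  # modal re-centering trigger

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")


@dataclass
class CandidateLocus:
    """A merged multi-probe candidate region with its selection statistics."""

    chromosome: str
    start: int  # 1-based inclusive bp, first member probe position
    end: int  # last member probe position
    probe_indices: np.ndarray  # global indices of member probes
    n_probes: int = 0
    mean_log2: float = float("nan")
    cum_neglog10p: float = float("nan")
    fisher_p: float = float("nan")
    odds_ratio: float = float("nan")
    frac_gaussian: float = float("nan")
    stage: str = "selection1"  # selection1 | selection2 | both
    common_cnv_overlap: bool | None = None

    def __post_init__(self):
        self.probe_indices = np.asarray(self.probe_indices, dtype=np.int64)
        if self.n_probes == 0:
            self.n_probes = len(self.probe_indices)
        if self.n_probes < 1:
            raise ValueError("a locus must contain at least one probe")

    @property
    def span_kb(self) -> float:
        return (self.end - self.start + 1) / 1000.0
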