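"""On-disk formats for the pipeline, with strict validation.

All files are plain text:

* ratio matrix — TSV with columns ``probe_id, chrom, pos, <pair...>``,
  log2 scale, missing values written as ``NA``;
* aberration calls and planted events — BED-like TSV (0-based half-open
  on disk);
* common-CNV catalogs — standard 3+ column BED;
* candidate-locus tables — TSV mirroring the reported locus summary;
* qPCR plates — CSV with columns ``sample, group, region, assay,
  replicate, ct``.

Every writer emits one ``#``-prefixed header comment with the tool
version; readers skip comment lines.  All conversion between disk
coordinates (0-based half-open) and in-memory coordinates (1-based
inclusive) happens in this module and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import CommonCnvCatalog
from .core import (
    AberrationCall,
    CandidateLocus,
    CnvEventSpec,
    PairRatioMatrix,
    ProbeMap,
    chrom_sort_key,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

MISSING_FRACTION_LIMIT = 0.20  # probes missing in more pairs are dropped


def _header(seed: int | None = None) -> str:
    tag = f"# cghscreen v{__version__}"
    if seed is not None:
        tag += f" seed={seed}"
    return tag + "\n"


# ---------------------------------------------------------------------------
# ratio matrix


def write_ratio_matrix(
    matrix: PairRatioMatrix, path: str | Path, seed: int | None = None
) -> None:
    path = Path(path)
    df = matrix.probe_map.to_frame()
    for k, pid in enumerate(matrix.pair_ids):
        df[pid] = matrix.values[:, k]
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_ratio_matrix(path: str | Path) -> PairRatioMatrix:
    """Read a ratio-matrix TSV.

    Unsorted probes are sorted with a warning; duplicate probe ids and
    non-numeric ratio cells are rejected with errors naming the offender;
    probes missing in more than 20% of pairs are dropped with a logged
    count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str, "chrom": str})
    required = ["probe_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"{path}: first three columns must be {required}, got {list(df.columns[:3])}"
        )
    pair_cols = list(df.columns[3:])
    if not pair_cols:
        raise ValueError(f"{path}: no pair columns")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate probe_id {dup.iloc[0]!r}")
    for col in pair_cols:
        if df[col].dtype == object:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric ratio {bad.iloc[0]!r} in column "
                    f"{col!r}, row {bad.index[0] + 2}"
                )
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    keys = df.apply(lambda r: (chrom_sort_key(r["chrom"]), int(r["pos"])), axis=1)
    if not keys.is_monotonic_increasing:
        logger.warning("%s: probes not in genome order; sorting", path)
        df = df.iloc[np.argsort(keys, kind="stable")].reset_index(drop=True)
    values = df[pair_cols].to_numpy(dtype=float)
    missing_frac = np.mean(~np.isfinite(values), axis=1)
    drop = missing_frac > MISSING_FRACTION_LIMIT
    if drop.any():
        logger.warning(
            "%s: dropped %d probes missing in > %.0f%% of pairs",
            path,
            int(drop.sum()),
            100 * MISSING_FRACTION_LIMIT,
        )
        df = df.loc[~drop].reset_index(drop=True)
        values = values[~drop]
    probe_map = ProbeMap(
        probe_id=df["probe_id"].to_numpy(dtype=object),
        chromosome=df["chrom"].to_numpy(dtype=object),
        position=df["pos"].to_numpy(dtype=np.int64),
    )
    return PairRatioMatrix(probe_map=probe_map, pair_ids=pair_cols, values=values)


# ---------------------------------------------------------------------------
# BED catalogs and event truth


def read_bed_catalog(path: str | Path, source: str | None = None) -> CommonCnvCatalog:
    """Read a 3+ column BED into an overlap-queryable catalog.

    Zero- or negative-length records are rejected with a warning; the
    half-open 0-based coordinates are preserved exactly.
    """
    path = Path(path)
    catalog = CommonCnvCatalog(source=source or path.name)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            if start0 >= end0:
                logger.warning(
                    "%s:%d: rejected empty interval %s:%d-%d",
                    path,
                    lineno,
                    chrom,
                    start0,
                    end0,
                )
                continue
            catalog.add(chrom, start0, end0)
    return catalog


def write_bed_catalog(catalog: CommonCnvCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header())
        for chrom, start0, end0 in catalog.intervals():
            fh.write(f"chr{chrom}\t{start0}\t{end0}\n")


def write_events_bed(
    events: list[CnvEventSpec], path: str | Path, seed: int | None = None
) -> None:
    """Ground-truth planted events as BED-like TSV:
    chrom, start0, end, subject_id, copy_state, fraction."""
    with open(path, "w") as fh:
        fh.write(_header(seed))
        for ev in events:
            for sid in sorted(ev.subject_ids):
                fh.write(
                    f"chr{ev.chromosome}\t{ev.start - 1}\t{ev.end}\t{sid}"
                    f"\t{ev.copy_state}\t{ev.carrier_cell_fraction:g}\n"
                )


# ---------------------------------------------------------------------------
# aberration calls


CALL_COLUMNS = ["chrom", "start0", "end", "pair_id", "direction", "score", "mean_log2"]


def write_calls(
    calls: list[AberrationCall],
    probe_map: ProbeMap,
    path: str | Path,
    seed: int | None = None,
) -> None:
    """Aberration calls as BED-like TSV; interval spans the first to last
    member probe position (converted to 0-based half-open on disk)."""
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            start1 = int(probe_map.position[c.first_probe_index])
            end1 = int(probe_map.position[c.last_probe_index])
            fh.write(
                f"chr{c.chromosome}\t{start1 - 1}\t{end1}\t{c.pair_id}"
                f"\t{c.direction}\t{c.score:.4f}\t{c.mean_log2:.6f}\n"
            )


def read_calls(path: str | Path, probe_map: ProbeMap) -> list[AberrationCall]:
    """Read calls back, mapping interval ends to probe indices (the end
    positions must be probe midpoints of the given map)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    calls = []
    slices = probe_map.chrom_slices()
    for _, r in df.iterrows():
        chrom = normalize_chrom(r["chrom"])
        sl = slices.get(chrom)
        if sl is None:
            raise ValueError(f"{path}: unknown chromosome {chrom!r}")
        pos = probe_map.position[sl]
        start1, end1 = int(r["start0"]) + 1, int(r["end"])
        i = int(np.searchsorted(pos, start1))
        j = int(np.searchsorted(pos, end1))
        if i >= len(pos) or pos[i] != start1 or j >= len(pos) or pos[j] != end1:
            raise ValueError(
                f"{path}: call {chrom}:{start1}-{end1} does not match probe positions"
            )
        calls.append(
            AberrationCall(
                pair_id=str(r["pair_id"]),
                chromosome=chrom,
                first_probe_index=sl.start + i,
                last_probe_index=sl.start + j,
                direction=str(r["direction"]),
                score=float(r["score"]),
                mean_log2=float(r["mean_log2"]),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# candidate-locus table


LOCUS_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_probes",
    "span_kb",
    "mean_log2",
    "OR",
    "cum_neglog10p",
    "fisher_p",
    "frac_gaussian",
    "stage",
    "common_cnv_overlap",
]


def loci_to_frame(loci: list[CandidateLocus]) -> pd.DataFrame:
    rows = []
    for l in loci:
        rows.append(
            {
                "chrom": l.chromosome,
                "start": l.start,
                "end": l.end,
                "n_probes": l.n_probes,
                "span_kb": round(l.span_kb, 3),
                "mean_log2": round(l.mean_log2, 6),
                "OR": round(l.odds_ratio, 2),
                "cum_neglog10p": round(l.cum_neglog10p, 4),
                "fisher_p": l.fisher_p,
                "frac_gaussian": round(l.frac_gaussian, 4)
                if np.isfinite(l.frac_gaussian)
                else l.frac_gaussian,
                "stage": l.stage,
                "common_cnv_overlap": l.common_cnv_overlap,
            }
        )
    return pd.DataFrame(rows, columns=LOCUS_COLUMNS)


def write_loci_table(
    loci: list[CandidateLocus], path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        loci_to_frame(loci).to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_loci_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


# ---------------------------------------------------------------------------
# qPCR plates


def write_qpcr_plate(
    plate: pd.DataFrame, path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        plate.to_csv(fh, index=False, float_format="%.6g")


def read_qpcr_plate(path: str | Path) -> pd.DataFrame:
    plate = pd.read_csv(path, comment="#", dtype={"sample": str, "region": str})
    required = {"sample", "group", "region", "assay", "replicate", "ct"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"{path}: qPCR plate missing columns {sorted(missing)}")
    return plate
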