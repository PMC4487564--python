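"""File-level orchestration of the screening stages.

Stages compose through the documented on-disk formats so any stage can be
re-run in isolation:

    simulate -> detect -> select1 -> select2 -> annotate -> qpcr -> report

Every run writes the fully resolved configuration (including the seed)
next to its outputs, and identical configuration + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, cgh_io, qpcr, segmentation, selection
from .annotation import annotate_overlap
from .core import CandidateLocus, CnvEventSpec, PairRatioMatrix, SegmentationParams
from .synthetic_data import (
    DEFAULT_N_PAIRS,
    DEFAULT_SIGMA_RANGE,
    simulate_qpcr_plate,
    simulate_study,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: str
    ratios: str | None = None  # input TSV; None -> produced by simulate
    catalog: str | None = None  # common-CNV BED (annotation optional)
    qpcr_plate: str | None = None  # well CSV (validation optional)
    pairing_file: str | None = None  # TSV case<TAB>control (for qPCR)
    simulate: dict | None = None  # synthetic-study parameters
    tau: float = 6.0
    fuzzy_zero: bool = True
    bin_size: int = 10
    centralization: float = 6.0
    min_diff: int = 4
    alpha: float = 0.05
    select1_rule: str = "diff"
    gap_probes: int = 0
    min_overlap_bp: int = 1
    seed: int = 0

    @property
    def seg_params(self) -> SegmentationParams:
        return SegmentationParams(
            tau=self.tau,
            fuzzy_zero=self.fuzzy_zero,
            bin_size=self.bin_size,
            centralization_threshold=self.centralization,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# resolved by cghscreen v{__version__}\n")
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _events_from_config(specs: list[dict]) -> list[CnvEventSpec]:
    return [
        CnvEventSpec(
            chromosome=str(s["chromosome"]),
            start=int(s["start"]),
            end=int(s["end"]),
            copy_state=int(s["copy_state"]),
            carrier_cell_fraction=float(s.get("carrier_cell_fraction", 1.0)),
            subject_ids=frozenset(s["subject_ids"]),
        )
        for s in specs
    ]


def stage_simulate(cfg: RunConfig, out: Path) -> Path:
    """Generate a synthetic study; writes ratios.tsv, truth_events.bed,
    pairing.tsv and, when events are planted, qpcr_plate.csv."""
    sim = dict(cfg.simulate or {})
    qpcr_cfg = sim.pop("qpcr", {})
    events = _events_from_config(sim.pop("events", []))
    study = simulate_study(
        n_probes=int(sim.pop("n_probes", 10_000)),
        n_pairs=int(sim.pop("n_pairs", DEFAULT_N_PAIRS)),
        events=events,
        sigma_range=tuple(sim.pop("sigma_range", DEFAULT_SIGMA_RANGE)),
        chromosome_lengths=sim.pop("chromosome_lengths", None),
        wave_amplitude=float(sim.pop("wave_amplitude", 0.0)),
        seed=cfg.seed,
    )
    if sim:
        raise ValueError(f"unknown simulate keys: {sorted(sim)}")
    ratios_path = out / "ratios.tsv"
    cgh_io.write_ratio_matrix(study.matrix, ratios_path, seed=cfg.seed)
    cgh_io.write_events_bed(list(study.events), out / "truth_events.bed", seed=cfg.seed)
    with open(out / "pairing.tsv", "w") as fh:
        for case_id, ctrl_id in study.pairing:
            fh.write(f"{case_id}\t{ctrl_id}\n")
    cfg.pairing_file = str(out / "pairing.tsv")

    if study.events:
        doses = _event_doses(study)
        plate = simulate_qpcr_plate(
            doses,
            ct0=float(qpcr_cfg.get("ct0", 26.0)),
            sigma_ct=float(qpcr_cfg.get("sigma_ct", 0.05)),
            replicates=int(qpcr_cfg.get("replicates", 4)),
            seed=cfg.seed + 1,
        )
        cgh_io.write_qpcr_plate(plate, out / "qpcr_plate.csv", seed=cfg.seed)
        cfg.qpcr_plate = str(out / "qpcr_plate.csv")
    return ratios_path


def _event_doses(study) -> pd.DataFrame:
    """Per-subject dose table at each planted event locus, one target
    assay per event, single region."""
    subjects = [(c, "case") for c, _ in study.pairing] + [
        (k, "control") for _, k in study.pairing
    ]
    rows = []
    for ev in study.events:
        assay = f"locus_chr{ev.chromosome}_{ev.start}"
        from .synthetic_data import effective_dose

        ed = effective_dose(ev.copy_state, ev.carrier_cell_fraction)
        for sid, group in subjects:
            rows.append(
                {
                    "sample": sid,
                    "group": group,
                    "region": "striatum",
                    "assay": assay,
                    "dose": ed if sid in ev.subject_ids else 1.0,
                }
            )
    return pd.DataFrame(rows)


def stage_detect(cfg: RunConfig, out: Path, matrix: PairRatioMatrix) -> list:
    calls = segmentation.detect_all_pairs(matrix, cfg.seg_params)
    cgh_io.write_calls(calls, matrix.probe_map, out / "calls.tsv", seed=cfg.seed)
    return calls


def stage_select1(cfg: RunConfig, out: Path, matrix, calls) -> list[CandidateLocus]:
    summary = selection.penetrance_summary(calls, matrix.probe_map)
    loci = selection.select1_candidates(
        summary,
        matrix.probe_map,
        min_diff=cfg.min_diff,
        gap_probes=cfg.gap_probes,
        rule=cfg.select1_rule,
    )
    # stage-2 statistics do not exist yet; they serialize as NA
    cgh_io.write_loci_table(loci, out / "loci_selection1.tsv", cfg.seed)
    return loci


def stage_select2(cfg: RunConfig, out: Path, matrix, loci) -> list[CandidateLocus]:
    loci = selection.annotate_locus_statistics(loci, matrix)
    loci = selection.bonferroni_select(loci, alpha=cfg.alpha)
    cgh_io.write_loci_table(loci, out / "loci.tsv", seed=cfg.seed)
    return loci


def stage_annotate(cfg: RunConfig, out: Path, loci) -> list[CandidateLocus]:
    if cfg.catalog is None:
        logger.info("no common-CNV catalog supplied; skipping annotation")
        return loci
    catalog = cgh_io.read_bed_catalog(cfg.catalog)
    loci = annotate_overlap(loci, catalog, min_overlap_bp=cfg.min_overlap_bp)
    cgh_io.write_loci_table(loci, out / "loci.tsv", seed=cfg.seed)
    return loci


def _read_pairing(path: str) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            case_id, ctrl_id = line.split("\t")[:2]
            pairs.append((case_id, ctrl_id))
    return pairs


def stage_qpcr(cfg: RunConfig, out: Path) -> pd.DataFrame | None:
    """ΔΔCT copy numbers for every target assay on the plate plus the
    validation statistics; returns the statistics table."""
    if cfg.qpcr_plate is None:
        logger.info("no qPCR plate supplied; skipping validation")
        return None
    plate = cgh_io.read_qpcr_plate(cfg.qpcr_plate)
    pairing = _read_pairing(cfg.pairing_file) if cfg.pairing_file else []
    pair_of = {case: f"{case}:{ctrl}" for case, ctrl in pairing}
    pair_of.update({ctrl: f"{case}:{ctrl}" for case, ctrl in pairing})
    targets = sorted(set(plate["assay"]) - {qpcr.INTERNAL_CONTROL})
    cn_frames = []
    stat_rows = []
    for target in targets:
        cn = qpcr.sample_copy_numbers(plate, target)
        cn.insert(0, "assay", target)
        cn_frames.append(cn)
        rep = qpcr.replicate_copy_numbers(plate, target)
        gc = qpcr.group_compare(cn[["group", "cn"]])
        stat_rows.append(
            {"assay": target, "test": "chi_square_group", "p": gc["chi2_p"]}
        )
        stat_rows.append(
            {"assay": target, "test": "mann_whitney_group", "p": gc["mwu_p"]}
        )
        if pairing:
            rep2 = rep.copy()
            rep2["pair"] = rep2["sample"].map(pair_of)
            rep2 = rep2.dropna(subset=["pair"])
            rep2["disease"] = rep2["group"]
            try:
                an = qpcr.pair_anova(rep2[["pair", "disease", "cn"]])
                stat_rows.append(
                    {
                        "assay": target,
                        "test": "anova_disease",
                        "p": float(an.loc["disease", "p"]),
                    }
                )
            except ValueError as exc:
                logger.warning("pair_anova skipped for %s: %s", target, exc)
            if rep["region"].nunique() >= 2:
                rr = qpcr.region_ratio_test(rep, pairing)
                if rr["anova"] is not None:
                    stat_rows.append(
                        {
                            "assay": target,
                            "test": "anova_region_ratio",
                            "p": float(rr["anova"].loc["region", "p"]),
                        }
                    )
    cgh_io.write_qpcr_plate(pd.concat(cn_frames), out / "qpcr_copy_numbers.csv", cfg.seed)
    stats = pd.DataFrame(stat_rows, columns=["assay", "test", "p"])
    with open(out / "qpcr_stats.tsv", "w") as fh:
        fh.write(f"# cghscreen v{__version__} seed={cfg.seed}\n")
        stats.to_csv(fh, sep="\t", index=False)
    return stats


def stage_report(cfg: RunConfig, out: Path, matrix, calls, loci) -> dict:
    positive = [l for l in loci if l.stage == "both"]
    report = {
        "version": __version__,
        "seed": cfg.seed,
        "n_probes": matrix.probe_map.n_probes,
        "n_pairs": matrix.n_pairs,
        "n_aberration_calls": len(calls),
        "n_selection1_loci": len(loci),
        "n_selection2_loci": len(positive),
        "bonferroni_neglog10_threshold": (
            round(selection.bonferroni_threshold(cfg.alpha, len(loci)), 4)
            if loci
            else None
        ),
        "selection2_loci": [
            {
                "chrom": l.chromosome,
                "start": l.start,
                "end": l.end,
                "n_probes": l.n_probes,
                "mean_log2": round(l.mean_log2, 4),
                "OR": round(l.odds_ratio, 2),
                "cum_neglog10p": round(l.cum_neglog10p, 2),
                "common_cnv_overlap": l.common_cnv_overlap,
            }
            for l in positive
        ],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the report dict.

    Partial outputs are retained on failure; the raised exception names
    the failing stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        if cfg.ratios is None:
            stage = "simulate"
            cfg.ratios = str(stage_simulate(cfg, out))
        cfg.dump(out / "resolved_config.yaml")
        stage = "detect"
        matrix = cgh_io.read_ratio_matrix(cfg.ratios)
        calls = stage_detect(cfg, out, matrix)
        stage = "select1"
        loci = stage_select1(cfg, out, matrix, calls)
        stage = "select2"
        loci = stage_select2(cfg, out, matrix, loci)
        stage = "annotate"
        loci = stage_annotate(cfg, out, loci)
        stage = "qpcr"
        stage_qpcr(cfg, out)
        stage = "report"
        return stage_report(cfg, out, matrix, calls, loci)
    except Exception:
        logger.error("pipeline failed at stage %r (partial outputs in %s)", stage, out)
        raise


def demo_config(out_dir: str | Path, seed: int = 20) -> RunConfig:
    """Configuration reproducing the packaged small demonstration study:
    1000 probes on two chromosomes, 8 pairs, two planted case-only
    events (a constitutional het deletion and a 50%-mosaic amplification)."""
    return RunConfig(
        out_dir=str(out_dir),
        simulate={
            "n_probes": 1000,
            "n_pairs": 8,
            "sigma_range": [0.10, 0.20],
            "chromosome_lengths": {"1": 100e6, "2": 100e6},
            "events": [
                {
                    "chromosome": "1",
                    "start": 20_000_000,
                    "end": 24_000_000,
                    "copy_state": 1,
                    "carrier_cell_fraction": 1.0,
                    "subject_ids": [f"case_{i:02d}" for i in (1, 2, 3, 4, 5)],
                },
                {
                    "chromosome": "2",
                    "start": 60_000_000,
                    "end": 66_000_000,
                    "copy_state": 4,
                    "carrier_cell_fraction": 0.5,
                    "subject_ids": [f"case_{i:02d}" for i in (1, 3, 4, 6, 7, 8)],
                },
            ],
        },
        seed=seed,
    )
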