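"""Overlap annotation of candidate loci against a common-CNV catalog.

Recurrent candidate regions that coincide with population-level common
CNVs are plausibly germline polymorphisms rather than disease-associated
somatic events, so each locus is flagged by whether it shares at least
``min_overlap_bp`` bases with any catalog interval.  The catalog itself
(e.g. a population CNV reference set) is user-supplied as BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .core import CandidateLocus, normalize_chrom


@dataclass
class CommonCnvCatalog:
    """Overlap-queryable set of genomic intervals.

    Intervals are stored 0-based half-open (the BED disk convention);
    queries from 1-based inclusive locus coordinates convert at the call
    site.
    """

    source: str = "unknown"
    _trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, chromosome: str, start0: int, end0: int) -> None:
        if start0 >= end0:
            raise ValueError(f"empty interval {chromosome}:{start0}-{end0}")
        chrom = normalize_chrom(chromosome)
        self._trees.setdefault(chrom, IntervalTree()).addi(start0, end0)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def overlap_bp(self, chromosome: str, start1: int, end1: int) -> int:
        """Largest base overlap between the 1-based inclusive query
        interval and any single catalog interval."""
        tree = self._trees.get(normalize_chrom(chromosome))
        if tree is None:
            return 0
        q0, q1 = start1 - 1, end1  # to half-open
        best = 0
        for iv in tree.overlap(q0, q1):
            best = max(best, min(iv.end, q1) - max(iv.begin, q0))
        return best


def annotate_overlap(
    loci: list[CandidateLocus],
    catalog: CommonCnvCatalog,
    min_overlap_bp: int = 1,
) -> list[CandidateLocus]:
    """Set each locus's common_cnv_overlap flag.

    True iff some catalog interval shares >= min_overlap_bp bases with the
    locus.  Abutting intervals share zero bases and do not count.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    for locus in loci:
        locus.common_cnv_overlap = (
            catalog.overlap_bp(locus.chromosome, locus.start, locus.end)
            >= min_overlap_bp
        )
    return loci
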