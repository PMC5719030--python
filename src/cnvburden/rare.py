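"""Rare-CNV definition, genic annotation, candidate-locus overlap, case-only extraction.

A consensus CNV is *rare* when (a) its carrier frequency among controls is
below ``rare_threshold`` percent (carriers matched by reciprocal overlap,
one count per distinct control sample), and (b) less than half of its
length is covered by the common-CNV / segmental-duplication track
(intervals with population frequency above 1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, fraction_covered, reciprocal_overlap
from .types import CnvCall, GeneModel, GenomicTrack, SampleRecord

__all__ = [
    "AnnotatedCnv",
    "control_frequency",
    "filter_rare",
    "annotate_genic",
    "candidate_overlap",
    "case_only_cnvs",
]


@dataclass(frozen=True)
class AnnotatedCnv:
    """A consensus CNV with rarity and gene annotation attached."""

    call: CnvCall
    control_freq: float  # % of control samples carrying a matching call
    common_overlap_frac: float  # fraction covered by the common-CNV/segdup track
    genes: Tuple[str, ...] = ()
    is_rare: bool = False
    pop_freq: Optional[float] = None  # % from a DGV-like table, if matched
    exclusion_reason: Optional[str] = None

    @property
    def is_genic(self) -> bool:
        return len(self.genes) > 0

    @property
    def sample_id(self) -> str:
        return self.call.sample_id

    @property
    def cnv_type(self) -> str:
        return self.call.cnv_type

    @property
    def interval(self) -> GenomicInterval:
        return self.call.interval


def _index_calls(calls: Iterable[CnvCall]) -> Dict[Tuple[str, str], List[CnvCall]]:
    index: Dict[Tuple[str, str], List[CnvCall]] = {}
    for c in calls:
        index.setdefault((c.cnv_type, c.interval.chrom), []).append(c)
    return index


def control_frequency(
    call: CnvCall,
    control_calls: Sequence[CnvCall],
    n_controls: int,
    min_ro: float = 0.5,
) -> float:
    """Percent of control samples carrying a matching same-type call.

    A control sample counts once no matter how many of its calls match
    (carrier frequency, not call frequency). Matching requires the same
    CNV type and reciprocal overlap >= ``min_ro``.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    carriers: Set[str] = set()
    for other in control_calls:
        if other.cnv_type != call.cnv_type:
            continue
        if reciprocal_overlap(call.interval, other.interval) >= min_ro:
            carriers.add(other.sample_id)
    return 100.0 * len(carriers) / n_controls


def _pop_freq_lookup(
    call: CnvCall, table: Optional[GenomicTrack], min_ro: float
) -> Optional[float]:
    """Max frequency among table intervals matching at RO >= min_ro; None if no match."""
    if table is None or len(table) == 0:
        return None
    best: Optional[float] = None
    for iv, freq in zip(table.intervals, table.freqs):
        if freq is None:
            continue
        if reciprocal_overlap(call.interval, iv) >= min_ro:
            best = freq if best is None else max(best, freq)
    return best


def filter_rare(
    calls: Sequence[CnvCall],
    control_calls: Sequence[CnvCall],
    common_track: GenomicTrack,
    n_controls: int,
    rare_threshold: float = 1.0,
    min_ro: float = 0.5,
    max_common_overlap: float = 0.5,
) -> List[AnnotatedCnv]:
    """Annotate every call with control frequency and common-track coverage.

    ``is_rare`` is set iff control frequency < ``rare_threshold`` (%) and
    common-track coverage < ``max_common_overlap``; non-rare calls carry
    the failing criterion in ``exclusion_reason`` (never silently dropped).
    """
    control_index = _index_calls(control_calls)
    track_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in common_track.intervals:
        track_by_chrom.setdefault(iv.chrom, []).append(iv)

    out: List[AnnotatedCnv] = []
    for call in calls:
        bucket = control_index.get((call.cnv_type, call.interval.chrom), [])
        freq = control_frequency(call, bucket, n_controls, min_ro=min_ro)
        cov = fraction_covered(call.interval, track_by_chrom.get(call.interval.chrom, []))
        reasons = []
        if freq >= rare_threshold:
            reasons.append(f"control frequency {freq:.2f}% >= {rare_threshold}%")
        if cov >= max_common_overlap:
            reasons.append(
                f"common-track coverage {cov:.2f} >= {max_common_overlap}"
            )
        out.append(
            AnnotatedCnv(
                call=call,
                control_freq=freq,
                common_overlap_frac=cov,
                is_rare=not reasons,
                exclusion_reason="; ".join(reasons) or None,
            )
        )
    return out


def annotate_genic(
    cnvs: Sequence[AnnotatedCnv], genes: Sequence[GeneModel]
) -> List[AnnotatedCnv]:
    """Attach the sorted, deduplicated list of gene symbols each CNV overlaps.

    A CNV is genic iff it shares at least one base with at least one gene
    span (transcript-level, not exon-resolved).
    """
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.interval.chrom, IntervalTree())
        # IntervalTree is half-open; +1 on end keeps 1-based inclusive semantics
        tree.addi(g.interval.start, g.interval.end + 1, g.gene_symbol)
    out: List[AnnotatedCnv] = []
    for cnv in cnvs:
        tree = trees.get(cnv.interval.chrom)
        hits: Set[str] = set()
        if tree is not None:
            for node in tree.overlap(cnv.interval.start, cnv.interval.end + 1):
                hits.add(node.data)
        out.append(replace(cnv, genes=tuple(sorted(hits))))
    return out


def candidate_overlap(
    cnvs: Sequence[AnnotatedCnv],
    candidate_loci: Sequence[GeneModel],
    samples: Sequence[SampleRecord],
    rare_only: bool = True,
) -> pd.DataFrame:
    """Tabulate carriers of rare CNVs over a candidate-locus list.

    Returns one row per (locus, cnv_type) with at least one carrier:
    columns ``gene, cnv_type, case_carriers, control_carriers``.
    Overlap is >=1 shared base with the locus span; a sample counts once
    per (locus, type).
    """
    for locus in candidate_loci:
        if locus.interval is None:  # defensive; GeneModel requires an interval
            raise ValueError(f"candidate locus {locus.gene_symbol} lacks coordinates")
    phenotype = {s.sample_id: s.phenotype for s in samples}
    carriers: Dict[Tuple[str, str], Dict[str, Set[str]]] = {}
    for cnv in cnvs:
        if rare_only and not cnv.is_rare:
            continue
        phen = phenotype.get(cnv.sample_id)
        if phen is None:
            continue
        for locus in candidate_loci:
            if cnv.interval.overlaps(locus.interval):
                entry = carriers.setdefault(
                    (locus.gene_symbol, cnv.cnv_type),
                    {"case": set(), "control": set()},
                )
                entry[phen].add(cnv.sample_id)
    rows = [
        {
            "gene": gene,
            "cnv_type": cnv_type,
            "case_carriers": len(entry["case"]),
            "control_carriers": len(entry["control"]),
        }
        for (gene, cnv_type), entry in sorted(carriers.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "cnv_type", "case_carriers", "control_carriers"])


def case_only_cnvs(
    cnvs: Sequence[AnnotatedCnv],
    samples: Sequence[SampleRecord],
    pop_freq_table: Optional[GenomicTrack] = None,
    max_pop_freq: float = 0.2,
    min_ro: float = 0.5,
) -> Tuple[List[AnnotatedCnv], List[str]]:
    """Extract genic rare CNVs private to cases and rare in the population table.

    Keeps case-sample CNVs that are rare, genic, have zero matching
    control carriers (``control_freq == 0`` at RO >= ``min_ro``), and
    whose population frequency — the maximum over table intervals matched
    at RO >= ``min_ro``, 0 when unmatched or the table is absent — is
    below ``max_pop_freq`` percent. Returns the kept CNVs and the sorted
    union of their gene symbols.
    """
    phenotype = {s.sample_id: s.phenotype for s in samples}
    kept: List[AnnotatedCnv] = []
    genes: Set[str] = set()
    for cnv in cnvs:
        if phenotype.get(cnv.sample_id) != "case":
            continue
        if not (cnv.is_rare and cnv.is_genic):
            continue
        if cnv.control_freq > 0:
            continue
        pop = _pop_freq_lookup(cnv.call, pop_freq_table, min_ro)
        cnv = replace(cnv, pop_freq=pop)
        if (pop or 0.0) >= max_pop_freq:
            continue
        kept.append(cnv)
        genes.update(cnv.genes)
    return kept, sorted(genes)
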