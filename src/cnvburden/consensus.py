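"""Multi-caller consensus merging and sample-level quality control.

The stringent calling strategy keeps only CNV events reported
concordantly by at least ``min_callers`` of the calling algorithms:
within each sample, same-type calls from different callers are clustered
by single-linkage on reciprocal overlap (>= ``min_ro``), and each
sufficiently supported cluster is collapsed to one consensus call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, reciprocal_overlap
from .types import CnvCall, SampleRecord

__all__ = [
    "ConsensusResult",
    "consensus_calls",
    "SizeFilterResult",
    "size_filter",
    "QcThresholds",
    "sample_qc",
]


@dataclass
class ConsensusResult:
    """Consensus calls plus full bookkeeping for the conservation audit."""

    calls: List[CnvCall]
    #: input calls that did not reach a supported cluster, with reasons
    excluded: List[Tuple[CnvCall, str]]
    #: each cluster as the list of member input calls (supported ones first)
    clusters: List[List[CnvCall]]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def consensus_calls(
    calls_by_caller: Mapping[str, Sequence[CnvCall]],
    min_callers: int = 2,
    min_ro: float = 0.5,
    boundary: str = "union",
    full: bool = False,
):
    """Merge per-caller call lists into stringent consensus calls.

    Parameters
    ----------
    calls_by_caller : mapping of caller name -> list of CnvCall
    min_callers : int
        Minimum number of *distinct* callers that must support a cluster.
    min_ro : float
        Reciprocal-overlap threshold for single-linkage clustering.
    boundary : {"union", "intersection"}
        How the consensus interval is formed from a cluster's members.
    full : bool
        If True return a :class:`ConsensusResult` (calls, excluded-with-
        reason, clusters); otherwise just the consensus call list.

    Output is invariant to the order in which callers (and calls) are
    supplied. Deletions never merge with duplications.
    """
    if min_callers > len(calls_by_caller):
        raise ValueError(
            f"min_callers={min_callers} exceeds the {len(calls_by_caller)} caller lists provided"
        )
    if boundary not in ("union", "intersection"):
        raise ValueError("boundary must be 'union' or 'intersection'")

    # flatten with caller provenance; deterministic order regardless of input order
    items: List[Tuple[str, CnvCall]] = []
    for caller in sorted(calls_by_caller):
        for call in calls_by_caller[caller]:
            items.append((caller, call))
    items.sort(key=lambda t: (
        t[1].sample_id, t[1].cnv_type, t[1].interval.chrom,
        t[1].interval.start, t[1].interval.end, t[0],
    ))

    groups: Dict[Tuple[str, str, str], List[int]] = {}
    for idx, (_, call) in enumerate(items):
        key = (call.sample_id, call.cnv_type, call.interval.chrom)
        groups.setdefault(key, []).append(idx)

    consensus: List[CnvCall] = []
    excluded: List[Tuple[CnvCall, str]] = []
    clusters_out: List[List[CnvCall]] = []
    for key in sorted(groups):
        idxs = groups[key]
        uf = _UnionFind(len(idxs))
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                ia, ib = items[idxs[a]][1].interval, items[idxs[b]][1].interval
                if reciprocal_overlap(ia, ib) >= min_ro:
                    uf.union(a, b)
        clusters: Dict[int, List[int]] = {}
        for local, idx in enumerate(idxs):
            clusters.setdefault(uf.find(local), []).append(idx)
        for root in sorted(clusters, key=lambda r: min(clusters[r])):
            member_idx = clusters[root]
            members = [items[i] for i in member_idx]
            callers = frozenset(caller for caller, _ in members)
            clusters_out.append([c for _, c in members])
            if len(callers) < min_callers:
                for _, c in members:
                    excluded.append(
                        (c, f"supported by {len(callers)} caller(s) < min_callers={min_callers}")
                    )
                continue
            ivs = [c.interval for _, c in members]
            chrom = ivs[0].chrom
            if boundary == "union":
                start, end = min(iv.start for iv in ivs), max(iv.end for iv in ivs)
            else:
                start, end = max(iv.start for iv in ivs), min(iv.end for iv in ivs)
                if end < start:  # hollow intersection under chained linkage
                    start, end = min(iv.start for iv in ivs), max(iv.end for iv in ivs)
            cns = {c.copy_number for _, c in members if c.copy_number is not None}
            srcs = {c.source_id for _, c in members if c.source_id is not None}
            consensus.append(
                CnvCall(
                    sample_id=key[0],
                    interval=GenomicInterval(chrom, start, end),
                    cnv_type=key[1],
                    callers=callers,
                    copy_number=min(cns) if cns else None,
                    source_id=sorted(srcs)[0] if srcs else None,
                )
            )
    consensus.sort(key=lambda c: (
        c.sample_id, c.interval.chrom, c.interval.start, c.interval.end, c.cnv_type,
    ))
    if full:
        return ConsensusResult(consensus, excluded, clusters_out)
    return consensus


@dataclass
class SizeFilterResult:
    kept: List[CnvCall]
    excluded: List[Tuple[CnvCall, str]]


def size_filter(calls: Iterable[CnvCall], min_kb: float = 100.0, full: bool = False):
    """Keep calls spanning at least ``min_kb`` kilobases.

    With ``full=True`` returns a :class:`SizeFilterResult` whose
    ``excluded`` list carries a per-call reason, so
    ``len(kept) + len(excluded) == len(input)`` always holds.
    """
    kept: List[CnvCall] = []
    excluded: List[Tuple[CnvCall, str]] = []
    threshold_bp = min_kb * 1000
    for c in calls:
        if c.length_bp >= threshold_bp:
            kept.append(c)
        else:
            excluded.append((c, f"length {c.length_bp} bp < {min_kb} kb"))
    if full:
        return SizeFilterResult(kept, excluded)
    return kept


@dataclass(frozen=True)
class QcThresholds:
    """Configuration for the four sample-QC steps (each independently switchable)."""

    check_sex: bool = True
    check_covariates: bool = True
    check_cnv_outlier: bool = True
    check_duplicates: bool = True
    cnv_outlier_sd: float = 3.0


def sample_qc(
    samples: Sequence[SampleRecord],
    calls: Sequence[CnvCall],
    thresholds: QcThresholds = QcThresholds(),
    inferred_sex: Optional[Mapping[str, str]] = None,
) -> List[SampleRecord]:
    """Apply the four-step sample QC and return records with ``qc_pass`` set.

    Steps, in order: (1) missing or genotype-contradicted sex (requires
    ``inferred_sex``; skipped when not supplied), (2) completeness of the
    adjustment covariates, (3) per-sample CNV-count outliers above
    mean + ``cnv_outlier_sd``·SD, (4) duplicated sample identifiers (all
    copies after the first fail). A sample failing an earlier step is not
    re-tested by later ones; each failure records its reason.
    """
    counts: Dict[str, int] = {s.sample_id: 0 for s in samples}
    for c in calls:
        if c.sample_id in counts:
            counts[c.sample_id] += 1
    count_arr = np.array([counts[s.sample_id] for s in samples], dtype=float)
    mean, sd = float(count_arr.mean()) if len(count_arr) else 0.0, (
        float(count_arr.std(ddof=0)) if len(count_arr) else 0.0
    )
    cutoff = mean + thresholds.cnv_outlier_sd * sd

    seen_ids: set = set()
    out: List[SampleRecord] = []
    for s in samples:
        reason: Optional[str] = None
        if thresholds.check_sex and inferred_sex is not None:
            inferred = inferred_sex.get(s.sample_id)
            if inferred is None:
                reason = "sex_check: no inferred sex"
            elif inferred != s.sex:
                reason = f"sex_check: reported {s.sex}, inferred {inferred}"
        if reason is None and thresholds.check_covariates:
            if not s.adjustment_covariates_complete():
                reason = "covariates: missing adjustment covariate"
        if reason is None and thresholds.check_cnv_outlier and sd > 0:
            if counts[s.sample_id] > cutoff:
                reason = (
                    f"cnv_outlier: {counts[s.sample_id]} calls > "
                    f"mean+{thresholds.cnv_outlier_sd}SD ({cutoff:.1f})"
                )
        if reason is None and thresholds.check_duplicates:
            if s.sample_id in seen_ids:
                reason = "duplicate: sample_id already seen"
        seen_ids.add(s.sample_id)
        out.append(replace(s, qc_pass=reason is None, qc_fail_reason=reason))
    return out
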