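"""End-to-end convenience wiring of the pipeline stages.

Each stage is an ordinary function in its own module; this wrapper only
chains them with the default study settings (consensus at >=2 of 3
callers, RO 0.5; >=100 kb; rare at <1% control carrier frequency and
<50% common-track coverage; transcript-span genic annotation) so a
simulated or loaded cohort can be pushed to annotated rare CNVs in one
call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

from .consensus import consensus_calls, size_filter
from .rare import AnnotatedCnv, annotate_genic, filter_rare
from .types import CnvCall, GeneModel, GenomicTrack, SampleRecord

__all__ = ["annotate_cohort"]


def annotate_cohort(
    calls_by_caller: Mapping[str, Sequence[CnvCall]],
    samples: Sequence[SampleRecord],
    genes: Sequence[GeneModel],
    common_track: Optional[GenomicTrack] = None,
    min_callers: int = 2,
    min_ro: float = 0.5,
    min_kb: float = 100.0,
    rare_threshold: float = 1.0,
) -> List[AnnotatedCnv]:
    """Consensus-merge, size-filter, rare-filter and genic-annotate a cohort.

    Control carrier frequencies are computed against the consensus calls
    of the cohort's own qc_pass controls (the study's definition of
    rare). Returns one AnnotatedCnv per surviving consensus call, for
    qc_pass samples only.
    """
    qc_ids = {s.sample_id for s in samples if s.qc_pass}
    control_ids = {s.sample_id for s in samples if s.qc_pass and not s.is_case}
    n_controls = len(control_ids)
    if n_controls == 0:
        raise ValueError("cohort has no qc_pass controls; the rare definition needs them")

    consensus = consensus_calls(calls_by_caller, min_callers=min_callers, min_ro=min_ro)
    large = size_filter(consensus, min_kb=min_kb)
    large = [c for c in large if c.sample_id in qc_ids]
    control_calls = [c for c in large if c.sample_id in control_ids]
    track = common_track if common_track is not None else GenomicTrack("empty", [])
    annotated = filter_rare(
        large, control_calls, track, n_controls,
        rare_threshold=rare_threshold, min_ro=min_ro,
    )
    return annotate_genic(annotated, genes)
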