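"""Domain records shared across the pipeline stages."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .intervals import GenomicInterval, merge_intervals

__all__ = [
    "DELETION",
    "DUPLICATION",
    "CNV_TYPES",
    "AUTOSOMES",
    "ADJUSTMENT_COVARIATES",
    "CnvCall",
    "SampleRecord",
    "GeneModel",
    "GenomicTrack",
]

DELETION = "deletion"
DUPLICATION = "duplication"
CNV_TYPES = (DELETION, DUPLICATION)

#: Autosome labels carried by default into burden statistics.
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

#: Covariates the burden permutation test adjusts for.
ADJUSTMENT_COVARIATES = ("sex", "bmi", "triglycerides", "mds1")


@dataclass(frozen=True)
class CnvCall:
    """One deletion/duplication event in one sample.

    ``callers`` records which calling algorithm(s) support the event; a
    consensus call carries every supporting caller. ``source_id`` is an
    optional lineage tag (used by the simulator to link an emitted call to
    the true event it descends from).
    """

    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    callers: frozenset = field(default_factory=frozenset)
    copy_number: Optional[int] = None
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"cnv_type must be one of {CNV_TYPES}, got {self.cnv_type!r}")
        if not self.callers:
            raise ValueError("callers must be a non-empty set")
        if not isinstance(self.callers, frozenset):
            object.__setattr__(self, "callers", frozenset(self.callers))

    @property
    def length_bp(self) -> int:
        return self.interval.length_bp

    @property
    def is_autosomal(self) -> bool:
        return self.interval.chrom in AUTOSOMES


@dataclass(frozen=True)
class SampleRecord:
    """Phenotype plus covariates and QC state for one genotyped sample.

    ``phenotype`` is ``"case"`` or ``"control"``; ``sex`` is ``"male"`` or
    ``"female"``. Covariate completeness for adjustment (sex, BMI,
    triglycerides, MDS1) is enforced at the reader boundary
    (:func:`cnvburden.io.read_samples`) and audited by
    :func:`cnvburden.consensus.sample_qc`.
    """

    sample_id: str
    phenotype: str
    sex: str
    age: float = math.nan
    bmi: float = math.nan
    cholesterol: float = math.nan
    triglycerides: float = math.nan
    mds1: float = math.nan
    mds2: float = math.nan
    mds3: float = math.nan
    qc_pass: bool = True
    qc_fail_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.phenotype not in ("case", "control"):
            raise ValueError(f"phenotype must be 'case' or 'control', got {self.phenotype!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    @property
    def is_case(self) -> bool:
        return self.phenotype == "case"

    def adjustment_covariates_complete(self) -> bool:
        return not any(
            isinstance(v, float) and math.isnan(v)
            for v in (self.bmi, self.triglycerides, self.mds1)
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene symbol and its transcript span."""

    gene_symbol: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")


@dataclass
class GenomicTrack:
    """A named collection of intervals, optionally with per-interval frequency (%).

    Intervals are kept sorted by (chrom, start, end); ``freqs`` is a
    parallel list (None where no frequency is attached).
    """

    name: str
    intervals: List[GenomicInterval] = field(default_factory=list)
    freqs: List[Optional[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.freqs:
            self.freqs = [None] * len(self.intervals)
        if len(self.freqs) != len(self.intervals):
            raise ValueError("freqs must parallel intervals")
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (
                self.intervals[i].chrom,
                self.intervals[i].start,
                self.intervals[i].end,
            ),
        )
        self.intervals = [self.intervals[i] for i in order]
        self.freqs = [self.freqs[i] for i in order]

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self) -> List[GenomicInterval]:
        return merge_intervals(self.intervals)
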