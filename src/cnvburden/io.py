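"""Readers and writers for the formats the pipeline touches.

Supported CNV-call dialects:

``tsv``
    The package's native tab-separated format with header
    ``sample_id chrom start end cnv_type callers copy_number``;
    round-trips byte-stably through :func:`write_cnv_calls`.
``plink_cnv``
    PLINK ``.cnv`` segment lists: ``FID IID CHR BP1 BP2 TYPE SCORE SITES``
    with copy-number codes 0/1 = deletion, 3/4 = duplication.
``penncnv``
    PennCNV ``rawcnv`` output lines, e.g.
    ``chr4:43276-146490 numsnp=10 length=103,215 state2,cn=1 sample1 ...``.

All genomic coordinates are converted to the internal 1-based inclusive
convention on the way in; BED (0-based half-open) converts at this
boundary and nowhere else.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Union

from .intervals import GenomicInterval
from .types import (
    DELETION,
    DUPLICATION,
    CnvCall,
    GeneModel,
    GenomicTrack,
    SampleRecord,
)

__all__ = [
    "read_cnv_calls",
    "write_cnv_calls",
    "read_gene_bed",
    "read_track_bed",
    "read_gmt",
    "write_gmt",
    "read_samples",
    "write_samples",
    "read_candidate_loci",
    "read_population_freq",
]

PathLike = Union[str, Path]

_PLINK_DEL_CODES = {0, 1}
_PLINK_DUP_CODES = {3, 4}

_TSV_HEADER = "sample_id\tchrom\tstart\tend\tcnv_type\tcallers\tcopy_number"


class ParseError(ValueError):
    """Malformed input file; message carries file, line number and dialect."""


def _norm_chrom(label: str) -> str:
    return label if label.startswith("chr") else f"chr{label}"


def _parse_error(path: PathLike, lineno: int, dialect: str, msg: str) -> ParseError:
    return ParseError(f"{path}:{lineno} [{dialect}] {msg}")


def read_cnv_calls(path: PathLike, dialect: str = "tsv") -> List[CnvCall]:
    """Read per-sample CNV calls under the named dialect."""
    readers = {
        "tsv": _read_tsv_calls,
        "plink_cnv": _read_plink_calls,
        "penncnv": _read_penncnv_calls,
    }
    if dialect not in readers:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(readers)}")
    return readers[dialect](Path(path))


def _read_tsv_calls(path: Path) -> List[CnvCall]:
    calls: List[CnvCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.startswith("sample_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise _parse_error(path, lineno, "tsv", f"expected >=6 fields, got {len(fields)}")
            try:
                sample_id, chrom, start, end, cnv_type, callers = fields[:6]
                cn = None
                if len(fields) > 6 and fields[6] not in ("", "."):
                    cn = int(fields[6])
                calls.append(
                    CnvCall(
                        sample_id=sample_id,
                        interval=GenomicInterval(_norm_chrom(chrom), int(start), int(end)),
                        cnv_type=cnv_type,
                        callers=frozenset(callers.split(",")),
                        copy_number=cn,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise _parse_error(path, lineno, "tsv", str(exc)) from exc
    return calls


def _read_plink_calls(path: Path) -> List[CnvCall]:
    calls: List[CnvCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if fields[0] == "FID":  # header
                continue
            if len(fields) < 6:
                raise _parse_error(path, lineno, "plink_cnv", f"expected >=6 fields, got {len(fields)}")
            try:
                iid = fields[1]
                chrom = _norm_chrom(fields[2])
                start, end = int(fields[3]), int(fields[4])
                code = int(fields[5])
            except ValueError as exc:
                raise _parse_error(path, lineno, "plink_cnv", str(exc)) from exc
            if code in _PLINK_DEL_CODES:
                cnv_type = DELETION
            elif code in _PLINK_DUP_CODES:
                cnv_type = DUPLICATION
            else:
                raise _parse_error(path, lineno, "plink_cnv", f"unknown copy-number code {code}")
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise _parse_error(path, lineno, "plink_cnv", str(exc)) from exc
            calls.append(
                CnvCall(
                    sample_id=iid,
                    interval=interval,
                    cnv_type=cnv_type,
                    callers=frozenset({"plink"}),
                    copy_number=code,
                )
            )
    return calls


_PENNCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>[\d,]+)-(?P<end>[\d,]+)\s+"
    r"numsnp=(?P<numsnp>[\d,]+)\s+length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
)


def _read_penncnv_calls(path: Path) -> List[CnvCall]:
    calls: List[CnvCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = _PENNCNV_RE.match(line)
            if m is None:
                raise _parse_error(path, lineno, "penncnv", "line does not match rawcnv layout")
            cn = int(m.group("cn"))
            if cn < 2:
                cnv_type = DELETION
            elif cn > 2:
                cnv_type = DUPLICATION
            else:
                raise _parse_error(path, lineno, "penncnv", f"cn=2 is not a CNV state")
            try:
                interval = GenomicInterval(
                    _norm_chrom(m.group("chrom")),
                    int(m.group("start").replace(",", "")),
                    int(m.group("end").replace(",", "")),
                )
            except ValueError as exc:
                raise _parse_error(path, lineno, "penncnv", str(exc)) from exc
            calls.append(
                CnvCall(
                    sample_id=m.group("sample"),
                    interval=interval,
                    cnv_type=cnv_type,
                    callers=frozenset({"penncnv"}),
                    copy_number=cn,
                )
            )
    return calls


def write_cnv_calls(calls: Sequence[CnvCall], path: PathLike) -> None:
    """Write calls in the native tsv dialect (deterministic ordering)."""
    rows = sorted(
        calls,
        key=lambda c: (c.sample_id, c.interval.chrom, c.interval.start, c.interval.end, c.cnv_type),
    )
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for c in rows:
            cn = "" if c.copy_number is None else str(c.copy_number)
            fh.write(
                f"{c.sample_id}\t{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.cnv_type}\t{','.join(sorted(c.callers))}\t{cn}\n"
            )


def read_gene_bed(path: PathLike) -> List[GeneModel]:
    """Read gene spans from BED4 (0-based half-open → 1-based inclusive)."""
    genes: List[GeneModel] = []
    seen: Set = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise _parse_error(path, lineno, "bed", "gene BED needs 4 columns (chrom start end name)")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if end <= start:
                raise _parse_error(path, lineno, "bed", f"end ({end}) <= start ({start})")
            gene = GeneModel(name, GenomicInterval(_norm_chrom(chrom), start + 1, end))
            key = (gene.gene_symbol, gene.interval)
            if key in seen:
                continue
            seen.add(key)
            genes.append(gene)
    return genes


def read_track_bed(path: PathLike, name: Optional[str] = None) -> GenomicTrack:
    """Read a BED3(+frequency) interval track; column 4, if numeric, is a % frequency."""
    intervals: List[GenomicInterval] = []
    freqs: List[Optional[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _parse_error(path, lineno, "bed", "track BED needs >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise _parse_error(path, lineno, "bed", f"end ({end}) <= start ({start})")
            freq: Optional[float] = None
            if len(fields) >= 4:
                try:
                    freq = float(fields[3])
                except ValueError:
                    freq = None
            intervals.append(GenomicInterval(_norm_chrom(chrom), start + 1, end))
            freqs.append(freq)
    return GenomicTrack(name or Path(path).stem, intervals, freqs)


def read_gmt(path: PathLike) -> Dict[str, Set[str]]:
    """Read a GMT gene-set database: name, description, member genes (set semantics)."""
    sets: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _parse_error(path, lineno, "gmt", "GMT rows need name, description, >=1 gene")
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise _parse_error(path, lineno, "gmt", f"gene set {name!r} has no genes")
            sets[name] = genes
    return sets


def write_gmt(sets: Dict[str, Set[str]], path: PathLike, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description] + sorted(sets[name])) + "\n")


_SAMPLE_COLUMNS = [
    "sample_id", "phenotype", "sex", "age", "bmi", "cholesterol",
    "triglycerides", "mds1", "mds2", "mds3", "qc_pass", "qc_fail_reason",
]


def _float_or_nan(text: str) -> float:
    if text in ("", ".", "NA", "nan"):
        return math.nan
    return float(text)


def read_samples(path: PathLike) -> List[SampleRecord]:
    """Read the sample table (phenotype + covariates + QC state).

    Raises for a qc_pass sample with a missing adjustment covariate
    (sex, BMI, triglycerides or MDS1): downstream covariate adjustment
    would silently drop or corrupt such a sample otherwise.
    """
    samples: List[SampleRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _SAMPLE_COLUMNS[:10] if c not in header]
        if missing:
            raise ParseError(f"{path}: sample table missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            try:
                qc_pass = True
                if "qc_pass" in idx and len(f) > idx["qc_pass"]:
                    qc_pass = f[idx["qc_pass"]].lower() in ("1", "true", "yes", "")
                reason = None
                if "qc_fail_reason" in idx and len(f) > idx["qc_fail_reason"]:
                    reason = f[idx["qc_fail_reason"]] or None
                rec = SampleRecord(
                    sample_id=f[idx["sample_id"]],
                    phenotype=f[idx["phenotype"]],
                    sex=f[idx["sex"]],
                    age=_float_or_nan(f[idx["age"]]),
                    bmi=_float_or_nan(f[idx["bmi"]]),
                    cholesterol=_float_or_nan(f[idx["cholesterol"]]),
                    triglycerides=_float_or_nan(f[idx["triglycerides"]]),
                    mds1=_float_or_nan(f[idx["mds1"]]),
                    mds2=_float_or_nan(f[idx["mds2"]]),
                    mds3=_float_or_nan(f[idx["mds3"]]),
                    qc_pass=qc_pass,
                    qc_fail_reason=reason,
                )
            except (ValueError, IndexError) as exc:
                raise _parse_error(path, lineno, "samples", str(exc)) from exc
            if rec.qc_pass and not rec.adjustment_covariates_complete():
                raise _parse_error(
                    path, lineno, "samples",
                    f"qc_pass sample {rec.sample_id} has a missing adjustment covariate",
                )
            samples.append(rec)
    return samples


def write_samples(samples: Sequence[SampleRecord], path: PathLike) -> None:
    def fmt(v: float) -> str:
        return "NA" if (isinstance(v, float) and math.isnan(v)) else repr(v)

    with open(path, "w") as fh:
        fh.write("\t".join(_SAMPLE_COLUMNS) + "\n")
        for s in samples:
            fh.write(
                "\t".join(
                    [
                        s.sample_id, s.phenotype, s.sex,
                        fmt(s.age), fmt(s.bmi), fmt(s.cholesterol),
                        fmt(s.triglycerides), fmt(s.mds1), fmt(s.mds2), fmt(s.mds3),
                        "1" if s.qc_pass else "0", s.qc_fail_reason or "",
                    ]
                )
                + "\n"
            )


def read_candidate_loci(path: PathLike) -> List[GeneModel]:
    """Read a candidate-locus table: gene, chrom, start, end (1-based, TSV)."""
    loci: List[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("gene"):
                continue
            f = line.split("\t")
            if len(f) < 4 or any(not x for x in f[:4]):
                raise _parse_error(path, lineno, "candidates", "candidate entry needs gene, chrom, start, end")
            try:
                loci.append(
                    GeneModel(f[0], GenomicInterval(_norm_chrom(f[1]), int(f[2]), int(f[3])))
                )
            except ValueError as exc:
                raise _parse_error(path, lineno, "candidates", str(exc)) from exc
    return loci


def read_population_freq(path: PathLike) -> GenomicTrack:
    """Read a DGV-like population-frequency table: chrom, start, end, cnv_type, freq (%).

    The cnv_type column is accepted but not used for matching by default
    (frequency lookup is interval-based; see rare-filter configuration).
    """
    intervals: List[GenomicInterval] = []
    freqs: List[Optional[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("chrom"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise _parse_error(path, lineno, "popfreq", "needs chrom, start, end, cnv_type, freq")
            try:
                intervals.append(GenomicInterval(_norm_chrom(f[0]), int(f[1]), int(f[2])))
                freqs.append(float(f[4]))
            except ValueError as exc:
                raise _parse_error(path, lineno, "popfreq", str(exc)) from exc
    return GenomicTrack("population_freq", intervals, freqs)
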