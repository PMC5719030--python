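"""Rare-CNV burden statistics.

The centrepiece is :class:`RareCnvBurden`, a model object built from
annotated consensus CNVs and a sample table, whose :meth:`~RareCnvBurden.fit`
runs seven burden measures × three CNV classes through a one-sided
adaptive permutation test, both raw and covariate-adjusted
(Freedman–Lane residualization on sex, BMI, triglycerides and the first
MDS ancestry coordinate), and returns a :class:`RareCnvBurdenResults`
carrying the group summaries, case/control ratios and p-values.

The seven measures, computed per sample and summarised per group:

1. ``cnv_rate`` — number of rare CNVs per sample;
2. ``sample_proportion`` — indicator of carrying >=1 rare CNV;
3. ``total_size`` — summed rare-CNV length (kb);
4. ``average_size`` — mean rare-CNV length (kb; CNV-free samples are
   excluded from the group summary);
5. ``genic_rate`` — number of distinct genes spanned;
6. ``genic_proportion`` — indicator of carrying >=1 genic rare CNV (the
   per-CNV fraction of genic calls is also reported as a diagnostic);
7. ``genic_enrichment`` — genes spanned per kb of rare CNV.

Regional association (per-gene carrier counts) uses the two-sided Fisher
exact test; group characteristics are compared with chi-square and
Mann–Whitney U; post-hoc power for two-proportion comparisons uses the
pooled-null / unpooled-alternative normal approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .rare import AnnotatedCnv
from .types import ADJUSTMENT_COVARIATES, AUTOSOMES, DELETION, DUPLICATION, SampleRecord

__all__ = [
    "MEASURES",
    "CNV_CLASSES",
    "BurdenResult",
    "RegionalTest",
    "burden_measures",
    "PermutationResult",
    "permutation_test",
    "fisher_region_test",
    "regional_scan",
    "group_comparison",
    "two_proportion_power",
    "RareCnvBurden",
    "RareCnvBurdenResults",
]

MEASURES = (
    "cnv_rate",
    "sample_proportion",
    "total_size",
    "average_size",
    "genic_rate",
    "genic_proportion",
    "genic_enrichment",
)

CNV_CLASSES = ("deletions", "duplications", "both")

_MEASURE_COLUMN = {
    "cnv_rate": "count",
    "sample_proportion": "has_cnv",
    "total_size": "total_kb",
    "average_size": "mean_kb",
    "genic_rate": "n_genes",
    "genic_proportion": "has_genic",
    "genic_enrichment": "genes_per_kb",
}

#: early-stop threshold for the adaptive permutation rule
ADAPTIVE_EXCEEDANCES = 100


def _class_matches(cnv_type: str, cnv_class: str) -> bool:
    if cnv_class == "both":
        return True
    if cnv_class == "deletions":
        return cnv_type == DELETION
    if cnv_class == "duplications":
        return cnv_type == DUPLICATION
    raise ValueError(f"cnv_class must be one of {CNV_CLASSES}, got {cnv_class!r}")


def burden_measures(
    annotated_cnvs: Sequence[AnnotatedCnv],
    samples: Sequence[SampleRecord],
    cnv_class: str = "both",
    autosomes_only: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, Dict[str, float]]]:
    """Per-sample burden statistics and per-group summaries for one CNV class.

    Only rare CNVs and qc_pass samples enter the computation. Returns
    ``(per_sample, summaries)`` where ``per_sample`` is indexed by
    sample_id with columns ``phenotype, count, has_cnv, total_kb, mean_kb,
    n_genes, has_genic, genes_per_kb`` and ``summaries`` maps
    ``case``/``control``/``all`` to the seven measures (means of the
    per-sample values; proportions are means of indicators; average size
    averages over CNV-carrying samples only) plus
    ``genic_proportion_per_cnv``, the fraction of the group's CNVs that
    are genic.
    """
    use = [s for s in samples if s.qc_pass]
    if not use:
        raise ValueError("no qc_pass samples to compute burden over")
    rows = {
        s.sample_id: {
            "phenotype": s.phenotype, "count": 0, "total_kb": 0.0,
            "genes": set(), "n_genic_cnvs": 0,
        }
        for s in use
    }
    n_cnvs = {"case": 0, "control": 0}
    n_genic = {"case": 0, "control": 0}
    for cnv in annotated_cnvs:
        if not cnv.is_rare or cnv.sample_id not in rows:
            continue
        if not _class_matches(cnv.cnv_type, cnv_class):
            continue
        if autosomes_only and cnv.interval.chrom not in AUTOSOMES:
            continue
        r = rows[cnv.sample_id]
        r["count"] += 1
        r["total_kb"] += cnv.interval.length_bp / 1000.0
        r["genes"].update(cnv.genes)
        phen = r["phenotype"]
        n_cnvs[phen] += 1
        if cnv.is_genic:
            r["n_genic_cnvs"] += 1
            n_genic[phen] += 1

    records = []
    for sid, r in rows.items():
        count, total_kb = r["count"], r["total_kb"]
        records.append(
            {
                "sample_id": sid, "phenotype": r["phenotype"],
                "count": count,
                "has_cnv": 1.0 if count > 0 else 0.0,
                "total_kb": total_kb,
                "mean_kb": total_kb / count if count else 0.0,
                "n_genes": len(r["genes"]),
                "has_genic": 1.0 if r["n_genic_cnvs"] > 0 else 0.0,
                "genes_per_kb": len(r["genes"]) / total_kb if total_kb > 0 else 0.0,
            }
        )
    per_sample = pd.DataFrame.from_records(records).set_index("sample_id")

    summaries: Dict[str, Dict[str, float]] = {}
    for group in ("case", "control", "all"):
        sub = per_sample if group == "all" else per_sample[per_sample["phenotype"] == group]
        carriers = sub[sub["count"] > 0]
        total_calls = n_cnvs["case"] + n_cnvs["control"] if group == "all" else n_cnvs[group]
        genic_calls = n_genic["case"] + n_genic["control"] if group == "all" else n_genic[group]
        summaries[group] = {
            "cnv_rate": float(sub["count"].mean()) if len(sub) else math.nan,
            "sample_proportion": float(sub["has_cnv"].mean()) if len(sub) else math.nan,
            "total_size": float(sub["total_kb"].mean()) if len(sub) else math.nan,
            "average_size": float(carriers["mean_kb"].mean()) if len(carriers) else 0.0,
            "genic_rate": float(sub["n_genes"].mean()) if len(sub) else math.nan,
            "genic_proportion": float(sub["has_genic"].mean()) if len(sub) else math.nan,
            "genic_enrichment": float(sub["genes_per_kb"].mean()) if len(sub) else math.nan,
            "genic_proportion_per_cnv": genic_calls / total_calls if total_calls else 0.0,
        }
    return per_sample, summaries


@dataclass(frozen=True)
class PermutationResult:
    p_raw: float
    p_adjusted: Optional[float]
    n_used: int


def _residualize(x: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(x)), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular covariate design matrix")
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def _perm_pvalue(
    x: np.ndarray,
    case_mask: np.ndarray,
    n_perm: int,
    adaptive: bool,
    rng: np.random.Generator,
    alternative: str,
) -> Tuple[float, int]:
    n = len(x)
    n_case = int(case_mask.sum())
    n_ctrl = n - n_case
    observed = x[case_mask].mean() - x[~case_mask].mean()
    tol = 1e-9 * max(1.0, abs(observed))

    def exceeds(stat: np.ndarray) -> np.ndarray:
        if alternative == "two-sided":
            return np.abs(stat) >= abs(observed) - tol
        return stat >= observed - tol

    # exhaustive enumeration when every distinct labelling fits the budget
    if math.comb(n, n_case) <= n_perm:
        total = exceed = 0
        idx = np.arange(n)
        for case_idx in combinations(range(n), n_case):
            mask = np.zeros(n, dtype=bool)
            mask[list(case_idx)] = True
            stat = x[mask].mean() - x[~mask].mean()
            total += 1
            if exceeds(np.array([stat]))[0]:
                exceed += 1
        return exceed / total, total  # includes the identity labelling, so > 0

    sum_x = x.sum()
    scale = 1.0 / n_case + 1.0 / n_ctrl
    exceed = 0
    used = 0
    chunk_size = 512
    base = np.broadcast_to(case_mask, (chunk_size, n))
    while used < n_perm:
        k = min(chunk_size, n_perm - used)
        perm = rng.permuted(np.array(base[:k], dtype=bool), axis=1)
        case_sums = perm.astype(np.float64) @ x
        stat = case_sums * scale - sum_x / n_ctrl
        exceed += int(exceeds(stat).sum())
        used += k
        if adaptive and exceed >= ADAPTIVE_EXCEEDANCES:
            break
    return (1 + exceed) / (1 + used), used


def permutation_test(
    per_sample_stat: Sequence[float],
    labels: Sequence,
    covariates: Optional[np.ndarray] = None,
    n_perm: int = 10_000,
    adaptive: bool = True,
    seed: Optional[int] = None,
    alternative: str = "greater",
) -> PermutationResult:
    """One-sided (case > control) label-permutation test on a per-sample statistic.

    The test statistic is mean(case) − mean(control). ``p_raw`` is the
    add-one permutation p-value ``(1 + #{permuted >= observed}) /
    (1 + n_used)``; ``p_adjusted`` applies the identical procedure to the
    residuals of an ordinary least-squares regression of the statistic on
    the covariates (plus intercept) — residualize first, then permute
    labels (Freedman–Lane). When every distinct case/control labelling
    fits within ``n_perm``, the null is enumerated exhaustively and the
    p-value is exact. The adaptive rule stops sampling once 100 permuted
    statistics have reached the observed one (the estimate is then
    precise enough far from significance); identical seeds give identical
    p-values.

    Parameters
    ----------
    labels : sequence of {1/0, True/False, "case"/"control"}
    alternative : {"greater", "two-sided"}
    """
    x = np.asarray(per_sample_stat, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype.kind in "US":
        case_mask = lab == "case"
    else:
        case_mask = lab.astype(bool)
    if case_mask.all() or not case_mask.any():
        raise ValueError("labels must contain both cases and controls")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    if np.ptp(x) == 0:
        warnings.warn("constant per-sample statistic; permutation p-value is 1")
        return PermutationResult(1.0, 1.0 if covariates is not None else None, 0)

    ss = np.random.SeedSequence(seed)
    rng_raw, rng_adj = (np.random.default_rng(s) for s in ss.spawn(2))
    p_raw, n_raw = _perm_pvalue(x, case_mask, n_perm, adaptive, rng_raw, alternative)

    p_adj: Optional[float] = None
    n_adj = 0
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        resid = _residualize(x, cov)
        if np.ptp(resid) == 0:
            warnings.warn("constant residual statistic; adjusted p-value is 1")
            p_adj, n_adj = 1.0, 0
        else:
            p_adj, n_adj = _perm_pvalue(resid, case_mask, n_perm, adaptive, rng_adj, alternative)
    return PermutationResult(p_raw, p_adj, max(n_raw, n_adj))


def fisher_region_test(
    carriers_case: int, n_case: int, carriers_control: int, n_control: int
) -> float:
    """Two-sided Fisher exact p for a 2x2 carrier table.

    Probability-mass rule: the p-value sums hypergeometric probabilities
    of all tables (with the observed margins) no more probable than the
    observed one.
    """
    if not (0 <= carriers_case <= n_case and 0 <= carriers_control <= n_control):
        raise ValueError("carrier counts must lie within group sizes")
    table = [
        [carriers_case, n_case - carriers_case],
        [carriers_control, n_control - carriers_control],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass(frozen=True)
class RegionalTest:
    """Per-gene carrier comparison between cases and controls."""

    gene: str
    cnv_class: str
    carriers_case: int
    carriers_control: int
    n_case: int
    n_control: int
    p: float
    q: Optional[float] = None


def regional_scan(
    annotated_cnvs: Sequence[AnnotatedCnv],
    samples: Sequence[SampleRecord],
    min_carriers: int = 1,
    cnv_classes: Sequence[str] = CNV_CLASSES,
    fdr: bool = False,
) -> List[RegionalTest]:
    """Fisher-test every (gene, CNV class) with >= ``min_carriers`` total carriers.

    A carrier is a qc_pass sample with >=1 rare CNV of the class
    overlapping the gene. With ``fdr=True``, Benjamini–Hochberg q-values
    are attached per class (off by default).
    """
    use = [s for s in samples if s.qc_pass]
    phenotype = {s.sample_id: s.phenotype for s in use}
    n_case = sum(1 for s in use if s.is_case)
    n_control = len(use) - n_case
    carriers: Dict[Tuple[str, str], Dict[str, set]] = {}
    for cnv in annotated_cnvs:
        if not (cnv.is_rare and cnv.is_genic):
            continue
        phen = phenotype.get(cnv.sample_id)
        if phen is None:
            continue
        for cls in cnv_classes:
            if not _class_matches(cnv.cnv_type, cls):
                continue
            for gene in cnv.genes:
                entry = carriers.setdefault((gene, cls), {"case": set(), "control": set()})
                entry[phen].add(cnv.sample_id)

    results: List[RegionalTest] = []
    for (gene, cls), entry in sorted(carriers.items()):
        a, b = len(entry["case"]), len(entry["control"])
        if a + b < min_carriers:
            continue
        results.append(
            RegionalTest(
                gene=gene, cnv_class=cls, carriers_case=a, carriers_control=b,
                n_case=n_case, n_control=n_control,
                p=fisher_region_test(a, n_case, b, n_control),
            )
        )
    if fdr and results:
        from statsmodels.stats.multitest import multipletests

        out: List[RegionalTest] = []
        for cls in cnv_classes:
            cls_results = [r for r in results if r.cnv_class == cls]
            if not cls_results:
                continue
            _, qvals, _, _ = multipletests([r.p for r in cls_results], method="fdr_bh")
            out.extend(
                RegionalTest(r.gene, r.cnv_class, r.carriers_case, r.carriers_control,
                             r.n_case, r.n_control, r.p, q=float(q))
                for r, q in zip(cls_results, qvals)
            )
        results = sorted(out, key=lambda r: (r.gene, r.cnv_class))
    return results


def _chi2_p(table: List[List[int]]) -> float:
    """Chi-square p without continuity correction; degenerate tables give p = 1."""
    rows = [row for row in table if sum(row) > 0]
    if len(rows) < 2 or any(sum(col) == 0 for col in zip(*rows)):
        return 1.0
    return float(stats.chi2_contingency(rows, correction=False)[1])


def _median_iqr(values: np.ndarray) -> str:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.2f} ± {q3 - q1:.2f}"


def group_comparison(
    samples: Sequence[SampleRecord],
    annotated_cnvs: Optional[Sequence[AnnotatedCnv]] = None,
) -> pd.DataFrame:
    """Case/control comparison of general characteristics (and, optionally, CNVs).

    Categorical variables (sex; deletion/duplication composition when
    CNVs are supplied) use the chi-square test without continuity
    correction; numeric covariates and CNV sizes use the Mann–Whitney U
    test with the tie-corrected normal approximation. Numeric rows are
    reported as median ± IQR, mirroring the usual cohort table.
    """
    use = [s for s in samples if s.qc_pass]
    cases = [s for s in use if s.is_case]
    controls = [s for s in use if not s.is_case]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need >= 2 qc_pass samples per group")

    rows = [{"characteristic": "n", "case": str(len(cases)), "control": str(len(controls)),
             "p": math.nan, "test": ""}]

    male = [sum(1 for s in g if s.sex == "male") for g in (cases, controls)]
    female = [len(g) - m for g, m in zip((cases, controls), male)]
    chi2_p = _chi2_p([male, female])
    rows.append({
        "characteristic": "male/female sex",
        "case": f"{male[0]}/{female[0]}", "control": f"{male[1]}/{female[1]}",
        "p": chi2_p, "test": "chi2",
    })

    for attr in ("age", "bmi", "cholesterol", "triglycerides", "mds1", "mds2", "mds3"):
        x = np.array([getattr(s, attr) for s in cases], dtype=float)
        y = np.array([getattr(s, attr) for s in controls], dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if np.ptp(np.concatenate([x, y])) == 0:
            warnings.warn(f"{attr}: zero variance in both groups; U test is degenerate")
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", use_continuity=False,
                                  method="asymptotic")
        rows.append({
            "characteristic": attr, "case": _median_iqr(x), "control": _median_iqr(y),
            "p": float(p), "test": "mannwhitneyu",
        })

    if annotated_cnvs is not None:
        phen = {s.sample_id: s.phenotype for s in use}
        counts = {("case", DELETION): 0, ("case", DUPLICATION): 0,
                  ("control", DELETION): 0, ("control", DUPLICATION): 0}
        sizes: Dict[str, List[float]] = {"case": [], "control": []}
        for cnv in annotated_cnvs:
            if not cnv.is_rare or cnv.sample_id not in phen:
                continue
            g = phen[cnv.sample_id]
            counts[(g, cnv.cnv_type)] += 1
            sizes[g].append(cnv.interval.length_bp / 1000.0)
        table = [
            [counts[("case", DELETION)], counts[("control", DELETION)]],
            [counts[("case", DUPLICATION)], counts[("control", DUPLICATION)]],
        ]
        rows.append({
            "characteristic": "rare CNVs (n)",
            "case": str(sum(table[i][0] for i in range(2))),
            "control": str(sum(table[i][1] for i in range(2))),
            "p": math.nan, "test": "",
        })
        if all(sum(row) > 0 for row in table):
            p_deldup = _chi2_p(table)
            rows.append({
                "characteristic": "deletions/duplications",
                "case": f"{table[0][0]}/{table[1][0]}",
                "control": f"{table[0][1]}/{table[1][1]}",
                "p": p_deldup, "test": "chi2",
            })
        if sizes["case"] and sizes["control"]:
            _, p_size = stats.mannwhitneyu(
                sizes["case"], sizes["control"], alternative="two-sided",
                use_continuity=False, method="asymptotic")
            rows.append({
                "characteristic": "CNV size (kb)",
                "case": _median_iqr(np.array(sizes["case"])),
                "control": _median_iqr(np.array(sizes["control"])),
                "p": float(p_size), "test": "mannwhitneyu",
            })
    return pd.DataFrame(rows, columns=["characteristic", "case", "control", "p", "test"])


def two_proportion_power(
    p1: float, p2: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Post-hoc power of a two-sided two-proportion z-test.

    Uses the pooled proportion for the null standard error and the
    unpooled proportions for the alternative:
    ``power = Phi((|p1 - p2| - z_{alpha/2} * se0) / se1)``. When
    ``p1 == p2`` the detectable difference is zero and the function
    returns ``Phi(-z_{alpha/2})``.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    z = stats.norm.ppf(1 - alpha / 2)
    if p1 == p2:
        return float(stats.norm.cdf(-z))
    diff = abs(p1 - p2)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    if se1 == 0:
        return 1.0
    return float(stats.norm.cdf((diff - z * se0) / se1))


@dataclass(frozen=True)
class BurdenResult:
    """One burden measure for one CNV class, with permutation p-values."""

    measure: str
    cnv_class: str
    value_case: float
    value_control: float
    value_all: float
    ratio: float
    p_raw: float
    p_adjusted: Optional[float]
    n_permutations_used: int


class RareCnvBurden:
    """Case/control rare-CNV burden model.

    Parameters
    ----------
    annotated_cnvs : sequence of AnnotatedCnv
        Consensus CNVs after rare filtering and genic annotation; only
        calls flagged ``is_rare`` contribute.
    samples : sequence of SampleRecord
        Cohort table; only qc_pass samples enter the analysis.
    covariates : sequence of str
        SampleRecord attributes to adjust for (default sex, BMI,
        triglycerides, MDS1; sex is coded male=1/female=0).
    autosomes_only : bool
        Restrict the burden to autosomal CNVs (default True).

    Examples
    --------
    >>> model = RareCnvBurden(annotated, samples)          # doctest: +SKIP
    >>> res = model.fit(n_perm=10_000, seed=17)            # doctest: +SKIP
    >>> print(res.summary())                               # doctest: +SKIP
    """

    def __init__(
        self,
        annotated_cnvs: Sequence[AnnotatedCnv],
        samples: Sequence[SampleRecord],
        covariates: Sequence[str] = ADJUSTMENT_COVARIATES,
        autosomes_only: bool = True,
    ) -> None:
        self.annotated_cnvs = list(annotated_cnvs)
        self.samples = [s for s in samples if s.qc_pass]
        if not self.samples:
            raise ValueError("no qc_pass samples")
        self.covariate_names = tuple(covariates)
        self.autosomes_only = autosomes_only
        self.labels = np.array([1 if s.is_case else 0 for s in self.samples])
        cols = []
        for name in self.covariate_names:
            if name == "sex":
                cols.append([1.0 if s.sex == "male" else 0.0 for s in self.samples])
            else:
                vals = [float(getattr(s, name)) for s in self.samples]
                if any(math.isnan(v) for v in vals):
                    raise ValueError(f"covariate {name!r} has missing values in qc_pass samples")
                cols.append(vals)
        self.covariate_matrix = np.array(cols).T if cols else None

    def fit(
        self,
        n_perm: int = 10_000,
        seed: Optional[int] = None,
        adaptive: bool = True,
        alternative: str = "greater",
        cnv_classes: Sequence[str] = CNV_CLASSES,
        measures: Sequence[str] = MEASURES,
    ) -> "RareCnvBurdenResults":
        """Run the permutation burden analysis and return the results object."""
        ss = np.random.SeedSequence(seed)
        child_seeds = iter(ss.spawn(len(cnv_classes) * len(measures)))
        results: List[BurdenResult] = []
        per_sample_frames: Dict[str, pd.DataFrame] = {}
        summaries: Dict[str, Dict[str, Dict[str, float]]] = {}
        order = [s.sample_id for s in self.samples]
        for cls in cnv_classes:
            per_sample, summary = burden_measures(
                self.annotated_cnvs, self.samples, cnv_class=cls,
                autosomes_only=self.autosomes_only,
            )
            per_sample = per_sample.loc[order]
            per_sample_frames[cls] = per_sample
            summaries[cls] = summary
            for measure in measures:
                col = _MEASURE_COLUMN[measure]
                x = per_sample[col].to_numpy(dtype=float)
                child = next(child_seeds)
                if np.ptp(x) == 0:
                    pres = PermutationResult(1.0, 1.0 if self.covariate_matrix is not None else None, 0)
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        pres = permutation_test(
                            x, self.labels, covariates=self.covariate_matrix,
                            n_perm=n_perm, adaptive=adaptive,
                            seed=int(child.generate_state(1)[0] % (2**31)),
                            alternative=alternative,
                        )
                v_case = summary["case"][measure]
                v_ctrl = summary["control"][measure]
                ratio = v_case / v_ctrl if v_ctrl else math.inf if v_case else math.nan
                results.append(
                    BurdenResult(
                        measure=measure, cnv_class=cls,
                        value_case=v_case, value_control=v_ctrl,
                        value_all=summary["all"][measure], ratio=ratio,
                        p_raw=pres.p_raw, p_adjusted=pres.p_adjusted,
                        n_permutations_used=pres.n_used,
                    )
                )
        return RareCnvBurdenResults(self, results, per_sample_frames, summaries)


class RareCnvBurdenResults:
    """Fitted burden analysis: estimates, ratios, permutation p-values.

    Attributes
    ----------
    results : list of BurdenResult
    table : pandas.DataFrame
        One row per (measure, class) with case/control/all values, the
        case:control ratio, and raw/adjusted p-values.
    per_sample : dict of class -> DataFrame
        The per-sample statistic vectors that fed each test.
    """

    def __init__(
        self,
        model: RareCnvBurden,
        results: List[BurdenResult],
        per_sample: Dict[str, pd.DataFrame],
        summaries: Dict[str, Dict[str, Dict[str, float]]],
    ) -> None:
        self.model = model
        self.results = results
        self.per_sample = per_sample
        self.summaries = summaries
        self.table = pd.DataFrame(
            [
                {
                    "measure": r.measure, "cnv_class": r.cnv_class,
                    "case": r.value_case, "control": r.value_control,
                    "all": r.value_all, "ratio": r.ratio,
                    "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
                    "n_perm": r.n_permutations_used,
                }
                for r in results
            ]
        )

    def summary(self) -> str:
        """Human-readable burden table (measure × class grid with p-values)."""
        n_case = int(self.model.labels.sum())
        n_ctrl = len(self.model.labels) - n_case
        lines = [
            "Rare CNV burden analysis",
            f"  samples: {n_case} cases / {n_ctrl} controls",
            f"  covariate adjustment: {', '.join(self.model.covariate_names) or 'none'}",
            "",
            self.table.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
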