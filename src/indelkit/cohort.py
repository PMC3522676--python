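"""Cohort-level statistics: allele frequencies, frequency classes,
consequence-by-provenance summary matrices, and validation statistics.

Frequency definitions
---------------------
The non-reference allele frequency of a variant is ``allele_count / (2 N)``
for a cohort of N diploid samples, with heterozygous carriers contributing
one allele and homozygous-alternative carriers two.  Classification
precedence is PRIVATE (exactly one carrier sample), then COMMON
(frequency >= threshold, inclusive), then RARE.  Summary tables additionally
use a "rare" stratum meaning frequency strictly below the threshold, which
covers both RARE and (almost always) PRIVATE variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import (
    CohortCallSet,
    Consequence,
    FrequencyClass,
    NormalizedIndel,
    Provenance,
)

__all__ = [
    "FrequencyRecord",
    "compute_frequencies",
    "summarize_counts",
    "recompute_excluding",
    "consequence_proportions",
    "compare_groups",
    "validation_chisq",
    "validation_rates",
    "size_spectrum",
    "round_half_up",
]


@dataclass(frozen=True)
class FrequencyRecord:
    variant: NormalizedIndel
    carrier_count: int
    allele_count: int
    freq: float
    freq_class: FrequencyClass


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (141/160 -> 88.13%, not banker's 88.12)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def classify_frequency(
    carrier_count: int, freq: float, threshold: float = 0.05
) -> FrequencyClass:
    if carrier_count == 1:
        return FrequencyClass.PRIVATE
    if freq >= threshold:  # threshold itself counts as common
        return FrequencyClass.COMMON
    return FrequencyClass.RARE


def compute_frequencies(
    cohort: CohortCallSet, threshold: float = 0.05
) -> dict[NormalizedIndel, FrequencyRecord]:
    """Non-reference allele frequency and class per distinct variant.

    Samples absent from a variant's carriers are homozygous reference;
    missing genotypes were already counted at VCF read time and are treated
    the same way.
    """
    if cohort.n_samples == 0:
        raise ValueError("cannot compute frequencies on an empty cohort")
    out: dict[NormalizedIndel, FrequencyRecord] = {}
    denom = 2 * cohort.n_samples
    for variant, calls in cohort.calls_by_variant().items():
        ac = sum(c.genotype.allele_count for c in calls)
        freq = ac / denom
        out[variant] = FrequencyRecord(
            variant=variant,
            carrier_count=len(calls),
            allele_count=ac,
            freq=freq,
            freq_class=classify_frequency(len(calls), freq, threshold),
        )
    return out


_PROV_ORDER = [Provenance.KNOWN_DB, Provenance.NEWLY_RELEASED_ONLY, Provenance.NOVEL]


def summarize_counts(
    cohort: CohortCallSet,
    provenance: Mapping[NormalizedIndel, Provenance],
    consequences: Mapping[NormalizedIndel, Consequence],
    frequencies: Mapping[NormalizedIndel, FrequencyRecord],
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Consequence x provenance summary matrix.

    Per cell: mean and standard deviation (ddof=1) of per-sample call
    counts, the same for the rare stratum (frequency < threshold), and the
    ratio of rare distinct variants over all distinct variants in the cell.
    A total row/column is appended.  Empty strata keep their zero rows.
    """
    n = cohort.n_samples
    samples = list(cohort.samples)
    cat_names = [c.name for c in Consequence]
    prov_names = [p.value for p in _PROV_ORDER]

    rows = []
    for call in cohort.calls:
        v = call.variant
        rows.append(
            (
                call.sample_id,
                consequences[v].name,
                provenance[v].value,
                frequencies[v].freq < threshold,
                v.key,
            )
        )
    df = pd.DataFrame(
        rows, columns=["sample", "consequence", "provenance", "rare", "variant"]
    )

    def _cell(sub: pd.DataFrame) -> dict[str, float]:
        per_sample = sub.groupby("sample").size().reindex(samples, fill_value=0)
        rare_sub = sub[sub["rare"]]
        per_sample_rare = (
            rare_sub.groupby("sample").size().reindex(samples, fill_value=0)
        )
        n_distinct = sub["variant"].nunique()
        n_rare = rare_sub["variant"].nunique()
        return {
            "mean": float(per_sample.mean()),
            "sd": float(per_sample.std(ddof=1)) if n > 1 else 0.0,
            "mean_rare": float(per_sample_rare.mean()),
            "sd_rare": float(per_sample_rare.std(ddof=1)) if n > 1 else 0.0,
            "ratio_rare_total": (n_rare / n_distinct) if n_distinct else float("nan"),
        }

    metrics = ["mean", "sd", "mean_rare", "sd_rare", "ratio_rare_total"]
    columns = pd.MultiIndex.from_product([prov_names + ["total"], metrics])
    out = pd.DataFrame(0.0, index=cat_names + ["total"], columns=columns)
    for prov in prov_names + ["total"]:
        for cat in cat_names + ["total"]:
            sub = df
            if prov != "total":
                sub = sub[sub["provenance"] == prov]
            if cat != "total":
                sub = sub[sub["consequence"] == cat]
            if sub.empty:
                cell = {m: (float("nan") if m == "ratio_rare_total" else 0.0) for m in metrics}
            else:
                cell = _cell(sub)
            for m in metrics:
                out.loc[cat, (prov, m)] = cell[m]
    return out


def recompute_excluding(
    cohort: CohortCallSet,
    subgroup_label: str,
    provenance: Mapping[NormalizedIndel, Provenance],
    consequences: Mapping[NormalizedIndel, Consequence],
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Summary matrix after dropping one subgroup and re-deriving MAF.

    Frequencies and the rare stratum are recomputed on the remaining
    samples only; variants carried exclusively by excluded samples vanish
    from the matrix.
    """
    if subgroup_label not in cohort.samples.values():
        raise ValueError(f"no samples labelled {subgroup_label!r}")
    reduced = cohort.exclude_subgroup(subgroup_label)
    freqs = compute_frequencies(reduced, threshold)
    return summarize_counts(reduced, provenance, consequences, freqs, threshold)


def consequence_proportions(
    cohort: CohortCallSet,
    consequences: Mapping[NormalizedIndel, Consequence],
) -> pd.DataFrame:
    """Per-sample percentages of calls in each consequence category.

    Rows are samples, columns the ten categories; each row sums to 100.
    Samples with zero calls are excluded (their proportions are undefined).
    """
    counts: dict[str, dict[str, int]] = {}
    for call in cohort.calls:
        cat = consequences[call.variant].name
        counts.setdefault(call.sample_id, {}).setdefault(cat, 0)
        counts[call.sample_id][cat] += 1
    cat_names = [c.name for c in Consequence]
    rows = {}
    for sample in cohort.samples:
        if sample not in counts:
            continue
        c = counts[sample]
        total = sum(c.values())
        rows[sample] = {cat: 100.0 * c.get(cat, 0) / total for cat in cat_names}
    return pd.DataFrame.from_dict(rows, orient="index", columns=cat_names)


def compare_groups(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    adjust_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Two-sided rank-sum test per consequence category between two groups
    of per-sample percentages.

    Uses the exact null distribution for small samples without ties and the
    tie-corrected normal approximation otherwise; p-values are adjusted
    across categories with ``adjust_method`` (statsmodels codes, default
    Benjamini-Hochberg).  Categories absent from both tables are omitted.
    """
    if len(table_a) < 2 or len(table_b) < 2:
        raise ValueError("need at least 2 samples per group")
    cats = [c for c in table_a.columns.union(table_b.columns)]
    results = []
    for cat in cats:
        a = table_a[cat].to_numpy() if cat in table_a else None
        b = table_b[cat].to_numpy() if cat in table_b else None
        if a is None and b is None:
            continue
        a = a if a is not None else np.zeros(len(table_b))
        b = b if b is not None else np.zeros(len(table_a))
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        results.append((cat, float(np.median(a)), float(np.median(b)),
                        float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(
        results, columns=["category", "median_a", "median_b", "statistic", "p_raw"]
    ).set_index("category")
    out["p_adjusted"] = multipletests(out["p_raw"], method=adjust_method)[1]
    return out


def validation_chisq(
    table, yates: bool = True
) -> tuple[float, int, float]:
    """Pearson chi-squared on a 2 x k validated/not-validated table.

    Yates' continuity correction is applied iff requested and the table is
    2 x 2 (matching the R defaults the statistics were originally computed
    with).  Returns (statistic, df, p_value).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column sum: chi-squared undefined")
    correction = yates and arr.shape == (2, 2)
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=correction)
    return float(chi2), int(dof), float(p)


def validation_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row and overall validation percentages at 2-decimal precision.

    ``table`` has two integer columns (validated, not validated); the
    result appends a ``rate_percent`` column and a ``Total`` row.  Rates are
    half-up rounded, matching how such percentages are conventionally
    printed.  Empty rows yield NaN rates.
    """
    arr = table.to_numpy(dtype=float)
    if arr.shape[1] != 2:
        raise ValueError("expected exactly 2 columns: validated / not validated")
    totals = arr.sum(axis=1)
    rates = np.full(len(arr), np.nan)
    nonzero = totals > 0
    rates[nonzero] = 100.0 * arr[nonzero, 0] / totals[nonzero]
    grand = arr.sum(axis=0)
    overall = 100.0 * grand[0] / grand.sum() if grand.sum() else np.nan
    total_row = pd.DataFrame(
        [[int(grand[0]), int(grand[1])]], index=["Total"], columns=table.columns
    )
    out = pd.concat([table.astype(int), total_row])
    out["rate_percent"] = [
        round_half_up(r) if np.isfinite(r) else np.nan for r in rates
    ] + [round_half_up(overall) if np.isfinite(overall) else np.nan]
    return out


def size_spectrum(
    variants_by_stratum: Mapping[str, Iterable[NormalizedIndel]],
    max_len: int | None = None,
) -> pd.DataFrame:
    """Histogram of signed indel length per stratum (e.g. calls vs the
    known and newly released databases), with per-stratum density columns.
    """
    counts: dict[str, dict[int, int]] = {}
    for stratum, variants in variants_by_stratum.items():
        c: dict[int, int] = {}
        for v in variants:
            if max_len is not None and abs(v.length) > max_len:
                continue
            c[v.length] = c.get(v.length, 0) + 1
        counts[stratum] = c
    lengths = sorted({l for c in counts.values() for l in c})
    if not lengths:
        lengths = [0]
    out = pd.DataFrame(index=pd.Index(lengths, name="length"))
    for stratum, c in counts.items():
        col = [c.get(l, 0) for l in lengths]
        out[stratum] = col
        total = sum(col)
        out[f"{stratum}_density"] = (
            np.array(col, dtype=float) / total if total else 0.0
        )
    return out
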