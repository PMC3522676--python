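"""End-to-end orchestration: normalize -> region filter -> database match ->
consequence annotation -> cohort statistics, plus the validation-statistics
stage that joins Sanger results to frequency classes."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cstats
from . import io as ikio
from .consequence import ConsequenceAnnotator, is_lof
from .dbmatch import classify_provenance, match_variant
from .model import (
    AnalysisConfig,
    CohortCallSet,
    Consequence,
    FrequencyClass,
    NormalizedIndel,
    Provenance,
    VariantDatabase,
)
from .normalize import left_align

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    cohort: CohortCallSet
    per_variant: pd.DataFrame
    summary: pd.DataFrame
    summary_excluding_familial: pd.DataFrame | None
    proportions: pd.DataFrame
    size_spectrum: pd.DataFrame
    provenance: dict[NormalizedIndel, Provenance]
    consequences: dict[NormalizedIndel, Consequence]
    frequencies: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ikio.write_report(self.per_variant, out / "per_variant.tsv", index=False)
        ikio.write_report(self.summary, out / "summary_matrix.tsv")
        if self.summary_excluding_familial is not None:
            ikio.write_report(
                self.summary_excluding_familial,
                out / "summary_matrix_excluding_familial.tsv",
            )
        ikio.write_report(self.proportions, out / "consequence_proportions.tsv")
        ikio.write_report(self.size_spectrum, out / "size_spectrum.tsv")


def analyze(
    cohort: CohortCallSet,
    reference,
    transcripts,
    known_db: VariantDatabase,
    newly_released_db: VariantDatabase,
    regions=None,
    config: AnalysisConfig | None = None,
    exclude_subgroup: str | None = "familial",
) -> AnalysisResult:
    """Run the full characterisation pipeline on a call set.

    ``reference`` is any object with a ``fetch(chrom, start, end)`` method;
    ``regions`` (optional) restricts calls to capture intervals.  Variants
    that touch no transcript (not even a flank) are dropped from the
    summaries with a logged count.
    """
    config = config or AnalysisConfig()
    logger.info(
        "thresholds: match_window=%d distance_window=%d freq_threshold=%g",
        config.match_window_bp, config.distance_window_bp, config.common_freq_threshold,
    )

    cohort = cohort.map_variants(lambda v: left_align(v, reference))
    if regions is not None:
        cohort = ikio.filter_by_regions(cohort, regions)

    frequencies = cstats.compute_frequencies(cohort, config.common_freq_threshold)
    variants = cohort.variants()

    provenance: dict[NormalizedIndel, Provenance] = {}
    match_rows = []
    for v in variants:
        provenance[v] = classify_provenance(
            v, known_db, newly_released_db, config.match_window_bp
        )
        m = match_variant(v, known_db, config.match_window_bp)
        if m.matched is None:
            m = match_variant(v, newly_released_db, config.match_window_bp)
        match_rows.append((m.tier.name, m.signed_distance))

    annotator = ConsequenceAnnotator(transcripts, config, reference=reference)
    consequences: dict[NormalizedIndel, Consequence] = {}
    unannotated = 0
    for v in variants:
        cat = annotator.most_severe_category(v)
        if cat is None:
            unannotated += 1
        else:
            consequences[v] = cat
    if unannotated:
        logger.warning("%d variants touch no transcript; dropped from summaries", unannotated)

    per_variant = pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref_seq": [v.ref_seq for v in variants],
            "alt_seq": [v.alt_seq for v in variants],
            "length": [v.length for v in variants],
            "provenance": [provenance[v].value for v in variants],
            "consequence": [
                consequences[v].name if v in consequences else "" for v in variants
            ],
            "is_lof": [
                is_lof(consequences[v]) if v in consequences else False
                for v in variants
            ],
            "match_tier": [r[0] for r in match_rows],
            "match_distance": [r[1] for r in match_rows],
            "carrier_count": [frequencies[v].carrier_count for v in variants],
            "allele_count": [frequencies[v].allele_count for v in variants],
            "freq": [frequencies[v].freq for v in variants],
            "freq_class": [frequencies[v].freq_class.value for v in variants],
        }
    )

    annotated_cohort = CohortCallSet(
        samples=dict(cohort.samples),
        calls=[c for c in cohort.calls if c.variant in consequences],
    )
    summary = cstats.summarize_counts(
        annotated_cohort, provenance, consequences, frequencies,
        config.common_freq_threshold,
    )
    excl = None
    if exclude_subgroup and exclude_subgroup in set(cohort.samples.values()):
        remaining = [s for s, g in cohort.samples.items() if g != exclude_subgroup]
        if remaining:
            excl = cstats.recompute_excluding(
                annotated_cohort, exclude_subgroup, provenance, consequences,
                config.common_freq_threshold,
            )
    proportions = cstats.consequence_proportions(annotated_cohort, consequences)
    spectrum = cstats.size_spectrum(
        {
            "calls": variants,
            "known_db": list(known_db),
            "newly_released_db": list(newly_released_db),
        },
        max_len=config.max_indel_len,
    )
    return AnalysisResult(
        cohort=cohort,
        per_variant=per_variant,
        summary=summary,
        summary_excluding_familial=excl,
        proportions=proportions,
        size_spectrum=spectrum,
        provenance=provenance,
        consequences=consequences,
        frequencies=frequencies,
    )


@dataclass
class ValidationStats:
    rates_by_class: pd.DataFrame
    chisq_common_vs_private: tuple[float, int, float] | None
    chisq_all_classes: tuple[float, int, float] | None
    false_negative_count: int
    n_reference_checked: int


def validate_stats(validation: pd.DataFrame, yates: bool = True) -> ValidationStats:
    """Validation-concordance statistics from a panel table.

    Expects columns ``freq_class``, ``carrier_confirmed`` (yes/no) and
    optionally ``reference_confirmed``.  Produces per-class validation
    rates, a Yates-corrected 2x2 chi-squared comparing COMMON vs PRIVATE,
    and an uncorrected 2xk chi-squared over all classes present.
    """
    classes = [c.value for c in FrequencyClass if c.value in set(validation["freq_class"])]
    counts = {
        fc: (
            int(((validation["freq_class"] == fc) & (validation["carrier_confirmed"] == "yes")).sum()),
            int(((validation["freq_class"] == fc) & (validation["carrier_confirmed"] == "no")).sum()),
        )
        for fc in classes
    }
    rates = cstats.validation_rates(
        pd.DataFrame(
            [counts[fc] for fc in classes],
            index=classes,
            columns=["validated", "not_validated"],
        )
    )

    chisq22 = None
    if "COMMON" in counts and "PRIVATE" in counts:
        table = [list(counts["COMMON"]), list(counts["PRIVATE"])]
        if all(sum(col) > 0 for col in zip(*table)):
            chisq22 = cstats.validation_chisq(table, yates=yates)
        else:
            logger.info("2x2 chi-squared skipped: zero column")
    chisq_all = None
    if len(classes) >= 2:
        table = [list(counts[fc]) for fc in classes]
        if all(sum(col) > 0 for col in zip(*table)) and all(sum(r) > 0 for r in table):
            chisq_all = cstats.validation_chisq(table, yates=False)

    if "reference_confirmed" in validation.columns:
        n_ref = int(validation["reference_confirmed"].notna().sum())
        fn = int((validation["reference_confirmed"] == "no").sum())
    else:
        n_ref, fn = 0, 0
    return ValidationStats(
        rates_by_class=rates,
        chisq_common_vs_private=chisq22,
        chisq_all_classes=chisq_all,
        false_negative_count=fn,
        n_reference_checked=n_ref,
    )


def truth_recovery(per_variant: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Fraction of truth variants whose provenance / frequency class /
    most-severe consequence the pipeline recovered (keyed on the
    left-aligned variant identity)."""
    key = ["chrom", "pos", "ref_seq", "alt_seq"]
    t = truth.copy()
    p = per_variant.copy()
    for df in (t, p):
        df["ref_seq"] = df["ref_seq"].fillna("")
        df["alt_seq"] = df["alt_seq"].fillna("")
    merged = t.merge(p, on=key, suffixes=("_truth", "_called"), how="left")
    n = len(merged)
    found = merged["provenance_called"].notna()
    out = {"fraction_found": float(found.sum() / n) if n else float("nan")}
    sub = merged[found]
    for col in ("provenance", "freq_class", "consequence"):
        agree = (sub[f"{col}_truth"] == sub[f"{col}_called"]).sum()
        out[f"{col}_recovery"] = float(agree / n) if n else float("nan")
    return out
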