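"""I/O boundaries: VCF, FASTA, GFF3, BED, TSV reports, config files.

All convention arithmetic (VCF anchor bases, BED half-open coordinates)
happens here and only here; the rest of the package works in anchor-free
1-based coordinates (see :mod:`indelkit.model`).
"""

from __future__ import annotations

import dataclasses
import logging
import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .model import (
    AnalysisConfig,
    CohortCallSet,
    Genotype,
    NormalizedIndel,
    SampleCall,
    TranscriptModel,
    VariantDatabase,
)

logger = logging.getLogger(__name__)


class VcfParseError(ValueError):
    pass


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip shared prefix/suffix from a VCF REF/ALT pair.

    Returns anchor-free (pos, ref_seq, alt_seq) in this package's
    convention: for a pure insertion, pos is the base 5' of the insertion
    point; for a deletion, the first deleted base.
    """
    # shared suffix first (keep at least one base on each side for prefix)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    k = 0
    while k < len(ref) and k < len(alt) and ref[k] == alt[k]:
        k += 1
    ref_seq, alt_seq = ref[k:], alt[k:]
    if ref_seq == "":
        return pos + k - 1, "", alt_seq
    return pos + k, ref_seq, alt_seq


def _iter_indel_alleles(rec) -> Iterable[tuple[int, int, str, str]]:
    """Yield (alt_index, pos, ref_seq, alt_seq) for indel alt alleles.

    SNVs, MNPs and symbolic alleles are skipped (the caller counts them).
    """
    for i, alt in enumerate(rec.alts or ()):
        if alt is None or "<" in alt or ">" in alt or alt in ("*", "."):
            continue
        if not set(alt.upper()) <= set("ACGTN"):
            continue
        pos, ref_seq, alt_seq = _trim_alleles(rec.pos, rec.ref.upper(), alt.upper())
        if len(ref_seq) == len(alt_seq):
            continue  # SNV / MNP
        yield i + 1, pos, ref_seq, alt_seq


def read_indel_calls(
    vcf_source: str | os.PathLike | Sequence[str | os.PathLike],
    sample_labels: Mapping[str, str],
) -> CohortCallSet:
    """Load per-sample carrier calls from one or more VCF files.

    ``sample_labels`` maps every cohort sample to its subgroup label and
    defines ``n_samples`` (samples absent from the VCFs simply carry no
    calls).  One :class:`SampleCall` is emitted per carrier genotype per alt
    allele; multi-allelic records are decomposed.  SNVs and symbolic alleles
    are skipped and counted; genotypes with ploidy != 2 are skipped with a
    warning; missing genotypes are treated as homozygous reference and
    counted.
    """
    paths = (
        [vcf_source]
        if isinstance(vcf_source, (str, os.PathLike))
        else list(vcf_source)
    )
    calls: list[SampleCall] = []
    skipped_non_indel = 0
    skipped_bad_ploidy = 0
    missing = 0
    seen: set[tuple[str, tuple]] = set()
    for path in paths:
        with pysam.VariantFile(str(path)) as vcf:
            vcf_samples = [s for s in vcf.header.samples if s in sample_labels]
            n_rec = 0
            try:
                for rec in vcf:
                    n_rec += 1
                    indels = list(_iter_indel_alleles(rec))
                    if not indels and rec.alts:
                        skipped_non_indel += 1
                    for alt_idx, pos, ref_seq, alt_seq in indels:
                        variant = NormalizedIndel(rec.chrom, pos, ref_seq, alt_seq)
                        for s in vcf_samples:
                            gt = rec.samples[s].get("GT")
                            if gt is None or all(a is None for a in gt):
                                missing += 1
                                continue
                            if len(gt) != 2:
                                skipped_bad_ploidy += 1
                                logger.warning(
                                    "ploidy %d genotype for %s at %s:%d; skipped",
                                    len(gt), s, rec.chrom, rec.pos,
                                )
                                continue
                            n_alt = sum(1 for a in gt if a == alt_idx)
                            if n_alt == 0:
                                continue
                            gtype = Genotype.HET if n_alt == 1 else Genotype.HOM_ALT
                            k = (s, variant.key)
                            if k in seen:
                                continue
                            seen.add(k)
                            calls.append(SampleCall(s, variant, gtype))
            except ValueError as exc:
                raise VcfParseError(
                    f"malformed VCF record near record {n_rec + 1} of {path}: {exc}"
                ) from exc
    return CohortCallSet(
        samples=dict(sample_labels),
        calls=calls,
        skipped_non_indel=skipped_non_indel,
        skipped_bad_ploidy=skipped_bad_ploidy,
        missing_genotypes=missing,
    )


def load_variant_database(
    path: str | os.PathLike, name: str, max_len: int | None = None
) -> VariantDatabase:
    """Load a known-variant database from a (sites-only) VCF."""
    records: list[NormalizedIndel] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for _, pos, ref_seq, alt_seq in _iter_indel_alleles(rec):
                v = NormalizedIndel(rec.chrom, pos, ref_seq, alt_seq)
                if max_len is not None and abs(v.length) > max_len:
                    continue
                records.append(v)
    return VariantDatabase(name, records)


def read_bed_regions(path: str | os.PathLike) -> dict[str, IntervalTree]:
    """BED (0-based half-open) -> per-chrom interval trees in the same
    convention; overlapping/adjacent intervals are merged."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    for tree in trees.values():
        tree.merge_overlaps()
    return trees


def filter_by_regions(
    calls: CohortCallSet, regions: str | os.PathLike | dict[str, IntervalTree]
) -> CohortCallSet:
    """Restrict calls to the capture regions.

    A deletion is kept iff its reference footprint overlaps a region; an
    insertion (empty footprint) iff its insertion point falls strictly
    inside a region.  Calls on chromosomes absent from the BED are dropped
    with a warning.
    """
    if not isinstance(regions, dict):
        regions = read_bed_regions(regions)
    kept = []
    unknown_chroms: set[str] = set()
    for call in calls.calls:
        v = call.variant
        tree = regions.get(v.chrom)
        if tree is None:
            unknown_chroms.add(v.chrom)
            continue
        lo, hi = v.footprint
        if lo > hi:
            # insertion point between pos and pos+1, 0-based boundary = pos;
            # strict interior of half-open [a, b) means a < pos < b
            if any(iv.begin < v.pos < iv.end for iv in tree.at(v.pos)):
                kept.append(call)
        else:
            # 1-based closed [lo, hi] == 0-based half-open [lo-1, hi)
            if tree.overlap(lo - 1, hi):
                kept.append(call)
    for chrom in sorted(unknown_chroms):
        logger.warning("dropping calls on %s: not in capture regions file", chrom)
    return CohortCallSet(samples=dict(calls.samples), calls=kept)


def write_report(
    table: pd.DataFrame,
    path: str | os.PathLike,
    float_precision: int = 4,
    index: bool = True,
) -> None:
    """Write a summary/contingency/proportion table as TSV.

    The rendered floating-point precision is recorded in a comment header so
    round-trips are well defined.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# float_precision={float_precision}\n")
        table.to_csv(fh, sep="\t", float_format=f"%.{float_precision}f", index=index)


def read_report(path: str | os.PathLike, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_fasta(path: str | os.PathLike, contigs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(
    path: str | os.PathLike,
    contig_lengths: Mapping[str, int],
    records: Sequence[tuple[str, int, str, str]],
    genotypes: Mapping[int, Mapping[str, tuple[int, int]]] | None = None,
    samples: Sequence[str] = (),
) -> None:
    """Write an uncompressed VCF.

    ``records`` are (chrom, pos, REF, ALT) already in VCF convention
    (anchor base included).  ``genotypes`` maps record index -> sample ->
    GT tuple; samples without an entry are written as 0/0.
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    for s in samples:
        header.add_sample(s)
    order = sorted(range(len(records)), key=lambda i: (records[i][0], records[i][1]))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in order:
            chrom, pos, ref, alt = records[i]
            rec = out.new_record(
                contig=chrom, start=pos - 1, stop=pos - 1 + len(ref),
                alleles=(ref, alt),
            )
            if samples:
                gts = (genotypes or {}).get(i, {})
                for s in samples:
                    rec.samples[s]["GT"] = gts.get(s, (0, 0))
                    rec.samples[s].phased = False
            out.write(rec)


def read_gene_models(gff_path: str | os.PathLike) -> list[TranscriptModel]:
    """Load transcript models from GFF3 (exon, CDS features under mRNA /
    transcript / *RNA parents)."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    transcripts: list[TranscriptModel] = []
    tx_types = [t for t in db.featuretypes() if t.endswith(("RNA", "transcript"))]
    for tx_type in tx_types:
        for tx in db.features_of_type(tx_type):
            exons = sorted(
                (f.start, f.end) for f in db.children(tx, featuretype="exon")
            )
            if not exons:
                exons = [(tx.start, tx.end)]
            cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
            cds_start = min(s for s, _ in cds) if cds else None
            cds_end = max(e for _, e in cds) if cds else None
            gene_id = tx.attributes.get("Parent", [tx.id])[0]
            transcripts.append(
                TranscriptModel(
                    transcript_id=tx.id,
                    gene_id=gene_id,
                    chrom=tx.seqid,
                    strand=tx.strand,
                    exons=tuple(exons),
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
    return transcripts


def write_config(config: AnalysisConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"{f.name} = {getattr(config, f.name)}\n")


def read_config(path: str | os.PathLike) -> AnalysisConfig:
    """Plain-text ``key = value`` config mirroring :class:`AnalysisConfig`."""
    kwargs = {}
    field_types = {f.name: f.type for f in dataclasses.fields(AnalysisConfig)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in field_types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = field_types[key]
            if "int" in str(typ):
                kwargs[key] = int(value)
            elif "float" in str(typ):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    return AnalysisConfig(**kwargs)
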