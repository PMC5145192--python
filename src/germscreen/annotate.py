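"""Variant annotation against pluggable knowledge tables and gene models.

Annotation is a pure join: a site either hits a row in the knowledge table
(a desk-scale stand-in for an ANNOVAR+ClinVar+population-frequency stack),
which is attached verbatim, or it is a novel variant whose gene and
functional consequence are derived from a minimal exon/CDS gene model.

The functional vocabulary is the set of classes a dominant-cancer-panel
screen collects — splicing, nonsynonymous, stop_gain, stop_loss,
frameshift — plus ``other`` for everything else (synonymous changes,
in-frame indels, deep intronic and intergenic variants).

Consequence rules for novel variants
------------------------------------
* indel inside a CDS interval: ``frameshift`` when the length difference is
  not a multiple of 3, else ``other`` (in-frame);
* SNV inside a CDS interval: codon substitution using the model's frame and
  optional reference bases — premature stop is ``stop_gain``, lost stop is
  ``stop_loss``, changed amino acid is ``nonsynonymous``, silent is
  ``other``; without reference bases the call falls back to
  ``nonsynonymous``;
* within 2 bases of an internal exon boundary (canonical splice sites):
  ``splicing``;
* anything else: ``other``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
from Bio.Seq import Seq

from .variant_io import CohortSite, VariantKey, normalize_variant

__all__ = [
    "FunctionalClass",
    "KnowledgeRecord",
    "AnnotatedVariant",
    "GeneModel",
    "AmbiguousAnnotationError",
    "max_population_maf",
    "annotate",
    "read_knowledge",
    "read_gene_model",
]


class AmbiguousAnnotationError(ValueError):
    """One variant key maps to more than one knowledge record."""


class FunctionalClass(str, enum.Enum):
    SPLICING = "splicing"
    NONSYNONYMOUS = "nonsynonymous"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    FRAMESHIFT = "frameshift"
    OTHER = "other"


CLINVAR_ASSERTIONS = {
    "pathogenic",
    "likely_pathogenic",
    "uncertain",
    "likely_benign",
    "benign",
    "conflicting",
}


@dataclass(frozen=True)
class KnowledgeRecord:
    """Everything the knowledge bases say about one variant.

    Frequencies are alternate-allele frequencies in the three population
    panels (1000 Genomes, ESP, ExAC); ``None`` means the variant is absent
    from that panel.
    """

    key: VariantKey
    gene: Optional[str]
    func: FunctionalClass
    aa_change: Optional[str] = None
    cdna_change: Optional[str] = None
    rsid: Optional[str] = None
    clinvar_present: bool = False
    clinvar_assertion: Optional[str] = None
    maf_1000g: Optional[float] = None
    maf_esp: Optional[float] = None
    maf_exac: Optional[float] = None

    def __post_init__(self) -> None:
        if self.clinvar_assertion is not None:
            if not self.clinvar_present:
                raise ValueError(f"{self.key}: ClinVar assertion without clinvar_present")
            if self.clinvar_assertion not in CLINVAR_ASSERTIONS:
                raise ValueError(f"{self.key}: unknown ClinVar assertion {self.clinvar_assertion!r}")


def max_population_maf(record: KnowledgeRecord) -> float:
    """Maximum frequency across the population panels; 0 when absent from all."""
    present = [f for f in (record.maf_1000g, record.maf_esp, record.maf_exac) if f is not None]
    for f in present:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{record.key}: frequency {f} outside [0, 1]")
    return max(present, default=0.0)


@dataclass
class AnnotatedVariant:
    """A cohort site joined with its knowledge record and summary MAF."""

    site: CohortSite
    record: KnowledgeRecord
    max_maf: float

    @property
    def key(self) -> VariantKey:
        return self.site.key


@dataclass(frozen=True)
class _Interval:
    gene: str
    chrom: str
    start: int  # 1-based, closed
    end: int
    feature: str  # "exon" or "cds"
    strand: str  # "+" or "-"
    frame: int  # bases before the first complete codon in this interval


class GeneModel:
    """Minimal exon/CDS interval model with optional reference bases.

    The model answers three questions: which gene (if any) spans a
    position, whether a position lies in coding sequence (and in which
    codon), and whether a position sits in a canonical splice window
    (within 2 bases of an internal exon boundary).  ``reference`` is a
    sparse ``(chrom, pos) -> base`` map, typically loaded from a small
    region FASTA covering the modelled intervals.
    """

    def __init__(self, intervals: list[_Interval], reference: Optional[Mapping[tuple[str, int], str]] = None):
        self.intervals = intervals
        self.reference = dict(reference or {})
        self._gene_spans: dict[str, tuple[str, int, int]] = {}
        for iv in intervals:
            g = self._gene_spans.get(iv.gene)
            if g is None:
                self._gene_spans[iv.gene] = (iv.chrom, iv.start, iv.end)
            else:
                self._gene_spans[iv.gene] = (g[0], min(g[1], iv.start), max(g[2], iv.end))

    def gene_at(self, chrom: str, pos: int) -> Optional[str]:
        for gene, (c, start, end) in self._gene_spans.items():
            if c == chrom and start - 2 <= pos <= end + 2:  # include splice windows
                return gene
        return None

    def cds_interval_at(self, chrom: str, start: int, end: int) -> Optional[_Interval]:
        for iv in self.intervals:
            if iv.feature == "cds" and iv.chrom == chrom and iv.start <= start and end <= iv.end:
                return iv
        return None

    def in_splice_window(self, chrom: str, pos: int) -> bool:
        """True within +/-2 bases of an internal exon edge (not transcript ends)."""
        by_gene: dict[str, list[_Interval]] = {}
        for iv in self.intervals:
            if iv.feature == "exon" and iv.chrom == chrom:
                by_gene.setdefault(iv.gene, []).append(iv)
        for exons in by_gene.values():
            tx_start = min(e.start for e in exons)
            tx_end = max(e.end for e in exons)
            for e in exons:
                if e.start != tx_start and e.start - 2 <= pos <= e.start - 1:
                    return True
                if e.end != tx_end and e.end + 1 <= pos <= e.end + 2:
                    return True
        return False

    def fetch(self, chrom: str, start: int, end: int) -> Optional[str]:
        bases = []
        for p in range(start, end + 1):
            b = self.reference.get((chrom, p))
            if b is None:
                return None
            bases.append(b)
        return "".join(bases)


def _codon_class(model: GeneModel, iv: _Interval, key: VariantKey) -> FunctionalClass:
    """Classify a coding SNV by codon substitution; fallback nonsynonymous."""
    pos = key.pos
    if iv.strand == "+":
        offset = pos - (iv.start + iv.frame)
        if offset < 0:
            return FunctionalClass.NONSYNONYMOUS  # partial codon at interval edge
        codon_start = iv.start + iv.frame + 3 * (offset // 3)
        if codon_start + 2 > iv.end:
            return FunctionalClass.NONSYNONYMOUS
        codon = model.fetch(iv.chrom, codon_start, codon_start + 2)
        idx = pos - codon_start
    else:
        offset = (iv.end - iv.frame) - pos
        if offset < 0:
            return FunctionalClass.NONSYNONYMOUS
        codon_end = iv.end - iv.frame - 3 * (offset // 3)
        if codon_end - 2 < iv.start:
            return FunctionalClass.NONSYNONYMOUS
        genomic = model.fetch(iv.chrom, codon_end - 2, codon_end)
        codon = str(Seq(genomic).reverse_complement()) if genomic else None
        idx = codon_end - pos
    if codon is None:
        return FunctionalClass.NONSYNONYMOUS
    ref_base, alt_base = key.ref, key.alt
    if iv.strand == "-":
        ref_base = str(Seq(ref_base).reverse_complement())
        alt_base = str(Seq(alt_base).reverse_complement())
    if codon[idx] != ref_base:
        raise ValueError(f"{key}: reference mismatch (model codon {codon}, ref {key.ref})")
    alt_codon = codon[:idx] + alt_base + codon[idx + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return FunctionalClass.OTHER  # synonymous
    if aa_alt == "*":
        return FunctionalClass.STOP_GAIN
    if aa_ref == "*":
        return FunctionalClass.STOP_LOSS
    return FunctionalClass.NONSYNONYMOUS


def _classify_novel(key: VariantKey, model: GeneModel) -> FunctionalClass:
    ref_span_end = key.pos + len(key.ref) - 1
    if len(key.ref) != len(key.alt):  # indel
        iv = model.cds_interval_at(key.chrom, key.pos, ref_span_end)
        if iv is not None:
            return (
                FunctionalClass.FRAMESHIFT
                if abs(len(key.ref) - len(key.alt)) % 3 != 0
                else FunctionalClass.OTHER
            )
        if model.in_splice_window(key.chrom, key.pos) or model.in_splice_window(key.chrom, ref_span_end):
            return FunctionalClass.SPLICING
        return FunctionalClass.OTHER
    if len(key.ref) == 1:  # SNV
        iv = model.cds_interval_at(key.chrom, key.pos, key.pos)
        if iv is not None:
            return _codon_class(model, iv, key)
        if model.in_splice_window(key.chrom, key.pos):
            return FunctionalClass.SPLICING
    return FunctionalClass.OTHER


def annotate(
    site: CohortSite,
    knowledge: Mapping[VariantKey, KnowledgeRecord],
    gene_model: GeneModel,
) -> AnnotatedVariant:
    """Attach gene, consequence, ClinVar status, and population MAFs to a site.

    A key present in the knowledge table is annotated verbatim from it;
    otherwise a novel record is synthesized from the gene model with all
    frequencies absent.  Annotation is a pure function of the site key and
    the tables.
    """
    record = knowledge.get(site.key)
    if record is None:
        gene = gene_model.gene_at(site.key.chrom, site.key.pos)
        func = _classify_novel(site.key, gene_model) if gene is not None else FunctionalClass.OTHER
        record = KnowledgeRecord(key=site.key, gene=gene, func=func)
    return AnnotatedVariant(site=site, record=record, max_maf=max_population_maf(record))


# ---------------------------------------------------------------------------
# fixture-table readers

KNOWLEDGE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "func", "aa_change", "cdna_change",
    "rsid", "clinvar_present", "clinvar_assertion", "maf_1000g", "maf_esp", "maf_exac",
]


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def _opt_float(value) -> Optional[float]:
    s = _opt_str(value)
    return None if s is None else float(s)


def read_knowledge(path: str | Path) -> dict[VariantKey, KnowledgeRecord]:
    """Read the knowledge-base TSV keyed on normalized variant coordinates."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(KNOWLEDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"knowledge table {path} lacks columns {sorted(missing)}")
    table: dict[VariantKey, KnowledgeRecord] = {}
    for row in df.itertuples(index=False):
        key = normalize_variant(VariantKey(row.chrom, int(row.pos), row.ref, row.alt))
        if key in table:
            raise AmbiguousAnnotationError(f"knowledge table has two records for {key}")
        table[key] = KnowledgeRecord(
            key=key,
            gene=_opt_str(row.gene),
            func=FunctionalClass(str(row.func)),
            aa_change=_opt_str(row.aa_change),
            cdna_change=_opt_str(row.cdna_change),
            rsid=_opt_str(row.rsid),
            clinvar_present=str(row.clinvar_present).strip().lower() == "true",
            clinvar_assertion=_opt_str(row.clinvar_assertion),
            maf_1000g=_opt_float(row.maf_1000g),
            maf_esp=_opt_float(row.maf_esp),
            maf_exac=_opt_float(row.maf_exac),
        )
    return table


GENE_MODEL_COLUMNS = ["gene", "chrom", "start", "end", "feature", "strand", "frame"]


def read_gene_model(path: str | Path, region_fasta: Optional[str | Path] = None) -> GeneModel:
    """Read a BED-like exon/CDS interval TSV, optionally with reference bases.

    ``region_fasta`` is a FASTA whose record ids are ``chrom:start-end``
    (1-based, closed) regions supplying reference bases for codon-level
    consequence calls.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(GENE_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene model {path} lacks columns {sorted(missing)}")
    intervals = [
        _Interval(
            gene=str(r.gene),
            chrom=_strip(r.chrom),
            start=int(r.start),
            end=int(r.end),
            feature=str(r.feature).lower(),
            strand=str(r.strand),
            frame=int(r.frame),
        )
        for r in df.itertuples(index=False)
    ]
    reference: dict[tuple[str, int], str] = {}
    if region_fasta is not None:
        from Bio import SeqIO

        for rec in SeqIO.parse(str(region_fasta), "fasta"):
            chrom, span = rec.id.split(":")
            start, _ = span.split("-")
            for i, base in enumerate(str(rec.seq).upper()):
                reference[(_strip(chrom), int(start) + i)] = base
    return GeneModel(intervals, reference)


def _strip(chrom) -> str:
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c
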