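"""Variant containers and cohort VCF / gene-panel input-output.

This module fixes the in-memory representation the rest of the pipeline
works with: a normalized :class:`VariantKey` (so VCF records, knowledge-base
rows, and manual-evidence rows all join on the same coordinates), per-sample
genotype calls with read depths (:class:`SampleCall`, :class:`CohortSite`),
and the autosomal-dominant gene panel (:class:`PanelGene`).

Conventions
-----------
* Coordinates are 1-based and fully closed, as in VCF.
* Chromosome labels are stored without a ``chr`` prefix.
* Multiallelic VCF records are split into one site per alternate allele
  before anything downstream sees them.
* Variant keys are reduced to their minimal representation: the common
  suffix is trimmed, then the common prefix (advancing ``pos``), always
  leaving at least one base in each allele.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "VariantKey",
    "SampleCall",
    "CohortSite",
    "PanelGene",
    "MalformedAlleleError",
    "VcfFormatError",
    "CohortSizeError",
    "PanelError",
    "normalize_variant",
    "read_cohort_vcf",
    "write_cohort_vcf",
    "read_panel",
    "panel_lookup",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class MalformedAlleleError(ValueError):
    """An allele string contains characters outside A/C/G/T."""


class VcfFormatError(ValueError):
    """The VCF lacks a required field (GT or DP)."""


class CohortSizeError(ValueError):
    """The VCF sample count does not match the expected cohort size."""


class PanelError(ValueError):
    """The gene-panel table is malformed (e.g. duplicate symbols)."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a biallelic variant: (chrom, 1-based pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _strip_chr(self.chrom))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos} ({self.ref})")

    def __str__(self) -> str:  # e.g. "17:41246018 TG>T"
        return f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"


def _strip_chr(label: str) -> str:
    label = str(label).strip()
    return label[3:] if label.lower().startswith("chr") else label


def _check_allele(allele: str, context: str) -> str:
    allele = allele.upper()
    if not _ALLELE_RE.match(allele):
        raise MalformedAlleleError(f"non-ACGT allele {allele!r} in record {context}")
    return allele


def normalize_variant(key: VariantKey) -> VariantKey:
    """Reduce a variant to its minimal (left-anchored) representation.

    The common suffix of ref/alt is trimmed first, then the common prefix
    with ``pos`` advanced one base per trimmed character; each allele keeps
    at least one base.  The operation is idempotent and preserves the
    sequence edit the pair represents.

    Raises
    ------
    MalformedAlleleError
        if either allele contains a character outside A/C/G/T.
    """
    ref = _check_allele(key.ref, str(key))
    alt = _check_allele(key.alt, str(key))
    pos = key.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(key.chrom, pos, ref, alt)


@dataclass(frozen=True)
class SampleCall:
    """One sample's genotype at one site.

    ``alt_copies`` is the number of alternate alleles carried (0, 1, 2) or
    ``None`` for a missing genotype; missing calls contribute to no tally.
    """

    sample_id: str
    alt_copies: Optional[int]
    depth: int

    def __post_init__(self) -> None:
        if self.alt_copies is not None and self.alt_copies not in (0, 1, 2):
            raise ValueError(f"alt_copies must be 0, 1, 2 or missing, got {self.alt_copies}")
        if self.depth < 0:
            raise ValueError(f"depth must be non-negative, got {self.depth}")


@dataclass
class CohortSite:
    """A normalized variant plus genotype calls across the whole cohort."""

    key: VariantKey
    calls: Sequence[SampleCall]

    @property
    def n_homref(self) -> int:
        return sum(1 for c in self.calls if c.alt_copies == 0)

    @property
    def n_het(self) -> int:
        return sum(1 for c in self.calls if c.alt_copies == 1)

    @property
    def n_homalt(self) -> int:
        return sum(1 for c in self.calls if c.alt_copies == 2)

    @property
    def carriers(self) -> list[str]:
        """Sample ids carrying at least one alternate allele."""
        return [c.sample_id for c in self.calls if c.alt_copies is not None and c.alt_copies >= 1]

    @property
    def site_depth(self) -> int:
        """Summary depth used by the depth filter.

        The minimum read depth among carrier samples — the conservative
        choice for a variant-collection filter: the variant is only as well
        supported as its worst-covered carrier.  At a site with no carriers
        the minimum over all called samples is used instead.
        """
        carrier_depths = [
            c.depth for c in self.calls if c.alt_copies is not None and c.alt_copies >= 1
        ]
        if carrier_depths:
            return min(carrier_depths)
        called = [c.depth for c in self.calls if c.alt_copies is not None]
        return min(called) if called else 0


@dataclass(frozen=True)
class PanelGene:
    """A gene on the screening panel.

    ``lof_mechanism`` records whether loss of function is an established
    disease mechanism for the gene (true for classical tumor suppressors,
    false for activation-mechanism genes such as RET) — the gate for the
    PVS1 evidence code.
    """

    symbol: str
    lof_mechanism: bool
    inheritance: str = "autosomal_dominant"


def read_panel(path: str | Path) -> list[PanelGene]:
    """Read a gene-panel TSV with columns ``symbol`` and ``lof_mechanism``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"symbol", "lof_mechanism"}
    if not required.issubset(df.columns):
        raise PanelError(f"panel file {path} must have columns {sorted(required)}")
    dupes = df["symbol"][df["symbol"].duplicated()].tolist()
    if dupes:
        raise PanelError(f"duplicate panel symbols: {sorted(set(dupes))}")
    genes = []
    for row in df.itertuples(index=False):
        lof = str(row.lof_mechanism).strip().lower()
        if lof not in {"true", "false"}:
            raise PanelError(f"lof_mechanism must be true/false, got {row.lof_mechanism!r} for {row.symbol}")
        genes.append(PanelGene(symbol=str(row.symbol).strip(), lof_mechanism=lof == "true"))
    return genes


def panel_lookup(panel: Iterable[PanelGene]) -> dict[str, PanelGene]:
    return {g.symbol: g for g in panel}


def read_cohort_vcf(
    path: str | Path,
    expected_samples: Optional[int] = None,
) -> list[CohortSite]:
    """Read a multi-sample VCF into normalized :class:`CohortSite` records.

    Multiallelic records are split into one site per alternate allele; for
    each alt, ``alt_copies`` counts alleles equal to that alt (so a ``1/2``
    genotype contributes one copy to each of the two split sites).  Sample
    order follows the VCF header and is identical across sites.

    Parameters
    ----------
    path:
        Plain or bgzipped VCF with per-sample GT and DP fields.
    expected_samples:
        If given, the header sample count must match.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if expected_samples is not None and len(samples) != expected_samples:
        raise CohortSizeError(
            f"{path}: expected {expected_samples} samples, header has {len(samples)}"
        )
    sites: list[CohortSite] = []
    for variant in vcf:
        context = f"{variant.CHROM}:{variant.POS}"
        if "GT" not in variant.FORMAT:
            raise VcfFormatError(f"record {context} lacks a GT field")
        if "DP" not in variant.FORMAT:
            raise VcfFormatError(f"record {context} lacks a per-sample DP field")
        dp = variant.format("DP")
        depths = [int(d) if int(d) >= 0 else 0 for d in dp[:, 0]]
        genotypes = variant.genotypes  # [allele1, allele2, phased] per sample
        for alt_index, alt in enumerate(variant.ALT, start=1):
            key = normalize_variant(
                VariantKey(variant.CHROM, variant.POS, variant.REF, alt)
            )
            calls = []
            for sample, gt, depth in zip(samples, genotypes, depths):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    copies: Optional[int] = None
                else:
                    copies = sum(1 for a in alleles if a == alt_index)
                calls.append(SampleCall(sample_id=sample, alt_copies=copies, depth=depth))
            sites.append(CohortSite(key=key, calls=calls))
    return sites


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (0, f"{int(chrom):09d}") if chrom.isdigit() else (1, chrom)


def write_cohort_vcf(
    sites: Sequence[CohortSite],
    sample_ids: Sequence[str],
    path: str | Path,
) -> Path:
    """Write sites as a plain-text VCF v4.2 with GT:DP per sample.

    Sites are sorted by (chromosome, position); every site must carry one
    call per cohort sample in the shared sample order.
    """
    path = Path(path)
    lines = [_VCF_HEADER]
    chroms = sorted({s.key.chrom for s in sites}, key=_chrom_sort_key)
    lines.extend(f"##contig=<ID={c}>\n" for c in chroms)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
    for site in sorted(sites, key=lambda s: (_chrom_sort_key(s.key.chrom), s.key.pos, s.key.ref, s.key.alt)):
        if [c.sample_id for c in site.calls] != list(sample_ids):
            raise CohortSizeError(f"site {site.key} sample order differs from cohort order")
        fields = [site.key.chrom, str(site.key.pos), ".", site.key.ref, site.key.alt, ".", "PASS", ".", "GT:DP"]
        for call in site.calls:
            gt = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}[call.alt_copies]
            fields.append(f"{gt}:{call.depth}")
        lines.append("\t".join(fields) + "\n")
    path.write_text("".join(lines))
    return path
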