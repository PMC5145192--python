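"""Seeded synthetic-cohort generator with an exact truth table.

The generator emulates the input the screening pipeline expects: a
multi-sample germline VCF for a 300-sample cohort together with the
matching fixture tables (gene panel, knowledge base, gene model, manual
evidence).  Its default conditions are the study design the pipeline is
built for: five known pathogenic/likely-pathogenic variants planted as
single heterozygotes in distinct, uniformly chosen samples and absent from
all three population panels, surrounded by decoy variants that exercise
every failure mode of the collection cascade plus the benign and
uncertain classification outcomes.

Per-call read depth follows a negative-binomial distribution (mean 45,
dispersion 10 — a realistic short-read WGS coverage profile) floored at
10, the calling threshold of the emulated input; carriers at sites meant
to survive the 30X collection filter are redrawn conditional on >= 30 so
the depth stage is decided by construction, not by luck.

Everything is a deterministic function of the seed: the same
:class:`SimulationConfig` writes byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import FunctionalClass
from .filters import FilterOutcome
from .variant_io import CohortSite, SampleCall, VariantKey, write_cohort_vcf

__all__ = [
    "PlantedVariant",
    "SimulationConfig",
    "TruthRow",
    "TruthTable",
    "SimulationResult",
    "default_planted_variants",
    "generate",
]

DECOY_CATEGORIES = (
    "fail_depth",
    "fail_panel",
    "fail_class",
    "fail_maf",
    "fail_hwe",
    "benign",
    "vus",
)


@dataclass(frozen=True)
class PlantedVariant:
    """A known-pathogenic variant to plant as a singleton heterozygote."""

    key: VariantKey
    gene: str
    func: FunctionalClass
    aa_change: str
    cdna_change: str
    rsid: str
    clinvar_assertion: str
    manual_codes: tuple[str, ...]


def default_planted_variants() -> tuple[PlantedVariant, ...]:
    """The five core variants from the packaged knowledge/evidence fixtures."""
    from . import data_path

    know = pd.read_csv(data_path("core_knowledge.tsv"), sep="\t", comment="#", dtype=str)
    manual = pd.read_csv(data_path("core_manual_evidence.tsv"), sep="\t", comment="#", dtype=str)
    codes_by_key = {
        (r.chrom, int(r.pos), r.ref, r.alt): tuple(str(r.codes).split(","))
        for r in manual.itertuples(index=False)
    }
    planted = []
    for r in know.itertuples(index=False):
        key = VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
        planted.append(
            PlantedVariant(
                key=key,
                gene=r.gene,
                func=FunctionalClass(r.func),
                aa_change=r.aa_change,
                cdna_change=r.cdna_change,
                rsid=r.rsid,
                clinvar_assertion=r.clinvar_assertion,
                manual_codes=codes_by_key.get((r.chrom, int(r.pos), r.ref, r.alt), ()),
            )
        )
    return tuple(planted)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort."""

    n_samples: int = 300
    planted: Optional[tuple[PlantedVariant, ...]] = None  # None -> the five core variants
    n_decoys: int = 5  # per decoy category
    depth_mean: float = 45.0
    depth_dispersion: float = 10.0
    depth_floor: int = 10
    collection_depth: int = 30  # carriers at depth-passing sites are drawn >= this
    seed: int = 1

    def resolved_planted(self) -> tuple[PlantedVariant, ...]:
        return self.planted if self.planted is not None else default_planted_variants()


@dataclass(frozen=True)
class TruthRow:
    key: VariantKey
    kind: str  # "planted" | "decoy"
    category: str  # "planted" or a decoy category
    carrier_sample: Optional[str]  # planted only
    zygosity: Optional[str]  # planted only
    expected_outcome: str  # FilterOutcome value
    expected_tier: Optional[str]  # for retained variants


@dataclass
class TruthTable:
    rows: list[TruthRow]

    @property
    def planted(self) -> list[TruthRow]:
        return [r for r in self.rows if r.kind == "planted"]

    @property
    def decoys(self) -> list[TruthRow]:
        return [r for r in self.rows if r.kind == "decoy"]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["chrom\tpos\tref\talt\tkind\tcategory\tcarrier_sample\tzygosity\texpected_outcome\texpected_tier\n"]
        for r in self.rows:
            lines.append(
                "\t".join(
                    [
                        r.key.chrom,
                        str(r.key.pos),
                        r.key.ref,
                        r.key.alt,
                        r.kind,
                        r.category,
                        r.carrier_sample or "",
                        r.zygosity or "",
                        r.expected_outcome,
                        r.expected_tier or "",
                    ]
                )
                + "\n"
            )
        path.write_text("".join(lines))
        return path

    @classmethod
    def read(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        rows = [
            TruthRow(
                key=VariantKey(r.chrom, int(r.pos), r.ref, r.alt),
                kind=r.kind,
                category=r.category,
                carrier_sample=r.carrier_sample or None,
                zygosity=r.zygosity or None,
                expected_outcome=r.expected_outcome,
                expected_tier=r.expected_tier or None,
            )
            for r in df.itertuples(index=False)
        ]
        return cls(rows)


@dataclass
class SimulationResult:
    out_dir: Path
    vcf: Path
    panel: Path
    knowledge: Path
    gene_model: Path
    manual_evidence: Path
    truth_path: Path
    truth: TruthTable
    sample_ids: list[str]


# --- synthetic gene models ---------------------------------------------------
# Three 200-bp coding exons separated by 500-bp introns, near each gene's
# genuine locus so coordinates look familiar; decoy positions are allocated
# inside these intervals and never collide with the planted coordinates.

_GENE_LOCI = {
    "APC": ("5", 112_100_000),
    "TP53": ("17", 7_560_000),
    "NF1": ("17", 29_660_000),
    "BRCA1": ("17", 41_190_000),
    "BRCA2": ("13", 32_880_000),
    "TTN": ("2", 179_390_000),  # off-panel decoy gene
}
_EXON_LEN = 200
_INTRON_LEN = 500
_N_EXONS = 3


def _gene_model_rows() -> list[dict]:
    rows = []
    for gene, (chrom, base) in _GENE_LOCI.items():
        cds_sofar = 0
        for i in range(_N_EXONS):
            start = base + i * (_EXON_LEN + _INTRON_LEN)
            end = start + _EXON_LEN - 1
            frame = (3 - cds_sofar % 3) % 3
            for feature in ("exon", "cds"):
                rows.append(
                    {
                        "gene": gene,
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "feature": feature,
                        "strand": "+",
                        "frame": frame,
                    }
                )
            cds_sofar += _EXON_LEN
    return rows


class _PositionAllocator:
    """Hand out unique, well-separated positions inside gene intervals."""

    def __init__(self, reserved: set[tuple[str, int]]):
        self.used = set(reserved)
        self.cursors: dict[str, int] = {}

    def _next(self, tag: str, chrom: str, start: int, step: int = 4, limit: Optional[int] = None) -> int:
        pos = self.cursors.get(tag, start)
        while (chrom, pos) in self.used:
            pos += step
        if limit is not None and pos > limit:
            raise ValueError(f"decoy positions exhausted for {tag}; lower n_decoys")
        self.used.add((chrom, pos))
        self.cursors[tag] = pos + step
        return pos

    def in_cds(self, gene: str) -> tuple[str, int]:
        chrom, base = _GENE_LOCI[gene]
        # middle exon, away from its edges so splice windows are not touched
        start = base + _EXON_LEN + _INTRON_LEN + 10
        limit = base + _EXON_LEN + _INTRON_LEN + _EXON_LEN - 10
        return chrom, self._next(f"{gene}:cds", chrom, start, limit=limit)

    def deep_intronic(self, gene: str) -> tuple[str, int]:
        chrom, base = _GENE_LOCI[gene]
        start = base + _EXON_LEN + _INTRON_LEN // 2  # mid first intron
        limit = base + _EXON_LEN + _INTRON_LEN - 10
        return chrom, self._next(f"{gene}:intron", chrom, start, limit=limit)

    def intergenic(self) -> tuple[str, int]:
        return "9", self._next("intergenic", "9", 1_000_000, step=50)


def _depth(rng: np.random.Generator, config: SimulationConfig, minimum: int) -> int:
    n = config.depth_dispersion
    p = n / (n + config.depth_mean)
    while True:
        d = int(rng.negative_binomial(n, p))
        if d >= minimum:
            return d


def _depths(rng, config, size: int, minimum: int) -> list[int]:
    return [_depth(rng, config, minimum) for _ in range(size)]


def generate(config: SimulationConfig, out_dir: str | Path) -> SimulationResult:
    """Write the cohort VCF, fixture tables, and truth table for a seed.

    Raises
    ------
    ValueError
        if ``n_samples`` is smaller than the number of planted carriers.
    """
    planted = config.resolved_planted()
    if config.n_samples < len(planted):
        raise ValueError(
            f"n_samples={config.n_samples} cannot host {len(planted)} distinct planted carriers"
        )
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sample_ids = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]
    n = config.n_samples

    reserved = {(v.key.chrom, v.key.pos) for v in planted}
    alloc = _PositionAllocator(reserved)
    panel_genes = [v.gene for v in planted] or list(_GENE_LOCI)[:5]

    sites: list[CohortSite] = []
    knowledge_rows: list[dict] = []
    manual_rows: list[dict] = []
    truth_rows: list[TruthRow] = []

    def add_site(key: VariantKey, het_idx: Sequence[int], depths: Sequence[int]) -> None:
        het = set(het_idx)
        calls = [
            SampleCall(sample_ids[i], 1 if i in het else 0, depths[i]) for i in range(n)
        ]
        sites.append(CohortSite(key=key, calls=calls))

    def knowledge_row(key: VariantKey, gene: str, func: str, clinvar: Optional[str], **mafs) -> None:
        knowledge_rows.append(
            {
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "gene": gene,
                "func": func,
                "aa_change": mafs.pop("aa_change", ""),
                "cdna_change": mafs.pop("cdna_change", ""),
                "rsid": mafs.pop("rsid", ""),
                "clinvar_present": "true" if clinvar is not None else "false",
                "clinvar_assertion": clinvar or "",
                "maf_1000g": mafs.get("maf_1000g", ""),
                "maf_esp": mafs.get("maf_esp", ""),
                "maf_exac": mafs.get("maf_exac", ""),
            }
        )

    # --- planted pathogenic variants: one heterozygote each, distinct samples
    carrier_idx = rng.choice(n, size=len(planted), replace=False)
    for variant, ci in zip(planted, carrier_idx):
        depths = _depths(rng, config, n, config.depth_floor)
        depths[ci] = _depth(rng, config, config.collection_depth)
        add_site(variant.key, [int(ci)], depths)
        knowledge_row(
            variant.key,
            variant.gene,
            variant.func.value,
            variant.clinvar_assertion,
            aa_change=variant.aa_change,
            cdna_change=variant.cdna_change,
            rsid=variant.rsid,
        )
        if variant.manual_codes:
            manual_rows.append(
                {
                    "chrom": variant.key.chrom,
                    "pos": variant.key.pos,
                    "ref": variant.key.ref,
                    "alt": variant.key.alt,
                    "codes": ",".join(variant.manual_codes),
                }
            )
        truth_rows.append(
            TruthRow(
                key=variant.key,
                kind="planted",
                category="planted",
                carrier_sample=sample_ids[ci],
                zygosity="het",
                expected_outcome=FilterOutcome.RETAINED.value,
                expected_tier="pathogenic_or_likely_pathogenic",
            )
        )

    # --- decoys, n_decoys per category ------------------------------------
    def few_het_carriers(k_max: int = 3) -> list[int]:
        k = int(rng.integers(1, k_max + 1))
        return [int(i) for i in rng.choice(n, size=k, replace=False)]

    for d in range(config.n_decoys):
        gene = panel_genes[d % len(panel_genes)]

        # (a) sub-threshold depth: well-annotated variant whose carriers are
        # all read at 10-29X, so the site fails the 30X collection filter.
        chrom, pos = alloc.in_cds(gene)
        key = VariantKey(chrom, pos, "C", "T")
        hets = few_het_carriers()
        depths = _depths(rng, config, n, config.depth_floor)
        for i in hets:
            depths[i] = int(rng.integers(config.depth_floor, config.collection_depth))
        add_site(key, hets, depths)
        knowledge_row(key, gene, "nonsynonymous", "uncertain")
        truth_rows.append(TruthRow(key, "decoy", "fail_depth", None, None, "fail_depth", None))

        # (b) off-panel gene: alternate a TTN coding variant with an
        # intergenic novel variant (no gene at all).
        if d % 2 == 0:
            chrom, pos = alloc.in_cds("TTN")
            key = VariantKey(chrom, pos, "G", "A")
            knowledge_row(key, "TTN", "nonsynonymous", "uncertain")
        else:
            chrom, pos = alloc.intergenic()
            key = VariantKey(chrom, pos, "A", "G")
        hets = few_het_carriers()
        depths = _depths(rng, config, n, config.depth_floor)
        for i in hets:
            depths[i] = _depth(rng, config, config.collection_depth)
        add_site(key, hets, depths)
        truth_rows.append(TruthRow(key, "decoy", "fail_panel", None, None, "fail_panel", None))

        # (c) disallowed functional class: a synonymous-type knowledge entry
        # alternating with a novel deep-intronic variant classified "other".
        if d % 2 == 0:
            chrom, pos = alloc.in_cds(gene)
            key = VariantKey(chrom, pos, "T", "C")
            knowledge_row(key, gene, "other", "uncertain")
        else:
            chrom, pos = alloc.deep_intronic(gene)
            key = VariantKey(chrom, pos, "C", "A")
        hets = few_het_carriers()
        depths = _depths(rng, config, n, config.depth_floor)
        for i in hets:
            depths[i] = _depth(rng, config, config.collection_depth)
        add_site(key, hets, depths)
        truth_rows.append(TruthRow(key, "decoy", "fail_class", None, None, "fail_class", None))

        # (d) novel but too common: absent from ClinVar with population
        # frequency above the 0.5% novel-variant ceiling.
        chrom, pos = alloc.in_cds(gene)
        key = VariantKey(chrom, pos, "A", "C")
        maf = float(rng.uniform(0.006, 0.05))
        knowledge_row(key, gene, "nonsynonymous", None, maf_exac=f"{maf:.6f}")
        hets = few_het_carriers()
        depths = _depths(rng, config, n, config.depth_floor)
        for i in hets:
            depths[i] = _depth(rng, config, config.collection_depth)
        add_site(key, hets, depths)
        truth_rows.append(TruthRow(key, "decoy", "fail_maf", None, None, "fail_maf", None))

        # (e) Hardy-Weinberg failure: every sample heterozygous — the
        # signature of a genotyping artifact; constructed, not sampled.
        chrom, pos = alloc.in_cds(gene)
        key = VariantKey(chrom, pos, "G", "C")
        knowledge_row(key, gene, "nonsynonymous", "uncertain")
        depths = _depths(rng, config, n, config.collection_depth)
        add_site(key, list(range(n)), depths)
        truth_rows.append(TruthRow(key, "decoy", "fail_hwe", None, None, "fail_hwe", None))

        # (f) common ClinVar-benign variant: sails through the cascade via
        # the ClinVar arm (no MAF condition) and classifies benign through
        # manually curated BA1 evidence.
        chrom, pos = alloc.in_cds(gene)
        key = VariantKey(chrom, pos, "T", "G")
        maf = float(rng.uniform(0.10, 0.30))
        knowledge_row(key, gene, "nonsynonymous", "benign", maf_exac=f"{maf:.6f}")
        copies = rng.binomial(2, maf, size=n)  # random mating
        if not (copies > 0).any():
            copies[int(rng.integers(0, n))] = 1
        depths = _depths(rng, config, n, config.collection_depth)
        calls = [
            SampleCall(sample_ids[i], int(copies[i]), depths[i]) for i in range(n)
        ]
        sites.append(CohortSite(key=key, calls=calls))
        manual_rows.append({"chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt, "codes": "BA1"})
        truth_rows.append(TruthRow(key, "decoy", "benign", None, None, "retained", "benign"))

        # (g) novel rare variant with no decisive evidence: retained, ends
        # uncertain.  Alternates a rare knowledge-base entry with a truly
        # novel coding variant annotated from the gene model alone.
        if d % 2 == 0:
            chrom, pos = alloc.in_cds(gene)
            key = VariantKey(chrom, pos, "C", "G")
            maf = float(rng.uniform(0.0005, 0.004))
            knowledge_row(key, gene, "nonsynonymous", None, maf_1000g=f"{maf:.6f}")
        else:
            chrom, pos = alloc.in_cds(gene)
            key = VariantKey(chrom, pos, "A", "T")  # novel: PM2 only -> uncertain
        hets = few_het_carriers()
        depths = _depths(rng, config, n, config.depth_floor)
        for i in hets:
            depths[i] = _depth(rng, config, config.collection_depth)
        add_site(key, hets, depths)
        truth_rows.append(TruthRow(key, "decoy", "vus", None, None, "retained", "uncertain"))

    # --- write everything --------------------------------------------------
    from . import data_path

    vcf_path = write_cohort_vcf(sites, sample_ids, out_dir / "cohort.vcf")
    panel_path = out_dir / "panel.tsv"
    panel_path.write_text(data_path("panel_genes.tsv").read_text())

    know_df = pd.DataFrame(
        knowledge_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "func", "aa_change", "cdna_change",
            "rsid", "clinvar_present", "clinvar_assertion", "maf_1000g", "maf_esp", "maf_exac",
        ],
    ).sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
    knowledge_path = out_dir / "knowledge.tsv"
    know_df.to_csv(knowledge_path, sep="\t", index=False)

    model_df = pd.DataFrame(_gene_model_rows())
    gene_model_path = out_dir / "gene_model.tsv"
    model_df.to_csv(gene_model_path, sep="\t", index=False)

    manual_df = pd.DataFrame(manual_rows, columns=["chrom", "pos", "ref", "alt", "codes"]).sort_values(
        ["chrom", "pos", "ref", "alt"], kind="mergesort"
    )
    manual_path = out_dir / "manual_evidence.tsv"
    manual_df.to_csv(manual_path, sep="\t", index=False)

    truth = TruthTable(truth_rows)
    truth_path = truth.write(out_dir / "truth.tsv")

    return SimulationResult(
        out_dir=out_dir,
        vcf=vcf_path,
        panel=panel_path,
        knowledge=knowledge_path,
        gene_model=gene_model_path,
        manual_evidence=manual_path,
        truth_path=truth_path,
        truth=truth,
        sample_ids=sample_ids,
    )
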