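"""Cohort-level aggregation and end-to-end pipeline orchestration.

A *carrier* is a cohort sample with at least one alternate allele at at
least one variant classified pathogenic or likely pathogenic.  The summary
reports the carrier set, the headline carrier percentage (rounded
half-away-from-zero to one decimal), and per-tier variant tallies; the
variant report keeps the per-variant homozygote/heterozygote counts in the
conventional "Homs/Hets" form.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .acmg import ClassifiedVariant, Tier, classify_batch, read_manual_evidence
from .annotate import annotate, read_gene_model, read_knowledge
from .filters import FilterConfig, FilterTrace, apply_cascade, write_trace_table
from .variant_io import read_cohort_vcf, read_panel

__all__ = ["CohortSummary", "summarize", "run_pipeline", "PipelineResult"]

PLP_TIERS = {Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC}


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 1.666... -> 1.7, 2.25 -> 2.3 at 1 dp)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


@dataclass
class CohortSummary:
    n_samples: int
    class_tally: dict[str, int]
    carriers: frozenset[str]
    carrier_count: int
    carrier_percent: float

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "class_tally": dict(sorted(self.class_tally.items())),
            "carriers": sorted(self.carriers),
            "carrier_count": self.carrier_count,
            "carrier_percent": self.carrier_percent,
        }


def summarize(classified: Sequence[ClassifiedVariant], n_samples: int) -> CohortSummary:
    """Aggregate classified variants into the cohort summary.

    Carrier status uses set semantics: a sample carrying several
    pathogenic/likely-pathogenic variants counts once.
    """
    if n_samples <= 0:
        raise ValueError("cohort must contain at least one sample")
    tally: dict[str, int] = {t.value: 0 for t in Tier}
    carriers: set[str] = set()
    for cv in classified:
        tally[cv.result.tier.value] += 1
        if cv.result.tier in PLP_TIERS:
            carriers.update(cv.variant.site.carriers)
    count = len(carriers)
    return CohortSummary(
        n_samples=n_samples,
        class_tally=tally,
        carriers=frozenset(carriers),
        carrier_count=count,
        carrier_percent=round_half_away(100.0 * count / n_samples, 1),
    )


def variant_report_frame(classified: Sequence[ClassifiedVariant]) -> pd.DataFrame:
    """Per-variant report with annotation, tier, evidence, and Homs/Hets."""
    rows = []
    for cv in classified:
        site = cv.variant.site
        rec = cv.variant.record
        rows.append(
            {
                "chrom": site.key.chrom,
                "pos": site.key.pos,
                "ref": site.key.ref,
                "alt": site.key.alt,
                "gene": rec.gene or "",
                "func": rec.func.value,
                "aa_change": rec.aa_change or "",
                "cdna_change": rec.cdna_change or "",
                "rsid": rec.rsid or "",
                "clinvar_assertion": rec.clinvar_assertion or "",
                "max_maf": cv.variant.max_maf,
                "tier": cv.result.tier.value,
                "rule_fired": cv.result.rule_fired,
                "codes": ",".join(sorted(cv.profile.codes)),
                "n_homalt": site.n_homalt,
                "n_het": site.n_het,
                "homs_hets": f"{site.n_homalt}/{site.n_het}",
            }
        )
    columns = [
        "chrom", "pos", "ref", "alt", "gene", "func", "aa_change", "cdna_change",
        "rsid", "clinvar_assertion", "max_maf", "tier", "rule_fired", "codes",
        "n_homalt", "n_het", "homs_hets",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class PipelineResult:
    summary: CohortSummary
    variant_report: pd.DataFrame
    traces: list[FilterTrace]
    classified: list[ClassifiedVariant]
    out_dir: Optional[Path] = None


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    vcf_path: str | Path,
    panel_path: str | Path,
    knowledge_path: str | Path,
    gene_model_path: str | Path,
    manual_evidence_path: Optional[str | Path] = None,
    config: Optional[FilterConfig] = None,
    out_dir: Optional[str | Path] = None,
    expected_samples: Optional[int] = None,
    region_fasta: Optional[str | Path] = None,
) -> PipelineResult:
    """Run read -> normalize -> annotate -> filter -> classify -> summarize.

    When ``out_dir`` is given, writes ``variant_report.tsv``,
    ``filter_trace.tsv``, ``summary.json`` and a ``run_manifest.json``
    recording input checksums and the effective configuration.  Outputs are
    deterministic given the inputs; the manifest is the only file carrying
    a timestamp.
    """
    panel = read_panel(panel_path)
    if config is None:
        config = FilterConfig(panel=panel)
    elif not config.panel:
        config = FilterConfig(
            panel=panel,
            min_depth=config.min_depth,
            novel_maf_max=config.novel_maf_max,
            hwe_p_min=config.hwe_p_min,
            allowed_classes=config.allowed_classes,
        )
    knowledge = read_knowledge(knowledge_path)
    gene_model = read_gene_model(gene_model_path, region_fasta=region_fasta)
    manual = read_manual_evidence(manual_evidence_path) if manual_evidence_path else {}

    sites = read_cohort_vcf(vcf_path, expected_samples=expected_samples)
    n_samples = len(sites[0].calls) if sites else (expected_samples or 0)
    annotated = [annotate(site, knowledge, gene_model) for site in sites]
    retained, traces = apply_cascade(annotated, config)
    classified = classify_batch(retained, manual, config.panel)
    summary = (
        summarize(classified, n_samples)
        if n_samples
        else CohortSummary(0, {t.value: 0 for t in Tier}, frozenset(), 0, 0.0)
    )
    report = variant_report_frame(classified)

    if out_dir is not None:
        out_dir = Path(out_dir)
        written_dir: Optional[Path] = out_dir
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "variant_report.tsv", sep="\t", index=False)
        write_trace_table(traces, out_dir / "filter_trace.tsv")
        summary_payload = summary.to_dict()
        summary_payload["per_variant_homs_hets"] = {
            f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}": r.homs_hets for r in report.itertuples(index=False)
        }
        (out_dir / "summary.json").write_text(json.dumps(summary_payload, indent=2) + "\n")
        manifest = {
            "germscreen_version": __version__,
            "generated_at": datetime.now(timezone.utc).isoformat(),
            "inputs": {
                "vcf": {"path": str(vcf_path), "sha256": _sha256(vcf_path)},
                "panel": {"path": str(panel_path), "sha256": _sha256(panel_path)},
                "knowledge": {"path": str(knowledge_path), "sha256": _sha256(knowledge_path)},
                "gene_model": {"path": str(gene_model_path), "sha256": _sha256(gene_model_path)},
                "manual_evidence": (
                    {"path": str(manual_evidence_path), "sha256": _sha256(manual_evidence_path)}
                    if manual_evidence_path
                    else None
                ),
            },
            "config": {
                "min_depth": config.min_depth,
                "novel_maf_max": config.novel_maf_max,
                "hwe_p_min": config.hwe_p_min,
                "allowed_classes": sorted(c.value for c in config.allowed_classes),
                "panel_size": len(config.panel),
            },
        }
        (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    else:
        written_dir = None

    return PipelineResult(
        summary=summary,
        variant_report=report,
        traces=traces,
        classified=classified,
        out_dir=written_dir,
    )
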