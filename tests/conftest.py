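from __future__ import annotations

from typing import Optional, Sequence

import pytest

from germscreen.annotate import AnnotatedVariant, FunctionalClass, KnowledgeRecord
from germscreen.report import run_pipeline
from germscreen.simulate import SimulationConfig, generate
from germscreen.variant_io import CohortSite, SampleCall, VariantKey


def make_annotated(
    pos: int,
    gene: Optional[str] = "BRCA1",
    func: FunctionalClass = FunctionalClass.NONSYNONYMOUS,
    clinvar_present: bool = False,
    clinvar_assertion: Optional[str] = None,
    maf_exac: Optional[float] = None,
    chrom: str = "17",
    ref: str = "C",
    alt: str = "T",
    n_samples: int = 10,
    het_samples: Sequence[int] = (0,),
    hom_samples: Sequence[int] = (),
    carrier_depth: int = 40,
    background_depth: int = 40,
) -> AnnotatedVariant:
    """Hand-build an annotated singleton-style site for filter/engine tests."""
    key = VariantKey(chrom, pos, ref, alt)
    calls = []
    for i in range(n_samples):
        copies = 2 if i in hom_samples else (1 if i in het_samples else 0)
        depth = carrier_depth if copies else background_depth
        calls.append(SampleCall(f"S{i:03d}", copies, depth))
    site = CohortSite(key=key, calls=calls)
    record = KnowledgeRecord(
        key=key,
        gene=gene,
        func=func,
        clinvar_present=clinvar_present,
        clinvar_assertion=clinvar_assertion,
        maf_exac=maf_exac,
    )
    maf = maf_exac if maf_exac is not None else 0.0
    return AnnotatedVariant(site=site, record=record, max_maf=maf)


@pytest.fixture(scope="session")
def sim300(tmp_path_factory):
    """Default 300-sample synthetic cohort, seed 1."""
    out_dir = tmp_path_factory.mktemp("sim300")
    return generate(SimulationConfig(seed=1), out_dir)


@pytest.fixture(scope="session")
def pipeline300(sim300, tmp_path_factory):
    """Full pipeline result on the default synthetic cohort."""
    out_dir = tmp_path_factory.mktemp("run300")
    return run_pipeline(
        sim300.vcf,
        sim300.panel,
        sim300.knowledge,
        sim300.gene_model,
        manual_evidence_path=sim300.manual_evidence,
        out_dir=out_dir,
        expected_samples=300,
    )
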