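"""germscreen: germline cancer-predisposition screening at cohort scale.

Reads a multi-sample VCF, annotates variants against pluggable knowledge
tables, applies a five-stage collection cascade (read depth, gene panel,
functional class, ClinVar/population frequency, Hardy-Weinberg exact
test), classifies survivors with an ACMG/AMP evidence engine, and reports
per-sample carrier status.  A seeded synthetic-cohort generator produces
fully structured test cohorts with exact truth tables.
"""

__version__ = "0.1.0"

from .variant_io import (  # noqa: F401,E402
    VariantKey,
    SampleCall,
    CohortSite,
    PanelGene,
    normalize_variant,
    read_cohort_vcf,
    write_cohort_vcf,
    read_panel,
)
from .annotate import (  # noqa: F401,E402
    FunctionalClass,
    KnowledgeRecord,
    AnnotatedVariant,
    GeneModel,
    annotate,
    max_population_maf,
    read_knowledge,
    read_gene_model,
)
from .filters import (  # noqa: F401,E402
    FilterConfig,
    FilterOutcome,
    FilterTrace,
    hwe_exact_test,
    apply_cascade,
)
from .acmg import (  # noqa: F401,E402
    EvidenceProfile,
    Tier,
    ClassificationResult,
    ClassifiedVariant,
    assign_automatic_evidence,
    merge_evidence,
    combine_evidence,
    classify_batch,
    read_manual_evidence,
)
from .report import CohortSummary, PipelineResult, summarize, run_pipeline  # noqa: F401,E402
from .simulate import SimulationConfig, PlantedVariant, TruthTable, generate  # noqa: F401,E402


def data_path(name: str):
    """Path to a packaged fixture table (panel, knowledge, manual evidence)."""
    from importlib.resources import files

    return files("germscreen.data").joinpath(name)
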