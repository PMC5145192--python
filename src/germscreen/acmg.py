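"""ACMG/AMP evidence assignment and five-tier combination.

The engine mirrors the split between automated assessment and manual
review used in clinical screening: the automatic step assigns only the two
codes that are derivable from annotation alone — PVS1 (null variant in a
gene where loss of function is an established disease mechanism) and PM2
(absent from all population panels) — while literature-dependent codes
(PS1, PM5, PP-level, benign-side evidence) arrive through a manual
override table.  The combining rules are the published 2015 ACMG/AMP
criteria; a ClinVar assertion accompanies results as context but never
overrides the engine's tier.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotate import AnnotatedVariant, FunctionalClass
from .variant_io import PanelGene, VariantKey, normalize_variant, panel_lookup

__all__ = [
    "CODE_VOCABULARY",
    "strength_class",
    "EvidenceProfile",
    "Tier",
    "ClassificationResult",
    "ClassifiedVariant",
    "assign_automatic_evidence",
    "merge_evidence",
    "combine_evidence",
    "classify_batch",
    "read_manual_evidence",
]

logger = logging.getLogger(__name__)

# The 28 ACMG/AMP criteria codes.
CODE_VOCABULARY: frozenset[str] = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

_STRENGTH_BY_PREFIX = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "stand_alone_benign",
    "BS": "strong_benign",
    "BP": "supporting_benign",
}

# Functional classes counting as "null variant" for PVS1.  Stop-loss is not
# a null consequence; splicing qualifies only because the annotator's
# splicing class is restricted to canonical +/-2 sites.
_NULL_CLASSES = {FunctionalClass.STOP_GAIN, FunctionalClass.FRAMESHIFT, FunctionalClass.SPLICING}


def strength_class(code: str) -> str:
    """Evidence strength implied by a code's prefix (PVS1 -> very_strong ...)."""
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix):
            return _STRENGTH_BY_PREFIX[prefix]
    raise ValueError(f"unknown evidence code {code!r}")


def _validate_codes(codes: Iterable[str], context: str = "") -> frozenset[str]:
    codes = frozenset(codes)
    unknown = codes - CODE_VOCABULARY
    if unknown:
        where = f" in {context}" if context else ""
        raise ValueError(f"unknown evidence code(s) {sorted(unknown)}{where}")
    return codes


@dataclass(frozen=True)
class EvidenceProfile:
    """The evidence codes attached to one variant, with per-code provenance."""

    key: VariantKey
    codes: frozenset[str]
    provenance: Mapping[str, str] = field(default_factory=dict)  # code -> automatic|manual
    removals: frozenset[str] = frozenset()  # manual "!CODE" directives

    def __post_init__(self) -> None:
        _validate_codes(self.codes, str(self.key))
        _validate_codes(self.removals, str(self.key))


class Tier(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


@dataclass(frozen=True)
class ClassificationResult:
    key: VariantKey
    tier: Tier
    rule_fired: str


@dataclass
class ClassifiedVariant:
    """A variant with its merged evidence and final tier, ready to report."""

    variant: AnnotatedVariant
    profile: EvidenceProfile
    result: ClassificationResult


def assign_automatic_evidence(
    variant: AnnotatedVariant,
    panel: Sequence[PanelGene],
    pm2_maf_max: float = 0.0,
) -> EvidenceProfile:
    """Assign the annotation-derivable codes: PVS1 and PM2.

    PVS1 requires a null consequence (stop-gain, frameshift, canonical
    splicing) in a gene whose panel entry records loss of function as the
    disease mechanism; for a gene missing from the panel the mechanism is
    unknowable and PVS1 is withheld with a warning.  PM2 requires absence
    from every population panel (``max_maf == 0``); ``pm2_maf_max`` relaxes
    that to an extreme-rarity threshold for users who want the lenient
    reading, but defaults to strict absence.
    """
    codes: set[str] = set()
    rec = variant.record
    if rec.func in _NULL_CLASSES:
        gene = panel_lookup(panel).get(rec.gene) if rec.gene else None
        if gene is None:
            logger.warning(
                "PVS1 withheld for %s: gene %s absent from panel, LoF mechanism unknown",
                variant.key, rec.gene,
            )
        elif gene.lof_mechanism:
            codes.add("PVS1")
    if variant.max_maf <= pm2_maf_max:
        codes.add("PM2")
    return EvidenceProfile(
        key=variant.key,
        codes=frozenset(codes),
        provenance={c: "automatic" for c in codes},
    )


def merge_evidence(auto: EvidenceProfile, manual: EvidenceProfile) -> EvidenceProfile:
    """Union automatic and manual evidence; manual wins, ``!CODE`` removes."""
    if auto.key != manual.key:
        raise ValueError(f"cannot merge evidence for {auto.key} with {manual.key}")
    codes = (set(auto.codes) | set(manual.codes)) - set(manual.removals)
    provenance = dict(auto.provenance)
    provenance.update(manual.provenance)
    provenance = {c: provenance.get(c, "manual") for c in codes}
    return EvidenceProfile(key=auto.key, codes=frozenset(codes), provenance=provenance)


def _counts(codes: frozenset[str]) -> tuple[int, int, int, int, bool, int, int]:
    pvs = sum(1 for c in codes if c == "PVS1")
    ps = sum(1 for c in codes if c.startswith("PS"))
    pm = sum(1 for c in codes if c.startswith("PM"))
    pp = sum(1 for c in codes if c.startswith("PP"))
    ba = "BA1" in codes
    bs = sum(1 for c in codes if c.startswith("BS"))
    bp = sum(1 for c in codes if c.startswith("BP"))
    return pvs, ps, pm, pp, ba, bs, bp


def _pathogenic_side(codes: frozenset[str]) -> Optional[tuple[Tier, str]]:
    pvs, ps, pm, pp, _, _, _ = _counts(codes)
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2):
        return Tier.PATHOGENIC, "P-i"
    if ps >= 2:
        return Tier.PATHOGENIC, "P-ii"
    if ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        return Tier.PATHOGENIC, "P-iii"
    if pvs >= 1 and pm >= 1:
        return Tier.LIKELY_PATHOGENIC, "LP-i"
    if ps == 1 and 1 <= pm <= 2:
        return Tier.LIKELY_PATHOGENIC, "LP-ii"
    if ps == 1 and pp >= 2:
        return Tier.LIKELY_PATHOGENIC, "LP-iii"
    if pm >= 3:
        return Tier.LIKELY_PATHOGENIC, "LP-iv"
    if pm == 2 and pp >= 2:
        return Tier.LIKELY_PATHOGENIC, "LP-v"
    if pm == 1 and pp >= 4:
        return Tier.LIKELY_PATHOGENIC, "LP-vi"
    return None


def _benign_side(codes: frozenset[str]) -> Optional[tuple[Tier, str]]:
    _, _, _, _, ba, bs, bp = _counts(codes)
    if ba:
        return Tier.BENIGN, "B-i"
    if bs >= 2:
        return Tier.BENIGN, "B-ii"
    if bs >= 1 and bp >= 1:
        return Tier.LIKELY_BENIGN, "LB-i"
    if bp >= 2:
        return Tier.LIKELY_BENIGN, "LB-ii"
    return None


def combine_evidence(profile: EvidenceProfile) -> ClassificationResult:
    """Combine evidence codes into a five-tier classification.

    Pathogenic and benign combining rules are evaluated independently; if
    rules on both sides fire the evidence is contradictory and the tier is
    uncertain (``conflict_uncertain``); if neither fires the tier defaults
    to uncertain (``default_uncertain``).  The engine is a pure function of
    the code set.
    """
    pathogenic = _pathogenic_side(profile.codes)
    benign = _benign_side(profile.codes)
    if pathogenic and benign:
        return ClassificationResult(profile.key, Tier.UNCERTAIN, "conflict_uncertain")
    if pathogenic:
        return ClassificationResult(profile.key, pathogenic[0], pathogenic[1])
    if benign:
        return ClassificationResult(profile.key, benign[0], benign[1])
    return ClassificationResult(profile.key, Tier.UNCERTAIN, "default_uncertain")


def classify_batch(
    variants: Sequence[AnnotatedVariant],
    manual_table: Mapping[VariantKey, EvidenceProfile],
    panel: Sequence[PanelGene],
    pm2_maf_max: float = 0.0,
) -> list[ClassifiedVariant]:
    """Per-variant assign -> merge -> combine over a retained variant set."""
    out: list[ClassifiedVariant] = []
    for variant in variants:
        auto = assign_automatic_evidence(variant, panel, pm2_maf_max=pm2_maf_max)
        manual = manual_table.get(variant.key)
        profile = merge_evidence(auto, manual) if manual is not None else auto
        out.append(ClassifiedVariant(variant=variant, profile=profile, result=combine_evidence(profile)))
    return out


def read_manual_evidence(path: str | Path) -> dict[VariantKey, EvidenceProfile]:
    """Read the manual-evidence TSV (``chrom pos ref alt codes``).

    ``codes`` is comma-separated; a ``!`` prefix marks a removal directive
    that deletes an automatically assigned code at merge time.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"chrom", "pos", "ref", "alt", "codes"}
    if not required.issubset(df.columns):
        raise ValueError(f"manual-evidence table {path} must have columns {sorted(required)}")
    table: dict[VariantKey, EvidenceProfile] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        key = normalize_variant(VariantKey(row.chrom, int(row.pos), row.ref, row.alt))
        raw = [] if pd.isna(row.codes) else [c.strip() for c in str(row.codes).split(",") if c.strip()]
        adds = [c for c in raw if not c.startswith("!")]
        removals = [c[1:] for c in raw if c.startswith("!")]
        try:
            profile = EvidenceProfile(
                key=key,
                codes=frozenset(adds),
                provenance={c: "manual" for c in adds},
                removals=frozenset(removals),
            )
        except ValueError as exc:
            raise ValueError(f"manual-evidence row {i + 1} ({key}): {exc}") from exc
        if key in table:
            raise ValueError(f"manual-evidence table has two rows for {key}")
        table[key] = profile
    return table
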