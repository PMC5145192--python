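"""The variant-collection filter cascade, including the HWE exact test.

Variants surviving this cascade are the candidate set handed to the
classification engine.  Five per-variant predicates run in a fixed order:

1. depth      — carrier-minimum site depth >= ``min_depth`` (default 30X);
2. panel      — the annotated gene is on the screening panel;
3. class      — the functional class is one the screen collects;
4. clinvar/maf — any ClinVar-present variant passes; a novel variant
                 passes only when its maximum population frequency is
                 <= ``novel_maf_max`` (default 0.5%);
5. hwe        — the exact Hardy-Weinberg test on the cohort genotype
                 tallies; gross departures (p below ``hwe_p_min``,
                 default 1e-6) flag genotyping artifacts and are removed.

Each stage is a pure per-variant predicate, so the retained set does not
depend on stage order; the order only determines which failure is recorded
for a variant that fails several stages.  Every input variant receives a
:class:`FilterTrace` so exclusions are auditable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .annotate import AnnotatedVariant, FunctionalClass
from .variant_io import PanelGene, VariantKey, panel_lookup, read_panel

__all__ = [
    "FilterConfig",
    "FilterOutcome",
    "FilterTrace",
    "hwe_exact_test",
    "apply_cascade",
    "write_trace_table",
]

DEFAULT_ALLOWED_CLASSES = frozenset(
    {
        FunctionalClass.SPLICING,
        FunctionalClass.NONSYNONYMOUS,
        FunctionalClass.STOP_GAIN,
        FunctionalClass.STOP_LOSS,
        FunctionalClass.FRAMESHIFT,
    }
)

# Tie tolerance when comparing genotype-configuration probabilities: float
# configurations that are exactly tied in rational arithmetic may differ by
# a few ulps after the recurrence.
_HWE_TIE_EPS = 1e-12


@dataclass
class FilterConfig:
    """Thresholds and tables for the collection cascade."""

    panel: Sequence[PanelGene] = ()
    min_depth: int = 30
    novel_maf_max: float = 0.005
    hwe_p_min: float = 1e-6
    allowed_classes: frozenset[FunctionalClass] = DEFAULT_ALLOWED_CLASSES

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0.0 <= self.novel_maf_max <= 1.0:
            raise ValueError("novel_maf_max must be in [0, 1]")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise ValueError("hwe_p_min must be in [0, 1]")
        self.allowed_classes = frozenset(FunctionalClass(c) for c in self.allowed_classes)

    @classmethod
    def from_yaml(cls, path: str | Path, panel: Sequence[PanelGene] = ()) -> "FilterConfig":
        """Load thresholds from a YAML mapping; unknown keys are rejected.

        Recognised keys: ``min_depth``, ``novel_maf_max``, ``hwe_p_min``,
        ``allowed_classes`` (list of class names), ``panel`` (path to a
        panel TSV, overridden by an explicit ``panel`` argument).
        """
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {"min_depth", "novel_maf_max", "hwe_p_min", "allowed_classes", "panel"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if not panel and "panel" in data:
            panel = read_panel(data["panel"])
        kwargs = {k: data[k] for k in ("min_depth", "novel_maf_max", "hwe_p_min") if k in data}
        if "allowed_classes" in data:
            kwargs["allowed_classes"] = frozenset(FunctionalClass(c) for c in data["allowed_classes"])
        return cls(panel=panel, **kwargs)


class FilterOutcome(str, enum.Enum):
    RETAINED = "retained"
    FAIL_DEPTH = "fail_depth"
    FAIL_PANEL = "fail_panel"
    FAIL_CLASS = "fail_class"
    FAIL_MAF = "fail_maf"
    FAIL_HWE = "fail_hwe"


_STAGE_ORDINAL = {
    FilterOutcome.FAIL_DEPTH: 1,
    FilterOutcome.FAIL_PANEL: 2,
    FilterOutcome.FAIL_CLASS: 3,
    FilterOutcome.FAIL_MAF: 4,
    FilterOutcome.FAIL_HWE: 5,
}


@dataclass(frozen=True)
class FilterTrace:
    """Per-variant record of the first failing stage (or retention)."""

    key: VariantKey
    outcome: FilterOutcome
    hwe_p: Optional[float] = None
    stage: Optional[int] = None


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts: with ``n`` diploid genotypes
    and the rarer allele seen ``n_rare`` times, the probability of ``h``
    heterozygotes under random mating is

        Pr(h) = C(n; a, h, b) * 2**h / C(2n, n_rare)

    with ``a = (n_rare - h) / 2`` rare homozygotes and ``b = n - h - a``
    common homozygotes.  The p-value sums Pr(h) over every compatible ``h``
    whose probability does not exceed that of the observed heterozygote
    count.  Probabilities are built by a multiplicative recurrence from the
    distribution mode, so the computation is stable for cohorts up to at
    least n = 10,000 (no factorials are formed).

    Returns a p-value in (0, 1].
    """
    for name, v in (("n_homref", n_homref), ("n_het", n_het), ("n_homalt", n_homalt)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    rare = min(2 * n_homref + n_het, 2 * n_homalt + n_het)
    if rare == 0:
        return 1.0  # monomorphic: a single possible configuration
    # valid heterozygote counts share the parity of the rare-allele count
    hets = list(range(rare % 2, rare + 1, 2))
    # start the recurrence near the mode to avoid underflow at the tails
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1
    mid = min(mid, rare)
    probs = {mid: 1.0}
    # downward: Pr(h-2) = Pr(h) * h*(h-1) / (4*(a+1)*(b+1))
    h = mid
    while h >= 2:
        a = (rare - h) // 2
        b = n - h - a
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (a + 1) * (b + 1))
        h -= 2
    # upward: Pr(h+2) = Pr(h) * 4*a*b / ((h+1)*(h+2))
    h = mid
    while h + 2 <= rare:
        a = (rare - h) // 2
        b = n - h - a
        probs[h + 2] = probs[h] * 4.0 * a * b / ((h + 1.0) * (h + 2.0))
        h += 2
    total = sum(probs[x] for x in hets)
    p_obs = probs[n_het]
    p = sum(probs[x] for x in hets if probs[x] <= p_obs * (1.0 + _HWE_TIE_EPS)) / total
    return min(p, 1.0)


def apply_cascade(
    variants: Sequence[AnnotatedVariant],
    config: FilterConfig,
) -> tuple[list[AnnotatedVariant], list[FilterTrace]]:
    """Run the five collection filters over annotated variants.

    Returns the retained variants (input order preserved) and one
    :class:`FilterTrace` per input variant.  ``hwe_p`` is recorded whenever
    the variant reaches the HWE stage.
    """
    symbols = set(panel_lookup(config.panel))
    retained: list[AnnotatedVariant] = []
    traces: list[FilterTrace] = []
    for variant in variants:
        rec = variant.record
        outcome = FilterOutcome.RETAINED
        hwe_p: Optional[float] = None
        if variant.site.site_depth < config.min_depth:
            outcome = FilterOutcome.FAIL_DEPTH
        elif rec.gene is None or rec.gene not in symbols:
            outcome = FilterOutcome.FAIL_PANEL
        elif rec.func not in config.allowed_classes:
            outcome = FilterOutcome.FAIL_CLASS
        elif not rec.clinvar_present and variant.max_maf > config.novel_maf_max:
            outcome = FilterOutcome.FAIL_MAF
        else:
            site = variant.site
            hwe_p = hwe_exact_test(site.n_homref, site.n_het, site.n_homalt)
            if hwe_p < config.hwe_p_min:
                outcome = FilterOutcome.FAIL_HWE
        traces.append(
            FilterTrace(
                key=variant.key,
                outcome=outcome,
                hwe_p=hwe_p,
                stage=_STAGE_ORDINAL.get(outcome),
            )
        )
        if outcome is FilterOutcome.RETAINED:
            retained.append(variant)
    return retained, traces


def write_trace_table(traces: Sequence[FilterTrace], path: str | Path) -> Path:
    """Write the per-variant filter outcomes as a TSV."""
    path = Path(path)
    lines = ["chrom\tpos\tref\talt\toutcome\thwe_p\tstage\n"]
    for t in traces:
        hwe = "" if t.hwe_p is None else f"{t.hwe_p:.6g}"
        stage = "" if t.stage is None else str(t.stage)
        lines.append(
            f"{t.key.chrom}\t{t.key.pos}\t{t.key.ref}\t{t.key.alt}\t{t.outcome.value}\t{hwe}\t{stage}\n"
        )
    path.write_text("".join(lines))
    return path
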