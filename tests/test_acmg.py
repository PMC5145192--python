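"""Evidence assignment, merging, and the five-tier combining rules."""

from __future__ import annotations

import itertools
import random

import pytest

from germscreen.acmg import (
    CODE_VOCABULARY,
    EvidenceProfile,
    Tier,
    assign_automatic_evidence,
    classify_batch,
    combine_evidence,
    merge_evidence,
    read_manual_evidence,
    strength_class,
)
from germscreen.annotate import FunctionalClass
from germscreen.variant_io import PanelGene, VariantKey

from conftest import make_annotated

PANEL = [PanelGene("APC", True), PanelGene("TP53", True), PanelGene("RET", False)]
KEY = VariantKey("17", 100, "C", "T")


def profile(*codes: str, removals: tuple[str, ...] = ()) -> EvidenceProfile:
    return EvidenceProfile(key=KEY, codes=frozenset(codes), removals=frozenset(removals))


# --- independent reference evaluator of the published combining rules -------

def reference_tier(codes: frozenset[str]) -> str:
    from collections import Counter

    c = Counter(strength_class(code) for code in codes)
    vs, s, m, p = c["very_strong"], c["strong"], c["moderate"], c["supporting"]
    ba, bs, bp = c["stand_alone_benign"], c["strong_benign"], c["supporting_benign"]
    pathogenic = (
        (vs == 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    )
    likely = (
        (vs == 1 and m == 1)
        or (s == 1 and m in (1, 2))
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2
    path_side = "pathogenic" if pathogenic else ("likely_pathogenic" if likely else None)
    benign_side = "benign" if benign else ("likely_benign" if likely_benign else None)
    if path_side and benign_side:
        return "uncertain"
    return path_side or benign_side or "uncertain"


class TestAssignAutomaticEvidence:
    def test_truncating_lof_gene_absent_from_controls(self):
        v = make_annotated(100, gene="APC", func=FunctionalClass.STOP_GAIN)
        assert assign_automatic_evidence(v, PANEL).codes == {"PVS1", "PM2"}

    def test_missense_gets_pm2_only(self):
        v = make_annotated(100, gene="TP53", func=FunctionalClass.NONSYNONYMOUS)
        assert assign_automatic_evidence(v, PANEL).codes == {"PM2"}

    def test_population_presence_blocks_pm2(self):
        v = make_annotated(100, gene="TP53", maf_exac=0.004)
        assert assign_automatic_evidence(v, PANEL).codes == frozenset()

    def test_pvs1_requires_lof_mechanism(self):
        v = make_annotated(100, gene="RET", func=FunctionalClass.FRAMESHIFT)
        assert assign_automatic_evidence(v, PANEL).codes == {"PM2"}

    def test_pvs1_withheld_for_gene_off_panel(self, caplog):
        v = make_annotated(100, gene="UNKNOWN9", func=FunctionalClass.FRAMESHIFT)
        with caplog.at_level("WARNING"):
            codes = assign_automatic_evidence(v, PANEL).codes
        assert codes == {"PM2"}
        assert any("PVS1 withheld" in r.message for r in caplog.records)

    def test_splicing_counts_as_null(self):
        v = make_annotated(100, gene="APC", func=FunctionalClass.SPLICING)
        assert "PVS1" in assign_automatic_evidence(v, PANEL).codes

    def test_stop_loss_is_not_null(self):
        v = make_annotated(100, gene="APC", func=FunctionalClass.STOP_LOSS)
        assert "PVS1" not in assign_automatic_evidence(v, PANEL).codes

    def test_relaxed_pm2_threshold(self):
        v = make_annotated(100, gene="TP53", maf_exac=0.00005)
        assert assign_automatic_evidence(v, PANEL).codes == frozenset()
        assert assign_automatic_evidence(v, PANEL, pm2_maf_max=0.0001).codes == {"PM2"}


class TestMergeEvidence:
    def test_union(self):
        merged = merge_evidence(profile("PVS1", "PM2"), profile("PS1"))
        assert merged.codes == {"PVS1", "PM2", "PS1"}

    def test_removal_directive(self):
        merged = merge_evidence(profile("PVS1", "PM2"), profile("PM5", removals=("PVS1",)))
        assert merged.codes == {"PM2", "PM5"}

    def test_empty_identity(self):
        assert merge_evidence(profile(), profile()).codes == frozenset()

    def test_manual_provenance_wins(self):
        auto = EvidenceProfile(key=KEY, codes=frozenset({"PM2"}), provenance={"PM2": "automatic"})
        manual = EvidenceProfile(key=KEY, codes=frozenset({"PM2"}), provenance={"PM2": "manual"})
        assert merge_evidence(auto, manual).provenance["PM2"] == "manual"

    def test_key_mismatch_rejected(self):
        other = EvidenceProfile(key=VariantKey("1", 5, "A", "G"), codes=frozenset())
        with pytest.raises(ValueError):
            merge_evidence(profile(), other)


class TestCombineEvidence:
    @pytest.mark.parametrize(
        "codes, tier, rule",
        [
            (("PVS1", "PS1", "PM2"), Tier.PATHOGENIC, "P-i"),
            (("PS1", "PS3"), Tier.PATHOGENIC, "P-ii"),
            (("PVS1", "PM2"), Tier.LIKELY_PATHOGENIC, "LP-i"),
            (("PS1", "PM2"), Tier.LIKELY_PATHOGENIC, "LP-ii"),
            (("BA1",), Tier.BENIGN, "B-i"),
            (("BS1", "BS2"), Tier.BENIGN, "B-ii"),
            (("BS1", "BP3"), Tier.LIKELY_BENIGN, "LB-i"),
            (("BP1", "BP4"), Tier.LIKELY_BENIGN, "LB-ii"),
            ((), Tier.UNCERTAIN, "default_uncertain"),
            # one BS alone fires no benign rule, so the pathogenic side stands
            (("PVS1", "PM2", "BS1"), Tier.LIKELY_PATHOGENIC, "LP-i"),
        ],
    )
    def test_rule_table(self, codes, tier, rule):
        result = combine_evidence(profile(*codes))
        assert (result.tier, result.rule_fired) == (tier, rule)

    def test_conflicting_evidence_is_uncertain(self):
        result = combine_evidence(profile("PVS1", "PM2", "BA1"))
        assert result.tier is Tier.UNCERTAIN
        assert result.rule_fired == "conflict_uncertain"

    def test_exhaustive_small_subsets_match_reference(self):
        codes = sorted(CODE_VOCABULARY)
        for size in range(0, 4):
            for subset in itertools.combinations(codes, size):
                got = combine_evidence(profile(*subset)).tier.value
                assert got == reference_tier(frozenset(subset)), subset

    def test_random_large_subsets_match_reference(self):
        rng = random.Random(5)
        codes = sorted(CODE_VOCABULARY)
        for _ in range(2000):
            subset = frozenset(rng.sample(codes, rng.randint(4, 12)))
            got = combine_evidence(profile(*subset)).tier.value
            assert got == reference_tier(subset), sorted(subset)

    def test_monotonicity_outside_conflict(self):
        """Adding pathogenic-side evidence never moves the tier toward benign
        (and symmetrically), except through the explicit conflict rule."""
        rank = {
            Tier.BENIGN: 0, Tier.LIKELY_BENIGN: 1, Tier.UNCERTAIN: 2,
            Tier.LIKELY_PATHOGENIC: 3, Tier.PATHOGENIC: 4,
        }
        rng = random.Random(17)
        path_codes = sorted(c for c in CODE_VOCABULARY if c[0] == "P")
        benign_codes = sorted(c for c in CODE_VOCABULARY if c[0] == "B")
        for _ in range(500):
            base = frozenset(rng.sample(sorted(CODE_VOCABULARY), rng.randint(0, 5)))
            before = combine_evidence(profile(*base))
            extra = rng.choice(path_codes)
            after = combine_evidence(profile(*(base | {extra})))
            if "conflict" not in (before.rule_fired, after.rule_fired):
                assert rank[after.tier] >= rank[before.tier]
            extra_b = rng.choice(benign_codes)
            after_b = combine_evidence(profile(*(base | {extra_b})))
            if "conflict" not in (before.rule_fired, after_b.rule_fired):
                assert rank[after_b.tier] <= rank[before.tier]

    def test_purity(self):
        p = profile("PVS1", "PM2", "PP3")
        assert combine_evidence(p) == combine_evidence(p)


def test_strength_class_prefix_mapping():
    assert strength_class("PVS1") == "very_strong"
    assert strength_class("PS4") == "strong"
    assert strength_class("PM6") == "moderate"
    assert strength_class("PP5") == "supporting"
    assert strength_class("BA1") == "stand_alone_benign"
    assert strength_class("BS4") == "strong_benign"
    assert strength_class("BP7") == "supporting_benign"
    with pytest.raises(ValueError):
        strength_class("XX1")


def test_unknown_code_rejected():
    with pytest.raises(ValueError, match="PX9"):
        EvidenceProfile(key=KEY, codes=frozenset({"PX9"}))


def test_read_manual_evidence_and_directives(tmp_path):
    path = tmp_path / "manual.tsv"
    path.write_text(
        "chrom\tpos\tref\talt\tcodes\n"
        "17\t100\tC\tT\tPS1,!PVS1\n"
        "17\t200\tA\tG\t\n"
    )
    table = read_manual_evidence(path)
    prof = table[VariantKey("17", 100, "C", "T")]
    assert prof.codes == {"PS1"} and prof.removals == {"PVS1"}
    assert table[VariantKey("17", 200, "A", "G")].codes == frozenset()

    bad = tmp_path / "bad.tsv"
    bad.write_text("chrom\tpos\tref\talt\tcodes\n17\t100\tC\tT\tPS1,WRONG\n")
    with pytest.raises(ValueError, match="row 1"):
        read_manual_evidence(bad)


def test_classify_batch_end_to_end():
    variants = [
        make_annotated(100, gene="APC", func=FunctionalClass.STOP_GAIN),
        make_annotated(104, gene="TP53", func=FunctionalClass.NONSYNONYMOUS),
        make_annotated(108, gene="TP53", maf_exac=0.002),
    ]
    manual = {
        variants[0].key: EvidenceProfile(
            key=variants[0].key, codes=frozenset({"PS1"}), provenance={"PS1": "manual"}
        )
    }
    out = classify_batch(variants, manual, PANEL)
    assert [cv.result.tier for cv in out] == [Tier.PATHOGENIC, Tier.UNCERTAIN, Tier.UNCERTAIN]
    assert out[0].profile.codes == {"PVS1", "PM2", "PS1"}
    # deterministic pure function of inputs
    again = classify_batch(variants, manual, PANEL)
    assert [cv.result for cv in again] == [cv.result for cv in out]
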