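"""Filter cascade behaviour and the exact Hardy-Weinberg test."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germscreen.annotate import FunctionalClass
from germscreen.filters import (
    FilterConfig,
    FilterOutcome,
    apply_cascade,
    hwe_exact_test,
)
from germscreen.variant_io import PanelGene

from conftest import make_annotated

PANEL = [PanelGene("BRCA1", True), PanelGene("TP53", True), PanelGene("RET", False)]


def hwe_oracle(n_homref: int, n_het: int, n_homalt: int) -> Fraction:
    """Exact-rational brute-force enumeration of the conditional HWE test."""
    n = n_homref + n_het + n_homalt
    rare = min(2 * n_homref + n_het, 2 * n_homalt + n_het)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        a = (rare - h) // 2
        weights[h] = comb(n, h) * comb(n - h, a) * 2**h
    w_obs = weights[n_het]
    return Fraction(sum(w for w in weights.values() if w <= w_obs), sum(weights.values()))


class TestHweExactTest:
    def test_monomorphic_site_is_one(self):
        assert hwe_exact_test(300, 0, 0) == 1.0

    def test_singleton_heterozygote_is_one(self):
        assert hwe_exact_test(299, 1, 0) == 1.0

    @pytest.mark.parametrize("n", [2, 10, 300, 5000])
    def test_singleton_het_is_one_for_any_cohort_size(self, n):
        # a planted pathogenic singleton can never be lost to the HWE stage
        assert hwe_exact_test(n - 1, 1, 0) == 1.0

    def test_equilibrium_tally_is_one(self):
        # (25, 50, 25) sits exactly at the modal configuration
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, rel=1e-12)

    def test_extreme_het_excess_fails_threshold(self):
        assert hwe_exact_test(0, 300, 0) < 1e-6

    @pytest.mark.parametrize(
        "tally, expected",
        [
            # frozen values from the exact-rational enumeration oracle
            ((0, 30, 0), 1.0390763893465774e-08),
            ((150, 150, 0), 1.7932772426132795e-11),
        ],
    )
    def test_frozen_oracle_values(self, tally, expected):
        assert hwe_exact_test(*tally) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=st.integers(0, 80), h=st.integers(0, 80), b=st.integers(0, 80))
    def test_symmetry_and_oracle_agreement(self, a, h, b):
        if a + h + b == 0:
            return
        p = hwe_exact_test(a, h, b)
        assert p == hwe_exact_test(b, h, a)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(float(hwe_oracle(a, h, b)), rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 5)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestApplyCascade:
    def config(self, **kw):
        return FilterConfig(panel=PANEL, **kw)

    def test_clinvar_pathogenic_singleton_retained(self):
        v = make_annotated(100, clinvar_present=True, clinvar_assertion="pathogenic")
        retained, traces = apply_cascade([v], self.config())
        assert retained == [v]
        assert traces[0].outcome is FilterOutcome.RETAINED
        assert traces[0].hwe_p == 1.0
        assert traces[0].stage is None

    def test_depth_boundary(self):
        at = make_annotated(100, clinvar_present=True, clinvar_assertion="uncertain", carrier_depth=30)
        below = make_annotated(104, clinvar_present=True, clinvar_assertion="uncertain", carrier_depth=29)
        retained, traces = apply_cascade([at, below], self.config())
        assert retained == [at]
        assert traces[1].outcome is FilterOutcome.FAIL_DEPTH
        assert traces[1].stage == 1

    def test_off_panel_gene_fails(self):
        v = make_annotated(100, gene="TTN", clinvar_present=True, clinvar_assertion="uncertain")
        none = make_annotated(104, gene=None)
        _, traces = apply_cascade([v, none], self.config())
        assert [t.outcome for t in traces] == [FilterOutcome.FAIL_PANEL] * 2

    def test_disallowed_class_fails(self):
        v = make_annotated(100, func=FunctionalClass.OTHER, clinvar_present=True, clinvar_assertion="benign")
        _, traces = apply_cascade([v], self.config())
        assert traces[0].outcome is FilterOutcome.FAIL_CLASS

    def test_novel_maf_boundary_inclusive(self):
        at = make_annotated(100, maf_exac=0.005)
        above = make_annotated(104, maf_exac=0.006)
        retained, traces = apply_cascade([at, above], self.config())
        assert retained == [at]
        assert traces[1].outcome is FilterOutcome.FAIL_MAF

    def test_clinvar_presence_waives_maf_condition(self):
        v = make_annotated(100, func=FunctionalClass.FRAMESHIFT, clinvar_present=True,
                           clinvar_assertion="pathogenic", maf_exac=0.02)
        retained, _ = apply_cascade([v], self.config())
        assert retained == [v]

    def test_hwe_failure(self):
        v = make_annotated(100, clinvar_present=True, clinvar_assertion="uncertain",
                           n_samples=300, het_samples=range(300))
        _, traces = apply_cascade([v], self.config())
        assert traces[0].outcome is FilterOutcome.FAIL_HWE
        assert traces[0].hwe_p < 1e-6
        assert traces[0].stage == 5

    def test_partition_and_first_failure_wins(self):
        # fails depth AND panel AND class; depth is stage 1 so it is recorded
        v = make_annotated(100, gene="TTN", func=FunctionalClass.OTHER, carrier_depth=5)
        variants = [
            v,
            make_annotated(104, clinvar_present=True, clinvar_assertion="pathogenic"),
            make_annotated(108, maf_exac=0.5),
        ]
        retained, traces = apply_cascade(variants, self.config())
        assert traces[0].outcome is FilterOutcome.FAIL_DEPTH
        assert len(traces) == len(variants)
        assert len(retained) + sum(1 for t in traces if t.outcome is not FilterOutcome.RETAINED) == len(variants)
        assert {t.key for t in traces} == {x.key for x in variants}

    def test_monotonicity_under_threshold_tightening(self):
        rng = np.random.default_rng(11)
        variants = []
        for i in range(60):
            variants.append(
                make_annotated(
                    100 + 4 * i,
                    gene=rng.choice(["BRCA1", "TP53", "TTN"]),
                    func=rng.choice(list(FunctionalClass)),
                    clinvar_present=bool(rng.integers(2)),
                    clinvar_assertion=None,
                    maf_exac=float(rng.uniform(0, 0.02)) if rng.integers(2) else None,
                    carrier_depth=int(rng.integers(5, 60)),
                    n_samples=30,
                    het_samples=list(rng.choice(30, size=rng.integers(1, 20), replace=False)),
                )
            )
        base = self.config()
        keys = lambda vs: {v.key for v in vs}
        loose = keys(apply_cascade(variants, base)[0])
        for tighter in (
            self.config(min_depth=45),
            self.config(novel_maf_max=0.001),
            self.config(hwe_p_min=0.05),
        ):
            assert keys(apply_cascade(variants, tighter)[0]) <= loose

    def test_extreme_depth_threshold_empties_retained_set(self):
        vs = [make_annotated(100, clinvar_present=True, clinvar_assertion="pathogenic")]
        retained, traces = apply_cascade(vs, self.config(min_depth=10_000))
        assert retained == [] and traces[0].outcome is FilterOutcome.FAIL_DEPTH


def test_config_validation_and_yaml(tmp_path):
    with pytest.raises(ValueError):
        FilterConfig(novel_maf_max=1.5)
    with pytest.raises(ValueError):
        FilterConfig(min_depth=-1)
    cfg_file = tmp_path / "cfg.yaml"
    cfg_file.write_text("min_depth: 20\nnovel_maf_max: 0.0005\nhwe_p_min: 1.0e-4\n")
    cfg = FilterConfig.from_yaml(cfg_file, panel=PANEL)
    assert (cfg.min_depth, cfg.novel_maf_max, cfg.hwe_p_min) == (20, 0.0005, 1.0e-4)
    bad = tmp_path / "bad.yaml"
    bad.write_text("depth: 20\n")
    with pytest.raises(ValueError, match="unknown config keys"):
        FilterConfig.from_yaml(bad, panel=PANEL)
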