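"""Drug-class registry, eQTL best-SNP selection and target validation."""

import numpy as np
import pandas as pd
import pytest
import yaml

from targetmr import (
    DrugClass,
    build_class_instrument,
    build_gw_significant_instrument,
    load_drug_class_registry,
    select_best_snps,
    stage_counts,
    validate_target,
)
from targetmr.instruments import RegistryError
from targetmr.simulate import DRUG_CLASSES

from conftest import small_panel


def eqtl_row(gene="ACE", tissue="artery", snp="rs1", beta=0.5, se=0.05,
             p=1e-8, ea="A", oa="G", eaf=0.2):
    return {"GENE": gene, "TISSUE": tissue, "SNP": snp, "EA": ea, "OA": oa,
            "EAF": eaf, "BETA": beta, "SE": se, "P": p}


def gwas_frame(rows):
    return pd.DataFrame(rows)


def gwas_row(snp, beta, se=0.005, p=1e-10, ea="A", oa="G", pos=100):
    return {"SNP": snp, "CHR": "1", "POS": pos, "EA": ea, "OA": oa,
            "EAF": 0.2, "BETA": beta, "SE": se, "P": p}


class TestRegistry:
    def write(self, tmp_path, payload):
        path = tmp_path / "registry.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)
        return path

    def test_twelve_classes(self, tmp_path):
        payload = [{"class": c, "genes": [f"G{i}"]} for i, c in enumerate(DRUG_CLASSES)]
        classes = load_drug_class_registry(self.write(tmp_path, payload))
        assert len(classes) == 12
        assert {c.name for c in classes} == set(DRUG_CLASSES)

    def test_duplicate_class_merged(self, tmp_path):
        payload = [{"class": "beta-adrenoceptor blockers", "genes": ["ADRB1"]},
                   {"class": "beta-adrenoceptor blockers", "genes": ["ADRB2", "ADRB1"]}]
        classes = load_drug_class_registry(self.write(tmp_path, payload))
        assert len(classes) == 1
        assert classes[0].target_genes == ["ADRB1", "ADRB2"]

    def test_empty_gene_list_retained_unanalysable(self, tmp_path):
        payload = [{"class": "renin inhibitors", "genes": []}]
        classes = load_drug_class_registry(self.write(tmp_path, payload))
        assert len(classes) == 1 and not classes[0].analysable

    def test_malformed_entry_names_offender(self, tmp_path):
        path = self.write(tmp_path, [{"genes": ["ACE"]}])
        with pytest.raises(RegistryError, match="lacks a 'class' key"):
            load_drug_class_registry(path)

    def test_shipped_default_registry_parses(self):
        from importlib.resources import files

        path = files("targetmr").joinpath("data/drug_classes.yaml")
        classes = load_drug_class_registry(str(path))
        assert len(classes) == 12


class TestBestSnpSelection:
    def test_same_top_variant_across_tissues_deduplicated(self):
        eqtl = pd.DataFrame([eqtl_row(tissue=t, snp="rs1", p=1e-9) for t in "abc"]
                            + [eqtl_row(tissue="a", snp="rs2", p=1e-4)])
        out = select_best_snps(eqtl, "ACE")
        assert list(out["SNP"]) == ["rs1"]

    def test_distinct_top_variants_union(self):
        eqtl = pd.DataFrame([
            eqtl_row(tissue="a", snp="rs1", p=1e-9),
            eqtl_row(tissue="b", snp="rs2", p=1e-7),
            eqtl_row(tissue="b", snp="rs1", p=1e-5),
        ])
        out = select_best_snps(eqtl, "ACE")
        assert sorted(out["SNP"]) == ["rs1", "rs2"]

    def test_tie_broken_by_position(self):
        eqtl = pd.DataFrame([
            eqtl_row(tissue="a", snp="rs_far", p=1e-8),
            eqtl_row(tissue="a", snp="rs_near", p=1e-8),
        ])
        out = select_best_snps(eqtl, "ACE", positions={"rs_near": 100, "rs_far": 999})
        assert list(out["SNP"]) == ["rs_near"]

    def test_absent_gene_gives_empty(self):
        eqtl = pd.DataFrame([eqtl_row()])
        assert select_best_snps(eqtl, "NOSUCH").empty


class TestValidation:
    def test_wald_ratio_and_retention(self):
        cands = pd.DataFrame([eqtl_row(snp="rs1", beta=0.5, se=0.05)])
        gwas = gwas_frame([gwas_row("rs1", beta=-0.05, se=0.005)])
        ti = validate_target("ACE", cands, gwas)
        assert ti.status == "validated"
        row = ti.validation.iloc[0]
        assert row["beta"] == pytest.approx(-0.10)  # SD SBP per SD expression
        assert row["se"] == pytest.approx(0.005 / 0.5)
        assert ti.validated_variants == ["rs1"]

    def test_null_exposure_effect_not_retained(self):
        cands = pd.DataFrame([eqtl_row(snp="rs1", beta=0.5)])
        gwas = gwas_frame([gwas_row("rs1", beta=0.0, se=0.01)])
        ti = validate_target("ACE", cands, gwas)
        assert ti.status == "expressed"
        assert ti.validation["pval"].iloc[0] == pytest.approx(1.0)

    def test_allele_swap_flips_expression_beta(self):
        cands = pd.DataFrame([eqtl_row(snp="rs1", beta=0.5, ea="G", oa="A")])
        gwas = gwas_frame([gwas_row("rs1", beta=-0.05, ea="A", oa="G")])
        ti = validate_target("ACE", cands, gwas)
        assert ti.validation["beta"].iloc[0] == pytest.approx(0.10)

    def test_candidate_absent_from_gwas_dropped_with_reason(self):
        cands = pd.DataFrame([eqtl_row(snp="rs_missing")])
        gwas = gwas_frame([gwas_row("rs1", beta=0.05)])
        ti = validate_target("ACE", cands, gwas)
        assert ti.status == "expressed"
        assert ti.validation["reason"].iloc[0] == "absent from exposure GWAS"

    def test_empty_candidates_stay_candidate(self):
        ti = validate_target("ACE", pd.DataFrame(columns=["SNP", "TISSUE", "P",
                                                          "EA", "OA", "BETA", "SE"]),
                             gwas_frame([gwas_row("rs1", 0.05)]))
        assert ti.status == "candidate"


class TestClassInstrument:
    def setup_method(self):
        self.panel = small_panel(np.eye(3))
        self.exposure = gwas_frame([
            gwas_row("rs1", 0.05, pos=1_000_000),
            gwas_row("rs2", 0.04, pos=1_050_000),
            gwas_row("rs3", 0.06, pos=1_100_000),
        ])
        self.outcome = gwas_frame([
            gwas_row("rs1", 0.01, pos=1_000_000),
            gwas_row("rs2", 0.02, pos=1_050_000),
            gwas_row("rs3", 0.015, pos=1_100_000),
        ])

    def validated(self, gene, snps):
        cands = pd.DataFrame([eqtl_row(gene=gene, snp=s) for s in snps])
        return validate_target(gene, cands, self.exposure)

    def test_independent_targets_combine(self):
        cls = DrugClass("calcium channel blockers", ["G1", "G2", "G3"])
        targets = [self.validated(g, [s]) for g, s in
                   zip(["G1", "G2", "G3"], ["rs1", "rs2", "rs3"])]
        ids, subs = build_class_instrument(cls, targets, self.outcome, self.panel,
                                           self.exposure)
        assert sorted(ids) == ["rs1", "rs2", "rs3"]
        assert all(t.status == "analysed" for t in targets)

    def test_shared_snp_deduplicated(self):
        cls = DrugClass("beta-adrenoceptor blockers", ["G1", "G2"])
        targets = [self.validated("G1", ["rs1"]), self.validated("G2", ["rs1"])]
        ids, _ = build_class_instrument(cls, targets, self.outcome, self.panel,
                                        self.exposure)
        assert ids == ["rs1"]

    def test_target_without_outcome_data_excluded(self):
        cls = DrugClass("loop diuretics", ["G1", "G2"])
        targets = [self.validated("G1", ["rs1"]), self.validated("G2", ["rs2"])]
        outcome = self.outcome[self.outcome["SNP"] != "rs2"]
        ids, subs = build_class_instrument(cls, targets, outcome, self.panel,
                                           self.exposure)
        assert ids == ["rs1"]
        assert targets[1].status == "excluded_no_outcome_data"
        assert (subs.loc[subs["SNP"] == "rs2", "status"] == "dropped").all()

    def test_stage_counts_monotone(self):
        targets = [self.validated("G1", ["rs1"]), self.validated("G2", ["rs_gone"])]
        counts = stage_counts(targets)
        assert (counts["candidates"] >= counts["expressed"] >= counts["validated"]
                >= counts["analysed"])


class TestGwSignificantInstrument:
    def test_known_signals_recovered(self, causal_study):
        """Strong true signals are retained; everything retained traces to a signal."""
        s = causal_study
        truth = s.truth
        maf = dict(zip(s.panel.variants["SNP"], s.panel.variants["MAF"]))
        joint = {v: truth.joint_exposure_effect(g) for g, v in truth.gene_variant.items()}
        for v, eff in truth.background_effects.items():
            joint[v] = joint.get(v, 0.0) + eff
        se = {v: 1.0 / np.sqrt(2 * truth.n_exposure * maf[v] * (1 - maf[v]))
              for v in joint}
        expected_z = {v: abs(b) / se[v] for v, b in joint.items()}
        ids, _ = build_gw_significant_instrument(s.exposure, s.panel, s.outcome)
        got = set(ids)
        # each retained variant is a true signal or in LD with one
        for v in got:
            assert v in joint or any(s.panel.r2_between(v, t) > 0.05 for t in joint)
        # each clearly significant signal (z >= 8) is represented, directly or by
        # an LD partner that clumping preferred
        for t, z in expected_z.items():
            if z >= 8:
                assert any(s.panel.r2_between(v, t) > 0.3 or v == t for v in got)

    def test_degenerate_threshold_returns_clumped_panel(self, causal_study):
        s = causal_study
        ids, _ = build_gw_significant_instrument(s.exposure, s.panel, s.outcome,
                                                 p_threshold=1.0)
        oracle = clump_all = [v for v in ids]
        assert len(ids) > 0
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if a in s.panel and b in s.panel:
                    assert s.panel.r2_between(a, b) <= 0.001

    def test_correlated_pair_one_survivor(self):
        r = np.array([[1.0, 0.9], [0.9, 1.0]])
        panel = small_panel(r)
        exposure = gwas_frame([gwas_row("rs1", 0.05, p=1e-10, pos=1_000_000),
                               gwas_row("rs2", 0.05, p=1e-9, pos=1_050_000)])
        outcome = exposure.copy()
        ids, _ = build_gw_significant_instrument(exposure, panel, outcome)
        assert ids == ["rs1"]

    def test_none_significant_empty(self):
        panel = small_panel(np.eye(1))
        exposure = gwas_frame([gwas_row("rs1", 0.001, p=0.2)])
        ids, _ = build_gw_significant_instrument(exposure, panel, exposure)
        assert ids == []
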