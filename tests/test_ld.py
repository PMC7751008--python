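"""Clumping against a brute-force oracle; proxy search and substitution rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from targetmr import LDPanel, apply_proxies, clump, find_proxy, substitute_proxies

from conftest import small_panel


def records_for(panel, pvals):
    v = panel.variants
    return pd.DataFrame({
        "SNP": v["SNP"], "CHR": v["CHR"], "POS": v["POS"],
        "EA": v["A1"], "OA": v["A2"], "EAF": v["MAF"],
        "BETA": 0.1, "SE": 0.01, "P": pvals,
    })


def clump_oracle(records, panel, r2_max, window_kb):
    """Keep a variant iff it conflicts with no better-ranked retained variant.

    Equivalent characterization of the p-ordered maximal independent set; an
    independent re-derivation of what greedy index selection must produce.
    """
    order = records.sort_values(["P", "POS", "SNP"], kind="mergesort")
    kept: list[tuple] = []
    for snp, chrom, pos in order[["SNP", "CHR", "POS"]].itertuples(index=False, name=None):
        conflict = False
        for ksnp, kchrom, kpos in kept:
            if (snp in panel and ksnp in panel and str(chrom) == str(kchrom)
                    and abs(int(pos) - int(kpos)) <= window_kb * 1000
                    and panel.r2_between(snp, ksnp) > r2_max):
                conflict = True
                break
        if not conflict:
            kept.append((snp, chrom, pos))
    return [k[0] for k in kept]


def random_panel_and_pvals(seed, n):
    """Random correlation matrix (via random factor model) and random p-values."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, max(1, n // 2)))
    cov = A @ A.T + np.diag(rng.uniform(0.1, 1.0, n))
    d = np.sqrt(np.diag(cov))
    r = cov / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    panel = small_panel(r, mafs=list(rng.uniform(0.05, 0.5, n)))
    pvals = rng.uniform(1e-12, 1.0, n)
    return panel, pvals


class TestClump:
    def test_uncorrelated_variants_all_retained(self):
        panel = small_panel(np.eye(3))
        recs = records_for(panel, [1e-8, 1e-6, 1e-4])
        assert sorted(clump(recs, panel)) == ["rs1", "rs2", "rs3"]

    def test_correlated_pair_keeps_smaller_p(self):
        r = np.array([[1.0, 0.9487], [0.9487, 1.0]])  # r2 = 0.9
        panel = small_panel(r)
        recs = records_for(panel, [1e-8, 1e-10])
        assert clump(recs, panel) == ["rs2"]

    def test_empty_input(self):
        panel = small_panel(np.eye(2))
        assert clump(records_for(panel, [0.1, 0.2]).iloc[0:0], panel) == []

    def test_variant_absent_from_panel_passes_through(self):
        panel = small_panel(np.eye(2))
        recs = records_for(panel, [1e-4, 1e-3])
        extra = recs.iloc[[0]].assign(SNP="rs_unknown", P=1e-2)
        out = clump(pd.concat([recs, extra], ignore_index=True), panel)
        assert "rs_unknown" in out

    @given(seed=st.integers(0, 10_000), n=st.integers(2, 10),
           r2_max=st.sampled_from([0.001, 0.1, 0.5]))
    @settings(max_examples=120, deadline=None)
    def test_matches_bruteforce_oracle(self, seed, n, r2_max):
        panel, pvals = random_panel_and_pvals(seed, n)
        recs = records_for(panel, pvals)
        got = clump(recs, panel, r2_max=r2_max, window_kb=10_000)
        assert sorted(got) == sorted(clump_oracle(recs, panel, r2_max, 10_000))
        # retained set is pairwise nearly independent within the window
        for i, a in enumerate(got):
            for b in got[i + 1:]:
                assert panel.r2_between(a, b) <= r2_max

    def test_adding_uncorrelated_variant_preserves_retained(self):
        panel, pvals = random_panel_and_pvals(7, 6)
        # append an uncorrelated variant on another chromosome
        v = panel.variants.copy()
        v.loc[len(v)] = {"SNP": "rs_new", "CHR": "2", "POS": 500, "A1": "A",
                         "A2": "G", "MAF": 0.2}
        r2 = np.eye(7)
        r2[:6, :6] = panel.r
        bigger = LDPanel(variants=v, r=r2)
        recs = records_for(panel, pvals)
        recs_more = pd.concat(
            [recs, pd.DataFrame([{"SNP": "rs_new", "CHR": "2", "POS": 500,
                                  "EA": "A", "OA": "G", "EAF": 0.2, "BETA": 0.1,
                                  "SE": 0.01, "P": 0.5}])], ignore_index=True)
        base = set(clump(recs, panel, r2_max=0.1))
        more = set(clump(recs_more, bigger, r2_max=0.1))
        assert base <= more and "rs_new" in more


class TestFindProxy:
    def make_panel(self, r_vec, mafs=None, palindromic=()):
        n = len(r_vec) + 1
        r = np.eye(n)
        r[0, 1:] = r_vec
        r[1:, 0] = r_vec
        return small_panel(r, mafs=mafs, palindromic=palindromic)

    def test_single_candidate(self):
        panel = self.make_panel([0.975])  # r2 ~ 0.95
        assert find_proxy("rs1", panel, {"rs2"}) == "rs2"

    def test_palindromic_high_maf_excluded(self):
        panel = self.make_panel([0.975], mafs=[0.2, 0.4], palindromic={1})
        assert find_proxy("rs1", panel, {"rs2"}) is None

    def test_palindromic_low_maf_allowed(self):
        panel = self.make_panel([0.975], mafs=[0.2, 0.2], palindromic={1})
        assert find_proxy("rs1", panel, {"rs2"}) == "rs2"

    def test_highest_r2_wins(self):
        panel = self.make_panel([np.sqrt(0.85), np.sqrt(0.92)])
        assert find_proxy("rs1", panel, {"rs2", "rs3"}) == "rs3"

    def test_below_threshold_returns_none(self):
        panel = self.make_panel([0.5])
        assert find_proxy("rs1", panel, {"rs2"}) is None

    def test_query_absent_from_panel(self):
        panel = self.make_panel([0.975])
        assert find_proxy("rs_missing", panel, {"rs2"}) is None

    def test_tie_breaks_by_distance_then_id(self):
        r = np.eye(4)
        for j in (1, 2, 3):
            r[0, j] = r[j, 0] = 0.95
        panel = small_panel(r)
        # rs2 is nearest to rs1 (positions are 50 kb apart in order)
        assert find_proxy("rs1", panel, {"rs2", "rs3", "rs4"}) == "rs2"
        assert find_proxy("rs1", panel, {"rs3", "rs4"}) == "rs3"


class TestSubstitution:
    def outcome_for(self, panel, snps):
        v = panel.variants.set_index("SNP").loc[list(snps)].reset_index()
        return pd.DataFrame({
            "SNP": v["SNP"], "CHR": v["CHR"], "POS": v["POS"],
            "EA": v["A1"], "OA": v["A2"], "EAF": v["MAF"],
            "BETA": [0.05] * len(v), "SE": 0.01, "P": 0.001,
        })

    def test_identity_when_all_present(self):
        panel = small_panel(np.eye(2))
        out = self.outcome_for(panel, ["rs1", "rs2"])
        subs = substitute_proxies(["rs1", "rs2"], out, panel)
        assert (subs["status"] == "present").all()

    def test_negative_r_flips_orientation(self):
        r = np.array([[1.0, -0.95], [-0.95, 1.0]])
        panel = small_panel(r)
        out = self.outcome_for(panel, ["rs2"])
        subs = substitute_proxies(["rs1"], out, panel)
        assert subs["status"].iloc[0] == "proxy" and subs["used"].iloc[0] == "rs2"
        eff = apply_proxies(subs, out, panel)
        # rs2's beta 0.05 on its A1 allele maps to -0.05 on rs1's A1 allele
        assert eff["SNP"].iloc[0] == "rs1"
        assert eff["BETA"].iloc[0] == pytest.approx(-0.05)
        assert eff["proxy_of"].iloc[0] == "rs2"

    def test_no_candidate_dropped(self):
        panel = small_panel(np.eye(2))
        out = self.outcome_for(panel, ["rs2"])
        subs = substitute_proxies(["rs1"], out, panel)
        assert subs["status"].iloc[0] == "dropped"

    def test_proxy_never_below_r2_min(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = 6
            A = rng.normal(size=(n, 3))
            cov = A @ A.T + np.eye(n) * 0.5
            d = np.sqrt(np.diag(cov))
            r = cov / np.outer(d, d)
            np.fill_diagonal(r, 1.0)
            panel = small_panel(r)
            avail = set(panel.variants["SNP"].iloc[1:])
            out = self.outcome_for(panel, sorted(avail))
            subs = substitute_proxies(["rs1"], out, panel)
            if subs["status"].iloc[0] == "proxy":
                assert subs["r2"].iloc[0] >= 0.8


class TestPanelValidation:
    def test_rejects_asymmetric_matrix(self):
        r = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            small_panel(r)

    def test_rejects_bad_diagonal(self):
        r = np.array([[0.9, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="diagonal"):
            small_panel(r)

    def test_save_load_round_trip(self, tmp_path):
        panel = small_panel(np.array([[1.0, 0.3], [0.3, 1.0]]), mafs=[0.1, 0.4])
        panel.save(tmp_path / "v.tsv", tmp_path / "r.tsv")
        again = LDPanel.load(tmp_path / "v.tsv", tmp_path / "r.tsv")
        pd.testing.assert_frame_equal(panel.variants, again.variants)
        np.testing.assert_allclose(panel.r, again.r, atol=1e-9)
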