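"""Variant selection, allele alignment, trait pruning and the pos/neg split."""

import numpy as np
import pandas as pd
import pytest

import insuclust as ic
from insuclust.zmatrix import AlignedZMatrix

from conftest import make_stats


class TestSelectVariants:
    def test_strict_threshold_and_filtering(self):
        stats = make_stats(
            [
                ("1:100", 1, 100, "A", "G", 0.5, 0.1, 1e-6, "FI"),
                ("1:200", 1, 200, "A", "G", 0.5, 0.1, 1e-4, "FI"),
                ("1:300", 1, 300, "A", "G", 0.5, 0.1, 1e-8, "FI"),
                ("1:400", 1, 400, "A", "G", 0.5, 0.1, 5e-5, "FI"),  # exactly at threshold
            ]
        )
        selected = ic.select_variants(stats, "FI")
        assert selected == ["1:100", "1:300"]  # 5e-5 itself excluded (strict <)

    def test_empty_table(self):
        stats = make_stats([("1:100", 1, 100, "A", "G", 0.5, 0.1, 0.5, "FI")])
        assert ic.select_variants(stats[stats.p_value < 0], "FI") == []
        # no FI hit below the threshold also yields an empty list
        stats_hi_p = make_stats([("1:100", 1, 100, "A", "G", 0.5, 0.1, 0.9, "FI")])
        assert ic.select_variants(stats_hi_p, "FI") == []

    def test_missing_fi_trait_names_available(self):
        stats = make_stats([("1:100", 1, 100, "A", "G", 0.5, 0.1, 1e-6, "HDL")])
        with pytest.raises(ValueError, match="HDL"):
            ic.select_variants(stats, "FI")

    def test_union_mode_merges_discovery_traits(self):
        stats = make_stats(
            [
                ("1:100", 1, 100, "A", "G", 0.5, 0.1, 1e-6, "FI"),
                ("1:200", 1, 200, "A", "G", 0.5, 0.1, 0.2, "FI"),
                ("1:200", 1, 200, "A", "G", 0.5, 0.1, 1e-7, "FIadjBMI"),
            ]
        )
        assert ic.select_variants(stats, "FI") == ["1:100"]
        assert ic.select_variants(stats, "FI", union_traits=["FIadjBMI"]) == ["1:100", "1:200"]

    def test_ordering_by_position(self):
        stats = make_stats(
            [
                ("2:50", 2, 50, "A", "G", 0.5, 0.1, 1e-6, "FI"),
                ("1:900", 1, 900, "A", "G", 0.5, 0.1, 1e-6, "FI"),
                ("1:100", 1, 100, "A", "G", 0.5, 0.1, 1e-6, "FI"),
            ]
        )
        assert ic.select_variants(stats, "FI") == ["1:100", "1:900", "2:50"]


class TestAlignment:
    def test_no_flip_flip_and_negative_fi(self):
        stats = make_stats(
            [
                ("1:100", 1, 100, "A", "G", 0.5, 0.1, 1e-7, "FI"),
                ("1:100", 1, 100, "A", "G", 0.2, 0.1, 0.05, "HDL"),  # same effect allele
                ("1:200", 1, 200, "A", "G", 0.4, 0.1, 1e-7, "FI"),
                ("1:200", 1, 200, "G", "A", 0.2, 0.1, 0.05, "HDL"),  # swapped alleles
                ("1:300", 1, 300, "A", "G", -0.3, 0.1, 1e-7, "FI"),  # FI allele is G
            ]
        )
        zmat = ic.align_to_risk_allele(stats, ["1:100", "1:200", "1:300"], "FI")
        assert zmat.Z.loc["1:100", "HDL"] == pytest.approx(2.0)
        assert zmat.Z.loc["1:200", "HDL"] == pytest.approx(-2.0)
        # flip-to-positive: beta=-0.3 for A means G is FI-increasing, Z=+3
        assert zmat.variants.loc["1:300", "fi_increasing_allele"] == "G"
        assert zmat.Z.loc["1:300", "FI"] == pytest.approx(3.0)
        assert (zmat.Z["FI"] >= 0).all()

    def test_strand_complement_accepted_when_unambiguous(self):
        stats = make_stats(
            [
                ("1:100", 1, 100, "A", "G", 0.5, 0.1, 1e-7, "FI"),
                ("1:100", 1, 100, "T", "C", 0.2, 0.1, 0.05, "HDL"),  # other strand
            ]
        )
        zmat = ic.align_to_risk_allele(stats, ["1:100"], "FI")
        assert zmat.Z.loc["1:100", "HDL"] == pytest.approx(2.0)

    def test_irreconcilable_alleles_error_lists_variant(self):
        stats = make_stats(
            [
                ("1:100", 1, 100, "A", "G", 0.5, 0.1, 1e-7, "FI"),
                ("1:100", 1, 100, "A", "C", 0.2, 0.1, 0.05, "HDL"),
            ]
        )
        with pytest.raises(ValueError, match="1:100"):
            ic.align_to_risk_allele(stats, ["1:100"], "FI")

    def test_missing_trait_record_marked_missing(self):
        stats = make_stats(
            [
                ("1:100", 1, 100, "A", "G", 0.5, 0.1, 1e-7, "FI"),
                ("1:200", 1, 200, "A", "G", 0.5, 0.1, 1e-7, "FI"),
                ("1:100", 1, 100, "A", "G", 0.2, 0.1, 0.05, "HDL"),
            ]
        )
        zmat = ic.align_to_risk_allele(stats, ["1:100", "1:200"], "FI")
        assert zmat.missing_mask.loc["1:200", "HDL"]
        assert not zmat.missing_mask.loc["1:100", "HDL"]

    def test_alignment_idempotence(self, sumstats_a):
        """Re-aligning an already-aligned table changes nothing."""
        _, stats, _ = sumstats_a
        variants = ic.select_variants(stats, "FI")[:25]
        zmat = ic.align_to_risk_allele(stats, variants, "FI")
        # rebuild a stats table whose effect alleles are the FI-increasing ones
        realigned = stats[stats.variant_id.isin(variants)].copy()
        fi_allele = zmat.variants["fi_increasing_allele"]
        flip = realigned.variant_id.map(fi_allele) != realigned.effect_allele
        realigned.loc[flip, ["effect_allele", "other_allele"]] = realigned.loc[
            flip, ["other_allele", "effect_allele"]
        ].to_numpy()
        realigned.loc[flip, "beta"] *= -1
        zmat2 = ic.align_to_risk_allele(realigned, variants, "FI")
        pd.testing.assert_frame_equal(zmat.Z, zmat2.Z)


class TestPruneTraits:
    def _zmat(self, Z, fi="FI"):
        variants = pd.DataFrame(
            {"chromosome": 1, "position": range(len(Z)), "fi_increasing_allele": "A"},
            index=Z.index,
        )
        return AlignedZMatrix(variants=variants, Z=Z, fi_trait=fi)

    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=50)
        Z = pd.DataFrame(
            {"FI": np.abs(base), "A": rng.normal(size=50), "A_copy": None},
            index=[f"v{i}" for i in range(50)],
        )
        Z["A_copy"] = Z["A"]
        out = ic.prune_traits(self._zmat(Z))
        assert out.traits == ["FI", "A"]

    def test_greedy_pass_keeps_first_of_correlated_pair(self):
        # construct A, B, C with r(A,B) ~ 0.9, r(A,C) and r(B,C) low
        rng = np.random.default_rng(1)
        a = rng.normal(size=400)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=400)
        c = rng.normal(size=400)
        fi = np.abs(rng.normal(size=400))
        Z = pd.DataFrame({"FI": fi, "A": a, "B": b, "C": c}, index=[f"v{i}" for i in range(400)])
        out = ic.prune_traits(self._zmat(Z), r_threshold=0.85)
        assert out.traits == ["FI", "A", "C"]

    def test_vacuous_threshold_retains_all(self):
        rng = np.random.default_rng(2)
        Z = pd.DataFrame(
            rng.normal(size=(30, 4)), columns=["FI", "A", "B", "C"], index=[f"v{i}" for i in range(30)]
        )
        Z["FI"] = Z["FI"].abs()
        Z["B"] = Z["A"]
        out = ic.prune_traits(self._zmat(Z), r_threshold=1.01)
        assert out.traits == ["FI", "A", "B", "C"]

    def test_zero_variance_column_retained_with_warning(self):
        rng = np.random.default_rng(3)
        Z = pd.DataFrame(
            {"FI": np.abs(rng.normal(size=30)), "flat": 1.0, "A": rng.normal(size=30)},
            index=[f"v{i}" for i in range(30)],
        )
        with pytest.warns(UserWarning, match="zero variance"):
            out = ic.prune_traits(self._zmat(Z))
        assert "flat" in out.traits

    def test_invariant_to_appending_copy_of_retained_trait(self):
        rng = np.random.default_rng(4)
        Z = pd.DataFrame(
            {"FI": np.abs(rng.normal(size=60)), "A": rng.normal(size=60), "B": rng.normal(size=60)},
            index=[f"v{i}" for i in range(60)],
        )
        base = ic.prune_traits(self._zmat(Z)).traits
        Z2 = Z.copy()
        Z2["A_dup"] = Z["A"]
        extended = ic.prune_traits(self._zmat(Z2)).traits
        assert extended == base


class TestNonNegMatrix:
    def _zmat(self, Z):
        variants = pd.DataFrame(
            {"chromosome": 1, "position": range(len(Z)), "fi_increasing_allele": "A"},
            index=Z.index,
        )
        return AlignedZMatrix(variants=variants, Z=Z, fi_trait="FI")

    def test_split_definition_and_reconstruction(self):
        Z = pd.DataFrame(
            {"FI": [1.0, 2.0], "T1": [-2.5, 0.5], "T2": [np.nan, -1.0]}, index=["v1", "v2"]
        )
        nn = ic.build_nonnegative_matrix(self._zmat(Z))
        assert nn.X.loc["v1", "T1_pos"] == 0.0
        assert nn.X.loc["v1", "T1_neg"] == 2.5
        assert (nn.X >= 0).to_numpy().all()
        # missing -> 0 in both halves
        assert nn.X.loc["v1", "T2_pos"] == 0.0 and nn.X.loc["v1", "T2_neg"] == 0.0
        # at most one side nonzero, and pos - neg reconstructs Z where observed
        for t in ["FI", "T1", "T2"]:
            prod = nn.X[f"{t}_pos"] * nn.X[f"{t}_neg"]
            assert (prod == 0).all()
            recon = nn.X[f"{t}_pos"] - nn.X[f"{t}_neg"]
            obs = Z[t].notna()
            assert np.allclose(recon[obs], Z[t][obs])

    def test_optional_column_scaling(self):
        rng = np.random.default_rng(6)
        Z = pd.DataFrame(
            {"FI": np.abs(rng.normal(size=20)) * 4, "T1": rng.normal(size=20) * 0.5},
            index=[f"v{i}" for i in range(20)],
        )
        scaled = ic.build_nonnegative_matrix(self._zmat(Z), scale_columns=True)
        recon = scaled.X["T1_pos"] - scaled.X["T1_neg"]
        assert np.isclose(recon.std(ddof=0), 1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        Z = pd.DataFrame(
            rng.normal(size=(10, 3)), columns=["FI", "T1", "T2"], index=[f"v{i}" for i in range(10)]
        )
        nn = ic.build_nonnegative_matrix(self._zmat(Z))
        nn_neg = ic.build_nonnegative_matrix(self._zmat(-Z))
        for t in ["FI", "T1", "T2"]:
            assert np.allclose(nn.X[f"{t}_pos"], nn_neg.X[f"{t}_neg"])
            assert np.allclose(nn.X[f"{t}_neg"], nn_neg.X[f"{t}_pos"])
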