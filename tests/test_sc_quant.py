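"""Species assignment, QC filtering, module scoring, shifts, volcano."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from glioquant import sc_quant as scq
from glioquant.cell_cycle_genes import G2M_GENES, S_GENES
from glioquant.synth_sc import ScDesign, generate_cycle_cohort


def toy_matrix(rows, var):
    """AnnData from a dense count array and a var DataFrame."""
    X = sparse.csr_matrix(np.asarray(rows, dtype=np.int32))
    return ad.AnnData(X=X, var=var.copy(),
                      obs=pd.DataFrame(index=[f"c{i}"
                                              for i in range(X.shape[0])]))


SPECIES_VAR = pd.DataFrame(
    {"species": ["human", "human", "mouse", "mouse"],
     "mito": [False] * 4},
    index=["H1", "H2", "M1", "M2"])


class TestSpeciesAssign:
    def test_clear_majorities_and_ambiguous(self):
        adata = toy_matrix([[98, 0, 2, 0],      # 98% human
                            [0, 2, 49, 49],     # 98% mouse
                            [55, 0, 45, 0]],    # ambiguous at 90% default
                           SPECIES_VAR)
        out = scq.species_assign(adata)
        assert out["species"].tolist() == ["human", "mouse", "ambiguous"]
        assert out["pct_human"].iloc[0] == pytest.approx(98.0)
        assert np.allclose(out["pct_human"] + out["pct_mouse"], 100.0)

    def test_no_species_tags_rejected(self):
        var = pd.DataFrame({"mito": [False, False]}, index=["a", "b"])
        with pytest.raises(ValueError, match="species"):
            scq.species_assign(toy_matrix([[1, 2]], var))

    def test_recovery_on_barnyard(self, barnyard_2000):
        out = scq.species_assign(barnyard_2000)
        acc = np.mean(out["species"].to_numpy()
                      == barnyard_2000.obs["species_true"].to_numpy())
        assert acc >= 0.99

    def test_refined_assignment_also_recovers(self, barnyard_2000):
        out = scq.species_assign(barnyard_2000, refine=True)
        acc = np.mean(out["species"].to_numpy()
                      == barnyard_2000.obs["species_true"].to_numpy())
        assert acc >= 0.99


MITO_VAR = pd.DataFrame(
    {"species": ["human"] * 8,
     "mito": [True] + [False] * 7},
    index=["MT-X"] + [f"G{i}" for i in range(7)])


def cell_with(n_genes, mito_pct, total=1000):
    """A synthetic count row with a given detected-gene count / mito %."""
    row = np.zeros(8, dtype=int)
    mito = int(round(total * mito_pct / 100))
    row[0] = mito
    rest = total - mito
    per = max(rest // max(n_genes - (mito > 0), 1), 1)
    k = n_genes - (1 if mito > 0 else 0)
    row[1:1 + k] = per
    return row


class TestQcFilter:
    def test_rule_on_toy_table(self):
        # five cells: (genes, mito%) = (150,1) (200,5) (3000,12) (6000,9)
        # (6500,2); exactly the middle two pass the 200/6000/10% rule
        rng = np.random.default_rng(0)
        n_genes_panel = 7000
        var = pd.DataFrame({
            "species": "human",
            "mito": [True] + [False] * (n_genes_panel - 1),
        }, index=["MT-X"] + [f"G{i}" for i in range(n_genes_panel - 1)])
        specs = [(150, 1.0), (200, 5.0), (3000, 12.0), (6000, 9.0),
                 (6500, 2.0)]
        rows = np.zeros((5, n_genes_panel), dtype=int)
        for i, (g, m) in enumerate(specs):
            total = 20000
            mito_counts = int(round(total * m / 100))
            rows[i, 0] = mito_counts
            body = np.zeros(n_genes_panel - 1, dtype=int)
            body[:g - 1] = (total - mito_counts) // (g - 1)
            body[0] += (total - mito_counts) - body[:g - 1].sum()
            rows[i, 1:] = body
        adata = ad.AnnData(X=sparse.csr_matrix(rows), var=var)
        keep = scq.qc_filter(adata)
        assert keep.sum() == 2
        assert keep.to_numpy().tolist() == [False, True, False, True, False]

    def test_empty_matrix(self):
        adata = ad.AnnData(X=sparse.csr_matrix((0, 8)), var=MITO_VAR.copy())
        assert scq.qc_filter(adata).sum() == 0

    def test_boundary_cells_retained(self):
        rows = [cell_with(5, 10.0), cell_with(5, 10.0)]
        adata = toy_matrix(rows, MITO_VAR)
        keep = scq.qc_filter(adata, min_genes=5, max_genes=5)
        assert keep.all()

    def test_idempotent_and_order_invariant(self, cohort_3000):
        adata = cohort_3000.copy()
        keep1 = scq.qc_filter(adata)
        sub = adata[keep1.to_numpy()].copy()
        assert scq.qc_filter(sub).all()          # idempotent
        perm = np.random.default_rng(0).permutation(adata.n_obs)
        keep2 = scq.qc_filter(adata[perm].copy())
        assert np.array_equal(keep1.to_numpy()[perm], keep2.to_numpy())


class TestModuleScore:
    def test_null_program_scores_near_zero(self):
        ad_null = generate_cycle_cohort(ScDesign(n_cells=600, fold_effect=1.0,
                                                 seed=19))
        s = scq.module_score(ad_null, S_GENES, seed=0)
        se = s.std() / np.sqrt(len(s))
        assert abs(s.mean()) < 4 * max(se, 1e-3) + 0.02

    def test_planted_s_cells_score_higher(self, cohort_3000):
        from scipy.stats import mannwhitneyu
        s = scq.module_score(cohort_3000, S_GENES, seed=0)
        truth = cohort_3000.obs["phase_true"].to_numpy()
        stat = mannwhitneyu(s[truth == "S"], s[truth == "G1"],
                            alternative="greater")
        assert stat.pvalue < 1e-6

    def test_invariant_to_constant_log_shift(self, cohort_3000):
        log_expr = scq.normalize_log1p(cohort_3000)
        s1 = scq.module_score(cohort_3000, S_GENES, seed=0,
                              log_expr=log_expr)
        s2 = scq.module_score(cohort_3000, S_GENES, seed=0,
                              log_expr=log_expr + 3.7)
        assert np.allclose(s1, s2, atol=1e-9)

    def test_missing_genes_warn_absent_program_errors(self, cohort_3000):
        with pytest.warns(UserWarning, match="absent"):
            scq.module_score(cohort_3000, S_GENES + ["NOT_A_GENE"], seed=0)
        with pytest.raises(ValueError):
            scq.module_score(cohort_3000, [], seed=0)
        with pytest.raises(ValueError, match="no program genes"):
            scq.module_score(cohort_3000, ["NOPE1", "NOPE2"], seed=0)

    def test_deterministic_given_seed(self, cohort_3000):
        a = scq.module_score(cohort_3000, G2M_GENES, seed=5)
        b = scq.module_score(cohort_3000, G2M_GENES, seed=5)
        assert np.array_equal(a, b)

    def test_correlates_with_scanpy_reference(self, cohort_3000):
        scanpy = pytest.importorskip("scanpy")
        mine = scq.module_score(cohort_3000, S_GENES, seed=0)
        ref = cohort_3000.copy()
        scanpy.pp.normalize_total(ref, target_sum=1e4)
        scanpy.pp.log1p(ref)
        scanpy.tl.score_genes(ref, S_GENES, score_name="ref_s", random_state=0)
        rho = np.corrcoef(mine, ref.obs["ref_s"])[0, 1]
        assert rho > 0.9


class TestAssignPhase:
    @pytest.mark.parametrize("s,g2m,expected", [
        (0.3, -0.1, "S"),
        (-0.2, -0.3, "G1"),
        (0.1, 0.4, "G2M"),
        (0.2, 0.2, "S"),       # tie goes to S
        (0.0, 0.0, "G1"),      # both non-positive
    ])
    def test_binning_rule(self, s, g2m, expected):
        assert scq.assign_phase(s, g2m)[0] == expected

    def test_recovery_at_fold_effect_4(self, cohort_3000):
        sc = scq.score_cell_cycle(cohort_3000.copy(), seed=0)
        acc = np.mean(sc["phase"].to_numpy()
                      == cohort_3000.obs["phase_true"].to_numpy())
        assert acc >= 0.90


class TestProportionShift:
    def test_identical_arms_zero_delta(self):
        df = pd.DataFrame({"arm": ["a"] * 10 + ["b"] * 10,
                           "phase": ["G1", "S"] * 10})
        shift = scq.proportion_shift(df, "phase", arms=("a", "b"))
        assert np.allclose(shift["delta_pct"], 0.0)

    def test_constructed_deltas(self):
        a = ["G1"] * 50 + ["S"] * 30 + ["G2M"] * 20
        b = ["G1"] * 70 + ["S"] * 20 + ["G2M"] * 10
        df = pd.DataFrame({"arm": ["a"] * 100 + ["b"] * 100, "phase": a + b})
        shift = scq.proportion_shift(df, "phase", arms=("a", "b")) \
            .set_index("phase")
        assert shift.loc["G1", "delta_pct"] == pytest.approx(20.0)
        assert shift.loc["S", "delta_pct"] == pytest.approx(-10.0)
        assert shift.loc["G2M", "delta_pct"] == pytest.approx(-10.0)
        assert shift["pct_a"].sum() == pytest.approx(100.0)
        assert shift["pct_b"].sum() == pytest.approx(100.0)

    def test_missing_arm_rejected(self):
        df = pd.DataFrame({"arm": ["a"] * 4, "phase": ["G1"] * 4})
        with pytest.raises(ValueError):
            scq.proportion_shift(df, "phase", arms=("a", "b"))

    def test_estimator_unbiased_over_replicates(self):
        # planted +15-point G1 shift; mean estimated delta over 200
        # multinomial replicates within 0.5 points of truth
        rng = np.random.default_rng(6)
        p1, p2 = [0.55, 0.25, 0.20], [0.70, 0.17, 0.13]
        deltas = []
        for _ in range(200):
            n = 800
            a = rng.choice(["G1", "S", "G2M"], size=n, p=p1)
            b = rng.choice(["G1", "S", "G2M"], size=n, p=p2)
            df = pd.DataFrame({"arm": ["a"] * n + ["b"] * n,
                               "phase": np.concatenate([a, b])})
            s = scq.proportion_shift(df, "phase", arms=("a", "b")) \
                .set_index("phase")
            deltas.append(s.loc["G1", "delta_pct"])
        assert abs(np.mean(deltas) - 15.0) < 0.5


class TestVolcano:
    @pytest.mark.parametrize("fc,p,expected", [
        (0.5, 1e-12, "up"),
        (0.23, 1e-12, "ns"),       # strict inequality at the threshold
        (-0.4, 1e-3, "ns"),
        (-0.4, 1e-12, "down"),
        (0.0, 1e-12, "ns"),
    ])
    def test_classification_rule(self, fc, p, expected):
        rec = pd.DataFrame({"gene": ["g"], "log2fc": [fc],
                            "p_bonferroni": [p]})
        assert scq.volcano_classify(rec)["category"].iloc[0] == expected

    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0, 1)),
                    min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_categories_partition_records(self, rows):
        rec = pd.DataFrame(rows, columns=["log2fc", "p_bonferroni"])
        out = scq.volcano_classify(rec)
        counts = out["category"].value_counts()
        assert counts.sum() == len(rec)
        assert set(counts.index) <= {"up", "down", "ns"}

    def test_bonferroni_helper(self):
        p = scq.bonferroni([1e-4, 0.5, 1e-2], m=100)
        assert np.allclose(p, [1e-2, 1.0, 1.0])

    def test_rank_sum_de_output_valid(self):
        adx = generate_cycle_cohort(ScDesign(n_cells=150, seed=13))
        de = scq.rank_sum_de(adx)
        assert len(de) == adx.n_vars
        assert ((de["p_bonferroni"] >= 0) & (de["p_bonferroni"] <= 1)).all()
        assert np.isfinite(de["log2fc"]).all()
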