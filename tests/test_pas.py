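"""CNR / BTIF / PAS engine: arithmetic examples, hand oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from paskit.errors import DesignError, ParameterError
from paskit.pas import compute_btif, compute_cnr, compute_pas, score_pathways
from paskit.pathway_db import GeneRole, PathwayCollection, PathwayDef
from paskit.simulate import TruthEntry, TruthSpec, make_design, simulate_counts


def _design(n_ref, n_case):
    rows = [(f"r{i}", "sham", 0.0, i, 1) for i in range(n_ref)]
    rows += [(f"c{i}", "ALPPS", 4.0, i, 0) for i in range(n_case)]
    return pd.DataFrame(
        rows, columns=["sample_id", "procedure", "timepoint_h", "replicate", "is_reference"]
    ).set_index("sample_id")


def _matrix(values, genes, design):
    return pd.DataFrame(np.asarray(values, dtype=float),
                        index=pd.Index(genes, name="gene_id"), columns=design.index)


class TestCNR:
    def test_ratio_against_reference_mean(self):
        design = _design(2, 1)
        m = _matrix([[10, 10, 15]], ["g1"], design)
        cnr = compute_cnr(m, design, pseudocount=0.0)
        assert cnr.loc["g1", "c0"] == pytest.approx(1.5)

    def test_sample_equal_to_reference_mean_gives_one(self):
        design = _design(2, 1)
        m = _matrix([[8, 12, 10]], ["g1"], design)
        cnr = compute_cnr(m, design, pseudocount=0.0)
        assert cnr.loc["g1", "c0"] == pytest.approx(1.0)
        assert np.log10(cnr.loc["g1", "c0"]) == 0.0

    def test_all_zero_gene_with_pseudocount_gives_exactly_one(self):
        design = _design(2, 2)
        m = _matrix([[0, 0, 0, 0]], ["g1"], design)
        cnr = compute_cnr(m, design, pseudocount=1.0)
        assert (cnr.loc["g1"] == 1.0).all()

    def test_reference_samples_scored_leave_self_in(self):
        design = _design(2, 1)
        m = _matrix([[10, 20, 30]], ["g1"], design)
        cnr = compute_cnr(m, design, pseudocount=0.0)
        assert cnr.loc["g1", "r0"] == pytest.approx(10 / 15)
        assert cnr.loc["g1", "r1"] == pytest.approx(20 / 15)

    def test_single_reference_sample_is_design_error(self):
        design = _design(1, 2)
        m = _matrix([[1, 2, 3]], ["g1"], design)
        with pytest.raises(DesignError):
            compute_cnr(m, design)


class TestBTIF:
    def test_cnr_inside_fold_band_never_flags(self):
        design = _design(3, 1)
        m = _matrix([[100, 100, 100, 120]], ["g1"], design)  # CNR = 1.2
        cnr = compute_cnr(m, design, pseudocount=0.0)
        btif = compute_btif(m, cnr, design, pseudocount=0.0)
        assert btif.loc["g1", "c0"] == 0

    def test_large_shift_with_tight_reference_flags(self):
        # reference log2 sd floored at 0.1; case 8 floored-sd above the mean
        design = _design(3, 1)
        ref = 100.0
        case = ref * 2 ** (8 * 0.1)  # z = 8 after the floor, CNR ≈ 1.74 ≥ 1.5
        m = _matrix([[ref, ref, ref, case]], ["g1"], design)
        cnr = compute_cnr(m, design, pseudocount=0.0)
        btif = compute_btif(m, cnr, design, pseudocount=0.0)
        z = 8.0
        assert 2 * sps.norm.sf(z) < 0.05  # hand oracle for the p criterion
        assert btif.loc["g1", "c0"] == 1

    def test_high_variance_gene_with_large_cnr_does_not_flag(self):
        # CNR = 2 but the reference spread is huge: z < 1 → p > 0.05
        design = _design(3, 1)
        m = _matrix([[10, 100, 1000, 740]], ["g1"], design)
        cnr = compute_cnr(m, design, pseudocount=0.0)
        assert cnr.loc["g1", "c0"] == pytest.approx(2.0)
        log2v = np.log2([10, 100, 1000])
        z = (np.log2(740) - log2v.mean()) / log2v.std(ddof=1)
        assert 2 * sps.norm.sf(abs(z)) > 0.05  # hand oracle
        btif = compute_btif(m, cnr, design, pseudocount=0.0)
        assert btif.loc["g1", "c0"] == 0

    def test_fold_thresholds_inclusive(self):
        design = _design(3, 2)
        # both cases exactly at the band edges with tiny reference spread
        m = _matrix([[100, 100, 100, 150, 66]], ["g1"], design)
        cnr = compute_cnr(m, design, pseudocount=0.0)
        btif = compute_btif(m, cnr, design, pseudocount=0.0)
        assert cnr.loc["g1", "c0"] == pytest.approx(1.5)
        assert btif.loc["g1", "c0"] == 1
        assert btif.loc["g1", "c1"] == 1

    def test_alpha_outside_unit_interval_rejected(self, toy_counts, toy_design):
        cnr = compute_cnr(toy_counts, toy_design)
        with pytest.raises(ParameterError):
            compute_btif(toy_counts, cnr, toy_design, alpha=1.5)


def _pas_inputs(genes, samples, cnr_values, btif_values):
    cnr = pd.DataFrame(cnr_values, index=pd.Index(genes, name="gene_id"), columns=samples)
    btif = pd.DataFrame(btif_values, index=cnr.index, columns=samples)
    return cnr, btif


class TestPAS:
    def test_single_activator_log10(self):
        db = PathwayCollection([PathwayDef("P", "main", (GeneRole("gA", 1.0),))])
        cnr, btif = _pas_inputs(["gA"], ["s"], [[100.0]], [[1]])
        pas = compute_pas(cnr, btif, db)
        assert pas.loc["P", "s"] == pytest.approx(2.0)

    def test_activator_repressor_symmetry_cancels(self):
        db = PathwayCollection(
            [PathwayDef("P", "main", (GeneRole("gA", 1.0), GeneRole("gB", -1.0)))]
        )
        cnr, btif = _pas_inputs(["gA", "gB"], ["s"], [[10.0], [10.0]], [[1], [1]])
        assert compute_pas(cnr, btif, db).loc["P", "s"] == pytest.approx(0.0)

    def test_missing_pathway_is_nan_sentinel_not_zero(self, tiny_db):
        cnr, btif = _pas_inputs(["gA", "gB", "gC"], ["s"],
                                [[2.0], [2.0], [2.0]], [[1], [1], [1]])
        pas = compute_pas(cnr, btif, tiny_db)
        assert np.isnan(pas.loc["Stress", "s"])  # no Stress gene present
        assert not np.isnan(pas.loc["Growth (proliferation)", "s"])

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            genes = [f"g{i}" for i in range(rng.integers(3, 11))]
            samples = [f"s{j}" for j in range(rng.integers(1, 5))]
            pathways = []
            for p in range(3):
                members = rng.choice(genes, size=rng.integers(1, len(genes) + 1),
                                     replace=False)
                arrs = rng.choice([-1.0, -0.5, 0.0, 0.5, 1.0], size=len(members))
                pathways.append(
                    PathwayDef(f"P{p}", "main",
                               tuple(GeneRole(g, a) for g, a in zip(members, arrs)))
                )
            db = PathwayCollection(pathways)
            cnr, btif = _pas_inputs(
                genes, samples,
                rng.uniform(0.1, 10, size=(len(genes), len(samples))),
                rng.integers(0, 2, size=(len(genes), len(samples))),
            )
            pas = compute_pas(cnr, btif, db)
            for pw in db:
                for s in samples:
                    expected = sum(
                        r.arr * btif.loc[r.gene, s] * np.log10(cnr.loc[r.gene, s])
                        for r in pw.roles
                    )
                    assert pas.loc[pw.name, s] == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self, tiny_db):
        cnr, btif = _pas_inputs(["gA"], ["s"], [[1.0]], [[1]])
        with pytest.raises(ParameterError):
            compute_pas(cnr, btif.iloc[:, :0], tiny_db)


class TestInvariants:
    def _random_case(self, seed):
        design = _design(3, 4)
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        m = _matrix(rng.integers(10, 1000, size=(30, 7)), genes, design)
        pathways = []
        for p in range(5):
            members = rng.choice(genes, size=6, replace=False)
            arrs = rng.choice([-1.0, -0.5, 0.5, 1.0], size=6)
            pathways.append(
                PathwayDef(f"P{p}", "main",
                           tuple(GeneRole(g, a) for g, a in zip(members, arrs)))
            )
        return m, design, PathwayCollection(pathways)

    def test_all_btif_zero_forces_pas_zero(self, tiny_db):
        design = _design(2, 2)
        genes = sorted(tiny_db.universe)
        cnr = pd.DataFrame(2.0, index=pd.Index(genes, name="gene_id"),
                           columns=design.index)
        btif = pd.DataFrame(0, index=cnr.index, columns=cnr.columns)
        pas = compute_pas(cnr, btif, tiny_db)
        assert (pas.to_numpy() == 0.0).all()

    def test_negating_all_arr_negates_pas_exactly(self):
        m, design, db = self._random_case(11)
        flipped = PathwayCollection(
            [
                PathwayDef(pw.main_pathway, pw.branch,
                           tuple(GeneRole(r.gene, -r.arr) for r in pw.roles))
                for pw in db
            ]
        )
        res = score_pathways(m, design, db)
        res_neg = score_pathways(m, design, flipped)
        np.testing.assert_array_equal(res.pas.to_numpy(), -res_neg.pas.to_numpy())

    def test_additive_over_disjoint_pathway_partition(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(12)]
        arrs = rng.choice([-1.0, -0.5, 0.5, 1.0], size=12)
        union = PathwayDef("U", "main",
                           tuple(GeneRole(g, a) for g, a in zip(genes, arrs)))
        part_a = PathwayDef("A", "main", union.roles[:5])
        part_b = PathwayDef("B", "main", union.roles[5:])
        db = PathwayCollection([union, part_a, part_b])
        cnr, btif = _pas_inputs(
            genes, ["s1", "s2"],
            rng.uniform(0.2, 5, size=(12, 2)),
            rng.integers(0, 2, size=(12, 2)),
        )
        pas = compute_pas(cnr, btif, db)
        np.testing.assert_allclose(
            pas.loc["U"], pas.loc["A"] + pas.loc["B"], rtol=1e-12
        )

    def test_global_rescaling_invariance_at_zero_pseudocount(self):
        m, design, db = self._random_case(23)
        base = score_pathways(m, design, db, normalization="none", pseudocount=0.0)
        scaled = score_pathways(m * 7.5, design, db, normalization="none",
                                pseudocount=0.0)
        np.testing.assert_allclose(base.cnr, scaled.cnr, rtol=1e-12)
        np.testing.assert_array_equal(base.btif, scaled.btif)
        np.testing.assert_allclose(base.pas, scaled.pas, rtol=1e-12)

    def test_planted_activation_gives_positive_pas_in_affected_samples(self):
        from paskit.simulate import generate_pathway_db

        db = generate_pathway_db(n_pathways=30, size_range=(8, 20), seed=3)
        design = make_design(procedures=("ALPPS",), timepoints=(4.0,), n_replicates=3)
        target = db.names[4]
        truth = TruthSpec(
            entries=(TruthEntry("ALPPS", 4.0, target, "activated", 2.0),)
        )
        counts = simulate_counts(db, truth, design, seed=9)
        res = score_pathways(counts, design, db)
        affected = [s for s in design.index if s.startswith("ALPPS")]
        assert (res.pas.loc[target, affected] > 0).all()
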