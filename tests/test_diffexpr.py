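"""Differential-expression engine: size factors, Wald test, BH FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest

import reprogramome as rp
from reprogramome.diffexpr import Contrast, bh_adjust, import_de_table

from conftest import make_counts


def brute_force_size_factors(mat: pd.DataFrame) -> np.ndarray:
    """Literal median-of-ratios: loop over samples and reference genes."""
    ref_genes = [g for g in mat.index if (mat.loc[g] > 0).all()]
    out = []
    for s in mat.columns:
        ratios = []
        for g in ref_genes:
            geo = np.exp(np.mean([np.log(mat.loc[g, c]) for c in mat.columns]))
            ratios.append(mat.loc[g, s] / geo)
        out.append(np.median(ratios))
    return np.array(out)


def brute_force_bh(p: list[float]) -> list[float]:
    """Step-up BH from the definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = [min(p[order[j]] * m / (j + 1) for j in range(i, m)) for i in range(m)]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return list(q)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        mat = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5], "s3": [10, 20, 5]})
        np.testing.assert_allclose(rp.size_factors(mat).to_numpy(), 1.0)

    def test_doubled_column_doubles_factor(self):
        mat = pd.DataFrame({"s1": [10, 20, 5], "s2": [20, 40, 10]})
        sf = rp.size_factors(mat)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        mat = pd.DataFrame(
            rng.poisson(50, size=(5, 3)) + 1,
            index=[f"G{i}" for i in range(5)],
            columns=["s1", "s2", "s3"],
        )
        np.testing.assert_allclose(
            rp.size_factors(mat).to_numpy(), brute_force_size_factors(mat)
        )

    def test_no_universal_gene_is_an_error(self):
        mat = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            rp.size_factors(mat)

    def test_normalization_reproduces_counts(self, toy_counts):
        norm = rp.normalize(toy_counts)
        recon = norm.values * norm.size_factors
        np.testing.assert_allclose(recon.to_numpy(), toy_counts.counts.to_numpy())


class TestBenjaminiHochberg:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equals_brute_force_on_short_vectors(self):
        """Exhaustive check against the step-up definition for all p-vectors
        of length <= 6 drawn from a fixed grid."""
        grid = [0.001, 0.01, 0.04, 0.05, 0.2, 0.5, 0.8, 1.0]
        for m in range(1, 7):
            for combo in itertools.combinations_with_replacement(grid, m):
                p = list(combo)
                np.testing.assert_allclose(
                    bh_adjust(p), brute_force_bh(p), err_msg=f"p={p}"
                )

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.02])

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestWaldContrast:
    def test_identical_counts_no_signal(self):
        cm = make_counts(
            {"a1": [7, 100], "a2": [9, 100], "b1": [7, 100], "b2": [9, 100]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        de = rp.test_contrast(rp.normalize(cm), Contrast("A", "B"))
        assert abs(de.table.loc["G1", "log2fc"]) < 1e-9
        assert de.table.loc["G1", "p"] == pytest.approx(1.0)

    def test_swapping_groups_negates_log2fc_and_keeps_p(self, toy_counts):
        norm = rp.normalize(toy_counts)
        ab = rp.test_contrast(norm, Contrast("A", "B"))
        ba = rp.test_contrast(norm, Contrast("B", "A"))
        np.testing.assert_allclose(
            ab.table["log2fc"].to_numpy(), -ba.table["log2fc"].to_numpy()
        )
        np.testing.assert_allclose(ab.table["p"].to_numpy(), ba.table["p"].to_numpy())

    def test_single_replicate_rejected(self):
        cm = make_counts(
            {"a1": [5], "b1": [5], "b2": [6]}, {"a1": "A", "b1": "B", "b2": "B"}
        )
        with pytest.raises(ValueError, match="replicates"):
            rp.test_contrast(rp.normalize(cm), Contrast("A", "B"))

    def test_silent_genes_get_nan(self):
        cm = make_counts(
            {"a1": [0, 10], "a2": [0, 12], "b1": [0, 11], "b2": [0, 9]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        de = rp.test_contrast(rp.normalize(cm), Contrast("A", "B"))
        assert np.isnan(de.table.loc["G0", "p"])
        assert np.isnan(de.table.loc["G0", "q"])

    def test_null_type_one_error_calibrated(self):
        """Empirical type-I error of the NB Wald test within the 95%
        binomial CI of the nominal 0.05 on a seeded 4000-gene null."""
        n_genes, alpha = 4000, 0.05
        cm = rp.simulate_null(n_genes, n_per_group=4, mu=200.0, seed=42)
        de = rp.test_contrast(rp.normalize(cm), Contrast("A", "B"))
        rate = (de.table["p"] < alpha).mean()
        half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_genes)
        assert alpha - half <= rate <= alpha + half

    def test_power_monotone_in_fold_change(self):
        """Detection power on planted DE genes grows with the fold at fixed
        n. DE genes sit in a mostly-null background so the median-of-ratios
        normalization assumption holds."""
        rng = np.random.default_rng(5)
        n_de, n_null, mu, disp = 200, 1000, 100.0, 0.05
        size = 1.0 / disp
        powers = []
        for fold in [1.5, 2.5, 4.0]:
            mu_a = np.r_[np.full(n_de, mu * fold), np.full(n_null, mu)]
            a = rng.negative_binomial(size, size / (size + mu_a[:, None]), (n_de + n_null, 4))
            b = rng.negative_binomial(size, size / (size + mu), (n_de + n_null, 4))
            cm = make_counts(
                {
                    **{f"a{i}": a[:, i] for i in range(4)},
                    **{f"b{i}": b[:, i] for i in range(4)},
                },
                {**{f"a{i}": "A" for i in range(4)}, **{f"b{i}": "B" for i in range(4)}},
            )
            de = rp.test_contrast(rp.normalize(cm), Contrast("A", "B"))
            powers.append((de.table["q"].iloc[:n_de] < 0.01).mean())
        assert powers[0] < powers[1] < powers[2]

    def test_agrees_with_deseq2_reference(self):
        """Cross-check against pyDESeq2 on a small two-group dataset:
        strongly significant genes agree in direction and largely in
        identity, despite the different dispersion machinery."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(19)
        n, disp, mu = 300, 0.05, 150.0
        fold = np.ones(n)
        fold[:60] = 4.0
        fold[60:120] = 0.25
        size = 1.0 / disp
        a = rng.negative_binomial(size, size / (size + mu * fold[:, None]), (n, 4))
        b = rng.negative_binomial(size, size / (size + mu), (n, 4))
        counts = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"G{i}" for i in range(n)],
            columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        cm = make_counts(
            {c: counts[c].to_numpy() for c in counts.columns},
            {c: ("A" if c.startswith("a") else "B") for c in counts.columns},
        )
        ours = rp.test_contrast(rp.normalize(cm), Contrast("A", "B"))

        meta = pd.DataFrame(
            {"condition": ["A"] * 4 + ["B"] * 4}, index=counts.columns
        )
        dds = DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        stats = DeseqStats(
            dds, contrast=["condition", "A", "B"], quiet=True
        )
        stats.summary()
        ref = stats.results_df

        ours_hits = set(ours.table.index[ours.table["q"] < 0.01])
        ref_hits = set(ref.index[ref["padj"] < 0.01])
        jaccard = len(ours_hits & ref_hits) / len(ours_hits | ref_hits)
        assert jaccard > 0.8
        common = sorted(ours_hits & ref_hits)
        sign_ours = np.sign(ours.table.loc[common, "log2fc"])
        sign_ref = np.sign(ref.loc[common, "log2FoldChange"])
        assert (sign_ours.to_numpy() == sign_ref.to_numpy()).all()


class TestImportExport:
    def test_roundtrip_preserves_table(self, toy_counts, tmp_path):
        de = rp.test_contrast(rp.normalize(toy_counts), Contrast("A", "B"))
        path = tmp_path / "de.tsv"
        de.save(path)
        back = import_de_table(path)
        pd.testing.assert_frame_equal(
            de.table, back.table[de.table.columns], check_names=False
        )

    def test_missing_q_column_is_an_error(self, tmp_path):
        path = tmp_path / "de.tsv"
        pd.DataFrame({"gene": ["G1"], "log2fc": [1.0]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValueError, match="q"):
            import_de_table(path)

    def test_toy_table(self, tmp_path):
        path = tmp_path / "de.tsv"
        pd.DataFrame(
            {"gene": ["G1", "G2", "G3"], "log2fc": [1.0, -2.0, 0.0],
             "q": [0.001, 0.5, 1.0]}
        ).to_csv(path, sep="\t", index=False)
        de = import_de_table(path)
        assert len(de.table) == 3
        assert "p" in de.table.columns  # filled with NaN
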