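"""Cell-state classification rules and their boundary semantics."""

import numpy as np
import pandas as pd
import pytest

import reprogramome as rp
from reprogramome.state import CATEGORIES, StateThresholds, summarize_state

from conftest import make_counts


def classify_two_group(target_reps, start_reps, params=None):
    """Classify genes given explicit per-replicate normalized counts.

    Treats the supplied values as already normalized (unit size factors),
    runs the target-vs-start Wald contrast on them, then classifies.
    """
    genes = {}
    for i, (t, s) in enumerate(zip(target_reps, start_reps)):
        genes[f"G{i}"] = (t, s)
    n_rep = len(next(iter(genes.values()))[0])
    cols = [f"t{r}" for r in range(n_rep)] + [f"s{r}" for r in range(n_rep)]
    values = pd.DataFrame(
        {
            **{f"t{r}": [float(genes[g][0][r]) for g in genes] for r in range(n_rep)},
            **{f"s{r}": [float(genes[g][1][r]) for g in genes] for r in range(n_rep)},
        },
        index=list(genes),
    )[cols]
    design = rp.SampleDesign(
        pd.DataFrame(
            {"sample": cols, "group": ["T"] * n_rep + ["S"] * n_rep,
             "time_h": [np.nan] * 2 * n_rep, "replicate": list(range(1, n_rep + 1)) * 2}
        )
    )
    norm = rp.NormalizedMatrix(
        values=values, size_factors=pd.Series(1.0, index=cols), design=design
    )
    de = rp.test_contrast(norm, rp.Contrast("T", "S"))
    calls = rp.classify_state(de, norm, "T", "S", params or StateThresholds())
    return calls.loc[list(genes)]


def classify_from_values(target, start, q, params=None):
    """Rule application with a prescribed q: fabricate the normalized matrix
    and DE table instead of running the engine."""
    n_rep = len(target)
    cols = [f"t{r}" for r in range(n_rep)] + [f"s{r}" for r in range(n_rep)]
    values = pd.DataFrame(
        [list(target) + list(start)], index=["G0"], columns=cols, dtype=float
    )
    design = rp.SampleDesign(
        pd.DataFrame(
            {"sample": cols,
             "group": ["T"] * n_rep + ["S"] * n_rep,
             "time_h": [np.nan] * 2 * n_rep,
             "replicate": list(range(1, n_rep + 1)) * 2}
        )
    )
    norm = rp.NormalizedMatrix(
        values=values, size_factors=pd.Series(1.0, index=cols), design=design
    )
    mean_t, mean_s = float(np.mean(target)), float(np.mean(start))
    de = rp.DiffExprResult(
        pd.DataFrame(
            {"mean_a": [mean_t], "mean_b": [mean_s],
             "log2fc": [np.log2(mean_t / mean_s)], "p": [q], "q": [q]},
            index=["G0"],
        ),
        "T_vs_S",
    )
    return rp.classify_state(de, norm, "T", "S", params or StateThresholds())


class TestIsActive:
    @pytest.mark.parametrize(
        "reps,expected",
        [
            ((60, 70, 55), True),
            ((60, 49, 70), False),  # one replicate at 49 fails the all-replicate rule
            ((50, 50, 50), False),  # strictly greater than the threshold
            ((50.0001,), True),
        ],
    )
    def test_all_replicates_above_threshold(self, reps, expected):
        assert rp.is_active(reps) is expected

    def test_empty_vector_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            rp.is_active([])


class TestClassifyState:
    def test_activatome_by_hand(self):
        calls = classify_two_group([(400, 410, 390)], [(45, 40, 48)])
        assert calls.iloc[0]["category"] == "activatome"
        assert calls.iloc[0]["active_in_target"]
        assert not calls.iloc[0]["active_in_start"]

    def test_erasome_is_the_mirror(self):
        calls = classify_two_group([(45, 40, 48)], [(400, 410, 390)])
        assert calls.iloc[0]["category"] == "erasome"

    def test_failing_q_lands_marginal(self):
        """2.1-fold enrichment with q = 0.2: fails the significance rule,
        and the fold rules out equal_active, so the gene is marginal."""
        calls = classify_from_values(
            target=(200, 210, 190), start=(90, 95, 100), q=0.2
        )
        assert calls.iloc[0]["category"] == "marginal"

    def test_prescribed_activatome(self):
        calls = classify_from_values(
            target=(400, 410, 390), start=(45, 40, 48), q=1e-8
        )
        assert calls.iloc[0]["category"] == "activatome"
        assert calls.iloc[0]["fold"] == pytest.approx(9.02, abs=0.01)

    def test_inactive_both_when_everything_below_50(self):
        calls = classify_two_group([(5, 8, 3)], [(10, 2, 7)])
        assert calls.iloc[0]["category"] == "inactive_both"

    def test_replicate_exactly_at_threshold_is_marginal(self):
        """A replicate exactly at 50 is neither active nor inactive: with a
        non-significant sub-2-fold difference the gene fits no category."""
        calls = classify_from_values(
            target=(300, 310, 290), start=(250, 245, 50), q=0.5
        )
        assert calls.iloc[0]["category"] == "marginal"

    def test_equal_active_requires_all_replicates_active(self):
        calls = classify_two_group([(300, 310, 290)], [(295, 305, 300)])
        assert calls.iloc[0]["category"] == "equal_active"

    def test_missing_gene_in_norm_is_an_error(self, toy_counts):
        norm = rp.normalize(toy_counts)
        de = rp.test_contrast(norm, rp.Contrast("A", "B"))
        extra = de.table.copy()
        extra.loc["GHOST"] = extra.iloc[0]
        with pytest.raises(KeyError, match="GHOST"):
            rp.classify_state(rp.DiffExprResult(extra, "x"), norm, "A", "B")


class TestPartitionInvariant:
    def test_categories_partition_default_run(self, default_run):
        _, truth, results = default_run
        calls = results.state_calls
        counts = summarize_state(calls)["counts"]
        assert sum(counts[c] for c in CATEGORIES) == len(calls) == len(truth)

    def test_union_definitions(self, default_run):
        _, _, results = default_run
        counts = summarize_state(results.state_calls)["counts"]
        assert counts["upreprogramome"] == counts["activatome"] + counts["upreprogramome_enriched"]
        assert counts["downreprogramome"] == counts["erasome"] + counts["downreprogramome_enriched"]

    def test_raising_activity_threshold_only_drains_exclusive_sets(self, default_run):
        """Monotonicity: a stricter activity requirement (inactivity cutoff
        held at 50) can only move genes out of activatome/erasome, never
        into them."""
        counts, _, _ = default_run
        norm = rp.normalize(counts)
        de = rp.test_contrast(norm, rp.Contrast("ESC", "fibroblast_naive"))
        lo = rp.classify_state(de, norm, "ESC", "fibroblast_naive",
                               StateThresholds(activity=50))
        hi = rp.classify_state(de, norm, "ESC", "fibroblast_naive",
                               StateThresholds(activity=120, inactivity=50))
        for cat in ("activatome", "erasome"):
            lo_set = set(lo.index[lo["category"] == cat])
            hi_set = set(hi.index[hi["category"] == cat])
            assert hi_set <= lo_set


class TestSummaries:
    def test_planted_counts_recovered(self, default_run):
        _, truth, results = default_run
        conf = rp.recovery_report(truth, results.state_calls)
        rates = rp.recovery_rates(conf)
        for cls in rates.index:
            if cls != "marginal":
                assert rates[cls] >= 0.99, f"{cls}: {rates[cls]}"

    def test_all_identical_matrix_is_all_equal_active(self):
        calls = classify_two_group(
            [(300, 300, 300), (70, 70, 70)], [(300, 300, 300), (70, 70, 70)]
        )
        assert (calls["category"] == "equal_active").all()

    def test_marginal_complements_the_published_partition(self):
        """With 1636 TFs split 315 inactive / 442 equal / 279 down / 310 up,
        the unclassifiable remainder is 290."""
        sizes = {
            "inactive_both": 315,
            "equal_active": 442,
            "erasome": 93,
            "downreprogramome_enriched": 186,
            "activatome": 70,
            "upreprogramome_enriched": 240,
        }
        rows = []
        for cat, n in sizes.items():
            fold = 4.0 if "up" in cat or cat == "activatome" else 0.25
            rows += [(cat, fold)] * n
        n_marginal = 1636 - sum(sizes.values())
        rows += [("marginal", 1.0)] * n_marginal
        calls = pd.DataFrame(rows, columns=["category", "fold"])
        calls["active_in_target"] = True
        calls["active_in_start"] = True
        calls["q"] = 0.5
        counts = summarize_state(calls)["counts"]
        assert counts["downreprogramome"] == 279
        assert counts["upreprogramome"] == 310
        assert counts["marginal"] == 290
        assert sum(counts[c] for c in CATEGORIES) == 1636

    def test_fold_bins_are_a_partition_of_enriched(self, default_run):
        _, _, results = default_run
        summary = summarize_state(results.state_calls)
        for side, cat in (
            ("up_enriched", "upreprogramome_enriched"),
            ("down_enriched", "downreprogramome_enriched"),
        ):
            bins = summary["fold_bins"][side]
            assert sum(bins.values()) == summary["counts"][cat]

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError, match="no state calls"):
            summarize_state(pd.DataFrame(columns=["category", "fold"]))
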