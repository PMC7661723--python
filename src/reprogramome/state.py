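"""Cell-state classification of TFs from the target-vs-start contrast.

Each TF is placed in exactly one category from the target-state (e.g. ESC)
vs start-state (fibroblast) comparison:

* ``inactive_both`` — every replicate of both groups below the activity
  threshold (normalized count < 50);
* ``activatome`` — active only in the target state (all target replicates
  > 50, all start replicates < 50), fold > 2 toward the target, q < 0.01;
* ``erasome`` — the mirror image, active only in the start state;
* ``upreprogramome_enriched`` — target-active with at least 2-fold
  enrichment toward the target at q < 0.01 (not already activatome);
* ``downreprogramome_enriched`` — the mirror toward the start state;
* ``equal_active`` — active in both (every replicate > 50) with q > 0.01
  and fold < 2 regardless of q;
* ``marginal`` — anything left (threshold-straddling replicates,
  significant sub-2-fold changes, etc.).

The up-reprogramome is activatome + upreprogramome_enriched; the
down-reprogramome is erasome + downreprogramome_enriched. Boundary
semantics are strict on both sides of the activity threshold: a replicate
exactly at 50 is neither active nor inactive, which routes the gene to
``marginal``. Enrichment uses fold >= 2 but the exclusive activatome /
erasome sets require fold strictly > 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import DiffExprResult, ZERO_MEAN_PSEUDOCOUNT
from .io import NormalizedMatrix

CATEGORIES = (
    "activatome",
    "erasome",
    "upreprogramome_enriched",
    "downreprogramome_enriched",
    "equal_active",
    "inactive_both",
    "marginal",
)

UPREPROGRAMOME = ("activatome", "upreprogramome_enriched")
DOWNREPROGRAMOME = ("erasome", "downreprogramome_enriched")


@dataclass(frozen=True)
class StateThresholds:
    """Thresholds for state classification.

    activity: a replicate is active when strictly above this normalized
    count. inactivity: a replicate is inactive when strictly below this
    (defaults to the activity threshold, i.e. the single cutoff of 50).
    fold: minimum enrichment (>= for the reprogramomes, > for
    activatome/erasome). q: strict significance level.
    """

    activity: float = 50.0
    inactivity: float | None = None
    fold: float = 2.0
    q: float = 0.01

    @property
    def inactivity_cutoff(self) -> float:
        return self.activity if self.inactivity is None else self.inactivity


def is_active(norm_counts: Sequence[float], threshold: float = 50.0) -> bool:
    """True iff every replicate exceeds the activity threshold (strict)."""
    vals = np.asarray(list(norm_counts), dtype=float)
    if vals.size == 0:
        raise ValueError("empty replicate vector")
    return bool((vals > threshold).all())


def _is_inactive(vals: np.ndarray, threshold: float) -> np.ndarray:
    return (vals < threshold).all(axis=1)


def classify_state(
    de: DiffExprResult,
    norm: NormalizedMatrix,
    target_group: str,
    start_group: str,
    params: StateThresholds = StateThresholds(),
) -> pd.DataFrame:
    """Classify every gene in ``de`` (the target-vs-start contrast).

    Returns one row per gene with columns ``category``,
    ``active_in_target``, ``active_in_start``, ``fold`` (ratio of
    normalized group means toward the larger group, always >= open
    direction; stored as target-over-start), and ``q``.
    """
    genes = de.table.index
    missing = [g for g in genes if g not in norm.values.index]
    if missing:
        raise KeyError(f"genes in DE result absent from normalized matrix: {missing[:10]}")

    tgt = norm.group_values(target_group).loc[genes].to_numpy(dtype=float)
    sta = norm.group_values(start_group).loc[genes].to_numpy(dtype=float)

    act_t = (tgt > params.activity).all(axis=1)
    act_s = (sta > params.activity).all(axis=1)
    inact_t = _is_inactive(tgt, params.inactivity_cutoff)
    inact_s = _is_inactive(sta, params.inactivity_cutoff)

    mean_t = tgt.mean(axis=1)
    mean_s = sta.mean(axis=1)
    zero = (mean_t == 0) | (mean_s == 0)
    ft = np.where(zero, mean_t + ZERO_MEAN_PSEUDOCOUNT, mean_t)
    fs = np.where(zero, mean_s + ZERO_MEAN_PSEUDOCOUNT, mean_s)
    fold_ts = ft / fs  # target over start

    q = de.table["q"].to_numpy(dtype=float)
    sig = ~np.isnan(q) & (q < params.q)

    cat = np.full(len(genes), "marginal", dtype=object)
    fold_up = fold_ts
    fold_down = 1.0 / fold_ts

    rules = [
        ("inactive_both", inact_t & inact_s),
        ("activatome", act_t & inact_s & (fold_up > params.fold) & sig),
        ("erasome", act_s & inact_t & (fold_down > params.fold) & sig),
        ("upreprogramome_enriched", act_t & (fold_up >= params.fold) & sig),
        ("downreprogramome_enriched", act_s & (fold_down >= params.fold) & sig),
        (
            "equal_active",
            act_t
            & act_s
            & ~np.isnan(q)
            & (q > params.q)
            & (fold_up < params.fold)
            & (fold_down < params.fold),
        ),
    ]
    assigned = np.zeros(len(genes), dtype=bool)
    for name, mask in rules:
        take = mask & ~assigned
        cat[take] = name
        assigned |= take

    return pd.DataFrame(
        {
            "category": cat,
            "active_in_target": act_t,
            "active_in_start": act_s,
            "fold": fold_ts,
            "q": q,
        },
        index=genes,
    )


def reprogramome_genes(calls: pd.DataFrame) -> pd.Index:
    """Genes needing reprogramming: union of up- and down-reprogramome."""
    mask = calls["category"].isin(UPREPROGRAMOME + DOWNREPROGRAMOME)
    return calls.index[mask]


FOLD_BINS = ("2-3", "3-5", ">5")


def _fold_histogram(folds: np.ndarray) -> dict[str, int]:
    return {
        "2-3": int(((folds >= 2) & (folds < 3)).sum()),
        "3-5": int(((folds >= 3) & (folds <= 5)).sum()),
        ">5": int((folds > 5).sum()),
    }


def summarize_state(
    calls: pd.DataFrame, families: pd.Series | None = None
) -> dict:
    """Category counts, per-direction fold-bin histograms, family cross-tab.

    Category counts always sum to the number of evaluated TFs. Fold bins
    cover the enriched-only sets (activatome/erasome excluded), matching
    how degrees of enrichment are usually reported.
    """
    if calls.empty:
        raise ValueError("no state calls to summarize")
    counts = {c: int((calls["category"] == c).sum()) for c in CATEGORIES}
    counts["upreprogramome"] = sum(counts[c] for c in UPREPROGRAMOME)
    counts["downreprogramome"] = sum(counts[c] for c in DOWNREPROGRAMOME)

    up_en = calls.loc[calls["category"] == "upreprogramome_enriched", "fold"]
    down_en = 1.0 / calls.loc[calls["category"] == "downreprogramome_enriched", "fold"]
    summary = {
        "counts": counts,
        "n_evaluated": int(len(calls)),
        "fold_bins": {
            "up_enriched": _fold_histogram(up_en.to_numpy()),
            "down_enriched": _fold_histogram(down_en.to_numpy()),
        },
    }
    if families is not None:
        tab = (
            pd.crosstab(calls["category"], families.reindex(calls.index).fillna("other"))
            .astype(int)
        )
        summary["family_crosstab"] = tab
    return summary
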