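"""Calling TF transcriptional responses to reprogramming-factor induction.

A gene is called up- (down-) regulated only when the induced (OSKM)
samples differ from EVERY configured reference at EVERY time point by at
least 2-fold with q < 0.01 — the conjunction over the reference x time
grid. Using both the naive fibroblasts and the GFP-transduced fibroblasts
as references removes transcriptional effects of viral transduction per
se; a design with a single reference degrades gracefully to that grid.

The exogenous reprogramming factors themselves (OCT4/POU5F1, SOX2, KLF4,
MYC by default) are delivered on viral vectors, so their apparent
upregulation is transgene expression: they are flagged and excluded from
responsive counts.

Reprogramome members that show no qualifying change are separately called
irresponsive under a multi-rule definition (see :func:`call_irresponsive`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .diffexpr import DiffExprResult, ZERO_MEAN_PSEUDOCOUNT
from .io import NormalizedMatrix
from .state import DOWNREPROGRAMOME, UPREPROGRAMOME

#: default exogenous reprogramming-factor symbols
DEFAULT_FACTORS = frozenset({"POU5F1", "OCT4", "SOX2", "KLF4", "MYC"})

DIRECTIONS = ("up", "down", "irresponsive", "unclassified")


@dataclass(frozen=True)
class ResponseThresholds:
    fold: float = 2.0
    q: float = 0.01
    activity: float = 50.0


def _check_grid(de_set: Mapping[tuple[str, float], DiffExprResult]) -> None:
    if not de_set:
        raise ValueError("empty DE set: need at least one (reference, time) contrast")
    refs = sorted({r for r, _ in de_set})
    times = sorted({t for _, t in de_set})
    missing = [(r, t) for r in refs for t in times if (r, t) not in de_set]
    if missing:
        raise ValueError(f"missing contrasts in reference x time grid: {missing}")


def call_responses(
    de_set: Mapping[tuple[str, float], DiffExprResult],
    factors: Iterable[str] = DEFAULT_FACTORS,
    params: ResponseThresholds = ResponseThresholds(),
) -> pd.DataFrame:
    """Call up/down responses over the full reference x time grid.

    ``de_set`` maps (reference label, time point) to the OSKM-over-reference
    DE result for that contrast. Returns one row per gene with ``direction``
    (up / down / unclassified), ``exogenous``, and per-contrast
    ``log2fc_<ref>_<t>h`` / ``q_<ref>_<t>h`` evidence columns.
    """
    _check_grid(de_set)
    factors = set(factors)
    keys = sorted(de_set, key=lambda k: (k[0], k[1]))
    genes = de_set[keys[0]].table.index
    for k in keys[1:]:
        if not genes.equals(de_set[k].table.index):
            genes = genes.intersection(de_set[k].table.index)

    log2_thr = np.log2(params.fold)
    up_all = np.ones(len(genes), dtype=bool)
    down_all = np.ones(len(genes), dtype=bool)
    evidence: dict[str, np.ndarray] = {}
    for ref, t in keys:
        tab = de_set[(ref, t)].table.loc[genes]
        l2 = tab["log2fc"].to_numpy(dtype=float)
        q = tab["q"].to_numpy(dtype=float)
        sig = ~np.isnan(q) & (q < params.q)
        up_all &= (l2 >= log2_thr) & sig
        down_all &= (l2 <= -log2_thr) & sig
        evidence[f"log2fc_{ref}_{t:g}h"] = l2
        evidence[f"q_{ref}_{t:g}h"] = q

    direction = np.full(len(genes), "unclassified", dtype=object)
    direction[up_all] = "up"
    direction[down_all] = "down"
    exogenous = np.array([g in factors for g in genes])

    out = pd.DataFrame({"direction": direction, "exogenous": exogenous}, index=genes)
    for col, arr in evidence.items():
        out[col] = arr
    return out


def responsive_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Counts of responsive TFs, excluding the exogenous factors."""
    endo = calls.loc[~calls["exogenous"]]
    return {
        "up": int((endo["direction"] == "up").sum()),
        "down": int((endo["direction"] == "down").sum()),
        "up_including_factors": int((calls["direction"] == "up").sum()),
        "down_including_factors": int((calls["direction"] == "down").sum()),
    }


def call_irresponsive(
    calls: pd.DataFrame,
    de_set: Mapping[tuple[str, float], DiffExprResult],
    state_calls: pd.DataFrame,
    norm: NormalizedMatrix,
    target_group: str,
    response_group: str,
    start_group: str | None = None,
    params: ResponseThresholds = ResponseThresholds(),
) -> pd.DataFrame:
    """Mark reprogramome members irresponsive to induction.

    A reprogramome gene is irresponsive iff, in every (reference, time)
    contrast:

    1. the fold change is below 2 in either direction (any gene with a
       > 2-fold change is removed regardless of significance);
    2. no contrast is significant at q < 0.01 (a significant 1.5-fold
       change still disqualifies);
    3. the gene has not already closed in on the target state: if at any
       induction time point the normalized-mean fold between the induced
       cells and the target (ESC) group falls below 2, the gene is
       excluded from the irresponsive list regardless of significance;
    4. (up-reprogramome only) a gene that *remains* inactive after
       induction — inactive in the start state (when ``start_group`` is
       given) and every induced replicate < 50 — is irresponsive
       outright, even when its fold change is > 2 and significant.

    Returns ``calls`` with the direction of qualifying genes set to
    ``irresponsive``. Genes outside the reprogramome are untouched.
    """
    _check_grid(de_set)
    genes = calls.index
    times = sorted({t for _, t in de_set})

    state = state_calls.reindex(genes)
    in_up = state["category"].isin(UPREPROGRAMOME).to_numpy()
    in_down = state["category"].isin(DOWNREPROGRAMOME).to_numpy()
    in_repro = in_up | in_down

    log2_thr = np.log2(params.fold)
    small_fold = np.ones(len(genes), dtype=bool)
    no_sig = np.ones(len(genes), dtype=bool)
    for key, de in de_set.items():
        tab = de.table.reindex(genes)
        l2 = tab["log2fc"].to_numpy(dtype=float)
        q = tab["q"].to_numpy(dtype=float)
        small_fold &= np.abs(l2) < log2_thr
        no_sig &= ~(~np.isnan(q) & (q < params.q))

    # rule 3: distance to target per time point, on normalized means
    mean_t = norm.group_means(target_group).reindex(genes).to_numpy(dtype=float)
    near_target = np.zeros(len(genes), dtype=bool)
    for t in times:
        mean_r = (
            norm.group_means(response_group, t).reindex(genes).to_numpy(dtype=float)
        )
        zero = (mean_t == 0) | (mean_r == 0)
        mt = np.where(zero, mean_t + ZERO_MEAN_PSEUDOCOUNT, mean_t)
        mr = np.where(zero, mean_r + ZERO_MEAN_PSEUDOCOUNT, mean_r)
        dist = np.where(mt >= mr, mt / mr, mr / mt)
        near_target |= dist < params.fold

    # rule 4: up-reprogramome genes that remain inactive after induction
    still_inactive = np.ones(len(genes), dtype=bool)
    if start_group is not None:
        sta = norm.group_values(start_group).reindex(genes).to_numpy(dtype=float)
        still_inactive &= (sta < params.activity).all(axis=1)
    for t in times:
        vals = norm.group_values(response_group, t).reindex(genes).to_numpy(dtype=float)
        still_inactive &= (vals < params.activity).all(axis=1)

    irre = in_repro & small_fold & no_sig & ~near_target
    irre |= in_up & still_inactive

    out = calls.copy()
    # a responsive call is never overwritten except by rule 4
    overwrite = irre & (
        (out["direction"] == "unclassified").to_numpy()
        | (in_up & still_inactive)
    )
    out.loc[overwrite, "direction"] = "irresponsive"
    return out
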