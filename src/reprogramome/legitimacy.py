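"""Reprogramming-legitimacy evaluation of responsive TFs.

A transcriptional response is judged against the gene's relative
expression in the target (PSC) versus the start (fibroblast) state:
upregulating a target-enriched gene, or downregulating a start-enriched
gene, is legitimate; moving a gene the wrong way is wrong reprogramming;
moving a gene that needed no change (including de novo activation of a
gene silent in both states) is unwanted. Because responsive genes are
heavily biased toward the matching enrichment, the enrichment here is
assessed at a relaxed significance (q < 0.05, any fold) rather than the
strict reprogramome criteria.

Legitimate responses are sub-classified by where the induced cells landed:
``proper`` when the induced mean profile moved closer to the target group
than to the start group, ``over`` when it overshot the target by more than
the configured margin in the direction of change, ``insufficient``
otherwise. Distances are measured per gene in log2(normalized + 1) space
between the mean of the induced samples and each group mean — a
deterministic stand-in for the visual "clusters with the target cells"
judgement; :func:`clustering_report` reproduces the average-linkage
correlation-distance clustering for concordance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DiffExprResult
from .io import NormalizedMatrix

ENRICHMENT_LABELS = ("target_higher", "start_higher", "equal", "silent_both")
VERDICTS = ("legitimate", "wrong", "unwanted")
SUBCLASSES = ("proper", "insufficient", "over", "none")

#: (direction, enrichment) -> verdict; total over both axes
VERDICT_TABLE: dict[tuple[str, str], str] = {
    ("up", "target_higher"): "legitimate",
    ("up", "start_higher"): "wrong",
    ("up", "equal"): "unwanted",
    ("up", "silent_both"): "unwanted",
    ("down", "start_higher"): "legitimate",
    ("down", "target_higher"): "wrong",
    ("down", "equal"): "unwanted",
    ("down", "silent_both"): "unwanted",
}


@dataclass(frozen=True)
class LegitimacyParams:
    q_relaxed: float = 0.05
    over_margin_fold: float = 2.0
    pseudocount: float = 1.0
    activity: float = 50.0


def relaxed_enrichment(
    de_target_vs_start: DiffExprResult,
    norm: NormalizedMatrix,
    target_group: str,
    start_group: str,
    params: LegitimacyParams = LegitimacyParams(),
) -> pd.Series:
    """Label each gene's target-vs-start enrichment at relaxed significance.

    ``target_higher`` iff q < q_relaxed and the target mean exceeds the
    start mean (any fold); ``start_higher`` is the mirror; ``silent_both``
    when every replicate of both groups is below the activity threshold;
    ``equal`` otherwise.
    """
    tab = de_target_vs_start.table
    q = tab["q"].to_numpy(dtype=float)
    mean_t = tab["mean_a"].to_numpy(dtype=float)
    mean_s = tab["mean_b"].to_numpy(dtype=float)

    tgt = norm.group_values(target_group).reindex(tab.index).to_numpy(dtype=float)
    sta = norm.group_values(start_group).reindex(tab.index).to_numpy(dtype=float)
    silent = (tgt < params.activity).all(axis=1) & (sta < params.activity).all(axis=1)

    sig = ~np.isnan(q) & (q < params.q_relaxed)
    label = np.full(len(tab), "equal", dtype=object)
    label[sig & (mean_t > mean_s)] = "target_higher"
    label[sig & (mean_s > mean_t)] = "start_higher"
    label[~sig & silent] = "silent_both"
    return pd.Series(label, index=tab.index, name="enrichment")


def evaluate_legitimacy(
    responses: pd.DataFrame,
    enrichments: pd.Series,
    norm: NormalizedMatrix,
    target_group: str,
    start_group: str,
    response_group: str,
    params: LegitimacyParams = LegitimacyParams(),
) -> pd.DataFrame:
    """Cross-classify responsive genes into verdicts and subclasses.

    Only endogenous genes with direction up/down are evaluated. Returns a
    frame with ``direction``, ``enrichment``, ``verdict``, ``subclass``,
    and the log2-space distances ``d_target``/``d_start`` of the induced
    mean profile to the two reference groups.
    """
    resp = responses.loc[
        responses["direction"].isin(("up", "down")) & ~responses["exogenous"]
    ]
    genes = resp.index
    enr = enrichments.reindex(genes)
    if enr.isna().any():
        missing = list(enr.index[enr.isna()])[:10]
        raise KeyError(f"responsive genes without enrichment labels: {missing}")

    pc = params.pseudocount
    log2 = lambda df: np.log2(df + pc)
    prof_r = log2(norm.group_values(response_group).reindex(genes)).mean(axis=1)
    prof_t = log2(norm.group_values(target_group).reindex(genes)).mean(axis=1)
    prof_s = log2(norm.group_values(start_group).reindex(genes)).mean(axis=1)
    d_target = (prof_r - prof_t).abs()
    d_start = (prof_r - prof_s).abs()

    margin = np.log2(params.over_margin_fold)
    rows = []
    for g in genes:
        direction = resp.loc[g, "direction"]
        verdict = VERDICT_TABLE[(direction, enr.loc[g])]
        subclass = "none"
        if verdict == "legitimate":
            overshoot = (
                prof_r[g] > prof_t[g] + margin
                if direction == "up"
                else prof_r[g] < prof_t[g] - margin
            )
            moved_with_direction = (
                prof_r[g] > prof_s[g] if direction == "up" else prof_r[g] < prof_s[g]
            )
            if overshoot:
                subclass = "over"
            elif d_target[g] < d_start[g] and moved_with_direction:
                subclass = "proper"
            else:
                subclass = "insufficient"
        rows.append((g, direction, enr.loc[g], verdict, subclass))

    out = pd.DataFrame(
        rows, columns=["gene", "direction", "enrichment", "verdict", "subclass"]
    ).set_index("gene")
    out["d_target"] = d_target
    out["d_start"] = d_start
    return out


def legitimacy_summary(calls: pd.DataFrame) -> dict:
    """Per-direction verdict/subclass counts and legitimate fractions.

    The legitimate fraction is legitimate / (legitimate + wrong + unwanted)
    per direction, reported as a percentage to one decimal; NaN when no
    gene of that direction was evaluated.
    """
    summary: dict = {}
    for direction in ("up", "down"):
        sub = calls.loc[calls["direction"] == direction] if len(calls) else calls
        n = int(len(sub))
        verdicts = {v: int((sub["verdict"] == v).sum()) for v in VERDICTS} if n else {
            v: 0 for v in VERDICTS
        }
        subclasses = (
            {s: int((sub["subclass"] == s).sum()) for s in SUBCLASSES[:3]}
            if n
            else {s: 0 for s in SUBCLASSES[:3]}
        )
        frac = round(100.0 * verdicts["legitimate"] / n, 1) if n else float("nan")
        summary[direction] = {
            "n": n,
            "verdicts": verdicts,
            "subclasses": subclasses,
            "legitimate_percent": frac,
        }
    return summary


def clustering_report(
    norm: NormalizedMatrix,
    genes: list[str],
    groups: list[str],
    params: LegitimacyParams = LegitimacyParams(),
) -> pd.DataFrame:
    """Average-linkage correlation-distance clustering of samples.

    Optional concordance check for the distance-based subclassing: returns
    the sample linkage order over the selected genes' log2 profiles.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    samples = [s for g in groups for s in norm.design.samples_of(g)]
    mat = np.log2(norm.values.loc[genes, samples] + params.pseudocount)
    dist = pdist(mat.T, metric="correlation")
    link = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(link)
    return pd.DataFrame(
        {"sample": [samples[i] for i in order], "position": range(len(order))}
    )
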