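"""Model/results interface tying the pipeline stages together.

:class:`ReprogramomeModel` is constructed from a count matrix (plus an
optional TF catalog and run configuration); :meth:`ReprogramomeModel.fit`
runs normalization, the differential-expression contrasts, state
classification, response calling, and legitimacy evaluation, and returns a
:class:`ReprogramomeResults` carrying every intermediate table, the
headline summaries, and a ``summary()`` report.

Precomputed DE tables (e.g. a DESeq2 export) can be supplied to bypass the
built-in engine for any contrast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diffexpr, legitimacy, response, state
from .catalog import TFCatalog
from .config import RunConfig
from .diffexpr import Contrast, DiffExprResult
from .io import CountMatrix, NormalizedMatrix, log2_matrix, read_counts

STATE_CONTRAST = "state"


class ReprogramomeModel:
    """TF reprogramming analysis of one start→target conversion experiment.

    Parameters
    ----------
    counts
        Full count matrix with design attached (all genes; normalization
        runs genome-wide before any TF subsetting).
    catalog
        Optional curated TF catalog; when given, classification is
        restricted to its active symbols. Without one, every gene in the
        matrix is treated as an evaluable TF.
    config
        Thresholds, group roles and contrast grid; defaults follow the
        standard design (activity 50, fold 2, q 0.01, relaxed q 0.05).
    de_tables
        Optional precomputed DE results keyed ``"state"`` for the
        target-vs-start contrast and ``(reference, time)`` for response
        contrasts; any contrast present here skips the built-in engine.
    """

    def __init__(
        self,
        counts: CountMatrix,
        catalog: TFCatalog | None = None,
        config: RunConfig | None = None,
        de_tables: dict | None = None,
    ) -> None:
        self.counts = counts
        self.catalog = catalog
        self.config = config or RunConfig()
        self.de_tables = de_tables or {}
        roles = self.config.roles
        groups = set(counts.design.groups)
        for role, g in (("target", roles.target), ("start", roles.start),
                        ("response", roles.response)):
            if g not in groups:
                raise ValueError(f"{role} group {g!r} not present in design")
        if roles.control and roles.control not in groups:
            raise ValueError(f"control group {roles.control!r} not present in design")

    @classmethod
    def from_files(
        cls,
        counts_path,
        design_path,
        catalog: TFCatalog | None = None,
        config: RunConfig | None = None,
    ) -> "ReprogramomeModel":
        return cls(read_counts(counts_path, design_path), catalog, config)

    # -- contrasts ---------------------------------------------------------

    def _time_points(self) -> list[float]:
        roles = self.config.roles
        if self.config.time_points is not None:
            return list(self.config.time_points)
        tps = self.counts.design.time_points(roles.response)
        if not tps:
            raise ValueError(f"response group {roles.response!r} has no time points")
        return tps

    def contrasts(self) -> dict:
        """The full contrast plan: 'state' plus the reference x time grid."""
        roles = self.config.roles
        plan: dict = {STATE_CONTRAST: Contrast(roles.target, roles.start, label="state")}
        for ref in roles.references:
            for t in self._time_points():
                plan[(ref, t)] = Contrast(
                    roles.response, ref, time_a=t, label=f"OSKM{t:g}h_vs_{ref}"
                )
        return plan

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "ReprogramomeResults":
        cfg = self.config
        roles = cfg.roles
        norm = diffexpr.normalize(self.counts)

        tf_genes = list(self.counts.counts.index)
        if self.catalog is not None:
            keep = self.catalog.symbols
            tf_genes = [g for g in tf_genes if g in keep]
            if not tf_genes:
                raise ValueError("no catalog TF present in the count matrix")

        de: dict = {}
        for key, contrast in self.contrasts().items():
            if key in self.de_tables:
                de[key] = self.de_tables[key]
            else:
                de[key] = diffexpr.test_contrast(norm, contrast)
        # genome-wide FDR first, then subset to the TF catalog
        de_tf = {k: v.subset(tf_genes) for k, v in de.items()}

        state_calls = state.classify_state(
            de_tf[STATE_CONTRAST], norm, roles.target, roles.start, cfg.state
        )
        response_de = {k: v for k, v in de_tf.items() if k != STATE_CONTRAST}
        response_calls = response.call_responses(
            response_de, cfg.factors, cfg.response
        )
        response_calls = response.call_irresponsive(
            response_calls, response_de, state_calls, norm,
            roles.target, roles.response, roles.start, cfg.response,
        )
        enrichments = legitimacy.relaxed_enrichment(
            de_tf[STATE_CONTRAST], norm, roles.target, roles.start, cfg.legitimacy
        )
        legitimacy_calls = legitimacy.evaluate_legitimacy(
            response_calls, enrichments, norm,
            roles.target, roles.start, roles.response, cfg.legitimacy,
        )

        families = None
        if self.catalog is not None:
            families = pd.Series(
                dict(zip(self.catalog.active["symbol"], self.catalog.active["family"]))
            )
        return ReprogramomeResults(
            model=self,
            normalized=norm,
            de=de_tf,
            de_genomewide=de,
            state_calls=state_calls,
            response_calls=response_calls,
            enrichments=enrichments,
            legitimacy_calls=legitimacy_calls,
            families=families,
        )


@dataclass
class ReprogramomeResults:
    """Fitted results: every per-gene table plus the headline summaries."""

    model: ReprogramomeModel
    normalized: NormalizedMatrix
    de: dict = field(repr=False)
    de_genomewide: dict = field(repr=False)
    state_calls: pd.DataFrame = field(repr=False)
    response_calls: pd.DataFrame = field(repr=False)
    enrichments: pd.Series = field(repr=False)
    legitimacy_calls: pd.DataFrame = field(repr=False)
    families: pd.Series | None = field(default=None, repr=False)

    @property
    def state_summary(self) -> dict:
        return state.summarize_state(self.state_calls, self.families)

    @property
    def response_summary(self) -> dict:
        counts = response.responsive_counts(self.response_calls)
        cat = self.state_calls["category"]
        irre = self.response_calls["direction"] == "irresponsive"
        counts["irresponsive_up_reprogramome"] = int(
            (irre & cat.isin(state.UPREPROGRAMOME)).sum()
        )
        counts["irresponsive_down_reprogramome"] = int(
            (irre & cat.isin(state.DOWNREPROGRAMOME)).sum()
        )
        return counts

    @property
    def legitimacy_summary(self) -> dict:
        return legitimacy.legitimacy_summary(self.legitimacy_calls)

    def headline(self) -> dict:
        """The run's headline tallies as one JSON-serializable dict."""
        ss = self.state_summary
        return {
            "n_tfs_evaluated": ss["n_evaluated"],
            "state_counts": ss["counts"],
            "fold_bins": ss["fold_bins"],
            "response_counts": self.response_summary,
            "legitimacy": self.legitimacy_summary,
        }

    def summary(self) -> str:
        """Human-readable run report."""
        h = self.headline()
        sc = h["state_counts"]
        rc = h["response_counts"]
        lines = [
            "TF reprogramome analysis",
            "=" * 60,
            f"TFs evaluated:            {h['n_tfs_evaluated']}",
            "",
            "Cell-state categories (target vs start):",
        ]
        for cat in state.CATEGORIES:
            lines.append(f"  {cat:<26s} {sc[cat]:>6d}")
        lines += [
            f"  {'upreprogramome (total)':<26s} {sc['upreprogramome']:>6d}",
            f"  {'downreprogramome (total)':<26s} {sc['downreprogramome']:>6d}",
            "",
            "Responses to factor induction (all references x time points):",
            f"  upregulated (endogenous)   {rc['up']:>6d}",
            f"  downregulated (endogenous) {rc['down']:>6d}",
            f"  irresponsive up-reprogramome   {rc['irresponsive_up_reprogramome']:>6d}",
            f"  irresponsive down-reprogramome {rc['irresponsive_down_reprogramome']:>6d}",
            "",
            "Reprogramming legitimacy:",
        ]
        for direction in ("up", "down"):
            leg = h["legitimacy"][direction]
            v, s = leg["verdicts"], leg["subclasses"]
            lines.append(
                f"  {direction:<5s} n={leg['n']:<4d} legitimate={v['legitimate']} "
                f"(proper={s['proper']}, insufficient={s['insufficient']}, "
                f"over={s['over']}), wrong={v['wrong']}, unwanted={v['unwanted']}"
                f"  -> {leg['legitimate_percent']}% legitimate"
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> Path:
        """Write per-stage TSV tables, the summary JSON, and the config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.model.config.save(outdir / "config.yaml")
        self.normalized.size_factors.to_csv(outdir / "size_factors.tsv", sep="\t")
        for key, res in self.de.items():
            name = res.contrast or (key if isinstance(key, str) else f"{key[0]}_{key[1]:g}h")
            res.save(outdir / f"de_{name}.tsv")
        for name, frame in (
            ("state_calls", self.state_calls),
            ("response_calls", self.response_calls),
            ("legitimacy_calls", self.legitimacy_calls),
        ):
            out = frame.copy()
            out.insert(0, "gene", out.index)
            out.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        log2 = log2_matrix(self.normalized, self.model.config.legitimacy.pseudocount)
        log2.to_csv(outdir / "log2_normalized.tsv", sep="\t")
        (outdir / "summary.json").write_text(json.dumps(self.headline(), indent=2))
        return outdir


def compare_datasets(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    de_a: DiffExprResult,
    de_b: DiffExprResult,
    direction: str = "up",
    p_relaxed: float = 0.05,
) -> dict:
    """Intersect state calls from two datasets sharing a catalog.

    ``shared`` is the strict intersection of the direction's reprogramome
    sets. Genes unique to one dataset are re-tested in the other under
    relaxed criteria (p < ``p_relaxed``, any fold, same direction — note
    p, not q, for this rescue step). Genes significant in opposite
    directions across the datasets are flagged as conflicts.
    """
    if set(calls_a.index) != set(calls_b.index):
        raise ValueError("datasets use different gene catalogs")
    cats = state.UPREPROGRAMOME if direction == "up" else state.DOWNREPROGRAMOME
    set_a = set(calls_a.index[calls_a["category"].isin(cats)])
    set_b = set(calls_b.index[calls_b["category"].isin(cats)])

    def rescued(unique: set, de_other: DiffExprResult) -> set:
        out = set()
        for g in unique:
            if g not in de_other.table.index:
                continue
            row = de_other.table.loc[g]
            p = row["p"] if "p" in row and pd.notna(row["p"]) else row["q"]
            same_dir = row["log2fc"] > 0 if direction == "up" else row["log2fc"] < 0
            if pd.notna(p) and p < p_relaxed and same_dir:
                out.add(g)
        return out

    def conflicts() -> set:
        out = set()
        common = set(de_a.table.index) & set(de_b.table.index)
        for g in common:
            ra, rb = de_a.table.loc[g], de_b.table.loc[g]
            pa = ra["p"] if "p" in ra and pd.notna(ra.get("p")) else ra["q"]
            pb = rb["p"] if "p" in rb and pd.notna(rb.get("p")) else rb["q"]
            if (
                pd.notna(pa) and pa < p_relaxed
                and pd.notna(pb) and pb < p_relaxed
                and ra["log2fc"] * rb["log2fc"] < 0
            ):
                out.add(g)
        return out

    unique_a = set_a - set_b
    unique_b = set_b - set_a
    return {
        "shared": set_a & set_b,
        "unique_a": unique_a,
        "unique_b": unique_b,
        "rescued_a_in_b": rescued(unique_a, de_b),
        "rescued_b_in_a": rescued(unique_b, de_a),
        "conflicts": conflicts(),
    }


def run_pipeline(
    counts_path,
    design_path,
    outdir,
    catalog: TFCatalog | None = None,
    config: RunConfig | None = None,
) -> ReprogramomeResults:
    """File-in, directory-out convenience wrapper around the model."""
    model = ReprogramomeModel.from_files(counts_path, design_path, catalog, config)
    results = model.fit()
    results.save(outdir)
    return results
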