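"""Seeded synthetic RNA-seq counts with planted state and response classes.

The generator emulates the design of the reprogramming study this package
analyses: five sample groups — ESC (target state), naive fibroblast (start
state), GFP-transduced fibroblast (vector control), and OSKM-transduced
fibroblasts harvested at 48 h and 72 h — with four biological replicates
each. Counts are negative binomial with variance mu + alpha * mu^2
(dispersion alpha, default 0.05, typical of well-replicated bulk RNA-seq)
on top of log-normal library-size factors (sd 0.15). Each gene carries a
planted state class (its ESC and fibroblast means) and a planted response
class (the endpoint its OSKM mean moves toward); OSKM means at each time
point are interpolated geometrically from the fibroblast mean toward the
endpoint (fraction 0.8 at 48 h, 1.0 at 72 h).

Default class means put "active" genes well above the activity threshold
of 50 (400 for the base active level, 5 for silent) and plant an 8-fold
enrichment for the enriched classes; blocks that exercise the
insufficient / over legitimacy subclasses use wider state folds so the
planted trajectory geometry is unambiguous. A deliberately hostile
"marginal" block sits at activity ~50 and fold ~2 to exercise the strict
boundary semantics; its recovery is reported, never asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleDesign

STATE_CLASSES = (
    "activatome",
    "erasome",
    "up_enriched",
    "down_enriched",
    "equal_active",
    "inactive_both",
    "marginal",
)

RESPONSE_CLASSES = (
    "legit_proper",
    "legit_insufficient",
    "over",
    "wrong",
    "unwanted",
    "irresponsive",
    "none",
)

#: planted state class -> category label the pipeline should recover
EXPECTED_STATE_CATEGORY = {
    "activatome": "activatome",
    "erasome": "erasome",
    "up_enriched": "upreprogramome_enriched",
    "down_enriched": "downreprogramome_enriched",
    "equal_active": "equal_active",
    "inactive_both": "inactive_both",
    "marginal": "marginal",
}


@dataclass(frozen=True)
class GeneBlock:
    """A homogeneous block of planted genes.

    ``esc_mean``/``fib_mean`` set the state class; ``oskm_end`` is the
    OSKM-mean endpoint the induced samples interpolate toward (defaults to
    the fibroblast mean, i.e. no response).
    """

    state_class: str
    response_class: str
    n: int
    esc_mean: float
    fib_mean: float
    oskm_end: float | None = None
    prefix: str = ""
    symbols: tuple[str, ...] = ()

    def endpoint(self) -> float:
        return self.fib_mean if self.oskm_end is None else self.oskm_end


# base levels: active genes sit well above the activity threshold of 50,
# silent genes well below; the default enriched fold is 8
ACTIVE = 400.0
SILENT = 5.0
FOLD = 8.0


def default_blocks() -> list[GeneBlock]:
    """The default planted design (500 study genes + 4 exogenous factors)."""
    B = GeneBlock
    blocks = [
        # activatome: ESC-specific genes
        B("activatome", "legit_proper", 20, ACTIVE, SILENT, ACTIVE),
        B("activatome", "irresponsive", 30, ACTIVE, SILENT, SILENT),
        B("activatome", "none", 10, ACTIVE, SILENT),
        # erasome: fibroblast-specific genes
        B("erasome", "legit_proper", 20, SILENT, ACTIVE, SILENT),
        B("erasome", "irresponsive", 30, SILENT, ACTIVE, ACTIVE),
        B("erasome", "none", 10, SILENT, ACTIVE),
        # ESC-enriched (up-reprogramome beyond the activatome)
        B("up_enriched", "legit_proper", 18, FOLD * 100, 100.0, FOLD * 100),
        B("up_enriched", "legit_insufficient", 15, 3200.0, 100.0, 400.0),
        B("up_enriched", "over", 8, 400.0, 100.0, 2400.0),
        B("up_enriched", "wrong", 7, 800.0, 100.0, 25.0),  # downregulated instead
        B("up_enriched", "irresponsive", 24, FOLD * 100, 100.0, 100.0),
        B("up_enriched", "none", 8, FOLD * 100, 100.0),
        # fibroblast-enriched (down-reprogramome beyond the erasome)
        B("down_enriched", "legit_proper", 18, 100.0, FOLD * 100, 100.0),
        B("down_enriched", "legit_insufficient", 15, 100.0, 3200.0, 800.0),
        B("down_enriched", "over", 8, 400.0, 1600.0, 100.0),
        B("down_enriched", "wrong", 7, 100.0, 800.0, 3200.0),  # upregulated instead
        B("down_enriched", "irresponsive", 24, 100.0, FOLD * 100, FOLD * 100),
        B("down_enriched", "none", 8, 100.0, FOLD * 100),
        # active with equal expression; unwanted responses move them anyway
        B("equal_active", "unwanted", 10, ACTIVE, ACTIVE, 1600.0),
        B("equal_active", "none", 90, ACTIVE, ACTIVE),
        # silent in both; unwanted de novo activation
        B("inactive_both", "unwanted", 5, SILENT, SILENT, 1600.0),
        B("inactive_both", "none", 95, SILENT, SILENT),
        # hostile boundary genes: activity ~50, fold ~2
        B("marginal", "none", 20, 70.0, 35.0),
        # exogenous reprogramming factors: transgene-driven overexpression
        B(
            "up_enriched",
            "none",
            4,
            FOLD * 100,
            100.0,
            2000.0,
            symbols=("POU5F1", "SOX2", "KLF4", "MYC"),
        ),
    ]
    return blocks


@dataclass
class SimSpec:
    """Full specification of one synthetic dataset."""

    blocks: list[GeneBlock] = field(default_factory=default_blocks)
    dispersion: float = 0.05
    n_replicates: int = 4
    library_size_sd: float = 0.15
    time_points: tuple[float, ...] = (48.0, 72.0)
    #: geometric interpolation fraction from fibroblast mean toward the
    #: endpoint, per time point
    time_fractions: dict = field(default_factory=lambda: {48.0: 0.8, 72.0: 1.0})
    seed: int = 0
    target_group: str = "ESC"
    start_group: str = "fibroblast_naive"
    control_group: str = "fibroblast_GFP"
    response_group: str = "OSKM"

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group")
        for b in self.blocks:
            if b.n < 0 or b.esc_mean < 0 or b.fib_mean < 0:
                raise ValueError(f"invalid block: {b}")
            if b.state_class not in STATE_CLASSES:
                raise ValueError(f"unknown state class: {b.state_class}")
            if b.response_class not in RESPONSE_CLASSES:
                raise ValueError(f"unknown response class: {b.response_class}")
        for t in self.time_points:
            if t not in self.time_fractions:
                raise ValueError(f"no interpolation fraction for time point {t}")

    @property
    def n_genes(self) -> int:
        return sum(b.n for b in self.blocks)


def _nb(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with variance mu + alpha * mu^2 (Poisson at mu == 0)."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        size = 1.0 / alpha
        p = size / (size + mu[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def simulate(spec: SimSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw one dataset; return the counts and the planted truth table.

    The truth table has one row per gene: ``state_class``,
    ``response_class``, the planted means, and the OSKM endpoint. The same
    seed always reproduces the identical matrix.
    """
    rng = np.random.default_rng(spec.seed)

    genes: list[str] = []
    truth_rows = []
    mean_esc, mean_fib, end = [], [], []
    counter = 0
    for b in spec.blocks:
        for i in range(b.n):
            if b.symbols:
                sym = b.symbols[i]
            else:
                counter += 1
                sym = f"{b.prefix or 'TF'}{counter:04d}"
            genes.append(sym)
            truth_rows.append(
                (sym, b.state_class, b.response_class, b.esc_mean, b.fib_mean, b.endpoint())
            )
            mean_esc.append(b.esc_mean)
            mean_fib.append(b.fib_mean)
            end.append(b.endpoint())
    mean_esc = np.array(mean_esc)
    mean_fib = np.array(mean_fib)
    end = np.array(end)

    # geometric interpolation from the fibroblast level toward the endpoint
    pc = 0.5
    oskm_means = {}
    for t in spec.time_points:
        f = spec.time_fractions[t]
        ratio = (end + pc) / (mean_fib + pc)
        oskm_means[t] = np.maximum((mean_fib + pc) * ratio**f - pc, 0.0)

    groups: list[tuple[str, float | None, np.ndarray]] = [
        (spec.target_group, None, mean_esc),
        (spec.start_group, None, mean_fib),
        (spec.control_group, None, mean_fib),
    ]
    for t in spec.time_points:
        groups.append((spec.response_group, t, oskm_means[t]))

    design_rows = []
    cols = {}
    for gname, t, mu in groups:
        for r in range(1, spec.n_replicates + 1):
            sname = f"{gname}_r{r}" if t is None else f"{gname}_{t:g}h_r{r}"
            lib = float(np.exp(rng.normal(0.0, spec.library_size_sd)))
            cols[sname] = _nb(rng, mu * lib, spec.dispersion)
            design_rows.append((sname, gname, t if t is not None else np.nan, r))

    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    design = SampleDesign(
        pd.DataFrame(design_rows, columns=["sample", "group", "time_h", "replicate"])
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene", "state_class", "response_class", "esc_mean", "fib_mean", "oskm_end"],
    ).set_index("gene")
    return CountMatrix(counts, design), truth


def simulate_null(
    n_genes: int,
    n_per_group: int = 4,
    mu: float = 200.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> CountMatrix:
    """Two identical NB groups, for type-I-error calibration checks."""
    rng = np.random.default_rng(seed)
    size = 1.0 / dispersion
    p = size / (size + mu)
    cols = {}
    design_rows = []
    for g in ("A", "B"):
        for r in range(1, n_per_group + 1):
            sname = f"{g}_r{r}"
            cols[sname] = rng.negative_binomial(size, p, size=n_genes)
            design_rows.append((sname, g, np.nan, r))
    counts = pd.DataFrame(
        cols, index=pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene")
    )
    design = SampleDesign(
        pd.DataFrame(design_rows, columns=["sample", "group", "time_h", "replicate"])
    )
    return CountMatrix(counts, design)


def recovery_report(truth: pd.DataFrame, state_calls: pd.DataFrame) -> pd.DataFrame:
    """Confusion matrix of planted state classes vs recovered categories.

    Rows are planted classes (row sums equal planted class sizes), columns
    the pipeline's categories.
    """
    if set(truth.index) != set(state_calls.index):
        a_only = sorted(set(truth.index) - set(state_calls.index))[:5]
        b_only = sorted(set(state_calls.index) - set(truth.index))[:5]
        raise ValueError(
            f"gene universe mismatch between truth and calls "
            f"(truth-only: {a_only}, calls-only: {b_only})"
        )
    planted = truth["state_class"].map(EXPECTED_STATE_CATEGORY)
    called = state_calls["category"].reindex(truth.index)
    tab = pd.crosstab(planted, called, rownames=["planted"], colnames=["called"])
    return tab


def recovery_rates(confusion: pd.DataFrame) -> pd.Series:
    """Per-class fraction of genes recovering their planted category."""
    rates = {}
    for cls in confusion.index:
        total = confusion.loc[cls].sum()
        hit = confusion.loc[cls, cls] if cls in confusion.columns else 0
        rates[cls] = hit / total if total else np.nan
    return pd.Series(rates, name="recovery")
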