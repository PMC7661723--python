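"""Transcription-factor catalog loading, curation, and family queries.

The catalog is modeled on the Lambert census of 1639 human TFs. Public TF
lists carry a handful of symbols that are stale or unusable against current
Ensembl annotation, so loading applies two curation steps:

* alias remapping to current official symbols (e.g. ``ZNF645`` -> ``CBLL2``,
  ``T`` -> ``TBXT``, ``ZUFSP`` -> ``ZUP1``, ``ZZZ3`` -> ``AC118549.1``);
* exclusion of entries that cannot be evaluated (``ZNF788`` is a pseudogene;
  ``DUX1`` and ``DUX3`` are not annotated).

Excluded entries are retained with a reason so the raw entry count is always
recoverable: ``len(active) + len(excluded) == raw entries``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: Default alias remapping applied when loading a catalog.
DEFAULT_REMAP: dict[str, str] = {
    "ZNF645": "CBLL2",
    "T": "TBXT",
    "ZUFSP": "ZUP1",
    "ZZZ3": "AC118549.1",
}

#: Default exclusions: symbol -> reason.
DEFAULT_EXCLUDE: dict[str, str] = {
    "ZNF788": "pseudogene",
    "DUX1": "not annotated",
    "DUX3": "not annotated",
}

#: Controlled vocabulary for family labels.
FAMILIES = (
    "zinc finger",
    "HOX",
    "forkhead",
    "T-box",
    "SOX",
    "POU",
    "SALL",
    "other",
)

# Symbol-prefix heuristic used when the catalog file carries no family
# annotation. Zinc-finger designations follow the usual census convention
# (ZNF/ZFP/ZIC/ZSCAN/GATA/KLF/ZBTB families are all zinc-finger classes).
# SALL genes are zinc fingers too but are reported under their own name,
# so the named-family prefixes are checked first.
_NAMED_PREFIXES = (
    ("HOX", "HOX"),
    ("FOX", "forkhead"),
    ("TBX", "T-box"),
    ("SOX", "SOX"),
    ("POU", "POU"),
    ("SALL", "SALL"),
)
_ZF_PREFIXES = ("ZNF", "ZFP", "ZIC", "ZSCAN", "GATA", "KLF", "ZBTB")


def infer_family(symbol: str) -> str:
    """Assign a family label from the gene-symbol prefix."""
    s = symbol.upper()
    for prefix, fam in _NAMED_PREFIXES:
        if s.startswith(prefix):
            return fam
    for prefix in _ZF_PREFIXES:
        if s.startswith(prefix):
            return "zinc finger"
    return "other"


@dataclass
class TFCatalog:
    """Curated TF catalog.

    ``entries`` has one row per raw catalog entry with columns
    ``symbol`` (post-remap), ``family``, ``aliases`` (pre-remap symbols,
    comma-joined), ``excluded`` (bool) and ``exclusion_reason``.
    """

    entries: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"symbol", "family", "aliases", "excluded", "exclusion_reason"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"catalog entries missing columns: {sorted(missing)}")
        active = self.entries.loc[~self.entries["excluded"], "symbol"]
        dup = active[active.duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate catalog symbols after curation: {sorted(dup)}")

    @property
    def active(self) -> pd.DataFrame:
        return self.entries.loc[~self.entries["excluded"]]

    @property
    def excluded(self) -> pd.DataFrame:
        return self.entries.loc[self.entries["excluded"]]

    @property
    def symbols(self) -> set[str]:
        """Active (evaluable) symbols."""
        return set(self.active["symbol"])

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def family_of(self, symbol: str) -> str:
        hit = self.entries.loc[self.entries["symbol"] == symbol, "family"]
        if hit.empty:
            raise KeyError(f"symbol not in catalog: {symbol}")
        return hit.iloc[0]

    def save(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def load_catalog(
    path: str | Path,
    remap: Mapping[str, str] | None = None,
    exclude: Mapping[str, str] | None = None,
) -> TFCatalog:
    """Load a TF catalog from a headered delimited table.

    The first column named ``symbol`` (case-insensitive) is required; an
    optional ``family`` column overrides the prefix heuristic; an optional
    ``aliases`` column is carried through.

    Parameters
    ----------
    path
        TSV/CSV file with at least a symbol column.
    remap
        Alias table mapping stale symbols to official ones. ``None`` uses
        :data:`DEFAULT_REMAP`; pass ``{}`` to disable remapping.
    exclude
        Symbols to flag as excluded, mapped to a reason. ``None`` uses
        :data:`DEFAULT_EXCLUDE`; pass ``{}`` to disable.
    """
    remap = DEFAULT_REMAP if remap is None else dict(remap)
    exclude = DEFAULT_EXCLUDE if exclude is None else dict(exclude)

    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    cols = {c.lower(): c for c in raw.columns}
    if "symbol" not in cols:
        raise ValueError(f"catalog file {path} has no 'symbol' column")

    symbols = raw[cols["symbol"]].str.strip()
    new_symbols = symbols.map(lambda s: remap.get(s, s))
    aliases = [orig if orig != new else "" for orig, new in zip(symbols, new_symbols)]

    if "family" in cols:
        family = [
            fam.strip() if fam.strip() else infer_family(sym)
            for fam, sym in zip(raw[cols["family"]], new_symbols)
        ]
    else:
        family = [infer_family(sym) for sym in new_symbols]

    # exclusion matches either the official or the pre-remap symbol
    excluded_flags, reasons = [], []
    for orig, new in zip(symbols, new_symbols):
        reason = exclude.get(new, exclude.get(orig, ""))
        excluded_flags.append(bool(reason))
        reasons.append(reason)

    entries = pd.DataFrame(
        {
            "symbol": new_symbols.to_numpy(),
            "family": family,
            "aliases": aliases,
            "excluded": excluded_flags,
            "exclusion_reason": reasons,
        }
    )
    active = entries.loc[~entries["excluded"], "symbol"]
    dup = active[active.duplicated()].unique()
    if len(dup):
        raise ValueError(
            "alias remapping produced duplicate symbols: " + ", ".join(sorted(dup))
        )
    return TFCatalog(entries)


def family_counts(catalog: TFCatalog, gene_set: Iterable[str]) -> dict[str, int]:
    """Tally catalog families over ``gene_set``.

    Unknown-family genes count under ``"other"``. Every symbol must be an
    active catalog entry; offenders are reported together.
    """
    genes = list(gene_set)
    known = catalog.symbols
    offenders = sorted(g for g in genes if g not in known)
    if offenders:
        raise KeyError(f"symbols absent from catalog: {offenders}")
    fam_map = dict(zip(catalog.active["symbol"], catalog.active["family"]))
    counts: dict[str, int] = {}
    for g in genes:
        fam = fam_map.get(g) or "other"
        if fam not in FAMILIES:
            fam = "other"
        counts[fam] = counts.get(fam, 0) + 1
    return counts
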