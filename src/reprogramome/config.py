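"""Run configuration: group roles, thresholds, contrast grid, provenance."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .legitimacy import LegitimacyParams
from .response import DEFAULT_FACTORS, ResponseThresholds
from .state import StateThresholds


@dataclass
class GroupRoles:
    """Mapping from analysis role to group label in the design table."""

    target: str = "ESC"
    start: str = "fibroblast_naive"
    control: str | None = "fibroblast_GFP"
    response: str = "OSKM"

    @property
    def references(self) -> list[str]:
        refs = [self.start]
        if self.control:
            refs.append(self.control)
        return refs


@dataclass
class RunConfig:
    """Everything a run needs beyond the data files themselves.

    Serialized verbatim into the output directory so a run can be
    reproduced byte-identically from its own provenance record.
    """

    roles: GroupRoles = field(default_factory=GroupRoles)
    state: StateThresholds = field(default_factory=StateThresholds)
    response: ResponseThresholds = field(default_factory=ResponseThresholds)
    legitimacy: LegitimacyParams = field(default_factory=LegitimacyParams)
    factors: tuple[str, ...] = tuple(sorted(DEFAULT_FACTORS))
    #: response time points (hours); None = every time point in the design
    time_points: tuple[float, ...] | None = None
    #: catalog curation rules; None = package defaults
    catalog_remap: dict | None = None
    catalog_exclude: dict | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["factors"] = list(self.factors)
        if self.time_points is not None:
            d["time_points"] = list(self.time_points)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs: dict = {}
        if "roles" in d:
            kwargs["roles"] = GroupRoles(**d.pop("roles"))
        for key, typ in (
            ("state", StateThresholds),
            ("response", ResponseThresholds),
            ("legitimacy", LegitimacyParams),
        ):
            if key in d:
                kwargs[key] = typ(**d.pop(key))
        if "factors" in d:
            kwargs["factors"] = tuple(d.pop("factors"))
        if d.get("time_points") is not None:
            kwargs["time_points"] = tuple(float(t) for t in d.pop("time_points"))
        else:
            d.pop("time_points", None)
        for key in ("catalog_remap", "catalog_exclude", "seed"):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
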