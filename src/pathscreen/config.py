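"""Run configuration: every screen threshold, with the published defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .mixture import EMConfig


@dataclass
class ScreenConfig:
    """Thresholds of the biomarker screen.

    sensitive_max / resistant_min: per-entity z-score cut-offs labelling a
    cell line sensitive (z <= -1.5) or not sensitive (z >= 0); lines in
    between are excluded.
    promiscuity_max_fraction: a cell line sensitive to more than this
    fraction of compounds is dropped from a drug screen entirely.
    compound_max_min_auc: within a tissue, a compound whose minimal dr-AUC
    exceeds this shows no real response and is omitted (``None`` disables).
    pathway_min_range: pathways whose activity range across samples is <=
    this are omitted as non-variable.
    q_significant / q_near_significant: BH q-value tier boundaries.
    min_group_size: fewest cell lines per arm for a Mann-Whitney test.
    reclassify_after_promiscuity_filter: recompute z-scores and labels on the
    reduced cell-line set after promiscuous lines are dropped.
    """

    sensitive_max: float = -1.5
    resistant_min: float = 0.0
    promiscuity_max_fraction: float = 0.20
    compound_max_min_auc: float | None = 8.0
    pathway_min_range: float = 0.1
    q_significant: float = 0.05
    q_near_significant: float = 0.25
    min_group_size: int = 3
    reclassify_after_promiscuity_filter: bool = False
    seed: int | None = None
    em: EMConfig = field(default_factory=EMConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        em = EMConfig(**raw.pop("em", {}))
        return cls(em=em, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
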