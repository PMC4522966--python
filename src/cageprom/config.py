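"""Analysis-wide thresholds.

Every numeric rule the pipeline applies lives in one dataclass so a run is
fully described by its config: detection (>5 TPM in at least one sample),
per-sample expression (>1 TPM), novelty distance from annotated TSSs
(>500 bp), ChIP intersection padding (±500 bp), TATA-box upstream window
(500 bp), CpG-island vicinity (±500 bp), enhancer search window (500 kb),
Bonferroni alpha (0.05), TFBS posterior retention (>=0.2) and reporting
(>0.7) cutoffs, TFBS summation window (±500 bp), the background promoter
population size (184,827 human / 116,227 mouse), and the sharp/broad shape
rule (best 5-nt window > 0.5 of the densest 50-bp cluster).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["AnalysisConfig", "HUMAN_BACKGROUND_N", "MOUSE_BACKGROUND_N"]

HUMAN_BACKGROUND_N = 184_827
MOUSE_BACKGROUND_N = 116_227


@dataclass(frozen=True)
class AnalysisConfig:
    tpm_detect_threshold: float = 5.0
    tpm_expressed_threshold: float = 1.0
    novelty_distance: int = 500
    chip_expand: int = 500
    tata_upstream: int = 500
    cpg_vicinity: int = 500
    enhancer_max_distance: int = 500_000
    link_alpha: float = 0.05
    posterior_min: float = 0.2
    site_report_min: float = 0.7
    tfbs_window: int = 500
    background_n: int = HUMAN_BACKGROUND_N
    sharp_window: int = 5
    sharp_fraction: float = 0.5
    cluster_window: int = 50

    def __post_init__(self) -> None:
        positive = (
            "tpm_detect_threshold",
            "tpm_expressed_threshold",
            "novelty_distance",
            "chip_expand",
            "tata_upstream",
            "cpg_vicinity",
            "enhancer_max_distance",
            "link_alpha",
            "posterior_min",
            "site_report_min",
            "tfbs_window",
            "background_n",
            "sharp_window",
            "cluster_window",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.sharp_fraction < 1.0):
            raise ValueError("sharp_fraction must be in (0, 1)")
        if self.sharp_window > self.cluster_window:
            raise ValueError("sharp_window must not exceed cluster_window")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
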