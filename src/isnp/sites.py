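"""Shared gain/loss/neutral site-change records.

A regulatory site change for a SNP is called by comparing the sites found on
the ancestral and variant allele windows.  Only sites whose interval covers
the SNP base itself count; a site present on the ancestral allele alone is a
loss, on the variant alone a gain, on both a neutral change.  Neutral
records are retained for reporting but never propagate into patient network
footprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GAIN, LOSS, NEUTRAL = "gain", "loss", "neutral"


@dataclass
class SiteChange:
    rsid: str
    regulator_id: str  # TF motif ID or miRNA ID
    target_genes: frozenset[str]
    change: str  # gain | loss | neutral
    site_type: str  # tfbs_promoter | tfbs_enhancer | mirna_ts
    evidence: list = field(default_factory=list)

    def __post_init__(self):
        if self.change not in (GAIN, LOSS, NEUTRAL):
            raise ValueError(f"bad change {self.change!r}")

    @property
    def propagates(self) -> bool:
        """Only gains and losses mark a gene as SNP-affected."""
        return self.change != NEUTRAL


def classify_change(ancestral_present: bool, variant_present: bool) -> str | None:
    """Gain/loss/neutral from per-allele site presence; None when absent on both."""
    if ancestral_present and variant_present:
        return NEUTRAL
    if ancestral_present:
        return LOSS
    if variant_present:
        return GAIN
    return None
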