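"""Closed region vocabularies used throughout the pipeline.

Regional tracer activity is measured on ROIs covering six cortical regions
plus the four candidate reference structures (cerebellar gray and white
matter, pons, subcortical white matter).  Visual reads score a slightly
different set of four cortical regions (posterior cingulate is read jointly
with the precuneus), and histopathology is available only for the two
regions that are both stained and visually assessed.
"""

from __future__ import annotations

# Cortical target regions entering the composite SUVR (arithmetic mean of 6).
COMPOSITE_REGIONS: tuple[str, ...] = (
    "frontal",
    "occipital",
    "parietal",
    "lateral_temporal",
    "anterior_cingulate",
    "posterior_cingulate",
)

# Non-cortical structures needed to build reference-region activities.
SUPPORT_REGIONS: tuple[str, ...] = (
    "cerebellar_gray",
    "cerebellar_white",
    "pons",
    "subcortical_white",
)

ACTIVITY_REGIONS: tuple[str, ...] = COMPOSITE_REGIONS + SUPPORT_REGIONS

# Reference regions used as SUVR denominators.
REFERENCE_REGIONS: tuple[str, ...] = ("GCER", "WCER", "PONS", "SWM")

# Activity ROI backing each reference region; WCER is derived (gray+white mean).
REFERENCE_SOURCE: dict[str, str] = {
    "GCER": "cerebellar_gray",
    "PONS": "pons",
    "SWM": "subcortical_white",
}

# Regions scored visually on the 3-level regional cortical tracer uptake scale.
VISUAL_REGIONS: tuple[str, ...] = (
    "lateral_temporal",
    "frontal",
    "parietal",
    "posterior_cingulate_precuneus",
)

# Regions with dual-stain histopathology that were also visually assessed.
PATHOLOGY_REGIONS: tuple[str, ...] = ("frontal", "posterior_cingulate")

# Targets for which positivity cutoffs are generated (5 x 4 grid).
CUTOFF_TARGETS: tuple[str, ...] = (
    "composite",
    "frontal",
    "lateral_temporal",
    "parietal",
    "posterior_cingulate",
)

# SUVR target region -> visual region carrying its per-region truth label.
TARGET_TO_VISUAL: dict[str, str] = {
    "frontal": "frontal",
    "lateral_temporal": "lateral_temporal",
    "parietal": "parietal",
    "posterior_cingulate": "posterior_cingulate_precuneus",
}
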