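"""Canonical grouping-feature / trait catalogue for stream macroinvertebrates.

Grouping features partition the traits: every trait belongs to exactly one
feature.  User-supplied affinity tables may use any free-text taxon and trait
names; this catalogue is the default vocabulary used by the synthetic-data
generator and the bundled examples.
"""

from __future__ import annotations

TRAIT_CATALOG: dict[str, tuple[str, ...]] = {
    "feeding_style": (
        "absorber",
        "deposit_feeder",
        "filter_feeder",
        "parasite",
        "piercer",
        "predator",
        "scraper",
        "shredder",
    ),
    "respiration_mode": ("gill", "plastron", "spiracle", "tegument"),
    "locomotion_mode": (
        "burrower",
        "crawler",
        "flier",
        "full_water_swimmer",
        "interstitial_endobenthic",
        "surface_swimmer",
        "temporarily_attached",
    ),
    "reproduction_mode": (
        "clutches_cemented",
        "clutches_free",
        "clutches_terrestrial",
        "clutches_in_vegetation",
        "isolated_eggs_cemented",
        "isolated_eggs_free",
        "oviviparity",
    ),
    "sizes": (
        "size1_le_0.25cm",
        "size2_0.25_0.5cm",
        "size3_0.5_1cm",
        "size4_1_2cm",
        "size5_2_4cm",
        "size6_4_8cm",
        "size7_gt_8cm",
    ),
}

GROUPING_FEATURES: tuple[str, ...] = tuple(TRAIT_CATALOG)

MAX_AFFINITY = 5
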