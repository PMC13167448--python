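"""Synthetic approximation of the Whittaker biome diagram.

Nine biomes delimited in (mean annual temperature, deg C) x (annual
precipitation, cm) space.  The vertex lists below are a simplified,
hand-specified tiling that preserves the relative positions of the nine
classic biomes (cold/low-precipitation tundra through hot/wet tropical rain
forest); they are *not* digitized from any published diagram, so absolute
boundary positions are approximate.  Points falling outside every polygon
are assigned downstream to the nearest polygon in standardized space.

Version 1 — vertices in (temperature_C, precipitation_cm), counter-clockwise.
"""

from __future__ import annotations

FIXTURE_VERSION = 1

#: biome id -> (name, vertex list); ids are stable and start at 1.
BIOME_POLYGONS: dict[int, tuple[str, list[tuple[float, float]]]] = {
    1: ("tundra", [(-25.0, 0.0), (-5.0, 0.0), (-5.0, 70.0), (-25.0, 70.0)]),
    2: ("boreal forest", [(-5.0, 0.0), (3.0, 0.0), (3.0, 120.0), (-5.0, 120.0)]),
    3: ("temperate grassland/desert", [(3.0, 0.0), (22.0, 0.0), (22.0, 25.0), (3.0, 25.0)]),
    4: ("woodland/shrubland", [(3.0, 25.0), (22.0, 25.0), (22.0, 60.0), (3.0, 60.0)]),
    5: ("temperate seasonal forest", [(3.0, 60.0), (22.0, 60.0), (22.0, 180.0), (3.0, 180.0)]),
    6: ("temperate rain forest", [(3.0, 180.0), (22.0, 180.0), (22.0, 350.0), (3.0, 350.0)]),
    7: ("subtropical desert", [(22.0, 0.0), (32.0, 0.0), (32.0, 60.0), (22.0, 60.0)]),
    8: ("tropical seasonal forest/savanna", [(22.0, 60.0), (32.0, 60.0), (32.0, 230.0), (22.0, 230.0)]),
    9: ("tropical rain forest", [(22.0, 230.0), (32.0, 230.0), (32.0, 450.0), (22.0, 450.0)]),
}

BIOME_NAMES: dict[int, str] = {k: v[0] for k, v in BIOME_POLYGONS.items()}
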