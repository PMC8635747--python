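"""Controlled vocabularies: wild-tomato taxa, phylogenetic groups, and the
categorical climate / soil-unit class lists.

The sixteen taxa are the twelve wild tomato species of *Solanum* sect.
Lycopersicon plus the four closely related species of sections Juglandifolia
and Lycopersicoides, partitioned into the standard six phylogenetic groups
(Lycopersicon, Arcanum, Eriopersicon, Neolycopersicon, Juglandifolia,
Lycopersicoides).
"""

from __future__ import annotations

from dataclasses import dataclass

GROUP_LABELS: dict[int, str] = {
    1: "Lycopersicon",
    2: "Arcanum",
    3: "Eriopersicon",
    4: "Neolycopersicon",
    5: "Juglandifolia",
    6: "Lycopersicoides",
}

#: species -> group id; the six groups partition the sixteen taxa.
SPECIES_GROUPS: dict[str, int] = {
    "Solanum pimpinellifolium": 1,
    "Solanum cheesmaniae": 1,
    "Solanum galapagense": 1,
    "Solanum arcanum": 2,
    "Solanum chmielewskii": 2,
    "Solanum neorickii": 2,
    "Solanum habrochaites": 3,
    "Solanum huaylasense": 3,
    "Solanum corneliomulleri": 3,
    "Solanum peruvianum": 3,
    "Solanum chilense": 3,
    "Solanum pennellii": 4,
    "Solanum juglandifolium": 5,
    "Solanum ochranthum": 5,
    "Solanum lycopersicoides": 6,
    "Solanum sitiens": 6,
}

SPECIES: tuple[str, ...] = tuple(SPECIES_GROUPS)

#: Default per-species elevational envelopes (metres above sea level) used by
#: the occurrence-cleaning altitude filter.  Values follow the published
#: per-species altitude ranges for these taxa.
ALTITUDE_RANGES_M: dict[str, tuple[float, float]] = {
    "Solanum cheesmaniae": (5.0, 1478.0),
    "Solanum galapagense": (4.0, 868.0),
    "Solanum pimpinellifolium": (1.0, 1774.0),
    "Solanum arcanum": (132.0, 3292.0),
    "Solanum chmielewskii": (1803.0, 3195.0),
    "Solanum neorickii": (1202.0, 3262.0),
    "Solanum huaylasense": (978.0, 3304.0),
    "Solanum corneliomulleri": (1018.0, 3097.0),
    "Solanum peruvianum": (2.0, 3191.0),
    "Solanum chilense": (0.0, 3995.0),
    "Solanum habrochaites": (40.0, 3692.0),
    "Solanum pennellii": (5.0, 2921.0),
    "Solanum juglandifolium": (1005.0, 3153.0),
    "Solanum ochranthum": (1195.0, 4008.0),
    "Solanum lycopersicoides": (1290.0, 3775.0),
    "Solanum sitiens": (2276.0, 3330.0),
}


@dataclass(frozen=True)
class SpeciesGroupMap:
    """Mapping of species names to phylogenetic group ids (1-6)."""

    groups: dict[str, int]
    labels: dict[int, str]

    def group_of(self, species: str) -> int:
        try:
            return self.groups[species]
        except KeyError:
            raise KeyError(f"species not in group map: {species!r}") from None

    def label_of(self, species: str) -> str:
        return self.labels[self.group_of(species)]

    def species_in(self, group_id: int) -> list[str]:
        return [s for s, g in self.groups.items() if g == group_id]


DEFAULT_GROUP_MAP = SpeciesGroupMap(groups=SPECIES_GROUPS, labels=GROUP_LABELS)

# --- categorical class vocabularies ---------------------------------------

#: Koeppen-Geiger climate classes (30 codes).
KOPPEN_CLASSES: tuple[str, ...] = (
    "Af", "Am", "Aw", "BWh", "BWk", "BSh", "BSk",
    "Csa", "Csb", "Csc", "Cwa", "Cwb", "Cwc",
    "Cfa", "Cfb", "Cfc",
    "Dsa", "Dsb", "Dsc", "Dsd", "Dwa", "Dwb", "Dwc", "Dwd",
    "Dfa", "Dfb", "Dfc", "Dfd",
    "ET", "EF",
)

#: FAO/HWSD soil units (28 codes).
SOIL_UNITS: tuple[str, ...] = (
    "AC", "AL", "AN", "AR", "AT", "CH", "CL", "CM", "FL", "FR",
    "GL", "GR", "GY", "HS", "KS", "LP", "LV", "LX", "NT", "PD",
    "PH", "PL", "PT", "PZ", "RG", "SC", "SN", "VR",
)

#: Default integer raster code -> class symbol dictionaries (codes start at 1).
KOPPEN_CODE_DICT: dict[int, str] = {i + 1: c for i, c in enumerate(KOPPEN_CLASSES)}
SOIL_CODE_DICT: dict[int, str] = {i + 1: c for i, c in enumerate(SOIL_UNITS)}

#: Environmental variable codes of the standard 35-layer information system:
#: 19 bioclimatic layers, annual evapotranspiration, altitude, and 14 soil
#: attributes.
CLIMATE_VARIABLES: tuple[str, ...] = tuple(f"Bio{i}" for i in range(1, 20)) + ("ET",)
GEOGRAPHIC_VARIABLES: tuple[str, ...] = ("Alt",)
SOIL_VARIABLES: tuple[str, ...] = (
    "GR", "SA", "SI", "CL", "BD", "CO", "pH", "CEC", "BS",
    "CaCO3", "TEB", "CaSO4", "SAL", "SOD",
)
ALL_VARIABLES: tuple[str, ...] = CLIMATE_VARIABLES + GEOGRAPHIC_VARIABLES + SOIL_VARIABLES
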