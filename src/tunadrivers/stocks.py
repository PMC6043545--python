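"""Registry of the assessed tuna stocks used throughout the pipeline.

Each stock code encodes an ocean basin prefix and a species suffix
(e.g. ``WCPOSKJ`` = western and central Pacific skipjack).  The registry
maps every stock to the ocean region used for the stock dummy variables,
the species (``ALB``, ``BET``, ``BFT``, ``SKJ``, ``YFT``) and the tuna
regional fisheries management organisation (tRFMO) whose gridded
catch-effort data cover it.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StockInfo:
    code: str
    region: str
    species: str
    org: str


#: The 19 stocks with usable F/Fmsy assessment series, by tRFMO.
DEFAULT_STOCKS: dict[str, StockInfo] = {
    s.code: s
    for s in [
        StockInfo("EPOBET", "EastPacific", "BET", "IATTC"),
        StockInfo("EPOYFT", "EastPacific", "YFT", "IATTC"),
        StockInfo("WCPOBET", "WestPacific", "BET", "WCPFC"),
        StockInfo("WCPOYFT", "WestPacific", "YFT", "WCPFC"),
        StockInfo("WCPOSKJ", "WestPacific", "SKJ", "WCPFC"),
        StockInfo("PONALB", "NorthPacific", "ALB", "ISC"),
        StockInfo("POSALB", "SouthPacific", "ALB", "WCPFC"),
        StockInfo("AOBET", "EastAtlantic", "BET", "ICCAT"),
        StockInfo("AOYFT", "EastAtlantic", "YFT", "ICCAT"),
        StockInfo("AOWSKJ", "WestAtlantic", "SKJ", "ICCAT"),
        StockInfo("AONALB", "NorthAtlantic", "ALB", "ICCAT"),
        StockInfo("AOSALB", "SouthAtlantic", "ALB", "ICCAT"),
        StockInfo("AOEBFT", "EastAtlantic", "BFT", "ICCAT"),
        StockInfo("AOWBFT", "WestAtlantic", "BFT", "ICCAT"),
        StockInfo("IOBET", "Indian", "BET", "IOTC"),
        StockInfo("IOYFT", "Indian", "YFT", "IOTC"),
        StockInfo("IOSKJ", "Indian", "SKJ", "IOTC"),
        StockInfo("IOALB", "Indian", "ALB", "IOTC"),
        StockInfo("SHBFT", "SouthernOcean", "BFT", "CCSBT"),
    ]
}

#: Ocean-region levels for the stock dummies (all levels encoded).
REGIONS: tuple[str, ...] = (
    "EastAtlantic",
    "EastPacific",
    "Indian",
    "NorthAtlantic",
    "NorthPacific",
    "SouthAtlantic",
    "SouthPacific",
    "SouthernOcean",
    "WestAtlantic",
    "WestPacific",
)

#: Species dummy levels; albacore (ALB) is the reference level.
SPECIES_LEVELS: tuple[str, ...] = ("BET", "BFT", "SKJ", "YFT")
SPECIES_REFERENCE = "ALB"

#: Gear dummy levels; baitboat is the reference level.
GEAR_LEVELS: tuple[str, ...] = ("gillnet", "longline", "purseseine", "trap", "troll")
GEAR_REFERENCE = "baitboat"
ALL_GEARS: tuple[str, ...] = ("baitboat",) + GEAR_LEVELS

#: Annual climate oscillation indices used as covariates.
CLIMATE_INDICES: tuple[str, ...] = (
    "EA",
    "WP",
    "EP_NP",
    "PNA",
    "DMI",
    "TNA",
    "TSA",
    "PDO",
    "SOI",
    "NAO",
)

ORGS: tuple[str, ...] = ("WCPFC", "IOTC", "ICCAT", "IATTC", "CCSBT", "ISC")


def species_of(stock_code: str) -> str:
    """Species implied by a stock code's three-letter suffix."""
    if stock_code in DEFAULT_STOCKS:
        return DEFAULT_STOCKS[stock_code].species
    return stock_code[-3:]
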