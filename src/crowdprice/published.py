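"""Summary tables of the deposited Nigerian FPCA crowdsourcing campaign.

Validated-observation counts by food product, packaging unit and outlet type
for the April–November 2021 campaign (as deposited at
https://zenodo.org/record/7261389), kept here so that headline shares and the
weekly submission volume can be recomputed without downloading the raw files.
"""

from __future__ import annotations

#: Validated observations per food product.
PRODUCT_COUNTS = {
    "local_rice": 37_013,
    "indian_rice": 12_608,
    "thailand_rice": 21_694,
    "maize_white": 25_966,
    "maize_yellow": 21_497,
    "red_beans": 18_707,
    "white_beans": 33_936,
    "white_garri": 21_199,
    "yellow_garri": 13_041,
    "soybean": 24_674,
}

#: Validated observations per packaging unit.
PACKAGING_COUNTS = {
    "Mudu/Kwano": 188_588,
    "Kongo": 255,
    "1 kg": 438,
    "5 kg": 317,
    "10 kg": 84,
    "25 kg": 364,
    "50 kg": 11_970,
    "100 kg": 28_319,
}

#: Validated observations per outlet (market) type.
MARKET_TYPE_COUNTS = {
    "Bulk and discount stores": 2_652,
    "Directly from farmer": 7_074,
    "Supermarket": 8_552,
    "Open-air markets": 137_090,
    "Neighbourhood shop": 63_730,
    "Specialised stores": 3_172,
    "Street outlets": 8_065,
}

#: Total validated observations of the campaign.
TOTAL_OBSERVATIONS = 230_335

#: ISO weeks spanned by the collection window (April–November 2021).
COLLECTION_WEEKS = 36


def shares(counts: dict) -> dict:
    """Percentage share of each category in the total count."""
    total = sum(counts.values())
    return {k: 100.0 * v / total for k, v in counts.items()}


def weekly_average(total: int = TOTAL_OBSERVATIONS, weeks: int = COLLECTION_WEEKS) -> float:
    """Mean number of observations submitted per collection week."""
    return total / weeks
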