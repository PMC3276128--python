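"""Shared fixtures: bundled screen tables and their published summaries.

The expected percentages below are the values the screen's published tables
print (two-decimal percent rendering); tests assert the package reproduces
them from the raw counts alone.
"""

from __future__ import annotations

import pytest

from ndjscreen import control_summary, datasets, ndj_frequency

# experiment id -> printed NDJ %
CONTROL_PCT = {
    "1": 16.60, "2": 19.51, "3": 21.34, "4": 22.76, "5": 22.99, "6": 23.36,
    "7": 24.54, "8": 25.00, "9": 26.39, "10": 26.96, "11": 27.41, "12": 28.06,
    "13": 28.86, "14": 31.28, "15": 32.78, "16": 35.20,
}

# genotype -> (printed NDJ %, printed adjusted total, delta matched %, delta average %, group)
MODIFIER_TABLE = {
    "Df(3L)BSC23": (34.21, 836, 14.70, 8.39, "enhancer"),
    "Df(3L)BSC13": (41.23, 1431, 18.24, 15.41, "enhancer"),
    "Df(3L)Pc-2q": (43.43, 571, 18.43, 17.61, "enhancer"),
    "Df(3R)ED5177": (34.38, 704, 9.84, 8.56, "enhancer"),
    "Df(3R)ED5780": (46.02, 113, 17.16, 20.20, "enhancer"),
    "Df(3R)D605": (42.19, 474, 17.19, 16.37, "enhancer"),
    "Df(3L)pbl-X1": (11.16, 878, -11.83, -14.66, "suppressor"),
    "Df(3L)ZP1": (17.41, 1172, -5.58, -8.41, "suppressor"),
    "Df(3L)BSC8": (17.53, 833, -7.01, -8.29, "suppressor"),
    "Df(3L)ED4858": (11.29, 638, -17.58, -14.53, "suppressor"),
    "Df(3L)rdgC-co2": (12.28, 782, -14.68, -13.54, "suppressor"),
    "Df(3L)ED4978": (10.08, 1904, -6.52, -15.74, "suppressor"),
    "Df(3L)Ten-m-AL29": (13.33, 1245, -6.17, -12.49, "suppressor"),
    "Df(3R)Tpl10": (11.49, 731, -8.02, -14.33, "suppressor"),
    "Df(3R)GB104": (3.08, 195, -13.52, -22.74, "suppressor"),
    "Df(3R)ED5559": (0.00, 270, -21.34, -25.82, "suppressor"),
    "Df(3R)sbd105": (20.16, 1280, -15.05, -5.66, "suppressor"),
    "Df(3R)ED5942": (20.94, 917, -6.47, -4.88, "suppressor"),
    "Df(3R)BSC55": (17.05, 739, -10.36, -8.77, "suppressor"),
    "Df(3R)mbc-30": (9.05, 199, -18.37, -16.77, "suppressor"),
    "Df(3R)mbc-R1": (11.07, 1464, -20.22, -14.75, "suppressor"),
    "Df(3R)Exel6202": (18.18, 1023, -10.68, -7.64, "suppressor"),
    "Df(3R)BSC42": (14.83, 2171, -16.45, -10.99, "suppressor"),
    "Df(3R)3450": (12.25, 1143, -7.26, -13.57, "suppressor"),
}

# genotype -> (printed NDJ %, printed adjusted total) for the retest table
POLO_TABLE = {
    "X/X;bubR1[D1326N]/bubR1[rev1]": (26.96, 1009),
    "Df(3L)rdgC-co2": (12.28, 782),
    "Df(3L)ED4858": (11.29, 638),
    "Df(3L)Exel6136": (1.38, 2024),
    "polo[1]/+": (19.19, 542),
    "polo[2]/+": (6.60, 1726),
    "polo[9]/+": (10.43, 1093),
}


@pytest.fixture(scope="session")
def control_rows():
    return datasets.control_experiments()


@pytest.fixture(scope="session")
def deficiency_rows():
    return datasets.deficiency_screen()


@pytest.fixture(scope="session")
def screen_rows():
    return datasets.screen_rows()


@pytest.fixture(scope="session")
def polo_rows():
    return datasets.polo_region_crosses()


@pytest.fixture(scope="session")
def region_table():
    return datasets.region_mapping()


@pytest.fixture(scope="session")
def control_band(control_rows):
    return control_summary(ndj_frequency(r.counts).ndj for r in control_rows)


@pytest.fixture(scope="session")
def controls_by_id(control_rows):
    return {r.experiment_id: r for r in control_rows}
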