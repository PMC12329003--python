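"""Published summary values for the Northwestern-Pacific *Ilisha elongata* survey.

The synthetic study design shipped with this package emulates a target-enrichment
survey of 144 elongate ilisha sampled at 18 coastal/estuarine localities in seven
marginal-sea regions, which collapse into four genetic populations (southern,
northern, Japanese, Yalu River Estuary). The tables below transcribe the survey's
printed per-locality summaries; they serve as worked-example inputs for the
statistics code and as the template for :class:`popsplit.synthetic_data.StudyDesign`.
"""

from __future__ import annotations

# locality code -> (number of sampled individuals, region)
SAMPLING_TABLE: dict[str, tuple[int, str]] = {
    "GX": (20, "South China Sea"),
    "BH": (18, "South China Sea"),
    "HA": (7, "South China Sea"),
    "ZJ": (1, "South China Sea"),
    "ZP": (3, "South China Sea"),
    "SW": (4, "South China Sea"),
    "XM": (6, "Taiwan Strait"),
    "MQ": (9, "Taiwan Strait"),
    "XP": (8, "East China Sea"),
    "WZ": (5, "East China Sea"),
    "XS": (3, "East China Sea"),
    "SS": (8, "East China Sea"),
    "YT": (8, "Yellow Sea"),
    "QD": (18, "Yellow Sea"),
    "DD": (8, "Yalu River Estuary"),
    "MP": (4, "Korean Peninsula"),
    "JJ": (5, "Korean Peninsula"),
    "AS": (9, "Japanese Archipelago"),
}

#: Genetic population each locality predominantly belongs to.  XM, XP and XS host
#: a mixture of southern and northern fish; they are tagged "mixed" and resolved
#: per individual by the synthetic generator's admixture fraction.
LOCALITY_POPULATION: dict[str, str] = {
    "GX": "southern", "BH": "southern", "HA": "southern", "ZJ": "southern",
    "ZP": "southern",
    "XM": "mixed", "XP": "mixed", "XS": "mixed",
    "SW": "northern", "MQ": "northern", "WZ": "northern", "SS": "northern",
    "YT": "northern", "QD": "northern", "MP": "northern", "JJ": "northern",
    "DD": "yalu",
    "AS": "japanese",
}

#: Observed heterozygosity at variant positions per locality (ZJ excluded: n = 1).
LOCALITY_HETEROZYGOSITY: dict[str, float] = {
    "GX": 0.2384, "BH": 0.2418, "HA": 0.2362, "ZP": 0.2194, "SW": 0.2379,
    "XM": 0.2511, "MQ": 0.2352,
    "XP": 0.2402, "WZ": 0.2466, "XS": 0.2255, "SS": 0.2467,
    "YT": 0.2608, "QD": 0.2390,
    "JJ": 0.2264, "MP": 0.2164,
    "DD": 0.1644,
    "AS": 0.2194,
}

#: Upper-triangular pairwise F_ST among the 17 retained localities.
#: Keyed by frozenset of the two locality codes.
PAIRWISE_FST: dict[frozenset, float] = {}

_FST_COLS = ["XP", "AS", "JJ", "DD", "YT", "BH", "HA", "ZP", "SW", "XM", "WZ",
             "MQ", "QD", "XS", "SS", "MP"]
_FST_ROWS: dict[str, list[float]] = {
    "GX": [0.0322, 0.0570, 0.0489, 0.0823, 0.0356, 0.0176, 0.0281, 0.0324,
           0.0422, 0.0351, 0.0405, 0.0339, 0.0340, 0.0428, 0.0348, 0.0453],
    "XP": [0.0601, 0.0516, 0.1253, 0.0336, 0.0302, 0.0483, 0.0709, 0.0495,
           0.0402, 0.0482, 0.0342, 0.0244, 0.0600, 0.0375, 0.0538],
    "AS": [0.0768, 0.1637, 0.0590, 0.0566, 0.0751, 0.1033, 0.0781, 0.0686,
           0.0749, 0.0600, 0.0434, 0.0856, 0.0621, 0.0788],
    "JJ": [0.1689, 0.0497, 0.0468, 0.0755, 0.1275, 0.0734, 0.0667, 0.0743,
           0.0516, 0.0317, 0.1030, 0.0532, 0.0851],
    "DD": [0.1303, 0.0823, 0.1231, 0.1693, 0.1671, 0.1443, 0.1555, 0.1261,
           0.1035, 0.1893, 0.1296, 0.1811],
    "YT": [0.0338, 0.0457, 0.0658, 0.0438, 0.0407, 0.0446, 0.0341, 0.0237,
           0.0567, 0.0328, 0.0510],
    "BH": [0.0256, 0.0364, 0.0422, 0.0323, 0.0406, 0.0345, 0.0334, 0.0423,
           0.0343, 0.0436],
    "HA": [0.0761, 0.0691, 0.0543, 0.0675, 0.0488, 0.0367, 0.0846, 0.0492,
           0.0785],
    "ZP": [0.1225, 0.0869, 0.1061, 0.0676, 0.0447, 0.1575, 0.0707, 0.1418],
    "SW": [0.0624, 0.0719, 0.0477, 0.0277, 0.1010, 0.0482, 0.0841],
    "XM": [0.0600, 0.0428, 0.0300, 0.0792, 0.0434, 0.0679],
    "WZ": [0.0449, 0.0294, 0.0926, 0.0489, 0.0837],
    "MQ": [0.0248, 0.0604, 0.0346, 0.0501],
    "QD": [0.0331, 0.0258, 0.0305],
    "XS": [0.0617, 0.1122],
    "SS": [0.0517],
}

for _row, _vals in _FST_ROWS.items():
    for _col, _v in zip(_FST_COLS[-len(_vals):], _vals):
        PAIRWISE_FST[frozenset((_row, _col))] = _v

#: Pre-filter SNP discovery totals for the survey.
N_SNPS_TOTAL = 10254
N_LOCI_TOTAL = 1602
#: Loci retained after MAF/missingness/depth filtering and one-SNP-per-locus thinning.
N_LOCI_RETAINED = 1392

TOTAL_INDIVIDUALS = 144
N_LOCALITIES = 18
N_REGIONS = 7
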