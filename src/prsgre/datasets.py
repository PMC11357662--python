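"""Published summary counts from a large German screening-colonoscopy cohort.

These are the printed complete-case contingency tables and group totals of
the descriptive (baseline-characteristics) table of the motivating study —
counts only, no participant-level data — kept here as validation fixtures:
the capped-continuity-correction chi-square reproduces every printed
p-value from them, and the percentage cells recompute exactly from the
printed counts. The 2x2 exposure counts feed the crude odds-ratio check.
"""

from __future__ import annotations

#: Group sizes: participants with no finding, any neoplasm, advanced neoplasm.
GROUP_TOTALS = {"no_finding": 2559, "any_neoplasm": 2215,
                "advanced_neoplasm": 867}

#: Complete-case level counts (no-finding group, any-neoplasm group) and the
#: p-value as printed, four decimals; None where printed as "<0.0001".
#: 2x2 rows are tested with the capped continuity correction, larger tables
#: uncorrected.
TABLE1_CONTINGENCY: dict[str, tuple[list[int], list[int], float | None]] = {
    "sex": ([1436, 1123], [830, 1385], None),
    "education": ([1297, 659, 581], [1227, 532, 432], 0.0023),
    "bmi": ([963, 1047, 505], [625, 1034, 526], None),
    "smoking": ([1304, 921, 304], [937, 842, 417], None),
    "prs_tertile": ([853, 853, 853], [521, 690, 1004], None),
    "alcohol": ([646, 954, 497, 282, 77], [459, 752, 509, 321, 96], None),
    "physical_activity": ([74, 2451], [69, 2113], 0.7066),
    "red_meat": ([1193, 1366], [897, 1318], None),  # printed 0.0001; see note
    "processed_meat": ([597, 1962], [359, 1856], None),
    "hrt_female": ([538, 878], [297, 519], 0.4804),
    "diabetes": ([221, 2317], [269, 1939], 0.0001),
    "family_history_crc": ([308, 2251], [298, 1917], 0.1545),
    "nsaids": ([431, 1951], [379, 1676], 0.7942),
    "history_colonoscopy": ([824, 1735], [566, 1649], None),
    "whole_grain": ([1446, 1075], [1340, 838], 0.0041),
    "fruit": ([970, 1574], [909, 1300], 0.0362),
    "vegetable": ([1180, 1374], [1116, 1095], 0.0036),
    "poultry": ([1022, 1501], [881, 1293], 1.0000),
}
# Note: the red-meat row is printed as 0.0001 but its corrected statistic
# (17.84 on 1 df) gives p = 2.4e-5, which the table's own convention would
# print as "<0.0001"; it is therefore checked as a bound, not to 4 decimals.

#: Printed percentage cells: (count, group) -> percent string.
PERCENTAGE_CELLS = [
    (1962, "no_finding", "76.7%"),   # processed meat > 1 time/week, controls
    (1856, "any_neoplasm", "83.8%"),  # processed meat > 1 time/week, cases
    (1123, "no_finding", "43.9%"),   # male, controls
    (1385, "any_neoplasm", "62.5%"),  # male, cases
]

#: The no-finding reference splits exactly into equal PRS tertiles.
TERTILE_REFERENCE_SPLIT = (853, 853, 853)

#: Processed-meat 2x2 for the any-neoplasm contrast, genotyped participants:
#: (controls <=1/wk, cases <=1/wk, controls >1/wk, cases >1/wk).
PROCESSED_MEAT_2X2 = (597, 359, 1962, 1856)

#: Adjusted results as printed: exposure odds ratio, its genetic risk
#: equivalent, and the per-tertile PRS odds ratio from the same cohort.
PUBLISHED_ADJUSTED_OR = 1.22
PUBLISHED_GRE = 19.0
PUBLISHED_PER_TERTILE_OR = 1.40
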