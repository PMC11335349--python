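"""Published fraction-silenced count pairs with their significance calls.

Each entry: (label, x1, n1, x2, n2, significant) where ``significant``
is True for an asterisk (p < 0.05) and False for "ns" in the published
summary-of-statistics table.  Counts are inputs to the analysis; only
the calls, not the printed p-value decimals, are asserted (the exact
test behind the printed decimals is not specified).
"""

TABLE3_PAIRS = [
    ("bli-1: wild type vs mut-16(jam138)", 391, 757, 0, 229, True),
    ("bli-1: wild type vs mut-16(jam140)", 391, 757, 0, 277, True),
    ("bli-1: wild type vs mut-16(jam141)", 391, 757, 0, 124, True),
    ("bli-1: wild type vs mut-16(jam247)", 391, 757, 1, 446, True),
    ("bli-1: wild type vs mut-16 rde-10 double", 391, 757, 1, 412, True),
    ("unc-22: wild type vs mut-16 rde-10 double", 282, 309, 0, 173, True),
    ("unc-22: mut-16(jam138) vs double", 111, 180, 0, 173, True),
    ("bli-1: wild type vs mut-16(jam148)", 159, 202, 0, 126, True),
    ("bli-1: wild type vs rde-10(jam206)", 159, 202, 0, 209, True),
    ("unc-22: wild type vs mut-16(jam148)", 204, 206, 119, 121, False),
    ("unc-22: wild type vs mut-16 rde-10(jam196)", 204, 206, 0, 146, True),
    ("unc-22: wild type vs rde-10(jam206)", 204, 206, 185, 190, False),
    ("bli-1: wild type vs nrde-3(jam205)", 172, 295, 16, 274, True),
    ("bli-1: wild type vs rde-10; nrde-3", 172, 295, 0, 219, True),
    ("unc-22: wild type vs nrde-3(jam205)", 127, 129, 108, 110, False),
    ("unc-22: wild type vs rde-10; nrde-3", 127, 129, 0, 111, True),
    ("weak RNAi: wild type vs mut-16", 179, 183, 5, 107, True),
    ("weak RNAi: wild type vs rde-10", 179, 183, 16, 116, True),
    ("weak RNAi: wild type vs nrde-3", 179, 183, 72, 105, True),
    ("weak RNAi: mut-16 vs rde-10", 5, 107, 16, 116, True),
    ("weak RNAi: rde-10 vs nrde-3", 16, 116, 72, 105, True),
    ("unc-54: wild type vs nrde-3", 142, 148, 49, 263, True),
    ("dpy-7: wild type vs mut-16", 279, 322, 34, 130, True),
    ("dpy-7: mut-16 vs nrde-3", 34, 130, 6, 126, True),
    ("enhanced: wild type vs eri-1", 134, 200, 145, 200, False),
    ("recovery: day 5 vs continuous day 7", 63, 110, 51, 55, True),
    ("recovery: day 8 vs continuous day 7", 45, 124, 51, 55, True),
    ("3'cis swap: wild type vs bli-1(jam308)", 390, 488, 185, 245, False),
    ("promoter swap: bli-1p::gfp vs nrde-3", 21, 21, 23, 25, False),
    ("pulse: day 1 vs day 2", 76, 94, 86, 91, True),
]
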