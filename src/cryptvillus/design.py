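"""Shared study-design vocabulary.

The experiment is a 2x2 design: genotype (wild type vs PepT1 knockout)
crossed with intestinal compartment (villus vs crypt).  Four pairwise
comparisons are made throughout the pipeline; each is identified by a short
label and an ordered (first, second) pair of group names.  Direction calls
("up"/"down") always describe the *second* group relative to the first, so
for the two axis comparisons "up" means higher in the crypt.
"""

GROUPS = ("WTV", "WTC", "KOV", "KOC")

#: label -> (first group, second group)
COMPARISONS = {
    "wt_axis": ("WTV", "WTC"),
    "ko_axis": ("KOV", "KOC"),
    "villi": ("WTV", "KOV"),
    "crypts": ("WTC", "KOC"),
}

COMPARISON_ORDER = ("wt_axis", "ko_axis", "villi", "crypts")

#: default fold threshold below which two levels are called "same"
DEFAULT_TAU = 1.45
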