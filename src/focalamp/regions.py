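"""Published region coordinates (GRCh37/HG19) used as defaults when the
pipeline is pointed at real urothelial-carcinoma array data.

Synthetic runs define their own scaled coordinates; these constants are
the real-genome analogs: the 6p22.3 target region, the peak regions used
for element-enrichment contingency tables, and the three 1q21-24
amplicons.
"""

from .calls import AmpliconDefinition

#: 6p22.3 focal-amplification target region
REGION_6P22 = ("chr6", 14_900_000, 24_800_000)

#: peak regions for sequence-element contingency comparisons
PEAK_6P = ("chr6", 17_400_000, 23_600_000)
PEAK_1Q = ("chr1", 143_600_000, 172_300_000)

#: recurrent 1q21-24 amplicons
AMPLICON_1 = AmpliconDefinition("1", "chr1", 143_900_000, 148_500_000)
AMPLICON_2 = AmpliconDefinition("2", "chr1", 149_800_000, 152_900_000)
AMPLICON_3 = AmpliconDefinition("3", "chr1", 159_700_000, 161_700_000)

AMPLICONS_1Q = [AMPLICON_1, AMPLICON_2, AMPLICON_3]

#: default window size for breakpoint binning and element content (bp)
WINDOW_SIZE = 50_000
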