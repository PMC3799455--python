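"""Published worked-example data for the CCR5- and VEGFA-targeted ZFN pairs.

These small tables come from a published stratified off-target screen of two
obligate-heterodimer ZFN pairs: per score-bin counts of screened loci, of
loci with significant ZFN-induced indels (Fisher's exact test, p < 0.05),
and of candidate sites in the human genome falling in each score range.
They serve as worked examples and as fixed inputs for reproducing the
screen's summary percentages; the percentage convention is integer rounding
with halves rounded up.
"""

from __future__ import annotations

import math

import pandas as pd

from .selection import SiteDefinition

# Composite target sites, written 5'->3' on the top strand as
# left half-site | spacer | right half-site.
CCR5_SITE_DEF = SiteDefinition("GTCATCCTCATC", "AAACTGCAAAAG", flank_width=0)
CCR5_ON_TARGET = "GTCATCCTCATCCTGATAAACTGCAAAAG"  # 12 + 5 + 12 nt

VEGFA_SITE_DEF = SiteDefinition("AGCAGCGTC", "GAGTGAGGA", flank_width=0)
VEGFA_ON_TARGET = "AGCAGCGTCTTCGAGAGTGAGGA"  # 9 + 5 + 9 nt

# A few validated off-target site sequences (classifier score, composite
# site) from the same screen, usable as parser examples: note both 5-nt
# (29/23 nt total) and 6-nt (30/24 nt total) spacers occur.
CCR5_EXAMPLE_OFFTARGETS = [
    (0.028, "GTCATCCTCATCCTGATAAACTGCAAAAG"),  # the intended CCR5 site
    (0.118, "GTCGTCCTCATCTTAATAAACTGCAAAAA"),  # CCR2
    (0.133, "TGCTTCCTCACCCCAGGTAAACTGGAACAG"),  # 6-nt spacer
    (0.204, "CTCTCCCTCATCTCAGAGCAACTGTAAAAG"),
]

# Stratified screen tables.  Columns: score bin [lo, hi), hits/screened for
# non-exonic and exonic groups, the printed percentage of screened loci with
# significant indels, and the number of genomic sites scoring in the range.
_CCR5_ROWS = [
    # lo,   hi,   ne_hit, ne_n, ex_hit, ex_n, printed_pct, genome_sites
    (0.0, 0.10, 0, 0, 1, 1, 100, 1),
    (0.1, 0.20, 1, 4, 1, 1, 40, 5),
    (0.2, 0.30, 6, 12, 1, 1, 54, 60),
    (0.3, 0.40, 2, 12, 1, 6, 17, 241),
    (0.4, 0.50, 4, 12, 1, 13, 20, 816),
    (0.5, 0.60, 2, 12, 2, 11, 17, 2155),
    (0.6, 0.70, 0, 13, 0, 13, 0, 5947),
    (0.7, 0.75, 0, 13, 1, 13, 4, 6657),
]

_VEGFA_ROWS = [
    (0.0, 0.10, 3, 4, 0, 0, 75, 4),
    (0.1, 0.20, 6, 12, 2, 2, 57, 31),
    (0.2, 0.30, 5, 13, 3, 6, 42, 96),
    (0.3, 0.40, 4, 12, 0, 13, 16, 246),
    (0.4, 0.50, 2, 12, 1, 12, 13, 559),
    (0.5, 0.60, 2, 13, 0, 13, 8, 1187),
    (0.6, 0.70, 2, 13, 0, 10, 9, 2295),
    (0.7, 0.75, 0, 12, 3, 12, 13, 2824),
]

_COLUMNS = [
    "bin_lo",
    "bin_hi",
    "non_exon_hits",
    "non_exon_screened",
    "exon_hits",
    "exon_screened",
    "printed_pct",
    "genome_sites",
]

# Tercile summary of the CCR5 screen: (hits, screened) per score tercile,
# lowest scores first, with the printed percentages.
CCR5_TERCILES = [(16, 46), (6, 46), (1, 46)]
CCR5_TERCILE_PRINTED_PCT = [35, 13, 2]

# Bona fide off-target sites known for the CCR5 pair before the screen
# (the intended site's CCR2 paralog plus the on-target locus itself).
CCR5_PREVIOUSLY_KNOWN_HITS = 2


def ccr5_screen() -> pd.DataFrame:
    return pd.DataFrame(_CCR5_ROWS, columns=_COLUMNS)


def vegfa_screen() -> pd.DataFrame:
    return pd.DataFrame(_VEGFA_ROWS, columns=_COLUMNS)


def percentage(hits: int, screened: int) -> int:
    """Integer percentage with halves rounded up (the tables' convention)."""
    if screened == 0:
        raise ValueError("cannot compute a percentage of zero screened sites")
    return math.floor(100.0 * hits / screened + 0.5)


def recompute_percentages(screen: pd.DataFrame) -> pd.DataFrame:
    """Add hits/screened totals and the recomputed per-bin percentage."""
    out = screen.copy()
    out["hits"] = out["non_exon_hits"] + out["exon_hits"]
    out["screened"] = out["non_exon_screened"] + out["exon_screened"]
    out["recomputed_pct"] = [percentage(h, n) for h, n in zip(out["hits"], out["screened"])]
    return out
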