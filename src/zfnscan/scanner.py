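"""Genome-wide enumeration, scoring, exon annotation and stratified sampling
of candidate heterodimeric ZFN sites.

Every position x strand x spacer-length combination whose half-site windows
contain only A/C/G/T is a candidate.  A site is reported on the strand where
it reads left-window + spacer + right-window; when a span is its own reverse
complement only the + strand copy is kept.  Scanning is heterodimer-only:
the classifier is trained on the heterodimeric composite window and the ZFNs
modeled here carry obligate-heterodimer FokI variants, so homodimeric
half-site pairings have no scoreable meaning.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._dna import encode, revcomp
from .classifier import NaiveBayesModel
from .selection import SiteDefinition


@dataclass
class ScoredSite:
    chrom: str
    start: int  # 0-based, spans left window through right window
    end: int  # half-open
    strand: str  # "+" | "-"
    spacer_len: int
    window: str  # classifier features (left + right half-site windows)
    spacer_seq: str
    score: float | None = None
    exonic: bool | None = None

    @property
    def sort_key(self):
        return (self.chrom, self.start, self.strand, self.spacer_len)


def _chrom_items(genome) -> Iterable[tuple[str, str]]:
    if isinstance(genome, Mapping):
        return genome.items()
    return genome


def enumerate_candidates(genome, site_def: SiteDefinition) -> Iterator[ScoredSite]:
    """Yield every candidate site in deterministic (chrom, start, strand,
    spacer_len) order.  Windows containing ambiguity codes are skipped; the
    spacer itself may contain any base (it is not a feature)."""
    lwl = site_def.half_window_left
    rwl = site_def.half_window_right
    spacers = sorted(site_def.spacer_lengths)
    for chrom, seq in _chrom_items(genome):
        seq = seq.upper()
        n = len(seq)
        if n < site_def.min_span:
            continue
        # prefix sums of non-ACGT positions for O(1) window-validity checks
        bad = np.concatenate([[0], np.cumsum(encode(seq) >= 4)])
        for start in range(n - site_def.min_span + 1):
            for strand in "+-":
                for spacer_len in spacers:
                    span = site_def.site_span(spacer_len)
                    end = start + span
                    if end > n:
                        continue
                    # genomic intervals of the two half-site windows
                    if strand == "+":
                        w1 = (start, start + lwl)
                        w2 = (end - rwl, end)
                    else:
                        w1 = (start, start + rwl)
                        w2 = (end - lwl, end)
                    if bad[w1[1]] - bad[w1[0]] or bad[w2[1]] - bad[w2[0]]:
                        continue
                    sub = seq[start:end]
                    if strand == "-":
                        sub = revcomp(sub)
                        if sub == seq[start:end]:
                            continue  # palindromic span already reported on +
                    left = sub[:lwl]
                    spacer_seq = sub[lwl : lwl + spacer_len]
                    right = sub[lwl + spacer_len :]
                    yield ScoredSite(
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        spacer_len=spacer_len,
                        window=left + right,
                        spacer_seq=spacer_seq,
                    )


def score_genome(
    model: NaiveBayesModel,
    candidates: Iterable[ScoredSite],
    site_def: SiteDefinition | None = None,
    batch_size: int = 8192,
) -> Iterator[ScoredSite]:
    """Annotate candidates with classifier scores, streaming in batches so
    memory stays constant in genome size.  Order is preserved, and since
    enumeration is (chrom, start)-ordered, output is too."""
    if site_def is not None and site_def.window_length != model.window_length:
        raise ValueError(
            f"model window length {model.window_length} != site definition "
            f"window length {site_def.window_length}"
        )
    buffer: list[ScoredSite] = []

    def flush():
        mat = np.stack([encode(s.window) for s in buffer])
        scores = model.score_encoded(mat)
        for site, score in zip(buffer, scores):
            site.score = float(score)
            yield site
        buffer.clear()

    for cand in candidates:
        if len(cand.window) != model.window_length:
            raise ValueError("candidate window length does not match model")
        buffer.append(cand)
        if len(buffer) >= batch_size:
            yield from flush()
    if buffer:
        yield from flush()


def scan(
    model: NaiveBayesModel,
    genome,
    site_def: SiteDefinition,
    exons: list[tuple] | None = None,
) -> list[ScoredSite]:
    """Convenience wrapper: enumerate, score and (optionally) exon-annotate."""
    sites = list(score_genome(model, enumerate_candidates(genome, site_def), site_def))
    if exons is not None:
        annotate_exonic(sites, exons)
    return sites


def annotate_exonic(sites: list[ScoredSite], exons: list[tuple]) -> list[ScoredSite]:
    """Flag sites overlapping any exon interval by >= 1 bp (half-open)."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for exon in exons:
        chrom, start, end = exon[0], int(exon[1]), int(exon[2])
        trees[chrom].addi(start, end)
    for site in sites:
        site.exonic = bool(trees[site.chrom].overlap(site.start, site.end)) if site.chrom in trees else False
    return sites


# --- binning and stratified sampling -----------------------------------

_BIN_EDGES = [round(0.1 * i, 1) for i in range(8)] + [0.75]  # 0.0 .. 0.7, 0.75
_INNER = _BIN_EDGES[1:-1]  # 0.1 .. 0.7


def bin_index(score: float, max_score: float = 0.75) -> int | None:
    """Bin a score into [0,0.1), ..., [0.6,0.7), [0.7,0.75]; None above max."""
    if score > max_score:
        return None
    return min(bisect_right(_INNER, score), 7)


@dataclass
class ScoreBin:
    lo: float
    hi: float
    exonic: bool
    members: list  # ScoredSite, sorted ascending by score
    selected: list  # first min(top_n, len(members))


@dataclass
class SamplingPlan:
    bins: list  # 8 intervals x {non-exonic, exonic}, interval-major order
    n_discarded: int  # sites with score > max_score
    top_n: int
    max_score: float

    @property
    def n_binned(self) -> int:
        return sum(len(b.members) for b in self.bins)

    def selected_sites(self) -> list:
        return [s for b in self.bins for s in b.selected]

    def summary_frame(self) -> pd.DataFrame:
        """Per-bin count table mirroring the published screen-table layout."""
        rows = []
        for i in range(8):
            non_exon, exon = self.bins[2 * i], self.bins[2 * i + 1]
            rows.append(
                {
                    "score_bin": f"{non_exon.lo:g}-{non_exon.hi:g}",
                    "non_exon_sites": len(non_exon.members),
                    "non_exon_selected": len(non_exon.selected),
                    "exon_sites": len(exon.members),
                    "exon_selected": len(exon.selected),
                }
            )
        return pd.DataFrame(rows)


def bin_and_sample(sites: Iterable[ScoredSite], top_n: int = 13, max_score: float = 0.75) -> SamplingPlan:
    """Stratify scored, exon-annotated sites into 8 score bins x 2 exonic
    groups and pick the top-N (lowest-scoring) sites per bin."""
    groups: dict[tuple[int, bool], list[ScoredSite]] = {
        (i, exonic): [] for i in range(8) for exonic in (False, True)
    }
    discarded = 0
    for site in sites:
        if site.score is None:
            raise ValueError("sites must be scored before binning")
        idx = bin_index(site.score, max_score)
        if idx is None:
            discarded += 1
            continue
        groups[(idx, bool(site.exonic))].append(site)
    bins = []
    for i in range(8):
        lo, hi = _BIN_EDGES[i], _BIN_EDGES[i + 1]
        for exonic in (False, True):
            members = sorted(groups[(i, exonic)], key=lambda s: (s.score, *s.sort_key))
            bins.append(ScoreBin(lo, hi, exonic, members, members[: max(top_n, 0)]))
    return SamplingPlan(bins=bins, n_discarded=discarded, top_n=top_n, max_score=max_score)


# --- tabular export ------------------------------------------------------

def sites_to_frame(sites: Iterable[ScoredSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "name": f"{s.window}/{s.spacer_seq}",
                "score": s.score,
                "strand": s.strand,
                "spacer_len": s.spacer_len,
                "exonic": int(bool(s.exonic)) if s.exonic is not None else ".",
            }
            for s in sites
        ],
        columns=["chrom", "start", "end", "name", "score", "strand", "spacer_len", "exonic"],
    )


def sites_to_bed_rows(sites: Iterable[ScoredSite]) -> Iterator[list]:
    """BED6+2 rows: classifier score in the score column, spacer_len and
    exonic flag as extra columns."""
    for s in sites:
        yield [
            s.chrom,
            s.start,
            s.end,
            f"{s.window}/{s.spacer_seq}",
            f"{s.score:.6f}" if s.score is not None else ".",
            s.strand,
            s.spacer_len,
            int(bool(s.exonic)) if s.exonic is not None else ".",
        ]
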