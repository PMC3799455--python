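"""Processing of in vitro cleavage-selection data into labeled training windows.

A zinc-finger-nuclease (ZFN) pair recognizes a composite site written on the
top strand as::

    [flank + left core + flank]  spacer (5-6 nt)  [flank + right core + flank]

The classifier features are the concatenated half-site windows; the spacer is
never a feature but is retained for deduplication (spacer variants of the same
window count as independent cleavage events) and for indel bookkeeping.
Selection-library members that cleaved efficiently in vitro form the *active*
class; library members whose windows never appear in the active set form the
*inactive* class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._dna import is_acgt


@dataclass(frozen=True)
class SiteDefinition:
    """The two half-site models of a ZFN pair.

    Parameters
    ----------
    half_site_left, half_site_right
        Core recognition sequences, 5'->3' as written on the composite
        top-strand site (12 bp each for the CCR5 pair, 9 bp for VEGFA).
    flank_width
        Number of adjacent nucleotides included per half-site edge in the
        feature window (0-4). Flanks sit outside the spacer, so features and
        spacer never overlap.
    spacer_lengths
        Allowed spacer lengths in nt between the two half-site windows.
    """

    half_site_left: str
    half_site_right: str
    flank_width: int = 1
    spacer_lengths: frozenset = field(default_factory=lambda: frozenset({5, 6}))

    def __post_init__(self):
        object.__setattr__(self, "half_site_left", self.half_site_left.upper())
        object.__setattr__(self, "half_site_right", self.half_site_right.upper())
        object.__setattr__(self, "spacer_lengths", frozenset(int(s) for s in self.spacer_lengths))
        if not self.half_site_left or not is_acgt(self.half_site_left):
            raise ValueError("half_site_left must be a non-empty ACGT string")
        if not self.half_site_right or not is_acgt(self.half_site_right):
            raise ValueError("half_site_right must be a non-empty ACGT string")
        if not 0 <= self.flank_width <= 4:
            raise ValueError("flank_width must be in 0..4")
        if not self.spacer_lengths or any(s <= 0 for s in self.spacer_lengths):
            raise ValueError("spacer_lengths must be a non-empty set of positive integers")

    @property
    def core_len_left(self) -> int:
        return len(self.half_site_left)

    @property
    def core_len_right(self) -> int:
        return len(self.half_site_right)

    @property
    def half_window_left(self) -> int:
        """Length of the left half-site feature window (core + both flanks)."""
        return self.core_len_left + 2 * self.flank_width

    @property
    def half_window_right(self) -> int:
        return self.core_len_right + 2 * self.flank_width

    @property
    def window_length(self) -> int:
        """Fixed feature-window length (both half-site windows, no spacer)."""
        return self.half_window_left + self.half_window_right

    def site_span(self, spacer_len: int) -> int:
        """Total genomic span of a site with the given spacer length."""
        return self.window_length + spacer_len

    @property
    def min_span(self) -> int:
        return self.window_length + min(self.spacer_lengths)


@dataclass(frozen=True)
class WindowRecord:
    """An extracted (not yet labeled) feature window."""

    features: str
    spacer_seq: str
    provenance: str = ""


@dataclass(frozen=True)
class LabeledWindow:
    features: str
    label: str  # "active" | "inactive"
    spacer_seq: str
    provenance: str = ""


class SiteParseError(ValueError):
    """Raised when raw sites fail to parse; carries an itemized report."""

    def __init__(self, failures: list[tuple[int, str, str]]):
        self.failures = failures
        lines = "\n".join(f"  [{i}] {seq!r}: {reason}" for i, seq, reason in failures[:20])
        more = "" if len(failures) <= 20 else f"\n  ... and {len(failures) - 20} more"
        super().__init__(f"{len(failures)} raw site(s) rejected:\n{lines}{more}")


def extract_windows(
    raw_sites: list[str],
    site_def: SiteDefinition,
    provenance: list[str] | str | None = None,
) -> list[WindowRecord]:
    """Parse full composite sites into feature windows plus spacer.

    Each raw site must split as left-window + spacer + right-window for
    exactly one allowed spacer length (determined by total length). Records
    that match no allowed spacer length, or that contain a non-ACGT character
    inside a window region, are rejected together via :class:`SiteParseError`
    — never silently dropped. Input order is preserved.
    """
    if provenance is None:
        tags = [""] * len(raw_sites)
    elif isinstance(provenance, str):
        tags = [provenance] * len(raw_sites)
    else:
        tags = list(provenance)
        if len(tags) != len(raw_sites):
            raise ValueError("provenance list length must match raw_sites")

    lwl = site_def.half_window_left
    wlen = site_def.window_length
    records: list[WindowRecord] = []
    failures: list[tuple[int, str, str]] = []
    for i, raw in enumerate(raw_sites):
        seq = raw.strip().upper()
        spacer_len = len(seq) - wlen
        if spacer_len not in site_def.spacer_lengths:
            allowed = sorted(site_def.spacer_lengths)
            failures.append(
                (i, seq, f"length {len(seq)} matches no allowed spacer (window {wlen} + one of {allowed})")
            )
            continue
        left = seq[:lwl]
        spacer = seq[lwl : lwl + spacer_len]
        right = seq[lwl + spacer_len :]
        if not is_acgt(left) or not is_acgt(right):
            failures.append((i, seq, "ambiguity code inside a half-site window"))
            continue
        records.append(WindowRecord(features=left + right, spacer_seq=spacer, provenance=tags[i]))
    if failures:
        raise SiteParseError(failures)
    return records


def _dedup(records: list[WindowRecord]) -> list[WindowRecord]:
    # Duplicates removed unless they are independent cleavage events:
    # distinct spacer sequence or distinct provenance tag.
    seen: dict[tuple[str, str, str], None] = {}
    for rec in records:
        seen.setdefault((rec.features, rec.spacer_seq, rec.provenance), None)
    return [WindowRecord(*key) for key in seen]


def build_training_sets(
    active_sites: list[WindowRecord],
    preselection_library: list[WindowRecord],
) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Label windows: active = deduplicated cleaved set; inactive = library
    windows whose features never appear among the active features."""
    if not preselection_library:
        raise ValueError("empty preselection library: inactive class is undefined")
    active = _dedup(active_sites)
    library = _dedup(preselection_library)
    active_features = {rec.features for rec in active}
    inactive = [rec for rec in library if rec.features not in active_features]
    return (
        [LabeledWindow(r.features, "active", r.spacer_seq, r.provenance) for r in active],
        [LabeledWindow(r.features, "inactive", r.spacer_seq, r.provenance) for r in inactive],
    )


def windows_to_rows(windows: list[LabeledWindow]) -> list[dict]:
    """Rows for the labeled-window TSV export."""
    return [
        {"features": w.features, "label": w.label, "spacer_seq": w.spacer_seq, "provenance": w.provenance}
        for w in windows
    ]
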