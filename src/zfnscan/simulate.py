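"""Seeded synthetic-data generators.

Three generators stand in for the three experimental inputs the method
consumes: a partially degenerate in vitro cleavage-selection library with a
planted per-position cleavage preference; a genome with planted heterodimeric
sites; and treated/control amplicon read sets with controlled indel and
base-error rates.  The cleavage truth model is additive per-position weights
with a threshold — the simplest ground truth a position-wise classifier can
learn — and is a statistical stand-in, not a claim about ZFN biochemistry.

All randomness flows from explicit integer seeds via numpy Generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dna import encode_strict, revcomp
from .indels import Amplicon
from .selection import SiteDefinition, WindowRecord

_BASES = np.array(list("ACGT"))


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


# --- selection library ----------------------------------------------------

@dataclass
class SelectionSimConfig:
    """Configuration for the simulated cleavage selection.

    degeneracy_rate is the per-position substitution probability of the
    library relative to the on-target window (0.2 by default: a partially
    degenerate library in which ~1 in 5 positions vary).  A library member is
    "active" (efficiently cleaved) when its summed planted per-position
    weights reach cleavage_threshold; the default profile scores 1 per
    on-target base with threshold window_length - 3, i.e. windows within 3
    mismatches of the intended site cleave.
    """

    site_def: SiteDefinition
    degeneracy_rate: float = 0.2
    planted_profile: np.ndarray | None = None  # (window_length, 4) weights
    cleavage_threshold: float | None = None
    n_library: int = 10_000
    seed: int = 0
    on_target_window: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.degeneracy_rate <= 1.0:
            raise ValueError("degeneracy_rate must be in [0, 1]")
        if self.n_library <= 0:
            raise ValueError("n_library must be positive")
        if self.on_target_window is None:
            if self.site_def.flank_width != 0:
                raise ValueError("on_target_window required when flank_width > 0")
            self.on_target_window = self.site_def.half_site_left + self.site_def.half_site_right
        if len(self.on_target_window) != self.site_def.window_length:
            raise ValueError("on_target_window length must equal the feature-window length")
        L = self.site_def.window_length
        if self.planted_profile is None:
            profile = np.zeros((L, 4))
            profile[np.arange(L), encode_strict(self.on_target_window)] = 1.0
            self.planted_profile = profile
        self.planted_profile = np.asarray(self.planted_profile, dtype=float)
        if self.planted_profile.shape != (L, 4):
            raise ValueError("planted_profile must have shape (window_length, 4)")
        if self.cleavage_threshold is None:
            self.cleavage_threshold = float(L - 3)


def simulate_selection_library(cfg: SelectionSimConfig) -> tuple[list[WindowRecord], list[WindowRecord]]:
    """Return (active windows, full preselection library); active is the
    subset of the library whose planted cleavage activity reaches the
    threshold."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.site_def.window_length
    target = encode_strict(cfg.on_target_window)
    n = cfg.n_library
    mat = np.tile(target, (n, 1))
    mutate = rng.random((n, L)) < cfg.degeneracy_rate
    # substitute with one of the three other bases, uniformly
    shifts = rng.integers(1, 4, size=(n, L))
    mat = np.where(mutate, (mat + shifts) % 4, mat)
    activity = cfg.planted_profile[np.arange(L), mat].sum(axis=1)
    spacer_lengths = sorted(cfg.site_def.spacer_lengths)
    spacer_len = rng.choice(spacer_lengths, size=n)
    library: list[WindowRecord] = []
    active: list[WindowRecord] = []
    for i in range(n):
        spacer = _decode(rng.integers(0, 4, size=int(spacer_len[i])))
        rec = WindowRecord(features=_decode(mat[i]), spacer_seq=spacer, provenance=f"sim{i}")
        library.append(rec)
        if activity[i] >= cfg.cleavage_threshold:
            active.append(rec)
    if not active:
        raise ValueError(
            f"cleavage_threshold {cfg.cleavage_threshold} yields an empty active class: "
            f"{len(active)} active of {len(library)} library members"
        )
    return active, library


# --- genome ---------------------------------------------------------------

def simulate_genome(
    length: int,
    gc: float = 0.41,
    planted: list[tuple[str, str, int, str]] = (),
    seed: int = 0,
    site_def: SiteDefinition | None = None,
    chrom: str = "chr1",
) -> dict[str, str]:
    """I.i.d. background sequence at the given GC content with sites planted
    exactly at stated coordinates.

    ``planted`` entries are (features, spacer_seq, position, strand); the
    composite site written into the + strand is left-window + spacer +
    right-window (reverse-complemented for strand '-').  Overlapping or
    out-of-bounds sites raise.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = list(_decode(codes))
    occupied: list[tuple[int, int]] = []
    for features, spacer_seq, position, strand in planted:
        if site_def is None:
            raise ValueError("site_def required to place planted sites")
        lwl = site_def.half_window_left
        if len(features) != site_def.window_length:
            raise ValueError("planted features length mismatch")
        site = features[:lwl] + spacer_seq + features[lwl:]
        if strand == "-":
            site = revcomp(site)
        lo, hi = position, position + len(site)
        if lo < 0 or hi > length:
            raise ValueError(f"planted site at {position} out of bounds")
        for a, b in occupied:
            if lo < b and hi > a:
                raise ValueError(f"planted sites overlap at [{lo}, {hi})")
        occupied.append((lo, hi))
        seq[lo:hi] = list(site)
    return {chrom: "".join(seq)}


# --- amplicon reads -------------------------------------------------------

def _default_length_dist() -> dict[int, float]:
    # NHEJ-scar-like length spectrum: short indels dominate, tail to 15 nt
    weights = {L: float(np.exp(-L / 4.0)) for L in range(1, 16)}
    total = sum(weights.values())
    return {L: w / total for L, w in weights.items()}


@dataclass
class AmpliconSimConfig:
    """Simulated amplicon sequencing of one locus.

    With probability ``indel_rate`` a read carries one planted indel whose
    length is drawn from ``indel_length_dist`` and whose position is uniform
    over the spacer; ``insertion_fraction`` of planted indels are insertions
    (deletions model the dominant NHEJ outcome).  Substitution errors are
    applied per base everywhere.  The control arm is generated with
    indel_rate 0 from an independent substream of the same seed.
    """

    amplicon: Amplicon
    indel_rate: float = 0.05
    indel_length_dist: dict = field(default_factory=_default_length_dist)
    insertion_fraction: float = 1.0 / 3.0
    substitution_error_rate: float = 0.005
    n_reads: int = 10_000
    seed: int = 0

    def __post_init__(self):
        for name in ("indel_rate", "insertion_fraction", "substitution_error_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        total = sum(self.indel_length_dist.values())
        if not np.isclose(total, 1.0):
            raise ValueError("indel_length_dist probabilities must sum to 1")


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in seq])
    hit = rng.random(len(codes)) < rate
    shifts = rng.integers(1, 4, size=len(codes))
    codes = np.where(hit, (codes + shifts) % 4, codes)
    return _decode(codes)


def _simulate_arm(cfg: AmpliconSimConfig, indel_rate: float, rng: np.random.Generator, prefix: str) -> list[tuple[str, str, str]]:
    ref = cfg.amplicon.reference_seq
    s_start, s_end = cfg.amplicon.spacer_interval
    lengths = sorted(cfg.indel_length_dist)
    probs = np.array([cfg.indel_length_dist[L] for L in lengths])
    reads = []
    for i in range(cfg.n_reads):
        seq = ref
        if rng.random() < indel_rate:
            for attempt in range(100):
                L = int(rng.choice(lengths, p=probs))
                if rng.random() < cfg.insertion_fraction:
                    point = int(rng.integers(s_start, s_end + 1))
                    insert = _decode(rng.integers(0, 4, size=L))
                    seq = ref[:point] + insert + ref[point:]
                    break
                start = int(rng.integers(s_start, s_end))
                if start + L <= len(ref) - len(cfg.amplicon.rev_primer):
                    seq = ref[:start] + ref[start + L :]
                    break
            else:
                raise ValueError("could not place an indel inside the amplicon after 100 attempts")
        seq = _apply_substitutions(seq, cfg.substitution_error_rate, rng)
        reads.append((f"{prefix}{i}", seq, "?" * len(seq)))  # constant Q30
    return reads


def simulate_amplicon_reads(cfg: AmpliconSimConfig) -> tuple[list, list]:
    """Return (treated-like, control-like) read lists of (id, seq, qual)."""
    rng_treated = np.random.default_rng([cfg.seed, 0])
    rng_control = np.random.default_rng([cfg.seed, 1])
    treated = _simulate_arm(cfg, cfg.indel_rate, rng_treated, "t")
    control = _simulate_arm(cfg, 0.0, rng_control, "c")
    return treated, control
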