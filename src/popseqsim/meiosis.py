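"""Gamete simulation: crossover counts, interference-aware placement, splicing.

The number of crossovers per chromosome per meiosis follows the trinomial
none/one/two-or-more model; the two-or-more category is resolved to a
realized count ``2 + G`` with geometric ``G`` (triple crossovers are rare in
empirical plant data, so the continuation probability is small).  The first
crossover is placed from the marginal per-interval density ``p_mi / l_i``;
subsequent crossovers are placed at gamma-distributed spacings in normalized
genetic-distance coordinates (cumulative ``p_mi``), modelling crossover
interference, and mapped back to base pairs by linear interpolation within
marker intervals.

A haplotype is stored as sorted integer breakpoints plus the origin label of
the first segment; origins alternate between the two parental labels at each
breakpoint.  Label 0 is the mutagenized founder ("A", foreground), label 1
the crossing partner ("B").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .landscape import ChromProfile, MarkerMap, RecombinationLandscape

logger = logging.getLogger(__name__)

FOUNDER = 0   #: origin label of the mutagenized founder (foreground)
PARTNER = 1   #: origin label of the crossing partner / recurrent parent

_PLACEMENT_RETRIES = 8


@dataclass
class Haplotype:
    """Per-chromosome breakpoint lists with alternating origin labels.

    ``breakpoints[chrom]`` holds sorted crossover positions ``x`` (bp);
    positions ``<= x`` belong to the segment left of the breakpoint.
    ``start_origin[chrom]`` labels the leftmost segment.
    """

    breakpoints: dict[str, np.ndarray]
    start_origin: dict[str, int]

    @classmethod
    def uniform(cls, genome, origin: int) -> "Haplotype":
        """A haplotype entirely of one parental origin."""
        return cls(breakpoints={c: np.empty(0, np.int64) for c in genome.names},
                   start_origin={c: origin for c in genome.names})

    def origin_at(self, chrom: str, pos) -> np.ndarray | int:
        """Origin label(s) at 1-based position(s) ``pos``."""
        bps = self.breakpoints[chrom]
        count = np.searchsorted(bps, np.asarray(pos), side="left")
        return self.start_origin[chrom] ^ (count & 1)

    def segments(self, chrom: str, length: int):
        """Yield ``(start, end, origin)`` with 1-based inclusive bounds."""
        bps = self.breakpoints[chrom]
        edges = np.concatenate([[0], bps, [length]])
        origin = self.start_origin[chrom]
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi > lo:
                yield int(lo) + 1, int(hi), origin
            origin ^= 1

    def origin_lengths(self, chrom: str, length: int) -> tuple[int, int]:
        """Total bp of (founder, partner) origin on one chromosome."""
        bps = self.breakpoints[chrom]
        edges = np.concatenate([[0], bps, [length]])
        widths = np.diff(edges)
        start = self.start_origin[chrom]
        a = widths[0::2].sum() if start == FOUNDER else widths[1::2].sum()
        return int(a), int(length - a)


class MeiosisModel:
    """Compiled sampler for gametes under a landscape and marker map.

    Compiling once avoids recomputing placement CDFs in the breeding loops.
    """

    def __init__(self, landscape: RecombinationLandscape, markers: MarkerMap):
        landscape.validate_against(markers)
        self.landscape = landscape
        self.genome = landscape.genome
        self.profiles: dict[str, ChromProfile] = {
            chrom: landscape.placement_profile(markers, chrom)
            for chrom in self.genome.names
        }

    def gamete(self, parent, rng: np.random.Generator) -> Haplotype:
        """Draw one recombinant gamete from a diploid parent."""
        return sample_gamete(parent, self, rng)


def sample_crossover_count(count_probs, rng: np.random.Generator,
                           tail_continuation: float = 0.1) -> int:
    """Draw a realized crossover count from the none/one/two-or-more model."""
    p1, p2, p3 = count_probs
    u = rng.random()
    if u < p1:
        return 0
    if u < p1 + p2:
        return 1
    # geometric number of extra crossovers beyond two
    if tail_continuation <= 0:
        return 2
    return 2 + int(rng.geometric(1.0 - tail_continuation) - 1)


def place_crossovers(count: int,
                     profile: ChromProfile,
                     interference: tuple[float, float] | None,
                     rng: np.random.Generator,
                     max_retries: int = _PLACEMENT_RETRIES) -> np.ndarray:
    """Place ``count`` crossovers on one chromosome, returning sorted bp.

    The first event's genetic coordinate is uniform on [0, 1) (equivalent to
    interval choice by ``p_mi`` and uniform bp within the interval); each
    further event sits a Gamma(shape, scale) genetic distance beyond the
    previous one.  Draws that overrun the chromosome end are redrawn a
    bounded number of times and then truncated to the remaining interval.
    With ``interference=None`` all events are i.i.d. from the marginal
    density.
    """
    if count < 0:
        raise ValidationError("crossover count must be >= 0")
    if count == 0:
        return np.empty(0, np.int64)
    if interference is None:
        gs = rng.random(count)
    else:
        shape, scale = interference
        gs = np.empty(count)
        gs[0] = rng.random()
        for i in range(1, count):
            g = None
            for _ in range(max_retries):
                cand = gs[i - 1] + rng.gamma(shape, scale)
                if cand < 1.0:
                    g = cand
                    break
            if g is None:
                # truncate: fall back to a uniform point in the remainder
                g = gs[i - 1] + (1.0 - gs[i - 1]) * rng.random()
                logger.debug("gamma spacing overran chromosome %s; truncated",
                             profile.chrom)
            gs[i] = g
    bp = profile.genetic_to_bp(np.sort(gs))
    length = profile.edges[-1]
    bp = np.unique(np.clip(np.round(bp), 1, length - 1).astype(np.int64))
    return bp


def splice(hap_a: tuple[np.ndarray, int],
           hap_b: tuple[np.ndarray, int],
           crossovers: np.ndarray,
           start_choice: int,
           length: int) -> tuple[np.ndarray, int]:
    """Recombine two homologous chromosome haplotypes at given crossovers.

    ``hap_a``/``hap_b`` are ``(breakpoints, start_origin)`` for one
    chromosome; ``start_choice`` selects which homolog contributes the
    leftmost segment.  Returns the recombined ``(breakpoints, start_origin)``
    with adjacent same-origin segments merged.
    """
    sources = (hap_a, hap_b) if start_choice == 0 else (hap_b, hap_a)
    edges = np.concatenate([[0], crossovers, [length]])
    out_bps: list[int] = []
    origins: list[int] = []
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        if hi <= lo:
            continue
        src_bps, src_start = sources[i % 2]
        # first source segment is the one containing positions > lo
        j = int(np.searchsorted(src_bps, lo, side="right"))
        pos = lo
        while pos < hi:
            nxt = src_bps[j] if j < len(src_bps) and src_bps[j] < hi else hi
            origin = src_start ^ (j & 1)
            if origins and origins[-1] == origin:
                out_bps.pop()  # merge with previous same-origin segment
            else:
                origins.append(origin)
            if nxt < length:
                out_bps.append(int(nxt))
            pos = nxt
            j += 1
    assert len(out_bps) == len(origins) - 1, "splice bookkeeping broken"
    return np.asarray(out_bps, np.int64), origins[0]


def sample_gamete(parent, model: MeiosisModel,
                  rng: np.random.Generator) -> Haplotype:
    """Simulate one meiosis of ``parent`` and return the gamete haplotype.

    The starting homolog is chosen with probability 1/2 per chromosome and
    origins alternate at each crossover; mutation genotypes are implied by
    segment origins (founder-origin segments carry the founder's mutations).
    """
    h1, h2 = parent.haplotypes
    breakpoints: dict[str, np.ndarray] = {}
    start: dict[str, int] = {}
    for chrom, length in model.genome.chromosomes:
        probs = model.landscape.count_probs[chrom]
        count = sample_crossover_count(probs, rng,
                                       model.landscape.tail_continuation)
        xovers = place_crossovers(count, model.profiles[chrom],
                                  model.landscape.interference[chrom], rng)
        choice = int(rng.integers(2))
        bps, s = splice((h1.breakpoints[chrom], h1.start_origin[chrom]),
                        (h2.breakpoints[chrom], h2.start_origin[chrom]),
                        xovers, choice, length)
        breakpoints[chrom] = bps
        start[chrom] = s
    return Haplotype(breakpoints=breakpoints, start_origin=start)
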