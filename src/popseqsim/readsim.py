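"""Single-end versus paired-end informative-read comparison.

Allele-frequency estimation only uses reads whose alignments overlap at
least one marker.  A read pair carries a single sampled chromosome, so a
pair counts once no matter how many markers its two mates hit, whereas two
single-end reads of the same total bases are sampled independently.  This
module draws random alignment locations (default 100,000 per configuration),
scores them as informative, and tabulates the paired-end excess over
single-end for a range of read lengths.  Paired-end insert length is fixed
at three times the read length; multi-mapping is modelled as an excluded
region mask whose draws are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .landscape import GenomeSpec, MarkerMap

logger = logging.getLogger(__name__)

READ_LENGTH_RANGE = (50, 750)
INSERT_MULTIPLIER = 3


@dataclass
class AlignmentDraws:
    """Vectorized random alignments on one genome."""

    chroms: np.ndarray       # chromosome index per draw
    starts: np.ndarray       # 1-based start of the (first) read
    read_length: int
    mode: str                # "SE" | "PE"

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def mate_starts(self) -> np.ndarray:
        """Start of the second read: ``start + insert - read_length``."""
        if self.mode != "PE":
            raise ValidationError("mate positions only exist in PE mode")
        insert = INSERT_MULTIPLIER * self.read_length
        return self.starts + insert - self.read_length


def draw_alignments(spec: GenomeSpec, read_length: int, mode: str,
                    n_draws: int = 100_000,
                    mappability: dict[str, np.ndarray] | None = None,
                    rng: np.random.Generator | None = None) -> AlignmentDraws:
    """Draw uniform random alignment locations.

    ``mappability`` maps chromosome name to an ``(n, 2)`` array of excluded
    ``[start, end]`` regions (repeats / multi-mapping targets); draws whose
    span overlaps an excluded region are discarded, mirroring the exclusion
    of reads that align equally well to multiple places.

    Starts are uniform over the space where the full span (read for SE,
    read..mate for PE) fits on the chromosome.
    """
    if mode not in ("SE", "PE"):
        raise ValidationError(f"unknown mode {mode!r}")
    if n_draws < 0:
        raise ValidationError("n_draws must be >= 0")
    if not READ_LENGTH_RANGE[0] <= read_length <= READ_LENGTH_RANGE[1]:
        logger.warning("read_length %d outside the usual %s bp range",
                       read_length, READ_LENGTH_RANGE)
    rng = np.random.default_rng() if rng is None else rng
    span = read_length if mode == "SE" else INSERT_MULTIPLIER * read_length
    names = spec.names
    space = np.array([spec.length_of(c) - span + 1 for c in names], np.int64)
    if (space <= 0).any():
        raise ValidationError(
            f"span {span} bp exceeds the shortest chromosome")
    if n_draws == 0:
        return AlignmentDraws(np.empty(0, np.int64), np.empty(0, np.int64),
                              read_length, mode)
    probs = space / space.sum()
    chrom_idx = rng.choice(len(names), size=n_draws, p=probs)
    starts = (rng.random(n_draws) * space[chrom_idx]).astype(np.int64) + 1

    if mappability:
        keep = np.ones(n_draws, bool)
        for ci, name in enumerate(names):
            regions = mappability.get(name)
            if regions is None or not len(regions):
                continue
            mask = chrom_idx == ci
            if not mask.any():
                continue
            s = starts[mask]
            hit = np.zeros(len(s), bool)
            for lo, hi in np.asarray(regions):
                hit |= (s <= hi) & (s + span - 1 >= lo)
            keep[np.flatnonzero(mask)[hit]] = False
        chrom_idx, starts = chrom_idx[keep], starts[keep]
        logger.debug("discarded %d multi-mapping draws", n_draws - keep.sum())
    return AlignmentDraws(chrom_idx, starts, read_length, mode)


def _covers_marker(positions: np.ndarray, starts: np.ndarray,
                   length: int) -> np.ndarray:
    """True where [start, start+length-1] contains >= 1 marker position."""
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, starts + length - 1, side="right")
    return hi > lo


def informative_fraction(draws: AlignmentDraws, markers: MarkerMap) -> float:
    """Fraction of draws overlapping at least one marker.

    A PE pair counts once even if both mates hit markers, since the two
    mates report the same sampled chromosome.
    """
    if len(draws) == 0:
        return 0.0
    names = markers.genome.names
    informative = np.zeros(len(draws), bool)
    for ci, name in enumerate(names):
        mask = draws.chroms == ci
        if not mask.any():
            continue
        pos = markers.positions(name)
        if not len(pos):
            continue
        s = draws.starts[mask]
        hit = _covers_marker(pos, s, draws.read_length)
        if draws.mode == "PE":
            hit |= _covers_marker(pos, draws.mate_starts[mask],
                                  draws.read_length)
        informative[mask] = hit
    return float(informative.mean())


def compare_se_pe(spec: GenomeSpec,
                  markers_se: MarkerMap,
                  markers_pe: MarkerMap,
                  read_lengths,
                  n_draws: int = 100_000,
                  rng: np.random.Generator | None = None,
                  mappability: dict[str, np.ndarray] | None = None
                  ) -> pd.DataFrame:
    """Tabulate informative fractions and the paired-end excess.

    Distinct marker sets may be supplied per mode (paired-end alignment
    reaches loci single-end alignment cannot).  ``pe_excess_pct`` is
    ``100 * (PE/SE - 1)``; reported as missing where the SE fraction is 0.
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for rl in sorted(read_lengths):
        se = informative_fraction(
            draw_alignments(spec, rl, "SE", n_draws, mappability, rng),
            markers_se)
        pe = informative_fraction(
            draw_alignments(spec, rl, "PE", n_draws, mappability, rng),
            markers_pe)
        excess = 100.0 * (pe / se - 1.0) if se > 0 else np.nan
        rows.append({"read_length": rl, "se_fraction": se,
                     "pe_fraction": pe, "pe_excess_pct": excess})
    return pd.DataFrame(rows)


def exhaustive_informative_fraction(spec: GenomeSpec, markers: MarkerMap,
                                    read_length: int, mode: str) -> float:
    """Exact informative fraction by enumerating every valid start position.

    Brute-force oracle for small (toy) genomes; the Monte-Carlo estimate of
    :func:`informative_fraction` converges to this value.
    """
    span = read_length if mode == "SE" else INSERT_MULTIPLIER * read_length
    total = hits = 0
    for name, length in spec.chromosomes:
        n_starts = length - span + 1
        if n_starts <= 0:
            raise ValidationError(f"span {span} exceeds chromosome {name}")
        starts = np.arange(1, n_starts + 1, dtype=np.int64)
        pos = markers.positions(name)
        if len(pos):
            hit = _covers_marker(pos, starts, read_length)
            if mode == "PE":
                mate = starts + span - read_length
                hit |= _covers_marker(pos, mate, read_length)
            hits += int(hit.sum())
        total += n_starts
    return hits / total
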