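"""Genomes, recombination landscapes and marker maps.

A mapping-by-sequencing simulation operates at marker resolution: the genome
is an ordered set of chromosomes, each carrying an ordered set of marker
positions.  Meiotic recombination on a chromosome is described by

* the probabilities ``(p1, p2, p3)`` of observing none, one, or two-or-more
  crossovers per chromosome per meiosis (a trinomial count model), and
* per-marker-interval recombination frequencies ``p_mi`` — the probability
  that a crossover falls between marker ``i-1`` and marker ``i`` — which act
  as a piecewise-uniform placement density along the physical chromosome, and
* a gamma spacing model ``(shape, scale)`` for crossover interference,
  expressed in normalized genetic-distance coordinates.

Coordinates are 1-based and inclusive throughout; the interval attached to
marker ``i`` is half-open ``(pos[i-1], pos[i]]`` with entry 0 covering the
chromosome start up to the first marker.  A terminal interval from the last
marker to the chromosome end is appended internally when a placement profile
is compiled, weighted by its length under the local (last-interval) rate.

Everything here can be loaded from, and written to, small tab-separated
files, or synthesized de novo for Arabidopsis-, rice- or barley-like genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-9

#: Expected extra crossovers in the "two or more" category follow
#: 2 + Geometric(continuation); this is the default continuation probability.
DEFAULT_TAIL_CONTINUATION = 0.1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes of a (marker-resolution) genome.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs, in genome order.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValidationError("chromosome names must be unique")
        if not chroms:
            raise ValidationError("genome must have at least one chromosome")
        for n, l in chroms:
            if l <= 0:
                raise ValidationError(f"chromosome {n!r} has non-positive length {l}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None


def arabidopsis_like() -> GenomeSpec:
    """Five chromosomes, ~119 Mb (standard reference lengths)."""
    mb = 1_000_000
    return GenomeSpec(tuple(zip(
        ("Chr1", "Chr2", "Chr3", "Chr4", "Chr5"),
        (int(30.4 * mb), int(19.7 * mb), int(23.5 * mb), int(18.6 * mb), int(26.9 * mb)),
    )))


def rice_like() -> GenomeSpec:
    """Twelve chromosomes, ~380 Mb."""
    mb = 1_000_000
    lengths = (43.3, 35.9, 36.4, 35.5, 30.0, 31.2, 29.7, 28.4, 23.0, 23.2, 29.0, 27.5)
    return GenomeSpec(tuple(
        (f"Chr{i + 1}", int(l * mb)) for i, l in enumerate(lengths)
    ))


def barley_like() -> GenomeSpec:
    """Seven chromosomes, ~4.6 Gb (target-enrichment sequencing is the
    realistic sequencing mode at this genome size)."""
    mb = 1_000_000
    lengths = (558, 768, 700, 647, 670, 583, 657)
    return GenomeSpec(tuple(
        (f"Chr{i + 1}H", int(l * mb)) for i, l in enumerate(lengths)
    ))


SPECIES_PRESETS = {
    "arabidopsis": arabidopsis_like,
    "rice": rice_like,
    "barley": barley_like,
}


@dataclass
class MarkerMap:
    """Ordered marker positions with per-marker metadata.

    Attributes
    ----------
    genome
        The genome the markers live on.
    df
        DataFrame with columns ``chrom``, ``pos`` (1-based bp), ``norm_weight``
        (coverage-normalization value, genome average ~1), and optional
        ``quality``, ``cnv``, ``enriched``.  Sorted by genome order then
        position; positions strictly increasing per chromosome.
    """

    genome: GenomeSpec
    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        required = {"chrom", "pos", "norm_weight"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"marker table missing columns: {sorted(missing)}")
        if "quality" not in df.columns:
            df["quality"] = np.nan
        if "cnv" not in df.columns:
            df["cnv"] = False
        if "enriched" not in df.columns:
            df["enriched"] = False
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["norm_weight"] = df["norm_weight"].astype(float)
        df["cnv"] = df["cnv"].astype(bool)
        df["enriched"] = df["enriched"].astype(bool)
        order = {c: i for i, c in enumerate(self.genome.names)}
        unknown = set(df["chrom"]) - set(order)
        if unknown:
            raise ValidationError(f"markers on unknown chromosomes: {sorted(unknown)}")
        df = df.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
        df = df.reset_index(drop=True)
        if (df["norm_weight"] < 0).any():
            raise ValidationError("norm_weight must be >= 0")
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) and (pos[0] < 1 or pos[-1] > self.genome.length_of(chrom)):
                raise ValidationError(f"marker positions outside chromosome {chrom}")
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"marker positions not strictly increasing on {chrom}")
        self.df = df

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()

    def chroms(self) -> list[str]:
        return [c for c in self.genome.names if (self.df["chrom"] == c).any()]

    @property
    def n_markers(self) -> int:
        return len(self.df)

    def multinomial_probs(self) -> np.ndarray:
        """Normalized coverage weights for use as multinomial probabilities."""
        w = self.df["norm_weight"].to_numpy(float)
        total = w.sum()
        if total <= 0:
            raise ValidationError("all marker norm_weights are zero")
        return w / total


@dataclass
class RecombinationLandscape:
    """Per-chromosome crossover count model, placement density and interference.

    Attributes
    ----------
    genome
        Chromosome structure.
    count_probs
        ``{chrom: (p1, p2, p3)}`` — probabilities of none / one / two-or-more
        crossovers per chromosome per meiosis; each triple sums to 1.
    interval_freqs
        ``{chrom: array}`` with one entry per marker on that chromosome;
        entry ``i`` is the probability that a crossover falls in
        ``(pos[i-1], pos[i]]`` (entry 0: chromosome start to first marker).
        Sums to 1 per chromosome.
    interference
        ``{chrom: (shape, scale)}`` gamma spacing parameters in normalized
        genetic-distance coordinates.
    tail_continuation
        Continuation probability of the geometric tail resolving the
        "two or more" category into a realized count ``2 + G``.
    """

    genome: GenomeSpec
    count_probs: dict[str, tuple[float, float, float]]
    interval_freqs: dict[str, np.ndarray]
    interference: dict[str, tuple[float, float]]
    tail_continuation: float = DEFAULT_TAIL_CONTINUATION

    def __post_init__(self):
        for chrom, probs in self.count_probs.items():
            p = np.asarray(probs, float)
            if p.shape != (3,) or (p < -_PROB_TOL).any():
                raise ValidationError(f"count_probs for {chrom} must be 3 non-negative values")
            if abs(p.sum() - 1.0) > _PROB_TOL:
                raise ValidationError(
                    f"count_probs for {chrom} sum to {p.sum():.17g}, expected 1")
            self.count_probs[chrom] = tuple(float(x) for x in p)
        for chrom, f in self.interval_freqs.items():
            f = np.asarray(f, float)
            if (f < 0).any():
                raise ValidationError(f"interval_freqs for {chrom} contain negatives")
            if abs(f.sum() - 1.0) > 1e-6:
                raise ValidationError(
                    f"interval_freqs for {chrom} sum to {f.sum():.17g}, expected 1")
            self.interval_freqs[chrom] = f
        for chrom, (shape, scale) in self.interference.items():
            if shape <= 0 or scale <= 0:
                raise ValidationError(f"gamma parameters for {chrom} must be positive")
        if not 0 <= self.tail_continuation < 1:
            raise ValidationError("tail_continuation must be in [0, 1)")

    @property
    def expected_tail_count(self) -> float:
        """Expected realized crossover count in the two-or-more category."""
        q = self.tail_continuation
        return 2.0 + q / (1.0 - q)

    def mean_crossovers(self, chrom: str) -> float:
        p1, p2, p3 = self.count_probs[chrom]
        return p2 + p3 * self.expected_tail_count

    def validate_against(self, markers: MarkerMap) -> None:
        """Check that interval frequencies align with the marker map."""
        for chrom in self.genome.names:
            n = len(markers.positions(chrom))
            got = len(self.interval_freqs.get(chrom, ()))
            if n != got:
                raise ValidationError(
                    f"{chrom}: {got} interval frequencies for {n} markers")

    def placement_profile(self, markers: MarkerMap, chrom: str) -> "ChromProfile":
        """Compile the per-bp placement density for one chromosome.

        Appends the terminal interval (last marker to chromosome end) with
        probability proportional to its length under the last stored
        interval's local rate, then renormalizes.
        """
        pos = markers.positions(chrom)
        freqs = np.asarray(self.interval_freqs[chrom], float)
        if len(pos) != len(freqs):
            raise ValidationError(f"{chrom}: markers and interval_freqs misaligned")
        length = self.genome.length_of(chrom)
        edges = np.concatenate([[0], pos, [length]]).astype(float)
        widths = np.diff(edges)
        if widths[-1] > 0:
            last_rate = freqs[-1] / max(widths[-2], 1.0)
            probs = np.concatenate([freqs, [last_rate * widths[-1]]])
        else:   # markers reach the chromosome end: no terminal interval
            probs = freqs.copy()
            edges = edges[:-1]
        total = probs.sum()
        if total <= 0:
            raise ValidationError(f"{chrom}: placement density is identically zero")
        probs = probs / total
        return ChromProfile(chrom=chrom, edges=edges, probs=probs,
                            cum=np.concatenate([[0.0], np.cumsum(probs)]))


@dataclass(frozen=True)
class ChromProfile:
    """Compiled placement density: bp edges, interval probabilities and CDF."""

    chrom: str
    edges: np.ndarray   # len n+1, bp
    probs: np.ndarray   # len n
    cum: np.ndarray     # len n+1, cum[0] = 0, cum[-1] = 1

    def genetic_to_bp(self, g) -> np.ndarray:
        """Map normalized genetic coordinate(s) in [0, 1] to bp."""
        return np.interp(g, self.cum, self.edges)


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def count_probs_for_mean(mean_crossovers: float,
                         tail_mass: float | None = None,
                         tail_continuation: float = DEFAULT_TAIL_CONTINUATION,
                         ) -> tuple[float, float, float]:
    """Map a target mean crossover count ``c`` to ``(p1, p2, p3)``.

    The tail mass ``p3`` defaults to ``min(c^2/4, 0.3)``; ``p2`` is then
    chosen so the expected realized count ``p2 + p3 * E[count | >=2]``
    equals ``c`` exactly, with ``E[count | >=2] = 2 + q/(1-q)``.  For means
    the capped tail cannot reach (c close to 2) the tail grows just enough
    to keep ``p1 = 0``.
    """
    c = float(mean_crossovers)
    if c < 0:
        raise ValidationError("mean_crossovers must be >= 0")
    if c > 2:
        raise ValidationError(
            f"mean_crossovers={c} not representable by the none/one/two-or-more "
            "count model (requires mean <= 2)")
    kbar = 2.0 + tail_continuation / (1.0 - tail_continuation)
    p3 = min(c * c / 4.0, 0.3) if tail_mass is None else float(tail_mass)
    p3 = min(p3, c / kbar)
    p2 = c - kbar * p3
    p1 = 1.0 - p2 - p3
    if p1 < -_PROB_TOL and tail_mass is None:
        # default tail cap cannot reach this mean; grow the tail instead
        p3 = (c - 1.0) / (kbar - 1.0)
        p2 = 1.0 - p3
        p1 = 0.0
    if p1 < -_PROB_TOL:
        raise ValidationError(
            f"mean_crossovers={c} with tail mass {p3} leaves p1 = {p1:.4f} < 0")
    return (max(p1, 0.0), p2, p3)


def synthesize_landscape(spec: GenomeSpec,
                         markers_per_chrom: int = 2000,
                         mean_crossovers: float = 1.0,
                         hotspot_profile: str = "uniform",
                         seed=None,
                         *,
                         tail_mass: float | None = None,
                         tail_continuation: float = DEFAULT_TAIL_CONTINUATION,
                         interference_shape: float = 2.0,
                         weight_cv: float = 0.3,
                         enriched_fraction: float = 0.0,
                         ) -> tuple[RecombinationLandscape, MarkerMap]:
    """Generate a species-like landscape and marker map.

    Markers are placed near-uniformly (jittered grid) along each chromosome.
    Coverage-normalization weights are gamma distributed with mean 1 and
    coefficient of variation ``weight_cv``, emulating the locus-to-locus
    coverage variability of Illumina resequencing.  The placement density is
    either proportional to interval length (``uniform``) or suppressed around
    the chromosome centre and elevated toward the ends (``peaked``), a coarse
    caricature of the distal crossover bias of plant chromosomes.

    Deterministic for a fixed ``seed``.
    """
    if markers_per_chrom < 2:
        raise ValidationError("markers_per_chrom must be >= 2")
    if hotspot_profile not in ("uniform", "peaked"):
        raise ValidationError(f"unknown hotspot_profile {hotspot_profile!r}")
    rng = np.random.default_rng(seed)
    probs = count_probs_for_mean(mean_crossovers, tail_mass, tail_continuation)

    rows = []
    interval_freqs: dict[str, np.ndarray] = {}
    for chrom, length in spec.chromosomes:
        k = markers_per_chrom
        grid = np.linspace(length / (k + 1.0), length * k / (k + 1.0), k)
        jitter = (rng.random(k) - 0.5) * 0.8 * (length / (k + 1.0))
        pos = np.unique(np.clip(np.round(grid + jitter), 1, length).astype(np.int64))
        # jitter collisions are only possible on absurdly dense grids
        shape_w = 1.0 / (weight_cv ** 2) if weight_cv > 0 else None
        w = rng.gamma(shape_w, 1.0 / shape_w, len(pos)) if shape_w else np.ones(len(pos))
        enr = np.zeros(len(pos), bool)
        if enriched_fraction > 0:
            n_enr = int(round(enriched_fraction * len(pos)))
            enr[rng.choice(len(pos), size=n_enr, replace=False)] = True
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "norm_weight": w,
            "quality": 40.0, "cnv": False, "enriched": enr,
        }))
        edges = np.concatenate([[0], pos]).astype(float)
        widths = np.diff(edges)
        if hotspot_profile == "uniform":
            f = widths.copy()
        else:
            mid = (edges[:-1] + edges[1:]) / 2.0
            x = 2.0 * mid / length - 1.0  # -1 .. 1
            f = widths * (0.25 + 2.25 * x * x)
        interval_freqs[chrom] = f / f.sum()

    markers = MarkerMap(genome=spec, df=pd.concat(rows, ignore_index=True))
    c = float(mean_crossovers)
    scale = 1.0 / (interference_shape * (c + 1.0))
    landscape = RecombinationLandscape(
        genome=spec,
        count_probs={chrom: probs for chrom in spec.names},
        interval_freqs=interval_freqs,
        interference={chrom: (interference_shape, scale) for chrom in spec.names},
        tail_continuation=tail_continuation,
    )
    landscape.validate_against(markers)
    return landscape, markers


# ---------------------------------------------------------------------------
# Marker filtering
# ---------------------------------------------------------------------------

def filter_markers(raw: MarkerMap,
                   quality_min: float = 25.0,
                   min_spacing: int = 50) -> MarkerMap:
    """Apply the high-quality marker selection rules.

    Markers with a quality score below ``quality_min`` are discarded (markers
    with no quality score are kept), as are markers flagged as overlapping
    copy-number-variable regions.  Then markers closer than ``min_spacing``
    are removed iteratively, scanning left to right and dropping the right
    member of each offending pair, until a fixed point is reached.  The
    operation is idempotent.
    """
    df = raw.df
    qual_ok = df["quality"].isna() | (df["quality"] >= quality_min)
    df = df[qual_ok & ~df["cnv"]]

    kept = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        keep_idx = sub.index.to_numpy()
        while True:
            keep = np.ones(len(pos), bool)
            last = -np.inf
            for i, p in enumerate(pos):
                if p - last < min_spacing:
                    keep[i] = False
                else:
                    last = p
            if keep.all():
                break
            pos, keep_idx = pos[keep], keep_idx[keep]
        kept.append(df.loc[keep_idx])
    out = pd.concat(kept) if kept else df.iloc[:0]
    return MarkerMap(genome=raw.genome, df=out.reset_index(drop=True))


# ---------------------------------------------------------------------------
# File dialects
# ---------------------------------------------------------------------------

_LS_HEADER1 = ["chrom", "length", "p1", "p2", "p3", "gamma_shape", "gamma_scale"]
_LS_HEADER2 = ["chrom", "interval_index", "p_mi"]
_MK_COLUMNS = ["chrom", "pos", "norm_weight", "quality", "cnv", "enriched"]


def write_landscape(landscape: RecombinationLandscape, path) -> None:
    """Write the two-table tab-separated landscape file.

    The first table (one row per chromosome) carries lengths, crossover count
    probabilities and gamma interference parameters; after a blank line the
    second table carries the per-interval recombination frequencies.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_LS_HEADER1) + "\n")
        for chrom, length in landscape.genome.chromosomes:
            p1, p2, p3 = landscape.count_probs[chrom]
            shape, scale = landscape.interference[chrom]
            fh.write(f"{chrom}\t{length}\t{p1:.17g}\t{p2:.17g}\t{p3:.17g}"
                     f"\t{shape:.17g}\t{scale:.17g}\n")
        fh.write("\n")
        fh.write("\t".join(_LS_HEADER2) + "\n")
        for chrom in landscape.genome.names:
            for i, f in enumerate(landscape.interval_freqs[chrom]):
                fh.write(f"{chrom}\t{i}\t{f:.17g}\n")


def write_markers(markers: MarkerMap, path) -> None:
    """Write the tab-separated marker table (1-based positions)."""
    df = markers.df[_MK_COLUMNS].copy()
    df["cnv"] = df["cnv"].astype(int)
    df["enriched"] = df["enriched"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _parse_row(path, lineno, line, ncols, types):
    parts = line.rstrip("\n").split("\t")
    if len(parts) != ncols:
        raise ParseError(f"{path}:{lineno}: expected {ncols} columns, got {len(parts)}")
    out = []
    for value, typ in zip(parts, types):
        try:
            out.append(typ(value))
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: cannot parse {value!r} as {typ.__name__}") from None
    return out


def load_landscape(landscape_path, marker_path
                   ) -> tuple[RecombinationLandscape, MarkerMap]:
    """Load a landscape + marker map pair from their file dialects.

    Raises
    ------
    ParseError
        Naming file and line, on any malformed row.
    ValidationError
        If probabilities do not sum to 1 or tables are misaligned.
    """
    with open(landscape_path) as fh:
        lines = fh.readlines()
    if not lines or lines[0].rstrip("\n").split("\t") != _LS_HEADER1:
        raise ParseError(f"{landscape_path}:1: expected header "
                         + "\t".join(_LS_HEADER1))
    chroms, count_probs, interference = [], {}, {}
    i = 1
    while i < len(lines) and lines[i].strip():
        chrom, length, p1, p2, p3, shape, scale = _parse_row(
            landscape_path, i + 1, lines[i], 7,
            [str, int, float, float, float, float, float])
        chroms.append((chrom, length))
        count_probs[chrom] = (p1, p2, p3)
        interference[chrom] = (shape, scale)
        i += 1
    while i < len(lines) and not lines[i].strip():
        i += 1
    if i >= len(lines) or lines[i].rstrip("\n").split("\t") != _LS_HEADER2:
        raise ParseError(f"{landscape_path}:{i + 1}: expected header "
                         + "\t".join(_LS_HEADER2))
    freqs: dict[str, list] = {c: [] for c, _ in chroms}
    for j in range(i + 1, len(lines)):
        if not lines[j].strip():
            continue
        chrom, idx, p = _parse_row(landscape_path, j + 1, lines[j], 3,
                                   [str, int, float])
        if chrom not in freqs:
            raise ParseError(f"{landscape_path}:{j + 1}: unknown chromosome {chrom!r}")
        if idx != len(freqs[chrom]):
            raise ParseError(f"{landscape_path}:{j + 1}: interval_index {idx} out of order")
        freqs[chrom].append(p)

    genome = GenomeSpec(tuple(chroms))
    landscape = RecombinationLandscape(
        genome=genome,
        count_probs=count_probs,
        interval_freqs={c: np.asarray(v, float) for c, v in freqs.items()},
        interference=interference,
    )
    markers = load_markers(marker_path, genome)
    landscape.validate_against(markers)
    return landscape, markers


def load_markers(path, genome: GenomeSpec) -> MarkerMap:
    """Load a marker table against a known genome."""
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    missing = {"chrom", "pos", "norm_weight"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}:1: missing columns {sorted(missing)}")
    for col in ("cnv", "enriched"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return MarkerMap(genome=genome, df=df)
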