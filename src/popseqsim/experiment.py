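"""Replicate sweeps over pool size x coverage x crossing scheme.

A sweep runs many independent simulated experiments per
``(pool_size, coverage)`` cell — each one full
breed -> select -> sequence -> analyse pass — and aggregates the mean and
standard deviation of the mapping-interval length (outcross) or CAM count
(backcross / direct sequencing), plus the fraction of replicates whose
interval or CAM list contains the causal mutation.  The entire sweep is a
pure function of ``(config, seed)``: every replicate derives its own child
RNG stream from the root seed and its replicate index, so single replicates
can be reproduced in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from . import landscape as ls
from .meiosis import MeiosisModel
from .pedigree import breed_pool, breed_population, mutagenize, select_pool
from .seqsim import SeqParams, sequence_pool
from .calling import (MappingResult, ThresholdParams, analyze_backcross,
                      analyze_outcross, direct_sequencing_cams)

logger = logging.getLogger(__name__)


@dataclass
class SweepConfig:
    """Declarative description of a sweep (YAML-serializable).

    Keys mirror the experiment configuration file: ``scheme`` is one of
    ``outcross`` / ``backcross`` / ``direct``; ``coverages`` are target mean
    reads per sequenced locus; ``n_mutations`` defaults to the high mutation
    load.
    """

    scheme: str = "outcross"
    backcross_rounds: int = 1
    parent_siblings: int = 1
    pool_sizes: list[int] = field(default_factory=lambda: [100])
    coverages: list[float] = field(default_factory=lambda: [25.0])
    n_mutations: int = 1400
    misscore_rate: float = 0.0
    error_rate: float = 0.003
    replicates: int = 500
    seed: int = 0
    species: str = "arabidopsis"
    landscape_path: str | None = None
    marker_path: str | None = None
    markers_per_chrom: int = 1000
    mean_crossovers: float = 1.0
    hotspot_profile: str = "uniform"
    enrichment: bool = False
    enriched_fraction: float = 0.0
    window: int | str = "auto"
    confidence: float = 0.99

    def __post_init__(self):
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not self.pool_sizes or not self.coverages:
            raise ValidationError("pool_sizes and coverages must be nonempty")
        if self.scheme not in ("outcross", "backcross", "direct"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "direct":
            self.pool_sizes = [1]

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        # accept the documented aliases
        if "generations" in raw:
            raw["backcross_rounds"] = raw.pop("generations")
        if "pool_size" in raw:
            raw["pool_sizes"] = [raw.pop("pool_size")]
        if "coverage" in raw:
            raw["coverages"] = [raw.pop("coverage")]
        if "total_reads" in raw:
            raise ValidationError("sweeps are parameterized by coverage")
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def build_inputs(config: SweepConfig):
    """Landscape, markers and compiled meiosis model for a config."""
    if config.landscape_path:
        if not config.marker_path:
            raise ValidationError("landscape_path requires marker_path")
        land, markers = ls.load_landscape(config.landscape_path,
                                          config.marker_path)
    else:
        try:
            spec = ls.SPECIES_PRESETS[config.species]()
        except KeyError:
            raise ValidationError(f"unknown species preset {config.species!r}") from None
        enr = config.enriched_fraction
        if config.enrichment and enr == 0.0:
            enr = 0.013  # ~60 Mb of the barley genome
        land, markers = ls.synthesize_landscape(
            spec, markers_per_chrom=config.markers_per_chrom,
            mean_crossovers=config.mean_crossovers,
            hotspot_profile=config.hotspot_profile,
            seed=config.seed,
            enriched_fraction=enr)
    return land, markers, MeiosisModel(land, markers)


def replicate_rng(seed: int, replicate_index: int,
                  cell: tuple = ()) -> np.random.Generator:
    """Independent, reproducible child stream for one replicate."""
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(*cell, replicate_index))
    logger.debug("replicate %s cell %s -> seed sequence %s",
                 replicate_index, cell, ss)
    return np.random.default_rng(ss)


def run_replicate(config: SweepConfig, replicate_index: int,
                  model: MeiosisModel | None = None,
                  markers: ls.MarkerMap | None = None,
                  pool_size: int | None = None,
                  coverage: float | None = None) -> MappingResult:
    """One full simulate -> sequence -> analyse pass.

    Deterministic given ``(config.seed, replicate_index)`` and the cell
    coordinates.  The heavyweight inputs may be passed in to avoid
    recompiling them per replicate.
    """
    if model is None or markers is None:
        _, markers, model = build_inputs(config)
    pool_size = pool_size if pool_size is not None else config.pool_sizes[0]
    coverage = coverage if coverage is not None else config.coverages[0]
    rng = replicate_rng(config.seed, replicate_index,
                        cell=(int(pool_size), int(round(coverage * 100))))
    try:
        mutations = mutagenize(model.genome, config.n_mutations, rng)
        seq = SeqParams(error_rate=config.error_rate, coverage=coverage,
                        mode="enrichment" if config.enrichment else "wgs")
        if config.scheme == "direct":
            population = breed_population(
                "backcross", 16, model, mutations, rng,
                backcross_rounds=config.backcross_rounds,
                n_parent_siblings=config.parent_siblings)
            pool = select_pool(population, mutations, 1, 0.0, rng,
                               scheme="direct",
                               generation=f"BC{config.backcross_rounds}F2")
            params = ThresholdParams(n=1, m_mis=0, e=config.error_rate)
            return direct_sequencing_cams(pool.individuals[0], mutations,
                                          seq, params, rng)
        rounds = config.backcross_rounds if config.scheme == "backcross" else 1
        pool = breed_pool(config.scheme, pool_size, model, mutations, rng,
                          misscore_rate=config.misscore_rate,
                          backcross_rounds=rounds,
                          n_parent_siblings=config.parent_siblings)
        if config.scheme == "outcross":
            counts = sequence_pool(pool, markers, seq, rng)
            return analyze_outcross(counts, mutations,
                                    confidence=config.confidence,
                                    window=config.window,
                                    pool_size=pool.size)
        counts = sequence_pool(pool, None, seq, rng)
        params = ThresholdParams(n=pool_size,
                                 m_mis=int(round(config.misscore_rate * pool_size)),
                                 e=config.error_rate)
        return analyze_backcross(counts, mutations, params)
    except Exception as exc:
        raise type(exc)(f"replicate {replicate_index} "
                        f"(pool={pool_size}, coverage={coverage}): {exc}") from exc


def run_sweep(config: SweepConfig, out_dir=None) -> pd.DataFrame:
    """Full sweep; returns the per-cell summary table.

    Persists ``summary.tsv`` and replicate-level ``replicates.tsv`` when
    ``out_dir`` is given.  The quantity summarized is the interval length for
    outcross sweeps and the CAM count for backcross / direct sweeps.
    """
    _, markers, model = build_inputs(config)
    records = []
    for pool_size in config.pool_sizes:
        for coverage in config.coverages:
            for rep in range(config.replicates):
                res = run_replicate(config, rep, model=model, markers=markers,
                                    pool_size=pool_size, coverage=coverage)
                records.append({
                    "pool_size": pool_size, "coverage": coverage,
                    "replicate": rep, "chrom": res.chrom or ".",
                    "start": res.start, "end": res.end,
                    "length_bp": res.length, "cam_count": res.cam_count,
                    "causal_inside": bool(res.causal_inside),
                    "warning": res.warning,
                })
            logger.info("cell pool=%s coverage=%s done (%d replicates)",
                        pool_size, coverage, config.replicates)
    reps = pd.DataFrame(records)
    metric = "length_bp" if config.scheme == "outcross" else "cam_count"
    summary = (reps.groupby(["pool_size", "coverage"])
               .agg(mean=(metric, "mean"),
                    sd=(metric, lambda s: s.std(ddof=1) if len(s) > 1 else np.nan),
                    causal_inside_fraction=("causal_inside", "mean"),
                    replicates=("replicate", "count"))
               .reset_index())
    summary.insert(2, "metric", metric)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        reps.to_csv(out / "replicates.tsv", sep="\t", index=False)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return summary


def plot_sweep(summary: pd.DataFrame, path) -> None:
    """Interval-length / CAM-count vs coverage, one line per pool size."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    metric = summary["metric"].iat[0]
    for pool, sub in summary.groupby("pool_size"):
        sub = sub.sort_values("coverage")
        ax.errorbar(sub["coverage"], sub["mean"], yerr=sub["sd"],
                    marker="o", capsize=3, label=f"pool {pool}")
    ax.set_xlabel("mean coverage (x)")
    ax.set_ylabel("mapping interval (bp)" if metric == "length_bp"
                  else "candidate mutations")
    ax.set_xscale("log")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
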