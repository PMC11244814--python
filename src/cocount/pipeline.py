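"""End-to-end orchestration: simulate or load, analyse, and emit a report.

The report bundle holds, per genotype: a gamma fit of pooled inter-focus
spacings, CoC curves per chromosome group (ranks 1-2 and 3-7 by default,
mirroring the convention of plotting long and short bivalents separately),
the E-distribution over bivalents, morphometry summaries, and the focus
count vs SC length regression.  A manifest records the package version, the
seed and a configuration hash; identical config + seed gives byte-identical
numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .errors import CocountError, ParameterError
from .interference import coc_curve, e_distribution, fit_gamma_shape, pooled_distances
from .io_tables import read_cohorts, write_results
from .model import Cohort
from .morphometry import co_density, regress_count_on_length, summarize
from .synthetic import FragmentationConfig, SimConfig, simulate_cohort

log = logging.getLogger(__name__)

ALL_ANALYSES = ("gamma", "coc", "e_dist", "morphometry", "regression")
DEFAULT_GROUPS = {"ranks_1_2": (1, 2), "ranks_3_7": (3, 4, 5, 6, 7)}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run: exactly one input source."""

    input_path: str | None = None
    sim: SimConfig | None = None
    analyses: tuple[str, ...] = ALL_ANALYSES
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    units: str = "microns"  # units for the gamma fit
    n_bootstrap: int = 200
    seed: int = 0
    out_dir: str | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ParameterError("exactly one of input_path / sim must be given")
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise ParameterError(f"unknown analyses {sorted(unknown)}")


def _config_hash(config: RunConfig) -> str:
    # output location and plotting do not affect the numbers
    essential = dataclasses.replace(config, out_dir=None, make_plots=False)
    return hashlib.sha256(repr(essential).encode()).hexdigest()[:16]


def _load_cohorts(config: RunConfig) -> dict[str, Cohort]:
    if config.sim is not None:
        cohort = simulate_cohort(config.sim)
        return {cohort.genotype: cohort}
    return read_cohorts(config.input_path)


def _stage(name: str, genotype: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except CocountError as err:
        raise type(err)(f"stage {name!r}, genotype {genotype!r}: {err}") from err


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analyses and return (and optionally write) a bundle."""
    cohorts = _load_cohorts(config)
    bundle: dict = {
        "manifest": {
            "cocount_version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "input": config.input_path or f"simulated:{config.sim.seed}",
            "genotypes": sorted(cohorts),
        },
        "genotypes": {},
    }
    for genotype, cohort in cohorts.items():
        res: dict = {}
        tracks = cohort.tracks()
        if "gamma" in config.analyses:
            spacings = pooled_distances(tracks, units=config.units)
            res["gamma_fit"] = _stage(
                "gamma", genotype, fit_gamma_shape, spacings,
                n_bootstrap=config.n_bootstrap, seed=config.seed,
                units_flag=config.units,
            )
        if "coc" in config.analyses:
            res["coc"] = {}
            for group_name, ranks in config.groups.items():
                group_tracks = cohort.tracks(ranks=set(ranks))
                if group_tracks:
                    res["coc"][group_name] = _stage(
                        "coc", genotype, coc_curve, group_tracks, "auto", group_name
                    )
        if "e_dist" in config.analyses:
            counts = [t.n_foci for t in tracks]
            res["e_distribution"] = _stage("e_dist", genotype, e_distribution, counts)
        if "morphometry" in config.analyses:
            res["morphometry"] = {
                q: _stage("morphometry", genotype, summarize, cohort, q)
                for q in ("focus_count", "total_sc_length", "n_segments",
                          "mean_inter_focus_distance")
            }
            res["morphometry"]["co_density_per_um"] = _stage(
                "morphometry", genotype, co_density, cohort
            )
        if "regression" in config.analyses:
            res["regression"] = _stage(
                "regression", genotype, regress_count_on_length, cohort
            )
        bundle["genotypes"][genotype] = res

    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    write_results(bundle["manifest"], os.path.join(config.out_dir, "manifest.json"),
                  format="json")
    write_results(bundle, os.path.join(config.out_dir, "report.json"), format="json")
    for genotype, res in bundle["genotypes"].items():
        write_results(res, os.path.join(config.out_dir, f"results_{genotype}.csv"),
                      format="csv")
    if config.make_plots:
        _write_plots(bundle, config.out_dir)


def _write_plots(bundle: dict, out_dir: str) -> None:
    """Optional CoC-curve and E-distribution panels (never part of acceptance)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for genotype, res in bundle["genotypes"].items():
        if "coc" in res and res["coc"]:
            fig, axes = plt.subplots(1, len(res["coc"]), figsize=(5 * len(res["coc"]), 4))
            if len(res["coc"]) == 1:
                axes = [axes]
            for ax, (group, curve) in zip(axes, res["coc"].items()):
                xs = [p.distance for p in curve.points]
                ys = [p.coc for p in curve.points]
                ax.plot(xs, ys, "o-", ms=3)
                ax.axhline(1.0, color="grey", lw=0.5)
                ax.axhline(0.5, color="red", lw=0.5, ls="--")
                ax.set_xlabel("inter-interval distance (um)")
                ax.set_ylabel("CoC")
                ax.set_title(f"{genotype} {group}")
            fig.tight_layout()
            fig.savefig(os.path.join(out_dir, f"coc_{genotype}.png"), dpi=120)
            plt.close(fig)
        if "e_distribution" in res:
            ed = res["e_distribution"]
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.bar(range(len(ed.proportions)), ed.proportions)
            ax.set_xlabel("foci per bivalent")
            ax.set_ylabel("proportion")
            ax.set_title(f"{genotype} E-distribution")
            fig.tight_layout()
            fig.savefig(os.path.join(out_dir, f"edist_{genotype}.png"), dpi=120)
            plt.close(fig)


# ---------------------------------------------------------------------------
# YAML config loading (for the CLI)


def load_run_config(path: str) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim = None
    if "sim" in raw:
        sim_raw = dict(raw.pop("sim"))
        if "fragmentation" in sim_raw and sim_raw["fragmentation"] is not None:
            sim_raw["fragmentation"] = FragmentationConfig(**sim_raw["fragmentation"])
        if "chromosome_lengths" in sim_raw:
            sim_raw["chromosome_lengths"] = tuple(sim_raw["chromosome_lengths"])
        sim = SimConfig(**sim_raw)
    if "analyses" in raw:
        raw["analyses"] = tuple(raw["analyses"])
    if "groups" in raw:
        raw["groups"] = {k: tuple(v) for k, v in raw["groups"].items()}
    return RunConfig(sim=sim, **raw)
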