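"""End-to-end analysis: data in, indices, dependence, regressions, bootstrap out.

The pipeline either loads the packaged study table (per-species L, H, CC and
IPD for the two communities) or rebuilds everything from raw inputs: census
records are aggregated into the weighted network, specialization indices are
computed for the species with seed-set data, dependence scores are derived
from the exclusion experiment, and IPD is regressed on each requested index
by OLS and — when a phylogeny is supplied — by GEE with a Brownian working
correlation.  An optional bootstrap reports, per predictor, the fraction of
resamples-to-larger-n whose slope is significant.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pollindep import io as pio
from pollindep import network as pnet
from pollindep.dependence import dependence_table
from pollindep.inference import (
    RegressionSpec,
    bootstrap_significance,
    fit_gee,
    fit_ols,
)
from pollindep.phylo import parse_newick, phylo_correlation, phylogenetic_df, resolve_polytomies

logger = logging.getLogger(__name__)

#: predictors that are natural-log transformed before regression, matching
#: the study's treatment of the right-skewed linkage level
DEFAULT_LOG_PREDICTORS = ("L",)


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; all randomness flows from ``seed``."""

    census_path: str | None = None
    seedset_path: str | None = None
    tree_path: str | None = None
    fixture_site: str | None = None  # SB | PM | both; overrides raw inputs
    predictors: tuple[str, ...] = ("L", "H", "CC")
    log_predictors: tuple[str, ...] = DEFAULT_LOG_PREDICTORS
    form: str = "linear"
    bootstrap: bool = False
    n_target: int = 27
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key = value`` (or ``key: value``) config file."""
        fields = cls.__dataclass_fields__
        kwargs = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            sep = "=" if "=" in line else ":"
            key, _, value = line.partition(sep)
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            hint = fields[key].type
            if "tuple" in hint:
                kwargs[key] = tuple(v.strip() for v in value.split(",") if v.strip())
            elif "bool" in hint:
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif "int" in hint:
                kwargs[key] = int(value)
            elif "float" in hint:
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _study_frame(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Per-species analysis table (species, L, H, CC, IPD) plus extras."""
    extras: dict = {}
    if config.fixture_site:
        table = pio.load_study_table(config.fixture_site)
        frame = table.rename(columns={"species": "plant_id"})[
            ["plant_id", "L", "H", "CC", "IPD"]
        ]
        return frame, extras
    if not (config.census_path and config.seedset_path):
        raise ValueError("need census_path and seedset_path (or a fixture_site)")
    census = pio.read_census(config.census_path)
    seedset = pio.read_seedset(config.seedset_path)
    net = pnet.build_network(census)
    extras["network"] = net
    extras["descriptors"] = pnet.descriptors(net)
    dep = dependence_table(seedset)
    known = set(net.plant_labels)
    missing = [s for s in dep["plant_id"] if s not in known]
    for species in missing:
        logger.warning("species %r has seed-set data but no network record: excluded", species)
    dep = dep[dep["plant_id"].isin(known)]
    if len(dep) < 3:
        raise ValueError(
            f"only {len(dep)} species remain after matching seed-set data to the "
            "network; at least 3 are needed for regression"
        )
    for species in sorted(known):
        logger.info(
            "species %r %s", species,
            "retained" if species in set(dep["plant_id"]) else "network-only (no seed set)",
        )
    indices = pnet.specialization_table(net, list(dep["plant_id"]))
    extras["dependence"] = dep
    frame = indices.merge(dep[["plant_id", "ipd"]], on="plant_id").rename(
        columns={"ipd": "IPD"}
    )
    return frame, extras


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; deterministic given ``config.seed``.

    Returns a bundle with the analysis frame, network descriptors when a
    census was read, a regression table (one LM row per predictor, plus a
    GEE row when a tree is given), and a bootstrap table when requested.
    When ``config.outdir`` is set, every table plus a JSON run log (seed,
    versions, settings) is written there.
    """
    frame, bundle = _study_frame(config)
    bundle["data"] = frame

    tree = corr = None
    dfp = None
    if config.tree_path:
        tree = resolve_polytomies(parse_newick(Path(config.tree_path).read_text()), config.seed)
        species = list(frame["plant_id"])
        corr = phylo_correlation(tree, species)
        dfp = phylogenetic_df(tree, species)

    y = frame["IPD"].to_numpy(float)
    reg_rows = []
    for predictor in config.predictors:
        transform = "log" if predictor in config.log_predictors else "none"
        x = frame[predictor].to_numpy(float)
        spec = RegressionSpec(predictor=predictor, transform=transform, form=config.form)
        fits = [fit_ols(x, y, spec)]
        if corr is not None:
            gee_spec = RegressionSpec(
                predictor=predictor, transform=transform, form=config.form, method="GEE"
            )
            fits.append(fit_gee(x, y, gee_spec, corr, dfp=dfp))
        for res in fits:
            reg_rows.append(
                {
                    "response": "IPD",
                    "variable": res.spec.label,
                    "type": res.spec.method,
                    "estimate": res.estimate,
                    "se": res.se,
                    "t": res.t,
                    "p": res.p,
                    "r2": res.r2,
                    "df": res.df,
                    "n": res.n,
                }
            )
    bundle["regressions"] = pd.DataFrame(reg_rows)

    if config.bootstrap:
        boot_rows = []
        for k, predictor in enumerate(config.predictors):
            transform = "log" if predictor in config.log_predictors else "none"
            spec = RegressionSpec(predictor=predictor, transform=transform)
            summary = bootstrap_significance(
                frame[predictor].to_numpy(float),
                y,
                spec,
                n_target=config.n_target,
                n_boot=config.n_boot,
                alpha=config.alpha,
                seed=config.seed + k,
            )
            boot_rows.append(summary.__dict__)
        bundle["bootstrap"] = pd.DataFrame(boot_rows)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(outdir / "analysis_data.csv", index=False)
        bundle["regressions"].to_csv(outdir / "regressions.csv", index=False)
        if "bootstrap" in bundle:
            bundle["bootstrap"].to_csv(outdir / "bootstrap.csv", index=False)
        if "descriptors" in bundle:
            pd.DataFrame([bundle["descriptors"].__dict__]).to_csv(
                outdir / "network_descriptors.csv", index=False
            )
        if "network" in bundle:
            bundle["network"].to_frame().to_csv(outdir / "network_edges.csv", index=False)
        settings = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.__dict__.items()
        }
        log = {
            "settings": settings,
            "seed": config.seed,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "dfP": dfp,
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return bundle
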