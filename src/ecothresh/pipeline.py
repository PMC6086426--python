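"""End-to-end orchestration: classify -> summarize -> fit -> select -> threshold.

One :class:`RunConfig` drives the whole analysis, either from real CSV
inputs (counts + covariates + literature labels) or from a synthetic
scenario.  Outputs are written atomically: everything is assembled in a
temporary directory and moved into place only when every stage succeeded,
so a failed run leaves no partial bundle behind.  With a fixed config and
seed the output CSVs are byte-identical across reruns (the run log records
the config hash, seed and library versions, never wall-clock time).
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels
import yaml

from . import __version__, community
from .classification import classify_all
from .community import CommunityTable, abundance_series, alpha_mean_series, gamma_series
from .errors import EmptySubgroupError, InputError
from .models import FitConfig, fit_all
from .selection import diagnose, select, selection_to_frame
from .simulate import ScenarioConfig, generate
from .threshold import PiecewiseConfig, threshold_report

log = logging.getLogger("ecothresh")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one input mode must be set: either the three real-data paths
    (``counts``, ``covariates``, ``literature``) or a synthetic
    ``scenario`` path/object.
    """

    outdir: str = "ecothresh_run"
    counts: str | None = None
    covariates: str | None = None
    literature: str | None = None
    scenario: str | ScenarioConfig | None = None
    abundance_level: str = "landscape"
    k_mode: str = "conventional"
    alpha: float = 0.05
    n_permutations: int = 999
    delta_aicc_cutoff: float = 2.0
    piecewise_flat_plateau: bool = False
    n_restarts: int = 20
    seed: int = 0
    subgroups: tuple = ("FS", "G", "OS")

    def __post_init__(self) -> None:
        real = all(p is not None for p in (self.counts, self.covariates, self.literature))
        synth = self.scenario is not None
        if real == synth:
            raise InputError(
                "set exactly one input mode: counts+covariates+literature, or scenario"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "subgroups" in raw:
            raw["subgroups"] = tuple(raw["subgroups"])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded, so identical analyses hash alike wherever they write)."""
        raw = {k: (str(v) if isinstance(v, (Path, ScenarioConfig)) else v)
               for k, v in self.__dict__.items() if k != "outdir"}
        blob = json.dumps(raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_table(config: RunConfig) -> CommunityTable:
    if config.scenario is not None:
        scenario = config.scenario
        if not isinstance(scenario, ScenarioConfig):
            scenario = ScenarioConfig.from_yaml(scenario)
        table, _ = generate(scenario)
        return table
    return community.read_community_table(config.counts, config.covariates)


def _series_inventory(table: CommunityTable, config: RunConfig):
    """The per-subgroup series the analysis fits: abundance and mean alpha
    per habitat, gamma pooled over all plots.  Subgroups with no member
    species (e.g. nothing classified OS) are skipped with a log line."""
    for subgroup in config.subgroups:
        specs = []
        for habitat in community.HABITATS:
            specs.append(("abundance", habitat))
            specs.append(("alpha_mean", habitat))
        specs.append(("gamma", "both"))
        for metric, habitat in specs:
            try:
                if metric == "abundance":
                    yield abundance_series(table, subgroup, habitat, level=config.abundance_level)
                elif metric == "alpha_mean":
                    yield alpha_mean_series(table, subgroup, habitat)
                else:
                    yield gamma_series(table, subgroup, habitat)
            except EmptySubgroupError as exc:
                log.info("skipping %s/%s/%s: %s", subgroup, metric, habitat, exc)
                break  # no member species: every metric would fail alike


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write the result bundle.

    Returns a summary dict with the output paths and the per-series best
    sets.  Any stage error aborts with a stage-tagged message and removes
    partial outputs.
    """
    outdir = Path(config.outdir)
    tmp = outdir.parent / (outdir.name + ".partial")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    stage = "setup"
    try:
        stage = "input"
        table = _load_table(config)

        stage = "classification"
        if config.scenario is not None:
            literature = pd.DataFrame(
                {
                    "species": list(table.species_labels),
                    "literature_label": list(table.species_labels.values()),
                }
            )
        else:
            literature = pd.read_csv(config.literature)
        classification = classify_all(
            table,
            literature,
            alpha=config.alpha,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        classification.to_frame().to_csv(tmp / "classification.csv", index=False)
        table = table.with_labels(classification.labels())

        stage = "series"
        series_list = list(_series_inventory(table, config))
        community.series_to_csv(series_list, tmp / "series.csv")

        stage = "fitting"
        fit_config = FitConfig(
            n_restarts=config.n_restarts, seed=config.seed, k_mode=config.k_mode
        )
        fit_rows, sel_frames, diag_rows, thr_frames = [], [], [], []
        summary = {}
        for series in series_list:
            fits = fit_all(series, fit_config)
            for f in fits:
                fit_rows.append(
                    {
                        "series": series.label,
                        "model": f.model,
                        "family": f.family,
                        "params": json.dumps(f.params.values) if f.params else "",
                        "sigma": f.params.sigma if f.params else np.nan,
                        "loglik": f.loglik,
                        "K": f.K,
                        "n": f.n,
                        "converged": f.converged,
                    }
                )
            sel = select(fits, delta_cutoff=config.delta_aicc_cutoff, series_id=series.label)
            sel_frames.append(selection_to_frame(sel))
            summary[series.label] = sel.best_set
            for f in fits:
                if f.converged and f.model in sel.best_set:
                    rep = diagnose(series, f, alpha=config.alpha)
                    diag_rows.append(rep.__dict__)
            log_fit = next((f for f in fits if f.model == "LOG" and f.converged), None)
            midpoint = log_fit.params.values["b"] if log_fit else None
            est = threshold_report(
                sel,
                series,
                PiecewiseConfig(flat_plateau=config.piecewise_flat_plateau),
                logistic_midpoint=midpoint,
            )
            thr_frames.append(est.to_frame(series.label))

        stage = "output"
        pd.DataFrame(fit_rows).to_csv(tmp / "fits.csv", index=False)
        pd.concat(sel_frames, ignore_index=True).to_csv(tmp / "selection.csv", index=False)
        pd.DataFrame(diag_rows).to_csv(tmp / "diagnostics.csv", index=False)
        pd.concat(thr_frames, ignore_index=True).to_csv(tmp / "thresholds.csv", index=False)
        run_log = {
            "config_hash": config.digest(),
            "seed": config.seed,
            "versions": {
                "ecothresh": __version__,
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "statsmodels": statsmodels.__version__,
            },
            "n_series": len(series_list),
            "best_sets": summary,
        }
        (tmp / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))

        if outdir.exists():
            shutil.rmtree(outdir)
        tmp.rename(outdir)
    except Exception as exc:
        shutil.rmtree(tmp, ignore_errors=True)
        exc.args = (f"[stage: {stage}] {exc}",)
        raise
    return {"outdir": str(outdir), "best_sets": summary}
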