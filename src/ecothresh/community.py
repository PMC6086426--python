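"""Plot-level community count tables and per-landscape response series.

The observational unit is a *plot*: a sampling site inside one landscape,
belonging to either the ``forest`` or the ``matrix`` (non-forest) habitat
class, with a vector of per-species individual counts.  Landscapes carry a
single covariate, percent forest cover, which is the predictor of every
downstream model.  Three summaries are derived per landscape:

* **abundance** — total individuals of a subgroup over the habitat's plots
  (count data, Poisson error family);
* **mean alpha diversity** — mean over plots of the number of subgroup
  species present in the plot, with a Student-t 95% confidence interval
  over plots (normal error family);
* **gamma diversity** — number of subgroup species present anywhere in the
  in-scope plots (observed richness, no estimator applied; normal family).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySubgroupError, InputError

HABITATS = ("forest", "matrix")
SUBGROUPS = ("FS", "G", "OS", "unclassified", "total")
METRICS = ("abundance", "alpha_mean", "gamma")
ID_COLUMNS = ("landscape_id", "habitat", "plot_id")


@dataclass
class CommunityTable:
    """Validated plot x species count matrix joined to landscape covariates.

    Parameters
    ----------
    plots
        One row per plot with columns ``landscape_id``, ``habitat``,
        ``plot_id`` followed by one non-negative integer column per species.
    covariates
        Mapping landscape_id -> percent forest cover (0-100), as a Series.
    species_labels
        Optional mapping species -> habitat-use subgroup
        (``FS``/``G``/``OS``/``unclassified``); attached after
        classification and required by the subgroup series operations.
    """

    plots: pd.DataFrame
    covariates: pd.Series
    species_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.plots = self.plots.reset_index(drop=True)
        self.covariates = pd.Series(self.covariates).astype(float)
        self.covariates.index = self.covariates.index.astype(str)
        self._validate()

    # -- structure ---------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return [c for c in self.plots.columns if c not in ID_COLUMNS]

    @property
    def landscapes(self) -> list[str]:
        """Landscape ids ordered by increasing forest cover."""
        ids = self.plots["landscape_id"].unique().tolist()
        return sorted(ids, key=lambda i: (self.covariates[i], i))

    def counts(self) -> pd.DataFrame:
        return self.plots[self.species]

    def with_labels(self, labels: dict[str, str]) -> "CommunityTable":
        missing = [s for s in self.species if s not in labels]
        if missing:
            raise InputError(f"species without a subgroup label: {missing}")
        return replace(self, species_labels=dict(labels))

    def _validate(self) -> None:
        for col in ID_COLUMNS:
            if col not in self.plots.columns:
                raise InputError(f"counts table lacks required column {col!r}")
        self.plots["landscape_id"] = self.plots["landscape_id"].astype(str)
        self.plots["plot_id"] = self.plots["plot_id"].astype(str)

        bad_hab = set(self.plots["habitat"]) - set(HABITATS)
        if bad_hab:
            raise InputError(
                f"unknown habitat label(s) {sorted(bad_hab)}; expected one of {HABITATS}"
            )
        if not self.species:
            raise InputError("counts table has no species columns")

        counts = self.plots[self.species]
        numeric = counts.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().any().any():
            r, c = np.argwhere(numeric.isna().to_numpy())[0]
            raise InputError(
                f"non-numeric count at row {r}, species {self.species[c]!r}"
            )
        frac, _ = np.modf(numeric.to_numpy(dtype=float))
        if np.any(frac != 0):
            r, c = np.argwhere(frac != 0)[0]
            raise InputError(
                f"non-integer count at row {r}, species {self.species[c]!r}"
            )
        if (numeric.to_numpy() < 0).any():
            r, c = np.argwhere(numeric.to_numpy() < 0)[0]
            raise InputError(
                f"negative count at row {r}, species {self.species[c]!r}"
            )
        self.plots[self.species] = numeric.astype(np.int64)

        missing_cov = sorted(
            set(self.plots["landscape_id"]) - set(self.covariates.index)
        )
        if missing_cov:
            raise InputError(
                f"no forest_cover covariate for landscape(s): {missing_cov}"
            )
        cov = self.covariates[self.plots["landscape_id"].unique()]
        if ((cov < 0) | (cov > 100)).any():
            raise InputError("forest_cover must lie in [0, 100]")

        dup = self.plots.duplicated(subset=list(ID_COLUMNS))
        if dup.any():
            raise InputError(
                "duplicate plot record(s): "
                f"{self.plots.loc[dup, list(ID_COLUMNS)].to_dict('records')}"
            )
        per = self.plots.groupby("landscape_id")["habitat"].agg(set)
        incomplete = [i for i, habs in per.items() if habs != set(HABITATS)]
        if incomplete:
            raise InputError(
                f"landscape(s) lacking a plot in each habitat class: {incomplete}"
            )

    # -- i/o ---------------------------------------------------------------

    def to_csv(self, counts_path, covariates_path) -> None:
        self.plots.to_csv(counts_path, index=False)
        cov = self.covariates.rename("forest_cover").rename_axis("landscape_id")
        cov.to_frame().reset_index().to_csv(covariates_path, index=False)


def read_community_table(counts_path, covariates_path) -> CommunityTable:
    """Read and validate the counts + covariates CSV pair.

    The counts file has ``landscape_id,habitat,plot_id`` then one column per
    species; the covariates file maps ``landscape_id`` to ``forest_cover``.
    Hard errors name the offending landscape, row or column.
    """
    plots = pd.read_csv(counts_path, dtype={c: str for c in ("landscape_id", "plot_id")})
    cov = pd.read_csv(covariates_path, dtype={"landscape_id": str})
    for col in ("landscape_id", "forest_cover"):
        if col not in cov.columns:
            raise InputError(f"covariates file lacks required column {col!r}")
    if cov["landscape_id"].duplicated().any():
        dups = cov.loc[cov["landscape_id"].duplicated(), "landscape_id"].tolist()
        raise InputError(f"duplicate covariate rows for landscape(s): {dups}")
    covariates = cov.set_index("landscape_id")["forest_cover"]
    return CommunityTable(plots=plots, covariates=covariates)


@dataclass
class ResponseSeries:
    """One (forest cover, response) series for a subgroup x metric x habitat.

    ``family`` tags the error model used downstream: ``poisson`` for
    abundance counts, ``normal`` for mean alpha and gamma diversity.
    ``level`` is ``landscape`` (one observation per landscape, the default
    design) or ``plot`` (one per plot; x values then repeat).
    """

    metric: str
    habitat: str
    subgroup: str
    x: np.ndarray
    y: np.ndarray
    family: str
    landscape_ids: list[str] = field(default_factory=list)
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    level: str = "landscape"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise InputError("x and y must have equal length")
        order = np.argsort(self.x, kind="stable")
        self.x = self.x[order]
        self.y = self.y[order]
        if self.landscape_ids:
            self.landscape_ids = [self.landscape_ids[i] for i in order]
        if self.ci_low is not None:
            self.ci_low = np.asarray(self.ci_low, float)[order]
            self.ci_high = np.asarray(self.ci_high, float)[order]
        if self.level == "landscape":
            if len(set(self.landscape_ids)) != self.n and self.landscape_ids:
                raise InputError("duplicate landscapes in a landscape-level series")
            if np.any(np.diff(self.x) <= 0) and self.n > 1:
                raise InputError("forest-cover values must be distinct per landscape")
        if self.family == "poisson":
            if np.any(self.y < 0) or np.any(np.modf(self.y)[0] != 0):
                raise InputError("poisson-family responses must be counts >= 0")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def label(self) -> str:
        return f"{self.subgroup}_{self.metric}_{self.habitat}"

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "metric": self.metric,
                "habitat": self.habitat,
                "subgroup": self.subgroup,
                "landscape_id": self.landscape_ids or [""] * self.n,
                "forest_cover": self.x,
                "y": self.y,
            }
        )
        out["ci_low"] = self.ci_low if self.ci_low is not None else np.nan
        out["ci_high"] = self.ci_high if self.ci_high is not None else np.nan
        return out


def _member_species(table: CommunityTable, subgroup: str) -> list[str]:
    if subgroup == "total":
        return table.species
    if table.species_labels is None:
        raise InputError(
            "subgroup series require species labels; call with_labels() first"
        )
    members = [s for s in table.species if table.species_labels.get(s) == subgroup]
    if not members:
        raise EmptySubgroupError(f"subgroup {subgroup!r} has no member species")
    return members


def _habitat_plots(table: CommunityTable, habitat: str) -> pd.DataFrame:
    if habitat not in HABITATS:
        raise InputError(f"habitat must be one of {HABITATS}, got {habitat!r}")
    return table.plots[table.plots["habitat"] == habitat]


def abundance_series(
    table: CommunityTable, subgroup: str, habitat: str, level: str = "landscape"
) -> ResponseSeries:
    """Total individuals of a subgroup per landscape (or per plot).

    A subgroup that exists but was never captured in the habitat yields an
    all-zero series (so that model selection can still run and pick the
    null model); a subgroup with no member species at all is an error.
    """
    members = _member_species(table, subgroup)
    sub = _habitat_plots(table, habitat)
    if level == "plot":
        y = sub[members].sum(axis=1).to_numpy()
        x = table.covariates[sub["landscape_id"]].to_numpy()
        ids = (sub["landscape_id"] + "/" + sub["plot_id"]).tolist()
        return ResponseSeries("abundance", habitat, subgroup, x, y, "poisson", ids, level="plot")
    totals = sub.groupby("landscape_id")[members].sum().sum(axis=1)
    ids = table.landscapes
    y = totals.reindex(ids, fill_value=0).to_numpy()
    x = table.covariates[ids].to_numpy()
    return ResponseSeries("abundance", habitat, subgroup, x, y, "poisson", list(ids))


def alpha_mean_series(table: CommunityTable, subgroup: str, habitat: str) -> ResponseSeries:
    """Mean per-plot richness of a subgroup, with t-based 95% CI over plots."""
    members = _member_species(table, subgroup)
    sub = _habitat_plots(table, habitat)
    richness = (sub[members] > 0).sum(axis=1).astype(float)
    grouped = richness.groupby(sub["landscape_id"])
    ids = table.landscapes
    means, lows, highs = [], [], []
    for lid in ids:
        vals = grouped.get_group(lid).to_numpy() if lid in grouped.groups else np.zeros(1)
        m = float(vals.mean())
        if vals.size > 1 and vals.std(ddof=1) > 0:
            half = stats.t.ppf(0.975, vals.size - 1) * vals.std(ddof=1) / np.sqrt(vals.size)
        else:
            half = 0.0
        means.append(m)
        lows.append(m - half)
        highs.append(m + half)
    x = table.covariates[ids].to_numpy()
    return ResponseSeries(
        "alpha_mean", habitat, subgroup, x, np.array(means), "normal",
        list(ids), ci_low=np.array(lows), ci_high=np.array(highs),
    )


def gamma_series(table: CommunityTable, subgroup: str, habitat_scope: str = "both") -> ResponseSeries:
    """Observed subgroup richness pooled over the in-scope plots per landscape.

    No richness estimator is applied: gamma is the raw count of subgroup
    species with total captures > 0 across the landscape's in-scope plots.
    """
    members = _member_species(table, subgroup)
    if habitat_scope == "both":
        sub = table.plots
    else:
        sub = _habitat_plots(table, habitat_scope)
    totals = sub.groupby("landscape_id")[members].sum()
    ids = table.landscapes
    gam = (totals.reindex(ids, fill_value=0) > 0).sum(axis=1).to_numpy(dtype=float)
    x = table.covariates[ids].to_numpy()
    return ResponseSeries("gamma", habitat_scope, subgroup, x, gam, "normal", list(ids))


def series_to_csv(series_list: list[ResponseSeries], path) -> None:
    """Write a tidy CSV of one or more response series."""
    frames = [s.to_frame() for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
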