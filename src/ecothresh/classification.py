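"""Habitat-use classification of species: literature vs. empirical labels.

Each species receives a literature-derived habitat-use label and, when at
least 20 individuals were captured, an empirical label from an indicator
species analysis (IndVal, Dufrene & Legendre site-group form) contrasting
forest against matrix plots.  The two labels are then reconciled into a
final category: forest specialist (FS), habitat generalist (G), open-area
specialist (OS), or unclassified when neither source is informative (II).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import HABITATS, CommunityTable
from .errors import InputError

LABELS = ("FS", "G", "OS", "II")
FINAL_LABELS = ("FS", "G", "OS", "unclassified")

#: minimum captures for an empirical (IndVal-based) label
MIN_INDIVIDUALS = 20


@dataclass
class IndValResult:
    """Indicator value of one species for its best site group.

    ``A`` is specificity (relative mean abundance in the group), ``B`` is
    fidelity (fraction of the group's plots occupied); ``indval`` is
    A*B*100 for the maximizing group, with a permutation p-value obtained
    by reshuffling habitat labels across plots.
    """

    species: str
    group: str
    A: float
    B: float
    indval: float
    p_value: float
    n_total: int
    per_group: dict[str, dict[str, float]]


def _group_stats(counts: np.ndarray, is_forest: np.ndarray) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    means = {}
    for g in HABITATS:
        mask = is_forest if g == "forest" else ~is_forest
        means[g] = counts[mask].mean()
    total_mean = sum(means.values())
    for g in HABITATS:
        mask = is_forest if g == "forest" else ~is_forest
        a = means[g] / total_mean if total_mean > 0 else 0.0
        b = float((counts[mask] > 0).mean())
        out[g] = {"A": a, "B": b, "indval": a * b * 100.0}
    return out


def indval(
    table: CommunityTable,
    species: str,
    n_permutations: int = 999,
    seed: int | None = None,
) -> IndValResult:
    """Indicator value analysis of one species over forest vs. matrix plots.

    The statistic for group g is ``A_g * B_g * 100`` where
    ``A_g = mean abundance in g / sum over groups of mean abundances`` and
    ``B_g = fraction of g's plots where the species occurs``; the species'
    IndVal is the maximum over the two groups.  Significance is assessed by
    permuting habitat labels across all plots: the p-value is the fraction
    of permutations (the observed labelling included) whose maximum IndVal
    reaches the observed one, hence never smaller than
    ``1 / (n_permutations + 1)``.
    """
    if species not in table.species:
        raise InputError(f"species {species!r} not present in the table")
    if n_permutations < 99:
        raise InputError("n_permutations must be >= 99")
    counts = table.plots[species].to_numpy(dtype=float)
    n_total = int(counts.sum())
    if n_total == 0:
        raise InputError(f"species {species!r} has zero total abundance")
    is_forest = (table.plots["habitat"] == "forest").to_numpy()
    if is_forest.sum() < 2 or (~is_forest).sum() < 2:
        raise InputError("IndVal requires at least 2 plots per habitat group")

    per_group = _group_stats(counts, is_forest)
    # forest wins deterministic ties, matching the HABITATS ordering
    group = max(HABITATS, key=lambda g: per_group[g]["indval"])
    observed = per_group[group]["indval"]

    rng = np.random.default_rng(seed)
    hits = 1  # observed labelling counts as one permutation
    for _ in range(n_permutations):
        perm = rng.permutation(is_forest)
        stat = max(_group_stats(counts, perm)[g]["indval"] for g in HABITATS)
        if stat >= observed - 1e-12:
            hits += 1
    p = hits / (n_permutations + 1)
    return IndValResult(
        species=species,
        group=group,
        A=per_group[group]["A"],
        B=per_group[group]["B"],
        indval=observed,
        p_value=p,
        n_total=n_total,
        per_group=per_group,
    )


def empirical_label(
    result: IndValResult,
    alpha: float = 0.05,
    generalist_rule: str = "both_habitats",
) -> str:
    """Empirical habitat-use label from an IndVal result.

    Species below the 20-individual cut-off are II (insufficient
    information).  A significant forest indicator is FS, a significant
    matrix indicator OS.  Without a significant single-group indication the
    default rule labels a species G when it occurs in both habitats
    (``generalist_rule="both_habitats"``); ``"any"`` labels every
    non-significant species G.
    """
    if result.n_total < MIN_INDIVIDUALS:
        return "II"
    if result.p_value < alpha:
        return "FS" if result.group == "forest" else "OS"
    if generalist_rule == "any":
        return "G"
    occupies_both = all(result.per_group[g]["B"] > 0 for g in HABITATS)
    return "G" if occupies_both else "II"


def reconcile(
    literature_label: str,
    empirical_label: str,
    policy: str = "prefer_empirical",
) -> str:
    """Reconcile a literature label with an empirical label.

    Concordant labels (or one II and one informative label) resolve to the
    informative label; two IIs resolve to ``unclassified``.  Discordant
    informative labels follow ``policy``: ``prefer_empirical`` (default,
    with a warning), ``prefer_literature``, or ``error``.
    """
    for name, lab in (("literature", literature_label), ("empirical", empirical_label)):
        if lab not in LABELS:
            raise InputError(f"{name} label {lab!r} not in {LABELS}")
    if literature_label == "II" and empirical_label == "II":
        return "unclassified"
    if literature_label == "II":
        return empirical_label
    if empirical_label == "II" or literature_label == empirical_label:
        return literature_label
    msg = (
        f"discordant labels: literature={literature_label}, "
        f"empirical={empirical_label}; policy={policy}"
    )
    if policy == "error":
        raise InputError(msg)
    warnings.warn(msg)
    return empirical_label if policy == "prefer_empirical" else literature_label


@dataclass
class SpeciesClassification:
    species: str
    n_total: int
    literature_label: str
    empirical_label: str
    final_label: str


@dataclass
class ClassificationResult:
    records: list[SpeciesClassification]
    n_unclassified: int
    unclassified_individual_share: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": r.species,
                    "N": r.n_total,
                    "literature": r.literature_label,
                    "empirical": r.empirical_label,
                    "final": r.final_label,
                }
                for r in self.records
            ]
        )

    def labels(self) -> dict[str, str]:
        return {r.species: r.final_label for r in self.records}


def classify_all(
    table: CommunityTable,
    literature: pd.DataFrame | dict[str, str] | str,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int = 0,
    generalist_rule: str = "both_habitats",
    policy: str = "prefer_empirical",
) -> ClassificationResult:
    """Classify every species in the table into a final habitat-use category.

    ``literature`` is a CSV path, DataFrame (columns ``species``,
    ``literature_label``) or dict mapping species to its literature label;
    every species in the table must appear (label II is allowed).  IndVal
    permutation seeds are derived per species from ``seed`` so the result
    is reproducible and independent of species order.
    """
    if isinstance(literature, str):
        literature = pd.read_csv(literature)
    if isinstance(literature, pd.DataFrame):
        for col in ("species", "literature_label"):
            if col not in literature.columns:
                raise InputError(f"literature table lacks column {col!r}")
        literature = dict(zip(literature["species"], literature["literature_label"]))
    missing = [s for s in table.species if s not in literature]
    if missing:
        raise InputError(f"species missing from the literature table: {missing}")

    ss = np.random.SeedSequence(seed)
    species = list(table.species)
    child_seeds = ss.generate_state(len(species))
    records = []
    for sp, sp_seed in zip(species, child_seeds):
        n_total = int(table.plots[sp].sum())
        lit = literature[sp]
        if n_total >= MIN_INDIVIDUALS:
            res = indval(table, sp, n_permutations=n_permutations, seed=int(sp_seed))
            emp = empirical_label(res, alpha=alpha, generalist_rule=generalist_rule)
        else:
            emp = "II"
        final = reconcile(lit, emp, policy=policy)
        records.append(SpeciesClassification(sp, n_total, lit, emp, final))

    grand_total = sum(r.n_total for r in records)
    uncl = [r for r in records if r.final_label == "unclassified"]
    share = sum(r.n_total for r in uncl) / grand_total if grand_total else 0.0
    return ClassificationResult(records, len(uncl), share)
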