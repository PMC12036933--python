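"""End-to-end analysis: from traced sections to the tidy results tables.

The flow mirrors the study design:

1. measure — descriptors for every traced birthdated (BrdU+/Hu+) soma
   in HVC, and for the non-birthdated Hu+ population after the grid
   rule (every fourth 100 µm square, forbidden top/left edges).
2. quantify — pooled areal densities per region and phenotype,
   Cavalieri HVC volume, total-cell extrapolations.
3. summarize — one row per bird: covariates, quantification, and the
   per-population mean of each soma descriptor (the bird is the unit
   of analysis).
4. battery — group t-tests on densities/volume/totals, descriptor
   t-tests with Benjamini–Hochberg correction within each population's
   descriptor family, the 2×2 mixed ANOVA on soma area with post-hoc
   paired t-tests, and covariate regressions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .geometry import descriptors, METRIC_FIELDS
from .grid import build_grid, sample_cells, select_squares, sample_table
from .stats import (
    DegenerateDataError,
    bh_fdr,
    mixed_anova_2x2,
    ols_regress,
    t_independent,
    t_paired,
)
from .stereology import quantify_region
from .simulate import StudyDataset

__all__ = [
    "MORPH_FAMILY",
    "COVARIATES",
    "measure_study",
    "grid_audit",
    "quantify_study",
    "bird_summaries",
    "battery",
    "recover_directions",
]

#: the descriptor family corrected together per population: five
#: dimensionless descriptors plus area and the two Feret diameters
MORPH_FAMILY: tuple[str, ...] = (
    "area",
    "feret_max",
    "feret_min",
    "aspect_ratio",
    "compactness",
    "roundness",
    "shape_factor",
    "form_factor",
)

COVARIATES: tuple[str, ...] = (
    "age_at_treatment_start",
    "treatment_duration",
    "age_at_first_brdu",
    "age_at_perfusion",
)


def _measured_markers(study: StudyDataset, square_size: float = 100.0):
    """Yield (bird_id, section_index, marker) for every cell that gets
    measured: all traced BrdU+/Hu+ cells, grid-sampled Hu+ cells."""
    for sec in study.sections:
        if sec.region != "HVC":
            continue
        for m in sec.markers:
            if m.phenotype == "BRDU_HU" and m.contour is not None:
                yield sec.bird_id, sec.section_index, m
        hu = [m for m in sec.markers if m.phenotype == "HU_ONLY"]
        if hu:
            grid = select_squares(build_grid(sec.outline, square_size=square_size))
            for m in sample_cells(hu, grid):
                yield sec.bird_id, sec.section_index, m


def measure_study(study: StudyDataset, square_size: float = 100.0) -> pd.DataFrame:
    """Per-cell soma measurements for both measured populations in HVC."""
    rows = []
    for bird_id, si, m in _measured_markers(study, square_size):
        met = descriptors(m.contour)
        rows.append(
            {"bird_id": bird_id, "section_index": si, "cell_id": m.cell_id,
             "population": m.phenotype, **met.as_dict()}
        )
    cols = ["bird_id", "section_index", "cell_id", "population", *METRIC_FIELDS]
    return pd.DataFrame(rows, columns=cols)


def grid_audit(study: StudyDataset, square_size: float = 100.0) -> pd.DataFrame:
    """Grid-sampling audit for the Hu+ population, all HVC sections."""
    out = []
    for sec in study.sections:
        if sec.region != "HVC":
            continue
        hu = [m for m in sec.markers if m.phenotype == "HU_ONLY"]
        if not hu:
            continue
        grid = select_squares(build_grid(sec.outline, square_size=square_size))
        t = sample_table(hu, grid)
        t.insert(0, "bird_id", sec.bird_id)
        t.insert(1, "section_index", sec.section_index)
        out.append(t)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def quantify_study(study: StudyDataset, mode: str = "volumetric") -> pd.DataFrame:
    """Density / volume / total table per bird, region and phenotype."""
    rows = []
    for bird_id in study.birds["bird_id"]:
        for region in ("HVC", "NCM"):
            secs = study.sections_of(bird_id, region)
            if not secs:
                continue
            for phen in ("BRDU_HU", "DCX"):
                q = quantify_region(secs, phen, mode=mode)
                rows.append(
                    {"bird_id": bird_id, "region": region, "phenotype": phen,
                     "areal_density": q.areal_density, "volume": q.volume,
                     "total_cells": q.total_cells,
                     "n_sections": q.n_sections_counted}
                )
    return pd.DataFrame(rows)


def bird_summaries(study: StudyDataset, square_size: float = 100.0) -> pd.DataFrame:
    """One row per bird: group, covariates, quantification and the
    unweighted per-bird mean of each descriptor per population."""
    birds = study.birds.set_index("bird_id")
    quant = quantify_study(study)
    cells = measure_study(study, square_size=square_size)

    out = birds.copy()
    for region in ("HVC", "NCM"):
        for phen in ("BRDU_HU", "DCX"):
            sub = quant[(quant.region == region) & (quant.phenotype == phen)]
            sub = sub.set_index("bird_id")
            out[f"{region}_{phen}_density"] = sub["areal_density"]
            if region == "HVC":
                out[f"{region}_{phen}_total"] = sub["total_cells"]
    hvc = quant[(quant.region == "HVC") & (quant.phenotype == "BRDU_HU")].set_index("bird_id")
    out["HVC_volume_mm3"] = hvc["volume"]

    means = cells.groupby(["bird_id", "population"])[list(MORPH_FAMILY)].mean()
    for pop in ("BRDU_HU", "HU_ONLY"):
        if pop in means.index.get_level_values("population"):
            sub = means.xs(pop, level="population")
            for metric in MORPH_FAMILY:
                out[f"{pop}_{metric}"] = sub[metric]
    return out.reset_index()


def _group_split(summary: pd.DataFrame, column: str):
    s = summary.loc[summary["group"] == "statin", column].dropna().to_numpy()
    c = summary.loc[summary["group"] == "control", column].dropna().to_numpy()
    return s, c


def _t_row(summary, column, family, population=None, metric=None):
    s, c = _group_split(summary, column)
    r = t_independent(s, c)
    return {
        "family": family, "population": population, "metric": metric or column,
        "statistic": r.statistic, "df": r.df, "p": r.p_value,
        "p_adjusted": np.nan, "direction": r.direction,
        "mean_statin": float(np.mean(s)), "mean_control": float(np.mean(c)),
    }


def battery(
    summary: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = True,
) -> dict[str, pd.DataFrame]:
    """The full statistical battery on a bird-summary table.

    Returns tidy tables: ``group_tests`` (t-tests on quantification and
    descriptors, with BH-adjusted p within each population's descriptor
    family when ``bh_correct``), ``anova`` (2×2 mixed on soma area),
    ``posthoc`` (paired population comparisons within each group), and
    ``regressions`` (covariate screens).
    """
    rows = []
    for col in (
        "HVC_BRDU_HU_density", "HVC_DCX_density",
        "NCM_BRDU_HU_density", "NCM_DCX_density",
        "HVC_volume_mm3", "HVC_BRDU_HU_total", "HVC_DCX_total",
    ):
        if col in summary:
            rows.append(_t_row(summary, col, family="quantification"))

    for pop in ("BRDU_HU", "HU_ONLY"):
        fam_rows = []
        for metric in MORPH_FAMILY:
            col = f"{pop}_{metric}"
            if col in summary:
                fam_rows.append(
                    _t_row(summary, col, family="morphology", population=pop, metric=metric)
                )
        if fam_rows and bh_correct:
            adj, _ = bh_fdr([r["p"] for r in fam_rows], alpha=alpha)
            for r, a in zip(fam_rows, adj):
                r["p_adjusted"] = a
        rows.extend(fam_rows)
    group_tests = pd.DataFrame(rows)

    # 2 (group) × 2 (population) mixed ANOVA on soma area
    anova = pd.DataFrame()
    posthoc = pd.DataFrame()
    if {"BRDU_HU_area", "HU_ONLY_area"}.issubset(summary.columns):
        paired = summary.dropna(subset=["BRDU_HU_area", "HU_ONLY_area"])
        values = paired[["BRDU_HU_area", "HU_ONLY_area"]].to_numpy()
        anova = mixed_anova_2x2(values, paired["group"].to_numpy())
        anova = anova.reset_index(names="effect")
        ph = []
        for grp in ("statin", "control"):
            sub = paired[paired["group"] == grp]
            r = t_paired(sub["HU_ONLY_area"], sub["BRDU_HU_area"])
            ph.append(
                {"group": grp, "comparison": "HU_ONLY_area - BRDU_HU_area",
                 "statistic": r.statistic, "df": r.df, "p": r.p_value,
                 "direction": r.direction}
            )
        posthoc = pd.DataFrame(ph)

    # covariate screens: densities in all subsets; morphology within statin
    reg_rows = []
    density_cols = [c for c in summary.columns if c.endswith("_density")]
    morph_cols = [f"BRDU_HU_{m}" for m in MORPH_FAMILY if f"BRDU_HU_{m}" in summary] + [
        f"HU_ONLY_{m}" for m in MORPH_FAMILY if f"HU_ONLY_{m}" in summary
    ]
    subsets = {
        "statin": summary[summary["group"] == "statin"],
        "control": summary[summary["group"] == "control"],
        "all": summary,
    }
    for name, sub in subsets.items():
        outcomes = density_cols if name != "statin" else density_cols + morph_cols
        for cov in COVARIATES:
            for outcome in outcomes:
                data = sub[[cov, outcome]].dropna()
                try:
                    r = ols_regress(data[cov], data[outcome])
                except DegenerateDataError:
                    continue
                reg_rows.append(
                    {"subset": name, "covariate": cov, "outcome": outcome,
                     "slope": r.slope, "r_squared": r.r_squared, "p": r.p_value,
                     "n": r.n}
                )
    regressions = pd.DataFrame(reg_rows)

    return {
        "group_tests": group_tests,
        "anova": anova,
        "posthoc": posthoc,
        "regressions": regressions,
    }


def recover_directions(
    study: StudyDataset,
    alpha: float = 0.05,
    summary: Optional[pd.DataFrame] = None,
) -> dict[str, bool]:
    """Check whether the pipeline recovers the study's effect pattern.

    Direction checks compare group means of the bird summaries; the
    density check asks for a *non*-significant group difference in
    new-neuron density (the null result).  Keys:

    - ``new_flatter``: statin BrdU+/Hu+ aspect ratio below control
    - ``new_rougher``: statin BrdU+/Hu+ form factor below control
    - ``new_convoluted``: statin BrdU+/Hu+ shape factor above control
    - ``old_smaller``: statin Hu+ area below control
    - ``density_null``: HVC new-neuron density t-test p ≥ alpha
    """
    if summary is None:
        summary = bird_summaries(study)

    def mean_diff(col):
        s, c = _group_split(summary, col)
        return float(np.mean(s) - np.mean(c))

    s, c = _group_split(summary, "HVC_BRDU_HU_density")
    dens_p = t_independent(s, c).p_value
    return {
        "new_flatter": mean_diff("BRDU_HU_aspect_ratio") < 0,
        "new_rougher": mean_diff("BRDU_HU_form_factor") < 0,
        "new_convoluted": mean_diff("BRDU_HU_shape_factor") > 0,
        "old_smaller": mean_diff("HU_ONLY_area") < 0,
        "density_null": dens_p >= alpha,
    }
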