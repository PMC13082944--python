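"""Metabolic-phenotype statistics: normalisations, matched pairs, plasma
panel cleaning, PCA, correlations and dosing arithmetic.

Traits are compared between an exposure group and the control group with
the MCW tests: unmatched traits (body weight, fasting glucose, tissue
weights, plasma metabolites, litter size, sex ratio) with uMCW, and
inherently paired measurements (pre/post-fasting body weight, cage
entry/exit water and food) with mbMCW. Trait values are normalised to the
units the analyses use: body weight by age (g per day of age), glucose and
plasma metabolites additionally by body weight ((mg/dL)/g/day and
(pg/mL)/g/day).

Matched pairs are oriented (later, earlier) — post-fasting minus
pre-fasting, exit minus entry — so a negative paired difference means loss
(weight lost while fasting, water or food consumed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from hecpipe.mcw import MCWConfig, MCWResult, mbmcw_test, umcw_test

logger = logging.getLogger(__name__)

#: ATSDR no-observed-adverse-effect level for tributyltin, mg/kg/day
TBT_NOAEL_MG_PER_KG_DAY = 0.025
#: molecular weight of the tributyltin cation, g/mol (chloride salt: 325.5)
TBT_CATION_MW = 290.06


def normalize_trait(
    value: float | np.ndarray,
    age_days: float | np.ndarray,
    body_weight: float | np.ndarray | None = None,
) -> float | np.ndarray:
    """Normalise a trait value by age and, when given, body weight.

    Body weight uses g/day-of-age; glucose, tissue weights and plasma
    metabolites divide additionally by body weight in grams.
    """
    age = np.asarray(age_days, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age_days must be positive")
    out = np.asarray(value, dtype=float) / age
    if body_weight is not None:
        bw = np.asarray(body_weight, dtype=float)
        if np.any(bw <= 0):
            raise ValueError("body_weight must be positive")
        out = out / bw
    return float(out) if np.isscalar(value) else out


def _matched_pairs(
    later: pd.Series, earlier: pd.Series, label: str
) -> list[tuple[float, float]]:
    joined = pd.concat({"later": later, "earlier": earlier}, axis=1)
    incomplete = joined[joined.isna().any(axis=1)]
    for subject in incomplete.index:
        logger.info("%s: excluding %s (incomplete pair)", label, subject)
    complete = joined.dropna()
    return list(zip(complete["later"], complete["earlier"]))


def fasting_pairs(
    pre: pd.Series, post: pd.Series, groups: pd.Series,
    exposure_group: str, control_group: str = "DMSO",
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Build (post, pre) matched pairs for an exposure and a control group.

    Series are indexed by mouse id. Mice missing either member of the pair
    are excluded with a log entry. The returned (x, y) sets feed
    :func:`hecpipe.mcw.mbmcw_test`; BI < 0 means exposure mice lose more
    weight over the fast than controls.
    """
    x_ids = groups.index[groups == exposure_group]
    y_ids = groups.index[groups == control_group]
    x = _matched_pairs(post.reindex(x_ids), pre.reindex(x_ids), exposure_group)
    y = _matched_pairs(post.reindex(y_ids), pre.reindex(y_ids), control_group)
    return x, y


def consumption_pairs(
    entry: pd.Series, exit: pd.Series, groups: pd.Series,
    exposure_group: str, control_group: str = "DMSO",
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Cage-level (exit, entry) matched pairs for water or food consumption.

    Series are indexed by cage id. An exit value above its entry value
    (a refill anomaly) is flagged but retained.
    """
    anomalies = exit[exit > entry.reindex(exit.index)]
    for cage in anomalies.index:
        logger.warning("cage %s: exit exceeds entry (refill anomaly?)", cage)
    return fasting_pairs(entry, exit, groups, exposure_group, control_group)


def clean_plasma(panel: pd.DataFrame, in_range: pd.DataFrame) -> pd.DataFrame:
    """Zero plasma values flagged out of the standard curve range.

    ``panel`` holds concentrations (mouse x metabolite); ``in_range`` is a
    same-shaped boolean mask (False = outside the standard curve or not
    extrapolable). Out-of-range entries are set to zero, in-range entries
    pass through untouched.
    """
    mask = in_range.reindex_like(panel).fillna(False).astype(bool)
    return panel.where(mask, 0.0)


def metabolite_pca(
    panel: pd.DataFrame, scale: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA on complete-case metabolites of one sex.

    Metabolites with a zero or missing value in any mouse are dropped
    (complete cases only). Data are centred and, by default, scaled to
    unit variance before the decomposition. The sign of each component is
    fixed so its largest-magnitude loading is positive, making outputs
    run-to-run identical.

    Returns (scores, loadings, explained variance fractions).
    """
    valid = panel.columns[(panel > 0).all(axis=0) & panel.notna().all(axis=0)]
    if len(valid) < 2:
        raise ValueError("need at least 2 complete-case metabolites for PCA")
    x = panel[valid].to_numpy(float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / sd
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # (metabolite, component)
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    scores = scores * flip
    loadings = loadings * flip
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return (
        pd.DataFrame(scores, index=panel.index, columns=comp_names),
        pd.DataFrame(loadings, index=valid, columns=comp_names),
        pca.explained_variance_ratio_,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class DoseModel:
    """Drinking-water dosing model for a dissolved compound."""

    concentration_nM: float
    molecular_weight: float = TBT_CATION_MW
    water_intake_L_per_day: float = 0.010
    body_weight_kg: float = 0.030
    noael: float = TBT_NOAEL_MG_PER_KG_DAY

    def __post_init__(self) -> None:
        for name in ("molecular_weight", "water_intake_L_per_day", "body_weight_kg", "noael"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.concentration_nM < 0:
            raise ValueError("concentration_nM must be non-negative")


def dose_equivalent(model: DoseModel) -> tuple[float, float]:
    """Daily dose in mg/kg/day and its ratio to the NOAEL.

    dose = concentration [mol/L] x MW [g/mol] x 1000 [mg/g]
           x intake [L/day] / body weight [kg].
    The NOAEL ratio is how many times below the NOAEL the dose sits
    (infinite at zero concentration).
    """
    mol_per_L = model.concentration_nM * 1e-9
    dose = mol_per_L * model.molecular_weight * 1e3 * model.water_intake_L_per_day
    dose /= model.body_weight_kg
    ratio = model.noael / dose if dose > 0 else float("inf")
    return dose, ratio


def litter_stats(
    litters: pd.DataFrame,
    exposure_group: str,
    control_group: str = "DMSO",
    config: MCWConfig | None = None,
) -> dict[str, MCWResult]:
    """uMCW tests on litter size and sex ratio, exposure vs control.

    ``litters`` needs columns ``group``, ``n_pups`` and ``n_females``;
    sex ratio is the female fraction of each litter.
    """
    config = config or MCWConfig()
    out = {}
    for trait, values in (
        ("litter_size", litters["n_pups"].astype(float)),
        ("sex_ratio", litters["n_females"] / litters["n_pups"]),
    ):
        a = values[litters["group"] == exposure_group].to_numpy()
        b = values[litters["group"] == control_group].to_numpy()
        out[trait] = umcw_test(a, b, config)
    return out


def trait_mcw(
    traits: pd.DataFrame,
    trait: str,
    exposure_group: str,
    control_group: str = "DMSO",
    config: MCWConfig | None = None,
    timepoint: str | None = None,
) -> MCWResult:
    """uMCW on one normalised trait, exposure vs control.

    ``traits`` is a long table with columns ``mouse_id``, ``group``,
    ``trait``, ``value`` and optionally ``timepoint``.
    """
    config = config or MCWConfig()
    rows = traits[traits["trait"] == trait]
    if timepoint is not None:
        rows = rows[rows["timepoint"] == timepoint]
    a = rows.loc[rows["group"] == exposure_group, "value"].to_numpy(float)
    b = rows.loc[rows["group"] == control_group, "value"].to_numpy(float)
    return umcw_test(a, b, config)


def fasting_mcw(
    pre: pd.Series, post: pd.Series, groups: pd.Series,
    exposure_group: str, control_group: str = "DMSO",
    config: MCWConfig | None = None,
) -> MCWResult:
    """mbMCW on (post, pre) fasting pairs, exposure vs control."""
    x, y = fasting_pairs(pre, post, groups, exposure_group, control_group)
    return mbmcw_test(x, y, config or MCWConfig())
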