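"""Component-level and cohort-level inference.

Component significance is assessed primarily on the loading parameters
(Welch two-sample t per component); a voxel-wise group t-map is provided as
a secondary output. Cross-modal component relationships are all-pairs
Pearson correlations of the loading columns, corrected with the
Benjamini-Hochberg false discovery rate at q < 0.05. Cohort demographics
are compared with the usual mixed battery: Welch t for continuous scores
(raw values or mean/sd/n summaries), chi-square without continuity
correction for 2x2 counts, and a tie-corrected Mann-Whitney test for
ordinal scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from petpica.errors import ConfigError, NumericalError, PairingError
from petpica.types import VoxelMatrix


@dataclass
class ComponentTest:
    component: int
    modality: str
    t: float
    p: float
    significant: bool


@dataclass
class CrossModalCorr:
    pair: tuple[int, int]
    r: float
    p: float
    q: float
    passes: bool


def zscore_map(source_row: np.ndarray) -> np.ndarray:
    """Z-score a spatial map over the mask (sample sd, ddof=1)."""
    x = np.asarray(source_row, dtype=float)
    if x.size < 2:
        raise ConfigError("need at least 2 voxels to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise NumericalError("zero-variance map cannot be z-scored")
    return (x - x.mean()) / sd


def threshold_map(zmap: np.ndarray, cutoff: float = 2.5
                  ) -> tuple[np.ndarray, int]:
    """Strict |z| > cutoff mask and surviving-voxel count."""
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    mask = np.abs(np.asarray(zmap, dtype=float)) > cutoff
    return mask, int(mask.sum())


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise NumericalError("degenerate groups: zero variance, unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def loading_group_test(
    loadings: np.ndarray, labels: np.ndarray, modality: str = "",
    alpha: float = 0.05, group_order: tuple[str, str] = ("MCI", "NC"),
) -> list[ComponentTest]:
    """Welch two-sample t-test on each component's loading column."""
    labels = np.asarray(labels)
    g1 = labels == group_order[0]
    g2 = labels == group_order[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ConfigError("both groups need at least 2 subjects")
    out = []
    for c in range(loadings.shape[1]):
        t, p = _welch(loadings[g1, c], loadings[g2, c])
        out.append(ComponentTest(component=c, modality=modality, t=t, p=p,
                                 significant=p < alpha))
    return out


def voxelwise_group_test(
    matrix: VoxelMatrix, labels: np.ndarray,
    group_order: tuple[str, str] = ("MCI", "NC"),
) -> tuple[np.ndarray, np.ndarray]:
    """Welch t and two-sided p per voxel; constant voxels flagged as NaN."""
    labels = np.asarray(labels)
    g1 = matrix.values[labels == group_order[0]]
    g2 = matrix.values[labels == group_order[1]]
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ConfigError("both groups need at least 2 subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(g1, g2, equal_var=False, axis=0)
    constant = (g1.std(axis=0) == 0) & (g2.std(axis=0) == 0)
    t = np.where(constant, np.nan, t)
    p = np.where(constant, np.nan, p)
    return np.asarray(t, float), np.asarray(p, float)


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and the rejection set at alpha."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    # multipletests rejects at q <= alpha; the reporting convention here is
    # strict q < alpha, consistent across the package
    return q, q < alpha


def crossmodal_correlations(
    a1: np.ndarray, a2: np.ndarray, alpha: float = 0.05
) -> list[CrossModalCorr]:
    """All-pairs Pearson correlations of loading columns with BH-FDR."""
    if a1.shape[0] != a2.shape[0]:
        raise PairingError("loading matrices have different subject counts")
    n = a1.shape[0]
    records = []
    ps = []
    for i in range(a1.shape[1]):
        for j in range(a2.shape[1]):
            r, p = sps.pearsonr(a1[:, i], a2[:, j])
            records.append((i, j, float(r), float(p)))
            ps.append(p)
    q, rej = bh_fdr(np.asarray(ps), alpha=alpha)
    return [
        CrossModalCorr(pair=(i, j), r=r, p=p, q=float(qv), passes=bool(rj))
        for (i, j, r, p), qv, rj in zip(records, q, rej)
    ]


def covariate_check(
    loadings: np.ndarray, age: np.ndarray, sex: np.ndarray,
    residualize: bool = False,
) -> pd.DataFrame:
    """Per-component association of loadings with age and sex.

    Returns a table with age correlation (r, p) and a two-sample t by sex
    (t, p); with ``residualize`` the loadings are additionally regressed on
    age and the residual columns appended.
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if age.std() == 0 or len(set(sex.tolist())) < 2:
        raise ConfigError("constant covariate")
    rows = []
    sex_levels = sorted(set(sex.tolist()))
    resid = None
    if residualize:
        design = np.column_stack([np.ones_like(age), age])
        beta, *_ = np.linalg.lstsq(design, loadings, rcond=None)
        resid = loadings - design @ beta
    for c in range(loadings.shape[1]):
        r, p_age = sps.pearsonr(loadings[:, c], age)
        t, p_sex = _welch(loadings[sex == sex_levels[0], c],
                          loadings[sex == sex_levels[1], c])
        rows.append({"component": c, "age_r": float(r), "age_p": float(p_age),
                     "sex_t": t, "sex_p": p_sex})
    table = pd.DataFrame(rows)
    if residualize:
        table.attrs["residualized_loadings"] = resid
    return table


def ttest_from_summary(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Welch two-sample t-test from group mean/sd/n summaries."""
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                    equal_var=False)
    return float(t), float(p)


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    chi2, p, _, _ = sps.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U, tie-corrected normal approximation."""
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u), float(p)


#: columns the cohort table is expected to carry
COHORT_COLUMNS = ("subject_id", "group", "age", "sex", "apoe4", "mmse", "cdr")


def cohort_table(subjects: pd.DataFrame,
                 group_order: tuple[str, str] = ("MCI", "NC")) -> pd.DataFrame:
    """Demographic comparison of the two groups (Welch t for age and MMSE,
    chi-square for sex and APOE4 carriage, Mann-Whitney for CDR)."""
    missing = [c for c in COHORT_COLUMNS if c not in subjects.columns]
    if missing:
        raise ConfigError(f"subject table lacks column(s): {', '.join(missing)}")
    g1 = subjects[subjects["group"] == group_order[0]]
    g2 = subjects[subjects["group"] == group_order[1]]
    rows = []

    def summarize(col):
        return (f"{g1[col].mean():.2f} ± {g1[col].std():.2f}",
                f"{g2[col].mean():.2f} ± {g2[col].std():.2f}")

    for col in ("age", "mmse"):
        s1, s2 = summarize(col)
        t, p = _welch(g1[col].to_numpy(float), g2[col].to_numpy(float))
        rows.append({"variable": col, group_order[0]: s1, group_order[1]: s2,
                     "statistic": t, "p": p, "test": "welch_t"})
    for col in ("sex", "apoe4"):
        levels = sorted(subjects[col].unique().tolist())
        tab = np.array([[int((g[col] == lv).sum()) for lv in levels]
                        for g in (g1, g2)])
        chi2, p = chi2_2x2(tab)
        rows.append({"variable": col,
                     group_order[0]: ":".join(str(x) for x in tab[0]),
                     group_order[1]: ":".join(str(x) for x in tab[1]),
                     "statistic": chi2, "p": p, "test": "chi2"})
    u, p = mann_whitney(g1["cdr"].to_numpy(float), g2["cdr"].to_numpy(float))
    rows.append({"variable": "cdr",
                 group_order[0]: f"{g1['cdr'].median():g}",
                 group_order[1]: f"{g2['cdr'].median():g}",
                 "statistic": u, "p": p, "test": "mann_whitney"})
    return pd.DataFrame(rows)


def component_tests_to_frame(tests: list[ComponentTest]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in tests])


def crossmodal_to_frame(records: list[CrossModalCorr]) -> pd.DataFrame:
    return pd.DataFrame([
        {"tau_component": r.pair[0], "abeta_component": r.pair[1],
         "r": r.r, "p": r.p, "q": r.q, "passes": r.passes}
        for r in records
    ])
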