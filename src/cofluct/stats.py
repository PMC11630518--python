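"""Subject classification and the cohort-level statistical models.

Classification: MDD patients with HAMD-17 total < 17 are excluded; among
the rest, HAMD item 9 (psychomotor agitation) >= 2 defines the agitated
subgroup (A-MDD), the remainder non-agitated (NA-MDD). Healthy controls
pass through untouched.

Group contrasts are covariate-adjusted OLS models: the metric is regressed
on a group indicator plus covariates, and the indicator's t statistic is
reported. Coding: the first-named group is 1, the second-named is the
reference, so t > 0 means the first-named group is higher. The three
contrasts of one metric (A-MDD vs HC, A-MDD vs NA-MDD, NA-MDD vs HC) form
one Benjamini–Hochberg FDR family; families are never pooled across
metrics. HC contrasts adjust for age, gender and education; the MDD
subgroup contrast additionally adjusts for the HAMA total and a HAMD
"depression sub-dimension" score (a configurable item subset that never
includes item 9, so the agitation contrast is not self-adjusted).

The agitation regressions take the brain metric as predictor and the item-9
score as outcome, with all continuous variables mean-centered; both the raw
slope (on centered variables) and the standardized slope are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from cofluct.io import CohortTable, HAMD_COLS, RunConfig, ValidationError

logger = logging.getLogger("cofluct")

__all__ = [
    "ContrastResult",
    "RegressionResult",
    "classify_subjects",
    "regroup",
    "adjusted_contrast",
    "fdr_adjust",
    "agitation_regression",
    "itemwise_comparison",
    "run_full_contrast_suite",
    "METRIC_FAMILIES",
]

METRIC_FAMILIES = ["mean_trough_duration", "mean_peak_height", "td_smn",
                   "fc_static", "fc_high", "fc_low"]

BASE_COVARIATES = ["age", "gender", "education"]


@dataclass
class ContrastResult:
    metric: str
    group_a: str
    group_b: str
    t: float
    p: float
    df: float
    n_a: int
    n_b: int
    covariates: list[str] = field(default_factory=list)
    p_fdr: float | None = None

    def as_row(self) -> dict:
        return {
            "family": self.metric,
            "contrast": f"{self.group_a} vs {self.group_b}",
            "t": self.t, "p": self.p, "p_fdr": self.p_fdr, "df": self.df,
            "n1": self.n_a, "n2": self.n_b,
            "covariates": "+".join(self.covariates) or "none",
        }


@dataclass
class RegressionResult:
    outcome: str
    predictor: str
    beta_raw: float
    beta_std: float
    t: float
    p: float
    n: int
    covariates: list[str] = field(default_factory=list)


def classify_subjects(cohort: CohortTable, cfg: RunConfig) -> CohortTable:
    """Apply inclusion and the item-9 agitation rule to MDD subjects.

    Requires a ``cohort`` column with values MDD / HC. MDD with
    hamd_total < ``hamd_inclusion_min`` or missing item 9 are marked
    ``qc_pass=False`` with a recorded reason; the rest are labelled A-MDD
    (item 9 >= ``agitation_cutoff``) or NA-MDD. HC are untouched.
    """
    df = cohort.df.copy()
    if "cohort" not in df.columns:
        raise ValidationError("classification needs a 'cohort' column (MDD/HC)")
    if "qc_pass" not in df.columns:
        df["qc_pass"] = True
    df["qc_pass"] = df["qc_pass"].astype(bool)
    if "exclusion_reason" not in df.columns:
        df["exclusion_reason"] = ""
    labels = []
    for _, row in df.iterrows():
        if row["cohort"] != "MDD":
            labels.append("HC")
            continue
        total = row.get("hamd_total", np.nan)
        item9 = row.get("hamd_09", np.nan)
        if pd.isna(total) or total < cfg.hamd_inclusion_min:
            df.loc[df.subject_id == row.subject_id, "qc_pass"] = False
            df.loc[df.subject_id == row.subject_id, "exclusion_reason"] = (
                f"hamd_total {total} below inclusion minimum "
                f"{cfg.hamd_inclusion_min}")
            labels.append("")
            continue
        if pd.isna(item9):
            df.loc[df.subject_id == row.subject_id, "qc_pass"] = False
            df.loc[df.subject_id == row.subject_id, "exclusion_reason"] = (
                "missing HAMD item 9")
            labels.append("")
            continue
        labels.append("A-MDD" if item9 >= cfg.agitation_cutoff else "NA-MDD")
    df["group_label"] = labels
    n_excl = int((~df["qc_pass"]).sum())
    if n_excl:
        logger.info("classification excluded %d subject(s)", n_excl)
    return CohortTable(df)


def regroup(cohort: CohortTable | pd.DataFrame, scale: str,
            cutoff: int = 24) -> pd.Series:
    """Severity labels for MDD subjects: total >= cutoff → "severe".

    ``scale`` is HAMA or HAMD. The >= convention (24 counts as severe) is
    logged; subjects with missing totals get NA and are dropped from that
    control analysis downstream.
    """
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    col = {"HAMA": "hama_total", "HAMD": "hamd_total"}.get(scale.upper())
    if col is None:
        raise ValidationError("scale must be HAMA or HAMD")
    if col not in df.columns:
        logger.info("regroup %s: no %s column; all subjects dropped",
                    scale, col)
        return pd.Series(pd.NA, index=df.index, dtype="object")
    totals = pd.to_numeric(df[col], errors="coerce")
    is_mdd = df["cohort"] == "MDD" if "cohort" in df.columns else pd.Series(
        True, index=df.index)
    out = pd.Series(pd.NA, index=df.index, dtype="object")
    out[is_mdd & totals.notna()] = np.where(
        totals[is_mdd & totals.notna()] >= cutoff, "severe", "moderate")
    n_missing = int((is_mdd & totals.isna()).sum())
    if n_missing:
        logger.info("regroup %s: %d MDD subject(s) missing totals dropped",
                    scale, n_missing)
    logger.debug("regroup %s: >= %d counts as severe", scale, cutoff)
    return out


def _encode_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding: categoricals become 0/1 indicators (reference =
    first sorted level, documented in the column name)."""
    out = {}
    for c in cov.columns:
        col = cov[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            if len(levels) > 2:
                raise ValidationError(
                    f"covariate {c} has {len(levels)} levels; recode first")
            ref = levels[0] if levels else None
            out[f"{c}[ref={ref}]"] = (col != ref).astype(float).where(col.notna())
        else:
            out[c] = pd.to_numeric(col, errors="coerce")
    return pd.DataFrame(out, index=cov.index)


def adjusted_contrast(y: pd.Series, labels: pd.Series, group_a: str,
                      group_b: str, covariates: pd.DataFrame | None = None,
                      family: str = "") -> ContrastResult:
    """Covariate-adjusted two-group contrast via OLS.

    Fits ``y ~ 1 + I(group==group_a) + covariates`` on the subjects in the
    two groups (listwise deletion over y and covariates; the per-model n is
    reported). Returns the indicator's t and two-sided p.
    """
    mask = labels.isin([group_a, group_b])
    y = pd.to_numeric(y[mask], errors="coerce")
    g = (labels[mask] == group_a).astype(float)
    pieces = [y.rename("y"), g.rename("group")]
    cov_cols: list[str] = []
    if covariates is not None:
        enc = _encode_covariates(covariates.loc[mask])
        cov_cols = list(enc.columns)
        pieces.append(enc)
    frame = pd.concat(pieces, axis=1).dropna()
    n_a = int(frame["group"].sum())
    n_b = int(len(frame) - n_a)
    if n_a < 3 or n_b < 3:
        raise ValidationError(
            f"contrast {group_a} vs {group_b}: need n >= 3 per group, "
            f"got {n_a}/{n_b}")
    x = sm.add_constant(frame[["group"] + cov_cols])
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        logger.warning("collinear covariates in %s vs %s; pseudoinverse fit",
                       group_a, group_b)
    fit = sm.OLS(frame["y"], x).fit()
    return ContrastResult(
        metric=family, group_a=group_a, group_b=group_b,
        t=float(fit.tvalues["group"]), p=float(fit.pvalues["group"]),
        df=float(fit.df_resid), n_a=n_a, n_b=n_b, covariates=cov_cols)


def fdr_adjust(pvals: list[float] | np.ndarray, family: str = "") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError(f"p-values outside [0, 1] in family {family!r}")
    return multipletests(p, method="fdr_bh")[1]


def agitation_regression(data: pd.DataFrame, predictor: str,
                         agitation: str = "hamd_09",
                         covariates: tuple[str, ...] = ("age", "gender",
                                                        "education",
                                                        "hama_total"),
                         ) -> RegressionResult:
    """OLS of the agitation score on a brain metric, covariate-adjusted.

    MDD subjects only; all continuous variables are mean-centered before
    fitting (guarding against multicollinearity with the intercept), which
    leaves the slope, t and p of the predictor unchanged. ``beta_std`` is
    the slope in SD units of predictor and outcome.
    """
    cols = [agitation, predictor, *covariates]
    cov = _encode_covariates(data[list(covariates)])
    frame = pd.concat(
        [pd.to_numeric(data[agitation], errors="coerce").rename("y"),
         pd.to_numeric(data[predictor], errors="coerce").rename("x"),
         cov], axis=1).dropna()
    if len(frame) < 10:
        raise ValidationError(f"regression needs n >= 10, got {len(frame)}")
    if frame["x"].std() == 0:
        raise ValidationError(f"predictor {predictor} has zero variance")
    centered = frame - frame.mean()
    x = sm.add_constant(centered[["x"] + list(cov.columns)])
    fit = sm.OLS(centered["y"], x).fit()
    beta = float(fit.params["x"])
    beta_std = beta * float(frame["x"].std(ddof=1)) / float(
        frame["y"].std(ddof=1))
    return RegressionResult(
        outcome=agitation, predictor=predictor, beta_raw=beta,
        beta_std=beta_std, t=float(fit.tvalues["x"]),
        p=float(fit.pvalues["x"]), n=len(frame),
        covariates=list(cov.columns))


def itemwise_comparison(data: pd.DataFrame, labels: pd.Series,
                        group_a: str = "A-MDD", group_b: str = "NA-MDD"
                        ) -> pd.DataFrame:
    """Per-item HAMD comparison between the MDD subgroups.

    One-way ANOVA F per item (with two groups F = t²), post-hoc two-sample
    t, raw p and BH-adjusted p across the 17-item family; both raw and
    adjusted p are reported. Items constant in both groups get p = 1 and a
    flag.
    """
    rows = []
    for i, col in enumerate(HAMD_COLS, start=1):
        a = pd.to_numeric(data.loc[labels == group_a, col], errors="coerce").dropna()
        b = pd.to_numeric(data.loc[labels == group_b, col], errors="coerce").dropna()
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            rows.append({"item": i, "F": 0.0, "t": 0.0, "p": 1.0,
                         "flag": "constant"})
            continue
        f_stat, _ = sstats.f_oneway(a, b)
        t_stat, p = sstats.ttest_ind(a, b, equal_var=True)
        rows.append({"item": i, "F": float(f_stat), "t": float(t_stat),
                     "p": float(p), "flag": ""})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_adjust(out["p"].to_numpy(), family="hamd_items")
    return out


CONTRASTS = [("A-MDD", "HC"), ("A-MDD", "NA-MDD"), ("NA-MDD", "HC")]


def _dep_subdim(df: pd.DataFrame, items: tuple[int, ...]) -> pd.Series:
    cols = [f"hamd_{i:02d}" for i in items]
    assert "hamd_09" not in cols
    return df[cols].apply(pd.to_numeric, errors="coerce").sum(axis=1,
                                                              min_count=len(cols))


def run_full_contrast_suite(data: pd.DataFrame, cfg: RunConfig,
                            metrics: list[str] | None = None,
                            include_controls: bool = True,
                            include_itemwise: bool = True
                            ) -> dict[str, pd.DataFrame]:
    """The full statistics stage on a merged metrics + phenotype table.

    ``data`` must carry ``group_label`` (A-MDD / NA-MDD / HC), the metric
    columns, and the covariate columns. Returns result tables: contrasts
    (three per metric family, BH within family), agitation regressions,
    item-wise comparison, and the HAMA-24 / HAMD-24 control regroupings.
    """
    metrics = metrics or METRIC_FAMILIES
    present = set(data["group_label"].dropna().unique())
    for a, b in CONTRASTS:
        if a not in present or b not in present:
            missing = a if a not in present else b
            raise ValidationError(
                f"cannot run contrast {a} vs {b}: group {missing!r} absent")
    data = data.copy()
    data["dep_subdim"] = _dep_subdim(data, cfg.depression_subdim_items)

    contrast_rows = []
    for metric in metrics:
        if metric not in data.columns:
            raise ValidationError(f"metric column {metric!r} missing")
        fam: list[ContrastResult] = []
        for a, b in CONTRASTS:
            covs = list(BASE_COVARIATES)
            if {a, b} == {"A-MDD", "NA-MDD"}:
                covs += ["hama_total", "dep_subdim"]
            res = adjusted_contrast(data[metric], data["group_label"], a, b,
                                    data[covs], family=metric)
            fam.append(res)
        adj = fdr_adjust([r.p for r in fam], family=metric)
        for r, q in zip(fam, adj):
            r.p_fdr = float(q)
            contrast_rows.append(r.as_row())
    contrasts = pd.DataFrame(contrast_rows)

    mdd = data[data["group_label"].isin(["A-MDD", "NA-MDD"])]
    reg_rows = []
    for pred in ("mean_trough_duration", "td_smn"):
        if pred in data.columns:
            r = agitation_regression(mdd, pred)
            reg_rows.append({"outcome": r.outcome, "predictor": r.predictor,
                             "beta_raw": r.beta_raw, "beta_std": r.beta_std,
                             "t": r.t, "p": r.p, "n": r.n,
                             "covariates": "+".join(r.covariates)})
    regressions = pd.DataFrame(reg_rows)

    out = {"contrasts": contrasts, "regressions": regressions}

    if include_itemwise and all(c in data.columns for c in HAMD_COLS):
        out["itemwise"] = itemwise_comparison(mdd, mdd["group_label"])

    if include_controls:
        ctrl_rows = []
        for scale in ("HAMA", "HAMD"):
            sev = regroup(data, scale, cutoff=24)
            lab = data["group_label"].where(data["group_label"] == "HC",
                                            sev)
            pairs = [("severe", "HC"), ("moderate", "HC"),
                     ("severe", "moderate")]
            for metric in metrics:
                fam = []
                for a, b in pairs:
                    try:
                        res = adjusted_contrast(
                            data[metric], lab, a, b, data[BASE_COVARIATES],
                            family=f"{scale.lower()}24_{metric}")
                    except ValidationError as err:
                        logger.warning("control %s-24 %s vs %s skipped: %s",
                                       scale, a, b, err)
                        continue
                    fam.append(res)
                adj = fdr_adjust([r.p for r in fam])
                for r, q in zip(fam, adj):
                    r.p_fdr = float(q)
                    row = r.as_row()
                    row["regrouping"] = f"{scale}-24"
                    ctrl_rows.append(row)
        out["controls"] = pd.DataFrame(ctrl_rows)
    return out
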