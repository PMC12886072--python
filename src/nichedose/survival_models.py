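"""Survival analysis of niche dose and contact.

The analysis plan mirrors a standard neuro-oncology dosimetry study:

* Kaplan-Meier curves with a log-rank test comparing patients whose lesion
  touches a neurogenic niche to those without contact;
* nested Cox proportional-hazards models for the mean niche dose (per Gy)
  and for contact, growing from univariable to fully adjusted:
  M0 = variable of interest alone; M1 adds age, sex, WHO performance
  status, histology and the niche volume; M2 adds tumour-burden and therapy
  covariates (number of brain metastases, extracranial metastases,
  chemotherapy, other systemic therapy, resection extent); M3 adds GTV
  volume;
* adjusted variance-inflation factors (GVIF^(1/(2 df)) for multi-level
  categoricals) as a collinearity check on each model's design matrix;
* sensitivity subsets (dropping the largest-PTV decile, restricting to
  single-metastasis patients, excluding the most central lesion decile);
* exploratory Spearman correlations between niche dose and tumour burden.

Missingness follows a complete-case policy per model: rows with an
``unknown`` level in any required categorical covariate are dropped and the
n actually used is reported alongside every fit.  Ties in the Cox partial
likelihood use the Efron approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .volume_io import CATEGORICAL_LEVELS

CONTINUOUS_COVARIATES = {
    "age",
    "gtv_volume_cm3",
    "ptv_volume_cm3",
    "svz_volume_cm3",
    "sgz_volume_cm3",
    "svz_mean_dose_gy",
    "hpc_mean_dose_gy",
    "centrality_cm",
}


class RankDeficientDesignError(ValueError):
    """Design matrix is rank deficient; carries the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxModelSpec:
    """One Cox model: ordered covariates and the variable of interest."""

    name: str
    covariates: tuple[str, ...]
    variable_of_interest: str

    def __post_init__(self) -> None:
        if self.covariates.count(self.variable_of_interest) != 1:
            raise ValueError(
                f"{self.name}: variable of interest {self.variable_of_interest!r} "
                "must appear exactly once in the covariate list"
            )


def _nested_specs(interest: str, niche_volume: str) -> dict[str, CoxModelSpec]:
    base = (interest,)
    demo = ("age", "sex", "who_status", "histology", niche_volume)
    burden = (
        "n_bm",
        "extracranial_mets",
        "chemotherapy",
        "other_systemic_therapy",
        "resection_extent",
    )
    tiers = {
        "m0": base,
        "m1": base + demo,
        "m2": base + demo + burden,
        "m3": base + demo + burden + ("gtv_volume_cm3",),
    }
    return {
        f"{interest.split('_')[0]}_{'dose' if 'dose' in interest else 'contact'}_{tier}":
            CoxModelSpec(
                name=f"{interest.split('_')[0]}_{'dose' if 'dose' in interest else 'contact'}_{tier}",
                covariates=covs,
                variable_of_interest=interest,
            )
        for tier, covs in tiers.items()
    }


#: Named nested model specs: {svz,hpc} x {dose,contact} x {m0..m3}.
MODEL_REGISTRY: dict[str, CoxModelSpec] = {}
for _interest, _vol in [
    ("svz_mean_dose_gy", "svz_volume_cm3"),
    ("hpc_mean_dose_gy", "sgz_volume_cm3"),
    ("svz_contact", "svz_volume_cm3"),
    ("hpc_contact", "sgz_volume_cm3"),
]:
    MODEL_REGISTRY.update(_nested_specs(_interest, _vol))


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def complete_cases(table: pd.DataFrame, covariates) -> pd.DataFrame:
    """Rows usable for a model: no 'unknown' categorical level, no NaN."""
    keep = pd.Series(True, index=table.index)
    for cov in covariates:
        if cov in CATEGORICAL_LEVELS:
            keep &= table[cov].astype(str) != "unknown"
        else:
            keep &= table[cov].notna()
    return table.loc[keep]


def build_design_matrix(table: pd.DataFrame, covariates) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Numeric design matrix with treatment-coded categoricals.

    Returns ``(X, groups)`` where ``groups`` maps each covariate to the
    design columns it produced (one for continuous, levels-1 dummies for
    categoricals, reference = first documented level).  The caller is
    responsible for restricting to complete cases first.
    """
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, list[str]] = {}
    for cov in covariates:
        if cov in CATEGORICAL_LEVELS:
            levels = [lv for lv in CATEGORICAL_LEVELS[cov] if lv != "unknown"]
            vals = table[cov].astype(str)
            group_cols = []
            for lv in levels[1:]:
                cname = f"{cov}[{lv}]"
                cols[cname] = (vals == lv).to_numpy(dtype=float)
                group_cols.append(cname)
            groups[cov] = group_cols
        else:
            cols[cov] = table[cov].to_numpy(dtype=float)
            groups[cov] = [cov]
    return pd.DataFrame(cols, index=table.index), groups


# ---------------------------------------------------------------------------
# Kaplan-Meier by contact group
# ---------------------------------------------------------------------------

@dataclass
class KMGroup:
    label: str
    n: int
    n_events: int
    times: np.ndarray
    survival: np.ndarray
    median_months: float | None  # None when the curve never crosses 0.5

    @property
    def median_not_reached(self) -> bool:
        return self.median_months is None

    @property
    def median_display(self) -> str:
        return "NR" if self.median_months is None else f"{self.median_months:g}"


@dataclass
class KMResult:
    groups: dict[str, KMGroup]
    logrank_p: float
    logrank_statistic: float
    hr_cox: float          # univariable Cox HR of group=second level vs first
    hr_cox_ci: tuple[float, float]
    hr_logrank: float      # (O/E) ratio approximation from the log-rank table


def km_by_group(table: pd.DataFrame, group_col: str) -> KMResult:
    """Kaplan-Meier curves, medians, log-rank test and HR for a binary split.

    Median survival is the smallest time at which the product-limit curve
    drops to <= 0.5 and is reported as not-reached (``None``) when the curve
    never crosses 0.5.  Two hazard-ratio variants are emitted: the
    univariable Cox estimate and the O/E log-rank approximation.
    """
    levels = sorted(table[group_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"{group_col} must have exactly 2 levels, got {levels}")
    groups: dict[str, KMGroup] = {}
    oe = {}
    for lv in levels:
        sub = table[table[group_col].astype(str) == lv]
        if len(sub) == 0:
            raise ValueError(f"empty group {lv!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_months"], sub["event"])
        med = kmf.median_survival_time_
        groups[lv] = KMGroup(
            label=lv,
            n=len(sub),
            n_events=int(sub["event"].sum()),
            times=kmf.survival_function_.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            median_months=None if not math.isfinite(med) else float(med),
        )
    res = logrank_test(
        table.loc[table[group_col].astype(str) == levels[0], "os_months"],
        table.loc[table[group_col].astype(str) == levels[1], "os_months"],
        table.loc[table[group_col].astype(str) == levels[0], "event"],
        table.loc[table[group_col].astype(str) == levels[1], "event"],
    )
    # O/E approximation from the pooled log-rank table
    for lv in levels:
        oe[lv] = groups[lv].n_events
    expected = _logrank_expected(table, group_col, levels)
    if min(expected.values()) > 0 and oe[levels[0]] > 0:
        hr_lr = (oe[levels[1]] / expected[levels[1]]) / (oe[levels[0]] / expected[levels[0]])
    else:
        hr_lr = float("nan")

    if sum(oe.values()) > 0:
        dummy = (table[group_col].astype(str) == levels[1]).astype(float)
        cph = CoxPHFitter()
        cph.fit(
            pd.DataFrame(
                {"group": dummy, "os_months": table["os_months"], "event": table["event"]}
            ),
            duration_col="os_months",
            event_col="event",
        )
        hr = float(np.exp(cph.params_["group"]))
        ci = cph.confidence_intervals_
        hr_ci = (float(np.exp(ci.iloc[0, 0])), float(np.exp(ci.iloc[0, 1])))
    else:  # no events at all: hazard ratio undefined
        hr, hr_ci = float("nan"), (float("nan"), float("nan"))
    return KMResult(
        groups=groups,
        logrank_p=float(res.p_value),
        logrank_statistic=float(res.test_statistic),
        hr_cox=hr,
        hr_cox_ci=hr_ci,
        hr_logrank=float(hr_lr),
    )


def _logrank_expected(table: pd.DataFrame, group_col: str, levels) -> dict[str, float]:
    """Expected event counts per group under the null, from the risk sets."""
    t = table["os_months"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    g = (table[group_col].astype(str) == levels[1]).to_numpy()
    expected = {levels[0]: 0.0, levels[1]: 0.0}
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        d = int(((t == tt) & (e == 1)).sum())
        n_risk = int(at_risk.sum())
        expected[levels[1]] += d * at_risk[g].sum() / n_risk
        expected[levels[0]] += d * at_risk[~g].sum() / n_risk
    return expected


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

@dataclass
class CoxFitResult:
    spec: CoxModelSpec
    table: pd.DataFrame          # index = design column; HR, CI, p
    n_used: int
    n_events: int
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def interest_row(self) -> pd.Series:
        """Result row of the variable of interest (first dummy if categorical)."""
        cols = [c for c in self.table.index if c == self.spec.variable_of_interest
                or c.startswith(self.spec.variable_of_interest + "[")]
        return self.table.loc[cols[0]]

    @property
    def interest_hr(self) -> float:
        return float(self.interest_row["hr"])

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "n": self.n_used,
            "events": self.n_events,
            "converged": self.converged,
            "coefficients": {
                str(ix): {
                    "hr": float(row["hr"]),
                    "ci_lower": float(row["ci_lower"]),
                    "ci_upper": float(row["ci_upper"]),
                    "p": float(row["p"]),
                }
                for ix, row in self.table.iterrows()
            },
        }


def fit_cox(table: pd.DataFrame, spec: CoxModelSpec) -> CoxFitResult:
    """Fit one Cox proportional-hazards model (Efron ties, complete cases).

    Hazard ratios for dose covariates are per Gy; categorical covariates are
    treatment-coded against the first documented level.  Non-convergence is
    flagged on the result rather than silently returned, and a model with no
    events is an error.
    """
    sub = complete_cases(table, spec.covariates)
    X, _groups = build_design_matrix(sub, spec.covariates)
    n_events = int(sub["event"].sum())
    if n_events == 0:
        raise ValueError("no events in the complete-case subset")
    df = X.copy()
    df["os_months"] = sub["os_months"].to_numpy(dtype=float)
    df["event"] = sub["event"].to_numpy(dtype=int)
    cph = CoxPHFitter()  # lifelines uses the Efron tie correction
    msgs: list[str] = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="os_months", event_col="event")
        except Exception as exc:
            raise RuntimeError(f"Cox fit failed for {spec.name}: {exc}") from exc
        for w in caught:
            text = str(w.message)
            if "convergence" in text.lower() or "collinear" in text.lower():
                msgs.append(text)
                converged = False
    ci = cph.confidence_intervals_
    out = pd.DataFrame(
        {
            "coef": cph.params_,
            "hr": np.exp(cph.params_),
            "ci_lower": np.exp(ci.iloc[:, 0]),
            "ci_upper": np.exp(ci.iloc[:, 1]),
            "p": cph.summary["p"],
        }
    )
    return CoxFitResult(spec, out, len(sub), n_events, converged, msgs)


# ---------------------------------------------------------------------------
# Adjusted variance inflation factors
# ---------------------------------------------------------------------------

def adjusted_vif(table: pd.DataFrame, spec: CoxModelSpec) -> pd.Series:
    """Adjusted VIF per covariate on the model's design matrix.

    Continuous covariates get the classical ``1/(1-R^2)``; multi-level
    categoricals get the generalized VIF raised to ``1/(2*df)`` so the scale
    is comparable across covariates.  All values are >= 1.  A rank-deficient
    design raises :class:`RankDeficientDesignError` naming the collinear
    columns.
    """
    sub = complete_cases(table, spec.covariates)
    X, groups = build_design_matrix(sub, spec.covariates)
    Xc = X.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    sd = Xc.std(axis=0)
    zero = sd < 1e-12
    if zero.any():
        raise RankDeficientDesignError(list(X.columns[zero]))
    Xc = Xc / sd
    R = (Xc.T @ Xc) / len(Xc)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or logdet < -30 * np.log(10):
        raise RankDeficientDesignError(_collinear_columns(Xc, list(X.columns)))

    col_index = {c: i for i, c in enumerate(X.columns)}
    result = {}
    for cov, cols in groups.items():
        if not cols:
            continue
        idx = np.array([col_index[c] for c in cols])
        rest = np.array([i for i in range(R.shape[0]) if i not in idx])
        if rest.size == 0:
            result[cov] = 1.0
            continue
        _, ld1 = np.linalg.slogdet(R[np.ix_(idx, idx)])
        _, ld2 = np.linalg.slogdet(R[np.ix_(rest, rest)])
        gvif = math.exp(ld1 + ld2 - logdet)
        df = len(cols)
        # single-column covariates report the classical 1/(1-R^2); only
        # multi-column blocks are rescaled to a comparable per-dimension size
        result[cov] = gvif if df == 1 else gvif ** (1.0 / (2.0 * df))
    return pd.Series(result, name="adjusted_vif")


def _collinear_columns(Xc: np.ndarray, names: list[str]) -> list[str]:
    """Columns near-perfectly explained by the others (diagnostic only)."""
    bad = []
    for j in range(Xc.shape[1]):
        others = np.delete(Xc, j, axis=1)
        resid = Xc[:, j] - others @ np.linalg.lstsq(others, Xc[:, j], rcond=None)[0]
        if np.sum(resid**2) / np.sum(Xc[:, j] ** 2) < 1e-10:
            bad.append(names[j])
    return bad or names


# ---------------------------------------------------------------------------
# Sensitivity subsets
# ---------------------------------------------------------------------------

SENSITIVITY_FILTERS = ("drop-largest-ptv-10pct", "single-bm", "exclude-central-decile")
MIN_SENSITIVITY_ROWS = 10


def sensitivity_filters(table: pd.DataFrame, which: str) -> pd.DataFrame:
    """Apply one of the predefined sensitivity subsets.

    * ``drop-largest-ptv-10pct``: removes the ``ceil(0.10 * n)`` rows with
      the largest PTV volume (stable order among ties);
    * ``single-bm``: keeps patients with exactly one brain metastasis;
    * ``exclude-central-decile``: within single-metastasis rows with a
      defined centrality, removes the decile with the smallest PTV-to-AC
      distance (the lesions most likely to irradiate the niches
      unavoidably).

    Row order of the survivors is preserved.  A subset smaller than
    ``MIN_SENSITIVITY_ROWS`` is flagged via ``table.attrs['small_subset']``
    so downstream fits can warn.
    """
    if which == "drop-largest-ptv-10pct":
        k = math.ceil(0.10 * len(table))
        order = np.argsort(-table["ptv_volume_cm3"].to_numpy(), kind="stable")
        drop = table.index[order[:k]]
        out = table.drop(index=drop)
    elif which == "single-bm":
        out = table[table["n_bm"].astype(str) == "1"]
    elif which == "exclude-central-decile":
        single = table[(table["n_bm"].astype(str) == "1") & table["centrality_cm"].notna()]
        k = math.ceil(0.10 * len(single))
        order = np.argsort(single["centrality_cm"].to_numpy(), kind="stable")
        out = single.drop(index=single.index[order[:k]])
    else:
        raise ValueError(f"unknown sensitivity filter {which!r}; choose from {SENSITIVITY_FILTERS}")
    out = out.copy()
    out.attrs["small_subset"] = len(out) < MIN_SENSITIVITY_ROWS
    return out


# ---------------------------------------------------------------------------
# Dose-burden correlations
# ---------------------------------------------------------------------------

_BURDEN_VARS = ("gtv_volume_cm3", "ptv_volume_cm3", "n_bm", "centrality_cm")
_DOSE_VARS = ("svz_mean_dose_gy", "hpc_mean_dose_gy")
_N_BM_ORDINAL = {"1": 1, "2-4": 2, ">4": 3}


def correlate_dose_burden(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations of niche dose with tumour burden and centrality.

    The number of brain metastases enters as an ordinal (1 < 2-4 < >4);
    centrality pairs are restricted to single-metastasis patients with a
    defined distance.  A constant column yields NaN (flagged, not an error).
    """
    rows = []
    for burden in _BURDEN_VARS:
        if burden == "n_bm":
            x_all = table["n_bm"].astype(str).map(_N_BM_ORDINAL).astype(float)
        else:
            x_all = table[burden].astype(float)
        for dose_var in _DOSE_VARS:
            y_all = table[dose_var].astype(float)
            ok = x_all.notna() & y_all.notna()
            x, y = x_all[ok], y_all[ok]
            if len(x) < 3:
                raise ValueError(f"fewer than 3 complete pairs for {burden} vs {dose_var}")
            if x.nunique() < 2 or y.nunique() < 2:
                rho, p, flag = float("nan"), float("nan"), True
            else:
                rho, p = stats.spearmanr(x, y)
                flag = False
            rows.append(
                {
                    "burden": burden,
                    "dose": dose_var,
                    "rho": float(rho),
                    "p": float(p),
                    "n": int(len(x)),
                    "undefined": flag,
                }
            )
    return pd.DataFrame(rows)
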