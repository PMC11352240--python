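"""Survival and clinical association analysis of subtype assignments.

Kaplan-Meier curves and the k-group log-rank test are implemented natively
(product-limit estimator; observed-minus-expected vector with the
hypergeometric covariance, chi-squared on k-1 df), keeping the core
comparison dependency-light.  Cox proportional-hazards models are fit with
lifelines (Efron tie handling, Wald confidence intervals) and the
proportional-hazards assumption is checked via the scaled-Schoenfeld
residual trend test reported alongside each fit.

The multivariate procedure mirrors common clinical practice: candidate
covariates are screened at univariate p < 0.2, backward elimination drops
the largest-p covariate while any p > 0.05, and the added value of the
subtypes is the likelihood-ratio test between the baseline (covariates-only)
and full (covariates + subtype) models.

Associations between subtypes and clinical variables use the Kruskal-Wallis
(>2 groups) or Wilcoxon rank-sum (2 groups) test for continuous variables
and Fisher's exact (2x2, any expected count <= 5) or Pearson's chi-squared
test for categorical ones, with listwise NA exclusion per variable.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import SubtypeAssignment
from .data_io import ClinicalTable, ValidationError

__all__ = [
    "KMCurve",
    "LogrankResult",
    "CoxResult",
    "AssociationResult",
    "km_curve",
    "km_logrank",
    "cox_fit",
    "stepwise_model",
    "likelihood_ratio_test",
    "association_tests",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    group: str
    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    censor_times: np.ndarray

    def __post_init__(self) -> None:
        s = self.survival
        if len(s) and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValidationError("survival curve must be non-increasing within [0, 1]")

    def median_survival(self) -> float:
        below = self.times[self.survival <= 0.5]
        return float(below[0]) if len(below) else float("nan")


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    curves: dict[str, KMCurve]
    dropped_groups: list[str] = field(default_factory=list)


@dataclass
class CoxResult:
    terms: pd.DataFrame  # term, coef, hr, ci_lower, ci_upper, p
    log_likelihood: float
    n: int
    n_events: int
    ph_test: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)
    global_p: dict[str, float] = field(default_factory=dict)  # multi-level terms


@dataclass
class AssociationResult:
    variable: str
    test: str  # Kruskal-Wallis | Wilcoxon | Fisher | chi-squared
    statistic: float
    p_value: float
    n: int
    note: str = ""


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank (native)
# ---------------------------------------------------------------------------


def km_curve(times, events, group: str = "") -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    surv, at_risk = [], []
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
    return KMCurve(
        group=group,
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        censor_times=times[events == 0],
    )


def _labels_frame(clinical: ClinicalTable, labels: SubtypeAssignment | dict) -> pd.DataFrame:
    lab = labels.labels if isinstance(labels, SubtypeAssignment) else dict(labels)
    common = [p for p in clinical.patients if p in lab]
    if not common:
        raise ValidationError("no overlap between clinical table and labeled patients")
    df = clinical.data.loc[common, ["os_time", "os_event"]].copy()
    df["subtype"] = [lab[p] for p in common]
    return df.dropna(subset=["os_time", "os_event"])


def km_logrank(
    clinical: ClinicalTable, labels: SubtypeAssignment | dict
) -> LogrankResult:
    """Per-group KM curves and the k-group log-rank chi-squared test.

    For each distinct event time the observed minus expected event counts per
    group are accumulated with the multivariate-hypergeometric covariance;
    the statistic is (O-E)' V^+ (O-E) on k-1 degrees of freedom.
    """
    df = _labels_frame(clinical, labels)
    groups = sorted(df["subtype"].unique())
    dropped = [str(g) for g in groups if (df["subtype"] == g).sum() == 0]
    groups = [g for g in groups if (df["subtype"] == g).sum() > 0]
    if len(groups) < 2:
        raise ValidationError("log-rank test needs at least two non-empty groups")

    curves = {
        str(g): km_curve(
            df.loc[df["subtype"] == g, "os_time"],
            df.loc[df["subtype"] == g, "os_event"],
            group=str(g),
        )
        for g in groups
    }

    times = df["os_time"].to_numpy(float)
    events = df["os_event"].to_numpy(int)
    gidx = df["subtype"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    k = len(groups)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = int(((times == t) & (events == 1)).sum())
        n_g = np.array([(at_risk & (gidx == i)).sum() for i in range(k)], dtype=float)
        d_g = np.array(
            [((times == t) & (events == 1) & (gidx == i)).sum() for i in range(k)],
            dtype=float,
        )
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            mult = d_t * (n_t - d_t) / (n_t - 1)
            V += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    stat = float(diff @ np.linalg.pinv(Vsub) @ diff) if diff.size else 0.0
    dfree = k - 1
    p = float(stats.chi2.sf(stat, dfree))
    return LogrankResult(statistic=stat, df=dfree, p_value=p, curves=curves, dropped_groups=dropped)


# ---------------------------------------------------------------------------
# Cox proportional hazards (lifelines behind the module surface)
# ---------------------------------------------------------------------------


def _design_frame(
    clinical: ClinicalTable,
    terms: list[str],
    labels: SubtypeAssignment | dict | None = None,
    reference_levels: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Build the one-hot design matrix; returns (frame, term -> columns map)."""
    reference_levels = reference_levels or {}
    df = clinical.data.copy()
    if labels is not None:
        lab = labels.labels if isinstance(labels, SubtypeAssignment) else dict(labels)
        df = df.loc[[p for p in df.index if p in lab]]
        df["subtype"] = pd.Categorical([str(lab[p]) for p in df.index])
    cols = ["os_time", "os_event", *terms]
    df = df[cols].dropna()
    out = df[["os_time", "os_event"]].copy()
    term_cols: dict[str, list[str]] = {}
    for term in terms:
        col = df[term]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            if col.nunique() < 2:
                raise ValidationError(f"term {term!r} has a single level")
            out[term] = col.astype(float)
            term_cols[term] = [term]
        else:
            levels = [str(v) for v in sorted(col.astype(str).unique())]
            if len(levels) < 2:
                raise ValidationError(f"term {term!r} has a single level")
            ref = str(reference_levels.get(term, levels[0]))
            names = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{term}[{lev}]"
                out[name] = (col.astype(str) == lev).astype(float)
                names.append(name)
            term_cols[term] = names
    return out, term_cols


def cox_fit(
    clinical: ClinicalTable,
    design: list[str],
    labels: SubtypeAssignment | dict | None = None,
    reference_levels: dict[str, str] | None = None,
    check_ph: bool = True,
) -> CoxResult:
    """Cox partial-likelihood fit (Efron ties) with Wald 95% CIs.

    Degenerate configurations (a level with zero events, monotone likelihood)
    are reported with a warning on the result, not raised: rare tiny subtypes
    are a real feature of stratification output and are kept visible.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    frame, term_cols = _design_frame(clinical, design, labels, reference_levels)
    n_params = sum(len(v) for v in term_cols.values())
    n_events = int(frame["os_event"].sum())
    if n_events < n_params:
        raise ValidationError(
            f"{n_events} events cannot support {n_params} parameters"
        )
    cph = CoxPHFitter()
    warn_msgs: list[str] = []
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        try:
            cph.fit(frame, duration_col="os_time", event_col="os_event")
        except ConvergenceError as err:
            # collinear or separated designs: refit with a tiny ridge so the
            # partial likelihood (and hence LRTs) is still reported
            try:
                cph = CoxPHFitter(penalizer=1e-4)
                cph.fit(frame, duration_col="os_time", event_col="os_event")
                warn_msgs.append(
                    f"ridge (1e-4) applied after convergence failure: {str(err).splitlines()[0]}"
                )
            except ConvergenceError:
                raise ValidationError(f"Cox model did not converge: {err}") from err
        for w in caught:
            msg = str(w.message)
            if "convergence" in msg.lower() or "complete separation" in msg.lower() or "collinear" in msg.lower():
                warn_msgs.append(msg.splitlines()[0])

    summary = cph.summary
    terms = pd.DataFrame(
        {
            "term": summary.index,
            "coef": summary["coef"].to_numpy(),
            "hr": summary["exp(coef)"].to_numpy(),
            "ci_lower": summary["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": summary["exp(coef) upper 95%"].to_numpy(),
            "p": summary["p"].to_numpy(),
        }
    ).reset_index(drop=True)

    global_p: dict[str, float] = {}
    for term, cols in term_cols.items():
        if len(cols) > 1:  # multi-level term: Wald chi-squared on all its columns
            beta = summary.loc[cols, "coef"].to_numpy()
            cov = cph.variance_matrix_.loc[cols, cols].to_numpy()
            try:
                w = float(beta @ np.linalg.solve(cov, beta))
                global_p[term] = float(stats.chi2.sf(w, len(cols)))
            except np.linalg.LinAlgError:
                global_p[term] = float("nan")

    ph = None
    if check_ph and n_events > n_params + 1:
        try:
            from lifelines.statistics import proportional_hazard_test

            res = proportional_hazard_test(cph, frame, time_transform="rank")
            ph = res.summary.reset_index()
        except Exception as err:  # degenerate designs can break the residual test
            warn_msgs.append(f"proportional-hazards check failed: {err}")

    return CoxResult(
        terms=terms,
        log_likelihood=float(cph.log_likelihood_),
        n=len(frame),
        n_events=n_events,
        ph_test=ph,
        warnings=warn_msgs,
        global_p=global_p,
    )


def likelihood_ratio_test(base: CoxResult, full: CoxResult) -> tuple[float, int, float]:
    """LRT on 2*(llf_full - llf_base); df = added parameters; never negative."""
    df = len(full.terms) - len(base.terms)
    if df <= 0:
        raise ValidationError("full model must add parameters over the baseline")
    stat = max(0.0, 2.0 * (full.log_likelihood - base.log_likelihood))
    return stat, df, float(stats.chi2.sf(stat, df))


def _null_cox(clinical: ClinicalTable, patients: pd.Index | None = None) -> CoxResult:
    """Covariate-free model: log partial likelihood of the null."""
    df = clinical.data if patients is None else clinical.data.loc[patients]
    df = df[["os_time", "os_event"]].dropna()
    times = df["os_time"].to_numpy(float)
    events = df["os_event"].to_numpy(int)
    # Closed-form null partial likelihood with Efron ties: at beta=0 the j-th
    # of d_t tied events contributes -log(n_t - j), matching lifelines' fits.
    ll = 0.0
    for t in np.unique(times[events == 1]):
        n_t = int(np.sum(times >= t))
        d_t = int(np.sum((times == t) & (events == 1)))
        for j in range(d_t):
            ll -= np.log(n_t - j)
    return CoxResult(
        terms=pd.DataFrame(columns=["term", "coef", "hr", "ci_lower", "ci_upper", "p"]),
        log_likelihood=ll,
        n=len(df),
        n_events=int(events.sum()),
    )


def stepwise_model(
    clinical: ClinicalTable,
    candidates: list[str],
    labels: SubtypeAssignment | dict,
    screen_p: float = 0.2,
    removal_p: float = 0.05,
    reference_levels: dict[str, str] | None = None,
) -> dict:
    """Backward-stepwise baseline model, then test the subtypes' added value.

    Candidates are screened at univariate p < ``screen_p``; backward
    elimination repeatedly removes the largest-p covariate above
    ``removal_p``.  The baseline (selected covariates) is compared with the
    full model (baseline + subtype) by the likelihood-ratio test.  Listwise
    NA handling: both nested models are fit on the complete-case rows of the
    full design so the LRT compares like with like.
    """
    lab = labels.labels if isinstance(labels, SubtypeAssignment) else dict(labels)

    screened: list[str] = []
    for cov in candidates:
        try:
            uni = cox_fit(clinical, [cov], reference_levels=reference_levels, check_ph=False)
        except ValidationError:
            continue
        p = uni.global_p.get(cov, uni.terms["p"].min() if len(uni.terms) else 1.0)
        if p < screen_p:
            screened.append(cov)

    selected = list(screened)
    while selected:
        fit = cox_fit(clinical, selected, reference_levels=reference_levels, check_ph=False)
        term_p = {}
        for term in selected:
            if term in fit.global_p:
                term_p[term] = fit.global_p[term]
            else:
                rows = fit.terms[fit.terms["term"].str.startswith(term)]
                term_p[term] = float(rows["p"].min()) if len(rows) else 1.0
        worst = max(term_p, key=term_p.get)
        if term_p[worst] > removal_p:
            selected.remove(worst)
        else:
            break

    # complete cases of the *full* design, so baseline and full are nested on
    # identical rows
    full_frame, _ = _design_frame(clinical, [*selected, "subtype"], labels, reference_levels)
    common = full_frame.index
    restricted = ClinicalTable(clinical.data.loc[common].copy())

    full = cox_fit(restricted, [*selected, "subtype"], labels, reference_levels, check_ph=False)
    if selected:
        base = cox_fit(restricted, selected, reference_levels=reference_levels, check_ph=False)
    else:
        base = _null_cox(restricted)
    stat, dfree, p = likelihood_ratio_test(base, full)
    return {
        "screened": screened,
        "selected": selected,
        "baseline": base,
        "full": full,
        "lrt_statistic": stat,
        "lrt_df": dfree,
        "lrt_p": p,
    }


# ---------------------------------------------------------------------------
# Clinical association tests
# ---------------------------------------------------------------------------


def association_tests(
    clinical: ClinicalTable,
    labels: SubtypeAssignment | dict,
    variables: list[str] | None = None,
) -> list[AssociationResult]:
    """Test each clinical variable against the subtype grouping.

    Continuous: Kruskal-Wallis (>2 groups) or Wilcoxon rank-sum (2 groups).
    Categorical: Fisher's exact for 2x2 tables with any expected count <= 5,
    Pearson's chi-squared otherwise (exact tests beyond 2x2 are out of
    reach of the scipy backend; such cases are flagged in the note).  NAs are
    excluded listwise per variable and the non-missing N reported.
    """
    lab = labels.labels if isinstance(labels, SubtypeAssignment) else dict(labels)
    common = [p for p in clinical.patients if p in lab]
    if not common:
        raise ValidationError("no overlap between clinical table and labels")
    data = clinical.data.loc[common]
    groups = pd.Series([lab[p] for p in common], index=data.index)
    variables = variables if variables is not None else clinical.covariates

    results: list[AssociationResult] = []
    for var in variables:
        col = data[var]
        mask = col.notna()
        x, g = col[mask], groups[mask]
        n = int(mask.sum())
        if x.nunique() < 2:
            results.append(
                AssociationResult(var, "skipped", float("nan"), float("nan"), n,
                                  note="variable has a single distinct value")
            )
            continue
        glabs = sorted(g.unique())
        if len(glabs) < 2:
            results.append(
                AssociationResult(var, "skipped", float("nan"), float("nan"), n,
                                  note="fewer than two subtypes after NA exclusion")
            )
            continue
        if pd.api.types.is_numeric_dtype(x) and x.nunique() > 5:
            samples = [x[g == gl].to_numpy(float) for gl in glabs]
            if len(glabs) == 2:
                stat, p = stats.ranksums(samples[0], samples[1])
                results.append(AssociationResult(var, "Wilcoxon", float(stat), float(p), n))
            else:
                stat, p = stats.kruskal(*samples)
                results.append(AssociationResult(var, "Kruskal-Wallis", float(stat), float(p), n))
        else:
            table = pd.crosstab(x.astype(str), g).to_numpy()
            expected = stats.contingency.expected_freq(table)
            note = ""
            if table.shape == (2, 2) and (expected <= 5).any():
                _, p = stats.fisher_exact(table)
                results.append(AssociationResult(var, "Fisher", float("nan"), float(p), n))
                continue
            if (expected < 5).any():
                note = "expected counts < 5; exact test unavailable beyond 2x2"
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            results.append(
                AssociationResult(var, "chi-squared", float(stat), float(p), n, note=note)
            )
    return results
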