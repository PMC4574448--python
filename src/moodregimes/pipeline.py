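"""Per-patient analysis over a cohort and cohort-level summaries.

For each complete series the pipeline computes (i) the bimodality
coefficient with its unimodal/bimodal label and (ii) the 1- vs 2-state
binomial HMM comparison by BIC with the mode distance and stay
probabilities; at the cohort level it reports the share of BC-bimodal
patients, the share where BIC prefers two states, the pooled BC over all
counts, distributional statistics and a normality check of the per-patient
BCs, and Spearman rank correlations among the per-patient quantities
(selection indicator coded 1 = 2-state model selected).

Patients with a constant series have an undefined BC; they are kept in the
HMM summaries, dropped pairwise from BC correlations, and the drop counts
are always reported rather than hidden.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from ._errors import DegenerateSeriesError, ValidationError
from .bimodality import BCResult, bimodality_coefficient
from .hmm import HMMFit, ModelComparison, compare_models, fit_hmm_many
from .io import AnalysisConfig
from .series import SymptomSeries

__all__ = [
    "PatientReport",
    "CohortSummary",
    "analyze_patient",
    "analyze_cohort",
    "table2_report",
    "select_percentile_cases",
    "render_patient_figure",
    "symptom_histogram",
    "patient_reports_frame",
    "cohort_summary_frame",
    "bc_results_frame",
    "hmm_fits_frame",
]

PERCENTILES = (5, 10, 25, 50, 75, 90, 95)


@dataclass
class PatientReport:
    """All per-patient results for one complete series."""

    patient_id: str
    bc_result: BCResult | None  # None: BC undefined (constant series)
    comparison: ModelComparison

    @property
    def bc(self) -> float | None:
        return None if self.bc_result is None else self.bc_result.bc

    @property
    def selected_K(self) -> int:
        return self.comparison.selected_K

    @property
    def mode_distance(self) -> float:
        return float(self.comparison.fit_2state.mode_distance)

    @property
    def stay_probabilities(self) -> np.ndarray:
        return self.comparison.fit_2state.stay_probabilities


@dataclass
class CohortSummary:
    """Cohort-level quantities.

    Correlations are Spearman rank correlations with two-sided p-values;
    entries are None when an input has zero variance (undefined rather than
    a fabricated number). ``proportion_bc_bimodal`` is the share of
    defined-BC patients above the threshold; ``n_bc_undefined`` counts the
    constant-series patients excluded from it and from BC correlations.
    """

    n_patients: int
    n_excluded: int
    n_bc_undefined: int
    proportion_bc_bimodal: float | None
    proportion_hmm_2state: float
    pooled_bc: float | None
    pooled_n: int
    bc_mean: float | None
    bc_median: float | None
    bc_sd: float | None
    bc_min: float | None
    bc_max: float | None
    normality_stat: float | None
    normality_p: float | None
    rho_bc_vs_selection: float | None
    p_bc_vs_selection: float | None
    rho_distance_vs_selection: float | None
    p_distance_vs_selection: float | None
    rho_distance_vs_bc: float | None
    p_distance_vs_bc: float | None


def _fit_seed(master_seed: int, patient_id: str) -> int:
    """Per-patient EM seed, stable under cohort reordering."""
    return (int(master_seed) ^ zlib.crc32(str(patient_id).encode())) % (2**31)


def analyze_patient(
    series: SymptomSeries, config: AnalysisConfig | None = None
) -> PatientReport:
    """BC and 1- vs 2-state HMM comparison for one patient.

    The two computations are independent views of the same counts; the EM
    seed is derived from (config seed, patient id) so results do not depend
    on where the patient sits in a cohort.
    """
    cfg = config or AnalysisConfig()
    if cfg.T is not None and series.T != cfg.T:
        raise ValidationError(
            f"series {series.patient_id!r} has {series.T} weeks, expected {cfg.T}"
        )
    try:
        bc_res: BCResult | None = bimodality_coefficient(
            series, threshold=cfg.bc_threshold
        )
    except DegenerateSeriesError:
        bc_res = None
    kwargs = dict(
        n_restarts=cfg.n_restarts,
        seed=_fit_seed(cfg.seed, series.patient_id),
        tol=cfg.tol,
        max_iter=cfg.max_iter,
    )
    fit1 = fit_hmm_many([series], 1, **kwargs)[0]
    fit2 = fit_hmm_many([series], 2, **kwargs)[0]
    return PatientReport(
        patient_id=series.patient_id,
        bc_result=bc_res,
        comparison=compare_models(fit1, fit2),
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float | None, float | None]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    rho, p = _stats.spearmanr(x, y)
    return float(rho), float(p)


def analyze_cohort(
    cohort: Sequence[SymptomSeries], config: AnalysisConfig | None = None
) -> tuple[list[PatientReport], CohortSummary]:
    """Run the per-patient analysis over a cohort and summarise it.

    Series whose length differs from the configured T are excluded (the
    complete-case rule) with the exclusion count reported in the summary;
    the analysis itself is deterministic given the config seed and invariant
    to patient order.
    """
    cfg = config or AnalysisConfig()
    if not cohort:
        raise ValidationError("cohort must contain at least one series")
    kept = [s for s in cohort if cfg.T is None or s.T == cfg.T]
    n_excluded = len(cohort) - len(kept)
    if not kept:
        raise ValidationError("no series of the configured length to analyse")

    kwargs = dict(n_restarts=cfg.n_restarts, tol=cfg.tol, max_iter=cfg.max_iter)
    seed_fn = lambda pid: _fit_seed(cfg.seed, pid)  # noqa: E731
    fits1 = fit_hmm_many(kept, 1, seed_fn=seed_fn, **kwargs)
    fits2 = fit_hmm_many(kept, 2, seed_fn=seed_fn, **kwargs)
    reports = []
    for s, f1, f2 in zip(kept, fits1, fits2):
        try:
            bc_res: BCResult | None = bimodality_coefficient(
                s, threshold=cfg.bc_threshold
            )
        except DegenerateSeriesError:
            bc_res = None
        reports.append(
            PatientReport(
                patient_id=s.patient_id,
                bc_result=bc_res,
                comparison=compare_models(f1, f2),
            )
        )

    # sort a copy by patient_id so summaries are order-invariant
    by_id = sorted(reports, key=lambda r: str(r.patient_id))
    bcs = np.array([r.bc for r in by_id if r.bc is not None], dtype=float)
    sel = np.array([1 if r.selected_K == 2 else 0 for r in by_id])
    dist = np.array([r.mode_distance for r in by_id])
    defined = np.array([r.bc is not None for r in by_id])
    n_undef = int((~defined).sum())

    pooled_counts = np.concatenate([s.counts for s in kept])
    try:
        pooled_bc: float | None = bimodality_coefficient(
            pooled_counts, threshold=cfg.bc_threshold
        ).bc
    except (DegenerateSeriesError, ValidationError):
        pooled_bc = None

    if bcs.size:
        if bcs.size >= 4 and np.ptp(bcs) > 0:
            # normality of the BC distribution, parameters estimated
            from statsmodels.stats.diagnostic import kstest_normal

            ks_stat, ks_p = kstest_normal(bcs, dist="norm")
            ks_stat, ks_p = float(ks_stat), float(ks_p)
        else:
            ks_stat = ks_p = None
        bc_stats = dict(
            bc_mean=float(bcs.mean()),
            bc_median=float(np.median(bcs)),
            bc_sd=float(bcs.std(ddof=1)) if bcs.size > 1 else None,
            bc_min=float(bcs.min()),
            bc_max=float(bcs.max()),
        )
        prop_bimodal = float(np.mean(bcs > cfg.bc_threshold))
    else:
        ks_stat = ks_p = None
        bc_stats = dict(
            bc_mean=None, bc_median=None, bc_sd=None, bc_min=None, bc_max=None
        )
        prop_bimodal = None

    rho_bs, p_bs = _spearman(bcs, sel[defined]) if bcs.size else (None, None)
    rho_ds, p_ds = _spearman(dist, sel)
    rho_db, p_db = (
        _spearman(dist[defined], bcs) if bcs.size else (None, None)
    )

    summary = CohortSummary(
        n_patients=len(kept),
        n_excluded=n_excluded,
        n_bc_undefined=n_undef,
        proportion_bc_bimodal=prop_bimodal,
        proportion_hmm_2state=float(sel.mean()),
        pooled_bc=pooled_bc,
        pooled_n=int(pooled_counts.size),
        normality_stat=ks_stat,
        normality_p=ks_p,
        rho_bc_vs_selection=rho_bs,
        p_bc_vs_selection=p_bs,
        rho_distance_vs_selection=rho_ds,
        p_distance_vs_selection=p_ds,
        rho_distance_vs_bc=rho_db,
        p_distance_vs_bc=p_db,
        **bc_stats,
    )
    return reports, summary


# ---------------------------------------------------------------------------
# reporting


def _fit_row(pid: str, fit: HMMFit, bc: float | None, first: bool) -> dict:
    theta = fit.modes_theta
    return {
        "patient_id": pid,
        "model": fit.K,
        "theta1": round(float(theta[0]), 2),
        "theta2": round(float(theta[1]), 2) if fit.K == 2 else np.nan,
        "mode_distance": (
            round(float(fit.mode_distance), 2) if fit.K == 2 else np.nan
        ),
        "logl": round(fit.logl, 2),
        "aic": round(fit.aic, 2),
        "bic": round(fit.bic, 2),
        "nfree": fit.nfree,
        "bc": round(bc, 2) if (first and bc is not None) else np.nan,
    }


def table2_report(
    reports: Sequence[PatientReport],
    patient_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Goodness-of-fit table: one row per patient per model, 2 decimals.

    Columns follow the published layout: state means (Theta), their
    distance, log-likelihood, AIC, BIC, number of free parameters, BC (shown
    on the patient's first row). Both the 1- and the 2-state fits must be
    present for every requested patient.
    """
    by_id = {r.patient_id: r for r in reports}
    if patient_ids is None:
        patient_ids = [r.patient_id for r in reports]
    rows = []
    for pid in patient_ids:
        if pid not in by_id:
            raise ValidationError(f"no report for patient {pid!r}")
        r = by_id[pid]
        if r.comparison.fit_1state is None or r.comparison.fit_2state is None:
            raise ValidationError("both the 1- and 2-state fits are required")
        rows.append(_fit_row(pid, r.comparison.fit_1state, r.bc, True))
        rows.append(_fit_row(pid, r.comparison.fit_2state, r.bc, False))
    return pd.DataFrame(rows)


def select_percentile_cases(
    reports: Sequence[PatientReport],
    percentiles: Sequence[float] = PERCENTILES,
) -> list[str]:
    """Patients at given percentiles of the BC distribution (defined BCs).

    Mirrors the illustrative case-selection scheme: one case at each
    requested percentile, ordered by BC.
    """
    defined = sorted(
        (r for r in reports if r.bc is not None), key=lambda r: (r.bc, r.patient_id)
    )
    if not defined:
        raise ValidationError("no patients with a defined BC")
    n = len(defined)
    ids = []
    for q in percentiles:
        idx = int(np.clip(round(q / 100.0 * (n - 1)), 0, n - 1))
        ids.append(defined[idx].patient_id)
    return ids


def symptom_histogram(series: SymptomSeries) -> np.ndarray:
    """Counts of weeks at each symptom level 0..trials_m (one bin per level)."""
    return np.bincount(series.counts, minlength=series.trials_m + 1)


def render_patient_figure(
    series: SymptomSeries,
    report: PatientReport | None,
    path: str | Path,
) -> Path:
    """Side-by-side weekly time-series plot and count histogram.

    The y-axis spans the full 0..trials_m scale; the histogram has one bin
    per count value and is annotated with the patient's BC (or marked
    undefined for constant series).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = series.trials_m
    fig, (ax_ts, ax_hist) = plt.subplots(
        1, 2, figsize=(9, 3), gridspec_kw={"width_ratios": [2.2, 1]}
    )
    ax_ts.plot(series.weeks, series.counts, lw=0.9, color="0.2")
    ax_ts.set_xlabel("week")
    ax_ts.set_ylabel("symptoms")
    ax_ts.set_ylim(-0.4, m + 0.4)
    ax_ts.set_title(str(series.patient_id))

    ax_hist.hist(
        series.counts, bins=np.arange(-0.5, m + 1.5), color="0.5", edgecolor="white"
    )
    ax_hist.set_xlabel("symptoms")
    ax_hist.set_ylabel("weeks")
    if report is not None and report.bc is not None:
        ax_hist.set_title(f"BC = {report.bc:.2f}")
    else:
        ax_hist.set_title("BC undefined")
    fig.tight_layout()
    path = Path(path)
    try:
        fig.savefig(path, dpi=120)
    except OSError as exc:
        raise OSError(f"cannot write figure to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# tabular exports


def bc_results_frame(reports: Sequence[PatientReport]) -> pd.DataFrame:
    """Per-patient BC results: patient_id,n,skewness,excess_kurtosis,C,BC,label."""
    rows = []
    for r in reports:
        b = r.bc_result
        if b is None:
            rows.append(
                dict(
                    patient_id=r.patient_id,
                    n=np.nan,
                    skewness=np.nan,
                    excess_kurtosis=np.nan,
                    C=np.nan,
                    BC=np.nan,
                    label="undefined (constant series)",
                )
            )
        else:
            rows.append(
                dict(
                    patient_id=r.patient_id,
                    n=b.n,
                    skewness=b.skewness,
                    excess_kurtosis=b.excess_kurtosis,
                    C=b.correction,
                    BC=b.bc,
                    label=b.label,
                )
            )
    return pd.DataFrame(rows)


def hmm_fits_frame(reports: Sequence[PatientReport]) -> pd.DataFrame:
    """Per-patient fit results, one row per model.

    Columns: patient_id,model,theta1,theta2,mode_distance,logl,aic,bic,
    nfree,converged.
    """
    rows = []
    for r in reports:
        for fit in (r.comparison.fit_1state, r.comparison.fit_2state):
            theta = fit.modes_theta
            rows.append(
                dict(
                    patient_id=r.patient_id,
                    model=fit.K,
                    theta1=float(theta[0]),
                    theta2=float(theta[1]) if fit.K == 2 else np.nan,
                    mode_distance=(
                        float(fit.mode_distance) if fit.K == 2 else np.nan
                    ),
                    logl=fit.logl,
                    aic=fit.aic,
                    bic=fit.bic,
                    nfree=fit.nfree,
                    converged=fit.converged,
                )
            )
    return pd.DataFrame(rows)


def patient_reports_frame(reports: Sequence[PatientReport]) -> pd.DataFrame:
    """Combined per-patient report (BC + model comparison key quantities)."""
    rows = []
    for r in reports:
        b = r.bc_result
        rows.append(
            dict(
                patient_id=r.patient_id,
                BC=np.nan if b is None else b.bc,
                bc_label="undefined" if b is None else b.label,
                selected_K=r.selected_K,
                delta_bic=r.comparison.delta_bic,
                theta1=float(r.comparison.fit_2state.modes_theta[0]),
                theta2=float(r.comparison.fit_2state.modes_theta[1]),
                mode_distance=r.mode_distance,
                stay1=float(r.stay_probabilities[0]),
                stay2=float(r.stay_probabilities[1]),
                bic_1state=r.comparison.fit_1state.bic,
                bic_2state=r.comparison.fit_2state.bic,
                converged_2state=r.comparison.fit_2state.converged,
            )
        )
    return pd.DataFrame(rows)


def cohort_summary_frame(summary: CohortSummary) -> pd.DataFrame:
    """One-row frame of the cohort summary (None rendered as NaN)."""
    d = {k: (np.nan if v is None else v) for k, v in vars(summary).items()}
    return pd.DataFrame([d])
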