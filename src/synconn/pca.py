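"""PCA over the panel of per-subject global network metrics.

The metric panel stacks the six grid-averaged functional metrics and the six
structural ones (12 columns) for every subject. Components come from the
eigendecomposition of the correlation matrix of the standardized panel
(unrotated); component scores are then residualized for covariates (head
motion, age) and associated with diagnosis, age and symptom severity.

Component signs are arbitrary in PCA; here each loading vector is flipped so
its largest-magnitude entry is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import DataError
from .groupstats import bh_fdr, two_sample_t

__all__ = ["MetricPanel", "PcaResult", "fit_pca", "residualize", "associate_components"]

PANEL_COLUMNS = tuple(
    f"{mod}_{m}"
    for mod in ("functional", "structural")
    for m in ("cc", "cpl", "lambda", "gamma", "small_worldness", "q")
)


@dataclass(frozen=True)
class MetricPanel:
    """Subjects x metrics table with no missing cells."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.isna().any().any():
            raise DataError("metric panel must have no missing cells")
        if df.shape[0] < 3:
            raise DataError("metric panel needs at least 3 subjects")
        object.__setattr__(self, "data", df.astype(float))

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def standardized(self) -> pd.DataFrame:
        sd = self.data.std(axis=0, ddof=1)
        flat = sd[sd == 0].index.tolist()
        if flat:
            raise DataError(f"metric(s) constant across subjects: {flat}")
        return (self.data - self.data.mean(axis=0)) / sd


@dataclass(frozen=True)
class PcaResult:
    """Loadings (metrics x components), scores (subjects x components),
    variance fractions and eigenvalues of the metric correlation matrix.

    ``loadings`` columns are unit-norm eigenvectors; ``scores`` are the
    standardized panel projected on them, so score variance per component
    equals the eigenvalue.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(panel: MetricPanel) -> PcaResult:
    """Unrotated PCA of the metric correlation matrix.

    Deterministic up to component sign, which is fixed by making each
    component's largest-magnitude loading positive.
    """
    z = panel.standardized()
    if panel.n_subjects <= z.shape[1]:
        # rank-deficient correlation matrices still decompose; note for the caller
        pass
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    comp = [f"PC{i + 1}" for i in range(evecs.shape[1])]
    loadings = pd.DataFrame(evecs, index=z.columns, columns=comp)
    scores = pd.DataFrame(z.to_numpy() @ evecs, index=z.index, columns=comp)
    return PcaResult(
        loadings=loadings,
        scores=scores,
        variance_explained=evals / evals.sum(),
        eigenvalues=evals,
    )


def residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of ``values`` on covariates (intercept added).

    ``values`` may be 1-D or subjects x variables; the covariate matrix must
    be full rank once the intercept is included.
    """
    y = np.asarray(values, dtype=float)
    flat = y.ndim == 1
    y = y[:, None] if flat else y
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != y.shape[0]:
        c = c.T
    if c.shape[0] != y.shape[0]:
        raise DataError("covariates must have one row per observation")
    x = np.column_stack([np.ones(y.shape[0]), c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DataError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return resid[:, 0] if flat else resid


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def associate_components(
    result: PcaResult,
    phenotypes: pd.DataFrame,
    which: str,
    n_components: int = 4,
    fdr_q: float = 0.05,
    group_column: str = "group",
    asd_label: str = "ASD-like",
    severity_columns: tuple[str, ...] = ("ados_social", "ados_comm", "adi_social", "adi_comm"),
) -> pd.DataFrame:
    """Associate component scores with diagnosis, age or symptom severity.

    diagnosis: two-sample t-test (and group regression coefficient) on
    motion-residualized scores.  age: Pearson r of motion-residualized
    scores vs age, pooled and per group.  severity: Pearson r of motion- and
    age-residualized scores vs each severity subscale within the ASD-like
    group (subjects missing a subscale are dropped for that test).
    FDR correction is applied across each tested family.
    """
    if n_components < 1 or n_components > result.n_components:
        raise DataError("n_components out of range")
    ph = phenotypes.reset_index(drop=True)
    scores = result.scores.reset_index(drop=True)
    if len(ph) != len(scores):
        raise DataError("phenotype table and scores must align one row per subject")
    comp_cols = list(scores.columns[:n_components])
    motion = ph["mean_motion"].to_numpy()
    rows = []
    if which == "diagnosis":
        resid = residualize(scores[comp_cols].to_numpy(), motion)
        is_b = (ph[group_column] == asd_label).to_numpy()
        x = np.column_stack([np.ones(len(ph)), is_b.astype(float), motion])
        for k, comp in enumerate(comp_cols):
            t, p, _ = two_sample_t(resid[~is_b, k][:, None], resid[is_b, k][:, None])
            beta, *_ = np.linalg.lstsq(x, scores[comp].to_numpy(), rcond=None)
            rows.append(
                {"component": comp, "statistic": float(t[0]), "b": float(beta[1]), "p": float(p[0])}
            )
    elif which == "age":
        resid = residualize(scores[comp_cols].to_numpy(), motion)
        age = ph["age"].to_numpy()
        age_r = residualize(age, motion)
        for k, comp in enumerate(comp_cols):
            r, p = _pearson(resid[:, k], age_r)
            rows.append({"component": comp, "statistic": r, "p": p})
    elif which == "severity":
        is_b = (ph[group_column] == asd_label).to_numpy()
        for col in severity_columns:
            if col not in ph.columns:
                continue
            ok = is_b & ph[col].notna().to_numpy()
            if ok.sum() < 4:
                continue
            cov = np.column_stack([motion[ok], ph.loc[ok, "age"].to_numpy()])
            sev = residualize(ph.loc[ok, col].to_numpy(), cov)
            sc = residualize(scores.loc[ok, comp_cols].to_numpy(), cov)
            for k, comp in enumerate(comp_cols):
                r, p = _pearson(sc[:, k], sev)
                rows.append({"component": comp, "subscale": col, "statistic": r, "p": p})
    else:
        raise DataError('which must be "diagnosis", "age" or "severity"')
    out = pd.DataFrame(rows)
    if len(out):
        out["significant_fdr"] = bh_fdr(out["p"].to_numpy(), q=fdr_q)
    return out
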