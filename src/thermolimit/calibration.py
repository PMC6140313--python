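"""Calibration of (v_thresh, w) by exhaustive grid search.

Neither detector parameter is identifiable from a single trace: the pair is
chosen by scoring every candidate combination with the variance in T_imm
explained (R-squared) by the experimental covariates — acclimation treatment
as a categorical predictor and body size as a continuous one — and taking
the maximising combination. The rationale: detector settings that recover a
biologically meaningful immobilisation time let known drivers of thermal
tolerance explain T_imm well, while settings dominated by tracking noise do
not.

Coefficient p-values are reported per cell without any multiple-testing
adjustment across the grid: the grid is a calibration objective, not a
family of 5400 hypothesis tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from joblib import Parallel, delayed

from .data import Dataset
from .immobility import DetectorParams, first_threshold_crossing, moving_median

logger = logging.getLogger(__name__)

CensorPolicy = Literal["end_of_record", "exclude"]
ModelForm = Literal["additive", "interactive"]


@dataclass(frozen=True)
class GridSpec:
    """The (v_thresh, w) calibration grid."""

    v_thresh_values: tuple[float, ...]
    w_values: tuple[int, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.v_thresh_values, dtype=float)
        w = np.asarray(self.w_values)
        if v.size == 0 or w.size == 0:
            raise ValueError("grid must be non-empty")
        if (v <= 0).any() or (np.diff(v) <= 0).any():
            raise ValueError("v_thresh_values must be > 0 and strictly increasing")
        if (w < 2).any() or (np.diff(w) <= 0).any() or not np.issubdtype(w.dtype, np.integer):
            raise ValueError("w_values must be integers >= 2, strictly increasing")

    def __len__(self) -> int:
        return len(self.v_thresh_values) * len(self.w_values)

    @classmethod
    def default(cls) -> "GridSpec":
        """The full calibration grid: thresholds 0.01-1.00 mm/s in steps of
        0.01 crossed with window widths 20-1080 observations in steps of 20
        (5400 combinations; 6.67-360 s windows at 3 obs/s)."""
        return cls(
            v_thresh_values=tuple(np.round(np.arange(1, 101) * 0.01, 2)),
            w_values=tuple(range(20, 1081, 20)),
        )

    @classmethod
    def coarse(cls) -> "GridSpec":
        """A 10x9 screening grid spanning the default ranges: thresholds
        roughly log-spaced (the phenomenon lives at low velocity) and window
        widths covering 20-1080 including the commonly used 280."""
        return cls(
            v_thresh_values=(0.01, 0.02, 0.03, 0.05, 0.08, 0.13, 0.22, 0.36, 0.60, 1.00),
            w_values=(20, 60, 140, 280, 420, 560, 700, 840, 1080),
        )


@dataclass(frozen=True)
class ModelSpec:
    """Linear model for T_imm: treatment (categorical) + body size (continuous).

    ``interactive`` additionally includes treatment x size terms. The dummy
    reference level defaults to the lexicographically first treatment label;
    block/run labels are carried through the pipeline but not modelled unless
    ``include_blocks`` is set.
    """

    form: ModelForm = "additive"
    reference_level: str | None = None
    include_blocks: bool = False

    def __post_init__(self) -> None:
        if self.form not in ("additive", "interactive"):
            raise ValueError(f"unknown model form {self.form!r}")


@dataclass(frozen=True)
class FitResult:
    """OLS fit summary: R-squared, per-term estimate/SE/t/p, sizes."""

    r_squared: float
    coefficients: pd.DataFrame
    n_used: int
    dof_resid: int


@dataclass(frozen=True)
class GridCell:
    """One grid point's model fit and bookkeeping.

    ``n_subjects`` counts every scored subject;
    ``n_used + n_excluded_size (+ n_censored if policy is exclude) = n_subjects``.
    """

    v_thresh: float
    w: int
    fit: FitResult | None
    r2_partial_treatment: float
    n_subjects: int
    n_used: int
    n_censored: int
    n_excluded_size: int
    censor_policy: str
    valid: bool
    reason: str = ""

    @property
    def censored_frac(self) -> float:
        return self.n_censored / self.n_subjects if self.n_subjects else float("nan")


def build_design(meta: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix for the calibration model.

    ``meta`` must hold columns ``treatment`` and ``body_size_mm`` (no missing
    sizes — callers exclude and count those rows). Treatment is dummy-coded
    against the reference level; a single-level table yields a valid design
    with no dummies (R-squared then reflects size alone).
    """
    if len(meta) == 0:
        raise ValueError("no subjects available for the design")
    if meta["body_size_mm"].isna().any():
        raise ValueError("design requires body_size_mm for every included subject")
    levels = sorted(meta["treatment"].astype(str).unique())
    ref = spec.reference_level if spec.reference_level is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} not among treatment levels {levels}")
    counts = meta["treatment"].value_counts()
    for lv, n in counts.items():
        if n < 2:
            warnings.warn(f"treatment level {lv!r} has only {n} subject(s)")
    X = pd.DataFrame(index=meta.index)
    X["intercept"] = 1.0
    treat = meta["treatment"].astype(str)
    size = meta["body_size_mm"].astype(float)
    for lv in levels:
        if lv != ref:
            X[f"treatment[{lv}]"] = (treat == lv).astype(float)
    X["body_size_mm"] = size
    if spec.form == "interactive":
        for lv in levels:
            if lv != ref:
                X[f"treatment[{lv}]:body_size_mm"] = X[f"treatment[{lv}]"] * size
    if spec.include_blocks:
        for col in ("block", "run"):
            if col in meta.columns:
                blevels = sorted(meta[col].astype(str).unique())
                for lv in blevels[1:]:
                    X[f"{col}[{lv}]"] = (meta[col].astype(str) == lv).astype(float)
    if len(X) < X.shape[1]:
        raise ValueError(
            f"fewer rows ({len(X)}) than design columns ({X.shape[1]})"
        )
    return X, list(X.columns)


def ols_fit(response: np.ndarray | pd.Series, design: pd.DataFrame) -> FitResult:
    """Ordinary least squares with the usual unbiased residual-variance SEs.

    Rejects a constant response (the objective is undefined when SST = 0) and
    a rank-deficient design (naming the collinear terms).
    """
    y = np.asarray(response, dtype=float)
    if y.shape[0] != design.shape[0]:
        raise ValueError("response and design have different numbers of rows")
    n, k = design.shape
    if n - k < 1:
        raise ValueError("no residual degrees of freedom")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= max(1.0, y.mean() ** 2) * n * 1e-12:
        raise ValueError("degenerate response: T_imm is (numerically) constant")
    Xv = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < k:
        # name the columns whose QR diagonal collapses
        _, R = np.linalg.qr(Xv)
        diag = np.abs(np.diag(R))
        bad = [design.columns[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"rank-deficient design; collinear terms: {bad or 'unidentified'}")
    res = sm.OLS(y, Xv).fit()
    coef = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        },
        index=pd.Index(design.columns, name="term"),
    )
    return FitResult(
        r_squared=float(res.rsquared),
        coefficients=coef,
        n_used=int(n),
        dof_resid=int(res.df_resid),
    )


def _invalid_cell(
    v: float, w: int, reason: str, n_subjects: int, policy: str,
    n_censored: int = 0, n_excluded_size: int = 0,
) -> GridCell:
    return GridCell(
        v_thresh=v, w=w, fit=None, r2_partial_treatment=float("nan"),
        n_subjects=n_subjects, n_used=0, n_censored=n_censored,
        n_excluded_size=n_excluded_size, censor_policy=policy,
        valid=False, reason=reason,
    )


def _cell_from_crossings(
    v: float,
    w: int,
    crossing_idx: np.ndarray,  # float; NaN = censored
    meta: pd.DataFrame,        # indexed by subject_id, aligned with crossings
    lengths: np.ndarray,
    rates: np.ndarray,
    offsets: np.ndarray,
    spec: ModelSpec,
    censor_policy: CensorPolicy,
) -> GridCell:
    n_subjects = len(meta)
    censored = np.isnan(crossing_idx)
    n_censored = int(censored.sum())
    timm = offsets + crossing_idx / rates
    if censor_policy == "end_of_record":
        timm = np.where(censored, offsets + (lengths - 1) / rates, timm)
        keep = np.ones(n_subjects, dtype=bool)
    elif censor_policy == "exclude":
        keep = ~censored
    else:
        raise ValueError(f"unknown censor_policy {censor_policy!r}")
    has_size = ~meta["body_size_mm"].isna().to_numpy()
    n_excluded_size = int((keep & ~has_size).sum())
    keep = keep & has_size
    sub = meta.loc[keep]
    y = timm[keep]
    try:
        X, _ = build_design(sub, spec)
        if len(X) < X.shape[1] + 1:
            raise ValueError("too few usable subjects for the design")
        fit = ols_fit(y, X)
        # treatment's increment over the covariate-only model (partial R^2
        # in the hierarchical sense); 0 when there are no treatment terms
        reduced_cols = [c for c in X.columns if not c.startswith("treatment[")]
        if len(reduced_cols) < X.shape[1]:
            r2_reduced = ols_fit(y, X[reduced_cols]).r_squared
            r2_partial = fit.r_squared - r2_reduced
        else:
            r2_partial = 0.0
    except ValueError as exc:
        return _invalid_cell(
            v, w, str(exc), n_subjects, censor_policy,
            n_censored=n_censored, n_excluded_size=n_excluded_size,
        )
    return GridCell(
        v_thresh=v, w=w, fit=fit, r2_partial_treatment=float(r2_partial),
        n_subjects=n_subjects, n_used=fit.n_used, n_censored=n_censored,
        n_excluded_size=n_excluded_size, censor_policy=censor_policy,
        valid=True,
    )


def _w_column(
    dataset: Dataset,
    w: int,
    v_values: Sequence[float],
    specs: Sequence[ModelSpec],
    censor_policy: CensorPolicy,
    detector: DetectorParams,
) -> list[list[GridCell]]:
    """Evaluate all thresholds for one window width, for each model spec.

    The smoothed series and threshold crossings are computed once per
    subject per ``w`` and shared across thresholds and model forms — a pure
    caching optimisation with bit-identical results to independent
    evaluation. Returns one list of cells per spec.
    """
    meta = dataset.meta_frame()
    lengths = np.array([t.n_samples for t in dataset.tracks], dtype=float)
    rates = np.array([t.sample_rate for t in dataset.tracks], dtype=float)
    offsets = np.array([t.intro_offset_s for t in dataset.tracks], dtype=float)
    n_subjects = len(dataset)
    if w > lengths.min():
        return [
            [
                _invalid_cell(v, w, "window exceeds series", n_subjects, censor_policy)
                for v in v_values
            ]
            for _ in specs
        ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-missing tracks warn once per w otherwise
        smoothed = [
            moving_median(t.velocities, w, detector.alignment, detector.max_missing_frac)
            for t in dataset.tracks
        ]
    columns: list[list[GridCell]] = [[] for _ in specs]
    for v in v_values:
        idx = np.array(
            [
                np.nan if (c := first_threshold_crossing(s, v, detector.crossing_mode)) is None else float(c)
                for s in smoothed
            ]
        )
        for k, spec in enumerate(specs):
            columns[k].append(
                _cell_from_crossings(
                    float(v), int(w), idx, meta, lengths, rates, offsets, spec, censor_policy
                )
            )
    return columns


def evaluate_grid_point(
    dataset: Dataset,
    v_thresh: float,
    w: int,
    spec: ModelSpec | None = None,
    censor_policy: CensorPolicy = "end_of_record",
    detector: DetectorParams | None = None,
) -> GridCell:
    """Score a single (v_thresh, w) combination.

    Runs the detector for every subject, applies the censoring policy
    (``end_of_record`` assigns censored subjects the last recorded time;
    ``exclude`` drops them from the fit — the default keeps them because
    dropping would reward absurd thresholds by filtering out exactly the
    hard-to-immobilise animals), and fits the calibration model. A cell that
    cannot be fit (window longer than a series, degenerate response, too few
    subjects) is returned invalid with a reason, never raised.
    """
    spec = spec or ModelSpec()
    detector = detector or DetectorParams()
    return _w_column(dataset, int(w), [float(v_thresh)], [spec], censor_policy, detector)[0][0]


def grid_search(
    dataset: Dataset,
    grid: GridSpec,
    spec: ModelSpec | Sequence[ModelSpec] | None = None,
    censor_policy: CensorPolicy = "end_of_record",
    detector: DetectorParams | None = None,
    n_jobs: int = 1,
) -> list[GridCell] | list[list[GridCell]]:
    """Evaluate every grid cell; returns cells ordered by (w, v_thresh).

    Cells are independent, so evaluation parallelises over window widths
    (``n_jobs``) with results identical to sequential evaluation. Passing a
    sequence of model specs scores them all against the same detections in
    one pass (one surface per spec, in order) — useful for comparing the
    additive and interactive objectives.
    """
    single = not isinstance(spec, (list, tuple))
    specs = [spec or ModelSpec()] if single else list(spec)
    detector = detector or DetectorParams()
    columns = Parallel(n_jobs=n_jobs)(
        delayed(_w_column)(dataset, int(w), grid.v_thresh_values, specs, censor_policy, detector)
        for w in grid.w_values
    )
    surfaces = [[c for col in columns for c in col[k]] for k in range(len(specs))]
    for cells in surfaces:
        if not any(c.valid for c in cells):
            raise ValueError("grid search produced no valid cell")
        logger.info(
            "grid search: %d cells (%d valid)", len(cells), sum(c.valid for c in cells)
        )
    return surfaces[0] if single else surfaces


def surface_frame(cells: Sequence[GridCell]) -> pd.DataFrame:
    """Machine-readable R-squared surface: one row per grid cell."""
    return pd.DataFrame(
        {
            "v_thresh": [c.v_thresh for c in cells],
            "w": [c.w for c in cells],
            "r_squared": [c.fit.r_squared if c.valid else np.nan for c in cells],
            "r2_partial_treatment": [c.r2_partial_treatment for c in cells],
            "n_used": [c.n_used for c in cells],
            "n_censored": [c.n_censored for c in cells],
            "valid": [c.valid for c in cells],
            "reason": [c.reason for c in cells],
        }
    ).sort_values(["v_thresh", "w"], ignore_index=True)


def select_optimum(
    cells: Sequence[GridCell],
    max_censored_frac: float = 0.1,
    tie_break: str = "narrow",
) -> tuple[float, int, GridCell]:
    """The admissible cell with maximal R-squared.

    Cells whose censored fraction exceeds ``max_censored_frac`` are excluded:
    their T_imm values are mostly truncation artifacts, not signal. Exact
    R-squared ties break to the smaller w then the smaller v_thresh — the
    less-smoothing, more conservative choice.
    """
    if tie_break != "narrow":
        raise ValueError(f"unknown tie_break {tie_break!r}")
    valid = [c for c in cells if c.valid]
    if not valid:
        raise ValueError("no valid grid cell to select from")
    admissible = [c for c in valid if c.censored_frac <= max_censored_frac]
    if not admissible:
        min_frac = min(c.censored_frac for c in valid)
        raise ValueError(
            f"no admissible cell: every valid cell censors more than "
            f"max_censored_frac={max_censored_frac} of subjects "
            f"(minimum censored fraction observed: {min_frac:.3f})"
        )
    best = max(admissible, key=lambda c: (c.fit.r_squared, -c.w, -c.v_thresh))
    logger.info(
        "optimum: v_thresh=%g, w=%d, R^2=%.4f (n_used=%d, censored=%d)",
        best.v_thresh, best.w, best.fit.r_squared, best.n_used, best.n_censored,
    )
    return best.v_thresh, best.w, best
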