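"""Reference-based tissue-of-origin deconvolution by constrained QP.

A sample's window-level methylation is modelled as a non-negative,
sum-to-one mixture of reference cell-type methylomes:

    minimize ||A w - b||^2   s.t.  w >= 0,  sum(w) = 1

after the window-preparation rules: deep mode keeps windows with >= 10
informative bases (Cs + Ts) in every reference, ranks windows by
across-cell-type variance of density and keeps the top 1%, then
binarizes both panel and sample at 0.1 (density < 0.1 -> 0, else 1).
Ultra-low-pass mode marks entries with < 5 informative bases as missing,
drops windows (and rejects samples) that are > 80% missing, keeps the
top 25% most variable windows, imputes remaining gaps by 5-nearest-
neighbour over windows, and binarizes.

`MethylomeDeconvolver` wraps the pipeline in a scikit-learn-style
estimator: fit() takes the reference panel, predict() a sample's window
table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.impute import KNNImputer

from .errors import DataFormatError, NumericalError, UsageError

logger = logging.getLogger(__name__)

BINARIZE_THRESHOLD = 0.1


@dataclass
class ReferenceMethylomePanel:
    """Cell-type x window methylation densities with evidence counts."""

    density: pd.DataFrame  # windows x cell types, values in [0,1] or NaN
    informative: pd.DataFrame  # windows x cell types, Cs+Ts counts

    def __post_init__(self) -> None:
        if list(self.density.columns) != list(self.informative.columns):
            raise DataFormatError("density and informative tables must share cell types")
        if not self.density.index.equals(self.informative.index):
            raise DataFormatError("density and informative tables must share windows")
        if self.density.columns.duplicated().any():
            raise DataFormatError("cell-type names must be unique")

    @property
    def cell_types(self) -> list[str]:
        return list(self.density.columns)

    def to_tsv(self, path: str) -> None:
        out = pd.DataFrame(index=self.density.index)
        for ct in self.cell_types:
            out[f"{ct}.density"] = self.density[ct]
            out[f"{ct}.count"] = self.informative[ct]
        out.to_csv(path, sep="\t", index_label="window")

    @classmethod
    def from_tsv(cls, path: str) -> "ReferenceMethylomePanel":
        df = pd.read_csv(path, sep="\t", index_col="window")
        cts = [c.rsplit(".", 1)[0] for c in df.columns if c.endswith(".density")]
        if not cts:
            raise DataFormatError(f"no '<cell>.density' columns in {path}")
        density = pd.DataFrame({ct: df[f"{ct}.density"] for ct in cts})
        informative = pd.DataFrame({ct: df[f"{ct}.count"] for ct in cts})
        return cls(density=density, informative=informative)


@dataclass
class DeconvolutionProblem:
    """Prepared (binarized) panel matrix and sample vector."""

    A: np.ndarray  # windows x cell types
    b: np.ndarray  # windows
    cell_types: list[str]
    windows: list = field(default_factory=list)
    mode: str = "deep"
    binarized: bool = True


@dataclass
class DeconvolutionResult:
    weights: pd.Series
    residual: float
    n_windows: int


def binarize(values: np.ndarray, threshold: float = BINARIZE_THRESHOLD) -> np.ndarray:
    """Density < threshold -> 0, otherwise 1 (strict less-than)."""
    return np.where(np.asarray(values, float) < threshold, 0.0, 1.0)


def _align(panel: ReferenceMethylomePanel, sample: pd.DataFrame):
    """Align sample windows (index, 'density', 'n_total') to the panel."""
    missing = {"density", "n_total"} - set(sample.columns)
    if missing:
        raise DataFormatError(f"sample window table lacks columns {sorted(missing)}")
    common = panel.density.index.intersection(sample.index)
    if common.empty:
        raise UsageError("panel and sample share no windows")
    return (
        panel.density.loc[common],
        panel.informative.loc[common],
        sample.loc[common, "density"].astype(float),
        sample.loc[common, "n_total"].astype(float),
    )


def prepare_deep(
    panel: ReferenceMethylomePanel,
    sample_windows: pd.DataFrame,
    min_bases: int = 10,
    top_fraction: float = 0.01,
    do_binarize: bool = True,
) -> DeconvolutionProblem:
    """Deep-coverage window preparation.

    Windows must carry >= ``min_bases`` informative bases in every
    reference and be covered in the sample; survivors are ranked by the
    across-cell-type variance of (pre-binarization) density and the top
    ``top_fraction`` retained, then both sides are binarized at 0.1.
    """
    dens, info, s_dens, s_tot = _align(panel, sample_windows)
    keep = (
        (info >= min_bases).all(axis=1)
        & dens.notna().all(axis=1)
        & s_dens.notna()
        & (s_tot > 0)
    )
    dens, s_dens = dens.loc[keep], s_dens.loc[keep]
    n_top = max(1, math.ceil(top_fraction * len(dens)))
    variance = dens.var(axis=1, ddof=0)
    top = variance.sort_values(ascending=False, kind="stable").index[:n_top]
    dens, s_dens = dens.loc[top], s_dens.loc[top]
    if len(dens) < 10:
        raise UsageError(f"only {len(dens)} usable windows after deep-mode filtering")
    A = binarize(dens.to_numpy()) if do_binarize else dens.to_numpy(float)
    b = binarize(s_dens.to_numpy()) if do_binarize else s_dens.to_numpy(float)
    return DeconvolutionProblem(
        A=A, b=b, cell_types=panel.cell_types, windows=list(dens.index),
        mode="deep", binarized=do_binarize,
    )


def prepare_ulp(
    panel: ReferenceMethylomePanel,
    sample_windows: pd.DataFrame,
    k: int = 5,
    min_bases: int = 5,
    top_fraction: float = 0.25,
    max_na_fraction: float = 0.8,
    do_binarize: bool = True,
) -> DeconvolutionProblem:
    """Ultra-low-pass window preparation with KNN imputation.

    Entries with < ``min_bases`` informative bases (reference or cfDNA)
    become NA; windows more than 80% NA are dropped and a sample more
    than 80% NA is rejected; the top 25% most variable surviving windows
    are kept; remaining NAs are imputed by ``k``-nearest-neighbour over
    windows (Euclidean on shared observed entries); both sides are then
    binarized at 0.1.
    """
    dens, info, s_dens, s_tot = _align(panel, sample_windows)
    dens = dens.where(info >= min_bases)
    s_dens = s_dens.where(s_tot >= min_bases)
    if s_dens.isna().mean() > max_na_fraction:
        raise UsageError("insufficient coverage: sample exceeds the NA budget")
    mat = pd.concat([dens, s_dens.rename("__sample__")], axis=1)
    keep = mat.isna().mean(axis=1) <= max_na_fraction
    mat = mat.loc[keep]
    variance = mat.drop(columns="__sample__").var(axis=1, ddof=0)
    n_top = max(1, math.ceil(top_fraction * len(mat)))
    top = variance.sort_values(ascending=False, kind="stable").index[:n_top]
    mat = mat.loc[top]
    if len(mat) < 10:
        raise UsageError(f"only {len(mat)} usable windows after ULP filtering")
    if mat.isna().any().any():
        imputer = KNNImputer(n_neighbors=min(k, max(1, len(mat) - 1)))
        mat = pd.DataFrame(
            imputer.fit_transform(mat), index=mat.index, columns=mat.columns
        )
    s_final = mat["__sample__"].to_numpy(float)
    A_dens = mat.drop(columns="__sample__").to_numpy(float)
    A = binarize(A_dens) if do_binarize else A_dens
    b = binarize(s_final) if do_binarize else s_final
    return DeconvolutionProblem(
        A=A, b=b, cell_types=panel.cell_types, windows=list(mat.index),
        mode="ulp", binarized=do_binarize,
    )


def solve_qp(problem: DeconvolutionProblem) -> DeconvolutionResult:
    """Minimise ||A w - b||^2 over the probability simplex.

    Deterministic SLSQP from the uniform start; the result is clipped
    and renormalised so the weight vector is exactly a probability
    vector.
    """
    A, b = problem.A, problem.b
    n_windows, n_cell = A.shape
    if n_windows < n_cell:
        logger.warning(
            "deconvolution with %d windows for %d cell types is under-determined",
            n_windows, n_cell,
        )
    AtA = A.T @ A
    Atb = A.T @ b

    def objective(w):
        return 0.5 * float(w @ AtA @ w) - float(Atb @ w) + 0.5 * float(b @ b)

    def gradient(w):
        return AtA @ w - Atb

    res = minimize(
        objective,
        np.full(n_cell, 1.0 / n_cell),
        jac=gradient,
        bounds=[(0.0, 1.0)] * n_cell,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    if not res.success and not np.isfinite(res.fun):
        raise NumericalError(f"QP solver failed: {res.message}")
    w = np.clip(res.x, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise NumericalError("QP returned a zero weight vector")
    w /= total
    # duplicate-column identifiability diagnostic
    if n_cell > 1:
        corr = np.corrcoef(A.T)
        dup = np.argwhere(np.triu(np.isclose(corr, 1.0, atol=1e-12), k=1))
        for i, j in dup:
            logger.warning(
                "reference columns %s and %s are identical; only their summed "
                "weight is identifiable", problem.cell_types[i], problem.cell_types[j],
            )
    residual = float(np.linalg.norm(A @ w - b))
    return DeconvolutionResult(
        weights=pd.Series(w, index=problem.cell_types, name="weight"),
        residual=residual,
        n_windows=n_windows,
    )


class MethylomeDeconvolver(BaseEstimator):
    """Estimator wrapper: fit() on a reference panel, predict() weights.

    Parameters follow the preparation rules of the selected ``mode``
    ('deep' or 'ulp'); ``binarize=False`` switches to the real-valued
    diagnostic mode.
    """

    def __init__(self, mode: str = "deep", k: int = 5, binarize: bool = True,
                 top_fraction: float | None = None):
        self.mode = mode
        self.k = k
        self.binarize = binarize
        self.top_fraction = top_fraction

    def fit(self, panel: ReferenceMethylomePanel, y=None) -> "MethylomeDeconvolver":
        if self.mode not in ("deep", "ulp"):
            raise UsageError(f"mode must be 'deep' or 'ulp', got {self.mode!r}")
        self.panel_ = panel
        return self

    def predict(self, sample_windows: pd.DataFrame) -> DeconvolutionResult:
        if not hasattr(self, "panel_"):
            raise UsageError("deconvolver is not fitted; call fit(panel) first")
        top = self.top_fraction
        if self.mode == "deep":
            problem = prepare_deep(
                self.panel_, sample_windows,
                top_fraction=0.01 if top is None else top,
                do_binarize=self.binarize,
            )
        else:
            problem = prepare_ulp(
                self.panel_, sample_windows, k=self.k,
                top_fraction=0.25 if top is None else top,
                do_binarize=self.binarize,
            )
        return solve_qp(problem)
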