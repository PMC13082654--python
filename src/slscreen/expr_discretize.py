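"""Density-based per-sample expression thresholding (zFPKM discretization).

Each RNA-seq sample is reduced to a per-gene activity score in {-1, 0, +1}:

1. a kernel density is estimated on the sample's log2(FPKM > 0) values;
2. a Gaussian ("expression curve", mean mu, s.d. sigma) is least-squares
   fitted to the right half of the main density peak and mirrored;
3. the fitted curve is subtracted from the density and a second Gaussian
   ("inexpression curve", mean mu_i) is fitted to the non-negative residual;
4. log2-FPKM is standardized to zFPKM = (log2(FPKM) - mu) / sigma;
5. genes above zFPKM 0 score +1 (active), genes below
   max(zFPKM(mu_i), -3) score -1 (inactive), genes in between score 0
   (unknown).  FPKM = 0 is unambiguous inexpression and scores -1 directly.

A cross-sample consensus then collapses the per-sample scores of each gene
into one score per gene by a fraction-threshold vote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import gaussian_kde

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "GaussianCurve",
    "DensityFit",
    "load_expression",
    "validate_expression",
    "fit_expression_density",
    "compute_zfpkm",
    "discretize_sample",
    "discretize_matrix",
    "consensus_scores",
]

#: Minimum number of genes with FPKM > 0 required to fit a density.
MIN_NONZERO_GENES = 100

#: zFPKM floor for the inactive threshold.
ZFPKM_FLOOR = -3.0

#: Number of grid points for the density evaluation.
GRID_SIZE = 512

#: Residual mass (relative to total density mass) below which the sample is
#: treated as unimodal and the inexpression curve as absent.
RESIDUAL_MASS_MIN = 0.01


@dataclass(frozen=True)
class GaussianCurve:
    """One fitted Gaussian component: amplitude · exp(−(x−mu)²/2sigma²)."""

    mu: float
    sigma: float
    amplitude: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((x - self.mu) / self.sigma) ** 2)


@dataclass(frozen=True)
class DensityFit:
    """Per-sample density decomposition and the derived zFPKM thresholds.

    ``expression_curve`` carries the mu and sigma used by the zFPKM
    transform.  ``inexpression_curve`` is None for unimodal samples, in
    which case the lower threshold falls back to the −3 zFPKM floor.
    """

    grid: np.ndarray
    density: np.ndarray
    main_peak_location: float
    expression_curve: GaussianCurve
    inexpression_curve: GaussianCurve | None
    lower_threshold_z: float
    expression_threshold_z: float = 0.0

    def zfpkm(self, log2_fpkm):
        return compute_zfpkm(
            log2_fpkm, self.expression_curve.mu, self.expression_curve.sigma
        )


def load_expression(path) -> pd.DataFrame:
    """Read a gene × sample FPKM matrix from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(df)
    return df


def validate_expression(df: pd.DataFrame) -> None:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ConfigurationError(f"duplicate gene ids in expression matrix: {dupes}")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ConfigurationError("expression matrix contains negative FPKM values")
    if (values > 0).sum(axis=0).min() == 0:
        raise ConfigurationError("expression matrix has a sample with no nonzero value")


def compute_zfpkm(log2_fpkm, mu: float, sigma: float):
    """Standardize log2-FPKM by the expression curve: (log2(FPKM) − mu)/sigma."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return (np.asarray(log2_fpkm, dtype=float) - mu) / sigma


def _fit_gaussian(x: np.ndarray, y: np.ndarray, p0) -> GaussianCurve:
    def gauss(x, amplitude, mu, sigma):
        return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    popt, _ = curve_fit(
        gauss,
        x,
        y,
        p0=p0,
        bounds=([0.0, -np.inf, 1e-3], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    amplitude, mu, sigma = popt
    return GaussianCurve(mu=float(mu), sigma=float(sigma), amplitude=float(amplitude))


def fit_expression_density(
    sample_fpkm: np.ndarray, floor_z: float = ZFPKM_FLOOR
) -> DensityFit:
    """Fit expression / inexpression Gaussian curves to one sample's density.

    Zeros are excluded from fitting (they are scored −1 directly).  The main
    peak is the global density maximum, ties broken toward larger log2-FPKM.
    The expression Gaussian is fitted only to grid points at or right of the
    peak; the symmetric curve implied by the fit is then subtracted from the
    density, negative residuals are clipped at zero, and the inexpression
    Gaussian is fitted to the residual.  If the residual carries less than
    1% of the total density mass the sample is treated as unimodal.
    """
    fpkm = np.asarray(sample_fpkm, dtype=float)
    positive = fpkm[fpkm > 0]
    if positive.size < MIN_NONZERO_GENES:
        raise InsufficientDataError(
            f"density fit needs ≥ {MIN_NONZERO_GENES} genes with FPKM > 0, "
            f"got {positive.size}"
        )
    log2_values = np.log2(positive)
    kde = gaussian_kde(log2_values, bw_method="silverman")
    grid = np.linspace(log2_values.min() - 1.0, log2_values.max() + 1.0, GRID_SIZE)
    density = kde(grid)

    # global maximum; ties broken toward the larger log2-FPKM
    peak_idx = int(np.flatnonzero(density == density.max()).max())
    peak_loc = float(grid[peak_idx])

    right = grid >= peak_loc
    sigma0 = max(float(np.std(log2_values)) / 2.0, 0.25)
    expression = _fit_gaussian(
        grid[right], density[right], p0=(float(density[peak_idx]), peak_loc, sigma0)
    )

    residual = np.clip(density - expression(grid), 0.0, None)
    residual_mass = np.trapezoid(residual, grid)
    total_mass = np.trapezoid(density, grid)
    inexpression: GaussianCurve | None = None
    if residual_mass >= RESIDUAL_MASS_MIN * total_mass:
        res_idx = int(np.argmax(residual))
        try:
            candidate = _fit_gaussian(
                grid,
                residual,
                p0=(float(residual[res_idx]), float(grid[res_idx]), sigma0),
            )
        except RuntimeError:
            candidate = None
        # a genuine inexpression curve lies well left of the expression curve;
        # KDE-vs-Gaussian mismatch near the main peak is not a second mode
        if (
            candidate is not None
            and candidate.mu <= expression.mu - 2.0 * expression.sigma
        ):
            inexpression = candidate

    if inexpression is None:
        lower_z = floor_z
    else:
        z_mu_i = (inexpression.mu - expression.mu) / expression.sigma
        lower_z = min(0.0, max(z_mu_i, floor_z))

    return DensityFit(
        grid=grid,
        density=density,
        main_peak_location=peak_loc,
        expression_curve=expression,
        inexpression_curve=inexpression,
        lower_threshold_z=lower_z,
    )


def discretize_sample(sample_fpkm: np.ndarray, fit: DensityFit) -> np.ndarray:
    """Score one sample's genes: −1 inactive, 0 unknown, +1 active.

    FPKM = 0 scores −1 outright.  Otherwise zFPKM strictly above 0 scores
    +1 and zFPKM strictly below the lower threshold scores −1; values at or
    between the thresholds are unknown (0).
    """
    fpkm = np.asarray(sample_fpkm, dtype=float)
    scores = np.zeros(fpkm.shape, dtype=np.int8)
    zero = fpkm == 0
    with np.errstate(divide="ignore"):
        z = fit.zfpkm(np.log2(np.where(zero, 1.0, fpkm)))
    scores[~zero & (z > fit.expression_threshold_z)] = 1
    scores[~zero & (z < fit.lower_threshold_z)] = -1
    scores[zero] = -1
    return scores


def discretize_matrix(
    expression: pd.DataFrame, floor_z: float = ZFPKM_FLOOR
) -> tuple[pd.DataFrame, dict[str, DensityFit]]:
    """Fit and discretize every sample of a gene × sample FPKM matrix."""
    validate_expression(expression)
    fits: dict[str, DensityFit] = {}
    columns = {}
    for sample in expression.columns:
        fit = fit_expression_density(expression[sample].to_numpy(), floor_z)
        fits[sample] = fit
        columns[sample] = discretize_sample(expression[sample].to_numpy(), fit)
    scores = pd.DataFrame(columns, index=expression.index, dtype=np.int8)
    return scores, fits


def consensus_scores(
    scores: pd.DataFrame,
    active_fraction: float = 0.9,
    inactive_fraction: float = 0.9,
) -> pd.Series:
    """Collapse per-sample scores to one consensus score per gene.

    A gene is +1 if it scores +1 in at least ``active_fraction`` of samples,
    −1 if it scores −1 in at least ``inactive_fraction`` of samples, else 0.
    Fractions must exceed 0.5 jointly so the two verdicts cannot both fire.
    """
    for name, frac in (("active_fraction", active_fraction),
                       ("inactive_fraction", inactive_fraction)):
        if not 0.5 <= frac <= 1.0:
            raise ConfigurationError(f"{name} must lie in [0.5, 1], got {frac}")
    values = scores.to_numpy()
    bad = ~np.isin(values, (-1, 0, 1))
    if bad.any():
        raise ConfigurationError("scores must take values in {-1, 0, +1}")
    n = values.shape[1]
    plus = (values == 1).sum(axis=1)
    minus = (values == -1).sum(axis=1)
    consensus = np.zeros(values.shape[0], dtype=np.int8)
    consensus[plus >= active_fraction * n] = 1
    consensus[minus >= inactive_fraction * n] = -1
    if ((plus >= active_fraction * n) & (minus >= inactive_fraction * n)).any():
        raise AssertionError(
            "a gene satisfied both consensus thresholds; fractions must exceed 0.5"
        )
    return pd.Series(consensus, index=scores.index, name="consensus")
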