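"""R2 / R2* / R2' estimation from gradient-echo trains.

The primary estimator is the model-free symmetric-pair ratio

    R2(n dTE) = ln[ S(sTE - n dTE) / S(sTE + n dTE) ] / (2 n dTE)

averaged over a range of pair indices n.  Least-squares alternatives
(nonlinear in the signal domain, ordinary least squares in the log
domain) are provided for comparison; all three agree exactly on
noiseless model data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .echo_model import MS_PER_S, EchoSeries, EchoTrainSpec, SECTION_FID

__all__ = [
    "RateMaps",
    "r2_from_pair",
    "r2_map_pair_average",
    "fit_exponential",
    "fit_loglinear",
    "fit_r2star_fid",
]


@dataclass
class RateMaps:
    """Per-voxel rate estimates (s^-1) plus a validity mask.

    Where ``R2``, ``R2star`` and ``R2prime`` are all present,
    ``R2prime = R2star - R2`` holds by construction.
    """

    R2: np.ndarray | None = None
    R2star: np.ndarray | None = None
    R2prime: np.ndarray | None = None
    valid_mask: np.ndarray | None = None

    def with_r2star(self, R2star: np.ndarray, valid: np.ndarray | None = None) -> "RateMaps":
        """Combine an R2 map with an R2* map into a full rate set."""
        if self.R2 is None:
            raise ValueError("R2 map required before deriving R2prime")
        mask = self.valid_mask if self.valid_mask is not None else np.isfinite(self.R2)
        if valid is not None:
            mask = mask & valid
        return RateMaps(
            R2=self.R2, R2star=R2star, R2prime=R2star - self.R2, valid_mask=mask
        )


def r2_from_pair(S_minus, S_plus, n: int, delta_TE: float):
    """Pair-ratio R2 (s^-1) from one symmetric echo pair.

    ``S_minus``/``S_plus`` are the magnitudes at ``sTE -/+ n*delta_TE``
    (``delta_TE`` in ms).  Scalars raise on non-positive magnitudes;
    array inputs return NaN there (map-level validity is handled by
    :func:`r2_map_pair_average`).
    """
    if n < 1:
        raise ValueError("pair index n must be >= 1")
    S_minus = np.asarray(S_minus, dtype=float)
    S_plus = np.asarray(S_plus, dtype=float)
    scalar = S_minus.ndim == 0 and S_plus.ndim == 0
    if scalar and (S_minus <= 0 or S_plus <= 0):
        raise ValueError("magnitudes must be positive")
    dt_s = 2.0 * n * delta_TE / MS_PER_S
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(
            (S_minus > 0) & (S_plus > 0), np.log(S_minus / S_plus) / dt_s, np.nan
        )
    return float(r2) if scalar else r2


def r2_map_pair_average(
    series: EchoSeries, spec: EchoTrainSpec, n_range=range(6, 12)
) -> RateMaps:
    """Unweighted mean over n of the per-n pair-ratio R2 maps.

    Voxels where any pair member is non-positive or non-finite are
    flagged invalid (NaN in the map, False in ``valid_mask``).
    """
    ns = list(n_range)
    if not ns:
        raise ValueError("n_range must be non-empty")
    missing = [n for n in ns if n not in spec.pair_ns]
    if missing:
        raise ValueError(f"pair indices {missing} not available in echo spec")
    per_n = []
    valid = np.ones(series.values.shape[:-1], dtype=bool)
    for n in ns:
        lo, hi = spec.pair_TEs(n)
        s_minus = series.values[..., series.echo_index(lo)]
        s_plus = series.values[..., series.echo_index(hi)]
        ok = (s_minus > 0) & (s_plus > 0) & np.isfinite(s_minus) & np.isfinite(s_plus)
        valid &= ok
        per_n.append(r2_from_pair(s_minus, s_plus, n, spec.delta_TE_ms))
    r2 = np.mean(per_n, axis=0)
    r2 = np.where(valid, r2, np.nan)
    return RateMaps(R2=r2, valid_mask=valid)


def _se_design(series: EchoSeries, spec: EchoTrainSpec):
    te_s = series.echo_TEs / MS_PER_S
    tau_s = np.abs(series.echo_TEs - spec.sTE_ms) / MS_PER_S
    return te_s, tau_s


def fit_loglinear(series: EchoSeries, spec: EchoTrainSpec):
    """OLS of ln S on {1, -TE, -|TE - sTE|}; exact on noiseless data.

    Returns ``(M0, R2, R2prime)``.  Raises if the design is rank
    deficient (e.g. all echoes on one side of sTE, where TE and
    |TE - sTE| are collinear) or any magnitude is non-positive.
    """
    if series.values.ndim != 1:
        raise ValueError("fit operates on a single-voxel series")
    if series.n_echoes < 4:
        raise ValueError("need at least 4 echoes")
    if np.any(series.values <= 0):
        raise ValueError("non-positive magnitudes cannot be log-fitted")
    te_s, tau_s = _se_design(series, spec)
    X = np.column_stack([np.ones_like(te_s), -te_s, -tau_s])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(
            "rank-deficient design: echoes must span both sides of sTE"
        )
    beta, *_ = np.linalg.lstsq(X, np.log(series.values), rcond=None)
    return float(np.exp(beta[0])), float(beta[1]), float(beta[2])


def fit_exponential(series: EchoSeries, spec: EchoTrainSpec):
    """Bounded nonlinear least squares on S(TE) = M0 exp(-R2 TE - R2'|TE-sTE|).

    Initialised from the log-linear fit; analytic Jacobian; returns
    ``(M0, R2, R2prime)``.
    """
    if series.values.ndim != 1:
        raise ValueError("fit operates on a single-voxel series")
    if series.n_echoes < 4:
        raise ValueError("need at least 4 echoes")
    te_s, tau_s = _se_design(series, spec)
    y = series.values
    try:
        m0_0, r2_0, r2p_0 = fit_loglinear(series, spec)
    except ValueError:
        m0_0, r2_0, r2p_0 = float(np.max(y)), 20.0, 1.0
    x0 = np.array([max(m0_0, 1e-12), max(r2_0, 0.0), max(r2p_0, 0.0)])

    def model(p):
        return p[0] * np.exp(-p[1] * te_s - p[2] * tau_s)

    def resid(p):
        return model(p) - y

    def jac(p):
        s = model(p)
        return np.column_stack([s / p[0], -te_s * s, -tau_s * s])

    sol = least_squares(
        resid,
        x0,
        jac=jac,
        bounds=([1e-12, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"exponential fit did not converge: {sol.message}")
    return float(sol.x[0]), float(sol.x[1]), float(sol.x[2])


def fit_r2star_fid(series: EchoSeries):
    """Log-linear mono-exponential fit of FID echoes -> ``(M0, R2star)``."""
    if series.values.ndim != 1:
        raise ValueError("fit operates on a single-voxel series")
    if np.any(series.section != SECTION_FID):
        raise ValueError("fit_r2star_fid expects FID-section echoes only")
    if series.n_echoes < 2:
        raise ValueError("need at least 2 FID echoes")
    if np.any(series.values <= 0):
        raise ValueError("non-positive magnitudes cannot be log-fitted")
    te_s = series.echo_TEs / MS_PER_S
    X = np.column_stack([np.ones_like(te_s), -te_s])
    beta, *_ = np.linalg.lstsq(X, np.log(series.values), rcond=None)
    return float(np.exp(beta[0])), float(beta[1])


def fit_r2star_fid_map(values: np.ndarray, TEs) -> RateMaps:
    """Vectorised log-linear R2* over a voxel stack (echoes on last axis).

    Negative fitted rates are flagged invalid rather than clamped.
    """
    TEs = np.asarray(TEs, dtype=float)
    te_s = TEs / MS_PER_S
    ok = np.all(values > 0, axis=-1) & np.all(np.isfinite(values), axis=-1)
    logv = np.where(values > 0, np.log(np.where(values > 0, values, 1.0)), 0.0)
    X = np.column_stack([np.ones_like(te_s), -te_s])
    flat = logv.reshape(-1, TEs.shape[0]).T
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    r2star = beta[1].reshape(values.shape[:-1])
    valid = ok & (r2star >= 0)
    return RateMaps(R2star=np.where(valid, r2star, np.nan), valid_mask=valid)
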