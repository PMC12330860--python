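"""White-matter fiber orientation analysis of R2.

Pipeline: select high-FA, high-tract-probability voxels; compute the
angle alpha between each voxel's principal eigenvector (PEV) and B0;
bin voxels per tract by sin^4(alpha) in 0.1-wide bins; fit the
multi-linear model

    R2 = a0 + a1*(d - dbar) + a2*sin^4(alpha) + a3*(d - dbar)*sin^4(alpha)

by ordinary least squares on the binned means, where ``d`` is the
tract's apparent axonal diameter index and ``dbar`` the voxel-count-
weighted mean diameter over the analyzed tracts.  Reduced models (terms
dropped) are compared via R^2 and adjusted R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "VOXEL_TABLE_COLUMNS",
    "BinnedObservation",
    "RegressionResult",
    "validate_voxel_table",
    "compute_alpha",
    "sin4_alpha",
    "select_voxels",
    "compute_dbar",
    "bin_by_sin4",
    "fit_model",
    "model_comparison",
]

#: Canonical column names of the fiber-voxel table (one row per voxel).
VOXEL_TABLE_COLUMNS = (
    "voxel_id",
    "R2",
    "FA",
    "tract_id",
    "tract_prob",
    "pev_x",
    "pev_y",
    "pev_z",
    "diameter_um",
)

DEFAULT_B0 = np.array([0.0, 0.0, 1.0])

N_BINS = 10
BIN_WIDTH = 0.1

ALL_TERMS = ("a1", "a2", "a3")
#: The four model variants compared: sin4-only, diameter-only,
#: diameter + sin4, and the full model with interaction.
MODEL_VARIANTS = (("a2",), ("a1",), ("a1", "a2"), ("a1", "a2", "a3"))


def validate_voxel_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VOXEL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"voxel table missing columns: {missing}")
    pev = table[["pev_x", "pev_y", "pev_z"]].to_numpy(float)
    norms = np.linalg.norm(pev, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("PEV columns must be unit-norm")
    for col, lo, hi in (("FA", 0.0, 1.0), ("tract_prob", 0.0, 1.0)):
        vals = table[col].to_numpy(float)
        if np.any(vals < lo) or np.any(vals > hi):
            raise ValueError(f"{col} must lie in [{lo}, {hi}]")
    if np.any(table["diameter_um"].to_numpy(float) <= 0):
        raise ValueError("diameter_um must be positive")
    return table


def compute_alpha(pev, b0=DEFAULT_B0):
    """Angle (degrees, in [0, 90]) between fiber axis and B0.

    The PEV is an axial datum (sign-ambiguous), so the absolute dot
    product is used: alpha = arccos(|PEV . b0|).  Inputs are normalised;
    ``pev`` may be a single 3-vector or an (n, 3) stack.
    """
    pev = np.asarray(pev, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    b0_norm = np.linalg.norm(b0)
    if b0_norm == 0:
        raise ValueError("b0 must be non-zero")
    single = pev.ndim == 1
    pev = np.atleast_2d(pev)
    norms = np.linalg.norm(pev, axis=1)
    if np.any(norms == 0):
        raise ValueError("PEV must be non-zero")
    cosa = np.abs(pev @ (b0 / b0_norm)) / norms
    alpha = np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0)))
    return float(alpha[0]) if single else alpha


def sin4_alpha(pev, b0=DEFAULT_B0):
    """sin^4 of the fiber-to-B0 angle; the orientation regressor."""
    alpha = np.radians(compute_alpha(pev, b0))
    return np.sin(alpha) ** 4


def select_voxels(
    table: pd.DataFrame, fa_min: float = 0.4, prob_min: float = 0.25
) -> pd.DataFrame:
    """Keep voxels with FA strictly above ``fa_min`` and tract
    probability strictly above ``prob_min``."""
    keep = (table["FA"] > fa_min) & (table["tract_prob"] > prob_min)
    return table.loc[keep].reset_index(drop=True)


def compute_dbar(table: pd.DataFrame) -> float:
    """Mean tract diameter weighted by each tract's voxel count (um)."""
    if len(table) == 0:
        raise ValueError("empty voxel table")
    per_tract = table.groupby("tract_id")["diameter_um"].agg(["first", "size"])
    return float(
        (per_tract["first"] * per_tract["size"]).sum() / per_tract["size"].sum()
    )


@dataclass(frozen=True)
class BinnedObservation:
    """Per-tract, per-sin^4(alpha)-bin summary of R2."""

    tract_id: int
    bin_index: int
    bin_sin4_mean: float
    R2_mean: float
    R2_se: float
    n_members: int
    d: float  # tract diameter index, um


def bin_by_sin4(table: pd.DataFrame, b0=DEFAULT_B0) -> pd.DataFrame:
    """Bin voxels per tract into 10 sin^4(alpha) bins of width 0.1.

    Bins are [0, 0.1), ..., [0.9, 1.0] (upper edge closed on the last
    bin); empty bins are omitted.  Returns one row per (tract, bin) with
    the within-bin mean sin^4(alpha), the R2 mean and standard error,
    the member count and the tract diameter.
    """
    pev = table[["pev_x", "pev_y", "pev_z"]].to_numpy(float)
    s4 = sin4_alpha(pev, b0)
    bin_idx = np.minimum((s4 / BIN_WIDTH).astype(int), N_BINS - 1)
    df = table.assign(_sin4=s4, _bin=bin_idx)
    rows = []
    for (tract, b), grp in df.groupby(["tract_id", "_bin"], sort=True):
        r2 = grp["R2"].to_numpy(float)
        n = len(grp)
        se = float(np.std(r2, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "tract_id": tract,
                "bin_index": int(b),
                "bin_sin4_mean": float(grp["_sin4"].mean()),
                "R2_mean": float(r2.mean()),
                "R2_se": se,
                "n_members": n,
                "d": float(grp["diameter_um"].iloc[0]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tract_id",
            "bin_index",
            "bin_sin4_mean",
            "R2_mean",
            "R2_se",
            "n_members",
            "d",
        ],
    )


@dataclass(frozen=True)
class RegressionResult:
    """One row of the model-comparison table."""

    a0: float
    a1: float | None
    a2: float | None
    a3: float | None
    se: dict = field(repr=False)
    included_terms: tuple
    R2_stat: float
    adjR2_stat: float
    n_obs: int
    d_bar: float

    def coef(self, name: str) -> float | None:
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {
            "a0": self.a0,
            "a1": self.a1,
            "a2": self.a2,
            "a3": self.a3,
            "se": dict(self.se),
            "included_terms": list(self.included_terms),
            "R2_stat": self.R2_stat,
            "adjR2_stat": self.adjR2_stat,
            "n_obs": self.n_obs,
            "d_bar": self.d_bar,
        }


def _design(obs: pd.DataFrame, d_bar: float, terms) -> tuple[np.ndarray, list]:
    dd = obs["d"].to_numpy(float) - d_bar
    s4 = obs["bin_sin4_mean"].to_numpy(float)
    cols = [np.ones(len(obs))]
    names = ["a0"]
    if "a1" in terms:
        cols.append(dd)
        names.append("a1")
    if "a2" in terms:
        cols.append(s4)
        names.append("a2")
    if "a3" in terms:
        cols.append(dd * s4)
        names.append("a3")
    return np.column_stack(cols), names


def fit_model(
    obs: pd.DataFrame,
    d_bar: float,
    terms=("a1", "a2"),
    weighted: bool = False,
    cov: str = "HC3",
) -> RegressionResult:
    """OLS fit of the (possibly reduced) multi-linear model on binned data.

    ``terms`` selects the free slopes among {a1, a2, a3}; the intercept
    a0 is always included.  Excluded coefficients are reported as None.
    The regressor for orientation is the within-bin mean sin^4(alpha).
    ``weighted=True`` switches to WLS with the bin member counts as
    weights (off by default: binning exists to undo the voxel-count
    weighting toward fibers near 0 and 90 degrees).

    Standard errors are heteroskedasticity-robust (HC3) by default,
    because bin means have variances proportional to 1/n_members and
    the member counts differ widely across bins; ``cov='nonrobust'``
    restores classical OLS standard errors.  Point estimates are
    unaffected by the choice.
    """
    terms = tuple(t for t in ALL_TERMS if t in terms)
    unknown = set(terms) - set(ALL_TERMS)
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}")
    X, names = _design(obs, d_bar, terms)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than free coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design (e.g. single tract with a1)")
    y = obs["R2_mean"].to_numpy(float)
    if weighted:
        model = sm.WLS(y, X, weights=obs["n_members"].to_numpy(float))
    else:
        model = sm.OLS(y, X)
    res = model.fit() if cov == "nonrobust" else model.fit(cov_type=cov)
    coefs = dict(zip(names, res.params))
    ses = dict(zip(names, res.bse))
    return RegressionResult(
        a0=float(coefs["a0"]),
        a1=float(coefs["a1"]) if "a1" in coefs else None,
        a2=float(coefs["a2"]) if "a2" in coefs else None,
        a3=float(coefs["a3"]) if "a3" in coefs else None,
        se={k: float(v) for k, v in ses.items()},
        included_terms=terms,
        R2_stat=float(res.rsquared),
        adjR2_stat=float(res.rsquared_adj),
        n_obs=n,
        d_bar=float(d_bar),
    )


def model_comparison(
    obs: pd.DataFrame, d_bar: float, weighted: bool = False
) -> list[RegressionResult]:
    """Fit the four model variants (sin4-only, d-only, d + sin4, full).

    Nesting guarantees R^2 is non-decreasing from the reduced models to
    the full model; adjusted R^2 may not be.
    """
    return [fit_model(obs, d_bar, terms, weighted=weighted) for terms in MODEL_VARIANTS]


def comparison_table(results: list[RegressionResult]) -> pd.DataFrame:
    """Model-comparison results as a tidy table (one row per variant)."""
    rows = []
    for i, r in enumerate(results, start=1):
        rows.append(
            {
                "fit_no": i,
                "intercept": r.a0,
                "d_minus_dbar": r.a1,
                "sin4_alpha": r.a2,
                "interaction": r.a3,
                "R2_stat": r.R2_stat,
                "adjR2_stat": r.adjR2_stat,
                "n_obs": r.n_obs,
            }
        )
    return pd.DataFrame(rows)
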