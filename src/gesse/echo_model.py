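"""Forward model of the GESFIDE/GESSE magnitude signal.

A single spin echo (SE) refocused at ``sTE`` is sampled by a train of
gradient echoes on both sides of the echo top, preceded by a sampled free
induction decay (FID).  The two-rate mono-exponential model is

    S(TE) = M0 * exp(-R2 * TE - R2' * |TE - sTE|)        (SE sections)
    S(TE) = M0 * exp(-(R2 + R2') * TE)                   (FID section)

Units: relaxation rates are stored in s^-1 and echo times in ms at every
interface; the conversion to seconds happens internally, once, here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EchoTrainSpec",
    "TissueParams",
    "EchoSeries",
    "simulate_se_signal",
    "simulate_fid_signal",
    "add_magnitude_noise",
]

MS_PER_S = 1000.0
_TE_MATCH_TOL_MS = 1e-6

SECTION_FID = "fid"
SECTION_REPHASE = "rephase"
SECTION_DEPHASE = "dephase"


@dataclass(frozen=True)
class EchoTrainSpec:
    """Timing of the three gradient-echo sections of the acquisition.

    ``pair_ns`` lists the integer indices ``n`` for which both
    ``sTE - n*delta_TE`` and ``sTE + n*delta_TE`` are sampled echoes, i.e.
    the symmetric pairs available for the ratio-based R2 estimator.
    """

    sTE_ms: float = 40.0
    delta_TE_ms: float = 1.30
    fid_TEs: tuple[float, ...] = field(default=())
    rephase_TEs: tuple[float, ...] = field(default=())
    dephase_TEs: tuple[float, ...] = field(default=())
    pair_ns: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        for name in ("fid_TEs", "rephase_TEs", "dephase_TEs", "pair_ns"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        for name in ("fid_TEs", "rephase_TEs", "dephase_TEs"):
            tes = getattr(self, name)
            if any(b <= a for a, b in zip(tes, tes[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.fid_TEs and self.rephase_TEs and max(self.fid_TEs) >= min(self.rephase_TEs):
            raise ValueError("FID echoes must precede rephasing echoes")
        if self.rephase_TEs and max(self.rephase_TEs) > self.sTE_ms + _TE_MATCH_TOL_MS:
            raise ValueError("rephasing echoes must not exceed sTE")
        if self.dephase_TEs and min(self.dephase_TEs) < self.sTE_ms - _TE_MATCH_TOL_MS:
            raise ValueError("dephasing echoes must not precede sTE")
        for n in self.pair_ns:
            if n < 1:
                raise ValueError("pair indices must be >= 1")
            lo, hi = self.pair_TEs(n)
            if not _contains(self.rephase_TEs, lo) or not _contains(self.dephase_TEs, hi):
                raise ValueError(f"pair n={n} has no matching rephase/dephase echoes")

    @classmethod
    def default(cls) -> "EchoTrainSpec":
        """Protocol-style timing: sTE 40 ms, 1.30 ms spacing, 6 FID /
        11 rephasing / 30 dephasing echoes, pairs n = 1..11.

        Rephasing and dephasing echoes sit on the literal
        ``sTE +/- n*delta_TE`` grid so that every rephasing echo is
        pairable (the printed per-section ranges are not exactly uniform
        at 1.30 ms; the uniform grid is used here).
        """
        return cls.from_counts()

    @classmethod
    def from_counts(
        cls,
        sTE_ms: float = 40.0,
        delta_TE_ms: float = 1.30,
        n_fid: int = 6,
        n_rephase: int = 11,
        n_dephase: int = 30,
        pair_ns=None,
        fid_start_ms: float = 7.0,
    ) -> "EchoTrainSpec":
        """Build a uniform-grid spec from per-section echo counts.

        Rephasing echoes are ``sTE - n*delta_TE`` for n = n_rephase..1,
        dephasing echoes ``sTE + n*delta_TE`` for n = 0..n_dephase-1.
        """
        if pair_ns is None:
            pair_ns = tuple(range(1, min(n_rephase, n_dephase - 1) + 1))
        return cls(
            sTE_ms=sTE_ms,
            delta_TE_ms=delta_TE_ms,
            fid_TEs=tuple(fid_start_ms + delta_TE_ms * k for k in range(n_fid)),
            rephase_TEs=tuple(sTE_ms - delta_TE_ms * n for n in range(n_rephase, 0, -1)),
            dephase_TEs=tuple(sTE_ms + delta_TE_ms * n for n in range(n_dephase)),
            pair_ns=tuple(pair_ns),
        )

    def pair_TEs(self, n: int) -> tuple[float, float]:
        """Echo times (ms) of the symmetric pair with index ``n``."""
        return (self.sTE_ms - n * self.delta_TE_ms, self.sTE_ms + n * self.delta_TE_ms)

    @property
    def se_TEs(self) -> tuple[float, ...]:
        """All echo times in the spin-echo (rephase + dephase) sections."""
        return self.rephase_TEs + self.dephase_TEs

    def section_of(self, TE: float) -> str:
        if _contains(self.fid_TEs, TE):
            return SECTION_FID
        if _contains(self.rephase_TEs, TE):
            return SECTION_REPHASE
        if _contains(self.dephase_TEs, TE):
            return SECTION_DEPHASE
        raise ValueError(f"TE={TE} ms is not an echo of this spec")

    def to_dict(self) -> dict:
        return {
            "sTE_ms": self.sTE_ms,
            "delta_TE_ms": self.delta_TE_ms,
            "fid_TEs": list(self.fid_TEs),
            "rephase_TEs": list(self.rephase_TEs),
            "dephase_TEs": list(self.dephase_TEs),
            "pair_ns": list(self.pair_ns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EchoTrainSpec":
        """Accepts either explicit TE lists or a counts-based schema
        (keys sTE_ms, delta_TE_ms, n_fid, n_rephase, n_dephase, pair_ns)."""
        if "n_fid" in d:
            return cls.from_counts(
                sTE_ms=float(d.get("sTE_ms", 40.0)),
                delta_TE_ms=float(d.get("delta_TE_ms", 1.30)),
                n_fid=int(d["n_fid"]),
                n_rephase=int(d.get("n_rephase", 11)),
                n_dephase=int(d.get("n_dephase", 30)),
                pair_ns=d.get("pair_ns"),
                fid_start_ms=float(d.get("fid_start_ms", 7.0)),
            )
        return cls(
            sTE_ms=float(d["sTE_ms"]),
            delta_TE_ms=float(d["delta_TE_ms"]),
            fid_TEs=tuple(d["fid_TEs"]),
            rephase_TEs=tuple(d["rephase_TEs"]),
            dephase_TEs=tuple(d["dephase_TEs"]),
            pair_ns=tuple(int(n) for n in d["pair_ns"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EchoTrainSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _contains(tes: tuple[float, ...], te: float) -> bool:
    return any(abs(t - te) <= _TE_MATCH_TOL_MS for t in tes)


@dataclass(frozen=True)
class TissueParams:
    """Per-voxel signal parameters; scalars or broadcastable arrays.

    ``M0`` is steady-state signal magnitude (arbitrary units), ``R2`` the
    irreversible and ``R2prime`` the reversible transverse rate, both s^-1.
    """

    M0: np.ndarray | float
    R2: np.ndarray | float
    R2prime: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        for name in ("M0", "R2", "R2prime"):
            val = np.asarray(getattr(self, name), dtype=float)
            if np.any(val < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, val)

    @property
    def R2star(self) -> np.ndarray:
        return self.R2 + self.R2prime


@dataclass
class EchoSeries:
    """Magnitude signal per echo; echoes on the last axis of ``values``."""

    values: np.ndarray
    echo_TEs: np.ndarray
    section: np.ndarray  # str label per echo

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.echo_TEs = np.asarray(self.echo_TEs, dtype=float)
        self.section = np.asarray(self.section)
        if self.values.shape[-1] != self.echo_TEs.shape[0]:
            raise ValueError("values last axis must match number of echo times")
        if self.section.shape[0] != self.echo_TEs.shape[0]:
            raise ValueError("section labels must match number of echo times")

    @property
    def n_echoes(self) -> int:
        return self.echo_TEs.shape[0]

    def echo_index(self, TE: float) -> int:
        idx = np.flatnonzero(np.abs(self.echo_TEs - TE) <= _TE_MATCH_TOL_MS)
        if idx.size == 0:
            raise ValueError(f"TE={TE} ms not present in series")
        return int(idx[0])


def simulate_se_signal(
    tissue: TissueParams, TEs, spec: EchoTrainSpec
) -> EchoSeries:
    """Noiseless GESSE magnitudes at the given spin-echo-section TEs (ms).

    ``S(TE) = M0 exp(-R2*TE - R2'*|TE - sTE|)`` with rates in s^-1; the
    R2' attenuation is identical for the two members of a symmetric pair,
    which is what makes the pair-ratio estimator insensitive to R2'.
    """
    TEs = np.asarray(TEs, dtype=float)
    sections = np.array([spec.section_of(te) for te in TEs])
    if np.any(sections == SECTION_FID):
        raise ValueError("SE model is only valid for rephase/dephase echoes")
    te_s = TEs / MS_PER_S
    tau_s = np.abs(TEs - spec.sTE_ms) / MS_PER_S
    m0 = np.asarray(tissue.M0)[..., None]
    vals = m0 * np.exp(
        -np.asarray(tissue.R2)[..., None] * te_s
        - np.asarray(tissue.R2prime)[..., None] * tau_s
    )
    return EchoSeries(values=vals, echo_TEs=TEs, section=sections)


def simulate_fid_signal(tissue: TissueParams, TEs) -> EchoSeries:
    """Noiseless FID magnitudes: ``S(TE) = M0 exp(-(R2 + R2') * TE)``."""
    TEs = np.asarray(TEs, dtype=float)
    te_s = TEs / MS_PER_S
    vals = np.asarray(tissue.M0)[..., None] * np.exp(
        -np.asarray(tissue.R2star)[..., None] * te_s
    )
    return EchoSeries(
        values=vals, echo_TEs=TEs, section=np.array([SECTION_FID] * TEs.shape[0])
    )


def add_magnitude_noise(
    series: EchoSeries, sigma: float, model: str = "rician", seed: int | None = None
) -> EchoSeries:
    """Return a noisy copy of ``series``.

    ``rician`` takes the magnitude of the signal plus complex Gaussian
    noise with SD ``sigma`` per channel (the distribution of magnitude MR
    data); ``gaussian`` adds real Gaussian noise and clips at zero.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if model not in ("rician", "gaussian"):
        raise ValueError(f"unknown noise model {model!r}")
    if sigma == 0:
        return EchoSeries(series.values.copy(), series.echo_TEs, series.section)
    rng = np.random.default_rng(seed)
    shape = series.values.shape
    if model == "rician":
        real = series.values + rng.normal(0.0, sigma, shape)
        imag = rng.normal(0.0, sigma, shape)
        noisy = np.hypot(real, imag)
    else:
        noisy = np.clip(series.values + rng.normal(0.0, sigma, shape), 0.0, None)
    return EchoSeries(values=noisy, echo_TEs=series.echo_TEs, section=series.section)
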