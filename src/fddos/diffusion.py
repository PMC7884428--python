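"""Semi-infinite frequency-domain photon diffusion model and multi-distance inversion.

In a homogeneous semi-infinite medium probed with an intensity-modulated
source, the AC amplitude and phase of the detected diffuse photon density
wave are, far from the source, linear in source-detector separation ``r``::

    ln(r^2 * AC(r)) = const - alpha * r
    phase(r)        = phi0  + beta  * r

with attenuation and phase slopes

    alpha = sqrt( (3 mua musp / 2) * [ sqrt(1 + (w / (v mua))^2) + 1 ] )
    beta  = sqrt( (3 mua musp / 2) * [ sqrt(1 + (w / (v mua))^2) - 1 ] )

where ``w = 2 pi f`` is the angular modulation frequency and ``v = c/n`` the
speed of light in tissue.  The slopes obey the exact identities

    alpha^2 - beta^2 = 3 mua musp
    alpha * beta     = 3 musp w / (2 v)

which invert in closed form: fitting straight lines to ln(r^2 AC) and phase
versus r yields slope estimates (alpha_hat, beta_hat), and then

    mua  = (w / 2v) * (alpha_hat/beta_hat - beta_hat/alpha_hat)   [primary]
    musp = (alpha_hat^2 - beta_hat^2) / (3 mua)                   [primary]
         = 2 alpha_hat beta_hat v / (3 w)                         [equivalent]

The two musp closed forms are algebraically identical given the mua formula;
both are computed and the first is primary.  A breakdown of multi-distance
linearity (light leak, probe shift) shows up as a depressed R^2 of either
straight-line fit, which is the quality-control signal used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: speed of light in vacuum, cm/s
C_VACUUM_CM_S = 2.99792458e10

#: analysis wavelengths, nm
WAVELENGTHS_NM = (690.0, 725.0, 785.0, 830.0)


class InversionError(ValueError):
    """Raised when a multi-distance frame cannot be inverted at all."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Multi-distance probe: separations, modulation frequency, tissue index."""

    separations_cm: tuple[float, ...] = (1.5, 2.0, 2.5, 3.0)
    modulation_freq_hz: float = 110e6
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        r = np.asarray(self.separations_cm, dtype=float)
        if r.size < 3:
            raise ValueError("need at least 3 source-detector separations")
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("separations must be positive and strictly increasing")
        if self.modulation_freq_hz <= 0:
            raise ValueError("modulation frequency must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def omega(self) -> float:
        """Angular modulation frequency, rad/s."""
        return 2.0 * np.pi * self.modulation_freq_hz

    @property
    def v(self) -> float:
        """Speed of light in tissue, cm/s."""
        return C_VACUUM_CM_S / self.refractive_index


def forward_semiinfinite(mua, musp, geom: ProbeGeometry):
    """Attenuation and phase slopes (alpha, beta) in 1/cm and rad/cm.

    ``mua`` and ``musp`` may be scalars or broadcastable arrays (1/cm).
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if np.any(mua <= 0) or np.any(musp <= 0):
        raise ValueError("optical properties must be positive")
    s = np.sqrt(1.0 + (geom.omega / (geom.v * mua)) ** 2)
    k = 1.5 * mua * musp
    alpha = np.sqrt(k * (s + 1.0))
    beta = np.sqrt(k * (s - 1.0))
    return alpha, beta


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Vectorized OLS of y on x along the last axis -> (slope, intercept, r2)."""
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    dx = x - xm
    dy = y - ym
    sxx = np.sum(dx * dx, axis=-1)
    slope = np.sum(dx * dy, axis=-1) / sxx
    intercept = ym[..., 0] - slope * xm[..., 0]
    resid = dy - slope[..., None] * dx
    ss_res = np.sum(resid * resid, axis=-1)
    ss_tot = np.sum(dy * dy, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return slope, intercept, r2


def invert_slopes(alpha_hat, beta_hat, geom: ProbeGeometry):
    """Closed-form (mua, musp) from fitted slopes; NaN where non-physical."""
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    beta_hat = np.asarray(beta_hat, dtype=float)
    ok = (alpha_hat > 0) & (beta_hat > 0) & (alpha_hat > beta_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        mua = np.where(
            ok,
            (geom.omega / (2.0 * geom.v))
            * (alpha_hat / beta_hat - beta_hat / alpha_hat),
            np.nan,
        )
        musp = np.where(ok, (alpha_hat**2 - beta_hat**2) / (3.0 * mua), np.nan)
    return mua, musp


def musp_alternate(alpha_hat, beta_hat, geom: ProbeGeometry):
    """Equivalent musp closed form 2*alpha*beta*v/(3*omega) (cross-check)."""
    return 2.0 * np.asarray(alpha_hat) * np.asarray(beta_hat) * geom.v / (3.0 * geom.omega)


FRAME_COLUMNS = ["t_s", "wavelength_nm", "separation_cm", "ac", "phase_rad"]


def fit_multidistance(frames: pd.DataFrame, geom: ProbeGeometry) -> pd.DataFrame:
    """Invert raw multi-distance frames to optical properties per timepoint.

    Parameters
    ----------
    frames
        Long-format frame table with columns ``t_s, wavelength_nm,
        separation_cm, ac, phase_rad`` (one row per timepoint, wavelength and
        separation; every (t, wavelength) must carry all separations of
        ``geom``).
    geom
        Probe geometry used for the measurement.

    Returns
    -------
    Wide optical-sample table: ``t_s``, per-wavelength ``mua_*``/``musp_*``
    (1/cm), amplitude/phase fit diagnostics ``r2_amp_*``/``r2_phase_*``, and a
    provisional ``qc_pass`` flag (positive, finite inversion).  Failed frames
    are returned with NaN optics and ``qc_pass=False``, never dropped.
    """
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise ValueError(f"frame table missing columns {missing}")
    if len(frames) == 0:
        raise ValueError("empty frame table")
    if np.any(frames["ac"].to_numpy() <= 0):
        raise InversionError("AC amplitudes must be positive")

    r = np.asarray(geom.separations_cm, dtype=float)
    wide = frames.pivot_table(
        index=["t_s", "wavelength_nm"], columns="separation_cm", sort=True
    )
    ac = wide["ac"].to_numpy()
    phase = wide["phase_rad"].to_numpy()
    if ac.shape[1] != r.size or not np.allclose(wide["ac"].columns.to_numpy(), r):
        raise ValueError("frame separations do not match probe geometry")

    # phases assumed within one 2*pi branch across separations at these
    # geometries; nearest-branch unwrap guards the general case
    phase = np.unwrap(phase, axis=-1)

    y_amp = np.log(r[None, :] ** 2 * ac)
    slope_amp, _, r2_amp = _ols_line(np.broadcast_to(r, y_amp.shape), y_amp)
    slope_ph, _, r2_ph = _ols_line(np.broadcast_to(r, phase.shape), phase)
    alpha_hat = -slope_amp
    beta_hat = slope_ph
    mua, musp = invert_slopes(alpha_hat, beta_hat, geom)

    idx = wide.index.to_frame(index=False)
    out = pd.DataFrame(
        {
            "t_s": idx["t_s"],
            "wavelength_nm": idx["wavelength_nm"],
            "mua": mua,
            "musp": musp,
            "r2_amp": r2_amp,
            "r2_phase": r2_ph,
        }
    )
    table = out.pivot(index="t_s", columns="wavelength_nm")
    cols = {}
    for wl in sorted(out["wavelength_nm"].unique()):
        suffix = f"{int(round(wl))}"
        cols[f"mua_{suffix}"] = table[("mua", wl)]
        cols[f"musp_{suffix}"] = table[("musp", wl)]
        cols[f"r2_amp_{suffix}"] = table[("r2_amp", wl)]
        cols[f"r2_phase_{suffix}"] = table[("r2_phase", wl)]
    optical = pd.DataFrame(cols)
    optical.insert(0, "t_s", table.index.to_numpy(dtype=float))
    optical = optical.reset_index(drop=True)

    mua_cols = [c for c in optical.columns if c.startswith("mua_")]
    musp_cols = [c for c in optical.columns if c.startswith("musp_")]
    finite = (
        optical[mua_cols + musp_cols].notna().all(axis=1)
        & (optical[mua_cols] > 0).all(axis=1)
        & (optical[musp_cols] > 0).all(axis=1)
    )
    optical["qc_pass"] = finite
    return optical


@dataclass
class QCReport:
    """Per-subject quality-control summary from :func:`qc_filter`."""

    n_samples: int
    n_fail: int
    fail_fraction: float
    r2_min: float
    #: epoch name -> fraction of qc-failed samples inside that window
    window_fail_fractions: dict = field(default_factory=dict)
    #: epoch name -> True if the epoch is unusable (>50% failed samples)
    window_excluded: dict = field(default_factory=dict)
    #: subject unusable for CPR-wide analyses (>50% of CPR samples failed)
    subject_excluded: bool = False


def qc_filter(
    optical: pd.DataFrame,
    r2_min: float = 0.97,
    windows: dict[str, tuple[float, float]] | None = None,
    cpr_window: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Finalize qc flags from fit diagnostics and build an exclusion report.

    A sample fails when the worst amplitude/phase R^2 across wavelengths drops
    below ``r2_min`` or its inversion was non-physical.  ``windows`` maps
    epoch names to half-open [start, end) time windows; an epoch is excluded
    for this subject when more than half its samples fail.  ``cpr_window``
    (half-open) drives the subject-level exclusion decision.
    """
    out = optical.copy()
    r2_cols = [c for c in out.columns if c.startswith(("r2_amp_", "r2_phase_"))]
    diag_ok = out[r2_cols].min(axis=1) >= r2_min if r2_cols else True
    base = out["qc_pass"] if "qc_pass" in out.columns else True
    out["qc_pass"] = np.asarray(base & diag_ok)

    t = out["t_s"].to_numpy()
    fail = ~out["qc_pass"].to_numpy()
    report = QCReport(
        n_samples=len(out),
        n_fail=int(fail.sum()),
        fail_fraction=float(fail.mean()) if len(out) else 0.0,
        r2_min=r2_min,
    )
    for name, (lo, hi) in (windows or {}).items():
        m = (t >= lo) & (t < hi)
        frac = float(fail[m].mean()) if m.any() else 1.0
        report.window_fail_fractions[name] = frac
        report.window_excluded[name] = frac > 0.5
    if cpr_window is not None:
        lo, hi = cpr_window
        m = (t >= lo) & (t < hi)
        frac = float(fail[m].mean()) if m.any() else 1.0
        report.subject_excluded = frac > 0.5
    return out, report
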