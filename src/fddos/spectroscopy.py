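"""Chromophore spectroscopy: scattering power-law fit and hemoglobin solve.

Two per-timepoint reductions of the measured optical properties:

* the reduced scattering spectrum is fit to the empirical Mie power law
  ``musp(lambda) = a * (lambda/500 nm)^(-b)`` for the scattering amplitude
  ``a`` (the fitted musp at 500 nm, 1/cm) and the dimensionless "scattering
  power" ``b``, with an adjusted R^2 goodness-of-fit;
* the absorption spectrum is decomposed into oxy- and deoxy-hemoglobin plus a
  fixed 75% water background,

      mua(lambda) = eps_HbO2(lambda)[HbO2] + eps_Hb(lambda)[Hb]
                    + water_fraction * mua_H2O(lambda),

  solved by ordinary least squares over the (overdetermined) wavelength set.
  Tissue oxygen saturation and total hemoglobin follow as
  StO2 = 100*[HbO2]/([HbO2]+[Hb]) (%) and THC = [HbO2]+[Hb] (umol/L).

Negative concentration solutions are reported and flagged, never clipped:
clipping would bias every downstream change statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .diffusion import WAVELENGTHS_NM

__all__ = [
    "ExtinctionTable",
    "MieFit",
    "fit_mie",
    "fit_mie_series",
    "solve_chromophores",
    "hemodynamics_series",
]


@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction coefficients (1/(cm*uM)) and water absorption (1/cm)."""

    wavelengths_nm: tuple[float, ...]
    eps_hbo2: tuple[float, ...]
    eps_hb: tuple[float, ...]
    mua_water: tuple[float, ...]
    water_fraction: float = 0.75

    def __post_init__(self) -> None:
        n = len(self.wavelengths_nm)
        if not (len(self.eps_hbo2) == len(self.eps_hb) == len(self.mua_water) == n):
            raise ValueError("extinction table columns must have equal length")
        if n < 2:
            raise ValueError("need at least 2 wavelengths to solve 2 chromophores")
        if any(e <= 0 for e in self.eps_hbo2 + self.eps_hb):
            raise ValueError("extinction coefficients must be positive")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError("water_fraction must be in [0, 1]")

    @classmethod
    def from_csv(cls, path, water_fraction: float = 0.75) -> "ExtinctionTable":
        df = pd.read_csv(path, comment="#")
        return cls(
            wavelengths_nm=tuple(df["wavelength_nm"].astype(float)),
            eps_hbo2=tuple(df["eps_hbo2"].astype(float)),
            eps_hb=tuple(df["eps_hb"].astype(float)),
            mua_water=tuple(df["mua_water"].astype(float)),
            water_fraction=water_fraction,
        )

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """The packaged table at 690/725/785/830 nm."""
        with resources.as_file(
            resources.files("fddos.data") / "extinction_table.csv"
        ) as p:
            return cls.from_csv(p)

    def design_matrix(self) -> np.ndarray:
        """(n_wavelengths, 2) matrix of [eps_HbO2, eps_Hb] columns."""
        return np.column_stack([self.eps_hbo2, self.eps_hb])

    def water_term(self) -> np.ndarray:
        return self.water_fraction * np.asarray(self.mua_water)

    def subset(self, wavelengths_nm) -> "ExtinctionTable":
        idx = [self.wavelengths_nm.index(float(w)) for w in wavelengths_nm]
        pick = lambda tup: tuple(tup[i] for i in idx)  # noqa: E731
        return ExtinctionTable(
            pick(self.wavelengths_nm),
            pick(self.eps_hbo2),
            pick(self.eps_hb),
            pick(self.mua_water),
            self.water_fraction,
        )

    def forward(self, hbo2, hb) -> np.ndarray:
        """Forward model: mua per wavelength for concentrations in uM.

        ``hbo2``/``hb`` may be scalars or (n,) arrays; returns (n_wl,) or
        (n, n_wl).
        """
        hbo2 = np.asarray(hbo2, dtype=float)
        hb = np.asarray(hb, dtype=float)
        e = self.design_matrix()
        mua = np.multiply.outer(hbo2, e[:, 0]) + np.multiply.outer(hb, e[:, 1])
        return mua + self.water_term()


@dataclass
class MieFit:
    """Power-law scattering fit result."""

    a: float
    b: float
    adj_r2: float
    converged: bool = True


def _loglog_init(musp: np.ndarray, x: np.ndarray):
    """Log-log OLS line through the scattering spectrum -> (a, b) start."""
    lx = np.log(x)
    ly = np.log(musp)
    lxm = lx.mean()
    slope = ((lx - lxm) * (ly - ly.mean(axis=-1, keepdims=True))).sum(axis=-1) / (
        (lx - lxm) ** 2
    ).sum()
    b = -slope
    a = np.exp(ly.mean(axis=-1) + b * lxm)
    return a, b


def fit_mie_series(
    musp: np.ndarray, wavelengths_nm=WAVELENGTHS_NM, max_iter: int = 50, tol: float = 1e-12
):
    """Vectorized Mie power-law fit of many scattering spectra.

    Parameters
    ----------
    musp
        (n, n_wavelengths) positive reduced scattering coefficients, 1/cm.
    wavelengths_nm
        Wavelength grid matching the columns of ``musp``.

    Returns
    -------
    ``(a, b, adj_r2, converged)`` arrays of shape (n,).  The nonlinear least
    squares runs on the linear scale via Gauss-Newton, initialized from the
    log-log OLS line (the two agree exactly on noise-free power-law spectra).
    Rows that fail to converge fall back to the log-log estimate and are
    flagged.  Adjusted R^2 uses p = 2 free parameters: with n wavelengths,
    adj = 1 - (1 - R^2)(n-1)/(n-p-1).
    """
    musp = np.atleast_2d(np.asarray(musp, dtype=float))
    if np.any(~np.isfinite(musp)) or np.any(musp <= 0):
        raise ValueError("scattering coefficients must be positive and finite")
    wl = np.asarray(wavelengths_nm, dtype=float)
    if musp.shape[1] != wl.size:
        raise ValueError("musp columns must match wavelengths")
    if musp.shape[1] < 2:
        raise ValueError("need >= 2 wavelengths to fit the power law")
    x = wl / 500.0

    a0, b0 = _loglog_init(musp, x)
    a, b = a0.copy(), b0.copy()
    active = np.ones(a.shape, dtype=bool)
    for _ in range(max_iter):
        model = a[:, None] * x[None, :] ** (-b[:, None])
        resid = musp - model
        j_a = x[None, :] ** (-b[:, None])
        j_b = -model * np.log(x)[None, :]
        # 2x2 normal equations, solved in closed form per row
        saa = (j_a * j_a).sum(axis=1)
        sab = (j_a * j_b).sum(axis=1)
        sbb = (j_b * j_b).sum(axis=1)
        ra = (j_a * resid).sum(axis=1)
        rb = (j_b * resid).sum(axis=1)
        det = saa * sbb - sab * sab
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        da = (sbb * ra - sab * rb) / det
        db = (saa * rb - sab * ra) / det
        da = np.where(active & np.isfinite(da), da, 0.0)
        db = np.where(active & np.isfinite(db), db, 0.0)
        a = a + da
        b = b + db
        # keep amplitude physical during iteration
        a = np.maximum(a, 1e-12)
        step = np.maximum(np.abs(da) / np.maximum(np.abs(a), 1e-12), np.abs(db))
        active = step > tol
        if not active.any():
            break
    converged = ~active
    bad = ~converged | ~np.isfinite(a) | ~np.isfinite(b) | (a <= 0)
    a = np.where(bad, a0, a)
    b = np.where(bad, b0, b)
    converged = ~bad

    model = a[:, None] * x[None, :] ** (-b[:, None])
    ss_res = ((musp - model) ** 2).sum(axis=1)
    centered = musp - musp.mean(axis=1, keepdims=True)
    ss_tot = (centered**2).sum(axis=1)
    n = musp.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.where(ss_res <= 1e-20, 1.0, 0.0))
    # adjusted R^2 with p = 2 free parameters needs n > 3 residual dof
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 3) if n > 3 else np.full(r2.shape, np.nan)
    return a, b, adj, converged


def fit_mie(musp, wavelengths_nm=WAVELENGTHS_NM) -> MieFit:
    """Fit one scattering spectrum to ``a (lambda/500)^(-b)``."""
    a, b, adj, conv = fit_mie_series(np.asarray(musp, dtype=float)[None, :], wavelengths_nm)
    return MieFit(a=float(a[0]), b=float(b[0]), adj_r2=float(adj[0]), converged=bool(conv[0]))


def solve_chromophores(mua, ext: ExtinctionTable | None = None) -> pd.DataFrame:
    """Solve hemoglobin concentrations from absorption spectra.

    Parameters
    ----------
    mua
        (n_wavelengths,) or (n, n_wavelengths) absorption coefficients, 1/cm,
        on the wavelength grid of ``ext``.
    ext
        Extinction table; packaged default when omitted.

    Returns
    -------
    DataFrame with ``hbo2_um, hb_um, thc_um, sto2_pct, negative`` per row.
    The water term is subtracted and the linear system solved by OLS.
    StO2 is NaN (and the row flagged) when THC is not positive.
    """
    ext = ext or ExtinctionTable.default()
    mua = np.atleast_2d(np.asarray(mua, dtype=float))
    e = ext.design_matrix()
    if mua.shape[1] != e.shape[0]:
        raise ValueError("mua columns must match extinction table wavelengths")
    if np.linalg.matrix_rank(e) < 2:
        raise ValueError("degenerate extinction table (singular design)")
    rhs = mua - ext.water_term()
    pinv = np.linalg.pinv(e)  # 2 x n_wl
    conc = rhs @ pinv.T
    hbo2, hb = conc[:, 0], conc[:, 1]
    thc = hbo2 + hb
    with np.errstate(divide="ignore", invalid="ignore"):
        sto2 = np.where(thc > 0, 100.0 * hbo2 / thc, np.nan)
    negative = (hbo2 < 0) | (hb < 0) | ~(thc > 0)
    return pd.DataFrame(
        {"hbo2_um": hbo2, "hb_um": hb, "thc_um": thc, "sto2_pct": sto2, "negative": negative}
    )


def hemodynamics_series(
    optical: pd.DataFrame,
    ext: ExtinctionTable | None = None,
    mie: bool = True,
) -> pd.DataFrame:
    """Per-timepoint chromophore solve (and optional Mie fit) of a series.

    ``optical`` is the wide optical-sample table (``t_s``, ``mua_*``,
    ``musp_*``, optional ``qc_pass``).  Output has exactly one row per input
    row; qc-failed or non-finite samples yield NaN hemodynamics and keep
    ``qc_pass=False`` — they are marked, never dropped.
    """
    ext = ext or ExtinctionTable.default()
    wl = [int(round(w)) for w in ext.wavelengths_nm]
    mua_cols = [f"mua_{w}" for w in wl]
    musp_cols = [f"musp_{w}" for w in wl]
    for c in mua_cols:
        if c not in optical.columns:
            raise ValueError(f"optical table missing column {c}")

    n = len(optical)
    qc = (
        optical["qc_pass"].to_numpy(dtype=bool)
        if "qc_pass" in optical.columns
        else np.ones(n, dtype=bool)
    )
    mua = optical[mua_cols].to_numpy(dtype=float)
    valid = qc & np.isfinite(mua).all(axis=1)

    out = pd.DataFrame(
        {
            "t_s": optical["t_s"].to_numpy(dtype=float),
            "hbo2_um": np.nan,
            "hb_um": np.nan,
            "thc_um": np.nan,
            "sto2_pct": np.nan,
            "negative": False,
        }
    )
    if valid.any():
        hemo = solve_chromophores(mua[valid], ext)
        for col in ("hbo2_um", "hb_um", "thc_um", "sto2_pct"):
            out.loc[valid, col] = hemo[col].to_numpy()
        out.loc[valid, "negative"] = hemo["negative"].to_numpy()

    if mie and all(c in optical.columns for c in musp_cols):
        musp = optical[musp_cols].to_numpy(dtype=float)
        mvalid = valid & np.isfinite(musp).all(axis=1) & (musp > 0).all(axis=1)
        out["mie_a"] = np.nan
        out["mie_b"] = np.nan
        out["mie_adj_r2"] = np.nan
        if mvalid.any():
            a, b, adj, _ = fit_mie_series(musp[mvalid], ext.wavelengths_nm)
            out.loc[mvalid, "mie_a"] = a
            out.loc[mvalid, "mie_b"] = b
            out.loc[mvalid, "mie_adj_r2"] = adj
    out["qc_pass"] = valid
    return out
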