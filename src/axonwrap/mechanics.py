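"""Spherical Hertzian contact fitting for AFM force-indentation curves.

The model for a rigid sphere of radius R indenting an elastic half-space of
Young's modulus E and Poisson ratio nu by a depth delta is

    F(delta) = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)

Fits are restricted to shallow indentation (default cutoff 200 nm) where
the half-space assumption holds for micron-scale hydrogel structures.
nu = 0.5 (incompressible hydrogel) is the default and is reported with
every fit.  At a fixed contact point the model is linear in E, so the
modulus is the exact native-scale least-squares solution; when the contact
point is estimated it is profiled out by bounded scalar minimization of
the mean squared residual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar


class FitError(RuntimeError):
    pass


def hertz_force(
    depth: np.ndarray | float, E: float, nu: float, R: float
) -> np.ndarray | float:
    """Closed-form spherical Hertz force (N) at indentation depth (m)."""
    delta = np.maximum(np.asarray(depth, dtype=float), 0.0)
    return (4.0 / 3.0) * E / (1.0 - nu**2) * np.sqrt(R) * delta**1.5


@dataclass
class ForceCurve:
    """One force-indentation approach curve.

    depth in metres (non-decreasing), force in newtons, probe radius in
    metres, cantilever spring constant in N/m.
    """

    depth: np.ndarray
    force: np.ndarray
    probe_radius: float
    spring_constant: float = 0.1
    label: str = ""

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.depth.shape != self.force.shape or self.depth.ndim != 1:
            raise ValueError("depth and force must be 1-D arrays of equal length")
        if len(self.depth) < 10:
            raise ValueError(f"need >= 10 points, got {len(self.depth)}")
        if np.any(np.diff(self.depth) < 0):
            raise ValueError("depth must be non-decreasing")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")


@dataclass
class HertzFit:
    """Result of fitting the spherical Hertz model to one curve."""

    E: float  # Young's modulus, Pa
    nu: float  # Poisson ratio assumed in the fit
    contact_offset: float  # contact-point shift delta_0, m
    depth_cutoff: float  # m
    rms_residual: float  # N
    n_points_used: int
    label: str = ""


def deflection_to_indentation(
    z_piezo: np.ndarray, force: np.ndarray, spring_constant: float
) -> np.ndarray:
    """Convert piezo displacement to indentation: delta = z - F/k."""
    return np.asarray(z_piezo, float) - np.asarray(force, float) / spring_constant


def fit_hertz(
    curve: ForceCurve,
    nu: float = 0.5,
    depth_cutoff: float = 200e-9,
    estimate_contact: bool = False,
) -> HertzFit:
    """Least-squares Hertz fit over delta - delta_0 in (0, depth_cutoff].

    With ``estimate_contact`` the contact point delta_0 is a free parameter
    bounded within the pre-contact region; otherwise delta_0 = 0.  Raises
    :class:`FitError` when fewer than 5 points fall below the cutoff or the
    optimizer fails.
    """
    delta = curve.depth
    force = curve.force
    prefac = (4.0 / 3.0) / (1.0 - nu**2) * np.sqrt(curve.probe_radius)

    def _window(d0: float) -> np.ndarray:
        eff = delta - d0
        return (eff > 0) & (eff <= depth_cutoff)

    if _window(0.0).sum() < 5:
        raise FitError(
            f"only {int(_window(0.0).sum())} points in (0, {depth_cutoff}] — need >= 5"
        )

    def _profiled_fit(d0: float) -> tuple[float, np.ndarray, float] | None:
        """The model is linear in E at fixed contact point: solve it exactly."""
        sel = _window(d0)
        if sel.sum() < 5:
            return None
        g = prefac * (delta[sel] - d0) ** 1.5
        denom = float(g @ g)
        if denom <= 0:
            return None
        e_hat = max(float(g @ force[sel]) / denom, 1e-9)
        resid = g * e_hat - force[sel]
        return e_hat, sel, float(np.mean(resid**2))

    if estimate_contact:
        # profile E out; scan the contact offset over the pre-contact region
        d_hi = min(depth_cutoff, float(np.partition(delta, -5)[-5]) - 1e-15)

        def objective(d0: float) -> float:
            out = _profiled_fit(d0)
            return out[2] if out is not None else np.inf

        res = minimize_scalar(
            objective, bounds=(-depth_cutoff, d_hi), method="bounded",
            options={"xatol": depth_cutoff * 1e-9},
        )
        if not res.success:
            raise FitError(f"contact-point fit did not converge: {res.message}")
        d0_fit = float(res.x)
    else:
        d0_fit = 0.0

    out = _profiled_fit(d0_fit)
    if out is None:
        raise FitError("fewer than 5 points below cutoff after contact shift")
    E_fit, sel, _ = out
    eff = np.clip(delta - d0_fit, 0.0, None)
    residuals = prefac * E_fit * eff[sel] ** 1.5 - force[sel]
    return HertzFit(
        E=float(E_fit),
        nu=nu,
        contact_offset=float(d0_fit),
        depth_cutoff=depth_cutoff,
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
        n_points_used=int(sel.sum()),
        label=curve.label,
    )


def summarize_modulus(fits: list[HertzFit]) -> tuple[float, float, int]:
    """Mean Young's modulus, standard error of the mean, and n over fits."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to summarize")
    E = np.array([f.E for f in fits], dtype=float)
    return float(E.mean()), float(E.std(ddof=1) / np.sqrt(len(E))), len(E)


def load_force_curve(path: str | Path, probe_radius: float | None = None,
                     spring_constant: float | None = None) -> ForceCurve:
    """Read a two-column (depth_m, force_N) CSV/TSV curve.

    A JSON sidecar ``<stem>.json`` may supply ``probe_radius`` and
    ``spring_constant``; explicit arguments override it.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    table = pd.read_csv(path, sep=sep, comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (depth_m, force_N)")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    R = probe_radius if probe_radius is not None else meta.get("probe_radius")
    k = spring_constant if spring_constant is not None else meta.get("spring_constant", 0.1)
    if R is None:
        raise ValueError(f"{path}: probe_radius not given and no sidecar value")
    return ForceCurve(
        depth=table.iloc[:, 0].to_numpy(),
        force=table.iloc[:, 1].to_numpy(),
        probe_radius=float(R),
        spring_constant=float(k),
        label=path.stem,
    )
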