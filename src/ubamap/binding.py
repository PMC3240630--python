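"""Exact 1:1 fast-exchange binding model and global Kd fitting.

Under fast exchange the observed CSP of a residue is the population-weighted
average of its free and bound shifts,

    dsigma_obs = dsigma_max * [PL] / [P]_t,

with the complex concentration from the exact 1:1 quadratic (ligand
depletion included):

    [PL] = (([P]_t + [L]_t + Kd) - sqrt(([P]_t + [L]_t + Kd)**2
            - 4 [P]_t [L]_t)) / 2.

Titrations performed by adding ligand stock into the NMR tube dilute the
protein; total concentrations at each point follow from exact stock/volume
bookkeeping.  A single shared Kd and one saturating amplitude per residue
are fitted to all (residue, point) observations by nonlinear least squares.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .csp import combined_shift
from .peaks import TitrationSeries

logger = logging.getLogger(__name__)

# Kd box constraints during optimisation, in uM, applied on a log10 scale.
KD_BOUNDS_UM = (1e-3, 1e5)


@dataclass
class BindingFit:
    """Result of a global shared-Kd titration fit."""

    kd_uM: float
    kd_se_uM: float
    max_csp: dict[int, float]            # residue -> saturating CSP, ppm
    max_csp_se: dict[int, float]
    residuals: np.ndarray                # ppm, one per (residue, point)
    cost: float
    n_obs: int
    success: bool
    message: str = ""

    def to_json(self) -> str:
        return json.dumps(
            dict(
                kd_uM=self.kd_uM,
                kd_se_uM=self.kd_se_uM,
                max_csp_ppm={str(k): v for k, v in sorted(self.max_csp.items())},
                max_csp_se_ppm={str(k): v for k, v in sorted(self.max_csp_se.items())},
                rms_residual_ppm=float(np.sqrt(np.mean(self.residuals**2))),
                n_obs=self.n_obs,
                success=self.success,
                message=self.message,
            ),
            indent=2,
        )


def titration_concentrations(P0_mM: float, V0_uL: float, stock_mM: float, ratios) -> list[tuple[float, float]]:
    """Total (protein, ligand) concentrations along a titration.

    The i-th point targets a total-ligand to total-protein molar ratio
    ``ratios[i]``.  Because protein and ligand share the sample volume, the
    ratio is independent of dilution and the cumulative added stock volume
    is ``v_i = r_i * P0 * V0 / stock``; then

        [P]_t,i = P0 * V0 / (V0 + v_i),   [L]_t,i = stock * v_i / (V0 + v_i).
    """
    if P0_mM <= 0 or V0_uL <= 0 or stock_mM <= 0:
        raise ValueError("concentrations and volume must be positive")
    if stock_mM <= P0_mM:
        raise ValueError("ligand stock must be more concentrated than the protein")
    out = []
    prev_v = -np.inf
    for r in ratios:
        if r < 0:
            raise ValueError(f"negative molar ratio {r}")
        v = r * P0_mM * V0_uL / stock_mM
        if v < prev_v:
            raise ValueError(f"ratio {r} unreachable: requires removing stock volume")
        prev_v = v
        P_t = P0_mM * V0_uL / (V0_uL + v)
        L_t = stock_mM * v / (V0_uL + v)
        out.append((P_t, L_t))
    return out


def bound_fraction(P_t: float, L_t: float, Kd: float) -> float:
    """Complex concentration [PL] (same units as inputs) for 1:1 binding.

    Uses the numerically stable root of the binding quadratic; satisfies
    0 <= [PL] <= min(P_t, L_t).
    """
    if P_t < 0 or L_t < 0 or Kd < 0:
        raise ValueError("concentrations and Kd must be non-negative")
    s = P_t + L_t + Kd
    disc = s * s - 4.0 * P_t * L_t
    # product form avoids cancellation when s >> sqrt(disc)
    root = np.sqrt(max(disc, 0.0))
    pl = 2.0 * P_t * L_t / (s + root) if (s + root) > 0 else 0.0
    return float(min(pl, min(P_t, L_t)))


def predict_csp(residue_max_csp: float, P_t: float, L_t: float, Kd: float) -> float:
    """Fast-exchange CSP: saturating amplitude times the bound fraction."""
    if P_t <= 0:
        raise ValueError("total protein concentration must be positive")
    return float(residue_max_csp * bound_fraction(P_t, L_t, Kd) / P_t)


def _series_observations(series: TitrationSeries, residues):
    """Extract (P_t, L_t, csp) arrays per residue from a titration series,
    taking the first point as the free reference."""
    ref = series.reference.peaks
    obs = {r: ([], [], []) for r in residues}
    for pt in series.points:
        for (resnum, restype), peak in pt.peaks.items():
            if resnum not in obs or not peak.present:
                continue
            rpeak = ref.get((resnum, restype))
            if rpeak is None:
                continue
            csp = combined_shift(peak.shift_H - rpeak.shift_H, peak.shift_N - rpeak.shift_N)
            obs[resnum][0].append(pt.P_tot_mM)
            obs[resnum][1].append(pt.L_tot_mM)
            obs[resnum][2].append(csp)
    return {r: tuple(np.asarray(v) for v in t) for r, t in obs.items() if len(t[0]) > 0}


def fit_kd(
    series: TitrationSeries,
    residues,
    exclude: set[int] | None = None,
    n_starts: int = 5,
) -> BindingFit:
    """Global shared-Kd fit over selected residues of a titration series.

    Parameters are log10(Kd/uM) plus one saturating CSP per residue.
    Multi-start initialisation over Kd decades guards against local minima.
    Standard errors come from the Gauss-Newton covariance at the optimum.
    """
    exclude = exclude or set()
    residues = [r for r in residues if r not in exclude]
    if len(series) < 3:
        raise ValueError("need at least 3 titration points")
    obs = _series_observations(series, residues)
    if not obs:
        raise ValueError("no usable residues in the series")
    resnums = sorted(obs)
    all_csp = np.concatenate([obs[r][2] for r in resnums])
    if np.allclose(all_csp, 0):
        raise ValueError("all CSPs are zero: no binding signal to fit")
    n_points = max(len(obs[r][2]) for r in resnums)
    n_par = 1 + len(resnums)
    n_obs = int(sum(len(obs[r][2]) for r in resnums))
    if n_obs <= n_par:
        raise ValueError(f"{n_obs} observations cannot constrain {n_par} parameters")

    def residuals(theta):
        kd_mM = 10.0 ** theta[0] / 1000.0
        out = []
        for amp, r in zip(theta[1:], resnums):
            P, L, y = obs[r]
            pred = amp * np.array([bound_fraction(p, l, kd_mM) for p, l in zip(P, L)]) / P
            out.append(pred - y)
        return np.concatenate(out)

    amp0 = np.array([max(obs[r][2][-1], 1e-4) for r in resnums])
    # median total ligand concentration as the natural Kd starting scale
    med_L_uM = float(np.median(np.concatenate([obs[r][1] for r in resnums]))) * 1000.0
    med_L_uM = max(med_L_uM, 1.0)
    starts = np.unique(
        np.clip(
            np.log10(med_L_uM) + np.linspace(-2, 2, n_starts),
            np.log10(KD_BOUNDS_UM[0]),
            np.log10(KD_BOUNDS_UM[1]),
        )
    )
    lo = np.concatenate([[np.log10(KD_BOUNDS_UM[0])], np.zeros(len(resnums))])
    hi = np.concatenate([[np.log10(KD_BOUNDS_UM[1])], np.full(len(resnums), np.inf)])
    best = None
    for s in starts:
        theta0 = np.concatenate([[s], amp0])
        sol = least_squares(residuals, theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError(f"Kd fit failed to converge: {getattr(best, 'message', 'no solution')}")

    kd_uM = 10.0 ** best.x[0]
    dof = max(n_obs - n_par, 1)
    s2 = 2.0 * best.cost / dof
    JTJ = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_par, np.nan)
    kd_se_uM = float(kd_uM * np.log(10) * se[0])
    logger.info("fit_kd: Kd = %.1f +/- %.1f uM over %d residues, %d points", kd_uM, kd_se_uM, len(resnums), n_points)
    return BindingFit(
        kd_uM=float(kd_uM),
        kd_se_uM=kd_se_uM,
        max_csp={r: float(a) for r, a in zip(resnums, best.x[1:])},
        max_csp_se={r: float(e) for r, e in zip(resnums, se[1:])},
        residuals=residuals(best.x),
        cost=float(best.cost),
        n_obs=n_obs,
        success=bool(best.success),
        message=str(best.message),
    )


def fit_kd_per_residue(series: TitrationSeries, residues) -> dict[int, BindingFit]:
    """Diagnostic per-residue Kd fits (one Kd and one amplitude each)."""
    return {r: fit_kd(series, [r]) for r in residues}
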