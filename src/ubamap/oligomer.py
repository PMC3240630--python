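"""Rotational correlation time and monomer-dimer self-association.

The overall tumbling time of a protein is estimated from the backbone 15N
relaxation ratio,

    tau_c = sqrt(6 T1/T2 - 7) / (4 pi omega_N),

with omega_N the 15N resonance frequency in Hz (the approximation is valid
for 6 T1/T2 > 7, i.e. tumbling slower than the extreme-narrowing limit).
tau_c scales roughly linearly with effective molecular mass over small
globular proteins, so a calibration line fitted to monomeric standards
converts tau_c to an apparent mass.

For a self-associating domain with dimer dissociation constant
Kd = [M]^2 / [D] and total chain concentration C = [M] + 2[D], the
monomer concentration is the positive root

    [M] = (-Kd + sqrt(Kd^2 + 8 Kd C)) / 4,

and fast exchange between species makes the observed tau_c the
population-weighted average  (1 - f_D) tau_M + f_D tau_D  with
f_D = 1 - [M]/C the fraction of chains in dimers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import trim_mean

logger = logging.getLogger(__name__)


@dataclass
class RelaxationRecord:
    conc_mM: float
    T1_s: float
    T2_s: float
    tau_c_ns: float | None = None


@dataclass
class RelaxationSeries:
    """Per-concentration 15N relaxation data at a single field."""

    records: list[RelaxationRecord] = field(default_factory=list)
    omega_N_Hz: float = 60.8e6

    def __post_init__(self):
        for r in self.records:
            if r.conc_mM <= 0 or r.T1_s <= 0 or r.T2_s <= 0:
                raise ValueError("concentrations and relaxation times must be positive")

    def concentrations(self) -> np.ndarray:
        return np.array([r.conc_mM for r in self.records])

    def tau_values(self) -> np.ndarray:
        """tau_c per record, computing it from T1/T2 where not stored."""
        return np.array(
            [
                r.tau_c_ns
                if r.tau_c_ns is not None
                else tau_c_from_relaxation(r.T1_s, r.T2_s, self.omega_N_Hz)
                for r in self.records
            ]
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            dict(
                conc_mM=[r.conc_mM for r in self.records],
                T1_s=[r.T1_s for r in self.records],
                T2_s=[r.T2_s for r in self.records],
                tauc_ns=self.tau_values(),
            )
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, omega_N_Hz: float = 60.8e6) -> "RelaxationSeries":
        df = pd.read_csv(path)
        recs = [
            RelaxationRecord(
                conc_mM=float(row["conc_mM"]),
                T1_s=float(row["T1_s"]),
                T2_s=float(row["T2_s"]),
                tau_c_ns=float(row["tauc_ns"]) if "tauc_ns" in df.columns else None,
            )
            for _, row in df.iterrows()
        ]
        return cls(records=recs, omega_N_Hz=omega_N_Hz)


@dataclass
class DimerModel:
    """Monomer-dimer equilibrium with fast-exchange tau_c averaging."""

    kd_dim_uM: float
    tau_M_ns: float
    tau_D_ns: float
    kd_se_uM: float = np.nan
    tau_M_se_ns: float = np.nan
    tau_D_se_ns: float = np.nan

    def __post_init__(self):
        if not (self.tau_D_ns > self.tau_M_ns > 0):
            raise ValueError("require tau_D > tau_M > 0")
        if self.kd_dim_uM <= 0:
            raise ValueError("dimer Kd must be positive")

    def to_json(self) -> str:
        return json.dumps(
            dict(
                kd_dim_uM=self.kd_dim_uM,
                kd_se_uM=self.kd_se_uM,
                tau_M_ns=self.tau_M_ns,
                tau_M_se_ns=self.tau_M_se_ns,
                tau_D_ns=self.tau_D_ns,
                tau_D_se_ns=self.tau_D_se_ns,
            ),
            indent=2,
        )


@dataclass
class CalibrationCurve:
    """Linear tau_c vs molecular-mass calibration from monomeric standards."""

    slope_ns_per_kDa: float
    intercept_ns: float
    mass_range_kDa: tuple[float, float] = (0.0, np.inf)

    def tau_for_mass(self, mass_kDa: float) -> float:
        return self.slope_ns_per_kDa * mass_kDa + self.intercept_ns


def tau_c_from_relaxation(T1_s: float, T2_s: float, omega_N_Hz: float) -> float:
    """Rotational correlation time in ns from the 15N T1/T2 ratio."""
    if T1_s <= 0 or T2_s <= 0 or omega_N_Hz <= 0:
        raise ValueError("T1, T2 and omega_N must be positive")
    arg = 6.0 * T1_s / T2_s - 7.0
    if arg < 0:
        raise ValueError(f"6*T1/T2 = {6 * T1_s / T2_s:.3f} < 7: outside the validity of the tau_c approximation")
    return float(np.sqrt(arg) / (4.0 * np.pi * omega_N_Hz) * 1e9)


def t2_for_tau_c(tau_c_ns: float, T1_s: float, omega_N_Hz: float) -> float:
    """Invert the tau_c formula for T2 at a chosen T1 (round-trip consistent)."""
    if tau_c_ns < 0:
        raise ValueError("tau_c must be non-negative")
    arg = (4.0 * np.pi * omega_N_Hz * tau_c_ns * 1e-9) ** 2
    return float(6.0 * T1_s / (7.0 + arg))


def sample_tau_c(per_residue_tau_ns, trim: float = 0.1) -> float:
    """Aggregate per-residue tau_c values into one per-sample estimate.

    A 10% trimmed mean discards residues with residual internal motion or
    exchange broadening at either tail.
    """
    return float(trim_mean(np.asarray(per_residue_tau_ns, dtype=float), trim))


def fit_calibration(standards) -> CalibrationCurve:
    """Least-squares line tau_c = a*mass + b through (mass_kDa, tau_c_ns) pairs."""
    standards = list(standards)
    if len(standards) < 2:
        raise ValueError("need at least two calibration standards")
    mass = np.array([s[0] for s in standards], dtype=float)
    tau = np.array([s[1] for s in standards], dtype=float)
    if np.ptp(mass) == 0:
        raise ValueError("degenerate calibration: all standards have the same mass")
    slope, intercept = np.polyfit(mass, tau, 1)
    if slope <= 0:
        raise ValueError("calibration slope must be positive (tau_c grows with mass)")
    return CalibrationCurve(
        slope_ns_per_kDa=float(slope),
        intercept_ns=float(intercept),
        mass_range_kDa=(float(mass.min()), float(mass.max())),
    )


def effective_mass(tau_c_ns: float, curve: CalibrationCurve) -> float:
    """Apparent molecular mass (kDa) by inverting the calibration line."""
    if curve.slope_ns_per_kDa == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    mass = (tau_c_ns - curve.intercept_ns) / curve.slope_ns_per_kDa
    lo, hi = curve.mass_range_kDa
    if not (lo <= mass <= hi):
        logger.warning("effective mass %.2f kDa extrapolates beyond calibration range %s", mass, curve.mass_range_kDa)
    return float(mass)


def monomer_concentration(C_mM: float, Kd_dim_mM: float) -> float:
    """Free monomer concentration under Kd = [M]^2/[D], C = [M] + 2[D]."""
    if C_mM <= 0 or Kd_dim_mM <= 0:
        raise ValueError("concentration and Kd must be positive")
    # conjugate form: no cancellation in the dilute limit, ~1e-15 relative error
    return float(2.0 * C_mM / (1.0 + np.sqrt(1.0 + 8.0 * C_mM / Kd_dim_mM)))


def dimer_fraction(C_mM: float, Kd_dim_mM: float) -> float:
    """Fraction of chains incorporated in dimers; in [0, 1]."""
    m = monomer_concentration(C_mM, Kd_dim_mM)
    return float(np.clip(1.0 - m / C_mM, 0.0, 1.0))


def predict_tau(C_mM: float, model: DimerModel) -> float:
    """Population-weighted tau_c at total chain concentration C."""
    f = dimer_fraction(C_mM, model.kd_dim_uM / 1000.0)
    return float((1.0 - f) * model.tau_M_ns + f * model.tau_D_ns)


def fit_dimer_kd(series: RelaxationSeries, n_starts: int = 7) -> DimerModel:
    """Fit (Kd_dim, tau_M, tau_D) to tau_c vs concentration.

    tau_D is parameterised as tau_M plus a positive increment so the
    ordering constraint holds throughout; Kd is fitted on a log10 scale
    with multi-start initialisation across decades.
    """
    C = series.concentrations()
    tau = series.tau_values()
    if len(C) < 4:
        raise ValueError("need at least 4 concentrations")
    if C.max() / C.min() < 5.0:
        raise ValueError("concentration range too narrow (<5-fold) to identify the equilibrium")
    if np.ptp(tau) < 1e-9:
        raise ValueError("tau_c series is flat: monomer-dimer equilibrium unidentifiable")

    def residuals(theta):
        kd_mM = 10.0 ** theta[0]
        tau_M, dtau = theta[1], theta[2]
        f = np.array([dimer_fraction(c, kd_mM) for c in C])
        return (1.0 - f) * tau_M + f * (tau_M + dtau) - tau

    tau_lo, tau_hi = float(tau.min()), float(tau.max())
    best = None
    for log_kd in np.linspace(np.log10(C.min()) - 2, np.log10(C.max()) + 2, n_starts):
        theta0 = [log_kd, tau_lo, max(2.0 * (tau_hi - tau_lo), 0.5)]
        sol = least_squares(
            residuals,
            theta0,
            bounds=([-6, 1e-3, 1e-3], [6, np.inf, np.inf]),
            method="trf",
            xtol=1e-13,
            ftol=1e-13,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError(f"dimer Kd fit failed: {getattr(best, 'message', 'no solution')}")

    kd_mM = 10.0 ** best.x[0]
    dof = max(len(C) - 3, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    kd_se_uM = float(kd_mM * 1000.0 * np.log(10) * se[0])
    tau_D_se = float(np.hypot(se[1], se[2]))
    model = DimerModel(
        kd_dim_uM=float(kd_mM * 1000.0),
        tau_M_ns=float(best.x[1]),
        tau_D_ns=float(best.x[1] + best.x[2]),
        kd_se_uM=kd_se_uM,
        tau_M_se_ns=float(se[1]),
        tau_D_se_ns=tau_D_se,
    )
    logger.info(
        "fit_dimer_kd: Kd = %.0f uM, tau_M = %.2f ns, tau_D = %.2f ns",
        model.kd_dim_uM, model.tau_M_ns, model.tau_D_ns,
    )
    return model
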