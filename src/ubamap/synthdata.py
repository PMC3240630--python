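"""Synthetic ground-truth inputs for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* titrations follow two-state fast exchange with exact ligand depletion
  and stock-dilution bookkeeping, so peak positions move linearly with the
  bound fraction from the 1:1 quadratic;
* concentration-dependent tau_c follows the population-weighted
  monomer-dimer average, back-converted to consistent (T1, T2) pairs;
* toy helical coordinate sets are ideal CA helices with a prescribed
  axis, for exercising the geometry operations against known answers.

Measurement noise is Gaussian and every design carries an explicit RNG
seed, so the same design is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import binding, oligomer
from .peaks import Peak, PeakList, TitrationPoint, TitrationSeries
from .structgeom import StructureModel

# one-letter codes excluding proline (no backbone amide proton)
_AMIDE_TYPES = "ACDEFGHIKLMNQRSTVWY"
_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

# amide spectral window used for free-peak placement (ppm)
H_WINDOW = (7.9, 9.5)
N_WINDOW = (105.0, 130.0)


@dataclass
class TitrationDesign:
    """Ground truth for one CSP titration experiment.

    Default concentrations follow the standard setup for a mono-ubiquitin
    titration: 0.5 mM labelled protein, 5 mM ligand stock, molar ratios
    rising from 0 to 5.5.
    """

    rng_seed: int
    initial_protein_conc_mM: float = 0.5
    initial_volume_uL: float = 500.0
    ligand_stock_mM: float = 5.0
    target_molar_ratios: tuple = tuple(np.round(np.linspace(0.0, 5.5, 10), 6))
    true_kd_uM: float = 249.0
    per_residue_max_csp: dict[int, float] = field(default_factory=dict)
    noise_sigma_H: float = 0.002
    noise_sigma_N: float = 0.01
    # residues whose peaks attenuate with the bound fraction (intermediate
    # exchange at the interface); endpoint intensity falls to 5%
    broadened_residues: tuple = ()

    def __post_init__(self):
        if self.initial_protein_conc_mM <= 0 or self.initial_volume_uL <= 0 or self.ligand_stock_mM <= 0:
            raise ValueError("concentrations and volume must be positive")
        if self.true_kd_uM <= 0:
            raise ValueError("Kd must be positive")
        r = np.asarray(self.target_molar_ratios, dtype=float)
        if len(r) < 2 or r[0] != 0 or np.any(np.diff(r) <= 0):
            raise ValueError("ratios must start at 0 and increase strictly")
        if self.noise_sigma_H < 0 or self.noise_sigma_N < 0:
            raise ValueError("noise sigmas must be non-negative")
        if not self.per_residue_max_csp:
            # 15 residues with saturating CSPs spanning weak to strong response
            rng = np.random.default_rng(self.rng_seed)
            amps = rng.uniform(0.05, 0.7, size=15)
            self.per_residue_max_csp = {400 + i: float(a) for i, a in enumerate(amps)}

    def concentrations(self):
        return binding.titration_concentrations(
            self.initial_protein_conc_mM,
            self.initial_volume_uL,
            self.ligand_stock_mM,
            self.target_molar_ratios,
        )

    def endpoint_bound_fraction(self) -> float:
        P, L = self.concentrations()[-1]
        return binding.bound_fraction(P, L, self.true_kd_uM / 1000.0) / P


def max_csp_for_endpoint(observed_endpoint_csp: float, design: TitrationDesign) -> float:
    """Saturating amplitude that yields a given observed CSP at the final
    titration point of a design (inverts the endpoint bound fraction)."""
    f = design.endpoint_bound_fraction()
    if f <= 0:
        raise ValueError("design never populates the complex")
    return observed_endpoint_csp / f


def diubiquitin_design(rng_seed: int, true_kd_uM: float, **kwargs) -> TitrationDesign:
    """Titration design for a diubiquitin ligand: 2.5 mM stock, ratios to 2.5."""
    kwargs.setdefault("ligand_stock_mM", 2.5)
    kwargs.setdefault("target_molar_ratios", tuple(np.round(np.linspace(0.0, 2.5, 10), 6)))
    return TitrationDesign(rng_seed=rng_seed, true_kd_uM=true_kd_uM, **kwargs)


def gen_titration(design: TitrationDesign) -> TitrationSeries:
    """Simulate a fast-exchange HSQC titration with known ground truth.

    Free peak positions are drawn uniformly from the amide window; each
    residue's perturbation moves along a fixed random direction in the
    scaled (1H, 15N/5) plane with total length max_csp * bound_fraction,
    plus per-point Gaussian noise.  Deterministic given the design seed.
    """
    rng = np.random.default_rng(design.rng_seed)
    residues = sorted(design.per_residue_max_csp)
    free_H = rng.uniform(*H_WINDOW, size=len(residues))
    free_N = rng.uniform(*N_WINDOW, size=len(residues))
    types = rng.choice(list(_AMIDE_TYPES), size=len(residues))
    phi = rng.uniform(0, 2 * np.pi, size=len(residues))
    kd_mM = design.true_kd_uM / 1000.0
    points = []
    for P_t, L_t in design.concentrations():
        peaks = PeakList()
        frac = binding.bound_fraction(P_t, L_t, kd_mM) / P_t
        for i, resnum in enumerate(residues):
            csp = design.per_residue_max_csp[resnum] * frac
            d_H = csp * np.cos(phi[i])
            d_N = 5.0 * csp * np.sin(phi[i])
            intensity = 1.0 - 0.95 * frac if resnum in design.broadened_residues else 1.0
            peaks[(resnum, str(types[i]))] = Peak(
                shift_H=free_H[i] + d_H + rng.normal(0, design.noise_sigma_H),
                shift_N=free_N[i] + d_N + rng.normal(0, design.noise_sigma_N),
                intensity=intensity,
            )
        points.append(TitrationPoint(P_tot_mM=P_t, L_tot_mM=L_t, peaks=peaks))
    return TitrationSeries(points=points)


@dataclass
class RelaxDesign:
    """Ground truth for a concentration-dependent 15N relaxation series.

    Defaults reproduce a weak self-association study: 8 concentrations
    from 0.16 to 1.9 mM, dimer Kd 900 uM, monomer and dimer tumbling
    times of 4.8 and 12.1 ns at a 600 MHz field (15N at 60.8 MHz).
    """

    rng_seed: int
    concentrations_mM: tuple = tuple(np.round(np.geomspace(0.16, 1.9, 8), 4))
    true_kd_dim_uM: float = 900.0
    tau_monomer_ns: float = 4.8
    tau_dimer_ns: float = 12.1
    field_15N_freq_Hz: float = 60.8e6
    noise_sigma_tau_ns: float = 0.1
    base_T1_s: float = 0.5

    def __post_init__(self):
        if not (self.tau_dimer_ns > self.tau_monomer_ns > 0):
            raise ValueError("require tau_dimer > tau_monomer > 0")
        if np.any(np.asarray(self.concentrations_mM) <= 0):
            raise ValueError("concentrations must be positive")
        if self.true_kd_dim_uM <= 0 or self.noise_sigma_tau_ns < 0:
            raise ValueError("invalid Kd or noise sigma")

    def model(self) -> oligomer.DimerModel:
        return oligomer.DimerModel(
            kd_dim_uM=self.true_kd_dim_uM,
            tau_M_ns=self.tau_monomer_ns,
            tau_D_ns=self.tau_dimer_ns,
        )


def gen_relaxation_series(design: RelaxDesign) -> oligomer.RelaxationSeries:
    """Simulate tau_c vs concentration and back-convert to (T1, T2) pairs.

    The noisy population-weighted tau_c is stored both directly and as a
    consistent (T1, T2) pair through the tau_c formula (T1 held at a
    nominal value, T2 solved), so either route through the analysis sees
    the same observable.
    """
    rng = np.random.default_rng(design.rng_seed)
    model = design.model()
    records = []
    for c in design.concentrations_mM:
        tau = oligomer.predict_tau(c, model) + rng.normal(0, design.noise_sigma_tau_ns)
        tau = max(tau, 0.05)
        T2 = oligomer.t2_for_tau_c(tau, design.base_T1_s, design.field_15N_freq_Hz)
        records.append(
            oligomer.RelaxationRecord(conc_mM=float(c), T1_s=design.base_T1_s, T2_s=T2, tau_c_ns=float(tau))
        )
    return oligomer.RelaxationSeries(records=records, omega_N_Hz=design.field_15N_freq_Hz)


# ---------------------------------------------------------------------------
# toy helical coordinates

ALPHA_HELIX = dict(rise=1.5, twist=100.0, radius=2.3)
HELIX_310 = dict(rise=2.0, twist=120.0, radius=1.9)


def _frame(direction: np.ndarray):
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm < 1e-10:
        raise ValueError("degenerate helix direction vector")
    d = d / norm
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, d)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, probe)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return d, u, v


def gen_ideal_helix(
    n_residues: int,
    rise: float = 1.5,
    twist: float = 100.0,
    origin=(0.0, 0.0, 0.0),
    direction=(0.0, 0.0, 1.0),
    radius: float = 2.3,
    chain: str = "A",
    start_resnum: int = 1,
) -> StructureModel:
    """CA-only ideal helix whose fitted axis equals ``direction``.

    Defaults are alpha-helical (1.5 A rise, 100 deg twist per residue);
    pass ``**HELIX_310`` for a 3-10 geometry.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    d, u, v = _frame(direction)
    origin = np.asarray(origin, dtype=float)
    xyz = []
    for i in range(n_residues):
        ang = np.radians(twist * i)
        xyz.append(origin + i * rise * d + radius * (np.cos(ang) * u + np.sin(ang) * v))
    n = n_residues
    return StructureModel(
        serial=np.arange(1, n + 1),
        name=np.full(n, "CA", dtype=object),
        element=np.full(n, "C", dtype=object),
        resnum=np.arange(start_resnum, start_resnum + n),
        restype=np.full(n, "ALA", dtype=object),
        chain=np.full(n, chain, dtype=object),
        xyz=np.asarray(xyz),
        mass=np.full(n, 12.011),
    )


# default helix residue ranges of the three-helix + 3-10 UBA fold
UBA_HELIX_RANGES = {
    "310": range(368, 373),
    "a1": range(375, 382),
    "a2": range(386, 401),
    "a3": range(407, 420),
}


def gen_helix_bundle(pair_angles_deg=(98.0, 138.0, 102.0), separation: float = 10.0) -> StructureModel:
    """Toy four-helix model with prescribed consecutive interhelical angles.

    Helix axes are coplanar unit vectors rotated successively by the
    requested angles, so the directed angle between consecutive helices
    is exactly the prescribed value; segments use the UBA residue ranges
    (3-10: 368-372, a1: 375-381, a2: 386-400, a3: 407-419).
    """
    names = ["310", "a1", "a2", "a3"]
    if len(pair_angles_deg) != len(names) - 1:
        raise ValueError("need one angle per consecutive helix pair")
    cumulative = np.concatenate([[0.0], np.cumsum(pair_angles_deg)])
    directions = [
        np.array([np.sin(np.radians(a)), 0.0, np.cos(np.radians(a))]) for a in cumulative
    ]
    pieces = []
    for k, (nm, d) in enumerate(zip(names, directions)):
        rng = UBA_HELIX_RANGES[nm]
        params = HELIX_310 if nm == "310" else ALPHA_HELIX
        origin = np.array([0.0, k * separation, 0.0])
        pieces.append(
            gen_ideal_helix(
                len(rng),
                origin=origin,
                direction=d,
                start_resnum=rng.start,
                **params,
            )
        )
    xyz = np.vstack([p.xyz for p in pieces])
    return StructureModel(
        serial=np.arange(1, sum(p.n_atoms for p in pieces) + 1),
        name=np.concatenate([p.name for p in pieces]),
        element=np.concatenate([p.element for p in pieces]),
        resnum=np.concatenate([p.resnum for p in pieces]),
        restype=np.concatenate([p.restype for p in pieces]),
        chain=np.concatenate([p.chain for p in pieces]),
        xyz=xyz,
        mass=np.concatenate([p.mass for p in pieces]),
    )
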