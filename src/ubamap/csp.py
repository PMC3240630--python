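"""Chemical shift perturbation (CSP) profiles and significance classes.

The combined backbone amide perturbation for a residue is

    dsigma = sqrt(dsigma_H**2 + (dsigma_N / 5)**2)

where ``dsigma_H`` and ``dsigma_N`` are the 1H and 15N shift changes in
ppm.  Residues are classed relative to the profile mean and standard
deviation: *active* above mean + 1 SD, *passive* between the mean and
mean + 1 SD, *insignificant* below the mean.  Residues whose peaks broaden
out of the spectrum cannot be quantified; they are excluded from the
statistics but treated as interface evidence (classed active), since
broadening marks intermediate exchange at a binding surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import N15_SCALE, PeakList, TitrationSeries

logger = logging.getLogger(__name__)

CLASS_ACTIVE = "active"
CLASS_PASSIVE = "passive"
CLASS_INSIGNIFICANT = "insignificant"
CLASS_EXCLUDED = "excluded"


def combined_shift(d_H: float, d_N: float) -> float:
    """Combined amide CSP in ppm from 1H and 15N shift differences."""
    return float(np.hypot(d_H, d_N / N15_SCALE))


@dataclass
class ResidueCSP:
    residue_type: str
    d_H: float
    d_N: float
    csp: float
    broadened: bool = False
    cls: str = CLASS_INSIGNIFICANT


@dataclass
class CSPProfile:
    """Per-residue combined CSPs plus the profile mean/SD used for classing."""

    residues: dict[int, ResidueCSP] = field(default_factory=dict)
    mean: float = np.nan
    sd: float = np.nan

    def quantified(self) -> dict[int, ResidueCSP]:
        """Residues with a measurable CSP (not broadened out)."""
        return {n: r for n, r in self.residues.items() if not r.broadened}

    def values(self) -> np.ndarray:
        return np.array([r.csp for r in self.quantified().values()])

    def residues_in_class(self, cls: str) -> list[int]:
        return sorted(n for n, r in self.residues.items() if r.cls == cls)

    @property
    def active(self) -> list[int]:
        return self.residues_in_class(CLASS_ACTIVE)

    @property
    def passive(self) -> list[int]:
        return self.residues_in_class(CLASS_PASSIVE)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                residue=n,
                residue_type=r.residue_type,
                dH_ppm=r.d_H,
                dN_ppm=r.d_N,
                csp_ppm=r.csp,
                broadened=r.broadened,
                cls=r.cls,
            )
            for n, r in sorted(self.residues.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CSPProfile":
        df = pd.read_csv(path)
        prof = cls()
        for _, row in df.iterrows():
            prof.residues[int(row["residue"])] = ResidueCSP(
                residue_type=str(row.get("residue_type", "X")),
                d_H=float(row["dH_ppm"]),
                d_N=float(row["dN_ppm"]),
                csp=float(row["csp_ppm"]),
                broadened=bool(row.get("broadened", False)),
                cls=str(row.get("cls", CLASS_INSIGNIFICANT)),
            )
        return _with_stats(prof)


def _with_stats(profile: CSPProfile) -> CSPProfile:
    """Recompute mean/SD over quantified, non-proline residues (ddof=0)."""
    vals = [
        r.csp
        for r in profile.quantified().values()
        if r.residue_type != "P"
    ]
    if vals:
        profile.mean = float(np.mean(vals))
        profile.sd = float(np.std(vals))
    else:
        profile.mean = profile.sd = np.nan
    return profile


def compute_csp(reference: PeakList, endpoint: PeakList) -> CSPProfile:
    """CSP profile between a reference (apo) and an endpoint peak list.

    Residues present in the reference but missing (or flagged absent) at
    the endpoint are marked broadened and carry no CSP value.
    """
    shared = set(reference) & set(endpoint)
    ref_only = set(reference) - set(endpoint)
    if not shared and not ref_only:
        raise ValueError("no shared residues between reference and endpoint")
    profile = CSPProfile()
    for (resnum, restype) in sorted(shared | ref_only):
        ref = reference[(resnum, restype)]
        end = endpoint.get((resnum, restype))
        if end is None or not end.present:
            profile.residues[resnum] = ResidueCSP(
                residue_type=restype, d_H=np.nan, d_N=np.nan, csp=np.nan, broadened=True
            )
            continue
        d_H = end.shift_H - ref.shift_H
        d_N = end.shift_N - ref.shift_N
        profile.residues[resnum] = ResidueCSP(
            residue_type=restype, d_H=d_H, d_N=d_N, csp=combined_shift(d_H, d_N)
        )
    if not profile.quantified():
        raise ValueError("no shared residues could be quantified")
    return _with_stats(profile)


def flag_broadened(series: TitrationSeries, intensity_ratio_threshold: float = 0.2) -> set[int]:
    """Residues whose endpoint intensity falls below the threshold fraction
    of the reference intensity, or which vanish altogether."""
    ref = series.reference.peaks
    end = series.endpoint.peaks
    flagged = set()
    for (resnum, restype), rpeak in ref.items():
        epeak = end.get((resnum, restype))
        if epeak is None or not epeak.present:
            flagged.add(resnum)
            continue
        if rpeak.intensity > 0 and epeak.intensity / rpeak.intensity < intensity_ratio_threshold:
            flagged.add(resnum)
    return flagged


def classify_residues(profile: CSPProfile) -> CSPProfile:
    """Assign active / passive / insignificant classes in place.

    Broadened residues are classed active (interface evidence); excluded
    from the mean/SD.  Idempotent.
    """
    profile = _with_stats(profile)
    hi = profile.mean + profile.sd
    for resnum, r in profile.residues.items():
        if r.broadened:
            r.cls = CLASS_ACTIVE
        elif profile.sd > 0 and r.csp > hi:
            r.cls = CLASS_ACTIVE
        elif profile.sd > 0 and r.csp > profile.mean:
            r.cls = CLASS_PASSIVE
        else:
            r.cls = CLASS_INSIGNIFICANT
    logger.info(
        "classified %d residues: mean=%.4f ppm, sd=%.4f ppm, active=%s, passive=%s",
        len(profile.residues), profile.mean, profile.sd, profile.active, profile.passive,
    )
    return profile


def mutant_activity(wt_profile: CSPProfile, mut_profile: CSPProfile, resonance_set: list[int]) -> float:
    """Relative binding activity of a mutant, in percent.

    100 * avg(CSP_mutant) / avg(CSP_wild-type) over a fixed set of
    well-resolved resonances present and quantified in both profiles.
    """
    for resnum in resonance_set:
        for prof, name in ((wt_profile, "wild-type"), (mut_profile, "mutant")):
            if resnum not in prof.residues or prof.residues[resnum].broadened:
                raise ValueError(f"residue {resnum} not quantified in {name} profile")
    wt = np.mean([wt_profile.residues[n].csp for n in resonance_set])
    mut = np.mean([mut_profile.residues[n].csp for n in resonance_set])
    if wt == 0:
        raise ValueError("wild-type average CSP is zero; activity undefined")
    return float(100.0 * mut / wt)
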