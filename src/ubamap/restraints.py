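"""Ambiguous interaction restraints (AIRs) for data-driven docking.

Active residues (significant CSP, or peaks broadened at the interface) on
one molecule are restrained to lie near any active-or-passive residue on
the partner; the restraint table is the standard ``ambig.tbl`` dialect of
CNS/HADDOCK ``assign`` statements with a 2.0 A effective upper bound.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

from .csp import CSPProfile

# distance target, minus, plus (A): upper bound = target - minus + plus = 2.0
DEFAULT_DISTANCE = (2.0, 2.0, 0.0)


@dataclass
class RestraintSet:
    """Active/passive residue lists per segment id, plus AIR distances."""

    active: dict[str, list[int]] = field(default_factory=dict)
    passive: dict[str, list[int]] = field(default_factory=dict)
    distance: tuple[float, float, float] = DEFAULT_DISTANCE

    def __post_init__(self):
        for seg in self.active:
            overlap = set(self.active.get(seg, [])) & set(self.passive.get(seg, []))
            if overlap:
                raise ValueError(f"segment {seg}: residues {sorted(overlap)} are both active and passive")
        if not any(self.active.values()):
            raise ValueError("no active residues on any segment: docking would be undriven")

    def segments(self) -> list[str]:
        return sorted(set(self.active) | set(self.passive))


def derive_airs(
    profile_A: CSPProfile,
    profile_B: CSPProfile | None = None,
    symmetric: bool = False,
    segids: tuple[str, str] = ("A", "B"),
) -> RestraintSet:
    """Build a restraint set from classified CSP profiles.

    For a heterocomplex pass both profiles; for a homodimer pass one
    profile with ``symmetric=True`` and both segments receive identical
    lists (docking two identical copies of the same coordinates).
    """
    if profile_B is None and not symmetric:
        raise ValueError("either supply profile_B or request a symmetric homodimer")
    a_seg, b_seg = segids
    act_a, pas_a = profile_A.active, profile_A.passive
    if symmetric and profile_B is None:
        act_b, pas_b = list(act_a), list(pas_a)
    else:
        act_b, pas_b = profile_B.active, profile_B.passive
    return RestraintSet(
        active={a_seg: act_a, b_seg: act_b},
        passive={a_seg: pas_a, b_seg: pas_b},
    )


def write_air_table(rs: RestraintSet, out) -> None:
    """Write one ``assign`` block per active residue, partner clauses
    or-joined over the partner's active+passive residues, ascending order."""
    if isinstance(out, (str, bytes, os.PathLike)):
        with open(out, "w") as fh:
            write_air_table(rs, fh)
            return
    segs = rs.segments()
    if len(segs) != 2:
        raise ValueError(f"AIR table requires exactly two segments, got {segs}")
    d, dminus, dplus = rs.distance
    for seg, partner in ((segs[0], segs[1]), (segs[1], segs[0])):
        partners = sorted(set(rs.active.get(partner, [])) | set(rs.passive.get(partner, [])))
        for resid in sorted(rs.active.get(seg, [])):
            out.write(f"assign ( resid {resid} and segid {seg} )\n")
            out.write("       (\n")
            clauses = [f"        ( resid {j} and segid {partner} )" for j in partners]
            out.write("\n     or\n".join(clauses))
            out.write(f"\n       )  {d:.1f} {dminus:.1f} {dplus:.1f}\n\n")


def filter_by_accessibility(
    rs: RestraintSet,
    rel_access: dict[str, dict[int, float]],
    min_rel: float = 0.4,
) -> RestraintSet:
    """Optional solvent-accessibility filter (off by default in the pipeline).

    Drops residues whose relative side-chain accessibility is below
    ``min_rel`` from both lists; residues missing from ``rel_access`` are
    kept.  ``rel_access`` maps segment id -> residue -> relative SASA.
    """

    def keep(seg, resid):
        acc = rel_access.get(seg, {})
        return resid not in acc or acc[resid] >= min_rel

    return RestraintSet(
        active={s: [r for r in lst if keep(s, r)] for s, lst in rs.active.items()},
        passive={s: [r for r in lst if keep(s, r)] for s, lst in rs.passive.items()},
        distance=rs.distance,
    )


_ASSIGN = re.compile(r"assign \( resid (\d+) and segid (\w+) \)")
_CLAUSE = re.compile(r"\( resid (\d+) and segid (\w+) \)")
_DIST = re.compile(r"\)\s+([\d.]+) ([\d.]+) ([\d.]+)\s*$")


def read_air_table(source) -> RestraintSet:
    """Parse an ``ambig.tbl`` written by :func:`write_air_table`.

    Active residues are those with their own assign block; partner
    residues appearing only in clause lists are the partner's passive set.
    """
    if isinstance(source, (str, bytes, os.PathLike)):
        with open(source) as fh:
            return read_air_table(fh)
    text = source.read()
    active: dict[str, set[int]] = {}
    partners_of: dict[str, set[int]] = {}
    distance = DEFAULT_DISTANCE
    for block in re.split(r"\n\s*\n", text):
        m = _ASSIGN.search(block)
        if m is None:
            continue
        resid, seg = int(m.group(1)), m.group(2)
        active.setdefault(seg, set()).add(resid)
        for cm in _CLAUSE.finditer(block[m.end():]):
            partners_of.setdefault(cm.group(2), set()).add(int(cm.group(1)))
        dm = _DIST.search(block.strip())
        if dm:
            distance = tuple(float(x) for x in dm.groups())
    segs = sorted(set(active) | set(partners_of))
    return RestraintSet(
        active={s: sorted(active.get(s, set())) for s in segs},
        passive={s: sorted(partners_of.get(s, set()) - active.get(s, set())) for s in segs},
        distance=distance,
    )
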