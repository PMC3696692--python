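"""Backbone i→i+4 hydrogen-bond occupancy and helical-defect calling.

An α-helix is held together by hydrogen bonds between the carbonyl
oxygen of residue i and the amide nitrogen of residue i+4.  Over a
conformational ensemble, the fraction of frames in which each such bond
is formed (its occupancy) maps where transmembrane helices kink or
unwind: a pair whose bond is absent in more than 30% of frames is called
a helical defect, marking a candidate hinge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .ensemble_io import StructureEnsemble

logger = logging.getLogger(__name__)

DEFECT_THRESHOLD_ABSENT = 0.30  # bond absent in > 30% of frames


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    Heavy-atom distance d(N, O) <= d_NO_max (inclusive); when hydrogens
    are present and ``use_hydrogens`` is set, additionally require the
    N-H...O angle >= angle_min degrees.
    """

    d_NO_max: float = 3.5
    angle_min: float = 120.0
    use_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.d_NO_max <= 0:
            raise ValueError("d_NO_max must be positive")
        if not (0.0 <= self.angle_min <= 180.0):
            raise ValueError("angle_min must lie in [0, 180]")


@dataclass
class HBondOccupancyMap:
    """Occupancy (fraction of frames bonded) per (chain, resid i) where
    residue i is the carbonyl acceptor and i+4 the amide donor."""

    occupancy: Dict[Tuple[str, int], float]
    criterion: HBondCriterion
    n_frames: int

    def __post_init__(self) -> None:
        for key, occ in self.occupancy.items():
            if not (0.0 <= occ <= 1.0):
                raise ValueError(f"occupancy {occ} out of [0, 1] at {key}")


@dataclass
class HelixDefectMap:
    """Boolean defect call per (chain, resid i)."""

    defect: Dict[Tuple[str, int], bool]
    threshold_absent: float = DEFECT_THRESHOLD_ABSENT
    strict_persistence: bool = False


def _atom_index(ensemble: StructureEnsemble) -> Dict[Tuple[str, int, str], int]:
    """(chain, resid, atom name) -> atom index; first occurrence wins."""
    table: Dict[Tuple[str, int, str], int] = {}
    for i, a in enumerate(ensemble.atoms):
        table.setdefault((a.chain, a.resid, a.name), i)
    return table


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b of the path a-b-c, degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbond_present(ensemble: StructureEnsemble, frame: int, chain: str,
                  resid_i: int,
                  criterion: HBondCriterion = HBondCriterion()) -> bool:
    """Is the i(C=O)...(i+4)(N-H) backbone bond formed in one frame?

    Residue ``resid_i`` is the acceptor (its O), ``resid_i + 4`` the
    donor (its N, and H when the criterion uses hydrogens).  Raises
    KeyError if the required backbone atoms are absent; callers that
    iterate over ranges should skip such pairs (see occupancy_map).
    """
    table = _atom_index(ensemble)
    o = table[(chain, resid_i, "O")]
    n = table[(chain, resid_i + 4, "N")]
    return _pair_present(ensemble, frame, o, n,
                         table.get((chain, resid_i + 4, "H")), criterion)


def _pair_present(ensemble: StructureEnsemble, frame: int, o_idx: int,
                  n_idx: int, h_idx: Optional[int],
                  criterion: HBondCriterion) -> bool:
    xyz = ensemble.coords[frame]
    d = float(np.linalg.norm(xyz[n_idx] - xyz[o_idx]))
    if d > criterion.d_NO_max:
        return False
    if criterion.use_hydrogens and h_idx is not None:
        ang = _angle_deg(xyz[n_idx], xyz[h_idx], xyz[o_idx])
        if ang < criterion.angle_min:
            return False
    return True


def occupancy_map(ensemble: StructureEnsemble, chain: str,
                  resid_range: Optional[Tuple[int, int]] = None,
                  criterion: HBondCriterion = HBondCriterion()) -> HBondOccupancyMap:
    """H-bond occupancy for every (i, i+4) pair of a chain.

    ``resid_range`` is an inclusive (lo, hi) interval of acceptor
    residues i; by default every residue of the chain with an existing
    i+4 partner is used.  Pairs missing a backbone O or N atom are
    skipped with a logged warning rather than raising.
    """
    table = _atom_index(ensemble)
    resids = sorted({a.resid for a in ensemble.atoms if a.chain == chain})
    if not resids:
        raise ValueError(f"no residues found in chain {chain!r}")
    if resid_range is not None:
        lo, hi = resid_range
        resids = [r for r in resids if lo <= r <= hi]
        if not resids:
            raise ValueError(f"empty residue range {resid_range} in chain {chain!r}")
    resid_set = {a.resid for a in ensemble.atoms if a.chain == chain}

    F = ensemble.n_frames
    occ: Dict[Tuple[str, int], float] = {}
    for i in resids:
        if i + 4 not in resid_set:
            continue
        o_idx = table.get((chain, i, "O"))
        n_idx = table.get((chain, i + 4, "N"))
        if o_idx is None or n_idx is None:
            logger.warning("skipping pair (%s, %d)-(%d): missing backbone atom",
                           chain, i, i + 4)
            continue
        h_idx = table.get((chain, i + 4, "H"))
        bonded = sum(
            _pair_present(ensemble, f, o_idx, n_idx, h_idx, criterion)
            for f in range(F)
        )
        occ[(chain, i)] = bonded / F
    if not occ:
        raise ValueError(f"no (i, i+4) pairs with backbone atoms in chain {chain!r}")
    return HBondOccupancyMap(occupancy=occ, criterion=criterion, n_frames=F)


def call_defects(occupancy: HBondOccupancyMap,
                 threshold_absent: float = DEFECT_THRESHOLD_ABSENT,
                 strict_persistence: bool = False) -> HelixDefectMap:
    """Call helical defects from an occupancy map.

    Default reading: a pair is defective when its bond is *absent* in
    strictly more than ``threshold_absent`` of the frames, i.e.
    (1 - occupancy) > threshold (occupancy < 0.7 at the default 0.30).
    With ``strict_persistence`` the alternative reading is used: the
    bond *persists* less than the threshold (occupancy < threshold).
    """
    eps = 1e-9  # guard so e.g. 1 - 0.70 does not exceed 0.30 by round-off
    calls: Dict[Tuple[str, int], bool] = {}
    for key, occ in occupancy.occupancy.items():
        if strict_persistence:
            calls[key] = occ < threshold_absent - eps
        else:
            calls[key] = (1.0 - occ) > threshold_absent + eps
    return HelixDefectMap(defect=calls, threshold_absent=threshold_absent,
                          strict_persistence=strict_persistence)


def residue_defect_view(defects: HelixDefectMap) -> Dict[Tuple[str, int], bool]:
    """Per-residue aggregate: residue r is marked defective when any
    pair with acceptor in r-4..r is defective (for structure coloring)."""
    out: Dict[Tuple[str, int], bool] = {}
    for (chain, i), flag in defects.defect.items():
        for r in range(i, i + 5):
            key = (chain, r)
            out[key] = out.get(key, False) or flag
    return out
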