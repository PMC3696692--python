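"""Ground-truthed synthetic inputs for every analysis stage.

The generators emulate the statistical structure of the study inputs —
a hinge-bending two-domain trajectory with a planted inter-domain
separation signal, ideal α-helical backbones with planted (i, i+4)
hydrogen-bond failures, DEER traces from Gaussian-mixture distance
distributions, and aligned sequence sets with controlled Gly/Pro
frequencies — and each one emits a machine-readable manifest recording
the planted ground truth, so analyzers can be closed against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import deer as deer_mod
from .ensemble_io import AlignmentBlock, AtomRecord, DeerTrace, StructureEnsemble, element_mass

# ---------------------------------------------------------------------------
# Ideal helix (internal-coordinate backbone builder)
# ---------------------------------------------------------------------------

# Ideal backbone internal coordinates (Engh–Huber-like values, Å / degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D given A-B-C,
    the C-D bond length, the B-C-D angle and the A-B-C-D dihedral."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_ideal_helix(n_res: int, phi: float = -57.0, psi: float = -47.0,
                     chain: str = "A", resid_start: int = 1,
                     serial_start: int = 1) -> StructureEnsemble:
    """An ideal α-helical backbone (N, CA, C, O per residue), built from
    internal coordinates at the given (φ, ψ).

    At the α-helical default (−57°, −47°) every (i, i+4) carbonyl-amide
    pair satisfies the default hydrogen-bond criterion.  Returns a
    single-frame ensemble.
    """
    if n_res < 5:
        raise ValueError("need at least 5 residues for an (i, i+4) pair")
    # Seed atoms of residue 1 in an arbitrary frame.
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(_A_N_CA_C)
    C = [CA[0] + np.array([-_B_CA_C * math.cos(ang), _B_CA_C * math.sin(ang), 0.0])]
    for i in range(1, n_res):
        N.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi))
        CA.append(_place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0))
        C.append(_place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi))
    O = []
    for i in range(n_res):
        if i < n_res - 1:
            # O is anti to the next amide nitrogen across the sp2 carbonyl.
            O.append(_place_atom(N[i + 1], CA[i], C[i], _B_C_O, _A_CA_C_O, 180.0))
        else:
            O.append(_place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0))

    atoms: List[AtomRecord] = []
    coords: List[np.ndarray] = []
    serial = serial_start
    for i in range(n_res):
        for name, pos in (("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O[i])):
            element = name[0]
            atoms.append(AtomRecord(serial=serial, name=name, resname="ALA",
                                    resid=resid_start + i, chain=chain,
                                    element=element, mass=element_mass(element)))
            coords.append(pos)
            serial += 1
    return StructureEnsemble(atoms=atoms, coords=np.asarray(coords)[None, :, :])


# ---------------------------------------------------------------------------
# Hinged two-domain trajectory
# ---------------------------------------------------------------------------

@dataclass
class HingedTrajectoryConfig:
    """Two rigid pseudo-domains on hinge arms plus two helical linkers.

    The planted inter-domain center-of-mass separation follows
    base + amplitude * sin(2π f / period) over frames f; per-atom
    isotropic Gaussian noise of s.d. ``thermal_sigma`` is added on top.
    ``broken_pairs`` lists (resid, break_fraction) pairs on the first
    linker helix whose carbonyl O is displaced beyond the hydrogen-bond
    criterion in exactly round(fraction * n_frames) random frames.
    """

    n_atoms_per_domain: int = 60
    separation_base: float = 40.0      # Å
    separation_amplitude: float = 20.0  # Å; mirrors the observed >= 20 Å span
    period_frames: int = 50
    n_frames: int = 100
    thermal_sigma: float = 0.3         # Å
    hinge_axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    linker_len: int = 15               # residues per linker helix
    broken_pairs: Sequence[Tuple[int, float]] = ()
    frame_dt_ns: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation_amplitude < 0 or self.thermal_sigma < 0:
            raise ValueError("amplitudes must be non-negative")
        for resid, frac in self.broken_pairs:
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"break fraction {frac} out of [0, 1] at resid {resid}")
        if self.separation_base - self.separation_amplitude <= 0:
            raise ValueError("separation must stay positive over the cycle")


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def make_hinged_trajectory(cfg: HingedTrajectoryConfig) -> Tuple[StructureEnsemble, Dict]:
    """Generate the hinged two-domain ensemble and its ground-truth
    manifest.

    Geometry: both domains sit at the ends of rigid arms of equal length
    L meeting at a hinge; the opening angle per frame is chosen so the
    noise-free CoM separation equals the planted signal exactly.  The
    two linker helices ride on the arms, so the separation change is
    produced by hinge bending, not translation of free bodies.
    """
    rng = np.random.default_rng(cfg.seed)
    F = cfg.n_frames
    d_planted = cfg.separation_base + cfg.separation_amplitude * np.sin(
        2.0 * math.pi * np.arange(F) / cfg.period_frames
    )
    d_max = float(d_planted.max())
    L = d_max / 2.0 + 5.0  # arm length; keeps the opening angle well-defined

    # Rigid domain template: isotropic Gaussian cloud (CA pseudo-atoms),
    # centered so its geometric/mass CoM is exactly at the arm end.
    def _domain_template() -> np.ndarray:
        cloud = rng.normal(0.0, 3.0, size=(cfg.n_atoms_per_domain, 3))
        return cloud - cloud.mean(axis=0)

    dom_a = _domain_template()
    dom_b = _domain_template()

    helix_a = make_ideal_helix(cfg.linker_len, chain="C", resid_start=1)
    helix_b = make_ideal_helix(cfg.linker_len, chain="D", resid_start=1)

    def _arm_frame(helix: StructureEnsemble, arm_dir: np.ndarray) -> np.ndarray:
        """Place a linker helix along an arm, starting 4 Å from the hinge."""
        xyz = helix.coords[0]
        centered = xyz - xyz.mean(axis=0)
        # Align the helix long axis (first principal component) with the arm.
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        rot = _align_rotation(axis, arm_dir)
        return centered @ rot.T + arm_dir * (L / 2.0)

    atoms: List[AtomRecord] = []
    serial = 1
    for k in range(cfg.n_atoms_per_domain):
        atoms.append(AtomRecord(serial=serial, name="CA", resname="ALA",
                                resid=k + 1, chain="A", element="C",
                                mass=element_mass("C")))
        serial += 1
    for k in range(cfg.n_atoms_per_domain):
        atoms.append(AtomRecord(serial=serial, name="CA", resname="ALA",
                                resid=k + 1, chain="B", element="C",
                                mass=element_mass("C")))
        serial += 1
    for rec in list(helix_a.atoms) + list(helix_b.atoms):
        atoms.append(AtomRecord(serial=serial, name=rec.name, resname=rec.resname,
                                resid=rec.resid, chain=rec.chain,
                                element=rec.element, mass=rec.mass))
        serial += 1

    axis = np.asarray(cfg.hinge_axis, dtype=float)
    axis /= np.linalg.norm(axis)
    # Base arm directions perpendicular to the hinge axis.
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)

    n_dom = cfg.n_atoms_per_domain
    n_hel = helix_a.n_atoms
    N = 2 * n_dom + 2 * n_hel
    coords = np.empty((F, N, 3))
    for f in range(F):
        theta = 2.0 * math.asin(d_planted[f] / (2.0 * L))
        rot_a = _rotation_about(axis, +theta / 2.0)
        rot_b = _rotation_about(axis, -theta / 2.0)
        dir_a = rot_a @ e1
        dir_b = rot_b @ e1
        coords[f, :n_dom] = dom_a + dir_a * L
        coords[f, n_dom:2 * n_dom] = dom_b + dir_b * L
        coords[f, 2 * n_dom:2 * n_dom + n_hel] = _arm_frame(helix_a, dir_a)
        coords[f, 2 * n_dom + n_hel:] = _arm_frame(helix_b, dir_b)
    if cfg.thermal_sigma > 0:
        coords += rng.normal(0.0, cfg.thermal_sigma, size=coords.shape)

    # Plant hydrogen-bond breaks on linker helix C: displace the carbonyl
    # O of the acceptor residue well beyond the distance criterion.
    o_index = {
        (a.chain, a.resid, a.name): i for i, a in enumerate(atoms)
    }
    broken: List[Dict] = []
    for resid, frac in cfg.broken_pairs:
        n_break = int(round(frac * F))
        frames = rng.choice(F, size=n_break, replace=False) if n_break else np.array([], dtype=int)
        oi = o_index.get(("C", resid, "O"))
        ni = o_index.get(("C", resid + 4, "N"))
        if oi is None or ni is None:
            raise ValueError(f"broken pair resid {resid} has no (i, i+4) partner "
                             "on linker helix C")
        for f in frames:
            # Push the carbonyl O directly away from the partner amide N,
            # guaranteeing d(N, O) exceeds any sane criterion.
            direction = coords[f, oi] - coords[f, ni]
            direction /= np.linalg.norm(direction)
            coords[f, oi] = coords[f, oi] + 4.0 * direction
        broken.append({"chain": "C", "resid": int(resid), "fraction": float(frac),
                       "n_broken_frames": int(n_break),
                       "frames": sorted(int(x) for x in frames)})

    ensemble = StructureEnsemble(
        atoms=atoms, coords=coords,
        frame_times=np.arange(F) * cfg.frame_dt_ns,
    )
    manifest = {
        "generator": "make_hinged_trajectory",
        "seed": cfg.seed,
        "n_frames": F,
        "n_atoms_per_domain": n_dom,
        "separation_base": cfg.separation_base,
        "separation_amplitude": cfg.separation_amplitude,
        "period_frames": cfg.period_frames,
        "thermal_sigma": cfg.thermal_sigma,
        "planted_distance": [float(x) for x in d_planted],
        "domain_selections": {"domain_a": "chain A", "domain_b": "chain B"},
        "linker_chains": ["C", "D"],
        "broken_pairs": broken,
    }
    return ensemble, manifest


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # Antiparallel: rotate 180° about any perpendicular axis.
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return _rotation_about(axis, math.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


# ---------------------------------------------------------------------------
# Synthetic DEER
# ---------------------------------------------------------------------------

@dataclass
class DeerSimConfig:
    """Gaussian-mixture ground truth plus acquisition parameters."""

    components: Sequence[Tuple[float, float, float]] = ((4.0, 0.3, 1.0),)  # (mean, sd, weight) nm
    t_max: float = 4.0   # µs
    n_t: int = 200
    mod_depth: float = 0.3
    bg_k: float = 0.05
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        weights = [w for _, _, w in self.components]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if any(sd <= 0 for _, sd, _ in self.components):
            raise ValueError("component sds must be positive")


def make_synthetic_deer(cfg: DeerSimConfig,
                        grid: Optional[deer_mod.RGrid] = None
                        ) -> Tuple[DeerTrace, deer_mod.DistanceDistribution, Dict]:
    """A DEER trace simulated from a Gaussian-mixture P(r), plus the
    ground-truth distribution and a manifest."""
    if grid is None:
        grid = deer_mod.default_rgrid()
    truth = deer_mod.gaussian_mixture(grid, cfg.components)
    t = np.linspace(0.0, cfg.t_max, cfg.n_t)
    params = deer_mod.DeerModelParams(mod_depth=cfg.mod_depth, bg_k=cfg.bg_k)
    trace = deer_mod.simulate_deer(truth, t, params,
                                   noise_sigma=cfg.noise_sigma, seed=cfg.seed)
    manifest = {
        "generator": "make_synthetic_deer",
        "seed": cfg.seed,
        "components": [list(c) for c in cfg.components],
        "t_max": cfg.t_max,
        "n_t": cfg.n_t,
        "mod_depth": cfg.mod_depth,
        "bg_k": cfg.bg_k,
        "noise_sigma": cfg.noise_sigma,
    }
    return trace, truth, manifest


# ---------------------------------------------------------------------------
# Synthetic sequence sets
# ---------------------------------------------------------------------------

@dataclass
class SeqSetConfig:
    """I.i.d. residue draws with controlled G and P frequencies; the
    remaining probability mass is spread uniformly over the other 18
    standard amino acids."""

    n_sequences: int = 100
    length: int = 200
    gly_freq: float = 0.09
    pro_freq: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gly_freq <= 1.0 and 0.0 <= self.pro_freq <= 1.0):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.gly_freq + self.pro_freq > 1.0:
            raise ValueError("gly_freq + pro_freq must not exceed 1")


_OTHER_AA = [a for a in "ACDEFHIKLMNQRSTVWY"]  # 18 standard minus G, P


def make_sequence_set(cfg: SeqSetConfig) -> Tuple[AlignmentBlock, Dict]:
    """An ungapped aligned sequence set with one full-length region span
    named "TMD", plus a manifest."""
    rng = np.random.default_rng(cfg.seed)
    other_p = (1.0 - cfg.gly_freq - cfg.pro_freq) / len(_OTHER_AA)
    alphabet = ["G", "P"] + _OTHER_AA
    probs = [cfg.gly_freq, cfg.pro_freq] + [other_p] * len(_OTHER_AA)
    draws = rng.choice(len(alphabet), size=(cfg.n_sequences, cfg.length), p=probs)
    rows = ["".join(alphabet[j] for j in row) for row in draws]
    ids = [f"seq{i:05d}" for i in range(cfg.n_sequences)]
    block = AlignmentBlock(ids=ids, rows=rows,
                           region_spans={"TMD": (0, cfg.length)})
    manifest = {
        "generator": "make_sequence_set",
        "seed": cfg.seed,
        "n_sequences": cfg.n_sequences,
        "length": cfg.length,
        "gly_freq": cfg.gly_freq,
        "pro_freq": cfg.pro_freq,
    }
    return block, manifest
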