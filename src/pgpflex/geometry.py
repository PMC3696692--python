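"""Distance, fluctuation and contact analytics over structural ensembles.

These are the quantities used to characterize inter-domain motion of an
ABC transporter from a conformational ensemble: center-of-mass distance
time traces and their pooled population histograms, per-atom r.m.s.f.
and the theoretical crystallographic temperature factor
theta = (8*pi^2/3) * rmsf^2, RMSD against an external template after
optimal rigid superposition, and per-frame contact counts (e.g. lipid
acyl-chain carbons entering the TMD lumen through a portal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.spatial import cKDTree

from .ensemble_io import AtomSelection, StructureEnsemble, resolve_selection

#: theta / rmsf^2 conversion factor between an isotropic mean-square
#: displacement and a crystallographic B-factor, 8*pi^2/3.
B_FACTOR_PREFACTOR = 8.0 * math.pi ** 2 / 3.0

DEFAULT_BIN_WIDTH = 0.1  # Å, the binning used for population distributions
DEFAULT_CONTACT_CUTOFF = 4.0  # Å, heavy-atom contact convention


@dataclass
class DistanceTrace:
    """A per-frame scalar distance (Å) between two labelled selections."""

    frame_index: np.ndarray
    d: np.ndarray
    label_a: str
    label_b: str
    time: Optional[np.ndarray] = None  # ns

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.d = np.asarray(self.d, dtype=float)
        if self.frame_index.shape != self.d.shape:
            raise ValueError("frame_index and d must have equal length")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.d)


@dataclass
class DistanceHistogram:
    """A normalized population distribution of a distance, binned on a
    uniform grid anchored at integer multiples of the bin width."""

    bin_edges: np.ndarray
    p: np.ndarray
    n_samples: int
    mean: float
    width: Optional[float] = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.bin_edges) != len(self.p) + 1:
            raise ValueError("need len(bin_edges) == len(p) + 1")

    @property
    def bin_width(self) -> float:
        if self.width is not None:
            return float(self.width)
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def support_width(self) -> float:
        """Width (Å) between the lowest and highest occupied bin edges."""
        occupied = np.flatnonzero(self.p > 0)
        if occupied.size == 0:
            return 0.0
        return float(self.bin_edges[occupied[-1] + 1] - self.bin_edges[occupied[0]])


@dataclass
class RMSFProfile:
    """Per-atom root-mean-square fluctuation about the time-mean
    position (Å), conventionally computed for Cα atoms."""

    chain: List[str]
    resid: List[int]
    rmsf: np.ndarray
    reference: str = "mean structure"

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf must be non-negative")


@dataclass
class TheoreticalBFactors:
    """Temperature factors theta (Å²) predicted from fluctuations."""

    chain: List[str]
    resid: List[int]
    theta: np.ndarray


@dataclass
class ContactCountTrace:
    """Per-frame count of probe atoms within a cutoff of any site atom."""

    frame_index: np.ndarray
    count: np.ndarray
    cutoff: float


def _coerce_selection(ensemble: StructureEnsemble,
                      sel: Union[AtomSelection, str]) -> AtomSelection:
    if isinstance(sel, str):
        return resolve_selection(ensemble, sel)
    return sel


def _weights(ensemble: StructureEnsemble, sel: AtomSelection,
             weighting: str) -> np.ndarray:
    if weighting == "mass":
        w = ensemble.masses[list(sel.indices)]
    elif weighting == "geometric":
        w = np.ones(len(sel))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return w / w.sum()


def center_of_mass(ensemble: StructureEnsemble, sel: Union[AtomSelection, str],
                   frame: int, weighting: str = "mass") -> np.ndarray:
    """Weighted mean position (Å) of a selection in one frame.

    ``weighting="mass"`` uses atomic masses; ``"geometric"`` is the
    unweighted centroid.
    """
    sel = _coerce_selection(ensemble, sel)
    w = _weights(ensemble, sel, weighting)
    xyz = ensemble.coords[frame][list(sel.indices)]
    return w @ xyz


def com_distance_trace(ensemble: StructureEnsemble,
                       sel_a: Union[AtomSelection, str],
                       sel_b: Union[AtomSelection, str],
                       weighting: str = "mass") -> DistanceTrace:
    """Per-frame Euclidean distance between the CoMs of two selections."""
    sel_a = _coerce_selection(ensemble, sel_a)
    sel_b = _coerce_selection(ensemble, sel_b)
    wa = _weights(ensemble, sel_a, weighting)
    wb = _weights(ensemble, sel_b, weighting)
    xa = np.einsum("i,fij->fj", wa, ensemble.coords[:, list(sel_a.indices)])
    xb = np.einsum("i,fij->fj", wb, ensemble.coords[:, list(sel_b.indices)])
    d = np.linalg.norm(xa - xb, axis=1)
    time = ensemble.frame_times
    return DistanceTrace(frame_index=np.arange(ensemble.n_frames), d=d,
                         label_a=sel_a.label, label_b=sel_b.label,
                         time=None if time is None else np.asarray(time))


def pooled_histogram(traces: Sequence[DistanceTrace],
                     bin_width: float = DEFAULT_BIN_WIDTH,
                     discard_first: int = 0) -> DistanceHistogram:
    """Pool one or more distance traces into a normalized histogram.

    Bins are anchored at integer multiples of ``bin_width`` (floor
    convention); a sample falling exactly on an edge goes to the upper
    bin.  ``discard_first`` drops that many leading frames from every
    trace before pooling (the equilibration-discard option).
    """
    if not traces:
        raise ValueError("need at least one trace")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pooled = np.concatenate([t.d[discard_first:] for t in traces])
    if pooled.size == 0:
        raise ValueError("no samples left after discarding leading frames")
    idx = np.floor(pooled / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    edges = (np.arange(lo, hi + 2)) * bin_width
    p = counts / counts.sum()
    return DistanceHistogram(bin_edges=edges, p=p, n_samples=pooled.size,
                             mean=float(pooled.mean()), width=bin_width)


def discard_ns_to_frames(ensemble: StructureEnsemble, t_ns: float) -> int:
    """Number of leading frames covering the first ``t_ns`` ns, from the
    ensemble's frame_times (requires them to be present)."""
    if ensemble.frame_times is None:
        raise ValueError("ensemble carries no frame_times")
    return int(np.searchsorted(ensemble.frame_times, t_ns))


# ---------------------------------------------------------------------------
# Rigid-body superposition, r.m.s.f., RMSD
# ---------------------------------------------------------------------------

def _check_fit_set(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("fit selection is degenerate (collinear or coincident)")


def _fit_frame(mobile_all: np.ndarray, mobile_fit: np.ndarray,
               ref_fit: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of mobile_fit onto ref_fit, applied
    to all atoms of the frame."""
    sup = SVDSuperimposer()
    sup.set(ref_fit, mobile_fit)
    sup.run()
    rot, tran = sup.get_rotran()
    return mobile_all @ rot + tran


def superpose(ensemble: StructureEnsemble, fit_sel: Union[AtomSelection, str],
              reference: Union[str, int, np.ndarray] = "mean") -> StructureEnsemble:
    """Rigid-body (rotation + translation, no scaling) superposition of
    every frame onto a reference, fitting on ``fit_sel`` and applying the
    transform to all atoms.

    ``reference`` may be ``"mean"`` (iterative two-pass fit to the mean
    structure), an integer frame index, or an explicit (M, 3) coordinate
    array for the fit selection.
    """
    fit_sel = _coerce_selection(ensemble, fit_sel)
    fit_idx = list(fit_sel.indices)
    _check_fit_set(ensemble.coords[0, fit_idx])

    coords = ensemble.coords.copy()

    if isinstance(reference, np.ndarray):
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (len(fit_idx), 3):
            raise ValueError("external reference shape must match fit selection")
        passes = [ref]
    elif reference == "mean":
        # Pass 1 fits to frame 0, pass 2 to the resulting mean structure.
        passes = [coords[0, fit_idx], None]
    else:
        passes = [coords[int(reference), fit_idx]]

    for ref in passes:
        if ref is None:
            ref = coords[:, fit_idx].mean(axis=0)
        for f in range(coords.shape[0]):
            coords[f] = _fit_frame(coords[f], coords[f, fit_idx], ref)
    return StructureEnsemble(atoms=ensemble.atoms, coords=coords,
                             frame_times=ensemble.frame_times)


def rmsf(ensemble: StructureEnsemble,
         sel: Union[AtomSelection, str]) -> RMSFProfile:
    """Per-atom r.m.s.f. (Å): sqrt of the time-averaged squared 3-D
    displacement about each atom's mean position.

    The ensemble is expected to be superposed already (see
    :func:`superpose`); at least two frames are required.
    """
    if ensemble.n_frames < 2:
        raise ValueError("r.m.s.f. needs at least 2 frames")
    sel = _coerce_selection(ensemble, sel)
    idx = list(sel.indices)
    xyz = ensemble.coords[:, idx]  # (F, M, 3)
    disp = xyz - xyz.mean(axis=0)
    vals = np.sqrt((disp ** 2).sum(axis=2).mean(axis=0))
    return RMSFProfile(
        chain=[ensemble.atoms[i].chain for i in idx],
        resid=[ensemble.atoms[i].resid for i in idx],
        rmsf=vals,
    )


def rmsf_to_bfactor(profile: RMSFProfile) -> TheoreticalBFactors:
    """Theoretical temperature factor theta = (8*pi^2/3) * rmsf^2, Å²."""
    return TheoreticalBFactors(chain=list(profile.chain),
                               resid=list(profile.resid),
                               theta=B_FACTOR_PREFACTOR * profile.rmsf ** 2)


def rmsd_to_template(ensemble: StructureEnsemble,
                     sel: Union[AtomSelection, str],
                     template_coords: np.ndarray) -> DistanceTrace:
    """Per-frame minimal RMSD (Å) of a selection against an external
    template after optimal rigid superposition.

    Atom correspondence is positional: the i-th selected atom pairs with
    the i-th template atom.
    """
    sel = _coerce_selection(ensemble, sel)
    template = np.asarray(template_coords, dtype=float)
    if template.shape != (len(sel), 3):
        raise ValueError(
            f"template has shape {template.shape}, expected ({len(sel)}, 3)"
        )
    if len(sel) < 3:
        raise ValueError("RMSD fit needs at least 3 atoms")
    idx = list(sel.indices)
    sup = SVDSuperimposer()
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        sup.set(template, ensemble.coords[f, idx])
        sup.run()
        out[f] = sup.get_rms()
    return DistanceTrace(frame_index=np.arange(ensemble.n_frames), d=out,
                         label_a=sel.label, label_b="template")


def pair_distance(ensemble: StructureEnsemble, atom_spec_a: str,
                  atom_spec_b: str, frame: int = 0) -> float:
    """Euclidean distance (Å) between two single-atom selections."""
    a = resolve_selection(ensemble, atom_spec_a)
    b = resolve_selection(ensemble, atom_spec_b)
    for spec, sel in ((atom_spec_a, a), (atom_spec_b, b)):
        if len(sel) != 1:
            raise ValueError(f"spec {spec!r} resolves to {len(sel)} atoms, need exactly 1")
    xa = ensemble.coords[frame, a.indices[0]]
    xb = ensemble.coords[frame, b.indices[0]]
    return float(np.linalg.norm(xa - xb))


def contact_count_trace(ensemble: StructureEnsemble,
                        probe_sel: Union[AtomSelection, str],
                        site_sel: Union[AtomSelection, str],
                        cutoff: float = DEFAULT_CONTACT_CUTOFF) -> ContactCountTrace:
    """Per-frame number of probe atoms within ``cutoff`` Å of any site
    atom (e.g. lipid-tail carbons against lumen-lining residues)."""
    probe_sel = _coerce_selection(ensemble, probe_sel)
    site_sel = _coerce_selection(ensemble, site_sel)
    if set(probe_sel.indices) & set(site_sel.indices):
        raise ValueError("probe and site selections must be disjoint")
    pi = list(probe_sel.indices)
    si = list(site_sel.indices)
    counts = np.empty(ensemble.n_frames, dtype=int)
    for f in range(ensemble.n_frames):
        tree = cKDTree(ensemble.coords[f, si])
        dmin, _ = tree.query(ensemble.coords[f, pi], k=1)
        counts[f] = int(np.count_nonzero(dmin <= cutoff))
    return ContactCountTrace(frame_index=np.arange(ensemble.n_frames),
                             count=counts, cutoff=cutoff)
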