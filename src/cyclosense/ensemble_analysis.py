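"""Structural statistics over cyclopeptide-anion coordinate ensembles.

The input is an ensemble of frames (typically extracted from an MD
trajectory of the receptor with a bound anion, after discarding
equilibration).  The analyses are purely geometric:

* a coordination matrix of donor-acceptor distances and angles per frame,
  which feeds PCA + clustering to pick a representative structure;
* intramolecular amide-to-carbonyl hydrogen-bond counting;
* per-amide coordination occupancy of the anion;
* phenyl-ring-centroid to backbone-centroid distance distributions;
* strided averaging of externally computed per-frame spectra.

Distances are in angstroms and angles in degrees throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "Ensemble",
    "CoordinationMatrix",
    "HBondCensus",
    "build_coordination_matrix",
    "hbond_census",
    "coordination_occupancy",
    "nearest_atom_attribution",
    "representative_frame",
    "ring_centroid_distances",
    "subsample_and_average",
]

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
}


def _element_from_name(name: str) -> str:
    m = re.match(r"([A-Za-z]+)", name.strip())
    sym = (m.group(1) if m else name).upper()
    for cand in (sym[:2], sym[:1]):
        if cand in ATOMIC_MASSES:
            return cand
    return sym[:1]


@dataclass
class Ensemble:
    """Coordinate frames with per-atom metadata and a tiny selection language.

    coordinates: (n_frames, n_atoms, 3) in angstrom; names/resids/elements
    are per-atom arrays.  Selections use expressions like
    ``"resid 3 and name N"`` or ``"element O"``, combinable with ``and``.
    """

    coordinates: np.ndarray
    names: np.ndarray
    resids: np.ndarray
    elements: np.ndarray | None = None
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        self.names = np.asarray(self.names, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        n = self.coordinates.shape[1]
        if len(self.names) != n or len(self.resids) != n:
            raise ValueError("atom metadata length does not match coordinates")
        if self.elements is None:
            self.elements = np.array(
                [_element_from_name(str(nm)) for nm in self.names], dtype=object)
        else:
            self.elements = np.asarray(self.elements, dtype=object)
        if self.masses is None:
            self.masses = np.array(
                [ATOMIC_MASSES.get(str(e).upper(), 0.0) for e in self.elements])

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def select(self, expr: str) -> np.ndarray:
        """Indices of atoms matching 'name X', 'resid I', 'element E' clauses
        joined by 'and'. A clause value list 'name N H' matches any of them."""
        mask = np.ones(self.n_atoms, dtype=bool)
        for clause in expr.split(" and "):
            parts = clause.split()
            if len(parts) < 2:
                raise ValueError(f"bad selection clause {clause!r}")
            key, vals = parts[0], parts[1:]
            if key == "name":
                mask &= np.isin(np.array([str(n) for n in self.names]), vals)
            elif key == "resid":
                mask &= np.isin(self.resids, [int(v) for v in vals])
            elif key == "element":
                mask &= np.isin(np.array([str(e).upper() for e in self.elements]),
                                [v.upper() for v in vals])
            else:
                raise ValueError(f"unknown selection key {key!r}")
        idx = np.nonzero(mask)[0]
        return idx

    def select_required(self, expr: str) -> np.ndarray:
        idx = self.select(expr)
        if idx.size == 0:
            raise ValueError(f"selection {expr!r} matched no atoms")
        return idx

    def amide_pairs(self, n_name: str = "N", h_name: str = "H") -> list[tuple[int, int]]:
        """(N, H) index pairs per residue, ordered by residue id."""
        pairs = []
        for resid in sorted(set(self.resids.tolist())):
            n_idx = self.select(f"resid {resid} and name {n_name}")
            h_idx = self.select(f"resid {resid} and name {h_name}")
            if n_idx.size == 1 and h_idx.size == 1:
                pairs.append((int(n_idx[0]), int(h_idx[0])))
        if not pairs:
            raise ValueError("no amide N-H pairs found")
        return pairs


@dataclass
class CoordinationMatrix:
    """Per-frame feature rows of donor-acceptor geometry.

    For each (amide N-H, acceptor heavy atom) pair there are three columns:
    d(N...X), d(H...X) and the N-H...X angle at the hydrogen.
    """

    values: np.ndarray              # (n_frames, 3 * n_pairs)
    column_labels: list[str]
    donor_labels: list[str]         # one per amide
    acceptor_labels: list[str]      # one per acceptor heavy atom

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("column label count mismatch")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def columns_of(self, kind: str) -> np.ndarray:
        """Column indices of one geometric kind: 'dNX' | 'dHX' | 'angle'."""
        return np.array([i for i, lab in enumerate(self.column_labels)
                         if lab.startswith(kind + ":")])

    def block(self, kind: str) -> np.ndarray:
        """(n_frames, n_donors, n_acceptors) array of one geometric kind."""
        cols = self.columns_of(kind)
        nd, na = len(self.donor_labels), len(self.acceptor_labels)
        return self.values[:, cols].reshape(self.n_frames, nd, na)


def _angle_deg(a: np.ndarray, apex: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle a-apex-b in degrees, vectorized over leading axes."""
    u = a - apex
    v = b - apex
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cosang = np.sum(u * v, axis=-1) / np.where(nu * nv > 0, nu * nv, 1.0)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def build_coordination_matrix(ensemble: Ensemble,
                              donor_pairs: list[tuple[int, int]] | None = None,
                              acceptors: np.ndarray | str = "element O",
                              ) -> CoordinationMatrix:
    """Distances and angles between amide N-H groups and acceptor heavy atoms.

    ``acceptors`` is a selection expression or an index array — the anion's
    heavy atoms for a complex, or the carbonyl oxygens for the free receptor.
    """
    if donor_pairs is None:
        donor_pairs = ensemble.amide_pairs()
    acc = (ensemble.select_required(acceptors) if isinstance(acceptors, str)
           else np.asarray(acceptors, dtype=int))
    if acc.size == 0:
        raise ValueError("empty acceptor selection")
    X = ensemble.coordinates
    cols = []
    labels = []
    donor_labels = [f"res{ensemble.resids[n]}" for n, _ in donor_pairs]
    acceptor_labels = [f"{ensemble.names[i]}{i}" for i in acc]
    for (n_i, h_i), dlab in zip(donor_pairs, donor_labels):
        for a_i, alab in zip(acc, acceptor_labels):
            dNX = np.linalg.norm(X[:, n_i] - X[:, a_i], axis=-1)
            dHX = np.linalg.norm(X[:, h_i] - X[:, a_i], axis=-1)
            ang = _angle_deg(X[:, n_i], X[:, h_i], X[:, a_i])
            cols += [dNX, dHX, ang]
            labels += [f"dNX:{dlab}-{alab}", f"dHX:{dlab}-{alab}",
                       f"angle:{dlab}-{alab}"]
    # interleaved per pair; reorder into kind-major blocks for block() access
    values = np.column_stack(cols)
    order = ([i for i, l in enumerate(labels) if l.startswith("dNX:")]
             + [i for i, l in enumerate(labels) if l.startswith("dHX:")]
             + [i for i, l in enumerate(labels) if l.startswith("angle:")])
    return CoordinationMatrix(values[:, order], [labels[i] for i in order],
                              donor_labels, acceptor_labels)


@dataclass
class HBondCensus:
    """Distribution of per-frame intramolecular hydrogen-bond counts."""

    counts: np.ndarray              # per frame
    fractions: dict[int, float]     # time fraction per count
    mean: float

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "HBondCensus":
        counts = np.asarray(counts, dtype=int)
        uniq, n = np.unique(counts, return_counts=True)
        fr = {int(u): float(c) / len(counts) for u, c in zip(uniq, n)}
        return cls(counts, fr, float(np.mean(counts)))


def hbond_census(ensemble: Ensemble,
                 donor_pairs: list[tuple[int, int]] | None = None,
                 acceptors: np.ndarray | str = "name O",
                 d_cut: float = 3.5, angle_min: float = 150.0) -> HBondCensus:
    """Count intramolecular N-H...O=C hydrogen bonds per frame.

    Geometric criterion: d(N...O) <= ``d_cut`` (angstrom) and
    N-H...O angle >= ``angle_min`` degrees; donor and acceptor in the same
    residue are excluded.
    """
    if donor_pairs is None:
        donor_pairs = ensemble.amide_pairs()
    acc = (ensemble.select_required(acceptors) if isinstance(acceptors, str)
           else np.asarray(acceptors, dtype=int))
    X = ensemble.coordinates
    counts = np.zeros(ensemble.n_frames, dtype=int)
    for n_i, h_i in donor_pairs:
        for a_i in acc:
            if ensemble.resids[a_i] == ensemble.resids[n_i]:
                continue
            dNO = np.linalg.norm(X[:, n_i] - X[:, a_i], axis=-1)
            ang = _angle_deg(X[:, n_i], X[:, h_i], X[:, a_i])
            counts += ((dNO <= d_cut) & (ang >= angle_min)).astype(int)
    return HBondCensus.from_counts(counts)


def coordination_occupancy(matrix: CoordinationMatrix, cutoff: float = 2.8,
                           angle_min: float | None = None) -> np.ndarray:
    """Fraction of frames in which each amide coordinates the acceptor group.

    An amide counts as bound in a frame when any acceptor heavy atom lies
    within ``cutoff`` of its hydrogen (optionally also requiring the
    N-H...X angle >= ``angle_min``).  Returns one fraction per amide.
    """
    dHX = matrix.block("dHX")
    ok = dHX <= cutoff
    if angle_min is not None:
        ok &= matrix.block("angle") >= angle_min
    return ok.any(axis=2).mean(axis=0)


def nearest_atom_attribution(matrix: CoordinationMatrix) -> dict[str, float]:
    """Which acceptor heavy atom receives the coordination, per frame.

    For each frame, the acceptor atom closest to any amide hydrogen is
    credited; returns the fraction of frames per acceptor label.  Used e.g.
    to verify that thiocyanate binds through its nitrogen terminus.
    """
    dHX = matrix.block("dHX")            # (frames, donors, acceptors)
    nearest = dHX.min(axis=1).argmin(axis=1)
    frac = {}
    for j, lab in enumerate(matrix.acceptor_labels):
        frac[lab] = float(np.mean(nearest == j))
    return frac


@dataclass
class RepresentativeReport:
    frame_index: int
    cluster_sizes: list[int]
    cluster_of_frame: int
    n_clusters: int
    n_components: int
    silhouette: float | None
    pc_coordinates: np.ndarray
    labels: np.ndarray


def representative_frame(matrix: CoordinationMatrix, n_components: int = 2,
                         k_max: int = 8, seed: int = 0,
                         silhouette_floor: float = 0.5) -> RepresentativeReport:
    """Representative structure by PCA + clustering of the coordination matrix.

    Columns are standardized (distances and angles carry different units),
    projected on the leading principal components, and k-means clustered
    with k chosen by silhouette over 2..k_max (falling back to a single
    cluster when no split scores above ``silhouette_floor``).  The returned
    frame minimizes the distance to the centroid of the most populous
    cluster in PC space.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    V = matrix.values
    if V.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    sd = V.std(axis=0)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("degenerate input: coordination matrix has zero variance")
    Z = (V[:, keep] - V[:, keep].mean(axis=0)) / sd[keep]
    ncomp = min(n_components, Z.shape[1], Z.shape[0] - 1)
    P = PCA(n_components=ncomp, random_state=seed).fit_transform(Z)

    import warnings as _warnings
    from sklearn.exceptions import ConvergenceWarning

    best = None  # (silhouette, k, labels, centers)
    for k in range(2, min(k_max, len(P) - 1) + 1):
        with _warnings.catch_warnings():
            # duplicate frames can leave fewer distinct clusters than k
            _warnings.simplefilter("ignore", ConvergenceWarning)
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(P)
        if len(set(km.labels_)) < 2:
            continue
        s = silhouette_score(P, km.labels_)
        if best is None or s > best[0]:
            best = (s, k, km.labels_, km.cluster_centers_)
    if best is None or best[0] < silhouette_floor:
        labels = np.zeros(len(P), dtype=int)
        centers = P.mean(axis=0, keepdims=True)
        k, sil = 1, (best[0] if best else None)
    else:
        sil, k, labels, centers = best

    sizes = [int(np.sum(labels == c)) for c in range(k)]
    top = int(np.argmax(sizes))
    members = np.nonzero(labels == top)[0]
    d = np.linalg.norm(P[members] - centers[top], axis=1)
    frame = int(members[np.argmin(d)])
    return RepresentativeReport(frame_index=frame, cluster_sizes=sizes,
                                cluster_of_frame=top, n_clusters=k,
                                n_components=ncomp,
                                silhouette=None if sil is None else float(sil),
                                pc_coordinates=P, labels=labels)


def ring_centroid_distances(ensemble: Ensemble,
                            rings: list[np.ndarray] | None = None,
                            calpha: np.ndarray | str = "name CA") -> np.ndarray:
    """Distance from each ring's center of mass to the backbone Ca centroid.

    Rings default to the per-residue aromatic carbon groups (atoms named
    CG/CD1/CD2/CE1/CE2/CZ); the backbone reference is the unweighted centroid
    of the Ca atoms.  Returns (n_frames, n_rings).
    """
    ca = (ensemble.select_required(calpha) if isinstance(calpha, str)
          else np.asarray(calpha, dtype=int))
    if rings is None:
        rings = []
        ring_names = "CG CD1 CD2 CE1 CE2 CZ"
        for resid in sorted(set(ensemble.resids.tolist())):
            idx = ensemble.select(f"resid {resid} and name {ring_names}")
            if idx.size:
                rings.append(idx)
        if not rings:
            raise ValueError("no aromatic ring atoms found")
    X = ensemble.coordinates
    center = X[:, ca].mean(axis=1)                       # unweighted Ca centroid
    out = np.empty((ensemble.n_frames, len(rings)))
    for j, ring in enumerate(rings):
        m = ensemble.masses[ring]
        if m.sum() <= 0:
            m = np.ones(len(ring))
        com = np.einsum("fak,a->fk", X[:, ring], m) / m.sum()
        out[:, j] = np.linalg.norm(com - center, axis=1)
    return out


def subsample_and_average(frame_spectra: np.ndarray, stride: int = 50,
                          count: int | None = None,
                          axes: np.ndarray | None = None) -> np.ndarray:
    """Arithmetic mean of every ``stride``-th per-frame spectrum.

    ``frame_spectra`` is (n_frames, n_wavelengths) on a common wavelength
    axis; when per-frame axes are supplied they must be identical.  ``count``
    caps the number of structures entering the average.
    """
    spectra = np.asarray(frame_spectra, dtype=float)
    if spectra.ndim != 2:
        raise ValueError("frame_spectra must be 2-D (frames x wavelengths)")
    if axes is not None:
        axes = np.asarray(axes)
        if axes.ndim == 2 and not np.allclose(axes, axes[0]):
            raise ValueError("per-frame wavelength axes do not match")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sub = spectra[::stride]
    if count is not None:
        sub = sub[:count]
    if sub.size == 0:
        raise ValueError("subsample is empty")
    return sub.mean(axis=0)
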