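"""Gaussian-overlap molecular shape similarity with chemical-feature "color".

Each heavy atom contributes a spherical Gaussian density
``p * exp(-alpha * |r - R_i|^2)`` with amplitude p = 2.70 and a width chosen
so the isolated-atom Gaussian volume equals the atom's hard-sphere volume:
``alpha_i = pi * (3 p / (4 pi))^(2/3) / sigma_i^2`` with sigma_i the van der
Waals radius. Overlap volumes are first-order (pairwise) only:

    O_AB = sum_{i in A, j in B} p^2 (pi / (a_i + a_j))^{3/2}
           exp(-a_i a_j d_ij^2 / (a_i + a_j))

Shape Tanimoto is ``O_AB / (O_AA + O_BB - O_AB)``; the color term applies the
same formalism to same-kind perceived features as unit-width Gaussians and
``combo = T_shape + T_color`` ranges over [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .chem import MoleculeRecord, perceive_features
from .ranking import RankedScreen, ScreenEntry

P_AMPLITUDE = 2.70
_ALPHA_NUM = np.pi * (3.0 * P_AMPLITUDE / (4.0 * np.pi)) ** (2.0 / 3.0)

# Bondi-style van der Waals radii (Angstrom) for elements seen in drug-like
# molecules; fallback 1.70 (carbon) for anything exotic.
VDW_RADII = {
    5: 1.92, 6: 1.70, 7: 1.55, 8: 1.52, 9: 1.47, 14: 2.10, 15: 1.80,
    16: 1.80, 17: 1.75, 34: 1.90, 35: 1.85, 53: 1.98,
}
_DEFAULT_VDW = 1.70

COLOR_KINDS = ("HBA", "HBD", "AR", "HY")
COLOR_SIGMA = 1.0  # Angstrom, unit-width feature Gaussians


@dataclass
class GaussianModel:
    """Atom-centered Gaussian density model of one conformer."""

    centers: np.ndarray  # (n, 3)
    alphas: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.alphas = np.asarray(self.alphas, dtype=float).ravel()
        if self.centers.shape[0] == 0:
            raise ValueError("empty Gaussian model")
        if np.any(self.alphas <= 0):
            raise ValueError("Gaussian widths must be positive")

    @classmethod
    def from_molecule(cls, rec: MoleculeRecord, conformer_index: int = 0) -> "GaussianModel":
        coords = rec.conformer_coords(conformer_index)
        sigmas = np.array(
            [VDW_RADII.get(a.GetAtomicNum(), _DEFAULT_VDW) for a in rec.mol.GetAtoms()]
        )
        return cls(coords, _ALPHA_NUM / sigmas**2)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "GaussianModel":
        return GaussianModel(self.centers @ np.asarray(R).T + np.asarray(t), self.alphas)


@dataclass
class ShapeScore:
    """Self/cross overlap volumes and the derived Tanimoto scores."""

    o_aa: float
    o_bb: float
    o_ab: float
    t_shape: float
    t_color: float
    combo: float
    rotation: np.ndarray
    translation: np.ndarray
    conformer_index: int = 0


def overlap(a: GaussianModel, b: GaussianModel) -> float:
    """First-order Gaussian overlap volume (Angstrom^3)."""
    ai = a.alphas[:, None]
    aj = b.alphas[None, :]
    s = ai + aj
    d2 = np.sum((a.centers[:, None, :] - b.centers[None, :, :]) ** 2, axis=2)
    terms = P_AMPLITUDE**2 * (np.pi / s) ** 1.5 * np.exp(-ai * aj * d2 / s)
    return float(terms.sum())


def tanimoto(a: GaussianModel, b: GaussianModel) -> float:
    o_ab = overlap(a, b)
    return o_ab / (overlap(a, a) + overlap(b, b) - o_ab)


def _feature_models(rec: MoleculeRecord, conformer_index: int) -> dict[str, GaussianModel]:
    alpha = _ALPHA_NUM / COLOR_SIGMA**2
    out: dict[str, GaussianModel] = {}
    by_kind: dict[str, list[np.ndarray]] = {}
    for f in perceive_features(rec, conformer_index):
        if f.kind in COLOR_KINDS:
            by_kind.setdefault(f.kind, []).append(f.center)
    for kind, centers in by_kind.items():
        arr = np.array(centers)
        out[kind] = GaussianModel(arr, np.full(len(arr), alpha))
    return out


def _color_tanimoto(
    ref_feats: dict[str, GaussianModel],
    probe_feats: dict[str, GaussianModel],
    R: np.ndarray,
    t: np.ndarray,
) -> float:
    o_aa = sum(overlap(m, m) for m in ref_feats.values())
    o_bb = sum(overlap(m, m) for m in probe_feats.values())
    if o_aa <= 0 or o_bb <= 0:
        return 0.0
    o_ab = 0.0
    for kind in set(ref_feats) & set(probe_feats):
        o_ab += overlap(ref_feats[kind], probe_feats[kind].transformed(R, t))
    return o_ab / (o_aa + o_bb - o_ab)


def _principal_axes_inits(ref: GaussianModel, probe: GaussianModel) -> list[tuple[np.ndarray, np.ndarray]]:
    """Centroid + principal-axes alignment in all 4 proper sign combinations."""

    def axes(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = centers.mean(axis=0)
        X = centers - c
        cov = X.T @ X / max(len(X), 1)
        w, V = np.linalg.eigh(cov)
        V = V[:, ::-1]  # descending variance
        if np.linalg.det(V) < 0:
            V[:, 2] *= -1
        return c, V

    c_ref, V_ref = axes(ref.centers)
    c_probe, V_probe = axes(probe.centers)
    inits = []
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([sx, sy, sx * sy])  # proper rotations only
        R = V_ref @ S @ V_probe.T
        t = c_ref - R @ c_probe
        inits.append((R, t))
    return inits


def _optimize_pose(
    ref: GaussianModel,
    probe: GaussianModel,
    R0: np.ndarray,
    t0: np.ndarray,
    maxiter: int = 300,
    tol: float = 1e-3,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Local derivative-free maximization of O_AB over the 6 rigid DOF."""
    rot0 = Rotation.from_matrix(R0)
    c_probe = probe.centers.mean(axis=0)

    def pose(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dR = Rotation.from_rotvec(x[:3]).as_matrix()
        R = dR @ rot0.as_matrix()
        # rotate about the probe centroid to decouple rotation and translation
        t = t0 + x[3:] + (rot0.as_matrix() - R) @ c_probe
        return R, t

    def neg(x: np.ndarray) -> float:
        R, t = pose(x)
        return -overlap(ref, probe.transformed(R, t))

    res = minimize(
        neg,
        np.zeros(6),
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-3, "fatol": tol},
    )
    x = res.x if -res.fun >= -neg(np.zeros(6)) else np.zeros(6)
    R, t = pose(x)
    return overlap(ref, probe.transformed(R, t)), R, t


def align_and_score(
    reference: MoleculeRecord,
    probe: MoleculeRecord,
    ref_conformer: int = 0,
    extra_inits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ShapeScore:
    """Overlay every probe conformer onto the fixed reference conformer and
    return the best conformer's shape/color/combo score.

    Initializations: centroid-and-principal-axes in all four proper sign
    combinations, plus any caller-supplied transforms (e.g. a pharmacophore
    alignment); each is locally optimized and the optimizer never returns a
    pose worse than its best initialization.
    """
    if reference.n_conformers == 0 or probe.n_conformers == 0:
        raise ValueError("both molecules need at least one conformer")
    ref_model = GaussianModel.from_molecule(reference, ref_conformer)
    o_aa = overlap(ref_model, ref_model)
    ref_feats = _feature_models(reference, ref_conformer)

    best: ShapeScore | None = None
    for ci in range(probe.n_conformers):
        probe_model = GaussianModel.from_molecule(probe, ci)
        o_bb = overlap(probe_model, probe_model)
        inits = _principal_axes_inits(ref_model, probe_model)
        if extra_inits:
            inits = inits + list(extra_inits)
        o_best, R_best, t_best = -np.inf, np.eye(3), np.zeros(3)
        for R0, t0 in inits:
            o, R, t = _optimize_pose(ref_model, probe_model, R0, t0)
            if o > o_best:
                o_best, R_best, t_best = o, R, t
        t_shape = o_best / (o_aa + o_bb - o_best)
        t_color = _color_tanimoto(ref_feats, _feature_models(probe, ci), R_best, t_best)
        score = ShapeScore(
            o_aa=o_aa,
            o_bb=o_bb,
            o_ab=o_best,
            t_shape=float(t_shape),
            t_color=float(t_color),
            combo=float(t_shape + t_color),
            rotation=R_best,
            translation=t_best,
            conformer_index=ci,
        )
        if best is None or score.combo > best.combo:
            best = score
    assert best is not None
    return best


def shape_screen(
    reference: MoleculeRecord,
    library: list[MoleculeRecord],
    top_n: int = 500,
    label_by_id: dict[str, str] | None = None,
) -> RankedScreen:
    """Rank a library by combo score against the reference; keep the top N.

    The default retrieval depth of 500 per library mirrors common shape-
    screening practice.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    entries = []
    for rec in library:
        s = align_and_score(reference, rec)
        label = (label_by_id or {}).get(rec.id, "unknown")
        entries.append(
            ScreenEntry(
                rec.id,
                s.combo,
                label,
                {
                    "t_shape": round(s.t_shape, 6),
                    "t_color": round(s.t_color, 6),
                    "conformer_index": s.conformer_index,
                },
            )
        )
    return RankedScreen(entries).top(top_n)
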