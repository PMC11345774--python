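"""3D pharmacophore query representation, matching and screening.

A query is a set of typed tolerance spheres (features) plus an exclusion-
volume coat. Matching enumerates kind-compatible assignments of ligand
features to query features, prunes on inter-feature distances, superposes
the matched ligand feature centers onto the query by a least-squares rigid
transform (Kabsch, proper rotations only) and accepts the assignment when
every matched feature lands inside its tolerance sphere and no ligand heavy
atom falls inside an exclusion sphere.

The fit score is ``S = 9 * n_matched + sum_f (1 - d_f / r_f)`` so that a
match with more fulfilled features always outranks a geometrically tighter
match with fewer; the fractional term orders matches of equal cardinality.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .chem import FEATURE_KINDS, MoleculeRecord, PerceivedFeature, perceive_features
from .ranking import RankedScreen, ScreenEntry

DEFAULT_FEATURE_RADIUS = 1.5  # Angstrom, conventional tolerance sphere
DEFAULT_EXCLUSION_RADIUS = 1.0  # Angstrom


@dataclass(frozen=True)
class QueryFeature:
    kind: str
    center: tuple[float, float, float]
    radius: float = DEFAULT_FEATURE_RADIUS
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")
        object.__setattr__(self, "center", tuple(float(x) for x in self.center))


@dataclass(frozen=True)
class ExclusionVolume:
    center: tuple[float, float, float]
    radius: float = DEFAULT_EXCLUSION_RADIUS

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("exclusion radius must be positive")
        object.__setattr__(self, "center", tuple(float(x) for x in self.center))


@dataclass
class PharmacophoreQuery:
    """Typed feature spheres plus an exclusion-volume coat."""

    features: list[QueryFeature]
    exclusion_volumes: list[ExclusionVolume] = field(default_factory=list)
    required_labels: frozenset[str] = frozenset()
    name: str = "query"

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("a pharmacophore query needs at least one feature")
        labels = [f.label for f in self.features]
        if len(set(labels)) != len(labels):
            raise ValueError("feature labels must be unique")
        self.required_labels = frozenset(self.required_labels)
        unknown = self.required_labels - set(labels)
        if unknown:
            raise ValueError(f"required labels not in query: {sorted(unknown)}")

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.features]

    def feature(self, label: str) -> QueryFeature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(f"no feature labeled {label!r}")

    def drop_feature(self, label: str) -> "PharmacophoreQuery":
        """Copy of the query without the named feature (exclusion volumes
        untouched); dropping a required label also unrequires it."""
        if label not in self.labels:
            raise KeyError(f"no feature labeled {label!r}")
        return PharmacophoreQuery(
            features=[f for f in self.features if f.label != label],
            exclusion_volumes=list(self.exclusion_volumes),
            required_labels=self.required_labels - {label},
            name=self.name,
        )

    def add_feature(self, feat: QueryFeature, required: bool = False) -> "PharmacophoreQuery":
        req = self.required_labels | ({feat.label} if required else set())
        return PharmacophoreQuery(
            features=[*self.features, feat],
            exclusion_volumes=list(self.exclusion_volumes),
            required_labels=req,
            name=self.name,
        )

    # --- serialization (JSON or YAML) --------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "features": [
                {"kind": f.kind, "center": list(f.center), "radius": f.radius, "label": f.label}
                for f in self.features
            ],
            "exclusion_volumes": [
                {"center": list(x.center), "radius": x.radius} for x in self.exclusion_volumes
            ],
            "required_labels": sorted(self.required_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreQuery":
        return cls(
            features=[
                QueryFeature(f["kind"], tuple(f["center"]), f.get("radius", DEFAULT_FEATURE_RADIUS), f["label"])
                for f in d["features"]
            ],
            exclusion_volumes=[
                ExclusionVolume(tuple(x["center"]), x.get("radius", DEFAULT_EXCLUSION_RADIUS))
                for x in d.get("exclusion_volumes", [])
            ],
            required_labels=frozenset(d.get("required_labels", [])),
            name=d.get("name", "query"),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PharmacophoreQuery":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls.from_dict(d)


@dataclass
class MatchResult:
    """A feature correspondence with its rigid transform and fit score."""

    assignment: dict[str, int]  # query label -> ligand feature index
    rotation: np.ndarray
    translation: np.ndarray
    residuals: dict[str, float]
    n_matched: int
    score: float
    conformer_index: int
    clash: bool


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t with R @ p + t ~ q.

    The reflection branch of the SVD solution is rejected (det(R) = +1).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _pairwise_ok(
    q_centers: np.ndarray, q_radii: np.ndarray, l_centers: np.ndarray
) -> bool:
    """Distance-matrix compatibility: |d_q(i,j) - d_l(i,j)| <= r_i + r_j."""
    n = len(q_centers)
    for i in range(n):
        for j in range(i + 1, n):
            dq = np.linalg.norm(q_centers[i] - q_centers[j])
            dl = np.linalg.norm(l_centers[i] - l_centers[j])
            if abs(dq - dl) > q_radii[i] + q_radii[j]:
                return False
    return True


def _clashes(coords: np.ndarray, query: PharmacophoreQuery) -> bool:
    for xv in query.exclusion_volumes:
        if np.any(np.linalg.norm(coords - np.asarray(xv.center), axis=1) < xv.radius):
            return True
    return False


def _evaluate_assignment(
    query: PharmacophoreQuery,
    subset: tuple[int, ...],
    lig_idx: tuple[int, ...],
    lig_feats: list[PerceivedFeature],
    coords: np.ndarray,
    conformer_index: int,
    fixed_frame: bool,
) -> MatchResult | None:
    q_feats = [query.features[i] for i in subset]
    q_centers = np.array([f.center for f in q_feats])
    l_centers = np.array([lig_feats[j].center for j in lig_idx])
    if fixed_frame:
        R, t = np.eye(3), np.zeros(3)
        placed = l_centers
    else:
        if len(subset) >= 2 and not _pairwise_ok(
            q_centers, np.array([f.radius for f in q_feats]), l_centers
        ):
            return None
        if len(subset) >= 3:
            R, t = kabsch(l_centers, q_centers)
        elif len(subset) == 2:
            # align the segment midpoints and direction; rotation about the
            # axis is unconstrained, pick the minimal one
            R, t = _two_point_transform(l_centers, q_centers)
        else:
            R, t = np.eye(3), q_centers[0] - l_centers[0]
        placed = l_centers @ R.T + t
    d = np.linalg.norm(placed - q_centers, axis=1)
    radii = np.array([f.radius for f in q_feats])
    if np.any(d > radii):
        return None
    score = 9.0 * len(subset) + float(np.sum(1.0 - d / radii))
    clash = _clashes(coords @ R.T + t, query)
    return MatchResult(
        assignment={q_feats[k].label: lig_idx[k] for k in range(len(subset))},
        rotation=R,
        translation=t,
        residuals={q_feats[k].label: float(d[k]) for k in range(len(subset))},
        n_matched=len(subset),
        score=score,
        conformer_index=conformer_index,
        clash=clash,
    )


def _two_point_transform(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform taking segment P onto segment Q (minimal rotation)."""
    u = P[1] - P[0]
    v = Q[1] - Q[0]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        R = np.eye(3)
    else:
        u, v = u / nu, v / nv
        c = float(np.clip(np.dot(u, v), -1.0, 1.0))
        axis = np.cross(u, v)
        s = np.linalg.norm(axis)
        if s < 1e-12:
            R = np.eye(3) if c > 0 else _any_perpendicular_flip(u)
        else:
            axis = axis / s
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            R = np.eye(3) + s * K + (1 - c) * (K @ K)
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    return R, t


def _any_perpendicular_flip(u: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(w, u)) > 0.9:
        w = np.array([0.0, 1.0, 0.0])
    axis = np.cross(u, w)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + 2.0 * (K @ K)  # 180 degree rotation about axis


def match(
    query: PharmacophoreQuery,
    rec: MoleculeRecord,
    mode: str = "full",
    fixed_frame: bool = False,
    conformer_indices: list[int] | None = None,
) -> MatchResult | None:
    """Best match of any conformer of ``rec`` against ``query``.

    ``full`` mode requires all required labels (all features when none are
    marked required); ``partial`` mode maximizes the fit score over feature
    subsets of size >= 1. ``fixed_frame`` pins the transform to the identity
    (pose re-scoring in the receptor frame). Returns the best non-clashing
    result, a clashing result when nothing else fits, or None.
    """
    if mode not in {"full", "partial"}:
        raise ValueError(f"mode must be 'full' or 'partial', got {mode!r}")
    required = set(query.required_labels) if query.required_labels else (
        set(query.labels) if mode == "full" else set()
    )
    if conformer_indices is None:
        conformer_indices = list(range(rec.n_conformers))
    n = len(query.features)
    label_to_idx = {f.label: i for i, f in enumerate(query.features)}
    required_idx = frozenset(label_to_idx[lab] for lab in required)

    best: MatchResult | None = None
    best_clash: MatchResult | None = None
    for ci in conformer_indices:
        lig_feats = perceive_features(rec, ci)
        if not lig_feats:
            continue
        coords = rec.conformer_coords(ci)
        by_kind: dict[str, list[int]] = {}
        for j, lf in enumerate(lig_feats):
            by_kind.setdefault(lf.kind, []).append(j)
        # subsets in decreasing cardinality; the 9*n term makes any larger
        # feasible subset beat every smaller one
        min_size = max(1, len(required_idx))
        for size in range(n, min_size - 1, -1):
            for subset in itertools.combinations(range(n), size):
                if not required_idx <= frozenset(subset):
                    continue
                pools = [by_kind.get(query.features[i].kind, []) for i in subset]
                if any(not p for p in pools):
                    continue
                for lig_idx in itertools.product(*pools):
                    if len(set(lig_idx)) != len(lig_idx):
                        continue
                    res = _evaluate_assignment(
                        query, subset, lig_idx, lig_feats, coords, ci, fixed_frame
                    )
                    if res is None:
                        continue
                    if res.clash:
                        if best_clash is None or res.score > best_clash.score:
                            best_clash = res
                    elif best is None or res.score > best.score:
                        best = res
            if best is not None:
                break  # no smaller subset can beat a feasible one at this size
    if best is not None:
        return best
    return best_clash


def screen(
    query: PharmacophoreQuery,
    library: list[MoleculeRecord],
    mode: str = "full",
    label_by_id: dict[str, str] | None = None,
) -> RankedScreen:
    """Score every molecule against the query and rank by fit score.

    Non-matchers (and clashing matches) score 0; in full mode they are
    excluded from the output, in partial mode retained with score 0.
    """
    if not library:
        raise ValueError("empty library")
    entries = []
    for rec in library:
        res = match(query, rec, mode=mode)
        ok = res is not None and not res.clash
        score = res.score if ok else 0.0
        if mode == "full" and not ok:
            continue
        extras = {
            "n_matched": res.n_matched if ok else 0,
            "conformer_index": res.conformer_index if ok else -1,
        }
        label = (label_by_id or {}).get(rec.id, "unknown")
        entries.append(ScreenEntry(rec.id, score, label, extras))
    return RankedScreen(entries)


def query_from_features(
    feats: list[PerceivedFeature],
    kinds_with_labels: list[tuple[int, str]],
    name: str = "query",
    radius: float = DEFAULT_FEATURE_RADIUS,
    exclusion_volumes: list[ExclusionVolume] | None = None,
) -> PharmacophoreQuery:
    """Build a query from perceived features: (feature index, label) pairs."""
    qf = [
        QueryFeature(feats[i].kind, tuple(feats[i].center), radius, label)
        for i, label in kinds_with_labels
    ]
    return PharmacophoreQuery(qf, exclusion_volumes or [], name=name)
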