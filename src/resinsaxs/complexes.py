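"""Rigid-body bead models of antibody / protein-A / agarose assemblies.

Every entity (agarose strand, each ligand domain of the tetrameric chain,
each antibody) is a rigid set of per-residue centroids.  Tetramer chains are
grown as a random walk of rigidly rotated domain copies; antibodies dock
rigidly at a configured consensus-site anchor (the Fc CH2-CH3 interface);
assemblies are accepted purely on geometric grounds (no inter-entity
centroid pair closer than a clash cutoff — no energy model).  Radial
densities of accepted assemblies, measured from the strand axis, are ranked
against experimental profiles by an L2 score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .containers import RadialDensity
from .transforms import pair_density_from_points

__all__ = [
    "CentroidModel",
    "AssemblyConfig",
    "ModelLibrary",
    "load_centroid_model",
    "structure_pair_density",
    "build_tetramer_chain",
    "build_agarose_strand",
    "dock_antibody",
    "clash_filter",
    "sample_library",
    "radial_density_of_assembly",
    "score_similarity",
    "rank_stoichiometries",
]

logger = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0


def _random_rotation(rng: np.random.Generator) -> Rotation:
    """Uniform random rotation via the unit-quaternion method."""
    quat = rng.standard_normal(4)
    return Rotation.from_quat(quat / np.linalg.norm(quat))


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


@dataclass
class CentroidModel:
    """Labeled per-residue centroid point set in nm.

    labels tag each point with its entity ('agarose', 'ligand_domain_1'..4,
    'antibody_1', ...); anchors are named reference points (nm) that follow
    the model through rigid transforms; axis is an optional (point,
    direction) pair marking the agarose backbone used as the radial origin.
    """

    points: np.ndarray
    labels: np.ndarray
    residue_ids: Optional[np.ndarray] = None
    anchors: Dict[str, np.ndarray] = field(default_factory=dict)
    axis: Optional[Tuple[np.ndarray, np.ndarray]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] == 0:
            raise ValueError("empty centroid model")
        if self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape[0] != self.points.shape[0]:
            raise ValueError("labels must match the number of points")
        if self.residue_ids is None:
            self.residue_ids = np.arange(self.points.shape[0])
        else:
            self.residue_ids = np.asarray(self.residue_ids)

    @property
    def entities(self) -> List[str]:
        seen: List[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def transformed(self, rotation: Optional[Rotation] = None,
                    translation=(0.0, 0.0, 0.0)) -> "CentroidModel":
        """Rigid transform (rotation about the origin, then translation)."""
        t = np.asarray(translation, dtype=float)
        pts = self.points if rotation is None else rotation.apply(self.points)
        anchors = {
            k: (v if rotation is None else rotation.apply(v)) + t
            for k, v in self.anchors.items()
        }
        axis = None
        if self.axis is not None:
            p, d = self.axis
            axis = (
                (p if rotation is None else rotation.apply(p)) + t,
                d if rotation is None else rotation.apply(d),
            )
        return CentroidModel(pts + t, self.labels.copy(), self.residue_ids.copy(),
                             anchors, axis, dict(self.meta))

    def relabeled(self, label: str) -> "CentroidModel":
        return CentroidModel(self.points.copy(),
                             np.full(self.points.shape[0], label, dtype=object),
                             self.residue_ids.copy(), dict(self.anchors),
                             self.axis, dict(self.meta))

    @staticmethod
    def merge(models: Sequence["CentroidModel"]) -> "CentroidModel":
        """Concatenate models; anchors are unioned, the first axis wins."""
        pts = np.vstack([m.points for m in models])
        labels = np.concatenate([m.labels for m in models])
        rids = np.concatenate([m.residue_ids for m in models])
        anchors: Dict[str, np.ndarray] = {}
        axis = None
        meta: dict = {}
        for m in models:
            for k, v in m.anchors.items():
                anchors.setdefault(k, v)
            if axis is None and m.axis is not None:
                axis = m.axis
            meta.update(m.meta)
        return CentroidModel(pts, labels, rids, anchors, axis, meta)


@dataclass
class AssemblyConfig:
    """Geometry and sampling settings for one stoichiometry arm.

    stoichiometry is 'n:1' (n antibodies per tetramer chain);
    bound_domains lists the occupied chain domains (1..4, distinct,
    one per antibody).
    """

    stoichiometry: str = "1:1"
    bound_domains: Tuple[int, ...] = (4,)
    strand_radius: float = 6.0
    strand_length: float = 40.0
    bead_spacing: float = 1.0
    linker_length: float = 1.0
    contact_distance: float = 0.5
    clash_cutoff: float = 0.4
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        n_ab = int(self.stoichiometry.split(":")[0])
        doms = tuple(sorted(self.bound_domains))
        if len(set(doms)) != len(doms):
            raise ValueError("bound domains must be distinct")
        if not set(doms) <= {1, 2, 3, 4}:
            raise ValueError("bound domains must be in 1..4")
        if len(doms) != n_ab:
            raise ValueError(
                f"stoichiometry {self.stoichiometry} needs {n_ab} bound domains, "
                f"got {doms}"
            )
        self.bound_domains = doms


@dataclass
class ModelLibrary:
    """Clash-free assembly library for one (stoichiometry, domain-set) arm."""

    members: List[CentroidModel]
    config: AssemblyConfig
    n_attempted: int
    n_accepted: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_accepted != len(self.members):
            raise ValueError("n_accepted must equal the number of stored members")
        if self.n_accepted > self.n_attempted:
            raise ValueError("accepted cannot exceed attempted")

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_attempted if self.n_attempted else 0.0


# ---------------------------------------------------------------------------
# Structure input
# ---------------------------------------------------------------------------

def load_centroid_model(
    path,
    chain_selection: Optional[Sequence[str]] = None,
    label: str = "antibody_1",
) -> CentroidModel:
    """Per-residue centroid model from a PDB/mmCIF file (coordinates in nm).

    Each centroid is the unweighted mean of all atom coordinates of a
    residue; zero-atom residues are skipped with a log line.
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    available = [ch.name for ch in model]
    if chain_selection is not None:
        missing = set(chain_selection) - set(available)
        if missing:
            raise ValueError(f"chains {sorted(missing)} not present; "
                             f"available: {available}")
    points, rids = [], []
    for chain in model:
        if chain_selection is not None and chain.name not in chain_selection:
            continue
        for residue in chain:
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in residue])
            if coords.shape[0] == 0:
                logger.info("skipping zero-atom residue %s/%s", chain.name,
                            residue.seqid.num)
                continue
            points.append(coords.mean(axis=0) / ANGSTROM_PER_NM)
            rids.append(residue.seqid.num)
    if not points:
        raise ValueError(f"no residues selected from {path}")
    pts = np.array(points)
    labels = np.full(pts.shape[0], label, dtype=object)
    return CentroidModel(pts, labels, np.asarray(rids),
                         meta={"source": str(path), "chains": chain_selection})


def structure_pair_density(model: CentroidModel, bin_width: float,
                           max_pairs: Optional[int] = None,
                           seed: Optional[int] = None) -> RadialDensity:
    """Pair density of a centroid model (delegates to the point-set routine)."""
    return pair_density_from_points(model.points, bin_width, max_pairs=max_pairs,
                                    seed=seed)


# ---------------------------------------------------------------------------
# Assembly construction
# ---------------------------------------------------------------------------

def _domain_anchors(domain: CentroidModel) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_term, c_term, binding_face) anchor points of a ligand domain."""
    n = domain.anchors.get("n_term", domain.points[0])
    c = domain.anchors.get("c_term", domain.points[-1])
    b = domain.anchors.get("binding_face", domain.points.mean(axis=0))
    return np.asarray(n), np.asarray(c), np.asarray(b)


def _self_clash(groups: List[np.ndarray], cutoff: float) -> bool:
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            tree = cKDTree(groups[i])
            if tree.query_ball_point(groups[j], r=cutoff, return_length=True).sum():
                return True
    return False


def _align_rotation(source: np.ndarray, target: np.ndarray) -> Rotation:
    """Minimal rotation taking unit vector ``source`` onto ``target``."""
    v = np.cross(source, target)
    s = np.linalg.norm(v)
    c = float(source @ target)
    if s < 1e-12:
        if c > 0:
            return Rotation.identity()
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(source, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(source, [0.0, 1.0, 0.0])
        return Rotation.from_rotvec(np.pi * perp / np.linalg.norm(perp))
    axis = v / s
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(angle * axis)


def _cone_direction(axis: np.ndarray, half_angle: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit vector within a cone about ``axis``."""
    cos_t = rng.uniform(np.cos(half_angle), 1.0)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    local = np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    return _align_rotation(np.array([0.0, 0.0, 1.0]), axis).apply(local)


def build_tetramer_chain(
    domain: CentroidModel,
    linker_length: float = 1.0,
    seed: Optional[int] = None,
    start_point=(0.0, 0.0, 0.0),
    start_direction=(0.0, 0.0, 1.0),
    clash_cutoff: float = 0.4,
    max_tries: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> CentroidModel:
    """Grow a four-domain ligand chain as a rigid-body random walk.

    Four rigid copies of ``domain`` (labels ligand_domain_1..4) are chained
    N-terminus-to-C-terminus: each copy is uniformly rotated and translated
    so its N-anchor lies ``linker_length`` from the previous copy's C-anchor
    in a random direction.  Loop-like folds are allowed; only non-adjacent
    domain copies closer than ``clash_cutoff`` force a retry.  The first
    domain's N-anchor is placed at ``start_point`` (the covalent agarose
    attachment, no spacer).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n0, c0, b0 = _domain_anchors(domain)
    start_point = np.asarray(start_point, dtype=float)
    start_direction = np.asarray(start_direction, dtype=float)
    start_direction = start_direction / np.linalg.norm(start_direction)

    for _ in range(max_tries):
        placed: List[CentroidModel] = []
        # first copy: random orientation, N-anchor on the attachment point,
        # nudged along the outward direction so the body sits off the surface
        rot = _random_rotation(rng)
        m = domain.transformed(rot)
        shift = start_point - rot.apply(n0)
        placed.append(m.transformed(translation=shift))
        ok = True
        for k in range(1, 4):
            prev_c = placed[-1].anchors.get("c_term")
            if prev_c is None:
                prev_c = Rotation.identity().apply(c0)  # pragma: no cover
            for _try in range(max_tries):
                rot = _random_rotation(rng)
                u = _random_unit_vector(rng)
                target_n = prev_c + linker_length * u
                cand = domain.transformed(rot)
                cand = cand.transformed(translation=target_n - cand.anchors.get(
                    "n_term", cand.points[0]))
                # keep every domain pair (bonded neighbours included) outside
                # the clash cutoff so the final assembly filter agrees
                if _self_clash([p.points for p in placed] + [cand.points],
                               clash_cutoff):
                    continue
                placed.append(cand)
                break
            else:
                ok = False
                break
        if not ok:
            continue
        parts = []
        anchors: Dict[str, np.ndarray] = {}
        for k, part in enumerate(placed, start=1):
            lab = f"ligand_domain_{k}"
            parts.append(part.relabeled(lab))
            nk, ck, bk = _domain_anchors(part)
            anchors[f"binding_site_{k}"] = bk
            anchors[f"n_term_{k}"] = nk
            anchors[f"c_term_{k}"] = ck
        chain = CentroidModel.merge(parts)
        chain.anchors = anchors
        chain.meta["linker_length"] = linker_length
        return chain
    raise RuntimeError(f"failed to place a clash-free tetramer chain in "
                       f"{max_tries} tries")


def build_agarose_strand(
    radius: float = 6.0,
    length: float = 40.0,
    bead_spacing: float = 1.0,
) -> CentroidModel:
    """Coarse agarose strand: beads on a cylinder surface plus its axis.

    The axis (recorded on the model) is the radial reference R = 0 of all
    radial density distributions.
    """
    if radius <= 0 or length <= 0 or bead_spacing <= 0:
        raise ValueError("radius, length and bead_spacing must be > 0")
    n_z = max(2, int(round(length / bead_spacing)) + 1)
    z = np.linspace(-length / 2.0, length / 2.0, n_z)
    n_phi = max(3, int(round(2.0 * np.pi * radius / bead_spacing)))
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    surface = np.array([
        [radius * np.cos(p), radius * np.sin(p), zz] for zz in z for p in phi
    ])
    axis_beads = np.column_stack([np.zeros(n_z), np.zeros(n_z), z])
    pts = np.vstack([surface, axis_beads])
    labels = np.full(pts.shape[0], "agarose", dtype=object)
    model = CentroidModel(pts, labels,
                          axis=(np.zeros(3), np.array([0.0, 0.0, 1.0])))
    model.meta.update({"radius": radius, "length": length,
                       "bead_spacing": bead_spacing})
    return model


def dock_antibody(
    assembly: CentroidModel,
    domain_index: int,
    antibody: CentroidModel,
    seed: Optional[int] = None,
    contact_distance: float = 0.5,
    tilt_half_angle: float = np.deg2rad(30.0),
    rng: Optional[np.random.Generator] = None,
) -> CentroidModel:
    """Dock one antibody rigidly to a ligand domain of an assembly.

    The antibody's consensus-site anchor (Fc CH2-CH3 interface) is placed at
    ``contact_distance`` from the domain's binding-face anchor along a
    contact axis (the domain's outward binding-face normal, tilted uniformly
    within ``tilt_half_angle``); the antibody body faces away from the
    domain and its orientation is sampled uniformly about the contact axis.
    A domain accepts at most one antibody.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    key = f"binding_site_{domain_index}"
    if key not in assembly.anchors:
        raise ValueError(f"assembly has no domain {domain_index}")
    occupied = set(assembly.meta.get("occupied_domains", ()))
    if domain_index in occupied:
        raise ValueError(f"domain {domain_index} is already occupied")
    site = assembly.anchors[key]
    ab_anchor = antibody.anchors.get("consensus_site")
    if ab_anchor is None:
        raise ValueError("antibody model lacks a 'consensus_site' anchor")

    n_existing = sum(1 for lab in assembly.entities if lab.startswith("antibody"))
    dom_mask = assembly.labels == f"ligand_domain_{domain_index}"
    dom_center = assembly.points[dom_mask].mean(axis=0)
    normal = site - dom_center
    norm = np.linalg.norm(normal)
    u0 = normal / norm if norm > 1e-9 else _random_unit_vector(rng)
    u = _cone_direction(u0, tilt_half_angle, rng)
    target = site + contact_distance * u

    # orient the antibody so its consensus face looks back at the domain,
    # then spin it uniformly about the contact axis
    ab_out = np.asarray(ab_anchor) - antibody.points.mean(axis=0)
    ab_out = ab_out / np.linalg.norm(ab_out)
    align = _align_rotation(ab_out, -u)
    spin = Rotation.from_rotvec(rng.uniform(0.0, 2.0 * np.pi) * u)
    rot = spin * align
    ab = antibody.transformed(rot)
    ab = ab.transformed(translation=target - ab.anchors["consensus_site"])
    ab = ab.relabeled(f"antibody_{n_existing + 1}")
    ab.anchors = {f"consensus_site_{n_existing + 1}": target.copy()}
    merged = CentroidModel.merge([assembly, ab])
    merged.anchors = {**assembly.anchors, **ab.anchors}
    merged.axis = assembly.axis
    merged.meta = dict(assembly.meta)
    merged.meta["occupied_domains"] = tuple(sorted(occupied | {domain_index}))
    return merged


def clash_filter(assembly: CentroidModel, cutoff: float = 0.4) -> Tuple[bool, int]:
    """Geometric steric acceptance: no inter-entity pair closer than cutoff.

    Centroid pairs within the same entity are exempt (intra-entity geometry
    is rigid by construction).  Returns (accepted, clash_count).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    tree = cKDTree(assembly.points)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if pairs.size == 0:
        return True, 0
    labels = assembly.labels
    inter = labels[pairs[:, 0]] != labels[pairs[:, 1]]
    n_clashes = int(inter.sum())
    return n_clashes == 0, n_clashes


def sample_library(
    config: AssemblyConfig,
    domain: CentroidModel,
    antibody: CentroidModel,
    strand: Optional[CentroidModel] = None,
    n_target: Optional[int] = 100,
    seed: Optional[int] = None,
    max_attempts: Optional[int] = None,
    min_acceptance: float = 1e-3,
) -> ModelLibrary:
    """Sample clash-free assemblies until ``n_target`` are accepted.

    Each attempt: grow a tetramer chain anchored at a random point on the
    strand surface, dock one antibody per configured domain, then apply the
    clash filter to the whole assembly.  Reproducible under ``seed``.

    With ``n_target=None`` exactly ``max_attempts`` attempts are made and
    every accepted assembly is kept — the mode for acceptance-rate
    experiments.
    """
    if n_target is not None and n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    if strand is None:
        strand = build_agarose_strand(config.strand_radius, config.strand_length,
                                      config.bead_spacing)
    if max_attempts is None:
        if n_target is None:
            raise ValueError("n_target=None requires an explicit max_attempts")
        max_attempts = max(200, 100 * n_target)

    members: List[CentroidModel] = []
    n_attempted = 0
    while (len(members) < (n_target if n_target is not None else np.inf)
           and n_attempted < max_attempts):
        n_attempted += 1
        # random attachment point on the cylinder surface, outward growth
        phi = rng.uniform(0.0, 2.0 * np.pi)
        zz = rng.uniform(-config.strand_length / 4.0, config.strand_length / 4.0)
        outward = np.array([np.cos(phi), np.sin(phi), 0.0])
        # ester-bond contact at centroid resolution: the chain's N-anchor
        # sits one contact distance off the strand surface
        attach = ((config.strand_radius + config.contact_distance) * outward
                  + np.array([0.0, 0.0, zz]))
        try:
            chain = build_tetramer_chain(
                domain, linker_length=config.linker_length,
                start_point=attach, start_direction=outward,
                clash_cutoff=config.clash_cutoff, rng=rng,
            )
        except RuntimeError:
            continue
        assembly = CentroidModel.merge([strand, chain])
        assembly.anchors = dict(chain.anchors)
        assembly.axis = strand.axis
        assembly.meta = {"occupied_domains": ()}
        try:
            for dom in config.bound_domains:
                assembly = dock_antibody(
                    assembly, dom, antibody, rng=rng,
                    contact_distance=config.contact_distance,
                )
        except ValueError:
            continue
        accepted, _ = clash_filter(assembly, cutoff=config.clash_cutoff)
        if accepted:
            members.append(assembly)
    if n_target is not None and len(members) < n_target:
        rate = len(members) / n_attempted if n_attempted else 0.0
        raise RuntimeError(
            f"library under-filled: {len(members)}/{n_target} accepted in "
            f"{n_attempted} attempts (acceptance {rate:.2%}, floor "
            f"{min_acceptance:.2%}) for {config.stoichiometry} on domains "
            f"{config.bound_domains}"
        )
    return ModelLibrary(members=members, config=config, n_attempted=n_attempted,
                        n_accepted=len(members), seed=seed)


def radial_density_of_assembly(
    assembly: CentroidModel, bin_width: float = 0.5
) -> RadialDensity:
    """Radial density of the non-agarose centroids about the strand axis."""
    if assembly.axis is None:
        raise ValueError("assembly carries no strand axis")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    origin, direction = assembly.axis
    direction = direction / np.linalg.norm(direction)
    mask = assembly.labels != "agarose"
    pts = assembly.points[mask]
    if pts.shape[0] == 0:
        raise ValueError("assembly has no non-agarose centroids")
    rel = pts - origin
    proj = rel @ direction
    radial = np.linalg.norm(rel - np.outer(proj, direction), axis=1)
    n_bins = max(1, int(np.ceil(radial.max() / bin_width)))
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(radial, bins=edges)
    density = counts / (pts.shape[0] * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialDensity(centers, density, kind="radial_density",
                         meta={"n_points": int(pts.shape[0])})


def score_similarity(model_density: RadialDensity,
                     experimental_density: RadialDensity) -> float:
    """Symmetric L2 distance between unit-area densities on a common grid."""
    for d in (model_density, experimental_density):
        if d.area() == 0:
            raise ValueError("zero-area density cannot be scored")
    r = np.union1d(model_density.r, experimental_density.r)
    a = np.interp(r, model_density.r, model_density.density, left=0.0, right=0.0)
    b = np.interp(r, experimental_density.r, experimental_density.density,
                  left=0.0, right=0.0)
    a = a / np.trapezoid(a, r)
    b = b / np.trapezoid(b, r)
    return float(np.sqrt(np.trapezoid((a - b) ** 2, r)))


def rank_stoichiometries(
    libraries: Dict[str, ModelLibrary],
    experiment: RadialDensity,
    bin_width: float = 0.5,
) -> pd.DataFrame:
    """Rank stoichiometry arms by their best member's similarity score.

    Returns a DataFrame sorted by best score; ties break toward fewer
    antibodies (parsimony), then lower domain indices.
    """
    if not libraries:
        raise ValueError("no libraries given")
    rows = []
    for name, lib in libraries.items():
        if not lib.members:
            raise ValueError(f"library {name!r} is empty")
        scores = [
            score_similarity(radial_density_of_assembly(m, bin_width), experiment)
            for m in lib.members
        ]
        k = int(np.argmin(scores))
        n_ab = int(lib.config.stoichiometry.split(":")[0])
        rows.append({
            "stoichiometry": lib.config.stoichiometry,
            "bound_domains": lib.config.bound_domains,
            "best_score": scores[k],
            "best_index": k,
            "n_antibodies": n_ab,
        })
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        by=["best_score", "n_antibodies", "bound_domains"],
    ).reset_index(drop=True)
    return frame
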