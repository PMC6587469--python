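"""Readers and writers for the package's on-disk formats.

Scattering curves travel as 3-column ASCII ``.dat`` (q [1/nm], intensity,
optional sigma; ``#`` comments; whitespace or comma separated).  Densities
are 2-column CSV with a JSON sidecar carrying kind/grid/residual metadata.
Centroid models are CSV tables plus coarse-bead PDB output for viewers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .containers import RadialDensity, ScatteringCurve
from .complexes import CentroidModel

__all__ = [
    "read_saxs",
    "write_saxs",
    "read_density",
    "write_density",
    "read_centroids",
    "write_centroids",
    "write_assembly_pdb",
    "read_image",
]

PathLike = Union[str, Path]


def read_saxs(path: PathLike) -> ScatteringCurve:
    """Read a 3-column ASCII scattering curve (q, I[, sigma])."""
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        rows.append([float(x) for x in parts])
    if not rows:
        raise ValueError(f"no data rows in {path}")
    ncol = len(rows[0])
    if ncol not in (2, 3) or any(len(r) != ncol for r in rows):
        raise ValueError(f"expected 2 or 3 columns throughout {path}")
    arr = np.asarray(rows, dtype=float)
    sigma = arr[:, 2] if ncol == 3 else None
    return ScatteringCurve(arr[:, 0], arr[:, 1], sigma,
                           meta={"source": str(path)})


def write_saxs(curve: ScatteringCurve, path: PathLike) -> None:
    """Write a curve in the same ASCII dialect the reader accepts."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# q_per_nm intensity" + (" sigma" if curve.sigma is not None
                                           else "") + "\n")
        for k in range(len(curve)):
            if curve.sigma is not None:
                fh.write(f"{curve.q[k]:.8e} {curve.intensity[k]:.8e} "
                         f"{curve.sigma[k]:.8e}\n")
            else:
                fh.write(f"{curve.q[k]:.8e} {curve.intensity[k]:.8e}\n")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_density(density: RadialDensity, path: PathLike) -> None:
    """Write a density as CSV (r_nm, density) plus a JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"r_nm": density.r, "density": density.density}).to_csv(
        path, index=False)
    meta = {"kind": density.kind,
            "r_min": float(density.r[0]), "r_max": float(density.r[-1]),
            "n": int(density.r.size)}
    for key in ("alpha", "residual_norm", "background", "normalization_scale",
                "weight", "df", "kappa"):
        if key in density.meta:
            meta[key] = float(density.meta[key])
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_density(path: PathLike) -> RadialDensity:
    path = Path(path)
    frame = pd.read_csv(path)
    kind = "pair_density"
    meta: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kind = meta.pop("kind", kind)
    return RadialDensity(frame["r_nm"].to_numpy(), frame["density"].to_numpy(),
                         kind=kind, meta=meta)


def write_centroids(model: CentroidModel, path: PathLike) -> None:
    """Write a centroid model as CSV (label, residue_id, x/y/z in nm)."""
    pd.DataFrame({
        "label": model.labels,
        "residue_id": model.residue_ids,
        "x_nm": model.points[:, 0],
        "y_nm": model.points[:, 1],
        "z_nm": model.points[:, 2],
    }).to_csv(Path(path), index=False)


def read_centroids(path: PathLike, label_override: Optional[str] = None
                   ) -> CentroidModel:
    frame = pd.read_csv(path)
    labels = (np.full(len(frame), label_override, dtype=object)
              if label_override else frame["label"].to_numpy(dtype=object))
    return CentroidModel(
        frame[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float),
        labels,
        frame["residue_id"].to_numpy(),
        meta={"source": str(path)},
    )


def write_assembly_pdb(model: CentroidModel, path: PathLike) -> None:
    """Write a coarse-bead assembly as PDB, one chain per entity."""
    import gemmi

    structure = gemmi.Structure()
    structure.name = "assembly"
    gmodel = gemmi.Model("1")
    chain_ids = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789")
    for entity in model.entities:
        chain = gemmi.Chain(next(chain_ids))
        mask = model.labels == entity
        for i, (pt, rid) in enumerate(zip(model.points[mask],
                                          model.residue_ids[mask]), start=1):
            res = gemmi.Residue()
            res.name = "BEA"
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*(pt * 10.0))  # nm -> Angstrom
            res.add_atom(atom)
            chain.add_residue(res)
        gmodel.add_chain(chain)
    structure.add_model(gmodel)
    structure.write_pdb(str(path))


def read_image(path: PathLike) -> np.ndarray:
    """Read a grayscale image (RGB converted by luminance)."""
    from PIL import Image

    with Image.open(Path(path)) as img:
        arr = np.asarray(img.convert("F"), dtype=float)
    return arr
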