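"""Standard-format I/O: NIfTI / MetaImage volumes, MSH / VTK / STL meshes.

Images use nibabel (NIfTI) and SimpleITK (MetaImage) with an axis-aligned
affine (voxel centers, world mm).  Meshes are written as Gmsh MSH v2.2 and
VTK legacy ASCII (unstructured grid for tet meshes, polydata for surfaces,
point-data vectors for displacement fields); surfaces also round-trip as
STL through trimesh.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import trimesh as _trimesh

from .core_mesh import DEFAULT_LEGEND, LabelImage3D, ScalarImage3D, TetMesh, TriSurface


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    A = np.eye(4)
    A[:3, :3] = np.diag(spacing)
    A[:3, 3] = origin
    return A


def save_image_nifti(path, image: ScalarImage3D) -> None:
    nib.save(nib.Nifti1Image(image.voxels.astype(np.float32), _affine(image.spacing, image.origin)),
             str(path))


def load_image_nifti(path) -> ScalarImage3D:
    img = nib.load(str(path))
    A = img.affine
    spacing = tuple(np.abs(np.diag(A)[:3]))
    return ScalarImage3D(np.asarray(img.dataobj, dtype=float), spacing, tuple(A[:3, 3]))


def save_labels_nifti(path, labels: LabelImage3D) -> None:
    """Integer NIfTI plus a JSON legend sidecar (<path>.legend.json)."""
    nib.save(
        nib.Nifti1Image(labels.labels.astype(np.int16), _affine(labels.spacing, labels.origin)),
        str(path),
    )
    with open(str(path) + ".legend.json", "w") as fh:
        json.dump({str(k): v for k, v in labels.legend.items()}, fh)


def load_labels_nifti(path) -> LabelImage3D:
    img = nib.load(str(path))
    A = img.affine
    legend_path = Path(str(path) + ".legend.json")
    if legend_path.exists():
        with open(legend_path) as fh:
            legend = {int(k): v for k, v in json.load(fh).items()}
    else:
        legend = dict(DEFAULT_LEGEND)
    return LabelImage3D(
        np.asarray(img.dataobj).astype(np.int32),
        legend,
        tuple(np.abs(np.diag(A)[:3])),
        tuple(A[:3, 3]),
    )


def save_image_metaimage(path, image: ScalarImage3D) -> None:
    itk = sitk.GetImageFromArray(np.transpose(image.voxels, (2, 1, 0)).astype(np.float32))
    itk.SetSpacing(tuple(float(s) for s in image.spacing))
    itk.SetOrigin(tuple(float(o) for o in image.origin))
    sitk.WriteImage(itk, str(path))


def load_image_metaimage(path) -> ScalarImage3D:
    itk = sitk.ReadImage(str(path))
    vox = np.transpose(sitk.GetArrayFromImage(itk), (2, 1, 0)).astype(float)
    return ScalarImage3D(vox, tuple(itk.GetSpacing()), tuple(itk.GetOrigin()))


def save_voxel_field_nifti(path, field: np.ndarray, spacing, origin=(0, 0, 0)) -> None:
    """3-component displacement field as a 4-D NIfTI (mm)."""
    nib.save(nib.Nifti1Image(np.asarray(field, dtype=np.float32), _affine(spacing, origin)),
             str(path))


def load_voxel_field_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


# ---------------------------------------------------------------------------
# Tetrahedral meshes: Gmsh MSH v2.2 and VTK legacy unstructured grid
# ---------------------------------------------------------------------------

def save_mesh_msh(path, mesh: TetMesh) -> None:
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y, z) in enumerate(mesh.node_coords, start=1):
            fh.write(f"{i} {x:.12g} {y:.12g} {z:.12g}\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_tets}\n")
        for e, (tet, tag) in enumerate(zip(mesh.tets, mesh.region_tag), start=1):
            a, b, c, d = (int(v) + 1 for v in tet)
            fh.write(f"{e} 4 2 {int(tag)} {int(tag)} {a} {b} {c} {d}\n")
        fh.write("$EndElements\n")


def load_mesh_msh(path) -> TetMesh:
    with open(path) as fh:
        lines = fh.read().split("\n")
    nodes, tets, tags = [], [], []
    i = 0
    while i < len(lines):
        if lines[i].strip() == "$Nodes":
            n = int(lines[i + 1])
            for j in range(n):
                parts = lines[i + 2 + j].split()
                nodes.append([float(v) for v in parts[1:4]])
            i += n + 2
        elif lines[i].strip() == "$Elements":
            n = int(lines[i + 1])
            for j in range(n):
                parts = lines[i + 2 + j].split()
                if int(parts[1]) == 4:  # 4-node tetrahedron
                    ntags = int(parts[2])
                    tags.append(int(parts[3]) if ntags else 1)
                    tets.append([int(v) - 1 for v in parts[3 + ntags:7 + ntags]])
            i += n + 2
        else:
            i += 1
    return TetMesh(np.asarray(nodes), np.asarray(tets), np.asarray(tags))


def save_mesh_vtk(path, mesh: TetMesh, point_vectors: np.ndarray | None = None,
                  vectors_name: str = "displacement") -> None:
    """VTK legacy ASCII unstructured grid, optional point-data vectors."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbrainshift-xfem mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y, z in mesh.node_coords:
            fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
        fh.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        for tet in mesh.tets:
            fh.write("4 " + " ".join(str(int(v)) for v in tet) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        fh.write("\n".join(["10"] * mesh.n_tets) + "\n")
        fh.write(f"CELL_DATA {mesh.n_tets}\nSCALARS region_tag int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(t)) for t in mesh.region_tag) + "\n")
        if point_vectors is not None:
            pv = np.asarray(point_vectors, dtype=float)
            fh.write(f"POINT_DATA {mesh.n_nodes}\nVECTORS {vectors_name} double\n")
            for x, y, z in pv:
                fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")


def load_mesh_vtk(path) -> TetMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    def after(word):
        return tokens.index(word)
    i = after("POINTS")
    n = int(tokens[i + 1])
    pts = np.asarray(tokens[i + 3: i + 3 + 3 * n], dtype=float).reshape(n, 3)
    i = after("CELLS")
    m = int(tokens[i + 1])
    cells = np.asarray(tokens[i + 3: i + 3 + 5 * m], dtype=int).reshape(m, 5)[:, 1:]
    tags = np.ones(m, dtype=np.int32)
    if "region_tag" in tokens:
        i = after("LOOKUP_TABLE")
        tags = np.asarray(tokens[i + 2: i + 2 + m], dtype=np.int32)
    return TetMesh(pts, cells, tags)


# ---------------------------------------------------------------------------
# Surfaces: VTK legacy polydata and STL
# ---------------------------------------------------------------------------

def save_surface_vtk(path, surface: TriSurface, point_vectors: np.ndarray | None = None,
                     vectors_name: str = "displacement") -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbrainshift-xfem surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {surface.n_vertices} double\n")
        for x, y, z in surface.vertices:
            fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
        nt = len(surface.triangles)
        fh.write(f"POLYGONS {nt} {4 * nt}\n")
        for t in surface.triangles:
            fh.write("3 " + " ".join(str(int(v)) for v in t) + "\n")
        data = []
        if point_vectors is not None:
            data.append((vectors_name, np.asarray(point_vectors, dtype=float)))
        if surface.vertex_normals is not None:
            data.append(("normals", surface.vertex_normals))
        if data:
            fh.write(f"POINT_DATA {surface.n_vertices}\n")
            for name, arr in data:
                fh.write(f"VECTORS {name} double\n")
                for x, y, z in arr:
                    fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")


def load_surface_vtk(path) -> TriSurface:
    with open(path) as fh:
        tokens = fh.read().split()
    i = tokens.index("POINTS")
    n = int(tokens[i + 1])
    pts = np.asarray(tokens[i + 3: i + 3 + 3 * n], dtype=float).reshape(n, 3)
    i = tokens.index("POLYGONS")
    m = int(tokens[i + 1])
    tris = np.asarray(tokens[i + 3: i + 3 + 4 * m], dtype=int).reshape(m, 4)[:, 1:]
    surf = TriSurface(pts, tris)
    if "normals" in tokens:
        i = tokens.index("normals")
        surf.vertex_normals = np.asarray(tokens[i + 2: i + 2 + 3 * n], dtype=float).reshape(n, 3)
    return surf


def save_surface_stl(path, surface: TriSurface) -> None:
    _trimesh.Trimesh(surface.vertices, surface.triangles, process=False).export(str(path))


def load_surface_stl(path) -> TriSurface:
    tm = _trimesh.load(str(path), process=True)
    return TriSurface(np.asarray(tm.vertices), np.asarray(tm.faces))
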