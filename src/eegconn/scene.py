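"""Clutter-controlled edge selection and 3D brain-network scene export.

Fractional display modes thin the edge set by recursive mean-splitting:
one pass computes the mean of the surviving weights and, if that mean is
positive, keeps only edges strictly above it (below it when the mean is
negative; strictly positive edges when the mean is exactly zero). The 1/2,
1/4, 1/8 and 1/16 modes apply 1-4 passes, so each mode's edge set nests
inside the previous one and roughly halves per pass.

Edges are styled by sign and magnitude: positive weights render in the
golden-red class, negative in black-white; thickness and opacity grow
linearly with |weight| relative to the strongest edge. Scenes carry
electrode nodes (midline electrodes red, others blue), one white convex
polyhedron per region, two hemisphere polyhedra, and the styled edges --
drawn between electrodes, region centroids, or hemisphere centroids
depending on the visualization level. Scenes serialize to a self-contained
JSON document or a static rendered image.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np

from .aggregate import GroupMatrix
from .errors import DomainError, MontageLookupError
from .metrics import ConnectivityMatrix
from .montage import Montage

MODES = ("full", "1/2", "1/4", "1/8", "1/16")

#: Style constants (scene units); qualitative encoding only.
T_MIN, T_MAX, O_MIN = 0.3, 3.0, 0.15

SCENE_SCHEMA_VERSION = 1


@dataclass
class EdgeSet:
    """Selected unordered edges with their weights, for one display mode."""

    edges: list[tuple[str, str, float]]
    mode: str
    metric: str = ""
    band: str = ""

    def pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class EdgeStyle:
    """Render attributes of one edge."""

    color_class: str  # "golden_red" (weight > 0) or "black_white" (< 0)
    thickness: float
    opacity: float


def mean_split(weights: np.ndarray) -> np.ndarray:
    """One mean-split pass over a weight set: mask of surviving edges.

    Positive mean keeps weights strictly above it; negative mean keeps
    weights strictly below it; an exactly-zero mean keeps the strictly
    positive weights (continuity with the positive branch).
    """
    weights = np.asarray(weights, dtype=float)
    mean = weights.mean()
    if mean > 0:
        return weights > mean
    if mean < 0:
        return weights < mean
    return weights > 0


def threshold_weights(weights: np.ndarray, mode: str) -> np.ndarray:
    """Survivor mask of k recursive mean-split passes (mode ``1/2**k``)."""
    if mode not in MODES:
        raise DomainError(f"mode must be one of {MODES}, got {mode!r}")
    weights = np.asarray(weights, dtype=float)
    keep = np.ones(weights.size, dtype=bool)
    for _ in range(MODES.index(mode)):
        if not keep.any():
            break
        keep[keep] = mean_split(weights[keep])
    return keep


def fractional_threshold(cm: Union[ConnectivityMatrix, GroupMatrix],
                         mode: str = "full") -> EdgeSet:
    """Keep the edges surviving k recursive mean-split passes (mode 1/2^k).

    ``full`` keeps all off-diagonal unordered pairs. Ties at the mean are
    dropped (strict inequality). An empty survivor set at any pass yields
    an empty edge set, not an error.
    """
    labels = cm.labels if isinstance(cm, ConnectivityMatrix) else cm.groups
    n = len(labels)
    ia, ib = np.triu_indices(n, k=1)
    weights = cm.weights[ia, ib]
    keep = threshold_weights(weights, mode)
    edges = [(labels[a], labels[b], float(w))
             for a, b, w in zip(ia[keep], ib[keep], weights[keep])]
    metric = cm.metric
    band = cm.band
    return EdgeSet(edges=edges, mode=mode, metric=metric, band=band)


def edge_style(weight: float, w_absmax: float,
               t_min: float = T_MIN, t_max: float = T_MAX,
               o_min: float = O_MIN) -> EdgeStyle:
    """Style one edge from its signed weight and the scene's |weight| max.

    Color encodes sign; thickness and opacity scale linearly with
    |weight| / w_absmax.
    """
    if w_absmax <= 0:
        raise DomainError("w_absmax must be positive")
    frac = min(abs(weight) / w_absmax, 1.0)
    return EdgeStyle(
        color_class="golden_red" if weight > 0 else "black_white",
        thickness=t_min + (t_max - t_min) * frac,
        opacity=o_min + (1.0 - o_min) * frac,
    )


@dataclass
class Mesh:
    """A polyhedron: vertices plus triangular faces (indices into vertices)."""

    name: str
    vertices: np.ndarray
    faces: list[list[int]]
    color: str = "white"


@dataclass
class Scene:
    """Renderable 3D brain-network scene at one visualization level."""

    level: str  # channel | region | hemisphere
    nodes: list[dict[str, Any]]
    region_meshes: list[Mesh]
    hemisphere_meshes: list[Mesh]
    styled_edges: list[dict[str, Any]]
    meta: dict[str, Any] = field(default_factory=dict)


def _hull_mesh(name: str, pts: np.ndarray, color: str) -> Mesh:
    """Convex hull of a point cloud; degenerate clouds fall back to a fan."""
    from scipy.spatial import ConvexHull, QhullError

    pts = np.asarray(pts, dtype=float)
    if len(pts) >= 4:
        try:
            hull = ConvexHull(pts)
            return Mesh(name=name, vertices=pts,
                        faces=[list(map(int, s)) for s in hull.simplices],
                        color=color)
        except QhullError:
            try:
                hull = ConvexHull(pts, qhull_options="QJ")
                return Mesh(name=name, vertices=pts,
                            faces=[list(map(int, s)) for s in hull.simplices],
                            color=color)
            except QhullError:
                pass
    faces = [[0, i, i + 1] for i in range(1, len(pts) - 1)]
    return Mesh(name=name, vertices=pts, faces=faces, color=color)


def _node_positions(level: str, montage: Montage,
                    labels: tuple[str, ...]) -> dict[str, np.ndarray]:
    if level == "channel":
        return {lab: montage.electrode(lab).coord for lab in labels}
    if level == "region":
        idx = montage.region_index
    elif level == "hemisphere":
        idx = {h: labs for h, labs in montage.hemisphere_index.items()
               if h in ("left", "right") and labs}
    else:
        idx = montage.region_hemisphere_index()
    pos = {}
    for name in labels:
        if name not in idx:
            raise MontageLookupError(f"group {name!r} not derivable from montage")
        pos[name] = montage.coords(idx[name]).mean(axis=0)
    return pos


def build_scene(cm: Union[ConnectivityMatrix, GroupMatrix], montage: Montage,
                level: str = "channel", mode: str = "full") -> Scene:
    """Assemble nodes, region/hemisphere polyhedra and styled edges.

    Channel level takes a :class:`ConnectivityMatrix`; region and
    hemisphere levels take a :class:`GroupMatrix` and draw edges between
    group centroids.
    """
    if level not in ("channel", "region", "hemisphere", "region-hemisphere"):
        raise DomainError(f"unknown scene level {level!r}")
    labels = cm.labels if isinstance(cm, ConnectivityMatrix) else cm.groups
    if isinstance(cm, ConnectivityMatrix):
        missing = [l for l in labels if l not in montage]
        if missing:
            raise MontageLookupError(
                f"labels not in montage: {', '.join(missing)}")
    edge_set = fractional_threshold(cm, mode)
    positions = _node_positions(level, montage, tuple(labels))

    nodes = [{"label": e.label, "coord": e.coord.tolist(),
              "color": "red" if e.hemisphere == "midline" else "blue",
              "region": e.region, "hemisphere": e.hemisphere}
             for e in montage.electrodes]

    region_meshes = [
        _hull_mesh(reg, montage.coords(labs), "white")
        for reg, labs in sorted(montage.region_index.items())
    ]
    hemisphere_meshes = [
        _hull_mesh(h, montage.coords(montage.hemisphere_index[h]), "white")
        for h in ("left", "right") if montage.hemisphere_index[h]
    ]

    absmax = max((abs(w) for _, _, w in edge_set.edges), default=0.0)
    styled = []
    for a, b, w in edge_set.edges:
        if w == 0 or absmax == 0:
            continue  # zero-weight edges are invisible
        st = edge_style(w, absmax)
        styled.append({"a": a, "b": b, "weight": w,
                       "coord_a": positions[a].tolist(),
                       "coord_b": positions[b].tolist(),
                       "style": asdict(st)})
    meta = {"metric": edge_set.metric, "band": edge_set.band, "mode": mode,
            "w_absmax": absmax,
            "style_constants": {"t_min": T_MIN, "t_max": T_MAX, "o_min": O_MIN}}
    return Scene(level=level, nodes=nodes, region_meshes=region_meshes,
                 hemisphere_meshes=hemisphere_meshes, styled_edges=styled,
                 meta=meta)


def _mesh_to_json(m: Mesh) -> dict[str, Any]:
    return {"name": m.name, "vertices": np.asarray(m.vertices).tolist(),
            "faces": m.faces, "color": m.color}


def scene_to_dict(scene: Scene) -> dict[str, Any]:
    return {
        "schema_version": SCENE_SCHEMA_VERSION,
        "level": scene.level,
        "nodes": scene.nodes,
        "region_meshes": [_mesh_to_json(m) for m in scene.region_meshes],
        "hemisphere_meshes": [_mesh_to_json(m) for m in scene.hemisphere_meshes],
        "edges": scene.styled_edges,
        "meta": scene.meta,
    }


def scene_from_dict(doc: dict[str, Any]) -> Scene:
    def mesh(d: dict[str, Any]) -> Mesh:
        return Mesh(name=d["name"], vertices=np.array(d["vertices"]),
                    faces=d["faces"], color=d["color"])

    return Scene(level=doc["level"], nodes=doc["nodes"],
                 region_meshes=[mesh(m) for m in doc["region_meshes"]],
                 hemisphere_meshes=[mesh(m) for m in doc["hemisphere_meshes"]],
                 styled_edges=doc["edges"], meta=doc["meta"])


def export_scene(scene: Scene, path: str | Path,
                 format: str = "scene-json") -> Path:
    """Write a scene as a self-contained JSON document or a static image."""
    path = Path(path)
    if format == "scene-json":
        path.write_text(json.dumps(scene_to_dict(scene), indent=1))
        return path
    if format == "static-image":
        _render_static(scene, path)
        return path
    raise DomainError(f"unknown export format {format!r}")


def load_scene(path: str | Path) -> Scene:
    return scene_from_dict(json.loads(Path(path).read_text()))


def export_dynamic(scenes: list[Scene], out_dir: str | Path,
                   format: str = "scene-json") -> Path:
    """One file per frame plus an index manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "json" if format == "scene-json" else "png"
    names = []
    for t, scene in enumerate(scenes):
        name = f"frame_T{t}.{ext}"
        export_scene(scene, out_dir / name, format)
        names.append(name)
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(
        {"schema_version": SCENE_SCHEMA_VERSION, "n_frames": len(names),
         "frames": names}, indent=1))
    return manifest


def _render_static(scene: Scene, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from mpl_toolkits.mplot3d.art3d import Poly3DCollection

    fig = plt.figure(figsize=(7, 7))
    ax = fig.add_subplot(projection="3d")
    for m in scene.region_meshes:
        verts = np.asarray(m.vertices)
        tris = [verts[f] for f in m.faces]
        ax.add_collection3d(Poly3DCollection(
            tris, facecolor="white", edgecolor="0.8", alpha=0.08))
    for nd in scene.nodes:
        x, y, z = nd["coord"]
        ax.scatter(x, y, z, color=nd["color"], s=12)
    for e in scene.styled_edges:
        st = e["style"]
        color = "darkgoldenrod" if st["color_class"] == "golden_red" else "black"
        xs, ys, zs = zip(e["coord_a"], e["coord_b"])
        ax.plot(xs, ys, zs, color=color, linewidth=st["thickness"],
                alpha=st["opacity"])
    ax.set_axis_off()
    ax.set_title(f"{scene.meta.get('metric', '')} {scene.meta.get('band', '')} "
                 f"{scene.meta.get('mode', '')} ({scene.level})")
    fig.savefig(path, dpi=110)
    plt.close(fig)
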