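"""File contracts: occupancy tables, edge lists, SIF/GraphML, rasters, config.

The occupancy table is the interface between segmentation (manual, in the
original workflow) and everything downstream: one row per
(cell, component, pattern) with columns ``cell_id, component, pattern_id,
x_um, y_um``.  ``component`` ∈ {soma, dendrite, axon}; ``pattern_id`` is
the 1-based serial id of the pattern (−1 for a soma outside every
pattern); ``x_um``/``y_um`` are filled on soma rows only.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connect import ConnectivityGraph
from .geometry import OUTSIDE, OUTSIDE_ID, LatticeSpec
from .simulate import Cell, CircuitAnnotation, SimulationParams

VALID_COMPONENTS = ("soma", "dendrite", "axon")


class ParseError(ValueError):
    """Occupancy-table contract violation, with the offending line number."""


def write_occupancy_table(annotation: CircuitAnnotation, spec: LatticeSpec, path) -> None:
    rows = []
    for cell in annotation.cells:
        soma_id = OUTSIDE_ID if cell.soma_pattern is OUTSIDE else spec.serial_id(cell.soma_pattern)
        rows.append((cell.cell_id, "soma", soma_id, cell.soma_point[0], cell.soma_point[1]))
        for comp, pats in (("dendrite", cell.dendrite_patterns), ("axon", cell.axon_patterns)):
            for pat in sorted(pats, key=spec.serial_id):
                rows.append((cell.cell_id, comp, spec.serial_id(pat), "", ""))
    pd.DataFrame(rows, columns=["cell_id", "component", "pattern_id", "x_um", "y_um"]).to_csv(
        path, index=False
    )


def read_occupancy_table(path, spec: LatticeSpec) -> CircuitAnnotation:
    """Parse and validate an occupancy table into a :class:`CircuitAnnotation`.

    Errors name the 1-based file line (header is line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["cell_id", "component", "pattern_id", "x_um", "y_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s): {', '.join(missing)}")

    somata: dict[int, tuple] = {}
    dend: dict[int, set] = {}
    axon: dict[int, set] = {}

    def fail(i: int, msg: str):
        raise ParseError(f"line {i + 2}: {msg}")

    for i, row in df.iterrows():
        comp = row["component"]
        if comp not in VALID_COMPONENTS:
            fail(i, f"unknown component {comp!r}")
        try:
            cell_id = int(row["cell_id"])
            pattern_id = int(row["pattern_id"])
        except ValueError:
            fail(i, f"non-integer id in {row['cell_id']!r}/{row['pattern_id']!r}")
        if comp == "soma":
            if cell_id in somata:
                fail(i, f"duplicate soma row for cell {cell_id}")
            try:
                x, y = float(row["x_um"]), float(row["y_um"])
            except ValueError:
                fail(i, f"soma row needs numeric x_um/y_um")
            pat = OUTSIDE if pattern_id == OUTSIDE_ID else spec.index_of_serial(pattern_id)
            somata[cell_id] = ((x, y), pat)
        else:
            if pattern_id == OUTSIDE_ID:
                fail(i, f"{comp} rows cannot be OUTSIDE")
            target = dend if comp == "dendrite" else axon
            target.setdefault(cell_id, set()).add(spec.index_of_serial(pattern_id))

    for comp_name, mapping in (("dendrite", dend), ("axon", axon)):
        unknown = set(mapping) - set(somata)
        if unknown:
            raise ParseError(f"{comp_name} rows for unknown cell(s) {sorted(unknown)}")

    cells = []
    for cell_id in sorted(somata):
        (pt, pat) = somata[cell_id]
        cells.append(
            Cell(
                cell_id=cell_id,
                soma_point=pt,
                soma_pattern=pat,
                dendrite_patterns=frozenset(dend.get(cell_id, ())),
                axon_patterns=frozenset(axon.get(cell_id, ())),
            )
        )
    return CircuitAnnotation(cells=tuple(cells))


# -- graph exports ---------------------------------------------------------

def edge_table(graph: ConnectivityGraph) -> pd.DataFrame:
    rows = [
        (pre, post, len(graph.evidence.get((pre, post), ())))
        for pre, post in sorted(graph.edges)
    ]
    return pd.DataFrame(rows, columns=["source_id", "target_id", "n_contact_patterns"])


def write_edges(graph: ConnectivityGraph, path) -> None:
    edge_table(graph).to_csv(path, index=False)


def write_sif(graph: ConnectivityGraph, path) -> None:
    """Cytoscape SIF: one "pre syn post" line per edge; isolated nodes bare."""
    connected = {n for e in graph.edges for n in e}
    with open(path, "w") as fh:
        for pre, post in sorted(graph.edges):
            fh.write(f"{pre} syn {post}\n")
        for node in sorted(graph.nodes - connected):
            fh.write(f"{node}\n")


_GRAPHML_KEYS = [
    ("k_in", "int"), ("k_out", "int"), ("eccentricity", "int"),
    ("closeness", "double"), ("betweenness", "double"), ("tags", "string"),
]


def write_graphml(graph: ConnectivityGraph, path, metrics: dict | None = None) -> None:
    """GraphML export with node metrics as attributes (Cytoscape/Gephi-ready)."""
    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    if metrics is not None:
        for name, typ in _GRAPHML_KEYS:
            ET.SubElement(
                root, "key", id=name, **{"for": "node", "attr.name": name, "attr.type": typ}
            )
    g = ET.SubElement(root, "graph", id="G", edgedefault="directed")
    for node in sorted(graph.nodes):
        el = ET.SubElement(g, "node", id=str(node))
        if metrics is not None and node in metrics:
            m = metrics[node]
            values = {
                "k_in": m.k_in, "k_out": m.k_out, "eccentricity": m.eccentricity,
                "closeness": m.closeness, "betweenness": m.betweenness,
                "tags": ",".join(sorted(m.tags)),
            }
            for name, _ in _GRAPHML_KEYS:
                d = ET.SubElement(el, "data", key=name)
                d.text = str(values[name])
    for i, (pre, post) in enumerate(sorted(graph.edges)):
        ET.SubElement(g, "edge", id=f"e{i}", source=str(pre), target=str(post))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def export_graph(graph: ConnectivityGraph, path, format: str, metrics: dict | None = None) -> None:
    if format == "sif":
        write_sif(graph, path)
    elif format == "graphml":
        write_graphml(graph, path, metrics)
    elif format == "csv":
        write_edges(graph, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def metrics_table(metrics: dict) -> pd.DataFrame:
    rows = [
        (n, m.k_in, m.k_out, m.eccentricity, m.closeness, m.betweenness,
         ";".join(sorted(m.tags)))
        for n, m in sorted(metrics.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["cell_id", "k_in", "k_out", "eccentricity", "closeness", "betweenness", "tags"],
    )


def motif_table(profile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class_id": list(profile.counts),
            "count": list(profile.counts.values()),
            "frequency": [profile.frequencies[c] for c in profile.counts],
        }
    )


# -- configuration ---------------------------------------------------------

@dataclass
class PipelineConfig:
    """Serializable configuration shared by all pipeline stages."""

    lattice: dict = field(default_factory=lambda: {
        "L_um": 55.0, "D_um": 70.0, "rows": 10, "cols": 10,
        "origin_x_um": 0.0, "origin_y_um": 0.0, "rotation_deg": 0.0,
    })
    simulation: dict = field(default_factory=dict)
    detection: dict = field(default_factory=lambda: {"px_per_um": 0.5, "score_min": 0.5})
    analysis: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def lattice_spec(self) -> LatticeSpec:
        lat = self.lattice
        return LatticeSpec(
            edge_length_L=float(lat.get("L_um", 55.0)),
            gap_D=float(lat.get("D_um", 70.0)),
            origin=(float(lat.get("origin_x_um", 0.0)), float(lat.get("origin_y_um", 0.0))),
            rotation=float(lat.get("rotation_deg", 0.0)),
            rows=int(lat.get("rows", 10)),
            cols=int(lat.get("cols", 10)),
        )

    def simulation_params(self) -> SimulationParams:
        sim = dict(self.simulation)
        sim.setdefault("n_cells", 50)
        sim.setdefault("seed", self.seed)
        return SimulationParams(**sim)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "lattice": self.lattice, "simulation": self.simulation,
                    "detection": self.detection, "analysis": self.analysis,
                    "seed": self.seed, "output_dir": str(self.output_dir),
                },
                fh, sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {k: raw[k] for k in ("lattice", "simulation", "detection", "analysis",
                                      "seed", "output_dir") if k in raw}
        return cls(**kwargs)


def write_raster(image: np.ndarray, path) -> None:
    """Write a channel-first stack as multi-page TIFF (or PNG if single page)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(image, dtype=np.float32), photometric="minisblack")
    else:
        import imageio.v3 as iio

        arr = np.asarray(image)
        if arr.ndim == 3:
            arr = np.moveaxis(arr[:3], 0, -1)
        iio.imwrite(path, (np.clip(arr, 0, 1) * 255).astype(np.uint8))


def read_raster(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = np.moveaxis(arr, -1, 0)
    return arr
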