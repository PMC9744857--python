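"""Tissue segments and branched transmission-line network models.

A propagation model is a rooted tree: the root is the transducer/skin
contact point, each edge is one tissue layer or nerve span modelled as an
ideal lossless transmission line (characteristic impedance Z = rho*c,
one-way delay tau = d/c), and every leaf carries a resistor matched to the
impedance of the segment feeding it, so terminal arrivals are absorbed
without re-reflection.

Two anatomical models are built in:

* :func:`cervical_vagus_model` — transducer at the neck; the pulse crosses
  the three skin layers, runs down the vagus trunk and bifurcates into the
  left recurrent laryngeal nerve, the cardiac branch, and — via the
  esophageal plexus three-way split — the hepatic, gastric and
  celiac/splenic pathways (5 terminals, lines T1..T18).
* :func:`site_focused_model` — transducer over the spleen; a strictly
  linear 8-layer chain ending at the splenic nerve (1 terminal, T1..T8).

Per-tissue constants come from a CSV table (`name, density_kg_m3,
speed_m_s, length_m[, reference]`); arbitrary topologies can be described
in a small YAML dialect (see :func:`load_topology`).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .acoustic import AcousticMedium

__all__ = [
    "TissueSegment",
    "TissueTable",
    "NetworkModel",
    "load_tissue_table",
    "default_tissue_table",
    "load_topology",
    "build_network",
    "cervical_vagus_model",
    "site_focused_model",
    "export_spice_netlist",
    "parse_spice_netlist",
]

_TABLE_COLUMNS = ("name", "density_kg_m3", "speed_m_s", "length_m")


@dataclass(frozen=True)
class TissueSegment:
    """One tissue layer / nerve span acting as an ideal transmission line."""

    name: str
    tissue: str
    medium: AcousticMedium
    length_d: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.length_d) and self.length_d > 0):
            raise ValueError(f"segment {self.name!r}: length must be positive, got {self.length_d!r}")

    @property
    def impedance_Z(self) -> float:
        """Characteristic impedance rho*c (rayl), recomputed on access."""
        return self.medium.impedance

    @property
    def delay_tau(self) -> float:
        """One-way delay d/c (s), recomputed on access."""
        return self.length_d / self.medium.speed_c


class TissueTable:
    """Validated per-tissue acoustic constants, keyed by unique name."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _TABLE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"tissue table missing columns: {missing}")
        dup = frame["name"][frame["name"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate tissue names: {dup}")
        for _, row in frame.iterrows():
            for col in ("density_kg_m3", "speed_m_s", "length_m"):
                val = row[col]
                if not (isinstance(val, (int, float)) and math.isfinite(val) and val > 0):
                    raise ValueError(
                        f"tissue {row['name']!r}: {col} must be positive, got {val!r}"
                    )
        self.frame = frame.reset_index(drop=True)
        self._rows = {row["name"]: row for _, row in self.frame.iterrows()}

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, name: str) -> bool:
        return name in self._rows

    @property
    def names(self) -> list[str]:
        return list(self._rows)

    def medium(self, name: str) -> AcousticMedium:
        row = self._row(name)
        return AcousticMedium(float(row["density_kg_m3"]), float(row["speed_m_s"]))

    def length(self, name: str) -> float:
        return float(self._row(name)["length_m"])

    def segment(self, line_id: str, tissue: str) -> TissueSegment:
        return TissueSegment(line_id, tissue, self.medium(tissue), self.length(tissue))

    def _row(self, name: str):
        try:
            return self._rows[name]
        except KeyError:
            raise KeyError(f"tissue {name!r} not found in table (have: {sorted(self._rows)})") from None


def load_tissue_table(path: str | Path) -> TissueTable:
    """Read a tissue-property CSV (name, density_kg_m3, speed_m_s, length_m)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tissue table not found: {path}")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message is the diagnostic
        raise ValueError(f"could not parse tissue table {path}: {exc}") from exc
    return TissueTable(frame)


def default_tissue_table() -> TissueTable:
    """The packaged table of literature acoustic constants and anatomy-based lengths."""
    return load_tissue_table(Path(__file__).parent / "data" / "tissue_properties.csv")


@dataclass
class NetworkModel:
    """Rooted tree of tissue segments with matched terminal loads.

    Attributes
    ----------
    name : str
        Model identifier (used in netlists and reports).
    graph : networkx.DiGraph
        Edges point away from the source; each edge carries its
        ``segment`` (:class:`TissueSegment`).
    source : str
        Root node (where the pulse is imposed).
    terminals : dict
        Leaf node -> matched load resistance (rayl).
    node_labels : dict
        Measurement label (e.g. ``"T7:B+"``) -> node.  The source carries
        the incident label ``"T1:A+"``.
    terminal_names : dict
        Terminal label -> anatomical display name.
    """

    name: str
    graph: nx.DiGraph
    source: str
    terminals: dict[str, float] = field(default_factory=dict)
    node_labels: dict[str, str] = field(default_factory=dict)
    terminal_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.graph
        if g.number_of_nodes() == 0:
            raise ValueError("empty network")
        if not nx.is_arborescence(g):
            raise ValueError("topology must be a rooted tree (single root, no cycles)")
        roots = [n for n in g if g.in_degree(n) == 0]
        if roots != [self.source]:
            raise ValueError(f"declared source {self.source!r} is not the unique root {roots}")
        leaves = {n for n in g if g.out_degree(n) == 0}
        if leaves != set(self.terminals):
            raise ValueError(f"terminal set {set(self.terminals)} does not match leaves {leaves}")
        for leaf, load in self.terminals.items():
            seg = self.upstream_segment(leaf)
            if not math.isclose(load, seg.impedance_Z, rel_tol=1e-12):
                raise ValueError(
                    f"terminal {leaf!r}: load {load} is not matched to upstream impedance {seg.impedance_Z}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def segments(self) -> list[TissueSegment]:
        """Segments in edge-insertion (construction) order."""
        return [d["segment"] for _, _, d in self.graph.edges(data=True)]

    def segment(self, line_id: str) -> TissueSegment:
        for seg in self.segments:
            if seg.name == line_id:
                return seg
        raise KeyError(f"no transmission line {line_id!r} in model {self.name!r}")

    def upstream_segment(self, node: str) -> TissueSegment:
        preds = list(self.graph.predecessors(node))
        if len(preds) != 1:
            raise ValueError(f"node {node!r} has no unique upstream segment")
        return self.graph.edges[preds[0], node]["segment"]

    @property
    def terminal_labels(self) -> list[str]:
        """Measurement labels of the terminal (B+) nodes, in construction order."""
        term_nodes = set(self.terminals)
        return [lab for lab, node in self.node_labels.items() if node in term_nodes]

    def path_delay(self, node: str) -> float:
        """Sum of segment delays d/c along the root -> node path."""
        path = nx.shortest_path(self.graph, self.source, node)
        return sum(
            self.graph.edges[u, v]["segment"].delay_tau for u, v in zip(path, path[1:])
        )


def build_network(table: TissueTable, topology_spec: Mapping, name: str | None = None) -> NetworkModel:
    """Assemble a :class:`NetworkModel` from a structured topology description.

    The spec is a mapping with keys:

    * ``source`` — name of the root node;
    * ``lines`` — ordered list of ``{id, tissue, from, to}`` records, one
      per transmission line (``tissue`` must exist in *table*);
    * ``terminal_labels`` (optional) — map line id -> anatomical name for
      lines ending at leaves.

    Leaves automatically receive matched loads; every line's output node
    gets the measurement label ``"<id>:B+"`` and the source node the
    incident label ``"T1:A+"``.
    """
    try:
        source = topology_spec["source"]
        lines = topology_spec["lines"]
    except KeyError as exc:
        raise ValueError(f"topology spec missing required key {exc}") from exc
    if not lines:
        raise ValueError("topology spec declares no transmission lines")

    missing = sorted({ln["tissue"] for ln in lines} - set(table.names))
    if missing:
        raise ValueError(f"topology references tissues absent from table: {missing}")

    g = nx.DiGraph()
    seen_ids: set[str] = set()
    b_plus: dict[str, str] = {}
    for ln in lines:
        lid, u, v = ln["id"], ln["from"], ln["to"]
        if lid in seen_ids:
            raise ValueError(f"duplicate transmission line id {lid!r}")
        seen_ids.add(lid)
        if g.has_edge(u, v):
            raise ValueError(f"parallel lines between {u!r} and {v!r}")
        g.add_edge(u, v, segment=table.segment(lid, ln["tissue"]))
        b_plus[lid] = v

    if source not in g:
        raise ValueError(f"declared source node {source!r} is not used by any line")

    terminals = {
        n: next(iter(g.pred[n].values()))["segment"].impedance_Z
        for n in g
        if g.out_degree(n) == 0
    }
    node_labels = {"T1:A+": source}
    node_labels.update({f"{lid}:B+": node for lid, node in b_plus.items()})

    terminal_names = {}
    for lid, display in dict(topology_spec.get("terminal_labels", {})).items():
        if lid not in b_plus:
            raise ValueError(f"terminal_labels references unknown line {lid!r}")
        if b_plus[lid] not in terminals:
            raise ValueError(f"terminal_labels line {lid!r} does not end at a leaf")
        terminal_names[f"{lid}:B+"] = display

    return NetworkModel(
        name=name or topology_spec.get("name", "network"),
        graph=g,
        source=source,
        terminals=terminals,
        node_labels=node_labels,
        terminal_names=terminal_names,
    )


def load_topology(path: str | Path) -> dict:
    """Read a YAML topology file (keys: name, source, lines, terminal_labels)."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, Mapping):
        raise ValueError(f"topology file {path} did not parse to a mapping")
    return dict(spec)


# ---------------------------------------------------------------------------
# Built-in anatomical models
# ---------------------------------------------------------------------------

#: line id, tissue row, upstream node, downstream node
_CERVICAL_LINES: list[tuple[str, str, str, str]] = [
    ("T1", "epidermis", "transducer", "n1"),
    ("T2", "dermis", "n1", "n2"),
    ("T3", "subcutaneous_tissue", "n2", "n3"),
    ("T4", "vagus_trunk_cervical", "n3", "lrln_branch"),
    ("T5", "lrln_descending", "lrln_branch", "n5"),
    ("T6", "lrln_ascending", "n5", "n6"),
    ("T7", "lrln_terminal", "n6", "lrln_end"),
    ("T8", "vagus_trunk_thoracic", "lrln_branch", "cardiac_branch_pt"),
    ("T9", "cardiac_branch", "cardiac_branch_pt", "cardiac_end"),
    ("T10", "anterior_vagal_trunk", "cardiac_branch_pt", "n8"),
    ("T11", "esophageal_plexus", "n8", "esophageal_split"),
    ("T12", "celiac_branch", "esophageal_split", "n10"),
    ("T13", "celiac_plexus", "n10", "n11"),
    ("T14", "splenic_nerve", "n11", "splenic_end"),
    ("T15", "hepatic_branch", "esophageal_split", "n12"),
    ("T16", "hepatic_plexus", "n12", "hepatic_end"),
    ("T17", "gastric_branch", "esophageal_split", "n13"),
    ("T18", "gastric_plexus", "n13", "gastric_end"),
]

_CERVICAL_TERMINALS = {
    "T7": "Left Recurrent Laryngeal Nerve",
    "T9": "Cardiac Plexus",
    "T16": "Hepatic Plexus",
    "T18": "Gastric Plexus",
    "T14": "Splenic Nerve",
}

_SITE_FOCUSED_LINES: list[tuple[str, str, str, str]] = [
    ("T1", "epidermis", "transducer", "n1"),
    ("T2", "dermis", "n1", "n2"),
    ("T3", "subcutaneous_tissue", "n2", "n3"),
    ("T4", "intercostal_muscle", "n3", "n4"),
    ("T5", "diaphragm", "n4", "n5"),
    ("T6", "spleen_capsule", "n5", "n6"),
    ("T7", "spleen", "n6", "n7"),
    ("T8", "splenic_nerve", "n7", "splenic_end"),
]

_SITE_FOCUSED_TERMINALS = {"T8": "Splenic Nerve"}


def _builder_spec(name: str, lines, terminals) -> dict:
    return {
        "name": name,
        "source": "transducer",
        "lines": [{"id": i, "tissue": t, "from": u, "to": v} for i, t, u, v in lines],
        "terminal_labels": dict(terminals),
    }


def cervical_vagus_model(table: TissueTable) -> NetworkModel:
    """Cervical stimulation model: skin -> vagus trunk -> 5 efferent terminals.

    Terminals: left recurrent laryngeal nerve (T7:B+), cardiac plexus
    (T9:B+), hepatic plexus (T16:B+), gastric plexus (T18:B+) and splenic
    nerve (T14:B+); the esophageal plexus splits three ways.
    """
    return build_network(table, _builder_spec("cervical_vagus", _CERVICAL_LINES, _CERVICAL_TERMINALS))


def site_focused_model(table: TissueTable) -> NetworkModel:
    """Site-focused splenic stimulation: a linear 8-layer chain ending at T8:B+."""
    return build_network(
        table, _builder_spec("site_focused_splenic", _SITE_FOCUSED_LINES, _SITE_FOCUSED_TERMINALS)
    )


# ---------------------------------------------------------------------------
# SPICE netlist round trip
# ---------------------------------------------------------------------------

def export_spice_netlist(model: NetworkModel, source) -> str:
    """Emit a SPICE-style netlist: one ideal T-element per segment, a pulsed
    voltage source at the root, matched terminal resistors, all negative
    rails grounded (node 0).

    *source* needs ``amplitude`` (V), ``period`` and ``width`` (s).
    """
    out = [f"* sonoline netlist: {model.name}"]
    out.append(
        f"V1 {model.source} 0 PULSE(0 {source.amplitude!r} 0 1e-09 1e-09 "
        f"{source.width!r} {source.period!r})"
    )
    for u, v, data in model.graph.edges(data=True):
        seg = data["segment"]
        out.append(f"{seg.name} {u} 0 {v} 0 Z0={seg.impedance_Z!r} TD={seg.delay_tau!r}")
    for i, (leaf, load) in enumerate(sorted(model.terminals.items()), start=1):
        out.append(f"R{i} {leaf} 0 {load!r}")
    out.append(".END")
    return "\n".join(out) + "\n"


_T_CARD = re.compile(
    r"^(?P<id>T\w+)\s+(?P<ap>\S+)\s+0\s+(?P<bp>\S+)\s+0\s+Z0=(?P<z0>\S+)\s+TD=(?P<td>\S+)$"
)
_R_CARD = re.compile(r"^R\w+\s+(?P<node>\S+)\s+0\s+(?P<val>\S+)$")
_V_CARD = re.compile(r"^V\w+\s+(?P<node>\S+)\s+0\s+PULSE\((?P<args>[^)]*)\)$")


def parse_spice_netlist(text: str) -> nx.DiGraph:
    """Parse an emitted netlist back into a graph (edges carry z0, td, line).

    The returned graph has ``graph['source']`` (the V-card node) and
    ``graph['loads']`` (leaf node -> resistance), so
    ``parse_spice_netlist(export_spice_netlist(m, s))`` reproduces the
    topology and element values of ``m`` exactly.
    """
    g = nx.DiGraph()
    loads: dict[str, float] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("*") or line.startswith("."):
            continue
        m = _T_CARD.match(line)
        if m:
            g.add_edge(m["ap"], m["bp"], line=m["id"], z0=float(m["z0"]), td=float(m["td"]))
            continue
        m = _R_CARD.match(line)
        if m:
            loads[m["node"]] = float(m["val"])
            continue
        m = _V_CARD.match(line)
        if m:
            g.graph["source"] = m["node"]
            g.graph["pulse_args"] = [float(x) for x in m["args"].split()]
            continue
        raise ValueError(f"unrecognised netlist card: {line!r}")
    g.graph["loads"] = loads
    return g
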