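"""Serialization: trajectory tables, causal-diagram export, run manifests.

Trajectories travel as CSV (``week,<var1>,<var2>,...``, full float
precision, lossless round trip); model graphs as JSON (see
:meth:`engine.ModelGraph.to_json`); causal loop diagrams as Graphviz DOT
text with nodes grouped by process, edges labeled by polarity and delayed
links drawn dashed.  A :class:`RunManifest` records what a command ran and
the SHA-256 digests of what it wrote, so a run can be replayed and checked
for bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import FeedbackLoop, ModelGraph, TrajectorySet, ValidationError

__all__ = [
    "write_trajectory_table",
    "read_trajectory_table",
    "export_cld",
    "parse_cld_counts",
    "RunManifest",
    "file_digest",
    "PROCESS_COLORS",
]

#: Display colors of the four processes of the full model's causal diagram.
PROCESS_COLORS = {
    "regulating demands": "lightblue",
    "regulating effort": "palegreen",
    "impacts on body and mind": "lightcoral",
    "burnout symptoms": "plum",
}


def write_trajectory_table(traj: TrajectorySet, path) -> Path:
    """Write a trajectory as ``week,<vars...>`` CSV (lossless precision)."""
    if not traj.series:
        raise ValidationError("refusing to write a trajectory with no variables")
    path = Path(path)
    frame = pd.DataFrame({"week": traj.times, **traj.series})
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trajectory_table(path) -> TrajectorySet:
    """Read a trajectory CSV written by :func:`write_trajectory_table`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if "week" not in frame.columns:
        raise ValidationError(f"{path}: missing 'week' column")
    variables = [c for c in frame.columns if c != "week"]
    if not variables:
        raise ValidationError(f"{path}: no variable columns besides 'week'")
    return TrajectorySet(
        times=frame["week"].to_numpy(dtype=float),
        series={c: frame[c].to_numpy(dtype=float) for c in variables},
    )


# --------------------------------------------------------------------------
# Causal-diagram export
# --------------------------------------------------------------------------


def _dot_id(name: str) -> str:
    return '"' + name.replace('"', r"\"") + '"'


def export_cld(model: ModelGraph, path,
               processes: dict[str, str] | None = None,
               loops: dict[str, FeedbackLoop] | None = None) -> Path:
    """Write the model's causal loop diagram as a Graphviz DOT file.

    ``processes`` maps variable names to process groups (one colored
    cluster per process); unknown process tags raise a validation error.
    ``loops`` adds named feedback loops as graph-level annotations.
    """
    processes = processes or {}
    unknown = sorted(set(processes.values()) - set(PROCESS_COLORS))
    if unknown:
        raise ValidationError(f"unknown process tag(s): {', '.join(unknown)}")
    lines = ["digraph model {", "  rankdir=LR;", "  node [shape=box, style=filled];"]
    if loops:
        for name, loop in sorted(loops.items()):
            sign = "R" if loop.polarity == "reinforcing" else "B"
            lines.append(
                f"  // loop [{sign}] {name}: {' -> '.join(loop.cycle)}"
            )
    by_process: dict[str, list[str]] = {}
    ungrouped = []
    for var in sorted(model.variables):
        tag = processes.get(var)
        if tag is None:
            ungrouped.append(var)
        else:
            by_process.setdefault(tag, []).append(var)
    for i, (tag, members) in enumerate(sorted(by_process.items())):
        lines.append(f"  subgraph cluster_{i} {{")
        lines.append(f'    label="{tag}";')
        lines.append(f'    node [fillcolor="{PROCESS_COLORS[tag]}"];')
        for var in members:
            lines.append(f"    {_dot_id(var)};")
        lines.append("  }")
    for var in ungrouped:
        lines.append(f"  {_dot_id(var)} [fillcolor=white];")
    for e in sorted(model.edges):
        style = ', style=dashed' if e.delayed else ""
        lines.append(
            f'  {_dot_id(e.source)} -> {_dot_id(e.target)} [label="{e.sign}"{style}];'
        )
    lines.append("}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


_DOT_EDGE = re.compile(r'^\s*"(?P<src>(?:[^"\\]|\\.)*)"\s*->\s*"(?P<dst>(?:[^"\\]|\\.)*)"')
_DOT_NODE = re.compile(r'^\s*"(?P<name>(?:[^"\\]|\\.)*)"\s*(?:\[[^\]]*\])?;')
_DOT_LOOP = re.compile(r"^\s*// loop \[(?P<pol>[RB])\] (?P<name>[^:]+):")


def parse_cld_counts(path) -> dict[str, int]:
    """Node/edge/cluster/loop counts of a DOT file written by export_cld."""
    nodes, edges, clusters, loops = set(), 0, 0, 0
    for line in Path(path).read_text().splitlines():
        if _DOT_LOOP.match(line):
            loops += 1
        elif "subgraph cluster_" in line:
            clusters += 1
        elif _DOT_EDGE.match(line):
            edges += 1
            m = _DOT_EDGE.match(line)
            nodes.add(m.group("src"))
            nodes.add(m.group("dst"))
        else:
            m = _DOT_NODE.match(line)
            if m:
                nodes.add(m.group("name"))
    return {"nodes": len(nodes), "edges": edges, "clusters": clusters,
            "loops": loops}


# --------------------------------------------------------------------------
# Run manifests
# --------------------------------------------------------------------------


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Record of one command invocation and the digests of its outputs."""

    command: str
    argv: list[str]
    config: dict
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "RunManifest":
        return cls(**json.loads(source))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls.from_json(Path(path).read_text())

    def verify_outputs(self) -> dict[str, bool]:
        """Compare recorded digests with the files currently on disk."""
        return {
            path: Path(path).exists() and file_digest(path) == digest
            for path, digest in self.outputs.items()
        }
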