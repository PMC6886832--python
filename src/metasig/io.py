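"""Readers and writers for the pipeline's tabular formats.

Matrices travel as TSV (first column metabolite identifier, header row of
sample identifiers; TSV because metabolite names routinely contain
commas), group labels as a two-column TSV, pathway libraries as standard
GMT (name, description, tab-separated members), and dendrograms as Newick
with branch lengths derived from merge heights.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import to_tree

from .exceptions import ValidationError
from .matrix import MetaboliteMatrix
from .simulate import PathwayLibrary

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_groups",
    "write_groups",
    "read_gmt",
    "write_gmt",
    "linkage_to_newick",
]

_FLOAT_FMT = "%.17g"  # shortest round-trippable float precision


def write_matrix(matrix: MetaboliteMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "metabolite"
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path, group_labels: dict[str, str] | None = None) -> MetaboliteMatrix:
    """Read a metabolite x sample TSV, validating every cell.

    Raises :class:`ValidationError` naming the offending cell for negative
    or non-numeric entries and for duplicate identifiers.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        sample_ids = header[1:]
        if not sample_ids:
            raise ValidationError(f"{path}: header has no sample columns")
        met_ids: list[str] = []
        rows: list[list[float]] = []
        for line_no, rec in enumerate(reader, start=2):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) != len(sample_ids) + 1:
                raise ValidationError(
                    f"{path}:{line_no}: expected {len(sample_ids) + 1} fields, "
                    f"got {len(rec)}"
                )
            met_ids.append(rec[0])
            vals = []
            for j, cell in enumerate(rec[1:]):
                try:
                    v = float(cell)
                except ValueError:
                    raise ValidationError(
                        f"{path}:{line_no}: non-numeric value {cell!r} for "
                        f"metabolite {rec[0]!r}, sample {sample_ids[j]!r}"
                    ) from None
                if not np.isfinite(v):
                    raise ValidationError(
                        f"{path}:{line_no}: non-finite value for metabolite "
                        f"{rec[0]!r}, sample {sample_ids[j]!r}"
                    )
                if v < 0:
                    raise ValidationError(
                        f"{path}:{line_no}: negative value {v} for metabolite "
                        f"{rec[0]!r}, sample {sample_ids[j]!r}"
                    )
                vals.append(v)
            rows.append(vals)
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    return MetaboliteMatrix(
        values=np.asarray(rows, dtype=float),
        metabolite_ids=met_ids,
        sample_ids=sample_ids,
        group_labels=group_labels,
    )


def write_groups(group_labels: dict[str, str], path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "group"])
        for sample, group in group_labels.items():
            writer.writerow([sample, group])


def read_groups(path) -> dict[str, str]:
    path = Path(path)
    labels: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValidationError(f"{path}: empty group file")
        for line_no, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != 2:
                raise ValidationError(f"{path}:{line_no}: expected 2 fields")
            sample, group = rec
            if sample in labels:
                raise ValidationError(f"{path}:{line_no}: duplicate sample {sample!r}")
            labels[sample] = group
    return labels


def read_gmt(path, universe: set[str] | None = None) -> PathwayLibrary:
    """Read a GMT pathway file.

    Members are de-duplicated per pathway; the universe defaults to the
    union of all members unless supplied explicitly.
    """
    path = Path(path)
    pathways: dict[str, set[str]] = {}
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{line_no}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name = fields[0]
            if name in pathways:
                raise ValidationError(f"{path}:{line_no}: duplicate pathway {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise ValidationError(f"{path}:{line_no}: pathway {name!r} is empty")
            pathways[name] = members
    if not pathways:
        raise ValidationError(f"{path}: no pathways")
    if universe is None:
        universe = set().union(*pathways.values())
    return PathwayLibrary(pathways=pathways, universe=universe)


def write_gmt(library: PathwayLibrary, path, description: str = "na") -> None:
    with Path(path).open("w") as fh:
        for name in sorted(library.pathways):
            members = sorted(library.pathways[name])
            fh.write("\t".join([name, description, *members]) + "\n")


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string.

    Branch lengths are the difference between a node's merge height and
    its child's, so root-to-leaf path lengths equal merge heights.
    """
    tree = to_tree(Z)

    def fmt(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    inner = (
        f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)})"
        if not tree.is_leaf()
        else leaf_names[tree.id]
    )
    return inner + ";"
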