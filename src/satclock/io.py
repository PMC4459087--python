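"""File formats: Newick trees, FASTA alignments, TSV tables, JSON configs.

Newick chronograms carry branch lengths in MY; dated trees are written with
each internal node's age as a node label of the form ``age=12.34`` (a plain
label, readable by any Newick parser).  Calibration tables are TSV with
columns ``clade_taxa`` (comma-separated), ``min_age``, ``shape``, ``spread``
and optionally ``label`` and ``soft_max``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calibrations import CalibrationPrior
from .distances import DistanceMatrix
from .grid import RunConfig
from .simulate import Alignment
from .trees import Chronogram

__all__ = [
    "read_newick",
    "write_newick",
    "write_dated_newick",
    "read_calibrations",
    "write_calibrations",
    "read_fasta",
    "write_fasta",
    "read_distances",
    "write_distances",
    "read_run_grid",
    "write_run_grid",
    "write_age_table",
]


# -- trees ------------------------------------------------------------------


def read_newick(path) -> Chronogram:
    """Parse a Newick file into a Chronogram (branch lengths in MY if present)."""
    return Chronogram.from_newick_path(path)


def write_newick(tree: Chronogram, path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def write_dated_newick(tree: Chronogram, estimates, path) -> None:
    """Write the topology with estimated ages as internal node labels."""
    by_clade = {e.clade: e for e in estimates}
    clone = tree.tree.clone(depth=1)
    for node in clone.postorder_internal_node_iter():
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        if clade in by_clade:
            node.label = f"age={by_clade[clade].point_age:.4g}"
    text = clone.as_string(schema="newick", unquoted_underscores=True, suppress_rooting=True)
    Path(path).write_text(text.strip() + "\n")


# -- calibrations -----------------------------------------------------------


def read_calibrations(path) -> list[CalibrationPrior]:
    """Read a TSV calibration table; returns [] for an empty file."""
    text = Path(path).read_text().strip()
    if not text:
        return []
    df = pd.read_csv(path, sep="\t")
    required = {"clade_taxa", "min_age", "shape", "spread"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration table lacks columns: {sorted(missing)}")
    priors = []
    for i, row in df.iterrows():
        soft_max = row.get("soft_max")
        priors.append(
            CalibrationPrior(
                label=str(row.get("label", f"calibration_{i}")),
                clade=frozenset(str(row["clade_taxa"]).split(",")),
                min_age=float(row["min_age"]),
                shape=str(row["shape"]),
                spread=float(row["spread"]),
                soft_max=None if pd.isna(soft_max) else float(soft_max),
            )
        )
    return priors


def write_calibrations(priors: Sequence[CalibrationPrior], path) -> None:
    rows = [
        {
            "label": c.label,
            "clade_taxa": ",".join(sorted(c.clade)),
            "min_age": c.min_age,
            "shape": c.shape,
            "spread": c.spread,
            "soft_max": c.soft_max if c.soft_max is not None else "",
        }
        for c in priors
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- sequences and distances ------------------------------------------------


def read_fasta(path, locus: Optional[str] = None) -> Alignment:
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no sequences in {path}")
    return Alignment.from_sequences(locus or Path(path).stem, records)


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(alignment.sequence(label)), id=label, description="")
        for label in alignment.labels
    ]
    SeqIO.write(records, str(path), "fasta")


def read_distances(path, locus: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(tuple(df.index), df.values, locus or Path(path).stem)


def write_distances(dist: DistanceMatrix, path) -> None:
    pd.DataFrame(dist.values, index=dist.labels, columns=dist.labels).to_csv(path, sep="\t")


# -- run grids and results --------------------------------------------------


def write_run_grid(grid: Sequence[RunConfig], path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in grid], indent=1) + "\n")


def read_run_grid(path) -> list[RunConfig]:
    return [RunConfig.from_dict(d) for d in json.loads(Path(path).read_text())]


def write_age_table(result, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)
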