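"""Readers and writers for the pipeline's exchange formats.

CSV/TSV use comma (resp. tab) separators, "." decimals and UTF-8 with a
required header.  Sequence coordinates are 1-based in all outputs; frame
indices in trace outputs are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .frap import IntensityTrace
from .phylo import Alignment, SupportTree

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "read_fasta",
    "write_fasta",
    "write_newick",
    "read_newick",
    "load_config",
]

_TRACE_COLUMNS = ["nucleus_id", "frame", "time_s", "phase", "roi_mean", "nucleus_mean"]


def write_traces_csv(traces: Sequence[IntensityTrace], path: str | Path) -> None:
    """Write traces as CSV with columns nucleus_id, frame, time_s, phase,
    roi_mean, nucleus_mean (frame indices 0-based within each trace)."""
    frames = []
    for trace in traces:
        frames.append(pd.DataFrame({
            "nucleus_id": trace.nucleus_id,
            "frame": np.arange(len(trace.times)),
            "time_s": trace.times,
            "phase": trace.phase.astype(str),
            "roi_mean": trace.roi_mean,
            "nucleus_mean": trace.nucleus_mean,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[IntensityTrace]:
    """Read traces written by :func:`write_traces_csv`.

    Rows are grouped by nucleus_id and ordered by frame, so a shuffled
    file loads identically.  Phase contiguity and the five-pre-bleach-frame
    minimum are validated per nucleus.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    traces = []
    for nucleus_id, group in df.groupby("nucleus_id", sort=True):
        group = group.sort_values("frame")
        traces.append(IntensityTrace(
            times=group["time_s"].to_numpy(dtype=float),
            roi_mean=group["roi_mean"].to_numpy(dtype=float),
            nucleus_mean=group["nucleus_mean"].to_numpy(dtype=float),
            phase=group["phase"].to_numpy(dtype=object),
            nucleus_id=str(nucleus_id),
        ))
    return traces


def read_fasta(path: str | Path, aligned: bool = False):
    """Read FASTA records as (name, sequence) pairs, or as an
    :class:`~chromodyn.phylo.Alignment` when ``aligned`` is set (equal
    lengths enforced).  Duplicate headers are rejected."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    names = [n for n, _ in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate FASTA headers")
    if not aligned:
        return records
    return Alignment(taxa=tuple(names), rows=tuple(s for _, s in records))


def write_fasta(records, path: str | Path) -> None:
    """Write (name, sequence) pairs or an Alignment as FASTA."""
    if isinstance(records, Alignment):
        records = list(zip(records.taxa, records.rows))
    seq_records = [SeqRecord(Seq(s), id=n, description="") for n, s in records]
    SeqIO.write(seq_records, str(path), "fasta")


def write_newick(tree: SupportTree | dendropy.Tree, path: str | Path) -> None:
    """Write a tree as single-line newick, branch lengths and integer
    bootstrap supports (internal node labels) included.  Taxon labels with
    reserved characters are quoted."""
    dtree = tree.tree if isinstance(tree, SupportTree) else tree
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=False,
        preserve_spaces=False,
    ).strip() + "\n"
    Path(path).write_text(text, encoding="utf-8")


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=False,
    )


def load_config(path: str | Path) -> dict:
    """Load a pipeline/stage configuration from YAML or JSON."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
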