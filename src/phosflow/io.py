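"""Readers and writers for the pipeline's external formats.

FASTA for proteins (via Biopython), TSV for site quantification / design /
PPI edges / kinase exemplars / annotations, and SIF or GraphML for the
kinase-regulatory network.  Every reader is total on the grammar produced by
the matching writer (round-trip property, fuzz-tested with the synthetic
generator).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AA20_SET,
    AnnotationTable,
    ParseError,
    PhosphoSite,
    ProteinRecord,
    QuantTable,
    extract_window,
)

logger = logging.getLogger("phosflow")

META_COLUMNS = ("protein_id", "position", "residue")


def read_fasta(path: str | Path, permissive: bool = False) -> list[ProteinRecord]:
    """Read a protein FASTA into a list of :class:`ProteinRecord`.

    Sequences are uppercased.  Characters outside the 20-letter alphabet are
    rejected unless ``permissive`` is set, in which case they are mapped to
    'X'.  Duplicate ids and empty sequences raise :class:`ParseError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if not pid:
            raise ParseError(f"{path}: record with empty header")
        if pid in seen:
            raise ParseError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for {pid!r}")
        if permissive:
            seq = "".join(c if c in AA20_SET else "X" for c in seq)
        prot = ProteinRecord(pid, seq)
        prot.validate_alphabet()
        records.append(prot)
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample, condition) into a design map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "condition"]:
        raise ParseError(f"{path}: design file must have columns sample, condition")
    return dict(zip(df["sample"], df["condition"]))


def write_design(design: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(design), "condition": [design[s] for s in design]}
    ).to_csv(path, sep="\t", index=False)


def read_site_table(
    path: str | Path,
    proteins: Sequence[ProteinRecord],
    design: dict[str, str] | str | Path,
    strict: bool = True,
    flank: int = 6,
) -> tuple[list[PhosphoSite], QuantTable]:
    """Read a site-level quantification TSV.

    Expected header: protein_id, position, residue, then one column per
    sample.  Windows are recomputed from the protein sequences and validated;
    in strict mode a residue mismatch (table vs sequence) raises, otherwise
    the row is logged and dropped.
    """
    if not isinstance(design, dict):
        design = read_design(design)
    by_id = {p.protein_id: p for p in proteins}
    df = pd.read_csv(
        path, sep="\t", dtype={"protein_id": str, "residue": str},
        float_precision="round_trip",
    )
    for col in META_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns")

    sites: list[PhosphoSite] = []
    keep: list[int] = []
    for i, row in enumerate(df.itertuples(index=False)):
        pid, pos, res = row.protein_id, int(row.position), row.residue
        prot = by_id.get(pid)
        if prot is None:
            raise ParseError(f"{path}: unknown protein_id {pid!r}")
        if res not in "STY":
            raise ParseError(f"{path}: {pid} position {pos}: residue {res!r} not in S/T/Y")
        actual = prot.sequence[pos - 1] if 1 <= pos <= len(prot) else None
        if actual != res:
            msg = (
                f"{pid} position {pos}: table residue {res!r} does not match "
                f"sequence character {actual!r}"
            )
            if strict:
                raise ParseError(f"{path}: {msg}")
            logger.warning("dropping site: %s", msg)
            continue
        sites.append(PhosphoSite(pid, pos, res, extract_window(prot, pos, flank)))
        keep.append(i)

    quant_df = df.iloc[keep][sample_cols].copy()
    quant_df.index = pd.Index([s.site_id for s in sites], name="site_id")
    quant = QuantTable(quant_df.astype(float), dict(design))
    quant.validate()
    logger.info("read %d sites x %d samples from %s", len(sites), len(sample_cols), path)
    return sites, quant


def write_site_table(
    sites: Sequence[PhosphoSite], quant: QuantTable, path: str | Path
) -> None:
    meta = pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in sites],
            "position": [s.position for s in sites],
            "residue": [s.residue for s in sites],
        },
        index=pd.Index([s.site_id for s in sites], name="site_id"),
    )
    out = meta.join(quant.intensities)
    out.to_csv(path, sep="\t", index=False)


def read_ppi(path: str | Path) -> set[frozenset[str]]:
    """Read an undirected PPI edge TSV (two protein ids per line, header
    ``protein_a<TAB>protein_b``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: PPI table needs two columns")
    a, b = df.columns[:2]
    return {frozenset((x, y)) for x, y in zip(df[a], df[b])}


def write_ppi(edges: Iterable[frozenset[str]], path: str | Path) -> None:
    rows = sorted(tuple(sorted(e)) for e in edges)
    pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AnnotationTable(df)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network export


def write_network(network: nx.DiGraph, path: str | Path, fmt: str = "sif") -> None:
    """Export a kinase->site network as SIF or GraphML.

    SIF lines are ``kinase<TAB>regulates<TAB>site_id``, sorted by
    (kinase, site) for byte-stable output.  GraphML carries node ``type``
    (kinase|site), ``state``/``status`` and numeric score attributes and is
    written with networkx (re-parseable by any XML reader).
    """
    fmt = fmt.lower()
    if fmt == "sif":
        lines = sorted(
            f"{u}\t{d.get('relation', 'regulates')}\t{v}"
            for u, v, d in network.edges(data=True)
        )
        Path(path).write_text("".join(line + "\n" for line in lines))
    elif fmt == "graphml":
        clean = nx.DiGraph()
        for n, d in network.nodes(data=True):
            clean.add_node(n, **{k: v for k, v in d.items() if v is not None})
        for u, v, d in network.edges(data=True):
            clean.add_edge(u, v, **{k: v for k, v in d.items() if v is not None})
        nx.write_graphml(clean, str(path))
    else:
        raise ValueError(f"unknown network format {fmt!r}; use 'sif' or 'graphml'")
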