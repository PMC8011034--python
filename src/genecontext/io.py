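"""Readers and writers for the external file formats.

Reads: gene tables (GFF3 via gffutils, or the canonical TSV dialect),
HMMER3 per-domain tables (domtblout, via Bio.SearchIO), OrthoMCL "groups"
text, the R-M reference TSV and a taxonomy TSV. Writes: tabular reports
(TSV with header), networks as SIF + GraphML, and a run manifest.

The canonical gene-table TSV dialect has columns
``genome_id  contig_id  start  end  strand  protein_id`` (protein_id empty
for non-coding loci). Ranks are always recomputed on read: genes are grouped
by contig, sorted by start (ties broken by end, then identifier) and indexed
0..n-1.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
from Bio import SearchIO
from gffutils.iterators import DataIterator

from .errors import ParseError, ValidationError
from .model import (
    DomainHit,
    GeneRecord,
    OrthologGroupMap,
    RMReference,
    TaxonRecord,
)

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = ["genome_id", "contig_id", "start", "end", "strand", "protein_id"]

#: GFF3 feature types treated as gene loci (each consumes one window rank).
DEFAULT_GFF_FEATURES = ("CDS", "rRNA", "tRNA", "ncRNA", "tmRNA", "pseudogene")

TAXONOMY_LEVELS = ["phylum", "class", "order", "family", "genus", "species"]


def _assign_ranks(raw: list[dict]) -> list[GeneRecord]:
    """Group raw loci by (genome, contig), sort by start (tie: end, then id)
    and assign 0-based ranks. Validates protein_id uniqueness per genome."""
    seen: dict[tuple[str, str], None] = {}
    for row in raw:
        pid = row["protein_id"]
        if pid is not None:
            key = (row["genome_id"], pid)
            if key in seen:
                raise ValidationError(
                    f"duplicate protein_id {pid!r} in genome {row['genome_id']!r}"
                )
            seen[key] = None
    records: list[GeneRecord] = []
    by_contig: dict[tuple[str, str], list[dict]] = {}
    for row in raw:
        by_contig.setdefault((row["genome_id"], row["contig_id"]), []).append(row)
    for (genome_id, contig_id), rows in by_contig.items():
        rows.sort(key=lambda r: (r["start"], r["end"], r["protein_id"] or ""))
        for rank, r in enumerate(rows):
            records.append(
                GeneRecord(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    rank=rank,
                    start=r["start"],
                    end=r["end"],
                    strand=r["strand"],
                    protein_id=r["protein_id"],
                )
            )
    return records


def read_gene_table(
    path,
    dialect: str = "tsv",
    genome_id: Optional[str] = None,
    feature_types: Sequence[str] = DEFAULT_GFF_FEATURES,
) -> list[GeneRecord]:
    """Read a gene table (``dialect`` "tsv" or "gff3") into ranked GeneRecords.

    For GFF3 input ``genome_id`` defaults to the file stem; the protein
    identifier is taken from the ``protein_id`` attribute, falling back to
    ``ID`` for coding features (non-coding features get none).
    """
    path = Path(path)
    if dialect == "tsv":
        raw = _read_gene_tsv(path)
    elif dialect == "gff3":
        raw = _read_gene_gff3(path, genome_id or path.stem, feature_types)
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    if not raw:
        logger.warning("gene table %s is empty", path)
        return []
    return _assign_ranks(raw)


def _read_gene_tsv(path: Path) -> list[dict]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed gene table: {exc}", path=path) from exc
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"gene table missing column(s) {missing}", path=path, line=1)
    raw = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            raw.append(
                {
                    "genome_id": row.genome_id,
                    "contig_id": row.contig_id,
                    "start": int(row.start),
                    "end": int(row.end),
                    "strand": row.strand,
                    "protein_id": row.protein_id or None,
                }
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"malformed gene-table line: {exc}", path=path, line=i) from exc
    return raw


def _read_gene_gff3(path: Path, genome_id: str, feature_types: Sequence[str]) -> list[dict]:
    wanted = set(feature_types)
    raw = []
    try:
        for feat in DataIterator(str(path)):
            if feat.featuretype not in wanted:
                continue
            attrs = feat.attributes
            pid = None
            if feat.featuretype == "CDS":
                pid = (attrs.get("protein_id") or attrs.get("ID") or [None])[0]
            raw.append(
                {
                    "genome_id": genome_id,
                    "contig_id": feat.seqid,
                    "start": int(feat.start),
                    "end": int(feat.end),
                    "strand": feat.strand if feat.strand in ("+", "-") else "+",
                    "protein_id": pid,
                }
            )
    except ParseError:
        raise
    except Exception as exc:  # gffutils raises assorted exceptions on bad lines
        raise ParseError(f"malformed GFF3: {exc}", path=path) from exc
    return raw


def write_gene_table(records: Iterable[GeneRecord], path) -> None:
    """Write GeneRecords to the canonical TSV dialect (round-trips losslessly)."""
    rows = [
        {
            "genome_id": g.genome_id,
            "contig_id": g.contig_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "protein_id": g.protein_id or "",
        }
        for g in sorted(records, key=lambda g: (g.genome_id, g.contig_id, g.rank))
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_domtblout(path) -> list[DomainHit]:
    """Read a HMMER3 per-domain table (hmmscan domtblout) into DomainHits.

    Uses the independent per-domain e-value and the envelope coordinates.
    File order of domain lines is preserved.
    """
    path = Path(path)
    # Cheap structural pre-check so errors can name the offending line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.split(None, 22)) < 23:
                raise ParseError(
                    "domtblout line has too few columns", path=path, line=lineno
                )
    hits: list[DomainHit] = []
    try:
        for qres in SearchIO.parse(str(path), "hmmscan3-domtab"):
            for hit in qres:
                for hsp in hit:
                    hits.append(
                        DomainHit(
                            protein_id=qres.id,
                            domain_name=hit.id,
                            accession=hit.accession if hit.accession != "-" else None,
                            evalue=float(hsp.evalue),
                            env_start=int(hsp.env_start) + 1,  # SearchIO is 0-based
                            env_end=int(hsp.env_end),
                            protein_len=int(qres.seq_len),
                        )
                    )
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"malformed domtblout: {exc}", path=path) from exc
    return hits


_DOMTBL_HEADER = (
    "#%-22s %-10s %5s %-20s %-10s %5s %9s %6s %5s %3s %3s %9s %9s %6s %5s %5s %5s %5s %5s %5s %5s %4s %s\n"
    % (
        "target name", "accession", "tlen", "query name", "accession", "qlen",
        "E-value", "score", "bias", "#", "of", "c-Evalue", "i-Evalue", "score",
        "bias", "from", "to", "from", "to", "from", "to", "acc",
        "description of target",
    )
)


def write_domtblout(hits: Iterable[DomainHit], path) -> None:
    """Write DomainHits in HMMER3 hmmscan domtblout layout (one domain/line)."""
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    with open(path, "w") as fh:
        fh.write(_DOMTBL_HEADER)
        for pid, phits in by_protein.items():
            n = len(phits)
            for i, h in enumerate(phits, start=1):
                tlen = h.env_end - h.env_start + 1
                qlen = h.protein_len or max(x.env_end for x in phits)
                fh.write(
                    f"{h.domain_name:<23}{h.accession or '-':<11}{tlen:>5} "
                    f"{pid:<20} {'-':<10}{qlen:>6} {h.evalue:9.2g} {50.0:6.1f} "
                    f"{0.0:5.1f} {i:>3} {n:>3} {h.evalue:9.2g} {h.evalue:9.2g} "
                    f"{50.0:6.1f} {0.0:5.1f} {1:>5} {tlen:>5} {h.env_start:>5} "
                    f"{h.env_end:>5} {h.env_start:>5} {h.env_end:>5} 0.98 -\n"
                )


def read_groups(path) -> OrthologGroupMap:
    """Read an OrthoMCL-style groups file (``OG_4: idA idB idC`` per line)."""
    path = Path(path)
    groups: dict[str, list[str]] = {}
    owner: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ParseError("groups line lacks 'label:' prefix", path=path, line=lineno)
            label, _, rest = line.partition(":")
            label = label.strip()
            members = rest.split()
            if not members:
                raise ParseError(f"group {label!r} lists no members", path=path, line=lineno)
            if len(members) < 2:
                logger.warning("%s:%d: singleton group %s", path, lineno, label)
            for m in members:
                if m in owner and owner[m] != label:
                    raise ValidationError(
                        f"protein {m!r} listed in both {owner[m]} and {label}"
                    )
                owner[m] = label
            groups.setdefault(label, []).extend(members)
    return OrthologGroupMap(groups)


def write_groups(ogmap: OrthologGroupMap, path) -> None:
    with open(path, "w") as fh:
        for label in sorted(ogmap.groups):
            fh.write(f"{label}: " + " ".join(ogmap.groups[label]) + "\n")


def read_rm_reference(path) -> RMReference:
    """Read the R-M reference TSV (columns: domain_name, rm_types comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("domain_name", "rm_types"):
        if col not in df.columns:
            raise ParseError(f"R-M reference missing column {col!r}", path=path, line=1)
    types = {
        row.domain_name: [t.strip() for t in row.rm_types.split(",") if t.strip()]
        for row in df.itertuples(index=False)
    }
    return RMReference(types)  # raises ValidationError on unknown labels


def write_rm_reference(rmref: RMReference, path) -> None:
    rows = [
        {"domain_name": name, "rm_types": ",".join(sorted(types))}
        for name, types in sorted(rmref.types.items())
    ]
    pd.DataFrame(rows, columns=["domain_name", "rm_types"]).to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> dict[str, TaxonRecord]:
    """Read the taxonomy TSV (genome_id + phylum/class/order/family/genus/species)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "genome_id" not in df.columns:
        raise ParseError("taxonomy missing column 'genome_id'", path=path, line=1)
    out: dict[str, TaxonRecord] = {}
    for d in df.to_dict("records"):  # itertuples would mangle the 'class' column
        gid = d["genome_id"]
        if gid in out:
            raise ValidationError(f"duplicate genome_id {gid!r} in taxonomy")
        out[gid] = TaxonRecord(
            genome_id=gid,
            phylum=d.get("phylum") or None,
            class_=d.get("class") or None,
            order=d.get("order") or None,
            family=d.get("family") or None,
            genus=d.get("genus") or None,
            species=d.get("species") or None,
        )
    return out


def write_taxonomy(taxonomy: Mapping[str, TaxonRecord], path) -> None:
    rows = [
        {
            "genome_id": t.genome_id,
            "phylum": t.phylum or "",
            "class": t.class_ or "",
            "order": t.order or "",
            "family": t.family or "",
            "genus": t.genus or "",
            "species": t.species or "",
        }
        for t in taxonomy.values()
    ]
    pd.DataFrame(rows, columns=["genome_id"] + TAXONOMY_LEVELS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------- networks

def _edge_attr_str(value) -> str:
    if isinstance(value, (set, frozenset)):
        return ",".join(sorted(value))
    return str(value)


def write_sif(graph: nx.DiGraph, path, relation: str = "adjacent_to") -> None:
    """Write a directed graph as SIF (``source relation target`` per edge)."""
    with open(path, "w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u}\t{relation}\t{v}\n")


def write_graphml(graph: nx.DiGraph, path) -> None:
    """Write GraphML with set-valued attributes serialized as sorted CSV strings."""
    g = nx.DiGraph()
    for n, attrs in graph.nodes(data=True):
        g.add_node(n, **{k: _edge_attr_str(v) for k, v in attrs.items()})
    for u, v, attrs in graph.edges(data=True):
        g.add_edge(u, v, **{k: _edge_attr_str(v_) for k, v_ in attrs.items()})
    nx.write_graphml(g, path)


def edge_table(graph: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {
            "source": u,
            "target": v,
            "weight": attrs.get("weight", 1),
            "genera": _edge_attr_str(attrs.get("genera", "")),
        }
        for u, v, attrs in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "weight", "genera"])


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    tables: Mapping[str, pd.DataFrame],
    network: Optional[nx.DiGraph],
    outdir,
) -> dict:
    """Write named tables as TSV and the network as SIF + GraphML + edge TSV.

    Returns (and writes as ``manifest.json``) a manifest listing every file
    with its row or edge count and content hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": []}
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        manifest["files"].append({"file": p.name, "rows": len(df), "sha256": sha256_of(p)})
    if network is not None:
        sif = outdir / "network.sif"
        gml = outdir / "network.graphml"
        edges = outdir / "network_edges.tsv"
        write_sif(network, sif)
        write_graphml(network, gml)
        edge_table(network).to_csv(edges, sep="\t", index=False)
        n_edges = network.number_of_edges()
        for p in (sif, gml, edges):
            manifest["files"].append(
                {"file": p.name, "edges": n_edges, "sha256": sha256_of(p)}
            )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_manifest(config: Mapping, inputs: Sequence, outputs: Sequence, path) -> dict:
    """Write a reproducibility manifest: config echo plus input/output hashes."""
    man = {
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in config.items()},
        "inputs": {str(p): sha256_of(p) for p in inputs if Path(p).exists()},
        "outputs": {str(p): sha256_of(p) for p in outputs if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(man, fh, indent=2)
    return man
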